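"""Variant effect mechanics: filtering, concordance, ranking, attribution."""

import numpy as np
import pandas as pd
import pytest

from scprofile.variants import (
    DeconvolutionBenchmark,
    Variant,
    VariantEffect,
    baseline_atac_peak_rank,
    baseline_expression_rank,
    deconvolve,
    filter_negligible,
    nearest_peak,
    rank_cell_types_by_effect,
    read_vcf,
    sign_concordance_by_distance,
    size_factor_normalize,
    write_vcf,
)


def make_effect(agg, per_type=None, dist=500):
    per_type = per_type if per_type is not None else pd.Series({"T0": agg})
    v = Variant("chr1", 100, "A", "C", "g0")
    return VariantEffect(v, per_type, agg, None, dist)


class TestVariant:
    def test_snv_only(self):
        with pytest.raises(ValueError):
            Variant("chr1", 5, "AT", "A", "g")

    def test_vcf_round_trip(self, tmp_path):
        vs = [Variant("chr1", 100, "A", "C", "g0"),
              Variant("chr2", 5, "G", "T", "g1")]
        path = tmp_path / "v.vcf"
        write_vcf(vs, path)
        assert read_vcf(path) == vs


class TestFilterNegligible:
    def test_all_zero(self):
        kept, frac = filter_negligible([make_effect(0.0)] * 4)
        assert kept == [] and frac == 0.0

    def test_boundary_is_inclusive(self):
        effects = [make_effect(0.04), make_effect(0.05), make_effect(0.5)]
        kept, frac = filter_negligible(effects)
        assert len(kept) == 2
        assert frac == pytest.approx(2 / 3)

    def test_zero_threshold_keeps_all(self):
        effects = [make_effect(x) for x in (0.0, 0.01, -0.02)]
        kept, _ = filter_negligible(effects, threshold=0.0)
        assert len(kept) == 3


class TestSignConcordance:
    def test_perfect_predictor(self):
        r = np.random.default_rng(0)
        effects, signs = [], []
        for _ in range(50):
            e = float(r.normal())
            effects.append(make_effect(e, dist=int(r.integers(0, 2000))))
            signs.append(np.sign(e))
        table = sign_concordance_by_distance(effects, signs, [0, 1000, 2000])
        assert (table["concordance"].dropna() == 1.0).all()

    def test_random_signs_near_half(self):
        r = np.random.default_rng(1)
        effects = [make_effect(float(r.normal()), dist=100) for _ in range(1000)]
        signs = r.choice([-1, 1], 1000)
        table = sign_concordance_by_distance(effects, signs, [0, 1000])
        assert abs(table["concordance"].iloc[0] - 0.5) < 0.05

    def test_empty_bin_is_missing(self):
        table = sign_concordance_by_distance(
            [make_effect(1.0, dist=10)], [1], [0, 100, 1_000_000]
        )
        assert np.isnan(table["concordance"].iloc[1])


class TestDeconvolve:
    def make_matrix(self, seed=0, n=40, types=("T0", "T1", "T2", "T3")):
        r = np.random.default_rng(seed)
        return pd.DataFrame(r.normal(0, 1, (n, len(types))),
                            index=[f"v{i}" for i in range(n)],
                            columns=list(types))

    def test_argmax_positives_give_precision_one(self):
        m = self.make_matrix()
        positives = {(v, m.loc[v].abs().idxmax()) for v in m.index}
        bench = deconvolve(m, positives, variance_quantile=0.0, ks=(1,))
        assert bench.precision_at["model"][1] == 1.0

    def test_random_positives_near_chance(self):
        m = self.make_matrix(seed=2, n=400)
        r = np.random.default_rng(3)
        positives = {(v, m.columns[r.integers(4)]) for v in m.index}
        bench = deconvolve(m, positives, variance_quantile=0.0, ks=(1,))
        assert abs(bench.precision_at["model"][1] - 0.25) < 0.08

    def test_k_beyond_cell_types_rejected(self):
        m = self.make_matrix()
        with pytest.raises(ValueError):
            deconvolve(m, set(), variance_quantile=0.0, ks=(5,))

    def test_variance_filter_keeps_top_tail(self):
        m = self.make_matrix(seed=4, n=100)
        bench = deconvolve(m, set(), variance_quantile=0.85, ks=(1,))
        assert len(bench.rankings["model"]) == len(
            m.index[m.var(axis=1) >= m.var(axis=1).quantile(0.85)]
        )

    def test_rankings_are_permutations(self):
        m = self.make_matrix(seed=5)
        bench = deconvolve(m, set(), variance_quantile=0.5, ks=(1,))
        for order in bench.rankings["model"].values():
            assert sorted(order) == sorted(m.columns)


class TestBaselines:
    def make_counts(self):
        cells = [f"c{i}" for i in range(6)]
        labels = pd.Series(dict(zip(cells, ["A", "A", "B", "B", "C", "C"])))
        counts = pd.DataFrame(
            {"g0": [10, 12, 0, 1, 3, 3], "g1": [1, 1, 1, 1, 1, 1]},
            index=cells, dtype=float,
        )
        return counts, labels

    def test_expression_rank_top_type(self):
        counts, labels = self.make_counts()
        order = baseline_expression_rank(counts, labels, "g0")
        assert order[0] == "A"

    def test_expression_rank_ties_stable_by_name(self):
        cells = ["c0", "c1"]
        labels = pd.Series({"c0": "B", "c1": "A"})
        counts = pd.DataFrame({"g": [1.0, 1.0]}, index=cells)
        assert baseline_expression_rank(counts, labels, "g") == ["A", "B"]

    def test_expression_rank_matches_brute_force(self):
        counts, labels = self.make_counts()
        norm = size_factor_normalize(counts)
        pb = norm.groupby(labels.values).sum()
        expected = list(pb["g0"].sort_values(ascending=False).index)
        assert baseline_expression_rank(counts, labels, "g0") == expected

    def test_nearest_peak_overlap_and_tie(self):
        peaks = [("p1", "chr1", 0, 100), ("p2", "chr1", 200, 300),
                 ("p3", "chr1", 400, 500)]
        assert nearest_peak(peaks, "chr1", 250)[0] == "p2"
        # equidistant between p2 end (300) and p3 start (400): pos 350
        # dist to p2 = 51, dist to p3 = 50 -> p3; at 349: 50 vs 51 -> p2
        assert nearest_peak(peaks, "chr1", 349)[0] == "p2"
        with pytest.raises(ValueError):
            nearest_peak(peaks, "chrX", 10)

    def test_atac_rank_uses_selected_peak(self):
        cells = [f"c{i}" for i in range(4)]
        labels = pd.Series(dict(zip(cells, ["A", "A", "B", "B"])))
        counts = pd.DataFrame(
            {"p1": [9.0, 9, 0, 0], "p2": [0.0, 0, 5, 5]}, index=cells
        )
        peaks = [("p1", "chr1", 0, 100), ("p2", "chr1", 500, 600)]
        v = Variant("chr1", 50, "A", "C", "g")
        assert baseline_atac_peak_rank(counts, labels, peaks, v)[0] == "A"
        v2 = Variant("chr1", 550, "A", "C", "g")
        assert baseline_atac_peak_rank(counts, labels, peaks, v2)[0] == "B"


def test_rank_by_effect_tie_break_by_name():
    row = pd.Series({"B": -0.5, "A": 0.5, "C": 0.1})
    assert rank_cell_types_by_effect(row) == ["A", "B", "C"]


class TestGradientPWM:
    def test_columns_sum_to_one_and_window_width(self, tiny_model):
        from scprofile.simulate import SimConfig, generate_world
        from scprofile.variants import gradient_pwm

        world = generate_world(SimConfig(
            n_chroms=2, chrom_length=16_384, n_genes=4, n_cells=12,
            n_variant_genes=1, seed=5,
        ))
        v = world.variants[0]
        gene = world.genes[v.gene]
        # a model whose input length matches the small world
        from scprofile.backbone import EncoderConfig
        from scprofile.model import ModelConfig, ProfileModel

        model = ProfileModel(ModelConfig(
            encoder=EncoderConfig(input_length=8192, channels=16,
                                  n_transformer_layers=1, seed=0),
            embedding_dim=world.config.embedding_dim, seed=0,
        ))
        labels = [world.cells.labels[b] for b in world.cells.barcodes]
        pwm = gradient_pwm(model, world.genome, v, gene,
                           world.cells.embedding, labels, labels[0])
        assert pwm.matrix.shape == (4, 10)
        np.testing.assert_allclose(pwm.matrix.sum(axis=0), 1.0, atol=1e-6)
        assert np.all(pwm.matrix > 0)

    def test_zero_gradient_gives_uniform_columns(self):
        # the normalization rule: 2^0 everywhere -> 0.25 per base
        grad = np.zeros((4, 10))
        mat = np.power(2.0, grad)
        mat /= mat.sum(axis=0, keepdims=True)
        np.testing.assert_allclose(mat, 0.25)


@pytest.fixture(scope="module")
def scoring_setup():
    from scprofile.backbone import EncoderConfig
    from scprofile.model import ModelConfig, ProfileModel
    from scprofile.simulate import SimConfig, generate_world

    world = generate_world(SimConfig(
        n_chroms=2, chrom_length=16_384, n_genes=4, n_cells=12,
        n_variant_genes=1, seed=6,
    ))
    model = ProfileModel(ModelConfig(
        encoder=EncoderConfig(input_length=8192, channels=16,
                              n_transformer_layers=1, seed=0),
        embedding_dim=world.config.embedding_dim, seed=0,
    ))
    labels = [world.cells.labels[b] for b in world.cells.barcodes]
    return world, model, labels


class TestScoreVariant:

    def test_alt_equals_ref_gives_zero_effect(self, scoring_setup):
        from scprofile.variants import score_variant

        world, model, labels = scoring_setup
        v0 = world.variants[0]
        v_same = Variant(v0.chrom, v0.pos, v0.ref, v0.ref, v0.gene)
        eff = score_variant(model, world.genome, v_same,
                            world.genes[v0.gene], world.cells.embedding,
                            labels)
        assert (eff.per_cell_type == 0).all()
        assert eff.aggregate == 0.0

    def test_aggregate_is_mean_of_per_type(self, scoring_setup):
        from scprofile.variants import score_variant

        world, model, labels = scoring_setup
        v = world.variants[0]
        eff = score_variant(model, world.genome, v, world.genes[v.gene],
                            world.cells.embedding, labels)
        assert eff.aggregate == pytest.approx(eff.per_cell_type.mean())
        assert eff.accessibility is not None
        assert eff.tss_distance is not None

    def test_reference_mismatch_names_observed_base(self, scoring_setup):
        from scprofile.variants import score_variant

        world, model, labels = scoring_setup
        v0 = world.variants[0]
        obs = world.genome.sequences[v0.chrom][v0.pos0]
        wrong = next(b for b in "ACGT" if b != obs)
        bad = Variant(v0.chrom, v0.pos, wrong, "A" if wrong != "A" else "C",
                      v0.gene)
        with pytest.raises(ValueError, match=obs):
            score_variant(model, world.genome, bad, world.genes[v0.gene],
                          world.cells.embedding, labels)
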