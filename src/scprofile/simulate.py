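"""Self-contained toy multiome world with planted regulatory logic.

The generator builds a small genome with genes, exons and promoter peaks,
plants transcription-factor motif sites whose activity differs by cell
type, and simulates 3'-biased spliced scRNA reads and peak-localized Tn5
insertions for a population of cells. Every downstream capability —
training, gene-count evaluation, motif effect scoring, variant effect
deconvolution — can then be exercised against known ground truth.

Planted regulation is multiplicative on the log scale: a gene with site
counts k_m of motifs with per-cell-type activities a_{t,m} has

    rate[t, g] = baseline * exp( sum_m k_{g,m} * a_{t,m} )

and observed reads are Poisson draws of per-cell rates normalized within
each cell type (so a cell's expected total is its depth). Cell embeddings
are the generator's latent cell-type centroids plus Gaussian noise — the
decoder only needs a vector that separates cell states, and embedding-model
internals are out of scope here.

The background genome is scrubbed of chance motif-consensus occurrences
before sites are planted, so a motif match in this world is a planted site:
recovery tests measure the model, not collisions in a random genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .backbone import EncoderConfig, TinyBackbone
from .fragments import FragmentRecord, FragmentStore
from .io import Gene, GeneSet
from .motifs import PWM
from .sequence import BASES, reverse_complement
from .variants import Variant

BIN_WIDTH = 32

# Consensus 8-mers for the default planted motif set; chosen pairwise
# distinct from each other and from their reverse complements.
DEFAULT_MOTIF_CONSENSUS = {
    "ACT_UNIV": "GGATTCCG",   # activator in every cell type
    "ACT_A": "CATGCCAT",      # activator in cell type T0 only
    "ACT_B": "TTGCGAGA",      # activator in cell type T1 only
    "REP_C": "CCAATGGC",      # repressor in cell type T2 only
}
CONSENSUS_PROB = 0.94  # per-position probability of the consensus base

# Gene-structure signals written into the sequence so that transcript
# anatomy is inferable from DNA, as in real genomes: a core-promoter
# element at the TSS, splice donor/acceptor words at intron boundaries,
# and a polyadenylation signal at the transcript 3' end. Without these a
# sequence-to-profile model would face irreducible uncertainty about
# where coverage belongs.
STRUCTURE_SIGNALS = {
    "promoter": "TATAAAGCGC",
    "donor": "GTAAGT",
    "acceptor": "TTTCAG",
    "polya": "AATAAA",
}


@dataclass
class SimConfig:
    n_chroms: int = 8
    chrom_length: int = 98_304  # must be a positive multiple of 32
    n_genes: int = 96
    n_cells: int = 240
    n_cell_types: int = 3
    embedding_dim: int = 14
    embedding_noise: float = 0.3
    depth_factor_sigma: float = 0.25
    window_length: int = 8_192
    # gene anatomy: "uniform" gives every gene the same canonical 2-exon
    # layout (desk-scale canonicalization so that learning capacity goes to
    # regulation rather than anatomy); "random" varies exon number/size
    exon_layout: str = "uniform"
    strand_mode: str = "plus"  # "plus" (canonical orientation) | "both"
    read_length: int = 96
    three_prime_bias: float = 0.003  # geometric decay per bp from the 3' end
    universal_activity: float = 0.8
    specific_activity: float = 1.5
    peak_activity_scale: float = 0.5  # accessibility responds more weakly
    n_variant_genes: int = 6
    atac_frag_range: tuple = (60, 150)
    atac_background: float = 0.05  # fraction of fragments outside peaks
    peak_width: int = 400  # promoter peaks
    site_peak_width: int = 128  # accessible footprint around bound sites
    constitutive_site_openness: float = 2.0  # openness of variant-site peaks
    seed: int = 1

    def __post_init__(self):
        if self.chrom_length <= 0 or self.chrom_length % BIN_WIDTH:
            raise ValueError(
                f"chrom_length must be a positive multiple of {BIN_WIDTH}, "
                f"got {self.chrom_length}"
            )
        if self.n_cell_types < 2:
            raise ValueError("need at least 2 cell types")


@dataclass
class ToyGenome:
    chrom_names: list
    sequences: dict  # chrom -> DNA string (ACGT only)
    seed: int

    def __post_init__(self):
        for c, s in self.sequences.items():
            if len(s) % BIN_WIDTH:
                raise ValueError(f"{c}: length {len(s)} not a multiple of 32")
            if set(s) - set(BASES):
                raise ValueError(f"{c}: non-ACGT characters")

    @property
    def chrom_sizes(self) -> dict:
        return {c: len(s) for c, s in self.sequences.items()}


@dataclass
class ToyCellPopulation:
    barcodes: list
    cell_type: list  # label per cell
    embedding: np.ndarray  # (n_cells, E)
    depth_factor: np.ndarray  # positive, mean ~1
    centroids: np.ndarray  # (n_types, E) latent coordinates

    def __post_init__(self):
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be unique")

    @property
    def labels(self) -> dict:
        return dict(zip(self.barcodes, self.cell_type))

    @property
    def cell_types(self) -> list:
        return sorted(set(self.cell_type))


@dataclass(frozen=True)
class PlantedSite:
    motif: str
    chrom: str
    start: int
    end: int
    strand: str
    gene: str


@dataclass
class PlantedRegulation:
    motif_pwms: list  # [PWM]
    motif_sites: dict  # motif name -> [PlantedSite]
    activity: pd.DataFrame  # cell types x motifs (signed log-scale effects)
    site_counts: pd.DataFrame  # genes x motifs
    variant_truth: pd.DataFrame  # variant_id, gene, causal_type, expected_sign


@dataclass
class ToyWorld:
    config: SimConfig
    genome: ToyGenome
    genes: GeneSet
    peaks: list  # [(name, chrom, start, end)]
    cells: ToyCellPopulation
    regulation: PlantedRegulation
    rate_table: pd.DataFrame  # cell types x genes (unnormalized rates)
    peak_intensity: pd.DataFrame  # cell types x peaks
    splits: dict = field(default_factory=dict)  # gene -> train|valid|test
    variants: list = field(default_factory=list)

    # -- derived ground truth ---------------------------------------------
    def genes_in_fold(self, fold: str) -> list:
        return [g for g in self.genes if self.splits[g.name] == fold]

    def expected_rna_reads(self, depth: float) -> pd.DataFrame:
        """Expected pseudobulk read counts (cell types x genes)."""
        rates = self.rate_table
        share = rates.div(rates.sum(axis=1), axis=0)
        df = pd.Series(self.cells.depth_factor, index=self.cells.barcodes)
        lab = pd.Series(self.cells.cell_type, index=self.cells.barcodes)
        df_per_type = df.groupby(lab.values).sum()
        return share.mul(df_per_type, axis=0) * depth

    def expected_atac_insertions(self, depth: float) -> pd.DataFrame:
        """Expected pseudobulk insertion counts per peak (types x peaks)."""
        share = self.peak_intensity.div(self.peak_intensity.sum(axis=1), axis=0)
        df = pd.Series(self.cells.depth_factor, index=self.cells.barcodes)
        lab = pd.Series(self.cells.cell_type, index=self.cells.barcodes)
        df_per_type = df.groupby(lab.values).sum()
        return share.mul(df_per_type, axis=0) * depth * (
            1.0 - self.config.atac_background
        ) * 2.0

    def split_regions(self) -> list:
        """Region-level split: one window per gene with its fold label."""
        L = self.config.window_length
        out = []
        for g in self.genes:
            start = g.midpoint - L // 2
            out.append((g.chrom, max(start, 0), start + L, g.name,
                        self.splits[g.name]))
        return out

    def write(self, outdir) -> dict:
        """Write FASTA/GTF/BED/TSV/VCF artifacts; returns the paths."""
        import os

        from . import io as sio
        from .variants import write_vcf

        os.makedirs(outdir, exist_ok=True)
        paths = {}

        def p(name):
            paths[name] = os.path.join(str(outdir), name)
            return paths[name]

        sio.write_fasta(self.genome.sequences, p("genome.fa"))
        sio.write_gtf(self.genes, p("genes.gtf"))
        sio.write_bed([(c, s, e, n) for n, c, s, e in self.peaks], p("peaks.bed"))
        sio.write_bed(self.split_regions(), p("splits.bed"))
        sio.write_embeddings_tsv(self.cells.barcodes, self.cells.embedding,
                                 p("embeddings.tsv"))
        sio.write_cell_metadata(self.cells.barcodes, self.cells.labels,
                                self.cells.depth_factor, p("cells.tsv"))
        if self.variants:
            truth = self.regulation.variant_truth.set_index("variant_id")
            extra = [
                f"CAUSAL_TYPE={truth.loc[vid, 'causal_type']}"
                for vid in truth.index
            ]
            write_vcf(self.variants, p("variants.vcf"), extra)
        self.rate_table.to_csv(p("rates.tsv"), sep="\t")
        return paths


def _consensus_pwm(name: str, consensus: str) -> PWM:
    W = len(consensus)
    mat = np.full((4, W), (1.0 - CONSENSUS_PROB) / 3.0)
    for j, b in enumerate(consensus):
        mat[BASES.index(b), j] = CONSENSUS_PROB
    return PWM(name, mat)


def default_motifs() -> list:
    return [_consensus_pwm(n, c) for n, c in DEFAULT_MOTIF_CONSENSUS.items()]


def default_activity(n_cell_types: int, universal: float, specific: float
                     ) -> pd.DataFrame:
    types = [f"T{i}" for i in range(n_cell_types)]
    names = list(DEFAULT_MOTIF_CONSENSUS)
    act = pd.DataFrame(0.0, index=types, columns=names)
    act["ACT_UNIV"] = universal
    act.loc[types[0], "ACT_A"] = specific
    act.loc[types[1 % n_cell_types], "ACT_B"] = specific
    act.loc[types[2 % n_cell_types], "REP_C"] = -specific
    return act


def _find_all(seq: str, word: str) -> list:
    out, i = [], seq.find(word)
    while i != -1:
        out.append(i)
        i = seq.find(word, i + 1)
    return out


def _scrub_chance_matches(sequences: dict, consensi: list,
                          rng: np.random.Generator,
                          protected: dict | None = None,
                          max_rounds: int = 50) -> dict:
    """Mutate random bases until no consensus word (either strand) occurs
    outside protected spans."""
    protected = protected or {}
    words = set()
    for c in consensi:
        words.add(c)
        words.add(reverse_complement(c))
    seqs = {c: list(s) for c, s in sequences.items()}
    for _ in range(max_rounds):
        dirty = False
        for chrom, seq_list in seqs.items():
            seq = "".join(seq_list)
            prot = protected.get(chrom, [])
            for w in sorted(words):
                for pos in _find_all(seq, w):
                    span = range(pos, pos + len(w))
                    free = [i for i in span
                            if not any(s <= i < e for s, e in prot)]
                    if not free:
                        continue  # fully inside a planted site
                    dirty = True
                    i = int(rng.choice(free))
                    old = seq_list[i]
                    choices = [b for b in BASES if b != old]
                    seq_list[i] = choices[int(rng.integers(3))]
        if not dirty:
            break
    else:
        raise RuntimeError("could not scrub chance motif matches")
    return {c: "".join(s) for c, s in seqs.items()}


def _place_genes(config: SimConfig, rng: np.random.Generator) -> GeneSet:
    genes = []
    per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    margin = config.window_length // 2 + 600
    idx = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        n_here = min(per_chrom, config.n_genes - idx)
        if n_here <= 0:
            break
        centers = np.linspace(margin, config.chrom_length - margin, n_here)
        centers = centers + rng.integers(-250, 250, size=n_here)
        for center in centers:
            if config.exon_layout == "uniform":
                exon_spans = [(0, 600), (1000, 1600)]
                pos = 1600
            else:
                n_exons = int(rng.integers(1, 4))
                pos = 0
                exon_spans = []
                for k in range(n_exons):
                    if k > 0:
                        pos += int(rng.integers(200, 600))  # intron
                    elen = int(rng.integers(300, 700))
                    exon_spans.append((pos, pos + elen))
                    pos += elen
            g_len = pos
            g_start = int(center) - g_len // 2
            exons = tuple((g_start + s, g_start + e) for s, e in exon_spans)
            strand = "+" if (config.strand_mode == "plus"
                             or rng.random() < 0.5) else "-"
            genes.append(Gene(f"g{idx:02d}", chrom, g_start, g_start + g_len,
                              strand, exons))
            idx += 1
    return GeneSet(genes)


def _assign_sites(config: SimConfig, genes: GeneSet,
                  rng: np.random.Generator) -> tuple:
    """Decide per-gene site counts and which genes carry planted variants.

    Non-variant genes cycle through specific-motif profiles so every motif
    is represented in every fold; variant genes carry one site of their
    causal motif plus two of the other activator, making the causal cell
    type deliberately NOT the top-expressing one.
    """
    motif_names = list(DEFAULT_MOTIF_CONSENSUS)
    counts = pd.DataFrame(0, index=genes.names, columns=motif_names)
    # variant genes sit on the training chromosomes (the held-out
    # chromosome is reserved for gene-level generalization)
    held_chrom = f"chr{config.n_chroms}"
    candidates = [g.name for g in genes if g.chrom != held_chrom]
    step = max(1, len(candidates) // max(config.n_variant_genes, 1))
    variant_genes = candidates[::step][:config.n_variant_genes]
    # each non-variant gene carries at most one specific motif on top of a
    # small universal-activator dose: dose-response and type-specific
    # regulation stay individually identifiable at desk scale
    profiles = [  # cycled over non-variant genes
        {}, {"ACT_UNIV": 1}, {"ACT_UNIV": 2},
        {"ACT_A": 1}, {"ACT_B": 1}, {"REP_C": 1},
        {"ACT_UNIV": 1, "ACT_A": 1}, {"ACT_UNIV": 1, "ACT_B": 1},
        {"ACT_UNIV": 2, "REP_C": 1},
        {"ACT_A": 2}, {"ACT_B": 2}, {"ACT_UNIV": 1, "REP_C": 2},
    ]
    pi = 0
    for name in genes.names:
        if name in variant_genes:
            causal = "ACT_A" if variant_genes.index(name) % 2 == 0 else "ACT_B"
            other = "ACT_B" if causal == "ACT_A" else "ACT_A"
            counts.loc[name, causal] = 1
            counts.loc[name, other] = 2
            counts.loc[name, "ACT_UNIV"] = 1
        else:
            for m, k in profiles[pi % len(profiles)].items():
                counts.loc[name, m] += k
            pi += 1
    return counts, variant_genes


def generate_world(config: SimConfig | None = None, **overrides) -> ToyWorld:
    """Build the deterministic toy world for a configuration's seed."""
    if config is None:
        config = SimConfig(**overrides)
    ss = np.random.SeedSequence(config.seed)
    (rng_genome, rng_genes, rng_sites, rng_cells,
     rng_scrub, rng_place) = [np.random.default_rng(s) for s in ss.spawn(6)]

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    sequences = {
        c: "".join(np.array(list(BASES))[rng_genome.integers(0, 4,
                                                             config.chrom_length)])
        for c in chrom_names
    }
    motifs = default_motifs()
    consensi = [DEFAULT_MOTIF_CONSENSUS[m.name] for m in motifs]
    scrub_words = consensi + list(STRUCTURE_SIGNALS.values())
    sequences = _scrub_chance_matches(sequences, scrub_words, rng_scrub)

    genes = _place_genes(config, rng_genes)
    site_counts, variant_gene_names = _assign_sites(config, genes, rng_sites)

    # write gene-structure signals (promoter, splice sites, polyA) so the
    # transcript anatomy is readable from the sequence
    seq_lists = {c: list(s) for c, s in sequences.items()}
    structure_spans: dict[str, list] = {c: [] for c in chrom_names}

    def plant_word(chrom, pos, word, strand):
        w = word if strand == "+" else reverse_complement(word)
        seq_lists[chrom][pos:pos + len(w)] = list(w)
        structure_spans[chrom].append((pos, pos + len(w)))

    for gene in genes:
        sig = STRUCTURE_SIGNALS
        if gene.strand == "+":
            plant_word(gene.chrom, gene.start - 24, sig["promoter"], "+")
            plant_word(gene.chrom, gene.end - 10, sig["polya"], "+")
        else:
            plant_word(gene.chrom, gene.end + 14, sig["promoter"], "-")
            plant_word(gene.chrom, gene.start + 4, sig["polya"], "-")
        for (s1, e1), (s2, e2) in zip(gene.exons[:-1], gene.exons[1:]):
            if gene.strand == "+":
                plant_word(gene.chrom, e1, sig["donor"], "+")
                plant_word(gene.chrom, s2 - 6, sig["acceptor"], "+")
            else:
                plant_word(gene.chrom, s2 - 6, sig["donor"], "-")
                plant_word(gene.chrom, e1, sig["acceptor"], "-")

    # plant regulatory sites in gene flanks (outside the gene body),
    # writing the consensus
    motif_sites: dict[str, list] = {m.name: [] for m in motifs}
    W = len(next(iter(DEFAULT_MOTIF_CONSENSUS.values())))
    flank = config.window_length // 2 - 600
    site_margin = config.site_peak_width // 2 + 8
    for gene in genes:
        # keep sites (and their accessibility footprints) clear of the gene
        # body, the promoter peak, and each other, so peaks are disjoint
        occupied = [(gene.start - config.peak_width - 40,
                     gene.end + config.peak_width + 40)]
        occupied += [(s - 12, e + 12) for s, e in
                     structure_spans[gene.chrom]]
        lo = gene.midpoint - flank
        hi = gene.midpoint + flank - W
        for motif_name in site_counts.columns:
            consensus = DEFAULT_MOTIF_CONSENSUS[motif_name]
            for _ in range(int(site_counts.loc[gene.name, motif_name])):
                for _try in range(300):
                    pos = int(rng_place.integers(lo, hi))
                    if any(s < pos + W + site_margin and
                           pos - site_margin < e for s, e in occupied):
                        continue
                    break
                else:
                    raise RuntimeError("could not place motif site")
                strand = "+" if rng_place.random() < 0.5 else "-"
                word = consensus if strand == "+" else reverse_complement(consensus)
                seq_lists[gene.chrom][pos:pos + W] = list(word)
                occupied.append((pos, pos + W))
                motif_sites[motif_name].append(
                    PlantedSite(motif_name, gene.chrom, pos, pos + W, strand,
                                gene.name)
                )
    sequences = {c: "".join(s) for c, s in seq_lists.items()}
    protected = {c: list(spans) for c, spans in structure_spans.items()}
    for sites in motif_sites.values():
        for s in sites:
            protected.setdefault(s.chrom, []).append((s.start, s.end))
    sequences = _scrub_chance_matches(sequences, scrub_words, rng_scrub,
                                      protected)
    genome = ToyGenome(chrom_names, sequences, config.seed)

    # activity and closed-form rate table
    activity = default_activity(config.n_cell_types,
                                config.universal_activity,
                                config.specific_activity)
    log_rate = site_counts.values @ activity.values.T  # genes x types
    rate_table = pd.DataFrame(np.exp(log_rate.T), index=activity.index,
                              columns=genes.names)
    # variant-carrying sites (one causal site per variant gene) are marked
    # before peak construction: their chromatin is constitutively open, so
    # the expression effect of the variant is NOT mirrored in accessibility
    variant_sites = {}
    for vi, gname in enumerate(variant_gene_names):
        causal = "ACT_A" if vi % 2 == 0 else "ACT_B"
        site = next(s for s in motif_sites[causal] if s.gene == gname)
        variant_sites[gname] = site

    # peaks: a promoter peak per gene (openness follows the gene's planted
    # regulation, attenuated) plus an accessible footprint at every bound
    # motif site (open where the motif's TF is active)
    peaks = []
    intensity_cols = {}
    for gene in genes:
        tss = gene.tss
        start = tss - config.peak_width // 2
        name = f"peak_{gene.name}"
        peaks.append((name, gene.chrom, start, start + config.peak_width))
        log_int = config.peak_activity_scale * (
            site_counts.loc[gene.name].values @ activity.values.T
        )
        intensity_cols[name] = np.exp(log_int)
    site_index = 0
    constitutive = set(id(s) for s in variant_sites.values())
    for motif_name, sites in motif_sites.items():
        for s in sites:
            name = f"sitepeak_{site_index:03d}_{motif_name}"
            site_index += 1
            mid = (s.start + s.end) // 2
            half = config.site_peak_width // 2
            peaks.append((name, s.chrom, mid - half, mid + half))
            if id(s) in constitutive:
                intensity_cols[name] = np.full(
                    len(activity.index), config.constitutive_site_openness
                )
            else:
                intensity_cols[name] = np.exp(activity[motif_name].values)
    peak_intensity = pd.DataFrame(
        intensity_cols, index=activity.index
    )[[p[0] for p in peaks]]

    # cells: balanced types, latent centroids + Gaussian noise
    types = list(activity.index)
    barcodes = [f"cell{i:04d}" for i in range(config.n_cells)]
    assignment = [types[i % len(types)] for i in range(config.n_cells)]
    assignment = list(rng_cells.permutation(assignment))
    centroids = rng_cells.normal(0.0, 1.0, (len(types), config.embedding_dim)) * 2.0
    emb = np.stack([centroids[types.index(t)] for t in assignment])
    emb = emb + rng_cells.normal(0.0, config.embedding_noise, emb.shape)
    depth_factor = rng_cells.lognormal(0.0, config.depth_factor_sigma,
                                       config.n_cells)
    depth_factor /= depth_factor.mean()
    cells = ToyCellPopulation(barcodes, assignment, emb, depth_factor,
                              centroids)

    # planted variants: break the causal motif's consensus at a fixed column
    variants = []
    truth_rows = []
    var_col = 3  # position inside the 8-mer whose base the variant flips
    for vi, gname in enumerate(variant_gene_names):
        causal = "ACT_A" if vi % 2 == 0 else "ACT_B"
        causal_type = types[0] if causal == "ACT_A" else types[1]
        site = next(s for s in motif_sites[causal] if s.gene == gname)
        pos0 = site.start + var_col
        ref = genome.sequences[site.chrom][pos0]
        alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]
        vid = f"var{vi}"
        variants.append(Variant(site.chrom, pos0 + 1, ref, alt, gname))
        truth_rows.append({"variant_id": vid, "gene": gname,
                           "causal_type": causal_type, "expected_sign": -1})
    truth = pd.DataFrame(truth_rows)

    # region-level split by chromosome: last chromosome holds valid + test
    splits = {}
    last = chrom_names[-1]
    held = [g.name for g in genes if g.chrom == last]
    n_valid = max(1, len(held) * 2 // 5)
    for g in genes:
        if g.chrom != last:
            splits[g.name] = "train"
        elif g.name in held[:n_valid]:
            splits[g.name] = "valid"
        else:
            splits[g.name] = "test"

    regulation = PlantedRegulation(motifs, motif_sites, activity, site_counts,
                                   truth)
    return ToyWorld(config, genome, genes, peaks, cells, regulation,
                    rate_table, peak_intensity, splits, variants)


# -- fragment simulation -----------------------------------------------------

def _exons_in_transcript_order(gene: Gene) -> list:
    return list(gene.exons) if gene.strand == "+" else list(gene.exons)[::-1]


def transcript_to_genomic(gene: Gene, u: int, v: int) -> list:
    """Map transcript-coordinate interval [u, v) (5'->3') to sorted genomic
    blocks, splitting across exon junctions."""
    blocks = []
    offset = 0
    for s, e in _exons_in_transcript_order(gene):
        elen = e - s
        lo, hi = max(u - offset, 0), min(v - offset, elen)
        if hi > lo:
            if gene.strand == "+":
                blocks.append((s + lo, s + hi))
            else:
                blocks.append((e - hi, e - lo))
        offset += elen
    return sorted(blocks)


def simulate_rna_fragments(world: ToyWorld, depth: float,
                           seed: int | None = None) -> FragmentStore:
    """Simulate spliced, 3'-biased scRNA reads as fragment records.

    Per cell, gene read counts are Poisson(depth * depth_factor * p_g) with
    p_g the gene's share of its cell type's total rate. Read starts decay
    geometrically with distance from the transcript 3' end (bias 0 =
    uniform); junction-spanning reads emit one record per exonic block, on
    the gene's strand. The realized per-cell x per-gene read-count matrix
    is attached as ``store.simulated_read_counts``.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    for gene in world.genes:
        if not gene.exons:
            raise ValueError(f"gene {gene.name} has no exons")
    cfg = world.config
    rng = np.random.default_rng(cfg.seed + 101 if seed is None else seed)
    rates = world.rate_table
    share = rates.div(rates.sum(axis=1), axis=0)
    type_idx = [world.cells.cell_types.index(t) for t in world.cells.cell_type]
    p = share.values[type_idx]  # cells x genes
    lam = depth * world.cells.depth_factor[:, None] * p
    counts = rng.poisson(lam)
    records = []
    q = cfg.three_prime_bias
    for gi, gene in enumerate(world.genes):
        T_len = gene.transcript_length
        if q > 0:
            w = (1.0 - q) ** (T_len - 1 - np.arange(T_len))
            w = w / w.sum()
        else:
            w = None
        for ci, barcode in enumerate(world.cells.barcodes):
            n = int(counts[ci, gi])
            if n == 0:
                continue
            starts = rng.choice(T_len, size=n, p=w) if w is not None \
                else rng.integers(0, T_len, size=n)
            for u in starts:
                v = min(int(u) + cfg.read_length, T_len)
                for bs, be in transcript_to_genomic(gene, int(u), v):
                    records.append(FragmentRecord(
                        gene.chrom, bs, be - bs, barcode, 1, gene.strand
                    ))
    store = FragmentStore.from_records(records, "rna", world.cells.barcodes,
                                       world.genome.chrom_sizes)
    store.simulated_read_counts = pd.DataFrame(
        counts, index=world.cells.barcodes, columns=world.genes.names
    )
    return store


def simulate_atac_fragments(world: ToyWorld, depth: float,
                            seed: int | None = None) -> FragmentStore:
    """Simulate Tn5 fragments concentrated in peaks.

    Per cell, Poisson(depth * depth_factor) fragments are split between
    peaks (chosen by the cell type's peak-intensity shares, both ends kept
    inside the peak) and uniform background at the configured rate.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    cfg = world.config
    rng = np.random.default_rng(cfg.seed + 202 if seed is None else seed)
    share = world.peak_intensity.div(world.peak_intensity.sum(axis=1), axis=0)
    peaks = world.peaks
    chrom_names = world.genome.chrom_names
    sizes = world.genome.chrom_sizes
    lmin, lmax = cfg.atac_frag_range
    records = []
    for ci, barcode in enumerate(world.cells.barcodes):
        t = world.cells.cell_type[ci]
        n = rng.poisson(depth * world.cells.depth_factor[ci])
        if n == 0:
            continue
        n_bg = rng.binomial(n, cfg.atac_background)
        n_peak = n - n_bg
        probs = share.loc[t].values
        if probs.sum() > 0 and n_peak > 0:
            choice = rng.choice(len(peaks), size=n_peak, p=probs / probs.sum())
            for pi in choice:
                _, chrom, ps, pe = peaks[pi]
                flen = int(rng.integers(lmin, min(lmax, pe - ps) + 1))
                start = int(rng.integers(ps, pe - flen + 1))
                records.append(FragmentRecord(chrom, start, flen, barcode))
        for _ in range(n_bg):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            flen = int(rng.integers(lmin, lmax + 1))
            start = int(rng.integers(0, sizes[chrom] - flen))
            records.append(FragmentRecord(chrom, start, flen, barcode))
    return FragmentStore.from_records(records, "atac", world.cells.barcodes,
                                      sizes)


def make_tiny_backbone(config: EncoderConfig | None = None, **overrides
                       ) -> TinyBackbone:
    """Desk-scale trainable sequence encoder satisfying the encoder
    contract (L/32 output bins; adaptable convolution / attention / MLP
    submodules); deterministic per seed."""
    if config is None:
        config = EncoderConfig(**overrides)
    return TinyBackbone(config)
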