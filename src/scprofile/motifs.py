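"""PWM scanning, in silico motif mutation, and TF motif effect scores.

Scanning follows the FIMO scheme: a hit's log-odds score (log2 of PWM
probability over background, summed over positions) is converted to a
p-value under the background distribution by dynamic programming over the
discretized per-position score distribution; hits are positions on either
strand with p <= 1e-4 (the conventional default).

The TF motif effect score measures how much predicted expression (or total
locus accessibility) changes when all matched binding sites around a gene
are simultaneously replaced by random sequence: per cell, the mean log2
fold-change between reference and mutated predictions across the evaluated
genes — positive for activators, negative for repressors. Replacement is
repeated (default 10 draws) to average out spurious motif creation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragments import BIN_WIDTH
from .inference import gene_window, pearson, predict
from .sequence import BASES, extract_window

DEFAULT_P_THRESHOLD = 1e-4
DEFAULT_N_REPLICATES = 10
TARGET_GENE_THRESHOLD = 0.1
_BASE_TO_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass
class PWM:
    """Position weight matrix: per-position base probabilities (4 x W).

    Columns sum to 1; a probability floor keeps all entries positive so
    log-odds scores are finite. Background defaults to uniform.
    """

    name: str
    matrix: np.ndarray  # (4, W)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    floor: float = 1e-3

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must be 4 x W")
        self.matrix = np.clip(self.matrix, self.floor, None)
        self.matrix /= self.matrix.sum(axis=0, keepdims=True)
        self.background = np.asarray(self.background, dtype=np.float64)
        self._pvalue_table = None

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background[:, None])

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.matrix[::-1, ::-1].copy(),
                   self.background[::-1].copy(), self.floor)

    # -- p-value calibration ----------------------------------------------
    def pvalue_table(self, step: float = 1e-3):
        """Survival function of the log-odds score under the background.

        Scores are discretized to ``step`` bits; returns (offset, sf) such
        that P(score >= s) ~= sf[round(s/step) - offset], exact up to a
        discretization error bounded by width * step in score.
        """
        if self._pvalue_table is not None and self._pvalue_table[2] == step:
            return self._pvalue_table[:2]
        lo = np.round(self.log_odds / step).astype(np.int64)  # (4, W)
        pmf = np.array([1.0])
        offset = 0
        for j in range(self.width):
            col = lo[:, j]
            cmin, cmax = int(col.min()), int(col.max())
            col_pmf = np.zeros(cmax - cmin + 1)
            for b in range(4):
                col_pmf[col[b] - cmin] += self.background[b]
            pmf = np.convolve(pmf, col_pmf)
            offset += cmin
        sf = np.cumsum(pmf[::-1])[::-1]
        self._pvalue_table = (offset, sf, step)
        return offset, sf

    def pvalue(self, score: float, step: float = 1e-3) -> float:
        offset, sf = self.pvalue_table(step)
        idx = int(np.round(score / step)) - offset
        if idx < 0:
            return 1.0
        if idx >= len(sf):
            return float(sf[-1])
        return float(min(sf[idx], 1.0))


@dataclass(frozen=True)
class MotifHit:
    chrom: str
    start: int  # 0-based, on the forward strand
    end: int
    strand: str
    score: float
    pvalue: float


def _scores_one_strand(seq_idx: np.ndarray, valid: np.ndarray,
                       lo: np.ndarray) -> np.ndarray:
    """Log-odds scores at every start position; windows containing
    ambiguous bases score -inf."""
    W = lo.shape[1]
    n = len(seq_idx) - W + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    ok = np.ones(n, dtype=bool)
    for j in range(W):
        col_idx = seq_idx[j:j + n]
        scores += lo[:, j][col_idx]
        ok &= valid[j:j + n]
    scores[~ok] = -np.inf
    return scores


def scan(sequence: str, pwm: PWM, p_threshold: float = DEFAULT_P_THRESHOLD,
         chrom: str = ".", offset: int = 0, step: float = 1e-3
         ) -> list[MotifHit]:
    """Scan both strands; hits are positions with p-value <= threshold.

    ``offset`` shifts reported coordinates (scanning a window of a larger
    chromosome). A motif wider than the sequence yields no hits.
    """
    seq = sequence.upper()
    if pwm.width > len(seq):
        return []
    idx = np.zeros(len(seq), dtype=np.int64)
    valid = np.zeros(len(seq), dtype=bool)
    for b, i in _BASE_TO_IDX.items():
        m = np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)
        idx[m] = i
        valid |= m
    hits = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        scores = _scores_one_strand(idx, valid, mat.log_odds)
        for pos in np.nonzero(np.isfinite(scores))[0]:
            p = pwm.pvalue(scores[pos], step)
            if p <= p_threshold:
                hits.append(MotifHit(chrom, offset + int(pos),
                                     offset + int(pos) + pwm.width,
                                     strand, float(scores[pos]), p))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def merge_hit_spans(hits) -> list[tuple[int, int]]:
    """Merge overlapping hit spans into disjoint replacement spans."""
    spans = sorted((h.start, h.end) for h in hits)
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def mutate_sites(sequence: str, hits, rng: np.random.Generator,
                 n_replicates: int = DEFAULT_N_REPLICATES) -> list[str]:
    """Replace ALL hit spans simultaneously with i.i.d. uniform ACGT.

    Returns ``n_replicates`` mutated copies differing only in the random
    replacement draws; positions outside hit spans are untouched.
    """
    spans = merge_hit_spans(hits)
    for s, e in spans:
        if s < 0 or e > len(sequence):
            raise ValueError(f"hit span [{s}, {e}) outside sequence")
    out = []
    for _ in range(n_replicates):
        seq = list(sequence)
        for s, e in spans:
            seq[s:e] = rng.choice(list(BASES), size=e - s)
        out.append("".join(seq))
    return out


# -- effect tables -----------------------------------------------------------

@dataclass
class EffectTable:
    """Per-cell x per-gene log2 fold-changes for one TF, plus the
    gene-averaged per-cell score."""

    tf: str
    assay: str  # "expression" | "accessibility"
    gene_effects: pd.DataFrame  # genes x cells
    cell_scores: pd.Series  # per cell (mean over genes)

    def cell_type_scores(self, labels) -> pd.Series:
        lab = pd.Series(labels).reindex(self.cell_scores.index)
        return self.cell_scores.groupby(lab.values).mean()

    def cell_type_gene_effects(self, labels) -> pd.DataFrame:
        lab = pd.Series(labels).reindex(self.gene_effects.columns)
        return self.gene_effects.T.groupby(lab.values).mean().T


def _window_readout(model, genome, gene, seqs, embeddings, assay: str
                    ) -> np.ndarray:
    """Predicted per-cell readout for each sequence of a gene window:
    exonic expression sum, or total ATAC signal over all output bins."""
    L = model.config.encoder.input_length
    start = gene_window(gene, L)
    crop = model.config.n_output_bins
    bin0 = start + ((L // BIN_WIDTH) - crop) // 2 * BIN_WIDTH
    out = np.zeros((len(seqs), len(embeddings)))
    for i, seq in enumerate(seqs):
        prof = predict(model, seq, embeddings)
        if assay == "expression":
            from .inference import gene_counts

            out[i] = gene_counts(prof["rna"], gene, bin0)
        else:
            out[i] = prof["atac"].sum(axis=(1, 2))
    return out


def tf_motif_effect(model, genome, genes, pwm: PWM, embeddings,
                    barcodes=None, assay: str = "expression",
                    p_threshold: float = DEFAULT_P_THRESHOLD,
                    n_replicates: int = DEFAULT_N_REPLICATES,
                    seed: int = 0) -> EffectTable:
    """TF motif effect score from simultaneous in silico site replacement.

    For each gene: scan the window centered on its body for PWM hits,
    replace all sites at once (``n_replicates`` random draws), predict
    reference and mutated readouts, normalize each cell by its
    reference-derived size factor, and take log2 fold-changes with
    pseudocount 1. Scores average over genes; genes without hits contribute
    an exact zero. Genes whose window leaves the chromosome entirely are
    skipped.
    """
    rng = np.random.default_rng(seed)
    if barcodes is None:
        barcodes = [f"cell{i}" for i in range(len(embeddings))]
    L = model.config.encoder.input_length
    n_cells = len(embeddings)
    ref_counts, mut_counts, used_genes = [], [], []
    for gene in genes:
        start = gene_window(gene, L)
        chrom_len = len(genome.sequences[gene.chrom])
        if start + L <= 0 or start >= chrom_len:
            continue
        seq = extract_window(genome.sequences[gene.chrom], start, L)
        hits = scan(seq, pwm, p_threshold, chrom=gene.chrom, offset=0)
        if not hits:
            ref = _window_readout(model, genome, gene, [seq], embeddings, assay)[0]
            ref_counts.append(ref)
            mut_counts.append(ref.copy())
            used_genes.append(gene.name)
            continue
        muts = mutate_sites(seq, hits, rng, n_replicates)
        readouts = _window_readout(model, genome, gene, [seq] + muts,
                                   embeddings, assay)
        ref_counts.append(readouts[0])
        mut_counts.append(readouts[1:].mean(axis=0))
        used_genes.append(gene.name)
    ref = np.array(ref_counts)  # genes x cells
    mut = np.array(mut_counts)
    # per-cell size factor from the reference predictions over the gene set
    totals = ref.sum(axis=0)
    sf = totals / np.median(totals) if np.median(totals) > 0 else np.ones(n_cells)
    sf = np.where(sf <= 0, 1.0, sf)
    effects = np.log2(ref / sf + 1.0) - np.log2(mut / sf + 1.0)
    gene_effects = pd.DataFrame(effects, index=used_genes, columns=list(barcodes))
    cell_scores = gene_effects.mean(axis=0)
    return EffectTable(pwm.name, assay, gene_effects, cell_scores)


def tf_motif_effect_accessibility(model, genome, genes, pwm: PWM, embeddings,
                                  **kwargs) -> EffectTable:
    """Accessibility variant: the same pipeline with window-total ATAC
    signal instead of exonic expression sums."""
    return tf_motif_effect(model, genome, genes, pwm, embeddings,
                           assay="accessibility", **kwargs)


def call_target_genes(table: EffectTable, labels, cell_types,
                      threshold: float = TARGET_GENE_THRESHOLD) -> dict:
    """Genes with |cell-type-mean effect| > threshold in the queried cell
    types; the sign of the effect is retained."""
    by_type = table.cell_type_gene_effects(labels)
    sub = by_type[[c for c in by_type.columns if c in set(cell_types)]]
    mean_effect = sub.mean(axis=1)
    return {g: float(e) for g, e in mean_effect.items() if abs(e) > threshold}


def correlate_with_tf_expression(cell_scores, tf_expression) -> float:
    """Pearson r between per-cell TF scores and log-normalized TF
    expression; zero-variance inputs give nan (missing)."""
    return pearson(np.asarray(cell_scores), np.asarray(tf_expression))


# -- MEME-format I/O ---------------------------------------------------------

def read_meme(path) -> list[PWM]:
    """Minimal MEME motif format reader (letter-probability matrices)."""
    pwms = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    background = np.full(4, 0.25)
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            background = np.array([float(parts[j]) for j in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            j = i + 1
            while j < len(lines) and "letter-probability" not in lines[j]:
                j += 1
            header = lines[j]
            w = int(header.split("w=")[1].split()[0])
            rows = [list(map(float, lines[j + 1 + k].split())) for k in range(w)]
            pwms.append(PWM(name, np.array(rows).T, background.copy()))
            i = j + w + 1
            continue
        i += 1
    return pwms


def write_meme(pwms, path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*bg))
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for j in range(pwm.width):
                fh.write(" ".join(f"{pwm.matrix[i, j]:.6f}" for i in range(4)) + "\n")
            fh.write("\n")


def hits_to_bed(hits, path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.chrom}\t{h.start}\t{h.end}\tscore={h.score:.3f};"
                     f"p={h.pvalue:.2e}\t0\t{h.strand}\n")
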