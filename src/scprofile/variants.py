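"""Variant effect scoring, cell-type deconvolution, and attribution.

A variant's effect on its linked gene (eGene) is scored by centering the
input window on the variant, predicting expression for the reference and
alternative alleles, summing predicted exonic expression (natural scale)
over all cells of each cell type, and taking log2((alt + 1) / (ref + 1));
the aggregate effect is the mean over cell types. Accessibility effects sum
the ATAC track over the whole output region instead.

Deconvolution asks whether, among variants with variable predicted effects
across cell types (top 15% of variance by default), the cell types ranked
highest by |effect| are the ones where the variant is truly active;
precision@k is compared against two baselines an analyst could use without
genotyped cohorts: eGene pseudobulk expression rank and accessibility of
the nearest ATAC peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import autodiff as ad
from .autodiff import Tensor
from .decoder import decode_cells_batched
from .fragments import BIN_WIDTH
from .inference import exon_bins, gene_counts, predict
from .motifs import PWM
from .sequence import extract_window, one_hot

NEGLIGIBLE_LOG2FC = 0.05  # |log2FC| < 0.05 i.e. < 3.5% fold change


@dataclass(frozen=True)
class Variant:
    """Single-nucleotide variant, VCF convention (pos is 1-based)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str  # linked eGene identifier

    def __post_init__(self):
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("single-nucleotide variants only")

    @property
    def pos0(self) -> int:
        return self.pos - 1


@dataclass
class VariantEffect:
    variant: Variant
    per_cell_type: pd.Series  # log2FC on expression per cell type
    aggregate: float  # mean over cell types
    accessibility: pd.Series | None = None
    tss_distance: int | None = None


def read_vcf(path) -> list[Variant]:
    """Read SNVs from a VCF; the linked gene is taken from INFO GENE=."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            chrom, pos, _, ref, alt = f[0], int(f[1]), f[2], f[3], f[4]
            if len(ref) != 1 or len(alt) != 1:
                continue  # non-SNVs are filtered out
            info = dict(
                kv.split("=", 1) for kv in f[7].split(";") if "=" in kv
            ) if len(f) > 7 else {}
            out.append(Variant(chrom, pos, ref, alt, info.get("GENE", "")))
    return out


def write_vcf(variants, path, extra_info=None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="eGene">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, v in enumerate(variants):
            info = f"GENE={v.gene}"
            if extra_info:
                info += ";" + extra_info[i]
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t{info}\n")


def read_finemap_tsv(path, pip_threshold: float = 0.9) -> pd.DataFrame:
    """Generic fine-mapping table (variant, gene, cell_type, pip); keeps
    rows with PIP >= threshold."""
    df = pd.read_csv(path, sep="\t")
    return df[df["pip"] >= pip_threshold].reset_index(drop=True)


# -- scoring -----------------------------------------------------------------

def _variant_window(model, genome, variant: Variant):
    L = model.config.encoder.input_length
    start = variant.pos0 - L // 2
    seq = extract_window(genome.sequences[variant.chrom], start, L)
    obs = seq[variant.pos0 - start]
    if obs.upper() != variant.ref.upper():
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: genome has "
            f"{obs!r}, variant says {variant.ref!r}"
        )
    alt_seq = seq[: variant.pos0 - start] + variant.alt + seq[variant.pos0 - start + 1:]
    return start, seq, alt_seq


def score_variant(model, genome, variant: Variant, gene, embeddings, labels,
                  with_accessibility: bool = True) -> VariantEffect:
    """Ref/alt effect per cell type; aggregate = mean over cell types."""
    start, ref_seq, alt_seq = _variant_window(model, genome, variant)
    L = model.config.encoder.input_length
    crop = model.config.n_output_bins
    bin0 = start + ((L // BIN_WIDTH) - crop) // 2 * BIN_WIDTH
    lab = pd.Series(list(labels))
    types = sorted(lab.unique())
    per_type = {}
    acc = {}
    preds = {}
    for key, seq in (("ref", ref_seq), ("alt", alt_seq)):
        preds[key] = predict(model, seq, embeddings)
    for t in types:
        m = (lab == t).values
        ref_e = gene_counts(preds["ref"]["rna"][m], gene, bin0).sum()
        alt_e = gene_counts(preds["alt"]["rna"][m], gene, bin0).sum()
        per_type[t] = float(np.log2((alt_e + 1.0) / (ref_e + 1.0)))
        if with_accessibility:
            ref_a = preds["ref"]["atac"][m].sum()
            alt_a = preds["alt"]["atac"][m].sum()
            acc[t] = float(np.log2((alt_a + 1.0) / (ref_a + 1.0)))
    per_type = pd.Series(per_type)
    tss = gene.start if gene.strand == "+" else gene.end
    return VariantEffect(
        variant, per_type, float(per_type.mean()),
        pd.Series(acc) if with_accessibility else None,
        abs(variant.pos0 - tss),
    )


def filter_negligible(effects, threshold: float = NEGLIGIBLE_LOG2FC):
    """Keep variants with |aggregate log2FC| >= threshold (inclusive:
    exactly 0.05 is non-negligible). Returns (subset, retained fraction)."""
    kept = [e for e in effects if abs(e.aggregate) >= threshold]
    frac = len(kept) / len(effects) if effects else 0.0
    return kept, frac


def sign_concordance_by_distance(effects, observed_signs, bins,
                                 apply_filter: bool = False,
                                 threshold: float = NEGLIGIBLE_LOG2FC
                                 ) -> pd.DataFrame:
    """Fraction of predictions with the observed sign per TSS-distance bin.

    ``bins`` are distance edges; a binomial test against chance (0.5) is
    reported per bin. Empty bins are missing (nan).
    """
    rows = []
    pairs = list(zip(effects, observed_signs))
    if apply_filter:
        pairs = [(e, s) for e, s in pairs if abs(e.aggregate) >= threshold]
    edges = list(bins)
    for lo, hi in zip(edges[:-1], edges[1:]):
        sub = [(e, s) for e, s in pairs
               if e.tss_distance is not None and lo <= e.tss_distance < hi]
        n = len(sub)
        if n == 0:
            rows.append({"lo": lo, "hi": hi, "n": 0,
                         "concordance": float("nan"), "p_binomial": float("nan")})
            continue
        conc = sum(np.sign(e.aggregate) == np.sign(s) for e, s in sub)
        test = stats.binomtest(conc, n, 0.5)
        rows.append({"lo": lo, "hi": hi, "n": n, "concordance": conc / n,
                     "p_binomial": test.pvalue})
    return pd.DataFrame(rows)


# -- deconvolution benchmark -------------------------------------------------

@dataclass
class DeconvolutionBenchmark:
    positives: set  # {(variant_id, cell_type)}
    rankings: dict  # method -> {variant_id: [cell types, |effect| desc]}
    precision_at: dict = field(default_factory=dict)  # method -> {k: value}

    def compute_precision(self, ks=(1,)) -> dict:
        n_types = None
        for method, ranking in self.rankings.items():
            self.precision_at[method] = {}
            for k in ks:
                vals = []
                for vid, order in ranking.items():
                    n_types = len(order)
                    if k > len(order):
                        raise ValueError(f"k={k} exceeds {len(order)} cell types")
                    hits = sum((vid, ct) in self.positives for ct in order[:k])
                    vals.append(hits / k)
                self.precision_at[method][k] = float(np.mean(vals)) if vals else float("nan")
        return self.precision_at


def rank_cell_types_by_effect(effect_row: pd.Series) -> list:
    """Cell types by |effect| descending; ties break by name (stable)."""
    return sorted(effect_row.index, key=lambda t: (-abs(effect_row[t]), t))


def deconvolve(effect_matrix: pd.DataFrame, positives: set,
               variance_quantile: float = 0.85, ks=(1,),
               extra_rankings: dict | None = None) -> DeconvolutionBenchmark:
    """Benchmark cell-type rankings against fine-mapped positives.

    ``effect_matrix``: variants x cell types (predicted log2FC). Variants
    are kept when their across-type effect variance is in the top
    (1 - variance_quantile) tail. ``extra_rankings`` supplies baseline
    rankings {method: {variant_id: ordered cell types}} for the same
    variants.
    """
    var = effect_matrix.var(axis=1)
    cut = var.quantile(variance_quantile)
    selected = effect_matrix.index[var >= cut]
    rankings = {
        "model": {
            vid: rank_cell_types_by_effect(effect_matrix.loc[vid])
            for vid in selected
        }
    }
    for method, table in (extra_rankings or {}).items():
        rankings[method] = {vid: table[vid] for vid in selected if vid in table}
    bench = DeconvolutionBenchmark(set(positives), rankings)
    bench.compute_precision(ks)
    return bench


def size_factor_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-cell size-factor normalization: divide each cell (row) by its
    total over the median total."""
    totals = counts.sum(axis=1)
    med = np.median(totals[totals > 0]) if (totals > 0).any() else 1.0
    sf = (totals / med).replace(0, 1.0)
    return counts.div(sf, axis=0)


def baseline_expression_rank(counts: pd.DataFrame, labels, gene: str) -> list:
    """Rank cell types by size-factor-normalized pseudobulk expression of
    the eGene, descending; ties break by cell-type name."""
    norm = size_factor_normalize(counts)
    lab = pd.Series(labels).reindex(norm.index)
    pb = norm.groupby(lab.values).sum()
    col = pb[gene]
    return sorted(col.index, key=lambda t: (-col[t], t))


def nearest_peak(peaks, chrom: str, pos0: int):
    """Overlapping peak, else nearest by genomic distance (tie: lower
    coordinate). ``peaks``: iterable of (name, chrom, start, end)."""
    best = None
    best_key = None
    for name, c, s, e in peaks:
        if c != chrom:
            continue
        if s <= pos0 < e:
            dist = 0
        else:
            dist = s - pos0 if pos0 < s else pos0 - e + 1
        key = (dist, s)
        if best_key is None or key < best_key:
            best, best_key = (name, c, s, e), key
    if best is None:
        raise ValueError(f"no peak on chromosome {chrom!r}")
    return best


def baseline_atac_peak_rank(peak_counts: pd.DataFrame, labels, peaks,
                            variant: Variant) -> list:
    """Rank cell types by size-factor-normalized pseudobulk accessibility
    of the variant's overlapping-or-nearest peak."""
    name, *_ = nearest_peak(peaks, variant.chrom, variant.pos0)
    norm = size_factor_normalize(peak_counts)
    lab = pd.Series(labels).reindex(norm.index)
    pb = norm.groupby(lab.values).sum()
    col = pb[name]
    return sorted(col.index, key=lambda t: (-col[t], t))


# -- gradient attribution ----------------------------------------------------

def _unsquash_t(y: Tensor, params) -> Tensor:
    """Differentiable inverse of the squashed-scale transform."""
    over = Tensor((y.data > params.clip_soft).astype(float))
    u = over * (params.clip_soft + ad.power(y - params.clip_soft, 2.0)) + \
        (1.0 - over) * y
    return ad.power(u, 1.0 / params.exponent) * (1.0 / params.scale)


def gradient_pwm(model, genome, variant: Variant, gene, embeddings, labels,
                 cell_type, window: int = 10) -> PWM:
    """Gradient-weighted PWM over a window centered on the variant.

    The readout is log(1 + summed exonic expression of the eGene over cells
    of the queried type) at the reference sequence; each column of the
    returned PWM is 2^gradient, sum-normalized over bases.
    """
    from .transforms import RNA_SQUASH
    from .inference import STRAND_TRACK

    start, ref_seq, _ = _variant_window(model, genome, variant)
    L = model.config.encoder.input_length
    crop = model.config.n_output_bins
    bin0 = start + ((L // BIN_WIDTH) - crop) // 2 * BIN_WIDTH
    lab = pd.Series(list(labels))
    m = (lab == cell_type).values
    emb = np.asarray(embeddings)[m]
    x = Tensor(one_hot(ref_seq), requires_grad=True)
    model.eval()
    track = model.embed(x)
    w = model.hypernet_rna(emb)
    prof = decode_cells_batched(track, w)  # squashed (C, bins, 2)
    natural = _unsquash_t(prof, RNA_SQUASH)
    bins = exon_bins(gene, bin0, crop)
    tr = STRAND_TRACK[gene.strand]
    total = natural[:, bins, tr].sum()
    readout = ad.tlog(total + 1.0)
    readout.backward()
    grad = x.grad  # (L, 4)
    center = variant.pos0 - start
    lo = center - window // 2
    cols = grad[lo:lo + window].T  # (4, window)
    mat = np.power(2.0, cols)
    mat /= mat.sum(axis=0, keepdims=True)
    return PWM(f"grad_{variant.chrom}_{variant.pos}", mat)
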