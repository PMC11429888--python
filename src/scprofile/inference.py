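"""Prediction and evaluation.

Prediction runs the model on a sequence and its reverse complement, reverse-
flips the RC output (positions reversed; RNA strand tracks swapped, since
strand identity inverts under reverse complement), averages the two, and
inverts the squashed scale — for ATAC this includes the x20 multiplier that
undoes the 0.05 training pre-scale.

Gene-level evaluation follows the count-based scheme: predicted coverage is
summed over bins overlapping exons on the gene's strand, pseudobulked by
cell type, log2(x+1)-transformed, and compared by Pearson correlation across
genes per cell type, plus a doubly mean-centered (gene-wise and cell-type-
wise) correlation that isolates cell-type-specific deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragments import BIN_WIDTH
from .sequence import one_hot, rc_one_hot
from .transforms import ATAC_SQUASH, RNA_SQUASH, unsquash

STRAND_TRACK = {"+": 0, "-": 1}


def _flip_tracks(profiles: dict) -> dict:
    """Reverse bins; swap RNA strand channels (ATAC is unstranded)."""
    return {
        "rna": profiles["rna"][:, ::-1, ::-1],
        "atac": profiles["atac"][:, ::-1, :],
    }


def predict(model, seq, embeddings, rc_average: bool = True,
            natural_scale: bool = True) -> dict:
    """Per-cell profile prediction for one window.

    seq: string or one-hot (L, 4); embeddings: (C, E). Returns
    {"rna": (C, bins, 2), "atac": (C, bins, 1)} numpy arrays, natural scale
    by default (squashed scale with ``natural_scale=False``).
    """
    x = one_hot(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.float64)
    if x.shape[0] != model.config.encoder.input_length:
        raise ValueError(
            f"sequence length {x.shape[0]} != model input length "
            f"{model.config.encoder.input_length}"
        )
    model.eval()
    fwd = model.forward_cells(x, embeddings)
    out = {k: v.data for k, v in fwd.items()}
    if rc_average:
        rev = model.forward_cells(rc_one_hot(x), embeddings)
        flipped = _flip_tracks({k: v.data for k, v in rev.items()})
        out = {k: 0.5 * (out[k] + flipped[k]) for k in out}
    if natural_scale:
        out = {
            "rna": unsquash(out["rna"], RNA_SQUASH),
            "atac": unsquash(out["atac"], ATAC_SQUASH),
        }
    return out


# -- windows and exon arithmetic --------------------------------------------

def gene_window(gene, window_length: int) -> int:
    """Window start so the window is centered on the gene-body midpoint.

    Windows extending past a chromosome edge are used as-is; the sequence
    extractor N-pads and coverage outside the chromosome is zero.
    """
    mid = (gene.start + gene.end) // 2
    return mid - window_length // 2


def exon_bins(gene, window_start: int, n_bins: int,
              bin_width: int = BIN_WIDTH) -> np.ndarray:
    """Indices of bins whose genomic span intersects any exon by >= 1 bp.

    Overlapping exons contribute their union (shared bins counted once).
    """
    hit = np.zeros(n_bins, dtype=bool)
    for es, ee in gene.exons:
        lo = max(0, (es - window_start) // bin_width)
        hi = min(n_bins, -(-(ee - window_start) // bin_width))
        if hi > lo:
            hit[lo:hi] = True
    return np.nonzero(hit)[0]


def gene_counts(rna_profile: np.ndarray, gene, window_start: int,
                bin_width: int = BIN_WIDTH) -> np.ndarray:
    """Per-cell exonic counts from a natural-scale RNA profile (C, bins, 2),
    using the output track matching the gene's strand."""
    track = STRAND_TRACK[gene.strand]
    bins = exon_bins(gene, window_start, rna_profile.shape[1], bin_width)
    if bins.size == 0:
        return np.zeros(rna_profile.shape[0])
    return rna_profile[:, bins, track].sum(axis=1)


def predict_gene_counts(model, genome, gene, embeddings) -> np.ndarray:
    """Center a window on the gene body, predict, and sum exonic coverage."""
    from .sequence import extract_window

    L = model.config.encoder.input_length
    start = gene_window(gene, L)
    seq = extract_window(genome.sequences[gene.chrom], start, L)
    prof = predict(model, seq, embeddings)
    crop = model.config.n_output_bins
    bin0 = start + ((L // BIN_WIDTH) - crop) // 2 * BIN_WIDTH
    return gene_counts(prof["rna"], gene, bin0)


# -- aggregation -------------------------------------------------------------

def pseudobulk(matrix, labels) -> pd.DataFrame:
    """Group-by-sum a cells x genes matrix into cell_type x genes.

    ``matrix`` is a DataFrame (index = barcodes) or array with ``labels``
    aligned to rows; every cell must be labeled. Column sums are conserved.
    """
    if isinstance(matrix, pd.DataFrame):
        df = matrix
        lab = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
        lab = lab.reindex(df.index)
        if lab.isna().any():
            missing = list(df.index[lab.isna()])[:5]
            raise ValueError(f"unlabeled cells: {missing}")
    else:
        arr = np.asarray(matrix)
        lab = pd.Series(list(labels))
        if len(lab) != arr.shape[0]:
            raise ValueError("labels length != number of cells")
        if lab.isna().any():
            raise ValueError("unlabeled cells")
        df = pd.DataFrame(arr)
    return df.groupby(lab.values).sum()


def pearson(a, b) -> float:
    """Pearson r; zero-variance input yields nan (reported as missing)."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    # zero variance up to float rounding (mean subtraction of identical
    # values can leave O(eps) residuals)
    if a.std() <= 1e-12 * (abs(a).mean() + 1) or \
            b.std() <= 1e-12 * (abs(b).mean() + 1):
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class EvalReport:
    """Gene-level evaluation: per-cell-type across-gene correlations of
    log2(count+1), and the doubly mean-centered across-cell-type metric."""

    per_cell_type: dict = field(default_factory=dict)
    across_genes_mean: float = float("nan")
    across_cell_types: float = float("nan")
    n_missing: int = 0

    def to_dict(self) -> dict:
        return {
            "per_cell_type": self.per_cell_type,
            "across_genes_mean": self.across_genes_mean,
            "across_cell_types": self.across_cell_types,
            "n_missing": self.n_missing,
        }


def eval_gene_level(pred_pb: pd.DataFrame, obs_pb: pd.DataFrame) -> EvalReport:
    """Compare predicted vs observed pseudobulk counts (cell_type x genes)."""
    pred_pb = pred_pb.loc[obs_pb.index, obs_pb.columns]
    lp = np.log2(pred_pb.values + 1.0)
    lo = np.log2(obs_pb.values + 1.0)
    report = EvalReport()
    rs = []
    for i, ct in enumerate(obs_pb.index):
        r = pearson(lp[i], lo[i])
        report.per_cell_type[ct] = r
        if np.isnan(r):
            report.n_missing += 1
        else:
            rs.append(r)
    report.across_genes_mean = float(np.mean(rs)) if rs else float("nan")

    def double_center(m):
        m = m - m.mean(axis=1, keepdims=True)  # gene-wise deviation per type
        return m - m.mean(axis=0, keepdims=True)

    report.across_cell_types = pearson(double_center(lp), double_center(lo))
    return report


def knn_average_profiles(profiles: np.ndarray, neighbor_graph: np.ndarray
                         ) -> np.ndarray:
    """Mean profile over each cell's stored neighbors.

    profiles: (C, ...); neighbor_graph: (C, k) integer indices (computed on
    cell embeddings; may include self).
    """
    neighbor_graph = np.asarray(neighbor_graph, dtype=np.int64)
    return profiles[neighbor_graph].mean(axis=1)


def knn_graph(embeddings: np.ndarray, k: int = 100) -> np.ndarray:
    """(C, k) nearest neighbors (self included) by Euclidean distance."""
    emb = np.asarray(embeddings, dtype=np.float64)
    d2 = ((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1)
    k = min(k, emb.shape[0])
    return np.argsort(d2, axis=1)[:, :k]


def eval_profile_level(single: np.ndarray, references: dict) -> pd.DataFrame:
    """Per-cell log-scale Pearson between single-cell profiles and each
    reference (pseudobulk, prediction, kNN-average, ...).

    single: (C, L) natural-scale concatenated profiles; each reference the
    same shape (or (L,), broadcast to all cells). Zero-variance comparisons
    are missing (nan) and excluded from column means.
    """
    rows = {}
    ls = np.log1p(single)
    for name, ref in references.items():
        ref = np.asarray(ref, dtype=np.float64)
        if ref.ndim == 1:
            ref = np.broadcast_to(ref, single.shape)
        lr = np.log1p(ref)
        rows[name] = [pearson(ls[c], lr[c]) for c in range(single.shape[0])]
    return pd.DataFrame(rows)
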