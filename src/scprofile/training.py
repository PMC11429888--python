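"""Fine-tuning loop: loss, cell sampling, augmentation, scheduling.

The loss couples a Poisson term on window-total counts with a multinomial
term on the positional distribution, per cell and track, the standard
recipe for coverage-profile models. Training updates only the adapter,
head, and hypernetwork parameters, with two optimizer groups (decoder at
4e-4; adapters + head at 2e-4), linear warmup then linear decay, gradient
clipping at 1.0 and weight decay 1e-6. Sequences are augmented by +-3 bp
shifts (targets re-extracted for the shifted window) and reverse
complementation (target bins reversed; RNA strand tracks swapped, because
strand identity inverts under RC; unstranded ATAC flips positions only).

Validation after each epoch scores the across-cell-type (doubly centered)
Pearson correlation of log2(pseudobulk+1) gene counts on the validation
genes; the checkpoint with the largest value is retained.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .autodiff import Tensor, tlog, tsum
from .fragments import BIN_WIDTH, bin_coverage
from .inference import eval_gene_level, gene_counts, gene_window, pseudobulk
from .nn import AdamW
from .sequence import extract_window, one_hot, rc_one_hot
from .transforms import ATAC_SQUASH, RNA_SQUASH, squash


@dataclass
class LossConfig:
    poisson_weight: float = 0.2  # Poisson/multinomial balance (assumed)
    epsilon: float = 1e-7


@dataclass
class TrainConfig:
    batch_sequences: int = 8
    cells_per_sequence: int = 64
    lr_decoder: float = 4e-4
    lr_lora_and_head: float = 2e-4
    warmup_steps: int = 1000
    epochs: int = 40
    grad_clip: float = 1.0
    weight_decay: float = 1e-6
    shift_max: int = 3
    rc_augment: bool = True
    stabilization_epochs: int = 1  # frozen batch-norm / no dropout phase
    loss: LossConfig = None
    # multi-task balance: ATAC counts are ~20x smaller in squashed space
    # after the 0.05 pre-scale, so its loss is up-weighted to match RNA
    assay_weights: dict = None
    # EMA of trainable parameters; evaluation and the returned model use
    # the averaged weights (0 disables)
    ema_decay: float = 0.995
    # pseudobulk stage: targets are per-cell-type mean profiles decoded at
    # the type's mean embedding (the desk-scale analogue of pretraining a
    # profile model on bulk data before single-cell fine-tuning)
    pseudobulk_targets: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.loss is None:
            self.loss = LossConfig()
        if self.assay_weights is None:
            self.assay_weights = {"rna": 1.0, "atac": 20.0}
        if self.epochs <= 0 or self.batch_sequences <= 0:
            raise ValueError("epochs and batch size must be positive")


def poisson_multinomial_loss(pred, target, cfg: LossConfig | None = None):
    """Combined Poisson + multinomial negative log-likelihood.

    pred: Tensor or array (C, B, S), nonnegative squashed-scale
    predictions; target: array of the same shape. The Poisson term acts on
    window totals (divided by the bin count); the multinomial term scores
    the positional distribution. Averaged over cells and tracks.
    """
    cfg = cfg or LossConfig()
    pred_t = pred if isinstance(pred, Tensor) else Tensor(pred)
    target = np.asarray(target, dtype=np.float64)
    if pred_t.shape != target.shape:
        raise ValueError(f"shape mismatch {pred_t.shape} vs {target.shape}")
    if np.any(pred_t.data < 0):
        raise ValueError("predictions must be nonnegative")
    n_cells, n_bins, n_tracks = target.shape
    eps = cfg.epsilon
    total_pred = tsum(pred_t, axis=1)  # (C, S)
    total_tgt = target.sum(axis=1)
    # Poisson NLL on totals, with the log-factorial constant
    poisson = total_pred - Tensor(total_tgt) * tlog(total_pred + eps) \
        + Tensor(gammaln(total_tgt + 1.0))
    # Multinomial NLL of target positions under the predicted distribution;
    # epsilon enters before the division so an all-zero prediction stays
    # finite (softplus can underflow to exactly 0 in float32)
    log_p = tlog(pred_t + eps) - tlog(
        total_pred.reshape((n_cells, 1, n_tracks)) + n_bins * eps
    )
    log_coef = gammaln(total_tgt + 1.0) - gammaln(target + 1.0).sum(axis=1)
    multinomial = -tsum(Tensor(target) * log_p, axis=1) - Tensor(log_coef)
    per_cs = cfg.poisson_weight * poisson * (1.0 / n_bins) + multinomial
    return per_cs.mean()


def augment(sequence, targets: dict, rng: np.random.Generator,
            shift_max: int = 3, rc_augment: bool = True, refetch=None):
    """Shift-and-RC augmentation of one training example.

    ``sequence`` is a one-hot array; ``targets`` maps assay -> (C, B, S).
    The shift is drawn uniformly from {-shift_max..shift_max}; when a
    ``refetch(shift)`` callback is given, the shifted window's sequence and
    targets are re-extracted through it. Reverse complementation (prob 1/2)
    flips target bins and swaps the RNA strand tracks.
    """
    shift = int(rng.integers(-shift_max, shift_max + 1)) if shift_max else 0
    if shift != 0 and refetch is not None:
        sequence, targets = refetch(shift)
    do_rc = rc_augment and rng.random() < 0.5
    if do_rc:
        sequence = rc_one_hot(np.asarray(sequence))
        flipped = {}
        for assay, t in targets.items():
            t = t[:, ::-1, :]
            if assay == "rna":
                t = t[:, :, ::-1]
            flipped[assay] = np.ascontiguousarray(t)
        targets = flipped
    return sequence, targets


# -- leakage audit -----------------------------------------------------------

def _overlaps(a, b) -> bool:
    return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]


def audit_leakage(features, split_regions) -> list:
    """Features (chrom, start, end, name) overlapping any validation or
    test region. Embedding-input feature sets must exclude these."""
    held = [r for r in split_regions if r[4] in ("valid", "test")]
    return [f for f in features
            if any(_overlaps(f[:3], h[:3]) for h in held)]


def exclude_leaky_features(features, split_regions) -> list:
    leaky = {f[3] if len(f) > 3 else f[:3] for f in
             audit_leakage(features, split_regions)}
    return [f for f in features
            if (f[3] if len(f) > 3 else f[:3]) not in leaky]


def filter_rare_features(matrix: pd.DataFrame,
                         min_cell_fraction: float = 0.01) -> pd.DataFrame:
    """Drop features detected in fewer than the given fraction of cells."""
    frac = (matrix > 0).mean(axis=0)
    return matrix.loc[:, frac >= min_cell_fraction]


# -- observed targets --------------------------------------------------------

def window_targets(stores: dict, chrom: str, start: int, n_bins: int,
                   cells, group_means: list | None = None) -> dict:
    """Squashed-scale binned targets for a window, per assay.

    With ``group_means`` (a list of index arrays into ``cells``), natural
    coverage is averaged within each group before squashing — the
    pseudobulk targets used by the pretraining stage.
    """
    out = {}
    for assay, store in stores.items():
        prof = bin_coverage(store, chrom, start, n_bins, cells=cells,
                            clip=True)
        values = prof.values
        if group_means is not None:
            values = np.stack([values[idx].mean(axis=0)
                               for idx in group_means])
        params = RNA_SQUASH if assay == "rna" else ATAC_SQUASH
        out[assay] = squash(values, params)
    return out


def observed_gene_counts(store, genes, window_length: int,
                         crop_bins: int | None = None) -> pd.DataFrame:
    """Observed per-cell exonic coverage counts (cells x genes), measured
    exactly as predictions are: strand-matched bp coverage summed over
    exon-overlapping bins inside the gene-centered (cropped) window."""
    n_bins = window_length // BIN_WIDTH
    crop = crop_bins or n_bins
    cols = {}
    for gene in genes:
        start = gene_window(gene, window_length)
        bin0 = start + (n_bins - crop) // 2 * BIN_WIDTH
        prof = bin_coverage(store, gene.chrom, bin0, crop, clip=True)
        cols[gene.name] = gene_counts(prof.values, gene, bin0)
    return pd.DataFrame(cols, index=store.barcodes)


# -- training loop -----------------------------------------------------------

@dataclass
class TrainResult:
    model: object
    log: list  # per-step dicts: step, loss, lr_scale, epoch
    val_log: list  # per-epoch dicts: epoch, metric
    best_epoch: int
    best_metric: float


def _lr_scale(step: int, warmup: int, total: int) -> float:
    if warmup > 0 and step < warmup:
        return (step + 1) / warmup
    if total <= warmup:
        return 1.0
    return max(0.0, (total - step) / (total - warmup))


def train(model, genome, genes, stores: dict, embeddings, splits: dict,
          cfg: TrainConfig, labels=None, on_epoch_end=None) -> TrainResult:
    """Fine-tune the model on gene-centered windows of the toy dataset.

    ``splits`` maps gene name -> train|valid|test; validation genes drive
    checkpoint selection. ``labels`` (barcode -> cell type) is required for
    the pseudobulk validation metric. Deterministic for a fixed seed.
    """
    from .inference import predict_gene_counts

    rng = np.random.default_rng(cfg.seed)
    train_genes = [g for g in genes if splits.get(g.name) == "train"]
    val_genes = [g for g in genes if splits.get(g.name) == "valid"]
    if not train_genes:
        raise ValueError("empty training split")
    L = model.config.encoder.input_length
    n_bins = L // BIN_WIDTH
    crop = model.config.n_output_bins
    barcodes = stores["rna"].barcodes
    emb = np.asarray(embeddings)
    if cfg.pseudobulk_targets:
        if labels is None:
            raise ValueError("pseudobulk_targets requires cell-type labels")
        lab = pd.Series(labels).reindex(barcodes)
        types = sorted(lab.unique())
        group_idx = [np.flatnonzero((lab == t).values) for t in types]
        type_emb = np.stack([emb[idx].mean(axis=0) for idx in group_idx])
        pb_cache: dict = {}

    groups = model.parameter_groups()
    opt = AdamW(
        [{"params": groups["decoder"], "lr": cfg.lr_decoder},
         {"params": groups["lora_head"], "lr": cfg.lr_lora_and_head}],
        weight_decay=cfg.weight_decay,
    )
    steps_per_epoch = max(1, len(train_genes) // cfg.batch_sequences)
    total_steps = steps_per_epoch * cfg.epochs
    log, val_log = [], []
    best_metric, best_epoch, best_state = -np.inf, -1, None

    trainable = [p for g in opt.groups for p in g["params"]]
    ema = [p.data.copy() for p in trainable] if cfg.ema_decay > 0 else None

    def swap_in_ema():
        if ema is None:
            return None
        backup = [p.data for p in trainable]
        for p, e in zip(trainable, ema):
            p.data = e
        return backup

    def swap_back(backup):
        if backup is not None:
            for p, b in zip(trainable, backup):
                p.data = b

    obs_val_pb = None
    if val_genes and labels is not None:
        obs_val = observed_gene_counts(stores["rna"], val_genes, L, crop)
        obs_val_pb = pseudobulk(obs_val, pd.Series(labels))

    step = 0
    for epoch in range(cfg.epochs):
        model.encoder.set_stabilization(epoch < cfg.stabilization_epochs)
        for m in model.modules():
            m.train()
        order = rng.permutation(len(train_genes))
        for bstart in range(0, steps_per_epoch * cfg.batch_sequences,
                            cfg.batch_sequences):
            batch = [train_genes[i % len(train_genes)]
                     for i in order[bstart:bstart + cfg.batch_sequences]]
            opt.set_lr_scale(_lr_scale(step, cfg.warmup_steps, total_steps))
            model.zero_grad()
            losses = []
            for gene in batch:
                start0 = gene_window(gene, L)
                bin_off = (n_bins - crop) // 2 * BIN_WIDTH
                if cfg.pseudobulk_targets:
                    batch_emb = type_emb

                    def refetch(shift, _g=gene, _s=start0):
                        key = (_g.name, shift)
                        if key not in pb_cache:
                            seq = extract_window(
                                genome.sequences[_g.chrom], _s + shift, L
                            )
                            tg = window_targets(
                                stores, _g.chrom, _s + shift + bin_off,
                                crop, barcodes, group_means=group_idx,
                            )
                            pb_cache[key] = (one_hot(seq), tg)
                        return pb_cache[key]
                else:
                    cell_idx = rng.choice(len(barcodes),
                                          size=min(cfg.cells_per_sequence,
                                                   len(barcodes)),
                                          replace=False)
                    cells = [barcodes[i] for i in cell_idx]
                    batch_emb = emb[cell_idx]

                    def refetch(shift, _g=gene, _c=cells, _s=start0):
                        seq = extract_window(genome.sequences[_g.chrom],
                                             _s + shift, L)
                        tg = window_targets(stores, _g.chrom,
                                            _s + shift + bin_off, crop, _c)
                        return one_hot(seq), tg

                seq_oh, targets = refetch(0)
                seq_oh, targets = augment(
                    seq_oh, targets, rng, cfg.shift_max, cfg.rc_augment,
                    refetch=refetch,
                )
                out = model.forward_cells(seq_oh, batch_emb)
                loss = None
                for assay in out:
                    term = poisson_multinomial_loss(
                        out[assay], targets[assay], cfg.loss
                    ) * cfg.assay_weights.get(assay, 1.0)
                    loss = term if loss is None else loss + term
                losses.append(loss)
            total = losses[0]
            for extra in losses[1:]:
                total = total + extra
            total = total * (1.0 / len(losses))
            total.backward()
            opt.clip_grad_norm(cfg.grad_clip)
            opt.step()
            if ema is not None:
                # e += (1-d)(p-e): exactly idempotent when p == e
                d = cfg.ema_decay
                for p, e in zip(trainable, ema):
                    e += (1.0 - d) * (p.data - e)
            log.append({"step": step, "epoch": epoch,
                        "loss": float(total.data),
                        "lr_scale": _lr_scale(step, cfg.warmup_steps,
                                              total_steps)})
            step += 1
        # validation (on EMA weights): across-cell-type correlation on
        # held-out genes
        backup = swap_in_ema()
        if obs_val_pb is not None:
            pred_counts = {}
            for gene in val_genes:
                pred_counts[gene.name] = predict_gene_counts(
                    model, genome, gene, emb
                )
            pred_df = pd.DataFrame(pred_counts, index=barcodes)
            pred_pb = pseudobulk(pred_df, pd.Series(labels))
            val_rep = eval_gene_level(pred_pb, obs_val_pb)
            # selection combines the across-gene and across-cell-type
            # correlations: with a handful of validation genes the
            # cell-type metric alone is too noisy to pick a checkpoint
            metric = float(np.nansum([val_rep.across_genes_mean,
                                      val_rep.across_cell_types]))
            extra = {"across_cell_types": val_rep.across_cell_types,
                     "across_genes_mean": val_rep.across_genes_mean}
        else:
            metric = -float(np.mean([r["loss"] for r in log[-steps_per_epoch:]]))
            extra = {}
        val_log.append({"epoch": epoch, "metric": float(metric), **extra})
        if on_epoch_end is not None:
            on_epoch_end(epoch, model, float(metric))
        if np.isnan(metric):
            metric = -np.inf
        if metric > best_metric:
            best_metric, best_epoch = float(metric), epoch
            best_state = copy.deepcopy(model.state_dict())
        swap_back(backup)
    # finish on the averaged weights, then restore the best checkpoint
    swap_in_ema()
    if best_state is not None:
        model.load_state_dict(best_state)
    return TrainResult(model, log, val_log, best_epoch, best_metric)
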