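"""End-to-end desk-scale study: simulate, train, evaluate, score.

This module pins the package's reference study conditions — the toy world,
sequencing depths, model size and training schedule used by the test suite
and the acceptance script — and provides one entry point, :func:`run_study`,
that executes the full pipeline from a single seed:

1. generate the toy multiome world and simulate fragments;
2. train the model (encoder + head + hypernetwork decoders) on the
   training chromosomes, selecting the checkpoint by validation
   correlation;
3. evaluate gene-level predictions on the held-out test genes;
4. score every planted TF motif (expression and accessibility) and check
   sign recovery against the planted activities;
5. score the planted variants, rank cell types, and compare deconvolution
   precision@1 against the expression and ATAC-peak baselines.

Problem sizes are chosen for a single CPU: 96 genes of 8,192-bp windows,
240 cells, a 64-channel encoder, and a few thousand optimization steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .backbone import EncoderConfig
from .inference import (
    eval_gene_level,
    predict_gene_counts,
    pseudobulk,
)
from .model import ModelConfig, ProfileModel
from .motifs import tf_motif_effect
from .simulate import (
    SimConfig,
    generate_world,
    simulate_atac_fragments,
    simulate_rna_fragments,
)
from .training import LossConfig, TrainConfig, observed_gene_counts, train
from .variants import (
    baseline_atac_peak_rank,
    baseline_expression_rank,
    deconvolve,
    score_variant,
)

RNA_DEPTH = 600.0  # reads per cell
ATAC_DEPTH = 1000.0  # fragments per cell


def default_sim_config(seed: int) -> SimConfig:
    return SimConfig(seed=seed)


def default_model_config(seed: int, embedding_dim: int) -> ModelConfig:
    return ModelConfig(
        encoder=EncoderConfig(input_length=8192, channels=64, seed=seed),
        embedding_dim=embedding_dim,
        seed=seed,
    )


def default_train_config(seed: int, epochs: int = 50) -> TrainConfig:
    """Desk-scale training schedule (see docs/methods.md for rationale)."""
    return TrainConfig(
        batch_sequences=2,
        cells_per_sequence=16,
        lr_decoder=4e-3,
        lr_lora_and_head=2e-3,
        warmup_steps=100,
        epochs=epochs,
        shift_max=3,
        rc_augment=True,
        stabilization_epochs=1,
        loss=LossConfig(poisson_weight=256.0),
        seed=seed,
    )


@dataclass
class StudyResult:
    world: object
    stores: dict
    model: ProfileModel
    train_result: object
    gene_report: object  # EvalReport on the test fold
    motif_tables: dict  # motif name -> {"expression": EffectTable, ...}
    sign_recovery: pd.DataFrame
    variant_effects: pd.DataFrame  # variants x cell types (expression log2FC)
    deconvolution: dict  # method -> precision@1
    extras: dict = field(default_factory=dict)


def train_study_model(world, stores, seed: int, epochs: int = 50,
                      train_config: TrainConfig | None = None) -> tuple:
    model = ProfileModel(
        default_model_config(seed, world.config.embedding_dim)
    )
    cfg = train_config or default_train_config(seed, epochs)
    result = train(model, world.genome, world.genes, stores,
                   world.cells.embedding, world.splits, cfg,
                   labels=world.cells.labels)
    return model, result


def evaluate_test_fold(world, stores, model):
    test_genes = world.genes_in_fold("test")
    L = model.config.encoder.input_length
    obs = observed_gene_counts(stores["rna"], test_genes, L,
                               model.config.n_output_bins)
    pred = pd.DataFrame(
        {g.name: predict_gene_counts(model, world.genome, g,
                                     world.cells.embedding)
         for g in test_genes},
        index=stores["rna"].barcodes,
    )
    lab = pd.Series(world.cells.labels)
    return eval_gene_level(pseudobulk(pred, lab), pseudobulk(obs, lab))


def score_motifs(world, model, seed: int, assays=("expression",),
                 genes=None, activity_margin: float = 0.5) -> tuple:
    """Score each planted motif; tabulate sign recovery per (motif, type).

    Returns (tables, recovery frame). Qualifying pairs have
    |planted activity| >= activity_margin; recovery marks whether the sign
    of the cell-type mean TF score matches the planted sign.
    """
    act = world.regulation.activity
    labels = pd.Series(world.cells.labels)
    if genes is None:
        # scoring uses a 24-gene training subset (runtime scales with genes)
        genes = [g for g in world.genes
                 if world.splits[g.name] == "train"][:24]
    else:
        genes = list(genes)
    tables: dict = {}
    rows = []
    for i, pwm in enumerate(world.regulation.motif_pwms):
        tables[pwm.name] = {}
        for assay in assays:
            table = tf_motif_effect(model, world.genome, genes, pwm,
                                    world.cells.embedding,
                                    barcodes=world.cells.barcodes,
                                    assay=assay, seed=seed + i)
            tables[pwm.name][assay] = table
            by_type = table.cell_type_scores(labels)
            for t, score in by_type.items():
                a = act.loc[t, pwm.name]
                if abs(a) < activity_margin:
                    continue
                rows.append({"motif": pwm.name, "cell_type": t,
                             "assay": assay, "activity": a, "score": score,
                             "sign_match": bool(np.sign(score) == np.sign(a))})
    return tables, pd.DataFrame(rows)


def score_variants_and_deconvolve(world, stores, model) -> tuple:
    """Per-cell-type variant effects, model ranking vs the two baselines."""
    labels = pd.Series(world.cells.labels)
    label_list = [world.cells.labels[b] for b in world.cells.barcodes]
    effects = {}
    for v in world.variants:
        eff = score_variant(model, world.genome, v, world.genes[v.gene],
                            world.cells.embedding, label_list,
                            with_accessibility=False)
        effects[f"{v.chrom}:{v.pos}"] = eff.per_cell_type
    effect_matrix = pd.DataFrame(effects).T
    truth = world.regulation.variant_truth
    vids = list(effect_matrix.index)
    positives = {
        (vid, truth.iloc[i]["causal_type"]) for i, vid in enumerate(vids)
    }
    # baselines from the observed toy data
    rna_counts = stores["rna"].simulated_read_counts.astype(float)
    peak_counts = _peak_count_matrix(world, stores["atac"])
    extra = {"expression_baseline": {}, "atac_baseline": {}}
    for i, vid in enumerate(vids):
        v = world.variants[i]
        extra["expression_baseline"][vid] = baseline_expression_rank(
            rna_counts, labels, v.gene
        )
        extra["atac_baseline"][vid] = baseline_atac_peak_rank(
            peak_counts, labels, world.peaks, v
        )
    bench = deconvolve(effect_matrix, positives, variance_quantile=0.0,
                       ks=(1,), extra_rankings=extra)
    precision = {m: p[1] for m, p in bench.precision_at.items()}
    return effect_matrix, precision, bench


def _peak_count_matrix(world, atac_store) -> pd.DataFrame:
    from .fragments import bin_coverage

    cols = {}
    for name, chrom, ps, pe in world.peaks:
        b0 = ps - ps % 32
        nb = -(-(pe - b0) // 32)
        prof = bin_coverage(atac_store, chrom, b0, nb, clip=True)
        cols[name] = prof.values.sum(axis=(1, 2))
    return pd.DataFrame(cols, index=atac_store.barcodes)


def run_study(seed: int = 1, epochs: int = 50,
              with_accessibility_scores: bool = False) -> StudyResult:
    world = generate_world(default_sim_config(seed))
    stores = {
        "rna": simulate_rna_fragments(world, RNA_DEPTH, seed=seed + 7001),
        "atac": simulate_atac_fragments(world, ATAC_DEPTH, seed=seed + 7002),
    }
    model, result = train_study_model(world, stores, seed, epochs)
    gene_report = evaluate_test_fold(world, stores, model)
    assays = ("expression", "accessibility") if with_accessibility_scores \
        else ("expression",)
    motif_tables, recovery = score_motifs(world, model, seed, assays=assays)
    effect_matrix, precision, bench = score_variants_and_deconvolve(
        world, stores, model
    )
    return StudyResult(world, stores, model, result, gene_report,
                       motif_tables, recovery, effect_matrix, precision,
                       extras={"benchmark": bench})
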