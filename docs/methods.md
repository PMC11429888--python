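# Methods

## The model

`scprofile` models single-cell RNA coverage and ATAC insertion profiles
along the genome from DNA sequence. The architecture has three parts:

1. **Sequence encoder.** A convolution + transformer network maps a one-hot
   window of L bp (L divisible by 32) to an embedding of L/32 bins × D
   channels. The full-scale geometry is L = 524,288 bp and D = 1,920
   channels with predictions made for the center 6,144 bins (196,608 bp);
   the desk-scale default used throughout the tests is L = 8,192 bp
   (256 bins, no crop) and D = 64. The package's own encoder
   (`TinyBackbone`) is a stride-4 convolution stem, two further
   convolutions with pooling (total pooling 32×), sinusoidal position
   codes, multi-head self-attention blocks, and two global-context
   pathways — an additive residual and a multiplicative (FiLM-style) gate
   driven by the mean bin embedding — that let per-bin amplitude scale
   with window-wide features such as total regulatory-site dosage. The
   conv stack is normalized with channel-wise LayerNorm: normalizing each
   channel across all positions of a window (instance-style batch norm)
   destroys exactly the occupancy information ("how many positions fire")
   that window-level outputs need. A `BatchNorm1d` layer with a freezing
   switch is provided for encoders that use it; the stabilization phase at
   the start of training freezes normalization statistics and disables
   dropout for a configurable number of epochs (default 1).

2. **Low-rank adapters and head.** Every convolution and the query/value/
   MLP projections of the attention blocks can be wrapped with LoRA
   adapters (rank 8 by default; scaling α/r = 1 since only the rank is
   prescribed): `W_eff = W + (α/r)·B·A`, `B` initialized to zero so the
   adapted encoder is exactly the base encoder at the start, and the delta
   can be merged back into `W` after training (equivalence verified to
   ≤ 1e-5 in float32). A trainable per-position affine map with GELU (the
   "pointwise head") refines the encoder embedding. When a pretrained
   encoder is adapted, only adapters + head + decoder receive gradients;
   when no pretrained weights exist — the desk-scale study trains the tiny
   encoder from scratch — the whole encoder trains end to end and the LoRA
   machinery is exercised by its own contract tests.

3. **Hypernetwork decoder.** A small MLP (two hidden layers of 256, GELU —
   the depth/width are not prescribed and are configurable) maps each
   cell's embedding vector (dimension 14 by default) to the weights of a
   position-wise linear read-out: shape (D+1, 2, 1) for stranded RNA
   (filter + bias per strand; 1,921 leading dimension at full scale) and
   (D+1, 1, 1) for unstranded ATAC. The read-out activation is a softplus,
   keeping decoded profiles nonnegative; the activation is not prescribed
   either and is a package choice. One hypernetwork per assay shares the
   same embedding input. Decoding is position-wise, so expression can be
   decoded only on exon-overlapping bins at cost proportional to the exon
   count.

Coverage is modeled on the squashed scale: `y = (s·x)^p` soft-clipped at
`clip_soft` (`y → clip_soft + sqrt(y − clip_soft)` above it), with p = 3/4,
clip_soft = 5 and pre-scale s = 1 for RNA, s = 0.05 for ATAC (inverted with
×20 at inference). The exponent and pre-scale are parameterized assumptions;
the transform is strictly increasing and exactly invertible, which the
suite checks to 1e-9 relative error.

## Training

The loss couples a Poisson term on window-total counts (divided by the bin
count and weighted by `poisson_weight`) with a multinomial term on the
positional distribution, per cell and track. Numerically the epsilon enters
the multinomial before the division so that an all-zero prediction (float32
softplus underflow) stays finite; steps with non-finite gradients are
skipped. With `poisson_weight = n_bins` the combination is algebraically the
per-bin Poisson likelihood; the desk-scale study uses exactly that setting
(256) because with a few thousand optimization steps the totals must carry
as much gradient as the shapes — the config default (0.2) matches the
published weighting of the scheme this follows, which assumes training runs
orders of magnitude longer. ATAC terms are up-weighted ×20 to undo the 0.05
pre-scale's effect on the multi-task balance.

Augmentation shifts the input window by up to ±3 bp (targets re-extracted
for the shifted window) and reverse-complements with probability 1/2,
reversing target bins and swapping the RNA strand tracks (strand identity
inverts under RC; unstranded ATAC flips positions only). Optimization is
AdamW with two parameter groups — decoder at 4e-4, adapters + head at
2e-4 by config default, the fine-tuning rates of the original setting —
with linear warmup then linear decay, gradient clipping at 1.0 and weight
decay 1e-6. The from-scratch desk-scale study raises the rates ×10
(4e-3 / 2e-3, warmup 100 steps), since the published rates are tuned for
adapting a pretrained network. An exponential moving average of trainable
weights (decay 0.995) is used for validation and the returned model. Each
epoch, validation computes both gene-count correlations on the validation
genes — the per-cell-type across-gene Pearson of log2(pseudobulk+1) and
the doubly mean-centered across-cell-type Pearson; the checkpoint
maximizing their sum is retained (with only a handful of validation genes
the cell-type metric alone fluctuates by ±0.4 between epochs and its
argmax selects flukes; both values are logged per epoch).

Inference averages the forward pass with the reverse-flipped prediction of
the reverse-complemented sequence, then inverts the squashed scale (ATAC
×20). Gene counts sum natural-scale coverage over bins overlapping any exon
(union; ≥1 bp intersection) on the track matching the gene strand, in a
window centered on the gene-body midpoint; windows beyond chromosome edges
are N-padded so bin arithmetic is preserved.

## The synthetic multiome world

The generator builds a self-contained world in which every downstream claim
can be checked against planted truth:

* **Genome & genes.** 8 chromosomes × 98,304 bp, 96 genes (the study holds
  out the last chromosome: 4 validation + 8 test genes). Genes default to a
  canonical 2-exon anatomy (600 + 600 bp, 400 bp intron) in plus
  orientation; variable anatomy (`exon_layout="random"`) and mixed strands
  (`strand_mode="both"`) are supported and unit-tested. Gene structure is
  written into the sequence — core-promoter word at the TSS, splice
  donor/acceptor words at intron boundaries, a polyadenylation signal at
  the 3' end — because a sequence model cannot place coverage whose
  location is not sequence-encoded.
* **Planted regulation.** Four 8-bp consensus motifs: a universal activator
  (+0.8 per site, all cell types), two type-specific activators (+1.5 in
  one of three types each) and a repressor (−1.5 in the third type). Gene
  rates are log-linear in site counts: `rate[t,g] = exp(Σ_m k_{g,m}
  a_{t,m})`. Each non-variant gene carries at most one specific motif plus
  a small universal dose (0–2): dose-response and cell-type specificity
  stay individually identifiable from ~80 training windows. The background
  is scrubbed of chance consensus occurrences, so a motif match is a
  planted site and recovery tests measure the model, not collisions.
* **Accessibility.** Each gene has a promoter peak whose openness follows
  its regulation (attenuated, exponent ×0.5), and every bound motif site
  is an accessible 128-bp footprint, open where its factor is active
  (intensity `exp(activity)`). This mirrors real multiome data — bound
  regulatory elements are Tn5-accessible — and is what makes motif
  detectors learnable from profile supervision at this scale.
* **Cells.** 240 cells in 3 balanced types; embeddings are the generator's
  latent type centroids plus Gaussian noise (σ = 0.3), dimension 14;
  per-cell depth factors are lognormal (σ = 0.25). Embedding-model
  internals are out of scope: the decoder only needs a vector separating
  cell states.
* **Reads.** scRNA reads (96 bp) are drawn per cell with Poisson gene
  counts proportional to within-type rate shares times depth; read starts
  decay geometrically from the transcript 3' end (0.003/bp, spreading the
  bias over a realistic ~300–800 bp); junction-spanning reads are emitted
  as split fragment records on the gene's strand. scATAC fragments
  (60–150 bp) fall inside peaks chosen by type-specific intensity shares,
  with a 5% uniform background. Study depths are 600 reads and 1,000
  fragments per cell — deliberately deeper per feature than a real
  experiment, compensating for having ~270× fewer cells than a real
  dataset would provide.
* **Variants.** Six genes carry a planted single-nucleotide variant that
  breaks one high-information position of a type-specific activator site.
  These genes also carry two sites of the *other* type's activator, so the
  causal cell type is deliberately not the top-expressing type (defeating
  the expression baseline), and the variant-carrying site is
  constitutively open (accessibility does not betray the causal type to
  the peak baseline) — the regime where sequence-based deconvolution adds
  information over both baselines, and the decoupling of accessibility
  from expression that motivates scoring the two layers separately.

What the passing tests do and do not show: the world has strong, clean,
log-linear planted effects, balanced cell types, no batch effects, no
doublets, no sequencing errors, and motif sites that match their consensus
exactly. Success here demonstrates that the architecture, losses, scoring
procedures and benchmarks are implemented coherently end to end — not that
the approach reaches any particular accuracy on real single-cell data.

## Motif and variant scoring

PWM scanning converts log-odds scores into p-values by dynamic programming
over the per-position score distribution discretized at 1/1000 bits
(exhaustively verified for widths ≤ 6 up to the discretization bound);
hits are positions on either strand with p ≤ 1e-4. For the TF motif
effect score, all hit spans in a gene-centered window are replaced
simultaneously with uniform random sequence (overlapping spans merged,
since simultaneous replacement of overlapping spans is ill-defined), 10
independent replacement draws are averaged, each cell is normalized by its
reference-derived size factor (reference total over the gene set divided by
the cohort median of that total), and the score is the mean over genes of
log2(ref+1) − log2(mut+1): positive for activators, negative for
repressors. Target genes are those with |cell-type-mean effect| > 0.1.

Variant scoring centers the window on the SNV, verifies the reference
allele against the genome, and computes per cell type
log2((Σ alt + 1)/(Σ ref + 1)) on natural-scale exonic sums (accessibility:
window totals); the aggregate is the unweighted mean over cell types.
Effects with |log2FC| < 0.05 (3.5% fold change) are negligible; the
boundary is inclusive on the non-negligible side. Deconvolution ranks cell
types by |effect| (ties by name), keeps variants in the top 15% of
across-type effect variance in the benchmark configuration (the study
scores its 6 planted variants directly), and reports precision@k against
fine-mapped positives, with the expression-rank and nearest-peak
accessibility baselines computed from size-factor-normalized pseudobulk of
the same toy data. Gradient attribution takes the gradient of
log(1 + summed exonic expression of the eGene over cells of the queried
type) at the reference sequence with respect to the one-hot input, and
reports the 10-bp window centered on the variant as a PWM: columns are
2^gradient, sum-normalized.

## Numerical choices

The trainable components run on a compact reverse-mode autodiff engine
over numpy arrays in float32 (tolerances in the suite reflect this:
merge equivalence ≤ 1e-5, slice-vs-full decode within 1e-5 relative).
Zero-variance vectors yield missing (NaN) correlations, excluded from
means and counted in the report. Ambiguous bases one-hot to the zero
vector. All random draws flow from explicit seeds; training is
deterministic for a fixed seed and a single worker.

## Known limitations

The toy world's regulatory grammar is far simpler than real enhancer
logic (no cooperativity, spacing rules, or chromatin context); the
desk-scale encoder is ~4 orders of magnitude smaller than a production
model and is trained from scratch rather than adapted from a pretrained
foundation; per-cell depths are unrealistically generous per feature; and
profile-level metrics on single sparse cells are dominated by sampling
noise, which is why gene-count aggregates drive evaluation and checkpoint
selection.
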