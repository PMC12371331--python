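# Methods

## Problem setting

`seqddg` predicts the change in binding free energy of an antibody–antigen
complex upon mutation (ΔΔG = ΔG_mut − ΔG_wild, kcal/mol; positive values
destabilize binding, via ΔG = −RT ln(1/Kd)) from sequence alone.  Each data
point supplies the wild-type antibody and antigen chain sequences, a list of
1–7 point substitutions, and a measured ΔΔG.  The mutant sequences are
derived by applying the substitutions; the model then sees four sequences
per record: wild-type and mutant antibody, wild-type and mutant antigen.

## Model

Per-residue embeddings H ∈ ℝ^{L×d} for the four sequences come from a
frozen, pluggable embedder (see *Embeddings* below).  The trainable
regressor is:

1. **Input projection** (only when the embedder width differs from the model
   width): a learned d → d_model linear map, shared by all four streams.
2. **Convolutional position gating.**
   H′ = softmax(Conv1D(LayerNorm(H))) ⊙ LayerNorm(H),
   where Conv1D maps the d_model channels to a single spatial score per
   position (kernel size 1 by default; any odd kernel is supported) and the
   softmax runs across sequence positions, broadcast over features.  The
   gate reweights positions, not features: the alternative reading (a
   per-position softmax over channels) would not produce "spatial" weights
   and is not implemented.
3. **Rotary Q/K projection.**  Q = RoPE(H′ W_q), K = RoPE(H′ W_k),
   V = H′ W_v.  RoPE rotates consecutive dimension pairs (2i, 2i+1) of row
   m by m·θ_i with θ_i = base^(−2i/d_model) (base 10⁴), so attention logits
   depend only on relative positions.  Rotation is applied to the full
   projected matrix before head splitting; because heads take contiguous
   dimension blocks this equals per-head rotation with shifted pair indices.
4. **Dual multi-head cross-attention.**  Antibody queries attend over
   antigen keys/values and vice versa, separately for the wild-type and
   mutant pairs: A = softmax(Q_ab K_ag^⊤ / s) V_ag and symmetrically.  The
   default scale s is the head dimension itself (`scale_mode="d_head"`);
   the conventional √d_head is available as `"sqrt_d"`.  Heads are
   concatenated and projected by W_o.
5. **Convolutional pooling.**  A scalar score per position,
   W_c·LayerNorm(H_o^l), softmaxed across valid positions, weights a sum of
   the normalized rows — masked attention-pooling producing one vector per
   stream: {f_ab^wt, f_ag^wt, f_ab^mt, f_ag^mt}.
6. **Prediction head.**  f = concat(f_ab^wt + f_ag^wt, f_ab^mt + f_ag^mt);
   ŷ = W_3·tanh(W_2·relu(dropout(W_1·f))).

One set of gate / projection / pooling weights serves all four streams: the
pipeline applies *the same operation* to each representation in parallel,
which we read as weight sharing (it also keeps the parameter count
independent of sequence roles).

### Defaults

| parameter | default | note |
|---|---|---|
| d_model | 256 | width after input projection |
| n_heads | 8 | must divide d_model; head dim even (rotary pairs) |
| scale_mode | d_head | logits divided by d_head |
| dropout | 0.1 | active only in training, on W_1·f |
| conv_kernel | 1 | odd kernels supported |
| rope_base | 10⁴ | |
| head widths | (64, 32) | the two hidden layers of the head |

Desk-scale studies (below) use d_model 32 with 2 heads to match the mock
embedder; all values are config-overridable.

### Ablation variants

`no_attention` removes steps 3–5's attention entirely (pooling applies to
the gated streams); `mlp_replacement` swaps the attention block for a
position-wise two-layer MLP whose hidden width 2·d_model reproduces the
4·d_model² weights of {W_q, W_k, W_v, W_o} exactly, so comparisons are
parameter-matched by construction (enforced within ±10%).

## Embeddings

The embedder contract is: frozen, per-residue output (special tokens
stripped, row count = residue count), deterministic in (sequence, spec).
Pre-trained protein-language-model backends plug in through
`register_embedder`.  The shipped backend is a **mock embedder** — a test
double, not a scientific claim: row(letter, pos) = base(letter) +
0.1·noise(letter, pos), both components hash-seeded.  It is deliberately
non-contextual so a point mutation perturbs exactly one row, and the
residue-identity component dominates so residue identity is decodable from
any row.  Embeddings are cached content-addressed (SHA-256 of sequence and
spec); the frozen embedder makes cache entries permanently valid.

## Training and evaluation

AdamW (β = 0.9/0.999, decoupled weight decay 0.01) minimizes MSE; the
embedder is excluded from optimization entirely.  Early stopping monitors
the MSE on a seeded 10% validation slice of the training partition and
returns the best-validation parameters (patience 10 by default).  Because
fits of this size occasionally stall in a poor basin, `restarts > 1`
enables multi-start optimization: each restart trains from a different
seeded initialization for `pilot_epochs` (30), the restart with the lowest
validation MSE continues to `max_epochs`, and the rest are discarded.  The
continued run's total epoch count never exceeds `max_epochs`.

Metrics: RMSE (kcal/mol), R² = 1 − SS_res/SS_tot (negative for
worse-than-mean predictors; reported as such), Pearson r, Spearman ρ with
average ranks on ties.  Correlations on degenerate inputs (n < 2 or a
zero-variance side) are reported as NaN with a reason, never as 0.
Cross-validated reports aggregate as mean ± standard deviation across
folds.

Three split protocols:

* **k-fold** — seeded exhaustive partition, fold sizes within 1.
* **Sequence-identity split** — records are clustered on their mutant
  complex sequence (antibody+antigen concatenated; configurable) by greedy
  single-linkage at 30% identity, where identity = 1 − edit-distance /
  max-length from a global (Needleman–Wunsch-mode) edlib alignment.  Whole
  clusters are assigned train-first, largest-first with a seeded shuffle
  among equal sizes, targeting an 8:2 record ratio; at least one cluster
  always tests.  When an `mmseqs` executable is on PATH, MMseqs2
  easy-cluster replaces the built-in clustering.
* **Mutation-depth split** — single-point records train, multi-point
  records test.

## Synthetic data

The generator emulates the *shape* of curated ΔΔG benchmarks — 32
complexes, 7–24 variants each, mutation depths 1–7 (default mass 0.7/0.2/0.1
on depths 1–3) — with a fully known ground truth:

label = Σ_m s(wt_m, mut_m) + Σ_{m ∈ interface} b·coupling(m) + ε,
ε ~ N(0, 0.2²) kcal/mol.

* **Effect table.**  s(w, m) = u(m) − u(w) + 0.3·ε_wm clipped to [−2, 2]:
  a residue-intrinsic propensity difference plus a pair-specific residual,
  frozen (seeded) and shipped as a CSV.  Mutation effects in empirical
  substitution data track residue-intrinsic properties (hydrophobicity,
  volume); a table with this structure is both more realistic than an
  arbitrary pair table and actually recoverable from sequences — which is
  the generator's purpose.  An arbitrary iid pair table was probed and makes
  the additive structure undecodable at this scale for any learner.
* **Mutation sampling** is alanine-biased (60% of substitutions to A,
  mirroring alanine-scanning-heavy curated panels), sides antibody-weighted
  (85%).
* **Interface.**  Each complex designates 5 antibody positions whose
  antigen partner is the *same sequence index* (a diagonal paratope–epitope
  contact geometry).  A mutation at an interface position earns b = 1.5
  kcal/mol only when the partner residue in the mutant antigen is
  hydrophobic (F/L/I/V/W).  The aligned geometry matters: rotary
  cross-attention can express "attend at relative position 0" while a
  pooling-only model cannot condition on specific partner positions, so the
  bonus is a signal the ablation comparison can actually detect.
* Chain lengths default to 20–30 residues per side — far shorter than real
  antibody chains; this is a deliberate desk-scale choice so that full
  training runs complete in minutes on one CPU.

What passing tests on this generator do **not** show: performance on real
complexes (no evolutionary context in the mock embeddings, no real ΔΔG
label distributions, no chain-length realism, no experimental noise
structure).  The generator validates the machinery — losses, splits,
attention mechanics, effect recovery — not biology.

## Standard desk-scale studies

`seqddg.experiments` fixes two reproducible end-to-end studies (both
seeded; the test suite runs the ablation study at its full 5 repetitions,
`scripts/acceptance.py` at 3):

* **Learnability** — 500 records, additive-only truth (b = 0), noise 0.2,
  80:20 record split; d_model 32, 2 heads, no dropout, lr 3·10⁻³, batch 8,
  ≤200 epochs, 3 pilot restarts.  Success criterion: held-out Pearson
  r ≥ 0.8.  Dropout is disabled here deliberately: with frozen
  non-contextual embeddings the informative wild-type/mutant feature
  difference is small, and multiplicative dropout noise on the head's first
  layer reliably traps optimization at the per-complex-mean solution.
* **Ablation** — 5 repetitions; each draws 500 records from a fresh seed,
  trains the full model and the parameter-matched MLP replacement under
  identical settings (≤200 epochs), and compares held-out Pearson r.  The
  ablation datasets are *interaction-dominant* by design: single-point
  records, every antibody mutation at an interface position, bonus raised
  to 3 kcal/mol — so a large share of the label variance lies on the
  cross-sequence term the ablated variants cannot resolve.  On
  additive-dominant data the position-wise MLP is the stronger desk-scale
  learner (it passes per-position information straight through to pooling),
  so that regime cannot separate the architectures.  Reported as the number
  of repetitions in which the full model meets or beats the variant.

## Numerical choices

* Softmaxes are max-subtracted; masked entries are exactly zero and receive
  no gradient; an all-masked axis raises rather than returning NaN.
* LayerNorm ε = 10⁻⁵ over the feature axis.
* Masking invariance (padding plus mask changes nothing) holds to 10⁻⁵ and
  is tested for every masked operation and the fused forward pass.
* The tensor engine is a minimal reverse-mode tape over float64 numpy
  arrays written for this package; every operation's gradient is checked
  against central finite differences in the test suite, and the fused
  forward pass is checked against an independent loop-based
  re-implementation.
* `top_interactions` breaks score ties by key index (deterministic
  reports).
* No argmax appears in the forward pass; there are no other tie-breaks.

## Known limitations

* The published-scale configuration (PLM embeddings, d_model 256, real
  benchmarks) is expressible but not exercised here: no pre-trained
  language-model backend ships with the package, and the Python-level
  tensor engine is sized for desk-scale experiments, not GPU-scale
  training.
* The default attention scale divides logits by the head dimension rather
  than its square root; both scalings are implemented behind a config
  switch, and no empirical comparison between them is made here.
* Identity clustering is greedy single-linkage on edit-distance identity —
  adequate for the synthetic regime; MMseqs2 is preferred when available.
* Attention-based interaction reports are qualitative: row-stochastic
  weights rank partners but carry no calibrated energetic meaning.
* The ablation comparison is meaningful against the MLP replacement on
  interaction-dominant data.  Under record-level splits the `no_attention`
  variant is not consistently worse: test records share complexes with
  training records, so any per-position model can memorize each complex's
  hot interface positions without reading the antigen.  Under complex-level
  splits every variant collapses — none of the desk-scale models transfers
  the cross-sequence rule to unseen complexes.
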