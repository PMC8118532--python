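# Methods

## Model

`cogdecode` decodes the psychological condition behind a subject-level
z-statistic map with a factorized linear model applied per study `j`:

```
logits = U^j · L · s(D x) + b^j,      prediction = argmax over the study's contrasts
```

`x ∈ R^p` is the masked map (row-major scan of in-mask voxels, a fixed
convention so serialized models stay valid), `D` the `(k×p)` non-negative
sparse dictionary of functional units, `s` a per-feature z-scoring of the
projected features frozen on the training fold, `L` the `(l×k)` embedding
shared across studies, and `(U^j, b^j)` the study head with one row per
contrast. All layers are linear by design: every intermediate
representation and every classification map (`U^j L diag(1/scale) D`, rank
at most `l` when stacked) remains a brain map that can be inspected.

The working assumption is that activation maps decompose onto a modest
number of latent spatial networks reused across cognitive paradigms. The
shared `L` is where transfer happens; heads stay study-specific because
contrast labels are never matched across studies.

## First layer

`fit_functional_units` minimizes
`½‖X − A D‖²_F + λ Σ_r ‖D_r‖₁` subject to `D ≥ 0`, `‖D_r‖₂ ≤ 1`, `A ≥ 0`,
by deterministic full alternations: loadings by exact non-negative least
squares (block coordinate descent, vectorized across samples; warm-started
across epochs), dictionary rows by block coordinate descent. For an
isotropic row subproblem, soft-thresholding, clipping at zero and projection
onto the unit ball compose into the exact proximal step, so every row
update is the constrained row minimizer and the recorded objective is
non-increasing — a property the tests assert at tolerance 1e-8. Rows that
shrink to zero are re-seeded from the worst-reconstructed sample at a
negligible scale (the next loadings step compensates; keeping the scale
tiny preserves the monotone trace). `batch_size` only chunks the loadings
computation (the problem separates per sample) and does not change the
result.

Rest data is smoothed with an isotropic Gaussian (sigma 1.5 voxels) before
factorization — standard fMRI preprocessing that acts as a matched filter
for spatially smooth components. At the default rest noise level the
per-direction signal variance of a single frame is far below the spectral
detection threshold of the raw data matrix, so smoothing (or an infeasibly
large number of frames) is required for the units to latch onto structure
rather than noise.

Defaults: `k = 48` units on the ~850-voxel synthetic mask, `λ = 0.1`
(yielding ≥50% zero entries at the default conditions), 15 epochs. A
production-scale configuration uses several hundred units (e.g. k = 465 on
a full grey-matter grid); `k` well above the number of expected latent
networks is deliberate — the units are a fine-grained parcellation, not the
networks themselves.

## Joint training

`train_multistudy` minimizes

```
Σ_j (1/n^j) Σ_i CE(U^j L s(D x_i^j) + b^j, y_i^j) + l2 · ‖U^j‖²
```

with Adam (lr 1e-3, β = (0.9, 0.999), ε = 1e-8). The `1/n^j` weight uses
the subject count, deliberately up-weighting small studies. At each step one
study is drawn uniformly (cyclic available via config); a batch of its
samples is taken without replacement from an epoch-shuffled per-study
order; the batch loss is scaled by `c^j/B` so it is an unbiased estimate of
the study term. Inverted dropout is applied to the projected features
(rate 0.25) and the embedded features (rate 0.5) during training only; `L`
is regularized by dropout alone, `l2 = 1e-4` applies to heads only, and
`b^j` is unpenalized. `L` starts from `N(0, 1/k)` entries, heads from zero,
so the untrained model predicts exactly at chance — a testable anchor.
Training runs 400 epochs by default: the desk-scale corpus is small enough
that Adam at lr 1e-3 needs that long to converge, and each run still takes
about a second. Runs are bit-reproducible from the config seed; exact
analytic gradients are checked against finite differences in the tests.

The latent width defaults to `l = 16`, twice the generator's true latent
dimension. Two reasons: in practice the true dimension is unknown and one
chooses `l` generously (the production-scale choice is l = 128, far above
the number of interpretable networks); and a strict bottleneck at the true
dimension measurably fails to cover latent directions that are weakly
expressed in the decoding objective, while a modest surplus lets the span
of `L D` cover them.

## Consensus

`U^j L` is invariant to `(L, U^j) → (M L, U^j M⁻¹)`, so `L` is not
identified — but the span of `L D` is stable across seeds (asserted against
a random-subspace null). `extract_mstons` stacks the `R` unit-normalized
embeddings into `L̃` and minimizes `‖L̃ − K L̄‖² + λ_c Σ‖L̄_r‖₁` with
`L̄ ≥ 0` (`K` free), alternating exact least squares for `K` with
non-negative shrinkage coordinate descent for `L̄`, initialized from the
non-negative part of the first run's embedding. Row normalization of `L̃`
makes the default `λ_c = 0.02` scale-free; it is chosen so the consensus has
at least ~30% zero entries under the default conditions (sparsity is what
makes the networks readable as a soft parcellation). The objective is
tracked per alternation and never increases; rows are rescaled to unit norm
at the end with `K` compensating, which leaves the product unchanged.
An empty row is re-seeded once from the largest residual direction, then
raises. Consensus heads are refit per study by l2-regularized multinomial
regression (lbfgs, tol 1e-8) on the frozen features `L̄ s(D x)` — a convex,
deterministic step. MSTON maps are the rows of `L̄ D`, non-negative by
construction; each network is associated to contrasts by cosine similarity
with the classification maps and named from similarity-weighted name tokens
(the machine-readable stand-in for word-cloud figures).

## Evaluation

- **Half-splits** (default 20 repeats; 10 in the acceptance script):
  each study's subjects are split into halves, resampled up to 100 times so
  every contrast appears on both sides (the metrics are undefined
  otherwise); deterministic under the seed.
- **Baselines**: per-study l2 multinomial regression on raw voxels or on
  `s(D x)`, with the l2 strength chosen on a deterministic inner
  subject-wise 2-fold split from the fixed grid {1e-4, 1e-2, 1}.
- **Balanced accuracy** is one-vs-rest `(sensitivity + specificity)/2` per
  contrast, so chance is 0.5 regardless of the number of contrasts;
  contrasts absent from a fold are recorded as missing, not zero.
- **Transfer summaries** report the mean and median accuracy delta, the
  fraction of study-by-split experiments improved, and the fraction of
  studies improved — both of the latter, since either reading of
  "experiments improved" may be wanted.
- **Similarity structure**: cosine matrices (Pearson can be substituted by
  flag at the caller level since maps are mean-free in practice),
  average-linkage clustering on `1 − cosine`, cophenetic correlation, mean
  absolute off-diagonal cosine, Newick export of the tree.

## Synthetic data

The generator draws `k_true = 24` truncated-Gaussian blob atoms (values
below 5% of peak zeroed, unit norm) on a 12×14×12 grid with an ellipsoidal
~850-voxel mask, `l_true = 8` latent networks (non-negative combinations of
3 atoms, unit norm), and for each of `N = 6` studies a set of 3–8 contrast
codes supported on 3 latent dimensions; a fraction ρ = 0.75 of the latent
dimensions is usable by every study, the rest by a single study. Subject
maps are `x = (W^j_c + η_s) L_true D_true + ε` with `η_s ~ N(0, τ²I)` drawn
once per subject and shared across that subject's contrasts (a subject-level
confound that subject-wise validation must overcome), `ε ~ N(0, σ²)` per
voxel, σ = 1.0 and τ = 0.5 by default. Rest data is
`X = A D_true + E` with `A ~ |N(0,1)|` over `n_rest = 1500` frames —
rest repositories are much larger than any task study, and the first layer
is meant to be trained well. Contrast codes have norm 3.0, putting
single-study decoding in an intermediate-accuracy regime (neither floor nor
ceiling), which is where transfer effects are scientifically interesting.

What the generator does *not* emulate: haemodynamics, temporal or spatial
autocorrelation of noise beyond atom smoothness, site/scanner effects,
non-linear subject variability, or label noise. One consequence matters for
interpreting the tests: because synthetic maps are *exactly* low-rank in
smooth non-negative atoms, projecting onto rest-derived units is strongly
denoising, and the network-projection baseline already outperforms voxel
decoding — on real data, where rest networks are not tuned to the task
signal, projection alone is roughly accuracy-neutral. Passing tests
therefore demonstrate the transfer mechanism (shared embedding beats
independent decoders, gains grow as studies shrink, the latent span is
recovered and stable), not the real-data magnitude of any gain.

## Numerical choices and degenerate inputs

Ties in `argmax` go to the lowest label index. Standardization scales are
floored at 1e-8 (constant features pass through unscaled). Sub-seeds for
ensembles and repeats are small integer offsets of the run seed. Maps on a
different grid are resampled trilinearly onto the mask grid
(nearest-neighbour for masks). Zero-norm maps: associations score 0 with a
warning; similarity clustering refuses them, as it refuses fewer than 3
maps or an all-equal distance matrix (cophenetic coefficient undefined).
Consensus head refits refuse feature matrices with fewer than two
informative components. Model serialization stores raw little-endian
float64 arrays with sha256 checksums and a format version; corruption and
version mismatch raise distinct errors.

## Problem sizes

Tests and the acceptance script run the full stack at the desk scale
described above (≈500–900 samples per corpus, k = 48, l = 16, R = 4
ensembles, 10 half-split repeats), which exercises every code path in a few
minutes on one CPU. Full-scale parameters (k = 465, l = 128, dozens of
studies) are accepted by the same code paths and are covered by shape-level
tests.

## Known limitations

The solver family is batch alternating minimization, adequate at desk scale
but not the streaming algorithm one would use for millions of rest frames.
Dropout rates, learning rate and epochs were chosen for the synthetic
conditions and are exposed in `TrainConfig` rather than claimed optimal for
real corpora. Negative transfer (large or cognitively isolated studies
losing accuracy) is visible in per-study tables but is not specifically
modelled or mitigated.
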