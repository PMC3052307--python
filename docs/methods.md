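# Methods

## Problem setting

Ubiquitin is conjugated to substrate lysines by the E1 (activating), E2
(conjugating) and E3 (ligating) enzyme cascade. E3 ligases supply substrate
specificity and engage the substrate over an extended surface, so sequence
determinants of modification need not sit adjacent to the modified lysine.
The package treats site prediction as binary classification of lysines
from a (2n+1)-residue window (offsets −n…+n, default n = 20), with the
explicit goal of detecting and exploiting *distant* within-window signal.

Coordinates are 1-based; window offsets are relative to the central K.
Positions past the protein termini are a 21st "terminal" symbol (`-` in
text). Unknown residues (X) are accepted in sequences; they contribute
nothing to composition counts or PSSM pooling and encode as zeros in the
BLOSUM block.

## Training-set redundancy reduction

Two proteins are homologous when the best local alignment (BLOSUM62,
gap open 11, extend 1 — standard protein BLAST defaults) has
identity = matches/aligned-columns > 0.30. Between homologous proteins,
fragments with identical window strings are collapsed to the first
occurrence in input order; positive and negative classes are reduced
independently, and fragments of a single protein are never collapsed
against each other (distinct sites are distinct observations). The rule
is applied pairwise, not by clustering, and is idempotent.

Note that local-alignment identity is generous: any two proteins sharing
one identical window already have a perfect-identity local alignment over
it, so the homology gate is effectively "shares enough similar sequence
anywhere". The `threshold` parameter (and the `--identity` flag) can relax
or disable the gate.

## Feature encodings

Blocks are concatenated in fixed order AAC, AAPC, BLOSUM, PSSM400, ASA,
SS; each encoder is pure and deterministic. The amino-acid order is
ARNDCQEGHILKMFPSTWYV throughout.

* **AAC** (20): residue counts over the window divided by the count of
  effective residues (markers and X excluded from numerator and
  denominator). Computed over the window by default; a flag switches to
  whole-protein composition.
* **AAPC** (400): adjacent-pair counts divided by the effective residue
  count, so the entries sum to (L−1)/L for a clean window; pairs spanning
  a marker or X are skipped.
* **BLOSUM** (21·(2n+1)): per position, the residue's BLOSUM62 row scaled
  to [0,1] by a global min–max over the 20×20 integer matrix (the simplest
  order-preserving normalisation), plus a terminal flag channel that is 1
  (with the row zeroed) beyond the termini.
* **PSSM400** (400): the m rows of the protein's L×20 PSSM centred on the
  site (m odd, default 2n+1; rows outside the protein skipped) are summed
  into the row of their sequence residue type, giving a 20×20 matrix;
  every element is divided by m — by m even near termini, keeping the
  scale fixed — and squashed with the logistic 1/(1+e^−x). Outputs are
  strictly inside (0,1); a residue type absent from the window yields a
  row of 0.5.
* **ASA** (2n+1): percent accessibility divided by 100; 0 outside the
  protein.
* **SS** (3·(2n+1)): one-hot helix/sheet/coil (H=100, E=010, C=001); all
  zeros outside the protein.

## F-score and positional scan

For one feature with positive sample x⁺ (n⁺ ≥ 2) and negative sample x⁻
(n⁻ ≥ 2),

    F = [(x̄⁺ − x̄)² + (x̄⁻ − x̄)²] /
        [ Σ(x⁺ − x̄⁺)²/(n⁺−1) + Σ(x⁻ − x̄⁻)²/(n⁻−1) ],

with x̄ the grand mean. F = 0 when the numerator vanishes and +inf when
the within-class variances vanish while the means differ; the infinity is
kept as a sentinel (it preserves ordering and serialises as "inf") rather
than capped. F is invariant under common affine maps of both samples and
symmetric in the class labels.

The positional scan computes, at each window offset, the 20 per-channel
F-scores — residue-identity indicators for the composition channel
(offset 0 excluded; it is always K), raw PSSM scores for the pssm channel
(offset 0 included) — and aggregates them into a single per-offset value.
Aggregation is by sum (default) or max; the figures such scans feed show
one bar per position, and the sum is the smoother choice. The scan
reports raw aggregates only; no significance threshold is imposed.

## RBF network

All training instances are centres (k = n) with one shared Gaussian
bandwidth σ = 5; the kernel is exp(−d²/(2σ²)) (a flag switches to
exp(−d²/σ²) for parity with implementations using that convention). The
output layer has one node per class with one-hot targets, and its weights
solve (Φ + λI)W = Y exactly. On distinct points the Gaussian kernel matrix
is symmetric positive definite, so at λ = 0 the network interpolates its
targets; λ defaults to 1e−8 because duplicate feature rows (possible after
composition encoding) make the unregularised system singular, and the tiny
ridge preserves interpolation fidelity (~1e−13 observed) while
guaranteeing solvability. Prediction is arg-max over output nodes, ties
resolving to the class sorted first ("negative" before "positive"); an
optional threshold mode predicts positive iff y⁺ − y⁻ ≥ t, enabling
sensitivity/specificity trade-offs under class imbalance. No feature
standardisation is applied by default.

A practical note: with low-variance features such as window composition
(values ≤ 0.25), pairwise distances are small relative to σ = 5 and the
kernel matrix is nearly singular; the exact solve then behaves like a
noisy interpolator and small-window models can score *below* the
majority rate out of fold. This is a real property of the
fixed-bandwidth exact-solve design, visible in the window-sweep
experiment, not a numerical bug; the position-resolved BLOSUM encoding
(distances of a few units) is the best-conditioned single block and is
the default encoding in the packaged benchmark experiments.

## Evaluation

Pr = TP/(TP+FP), Sn = TP/(TP+FN), Sp = TN/(TN+FP),
Acc = (TP+TN)/total; a zero-denominator ratio is reported as None, never
as 0. Cross-validation is stratified by class at the site level with a
recorded seed (scikit-learn's StratifiedKFold); pooled (micro-averaged)
counts across folds produce the single reported estimate. Optional
protein-level grouping (StratifiedGroupKFold) keeps all sites of a protein
in one fold to prevent homolog leakage; both modes exist because the
choice is genuinely open for this kind of data. The window sweep runs one
CV per half-width n (default 5…20) with a shared fold seed; the feature
comparison runs one CV per named block set, likewise with shared folds.

## Synthetic proteome generator

The generator emulates exactly the statistical structure the method
consumes:

* sequences i.i.d. from a background composition (default uniform 1/20;
  a realistic frequency table can be supplied) — candidate sites are the
  lysines that arise naturally, ~1 per 20 residues;
* positive sites: a chosen subset of lysines; at each signal offset
  (default −16, −10, −3, −1, +1, +5, +13, +17) the residue is replaced,
  with probability `signal_strength` (default 0.8), by a uniform draw from
  the enriched set (default {D, E}, the acidic residues over-represented
  around real sites); negatives are the remaining lysines;
* PSSM: per position, integer-rounded log-odds (2·log₂(p/q)) of the ±7
  local composition with pseudo-counts against the background, plus
  Gaussian noise (sd 1.0) — preserving the property the pooled PSSM
  encoder exploits, that profile scores correlate with local composition,
  without any database search;
* ASA: N(45, 15) percent clipped to [0,100], elevated by `asa_shift`
  (default +15 points) within ±5 of positive sites;
* SS: i.i.d. H/E/C at (0.30, 0.22, 0.48), blended toward a coil/helix-only
  mixture by `ss_coil_bias` (default 0.3) within ±5 of positive sites.

Everything is deterministic given the seed, and the truth record retains
the parameters and every planted residue.

What the generator does **not** model: phylogeny-aware conservation (PSSMs
are composition proxies, not alignments of real homolog sets), motif
grammar or positional correlation beyond the planted offsets, realistic
protein length/composition heterogeneity, and the biophysics of E3
binding. Passing benchmarks therefore demonstrate that the pipeline
recovers the signal it is pointed at under controlled conditions — not
field performance on curated ubiquitylome data, which depends on database
versions and profile software outside this package's scope.

### Benchmark presets

`benchmark_params(kind)` freezes the study conditions used by the tests,
the examples and `scripts/acceptance.py`:

* **distant**: 350 proteins of 300–500 residues; 300 positive / 1200
  negative sites; strength-0.8 acidic signal at offsets −16, −10, +13,
  +17 only. The protein scale (~1 positive site per protein, lengths in
  the hundreds of residues, as in real substrate sets) matters: it keeps
  41-mer windows clear of the termini so the planted distant offsets
  actually exist in the windows, and keeps most negative windows outside
  planted zones.
* **proximal**: identical but signal at ±1, ±2 — the control for the
  window-length experiment.
* **null**: 500/500 balanced sites, no planted effect of any kind —
  calibration at chance.

Because negatives are real lysines of the same proteins, a negative whose
window overlaps a positive's planted zone inherits some signal; at the
benchmark scale this affects a small minority of negatives and is a
faithful property of site data mined from shared sequences.

## Numerical choices and degenerate inputs

* Exact F-score arithmetic at 1e−12 agreement with a loop-coded formula
  oracle; +inf sentinel on zero denominator.
* RBFN solve via LAPACK `solve`; duplicate rows at λ=0 raise with advice
  rather than returning garbage; model files round-trip float64 bit-exact
  (JSON header + little-endian arrays).
* Profile readers reject length mismatches, out-of-range ASA and illegal
  secondary-structure symbols outright — no silent truncation.
* Composition encoders raise on windows with no effective residues.
* Fold assignment requires ≥ k members per class under stratification.
* Problem sizes in tests and the acceptance script (≤1500 sites, ≤10
  seeds, two-point window sweeps) are chosen so the full benchmark suite
  completes in about a minute while keeping every estimate's sampling
  error well inside the asserted margins.

## Known limitations

* Local-alignment identity makes the 30% homology gate nearly always fire
  for proteins sharing an identical window (see above); a global-identity
  mode would change which fragments are collapsed.
* The σ=5 exact-solve network has no imbalance correction; sensitivity at
  1:4 class ratios is modest under arg-max and should be tuned via the
  threshold mode when recall matters.
* The 41-mer default window assumes the relevant signal lies within ±20;
  nothing beyond that range is visible to any encoder.
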