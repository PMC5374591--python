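# Methods

## The model

`burialcrf` predicts the binary burial state of each residue in a protein
chain: buried (1, relative solvent accessibility below 0.25) or exposed
(0).  Burial states are strongly correlated along the chain, and the
correlation structure depends on secondary structure: on an α-helix the
periodicity of the backbone makes residues 3 and 4 positions apart face
the same side of the helix, so they tend to share a burial state; on a
β-strand the alternation of side chains couples residues 2 positions
apart; coils show only weak adjacent-residue correlation.

The model is a conditional random field over the label sequence
Y = Y₁…Y_L given per-residue observations X,

    p(Y | X) = Z(X)⁻¹ ∏ⱼ exp( Σ_{i ∈ e_j} φ_{t(e_j)}(·, i, X) ),

where the product runs over secondary-structure segments e_j and the
log-potential type is selected by the segment type:

* coil:   φ_C = θᵀf⁰(Y_i) + λᵀf¹(Y_{i−1}, Y_i)
* strand: φ_E = φ_C + μᵀf²(Y_{i−2}, Y_i)
* helix:  φ_H = θᵀf⁰(Y_i) + λᵀf¹(Y_{i−1}, Y_i) + γᵀf³(Y_{i−3}, Y_i)
           + τᵀf⁴(Y_{i−4}, Y_i)

Note the helix potential couples separations 1, 3 and 4 but **not** 2 —
a separation-2 term on helices would couple residues on opposite faces.
Λ = (θ, λ, μ, γ, τ) is the full weight vector.  Singlet functions f⁰
conjoin each observation column with each of the two labels; doublet
functions f^d conjoin each ordered label pair at separation d (4
combinations) with an observation vector u_d(i) — a bare bias for d = 1,
and [bias, mutual information, cosine similarity, contact-map score] of
profile columns i−d and i for d ∈ {2, 3, 4} (the nine doublet features).

Two structural conventions make the model well defined for segments of
every length:

1. **Every position contributes its singlet term exactly once**,
   regardless of where it falls in a segment.
2. **Doublet terms never cross a segment boundary**, and within a
   segment the order-d term activates only from in-segment offset d
   (e.g. the second helix position carries only the separation-1 term).

For long segments this reduces to products of full interior potentials;
for a length-1 segment only the singlet term remains.  A consequence of
convention 2 is that the distribution factorises over segments.  An
alternative in which doublets span boundaries would be a different model
class (segments would no longer decouple) and is out of scope.

## Inference

Within a segment of maximal order k (4 helix, 2 strand, 1 coil) the
forward–backward recursion runs over states that remember the last
min(p+1, k) labels, at most 2^k = 16 states per position and 32 label
tuples per transition — time O(L·2^(k+1)) overall.  All computation is
in natural-log space with log-sum-exp; the forward and backward
partition functions must agree to 1e-9 (checked at run time).  The
per-position marginals p(Y_i = y | X) come from the same trellis, and
prediction is the per-position argmax of the marginals, with exact ties
resolved to buried (determinism).

Printed closed forms for the marginals in terms of forward/backward
vectors leave the exact factor bookkeeping (which potentials live inside
α versus β) underdetermined, so the implementation defines the marginals
operationally by exact dynamic programming, and a brute-force
enumeration over all 2^L labelings — scored by an independent, non-DP
code path — is the normative oracle in the test suite: DP log-partition
and marginals match enumeration to 1e-9 over randomized suites that
include length-1 segments and pure-helix/strand/coil chains.

## Training

The objective is the penalized conditional log-likelihood
Σ_m log p(Y^m | X^m) − (ℓ2/2)‖Λ‖².  Its gradient per weight is the
empirical feature count minus the model-expected count; expectations,
including the 4-tuple expectations needed for the helix separation-3/4
blocks, come directly from the transition joints of the order-k trellis,
with no approximation.  Analytic gradients are verified against central
finite differences (h = 1e-5, per-coordinate relative error < 1e-5) on
all five weight blocks.

The objective is concave (log-linear model), strictly so for ℓ2 > 0, so
the maximizer is unique and initialisation is inessential; all fits
start from Λ = 0 and are deterministic.  The default optimizer is
full-batch gradient ascent with a backtracking (Armijo) line search —
the penalized objective is non-decreasing across iterations; an L-BFGS
mode (`optimizer="lbfgs"`) is available and preferred when wall time
matters, reaching the same optimum (checked to 1e-4 in held-out
marginals from different initialisations).  Defaults: ℓ2 = 1.0,
tol = 1e-6 on the relative objective change, max 200 iterations.
Real-valued singlet columns are z-scored with training-set statistics
stored in the model file; binary columns pass through.

## Features

* **Sequence profile**: PSI-BLAST ASCII PSSM reader exposing both the
  log-odds and frequency views; a one-hot pseudo-profile stands in when
  no PSSM exists.
* **Sequence conservation**: relative entropy (bits) of the profile
  column against the background, 0·log 0 := 0.
* **Contact number**: residues within 8 Å (strict) and ≥ 5 positions
  apart in sequence, from Cα coordinates.
* **Doublet features**: mutual information and cosine similarity of
  profile columns at separations 2/3/4.  A single profile supplies only
  marginals, so the default MI joint is the outer product (exactly 0);
  an alignment-derived pair joint can be supplied.  The contact-map
  doublet score is consumed as an optional precomputed column
  (zero-filled by default) — its source formula is not public, and
  inventing one silently would be worse than an explicit zero.
* **Singlet assembly** is registry-driven: named column groups (bias,
  residue one-hot, terminal flags, profile, conservation, SS
  probabilities, contact number, window-shifted profile copies, plus
  arbitrary precomputed per-residue columns from external predictors
  such as disorder or binding-site probabilities).  The total width is
  asserted from the registry, never hard-coded: published feature
  inventories for this task do not itemise every column, so the registry
  is the single source of truth for layout.
* **Burial labels**: ASA from classic DSSP files, divided by the
  residue-type maximum ASA (shipped table: Tien et al. 2013 theoretical
  values; any 2-column TSV can be substituted — the literature does not
  agree on one table), thresholded at 0.25 with RSA = 0.25 → exposed
  ("exposure threshold" read as minimum exposure; configurable).
  Chains with breaks are rejected for training and split for prediction.

## Synthetic data

The generator emulates the *structure* of a burial corpus while keeping
the label law exactly known:

* proteins of 50–150 residues (mean 100);
* alternating H/E/C segments, geometric lengths (defaults: helix mean 8
  so order-4 terms activate in most helices, strand 5, coil 4),
  stationary type frequencies per composition preset (α-rich, β-rich,
  α/β, α+β analogues, plus `helix_coupled` / `strand_coupled` regimes
  with strong long-range coupling and deliberately weak singlet signal);
* singlet observations: a bias plus unit-variance Gaussian columns, of
  which `n_signal_cols` receive generating weights ±effect_size/2
  (buried positive) — the signal therefore lives in θ*, and class-
  conditional feature means separate a posteriori; effect size 0 means
  no label information at all;
* doublet observations: bias plus MI-like (|N(0, 0.3)|) and cosine-like
  (tanh N(0,1)) columns; generating coupling weights sit on the bias,
  +c_d for equal label pairs and −c_d for unequal ones;
* labels drawn **exactly** from p(Y | X; Λ*) by forward-filtering
  backward-sampling on the same trellis the inference module uses.  The
  total-variation agreement between 10⁵ draws and the enumerated law is
  the keystone test: it certifies sampler and inference against each
  other through two independent code paths.

What the generator does not emulate: real PSSM evolution, real
secondary-structure prediction errors, 3-D structure, residue-type-
dependent composition.  Passing tests therefore certify the *method* —
exact inference, correct gradients, recoverable parameters, the value of
high-order coupling when it is present — not accuracy on real proteins,
which depends on externally generated features.

## Problem sizes and statistical design

* Oracle equivalence uses chains of L ≤ 12 (enumeration is 2^L) over
  ≥ 500 random instances.
* The sampler total-variation check uses L ∈ {5, 6, 8} with 10⁵ draws:
  the plug-in TV of a perfect sampler has expectation
  ½ Σ_k √(2 p_k(1−p_k)/(π n)), about 0.003–0.007 at these sizes —
  comfortably inside the 0.02 bound, whereas at L = 10 and near-uniform
  weights the noise floor alone would exceed it.
* Parameter recovery trains on 25/50/100/200 proteins of mean length
  100 and measures mean |Δp(buried)| on 40 held-out proteins against
  the generating model.
* The model comparison (high-order vs chain CRF vs logistic regression)
  repeats a 40-train/30-test split over 5 seeds in the `helix_coupled`
  regime and requires each accuracy gap to exceed twice the standard
  error of the per-seed paired differences.

## Numerical choices and edge cases

* Ties in decoding go to buried; the 0.25 RSA boundary goes to exposed.
* MI is clamped at 0 (float round-off on outer-product joints can
  produce −1e-17).
* Zero-norm profile columns define cosine 0; zero-sum PSSM percentage
  rows become uniform frequencies.
* Unknown residues map to 'X' (uniform profile row, mean max-ASA);
  unknown 8-state SS codes map to coil with a warning.
* Model files are JSON; floats round-trip bit-exactly via Python's
  shortest-repr serialization.

## Known limitations

* The chain CRF baseline is the same engine restricted to the coil
  potential everywhere; it shares any systematic quirks of that engine
  (this is intentional for a controlled comparison, but it is not an
  independent reimplementation).
* Marginal (posterior-decoding) prediction only; no Viterbi joint
  decoding.
* Two burial states only; finer burial alphabets are out of scope.
* External predictors (PSI-BLAST, PSIPRED, DeepCNF, AcconPred, I-sites,
  contact potentials) are never run; their outputs are consumed as
  files when available and zero-filled otherwise.
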