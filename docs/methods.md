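# Methods

## The model

`strdyn` treats a genome, for one focal motif class, as an alternating
sequence of A-repeat tracts (lengths in complete motif units) and
non-motif B strings (lengths in nt).  The state of the system is the pair
of length histograms `a[L]`, `b[l]`; everything the package does —
extraction, forward evolution, inference, analytics — is phrased on this
pair.

Mutations enter as per-generation transition rules:

| process | context / rate | effect |
|---|---|---|
| lengthening | `BBA>BAA`, per eligible B end | `L → L+1`, adjacent B shrinks |
| shortening | `AAB>ABB`, 2 per tract (`L ≥ 2`) | `L → L−1`, adjacent B grows |
| fission | `AAA>ABA`, `L−2` per tract | tract splits: pieces sum `L−1`, each uniform on `1..L−2`; a B₁ appears |
| fusion | `ABA>AAA`, per B₁ | two tracts join to `l₁+l₂+1`; the B₁ vanishes |
| A₁ create/destroy | `BBB>BAB` / `BAB>BBB` | bin-1 source/sink with B-side bookkeeping |
| expansion / contraction | `ε(L)·L`, `κ(L)·L` per tract | `L → L±1` |
| non-motif insertion | `ι(L)·L` per tract (`L ≥ 2`) | splits: pieces sum `L`, uniform on `1..L−1`; a B₁ appears |
| B indels | `BB>BBB`, `BBB>BB`, `ABA>AA` | B-side length changes; the last is a fusion channel |

All fluxes are computed from the start-of-generation state and applied
simultaneously (no within-generation ordering).  Substitutions conserve
total nucleotide content exactly; local indels conserve the tract count;
fission/fusion change it by ±1 per event.  These conservation laws are
asserted in the unit tests.

Two deliberate refinements of the naive bookkeeping:

* **Lengthening targets.**  A tract boundary can only lengthen by
  substitution if the adjacent B string has length ≥ 2 (`BBA` context); a
  single-unit B is the fusion channel's target.  Booking a blanket two
  targets per tract double-counts B₁ sites and demonstrably shifts the
  substitution-only fixed point off the geometric law.  The kernel books
  `2·rate·#(B strings ≥ 2)` lengthening events, spread over tracts in
  proportion to counts; with this, the geometric law is an exact fixed
  point (verified to ~1e-10 relative).
* **Fusion pairing.**  Partner tract lengths are drawn from the tract
  distribution itself (count-weighted pairing — neighbors in an
  unstructured genome are independent draws from the DRL), while the two
  consumed counts are removed evenly across bins `≤ L−2`.  For a
  geometric distribution the two prescriptions coincide exactly, because
  `q(l₁)q(l₂)` is constant on `l₁+l₂ = const`.  A fully count-weighted
  consumption variant sits behind `count_weighted=True`.

Edge conventions: shortening and contraction apply for `L ≥ 2`; non-motif
insertion for `L ≥ 2` (an interior insertion needs two units); loss of a
single-unit tract is carried by the `BAB>BBB` channel alone.  A
reflective boundary assigns transitions beyond `L_bound` to `L_bound`;
reflected mass keeps mutating at boundary rates.  Fractional expected
counts are allowed; a zero floor guards bins that tiny fusion-consumption
terms would otherwise drive negative.

## Time rescaling and schedule

One iteration represents `10^r` generations (all rates multiplied by
`10^r`).  The saturation length `L_max` is the first length whose total
per-tract event probability exceeds 0.1; the modeled range is
`L_bound = min(L_max, 200)`, recomputed per stage and separately for the
B side.  Runs whose rates clear `L_bound = 200` at some `r ≥ 3` take a
single stage at the largest such `r` (default cap `r = 5`); all others
run stages at `r = 3, 2, 1, 0`, stopping early once the current stage's
rates clear the cap.  Runs finishing at `r = 0` with `L_max < 200` have
bins above `L_max` zeroed before analysis.  Boundary mass exceeding one
expected count and still growing at the end of the last stage flags the
run as non-equilibrated (the `Δτ ≤ 0` signature).

The initial condition is the i.i.d.-genome expectation
`a[L] = G·p_B²·p_A^L` with `p_A = μ/(μ+ν)`, sharpened by a
substitution-only pre-run at `r = 5` for 10¹⁰ generations; an alternative
"geometric + uniform" initializer (rescaled to the same nucleotide
content) exists for robustness checks, and the two agree at late times to
< 1% per populated bin of the normalized distribution.

## Default parameters

* Context substitution rates (per target per generation, mono-A):
  lengthening 4.58e-9, shortening 7.74e-9, fusion 2.74e-9, fission
  4.35e-9, A₁ creation 3.80e-9, A₁ destruction 6.17e-9; B-side indels
  1.38e-10 (`BB>BBB`), 4.37e-12 (`BBB>BB`), 2.76e-10 (`ABA>AA`).
* `ι(L) = ε(L)/100` wherever the curves are parameterized (configurable).
* The shipped short-range instability table (`default_empirical_curve`)
  is a **synthetic anchor**, not a measured dataset: ε and κ rise about
  e-fold per unit through `L = 5..8` and are pinned at
  `ε(8) = 1.1e-8`, `κ(8) = 6.8e-9`.  Those anchors follow from the
  inferred power-law constants (`c_ε ≈ 2.7e-8`, `c_κ ≈ 1.7e-8` at `L = 9`
  with a multiplier jump `m ≈ 2.5`), keep `L = 8` expansion-biased, and
  set the balance between context-substitution fission and repeat
  instability that the dynamical regimes hinge on.  Users with real
  per-length estimates load them via the rate-table TSV.
* Parameterization families: symmetric / decoupled / shared-constant /
  shared-exponent / multiplier-coupled power laws, the logarithmic
  variants (`log(L−7)/log 2` in place of `L/9`), and the fully
  parameterized pure power law `ε(L) = μ(L/λε)^τε`,
  `κ(L) = ν(L/λκ)^τκ` (the printed form carries a τ-subscript typo in
  κ's exponent; the parameter list makes `τκ` unambiguous).
* Default grids: rate constants log-spaced over 1e-9..1e-6 (31 points),
  exponents 0..4 step 0.1, multipliers {1, 1.6, 2.5, 4, 6.4, 10}, onset
  lengths 4..20.

## Inference

The KL statistic adds a pseudocount (default 1) to every length class up
to 200 in both distributions, renormalizes conditionally on
`L ∈ [4, 200]`, and uses natural logarithms.  σ is half the largest
retained divergence after dropping the top ⌈5%⌉ of ensemble members
(2 of 36).  The posterior is computed in log space (no silent underflow);
max-posterior ties break toward the lexicographically smallest parameter
vector.  Bayes factors are grid quadratures of `prior·exp(−D²/2σ²)` and
are only comparable at equal σ.  Informative priors fit the mid-length
rate estimates by weighted log–log regression (variance inflated 100×
outside the trusted range `L = 13..21`), convert the fit value and spread
at `L = 9` into a block-diagonal covariance over
`(log c_ε, τε, log c_κ, τκ)`, inflate it 100× ("restrictive") or 1000×
("permissive"), and evaluate the resulting normal on the grid.

## Steady-state analytics

Short repeats: `P(L) ∝ (μ/(μ+ν))^L`, anchored at the `L = 1` bin.
Long repeats: with `a(L) = ½(ε+κ)L`, the nested continuum approximations

1. `∂²[a P] − ∂[(ε−κ)L P] = 0` (local only),
2. … `− (ν+ι)L P = 0` (adds fission-out),
3. the overall-derivative third-order form with the zero-net-flux
   selection (adds fission-in; fusion neglected throughout, `L > 10`),

are solved as linear BVPs by superposing fundamental solutions
(DOP853, rtol 1e-10; coefficients differentiated by complex step), with
constraints taken from a reference DRL at `L₁ = round(L*)`,
`L₂ = ⌊L_trunc⌋`, and `L₃ = L₂ − 1` for the third-order equation.
Constraint reproduction is checked to 1e-6 relative.

Regime classification uses `Δτ` with thresholds calibrated at `m = 4`:
non-equilibrating for `Δτ ≤ 0` (the symmetric edge case inherits
expansion bias from the `L = 8` rates), weak below 0.7, moderate to 1.5,
strong above.

**Known accuracy limits.**  The continuum equations are second-order
truncations of the discrete kernel.  At the per-bin decay ratios the
contraction-biased regimes produce (0.4–0.75), the retained nesting holds
cleanly — the fission-aware equation is uniformly the most accurate and
the local-only equation fails outside strong bias — but pointwise
agreement with the kernel is tens of percent, not percent: even the exact
discrete local-balance law deviates from the kernel by up to ~90% in the
strong regime once fission (subdominant, never negligible) and
Kramers–Moyal truncation are neglected.  On logarithmic axes spanning the
distribution's ~6 decades these offsets are small; treat the analytic
solutions as structural descriptions, not high-precision predictors.

## Synthetic data

The sequence-level simulator is the package's independent oracle: it
applies every process literally to an explicit two-letter genome (events
Poisson-sampled per generation against real sequence targets; fission and
fusion emerge from the sequence).  Kernel-vs-oracle agreement on a 10⁵-nt
genome over 10³ generations, 200 replicates, is the central correctness
test (max |z| < 4 over all bins with expected count ≥ 5, with every
process producing ≥ 100 expected events).

Primate-like ensembles perturb a base DRL with gamma–Poisson noise
(`count ~ Poisson(c·g)`, `g ~ Gamma(1/d², d²)`, dispersion `d` = CV of
the per-bin multiplier; default 0.05), then apply the <30-count
truncation rule.  This emulates assembly-quality scatter around a shared
steady state; it does not model phylogenetic correlation, motif-specific
error profiles, or coverage-dependent dropout, so passing tests bound the
machinery's correctness, not the realism of any particular noise level.
Labeled de novo events are rendered as flanked reference/alternate
alleles so the classifier is exercised on its real input format.

The parameter-recovery experiment uses one forward operator throughout —
truth DRL and grid points are produced by the same evolve configuration
(stages of 10⁴ iterations at the recovery scale; 10⁵ elsewhere), so the
experiment isolates the inference machinery rather than equilibration
convergence.  Problem sizes in the test suite (10⁵-nt oracle genome, 200
replicates, 5×9×9 recovery grid, ~10⁶ synthetic events) were chosen to
give clear statistical power at desk scale.

## Formats

TSV with `#`-prefixed metadata headers everywhere (17-significant-digit
floats; reads use round-trip parsing), YAML for configuration and the
nine named substitution rates, JSON for summaries.  Foreign table
layouts map onto the canonical columns via an explicit column map;
missing lengths in a rate table raise rather than default to zero.
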