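# Methods

This note documents the models implemented in `ofmkit`, the defaults they
ship with, the choices made where the underlying experimental description
leaves the design open, and what the synthetic-data validation does and does
not demonstrate.

## Fluctuation analysis (`ofmkit.fluctuation`)

**Model.** A culture grows from one fragment-bearing cell to *N* cells;
each division loses the marked chromosome with probability μ.  The number of
loss *events* per culture is Poisson with mean *m = μN* (divisions per
culture are taken as *N*, not *N−1*; for *N* ≥ 10³ the difference is
negligible).  An event occurring when the culture has *n* cells founds a
clone of ~*N/n* loss-derived cells at saturation; with events uniform over
divisions this gives the classical clone-size law *P(size ≥ k) = 1/k* and the
Luria–Delbrück count distribution.  The simulator draws clone sizes as
⌊u^(−w)⌋ with *u* ~ U(0,1), where *w* is the fitness of loss-derived (red)
cells relative to fragment-bearing cells.  *w* = 1 by default (equal growth);
the parameter is exposed but has not been validated against data.

**Estimators.**

- `p0`: *m* = −ln(fraction of zero-count cultures).  Exact closed form;
  uninformative when no culture is clean.
- `lc_median`: the unique positive root of *r̃/m − ln m = 1.24* (the
  classical median-equation constant), found by Brent bracketing on
  [10⁻⁶, 10⁶] in log space to machine tolerance.  The median of counts is the
  lower median for even *n* (conservative, deterministic).
- `mss_mle`: maximizes Σᵢ ln p(rᵢ | m) with the pmf from the
  Ma–Sandri–Sarkar recursion p₀ = e^(−m),
  p_r = (m/r) Σ_{i<r} pᵢ/(r−i+1).  The optimum is bracketed one decade either
  side of a pilot estimate (median method, or P0 when the median is 0).
  Counts above a cap (default 1500) enter the likelihood as right-censored
  observations, which bounds the O(r²) recursion cost without discarding
  jackpot cultures.  All-zero counts put the MLE at the m = 0 boundary
  (returned with a warning).

**Working range.**  All three estimators are accurate for *m* roughly in
[1, 20]; assay design should choose *N* so the expected events per culture
land there (the synthetic screen uses 10³-cell cultures for the unstable
gapped derivative and 10⁵ for the stable full-origin derivative).  Parameter
recovery on simulated assays (*m* ∈ {1, 2, 5, 20}, 200 cultures) is within
20% in ≥ 80% of seeds for both the median method and the MLE.

**Uncertainty.**  Percentile bootstrap over cultures (resampling with
replacement, estimator re-applied per resample; resamples on which the
estimator is undefined are dropped, erroring if they exceed half).  The
published tables report "± S.D." without stating its computation, so no
attempt is made to reproduce those numbers; the bootstrap is the package's
own uncertainty convention.  When only a sample of *s* of the *N* cells is
plated, counts are treated as binomially thinned and the rate is *m̂/s*.

## Ofm index (`ofmkit.scoring`)

With rates in common units, `index = (mut5 − base5)/(mut0 − base0)`.
Conventions:

- the baseline strain supplies **both** reference rates.  The published
  alternate-baseline values (83, 7 and 34 for the mec1, rad53 and
  rad53 chk1 double/triple deletions scored against the sml1 deletion) only
  reproduce under this reading; applying the alternate baseline to the
  denominator alone gives 79, not 83, for the mec1 row.
- denominator ≤ 0 → the index is undefined (never ±∞); a strain scored
  against itself is undefined by construction.  A negative numerator over a
  positive denominator is reported as-is (the sml1 row: −3).
- display rounding is half-away-from-zero (−3.33 → −3, 18.6 → 19).
- `index_sd` is the first-order delta-method SD assuming independent rate
  errors: var = (sd5² + sdb5²)/D² + A²(sd0² + sdb0²)/D⁴ with A, D the
  numerator and denominator differences.  When the denominator's CV is large
  the true ratio distribution is right-skewed with infinite variance, and the
  delta value tracks the robust (MAD) core spread rather than tail-sensitive
  moments.

**Classification.**  Defaults: Ofm requires index ≥ 20 *and* at least 2-fold
destabilization of the gapped derivative; index < 10 is non-Ofm; anything
else (including an undefined index) is indeterminate.  The 10 bound is chosen
so that index-7 strains (the mrc1 and rad53 deletions, both described as not
Ofm mutants) classify as non-Ofm; an earlier draft bound of 5 would leave
them unclassified.  Under these defaults the chk1 deletion (index 33 but only
1.95-fold destabilization) lands indeterminate — the thresholds are policy
knobs, exposed as arguments, not biological constants.

## Colony sectoring (`ofmkit.sectoring`)

**Model.**  A synchronous binary tree grows from one fragment-bearing cell
for *G* generations.  At each division of a fragment-bearing cell, with
probability μ exactly one daughter loses the fragment (matching the
per-division rate definition used by the loss-rate tables, rather than
independent per-daughter loss).  Each loss in a fragment-bearing lineage
founds one visible sector; losses inside red lineages are invisible (nested
sectors merge, as in visual scoring).  Red lineages keep growing; sector
*size* is irrelevant once founded.  No cell death, no spatial geometry.
Mean sectors = Σ_{g<G} μ(2−μ)^g, verified against exhaustive enumeration at
G = 3 and against the closed form at G = 10.

**Visibility horizon.**  *G* = 10 by default: a sector founded later than
~10 doublings comprises ≲0.1% of the colony and is not scored by eye.  G is
the model's only calibration knob and is validated only against the three
anchor patterns (loss rates 2.1×10⁻³ / 10⁻² / 10⁻¹ → median sectors ~2 / ~9–10
/ ~70).

**Classes and verdicts.**  Median sectors ≤ 3 → wildtype_like, 4–10 →
elevated, ≥ 11 → high.  The verbal calibration assigns 10 sectors to both the
"5–10" and "≥10" patterns and leaves 4 unassigned; both are resolved into the
elevated class, which keeps the 10⁻² anchor stably classified.  Screen
verdicts from duplicate chromoductants: both gapped-derivative replicates
wildtype_like → not_a_hit; both full-origin replicates high → non_Ofm
(general transmission defect); discordant replicates in either pair →
possible_probable; elevated-or-high gapped with quiet full-origin → Ofm;
remaining concordant intermediates → possible_probable.

## Gap replication (`ofmkit.replication`)

**Model.**  Per simulated cell, each origin is licensed with probability *p*
(its efficiency class) and draws a firing time from a normal truncated at 0.
An origin fires only if its locus is unreplicated at its drawn time — one
rule that yields passive replication and dormancy.  Firing launches two forks
at constant speed *v*; each fork independently arrests permanently after an
exponential travel distance with survival (1−f)^d over *d* kb.  Replication
may continue past S phase until `available_min`; a cell with any unreplicated
DNA at that time is scored incomplete, and incomplete replication is equated
with construct loss (no breakage/repair or break-induced replication is
modelled).  Fork collisions need no special handling for coverage: the
covered set is the union of per-fork intervals, and the firing test is
time-resolved.

**Efficiency encoding.**  Origins active in ≥ 90% of cycles get *p* = 0.9
with early firing (t ~ N(15, 5) min); 15–25% origins get *p* = 0.2,
t ~ N(25, 6); dormant origins get *p* = 0.9 but late firing (t ~ N(55, 5),
the end of a 55-min S phase), so with a full origin complement they are
passively replicated first (< 2% firing in the wild-type full-origin
setting) and fire mainly when upstream origins are deleted or forks are
slowed.

**Geometry.**  Packaged maps use full-length coordinates with the efficient
set ARS305–ARS310 at 40–140 kb (a 100-kb deletion gap), HML-associated
dormant origins at 8/14/25 kb, ARS308 (inefficient) at 110 kb, ARS313 and
ARS315 at +20 and +50 kb distal to the ARS310 deletion, a 200-kb full-length
chromosome, 150-kb ΔR fragments and a 170-kb ΔL fragment.  These are
schematic positions preserving the relative geometry that matters (gap span,
distal origin offsets, fragmentation points); all maps are overridable via
origin-map TSV, and every claim made with the simulator is an ordering or
ratio between constructs/regimes, never an absolute loss rate.

**Regimes.**  wild_type: v = 2.3 kb/min, f = 0 (crippled forks are restored,
idealized as no permanent arrest).  rad9_like: f = 10⁻³/kb, so ~10% of single
forks fail across the 100-kb gap — the observed scale of gap-traversal
failure in DNA-damage-response mutants.  mec1_like/mrc1_like: half fork
speed with small f (2×10⁻⁴) — slow but stable forks.  All regimes allow
replication until 170 min.  The 170-min window (rather than the 55-min
S phase) is deliberate: a 160-kb trek at 2.3 kb/min needs ~70 min and at half
speed ~140 min, so terminating at S-phase end would make every long-gap
construct fail in every regime and erase the contrasts the simulator exists
to expose; biologically, replication of late regions runs into G2.  With
these defaults the simulator reproduces the qualitative published pattern:
removing the dormant origins (ΔL-6ORIΔ vs full-length 5ORIΔ) is ~18-fold
costly under fork arrest but only ~1.5-fold under slow forks — an order of
magnitude separation matching the published 9600/30 vs 610/260 contrast in
structure, not in absolute value.

**Known limitations.**  Dormant-origin firing fractions in the gapped
constructs are much higher than the 2D-gel-measured 1.7–14.6% activation
range, because the *p* = 0.9 licensing assigned to dormant origins makes them
fire whenever forks are absent; matching those percentages would require a
separate licensing probability for dormant origins and is left as a
calibration exercise.  Origin-addition monotonicity (more origins never hurt)
holds exactly only without fork arrest: an arresting fork can passively
replicate an origin locus, suppress its firing, and then die, so the
common-random-number monotonicity checks use the f = 0 regime.  Common random
numbers are implemented by keying each origin's draws to a hash of its name,
so adding an origin leaves all other origins' randomness untouched.

## Synthetic screens (`ofmkit.synth`)

Panels anchor wild type at 2.1×10⁻³ (gapped) and 3×10⁻⁵ (full-origin) per
division.  ofm_like strains multiply the gapped rate log-uniformly by 5–50
and the full-origin rate uniformly by 1–4; general_instability strains
multiply both by a common log-uniform 10³–10⁴ factor (rates clipped to 0.5) —
the magnitude implied by "highly sectored" full-origin chromoductants, since
a mere 100× increase (3×10⁻³) would still sector like wild type and is not
what disqualifies a strain; intermediate strains get a mild 2–5× / 1–2×
destabilization.  The virtual screen runs duplicate 500-colony sectoring
observations per construct, applies the verdict rules, and follows up hits
with 50-culture fluctuation assays and the Ofm index against a simulated
wild-type reference.

Under these defaults (10 seeds × 200 strains) sensitivity for ofm_like
strains is ≥ 0.95, no general_instability strain is ever called Ofm (the
full-origin sectoring guard), and the Spearman correlation between true and
estimated Ofm indices across called strains is ≈ 0.96.  What this validates:
the pipeline's statistical machinery, thresholds and plumbing are mutually
consistent and recover known truth at realistic assay sizes.  What it does
not validate: real colonies are asynchronous, spatially structured, and
scored by eye with observer noise; real loss-rate measurements face plating
efficiency and marker-instability artifacts; and real mutants are not drawn
from tidy multiplier distributions.  Passing the virtual screen therefore
demonstrates internal correctness, not field performance.

## Reproducibility conventions

Every stochastic entry point takes an explicit seed; derived substreams come
from the master seed deterministically (per-origin hashes, sequential child
seeds in the virtual screen), and all outputs record the seed.  CLI runs with
a fixed seed produce byte-identical output files; diagnostics go to stderr.
Rates in files are in ×10⁻⁵ display units with `ND`/`N.D.`/`Not defined` as
the only missing-value tokens; internal computation uses raw probabilities.
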