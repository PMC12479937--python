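# Methods

## The problem

In-scanner head motion systematically biases resting-state functional
connectivity (FC).  Denoising removes much of the artifact, but a residual
component remains, and its impact is *trait-specific*: traits correlated
with motion (body habitus, attention, cognition) can have their trait–FC
associations inflated (false-positive risk) or suppressed (false-negative
risk) by whatever motion signal survives preprocessing.  This package
implements a split-half permutation statistic that assigns each trait a
**motion impact score**: an omnibus Stouffer Z over all connectivity edges,
with a permutation p-value, plus directional **overestimation** and
**underestimation** scores.

## The statistic

The core assumption is the trait/state distinction: a trait (BMI, an IQ
subscore) is constant over the minutes of an fMRI scan, while motion is a
state that fluctuates second to second.  If residual motion did not distort
a trait's FC correlates, any split of a participant's timeseries would
support the same inference up to sampling error.  The algorithm therefore:

1. concatenates each participant's runs and splits the frames into the
   lowest-FD half (LOW) and the highest-FD half (HIGH), sorting per-frame
   framewise displacement (FD, mm) with stable tie-breaking (earlier frames
   go LOW; odd counts give LOW the extra frame);
2. computes Fisher-z (atanh) edge vectors separately for each half
   (Pearson correlations over the half's frames, clipped to
   ±(1 − 10⁻⁷) before atanh; row-major upper-triangle ordering);
3. records the mean FD of each half;
4. across participants, regresses each half's edges on an intercept and
   that half's mean FD, and differences the residuals (HIGH − LOW);
5. regresses the trait (plus optional covariates) on the residual
   difference at every edge, yielding a per-edge coefficient and t-value —
   the edgewise motion impact map.

Under no residual motion impact, step 5's t-values are null: the
trait-related FC structure is identical in both halves and cancels in the
difference.

### Inference: motion-blocks permutation + non-parametric combining

BOLD is autocorrelated, so frames are not exchangeable.  The permutation
null therefore reassigns the *motion blocks* — the maximal runs of
consecutive same-label frames from the observed split, additionally broken
at run boundaries — rather than individual frames.  Blocks are shuffled
uniformly, dealt to one half until its frame count first reaches half the
total (the final block is diverted if the other half would otherwise be
empty), and a fair coin picks which half is called LOW.  The block-length
multiset is preserved exactly, keeping the temporal dependence of the null
splits identical to the observed split.

Each permutation replays steps 2–5 with its own splits (re-deriving each
half's mean FD).  Per edge, the observed t gets an add-one empirical
p-value against the P-row null ensemble, one-sided in a chosen direction or
two-sided on |t|, mapped to z = Φ⁻¹(1 − p); the omnibus score is Stouffer's
Z = Σz/√E.  Every permutation row is then ranked against the same ensemble
by the identical recipe, and the omnibus p is (1 + #{Z_perm ≥ Z_obs})/(1 + P).
This two-pass recipe is slightly conservative for the two-sided omnibus
score (each permutation is a member of the ensemble it is ranked against),
which we accept; the calibration experiment below quantifies it.

Numerical detail: empirical p-values are clipped to
[1/(2(P+1)), 1 − 1/(2(P+1))] before Φ⁻¹ so that an observation at the
ensemble extreme maps to a finite z.

### Directional scores and the sign gate

Edges whose trait-FC effect (from the conventional edgewise regression
FC ~ 1 + trait + FD) has |t| ≤ 2 are ignored — the sign of the trait-FC
effect there is too uncertain to orient a directional score.  Among the
remaining edges, those whose motion impact t shares the trait-FC sign form
the overestimation set (combined one-sided in the trait-FC direction);
opposite signs form the underestimation set (combined one-sided the other
way).  The sets are disjoint by construction, and negating the trait leaves
both scores unchanged.

The edge sets are data-dependent, so the identical selection rule is
applied to every permutation row: each row combines its own
sign-agreement set.  Selecting the observed set once and reusing it for
the null would build a selection bias into the score (we verified it
rejects over half the time on null data); the row-wise rule restores
near-exact calibration.

### Node analysis

Stouffer combining restricts to any edge subset, so a node's score combines
the z-values of its incident edges, with significance recomputed from the
same permutation ensemble restricted to those columns (no re-permutation).
The number of motion-contributing regions is counted by iteratively
excluding the highest-scoring node (ties go to the lowest index) until the
whole-matrix score is no longer significant; the reported p-path is not
forced monotone.  Parcel-level projection of any symmetric effect matrix
uses the root-mean-square of each node's off-diagonal row.

## The synthetic cohort generator

The generator works backwards from the massively univariate FC regression.
Two basis correlation matrices — a participant-stable BRAIN pattern and a
time-varying MOTION pattern — are Cholesky-factorised; white Gaussian
draws premultiplied by the factors give unit-variance node series with the
target correlation.  The default patterns are edge-disjoint equicorrelated
communities (BRAIN: the first third of the nodes; MOTION: two communities
over the remaining two thirds) at peak correlation 0.3.  Equicorrelated
blocks are positive definite at any peak below 1, so neither source is
weakened by PD conditioning; arbitrary user patterns are conditioned by
multiplying off-diagonals by 0.95 until a Cholesky factorisation succeeds
(cap 200 iterations, shrinkage recorded).

Per participant: FD is *defined* as the across-node variance of the motion
series at each frame (population convention), so high-FD frames are exactly
the frames where the motion pattern is most strongly expressed.  The
observed series is

    mixed = √w_brain · brain + √w_motion · motion_unit,

with w_brain the participant's trait value (standard normal shifted by
|min| + 0.01 to be all positive) and w_motion their mean FD, followed by
rescaling every node to unit sample variance (the variance correction that
keeps participants comparably scaled for correlation-matrix regressions; a
stand-in for an unpublished procedure, chosen for its stated goal rather
than reconstructed).

Two properties of this construction matter:

* **The default cohort genuinely carries a trait-specific motion impact.**
  Edges are correlations, so the motion pattern's expression at an edge is
  the share w_motion/(w_brain + w_motion): the visible artifact — and the
  difference between a participant's high- and low-motion halves — depends
  on the trait itself.  This is the planted signal for detection
  experiments, and its impact map is negative on the motion edges (larger
  traits dilute the artifact), which is why localisation is scored by the
  *magnitude* of the Spearman correlation between the impact-t map and the
  motion-pattern edge mask.
* **The ground-truth null replaces the analysis trait.**  With
  `null_trait=True` the analysed trait is an independent random draw
  (equivalent to analysing a randomly assigned participant ID): unrelated
  to every series, weight, and FD value.  Merely decoupling the motion
  scale from the trait is *not* a null — the share interaction above still
  ties the visible artifact to the trait.

Per-participant motion variance is lognormal around the default level
0.2216 (the worked mixing-weight example; sigma 0.5, a spread comparable to
the wide FD distributions of large developmental cohorts).
`trait_motion_coupling` optionally adds a quadratic trait→motion-variance
link (a proportional link cancels exactly in the correlation
normalisation and plants nothing).

What the generator does **not** emulate: hemodynamics (no HRF, drift, or
spectral structure), spatial smoothness, scanner noise, respiratory
pseudo-motion, or distance-dependent artifact profiles.  Passing tests
show the statistic behaves correctly for correlation-structured Gaussian
data with motion defined as cross-node variance; they do not certify
behaviour under every real-data artifact.

## Validation experiments and problem sizes

All experiments run at desk scale; the statistical properties they probe
(permutation validity, selection-rule symmetry, localisation) do not depend
on matrix size.  The study-scale 394 × 1024 × 1024 configuration is
available behind `CohortConfig(full_scale=True)`.

* **Type-I calibration**: 100 null cohorts (24 nodes × 192 frames × 80
  participants, 80 permutations).  Directional-score rejection rates at
  α = 0.05 fall within the exact binomial 95% band [0.012, 0.105], and the
  p-values of all three scores are valid under a one-sided KS check (their
  empirical CDF never exceeds uniform beyond sampling noise); the two-sided
  omnibus score is conservative (rate below nominal, consistent with its
  two-pass construction) and is asserted never to exceed the band's upper
  edge.
* **Planted-signal detection**: 20 default cohorts (48 nodes × 512 frames
  × 300 participants, 60 permutations).  Detection (overestimation score,
  and the two-sided omnibus) in ≥ 90% of repeats; in every detected run the
  impact map's |Spearman| with the motion mask exceeds 0.3.
* **Power curve**: detection rate at n ∈ {12, 48, 192} (24 × 192, 60
  permutations, 20 repeats each), non-decreasing within a 0.25
  Monte-Carlo tolerance.
* **Oracles**: Stouffer closed form to 10⁻¹²; all four edgewise
  regressions against statsmodels OLS to 10⁻¹⁰; block-permutation
  invariants over 10⁴ random FD series; a planted motion-FC slope
  recovered within 10% at n = 1000.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| censoring threshold | none (∞) | keep frames with FD < threshold (mm); 0.1/0.2/0.3 studied |
| minimum duration | 8 min | participants with less data (post-censoring) are excluded |
| frame clamp | off (600 typical) | keep only the earliest N frames |
| `n_perm` | 1000 | permutations; smallest attainable p is 1/(n_perm+1) |
| `gate` | 2 | trait-FC \|t\| below which an edge's sign is treated as unknown |
| `alpha` | 0.05 | significance level for scores and the exclusion trace |
| `peak` | 0.3 | basis pattern correlation amplitude |
| `motion_level` | 0.2216 | mean per-participant motion variance (FD units, mm) |
| `motion_scale_sigma` | 0.5 | lognormal spread of motion variance across participants |

## Design choices in open territory

* Fisher-z clipping at ±(1 − 10⁻⁷); strict `fd < threshold` censoring;
  temporal-prefix clamping; LOW receives the extra frame at odd counts;
  FD ties broken by temporal order — all fixed for determinism and
  documented rather than prescribed by any convention.
* Correlations are computed over concatenated runs; blocks break at run
  boundaries because temporal dependence does not span runs.
* Permuted halves need not balance exactly (block-level assignment
  precludes it); the imbalance is bounded by twice the largest block.
* Effect sizes convert t to a partial correlation r = t/√(t² + df);
  percentiles of |r| use linear interpolation.
* Spearman p-values are exact (full enumeration) below n = 10,
  t-approximate above.
* Per-permutation and per-participant random streams are spawned from the
  master seed with `numpy.random.SeedSequence`, so results are independent
  of execution order.

## Known limitations

* The two-sided omnibus score is conservative by construction; the
  directional scores are the calibrated decision outputs.
* The generator's Gaussian, stationary world contains no non-motion
  artifact; specificity against e.g. scanner drift is untested.
* The bundled 394-node parcel label table is a synthetic stand-in with the
  correct network totals (333 cortical + 61 subcortical), not the actual
  anatomical assignment.
* Real-data FD at run boundaries is pipeline-dependent; FD is consumed as
  given and never recomputed.
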