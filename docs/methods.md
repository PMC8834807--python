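# Methods

## The model

`hevindex` operationalizes climate-related *potential impact* on an urban
public-health service network with the IPCC AR5 risk decomposition

    potential impact = Hazard × Exposure × Vulnerability

computed through a three-layer composite-indicator hierarchy (pillar →
indicator → sub-indicator):

* **sub-indicator layer** — raw survey or storyline inputs are normalized by
  *distance to target*: `x / target`. The ratio is deliberately uncapped; an
  indicator may exceed its reference (e.g. water-scarcity intensity 1.442 in
  the shipped worked example), which preserves proportionality and lets a
  monitoring programme track movement toward the target. Sub-indicators
  aggregate to their indicator with an equal-weighted arithmetic mean.
* **indicator layer** — indicators aggregate additively under
  proportionately normalized weights. Three weighting rules are supported:
  equal (the fallback when no expert judgement is available), budget
  allocation (expert points shares), and ascending-order prioritization
  (rank r_i among n items becomes weight (n − r_i + 1) / Σ, the rank-sum
  rule). The additive form is required because an indicator value can
  legitimately be 0.
* **pillar layer** — the three pillar scores multiply. Multiplication
  encodes *non-compensability*: a zero hazard, exposure or vulnerability
  annihilates the impact and no other pillar can offset it.

Vulnerability blends three components — sensitivity, coping capacity and
adaptive capacity. Capacities are phrased as *lacks* so that a higher raw
value is always worse; no polarity flipping is needed anywhere in the tree.

### Pillar scale constants

The impact product is meaningful on [0, 1] when each pillar lives on
[0, 1]. Because distance-to-target values may exceed 1, each pillar divides
its additive aggregate by a scale constant carried in the catalog:

| pillar        | scale | rationale |
|---------------|-------|-----------|
| vulnerability | 1     | deficit ratios are already fractions of targets |
| exposure      | 2     | exposure sub-indicators range up to twice their reference; the constant is calibrated so that all eight exposure pillar values of the shipped worked example reproduce at 3 decimals |
| hazard        | 2 (config) | hazard levels arrive pre-normalized from storyline analysis and reach ≈1.5 |

The worked example's hazard pillar values (0.827 area / 0.840 network)
derive from an expert budget allocation between floods and water scarcity
whose outcome was never published; no convex weighting of the published
hazard indicator rows (0.588/0.639, 1.279, 1.442) yields both values under
a common scale. The hazard pillar therefore takes an explicit weight vector
and scale from configuration, and the worked-example module ships the two
published hazard pillar values as fixture constants. Everything downstream
of them (products, classes, comparisons) is recomputed.

### Impact classes

Impacts fall into four classes whose right-closed boundaries are the cubes
of the quarter-points of a unit pillar scale — three pillars each at 1/4,
1/2, 3/4 of their range:

    very low [0, 0.016]   low (0.016, 0.125]   medium (0.125, 0.422]   high (0.422, 1]

Classification always uses the unrounded product; display rounding (decimal
half-up to 3 places, matching the published precision) never feeds back
into computation.

## Scenarios and views

A scenario couples hazard levels (per sub-indicator, optionally per city
zone) with response overrides addressed by facility id, type, zone or CUP
role. Overrides either *replace* a response (`value`, used to zero capacity
deficits sector-wide) or *scale* it (`scale` ∈ [0, 1], used to retreat
working-system exposure in flood zones). Restricting scales to [0, 1] makes
every desirable-scenario measure non-increasing, which guarantees the
monotonicity property impact(desirable) ≤ impact(trend) facility-by-facility.
Scenario application is pure: it returns a new dataset and logs every change.

Under the conservative assumption that city-wide mitigation cannot be
guaranteed, trend and desirable storylines carry identical hazard levels;
the desirable scenario acts only on exposure and vulnerability.

Views: *facility* (one record), *area* (equal-weighted mean of facility
indicator values — the "(on average)" city perspective), and *network*
(host-only, units-average, and combined results for a CUP service network).
The combined network view weights each facility equally; workload weighting
(the host carries ~75% of network workload in the study setting) can be
expressed through a custom `WeightScheme` but is off by default, because the
published network vulnerability columns are consistent with plain
equal-weighted means.

The acceptability bandwidth compares classes in the severity order
very_low < low < medium < high: the default target is "acceptable at low
under trend, desirable at very low".

## Robustness suite

Given a complete facility × indicator matrix (missing entries raise — the
suite does no imputation):

* **Cronbach's alpha** `k/(k−1)·(1 − Σs²ᵢ/s²_total)` plus corrected
  item-total correlations (item vs. the sum of the remaining items; flags
  below 0.3, severe below 0.2) and alpha-if-deleted.
* **KMO** from the scaled inverse correlation matrix
  (`a_ij = −R⁻¹_ij/√(R⁻¹_ii R⁻¹_jj)`), overall and per variable; for p = 2
  the partial correlation equals the correlation, forcing KMO = 0.5.
* **Bartlett's sphericity** `χ² = −(n − 1 − (2p+5)/6)·ln det R`,
  df = p(p−1)/2.
* **PCA** by eigendecomposition of the Pearson correlation matrix
  (loadings = eigenvector·√eigenvalue). Retention: eigenvalue > 1 (default)
  or smallest k reaching a cumulative-variance threshold (default 75%,
  inside the conventional 70–80% band).
* **Direct oblimin rotation** (γ = 0, i.e. quartimin — the common software
  default when "Oblimin" is named without a parameter) by gradient
  projection on the oblique manifold, with Kaiser row normalization before
  and denormalization after. Convergence: gradient-projection norm below
  10⁻⁶, max 1000 iterations, 3 seeded starts (identity + 2 random) with the
  lowest criterion winning. Oblique rotation preserves communalities
  (diag(PΦPᵀ) is rotation-invariant) and yields structure = pattern·Φ.
  Because rotation is sign- and permutation-ambiguous, each pattern
  column's sign is fixed so its largest-magnitude loading is positive;
  components keep descending-eigenvalue order.
* **Drop rule** — items whose |pattern loading| is below 0.4 on all of the
  leading two components are suggested for removal.

The study's own published statistics (α = 0.852, KMO = 0.524,
χ² = 268.26, 75.781% variance in 5 PCs) depend on a raw 25-facility survey
that exists only as a questionnaire appendix and is not machine-readable;
they are context, not test targets. The suite is instead validated against
closed-form oracles (2-variable KMO = 0.5, identity-matrix Bartlett = 0,
eigenvalues 1 ± r, eigenvalue sum = p, structure = pattern·Φ, communality
preservation) and a brute-force comparison of the oblimin criterion against
1000 random oblique rotations. The brute-force check runs with Kaiser
normalization disabled so that the optimizer and the random rotations
minimize the same objective.

## Synthetic survey generator

The generator emulates the study conditions rather than any particular
dataset: 36 facilities invited, response rate 25/36 (the host always
returns its questionnaire), one tertiary CUP host in the dense inner-city
zone, 5 primary-care and 27 SHPH CUP units, 3 independently operated
specialized facilities; zones drawn from (0.20, 0.20, 0.35, 0.25) over
zones 1–4.

Each vulnerability block follows a single-common-factor Gaussian model:
item j of facility i is `target·(μ + σ·(λf_i + √(1−λ²)e_ij))`, truncated at
0, so the population inter-item correlation is λ². Block parameters encode
the qualitative contrast the study reports — policy-checklist adaptive
items on which facilities answer almost identically, versus heterogeneous
day-to-day sensitivity and coping data:

| block       | λ    | μ (frac. of target) | σ | implied inter-item r |
|-------------|------|------|------|------|
| sensitivity | 0.20 | 0.50 | 0.20 | 0.04 |
| coping      | 0.45 | 0.45 | 0.20 | 0.20 |
| adaptive    | 0.95 | 0.55 | 0.10 | 0.90 |

λ = 0.20 for sensitivity reflects "distinctly heterogeneous" operational
data (population block alpha ≈ 0.3 at the indicator level); λ = 0.95 makes
the adaptive block near-homogeneous (block alpha ≈ 0.99). Truncation at 0
affects < 1% of draws at these settings, so sample inter-item correlations
recover λ² within 0.05 at n = 2000. Exposure responses are zone-driven
(multipliers 1.5/1.3/1.1/0.5 for zones 1–4) with facility-level noise
shared across items; hazard levels place fluvial flood in zones 1–2
(1.20/1.00, tapering to 0.15 in zone 4) with pluvial flood 1.279 and water
scarcity 1.442 city-wide, echoing the worked example's levels.

What the generator does **not** emulate: the real 84-item questionnaire
structure (the mapping of items to the 49 sub-indicators is not public),
floor/ceiling effects and ordinal response formats, spatial correlation
between neighbouring facilities, and the exact covariances that produced
the published survey statistics. Passing tests therefore demonstrate that
the pipeline and the statistical machinery behave correctly under the
study's *conditions*, not that they reproduce the study's raw data.

All randomness flows from a single root seed through one
`numpy.random.Generator`; identical profiles yield bit-identical datasets.

## Numerical and design choices

* Missing responses are excluded from their sibling mean with weights
  renormalized over present siblings — zero means "no deficit", absence
  means "unknown". A fully missing pillar subtree is an error naming the
  pillar.
* Equal weighting is the default wherever a scheme is unspecified.
* PCA/eigendecomposition uses `numpy.linalg.eigh` (symmetric); eigenvector
  signs are fixed by the largest-magnitude entry for reproducibility.
* Correlation matrices are symmetrized and clipped to [−1, 1] before use;
  singular matrices raise with advice to remove collinear items.
* The robustness report warns when n < 30 — at the study's n = 25,
  data-driven statistics are fragile, and the package surfaces that rather
  than hiding it.
* Problem sizes in the test suite and the acceptance script (n = 25
  surveys, 100 seeds for the reliability-contrast rate, n = 1000–2000 for
  simulation-based oracles) are chosen so the whole suite runs in seconds
  while keeping Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* The hazard pillar of the worked example cannot be recomputed from
  published information (see above); it is the one fixture constant in an
  otherwise fully recomputed pipeline.
* The suite requires complete item matrices; listwise deletion or
  imputation is the caller's responsibility.
* Only PCA-based dimensionality analysis is provided (no maximum-likelihood
  factor extraction), and only the additive/multiplicative aggregation pair
  of the index design (no geometric means or OWA operators).
* Whether the "service network" perspective should include independently
  operated specialized facilities is a modelling choice; the network view
  operates on an explicit `NetworkSpec`, so either convention can be
  expressed.
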