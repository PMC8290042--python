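# Methods

## The connectivity model

`placeconn` treats a stream of geotagged events as repeated sightings
of users in polygon places. Over an analysis period *T* (half-open
`[start, end)`, default one calendar year; UTC calendar days
throughout), a user is *observed in* a place when they have at least
one assigned event there — no minimum-activity threshold is applied,
so a single event counts. From the user→place observation sets the
package derives:

* **S_i** — unique users observed in place *i*;
* **S_ij** — users observed in both *i* and *j* (shared users);
* **PCI_ij = S_ij / √(S_i·S_j)** — the symmetric connectivity index;
* **PCI_{i→j} = S_ij / S_i** — the directional variant, chosen so that
  the geometric mean of the two directions reproduces the symmetric
  index identically;
* **person-day movements** — per (user, UTC day): in `home_based` mode
  one count to (home, j) for each distinct non-home place j visited
  that day (homes inferred as the modal place by event count, ties to
  the earliest-first-seen place, then the smallest id); in
  `copresence` mode one count to each of the C(m, 2) pairs among the m
  distinct places seen that day.

Self-pairs are omitted from all edge lists (PCI_ii ≡ 1) and zero
pairs are implicit: at county-like scales the overwhelming majority of
pairs share no user, so edge lists are sparse by construction.
Multi-scale indices are obtained by re-keying event assignments to the
coarser level and *recounting* unique users — summing child-level
shared counts would double-count users seen in several siblings.

Assumptions worth stating plainly: events carry no uncertainty
(point-in-polygon with "covers" semantics; boundary points go to the
lexicographically smallest covering place, deterministically); users
are not deduplicated, weighted or bot-filtered; one event is enough to
"observe" a user somewhere. The index is a long-run summary — it is
not a real-time flow estimate.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| analysis period | 1 year | time | long enough to summarize stable interaction patterns |
| `min_users` | 5 | users | places below this are dropped; small-S places are dominated by individual idiosyncrasy |
| distance | haversine, R = 3958.8 | statute miles | centroid-to-centroid great-circle distance; ellipsoidal accuracy is immaterial at this precision |
| PCI log transform | ×1000, then log10 | — | keeps PCI ≥ 0.001 non-negative on the log scale |
| significance stars | 0.1 / 0.05 / 0.01 | — | conventional regression-table thresholds |

## Statistical analyses

* **Edge-list comparison** (`pair_edges` + `correlate`): inner join on
  unordered pairs — only pairs with a value in *both* inputs enter, and
  the dropped counts are reported. Pearson r on optionally
  log-transformed columns; per-origin statistics attach each pair to
  both of its endpoints and require ≥ 3 incident pairs.
* **Distance decay** (`fit_distance_decay`): y = a·d^(−b). For a
  *single origin* the default is nonlinear least squares on the raw
  scale, initialized from the log–log OLS closed form, with raw-scale
  R² — the amplitude is shared by all of the origin's pairs, and the
  raw-scale R² is the quantity of interest. For an exponent *pooled
  over many origins* use `method="loglog"`: amplitudes then vary by
  orders of magnitude (√(S_i·S_j), boundary boosts), and the raw-scale
  objective would be dominated by a handful of near pairs — on
  noiseless model expectations the raw fit under-estimates a planted
  exponent of 1.7 by ≈ 0.2 while the log–log fit recovers it. If the
  nonlinear fit fails to converge the log–log solution is returned
  flagged `fallback=True`.
* **Boundary effect** (`boundary_regression`): OLS of connectivity on
  an intercept, a same-parent indicator and distance, with
  conventional (non-robust) standard errors and two-sided t p-values.
  The caller chooses the scale of y and distance; see the validation
  design below for when the log scale is the defensible choice.
* **Focal association** (`focal_association`): OLS of a per-place
  outcome (infection rate, evacuee count, …) on connectivity to one
  focal place, scaled ×1000 for readable coefficients, optionally
  controlling for distance to the focal place.

## Regionalization

Places are clustered by unweighted average linkage (UPGMA) on the
dissimilarity d_ij = 1/PCI_ij. Pairs with no shared users receive a
finite sentinel of 10× the largest finite dissimilarity — they merge
last without introducing infinities. The linkage is implemented
in-package with the exact Lance–Williams update
d(A∪B, C) = (|A|·d(A,C) + |B|·d(B,C)) / (|A|+|B|) because a
deterministic tie-break is part of the contract: among equally close
community pairs, the merge whose combined member set has the
lexicographically smallest (min id, max id) — then smallest full
sorted member tuple — wins. Average linkage is reducible, so merge
heights are non-decreasing and cutting one dendrogram at several k
yields nested partitions. Agreement with `scipy.cluster.hierarchy`
average linkage on tie-free inputs is enforced by test.

## The synthetic generator

`make_world` builds a grid of square lon/lat cells centered on the
equator (so a 69.09-mile cell has ≈ 69.09-mile centroid spacing),
tiled into equal "states", with uniform-random populations.
`simulate_events` draws users with homes ∝ population, Poisson event
counts per user, and for each event a Bernoulli(trip_fraction) choice
between home and a trip destination drawn ∝
P_j · d(home, j)^(−β) · γ^[same state] — the minimal kernel that
produces the three regularities connectivity indices show on real
mobility data: population scaling, power-law distance decay, and
excess within-state interaction. The home cell is excluded from the
trip kernel (d = 0). Coordinates are uniform inside the destination
cell, timestamps uniform over the period, and the realized visit sets
and trip counts are returned as ground truth.

Defaults: β = 1.7, γ = 3, 12 events/user/year, trip fraction 0.25,
populations U(5 000, 50 000), ≈ 2 users per 1 000 population. The
activity level matters more than it looks: shared-*user* counts are
proportional to trip flows only while per-destination visit
probabilities stay small. At high activity the visit indicator
saturates (a user seen once in a nearby place is the same user seen
twenty times), the near-pair connectivity flattens, and a planted
decay exponent is structurally under-recovered. Twelve geotagged
events per user-year — typical of sparse geotagged social-media
activity — keeps the process in the near-linear regime.

What the generator does **not** emulate: diurnal/seasonal rhythms,
episodic shocks (holidays, hurricanes), platform population bias, bot
accounts, multi-day trips with durations, or contiguity constraints on
states. Passing tests therefore demonstrate the correctness of the
pipeline's accounting and the recoverability of planted structure —
not robustness to the biases of real social-media data.

## Validation study designs and problem sizes

* **Oracle agreement**: 50 random incidence fixtures (≤ 50 places,
  ≤ 500 users); the sparse-matrix PCI must match an independent
  brute-force set-intersection implementation bit-exactly, including
  which pairs are present.
* **Decay recovery**: an 8×8 grid, 4 states, 5 000 users; the pooled
  log–log exponent over all pairs must land within ±0.2 of the planted
  1.7.
* **Boundary effect**: a 24-cell equatorial ring (cells of 15°, so the
  ring closes exactly) with 4 states and *equal* populations, 1 000
  users. On a bounded grid the γ = 1 null is not actually null:
  corner places see fewer reachable destinations, so same-state
  (same-block) pairs carry systematically higher PCI at fixed distance
  — a purely geometric confound, visible even on noiseless model
  expectations. The ring's translational symmetry removes it: at any
  fixed distance, same-state and cross-state pairs are congruent. The
  regression runs on log10(1000·PCI) against the same-state indicator
  and log10(distance) because the gravity mean model is linear on
  exactly that scale; under γ = 1 the same-state coefficient is then
  truly zero and, at this sample size, sampling noise dominates the
  deterministic saturation lack-of-fit so conventional OLS inference
  is approximately calibrated (measured sd(coef)/SE ≈ 0.8). At much
  larger user counts the test turns conservative — the lack-of-fit
  term inflates residual variance without adding coefficient variance
  — which is a property of conventional OLS inference under mild
  misspecification, and one reason the raw-scale variant should be
  read descriptively rather than inferentially. Equal populations
  matter for the same reason: population heterogeneity induces
  dyadic (place-level) error components that OLS treats as
  independent.
* **Regionalization**: planted 4-block PCI (blocks of 10, intra 0.2,
  inter 0.01, noise sd 0.005) must be recovered with adjusted Rand
  index ≥ 0.9; nestedness is checked on a 100-place world cut at
  k ∈ {20, 48, 75}.
* **Reproducibility**: the shell pipeline (simulate → compute → decay
  → boundary → regionalize) at a fixed seed must reproduce committed
  golden outputs byte-for-byte.

These sizes were chosen so the whole validation battery runs in well
under a minute on one CPU while leaving each recovery comfortably
identified.

## Numerical and degenerate-input conventions

* Edge-list floats are serialized with 17 significant digits —
  write/read round trips are bit-exact, including record order.
* Symmetric edge kinds store one record per unordered pair with
  `place_i < place_j` lexicographically.
* Timestamps without timezone are taken as UTC; person-day logic uses
  UTC days.
* Duplicate event rows are kept by the reader (they cannot affect
  unique-user quantities); rejected rows (bad coordinates, unparseable
  timestamps, empty user ids) are tallied, and accepted + rejected
  always equals the input row count.
* A constant response in a decay fit returns b = 0 with R² = 1;
  non-positive values are dropped (with a count) before any log.
* Collinear regression designs raise an error rather than returning a
  pseudo-inverse fit.

## Known limitations

* OLS inference on pairwise tables ignores dyadic dependence; p-values
  on real data should be treated as descriptive (no
  spatial-autocorrelation correction, no multiple-testing control
  across origins).
* The directional index and person-day definitions follow the
  consistency arguments stated above; other conventions exist.
* Regionalization imposes no spatial contiguity — contiguous-looking
  communities must emerge from the connectivity structure itself.
* The O(n³) in-package linkage is intended for up to a few thousand
  places, which covers county-scale work but not, e.g., census tracts
  nationwide.
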