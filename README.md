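# placeconn

Shared-user place connectivity from geotagged point events.

`placeconn` computes the **Place Connectivity Index (PCI)** — a
normalized measure of how strongly two places are linked by the people
observed in both — from a stream of geotagged events (user id,
timestamp, longitude, latitude) and a polygon place layer. Around the
index it provides the standard companion analyses: directional
connectivity, person-day movement matrices, distance-decay power-law
fits, boundary-effect regressions, focal-place association models, and
agglomerative regionalization on inverse connectivity. A gravity-model
synthetic generator makes the entire pipeline testable offline with
known ground truth.

It is aimed at spatial epidemiologists, mobility researchers and
regional scientists who want a reproducible, desk-scale implementation
of shared-user connectivity — for example to relate epidemic seeding or
evacuation destinations to a place's connectivity with an epicenter.

## The index

Let S\_i be the number of unique users observed (≥ 1 event) in place
*i* during an analysis period *T* (typically one year), and S\_ij the
number observed in both *i* and *j*. Then

```
PCI_ij = S_ij / sqrt(S_i · S_j)
```

PCI lies in [0, 1]: 0 when no user is shared, 1 when *i* = *j*. The
geometric-mean denominator removes the first-order effect of place
size, so connectivity is comparable between places with very different
user counts. A directional variant `PCI_{i→j} = S_ij / S_i` captures
asymmetric pull; the geometric mean of the two directions reproduces
the symmetric index exactly. Places with fewer than five observed
users are dropped by default — their index values are dominated by a
handful of individuals.

## Worked example

Simulate a year of events on a 4×4 grid world (4 states, gravity
mobility with decay exponent 1.7 and same-state boost 3), then run the
pipeline:

```sh
placeconn simulate --grid 4x4 --states 4 --users 300 --seed 7 --out events.csv
# wrote 12097 events for 300 users

placeconn compute --events events.csv --layer world.geojson --min-users 5 --out pci.csv
# 120 connected pairs over 16 places (min_users=5)

placeconn decay pci.csv --layer world.geojson --origin r01c01
# origin=r01c01 a=8.61918 b=0.6345 R2=0.5214 n=15

placeconn boundary pci.csv --layer world.geojson
# term             coefficient          SE  sig
# intercept           0.476534     0.02691  ***
# same_parent         0.207181     0.02307  ***
# distance        -0.000980888   0.0001547  ***
# Adjusted R2: 0.7022
# Observations: 120
# *p < 0.1, **p < 0.05, ***p < 0.01

placeconn regionalize pci.csv --k 2,4 --summary place_summary.csv --out regions.csv
# wrote assignments for k in [2, 4]
```

Reading the output: `compute` found 120 of the 16·15/2 = 120 possible
county pairs connected by at least one shared user. The single-origin
decay fit for the central place r01c01 returns the power law
PCI ≈ 8.6·d^(−0.63) with raw-scale R² = 0.52 (a small saturated world —
a flat, noisy decay is expected at this scale; the pooled log–log fit
on the larger validation world recovers the planted exponent, see
`docs/methods.md`). The boundary regression shows same-state pairs
carry an excess PCI of about 0.21 at fixed distance — the planted
boundary effect. `regions.csv` holds the place → community labels at
each requested cut.

The same pipeline is available from Python; see
`placeconn.studies` for complete worked runs.

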