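# Methods

This note documents the models, defaults and numerical choices behind
`coopnet`, and what the synthetic data do and do not establish.

## Network construction

A year's network has one node per physician practice that, after filtering,
served at least `min_patients_per_year` (default 30) distinct patients that
calendar year. Filters run in this order: (1) drop emergency visits and
visits to the excluded specialties (anaesthesiology, radiology,
neuropathology — little patient contact or care-coordination role); (2)
apply the 30-patient activity rule to the retained claims; (3) count, for
each pair of surviving practices, the distinct patients with at least one
retained visit to both in that year (visit multiplicity is irrelevant —
"shared patient" is a set relation); (4) connect pairs at or above the
shared-patient threshold (default 9). The ordering of (1) and (2) is a
design choice: the activity rule is evaluated on coordination-relevant
visits only, and it is configurable. Practices passing the activity filter
but without qualifying edges stay as isolated nodes — they are part of the
active roster and belong in the density denominator. Sharing is computed
within single calendar years; no cross-year windows. Edges are undirected
and unweighted after thresholding; the underlying shared counts are kept as
edge attributes for sensitivity reruns.

## Network-level indicators

*Density* is `|E|/(n(n−1)/2)`. *Mean distance* averages shortest-path
lengths over **connected pairs only**; claims networks routinely contain
isolates and small components, and dropping unreachable pairs is the
standard convention there. Two consequences are worth knowing: a network
with no edges has no defined mean distance (signalled as an error), and on
*disconnected* graphs adding an edge can raise the average by connecting
distant new pairs — the "edges shorten paths" monotonicity only holds on
connected graphs, and the tests scope it accordingly.

*Transformed mean distance* draws `n_replicates` (default 5,000; tests and
the acceptance script use 200) uniform random graphs with exactly the
observed node and edge counts — the G(n, m) model, chosen over G(n, p)
because it holds density fixed rather than in expectation — and reports
`z = (observed − null mean) / null SD`. Replicates are sampled by drawing
m distinct pair indices without replacement and decoding them to edges;
mean distances use the same connected-pairs convention. A complete (or
otherwise fully determined) graph makes every replicate identical; the
zero-SD null is signalled as degenerate rather than returning ±inf. For a
graph actually drawn from the null, z is centred at zero but *not* unit
normal (the mean-distance distribution is discrete and skewed); the
self-consistency test therefore checks the mean over 100 trials against a
3/√100 band rather than distributional shape.

## Node-level indicators

Degree is normalized by n−1. Eigenvector centrality is the dominant
eigenvector of the binary adjacency, computed by a deterministic Lanczos
iteration (fixed all-ones start vector; tolerance and iteration budget are
arguments; non-convergence raises). On disconnected graphs the global mode
gives nodes outside the dominant component near-zero scores — appropriate
when the giant component carries the cooperation structure — and a
per-component mode is available. Scores are scaled to unit maximum.
Betweenness is shortest-path betweenness with even splitting across
equal-length geodesics, normalized by (n−1)(n−2)/2. Because both scores are
only comparable within a single network, each year's values are converted
to percentage rankings: ascending average ranks divided by n, so ranks live
in (0, 1], ties share their mean rank, and an untied maximum maps to 1.
The panel outcome for "degree" is normalized degree (raw degree remains
available by configuration); coefficient magnitudes on a (0, 1] scale are
comparable across years of different size.

## Synthetic claims generator

The generator emulates the study conditions of a 14-wave regional
outpatient sector: 197 practices in the first year (14.2% integrated),
25,979 patients growing 0.97%/year, practices growing 1.15%/year with
8%/year turnover (entry and exit make the panel unbalanced), ~3.5 visits
per patient-year, 8% emergency visits, 8% of practices in excluded
specialties, and gamma-distributed Charlson scores (mean 2.0, SD 1.6).
Patients belong to one of 8 community blocks and choose practices with
weight

```
w ∝ size_i · (1 + a·same_community) · (1 + d·t·IP_i)
```

with attachment `a = 14`, lognormal practice size weights (σ = 0.5), and
cooperation drift `d` (default 0.03 at full scale). Visit counts are
Poisson. The size weights matter: without them every within-community pair
crosses the 9-shared-patient threshold and the network saturates. With
them, the full-scale defaults produce densities of 0.15–0.18 and mean
distances of 1.9–2.0 — the right magnitudes for a regional network of this
size. A test-scale configuration (60 practices, 2,000 patients) keeps the
same structure at ~1/13 the patient volume.

Two deliberate simplifications: (1) integrated practices start
*exchangeable* with their peers conditional on community — only the drift
`d·t` separates them. A real integrated system's members already sit above
their peers at baseline; here the baseline advantage is sacrificed so that
`d = 0` is an exact null (IP and non-IP shared-patient counts equal in
expectation), which the tests exploit. (2) Charlson scores are drawn
directly from a gamma distribution rather than derived from diagnosis
codes; no ICD coding, geography or insurance-plan structure is modelled.
Consequently, passing tests show the pipeline detects a *drift* in
cooperation against exchangeable baselines under community-block mixing —
they do not show robustness to baseline selection effects, coding artefacts
or real referral behaviour.

The direct panel simulator (`generate_panel_from_model`) bypasses the
claims layer entirely: it draws the dynamic model's outcome from known
coefficients with normal fixed effects and noise, initialising each series
at its conditional stationary mean and burning in 25 periods so the
mean-stationarity assumption behind the system-GMM level moments holds.
Latent fixed effects and shocks are returned as columns so tests can verify
the generating identity exactly.

## Panel assembly

One row per practice-year in which the practice was an active network node.
`n_patients` and `mean_charlson` come from the retained claims of that
year. `year` enters as the 0-based year index (centering only shifts the
intercept, which the fixed effect absorbs). Lags are gap-aware: a practice
unobserved in t−1 has a missing lag in t even if t−2 exists; gaps are never
bridged. Default lag order is 2 for the degree outcome and 1 for the
ranking outcomes.

## System GMM

The estimator stacks, per practice, first-differenced equations
(eliminating the fixed effect) and level equations. Difference equations at
period t are instrumented by outcome levels `y_{t−l}` for l in a
configurable window (defaults per outcome: 4:11 for degree, 6:11 for the
eigenvector ranking, 3:14 for the betweenness ranking), one instrument
column per (period, lag) pair — or one per lag when collapsed — with zeros
where a lag is unavailable, the standard unbalanced-panel convention.
Level equations are instrumented by the lagged first difference
`Δy_{t−1}`, valid under mean stationarity. Exogenous regressors instrument
themselves (differences in the difference block, levels in the level
block). Instrument columns that never fire are dropped. Observations
lacking a required lag drop from the affected equation block only.

The one-step weighting is block diagonal per practice: the tridiagonal
matrix implied by i.i.d. errors (2 on the diagonal, −1 between adjacent
periods) for the difference block, identity for the level block, zero
across blocks — implementations differ here, so the choice is stated
explicitly. The second step re-weights with the first-step residual
moments (Moore–Penrose inverse, since the moment matrix is singular when
instruments outnumber practices). Reported standard errors apply the
Windmeijer finite-sample correction by default — uncorrected two-step SEs
are known to be badly downward biased — and the correction can be switched
off to mimic estimators that do not apply it. If the first-step residuals
are exactly zero (a noise-free model), the optimal weighting is undefined
and the one-step estimate, which already fits perfectly, is returned.

Diagnostics: Sargan–Hansen `J = (Z'u)' W (Z'u)` with df = instruments −
parameters (undefined and signalled when just identified); Arellano–Bond
AR(m) on the differenced residuals with the full variance expression
including the estimation-noise terms (the leading term alone is used as a
fallback if the correction overshoots to a non-positive variance); a joint
Wald test on all slope coefficients (df = parameter count: 6 with two
outcome lags, 5 with one); and pseudo-R² = corr(y, ŷ)² on the level
equations. Estimation is fully deterministic for a fixed panel.

Validation, in the absence of any independent system-GMM implementation in
the environment: instrument matrices are checked against hand-built
matrices on toy panels; the estimator recovers known coefficients on
simulated dynamics (θ1 mean bias below 0.05 at N=300, T=14 over 50 seeds;
the IP-by-year coefficient covered by ±2 SE in ≥90% of replicates);
Sargan, AR(2) and Wald reject at approximately the nominal 5% under a null
DGP (measured at N=300, T=8 over 200 replicates; the joint Wald oversizes
noticeably at N≲150, which is why the size battery uses N=300); and
algebraic invariances (weighting proportionality, practice relabelling,
outcome scaling) hold to machine precision.

## Sensitivity analysis and statistical power

The threshold ladder {3, 6, 9, 12, 15} re-runs construction through
estimation; thresholds that empty the network (or make the random-graph
null degenerate, as happens at threshold 3 on small dense test networks)
are reported as degenerate rather than failing the run. A caveat on the
IP-by-year coefficient at test scale: with ~350 usable panel observations
its standard error (~5e-3) exceeds the drift-implied signal
(θ3 ≈ slope·(1−θ1) ≈ 2–4e-3), so individual estimates flip sign freely —
exactly the regime where the original-scale analysis (≈3,000 observations)
sits at p ≈ 0.06. The direction-stability check is therefore aggregated:
across 8 seeded replicates, every per-threshold mean coefficient must be
positive and a clear majority of individual estimates positive. The
descriptive trend gap (IP minus non-IP yearly mean ranking slope), which
the generator controls directly, is reported alongside as the powered
quantity.

## Problem sizes

Defaults used by the test suite and acceptance script: recovery at N=300,
T=14 over 50 (tests) / 25 (script) seeds; size batteries over 200 / 100
replicates at N=300, T=8 with instrument lags 2:4; null self-consistency
over 100 / 50 G(55, 200) draws with 200 replicates each; pipeline runs at
the 60-practice test scale. These sizes make the whole suite run in a few
minutes while leaving every Monte Carlo band far wider than its simulation
error.

## Known limitations

- No baseline IP centrality advantage and no selection-into-treatment
  process; θ3 here measures a clean drift, not the observational contrast a
  real IHS evaluation faces.
- The claims generator has no referral structure (visits are independent
  draws), so directedness and visit ordering are meaningless by
  construction — consistent with the undirected network definition.
- Eigenvector centrality on graphs with two nearly-equal dominant
  components mixes the components' eigenvectors; rankings remain
  well-defined but component attribution is not.
- Sargan's power is low when instruments are many relative to practices;
  the default windows follow the per-outcome conventions above rather than
  minimizing instrument count.
- The published reference table is reproduced only at its summary-row
  level; the underlying claims are proprietary, so coefficient-level
  replication of the original panel models is out of reach by design.
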