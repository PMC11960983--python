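# Methods

## The presence model

A night yields classified file counts `c = (c_1, ..., c_9)` over the
nine northeastern-US species labels (files left unidentified, NOID,
are excluded). Given a classifier confusion matrix θ — `θ_ij` the
probability a file of true species *i* is assigned label *j* — we
condition on the file having received a species label and renormalise
each row over the nine species columns, giving `θ′`. Conditional on
the night's true composition `π` (a point on the 9-simplex), each
classified file's label is an i.i.d. draw from the mixture

    P(label = j | π) = Σ_i π_i θ′_ij .

The night log-likelihood is `ℓ(π) = Σ_j c_j log Σ_i π_i θ′_ij`, which
is concave in π. We maximise it with the standard EM update for
mixture weights,

    π_i ← π_i · (Σ_j c_j θ′_ij / m_j) / n ,   m_j = Σ_k π_k θ′_kj ,

starting from the uniform composition, stopping when the per-iteration
log-likelihood gain falls below 1e-10 or after 10,000 iterations.
Because the objective is concave, EM converges to the global optimum;
a grid oracle (exhaustive simplex enumeration, ≤ 3 active species)
verifies this in the test suite, and seeded random restarts are
available for flat likelihoods. Fractional counts are accepted
throughout: they act as weights in ℓ and arise naturally when a
species ratio is multiplied by a nightly total.

**Presence test.** Acoustic presence of species *s* is the
likelihood-ratio test of H₀: π_s = 0 against the unconstrained
alternative, Λ = 2(ℓ̂_full − ℓ̂_0). H₀ pins π_s to the boundary of the
simplex, so Λ is asymptotically distributed as the mixture
½δ₀ + ½χ²₁ rather than χ²₁; we report p = 1 when Λ = 0 and
p = ½·P(χ²₁ ≥ Λ) otherwise. A parametric bootstrap (multinomial
nights of the same integer total drawn from the null fit, add-one
smoothed tail proportion) serves as the reference method. p ≤ α
(default 0.05, the conventional survey threshold) declares presence.

Null simulations under the shipped classifier put the type-I error at
α = 0.05 around 0.04 — the boundary mixture keeps the test slightly
conservative. The χ̄² approximation is excellent when Λ is near 0 or
large, but in the mid-p regime on very small nights (≈20 files) it
can deviate from the bootstrap by several hundredths; the bootstrap
is the arbiter there.

**Conditioning choice.** We renormalise away the NOID column, i.e.
condition on classified files only. The alternative — modelling NOID
as a tenth outcome — would add information only if NOID rates differ
strongly by species; commercial tools do not document their choice,
and conditioning keeps nightly totals interpretable as "files
classified to some species".

## The simulated-night design

The design isolates how count and species ratio drive the test. For
each target species, 25 subsets set its count t = 25, 24, ..., 1;
each subset spawns 25 nights in which every one of the 8 other
species has count o = 25, 24, ..., 1. That is 9 × 25 × 25 = 5,625
nights; testing all nine species on each gives 50,625 records. Every
species is present on every night (counts ≥ 1), so p ≤ α is a true
positive and p > α a false negative. Per-night ratios average exactly
1/9 (reported as 0.11) with population SD 0.054 (reported 0.05), and
every (species, count) cell contains 225 nights — the design mostly
probes the low-ratio regime where presence testing is hard.

**Classification modes.** The default, `exact`, feeds the true counts
directly to the presence test: it emulates building nights only from
files the classifier identifies correctly, so the test's
misclassification accounting — not the classifier's identification
errors — is what is being measured. `expected` pushes counts through
θ deterministically and `sampled` draws each file's label from its
θ row. The distinction matters: in `expected`/`sampled` modes,
misclassification *inflow* inflates a high-sensitivity species'
counts on low-ratio nights and can make detection easier there
(the "swamping" effect, visible for MYSO-like species in real
programs); `exact` mode removes it so the count/ratio dependence of
the test itself is measured cleanly.

## Synthetic classifiers

Real classifier confusion matrices are proprietary, so the package
generates them. A profile fixes per-species diagonal sensitivities,
sends a per-species share of files to NOID, and distributes the
remaining mass over other species with weight w_in = 8 within a
confusable group versus w_out = 1 outside, Dirichlet-jittered with
concentration 50 around those weights (seeded, reproducible). The
default group is the four *Myotis* species, whose calls overlap
heavily.

Two shipped profiles span the accuracy structure published for
northeastern-US classifiers (sensitivities roughly 0.24–0.97, Myotis
low, *Lasiurus*/*Perimyotis* high, and one profile with a notably weak
LABO classifier):

| | EPFU | LABO | LACI | LANO | MYLE | MYLU | MYSE | MYSO | PESU |
|---|---|---|---|---|---|---|---|---|---|
| kpro-like | 0.85 | 0.24 | 0.90 | 0.60 | 0.45 | 0.80 | 0.38 | 0.50 | 0.91 |
| sono-like | 0.80 | 0.92 | 0.72 | 0.70 | 0.55 | 0.60 | 0.52 | 0.55 | 0.97 |

The NOID rate defaults to min(0.05, (1 − sensitivity)/2): about 5% of
files unidentified, capped so that highly sensitive species retain
some misclassification mass (a flat 5% would be infeasible at
sensitivity 0.97). Real NOID rates are not published per species;
this is the package's own choice and is fully overridable.

What the generator does *not* emulate: call-quality variation within
a species, night-to-night classifier drift, correlated errors between
files of the same bat pass, and true spatial/temporal activity
structure. Passing tests therefore demonstrate properties of the
presence test under known, stable misclassification rates — not
field performance of any commercial product.

## Summary metrics

Simulation records are grouped by (examined species, its count);
`pct_tp` is the share of nights with p ≤ α. The **critical count**
(CC) at reliability τ is the smallest count whose `pct_tp ≥ τ`;
survey practice quotes both τ = 75% and 90%, so both are parameters
and the CLI reports both. **Real-world recordings** RWR = CC /
sensitivity converts correctly classified files into field recordings
needed, under the deliberately conservative assumption that no other
species' files leak in; RWR ≥ CC always, with equality only at
sensitivity 1.

## The count-and-ratio meta-model

Per species, ordinary least squares of the p-value on
`[1, log10(count), ratio]`. A Gaussian linear model for a bounded
response is statistically crude — predictions are clipped to [0, 1] —
but it is the standard survey-calibration summary and supports
interpolation to counts and ratios the ladder design never visits.
Each species trains on all 5,625 of its examined records (ratio
distribution mean 0.11, SD 0.05); restricting to the 625 target-only
rows is available but leaves count and ratio collinear enough that
the ratio coefficient's sign is unstable for species whose response
saturates early. The `ratio` covariate is the species' share of the
night's files; an `odds` variant (count over all *other* files) is
selectable and recorded in the fit metadata.

Model error is leave-one-out cross-validated MAE/RMSE computed
exactly via the linear-smoother identity `e_i,loo = e_i / (1 − h_ii)`
(verified against explicit refits in tests), on raw (unclipped)
predictions. CC curves solve for the smallest integer count whose
predicted p ≤ α on a ratio grid; the ±2·MAE band re-solves with the
prediction shifted by ±2·MAE. On the shipped profiles CC rises
steeply as ratio falls below ~0.25, and for low-sensitivity Myotis
species RWR separates sharply from CC — the regime where per-night
presence determination becomes impractical.

The model CC at the design's mean ratio lands within a few files of
where the empirical mean p-value crosses α (a like-for-like check;
the log-linear form smooths a convex decay, so exact agreement is not
expected and a ±5-file sanity band is asserted in tests).

## Site projections

A scenario is a label, nine species ratios and a list of nightly
totals (defaults 75, 175, 275, 475 — spanning zero-crossing detector
reality up to full-spectrum scales). Counts are ratio × total with
fractional values kept (they represent abundance more precisely than
whole files). Counts are pushed through the classifier's full
confusion matrix to **total positives** (true + false positives) per
species, ratios are recomputed from the positives, and each species'
meta-model predicts its p-value at (positives, derived ratio) with a
±2·MAE band. Totals positives ≥ 25 short-circuit to p = 0.00: on the
ladder design the test always fires at or before 25 files. Zero
positives report p = 1 (nothing classified as the species).

The shipped Fort Drum scenarios (pre/post White Nose Syndrome
relative-activity shares) are kept exactly as published, including
the pre-WNS row summing to 1.001 from three-decimal rounding; ratios
are deliberately not renormalised so that ratio × total reproduces
the published per-species counts. Scenario validation therefore
accepts ratio sums within 2e-3 of 1. Under the default classifier and
fitted models, species below 1% of site activity (MYLE, MYSE) are
never declared present at any total up to 475 files — the
rare-species failure mode the pipeline exists to expose.

## Numerical choices

- EM: uniform start; tolerance 1e-10 on log-likelihood gain; cap
  10,000 iterations; iteration count and convergence flag returned
  with every fit. Mixture probabilities are clipped at 1e-300 before
  logs; if a constrained fit's active species give zero mass to every
  observed label the update would collapse, so the current point is
  kept and its (hugely negative) clipped log-likelihood stands —
  yielding Λ ≫ 0 and p ≈ 0, the correct limit.
- Λ is floored at 0 before the tail probability (EM tolerance can
  leave it at −1e-12).
- Bootstrap p-values use add-one smoothing, (1 + #{Λ* ≥ Λ})/(B + 1),
  and require an integer night total.
- Confusion-matrix CSVs round-trip float64 exactly (shortest-repr
  writing, correctly rounded parsing).
- Ties on the CC grid resolve to the smallest count; an undefined CC
  (threshold unreachable within `max_count` = 1,000) propagates as
  None rather than a sentinel value.

## Known limitations

- The presence test assumes the confusion matrix is known exactly and
  is stationary; uncertainty in θ is not propagated.
- The Gaussian meta-model can predict outside [0, 1] before clipping
  and its MAE band is symmetric even where the response saturates.
- The χ̄² reference is asymptotic; for nights of a few dozen files in
  the mid-p regime, use the bootstrap method.
- Specificity/false-positive behaviour of the *pipeline's metrics* is
  out of scope by design: the simulation scores false negatives only,
  since every species is truly present on every design night.
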