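# Methods

## Overview

`specnet` classifies subjects (patients vs. controls) from digitized mass
spectra by first reducing the measurement set, then representing each
subject as a weighted, fully connected network over the selected
measurements, and finally classifying subjects from the topological
properties of those networks binarized at a sweep of thresholds.  The
method assumes that disease-relevant signal lives in the *pairwise linear
relationships* between measurements, not only in their marginal values.

## Feature selection

Spectra contain thousands of measurements, most of them noise, so the
network is built over k selected measurements (typical k: 25–300).

* **Binning** (`bin_average`): the spectrum is split into k sequential,
  non-overlapping regions and each region becomes one feature equal to the
  per-subject mean of its columns.  With N columns and B bins, the first
  `N mod B` bins have width `ceil(N/B)` and the rest `floor(N/B)` — widths
  differ by at most one and the partition is deterministic.
* **Shared-information ranking** (`shared_information_score`): each
  feature i receives S_i = mean over j ≠ i of I(X_i; X_j), the average
  mutual information it shares with all other features, in bits.  `high_S`
  selection keeps the k largest-S features (noise shares little
  information; high-S features form correlated, meaningful groups);
  `low_S` keeps the k smallest (the minimal-redundancy principle).  Ties
  break toward the smaller original index; selected indices are returned
  sorted so downstream pair enumeration is stable.

**MI estimator.** Each variable is discretized into `n_levels = 8` (default)
equal-width levels over its own observed range; MI is the discrete sum over
the empirical joint, base-2 logs, zero-probability cells contributing 0.
This is the simplest deterministic estimator consistent with the discrete
MI definition.  Absolute S values are estimator-dependent (equal-width
histogram MI carries a positive small-sample bias of roughly
(cells−1)/(2 n ln 2) bits); only *orderings* should be interpreted, which is
all selection uses.  A constant feature occupies a single level and scores
0 with everything, sinking to the bottom of the high-S ranking.  S divides
by N−1 ("average" rather than total shared information); the division does
not affect ordering.

## Per-subject networks

For every unordered pair (i, j) of selected features, i < j, two OLS lines
are fitted for m_j as a function of m_i — one on control subjects, one on
patients (at least 3 subjects per class required; fitting is invariant to
subject order).  The *higher*-index feature is always the response, so each
unordered pair carries exactly one deterministic model.  Residual standard
deviations use denominator n − 2 and are floored at
`1e-9 × IQR(m_j over the training set)` (1e-9 absolute if that IQR is 0),
so perfectly collinear training pairs remain usable without affecting
realistic fits.  A zero-variance predictor within a class falls back to
slope 0 and the class mean of m_j (the OLS limit), with a logged warning.

For a subject with values (x_i, x_j), the vertical residual from each class
line is scored under a zero-mean normal with that line's sigma, and the
edge weight is the normalized patient probability

    w = p_patient / (p_patient + p_control) ∈ [0, 1].

Likelihoods are normal *densities* (the 1/σ prefactor is kept, since the
two sigmas generally differ) evaluated in log space, so the ratio is
computed stably as a logistic of the log-density difference; an
indeterminate 0/0 resolves to 0.5, the symmetric completion.  Identical
class models give w = 0.5 exactly, and swapping the class labels of the
training set maps every weight to 1 − w.  The result per subject is a
weighted clique on the k selected features.

## Threshold sweep and topology metrics

Each clique is binarized over a grid of thresholds (default 0.00–1.00 in
steps of 0.05), edge present iff w > τ strictly — so τ = 1 always yields
the empty graph.  From each binarized graph a fixed 12-component metric
vector is extracted: link density, mean degree, degree SD, global
clustering coefficient (3·triangles / connected triples), degree
assortativity, global efficiency (mean inverse shortest-path length over
ordered pairs, 0 for disconnected pairs), diameter of the largest
connected component, number of components, largest-component fraction,
greedy modularity, triangle count, and open-triad count.  Low thresholds
produce dense graphs where local structure (motifs, clustering)
discriminates; high thresholds produce sparse graphs where macroscopic
structure (diameter, modularity) carries the signal — the fixed vector
covers both regimes.

Degenerate conventions (documented constants, keeping the classifier's
feature matrix finite): clustering 0 without connected triples; diameter 0
for edgeless graphs; assortativity 0 when the degree variance at edge
endpoints is 0 (includes regular graphs); modularity 0 for edgeless
graphs.  When several components tie for largest, the one containing the
smallest node index provides the diameter.

Community detection uses deterministic fast-greedy (CNM) modularity
maximization via igraph; metric extraction sits in the innermost
cross-validation loop (folds × subjects × thresholds graphs), so metrics
are computed with dense numpy plus `scipy.sparse.csgraph` (~1 ms/graph)
rather than per-graph networkx calls, and the test suite cross-checks every
quantity against networkx on random graphs.

## Classification and evaluation

Per threshold, each subject is the metric vector of their binarized
network; the per-threshold classifier never concatenates across
thresholds, so scores are a function of the applied threshold.  Two tracks:

* **SVM**: linear kernel, C = 1, features standardized with training-fold
  statistics.  Scored by precision, recall and F (harmonic mean; 0 when
  precision + recall = 0), patient as the positive class, and precision
  defined as 0 when no positive predictions are made.
* **PNN**: Parzen-window class-conditional density classifier; the class
  score of a held-out vector is the mean Gaussian kernel over that class's
  (standardized) training vectors, the posterior the normalized patient
  score.  The kernel width defaults to the median pairwise training
  distance per fold (scale-free, no tuning loop).  Scored additionally by
  AUROC of pooled held-out posteriors — the Mann–Whitney rank statistic,
  ties counting one half.

**Cross-validation and leakage.** The default protocol is stratified
leave-one-out (the standard choice at ~10¹–10² subjects; stratified k-fold
is available).  The pair models are themselves fitted on labeled subjects,
so inside every fold they are refit on the training fold only and the
held-out subjects' networks and metrics are rebuilt from those
fold-specific models; held-out predictions are pooled over folds before
scoring.  Feature selection (binning or MI ranking) never reads class
labels and is applied once outside the folds.

`best_scores` summarizes a set of curves as the maximum score over
thresholds per (network size, selection method) cell.

## Synthetic data

The generator emulates the assumed structure of SELDI-style benchmark
cohorts at desk scale: many independent Gaussian noise features (sd 1.0
around a baseline of 0 — mean-centered arbitrary units, so values may be
negative and generated datasets set `allow_negative`) plus a minority of
informative features forming a linear chain
`m_{i+1} = a_class · m_i + b_class + ε`.  A chain gives every informative
feature high mutual MI with the others (the regime where high-S recovery
is expected) while keeping per-class adjacent-pair OLS slopes analytically
known.  Defaults (the "strong effect" regime): 30 + 30 subjects, 200
features, 20 informative, control slope +1, patient slope −1, equal
intercepts, chain residual sd 0.1.  The "null" regime gives both classes
the control parameters: features remain correlated but carry no class
signal, so any cross-validated score above the class prior indicates
leakage.  Randomness uses numpy's seeded PCG64 generator; identical specs
produce identical cohorts.

What a green synthetic test does *not* establish: real spectra have
heteroscedastic, non-Gaussian noise, baseline drift, correlated noise
blocks and mixed disease subtypes; the generator plants exactly one clean
chain.  Recovery and power results on it bound the method's behavior in
the intended regime, not on any particular clinical cohort.

## Numerical and protocol notes

* Best-over-thresholds under the null sits *above* the class prior by the
  expected max-over-grid selection bias (~0.1 at 21 correlated
  thresholds, 30 subjects); the leakage guard therefore tests closeness to
  the prior in units of the across-seed Monte-Carlo SD, not equality.
* The end-to-end null check runs 10 seeds at 30 subjects / 60 features
  (the strong-effect check runs at the full 60 / 200) to stay inside a
  CPU-minutes budget.
* Delimited I/O writes floats with `%.17g` and parses with a round-trip
  float parser, so `read(write(x))` is bit-for-bit.
* Published best-score tables for the external ARCENE benchmark are an
  external reference only: reproducing them requires the original download
  and unreported classifier settings, and no test asserts them.

## Known limitations

* Pair models are strictly linear with vertical residuals; no robust or
  nonlinear variants.
* The histogram MI estimator is biased upward at small n; fine for
  ranking, not for reporting absolute bits.
* The motif census stops at 3-node subgraphs (triangles, open triads).
* Leave-one-out with per-fold model refits is O(n²k²) in time; for
  cohorts much beyond ~10² subjects use the k-fold protocol.
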