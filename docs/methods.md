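# Methods

This note documents the models and procedures implemented in
`careact`, the defaults they use, and what the synthetic-data
experiments do and do not demonstrate.

## Response model and T-score

Peri-event activity is measured in two 500-ms bins immediately after
each stimulus onset (windows half-open, times in seconds, 0-based bin
indices throughout). The baseline `f0` of a unit is its mean rate over
all recording time outside `[onset, onset + 3 s)` windows; `g0` is the
population mean of `f0`. Responses are normalized as

    R = (f_startle − f0) / (g0 + f0),      T = ln(1 + R).

For low-firing units (`f0 ≪ g0`) `T` tracks absolute rate changes; for
high-firing units it tracks relative changes, so one threshold serves
both. The natural logarithm is used (the transform is reported without
a base elsewhere; any base only rescales thresholds).

## Unit taxonomy

* **Responsive** to a type: Mann–Whitney rank-sum of per-trial 1-s
  rates against four matched pre-event baseline windows per trial at
  α = 0.05, *and* `|T| ≥ 0.2` for that type. Trials are pooled across
  intensity levels, so a parametric type contributes 21 trials. The
  rank-sum form (rather than a 7-vs-7 signed-rank pairing) was chosen
  for power: with only seven repetitions a paired test cannot reach
  p < 0.05 two-sided unless every pair agrees.
* **Selectivity**: general = responsive to all four types; subgeneral =
  a strict subset of 2–3; specific = exactly one. With fewer than four
  types in the schedule the label is relative to the available types
  (warned).
* **Intensity class**: least-squares slope of trial rate on intensity
  rank, permutation p-value (1000 permutations, seeded), α = 0.05;
  significant slopes are `sensitive-up`/`-down` by sign, otherwise
  `invariant`. Units without a responsive parametric type are `n/a`.
* **Unit class**: mean rate < 5 Hz → putative pyramidal, > 8 Hz →
  interneuron, otherwise unknown; fewer than 100 spikes → unknown. The
  complex spike index is the percentage of first-lag ISIs in 2–15 ms
  whose second spike has smaller amplitude (denominator: number of
  ISIs); it needs per-spike amplitudes.
* **Rate smoothing** uses a causal one-sided exponential kernel
  (τ = 100 ms default), normalized exactly on the discrete grid so the
  integral of the rate equals the spike count.

## Hierarchical clustering

Per-unit T-score vectors are agglomerated by repeatedly merging the two
nearest groups under Euclidean distance between group centroids, the
merged centroid recomputed as the mean of all member rows. Ties break
on the smallest (left id, right id) pair. For display, subtrees at each
merge may be flipped to minimize the distance between the two boundary
leaves at the junction ("best matching endpoints" read as boundary-leaf
distance; centroid alignment is the plausible alternative reading).
Centroid linkage can produce non-monotone merge distances; no
monotonicity is asserted.

## Regularized MDA

Patterns are the concatenated two-bin rates of every unit (features
`[0, U)` = bin 1, `[U, 2U)` = bin 2); concatenation rather than
averaging keeps the transient structure of the response. Classes are
the stimulus conditions plus a rest class sampled from randomly placed
pre-event windows (two rest patterns per event by default in the
analysis pipelines).

With class means `m_i`, counts `n_i` and global mean `m`:

    S_B = Σ n_i (m_i − m)(m_i − m)ᵗ
    S_W = Σ_i Σ_{x∈D_i} (x − m_i)(x − m_i)ᵗ
    Ω_i′ = (1 − λ) Ω_i + λ c_i I,   S_W′ = Σ n_i Ω_i′

where `Ω_i` is the maximum-likelihood class covariance, so
`S_W′ = S_W` exactly at λ = 0. By default the shrinkage target is
scaled by `c_i`, the mean diagonal of `Ω_i`: with firing rates spanning
two orders of magnitude, a plain identity target would distort the
metric (a flag restores the plain `I`). The discriminant basis solves
`S_B v = e S_W′ v` as a symmetric-definite generalized eigenproblem
(numerically stabler than forming `S_W′⁻¹S_B`; agreement with the dense
non-symmetric solver is asserted to 1e-8). At most `N − 1` directions
are kept, fewer if `S_B` is rank-deficient.

Classes are modelled as Gaussians in the subspace (covariances shrunk
with the same λ); classification is minimal Mahalanobis distance, ties
to the lowest class index. Distances from rest are reported in units of
the rest cluster's isotropic standard deviation `√(tr(Σ_rest)/k)`.

λ is selected by grid-search cross-validation (`select_lambda`, ties to
the smallest value). The analysis defaults use λ = 0.8, the typical
grid optimum in the under-sampled regime these experiments live in
(hundreds of units, seven trials per condition); at small λ the
eigenvectors exploit sampling noise of the within-scatter.

Cross-validation holds out one randomly chosen sample per class
(one pattern per condition plus one rest pattern), refits, and scores
the held-out points; repetitions and partitions are seeded.

## Trajectories and reactivation detection

The fitted projection is applied to overlapping windows: the window
stamped `t` covers `[t, t + 0.5)` and `[t + 0.5, t + 1.0)`, advancing
in 10-ms steps. The detection statistic is the Mahalanobis distance
from the rest Gaussian, **re-standardized on the trajectory itself**:
the model's rest Gaussian is estimated from a few dozen training
windows and, in the many-units/few-trials regime, understates the
out-of-sample spread; the score is therefore anchored at the median of
the non-stimulation samples and scaled so that 2 equals the
equivalent-Gaussian 97.7th percentile of that distribution. "Inside the
rest 2σ boundary" always refers to this calibrated score.

A putative reactivation is an excursion that

* exceeds θ = 2 for at least `d_min = 0.5 s` (gaps < 200 ms bridged),
  outside stimulation windows `[onset − 1 s, onset + 3 s)`;
* is directed: the Mahalanobis-nearest non-rest class at the peak must
  be nearer at the peak than at the excursion start;
* is an ensemble event: removing the single largest unit contribution
  from the peak window must retain ≥ 70% of the peak score. A lone
  burst from one low-rate, highly weighted unit can carry a whole
  window across the threshold for exactly one window-width; a genuine
  pattern reactivation is carried by many co-active units.

The minimum duration is set well above the ~0.1-s excursions that
boxcar-correlated rest noise produces, and below the ~1.3 s that a
one-second reactivation spends above threshold; with these filters the
false-event rate on reactivation-free synthetic data is well under 0.1
per minute while amplitude-0.4 injections are recovered with
sensitivity above 0.8.

Subpopulation analyses refit the subspace on the selected units'
feature columns (data partitioned, then projected), never by slicing
the full-population basis.

## Shuffle controls

* **Unit identity**: spike trains are reassigned among unit ids — once
  globally, or per time segment (`segment_s`), which exchanges activity
  among units at all times and is the variant that collapses
  classification. Both variants conserve every train and hence the
  population rate function exactly.
* **Temporal**: within ±2 s of a reactivation, each cell's spikes are
  placed in 10-ms bins (50 ms available as a flag; both bin widths are
  in circulation) and the bin order is permuted within the cell,
  preserving the within-bin offsets and each cell's window count.

## Correlation and Explained Variance

Pair correlations are Pearson coefficients between two units'
concatenated per-repetition rate sequences in 50-ms bins (a
per-repetition-average variant is available behind a flag). Periods:
pre-event baseline windows, 1-s event windows, ±2-s windows around
detected reactivation peaks, and matched post-event non-reactivation
windows. Zero-variance sequences give NaN and are excluded. Pairs are
screened by `max |r|` over non-basal periods (defaults 0.1 for the
invariant group, 0.05 for the sensitive group); display statistics use
the top 10/20/30 pairs for specific/subgeneral/general groups, ranked
by event-period |r|. Period contrasts use Wilcoxon signed-rank on |r|
against the pre period; the reactivation-magnitude contrast uses
Mann–Whitney (one-sided), as no specific test is prescribed for either.

EV is the squared partial correlation of the event- and post-period
pair-correlation vectors controlling for pre:

    EV = [(r_ep,post − r_ep,pre·r_pre,post) / √((1 − r²_ep,pre)(1 − r²_pre,post))]²

bounded in [0, 1]; the reversed control swaps the roles of pre and
post. Reactivation-period correlations use the MDA-detected windows.

## The synthetic generator

The generator is a piecewise-constant inhomogeneous Poisson model:
baseline rate `f0` everywhere, `f0 × gain` inside 1-s event-response
windows. Defaults encode the study conditions: six sessions (drop at
levels 1–3, sound, air, shake), seven repetitions at uniform 60–180-s
intervals, 5–10-min session gaps, 300 s of pre-event baseline; 36%
responsive units split 1:1 invariant:sensitive, selectivity splits
54/26/20% (invariant) and 45/25/30% (sensitive) assigned by
largest-remainder rounding; pyramidal baselines 0.2–3 Hz, interneuron
8–30 Hz, with cliques drawn from pyramidal units only (responses of
8–30-Hz cells at multi-fold gains would dominate every population
statistic through a handful of cells).

Gains: invariant 3.75×, sensitive-up (3, 8, 20)×, sensitive-down
(0.6, 0.35, 0.15)×; fixed-intensity stimuli use the middle gain. These
place synthetic event clusters a few to a few tens of rest-SDs from the
rest cluster — the range real ensembles of this size show — while an
amplitude-0.4 reactivation of the invariant component clears the 2-σ
detection threshold with a margin yet stays inside the rest cluster
after a 4-s temporal shuffle dilutes it fourfold.

Trial-to-trial structure has two parts, both shared within a
selectivity group (and drawn independently for the invariant and
sensitive categories so that no mixed common-gain axis scrambles the
level ordering of cluster separations):

* a log-normal amplitude jitter (sd 0.3/0.18/0.08 for
  general/subgeneral/specific), and
* a shared burst envelope: each event's (and each reactivation's) extra
  spikes follow one gamma-weighted 50-ms envelope common to all
  participating units, tilted toward the onset for events (τ = 0.4 s).
  This is what gives co-responding units genuinely correlated 50-ms bin
  sequences, as real co-firing has; without it, constant-rate windows
  would leave pair correlations near zero at these firing rates.

Reactivations: 1–3 per event (the count distribution is a free choice;
nothing constrains it beyond "several"), placed uniformly 5–120 s after
the event outside stimulation windows, amplitude 0.4, one shared
Bernoulli participation gate per injection per selectivity group
(probabilities 1.0/0.85/0.45 general/subgeneral/specific, zero for
sensitive units, matching the finding the generator emulates) and a small shared amplitude jitter (sd 0.1).

**What the generator does not emulate**: theta/ripple structure and any
spike-timing organization finer than the shared 50-ms envelopes,
burst/refractory ISI statistics, behavioral state, electrode drift, or
sequential within-reactivation order (none was found in the recordings
either). Passing the synthetic benchmarks therefore demonstrates that
the pipeline recovers the population-level structure it assumes — not
that it is robust to every property of in-vivo data.

## Problem sizes and determinism

The validation experiments use populations of 200–500 units and 3–6
sessions: taxonomy recovery on 500 units, intensity recovery on 200
units at gain ratio 1:2:4 and 2-Hz baseline, the monotone-intensity
trend over 100 seeded runs of 400 units, reactivation detection pooled
over 20 seeded 280-unit sessions (≈50 invariant units each), and
correlation/EV over 20 seeded 200-unit sessions. Every random draw
derives from an explicit integer seed (numpy `default_rng` /
`SeedSequence` spawning in the pipeline), so identical configurations
reproduce byte-identical outputs.

## Known limitations

* The rest-score calibration assumes reactivations occupy a negligible
  fraction of rest time; recordings dominated by reactivation would
  bias the scale upward and the detector conservative.
* Centroid-linkage clustering is O(N²) per merge (O(N³) total) —
  adequate for a few hundred responsive units, not for thousands.
* The λ grid search optimizes held-out accuracy only; it does not
  penalize subspace instability.
* The intensity-dependence test assumes monotone dependence; a
  non-monotone (e.g. band-pass) intensity tuning would be labelled
  invariant or by the dominant limb.
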