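# Methods

## Pipeline

A record enters as a 12-lead, 10-s signal at 500 Hz. Analysis of one
(lead, coarse graining, complexity measure, sampling frequency,
classifier) combination proceeds as: decimate → binarize → score →
assemble feature table over the cohort → patient-grouped LOOCV with
hyperparameter optimization. The evaluation grid crosses 13 lead
configurations (12 single leads plus all-leads-combined), 4 coarse
grainings, 3 measures, 4 frequencies and 2 classifier families — 1248
cases.

## Decimation

Downsampling is sample discarding on a fixed pattern from the 500 Hz
native rate: every 4th sample kept (125 Hz), every 2nd (250 Hz), three
of every four with indices ≡ 3 (mod 4) dropped (375 Hz), identity
(500 Hz). No anti-alias filtering or interpolation is applied — the
point is to emulate what a lower-rate acquisition device would record,
not to resample optimally. Index 0 is always kept; the 3-of-4 phase
convention for 375 Hz is otherwise arbitrary and is fixed for
reproducibility. Upsampling is deliberately unsupported.

## Coarse graining

* **TC**: threshold at the per-lead median; points equal to the
  threshold map to 0. Sensitive to baseline wander and noise, which is
  why the synthetic generator includes both.
* **KM**: 1-D two-centroid k-means. Centroids start at mean ± δ with
  δ = 0.05 × SD by default; each iteration assigns points to the
  nearest centroid (absolute distance; ties to the lower centroid,
  mirroring TC's boundary rule), recomputes centroids as cluster means,
  and stops when the mean point-to-nearest-centroid distance changes by
  less than 10⁻⁶ × range, or after n iterations. A centroid that loses
  all points is re-seeded at the signal extremum on its side. In 1-D,
  absolute and squared distance give identical assignments; only the
  stopping statistic would differ. Both δ and the tolerance are
  caller-overridable.
* **FD/BD**: zeros with ones at fiducial indices — all five wave peaks
  (FD) or R peaks only (BD). BD's ones are a subset of FD's by
  construction, and the count of ones for one record is
  frequency-independent (only the zero gaps change length).

## Fiducial detection

Delineation is treated as a commodity stage and runs on the
already-decimated signal. The detector: (1) median-center the lead and
correct polarity so the dominant QRS deflection is positive; (2) smooth
the squared first difference with a 150 ms moving window; (3) take
energy peaks at least 300 ms apart and above 25% of the maximum as QRS
marks; (4) refine R as the extremum within ±100 ms; (5) locate P
(maximum in [R−280, R−80] ms), Q (minimum in [R−100, R) ms), S
(minimum in (R, R+100] ms) and T (maximum in [R+100, R+400] ms), with
window-truncated or ordering-violating waves recorded as absent. A flat
or beatless signal yields an empty fiducial set, which downstream
produces all-zero FD/BD strings (and a logged warning). The detector is
deterministic and recovers synthetic ground-truth R peaks exactly (±2
samples contractually) on noise-free records at every supported rate.
Note that on overlapping waveforms the extremum of the *summed* signal
shifts away from the generating component's center, so Q/S agreement
with synthetic ground truth is looser (±8 samples in tests) than for
the well-separated P/R/T.

## Complexity measures and normalization

* **LZ76** counts components of the exhaustive production history
  (scan left to right, extend the component while it can be copied from
  the extended history — self-overlap allowed; the trailing, possibly
  reproducible component counts as one).
* **LZ78** counts phrases of the incremental dictionary parse; an
  incomplete final phrase counts.
* **Titchener T-complexity** uses a deterministic left-to-right
  token-merge T-decomposition: tokens start as single symbols; at each
  level the leading token is the copy pattern p, its leading run length
  k contributes log₂(k+1), and remaining runs of p are absorbed into
  their following token; a trailing p-run collapses to one token;
  recursion stops at a single terminal token. Strings shorter than 2
  score 0 by convention. Several T-complexity formulations exist in the
  literature; this package fixes the one above, implements it twice
  (fast span-based and a naive reference used in tests), and makes no
  claim of numeric identity with other published variants.

Normalization divides the raw score by n/log₂(n). Values are **not**
clipped to [0, 1]: the unit bound is asymptotic only. On i.i.d.
fair-coin strings at the lengths this pipeline produces (1250–5000),
mean normalized LZ76 is ≈ 1.03–1.05 and LZ78 ≈ 1.6–1.7; the
finite-length correction to the Lempel–Ziv counting bound is still
large at these n, and the LZ78 phrase count scales as n/log₂(c) with
c ≪ n. Periodic strings score far below random ones at equal length,
which is the property the normalization is actually used for. For
T-complexity no general unit bound holds either way.

## Cohort construction

Cases are all SR records of patients with a strictly earlier AFIB
record (the AFIB record itself is never analyzed). Age groups follow
the decade convention `<20, 20-29, …, 80-89, >=90`. Controls are SR
records with no comorbidity flags, from patients with no AFIB record
anywhere, one record per distinct patient, drawn uniformly under a seed
to match the case count in every (sex × age-group) cell. A cell that
cannot be filled raises an explicit shortfall error listing the cell —
matching is never silently relaxed. Record ordering uses the
`acquisition_index` column by default (configurable), standing in for a
recording timestamp.

## Classification harness

Folds are per patient; features are z-scored with training-fold
statistics only (required for the distance metrics and Gaussian kernels
to be comparable; toggleable). KNN uses brute-force distances
(`scipy.spatial.distance.cdist`) with majority vote — odd k guarantees
no vote ties. The 10 metrics are euclidean, cityblock, chebyshev,
minkowski (p=3), cosine, correlation, canberra, braycurtis, hamming and
jaccard; the list is a package convention (the metric-count constraint
is what matters) and is overridable via `KnnSpace(metrics=...)`.
Non-finite distances (e.g. correlation on a single-feature table) are
treated as infinitely far. The SVM family maps the outlier fraction to
ν of a ν-SVM (floored at 0.01) with linear, quadratic-polynomial or
Gaussian kernels; an infeasible ν in a fold falls back to the
training-majority prediction.

Record-level accuracy over the pooled predictions is the primary
metric, with sensitivity/specificity taking PAF as the positive class;
a patient-level majority-vote accuracy is stored alongside. Note a
small-sample property of grouped LOOCV relevant to null calibration:
with one record per patient and balanced arms, each training fold is
imbalanced against the held-out record's class, biasing null accuracy
*below* chance by O(1/n). At 60 records the bias is negligible against
the permutation standard error, which is the size used for the
chance-level checks.

The optimizer minimizes 1 − accuracy. If the discrete space fits within
the iteration budget it is enumerated exhaustively; at the defaults
both spaces are too large (KNN: 500 combinations vs 300 iterations,
SVM: 153 vs 50), so a sequential model-based loop runs: a seeded 10-point random initial
design, then a 30-tree random-forest surrogate whose per-tree spread
provides the predictive uncertainty for an expected-improvement
acquisition over the not-yet-evaluated candidates. Everything is
seeded; for a fixed seed the evaluation sequence of a longer run is a
prefix-extension of a shorter one, so the best found accuracy is
monotone in the budget. Tied optima are resolved by the componentwise
mode (ties to first appearance); if the mode combination is not itself
optimal a diagnostic warning is raised and the first optimum in trace
order is used — on small noisy tables this fallback does occur.

## Synthetic data

Each beat is five Gaussian bumps (P, Q, R, S, T) with default
amplitudes (0.15, −0.10, 1.00, −0.15, 0.30) mV, centers (−200, −40, 0,
+40, +250) ms relative to R, and widths (40, 15, 20, 15, 70) ms —
magnitudes in the range of scalar textbook values, not fitted to any
recording. All 12 leads share this waveform scaled by a fixed gain
vector (lead II largest, aVR inverted). RR intervals are log-normal
with mean 60/HR and a stated CV (strictly positive by construction);
wave centers snap to the sample grid so every true peak is a strict
local extremum of the clean signal. Defaults for cohorts: HR uniform in
55–80 bpm per patient, RR CV 0.05, noise SD 0.01 mV, 0.25 Hz baseline
wander of 0.05 mV — values a clean resting SR strip plausibly shows,
chosen once. AFIB records (used only as labels for case selection) get
zero P amplitude and RR CV ≥ 0.25.

Case effects are declarative template perturbations (RR-CV scale,
P amplitude/width scale, HR shift) so tests inject exactly one
difference. The default study effect doubles RR CV (0.05 → 0.10). This
is intentionally subtle: reduced-grid accuracies land in the 0.55–0.70
range, comparable to what modest real cohorts support, and the
group-mean excess in normalized LZ78(BD) is on the order of 10⁻³ —
near the edge of detectability at a few hundred records. What passing
tests show is that the pipeline *recovers a pure beat-timing effect
through the beat-timing binarizers and stays at chance on null
cohorts*; they do not show that real post-AF sinus rhythm carries such
an effect, nor calibrate real-data accuracy. The generator has no AF
f-waves, no ectopy, no electrode artifacts, and identical morphology
across leads up to scaling.

## Problem sizes

Default test and acceptance runs use 10-s records, cohorts of 12–20
cases with equal controls, a reduced grid (lead II, four coarse
grainings, LZ78, 125 Hz, KNN at 20 optimizer iterations), 20-fold
permutation nulls at 60 records, and exhaustive oracle sweeps over all
binary strings of length ≤ 12 (Lempel–Ziv) and ≤ 10 (T-complexity) —
sizes at which every check runs in seconds while still exercising the
full code paths.

## Known limitations

* The T-complexity variant is a fixed package convention; cross-study
  numeric identity is not guaranteed.
* Delineation is simple; on real, artifact-laden ECGs an established
  delineator should be substituted (the binarizers only need peak
  indices).
* WFDB support covers the format-16 single-gain dialect this pipeline
  writes and reads, not the full WFDB specification.
* The full 1248-case grid at publication-scale budgets (300 optimizer
  iterations per cell) is compute-heavy; the grid runner caches
  features and records per-cell errors, but no parallel execution is
  provided.
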