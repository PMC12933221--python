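# Methods

## Scope and model

`hrmsqc` monitors instrument performance during internal-standardised
LC-HRMS acquisition. The quality of a run is judged entirely from its
isotopically labelled internal standards: their peak heights, apex
retention times and mass errors proxy the detector, the chromatography and
the mass calibration respectively. Two complementary layers act on the
same three metrics — fixed univariate limits against rolling expectations,
and a multivariate PCA-based control chart (Hotelling T² + SPE) trained on
recent in-control runs. The univariate layer gives predefined, auditable
criteria; the multivariate layer catches correlated, sub-threshold shifts
that no single limit sees, at the price of less direct interpretability.

## Peak measurement

For each compound an extracted-ion chromatogram (EIC) is formed per MS1
scan by summing centroid intensities within ±`eic_ppm` (default 20 ppm,
inclusive bounds) of the exact m/z. The 20 ppm extraction window is
deliberately twice the 10 ppm mass-error limit so an over-limit mass error
still yields a measurable peak rather than a missing one. Summation (not
the single nearest centroid) makes the trace robust to centroid splitting.

The EIC is smoothed twice with a quadratic five-point Savitzky–Golay
filter (interior weights (−3, 12, 17, 12, −3)/35). Edge points are
evaluated from a quadratic fitted to the nearest five points
(`scipy.signal.savgol_filter(..., mode="interp")`), so the series never
shrinks; traces shorter than five points pass through unsmoothed and are
flagged. The apex is the maximum smoothed intensity within
±`apex_search_half` (default 13.5 s, i.e. a 27 s extraction window) of the
drift-corrected expected retention time; ties break to the earlier time.
The narrower ±9 s `peak_half_window` centred on the found apex is the
quantification window.

Baseline and noise come from two 15 s windows: [apex−30 s, apex−15 s) and
(apex+15 s, apex+30 s] (half-open away from the peak). Each window's noise
is its raw max − min; the smaller value is the noise estimate and the mean
of that quieter window is the baseline — so an isobaric co-eluting peak in
one window cannot inflate the noise. Windows with fewer than two points
are excluded; if both drop out the measurement is flagged low-confidence.
A peak is accepted when S/N = height/noise exceeds 5 (S/N = +∞ when noise
is 0 and height positive, which noise-free synthetic data can produce) and
at least 5 raw EIC points in the peak window lie strictly above
baseline + 2·noise. Height is the smoothed apex intensity minus baseline,
floored at 0. Mass error is the signed ppm deviation of the mean m/z over
the apex scan ±2 neighbours (most intense qualifying centroid per scan,
unweighted mean; fewer scans at run edges).

## Retention-time correction

Stored expected retention times are corrected by a single uniform shift:
the median (apex − expected) over internal standards detected in the most
recent blank, searched with a tripled apex window so drifted standards are
still found. The shift is recomputed against the original stored times at
every blank — the latest blank wins and corrections never compound, which
prevents drift-accumulation errors. Even-count medians are the mean of the
two middle values. All compounds, targets included, receive the same
shift; no per-compound warping is attempted.

## Univariate control

Expectations are rolling medians over the half-open window
[t − 60 d, t), which structurally excludes the run under evaluation.
Normalised intensity is height over the 60-day median height;
retention-time deviation is the difference from the 60-day median apex
time. Acceptable regions are inclusive: [0.5, 2.0], ±10 s, ±10 ppm — a
value exactly on a limit passes. A median needs at least `min_history`
(default 5) prior detections, otherwise the corresponding check is skipped
and logged; a single prior run would make a normalised intensity
meaningless. Conventions on pooling: height medians use sample runs only
(blanks and standard injections carry the standards but not the matrix);
retention-time medians pool every run type; medians include failing runs —
a robust statistic tolerates a minority of faulty runs, while the
multivariate reference set below does not. Blank and standard injections
are themselves evaluated (retention time, mass error, missing standards)
but skip the intensity check.

An undetected internal standard is its own failure category
(`missing_is`) and takes precedence; otherwise a run with two or more
distinct limit reasons is `multiple`. The per-reason counts then satisfy
`flagged − missing = height + retention_time + mass_error − overlap`,
where overlap counts the extra reasons on multiple-category runs — the
identity the summary reports for any campaign.

## Multivariate control (MSPC)

Heights and retention times are transformed to pair ratios
R = v_i/(v_i+v_j) over all unique standard pairs in compound-list order
(28 features for 8 standards; only one orientation is kept since
R(i,j) + R(j,i) = 1). Ratios cancel any common multiplicative shift, so a
uniform post-maintenance gain moves no height feature — by design that
fault is left to the univariate intensity limit. Mass errors enter raw,
per standard. Missing values are set to zero *before* ratio formation and
autoscaling: a zeroed standard is maximally anomalous and flags the run;
it can never contaminate the reference set, which admits only complete
runs.

The normal-operating-conditions (NOC) set contains the sample runs of the
rolling window that passed univariate QC, had all required standards
detected (`min_is_per_polarity`, default: every listed standard), **and**
were not themselves flagged out of control by MSPC. The last condition
goes beyond the classical "univariate-passing" rule and is the package's
own choice, standard in Phase-II control charting: without it a sustained
sub-threshold fault (e.g. a +1.3 ppm mass bias that breaks no fixed limit)
is absorbed into its own rolling reference within a handful of injections
and masks its own detection. Below `min_noc` (default 20) rows, MSPC
defers to univariate QC with a logged notice.

Per block, features are autoscaled with NOC means and standard deviations;
zero-variance features are dropped from the PCA and recorded — a new run's
deviation on a dropped feature is added to the SPE as its squared
deviation from the NOC constant over a floor standard deviation (1e-8), a
documented implementation convention. PCA is computed by SVD;
k = min(`n_pcs`, rank) components (default 3) are kept, and each
component's sign is fixed by making its largest-magnitude loading
positive, so loadings and contributions are identical across refits.
λᵢ are the NOC score sample variances (n−1 denominator).

* **T² limit** (new-observation form):
  k(n−1)(n+1)/(n(n−k)) · F₁₋α(k, n−k), which tends to the χ²(k) quantile
  for large n.
* **SPE limit**: moment-matched scaled chi-square g·χ²₁₋α(h) with
  g = v/(2m), h = 2m²/v from the mean and variance of NOC SPE values.
  Critically, those SPE values are *held-out*: deterministic strided
  7-fold refits score each NOC row with a model fitted without it.
  Training-row residuals understate new-observation error whenever the
  feature count is a sizeable fraction of the row count (28 features on
  100 rows: ~17 % low, which quadruples the false-rejection rate); the
  cross-validated variant restores the nominal level. With very small NOC
  the fold count shrinks (min 2, at most n/3 folds).

α per test is `alpha_initial` / (2 × available blocks) under the default
Bonferroni correction (0.05/6 = 0.00833 with all three blocks; the
denominator follows the tests actually run when a block lacks a model).
The correction can be disabled, which lowers the thresholds and raises the
Type I rate — useful only when missed faults are costlier than false
alarms. A block flags when **both** T² and SPE reject (default; an OR rule
is configurable), and a run is out of control when any block flags.
Contributions per feature and PC are score × loading.

At small n the T² limit becomes very large (the F factor blows up as
n → k), so multivariate sensitivity is poor right after the minimum NOC
size is reached — expected behaviour, not a defect.

## MS² confirmation

One JSON library entry per compound, filename stem equal to the
identifier (mismatches are rejected). The DDA spectrum whose precursor is
within ±`eic_ppm` of the theoretical m/z and whose time is nearest the
apex inside the ±9 s window is compared by binned cosine similarity —
floor binning from 0 with 0.5 Da bins, raw intensities, plain dot product
— and by counting library fragments with an acquired fragment within
±`ms2_fragment_tol` (default 0.01 Da; greedy nearest one-to-one pairing,
so the count never exceeds the smaller list). DIA/SWATH spectra are parsed
but never used for library checks. Absent DDA events or library entries
simply skip the check.

## File handling and persistence

mzML 1.1 is read with a compact cvParam-driven lxml reader (32/64-bit
float arrays, zlib or no compression; profile-mode spectra are rejected
with a clear error), mzXML via pyteomics. Vendor conversion is external:
point the converter's output at the watched folder. A file is processed
once it has not been modified for `quiet_period` (default 120 s, boundary
inclusive); unreadable files are skipped and retried next cycle. Sample
types come from filename tokens (`blank`, `standard`/`_std`), a
convention, configurable. Results live in a single-file SQLite store
(runs, per-standard results, verdicts, MSPC statistics *with their
limits*, MS² outcomes); re-recording a run replaces its rows atomically.
Alerts are text + JSON documents in an outbox folder; MSPC-only anomalies
are labelled advisory. The per-standard CSV export re-imports through a
header-tolerant shim, and export → import → re-evaluate reproduces every
verdict category exactly.

## Synthetic batches

The simulator generates what the QC engine assumes and nothing more:
MS1 scans every 0.5 s over a 900 s gradient, one centroid per compound per
scan, Gaussian peaks (σ = 3 s) of base height 1e5 counts on a 500-count
baseline with white noise (σ = 200). Run-to-run variation: log-normal
per-standard height factors (cv 10 %), retention jitter (σ = 1 s), and a
per-run per-standard mass bias (σ = 0.15 ppm) plus per-scan centroid
jitter (σ = 0.3 ppm) — together ≈ 0.2 ppm run-to-run measured mass error,
the reproducibility of a lock-mass-corrected QTOF; a noisier mass axis
would make sub-2-ppm anomalies statistically invisible, which contradicts
how such faults present on real instruments. Each run's stream is seeded
from (seed, injection index), so batches are bitwise reproducible and
order-independent.

Fault scenarios reproduce recognised failure signatures: `hv_failure`
attenuates standards above a pivot m/z (down to 0.3× at the heaviest,
linearly interpolated) and boosts lighter ones 1.5×; `pump_drift` shifts
retention times later by (i/n)·30 s at the earliest eluter, scaled down to
0.5× for the latest; `ac_mass_bias` adds N(+1.3, 0.3) ppm to every
standard's mass error; `post_maintenance_gain` multiplies all heights by
2.5. The first injection of a batch is a blank by default.

What the simulator does **not** emulate: peak tailing and saturation,
matrix interferences and isobaric co-elution, DIA spectra, intensity
drifts within a run, correlated mass-error structure beyond the scenario
shifts. Passing scenario tests therefore demonstrates that each fault
class is routed to the intended control layer under clean chromatography —
not that detection rates transfer quantitatively to any particular
instrument or matrix.

## Problem sizes and determinism

The test suite and the acceptance script process a 60- and 100-injection
in-control history respectively through the full raw-signal pipeline and
one 25-injection batch per scenario (34 for the mass-bias case, a
realistic batch size for that fault class) — large enough for stable
60-day medians and a 3-PC NOC model, small enough to run comfortably on a
laptop. All randomness flows from explicit seeds; hypothesis profiles are
derandomised.

## Known limitations

* One uniform RT shift per blank; nonlinear or per-compound drift is out
  of scope.
* No peak-area integration or co-elution deconvolution — height is the
  deliberate choice for unattended operation.
* MSPC alarms need interpretation (contributions help, but translating a
  T² exceedance into "the mass error moved by x ppm" is not direct).
* TIC level and blank contamination are not monitored.
* Email/dashboard delivery is out of scope; alerts are files, the store is
  plain SQLite.
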