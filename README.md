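# hrmsqc — near real-time QC for internal-standardised LC-HRMS

Routine LC-HRMS screening (environmental surveillance, clinical panels,
non-target workflows) typically discovers instrument trouble only at
post-acquisition review, after a fault has wasted days of runtime and
irreplaceable samples. `hrmsqc` closes that gap: it watches an acquisition
folder, measures every isotopically labelled internal standard in each new
run, checks the results against the laboratory's own recent behaviour, and
raises an alert on the first bad injection. It is written for operators of
internal-standardised LC-HRMS methods — if every injection carries a fixed
set of labelled standards, the package needs nothing else about the assay.

## What it computes

For each internal standard in each run, three quality metrics from the
raw MS1 scan stream:

* **Peak height** above a local baseline, from an extracted-ion
  chromatogram at exact mass ±20 ppm, smoothed twice with a quadratic
  five-point Savitzky–Golay filter. A peak is accepted when S/N > 5 and at
  least 5 EIC points lie above baseline + 2·noise, with noise taken as the
  smaller (max − min) of two 15 s windows flanking the peak.
* **Retention time** of the apex, after a uniform drift correction: the
  median deviation of all standards in the most recent blank.
* **Mass error** in ppm, from the mean m/z of the five spectra around the
  apex.

Two control layers then act on these metrics:

**Univariate limits** against rolling 60-day expectations — normalised
intensity `h / median₆₀(h)` must stay in [0.5, 2.0], retention-time
deviation from the 60-day median within ±10 s, mass error within ±10 ppm,
and every standard must be detected at all. Each failing run is
categorised (height / retention time / mass error / multiple / missing
standard) for fault bookkeeping.

**Multivariate statistical process control (MSPC)** for the faults no
single limit can see. Heights and retention times are converted to pair
ratios, R = v_i / (v_i + v_j) over all p(p−1)/2 standard pairs, which
cancels common multiplicative shifts; mass errors enter raw. Per block a
PCA model (3 PCs) is fitted to the *normal operating conditions* — the
QC-passing runs of the rolling window — and each new run is autoscaled and
projected. Hotelling's T² = Σ tᵢ²/λᵢ (D-statistic) tests the model
subspace; the squared prediction error SPE = ‖x − x̂‖² (Q-statistic) tests
the residual. Limits are set at α = 0.05/6 = 0.00833 (Bonferroni over two
statistics × three blocks); a run is out of control when both statistics
reject in any block. Per-feature contributions (score × loading) point to
the standards driving an alarm.

Everything is persisted in an embedded SQLite store, alerts are rendered
as text + JSON documents, and the per-standard table exports to CSV for
retrospective reanalysis. A bundled batch simulator generates realistic
multi-injection batches — including detector high-voltage failure, pump
retention drift, sub-threshold mass bias and post-maintenance gain
scenarios — so the entire chain is testable without instrument data.

## Worked example

`examples/03_mspc_walkthrough.py` fits the control models on a 30-run
in-control history and projects one clean and one mass-biased run:

```
height        : n=30, 3 PCs explain 63% | T2 limit 16.0, SPE limit 54.7 (alpha=0.00833)
retention_time: n=30, 3 PCs explain 67% | T2 limit 16.0, SPE limit 71.6 (alpha=0.00833)
mass_error    : n=30, 3 PCs explain 55% | T2 limit 16.0, SPE limit 24.7 (alpha=0.00833)
in-control  : mass errors -0.40..+0.23 ppm | T2     2.7 (limit 16.0), SPE    2.8 (limit 24.7) -> in control
mass-biased : mass errors +0.55..+1.49 ppm | T2    48.4 (limit 16.0), SPE  222.6 (limit 24.7) -> OUT OF CONTROL
```

The biased run's mass errors never approach the ±10 ppm univariate limit,
yet both the D- and Q-statistics reject decisively — the signature of an
instrument-wide calibration shift (e.g. a lab temperature excursion) caught
while the batch is still running. The other examples walk through peak
measurement (`02`), a full batch with a detector fault (`01`), MS² library
confirmation (`04`) and table reanalysis (`05`); each prints the numbers it
computes and a line on what they mean.

A thin CLI wraps the same library:

```bash
hrmsqc simulate batch/ --scenario hv_failure --seed 7   # synthetic mzML batch
hrmsqc process batch/ --store results.sqlite            # one polling cycle
hrmsqc watch acquisition/ --interval 60                 # continuous watcher
hrmsqc reanalyse internal_standard_table.csv            # retrospective counts
```

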