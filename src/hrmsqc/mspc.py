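"""Multivariate statistical process control (MSPC) on internal standards.

Three parameter blocks are monitored per run: peak height, retention time
and mass error. Height and retention time are first transformed to
pairwise ratios R = v_i / (v_i + v_j) over all unique internal-standard
pairs, which cancels any common multiplicative shift (a detector gain step
moves every height by the same factor and leaves every ratio untouched);
mass errors enter raw, per standard. For each block a PCA model is fitted
to the "normal operating conditions" (NOC): QC-passing sample runs from
the rolling window with all required internal standards detected. New runs
are autoscaled with the NOC statistics and projected; Hotelling's T2
(D-statistic) tests for systematic shifts inside the model subspace and
the squared prediction error (SPE, Q-statistic) for deviations outside it.
Both limits are set at a Bonferroni-corrected significance (six tests per
run by default: two statistics times three blocks). A run is out of
control when, in any block, both statistics reject (the default rule; an
OR rule is available).

Missing values (undetected standards) are set to zero before ratio
formation and autoscaling — a zero height or retention time is maximally
anomalous, so such runs are flagged rather than silently repaired. They
can never contaminate the NOC, which only admits complete runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .config import QCConfig
from .peak_metrics import PeakMeasurement
from .univariate import HistoryStore

__all__ = [
    "BLOCKS",
    "RatioFeatureVector",
    "NOCModel",
    "BlockResult",
    "MSPCResult",
    "pairwise_ratios",
    "block_raw_values",
    "block_features",
    "build_noc",
    "fit_block_model",
    "project_sample",
    "evaluate_mspc",
    "t2_limit_f",
    "spe_limit_chi2",
]

Block = Literal["height", "retention_time", "mass_error"]
BLOCKS: tuple[Block, ...] = ("height", "retention_time", "mass_error")

_ZERO_VAR_TOL = 1e-12
_FLOOR_SD = 1e-8


@dataclass
class RatioFeatureVector:
    """Feature vector for one run and block: pair ratios or raw ppm values."""

    block: Block
    feature_names: list[str]
    values: np.ndarray


def pairwise_ratios(
    values: Sequence[float], names: Sequence[str]
) -> tuple[list[str], np.ndarray]:
    """R = v_i / (v_i + v_j) for each unordered pair (i < j, list order).

    Only one orientation is stored — the complementary ratio is affinely
    dependent (R(i,j) + R(j,i) = 1). Both inputs zero gives R = 0, which
    keeps a fully missing pair maximally anomalous rather than neutral.
    """
    v = np.asarray(values, dtype=float)
    p = v.size
    out_names: list[str] = []
    out: list[float] = []
    for i in range(p):
        for j in range(i + 1, p):
            denom = v[i] + v[j]
            out.append(v[i] / denom if denom != 0 else 0.0)
            out_names.append(f"R({names[i]},{names[j]})")
    return out_names, np.array(out)


def block_raw_values(
    measurements: Mapping[str, PeakMeasurement] | Sequence[PeakMeasurement],
    is_order: Sequence[str],
    block: Block,
) -> np.ndarray:
    """Raw per-standard values for a block, in compound-list order.

    Undetected standards (or missing mass errors) contribute 0.
    """
    if not isinstance(measurements, Mapping):
        measurements = {m.compound_id: m for m in measurements}
    out = np.zeros(len(is_order))
    for i, cid in enumerate(is_order):
        m = measurements.get(cid)
        if m is None or not m.detected:
            continue
        if block == "height":
            out[i] = m.height
        elif block == "retention_time":
            out[i] = m.apex_rt if m.apex_rt is not None else 0.0
        elif block == "mass_error":
            out[i] = m.mass_error if m.mass_error is not None else 0.0
        else:
            raise ValueError(f"unknown block {block!r}")
    return out


def block_features(
    measurements: Mapping[str, PeakMeasurement] | Sequence[PeakMeasurement],
    is_order: Sequence[str],
    block: Block,
) -> RatioFeatureVector:
    """Feature vector for one run: pair ratios for height and retention
    time, raw ppm per standard for mass error."""
    raw = block_raw_values(measurements, is_order, block)
    if block in ("height", "retention_time"):
        names, vals = pairwise_ratios(raw, is_order)
    else:
        names, vals = list(is_order), raw
    return RatioFeatureVector(block=block, feature_names=names, values=vals)


def build_noc(
    history: HistoryStore,
    at: datetime,
    cfg: QCConfig,
    is_order: Sequence[str],
) -> dict[Block, tuple[np.ndarray, list[str]] | None]:
    """Assemble per-block NOC matrices from the rolling history.

    Rows are QC-passing sample runs in [at - window, at) with at least
    ``cfg.min_is_per_polarity`` (default: all) internal standards detected;
    runs previously flagged out of control by MSPC are excluded too, so a
    sustained fault cannot drift into its own reference window.
    Height and retention-time rows are ratio-transformed; mass-error rows
    are the raw per-standard ppm values. A block with fewer than
    ``cfg.min_noc`` rows returns None — MSPC then defers to univariate QC.
    """
    min_is = cfg.min_is_per_polarity or len(is_order)
    df = history.window(at, cfg.rolling_window_days)
    out: dict[Block, tuple[np.ndarray, list[str]] | None] = {b: None for b in BLOCKS}
    rows_by_block: dict[Block, list[np.ndarray]] = {b: [] for b in BLOCKS}
    names_by_block: dict[Block, list[str]] = {}
    if not df.empty:
        df = df[
            (df["sample_type"] == "sample") & df["qc_pass"] & ~df["mspc_flag"]
            & df["detected"] & (df["n_detected"] >= min_is)
        ]
        for _run_id, grp in df.groupby("run_id", sort=False):
            by_cid = {r.compound_id: r for r in grp.itertuples()}
            if any(c not in by_cid for c in is_order):
                continue
            heights = np.array([by_cid[c].height for c in is_order], dtype=float)
            rts = np.array([by_cid[c].apex_rt for c in is_order], dtype=float)
            errs = np.array([by_cid[c].mass_error for c in is_order], dtype=float)
            if np.isnan(heights).any() or np.isnan(rts).any():
                continue
            errs = np.nan_to_num(errs, nan=0.0)
            h_names, h_vals = pairwise_ratios(heights, is_order)
            r_names, r_vals = pairwise_ratios(rts, is_order)
            rows_by_block["height"].append(h_vals)
            rows_by_block["retention_time"].append(r_vals)
            rows_by_block["mass_error"].append(errs)
            names_by_block.setdefault("height", h_names)
            names_by_block.setdefault("retention_time", r_names)
            names_by_block.setdefault("mass_error", list(is_order))
    for b in BLOCKS:
        rows = rows_by_block[b]
        if len(rows) >= cfg.min_noc:
            out[b] = (np.vstack(rows), names_by_block[b])
    return out


@dataclass
class NOCModel:
    """Fitted per-block PCA control model.

    ``loadings`` has orthonormal columns (one per retained PC) over the
    kept (non-constant) features; ``score_variances`` are the NOC score
    sample variances used in the T2 metric. Features with zero NOC
    variance are dropped from the model and listed in ``dropped`` with
    their constant value; a new run's deviation on such a feature enters
    the SPE directly, scaled by a floor standard deviation.
    """

    block: Block
    n_samples: int
    feature_names: list[str]          # kept features, model order
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray              # (p_kept, k)
    score_variances: np.ndarray       # (k,)
    explained_variance: float
    t2_limit: float
    spe_limit: float
    alpha_corrected: float
    dropped: list[tuple[str, float]] = field(default_factory=list)
    all_feature_names: list[str] = field(default_factory=list)
    window_start: datetime | None = None
    window_end: datetime | None = None
    floor_sd: float = _FLOOR_SD

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_dict(self) -> dict:
        d = {
            "block": self.block,
            "n_samples": self.n_samples,
            "feature_names": self.feature_names,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "score_variances": self.score_variances.tolist(),
            "explained_variance": self.explained_variance,
            "t2_limit": self.t2_limit,
            "spe_limit": self.spe_limit,
            "alpha_corrected": self.alpha_corrected,
            "dropped": [[n, v] for n, v in self.dropped],
            "all_feature_names": self.all_feature_names,
            "window_start": self.window_start.isoformat() if self.window_start else None,
            "window_end": self.window_end.isoformat() if self.window_end else None,
            "floor_sd": self.floor_sd,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NOCModel":
        return cls(
            block=d["block"],
            n_samples=d["n_samples"],
            feature_names=list(d["feature_names"]),
            means=np.array(d["means"]),
            sds=np.array(d["sds"]),
            loadings=np.array(d["loadings"]),
            score_variances=np.array(d["score_variances"]),
            explained_variance=d["explained_variance"],
            t2_limit=d["t2_limit"],
            spe_limit=d["spe_limit"],
            alpha_corrected=d["alpha_corrected"],
            dropped=[(n, v) for n, v in d.get("dropped", [])],
            all_feature_names=list(d.get("all_feature_names", d["feature_names"])),
            window_start=(
                datetime.fromisoformat(d["window_start"]) if d.get("window_start") else None
            ),
            window_end=(
                datetime.fromisoformat(d["window_end"]) if d.get("window_end") else None
            ),
            floor_sd=d.get("floor_sd", _FLOOR_SD),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "NOCModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def t2_limit_f(n: int, k: int, alpha: float) -> float:
    """Upper control limit of T2 for a NEW observation projected onto a PCA
    model fitted on n NOC rows with k components:

        k (n - 1)(n + 1) / (n (n - k)) * F_{1-alpha}(k, n - k).

    Approaches the chi-square(k) quantile for large n.
    """
    if n <= k:
        raise ValueError(f"need n > k for the T2 limit (n={n}, k={k})")
    factor = k * (n - 1) * (n + 1) / (n * (n - k))
    return float(factor * stats.f.ppf(1.0 - alpha, k, n - k))


def cross_validated_spe(X_raw: np.ndarray, k: int, n_folds: int = 7) -> np.ndarray:
    """Held-out SPE for every NOC row via strided K-fold refits.

    Training-row residuals systematically understate the prediction error
    of new observations (the fitted subspace partly chases the training
    noise, appreciably so when the feature count is a sizeable fraction of
    the row count), which would place the SPE limit too low. Refitting the
    autoscaling and PCA without each fold and scoring the held-out rows
    yields an honest sample of the in-control SPE distribution. Folds are
    strided and deterministic.
    """
    n, p = X_raw.shape
    n_folds = max(2, min(n_folds, n // 3))
    idx = np.arange(n)
    out = np.empty(n)
    for f in range(n_folds):
        test = idx[f::n_folds]
        train = np.setdiff1d(idx, test)
        Xt = X_raw[train]
        m = Xt.mean(axis=0)
        s = Xt.std(axis=0, ddof=1)
        s = np.where(s > _ZERO_VAR_TOL, s, 1.0)
        Xs = (Xt - m) / s
        _U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
        kk = min(k, int(np.sum(S > (S[0] * max(Xs.shape) * np.finfo(float).eps))))
        P = Vt[:max(kk, 1)].T
        Y = (X_raw[test] - m) / s
        R = Y - (Y @ P) @ P.T
        out[test] = (R ** 2).sum(axis=1)
    return out


def spe_limit_chi2(noc_spe: np.ndarray, alpha: float) -> float:
    """Moment-matched scaled chi-square upper limit for the SPE:
    g * chi2_{1-alpha}(h) with g = v/(2m), h = 2 m^2 / v where m, v are the
    mean and variance of the NOC SPE values (use held-out values from
    :func:`cross_validated_spe` so the limit reflects new observations).
    Degenerate NOC SPE (all ~0, e.g. when the model spans the full rank)
    yields a near-zero limit."""
    m = float(np.mean(noc_spe))
    v = float(np.var(noc_spe, ddof=1)) if noc_spe.size > 1 else 0.0
    if m <= 0 or v <= 0:
        return _FLOOR_SD
    g = v / (2.0 * m)
    h = 2.0 * m * m / v
    return float(g * stats.chi2.ppf(1.0 - alpha, h))


def fit_block_model(
    noc_matrix: np.ndarray,
    feature_names: Sequence[str],
    cfg: QCConfig,
    block: Block = "height",
    alpha_corrected: float | None = None,
    window: tuple[datetime, datetime] | None = None,
) -> NOCModel:
    """Autoscale the NOC matrix, fit PCA by SVD and set both control limits.

    Keeps k = min(cfg.n_pcs, rank) components (reduction is recorded by the
    returned model's shape). PC signs are fixed by making the
    largest-magnitude loading of each component positive, so contributions
    are deterministic across refits.
    """
    X = np.asarray(noc_matrix, dtype=float)
    n, p = X.shape
    alpha = cfg.alpha_corrected if alpha_corrected is None else alpha_corrected
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    keep = sds > _ZERO_VAR_TOL
    dropped = [(feature_names[i], float(means[i])) for i in np.flatnonzero(~keep)]
    Xk = (X[:, keep] - means[keep]) / sds[keep]
    U, S, Vt = np.linalg.svd(Xk, full_matrices=False)
    tol = S[0] * max(n, Xk.shape[1]) * np.finfo(float).eps if S.size else 0.0
    rank = int(np.sum(S > tol))
    k = max(1, min(cfg.n_pcs, rank))
    P = Vt[:k].T.copy()
    for j in range(k):
        i_max = int(np.argmax(np.abs(P[:, j])))
        if P[i_max, j] < 0:
            P[:, j] = -P[:, j]
    scores = Xk @ P
    lambdas = scores.var(axis=0, ddof=1)
    total_var = Xk.shape[1]  # autoscaled columns have unit variance
    explained = float(lambdas.sum() / total_var) if total_var else 0.0
    t2_lim = t2_limit_f(n, k, alpha)
    noc_spe = cross_validated_spe(X[:, keep], k)
    spe_lim = spe_limit_chi2(noc_spe, alpha)
    return NOCModel(
        block=block,
        n_samples=n,
        feature_names=[feature_names[i] for i in np.flatnonzero(keep)],
        means=means[keep],
        sds=sds[keep],
        loadings=P,
        score_variances=lambdas,
        explained_variance=explained,
        t2_limit=t2_lim,
        spe_limit=spe_lim,
        alpha_corrected=alpha,
        dropped=dropped,
        all_feature_names=list(feature_names),
        window_start=window[0] if window else None,
        window_end=window[1] if window else None,
    )


@dataclass
class BlockResult:
    """T2 / SPE outcome of projecting one run onto one block model."""

    block: Block
    t2: float
    spe: float
    t2_limit: float
    spe_limit: float
    t2_reject: bool
    spe_reject: bool
    scores: np.ndarray
    contributions: np.ndarray  # (k, p_kept): score_i * loading_{feature, i}
    feature_names: list[str]


def project_sample(
    features: RatioFeatureVector | np.ndarray,
    model: NOCModel,
) -> BlockResult:
    """Project one run's feature vector onto a fitted NOC model.

    The vector must be aligned to ``model.all_feature_names`` (as produced
    by :func:`block_features` with the same compound order). Missing raw
    values must already be zero-imputed. T2 sums squared scores over the
    NOC score variances; SPE is the squared residual norm, plus the
    floor-scaled squared deviation on any feature that was constant in the
    NOC.
    """
    x = features.values if isinstance(features, RatioFeatureVector) else np.asarray(features, float)
    by_name = dict(zip(model.all_feature_names, x))
    xk = np.array([by_name[nm] for nm in model.feature_names])
    xs = (xk - model.means) / model.sds
    t = xs @ model.loadings
    t2 = float(np.sum(t * t / model.score_variances))
    xhat = model.loadings @ t
    resid = xs - xhat
    spe = float(resid @ resid)
    for name, const in model.dropped:
        dev = (by_name[name] - const) / max(model.floor_sd, _FLOOR_SD)
        spe += float(dev * dev)
    contributions = t[:, None] * model.loadings.T  # (k, p_kept)
    return BlockResult(
        block=model.block,
        t2=t2,
        spe=spe,
        t2_limit=model.t2_limit,
        spe_limit=model.spe_limit,
        t2_reject=t2 > model.t2_limit,
        spe_reject=spe > model.spe_limit,
        scores=t,
        contributions=contributions,
        feature_names=list(model.feature_names),
    )


@dataclass
class MSPCResult:
    """Per-run MSPC outcome across parameter blocks."""

    run_id: str
    blocks: dict[str, BlockResult]
    flagged_blocks: list[str]
    out_of_control: bool
    rule: str = "and"


def evaluate_mspc(
    measurements: Mapping[str, PeakMeasurement] | Sequence[PeakMeasurement],
    models: Mapping[str, NOCModel],
    cfg: QCConfig,
    is_order: Sequence[str],
    run_id: str = "",
) -> MSPCResult:
    """Project one run onto all available block models and combine.

    Default decision rule: a block flags when BOTH T2 and SPE reject; the
    run is out of control when any block flags. The OR rule
    (``cfg.mspc_rule = "or"``) flags on either statistic. Blocks without a
    model (insufficient NOC) are skipped; the Bonferroni correction used
    when fitting should already reflect the number of tests actually run
    (two per available block).
    """
    block_results: dict[str, BlockResult] = {}
    flagged: list[str] = []
    for b in BLOCKS:
        model = models.get(b)
        if model is None:
            continue
        feats = block_features(measurements, is_order, b)
        res = project_sample(feats, model)
        block_results[b] = res
        hit = (res.t2_reject and res.spe_reject) if cfg.mspc_rule == "and" \
            else (res.t2_reject or res.spe_reject)
        if hit:
            flagged.append(b)
    return MSPCResult(
        run_id=run_id,
        blocks=block_results,
        flagged_blocks=flagged,
        out_of_control=bool(flagged),
        rule=cfg.mspc_rule,
    )
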