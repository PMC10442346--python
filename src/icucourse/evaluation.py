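"""Model and information evaluation.

Covers the study's evaluation machinery: repeated stratified nested
cross-validation partitions (20 repeats x 5 folds), ordinal discrimination
via Somers' Dxy (interpreted as the proportion of ordinal outcome variation
explained by model output), reliability via logistic-recalibration
calibration slope and smoothed calibration curves, bootstrap
bias-corrected cross-validation (BBC-CV) intervals over candidate
configurations, and time-resolved metric series aligned both from ICU
admission and backwards from discharge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .trajectory_model import Trajectory

MIN_PATIENTS_PER_TIMEPOINT = 50


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------


@dataclass
class FoldAssignment:
    repeat: int
    fold: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class PartitionScheme:
    repeats: int
    folds: int
    assignments: list[FoldAssignment] = field(default_factory=list)

    def cells(self):
        return self.assignments


def make_partitions(
    outcomes: np.ndarray,
    repeats: int = 20,
    folds: int = 5,
    val_fraction: float = 0.15,
    seed: int = 0,
) -> PartitionScheme:
    """Repeated stratified k-fold partitions with nested validation sets.

    Per (repeat, fold): a disjoint test set stratified by outcome category,
    and a validation set stratified within the remaining training patients.
    Deterministic given the seed.
    """
    from sklearn.model_selection import StratifiedKFold, train_test_split

    outcomes = np.asarray(outcomes)
    counts = np.bincount(outcomes)
    too_few = [int(c) for c in np.unique(outcomes) if counts[c] < folds]
    if too_few:
        raise ValueError(
            f"outcome categories {too_few} have fewer patients than folds={folds}"
        )
    scheme = PartitionScheme(repeats=repeats, folds=folds)
    idx = np.arange(len(outcomes))
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        for fold, (rest, test) in enumerate(skf.split(idx, outcomes)):
            # stratify the nested validation split when feasible (enough
            # patients per category for both sides), else plain shuffle
            cats = np.unique(outcomes[rest])
            n_val = max(int(round(len(rest) * val_fraction)), 1)
            feasible = (
                np.min(np.bincount(outcomes[rest])[cats]) >= 2
                and n_val >= len(cats)
                and len(rest) - n_val >= len(cats)
            )
            train, val = train_test_split(
                rest,
                test_size=val_fraction,
                random_state=seed * 1000 + rep * folds + fold,
                stratify=outcomes[rest] if feasible else None,
            )
            scheme.assignments.append(
                FoldAssignment(
                    repeat=rep,
                    fold=fold,
                    train_idx=np.sort(train),
                    val_idx=np.sort(val),
                    test_idx=np.sort(test),
                )
            )
    return scheme


# ---------------------------------------------------------------------------
# Somers' Dxy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DxyResult:
    value: float | None
    reason: str | None = None

    def __float__(self) -> float:
        if self.value is None:
            raise ValueError(f"Dxy undefined: {self.reason}")
        return self.value


def somers_dxy(scores, outcomes) -> DxyResult:
    """Somers' Dxy of the ordinal outcome given a scalar model score.

    Over all patient pairs with different outcomes:
    ``(concordant - discordant) / (concordant + discordant + score_ties)``,
    i.e. twice the usable-pair concordance index minus one.  Pairs tied on
    outcome are excluded; pairs tied on score count in the denominator.
    """
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes)
    if len(scores) != len(outcomes):
        raise ValueError("scores and outcomes length mismatch")
    if len(np.unique(outcomes)) < 2:
        return DxyResult(None, "all outcomes identical; no usable pairs")
    if np.ptp(scores) == 0:
        # every usable pair is a score tie: (C - D) / (C + D + T) = 0
        return DxyResult(0.0)
    res = stats.somersd(outcomes, scores)
    return DxyResult(float(res.statistic))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

PROB_CLIP = 1e-6


@dataclass(frozen=True)
class CalibrationResult:
    slope: float | None
    reason: str | None = None


def calibration_slope(threshold_probs, binary_outcomes) -> CalibrationResult:
    """Slope of a logistic recalibration of outcome on logit(predicted q).

    Slope < 1 indicates overfitting (predictions too extreme); slope > 1
    underfitting.  Probabilities are clipped away from {0, 1} before the
    logit.  A single-class outcome or a constant predictor makes the slope
    undefined and is reported as missing with a reason.
    """
    import statsmodels.api as sm

    q = np.clip(np.asarray(threshold_probs, float), PROB_CLIP, 1 - PROB_CLIP)
    y = np.asarray(binary_outcomes, int)
    if len(np.unique(y)) < 2:
        return CalibrationResult(None, "single-class outcome at this cut")
    lo = np.log(q / (1 - q))
    if np.ptp(lo) < 1e-12:
        return CalibrationResult(None, "constant predictions; slope undefined")
    X = sm.add_constant(lo)
    try:
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    except Exception as exc:  # pragma: no cover - defensive
        return CalibrationResult(None, f"recalibration fit failed: {exc}")
    return CalibrationResult(float(fit.params[1]))


def mean_calibration_slope(threshold_probs, outcome_indices) -> float | None:
    """Per-timepoint summary: slope averaged over the six outcome cuts."""
    q = np.asarray(threshold_probs)  # (n, 6)
    y = np.asarray(outcome_indices)
    slopes = []
    for k in range(q.shape[1]):
        res = calibration_slope(q[:, k], (y > k).astype(int))
        if res.slope is not None:
            slopes.append(res.slope)
    return float(np.mean(slopes)) if slopes else None


@dataclass
class CalibrationCurve:
    grid: np.ndarray  # predicted-probability grid within observed range
    observed: np.ndarray  # smoothed observed frequency at each grid point
    mace: float  # mean absolute error vs the diagonal


def calibration_curve(
    threshold_probs, binary_outcomes, span: float = 0.75, n_grid: int = 101
) -> CalibrationCurve:
    """Locally smoothed observed-vs-predicted curve and its mean absolute
    deviation from the perfect-calibration diagonal.

    Uses a local-linear (LOWESS) smoother over the observed prediction
    range; for very small samples the span widens to cover enough points.
    """
    import statsmodels.api as sm
    import warnings

    q = np.clip(np.asarray(threshold_probs, float), PROB_CLIP, 1 - PROB_CLIP)
    y = np.asarray(binary_outcomes, float)
    n = len(q)
    if n * span < 20:
        span = min(1.0, 20 / max(n, 1))
        warnings.warn(
            f"sample too small for requested span; widened to {span:.2f}",
            stacklevel=2,
        )
    lo_v, hi_v = float(q.min()), float(q.max())
    grid = np.linspace(lo_v, hi_v, n_grid)
    if hi_v - lo_v < 1e-9:
        obs = np.full(n_grid, y.mean())
    else:
        sm_xy = sm.nonparametric.lowess(
            y, q, frac=span, it=0, xvals=grid, return_sorted=False
        )
        obs = np.clip(np.asarray(sm_xy, float), 0.0, 1.0)
    mace = float(np.mean(np.abs(obs - grid)))
    return CalibrationCurve(grid=grid, observed=obs, mace=mace)


# ---------------------------------------------------------------------------
# BBC-CV
# ---------------------------------------------------------------------------


@dataclass
class BBCResult:
    estimate: float
    ci_lo: float
    ci_hi: float
    naive_best: float
    n_redrawn: int
    best_config_counts: np.ndarray


def bbc_cv_interval(
    config_scores: np.ndarray,
    outcomes: np.ndarray,
    metric_fn=None,
    n_boot: int = 1000,
    seed: int = 0,
    higher_is_better: bool = True,
) -> BBCResult:
    """Bootstrap bias-corrected cross-validation over configurations.

    ``config_scores`` is (n_patients, n_configs) of pooled out-of-fold
    scalar predictions, one column per candidate configuration.  Each
    bootstrap resample selects the best configuration on the in-bag
    patients and evaluates it on the out-of-bag patients, correcting the
    optimism of "pick best, evaluate on the same data".  Resamples whose
    out-of-bag set cannot support the metric are redrawn (counted).
    """
    if metric_fn is None:
        def metric_fn(s, y):
            r = somers_dxy(s, y)
            return r.value
    scores = np.atleast_2d(np.asarray(config_scores, float))
    if scores.shape[0] == len(outcomes):
        pass
    elif scores.shape[1] == len(outcomes):
        scores = scores.T
    outcomes = np.asarray(outcomes)
    n, n_cfg = scores.shape
    rng = np.random.default_rng(seed)
    full_metrics = np.array(
        [metric_fn(scores[:, c], outcomes) for c in range(n_cfg)], dtype=float
    )
    naive_best = float(np.nanmax(full_metrics) if higher_is_better
                       else np.nanmin(full_metrics))
    oob_vals = []
    counts = np.zeros(n_cfg, dtype=int)
    n_redrawn = 0
    draws = 0
    while len(oob_vals) < n_boot and draws < 20 * n_boot:
        draws += 1
        inbag = rng.integers(0, n, size=n)
        oob_mask = np.ones(n, bool)
        oob_mask[inbag] = False
        oob = np.nonzero(oob_mask)[0]
        if len(oob) < 2 or len(np.unique(outcomes[oob])) < 2 or len(
            np.unique(outcomes[inbag])
        ) < 2:
            n_redrawn += 1
            continue
        in_metrics = [
            metric_fn(scores[inbag, c], outcomes[inbag]) for c in range(n_cfg)
        ]
        in_metrics = np.array(
            [np.nan if v is None else v for v in in_metrics], float
        )
        best = (
            int(np.nanargmax(in_metrics))
            if higher_is_better
            else int(np.nanargmin(in_metrics))
        )
        counts[best] += 1
        val = metric_fn(scores[oob, best], outcomes[oob])
        if val is None:
            n_redrawn += 1
            continue
        oob_vals.append(val)
    oob_vals = np.asarray(oob_vals)
    return BBCResult(
        estimate=float(oob_vals.mean()),
        ci_lo=float(np.percentile(oob_vals, 2.5)),
        ci_hi=float(np.percentile(oob_vals, 97.5)),
        naive_best=naive_best,
        n_redrawn=n_redrawn,
        best_config_counts=counts,
    )


# ---------------------------------------------------------------------------
# Time-resolved metrics
# ---------------------------------------------------------------------------


@dataclass
class MetricPoint:
    timepoint_h: float
    alignment: str  # from_admission | to_discharge
    estimate: float
    ci_lo: float
    ci_hi: float
    n_patients: int


def _score_at(traj: Trajectory, window: int, score: str) -> float:
    if score == "expected_index":
        return float(traj.expected_index[window])
    raise ValueError(f"unknown score {score!r}")


def _collect(trajectories, alignment: str, offset: int, score: str):
    vals, ys = [], []
    for tr in trajectories:
        T = tr.n_windows
        if offset >= T:
            continue
        w = offset if alignment == "from_admission" else T - 1 - offset
        vals.append(_score_at(tr, w, score))
        ys.append(tr.outcome_index)
    return np.asarray(vals), np.asarray(ys)


def metric_timeseries(
    trajectories: list[Trajectory],
    window_h: int,
    metric: str = "dxy",
    alignment: str = "from_admission",
    horizon_h: float = 168.0,
    n_boot: int = 200,
    min_patients: int = MIN_PATIENTS_PER_TIMEPOINT,
    seed: int = 0,
    score: str = "expected_index",
) -> list[MetricPoint]:
    """Metric estimates with patient-level bootstrap CIs per window
    position over the first (or last) ``horizon_h`` hours of stay.

    Patients contribute only while still in ICU at the evaluated position;
    positions with fewer than ``min_patients`` contributors are suppressed.
    """
    rng = np.random.default_rng(seed)
    n_offsets = int(horizon_h // window_h)
    points: list[MetricPoint] = []

    def compute(vals, ys):
        if metric == "dxy":
            return somers_dxy(vals, ys).value
        raise ValueError(f"unknown metric {metric!r}")

    for off in range(n_offsets):
        vals, ys = _collect(trajectories, alignment, off, score)
        if len(vals) < min_patients:
            continue
        est = compute(vals, ys)
        if est is None:
            continue
        boot = []
        for _ in range(n_boot):
            bi = rng.integers(0, len(vals), len(vals))
            if len(np.unique(ys[bi])) < 2:
                continue
            b = compute(vals[bi], ys[bi])
            if b is not None:
                boot.append(b)
        lo, hi = (
            (np.percentile(boot, 2.5), np.percentile(boot, 97.5))
            if boot
            else (est, est)
        )
        t_h = (off + 1) * window_h if alignment == "from_admission" else -(
            off * window_h
        )
        points.append(
            MetricPoint(
                timepoint_h=float(t_h),
                alignment=alignment,
                estimate=float(est),
                ci_lo=float(min(lo, est)),
                ci_hi=float(max(hi, est)),
                n_patients=len(vals),
            )
        )
    return points


def metric_difference_timeseries(
    trajectories_a,
    trajectories_b,
    window_h: int,
    alignment: str = "from_admission",
    horizon_h: float = 168.0,
    n_boot: int = 200,
    min_patients: int = MIN_PATIENTS_PER_TIMEPOINT,
    seed: int = 0,
) -> list[MetricPoint]:
    """Dxy difference (A minus B) on the same remaining patients over time."""
    rng = np.random.default_rng(seed)
    by_id_b = {tr.patient_id: tr for tr in trajectories_b}
    n_offsets = int(horizon_h // window_h)
    points = []
    for off in range(n_offsets):
        va, ya, vb = [], [], []
        for tr in trajectories_a:
            other = by_id_b.get(tr.patient_id)
            if other is None or off >= tr.n_windows or off >= other.n_windows:
                continue
            wa = off if alignment == "from_admission" else tr.n_windows - 1 - off
            wb = off if alignment == "from_admission" else other.n_windows - 1 - off
            va.append(float(tr.expected_index[wa]))
            vb.append(float(other.expected_index[wb]))
            ya.append(tr.outcome_index)
        va, vb, ya = np.asarray(va), np.asarray(vb), np.asarray(ya)
        if len(va) < min_patients:
            continue
        da, db = somers_dxy(va, ya).value, somers_dxy(vb, ya).value
        if da is None or db is None:
            continue
        est = da - db
        boot = []
        for _ in range(n_boot):
            bi = rng.integers(0, len(va), len(va))
            if len(np.unique(ya[bi])) < 2:
                continue
            b1 = somers_dxy(va[bi], ya[bi]).value
            b2 = somers_dxy(vb[bi], ya[bi]).value
            if b1 is not None and b2 is not None:
                boot.append(b1 - b2)
        lo, hi = (
            (np.percentile(boot, 2.5), np.percentile(boot, 97.5))
            if boot
            else (est, est)
        )
        t_h = (off + 1) * window_h if alignment == "from_admission" else -(
            off * window_h
        )
        points.append(
            MetricPoint(
                timepoint_h=float(t_h),
                alignment=alignment,
                estimate=float(est),
                ci_lo=float(min(lo, est)),
                ci_hi=float(max(hi, est)),
                n_patients=len(va),
            )
        )
    return points


def metric_points_frame(points: list[MetricPoint], metric: str):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "metric": metric,
                "alignment": p.alignment,
                "timepoint_h": p.timepoint_h,
                "estimate": p.estimate,
                "ci_lo": p.ci_lo,
                "ci_hi": p.ci_hi,
                "n": p.n_patients,
            }
            for p in points
        ]
    )
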