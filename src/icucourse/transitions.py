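"""High-magnitude prognostic transitions.

A transition is a consecutive-window change in a threshold probability that
reaches the population's extreme percentiles for that threshold: at or
below the 1st percentile of negative differences (worsening) or at or
above the 99th percentile of positive differences (improvement).  Cut-offs
are computed per threshold on test-set trajectories pooled across
partitions, within a calibrated analysis region (default 10 h to 168 h
after admission).  Comparisons are inclusive at the cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort_io import N_THRESHOLDS
from .trajectory_model import Trajectory

DEFAULT_REGION_H = (10.0, 168.0)


@dataclass(frozen=True)
class AnalysisRegion:
    start_h: float = DEFAULT_REGION_H[0]
    end_h: float = DEFAULT_REGION_H[1]

    def window_in_region(self, t: int, window_h: float) -> bool:
        """True when the transition into window t lies inside the region.

        The transition between windows t-1 and t is stamped at the start of
        window t (t * window_h hours after admission).
        """
        time_h = t * window_h
        return self.start_h <= time_h <= self.end_h


@dataclass(frozen=True)
class TransitionEvent:
    patient_id: str
    window: int  # transition between window-1 and window
    threshold: int  # k in 1..6
    delta: float
    direction: str  # positive | negative

    @property
    def time_h(self) -> float | None:
        return None


@dataclass
class TransitionCutoffs:
    """Per-threshold extreme-percentile cut-offs on pooled deltas."""

    negative: np.ndarray  # (6,) 1st percentile of negative deltas (< 0)
    positive: np.ndarray  # (6,) 99th percentile of positive deltas (> 0)
    percentile: float = 99.0

    def defined(self, k: int) -> tuple[bool, bool]:
        return (
            bool(np.isfinite(self.negative[k - 1])),
            bool(np.isfinite(self.positive[k - 1])),
        )


def probability_differences(
    trajectories: list[Trajectory],
    window_h: float,
    region: AnalysisRegion = AnalysisRegion(),
):
    """Pool consecutive-window threshold-probability differences by sign.

    Returns (negatives, positives): two lists of 6 arrays, one per
    threshold, holding strictly negative / strictly positive deltas whose
    transition time falls in the analysis region.  Zeros are excluded.
    """
    negs = [[] for _ in range(N_THRESHOLDS)]
    poss = [[] for _ in range(N_THRESHOLDS)]
    for tr in trajectories:
        q = tr.threshold_probs
        for t in range(1, tr.n_windows):
            if not region.window_in_region(t, window_h):
                continue
            d = q[t] - q[t - 1]
            for k in range(N_THRESHOLDS):
                if d[k] < 0:
                    negs[k].append(d[k])
                elif d[k] > 0:
                    poss[k].append(d[k])
    return (
        [np.asarray(a) for a in negs],
        [np.asarray(a) for a in poss],
    )


def compute_cutoffs(
    negatives, positives, percentile: float = 99.0
) -> TransitionCutoffs:
    """Extreme-percentile cut-offs of the pooled population distribution.

    Quantiles use linear interpolation (same convention as the tokeniser's
    bins).  An empty sign-collection leaves that cut-off undefined (NaN),
    flagged via :meth:`TransitionCutoffs.defined`.
    """
    neg = np.full(N_THRESHOLDS, np.nan)
    pos = np.full(N_THRESHOLDS, np.nan)
    for k in range(N_THRESHOLDS):
        if len(negatives[k]):
            neg[k] = np.percentile(
                negatives[k], 100.0 - percentile, method="linear"
            )
        if len(positives[k]):
            pos[k] = np.percentile(positives[k], percentile, method="linear")
    return TransitionCutoffs(negative=neg, positive=pos, percentile=percentile)


def detect_transitions(
    trajectories: list[Trajectory],
    cutoffs: TransitionCutoffs,
    window_h: float,
    region: AnalysisRegion = AnalysisRegion(),
) -> list[TransitionEvent]:
    """Flag every in-region consecutive delta meeting its sign's cut-off.

    The comparison is inclusive: a delta exactly at the cut-off is flagged.
    """
    events: list[TransitionEvent] = []
    for tr in trajectories:
        q = tr.threshold_probs
        for t in range(1, tr.n_windows):
            if not region.window_in_region(t, window_h):
                continue
            d = q[t] - q[t - 1]
            for k in range(N_THRESHOLDS):
                if d[k] < 0 and np.isfinite(cutoffs.negative[k]):
                    if d[k] <= cutoffs.negative[k]:
                        events.append(
                            TransitionEvent(
                                tr.patient_id, t, k + 1, float(d[k]), "negative"
                            )
                        )
                elif d[k] > 0 and np.isfinite(cutoffs.positive[k]):
                    if d[k] >= cutoffs.positive[k]:
                        events.append(
                            TransitionEvent(
                                tr.patient_id, t, k + 1, float(d[k]), "positive"
                            )
                        )
    return events


def per_patient_counts(
    events: list[TransitionEvent], patient_ids: list[str]
) -> dict[str, int]:
    counts = {pid: 0 for pid in patient_ids}
    for ev in events:
        counts[ev.patient_id] = counts.get(ev.patient_id, 0) + 1
    return counts


def timing_distribution(events: list[TransitionEvent], window_h: float):
    """Transition times in hours since admission, split by direction."""
    pos = np.array(
        [ev.window * window_h for ev in events if ev.direction == "positive"]
    )
    neg = np.array(
        [ev.window * window_h for ev in events if ev.direction == "negative"]
    )
    return {"positive_h": pos, "negative_h": neg}


def events_frame(events: list[TransitionEvent]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "window": e.window,
                "threshold": e.threshold,
                "delta": e.delta,
                "direction": e.direction,
            }
            for e in events
        ]
    )


def cutoffs_frame(cutoffs: TransitionCutoffs):
    import pandas as pd

    return pd.DataFrame(
        {
            "threshold": np.arange(1, N_THRESHOLDS + 1),
            "negative_cutoff": cutoffs.negative,
            "positive_cutoff": cutoffs.positive,
        }
    )
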