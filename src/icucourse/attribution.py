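"""Shapley-value attribution of trajectory outputs at transitions.

Following the TimeSHAP recipe for recurrent models, a model output at an
event window is attributed to time windows and to tokens by treating them
as players in a cooperative game: a player that is "absent" has its tokens
replaced by the *average patient* baseline (the token set present in at
least half of training time windows).  Distant low-contributing windows
are grouped into a single pruned-past player, found by growing the suffix
of individually resolved windows until the grouped past's two-player
Shapley contribution falls below a tolerance.  Games with at most 12
players are solved by exhaustive enumeration (exact efficiency, null
player and symmetry); larger games use paired KernelSHAP-weighted
coalition sampling with a fixed seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .tokenise import TokenisedStay, Vocabulary
from .trajectory_model import TrajectoryModel, expected_index

EXACT_ENUMERATION_LIMIT = 12
DEFAULT_PRUNE_TOL = 0.05


# ---------------------------------------------------------------------------
# Baseline
# ---------------------------------------------------------------------------


def average_patient_baseline(
    training_stays: list[TokenisedStay], threshold: float = 0.5
) -> np.ndarray:
    """Token ids present in at least ``threshold`` of all training windows.

    The boundary is inclusive (a token in exactly 50% of windows is kept).
    Rarely observed dynamic variables are represented by their missing
    tokens, which appear in most windows, so the baseline is never empty.
    """
    counts: dict[int, int] = {}
    n_windows = 0
    for stay in training_stays:
        for ids in stay.windows:
            n_windows += 1
            for i in ids:
                counts[int(i)] = counts.get(int(i), 0) + 1
    kept = [i for i, c in counts.items() if c / n_windows >= threshold]
    if not kept:
        raise ValueError("baseline token set is empty; check tokenisation")
    return np.array(sorted(kept), dtype=np.int64)


# ---------------------------------------------------------------------------
# Output targets
# ---------------------------------------------------------------------------


def _target_fn(target: str):
    """Map a target spec to a function of (class_probs, threshold_probs)."""
    if target == "expected_index":
        return lambda p, q: expected_index(p)
    if target.startswith("threshold_prob:"):
        k = int(target.split(":")[1])
        if not 1 <= k <= 6:
            raise ValueError("threshold index must be in 1..6")
        return lambda p, q: q[..., k - 1]
    raise ValueError(f"unknown attribution target {target!r}")


# ---------------------------------------------------------------------------
# Games
# ---------------------------------------------------------------------------


class _Game:
    """Batch-evaluable coalition game over a truncated stay."""

    def __init__(self, model: TrajectoryModel, target: str, t_event: int):
        self.model = model
        self.target = _target_fn(target)
        self.t_event = t_event
        self._cache: dict[tuple, float] = {}

    def build(self, mask: np.ndarray) -> list[np.ndarray]:
        raise NotImplementedError

    def evaluate(self, masks: list[np.ndarray]) -> np.ndarray:
        """Model output at t_event for each coalition mask, cached."""
        todo, keys = [], []
        for m in masks:
            key = tuple(bool(b) for b in m)
            if key not in self._cache:
                todo.append(self.build(np.asarray(m, bool)))
                keys.append(key)
        if todo:
            p, q, _ = self.model.predict_windows(todo)
            vals = self.target(p, q)[:, self.t_event]
            for key, v in zip(keys, vals):
                self._cache[key] = float(v)
        return np.array(
            [self._cache[tuple(bool(b) for b in m)] for m in masks]
        )


class WindowGame(_Game):
    """Players are time-window groups; absent windows become baseline."""

    def __init__(
        self,
        model: TrajectoryModel,
        stay: TokenisedStay,
        t_event: int,
        baseline: np.ndarray,
        target: str,
        groups: list[list[int]],
    ):
        super().__init__(model, target, t_event)
        self.windows = [np.asarray(w) for w in stay.windows[: t_event + 1]]
        self.baseline = np.asarray(baseline)
        self.groups = groups  # each group is a list of window indices

    def build(self, mask: np.ndarray) -> list[np.ndarray]:
        out = [w for w in self.windows]
        for g, present in zip(self.groups, mask):
            if not present:
                for t in g:
                    out[t] = self.baseline
        return out


class TokenGame(_Game):
    """Players are tokens within scope windows; absent tokens are swapped
    for their variable's baseline token(s)."""

    def __init__(
        self,
        model: TrajectoryModel,
        stay: TokenisedStay,
        t_event: int,
        baseline: np.ndarray,
        target: str,
        scope: list[int],
        players: list[int],
        variables: list[str],
        vocab: Vocabulary,
    ):
        super().__init__(model, target, t_event)
        self.windows = [np.asarray(w) for w in stay.windows[: t_event + 1]]
        self.scope = scope
        self.players = players  # token ids
        id_to_token = vocab.id_to_token()
        var_of = {
            tid: token_variable(id_to_token[tid], variables)
            for tid in set(players) | set(int(i) for i in baseline)
        }
        # baseline replacement tokens grouped by variable
        self.repl: dict[str | None, list[int]] = {}
        for tid in baseline:
            self.repl.setdefault(var_of[int(tid)], []).append(int(tid))
        self.player_var = [var_of[tid] for tid in players]

    def build(self, mask: np.ndarray) -> list[np.ndarray]:
        absent = {
            tid for tid, keep in zip(self.players, mask) if not keep
        }
        out = [w for w in self.windows]
        for t in self.scope:
            ids = set(int(i) for i in out[t])
            changed = False
            for tid, var in zip(self.players, self.player_var):
                if tid in absent and tid in ids:
                    ids.discard(tid)
                    ids.update(self.repl.get(var, ()))
                    changed = True
            if changed:
                out[t] = np.array(sorted(ids), dtype=np.int64)
        return out


def token_variable(token: str, variables: list[str]) -> str | None:
    """Variable owning a token: longest name v with token == v_<suffix>."""
    best = None
    for v in variables:
        if token.startswith(v + "_") and (best is None or len(v) > len(best)):
            best = v
    return best


# ---------------------------------------------------------------------------
# Shapley estimators
# ---------------------------------------------------------------------------


def exact_shapley(game: _Game, n_players: int) -> np.ndarray:
    """Exhaustive Shapley values over all 2^m coalitions."""
    m = n_players
    masks = list(itertools.product([False, True], repeat=m))
    vals = game.evaluate([np.array(mask) for mask in masks])
    v = {mask: val for mask, val in zip(masks, vals)}
    phi = np.zeros(m)
    fact = [math.factorial(i) for i in range(m + 1)]
    for mask in masks:
        s = sum(mask)
        for i in range(m):
            if mask[i]:
                continue
            w = fact[s] * fact[m - s - 1] / fact[m]
            with_i = tuple(
                True if j == i else mask[j] for j in range(m)
            )
            phi[i] += w * (v[with_i] - v[mask])
    return phi


def sampled_shapley(
    game: _Game, n_players: int, n_samples: int, seed: int = 0
) -> np.ndarray:
    """KernelSHAP-weighted regression estimate with paired (antithetic)
    coalition sampling; satisfies the efficiency constraint exactly."""
    m = n_players
    rng = np.random.default_rng(seed)
    sizes = np.arange(1, m)
    kernel = (m - 1) / (
        np.array([math.comb(m, s) for s in sizes]) * sizes * (m - sizes)
    )
    size_p = kernel * np.array([math.comb(m, s) for s in sizes])
    size_p = size_p / size_p.sum()
    Z, W = [], []
    n_pairs = max(n_samples // 2, 1)
    for _ in range(n_pairs):
        s = rng.choice(sizes, p=size_p)
        members = rng.choice(m, size=s, replace=False)
        z = np.zeros(m, bool)
        z[members] = True
        Z.append(z.copy())
        Z.append(~z)  # antithetic complement
        w = 1.0
        W.extend([w, w])
    Z = np.array(Z)
    W = np.array(W)
    v_empty, v_full = game.evaluate([np.zeros(m, bool), np.ones(m, bool)])
    y = game.evaluate(list(Z)) - v_empty
    total = v_full - v_empty
    # eliminate the last player's coefficient via the efficiency constraint
    Zf = Z.astype(float)
    X = Zf[:, :-1] - Zf[:, -1:]
    yy = y - Zf[:, -1] * total
    sw = np.sqrt(W)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], yy * sw, rcond=None)
    phi = np.empty(m)
    phi[:-1] = coef
    phi[-1] = total - coef.sum()
    return phi


# ---------------------------------------------------------------------------
# Temporal pruning and public API
# ---------------------------------------------------------------------------


@dataclass
class AttributionReport:
    patient_id: str
    t_event: int
    target: str
    window_values: dict[int, float] = field(default_factory=dict)
    pruned_value: float | None = None
    pruned_windows: list[int] = field(default_factory=list)
    token_values: dict[str, float] = field(default_factory=dict)
    baseline_output: float = 0.0
    explained_output: float = 0.0

    @property
    def efficiency_gap(self) -> float:
        total = sum(self.window_values.values()) + (self.pruned_value or 0.0)
        return total - (self.explained_output - self.baseline_output)


def prune_past(
    model: TrajectoryModel,
    stay: TokenisedStay,
    t_event: int,
    baseline: np.ndarray,
    target: str = "expected_index",
    prune_tol: float = DEFAULT_PRUNE_TOL,
) -> int:
    """Smallest suffix length L such that the grouped past (windows before
    the last L) contributes at most ``prune_tol`` in two-player Shapley
    magnitude.  Returns L in 1..t_event+1."""
    n = t_event + 1
    for L in range(1, n):
        suffix = list(range(n - L, n))
        past = list(range(0, n - L))
        game = WindowGame(
            model, stay, t_event, baseline, target, [suffix, past]
        )
        v = game.evaluate(
            [
                np.array([False, False]),
                np.array([False, True]),
                np.array([True, False]),
                np.array([True, True]),
            ]
        )
        phi_past = 0.5 * ((v[1] - v[0]) + (v[3] - v[2]))
        if abs(phi_past) <= prune_tol:
            return L
    return n


def shapley_windows(
    model: TrajectoryModel,
    stay: TokenisedStay,
    t_event: int,
    baseline: np.ndarray,
    target: str = "expected_index",
    n_samples: int = 512,
    prune_tol: float = DEFAULT_PRUNE_TOL,
    seed: int = 0,
) -> AttributionReport:
    """Per-window Shapley values at an event, with the distant past pruned
    into one grouped player."""
    if not 0 <= t_event < stay.n_windows:
        raise ValueError("t_event outside the stay")
    n = t_event + 1
    L = prune_past(model, stay, t_event, baseline, target, prune_tol)
    resolved = list(range(n - L, n))
    pruned = list(range(0, n - L))
    groups: list[list[int]] = [[t] for t in resolved]
    if pruned:
        groups.append(pruned)
    game = WindowGame(model, stay, t_event, baseline, target, groups)
    m = len(groups)
    if m <= EXACT_ENUMERATION_LIMIT:
        phi = exact_shapley(game, m)
    else:
        phi = sampled_shapley(game, m, n_samples, seed)
    v_empty, v_full = game.evaluate(
        [np.zeros(m, bool), np.ones(m, bool)]
    )
    report = AttributionReport(
        patient_id=stay.patient_id,
        t_event=t_event,
        target=target,
        baseline_output=float(v_empty),
        explained_output=float(v_full),
    )
    for g, val in zip(groups[: len(resolved)], phi[: len(resolved)]):
        report.window_values[g[0]] = float(val)
    if pruned:
        report.pruned_value = float(phi[-1])
        report.pruned_windows = pruned
    return report


def shapley_tokens(
    model: TrajectoryModel,
    stay: TokenisedStay,
    t_event: int,
    baseline: np.ndarray,
    vocab: Vocabulary,
    variables: list[str],
    target: str = "expected_index",
    window_scope: list[int] | None = None,
    n_samples: int = 512,
    seed: int = 0,
) -> AttributionReport:
    """Per-token Shapley values within the event scope windows.

    Default scope: the event window and the one before it.  Efficiency is
    restricted to the scope's marginal contribution: the values sum to
    f(x) minus f(x with the scope fully swapped for the baseline).
    """
    if window_scope is None:
        window_scope = [t for t in (t_event - 1, t_event) if t >= 0]
    players = sorted(
        {int(i) for t in window_scope for i in stay.windows[t]}
    )
    game = TokenGame(
        model,
        stay,
        t_event,
        baseline,
        target,
        window_scope,
        players,
        variables,
        vocab,
    )
    m = len(players)
    if m == 0:
        raise ValueError("empty token scope")
    if m == 1:
        v = game.evaluate([np.array([False]), np.array([True])])
        phi = np.array([v[1] - v[0]])
    elif m <= EXACT_ENUMERATION_LIMIT:
        phi = exact_shapley(game, m)
    else:
        phi = sampled_shapley(game, m, n_samples, seed)
    v_empty, v_full = game.evaluate(
        [np.zeros(m, bool), np.ones(m, bool)]
    )
    id_to_token = vocab.id_to_token()
    report = AttributionReport(
        patient_id=stay.patient_id,
        t_event=t_event,
        target=target,
        baseline_output=float(v_empty),
        explained_output=float(v_full),
    )
    for tid, val in zip(players, phi):
        report.token_values[id_to_token[tid]] = float(val)
    return report


def population_attribution_summary(
    reports: list[AttributionReport],
    variables: list[str],
    top_n: int = 10,
):
    """Ranked variable table across patients' high-magnitude transitions.

    Token values are first averaged within each patient (over that
    patient's events), then the median across patients is taken per token.
    Among tokens with non-missing values, the ``top_n`` most negative
    medians are ranked first, then the ``top_n`` most positive of the
    remaining variables; missing-token medians are summarised separately.
    """
    import pandas as pd

    per_patient: dict[str, dict[str, list[float]]] = {}
    for rep in reports:
        d = per_patient.setdefault(rep.patient_id, {})
        for tok, val in rep.token_values.items():
            d.setdefault(tok, []).append(val)
    token_rows: dict[str, list[float]] = {}
    for pid, toks in per_patient.items():
        for tok, vals in toks.items():
            token_rows.setdefault(tok, []).append(float(np.mean(vals)))
    rows = []
    for tok, vals in token_rows.items():
        rows.append(
            {
                "token": tok,
                "variable": token_variable(tok, variables),
                "is_missing_token": tok.endswith("_NA"),
                "median_value": float(np.median(vals)),
                "n_patients": len(vals),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    value_df = df[~df.is_missing_token].sort_values("median_value")
    neg = value_df.head(top_n)
    pos = (
        value_df[~value_df.variable.isin(neg.variable)]
        .sort_values("median_value", ascending=False)
        .head(top_n)
    )
    df["rank_group"] = "unranked"
    df.loc[df.token.isin(neg.token), "rank_group"] = "top_negative"
    df.loc[df.token.isin(pos.token), "rank_group"] = "top_positive"
    df.loc[df.is_missing_token, "rank_group"] = "missing_token"
    return df.sort_values(
        ["rank_group", "median_value"]
    ).reset_index(drop=True)


def report_frame(reports: list[AttributionReport]):
    import pandas as pd

    rows = []
    for i, rep in enumerate(reports):
        for w, v in rep.window_values.items():
            rows.append(
                {
                    "event": i,
                    "patient_id": rep.patient_id,
                    "player_type": "window",
                    "player": str(w),
                    "value": v,
                    "target": rep.target,
                    "pruned": False,
                }
            )
        if rep.pruned_value is not None:
            rows.append(
                {
                    "event": i,
                    "patient_id": rep.patient_id,
                    "player_type": "window",
                    "player": "pruned_past",
                    "value": rep.pruned_value,
                    "target": rep.target,
                    "pruned": True,
                }
            )
        for tok, v in rep.token_values.items():
            rows.append(
                {
                    "event": i,
                    "patient_id": rep.patient_id,
                    "player_type": "token",
                    "player": tok,
                    "value": v,
                    "target": rep.target,
                    "pruned": False,
                }
            )
    return pd.DataFrame(rows)
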