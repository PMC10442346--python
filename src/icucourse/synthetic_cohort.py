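"""Synthetic ICU cohorts with known ground truth.

Emulates the statistical structure the pipeline assumes — mixed-type static
and dynamic variables, 2-h sampling, variable-length stays (>= 24 h),
informative (MNAR) missingness, and a proportional-odds ordinal outcome —
without imitating any real cohort's marginals.

Generative model, per patient i:

* static numerics z_ij ~ N(0,1); static categoricals uniform over levels
  with level effects; free-text variables drawn from a phrase bank with
  injected punctuation/case noise (exercises text normalisation).
* a dynamic-only latent u_i ~ N(0,1), expressed solely through the dynamic
  trajectories, never through statics.
* latent severity  s_i = beta · (static effects) + gamma * u_i + eps_i.
* dynamic numerics: AR(1) around a drift linked to u_i (and optionally
  s_i), sampled every 2 h.
* outcome: proportional odds, P(Y > k) = sigmoid(s_i - theta_k) for the 6
  cuts of the 7-category scale.
* missingness: each observation goes missing with probability
  sigmoid(logit(base_rate) + delta_var * s_i) — missing-not-at-random when
  delta_var != 0, so the missing token itself carries outcome signal.
* stay length: log-linear in severity (coupling configurable, including an
  "extreme severities discharge sooner" mode), floored at 24 h.

All randomness flows from one seed through named substreams so cohorts are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort_io import (
    Cohort,
    MISSING_MARKER,
    Observation,
    OrdinalOutcome,
    Stay,
    TemporalClass,
    ValueClass,
    VariableSpec,
)
from .trajectory_model import sigmoid

_PHRASES = [
    "Road-Traffic Accident!",
    "Fall from height (ladder)",
    "assault, blunt object",
    "Bicycle crash; no helmet",
    "Sports injury",
    "unknown mechanism??",
]

SAMPLING_INTERVAL_H = 2.0  # highest regular collection resolution


@dataclass
class GeneratorConfig:
    n_patients: int = 500
    n_static_numeric: int = 4
    n_static_categorical: int = 3
    n_text: int = 1
    n_dynamic_numeric: int = 4
    n_dynamic_categorical: int = 2
    # effect of each static numeric on severity; categoricals get level
    # effects scaled by beta_categorical
    beta: tuple[float, ...] = (1.0, 0.8, 0.5, 0.0)
    beta_categorical: float = 0.6
    gamma: float = 0.8  # weight of the dynamic-only latent
    noise_sd: float = 0.25  # eps_i
    ar_rho: float = 0.7
    ar_noise_sd: float = 0.5
    dynamic_loading: float = 1.0  # drift of dynamic numerics on u_i
    missing_base_rate: float = 0.10
    missing_delta: tuple[float, ...] = ()  # per dynamic numeric; default 0
    uninformative_dynamic: tuple[int, ...] = ()  # indices with pure-noise values
    outcome_cuts: tuple[float, ...] = (-2.0, -1.1, -0.4, 0.2, 0.9, 1.8)
    stay_base_h: float = 48.0
    stay_length_coupling: float = 0.35  # log-linear in s_i
    stay_extreme_shorter: float = 0.0  # >0: extreme |s| discharged sooner
    stay_max_h: float = 336.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.beta) != self.n_static_numeric:
            raise ValueError("beta must have one entry per static numeric")
        if not all(
            a < b for a, b in zip(self.outcome_cuts, self.outcome_cuts[1:])
        ):
            raise ValueError("outcome cut points must be strictly increasing")
        if not 0.0 <= self.missing_base_rate < 1.0:
            raise ValueError("missing_base_rate must be in [0, 1)")


@dataclass
class GroundTruth:
    severity: np.ndarray  # per-patient latent s_i (systematic + noise)
    systematic: np.ndarray  # recoverable part: beta·statics + gamma·u
    outcome_probs: np.ndarray  # (n, 7) true class probabilities
    oracle_dxy: float | None = None
    patient_ids: list[str] = field(default_factory=list)


def _class_probs(severity: np.ndarray, cuts) -> np.ndarray:
    q = sigmoid(severity[:, None] - np.asarray(cuts)[None, :])  # (n, 6)
    p = np.empty((len(severity), 7))
    p[:, 0] = 1 - q[:, 0]
    p[:, 1:6] = q[:, :-1] - q[:, 1:]
    p[:, 6] = q[:, -1]
    return p


def _sample_outcomes(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(len(p))
    return (u[:, None] > np.cumsum(p, axis=1)[:, :-1]).sum(axis=1)


def build_dictionary(cfg: GeneratorConfig) -> dict[str, VariableSpec]:
    d: dict[str, VariableSpec] = {}

    def add(name, tc, vc, group, interv=False, impress=False):
        d[name] = VariableSpec(name, tc, vc, group, interv, impress)

    groups = [
        "demographics",
        "history",
        "injury",
        "emergency_care",
        "imaging",
        "labs",
        "medications",
        "vitals_assessments",
        "surgery_neuromonitoring",
    ]
    for j in range(cfg.n_static_numeric):
        add(
            f"sn{j}",
            TemporalClass.STATIC,
            ValueClass.NUMERIC,
            groups[j % 5],
            impress=(j == 0),
        )
    for j in range(cfg.n_static_categorical):
        add(f"sc{j}", TemporalClass.STATIC, ValueClass.CATEGORICAL, groups[j % 5])
    for j in range(cfg.n_text):
        add(f"tx{j}", TemporalClass.STATIC, ValueClass.TEXT, "injury")
    for j in range(cfg.n_dynamic_numeric):
        add(
            f"dn{j}",
            TemporalClass.DYNAMIC,
            ValueClass.NUMERIC,
            groups[5 + j % 4],
        )
    for j in range(cfg.n_dynamic_categorical):
        add(
            f"dc{j}",
            TemporalClass.DYNAMIC,
            ValueClass.CATEGORICAL,
            "vitals_assessments",
            interv=(j == 0),
        )
    return d


def generate_cohort(cfg: GeneratorConfig) -> tuple[Cohort, GroundTruth]:
    """Draw a cohort and its ground truth from the generative model."""
    root = np.random.default_rng(cfg.seed)
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("statics", "dynamics", "missingness", "outcome", "lengths"),
            root.integers(0, 2**31 - 1, size=5),
        )
    }
    n = cfg.n_patients
    rs, rd, rm, ro, rl = (
        streams["statics"],
        streams["dynamics"],
        streams["missingness"],
        streams["outcome"],
        streams["lengths"],
    )

    dictionary = build_dictionary(cfg)
    pids = [f"P{i:05d}" for i in range(n)]

    # -- statics and latent severity --
    Z = rs.normal(size=(n, cfg.n_static_numeric))
    cat_levels = 3
    C = rs.integers(0, cat_levels, size=(n, cfg.n_static_categorical))
    # centred level effects -1, 0, +1 scaled
    cat_eff = (C - 1).sum(axis=1) * cfg.beta_categorical
    u = rd.normal(size=n)  # dynamic-only latent
    eps = ro.normal(scale=cfg.noise_sd, size=n)
    systematic = Z @ np.asarray(cfg.beta) + cat_eff + cfg.gamma * u
    severity = systematic + eps

    probs = _class_probs(severity, cfg.outcome_cuts)
    y = _sample_outcomes(probs, ro)

    # -- stay lengths --
    s_std = (severity - severity.mean()) / max(severity.std(), 1e-9)
    log_mult = cfg.stay_length_coupling * s_std
    if cfg.stay_extreme_shorter > 0:
        log_mult = log_mult - cfg.stay_extreme_shorter * np.abs(s_std)
    lengths = cfg.stay_base_h * np.exp(log_mult + rl.normal(scale=0.3, size=n))
    lengths = np.clip(lengths, 24.0 + SAMPLING_INTERVAL_H, cfg.stay_max_h)

    # -- missingness couplings --
    deltas = np.zeros(cfg.n_dynamic_numeric)
    for j, dlt in enumerate(cfg.missing_delta):
        if j < cfg.n_dynamic_numeric:
            deltas[j] = dlt
    base_logit = np.log(
        cfg.missing_base_rate / (1 - cfg.missing_base_rate)
    ) if cfg.missing_base_rate > 0 else -np.inf

    stays: list[Stay] = []
    for i in range(n):
        obs: list[Observation] = []
        pid = pids[i]
        for j in range(cfg.n_static_numeric):
            if rm.random() < cfg.missing_base_rate:
                obs.append(Observation(pid, f"sn{j}", None, MISSING_MARKER))
            else:
                obs.append(Observation(pid, f"sn{j}", None, f"{Z[i, j]:.3f}"))
        for j in range(cfg.n_static_categorical):
            if rm.random() < cfg.missing_base_rate:
                obs.append(Observation(pid, f"sc{j}", None, MISSING_MARKER))
            else:
                obs.append(
                    Observation(pid, f"sc{j}", None, f"level{C[i, j]}")
                )
        for j in range(cfg.n_text):
            phrase = _PHRASES[rs.integers(0, len(_PHRASES))]
            obs.append(Observation(pid, f"tx{j}", None, phrase))

        times = np.arange(
            SAMPLING_INTERVAL_H, lengths[i], SAMPLING_INTERVAL_H
        )
        T = len(times)
        for j in range(cfg.n_dynamic_numeric):
            if j in cfg.uninformative_dynamic:
                mu = 0.0
            else:
                mu = cfg.dynamic_loading * u[i]
            x = mu + rd.normal(scale=cfg.ar_noise_sd)
            vals = np.empty(T)
            for t in range(T):
                x = mu + cfg.ar_rho * (x - mu) + rd.normal(
                    scale=cfg.ar_noise_sd
                )
                vals[t] = x
            if cfg.missing_base_rate > 0 or deltas[j] != 0:
                p_miss = sigmoid(base_logit + deltas[j] * severity[i])
            else:
                p_miss = 0.0
            miss = rm.random(T) < p_miss
            for t in range(T):
                v = MISSING_MARKER if miss[t] else f"{vals[t]:.3f}"
                obs.append(Observation(pid, f"dn{j}", float(times[t]), v))
        for j in range(cfg.n_dynamic_categorical):
            # slow regime switches linked to u_i
            state = int(u[i] + rd.normal(scale=1.0) > 0)
            for t in range(T):
                if rd.random() < 0.05:
                    state = 1 - state
                if rm.random() < cfg.missing_base_rate:
                    v = MISSING_MARKER
                else:
                    v = f"on{state}"
                obs.append(Observation(pid, f"dc{j}", float(times[t]), v))

        stays.append(
            Stay(
                patient_id=pid,
                discharge_h=float(np.ceil(lengths[i])),
                observations=obs,
                outcome=OrdinalOutcome(int(y[i])),
            )
        )

    cohort = Cohort(dictionary=dictionary, stays=stays)
    cohort.validate()
    truth = GroundTruth(
        severity=severity,
        systematic=systematic,
        outcome_probs=probs,
        patient_ids=pids,
    )
    return cohort, truth


def oracle_dxy(cfg: GeneratorConfig, n_mc: int = 100_000, seed: int | None = None):
    """Monte-Carlo Somers' Dxy of the systematic severity against outcomes.

    This is the generator's explanation ceiling D*: the concordance a model
    would reach if it recovered the systematic part of the latent severity
    (beta-weighted statics plus gamma-weighted dynamic latent) exactly.
    The idiosyncratic noise term contributes to the sampled outcomes but is
    excluded from the score, since no model observing the records could
    recover it.  Returns (D*, standard error) from 20 batch replicates.
    """
    from .evaluation import somers_dxy

    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_batches = 20
    per = max(n_mc // n_batches, 100)
    vals = []
    for _ in range(n_batches):
        beta = np.asarray(cfg.beta)
        z = rng.normal(size=(per, cfg.n_static_numeric))
        c = rng.integers(0, 3, size=(per, cfg.n_static_categorical))
        u = rng.normal(size=per)
        eps = rng.normal(scale=cfg.noise_sd, size=per)
        s_sys = (
            z @ beta
            + (c - 1).sum(axis=1) * cfg.beta_categorical
            + cfg.gamma * u
        )
        p = _class_probs(s_sys + eps, cfg.outcome_cuts)
        y = _sample_outcomes(p, rng)
        d = somers_dxy(s_sys, y)
        if d.value is not None:
            vals.append(d.value)
    vals = np.asarray(vals)
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(len(vals)))


def write_ground_truth(truth: GroundTruth, path: str) -> None:
    import pandas as pd

    pd.DataFrame(
        {"patient_id": truth.patient_ids, "latent_severity": truth.severity}
    ).to_csv(path, sep="\t", index=False)
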