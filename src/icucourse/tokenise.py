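"""Tokenisation of ICU stays into time-windowed token-id sets.

Every variable value becomes a string token: numeric values are discretised
into quantile bins learned from training data, categorical and free-text
values are appended (normalised) to the variable name, and missingness gets
its own ``<var>_NA`` token so the model can learn informative-missingness
patterns instead of imputing.  Static tokens are carried into every window;
a dynamic variable unobserved in a window contributes its missing token, so
each window represents every variable exactly once-or-more.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort_io import Cohort, Stay, TemporalClass, ValueClass, MISSING_MARKER

WINDOW_HOURS = (2, 8, 12, 24)
BIN_COUNTS = (3, 4, 5, 7, 10, 20)

UNK_TOKEN = "<UNK>"

_NON_ALNUM = re.compile(r"[^a-z0-9]")


@dataclass(frozen=True)
class TokeniserConfig:
    """Window length (hours) and quantile-bin count, on the study grid."""

    window_h: int = 2
    n_bins: int = 20

    def __post_init__(self) -> None:
        if self.window_h not in WINDOW_HOURS:
            raise ValueError(f"window_h must be one of {WINDOW_HOURS}")
        if self.n_bins not in BIN_COUNTS:
            raise ValueError(f"n_bins must be one of {BIN_COUNTS}")


def normalise_text(raw: str) -> str:
    """Strip special characters, spaces, and capitalisation from free text.

    Returns a lowercase-alphanumeric suffix; an empty result signals that
    the value should map to the variable's missing token.
    """
    return _NON_ALNUM.sub("", raw.lower())


def missing_token(variable: str) -> str:
    return f"{variable}_NA"


@dataclass
class Vocabulary:
    """Learned token inventory: ids, per-variable bin edges, missing tokens.

    Bin edges are the interior n-quantile cut points of each numeric
    variable's pooled training values (linear-interpolation quantiles,
    duplicates collapsed), so a heavily tied variable gets fewer bins.
    """

    token_to_id: dict[str, int] = field(default_factory=dict)
    bin_edges: dict[str, np.ndarray] = field(default_factory=dict)
    n_bins: int = 20

    @property
    def size(self) -> int:
        return len(self.token_to_id)

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK_TOKEN]

    def id_to_token(self) -> list[str]:
        inv = [""] * len(self.token_to_id)
        for tok, i in self.token_to_id.items():
            inv[i] = tok
        return inv

    def add(self, token: str) -> int:
        if token not in self.token_to_id:
            self.token_to_id[token] = len(self.token_to_id)
        return self.token_to_id[token]

    def lookup(self, token: str) -> int:
        return self.token_to_id.get(token, self.token_to_id[UNK_TOKEN])

    def numeric_token(self, variable: str, value: float) -> str:
        """Bin a numeric value; out-of-range values clamp to extreme bins."""
        edges = self.bin_edges.get(variable)
        if edges is None or len(edges) == 0:
            return f"{variable}_BIN1"
        # bin index b in 1..len(edges)+1; value <= edges[b-1] -> bin b
        b = int(np.searchsorted(edges, value, side="left")) + 1
        return f"{variable}_BIN{b}"

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#vocabulary v1\n")
            fh.write(f"#n_bins\t{self.n_bins}\n")
            for var in sorted(self.bin_edges):
                edges = "\t".join(repr(float(e)) for e in self.bin_edges[var])
                fh.write(f"#edges\t{var}\t{edges}\n")
            for tok, i in sorted(self.token_to_id.items(), key=lambda kv: kv[1]):
                fh.write(f"{tok}\t{i}\n")

    @classmethod
    def load(cls, path: str) -> "Vocabulary":
        vocab = cls()
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("#vocabulary"):
                raise ValueError(f"{path} is not a vocabulary file")
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#n_bins\t"):
                    vocab.n_bins = int(line.split("\t")[1])
                elif line.startswith("#edges\t"):
                    parts = line.split("\t")
                    vocab.bin_edges[parts[1]] = np.array(
                        [float(x) for x in parts[2:]]
                    )
                elif line:
                    tok, i = line.rsplit("\t", 1)
                    vocab.token_to_id[tok] = int(i)
        return vocab

    def checksum(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for tok, i in sorted(self.token_to_id.items(), key=lambda kv: kv[1]):
            h.update(f"{tok}:{i};".encode())
        for var in sorted(self.bin_edges):
            h.update(var.encode())
            h.update(np.ascontiguousarray(self.bin_edges[var]).tobytes())
        return h.hexdigest()[:16]


def value_token(
    variable: str, raw_value: str, value_class: ValueClass, vocab: Vocabulary
) -> str:
    """Token string for one observed (non-missing) value."""
    if raw_value == MISSING_MARKER:
        return missing_token(variable)
    if value_class is ValueClass.NUMERIC:
        return vocab.numeric_token(variable, float(raw_value))
    suffix = normalise_text(raw_value)
    if not suffix:
        return missing_token(variable)
    return f"{variable}_{suffix}"


def fit_vocabulary(
    training_stays: list[Stay],
    dictionary,
    config: TokeniserConfig,
) -> Vocabulary:
    """Learn bin edges and the token inventory from training stays only.

    Every variable gets a missing token; numeric variables get interior
    quantile cut points (type-7 / linear interpolation, duplicates merged);
    a numeric variable with zero training values keeps only its missing
    token (warning, not an error).  Id 0 is the reserved ``<UNK>`` token.
    """
    if not training_stays:
        raise ValueError("training_stays is empty")
    vocab = Vocabulary(n_bins=config.n_bins)
    vocab.add(UNK_TOKEN)

    numeric_values: dict[str, list[float]] = {
        name: []
        for name, spec in dictionary.items()
        if spec.value_class is ValueClass.NUMERIC
    }
    observed_tokens: set[str] = set()
    for stay in training_stays:
        for obs in stay.observations:
            if obs.is_missing:
                continue
            spec = dictionary[obs.variable]
            if spec.value_class is ValueClass.NUMERIC:
                numeric_values[obs.variable].append(float(obs.value))
            else:
                suffix = normalise_text(obs.value)
                if suffix:
                    observed_tokens.add(f"{obs.variable}_{suffix}")

    for var, values in numeric_values.items():
        if not values:
            warnings.warn(
                f"numeric variable {var!r} has no training values; "
                "only its missing token is created",
                stacklevel=2,
            )
            continue
        qs = np.arange(1, config.n_bins) / config.n_bins
        edges = np.unique(np.quantile(values, qs, method="linear"))
        vocab.bin_edges[var] = edges
        for b in range(1, len(edges) + 2):
            vocab.add(f"{var}_BIN{b}")

    for tok in sorted(observed_tokens):
        vocab.add(tok)
    for name in sorted(dictionary):
        vocab.add(missing_token(name))
    return vocab


@dataclass
class TokenisedStay:
    """Per-window deduplicated token-id sets for one stay."""

    patient_id: str
    window_h: int
    windows: list[np.ndarray]  # sorted unique token ids per window
    outcome_index: int

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def n_windows_for(discharge_h: float, window_h: int) -> int:
    return max(1, math.ceil(discharge_h / window_h))


def tokenise_stay(
    stay: Stay, vocab: Vocabulary, dictionary, config: TokeniserConfig
) -> TokenisedStay:
    """Convert one stay into per-window token-id sets.

    Windows are half-open ``[w*window_h, (w+1)*window_h)`` from admission;
    the final partial window is kept.  Each window's set is the union of the
    patient's static tokens and the window's dynamic value tokens, with a
    ``<var>_NA`` token for every dynamic variable unobserved in the window
    (and for missing statics).  Tokens outside the vocabulary map to
    ``<UNK>``.
    """
    n_win = n_windows_for(stay.discharge_h, config.window_h)

    static_ids: set[int] = set()
    seen_static: set[str] = set()
    dyn_obs: dict[int, set[int]] = {w: set() for w in range(n_win)}
    dyn_seen: dict[int, set[str]] = {w: set() for w in range(n_win)}

    for obs in stay.observations:
        spec = dictionary[obs.variable]
        tok = value_token(obs.variable, obs.value, spec.value_class, vocab)
        if spec.temporal_class is TemporalClass.STATIC:
            static_ids.add(vocab.lookup(tok))
            seen_static.add(obs.variable)
        else:
            w = min(int(obs.time_h // config.window_h), n_win - 1)
            dyn_obs[w].add(vocab.lookup(tok))
            dyn_seen[w].add(obs.variable)

    static_vars = [
        n for n, s in dictionary.items() if s.temporal_class is TemporalClass.STATIC
    ]
    dynamic_vars = [
        n for n, s in dictionary.items() if s.temporal_class is TemporalClass.DYNAMIC
    ]
    for var in static_vars:
        if var not in seen_static:
            static_ids.add(vocab.lookup(missing_token(var)))

    windows = []
    for w in range(n_win):
        ids = set(static_ids)
        ids.update(dyn_obs[w])
        for var in dynamic_vars:
            if var not in dyn_seen[w]:
                ids.add(vocab.lookup(missing_token(var)))
        windows.append(np.array(sorted(ids), dtype=np.int64))
    return TokenisedStay(
        patient_id=stay.patient_id,
        window_h=config.window_h,
        windows=windows,
        outcome_index=stay.outcome.category_index,
    )


def tokenise_cohort(
    cohort: Cohort, vocab: Vocabulary, config: TokeniserConfig
) -> list[TokenisedStay]:
    return [
        tokenise_stay(stay, vocab, cohort.dictionary, config)
        for stay in cohort.stays
    ]
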