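"""Cross-validated experiment driver.

Glue between the modules: for each (repeat, fold) cell it fits a
vocabulary on the training patients only, tokenises, trains the
trajectory model with its nested validation set, and predicts test-set
trajectories, pooling out-of-fold results for downstream evaluation,
transition detection and attribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort_io import Cohort
from .evaluation import PartitionScheme, somers_dxy
from .tokenise import TokeniserConfig, fit_vocabulary, tokenise_cohort
from .trajectory_model import ModelConfig, Trajectory, TrajectoryModel


@dataclass
class FoldResult:
    repeat: int
    fold: int
    test_idx: np.ndarray
    trajectories: list[Trajectory]
    model: TrajectoryModel | None = None
    vocab: object | None = None


@dataclass
class ExperimentResult:
    tokeniser_config: TokeniserConfig
    model_config: ModelConfig
    folds: list[FoldResult] = field(default_factory=list)

    def pooled_trajectories(self) -> list[Trajectory]:
        out = []
        for f in self.folds:
            out.extend(f.trajectories)
        return out

    def patient_scores(self, at: str = "discharge") -> tuple[np.ndarray, np.ndarray]:
        """Pooled out-of-fold (score, outcome) pairs, one per patient.

        ``at`` selects the evaluated window: 'discharge' (last window) or
        an integer-hour offset handled by the caller via trajectories.
        """
        scores, ys = [], []
        for f in self.folds:
            for tr in f.trajectories:
                w = tr.n_windows - 1 if at == "discharge" else 0
                scores.append(float(tr.expected_index[w]))
                ys.append(tr.outcome_index)
        return np.asarray(scores), np.asarray(ys)

    def test_dxy(self, at: str = "discharge") -> float | None:
        s, y = self.patient_scores(at)
        return somers_dxy(s, y).value


def run_fold(
    cohort: Cohort,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    test_idx: np.ndarray,
    tok_cfg: TokeniserConfig,
    model_cfg: ModelConfig,
    keep_model: bool = False,
):
    """Fit one cross-validation cell; the vocabulary never sees test data."""
    train_stays = [cohort.stays[i] for i in train_idx]
    vocab = fit_vocabulary(train_stays, cohort.dictionary, tok_cfg)
    tokenised = {"train": [], "val": [], "test": []}
    for name, idx in (("train", train_idx), ("val", val_idx), ("test", test_idx)):
        sub = Cohort(cohort.dictionary, [cohort.stays[i] for i in idx])
        tokenised[name] = tokenise_cohort(sub, vocab, tok_cfg)
    model = TrajectoryModel(model_cfg, vocab.size, vocab.checksum())
    model.fit(tokenised["train"], tokenised["val"])
    trajectories = model.predict(tokenised["test"])
    return vocab, model, tokenised, trajectories


def run_experiment(
    cohort: Cohort,
    scheme: PartitionScheme,
    tok_cfg: TokeniserConfig,
    model_cfg: ModelConfig,
    max_cells: int | None = None,
    keep_models: bool = False,
    verbose: bool = False,
) -> ExperimentResult:
    result = ExperimentResult(tokeniser_config=tok_cfg, model_config=model_cfg)
    cells = scheme.cells()
    if max_cells is not None:
        cells = cells[:max_cells]
    for cell in cells:
        cfg = ModelConfig(
            **{
                **model_cfg.__dict__,
                "seed": model_cfg.seed + 7919 * cell.repeat + 104729 * cell.fold,
            }
        )
        vocab, model, _, trajectories = run_fold(
            cohort,
            cell.train_idx,
            cell.val_idx,
            cell.test_idx,
            tok_cfg,
            cfg,
            keep_model=keep_models,
        )
        fr = FoldResult(
            repeat=cell.repeat,
            fold=cell.fold,
            test_idx=cell.test_idx,
            trajectories=trajectories,
        )
        if keep_models:
            fr.model = model
            fr.vocab = vocab
        result.folds.append(fr)
        if verbose:
            s = [float(t.expected_index[-1]) for t in trajectories]
            y = [t.outcome_index for t in trajectories]
            d = somers_dxy(np.array(s), np.array(y)).value
            print(
                f"repeat {cell.repeat} fold {cell.fold}: "
                f"test Dxy at discharge = {d:.3f}"
            )
    return result


def static_only_cohort(cohort: Cohort) -> Cohort:
    """Variant keeping only static observations (dynamic vars stay in the
    dictionary, so every window carries their missing tokens)."""
    from .cohort_io import Stay

    stays = []
    for s in cohort.stays:
        obs = [
            o
            for o in s.observations
            if cohort.dictionary[o.variable].temporal_class.value == "static"
        ]
        stays.append(
            Stay(
                patient_id=s.patient_id,
                discharge_h=s.discharge_h,
                observations=obs,
                outcome=s.outcome,
            )
        )
    return Cohort(cohort.dictionary, stays)


def drop_variable_cohort(cohort: Cohort, variable: str) -> Cohort:
    """Variant with one variable removed entirely (dictionary and data)."""
    from .cohort_io import Stay

    new_dict = {k: v for k, v in cohort.dictionary.items() if k != variable}
    stays = []
    for s in cohort.stays:
        obs = [o for o in s.observations if o.variable != variable]
        stays.append(
            Stay(
                patient_id=s.patient_id,
                discharge_h=s.discharge_h,
                observations=obs,
                outcome=s.outcome,
            )
        )
    return Cohort(new_dict, stays)
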