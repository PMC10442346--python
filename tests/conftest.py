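import warnings

import numpy as np
import pytest

from icucourse.synthetic_cohort import GeneratorConfig, generate_cohort
from icucourse.tokenise import TokeniserConfig, fit_vocabulary, tokenise_cohort
from icucourse.trajectory_model import ModelConfig, TrajectoryModel

warnings.filterwarnings(
    "ignore", message="numeric variable .* has no training values"
)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = GeneratorConfig(n_patients=60, seed=42)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def tok_cfg():
    return TokeniserConfig(window_h=24, n_bins=5)


@pytest.fixture(scope="session")
def small_vocab(small_cohort, tok_cfg):
    cohort, _ = small_cohort
    return fit_vocabulary(cohort.stays, cohort.dictionary, tok_cfg)


@pytest.fixture(scope="session")
def small_tokenised(small_cohort, small_vocab, tok_cfg):
    cohort, _ = small_cohort
    return tokenise_cohort(cohort, small_vocab, tok_cfg)


@pytest.fixture(scope="session")
def trained_model(small_tokenised, small_vocab):
    """A small trained GRU/ordinal model shared across model-level tests."""
    cfg = ModelConfig(
        embed_dim=16, hidden_dim=16, seed=0, epochs=40, patience=6
    )
    model = TrajectoryModel(cfg, small_vocab.size, small_vocab.checksum())
    model.fit(small_tokenised[:45], small_tokenised[45:])
    return model


@pytest.fixture(scope="session")
def trained_model_medium():
    """A 300-patient trained model whose outputs span the unit interval;
    used where degenerate output spread would make the check vacuous."""
    cfg = GeneratorConfig(n_patients=300, seed=42)
    cohort, _ = generate_cohort(cfg)
    tcfg = TokeniserConfig(window_h=24, n_bins=5)
    vocab = fit_vocabulary(cohort.stays, cohort.dictionary, tcfg)
    toks = tokenise_cohort(cohort, vocab, tcfg)
    model = TrajectoryModel(
        ModelConfig(embed_dim=16, hidden_dim=32, seed=0), vocab.size
    )
    model.fit(toks[:240], toks[240:])
    return model, toks


def brute_force_dxy(scores, outcomes):
    """Exhaustive O(n^2) pair-count concordance oracle."""
    scores = np.asarray(scores)
    outcomes = np.asarray(outcomes)
    n = len(scores)
    conc = disc = ties = 0
    for i in range(n):
        for j in range(i + 1, n):
            if outcomes[i] == outcomes[j]:
                continue
            ds = scores[i] - scores[j]
            dy = outcomes[i] - outcomes[j]
            if ds == 0:
                ties += 1
            elif (ds > 0) == (dy > 0):
                conc += 1
            else:
                disc += 1
    denom = conc + disc + ties
    return None if denom == 0 else (conc - disc) / denom
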