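"""Shared fixtures: a tiny fast corpus for unit tests and one default-scale
setup (ground truth, corpus, dictionary, trained model) reused across the
slower behavioural tests."""

from __future__ import annotations

import numpy as np
import pytest

import cogdecode as cd
from cogdecode.core_data import RestDataset, smooth_maps


TINY = cd.SimulationConfig(
    grid_shape=(8, 9, 8),
    k_true=6,
    l_true=3,
    n_studies=3,
    n_contrasts_range=(3, 4),
    n_subjects_range=(6, 10),
    n_rest=120,
    seed=0,
)


@pytest.fixture(scope="session")
def tiny_gt():
    return cd.make_ground_truth(TINY)


@pytest.fixture(scope="session")
def tiny_corpus(tiny_gt):
    return cd.simulate_corpus(tiny_gt)


@pytest.fixture(scope="session")
def tiny_rest(tiny_gt):
    return cd.simulate_rest(tiny_gt, TINY.n_rest)


@pytest.fixture(scope="session")
def tiny_dictionary(tiny_gt, tiny_rest):
    X = smooth_maps(tiny_rest.X, tiny_gt.mask, 1.5)
    fact = cd.fit_functional_units(
        RestDataset(X=X, mask=tiny_gt.mask), k=6, lam=0.05, n_epochs=10, seed=0
    )
    return fact.dictionary


def fit_default_dictionary(gt, n_rest=1500, k=48, seed=0):
    """The package's standard first-layer recipe on a synthetic ground truth."""
    rest = cd.simulate_rest(gt, n_rest)
    X = smooth_maps(rest.X, gt.mask, 1.5)
    fact = cd.fit_functional_units(
        RestDataset(X=X, mask=gt.mask), k=k, lam=0.1, n_epochs=15, seed=seed
    )
    return fact.dictionary


@pytest.fixture(scope="session")
def default_setup():
    """Default-condition synthetic world with fitted first layer (seed 0)."""
    cfg = cd.SimulationConfig(seed=0)
    gt = cd.make_ground_truth(cfg)
    corpus = cd.simulate_corpus(gt)
    dictionary = fit_default_dictionary(gt)
    return cfg, gt, corpus, dictionary


@pytest.fixture(scope="session")
def default_model(default_setup):
    _, _, corpus, dictionary = default_setup
    return cd.train_multistudy(corpus, dictionary, cd.TrainConfig(seed=0))


@pytest.fixture(scope="session")
def default_ensemble(default_setup):
    _, _, corpus, dictionary = default_setup
    return cd.train_ensemble(
        corpus, dictionary, cd.TrainConfig(seed=0), seeds=[11, 22, 33, 44]
    )


def make_study(maps, labels, subject_ids, names, study_id="s"):
    return cd.StudyDataset(
        study_id=study_id,
        maps=np.asarray(maps, float),
        labels=np.asarray(labels, int),
        subject_ids=np.asarray(subject_ids, int),
        contrast_names=list(names),
    )
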