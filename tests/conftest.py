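"""Shared fixtures.

The default-protocol dataset and its cross-validation reports are expensive
(about a minute and several minutes respectively), so they are produced
once per session and shared by the feature-level, regression-level and
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from echogaze.bench import (
    BurstSpec,
    NoiseSpec,
    ProtocolSpec,
    bench_scene_factory,
    run_protocol,
)
from echogaze.features import build_feature_matrix, feature_columns
from echogaze.regression import (
    ablation,
    cross_validate,
    feature_importance,
    fit,
    permutation_null,
)

#: one seed for the default synthetic study; every consumer shares it
STUDY_SEED = 11


@pytest.fixture(scope="session")
def default_dataset():
    """The default emulated protocol (36 poses, 19 positions, 9 sessions)."""
    return run_protocol(
        ProtocolSpec(),
        bench_scene_factory(),
        BurstSpec(),
        NoiseSpec(),
        seed=STUDY_SEED,
        fast=True,
    )


@pytest.fixture(scope="session")
def default_features(default_dataset):
    """Feature table of the default protocol: 1620 rows x 38 features."""
    return build_feature_matrix(default_dataset)


@pytest.fixture(scope="session")
def default_xy(default_features):
    cols = feature_columns(tuple(range(-90, 91, 10)))
    X = default_features[cols]
    Y = default_features[["theta_deg", "phi_deg"]].to_numpy(dtype=float)
    return X, Y


@pytest.fixture(scope="session")
def default_cv(default_xy):
    """CV reports of the default study: gbrt, linear, family ablations."""
    X, Y = default_xy
    return {
        "gbrt": cross_validate(X, Y, kind="gbrt", seed=STUDY_SEED),
        "linear": cross_validate(X, Y, kind="linear", seed=STUDY_SEED),
        "tof": ablation(X, Y, family="tof", seed=STUDY_SEED),
        "amp": ablation(X, Y, family="amp", seed=STUDY_SEED),
    }


@pytest.fixture(scope="session")
def default_importance(default_xy):
    X, Y = default_xy
    est = fit(X, Y, kind="gbrt", seed=STUDY_SEED)
    return feature_importance(est)


@pytest.fixture(scope="session")
def default_null(default_xy):
    """Label-shuffle null distribution of the GBRT CV metrics."""
    X, Y = default_xy
    return permutation_null(X, Y, kind="gbrt", n_shuffles=20, seed=STUDY_SEED)
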