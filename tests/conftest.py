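"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import fingermet as fm


@pytest.fixture(scope="session")
def small_library():
    """60 background + 8 planted markers at standardized effect 1.5."""
    return fm.build_template_library(60, 8, 1.5, seed=101)


@pytest.fixture(scope="session")
def clean_noise():
    """Deterministic-instrument limit: biological variation only."""
    return fm.NoiseSpec(baseline_amplitude=0.0, mz_jitter_sd=0.0,
                        intensity_cv=0.10, additive_noise_sd=0.0,
                        dropout_prob=0.0)


@pytest.fixture(scope="session")
def matrix_cohort(small_library, clean_noise):
    """Matrix-level cohort, 50/50, with the 8 planted markers."""
    templates, truth = small_library
    spec = fm.CohortSpec(groups=(("HC", 50), ("AECOPD", 50)), seed=102)
    matrix, meta, gt = fm.simulate_feature_matrix(spec, templates, clean_noise, truth)
    return matrix, meta, gt


def make_null_matrix(n_per_group: int = 30, n_features: int = 20, seed: int = 0):
    """Label-independent cohort: every feature null."""
    templates, truth = fm.build_template_library(n_features, 0, 0.0, seed=seed)
    spec = fm.CohortSpec(groups=(("HC", n_per_group), ("AECOPD", n_per_group)), seed=seed)
    return fm.simulate_feature_matrix(spec, templates, fm.NoiseSpec(), truth)


def planted_single_matrix(delta: float, n_per_group: int, n_null: int = 30,
                          seed: int = 0):
    """One planted marker at standardized effect delta among nulls."""
    templates, truth = fm.build_template_library(n_null, 1, delta, seed=seed)
    spec = fm.CohortSpec(groups=(("HC", n_per_group), ("AECOPD", n_per_group)), seed=seed)
    matrix, meta, gt = fm.simulate_feature_matrix(spec, templates, fm.NoiseSpec(), truth)
    return matrix, meta, gt


def label_vector(matrix) -> np.ndarray:
    return (np.asarray(matrix.labels) == "AECOPD").astype(int)
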