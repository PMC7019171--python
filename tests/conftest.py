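"""Shared fixtures: one default synthetic cohort and one fitted model.

Generation and fitting are deterministic, so session scope is safe and
keeps the suite fast.  Tests needing other settings build their own
configs.
"""

from __future__ import annotations

import numpy as np
import pytest

import metastrat as ms
from metastrat.stratify import StratifyConfig


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition cohort: 7 diseases x 7 samples, three layers."""
    return ms.generate_cohort(ms.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def fitted(default_cohort):
    """Stratification fitted on the default cohort (reduced resampling)."""
    mats, clin, design = default_cohort
    model = ms.StratificationModel(mats, clin, design,
                                   config=StratifyConfig(reps=300))
    return model.fit(seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """Small, fast cohort for statistical property checks."""
    cfg = ms.SimulationConfig(
        n_metabolites=60, n_proteins=60, n_peptides=40,
        n_lipid_metabolites=12, n_lcat_proteins=8, n_immune_peptides=10,
        n_bp_proteins=5, seed=3)
    return ms.generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
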