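"""Shared fixtures: panels, atlases and small synthetic cohorts."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from cytofpipe import default_design, default_panel, make_default_atlas, simulate_cohort


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def atlas(panel):
    return make_default_atlas(panel)


@pytest.fixture(scope="session")
def small_cohort():
    """Two batches x four samples at 5,000 events/sample with a rich
    (30%) target fraction, so every stage has enough cells at test
    scale."""
    design = default_design(
        seed=11, n_batches=2, samples_per_batch=4,
        events_per_sample=5000, frac_cd45=0.3,
    )
    tables, truth = simulate_cohort(design)
    return design, tables, truth


@pytest.fixture(scope="session")
def target_cohort():
    """Target-dominated cohort (nearly all events are live CD45+ cells)
    for clustering/statistics tests that start downstream of gating."""
    design = default_design(
        seed=5, n_batches=2, samples_per_batch=8,
        events_per_sample=700, frac_cd45=0.75,
        frac_dead=0.02, frac_beads=0.0,
    )
    design.frac_debris = 0.0
    tables, truth = simulate_cohort(design)
    return design, tables, truth


@pytest.fixture(scope="session")
def chain_result():
    """One full end-to-end run on the default two-group cohort (20,000
    events/sample, ~5% CD45+ target), analysed at 800 events per file."""
    from cytofpipe.workflows import run_synthetic_chain

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_synthetic_chain(
            seed=1, design=default_design(seed=1), min_cells=800, n_per_file=800,
        )
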