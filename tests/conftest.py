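"""Shared fixtures and table builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lome.peak_io import PeakTable


def make_table(
    matrix,
    axis_mz=None,
    labels=None,
    sets=None,
    sample_ids=None,
    replicates=None,
) -> PeakTable:
    """Build a PeakTable from a matrix with defaulted metadata."""
    matrix = np.asarray(matrix, dtype=float)
    n_ions, n_cols = matrix.shape
    if axis_mz is None:
        axis_mz = 100.0 + 10.0 * np.arange(n_ions)
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(n_cols)]
    if labels is None:
        labels = ["case"] * n_cols
    if sets is None:
        sets = ["A1"] * n_cols
    if replicates is None:
        replicates = [1] * n_cols
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "label": labels,
            "set": sets,
            "replicate": replicates,
        }
    )
    return PeakTable(np.asarray(axis_mz, float), matrix, meta)


@pytest.fixture(scope="session")
def trained_small_cohort():
    """A small trained cohort shared by pipeline-level tests.

    Uses a reduced desk-scale cohort (fewer ions/samples than the generator
    default) so session setup stays fast; pipeline behavior is unchanged.
    """
    from lome import CohortConfig, RunConfig, build_lome, generate_cohort, trisect

    cfg = CohortConfig(
        n_per_class=10, n_ions=300, n_planted=3, effect_size=3.0, rng_seed=11
    )
    spectra, manifest, truth = generate_cohort(cfg)
    manifest = manifest.copy()
    manifest["set"] = manifest["sample_id"].map(trisect(manifest, ("label",), 11))
    run_cfg = RunConfig(rng_seed=11)
    model, report = build_lome(spectra, manifest, run_cfg)
    return {
        "cohort_config": cfg,
        "run_config": run_cfg,
        "spectra": spectra,
        "manifest": manifest,
        "truth": truth,
        "model": model,
        "report": report,
    }
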