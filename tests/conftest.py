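"""Shared fixtures: small synthetic cohorts and constructed feature tables."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from musclenet import pipeline as pl
from musclenet.synthetic import (
    CohortParams,
    TASKS,
    cohort_subjects,
    generate_recording,
)

#: Feature-style column names (parseable into feature/muscle/side) used when a
#: test needs a table but not real signals.
def table_column_names(n: int) -> list[str]:
    feats = ("MAV", "RMS", "VAR", "WL", "SSI", "MNF", "MDF", "PKF", "MNP", "TTP")
    muscles = ("SCM", "SC", "UT")
    sides = ("L", "R")
    names = []
    i = 0
    while len(names) < n:
        names.append(
            f"{feats[i % len(feats)]}_{muscles[(i // 2) % 3]}_{sides[i % 2]}"
        )
        i += 1
    # feature/muscle/side combinations repeat after 60; disambiguate by index
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            parts = name.split("_")
            out.append(f"{parts[0]}{seen[name]}_{parts[1]}_{parts[2]}")
        else:
            seen[name] = 0
            out.append(name)
    return out


def make_table(
    n_per_group: int = 20,
    n_features: int = 10,
    informative: int = 0,
    effect: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian feature table with the first ``informative`` columns shifted
    by ``effect`` between groups."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    X = rng.normal(0.0, noise_sd, size=(n, n_features))
    y = np.array(["CNP"] * n_per_group + ["control"] * n_per_group)
    X[: n_per_group, :informative] += effect
    cols = table_column_names(n_features)
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "group", y)
    df.index = [f"S{i + 1:02d}" for i in range(n)]
    df.index.name = "subject"
    return df


@pytest.fixture(scope="session")
def tiny_params() -> CohortParams:
    return CohortParams(n_per_group=4, duration_s=3.0, n_trials=2, seed=11)


@pytest.fixture(scope="session")
def tiny_recordings(tiny_params):
    recs = []
    for sid, grp in cohort_subjects(tiny_params):
        for task in TASKS:
            for trial in range(1, tiny_params.n_trials + 1):
                recs.append(generate_recording(tiny_params, sid, grp, task, trial))
    return recs


@pytest.fixture(scope="session")
def tiny_tables(tiny_recordings):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pl.feature_tables(tiny_recordings)


@pytest.fixture(scope="session")
def default_cohort_tables():
    """Feature tables of the full default cohort (the study's design sizes)."""
    params = CohortParams(seed=20210621)
    recs = []
    for sid, grp in cohort_subjects(params):
        for task in TASKS:
            for trial in range(1, params.n_trials + 1):
                recs.append(generate_recording(params, sid, grp, task, trial))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        processed = pl.preprocess_cohort(recs, pl.RunConfig().preprocess_config())
        tables = pl.feature_tables(recs, processed=processed)
    return {"params": params, "tables": tables, "processed": processed}
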