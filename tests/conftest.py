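from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from retclust import AnalysisConfig, GeneratorParams, OrganoidTable
from retclust.io import CELL_COLUMNS, MARKER_COLUMNS
from retclust.synthetic import generate_cohort

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


def make_table(rows: list[dict], organoid_id: str = "org-A") -> OrganoidTable:
    """Build a validated OrganoidTable from partial row dicts.

    Unspecified marker flags default to False; cell ids are generated when
    absent.
    """
    full = []
    for k, row in enumerate(rows):
        r = {
            "cell_id": row.get("cell_id", f"{organoid_id}-{k:04d}"),
            "x": float(row.get("x", 0.0)),
            "y": float(row.get("y", 0.0)),
            "z": float(row.get("z", 0.0)),
            "organoid_id": organoid_id,
        }
        for m in MARKER_COLUMNS:
            r[m] = bool(row.get(m, False))
        full.append(r)
    frame = pd.DataFrame(full, columns=list(CELL_COLUMNS))
    for m in MARKER_COLUMNS:
        frame[m] = frame[m].astype(bool)
    return OrganoidTable(organoid_id=organoid_id, cells=frame)


def points_table(points: np.ndarray, organoid_id: str = "org-A", **flags) -> OrganoidTable:
    """Table of identical-marker cells at the given 3-D positions."""
    return make_table(
        [{"x": p[0], "y": p[1], "z": p[2], **flags} for p in np.atleast_2d(points)],
        organoid_id=organoid_id,
    )


@pytest.fixture(scope="session")
def default_config() -> AnalysisConfig:
    return AnalysisConfig(rng_seed=1)


@pytest.fixture(scope="session")
def clustered_cohort():
    """Ten clustered-mode organoids at generator defaults (fixed seed)."""
    return generate_cohort(GeneratorParams(mode="clustered", seed=1), 10)
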