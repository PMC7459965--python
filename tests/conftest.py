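"""Shared fixtures: small hand-built designs and the published survival table."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gynoscreen import CountMatrix, SurvivalTable

FEMALES = ["F1", "F2", "F3", "F4"]
SAMPLES = ["Fc1", "Fc2", "Fc3", "Fc4", "Fg1", "Fg2", "Fg3", "Fg4"]

# Table-1 group means (percent): eyed then swim-up, controls then gynogenesis
CONTROL_EYED = (95.0, 94.5, 91.9, 96.4)
CONTROL_SWIMUP = (88.7, 85.6, 89.8, 96.4)
GYNO_EYED = (3.5, 57.2, 3.1, 6.2)
GYNO_SWIMUP = (0.8, 41.5, 1.0, 5.0)


def make_meta(samples=SAMPLES) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "female_id": [f"F{s[-1]}" for s in samples],
            "condition": ["control" if s[1] == "c" else "gynogenetic" for s in samples],
        },
        index=pd.Index(samples, name="sample_id"),
    )


def make_count_matrix(counts, transcript_ids=None, samples=SAMPLES) -> CountMatrix:
    counts = np.asarray(counts)
    if transcript_ids is None:
        transcript_ids = [f"t{i}" for i in range(counts.shape[0])]
    return CountMatrix(
        transcript_ids=list(transcript_ids),
        sample_ids=list(samples),
        counts=counts,
        meta=make_meta(samples),
    )


@pytest.fixture
def table1_survival() -> SurvivalTable:
    """Replicate counts whose per-group rates equal the published means exactly.

    Each replicate starts with 1000 eggs and survives at exactly the group
    mean, so means are exact and SDs are 0.
    """
    rows = []
    for i in range(4):
        for rep in (1, 2):
            rows.append({
                "group_id": f"Fc{i + 1}", "condition": "control", "replicate": rep,
                "n_initial": 1000,
                "n_eyed": round(10 * CONTROL_EYED[i]),
                "n_swimup": round(10 * CONTROL_SWIMUP[i]),
            })
    for i in range(4):
        for rep in (1, 2, 3):
            rows.append({
                "group_id": f"Fg{i + 1}", "condition": "gynogenetic", "replicate": rep,
                "n_initial": 1000,
                "n_eyed": round(10 * GYNO_EYED[i]),
                "n_swimup": round(10 * GYNO_SWIMUP[i]),
            })
    return SurvivalTable(pd.DataFrame(rows))
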