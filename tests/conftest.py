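import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from promthresh.cohort_io import (
    BUILTIN_PROMS,
    Cohort,
    PatientRecord,
    dichotomize_anchor,
)


def build_cohort(anchors, scores=None, prom_defs=None):
    """Assemble a Cohort directly from anchor levels and per-PROM score lists.

    `scores` maps PROM name -> list (entries may be None for missing).
    """
    scores = scores or {}
    defs = prom_defs or {
        name: BUILTIN_PROMS[name] for name in (scores or BUILTIN_PROMS)
    }
    records = []
    for i, a in enumerate(anchors):
        rec_scores = {
            name: int(vals[i])
            for name, vals in scores.items()
            if vals[i] is not None
        }
        records.append(
            PatientRecord(
                id=f"T{i:03d}",
                anchor=a,
                outcome=dichotomize_anchor(a),
                scores=rec_scores,
            )
        )
    return Cohort(records=records, prom_defs=dict(defs))


@pytest.fixture
def rng():
    return np.random.default_rng(20240921)


@pytest.fixture
def pain():
    return BUILTIN_PROMS["womac_pain"]


@pytest.fixture
def kujala():
    return BUILTIN_PROMS["kujala"]


@pytest.fixture
def overlap_fixture():
    """12-point fixture with overlapping classes: failures at x >= 8 plus one at x = 3."""
    x = np.arange(12, dtype=float)
    y = np.zeros(12)
    y[x >= 8] = 1.0
    y[3] = 1.0
    return x, y
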