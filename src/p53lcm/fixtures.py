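"""Frozen study panel reconstructed from the published pairwise tables.

The study published only the six pairwise cross-tabulations of the four
genotyping methods (stratified by cytology), never the 4-way joint table.
:func:`build_study_panel` reconstructs *a* subject-level dataset whose six
stratified pairwise cross-tabs match the published counts exactly, by
integer linear programming over the 3^4 response patterns; the result was
frozen once into ``fixtures/study_crosstabs_panel.csv`` (a synthetic
panel: consistent with every published margin, but not the study's actual
joint data, so latent-class fits on it need not reproduce the published
classification probabilities).  :func:`load_study_panel` loads the frozen
copy.
"""

from __future__ import annotations

import itertools
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import published
from .dataset import (
    MISSING,
    TestPanelDataset,
    panel_from_patterns,
)

_FIXTURE_NAME = "study_crosstabs_panel.csv"

# The single subject with a missing RFLP-2 call: every published
# "missing" margin places them at Arg/Arg on the three observed tests,
# in the negative-cytology stratum.
_MISSING_SUBJECT = (1, 1, 1, MISSING, 1)


def _stratum_patterns(stratum_key: str, drop_missing_subject: bool) -> tuple[np.ndarray, np.ndarray]:
    """Solve for integer counts over the 81 complete response patterns
    matching all six pairwise tables of one cytology stratum."""
    from scipy.optimize import Bounds, LinearConstraint, milp

    names = published.TEST_NAMES
    patterns = np.array(list(itertools.product((1, 2, 3), repeat=4)))
    A, b = [], []
    for (t1, t2), block in published.PAIRWISE_CROSSTABS.items():
        i1, i2 = names.index(t1), names.index(t2)
        tab = np.array(block[stratum_key], dtype=float)
        if drop_missing_subject and i2 != 3 and i1 != 3:
            # the RFLP-2-missing subject contributes (1,1) to pairs among
            # the other three tests; the complete patterns must carry the rest
            tab[0, 0] -= 1
        for i in range(3):
            for j in range(3):
                A.append((patterns[:, i1] == i + 1) & (patterns[:, i2] == j + 1))
                b.append(tab[i, j])
    A = np.array(A, dtype=float)
    b = np.array(b)
    # prefer concordant patterns: minimize total pairwise disagreement so
    # the reconstruction looks like plausible genotyping data
    cost = np.array(
        [sum(p[i] != p[j] for i in range(4) for j in range(i + 1, 4)) for p in patterns],
        dtype=float,
    )
    res = milp(
        c=cost,
        constraints=LinearConstraint(A, b, b),
        bounds=Bounds(0, np.inf),
        integrality=np.ones(len(patterns)),
    )
    if res.status != 0:  # pragma: no cover - published margins are feasible
        raise RuntimeError(f"pattern reconstruction infeasible: {res.message}")
    counts = np.round(res.x).astype(np.int64)
    keep = counts > 0
    return patterns[keep], counts[keep]


def build_study_panel() -> TestPanelDataset:
    """Re-run the constraint satisfaction and return a consistent panel."""
    rows, cnts = [], []
    for stratum_key, outcome, drop in (("negative", 1, True), ("sil", 2, False)):
        pats, counts = _stratum_patterns(stratum_key, drop)
        for p, c in zip(pats, counts):
            rows.append((*p, outcome))
            cnts.append(c)
    rows.append(_MISSING_SUBJECT)
    cnts.append(1)
    order = np.lexsort(np.array(rows).T[::-1])
    patterns = np.array(rows)[order]
    counts = np.array(cnts)[order]
    return panel_from_patterns(
        patterns,
        counts,
        published.TEST_NAMES,
        published.CATEGORY_LABELS,
        outcome_included=True,
    )


def _fixture_path() -> Path:
    return Path(resources.files("p53lcm") / "fixtures" / _FIXTURE_NAME)


def write_fixture(path: str | Path | None = None) -> Path:
    """Freeze the reconstructed panel as a grouped-count CSV."""
    panel = build_study_panel()
    cols = np.column_stack([panel.calls, panel.outcome])
    patterns, counts = np.unique(cols, axis=0, return_counts=True)
    df = pd.DataFrame(patterns, columns=[*published.TEST_NAMES, "cytology"])
    df["count"] = counts
    path = Path(path) if path is not None else _fixture_path()
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def load_study_panel() -> TestPanelDataset:
    """Load the frozen study panel (911 subjects, 4 tests + cytology)."""
    df = pd.read_csv(_fixture_path())
    patterns = df[[*published.TEST_NAMES, "cytology"]].to_numpy(dtype=np.int64)
    counts = df["count"].to_numpy(dtype=np.int64)
    return panel_from_patterns(
        patterns,
        counts,
        published.TEST_NAMES,
        published.CATEGORY_LABELS,
        outcome_included=True,
    )
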