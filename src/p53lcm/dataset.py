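"""Subject-level multi-test categorical data: containers, I/O, cross-tabs.

The central container is :class:`TestPanelDataset`: one row per subject,
one categorical genotype call per test (coded 1..C, 0 = missing) and an
optional binary outcome (1 = negative cytology, 2 = SIL, 0 = missing).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing call / outcome in integer-coded arrays.
MISSING = 0

POOLED = "pooled"


class InputError(ValueError):
    """Malformed or inconsistent input data."""


class ConfigError(ValueError):
    """Invalid configuration (schemes, specs, flags)."""


@dataclass(frozen=True)
class TestPanelDataset:
    """Categorical calls of T tests on n subjects, with optional outcome.

    Parameters
    ----------
    subject_id
        Opaque identifiers, unique per subject.
    calls
        (n, T) integer array with values in {1..C} or ``MISSING`` (0).
    test_names
        Ordered labels of the T tests.
    category_labels
        Ordered labels of the C call categories.
    outcome
        Length-n integer array in {1, 2} or ``MISSING``; ``None`` when the
        panel carries no outcome.
    """

    __test__ = False  # not a pytest class, despite the name

    subject_id: np.ndarray
    calls: np.ndarray
    test_names: tuple[str, ...]
    category_labels: tuple[str, ...]
    outcome: np.ndarray | None = None

    def __post_init__(self) -> None:
        calls = np.asarray(self.calls, dtype=np.int64)
        object.__setattr__(self, "calls", calls)
        object.__setattr__(self, "subject_id", np.asarray(self.subject_id))
        object.__setattr__(self, "test_names", tuple(self.test_names))
        object.__setattr__(self, "category_labels", tuple(self.category_labels))
        if calls.ndim != 2 or calls.shape[1] != len(self.test_names):
            raise InputError(
                f"calls must be (n, {len(self.test_names)}); got {calls.shape}"
            )
        C = self.n_categories
        if calls.size and ((calls < 0) | (calls > C)).any():
            raise InputError(f"calls must lie in 0..{C} (0 = missing)")
        if len(np.unique(self.subject_id)) != len(self.subject_id):
            dupes = pd.Series(self.subject_id).value_counts()
            raise InputError(
                f"duplicate subject_id: {dupes[dupes > 1].index.tolist()[:5]}"
            )
        if self.outcome is not None:
            out = np.asarray(self.outcome, dtype=np.int64)
            object.__setattr__(self, "outcome", out)
            if out.shape != (calls.shape[0],):
                raise InputError("outcome length must match number of subjects")
            if out.size and ((out < 0) | (out > 2)).any():
                raise InputError("outcome must be 1, 2 or 0 (missing)")

    @property
    def n_subjects(self) -> int:
        return self.calls.shape[0]

    @property
    def n_tests(self) -> int:
        return len(self.test_names)

    @property
    def n_categories(self) -> int:
        return len(self.category_labels)

    def test_index(self, name: str) -> int:
        try:
            return self.test_names.index(name)
        except ValueError:
            raise InputError(f"unknown test label {name!r}; have {self.test_names}")

    def missing_summary(self) -> pd.Series:
        """Number of missing calls per test (log-friendly)."""
        return pd.Series(
            (self.calls == MISSING).sum(axis=0), index=list(self.test_names)
        )

    def without_outcome(self) -> "TestPanelDataset":
        return replace(self, outcome=None)

    def subset(self, mask: np.ndarray) -> "TestPanelDataset":
        return TestPanelDataset(
            subject_id=self.subject_id[mask],
            calls=self.calls[mask],
            test_names=self.test_names,
            category_labels=self.category_labels,
            outcome=None if self.outcome is None else self.outcome[mask],
        )


@dataclass(frozen=True)
class PairwiseCrossTab:
    """C x C count table for an ordered test pair, plus the margin of
    subjects with the first call observed and the second missing."""

    first_test: str
    second_test: str
    counts: np.ndarray
    missing_second: np.ndarray
    stratum: object = POOLED  # outcome level (1 / 2) or POOLED

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        miss = np.asarray(self.missing_second, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "missing_second", miss)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise InputError("counts must be a square matrix")
        if (counts < 0).any() or (miss < 0).any():
            raise InputError("counts must be non-negative")

    @property
    def n(self) -> int:
        """Subjects with both calls observed."""
        return int(self.counts.sum())

    def to_frame(self, labels: Sequence[str] | None = None) -> pd.DataFrame:
        C = self.counts.shape[0]
        labels = list(labels) if labels is not None else [str(i + 1) for i in range(C)]
        df = pd.DataFrame(self.counts, index=labels, columns=labels)
        df["missing"] = self.missing_second
        return df


@dataclass(frozen=True)
class PanelSchema:
    """Column mapping for :func:`read_panel`.

    ``test_cols`` maps CSV column name -> test label; iteration order fixes
    the test order.  ``outcome_col`` is optional.
    """

    subject_col: str
    test_cols: Mapping[str, str]
    category_labels: tuple[str, ...]
    outcome_col: str | None = None


def _parse_categorical(
    series: pd.Series, valid: range, col: str
) -> np.ndarray:
    out = np.full(len(series), MISSING, dtype=np.int64)
    for i, v in enumerate(series):
        if pd.isna(v) or (isinstance(v, str) and v.strip() == ""):
            continue
        try:
            iv = int(v)
        except (TypeError, ValueError):
            iv = -1
        if iv not in valid:
            raise InputError(
                f"unparseable category value {v!r} in column {col!r}, row {i}"
            )
        out[i] = iv
    return out


def read_panel(path: str | Path, schema: PanelSchema) -> TestPanelDataset:
    """Read a wide subject-level CSV (one row per subject) into a panel.

    Blank / NA cells become missing calls.  Raises :class:`InputError` on
    unparseable categories (naming row and column) or duplicate subject
    ids.
    """
    df = pd.read_csv(path, dtype=str)
    needed = [schema.subject_col, *schema.test_cols]
    if schema.outcome_col:
        needed.append(schema.outcome_col)
    absent = [c for c in needed if c not in df.columns]
    if absent:
        raise InputError(f"missing columns in {path}: {absent}")
    C = len(schema.category_labels)
    calls = np.column_stack(
        [
            _parse_categorical(df[col], range(1, C + 1), col)
            for col in schema.test_cols
        ]
    )
    outcome = None
    if schema.outcome_col:
        outcome = _parse_categorical(df[schema.outcome_col], range(1, 3), schema.outcome_col)
    return TestPanelDataset(
        subject_id=df[schema.subject_col].to_numpy(),
        calls=calls,
        test_names=tuple(schema.test_cols.values()),
        category_labels=schema.category_labels,
        outcome=outcome,
    )


def write_panel(data: TestPanelDataset, path: str | Path) -> None:
    """Write a panel as a wide CSV (missing cells blank)."""
    df = pd.DataFrame(data.calls, columns=list(data.test_names))
    df.insert(0, "subject_id", data.subject_id)
    if data.outcome is not None:
        df["cytology"] = data.outcome
    df = df.replace(MISSING, pd.NA)
    df.to_csv(path, index=False)


def crosstab_pair(
    data: TestPanelDataset, t1: str, t2: str, stratify: bool = False
) -> list[PairwiseCrossTab]:
    """Cross-tabulate calls of two tests.

    Returns ``[pooled]`` or, with ``stratify=True``, one table per outcome
    level followed by the pooled table.  ``counts[i, j]`` counts subjects
    with test ``t1`` = i+1 and ``t2`` = j+1 (both observed);
    ``missing_second[i]`` counts those with ``t1`` observed, ``t2``
    missing.
    """
    if t1 == t2:
        raise InputError("crosstab_pair requires two distinct tests")
    i1, i2 = data.test_index(t1), data.test_index(t2)
    C = data.n_categories

    def one(mask: np.ndarray, stratum: object) -> PairwiseCrossTab:
        a, b = data.calls[mask, i1], data.calls[mask, i2]
        both = (a != MISSING) & (b != MISSING)
        counts = np.zeros((C, C), dtype=np.int64)
        np.add.at(counts, (a[both] - 1, b[both] - 1), 1)
        m2 = (a != MISSING) & (b == MISSING)
        missing_second = np.bincount(a[m2] - 1, minlength=C)
        return PairwiseCrossTab(t1, t2, counts, missing_second, stratum)

    everyone = np.ones(data.n_subjects, dtype=bool)
    if not stratify:
        return [one(everyone, POOLED)]
    if data.outcome is None:
        raise InputError("cannot stratify: panel has no outcome")
    tabs = [one(data.outcome == level, level) for level in (1, 2)]
    tabs.append(one(everyone, POOLED))
    return tabs


def collapse_categories(
    data: TestPanelDataset,
    scheme: Mapping[int, int],
    category_labels: Sequence[str] | None = None,
) -> TestPanelDataset:
    """Remap call categories via a surjective map {1..C} -> {1..C'}.

    Used to regroup genotypes into two levels (Arg/Arg vs. others, or
    Pro/Pro vs. others) when three-level fits are unstable.  Missing calls
    are preserved.
    """
    C = data.n_categories
    if set(scheme.keys()) != set(range(1, C + 1)):
        raise ConfigError(f"scheme must map every category 1..{C}")
    targets = sorted(set(scheme.values()))
    Cp = len(targets)
    if targets != list(range(1, Cp + 1)) or not 2 <= Cp < C:
        raise ConfigError(
            "scheme must be surjective onto 1..C' with 2 <= C' < C"
        )
    lut = np.zeros(C + 1, dtype=np.int64)  # 0 -> 0 keeps MISSING
    for k, v in scheme.items():
        lut[k] = v
    if category_labels is None:
        grouped: dict[int, list[str]] = {}
        for k in range(1, C + 1):
            grouped.setdefault(scheme[k], []).append(data.category_labels[k - 1])
        category_labels = ["+".join(grouped[v]) for v in range(1, Cp + 1)]
    return TestPanelDataset(
        subject_id=data.subject_id,
        calls=lut[data.calls],
        test_names=data.test_names,
        category_labels=tuple(category_labels),
        outcome=data.outcome,
    )


def pattern_table(
    data: TestPanelDataset, include_outcome: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Group subjects by observable response pattern.

    Returns ``(patterns, counts)``: patterns is (P, T) (or (P, T+1) with
    the outcome appended) with ``MISSING`` kept as a distinct symbol;
    counts sums to the number of subjects.  Fitting on this grouped
    representation is exactly equivalent to fitting subject-level rows.
    """
    cols = data.calls
    if include_outcome:
        if data.outcome is None:
            raise InputError("panel has no outcome to include")
        cols = np.column_stack([cols, data.outcome])
    patterns, counts = np.unique(cols, axis=0, return_counts=True)
    return patterns, counts


def pattern_frame(data: TestPanelDataset, include_outcome: bool = False) -> pd.DataFrame:
    patterns, counts = pattern_table(data, include_outcome)
    names = list(data.test_names) + (["cytology"] if include_outcome else [])
    df = pd.DataFrame(patterns, columns=names)
    df["count"] = counts
    return df


def panel_from_patterns(
    patterns: np.ndarray,
    counts: np.ndarray,
    test_names: Sequence[str],
    category_labels: Sequence[str],
    outcome_included: bool = False,
    id_prefix: str = "S",
) -> TestPanelDataset:
    """Expand a grouped pattern table back to a subject-level panel."""
    rows = np.repeat(np.arange(len(counts)), counts)
    full = np.asarray(patterns)[rows]
    calls = full[:, : len(test_names)]
    outcome = full[:, len(test_names)] if outcome_included else None
    ids = np.array([f"{id_prefix}{i:05d}" for i in range(len(rows))])
    return TestPanelDataset(
        subject_id=ids,
        calls=calls,
        test_names=tuple(test_names),
        category_labels=tuple(category_labels),
        outcome=outcome,
    )
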