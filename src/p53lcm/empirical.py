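"""Empirical (no-latent-variable) genotype-outcome analysis.

For each test in turn, treat its calls as if they were the truth:
per-category prevalences among cases (SIL) and non-cases with binomial
standard errors, and the empirical odds ratio of SIL for each category
against a reference category.  These estimates ignore misclassification
and are the comparator the latent-class odds ratios correct.

Denominators are per test: subjects missing that test's call are
excluded for that test only, not listwise across tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import MISSING, InputError, TestPanelDataset


class UndefinedResultError(ValueError):
    """Requested estimate undefined (empty group / zero cell)."""


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    se: float
    ci_low: float
    ci_high: float
    cells: tuple[int, int, int, int]  # cases(cat), cases(ref), noncases(cat), noncases(ref)
    scale: str  # "or" (symmetric on OR scale) or "log"


def _group_counts(data: TestPanelDataset, test: str) -> pd.DataFrame:
    if data.outcome is None:
        raise InputError("empirical analysis requires an outcome column")
    t = data.test_index(test)
    calls = data.calls[:, t]
    ok = (calls != MISSING) & (data.outcome != MISSING)
    C = data.n_categories
    rows = {}
    for level, name in ((2, "cases"), (1, "noncases")):
        sel = calls[ok & (data.outcome == level)]
        rows[name] = np.bincount(sel - 1, minlength=C)
    return pd.DataFrame(rows, index=list(data.category_labels))


def empirical_prevalence(data: TestPanelDataset, test: str) -> pd.DataFrame:
    """Per-category genotype prevalence among cases and non-cases.

    Returns a frame indexed by category with counts, proportions and
    binomial SEs ``sqrt(p (1-p) / n)`` for each outcome group.
    """
    counts = _group_counts(data, test)
    out = counts.copy()
    for name in ("cases", "noncases"):
        n = counts[name].sum()
        if n == 0:
            raise UndefinedResultError(f"no {name} with an observed {test} call")
        p = counts[name] / n
        out[f"prev_{name}"] = p
        out[f"se_{name}"] = np.sqrt(p * (1 - p) / n)
        out[f"n_{name}"] = n
    return out


def empirical_or(
    data: TestPanelDataset,
    test: str,
    category: int,
    ref_category: int = 3,
    scale: str = "or",
    alpha: float = 0.05,
    continuity: bool = False,
) -> OddsRatioResult:
    """Empirical odds ratio of SIL for one call category vs. a reference.

    ``scale="or"`` gives the conventional symmetric Wald interval on the
    OR scale (matching the published presentation); ``scale="log"`` the
    log-scale Wald interval.  A zero cell raises unless ``continuity``
    adds 0.5 to all four cells.
    """
    if category == ref_category:
        raise InputError("category and ref_category must differ")
    counts = _group_counts(data, test)
    a = counts["cases"].iloc[category - 1]
    c = counts["cases"].iloc[ref_category - 1]
    b = counts["noncases"].iloc[category - 1]
    d = counts["noncases"].iloc[ref_category - 1]
    cells = (int(a), int(c), int(b), int(d))
    if min(cells) == 0:
        if not continuity:
            raise UndefinedResultError(
                f"zero cell in 2x2 for {test} {category} vs {ref_category}: {cells}"
            )
        a, c, b, d = (x + 0.5 for x in cells)
    orr = (a / c) / (b / d)
    se_log = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    z = stats.norm.ppf(1 - alpha / 2)
    if scale == "log":
        lo, hi = orr * np.exp(-z * se_log), orr * np.exp(z * se_log)
        se = se_log
    elif scale == "or":
        se = orr * se_log
        lo, hi = orr - z * se, orr + z * se
    else:
        raise ValueError("scale must be 'or' or 'log'")
    return OddsRatioResult(float(orr), float(se), float(lo), float(hi), cells, scale)


def empirical_table(
    data: TestPanelDataset, ref_category: int = 3, scale: str = "or"
) -> pd.DataFrame:
    """Per-test prevalence + OR summary across all tests and categories."""
    rows = []
    for cat in range(1, data.n_categories + 1):
        for test in data.test_names:
            prev = empirical_prevalence(data, test)
            row = {
                "category": data.category_labels[cat - 1],
                "test": test,
                "prev_cases": prev["prev_cases"].iloc[cat - 1],
                "se_cases": prev["se_cases"].iloc[cat - 1],
                "prev_noncases": prev["prev_noncases"].iloc[cat - 1],
                "se_noncases": prev["se_noncases"].iloc[cat - 1],
            }
            if cat != ref_category:
                orr = empirical_or(data, test, cat, ref_category, scale=scale)
                row.update(
                    odds_ratio=orr.odds_ratio, ci_low=orr.ci_low, ci_high=orr.ci_high
                )
            else:
                row.update(odds_ratio=1.0, ci_low=np.nan, ci_high=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)
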