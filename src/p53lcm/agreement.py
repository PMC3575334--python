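"""Crude agreement and Cohen's kappa (unweighted / linear-weighted) for
pairs of categorical tests, with large-sample standard errors.

Weighted kappa uses Cicchetti–Allison linear weights
``w[i, j] = 1 - |i - j| / (C - 1)`` and the Fleiss–Cohen–Everitt
large-sample variance; the unweighted statistic is the same machinery
with identity weights.  Subjects missing either member of the pair are
excluded (pairwise-complete analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.inter_rater import cohens_kappa as _sm_kappa

from .dataset import POOLED, PairwiseCrossTab, TestPanelDataset, crosstab_pair

NONE = "none"
LINEAR = "linear"


class DegenerateTableError(ValueError):
    """Agreement undefined: empty table or chance agreement of 1."""


@dataclass(frozen=True)
class AgreementResult:
    pair: tuple[str, str]
    crude: float
    kappa: float
    kappa_weighted: float
    ase: float
    ase_weighted: float
    n: int


def linear_weights(C: int) -> np.ndarray:
    """Cicchetti–Allison agreement weights, 1 on the diagonal and
    decreasing linearly with category distance."""
    idx = np.arange(C)
    return 1.0 - np.abs(idx[:, None] - idx[None, :]) / (C - 1)


def crude_agreement(tab: PairwiseCrossTab) -> float:
    """Proportion of exact agreement among pairwise-complete subjects."""
    total = tab.counts.sum()
    if total == 0:
        raise DegenerateTableError("empty cross-tab: crude agreement undefined")
    return float(np.trace(tab.counts) / total)


def _kappa_one(counts: np.ndarray, weights: str) -> tuple[float, float]:
    p = counts / counts.sum()
    pe = p.sum(0) @ (linear_weights(counts.shape[0]) if weights == LINEAR else np.eye(counts.shape[0])) @ p.sum(1)
    if pe >= 1 - 1e-12:
        raise DegenerateTableError("chance agreement is 1: kappa undefined")
    res = _sm_kappa(counts, wt="ca" if weights == LINEAR else None)
    return float(res.kappa), float(res.std_kappa)


def cohen_kappa(tab: PairwiseCrossTab, weights: str = NONE) -> AgreementResult:
    """Chance-corrected agreement for one test pair.

    ``weights=NONE`` gives the classic unweighted kappa; ``LINEAR`` gives
    linear-weighted kappa.  The returned :class:`AgreementResult` carries
    both, plus crude agreement and asymptotic SEs, at full precision.
    """
    if weights not in (NONE, LINEAR):
        raise ValueError(f"weights must be {NONE!r} or {LINEAR!r}")
    if tab.counts.sum() == 0:
        raise DegenerateTableError("empty cross-tab: kappa undefined")
    k, ase = _kappa_one(tab.counts, NONE)
    kw, asew = _kappa_one(tab.counts, LINEAR)
    return AgreementResult(
        pair=(tab.first_test, tab.second_test),
        crude=crude_agreement(tab),
        kappa=k,
        kappa_weighted=kw,
        ase=ase,
        ase_weighted=asew,
        n=tab.n,
    )


def agreement_table(
    data: TestPanelDataset, stratum: object = POOLED
) -> pd.DataFrame:
    """Pairwise agreement summary over all test pairs of a panel."""
    rows = []
    T = data.n_tests
    for i in range(T):
        for j in range(i + 1, T):
            t1, t2 = data.test_names[i], data.test_names[j]
            tabs = crosstab_pair(data, t1, t2, stratify=stratum != POOLED)
            tab = next(t for t in tabs if t.stratum == stratum)
            r = cohen_kappa(tab)
            rows.append(
                {
                    "pair": f"{t1} and {t2}",
                    "n": r.n,
                    "crude": r.crude,
                    "kappa": r.kappa,
                    "ase": r.ase,
                    "kappa_weighted": r.kappa_weighted,
                    "ase_weighted": r.ase_weighted,
                }
            )
    return pd.DataFrame(rows)
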