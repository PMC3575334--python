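"""Synthetic panels from the assumed data-generating process.

Each subject draws a true class X ~ Categorical(pi), a binary outcome
~ Bernoulli(rho_X) (coded 1 = negative, 2 = SIL), and one call per test
from the class-conditional classification matrix theta_t[. | X] -
independently across tests, or jointly for a flagged pair via the same
log-linear agreement mechanism the dependence fitter uses.  Per-test
MCAR masking is applied last.  True classes are returned separately so
recovery tests can score the fits.

Defaults reproduce the study's scale and published operating points:
n = 911 women, four tests at the published classification probabilities,
prevalence matched to the observed marginal call distribution (about 61
expected SIL cases), and one-in-911 missingness on RFLP-2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import published
from .dataset import MISSING, ConfigError, TestPanelDataset, pattern_table  # noqa: F401

__all__ = ["GeneratorConfig", "generate", "pattern_table", "pair_joint_table"]


def _default_thetas() -> np.ndarray:
    return published.classification_matrices()


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition defaults for the synthetic panel generator."""

    n_subjects: int = 911
    prevalence: tuple[float, ...] = published.DEFAULT_PREVALENCE
    thetas: np.ndarray = field(default_factory=_default_thetas)
    outcome_risks: tuple[float, ...] | None = published.SIL_RISKS
    dependence: Mapping[tuple[str, str], float] | None = None
    missing_rates: tuple[float, ...] = (0.0, 0.0, 0.0, 1.0 / 911.0)
    test_names: tuple[str, ...] = published.TEST_NAMES
    category_labels: tuple[str, ...] = published.CATEGORY_LABELS
    seed: int = 20130218

    def __post_init__(self) -> None:
        pi = np.asarray(self.prevalence, dtype=float)
        thetas = np.asarray(self.thetas, dtype=float)
        object.__setattr__(self, "prevalence", tuple(pi))
        object.__setattr__(self, "thetas", thetas)
        C = pi.size
        T = len(self.test_names)
        if not np.isclose(pi.sum(), 1.0) or (pi < 0).any():
            raise ConfigError("prevalence must be a probability simplex")
        if thetas.shape != (T, C, C):
            raise ConfigError(f"thetas must have shape ({T}, {C}, {C})")
        if not np.allclose(thetas.sum(axis=1), 1.0) or (thetas < 0).any():
            raise ConfigError("every theta column must be a probability simplex")
        if self.outcome_risks is not None:
            rho = np.asarray(self.outcome_risks, dtype=float)
            if rho.shape != (C,) or (rho < 0).any() or (rho > 1).any():
                raise ConfigError("outcome_risks must be C probabilities")
        rates = np.asarray(self.missing_rates, dtype=float)
        if rates.shape != (T,) or (rates < 0).any() or (rates >= 1).any():
            raise ConfigError("missing_rates must be T probabilities in [0, 1)")
        if self.dependence:
            seen: set[str] = set()
            for a, b in self.dependence:
                if a not in self.test_names or b not in self.test_names or a == b:
                    raise ConfigError(f"bad dependence pair ({a}, {b})")
                if a in seen or b in seen:
                    raise ConfigError("a test may appear in at most one dependence pair")
                seen.update((a, b))

    @property
    def n_classes(self) -> int:
        return len(self.prevalence)


def pair_joint_table(
    theta_a: np.ndarray, theta_b: np.ndarray, lam: float
) -> np.ndarray:
    """Within-class joint C x C cell table for a dependent pair: product
    form times exp(lam) on the agreement diagonal, renormalized.  This is
    exactly the fitter's parameterization."""
    joint = np.outer(theta_a, theta_b)
    joint[np.diag_indices_from(joint)] *= np.exp(lam)
    return joint / joint.sum()


def generate(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[TestPanelDataset, np.ndarray]:
    """Draw a synthetic panel; returns ``(panel, true_classes)``.

    Deterministic for a fixed config (``seed`` overrides the config's)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, C, T = config.n_subjects, config.n_classes, len(config.test_names)
    pi = np.asarray(config.prevalence)
    thetas = config.thetas

    x = rng.choice(C, size=n, p=pi)  # 0-based true class

    outcome = None
    if config.outcome_risks is not None:
        rho = np.asarray(config.outcome_risks)
        outcome = 1 + (rng.random(n) < rho[x]).astype(np.int64)

    calls = np.zeros((n, T), dtype=np.int64)
    dep = dict(config.dependence or {})
    dep_idx = {
        (config.test_names.index(a), config.test_names.index(b)): lam
        for (a, b), lam in dep.items()
    }
    in_pair = {t for ab in dep_idx for t in ab}

    for c in range(C):
        sel = np.where(x == c)[0]
        if sel.size == 0:
            continue
        for t in range(T):
            if t in in_pair:
                continue
            calls[sel, t] = rng.choice(C, size=sel.size, p=thetas[t, :, c]) + 1
        for (a, b), lam in dep_idx.items():
            joint = pair_joint_table(thetas[a, :, c], thetas[b, :, c], lam)
            cells = rng.choice(C * C, size=sel.size, p=joint.ravel())
            calls[sel, a] = cells // C + 1
            calls[sel, b] = cells % C + 1

    for t, rate in enumerate(config.missing_rates):
        if rate > 0:
            calls[rng.random(n) < rate, t] = MISSING

    panel = TestPanelDataset(
        subject_id=np.array([f"SIM{i:06d}" for i in range(n)]),
        calls=calls,
        test_names=config.test_names,
        category_labels=config.category_labels,
        outcome=outcome,
    )
    return panel, x + 1
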