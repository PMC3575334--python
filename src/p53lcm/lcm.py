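"""Latent class model for T fallible categorical tests, no gold standard.

An unobserved class X in {1..C} (the true p53 genotype) has prevalence
pi_c; test t reports category r with classification probability
theta_t[r | c] = P(call r | X = c), conditionally independent across
tests given X.  A subject with calls r_1..r_T (missing slots skipped)
contributes

    L = sum_c pi_c * prod_{t observed} theta_t[r_t | c]

to the likelihood, which is maximized by EM: the E-step computes each
subject's posterior class membership, the M-step re-estimates pi and the
theta columns as posterior-weighted proportions (closed form).  With
T >= 3 independent tests the model is identified without any reference
standard; estimation uses the grouped representation over distinct
response patterns, which is exactly equivalent to subject-level fitting.

Multimodality is the known failure mode, so every fit runs a moment-style
start plus ``n_restarts`` random restarts and keeps the best local
maximum.  Latent class labels are aligned by maximizing total diagonal
classification mass, so class c is interpreted as genotype c.  Standard
errors come from the numerical observed information on a minimal
parameterization (each simplex loses its last element), with the delta
method recovering the removed elements; parameters that converge to the
boundary (0 or 1) are reported as exact with SE 0 and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations
from typing import Sequence

import numpy as np

from .dataset import (
    MISSING,
    ConfigError,
    TestPanelDataset,
    pattern_table,
)

PROB_FLOOR = 1e-12
BOUNDARY_TOL = 1e-6

NONE = "none"
EQUAL_ACCURACY = "equal_accuracy"


class IdentifiabilityError(ValueError):
    """More free parameters than the data can support."""


@dataclass(frozen=True)
class EmSettings:
    max_iter: int = 5000
    rel_tol: float = 1e-8
    n_restarts: int = 20
    seed: int = 20130218


@dataclass(frozen=True)
class LcmSpec:
    """Model configuration: C latent classes for the named tests, with an
    optional equal-accuracy-across-tests constraint."""

    n_classes: int
    test_names: tuple[str, ...]
    constraint: str = NONE
    em: EmSettings = field(default_factory=EmSettings)

    def __post_init__(self) -> None:
        object.__setattr__(self, "test_names", tuple(self.test_names))
        if self.n_classes < 2:
            raise ConfigError("need at least 2 latent classes")
        if self.constraint not in (NONE, EQUAL_ACCURACY):
            raise ConfigError(f"unknown constraint {self.constraint!r}")
        if self.constraint == NONE and len(self.test_names) < 3:
            raise ConfigError(
                "an unconstrained latent class model needs three or more tests"
            )

    @property
    def n_params(self) -> int:
        C, T = self.n_classes, len(self.test_names)
        theta_free = C * (C - 1) if self.constraint == EQUAL_ACCURACY else T * C * (C - 1)
        return (C - 1) + theta_free


@dataclass(frozen=True)
class LcmFit:
    spec: LcmSpec
    prevalence: np.ndarray          # (C,)
    theta: np.ndarray               # (T, C, C): [t, r, c] = P(r | c)
    loglik: float
    se_prevalence: np.ndarray | None
    se_theta: np.ndarray | None
    boundary_prevalence: np.ndarray  # bool (C,)
    boundary_theta: np.ndarray       # bool (T, C, C)
    n_params: int
    converged: bool
    em_converged: bool
    identified: bool
    n_subjects: int
    n_iter: int
    ll_history: tuple[float, ...]

    @property
    def has_boundary(self) -> bool:
        return bool(self.boundary_prevalence.any() or self.boundary_theta.any())


# ---------------------------------------------------------------------------
# likelihood pieces

def _class_lik(patterns: np.ndarray, pi: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    """f[p, c] = pi_c * prod over observed tests of theta_t[r | c]."""
    f = np.broadcast_to(pi, (patterns.shape[0], pi.size)).copy()
    for t in range(patterns.shape[1]):
        r = patterns[:, t]
        obs = r != MISSING
        f[obs] *= thetas[t, r[obs] - 1, :]
    return f


def subject_likelihood(
    calls: Sequence[int], pi: np.ndarray, thetas: np.ndarray
) -> float:
    """Marginal likelihood of one subject's call vector (missing = 0)."""
    calls = np.asarray(calls, dtype=np.int64).reshape(1, -1)
    if (calls == MISSING).all():
        warnings.warn("all calls missing: subject contributes likelihood 1")
    return float(_class_lik(calls, np.asarray(pi, float), np.asarray(thetas, float)).sum())


def loglik_dataset(
    data: TestPanelDataset | tuple[np.ndarray, np.ndarray],
    pi: np.ndarray,
    thetas: np.ndarray,
) -> float:
    """Sum of log subject likelihoods (grouped over response patterns).

    Zero-probability patterns are floored at ``PROB_FLOOR`` with a
    warning rather than returning -inf.
    """
    patterns, counts = _as_patterns(data)
    lik = _class_lik(patterns, np.asarray(pi, float), np.asarray(thetas, float)).sum(1)
    if (lik <= PROB_FLOOR).any():
        warnings.warn("zero-probability response pattern: log-likelihood floored")
    return float(counts @ np.log(np.maximum(lik, PROB_FLOOR)))


def posterior_class(fit: LcmFit, calls: Sequence[int]) -> np.ndarray:
    """Posterior P(X = c | calls) under a fitted model; the prior for an
    all-missing call vector."""
    calls = np.asarray(calls, dtype=np.int64).reshape(1, -1)
    f = _class_lik(calls, fit.prevalence, fit.theta)[0]
    total = f.sum()
    if total <= 0:
        return fit.prevalence.copy()
    return f / total


# ---------------------------------------------------------------------------
# EM

def _m_step(
    patterns: np.ndarray,
    counts: np.ndarray,
    w: np.ndarray,
    C: int,
    constraint: str,
) -> tuple[np.ndarray, np.ndarray]:
    wc = w * counts[:, None]
    pi = wc.sum(0)
    pi = pi / pi.sum()
    T = patterns.shape[1]
    num = np.zeros((T, C, C))
    for t in range(T):
        r = patterns[:, t]
        for cat in range(1, C + 1):
            sel = r == cat
            if sel.any():
                num[t, cat - 1] = wc[sel].sum(0)
    if constraint == EQUAL_ACCURACY:
        num[:] = num.sum(0, keepdims=True)
    denom = num.sum(1, keepdims=True)  # observed posterior mass per (t, c)
    theta = np.divide(num, denom, out=np.full_like(num, 1.0 / C), where=denom > 0)
    return pi, theta


def _em_run(
    patterns: np.ndarray,
    counts: np.ndarray,
    pi: np.ndarray,
    thetas: np.ndarray,
    constraint: str,
    settings: EmSettings,
) -> tuple[np.ndarray, np.ndarray, float, list[float], bool, int]:
    C = pi.size
    history: list[float] = []
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, settings.max_iter + 1):
        f = _class_lik(patterns, pi, thetas)
        lik = np.maximum(f.sum(1), PROB_FLOOR)
        ll = float(counts @ np.log(lik))
        if ll < ll_prev - 1e-8 * (abs(ll_prev) + 1.0):
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {it}: {ll_prev} -> {ll}"
            )
        history.append(ll)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= settings.rel_tol * (abs(ll_prev) + 1e-10):
            converged = True
            break
        ll_prev = ll
        w = f / lik[:, None]
        pi, thetas = _m_step(patterns, counts, w, C, constraint)
        pi = np.maximum(pi, PROB_FLOOR)
        pi /= pi.sum()
        thetas = np.maximum(thetas, PROB_FLOOR)
        thetas /= thetas.sum(1, keepdims=True)
    return pi, thetas, history[-1], history, converged, it


def _moment_start(
    patterns: np.ndarray, counts: np.ndarray, C: int, T: int
) -> tuple[np.ndarray, np.ndarray]:
    """Near-diagonal theta plus the average empirical call distribution:
    assumes tests are better than chance, which anchors class labels."""
    marg = np.zeros(C)
    for t in range(T):
        r = patterns[:, t]
        obs = r != MISSING
        marg += np.bincount(r[obs] - 1, weights=counts[obs], minlength=C)
    marg = marg / marg.sum() if marg.sum() > 0 else np.full(C, 1.0 / C)
    theta0 = 0.6 * np.eye(C) + 0.4 / C
    return marg, np.tile(theta0, (T, 1, 1))


def _random_start(rng: np.random.Generator, C: int, T: int) -> tuple[np.ndarray, np.ndarray]:
    pi = rng.dirichlet(np.ones(C))
    thetas = rng.dirichlet(np.ones(C), size=(T, C)).swapaxes(1, 2)
    return pi, thetas


def _align_labels(
    pi: np.ndarray, thetas: np.ndarray
) -> tuple[np.ndarray, np.ndarray, tuple[int, ...]]:
    """Permute latent classes to maximize total diagonal classification
    mass; ties broken by descending prevalence."""
    C = pi.size
    best = None
    for perm in permutations(range(C)):
        diag = sum(thetas[:, c, perm[c]].sum() for c in range(C))
        key = (round(diag, 12), tuple(pi[list(perm)]))
        if best is None or key > best[0]:
            best = (key, perm)
    perm = list(best[1])
    return pi[perm], thetas[:, :, perm], tuple(perm)


def _as_patterns(
    data: TestPanelDataset | tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, TestPanelDataset):
        return pattern_table(data)
    patterns, counts = data
    return np.asarray(patterns, dtype=np.int64), np.asarray(counts, dtype=np.float64)


# ---------------------------------------------------------------------------
# standard errors on the minimal parameterization

def _numeric_hessian(
    f, x, h: float = 1e-5, steps=None
):
    k = x.size
    H = np.empty((k, k))
    hs = h * np.maximum(np.abs(x), 0.1) if steps is None else steps
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k); ei[i] = hs[i]
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / hs[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k); ej[j] = hs[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * hs[i] * hs[j])
    return H


class SimplexPacker:
    """Minimal parameterization of a list of probability simplexes.

    Per block, entries at the boundary (within ``BOUNDARY_TOL`` of 0 or
    1) are held fixed, the largest interior entry is removed (recovered
    as one minus the rest, so small perturbations of the free entries
    never cross a simplex edge), and the remaining interior entries are
    the free parameters.  ``ses`` recovers delta-method SEs for every
    entry: sqrt of the covariance diagonal for free entries, the summed
    block covariance for the removed entry, and 0 for fixed ones.
    """

    def __init__(self, blocks):
        self.values = [np.asarray(b, dtype=float) for b in blocks]
        self.free_idx = []
        self.dep_idx = []
        self.offsets = []
        k = 0
        for b in self.values:
            interior = np.where((b > BOUNDARY_TOL) & (b < 1 - BOUNDARY_TOL))[0]
            if interior.size == 0:
                dep, free = None, np.array([], dtype=int)
            else:
                dep = interior[np.argmax(b[interior])]
                free = interior[interior != dep]
            self.offsets.append(k)
            self.free_idx.append(free)
            self.dep_idx.append(dep)
            k += free.size
        self.n_free = k

    def pack(self):
        if self.n_free == 0:
            return np.empty(0)
        return np.concatenate([b[f] for b, f in zip(self.values, self.free_idx)])

    def unpack(self, x):
        out = []
        for b, f, d, o in zip(self.values, self.free_idx, self.dep_idx, self.offsets):
            v = b.copy()
            v[f] = x[o : o + f.size]
            if d is not None:
                v[d] = 1.0 - (v.sum() - v[d])
            out.append(v)
        return out

    def steps(self, h: float = 1e-5):
        x = self.pack()
        base = h * np.maximum(np.abs(x), 0.1)
        return np.minimum(base, np.maximum(0.4 * np.minimum(x, 1 - x), 1e-10))

    def ses(self, cov):
        out = []
        for b, f, d, o in zip(self.values, self.free_idx, self.dep_idx, self.offsets):
            se = np.zeros_like(b)
            sub = cov[o : o + f.size, o : o + f.size]
            se[f] = np.sqrt(np.maximum(np.diag(sub), 0.0))
            if d is not None:
                se[d] = np.sqrt(max(sub.sum(), 0.0))
            out.append(se)
        return out

    def covariance(self, negll):
        """Inverse numerical observed information on the free entries."""
        if self.n_free == 0:
            return np.zeros((0, 0))
        H = _numeric_hessian(negll, self.pack(), steps=self.steps())
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < -1e-8):
            warnings.warn(
                "observed information matrix rank-deficient or indefinite; "
                "SEs from pseudo-inverse are unreliable"
            )
            cov = np.abs(np.linalg.pinv(H))
        return cov


def _theta_blocks(thetas: np.ndarray, constraint: str):
    Teff = 1 if constraint == EQUAL_ACCURACY else thetas.shape[0]
    return [thetas[t, :, c] for t in range(Teff) for c in range(thetas.shape[2])]


def _thetas_from_blocks(blocks, C: int, T: int, constraint: str) -> np.ndarray:
    th = np.stack(blocks).reshape(-1, C, C).swapaxes(1, 2)
    if constraint == EQUAL_ACCURACY:
        th = np.tile(th, (T, 1, 1))
    return th


def _assemble_theta_ses(ses, C: int, T: int, constraint: str) -> np.ndarray:
    Teff = 1 if constraint == EQUAL_ACCURACY else T
    se_theta = np.empty((Teff, C, C))
    k = 0
    for t in range(Teff):
        for c in range(C):
            se_theta[t, :, c] = ses[k]
            k += 1
    if constraint == EQUAL_ACCURACY:
        se_theta = np.tile(se_theta, (T, 1, 1))
    return se_theta


def _standard_errors(
    patterns: np.ndarray,
    counts: np.ndarray,
    pi: np.ndarray,
    thetas: np.ndarray,
    constraint: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Delta-method SEs for all probabilities from the observed
    information on the free (simplex-minimal) parameters.  Boundary
    probabilities are held fixed and get SE 0."""
    C, T = pi.size, thetas.shape[0]
    packer = SimplexPacker([pi, *_theta_blocks(thetas, constraint)])

    def negll(x: np.ndarray) -> float:
        blocks = packer.unpack(x)
        th = _thetas_from_blocks(blocks[1:], C, T, constraint)
        f = _class_lik(
            patterns, np.maximum(blocks[0], PROB_FLOOR), np.maximum(th, PROB_FLOOR)
        )
        return -float(counts @ np.log(np.maximum(f.sum(1), PROB_FLOOR)))

    ses = packer.ses(packer.covariance(negll))
    return ses[0], _assemble_theta_ses(ses[1:], C, T, constraint)


# ---------------------------------------------------------------------------

def fit_lcm(
    data: TestPanelDataset | tuple[np.ndarray, np.ndarray],
    spec: LcmSpec,
    compute_se: bool = True,
) -> LcmFit:
    """Maximum-likelihood latent class fit by EM with restarts.

    ``data`` is a panel or a grouped ``(patterns, counts)`` pair (the two
    give identical results).  The fit is flagged unidentified - and hence
    not converged - when the free-parameter count exceeds the number of
    distinct observed response patterns minus one.
    """
    patterns, counts = _as_patterns(data)
    C, T = spec.n_classes, len(spec.test_names)
    if patterns.shape[1] != T:
        raise ConfigError(
            f"data has {patterns.shape[1]} tests but spec names {T}"
        )
    n_subjects = int(counts.sum())
    if n_subjects == 0 or not ((patterns != MISSING).any(axis=1) * counts).any():
        raise ConfigError("no subjects with any observed call")
    identified = spec.n_params <= patterns.shape[0] - 1
    if not identified:
        warnings.warn(
            f"{spec.n_params} free parameters but only {patterns.shape[0]} "
            "distinct response patterns: model not identified by these data"
        )

    rng = np.random.default_rng(spec.em.seed)
    starts = [_moment_start(patterns, counts, C, T)]
    starts += [_random_start(rng, C, T) for _ in range(spec.em.n_restarts)]
    best = None
    for pi0, th0 in starts:
        result = _em_run(patterns, counts, pi0, th0, spec.constraint, spec.em)
        if best is None or result[2] > best[2]:
            best = result
    pi, thetas, ll, history, em_converged, n_iter = best
    if not em_converged:
        warnings.warn(f"EM did not converge within {spec.em.max_iter} iterations")
    pi, thetas, _ = _align_labels(pi, thetas)

    boundary_pi = (pi <= BOUNDARY_TOL) | (pi >= 1 - BOUNDARY_TOL)
    boundary_theta = (thetas <= BOUNDARY_TOL) | (thetas >= 1 - BOUNDARY_TOL)
    pi_out = np.where(pi <= BOUNDARY_TOL, 0.0, pi)
    theta_out = np.where(thetas <= BOUNDARY_TOL, 0.0, thetas)

    se_pi = se_theta = None
    if compute_se:
        se_pi, se_theta = _standard_errors(patterns, counts, pi, thetas, spec.constraint)
        se_pi = np.where(boundary_pi, 0.0, se_pi)
        se_theta = np.where(boundary_theta, 0.0, se_theta)

    return LcmFit(
        spec=spec,
        prevalence=pi_out,
        theta=theta_out,
        loglik=ll,
        se_prevalence=se_pi,
        se_theta=se_theta,
        boundary_prevalence=boundary_pi,
        boundary_theta=boundary_theta,
        n_params=spec.n_params,
        converged=em_converged and identified,
        em_converged=em_converged,
        identified=identified,
        n_subjects=n_subjects,
        n_iter=n_iter,
        ll_history=tuple(history),
    )
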