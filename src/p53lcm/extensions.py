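"""Extensions of the basic latent class model.

* outcome model: the latent genotype additionally drives a binary
  outcome (two-year cumulative SIL risk rho_c per class), yielding
  misclassification-corrected odds ratios against a reference genotype;
* stratified accuracy: classification probabilities allowed to differ by
  outcome stratum, testable against the pooled model;
* conditional dependence: a log-linear agreement term for flagged test
  pairs, relaxing conditional independence;
* likelihood ratio tests between nested fits, with a Bonferroni screen
  over all pairwise dependence terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dataset import (
    MISSING,
    ConfigError,
    TestPanelDataset,
)
from .lcm import (
    BOUNDARY_TOL,
    PROB_FLOOR,
    IdentifiabilityError,
    LcmFit,
    LcmSpec,
    _align_labels,
    _class_lik,
    _m_step,
    _moment_start,
    _numeric_hessian,
    _random_start,
    fit_lcm,
)

PAIR = "pair"
PAIR_CLASS = "pair_class"


class InconsistentFitError(ValueError):
    """Null fit beat the alternative: optimizer failure somewhere."""


@dataclass(frozen=True)
class OddsRatioEstimate:
    odds_ratio: float
    se: float
    ci_low: float
    ci_high: float
    scale: str


@dataclass(frozen=True)
class OutcomeModelFit:
    """Latent class fit plus per-class outcome risks and odds ratios."""

    lcm: LcmFit
    rho: np.ndarray                     # (C,) per-class outcome risk
    se_rho: np.ndarray | None
    boundary_rho: np.ndarray
    odds_ratios: dict[int, OddsRatioEstimate]  # class (1-based) -> OR vs ref
    ref_class: int

    @property
    def loglik(self) -> float:
        return self.lcm.loglik

    @property
    def n_params(self) -> int:
        return self.lcm.n_params + self.rho.size

    @property
    def converged(self) -> bool:
        return self.lcm.converged

    @property
    def has_boundary(self) -> bool:
        return bool(self.lcm.has_boundary or self.boundary_rho.any())


def odds_ratio_from_risks(
    rho_c: float,
    rho_ref: float,
    se_rho_c: float = 0.0,
    se_rho_ref: float = 0.0,
    cov: float = 0.0,
    scale: str = "or",
    alpha: float = 0.05,
) -> OddsRatioEstimate:
    """Odds ratio between two per-class risks with a delta-method CI.

    ``scale="or"`` gives the symmetric Wald interval on the OR scale
    (the published presentation); ``"log"`` the log-scale interval.
    """
    for r in (rho_c, rho_ref):
        if not 0.0 < r < 1.0:
            raise ValueError(f"risk {r} at boundary: odds ratio undefined")
    orr = (rho_c / (1 - rho_c)) / (rho_ref / (1 - rho_ref))
    g_c = orr / (rho_c * (1 - rho_c))
    g_ref = -orr / (rho_ref * (1 - rho_ref))
    var = (
        g_c**2 * se_rho_c**2 + g_ref**2 * se_rho_ref**2 + 2 * g_c * g_ref * cov
    )
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(1 - alpha / 2)
    if scale == "log":
        se_log = se / orr if orr > 0 else np.nan
        lo, hi = orr * np.exp(-z * se_log), orr * np.exp(z * se_log)
    elif scale == "or":
        lo, hi = orr - z * se, orr + z * se
    else:
        raise ValueError("scale must be 'or' or 'log'")
    return OddsRatioEstimate(float(orr), se, float(lo), float(hi), scale)


# ---------------------------------------------------------------------------
# Model 2: latent class + outcome risk

def _outcome_class_lik(
    patterns: np.ndarray, pi: np.ndarray, thetas: np.ndarray, rho: np.ndarray
) -> np.ndarray:
    """Pattern rows carry the outcome in the last column (0 missing)."""
    f = _class_lik(patterns[:, :-1], pi, thetas)
    d = patterns[:, -1]
    f[d == 1] *= (1 - rho)
    f[d == 2] *= rho
    return f


def fit_lcm_outcome(
    data: TestPanelDataset,
    spec: LcmSpec,
    ref_class: int = 3,
    compute_se: bool = True,
    or_scale: str = "or",
) -> OutcomeModelFit:
    """Joint maximum likelihood for genotype accuracy and outcome risk.

    The latent class drives both the T test calls and the binary outcome
    (risk rho_c), with test accuracy independent of the outcome.  With no
    observed outcome at all, this reduces exactly to the basic model and
    rho is undefined (NaN).
    """
    C, T = spec.n_classes, len(spec.test_names)
    if not 1 <= ref_class <= C:
        raise ConfigError(f"ref_class must be in 1..{C}")
    if data.outcome is None or (np.asarray(data.outcome) == MISSING).all():
        base = fit_lcm(data.without_outcome() if data.outcome is not None else data,
                       spec, compute_se=compute_se)
        nan = np.full(C, np.nan)
        return OutcomeModelFit(
            lcm=base, rho=nan, se_rho=None,
            boundary_rho=np.zeros(C, dtype=bool), odds_ratios={}, ref_class=ref_class,
        )

    cols = np.column_stack([data.calls, data.outcome])
    patterns, counts = np.unique(cols, axis=0, return_counts=True)
    counts = counts.astype(float)
    n_subjects = int(counts.sum())
    n_params = spec.n_params + C
    identified = n_params <= patterns.shape[0] - 1
    if not identified:
        warnings.warn("outcome model not identified by these data")

    rng = np.random.default_rng(spec.em.seed)
    d = patterns[:, -1]
    obs_rate = counts[d == 2].sum() / max(counts[d != MISSING].sum(), 1.0)

    def em(pi0, th0, rho0):
        pi, thetas, rho = pi0.copy(), th0.copy(), rho0.copy()
        history, ll_prev, converged, it = [], -np.inf, False, 0
        for it in range(1, spec.em.max_iter + 1):
            f = _outcome_class_lik(patterns, pi, thetas, rho)
            lik = np.maximum(f.sum(1), PROB_FLOOR)
            ll = float(counts @ np.log(lik))
            if ll < ll_prev - 1e-8 * (abs(ll_prev) + 1.0):
                raise RuntimeError("EM log-likelihood decreased")
            history.append(ll)
            if np.isfinite(ll_prev) and abs(ll - ll_prev) <= spec.em.rel_tol * (abs(ll_prev) + 1e-10):
                converged = True
                break
            ll_prev = ll
            w = f / lik[:, None]
            pi, thetas = _m_step(patterns[:, :-1], counts, w, C, spec.constraint)
            wc = w * counts[:, None]
            num = wc[d == 2].sum(0)
            den = wc[d != MISSING].sum(0)
            rho = np.divide(num, den, out=np.full(C, obs_rate), where=den > 0)
            pi = np.maximum(pi, PROB_FLOOR); pi /= pi.sum()
            thetas = np.maximum(thetas, PROB_FLOOR)
            thetas /= thetas.sum(1, keepdims=True)
            rho = np.clip(rho, PROB_FLOOR, 1 - PROB_FLOOR)
        return pi, thetas, rho, history[-1], history, converged, it

    starts = [(_moment_start(patterns[:, :-1], counts, C, T), np.full(C, obs_rate))]
    for _ in range(spec.em.n_restarts):
        starts.append((_random_start(rng, C, T), rng.uniform(0.01, 0.5, C)))
    best = None
    for (pi0, th0), rho0 in starts:
        result = em(pi0, th0, np.asarray(rho0, float))
        if best is None or result[3] > best[3]:
            best = result
    pi, thetas, rho, ll, history, em_converged, n_iter = best
    if not em_converged:
        warnings.warn(f"EM did not converge within {spec.em.max_iter} iterations")
    pi, thetas, perm = _align_labels(pi, thetas)
    rho = rho[list(perm)]

    boundary_pi = (pi <= BOUNDARY_TOL) | (pi >= 1 - BOUNDARY_TOL)
    boundary_theta = (thetas <= BOUNDARY_TOL) | (thetas >= 1 - BOUNDARY_TOL)
    boundary_rho = (rho <= BOUNDARY_TOL) | (rho >= 1 - BOUNDARY_TOL)

    se_pi = se_theta = se_rho = None
    cov_rho = np.zeros((C, C))
    if compute_se:
        se_pi, se_theta, se_rho, cov_rho = _outcome_standard_errors(
            patterns, counts, pi, thetas, rho, spec.constraint
        )
        se_pi = np.where(boundary_pi, 0.0, se_pi)
        se_theta = np.where(boundary_theta, 0.0, se_theta)
        se_rho = np.where(boundary_rho, 0.0, se_rho)

    odds_ratios: dict[int, OddsRatioEstimate] = {}
    r0 = ref_class - 1
    for c in range(C):
        if c == r0:
            odds_ratios[c + 1] = OddsRatioEstimate(1.0, 0.0, np.nan, np.nan, or_scale)
            continue
        if boundary_rho[c] or boundary_rho[r0]:
            warnings.warn(f"risk at boundary: OR for class {c + 1} undefined")
            odds_ratios[c + 1] = OddsRatioEstimate(np.nan, np.nan, np.nan, np.nan, or_scale)
            continue
        odds_ratios[c + 1] = odds_ratio_from_risks(
            rho[c], rho[r0],
            0.0 if se_rho is None else se_rho[c],
            0.0 if se_rho is None else se_rho[r0],
            cov=cov_rho[c, r0],
            scale=or_scale,
        )

    lcm_fit = LcmFit(
        spec=spec,
        prevalence=np.where(boundary_pi & (pi <= BOUNDARY_TOL), 0.0, pi),
        theta=np.where(boundary_theta & (thetas <= BOUNDARY_TOL), 0.0, thetas),
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
    return OutcomeModelFit(
        lcm=lcm_fit,
        rho=np.where(boundary_rho & (rho <= BOUNDARY_TOL), 0.0, rho),
        se_rho=se_rho,
        boundary_rho=boundary_rho,
        odds_ratios=odds_ratios,
        ref_class=ref_class,
    )


def _outcome_standard_errors(patterns, counts, pi, thetas, rho, constraint):
    from .lcm import (
        SimplexPacker,
        _assemble_theta_ses,
        _theta_blocks,
        _thetas_from_blocks,
    )

    C, T = pi.size, thetas.shape[0]
    # each risk is its own 2-simplex block (rho_c, 1 - rho_c)
    rho_blocks = [np.array([r, 1.0 - r]) for r in rho]
    packer = SimplexPacker([pi, *_theta_blocks(thetas, constraint), *rho_blocks])

    def negll(x):
        blocks = packer.unpack(x)
        th = _thetas_from_blocks(blocks[1:-C], C, T, constraint)
        r = np.array([b[0] for b in blocks[-C:]])
        f = _outcome_class_lik(
            patterns, np.maximum(blocks[0], PROB_FLOOR), np.maximum(th, PROB_FLOOR),
            np.clip(r, PROB_FLOOR, 1 - PROB_FLOOR),
        )
        return -float(counts @ np.log(np.maximum(f.sum(1), PROB_FLOOR)))

    cov = packer.covariance(negll)
    ses = packer.ses(cov)
    se_pi = ses[0]
    se_theta = _assemble_theta_ses(ses[1 : 1 + len(_theta_blocks(thetas, constraint))], C, T, constraint)
    se_rho = np.array([s[0] for s in ses[-C:]])
    # covariance between the per-class risks, with a sign flip when the
    # free entry of a block is the complement 1 - rho
    cov_rho = np.zeros((C, C))
    rho_pos = len(packer.values) - C
    for i in range(C):
        for j in range(C):
            bi, bj = rho_pos + i, rho_pos + j
            fi, fj = packer.free_idx[bi], packer.free_idx[bj]
            if fi.size == 0 or fj.size == 0:
                continue
            si = 1.0 if fi[0] == 0 else -1.0
            sj = 1.0 if fj[0] == 0 else -1.0
            cov_rho[i, j] = si * sj * cov[packer.offsets[bi], packer.offsets[bj]]
    return se_pi, se_theta, se_rho, cov_rho


# ---------------------------------------------------------------------------
# stratified accuracy

@dataclass(frozen=True)
class StratifiedAccuracyFit:
    """Per-stratum classification probabilities with (optionally) shared
    prevalence; the joint log-likelihood supports an LRT against the
    pooled-accuracy model."""

    spec: LcmSpec
    strata: tuple[int, ...]
    prevalence: dict[int, np.ndarray]
    theta: dict[int, np.ndarray]
    loglik: float
    n_params: int
    converged: bool
    em_converged: bool
    identified: bool
    share_prevalence: bool
    n_subjects: int
    boundary_theta: dict[int, np.ndarray]

    @property
    def has_boundary(self) -> bool:
        return any(b.any() for b in self.boundary_theta.values())


def fit_lcm_stratified_accuracy(
    data: TestPanelDataset,
    spec: LcmSpec,
    share_prevalence: bool = True,
) -> StratifiedAccuracyFit:
    """Let test accuracy differ by outcome stratum.

    Doubles the classification-probability count, which routinely
    exhausts small strata; such fits come back ``converged=False``
    (unidentified) rather than raising.
    """
    if data.outcome is None:
        raise ConfigError("stratified accuracy requires an outcome column")
    C, T = spec.n_classes, len(spec.test_names)
    strata = (1, 2)
    masks = {s: np.asarray(data.outcome) == s for s in strata}
    if any(not m.any() for m in masks.values()):
        raise ConfigError("every outcome stratum must be non-empty")

    pats, cnts, sidx = [], [], []
    for k, s in enumerate(strata):
        p, c = np.unique(data.calls[masks[s]], axis=0, return_counts=True)
        pats.append(p); cnts.append(c.astype(float)); sidx.append(np.full(len(c), k))
    patterns = np.vstack(pats)
    counts = np.concatenate(cnts)
    stratum_of = np.concatenate(sidx)

    n_theta = 2 * T * C * (C - 1)
    n_params = ((C - 1) if share_prevalence else 2 * (C - 1)) + n_theta
    identified = n_params <= patterns.shape[0] - 2
    if not identified:
        warnings.warn(
            "stratified-accuracy model not identified: "
            f"{n_params} parameters vs {patterns.shape[0]} distinct patterns"
        )

    rng = np.random.default_rng(spec.em.seed)
    settings = spec.em

    def em(pi0s, th0s):
        pis = [p.copy() for p in pi0s]
        ths = [t.copy() for t in th0s]
        ll_prev, converged = -np.inf, False
        for _ in range(settings.max_iter):
            f = np.empty((patterns.shape[0], C))
            for k in range(2):
                sel = stratum_of == k
                f[sel] = _class_lik(patterns[sel], pis[k], ths[k])
            lik = np.maximum(f.sum(1), PROB_FLOOR)
            ll = float(counts @ np.log(lik))
            if ll < ll_prev - 1e-8 * (abs(ll_prev) + 1.0):
                raise RuntimeError("EM log-likelihood decreased")
            if np.isfinite(ll_prev) and abs(ll - ll_prev) <= settings.rel_tol * (abs(ll_prev) + 1e-10):
                converged = True
                break
            ll_prev = ll
            w = f / lik[:, None]
            new_pis = []
            for k in range(2):
                sel = stratum_of == k
                pi_k, th_k = _m_step(patterns[sel], counts[sel], w[sel], C, spec.constraint)
                th_k = np.maximum(th_k, PROB_FLOOR)
                ths[k] = th_k / th_k.sum(1, keepdims=True)
                new_pis.append(pi_k)
            if share_prevalence:
                wc = w * counts[:, None]
                pooled = wc.sum(0)
                pooled = np.maximum(pooled / pooled.sum(), PROB_FLOOR)
                pis = [pooled / pooled.sum()] * 2
            else:
                pis = [np.maximum(p, PROB_FLOOR) / np.maximum(p, PROB_FLOOR).sum() for p in new_pis]
        return pis, ths, ll, converged

    starts = []
    m_pi, m_th = _moment_start(patterns, counts, C, T)
    starts.append(([m_pi, m_pi.copy()], [m_th, m_th.copy()]))
    for _ in range(settings.n_restarts):
        p1, t1 = _random_start(rng, C, T)
        p2, t2 = _random_start(rng, C, T)
        starts.append(([p1, p2], [t1, t2]))
    best = None
    for pi0s, th0s in starts:
        result = em(pi0s, th0s)
        if best is None or result[2] > best[2]:
            best = result
    pis, ths, ll, em_converged = best

    # align labels jointly so the two strata describe the same classes
    stacked = np.concatenate(ths, axis=0)
    _, _, perm = _align_labels(sum(pis) / 2, stacked)
    perm = list(perm)
    prevalence = {s: pis[k][perm] for k, s in enumerate(strata)}
    theta = {s: ths[k][:, :, perm] for k, s in enumerate(strata)}
    boundary = {
        s: (theta[s] <= BOUNDARY_TOL) | (theta[s] >= 1 - BOUNDARY_TOL) for s in strata
    }
    return StratifiedAccuracyFit(
        spec=spec,
        strata=strata,
        prevalence=prevalence,
        theta=theta,
        loglik=ll,
        n_params=n_params,
        converged=em_converged and identified,
        em_converged=em_converged,
        identified=identified,
        share_prevalence=share_prevalence,
        n_subjects=int(counts.sum()),
        boundary_theta=boundary,
    )


# ---------------------------------------------------------------------------
# conditional dependence

@dataclass(frozen=True)
class DependenceSpec:
    """Test pairs carrying a within-class log-linear agreement term.

    ``sharing="pair"`` estimates one association per pair (shared across
    classes); ``"pair_class"`` one per pair and class.  A test may appear
    in at most one pair (the pairwise factorization is otherwise
    ill-defined).
    """

    pairs: tuple[tuple[str, str], ...]
    sharing: str = PAIR

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(tuple(p) for p in self.pairs))
        if self.sharing not in (PAIR, PAIR_CLASS):
            raise ConfigError("sharing must be 'pair' or 'pair_class'")
        seen: set[str] = set()
        for a, b in self.pairs:
            if a == b:
                raise ConfigError(f"pair ({a}, {b}) is degenerate")
            if a in seen or b in seen:
                raise ConfigError("a test may appear in at most one dependence pair")
            seen.update((a, b))

    def n_lambda(self, n_classes: int) -> int:
        per = n_classes if self.sharing == PAIR_CLASS else 1
        return per * len(self.pairs)


@dataclass(frozen=True)
class DependentLcmFit:
    spec: LcmSpec
    dep: DependenceSpec
    prevalence: np.ndarray
    theta: np.ndarray
    lambdas: np.ndarray          # (n_pairs, C) or (n_pairs, 1)
    se_lambda: np.ndarray | None
    loglik: float
    n_params: int
    converged: bool
    n_subjects: int
    boundary_theta: np.ndarray

    @property
    def has_boundary(self) -> bool:
        return bool(self.boundary_theta.any())


def _dep_class_lik(
    patterns: np.ndarray,
    pi: np.ndarray,
    thetas: np.ndarray,
    pair_idx: Sequence[tuple[int, int]],
    lam: np.ndarray,  # (n_pairs, C)
) -> np.ndarray:
    C = pi.size
    in_pair = {t for ab in pair_idx for t in ab}
    f = np.broadcast_to(pi, (patterns.shape[0], C)).copy()
    for t in range(patterns.shape[1]):
        if t in in_pair:
            continue
        r = patterns[:, t]
        obs = r != MISSING
        f[obs] *= thetas[t, r[obs] - 1, :]
    for k, (a, b) in enumerate(pair_idx):
        e = np.exp(lam[k])  # (C,)
        s = (thetas[a] * thetas[b]).sum(0)  # sum_r P_a(r|c) P_b(r|c)
        Z = 1.0 + (e - 1.0) * s
        ra, rb = patterns[:, a], patterns[:, b]
        oa, ob = ra != MISSING, rb != MISSING
        both = oa & ob
        if both.any():
            agree = (ra[both] == rb[both]).astype(float)[:, None]
            term = (
                thetas[a][ra[both] - 1, :]
                * thetas[b][rb[both] - 1, :]
                * np.power(e, agree)
                / Z
            )
            f[both] *= term
        only_a = oa & ~ob
        if only_a.any():
            pa = thetas[a][ra[only_a] - 1, :]
            pb_same = thetas[b][ra[only_a] - 1, :]
            f[only_a] *= pa * (1.0 + (e - 1.0) * pb_same) / Z
        only_b = ob & ~oa
        if only_b.any():
            pb = thetas[b][rb[only_b] - 1, :]
            pa_same = thetas[a][rb[only_b] - 1, :]
            f[only_b] *= pb * (1.0 + (e - 1.0) * pa_same) / Z
    return f


def _alr(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-9, None)
    return np.log(p[:-1] / p[-1])


def _inv_alr(y: np.ndarray) -> np.ndarray:
    e = np.exp(np.append(y, 0.0) - max(np.max(y), 0.0))
    return e / e.sum()


def fit_lcm_dependent(
    data: TestPanelDataset | tuple[np.ndarray, np.ndarray],
    spec: LcmSpec,
    dep: DependenceSpec,
    compute_se: bool = True,
) -> DependentLcmFit:
    """Latent class fit with log-linear agreement terms for flagged pairs.

    Within each class the flagged pair's joint cell table is the product
    form times ``exp(lambda * 1[agree])``, renormalized; all other pairs
    stay conditionally independent, and lambda = 0 recovers the basic
    model exactly.  Fitted by quasi-Newton ascent in an unconstrained
    (additive log-ratio) parameterization, warm-started from the
    conditional-independence EM solution.
    """
    from .lcm import _as_patterns

    patterns, counts = _as_patterns(data)
    C, T = spec.n_classes, len(spec.test_names)
    pair_idx = []
    for a, b in dep.pairs:
        if a not in spec.test_names or b not in spec.test_names:
            raise ConfigError(f"dependence pair ({a}, {b}) not among spec tests")
        pair_idx.append((spec.test_names.index(a), spec.test_names.index(b)))
    n_lam = dep.n_lambda(C)
    n_params = spec.n_params + n_lam
    if n_params > patterns.shape[0] - 1:
        raise IdentifiabilityError(
            f"{n_params} parameters exceed {patterns.shape[0]} distinct patterns - 1"
        )

    base = fit_lcm((patterns, counts), spec, compute_se=False)
    per = C if dep.sharing == PAIR_CLASS else 1

    def split(x):
        pi = _inv_alr(x[: C - 1])
        thetas = np.empty((T, C, C))
        k = C - 1
        for t in range(T):
            for c in range(C):
                thetas[t, :, c] = _inv_alr(x[k : k + C - 1])
                k += C - 1
        lam_flat = x[k:]
        lam = lam_flat.reshape(len(pair_idx), per)
        lam_full = np.repeat(lam, C, axis=1) if per == 1 else lam
        return pi, thetas, lam_full

    def negll(x):
        pi, thetas, lam = split(x)
        f = _dep_class_lik(patterns, pi, thetas, pair_idx, lam)
        return -float(counts @ np.log(np.maximum(f.sum(1), PROB_FLOOR)))

    x0 = [_alr(np.clip(base.prevalence, 1e-8, None))]
    th0 = np.clip(base.theta, 1e-8, None)
    for t in range(T):
        for c in range(C):
            x0.append(_alr(th0[t, :, c]))
    x0.append(np.zeros(n_lam))
    x0 = np.concatenate(x0)

    res = optimize.minimize(
        negll, x0, method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8},
    )
    ll = -float(res.fun)
    if ll < base.loglik - 1e-6:
        # the independence solution is admissible (lambda = 0); never worse
        ll = base.loglik
        res.x = x0
    pi, thetas, lam_full = split(res.x)
    pi, thetas, perm = _align_labels(pi, thetas)
    lam_full = lam_full[:, list(perm)] if per == C else lam_full
    lam_report = lam_full if per == C else lam_full[:, :1]

    se_lambda = None
    if compute_se:
        H = _numeric_hessian(negll, res.x, h=1e-4)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        d = np.diag(cov)[-n_lam:]
        if np.any(d < 0) or not np.all(np.isfinite(d)):
            warnings.warn("information matrix irregular at optimum; lambda SEs via pinv")
            d = np.abs(np.diag(np.linalg.pinv(H))[-n_lam:])
        se_lambda = np.sqrt(d).reshape(len(pair_idx), per)

    boundary_theta = (thetas <= BOUNDARY_TOL) | (thetas >= 1 - BOUNDARY_TOL)
    return DependentLcmFit(
        spec=spec,
        dep=dep,
        prevalence=pi,
        theta=thetas,
        lambdas=lam_report,
        se_lambda=se_lambda,
        loglik=ll,
        n_params=n_params,
        converged=bool(res.success) and base.converged,
        n_subjects=int(counts.sum()),
        boundary_theta=boundary_theta,
    )


# ---------------------------------------------------------------------------
# likelihood ratio tests

@dataclass(frozen=True)
class LrtResult:
    stat: float
    df: int
    p_value: float
    boundary_warning: bool


def likelihood_ratio_test(null_fit, alt_fit, tol: float = 1e-6) -> LrtResult:
    """Chi-square LRT between nested fits on the same data.

    ``boundary_warning`` flags fits with boundary parameters, where the
    chi-square reference distribution is only approximate.  A null
    log-likelihood exceeding the alternative's beyond tolerance signals
    an optimizer failure and raises.
    """
    ll0, ll1 = float(null_fit.loglik), float(alt_fit.loglik)
    df = int(alt_fit.n_params) - int(null_fit.n_params)
    if df < 1:
        raise ConfigError("alternative must have more free parameters than the null")
    stat = 2.0 * (ll1 - ll0)
    if stat < -tol * (abs(ll0) + 1.0):
        raise InconsistentFitError(
            f"null log-likelihood {ll0} exceeds alternative {ll1}"
        )
    stat = max(stat, 0.0)
    boundary = bool(
        getattr(null_fit, "has_boundary", False) or getattr(alt_fit, "has_boundary", False)
    )
    return LrtResult(stat, df, float(stats.chi2.sf(stat, df)), boundary)


def dependence_screen(
    data: TestPanelDataset,
    spec: LcmSpec,
    sharing: str = PAIR,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """LRT of conditional independence for every test pair, one pair at
    a time, with a Bonferroni adjustment over the T(T-1)/2 tests."""
    base = fit_lcm(data, spec, compute_se=False)
    names = spec.test_names
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rows = []
    for a, b in pairs:
        alt = fit_lcm_dependent(data, spec, DependenceSpec(((a, b),), sharing),
                                compute_se=False)
        lrt = likelihood_ratio_test(base, alt)
        rows.append(
            {
                "pair": f"{a}-{b}",
                "lambda": float(alt.lambdas.mean()),
                "stat": lrt.stat,
                "df": lrt.df,
                "p_value": lrt.p_value,
                "p_adjusted": min(1.0, lrt.p_value * len(pairs))
                if adjust == "bonferroni" else lrt.p_value,
                "boundary_warning": lrt.boundary_warning,
            }
        )
    return pd.DataFrame(rows)
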