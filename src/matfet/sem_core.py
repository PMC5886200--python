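"""Latent-genotype structural equation model for maternal and fetal effects.

The model explains three observed variables per genotyped individual — their
own birth weight (BW), the birth weight of their first child (BW_O) and their
genotype (SNP) — through two latent genotypes: that of their mother (G_G) and
that of their child (G_O).  Parent-offspring transmission fixes both latent
paths at 0.5, so with maternal path ``m`` and fetal path ``f``:

    BW   = m * G_G + f * SNP + eps
    BW_O = m * SNP + f * G_O + eps_O

Path tracing gives the implied moments of (SNP, BW, BW_O):

    var(SNP)      = phi
    cov(BW, SNP)  = (0.5 m + f) phi
    cov(BW_O,SNP) = (m + 0.5 f) phi
    var(BW)       = (m^2 + f^2 + m f) phi + sigma2
    var(BW_O)     = (m^2 + f^2 + m f) phi + sigma2_o
    cov(BW, BW_O) = (0.5 m^2 + 1.25 m f + 0.5 f^2) phi + rho

The genotype is treated as continuous Gaussian in the likelihood despite
being 0/1/2 (pseudo-maximum-likelihood, inherited from standard SEM engines);
calibration under this misspecification is checked by simulation.  Records
fall into three planned-missingness patterns (own birth weight only /
offspring birth weight only / both) and each contributes the marginal
multivariate-normal density of its observed variables — full-information
maximum likelihood, valid when the pattern is independent of the phenotypes.

The per-pattern likelihood is evaluated from sufficient statistics
(block size, mean, maximum-likelihood scatter), which is algebraically
identical to the per-record density sum but O(1) in sample size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .simgen import Pattern

__all__ = [
    "SEMParameters",
    "PatternedDataset",
    "SEMFit",
    "implied_moments",
    "fiml_loglik",
    "closed_form_mf",
    "fit_sem",
    "lrt_2df",
]

_LOG_2PI = math.log(2.0 * math.pi)

# Column indices of each pattern's observed variables within (SNP, BW, BW_O).
_PATTERN_INDEX: dict[Pattern, tuple[int, ...]] = {
    Pattern.OWN_ONLY: (0, 1),
    Pattern.OFFSPRING_ONLY: (0, 2),
    Pattern.BOTH: (0, 1, 2),
}

_PARAM_NAMES = (
    "m",
    "f",
    "phi",
    "sigma2",
    "sigma2_o",
    "rho",
    "mu_snp",
    "mu_bw",
    "mu_bwo",
)


@dataclass(frozen=True)
class SEMParameters:
    """Free parameters of the model.

    m, f        maternal and fetal paths (SD of birth weight per allele)
    phi         variance of the observed genotype (2p(1-p) under HWE)
    sigma2(_o)  residual variances of own / offspring birth weight
    rho         residual covariance between the two birth weights
    mu_*        means of (SNP, BW, BW_O)
    """

    m: float
    f: float
    phi: float
    sigma2: float
    sigma2_o: float
    rho: float
    mu_snp: float = 0.0
    mu_bw: float = 0.0
    mu_bwo: float = 0.0

    def __post_init__(self) -> None:
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.sigma2 <= 0 or self.sigma2_o <= 0:
            raise ValueError("residual variances must be positive")
        if self.rho**2 > self.sigma2 * self.sigma2_o * (1 + 1e-12):
            raise ValueError("rho violates Cauchy-Schwarz")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in _PARAM_NAMES])

    @staticmethod
    def from_array(theta: np.ndarray) -> "SEMParameters":
        return SEMParameters(**dict(zip(_PARAM_NAMES, map(float, theta))))


class PatternedDataset:
    """Records grouped by missingness pattern, with cached sufficient stats.

    Each block stores (n, mean, ML scatter) of its observed variables in the
    (SNP, BW, BW_O) ordering restricted to the pattern's observed subset.
    """

    def __init__(self, blocks: dict[Pattern, np.ndarray]):
        self.blocks = {p: np.asarray(x, dtype=float) for p, x in blocks.items() if len(x)}
        for p, x in self.blocks.items():
            k = len(_PATTERN_INDEX[p])
            if x.ndim != 2 or x.shape[1] != k:
                raise ValueError(f"block {p.value} must have {k} columns")
            if not np.isfinite(x).all():
                raise ValueError(f"block {p.value} contains non-finite values")
        self._suffstats = {}
        for p, x in self.blocks.items():
            n = x.shape[0]
            xbar = x.mean(axis=0)
            d = x - xbar
            scatter = d.T @ d / n  # ML (n-denominator) covariance
            self._suffstats[p] = (n, xbar, scatter)

    @property
    def suffstats(self):
        return self._suffstats

    @property
    def n_by_pattern(self) -> dict[str, int]:
        return {p.value: s[0] for p, s in self._suffstats.items()}

    @property
    def n_total(self) -> int:
        return sum(s[0] for s in self._suffstats.values())

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        snp_col: str = "g_self",
        bw_col: str = "bw_own",
        bwo_col: str = "bw_offspring",
    ) -> "PatternedDataset":
        """Split a cohort table into pattern blocks by observed missingness."""
        snp = df[snp_col].notna()
        own = df[bw_col].notna()
        off = df[bwo_col].notna()
        blocks: dict[Pattern, np.ndarray] = {}
        sel = snp & own & ~off
        blocks[Pattern.OWN_ONLY] = df.loc[sel, [snp_col, bw_col]].to_numpy(float)
        sel = snp & ~own & off
        blocks[Pattern.OFFSPRING_ONLY] = df.loc[sel, [snp_col, bwo_col]].to_numpy(float)
        sel = snp & own & off
        blocks[Pattern.BOTH] = df.loc[sel, [snp_col, bw_col, bwo_col]].to_numpy(float)
        return cls(blocks)


@dataclass
class SEMFit:
    """Result of a full-information maximum-likelihood fit."""

    estimates: SEMParameters
    se: dict[str, float]
    vcov: np.ndarray
    param_names: tuple[str, ...]
    loglik: float
    converged: bool
    grad_max_norm: float
    n_by_pattern: dict[str, int]
    wald_m: tuple[float, float]  # (z, p)
    wald_f: tuple[float, float]
    lrt_2df: tuple[float, float] | None = None  # (statistic, p)


def implied_moments(params: SEMParameters) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector and covariance of (SNP, BW, BW_O)."""
    m, f, phi = params.m, params.f, params.phi
    mf = m * f
    var_bw_genetic = (m * m + f * f + mf) * phi
    sigma = np.array(
        [
            [phi, (0.5 * m + f) * phi, (m + 0.5 * f) * phi],
            [
                (0.5 * m + f) * phi,
                var_bw_genetic + params.sigma2,
                (0.5 * m * m + 1.25 * mf + 0.5 * f * f) * phi + params.rho,
            ],
            [
                (m + 0.5 * f) * phi,
                (0.5 * m * m + 1.25 * mf + 0.5 * f * f) * phi + params.rho,
                var_bw_genetic + params.sigma2_o,
            ],
        ]
    )
    mu = np.array([params.mu_snp, params.mu_bw, params.mu_bwo])
    # eigenvalue check is cheap at 3x3 and catches indefinite combinations
    if np.linalg.eigvalsh(sigma)[0] <= 0:
        raise ValueError("implied covariance matrix is not positive definite")
    return mu, sigma


def _implied_unchecked(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    m, f, phi, s2, s2o, rho, mu1, mu2, mu3 = theta
    mf = m * f
    g = (m * m + f * f + mf) * phi
    c = (0.5 * m * m + 1.25 * mf + 0.5 * f * f) * phi + rho
    sigma = np.array(
        [
            [phi, (0.5 * m + f) * phi, (m + 0.5 * f) * phi],
            [(0.5 * m + f) * phi, g + s2, c],
            [(m + 0.5 * f) * phi, c, g + s2o],
        ]
    )
    return np.array([mu1, mu2, mu3]), sigma


def _block_loglik(n, xbar, scatter, mu_b, sigma_b) -> float:
    try:
        cho = linalg.cho_factor(sigma_b, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.log(np.diag(cho[0])).sum()
    d = xbar - mu_b
    sinv_scatter = linalg.cho_solve(cho, scatter, check_finite=False)
    quad = n * (np.trace(sinv_scatter) + d @ linalg.cho_solve(cho, d, check_finite=False))
    k = len(mu_b)
    return -0.5 * (n * k * _LOG_2PI + n * logdet + quad)


def fiml_loglik(params: SEMParameters, data: PatternedDataset) -> float:
    """Total log-likelihood summed over the three missingness patterns.

    Each pattern contributes the multivariate-normal log-density of its
    observed variables under the corresponding marginal of the implied
    moments; equals the complete-data log-likelihood when only the BOTH
    block is populated.  Returns -inf (optimizer-safe) if any marginal
    covariance is not positive definite.
    """
    theta = params.as_array()
    return _loglik_from_theta(theta, data)


def _loglik_from_theta(theta: np.ndarray, data: PatternedDataset) -> float:
    mu, sigma = _implied_unchecked(theta)
    total = 0.0
    for pattern, (n, xbar, scatter) in data.suffstats.items():
        idx = list(_PATTERN_INDEX[pattern])
        ll = _block_loglik(n, xbar, scatter, mu[idx], sigma[np.ix_(idx, idx)])
        if not np.isfinite(ll):
            return -np.inf
        total += ll
    return total


def closed_form_mf(sample_cov: np.ndarray) -> tuple[float, float]:
    """Method-of-moments inversion of the path equations on complete data.

    With a = cov(BW, SNP)/phi and b = cov(BW_O, SNP)/phi (phi = var(SNP)),
    the two covariance equations a = 0.5 m + f, b = m + 0.5 f solve to
    f = (4a - 2b)/3, m = (4b - 2a)/3.  Serves as the just-identified
    complete-data oracle for the iterative fit.
    """
    s = np.asarray(sample_cov, dtype=float)
    if s.shape != (3, 3):
        raise ValueError("sample_cov must be 3x3 ordered (SNP, BW, BW_O)")
    phi = s[0, 0]
    if phi <= 0:
        raise ValueError("var(SNP) must be positive")
    a = s[0, 1] / phi
    b = s[0, 2] / phi
    f = (4.0 * a - 2.0 * b) / 3.0
    m = (4.0 * b - 2.0 * a) / 3.0
    return m, f


# --------------------------------------------------------------------------
# fitting machinery

_R_CLIP = 0.9999


def _to_working(theta: np.ndarray, free_mf: bool) -> np.ndarray:
    m, f, phi, s2, s2o, rho, mu1, mu2, mu3 = theta
    r = np.clip(rho / math.sqrt(s2 * s2o), -_R_CLIP, _R_CLIP)
    core = [math.log(phi), math.log(s2), math.log(s2o), math.atanh(r), mu1, mu2, mu3]
    return np.array(([m, f] if free_mf else []) + core)


def _from_working(w: np.ndarray, free_mf: bool) -> np.ndarray:
    if free_mf:
        m, f = w[0], w[1]
        rest = w[2:]
    else:
        m = f = 0.0
        rest = w
    phi = math.exp(rest[0])
    s2 = math.exp(rest[1])
    s2o = math.exp(rest[2])
    rho = math.tanh(rest[3]) * math.sqrt(s2 * s2o)
    return np.array([m, f, phi, s2, s2o, rho, rest[4], rest[5], rest[6]])


def _pooled_start(data: PatternedDataset) -> np.ndarray:
    """Data-driven starting values from pattern-pooled moments."""
    ss = data.suffstats
    # pooled genotype moments
    n_tot = sum(n for n, _, _ in ss.values())
    mu_snp = sum(n * xb[0] for n, xb, _ in ss.values()) / n_tot
    phi = sum(n * (sc[0, 0] + (xb[0] - mu_snp) ** 2) for n, xb, sc in ss.values()) / n_tot
    phi = max(phi, 1e-8)

    def pooled(patterns, col):
        # pooled mean/var/cov-with-snp of a phenotype column over its blocks
        tot = sum(ss[p][0] for p in patterns if p in ss)
        if tot == 0:
            return 0.0, 1.0, 0.0
        mean = sum(ss[p][0] * ss[p][1][col] for p in patterns if p in ss) / tot
        var = (
            sum(
                ss[p][0] * (ss[p][2][col, col] + (ss[p][1][col] - mean) ** 2)
                for p in patterns
                if p in ss
            )
            / tot
        )
        cov = (
            sum(
                ss[p][0]
                * (ss[p][2][0, col] + (ss[p][1][0] - mu_snp) * (ss[p][1][col] - mean))
                for p in patterns
                if p in ss
            )
            / tot
        )
        return mean, var, cov

    mu_bw, var_bw, cov_bw = pooled((Pattern.OWN_ONLY, Pattern.BOTH), 1)
    # in the OFFSPRING_ONLY block BW_O sits in column 1; in BOTH in column 2
    off_parts = []
    if Pattern.OFFSPRING_ONLY in ss:
        off_parts.append((Pattern.OFFSPRING_ONLY, 1))
    if Pattern.BOTH in ss:
        off_parts.append((Pattern.BOTH, 2))
    tot = sum(ss[p][0] for p, _ in off_parts)
    mu_bwo = sum(ss[p][0] * ss[p][1][c] for p, c in off_parts) / tot
    var_bwo = (
        sum(ss[p][0] * (ss[p][2][c, c] + (ss[p][1][c] - mu_bwo) ** 2) for p, c in off_parts)
        / tot
    )
    cov_bwo = (
        sum(
            ss[p][0] * (ss[p][2][0, c] + (ss[p][1][0] - mu_snp) * (ss[p][1][c] - mu_bwo))
            for p, c in off_parts
        )
        / tot
    )

    a = cov_bw / phi
    b = cov_bwo / phi
    f0 = (4.0 * a - 2.0 * b) / 3.0
    m0 = (4.0 * b - 2.0 * a) / 3.0
    g = (m0 * m0 + f0 * f0 + m0 * f0) * phi
    s2 = max(var_bw - g, 0.05 * max(var_bw, 1e-6))
    s2o = max(var_bwo - g, 0.05 * max(var_bwo, 1e-6))
    rho0 = 0.0
    if Pattern.BOTH in ss:
        nB, xbB, scB = ss[Pattern.BOTH]
        implied_gen = (0.5 * m0 * m0 + 1.25 * m0 * f0 + 0.5 * f0 * f0) * phi
        rho0 = scB[1, 2] - implied_gen
        cap = 0.95 * math.sqrt(s2 * s2o)
        rho0 = float(np.clip(rho0, -cap, cap))
    return np.array([m0, f0, phi, s2, s2o, rho0, mu_snp, mu_bw, mu_bwo])


def _num_grad(fun, x, rel_step=1e-6):
    g = np.empty_like(x)
    for i in range(len(x)):
        h = rel_step * max(1.0, abs(x[i]))
        xp = x.copy()
        xm = x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (fun(xp) - fun(xm)) / (2 * h)
    return g


def _num_hess(fun, x, rel_step=1e-5):
    k = len(x)
    h = np.array([rel_step * max(1.0, abs(xi)) for xi in x])
    hess = np.empty((k, k))
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                xp = x.copy()
                xm = x.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                hess[i, i] = (fun(xp) - 2 * f0 + fun(xm)) / h[i] ** 2
            else:
                xpp = x.copy()
                xpm = x.copy()
                xmp = x.copy()
                xmm = x.copy()
                xpp[[i, j]] += [h[i], h[j]]
                xpm[i] += h[i]
                xpm[j] -= h[j]
                xmp[i] -= h[i]
                xmp[j] += h[j]
                xmm[[i, j]] -= [h[i], h[j]]
                hess[i, j] = hess[j, i] = (
                    fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)
                ) / (4 * h[i] * h[j])
    return hess


def _optimize(data: PatternedDataset, start: np.ndarray, free_mf: bool, grad_tol: float):
    """Minimize the mean negative log-likelihood on the working scale.

    L-BFGS-B from the moment-based start, then Newton polish with numeric
    gradient/Hessian until the gradient max-norm of the *mean* log-likelihood
    drops below ``grad_tol`` (the mean scale keeps the criterion n-invariant).
    """
    n_tot = data.n_total

    def neg_mean_ll(w):
        ll = _loglik_from_theta(_from_working(w, free_mf), data)
        return np.inf if not np.isfinite(ll) else -ll / n_tot

    w0 = _to_working(start, free_mf)
    res = optimize.minimize(neg_mean_ll, w0, method="L-BFGS-B", options={"maxiter": 500})
    w = res.x
    fval = res.fun
    # Newton polish to push the finite-difference gradient to its noise floor
    for _ in range(30):
        g = _num_grad(neg_mean_ll, w)
        if np.max(np.abs(g)) < grad_tol:
            break
        hess = _num_hess(neg_mean_ll, w)
        try:
            step = np.linalg.solve(hess, g)
        except np.linalg.LinAlgError:
            step = g
        # backtracking line search keeps the polish monotone
        t = 1.0
        improved = False
        for _ in range(20):
            w_new = w - t * step
            f_new = neg_mean_ll(w_new)
            if f_new < fval:
                w, fval = w_new, f_new
                improved = True
                break
            t *= 0.5
        if not improved:
            break
    g = _num_grad(neg_mean_ll, w)
    grad_norm = float(np.max(np.abs(g)))
    theta = _from_working(w, free_mf)
    return theta, -fval * n_tot, grad_norm


def _fit_theta(
    data: PatternedDataset,
    free_mf: bool,
    grad_tol: float = 1e-6,
    n_restarts: int = 2,
    seed: int = 0,
):
    start = _pooled_start(data)
    if not free_mf:
        start[0] = start[1] = 0.0
    theta, ll, grad_norm = _optimize(data, start, free_mf, grad_tol)
    best = (theta, ll, grad_norm)
    if grad_norm >= grad_tol:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            jitter = start.copy()
            jitter[:2] += rng.normal(0, 0.05, 2) if free_mf else 0.0
            jitter[2:6] *= np.exp(rng.normal(0, 0.1, 4))
            jitter[5] = np.clip(
                jitter[5],
                -0.9 * math.sqrt(jitter[3] * jitter[4]),
                0.9 * math.sqrt(jitter[3] * jitter[4]),
            )
            theta_r, ll_r, gn_r = _optimize(data, jitter, free_mf, grad_tol)
            if ll_r > best[1] or (gn_r < best[2] and ll_r >= best[1] - 1e-9):
                best = (theta_r, ll_r, gn_r)
            if best[2] < grad_tol:
                break
    return best


def fit_sem(
    data: PatternedDataset,
    *,
    fix_phi: float | None = None,
    compute_lrt: bool = True,
    grad_tol: float = 1e-6,
) -> SEMFit:
    """Fit the model by full-information maximum likelihood.

    Requires at least one pattern containing own birth weight and one
    containing offspring birth weight (otherwise the two paths are not
    separately identified).  Standard errors come from the inverse numerical
    observed information (central differences) of the total log-likelihood at
    the optimum, on the natural parameter scale; Wald z uses a normal
    reference.  ``fix_phi`` pins the genotype variance instead of estimating
    it (e.g. at 2p(1-p)).
    """
    if not data.suffstats:
        raise ValueError("dataset has no records")
    has_bw = any(p in data.suffstats for p in (Pattern.OWN_ONLY, Pattern.BOTH))
    has_bwo = any(p in data.suffstats for p in (Pattern.OFFSPRING_ONLY, Pattern.BOTH))
    if not has_bw:
        raise ValueError(
            "no pattern contains own birth weight (OWN_ONLY or BOTH needed); "
            "maternal and fetal paths are not identified"
        )
    if not has_bwo:
        raise ValueError(
            "no pattern contains offspring birth weight (OFFSPRING_ONLY or BOTH "
            "needed); maternal and fetal paths are not identified"
        )

    theta, ll, grad_norm = _fit_theta(data, free_mf=True, grad_tol=grad_tol)
    if fix_phi is not None:
        # profile out phi by refitting with phi pinned (working scale drops it)
        theta, ll, grad_norm = _fit_theta_fixed_phi(data, fix_phi, grad_tol)

    names = _PARAM_NAMES if fix_phi is None else tuple(
        k for k in _PARAM_NAMES if k != "phi"
    )

    def neg_ll_natural(t_free):
        full = _theta_with_fixed(t_free, fix_phi)
        ll_val = _loglik_from_theta(full, data)
        return np.inf if not np.isfinite(ll_val) else -ll_val

    t_free = _theta_free(theta, fix_phi)
    hess = _num_hess(neg_ll_natural, t_free, rel_step=1e-5)
    converged = grad_norm < grad_tol
    try:
        vcov = np.linalg.inv(hess)
        ses = np.sqrt(np.diag(vcov))
        if not np.isfinite(ses).all():
            raise np.linalg.LinAlgError
    except (np.linalg.LinAlgError, FloatingPointError):
        vcov = np.full((len(t_free), len(t_free)), np.nan)
        ses = np.full(len(t_free), np.nan)
        converged = False
    if np.isfinite(np.diag(hess)).all() and (np.linalg.eigvalsh((hess + hess.T) / 2) <= 0).any():
        converged = False  # observed information not PD at the reported optimum

    se = dict(zip(names, map(float, ses)))
    params = SEMParameters.from_array(theta)

    def wald(name):
        est = getattr(params, name)
        s = se.get(name, np.nan)
        if not np.isfinite(s) or s <= 0:
            return (np.nan, np.nan)
        z = est / s
        return (float(z), float(2 * stats.norm.sf(abs(z))))

    fit = SEMFit(
        estimates=params,
        se=se,
        vcov=vcov,
        param_names=names,
        loglik=float(ll),
        converged=bool(converged),
        grad_max_norm=float(grad_norm),
        n_by_pattern=data.n_by_pattern,
        wald_m=wald("m"),
        wald_f=wald("f"),
    )
    if compute_lrt:
        fit.lrt_2df = lrt_2df(fit, data)
    return fit


def _theta_free(theta: np.ndarray, fix_phi: float | None) -> np.ndarray:
    if fix_phi is None:
        return np.asarray(theta, dtype=float)
    return np.delete(np.asarray(theta, dtype=float), 2)


def _theta_with_fixed(t_free: np.ndarray, fix_phi: float | None) -> np.ndarray:
    if fix_phi is None:
        return t_free
    return np.insert(t_free, 2, fix_phi)


def _fit_theta_fixed_phi(data: PatternedDataset, phi: float, grad_tol: float):
    n_tot = data.n_total

    def neg_mean_ll(w):
        theta = _from_working_fixed_phi(w, phi)
        ll = _loglik_from_theta(theta, data)
        return np.inf if not np.isfinite(ll) else -ll / n_tot

    start = _pooled_start(data)
    start[2] = phi
    w0 = np.concatenate(
        [
            start[:2],
            [math.log(start[3]), math.log(start[4])],
            [math.atanh(np.clip(start[5] / math.sqrt(start[3] * start[4]), -_R_CLIP, _R_CLIP))],
            start[6:],
        ]
    )
    res = optimize.minimize(neg_mean_ll, w0, method="L-BFGS-B", options={"maxiter": 500})
    w = res.x
    fval = res.fun
    for _ in range(30):
        g = _num_grad(neg_mean_ll, w)
        if np.max(np.abs(g)) < grad_tol:
            break
        hess = _num_hess(neg_mean_ll, w)
        try:
            step = np.linalg.solve(hess, g)
        except np.linalg.LinAlgError:
            step = g
        t = 1.0
        improved = False
        for _ in range(20):
            w_new = w - t * step
            f_new = neg_mean_ll(w_new)
            if f_new < fval:
                w, fval = w_new, f_new
                improved = True
                break
            t *= 0.5
        if not improved:
            break
    g = _num_grad(neg_mean_ll, w)
    return _from_working_fixed_phi(w, phi), -fval * n_tot, float(np.max(np.abs(g)))


def _from_working_fixed_phi(w: np.ndarray, phi: float) -> np.ndarray:
    m, f = w[0], w[1]
    s2 = math.exp(w[2])
    s2o = math.exp(w[3])
    rho = math.tanh(w[4]) * math.sqrt(s2 * s2o)
    return np.array([m, f, phi, s2, s2o, rho, w[5], w[6], w[7]])


def lrt_2df(full: SEMFit, data: PatternedDataset) -> tuple[float, float]:
    """Two-degree-of-freedom likelihood-ratio test of m = f = 0.

    Refits the model with both genetic paths removed; the statistic
    2*(loglik_full - loglik_null) is referred to a chi-square with 2 df.
    """
    _, ll_null, _ = _fit_theta(data, free_mf=False)
    stat = 2.0 * (full.loglik - ll_null)
    if stat < -1e-6 * max(1.0, abs(full.loglik)):
        raise RuntimeError(
            f"null log-likelihood exceeds full log-likelihood ({ll_null:.6f} > "
            f"{full.loglik:.6f}); optimizer failure"
        )
    stat = max(stat, 0.0)
    return float(stat), float(stats.chi2.sf(stat, df=2))
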