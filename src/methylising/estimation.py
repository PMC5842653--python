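"""Maximum marginal-likelihood fitting of region parameters from WGBS reads.

Each eligible 3-kb region is fitted by maximizing the average marginalized
log-likelihood (incomplete reads marginalized over unmeasured sites) over the
five-parameter box with a derivative-free global search (DIRECT) followed by
a bounded Nelder-Mead polish. The unconstrained ("general") Ising model with
one field per site and one coupling per pair is fitted for model comparison
by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import _kernels
from .ising import RegionModel, build_potentials

__all__ = [
    "ObservationMatrix",
    "EstimationConfig",
    "FitResult",
    "ModelComparison",
    "region_eligible",
    "average_marginal_loglik",
    "estimate_region_params",
    "fit_general_ising",
    "aic_compare",
]


class ObservationMatrix:
    """Partial observations of the CpG states of one region.

    One record per read x observed site; a read is stored as its maximal
    contiguous runs of observed sites (flattened arrays), which is the unit
    of exact marginalization. Duplicate (read, site) pairs are rejected.
    """

    __slots__ = ("n_sites", "n_reads", "run_start", "run_off", "run_vals")

    def __init__(self, n_sites, n_reads, run_start, run_off, run_vals):
        self.n_sites = int(n_sites)
        self.n_reads = int(n_reads)
        self.run_start = np.asarray(run_start, dtype=np.int64)
        self.run_off = np.asarray(run_off, dtype=np.int64)
        self.run_vals = np.asarray(run_vals, dtype=np.int64)

    @classmethod
    def from_reads(cls, n_sites: int, reads) -> "ObservationMatrix":
        """Build from an iterable of (site_indices, states) pairs, one per read."""
        run_start: list[int] = []
        run_off: list[int] = [0]
        run_vals: list[int] = []
        n_reads = 0
        for sites, states in reads:
            sites = np.asarray(sites, dtype=np.int64)
            states = np.asarray(states, dtype=np.int64)
            if len(sites) == 0:
                raise ValueError("each read must observe at least one site")
            order = np.argsort(sites)
            sites, states = sites[order], states[order]
            if sites[0] < 0 or sites[-1] >= n_sites:
                raise ValueError("observed site index outside region")
            if len(sites) > 1 and np.any(np.diff(sites) == 0):
                raise ValueError("duplicate (read, site) observation")
            if not np.isin(states, (0, 1)).all():
                raise ValueError("states must be 0 or 1")
            n_reads += 1
            breaks = np.flatnonzero(np.diff(sites) > 1) + 1
            for s, v in zip(np.split(sites, breaks), np.split(states, breaks)):
                run_start.append(int(s[0]))
                run_vals.extend(int(x) for x in v)
                run_off.append(len(run_vals))
        return cls(n_sites, n_reads, run_start, run_off, run_vals)

    @property
    def n_runs(self) -> int:
        return len(self.run_start)

    def total_observations(self) -> int:
        return len(self.run_vals)

    def sites_observed(self) -> np.ndarray:
        """Distinct site indices observed by at least one read."""
        idx = np.concatenate(
            [
                np.arange(self.run_start[r], self.run_start[r] + self.run_off[r + 1] - self.run_off[r])
                for r in range(self.n_runs)
            ]
        ) if self.n_runs else np.empty(0, dtype=np.int64)
        return np.unique(idx)

    def reads_iter(self):
        """Yield {site -> state} per run (for the slow exact-likelihood path)."""
        for r in range(self.n_runs):
            o0, o1 = self.run_off[r], self.run_off[r + 1]
            s0 = self.run_start[r]
            yield {int(s0 + j): int(self.run_vals[o0 + j]) for j in range(o1 - o0)}


@dataclass
class EstimationConfig:
    """Optimizer box, budget and region-eligibility thresholds."""

    bounds: tuple = ((-10.0, 10.0), (-10.0, 10.0), (-10.0, 10.0), (-100.0, 100.0), (-20.0, 20.0))
    budget: int = 5000  # total objective evaluations per region
    improvement_tol: float = 1e-5
    # tiny ridge on theta: a numerical tie-break that pins directions the
    # marginal likelihood leaves flat (e.g. the boundary field of a site no
    # read observed, or alpha/beta at locally constant density) to the
    # smallest-magnitude optimum; negligible against any data-constrained
    # direction
    ridge: float = 1e-4
    min_sites: int = 10
    min_obs_fraction: float = 2.0 / 3.0
    min_depth: float = 2.5
    general_cap: int = 25  # max CpGs for the 2R-1 parameter fit
    general_budget: int = 20000


@dataclass
class FitResult:
    theta_hat: np.ndarray | None
    loglik: float  # achieved average marginal log-likelihood, <= 0
    n_params: int
    n_reads: int
    status: str = "fitted"  # fitted | skipped
    reason: str | None = None

    @property
    def ok(self) -> bool:
        return self.status == "fitted"


@dataclass
class ModelComparison:
    aic1: float  # constrained (5-parameter) model
    aic2: float  # general (2R-1 parameter) model
    pi: float  # AIC probability that the constrained model is best


def region_eligible(
    n_sites: int, obs: ObservationMatrix, config: EstimationConfig | None = None
) -> tuple[bool, str | None]:
    """Eligibility filters for fitting a region: at least ``min_sites`` CpGs,
    at least 2/3 of the sites observed by >= 1 read, and average depth of at
    least 2.5 observations per CpG site."""
    cfg = config or EstimationConfig()
    if n_sites < cfg.min_sites:
        return False, "min_sites"
    if len(obs.sites_observed()) / n_sites < cfg.min_obs_fraction:
        return False, "coverage_fraction"
    if obs.total_observations() / n_sites < cfg.min_depth:
        return False, "depth"
    return True, None


def average_marginal_loglik(
    theta, rho: np.ndarray, positions: np.ndarray, obs: ObservationMatrix
) -> float:
    """(1/M) sum_m ln P({x_r, r observed in read m} | theta)."""
    if obs.n_reads == 0:
        raise ValueError("no reads")
    model = build_potentials(theta, rho, positions)
    return _kernels.avg_marginal_loglik(
        model.a, model.c, obs.run_start, obs.run_off, obs.run_vals, obs.n_reads
    )


def _potential_loglik(a, c, obs: ObservationMatrix) -> float:
    return _kernels.avg_marginal_loglik(
        np.asarray(a, float), np.asarray(c, float), obs.run_start, obs.run_off, obs.run_vals, obs.n_reads
    )


def estimate_region_params(
    rho: np.ndarray,
    positions: np.ndarray,
    obs: ObservationMatrix,
    config: EstimationConfig | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit theta = (alpha', alpha, alpha'', beta, gamma) for one region.

    Global derivative-free DIRECT search over the box, then a bounded
    Nelder-Mead polish; deterministic (DIRECT is deterministic, the seed is
    accepted for interface stability). Regions should be pre-filtered with
    :func:`region_eligible`.
    """
    cfg = config or EstimationConfig()
    rho = np.asarray(rho, float)
    positions = np.asarray(positions, np.int64)
    R = len(rho)
    d = np.diff(positions).astype(float)

    def loglik(theta: np.ndarray) -> float:
        alpha_p, alpha, alpha_pp, beta, gamma = theta
        a = np.full(R, alpha)
        a[0] = alpha_p
        if R > 1:
            a[-1] = alpha_pp
        a = a + beta * rho
        c = gamma / d if R > 1 else np.empty(0)
        return _kernels.avg_marginal_loglik(a, c, obs.run_start, obs.run_off, obs.run_vals, obs.n_reads)

    def neg(theta: np.ndarray) -> float:
        ll = loglik(theta)
        if not np.isfinite(ll):
            return np.inf
        return -ll + cfg.ridge * float(np.dot(theta, theta))

    try:
        n_direct = max(cfg.budget // 2, 100)
        res = optimize.direct(neg, bounds=list(cfg.bounds), maxfun=n_direct, maxiter=10 * n_direct)
        polish = optimize.minimize(
            neg,
            res.x,
            method="Nelder-Mead",
            bounds=list(cfg.bounds),
            options={
                "maxfev": max(cfg.budget - res.nfev, 200),
                "fatol": cfg.improvement_tol,
                "xatol": 1e-4,
            },
        )
        best = polish if polish.fun <= res.fun else res
        if not np.isfinite(best.fun):
            return FitResult(None, -np.inf, 5, obs.n_reads, "skipped", "opt_fail")
    except Exception:  # optimizer failure is a per-region skip, not a crash
        return FitResult(None, -np.inf, 5, obs.n_reads, "skipped", "opt_fail")
    theta = np.clip(best.x, [b[0] for b in cfg.bounds], [b[1] for b in cfg.bounds])
    return FitResult(theta, float(loglik(theta)), 5, obs.n_reads)


def fit_general_ising(
    positions: np.ndarray,
    obs: ObservationMatrix,
    config: EstimationConfig | None = None,
    start: FitResult | None = None,
    rho: np.ndarray | None = None,
) -> FitResult:
    """Fit the unconstrained Ising model (one a_n per site, one c_n per pair;
    2R-1 parameters) on the same marginal likelihood.

    Regions larger than ``general_cap`` CpGs are skipped (complexity guard).
    The search starts from the constrained fit's potentials when available.
    """
    cfg = config or EstimationConfig()
    positions = np.asarray(positions, np.int64)
    R = len(positions)
    if R > cfg.general_cap:
        return FitResult(None, -np.inf, 2 * R - 1, obs.n_reads, "skipped", "too_large")
    a_lo, a_hi = cfg.bounds[1]
    c_lo, c_hi = -20.0, 20.0
    x0 = np.zeros(2 * R - 1)
    if start is not None and start.ok and rho is not None:
        m = build_potentials(tuple(start.theta_hat), rho, positions)
        x0[:R] = np.clip(m.a, a_lo, a_hi)
        x0[R:] = np.clip(m.c, c_lo, c_hi)

    def neg(x: np.ndarray) -> float:
        ll = _potential_loglik(x[:R], x[R:], obs)
        if not np.isfinite(ll):
            return np.inf
        return -ll + cfg.ridge * float(np.dot(x, x))

    bounds = [(a_lo, a_hi)] * R + [(c_lo, c_hi)] * (R - 1)
    try:
        res = optimize.minimize(
            neg, x0, method="Powell", bounds=bounds, options={"maxfev": cfg.general_budget}
        )
        if not np.isfinite(res.fun):
            return FitResult(None, -np.inf, 2 * R - 1, obs.n_reads, "skipped", "opt_fail")
    except Exception:
        return FitResult(None, -np.inf, 2 * R - 1, obs.n_reads, "skipped", "opt_fail")
    x = np.asarray(res.x)
    return FitResult(x, float(_potential_loglik(x[:R], x[R:], obs)), 2 * R - 1, obs.n_reads)


def general_model(fit: FitResult) -> RegionModel:
    """RegionModel from a general-Ising fit's parameter vector."""
    R = (fit.n_params + 1) // 2
    return RegionModel(a=fit.theta_hat[:R], c=fit.theta_hat[R:])


def aic_compare(fit1: FitResult, fit2: FitResult, n_reads: int | None = None) -> ModelComparison:
    """AIC_i = -2 * (M * average marginal loglik_i) + 2 p_i, and the AIC
    probability pi that the constrained model is the best of the two."""
    if n_reads is None:
        n_reads = fit1.n_reads
    if fit1.n_reads != fit2.n_reads:
        raise ValueError("fits must be on the same data")
    aic1 = -2.0 * n_reads * fit1.loglik + 2.0 * fit1.n_params
    aic2 = -2.0 * n_reads * fit2.loglik + 2.0 * fit2.n_params
    best = min(aic1, aic2)
    e1 = np.exp(-(aic1 - best) / 2.0)
    e2 = np.exp(-(aic2 - best) / 2.0)
    return ModelComparison(aic1=float(aic1), aic2=float(aic2), pi=float(e1 / (e1 + e2)))
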