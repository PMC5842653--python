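"""Exact computation with the inhomogeneous 1D Ising distribution.

The methylation state of the R CpG sites of an estimation region is a binary
vector X with PMF

    P(x) = (1/Z) exp{ sum_n a_n (2x_n - 1) + sum_{n>=2} c_n (2x_n - 1)(2x_{n-1} - 1) },

where a_n is a per-site field and c_n couples neighboring sites. Within a
region the fields derive from five region parameters theta = (alpha',
alpha, alpha'', beta, gamma):

    a_1 = alpha' + beta rho_1,  a_R = alpha'' + beta rho_R,
    a_n = alpha  + beta rho_n  (1 < n < R),        c_n = gamma / d_n,

with rho_n the CpG density and d_n the bp distance to the previous site.
alpha'/alpha'' are boundary fields on the region's first/last CpG that absorb
coupling across the (statistically independent) region boundaries.

All chain computations (partition function, marginals, level PMFs, sampling)
run in log domain or with per-step rescaling; brute-force enumeration over
2^R states is the test oracle for R <= 12.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RegionModel",
    "build_potentials",
    "log_partition",
    "state_log_probability",
    "state_probability",
    "site_marginals",
    "block_marginal_likelihood",
    "level_pmf",
    "sample_states",
]

_LOG_EPS = 1e-300


@dataclass
class RegionModel:
    """Per-site fields ``a`` (length R) and nearest-neighbor couplings ``c``
    (length R-1; c[i] couples sites i and i+1, 0-based)."""

    a: np.ndarray
    c: np.ndarray
    theta: tuple[float, float, float, float, float] | None = None

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.a.ndim != 1 or len(self.a) < 1:
            raise ValueError("a must be a non-empty 1D array")
        if len(self.c) != len(self.a) - 1:
            raise ValueError("c must have length R-1")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.c))):
            raise ValueError("potentials must be finite")

    @property
    def n_sites(self) -> int:
        return len(self.a)


def build_potentials(
    theta: tuple[float, float, float, float, float],
    rho: np.ndarray,
    positions: np.ndarray,
) -> RegionModel:
    """Region model from theta = (alpha', alpha, alpha'', beta, gamma) and the
    region's CpG densities and coordinates.

    Distances are taken between consecutive sites *within* the region; for a
    single-site region the model degenerates to one Bernoulli with field
    alpha' + beta*rho_1 (such regions are filtered upstream anyway).
    """
    alpha_p, alpha, alpha_pp, beta, gamma = (float(t) for t in theta)
    rho = np.asarray(rho, dtype=float)
    positions = np.asarray(positions, dtype=np.int64)
    R = len(rho)
    if R < 1 or len(positions) != R:
        raise ValueError("rho and positions must be non-empty and equal-length")
    a = np.full(R, alpha)
    a[0] = alpha_p
    if R > 1:
        a[-1] = alpha_pp
    a = a + beta * rho
    d = np.diff(positions).astype(float)
    if np.any(d <= 0):
        raise ValueError("site distances must be positive")
    c = gamma / d if R > 1 else np.empty(0)
    return RegionModel(a=a, c=c, theta=(alpha_p, alpha, alpha_pp, beta, gamma))


def _logaddexp2(v0: float | np.ndarray, v1: float | np.ndarray):
    return np.logaddexp(v0, v1)


def _forward(model: RegionModel) -> np.ndarray:
    """log F[n, x]: log of the sum over x_1..x_{n-1} of the chain weight up to
    and including site n fixed at x."""
    R = model.n_sites
    a, c = model.a, model.c
    logF = np.empty((R, 2))
    logF[0] = (-a[0], a[0])
    for n in range(1, R):
        # transition into x=0 (s=-1) and x=1 (s=+1) from x'=0/1
        logF[n, 0] = -a[n] + _logaddexp2(logF[n - 1, 0] + c[n - 1], logF[n - 1, 1] - c[n - 1])
        logF[n, 1] = a[n] + _logaddexp2(logF[n - 1, 0] - c[n - 1], logF[n - 1, 1] + c[n - 1])
    return logF


def _backward(model: RegionModel) -> np.ndarray:
    """log B[n, x]: log of the sum over x_{n+1}..x_R of the chain weight
    beyond site n, given X_n = x."""
    R = model.n_sites
    a, c = model.a, model.c
    logB = np.zeros((R, 2))
    for n in range(R - 2, -1, -1):
        logB[n, 0] = _logaddexp2(c[n] - a[n + 1] + logB[n + 1, 0], -c[n] + a[n + 1] + logB[n + 1, 1])
        logB[n, 1] = _logaddexp2(-c[n] - a[n + 1] + logB[n + 1, 0], c[n] + a[n + 1] + logB[n + 1, 1])
    return logB


def log_partition(model: RegionModel) -> float:
    """log Z by the forward transfer recursion."""
    logF = _forward(model)
    return float(_logaddexp2(logF[-1, 0], logF[-1, 1]))


def state_log_probability(model: RegionModel, x: np.ndarray) -> float:
    x = np.asarray(x)
    if len(x) != model.n_sites or not np.isin(x, (0, 1)).all():
        raise ValueError("x must be a binary vector of length R")
    s = 2.0 * x - 1.0
    energy = float(np.dot(model.a, s))
    if model.n_sites > 1:
        energy += float(np.dot(model.c, s[1:] * s[:-1]))
    return energy - log_partition(model)


def state_probability(model: RegionModel, x: np.ndarray) -> float:
    """Exact probability of one complete methylation state."""
    return float(np.exp(state_log_probability(model, x)))


def site_marginals(model: RegionModel) -> np.ndarray:
    """Pr[X_n = 1] for every site, via forward-backward messages."""
    logF = _forward(model)
    logB = _backward(model)
    logit = (logF[:, 1] + logB[:, 1]) - (logF[:, 0] + logB[:, 0])
    out = np.empty(model.n_sites)
    pos = logit >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-logit[pos]))
    out[~pos] = np.exp(logit[~pos]) / (1.0 + np.exp(logit[~pos]))
    return out


def _run_log_marginal(
    model: RegionModel,
    logF: np.ndarray,
    logB: np.ndarray,
    logZ: float,
    start: int,
    values: np.ndarray,
) -> float:
    """Exact log marginal probability of one contiguous observed run."""
    s = 2.0 * values - 1.0
    n = np.arange(start + 1, start + len(values))
    lm = logF[start, values[0]] + logB[start + len(values) - 1, values[-1]] - logZ
    if len(values) > 1:
        lm += float(np.dot(model.a[n], s[1:]) + np.dot(model.c[n - 1], s[1:] * s[:-1]))
    return float(lm)


def _split_runs(observed: dict[int, int], n_sites: int):
    if not observed:
        return []
    sites = np.array(sorted(observed), dtype=np.int64)
    if sites[0] < 0 or sites[-1] >= n_sites:
        raise ValueError("observed site index outside region")
    values = np.array([observed[int(i)] for i in sites], dtype=np.int64)
    if not np.isin(values, (0, 1)).all():
        raise ValueError("observed states must be 0 or 1")
    breaks = np.flatnonzero(np.diff(sites) > 1) + 1
    return [
        (int(s[0]), v)
        for s, v in zip(np.split(sites, breaks), np.split(values, breaks))
    ]


def block_marginal_likelihood(model: RegionModel, observed: dict[int, int]) -> float:
    """Marginal probability of a partial observation {site index -> state}.

    A single contiguous run of observed sites is marginalized exactly by
    message passing (flanking sites summed out). Non-contiguous observations
    are split into maximal contiguous runs and the product of the exact run
    marginals is returned — an approximation that is exact when couplings
    between the runs vanish. An empty observation has probability 1.
    """
    runs = _split_runs(observed, model.n_sites)
    if not runs:
        return 1.0
    logF = _forward(model)
    logB = _backward(model)
    logZ = float(_logaddexp2(logF[-1, 0], logF[-1, 1]))
    total = sum(_run_log_marginal(model, logF, logB, logZ, s, v) for s, v in runs)
    return float(np.exp(total))


def level_pmf(model: RegionModel, lo: int, hi: int) -> np.ndarray:
    """PMF of the methylation level L = (1/K) sum of states over the GU sites
    [lo, hi) (region-local indices), marginalizing all other sites of the
    region exactly.

    Returns an array of length K+1 over levels {0, 1/K, ..., 1}. Dynamic
    program over (site, methylated count) with per-step rescaling.
    """
    R = model.n_sites
    if not (0 <= lo < hi <= R):
        raise ValueError("GU site range must be a non-empty subrange of the region")
    K = hi - lo
    logF = _forward(model)
    logB = _backward(model)
    # linear-domain DP, rescaled each step; normalization at the end absorbs
    # all scale factors and Z
    scale = max(logF[lo, 0], logF[lo, 1])
    W = np.zeros((2, K + 1))
    W[0, 0] = np.exp(logF[lo, 0] - scale)
    W[1, 1] = np.exp(logF[lo, 1] - scale)
    for n in range(lo + 1, hi):
        cn = model.c[n - 1]
        an = model.a[n]
        Wn = np.zeros_like(W)
        # into x=0: shift of counts is 0
        Wn[0, :] = np.exp(-an) * (np.exp(cn) * W[0, :] + np.exp(-cn) * W[1, :])
        # into x=1: count increments by 1
        Wn[1, 1:] = np.exp(an) * (np.exp(-cn) * W[0, :-1] + np.exp(cn) * W[1, :-1])
        m = Wn.max()
        if m <= 0:
            raise FloatingPointError("level PMF recursion underflowed")
        W = Wn / m
    e = hi - 1
    bscale = max(logB[e, 0], logB[e, 1])
    p = W[0, :] * np.exp(logB[e, 0] - bscale) + W[1, :] * np.exp(logB[e, 1] - bscale)
    total = p.sum()
    if total <= 0:
        raise FloatingPointError("level PMF normalization underflowed")
    return p / total


def sample_states(
    model: RegionModel, n_samples: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Exact forward sampling of complete states: X_1 from its marginal, then
    X_n | X_{n-1} from the exact chain conditionals (backward messages).

    Returns an (n_samples, R) uint8 matrix; deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    R = model.n_sites
    logB = _backward(model)
    out = np.empty((n_samples, R), dtype=np.uint8)
    # P(X_1 = 1) = sigma(2 a_1 + logB[0,1] - logB[0,0])
    logit1 = 2.0 * model.a[0] + logB[0, 1] - logB[0, 0]
    p1 = 1.0 / (1.0 + np.exp(-logit1))
    out[:, 0] = rng.random(n_samples) < p1
    for n in range(1, R):
        sprev = 2.0 * out[:, n - 1].astype(float) - 1.0
        logit = 2.0 * model.c[n - 1] * sprev + 2.0 * model.a[n] + (logB[n, 1] - logB[n, 0])
        pn = 1.0 / (1.0 + np.exp(-logit))
        out[:, n] = rng.random(n_samples) < pn
    return out
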