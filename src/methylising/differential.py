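"""Two-sample per-GU statistics: dMML, dNME, the PMF of the level difference
D_L = L_t - L_r, the Jensen-Shannon distance (JSD), and the differential
classification schemes.

Level PMFs live on exact rational grids {k/K}; when the two samples model a
GU with different K, PMFs are embedded on the union of the two grids before
comparison (two levels coincide only if k_t/K_t = k_r/K_r exactly), which
preserves the disjoint-support => JSD = 1 property.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = [
    "DiffPMF",
    "DiffClassificationConfig",
    "diff_level_pmf",
    "kl_divergence",
    "jsd",
    "classify_diff_level",
    "classify_diff_entropy",
    "DIFF_LEVEL_CLASSES",
    "DIFF_ENTROPY_CLASSES",
]

DIFF_LEVEL_CLASSES = (
    "strongly_hypomethylated",
    "moderately_hypomethylated",
    "weakly_hypomethylated",
    "isomethylated",
    "weakly_hypermethylated",
    "moderately_hypermethylated",
    "strongly_hypermethylated",
)

DIFF_ENTROPY_CLASSES = (
    "strongly_hypoentropic",
    "moderately_hypoentropic",
    "weakly_hypoentropic",
    "isoentropic",
    "weakly_hyperentropic",
    "moderately_hyperentropic",
    "strongly_hyperentropic",
)


@dataclass
class DiffPMF:
    """PMF of D_L = L_t - L_r on its exact rational support in [-1, 1]."""

    support: tuple[Fraction, ...]
    p: np.ndarray

    @property
    def support_float(self) -> np.ndarray:
        return np.array([float(s) for s in self.support])

    def mean(self) -> float:
        return float(np.dot(self.support_float, self.p))


def _grid(pmf: np.ndarray) -> list[Fraction]:
    K = len(pmf) - 1
    if K == 0:
        return [Fraction(0)]
    return [Fraction(k, K) for k in range(K + 1)]


def diff_level_pmf(pmf_t: np.ndarray, pmf_r: np.ndarray) -> DiffPMF:
    """PMF of L_t - L_r by cross-convolution of the two level PMFs, assuming
    independence; masses at identical rational differences are merged."""
    pt = np.asarray(pmf_t, dtype=float)
    pr = np.asarray(pmf_r, dtype=float)
    gt, gr = _grid(pt), _grid(pr)
    acc: dict[Fraction, float] = {}
    for i, li in enumerate(gt):
        if pt[i] == 0.0:
            continue
        for j, lj in enumerate(gr):
            if pr[j] == 0.0:
                continue
            acc[li - lj] = acc.get(li - lj, 0.0) + pt[i] * pr[j]
    support = tuple(sorted(acc))
    return DiffPMF(support=support, p=np.array([acc[s] for s in support]))


def kl_divergence(P: np.ndarray, Q: np.ndarray) -> float:
    """Kullback-Leibler divergence sum P log2(P/Q) in bits over aligned
    supports; 0 log(0/q) = 0, and +inf where P > 0 with Q = 0."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("supports must be aligned")
    mask = P > 0
    if np.any(Q[mask] == 0):
        return float("inf")
    return float(np.sum(P[mask] * np.log2(P[mask] / Q[mask])))


def _align(pmf1: np.ndarray, pmf2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if len(pmf1) == len(pmf2):
        return np.asarray(pmf1, float), np.asarray(pmf2, float)
    g1, g2 = _grid(np.asarray(pmf1)), _grid(np.asarray(pmf2))
    union = sorted(set(g1) | set(g2))
    idx = {lv: i for i, lv in enumerate(union)}
    P = np.zeros(len(union))
    Q = np.zeros(len(union))
    for lv, p in zip(g1, pmf1):
        P[idx[lv]] += p
    for lv, p in zip(g2, pmf2):
        Q[idx[lv]] += p
    return P, Q


def jsd(pmf1: np.ndarray, pmf2: np.ndarray) -> float:
    """Jensen-Shannon distance in [0, 1]:
    sqrt((D(P1, Pbar) + D(P2, Pbar)) / 2) with Pbar the average PMF and D in
    bits. Zero iff the PMFs are equal; 1 iff their supports are disjoint.

    Equal-length inputs are taken as sharing the level grid {k/K}; otherwise
    both are embedded on the exact union grid.
    """
    P, Q = _align(pmf1, pmf2)
    M = 0.5 * (P + Q)
    div = 0.5 * (kl_divergence(P, M) + kl_divergence(Q, M))
    return float(np.sqrt(min(max(div, 0.0), 1.0)))


@dataclass
class DiffClassificationConfig:
    """Cut points for the differential level / entropy classes (symmetric
    about zero; configurable stand-ins for the published scheme)."""

    strong_shift: float = 0.5
    strong_mass: float = 0.9
    moderate_shift: float = 0.25
    moderate_mass: float = 0.75
    weak_mass: float = 0.5
    # |dNME| bin edges: iso within +/- iso_edge, then weak / moderate / strong
    iso_edge: float = 0.05
    weak_edge: float = 0.25
    moderate_edge: float = 0.55


def classify_diff_level(dl_pmf: DiffPMF, config: DiffClassificationConfig | None = None) -> str:
    """Seven-way differential-methylation class of a GU from the PMF of D_L."""
    cfg = config or DiffClassificationConfig()
    x = dl_pmf.support_float
    p = dl_pmf.p

    def mass_le(t: float) -> float:
        return float(p[x <= t + 1e-12].sum())

    def mass_ge(t: float) -> float:
        return float(p[x >= t - 1e-12].sum())

    if mass_le(-cfg.strong_shift) >= cfg.strong_mass:
        return "strongly_hypomethylated"
    if mass_ge(cfg.strong_shift) >= cfg.strong_mass:
        return "strongly_hypermethylated"
    if mass_le(-cfg.moderate_shift) >= cfg.moderate_mass:
        return "moderately_hypomethylated"
    if mass_ge(cfg.moderate_shift) >= cfg.moderate_mass:
        return "moderately_hypermethylated"
    if mass_le(-cfg.moderate_shift) >= cfg.weak_mass:
        return "weakly_hypomethylated"
    if mass_ge(cfg.moderate_shift) >= cfg.weak_mass:
        return "weakly_hypermethylated"
    return "isomethylated"


def classify_diff_entropy(dnme: float, config: DiffClassificationConfig | None = None) -> str:
    """Seven ordered bins of dNME = h_t - h_r, symmetric about zero."""
    cfg = config or DiffClassificationConfig()
    if not -1.0 <= dnme <= 1.0:
        raise ValueError("dnme must lie in [-1, 1]")
    mag = abs(dnme)
    if mag <= cfg.iso_edge:
        return "isoentropic"
    if mag <= cfg.weak_edge:
        kind = "weakly"
    elif mag <= cfg.moderate_edge:
        kind = "moderately"
    else:
        kind = "strongly"
    side = "hypoentropic" if dnme < 0 else "hyperentropic"
    return f"{kind}_{side}"
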