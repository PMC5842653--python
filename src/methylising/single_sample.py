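"""Per-GU single-sample statistics: mean methylation level (MML), normalized
methylation entropy (NME), and the level / entropy classification schemes.

For a GU with K CpG sites the methylation level is L = (1/K) sum_k X_k with
PMF P_L over {0, 1/K, ..., 1}. MML is E[L]; NME is the Shannon entropy of
P_L normalized by log2(K+1), so that a perfectly random level has NME 1
regardless of K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClassificationConfig",
    "compute_mml",
    "compute_nme",
    "classify_level",
    "classify_entropy",
    "LEVEL_CLASSES",
    "ENTROPY_CLASSES",
]

LEVEL_CLASSES = (
    "highly_unmethylated",
    "partially_unmethylated",
    "partially_methylated",
    "highly_methylated",
    "mixed",
    "highly_mixed",
    "bistable",
)

ENTROPY_CLASSES = (
    "highly_ordered",
    "moderately_ordered",
    "weakly_ordered_disordered",
    "moderately_disordered",
    "highly_disordered",
)


@dataclass
class ClassificationConfig:
    """Cut points of the level and entropy classification schemes.

    The defaults realize a symmetric rule set on the tail masses of P_L
    (p_low = Pr[L <= low_level], p_high = Pr[L >= high_level]); the exact
    published cut points are not fixed by the statistics themselves, so all
    of them are configurable.
    """

    low_level: float = 0.25
    high_level: float = 0.75
    highly_threshold: float = 0.9
    partially_threshold: float = 0.75
    bistable_threshold: float = 0.4
    highly_mixed_threshold: float = 0.9
    mixed_threshold: float = 0.75
    uniform_tail: float = 0.2  # fallback: tails this heavy + mid-dominant -> highly_mixed
    # entropy bins, symmetric around 0.5 (upper edges of the first four classes)
    entropy_edges: tuple[float, float, float, float] = (0.28, 0.44, 0.56, 0.72)


def _levels(pmf: np.ndarray) -> np.ndarray:
    K = len(pmf) - 1
    return np.arange(K + 1) / max(K, 1)


def compute_mml(level_pmf: np.ndarray | None = None, site_marginals=None) -> float:
    """Mean methylation level, either as the mean of the level PMF or as the
    average of the per-site marginals Pr[X_k = 1]; the two routes agree."""
    if level_pmf is not None:
        p = np.asarray(level_pmf, dtype=float)
        return float(np.dot(_levels(p), p))
    if site_marginals is None:
        raise ValueError("provide level_pmf or site_marginals")
    return float(np.mean(site_marginals))


def compute_nme(level_pmf: np.ndarray, n_sites: int | None = None) -> float:
    """Normalized methylation entropy h = -(1/log2(N+1)) sum P log2 P, with
    0 log 0 = 0; h in [0, 1] and equals 1 exactly for the uniform PMF."""
    p = np.asarray(level_pmf, dtype=float)
    if n_sites is None:
        n_sites = len(p) - 1
    if n_sites < 1:
        raise ValueError("GU must contain at least one CpG site")
    nz = p[p > 0]
    h = -float(np.sum(nz * np.log2(nz))) / np.log2(n_sites + 1)
    return float(min(max(h, 0.0), 1.0))


def classify_level(level_pmf: np.ndarray, config: ClassificationConfig | None = None) -> str:
    """Seven-way methylation-level class of a GU from the shape of P_L.

    Rules are tried in order on the tail masses; a PMF matching none falls
    back to the family with the largest mass (a mid-dominant PMF with both
    tails appreciable, e.g. the uniform one, is highly_mixed).
    """
    cfg = config or ClassificationConfig()
    p = np.asarray(level_pmf, dtype=float)
    lv = _levels(p)
    p_low = float(p[lv <= cfg.low_level].sum())
    p_high = float(p[lv >= cfg.high_level].sum())
    p_mid = float(p[(lv > cfg.low_level) & (lv < cfg.high_level)].sum())
    if p_low >= cfg.highly_threshold:
        return "highly_unmethylated"
    if p_high >= cfg.highly_threshold:
        return "highly_methylated"
    if p_low >= cfg.partially_threshold:
        return "partially_unmethylated"
    if p_high >= cfg.partially_threshold:
        return "partially_methylated"
    if min(p_low, p_high) >= cfg.bistable_threshold:
        return "bistable"
    if p_mid >= cfg.highly_mixed_threshold:
        return "highly_mixed"
    if p_mid >= cfg.mixed_threshold:
        return "mixed"
    # fallback: largest mass wins
    if p_mid >= p_low and p_mid >= p_high:
        if min(p_low, p_high) >= cfg.uniform_tail:
            return "highly_mixed"
        return "mixed"
    if p_low >= p_high:
        return "partially_unmethylated"
    return "partially_methylated"


def classify_entropy(nme: float, config: ClassificationConfig | None = None) -> str:
    """Five ordered entropy classes by simple thresholding of the NME."""
    cfg = config or ClassificationConfig()
    if not 0.0 <= nme <= 1.0:
        raise ValueError("nme must lie in [0, 1]")
    idx = int(np.searchsorted(np.asarray(cfg.entropy_edges), nme, side="left"))
    return ENTROPY_CLASSES[idx]
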