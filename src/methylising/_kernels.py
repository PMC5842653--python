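"""Hot-path likelihood kernel for region fitting.

The marginal log-likelihood of a read reduces, for each contiguous observed
run, to forward-message + interior-energy + backward-message - log Z, so one
objective evaluation costs O(R + total observed sites). numba compiles the
kernel when available; the plain-Python fallback computes the same numbers.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _lae(x: float, y: float) -> float:
    if x < y:
        x, y = y, x
    if x - y > 40.0:
        return x
    return x + math.log1p(math.exp(y - x))


@njit(cache=True)
def _messages(a, c, logF, logB) -> float:
    R = a.shape[0]
    logF[0, 0] = -a[0]
    logF[0, 1] = a[0]
    for n in range(1, R):
        logF[n, 0] = -a[n] + _lae(logF[n - 1, 0] + c[n - 1], logF[n - 1, 1] - c[n - 1])
        logF[n, 1] = a[n] + _lae(logF[n - 1, 0] - c[n - 1], logF[n - 1, 1] + c[n - 1])
    logB[R - 1, 0] = 0.0
    logB[R - 1, 1] = 0.0
    for n in range(R - 2, -1, -1):
        logB[n, 0] = _lae(c[n] - a[n + 1] + logB[n + 1, 0], -c[n] + a[n + 1] + logB[n + 1, 1])
        logB[n, 1] = _lae(-c[n] - a[n + 1] + logB[n + 1, 0], c[n] + a[n + 1] + logB[n + 1, 1])
    return _lae(logF[R - 1, 0], logF[R - 1, 1])


@njit(cache=True)
def _avg_marginal_loglik(a, c, run_start, run_off, run_vals, n_reads: int) -> float:
    R = a.shape[0]
    logF = np.empty((R, 2))
    logB = np.empty((R, 2))
    logZ = _messages(a, c, logF, logB)
    total = 0.0
    for r in range(run_start.shape[0]):
        s = run_start[r]
        o0 = run_off[r]
        o1 = run_off[r + 1]
        v0 = run_vals[o0]
        lm = logF[s, v0]
        sprev = 2.0 * v0 - 1.0
        for j in range(1, o1 - o0):
            n = s + j
            sv = 2.0 * run_vals[o0 + j] - 1.0
            lm += a[n] * sv + c[n - 1] * sprev * sv
            sprev = sv
        e = s + (o1 - o0) - 1
        lm += logB[e, run_vals[o1 - 1]] - logZ
        total += lm
    return total / n_reads


def avg_marginal_loglik(
    a: np.ndarray,
    c: np.ndarray,
    run_start: np.ndarray,
    run_off: np.ndarray,
    run_vals: np.ndarray,
    n_reads: int,
) -> float:
    """Average marginal log-likelihood (1/M) sum_m ln P(observed run set of
    read m) for flattened contiguous runs."""
    return float(
        _avg_marginal_loglik(
            np.ascontiguousarray(a, dtype=np.float64),
            np.ascontiguousarray(c, dtype=np.float64),
            run_start,
            run_off,
            run_vals,
            n_reads,
        )
    )
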