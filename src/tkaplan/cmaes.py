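"""Covariance matrix adaptation evolution strategy (CMA-ES).

A compact (mu/mu_w, lambda) CMA-ES minimizer with cumulative step-size
adaptation and rank-one plus rank-mu covariance updates, following the
standard formulation.  Sufficient for the low-dimensional (<= 6 DOF),
smooth, bounded pose searches used by the femoral planner; it is not a
general-purpose replacement for a full-featured CMA-ES library.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["CMAResult", "cma_es_minimize"]


@dataclass
class CMAResult:
    x_best: np.ndarray
    f_best: float
    n_evals: int
    converged: bool


def cma_es_minimize(
    fn: Callable[[np.ndarray], float],
    x0: np.ndarray,
    sigma0: float = 1.0,
    popsize: int | None = None,
    max_evals: int = 2000,
    seed: int = 0,
    ftol: float = 1e-10,
    xtol: float = 1e-9,
) -> CMAResult:
    """Minimize ``fn`` starting from ``x0`` with step size ``sigma0``.

    Deterministic for a fixed ``seed``.  Stops on evaluation budget, on
    step-size collapse (``sigma`` below ``xtol``) or when the function
    spread within a generation falls below ``ftol``.
    """
    rng = np.random.default_rng(seed)
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    lam = popsize if popsize is not None else 4 + int(3 * np.log(n))
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / (w**2).sum()

    cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    cs = (mueff + 2) / (n + mueff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    damps = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + cs
    chin = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

    mean = x0.copy()
    sigma = float(sigma0)
    C = np.eye(n)
    pc = np.zeros(n)
    ps = np.zeros(n)

    x_best = x0.copy()
    f_best = float(fn(x0))
    n_evals = 1
    converged = False

    while n_evals + lam <= max_evals:
        # eigendecomposition each generation; n is tiny so this is cheap
        D2, B = np.linalg.eigh(C)
        D = np.sqrt(np.maximum(D2, 1e-20))
        z = rng.standard_normal((lam, n))
        y = z @ np.diag(D) @ B.T
        xs = mean + sigma * y
        fs = np.array([fn(x) for x in xs])
        n_evals += lam

        order = np.argsort(fs)
        if fs[order[0]] < f_best:
            f_best = float(fs[order[0]])
            x_best = xs[order[0]].copy()

        y_sel = y[order[:mu]]
        y_w = w @ y_sel
        mean = mean + sigma * y_w

        C_invsqrt_y = B @ np.diag(1.0 / D) @ B.T @ y_w
        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mueff) * C_invsqrt_y
        hsig = float(
            np.linalg.norm(ps) / np.sqrt(1 - (1 - cs) ** (2 * n_evals / lam)) / chin
            < 1.4 + 2 / (n + 1)
        )
        pc = (1 - cc) * pc + hsig * np.sqrt(cc * (2 - cc) * mueff) * y_w

        rank_mu = (y_sel * w[:, None]).T @ y_sel
        C = (
            (1 - c1 - cmu) * C
            + c1 * (np.outer(pc, pc) + (1 - hsig) * cc * (2 - cc) * C)
            + cmu * rank_mu
        )
        sigma *= np.exp((cs / damps) * (np.linalg.norm(ps) / chin - 1))

        if sigma * D.max() < xtol or (fs.max() - fs.min()) < ftol:
            converged = True
            break

    return CMAResult(x_best=x_best, f_best=f_best, n_evals=n_evals, converged=converged)
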