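"""Nonnegative matrix factorization by multiplicative updates, plus the
variance-accounted-for (VAF) reconstruction metric.

The pooled envelope ``E`` (n channels x T samples) is approximated as
``E ~ W @ H`` with ``W`` an ``n x k`` nonnegative matrix of synergy
weights and ``H`` a ``k x T`` nonnegative matrix of activation
coefficients. Factors are estimated with the classical Euclidean
(Frobenius-norm) multiplicative update rules, whose objective is
guaranteed not to increase from one iteration to the next.

Reconstruction quality is measured as

    VAF = 100 * (1 - SSE / SST)

where SSE is the squared residual and SST the squared original data
(no mean removal): VAF is 100 only for a perfect reconstruction and may
be negative for a very poor one. ``vaf_global`` pools all entries;
``vaf_local`` applies the same formula per channel row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateDataError

_EPS = 1e-12


@dataclass
class SynergyModel:
    """A fitted nonnegative factor pair with its reconstruction quality."""

    W: np.ndarray
    H: np.ndarray
    k: int
    global_vaf: float
    local_vaf: np.ndarray
    seed: int | None
    iterations_run: int
    #: squared reconstruction error after every iteration (diagnostics)
    objective_trace: np.ndarray = field(repr=False, default=None)

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H


def _check_nonnegative(E: np.ndarray) -> np.ndarray:
    E = np.asarray(E, dtype=float)
    if E.ndim != 2:
        raise ValueError("E must be a 2-D matrix")
    if (E < 0).any():
        raise ValueError("E must be nonnegative")
    return E


def _uniform_open_closed(rng: np.random.Generator, shape) -> np.ndarray:
    # uniform in (0, 1]: avoids exact zeros, which are absorbing states
    # of the multiplicative updates
    return 1.0 - rng.random(shape)


def factorize(E: np.ndarray, k: int, seed=0, max_iter: int = 500,
              tol: float = 1e-6) -> SynergyModel:
    """Factor ``E ~ W @ H`` at rank ``k`` by multiplicative updates.

    Both factors are initialized uniformly at random in (0, 1] from
    ``seed`` and updated with the Euclidean multiplicative rules until the
    relative per-iteration decrease of the squared error falls below
    ``tol`` or ``max_iter`` iterations have run.

    Parameters
    ----------
    seed
        Anything acceptable to :func:`numpy.random.default_rng`.
    """
    E = _check_nonnegative(E)
    n, T = E.shape
    if not 1 <= k <= min(n, T):
        raise ValueError(f"k={k} out of range [1, {min(n, T)}]")
    rng = np.random.default_rng(seed)
    W = _uniform_open_closed(rng, (n, k))
    H = _uniform_open_closed(rng, (k, T))

    sst = float(np.vdot(E, E))
    trace = np.empty(max_iter)
    prev = np.inf
    it = 0
    WtE = W.T @ E
    for it in range(1, max_iter + 1):
        # H-step
        WtW = W.T @ W
        H *= WtE / (WtW @ H + _EPS)
        # W-step
        HHt = H @ H.T
        W *= (E @ H.T) / (W @ HHt + _EPS)
        # objective ||E - WH||^2 via the Gram expansion (no n x T product)
        WtE = W.T @ E
        WtW = W.T @ W
        err = sst - 2.0 * float(np.vdot(WtE, H)) + float(np.vdot(WtW, HHt))
        trace[it - 1] = err
        if prev - err < tol * max(prev, _EPS):
            break
        prev = err
    R = W @ H
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return SynergyModel(
        W=W, H=H, k=k,
        global_vaf=vaf_global(E, R),
        local_vaf=vaf_local(E, R),
        seed=seed_val,
        iterations_run=it,
        objective_trace=trace[:it].copy(),
    )


def fit_coefficients(E: np.ndarray, W: np.ndarray, seed=0,
                     max_iter: int = 500, tol: float = 1e-6) -> np.ndarray:
    """Estimate activation coefficients ``H`` for a fixed basis ``W``.

    Runs the multiplicative H-update only, with the same stopping rule as
    :func:`factorize`. Used to evaluate a basis fitted on the extraction
    subset against held-out validation samples.
    """
    E = _check_nonnegative(E)
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != E.shape[0]:
        raise ValueError(
            f"W has {W.shape[0] if W.ndim == 2 else '?'} rows, "
            f"E has {E.shape[0]}"
        )
    k = W.shape[1]
    rng = np.random.default_rng(seed)
    H = _uniform_open_closed(rng, (k, E.shape[1]))
    WtE = W.T @ E
    WtW = W.T @ W
    sst = float(np.vdot(E, E))
    prev = np.inf
    for _ in range(max_iter):
        H *= WtE / (WtW @ H + _EPS)
        err = sst - 2.0 * float(np.vdot(WtE, H)) + float(np.vdot(WtW, H @ H.T))
        if prev - err < tol * max(prev, _EPS):
            break
        prev = err
    return H


def best_factorize(E: np.ndarray, k: int, restarts: int = 50, seed=0,
                   max_iter: int = 500, tol: float = 1e-6) -> SynergyModel:
    """Best of ``restarts`` random-restart factorizations by global VAF."""
    base = seed if isinstance(seed, (int, np.integer)) else 0
    best = None
    for r in range(restarts):
        ss = np.random.SeedSequence(base, spawn_key=(r,))
        model = factorize(E, k, seed=ss, max_iter=max_iter, tol=tol)
        if best is None or model.global_vaf > best.global_vaf:
            best = model
    return best


def vaf_global(E: np.ndarray, R: np.ndarray) -> float:
    """Global variance accounted for, ``100 * (1 - SSE/SST)``."""
    E = np.asarray(E, dtype=float)
    R = np.asarray(R, dtype=float)
    if E.shape != R.shape:
        raise ValueError("E and R must have the same shape")
    sst = float(np.vdot(E, E))
    if sst == 0.0:
        raise DegenerateDataError("VAF undefined: E is all zero (SST = 0)")
    sse = float(np.vdot(E - R, E - R))
    return 100.0 * (1.0 - sse / sst)


def vaf_local(E: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Per-channel VAF: the same formula restricted to each row."""
    E = np.asarray(E, dtype=float)
    R = np.asarray(R, dtype=float)
    if E.shape != R.shape:
        raise ValueError("E and R must have the same shape")
    sst = (E ** 2).sum(axis=1)
    zero = np.flatnonzero(sst == 0.0)
    if zero.size:
        raise DegenerateDataError(
            f"VAF undefined for all-zero channel(s) {zero.tolist()}"
        )
    sse = ((E - R) ** 2).sum(axis=1)
    return 100.0 * (1.0 - sse / sst)
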