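"""Estimating the number of muscle synergies per subject.

For every candidate rank ``k`` the pooled envelope is repeatedly split at
random into an extraction subset (75% of samples) and a validation subset
(25%). The basis ``W`` is fitted on the extraction part, held fixed, and
the coefficients refit on the validation part; both global and local VAF
of the validation reconstruction are recorded. Of the repeated trials the
one with the highest validation global VAF is kept for that ``k``. The
estimated synergy count is the smallest ``k`` whose kept trial has
global VAF strictly above 95% AND every channel's local VAF strictly
above 85% (both thresholds configurable). If no rank qualifies, the
largest rank scanned is reported with ``saturated=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from . import nmf
from .errors import DegenerateDataError
from .preprocess import PooledEnvelope, electrode_set, preprocess
from .ninapro_io import EmgRecording


class Split(NamedTuple):
    extraction: np.ndarray
    validation: np.ndarray
    extraction_idx: np.ndarray
    validation_idx: np.ndarray


@dataclass
class DimensionalityResult:
    """Outcome of the repeated split/refit rank scan for one subject."""

    chosen_k: int
    per_k_global_vaf: np.ndarray
    per_k_min_local_vaf: np.ndarray
    thresholds: tuple[float, float]
    n_repeats: int
    criteria_met: np.ndarray
    saturated: bool
    k_values: np.ndarray

    def summary(self) -> dict:
        return {
            "chosen_k": int(self.chosen_k),
            "saturated": bool(self.saturated),
            "thresholds": {"global": self.thresholds[0], "local": self.thresholds[1]},
            "n_repeats": int(self.n_repeats),
            "per_k": [
                {
                    "k": int(k),
                    "global_vaf": float(g),
                    "min_local_vaf": float(l),
                    "criteria_met": bool(c),
                }
                for k, g, l, c in zip(self.k_values, self.per_k_global_vaf,
                                      self.per_k_min_local_vaf, self.criteria_met)
            ],
        }


def _trial_seed(seed, k: int, rep: int) -> np.random.SeedSequence:
    """Independent child seed per (rank, repeat) trial."""
    if isinstance(seed, np.random.SeedSequence):
        return np.random.SeedSequence(entropy=seed.entropy,
                                      spawn_key=tuple(seed.spawn_key) + (k, rep))
    return np.random.SeedSequence(seed, spawn_key=(k, rep))


def split_pool(E, fraction: float = 0.75, seed=0) -> Split:
    """Randomly partition pooled samples (columns) into extraction and
    validation subsets of ``round(fraction * T)`` and the remaining
    samples. Each part keeps the original temporal order.
    """
    X = E.E if isinstance(E, PooledEnvelope) else np.asarray(E, dtype=float)
    T = X.shape[1]
    if T < 8:
        raise DegenerateDataError(f"too few samples to split (T={T})")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(T)
    n_ext = round(fraction * T)
    if n_ext == 0 or n_ext == T:
        raise DegenerateDataError("split leaves one part empty")
    ext_idx = np.sort(perm[:n_ext])
    val_idx = np.sort(perm[n_ext:])
    return Split(X[:, ext_idx], X[:, val_idx], ext_idx, val_idx)


def estimate_k(pool: PooledEnvelope, n_repeats: int = 50, fraction: float = 0.75,
               global_threshold: float = 95.0, local_threshold: float = 85.0,
               seed: int = 0, k_max: int | None = None,
               stop_when_met: bool = False, max_iter: int = 500,
               tol: float = 1e-6) -> DimensionalityResult:
    """Estimate the synergy count of a pooled envelope.

    Parameters
    ----------
    n_repeats
        Independent (split, factorize, refit) trials per rank.
    k_max
        Largest rank to scan (default: the channel count).
    stop_when_met
        Stop scanning ranks once the criteria are first met. The chosen
        rank is unaffected (it is the minimum qualifying rank and every
        rank draws its own independent trials); only the recorded
        per-rank curve is truncated.
    seed
        Master seed; each (rank, repeat) trial derives an independent
        child seed so results do not depend on execution order.
    """
    if not (0 < local_threshold <= 100 and 0 < global_threshold <= 100):
        raise ValueError("thresholds must lie in (0, 100]")
    if n_repeats < 1:
        raise ValueError("n_repeats must be at least 1")
    n = pool.n_channels
    if n < 2:
        raise DegenerateDataError("need at least 2 channels")
    k_hi = n if k_max is None else min(k_max, n)

    per_k_global: list[float] = []
    per_k_min_local: list[float] = []
    met: list[bool] = []
    chosen = None
    for k in range(1, k_hi + 1):
        best_gv = -np.inf
        best_lv: np.ndarray | None = None
        for rep in range(n_repeats):
            ss = _trial_seed(seed, k, rep)
            split_seed, init_seed, h_seed = ss.spawn(3)
            sp = split_pool(pool, fraction=fraction, seed=split_seed)
            model = nmf.factorize(sp.extraction, k, seed=init_seed,
                                  max_iter=max_iter, tol=tol)
            H_val = nmf.fit_coefficients(sp.validation, model.W, seed=h_seed,
                                         max_iter=max_iter, tol=tol)
            R = model.W @ H_val
            gv = nmf.vaf_global(sp.validation, R)
            if gv > best_gv:
                best_gv = gv
                best_lv = nmf.vaf_local(sp.validation, R)
        per_k_global.append(best_gv)
        per_k_min_local.append(float(best_lv.min()))
        ok = best_gv > global_threshold and bool((best_lv > local_threshold).all())
        met.append(ok)
        if ok and chosen is None:
            chosen = k
            if stop_when_met:
                break

    saturated = chosen is None
    if saturated:
        chosen = k_hi
    return DimensionalityResult(
        chosen_k=chosen,
        per_k_global_vaf=np.array(per_k_global),
        per_k_min_local_vaf=np.array(per_k_min_local),
        thresholds=(global_threshold, local_threshold),
        n_repeats=n_repeats,
        criteria_met=np.array(met, dtype=bool),
        saturated=saturated,
        k_values=np.arange(1, len(per_k_global) + 1),
    )


def compare_configurations(recording: EmgRecording,
                           sets: dict[str, tuple[str, ...]] | list[str],
                           cutoff: float = 3.0, order: int = 4,
                           envelope_rate: float = 100.0,
                           **estimate_kwargs) -> dict[str, DimensionalityResult]:
    """Rerun the full pipeline for several electrode subsets.

    Each subset is re-pooled and re-normalized from the envelope stage,
    then rank-scanned independently, so the per-set results are suitable
    for paired statistical comparison.
    """
    if isinstance(sets, list):
        sets = {name: electrode_set(name) for name in sets}
    if not sets:
        raise ValueError("no electrode sets given")
    results: dict[str, DimensionalityResult] = {}
    for name, roles in sets.items():
        if len(roles) == 0:
            raise ValueError(f"electrode set {name!r} is empty")
        pool = preprocess(recording, keep_roles=tuple(roles), cutoff=cutoff,
                          order=order, envelope_rate=envelope_rate)
        results[name] = estimate_k(pool, **estimate_kwargs)
    return results
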