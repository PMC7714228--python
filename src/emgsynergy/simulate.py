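"""Synthetic synergy-driven EMG with known ground truth.

Every stage of the analysis pipeline can be exercised without real
recordings: a ground truth plants nonnegative electrode-weight columns
(``W_true``) and per-movement activation levels, a protocol schedules
17 movements x 6 repetitions with rest gaps (NinaPro-like: 5 s movement,
3 s rest, 2 kHz), and the synthesized signal is broadband noise
amplitude-modulated by the planted envelope ``W_true @ H_true`` — so
rectification, lowpass filtering and downsampling are genuinely
exercised, not bypassed. Additive sensor noise is scaled to the mean
envelope amplitude.

Cohorts share a library of synergy "types" (archetypal movement-
activation rows with disjoint dominant movements); each subject's
synergies are jittered copies of a subset of the library, which makes
the type structure recoverable by the clustering stage and provides the
oracle for typing benchmarks. Clinical covariates are drawn through a
Gaussian copula with configurable rank correlation to the planted
synergy count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.ndimage
import scipy.signal
import scipy.stats

from .ninapro_io import (ALL_ROLES, EmgRecording, FOREARM10_ROLES, RING_ROLES,
                         SubjectClinical)


@dataclass(frozen=True)
class Protocol:
    """Recording schedule: blocks of movement interleaved with rest."""

    n_movements: int = 17
    repetitions: int = 6
    movement_duration: float = 5.0
    rest_duration: float = 3.0
    sampling_rate: float = 2000.0


@dataclass
class GroundTruth:
    """Planted generative model of one subject's EMG."""

    W_true: np.ndarray               # (n_electrodes, k_true), nonnegative
    movement_activation: np.ndarray  # (k_true, n_movements), nonnegative
    noise_sd: float
    k_true: int
    protocol: Protocol = field(default_factory=Protocol)
    separation: float = 0.7
    #: global type-library row index of each synergy (set by cohorts)
    type_indices: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.W_true = np.asarray(self.W_true, dtype=float)
        self.movement_activation = np.asarray(self.movement_activation, dtype=float)
        if (self.W_true < 0).any() or (self.movement_activation < 0).any():
            raise ValueError("ground-truth factors must be nonnegative")
        if self.W_true.shape[1] != self.k_true:
            raise ValueError("W_true column count != k_true")
        if self.movement_activation.shape != (self.k_true,
                                              self.protocol.n_movements):
            raise ValueError("movement_activation shape mismatch")
        dominant = self.movement_activation.argmax(axis=0)
        if set(range(self.k_true)) - set(dominant.tolist()):
            raise ValueError("every synergy must dominate at least one movement")

    @property
    def n_electrodes(self) -> int:
        return self.W_true.shape[0]


def _child_seq(seed, key: int) -> np.random.SeedSequence:
    """Independent child seed stream; accepts ints or SeedSequences."""
    if isinstance(seed, np.random.SeedSequence):
        return np.random.SeedSequence(entropy=seed.entropy,
                                      spawn_key=tuple(seed.spawn_key) + (key,))
    return np.random.SeedSequence(seed, spawn_key=(key,))


def _pairwise_cosines(W: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(W, axis=0)
    G = (W.T @ W) / np.outer(norms, norms)
    return G[np.triu_indices(W.shape[1], k=1)]


def make_type_library(n_types: int, n_movements: int = 17, seed=0,
                      dominant_range=(0.7, 1.0),
                      off_range=(0.0, 0.15)) -> np.ndarray:
    """Archetypal movement-activation rows with disjoint dominant sets.

    Movements are split round-robin among the types; each type activates
    strongly on its own movements and weakly elsewhere.
    """
    if n_types > n_movements:
        raise ValueError("cannot give every type a dominant movement")
    rng = np.random.default_rng(seed)
    lib = rng.uniform(*off_range, size=(n_types, n_movements))
    for m in range(n_movements):
        t = m % n_types
        lib[t, m] = rng.uniform(*dominant_range)
    return lib


def make_ground_truth(n_electrodes: int, k_true: int, seed=0,
                      separation: float = 0.7, noise_sd: float = 0.1,
                      protocol: Protocol | None = None,
                      type_library: np.ndarray | None = None,
                      type_indices: tuple[int, ...] | None = None,
                      activation_jitter: float = 0.05,
                      max_rejections: int = 500) -> GroundTruth:
    """Sample a ground truth with well-separated synergy columns.

    ``W_true`` columns are drawn by rejection until every pairwise cosine
    similarity is at most ``separation``. Movement activations default to
    a fresh type library with one archetype per synergy (disjoint
    dominant movements); pass a shared ``type_library`` plus
    ``type_indices`` to plant cohort-wide synergy types.
    """
    if not 1 <= k_true <= n_electrodes:
        raise ValueError("need 1 <= k_true <= n_electrodes")
    protocol = protocol or Protocol()
    rng = np.random.default_rng(seed)
    # Synergies are localized: each gets a disjoint dominant electrode
    # subset (round-robin over a random electrode permutation) with strong
    # weights there and weak weights elsewhere — mirroring spatially
    # localized muscle groups and guaranteeing that each planted synergy
    # carries variance no smaller rank can absorb. Rejection sampling
    # enforces the pairwise cosine bound on top.
    cols: list[np.ndarray] = []
    attempts = 0
    while len(cols) < k_true:
        if not cols:
            electrode_perm = rng.permutation(n_electrodes)
        j = len(cols)
        dominant = electrode_perm[j::k_true]
        col = rng.uniform(0.0, 0.15, n_electrodes)
        col[dominant] = rng.uniform(0.7, 1.0, size=len(dominant))
        if all(
            float(col @ c / (np.linalg.norm(col) * np.linalg.norm(c)))
            <= separation for c in cols
        ):
            cols.append(col)
        else:
            attempts += 1
            if attempts > max_rejections:
                raise RuntimeError(
                    f"could not place {k_true} columns with pairwise cosine "
                    f"<= {separation}; loosen the separation bound"
                )
    W = np.column_stack(cols)

    if type_library is None:
        type_library = make_type_library(k_true, protocol.n_movements,
                                         seed=rng.integers(2 ** 31))
        type_indices = tuple(range(k_true))
    else:
        if type_indices is None:
            type_indices = tuple(
                rng.choice(type_library.shape[0], size=k_true, replace=False)
            )
    activation = type_library[list(type_indices)].copy()
    activation += rng.uniform(0.0, activation_jitter, size=activation.shape)
    return GroundTruth(
        W_true=W,
        movement_activation=activation,
        noise_sd=noise_sd,
        k_true=k_true,
        protocol=protocol,
        separation=separation,
        type_indices=tuple(int(t) for t in type_indices),
    )


def _roles_for(n: int) -> tuple[str, ...]:
    if n == 8:
        return RING_ROLES
    if n == 10:
        return FOREARM10_ROLES
    return ALL_ROLES[:n]


def planted_tracks(truth: GroundTruth, seed=0):
    """Deterministic planted envelope and labels for a given seed.

    Returns ``(envelope, H_true, movement_label, repetition_label)``
    where ``envelope = W_true @ H_true`` is ``n_electrodes x T`` at the
    protocol sampling rate. Per-repetition amplitude jitter and smooth
    process noise (scaled by ``noise_sd``) act on ``H_true`` and leave
    the envelope exactly rank ``k_true``; at ``noise_sd = 0`` the
    envelope is a clean synergy mixture.
    """
    p = truth.protocol
    fs = p.sampling_rate
    rng = np.random.default_rng(_child_seq(seed, 1))
    L_m = max(8, round(p.movement_duration * fs))
    L_r = max(0, round(p.rest_duration * fs))
    T = L_r + p.n_movements * p.repetitions * (L_m + L_r)
    k = truth.k_true
    H = np.zeros((k, T))
    movement = np.zeros(T, dtype=int)
    repetition = np.zeros(T, dtype=int)
    pulse = scipy.signal.windows.tukey(L_m, alpha=0.4)
    smooth_len = max(2, int(0.1 * fs))
    pos = L_r
    for m in range(1, p.n_movements + 1):
        level = truth.movement_activation[:, m - 1]
        for rep in range(1, p.repetitions + 1):
            jitter = rng.uniform(0.8, 1.2, size=k)
            block = np.outer(level * jitter, pulse)
            if truth.noise_sd > 0:
                wob = scipy.ndimage.uniform_filter1d(
                    rng.standard_normal((k, L_m)), size=smooth_len, axis=1)
                wob *= np.sqrt(smooth_len)  # restore ~unit variance
                block += truth.noise_sd * level[:, None] * np.abs(wob)
            H[:, pos:pos + L_m] = block
            movement[pos:pos + L_m] = m
            repetition[pos:pos + L_m] = rep
            pos += L_m + L_r
    envelope = truth.W_true @ H
    return envelope, H, movement, repetition


def synthesize(truth: GroundTruth, seed=0, carrier: bool = True) -> EmgRecording:
    """Render a ground truth as a raw multichannel EMG recording.

    With ``carrier=True`` (default) the signal is zero-mean broadband
    noise amplitude-modulated by the planted envelope, plus additive
    broadband sensor noise with standard deviation ``noise_sd`` times the
    mean movement-sample envelope amplitude. With ``carrier=False`` the
    (nonnegative) envelope itself is emitted, useful for fast tests of
    the post-envelope stages.
    """
    envelope, _, movement, repetition = planted_tracks(truth, seed)
    rng = np.random.default_rng(_child_seq(seed, 2))
    active = movement > 0
    scale = float(envelope[:, active].mean()) if active.any() else 1.0
    n, T = envelope.shape
    if carrier:
        signal = envelope * rng.standard_normal((n, T))
        if truth.noise_sd > 0:
            signal += truth.noise_sd * scale * rng.standard_normal((n, T))
    else:
        signal = envelope.copy()
        if truth.noise_sd > 0:
            signal += truth.noise_sd * scale * rng.standard_normal((n, T))
            np.clip(signal, 0.0, None, out=signal)
    return EmgRecording(
        signal=signal.T,
        sampling_rate=truth.protocol.sampling_rate,
        movement_label=movement,
        repetition_label=repetition,
        channel_roles=_roles_for(n),
        subject_id="synthetic",
        exercise_id="B",
    )


# ---------------------------------------------------------------------------
# Cohorts

@dataclass
class ClinicalModel:
    """Rank correlations (Gaussian copula) between the planted synergy
    count and each clinical covariate, plus uniform marginal ranges
    spanning the clinically plausible values."""

    rho_residual_forearm: float = 0.7
    rho_age: float = 0.5
    rho_years: float = 0.0
    rho_phantom: float = 0.0
    residual_range: tuple[float, float] = (0.0, 90.0)
    age_range: tuple[float, float] = (30.0, 67.0)
    years_range: tuple[float, float] = (1.0, 14.0)


@dataclass
class CohortSubject:
    """One synthetic subject; the raw recording is rendered on demand
    (a full-protocol recording is large, a cohort of eager recordings
    would not fit comfortably in memory)."""

    subject_id: str
    truth: GroundTruth
    clinical: SubjectClinical
    group: str = "control"
    _record_seed: int = 0

    def recording(self, carrier: bool = True) -> EmgRecording:
        rec = synthesize(self.truth, seed=self._record_seed, carrier=carrier)
        rec.subject_id = self.subject_id
        return rec


def _latent_rho_for_spearman(target: float, k_distribution: dict[int, float]) -> float:
    """Latent Gaussian correlation that delivers a population Spearman of
    ``target`` between a continuous copula covariate and the *discretized*
    synergy count (mid-rank convention).

    Setting the latent correlation to the target directly would
    under-deliver the configured association: discretization of the count
    and the Gaussian-to-grade mapping both attenuate rank correlation.
    """
    if abs(target) < 1e-12:
        return 0.0
    import scipy.integrate
    import scipy.optimize

    ks = sorted(k_distribution)
    p = np.array([k_distribution[k] for k in ks], dtype=float)
    p = p / p.sum()
    cum = np.minimum(np.cumsum(p), 1.0)
    cum[-1] = 1.0
    edges = scipy.stats.norm.ppf(np.concatenate([[0.0], cum]))
    mid = (np.concatenate([[0.0], cum[:-1]]) + cum) / 2  # mid-CDF grade
    var_g = float((p * mid ** 2).sum() - 0.25)
    if var_g <= 1e-12:
        # single-valued count: no association is attainable
        return 0.0

    def population_spearman(rho: float) -> float:
        scale = rho / np.sqrt(2.0 - rho ** 2)
        cov = 0.0
        for j in range(len(ks)):
            val, _ = scipy.integrate.quad(
                lambda t: scipy.stats.norm.cdf(scale * t)
                * scipy.stats.norm.pdf(t),
                edges[j], edges[j + 1])
            cov += mid[j] * val
        cov -= 0.25
        return cov / np.sqrt(var_g / 12.0)

    hi = 0.9999
    attainable = population_spearman(np.sign(target) * hi)
    if abs(target) >= abs(attainable):
        return float(np.sign(target) * hi)
    return float(scipy.optimize.brentq(
        lambda r: population_spearman(r) - target,
        -hi, hi, xtol=1e-6))


def _draw_from_distribution(dist: dict[int, float], u: float) -> int:
    ks = sorted(dist)
    probs = np.array([dist[k] for k in ks], dtype=float)
    if (probs < 0).any() or probs.sum() <= 0:
        raise ValueError("invalid k distribution")
    cum = np.cumsum(probs / probs.sum())
    return ks[int(np.searchsorted(cum, u, side="left"))]


def make_cohort(n_subjects: int, k_distribution: dict[int, float] | None = None,
                clinical_model: ClinicalModel | None = None, seed=0,
                n_electrodes: int = 10, n_types: int = 6,
                noise_sd: float = 0.1, separation: float = 0.7,
                protocol: Protocol | None = None,
                group: str = "control") -> list[CohortSubject]:
    """Generate a cohort sharing one synergy-type library.

    ``k_distribution`` maps synergy counts to probabilities (default: a
    control-like distribution concentrated on 5-6). Covariates are drawn
    with the configured Spearman association to the planted count via a
    Gaussian copula. Deterministic per seed.
    """
    if n_subjects < 4:
        raise ValueError("need at least 4 subjects")
    if k_distribution is None:
        k_distribution = {4: 0.2, 5: 0.45, 6: 0.35}
    if max(k_distribution) > min(n_types, n_electrodes):
        raise ValueError("k_distribution exceeds the type library size")
    cm = clinical_model or ClinicalModel()
    protocol = protocol or Protocol()
    root = np.random.SeedSequence(seed)
    lib_seed, cov_seed, *subj_seeds = root.spawn(2 + n_subjects)
    library = make_type_library(n_types, protocol.n_movements, seed=lib_seed)

    rng = np.random.default_rng(cov_seed)
    z_k = rng.standard_normal(n_subjects)

    def copula_uniform(rho):
        # calibrate so the realized Spearman vs the discrete count hits rho
        latent = _latent_rho_for_spearman(rho, k_distribution)
        eps = rng.standard_normal(n_subjects)
        z = latent * z_k + np.sqrt(max(0.0, 1 - latent ** 2)) * eps
        return scipy.stats.norm.cdf(z)

    u_res = copula_uniform(cm.rho_residual_forearm)
    u_age = copula_uniform(cm.rho_age)
    u_years = copula_uniform(cm.rho_years)
    u_phantom = copula_uniform(cm.rho_phantom)
    u_k = scipy.stats.norm.cdf(z_k)

    subjects = []
    for i in range(n_subjects):
        k_true = _draw_from_distribution(k_distribution, float(u_k[i]))
        truth_seed, rec_seed = subj_seeds[i].spawn(2)
        srng = np.random.default_rng(subj_seeds[i])
        type_idx = tuple(
            int(t) for t in srng.choice(n_types, size=k_true, replace=False)
        )
        truth = make_ground_truth(
            n_electrodes, k_true, seed=truth_seed, separation=separation,
            noise_sd=noise_sd, protocol=protocol, type_library=library,
            type_indices=type_idx,
        )
        clinical = SubjectClinical(
            residual_forearm_pct=float(np.interp(u_res[i], [0, 1],
                                                 cm.residual_range)),
            age=float(np.interp(u_age[i], [0, 1], cm.age_range)),
            years_since_amputation=float(np.interp(u_years[i], [0, 1],
                                                   cm.years_range)),
            phantom_sensation=int(min(5, np.floor(u_phantom[i] * 6))),
            prosthesis_experience=str(srng.choice(["Myo", "Cos", "Kin", "No"])),
            amputated_hand=str(srng.choice(["R", "L"])),
        )
        subjects.append(CohortSubject(
            subject_id=f"{group[:3]}{i + 1:02d}",
            truth=truth,
            clinical=clinical,
            group=group,
            _record_seed=rec_seed,
        ))
    return subjects


def planted_type_of(profile: np.ndarray, truth: GroundTruth) -> int:
    """Oracle for typing benchmarks: the global type id of the planted
    synergy whose (z-scored) activation archetype correlates best with a
    recovered feature profile."""
    if truth.type_indices is None:
        raise ValueError("ground truth carries no type indices")
    rows = truth.movement_activation
    best, best_r = -1, -np.inf
    for j in range(rows.shape[0]):
        row = rows[j]
        r = float(np.corrcoef(profile, row)[0, 1])
        if r > best_r:
            best_r, best = r, j
    return int(truth.type_indices[best])


def truth_to_json(truth: GroundTruth) -> dict:
    """JSON-serializable sidecar describing a ground truth."""
    d = asdict(truth)
    d["W_true"] = truth.W_true.tolist()
    d["movement_activation"] = truth.movement_activation.tolist()
    d["protocol"] = asdict(truth.protocol)
    return d
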