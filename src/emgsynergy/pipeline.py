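"""Per-subject and cohort-level orchestration.

``run_subject`` chains preprocessing, the rank scan, a final refit of the
factorization at the chosen rank on all pooled samples (best of random
restarts), and feature construction. ``run_cohort`` pools control
features, clusters them into synergy types, names representative
movements, assigns every patient synergy to a control type (or 0), and
runs the group statistics.

Per-subject seeds are derived from the master seed and a hash of the
subject id — never from the subject's position in the cohort — so adding
or removing one subject cannot perturb any other subject's results, and
control clustering is invariant to the patient list.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import group_stats
from .dimensionality import DimensionalityResult, estimate_k
from .nmf import SynergyModel, best_factorize
from .ninapro_io import EmgRecording, SubjectClinical
from .preprocess import PooledEnvelope, electrode_set, preprocess
from .synergy_typing import (ClusterModel, EXERCISE_B_MOVEMENTS,
                             assign_patient_synergy, build_features,
                             cluster_features)


@dataclass
class RunConfig:
    """Full parameter surface of a run; serializable and hashable so a
    run is reproducible from (config, inputs) alone."""

    electrode_set: str = "forearm10"
    cutoff_hz: float = 3.0
    filter_order: int = 4
    envelope_rate_hz: float = 100.0
    n_repeats: int = 50
    split_fraction: float = 0.75
    global_threshold: float = 95.0
    local_threshold: float = 85.0
    nmf_max_iter: int = 500
    nmf_tol: float = 1e-6
    refit_restarts: int = 50
    k_max: int | None = None
    stop_when_met: bool = False
    cluster_k_min: int = 2
    cluster_k_max: int = 15
    cluster_restarts: int = 50
    movement_list: tuple[int, ...] = EXERCISE_B_MOVEMENTS
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["movement_list"] = list(self.movement_list)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _subject_seed(config_seed: int, subject_id: str, purpose: str) -> np.random.SeedSequence:
    digest = hashlib.sha256(f"{subject_id}/{purpose}".encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.SeedSequence(config_seed, spawn_key=(key,))


@dataclass
class SubjectResult:
    subject_id: str
    dimensionality: DimensionalityResult
    model: SynergyModel
    features: list
    pool: PooledEnvelope = field(repr=False, default=None)

    @property
    def chosen_k(self) -> int:
        return self.dimensionality.chosen_k


def run_subject(recording: EmgRecording, config: RunConfig) -> SubjectResult:
    """Preprocess -> rank scan -> full-data refit -> feature vectors."""
    roles = electrode_set(config.electrode_set)
    missing = set(roles) - set(recording.channel_roles)
    if missing:
        raise KeyError(
            f"subject {recording.subject_id!r}: electrode set "
            f"{config.electrode_set!r} needs channels {sorted(missing)} "
            f"that the recording lacks"
        )
    try:
        pool = preprocess(recording, keep_roles=roles, cutoff=config.cutoff_hz,
                          order=config.filter_order,
                          envelope_rate=config.envelope_rate_hz)
    except Exception as exc:
        raise type(exc)(f"[preprocess] {exc}") from exc
    dim = estimate_k(
        pool,
        n_repeats=config.n_repeats,
        fraction=config.split_fraction,
        global_threshold=config.global_threshold,
        local_threshold=config.local_threshold,
        seed=_subject_seed(config.seed, recording.subject_id, "estimate"),
        k_max=config.k_max,
        stop_when_met=config.stop_when_met,
        max_iter=config.nmf_max_iter,
        tol=config.nmf_tol,
    )
    # the model fed to feature construction is refit on 100% of the pooled
    # samples at the chosen rank, best of random restarts
    model = best_factorize(
        pool.E, dim.chosen_k, restarts=config.refit_restarts,
        seed=int(_subject_seed(config.seed, recording.subject_id,
                               "refit").generate_state(1)[0] >> 1),
        max_iter=config.nmf_max_iter, tol=config.nmf_tol,
    )
    features = build_features(model, pool.movement_of_sample,
                              movement_list=config.movement_list, E=pool.E)
    for f in features:
        f.subject_id = recording.subject_id
    return SubjectResult(
        subject_id=recording.subject_id,
        dimensionality=dim,
        model=model,
        features=features,
        pool=pool,
    )


@dataclass
class CohortReport:
    clusters: ClusterModel
    subject_results: dict[str, SubjectResult]
    cluster_summary: pd.DataFrame
    patient_assignments: pd.DataFrame
    activation_matrix: pd.DataFrame
    stats: dict[str, group_stats.StatResult]


def run_cohort(controls, patients=(), config: RunConfig | None = None,
               clinical: dict[str, SubjectClinical] | None = None,
               recordings_of=None) -> CohortReport:
    """Cohort-level analysis.

    Parameters
    ----------
    controls, patients
        Iterables of :class:`EmgRecording`, or of objects with a
        ``recording()`` method and ``subject_id``/``clinical`` attributes
        (e.g. :class:`emgsynergy.simulate.CohortSubject`).
    clinical
        Optional subject_id -> :class:`SubjectClinical` mapping for the
        patient group (merged with any ``clinical`` attributes found).
    """
    config = config or RunConfig()
    clinical = dict(clinical or {})

    def _resolve(item):
        if isinstance(item, EmgRecording):
            return item.subject_id, item
        rec = item.recording()
        if getattr(item, "clinical", None) is not None:
            clinical.setdefault(rec.subject_id, item.clinical)
        return rec.subject_id, rec

    results: dict[str, SubjectResult] = {}
    control_ids, patient_ids = [], []
    for group, ids, items in (("control", control_ids, controls),
                              ("patient", patient_ids, patients)):
        for item in items:
            sid, rec = _resolve(item)
            results[sid] = run_subject(rec, config)
            ids.append(sid)
    if len(control_ids) < 2:
        raise ValueError("need at least 2 control subjects for clustering")

    control_features = [f for sid in control_ids for f in results[sid].features]
    clusters = cluster_features(
        control_features,
        k_range=range(config.cluster_k_min, config.cluster_k_max + 1),
        restarts=config.cluster_restarts,
        seed=config.seed,
        movement_ids=config.movement_list,
    )

    rows = []
    for j in range(clusters.n_clusters):
        members = clusters.assignment == j + 1
        shares = [f.explained_variance_share
                  for f, m in zip(control_features, members) if m]
        primary, secondary = clusters.representatives[j]
        rows.append({
            "cluster": j + 1,
            "n_synergy_samples": int(members.sum()),
            "mean_variance_share": float(np.mean(shares)),
            "sd_variance_share": float(np.std(shares)),
            "primary_movement": primary,
            "secondary_movement": secondary,
        })
    cluster_summary = pd.DataFrame(rows)

    assign_rows = []
    for sid in patient_ids:
        feats = sorted(results[sid].features,
                       key=lambda f: -(f.explained_variance_share or 0.0))
        for f in feats:
            assign_rows.append({
                "subject_id": sid,
                "synergy_index": f.synergy_index,
                "cluster": assign_patient_synergy(f, clusters),
                "variance_share": f.explained_variance_share,
            })
    patient_assignments = pd.DataFrame(
        assign_rows, columns=["subject_id", "synergy_index", "cluster",
                              "variance_share"])

    activation_matrix = pd.DataFrame(
        clusters.centroids,
        index=[f"cluster{j + 1}" for j in range(clusters.n_clusters)],
        columns=[f"m{m}" for m in clusters.movement_ids],
    )

    stats: dict[str, group_stats.StatResult] = {}
    patient_k = [results[sid].chosen_k for sid in patient_ids]
    control_k = [results[sid].chosen_k for sid in control_ids]
    if len(patient_k) >= 3 and len(control_k) >= 3:
        stats["k_control_vs_patient"] = group_stats.unpaired_compare(
            control_k, patient_k)
    covariates = {
        "residual_forearm_pct": lambda c: c.residual_forearm_pct,
        "age": lambda c: c.age,
        "years_since_amputation": lambda c: c.years_since_amputation,
        "phantom_sensation": lambda c: c.phantom_sensation,
    }
    with_clinical = [sid for sid in patient_ids if sid in clinical]
    if len(with_clinical) >= 4:
        ks = [results[sid].chosen_k for sid in with_clinical]
        for name, getter in covariates.items():
            vals = [getter(clinical[sid]) for sid in with_clinical]
            try:
                stats[f"k_vs_{name}"] = group_stats.spearman_assoc(vals, ks)
            except group_stats.DegenerateDataError:
                continue  # constant covariate or constant counts
    return CohortReport(
        clusters=clusters,
        subject_results=results,
        cluster_summary=cluster_summary,
        patient_assignments=patient_assignments,
        activation_matrix=activation_matrix,
        stats=stats,
    )
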