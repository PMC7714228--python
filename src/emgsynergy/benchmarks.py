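"""Parameter-recovery benchmarks against the synthetic generator.

These routines measure how well the pipeline recovers quantities the
generator planted: the synergy count, the synergy-type structure, and
the rank correlation embedded between clinical covariates and the
planted count. They are shared by the test suite and the acceptance
script.

Benchmarks run on shortened movement/rest blocks (the planted structure
is unaffected; only the sample count per movement shrinks) and a reduced
repeat count for the rank scan; see the methods note for the problem
sizes used.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import simulate
from .dimensionality import estimate_k
from .group_stats import spearman_assoc
from .nmf import best_factorize
from .preprocess import preprocess
from .synergy_typing import assign_patient_synergy, build_features, cluster_features

#: shortened protocols used by desk-scale benchmarks
K_RECOVERY_PROTOCOL = simulate.Protocol(movement_duration=1.0, rest_duration=0.5)
TYPING_PROTOCOL = simulate.Protocol(movement_duration=0.5, rest_duration=0.25)


def _sub_seed(seed: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(seed, spawn_key=tuple(key))


def k_recovery(k_values=(2, 3, 4, 5, 6), n_seeds: int = 20,
               n_electrodes: int = 10, noise_sd: float = 0.1,
               n_repeats: int = 10, seed: int = 0,
               protocol: simulate.Protocol = K_RECOVERY_PROTOCOL) -> dict:
    """Fraction of runs in which estimate_k returns the planted count.

    Each run draws a fresh ground truth, renders a raw recording, runs the
    full preprocessing chain and the rank scan.
    """
    per_k: dict[int, float] = {}
    for ki, k_true in enumerate(k_values):
        hits = 0
        for i in range(n_seeds):
            truth_seed, rec_seed, est_seed = _sub_seed(seed, ki, i).spawn(3)
            truth = simulate.make_ground_truth(
                n_electrodes, k_true, seed=truth_seed, noise_sd=noise_sd,
                protocol=protocol)
            rec = simulate.synthesize(truth, seed=rec_seed)
            pool = preprocess(rec, keep_roles=rec.channel_roles)
            res = estimate_k(pool, n_repeats=n_repeats, seed=est_seed,
                             stop_when_met=True)
            hits += int(res.chosen_k == k_true)
        per_k[k_true] = hits / n_seeds
    overall = float(np.mean(list(per_k.values())))
    return {"per_k": per_k, "overall": overall,
            "n_runs": len(k_values) * n_seeds}


def typing_recovery(n_subjects: int = 40, n_types: int = 6, seed: int = 0,
                    noise_sd: float = 0.1, refit_restarts: int = 3,
                    cluster_restarts: int = 50,
                    protocol: simulate.Protocol = TYPING_PROTOCOL) -> dict:
    """Cluster-count and assignment agreement against planted synergy types.

    Factorizes every control subject at the planted rank, pools the
    feature vectors, clusters them, and scores the partition against the
    planted type of each synergy via the best cluster-to-type bijection.
    Additionally plants one patient synergy of a type absent from the
    library and reports whether it is (correctly) left untyped.
    """
    cohort = simulate.make_cohort(n_subjects, seed=seed, n_types=n_types,
                                  noise_sd=noise_sd, protocol=protocol)
    features, true_types = [], []
    for si, subj in enumerate(cohort):
        rec = subj.recording()
        pool = preprocess(rec)
        model = best_factorize(pool.E, subj.truth.k_true,
                               restarts=refit_restarts,
                               seed=int(_sub_seed(seed, 1, si)
                                        .generate_state(1)[0] >> 1))
        for f in build_features(model, pool.movement_of_sample, E=pool.E):
            f.subject_id = subj.subject_id
            features.append(f)
            true_types.append(simulate.planted_type_of(f.profile, subj.truth))
    clusters = cluster_features(features, restarts=cluster_restarts, seed=seed)

    # agreement under the best bijection between clusters and planted types
    tt = np.asarray(true_types)
    contingency = np.zeros((clusters.n_clusters, n_types))
    for lab, t in zip(clusters.assignment, tt):
        contingency[lab - 1, t] += 1
    rows, cols = linear_sum_assignment(-contingency)
    agreement = float(contingency[rows, cols].sum() / len(tt))

    # a patient synergy of a novel type must stay untyped (cluster 0)
    lib_seed = np.random.SeedSequence(seed).spawn(1)[0]
    library = simulate.make_type_library(n_types, protocol.n_movements,
                                         seed=lib_seed)
    rng = np.random.default_rng(_sub_seed(seed, 2))
    novel_row = rng.uniform(0.0, 0.1, protocol.n_movements)
    # strong on exactly one dominant movement of every planted type, so it
    # correlates only weakly with each of them
    novel_row[list(range(n_types))] = rng.uniform(0.8, 1.0, n_types)
    augmented = np.vstack([library, novel_row])
    novel_truth = simulate.make_ground_truth(
        10, 1, seed=_sub_seed(seed, 3), noise_sd=noise_sd, protocol=protocol,
        type_library=augmented, type_indices=(n_types,))
    novel_rec = simulate.synthesize(novel_truth, seed=_sub_seed(seed, 4))
    novel_pool = preprocess(novel_rec)
    novel_model = best_factorize(novel_pool.E, 1, restarts=refit_restarts,
                                 seed=7)
    novel_feature = build_features(novel_model, novel_pool.movement_of_sample,
                                   E=novel_pool.E)[0]
    novel_assignment = assign_patient_synergy(novel_feature, clusters)

    return {
        "n_clusters": clusters.n_clusters,
        "agreement": agreement,
        "n_features": len(features),
        "novel_assignment": novel_assignment,
        "silhouette_by_k": clusters.silhouette_by_k,
    }


def cohort_stat_recovery(rho: float, n_cohorts: int = 10,
                         n_subjects: int = 40, seed: int = 0,
                         covariate: str = "residual_forearm_pct") -> list[float]:
    """Spearman rho between a copula-linked covariate and the planted
    synergy count, across independent cohort draws."""
    out = []
    model = simulate.ClinicalModel(rho_residual_forearm=rho, rho_age=0.0)
    for c in range(n_cohorts):
        cohort = simulate.make_cohort(
            n_subjects,
            k_distribution={2: 0.15, 3: 0.2, 4: 0.3, 5: 0.2, 6: 0.15},
            clinical_model=model,
            seed=int(_sub_seed(seed, 5, c).generate_state(1)[0] >> 1),
            group="patient",
        )
        ks = [s.truth.k_true for s in cohort]
        covs = [getattr(s.clinical, covariate) for s in cohort]
        out.append(spearman_assoc(covs, ks).statistic)
    return out
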