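"""End-to-end cohort analysis: edges -> states -> dynamics -> energy -> stats.

Ties the modules together the way the study design prescribes: pool edge
frames across subjects, cluster them into connectivity states (selecting k
by the elbow rule unless fixed), reduce each subject's state sequence to
dynamics measures, compute control energies on each subject's connectome,
z-score energy matrices against the healthy controls, and run
covariate-adjusted group comparisons with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cognition import DOMAINS, adjust_and_zscore, classify_table
from .dynamics import StateSequence, summarize_dynamics
from .edges import edge_time_series, zscore_regional
from .energy import (build_control_system, energy_transition_matrix,
                     framewise_energy, summarize_energy, zscore_vs_controls)
from .states import StateSet, fit_states, inertia_curve, select_k_elbow
from .stats import GroupComparisonResult, compare_groups
from .synthetic import Cohort

__all__ = ["CohortAnalysis", "pool_edges", "analyze_cohort"]


def pool_edges(timeseries: dict, dtype=np.float32):
    """Z-score each subject, build edge series, and stack frames cohort-wide.

    Returns ``(pooled, provenance, z_by_subject)`` where ``provenance`` maps
    each pooled row to ``(subject_id, frame_index)``.  float32 by default:
    clustering 10^4+ frames by 10^3+ edges is memory-bound and the cluster
    geometry is unaffected at that precision.
    """
    blocks, provenance, z_by_subject = [], [], {}
    for sid, ts in timeseries.items():
        z = zscore_regional(np.asarray(ts, dtype=float))
        z_by_subject[sid] = z
        edges, _ = edge_time_series(z)
        blocks.append(edges.astype(dtype))
        provenance.extend((sid, t) for t in range(edges.shape[0]))
    return np.vstack(blocks), provenance, z_by_subject


@dataclass
class CohortAnalysis:
    selected_k: int
    inertia_by_k: dict
    states: StateSet
    sequences: dict                       # subject_id -> StateSequence
    dynamics: pd.DataFrame                # one row per subject
    energy_matrices: dict                 # subject_id -> k x k ndarray (raw)
    energy_zscored: dict                  # subject_id -> k x k ndarray (vs HC)
    energy: pd.DataFrame                  # per-subject summaries (z-scored)
    comparisons: list = field(default_factory=list)

    @property
    def comparisons_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.comparisons:
            rows.append({"measure": r.measure, "method": r.method, "F": r.F,
                         "p_raw": r.p_raw, "p_bonferroni": r.p_bonferroni,
                         "beta": r.contrast_beta, "ci_low": r.contrast_ci95[0],
                         "ci_high": r.contrast_ci95[1], "n": r.n_complete})
        return pd.DataFrame(rows)


def _split_assignments(states: StateSet, provenance) -> dict:
    per_subject: dict[str, list[int]] = {}
    for label, (sid, _) in zip(states.assignments, provenance):
        per_subject.setdefault(sid, []).append(int(label))
    return {sid: StateSequence(subject_id=sid, labels=np.array(lab), k=states.k)
            for sid, lab in per_subject.items()}


def analyze_cohort(cohort: Cohort, k_range=range(2, 8), replicates: int = 5,
                   fixed_k: int | None = None, horizon: float = 1.0,
                   c: float = 1.0, seed: int = 0, run_stats: bool = True,
                   precomputed_states: StateSet | None = None) -> CohortAnalysis:
    """Run the full pipeline on a cohort (synthetic or loaded from disk).

    ``precomputed_states`` (with frame provenance) skips the clustering
    stage, e.g. to reuse one model-order scan for several analyses.
    """
    pooled, provenance, z_by_subject = pool_edges(cohort.timeseries)

    if precomputed_states is not None:
        states = precomputed_states
        if states.frame_provenance is not None:
            provenance = states.frame_provenance
        inertias = dict(states.inertia_by_k)
        selected_k = states.k
    elif fixed_k is not None:
        states = fit_states(pooled, fixed_k, replicates=replicates, seed=seed,
                            frame_provenance=provenance)
        inertias = dict(states.inertia_by_k)
        selected_k = fixed_k
    else:
        inertias, fits = inertia_curve(pooled, k_values=k_range,
                                       replicates=replicates, seed=seed,
                                       frame_provenance=provenance)
        selected_k = select_k_elbow(inertias)
        states = fits[selected_k]

    sequences = _split_assignments(states, provenance)
    k = states.k

    groups = cohort.subjects["group"]
    dyn_rows = []
    for sid, seq in sequences.items():
        summ = summarize_dynamics(seq)
        row = {"subject_id": sid, "group": groups.get(sid, "NA"),
               "total_transitions": summ.total_transitions}
        row.update({f"fo_{i + 1}": summ.fractional_occupancy[i] for i in range(k)})
        for i in range(k):
            for j in range(k):
                row[f"tp_{i + 1}_{j + 1}"] = summ.transition_probability[i, j]
        dyn_rows.append(row)
    dynamics = pd.DataFrame(dyn_rows).set_index("subject_id")

    matrices = {}
    for sid, seq in sequences.items():
        sys = build_control_system(cohort.connectomes[sid], horizon=horizon, c=c)
        energies = framewise_energy(z_by_subject[sid], sys)
        matrices[sid] = energy_transition_matrix(energies, seq)
    zscored = zscore_vs_controls(matrices, cohort.hc_ids)

    en_rows = []
    for sid, zm in zscored.items():
        s = summarize_energy(zm)
        en_rows.append({"subject_id": sid, "group": groups.get(sid, "NA"),
                        "total_ce": s.total, "persistence_ce": s.persistence,
                        "transition_ce": s.transition})
    energy = pd.DataFrame(en_rows).set_index("subject_id")

    comparisons: list[GroupComparisonResult] = []
    if run_stats:
        covs = cohort.subjects[["age", "sex", "education"]]
        comparisons.append(compare_groups(
            dynamics["total_transitions"], dynamics["group"],
            covs.loc[dynamics.index].reset_index(drop=True),
            measure="total_transitions", family_size=1))
        for col in ("total_ce", "persistence_ce", "transition_ce"):
            comparisons.append(compare_groups(
                energy[col], energy["group"],
                covs.loc[energy.index].reset_index(drop=True),
                measure=col, family_size=3))

    return CohortAnalysis(selected_k=selected_k, inertia_by_k=inertias,
                          states=states, sequences=sequences, dynamics=dynamics,
                          energy_matrices=matrices, energy_zscored=zscored,
                          energy=energy, comparisons=comparisons)


def classify_cohort(cohort: Cohort) -> pd.Series:
    """HC-referenced cognitive z-scores + CP/MCI/CI labels for the patients."""
    z = adjust_and_zscore(cohort.subjects[list(DOMAINS)],
                          cohort.subjects[["age", "sex", "education"]],
                          cohort.hc_ids)
    patients = cohort.subjects.index[cohort.subjects["group"] != "HC"]
    return classify_table(z.loc[patients])
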