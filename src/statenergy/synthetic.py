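"""Synthetic cohort with planted connectivity states and group effects.

Generates a cohort of HC / CP / MCI / CI subjects in which every quantity
the pipeline estimates has a known ground truth:

* k orthonormal activation templates define the connectivity states; a
  hidden Markov chain (initialised at its stationary distribution) selects
  the active state per frame, and the regional signal is the template times
  a random-sign amplitude plus Gaussian noise.  Impaired groups get more
  Markov mass on the diagonal (fewer transitions).
* Structural connectomes follow a stochastic block model with log-normal
  weights plus a structure-function coupling term supporting the planted
  activity patterns.  Impaired groups get globally weaker weights (the
  "integrity" factor) and, critically, a selective loss of the coupling
  term — which is what makes their state transitions energetically costly
  (a uniform weight loss is cancelled by the spectral normalisation of
  the control model).
* Cognitive domain scores are linear in age/sex/education plus a planted
  group deficit (in HC-SD units) and unit-variance noise, so HC-referenced
  adjustment has real structure to remove.

Everything is reproducible bitwise from a single seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import StateSequence
from .exceptions import InvalidParameterError

__all__ = [
    "StateTemplate",
    "CohortConfig",
    "CohortGroundTruth",
    "Cohort",
    "generate_state_templates",
    "persistent_markov_matrix",
    "simulate_markov_chain",
    "generate_subject_timeseries",
    "generate_structural_connectome",
    "generate_cohort",
    "write_cohort",
    "NETWORK_NAMES",
    "DOMAIN_DEFICITS",
]

NETWORK_NAMES = ("VIS", "SMN", "DAN", "VAN", "LIM", "FPN", "DMN", "DGM")

# Planted deficits in HC-SD units; CI exceeds 2 SD on 3 domains, MCI on none
# (MCI sits between the 1.5 and 2 SD thresholds on 2 domains).
DOMAIN_DEFICITS = {
    "CI": {"processing_speed": -3.5, "verbal_memory": -3.5, "attention": -3.5},
    "MCI": {"processing_speed": -1.9, "attention": -1.9},
}


@dataclass
class StateTemplate:
    """Unit-norm regional activation pattern of one planted state."""

    state_id: int
    activation_pattern: np.ndarray
    name_hint: str = ""


def generate_state_templates(k: int, n_regions: int, seed=None) -> list[StateTemplate]:
    """k mutually orthonormal unit-norm activation patterns (seeded).

    Orthonormality (QR of a random Gaussian matrix) makes the pairwise
    cosine similarity exactly 0, comfortably below the 0.3 separation bound.
    """
    if k < 2:
        raise InvalidParameterError("k must be >= 2")
    if n_regions < k:
        raise InvalidParameterError("need n_regions >= k for separable templates")
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((n_regions, k)))
    q = q * np.sign(np.diag(r))          # sign-fix for determinism
    return [StateTemplate(state_id=i + 1, activation_pattern=q[:, i].copy(),
                          name_hint=f"state{i + 1}")
            for i in range(k)]


def persistent_markov_matrix(k: int, persistence: float) -> np.ndarray:
    """Row-stochastic matrix with ``persistence`` on the diagonal, uniform off."""
    if not 0 <= persistence <= 1:
        raise InvalidParameterError("persistence must lie in [0, 1]")
    if k < 2:
        raise InvalidParameterError("k must be >= 2")
    P = np.full((k, k), (1.0 - persistence) / (k - 1))
    np.fill_diagonal(P, persistence)
    return P


def _check_stochastic(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise InvalidParameterError("markov matrix must be square")
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-10):
        raise InvalidParameterError("markov matrix rows must be nonnegative and sum to 1")
    return P


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Left principal eigenvector of a row-stochastic matrix, normalised."""
    P = _check_stochastic(P)
    eigvals, eigvecs = np.linalg.eig(P.T)
    idx = int(np.argmin(np.abs(eigvals - 1.0)))
    pi = np.real(eigvecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_markov_chain(P: np.ndarray, n_frames: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Hidden chain (labels 1..k), initial state from the stationary law."""
    P = _check_stochastic(P)
    k = P.shape[0]
    cum = np.cumsum(P, axis=1)
    labels = np.empty(n_frames, dtype=int)
    state = int(np.searchsorted(np.cumsum(stationary_distribution(P)), rng.random()))
    labels[0] = state + 1
    u = rng.random(n_frames - 1)
    for t in range(1, n_frames):
        state = int(np.searchsorted(cum[state], u[t - 1]))
        labels[t] = state + 1
    return labels


def generate_subject_timeseries(templates, markov_matrix, n_frames: int,
                                noise_sd: float, seed=None,
                                amplitude_range=(0.8, 1.2),
                                random_sign: bool = True,
                                subject_id: str = "S000"):
    """Regional time series driven by a hidden Markov state chain.

    Frame t is ``amplitude(t) * template[s(t)] + N(0, noise_sd)`` with
    |amplitude| ~ Uniform(amplitude_range) per frame and a random sign that
    is constant within each state visit (a dwell is one activation episode;
    the sign re-randomises when the state changes).  Edge patterns — outer
    products — are therefore sign-stable per state while regional
    activation varies.  Returns ``(DataFrame frames x regions,
    StateSequence)`` with the hidden chain as ground truth.
    """
    if n_frames < 2:
        raise InvalidParameterError("need n_frames >= 2")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    P = _check_stochastic(markov_matrix)
    k = len(templates)
    if P.shape[0] != k:
        raise InvalidParameterError("markov matrix size must equal the state count")
    patterns = np.stack([np.asarray(t.activation_pattern, dtype=float)
                         for t in templates])
    n_regions = patterns.shape[1]
    rng = np.random.default_rng(seed)
    labels = simulate_markov_chain(P, n_frames, rng)
    amp = rng.uniform(*amplitude_range, size=n_frames)
    if random_sign:
        visit_signs = rng.choice([-1.0, 1.0], size=n_frames)
        signs = np.empty(n_frames)
        signs[0] = visit_signs[0]
        for t in range(1, n_frames):
            signs[t] = visit_signs[t] if labels[t] != labels[t - 1] else signs[t - 1]
        amp *= signs
    values = amp[:, None] * patterns[labels - 1]
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    columns = [f"R{i:03d}" for i in range(n_regions)]
    ts = pd.DataFrame(values, columns=columns)
    return ts, StateSequence(subject_id=subject_id, labels=labels, k=k)


def template_support_matrix(templates) -> np.ndarray:
    """Structural support for the planted coactivation patterns.

    Sum over states of the positive part of the template outer product
    (hollow diagonal): edges link regions that coactivate with the same
    sign, so the matrix carries controllable directions aligned with the
    activity patterns the states visit.
    """
    pats = np.stack([np.asarray(t.activation_pattern, dtype=float)
                     for t in templates])
    C = np.zeros((pats.shape[1], pats.shape[1]))
    for p in pats:
        O = np.outer(p, p)
        C += np.where(O > 0, O, 0.0)
    np.fill_diagonal(C, 0.0)
    return C


def generate_structural_connectome(n_regions: int, n_modules: int = 4,
                                   integrity: float = 1.0, seed=None,
                                   p_within: float = 0.8, p_between: float = 0.15,
                                   weight_sigma: float = 0.5,
                                   within_scale: float = 3.0,
                                   templates=None, coupling: float = 60.0,
                                   coupling_integrity: float = 1.0) -> np.ndarray:
    """Modular weighted connectome (stochastic block model, log-normal weights).

    Symmetric, hollow-diagonal, nonnegative and connected, with stronger
    within- than between-module weights.  All weights are multiplied by
    ``integrity`` in (0, 1] — the planted global "structural damage" dial.

    When ``templates`` is given, a structure-function coupling term
    ``coupling * coupling_integrity * template_support_matrix(templates)``
    is added before the global scaling.  ``coupling_integrity`` < 1 damages
    specifically the tracts supporting the functional coactivation
    patterns; because the system matrix is normalised by its own largest
    eigenvalue, a *uniform* weight loss barely changes control energy, and
    it is this selective decoupling that makes state transitions
    energetically costly in the damaged groups.
    """
    if n_modules < 1:
        raise InvalidParameterError("n_modules must be >= 1")
    if not 0 < integrity <= 1:
        raise InvalidParameterError("integrity must lie in (0, 1]")
    if not 0 < coupling_integrity <= 1:
        raise InvalidParameterError("coupling_integrity must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    modules = np.arange(n_regions) * n_modules // n_regions
    W = np.zeros((n_regions, n_regions))
    iu, ju = np.triu_indices(n_regions, k=1)
    same = modules[iu] == modules[ju]
    p_edge = np.where(same, p_within, p_between)
    present = rng.random(iu.size) < p_edge
    scale = np.where(same, within_scale, 1.0)
    weights = scale * rng.lognormal(mean=0.0, sigma=weight_sigma, size=iu.size)
    vals = np.where(present, weights, 0.0)
    W[iu, ju] = vals
    W[ju, iu] = vals
    # guarantee a single component: chain any disconnected pieces together
    from scipy.sparse.csgraph import connected_components
    n_comp, comp = connected_components(W > 0, directed=False)
    if n_comp > 1:
        med = np.median(vals[vals > 0]) if np.any(vals > 0) else 1.0
        reps = [int(np.flatnonzero(comp == c)[0]) for c in range(n_comp)]
        for a, b in zip(reps[:-1], reps[1:]):
            W[a, b] = W[b, a] = med
    if templates is not None and coupling > 0:
        W = W + coupling * coupling_integrity * template_support_matrix(templates)
    return W * integrity


@dataclass
class CohortConfig:
    """Study conditions of the default synthetic cohort.

    Defaults: 20 HC / 20 CP / 20 CI subjects; 4 states over 100 regions in
    8 networks; 200 analysed frames per scan; Markov persistence 0.75
    (HC/CP) vs 0.85 (CI: fewer transitions); global connectome integrity
    1.0 vs 0.7 and structure-function coupling integrity 1.0 vs 0.3
    (CI: selectively decoupled tracts, costlier transitions); CI cognitive
    deficits of 3.5 HC SDs on three domains.
    """

    group_sizes: dict = field(default_factory=lambda: {"HC": 20, "CP": 20, "CI": 20})
    k: int = 4
    n_regions: int = 100
    n_frames: int = 200
    n_networks: int = 8
    n_modules: int = 4
    noise_sd: float = 0.02
    amplitude_range: tuple = (0.8, 1.2)
    persistence_by_group: dict = field(default_factory=lambda: {
        "HC": 0.75, "CP": 0.75, "MCI": 0.80, "CI": 0.85})
    integrity_by_group: dict = field(default_factory=lambda: {
        "HC": 1.0, "CP": 1.0, "MCI": 0.85, "CI": 0.7})
    coupling: float = 60.0
    coupling_integrity_by_group: dict = field(default_factory=lambda: {
        "HC": 1.0, "CP": 1.0, "MCI": 0.6, "CI": 0.3})
    deficits_by_group: dict = field(default_factory=lambda: {
        g: dict(d) for g, d in DOMAIN_DEFICITS.items()})
    cognitive_noise_sd: float = 1.0
    age_mean: float = 48.0
    age_sd: float = 11.0
    age_shift_by_group: dict = field(default_factory=lambda: {"MCI": 2.0, "CI": 4.0})

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        if "amplitude_range" in raw:
            raw["amplitude_range"] = tuple(raw["amplitude_range"])
        return cls(**raw)

    def validate(self) -> "CohortConfig":
        if not self.group_sizes:
            raise InvalidParameterError("group_sizes must not be empty")
        for g, n in self.group_sizes.items():
            if g not in ("HC", "CP", "MCI", "CI"):
                raise InvalidParameterError(f"unknown group {g!r}")
            if n < 1:
                raise InvalidParameterError(f"group size for {g!r} must be >= 1")
        if "HC" not in self.group_sizes:
            raise InvalidParameterError("cohort needs an HC reference group")
        if self.k < 2 or self.n_regions < self.k:
            raise InvalidParameterError("need k >= 2 and n_regions >= k")
        return self


@dataclass
class CohortGroundTruth:
    """Everything planted: templates, chains, group effects."""

    templates: list
    markov_matrix_by_group: dict
    true_sequences: dict
    connectome_integrity_by_group: dict
    coupling_integrity_by_group: dict
    deficits_by_group: dict


@dataclass
class Cohort:
    subjects: pd.DataFrame          # subject_id-indexed metadata + raw domain scores
    timeseries: dict                # subject_id -> frames x regions DataFrame
    connectomes: dict               # subject_id -> n x n ndarray
    regions: pd.DataFrame           # region, network
    ground_truth: CohortGroundTruth

    @property
    def hc_ids(self) -> list:
        return list(self.subjects.index[self.subjects["group"] == "HC"])


from .cognition import DOMAINS as _DOMAINS  # noqa: E402  (7 canonical domains)

_COVARIATE_BETAS = {"age": -0.08, "sex": 0.4, "education": 0.6}


def _region_networks(n_regions: int, n_networks: int) -> list:
    names = NETWORK_NAMES[:n_networks]
    return [names[i * n_networks // n_regions] for i in range(n_regions)]


def generate_cohort(config: CohortConfig | None = None, seed=None) -> Cohort:
    """Full synthetic cohort: metadata, time series, connectomes, ground truth."""
    config = (config or CohortConfig()).validate()
    rng = np.random.default_rng(seed)
    templates = generate_state_templates(
        config.k, config.n_regions, seed=int(rng.integers(2**31 - 1)))
    markov = {g: persistent_markov_matrix(config.k, config.persistence_by_group[g])
              for g in config.group_sizes}

    rows, timeseries, connectomes, sequences = [], {}, {}, {}
    for group in config.group_sizes:            # insertion order: deterministic
        deficits = config.deficits_by_group.get(group, {})
        for i in range(config.group_sizes[group]):
            sid = f"{group}{i:03d}"
            age = float(rng.normal(config.age_mean, config.age_sd)
                        + config.age_shift_by_group.get(group, 0.0))
            age = float(np.clip(age, 20.0, 80.0))
            sex = int(rng.random() < 0.35)            # 1 = male
            education = int(rng.random() < 0.5)       # 1 = higher education
            ts, seq = generate_subject_timeseries(
                templates, markov[group], config.n_frames, config.noise_sd,
                seed=int(rng.integers(2**31 - 1)),
                amplitude_range=config.amplitude_range, subject_id=sid)
            W = generate_structural_connectome(
                config.n_regions, n_modules=config.n_modules,
                integrity=config.integrity_by_group[group],
                seed=int(rng.integers(2**31 - 1)),
                templates=templates, coupling=config.coupling,
                coupling_integrity=config.coupling_integrity_by_group[group])
            scores = {}
            for dom in _DOMAINS:
                base = (50.0
                        + _COVARIATE_BETAS["age"] * (age - config.age_mean)
                        + _COVARIATE_BETAS["sex"] * sex
                        + _COVARIATE_BETAS["education"] * education
                        + deficits.get(dom, 0.0) * config.cognitive_noise_sd)
                scores[dom] = float(base + rng.normal(0.0, config.cognitive_noise_sd))
            rows.append({"subject_id": sid, "group": group, "age": age,
                         "sex": sex, "education": education, **scores})
            timeseries[sid] = ts
            connectomes[sid] = W
            sequences[sid] = seq

    subjects = pd.DataFrame(rows).set_index("subject_id")
    regions = pd.DataFrame({
        "region": [f"R{i:03d}" for i in range(config.n_regions)],
        "network": _region_networks(config.n_regions, config.n_networks),
    })
    truth = CohortGroundTruth(
        templates=templates,
        markov_matrix_by_group=markov,
        true_sequences=sequences,
        connectome_integrity_by_group=dict(config.integrity_by_group),
        coupling_integrity_by_group=dict(config.coupling_integrity_by_group),
        deficits_by_group={g: dict(d) for g, d in config.deficits_by_group.items()},
    )
    return Cohort(subjects=subjects, timeseries=timeseries,
                  connectomes=connectomes, regions=regions, ground_truth=truth)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write a cohort as delimited text plus a ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.subjects.to_csv(outdir / "subjects.tsv", sep="\t")
    cohort.regions.to_csv(outdir / "regions.tsv", sep="\t", index=False)
    for sid, ts in cohort.timeseries.items():
        ts.to_csv(outdir / f"{sid}_timeseries.tsv", sep="\t", index=False)
        np.savetxt(outdir / f"{sid}_connectome.tsv",
                   cohort.connectomes[sid], delimiter="\t")
    truth = cohort.ground_truth
    payload = {
        "templates": [t.activation_pattern.tolist() for t in truth.templates],
        "markov_matrix_by_group": {g: P.tolist()
                                   for g, P in truth.markov_matrix_by_group.items()},
        "true_sequences": {s: seq.labels.tolist()
                           for s, seq in truth.true_sequences.items()},
        "k": len(truth.templates),
        "connectome_integrity_by_group": truth.connectome_integrity_by_group,
        "coupling_integrity_by_group": truth.coupling_integrity_by_group,
        "deficits_by_group": truth.deficits_by_group,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(payload, fh)
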