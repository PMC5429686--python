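"""Synthetic cohorts with the statistical structure the pipeline assumes.

Real inputs to this pipeline are a tumor mutation table, a scored
protein-protein interaction network, and a clinical table. The generator
emulates their load-bearing features:

* a modular undirected network (planted-partition topology) whose edge
  scores lie in (0.7, 1.0], so the high-confidence threshold keeps the whole
  graph unless a test overrides scores;
* an extremely sparse binary patient x gene mutation matrix — each planted
  subtype mutates driver genes concentrated in one network module at a high
  rate, all genes mutate at a low background rate, and a small hypermutator
  fraction has its background rate multiplied so per-patient burden spans
  orders of magnitude;
* clinical covariates (ordinal grade, nodal status, PSA-like marker,
  exponential survival with censoring) whose distributions may shift by
  planted subtype; survival is subtype-independent by default.

Everything is deterministic given the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .mutation_io import MutationMatrix
from .ppi import PPINetwork

__all__ = [
    "SyntheticSpec",
    "ClinicalEffectSpec",
    "SyntheticCohort",
    "generate_network",
    "generate_cohort",
    "generate_clinical",
    "generate",
    "write_maf",
    "write_edge_list",
    "write_clinical",
    "write_labels",
]

GRADES = np.arange(6, 11)  # Gleason-like ordinal scale


def _check_prob(name, p):
    if not (0.0 <= p <= 1.0):
        raise ConfigurationError(f"{name}={p} outside [0, 1]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-subtype generative model.

    Defaults describe the reference study conditions used throughout the
    tests: 300 patients in 3 balanced subtypes on a 1000-gene modular
    network, driver mutation probability 0.8 and background rate 0.002.
    """

    n_genes: int = 1000
    n_modules: int = 10
    module_sizes: tuple[int, ...] | None = None
    intra_edge_prob: float = 0.15
    inter_edge_prob: float = 0.002
    n_patients: int = 300
    subtype_proportions: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    drivers_per_subtype: int = 5
    driver_mut_prob: float = 0.8
    background_mut_prob: float = 0.002
    hypermutator_fraction: float = 0.08
    hypermutator_multiplier: float = 25.0
    seed: int = 0

    def __post_init__(self):
        if self.n_modules < 1:
            raise ConfigurationError("n_modules must be >= 1")
        sizes = self.sizes()
        if sum(sizes) != self.n_genes:
            raise ConfigurationError(
                f"module_sizes sum to {sum(sizes)}, expected n_genes={self.n_genes}")
        for name in ("intra_edge_prob", "inter_edge_prob", "driver_mut_prob",
                     "background_mut_prob", "hypermutator_fraction"):
            _check_prob(name, getattr(self, name))
        props = np.asarray(self.subtype_proportions, dtype=float)
        if abs(props.sum() - 1.0) > 1e-12 or (props < 0).any():
            raise ConfigurationError("subtype_proportions must be nonnegative and sum to 1")
        if len(props) > self.n_modules:
            raise ConfigurationError("need at least one module per subtype")
        if self.drivers_per_subtype > min(sizes[: len(props)]):
            raise ConfigurationError("drivers_per_subtype exceeds its module size")
        if self.hypermutator_multiplier <= 0:
            raise ConfigurationError("hypermutator_multiplier must be positive")

    def sizes(self) -> tuple[int, ...]:
        if self.module_sizes is not None:
            return tuple(self.module_sizes)
        base = self.n_genes // self.n_modules
        sizes = [base] * self.n_modules
        sizes[-1] += self.n_genes - base * self.n_modules
        return tuple(sizes)

    @property
    def n_subtypes(self) -> int:
        return len(self.subtype_proportions)


@dataclass(frozen=True)
class ClinicalEffectSpec:
    """Per-subtype clinical distributions.

    ``grade_probs`` rows are distributions over the ordinal grades 6..10;
    ``nodal_probs`` are per-subtype probabilities of positive nodal status;
    ``psa_log_means`` shift a log-normal PSA-like marker; survival is
    exponential with a shared scale unless ``survival_scales`` differ.
    """

    grade_probs: tuple[tuple[float, ...], ...] = (
        (0.05, 0.25, 0.35, 0.25, 0.10),
        (0.15, 0.40, 0.30, 0.10, 0.05),
        (0.30, 0.40, 0.20, 0.08, 0.02),
    )
    nodal_probs: tuple[float, ...] = (0.30, 0.20, 0.08)
    psa_log_means: tuple[float, ...] = (1.2, 1.6, 0.4)
    psa_log_sd: float = 0.8
    survival_scales: tuple[float, ...] = (2000.0, 2000.0, 2000.0)
    censor_prob: float = 0.9
    age_mean: float = 61.0
    age_sd: float = 7.0

    def for_n_subtypes(self, k: int) -> "ClinicalEffectSpec":
        """Recycle the distribution rows if labels use a different subtype count."""
        def cyc(t):
            return tuple(t[i % len(t)] for i in range(k))
        return replace(self, grade_probs=cyc(self.grade_probs), nodal_probs=cyc(self.nodal_probs),
                       psa_log_means=cyc(self.psa_log_means), survival_scales=cyc(self.survival_scales))

    @classmethod
    def null(cls, k: int = 3) -> "ClinicalEffectSpec":
        """Identical distributions across subtypes (no clinical association)."""
        return cls(
            grade_probs=((0.10, 0.35, 0.30, 0.18, 0.07),) * k,
            nodal_probs=(0.18,) * k,
            psa_log_means=(1.0,) * k,
            survival_scales=(2000.0,) * k,
        )


@dataclass
class SyntheticCohort:
    mutation_matrix: MutationMatrix
    true_labels: np.ndarray  # subtype index per patient, 0-based
    network: PPINetwork
    clinical: pd.DataFrame
    driver_genes: list[list[str]]  # per subtype

    def __post_init__(self):
        if len(self.true_labels) != self.mutation_matrix.n_patients:
            raise DataError("label count differs from patient count")
        node_set = set(self.network.nodes)
        for genes in self.driver_genes:
            missing = set(genes) - node_set
            if missing:
                raise DataError(f"driver genes absent from network: {sorted(missing)}")


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate_network(spec: SyntheticSpec) -> PPINetwork:
    """Planted-partition scored graph: dense within modules, sparse across."""
    rng = np.random.default_rng(spec.seed)
    sizes = spec.sizes()
    names = _gene_names(spec.n_genes)
    module = np.repeat(np.arange(spec.n_modules), sizes)
    prob = np.where(module[:, None] == module[None, :], spec.intra_edge_prob, spec.inter_edge_prob)
    draws = rng.random((spec.n_genes, spec.n_genes))
    iu, ju = np.triu_indices(spec.n_genes, k=1)
    hit = draws[iu, ju] < prob[iu, ju]
    ei, ej = iu[hit], ju[hit]
    # scores uniform on (0.7, 1.0] so the default confidence threshold keeps everything
    scores = 1.0 - rng.random(ei.size) * 0.3
    g = nx.Graph()
    g.add_nodes_from(names)
    g.add_edges_from(
        (names[a], names[b], {"score": s}) for a, b, s in zip(ei, ej, scores)
    )
    return PPINetwork(graph=g, score_threshold=0.7)


def _driver_genes(spec: SyntheticSpec, rng: np.random.Generator) -> list[np.ndarray]:
    sizes = spec.sizes()
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    drivers = []
    for s in range(spec.n_subtypes):
        lo, hi = offsets[s], offsets[s + 1]
        drivers.append(np.sort(rng.choice(np.arange(lo, hi), size=spec.drivers_per_subtype,
                                          replace=False)))
    return drivers


def generate_cohort(spec: SyntheticSpec, network: PPINetwork | None = None) -> SyntheticCohort:
    """Draw patients, planted labels, mutations, and clinical covariates.

    Each patient's subtype drivers mutate independently with
    ``driver_mut_prob``; every gene mutates with the background rate
    (multiplied for hypermutators). Patients with zero mutations are redrawn
    so every row has at least one 1 (the walk needs a seed).
    """
    if network is None:
        network = generate_network(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    names = _gene_names(spec.n_genes)
    labels = rng.choice(spec.n_subtypes, size=spec.n_patients, p=spec.subtype_proportions)
    hyper = rng.random(spec.n_patients) < spec.hypermutator_fraction
    drivers = _driver_genes(spec, rng)

    values = np.zeros((spec.n_patients, spec.n_genes), dtype=np.int8)
    for i in range(spec.n_patients):
        bg = min(1.0, spec.background_mut_prob * (spec.hypermutator_multiplier if hyper[i] else 1.0))
        while True:
            row = (rng.random(spec.n_genes) < bg).astype(np.int8)
            didx = drivers[labels[i]]
            row[didx] |= rng.random(didx.size) < spec.driver_mut_prob
            if row.any():
                break
        values[i] = row

    patients = [f"P{i:04d}" for i in range(spec.n_patients)]
    nonzero = values.any(axis=0)
    matrix = MutationMatrix(patients, [g for g, nz in zip(names, nonzero) if nz],
                            values[:, nonzero])
    clinical = generate_clinical(labels, ClinicalEffectSpec().for_n_subtypes(spec.n_subtypes),
                                 seed=spec.seed, patient_ids=patients)
    return SyntheticCohort(
        mutation_matrix=matrix,
        true_labels=labels,
        network=network,
        clinical=clinical,
        driver_genes=[[names[j] for j in d] for d in drivers],
    )


def generate_clinical(true_labels, effect_spec: ClinicalEffectSpec | None = None,
                      seed: int = 0, patient_ids=None) -> pd.DataFrame:
    """One clinical row per patient, distributions shifting by planted subtype."""
    labels = np.asarray(true_labels)
    k = int(labels.max()) + 1 if labels.size else 0
    eff = effect_spec or ClinicalEffectSpec()
    if np.any(labels < 0) or k > len(eff.grade_probs):
        raise DataError("unknown subtype index in labels for the given effect spec")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    n = labels.size
    if patient_ids is None:
        patient_ids = [f"P{i:04d}" for i in range(n)]

    grade = np.empty(n, dtype=int)
    nodal = np.empty(n, dtype=bool)
    psa = np.empty(n)
    followup = np.empty(n)
    event = np.empty(n, dtype=int)
    for s in range(k):
        m = labels == s
        cnt = int(m.sum())
        if cnt == 0:
            continue
        probs = np.asarray(eff.grade_probs[s], dtype=float)
        probs = probs / probs.sum()
        grade[m] = rng.choice(GRADES, size=cnt, p=probs)
        nodal[m] = rng.random(cnt) < eff.nodal_probs[s]
        psa[m] = np.exp(rng.normal(eff.psa_log_means[s], eff.psa_log_sd, size=cnt))
        t = rng.exponential(eff.survival_scales[s], size=cnt)
        censored = rng.random(cnt) < eff.censor_prob
        followup[m] = np.where(censored, rng.random(cnt) * t, t)
        event[m] = (~censored).astype(int)

    node_count = np.where(nodal, rng.poisson(2.0, size=n) + 1, 0)
    return pd.DataFrame({
        "patient_id": patient_ids,
        "age": np.round(rng.normal(eff.age_mean, eff.age_sd, size=n)).astype(int),
        "followup_days": followup,
        "event": event,
        "gleason": grade,
        "path_n": np.where(nodal, "N1", "N0"),
        "lymph_status": np.where(nodal, "positive", "negative"),
        "positive_node_count": node_count,
        "psa": psa,
    })


def generate(spec: SyntheticSpec) -> SyntheticCohort:
    """Network + cohort in one call (the usual entry point)."""
    return generate_cohort(spec, generate_network(spec))


# ---------------------------------------------------------------- writers

def write_maf(matrix: MutationMatrix, path, variant_class: str = "Missense_Mutation") -> None:
    rows = []
    for i, p in enumerate(matrix.patients):
        for j, g in enumerate(matrix.genes):
            if matrix.values[i, j]:
                rows.append((g, p, variant_class))
    pd.DataFrame(rows, columns=["Hugo_Symbol", "Tumor_Sample_Barcode",
                                "Variant_Classification"]).to_csv(path, sep="\t", index=False)


def write_edge_list(network: PPINetwork, path) -> None:
    # full float repr so scores survive a write/read round trip exactly
    rows = [(a, b, repr(float(d["score"]))) for a, b, d in network.graph.edges(data=True)]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "combined_score"]).to_csv(
        path, sep="\t", index=False)


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def write_labels(patients, labels, path) -> None:
    pd.DataFrame({"patient_id": patients, "subtype": np.asarray(labels) + 1}).to_csv(
        path, sep="\t", index=False)
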