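"""End-to-end orchestration: mutations + network -> subtypes -> report.

Stage order: input loading -> network threshold -> restriction of the
mutation matrix to network genes -> random-walk smoothing -> variability
filter -> consensus GNMF over the candidate k range -> cophenetic selection
of k -> silhouette core samples -> elastic-net classification of the core
-> clinical association battery. A master seed fans out deterministically
to every randomized stage, so identical configurations give identical
outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classifier import ElasticNetConfig, SubtypeModel, extract_biomarkers, jackknife_tune
from .clinical import association_battery
from .consensus import ConsensusResult, consensus_cluster, select_k, silhouette_widths
from .errors import ConfigurationError
from .features import FeatureSelectionConfig, prepare_gnmf_input, rank_by_variability
from .gnmf import GNMFConfig, build_affinity
from .mutation_io import build_binary_matrix, read_maf
from .ppi import intersect_with_network, read_string_edges
from .propagation import PropagationConfig, smooth_cohort
from . import synthetic

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    # either the three input paths or a synthetic spec
    maf_path: str | None = None
    edges_path: str | None = None
    clinical_path: str | None = None
    synthetic_spec: synthetic.SyntheticSpec | None = None

    score_threshold: float = 0.7
    propagation: PropagationConfig = field(default_factory=PropagationConfig)
    features: FeatureSelectionConfig = field(default_factory=FeatureSelectionConfig)
    gnmf: GNMFConfig = field(default_factory=GNMFConfig)
    k_range: tuple[int, ...] = tuple(range(2, 10))
    n_runs: int = 100
    silhouette_threshold: float = 0.20
    classifier: ElasticNetConfig = field(default_factory=ElasticNetConfig)
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        real = self.maf_path is not None and self.edges_path is not None
        if not real and self.synthetic_spec is None:
            raise ConfigurationError("provide input paths or a synthetic spec")
        if any(k < 2 for k in self.k_range):
            raise ConfigurationError("k_range values must be >= 2")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        kwargs = {}
        if "synthetic" in raw:
            kwargs["synthetic_spec"] = synthetic.SyntheticSpec(**raw.pop("synthetic"))
        for key, ctor in (("propagation", PropagationConfig), ("features", FeatureSelectionConfig),
                          ("gnmf", GNMFConfig), ("classifier", ElasticNetConfig)):
            if key in raw:
                kwargs[key] = ctor(**{k: tuple(v) if isinstance(v, list) else v
                                      for k, v in raw.pop(key).items()})
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        kwargs.update(raw)
        return cls(**kwargs)


@dataclass
class PipelineResult:
    mutation_matrix: object
    network: object
    smoothed: object
    selected_genes: pd.Series
    per_k: dict[int, ConsensusResult]
    k_star: int
    cophenetic_table: dict[int, float]
    labels: np.ndarray
    silhouette: object
    core_model: SubtypeModel | None
    biomarkers: dict | None
    battery: dict | None
    manifest: dict


def _stage_seed(master: int, stage: int) -> int:
    return int(np.random.SeedSequence([master, stage]).generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    stages = []

    # 1-2: inputs
    clinical = None
    true_labels = None
    if config.synthetic_spec is not None:
        cohort = synthetic.generate(config.synthetic_spec)
        matrix, network, clinical = cohort.mutation_matrix, cohort.network, cohort.clinical
        true_labels = cohort.true_labels
    else:
        matrix = build_binary_matrix(read_maf(config.maf_path))
        network = read_string_edges(config.edges_path, score_threshold=config.score_threshold)
        if config.clinical_path:
            clinical = pd.read_csv(config.clinical_path, sep="\t")
    stages.append({"stage": "io", "patients": matrix.n_patients, "genes": matrix.n_genes})
    stages.append({"stage": "network", **network.summary()})

    # 3: restriction + smoothing
    restricted, drop_report = intersect_with_network(matrix, network)
    stages.append({"stage": "restrict", "dropped_genes": drop_report["n_dropped_genes"]})
    smoothed = smooth_cohort(restricted, network, config.propagation)
    stages.append({"stage": "propagation", "patients": len(smoothed.patients),
                   "dropped_patients": len(smoothed.dropped_patients or [])})

    # 4: variability filter
    fs = config.features
    if fs.top_n > len(smoothed.genes):
        fs = FeatureSelectionConfig(top_n=len(smoothed.genes), variability=fs.variability,
                                    center=fs.center, nonneg_fix=fs.nonneg_fix)
    selected = rank_by_variability(smoothed, fs)
    A, transform = prepare_gnmf_input(smoothed, selected.index, fs)
    stages.append({"stage": "selection", "top_n": fs.top_n, **transform})

    # 5-7: consensus over k, cophenetic selection
    graph = build_affinity(A, config.gnmf.knn_p)
    stages.append({"stage": "affinity", "knn_p": config.gnmf.knn_p})
    per_k = consensus_cluster(A, graph, k_range=config.k_range, n_runs=config.n_runs,
                              base_seed=_stage_seed(config.seed, 6), config=config.gnmf)
    k_star, table = select_k(per_k)
    stages.append({"stage": "consensus", "k_star": k_star,
                   "cophenetic": {int(k): float(v) for k, v in table.items()}})
    labels = per_k[k_star].labels

    # 8: silhouette core
    sil = silhouette_widths(per_k[k_star].consensus, labels, config.silhouette_threshold)
    stages.append({"stage": "silhouette", "core": int(sil.core_mask.sum())})

    # 9: classifier on the core samples
    core = sil.core_mask
    core_model = biomarkers = None
    core_labels = labels[core]
    if np.unique(core_labels).size >= 2 and core.sum() >= 10:
        X = smoothed.to_frame()[selected.index].to_numpy()[core]
        core_model = jackknife_tune(X, core_labels, config.classifier,
                                    feature_names=list(selected.index))
        biomarkers = extract_biomarkers(core_model)
        stages.append({"stage": "classifier",
                       "jackknife_accuracy": core_model.jackknife_accuracy,
                       "alpha": core_model.chosen_alpha, "lambda": core_model.chosen_lambda})
    else:
        stages.append({"stage": "classifier", "skipped": "degenerate core labeling"})

    # 10: clinical battery (patients retained by propagation, all computed k's)
    battery = None
    if clinical is not None:
        cl = clinical.set_index("patient_id").loc[smoothed.patients].reset_index()
        battery = {k: association_battery(per_k[k].labels, cl) for k in per_k}
        stages.append({"stage": "clinical",
                       "p_values": {int(k): {v: float(t.p_value) for v, t in b.items()}
                                    for k, b in battery.items()}})
    else:
        stages.append({"stage": "clinical", "skipped": "no clinical table"})

    manifest = {"seed": config.seed, "stages": stages}
    if true_labels is not None:
        manifest["true_labels_available"] = True
    result = PipelineResult(
        mutation_matrix=matrix, network=network, smoothed=smoothed, selected_genes=selected,
        per_k=per_k, k_star=k_star, cophenetic_table=table, labels=labels, silhouette=sil,
        core_model=core_model, biomarkers=biomarkers, battery=battery, manifest=manifest)
    if config.out_dir:
        _write_outputs(result, smoothed, config)
    return result


def _write_outputs(result: PipelineResult, smoothed, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
    pd.DataFrame({"k": list(result.cophenetic_table),
                  "cophenetic": list(result.cophenetic_table.values())}).to_csv(
        out / "cophenetic.tsv", sep="\t", index=False)
    for k, res in result.per_k.items():
        synthetic.write_labels(smoothed.patients, res.labels - 1, out / f"labels_k{k}.tsv")
    pd.DataFrame({"patient_id": smoothed.patients, "silhouette": result.silhouette.widths,
                  "core": result.silhouette.core_mask}).to_csv(
        out / "silhouette.tsv", sep="\t", index=False)
    if result.biomarkers is not None:
        with open(out / "biomarkers.json", "w") as fh:
            json.dump({str(k): v for k, v in result.biomarkers["per_subtype"].items()}
                      | {"union_size": result.biomarkers["union_size"]},
                      fh, indent=2, default=str)
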