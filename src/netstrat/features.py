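"""Variability-based gene filtering and GNMF input preparation.

After smoothing, genes are ranked by their variability across patients and
the top N (default 500) kept. The retained sub-matrix is median-centered per
gene and then shifted back into the nonnegative orthant, since the
factorization requires A >= 0: the default global shift adds |min| of the
whole matrix (rank- and distance-preserving), clamping at zero is available
as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .propagation import SmoothedMatrix

__all__ = ["FeatureSelectionConfig", "rank_by_variability", "prepare_gnmf_input"]


@dataclass(frozen=True)
class FeatureSelectionConfig:
    top_n: int = 500
    variability: str = "variance"  # or "coefficient_of_variation"
    center: str = "median"  # or "none"
    nonneg_fix: str = "global_shift"  # or "clamp_zero", "none"
    scale: str = "unit_rms"  # or "none"

    def __post_init__(self):
        if self.top_n < 2:
            raise ConfigurationError("top_n must be >= 2")
        if self.variability not in ("variance", "coefficient_of_variation"):
            raise ConfigurationError(f"unknown variability '{self.variability}'")
        if self.center not in ("median", "none"):
            raise ConfigurationError(f"unknown center '{self.center}'")
        if self.nonneg_fix not in ("global_shift", "clamp_zero", "none"):
            raise ConfigurationError(f"unknown nonneg_fix '{self.nonneg_fix}'")
        if self.scale not in ("unit_rms", "none"):
            raise ConfigurationError(f"unknown scale '{self.scale}'")


def rank_by_variability(smoothed: SmoothedMatrix,
                        config: FeatureSelectionConfig = FeatureSelectionConfig()) -> pd.Series:
    """Top-N genes by descending variability across patients.

    Sample variance uses the n-1 denominator. Coefficient of variation is
    sd/mean; genes with zero mean have an undefined CV and rank last. Ties
    break by gene symbol ascending. Returns a Series (gene -> score) of
    length ``top_n`` in rank order.
    """
    if config.top_n > len(smoothed.genes):
        raise ConfigurationError(
            f"top_n={config.top_n} exceeds gene count {len(smoothed.genes)}")
    if len(smoothed.patients) < 2:
        raise ConfigurationError("need at least two patients to measure variability")
    X = smoothed.values
    var = X.var(axis=0, ddof=1)
    if config.variability == "variance":
        score = var
    else:
        mean = X.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.sqrt(var) / mean
        score[mean == 0] = -np.inf  # undefined CV ranks last
    # stable sort on a symbol-sorted index breaks score ties by gene ascending
    s = pd.Series(score, index=smoothed.genes, name=config.variability).sort_index()
    s = s.sort_values(ascending=False, kind="mergesort")
    return s.iloc[: config.top_n]


def prepare_gnmf_input(smoothed: SmoothedMatrix, selected_genes,
                       config: FeatureSelectionConfig = FeatureSelectionConfig()):
    """Restrict to the selected genes, center, and re-establish nonnegativity.

    Returns ``(A, manifest)`` where A is genes x patients (the factorization
    orientation) and the manifest records the applied transform. By default
    the final matrix is rescaled to unit root-mean-square entry: the
    graph-regularization penalty in the factorization competes with the data
    misfit term, so the effective regularization strength for a fixed lambda
    depends on the overall matrix scale; pinning the scale makes the same
    lambda behave comparably across cohorts.
    """
    selected = list(selected_genes)
    missing = set(selected) - set(smoothed.genes)
    if missing:
        raise ConfigurationError(f"selected genes absent from smoothed matrix: {sorted(missing)[:5]}")
    frame = smoothed.to_frame()[selected]  # patients x genes
    A = frame.to_numpy().T.astype(float)  # genes x patients
    manifest = {"center": config.center, "nonneg_fix": config.nonneg_fix, "shift": 0.0}
    if config.center == "median":
        A = A - np.median(A, axis=1, keepdims=True)
    if config.nonneg_fix == "global_shift":
        mn = A.min()
        if mn < 0:
            A = A - mn
            manifest["shift"] = float(-mn)
    elif config.nonneg_fix == "clamp_zero":
        A = np.maximum(A, 0.0)
    if config.scale == "unit_rms":
        rms = float(np.sqrt(np.mean(A ** 2)))
        if rms > 0:
            A = A / rms
        manifest["rms"] = rms
    return A, manifest
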