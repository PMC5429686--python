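"""Somatic mutation tables and the binary patient x gene incidence matrix.

A gene is coded 1 for a patient if that patient carries at least one somatic
mutation in it, else 0 — variant multiplicity and class are deliberately
collapsed. Burden summaries assume a simplified exome of 20000 genes x 1500
coding nucleotides (30 Mb) so that per-patient mutation counts convert to
mutations per megabase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

__all__ = [
    "MutationRecord",
    "MutationMatrix",
    "ExomeModel",
    "read_maf",
    "build_binary_matrix",
    "mutation_rate_per_mb",
    "gene_mutation_fraction",
    "cohort_summary",
    "round_half_up",
]


@dataclass(frozen=True)
class MutationRecord:
    sample_id: str
    gene_symbol: str
    variant_class: str | None = None

    def __post_init__(self):
        if not self.sample_id or not self.gene_symbol:
            raise DataError("sample_id and gene_symbol must be non-empty")


@dataclass
class MutationMatrix:
    """Binary incidence of somatic mutation, patients x genes."""

    patients: list[str]
    genes: list[str]
    values: np.ndarray  # shape (n_patients, n_genes), entries in {0, 1}

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.patients), len(self.genes)):
            raise DataError("matrix shape inconsistent with patient/gene lists")
        if len(set(self.patients)) != len(self.patients):
            raise DataError("duplicate patient ids")
        if len(set(self.genes)) != len(self.genes):
            raise DataError("duplicate gene symbols")
        uniq = np.unique(self.values)
        if not np.isin(uniq, [0, 1]).all():
            raise DataError("matrix entries must be 0/1")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patients, columns=self.genes)

    def restrict_genes(self, genes) -> "MutationMatrix":
        idx = {g: j for j, g in enumerate(self.genes)}
        cols = [idx[g] for g in genes]
        return MutationMatrix(list(self.patients), list(genes), self.values[:, cols].copy())

    def patient_burden(self) -> np.ndarray:
        """Number of mutated genes per patient."""
        return self.values.sum(axis=1)


@dataclass(frozen=True)
class ExomeModel:
    """Simplified exome used to convert mutation counts to per-Mb rates."""

    n_genes_assumed: int = 20000
    coding_length_nt: int = 1500

    def __post_init__(self):
        if self.n_genes_assumed <= 0 or self.coding_length_nt <= 0:
            raise DataError("exome dimensions must be positive")

    @property
    def megabases(self) -> float:
        return self.n_genes_assumed * self.coding_length_nt / 1e6


def read_maf(path, gene_col: str = "Hugo_Symbol", sample_col: str = "Tumor_Sample_Barcode",
             class_col: str = "Variant_Classification") -> list[MutationRecord]:
    """Read a MAF-like TSV into mutation records, preserving line order.

    Lines starting with ``#`` are skipped. Raises :class:`FormatError` if the
    file is empty or a required column is missing.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty MAF file: {path}")
    for col in (gene_col, sample_col):
        if col not in df.columns:
            raise FormatError(f"required column '{col}' missing from {path}")
    has_class = class_col in df.columns
    return [
        MutationRecord(
            sample_id=row[sample_col],
            gene_symbol=row[gene_col],
            variant_class=row[class_col] if has_class else None,
        )
        for row in df.to_dict("records")
    ]


def build_binary_matrix(records, exclude_classes=()) -> MutationMatrix:
    """Collapse records to the binary patient x gene matrix.

    Patients sort by barcode, genes by symbol; multiplicity collapses to a
    single 1. ``exclude_classes`` optionally drops records whose
    variant class is listed (no class is excluded by default).
    """
    if not records:
        raise DataError("no mutation records")
    excl = set(exclude_classes)
    pairs = {
        (r.sample_id, r.gene_symbol)
        for r in records
        if not (excl and r.variant_class in excl)
    }
    if not pairs:
        raise DataError("all records excluded by variant-class filter")
    patients = sorted({p for p, _ in pairs})
    genes = sorted({g for _, g in pairs})
    pi = {p: i for i, p in enumerate(patients)}
    gi = {g: j for j, g in enumerate(genes)}
    values = np.zeros((len(patients), len(genes)), dtype=np.int8)
    for p, g in pairs:
        values[pi[p], gi[g]] = 1
    return MutationMatrix(patients, genes, values)


def mutation_rate_per_mb(matrix: MutationMatrix, exome: ExomeModel = ExomeModel()) -> pd.Series:
    """Per-patient mutated-gene count divided by the simplified exome size in Mb."""
    return pd.Series(matrix.patient_burden() / exome.megabases, index=matrix.patients,
                     name="mutations_per_mb")


def gene_mutation_fraction(matrix: MutationMatrix, threshold: float = 0.05):
    """Fraction of patients mutated per gene, plus the genes above ``threshold``.

    Returns ``(fractions, recurrent)`` where fractions is a Series over genes
    and recurrent the sub-Series with fraction strictly greater than threshold.
    """
    if matrix.n_patients < 1:
        raise DataError("need at least one patient")
    frac = pd.Series(matrix.values.sum(axis=0) / matrix.n_patients,
                     index=matrix.genes, name="fraction_mutated")
    return frac, frac[frac > threshold]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the printed-table convention)."""
    factor = 10 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def cohort_summary(clinical: pd.DataFrame,
                   categorical=("gleason", "path_n", "path_t", "clin_t", "lymph_status", "psa_level"),
                   continuous=("age", "followup_days")) -> dict:
    """Per-category counts and percentages plus median/range for continuous variables.

    Missing values are their own ``NA`` category so that percentages over all
    rows of a variable sum to 100 up to rounding. Percentages are rounded
    half-up to two decimals.
    """
    n = len(clinical)
    out: dict = {"n_patients": n}
    for var in categorical:
        if var not in clinical.columns:
            continue
        col = clinical[var].astype("object").where(clinical[var].notna(), "NA")
        counts = col.value_counts(dropna=False)
        out[var] = {
            str(cat): {"count": int(c), "percent": round_half_up(100.0 * c / n)}
            for cat, c in counts.items()
        }
    for var in continuous:
        if var not in clinical.columns:
            continue
        vals = pd.to_numeric(clinical[var], errors="coerce").dropna()
        out[var] = {
            "median": float(vals.median()),
            "range": (float(vals.min()), float(vals.max())),
        }
    return out
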