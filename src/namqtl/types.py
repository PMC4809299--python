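"""Core domain types shared across the pipeline.

Conventions:

* Marker dosage codes the number of donor ("wild") alleles: 2 = homozygous
  donor, 1 = heterozygous, 0 = homozygous recurrent.  Missing values are NaN.
* Map positions are centimorgans on a per-chromosome scale starting at 0.
* Phenotype records are long-format pandas DataFrames with columns
  ``line_id, year, rep, trait, value`` (see :func:`validate_phenotypes`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHENOTYPE_COLUMNS = ("line_id", "year", "rep", "trait", "value")


class ConfigurationError(ValueError):
    """Raised when a simulation or analysis is configured inconsistently."""


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker positions in cM, grouped by chromosome.

    Markers must be sorted by (chromosome, position); positions are
    non-decreasing within a chromosome and marker ids are unique.
    """

    marker_ids: tuple
    chromosomes: tuple
    positions_cm: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions_cm, dtype=float)
        object.__setattr__(self, "positions_cm", pos)
        object.__setattr__(self, "marker_ids", tuple(self.marker_ids))
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        n = len(self.marker_ids)
        if not (len(self.chromosomes) == n == pos.size):
            raise ConfigurationError("map fields have inconsistent lengths")
        if n == 0:
            raise ConfigurationError("map must contain at least one marker")
        if len(set(self.marker_ids)) != n:
            raise ConfigurationError("marker ids must be unique")
        if np.any(pos < 0) or not np.all(np.isfinite(pos)):
            raise ConfigurationError("map positions must be finite and >= 0")
        for chrom in set(self.chromosomes):
            p = pos[np.array([c == chrom for c in self.chromosomes])]
            if np.any(np.diff(p) < 0):
                raise ConfigurationError(
                    f"positions not sorted within chromosome {chrom!r}"
                )

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def chromosome_names(self) -> tuple:
        seen = dict.fromkeys(self.chromosomes)
        return tuple(seen)

    def chromosome_slices(self) -> dict:
        """Contiguous index slice per chromosome (markers are map-sorted)."""
        out = {}
        chroms = np.asarray(self.chromosomes, dtype=object)
        for chrom in self.chromosome_names:
            idx = np.flatnonzero(chroms == chrom)
            out[chrom] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def marker_index(self, marker_id) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"unknown marker {marker_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": list(self.marker_ids),
                "chromosome": list(self.chromosomes),
                "cM": self.positions_cm,
            }
        )


@dataclass
class GenotypeMatrix:
    """Lines x markers donor-allele dosages with a family label per line."""

    line_ids: np.ndarray
    families: np.ndarray
    marker_ids: tuple
    dosage: np.ndarray  # float array, NaN = missing

    def __post_init__(self):
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.families = np.asarray(self.families, dtype=object)
        self.marker_ids = tuple(self.marker_ids)
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if self.line_ids.size != n or self.families.size != n:
            raise ConfigurationError("line/family labels do not match dosage rows")
        if len(self.marker_ids) != m:
            raise ConfigurationError("marker ids do not match dosage columns")
        if len(set(self.line_ids)) != n:
            raise ConfigurationError("line ids must be unique")
        observed = self.dosage[~np.isnan(self.dosage)]
        if not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ConfigurationError("dosage values must be 0, 1, 2 or missing")

    @property
    def n_lines(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    @property
    def family_names(self) -> tuple:
        return tuple(dict.fromkeys(self.families))

    def subset_lines(self, indices) -> "GenotypeMatrix":
        indices = np.asarray(indices)
        return GenotypeMatrix(
            line_ids=self.line_ids[indices],
            families=self.families[indices],
            marker_ids=self.marker_ids,
            dosage=self.dosage[indices],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosage, columns=list(self.marker_ids))
        df.insert(0, "family", self.families)
        df.insert(0, "line_id", self.line_ids)
        return df


@dataclass(frozen=True)
class QTLModel:
    """Truth object for simulated traits: additive marker effects.

    ``effects`` are per-dosage coefficients; the homozygous difference
    (donor homozygote minus recurrent homozygote) is ``2 * effect``.
    ``family_masks[i]`` restricts QTL i to a subset of families
    (None = functional in all families).
    """

    marker_indices: tuple
    effects: tuple
    family_masks: tuple = ()
    intercept: float = 0.0

    def __post_init__(self):
        idx = tuple(int(i) for i in self.marker_indices)
        eff = tuple(float(e) for e in self.effects)
        masks = tuple(self.family_masks) if self.family_masks else tuple(
            None for _ in idx
        )
        if len(eff) != len(idx) or len(masks) != len(idx):
            raise ConfigurationError("QTL model fields have inconsistent lengths")
        object.__setattr__(self, "marker_indices", idx)
        object.__setattr__(self, "effects", eff)
        object.__setattr__(
            self,
            "family_masks",
            tuple(frozenset(m) if m is not None else None for m in masks),
        )

    @property
    def n_qtl(self) -> int:
        return len(self.marker_indices)


@dataclass(frozen=True)
class VarianceSpec:
    """Variance decomposition of a simulated trait and its trial design."""

    v_g: float
    v_gy: float
    v_r: float
    years: int = 1
    reps: int = 1

    def __post_init__(self):
        for name in ("v_g", "v_gy", "v_r"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.years < 1 or self.reps < 1:
            raise ConfigurationError("years and reps must be >= 1")


def validate_phenotypes(records: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format phenotype table and return it with sorted columns.

    Raises on missing columns, duplicate (line, year, rep, trait) keys or
    non-finite values.
    """
    missing = [c for c in PHENOTYPE_COLUMNS if c not in records.columns]
    if missing:
        raise ConfigurationError(f"phenotype table missing columns: {missing}")
    records = records.loc[:, list(PHENOTYPE_COLUMNS)]
    key = ["line_id", "year", "rep", "trait"]
    if records.duplicated(subset=key).any():
        dup = records[records.duplicated(subset=key, keep=False)].iloc[0]
        raise ConfigurationError(
            "duplicate phenotype record for "
            f"(line={dup['line_id']!r}, year={dup['year']!r}, "
            f"rep={dup['rep']!r}, trait={dup['trait']!r})"
        )
    values = records["value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ConfigurationError("phenotype values must be finite")
    return records
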