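"""Validated sample-by-taxon and sample-by-phenotype tables.

Abundance tables hold either raw read counts or relative abundances
(rows on the simplex); phenotype tables are stored z-scored per column
with an explicit missingness mask so that downstream losses can skip
unobserved entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "PhenotypeMatrix",
    "read_abundance_table",
    "read_phenotype_table",
    "aggregate_rare_taxa",
]

_ROW_SUM_TOL = 1e-8


@dataclass
class AbundanceTable:
    """S x O table of microbial abundances (samples as rows).

    Parameters
    ----------
    sample_ids, taxon_ids : labels for rows and columns.
    values : nonnegative matrix; relative abundances (rows summing to 1)
        when ``is_relative`` is true, raw counts otherwise.
    depths : per-sample read depths retained when counts were normalized.
    """

    sample_ids: list
    taxon_ids: list
    values: np.ndarray
    is_relative: bool = True
    depths: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = list(self.sample_ids)
        self.taxon_ids = list(self.taxon_ids)
        S, O = self.values.shape
        if S < 1 or O < 2:
            raise ValueError(f"need at least 1 sample and 2 taxa, got shape {(S, O)}")
        if len(self.sample_ids) != S or len(self.taxon_ids) != O:
            raise ValueError("label lengths do not match value matrix shape")
        if len(set(self.taxon_ids)) != O:
            raise ValueError("taxon_ids are not unique")
        if len(set(self.sample_ids)) != S:
            raise ValueError("sample_ids are not unique")
        if np.any(self.values < 0):
            raise ValueError("abundance values must be nonnegative")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("abundance values must be finite")
        if self.is_relative:
            sums = self.values.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > _ROW_SUM_TOL):
                bad = int(np.argmax(np.abs(sums - 1.0)))
                raise ValueError(
                    f"relative table rows must sum to 1; row {self.sample_ids[bad]} "
                    f"sums to {sums[bad]:.6g}"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def to_relative(self) -> "AbundanceTable":
        """Row-normalize counts; a relative table is returned unchanged."""
        if self.is_relative:
            return self
        depths = self.values.sum(axis=1)
        if np.any(depths <= 0):
            raise ValueError("cannot normalize a sample with zero total count")
        return AbundanceTable(
            self.sample_ids,
            self.taxon_ids,
            self.values / depths[:, None],
            is_relative=True,
            depths=depths,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)

    def write(self, path, sep: str = "\t") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index_label="sample_id")

    def reorder_taxa(self, taxon_ids) -> "AbundanceTable":
        """Return a copy with columns reordered to match ``taxon_ids``."""
        missing = [t for t in taxon_ids if t not in self.taxon_ids]
        extra = [t for t in self.taxon_ids if t not in list(taxon_ids)]
        if missing or extra:
            raise ValueError(
                f"taxa mismatch: missing from table {missing}; unexpected {extra}"
            )
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return AbundanceTable(
            self.sample_ids,
            list(taxon_ids),
            self.values[:, idx],
            is_relative=self.is_relative,
            depths=self.depths,
        )


@dataclass
class PhenotypeMatrix:
    """S x P host phenotype table, stored z-scored with a missingness mask.

    ``values`` holds z-scores with missing entries set to 0 (masked out of
    every loss); ``mean`` and ``sd`` allow mapping predictions back to the
    original units.
    """

    sample_ids: list
    phenotype_ids: list
    values: np.ndarray
    mask: np.ndarray
    mean: np.ndarray = field(default=None)
    sd: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        S, P = self.values.shape
        if len(self.sample_ids) != S or len(self.phenotype_ids) != P:
            raise ValueError("label lengths do not match value matrix shape")
        if self.mean is None:
            self.mean = np.zeros(P)
        if self.sd is None:
            self.sd = np.ones(P)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)

    @classmethod
    def from_raw(cls, df: pd.DataFrame) -> "PhenotypeMatrix":
        """Z-score a raw phenotype table, masking NaN cells.

        Columns with no observed entries are kept (fully masked) with a
        warning; zero-variance columns get sd 1 so z-scores stay finite.
        """
        raw = df.to_numpy(dtype=float)
        mask = np.isfinite(raw)
        mean = np.zeros(raw.shape[1])
        sd = np.ones(raw.shape[1])
        z = np.zeros_like(raw)
        for j in range(raw.shape[1]):
            obs = raw[mask[:, j], j]
            if obs.size == 0:
                warnings.warn(
                    f"phenotype {df.columns[j]!r} has no observed values", stacklevel=2
                )
                continue
            mean[j] = obs.mean()
            s = obs.std(ddof=0)
            if s == 0:
                warnings.warn(
                    f"phenotype {df.columns[j]!r} is constant; sd set to 1", stacklevel=2
                )
                s = 1.0
            sd[j] = s
            z[mask[:, j], j] = (obs - mean[j]) / s
        return cls(list(df.index), list(df.columns), z, mask, mean, sd)

    def to_original_units(self, z: np.ndarray | None = None) -> np.ndarray:
        if z is None:
            z = self.values
        return z * self.sd + self.mean

    def to_dataframe(self) -> pd.DataFrame:
        raw = self.to_original_units()
        raw = np.where(self.mask, raw, np.nan)
        return pd.DataFrame(raw, index=self.sample_ids, columns=self.phenotype_ids)

    def write(self, path, sep: str = "\t") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index_label="sample_id")


def _read_frame(path, sep):
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ID(s): {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate column ID(s): {dup}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            if len(bad):
                # +2: header row plus 1-based numbering
                line = df.index.get_loc(bad.index[0]) + 2
                raise ValueError(
                    f"non-numeric cell {bad.iloc[0]!r} in column {col!r} (line {line})"
                )
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def read_abundance_table(path, sep: str = "\t", transpose: bool = False) -> AbundanceTable:
    """Read a delimited abundance table (samples as rows, taxa as columns).

    Counts are auto-detected (integer-valued rows summing above 1) and
    normalized, with the raw depths retained on the returned table.
    """
    df = _read_frame(path, sep)
    if transpose:
        df = df.T
    vals = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("abundance tables may not contain missing values")
    integral = np.allclose(vals, np.round(vals))
    looks_like_counts = integral and np.all(vals.sum(axis=1) > 1 + _ROW_SUM_TOL)
    table = AbundanceTable(
        list(df.index), list(df.columns), vals, is_relative=not looks_like_counts
    )
    return table.to_relative() if looks_like_counts else table


def read_phenotype_table(path, sep: str = "\t") -> PhenotypeMatrix:
    """Read a delimited phenotype table; blank/NA cells are missing."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ID(s): {dup}")
    return PhenotypeMatrix.from_raw(df.apply(pd.to_numeric, errors="coerce"))


OTHER_TAXON = "OTHER"


def aggregate_rare_taxa(table: AbundanceTable, cutoff: float = 0.001) -> AbundanceTable:
    """Sum taxa with mean relative abundance below ``cutoff`` into "OTHER".

    Mirrors the common practice of aggregating taxa whose variation sits
    below the technical-noise floor (default 0.1% mean relative abundance).
    The OTHER column is always appended, even when empty, so that the taxon
    set is stable across cutoffs; surviving taxa keep their original order.
    """
    rel = table.to_relative()
    means = rel.values.mean(axis=0)
    keep = means >= cutoff
    if keep.sum() < 2:
        raise ValueError(
            f"cutoff {cutoff} leaves {int(keep.sum())} taxa; need at least 2"
        )
    other = rel.values[:, ~keep].sum(axis=1)
    values = np.column_stack([rel.values[:, keep], other])
    taxa = [t for t, k in zip(rel.taxon_ids, keep) if k] + [OTHER_TAXON]
    return AbundanceTable(rel.sample_ids, taxa, values, is_relative=True)
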