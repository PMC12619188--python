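"""Sample-by-metabolite abundance container shared by every pipeline stage.

LC-MS metabolomics feature tables come with two kinds of side information:
per-sample metadata (batch of acquisition, whether the injection is a pooled
QC replicate, the case/control label) and per-metabolite metadata (dataset of
origin, lipid class, KEGG compound identifier).  :class:`AbundanceMatrix`
bundles the three aligned :class:`pandas.DataFrame` objects and enforces the
alignment invariants once, so downstream stages can operate on plain pandas
objects without re-validating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Allowed dataset-of-origin tags for metabolite metadata.
DATASET_TAGS = ("polar", "nonpolar_pos", "nonpolar_neg")

SAMPLE_META_COLUMNS = ("batch_id", "is_qc", "label")
METABOLITE_META_COLUMNS = ("dataset", "lipid_class", "kegg_id")


@dataclass
class AbundanceMatrix:
    """Samples x metabolites abundances plus aligned metadata tables.

    Parameters
    ----------
    values
        Non-negative abundances (missing allowed as NaN); index is the sample
        identifier, columns are metabolite names.
    sample_meta
        One row per sample, same index as ``values``.  Columns: ``batch_id``,
        ``is_qc`` (bool), ``label`` (0/1 for biological samples, NaN for QC
        injections).
    metabolite_meta
        One row per metabolite, same index as ``values.columns``.  Columns:
        ``dataset`` (one of :data:`DATASET_TAGS`), ``lipid_class``,
        ``kegg_id`` (KEGG compound ID or NaN).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    metabolite_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.metabolite_meta is None:
            self.metabolite_meta = pd.DataFrame(
                {"dataset": "polar", "lipid_class": "unknown", "kegg_id": np.nan},
                index=self.values.columns,
            )
        if not self.values.index.is_unique:
            raise ValueError("sample IDs must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("metabolite names must be unique within a matrix")
        if not self.values.index.equals(self.sample_meta.index):
            raise ValueError("values and sample_meta indices differ")
        if not self.values.columns.equals(self.metabolite_meta.index):
            raise ValueError("values columns and metabolite_meta index differ")
        for col in ("batch_id", "is_qc"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta lacks required column {col!r}")
        if (self.values.to_numpy(dtype=float) < 0).any() and not getattr(
            self, "allow_negative", False
        ):
            # log/standardized stages mark themselves via flag_transformed()
            raise ValueError("negative abundances on the raw scale")

    # -- convenience views -------------------------------------------------

    @property
    def is_qc(self) -> pd.Series:
        return self.sample_meta["is_qc"].astype(bool)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def qc_values(self) -> pd.DataFrame:
        """Abundances of the pooled-QC injections only."""
        return self.values.loc[self.is_qc]

    def biological_values(self) -> pd.DataFrame:
        """Abundances of the biological (non-QC) samples only."""
        return self.values.loc[~self.is_qc]

    def biological_labels(self) -> pd.Series:
        return self.sample_meta.loc[~self.is_qc, "label"].astype(int)

    def replace(self, values: pd.DataFrame) -> "AbundanceMatrix":
        """New matrix with the same metadata rows/columns as ``values``."""
        out = object.__new__(AbundanceMatrix)
        out.values = values
        out.sample_meta = self.sample_meta.loc[values.index]
        out.metabolite_meta = self.metabolite_meta.loc[values.columns]
        out.allow_negative = getattr(self, "allow_negative", False)
        return out

    def flag_transformed(self) -> "AbundanceMatrix":
        """Mark the matrix as past the log/standardize stages (negatives OK)."""
        self.allow_negative = True
        return self

    # -- text I/O ----------------------------------------------------------

    def to_dir(self, path: str | Path, prefix: str = "matrix") -> None:
        """Write values plus the two metadata sidecars as TSV files."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.values.to_csv(path / f"{prefix}_values.tsv", sep="\t")
        self.sample_meta.to_csv(path / f"{prefix}_samples.tsv", sep="\t")
        self.metabolite_meta.to_csv(path / f"{prefix}_metabolites.tsv", sep="\t")

    @classmethod
    def from_dir(cls, path: str | Path, prefix: str = "matrix") -> "AbundanceMatrix":
        path = Path(path)
        values = pd.read_csv(path / f"{prefix}_values.tsv", sep="\t", index_col=0)
        sample_meta = pd.read_csv(path / f"{prefix}_samples.tsv", sep="\t", index_col=0)
        metabolite_meta = pd.read_csv(
            path / f"{prefix}_metabolites.tsv", sep="\t", index_col=0
        )
        sample_meta["is_qc"] = sample_meta["is_qc"].astype(bool)
        return cls(values, sample_meta, metabolite_meta)
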