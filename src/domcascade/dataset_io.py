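"""Aligned formula x sample datasets with per-sample metadata, and table IO.

Per-sample normalised formula tables are assembled into a single matrix keyed
by canonical formula strings (assignment already discretised masses, so no
mass-tolerance joining happens here).  Intensities are never renormalised
after subsetting: the relative abundance of a compound group within a sample
is the sum of its original normalised intensities, i.e. a fraction of the
sample's total assigned signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .chem_core import (
    ClassBoundaryTable,
    DEFAULT_CLASS_TABLE,
    descriptors,
    format_formula,
    parse_formula,
)

__all__ = ["SampleMetadata", "DOMDataset", "build_dataset", "subset"]

POSITIONS: tuple[str, ...] = ("shoulder", "back", "foot", "toe", "stream")
DEPTHS_CM: tuple[int, ...] = (5, 15, 30, 60)

METADATA_COLUMNS = ["sample_id", "catchment", "position", "depth_cm", "sample_type"]


@dataclass(frozen=True)
class SampleMetadata:
    """Where one sample sits in the catchment design.

    Soil samples carry a depth (cm); stream samples have none.
    """

    sample_id: str
    catchment: str
    position: str
    depth_cm: float | None
    sample_type: str

    def __post_init__(self) -> None:
        if self.position not in POSITIONS:
            raise ValueError(f"unknown position {self.position!r}; expected one of {POSITIONS}")
        if self.sample_type not in ("soil", "stream"):
            raise ValueError(f"sample_type must be 'soil' or 'stream', got {self.sample_type!r}")
        if self.sample_type == "stream" and self.depth_cm is not None:
            raise ValueError(f"stream sample {self.sample_id!r} must not have a depth")
        if self.sample_type == "soil" and self.depth_cm is None:
            raise ValueError(f"soil sample {self.sample_id!r} needs a depth")


class DOMDataset:
    """Formula x sample matrix of normalised intensities plus metadata.

    Attributes
    ----------
    intensities : DataFrame, index = canonical formula strings, columns =
        sample ids; 0 means the formula was not detected in that sample.
    metadata : DataFrame indexed by sample id with catchment / position /
        depth_cm / sample_type columns, ordered like the intensity columns.
    descriptors : DataFrame indexed by formula with neutral_mass, hc, oc, nc,
        dbe, ai_mod, hetero_group, compound_class.
    """

    def __init__(
        self,
        intensities: pd.DataFrame,
        metadata: pd.DataFrame,
        descriptor_table: pd.DataFrame,
    ) -> None:
        if list(intensities.columns) != list(metadata.index):
            raise ValueError("intensity columns and metadata rows must align")
        if list(intensities.index) != list(descriptor_table.index):
            raise ValueError("intensity rows and descriptor rows must align")
        self.intensities = intensities
        self.metadata = metadata
        self.descriptors = descriptor_table

    # -- basic views -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def formulas(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_formulas(self) -> int:
        return self.intensities.shape[0]

    def presence(self) -> pd.DataFrame:
        """Boolean detection matrix (intensity > 0)."""
        return self.intensities > 0

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DOMDataset({self.n_formulas} formulas x {self.n_samples} samples)"

    # -- IO ----------------------------------------------------------------
    def to_tsv(self, intensity_path, metadata_path) -> None:
        """Write the long-format intensity table and the metadata table."""
        long = (
            self.intensities.rename_axis("formula")
            .reset_index()
            .melt(id_vars="formula", var_name="sample_id", value_name="intensity")
        )
        long = long[long["intensity"] > 0]
        long[["sample_id", "formula", "intensity"]].to_csv(
            intensity_path, sep="\t", index=False, float_format="%.17g"
        )
        meta = self.metadata.rename_axis("sample_id").reset_index()
        meta.to_csv(metadata_path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, intensity_path, metadata_path, table: ClassBoundaryTable = DEFAULT_CLASS_TABLE
    ) -> "DOMDataset":
        long = pd.read_csv(intensity_path, sep="\t")
        meta = pd.read_csv(metadata_path, sep="\t")
        metadata = _metadata_frame(
            SampleMetadata(
                sample_id=str(r.sample_id),
                catchment=str(r.catchment),
                position=str(r.position),
                depth_cm=None if pd.isna(r.depth_cm) else float(r.depth_cm),
                sample_type=str(r.sample_type),
            )
            for r in meta.itertuples()
        )
        tables = {
            sid: grp.set_index("formula")["intensity"]
            for sid, grp in long.groupby("sample_id", sort=False)
        }
        return build_dataset(tables, metadata, table=table, validate_sums=False)


def _metadata_frame(samples: Iterable[SampleMetadata]) -> pd.DataFrame:
    rows = list(samples)
    ids = [s.sample_id for s in rows]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample_id(s): {dupes}")
    return pd.DataFrame(
        {
            "catchment": [s.catchment for s in rows],
            "position": [s.position for s in rows],
            "depth_cm": [s.depth_cm for s in rows],
            "sample_type": [s.sample_type for s in rows],
        },
        index=pd.Index(ids, name="sample_id"),
    )


def build_dataset(
    tables: Mapping[str, pd.Series],
    metadata: Iterable[SampleMetadata] | pd.DataFrame,
    table: ClassBoundaryTable = DEFAULT_CLASS_TABLE,
    validate_sums: bool = True,
) -> DOMDataset:
    """Union per-sample formula tables into one aligned dataset.

    ``tables`` maps sample ids to Series of normalised intensity keyed by
    canonical formula string.  Formulas are unioned across samples; a formula
    missing from a sample gets intensity 0; descriptors are computed once per
    formula.  Sample ids must match the metadata exactly.
    """
    meta = metadata if isinstance(metadata, pd.DataFrame) else _metadata_frame(metadata)
    table_ids = set(tables)
    meta_ids = set(meta.index)
    if table_ids != meta_ids:
        orphans = sorted(table_ids ^ meta_ids)
        raise ValueError(f"sample ids mismatch between tables and metadata: {orphans}")

    matrix = pd.DataFrame({sid: tables[sid] for sid in meta.index}).fillna(0.0)
    matrix = matrix.loc[(matrix > 0).any(axis=1)]  # no all-zero rows
    matrix = matrix.sort_index()

    if validate_sums:
        sums = matrix.sum(axis=0)
        bad = sums[(sums - 1.0).abs() > 1e-9]
        if len(bad):
            raise ValueError(
                f"per-sample intensities must sum to 1; offending samples: {list(bad.index)}"
            )

    desc_rows = {}
    for key in matrix.index:
        d = descriptors(parse_formula(key), table)
        desc_rows[key] = {
            "c": d.formula.c, "h": d.formula.h, "n": d.formula.n, "o": d.formula.o,
            "s": d.formula.s, "p": d.formula.p,
            "neutral_mass": d.neutral_mass, "hc": d.hc, "oc": d.oc, "nc": d.nc,
            "dbe": d.dbe, "ai_mod": d.ai_mod, "hetero_group": d.hetero_group,
            "compound_class": d.compound_class,
        }
    desc = pd.DataFrame.from_dict(desc_rows, orient="index")
    desc.index.name = "formula"
    return DOMDataset(matrix, meta, desc)


def subset(
    dataset: DOMDataset,
    formula_predicate: Callable[[pd.Series], bool] | pd.Series | None = None,
    sample_predicate: Callable[[pd.Series], bool] | pd.Series | None = None,
) -> DOMDataset:
    """Filter rows/columns; intensities are deliberately NOT renormalised.

    Predicates may be callables over the per-formula descriptor row / the
    per-sample metadata row, or precomputed boolean Series aligned to the
    respective index.
    """
    fmask = _mask(dataset.descriptors, formula_predicate)
    smask = _mask(dataset.metadata, sample_predicate)
    out = DOMDataset(
        dataset.intensities.loc[fmask, smask],
        dataset.metadata.loc[smask],
        dataset.descriptors.loc[fmask],
    )
    if out.n_formulas == 0 or out.n_samples == 0:
        warnings.warn("subset produced an empty dataset", stacklevel=2)
    return out


def _mask(frame: pd.DataFrame, predicate) -> pd.Series:
    if predicate is None:
        return pd.Series(True, index=frame.index)
    if isinstance(predicate, pd.Series):
        return predicate.reindex(frame.index, fill_value=False).astype(bool)
    return frame.apply(predicate, axis=1).astype(bool)
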