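"""Core domain types and delimited-text I/O for well-level profile tables.

A profile table follows the Cell Painting convention: one row per well,
metadata columns prefixed ``Metadata_``, and every remaining column a
numeric morphological feature.  The same layout (plus a cell identifier)
is used for single-cell tables.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

METADATA_PREFIX = "Metadata_"

#: Mandatory metadata columns for a well-level profile table.
REQUIRED_METADATA = (
    "Metadata_Plate",
    "Metadata_Well",
    "Metadata_perturbation",
    "Metadata_modality",
    "Metadata_control_type",
    "Metadata_target",
    "Metadata_cell_type",
    "Metadata_timepoint",
)

#: Mandatory metadata columns for a single-cell table.
REQUIRED_SINGLE_CELL_METADATA = (
    "Metadata_Plate",
    "Metadata_Well",
    "Metadata_cell_id",
)

PLATE_ROWS = "ABCDEFGHIJKLMNOP"  # 16 rows
PLATE_COLUMNS = tuple(range(1, 25))  # 24 columns
WELLS_PER_PLATE = len(PLATE_ROWS) * len(PLATE_COLUMNS)

TARGET_SEPARATOR = "|"

_WELL_RE = re.compile(r"^([A-P])(\d{2})$")


class SchemaError(ValueError):
    """A table is missing mandatory metadata or violates an invariant."""


class FeatureParseError(ValueError):
    """A feature cell could not be parsed as a number."""


class Modality(str, enum.Enum):
    COMPOUND = "compound"
    CRISPR = "crispr"
    ORF = "orf"


class ControlType(str, enum.Enum):
    TRT = "trt"
    NEGCON = "negcon"
    POSCON_CP = "poscon_cp"
    POSCON_ORF = "poscon_orf"
    POSCON_DIVERSE = "poscon_diverse"


POSITIVE_CONTROL_TYPES = frozenset(
    {ControlType.POSCON_CP.value, ControlType.POSCON_ORF.value, ControlType.POSCON_DIVERSE.value}
)


@dataclass(frozen=True)
class WellAddress:
    """A well on a 384-well plate (16 rows A-P, 24 columns)."""

    plate_id: str
    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in PLATE_ROWS:
            raise ValueError(f"row must be one of A-P, got {self.row!r}")
        if not 1 <= self.column <= 24:
            raise ValueError(f"column must be in 1..24, got {self.column}")

    @property
    def name(self) -> str:
        """Render as letter row + zero-padded column, e.g. 'A01'."""
        return f"{self.row}{self.column:02d}"

    @property
    def zone(self) -> str:
        """'outer' for the two rows/columns nearest each edge, else 'inner'."""
        if self.row in "ABOP" or self.column in (1, 2, 23, 24):
            return "outer"
        return "inner"

    @classmethod
    def parse(cls, plate_id: str, well_name: str) -> "WellAddress":
        m = _WELL_RE.match(well_name)
        if m is None:
            raise ValueError(f"not a valid 384-well name: {well_name!r}")
        return cls(plate_id=plate_id, row=m.group(1), column=int(m.group(2)))


def enumerate_wells(plate_id: str) -> list[WellAddress]:
    """All 384 wells of a plate in row-major order."""
    return [
        WellAddress(plate_id, row, col) for row in PLATE_ROWS for col in PLATE_COLUMNS
    ]


@dataclass(frozen=True)
class PerturbationLabel:
    """Identity and annotation of the treatment in a well.

    Negative controls carry no target genes.  CRISPR and ORF treatments
    target exactly one gene; compounds may target several
    (polypharmacology).
    """

    perturbation_id: str
    modality: str
    control_type: str
    target_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        Modality(self.modality)
        ControlType(self.control_type)
        if self.control_type == ControlType.NEGCON.value and self.target_genes:
            raise ValueError(
                f"negative control {self.perturbation_id!r} must have no target genes"
            )
        if (
            self.control_type == ControlType.TRT.value
            and self.modality in (Modality.CRISPR.value, Modality.ORF.value)
            and len(self.target_genes) != 1
        ):
            raise ValueError(
                f"{self.modality} treatment {self.perturbation_id!r} must target "
                f"exactly one gene, got {sorted(self.target_genes)}"
            )


def format_targets(genes: Iterable[str]) -> str:
    return TARGET_SEPARATOR.join(sorted(genes))


def parse_targets(value: object) -> frozenset[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return frozenset()
    text = str(value).strip()
    if not text:
        return frozenset()
    return frozenset(g for g in text.split(TARGET_SEPARATOR) if g)


class ProfileTable:
    """Well-level profiles: a metadata block plus a numeric feature block.

    Thin wrapper over a :class:`pandas.DataFrame` that enforces the
    schema (mandatory metadata columns, numeric features) and exposes
    typed views of the metadata.
    """

    required_metadata: tuple[str, ...] = REQUIRED_METADATA

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.required_metadata if c not in data.columns]
        if missing:
            raise SchemaError(f"missing mandatory metadata column(s): {missing}")
        meta_cols = [c for c in data.columns if c.startswith(METADATA_PREFIX)]
        feat_cols = [c for c in data.columns if not c.startswith(METADATA_PREFIX)]
        for col in feat_cols:
            if not pd.api.types.is_numeric_dtype(data[col]):
                coerced = pd.to_numeric(data[col], errors="coerce")
                bad = coerced.isna() & data[col].notna()
                if bad.any():
                    row = int(np.flatnonzero(bad.to_numpy())[0])
                    raise FeatureParseError(
                        f"non-numeric value in feature column {col!r}, row {row}: "
                        f"{data[col].iloc[row]!r}"
                    )
                data = data.assign(**{col: coerced})
        # metadata first, features after, preserving within-block order
        self._data = data.loc[:, meta_cols + feat_cols].reset_index(drop=True)
        self._feature_names = feat_cols

    # -- accessors ---------------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def metadata_columns(self) -> list[str]:
        return [c for c in self._data.columns if c.startswith(METADATA_PREFIX)]

    @property
    def feature_names(self) -> list[str]:
        return list(self._feature_names)

    @property
    def metadata(self) -> pd.DataFrame:
        return self._data[self.metadata_columns]

    @property
    def features(self) -> np.ndarray:
        return self._data[self._feature_names].to_numpy(dtype=float)

    @property
    def n_wells(self) -> int:
        return len(self._data)

    def __len__(self) -> int:
        return len(self._data)

    # -- derived views -----------------------------------------------------
    def well_addresses(self) -> list[WellAddress]:
        return [
            WellAddress.parse(str(p), str(w))
            for p, w in zip(self._data["Metadata_Plate"], self._data["Metadata_Well"])
        ]

    def labels(self) -> list[PerturbationLabel]:
        return [
            PerturbationLabel(
                perturbation_id=str(r.Metadata_perturbation),
                modality=str(r.Metadata_modality),
                control_type=str(r.Metadata_control_type),
                target_genes=parse_targets(r.Metadata_target),
            )
            for r in self._data.itertuples()
        ]

    def subset(self, **filters: object) -> "ProfileTable":
        """Rows matching all ``Metadata_<key> == value`` filters."""
        mask = pd.Series(True, index=self._data.index)
        for key, value in filters.items():
            col = key if key.startswith(METADATA_PREFIX) else METADATA_PREFIX + key
            mask &= self._data[col] == value
        return ProfileTable(self._data.loc[mask].reset_index(drop=True))

    def with_features(self, matrix: np.ndarray, names: Sequence[str]) -> "ProfileTable":
        """Same metadata, new feature block."""
        meta = self.metadata.reset_index(drop=True)
        feats = pd.DataFrame(np.asarray(matrix, dtype=float), columns=list(names))
        return ProfileTable(pd.concat([meta, feats], axis=1))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ProfileTable({self.n_wells} wells x {len(self._feature_names)} features, "
            f"{self._data['Metadata_Plate'].nunique()} plate(s))"
        )


class SingleCellTable(ProfileTable):
    """Per-cell profiles; every cell belongs to exactly one well."""

    required_metadata = REQUIRED_SINGLE_CELL_METADATA


def _resolve_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_profiles(
    path: str | Path,
    delimiter: str | None = None,
    rename: Mapping[str, str] | None = None,
    single_cell: bool = False,
) -> ProfileTable:
    """Read a delimited profile table.

    Parameters
    ----------
    path
        CSV/TSV file; the delimiter is inferred from the suffix unless given.
    rename
        Optional ``{foreign column -> canonical column}`` map for tables
        that do not follow the ``Metadata_`` dialect.
    single_cell
        Parse as a :class:`SingleCellTable` instead.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep=_resolve_delimiter(path, delimiter), float_precision="round_trip"
    )
    if rename:
        df = df.rename(columns=dict(rename))
    for col in df.columns:
        # empty metadata cells (e.g. no target annotation) read as NaN
        if col.startswith(METADATA_PREFIX) and df[col].isna().any():
            df[col] = df[col].where(df[col].notna(), "")
    cls = SingleCellTable if single_cell else ProfileTable
    return cls(df)


def write_profiles(
    table: ProfileTable, path: str | Path, delimiter: str | None = None
) -> None:
    """Write a profile table: metadata columns first, features after."""
    path = Path(path)
    table.data.to_csv(path, sep=_resolve_delimiter(path, delimiter), index=False)
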