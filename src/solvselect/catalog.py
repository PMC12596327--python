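"""Solvent catalog: data model, CSV I/O and hazard/boiling-point filtering.

A catalog is an ordered collection of solvents, each carrying a CHEM21-style
hazard class (recommended / problematic / hazardous), a boiling point, and —
where available — Hansen parameters, Abraham descriptors and a block of
physicochemical descriptors used for the PCA chemical space.  The filter
implements the usual pre-screening of a substitution study: drop solvents of
excluded hazard classes (with a configurable exception list for reference
solvents that must stay, e.g. chloroform itself) and drop solvents whose
boiling point makes post-extraction evaporation impractical.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .abraham import AbrahamDescriptors
from .errors import CatalogValidationError, SchemaError
from .hansen import HansenParameters

__all__ = [
    "HazardClass",
    "SolventFlags",
    "SolventRecord",
    "Catalog",
    "CatalogFilterConfig",
    "DEFAULT_EXCEPTION_NAMES",
    "read_catalog",
    "write_catalog",
    "filter_catalog",
    "normalize_name",
]

MANDATORY_COLUMNS = ("name", "hazard_class", "boiling_point_c")
HANSEN_COLUMNS = ("delta_d", "delta_p", "delta_h")
FLAG_COLUMNS = ("aromatic", "chlorinated", "commercially_available")
ABRAHAM_PREFIX = "abr_"

#: Hazardous solvents routinely used in lipid extraction that a substitution
#: screen keeps as reference compounds despite their classification.
DEFAULT_EXCEPTION_NAMES = (
    "chloroform",
    "dichloromethane",
    "methanol",
    "n-hexane",
    "methyl tert-butyl ether",
)


class HazardClass(enum.Enum):
    """CHEM21-style safety/health/environment ranking."""

    RECOMMENDED = "recommended"
    PROBLEMATIC = "problematic"
    HAZARDOUS = "hazardous"
    UNCLASSIFIED = "unclassified"

    @classmethod
    def parse(cls, value: object) -> "HazardClass":
        if isinstance(value, cls):
            return value
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return cls.UNCLASSIFIED
        text = str(value).strip().lower()
        if not text:
            return cls.UNCLASSIFIED
        try:
            return cls(text)
        except ValueError as exc:
            raise CatalogValidationError(f"unknown hazard class {value!r}") from exc


def normalize_name(name: str) -> str:
    """Case-insensitive key with collapsed internal whitespace."""
    return re.sub(r"\s+", " ", name.strip()).lower()


@dataclass(frozen=True)
class SolventFlags:
    """Boolean annotations consumed by the practical selection rules."""

    aromatic: bool = False
    chlorinated: bool = False
    commercially_available: bool = True


@dataclass(frozen=True)
class SolventRecord:
    """One solvent with its classification, parameters and descriptors.

    ``descriptors`` holds the physicochemical block used for PCA; missing
    entries are NaN, never zero.
    """

    name: str
    hazard_class: HazardClass = HazardClass.UNCLASSIFIED
    boiling_point: float | None = None
    hansen: HansenParameters | None = None
    abraham: AbrahamDescriptors | None = None
    descriptors: Mapping[str, float] = field(default_factory=dict)
    flags: SolventFlags = field(default_factory=SolventFlags)

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise CatalogValidationError("solvent name must be non-empty")
        if self.boiling_point is not None and not math.isfinite(self.boiling_point):
            raise CatalogValidationError(
                f"boiling point of {self.name!r} must be finite when present"
            )
        object.__setattr__(self, "descriptors", dict(self.descriptors))


class Catalog:
    """Ordered, name-unique collection of :class:`SolventRecord`."""

    def __init__(
        self,
        records: Iterable[SolventRecord] = (),
        descriptor_schema: Sequence[str] | None = None,
    ) -> None:
        self._records: list[SolventRecord] = list(records)
        self.descriptor_schema: tuple[str, ...] = tuple(descriptor_schema or ())
        self._index: dict[str, int] = {}
        for i, record in enumerate(self._records):
            key = normalize_name(record.name)
            if key in self._index:
                raise CatalogValidationError(f"duplicate solvent name {record.name!r}")
            self._index[key] = i
        if self.descriptor_schema:
            schema = set(self.descriptor_schema)
            for record in self._records:
                extra = set(record.descriptors) - schema
                if extra:
                    raise CatalogValidationError(
                        f"{record.name!r} carries descriptors outside the declared "
                        f"schema: {sorted(extra)}"
                    )

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[SolventRecord]:
        return iter(self._records)

    def __getitem__(self, i: int) -> SolventRecord:
        return self._records[i]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self._records]

    def __contains__(self, name: object) -> bool:
        return isinstance(name, str) and normalize_name(name) in self._index

    def get(self, name: str) -> SolventRecord | None:
        i = self._index.get(normalize_name(name))
        return None if i is None else self._records[i]

    def descriptor_matrix(self, schema: Sequence[str] | None = None) -> pd.DataFrame:
        """Solvent x descriptor matrix (NaN where a value is missing)."""
        columns = tuple(schema) if schema is not None else self.descriptor_schema
        if not columns:
            raise SchemaError("no descriptor schema declared or supplied")
        data = {
            record.name: [record.descriptors.get(c, float("nan")) for c in columns]
            for record in self._records
        }
        return pd.DataFrame.from_dict(data, orient="index", columns=list(columns))

    def subset(self, names: Iterable[str]) -> "Catalog":
        wanted = {normalize_name(n) for n in names}
        return Catalog(
            (r for r in self._records if normalize_name(r.name) in wanted),
            descriptor_schema=self.descriptor_schema,
        )


@dataclass(frozen=True)
class CatalogFilterConfig:
    """Rules for the two-stage pre-screening filter.

    Solvents of an excluded hazard class are removed unless named on the
    exception list (matched case-insensitively after whitespace
    normalization, with optional synonym aliases); solvents boiling strictly
    above ``bp_max`` are removed unconditionally.
    """

    excluded_classes: frozenset[HazardClass] = frozenset({HazardClass.HAZARDOUS})
    exception_names: tuple[str, ...] = DEFAULT_EXCEPTION_NAMES
    bp_max: float = 125.0
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bp_max <= 0:
            raise ValueError("bp_max must be positive")
        object.__setattr__(self, "excluded_classes", frozenset(self.excluded_classes))
        object.__setattr__(
            self, "aliases", {normalize_name(k): normalize_name(v) for k, v in dict(self.aliases).items()}
        )

    def is_exception(self, name: str) -> bool:
        key = normalize_name(name)
        key = self.aliases.get(key, key)
        return key in {normalize_name(n) for n in self.exception_names}


def filter_catalog(
    catalog: Catalog, cfg: CatalogFilterConfig | None = None
) -> Catalog:
    """Apply the hazard-class and boiling-point rules; order preserved.

    A record is kept iff (its class is not excluded OR its name is on the
    exception list) AND its boiling point is <= ``bp_max``.  Idempotent; the
    input catalog is not modified.
    """
    cfg = cfg or CatalogFilterConfig()
    missing_bp = [r.name for r in catalog if r.boiling_point is None]
    if missing_bp:
        raise CatalogValidationError(
            f"records missing boiling_point: {missing_bp}"
        )
    kept = [
        r
        for r in catalog
        if (r.hazard_class not in cfg.excluded_classes or cfg.is_exception(r.name))
        and r.boiling_point <= cfg.bp_max
    ]
    return Catalog(kept, descriptor_schema=catalog.descriptor_schema)


def _parse_float(value: object) -> float | None:
    if value is None:
        return None
    if isinstance(value, str):
        value = value.strip()
        if not value:
            return None
    try:
        out = float(value)
    except (TypeError, ValueError):
        return None
    return out if math.isfinite(out) else None


def _parse_flag(value: object, default: bool) -> bool:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return default
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"1", "true", "yes", "y"}:
        return True
    if text in {"0", "false", "no", "n"}:
        return False
    return default


def read_catalog(
    path: str | Path, schema: Sequence[str] | None = None
) -> Catalog:
    """Read a catalog CSV into an ordered :class:`Catalog`.

    The file must carry the mandatory columns ``name, hazard_class,
    boiling_point_c``.  Hansen components come from ``delta_d, delta_p,
    delta_h`` (a record with any of the three blank gets ``hansen=None``),
    Abraham descriptors from columns prefixed ``abr_``, boolean flags from
    ``aromatic, chlorinated, commercially_available``.  If *schema* is not
    given, every remaining column is treated as a PCA descriptor.  Empty
    cells become missing values, never zeros; row order is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"name": str}, skipinitialspace=True)
    df.columns = [str(c).strip() for c in df.columns]
    for column in MANDATORY_COLUMNS:
        if column not in df.columns:
            raise SchemaError(f"mandatory column {column!r} missing from {path.name}")

    abraham_cols = [c for c in df.columns if c.startswith(ABRAHAM_PREFIX)]
    known = set(MANDATORY_COLUMNS) | set(HANSEN_COLUMNS) | set(FLAG_COLUMNS) | set(abraham_cols)
    if schema is None:
        schema = [c for c in df.columns if c not in known]
    else:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise SchemaError(f"descriptor columns {missing} missing from {path.name}")

    records: list[SolventRecord] = []
    for _, row in df.iterrows():
        hansen_values = [_parse_float(row.get(c)) for c in HANSEN_COLUMNS]
        hansen = (
            HansenParameters(*hansen_values)
            if all(v is not None for v in hansen_values)
            else None
        )
        abraham_values = {
            c[len(ABRAHAM_PREFIX):]: v
            for c in abraham_cols
            if (v := _parse_float(row.get(c))) is not None
        }
        abraham = AbrahamDescriptors(abraham_values) if len(abraham_values) >= 2 else None
        descriptors = {
            c: (v if (v := _parse_float(row.get(c))) is not None else float("nan"))
            for c in schema
        }
        records.append(
            SolventRecord(
                name=str(row["name"]).strip(),
                hazard_class=HazardClass.parse(row.get("hazard_class")),
                boiling_point=_parse_float(row.get("boiling_point_c")),
                hansen=hansen,
                abraham=abraham,
                descriptors=descriptors,
                flags=SolventFlags(
                    aromatic=_parse_flag(row.get("aromatic"), False),
                    chlorinated=_parse_flag(row.get("chlorinated"), False),
                    commercially_available=_parse_flag(
                        row.get("commercially_available"), True
                    ),
                ),
            )
        )
    return Catalog(records, descriptor_schema=schema)


def write_catalog(catalog: Catalog, path: str | Path) -> None:
    """Write a catalog back to the CSV dialect :func:`read_catalog` accepts."""
    abraham_symbols: list[str] = []
    for record in catalog:
        if record.abraham is not None:
            for s in record.abraham.symbols:
                if s not in abraham_symbols:
                    abraham_symbols.append(s)
    rows = []
    for r in catalog:
        row: dict[str, object] = {
            "name": r.name,
            "hazard_class": r.hazard_class.value,
            "boiling_point_c": r.boiling_point,
        }
        for i, c in enumerate(HANSEN_COLUMNS):
            row[c] = r.hansen.as_tuple()[i] if r.hansen is not None else None
        for s in abraham_symbols:
            row[ABRAHAM_PREFIX + s] = (
                r.abraham.values.get(s) if r.abraham is not None else None
            )
        row["aromatic"] = r.flags.aromatic
        row["chlorinated"] = r.flags.chlorinated
        row["commercially_available"] = r.flags.commercially_available
        for c in catalog.descriptor_schema:
            row[c] = r.descriptors.get(c, float("nan"))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _with_flags(record: SolventRecord, **flags: bool) -> SolventRecord:
    return replace(record, flags=replace(record.flags, **flags))
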