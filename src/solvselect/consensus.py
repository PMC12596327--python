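"""Consensus candidate selection across the HSP, ASP and PCA screens.

Solvents are partitioned into three prioritization categories — short-listed
by both similarity models, by exactly one, or by neither (the last group
supplies negative controls) — and then passed through declarative practical
exclusion rules (aromatic odor, chemotype over-representation, commercial
availability, ad-hoc exclusions).  Encoding the practical judgments as
configurable rules with a per-solvent audit trail keeps an intrinsically
subjective step reproducible: the choices are data, not code.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import pandas as pd

from .catalog import Catalog, normalize_name
from .errors import CatalogValidationError

__all__ = [
    "Category",
    "ConsensusRecord",
    "PracticalRules",
    "ConsensusSelection",
    "categorize",
    "apply_practical_rules",
]


class Category(enum.Enum):
    BOTH = "both"
    EITHER = "either"
    NEITHER = "neither"


@dataclass(frozen=True)
class ConsensusRecord:
    solvent_name: str
    in_hsp: bool
    in_asp: bool
    category: Category
    pc1_offset: float | None = None
    pc2_offset: float | None = None
    excluded_by: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        expected = (
            Category.BOTH
            if self.in_hsp and self.in_asp
            else Category.NEITHER
            if not self.in_hsp and not self.in_asp
            else Category.EITHER
        )
        if self.category is not expected:
            raise ValueError(
                f"category {self.category} inconsistent with memberships "
                f"(in_hsp={self.in_hsp}, in_asp={self.in_asp})"
            )


def categorize(
    hsp_selected: Iterable[str],
    asp_selected: Iterable[str],
    universe: Sequence[str],
    scores: pd.DataFrame | None = None,
    reference: str | None = None,
) -> list[ConsensusRecord]:
    """Assign every universe member to both / either / neither.

    Membership is matched case-insensitively.  If a PCA score table and a
    reference name are supplied, signed PC1/PC2 offsets from the reference
    are attached.  Selected names outside the universe raise.
    """
    universe_keys = {normalize_name(n) for n in universe}
    hsp_keys = {normalize_name(n) for n in hsp_selected}
    asp_keys = {normalize_name(n) for n in asp_selected}
    stray = (hsp_keys | asp_keys) - universe_keys
    if stray:
        raise CatalogValidationError(
            f"selected solvents outside the universe: {sorted(stray)}"
        )

    offsets: dict[str, tuple[float, float]] = {}
    if scores is not None and reference is not None:
        centre = scores.loc[reference]
        lookup = {normalize_name(str(i)): str(i) for i in scores.index}
        for key, label in lookup.items():
            row = scores.loc[label]
            offsets[key] = (
                float(row.get("PC1", float("nan")) - centre.get("PC1", float("nan"))),
                float(row.get("PC2", float("nan")) - centre.get("PC2", float("nan")))
                if "PC2" in scores.columns
                else float("nan"),
            )

    records = []
    for name in universe:
        key = normalize_name(name)
        in_hsp = key in hsp_keys
        in_asp = key in asp_keys
        category = (
            Category.BOTH
            if in_hsp and in_asp
            else Category.NEITHER
            if not (in_hsp or in_asp)
            else Category.EITHER
        )
        pc1, pc2 = offsets.get(key, (None, None))
        records.append(
            ConsensusRecord(
                solvent_name=name,
                in_hsp=in_hsp,
                in_asp=in_asp,
                category=category,
                pc1_offset=pc1,
                pc2_offset=pc2,
            )
        )
    return records


@dataclass(frozen=True)
class PracticalRules:
    """Declarative exclusion rules applied after categorization.

    ``chlorinated_cap`` keeps at most that many chlorinated solvents in the
    shortlist (best-ranked first, following the record order given), flagging
    the surplus as ``over-represented-chemotype``.  ``n_controls`` negative
    controls are drawn from the neither category, nearest the reference along
    PC1.
    """

    exclude_aromatic: bool = True
    chlorinated_cap: int | None = 2
    require_commercial_availability: bool = True
    manual_exclusions: Mapping[str, str] = field(default_factory=dict)
    n_controls: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "manual_exclusions",
            {normalize_name(k): v for k, v in dict(self.manual_exclusions).items()},
        )


@dataclass(frozen=True)
class ConsensusSelection:
    shortlist: tuple[ConsensusRecord, ...]
    controls: tuple[ConsensusRecord, ...]
    records: tuple[ConsensusRecord, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [r.solvent_name for r in self.records],
                "category": [r.category.value for r in self.records],
                "in_hsp": [r.in_hsp for r in self.records],
                "in_asp": [r.in_asp for r in self.records],
                "pc1_offset": [r.pc1_offset for r in self.records],
                "pc2_offset": [r.pc2_offset for r in self.records],
                "excluded_by": ["; ".join(r.excluded_by) for r in self.records],
                "shortlisted": [r in self.shortlist for r in self.records],
                "control": [r in self.controls for r in self.records],
            }
        )


def apply_practical_rules(
    records: Sequence[ConsensusRecord],
    catalog: Catalog,
    rules: PracticalRules | None = None,
) -> ConsensusSelection:
    """Apply the exclusion rules and pick negative controls.

    Only prioritized records (both/either) can enter the shortlist; each
    exclusion a record hits is appended to its ``excluded_by`` audit trail.
    Controls are the ``n_controls`` neither-category solvents with the
    smallest absolute PC1 offset (requires offsets to have been attached).
    """
    rules = rules or PracticalRules()
    annotated: list[ConsensusRecord] = []
    n_chlorinated = 0
    for record in records:
        reasons: list[str] = []
        cat_record = catalog.get(record.solvent_name)
        flags = cat_record.flags if cat_record is not None else None
        prioritized = record.category is not Category.NEITHER
        if prioritized:
            if rules.exclude_aromatic and flags is not None and flags.aromatic:
                reasons.append("aromatic")
            if (
                rules.require_commercial_availability
                and flags is not None
                and not flags.commercially_available
            ):
                reasons.append("unavailable")
            manual = rules.manual_exclusions.get(normalize_name(record.solvent_name))
            if manual is not None:
                reasons.append(manual)
            if (
                not reasons
                and rules.chlorinated_cap is not None
                and flags is not None
                and flags.chlorinated
            ):
                # surviving chlorinated entries count against the cap in order
                if n_chlorinated >= rules.chlorinated_cap:
                    reasons.append("over-represented-chemotype")
                else:
                    n_chlorinated += 1
        annotated.append(replace(record, excluded_by=tuple(reasons)))

    shortlist = tuple(
        r
        for r in annotated
        if r.category is not Category.NEITHER and not r.excluded_by
    )
    neither = [r for r in annotated if r.category is Category.NEITHER]
    with_offset = [r for r in neither if r.pc1_offset is not None]
    with_offset.sort(key=lambda r: abs(r.pc1_offset))
    controls = tuple(with_offset[: rules.n_controls])
    return ConsensusSelection(
        shortlist=shortlist, controls=controls, records=tuple(annotated)
    )
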