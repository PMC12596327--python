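"""Hansen solubility parameter (HSP) screening.

Hansen's model decomposes a solvent's cohesive energy density into three
components — dispersion (:math:`\\delta_d`), polar (:math:`\\delta_p`) and
hydrogen bonding (:math:`\\delta_h`), all in MPa\\ :sup:`0.5`.  Two liquids
that sit close together in this three-dimensional space are likely to be
mutually soluble and to dissolve similar solutes, which makes the Hansen
distance

.. math::

    R_a^2 = 4\\,(\\delta_{d,1}-\\delta_{d,2})^2
          + (\\delta_{p,1}-\\delta_{p,2})^2
          + (\\delta_{h,1}-\\delta_{h,2})^2

a practical similarity score for solvent substitution: candidates are ranked
by ascending :math:`R_a` to a reference solvent and short-listed below a
threshold (screens in the green-chemistry literature typically use
:math:`R_a` between 4 and 6).  The factor 4 on the dispersion term is the
standard Hansen convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

from .errors import IncompleteDataError, SolventLookupError

if TYPE_CHECKING:  # pragma: no cover
    import pandas as pd

    from .catalog import Catalog

__all__ = [
    "HansenParameters",
    "HSPResult",
    "HSPRanking",
    "hansen_distance",
    "rank_by_hsp",
    "select_by_ra",
]


@dataclass(frozen=True)
class HansenParameters:
    """The three Hansen components of one solvent, in MPa^0.5."""

    delta_d: float
    delta_p: float
    delta_h: float

    def __post_init__(self) -> None:
        for field in ("delta_d", "delta_p", "delta_h"):
            value = getattr(self, field)
            if not math.isfinite(value) or value < 0:
                raise ValueError(
                    f"Hansen component {field}={value!r} must be finite and >= 0"
                )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.delta_d, self.delta_p, self.delta_h)


@dataclass(frozen=True)
class HSPResult:
    """Hansen distance of one solvent to the screening reference."""

    solvent_name: str
    ra: float
    rank: int


@dataclass(frozen=True)
class HSPRanking:
    """Ranked Hansen screen plus the solvents that could not be scored."""

    reference: str
    results: tuple[HSPResult, ...]
    missing: tuple[str, ...]

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        return pd.DataFrame(
            {
                "name": [r.solvent_name for r in self.results],
                "ra": [r.ra for r in self.results],
                "rank": [r.rank for r in self.results],
            }
        )


def hansen_distance(a: HansenParameters, b: HansenParameters) -> float:
    """Hansen distance Ra between two complete parameter sets (MPa^0.5).

    Symmetric, non-negative, zero iff the parameters coincide.  Because it is
    a Euclidean norm after stretching the dispersion axis by 2, it satisfies
    the triangle inequality.
    """
    if a is None or b is None:
        raise IncompleteDataError("both solvents need complete Hansen parameters")
    return math.sqrt(
        4.0 * (a.delta_d - b.delta_d) ** 2
        + (a.delta_p - b.delta_p) ** 2
        + (a.delta_h - b.delta_h) ** 2
    )


def rank_by_hsp(catalog: "Catalog", reference: str) -> HSPRanking:
    """Rank every catalog solvent by ascending Hansen distance to *reference*.

    The reference itself is excluded.  Solvents without complete Hansen
    parameters cannot be scored and are reported in ``missing`` rather than
    silently dropped.  Ties keep catalog order (stable sort).
    """
    ref_record = catalog.get(reference)
    if ref_record is None:
        raise SolventLookupError(f"reference solvent {reference!r} not in catalog")
    if ref_record.hansen is None:
        raise SolventLookupError(
            f"reference solvent {reference!r} lacks complete Hansen parameters"
        )

    scored: list[tuple[str, float]] = []
    missing: list[str] = []
    for record in catalog:
        if record.name == ref_record.name:
            continue
        if record.hansen is None:
            missing.append(record.name)
        else:
            scored.append((record.name, hansen_distance(record.hansen, ref_record.hansen)))

    scored.sort(key=lambda item: item[1])  # stable: ties keep catalog order
    results = tuple(
        HSPResult(solvent_name=name, ra=ra, rank=i + 1)
        for i, (name, ra) in enumerate(scored)
    )
    return HSPRanking(reference=ref_record.name, results=results, missing=tuple(missing))


def select_by_ra(
    results: Sequence[HSPResult] | HSPRanking, ra_max: float
) -> list[str]:
    """Names with Ra strictly below *ra_max*, in rank order.

    The strict inequality mirrors the usual "Ra < threshold" short-listing
    rule; an empty selection is a valid outcome.
    """
    if isinstance(results, HSPRanking):
        results = results.results
    return [r.solvent_name for r in results if r.ra < ra_max]


def _iter_results(results: Iterable[HSPResult]) -> Iterable[HSPResult]:
    return results
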