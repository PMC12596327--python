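"""Abraham solvation parameter (ASP) screening.

The Abraham model is a cavity-based linear free-energy relationship whose
solute descriptors — excess molar refraction ``E``, dipolarity/polarizability
``S``, hydrogen-bond acidity ``A``, hydrogen-bond basicity ``B`` and McGowan
characteristic volume ``V`` — summarize the interactions a molecule can make
with a solvent.  Two solvents with similar descriptor vectors participate in
similar solvation equilibria, so the screening score used here is the mean
absolute descriptor difference

.. math:: \\Delta = \\frac{1}{n}\\sum_i |d_{i,1} - d_{i,2}|

over the descriptors the two solvents share; smaller is more similar.
Missing descriptors are handled by pairwise deletion (only shared symbols
enter the average) with the count used reported alongside the score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

from .errors import IncompleteDataError, SolventLookupError

if TYPE_CHECKING:  # pragma: no cover
    import pandas as pd

    from .catalog import Catalog

__all__ = [
    "DEFAULT_SYMBOLS",
    "AbrahamDescriptors",
    "ASPResult",
    "ASPRanking",
    "abraham_delta",
    "rank_by_asp",
    "select_top_k",
]

#: The five classical solute descriptors.
DEFAULT_SYMBOLS: tuple[str, ...] = ("E", "S", "A", "B", "V")


@dataclass(frozen=True)
class AbrahamDescriptors:
    """An ordered map of Abraham descriptor symbol -> value for one solvent.

    At least two descriptors are required (a single shared number cannot
    express similarity), and the McGowan volume must be positive when given.
    Extended symbols (e.g. ``L``, the hexadecane partition descriptor) are
    allowed.
    """

    values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = dict(self.values)
        if len(values) < 2:
            raise ValueError("at least two Abraham descriptors are required")
        for symbol, value in values.items():
            if not math.isfinite(value):
                raise ValueError(f"descriptor {symbol}={value!r} must be finite")
        if "V" in values and values["V"] <= 0:
            raise ValueError("McGowan volume V must be positive")
        object.__setattr__(self, "values", values)

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(self.values)

    def __getitem__(self, symbol: str) -> float:
        return self.values[symbol]


def abraham_delta(
    a: AbrahamDescriptors,
    b: AbrahamDescriptors,
    symbols: Sequence[str] | None = None,
) -> tuple[float, int]:
    """Mean absolute difference over shared descriptors; returns (delta, n_used)."""
    if a is None or b is None:
        raise IncompleteDataError("both solvents need Abraham descriptors")
    requested = tuple(symbols) if symbols is not None else None
    shared = [
        s
        for s in (requested if requested is not None else a.symbols)
        if s in a.values and s in b.values
    ]
    if len(shared) < 2:
        raise IncompleteDataError(
            f"fewer than two shared Abraham descriptors (shared: {shared!r})"
        )
    delta = sum(abs(a[s] - b[s]) for s in shared) / len(shared)
    return delta, len(shared)


@dataclass(frozen=True)
class ASPResult:
    solvent_name: str
    avg_delta: float
    n_descriptors_used: int
    rank: int


@dataclass(frozen=True)
class ASPRanking:
    """Ranked Abraham screen plus solvents with too few shared descriptors."""

    reference: str
    results: tuple[ASPResult, ...]
    missing: tuple[str, ...]

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        return pd.DataFrame(
            {
                "name": [r.solvent_name for r in self.results],
                "avg_delta": [r.avg_delta for r in self.results],
                "n_descriptors_used": [r.n_descriptors_used for r in self.results],
                "rank": [r.rank for r in self.results],
            }
        )


def rank_by_asp(
    catalog: "Catalog",
    reference: str,
    symbols: Sequence[str] | None = None,
) -> ASPRanking:
    """Rank catalog solvents by ascending mean |descriptor difference| to *reference*.

    Solvents sharing fewer than two of the requested descriptors with the
    reference are reported in ``missing``.  Ties keep catalog order.
    """
    ref_record = catalog.get(reference)
    if ref_record is None:
        raise SolventLookupError(f"reference solvent {reference!r} not in catalog")
    if ref_record.abraham is None:
        raise SolventLookupError(
            f"reference solvent {reference!r} lacks Abraham descriptors"
        )

    scored: list[tuple[str, float, int]] = []
    missing: list[str] = []
    for record in catalog:
        if record.name == ref_record.name:
            continue
        if record.abraham is None:
            missing.append(record.name)
            continue
        try:
            delta, n_used = abraham_delta(ref_record.abraham, record.abraham, symbols)
        except IncompleteDataError:
            missing.append(record.name)
            continue
        scored.append((record.name, delta, n_used))

    scored.sort(key=lambda item: item[1])
    results = tuple(
        ASPResult(solvent_name=name, avg_delta=delta, n_descriptors_used=n, rank=i + 1)
        for i, (name, delta, n) in enumerate(scored)
    )
    return ASPRanking(reference=ref_record.name, results=results, missing=tuple(missing))


def select_top_k(results: Sequence[ASPResult] | ASPRanking, k: int) -> list[str]:
    """First min(k, n) names in rank order; k = 0 gives an empty list."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if isinstance(results, ASPRanking):
        results = results.results
    return [r.solvent_name for r in results[: min(k, len(results))]]
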