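"""Spike-recovery and class-level fold-change analytics for extraction methods.

Extraction recovery of a lipid is measured with isotope-labelled standards
spiked either before or after extraction:

.. math:: R_x(\\%) = \\frac{\\bar A_x(\\text{spike pre-extraction})}
                         {\\bar A_x(\\text{spike post-extraction})} \\times 100

where :math:`A_x` is the monoisotopic peak area.  Because the pre and post
groups are unpaired, the reported dispersion is the first-order propagation
of the two group coefficients of variation,
:math:`R \\sqrt{cv_\\text{pre}^2 + cv_\\text{post}^2}`.

For endogenous lipids without a matched spike design, extraction efficiency
is compared across methods at the class level: each species' area is first
normalized to its class-matched deuterated internal standard, species are
summed per class and replicate, and the per-class fold change of a test
method versus a reference method is tested with a two-sided two-sample
Student's t-test whose p-value is mapped onto the conventional star tiers.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import IncompleteDesignError, SchemaError, SolvselectError

__all__ = [
    "PEAK_AREA_COLUMNS",
    "SpikeTiming",
    "RecoveryResult",
    "MethodSummary",
    "FoldChangeResult",
    "DEFAULT_TIERS",
    "read_peak_areas",
    "validate_peak_areas",
    "compute_recovery",
    "compute_all_recoveries",
    "summarize_recoveries",
    "normalize_and_sum",
    "fold_change",
]

PEAK_AREA_COLUMNS = ("lipid_id", "method", "replicate", "spike_timing", "area")
SPECIES_COLUMNS = ("species", "lipid_class", "method", "replicate", "area")

#: Two-sided p-value thresholds for the star tiers, most stringent first.
DEFAULT_TIERS: tuple[tuple[float, str], ...] = (
    (0.001, "****"),
    (0.005, "***"),
    (0.01, "**"),
    (0.05, "*"),
)


class SpikeTiming(enum.Enum):
    PRE = "pre"
    POST = "post"


@dataclass(frozen=True)
class RecoveryResult:
    """Recovery percentage of one lipid under one extraction method."""

    lipid_id: str
    method: str
    recovery_pct: float
    dispersion_pct: float
    n_pre: int
    n_post: int


@dataclass(frozen=True)
class MethodSummary:
    """Unweighted mean +/- sample SD of per-lipid recoveries for one method."""

    method: str
    mean_pct: float
    sd_pct: float
    n_lipids: int
    sd_defined: bool

    def rounded(self) -> tuple[int, int]:
        return round(self.mean_pct), round(self.sd_pct)


@dataclass(frozen=True)
class FoldChangeResult:
    """Class-level fold change of a method versus the reference method."""

    lipid_class: str
    method: str
    reference: str
    fold_change: float
    sd: float
    p_value: float | None
    tier: str
    n_method: int
    n_reference: int


def read_peak_areas(path: str | Path) -> pd.DataFrame:
    """Read a long-format peak-area CSV and validate it."""
    df = pd.read_csv(path)
    validate_peak_areas(df)
    return df


def validate_peak_areas(table: pd.DataFrame) -> None:
    missing = [c for c in PEAK_AREA_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"peak-area table missing columns {missing}")
    timings = set(table["spike_timing"].astype(str).str.lower())
    unknown = timings - {t.value for t in SpikeTiming}
    if unknown:
        raise SolvselectError(f"unknown spike_timing values {sorted(unknown)}")
    areas = pd.to_numeric(table["area"], errors="coerce")
    if areas.isna().any() or (areas <= 0).any():
        raise SolvselectError("peak areas must be strictly positive numbers")


def _group_areas(
    table: pd.DataFrame, lipid: str, method: str, timing: SpikeTiming
) -> np.ndarray:
    sel = table[
        (table["lipid_id"] == lipid)
        & (table["method"] == method)
        & (table["spike_timing"].astype(str).str.lower() == timing.value)
    ]
    return sel["area"].to_numpy(dtype=float)


def compute_recovery(
    table: pd.DataFrame, lipid: str, method: str
) -> RecoveryResult:
    """Recovery of one (lipid, method): 100 x mean(pre) / mean(post).

    The dispersion is ``R * sqrt(cv_pre^2 + cv_post^2)`` with sample (n-1)
    CVs; with a single replicate in a group its CV contribution is zero.
    Invariant under rescaling all areas of the block by a positive constant.
    """
    validate_peak_areas(table)
    pre = _group_areas(table, lipid, method, SpikeTiming.PRE)
    post = _group_areas(table, lipid, method, SpikeTiming.POST)
    if pre.size == 0 or post.size == 0:
        raise IncompleteDesignError(
            f"({lipid!r}, {method!r}) needs both pre- and post-extraction spikes "
            f"(n_pre={pre.size}, n_post={post.size})"
        )
    recovery = 100.0 * pre.mean() / post.mean()
    cv_pre = pre.std(ddof=1) / pre.mean() if pre.size > 1 else 0.0
    cv_post = post.std(ddof=1) / post.mean() if post.size > 1 else 0.0
    dispersion = recovery * math.sqrt(cv_pre**2 + cv_post**2)
    return RecoveryResult(
        lipid_id=lipid,
        method=method,
        recovery_pct=recovery,
        dispersion_pct=dispersion,
        n_pre=int(pre.size),
        n_post=int(post.size),
    )


def compute_all_recoveries(table: pd.DataFrame) -> list[RecoveryResult]:
    """Recovery for every (lipid, method) pair present in the table."""
    validate_peak_areas(table)
    pairs = table[["lipid_id", "method"]].drop_duplicates()
    return [
        compute_recovery(table, row.lipid_id, row.method)
        for row in pairs.itertuples()
    ]


def summarize_recoveries(
    results: Sequence[RecoveryResult], method: str
) -> MethodSummary:
    """Unweighted mean and sample SD of per-lipid recoveries for *method*.

    With a single lipid the SD is undefined; it is reported as 0 with
    ``sd_defined=False``.
    """
    values = [r.recovery_pct for r in results if r.method == method]
    if not values:
        raise IncompleteDesignError(f"no recovery results for method {method!r}")
    mean = float(np.mean(values))
    if len(values) > 1:
        sd = float(np.std(values, ddof=1))
        defined = True
    else:
        sd, defined = 0.0, False
    return MethodSummary(
        method=method, mean_pct=mean, sd_pct=sd, n_lipids=len(values), sd_defined=defined
    )


def normalize_and_sum(
    species_areas: pd.DataFrame,
    standards: Mapping[str, str],
) -> tuple[pd.DataFrame, list[str]]:
    """Internal-standard normalization and per-class summation.

    For every (method, replicate), each species' area is divided by the area
    of its class-matched standard species in the same run, and the ratios are
    summed per class.  Classes without an entry in *standards* are excluded
    and returned in the second element, mirroring designs where only classes
    covered by the spiked standard mixture can be quantified.  Standards
    themselves do not contribute to the class sums.

    Returns a long table ``lipid_class, method, replicate, value``.
    """
    missing = [c for c in SPECIES_COLUMNS if c not in species_areas.columns]
    if missing:
        raise SchemaError(f"species table missing columns {missing}")
    classes = sorted(set(species_areas["lipid_class"].astype(str)))
    excluded = [c for c in classes if c not in standards]
    kept = [c for c in classes if c in standards]

    standard_ids = set(standards.values())
    rows: list[dict[str, object]] = []
    for lipid_class in kept:
        std_id = standards[lipid_class]
        class_species = species_areas[
            (species_areas["lipid_class"] == lipid_class)
            & (~species_areas["species"].isin(standard_ids))
        ]
        std_rows = species_areas[species_areas["species"] == std_id]
        for (method, replicate), group in class_species.groupby(
            ["method", "replicate"]
        ):
            std = std_rows[
                (std_rows["method"] == method) & (std_rows["replicate"] == replicate)
            ]["area"]
            if std.empty or (std <= 0).any():
                raise SolvselectError(
                    f"standard {std_id!r} for class {lipid_class!r} has no positive "
                    f"area in (method={method!r}, replicate={replicate!r})"
                )
            value = float((group["area"] / float(std.iloc[0])).sum())
            rows.append(
                {
                    "lipid_class": lipid_class,
                    "method": method,
                    "replicate": replicate,
                    "value": value,
                }
            )
    return pd.DataFrame(rows, columns=["lipid_class", "method", "replicate", "value"]), excluded


def assign_tier(
    p_value: float | None,
    tiers: Sequence[tuple[float, str]] = DEFAULT_TIERS,
) -> str:
    """Map a p-value to its star tier ('ns' when no threshold is met)."""
    if p_value is None or not math.isfinite(p_value):
        return "not-assessable"
    for threshold, label in sorted(tiers):
        if p_value < threshold:
            return label
    return "ns"


def fold_change(
    norm: pd.DataFrame,
    method: str,
    reference: str,
    tiers: Sequence[tuple[float, str]] = DEFAULT_TIERS,
    equal_var: bool = True,
) -> list[FoldChangeResult]:
    """Per-class fold change of *method* vs *reference* with significance tier.

    ``fold_change = mean(method class sums) / mean(reference class sums)``;
    the SD propagates both group CVs to first order, and the p-value comes
    from a two-sided two-sample t-test on the replicate class sums (classical
    Student by default, Welch with ``equal_var=False``).  Classes with fewer
    than two replicates in either group skip the test (tier
    ``not-assessable``).
    """
    for column in ("lipid_class", "method", "replicate", "value"):
        if column not in norm.columns:
            raise SchemaError(f"normalized class table missing column {column!r}")
    results: list[FoldChangeResult] = []
    for lipid_class in sorted(set(norm["lipid_class"])):
        block = norm[norm["lipid_class"] == lipid_class]
        a = block[block["method"] == method]["value"].to_numpy(dtype=float)
        b = block[block["method"] == reference]["value"].to_numpy(dtype=float)
        if a.size == 0 or b.size == 0:
            raise IncompleteDesignError(
                f"class {lipid_class!r} lacks replicates for "
                f"{method!r} or {reference!r}"
            )
        fc = float(a.mean() / b.mean())
        cv_a = a.std(ddof=1) / a.mean() if a.size > 1 else 0.0
        cv_b = b.std(ddof=1) / b.mean() if b.size > 1 else 0.0
        sd = fc * math.sqrt(cv_a**2 + cv_b**2)
        if a.size >= 2 and b.size >= 2:
            if method == reference:
                p_value = 1.0
            elif (
                a.std(ddof=1) <= 1e-12 * abs(a.mean())
                and b.std(ddof=1) <= 1e-12 * abs(b.mean())
            ):
                # degenerate noiseless groups: identical means are a null result
                p_value = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
            else:
                p_value = float(
                    stats.ttest_ind(a, b, equal_var=equal_var).pvalue
                )
            tier = assign_tier(p_value, tiers)
        else:
            p_value, tier = None, "not-assessable"
        results.append(
            FoldChangeResult(
                lipid_class=lipid_class,
                method=method,
                reference=reference,
                fold_change=fc,
                sd=sd,
                p_value=p_value,
                tier=tier,
                n_method=int(a.size),
                n_reference=int(b.size),
            )
        )
    return results
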