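"""Bundled benchmark data for the chloroform-substitution case study.

Four small curated tables ship with the package:

* Hansen parameters (handbook values, MPa^0.5) for chloroform and the
  solvents whose published screening distances they reproduce exactly;
* classical Abraham solute descriptors (E, S, A, B, V) for chloroform and a
  few close analogues;
* the published HSP/ASP top-12 screening shortlists for chloroform
  replacement, with their Ra / mean-|Δ| scores;
* per-lipid spike recoveries (mean ± SD, percent) for a deuterated standard
  mixture extracted with chloroform and candidate replacement solvents,
  without (``equisplash``) and with (``plasma``) a plasma matrix.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .abraham import AbrahamDescriptors
from .hansen import HansenParameters
from .recovery import RecoveryResult

__all__ = [
    "load_hansen_reference",
    "load_abraham_reference",
    "load_screening_shortlists",
    "load_equisplash_recoveries",
    "load_plasma_recoveries",
    "recoveries_as_results",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("solvselect.data").joinpath(name).open("r") as handle:
        return pd.read_csv(handle)


def load_hansen_reference() -> dict[str, HansenParameters]:
    """Handbook Hansen parameters keyed by solvent name."""
    df = _read("hansen_reference.csv")
    return {
        row.name: HansenParameters(row.delta_d, row.delta_p, row.delta_h)
        for row in df.itertuples(index=False)
    }


def load_abraham_reference() -> dict[str, AbrahamDescriptors]:
    """Classical Abraham solute descriptors keyed by solvent name."""
    df = _read("abraham_reference.csv")
    return {
        row["name"]: AbrahamDescriptors(
            {s: float(row[s]) for s in ("E", "S", "A", "B", "V")}
        )
        for _, row in df.iterrows()
    }


def load_screening_shortlists() -> pd.DataFrame:
    """Published top-12 shortlists: columns ``model`` (hsp/asp), ``rank``,
    ``name``, ``score`` (Ra for hsp, mean |Δ| for asp)."""
    return _read("screening_shortlists.csv")


def load_equisplash_recoveries() -> pd.DataFrame:
    """Per-lipid recoveries (%) of an equimolar deuterated standard mixture
    under chloroform, five candidate solvents and two negative controls."""
    return _read("equisplash_recoveries.csv")


def load_plasma_recoveries() -> pd.DataFrame:
    """Per-lipid recoveries (%) of a plasma-ratio standard mixture spiked
    into human plasma, across two-phase and one-phase extraction protocols."""
    return _read("plasma_recoveries.csv")


def recoveries_as_results(table: pd.DataFrame) -> list[RecoveryResult]:
    """Adapt a recovery table to :class:`RecoveryResult` objects so the
    summary statistics can run on bundled data."""
    return [
        RecoveryResult(
            lipid_id=row.lipid_id,
            method=row.method,
            recovery_pct=float(row.recovery_pct),
            dispersion_pct=float(row.sd_pct),
            n_pre=3,
            n_post=3,
        )
        for row in table.itertuples(index=False)
    ]
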