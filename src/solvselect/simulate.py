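"""Synthetic-data generators with known ground truth for the whole pipeline.

Two generators cover the two kinds of input the pipeline consumes:

* :func:`simulate_catalog` builds a solvent catalog with a planted low-rank
  descriptor structure (scores x orthonormal loadings plus Gaussian noise),
  a Hansen-space cluster of configurable radius around a chloroform-like
  reference, Abraham descriptors correlated with cluster membership,
  uniform-at-random missing descriptor cells, and a hazard-class /
  boiling-point composition tuned so that the default filter retains a
  prescribed number of solvents.  The returned ground truth (cluster
  membership, latent scores, survivor list) supports exact assertions.

* :func:`simulate_peak_areas` builds spike pre-/post-extraction peak-area
  tables with prescribed true recoveries and an endogenous species table
  with prescribed class-level fold changes versus a reference method.  Noise
  is multiplicative log-normal — peak areas are positive and MS intensity
  noise scales with signal — with ``cv`` as the standard deviation of the
  linearized log-scale factor.  In the noiseless limit every planted
  parameter is recovered exactly by the downstream analytics.

Both generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abraham import AbrahamDescriptors
from .catalog import (
    Catalog,
    HazardClass,
    SolventFlags,
    SolventRecord,
)
from .hansen import HansenParameters

__all__ = [
    "CatalogSimSpec",
    "CatalogGroundTruth",
    "RecoverySimSpec",
    "SimulatedAreas",
    "DEFAULT_LIPID_PANEL",
    "simulate_catalog",
    "simulate_peak_areas",
]

_CHLOROFORM_HANSEN = (17.8, 3.1, 5.7)
_CHLOROFORM_ABRAHAM = {"E": 0.425, "S": 0.49, "A": 0.15, "B": 0.02, "V": 0.6167}

#: Deuterated standard panel emulating an equimolar spike mixture:
#: one labelled species per major lipid class.
DEFAULT_LIPID_PANEL: tuple[tuple[str, str], ...] = (
    ("LPC 18:1-d7", "LPC"),
    ("LPE 18:1-d7", "LPE"),
    ("PC 15:0_18:1-d7", "PC"),
    ("PE 15:0_18:1-d7", "PE"),
    ("PI 15:0_18:1-d7", "PI"),
    ("PS 15:0_18:1-d7", "PS"),
    ("PG 15:0_18:1-d7", "PG"),
    ("SM 18:1-d9", "SM"),
    ("Cer 18:1-d7", "Cer"),
    ("MG 18:1-d7", "MG"),
    ("DG 15:0_18:1-d7", "DG"),
    ("TG 15:0_18:1-d7", "TG"),
    ("CE 18:1-d7", "CE"),
)


@dataclass(frozen=True)
class CatalogSimSpec:
    """Conditions for one synthetic solvent catalog.

    Defaults emulate the screening study's input: 272 solvents, 29
    physicochemical descriptors, a filter composition retaining 83, and a
    shortlist-sized Hansen cluster within Ra 5 of the chloroform-like
    reference.
    """

    n_solvents: int = 272
    n_descriptors: int = 29
    n_latent: int = 2
    reference_cluster_size: int = 12
    cluster_radius: float = 5.0
    missing_fraction: float = 0.05
    seed: int = 0
    noise_sd: float = 0.05
    n_pass_filter: int = 83
    reference_name: str = "chloroform"

    def __post_init__(self) -> None:
        if self.n_latent > self.n_descriptors:
            raise ValueError("n_latent cannot exceed n_descriptors")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.reference_cluster_size + 1 > self.n_pass_filter:
            raise ValueError("cluster plus reference cannot exceed the survivor count")
        if self.n_pass_filter > self.n_solvents:
            raise ValueError("n_pass_filter cannot exceed n_solvents")
        if self.cluster_radius <= 0 or self.noise_sd < 0:
            raise ValueError("cluster_radius must be > 0 and noise_sd >= 0")


@dataclass(frozen=True)
class CatalogGroundTruth:
    reference_name: str
    cluster_members: tuple[str, ...]
    surviving_names: tuple[str, ...]
    latent_scores: pd.DataFrame
    latent_loadings: np.ndarray
    hansen_distances: Mapping[str, float]


def _hansen_offset(rng: np.random.Generator, ra: float) -> np.ndarray:
    """A random offset at exact Hansen distance *ra* with nonnegative result."""
    for _ in range(1000):
        g = rng.standard_normal(3)
        norm = np.sqrt(4 * g[0] ** 2 + g[1] ** 2 + g[2] ** 2)
        offset = g / norm * ra
        candidate = np.array(_CHLOROFORM_HANSEN) + offset
        if (candidate >= 0).all():
            return offset
    raise RuntimeError("could not draw a nonnegative Hansen parameter set")


def simulate_catalog(spec: CatalogSimSpec) -> tuple[Catalog, CatalogGroundTruth]:
    """Generate a catalog plus the ground truth needed for assertions."""
    rng = np.random.default_rng(spec.seed)
    n, p, k = spec.n_solvents, spec.n_descriptors, spec.n_latent
    names = [spec.reference_name] + [f"solvent_{i:03d}" for i in range(1, n)]
    schema = [f"desc_{j:02d}" for j in range(1, p + 1)]

    # --- Hansen cluster ------------------------------------------------
    cluster = names[1 : spec.reference_cluster_size + 1]
    hansen: dict[str, HansenParameters] = {
        spec.reference_name: HansenParameters(*_CHLOROFORM_HANSEN)
    }
    distances: dict[str, float] = {spec.reference_name: 0.0}
    for name in names[1:]:
        if name in cluster:
            ra = rng.uniform(0.3, 0.95 * spec.cluster_radius)
        else:
            ra = rng.uniform(1.2 * spec.cluster_radius, 4.0 * spec.cluster_radius)
        offset = _hansen_offset(rng, ra)
        hansen[name] = HansenParameters(*(np.array(_CHLOROFORM_HANSEN) + offset))
        distances[name] = float(ra)

    # --- Abraham descriptors correlated with the Hansen cluster --------
    abraham: dict[str, AbrahamDescriptors] = {}
    for name in names:
        scale = 0.02 + 0.02 * distances[name]  # similar solvents stay similar
        values = {
            s: max(v + rng.uniform(-scale, scale), 1e-3 if s == "V" else -10.0)
            for s, v in _CHLOROFORM_ABRAHAM.items()
        }
        abraham[name] = AbrahamDescriptors(values)

    # --- planted low-rank descriptor block ------------------------------
    # latent axis 1 separates the reference cluster from the rest; the
    # remaining axes carry decreasing variance
    scores = np.zeros((n, k))
    for i, name in enumerate(names):
        if name == spec.reference_name:
            scores[i, 0] = 0.0
        elif name in cluster:
            scores[i, 0] = rng.uniform(-0.4, 0.4)
        else:
            scores[i, 0] = rng.choice([-1.0, 1.0]) * rng.uniform(1.5, 4.0)
    for j in range(1, k):
        scores[:, j] = rng.normal(0.0, 1.5 * 0.6 ** (j - 1), size=n)
    loadings, _ = np.linalg.qr(rng.standard_normal((p, k)))
    loadings = loadings.T  # k x p, orthonormal rows
    block = scores @ loadings
    if spec.noise_sd > 0:
        block = block + rng.normal(0.0, spec.noise_sd, size=block.shape)

    # --- missingness, uniform at random ---------------------------------
    if spec.missing_fraction > 0:
        mask = rng.random(block.shape) < spec.missing_fraction
        for i in range(n):  # keep every row and column observable
            if mask[i].all():
                mask[i, rng.integers(p)] = False
        for j in range(p):
            observed = ~mask[:, j]
            if observed.sum() < 2:
                unmask = rng.choice(n, size=2, replace=False)
                mask[unmask, j] = False
        block = np.where(mask, np.nan, block)

    # --- hazard / boiling-point composition -----------------------------
    survivors = set(names[: spec.n_pass_filter])
    hazard: dict[str, HazardClass] = {}
    bp: dict[str, float] = {}
    failure_modes = rng.integers(0, 3, size=n)
    for i, name in enumerate(names):
        if name == spec.reference_name:
            # chloroform-like: hazardous but retained via the exception list
            hazard[name] = HazardClass.HAZARDOUS
            bp[name] = 61.2
        elif name in survivors:
            hazard[name] = (
                HazardClass.RECOMMENDED if rng.random() < 0.5 else HazardClass.PROBLEMATIC
            )
            bp[name] = float(rng.uniform(35.0, 120.0))
        else:
            mode = failure_modes[i]
            if mode == 0:  # hazardous, volatile
                hazard[name] = HazardClass.HAZARDOUS
                bp[name] = float(rng.uniform(35.0, 120.0))
            elif mode == 1:  # benign but high-boiling
                hazard[name] = (
                    HazardClass.RECOMMENDED
                    if rng.random() < 0.5
                    else HazardClass.PROBLEMATIC
                )
                bp[name] = float(rng.uniform(126.0, 250.0))
            else:  # fails both rules
                hazard[name] = HazardClass.HAZARDOUS
                bp[name] = float(rng.uniform(126.0, 250.0))

    records = []
    for i, name in enumerate(names):
        records.append(
            SolventRecord(
                name=name,
                hazard_class=hazard[name],
                boiling_point=bp[name],
                hansen=hansen[name],
                abraham=abraham[name],
                descriptors=dict(zip(schema, block[i])),
                flags=SolventFlags(
                    aromatic=bool(rng.random() < 0.15),
                    chlorinated=(name == spec.reference_name or bool(rng.random() < 0.1)),
                    commercially_available=bool(rng.random() < 0.95),
                ),
            )
        )
    catalog = Catalog(records, descriptor_schema=schema)
    truth = CatalogGroundTruth(
        reference_name=spec.reference_name,
        cluster_members=tuple(cluster),
        surviving_names=tuple(names[: spec.n_pass_filter]),
        latent_scores=pd.DataFrame(
            scores, index=names, columns=[f"latent_{j + 1}" for j in range(k)]
        ),
        latent_loadings=loadings,
        hansen_distances=distances,
    )
    return catalog, truth


@dataclass(frozen=True)
class RecoverySimSpec:
    """Conditions for one synthetic spike-recovery experiment.

    Defaults mirror a standard-mixture spike design: a 13-standard panel,
    triplicate pre- and post-extraction spikes, 5 % multiplicative noise.
    ``true_recovery`` may be a scalar (applied to every lipid/method) or a
    map keyed by ``(lipid_id, method)``; ``class_effect`` maps
    ``(lipid_class, method)`` to the fold change versus the reference method
    (the reference is pinned at 1).
    """

    lipids: tuple[tuple[str, str], ...] = DEFAULT_LIPID_PANEL
    methods: tuple[str, ...] = ("folch_chcl3", "mmc_cpme")
    reference_method: str = "folch_chcl3"
    true_recovery: float | Mapping[tuple[str, str], float] = 95.0
    class_effect: Mapping[tuple[str, str], float] = field(default_factory=dict)
    cv: float = 0.05
    n_replicates: int = 3
    n_species_per_class: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.reference_method not in self.methods:
            raise ValueError("reference_method must be one of methods")
        recoveries = (
            [self.true_recovery]
            if isinstance(self.true_recovery, (int, float))
            else list(dict(self.true_recovery).values())
        )
        if any(r <= 0 for r in recoveries):
            raise ValueError("true recoveries must be positive")

    def recovery_of(self, lipid_id: str, method: str) -> float:
        if isinstance(self.true_recovery, (int, float)):
            return float(self.true_recovery)
        return float(dict(self.true_recovery)[(lipid_id, method)])

    def effect_of(self, lipid_class: str, method: str) -> float:
        if method == self.reference_method:
            return 1.0
        return float(dict(self.class_effect).get((lipid_class, method), 1.0))


@dataclass(frozen=True)
class SimulatedAreas:
    """Generator output: spike areas, endogenous species areas, standards map."""

    areas: pd.DataFrame
    species: pd.DataFrame
    standards: Mapping[str, str]
    spec: RecoverySimSpec


def _noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    return np.exp(cv * rng.standard_normal(size))


def simulate_peak_areas(spec: RecoverySimSpec) -> SimulatedAreas:
    """Generate spike pre-/post-extraction areas and an endogenous species table."""
    rng = np.random.default_rng(spec.seed)
    baselines = {
        lipid_id: float(rng.uniform(5e5, 5e6)) for lipid_id, _ in spec.lipids
    }

    area_rows: list[dict[str, object]] = []
    for lipid_id, _ in spec.lipids:
        for method in spec.methods:
            base = baselines[lipid_id]
            recovery = spec.recovery_of(lipid_id, method)
            post = base * _noise(rng, spec.cv, spec.n_replicates)
            pre = base * recovery / 100.0 * _noise(rng, spec.cv, spec.n_replicates)
            for r in range(spec.n_replicates):
                area_rows.append(
                    {
                        "lipid_id": lipid_id,
                        "method": method,
                        "replicate": r + 1,
                        "spike_timing": "post",
                        "area": post[r],
                    }
                )
                area_rows.append(
                    {
                        "lipid_id": lipid_id,
                        "method": method,
                        "replicate": r + 1,
                        "spike_timing": "pre",
                        "area": pre[r],
                    }
                )
    areas = pd.DataFrame(area_rows)

    classes = sorted({lipid_class for _, lipid_class in spec.lipids})
    standards = {c: f"IS_{c}" for c in classes}
    species_base = {
        (c, s): float(rng.uniform(1e5, 1e6))
        for c in classes
        for s in range(spec.n_species_per_class)
    }
    standard_base = {c: float(rng.uniform(5e5, 2e6)) for c in classes}

    species_rows: list[dict[str, object]] = []
    for c in classes:
        for method in spec.methods:
            effect = spec.effect_of(c, method)
            for r in range(spec.n_replicates):
                std_area = standard_base[c] * _noise(rng, spec.cv, 1)[0]
                species_rows.append(
                    {
                        "species": standards[c],
                        "lipid_class": c,
                        "method": method,
                        "replicate": r + 1,
                        "area": std_area,
                    }
                )
                for s in range(spec.n_species_per_class):
                    species_rows.append(
                        {
                            "species": f"{c}_species_{s + 1}",
                            "lipid_class": c,
                            "method": method,
                            "replicate": r + 1,
                            "area": species_base[(c, s)]
                            * effect
                            * _noise(rng, spec.cv, 1)[0],
                        }
                    )
    species = pd.DataFrame(species_rows)
    return SimulatedAreas(areas=areas, species=species, standards=standards, spec=spec)
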