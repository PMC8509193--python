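"""Synthetic-data generators standing in for external dependencies.

Two generators are provided:

* :func:`make_sobp_scoring` emits a parametric spread-out-Bragg-peak (SOBP)
  particle-scoring file of the kind a transport code would produce: an
  entrance channel below the prescription dose, a flat SOBP, a decaying
  fragment-only tail, per-species dose fractions and LET ramps. The shapes
  are openly invented; only their bookkeeping invariants matter to the RBE
  engine.
* :func:`make_pseudo_experiment` runs the aberration simulator at a known
  ground-truth lesion yield and writes an experimental-style dose-response
  TSV plus a sidecar recording the truth, for calibration-recovery tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .calibration import IonCategory
from .config import SimulationConfig
from .database import CategoryTable, DicentricDatabase, PhotonReference
from .mc import DoseResponseCurve, simulate_dose_response
from .mixed_field import Contribution, VoxelDeposition

# fragment species produced by a carbon beam, with nominal LETs [keV/um]
# and shares of the non-carbon dose; the photon/electron share rides along
_FRAGMENT_SPECIES: tuple[tuple[int, float, float], ...] = (
    (1, 2.5, 0.45),  # H
    (2, 10.0, 0.28),  # He
    (3, 16.0, 0.08),  # Li
    (4, 21.0, 0.05),  # Be
    (5, 26.0, 0.08),  # B
    (0, 0.0, 0.06),  # photons / electrons
)


@dataclass(frozen=True)
class SOBPSpec:
    """Parametric carbon-beam SOBP scenario."""

    depth_min_mm: float = 0.0
    depth_max_mm: float = 200.0
    step_mm: float = 1.0
    proximal_mm: float = 60.0
    distal_mm: float = 110.0
    dose_gy: float = 2.0  # prescribed uniform SOBP dose
    opposed_beams: bool = False
    entrance_fraction: float = 0.55  # entrance dose / prescription at surface
    tail_fraction: float = 0.15  # tail dose / prescription just past distal edge
    tail_decay_mm: float = 30.0
    carbon_let_entrance: float = 13.0  # keV/um at the surface
    carbon_let_distal: float = 80.0  # keV/um at the distal edge
    carbon_fraction_entrance: float = 0.95
    carbon_fraction_distal: float = 0.70
    noise_rel: float = 0.0  # optional seeded multiplicative dose jitter

    def __post_init__(self) -> None:
        if self.distal_mm <= self.proximal_mm:
            raise ValueError("distal edge must exceed proximal edge")
        if self.distal_mm > self.depth_max_mm:
            raise ValueError("distal edge beyond the scored depth range")
        if self.dose_gy <= 0:
            raise ValueError("prescription dose must be positive")
        if not (0 < self.entrance_fraction < 1):
            raise ValueError("entrance_fraction must be in (0, 1)")
        if self.tail_fraction <= 0:
            raise ValueError("fragment tail must carry dose")

    @property
    def depths_mm(self) -> np.ndarray:
        """Voxel-centre depths."""
        edges = np.arange(self.depth_min_mm, self.depth_max_mm, self.step_mm)
        return edges + 0.5 * self.step_mm


@dataclass(frozen=True)
class PseudoExperimentSpec:
    """Ground-truth configuration for an emulated literature curve."""

    category: IonCategory
    let_kev_um: float
    true_cl_per_um: float
    doses_gy: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
    n_cells: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses_gy, dtype=float)
        if doses.size == 0 or np.any(doses <= 0) or np.any(doses > 3.0):
            raise ValueError("doses must lie in (0, 3] Gy")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.let_kev_um <= 0:
            raise ValueError("LET must be positive")
        if self.true_cl_per_um < 0:
            raise ValueError("true yield must be non-negative")


def _total_dose(spec: SOBPSpec, depth: float) -> float:
    """Analytic mono-directional depth-dose profile [Gy]."""
    p = spec.dose_gy
    if depth < spec.proximal_mm:
        # slow quadratic rise through the entrance channel
        x = depth / spec.proximal_mm
        top = 0.98  # just below prescription at the proximal edge
        return p * (spec.entrance_fraction + (top - spec.entrance_fraction) * x**2)
    if depth <= spec.distal_mm:
        return p
    return p * spec.tail_fraction * math.exp(-(depth - spec.distal_mm) / spec.tail_decay_mm)


def _carbon_fraction(spec: SOBPSpec, depth: float) -> float:
    """Primary-carbon dose fraction; zero beyond the distal edge."""
    if depth > spec.distal_mm:
        return 0.0
    x = depth / spec.distal_mm
    return spec.carbon_fraction_entrance + (
        spec.carbon_fraction_distal - spec.carbon_fraction_entrance
    ) * x


def _carbon_let(spec: SOBPSpec, depth: float) -> float:
    """Primary-carbon LET ramp, accelerating toward the distal edge."""
    x = min(depth / spec.distal_mm, 1.0)
    return spec.carbon_let_entrance + (
        spec.carbon_let_distal - spec.carbon_let_entrance
    ) * x**2


def _beam_contributions(spec: SOBPSpec, depth: float, noise: float) -> list[Contribution]:
    total = _total_dose(spec, depth) * (1.0 + noise)
    if total <= 0:
        return []
    f_carbon = _carbon_fraction(spec, depth)
    # fragment LETs soften slowly with depth past the distal edge
    soften = 1.0 / (1.0 + max(depth - spec.distal_mm, 0.0) / 400.0)
    contribs = []
    if f_carbon > 0:
        contribs.append(Contribution(6, _carbon_let(spec, depth), total * f_carbon))
    rest = total * (1.0 - f_carbon)
    for z, let, share in _FRAGMENT_SPECIES:
        contribs.append(Contribution(z, let * soften if z > 0 else 0.0, rest * share))
    return contribs


def make_sobp_scoring(
    spec: SOBPSpec, seed: int = 0, path: str | Path | None = None
) -> list[VoxelDeposition]:
    """Generate per-voxel scoring for the SOBP scenario; optionally write TSV.

    The opposed-beams case sums a half-weight beam with its exact mirror
    about the depth midplane, so the combined depth-dose profile is
    symmetric by construction. Deterministic given ``seed``.
    """
    depths = spec.depths_mm
    rng = np.random.default_rng(seed)
    noise = (
        rng.normal(0.0, spec.noise_rel, size=depths.size)
        if spec.noise_rel > 0
        else np.zeros(depths.size)
    )
    midplane = 0.5 * (spec.depth_min_mm + spec.depth_max_mm)
    voxels: list[VoxelDeposition] = []
    for i, depth in enumerate(depths):
        if spec.opposed_beams:
            half = SOBPSpec(**{**asdict(spec), "dose_gy": spec.dose_gy / 2.0,
                               "opposed_beams": False})
            mirrored = 2.0 * midplane - depth
            contribs = _beam_contributions(half, depth, noise[i])
            contribs += _beam_contributions(half, mirrored, noise[depths.size - 1 - i])
        else:
            contribs = _beam_contributions(spec, depth, noise[i])
        voxels.append(VoxelDeposition(float(depth), 0.0, tuple(contribs)))
    if path is not None:
        write_scoring(voxels, path, metadata={
            "generator": "sobp",
            "seed": seed,
            "dose_gy": spec.dose_gy,
            "proximal_mm": spec.proximal_mm,
            "distal_mm": spec.distal_mm,
            "opposed_beams": spec.opposed_beams,
        })
    return voxels


def write_scoring(
    voxels: list[VoxelDeposition], path: str | Path, metadata: dict | None = None
) -> None:
    lines = [f"# {k} = {v}" for k, v in (metadata or {}).items()]
    lines.append("voxel_depth_mm\tvoxel_radial_mm\tZ\tLET_keV_um\tdose_Gy")
    for voxel in voxels:
        for c in voxel.contributions:
            lines.append(
                f"{voxel.depth_mm:.17g}\t{voxel.radial_mm:.17g}\t{c.z}\t"
                f"{c.let_kev_um:.17g}\t{c.dose_gy:.17g}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def make_pseudo_experiment(
    spec: PseudoExperimentSpec,
    sim_config: SimulationConfig | None = None,
    path: str | Path | None = None,
) -> tuple[DoseResponseCurve, dict]:
    """Emulate a literature dose-response curve from a known ground truth.

    Returns the simulated curve and a ground-truth record; when ``path`` is
    given the curve is written as TSV and the record as a JSON sidecar next
    to it.
    """
    config = sim_config or SimulationConfig()
    curve = simulate_dose_response(
        cl_yield=spec.true_cl_per_um,
        doses_gy=spec.doses_gy,
        n_cells=spec.n_cells,
        seed=spec.seed,
        config=config,
        let_kev_um=spec.let_kev_um,
    )
    truth = {
        "category": IonCategory(spec.category).value,
        "let_kev_um": spec.let_kev_um,
        "true_cl_per_um": spec.true_cl_per_um,
        "n_cells": spec.n_cells,
        "seed": spec.seed,
        "config_hash": config.config_hash(),
    }
    metadata = dict(curve.metadata)
    metadata.update(
        {"ion_category": IonCategory(spec.category).value, "let_kev_um": spec.let_kev_um}
    )
    curve = DoseResponseCurve(
        curve.doses_gy, curve.yields, curve.stderr, curve.n_cells, metadata
    )
    if path is not None:
        curve.write_tsv(path)
        sidecar = Path(path).with_suffix(".truth.json")
        sidecar.write_text(json.dumps(truth, indent=2) + "\n")
    return curve, truth


def make_second_endpoint_table(
    db: DicentricDatabase,
    alpha_x: float = 0.159,
    beta_x: float = 0.0795,
    alpha_let_scale: float = 40.0,
) -> DicentricDatabase:
    """Synthetic survival-like endpoint table sharing the dicentric LET grids.

    The photon reference defaults to alpha/beta = 2 Gy and the per-node
    alpha grows linearly with LET, mimicking the qualitatively different
    dose dependence of a cell-death endpoint. Purely a test fixture.
    """
    tables = {}
    for category, table in db.tables.items():
        alphas = alpha_x * (1.0 + table.lets / alpha_let_scale)
        betas = np.full_like(table.lets, beta_x)
        tables[category] = CategoryTable(table.lets.copy(), alphas, betas)
    metadata = dict(db.metadata)
    metadata["endpoint"] = "synthetic-survival"
    return DicentricDatabase(
        tables=tables,
        photon=PhotonReference(alpha_x, beta_x),
        metadata=metadata,
    )
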