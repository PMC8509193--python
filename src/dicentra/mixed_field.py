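"""Per-voxel mixed-field dicentric coefficients, photon-equivalent dose and RBE.

Each scored voxel carries dose contributions from several particle species;
its effective linear-quadratic coefficients are the dose-weighted means of
the per-species coefficients (Theory of Dual Radiation Action closure). The
photon-equivalent dose D_X inverts the photon LQ at the voxel's total yield
and RBE = D_X / D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .database import DicentricDatabase, PhotonReference, lookup

SCORING_COLUMNS = ("voxel_depth_mm", "voxel_radial_mm", "Z", "LET_keV_um", "dose_Gy")

PROFILE_COLUMNS = (
    "depth_mm",
    "dose_Gy",
    "alpha_bar",
    "beta_bar",
    "yield",
    "D_X_Gy",
    "RBE",
    "RBE_weighted_dose_Gy",
    "endpoint",
)


@dataclass(frozen=True)
class Contribution:
    """Dose deposited in a voxel by one particle species at one LET."""

    z: int  # atomic number; 0 for photons/electrons
    let_kev_um: float
    dose_gy: float

    def __post_init__(self) -> None:
        if self.z < 0:
            raise ValueError(f"unknown Z {self.z}")
        if self.dose_gy < 0:
            raise ValueError(f"negative dose {self.dose_gy}")
        if self.z > 0 and self.let_kev_um <= 0:
            raise ValueError(f"ion contribution needs positive LET, got {self.let_kev_um}")


@dataclass(frozen=True)
class VoxelDeposition:
    """All dose contributions scored in one voxel."""

    depth_mm: float
    radial_mm: float
    contributions: tuple[Contribution, ...]

    @property
    def total_dose_gy(self) -> float:
        return sum(c.dose_gy for c in self.contributions)


@dataclass(frozen=True)
class MixedCoefficients:
    """Dose-weighted mean LQ coefficients of a mixed field."""

    alpha_bar: float
    beta_bar: float


@dataclass(frozen=True)
class VoxelRBEResult:
    """RBE bookkeeping for one voxel; RBE fields are None at zero dose."""

    depth_mm: float
    dose_gy: float
    alpha_bar: float | None
    beta_bar: float | None
    yield_per_cell: float | None
    d_x_gy: float | None
    rbe: float | None

    @property
    def rbe_weighted_dose_gy(self) -> float | None:
        if self.rbe is None:
            return None
        return self.rbe * self.dose_gy


def read_scoring(path: str | Path) -> list[VoxelDeposition]:
    """Parse a scoring TSV into per-voxel depositions, grouped by voxel id.

    Malformed rows (missing columns, negative dose, negative Z) raise with
    their line number.
    """
    voxels: dict[tuple[float, float], list[Contribution]] = {}
    header: list[str] | None = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split("\t")
        if header is None:
            header = parts
            missing = set(SCORING_COLUMNS) - set(parts)
            if missing:
                raise ValueError(f"{path}:{lineno}: missing columns {sorted(missing)}")
            continue
        if len(parts) < len(SCORING_COLUMNS):
            raise ValueError(f"{path}:{lineno}: expected {len(SCORING_COLUMNS)} columns")
        row = dict(zip(header, parts))
        try:
            depth = float(row["voxel_depth_mm"])
            radial = float(row["voxel_radial_mm"])
            z = int(row["Z"])
            let = float(row["LET_keV_um"])
            dose = float(row["dose_Gy"])
            contribution = Contribution(z, let, dose)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        voxels.setdefault((depth, radial), []).append(contribution)
    return [
        VoxelDeposition(depth, radial, tuple(contribs))
        for (depth, radial), contribs in sorted(voxels.items())
    ]


def collapse_radial(voxels: Sequence[VoxelDeposition]) -> list[VoxelDeposition]:
    """Sum contributions over the radial index, keeping one voxel per depth."""
    by_depth: dict[float, list[Contribution]] = {}
    for voxel in voxels:
        by_depth.setdefault(voxel.depth_mm, []).extend(voxel.contributions)
    return [
        VoxelDeposition(depth, 0.0, tuple(contribs))
        for depth, contribs in sorted(by_depth.items())
    ]


def average_coefficients(
    voxel: VoxelDeposition, db: DicentricDatabase
) -> MixedCoefficients:
    """Dose-weighted mean alpha and beta over the voxel's contributions."""
    total = voxel.total_dose_gy
    if total <= 0:
        raise ValueError("mixed-field average undefined for zero total dose")
    alpha_bar = 0.0
    beta_bar = 0.0
    for c in voxel.contributions:
        lq = lookup(db, c.z, c.let_kev_um if c.z > 0 else None)
        alpha_bar += lq.alpha * c.dose_gy
        beta_bar += lq.beta * c.dose_gy
    return MixedCoefficients(alpha_bar / total, beta_bar / total)


def photon_equivalent_dose(yield_per_cell: float, ref: PhotonReference) -> float:
    """Photon dose producing the same dicentric yield.

    D_X = (-alpha_X + sqrt(alpha_X^2 + 4 beta_X Y)) / (2 beta_X); the
    beta_X = 0 case reduces to the linear limit Y / alpha_X.
    """
    if yield_per_cell < 0:
        raise ValueError(f"yield must be non-negative, got {yield_per_cell}")
    if ref.beta_x == 0.0:
        return yield_per_cell / ref.alpha_x
    disc = ref.alpha_x**2 + 4.0 * ref.beta_x * yield_per_cell
    return (-ref.alpha_x + math.sqrt(disc)) / (2.0 * ref.beta_x)


def voxel_rbe(
    voxel: VoxelDeposition,
    db: DicentricDatabase,
    ref: PhotonReference | None = None,
) -> VoxelRBEResult:
    """Yield, photon-equivalent dose and RBE for one voxel.

    Zero-dose voxels yield a flagged result with absent (None) RBE fields
    rather than zeros.
    """
    dose = voxel.total_dose_gy
    if dose <= 0:
        return VoxelRBEResult(voxel.depth_mm, dose, None, None, None, None, None)
    reference = db.photon if ref is None else ref
    mixed = average_coefficients(voxel, db)
    y = mixed.alpha_bar * dose + mixed.beta_bar * dose**2
    d_x = photon_equivalent_dose(y, reference)
    return VoxelRBEResult(
        depth_mm=voxel.depth_mm,
        dose_gy=dose,
        alpha_bar=mixed.alpha_bar,
        beta_bar=mixed.beta_bar,
        yield_per_cell=y,
        d_x_gy=d_x,
        rbe=d_x / dose,
    )


def profile(
    voxels: Sequence[VoxelDeposition],
    db: DicentricDatabase,
    endpoint2: DicentricDatabase | None = None,
    endpoint_names: tuple[str, str] = ("dicentrics", "endpoint2"),
    radial: bool = False,
) -> pd.DataFrame:
    """Depth-ordered RBE table, one row per voxel per endpoint.

    The radial dimension is collapsed onto the axis unless ``radial`` is
    set. A second endpoint database adds a second block of rows sharing the
    absorbed-dose column.
    """
    if not radial:
        voxels = collapse_radial(voxels)
    ids = [(v.depth_mm, v.radial_mm) for v in voxels]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate voxel ids: {dupes}")
    voxels = sorted(voxels, key=lambda v: (v.depth_mm, v.radial_mm))

    endpoints: list[tuple[str, DicentricDatabase]] = [(endpoint_names[0], db)]
    if endpoint2 is not None:
        endpoints.append((endpoint_names[1], endpoint2))

    records = []
    for name, table in endpoints:
        for voxel in voxels:
            result = voxel_rbe(voxel, table)
            records.append(
                {
                    "depth_mm": result.depth_mm,
                    "dose_Gy": result.dose_gy,
                    "alpha_bar": result.alpha_bar,
                    "beta_bar": result.beta_bar,
                    "yield": result.yield_per_cell,
                    "D_X_Gy": result.d_x_gy,
                    "RBE": result.rbe,
                    "RBE_weighted_dose_Gy": result.rbe_weighted_dose_gy,
                    "endpoint": name,
                }
            )
    return pd.DataFrame.from_records(records, columns=list(PROFILE_COLUMNS))


def write_profile(
    table: pd.DataFrame, path: str | Path, metadata: dict | None = None
) -> None:
    """Write a profile TSV with optional '#' metadata header lines."""
    with open(path, "w") as handle:
        for key, value in (metadata or {}).items():
            handle.write(f"# {key} = {value}\n")
        table.to_csv(handle, sep="\t", index=False, float_format="%.12g", na_rep="nan")
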