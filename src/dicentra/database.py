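"""Radiobiological database: linear-quadratic dicentric coefficients per
ion category and LET, with photon reference, lookup rules and TSV I/O.

Lookup maps atomic number to category (Z=1 proton; Z=2,3 helium; Z>=4
heavy; Z=0 the photon reference), interpolates linearly in LET inside the
category grid and clamps to the nearest edge outside it — in particular the
high-LET behaviour is the plateau given by the last grid entry.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .calibration import (
    CATEGORY_LET_BOUNDS,
    CLYieldModel,
    IonCategory,
    predict_cl_yield,
)
from .config import SimulationConfig
from .mc import DoseResponseCurve, simulate_dose_response

logger = logging.getLogger(__name__)

DB_FORMAT_VERSION = "1"

#: Default dose grid [Gy] used when simulating curves for database rows.
DEFAULT_DB_DOSES = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)


@dataclass(frozen=True)
class LQCoefficients:
    """Linear-quadratic coefficients of Y(D) = alpha*D + beta*D^2."""

    alpha: float  # Gy^-1
    beta: float  # Gy^-2

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError(f"LQ coefficients must be non-negative, got {self}")

    def yield_at(self, dose_gy: float) -> float:
        return self.alpha * dose_gy + self.beta * dose_gy**2


@dataclass(frozen=True)
class PhotonReference:
    """Photon dicentric dose-response coefficients (Cs-137 defaults)."""

    alpha_x: float = 0.020  # Gy^-1
    beta_x: float = 0.047  # Gy^-2

    def __post_init__(self) -> None:
        if self.alpha_x < 0 or self.beta_x < 0:
            raise ValueError("photon coefficients must be non-negative")
        if self.alpha_x == 0 and self.beta_x == 0:
            raise ValueError("photon reference must have alpha_x > 0 or beta_x > 0")

    def yield_at(self, dose_gy: float) -> float:
        return self.alpha_x * dose_gy + self.beta_x * dose_gy**2

    def as_lq(self) -> LQCoefficients:
        return LQCoefficients(self.alpha_x, self.beta_x)


@dataclass(frozen=True)
class CategoryTable:
    """Strictly increasing LET grid with LQ coefficients at each node."""

    lets: np.ndarray
    alphas: np.ndarray
    betas: np.ndarray

    def __post_init__(self) -> None:
        lets = np.asarray(self.lets, dtype=float)
        if lets.size == 0:
            raise ValueError("empty category grid")
        if np.any(np.diff(lets) <= 0):
            raise ValueError("LET grid must be strictly increasing")
        alphas = np.asarray(self.alphas, dtype=float)
        betas = np.asarray(self.betas, dtype=float)
        if alphas.shape != lets.shape or betas.shape != lets.shape:
            raise ValueError("grid arrays must have matching shapes")
        if np.any(alphas < 0) or np.any(betas < 0):
            raise ValueError("LQ coefficients must be non-negative")
        object.__setattr__(self, "lets", lets)
        object.__setattr__(self, "alphas", alphas)
        object.__setattr__(self, "betas", betas)


@dataclass(frozen=True)
class DicentricDatabase:
    """Per-category LQ tables plus the photon reference and provenance."""

    tables: Mapping[IonCategory, CategoryTable]
    photon: PhotonReference
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for category, table in self.tables.items():
            lo, hi = CATEGORY_LET_BOUNDS[IonCategory(category)]
            if table.lets.min() < lo or table.lets.max() > hi:
                raise ValueError(
                    f"{IonCategory(category).value} grid must lie within "
                    f"[{lo}, {hi}] keV/um"
                )


def default_let_grid(category: IonCategory, step: float = 2.5) -> np.ndarray:
    """Evenly spaced LET grid spanning the category interval."""
    lo, hi = CATEGORY_LET_BOUNDS[IonCategory(category)]
    n = int(round((hi - lo) / step)) + 1
    return np.linspace(lo, hi, n)


def fit_lq(curve: DoseResponseCurve) -> LQCoefficients:
    """Weighted zero-intercept least squares of Y on (D, D^2).

    Weights are 1/sigma^2 when every point carries a positive standard
    error, unit otherwise. Negative fitted coefficients are clipped to zero
    with a warning.
    """
    mask = curve.doses_gy > 0
    doses = curve.doses_gy[mask]
    ys = curve.yields[mask]
    if doses.size < 2:
        raise ValueError("LQ fit needs >= 2 nonzero-dose points")
    if np.unique(doses).size < 2:
        raise ValueError("singular design: all doses equal")
    stderr = curve.stderr[mask]
    if np.all(np.isfinite(stderr)) and np.all(stderr > 0):
        w = 1.0 / stderr
    else:
        w = np.ones_like(doses)
    design = np.column_stack([doses, doses**2]) * w[:, None]
    coef, *_ = np.linalg.lstsq(design, ys * w, rcond=None)
    alpha, beta = (float(c) for c in coef)
    if alpha < 0 or beta < 0:
        warnings.warn(
            f"negative LQ coefficient clipped to zero (alpha={alpha:.4g}, "
            f"beta={beta:.4g})",
            stacklevel=2,
        )
        alpha, beta = max(alpha, 0.0), max(beta, 0.0)
    return LQCoefficients(alpha, beta)


def build_database(
    cl_models: Mapping[IonCategory, CLYieldModel],
    grids: Mapping[IonCategory, Sequence[float]],
    sim_config: SimulationConfig,
    n_cells: int = 2000,
    seed: int = 0,
    doses_gy: Sequence[float] = DEFAULT_DB_DOSES,
) -> DicentricDatabase:
    """Simulate and LQ-fit a dose-response curve for every grid node.

    Each (category, LET) node gets its lesion yield from the category's
    fitted yield law, a simulated curve at ``doses_gy``, and a zero-intercept
    LQ fit. Deterministic given ``seed``.
    """
    tables: dict[IonCategory, CategoryTable] = {}
    for category in sorted(grids, key=lambda c: IonCategory(c).value):
        category = IonCategory(category)
        lets = np.asarray(sorted(grids[category]), dtype=float)
        lo, hi = CATEGORY_LET_BOUNDS[category]
        if lets.min() < lo or lets.max() > hi:
            raise ValueError(
                f"{category.value} grid outside bounds [{lo}, {hi}] keV/um"
            )
        model = cl_models[category]
        category_key = zlib.crc32(category.value.encode())
        child = np.random.SeedSequence((seed, category_key))
        node_seeds = child.generate_state(lets.size)
        alphas = np.empty(lets.size)
        betas = np.empty(lets.size)
        for i, let in enumerate(lets):
            cl = predict_cl_yield(model, float(let))
            curve = simulate_dose_response(
                cl_yield=cl,
                doses_gy=doses_gy,
                n_cells=n_cells,
                seed=int(node_seeds[i]),
                config=sim_config,
                let_kev_um=float(let),
            )
            lq = fit_lq(curve)
            alphas[i], betas[i] = lq.alpha, lq.beta
            logger.info(
                "db node %s LET=%.3g: cl=%.4g alpha=%.4g beta=%.4g",
                category.value, let, cl, lq.alpha, lq.beta,
            )
        tables[category] = CategoryTable(lets, alphas, betas)
    photon = PhotonReference(sim_config.photon_alpha, sim_config.photon_beta)
    metadata = {
        "format_version": DB_FORMAT_VERSION,
        "seed": seed,
        "n_cells": n_cells,
        "config_hash": sim_config.config_hash(),
        "doses_gy": ",".join(f"{d:g}" for d in doses_gy),
        "r0_um": sim_config.r0_um,
        "c_free": sim_config.c_free,
        "radius_um": sim_config.radius_um,
    }
    return DicentricDatabase(tables=tables, photon=photon, metadata=metadata)


def lookup(db: DicentricDatabase, z: int, let_kev_um: float | None = None) -> LQCoefficients:
    """Coefficients for a particle of atomic number ``z`` at ``let_kev_um``.

    Z = 0 selects the photon reference. LET outside the category grid is
    clamped to the nearest edge (high-LET plateau).
    """
    if z < 0:
        raise ValueError(f"atomic number must be >= 0, got {z}")
    if z == 0:
        return db.photon.as_lq()
    if let_kev_um is None or let_kev_um <= 0:
        raise ValueError(f"LET must be positive for ions, got {let_kev_um}")
    category = IonCategory.from_z(z)
    table = db.tables.get(category)
    if table is None:
        raise KeyError(f"database has no {category.value} table")
    alpha = float(np.interp(let_kev_um, table.lets, table.alphas))
    beta = float(np.interp(let_kev_um, table.lets, table.betas))
    return LQCoefficients(alpha, beta)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_db(db: DicentricDatabase, path: str | Path) -> None:
    """Lossless TSV serialization with '#' metadata header lines."""
    lines = [f"# {k} = {v}" for k, v in db.metadata.items()]
    lines.append("category\tLET_keV_um\talpha_Gy-1\tbeta_Gy-2")
    lines.append(f"photon\t-\t{db.photon.alpha_x:.17g}\t{db.photon.beta_x:.17g}")
    for category in sorted(db.tables, key=lambda c: IonCategory(c).value):
        table = db.tables[category]
        for let, alpha, beta in zip(table.lets, table.alphas, table.betas):
            lines.append(
                f"{IonCategory(category).value}\t{let:.17g}\t{alpha:.17g}\t{beta:.17g}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_db(path: str | Path) -> DicentricDatabase:
    """Parse a database TSV; malformed content raises with the line number."""
    metadata: dict = {}
    photon: PhotonReference | None = None
    rows: dict[IonCategory, list[tuple[float, float, float]]] = {}
    header_seen = False
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            if "=" in stripped:
                key, _, value = stripped[1:].partition("=")
                metadata[key.strip()] = value.strip()
            continue
        if not header_seen:
            header_seen = True
            columns = stripped.split("\t")
            if len(columns) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns in header")
            continue
        parts = stripped.split("\t")
        if len(parts) < 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns")
        name = parts[0]
        if name == "photon":
            photon = PhotonReference(float(parts[2]), float(parts[3]))
            continue
        try:
            category = IonCategory(name)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: unknown category {name!r}") from exc
        let, alpha, beta = float(parts[1]), float(parts[2]), float(parts[3])
        bucket = rows.setdefault(category, [])
        if bucket and let <= bucket[-1][0]:
            raise ValueError(
                f"{path}:{lineno}: LET grid not strictly increasing "
                f"({let} after {bucket[-1][0]})"
            )
        bucket.append((let, alpha, beta))
    if photon is None:
        raise ValueError(f"{path}: photon reference row required")
    tables = {
        category: CategoryTable(*map(np.array, zip(*bucket)))
        for category, bucket in rows.items()
    }
    return DicentricDatabase(tables=tables, photon=photon, metadata=metadata)
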