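"""Critical-lesion yield calibration and its LET dependence per ion category.

The per-micrometre lesion yield is the simulator's adjustable parameter.
It is calibrated against an observed dicentric dose-response curve by
golden-section search on an error-weighted least-squares objective, then its
LET dependence is fitted per ion category: a through-origin linear law for
helium, through-origin linear-quadratic for protons and heavy ions, with
high-LET points excluded above a per-category threshold (113 keV/um for
helium, 155 keV/um for heavy ions) because observed yields there fall below
the threshold yield and would bias the fit low.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .config import SimulationConfig
from .mc import DoseResponseCurve, simulate_dose_response

logger = logging.getLogger(__name__)


class IonCategory(str, Enum):
    """Ion category used for yield fitting and database rows."""

    PROTON = "proton"
    HELIUM = "helium"
    HEAVY = "heavy"

    @classmethod
    def from_z(cls, z: int) -> "IonCategory":
        """Map atomic number to category: Z=1 proton, Z in {2,3} helium
        (Li borrows He coefficients), Z >= 4 heavy (Be and B borrow the
        heavy-ion coefficients; 'heavy' proper is Z >= 6)."""
        if z < 1:
            raise ValueError(f"atomic number must be >= 1, got {z}")
        if z == 1:
            return cls.PROTON
        if z in (2, 3):
            return cls.HELIUM
        return cls.HEAVY


#: LET interval [keV/um] covered by each category's database grid.
CATEGORY_LET_BOUNDS: dict[IonCategory, tuple[float, float]] = {
    IonCategory.PROTON: (2.5, 30.0),
    IonCategory.HELIUM: (5.0, 110.0),
    IonCategory.HEAVY: (5.0, 150.0),
}

#: Yield points above these LETs [keV/um] are excluded from the category fit.
EXCLUSION_THRESHOLDS: dict[IonCategory, float] = {
    IonCategory.PROTON: math.inf,
    IonCategory.HELIUM: 113.0,
    IonCategory.HEAVY: 155.0,
}

#: Functional form of the yield-vs-LET fit per category.
CATEGORY_FORMS: dict[IonCategory, str] = {
    IonCategory.PROTON: "linear_quadratic",
    IonCategory.HELIUM: "linear",
    IonCategory.HEAVY: "linear_quadratic",
}


@dataclass(frozen=True)
class CLYieldPoint:
    """One calibrated lesion yield at a given LET."""

    category: IonCategory
    let_kev_um: float
    cl_per_um: float
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.let_kev_um <= 0:
            raise ValueError(f"LET must be positive, got {self.let_kev_um}")
        if self.cl_per_um < 0:
            raise ValueError(f"cl_per_um must be non-negative, got {self.cl_per_um}")


@dataclass(frozen=True)
class CLYieldModel:
    """Through-origin lesion-yield law y(L) = c1*L [+ c2*L^2] per category."""

    category: IonCategory
    form: str  # "linear" or "linear_quadratic"
    c1: float  # CLs/um per keV/um
    c2: float  # CLs/um per (keV/um)^2, zero for the linear form
    let_max: float  # upper edge of the valid LET range; plateau beyond
    exclusion_threshold: float

    def __post_init__(self) -> None:
        if self.form not in ("linear", "linear_quadratic"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.form == "linear" and self.c2 != 0.0:
            raise ValueError("linear form must have c2 = 0")
        if self.let_max <= 0:
            raise ValueError("let_max must be positive")

    def _evaluate(self, let: float) -> float:
        return self.c1 * let + self.c2 * let * let


@dataclass(frozen=True)
class CalibrationResult:
    """Calibrated yield with the objective value and search diagnostics."""

    cl_per_um: float
    objective: float
    n_evaluations: int
    converged: bool
    warnings: tuple[str, ...] = ()


def fit_cl_vs_let(
    points: Sequence[CLYieldPoint],
    category: IonCategory,
    exclusion_threshold: float | None = None,
    let_max: float | None = None,
) -> CLYieldModel:
    """Least-squares fit of the category's yield-vs-LET law through the origin.

    Points with LET above the category's exclusion threshold are marked
    excluded and dropped before fitting; the rule is idempotent.
    """
    category = IonCategory(category)
    threshold = (
        EXCLUSION_THRESHOLDS[category]
        if exclusion_threshold is None
        else exclusion_threshold
    )
    form = CATEGORY_FORMS[category]
    kept = [p for p in points if p.category == category and p.let_kev_um <= threshold]
    n_params = 1 if form == "linear" else 2
    if len(kept) < n_params:
        raise ValueError(
            f"need >= {n_params} non-excluded {category.value} points, "
            f"got {len(kept)}"
        )
    lets = np.array([p.let_kev_um for p in kept])
    ys = np.array([p.cl_per_um for p in kept])
    if form == "linear":
        c1 = float(lets @ ys / (lets @ lets))
        c2 = 0.0
    else:
        design = np.column_stack([lets, lets**2])
        coef, *_ = np.linalg.lstsq(design, ys, rcond=None)
        c1, c2 = (float(c) for c in coef)
    model = CLYieldModel(
        category=category,
        form=form,
        c1=c1,
        c2=c2,
        let_max=CATEGORY_LET_BOUNDS[category][1] if let_max is None else let_max,
        exclusion_threshold=threshold,
    )
    lo = min(float(lets.min()), CATEGORY_LET_BOUNDS[category][0])
    grid = np.linspace(lo, model.let_max, 64)
    if any(model._evaluate(v) < 0 for v in grid):
        warnings.warn(
            f"{category.value} yield model dips below zero on its valid range",
            stacklevel=2,
        )
    return model


def mark_exclusions(
    points: Sequence[CLYieldPoint], threshold: float | None = None
) -> list[CLYieldPoint]:
    """Return points with ``excluded`` set per the category threshold."""
    out = []
    for p in points:
        thr = EXCLUSION_THRESHOLDS[p.category] if threshold is None else threshold
        out.append(replace(p, excluded=p.let_kev_um > thr))
    return out


def predict_cl_yield(model: CLYieldModel, let_kev_um: float) -> float:
    """Evaluate the fitted yield law; LET above the valid range plateaus at
    the range maximum (conservative high-LET rule)."""
    if let_kev_um <= 0:
        raise ValueError(f"LET must be positive, got {let_kev_um}")
    let = min(let_kev_um, model.let_max)
    return max(model._evaluate(let), 0.0)


def _golden_section(
    objective: Callable[[float], float],
    lo: float,
    hi: float,
    rel_tol: float = 1e-2,
) -> tuple[float, float, int]:
    """Minimise a unimodal scalar function on [lo, hi]; returns (x, f(x), n)."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = objective(c), objective(d)
    n = 2
    while (b - a) > rel_tol * max(abs(a), abs(b), 1e-30):
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = objective(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = objective(d)
        n += 1
    x = c if fc < fd else d
    return x, min(fc, fd), n


def calibrate_cl_yield(
    curve: DoseResponseCurve,
    let_kev_um: float,
    sim_config: SimulationConfig,
    search_bounds: tuple[float, float] = (0.01, 3.0),
    n_cells: int = 2000,
    seed: int = 0,
    rel_tol: float = 1e-2,
    grid_points: int = 12,
) -> CalibrationResult:
    """Adjust the per-micrometre lesion yield to reproduce an observed curve.

    The objective is the error-weighted sum of squared deviations between
    simulated and observed mean yields at the observed (nonzero) doses; each
    objective evaluation reuses the same simulation seed so the search sees
    a deterministic function. If the objective is not unimodal on the
    bounds, a warning is issued and a grid scan picks the best bracket
    before the golden-section refinement.
    """
    lo, hi = search_bounds
    if not (0 < lo < hi):
        raise ValueError(f"search bounds must satisfy 0 < lo < hi, got {search_bounds}")
    mask = curve.doses_gy > 0
    doses = curve.doses_gy[mask]
    observed = curve.yields[mask]
    if doses.size < 2:
        raise ValueError("calibration needs >= 2 nonzero-dose points")
    stderr = curve.stderr[mask]
    if np.all(np.isfinite(stderr)) and np.all(stderr > 0):
        weights = 1.0 / stderr**2
    else:
        # Poisson floor: var(mean) ~ Y / n_cells, guarded away from zero
        n = np.where(curve.n_cells[mask] > 0, curve.n_cells[mask], n_cells)
        weights = n / np.maximum(observed, 1e-3)

    cache: dict[float, float] = {}

    def objective(y: float) -> float:
        if y not in cache:
            sim = simulate_dose_response(
                cl_yield=y,
                doses_gy=doses,
                n_cells=n_cells,
                seed=seed,
                config=sim_config,
                let_kev_um=let_kev_um,
            )
            cache[y] = float(np.sum(weights * (sim.yields - observed) ** 2))
        return cache[y]

    issued: list[str] = []
    f_lo, f_hi = objective(lo), objective(hi)
    mid = 0.5 * (lo + hi)
    f_mid = objective(mid)
    if f_mid >= min(f_lo, f_hi):
        msg = (
            "calibration objective is not unimodal on the search bounds; "
            "falling back to a grid scan"
        )
        warnings.warn(msg, stacklevel=2)
        issued.append(msg)
        grid = np.linspace(lo, hi, grid_points)
        values = [objective(float(g)) for g in grid]
        k = int(np.argmin(values))
        lo = float(grid[max(k - 1, 0)])
        hi = float(grid[min(k + 1, grid_points - 1)])
    x, fx, n_eval = _golden_section(objective, lo, hi, rel_tol=rel_tol)
    logger.info(
        "calibrated cl_per_um=%.4f (objective=%.4g, %d evaluations)", x, fx, n_eval
    )
    return CalibrationResult(
        cl_per_um=x,
        objective=fx,
        n_evaluations=len(cache),
        converged=not issued,
        warnings=tuple(issued),
    )


# ---------------------------------------------------------------------------
# yield-table I/O
# ---------------------------------------------------------------------------


def write_yield_table(points: Sequence[CLYieldPoint], path: str | Path) -> None:
    lines = ["category\tLET_keV_um\tcl_per_um\texcluded"]
    for p in points:
        lines.append(
            f"{p.category.value}\t{p.let_kev_um:.17g}\t{p.cl_per_um:.17g}\t"
            f"{int(p.excluded)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_yield_table(path: str | Path) -> list[CLYieldPoint]:
    points: list[CLYieldPoint] = []
    header_seen = False
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
        excluded = bool(int(parts[3])) if len(parts) > 3 else False
        points.append(
            CLYieldPoint(
                category=IonCategory(parts[0]),
                let_kev_um=float(parts[1]),
                cl_per_um=float(parts[2]),
                excluded=excluded,
            )
        )
    return points
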