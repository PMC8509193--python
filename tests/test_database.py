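"""LQ fitting, database construction, lookup rules and serialization."""

import numpy as np
import pytest

from dicentra import SimulationConfig
from dicentra.calibration import (
    CATEGORY_FORMS,
    CATEGORY_LET_BOUNDS,
    EXCLUSION_THRESHOLDS,
    CLYieldModel,
    IonCategory,
)
from dicentra.database import (
    CategoryTable,
    LQCoefficients,
    PhotonReference,
    build_database,
    default_let_grid,
    fit_lq,
    lookup,
    read_db,
    write_db,
)
from dicentra.mc import DoseResponseCurve


def exact_curve(alpha, beta, doses):
    doses = np.asarray(doses, dtype=float)
    return DoseResponseCurve(
        doses,
        alpha * doses + beta * doses**2,
        np.full(doses.size, np.nan),
        np.zeros(doses.size, dtype=int),
    )


def make_model(category, c1, c2=0.0):
    return CLYieldModel(
        category=category,
        form=CATEGORY_FORMS[category],
        c1=c1,
        c2=c2,
        let_max=CATEGORY_LET_BOUNDS[category][1],
        exclusion_threshold=EXCLUSION_THRESHOLDS[category],
    )


class TestFitLq:
    def test_exact_recovery_of_photon_reference(self):
        curve = exact_curve(0.020, 0.047, np.linspace(0.0, 3.0, 13))
        lq = fit_lq(curve)
        assert lq.alpha == pytest.approx(0.020, abs=1e-9)
        assert lq.beta == pytest.approx(0.047, abs=1e-9)

    def test_stochastic_recovery_from_poisson_counts(self):
        # Poisson-sampled cell counts around a known LQ truth
        alpha, beta, n_cells = 0.05, 0.03, 5000
        rng = np.random.default_rng(99)
        doses = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
        means, errs = [], []
        for d in doses:
            counts = rng.poisson(alpha * d + beta * d**2, size=n_cells)
            means.append(counts.mean())
            errs.append(counts.std(ddof=1) / np.sqrt(n_cells))
        curve = DoseResponseCurve(doses, means, errs, np.full(doses.size, n_cells))
        lq = fit_lq(curve)
        assert lq.alpha == pytest.approx(alpha, rel=0.15)
        assert lq.beta == pytest.approx(beta, rel=0.15)

    def test_singular_design_rejected(self):
        curve = DoseResponseCurve(
            np.array([2.0]), np.array([0.5]), np.array([0.1]), np.array([10])
        )
        with pytest.raises(ValueError):
            fit_lq(curve)
        flat = DoseResponseCurve.__new__(DoseResponseCurve)  # bypass monotone guard
        object.__setattr__(flat, "doses_gy", np.array([2.0, 2.0]))
        object.__setattr__(flat, "yields", np.array([0.5, 0.6]))
        object.__setattr__(flat, "stderr", np.array([0.1, 0.1]))
        object.__setattr__(flat, "n_cells", np.array([10, 10]))
        with pytest.raises(ValueError, match="singular"):
            fit_lq(flat)

    def test_negative_coefficient_clipped_with_warning(self):
        # strongly concave data forces a negative quadratic coefficient
        doses = np.array([0.5, 1.0, 2.0, 3.0])
        curve = DoseResponseCurve(
            doses, np.sqrt(doses), np.full(4, np.nan), np.zeros(4, dtype=int)
        )
        with pytest.warns(UserWarning, match="clipped"):
            lq = fit_lq(curve)
        assert lq.beta == 0.0

    def test_weighted_fit_uses_stderr(self):
        doses = np.array([0.5, 1.0, 2.0, 3.0])
        y = 0.1 * doses + 0.05 * doses**2
        y_perturbed = y.copy()
        y_perturbed[0] += 0.5  # outlier at the low-dose point
        tight = DoseResponseCurve(
            doses, y_perturbed, np.array([1e3, 1e-3, 1e-3, 1e-3]),
            np.full(4, 100),
        )
        lq = fit_lq(tight)  # outlier massively down-weighted
        assert lq.alpha == pytest.approx(0.1, rel=1e-3)
        assert lq.beta == pytest.approx(0.05, rel=1e-3)


@pytest.fixture(scope="module")
def small_db():
    config = SimulationConfig()
    models = {IonCategory.HELIUM: make_model(IonCategory.HELIUM, 0.0012)}
    grids = {IonCategory.HELIUM: [20.0, 60.0]}
    return build_database(models, grids, config, n_cells=1500, seed=11)


class TestBuildDatabase:
    def test_shape(self, small_db):
        table = small_db.tables[IonCategory.HELIUM]
        assert list(table.lets) == [20.0, 60.0]
        assert np.all(np.isfinite(table.alphas))
        assert np.all(table.alphas >= 0) and np.all(table.betas >= 0)

    def test_alpha_increases_with_let(self, small_db):
        table = small_db.tables[IonCategory.HELIUM]
        assert table.alphas[1] > table.alphas[0]

    def test_deterministic_files(self, small_db, tmp_path):
        config = SimulationConfig()
        models = {IonCategory.HELIUM: make_model(IonCategory.HELIUM, 0.0012)}
        grids = {IonCategory.HELIUM: [20.0, 60.0]}
        again = build_database(models, grids, config, n_cells=1500, seed=11)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_db(small_db, p1)
        write_db(again, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_grid_outside_bounds_rejected(self):
        config = SimulationConfig()
        models = {IonCategory.HELIUM: make_model(IonCategory.HELIUM, 0.0012)}
        with pytest.raises(ValueError, match="bounds"):
            build_database(
                models, {IonCategory.HELIUM: [20.0, 150.0]}, config, n_cells=10, seed=1
            )

    def test_default_grid_bounds(self):
        for category in IonCategory:
            grid = default_let_grid(category)
            lo, hi = CATEGORY_LET_BOUNDS[category]
            assert grid[0] == lo and grid[-1] == hi


class TestLookup:
    def test_photon_row(self, toy_db):
        lq = lookup(toy_db, 0)
        assert (lq.alpha, lq.beta) == (0.020, 0.047)

    def test_lithium_borrows_helium(self, toy_db):
        assert lookup(toy_db, 3, 50.0) == lookup(toy_db, 2, 50.0)

    def test_beryllium_and_boron_borrow_heavy(self, toy_db):
        assert lookup(toy_db, 4, 60.0) == lookup(toy_db, 6, 60.0)
        assert lookup(toy_db, 5, 60.0) == lookup(toy_db, 6, 60.0)

    def test_high_let_plateau(self, toy_db):
        assert lookup(toy_db, 2, 200.0) == lookup(toy_db, 2, 110.0)
        assert lookup(toy_db, 6, 300.0) == lookup(toy_db, 6, 150.0)

    def test_below_grid_clamps_to_first_node(self, toy_db):
        assert lookup(toy_db, 6, 1.0) == lookup(toy_db, 6, 5.0)

    def test_exact_node(self, toy_db):
        lq = lookup(toy_db, 6, 80.0)
        assert lq.alpha == pytest.approx(0.30, rel=1e-12)

    def test_interpolation_continuous(self, toy_db):
        lets = np.linspace(5.0, 150.0, 300)
        alphas = np.array([lookup(toy_db, 6, v).alpha for v in lets])
        assert np.all(np.abs(np.diff(alphas)) < 0.01)

    def test_invalid_inputs(self, toy_db):
        with pytest.raises(ValueError):
            lookup(toy_db, -1, 10.0)
        with pytest.raises(ValueError):
            lookup(toy_db, 6, 0.0)


class TestSerialization:
    def test_round_trip_lossless(self, toy_db, tmp_path):
        path = tmp_path / "db.tsv"
        write_db(toy_db, path)
        back = read_db(path)
        assert back.photon == toy_db.photon
        for category, table in toy_db.tables.items():
            np.testing.assert_array_equal(back.tables[category].lets, table.lets)
            np.testing.assert_array_equal(back.tables[category].alphas, table.alphas)
            np.testing.assert_array_equal(back.tables[category].betas, table.betas)
        assert back.metadata["origin"] == "toy"

    def test_decreasing_let_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "category\tLET_keV_um\talpha_Gy-1\tbeta_Gy-2\n"
            "photon\t-\t0.02\t0.047\n"
            "helium\t60\t0.2\t0.03\n"
            "helium\t20\t0.1\t0.03\n"
        )
        with pytest.raises(ValueError, match="increasing"):
            read_db(path)

    def test_missing_photon_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "category\tLET_keV_um\talpha_Gy-1\tbeta_Gy-2\n"
            "helium\t20\t0.1\t0.03\n"
        )
        with pytest.raises(ValueError, match="photon reference"):
            read_db(path)

    def test_missing_column_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "category\tLET_keV_um\talpha_Gy-1\tbeta_Gy-2\n"
            "photon\t-\t0.02\t0.047\n"
            "helium\t20\t0.1\n"
        )
        with pytest.raises(ValueError, match="bad.tsv:3"):
            read_db(path)


class TestInvariantTypes:
    def test_negative_coefficients_rejected(self):
        with pytest.raises(ValueError):
            LQCoefficients(-0.1, 0.05)
        with pytest.raises(ValueError):
            PhotonReference(0.0, 0.0)

    def test_yield_increasing_in_dose(self, toy_db):
        for table in toy_db.tables.values():
            for alpha, beta in zip(table.alphas, table.betas):
                lq = LQCoefficients(alpha, beta)
                doses = np.linspace(0.0, 3.0, 40)
                ys = [lq.yield_at(d) for d in doses]
                assert np.all(np.diff(ys) > 0)
                assert np.all(np.asarray(ys) >= 0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            CategoryTable(np.array([]), np.array([]), np.array([]))
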