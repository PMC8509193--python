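"""Mixed-field averaging, photon-equivalent dose and per-voxel RBE."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dicentra.database import (
    CategoryTable,
    DicentricDatabase,
    PhotonReference,
    lookup,
)
from dicentra.calibration import IonCategory
from dicentra.mixed_field import (
    Contribution,
    VoxelDeposition,
    average_coefficients,
    photon_equivalent_dose,
    profile,
    read_scoring,
    voxel_rbe,
    write_profile,
)


def voxel(*contribs, depth=10.0):
    return VoxelDeposition(depth, 0.0, tuple(Contribution(*c) for c in contribs))


class TestReadScoring:
    def test_groups_by_voxel(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(
            "# test file\n"
            "voxel_depth_mm\tvoxel_radial_mm\tZ\tLET_keV_um\tdose_Gy\n"
            "10\t0\t6\t30\t0.5\n"
            "10\t0\t1\t2\t0.1\n"
        )
        voxels = read_scoring(path)
        assert len(voxels) == 1
        assert voxels[0].total_dose_gy == pytest.approx(0.6)
        assert len(voxels[0].contributions) == 2

    def test_empty_file(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("voxel_depth_mm\tvoxel_radial_mm\tZ\tLET_keV_um\tdose_Gy\n")
        assert read_scoring(path) == []

    def test_negative_dose_rejected_with_line(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(
            "voxel_depth_mm\tvoxel_radial_mm\tZ\tLET_keV_um\tdose_Gy\n"
            "10\t0\t6\t30\t0.5\n"
            "11\t0\t6\t30\t-0.1\n"
        )
        with pytest.raises(ValueError, match="s.tsv:3"):
            read_scoring(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("voxel_depth_mm\tZ\tLET_keV_um\tdose_Gy\n10\t6\t30\t0.5\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_scoring(path)

    def test_negative_z_rejected(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(
            "voxel_depth_mm\tvoxel_radial_mm\tZ\tLET_keV_um\tdose_Gy\n"
            "10\t0\t-2\t30\t0.5\n"
        )
        with pytest.raises(ValueError, match="s.tsv:2"):
            read_scoring(path)


class TestAverageCoefficients:
    def test_single_component_identity(self, toy_db):
        v = voxel((6, 80.0, 1.0))
        mixed = average_coefficients(v, toy_db)
        lq = lookup(toy_db, 6, 80.0)
        assert mixed.alpha_bar == pytest.approx(lq.alpha, rel=1e-12)
        assert mixed.beta_bar == pytest.approx(lq.beta, rel=1e-12)

    def test_equal_doses_average_symmetrically(self, toy_db):
        v = voxel((6, 5.0, 1.0), (6, 150.0, 1.0))
        mixed = average_coefficients(v, toy_db)
        a1 = lookup(toy_db, 6, 5.0).alpha
        a2 = lookup(toy_db, 6, 150.0).alpha
        assert mixed.alpha_bar == pytest.approx(0.5 * (a1 + a2), rel=1e-12)

    def test_hand_computed_weighted_mean(self, toy_db):
        # doses (1, 3) with alphas (0.05, 0.30) at the toy grid nodes
        v = voxel((6, 5.0, 1.0), (6, 80.0, 3.0))
        mixed = average_coefficients(v, toy_db)
        assert mixed.alpha_bar == pytest.approx((0.05 * 1 + 0.30 * 3) / 4, rel=1e-12)

    def test_zero_total_dose_rejected(self, toy_db):
        with pytest.raises(ValueError, match="zero total dose"):
            average_coefficients(voxel((6, 80.0, 0.0)), toy_db)

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from([0, 1, 2, 3, 6, 8]),
                st.floats(min_value=1.0, max_value=300.0),
                st.floats(min_value=1e-6, max_value=5.0),
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_envelope_and_weight_normalization(self, toy_db, components):
        v = voxel(*components)
        mixed = average_coefficients(v, toy_db)
        alphas = [
            lookup(toy_db, z, let if z > 0 else None).alpha for z, let, _ in components
        ]
        betas = [
            lookup(toy_db, z, let if z > 0 else None).beta for z, let, _ in components
        ]
        assert min(alphas) - 1e-12 <= mixed.alpha_bar <= max(alphas) + 1e-12
        assert min(betas) - 1e-12 <= mixed.beta_bar <= max(betas) + 1e-12
        weights = np.array([d for _, _, d in components]) / v.total_dose_gy
        assert weights.sum() == pytest.approx(1.0, abs=1e-12)


class TestPhotonEquivalentDose:
    def test_zero_yield(self):
        assert photon_equivalent_dose(0.0, PhotonReference()) == 0.0

    def test_inverts_forward_evaluation_at_1_and_2_gy(self):
        ref = PhotonReference(0.020, 0.047)
        assert photon_equivalent_dose(ref.yield_at(1.0), ref) == pytest.approx(1.0, rel=1e-12)
        assert photon_equivalent_dose(ref.yield_at(2.0), ref) == pytest.approx(2.0, rel=1e-12)
        # printed-value form: Y(1) = 0.067, Y(2) = 0.228
        assert photon_equivalent_dose(0.067, ref) == pytest.approx(1.000, abs=1e-9)
        assert photon_equivalent_dose(0.228, ref) == pytest.approx(2.000, abs=1e-9)

    def test_linear_limit_when_beta_zero(self):
        ref = PhotonReference(0.05, 0.0)
        assert photon_equivalent_dose(0.25, ref) == pytest.approx(5.0, rel=1e-12)

    def test_negative_yield_rejected(self):
        with pytest.raises(ValueError):
            photon_equivalent_dose(-0.1, PhotonReference())

    @settings(max_examples=300, deadline=None)
    @given(
        st.floats(min_value=1e-4, max_value=1.0),
        st.floats(min_value=1e-4, max_value=1.0),
        st.floats(min_value=0.0, max_value=10.0),
    )
    def test_inversion_identity(self, alpha_x, beta_x, dose):
        ref = PhotonReference(alpha_x, beta_x)
        d = photon_equivalent_dose(ref.yield_at(dose), ref)
        assert d == pytest.approx(dose, rel=1e-10, abs=1e-12)


class TestVoxelRbe:
    def test_pure_photon_field_rbe_one(self, toy_db):
        v = voxel((0, 0.0, 0.4), (0, 0.0, 0.8))
        result = voxel_rbe(v, toy_db)
        assert result.rbe == pytest.approx(1.0, rel=1e-10)
        assert result.rbe_weighted_dose_gy == pytest.approx(1.2, rel=1e-10)

    def test_closed_form_example(self):
        # D = 1 Gy, alpha_bar = 0.06, beta_bar = 0.047 against (0.020, 0.047)
        db = DicentricDatabase(
            tables={
                IonCategory.HEAVY: CategoryTable(
                    np.array([10.0]), np.array([0.06]), np.array([0.047])
                )
            },
            photon=PhotonReference(0.020, 0.047),
        )
        result = voxel_rbe(voxel((6, 10.0, 1.0)), db)
        assert result.yield_per_cell == pytest.approx(0.107, rel=1e-9)
        assert result.d_x_gy == pytest.approx(1.311, abs=5e-4)
        assert result.rbe == pytest.approx(1.311, abs=5e-4)

    def test_zero_dose_flagged_not_zero(self, toy_db):
        result = voxel_rbe(voxel((6, 80.0, 0.0)), toy_db)
        assert result.rbe is None
        assert result.d_x_gy is None
        assert result.rbe_weighted_dose_gy is None

    def test_rbe_increasing_in_alpha_bar(self):
        ref = PhotonReference(0.020, 0.047)
        rbes = []
        for alpha in (0.05, 0.10, 0.20, 0.40):
            db = DicentricDatabase(
                tables={
                    IonCategory.HEAVY: CategoryTable(
                        np.array([10.0]), np.array([alpha]), np.array([0.03])
                    )
                },
                photon=ref,
            )
            rbes.append(voxel_rbe(voxel((6, 10.0, 1.0)), db).rbe)
        assert np.all(np.diff(rbes) > 0)

    def test_low_dose_limit_alpha_ratio(self, toy_db):
        v = voxel((6, 80.0, 1e-6))
        result = voxel_rbe(v, toy_db)
        expected = lookup(toy_db, 6, 80.0).alpha / toy_db.photon.alpha_x
        assert result.rbe == pytest.approx(expected, rel=1e-4)


class TestProfile:
    def test_shape_and_order(self, toy_db):
        voxels = [voxel((6, 50.0, 1.0), depth=float(d)) for d in range(200)]
        table = profile(voxels, toy_db)
        assert len(table) == 200
        assert list(table["endpoint"].unique()) == ["dicentrics"]
        assert np.all(np.diff(table["depth_mm"].to_numpy()) > 0)

    def test_duplicate_voxels_rejected(self, toy_db):
        voxels = [voxel((6, 50.0, 1.0), depth=5.0), voxel((1, 3.0, 0.2), depth=5.0)]
        with pytest.raises(ValueError, match="duplicate"):
            profile(voxels, toy_db, radial=True)

    def test_radial_collapse_merges_contributions(self, toy_db):
        voxels = [
            VoxelDeposition(5.0, 0.0, (Contribution(6, 50.0, 0.5),)),
            VoxelDeposition(5.0, 1.0, (Contribution(6, 50.0, 0.25),)),
        ]
        table = profile(voxels, toy_db)
        assert len(table) == 1
        assert table.loc[0, "dose_Gy"] == pytest.approx(0.75)

    def test_second_endpoint_shares_absorbed_dose(self, toy_db):
        second = DicentricDatabase(
            tables=toy_db.tables, photon=PhotonReference(1.0, 0.5)
        )
        voxels = [voxel((6, 50.0, 1.0), depth=float(d)) for d in range(5)]
        table = profile(voxels, toy_db, endpoint2=second)
        assert len(table) == 10
        a = table[table.endpoint == "dicentrics"]["dose_Gy"].to_numpy()
        b = table[table.endpoint == "endpoint2"]["dose_Gy"].to_numpy()
        np.testing.assert_array_equal(a, b)

    def test_low_vs_high_dose_rbe_ordering_flips_between_endpoints(self):
        # dicentric-like endpoint: photon alpha/beta ~ 0.43 Gy; survival-like
        # endpoint: photon alpha/beta = 2 Gy. The first wins at 0.1 Gy and
        # loses at 4 Gy on the same voxel.
        def single_entry_db(alpha, beta, ref):
            return DicentricDatabase(
                tables={
                    IonCategory.HEAVY: CategoryTable(
                        np.array([80.0]), np.array([alpha]), np.array([beta])
                    )
                },
                photon=ref,
            )

        dic_db = single_entry_db(0.06, 0.047, PhotonReference(0.020, 0.047))
        srv_db = single_entry_db(0.30, 0.0795, PhotonReference(0.159, 0.0795))
        low = voxel((6, 80.0, 0.1))
        high = voxel((6, 80.0, 4.0))
        assert voxel_rbe(low, dic_db).rbe > voxel_rbe(low, srv_db).rbe
        assert voxel_rbe(high, dic_db).rbe < voxel_rbe(high, srv_db).rbe

    def test_deterministic_output_files(self, toy_db, tmp_path):
        voxels = [voxel((6, 50.0, 1.0), depth=float(d)) for d in range(20)]
        table = profile(voxels, toy_db)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_profile(table, p1, metadata={"x": 1})
        write_profile(profile(voxels, toy_db), p2, metadata={"x": 1})
        assert p1.read_bytes() == p2.read_bytes()
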