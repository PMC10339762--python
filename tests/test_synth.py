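"""Binding equilibria, sample/titration simulation and the packaged fixture."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hsqcscreen.synth import (
    DualSchedule,
    FragmentRecord,
    PlexDesign,
    SITE1_RESIDUES,
    SITE2_RESIDUES,
    STYR_HOTSPOTS,
    TitrationSeries,
    dual_species,
    fraction_bound,
    make_ccl28_fixture,
    make_sulfotyrosine_probe,
    read_manifest,
    read_plex_design,
    simulate_dual,
    simulate_sample,
    simulate_titration,
    write_manifest,
    write_plex_design,
)


class TestFractionBound:
    def test_zero_ligand_gives_zero(self):
        assert fraction_bound(50.0, 0.0, 1.0) == 0.0

    def test_saturation_limit(self):
        assert fraction_bound(50.0, 1e4 * 0.85, 0.85) == pytest.approx(1.0, abs=1e-3)

    def test_quadratic_root_hand_value(self):
        # P=0.05 mM, L=0.85 mM, kd=0.85 mM: b=1.75, sqrt(b^2-4PL)=1.700735
        assert fraction_bound(50.0, 0.85, 0.85) == pytest.approx(0.4927, abs=1e-4)

    @given(
        st.floats(1e-3, 50.0),   # L in mM
        st.floats(0.01, 100.0),  # kd in mM
    )
    def test_dilute_limit_matches_langmuir(self, L, kd):
        P_uM = 1e-3 * kd * 1000.0  # P_T = 1e-3 * kd, in uM
        f = fraction_bound(P_uM, L, kd)
        assert f == pytest.approx(L / (L + kd), rel=1e-3)

    @given(st.floats(0.05, 20.0), st.floats(0.05, 20.0))
    def test_monotone_in_ligand_and_kd(self, L, kd):
        assert fraction_bound(50.0, L * 1.1, kd) > fraction_bound(50.0, L, kd)
        assert fraction_bound(50.0, L, kd * 1.1) < fraction_bound(50.0, L, kd)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fraction_bound(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            fraction_bound(50.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            fraction_bound(50.0, np.inf, 1.0)


def _binder(label_shifts, kd=1.0, fid="X1"):
    return FragmentRecord(fid, "lib", "site2_sY_cleft", kd, dmax=label_shifts,
                          truth="specific")


class TestSimulateSample:
    def test_no_fragments_no_noise_reproduces_apo(self, small_assign):
        pl = simulate_sample(small_assign, [], noise_sd=(0, 0), seed=3)
        for peak, entry in zip(pl.peaks, small_assign):
            assert peak.delta_H == entry.delta_H
            assert peak.delta_N == entry.delta_N
            assert peak.label == entry.label

    def test_half_saturation_shift_in_dilute_regime(self, small_assign):
        frag = _binder({"I53": (0.2, 1.0)}, kd=10.0)
        pl = simulate_sample(small_assign, [(frag, 10.0)], protein_conc=0.01,
                             noise_sd=(0, 0), seed=0)
        apo = small_assign["I53"]
        moved = pl.by_label()["I53"]
        f = fraction_bound(0.01, 10.0, 10.0)  # ~0.5 with depletion correction
        assert moved.delta_H - apo.delta_H == pytest.approx(0.2 * f, abs=1e-9)
        assert moved.delta_N - apo.delta_N == pytest.approx(1.0 * f, abs=1e-9)
        assert f == pytest.approx(0.5, abs=1e-3)

    def test_same_seed_identical_output(self, small_assign):
        frag = _binder({"I53": (0.1, 0.5)})
        a = simulate_sample(small_assign, [(frag, 1.0)], seed=11)
        b = simulate_sample(small_assign, [(frag, 1.0)], seed=11)
        assert a.positions().tolist() == b.positions().tolist()

    def test_contributions_of_two_fragments_add(self, small_assign):
        f1 = _binder({"I53": (0.1, 0.0)}, kd=1.0, fid="A")
        f2 = _binder({"I53": (0.05, 0.0)}, kd=2.0, fid="B")
        both = simulate_sample(small_assign, [(f1, 1.0), (f2, 1.0)], noise_sd=(0, 0))
        only1 = simulate_sample(small_assign, [(f1, 1.0)], noise_sd=(0, 0))
        only2 = simulate_sample(small_assign, [(f2, 1.0)], noise_sd=(0, 0))
        apo = small_assign["I53"].delta_H
        d_both = both.by_label()["I53"].delta_H - apo
        d_sum = (only1.by_label()["I53"].delta_H - apo) + (
            only2.by_label()["I53"].delta_H - apo
        )
        assert d_both == pytest.approx(d_sum, abs=1e-12)


class TestSimulateTitration:
    def test_weak_binding_series_is_linear_in_ligand(self, small_assign):
        frag = _binder({"I53": (0.3, 0.0)}, kd=6000.0)  # kd >> max L
        totals = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
        ser = simulate_titration(small_assign, frag, totals, noise_sd=(0, 0))
        apo = small_assign["I53"].delta_H
        shifts = [p.by_label()["I53"].delta_H - apo for p in ser.points]
        slopes = np.diff(shifts) / np.diff(totals)
        assert np.allclose(slopes, slopes[0], rtol=2e-3)

    def test_endpoint_shift_equals_fraction_bound_times_dmax(self, small_assign):
        frag = _binder({"I53": (0.25, 0.0)}, kd=0.85)
        ser = simulate_titration(small_assign, frag, (0, 1, 3, 6), noise_sd=(0, 0))
        apo = small_assign["I53"].delta_H
        shift = ser.points[-1].by_label()["I53"].delta_H - apo
        assert shift / 0.25 == pytest.approx(fraction_bound(50.0, 6.0, 0.85), rel=1e-12)

    def test_empty_ladder_rejected(self, small_assign):
        with pytest.raises(ValueError):
            simulate_titration(small_assign, _binder({"I53": (0.1, 0)}), ())

    def test_first_point_must_be_apo(self, small_assign):
        with pytest.raises(ValueError, match="0 mM"):
            simulate_titration(small_assign, _binder({"I53": (0.1, 0)}), (1.0, 2.0))


class TestDualEquilibria:
    def test_independent_sites_conserve_mass(self):
        s = dual_species(50.0, 3.0, 3.0, 0.85, 6.6, "independent_sites")
        P = 0.05
        assert s["P"] + s["PA"] + s["PB"] + s["PAB"] == pytest.approx(P, rel=1e-10)
        assert s["A_free"] + s["PA"] + s["PAB"] == pytest.approx(3.0, rel=1e-10)
        assert s["B_free"] + s["PB"] + s["PAB"] == pytest.approx(3.0, rel=1e-10)

    def test_independent_occupancy_matches_single_ligand_quadratic(self):
        s = dual_species(50.0, 2.0, 3.0, 0.85, 6.6, "independent_sites")
        assert s["fA"] == pytest.approx(fraction_bound(50.0, 2.0, 0.85), rel=1e-9)
        assert s["fB"] == pytest.approx(fraction_bound(50.0, 3.0, 6.6), rel=1e-9)

    def test_competitive_occupancies_are_suppressed(self):
        solo = fraction_bound(50.0, 2.0, 1.0)
        s = dual_species(50.0, 2.0, 2.0, 1.0, 1.0, "competitive")
        assert s["fA"] < solo and s["fB"] < solo
        assert s["fA"] == pytest.approx(s["fB"], rel=1e-9)
        P = 0.05
        assert s["P"] + s["PA"] + s["PB"] == pytest.approx(P, rel=1e-10)

    def test_fixed_ligand_zero_reduces_to_single_titration(self, small_assign):
        fa = _binder({"I53": (0.2, 0.4)}, kd=1.0, fid="A")
        fb = _binder({"M66": (0.1, -0.5)}, kd=2.0, fid="B")
        sched = DualSchedule(("B", 0.0), "A", [0.0, 1.0, 3.0], "independent_sites")
        dual = simulate_dual(small_assign, fa, fb, sched, noise_sd=(0, 0), seed=5)
        single = simulate_titration(small_assign, fa, (0.0, 1.0, 3.0),
                                    noise_sd=(0, 0), seed=5)
        for dp, sp in zip(dual.points, single.points):
            np.testing.assert_allclose(dp.positions(), sp.positions(), atol=1e-12)

    def test_saturating_independent_sites_sum_both_dmax(self, small_assign):
        fa = _binder({"I53": (0.2, 0.0)}, kd=0.5, fid="A")
        fb = _binder({"I53": (0.1, 0.0)}, kd=0.5, fid="B")
        sched = DualSchedule(("B", 5000.0), "A", [0.0, 5000.0], "independent_sites")
        dual = simulate_dual(small_assign, fa, fb, sched, noise_sd=(0, 0))
        apo = small_assign["I53"].delta_H
        end = dual.points[-1].by_label()["I53"].delta_H
        assert end - apo == pytest.approx(0.3, abs=1e-3)


class TestFixture:
    def test_library_and_hit_counts(self, ccl28_fixture):
        assign, fragments, design = ccl28_fixture
        assert len(fragments) == 2678
        truths = [f.truth for f in fragments]
        assert truths.count("specific") == 13
        assert truths.count("nonspecific") + truths.count("ph") == 12
        assert len(design.assignments) == 224  # ceil(2678 / 12)

    def test_site_ground_truth_split(self, ccl28_fixture):
        _, fragments, _ = ccl28_fixture
        sites = [f.site_label for f in fragments if f.truth == "specific"]
        assert sites.count("site1_Nloop_helix") == 4
        assert sites.count("site2_sY_cleft") == 8
        assert sites.count("both") == 1

    def test_named_residues_present(self, ccl28_fixture):
        assign, _, _ = ccl28_fixture
        for lab in ["C11", "S20", "R21", "L24", "E25", "K49", "R50", "R52",
                    "I53", "C54", "M66", "Q69", "Q69sc", "K83"]:
            assert lab in assign
        assert 70 <= len(assign) <= 80
        his = [e.label for e in assign if e.residue_code == "H"]
        assert len(his) == 3

    def test_fixture_is_deterministic(self):
        a1, f1, d1 = make_ccl28_fixture(7)
        a2, f2, d2 = make_ccl28_fixture(7)
        assert [e.delta_H for e in a1] == [e.delta_H for e in a2]
        assert [(f.fragment_id, f.kd) for f in f1] == [(f.fragment_id, f.kd) for f in f2]
        assert d1.assignments == d2.assignments

    def test_styr_probe_targets_hotspots(self):
        probe = make_sulfotyrosine_probe(1)
        assert STYR_HOTSPOTS <= set(probe.dmax)
        assert probe.kd > 0

    def test_site_definitions_disjoint(self):
        assert not SITE1_RESIDUES & SITE2_RESIDUES

    def test_manifest_and_design_round_trip(self, tmp_path, ccl28_fixture):
        _, fragments, design = ccl28_fixture
        write_manifest(fragments, tmp_path / "m.csv")
        df = read_manifest(tmp_path / "m.csv")
        assert len(df) == 2678
        assert (df["truth"] == "specific").sum() == 13
        write_plex_design(design, tmp_path / "p.csv")
        back = read_plex_design(tmp_path / "p.csv")
        assert back.assignments == design.assignments


class TestDesignValidation:
    def test_fragment_in_two_plexes_rejected(self):
        with pytest.raises(ValueError, match="more than one"):
            PlexDesign({"P1": ["a", "b"], "P2": ["b"]}, plex_size=12)

    def test_oversized_plex_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            PlexDesign({"P1": ["a", "b", "c"]}, plex_size=2)
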