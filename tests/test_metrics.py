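import copy
import logging

import numpy as np
import pytest

from thermodesign import metrics as met
from thermodesign.fixtures import FixtureSpec, build_chain, build_salt_bridge_toy
from thermodesign.structio import ALPHABET, BackboneStructure, ChainRecord
from tests.conftest import (
    apply_rigid,
    brute_force_contact_order,
    brute_force_salt_bridges,
    monte_carlo_sasa,
    rigid_transform,
)


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        for r in (1.52, 1.70, 1.80):
            area = met.sasa_of_spheres(np.zeros((1, 3)), np.array([r]))
            expected = 4 * np.pi * (r + 1.4) ** 2
            assert abs(area[0] - expected) / expected <= 0.01

    def test_free_dipeptide_matches_monte_carlo(self):
        s = build_chain(FixtureSpec(n_res=2, secondary="coil",
                                    sequence="KD", seed=0))
        total = sum(met.per_residue_sasa(s).values())
        oracle = monte_carlo_sasa(s, n_points_total=200_000, seed=1)
        assert abs(total - oracle) / oracle <= 0.02

    def test_total_equals_sum_of_residues(self, helix20):
        per_res = met.per_residue_sasa(helix20)
        coords, radii, _ = met._collect_atoms(helix20)
        total_atoms = met.sasa_of_spheres(coords, radii).sum()
        assert sum(per_res.values()) == pytest.approx(total_atoms, abs=1e-9)

    def test_fully_enclosed_residue_is_buried(self):
        s = build_chain(FixtureSpec(n_res=3, secondary="coil",
                                    sequence="AAA", seed=0))
        center_res = s.chains[0].residues[1]
        centroid = center_res.ca_xyz
        # surround the middle residue with a dense shell of carbon atoms
        shell = met._fibonacci_sphere(500) * 5.5 + centroid
        s.chains[0].residues[0].sidechain_atoms.update(
            {f"C{i}": xyz for i, xyz in enumerate(shell)})
        sasa = met.per_residue_sasa(s)
        assert sasa[1] < 1.0

    def test_classification_boundary(self):
        assert met.classify_surface_core({0: 30.0})[0] == "core"
        assert met.classify_surface_core({0: 30.1})[0] == "surface"

    def test_buried_residue_classified_core(self):
        s = build_chain(FixtureSpec(n_res=3, secondary="coil",
                                    sequence="AAA", seed=0))
        shell = met._fibonacci_sphere(500) * 5.5 + s.chains[0].residues[1].ca_xyz
        s.chains[0].residues[0].sidechain_atoms.update(
            {f"C{i}": xyz for i, xyz in enumerate(shell)})
        region = met.classify_surface_core(met.per_residue_sasa(s))
        assert region[1] == "core"


class TestComposition:
    def test_poly_lysine_strand_is_all_surface_positive(self):
        s = build_chain(FixtureSpec(n_res=10, secondary="strand",
                                    sequence="K" * 10, seed=0))
        table = met.composition([s])
        cls = table.class_frequencies()
        assert cls.loc["positively_charged", "surface"] == pytest.approx(1.0)

    def test_difference_with_itself_is_zero(self, helix20):
        table = met.composition([helix20])
        diff = met.composition_difference(table, table)
        assert np.nanmax(np.abs(diff.to_numpy())) == 0.0

    def test_difference_matches_hand_tally(self):
        a = build_chain(FixtureSpec(n_res=10, secondary="strand",
                                    sequence="K" * 10, seed=0))
        b = build_chain(FixtureSpec(n_res=10, secondary="strand",
                                    sequence="KKKKKDDDDD", seed=0))
        ta, tb = met.composition([a]), met.composition([b])
        # every strand residue of these short chains is solvent exposed
        assert ta.counts["surface"].sum() == 10
        assert tb.counts["surface"].sum() == 10
        diff = met.composition_difference(ta, tb)
        # hand tally: a surface is 100% K; b surface is 50% K, 50% D
        assert diff.loc["positively_charged", "surface"] == pytest.approx(50.0)
        assert diff.loc["negatively_charged", "surface"] == pytest.approx(-50.0)

    def test_frequencies_normalise_per_region(self, helix20):
        table = met.composition([helix20])
        freq = table.frequencies()
        for region in ("surface", "core"):
            if table.counts[region].sum() > 0:
                assert freq[region].sum() == pytest.approx(1.0)

    def test_class_scheme_must_cover_alphabet(self):
        bad = dict(met.DEFAULT_CLASS_SCHEME)
        del bad["A"]
        with pytest.raises(ValueError, match="20"):
            met.validate_class_scheme(bad)


class TestCharge:
    def test_charge_at_isoelectric_point_is_zero(self):
        for seq in ("KDKD", "ACDEFGHIKLMNPQRSTVWY", "KKKKDE"):
            pi = met.isoelectric_point(seq)
            assert abs(met.net_charge(seq, pi)) <= 1e-3

    @pytest.mark.parametrize("seed", range(20))
    def test_net_charge_monotone_decreasing_in_ph(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list(ALPHABET), size=25))
        grid = np.linspace(0.0, 14.0, 57)
        charges = [met.net_charge(seq, ph) for ph in grid]
        assert np.all(np.diff(charges) < 0)

    def test_kdkd_matches_term_by_term_summation(self):
        # independent spreadsheet-style evaluation with the EMBOSS table
        ph = 7.0
        pos = [8.6, 10.8, 10.8]          # N-term + 2x Lys
        neg = [3.6, 3.9, 3.9]            # C-term + 2x Asp
        expected = (sum(10 ** p / (10 ** p + 10 ** ph) for p in pos)
                    - sum(10 ** ph / (10 ** p + 10 ** ph) for p in neg))
        assert met.net_charge("KDKD", ph) == pytest.approx(expected, abs=1e-12)

    def test_ph_limits_count_titratable_groups(self):
        seq = "KRHDEY"  # 3 basic + N-term vs 2 acidic + Y + C-term
        assert met.net_charge(seq, 0.0) == pytest.approx(4.0, abs=1e-2)
        assert met.net_charge(seq, 14.0) == pytest.approx(-4.0, abs=1e-1)

    def test_cys_tyr_titration_flags(self):
        with_cy = met.net_charge("ACY", 12.0)
        model = met.ChargeModel(titrate_cys=False, titrate_tyr=False)
        without = met.net_charge("ACY", 12.0, model)
        assert with_cy < without

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            met.net_charge("", 7.0)


class TestSaltBridges:
    def test_single_pair_at_construction_distance(self):
        toy = build_salt_bridge_toy([("K", "D", 3.5)])
        assert met.count_salt_bridges(toy) == 1

    def test_two_pairs_one_under_cutoff(self, salt_bridge_toy_two_pairs):
        assert met.count_salt_bridges(salt_bridge_toy_two_pairs) == 1
        assert brute_force_salt_bridges(salt_bridge_toy_two_pairs, 4.0) == 1

    def test_no_acidic_residues_no_bridges(self):
        s = build_chain(FixtureSpec(n_res=10, secondary="helix",
                                    sequence="KAKAKAKAKA", seed=0))
        assert met.count_salt_bridges(s) == 0

    @pytest.mark.parametrize("cutoffs", [(3.0, 4.0, 5.5, 8.0)])
    def test_monotone_in_cutoff(self, cutoffs, salt_bridge_toy_two_pairs):
        counts = [met.count_salt_bridges(
            salt_bridge_toy_two_pairs,
            met.MetricsConfig(salt_bridge_cutoff=c)) for c in cutoffs]
        assert counts == sorted(counts)

    def test_cb_proxy_mode_for_backbone_only(self, caplog):
        toy = build_salt_bridge_toy([("K", "D", 3.5)])
        stripped = copy.deepcopy(toy)
        for _, res in stripped.residues():
            res.sidechain_atoms = {}
        from thermodesign.structio import infer_cb
        k_res = next(r for _, r in stripped.residues() if r.aa == "K")
        d_res = next(r for _, r in stripped.residues() if r.aa == "D")
        cb_dist = np.linalg.norm(infer_cb(k_res) - infer_cb(d_res))
        with caplog.at_level(logging.WARNING):
            count_default = met.count_salt_bridges(stripped)
            count_wide = met.count_salt_bridges(
                stripped, met.MetricsConfig(cb_proxy_cutoff=cb_dist + 0.1))
        assert any("CB-proxy" in r.message for r in caplog.records)
        # the pair counts exactly when the proxy cutoff includes its CB-CB
        # distance (6.93 A on this strand geometry)
        assert count_default == (1 if cb_dist <= 6.0 else 0)
        assert count_wide == 1


class TestContactOrder:
    def test_helix_single_separation_case(self, polyala_helix20):
        """With a 5 A cutoff and minimum separation 4, the ideal helix has
        contacts only at |i-j| = 4, so CO = 4 exactly (verified brute
        force)."""
        cfg = met.MetricsConfig(contact_cutoff=5.0, min_seq_separation=4)
        assert brute_force_contact_order(polyala_helix20, 5.0, 4) == 4.0
        assert met.contact_order(polyala_helix20, cfg) == 4.0

    def test_helix_default_config_matches_brute_force(self, polyala_helix20):
        cfg = met.MetricsConfig()
        oracle = brute_force_contact_order(polyala_helix20, 6.0, 3)
        assert met.contact_order(polyala_helix20, cfg) == pytest.approx(oracle)

    def test_extended_strand_has_no_contacts(self, caplog):
        s = build_chain(FixtureSpec(n_res=20, secondary="strand",
                                    sequence="A" * 20, seed=0))
        with caplog.at_level(logging.WARNING):
            co = met.contact_order(s)
        assert co == 0.0
        assert any("no contacts" in r.message for r in caplog.records)

    def test_rigid_motion_invariance(self, polyala_helix20):
        rot, shift = rigid_transform(np.random.default_rng(3))
        moved = apply_rigid(polyala_helix20, rot, shift)
        assert met.contact_order(moved) == pytest.approx(
            met.contact_order(polyala_helix20))


class TestRadiusOfGyration:
    def test_coincident_points_give_zero(self, polyala_helix20):
        s = copy.deepcopy(polyala_helix20)
        for _, res in s.residues():
            res.ca_xyz = np.array([1.0, 2.0, 3.0])
        assert met.radius_of_gyration(s) == 0.0

    def test_points_on_sphere_give_radius(self, polyala_helix20):
        s = copy.deepcopy(polyala_helix20)
        directions = met._fibonacci_sphere(s.n_residues)
        for d, (_, res) in zip(directions, s.residues()):
            res.ca_xyz = 7.5 * d
        # centroid of a fibonacci lattice is ~0, so Rg ~ radius
        assert met.radius_of_gyration(s) == pytest.approx(7.5, abs=0.01)

    def test_matches_direct_formula(self, helix20):
        ca = np.array([r.ca_xyz for _, r in helix20.residues()])
        expected = np.sqrt(np.mean(np.sum((ca - ca.mean(0)) ** 2, axis=1)))
        assert met.radius_of_gyration(helix20) == pytest.approx(expected)

    def test_rigid_motion_invariance(self, helix20):
        rot, shift = rigid_transform(np.random.default_rng(8))
        assert met.radius_of_gyration(apply_rigid(helix20, rot, shift)) == \
            pytest.approx(met.radius_of_gyration(helix20))


class TestAggregateReport:
    def test_median_iqr_of_hand_set(self):
        structures = [build_chain(FixtureSpec(n_res=6 + 2 * i, secondary="helix",
                                              seed=i), id=f"r{i}")
                      for i in range(5)]
        report = met.aggregate_report(structures)
        values = sorted(report.per_structure["radius_of_gyration"])
        assert report.aggregate.loc["radius_of_gyration", "median"] == values[2]
        q1 = np.quantile(values, 0.25)
        q3 = np.quantile(values, 0.75)
        assert report.aggregate.loc["radius_of_gyration", "iqr"] == \
            pytest.approx(q3 - q1)

    def test_single_structure_median_is_value(self, helix20):
        report = met.aggregate_report([helix20])
        assert report.aggregate.loc["net_charge", "median"] == \
            report.per_structure["net_charge"].iloc[0]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            met.aggregate_report([])
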