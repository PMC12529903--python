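"""Aggregation analyses: clustering, hydrogen bonds, steric zipper,
radius of gyration, scaling fits, intersheet spacing, growth curves."""

import numpy as np
import pandas as pd
import pytest

from polyqcg import (BeadKind, ParameterSet, Topology, assign_sheets,
                     average_growth_curves, build_amyloid_stack,
                     build_beta_sheet, build_chain, build_solution,
                     cluster_molecules, count_hbonds, fit_scaling_exponent,
                     growth_curve, hbond_counts_per_residue,
                     intersheet_spacing, merge, radius_of_gyration,
                     zipper_fraction)
from polyqcg.trajectory import Trajectory


def _two_chains_at_gap(params, gap):
    """Two identical Q5 chains whose nearest bead distance equals gap."""
    top1, st1 = build_chain(5, params)
    shifted = st1.positions + np.array([0.0, gap, 0.0])
    return merge([(top1, st1.positions), (top1, shifted)], box=60.0)


class TestClustering:
    @pytest.mark.parametrize("gap,n_expected", [(0.59, 1), (0.61, 2)])
    def test_cutoff_threshold_semantics(self, params, gap, n_expected):
        top, state = _two_chains_at_gap(params, gap)
        labels, sizes = cluster_molecules(top, state.positions, state.box,
                                          cutoff=0.6)
        assert sizes.size == n_expected

    def test_isolated_monomers_form_singleton_clusters(self, params):
        top, state = build_solution(6, 4, 1.0e-4, seed=1, params=params)
        labels, sizes = cluster_molecules(top, state.positions, state.box)
        # dilute box: chains may touch by chance, but labels must cover
        # all molecules and each multi-cluster only joins close pairs
        assert labels.size == 6
        assert sizes.sum() == 6

    def test_labels_match_brute_force_union_find(self, params, rng):
        top, state = build_solution(20, 4, 5.0e-3, seed=7, params=params)
        pos = state.positions + 0.2 * rng.standard_normal(
            state.positions.shape)
        top.place_virtual_sites(pos, params)
        labels, _ = cluster_molecules(top, pos, state.box, cutoff=0.6)

        # oracle: union-find over all massive bead pairs
        parent = list(range(20))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        beads = np.flatnonzero(top.is_massive)
        for a in range(len(beads)):
            for b in range(a + 1, len(beads)):
                d = pos[beads[a]] - pos[beads[b]]
                d -= state.box * np.round(d / state.box)
                if np.linalg.norm(d) <= 0.6:
                    ra, rb = find(top.molecule[beads[a]]), \
                        find(top.molecule[beads[b]])
                    parent[ra] = rb
        oracle = [find(m) for m in range(20)]
        # same partition: equal label <=> equal root
        for i in range(20):
            for j in range(20):
                assert (labels[i] == labels[j]) == \
                    (oracle[i] == oracle[j])

    def test_empty_frame_rejected(self, params):
        top, state = build_chain(3, params)
        with pytest.raises(ValueError):
            cluster_molecules(top, np.empty((0, 3)), 10.0)


class TestHydrogenBonds:
    def test_ideal_sheet_count_matches_enumeration(self, sheet_2x8,
                                                   params):
        top, state = sheet_2x8
        per_mol, pairs = count_hbonds(top, state.positions, state.box)
        hbo = top.indices_of(BeadKind.HBO)
        hbh = top.indices_of(BeadKind.HBH)
        d = np.linalg.norm(state.positions[hbo][:, None]
                           - state.positions[hbh][None, :], axis=2)
        n_ideal = int((d <= 0.12).sum())
        assert len(pairs) == n_ideal
        assert per_mol == pytest.approx(n_ideal / 2)

    def test_dispersed_monomers_have_no_intermolecular_bonds(self, params):
        top, state = build_solution(5, 6, 1.0e-4, seed=2, params=params)
        _, pairs = count_hbonds(top, state.positions, state.box)
        inter = top.molecule[pairs[:, 0]] != top.molecule[pairs[:, 1]]
        assert inter.sum() == 0

    def test_per_residue_count_capped_at_two(self, params, rng):
        """Each residue owns one donor and one acceptor site, so it can
        never take part in more than two bonds."""
        top, state = build_beta_sheet(4, 9, "antiparallel", params)
        pos = state.positions + 0.03 * rng.standard_normal(
            state.positions.shape)
        top.place_virtual_sites(pos, params)
        counts = hbond_counts_per_residue(top, pos, state.box)
        assert counts.max() <= 2

    def test_missing_sites_rejected(self, params):
        top, state = build_chain(4, params)
        bare = Topology(**{**top.__dict__})
        bare.kinds = top.kinds.copy()
        bare.kinds[bare.kinds == BeadKind.HBO] = BeadKind.REF
        with pytest.raises(ValueError, match="HBO"):
            count_hbonds(bare, state.positions, state.box)


class TestZipper:
    def test_interdigitated_stack_flags_interior_residues(self, params):
        top, state = build_amyloid_stack(2, 4, 10, params=params)
        frac, flags = zipper_fraction(top, state.positions, state.box,
                                      params)
        assert frac > 0.3
        assert flags.any()

    def test_single_sheet_has_no_zipper(self, params):
        """The far-distance zipper condition (opposing side chains 1.2-2.5 nm) is unsatisfiable
        without a second sheet."""
        top, state = build_beta_sheet(4, 10, "antiparallel", params)
        frac, _ = zipper_fraction(top, state.positions, state.box, params)
        assert frac == pytest.approx(0.0, abs=1e-12)

    def test_dispersed_monomers_zero_fraction(self, params):
        top, state = build_solution(4, 8, 1.0e-4, seed=5, params=params)
        frac, _ = zipper_fraction(top, state.positions, state.box, params)
        assert frac == 0.0

    def test_single_isolated_chain_zero(self, params):
        top, state = build_chain(12, params)
        frac, _ = zipper_fraction(top, state.positions, state.box, params)
        assert frac == 0.0

    def test_mixed_mode_is_subset_of_all_mode(self, params):
        top, state = build_amyloid_stack(2, 4, 10, params=params)
        frac_all, _ = zipper_fraction(top, state.positions, state.box,
                                      params, mode="all")
        frac_mixed, _ = zipper_fraction(top, state.positions, state.box,
                                        params, mode="mixed")
        assert 0.0 <= frac_mixed <= 1.0
        assert 0.0 <= frac_all <= 1.0


class TestRadiusOfGyration:
    def test_straight_rod_matches_closed_form(self):
        """Uniform rod of m beads, spacing a: R_g^2 = a^2 (m^2-1)/12."""
        m, a = 11, 0.38
        kinds = np.full(m, BeadKind.BB, dtype=np.int8)
        bonds = np.column_stack([np.arange(m - 1), np.arange(1, m)])
        top = Topology(
            kinds=kinds, residue=np.arange(m, dtype=np.int32),
            molecule=np.zeros(m, dtype=np.int32),
            bonds=bonds.astype(np.int32),
            bond_l0=np.full(m - 1, a), bond_k=np.full(m - 1, 1.0),
            angles=np.empty((0, 3), dtype=np.int32),
            angle_theta0=np.empty(0), angle_k=np.empty(0),
            bend_triplets=np.empty((0, 3), dtype=np.int32),
            torsion_quads=np.empty((0, 4), dtype=np.int32),
            vsites=np.empty(0, dtype=np.int32),
            vsite_parents=np.empty((0, 3), dtype=np.int32),
            vsite_coeffs=np.empty((0, 3)), vsite_signs=np.empty(0),
            n_residues=np.array([m], dtype=np.int32))
        pos = np.zeros((m, 3))
        pos[:, 0] = np.arange(m) * a
        rg = radius_of_gyration(top, pos, box=100.0)
        assert rg[0] == pytest.approx(a * np.sqrt((m * m - 1) / 12.0))

    def test_rotation_invariance(self, params, chain6):
        from scipy.spatial.transform import Rotation
        top, state = chain6
        rg0 = radius_of_gyration(top, state.positions, state.box, params)
        R = Rotation.random(random_state=3).as_matrix()
        rg1 = radius_of_gyration(top, state.positions @ R.T, state.box,
                                 params)
        np.testing.assert_allclose(rg0, rg1, atol=1e-10)

    def test_unwraps_across_periodic_boundary(self, params):
        top, state = build_chain(8, params)
        wrapped = state.positions % state.box  # molecule split at boundary
        shifted = state.copy()
        shifted.positions = state.positions - np.array([state.box - 0.5,
                                                        0.0, 0.0])
        rg_ref = radius_of_gyration(top, state.positions, state.box, params)
        rg_wrapped = radius_of_gyration(top, shifted.positions % state.box,
                                        state.box, params)
        np.testing.assert_allclose(rg_wrapped, rg_ref, atol=1e-9)

    def test_broken_molecule_detected(self, params):
        top, state = build_chain(5, params)
        bad = state.positions.copy()
        bad[top.indices_of(BeadKind.BB)[3]:] += 5.0  # tear the chain
        with pytest.raises(ValueError, match="unwrap"):
            radius_of_gyration(top, bad, state.box, params)


class TestScalingExponent:
    def test_noiseless_power_law_recovered_exactly(self):
        n = np.array([10, 20, 40, 80])
        rg = 0.3 * n ** 0.5
        nu, se = fit_scaling_exponent(n, rg)
        assert nu == pytest.approx(0.5, abs=1e-12)

    def test_noisy_power_law_recovered(self):
        rng = np.random.default_rng(0)
        n = np.arange(10, 80, 4)
        rg = 0.3 * n ** 0.6 * (1 + 0.02 * rng.standard_normal(n.size))
        nu, se = fit_scaling_exponent(n, rg)
        assert nu == pytest.approx(0.6, abs=0.02)

    def test_invariant_to_unit_rescaling(self):
        n = np.array([12, 24, 48])
        rg = 0.4 * n ** 0.55
        nu1, _ = fit_scaling_exponent(n, rg)
        nu2, _ = fit_scaling_exponent(n, rg * 10.0)  # nm -> Å
        assert nu1 == pytest.approx(nu2, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_scaling_exponent([10, 20], [1.0, 2.0])
        with pytest.raises(ValueError):
            fit_scaling_exponent([10, 20, -5], [1.0, 2.0, 3.0])


class TestIntersheetSpacing:
    def test_built_stack_spacing_is_construction_identity(self, params):
        top, state = build_amyloid_stack(4, 4, 8, intersheet_spacing=0.82,
                                         params=params)
        sp = intersheet_spacing(top, state.positions, state.box)
        assert sp == pytest.approx(0.82, abs=1e-9)

    def test_hb_connectivity_fallback_groups_strands(self, params):
        top, state = build_beta_sheet(3, 9, "antiparallel", params)
        top.sheet_id = None
        labels = assign_sheets(top, state.positions, state.box)
        assert len(np.unique(labels)) == 1  # one sheet of 3 strands

    def test_fewer_than_two_sheets_rejected(self, params):
        top, state = build_beta_sheet(2, 6, "antiparallel", params)
        top.sheet_id = np.zeros(2, dtype=np.int32)
        with pytest.raises(ValueError):
            intersheet_spacing(top, state.positions, state.box)


class TestGrowthCurve:
    def _static_traj(self, params):
        top, state = build_amyloid_stack(4, 4, 23, params=params)
        traj = Trajectory(box=state.box)
        for t in (0.0, 0.1, 0.2):
            traj.append(t, state.positions)
        return top, traj

    def test_static_seed_run_is_constant_sixteen(self, params):
        top, traj = self._static_traj(params)
        curve = growth_curve(traj, top)
        assert list(curve["largest_cluster"]) == [16, 16, 16]

    def test_replica_average_of_identical_series_is_identity(self, params):
        top, traj = self._static_traj(params)
        c = growth_curve(traj, top)
        avg = average_growth_curves([c, c.copy()])
        np.testing.assert_allclose(avg["largest_cluster"],
                                   c["largest_cluster"])

    def test_analyses_are_pure_functions_of_the_frame(self, params, rng):
        top, state = build_amyloid_stack(2, 3, 8, params=params)
        pos = state.positions + 0.02 * rng.standard_normal(
            state.positions.shape)
        top.place_virtual_sites(pos, params)
        a1 = count_hbonds(top, pos, state.box)[0]
        z1 = zipper_fraction(top, pos, state.box, params)[0]
        a2 = count_hbonds(top, pos, state.box)[0]
        z2 = zipper_fraction(top, pos, state.box, params)[0]
        assert a1 == a2 and z1 == z2
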