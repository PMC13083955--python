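"""Unit and property tests for the coarse-grained model builder."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stigroove as sg
from stigroove.cg_model import (
    DomainAnnotation,
    ValidationError,
    dielectric_constant,
    rescale_buried_lambda,
    topology_from_yaml,
    topology_to_yaml,
)


# ---------------------------------------------------------------------------
# Parameter table
# ---------------------------------------------------------------------------

class TestParameterTable:
    def test_bundled_table_is_valid(self, params):
        assert len(params.table) == 20
        assert ((params.table["lambda"] >= 0) & (params.table["lambda"] <= 1)).all()
        assert (params.table["sigma"] > 0).all()
        assert (params.table["mass"] > 0).all()

    def test_lambda_out_of_range_rejected(self, params, tmp_path):
        df = params.table.reset_index()
        df.loc[df["residue"] == "A", "lambda"] = 1.2
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="lambda"):
            sg.load_parameter_table(path)

    def test_missing_tryptophan_rejected(self, params, tmp_path):
        df = params.table.reset_index()
        path = tmp_path / "missing.csv"
        df[df["residue"] != "W"].to_csv(path, index=False)
        with pytest.raises(ValidationError, match="W"):
            sg.load_parameter_table(path)


# ---------------------------------------------------------------------------
# Charges
# ---------------------------------------------------------------------------

class TestAssignCharges:
    @pytest.mark.parametrize("aa,expected", [("D", -1.0), ("E", -1.0),
                                             ("K", 1.0), ("R", 1.0), ("A", 0.0)])
    def test_fixed_charges(self, aa, expected):
        q = sg.assign_charges(aa * 3, ph=7.0, include_termini=False)
        assert np.allclose(q, expected)

    def test_histidine_henderson_hasselbalch(self):
        q = sg.assign_charges("H", ph=6.8, his_pka=6.0, include_termini=False)
        assert q[0] == pytest.approx(1.0 / (1.0 + 10.0 ** 0.8), abs=1e-12)

    def test_histidine_half_charged_at_pka(self):
        q = sg.assign_charges("H", ph=6.0, his_pka=6.0, include_termini=False)
        assert q[0] == pytest.approx(0.5)

    def test_termini(self):
        q = sg.assign_charges("AAA", ph=7.0, include_termini=True)
        assert q[0] == 1.0 and q[-1] == -1.0 and q[1] == 0.0

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValidationError):
            sg.assign_charges("AXA", ph=7.0)


# ---------------------------------------------------------------------------
# Pair energies
# ---------------------------------------------------------------------------

class TestAhEnergy:
    def test_lambda_one_is_plain_lj(self):
        r = np.linspace(0.4, 1.9, 40)
        sigma, eps = 0.6, 0.8368
        sr6 = (sigma / r) ** 6
        lj = 4 * eps * (sr6 ** 2 - sr6)
        assert np.allclose(sg.ah_energy(r, sigma, 1.0, eps), lj)

    @given(lam=st.floats(0, 1), sigma=st.floats(0.3, 0.8),
           eps=st.floats(0.1, 2.0))
    @settings(max_examples=100, deadline=None)
    def test_continuity_at_branch_point(self, lam, sigma, eps):
        rmin = 2 ** (1 / 6) * sigma
        below = sg.ah_energy(rmin * (1 - 1e-9), sigma, lam, eps)
        above = sg.ah_energy(rmin * (1 + 1e-9), sigma, lam, eps)
        assert below == pytest.approx(-lam * eps, rel=1e-6, abs=1e-9)
        assert above == pytest.approx(below, rel=1e-6, abs=1e-9)

    def test_lambda_zero_kills_attraction(self):
        assert sg.ah_energy(0.9, 0.6, 0.0) == 0.0

    def test_zero_beyond_cutoff(self):
        assert sg.ah_energy(2.5, 0.6, 1.0) == 0.0

    def test_nonpositive_r_rejected(self):
        with pytest.raises(ValidationError):
            sg.ah_energy(0.0, 0.6, 0.5)


class TestDhEnergy:
    def test_zero_charge(self):
        assert sg.dh_energy(1.0, 0.0, 1.0, 0.22, 298.15) == 0.0

    def test_coulomb_limit_at_zero_ionic_strength(self):
        e = sg.dh_energy(1.0, 1.0, 1.0, 0.0, 298.15, dielectric=80.0)
        assert e == pytest.approx(138.935458 / 80.0, rel=1e-6)

    def test_monotone_decreasing_for_like_charges(self):
        r = np.linspace(0.3, 3.9, 100)
        e = sg.dh_energy(r, 1.0, 1.0, 0.22, 298.15)
        assert np.all(np.diff(e) < 0)

    def test_negative_ionic_strength_rejected(self):
        with pytest.raises(ValidationError):
            sg.dh_energy(1.0, 1.0, 1.0, -0.1, 298.15)

    def test_dielectric_relation_near_ambient(self):
        # empirical water permittivity is ~78.4 at 298.15 K
        assert dielectric_constant(298.15) == pytest.approx(78.4, abs=0.5)


# ---------------------------------------------------------------------------
# Topology building
# ---------------------------------------------------------------------------

def _brute_force_enm(coords, groups, cutoff):
    """Independent O(n^2) enumeration of elastic-network pairs."""
    expected = set()
    for indices in groups:
        for a in indices:
            for b in indices:
                if b - a >= 2 and np.linalg.norm(coords[a] - coords[b]) < cutoff:
                    expected.add((a, b))
    return expected


class TestBuildTopology:
    def test_square_domain_restraints(self, params):
        coords = np.array([[0, 0, 0], [0.5, 0, 0], [0.5, 0.5, 0], [0, 0.5, 0.0]])
        topo = sg.build_topology("AAAA", params, coords,
                                 [DomainAnnotation("sq", 1, 4)], enm_cutoff=0.9)
        pairs = {(i, j) for i, j, _, _ in topo.restraints}
        assert pairs == {(0, 2), (1, 3), (0, 3)}

    def test_no_domains_no_restraints(self, params):
        topo = sg.build_topology("AAAA", params)
        assert topo.restraints == []

    def test_zero_cutoff_no_restraints(self, params):
        coords = np.zeros((4, 3)) + np.arange(4)[:, None] * 0.38
        topo = sg.build_topology("AAAA", params, coords,
                                 [DomainAnnotation("d", 1, 4)], enm_cutoff=0.0)
        assert topo.restraints == []

    def test_bonds_connect_consecutive_beads(self, params):
        topo = sg.build_topology("ACDEFG", params)
        assert [(i, j) for i, j, _, _ in topo.bonds] == [(i, i + 1) for i in range(5)]

    def test_domain_beyond_sequence_rejected(self, params):
        with pytest.raises(ValidationError):
            sg.build_topology("AAAA", params, np.zeros((4, 3)),
                              [DomainAnnotation("d", 1, 9)])

    def test_nonfinite_coords_rejected(self, params):
        coords = np.zeros((4, 3))
        coords[2, 1] = np.nan
        with pytest.raises(ValidationError):
            sg.build_topology("AAAA", params, coords, [DomainAnnotation("d", 1, 4)])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_enm_matches_brute_force_on_random_chains(self, params, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 51))
        coords = rng.normal(scale=0.8, size=(n, 3))
        half = n // 2
        domains = [DomainAnnotation("a", 1, half, "g1"),
                   DomainAnnotation("b", half + 1, n, "g2")]
        cutoff = float(rng.uniform(0.5, 1.5))
        topo = sg.build_topology("A" * n, params, coords, domains, enm_cutoff=cutoff)
        pairs = {(i, j) for i, j, _, _ in topo.restraints}
        expected = _brute_force_enm(coords, [range(half), range(half, n)], cutoff)
        assert pairs == expected

    def test_restraint_reference_distances_from_coords(self, params):
        rng = np.random.default_rng(3)
        coords = rng.normal(scale=0.5, size=(10, 3))
        topo = sg.build_topology("A" * 10, params, coords,
                                 [DomainAnnotation("d", 1, 10)], enm_cutoff=1.2)
        for i, j, r0, k in topo.restraints:
            assert r0 == pytest.approx(np.linalg.norm(coords[i] - coords[j]))
            assert k == pytest.approx(700.0)


class TestVariants:
    def test_excluded_volume_zeroes_stickiness_and_charge(self, toy_topology):
        ev = sg.excluded_volume_variant(toy_topology)
        assert np.abs(ev.charges).sum() == 0.0
        assert ev.lambdas.max() == 0.0
        assert ev.restraints == toy_topology.restraints
        assert ev.bonds == toy_topology.bonds

    def test_excluded_volume_idempotent(self, toy_topology):
        ev1 = sg.excluded_volume_variant(toy_topology)
        ev2 = sg.excluded_volume_variant(ev1)
        assert np.array_equal(ev1.lambdas, ev2.lambdas)
        assert np.array_equal(ev1.charges, ev2.charges)
        assert ev1.restraints == ev2.restraints

    def test_keep_charges_flag(self, toy_topology):
        ev = sg.excluded_volume_variant(toy_topology, keep_charges=True)
        assert np.array_equal(ev.charges, toy_topology.charges)


class TestBoundComplexVariant:
    @staticmethod
    def _two_domain_topology(params, separation):
        rng = np.random.default_rng(11)
        blob = rng.normal(scale=0.3, size=(5, 3))
        coords = np.vstack([blob, blob + np.array([separation, 0, 0])])
        domains = [DomainAnnotation("a", 1, 5, "A"), DomainAnnotation("b", 6, 10, "B")]
        return sg.build_topology("A" * 10, params, coords, domains), coords, domains

    def test_far_apart_groups_unchanged(self, params):
        topo, coords, _ = self._two_domain_topology(params, separation=10.0)
        merged = sg.bound_complex_variant(topo, ["A", "B"], coords)
        assert set(map(tuple, merged.restraints)) == set(map(tuple, topo.restraints))

    def test_contact_pose_adds_interdomain_restraints(self, params):
        topo, far_coords, _ = self._two_domain_topology(params, separation=10.0)
        bound = far_coords.copy()
        bound[5:] -= np.array([9.4, 0, 0])   # bring domain B into contact
        merged = sg.bound_complex_variant(topo, ["A", "B"], bound)
        pairs = {(i, j) for i, j, _, _ in merged.restraints}
        expected = _brute_force_enm(bound, [range(10)], 0.9)
        assert pairs == expected
        inter = {(i, j) for i, j in pairs if i < 5 <= j}
        assert inter, "contact pose must create inter-domain restraints"

    def test_intra_restraints_preserved_under_rigid_motion(self, params):
        topo, coords, _ = self._two_domain_topology(params, separation=10.0)
        bound = coords.copy()
        bound[5:] -= np.array([8.0, 0, 0])   # rigid translation of domain B
        merged = sg.bound_complex_variant(topo, ["A", "B"], bound)
        old_pairs = {(i, j) for i, j, _, _ in topo.restraints}
        new_pairs = {(i, j) for i, j, _, _ in merged.restraints}
        assert old_pairs <= new_pairs

    def test_missing_coords_rejected(self, params):
        topo, coords, _ = self._two_domain_topology(params, separation=10.0)
        bad = coords.copy()
        bad[7] = np.nan
        with pytest.raises(ValidationError):
            sg.bound_complex_variant(topo, ["A", "B"], bad)


class TestBuriedRescaling:
    def test_only_buried_domain_residues_scaled(self):
        lambdas = np.full(6, 0.8)
        rsasa = np.array([0.05, 0.5, 0.1, 0.9, 0.05, 0.05])
        out = rescale_buried_lambda(lambdas, rsasa, domain_indices=[0, 1, 2, 3],
                                    buried_rsasa=0.2, buried_scale=0.7)
        assert np.allclose(out, [0.56, 0.8, 0.56, 0.8, 0.8, 0.8])


def test_topology_yaml_roundtrip(tmp_path, toy_topology):
    path = tmp_path / "topo.yaml"
    topology_to_yaml(toy_topology, path)
    loaded = topology_from_yaml(path)
    assert loaded.sequence == toy_topology.sequence
    assert np.allclose(loaded.charges, toy_topology.charges)
    assert loaded.restraints == [tuple(r) for r in toy_topology.restraints]
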