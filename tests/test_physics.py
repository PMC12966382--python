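"""Non-bonded energies: combining rules, switching, oracles, gradients."""

import math

import numpy as np
import pytest

import physdual as pdl
from physdual.errors import ComputationError, InputError
from physdual.ligand import LigandRecord
from physdual.physics import (
    COULOMB_CONSTANT,
    ChargedParticle,
    LJTypeParameters,
    NonbondedConfig,
    MinMaxScaler,
    combine_lj,
    coulomb_energy,
    coulomb_gradient,
    exclusion_pairs,
    fit_minmax,
    gradient_check,
    lj_energy,
    lj_gradient,
    ligand_particles,
    switching_factor,
    switching_derivative,
    total_physical_energy,
)
from physdual.synthetic import make_toy_particles

CFG = NonbondedConfig()


def brute_force_energies(particles, table, config=CFG, exclude=None):
    """Independent per-pair double loop over the defining formulas."""
    e_c = e_l = 0.0
    for i in range(len(particles)):
        for j in range(i + 1, len(particles)):
            if exclude and (i, j) in exclude:
                continue
            a, b = particles[i], particles[j]
            r = math.dist(a.position, b.position)
            if r <= config.r_on:
                s = 1.0
            elif r >= config.r_off:
                s = 0.0
            else:
                ron2, roff2 = config.r_on**2, config.r_off**2
                s = ((roff2 - r * r) ** 2 * (roff2 + 2 * r * r - 3 * ron2)
                     / (roff2 - ron2) ** 3)
            e_c += config.coulomb_constant * a.charge * b.charge / (
                config.dielectric * r
            ) * s
            pa, pb = table[a.lj_type], table[b.lj_type]
            sig = 0.5 * (pa.sigma + pb.sigma)
            eps = math.sqrt(pa.epsilon_well * pb.epsilon_well)
            e_l += 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6) * s
    return e_c, e_l


class TestCombineLJ:
    def test_stated_rule(self):
        c = combine_lj(LJTypeParameters(3.4, 0.1), LJTypeParameters(3.0, 0.4))
        assert c.sigma == pytest.approx(3.2)
        assert c.epsilon_well == pytest.approx(0.2)

    def test_identical_types_unchanged(self):
        p = LJTypeParameters(3.5, 0.25)
        c = combine_lj(p, p)
        assert (c.sigma, c.epsilon_well) == pytest.approx((3.5, 0.25))

    def test_zero_well_depth_dominates(self):
        assert combine_lj(
            LJTypeParameters(3.0, 0.0), LJTypeParameters(3.0, 0.5)
        ).epsilon_well == 0.0


class TestSwitching:
    def test_boundary_values(self):
        assert switching_factor(6.0) == 1.0
        assert switching_factor(8.0) == 0.0
        assert switching_factor(2.0) == 1.0
        assert switching_factor(12.0) == 0.0

    def test_interior_value_matches_polynomial(self):
        r = 7.0
        ron2, roff2 = 36.0, 64.0
        expected = (roff2 - 49) ** 2 * (roff2 + 98 - 3 * ron2) / (roff2 - ron2) ** 3
        assert switching_factor(r) == pytest.approx(expected)
        assert 0.0 < switching_factor(r) < 1.0

    @pytest.mark.parametrize("r", [6.0, 8.0])
    def test_c1_continuity_at_boundaries(self, r):
        h = 1e-6
        fd = (switching_factor(r + h) - switching_factor(r - h)) / (2 * h)
        assert abs(fd) < 1e-4  # derivative -> 0 at both ends

    def test_derivative_matches_finite_differences_inside_window(self):
        for r in np.linspace(6.05, 7.95, 9):
            h = 1e-6
            fd = (switching_factor(r + h) - switching_factor(r - h)) / (2 * h)
            assert switching_derivative(r) == pytest.approx(fd, abs=1e-8)


class TestCoulomb:
    def test_single_pair_closed_form(self):
        parts = [
            ChargedParticle((0.0, 0, 0), +1.0, "c"),
            ChargedParticle((1.0, 0, 0), -1.0, "c"),
        ]
        expected = COULOMB_CONSTANT * (1.0 * -1.0) / (4.0 * 1.0)
        assert coulomb_energy(parts) == pytest.approx(expected, rel=1e-12)

    def test_zero_charges_zero_energy(self):
        parts = [ChargedParticle((float(i), 0, 0), 0.0, "c") for i in range(4)]
        assert coulomb_energy(parts) == 0.0

    def test_beyond_cutoff_zero(self):
        parts = [
            ChargedParticle((0.0, 0, 0), 1.0, "c"),
            ChargedParticle((9.0, 0, 0), 1.0, "c"),
        ]
        assert coulomb_energy(parts) == 0.0

    def test_clash_guard(self):
        parts = [
            ChargedParticle((0.0, 0, 0), 1.0, "c"),
            ChargedParticle((0.3, 0, 0), 1.0, "c"),
        ]
        with pytest.raises(ComputationError, match="clash"):
            coulomb_energy(parts)


class TestLennardJones:
    table = {"c": LJTypeParameters(3.4, 0.11), "o": LJTypeParameters(3.0, 0.21)}

    def test_zero_at_sigma(self):
        sig = 0.5 * (3.4 + 3.0)
        parts = [
            ChargedParticle((0.0, 0, 0), 0.0, "c"),
            ChargedParticle((sig, 0, 0), 0.0, "o"),
        ]
        assert lj_energy(parts, table=self.table) == pytest.approx(0.0, abs=1e-12)

    def test_minimum_minus_epsilon(self):
        sig = 0.5 * (3.4 + 3.0)
        eps = math.sqrt(0.11 * 0.21)
        parts = [
            ChargedParticle((0.0, 0, 0), 0.0, "c"),
            ChargedParticle((2 ** (1 / 6) * sig, 0, 0), 0.0, "o"),
        ]
        assert lj_energy(parts, table=self.table) == pytest.approx(-eps, rel=1e-12)

    def test_missing_type_named(self):
        parts = [
            ChargedParticle((0.0, 0, 0), 0.0, "zz"),
            ChargedParticle((3.0, 0, 0), 0.0, "c"),
        ]
        with pytest.raises(InputError, match="zz"):
            lj_energy(parts, table=self.table)


class TestPairSumOracle:
    @pytest.mark.parametrize("n", [5, 12, 20])
    def test_vectorized_equals_bruteforce(self, n):
        parts = make_toy_particles(n, seed=n)
        table = pdl.default_lj_table()
        bc, bl = brute_force_energies(parts, table)
        assert coulomb_energy(parts) == pytest.approx(bc, abs=1e-10)
        assert lj_energy(parts, table=table) == pytest.approx(bl, abs=1e-10)

    def test_cross_mode_counts_all_pairs(self):
        a = make_toy_particles(4, seed=1)
        b = [
            ChargedParticle((p.position[0] + 2.0, p.position[1], p.position[2]),
                            p.charge, p.lj_type)
            for p in make_toy_particles(3, seed=2)
        ]
        table = pdl.default_lj_table()
        expect = 0.0
        for pa in a:
            for pb in b:
                expect += brute_force_energies([pa, pb], table)[0]
        assert coulomb_energy(a, b) == pytest.approx(expect, abs=1e-10)


class TestTotalPhysicalEnergy:
    def test_identity_e_phys(self, fixture_ligand_graphs):
        b = total_physical_energy(fixture_ligand_graphs[0])
        assert b.e_phys == b.e_coul + b.e_lj

    def test_all_zero_parameters_give_zero(self):
        g = pdl.prepare_ligand(LigandRecord("e", "CCO"), seed=0)
        for a in g.atoms:
            a.partial_charge = 0.0
        table = {k: LJTypeParameters(v.sigma, 0.0)
                 for k, v in pdl.default_lj_table().items()}
        b = total_physical_energy(g, table=table)
        assert (b.e_coul, b.e_lj, b.e_phys) == (0.0, 0.0, 0.0)

    def test_ligand_matches_bruteforce_with_exclusions(self):
        g = pdl.prepare_ligand(LigandRecord("t", "CC(=O)O"), seed=2)
        parts = ligand_particles(g)
        excl = exclusion_pairs(g)
        table = pdl.default_lj_table()
        bc, bl = brute_force_energies(parts, table, exclude=excl)
        b = total_physical_energy(g)
        assert b.e_coul == pytest.approx(bc, abs=1e-10)
        assert b.e_lj == pytest.approx(bl, abs=1e-10)

    def test_exclusion_pairs_cover_bonds_and_angles(self):
        g = pdl.parse_smiles(LigandRecord("p", "CCC"))
        assert exclusion_pairs(g) == {(0, 1), (1, 2), (0, 2)}


class TestInvariances:
    def test_rigid_motion_invariance(self):
        parts = make_toy_particles(8, seed=3)
        table = pdl.default_lj_table()
        e0 = coulomb_energy(parts) + lj_energy(parts, table=table)
        rng = np.random.default_rng(4)
        for _ in range(3):
            # random rotation via QR + random translation
            q, _r = np.linalg.qr(rng.normal(size=(3, 3)))
            t = rng.uniform(-20, 20, size=3)
            moved = [
                ChargedParticle(tuple(q @ np.array(p.position) + t), p.charge, p.lj_type)
                for p in parts
            ]
            e1 = coulomb_energy(moved) + lj_energy(moved, table=table)
            assert e1 == pytest.approx(e0, abs=1e-8)

    @pytest.mark.parametrize("delta", [1e-2, 1e-4])
    def test_no_discontinuity_at_cutoff(self, delta):
        parts = [
            ChargedParticle((0.0, 0, 0), 1.0, "c"),
            ChargedParticle((8.0 - delta, 0, 0), 1.0, "c"),
        ]
        e = coulomb_energy(parts)
        assert abs(e) < 50 * delta  # energy vanishes continuously at r_off


class TestGradients:
    def test_pair_outside_switching_window(self):
        parts = [
            ChargedParticle((0.0, 0, 0), 0.5, "c"),
            ChargedParticle((3.0, 0, 0), -0.8, "o"),
        ]
        assert gradient_check("coulomb", parts) < 1e-4
        assert gradient_check("lj", parts) < 1e-4

    def test_pair_inside_switching_window(self):
        parts = [
            ChargedParticle((0.0, 0, 0), 0.5, "c"),
            ChargedParticle((7.0, 0, 0), -0.8, "o"),
        ]
        assert gradient_check("coulomb", parts) < 1e-4
        assert gradient_check("lj", parts) < 1e-4

    def test_many_body_gradients(self):
        parts = make_toy_particles(6, seed=9)
        assert gradient_check("coulomb", parts) < 1e-4
        assert gradient_check("lj", parts) < 1e-4

    def test_newtons_third_law_on_dimer(self):
        parts = [
            ChargedParticle((0.0, 0, 0), 0.4, "c"),
            ChargedParticle((3.0, 0, 0), -0.6, "c"),
        ]
        gc, _ = coulomb_gradient(parts)
        gl, _ = lj_gradient(parts)
        assert np.allclose(gc[0], -gc[1], atol=1e-8)
        assert np.allclose(gl[0], -gl[1], atol=1e-8)


class TestMinMax:
    def test_endpoint_mapping(self):
        s = fit_minmax([-10.8, -6.9])
        assert s.apply(-10.8) == 0.0
        assert s.apply(-6.9) == 1.0

    def test_linearity_at_midpoint(self):
        s = fit_minmax([-10.8, -6.9])
        assert s.apply((-10.8 - 6.9) / 2) == pytest.approx(0.5)

    def test_clipping_outside_range(self):
        s = fit_minmax([0.0, 1.0])
        assert s.apply(-5.0) == 0.0
        assert s.apply(7.0) == 1.0

    def test_constant_values_rejected(self):
        with pytest.raises(InputError, match="distinct"):
            fit_minmax([2.0, 2.0, 2.0])

    def test_outputs_always_in_unit_interval(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=200) * 30
        s = fit_minmax(vals[:100])
        out = s.apply(vals)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_degenerate_construction_rejected(self):
        with pytest.raises(InputError):
            MinMaxScaler(1.0, 1.0)
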