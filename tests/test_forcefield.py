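import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanopost.array_geometry import derive_geometry, min_distance_to_post_axis
from nanopost.forcefield import (
    DEFAULT_FF,
    OverlapError,
    OverstretchError,
    PostOverlapError,
    bending_energy,
    fene_energy,
    post_energy,
    total_energy_and_forces,
    wca_pair_energy,
)
from nanopost.polymer_model import (
    SimulationState,
    build_initial_conformation,
    make_topology,
)

RC = 2.0 ** (1.0 / 6.0)


class TestWCA:
    def test_zero_at_cutoff(self):
        assert wca_pair_energy(RC) == 0.0

    def test_unit_distance(self):
        # 4(1 - 1) + 1 = 1
        assert wca_pair_energy(1.0) == pytest.approx(1.0, rel=1e-14)

    def test_zero_beyond_cutoff(self):
        assert wca_pair_energy(2.0) == 0.0

    def test_overlap_raises(self):
        with pytest.raises(OverlapError):
            wca_pair_energy(0.0)

    @settings(max_examples=100, deadline=None)
    @given(r=st.floats(0.8, 2.0))
    def test_nonnegative_and_monotone_inside(self, r):
        e = wca_pair_energy(r)
        assert e >= 0.0
        if r < RC:
            assert wca_pair_energy(r * 0.99) > e


class TestPostEnergy:
    def test_zero_at_shifted_cutoff(self):
        assert post_energy(5.0 / 2 + RC, 5.0) == 0.0

    def test_shifted_unit_distance(self):
        assert post_energy(5.0 / 2 + 1.0, 5.0) == pytest.approx(1.0, rel=1e-14)

    def test_zero_diameter_reduces_to_wca(self):
        for r in (0.9, 1.0, 1.1, 1.5):
            assert post_energy(r, 0.0) == wca_pair_energy(r)

    def test_inside_post_raises(self):
        with pytest.raises(PostOverlapError):
            post_energy(2.4, 5.0)


class TestFene:
    def test_zero_extension(self):
        assert fene_energy(0.0) == 0.0

    def test_equilibrium_bond(self):
        # -15 * 2.25 * ln(1 - (0.97/1.5)^2)
        expected = -0.5 * 30.0 * 1.5 ** 2 * math.log(1.0 - (0.97 / 1.5) ** 2)
        assert fene_energy(0.97) == pytest.approx(expected, rel=1e-14)
        assert fene_energy(0.97) == pytest.approx(18.28, abs=0.01)

    def test_divergence_near_max(self):
        # unbounded growth approaching R_o
        assert fene_energy(1.5 - 1e-6) > fene_energy(1.49) > fene_energy(1.4)
        assert fene_energy(1.5 - 1e-12) > 900.0

    def test_overstretch_raises(self):
        with pytest.raises(OverstretchError):
            fene_energy(1.5)


class TestBending:
    def test_straight_chain_zero(self):
        for b in (0.0, 5.0, 20.0):
            assert bending_energy(math.pi, b) == pytest.approx(0.0, abs=1e-12)

    def test_right_angle(self):
        assert bending_energy(math.pi / 2, 20.0) == pytest.approx(20.0, rel=1e-12)

    def test_flexible_always_zero(self):
        for theta in np.linspace(0, math.pi, 7):
            assert bending_energy(theta, 0.0) == 0.0


def brute_force_energy(state, ff=DEFAULT_FF):
    """Independent all-pairs / per-term reference implementation (numpy)."""
    pos = state.positions
    n = len(pos)
    e = 0.0
    # WCA over all pairs within cutoff (bonded included)
    if ff.nonbonded:
        for i in range(n - 1):
            for j in range(i + 1, n):
                r = np.linalg.norm(pos[i] - pos[j])
                if r < RC:
                    e += wca_pair_energy(r)
    else:
        for i in range(n - 1):
            r = np.linalg.norm(pos[i] - pos[i + 1])
            if r < RC:
                e += wca_pair_energy(r)
    # FENE
    for i in range(n - 1):
        e += fene_energy(np.linalg.norm(pos[i] - pos[i + 1]))
    # bending
    for k in range(n - 2):
        u = pos[k] - pos[k + 1]
        v = pos[k + 2] - pos[k + 1]
        ct = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        theta = math.acos(max(-1.0, min(1.0, ct)))
        e += bending_energy(theta, state.topology.angle_b[k], ff.kT)
    # posts: sum over all lattice images within range
    if state.array is not None:
        arr = state.array
        for p in pos:
            iy = math.floor(p[1] / arr.S_p)
            iz = math.floor(p[2] / arr.S_p)
            for a in (iy, iy + 1):
                for b in (iz, iz + 1):
                    r = math.hypot(p[1] - a * arr.S_p, p[2] - b * arr.S_p)
                    s = r - max(arr.D_p, 0.0) / 2.0
                    if s < RC:
                        e += wca_pair_energy(s)
    return e


def random_state(n=10, seed=0, kind="diblock", array=None, spread=0.9):
    rng = np.random.default_rng(seed)
    topo = make_topology(n, kind)
    # bonded random walk with safe bond lengths and separations
    pos = np.zeros((n, 3))
    d = np.array([1.0, 0.0, 0.0])
    for i in range(1, n):
        step = d + rng.normal(0, 0.25, 3)
        step *= spread / np.linalg.norm(step)
        pos[i] = pos[i - 1] + step
    if array is not None:
        pos[:, 1:] += array.S_p / 2.0  # center in a cell
    state = SimulationState(positions=pos, velocities=np.zeros((n, 3)),
                            topology=topo, array=array)
    return state


class TestTotalEnergyAndForces:
    def test_straight_trimer(self):
        topo = make_topology(3, "semiflexible", 20.0)
        pos = np.array([[0, 0, 0], [0.97, 0, 0], [1.94, 0, 0]], dtype=float)
        state = SimulationState(pos, np.zeros((3, 3)), topo)
        e, f = total_energy_and_forces(state)
        expected = 2.0 * (fene_energy(0.97) + wca_pair_energy(0.97))
        assert e == pytest.approx(expected, rel=1e-12)
        # bending contributes nothing on a straight chain
        assert f[:, 1:] == pytest.approx(np.zeros((3, 2)), abs=1e-12)

    def test_matches_brute_force(self):
        arr = derive_geometry(6.0, d_p=3.0)
        for seed in range(4):
            state = random_state(12, seed=seed, array=arr)
            e, _ = total_energy_and_forces(state)
            assert e == pytest.approx(brute_force_energy(state), rel=1e-12)

    def test_matches_brute_force_large_free(self):
        # pair-list route vs all-pairs reference on a 100-bead coil
        state = random_state(100, seed=7, kind="flexible", array=None)
        e, _ = total_energy_and_forces(state)
        assert e == pytest.approx(brute_force_energy(state), rel=1e-12)

    def test_phantom_mode(self):
        state = random_state(12, seed=1, kind="semiflexible")
        ff = DEFAULT_FF.phantom()
        e, _ = total_energy_and_forces(state, ff)
        assert e == pytest.approx(brute_force_energy(state, ff), rel=1e-12)

    @pytest.mark.parametrize("kind,use_array,phantom", [
        ("diblock", False, False),
        ("diblock", True, False),
        ("semiflexible", False, True),
        ("flexible", True, False),
    ])
    def test_forces_match_finite_differences(self, kind, use_array, phantom):
        arr = derive_geometry(6.0, d_p=3.0) if use_array else None
        state = random_state(10, seed=3, kind=kind, array=arr)
        ff = DEFAULT_FF.phantom() if phantom else DEFAULT_FF
        _, f = total_energy_and_forces(state, ff)
        h = 1e-6
        num = np.zeros_like(f)
        for i in range(10):
            for d in range(3):
                orig = state.positions[i, d]
                state.positions[i, d] = orig + h
                ep, _ = total_energy_and_forces(state, ff)
                state.positions[i, d] = orig - h
                em, _ = total_energy_and_forces(state, ff)
                state.positions[i, d] = orig
                num[i, d] = -(ep - em) / (2 * h)
        scale = np.abs(f).max()
        assert np.abs(num - f).max() / scale < 1e-6

    def test_post_x_force_identically_zero(self):
        arr = derive_geometry(6.0, d_p=4.0)
        state = random_state(15, seed=5, array=arr)
        _, f_with = total_energy_and_forces(state)
        state_free = SimulationState(state.positions, state.velocities,
                                     state.topology, array=None)
        _, f_free = total_energy_and_forces(state_free)
        # posts contribute exactly zero x-force (x-invariant cylinders)
        assert f_with[:, 0] == pytest.approx(f_free[:, 0], abs=0.0)

    def test_translation_invariance(self):
        arr = derive_geometry(6.0, d_p=3.0)
        state = random_state(12, seed=9, array=arr)
        e0, _ = total_energy_and_forces(state)
        # rigid x translation
        state.positions[:, 0] += 13.7
        e1, _ = total_energy_and_forces(state)
        assert e1 == pytest.approx(e0, rel=1e-12)
        # lattice translation by S_p in y and z
        state.positions[:, 1] += arr.S_p
        state.positions[:, 2] -= 2 * arr.S_p
        e2, _ = total_energy_and_forces(state)
        assert e2 == pytest.approx(e0, rel=1e-12)

    def test_overstretch_propagates(self):
        topo = make_topology(3, "flexible")
        pos = np.array([[0, 0, 0], [1.51, 0, 0], [2.2, 0, 0]], dtype=float)
        state = SimulationState(pos, np.zeros((3, 3)), topo)
        with pytest.raises(OverstretchError):
            total_energy_and_forces(state)

    def test_post_overlap_propagates(self):
        arr = derive_geometry(6.0, d_p=3.0)
        topo = make_topology(2, "flexible")
        pos = np.array([[0, 0.1, 0.1], [0.97, 0.1, 0.1]])  # near a post axis
        state = SimulationState(pos, np.zeros((2, 3)), topo, array=arr)
        with pytest.raises(PostOverlapError):
            total_energy_and_forces(state)

    def test_nonbonded_pair_beyond_cutoff_inert(self):
        # two beads at r = 2 interact through nothing but (vanishing) WCA
        assert wca_pair_energy(2.0) == 0.0
        state = random_state(20, seed=11, kind="flexible")
        e, _ = total_energy_and_forces(state)
        # adding a far-away bead pair cannot change the WCA sum
        assert e == pytest.approx(brute_force_energy(state), rel=1e-12)
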