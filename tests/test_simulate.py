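"""Potential evaluation, forces and Langevin sampling."""

import numpy as np
import pytest
from scipy.integrate import quad

from fretforge import (
    KB,
    SimulationDivergence,
    SimulationParams,
    Trajectory,
    derive_topology,
    forces,
    kinetic_temperature,
    load_trajectory,
    potential_energy,
    run_langevin,
    save_trajectory,
)
from conftest import fp_rmsd_series, make_chain, random_compact_chain


def naive_energy(structure, topology, coords):
    """Independent term-by-term oracle (plain numpy, no shared kernel)."""
    x = np.asarray(coords, float)
    t = topology
    e = 0.0
    for (i, j), r0, k in zip(t.bond_idx, t.bond_r0, t.bond_k):
        e += k * (np.linalg.norm(x[i] - x[j]) - r0) ** 2
    for (i, j, k_), t0, kt in zip(t.angle_idx, t.angle_t0, t.angle_k):
        u, v = x[i] - x[j], x[k_] - x[j]
        c = np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)
        e += kt * (np.arccos(c) - t0) ** 2
    for (i, j, k_, l), p0, kp in zip(t.dihedral_idx, t.dihedral_p0,
                                     t.dihedral_k):
        b1, b2, b3 = x[j] - x[i], x[k_] - x[j], x[l] - x[k_]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        phi = np.arctan2(np.cross(n1, n2) @ b2 / np.linalg.norm(b2), n1 @ n2)
        s2t1 = (n1 @ n1) / ((b1 @ b1) * (b2 @ b2))
        s2t2 = (n2 @ n2) / ((b2 @ b2) * (b3 @ b3))

        def sw(u):
            if u <= 0.01:
                return 0.0
            if u >= 0.09:
                return 1.0
            tt = (u - 0.01) / 0.08
            return tt * tt * (3 - 2 * tt)

        e += sw(s2t1) * sw(s2t2) * kp * (1 - np.cos(phi - p0))
    contact_pairs = set()
    for (i, j), r0, eps in zip(t.contact_idx, t.contact_r0, t.contact_eps):
        r = np.linalg.norm(x[i] - x[j])
        e += eps * (5 * (r0 / r) ** 12 - 6 * (r0 / r) ** 10)
        contact_pairs.add((i, j))
    cutoff = 2.5 * t.sigma_ev
    shift = t.eps_ev * (t.sigma_ev / cutoff) ** 12
    n = x.shape[0]
    for i in range(n):
        for j in range(i + 2, n):
            if (i, j) in contact_pairs:
                continue
            r = np.linalg.norm(x[i] - x[j])
            if r < cutoff:
                e += t.eps_ev * (t.sigma_ev / r) ** 12 - shift
    return e


class TestPotentialEnergy:
    def test_native_contact_term(self, open_dumbbell):
        """At native coordinates every contact sits at the 12-10 minimum
        (-eps each) and all bonded terms vanish; only the excluded-volume
        background remains, so E <= -sum(eps) + EV with EV >= 0."""
        topo = derive_topology(open_dumbbell, interdomain_scale=0.0,
                               eps_ev=0.0)
        e = potential_energy(open_dumbbell, topo)
        assert np.isclose(e, -topo.contact_eps.sum(), rtol=1e-12)

    def test_stretched_bond_closed_form(self):
        s = make_chain([[0, 0, 0], [3.8, 0, 0]])
        t = derive_topology(s, k_bond=100.0)
        e = potential_energy(s, t, np.array([[0, 0, 0], [4.8, 0, 0.0]]))
        assert np.isclose(e, 100.0 * 1.0 ** 2)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            s = random_compact_chain(rng, 10)
            t = derive_topology(s)
            x = s.coords + rng.normal(0, 0.4, s.coords.shape)
            assert np.isclose(potential_energy(s, t, x), naive_energy(s, t, x),
                              rtol=1e-10)

    def test_coincident_beads_guarded(self):
        s = make_chain([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [7.6, 3.8, 0]])
        t = derive_topology(s)
        x = s.coords.copy()
        x[3] = x[0] + 1e-12     # collapse a |i-j|=3 excluded-volume pair
        with pytest.warns(UserWarning, match="clamped"):
            e = potential_energy(s, t, x)
        assert np.isfinite(e)


class TestForces:
    def test_native_stationary_without_background(self, open_dumbbell):
        """Bonded + contact terms are exactly stationary at the native
        coordinates (the excluded-volume background is a separate,
        reference-free term)."""
        topo = derive_topology(open_dumbbell, eps_ev=0.0)
        f = forces(open_dumbbell, topo)
        assert np.abs(f).max() < 1e-8

    def test_matches_numerical_gradient(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(10):
            s = random_compact_chain(rng, 9)
            t = derive_topology(s)
            x = s.coords + rng.normal(0, 0.3, s.coords.shape)
            f = forces(s, t, x)
            scale = max(np.abs(f).max(), 1.0)
            h = 1e-5
            for i in range(s.n_beads):
                for d in range(3):
                    xp, xm = x.copy(), x.copy()
                    xp[i, d] += h
                    xm[i, d] -= h
                    fn = -(potential_energy(s, t, xp)
                           - potential_energy(s, t, xm)) / (2 * h)
                    worst = max(worst, abs(fn - f[i, d]) / scale)
        assert worst < 1e-5

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        s = random_compact_chain(rng, 8)
        t = derive_topology(s)
        x = s.coords + rng.normal(0, 0.3, s.coords.shape)
        f0 = forces(s, t, x)
        f1 = forces(s, t, x + np.array([11.0, -3.0, 0.5]))
        assert np.allclose(f0, f1, atol=1e-9)
        assert np.abs(f0.sum(axis=0)).max() < 1e-8

    def test_zero_net_torque(self):
        rng = np.random.default_rng(2)
        s = random_compact_chain(rng, 8)
        t = derive_topology(s)
        x = s.coords + rng.normal(0, 0.3, s.coords.shape)
        f = forces(s, t, x)
        torque = np.cross(x - x.mean(axis=0), f).sum(axis=0)
        assert np.abs(torque).max() < 1e-6

    def test_rotation_invariance_of_energy(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(3)
        s = random_compact_chain(rng, 8)
        t = derive_topology(s)
        x = s.coords + rng.normal(0, 0.3, s.coords.shape)
        e0 = potential_energy(s, t, x)
        for seed in range(3):
            rot = Rotation.random(random_state=seed).as_matrix()
            e1 = potential_energy(s, t, x @ rot.T + [5.0, 0, -2.0])
            assert np.isclose(e0, e1, rtol=1e-10)


def bond_boltzmann_moments(k=100.0, r0=3.8, kT=1.0):
    """Quadrature oracle: p(r) ~ r^2 exp(-k (r-r0)^2 / kT) in 3-D."""
    w = lambda r: r * r * np.exp(-k * (r - r0) ** 2 / kT)
    lo, hi = max(r0 - 1.5, 0.0), r0 + 1.5
    z = quad(w, lo, hi)[0]
    mean = quad(lambda r: r * w(r), lo, hi)[0] / z
    var = quad(lambda r: (r - mean) ** 2 * w(r), lo, hi)[0] / z
    return mean, var


class TestLangevin:
    def test_bond_sampling_matches_quadrature(self):
        s = make_chain([[0, 0, 0], [3.8, 0, 0]])
        t = derive_topology(s)
        p = SimulationParams(n_steps=400_000, snapshot_interval=40,
                             friction=2.0, rng_seed=5)
        traj = run_langevin(s, t, p)
        r = np.linalg.norm(traj.frames[:, 1] - traj.frames[:, 0], axis=1)
        mean_ref, var_ref = bond_boltzmann_moments()
        assert abs(r.mean() - mean_ref) < 0.02 * mean_ref
        assert abs(r.var() - var_ref) < 0.05 * var_ref
        _, t_mean = kinetic_temperature(traj)
        assert abs(t_mean - 300.0) < 0.03 * 300.0

    def test_zero_temperature_descent(self):
        s = make_chain([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [11.4, 0, 0]])
        t = derive_topology(s)
        rng = np.random.default_rng(0)
        s.coords += rng.normal(0, 0.3, s.coords.shape)
        # overdamped regime (friction well above 2*omega of the stiffest
        # bond mode) so the potential energy descends monotonically
        p = SimulationParams(temperature=0.0, n_steps=4000,
                             snapshot_interval=40, friction=50.0,
                             timestep=0.002, equilibration_fraction=0.0,
                             rng_seed=1)
        traj = run_langevin(s, t, p)
        de = np.diff(traj.energies)
        assert (de <= 1e-8).all()
        assert traj.energies[-1] < traj.energies[0]

    def test_determinism(self, open_dumbbell):
        topo = derive_topology(open_dumbbell, interdomain_scale=0.0)
        p = SimulationParams(n_steps=2000, snapshot_interval=200, rng_seed=3)
        a = run_langevin(open_dumbbell, topo, p)
        b = run_langevin(open_dumbbell, topo, p)
        assert np.array_equal(a.frames, b.frames)
        assert np.array_equal(a.energies, b.energies)

    def test_doubled_noise_quadruples_temperature(self):
        s = make_chain([[0, 0, 0], [3.8, 0, 0]])
        t = derive_topology(s)
        base = SimulationParams(n_steps=200_000, snapshot_interval=50,
                                friction=2.0, rng_seed=8)
        hot = SimulationParams(n_steps=200_000, snapshot_interval=50,
                               friction=2.0, rng_seed=8, noise_scale=2.0)
        _, t1 = kinetic_temperature(run_langevin(s, t, base))
        _, t4 = kinetic_temperature(run_langevin(s, t, hot))
        assert abs(t4 / t1 - 4.0) < 0.4

    def test_zero_velocities_zero_temperature(self):
        s = make_chain([[0, 0, 0], [3.8, 0, 0]])
        traj = Trajectory(frames=s.coords[None], energies=np.zeros(1),
                          velocities=np.zeros((1, 2, 3)),
                          params=SimulationParams(n_steps=1))
        inst, mean = kinetic_temperature(traj)
        assert mean == 0.0

    def test_divergence_aborts_with_step(self):
        s = make_chain([[0, 0, 0], [3.8, 0, 0]])
        t = derive_topology(s, k_bond=1e7)    # dt far beyond stability
        p = SimulationParams(n_steps=5000, snapshot_interval=100,
                             timestep=0.05, rng_seed=0)
        with pytest.raises(SimulationDivergence, match="step"):
            run_langevin(s, t, p)

    def test_native_domain_stays_rigid(self, open_dumbbell,
                                       desk_scale_ensembles):
        """A contact-dense FP stand-in keeps RMSD < 3 A at the default
        contact strength over a desk-scale run."""
        from fretforge import Segment

        traj = desk_scale_ensembles["open"]
        idx = open_dumbbell.segment_indices(Segment.YFP)
        rmsd = fp_rmsd_series(traj.frames, open_dumbbell.coords, idx)
        assert rmsd.mean() < 3.0
        assert rmsd.max() < 5.0

    def test_trajectory_round_trip(self, tmp_path, open_dumbbell):
        topo = derive_topology(open_dumbbell, interdomain_scale=0.0)
        p = SimulationParams(n_steps=1000, snapshot_interval=200, rng_seed=4)
        traj = run_langevin(open_dumbbell, topo, p)
        save_trajectory(traj, tmp_path / "t")
        back = load_trajectory(tmp_path / "t", structure=open_dumbbell)
        assert np.array_equal(back.frames, traj.frames)
        assert np.array_equal(back.energies, traj.energies)
        assert back.params == traj.params
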