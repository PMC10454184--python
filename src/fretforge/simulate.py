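"""Structure-based potential and Langevin dynamics for the bead models.

The potential is a single-basin Go-type surrogate:

    E = sum k (r - r0)^2                       bonds
      + sum k_theta (theta - theta0)^2         angles
      + sum k_phi [1 - cos(phi - phi0)]        dihedrals
      + sum eps [5 (r0/r)^12 - 6 (r0/r)^10]    native contacts
      + sum eps_ev (sigma/r)^12                excluded volume

Excluded volume applies to every non-bonded, non-contact pair with
|i - j| >= 2, truncated at 2.5 sigma and accelerated by a Verlet neighbor
list with a 1.5x cutoff skin.

Units are reduced: lengths in Angstrom, energies such that kT at 300 K
equals 1 (one unit is then ~0.596 kcal/mol), uniform bead mass 1, and time
in units where the thermal velocity at 300 K is ~1 A per time unit.
Integration uses the BAOAB splitting of Langevin dynamics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from numba import njit

from .construct import CGStructure, Topology

__all__ = [
    "KB",
    "SimulationParams",
    "Trajectory",
    "SimulationDivergence",
    "potential_energy",
    "forces",
    "run_langevin",
    "kinetic_temperature",
    "save_trajectory",
    "load_trajectory",
]

#: Boltzmann constant in reduced energy units per kelvin (kT = 1 at 300 K).
KB = 1.0 / 300.0

_EV_CUTOFF_FACTOR = 2.5     # excluded-volume truncation, in units of sigma
_SKIN_FACTOR = 1.5          # Verlet-list cutoff = skin * truncation
_NLIST_INTERVAL = 20        # steps between neighbor-list rebuilds
_R_GUARD = 0.5              # pair distances clamped here to keep E finite


class SimulationDivergence(RuntimeError):
    """Raised when the integrator produces divergent energies."""


@dataclass
class SimulationParams:
    """Langevin run settings.

    The reference production run used 300 K and 1e7 steps; desk-scale runs
    of 1e5-1e6 steps with the same thermostat are the testing default.
    ``noise_scale`` multiplies the thermal-noise amplitude only (friction
    untouched) and exists for fluctuation-dissipation checks; 1.0 samples
    the target temperature.
    """

    temperature: float = 300.0        # kelvin
    n_steps: int = 100_000
    timestep: float = 0.01            # reduced time units
    friction: float = 0.25            # reduced units (gamma)
    snapshot_interval: int = 1000     # steps between recorded frames
    equilibration_fraction: float = 0.1
    rng_seed: int = 0
    mass: float = 1.0                 # uniform bead mass, reduced units
    noise_scale: float = 1.0
    energy_abort_threshold: float = 1e9

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not 0.0 <= self.equilibration_fraction < 1.0:
            raise ValueError("equilibration_fraction must lie in [0, 1)")
        if self.snapshot_interval < 1:
            raise ValueError("snapshot_interval must be >= 1")

    @classmethod
    def paper_scale(cls, **overrides) -> "SimulationParams":
        """The full-scale preset: 300 K, 1e7 integration steps."""
        defaults = dict(temperature=300.0, n_steps=10_000_000,
                        snapshot_interval=1000)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class Trajectory:
    """Time-ordered snapshots of a run (coordinates in Angstrom)."""

    frames: np.ndarray                 # (n_frames, n_beads, 3)
    energies: np.ndarray               # (n_frames,) potential energy
    params: Optional[SimulationParams] = None
    structure: Optional[CGStructure] = None
    velocities: Optional[np.ndarray] = None
    step_indices: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.energies = np.asarray(self.energies, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, n_beads, 3)")
        if len(self.energies) != self.n_frames:
            raise ValueError("one energy per frame required")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("non-finite frame energies")
        if self.structure is not None and \
                self.frames.shape[1] != self.structure.n_beads:
            raise ValueError("frame bead count differs from structure")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]


# ---------------------------------------------------------------------------
# Energy/force kernels


_DIH_SW0 = 0.01   # sin^2(theta) below which torsions are fully off
_DIH_SW1 = 0.09   # sin^2(theta) above which torsions are fully on


@njit(cache=True)
def _smoothstep(u):
    """Cubic switch on sin^2(theta); returns (S, dS/du)."""
    if u <= _DIH_SW0:
        return 0.0, 0.0
    if u >= _DIH_SW1:
        return 1.0, 0.0
    t = (u - _DIH_SW0) / (_DIH_SW1 - _DIH_SW0)
    return t * t * (3.0 - 2.0 * t), 6.0 * t * (1.0 - t) / (_DIH_SW1 - _DIH_SW0)


@njit(cache=True)
def _eval(coords, bond_idx, bond_r0, bond_k,
          angle_idx, angle_t0, angle_k,
          dih_idx, dih_p0, dih_k,
          con_idx, con_r0, con_eps,
          ev_pairs, sigma_ev, eps_ev, ev_cut2):
    """Energy and forces of the full potential.  Returns (E, F, n_guard)."""
    n = coords.shape[0]
    f = np.zeros((n, 3))
    energy = 0.0
    n_guard = 0

    for b in range(bond_idx.shape[0]):
        i, j = bond_idx[b, 0], bond_idx[b, 1]
        dx = coords[i] - coords[j]
        r = np.sqrt(dx[0]**2 + dx[1]**2 + dx[2]**2)
        dr = r - bond_r0[b]
        energy += bond_k[b] * dr * dr
        if r > 1e-12:
            g = 2.0 * bond_k[b] * dr / r
            for d in range(3):
                f[i, d] -= g * dx[d]
                f[j, d] += g * dx[d]

    for a in range(angle_idx.shape[0]):
        i, j, k = angle_idx[a, 0], angle_idx[a, 1], angle_idx[a, 2]
        u = coords[i] - coords[j]
        v = coords[k] - coords[j]
        nu = np.sqrt(u[0]**2 + u[1]**2 + u[2]**2)
        nv = np.sqrt(v[0]**2 + v[1]**2 + v[2]**2)
        c = (u[0]*v[0] + u[1]*v[1] + u[2]*v[2]) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        dth = theta - angle_t0[a]
        energy += angle_k[a] * dth * dth
        # (theta - theta0)/sin(theta) diverges at collinearity unless
        # theta0 is itself straight; capping the coefficient bounds the
        # force while staying exact everywhere it is moderate
        s = np.sqrt(1.0 - c * c)
        if s < 1e-12:
            s = 1e-12
        coef = 2.0 * angle_k[a] * dth / s
        cap = 100.0 * angle_k[a]
        if coef > cap:
            coef = cap
        elif coef < -cap:
            coef = -cap
        for d in range(3):
            dthi = (c * u[d] / nu - v[d] / nv) / nu
            dthk = (c * v[d] / nv - u[d] / nu) / nv
            fi = -coef * dthi
            fk = -coef * dthk
            f[i, d] += fi
            f[k, d] += fk
            f[j, d] -= fi + fk

    # torsions are ill-defined when either flanking bend approaches
    # collinearity, so each dihedral is multiplied by a smooth switch
    # S(sin^2 theta1) S(sin^2 theta2) that vanishes near straight backbone
    # (smoothstep between _DIH_SW0 and _DIH_SW1); its gradient is included
    for q in range(dih_idx.shape[0]):
        i, j, k, l = dih_idx[q, 0], dih_idx[q, 1], dih_idx[q, 2], dih_idx[q, 3]
        b1 = coords[j] - coords[i]
        b2 = coords[k] - coords[j]
        b3 = coords[l] - coords[k]
        n1 = np.empty(3)
        n2 = np.empty(3)
        n1[0] = b1[1]*b2[2] - b1[2]*b2[1]
        n1[1] = b1[2]*b2[0] - b1[0]*b2[2]
        n1[2] = b1[0]*b2[1] - b1[1]*b2[0]
        n2[0] = b2[1]*b3[2] - b2[2]*b3[1]
        n2[1] = b2[2]*b3[0] - b2[0]*b3[2]
        n2[2] = b2[0]*b3[1] - b2[1]*b3[0]
        n1sq = n1[0]**2 + n1[1]**2 + n1[2]**2
        n2sq = n2[0]**2 + n2[1]**2 + n2[2]**2
        b1n = np.sqrt(b1[0]**2 + b1[1]**2 + b1[2]**2)
        b2n = np.sqrt(b2[0]**2 + b2[1]**2 + b2[2]**2)
        b3n = np.sqrt(b3[0]**2 + b3[1]**2 + b3[2]**2)
        if b1n < 1e-9 or b2n < 1e-9 or b3n < 1e-9:
            continue
        c1_ = (b1[0]*b2[0] + b1[1]*b2[1] + b1[2]*b2[2]) / (b1n * b2n)
        c2_ = (b2[0]*b3[0] + b2[1]*b3[1] + b2[2]*b3[2]) / (b2n * b3n)
        u1 = 1.0 - c1_ * c1_
        u2 = 1.0 - c2_ * c2_
        s1, ds1 = _smoothstep(u1)
        s2, ds2 = _smoothstep(u2)
        sw = s1 * s2
        if sw <= 0.0 or n1sq < 1e-12 or n2sq < 1e-12:
            continue
        # phi = atan2((n1 x n2).b2hat, n1.n2)
        cxx = n1[1]*n2[2] - n1[2]*n2[1]
        cxy = n1[2]*n2[0] - n1[0]*n2[2]
        cxz = n1[0]*n2[1] - n1[1]*n2[0]
        sin_t = (cxx*b2[0] + cxy*b2[1] + cxz*b2[2]) / b2n
        cos_t = n1[0]*n2[0] + n1[1]*n2[1] + n1[2]*n2[2]
        phi = np.arctan2(sin_t, cos_t)
        e_phi = dih_k[q] * (1.0 - np.cos(phi - dih_p0[q]))
        energy += sw * e_phi
        dV = sw * dih_k[q] * np.sin(phi - dih_p0[q])
        s12 = (b1[0]*b2[0] + b1[1]*b2[1] + b1[2]*b2[2]) / (b2n * b2n)
        s32 = (b3[0]*b2[0] + b3[1]*b2[1] + b3[2]*b2[2]) / (b2n * b2n)
        # switch-gradient prefactors: du = -2 c dc
        g1 = -e_phi * s2 * ds1 * 2.0 * c1_
        g2 = -e_phi * s1 * ds2 * 2.0 * c2_
        for d in range(3):
            dpi = -(b2n / n1sq) * n1[d]
            dpl = (b2n / n2sq) * n2[d]
            dpj = -(1.0 + s12) * dpi + s32 * dpl
            dpk = s12 * dpi - (1.0 + s32) * dpl
            f[i, d] -= dV * dpi
            f[j, d] -= dV * dpj
            f[k, d] -= dV * dpk
            f[l, d] -= dV * dpl
            # d(c1)/dr over beads i, j, k  (c1 built from b1, b2)
            dc1_db1 = b2[d] / (b1n * b2n) - c1_ * b1[d] / (b1n * b1n)
            dc1_db2 = b1[d] / (b1n * b2n) - c1_ * b2[d] / (b2n * b2n)
            f[i, d] -= g1 * (-dc1_db1)
            f[j, d] -= g1 * (dc1_db1 - dc1_db2)
            f[k, d] -= g1 * dc1_db2
            # d(c2)/dr over beads j, k, l  (c2 built from b2, b3)
            dc2_db2 = b3[d] / (b2n * b3n) - c2_ * b2[d] / (b2n * b2n)
            dc2_db3 = b2[d] / (b2n * b3n) - c2_ * b3[d] / (b3n * b3n)
            f[j, d] -= g2 * (-dc2_db2)
            f[k, d] -= g2 * (dc2_db2 - dc2_db3)
            f[l, d] -= g2 * dc2_db3

    for c_ in range(con_idx.shape[0]):
        i, j = con_idx[c_, 0], con_idx[c_, 1]
        dx = coords[i] - coords[j]
        r = np.sqrt(dx[0]**2 + dx[1]**2 + dx[2]**2)
        if r < _R_GUARD:
            r = _R_GUARD
            n_guard += 1
        q10 = (con_r0[c_] / r) ** 10
        q12 = q10 * (con_r0[c_] / r) ** 2
        energy += con_eps[c_] * (5.0 * q12 - 6.0 * q10)
        g = -60.0 * con_eps[c_] * (q12 - q10) / (r * r)
        for d in range(3):
            f[i, d] -= g * dx[d]
            f[j, d] += g * dx[d]

    # excluded volume is truncated at the cutoff and shifted to zero there,
    # keeping the energy continuous
    ev_shift = eps_ev * (sigma_ev * sigma_ev / ev_cut2) ** 6
    for p in range(ev_pairs.shape[0]):
        i, j = ev_pairs[p, 0], ev_pairs[p, 1]
        dx = coords[i] - coords[j]
        r2 = dx[0]**2 + dx[1]**2 + dx[2]**2
        if r2 >= ev_cut2:
            continue
        if r2 < _R_GUARD * _R_GUARD:
            r2 = _R_GUARD * _R_GUARD
            n_guard += 1
        s2 = sigma_ev * sigma_ev / r2
        s12 = s2 ** 6
        energy += eps_ev * s12 - ev_shift
        g = 12.0 * eps_ev * s12 / r2
        for d in range(3):
            f[i, d] += g * dx[d]
            f[j, d] -= g * dx[d]

    return energy, f, n_guard


@njit(cache=True)
def _build_nlist(coords, excluded_keys, n, list_cut2):
    """All pairs |i-j| >= 2 within the list cutoff, minus excluded keys."""
    count = 0
    cap = 64 + 16 * n
    pairs = np.empty((cap, 2), np.int64)
    for i in range(n):
        for j in range(i + 2, n):
            dx0 = coords[i, 0] - coords[j, 0]
            dx1 = coords[i, 1] - coords[j, 1]
            dx2 = coords[i, 2] - coords[j, 2]
            if dx0*dx0 + dx1*dx1 + dx2*dx2 > list_cut2:
                continue
            key = i * n + j
            lo = np.searchsorted(excluded_keys, key)
            if lo < excluded_keys.shape[0] and excluded_keys[lo] == key:
                continue
            if count >= cap:
                new = np.empty((cap * 2, 2), np.int64)
                new[:cap] = pairs
                pairs = new
                cap *= 2
            pairs[count, 0] = i
            pairs[count, 1] = j
            count += 1
    return pairs[:count]


@njit(cache=True)
def _baoab_chunk(coords, vel, f, noise,
                 bond_idx, bond_r0, bond_k,
                 angle_idx, angle_t0, angle_k,
                 dih_idx, dih_p0, dih_k,
                 con_idx, con_r0, con_eps,
                 excluded_keys, sigma_ev, eps_ev, ev_cut2, list_cut2,
                 dt, mass, c1, c2):
    """Advance ``noise.shape[0]`` BAOAB steps in place; return (E, F, guard)."""
    n = coords.shape[0]
    n_guard = 0
    ev_pairs = _build_nlist(coords, excluded_keys, n, list_cut2)
    energy = 0.0
    for step in range(noise.shape[0]):
        if step % _NLIST_INTERVAL == 0 and step > 0:
            ev_pairs = _build_nlist(coords, excluded_keys, n, list_cut2)
        half = 0.5 * dt
        for i in range(n):
            for d in range(3):
                vel[i, d] += half * f[i, d] / mass
                coords[i, d] += half * vel[i, d]
        for i in range(n):
            for d in range(3):
                vel[i, d] = c1 * vel[i, d] + c2 * noise[step, i, d]
                coords[i, d] += half * vel[i, d]
        energy, f_new, g = _eval(coords, bond_idx, bond_r0, bond_k,
                                 angle_idx, angle_t0, angle_k,
                                 dih_idx, dih_p0, dih_k,
                                 con_idx, con_r0, con_eps,
                                 ev_pairs, sigma_ev, eps_ev, ev_cut2)
        n_guard += g
        for i in range(n):
            for d in range(3):
                f[i, d] = f_new[i, d]
                vel[i, d] += half * f[i, d] / mass
    return energy, f, n_guard


def _excluded_keys(topology: Topology, n: int) -> np.ndarray:
    """Sorted pair keys (i*n + j, i < j) removed from the excluded-volume sum:
    bonded neighbors and native-contact pairs."""
    keys = []
    for i, j in topology.bond_idx:
        a, b = (int(i), int(j)) if i < j else (int(j), int(i))
        keys.append(a * n + b)
    for i, j in topology.contact_idx:
        keys.append(int(i) * n + int(j))
    return np.unique(np.asarray(keys, dtype=np.int64)) if keys else \
        np.zeros(0, dtype=np.int64)


def _eval_full(coords: np.ndarray, topology: Topology):
    n = coords.shape[0]
    t = topology
    excl = _excluded_keys(t, n)
    ev_cut = _EV_CUTOFF_FACTOR * t.sigma_ev
    ev_pairs = _build_nlist(np.ascontiguousarray(coords, dtype=np.float64),
                            excl, n, ev_cut * ev_cut)
    return _eval(np.ascontiguousarray(coords, dtype=np.float64),
                 t.bond_idx, t.bond_r0, t.bond_k,
                 t.angle_idx, t.angle_t0, t.angle_k,
                 t.dihedral_idx, t.dihedral_p0, t.dihedral_k,
                 t.contact_idx, t.contact_r0, t.contact_eps,
                 ev_pairs, t.sigma_ev, t.eps_ev, ev_cut * ev_cut)


def potential_energy(structure: CGStructure, topology: Topology,
                     coords: Optional[np.ndarray] = None) -> float:
    """Total potential energy (reduced units) of one configuration.

    At the native coordinates each contact contributes exactly -eps (the
    minimum of the 12-10 form at r = r0) and all bonded terms vanish.
    Coincident beads in a non-bonded pair are guarded (distance clamped)
    so the result stays finite; a warning reports the number of clamps.
    """
    x = structure.coords if coords is None else np.asarray(coords, float)
    if x.shape != (structure.n_beads, 3):
        raise ValueError("coords shape does not match bead count")
    energy, _, n_guard = _eval_full(x, topology)
    if n_guard:
        warnings.warn(f"{n_guard} near-coincident pair(s) clamped in energy",
                      stacklevel=2)
    return float(energy)


def forces(structure: CGStructure, topology: Topology,
           coords: Optional[np.ndarray] = None) -> np.ndarray:
    """Analytic forces -grad E, one 3-vector per bead."""
    x = structure.coords if coords is None else np.asarray(coords, float)
    if x.shape != (structure.n_beads, 3):
        raise ValueError("coords shape does not match bead count")
    _, f, n_guard = _eval_full(x, topology)
    if n_guard:
        warnings.warn(f"{n_guard} near-coincident pair(s) clamped in forces",
                      stacklevel=2)
    return np.asarray(f)


def run_langevin(structure: CGStructure, topology: Topology,
                 params: SimulationParams) -> Trajectory:
    """Integrate Langevin dynamics with the BAOAB splitting.

    Snapshots (coordinates, velocities, potential energy) are recorded
    every ``snapshot_interval`` steps; the leading
    ``equilibration_fraction`` of recorded snapshots is discarded.  The
    thermal noise stream comes from a seeded PCG64 generator, so repeated
    runs with the same parameters are bitwise identical.  Energies beyond
    ``energy_abort_threshold`` abort with a diagnostic naming the step.
    """
    p = params
    t = topology
    n = structure.n_beads
    x = np.ascontiguousarray(structure.coords, dtype=np.float64).copy()
    rng = np.random.default_rng(p.rng_seed)
    kt = KB * p.temperature
    if kt > 0:
        v = rng.standard_normal((n, 3)) * np.sqrt(kt / p.mass)
    else:
        v = np.zeros((n, 3))

    e0, f, _ = _eval_full(x, t)
    if not np.isfinite(e0):
        raise SimulationDivergence("initial energy is not finite")

    c1 = np.exp(-p.friction * p.timestep)
    c2 = p.noise_scale * np.sqrt(kt * (1.0 - c1 * c1) / p.mass)
    excl = _excluded_keys(t, n)
    ev_cut = _EV_CUTOFF_FACTOR * t.sigma_ev
    list_cut = _SKIN_FACTOR * ev_cut

    n_snap = p.n_steps // p.snapshot_interval
    frames, vels, energies, steps_rec = [], [], [], []
    step = 0
    total_guard = 0
    for s in range(n_snap):
        chunk = min(p.snapshot_interval, p.n_steps - step)
        noise = rng.standard_normal((chunk, n, 3))
        energy, f, g = _baoab_chunk(
            x, v, f, noise,
            t.bond_idx, t.bond_r0, t.bond_k,
            t.angle_idx, t.angle_t0, t.angle_k,
            t.dihedral_idx, t.dihedral_p0, t.dihedral_k,
            t.contact_idx, t.contact_r0, t.contact_eps,
            excl, t.sigma_ev, t.eps_ev, ev_cut * ev_cut,
            list_cut * list_cut, p.timestep, p.mass, c1, c2)
        total_guard += g
        step += chunk
        if not np.isfinite(energy) or abs(energy) > p.energy_abort_threshold:
            raise SimulationDivergence(
                f"energy {energy:.3e} beyond threshold at step {step}")
        frames.append(x.copy())
        vels.append(v.copy())
        energies.append(energy)
        steps_rec.append(step)
    if total_guard:
        warnings.warn(f"{total_guard} near-coincident pair(s) clamped during run",
                      stacklevel=2)

    n_skip = int(np.ceil(p.equilibration_fraction * len(frames)))
    return Trajectory(
        frames=np.asarray(frames[n_skip:]),
        energies=np.asarray(energies[n_skip:]),
        params=p,
        structure=structure,
        velocities=np.asarray(vels[n_skip:]),
        step_indices=np.asarray(steps_rec[n_skip:]),
    )


def kinetic_temperature(trajectory: Trajectory) -> tuple[np.ndarray, float]:
    """Per-frame and mean temperature (K) from equipartition.

    T = m <v^2> / (3 N kB) summed over all beads; requires velocities.
    """
    if trajectory.velocities is None:
        raise ValueError("trajectory carries no velocities")
    mass = trajectory.params.mass if trajectory.params is not None else 1.0
    v2 = np.sum(trajectory.velocities ** 2, axis=(1, 2))
    n_dof = 3 * trajectory.n_beads
    inst = mass * v2 / (n_dof * KB)
    return inst, float(inst.mean())


# ---------------------------------------------------------------------------
# Trajectory I/O: NPZ arrays plus a JSON metadata sidecar

def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write frames/energies to ``<path>.npz`` and metadata to ``<path>.json``."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".npz", ".json") else path
    arrays = {"frames": traj.frames, "energies": traj.energies}
    if traj.velocities is not None:
        arrays["velocities"] = traj.velocities
    if traj.step_indices is not None:
        arrays["step_indices"] = traj.step_indices
    np.savez_compressed(str(base) + ".npz", **arrays)
    meta = {
        "n_frames": traj.n_frames,
        "n_beads": traj.n_beads,
        "params": asdict(traj.params) if traj.params is not None else None,
    }
    with open(str(base) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_trajectory(path: str | Path,
                    structure: Optional[CGStructure] = None) -> Trajectory:
    """Read a trajectory written by :func:`save_trajectory`."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".npz", ".json") else path
    with np.load(str(base) + ".npz") as data:
        frames = data["frames"]
        energies = data["energies"]
        velocities = data["velocities"] if "velocities" in data else None
        step_indices = data["step_indices"] if "step_indices" in data else None
    params = None
    meta_path = Path(str(base) + ".json")
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
        if meta.get("params"):
            params = SimulationParams(**meta["params"])
    return Trajectory(frames=frames, energies=energies, params=params,
                      structure=structure, velocities=velocities,
                      step_indices=step_indices)
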