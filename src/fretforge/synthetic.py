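"""Synthetic inputs with known ground truth for every pipeline stage.

The structural generator emulates the fusion construct with geometric
stand-ins: each fluorescent protein and each core domain is a compact
walk on a cubic lattice (3.8 A spacing, dense native contacts, hence
rigid under the structure-based potential), joined by circular-arc
bridges with exact 3.8 A bead spacing.  Two arrangements are produced:

* ``open``  -- the two core domains lie side by side separated by a
  configurable surface gap (no intercore contacts) and the chain doubles
  back so both FP stand-ins sit adjacent near the hinge: chromophores
  ~20 A apart, i.e. the high-FRET geometry of the oxidized-form model.
* ``closed`` -- the core domains merge into a single compact body (the
  reduced form behaves as one particle), the shared interface carrying
  abundant interdomain contacts, and the FPs attach at the opposite ends
  of the merged block: chromophores ~90 A apart, beyond the reach of
  E > 0.5 for any dipole orientation, i.e. the low-FRET reduced-form
  geometry.

Which arrangement is high-FRET is therefore fixed by the generated
geometry (termini proximity), not by any label in the scoring code.

Spectra, titration series and time courses are generated from the same
closed forms the analysis fits, with seeded noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import pdist

from .construct import CA_SPACING, CGStructure, Segment
from .simulate import SimulationParams, Trajectory
from .titration import EmissionSpectrum, RedoxFit, TitrationPoint, predict_ratio

__all__ = [
    "DumbbellSpec",
    "GroundTruth",
    "GenerationError",
    "make_dumbbell",
    "synth_two_state_trajectory",
    "synth_spectrum",
    "synth_titration",
    "synth_timecourse",
]

_RES_CYCLE = ["ALA", "GLY", "SER", "THR", "VAL", "LEU", "ASN", "ASP"]


class GenerationError(RuntimeError):
    """Raised when a requested synthetic geometry is infeasible."""


@dataclass
class DumbbellSpec:
    """Geometry of the two-domain dumbbell with FP stand-ins.

    Bead counts default to 40 per FP stand-in and 60 per core domain
    (each core = a lattice block of ``n_core - 4`` beads plus a 4-bead
    hinge strand at the interdomain junction).  ``open_gap`` is the
    surface-to-surface distance between the core blocks in the open
    arrangement; ``closed_contact`` the face distance of the shared
    interface in the closed one.  Linker lengths follow the reference
    construct (2 and 4 residues).  Chromophore/dipole-reference offsets
    are 0-based bead indices within each FP stand-in.
    """

    n_fp: int = 40
    n_core: int = 60
    open_gap: float = 30.0        # Angstrom, open arrangement
    closed_contact: float = 3.8   # Angstrom, closed interface plane distance
    linker1_len: int = 2
    linker2_len: int = 4
    acceptor_chromophore_offset: int = 8
    acceptor_dipole_ref_offset: int = 21
    donor_chromophore_offset: int = 36
    donor_dipole_ref_offset: int = 25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fp < 4 or self.n_core < 13:
            raise ValueError("need n_fp >= 4 and n_core >= 13")
        if self.open_gap <= self.closed_contact:
            raise ValueError("open gap must exceed the closed contact distance")
        for off in (self.acceptor_chromophore_offset,
                    self.acceptor_dipole_ref_offset,
                    self.donor_chromophore_offset,
                    self.donor_dipole_ref_offset):
            if not 0 <= off < self.n_fp:
                raise ValueError("FP bead offsets must lie inside the FP")


@dataclass
class GroundTruth:
    """Known parameters behind a synthetic data set."""

    p_open: float = 0.7
    open_chromophore_distance: float = float("nan")
    closed_chromophore_distance: float = float("nan")
    k_eq: float = 1e-6            # M
    r_ox: float = 1.2
    r_red: float = 0.6
    noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_open <= 1.0:
            raise ValueError("p_open must lie in [0, 1]")
        if self.k_eq <= 0 or self.noise < 0:
            raise ValueError("k_eq must be positive and noise non-negative")

    def as_fit(self) -> RedoxFit:
        return RedoxFit(k_eq=self.k_eq, r_ox=self.r_ox, r_red=self.r_red)


# ---------------------------------------------------------------------------
# Lattice building blocks

def _snake_block(n: int, nx: int, ny: int,
                 spacing: float = CA_SPACING) -> np.ndarray:
    """First ``n`` sites of a boustrophedon walk through an nx*ny*inf lattice.

    Consecutive sites are always lattice neighbors, so the chain spacing is
    exactly ``spacing`` everywhere.
    """
    coords = np.empty((n, 3))
    ix = iy = iz = 0
    dx, dy = 1, 1
    for k in range(n):
        coords[k] = (ix, iy, iz)
        nxt = ix + dx
        if 0 <= nxt < nx:
            ix = nxt
            continue
        ynxt = iy + dy
        dx = -dx
        if 0 <= ynxt < ny:
            iy = ynxt
            continue
        dy = -dy
        iz += 1
    return coords * spacing


def _arc_bridge(start: np.ndarray, end: np.ndarray, n_inner: int,
                bulge_hint: np.ndarray,
                spacing: float = CA_SPACING) -> np.ndarray:
    """``n_inner`` beads between two anchors, every chord exactly ``spacing``.

    The beads lie on a circular arc in the plane spanned by the anchor
    chord and ``bulge_hint``; if the anchors are almost exactly
    ``(n_inner + 1) * spacing`` apart the bridge degenerates to a straight
    line.  Raises :class:`GenerationError` when no arc exists.
    """
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    n_seg = n_inner + 1
    chord = float(np.linalg.norm(end - start))
    max_span = n_seg * spacing
    if chord > max_span + 1e-9:
        raise GenerationError(
            f"anchors {chord:.2f} A apart exceed bridge reach {max_span:.2f} A")
    if n_inner == 0:
        return np.zeros((0, 3))
    u = (end - start) / chord
    if chord > max_span - 1e-9:
        steps = np.arange(1, n_seg)[:, None] * (chord / n_seg) * u[None, :]
        return start[None, :] + steps

    # solve for the per-segment turn: sin(n d/2) / sin(d/2) = chord / spacing
    ratio = chord / spacing

    def f(d):
        return np.sin(n_seg * d / 2.0) / np.sin(d / 2.0) - ratio

    d_hi = 2.0 * np.pi / n_seg - 1e-9
    d = brentq(f, 1e-9, d_hi)
    radius = spacing / (2.0 * np.sin(d / 2.0))

    w = np.asarray(bulge_hint, float)
    w = w - (w @ u) * u
    wn = np.linalg.norm(w)
    if wn < 1e-9:
        raise GenerationError("bulge_hint is parallel to the anchor chord")
    w /= wn
    half = n_seg * d / 2.0
    center = 0.5 * (start + end) - w * radius * np.cos(half)
    # angles measured in the (u, w) plane around the center
    v0 = start - center
    # start anchor sits at phase phi0 = pi/2 + (total angle)/2 in the (u, w)
    # plane around the center; walking toward the end anchor decreases it
    a = v0 @ u
    b = v0 @ w
    rad = np.hypot(a, b)
    phi0 = np.arctan2(b, a)
    out = np.empty((n_inner, 3))
    for k in range(1, n_seg):
        ang = phi0 - k * d
        out[k - 1] = center + rad * (np.cos(ang) * u + np.sin(ang) * w)
    return out


def _rot(mapping: str) -> np.ndarray:
    """Proper rotation matrix from a compact axis-mapping string.

    ``mapping`` lists, for each world axis, the local axis (with sign) that
    feeds it, e.g. ``"z,x,y"`` or ``"-x,-y,z"``.
    """
    m = np.zeros((3, 3))
    axes = {"x": 0, "y": 1, "z": 2}
    for row, token in enumerate(mapping.split(",")):
        token = token.strip()
        sign = -1.0 if token.startswith("-") else 1.0
        m[row, axes[token.lstrip("+-")]] = sign
    if not np.isclose(np.linalg.det(m), 1.0):
        raise ValueError(f"mapping {mapping!r} is not a proper rotation")
    return m


def _min_nonbonded(coords: np.ndarray) -> float:
    """Minimum distance over pairs |i-j| >= 2."""
    n = coords.shape[0]
    d = pdist(coords)
    # mask out consecutive pairs
    keep = np.ones(d.shape[0], dtype=bool)
    pos = 0
    for i in range(n - 1):
        keep[pos] = False  # pair (i, i+1) is first in row i
        pos += n - 1 - i
    return float(d[keep].min())


def make_dumbbell(spec: DumbbellSpec, arrangement: str) -> CGStructure:
    """Generate the open or closed dumbbell template.

    Deterministic for a given spec (the seed only steers clash-resolution
    fallbacks of the bridge bulge directions).  The returned structure has
    ``heavy=None`` so topology derivation uses the C-alpha contact rule.
    """
    if arrangement not in ("open", "closed"):
        raise ValueError("arrangement must be 'open' or 'closed'")
    s = spec
    rng = np.random.default_rng(s.rng_seed)
    fp = _snake_block(s.n_fp, 4, 4)
    lat = CA_SPACING
    fp_zlen = fp[:, 2].max()

    if arrangement == "open":
        # two separated blocks joined by an 8-bead junction strand spanning
        # the gap; the chain doubles back so both FPs sit beside each other
        gap = s.open_gap
        core = _snake_block(s.n_core - 4, 3, 3)
        core_len = core[:, 2].max()
        rb = _rot("z,x,y")
        b_box = core @ rb.T
        ra = _rot("-z,x,-y")
        t_a = np.array([core_len, 2 * lat + gap, 0.0])
        a_box = core @ ra.T + t_a
        hinge_inner = 8
        hinge_bulge = np.array([1.0, 0.0, 0.0])
        rfa = _rot("z,x,y")
        t_fa = np.array([-fp_zlen - 8.4, 6.0, -5.7])
        fa_box = fp @ rfa.T + t_fa
        rfd = _rot("z,-x,-y")
        t_fd = np.array([-fp_zlen - 8.4, t_a[1] + lat - 6.0, 5.7])
        fd_box = fp @ rfd.T + t_fd
    else:
        # the reduced-form domains behave as a single body: one merged
        # lattice block, entry at the bottom, exit at the top, so the FP
        # attachment points end up at opposite ends of the particle
        merged = _snake_block(2 * s.n_core, 3, 3)
        shift = s.closed_contact - lat
        if abs(shift) > 0.4:
            raise GenerationError(
                "closed_contact must stay within 0.4 A of the 3.8 A lattice "
                "spacing to keep the interface chain connected")
        merged = merged.copy()
        merged[s.n_core:, 2] += shift
        b_box = merged[:s.n_core]
        a_box = merged[s.n_core:]
        hinge_inner = 0
        hinge_bulge = np.array([1.0, 0.0, 0.0])
        rfa = _rot("x,y,z")
        t_fa = np.array([0.0, 0.0, -fp_zlen - 9.79])
        fa_box = fp @ rfa.T + t_fa
        # donor FP above the merged block on a near-straight linker arc
        a_exit_ = a_box[-1]
        reach = (s.linker2_len + 1) * lat
        chord_target = 0.92 * reach
        h2 = chord_target ** 2 - a_exit_[0] ** 2 - a_exit_[1] ** 2
        rfd = _rot("x,y,z")
        t_fd = np.array([0.0, 0.0, a_exit_[2] + np.sqrt(max(h2, 36.0))])
        fd_box = fp @ rfd.T + t_fd

    b_entry, b_exit = b_box[0], b_box[-1]
    a_entry, a_exit = a_box[0], a_box[-1]
    fa_exit = fa_box[-1]
    fd_entry = fd_box[0]

    def build(bulge_rotations: tuple[float, float, float]) -> np.ndarray:
        link1 = _arc_bridge(fa_exit, b_entry, s.linker1_len,
                            _spun(fa_exit, b_entry, np.array([0, 0, 1.0]),
                                  bulge_rotations[0]))
        link2 = _arc_bridge(a_exit, fd_entry, s.linker2_len,
                            _spun(a_exit, fd_entry, np.array([0, 0, 1.0]),
                                  bulge_rotations[2]))
        if hinge_inner:
            hinge = _arc_bridge(b_exit, a_entry, hinge_inner,
                                _spun(b_exit, a_entry, hinge_bulge,
                                      bulge_rotations[1]))
            mid = [b_box, hinge[:4], hinge[4:], a_box]
        else:
            mid = [b_box, a_box]
        return np.vstack([fa_box, link1] + mid + [link2, fd_box])

    coords = None
    for attempt in range(40):
        if attempt == 0:
            angles = (0.0, 0.0, 0.0)
        else:
            angles = tuple(rng.uniform(0, 2 * np.pi, size=3))
        try:
            cand = build(angles)
        except GenerationError:
            continue
        if _min_nonbonded(cand) >= 3.2:
            coords = cand
            break
    if coords is None:
        raise GenerationError("no clash-free dumbbell geometry found")

    segments = np.concatenate([
        np.full(s.n_fp, int(Segment.YFP)),
        np.full(s.linker1_len, int(Segment.LINKER1)),
        np.full(s.n_core, int(Segment.PDI_B)),
        np.full(s.n_core, int(Segment.PDI_A)),
        np.full(s.linker2_len, int(Segment.LINKER2)),
        np.full(s.n_fp, int(Segment.CFP)),
    ]).astype(np.int8)
    n_total = len(segments)
    names = [_RES_CYCLE[i % len(_RES_CYCLE)] for i in range(n_total)]
    donor_start = n_total - s.n_fp
    out = CGStructure(
        coords=coords,
        residue_names=names,
        segments=segments,
        chromophore_acceptor_idx=s.acceptor_chromophore_offset,
        dipole_ref_acceptor_idx=s.acceptor_dipole_ref_offset,
        chromophore_donor_idx=donor_start + s.donor_chromophore_offset,
        dipole_ref_donor_idx=donor_start + s.donor_dipole_ref_offset,
        redox_state="oxidized" if arrangement == "open" else "reduced",
        heavy=None,
    )
    out.validate()
    return out


def _spun(start: np.ndarray, end: np.ndarray, hint: np.ndarray,
          angle: float) -> np.ndarray:
    """Rotate a bulge hint about the anchor chord by ``angle``."""
    if angle == 0.0:
        return hint
    u = end - start
    u = u / np.linalg.norm(u)
    w = hint - (hint @ u) * u
    wn = np.linalg.norm(w)
    if wn < 1e-9:
        w = np.array([1.0, 0, 0]) if abs(u[0]) < 0.9 else np.array([0, 1.0, 0])
        w = w - (w @ u) * u
        wn = np.linalg.norm(w)
    w /= wn
    v = np.cross(u, w)
    return np.cos(angle) * w + np.sin(angle) * v


# ---------------------------------------------------------------------------
# Trajectories, spectra, titrations, time courses

def synth_two_state_trajectory(open_structure: CGStructure,
                               closed_frame: np.ndarray,
                               p_open: float, n_frames: int,
                               jitter: float = 0.5,
                               seed: int = 0
                               ) -> tuple[Trajectory, np.ndarray]:
    """Bernoulli mixture of the open and closed templates with bead jitter.

    Each frame is the open template (probability ``p_open``) or the closed
    one, plus isotropic Gaussian displacement of every bead (sigma =
    ``jitter`` A).  Returns the trajectory and the boolean per-frame state
    labels (True = open), which allow exact reconstruction of per-state
    statistics.
    """
    if not 0.0 <= p_open <= 1.0:
        raise ValueError("p_open must lie in [0, 1]")
    open_frame = open_structure.coords
    closed_frame = np.asarray(closed_frame, float)
    if closed_frame.shape != open_frame.shape:
        raise ValueError("open and closed templates are not conformable")
    rng = np.random.default_rng(seed)
    labels = rng.random(n_frames) < p_open
    frames = np.where(labels[:, None, None], open_frame[None],
                      closed_frame[None]).astype(np.float64)
    if jitter > 0:
        frames = frames + rng.normal(0.0, jitter, size=frames.shape)
    traj = Trajectory(frames=frames, energies=np.zeros(n_frames),
                      params=SimulationParams(n_steps=max(n_frames, 1),
                                              snapshot_interval=1,
                                              equilibration_fraction=0.0,
                                              rng_seed=seed),
                      structure=open_structure)
    return traj, labels


def synth_spectrum(target_ratio: float, width_donor: float = 25.0,
                   width_acceptor: float = 25.0, noise: float = 0.0,
                   seed: int = 0,
                   grid: Optional[np.ndarray] = None) -> EmissionSpectrum:
    """Two-Gaussian emission spectrum with an exact noiseless 530/475 ratio.

    The donor peak (475 nm, unit amplitude) and FRET peak (530 nm) are
    Gaussians on a 400-600 nm grid; the acceptor amplitude solves the
    closed form so that I(530)/I(475) of the noiseless construction equals
    ``target_ratio`` exactly.  Additive Gaussian noise (sd = ``noise`` in
    donor-amplitude units) is applied afterwards and clipped at zero.
    """
    if target_ratio <= 0:
        raise ValueError("target_ratio must be positive")
    w = np.arange(400.0, 601.0) if grid is None else np.asarray(grid, float)
    g_da = float(np.exp(-0.5 * ((530.0 - 475.0) / width_donor) ** 2))
    g_ad = float(np.exp(-0.5 * ((475.0 - 530.0) / width_acceptor) ** 2))
    denom = 1.0 - target_ratio * g_ad
    amp_a = (target_ratio - g_da) / denom
    if denom <= 0 or amp_a < 0:
        raise ValueError(
            f"target_ratio {target_ratio} infeasible for these peak widths")
    intens = (np.exp(-0.5 * ((w - 475.0) / width_donor) ** 2)
              + amp_a * np.exp(-0.5 * ((w - 530.0) / width_acceptor) ** 2))
    if noise > 0:
        rng = np.random.default_rng(seed)
        intens = np.clip(intens + rng.normal(0.0, noise, size=w.shape), 0.0,
                         None)
    return EmissionSpectrum(w, intens)


def synth_titration(truth: GroundTruth,
                    x_grid: Optional[np.ndarray] = None,
                    seed: Optional[int] = None,
                    gssg: float = 1e-3) -> list[TitrationPoint]:
    """Titration points from the two-state closed form with seeded noise.

    ``x_grid`` is the [GSH]^2/[GSSG] axis in molar (default: 12 points
    log-spaced over 1e-8..1e-4, four decades around the default K_eq of
    1e-6 M).  Ratios get multiplicative Gaussian noise of relative sd
    ``truth.noise``; GSH is back-solved from each x at fixed [GSSG].
    """
    if x_grid is None:
        x_grid = np.logspace(-8, -4, 12)
    x_grid = np.asarray(x_grid, float)
    if x_grid.size < 4 or np.any(x_grid <= 0):
        raise ValueError("x grid must hold >= 4 positive points")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    ratios = predict_ratio(x_grid, truth.as_fit())
    if truth.noise > 0:
        ratios = ratios * (1.0 + truth.noise * rng.standard_normal(x_grid.size))
    return [TitrationPoint(gsh=float(np.sqrt(x * gssg)), gssg=gssg,
                           observed_ratio=float(r))
            for x, r in zip(x_grid, ratios)]


def synth_timecourse(step_factor: float = 1.3, n_samples: int = 30,
                     dt: float = 20.0, stim_time: float = 120.0,
                     level: float = 0.9, noise: float = 0.0,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """FRET/CFP ratio time series with a known step response.

    Emulates imaging every ``dt`` seconds with a stimulus at
    ``stim_time``: the ratio steps from ``level`` to ``level *
    step_factor``, with optional multiplicative Gaussian noise.  Returns
    (times, ratios).
    """
    times = np.arange(n_samples) * dt
    ratios = np.where(times < stim_time, level, level * step_factor)
    if noise > 0:
        rng = np.random.default_rng(seed)
        ratios = ratios * (1.0 + noise * rng.standard_normal(n_samples))
    return times, ratios
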