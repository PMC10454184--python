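"""Per-snapshot FRET efficiency from chromophore dipole geometry.

Each fluorescent protein's transition dipole is approximated by the vector
from its chromophore Tyr/Trp C-alpha bead to its Ser147-equivalent C-alpha
bead.  For a donor/acceptor pair the transfer efficiency is

    E = 1 / (1 + r^6 / (R0^6 alpha)),      alpha = kappa^2 / (2/3)

with r the distance between the dipole origins and R0 the Foerster
distance at random orientation (53 A for the CFP/YFP pair used here).
kappa is the standard orientation factor

    kappa = d.a - 3 (d.R)(a.R)

for unit dipole directions d, a and unit separation vector R; kappa^2 lies
in [0, 4] and averages 2/3 over isotropic orientations, so alpha rescales
the efficiency relative to the random-orientation R0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .construct import CGStructure
from .simulate import Trajectory

__all__ = [
    "FRETParams",
    "EnsembleSummary",
    "DegenerateDipoleError",
    "dipole_vector",
    "kappa_squared",
    "fret_efficiency",
    "score_trajectory",
    "superpose_on_domain",
    "write_records",
    "write_summary",
]

TWO_THIRDS = 2.0 / 3.0


class DegenerateDipoleError(ValueError):
    """Raised when a dipole or separation vector has zero length."""


@dataclass(frozen=True)
class FRETParams:
    """Foerster parameters: R0 in Angstrom, threshold for the high-FRET tally."""

    R0: float = 53.0
    efficiency_threshold: float = 0.5
    histogram_bins: int = 50

    def __post_init__(self) -> None:
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")
        if not 0.0 < self.efficiency_threshold < 1.0:
            raise ValueError("efficiency_threshold must lie in (0, 1)")


@dataclass
class EnsembleSummary:
    """Distributional summary of per-frame efficiencies."""

    n_frames: int
    mean_efficiency: float
    median_efficiency: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    fraction_above_threshold: float
    threshold: float


def dipole_vector(coords: np.ndarray, chromophore_idx: int,
                  ref_idx: int) -> tuple[np.ndarray, np.ndarray]:
    """Dipole origin (at the chromophore bead) and unit direction.

    The direction points from the chromophore C-alpha to the
    Ser147-equivalent C-alpha.  Coincident beads raise
    :class:`DegenerateDipoleError`.
    """
    coords = np.asarray(coords, dtype=np.float64)
    origin = coords[chromophore_idx]
    vec = coords[ref_idx] - origin
    norm = np.linalg.norm(vec)
    if norm < 1e-9:
        raise DegenerateDipoleError(
            f"beads {chromophore_idx} and {ref_idx} are coincident")
    return origin, vec / norm


def kappa_squared(donor_origin: np.ndarray, donor_dir: np.ndarray,
                  acceptor_origin: np.ndarray,
                  acceptor_dir: np.ndarray) -> float:
    """Orientation factor kappa^2 = (d.a - 3 (d.R)(a.R))^2 in [0, 4]."""
    r = np.asarray(acceptor_origin, float) - np.asarray(donor_origin, float)
    dist = np.linalg.norm(r)
    if dist < 1e-9:
        raise DegenerateDipoleError("dipole origins are coincident")
    rhat = r / dist
    d = np.asarray(donor_dir, float)
    a = np.asarray(acceptor_dir, float)
    kappa = d @ a - 3.0 * (d @ rhat) * (a @ rhat)
    k2 = float(kappa * kappa)
    return min(k2, 4.0)


def fret_efficiency(r: float, kappa2: float,
                    params: FRETParams = FRETParams()) -> float:
    """Transfer efficiency E = 1 / (1 + r^6 / (R0^6 alpha)).

    ``alpha = kappa2 / (2/3)``; a vanishing kappa^2 yields E = 0 directly
    (no transfer for perpendicular dipoles) instead of a singularity.
    E is strictly decreasing in r for fixed alpha > 0.
    """
    if r <= 0:
        raise ValueError("dipole distance must be positive")
    if kappa2 < 0:
        raise ValueError("kappa2 must be non-negative")
    if kappa2 == 0.0:
        return 0.0
    alpha = kappa2 / TWO_THIRDS
    return float(1.0 / (1.0 + r**6 / (params.R0**6 * alpha)))


def _frame_record(coords: np.ndarray, structure: CGStructure,
                  params: FRETParams) -> tuple[float, float, float, float]:
    d_origin, d_dir = dipole_vector(coords, structure.chromophore_donor_idx,
                                    structure.dipole_ref_donor_idx)
    a_origin, a_dir = dipole_vector(coords, structure.chromophore_acceptor_idx,
                                    structure.dipole_ref_acceptor_idx)
    r = float(np.linalg.norm(a_origin - d_origin))
    k2 = kappa_squared(d_origin, d_dir, a_origin, a_dir)
    eff = fret_efficiency(r, k2, params)
    return r, k2, k2 / TWO_THIRDS, eff


def score_trajectory(traj: Trajectory, structure: Optional[CGStructure] = None,
                     params: FRETParams = FRETParams()
                     ) -> tuple[pd.DataFrame, EnsembleSummary]:
    """Per-frame FRET records and an ensemble summary.

    Returns a DataFrame with columns ``frame, r, kappa2, alpha, efficiency``
    (one row per analysis frame) and an :class:`EnsembleSummary` whose
    ``fraction_above_threshold`` reproduces the high-FRET proportion
    statistic (fraction of snapshots with E above the threshold, 0.5 by
    default).
    """
    structure = structure if structure is not None else traj.structure
    if structure is None:
        raise ValueError("a structure with chromophore indices is required")
    for name in ("chromophore_donor_idx", "dipole_ref_donor_idx",
                 "chromophore_acceptor_idx", "dipole_ref_acceptor_idx"):
        if getattr(structure, name) is None:
            raise ValueError(f"structure lacks {name}")

    rows = [(f, *_frame_record(traj.frames[f], structure, params))
            for f in range(traj.n_frames)]
    records = pd.DataFrame(rows, columns=["frame", "r", "kappa2", "alpha",
                                          "efficiency"])
    eff = records["efficiency"].to_numpy()
    counts, edges = np.histogram(eff, bins=params.histogram_bins,
                                 range=(0.0, 1.0))
    summary = EnsembleSummary(
        n_frames=len(eff),
        mean_efficiency=float(eff.mean()) if len(eff) else float("nan"),
        median_efficiency=float(np.median(eff)) if len(eff) else float("nan"),
        hist_edges=edges,
        hist_counts=counts,
        fraction_above_threshold=float(
            np.count_nonzero(eff > params.efficiency_threshold) / len(eff))
        if len(eff) else float("nan"),
        threshold=params.efficiency_threshold,
    )
    return records, summary


def superpose_on_domain(traj: Trajectory, segment_idx: np.ndarray) -> Trajectory:
    """Rigid-body align every frame onto the first frame's segment (Kabsch).

    ``segment_idx`` selects the reference beads (at least three,
    non-collinear).  The whole frame is moved with the segment's optimal
    rotation/translation, so all internal geometry -- including r, kappa^2
    and E -- is unchanged; only the viewing frame is fixed, as when
    ensembles are displayed superimposed on the b' domain.
    """
    segment_idx = np.asarray(segment_idx, dtype=int)
    if segment_idx.size < 3:
        raise ValueError("need at least 3 beads to superpose")
    ref = traj.frames[0][segment_idx]
    ref_c = ref.mean(axis=0)
    sing = np.linalg.svd(ref - ref_c, compute_uv=False)
    if sing[1] < 1e-8 * max(sing[0], 1.0):
        raise ValueError("segment beads are (nearly) collinear")

    out = np.empty_like(traj.frames)
    for f in range(traj.n_frames):
        mobile = traj.frames[f][segment_idx]
        mob_c = mobile.mean(axis=0)
        h = (mobile - mob_c).T @ (ref - ref_c)
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
        out[f] = (traj.frames[f] - mob_c) @ rot.T + ref_c
    return Trajectory(frames=out, energies=traj.energies.copy(),
                      params=traj.params, structure=traj.structure,
                      velocities=traj.velocities,
                      step_indices=traj.step_indices)


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Per-frame records as TSV (frame, r, kappa2, alpha, efficiency)."""
    records.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_summary(summary: EnsembleSummary, json_path: str | Path,
                  hist_csv_path: Optional[str | Path] = None) -> None:
    """Summary as JSON; optionally the histogram as two-column CSV."""
    import json

    payload = {
        "n_frames": summary.n_frames,
        "mean_efficiency": summary.mean_efficiency,
        "median_efficiency": summary.median_efficiency,
        "fraction_above_threshold": summary.fraction_above_threshold,
        "threshold": summary.threshold,
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2)
    if hist_csv_path is not None:
        pd.DataFrame({
            "bin_left": summary.hist_edges[:-1],
            "bin_right": summary.hist_edges[1:],
            "count": summary.hist_counts,
        }).to_csv(hist_csv_path, index=False)
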