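"""Shared fixtures: toy structures, synthetic dumbbells, desk-scale runs."""

from __future__ import annotations

import numpy as np
import pytest

from fretforge import (
    CGStructure,
    DumbbellSpec,
    SimulationParams,
    Segment,
    derive_topology,
    make_dumbbell,
    run_langevin,
)


def make_chain(coords: np.ndarray) -> CGStructure:
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    return CGStructure(coords=coords, residue_names=["ALA"] * n,
                       segments=np.zeros(n, dtype=np.int8))


def random_compact_chain(rng: np.random.Generator, n: int = 10) -> CGStructure:
    """Random self-avoiding-ish chain with 3.8 A bonds for force tests."""
    coords = [np.zeros(3)]
    while len(coords) < n:
        step = rng.standard_normal(3)
        step *= 3.8 / np.linalg.norm(step)
        cand = coords[-1] + step
        if all(np.linalg.norm(cand - c) > 3.0 for c in coords[:-1]):
            coords.append(cand)
    return make_chain(np.asarray(coords))


def fp_rmsd_series(frames: np.ndarray, ref: np.ndarray,
                   idx: np.ndarray) -> np.ndarray:
    """Per-frame RMSD of a bead subset after optimal superposition."""
    ref_seg = ref[idx]
    c_ref = ref_seg.mean(axis=0)
    out = []
    for fr in frames:
        m = fr[idx]
        c_m = m.mean(axis=0)
        h = (m - c_m).T @ (ref_seg - c_ref)
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
        out.append(np.sqrt((((m - c_m) @ rot.T - (ref_seg - c_ref)) ** 2)
                           .sum(axis=1).mean()))
    return np.asarray(out)


@pytest.fixture(scope="session")
def dumbbell_spec() -> DumbbellSpec:
    return DumbbellSpec(rng_seed=1)


@pytest.fixture(scope="session")
def open_dumbbell(dumbbell_spec):
    return make_dumbbell(dumbbell_spec, "open")


@pytest.fixture(scope="session")
def closed_dumbbell(dumbbell_spec):
    return make_dumbbell(dumbbell_spec, "closed")


@pytest.fixture(scope="session")
def desk_scale_ensembles(open_dumbbell, closed_dumbbell):
    """1e5-step Langevin ensembles of both arrangements (run once)."""
    out = {}
    for name, structure, scale in (("open", open_dumbbell, 0.0),
                                   ("closed", closed_dumbbell, 1.0)):
        topo = derive_topology(structure, interdomain_scale=scale)
        params = SimulationParams(n_steps=100_000, snapshot_interval=100,
                                  rng_seed=11)
        out[name] = run_langevin(structure, topo, params)
    return out


TOY_PDB_3RES = """\
ATOM      1  N   ALA A   1      -1.000   0.500   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      4  CB  GLY A   2       4.200   1.200   0.500  1.00  0.00           C
ATOM      5  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""

TOY_PDB_1RES = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
END
"""

TOY_PDB_NO_CA = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  N   GLY A   2       3.800   0.000   0.000  1.00  0.00           N
ATOM      3  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""
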