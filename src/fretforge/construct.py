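"""Build coarse-grained models of FP-flanked PDI-b'a' fusion constructs.

This module turns reference coordinates (PDB files or synthetic templates)
into a one-bead-per-residue chain for the fusion construct

    YFP -- linker1 -- PDI-b' -- PDI-a' -- linker2 -- CFP

and derives the structure-based ("Go-model") topology that the Langevin
simulator integrates: harmonic bonds/angles, cosine dihedrals, a 12-10
native-contact attraction and a repulsive excluded-volume background.

Coordinates are Angstrom throughout.  Residue indices are 0-based in memory
and 1-based in every file written or read.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.spatial.distance import cdist

__all__ = [
    "Segment",
    "ResidueBead",
    "CGStructure",
    "ConstructSpec",
    "Topology",
    "PDBFormatError",
    "EmptySelectionError",
    "AssemblyError",
    "read_reference_pdb",
    "assemble_fusion",
    "derive_topology",
    "write_structure_pdb",
    "read_structure_pdb",
    "write_topology",
    "read_topology",
]

# Geometry and force-field defaults (reduced energy units; kT at 300 K == 1).
CA_SPACING = 3.8          # ideal consecutive C-alpha distance, Angstrom
BOND_MIN, BOND_MAX = 2.8, 4.2   # tolerated consecutive spacing after assembly
HEAVY_CONTACT_CUTOFF = 4.5      # native contact if any heavy-atom pair closer
CA_CONTACT_CUTOFF = 6.5         # fallback when only C-alpha coordinates exist
MIN_CONTACT_SEPARATION = 4      # |i - j| >= 4 for native contacts
DEFAULT_EPS_CONTACT = 1.0       # uniform native-contact well depth (~1 kT at 300 K)
DEFAULT_K_BOND = 100.0          # per Angstrom^2
DEFAULT_K_ANGLE = 20.0          # per rad^2
DEFAULT_K_DIHEDRAL = 1.0
DEFAULT_SIGMA_EV = 4.0          # excluded-volume radius, Angstrom
DEFAULT_EPS_EV = 0.2

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


class PDBFormatError(ValueError):
    """Raised when a coordinate file cannot be parsed as PDB."""


class EmptySelectionError(ValueError):
    """Raised when a chain/model selection matches no usable residue."""


class AssemblyError(RuntimeError):
    """Raised when a clash-free fusion geometry cannot be found."""


class Segment(IntEnum):
    """Contiguous segments of the fusion chain, in N->C order."""

    YFP = 0       # acceptor fluorescent protein (N-terminal)
    LINKER1 = 1   # "LE" in the reference construct
    PDI_B = 2     # b' domain
    PDI_A = 3     # a' domain
    LINKER2 = 4   # "AGGR" in the reference construct
    CFP = 5       # donor fluorescent protein (C-terminal)


@dataclass(frozen=True)
class ResidueBead:
    """One residue of the coarse-grained chain."""

    index: int
    residue_name: str
    segment: Segment
    coords: np.ndarray


@dataclass
class CGStructure:
    """Array-backed one-bead-per-residue model.

    ``heavy`` optionally retains the heavy-atom coordinates of each residue
    (list of (m_i, 3) arrays) so native contacts can be derived from
    all-atom geometry; synthetic structures carry ``heavy=None`` and fall
    back to the C-alpha contact rule.  ``modeled`` marks residues placed by
    the assembler (linkers, completed missing residues); they receive
    bonded terms only, never native contacts.
    """

    coords: np.ndarray                      # (n, 3) float64, Angstrom
    residue_names: list[str]
    segments: np.ndarray                    # (n,) int codes from Segment
    chromophore_donor_idx: Optional[int] = None
    chromophore_acceptor_idx: Optional[int] = None
    dipole_ref_donor_idx: Optional[int] = None
    dipole_ref_acceptor_idx: Optional[int] = None
    redox_state: str = "none"               # oxidized | reduced | none
    heavy: Optional[list[Optional[np.ndarray]]] = None
    modeled: Optional[np.ndarray] = None    # (n,) bool

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.segments = np.asarray(self.segments, dtype=np.int8)
        if self.modeled is None:
            self.modeled = np.zeros(self.n_beads, dtype=bool)
        if self.redox_state not in ("oxidized", "reduced", "none"):
            raise ValueError(f"unknown redox_state {self.redox_state!r}")

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    @property
    def beads(self) -> list[ResidueBead]:
        return [
            ResidueBead(i, self.residue_names[i], Segment(int(self.segments[i])),
                        self.coords[i])
            for i in range(self.n_beads)
        ]

    def segment_indices(self, segment: Segment) -> np.ndarray:
        """0-based bead indices belonging to one segment."""
        return np.flatnonzero(self.segments == int(segment))

    def validate(self, check_spacing: bool = True) -> None:
        """Check the chain invariants; raise ``ValueError`` on violation."""
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite bead coordinates")
        if len(self.residue_names) != self.n_beads:
            raise ValueError("residue_names length mismatch")
        if check_spacing and self.n_beads > 1:
            d = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
            if d.min() < BOND_MIN or d.max() > BOND_MAX:
                raise ValueError(
                    f"consecutive bead spacing outside [{BOND_MIN}, {BOND_MAX}] A "
                    f"(min {d.min():.2f}, max {d.max():.2f})")
        # segment codes must be non-decreasing => contiguous in declared order
        if np.any(np.diff(self.segments) < 0):
            raise ValueError("segments are not contiguous in N->C order")
        for idx, seg in (
            (self.chromophore_acceptor_idx, Segment.YFP),
            (self.dipole_ref_acceptor_idx, Segment.YFP),
            (self.chromophore_donor_idx, Segment.CFP),
            (self.dipole_ref_donor_idx, Segment.CFP),
        ):
            if idx is not None and int(self.segments[idx]) != int(seg):
                raise ValueError(
                    f"index {idx} does not fall inside its {seg.name} segment")


@dataclass
class ConstructSpec:
    """Sequence-level description of the fusion construct.

    The reference probe places the YFP variant (YPet) N-terminal and the
    CFP variant (Turquoise-GL) C-terminal, joined to the PDI b'a' fragment
    (source residues 208-449, 242 residues) by the linkers "LE" and "AGGR".
    FP sequences are user input; chromophore/Ser147-equivalent positions are
    0-based offsets within each FP segment.  ``cp_offset`` applies a
    circular permutation to the acceptor FP (sequence rotation plus
    relocated offsets, bookkeeping only).
    """

    yfp_seq: str
    cfp_seq: str
    linker1: str = "LE"
    linker2: str = "AGGR"
    core_span: tuple[int, int] = (208, 449)   # 1-based, inclusive, source numbering
    core_domain_boundary: int = 121           # 0-based index in core where a' starts
    yfp_chromophore_offset: int = 0
    yfp_dipole_ref_offset: int = 0
    cfp_chromophore_offset: int = 0
    cfp_dipole_ref_offset: int = 0
    cp_offset: int = 0

    def __post_init__(self) -> None:
        if self.cp_offset:
            n = len(self.yfp_seq)
            k = self.cp_offset % n
            self.yfp_seq = self.yfp_seq[k:] + self.yfp_seq[:k]
            self.yfp_chromophore_offset = (self.yfp_chromophore_offset - k) % n
            self.yfp_dipole_ref_offset = (self.yfp_dipole_ref_offset - k) % n
            self.cp_offset = 0

    @property
    def core_length(self) -> int:
        lo, hi = self.core_span
        return hi - lo + 1

    @property
    def total_length(self) -> int:
        return (len(self.yfp_seq) + len(self.linker1) + self.core_length
                + len(self.linker2) + len(self.cfp_seq))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ConstructSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        seg = raw.get("segments", raw)
        fps = raw.get("fluorophores", {})
        kwargs = dict(
            yfp_seq=seg["yfp_seq"],
            cfp_seq=seg["cfp_seq"],
            linker1=seg.get("linker1", "LE"),
            linker2=seg.get("linker2", "AGGR"),
        )
        if "core_span" in seg:
            kwargs["core_span"] = tuple(seg["core_span"])
        if "core_domain_boundary" in seg:
            kwargs["core_domain_boundary"] = int(seg["core_domain_boundary"])
        for key in ("yfp_chromophore_offset", "yfp_dipole_ref_offset",
                    "cfp_chromophore_offset", "cfp_dipole_ref_offset",
                    "cp_offset"):
            if key in fps:
                kwargs[key] = int(fps[key])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "segments": {
                "yfp_seq": self.yfp_seq,
                "cfp_seq": self.cfp_seq,
                "linker1": self.linker1,
                "linker2": self.linker2,
                "core_span": list(self.core_span),
                "core_domain_boundary": self.core_domain_boundary,
            },
            "fluorophores": {
                "yfp_chromophore_offset": self.yfp_chromophore_offset,
                "yfp_dipole_ref_offset": self.yfp_dipole_ref_offset,
                "cfp_chromophore_offset": self.cfp_chromophore_offset,
                "cfp_dipole_ref_offset": self.cfp_dipole_ref_offset,
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class Topology:
    """Bonded terms plus native contacts of the structure-based potential.

    All index arrays are 0-based; :func:`write_topology` emits 1-based
    records.  Contact pairs are stored once with i < j; ``contact_inter``
    flags pairs spanning the b'/a' domain boundary.
    """

    bond_idx: np.ndarray       # (nb, 2) int
    bond_r0: np.ndarray
    bond_k: np.ndarray
    angle_idx: np.ndarray      # (na, 3)
    angle_t0: np.ndarray       # rad
    angle_k: np.ndarray
    dihedral_idx: np.ndarray   # (nd, 4)
    dihedral_p0: np.ndarray    # rad
    dihedral_k: np.ndarray
    contact_idx: np.ndarray    # (nc, 2)
    contact_r0: np.ndarray
    contact_eps: np.ndarray
    contact_inter: np.ndarray  # (nc,) bool
    sigma_ev: float = DEFAULT_SIGMA_EV
    eps_ev: float = DEFAULT_EPS_EV

    def __post_init__(self) -> None:
        for name in ("bond_idx", "angle_idx", "dihedral_idx", "contact_idx"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        for name in ("bond_r0", "bond_k", "angle_t0", "angle_k",
                     "dihedral_p0", "dihedral_k", "contact_r0", "contact_eps"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        self.contact_inter = np.asarray(self.contact_inter, dtype=bool)
        self._check()

    def _check(self) -> None:
        if self.contact_idx.size:
            i, j = self.contact_idx.T
            if np.any(j - i < MIN_CONTACT_SEPARATION):
                raise ValueError("contact pair with |i-j| < 4")
            if np.any(self.contact_r0 <= 0):
                raise ValueError("contact with nonpositive r0")
            keys = i * (self.contact_idx.max() + 1) + j
            if len(np.unique(keys)) != len(keys):
                raise ValueError("duplicate contact pair")

    @property
    def n_contacts(self) -> int:
        return int(self.contact_idx.shape[0])

    @property
    def n_interdomain(self) -> int:
        return int(self.contact_inter.sum())


# ---------------------------------------------------------------------------
# PDB input

def read_reference_pdb(path: str | Path, chain: Optional[str] = None,
                       model: int = 1) -> CGStructure:
    """Coarse-grain a PDB file: one bead per residue at the C-alpha position.

    Residues lacking a C-alpha atom are skipped with a warning.  Heavy-atom
    coordinates of each kept residue are retained for contact derivation.
    Alternate locations resolve to the first occupancy ('A' preferred);
    insertion codes are honored when grouping residues.

    Parameters
    ----------
    path : PDB file path.
    chain : chain identifier; default is the first chain in the file.
    model : 1-based model number.
    """
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=model, altloc="first")
    except Exception as exc:  # noqa: BLE001 - biotite raises assorted types
        raise PDBFormatError(f"cannot parse {path!s} as PDB: {exc}") from exc
    if atoms.array_length() == 0:
        raise EmptySelectionError(f"{path!s} contains no atoms")

    if chain is None:
        chain = str(atoms.chain_id[0])
    mask = atoms.chain_id == chain
    # drop waters and hydrogens; keep standard + het residues with a CA
    mask &= atoms.res_name != "HOH"
    mask &= atoms.element != "H"
    sel = atoms[mask]
    if sel.array_length() == 0:
        raise EmptySelectionError(f"chain {chain!r} has no heavy atoms")

    coords, names, heavy = [], [], []
    n_skipped = 0
    # group by (res_id, ins_code) in file order
    res_keys = list(zip(sel.res_id.tolist(), sel.ins_code.tolist()))
    seen: dict[tuple, list[int]] = {}
    order: list[tuple] = []
    for k, key in enumerate(res_keys):
        if key not in seen:
            seen[key] = []
            order.append(key)
        seen[key].append(k)
    for key in order:
        idx = np.array(seen[key])
        res_atoms = sel[idx]
        ca = res_atoms[res_atoms.atom_name == "CA"]
        if ca.array_length() == 0:
            n_skipped += 1
            continue
        coords.append(np.asarray(ca.coord[0], dtype=np.float64))
        names.append(str(res_atoms.res_name[0]))
        heavy.append(np.asarray(res_atoms.coord, dtype=np.float64))
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} residue(s) without a C-alpha atom",
                      stacklevel=2)
    if not coords:
        raise EmptySelectionError(f"chain {chain!r} has no residue with a C-alpha")

    n = len(coords)
    return CGStructure(
        coords=np.vstack(coords),
        residue_names=names,
        segments=np.full(n, int(Segment.PDI_B), dtype=np.int8),
        heavy=heavy,
    )


# ---------------------------------------------------------------------------
# Fusion assembly

def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(
        rng.integers(0, 2**31 - 1))).as_matrix()


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    if a.size == 0 or b.size == 0:
        return np.inf
    return float(cdist(a, b).min())


def _grow_extended(anchor: np.ndarray, preferred: np.ndarray, n: int,
                   existing: np.ndarray, sigma: float,
                   rng: np.random.Generator, max_tries: int = 200) -> np.ndarray:
    """Place ``n`` beads in a straight line from ``anchor`` at 3.8 A spacing,
    avoiding approaches closer than ``sigma`` to ``existing`` beads."""
    if n == 0:
        return np.zeros((0, 3))
    direction = preferred / np.linalg.norm(preferred)
    for attempt in range(max_tries):
        steps = np.arange(1, n + 1)[:, None] * CA_SPACING * direction[None, :]
        cand = anchor[None, :] + steps
        # the first new bead is bonded to the anchor, so exempt that pair
        if _min_dist(cand, existing[:-1]) >= sigma and \
           _min_dist(cand[1:], existing[-1:]) >= sigma:
            return cand
        direction = _random_unit(rng)
    raise AssemblyError(f"could not place {n} extended beads without clashes")


def _place_rigid(domain: np.ndarray, anchor: np.ndarray, preferred: np.ndarray,
                 existing: np.ndarray, sigma: float,
                 rng: np.random.Generator, max_tries: int = 200) -> np.ndarray:
    """Rigidly place a domain so its first bead bonds to ``anchor``.

    The domain is translated so bead 0 sits one bond length from the anchor
    along a trial direction, then rotated about bead 0 until no bead comes
    closer than ``sigma`` to the existing chain (the bonded first bead is
    exempt from the check against the anchor itself).
    """
    direction = preferred / np.linalg.norm(preferred)
    local = domain - domain[0]
    rot = np.eye(3)
    for attempt in range(max_tries):
        origin = anchor + CA_SPACING * direction
        cand = origin[None, :] + local @ rot.T
        # ignore the unavoidable proximity of the junction bead to the anchor
        if _min_dist(cand, existing[:-1]) >= sigma and \
           _min_dist(cand[1:], existing[-1:]) >= sigma:
            return cand
        rot = _random_rotation(rng)
        if attempt % 4 == 3:
            direction = _random_unit(rng)
    raise AssemblyError("could not place domain without steric clashes")


def assemble_fusion(spec: ConstructSpec, core: CGStructure,
                    donor_fp: CGStructure, acceptor_fp: CGStructure,
                    rng_seed: int = 0,
                    sigma: float = DEFAULT_SIGMA_EV) -> CGStructure:
    """Assemble acceptor-FP -- linker1 -- core -- linker2 -- donor-FP.

    The acceptor FP (YFP) is N-terminal and the donor FP (CFP) C-terminal.
    Missing FP residues (sequence longer than the reference structure, e.g.
    the seven-residue YFP C-terminal completion) and linker residues are
    placed along extended geometry at 3.8 A spacing; the core and donor FP
    are rigidly attached with clash-avoiding seeded retries, so the result
    is deterministic for a given ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)

    n_acc, n_core, n_don = acceptor_fp.n_beads, core.n_beads, donor_fp.n_beads
    if n_core != spec.core_length:
        raise AssemblyError(
            f"core has {n_core} beads but spec.core_span implies {spec.core_length}")
    missing_acc = spec.yfp_seq[n_acc:] if len(spec.yfp_seq) > n_acc else ""
    missing_don = spec.cfp_seq[n_don:] if len(spec.cfp_seq) > n_don else ""

    coords = acceptor_fp.coords - acceptor_fp.coords.mean(axis=0)
    names = list(acceptor_fp.residue_names)
    heavy: list[Optional[np.ndarray]] = (
        [h - acceptor_fp.coords.mean(axis=0) for h in acceptor_fp.heavy]
        if acceptor_fp.heavy is not None else [None] * n_acc)
    modeled = [False] * n_acc
    segments = [int(Segment.YFP)] * n_acc

    def tail_direction() -> np.ndarray:
        if coords.shape[0] >= 2:
            d = coords[-1] - coords[-2]
            nrm = np.linalg.norm(d)
            if nrm > 1e-9:
                return d / nrm
        return _random_unit(rng)

    def append_extended(seq: str, segment: Segment) -> None:
        nonlocal coords
        new = _grow_extended(coords[-1], tail_direction(), len(seq), coords,
                             sigma, rng)
        coords = np.vstack([coords, new])
        names.extend(_AA3.get(c, "UNK") for c in seq)
        heavy.extend([None] * len(seq))
        modeled.extend([True] * len(seq))
        segments.extend([int(segment)] * len(seq))

    def append_rigid(dom: CGStructure, segment_codes: Sequence[int]) -> None:
        nonlocal coords
        placed = _place_rigid(dom.coords, coords[-1], tail_direction(), coords,
                              sigma, rng)
        coords = np.vstack([coords, placed])
        names.extend(dom.residue_names)
        if dom.heavy is not None:
            # transform heavy atoms with the same rigid map (affine from 3+ beads)
            heavy.extend(_transform_heavy(dom, placed))
        else:
            heavy.extend([None] * dom.n_beads)
        modeled.extend([False] * dom.n_beads)
        segments.extend(list(segment_codes))

    # YFP C-terminal completion (e.g. EGMNELY), still part of the YFP segment
    if missing_acc:
        append_extended(missing_acc, Segment.YFP)
    append_extended(spec.linker1, Segment.LINKER1)
    b = spec.core_domain_boundary
    core_codes = [int(Segment.PDI_B)] * b + [int(Segment.PDI_A)] * (n_core - b)
    append_rigid(core, core_codes)
    append_extended(spec.linker2, Segment.LINKER2)
    append_rigid(donor_fp, [int(Segment.CFP)] * n_don)
    if missing_don:
        append_extended(missing_don, Segment.CFP)

    seg_arr = np.asarray(segments, dtype=np.int8)
    yfp_idx = np.flatnonzero(seg_arr == int(Segment.YFP))
    cfp_idx = np.flatnonzero(seg_arr == int(Segment.CFP))
    out = CGStructure(
        coords=coords,
        residue_names=names,
        segments=seg_arr,
        chromophore_acceptor_idx=int(yfp_idx[0] + spec.yfp_chromophore_offset),
        dipole_ref_acceptor_idx=int(yfp_idx[0] + spec.yfp_dipole_ref_offset),
        chromophore_donor_idx=int(cfp_idx[0] + spec.cfp_chromophore_offset),
        dipole_ref_donor_idx=int(cfp_idx[0] + spec.cfp_dipole_ref_offset),
        redox_state=core.redox_state,
        heavy=heavy if any(h is not None for h in heavy) else None,
        modeled=np.asarray(modeled, dtype=bool),
    )
    out.validate()
    return out


def _transform_heavy(dom: CGStructure, placed: np.ndarray) -> list:
    """Apply the bead-coordinate rigid map to each residue's heavy atoms."""
    src = dom.coords
    # least-squares rigid transform src -> placed (Kabsch)
    c_src, c_dst = src.mean(axis=0), placed.mean(axis=0)
    h = (src - c_src).T @ (placed - c_dst)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    out = []
    for arr in dom.heavy:  # type: ignore[union-attr]
        if arr is None:
            out.append(None)
        else:
            out.append((arr - c_src) @ rot.T + c_dst)
    return out


# ---------------------------------------------------------------------------
# Topology derivation

def derive_topology(structure: CGStructure,
                    contact_cutoff: Optional[float] = None,
                    eps: float = DEFAULT_EPS_CONTACT,
                    interdomain_scale: float = 1.0,
                    k_bond: float = DEFAULT_K_BOND,
                    k_angle: float = DEFAULT_K_ANGLE,
                    k_dihedral: float = DEFAULT_K_DIHEDRAL,
                    sigma_ev: float = DEFAULT_SIGMA_EV,
                    eps_ev: float = DEFAULT_EPS_EV) -> Topology:
    """Derive the structure-based topology from an assembled structure.

    Bonds, angles and dihedrals cover every consecutive bead run with native
    values taken from the input coordinates.  Native contacts join residue
    pairs with |i-j| >= 4 whose minimum heavy-atom distance is below the
    cutoff (default 4.5 A); when heavy atoms are absent for either residue
    the C-alpha distance is used with a 6.5 A default cutoff.  Contacts are
    never anchored in linker or assembler-modeled beads.  Contacts spanning
    the b'/a' boundary are flagged interdomain and their well depth is
    multiplied by ``interdomain_scale`` (0 removes them from the energy
    while keeping them excluded from the excluded-volume background).
    """
    x = structure.coords
    n = structure.n_beads
    seg = structure.segments
    modeled = structure.modeled

    bond_idx = np.column_stack([np.arange(n - 1), np.arange(1, n)]) \
        if n > 1 else np.zeros((0, 2), int)
    bond_r0 = np.linalg.norm(x[1:] - x[:-1], axis=1) if n > 1 else np.zeros(0)

    if n > 2:
        angle_idx = np.column_stack([np.arange(n - 2), np.arange(1, n - 1),
                                     np.arange(2, n)])
        u = x[angle_idx[:, 0]] - x[angle_idx[:, 1]]
        v = x[angle_idx[:, 2]] - x[angle_idx[:, 1]]
        cosang = np.einsum("ij,ij->i", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
        angle_t0 = np.arccos(np.clip(cosang, -1.0, 1.0))
    else:
        angle_idx = np.zeros((0, 3), int)
        angle_t0 = np.zeros(0)

    if n > 3:
        dihedral_idx = np.column_stack([np.arange(n - 3), np.arange(1, n - 2),
                                        np.arange(2, n - 1), np.arange(3, n)])
        dihedral_p0 = _dihedral_angles(x, dihedral_idx)
    else:
        dihedral_idx = np.zeros((0, 4), int)
        dihedral_p0 = np.zeros(0)

    # native contacts
    linkerish = (np.isin(seg, [int(Segment.LINKER1), int(Segment.LINKER2)])
                 | modeled)
    use_heavy = structure.heavy is not None
    cutoff = contact_cutoff if contact_cutoff is not None else (
        HEAVY_CONTACT_CUTOFF if use_heavy else CA_CONTACT_CUTOFF)
    ca_d = cdist(x, x)
    # prefilter: heavy-atom minimum distance cannot be below cutoff if the
    # C-alpha distance exceeds cutoff + 2 * max residue radius (~12 A margin)
    prefilter = cutoff + 12.0 if use_heavy else cutoff
    ci, cj, cr0, cinter = [], [], [], []
    for i in range(n - MIN_CONTACT_SEPARATION):
        if linkerish[i]:
            continue
        for j in range(i + MIN_CONTACT_SEPARATION, n):
            if linkerish[j] or ca_d[i, j] >= prefilter:
                continue
            if use_heavy:
                hi = structure.heavy[i] if structure.heavy[i] is not None else x[i:i + 1]
                hj = structure.heavy[j] if structure.heavy[j] is not None else x[j:j + 1]
                dmin = _min_dist(hi, hj)
            else:
                dmin = ca_d[i, j]
            if dmin < cutoff:
                ci.append(i)
                cj.append(j)
                cr0.append(ca_d[i, j])
                cinter.append(
                    (seg[i] == int(Segment.PDI_B) and seg[j] == int(Segment.PDI_A))
                    or (seg[i] == int(Segment.PDI_A) and seg[j] == int(Segment.PDI_B)))
    contact_idx = np.column_stack([ci, cj]) if ci else np.zeros((0, 2), int)
    contact_inter = np.asarray(cinter, dtype=bool)
    contact_eps = np.full(len(ci), eps)
    contact_eps[contact_inter] *= interdomain_scale

    return Topology(
        bond_idx=bond_idx, bond_r0=bond_r0,
        bond_k=np.full(len(bond_r0), k_bond),
        angle_idx=angle_idx, angle_t0=angle_t0,
        angle_k=np.full(len(angle_t0), k_angle),
        dihedral_idx=dihedral_idx, dihedral_p0=dihedral_p0,
        dihedral_k=np.full(len(dihedral_p0), k_dihedral),
        contact_idx=contact_idx, contact_r0=np.asarray(cr0),
        contact_eps=contact_eps, contact_inter=contact_inter,
        sigma_ev=sigma_ev, eps_ev=eps_ev,
    )


def _dihedral_angles(x: np.ndarray, quads: np.ndarray) -> np.ndarray:
    b1 = x[quads[:, 1]] - x[quads[:, 0]]
    b2 = x[quads[:, 2]] - x[quads[:, 1]]
    b3 = x[quads[:, 3]] - x[quads[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, n2)
    sin_t = np.einsum("ij,ij->i", m, b2) / np.linalg.norm(b2, axis=1)
    return np.arctan2(sin_t, np.einsum("ij,ij->i", n1, n2))


# ---------------------------------------------------------------------------
# File output

_SEGMENT_CHAIN = {s: c for s, c in zip(Segment, "ABCDEF")}
_CHAIN_SEGMENT = {c: s for s, c in _SEGMENT_CHAIN.items()}


def write_structure_pdb(structure: CGStructure, path: str | Path,
                        frames: Optional[np.ndarray] = None) -> None:
    """Write the bead model as CA-only PDB (multi-model if ``frames`` given).

    Segments map to chain identifiers A..F in segment-enum order, so a
    round trip through :func:`read_structure_pdb` restores both coordinates
    (to the 1e-3 A precision of the format) and segment labels.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = structure.n_beads
    atoms = struc.AtomArray(n)
    atoms.coord = structure.coords.astype(np.float32)
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.res_name = np.asarray(structure.residue_names)
    atoms.res_id = np.arange(1, n + 1)          # 1-based in files
    atoms.chain_id = np.asarray(
        [_SEGMENT_CHAIN[Segment(int(s))] for s in structure.segments])
    atoms.hetero = np.zeros(n, dtype=bool)

    pdb = PDBFile()
    if frames is None:
        pdb.set_structure(atoms)
    else:
        stack = struc.stack([atoms] * frames.shape[0])
        stack.coord = frames.astype(np.float32)
        pdb.set_structure(stack)
    pdb.write(str(path))


def read_structure_pdb(path: str | Path) -> CGStructure:
    """Read a CA-only bead PDB written by :func:`write_structure_pdb`."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1)
    ca = atoms[atoms.atom_name == "CA"]
    segments = np.asarray([int(_CHAIN_SEGMENT.get(str(c), Segment.PDI_B))
                           for c in ca.chain_id], dtype=np.int8)
    return CGStructure(
        coords=np.asarray(ca.coord, dtype=np.float64),
        residue_names=[str(r) for r in ca.res_name],
        segments=segments,
    )


def write_topology(topology: Topology, path: str | Path) -> None:
    """Write the topology as a plain-text table, one record per line.

    Record types: BOND i j r0 k; ANGLE i j k theta0 ktheta;
    DIHEDRAL i j k l phi0 kphi; CONTACT i j r0 eps inter(0/1).
    Indices are 1-based.  A header line carries the excluded-volume
    parameters.
    """
    t = topology
    with open(path, "w") as fh:
        fh.write(f"# fretforge topology; sigma_ev={t.sigma_ev:.4f} "
                 f"eps_ev={t.eps_ev:.4f}\n")
        for (i, j), r0, k in zip(t.bond_idx, t.bond_r0, t.bond_k):
            fh.write(f"BOND {i + 1} {j + 1} {r0:.6f} {k:.6f}\n")
        for (i, j, k_), t0, kt in zip(t.angle_idx, t.angle_t0, t.angle_k):
            fh.write(f"ANGLE {i + 1} {j + 1} {k_ + 1} {t0:.8f} {kt:.6f}\n")
        for (i, j, k_, l), p0, kp in zip(t.dihedral_idx, t.dihedral_p0,
                                         t.dihedral_k):
            fh.write(f"DIHEDRAL {i + 1} {j + 1} {k_ + 1} {l + 1} "
                     f"{p0:.8f} {kp:.6f}\n")
        for (i, j), r0, e, flag in zip(t.contact_idx, t.contact_r0,
                                       t.contact_eps, t.contact_inter):
            fh.write(f"CONTACT {i + 1} {j + 1} {r0:.6f} {e:.6f} {int(flag)}\n")


def read_topology(path: str | Path) -> Topology:
    """Read a topology table written by :func:`write_topology`."""
    sigma_ev, eps_ev = DEFAULT_SIGMA_EV, DEFAULT_EPS_EV
    rec: dict[str, list] = {"BOND": [], "ANGLE": [], "DIHEDRAL": [], "CONTACT": []}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].replace(";", " ").split():
                    if token.startswith("sigma_ev="):
                        sigma_ev = float(token.split("=")[1])
                    elif token.startswith("eps_ev="):
                        eps_ev = float(token.split("=")[1])
                continue
            parts = line.split()
            rec[parts[0]].append([float(p) for p in parts[1:]])

    def arr(kind: str, ncols: int):
        a = np.asarray(rec[kind], dtype=np.float64)
        if a.size == 0:
            return np.zeros((0, ncols), int), np.zeros((0, a.shape[1] if a.ndim > 1 else 0))
        return a[:, :ncols].astype(int) - 1, a[:, ncols:]

    b_idx, b_rest = arr("BOND", 2)
    a_idx, a_rest = arr("ANGLE", 3)
    d_idx, d_rest = arr("DIHEDRAL", 4)
    c_idx, c_rest = arr("CONTACT", 2)
    empty = np.zeros(0)
    return Topology(
        bond_idx=b_idx,
        bond_r0=b_rest[:, 0] if b_rest.size else empty,
        bond_k=b_rest[:, 1] if b_rest.size else empty,
        angle_idx=a_idx,
        angle_t0=a_rest[:, 0] if a_rest.size else empty,
        angle_k=a_rest[:, 1] if a_rest.size else empty,
        dihedral_idx=d_idx,
        dihedral_p0=d_rest[:, 0] if d_rest.size else empty,
        dihedral_k=d_rest[:, 1] if d_rest.size else empty,
        contact_idx=c_idx,
        contact_r0=c_rest[:, 0] if c_rest.size else empty,
        contact_eps=c_rest[:, 1] if c_rest.size else empty,
        contact_inter=(c_rest[:, 2].astype(bool) if c_rest.size
                       else np.zeros(0, bool)),
        sigma_ev=sigma_ev, eps_ev=eps_ev,
    )
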