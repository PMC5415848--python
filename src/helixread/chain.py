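"""Peptide backbone containers.

A :class:`PeptideChain` holds the backbone (N, CA, C, O) of a short peptide
such as the histone H3 N-terminal tail, one frame at a time; a
:class:`ConformerEnsemble` stacks frames (e.g. snapshots of a simulated
trajectory) that share a residue roster.  Coordinates are in Angstrom,
residue indices are 1-based and contiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

BACKBONE_ATOMS = ("N", "CA", "C", "O")

AA1_TO_3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA3_TO_1 = {v: k for k, v in AA1_TO_3.items()}


@dataclass
class Residue:
    """One residue: 1-based index, 3-letter name, backbone atom coordinates.

    ``atoms`` maps atom name -> (3,) float array; sidechain polar atoms
    (e.g. Thr OG1, Arg NH1) may be present in addition to the backbone.
    """

    index: int
    name: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return all(a in self.atoms for a in BACKBONE_ATOMS)

    def __getitem__(self, atom: str) -> np.ndarray:
        return self.atoms[atom]

    def sidechain_polar_atoms(self) -> list[str]:
        return [
            a for a in self.atoms
            if a not in BACKBONE_ATOMS and a[0] in ("N", "O")
        ]


class PeptideChain:
    """Ordered residues of a single peptide conformation."""

    def __init__(self, residues: Sequence[Residue]):
        residues = list(residues)
        if not residues:
            raise ValueError("empty chain")
        indices = [r.index for r in residues]
        if any(b - a != 1 for a, b in zip(indices, indices[1:])):
            raise ValueError(
                f"residue indices must increase contiguously, got {indices}"
            )
        self.residues = residues
        self._check_connectivity()

    def _check_connectivity(self) -> None:
        for a, b in zip(self.residues, self.residues[1:]):
            if a.complete and b.complete:
                d = float(np.linalg.norm(a["CA"] - b["CA"]))
                if not (2.8 <= d <= 4.2):
                    raise ValueError(
                        f"CA-CA distance {d:.2f} A between residues "
                        f"{a.index} and {b.index} outside [2.8, 4.2]"
                    )

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __getitem__(self, i: int) -> Residue:
        return self.residues[i]

    @property
    def indices(self) -> list[int]:
        return [r.index for r in self.residues]

    @property
    def sequence(self) -> str:
        return "".join(AA3_TO_1.get(r.name, "X") for r in self.residues)

    def residue(self, index: int) -> Residue:
        off = index - self.residues[0].index
        if not 0 <= off < len(self.residues):
            raise KeyError(f"no residue with index {index}")
        return self.residues[off]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PeptideChain":
        """Rigid-body copy: x -> R x + t."""
        out = []
        for r in self.residues:
            atoms = {a: rotation @ xyz + translation for a, xyz in r.atoms.items()}
            out.append(Residue(r.index, r.name, atoms))
        return PeptideChain(out)

    def roster(self) -> tuple[tuple[int, str], ...]:
        return tuple((r.index, r.name) for r in self.residues)


class ConformerEnsemble:
    """Frames of one peptide, each tagged with a replica id."""

    def __init__(self, frames: Sequence[PeptideChain], replica_ids: Sequence[int] | None = None):
        frames = list(frames)
        if not frames:
            raise ValueError("ensemble needs at least one frame")
        roster = frames[0].roster()
        for k, f in enumerate(frames[1:], start=2):
            if f.roster() != roster:
                raise ValueError(f"frame {k} roster differs from frame 1")
        if replica_ids is None:
            replica_ids = [0] * len(frames)
        replica_ids = list(replica_ids)
        if len(replica_ids) != len(frames):
            raise ValueError("replica_ids length must match number of frames")
        self.frames = frames
        self.replica_ids = replica_ids

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[PeptideChain]:
        return iter(self.frames)

    @property
    def n_residues(self) -> int:
        return len(self.frames[0])

    @property
    def indices(self) -> list[int]:
        return self.frames[0].indices

    def replicas(self) -> dict[int, list[PeptideChain]]:
        out: dict[int, list[PeptideChain]] = {}
        for rid, frame in zip(self.replica_ids, self.frames):
            out.setdefault(rid, []).append(frame)
        return out

    def coordinates(self) -> np.ndarray:
        """(n_frames, n_residues, 4, 3) backbone coordinate array."""
        arr = np.empty((len(self.frames), self.n_residues, 4, 3))
        for i, f in enumerate(self.frames):
            for j, r in enumerate(f):
                for k, a in enumerate(BACKBONE_ATOMS):
                    arr[i, j, k] = r[a]
        return arr


# --- internal-coordinate construction -------------------------------------

# Engh & Huber style ideal backbone geometry.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
OMEGA_TRANS = 180.0


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D so |CD|=bond, angle(B,C,D)=angle, dihedral(A,B,C,D)=dihedral."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dihedral),
        bond * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle in degrees (IUPAC convention)."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def build_backbone(sequence: str, phi_psi: Sequence[tuple[float, float]]) -> PeptideChain:
    """Build an all-trans backbone with ideal geometry and per-residue (phi, psi).

    phi of the first residue and psi of the last have no structural effect on
    placed atoms other than the terminal carbonyl oxygen.
    """
    if len(sequence) < 2:
        raise ValueError("sequence must have at least 2 residues")
    bad = [c for c in sequence if c not in AA1_TO_3]
    if bad:
        raise ValueError(f"unknown residue letter {bad[0]!r} in sequence")
    if len(phi_psi) != len(sequence):
        raise ValueError("phi_psi length must equal sequence length")

    n = len(sequence)
    N = np.empty((n, 3))
    CA = np.empty((n, 3))
    C = np.empty((n, 3))
    O = np.empty((n, 3))

    # seed frame for residue 1
    N[0] = np.array([0.0, 0.0, 0.0])
    CA[0] = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])

    for i in range(n - 1):
        psi_i = phi_psi[i][1]
        phi_next = phi_psi[i + 1][0]
        N[i + 1] = place_atom(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psi_i)
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], BOND_CA_C, ANGLE_N_CA_C, phi_next)
        # carbonyl O anti to the next amide N, in the peptide plane
        O[i] = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi_i + 180.0)
    O[n - 1] = place_atom(N[n - 1], CA[n - 1], C[n - 1], BOND_C_O, ANGLE_CA_C_O,
                          phi_psi[n - 1][1] + 180.0)

    residues = []
    for i, letter in enumerate(sequence):
        residues.append(Residue(
            index=i + 1,
            name=AA1_TO_3[letter],
            atoms={"N": N[i], "CA": CA[i], "C": C[i], "O": O[i]},
        ))
    return PeptideChain(residues)
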