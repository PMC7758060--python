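"""Loop superposition and ligand transplantation.

A liganded donor loop is rigidly superposed (Kabsch least squares, proper
rotations only) onto an unliganded acceptor loop using matched Cα atoms;
the fitted transform then carries the donor's ligand into the acceptor
frame, giving a model of where the ligand would sit in the unliganded
structure.  Loop correspondence is positional: the two residue ranges
must select the same number of atoms and the i-th maps to the i-th.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io_formats import Atom, StructureModel


@dataclass(frozen=True)
class LoopSelection:
    """Chain + inclusive author-numbered residue range + atom name."""

    chain: str
    residue_range: tuple[int, int]
    atom_name: str = "CA"

    def __post_init__(self):
        if self.residue_range[0] > self.residue_range[1]:
            raise ValueError("residue range start must be <= end")


@dataclass(frozen=True)
class LoopSuperposition:
    """Rigid transform (y ~ R x + t) and its Cα RMSD."""

    rotation: np.ndarray  # (3,3), proper
    translation: np.ndarray  # (3,)
    rmsd: float
    n_atoms: int

    def __post_init__(self):
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def extract_loop(s: StructureModel, sel: LoopSelection) -> np.ndarray:
    """Coordinates of the selected atom for each residue in the range.

    Ordered by residue number (insertion codes after their base number);
    every residue in the range must carry the named atom.
    """
    lo, hi = sel.residue_range
    found: dict[tuple[int, str], tuple[float, float, float]] = {}
    for a in s.atoms:
        if (a.chain == sel.chain and not a.is_het
                and lo <= a.residue_number <= hi
                and a.atom_name == sel.atom_name):
            key = (a.residue_number, a.insertion_code)
            found.setdefault(key, a.xyz)
    missing = [n for n in range(lo, hi + 1)
               if not any(k[0] == n for k in found)]
    if missing:
        raise ValueError(
            f"chain {sel.chain}: residues missing atom {sel.atom_name!r}: {missing}")
    ordered = [found[k] for k in sorted(found)]
    return np.asarray(ordered, dtype=float)


def kabsch_superpose(mobile: np.ndarray, fixed: np.ndarray) -> LoopSuperposition:
    """Least-squares optimal proper rotation + translation (Kabsch/SVD).

    Reflections are rejected by flipping the sign of the smallest
    singular direction, so the transform is always a physical rotation.
    """
    mobile = np.asarray(mobile, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if mobile.shape != fixed.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    mc = mobile.mean(axis=0)
    fc = fixed.mean(axis=0)
    X = mobile - mc
    Y = fixed - fc
    H = X.T @ Y
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear) point geometry")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = fc - R @ mc
    moved = X @ R.T + fc
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1))))
    return LoopSuperposition(R, t, rmsd, n)


def transplant_ligand(donor: StructureModel, acceptor: StructureModel,
                      donor_sel: LoopSelection, acceptor_sel: LoopSelection,
                      ligand_resname: str) -> tuple[StructureModel, LoopSuperposition]:
    """Carry the donor's ligand into the acceptor frame via loop superposition.

    Returns the acceptor model with the transformed ligand appended
    (HETATM, donor residue name, renumbered past the acceptor's highest
    residue number in the acceptor loop's chain) plus the superposition.
    """
    ligands = donor.het_residues(ligand_resname)
    if not ligands:
        raise ValueError(f"donor has no HETATM residue named {ligand_resname!r}")
    d_loop = extract_loop(donor, donor_sel)
    a_loop = extract_loop(acceptor, acceptor_sel)
    if len(d_loop) != len(a_loop):
        raise ValueError(
            f"loop length mismatch: donor {len(d_loop)} vs acceptor {len(a_loop)}")
    sup = kabsch_superpose(d_loop, a_loop)
    chain = acceptor_sel.chain
    max_num = max((a.residue_number for a in acceptor.atoms if a.chain == chain),
                  default=0)
    out_atoms = list(acceptor.atoms)
    for k, residue in enumerate(ligands, start=1):
        for a in residue:
            xyz = sup.apply(np.asarray(a.xyz))
            out_atoms.append(Atom(
                chain=chain, residue_number=max_num + k, insertion_code="",
                residue_name=a.residue_name, atom_name=a.atom_name,
                element=a.element, xyz=tuple(float(v) for v in xyz), is_het=True,
            ))
    return StructureModel(out_atoms), sup
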