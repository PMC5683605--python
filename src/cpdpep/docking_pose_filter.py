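"""Geometric docking-pose correctness filter for carboxypeptidase subsites.

A docked peptide pose is "correct" when the center of mass (COM) of its P1'
(C-terminal) residue lies within a cutoff distance (default 10 A) of the COM
of the receptor's S1' pocket residue AND the COM of its P1 (penultimate)
residue lies within the cutoff of the S1 pocket residue.  For CPD the pocket
residues are Asp268 (S1') and Glu315 (S1) in domain I, and Asp682/Glu727 in
domain II.  The per-peptide score is the percentage of correct poses over the
set of retained docking solutions (101 in the reference protocol).

COMs are mass-weighted means over heavy atoms (hydrogens excluded; pose files
typically lack them), using standard atomic weights, over all atoms of the
residue (backbone + side chain).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Atom",
    "PocketDefinition",
    "PoseSet",
    "PoseScore",
    "center_of_mass",
    "pose_is_correct",
    "score_poses",
    "rank_correlation",
    "read_receptor_pdb",
    "read_pose_models_pdb",
]

from .constants import ATOMIC_MASS

#: An atom is (element symbol, x, y, z) in Angstrom.
Atom = tuple[str, float, float, float]

#: A residue is an ordered list of atoms; a pose is one list per peptide residue.
Residue = Sequence[Atom]


@dataclass(frozen=True)
class PocketDefinition:
    """S1'/S1 pocket residues of one receptor domain and the distance cutoff."""

    s1prime_residue: tuple[str, int, str]  # (chain, residue number, name)
    s1_residue: tuple[str, int, str]
    cutoff: float = 10.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class PoseSet:
    """Receptor residues plus candidate peptide poses."""

    receptor: dict[tuple[str, int], Residue]
    poses: list[list[Residue]]
    peptide_sequence: str
    domain_label: str = ""

    def __post_init__(self) -> None:
        n = len(self.peptide_sequence)
        for i, pose in enumerate(self.poses):
            if len(pose) != n:
                raise ValueError(
                    f"pose {i} has {len(pose)} residues, expected {n}"
                )


@dataclass(frozen=True)
class PoseScore:
    per_pose_correct: tuple[bool, ...]
    percent_correct: float


def center_of_mass(atoms: Residue, include_hydrogens: bool = False) -> np.ndarray:
    """Mass-weighted mean coordinate of a residue's atoms (heavy atoms only
    by default)."""
    if not atoms:
        raise ValueError("empty atom list")
    coords, masses = [], []
    for element, x, y, z in atoms:
        el = element.strip().upper()
        if el == "H" and not include_hydrogens:
            continue
        if el not in ATOMIC_MASS:
            raise ValueError(f"no atomic mass for element {element!r}")
        coords.append((x, y, z))
        masses.append(ATOMIC_MASS[el])
    if not coords:
        raise ValueError("no heavy atoms in residue")
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def _pocket_com(
    receptor: Mapping[tuple[str, int], Residue], spec: tuple[str, int, str]
) -> np.ndarray:
    chain, resnum, name = spec
    key = (chain, resnum)
    if key not in receptor:
        raise ValueError(f"pocket residue {name} {chain}:{resnum} not in receptor")
    return center_of_mass(receptor[key])


def pose_is_correct(
    pose: Sequence[Residue],
    receptor: Mapping[tuple[str, int], Residue],
    pocket: PocketDefinition,
) -> bool:
    """Both subsites engaged: P1' COM within cutoff of the S1' pocket COM and
    P1 COM within cutoff of the S1 pocket COM."""
    if len(pose) < 2:
        raise ValueError("peptide pose must have at least two residues")
    s1p_com = _pocket_com(receptor, pocket.s1prime_residue)
    s1_com = _pocket_com(receptor, pocket.s1_residue)
    p1prime_com = center_of_mass(pose[-1])
    p1_com = center_of_mass(pose[-2])
    return bool(
        np.linalg.norm(p1prime_com - s1p_com) <= pocket.cutoff
        and np.linalg.norm(p1_com - s1_com) <= pocket.cutoff
    )


def score_poses(ps: PoseSet, pocket: PocketDefinition) -> PoseScore:
    """Percentage of correct poses over all supplied docking solutions."""
    if not ps.poses:
        raise ValueError("pose set is empty")
    flags = tuple(pose_is_correct(pose, ps.receptor, pocket) for pose in ps.poses)
    return PoseScore(
        per_pose_correct=flags,
        percent_correct=100.0 * sum(flags) / len(flags),
    )


def rank_correlation(
    scores: Mapping[str, float], ratios: Mapping[str, float]
) -> float:
    """Spearman rank correlation between percent-correct and cleavage extent.

    Cleavage extent is (1 - enzyme/control ratio), so a positive coefficient
    means peptides with more correct poses are cleaved more.  Returns NaN for
    constant inputs (undefined correlation).
    """
    from scipy.stats import spearmanr

    common = sorted(set(scores) & set(ratios))
    if len(common) < 3:
        raise ValueError("need at least three paired peptides")
    x = [scores[k] for k in common]
    y = [1.0 - ratios[k] for k in common]
    if len(set(x)) == 1 or len(set(y)) == 1:
        return float("nan")
    rho = spearmanr(x, y).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# PDB input (Biopython)
# ---------------------------------------------------------------------------

def _structure_atoms(chain) -> dict[tuple[str, int], list[Atom]]:
    out: dict[tuple[str, int], list[Atom]] = {}
    for residue in chain:
        resnum = residue.id[1]
        atoms = [
            (atom.element, *map(float, atom.coord)) for atom in residue
        ]
        out[(chain.id, resnum)] = atoms
    return out


def read_receptor_pdb(path: str | Path) -> dict[tuple[str, int], list[Atom]]:
    """Read receptor heavy-atom coordinates indexed by (chain, residue number)."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("receptor", str(path))
    model = next(iter(structure))
    receptor: dict[tuple[str, int], list[Atom]] = {}
    for chain in model:
        receptor.update(_structure_atoms(chain))
    return receptor


def read_pose_models_pdb(path: str | Path) -> list[list[list[Atom]]]:
    """Read a multi-model pose PDB (MODEL/ENDMDL records).

    Each model is one peptide pose; residues are returned in chain order as
    ordered atom lists.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("poses", str(path))
    poses = []
    for model in structure:
        residues: list[list[Atom]] = []
        for chain in model:
            for residue in chain:
                residues.append(
                    [(atom.element, *map(float, atom.coord)) for atom in residue]
                )
        poses.append(residues)
    if not poses:
        raise ValueError(f"no MODEL records found in {path}")
    return poses
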