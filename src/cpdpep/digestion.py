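"""In-silico tryptic digestion and peptide-library construction.

Trypsin cleaves C-terminal to Lys or Arg; by default a site is suppressed
when the next residue is Pro (Keil rule).  Fragments with up to ``max_missed``
internal uncut sites are enumerated with 1-based precursor coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .constants import AMINO_ACIDS
from .peptide_chem import Peptide, count_free_amines, expected_charge, monoisotopic_mass

__all__ = [
    "ProteinRecord",
    "LibraryPeptide",
    "trypsin_digest",
    "build_library",
    "read_fasta",
    "load_tryptic_precursors",
    "write_library_tsv",
]


@dataclass(frozen=True)
class ProteinRecord:
    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty protein sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"non-standard residues {sorted(bad)} in protein {self.name!r}"
            )


@dataclass(frozen=True)
class LibraryPeptide:
    """A tryptic fragment with its position in the precursor (1-based, inclusive)."""

    peptide: Peptide
    precursor_name: str
    start: int
    end: int
    missed_cleavages: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end must be >= start")


def _cleavage_points(sequence: str, no_cleave_before_proline: bool) -> list[int]:
    """Indices after which trypsin cuts (0-based, position of the K/R)."""
    points = []
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR":
            if no_cleave_before_proline and sequence[i + 1] == "P":
                continue
            points.append(i)
    return points


def trypsin_digest(
    protein: ProteinRecord,
    max_missed: int = 2,
    no_cleave_before_proline: bool = True,
) -> list[LibraryPeptide]:
    """All tryptic fragments of ``protein`` with 0..max_missed missed cleavages."""
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = protein.sequence
    cuts = _cleavage_points(seq, no_cleave_before_proline)
    # Fragment boundaries: starts of 0-missed fragments plus the sequence end.
    starts = [0] + [c + 1 for c in cuts]
    ends = [c + 1 for c in cuts] + [len(seq)]  # exclusive
    out: list[LibraryPeptide] = []
    n_frag = len(starts)
    for i in range(n_frag):
        for k in range(max_missed + 1):
            j = i + k
            if j >= n_frag:
                break
            s, e = starts[i], ends[j]
            out.append(
                LibraryPeptide(
                    peptide=Peptide(seq[s:e], precursor_name=protein.name),
                    precursor_name=protein.name,
                    start=s + 1,
                    end=e,
                    missed_cleavages=k,
                )
            )
    return out


def build_library(
    proteins: Iterable[ProteinRecord],
    max_missed: int = 2,
    no_cleave_before_proline: bool = True,
) -> list[LibraryPeptide]:
    """Pooled digest of several proteins, de-duplicated, deterministically ordered."""
    proteins = list(proteins)
    if not proteins:
        raise ValueError("at least one protein is required")
    seen: set[tuple[str, str, int, int]] = set()
    library: list[LibraryPeptide] = []
    for prot in proteins:
        for lp in trypsin_digest(prot, max_missed, no_cleave_before_proline):
            key = (lp.peptide.sequence, lp.precursor_name, lp.start, lp.end)
            if key in seen:
                continue
            seen.add(key)
            library.append(lp)
    library.sort(key=lambda lp: (lp.precursor_name, lp.start, lp.end))
    return library


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-FASTA into protein records (description line kept as name)."""
    records = []
    # fasta-pearson tolerates ';' comment lines (used in the packaged fixture)
    for rec in SeqIO.parse(str(path), "fasta-pearson"):
        records.append(ProteinRecord(name=rec.id, sequence=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def load_tryptic_precursors() -> list[ProteinRecord]:
    """Packaged five-protein precursor set for the tryptic library.

    These are synthetic scaffold sequences (see the fixture file header):
    each precursor is constructed so that tryptic digestion with up to two
    missed cleavages yields the peptides reported for it in the reference
    identification tables.  They are stand-ins for the database sequences,
    not UniProt entries.
    """
    with resources.as_file(
        resources.files("cpdpep.data") / "synthetic_tryptic_precursors.fasta"
    ) as path:
        return read_fasta(path)


def write_library_tsv(library: list[LibraryPeptide], path: str | Path) -> None:
    """Write a library table: sequence, precursor, coordinates, mass, tags, charge."""
    with open(path, "w") as fh:
        fh.write(
            "sequence\tprecursor\tstart\tend\tmissed\ttheor_mass\ttags\tcharge\n"
        )
        for lp in library:
            p = lp.peptide
            fh.write(
                f"{p.notation()}\t{lp.precursor_name}\t{lp.start}\t{lp.end}\t"
                f"{lp.missed_cleavages}\t{monoisotopic_mass(p).monoisotopic_mass:.5f}\t"
                f"{count_free_amines(p)}\t{expected_charge(p)}\n"
            )
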