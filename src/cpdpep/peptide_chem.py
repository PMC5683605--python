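"""Peptide mass and charge bookkeeping.

Monoisotopic masses, free-amine (isotopic tag) counting, expected charge
states, b/y fragment series and ppm mass comparison for peptides written in
one-letter code with an optional N-terminal acetyl group and Met oxidation.

Conventions
-----------
* All peptide masses are neutral monoisotopic masses in Da (the convention in
  which observed/theoretical mass tables are printed).
* Fragment ions are reported singly protonated.
* "Basic residues" for the expected charge are Lys and Arg by default; His
  can be included with a flag, but His-containing peptides are normally
  excluded from TMAB quantification because of iodination side reactions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .constants import (
    ACETYL_DELTA,
    AMINO_ACIDS,
    MONOISOTOPIC_RESIDUE_MASS,
    OXIDATION_DELTA,
    PROTON,
    WATER,
)

__all__ = [
    "Peptide",
    "MassResult",
    "ChargeTagPrediction",
    "parse_peptide",
    "monoisotopic_mass",
    "count_free_amines",
    "expected_charge",
    "by_fragment_series",
    "ppm_difference",
]

#: Residues excluded from TMAB quantification (variable intensities caused by
#: label impurities: cyano-Cys, iodo-Tyr and iodo-His adducts).
EXCLUDED_RESIDUES = frozenset("CYH")

OXIDATION = "ox"
N_TERM_FREE = "free"
N_TERM_ACETYL = "acetyl"


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence with termini state and residue modifications.

    ``residue_mods`` maps 0-based positions to modification tags; the only
    supported residue modification is Met oxidation (``"ox"``).  The
    C-terminus is a free acid.
    """

    sequence: str
    n_term_mod: str = N_TERM_FREE
    residue_mods: tuple[tuple[int, str], ...] = field(default_factory=tuple)
    precursor_name: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        for i, aa in enumerate(self.sequence):
            if aa not in AMINO_ACIDS:
                raise ValueError(
                    f"unknown residue code {aa!r} at position {i + 1}"
                )
        if self.n_term_mod not in (N_TERM_FREE, N_TERM_ACETYL):
            raise ValueError(f"unsupported N-terminal state {self.n_term_mod!r}")
        for pos, tag in self.residue_mods:
            if not 0 <= pos < len(self.sequence):
                raise ValueError(f"modification position {pos} out of bounds")
            if tag != OXIDATION:
                raise ValueError(f"unsupported residue modification {tag!r}")
            if self.sequence[pos] != "M":
                raise ValueError(
                    f"oxidation only supported on Met, not {self.sequence[pos]!r} "
                    f"at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mod_map(self) -> dict[int, str]:
        return dict(self.residue_mods)

    @property
    def is_acetylated(self) -> bool:
        return self.n_term_mod == N_TERM_ACETYL

    @property
    def p1_prime(self) -> str:
        """C-terminal residue (the one a carboxypeptidase releases)."""
        return self.sequence[-1]

    @property
    def p1(self) -> str:
        """Penultimate residue (becomes the new C-terminus after cleavage)."""
        if len(self.sequence) < 2:
            raise ValueError("P1 undefined for a single-residue peptide")
        return self.sequence[-2]

    def contains_excluded_residue(self) -> bool:
        return any(aa in EXCLUDED_RESIDUES for aa in self.sequence)

    def notation(self) -> str:
        """Render in text notation (``Ac-`` prefix, ``Mox`` inline)."""
        mods = self.mod_map
        out = []
        for i, aa in enumerate(self.sequence):
            out.append(aa)
            if mods.get(i) == OXIDATION:
                out.append("ox")
        prefix = "Ac-" if self.is_acetylated else ""
        return prefix + "".join(out)


@dataclass(frozen=True)
class MassResult:
    monoisotopic_mass: float
    formula_basis: str


@dataclass(frozen=True)
class ChargeTagPrediction:
    expected_charge: int
    tag_count: int


_MOD_TOKEN = re.compile(r"ox|\(ox\)")


def parse_peptide(text: str, precursor_name: str | None = None) -> Peptide:
    """Parse table-style peptide notation.

    Accepts an optional ``Ac-`` prefix for N-terminal acetylation and inline
    ``ox`` or ``(ox)`` markers immediately after an oxidized Met, e.g.
    ``"Ac-ADEIAKAQVAR"`` or ``"SAMoxTEEAAVAIKAMAK"``.
    """
    text = text.strip()
    n_term = N_TERM_FREE
    if text.startswith("Ac-"):
        n_term = N_TERM_ACETYL
        text = text[3:]
    sequence: list[str] = []
    mods: list[tuple[int, str]] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isupper():
            sequence.append(ch)
            i += 1
            m = _MOD_TOKEN.match(text, i)
            if m:
                mods.append((len(sequence) - 1, OXIDATION))
                i = m.end()
        else:
            raise ValueError(f"cannot parse peptide notation at {text[i:]!r}")
    return Peptide(
        sequence="".join(sequence),
        n_term_mod=n_term,
        residue_mods=tuple(mods),
        precursor_name=precursor_name,
    )


def _residue_masses(p: Peptide) -> list[float]:
    mods = p.mod_map
    masses = []
    for i, aa in enumerate(p.sequence):
        m = MONOISOTOPIC_RESIDUE_MASS[aa]
        if mods.get(i) == OXIDATION:
            m += OXIDATION_DELTA
        masses.append(m)
    return masses


def monoisotopic_mass(p: Peptide) -> MassResult:
    """Neutral monoisotopic mass: residues + water + modification deltas."""
    total = sum(_residue_masses(p)) + WATER
    basis = f"{len(p)} residues + water"
    if p.is_acetylated:
        total += ACETYL_DELTA
        basis += " + acetyl"
    n_ox = sum(1 for _, tag in p.residue_mods if tag == OXIDATION)
    if n_ox:
        basis += f" + {n_ox} Met-oxidation"
    return MassResult(monoisotopic_mass=total, formula_basis=basis)


def count_free_amines(p: Peptide) -> int:
    """Number of amine-reactive sites = Lys side chains + free N-terminus.

    This equals the number of isotopic TMAB tags a fully labeled peptide
    carries (the T column of identification tables).
    """
    return p.sequence.count("K") + (0 if p.is_acetylated else 1)


def expected_charge(p: Peptide, include_his: bool = False) -> int:
    """Expected charge: basic residues plus one for a free N-terminus.

    By default basic residues are Lys and Arg; His is excluded because
    His-containing peptides are dropped from the quantification.
    """
    basics = "KRH" if include_his else "KR"
    z = sum(p.sequence.count(aa) for aa in basics)
    if not p.is_acetylated:
        z += 1
    return max(z, 1)


def by_fragment_series(p: Peptide) -> list[tuple[str, float]]:
    """Singly protonated b- and y-ion series, b1..b(n-1) and y1..y(n-1).

    b_i = sum(residues 1..i) [+ N-terminal mod] + proton;
    y_i = sum(last i residues) + water + proton.
    """
    n = len(p)
    if n < 2:
        raise ValueError("fragment series undefined for a single residue")
    masses = _residue_masses(p)
    nterm = ACETYL_DELTA if p.is_acetylated else 0.0
    out: list[tuple[str, float]] = []
    running = nterm
    for i in range(n - 1):
        running += masses[i]
        out.append((f"b{i + 1}", running + PROTON))
    running = 0.0
    for i in range(n - 1):
        running += masses[n - 1 - i]
        out.append((f"y{i + 1}", running + WATER + PROTON))
    return out


def ppm_difference(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return (observed - theoretical) / theoretical * 1e6
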