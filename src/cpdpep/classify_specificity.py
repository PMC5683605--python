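"""Substrate classification, domain-preference calls and P1'/P1 profiling.

Classification thresholds (on the enzyme/control intensity ratio at the
highest enzyme amount):

* good substrate:   decrease >= 60%  (ratio <= 0.40)
* weak substrate:   decrease >= 20% and < 60%  (0.40 < ratio <= 0.80)
* non-substrate:    decrease < 20%  (ratio > 0.80)
* product:          ratio >= 1.5 at the highest enzyme amount and
                    non-decreasing (within a relative slack) across amounts

Domain preference is called from the ratio of peak intensities remaining
after incubation with the domain-I-only-active enzyme (E762Q) over the
domain-II-only-active enzyme (E350Q).  A high ratio means domain I left the
peptide intact while domain II consumed it, i.e. a preferential substrate of
domain II, and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .digestion import LibraryPeptide
from .peptide_chem import Peptide
from .quantify import RatioProfile
from .reference_data import RATIO_CAP, RATIO_FLOOR, Ratio

__all__ = [
    "SubstrateCall",
    "DomainPreference",
    "SpecificityProfile",
    "CleavageDeduction",
    "classify_substrate",
    "call_domain_preference",
    "build_profile",
    "deduce_cleavage",
    "drop_excluded",
    "plot_profile",
]

GOOD_DECREASE = 0.60
WEAK_DECREASE = 0.20
PRODUCT_RATIO = 1.5
PRODUCT_MONO_SLACK = 0.15
PREF_LOW_CUTOFF = 0.50   # dI/dII at or below -> domain I preferential
PREF_HIGH_CUTOFF = 2.00  # dI/dII at or above -> domain II preferential

CATEGORIES = ("good", "weak", "non", "product", "unquantifiable")


@dataclass(frozen=True)
class SubstrateCall:
    category: str
    evidence: tuple[tuple[str, Ratio], ...] = ()
    dose_consistent: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class DomainPreference:
    call: str  # domain_I_preferential | domain_II_preferential | shared | neither
    dI_dII_ratio: Ratio
    indeterminate: bool = False


@dataclass
class SpecificityProfile:
    """Residue-by-category counts at P1' (C-terminal) or P1 (penultimate)."""

    position: str  # "P1'" or "P1"
    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def add(self, residue: str, category: str) -> None:
        self.counts.setdefault(residue, {})
        self.counts[residue][category] = self.counts[residue].get(category, 0) + 1

    def count(self, residue: str, category: str) -> int:
        return self.counts.get(residue, {}).get(category, 0)

    def total(self, category: str | None = None) -> int:
        return sum(
            n
            for per_res in self.counts.values()
            for cat, n in per_res.items()
            if category is None or cat == category
        )

    def to_frame(self):
        import pandas as pd

        return (
            pd.DataFrame(self.counts)
            .T.fillna(0)
            .astype(int)
            .sort_index()
        )


@dataclass(frozen=True)
class CleavageDeduction:
    product_sequence: str
    precursor_name: str
    cleaved_residue: str
    site: int  # 1-based precursor position of the removed residue
    ambiguous: bool = False


def _ordered_enzyme_ratios(
    rp: RatioProfile, enzyme_conditions: Sequence[str]
) -> list[tuple[str, Ratio]]:
    missing = [c for c in enzyme_conditions if c not in rp.ratios]
    if missing:
        raise ValueError(f"conditions missing from profile: {missing}")
    return [(c, rp.ratios[c]) for c in enzyme_conditions]


def classify_substrate(
    rp: RatioProfile,
    enzyme_conditions: Sequence[str],
    good_decrease: float = GOOD_DECREASE,
    weak_decrease: float = WEAK_DECREASE,
    product_ratio: float = PRODUCT_RATIO,
    mono_slack: float = PRODUCT_MONO_SLACK,
) -> SubstrateCall:
    """Classify one ratio profile.

    ``enzyme_conditions`` are ordered by increasing enzyme amount (control
    excluded); the ratio at the last (highest) condition decides the category.
    """
    if not rp.quantifiable:
        return SubstrateCall(category="unquantifiable")
    ordered = _ordered_enzyme_ratios(rp, enzyme_conditions)
    values = [r.value for _, r in ordered]
    r_max_enzyme = values[-1]
    evidence = tuple(ordered)

    increasing = all(
        b >= a * (1.0 - mono_slack) for a, b in zip(values, values[1:])
    )
    if r_max_enzyme >= product_ratio and increasing:
        return SubstrateCall(category="product", evidence=evidence,
                             dose_consistent=increasing)
    decreasing = all(
        b <= a * (1.0 + mono_slack) for a, b in zip(values, values[1:])
    )
    decrease = 1.0 - r_max_enzyme
    eps = 1e-9  # closed thresholds survive float round-off (0.40 good, 0.80 weak)
    if decrease >= good_decrease - eps:
        category = "good"
    elif decrease >= weak_decrease - eps:
        category = "weak"
    else:
        category = "non"
    return SubstrateCall(category=category, evidence=evidence,
                         dose_consistent=decreasing)


def call_domain_preference(
    rp: RatioProfile,
    domain_i_condition: str = "domain_I_active",
    domain_ii_condition: str = "domain_II_active",
    low_cutoff: float = PREF_LOW_CUTOFF,
    high_cutoff: float = PREF_HIGH_CUTOFF,
    floor: float = RATIO_FLOOR,
    cap: float = RATIO_CAP,
) -> DomainPreference:
    """Call domain preference from single-domain-active intensity ratios.

    The dI/dII ratio divides the peptide intensity remaining with only
    domain I active (E762Q) by that remaining with only domain II active
    (E350Q).  Censoring propagates the way a raw-intensity ratio would: a
    below-background numerator gives a "<floor" ratio, a below-background
    denominator a ">cap" ratio; both censored is indeterminate.
    """
    for cond in (domain_i_condition, domain_ii_condition):
        if cond not in rp.ratios:
            raise ValueError(f"missing condition {cond!r} in ratio profile")
    ri = rp.ratios[domain_i_condition]
    rii = rp.ratios[domain_ii_condition]
    if ri.censor == "low" and rii.censor == "low":
        return DomainPreference(call="shared", dI_dII_ratio=Ratio(1.0),
                                indeterminate=True)
    if ri.censor == "low":
        ratio = Ratio(floor, censor="low")
    elif rii.censor == "low":
        ratio = Ratio(cap, censor="high")
    else:
        raw = ri.value / rii.value
        if raw < floor:
            ratio = Ratio(floor, censor="low")
        elif raw > cap:
            ratio = Ratio(cap, censor="high")
        else:
            ratio = Ratio(raw)
    if ratio.value <= low_cutoff:
        call = "domain_I_preferential"
    elif ratio.value >= high_cutoff:
        call = "domain_II_preferential"
    else:
        call = "shared"
    return DomainPreference(call=call, dI_dII_ratio=ratio)


def build_profile(
    calls: Iterable[tuple[Peptide | LibraryPeptide, SubstrateCall]],
    position: str,
    permissive: frozenset[str] = frozenset("KR"),
) -> SpecificityProfile:
    """Tally residues at P1' or P1 per substrate category.

    The P1 profile counts only peptides whose C-terminal (P1') residue is
    permissive (Lys or Arg), since only those engage the carboxypeptidase
    productively.
    """
    if position not in ("P1'", "P1"):
        raise ValueError("position must be \"P1'\" or \"P1\"")
    profile = SpecificityProfile(position=position)
    for entry, call in calls:
        p = entry.peptide if isinstance(entry, LibraryPeptide) else entry
        if position == "P1'":
            profile.add(p.p1_prime, call.category)
        else:
            if len(p) < 2:
                raise ValueError("P1 undefined for single-residue peptide")
            if p.p1_prime in permissive:
                profile.add(p.p1, call.category)
    return profile


def deduce_cleavage(
    product: Peptide | str,
    precursors: Mapping[str, str],
) -> list[CleavageDeduction]:
    """Locate a product peptide in precursor sequences and name the residue
    whose removal generated it (the residue immediately downstream).

    Returns one deduction per occurrence; multiple occurrences are flagged
    ambiguous.  A product at the very C-terminus of a precursor has no
    downstream residue and does not count as a carboxypeptidase product.
    """
    seq = product.sequence if isinstance(product, Peptide) else product
    hits: list[CleavageDeduction] = []
    for name, prec in precursors.items():
        start = 0
        while True:
            idx = prec.find(seq, start)
            if idx < 0:
                break
            site = idx + len(seq)  # 0-based index of the downstream residue
            if site < len(prec):
                hits.append(
                    CleavageDeduction(
                        product_sequence=seq,
                        precursor_name=name,
                        cleaved_residue=prec[site],
                        site=site + 1,
                    )
                )
            start = idx + 1
    if not hits:
        raise ValueError(
            f"product {seq!r} not found upstream of a cleavable residue in any precursor"
        )
    if len(hits) > 1:
        hits = [
            CleavageDeduction(
                product_sequence=h.product_sequence,
                precursor_name=h.precursor_name,
                cleaved_residue=h.cleaved_residue,
                site=h.site,
                ambiguous=True,
            )
            for h in hits
        ]
    return hits


def drop_excluded(
    entries: Iterable[Peptide | LibraryPeptide],
) -> list[Peptide | LibraryPeptide]:
    """Remove peptides containing Cys, Tyr or His before classification."""
    kept = []
    for entry in entries:
        p = entry.peptide if isinstance(entry, LibraryPeptide) else entry
        if not p.contains_excluded_residue():
            kept.append(entry)
    return kept


def plot_profile(profile: SpecificityProfile, ax=None):
    """Stacked bar chart of residue counts per category (matplotlib)."""
    import matplotlib.pyplot as plt

    frame = profile.to_frame()
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    frame.plot(kind="bar", stacked=True, ax=ax)
    ax.set_xlabel(f"{profile.position} residue")
    ax.set_ylabel("peptide count")
    return ax
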