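"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here: enzyme
action on a peptide library (per-peptide cleavage efficiencies and expected
5-channel ratio structure), rendered centroided MS1 peak lists, HEK293T-like
peptidomes dominated by non-basic C-termini, Michaelis-Menten rate data, and
toy docking pose sets around defined pocket centers.

The enzyme model encodes the study's qualitative findings: cleavage only of
C-terminal Lys/Arg, a veto on Pro/Asp/Ile in the P1 position, an Arg-skewed
P1' preference for domain I and comparable Lys/Arg handling for domain II.
The enzyme-amount response of a substrate's peak ratio is

    ratio(E) = (1 - eff) + eff * exp(-E / E50)

with a per-peptide midpoint E50, so the ratio is 1 with no enzyme and
approaches (1 - eff) at saturating enzyme.  Products rise complementarily:
ratio_product(E) = 1 + gain * eff * (1 - exp(-E / E50)).

All generators are deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import TMAB_CHANNELS
from .digestion import LibraryPeptide
from .docking_pose_filter import PocketDefinition, PoseSet
from .kinetics import KineticDataset, enzyme_nM_to_uM, mm_rate
from .peptide_chem import Peptide, count_free_amines, expected_charge
from .quantify import PeakList
from .tmab import peakset_pattern

__all__ = [
    "EnzymeModel",
    "TruthPeptide",
    "SimulationTruth",
    "full_cpd_model",
    "domain_I_model",
    "domain_II_model",
    "simulate_cleavage",
    "render_spectra",
    "generate_hek_peptidome",
    "generate_poses",
    "generate_rates",
    "ENZYME_TITRATION_NM",
    "ASSAY_SUBSTRATE_CONCENTRATIONS_UM",
]

#: Enzyme titration of the peptidomics experiments, nM (0 = control).
ENZYME_TITRATION_NM = (0.0, 0.1, 1.0, 10.0, 100.0)

#: Substrate concentrations of the fluorescent kinetic assays, uM.
ASSAY_SUBSTRATE_CONCENTRATIONS_UM = (6.25, 12.5, 25.0, 50.0, 100.0, 200.0, 300.0, 600.0)

#: Cleavage-efficiency bands by true category.  Expected max-enzyme ratios
#: (1 - eff) then fall in 0.05-0.25 (good), 0.50-0.65 (weak), 0.92-1.0 (non),
#: keeping a margin of at least ~0.10 from the 0.40/0.80 classification
#: boundaries so that multiplicative measurement noise rarely flips a call.
EFFICIENCY_BANDS = {
    "good": (0.75, 0.95),
    "weak": (0.35, 0.50),
    "non": (0.0, 0.08),
}


def _condition_label(amount_nM: float) -> str:
    return f"{amount_nM:g}nM"


@dataclass(frozen=True)
class EnzymeModel:
    """Cleavage rules of one enzyme form.

    ``category_probs`` maps each permissive P1' residue to the probability of
    a peptide with that C-terminus being a good, weak or non-substrate.
    """

    name: str
    p1prime_permissive: frozenset = frozenset("KR")
    p1_forbidden: frozenset = frozenset("PDI")
    category_probs: dict = field(
        default_factory=dict, hash=False
    )  # residue -> (p_good, p_weak, p_non)

    def probs_for(self, residue: str) -> tuple[float, float, float]:
        return self.category_probs[residue]


def full_cpd_model() -> EnzymeModel:
    """Both domains active: most Lys-ending peptides cleaved, Arg mixed."""
    return EnzymeModel(
        name="rhCPD",
        category_probs={"K": (0.50, 0.30, 0.20), "R": (0.35, 0.30, 0.35)},
    )


def domain_I_model() -> EnzymeModel:
    """Domain I only: strong preference for C-terminal Arg over Lys."""
    return EnzymeModel(
        name="domain_I",
        category_probs={"K": (0.08, 0.15, 0.77), "R": (0.45, 0.30, 0.25)},
    )


def domain_II_model() -> EnzymeModel:
    """Domain II only: Lys and Arg handled comparably."""
    return EnzymeModel(
        name="domain_II",
        category_probs={"K": (0.42, 0.30, 0.28), "R": (0.42, 0.30, 0.28)},
    )


@dataclass(frozen=True)
class TruthPeptide:
    peptide: Peptide
    kind: str                      # "library" or "product"
    category: str                  # good / weak / non / product
    efficiency: float
    e50_nM: float
    base_intensity: float
    expected_ratio: dict = field(hash=False)   # condition label -> ratio
    source_name: str = ""          # identifier of the (parent) library peptide
    cleaved_residue: str | None = None  # for products: the residue removed


@dataclass
class SimulationTruth:
    entries: list[TruthPeptide]
    conditions: tuple[float, ...]          # enzyme amounts, nM
    control_condition: str                 # condition label of 0 enzyme
    channel_condition: dict[str, str]      # channel -> condition label
    model_name: str
    seed: int

    @property
    def precursor_index(self) -> dict[str, str]:
        """Library-peptide sequences usable as a precursor index for
        product cleavage deduction."""
        return {
            e.source_name: e.peptide.sequence
            for e in self.entries
            if e.kind == "library"
        }

    def true_categories(self) -> dict[str, str]:
        return {e.peptide.sequence: e.category for e in self.entries}


def _substrate_ratio(eff: float, e50: float, amount: float) -> float:
    return (1.0 - eff) + eff * float(np.exp(-amount / e50))


def _product_ratio(eff: float, e50: float, amount: float, gain: float) -> float:
    return 1.0 + gain * eff * (1.0 - float(np.exp(-amount / e50)))


def simulate_cleavage(
    library: list[LibraryPeptide] | list[Peptide],
    model: EnzymeModel,
    conditions: tuple[float, ...] = ENZYME_TITRATION_NM,
    seed: int = 0,
    product_fraction: float = 0.5,
    product_gain: float = 2.5,
) -> SimulationTruth:
    """Assign ground-truth enzyme action to every library peptide.

    Peptides whose P1' residue is not permissive, or whose P1 residue is
    forbidden (Pro/Asp/Ile), are non-substrates by rule; permissive peptides
    draw a category from the model's per-residue probabilities and a cleavage
    efficiency from the category band.  A fraction of good substrates also
    emits the matching product peptide (C-terminal residue removed) with a
    complementary intensity increase.

    The five TMAB channels are bound to the five conditions in decreasing
    enzyme order D0 -> highest ... D12 -> control (the no-enzyme sample).
    """
    if not library:
        raise ValueError("library must be non-empty")
    if len(conditions) != len(TMAB_CHANNELS):
        raise ValueError("need exactly one condition per TMAB channel")
    if 0.0 not in conditions:
        raise ValueError("a zero-enzyme control condition is required")
    rng = np.random.default_rng(seed)
    labels = {amt: _condition_label(amt) for amt in conditions}
    channel_condition = {
        ch: labels[amt]
        for ch, amt in zip(TMAB_CHANNELS, sorted(conditions, reverse=True))
    }

    peptides: list[tuple[Peptide, str]] = []
    seen: set[str] = set()
    for i, entry in enumerate(library):
        p = entry.peptide if isinstance(entry, LibraryPeptide) else entry
        if p.sequence in seen:
            continue
        seen.add(p.sequence)
        name = (
            f"{entry.precursor_name}:{entry.start}-{entry.end}"
            if isinstance(entry, LibraryPeptide)
            else f"pep{i:04d}"
        )
        peptides.append((p, name))

    entries: list[TruthPeptide] = []
    product_seqs: set[str] = set()
    for p, name in peptides:
        cleavable = (
            len(p) >= 2
            and p.p1_prime in model.p1prime_permissive
            and p.p1 not in model.p1_forbidden
            and count_free_amines(p) >= 1
        )
        if cleavable:
            category = str(
                rng.choice(["good", "weak", "non"], p=model.probs_for(p.p1_prime))
            )
        else:
            category = "non"
        lo, hi = EFFICIENCY_BANDS[category]
        eff = float(rng.uniform(lo, hi)) if cleavable else 0.0
        e50 = float(rng.uniform(2.0, 20.0))
        base = float(10 ** rng.uniform(4.0, 6.0))
        ratios = {
            labels[amt]: _substrate_ratio(eff, e50, amt) for amt in conditions
        }
        entries.append(
            TruthPeptide(
                peptide=p,
                kind="library",
                category=category,
                efficiency=eff,
                e50_nM=e50,
                base_intensity=base,
                expected_ratio=ratios,
                source_name=name,
            )
        )
        # Complementary product for a fraction of good substrates.
        if (
            category == "good"
            and len(p) >= 4
            and rng.uniform() < product_fraction
        ):
            prod_seq = p.sequence[:-1]
            if prod_seq in seen or prod_seq in product_seqs:
                continue
            product_seqs.add(prod_seq)
            prod = Peptide(prod_seq, n_term_mod=p.n_term_mod,
                           residue_mods=p.residue_mods)
            if count_free_amines(prod) < 1:
                continue
            prod_ratios = {
                labels[amt]: _product_ratio(eff, e50, amt, product_gain)
                for amt in conditions
            }
            entries.append(
                TruthPeptide(
                    peptide=prod,
                    kind="product",
                    category="product",
                    efficiency=eff,
                    e50_nM=e50,
                    base_intensity=float(10 ** rng.uniform(4.0, 6.0)),
                    expected_ratio=prod_ratios,
                    source_name=name,
                    cleaved_residue=p.p1_prime,
                )
            )
    # A product that coincides with a library peptide would give two
    # inconsistent truth entries for one m/z pattern; drop such products.
    library_seqs = {e.peptide.sequence for e in entries if e.kind == "library"}
    entries = [
        e for e in entries
        if e.kind == "library" or e.peptide.sequence not in library_seqs
    ]
    return SimulationTruth(
        entries=entries,
        conditions=tuple(conditions),
        control_condition=labels[0.0],
        channel_condition=channel_condition,
        model_name=model.name,
        seed=seed,
    )


def render_spectra(
    truth: SimulationTruth,
    noise_cv: float = 0.0,
    background: float = 0.0,
    n_background_peaks: int = 0,
    seed: int = 0,
    run_id: str | None = None,
) -> PeakList:
    """Render the truth as one centroided MS1 peak list.

    Channel intensities are the expected ratios times the peptide's base
    intensity with log-normal multiplicative noise of the given CV; peaks at
    or below the background level are omitted, and optional uniform
    background peaks are added.
    """
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log(1.0 + noise_cv**2))) if noise_cv > 0 else 0.0
    mz_list: list[float] = []
    int_list: list[float] = []
    for e in truth.entries:
        z = expected_charge(e.peptide)
        pattern = peakset_pattern(e.peptide, z)
        for ch in TMAB_CHANNELS:
            cond = truth.channel_condition[ch]
            inten = e.base_intensity * e.expected_ratio[cond]
            if sigma > 0:
                inten *= float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))
            if inten <= background:
                continue
            mz_list.append(pattern.channel_mz[ch])
            int_list.append(inten)
    for _ in range(n_background_peaks):
        mz_list.append(float(rng.uniform(300.0, 2000.0)))
        int_list.append(float(rng.uniform(0.2, 1.0)) * max(background, 1.0))
    order = np.argsort(mz_list, kind="stable")
    return PeakList(
        run_id=run_id or f"sim-{truth.model_name}-seed{truth.seed}",
        mz=tuple(float(mz_list[i]) for i in order),
        intensity=tuple(float(int_list[i]) for i in order),
    )


def generate_hek_peptidome(
    n: int,
    basic_cterm_fraction: float = 0.3,
    seed: int = 0,
    length_range: tuple[int, int] = (5, 20),
    exclude_residues: str = "CYH",
) -> list[Peptide]:
    """Random peptidome with a fixed fraction of basic (K/R) C-termini.

    HEK293T-derived peptidomes are dominated by non-basic C-termini, hence
    the default fraction below one half.  Cys/Tyr/His are excluded by default
    because such peptides are dropped from TMAB quantification anyway.
    Sequences are unique and deterministic under the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= basic_cterm_fraction <= 1.0:
        raise ValueError("basic_cterm_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    alphabet = [aa for aa in "ACDEFGHIKLMNPQRSTVWY" if aa not in exclude_residues]
    non_basic = [aa for aa in alphabet if aa not in "KR"]
    out: list[Peptide] = []
    seen: set[str] = set()
    while len(out) < n:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        body = "".join(rng.choice(alphabet, size=length - 1))
        if rng.uniform() < basic_cterm_fraction:
            cterm = str(rng.choice(["K", "R"]))
        else:
            cterm = str(rng.choice(non_basic))
        seq = body + cterm
        if seq in seen:
            continue
        seen.add(seq)
        out.append(Peptide(seq))
    return out


def generate_poses(
    peptide_len: int,
    n_inside: int,
    n_outside: int,
    pocket: PocketDefinition | None = None,
    seed: int = 0,
) -> tuple[PoseSet, list[bool]]:
    """Toy receptor and poses constructed inside/outside the pocket cutoff.

    The receptor holds the two pocket residues at known centers; "inside"
    poses place the P1' and P1 residue COMs within 80% of the cutoff of the
    S1' and S1 centers, "outside" poses place the P1' COM at 1.2-2x the
    cutoff.  Returns the pose set and the constructed correctness flags.
    """
    if peptide_len < 2:
        raise ValueError("peptide_len must be >= 2")
    if n_inside + n_outside < 1:
        raise ValueError("need at least one pose")
    if pocket is None:
        pocket = PocketDefinition(
            s1prime_residue=("A", 268, "ASP"),
            s1_residue=("A", 315, "GLU"),
            cutoff=10.0,
        )
    rng = np.random.default_rng(seed)
    c1 = np.array([0.0, 0.0, 0.0])            # S1' center
    c2 = np.array([8.0, 0.0, 0.0])            # S1 center

    def residue_at(com: np.ndarray) -> list:
        off = np.array([0.5, 0.0, 0.0])
        a, b = com + off, com - off
        return [("C", *map(float, a)), ("C", *map(float, b))]

    receptor = {
        (pocket.s1prime_residue[0], pocket.s1prime_residue[1]): residue_at(c1),
        (pocket.s1_residue[0], pocket.s1_residue[1]): residue_at(c2),
    }

    def unit(rng) -> np.ndarray:
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    poses: list[list] = []
    flags: list[bool] = []
    for inside in [True] * n_inside + [False] * n_outside:
        if inside:
            p1prime_com = c1 + unit(rng) * rng.uniform(0.0, 0.8 * pocket.cutoff)
            p1_com = c2 + unit(rng) * rng.uniform(0.0, 0.8 * pocket.cutoff)
        else:
            p1prime_com = c1 + unit(rng) * rng.uniform(1.2, 2.0) * pocket.cutoff
            p1_com = c2 + unit(rng) * rng.uniform(1.2, 2.0) * pocket.cutoff
        residues = [
            residue_at(p1_com + np.array([0.0, 0.0, 2.0 * (k + 1)]))
            for k in range(peptide_len - 2)
        ]
        residues.append(residue_at(p1_com))
        residues.append(residue_at(p1prime_com))
        poses.append(residues)
        flags.append(inside)
    ps = PoseSet(
        receptor=receptor,
        poses=poses,
        peptide_sequence="A" * peptide_len,
        domain_label="toy",
    )
    return ps, flags


def generate_rates(
    km: float,
    kcat: float,
    enzyme_conc: float,
    concentrations: tuple[float, ...] = ASSAY_SUBSTRATE_CONCENTRATIONS_UM,
    noise_cv: float = 0.0,
    seed: int = 0,
    substrate_name: str = "dansyl-Phe-Ala-Arg",
) -> KineticDataset:
    """Michaelis-Menten rate data from (Km, kcat, enzyme amount).

    Km in uM, kcat in s^-1, enzyme in nM; rates come out in uM/s with
    optional log-normal multiplicative noise.
    """
    if km <= 0 or kcat <= 0 or enzyme_conc <= 0:
        raise ValueError("parameters must be positive")
    rng = np.random.default_rng(seed)
    vmax = kcat * enzyme_nM_to_uM(enzyme_conc)
    rates = mm_rate(np.asarray(concentrations, dtype=float), vmax, km)
    if noise_cv > 0:
        sigma = float(np.sqrt(np.log(1.0 + noise_cv**2)))
        rates = rates * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma,
                                      size=len(rates))
    return KineticDataset(
        substrate_conc=tuple(float(s) for s in concentrations),
        rate=tuple(float(r) for r in rates),
        enzyme_conc=enzyme_conc,
        substrate_name=substrate_name,
    )
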