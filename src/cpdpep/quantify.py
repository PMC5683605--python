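"""Peak-set detection and censored ratio quantification on centroided MS1 data.

A labeled peptide appears as a set of five co-eluting MS1 peaks (one per TMAB
channel).  Detection searches the predicted pattern for every library peptide
at every admissible charge state, assigns the nearest centroid within a ppm
tolerance to each channel, and reports a peak set when at least two channels
match.  Ratios are computed against a designated control channel and censored
at a floor (below-background) and a cap.

Identification validation mirrors the acceptance rules of the labeling
workflow: parent mass within 50 ppm, tag count equal to the number of free
amines, observed charge no greater than the expected charge, and at least
80% of the major MS2 fragments (minimum five) matching the predicted b/y
series.  Peptides containing Cys, Tyr or His are flagged for exclusion.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .digestion import LibraryPeptide
from .peptide_chem import (
    Peptide,
    by_fragment_series,
    count_free_amines,
    expected_charge,
    monoisotopic_mass,
    ppm_difference,
)
from .reference_data import RATIO_CAP, RATIO_FLOOR, Ratio
from .tmab import LabeledPattern, peakset_pattern
from .constants import TMAB_CHANNELS

__all__ = [
    "PeakList",
    "PeakSet",
    "RatioProfile",
    "ValidationReport",
    "read_peaklist",
    "write_peaklist",
    "detect_peaksets",
    "validate_identification",
    "select_major_fragments",
    "compute_ratios",
    "read_ms2_mgf",
]

DEFAULT_TOL_PPM = 50.0
MIN_FRAGMENT_MATCHES = 5
MIN_FRAGMENT_FRACTION = 0.80


@dataclass(frozen=True)
class PeakList:
    """Centroided MS1 peaks of one LC-MS run, sorted by m/z."""

    run_id: str
    mz: tuple[float, ...]
    intensity: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.mz) != len(self.intensity):
            raise ValueError("mz and intensity must have equal length")
        if any(b < a for a, b in zip(self.mz, self.mz[1:])):
            raise ValueError("peak list must be sorted by m/z")
        if any(i < 0 for i in self.intensity):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.mz)

    def background_level(self, quantile: float = 0.05) -> float:
        """Background intensity estimate: a low quantile of run intensities."""
        if not self.intensity:
            return 0.0
        return float(np.quantile(np.asarray(self.intensity), quantile))


@dataclass
class PeakSet:
    """One peptide's 5-channel observations in a run."""

    pattern: LabeledPattern
    channel_intensity: dict[str, float]
    match_ppm: dict[str, float]
    library_peptide: LibraryPeptide | None = None

    @property
    def n_matched(self) -> int:
        return len(self.match_ppm)


@dataclass
class RatioProfile:
    """Censored condition/control intensity ratios for one peptide."""

    peptide: Peptide
    ratios: dict[str, Ratio]
    control_condition: str
    quantifiable: bool = True
    library_peptide: LibraryPeptide | None = None


@dataclass(frozen=True)
class ValidationReport:
    mass_ok: bool
    tag_ok: bool
    charge_ok: bool
    fragment_ok: bool | None
    fragment_match_fraction: float
    fragment_match_count: int
    excluded_residue_flag: bool
    ppm_error: float

    @property
    def accepted(self) -> bool:
        frag = self.fragment_ok if self.fragment_ok is not None else True
        return (
            self.mass_ok
            and self.tag_ok
            and self.charge_ok
            and frag
            and not self.excluded_residue_flag
        )


def read_peaklist(path: str | Path, run_id: str | None = None) -> PeakList:
    """Read a tab-separated (mz, intensity) peak list.

    A leading ``# run: <id>`` header line sets the run id; other ``#`` lines
    are ignored.
    """
    mz: list[float] = []
    inten: list[float] = []
    rid = run_id
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if rid is None and line[1:].strip().lower().startswith("run:"):
                    rid = line.split(":", 1)[1].strip()
                continue
            a, b = line.split("\t")[:2]
            mz.append(float(a))
            inten.append(float(b))
    order = np.argsort(mz, kind="stable")
    return PeakList(
        run_id=rid or Path(path).stem,
        mz=tuple(float(mz[i]) for i in order),
        intensity=tuple(float(inten[i]) for i in order),
    )


def write_peaklist(pl: PeakList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# run: {pl.run_id}\n")
        for m, i in zip(pl.mz, pl.intensity):
            fh.write(f"{m:.5f}\t{i:.3f}\n")


def read_ms2_mgf(path: str | Path) -> dict[str, list[float]]:
    """Read MGF MS2 spectra; returns title -> fragment m/z list."""
    from pyteomics import mgf

    out: dict[str, list[float]] = {}
    with mgf.MGF(str(path)) as reader:
        for spec in reader:
            title = spec["params"].get("title", f"spectrum_{len(out)}")
            out[title] = [float(x) for x in spec["m/z array"]]
    return out


def _nearest_match(pl: PeakList, target: float, tol_ppm: float) -> int | None:
    """Index of the nearest peak within tol_ppm of target, or None.

    Exact ppm ties are broken toward the lower m/z for determinism.
    """
    tol = target * tol_ppm * 1e-6
    lo = bisect.bisect_left(pl.mz, target - tol)
    hi = bisect.bisect_right(pl.mz, target + tol)
    if lo >= hi:
        return None
    best = None
    best_err = None
    for idx in range(lo, hi):
        err = abs(pl.mz[idx] - target)
        if best_err is None or err < best_err:  # strict: ties keep lower m/z
            best, best_err = idx, err
    return best


def detect_peaksets(
    peaks: PeakList,
    library: list[LibraryPeptide] | list[Peptide],
    charges: range | None = None,
    tol_ppm: float = DEFAULT_TOL_PPM,
    min_channels: int = 2,
) -> list[PeakSet]:
    """Search the predicted 5-channel pattern of every library peptide.

    For each peptide, charges 1..expected_charge (or the supplied range) are
    tried and the best-supported charge state is kept, so each peptide is
    reported at most once.  Unlabelable peptides are skipped.  Entries may be
    :class:`LibraryPeptide` or bare :class:`Peptide` objects.
    """
    if not library:
        raise ValueError("library must be non-empty")
    out: list[PeakSet] = []
    for lp in library:
        if isinstance(lp, Peptide):
            lp, p = None, lp
        else:
            p = lp.peptide
        if count_free_amines(p) < 1:
            continue
        z_range = charges if charges is not None else range(1, expected_charge(p) + 1)
        best: PeakSet | None = None
        for z in z_range:
            pattern = peakset_pattern(p, z)
            intens: dict[str, float] = {}
            ppms: dict[str, float] = {}
            for ch in TMAB_CHANNELS:
                idx = _nearest_match(peaks, pattern.channel_mz[ch], tol_ppm)
                if idx is None:
                    intens[ch] = 0.0
                else:
                    intens[ch] = peaks.intensity[idx]
                    ppms[ch] = ppm_difference(peaks.mz[idx], pattern.channel_mz[ch])
            if len(ppms) < min_channels:
                continue
            cand = PeakSet(
                pattern=pattern,
                channel_intensity=intens,
                match_ppm=ppms,
                library_peptide=lp,
            )
            if best is None:
                best = cand
            else:
                key = lambda ps: (
                    ps.n_matched,
                    -float(np.mean([abs(v) for v in ps.match_ppm.values()])),
                )
                if key(cand) > key(best):
                    best = cand
        if best is not None:
            out.append(best)
    return out


def select_major_fragments(
    fragments_mz: list[float],
    fragment_intensity: list[float] | None = None,
    top_n: int = 20,
    rel_threshold: float = 0.05,
) -> list[float]:
    """Major MS2 fragments: the top-N peaks or those >= 5% of the base peak.

    Without intensities, all submitted fragments are treated as major.
    """
    if fragment_intensity is None:
        return list(fragments_mz)
    pairs = sorted(
        zip(fragments_mz, fragment_intensity), key=lambda t: t[1], reverse=True
    )
    base = pairs[0][1] if pairs else 0.0
    major = [mz for i, (mz, inten) in enumerate(pairs)
             if i < top_n or (base > 0 and inten >= rel_threshold * base)]
    return major


def validate_identification(
    peptide: LibraryPeptide | Peptide,
    observed_mass: float,
    observed_charge: int,
    observed_tags: int,
    ms2_fragments: list[float] | None = None,
    frag_tol: float = 0.5,
    tol_ppm: float = DEFAULT_TOL_PPM,
    strict_charge: bool = False,
) -> ValidationReport:
    """Apply the identification acceptance rules to one candidate match."""
    if observed_mass <= 0:
        raise ValueError("observed mass must be positive")
    p = peptide.peptide if isinstance(peptide, LibraryPeptide) else peptide
    theor = monoisotopic_mass(p).monoisotopic_mass
    ppm = ppm_difference(observed_mass, theor)
    mass_ok = abs(ppm) <= tol_ppm
    tag_ok = observed_tags == count_free_amines(p)
    exp_z = expected_charge(p)
    charge_ok = observed_charge == exp_z if strict_charge else observed_charge <= exp_z
    if ms2_fragments is None:
        fragment_ok: bool | None = None
        frac, count = 0.0, 0
    elif len(p) < 2 or not ms2_fragments:
        fragment_ok, frac, count = False, 0.0, 0
    else:
        predicted = [mz for _, mz in by_fragment_series(p)]
        count = 0
        for f in ms2_fragments:
            if any(abs(f - pm) <= frag_tol for pm in predicted):
                count += 1
        frac = count / len(ms2_fragments)
        fragment_ok = frac >= MIN_FRAGMENT_FRACTION and count >= MIN_FRAGMENT_MATCHES
    return ValidationReport(
        mass_ok=mass_ok,
        tag_ok=tag_ok,
        charge_ok=charge_ok,
        fragment_ok=fragment_ok,
        fragment_match_fraction=frac,
        fragment_match_count=count,
        excluded_residue_flag=p.contains_excluded_residue(),
        ppm_error=ppm,
    )


def compute_ratios(
    ps: PeakSet,
    channel_condition: dict[str, str],
    control: str,
    floor: float = RATIO_FLOOR,
    cap: float = RATIO_CAP,
    background: float = 0.0,
) -> RatioProfile:
    """Condition/control intensity ratios with floor/cap censoring.

    The control channel must be above background; otherwise the profile is
    marked unquantifiable.  A condition intensity at or below background is
    censored at the floor regardless of its nominal ratio.
    """
    cond_to_channel = {cond: ch for ch, cond in channel_condition.items()}
    if control not in cond_to_channel:
        raise ValueError(f"control condition {control!r} not in channel map")
    control_intensity = ps.channel_intensity.get(cond_to_channel[control], 0.0)
    peptide = ps.pattern.base_peptide
    if control_intensity <= background or control_intensity <= 0:
        return RatioProfile(
            peptide=peptide,
            ratios={},
            control_condition=control,
            quantifiable=False,
            library_peptide=ps.library_peptide,
        )
    ratios: dict[str, Ratio] = {}
    for cond, ch in cond_to_channel.items():
        if cond == control:
            ratios[cond] = Ratio(1.0)
            continue
        inten = ps.channel_intensity.get(ch, 0.0)
        if inten <= background:
            ratios[cond] = Ratio(floor, censor="low")
            continue
        r = inten / control_intensity
        if r < floor:
            ratios[cond] = Ratio(floor, censor="low")
        elif r > cap:
            ratios[cond] = Ratio(cap, censor="high")
        else:
            ratios[cond] = Ratio(r)
    return RatioProfile(
        peptide=peptide,
        ratios=ratios,
        control_condition=control,
        library_peptide=ps.library_peptide,
    )
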