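"""5-plex TMAB isotopic label model: per-channel masses and peak-set geometry.

Each free amine (the peptide N-terminus plus every Lys side chain) carries one
4-trimethylammoniumbutyryl (TMAB) tag.  Five isotopologue tags (D0, D3, D6,
D9, D12) encode five experimental conditions in one LC-MS run; a labeled
peptide therefore appears as a set of five peaks whose spacing is

    tags x per-tag step / charge

with a per-tag step of 3.01883 Da between deuterated channels and 3.01007 Da
between D9 and D12 (three 13C substitutions).

Charge bookkeeping: the TMAB quaternary ammonium is permanently charged, so
each tag contributes its cation mass and one unit of charge; any remaining
charge is carried by protons.  For a peptide with ``t`` tags observed at
charge ``z``:

    m/z = (labeled_mass + (z - t) x proton) / z

where ``labeled_mass`` is the neutral peptide mass plus ``t`` tag cation
masses.  The channel-to-channel spacing is unaffected by this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constants import (
    PROTON,
    TMAB_CHANNEL_DELTA,
    TMAB_CHANNELS,
    TMAB_TAG_CATION_MASS,
)
from .peptide_chem import Peptide, count_free_amines, monoisotopic_mass

__all__ = [
    "LabelChannel",
    "LabeledPattern",
    "CHANNELS",
    "labeled_mass",
    "peakset_pattern",
    "infer_tag_count_and_charge",
]


@dataclass(frozen=True)
class LabelChannel:
    """One isotopologue channel, optionally bound to an experimental condition."""

    name: str
    per_tag_delta: float
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.name not in TMAB_CHANNEL_DELTA:
            raise ValueError(f"unknown TMAB channel {self.name!r}")


#: The five channels with their per-tag mass offsets relative to D0.
CHANNELS: dict[str, LabelChannel] = {
    name: LabelChannel(name=name, per_tag_delta=TMAB_CHANNEL_DELTA[name])
    for name in TMAB_CHANNELS
}


@dataclass(frozen=True)
class LabeledPattern:
    base_peptide: Peptide
    tag_count: int
    charge: int
    channel_mz: dict[str, float] = field(hash=False)

    def spacing(self, ch_a: str, ch_b: str) -> float:
        return self.channel_mz[ch_b] - self.channel_mz[ch_a]


def labeled_mass(p: Peptide, channel: LabelChannel | str) -> float:
    """Mass of the fully labeled peptide in the given channel.

    This is a "neutral-equivalent" mass: the neutral peptide plus one tag
    cation mass per free amine (charge is handled at the m/z stage).
    """
    if isinstance(channel, str):
        channel = CHANNELS[channel]
    tags = count_free_amines(p)
    if tags < 1:
        raise ValueError(
            f"unlabelable peptide {p.notation()}: no free amines "
            "(acetylated N-terminus and no Lys)"
        )
    return (
        monoisotopic_mass(p).monoisotopic_mass
        + tags * (TMAB_TAG_CATION_MASS + channel.per_tag_delta)
    )


def peakset_pattern(p: Peptide, charge: int) -> LabeledPattern:
    """Predicted 5-channel m/z pattern for a labeled peptide at ``charge``."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    tags = count_free_amines(p)
    mz = {
        name: (labeled_mass(p, name) + (charge - tags) * PROTON) / charge
        for name in TMAB_CHANNELS
    }
    return LabeledPattern(base_peptide=p, tag_count=tags, charge=charge, channel_mz=mz)


def infer_tag_count_and_charge(
    d0_to_d9_spacing: float, d9_to_d12_spacing: float, atol: float = 1e-6
) -> tuple[int, int]:
    """Recover (tag_count, charge) from ideal peak-set spacings.

    The D0-D9 spacing is 3 x 3.01883 x tags / charge and the D9-D12 spacing
    is 3.01007 x tags / charge, so their ratio fixes the geometry and the
    magnitudes fix tags/charge.  Searches tag counts 1..12 and charges 1..8.
    """
    from .constants import C13_STEP, HD_STEP

    for tags in range(1, 13):
        for charge in range(1, 9):
            if (
                abs(d0_to_d9_spacing - 3 * HD_STEP * tags / charge) <= atol
                and abs(d9_to_d12_spacing - C13_STEP * tags / charge) <= atol
            ):
                return tags, charge
    raise ValueError("spacings do not match any TMAB peak-set geometry")
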