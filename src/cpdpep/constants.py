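"""Frozen physical constants used throughout the package.

The residue mass table is versioned here rather than taken from an external
library so that every theoretical-mass column the package reproduces is
traceable to a single fixed set of numbers.  Values are standard monoisotopic
residue (amino-acid minus water) masses to five decimals.
"""

from __future__ import annotations

from types import MappingProxyType

#: Monoisotopic residue masses, Da (residue = amino acid minus water). v1.
MONOISOTOPIC_RESIDUE_MASS = MappingProxyType({
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
})

AMINO_ACIDS = frozenset(MONOISOTOPIC_RESIDUE_MASS)

WATER = 18.01056           # Da, H2O added on hydrolysis of the chain
PROTON = 1.00728           # Da, mass of H+ used for m/z bookkeeping

# Modification deltas, Da
ACETYL_DELTA = 42.01057      # N-terminal acetylation (+C2H2O)
OXIDATION_DELTA = 15.99491   # Met oxidation (+O)

# ---------------------------------------------------------------------------
# TMAB 5-plex label chemistry.
#
# The 4-trimethylammoniumbutyryl (TMAB) group transferred from the NHS ester
# to a free amine is the cation C7H14NO+:
#   7 x 12.000000 + 14 x 1.0078250 + 14.0030740 + 15.9949146 = 128.10753 Da
# The deuterated channels replace 3, 6 or 9 hydrogens with deuterium
# (D - H = 1.0062767 Da, so 3 substitutions add 3.01883 Da), and the heaviest
# channel additionally replaces three 12C with 13C
# (13C - 12C = 1.0033548 Da, so 3 substitutions add 3.01007 Da).
# ---------------------------------------------------------------------------

TMAB_TAG_CATION_MASS = 128.10753   # Da, light (D0) tag added per free amine

HD_STEP = 3.01883      # Da per tag, 3 x (2H - 1H)
C13_STEP = 3.01007     # Da per tag, 3 x (13C - 12C)

#: Mass added per tag relative to the D0 tag, by channel name.
TMAB_CHANNEL_DELTA = MappingProxyType({
    "D0": 0.0,
    "D3": HD_STEP,
    "D6": 2 * HD_STEP,
    "D9": 3 * HD_STEP,
    "D12": 3 * HD_STEP + C13_STEP,
})

TMAB_CHANNELS = ("D0", "D3", "D6", "D9", "D12")

#: Standard atomic weights (heavy atoms) for center-of-mass calculations.
ATOMIC_MASS = MappingProxyType({
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
    "ZN": 65.38,
    "FE": 55.845,
})
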