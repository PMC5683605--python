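"""Loaders for the packaged reference measurement tables.

The package ships the published identification/quantification tables for the
tryptic-library and HEK293T peptidome experiments, and the fitted kinetic
constants for the dansyl-Phe-Ala-Arg assays.  Ratio cells may be censored:
``<0.10`` (below background) and ``>5.00`` (above the reporting cap) are
parsed into :class:`Ratio` values with a censor direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "Ratio",
    "parse_ratio",
    "load_tryptic_good_substrates",
    "load_tryptic_domain_substrates",
    "load_hek_good_substrates",
    "load_kinetic_constants",
]

RATIO_FLOOR = 0.10
RATIO_CAP = 5.00


@dataclass(frozen=True)
class Ratio:
    """A peak-intensity ratio, possibly censored at the floor or cap."""

    value: float
    censor: str | None = None  # None, "low" or "high"

    def __post_init__(self) -> None:
        if self.censor not in (None, "low", "high"):
            raise ValueError(f"invalid censor flag {self.censor!r}")
        if self.value <= 0:
            raise ValueError("ratio must be positive")

    @property
    def censored(self) -> bool:
        return self.censor is not None

    def __str__(self) -> str:
        if self.censor == "low":
            return f"<{self.value:.2f}"
        if self.censor == "high":
            return f">{self.value:.2f}"
        return f"{self.value:.2f}"


def parse_ratio(cell: str | float) -> Ratio:
    """Parse a printed ratio cell such as ``0.54``, ``<0.10`` or ``>5.00``."""
    if isinstance(cell, (int, float)):
        return Ratio(float(cell))
    cell = cell.strip()
    if cell.startswith("<"):
        return Ratio(float(cell[1:]), censor="low")
    if cell.startswith(">"):
        return Ratio(float(cell[1:]), censor="high")
    return Ratio(float(cell))


def _load(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("cpdpep.data") / name) as path:
        return pd.read_csv(path, sep="\t", dtype=str)


def _numeric(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    for c in cols:
        df[c] = pd.to_numeric(df[c])
    return df


def load_tryptic_good_substrates() -> pd.DataFrame:
    """Good substrates from the tryptic-library titration (0.1-100 nM enzyme)."""
    df = _load("tryptic_good_substrates.tsv")
    return _numeric(df, ["z", "t", "obs_m", "theor_m", "ppm"])


def load_tryptic_domain_substrates() -> pd.DataFrame:
    """Good and weak substrates from the domain I/II comparison experiment."""
    df = _load("tryptic_domain_substrates.tsv")
    return _numeric(df, ["z", "t", "obs_m", "theor_m", "ppm"])


def load_hek_good_substrates() -> pd.DataFrame:
    """Good substrates from the HEK293T-derived peptidome titration."""
    df = _load("hek_good_substrates.tsv")
    return _numeric(df, ["z", "t", "obs_m", "theor_m", "ppm"])


def load_kinetic_constants() -> pd.DataFrame:
    """Fitted Michaelis-Menten constants for dansyl-Phe-Ala-Arg hydrolysis."""
    df = _load("kinetic_constants.tsv")
    return _numeric(
        df,
        [
            "enzyme_conc_nM",
            "km_uM",
            "km_se",
            "kcat_per_s",
            "kcat_se",
            "kcat_over_km",
            "kcat_over_km_se",
        ],
    )
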