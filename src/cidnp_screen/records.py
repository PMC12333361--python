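"""Domain types: per-site records, molecules, radical hypotheses and the
flat per-site feature table that the whole analysis revolves around.

The feature table joins, for every proton site, the eight molecular
features used to model steady-state photo-CIDNP enhancement:

==================  =====================================================
column              meaning (units)
==================  =====================================================
ip                  ionization potential of the molecule (eV)
nucleophilicity     nucleophilicity index N (eV)
lumo_homo           E_LUMO(dye) - E_HOMO(molecule) (eV)
delta_g             |g_dye - g_radical| (dimensionless)
a_iso               isotropic hyperfine coupling of the site (MHz, signed)
fukui               condensed nucleophilic Fukui index f- (dimensionless)
q_value             geminate polarization probability Q, stored divided
                    by the ``q_scale`` metadata constant (default 1e21
                    rad^3 s^-3)
log_p               octanol-water partition coefficient (dimensionless)
==================  =====================================================

plus the observed absolute signal-to-noise enhancement ``sne`` (>= 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

FAMILIES = ("indole", "amino_acid", "phenol")
MECHANISMS = ("ET", "PCET", "unknown")

#: The eight feature columns, in canonical order.
FEATURE_COLUMNS = (
    "ip",
    "nucleophilicity",
    "lumo_homo",
    "delta_g",
    "a_iso",
    "fukui",
    "q_value",
    "log_p",
)
ID_COLUMNS = ("molecule_id", "family", "series", "site_id")
RESPONSE_COLUMN = "sne"
OPTIONAL_COLUMNS = ("hirshfeld_charge", "spin_density", "mechanism")
REQUIRED_COLUMNS = ID_COLUMNS + FEATURE_COLUMNS + (RESPONSE_COLUMN,)

#: Mapping internal column name -> CSV header (units live in the header).
CSV_HEADERS = {
    "ip": "ip_eV",
    "nucleophilicity": "nucleophilicity_eV",
    "lumo_homo": "lumo_homo_eV",
    "a_iso": "a_iso_MHz",
}


@dataclass
class SiteRecord:
    """One proton site of one molecule."""

    molecule_id: str
    site_id: str
    a_iso: float  # MHz, signed
    fukui: float
    q_value: float
    sne: float
    hirshfeld_charge: Optional[float] = None
    spin_density: Optional[float] = None


@dataclass
class MoleculeRecord:
    """A molecule with its molecule-level features and proton sites."""

    molecule_id: str
    family: str
    series: str
    ip: float
    nucleophilicity: float
    lumo_homo: float
    delta_g: float
    log_p: float
    sites: list[SiteRecord] = field(default_factory=list)
    mechanism: str = "unknown"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")


@dataclass
class RadicalHypothesis:
    """Candidate radical formed by one mechanism (ET or PCET).

    Carries the radical's g-factor and the signed isotropic hyperfine
    coupling of every proton site, as needed by Kaptein's sign rules.
    """

    mechanism: str  # "ET" or "PCET"
    g_radical: float
    a_iso_by_site: dict[str, float]

    def __post_init__(self) -> None:
        if self.mechanism not in ("ET", "PCET"):
            raise ValueError(f"mechanism must be 'ET' or 'PCET', got {self.mechanism!r}")


@dataclass
class FeatureTable:
    """Flat per-site table of the eight features plus observed SNE.

    Thin wrapper around a :class:`pandas.DataFrame` that fixes the schema
    and carries table-level metadata (notably the Q storage scale).
    """

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    feature_names: tuple[str, ...] = FEATURE_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"feature table is missing required columns: {missing}")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_molecules(self) -> int:
        return self.frame["molecule_id"].nunique()

    def features(self) -> pd.DataFrame:
        """The 8-column feature matrix, in canonical column order."""
        return self.frame[list(FEATURE_COLUMNS)]

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.frame.copy(), dict(self.metadata))
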