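"""Derived molecular features.

The non-trivial derivations implemented here are

* the condensed nucleophilic Fukui index f-, the per-atom change of
  electron density upon removal of one electron, which localizes the
  radical hole and thereby the site most likely to polarize;
* the geminate polarization probability
  Q = (1/12) |a_iso|^2 |g_D - g_M| mu_B B0 / hbar,
  the field- and coupling-dependent part of the geminate polarization of a
  spin-correlated radical pair (the radical-pair lifetime factor is
  deliberately omitted: for rapid diffusion beyond the exchange region it
  is a common prefactor across sites);
* the LUMO(dye)-HOMO(target) gap and an atom-contribution logP estimate.

Ionization potential and nucleophilicity index are ingested numbers —
computing them requires electronic-structure calculations, which are out
of scope for this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .constants import CODATA, PhysicalConstants
from .records import FeatureTable, MoleculeRecord


class MappingError(KeyError):
    """A site map references an atom absent from the charge table."""


@dataclass
class ChargeTable:
    """Partial charges of a molecule in its N and N-1 electron states.

    ``site_map`` maps each proton site label to the heavy atom bearing it;
    hydrogen charges are assumed already folded into their bonded heavy
    atoms (standard condensed-Fukui practice).
    """

    molecule_id: str
    atom_ids: list[str]
    charges_n: np.ndarray
    charges_nm1: np.ndarray
    site_map: Mapping[str, str]

    def __post_init__(self) -> None:
        self.charges_n = np.asarray(self.charges_n, dtype=float)
        self.charges_nm1 = np.asarray(self.charges_nm1, dtype=float)
        if len(self.atom_ids) != self.charges_n.size or self.charges_n.size != self.charges_nm1.size:
            raise ValueError("atom_ids, charges_n and charges_nm1 must have equal length")
        removed = float(self.charges_nm1.sum() - self.charges_n.sum())
        if abs(removed - 1.0) > 1e-6:
            raise ValueError(
                f"{self.molecule_id}: charge difference between N-1 and N states is "
                f"{removed:+.8f} e, expected +1 (one electron removed)"
            )


def fukui_per_atom(charges: ChargeTable) -> np.ndarray:
    """Per-atom nucleophilic Fukui indices f-_k = q_k(N-1) - q_k(N).

    Sums to exactly the one removed electron (within the charge-table
    tolerance), so the values form a normalized distribution of the hole.
    """
    return charges.charges_nm1 - charges.charges_n


def condensed_fukui(charges: ChargeTable) -> dict[str, float]:
    """Condense f- onto each proton site's heavy atom.

    Returns a mapping site_id -> f- of the heavy atom bearing the proton.
    Raises :class:`MappingError` if the site map points at an unknown atom.
    """
    f = fukui_per_atom(charges)
    index = {a: i for i, a in enumerate(charges.atom_ids)}
    out: dict[str, float] = {}
    for site_id, heavy_atom in charges.site_map.items():
        if heavy_atom not in index:
            raise MappingError(
                f"{charges.molecule_id}: site {site_id!r} maps to unknown atom {heavy_atom!r}"
            )
        out[site_id] = float(f[index[heavy_atom]])
    return out


def geminate_polarization_q(
    a_iso,
    g_dye: float,
    g_mol,
    b0: float,
    constants: PhysicalConstants = CODATA,
):
    """Geminate polarization probability Q in rad^3 s^-3.

    Q = (1/12) (a_iso in rad/s)^2 |g_dye - g_mol| (mu_B/hbar) B0.
    Quadratic in the hyperfine coupling and linear in both the g-factor
    difference and the field. Accepts scalars or arrays for ``a_iso`` and
    ``g_mol``. ``a_iso`` is in MHz; its sign (used by Kaptein's rules)
    does not affect Q.
    """
    if b0 <= 0:
        raise ValueError(f"b0 must be positive, got {b0}")
    omega = np.asarray(a_iso, dtype=float) * constants.mhz_to_rad_s
    dg = np.abs(g_dye - np.asarray(g_mol, dtype=float))
    q = (omega**2 / 12.0) * dg * constants.mu_B_over_hbar * b0
    return q if q.ndim else float(q)


def lumo_homo_gap(e_homo_target, e_lumo_dye: float):
    """Energy gap E_LUMO(dye) - E_HOMO(target), eV."""
    gap = np.asarray(e_lumo_dye, dtype=float) - np.asarray(e_homo_target, dtype=float)
    return gap if gap.ndim else float(gap)


class LogPFlag(str, Enum):
    SUPPLIED = "supplied"
    ESTIMATED = "estimated"


def estimate_log_p(
    smiles: Optional[str] = None, supplied: Optional[float] = None
) -> tuple[float, LogPFlag]:
    """Partition coefficient logP: pass through a supplied value, or
    estimate it from a SMILES string with the Wildman-Crippen
    atom-contribution scheme.

    Returns ``(value, flag)`` where the flag records provenance.
    """
    if supplied is not None:
        return float(supplied), LogPFlag.SUPPLIED
    if smiles is None:
        raise ValueError("logP needs either a supplied value or a SMILES structure")
    from rdkit import Chem
    from rdkit.Chem import Crippen

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"could not parse SMILES {smiles!r}")
    return float(Crippen.MolLogP(mol)), LogPFlag.ESTIMATED


class AmbiguousMechanismError(ValueError):
    """A molecule still carries two competing radical parameter sets."""


def assemble_features(
    molecules: list[MoleculeRecord], config: PipelineConfig
) -> FeatureTable:
    """Assemble the flat per-site 8-feature table from molecule records.

    One row per proton site; Q is recomputed from each site's (signed)
    a_iso and the molecule's delta_g under the configured field, then
    stored divided by ``config.q_scale``. Molecules whose mechanism is
    still unresolved between ET and PCET are rejected — resolve them with
    the mechanism module first. Deterministic: identical inputs give a
    bit-identical table.
    """
    rows = []
    for mol in molecules:
        if mol.mechanism == "unknown" and getattr(mol, "pending_hypotheses", None):
            raise AmbiguousMechanismError(
                f"{mol.molecule_id}: two candidate radical parameter sets present; "
                "run mechanism assignment before assembling features"
            )
        if not mol.sites:
            raise ValueError(f"{mol.molecule_id}: molecule has no sites")
        for site in mol.sites:
            q = geminate_polarization_q(
                abs(site.a_iso), config.g_dye, config.g_dye - mol.delta_g, config.b0
            )
            rows.append(
                {
                    "molecule_id": mol.molecule_id,
                    "family": mol.family,
                    "series": mol.series,
                    "site_id": site.site_id,
                    "ip": mol.ip,
                    "nucleophilicity": mol.nucleophilicity,
                    "lumo_homo": mol.lumo_homo,
                    "delta_g": mol.delta_g,
                    "a_iso": site.a_iso,
                    "fukui": site.fukui,
                    "q_value": q / config.q_scale,
                    "log_p": mol.log_p,
                    "sne": site.sne,
                    "hirshfeld_charge": site.hirshfeld_charge,
                    "spin_density": site.spin_density,
                    "mechanism": mol.mechanism,
                }
            )
    frame = pd.DataFrame(rows)
    return FeatureTable(frame, {"q_scale": config.q_scale, "b0": config.b0, "g_dye": config.g_dye})
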