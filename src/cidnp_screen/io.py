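"""CSV readers/writers and dataset validation.

All tabular I/O is UTF-8 CSV with a header row and "." decimal separator.
The feature-table schema (units in the headers) is::

    molecule_id,family,series,site_id,ip_eV,nucleophilicity_eV,lumo_homo_eV,
    delta_g,a_iso_MHz,fukui,q_value,log_p,sne[,hirshfeld_charge,spin_density,mechanism]
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .records import (
    CSV_HEADERS,
    FAMILIES,
    FEATURE_COLUMNS,
    OPTIONAL_COLUMNS,
    REQUIRED_COLUMNS,
    FeatureTable,
)

log = logging.getLogger("cidnp_screen")

_CSV_TO_INTERNAL = {v: k for k, v in CSV_HEADERS.items()}


class SchemaError(ValueError):
    """A required column is absent or mis-named."""


class IntegrityError(ValueError):
    """Duplicate keys or structurally inconsistent rows."""


@dataclass
class Violation:
    row: int  # positional index in the table, -1 for table-level issues
    molecule_id: str
    site_id: str
    kind: str
    message: str


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_dataset`; report-only, never raises."""

    n_rows: int
    n_molecules: int
    violations: list[Violation] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.violations

    def summary(self) -> str:
        status = "clean" if self.clean else f"{len(self.violations)} violation(s)"
        return f"{self.n_rows} sites / {self.n_molecules} molecules: {status}"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(v.row, v.molecule_id, v.site_id, v.kind, v.message) for v in self.violations],
            columns=["row", "molecule_id", "site_id", "kind", "message"],
        )


def load_feature_table(path: str | Path, config: PipelineConfig | None = None) -> FeatureTable:
    """Read a per-site feature CSV into a validated :class:`FeatureTable`.

    Rows with any missing required field are rejected; a report of the
    dropped rows is logged. Raises :class:`SchemaError` when a required
    column is absent and :class:`IntegrityError` on duplicate
    (molecule_id, site_id) keys.
    """
    df = pd.read_csv(
        path,
        dtype={"molecule_id": str, "site_id": str, "series": str},
        float_precision="round_trip",
    )
    df = df.rename(columns=_CSV_TO_INTERNAL)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    n_before = len(df)
    bad = df[list(REQUIRED_COLUMNS)].isna().any(axis=1)
    if bad.any():
        dropped = df.loc[bad, ["molecule_id", "site_id"]]
        log.warning(
            "%s: rejected %d row(s) with missing required fields: %s",
            path, int(bad.sum()), dropped.to_dict("records"),
        )
        df = df.loc[~bad]
    dup = df.duplicated(subset=["molecule_id", "site_id"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["molecule_id", "site_id"]].drop_duplicates().to_dict("records")
        raise IntegrityError(f"{path}: duplicate (molecule_id, site_id) keys: {keys}")

    meta = {"source": str(path), "n_rejected_rows": int(n_before - len(df))}
    if config is not None:
        meta["q_scale"] = config.q_scale
    return FeatureTable(df.reset_index(drop=True), meta)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table using the documented unit-suffixed headers.

    Floats are written with ``repr`` precision so that write -> read is an
    identity for finite values.
    """
    df = table.frame.rename(columns=CSV_HEADERS)
    df.to_csv(path, index=False, float_format="%.17g")


def validate_dataset(table: FeatureTable) -> ValidationReport:
    """Check every table invariant and list violations per row.

    Checks: non-negative SNE and q_value, non-negative delta_g, finite
    feature values, known family labels, unique (molecule_id, site_id).
    Idempotent and side-effect free.
    """
    df = table.frame
    report = ValidationReport(n_rows=len(df), n_molecules=table.n_molecules)

    def _add(idx: int, kind: str, message: str) -> None:
        mol = str(df.at[idx, "molecule_id"]) if idx >= 0 else ""
        site = str(df.at[idx, "site_id"]) if idx >= 0 else ""
        report.violations.append(Violation(idx, mol, site, kind, message))

    feat = df[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    finite = np.isfinite(feat).all(axis=1)
    for idx in df.index[~finite]:
        _add(int(idx), "non_finite_feature", "non-finite value in feature columns")
    for idx in df.index[df["sne"].to_numpy(dtype=float) < 0]:
        _add(int(idx), "negative_sne", f"sne = {df.at[idx, 'sne']} < 0")
    for idx in df.index[df["q_value"].to_numpy(dtype=float) < 0]:
        _add(int(idx), "negative_q", f"q_value = {df.at[idx, 'q_value']} < 0")
    for idx in df.index[df["delta_g"].to_numpy(dtype=float) < 0]:
        _add(int(idx), "negative_delta_g", f"delta_g = {df.at[idx, 'delta_g']} < 0")
    for idx in df.index[~df["family"].isin(FAMILIES)]:
        _add(int(idx), "unknown_family", f"family {df.at[idx, 'family']!r} not in {FAMILIES}")
    dup = df.duplicated(subset=["molecule_id", "site_id"], keep=False)
    for idx in df.index[dup]:
        _add(int(idx), "duplicate_site", "duplicate (molecule_id, site_id)")
    return report


# -- auxiliary tables -----------------------------------------------------

def load_charge_tables(charges_path: str | Path, site_map_path: str | Path):
    """Read per-atom charge CSVs for the N / N-1 electron states.

    ``charges_path`` columns: molecule_id,atom_id,charge_n,charge_nm1.
    ``site_map_path`` columns: molecule_id,site_id,heavy_atom_id.
    Returns a dict molecule_id -> :class:`~cidnp_screen.features.ChargeTable`.
    """
    from .features import ChargeTable  # local import to avoid a cycle

    charges = pd.read_csv(charges_path, dtype={"molecule_id": str, "atom_id": str})
    smap = pd.read_csv(site_map_path, dtype={"molecule_id": str, "site_id": str, "heavy_atom_id": str})
    tables: dict[str, ChargeTable] = {}
    for mol, grp in charges.groupby("molecule_id", sort=False):
        mol_map = smap[smap["molecule_id"] == mol]
        tables[str(mol)] = ChargeTable(
            molecule_id=str(mol),
            atom_ids=list(grp["atom_id"]),
            charges_n=grp["charge_n"].to_numpy(dtype=float),
            charges_nm1=grp["charge_nm1"].to_numpy(dtype=float),
            site_map=dict(zip(mol_map["site_id"], mol_map["heavy_atom_id"])),
        )
    return tables


def load_radical_hypotheses(g_path: str | Path, a_iso_path: str | Path):
    """Read candidate-radical CSVs.

    ``g_path`` columns: molecule_id,mechanism,g_radical; ``a_iso_path``
    columns: molecule_id,mechanism,site_id,a_iso_MHz. Returns a dict
    molecule_id -> list[RadicalHypothesis].
    """
    from .records import RadicalHypothesis

    gdf = pd.read_csv(g_path, dtype={"molecule_id": str, "mechanism": str})
    adf = pd.read_csv(a_iso_path, dtype={"molecule_id": str, "mechanism": str, "site_id": str})
    out: dict[str, list[RadicalHypothesis]] = {}
    for (mol, mech), grp in gdf.groupby(["molecule_id", "mechanism"], sort=False):
        if len(grp) != 1:
            raise IntegrityError(f"multiple g_radical rows for ({mol}, {mech})")
        sub = adf[(adf["molecule_id"] == mol) & (adf["mechanism"] == mech)]
        hyp = RadicalHypothesis(
            mechanism=str(mech),
            g_radical=float(grp["g_radical"].iloc[0]),
            a_iso_by_site=dict(zip(sub["site_id"], sub["a_iso_MHz"].astype(float))),
        )
        out.setdefault(str(mol), []).append(hyp)
    return out


def load_observed_signs(path: str | Path) -> dict[str, dict[str, int]]:
    """Read observed per-site polarization signs (+1 absorptive / -1 emissive)."""
    df = pd.read_csv(path, dtype={"molecule_id": str, "site_id": str})
    out: dict[str, dict[str, int]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["molecule_id"], {})[row["site_id"]] = int(row["sign"])
    return out
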