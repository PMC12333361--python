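"""Pipeline configuration.

A single :class:`PipelineConfig` carries every tunable of the analysis:
the spectrometer field, the dye's electronic parameters, the SNE class
thresholds, repeated-split run counts and the one global random seed from
which every stochastic stage derives its own child seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .constants import Q_SCALE


@dataclass
class PipelineConfig:
    """Configuration for the whole screening pipeline.

    Parameters
    ----------
    b0
        Static magnetic field in Tesla. Default 14.1 T (600 MHz proton
        Larmor frequency).
    g_dye
        g-factor of the dye radical. Typical xanthene-dye radical value;
        override to match the dye actually used.
    e_lumo_dye
        LUMO energy of the dye in eV, used for the LUMO-HOMO gap feature.
    class_thresholds
        (low_upper, high_lower) SNE boundaries of the low/medium/high
        enhancement classes.
    n_class_runs, n_regress_runs
        Number of repeated random splits for classification / regression.
    class_train_fraction
        Train fraction of the stratified classification split.
    regress_fractions
        (train, validation, test) fractions for the regression suite.
    kaptein_mu, kaptein_eps
        Sign conventions of Kaptein's net-effect rule: precursor
        multiplicity (+1 triplet, -1 singlet) and product channel
        (+1 recombination, -1 escape).
    q_scale
        Divisor applied to Q before it is stored as the ``q_value``
        feature, recorded in table metadata.
    random_seed
        Global seed; every stochastic operation derives a child seed
        deterministically from it.
    """

    b0: float = 14.1
    g_dye: float = 2.0034
    e_lumo_dye: float = -2.87
    class_thresholds: tuple[float, float] = (40.0, 90.0)
    n_class_runs: int = 10_000
    n_regress_runs: int = 100
    class_train_fraction: float = 0.7
    regress_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    kaptein_mu: int = +1
    kaptein_eps: int = +1
    q_scale: float = Q_SCALE
    random_seed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        low, high = self.class_thresholds
        if not (0 < low < high):
            raise ValueError(
                f"class_thresholds must satisfy 0 < low_upper < high_lower, got {self.class_thresholds}"
            )
        if self.b0 <= 0:
            raise ValueError(f"b0 must be positive, got {self.b0}")
        if self.kaptein_mu not in (+1, -1) or self.kaptein_eps not in (+1, -1):
            raise ValueError("kaptein_mu and kaptein_eps must be +1 or -1")

    # -- seeding ---------------------------------------------------------
    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed.

        Hashing the stage name keeps stages statistically independent while
        the whole run remains reproducible from ``random_seed`` alone.
        """
        digest = hashlib.sha256(f"{self.random_seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(self.child_seed(stage))

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_thresholds"] = list(self.class_thresholds)
        d["regress_fractions"] = list(self.regress_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "class_thresholds" in d:
            d["class_thresholds"] = tuple(d["class_thresholds"])
        if "regress_fractions" in d:
            d["regress_fractions"] = tuple(d["regress_fractions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        """Stable hash of the configuration, recorded in run manifests."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, random_seed=int(seed))
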