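"""Simulation configuration and seeded random substreams.

A single :class:`SimConfig` drives every synthetic-data generator. One
global seed is split into independent, named substreams (one per pipeline
stage) so that regenerating a single stage is reproducible without
replaying the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Tuple

import numpy as np
import yaml


class InvalidConfigError(ValueError):
    """Raised when a SimConfig violates one of its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Fractions are in [0, 1]; counts are >= 1; times are in days. The
    defaults describe the simulated study conditions used throughout the
    test-suite: four screens over 5,000 genes, a dual-guide library with a
    30% recombined-pair rate, single-timepoint heavy/light labeling at
    7 days, and a two-condition RNA-seq design with four replicates.
    """

    seed: int = 0

    # --- screens ---
    n_genes: int = 5000
    n_screens: int = 4
    frac_shared_hits: float = 0.02
    frac_specific_hits: float = 0.01
    frac_weak_hits: float = 0.0
    effect_mean: float = 4.0
    effect_sd: float = 0.3
    weak_effect_mean: float = 2.2

    # --- dual-guide reads ---
    n_reads: int = 100_000
    n_constructs: int = 200
    recombination_rate: float = 0.3
    guide_length: int = 20
    read_length: int = 50

    # --- dSILAC peptides ---
    n_proteins: int = 200
    peptides_per_protein: Tuple[int, int] = (3, 8)
    true_halflife_range: Tuple[float, float] = (0.5, 30.0)
    labeling_time: float = 7.0
    ratio_cv: float = 0.05
    n_replicates: int = 4
    frac_halflife_change: float = 0.0
    halflife_lfc: float = 1.0
    contaminant_rate: float = 0.0
    outlier_ratio_rate: float = 0.0

    # --- splice junctions ---
    n_junctions: int = 400
    frac_cryptic: float = 0.2
    frac_skipping: float = 0.15
    frac_retention: float = 0.15
    cryptic_dpsi: float = 0.5
    psi_noise: float = 0.02
    n_samples_per_group: int = 4

    # --- RNA-seq counts ---
    nb_dispersion: float = 0.05
    frac_de: float = 0.05
    de_lfc: float = 2.0

    def __post_init__(self) -> None:
        fracs = {
            "frac_shared_hits": self.frac_shared_hits,
            "frac_specific_hits": self.frac_specific_hits,
            "frac_weak_hits": self.frac_weak_hits,
            "recombination_rate": self.recombination_rate,
            "ratio_cv": self.ratio_cv,
            "frac_cryptic": self.frac_cryptic,
            "frac_skipping": self.frac_skipping,
            "frac_retention": self.frac_retention,
            "frac_de": self.frac_de,
            "frac_halflife_change": self.frac_halflife_change,
            "contaminant_rate": self.contaminant_rate,
            "outlier_ratio_rate": self.outlier_ratio_rate,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise InvalidConfigError(f"{name}={value} must be in [0, 1]")
        counts = {
            "n_genes": self.n_genes,
            "n_screens": self.n_screens,
            "n_reads": self.n_reads,
            "n_constructs": self.n_constructs,
            "n_proteins": self.n_proteins,
            "n_junctions": self.n_junctions,
            "n_samples_per_group": self.n_samples_per_group,
            "n_replicates": self.n_replicates,
        }
        for name, value in counts.items():
            if value < 1:
                raise InvalidConfigError(f"{name}={value} must be >= 1")
        if self.frac_shared_hits + self.frac_specific_hits + self.frac_weak_hits > 1:
            raise InvalidConfigError(
                "hit fractions sum to more than 1: "
                f"{self.frac_shared_hits} + {self.frac_specific_hits} "
                f"+ {self.frac_weak_hits}"
            )
        if self.labeling_time <= 0:
            raise InvalidConfigError("labeling_time must be > 0")
        lo, hi = self.true_halflife_range
        if lo <= 0 or hi < lo:
            raise InvalidConfigError(
                f"true_halflife_range={self.true_halflife_range} must be 0 < lo <= hi"
            )
        plo, phi = self.peptides_per_protein
        if plo < 1 or phi < plo:
            raise InvalidConfigError(
                f"peptides_per_protein={self.peptides_per_protein} must be 1 <= lo <= hi"
            )
        if self.nb_dispersion <= 0:
            raise InvalidConfigError("nb_dispersion must be > 0")
        if self.frac_de > 0 and self.de_lfc == 0:
            raise InvalidConfigError("frac_de > 0 requires a nonzero de_lfc")
        if not 0 < self.frac_cryptic + self.frac_skipping + self.frac_retention <= 1:
            if self.frac_cryptic + self.frac_skipping + self.frac_retention > 1:
                raise InvalidConfigError("junction category fractions sum to more than 1")

    def rng(self, stage: str) -> np.random.Generator:
        """Independent generator for a named pipeline stage.

        The stage name is hashed (CRC32, stable across runs and platforms)
        and combined with the global seed, so each stage sees its own
        reproducible stream.
        """
        return np.random.default_rng([self.seed, zlib.crc32(stage.encode())])

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("peptides_per_protein", "true_halflife_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)
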