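"""Configuration objects for cohort simulation and the pipeline.

Defaults reproduce the structure of the study cohort this package models:
11 colorectal-cancer patients (3 mismatch-repair deficient), 623 routine
2 mm TMA cores plus a 337-core over-fixed stock-tissue batch that fails QC,
and 323 digitally quantified cores split 146/177 into test and validation
sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

PROTEINS = ("MLH1", "PMS2", "MSH2", "MSH6")

#: Loss patterns seen in MMR-deficient colorectal tumors.  MLH1 loss drags
#: PMS2 down with it (heterodimer partner), MSH2 loss drags MSH6; isolated
#: PMS2 or MSH6 loss occurs alone.
DEFAULT_PATTERN_WEIGHTS: Mapping[str, float] = {
    "MLH1+PMS2": 0.5,
    "MSH2+MSH6": 0.25,
    "PMS2": 0.125,
    "MSH6": 0.125,
}


class ConfigurationError(ValueError):
    """Raised when simulation or pipeline parameters are inconsistent."""


@dataclass
class CohortConfig:
    """Parameters of the synthetic TMA cohort generator.

    Parameters
    ----------
    n_patients, n_deficient
        Cohort size and number of MMR-deficient patients.
    n_routine_cores
        Cores taken from routinely fixed blocks, spread as evenly as
        possible across patients.
    n_overfixed_cores
        Cores from over-fixed tissue stocks; they lose PMS2 nuclear
        staining and always fail QC.
    n_quantified
        QC-passing cores selected for digital quantification (``None``
        means all of them).
    tumor_fraction
        Fraction of each patient's cores taken from tumor rather than
        normal mucosa.
    cores_per_block
        TMA block capacity (2 mm cores per paraffin block).
    pattern_weights
        Probability of each protein-loss pattern for deficient patients.
    b_mean, b_sd
        Truncated-normal parameters (on [0, 100]) of the latent mean
        strong-positive intensity ``B`` of stained sections.
    w_alpha, w_beta
        Beta parameters of the latent stained-pixel fraction ``W`` of
        stained sections.
    background_ceiling
        Hard upper bound on ``W`` of an unstained section (residual
        background DAB only).
    heterogeneity
        Focal staining extent in (0, 1]; multiplies ``W`` of stained
        sections.  1.0 disables the effect.
    """

    n_patients: int = 11
    n_deficient: int = 3
    n_routine_cores: int = 623
    n_overfixed_cores: int = 337
    n_quantified: int | None = 323
    tumor_fraction: float = 0.6
    cores_per_block: int = 60
    pattern_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATTERN_WEIGHTS)
    )
    b_mean: float = 80.0
    b_sd: float = 10.0
    w_alpha: float = 5.0
    w_beta: float = 3.0
    background_ceiling: float = 0.05
    heterogeneity: float = 1.0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not 0 <= self.n_deficient <= self.n_patients:
            raise ConfigurationError("n_deficient must lie in [0, n_patients]")
        if self.n_routine_cores < self.n_patients:
            raise ConfigurationError("need at least one routine core per patient")
        if self.n_overfixed_cores < 0:
            raise ConfigurationError("n_overfixed_cores must be >= 0")
        if not 0.0 < self.tumor_fraction <= 1.0:
            raise ConfigurationError("tumor_fraction must be in (0, 1]")
        if self.cores_per_block < 1:
            raise ConfigurationError("cores_per_block must be >= 1")
        total = sum(self.pattern_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"pattern_weights must sum to 1 (got {total:g})"
            )
        for pattern in self.pattern_weights:
            for protein in pattern.split("+"):
                if protein not in PROTEINS:
                    raise ConfigurationError(f"unknown protein {protein!r}")
        if not 0.0 < self.background_ceiling < 1.0:
            raise ConfigurationError("background_ceiling must be in (0, 1)")
        if not 0.0 < self.heterogeneity <= 1.0:
            raise ConfigurationError("heterogeneity must be in (0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pattern_weights"] = dict(self.pattern_weights)
        return d


@dataclass
class NoiseConfig:
    """Measurement noise of the tabular (image-free) quantification path.

    Observed values are latent values plus independent Gaussian noise,
    clipped to their valid ranges.
    """

    b_noise_sd: float = 4.0
    w_noise_sd: float = 0.02
    histoscore_noise_sd: float = 10.0

    def validate(self) -> None:
        if min(self.b_noise_sd, self.w_noise_sd, self.histoscore_noise_sd) < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
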