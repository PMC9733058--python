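"""Synthetic TMA cohort generation.

Produces patients with known MMR status, 2 mm tissue cores distributed
over TMA blocks, and per-section ground truth (stained / unstained plus
latent quantification values) for the four MMR proteins MLH1, PMS2, MSH2
and MSH6.  Tumor cores of a deficient patient lose exactly the proteins
in the patient's loss pattern; normal-mucosa and control cores always
retain all four.  Cores from over-fixed tissue stocks additionally lose
PMS2 and are flagged to fail QC — mirroring the formalin over-fixation
artifact — so every downstream stage can be exercised without any
patient data.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import PROTEINS, CohortConfig, ConfigurationError, NoiseConfig

logger = logging.getLogger(__name__)


class StructuralError(ValueError):
    """Raised when a table violates the cohort schema (e.g. a core is
    missing one of the four protein sections)."""


@dataclass
class CohortTable:
    """A synthetic cohort: patients, cores and per-section ground truth.

    Attributes
    ----------
    patients
        Columns ``patient_id``, ``mmr_status`` (``deficient`` /
        ``proficient``), ``loss_pattern`` (``+``-joined proteins, empty
        string for proficient patients).
    cores
        Columns ``core_id``, ``patient_id``, ``block_id``,
        ``tissue_type`` (``tumor`` / ``normal_mucosa`` / ``control``),
        ``fixation_class`` (``routine`` / ``over_fixed``), ``qc_pass``.
    sections
        One row per (core, protein): ``core_id``, ``protein``,
        ``stained`` (ground truth), ``latent_B``, ``latent_W``,
        ``heterogeneity``.
    n_qc_excluded
        Cores removed by :func:`apply_qc_filter` (0 before filtering).
    """

    patients: pd.DataFrame
    cores: pd.DataFrame
    sections: pd.DataFrame
    n_qc_excluded: int = 0

    def to_csv_bytes(self) -> bytes:
        """Serialize the three tables into one reproducible CSV stream."""
        buf = io.StringIO()
        for name, frame in (
            ("patients", self.patients),
            ("cores", self.cores),
            ("sections", self.sections),
        ):
            buf.write(f"# {name}\n")
            frame.to_csv(buf, index=False, float_format="%.10g")
        return buf.getvalue().encode()


def _loss_patterns(rng: np.random.Generator, cfg: CohortConfig) -> list[str]:
    patterns = list(cfg.pattern_weights)
    weights = np.array([cfg.pattern_weights[p] for p in patterns])
    picks = rng.choice(len(patterns), size=cfg.n_deficient, p=weights)
    return [patterns[i] for i in picks]


def _split_counts(total: int, parts: int) -> np.ndarray:
    """Distribute `total` items over `parts` bins as evenly as possible."""
    base = total // parts
    counts = np.full(parts, base, dtype=int)
    counts[: total - base * parts] += 1
    return counts


def generate_cohort(config: CohortConfig, seed: int) -> CohortTable:
    """Generate a cohort with the configured structure, deterministically.

    All randomness derives from ``seed`` through per-stage substreams, so
    the same (config, seed) pair yields byte-identical tables.
    """
    config.validate()
    if seed is None:
        raise ConfigurationError("a seed is required")
    root = np.random.SeedSequence(seed)
    rng_struct, rng_latent = (np.random.default_rng(s) for s in root.spawn(2))

    status = ["deficient"] * config.n_deficient + ["proficient"] * (
        config.n_patients - config.n_deficient
    )
    losses = _loss_patterns(rng_struct, config)
    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(config.n_patients)],
            "mmr_status": status,
            "loss_pattern": losses + [""] * (config.n_patients - config.n_deficient),
        }
    )

    # Cores: routine batch spread evenly over patients, then the
    # over-fixed stock batch.  Blocks are filled sequentially.
    rows = []
    routine_counts = _split_counts(config.n_routine_cores, config.n_patients)
    overfixed_counts = (
        _split_counts(config.n_overfixed_cores, config.n_patients)
        if config.n_overfixed_cores
        else np.zeros(config.n_patients, dtype=int)
    )
    for pid, n_routine, n_over in zip(
        patients["patient_id"], routine_counts, overfixed_counts
    ):
        n_tumor = int(round(config.tumor_fraction * n_routine))
        for j in range(n_routine):
            rows.append(
                (pid, "tumor" if j < n_tumor else "normal_mucosa", "routine")
            )
        for _ in range(n_over):
            rows.append((pid, "tumor", "over_fixed"))
    core_df = pd.DataFrame(rows, columns=["patient_id", "tissue_type", "fixation_class"])
    # Shuffle placement across blocks so over-fixed cores are interleaved.
    order = rng_struct.permutation(len(core_df))
    core_df = core_df.iloc[order].reset_index(drop=True)
    core_df.insert(0, "core_id", [f"C{i + 1:04d}" for i in range(len(core_df))])
    core_df["block_id"] = [
        f"B{i // config.cores_per_block + 1:02d}" for i in range(len(core_df))
    ]
    core_df["qc_pass"] = core_df["fixation_class"] == "routine"
    core_df = core_df[
        ["core_id", "patient_id", "block_id", "tissue_type", "fixation_class", "qc_pass"]
    ]

    sections = _draw_section_truths(core_df, patients, config, rng_latent)
    logger.info(
        "generated cohort: %d patients (%d deficient), %d cores, %d sections",
        len(patients), config.n_deficient, len(core_df), len(sections),
    )
    return CohortTable(patients=patients, cores=core_df, sections=sections)


def _draw_section_truths(
    cores: pd.DataFrame,
    patients: pd.DataFrame,
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    loss_by_patient = {
        row.patient_id: set(row.loss_pattern.split("+")) if row.loss_pattern else set()
        for row in patients.itertuples()
    }
    n = len(cores) * len(PROTEINS)
    core_ids = np.repeat(cores["core_id"].to_numpy(), len(PROTEINS))
    protein_col = np.tile(np.array(PROTEINS), len(cores))

    stained = np.ones(n, dtype=bool)
    for i, core in enumerate(cores.itertuples()):
        sl = slice(i * len(PROTEINS), (i + 1) * len(PROTEINS))
        lost: set[str] = set()
        if core.tissue_type == "tumor":
            lost |= loss_by_patient[core.patient_id]
        if core.fixation_class == "over_fixed":
            lost.add("PMS2")
        if lost:
            stained[sl] = [p not in lost for p in PROTEINS]

    # Latent quantities.  Stained: B ~ TruncNormal(b_mean, b_sd) on
    # [0, 100], W ~ Beta(w_alpha, w_beta) scaled by the focal
    # heterogeneity extent.  Unstained: B = 0 (no strong-positive
    # pixels), W = residual background strictly below the ceiling.
    a, b = (0 - cfg.b_mean) / cfg.b_sd, (100 - cfg.b_mean) / cfg.b_sd
    latent_B = np.zeros(n)
    latent_W = np.zeros(n)
    n_stained = int(stained.sum())
    latent_B[stained] = stats.truncnorm.rvs(
        a, b, loc=cfg.b_mean, scale=cfg.b_sd, size=n_stained, random_state=rng
    )
    latent_W[stained] = rng.beta(cfg.w_alpha, cfg.w_beta, size=n_stained)
    latent_W[stained] *= cfg.heterogeneity
    latent_W[~stained] = cfg.background_ceiling * rng.beta(2.0, 8.0, size=n - n_stained)

    return pd.DataFrame(
        {
            "core_id": core_ids,
            "protein": protein_col,
            "stained": stained,
            "latent_B": latent_B,
            "latent_W": latent_W,
            "heterogeneity": np.where(stained, cfg.heterogeneity, 1.0),
        }
    )


def apply_qc_filter(cohort: CohortTable) -> CohortTable:
    """Drop cores that fail QC (over-fixed stock tissue with PMS2 loss).

    Returns a new cohort restricted to ``qc_pass`` cores, with
    ``n_qc_excluded`` recording how many were removed.  Warns when
    nothing survives.
    """
    keep = cohort.cores["qc_pass"].to_numpy()
    excluded = int((~keep).sum())
    cores = cohort.cores.loc[keep].reset_index(drop=True)
    sections = (
        cohort.sections[cohort.sections["core_id"].isin(cores["core_id"])]
        .reset_index(drop=True)
    )
    if len(cores) == 0:
        logger.warning("QC filter removed every core (%d excluded)", excluded)
    else:
        logger.info("QC filter: %d cores excluded, %d retained", excluded, len(cores))
    return CohortTable(
        patients=cohort.patients.copy(),
        cores=cores,
        sections=sections,
        n_qc_excluded=excluded,
    )


def emit_measurements(
    cohort: CohortTable,
    noise: NoiseConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw observed per-section measurements around the latent truth.

    This is the tabular shortcut past image rendering: for every
    (core, protein) section it produces observed ``B``, ``W`` and a
    synthetic histoscore by adding Gaussian noise to the latent values
    and clipping to the valid ranges ([0, 100], [0, 1], [0, 300]).

    Raises
    ------
    StructuralError
        If any retained core is missing one of the four protein sections.
    """
    noise = noise or NoiseConfig()
    noise.validate()
    counts = cohort.sections.groupby("core_id").size()
    bad = counts[counts != len(PROTEINS)]
    if len(bad) or set(cohort.cores["core_id"]) - set(counts.index):
        raise StructuralError(
            "every core must have exactly one section per MMR protein"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    s = cohort.sections
    n = len(s)
    b_obs = np.clip(s["latent_B"] + rng.normal(0, noise.b_noise_sd, n), 0, 100)
    w_obs = np.clip(s["latent_W"] + rng.normal(0, noise.w_noise_sd, n), 0, 1)
    latent_h = 300.0 * s["latent_W"] * (0.55 + 0.45 * s["latent_B"] / 100.0)
    h_obs = np.clip(latent_h + rng.normal(0, noise.histoscore_noise_sd, n), 0, 300)
    return pd.DataFrame(
        {
            "core_id": s["core_id"].to_numpy(),
            "protein": s["protein"].to_numpy(),
            "B": b_obs.to_numpy(),
            "W": w_obs.to_numpy(),
            "histoscore": h_obs.to_numpy(),
        }
    )


def select_quantified(
    cohort: CohortTable, n_quantified: int | None, seed: int
) -> CohortTable:
    """Pick the subset of QC-passing cores sent for digital quantification.

    The study quantified fewer cores than passed QC; which cores is not
    recorded, so a seeded uniform draw stands in.  ``None`` keeps all.
    """
    if n_quantified is None or n_quantified >= len(cohort.cores):
        return cohort
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    idx = np.sort(rng.choice(len(cohort.cores), size=n_quantified, replace=False))
    cores = cohort.cores.iloc[idx].reset_index(drop=True)
    sections = (
        cohort.sections[cohort.sections["core_id"].isin(cores["core_id"])]
        .reset_index(drop=True)
    )
    return CohortTable(
        patients=cohort.patients.copy(),
        cores=cores,
        sections=sections,
        n_qc_excluded=cohort.n_qc_excluded,
    )
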