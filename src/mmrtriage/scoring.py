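"""Staining intensity score (SIS) and per-core aggregation.

A core section's SIS is ``B * W``: the mean strong-positive DAB
intensity (0–100) weighted by the fraction of the core's pixels that are
stained, so a tiny strongly stained focus cannot masquerade as a stained
section.  Because an unstained protein is the pathological finding, each
core is represented by its *minimum* score over the four MMR protein
sections, and a core is called pathological when that representative
falls below the cutoff (or, for the pathologist, when at least one
section is unstained).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import PROTEINS


class ValidationError(ValueError):
    """Raised on out-of-range score inputs."""


class IncompleteCoreError(ValueError):
    """Raised when a core lacks one of the four MMR protein sections.

    Only cores with sections for all four proteins are scoreable."""


def section_sis(B: float, W: float) -> float:
    """Staining intensity score of one section: ``B * W`` on 0–100."""
    if not 0.0 <= B <= 100.0:
        raise ValidationError(f"B must be in [0, 100], got {B!r}")
    if not 0.0 <= W <= 1.0:
        raise ValidationError(f"W must be in [0, 1], got {W!r}")
    return B * W


def core_representative(scores: Mapping[str, float] | Iterable[float]) -> float:
    """Representative score of a core: the minimum over its four sections.

    Accepts either a protein->score mapping (must cover exactly the four
    MMR proteins) or four bare values.
    """
    if isinstance(scores, Mapping):
        missing = set(PROTEINS) - set(scores)
        if missing:
            raise IncompleteCoreError(f"missing protein sections: {sorted(missing)}")
        extra = set(scores) - set(PROTEINS)
        if extra:
            raise IncompleteCoreError(f"unknown protein sections: {sorted(extra)}")
        values = [float(scores[p]) for p in PROTEINS]
    else:
        values = [float(v) for v in scores]
        if len(values) != len(PROTEINS):
            raise IncompleteCoreError(
                f"need exactly {len(PROTEINS)} section scores, got {len(values)}"
            )
    return min(values)


def pathologist_core_call(section_calls: Mapping[str, bool] | Iterable[bool]) -> str:
    """Pathologist-style core call from four stained/unstained reads.

    ``pathological`` iff at least one protein section is unstained;
    ``normal`` when all four are stained.
    """
    if isinstance(section_calls, Mapping):
        missing = set(PROTEINS) - set(section_calls)
        if missing:
            raise IncompleteCoreError(f"missing section calls: {sorted(missing)}")
        calls = [bool(section_calls[p]) for p in PROTEINS]
    else:
        calls = [bool(v) for v in section_calls]
        if len(calls) != len(PROTEINS):
            raise IncompleteCoreError(
                f"need exactly {len(PROTEINS)} section calls, got {len(calls)}"
            )
    return "normal" if all(calls) else "pathological"


def classify_core(representative: float, cutoff: float) -> str:
    """Score-based call: ``pathological`` iff representative < cutoff.

    A score exactly equal to the cutoff classifies as normal (strict
    ``<``); configurable only by nudging the cutoff.
    """
    if not (np.isfinite(representative) and np.isfinite(cutoff)):
        raise ValidationError("representative and cutoff must be finite")
    return "pathological" if representative < cutoff else "normal"


def score_cores(
    measurements: pd.DataFrame,
    section_truth: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Aggregate per-section measurements into per-core scores.

    Parameters
    ----------
    measurements
        Columns ``core_id``, ``protein``, ``B``, ``W`` and optionally
        ``histoscore``.  Every core must carry all four proteins.
    section_truth
        Optional ``core_id``/``protein``/``stained`` table; when given,
        the pathologist-style call is derived from it.

    Returns
    -------
    One row per core: per-protein ``sis_<P>`` (and ``histo_<P>``),
    ``min_sis``, ``min_histoscore``, and ``pathologist_call`` when truth
    was supplied.  Scores are kept unrounded; round only at report time.
    """
    required = {"core_id", "protein", "B", "W"}
    if not required <= set(measurements.columns):
        raise ValidationError(f"measurements need columns {sorted(required)}")
    df = measurements.copy()
    if ((df["B"] < 0) | (df["B"] > 100) | (df["W"] < 0) | (df["W"] > 1)).any():
        raise ValidationError("B out of [0, 100] or W out of [0, 1]")
    df["sis"] = df["B"] * df["W"]

    wide = df.pivot_table(index="core_id", columns="protein", values="sis", aggfunc="first")
    missing = wide.isna().any(axis=1) | (wide.shape[1] < len(PROTEINS))
    if wide.shape[1] < len(PROTEINS) or missing.any():
        bad = list(wide.index[wide.isna().any(axis=1)]) or "all"
        raise IncompleteCoreError(f"cores missing protein sections: {bad}")
    out = wide.rename(columns={p: f"sis_{p}" for p in PROTEINS})
    out["min_sis"] = wide[list(PROTEINS)].min(axis=1)

    if "histoscore" in df.columns:
        hwide = df.pivot_table(
            index="core_id", columns="protein", values="histoscore", aggfunc="first"
        )
        for p in PROTEINS:
            out[f"histo_{p}"] = hwide[p]
        out["min_histoscore"] = hwide[list(PROTEINS)].min(axis=1)

    if section_truth is not None:
        calls = (
            section_truth.groupby("core_id")["stained"]
            .agg(lambda s: "normal" if s.all() else "pathological")
            .rename("pathologist_call")
        )
        out = out.join(calls, how="left")

    return out.reset_index()


def apply_cutoff(
    core_scores: pd.DataFrame, cutoff: float, score_column: str = "min_sis"
) -> pd.DataFrame:
    """Add a ``predicted_call`` column: pathological iff score < cutoff."""
    out = core_scores.copy()
    out["predicted_call"] = np.where(
        out[score_column] < cutoff, "pathological", "normal"
    )
    return out
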