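"""Triage worklist construction.

The suggested clinical workflow: every core is scored automatically,
cores whose minimum score falls below the cutoff (suspected MMR protein
loss) are flagged and sorted to the top of the pathologist's worklist,
most-suspicious first.  Nothing is ever dropped — flagging only
re-prioritizes review order.  A patient is prioritized when any of
their cores is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class TriageWorklist:
    """Ordered review list: flagged cores first, ascending score within
    each group; ranks are a permutation of 1..N."""

    entries: pd.DataFrame  # rank, core_id, patient_id, min_sis, flag
    cutoff: float

    @property
    def n_flagged(self) -> int:
        return int(self.entries["flag"].sum())

    @property
    def n_total(self) -> int:
        return len(self.entries)

    def prioritized_patients(self) -> list[str]:
        """Patients with at least one flagged core, in worklist order."""
        flagged = self.entries[self.entries["flag"]]
        return list(dict.fromkeys(flagged["patient_id"]))

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "n_flagged": self.n_flagged,
            "n_total": self.n_total,
            "prioritized_patients": self.prioritized_patients(),
            "entries": self.entries.to_dict(orient="records"),
        }


def build_worklist(
    core_scores: pd.DataFrame,
    cutoff: float,
    score_column: str = "min_sis",
    patient_of: pd.Series | None = None,
) -> TriageWorklist:
    """Flag and order cores for pathologist review.

    ``core_scores`` needs ``core_id`` and the score column (and
    ``patient_id`` unless ``patient_of`` maps core ids to patients).
    Flag = score < cutoff.  All cores are retained.
    """
    df = core_scores[["core_id"]].copy()
    df["min_sis"] = core_scores[score_column].to_numpy(dtype=float)
    if "patient_id" in core_scores.columns:
        df["patient_id"] = core_scores["patient_id"].to_numpy()
    elif patient_of is not None:
        df["patient_id"] = df["core_id"].map(patient_of)
    else:
        df["patient_id"] = ""
    df["flag"] = df["min_sis"] < cutoff
    df = df.sort_values(
        ["flag", "min_sis", "core_id"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return TriageWorklist(
        entries=df[["rank", "core_id", "patient_id", "min_sis", "flag"]],
        cutoff=float(cutoff),
    )
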