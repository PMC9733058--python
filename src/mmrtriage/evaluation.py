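"""ROC analysis, cutoff selection and exact binomial accuracy measures.

The score convention throughout is that *lower* scores indicate a
pathological core (an unstained MMR protein drags the minimum score
down), so a core is predicted pathological when its representative score
is strictly below the cutoff.  ROC curves are swept over all candidate
cutoffs placed midway between adjacent distinct scores; the area under
the curve (trapezoid rule) then coincides with the Mann–Whitney
concordance probability, ties counting one half.  Sensitivity and
specificity are reported with exact Clopper–Pearson binomial confidence
intervals, and paired ROC curves are compared with the DeLong test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class EvaluationError(ValueError):
    """Raised on invalid evaluation inputs (single-class labels, empty
    sets, mismatched core ids)."""


# ---------------------------------------------------------------------------
# splitting


def random_split(
    core_ids: np.ndarray | pd.Series | list,
    test_fraction: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition cores into disjoint test and validation sets.

    The test set has ``round(test_fraction * n)`` cores; the split is a
    seeded uniform permutation, so it is reproducible but — like the
    study's own unrecorded split — arbitrary.
    """
    ids = np.asarray(core_ids)
    if ids.size == 0:
        raise EvaluationError("cannot split an empty set of cores")
    if not 0.0 < test_fraction < 1.0:
        raise EvaluationError("test_fraction must be in (0, 1)")
    n_test = int(round(test_fraction * ids.size))
    n_test = min(max(n_test, 1), ids.size - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids.size)
    return np.sort(ids[perm[:n_test]]), np.sort(ids[perm[n_test:]])


# ---------------------------------------------------------------------------
# ROC


def _check_labels(labels: np.ndarray) -> np.ndarray:
    lab = np.asarray(labels, dtype=bool)
    if lab.all() or not lab.any():
        raise EvaluationError("both classes must be present")
    return lab


def _candidate_cutoffs(scores: np.ndarray) -> np.ndarray:
    """Cutoffs midway between adjacent distinct scores, plus sentinels
    below the minimum (nothing flagged) and above the maximum (all
    flagged)."""
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])


def roc_curve(
    scores: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
) -> pd.DataFrame:
    """ROC sweep for a "low score = pathological" marker.

    Returns a frame with one row per candidate cutoff: ``cutoff``,
    ``tpr`` (sensitivity), ``fpr`` (1 - specificity), ordered so both
    coordinates are non-decreasing.
    """
    s = np.asarray(scores, dtype=float)
    lab = _check_labels(labels)
    if s.shape != lab.shape:
        raise EvaluationError("scores and labels must align")
    cuts = _candidate_cutoffs(s)
    pos, neg = lab.sum(), (~lab).sum()
    # predicted pathological iff score < cutoff
    tpr = np.array([(s[lab] < c).sum() / pos for c in cuts])
    fpr = np.array([(s[~lab] < c).sum() / neg for c in cuts])
    return pd.DataFrame({"cutoff": cuts, "fpr": fpr, "tpr": tpr})


def auc_from_roc(roc: pd.DataFrame) -> float:
    """Area under the ROC curve by the trapezoid rule (equals the
    Mann–Whitney concordance probability, ties counted half)."""
    return float(np.trapezoid(roc["tpr"], roc["fpr"]))


def roc_auc(scores, labels) -> float:
    """Convenience: AUC of a "low = pathological" score."""
    return auc_from_roc(roc_curve(scores, labels))


def select_cutoff(roc: pd.DataFrame) -> tuple[float, float]:
    """Youden-optimal cutoff from a ROC sweep.

    Maximizes J = sensitivity + specificity - 1; ties broken toward
    higher sensitivity, then toward the lower cutoff.  Returns
    ``(cutoff, J)``; the cutoff lies midway between adjacent distinct
    scores (or just outside the score range).
    """
    if len(roc) == 0:
        raise EvaluationError("empty ROC")
    j = roc["tpr"] - roc["fpr"]
    order = np.lexsort(
        (roc["cutoff"].to_numpy(), -roc["tpr"].to_numpy(), -j.to_numpy())
    )
    best = order[0]
    return float(roc["cutoff"].iloc[best]), float(j.iloc[best])


# ---------------------------------------------------------------------------
# exact binomial intervals


def binomial_ci(
    x: int,
    n: int,
    level: float = 0.95,
    sided: str = "two",
) -> tuple[float, float]:
    """Exact (Clopper–Pearson) binomial confidence bounds, in percent.

    ``sided="two"`` gives the equal-tailed interval from beta quantiles;
    ``sided="lower_one"`` gives the one-sided lower bound (upper bound
    reported as 100).  The lower bound is 0 when ``x == 0`` and the
    two-sided upper bound is 100 when ``x == n``.
    """
    if not (isinstance(x, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise EvaluationError("x and n must be integers")
    if n < 1 or not 0 <= x <= n:
        raise EvaluationError(f"need 0 <= x <= n, n >= 1; got x={x}, n={n}")
    if not 0.0 < level < 1.0:
        raise EvaluationError("level must be in (0, 1)")
    alpha = 1.0 - level
    if sided == "two":
        lo = 0.0 if x == 0 else stats.beta.ppf(alpha / 2, x, n - x + 1)
        hi = 1.0 if x == n else stats.beta.ppf(1 - alpha / 2, x + 1, n - x)
    elif sided == "lower_one":
        lo = 0.0 if x == 0 else stats.beta.ppf(alpha, x, n - x + 1)
        hi = 1.0
    else:
        raise EvaluationError(f"sided must be 'two' or 'lower_one', got {sided!r}")
    return 100.0 * float(lo), 100.0 * float(hi)


# ---------------------------------------------------------------------------
# confusion / report


@dataclass
class EvalReport:
    """Accuracy of predicted core calls against a ground truth."""

    dataset: str
    ground_truth: str
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float            # percent
    specificity: float            # percent
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    ci_level: float = 0.95
    cutoff: float | None = None
    auc: float | None = None
    roc: pd.DataFrame | None = None
    per_protein_sensitivity: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "dataset": self.dataset,
            "ground_truth": self.ground_truth,
            "counts": {"TP": self.tp, "FN": self.fn, "TN": self.tn, "FP": self.fp},
            "sensitivity_pct": round(self.sensitivity, 1),
            "specificity_pct": round(self.specificity, 1),
            "sensitivity_ci_pct": [round(v, 1) for v in self.sensitivity_ci],
            "specificity_ci_pct": [round(v, 1) for v in self.specificity_ci],
            "ci_level": self.ci_level,
        }
        if self.cutoff is not None:
            d["cutoff"] = round(self.cutoff, 4)
        if self.auc is not None:
            d["auc_pct"] = round(100.0 * self.auc, 1)
        if self.per_protein_sensitivity:
            d["per_protein_sensitivity_pct"] = {
                k: round(v, 1) for k, v in self.per_protein_sensitivity.items()
            }
        return d

    def summary(self) -> str:
        lines = [
            f"[{self.dataset} vs {self.ground_truth}]",
            f"  TP={self.tp} FN={self.fn} TN={self.tn} FP={self.fp}",
            f"  sensitivity {self.sensitivity:.1f}% "
            f"[{self.sensitivity_ci[0]:.1f}-{self.sensitivity_ci[1]:.1f}%]",
            f"  specificity {self.specificity:.1f}% "
            f"[{self.specificity_ci[0]:.1f}-{self.specificity_ci[1]:.1f}%]",
        ]
        if self.auc is not None:
            lines.append(f"  AUC {100 * self.auc:.1f}%")
        if self.cutoff is not None:
            lines.append(f"  cutoff {self.cutoff:.4g}")
        for prot, sens in self.per_protein_sensitivity.items():
            lines.append(f"  sensitivity[{prot}] {sens:.1f}%")
        return "\n".join(lines)


def confusion_eval(
    predicted: pd.Series | np.ndarray,
    truth: pd.Series | np.ndarray,
    dataset: str = "",
    ground_truth: str = "",
    level: float = 0.95,
    sided: str = "two",
) -> EvalReport:
    """Confusion counts and exact-CI sensitivity/specificity.

    ``predicted`` and ``truth`` are aligned ``pathological``/``normal``
    calls (index-aligned when both are pandas Series).
    """
    if isinstance(predicted, pd.Series) and isinstance(truth, pd.Series):
        if not predicted.index.equals(truth.index):
            if set(predicted.index) != set(truth.index):
                raise EvaluationError("mismatched core ids")
            truth = truth.reindex(predicted.index)
    pred = np.asarray(predicted) == "pathological"
    tru = np.asarray(truth) == "pathological"
    if pred.shape != tru.shape:
        raise EvaluationError("predicted and truth calls must align")
    tp = int((pred & tru).sum())
    fn = int((~pred & tru).sum())
    tn = int((~pred & ~tru).sum())
    fp = int((pred & ~tru).sum())
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    sens_ci = binomial_ci(tp, tp + fn, level, sided) if tp + fn else (0.0, 100.0)
    spec_ci = binomial_ci(tn, tn + fp, level, sided) if tn + fp else (0.0, 100.0)
    return EvalReport(
        dataset=dataset,
        ground_truth=ground_truth,
        tp=tp, fn=fn, tn=tn, fp=fp,
        sensitivity=sens, specificity=spec,
        sensitivity_ci=sens_ci, specificity_ci=spec_ci,
        ci_level=level,
    )


def per_protein_sensitivity(
    sections: pd.DataFrame,
    cutoff: float,
    score_column: str = "sis",
) -> dict[str, float]:
    """Section-level detection rate of each protein's loss.

    For each protein, among sections whose ground truth is unstained,
    the percentage whose section score falls below the cutoff.  Proteins
    with no unstained sections are omitted.
    """
    out: dict[str, float] = {}
    for prot, grp in sections.groupby("protein"):
        lost = grp[~grp["stained"].astype(bool)]
        if len(lost):
            out[str(prot)] = 100.0 * float((lost[score_column] < cutoff).mean())
    return out


# ---------------------------------------------------------------------------
# DeLong paired-AUC comparison


def _midrank_structural(pathological: np.ndarray, normal: np.ndarray):
    """Structural components of the concordance AUC for lower-is-
    pathological scores: psi = 1 if p < q, 1/2 if tied, else 0."""
    def psi(p, q):
        return (p < q) + 0.5 * (p == q)

    v10 = np.array([psi(p, normal).mean() for p in pathological])
    v01 = np.array([psi(pathological, q).mean() for q in normal])
    return v10, v01


def delong_compare(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    labels: np.ndarray,
) -> tuple[float, float, float, float]:
    """DeLong test for two paired "low = pathological" markers.

    Returns ``(auc_a, auc_b, z, p)`` with a two-sided normal p-value.
    Identical scores give z = 0, p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    lab = _check_labels(labels)
    if not (a.shape == b.shape == lab.shape):
        raise EvaluationError("paired scores must align with labels")
    v10a, v01a = _midrank_structural(a[lab], a[~lab])
    v10b, v01b = _midrank_structural(b[lab], b[~lab])
    auc_a, auc_b = v10a.mean(), v10b.mean()
    m, n = lab.sum(), (~lab).sum()
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var_diff <= 0 or diff == 0:
        z = 0.0
    else:
        z = diff / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z)) if z != 0 else 1.0
    return float(auc_a), float(auc_b), float(z), float(p)


def delong_auc_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """DeLong AUC and its variance for a single marker."""
    s = np.asarray(scores, dtype=float)
    lab = _check_labels(labels)
    v10, v01 = _midrank_structural(s[lab], s[~lab])
    var = np.var(v10, ddof=1) / lab.sum() + np.var(v01, ddof=1) / (~lab).sum()
    return float(v10.mean()), float(var)
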