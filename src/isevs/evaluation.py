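"""Model validation: metrics, cross-validation, Y-randomization,
drug–target interaction matrices, diversity and descriptor-family reports.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from ._bitset import exact_mcc
from .chem_io import DescriptorTable, Fingerprint, tanimoto
from .dataset import FoldAssignment, LearningSet
from .ise import IseConfig, run_ise
from .screening import enrichment_factor, screen_library


@dataclass(frozen=True)
class ConfusionMetrics:
    mcc: float
    tpr: float
    fpr: float
    tnr: float
    degenerate: bool = False  # some rate had a zero denominator


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    """MCC, sensitivity (TPR), FPR and specificity (TNR) from counts.
    A zero denominator yields 0 for that quantity, flagged."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fp + tn + fn == 0:
        raise ValueError("confusion counts must not all be zero")
    degenerate = False
    mcc = exact_mcc(tp, fp, tn, fn)
    den2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den2 == 0:
        degenerate = True
    if tp + fn > 0:
        tpr = tp / (tp + fn)
    else:
        tpr, degenerate = 0.0, True
    if fp + tn > 0:
        fpr = fp / (fp + tn)
        tnr = tn / (fp + tn)
    else:
        fpr, tnr, degenerate = 0.0, 0.0, True
    return ConfusionMetrics(mcc, tpr, fpr, tnr, degenerate)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability a random active outscores a random decoy, ties at ½."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("roc_auc needs both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class FoldResult:
    fold: int
    top_filter_mcc: float
    top5_mean_mcc: float
    n_test: int


@dataclass
class MetricsReport:
    mean_top_filter_mcc: float
    mean_top5_filter_mcc: float
    auc: float
    tpr: float
    tnr: float
    fpr: float
    ef_at_selection: float
    ef_selection_fraction: float
    scheme: str
    per_fold: list[FoldResult] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def cross_validate(
    ls: LearningSet,
    table: DescriptorTable,
    folds: FoldAssignment,
    ise_config: IseConfig | None = None,
    ef_selection_fraction: float = 0.01,
) -> MetricsReport:
    """Train on k−1 folds, score the held-out fold, pool all test scores.

    Reports the top filter's MCC averaged over folds (and a top-5 variant),
    pooled AUC, TPR/TNR at the index > 0 cutoff, and EF at the configured
    top fraction of the pooled ranking. Deterministic under the config seed.
    """
    ise_config = ise_config or IseConfig()
    ids = ls.molecule_ids
    missing = set(ids) - set(table.molecule_ids)
    if missing:
        raise ValueError(f"table lacks learning-set molecules: {sorted(missing)[:5]}")
    unassigned = set(ids) - set(folds.fold_of)
    if unassigned:
        raise ValueError("fold assignment must cover the learning set")
    row_of = {mid: i for i, mid in enumerate(table.molecule_ids)}
    labels_of = {mid: lab for mid, lab in zip(ids, ls.labels_for(ids))}

    pooled_scores: list[float] = []
    pooled_labels: list[int] = []
    per_fold: list[FoldResult] = []
    for fold in range(folds.n_folds):
        test_ids = [mid for mid in ids if folds.fold_of[mid] == fold]
        train_ids = [mid for mid in ids if folds.fold_of[mid] != fold]
        train_labels = np.array([labels_of[m] for m in train_ids])
        if train_labels.min() == train_labels.max():
            raise ValueError(f"training split for fold {fold} has one class")
        train_table = table.select_rows([row_of[m] for m in train_ids])
        test_table = table.select_rows([row_of[m] for m in test_ids])
        model = run_ise(train_table, train_labels, ise_config)
        top5 = [f.mcc for f in model.filters[:5]]
        per_fold.append(
            FoldResult(
                fold=fold,
                top_filter_mcc=model.filters[0].mcc,
                top5_mean_mcc=float(np.mean(top5)),
                n_test=len(test_ids),
            )
        )
        for res in screen_library(model, test_table):
            pooled_scores.append(res.index)
            pooled_labels.append(int(labels_of[res.molecule_id]))

    pooled_scores_arr = np.asarray(pooled_scores)
    pooled_labels_arr = np.asarray(pooled_labels)
    auc = roc_auc(pooled_scores_arr, pooled_labels_arr)
    positive = pooled_scores_arr > 0.0
    tp = int((positive & (pooled_labels_arr == 1)).sum())
    fp = int((positive & (pooled_labels_arr == 0)).sum())
    fn = int(((~positive) & (pooled_labels_arr == 1)).sum())
    tn = int(((~positive) & (pooled_labels_arr == 0)).sum())
    cm = confusion_metrics(tp, fp, tn, fn)
    order = np.lexsort((np.arange(len(pooled_scores_arr)), -pooled_scores_arr))
    n_sel = max(1, int(round(ef_selection_fraction * len(order))))
    ef = enrichment_factor(pooled_labels_arr[order], n_sel)
    return MetricsReport(
        mean_top_filter_mcc=float(np.mean([f.top_filter_mcc for f in per_fold])),
        mean_top5_filter_mcc=float(np.mean([f.top5_mean_mcc for f in per_fold])),
        auc=auc,
        tpr=cm.tpr,
        tnr=cm.tnr,
        fpr=cm.fpr,
        ef_at_selection=ef,
        ef_selection_fraction=ef_selection_fraction,
        scheme=folds.scheme,
        per_fold=per_fold,
    )


# ---------------------------------------------------------------------------
# Interaction matrices


@dataclass
class InteractionMatrix:
    """Binary drugs × targets adjacency; kind is 'reported' or 'predicted'."""

    drug_ids: list[str]
    target_ids: list[str]
    values: np.ndarray
    kind: str = "reported"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.drug_ids), len(self.target_ids)):
            raise ValueError("matrix shape must be drugs × targets")
        if not set(np.unique(self.values)) <= {0, 1}:
            raise ValueError("matrix entries must be 0/1")
        if self.kind not in ("reported", "predicted"):
            raise ValueError(f"bad matrix kind {self.kind!r}")

    @property
    def n_interactions(self) -> int:
        return int(self.values.sum())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.values, index=self.drug_ids, columns=self.target_ids
        ).rename_axis("drug_id").to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "reported") -> "InteractionMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            df.to_numpy(),
            kind,
        )


def y_randomization(
    predicted: InteractionMatrix,
    n_activities: int,
    n_reps: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Null success rate: place ``n_activities`` ones uniformly (without
    replacement within a replicate) in the matrix frame and measure the
    fraction landing on predicted-positive cells; mean ± SD over reps."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n_cells = predicted.values.size
    if n_activities > n_cells:
        raise ValueError("n_activities exceeds the matrix cell count")
    flat = predicted.values.ravel().astype(bool)
    rng = np.random.default_rng(seed)
    successes = np.empty(n_reps)
    for i in range(n_reps):
        cells = rng.choice(n_cells, size=n_activities, replace=False)
        successes[i] = flat[cells].mean()
    return float(successes.mean()), float(successes.std(ddof=1)) if n_reps > 1 else 0.0


@dataclass
class MatrixComparison:
    overall_success_pct: float
    n_reported: int
    n_correct: int
    per_target: pd.DataFrame
    per_drug: pd.DataFrame


def compare_matrices(
    predicted: InteractionMatrix, reported: InteractionMatrix
) -> MatrixComparison:
    """Fraction of reported interactions carrying a positive prediction,
    with per-target and per-drug breakdowns (reported/predicted/correct
    counts in the style of the interaction summary tables)."""
    if (
        predicted.drug_ids != reported.drug_ids
        or predicted.target_ids != reported.target_ids
    ):
        raise ValueError("predicted and reported matrices must share axes")
    rep = reported.values.astype(bool)
    pred = predicted.values.astype(bool)
    correct = rep & pred
    n_rep = int(rep.sum())
    n_cor = int(correct.sum())
    pct = 100.0 * n_cor / n_rep if n_rep else float("nan")

    def breakdown(axis: int, ids: list[str], name: str) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "reported": rep.sum(axis=axis),
                "predicted": pred.sum(axis=axis),
                "correct": correct.sum(axis=axis),
            },
            index=pd.Index(ids, name=name),
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            df["success_pct"] = np.where(
                df["reported"] > 0, 100.0 * df["correct"] / df["reported"], np.nan
            )
        return df

    return MatrixComparison(
        overall_success_pct=pct,
        n_reported=n_rep,
        n_correct=n_cor,
        per_target=breakdown(0, predicted.target_ids, "target_id"),
        per_drug=breakdown(1, predicted.drug_ids, "drug_id"),
    )


# ---------------------------------------------------------------------------
# Diversity and descriptor-family occupancy


DIVERSITY_TC_THRESHOLD = 0.7


@dataclass
class DiversityReport:
    tc_actives: float
    tc_top_vs_actives: float
    tc_top_internal: float
    actives_diverse: bool
    top_diverse: bool


def _mean_pairwise_tc(fps: Sequence[Fingerprint]) -> float:
    if len(fps) < 2:
        raise ValueError("pairwise Tc undefined for fewer than two molecules")
    vals = [
        tanimoto(fps[i], fps[j])
        for i in range(len(fps))
        for j in range(i + 1, len(fps))
    ]
    return float(np.mean(vals))


def diversity_report(
    active_fps: Sequence[Fingerprint], top_screen_fps: Sequence[Fingerprint]
) -> DiversityReport:
    """Mean pairwise Tc within actives and within the screened top set, and
    the mean per-top-molecule maximum Tc against the actives. Sets with mean
    Tc below 0.7 are flagged diverse."""
    if not active_fps or not top_screen_fps:
        raise ValueError("fingerprint sets must be non-empty")
    tc_act = _mean_pairwise_tc(active_fps)
    tc_top = _mean_pairwise_tc(top_screen_fps)
    tc_cross = float(
        np.mean([max(tanimoto(t, a) for a in active_fps) for t in top_screen_fps])
    )
    return DiversityReport(
        tc_actives=tc_act,
        tc_top_vs_actives=tc_cross,
        tc_top_internal=tc_top,
        actives_diverse=tc_act < DIVERSITY_TC_THRESHOLD,
        top_diverse=tc_top < DIVERSITY_TC_THRESHOLD,
    )


def descriptor_family_occurrence(model, family_map: dict[str, str]) -> pd.Series:
    """Percentage of filter slots (5 × n_filters) occupied by each
    descriptor family; sums to 100."""
    if not model.filters:
        raise ValueError("model has no filters")
    counts: dict[str, int] = {}
    total = 0
    for f in model.filters:
        for r in f.ranges:
            if r.descriptor not in family_map:
                raise ValueError(f"descriptor {r.descriptor!r} missing from family map")
            fam = family_map[r.descriptor]
            counts[fam] = counts.get(fam, 0) + 1
            total += 1
    return pd.Series(
        {fam: 100.0 * c / total for fam, c in sorted(counts.items())},
        name="occurrence_pct",
    )
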