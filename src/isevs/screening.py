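"""Score molecules on the [−1, +1] index and pick selection cutoffs.

Each filter contributes its weight positively when the molecule passes it
and negatively otherwise; the sum is normalised by the total weight, so a
molecule passing every filter scores +1 and one failing every filter −1.
Unit weights reproduce the plain (passes − fails)/n index; ``mcc`` and
``fscore`` weighting emphasise the better-discriminating filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem_io import DescriptorTable
from .ise import Model

_WEIGHT_EPS = 1e-6


@dataclass(frozen=True)
class ScreenResult:
    molecule_id: str
    index: float
    n_filters_passed: int


def filter_weights(model: Model) -> np.ndarray:
    """Per-filter weights under the model's weighting scheme (all > 0)."""
    scheme = model.weights_scheme
    if scheme == "unit":
        return np.ones(len(model.filters))
    if scheme == "mcc":
        return np.array([max(f.mcc, _WEIGHT_EPS) for f in model.filters])
    if scheme == "fscore":
        out = []
        for f in model.filters:
            denom = 2 * f.tp + f.fp + f.fn
            out.append(max(2 * f.tp / denom if denom else 0.0, _WEIGHT_EPS))
        return np.array(out)
    raise ValueError(f"unknown weights scheme {scheme!r}")


def _pass_matrix(model: Model, table: DescriptorTable) -> np.ndarray:
    """(n_molecules, n_filters) boolean pass matrix."""
    missing = set(d for f in model.filters for d in f.descriptors()) - set(
        table.descriptor_names
    )
    if missing:
        raise ValueError(f"library table lacks model descriptors: {sorted(missing)}")
    cols = {d: table.column(d) for f in model.filters for d in f.descriptors()}
    out = np.empty((table.n_molecules, len(model.filters)), dtype=bool)
    for j, f in enumerate(model.filters):
        mask = np.ones(table.n_molecules, dtype=bool)
        for r in f.ranges:
            mask &= r.contains(cols[r.descriptor])
        out[:, j] = mask
    return out


def score_molecule(model: Model, row: Mapping[str, float]) -> ScreenResult:
    """Index of one molecule given its descriptor values."""
    if not model.filters:
        raise ValueError("model has no filters")
    for f in model.filters:
        for d in f.descriptors():
            if d not in row:
                raise ValueError(f"descriptor {d!r} missing from input row")
    w = filter_weights(model)
    passed = np.array([f.passes(row) for f in model.filters])
    index = float((w[passed].sum() - w[~passed].sum()) / w.sum())
    index = min(1.0, max(-1.0, index))  # guard 1-ulp float overshoot
    return ScreenResult(str(row.get("molecule_id", "")), index, int(passed.sum()))


def screen_library(model: Model, table: DescriptorTable) -> list[ScreenResult]:
    """Score every molecule; results sorted index-descending, ties broken by
    molecule id."""
    if table.n_molecules == 0:
        return []
    if not model.filters:
        raise ValueError("model has no filters")
    w = filter_weights(model)
    passes = _pass_matrix(model, table)
    indices = np.clip((passes @ w - (~passes) @ w) / w.sum(), -1.0, 1.0)
    results = [
        ScreenResult(mid, float(indices[i]), int(passes[i].sum()))
        for i, mid in enumerate(table.molecule_ids)
    ]
    results.sort(key=lambda r: (-r.index, r.molecule_id))
    return results


def screen_to_csv(results: Sequence[ScreenResult], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "molecule_id": [r.molecule_id for r in results],
            "index": [r.index for r in results],
            "n_filters_passed": [r.n_filters_passed for r in results],
            "rank": np.arange(1, len(results) + 1),
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def enrichment_factor(ranked_labels: Sequence[int], n_selected: int) -> float:
    """EF = (hit rate in the top ``n_selected``) / (hit rate overall)."""
    labels = np.asarray(ranked_labels)
    n_total = len(labels)
    if not 1 <= n_selected <= n_total:
        raise ValueError("n_selected must be in [1, len(ranked_labels)]")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("enrichment undefined: no positives in the library")
    tp_sel = int(labels[:n_selected].sum())
    return (tp_sel / n_selected) / (n_pos / n_total)


@dataclass
class CutoffRow:
    cutoff: float
    tp: int
    fp: int
    tp_fp_ratio: float  # inf when fp == 0 and tp > 0
    ef: float


def choose_cutoff(
    scores: Sequence[float],
    labels: Sequence[int],
    grid: Sequence[float] | None = None,
    min_tp: int = 1,
) -> tuple[list[CutoffRow], float | None]:
    """Confusion summary per index cutoff (selection: index ≥ cutoff).

    The recommended cutoff is the highest one whose TP/FP ratio is maximal
    among cutoffs keeping at least ``min_tp`` true positives. The default
    grid spans [−1, 1] in 0.1 steps and always includes 0.0 and 0.7.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if grid is None:
        grid = sorted(set(np.round(np.arange(-1.0, 1.01, 0.1), 10)) | {0.0, 0.7})
    grid = list(grid)
    if not grid:
        raise ValueError("cutoff grid must not be empty")
    n_pos = int(labels.sum())
    rows: list[CutoffRow] = []
    for c in grid:
        sel = scores >= c
        tp = int(labels[sel].sum())
        fp = int(sel.sum()) - tp
        if fp == 0:
            ratio = float("inf") if tp > 0 else 0.0
        else:
            ratio = tp / fp
        if sel.sum() >= 1 and n_pos > 0:
            ef = (tp / sel.sum()) / (n_pos / len(labels))
        else:
            ef = float("nan")
        rows.append(CutoffRow(float(c), tp, fp, ratio, ef))
    eligible = [r for r in rows if r.tp >= min_tp]
    recommended = None
    if eligible:
        best = max(r.tp_fp_ratio for r in eligible)
        recommended = max(r.cutoff for r in eligible if r.tp_fp_ratio == best)
    return rows, recommended
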