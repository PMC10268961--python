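"""Bioactivity curation, property-matched decoy selection, CV folds.

Curation applies the exclusion cascade used for receptor learning sets:
flagged comments, approximate qualifiers, weak potency (> 100 µM), low
source confidence, known-drug exclusion, duplicate collapse to the worst
reported value, and structural-alert removal. Decoys are drawn from a pool
restricted to the actives' applicability domain — each of MW, clogP, HBA
and HBD within mean ± 2 SD of the actives — at a configurable
inactive:active dilution (100:1 by default, 1000:1 preferred when the pool
allows).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_io import MoleculeRecord

logger = logging.getLogger(__name__)

AD_PROPERTIES = ("MW", "clogP", "HBA", "HBD")
VALID_QUALIFIERS = ("=", ">", "<", "~")
FLAGGED_COMMENTS = ("outside typical range", "potential transcription error")

# Minimal structural-alert list (reactive / potentially mutagenic groups).
STRUCTURAL_ALERTS = {
    "nitro": "[N+](=O)[O-]",
    "acyl_halide": "[CX3](=O)[F,Cl,Br,I]",
    "aldehyde": "[CX3H1](=O)[#6]",
    "epoxide": "C1OC1",
    "isocyanate": "N=C=O",
    "michael_acceptor": "[CX3]=[CX3][CX3](=O)[#6,#8]",
    "azide": "[N-]=[N+]=N",
    "alkyl_halide_primary": "[CH2X4][Br,I]",
}
_ALERT_MOLS = {name: Chem.MolFromSmarts(s) for name, s in STRUCTURAL_ALERTS.items()}


@dataclass(frozen=True)
class ActivityRecord:
    molecule_id: str
    smiles: str
    target_id: str
    activity_type: str  # agonist | antagonist
    measure: str  # EC50 | IC50 | Ki
    value_nM: float
    qualifier: str = "="
    confidence: int = 9
    comment: str = ""

    def __post_init__(self) -> None:
        if self.activity_type not in ("agonist", "antagonist"):
            raise ValueError(f"bad activity_type {self.activity_type!r}")
        if self.measure not in ("EC50", "IC50", "Ki"):
            raise ValueError(f"bad measure {self.measure!r}")
        if self.activity_type == "agonist" and self.measure != "EC50":
            raise ValueError("agonist records must carry EC50")
        if self.activity_type == "antagonist" and self.measure == "EC50":
            raise ValueError("antagonist records must carry IC50 or Ki")
        if self.value_nM <= 0:
            raise ValueError("value_nM must be positive")
        if self.qualifier not in VALID_QUALIFIERS:
            raise ValueError(f"bad qualifier {self.qualifier!r}")
        if not 0 <= self.confidence <= 9:
            raise ValueError("confidence must be 0–9")


def read_activity_csv(path: str | Path) -> list[ActivityRecord]:
    records = []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            records.append(
                ActivityRecord(
                    molecule_id=row["molecule_id"],
                    smiles=row["smiles"],
                    target_id=row["target_id"],
                    activity_type=row["activity_type"],
                    measure=row["measure"],
                    value_nM=float(row["value_nM"]),
                    qualifier=row.get("qualifier", "="),
                    confidence=int(row.get("confidence", 9)),
                    comment=row.get("comment", ""),
                )
            )
    return records


@dataclass
class CurationAudit:
    """Every input record accounted for: kept, or dropped citing the first
    applicable rule."""

    kept_ids: list[str] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (id, rule)

    def drop_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, rule in self.dropped:
            counts[rule] = counts.get(rule, 0) + 1
        return counts


class InsufficientActivesError(ValueError):
    pass


RULES = (
    "flagged_comment",
    "approximate_qualifier",
    "weak_activity",
    "low_confidence",
    "excluded_id",
    "duplicate_id",
    "structural_alert",
)


def _has_alert(smiles: str) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return False
    return any(mol.HasSubstructMatch(p) for p in _ALERT_MOLS.values())


def curate_actives(
    records: Sequence[ActivityRecord],
    exclusion_list: set[str] | None = None,
    max_value_nM: float = 100_000.0,
    min_confidence: int = 7,
    apply_alerts: bool = True,
    high_activity_nM: float | None = None,
) -> tuple[list[ActivityRecord], CurationAudit]:
    """Apply the exclusion cascade in fixed order; first matching rule wins.

    1. flagged comments; 2. non-"=" qualifiers; 3. value above
    ``max_value_nM``; 4. confidence not above ``min_confidence``; 5. ids in
    ``exclusion_list``; 6. duplicate ids collapsed keeping the largest
    (worst) value; 7. structural alerts. ``high_activity_nM`` optionally
    restricts to a highly active subset (off by default).
    """
    exclusion_list = exclusion_list or set()
    audit = CurationAudit()
    survivors: list[ActivityRecord] = []
    for rec in records:
        if any(flag in rec.comment.lower() for flag in FLAGGED_COMMENTS):
            audit.dropped.append((rec.molecule_id, "flagged_comment"))
        elif rec.qualifier != "=":
            audit.dropped.append((rec.molecule_id, "approximate_qualifier"))
        elif rec.value_nM > max_value_nM:
            audit.dropped.append((rec.molecule_id, "weak_activity"))
        elif rec.confidence <= min_confidence:
            audit.dropped.append((rec.molecule_id, "low_confidence"))
        elif rec.molecule_id in exclusion_list:
            audit.dropped.append((rec.molecule_id, "excluded_id"))
        else:
            survivors.append(rec)
    # collapse duplicates, keep worst (numerically largest) value
    by_id: dict[str, ActivityRecord] = {}
    for rec in survivors:
        prev = by_id.get(rec.molecule_id)
        if prev is None:
            by_id[rec.molecule_id] = rec
        else:
            if rec.value_nM > prev.value_nM:
                by_id[rec.molecule_id] = rec
            audit.dropped.append((rec.molecule_id, "duplicate_id"))
    kept: list[ActivityRecord] = []
    for rec in by_id.values():
        if apply_alerts and _has_alert(rec.smiles):
            audit.dropped.append((rec.molecule_id, "structural_alert"))
        elif high_activity_nM is not None and rec.value_nM >= high_activity_nM:
            audit.dropped.append((rec.molecule_id, "not_highly_active"))
        else:
            kept.append(rec)
            audit.kept_ids.append(rec.molecule_id)
    if records and not kept:
        raise InsufficientActivesError(
            "no actives survive curation; drop counts: "
            f"{audit.drop_counts()}"
        )
    return kept, audit


# ---------------------------------------------------------------------------
# Applicability domain and decoys


@dataclass(frozen=True)
class ApplicabilityDomain:
    """Per-property mean and sample SD over the actives (MW/clogP/HBA/HBD);
    the decoy-eligible region is mean ± 2 SD in every property."""

    stats: dict[str, tuple[float, float]]  # property → (mean, sd)
    n_sd: float = 2.0

    def bounds(self) -> dict[str, tuple[float, float]]:
        return {
            p: (m - self.n_sd * s, m + self.n_sd * s)
            for p, (m, s) in self.stats.items()
        }

    def contains(self, props: pd.DataFrame) -> np.ndarray:
        ok = np.ones(len(props), dtype=bool)
        for p, (lo, hi) in self.bounds().items():
            v = props[p].to_numpy(dtype=float)
            ok &= (v >= lo) & (v <= hi)
        return ok


def fit_applicability_domain(actives_props: pd.DataFrame) -> ApplicabilityDomain:
    missing = [p for p in AD_PROPERTIES if p not in actives_props.columns]
    if missing:
        raise ValueError(f"missing property columns: {missing}")
    if len(actives_props) < 2:
        raise ValueError("applicability domain needs at least two actives")
    stats = {}
    for p in AD_PROPERTIES:
        v = actives_props[p].to_numpy(dtype=float)
        stats[p] = (float(np.mean(v)), float(np.std(v, ddof=1)))
    return ApplicabilityDomain(stats)


@dataclass
class DecoySelection:
    decoys: list[MoleculeRecord]
    requested: int
    shortfall: bool


def sample_decoys(
    pool: Sequence[MoleculeRecord],
    pool_props: pd.DataFrame,
    ad: ApplicabilityDomain,
    n_actives: int,
    ratio: int,
    seed: int,
) -> DecoySelection:
    """Uniform sample without replacement of ratio × n_actives pool members
    whose four properties all fall inside the AD box. A short pool returns
    every eligible member with the shortfall flagged."""
    ids = [rec.id for rec in pool]
    props = pool_props.loc[ids]
    eligible_mask = ad.contains(props)
    eligible = [rec for rec, ok in zip(pool, eligible_mask) if ok]
    n_request = ratio * n_actives
    rng = np.random.default_rng(seed)
    if len(eligible) <= n_request:
        if len(eligible) < n_request:
            logger.warning(
                "decoy shortfall: requested %d, only %d eligible",
                n_request, len(eligible),
            )
        chosen = list(eligible)
        shortfall = len(eligible) < n_request
    else:
        pick = rng.choice(len(eligible), size=n_request, replace=False)
        chosen = [eligible[i] for i in sorted(pick)]
        shortfall = False
    decoys = [MoleculeRecord(r.id, r.smiles, "decoy") for r in chosen]
    return DecoySelection(decoys, n_request, shortfall)


# ---------------------------------------------------------------------------
# Learning set and folds


@dataclass
class LearningSet:
    actives: list[MoleculeRecord]
    decoys: list[MoleculeRecord]
    ratio: int
    shortfall: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = {r.id for r in self.actives} & {r.id for r in self.decoys}
        if overlap:
            raise ValueError(f"actives and decoys share ids: {sorted(overlap)[:5]}")
        if not self.shortfall and len(self.decoys) != self.ratio * len(self.actives):
            raise ValueError(
                "decoy count must equal ratio × actives unless flagged short"
            )

    @property
    def molecule_ids(self) -> list[str]:
        return [r.id for r in self.actives] + [r.id for r in self.decoys]

    def write(self, out_dir: str | Path) -> None:
        """Serialize as actives.smi + decoys.smi + provenance JSON."""
        from .chem_io import write_smiles_file

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_smiles_file(self.actives, out / "actives.smi")
        write_smiles_file(self.decoys, out / "decoys.smi")
        payload = {
            "ratio": self.ratio,
            "shortfall": self.shortfall,
            "n_actives": len(self.actives),
            "n_decoys": len(self.decoys),
            "provenance": self.provenance,
        }
        (out / "provenance.json").write_text(
            json.dumps(payload, sort_keys=True, indent=1)
        )

    def labels_for(self, ids: Iterable[str]) -> np.ndarray:
        active_ids = {r.id for r in self.actives}
        return np.array([1 if i in active_ids else 0 for i in ids], dtype=np.int64)


@dataclass
class FoldAssignment:
    scheme: str  # kfold | loo
    fold_of: dict[str, int]
    n_folds: int

    def members(self, fold: int) -> list[str]:
        return [mid for mid, f in self.fold_of.items() if f == fold]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["molecule_id", "fold"])
            for mid, f in self.fold_of.items():
                w.writerow([mid, f])


def assign_folds(
    ls: LearningSet, k: int = 5, loo_threshold: int = 20, seed: int = 0
) -> FoldAssignment:
    """Stratified k-fold over actives and decoys; leave-one-out (over the
    actives, decoys dealt evenly alongside) when actives are scarce."""
    if not ls.actives or not ls.decoys:
        raise ValueError("learning set must contain both actives and decoys")
    rng = np.random.default_rng(seed)
    active_ids = [r.id for r in ls.actives]
    decoy_ids = [r.id for r in ls.decoys]
    if len(active_ids) < loo_threshold:
        n_folds = len(active_ids)
        scheme = "loo"
    else:
        if k < 2:
            raise ValueError("k must be >= 2")
        if k > len(active_ids):
            raise ValueError("k exceeds the number of actives")
        n_folds = k
        scheme = "kfold"
    fold_of: dict[str, int] = {}
    for ids in (active_ids, decoy_ids):
        perm = rng.permutation(len(ids))
        for pos, idx in enumerate(perm):
            fold_of[ids[idx]] = pos % n_folds
    if scheme == "loo":
        # exactly one active per fold
        for pos, mid in enumerate(active_ids):
            fold_of[mid] = pos
    return FoldAssignment(scheme, fold_of, n_folds)
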