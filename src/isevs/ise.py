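"""Iterative Stochastic Elimination of descriptor-range filters.

A *filter* is a conjunction of five closed value ranges on five distinct
molecular descriptors; a molecule passes iff every one of its five values
lies inside its range. Filters are scored by the Matthews correlation
coefficient (MCC) of the active/inactive split they induce on the learning
set. The combinatorial space of filters is reduced by iterated stochastic
sampling — ranges that consistently drag sampled filters to the bottom of
the score histogram are eliminated — until fewer than ``exhaustive_threshold``
combinations remain, at which point every remaining filter is enumerated,
scored, and ranked. The model is the MCC-sorted head of that ranking.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from ._bitset import confusion_batch, exact_mcc, mcc_batch, pack_rows
from .chem_io import DescriptorTable


class IseError(ValueError):
    pass


class IseConvergenceError(IseError):
    """Stochastic elimination stopped making progress above the exhaustive
    threshold."""


@dataclass(frozen=True)
class DescriptorRange:
    """Closed interval [low, high] on one named descriptor."""

    descriptor: str
    low: float
    high: float
    single_mcc: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"{self.descriptor}: low {self.low} > high {self.high}")

    def contains(self, values: np.ndarray) -> np.ndarray:
        return (values >= self.low) & (values <= self.high)

    def key(self) -> tuple[str, float, float]:
        return (self.descriptor, self.low, self.high)


@dataclass
class RangeCatalog:
    """Surviving candidate ranges per descriptor, descriptors name-sorted."""

    ranges_by_descriptor: dict[str, list[DescriptorRange]]

    def __post_init__(self) -> None:
        self.ranges_by_descriptor = {
            name: list(self.ranges_by_descriptor[name])
            for name in sorted(self.ranges_by_descriptor)
        }
        for name, ranges in self.ranges_by_descriptor.items():
            if not ranges:
                raise ValueError(f"descriptor {name} has no surviving ranges")
            if len({r.key() for r in ranges}) != len(ranges):
                raise ValueError(f"descriptor {name} has duplicate ranges")

    @property
    def descriptors(self) -> list[str]:
        return list(self.ranges_by_descriptor)

    def counts(self) -> list[int]:
        return [len(v) for v in self.ranges_by_descriptor.values()]

    def n_ranges(self) -> int:
        return sum(self.counts())

    def all_ranges(self) -> list[DescriptorRange]:
        return [r for v in self.ranges_by_descriptor.values() for r in v]


@dataclass(frozen=True)
class Filter:
    """Five descriptor ranges plus the confusion counts they induce."""

    ranges: tuple[DescriptorRange, ...]
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    mcc: float = 0.0

    def __post_init__(self) -> None:
        names = [r.descriptor for r in self.ranges]
        if len(set(names)) != len(names):
            raise ValueError("filter ranges must use distinct descriptors")
        object.__setattr__(
            self, "ranges", tuple(sorted(self.ranges, key=lambda r: r.descriptor))
        )

    def sort_key(self) -> tuple:
        return tuple(r.key() for r in self.ranges)

    def descriptors(self) -> list[str]:
        return [r.descriptor for r in self.ranges]

    def passes(self, row: dict[str, float]) -> bool:
        return all(r.low <= row[r.descriptor] <= r.high for r in self.ranges)


@dataclass
class IseConfig:
    """All tunables of a model build; serialized into the model for replay."""

    n_bins: int = 8
    filter_size: int = 5
    sample_size_t: int = 100_000
    elim_fraction: float = 0.2
    min_observations: int = 30
    exhaustive_threshold: int = 1_000_000
    max_filters: int | None = 1000
    retain_fraction: float | None = 0.2
    min_descriptors: int | None = None  # default: filter_size
    max_iterations: int = 100
    weights_scheme: str = "unit"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weights_scheme not in ("unit", "mcc", "fscore"):
            raise ValueError(f"unknown weights scheme {self.weights_scheme!r}")
        if self.filter_size < 1:
            raise ValueError("filter_size must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "IseConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class IterationReport:
    n_sampled: int
    combinations_before: int
    combinations_after: int
    n_eliminated: int
    mode: str
    eliminated: list[dict] = field(default_factory=list)


@dataclass
class Model:
    """Ranked filter ensemble (MCC descending) plus its build provenance."""

    filters: list[Filter]
    weights_scheme: str
    config: IseConfig
    descriptor_names: list[str]
    n_enumerated: int = 0
    iteration_summary: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in zip(self.filters, self.filters[1:]):
            if b.mcc > a.mcc:
                raise ValueError("filters must be sorted by MCC descending")

    def descriptors_used(self) -> list[str]:
        return sorted({r.descriptor for f in self.filters for r in f.ranges})

    def to_json(self) -> str:
        payload = {
            "meta": {
                "seed": self.config.seed,
                "config": asdict(self.config),
                "descriptor_names": list(self.descriptor_names),
                "n_enumerated": self.n_enumerated,
                "iteration_summary": self.iteration_summary,
            },
            "weights_scheme": self.weights_scheme,
            "filters": [
                {
                    "mcc": f.mcc,
                    "tp": f.tp,
                    "fp": f.fp,
                    "tn": f.tn,
                    "fn": f.fn,
                    "ranges": [
                        {"descriptor": r.descriptor, "low": r.low, "high": r.high}
                        for r in f.ranges
                    ],
                }
                for f in self.filters
            ],
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "Model":
        payload = json.loads(text)
        config = IseConfig.from_dict(payload["meta"]["config"])
        filters = [
            Filter(
                ranges=tuple(
                    DescriptorRange(r["descriptor"], r["low"], r["high"])
                    for r in f["ranges"]
                ),
                tp=f["tp"], fp=f["fp"], tn=f["tn"], fn=f["fn"], mcc=f["mcc"],
            )
            for f in payload["filters"]
        ]
        return cls(
            filters=filters,
            weights_scheme=payload["weights_scheme"],
            config=config,
            descriptor_names=list(payload["meta"]["descriptor_names"]),
            n_enumerated=payload["meta"].get("n_enumerated", 0),
            iteration_summary=payload["meta"].get("iteration_summary", []),
        )

    @classmethod
    def load(cls, path: str | Path) -> "Model":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# Evaluation context: packed pass-vectors for every candidate range


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(np.int64)
    if not set(np.unique(labels)) <= {0, 1}:
        raise IseError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise IseError("both classes must be present")
    return labels


class _EvalContext:
    """Packed membership masks for the flattened range list of a catalog."""

    def __init__(self, catalog: RangeCatalog, table: DescriptorTable, labels: np.ndarray):
        self.labels = _check_labels(labels)
        if len(self.labels) != table.n_molecules:
            raise IseError("labels length must match table rows")
        self.n_total = table.n_molecules
        self.n_active = int(self.labels.sum())
        self.active_words = pack_rows(self.labels.astype(bool))[0]
        self.descriptors = catalog.descriptors
        self.flat_ranges: list[DescriptorRange] = []
        self.offsets = []
        self.counts = []
        masks = []
        off = 0
        for name in self.descriptors:
            col = table.column(name)
            ranges = catalog.ranges_by_descriptor[name]
            lows = np.array([r.low for r in ranges])
            highs = np.array([r.high for r in ranges])
            masks.append((col[None, :] >= lows[:, None]) & (col[None, :] <= highs[:, None]))
            self.flat_ranges.extend(ranges)
            self.offsets.append(off)
            self.counts.append(len(ranges))
            off += len(ranges)
        self.offsets = np.array(self.offsets, dtype=np.int64)
        self.counts = np.array(self.counts, dtype=np.int64)
        self.pass_words = pack_rows(np.concatenate(masks, axis=0))
        self.range_descriptor = np.repeat(
            np.arange(len(self.descriptors)), self.counts
        )

    def confusion(self, range_idx: np.ndarray) -> tuple[np.ndarray, ...]:
        """Confusion counts for filters given as (m, k) global range indices."""
        out_tp = np.empty(len(range_idx), dtype=np.int64)
        out_fp = np.empty_like(out_tp)
        out_tn = np.empty_like(out_tp)
        out_fn = np.empty_like(out_tp)
        chunk = max(1, 2**22 // max(1, self.pass_words.shape[1] * range_idx.shape[1]))
        for start in range(0, len(range_idx), chunk):
            idx = range_idx[start : start + chunk]
            words = self.pass_words[idx[:, 0]].copy()
            for j in range(1, idx.shape[1]):
                words &= self.pass_words[idx[:, j]]
            tp, fp, tn, fn = confusion_batch(
                words, self.active_words, self.n_active, self.n_total
            )
            sl = slice(start, start + len(idx))
            out_tp[sl], out_fp[sl], out_tn[sl], out_fn[sl] = tp, fp, tn, fn
        return out_tp, out_fp, out_tn, out_fn

    def mcc(self, range_idx: np.ndarray) -> np.ndarray:
        return mcc_batch(*self.confusion(range_idx))


# ---------------------------------------------------------------------------
# Catalog construction


def build_range_catalog(
    table: DescriptorTable, labels: Sequence[int], n_bins: int = 8
) -> RangeCatalog:
    """Candidate ranges per descriptor: all contiguous unions of quantile
    bins of the active-class distribution (``n_bins`` bins → up to
    n_bins·(n_bins+1)/2 ranges). Each range carries its single-descriptor
    MCC. A descriptor constant over the actives yields one degenerate
    range, flagged."""
    labels = _check_labels(np.asarray(labels))
    if n_bins < 1:
        raise IseError("n_bins must be >= 1")
    active_rows = labels == 1
    ranges_by_descriptor: dict[str, list[DescriptorRange]] = {}
    for name in table.descriptor_names:
        col = table.column(name)
        act = col[active_rows]
        edges = np.unique(np.quantile(act, np.linspace(0.0, 1.0, n_bins + 1)))
        if len(edges) == 1:
            v = float(edges[0])
            mask = (col >= v) & (col <= v)
            mcc = _single_range_mcc(mask, labels)
            ranges_by_descriptor[name] = [
                DescriptorRange(name, v, v, single_mcc=mcc, degenerate=True)
            ]
            continue
        ranges = []
        for i in range(len(edges) - 1):
            for j in range(i + 1, len(edges)):
                low, high = float(edges[i]), float(edges[j])
                mask = (col >= low) & (col <= high)
                mcc = _single_range_mcc(mask, labels)
                ranges.append(DescriptorRange(name, low, high, single_mcc=mcc))
        ranges_by_descriptor[name] = ranges
    return RangeCatalog(ranges_by_descriptor)


def _single_range_mcc(mask: np.ndarray, labels: np.ndarray) -> float:
    tp = int((mask & (labels == 1)).sum())
    fp = int((mask & (labels == 0)).sum())
    fn = int(labels.sum()) - tp
    tn = int((labels == 0).sum()) - fp
    return exact_mcc(tp, fp, tn, fn)


# ---------------------------------------------------------------------------
# Single-filter evaluation and combination counting


def evaluate_filter(
    f: Filter, table: DescriptorTable, labels: Sequence[int]
) -> Filter:
    """Tally tp/fp/tn/fn for one filter (a molecule passes iff all five
    values lie inside their closed ranges) and attach the exact MCC."""
    labels = _check_labels(np.asarray(labels))
    mask = np.ones(table.n_molecules, dtype=bool)
    for r in f.ranges:
        if r.descriptor not in table.descriptor_names:
            raise IseError(f"descriptor {r.descriptor!r} missing from table")
        mask &= r.contains(table.column(r.descriptor))
    tp = int((mask & (labels == 1)).sum())
    fp = int((mask & (labels == 0)).sum())
    fn = int(labels.sum()) - tp
    tn = int((labels == 0).sum()) - fp
    return replace(f, tp=tp, fp=fp, tn=tn, fn=fn, mcc=exact_mcc(tp, fp, tn, fn))


def count_combinations(catalog: RangeCatalog, filter_size: int = 5) -> int:
    """Number of distinct filters: the degree-``filter_size`` elementary
    symmetric polynomial of the per-descriptor range counts."""
    counts = catalog.counts()
    if len(counts) < filter_size:
        return 0
    e = [0] * (filter_size + 1)
    e[0] = 1
    for c in counts:
        for k in range(filter_size, 0, -1):
            e[k] += e[k - 1] * c
    return e[filter_size]


# ---------------------------------------------------------------------------
# Stochastic elimination


def _sample_filters(
    ctx: _EvalContext, t: int, k: int, rng: np.random.Generator
) -> np.ndarray:
    """(t, k) global range indices: k distinct descriptors per filter, one
    uniformly chosen surviving range each."""
    d = len(ctx.descriptors)
    if d < k:
        raise IseError(f"need at least {k} descriptors, have {d}")
    scores = rng.random((t, d))
    desc = np.argpartition(scores, k - 1, axis=1)[:, :k]
    u = rng.random((t, k))
    ridx = np.minimum((u * ctx.counts[desc]).astype(np.int64), ctx.counts[desc] - 1)
    return ctx.offsets[desc] + ridx


def stochastic_iteration(
    catalog: RangeCatalog,
    table: DescriptorTable,
    labels: Sequence[int],
    sample_size_t: int,
    elim_fraction: float,
    min_observations: int,
    rng: np.random.Generator,
    filter_size: int = 5,
    min_descriptors: int = 5,
    mode: str = "strict",
) -> tuple[RangeCatalog, IterationReport]:
    """One elimination round.

    ``sample_size_t`` filters are drawn, scored, and per-range statistics
    accumulated (mean MCC of filters containing the range; membership counts
    in the top and bottom deciles of the sampled score histogram). In
    ``strict`` mode a range is eliminated when observed ≥
    ``min_observations`` times, its mean MCC falls strictly below the
    ``elim_fraction`` quantile of observed range means, it is
    over-represented in the bottom decile, and absent from the top decile;
    ties at the cut are never split. ``mean`` mode keeps only the mean-MCC
    condition (eliminating a whole tied bottom group when nothing lies
    strictly below the cut); ``forced`` mode eliminates a fixed quota of
    the worst observed ranges with a deterministic lexicographic tie-break.
    A descriptor losing its last range drops out of the catalog, but never
    below ``min_descriptors`` surviving descriptors.
    """
    if sample_size_t < 1:
        raise IseError("sample_size_t must be >= 1")
    labels = np.asarray(labels)
    ctx = _EvalContext(catalog, table, labels)
    n_before = count_combinations(catalog, filter_size)
    idx = _sample_filters(ctx, sample_size_t, filter_size, rng)
    mcc = ctx.mcc(idx)

    n_ranges = len(ctx.flat_ranges)
    flat = idx.ravel()
    count = np.bincount(flat, minlength=n_ranges)
    mcc_sum = np.bincount(flat, weights=np.repeat(mcc, filter_size), minlength=n_ranges)

    dec = max(1, sample_size_t // 10)
    order = np.argsort(mcc, kind="stable")
    bottom_count = np.bincount(idx[order[:dec]].ravel(), minlength=n_ranges)
    top_count = np.bincount(idx[order[-dec:]].ravel(), minlength=n_ranges)

    observed = count >= max(1, min_observations)
    mean_mcc = np.full(n_ranges, np.nan)
    mean_mcc[count > 0] = mcc_sum[count > 0] / count[count > 0]

    eliminate = np.zeros(n_ranges, dtype=bool)
    if elim_fraction > 0 and observed.any():
        cut = np.quantile(mean_mcc[observed], elim_fraction)
        if mode == "strict":
            expected_rate = dec / sample_size_t
            over_bottom = bottom_count > count * expected_rate
            eliminate = (
                observed & (mean_mcc < cut) & over_bottom & (top_count == 0)
            )
        elif mode == "mean":
            eliminate = observed & (mean_mcc < cut)
            if not eliminate.any():
                # the bottom of the mean-MCC histogram is one large tie
                # (typical once every filter that passes nothing scores
                # exactly 0): drop the whole tied group — tied ranges still
                # share one fate
                eliminate = observed & (mean_mcc <= cut)
        elif mode == "forced":
            # guaranteed progress: a fixed quota of the worst observed
            # ranges, deterministic lexicographic tie-break
            quota = max(1, int(math.ceil(elim_fraction * observed.sum())))
            obs_idx = np.where(observed)[0]
            keys = sorted(
                obs_idx, key=lambda g: (mean_mcc[g], ctx.flat_ranges[g].key())
            )
            eliminate[keys[:quota]] = True
        else:
            raise IseError(f"unknown elimination mode {mode!r}")

    # survivor floor: a descriptor may lose its last range (dropping out of
    # the catalog) only while at least min_descriptors remain; rescue the
    # best range of the strongest would-vanish descriptors otherwise
    d_count = len(ctx.descriptors)
    vanish = [
        d for d in range(d_count)
        if eliminate[ctx.range_descriptor == d].all()
    ]
    allowed = max(0, d_count - min_descriptors)
    if len(vanish) > allowed:
        best_mean = {
            d: np.nanmax(np.where(np.isnan(mean_mcc), -2.0, mean_mcc)[
                ctx.range_descriptor == d
            ])
            for d in vanish
        }
        rescue = sorted(vanish, key=lambda d: -best_mean[d])[: len(vanish) - allowed]
        for d in rescue:
            sel = np.where(ctx.range_descriptor == d)[0]
            scores = np.where(np.isnan(mean_mcc[sel]), -2.0, mean_mcc[sel])
            eliminate[sel[int(np.argmax(scores))]] = False

    eliminated_stats = []
    new_ranges: dict[str, list[DescriptorRange]] = {}
    for d_idx, name in enumerate(ctx.descriptors):
        sel = np.where(ctx.range_descriptor == d_idx)[0]
        keep = []
        for g in sel:
            r = ctx.flat_ranges[g]
            if eliminate[g]:
                eliminated_stats.append(
                    {
                        "descriptor": r.descriptor,
                        "low": r.low,
                        "high": r.high,
                        "mean_mcc": float(mean_mcc[g]),
                        "count": int(count[g]),
                        "top_decile_count": int(top_count[g]),
                        "bottom_decile_count": int(bottom_count[g]),
                    }
                )
            else:
                keep.append(r)
        if keep:
            new_ranges[name] = keep
    new_catalog = RangeCatalog(new_ranges)
    report = IterationReport(
        n_sampled=sample_size_t,
        combinations_before=n_before,
        combinations_after=count_combinations(new_catalog, filter_size),
        n_eliminated=len(eliminated_stats),
        mode=mode,
        eliminated=eliminated_stats,
    )
    return new_catalog, report


# ---------------------------------------------------------------------------
# Exhaustive enumeration


def _enumerate_subset_indices(ctx: _EvalContext, subset: tuple[int, ...]) -> np.ndarray:
    grids = np.meshgrid(
        *[np.arange(ctx.counts[d]) + ctx.offsets[d] for d in subset], indexing="ij"
    )
    return np.stack([g.ravel() for g in grids], axis=1)


def exhaustive_search(
    catalog: RangeCatalog,
    table: DescriptorTable,
    labels: Sequence[int],
    exhaustive_threshold: int = 1_000_000,
    filter_size: int = 5,
    top_k: int | None = None,
) -> list[Filter]:
    """Evaluate every remaining filter and return them MCC-descending with
    a lexicographic (descriptor, low, high) tie-break. ``top_k`` bounds the
    number of materialized filters without changing which are best.

    The flattened global range index is itself ordered by (descriptor name,
    low, high), so lexsorting the index columns under −MCC realizes the
    tie-break without materializing keys.
    """
    n = count_combinations(catalog, filter_size)
    if n == 0:
        return []
    if n >= exhaustive_threshold:
        raise IseError(
            f"{n} combinations remain, exhaustive search allowed below "
            f"{exhaustive_threshold}"
        )
    labels = np.asarray(labels)
    ctx = _EvalContext(catalog, table, labels)
    all_idx = []
    for subset in itertools.combinations(range(len(ctx.descriptors)), filter_size):
        all_idx.append(_enumerate_subset_indices(ctx, subset))
    idx = np.concatenate(all_idx, axis=0)
    tp, fp, tn, fn = ctx.confusion(idx)
    mcc = mcc_batch(tp, fp, tn, fn)
    order = np.lexsort(
        tuple(idx[:, j] for j in reversed(range(filter_size))) + (-mcc,)
    )
    if top_k is not None:
        order = order[:top_k]
    filters = []
    for g in order:
        ranges = tuple(ctx.flat_ranges[j] for j in idx[g])
        filters.append(
            Filter(
                ranges=ranges,
                tp=int(tp[g]), fp=int(fp[g]), tn=int(tn[g]), fn=int(fn[g]),
                mcc=exact_mcc(int(tp[g]), int(fp[g]), int(tn[g]), int(fn[g])),
            )
        )
    return filters


# ---------------------------------------------------------------------------
# Full build


def retention_cap(n_enumerated: int, config: IseConfig) -> int | None:
    """min(max_filters, ceil(retain_fraction · enumerated)); None = keep all."""
    caps = []
    if config.max_filters is not None:
        caps.append(config.max_filters)
    if config.retain_fraction is not None:
        caps.append(max(1, math.ceil(config.retain_fraction * n_enumerated)))
    return min(caps) if caps else None


def run_ise(
    table: DescriptorTable, labels: Sequence[int], config: IseConfig | None = None
) -> Model:
    """Build a model: range catalog → stochastic elimination until below the
    exhaustive threshold → exhaustive enumeration → retain the top filters.
    Deterministic for a given seed and input."""
    config = config or IseConfig()
    labels = _check_labels(np.asarray(labels))
    if len(table.descriptor_names) < config.filter_size:
        raise IseError(
            f"need at least {config.filter_size} descriptors, "
            f"have {len(table.descriptor_names)}"
        )
    rng = np.random.default_rng(config.seed)
    catalog = build_range_catalog(table, labels, config.n_bins)
    reports: list[IterationReport] = []
    min_descriptors = (
        config.min_descriptors
        if config.min_descriptors is not None
        else config.filter_size
    )
    modes = ("strict", "mean", "forced")
    mode_idx = 0
    while count_combinations(catalog, config.filter_size) >= config.exhaustive_threshold:
        if len(reports) >= config.max_iterations:
            raise IseConvergenceError(
                f"no convergence after {config.max_iterations} iterations; "
                f"{count_combinations(catalog, config.filter_size)} combinations remain"
            )
        catalog, rep = stochastic_iteration(
            catalog,
            table,
            labels,
            config.sample_size_t,
            config.elim_fraction,
            config.min_observations,
            rng,
            filter_size=config.filter_size,
            min_descriptors=min_descriptors,
            mode=modes[mode_idx],
        )
        reports.append(rep)
        # escalate (and never de-escalate) when a round makes no progress:
        # strict's decile conditions go quiet once every range is observed
        # often enough to appear in some top-decile filter
        if rep.n_eliminated == 0:
            if mode_idx == len(modes) - 1:
                raise IseConvergenceError(
                    "elimination stalled in forced mode; "
                    f"{rep.combinations_after} combinations remain"
                )
            mode_idx += 1
    if len(catalog.descriptors) < config.filter_size:
        raise IseError("catalog collapsed below the filter size")
    n_enum = count_combinations(catalog, config.filter_size)
    cap = retention_cap(n_enum, config)
    filters = exhaustive_search(
        catalog,
        table,
        labels,
        config.exhaustive_threshold,
        config.filter_size,
        top_k=cap,
    )
    return Model(
        filters=filters,
        weights_scheme=config.weights_scheme,
        config=config,
        descriptor_names=list(table.descriptor_names),
        n_enumerated=n_enum,
        iteration_summary=[
            {
                "n_sampled": r.n_sampled,
                "combinations_before": r.combinations_before,
                "combinations_after": r.combinations_after,
                "n_eliminated": r.n_eliminated,
                "mode": r.mode,
            }
            for r in reports
        ],
    )
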