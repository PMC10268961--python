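"""Synthetic fixtures with known ground truth.

Two generators: a numeric one that plants perfectly separating
five-descriptor boxes in an otherwise uniform descriptor space (the
actives-vs-diluted-decoys geometry of a virtual-screening learning set),
and a toy SMILES generator (arylpiperazine-like actives vs. small aliphatic
decoys) for end-to-end runs through real descriptor computation.

Geometry of the planted fixture: decoys are uniform over a wide hyper-box;
actives are Gaussian inside every planted box (boxes occupy disjoint
5-descriptor blocks, so their intersection is non-empty); decoys falling
inside any planted box are resampled. Label noise relabels a fraction of
the actives as decoys — coordinates are untouched, so the planted filters
remain the best attainable classifiers, and the decoy class acquires the
realistic contamination of unrecognised actives.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem_io import FAMILIES, DescriptorTable, MoleculeRecord
from .ise import DescriptorRange, Filter, evaluate_filter

SUPPORT = (0.0, 100.0)
BOX_WIDTH = 10.0


@dataclass
class PlantedFixture:
    table: DescriptorTable
    labels: np.ndarray
    planted_filters: list[Filter]
    noise_rate: float
    seed: int
    flipped_ids: list[str] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "descriptors.csv")
        with open(out / "labels.csv", "w") as fh:
            fh.write("molecule_id,label\n")
            for mid, lab in zip(self.table.molecule_ids, self.labels):
                fh.write(f"{mid},{int(lab)}\n")
        truth = {
            "seed": self.seed,
            "noise_rate": self.noise_rate,
            "flipped_ids": self.flipped_ids,
            "planted_filters": [
                {
                    "mcc": f.mcc,
                    "tp": f.tp, "fp": f.fp, "tn": f.tn, "fn": f.fn,
                    "ranges": [
                        {"descriptor": r.descriptor, "low": r.low, "high": r.high}
                        for r in f.ranges
                    ],
                }
                for f in self.planted_filters
            ],
        }
        (out / "truth.json").write_text(json.dumps(truth, sort_keys=True, indent=1))


def generate_planted_fixture(
    n_actives: int,
    n_decoys: int,
    n_descriptors: int = 20,
    n_planted: int = 1,
    noise_rate: float = 0.0,
    seed: int = 0,
    box_width: float = BOX_WIDTH,
) -> PlantedFixture:
    """Descriptor table with ``n_planted`` planted separating boxes.

    Planted box *b* constrains descriptors 5b…5b+4. Every active lies inside
    every box; no decoy lies inside any. The recorded planted filters carry
    the empirical active span per planted descriptor — the tightest box
    containing all actives, which is exactly the full-span candidate range
    the catalog builder produces — and are evaluated against the emitted
    (possibly noisy) labels.
    """
    if n_descriptors < 5 * n_planted:
        raise ValueError("need at least 5 descriptors per planted box")
    if not 0.0 <= noise_rate < 1.0:
        raise ValueError("noise_rate must be in [0, 1)")
    lo, hi = SUPPORT
    if box_width >= hi - lo:
        raise ValueError("planted box must be narrower than the decoy support")
    rng = np.random.default_rng(seed)
    d = n_descriptors
    planted_dims = [list(range(5 * b, 5 * b + 5)) for b in range(n_planted)]
    centers = rng.uniform(lo + box_width, hi - box_width, size=5 * n_planted)

    actives = rng.uniform(lo, hi, size=(n_actives, d))
    for b, dims in enumerate(planted_dims):
        for j, dim in enumerate(dims):
            c = centers[5 * b + j]
            vals = rng.normal(c, box_width / 6.0, size=n_actives)
            actives[:, dim] = np.clip(vals, c - box_width / 2, c + box_width / 2)

    decoys = rng.uniform(lo, hi, size=(n_decoys, d))
    for _ in range(1000):
        inside_any = np.zeros(n_decoys, dtype=bool)
        for b, dims in enumerate(planted_dims):
            inside = np.ones(n_decoys, dtype=bool)
            for j, dim in enumerate(dims):
                c = centers[5 * b + j]
                inside &= np.abs(decoys[:, dim] - c) <= box_width / 2
            inside_any |= inside
        if not inside_any.any():
            break
        decoys[inside_any] = rng.uniform(lo, hi, size=(int(inside_any.sum()), d))
    else:
        raise ValueError("could not place decoys outside the planted boxes")

    names = [f"d{i:02d}" for i in range(d)]
    ids = [f"A{i:05d}" for i in range(n_actives)] + [
        f"D{i:05d}" for i in range(n_decoys)
    ]
    values = np.vstack([actives, decoys])
    family_map = {n: FAMILIES[i % len(FAMILIES)] for i, n in enumerate(names)}
    table = DescriptorTable(ids, names, values, family_map)

    labels = np.array([1] * n_actives + [0] * n_decoys, dtype=np.int64)
    n_flip = int(noise_rate * n_actives)
    flipped_ids: list[str] = []
    if n_flip:
        flip = rng.choice(n_actives, size=n_flip, replace=False)
        labels[flip] = 0
        flipped_ids = [ids[i] for i in sorted(flip)]

    planted_filters = []
    for dims in planted_dims:
        ranges = tuple(
            DescriptorRange(
                names[dim],
                float(actives[:, dim].min()),
                float(actives[:, dim].max()),
            )
            for dim in dims
        )
        planted_filters.append(evaluate_filter(Filter(ranges=ranges), table, labels))
    return PlantedFixture(table, labels, planted_filters, noise_rate, seed, flipped_ids)


def load_labels_csv(path: str | Path) -> tuple[list[str], np.ndarray]:
    ids, labels = [], []
    with open(path) as fh:
        header = fh.readline()
        assert header.strip().split(",")[0] == "molecule_id"
        for line in fh:
            mid, lab = line.strip().split(",")
            ids.append(mid)
            labels.append(int(lab))
    return ids, np.array(labels, dtype=np.int64)


# ---------------------------------------------------------------------------
# Toy SMILES sets

_ARYL = [
    "c2ccccc2", "c2ccc(F)cc2", "c2ccc(Cl)cc2", "c2ccc(C)cc2",
    "c2ccc(OC)cc2", "c2ccccn2", "c2ccc(C#N)cc2", "c2cccc(F)c2",
    "c2cccc(Cl)c2", "c2ccc(CC)cc2",
]
_LINKER = ["CC", "CCC", "CCCC", "CC(C)", "CCCCC", "CCOCC"]
_CAP = ["", "O", "OC", "N", "CC(=O)"]

_DECOY_TERM = ["", "O", "N", "Cl", "Br", "OC", "C#N", "C(=O)O", "C(C)=O", "S"]
_DECOY_CHAIN = ["C" * k for k in range(2, 10)] + [
    "C1CCCCC1", "C1CCCC1", "CC(C)C", "CC(C)(C)C", "C1CCOC1", "C1CCNCC1",
]


def generate_toy_smiles(
    n_actives: int = 40, n_decoys: int = 80, seed: int = 0
) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Arylpiperazine-like actives (a receptor-ligand-like property profile)
    and small aliphatic decoys chosen to sit outside the actives' MW box."""
    rng = np.random.default_rng(seed)
    active_pool = [
        f"{cap}{link}N1CCN({aryl})CC1"
        for aryl, link, cap in itertools.product(_ARYL, _LINKER, _CAP)
    ]
    decoy_pool = [
        f"{chain}{term}" for chain, term in itertools.product(_DECOY_CHAIN, _DECOY_TERM)
    ]
    a_idx = rng.permutation(len(active_pool))
    d_idx = rng.permutation(len(decoy_pool))
    actives = [
        MoleculeRecord(f"ACT{i:04d}", active_pool[a_idx[i % len(active_pool)]], "active")
        for i in range(n_actives)
    ]
    decoys = [
        MoleculeRecord(f"DEC{i:04d}", decoy_pool[d_idx[i % len(decoy_pool)]], "decoy")
        for i in range(n_decoys)
    ]
    return actives, decoys
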