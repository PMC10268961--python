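"""Molecule I/O, structure standardization, 2D descriptors and fingerprints.

The descriptor panel is an open-source 2D set grouped into seven families
(partial-charge surface areas, atom/bond counts, pharmacophore feature
counts, physical properties, subdivided surface areas, adjacency/distance
matrix indices, Kier–Hall connectivity). The grouping ships as a CSV next
to the package so screened tables can be audited by family.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.AtomPairs import Pairs
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

FAMILIES = (
    "partial_charge",
    "atom_bond_counts",
    "pharmacophore_feature",
    "physical_properties",
    "subdivided_surface_areas",
    "adjacency_distance_matrix",
    "kier_hall_connectivity",
)

VALID_LABELS = ("active", "decoy", "unknown")


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule: stable id, SMILES, optional activity label."""

    id: str
    smiles: str
    label: str = "unknown"

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}, got {self.label!r}")


@dataclass(frozen=True)
class Fingerprint:
    """Sparse binary fingerprint as a set of non-negative feature indices."""

    bits: frozenset[int]

    def __post_init__(self) -> None:
        if any(b < 0 for b in self.bits):
            raise ValueError("fingerprint bit indices must be non-negative")

    def __len__(self) -> int:
        return len(self.bits)


@dataclass
class DescriptorTable:
    """Dense molecules × descriptors matrix with a per-descriptor family map."""

    molecule_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    family_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.molecule_ids), len(self.descriptor_names)):
            raise ValueError("values shape does not match ids × descriptors")
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise ValueError("descriptor names must be unique")
        if np.isnan(self.values).any():
            raise ValueError("descriptor table must not contain missing values")

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.descriptor_names.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.molecule_ids, columns=self.descriptor_names
        )

    def select_columns(self, names: Sequence[str]) -> "DescriptorTable":
        idx = [self.descriptor_names.index(n) for n in names]
        return DescriptorTable(
            list(self.molecule_ids),
            list(names),
            self.values[:, idx],
            {n: self.family_map[n] for n in names if n in self.family_map},
        )

    def select_rows(self, row_idx: Sequence[int]) -> "DescriptorTable":
        row_idx = list(row_idx)
        return DescriptorTable(
            [self.molecule_ids[i] for i in row_idx],
            list(self.descriptor_names),
            self.values[row_idx, :],
            dict(self.family_map),
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "molecule_id"
        df.to_csv(path, float_format="%.10g")

    @classmethod
    def from_csv(
        cls, path: str | Path, family_map: dict[str, str] | None = None
    ) -> "DescriptorTable":
        df = pd.read_csv(path, index_col=0)
        return cls(
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            df.to_numpy(dtype=np.float64),
            family_map or {},
        )


# ---------------------------------------------------------------------------
# SMILES / SDF reading


def read_smiles_file(path: str | Path, label: str = "unknown") -> list[MoleculeRecord]:
    """Read 'SMILES<TAB>id' lines; a missing id column gets a positional id."""
    records: list[MoleculeRecord] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol{i}"
            records.append(MoleculeRecord(mol_id, smiles, label))
    return records


def write_smiles_file(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.smiles}\t{rec.id}\n")


def read_sdf(path: str | Path, label: str = "unknown") -> list[MoleculeRecord]:
    records = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            continue
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
        records.append(MoleculeRecord(mol_id, Chem.MolToSmiles(mol), label))
    return records


# ---------------------------------------------------------------------------
# Standardization

_ACID_SMARTS = Chem.MolFromSmarts("[CX3](=O)[OX2H1]")
# basic aliphatic amine: neutral sp3 N bonded only to C/H, not amide, not
# aniline-type, not itself aromatic
_AMINE_SMARTS = Chem.MolFromSmarts(
    "[NX3;+0;!a;!$([N]-a);!$([N]-C=[O,N,S]);!$([N]~[!#6;!#1])]"
)


def _apply_protonation_rules(mol: Chem.Mol) -> Chem.Mol:
    """Single dominant microspecies at physiological pH: carboxylic acids
    deprotonated, basic aliphatic amines protonated."""
    rw = Chem.RWMol(mol)
    for match in rw.GetSubstructMatches(_ACID_SMARTS):
        o = rw.GetAtomWithIdx(match[2])
        o.SetFormalCharge(-1)
        o.SetNumExplicitHs(0)
    for match in rw.GetSubstructMatches(_AMINE_SMARTS):
        n = rw.GetAtomWithIdx(match[0])
        n.SetFormalCharge(1)
        n.SetNumExplicitHs(n.GetTotalNumHs() + 1)
        n.SetNoImplicit(True)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


@dataclass
class RejectedRecord:
    record: MoleculeRecord
    reason: str


def standardize_structures(
    records: Sequence[MoleculeRecord],
) -> tuple[list[MoleculeRecord], list[RejectedRecord]]:
    """Strip counterions/minor components, assign the charge state, and emit
    canonical SMILES. Unparseable or empty structures are returned separately
    with a reason; the operation is idempotent on its own output."""
    chooser = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
    kept: list[MoleculeRecord] = []
    rejected: list[RejectedRecord] = []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            rejected.append(RejectedRecord(rec, "SMILES parse error"))
            continue
        if mol.GetNumAtoms() == 0:
            rejected.append(RejectedRecord(rec, "empty structure"))
            continue
        try:
            mol = rdMolStandardize.Cleanup(mol)
            mol = chooser.choose(mol)
            if not any(a.GetAtomicNum() == 6 for a in mol.GetAtoms()):
                rejected.append(RejectedRecord(rec, "no organic component"))
                continue
            mol = rdMolStandardize.Uncharger().uncharge(mol)
            mol = _apply_protonation_rules(mol)
            smiles = Chem.MolToSmiles(mol)
        except Exception as exc:  # rdkit sanitization failures
            rejected.append(RejectedRecord(rec, f"standardization failed: {exc}"))
            continue
        kept.append(MoleculeRecord(rec.id, smiles, rec.label))
    for rej in rejected:
        logger.warning("rejected %s: %s", rej.record.id, rej.reason)
    if records and not kept:
        logger.error("all %d input records failed standardization", len(records))
    return kept, rejected


# ---------------------------------------------------------------------------
# Descriptor panel

_PHARMACOPHORE_SMARTS = {
    "phf_acceptor": "[$([O;H1;v2]),$([O;H0;v2]),$([O;-]),$([N;v3;!$(N-*=[O,N,P,S])]),$([n;H0])]",
    "phf_donor": "[$([N;!H0]),$([O;H1]),$([n;H1])]",
    "phf_basic": "[$([NX3;+0;!a;!$([N]-a);!$([N]-C=[O,N,S]);!$([N]~[!#6;!#1])]),$([NX4;+1])]",
    "phf_acidic": "[$([CX3](=O)[OX2H1]),$([CX3](=O)[OX1-]),$([SX4](=O)(=O)[OX2H1])]",
    "phf_aromatic_atom": "[a]",
    "phf_hydrophobe": "[C;!$(C~[!#6;!#1])]",
}


def _smarts_counter(smarts: str) -> Callable[[Chem.Mol], float]:
    patt = Chem.MolFromSmarts(smarts)

    def count(mol: Chem.Mol) -> float:
        return float(len(mol.GetSubstructMatches(patt)))

    return count


def _build_panel() -> dict[str, tuple[str, Callable[[Chem.Mol], float]]]:
    panel: dict[str, tuple[str, Callable[[Chem.Mol], float]]] = {}

    def add(names: Sequence[str], family: str) -> None:
        for n in names:
            panel[n] = (family, getattr(Descriptors, n))

    add(
        ["MaxPartialCharge", "MinPartialCharge", "MaxAbsPartialCharge", "MinAbsPartialCharge"]
        + [f"PEOE_VSA{i}" for i in range(1, 15)],
        "partial_charge",
    )
    add(
        [
            "HeavyAtomCount", "NHOHCount", "NOCount", "NumRotatableBonds",
            "RingCount", "NumAromaticRings", "NumAliphaticRings",
            "NumSaturatedRings", "FractionCSP3", "NumHeteroatoms",
        ],
        "atom_bond_counts",
    )
    for name, smarts in _PHARMACOPHORE_SMARTS.items():
        panel[name] = ("pharmacophore_feature", _smarts_counter(smarts))
    add(
        ["MolWt", "MolLogP", "NumHAcceptors", "NumHDonors", "TPSA", "MolMR", "LabuteASA"],
        "physical_properties",
    )
    add(
        [f"SlogP_VSA{i}" for i in range(1, 13)] + [f"SMR_VSA{i}" for i in range(1, 11)],
        "subdivided_surface_areas",
    )
    add(["BalabanJ", "BertzCT"], "adjacency_distance_matrix")
    add(
        ["Chi0", "Chi1"]
        + [f"Chi{i}v" for i in range(5)]
        + [f"Chi{i}n" for i in range(5)]
        + ["Kappa1", "Kappa2", "Kappa3", "HallKierAlpha"],
        "kier_hall_connectivity",
    )
    return panel


_PANEL = _build_panel()


def descriptor_panel_names(descriptor_set: str = "rdkit2d") -> list[str]:
    if descriptor_set != "rdkit2d":
        raise ValueError(f"unknown descriptor set {descriptor_set!r}")
    return list(_PANEL)


def load_family_map() -> dict[str, str]:
    """Family assignment shipped with the package (descriptor_name,family)."""
    text = resources.files("isevs").joinpath("data/descriptor_families.csv").read_text()
    out: dict[str, str] = {}
    for row in csv.DictReader(text.splitlines()):
        out[row["descriptor_name"]] = row["family"]
    return out


def compute_descriptors(
    records: Sequence[MoleculeRecord], descriptor_set: str = "rdkit2d"
) -> DescriptorTable:
    """One descriptor row per record; molecules where any descriptor fails
    (NaN/inf or an RDKit error) are dropped and logged, never imputed."""
    names = descriptor_panel_names(descriptor_set)
    ids: list[str] = []
    rows: list[list[float]] = []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            logger.warning("descriptor row dropped for %s: unparseable SMILES", rec.id)
            continue
        try:
            row = [float(_PANEL[n][1](mol)) for n in names]
        except Exception as exc:
            logger.warning("descriptor row dropped for %s: %s", rec.id, exc)
            continue
        if not np.all(np.isfinite(row)):
            logger.warning("descriptor row dropped for %s: non-finite value", rec.id)
            continue
        ids.append(rec.id)
        rows.append(row)
    values = np.array(rows, dtype=np.float64).reshape(len(ids), len(names))
    family_map = {n: _PANEL[n][0] for n in names}
    return DescriptorTable(ids, names, values, family_map)


def compute_ad_properties(records: Sequence[MoleculeRecord]) -> pd.DataFrame:
    """MW, clogP, HBA, HBD per molecule — the four applicability-domain
    properties used for decoy matching."""
    rows = {}
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            continue
        rows[rec.id] = {
            "MW": Descriptors.MolWt(mol),
            "clogP": Descriptors.MolLogP(mol),
            "HBA": float(Descriptors.NumHAcceptors(mol)),
            "HBD": float(Descriptors.NumHDonors(mol)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Pruning

def prune_descriptors(table: DescriptorTable, r_max: float = 0.9) -> DescriptorTable:
    """Drop constant columns, then greedily drop the later-listed member of
    every pair with |Pearson r| > r_max. Idempotent by construction."""
    if not 0.0 < r_max <= 1.0:
        raise ValueError(f"r_max must be in (0, 1], got {r_max}")
    if table.n_molecules < 2:
        raise ValueError("pruning needs at least two molecules")
    values = table.values
    variable = [
        i for i in range(values.shape[1])
        if np.ptp(values[:, i]) > 0.0
    ]
    kept: list[int] = []
    for j in variable:
        ok = True
        vj = values[:, j]
        for i in kept:
            r = np.corrcoef(values[:, i], vj)[0, 1]
            if abs(r) > r_max:
                ok = False
                break
        if ok:
            kept.append(j)
    names = [table.descriptor_names[i] for i in kept]
    return table.select_columns(names)


# ---------------------------------------------------------------------------
# Fingerprints

def compute_fingerprint(record: MoleculeRecord, scheme: str = "atom_pair") -> Fingerprint:
    if scheme != "atom_pair":
        raise ValueError(f"unknown fingerprint scheme {scheme!r}")
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError(f"cannot fingerprint {record.id}: invalid or empty structure")
    fp = Pairs.GetAtomPairFingerprint(mol)
    return Fingerprint(frozenset(fp.GetNonzeroElements()))


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tc = N_c / (N_a + N_b − N_c); two empty fingerprints → 0."""
    n_c = len(a.bits & b.bits)
    denom = len(a.bits) + len(b.bits) - n_c
    if denom == 0:
        return 0.0
    return n_c / denom
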