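"""Molecule records, descriptors, fingerprints, similarity and selection.

This module wraps RDKit behind the small vocabulary the screening pipeline
needs: a :class:`MoleculeRecord` carrying the descriptors used by the
lead-like filter and the scoring oracles, Morgan fingerprints with Tanimoto
similarity, leader-style diversity selection, SMARTS substructure counting,
and SMILES/CSV/SDF round-trip I/O.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator, rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

#: SMARTS selections used across the pipeline (substructure counts, density
#: grids, the acid-group filter of the rescoring campaign).
SMARTS_PATTERNS: dict[str, str] = {
    "carboxylic_acid": "[CX3](=O)[OX2H1,OX1-]",
    "sulfonamide": "S(=O)(=O)N",
    "sulfone": "S(=O)(=O)",
    "amide": "C(=O)N",
    "aromatic_atom": "a",
    # conventional H-bond definitions: donors are N/O bearing a hydrogen,
    # acceptors are N/O excluding amide nitrogens
    "hbond_donor": "[N,O;!H0]",
    "hbond_acceptor": "[$([O;X1,X2]),$([N;X1,X2,X3;!$(NC=O)])]",
}

_compiled_smarts: dict[str, Chem.Mol] = {}


def compiled_smarts(pattern: str) -> Chem.Mol:
    """Compile (and cache) a SMARTS pattern, raising ``ValueError`` if invalid."""
    key = SMARTS_PATTERNS.get(pattern, pattern)
    patt = _compiled_smarts.get(key)
    if patt is None:
        patt = Chem.MolFromSmarts(key)
        if patt is None:
            raise ValueError(f"invalid SMARTS pattern: {key!r}")
        _compiled_smarts[key] = patt
    return patt


class MoleculeError(ValueError):
    """Raised for unparseable structures or malformed molecule inputs."""


@dataclass(frozen=True, slots=True)
class Fingerprint:
    """A Morgan (circular) fingerprint as a sorted tuple of on-bit indices."""

    n_bits: int = 2048
    radius: int = 2
    on_bits: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.on_bits and not (0 <= self.on_bits[0] and self.on_bits[-1] < self.n_bits):
            raise ValueError("fingerprint bit index out of range")

    def to_bitvect(self) -> DataStructs.ExplicitBitVect:
        bv = DataStructs.ExplicitBitVect(self.n_bits)
        for b in self.on_bits:
            bv.SetBit(b)
        return bv


def morgan_fingerprint(mol: Chem.Mol, n_bits: int = 2048, radius: int = 2) -> Fingerprint:
    gen = _fp_generator(n_bits, radius)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(n_bits=n_bits, radius=radius, on_bits=tuple(bv.GetOnBits()))


_generators: dict[tuple[int, int], object] = {}


def _fp_generator(n_bits: int, radius: int):
    key = (n_bits, radius)
    gen = _generators.get(key)
    if gen is None:
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
        _generators[key] = gen
    return gen


@dataclass(slots=True)
class MoleculeRecord:
    """A molecule with the descriptors used by the filter and the oracles."""

    id: str
    smiles: str
    mw: float
    clogp: float
    n_rings: int
    n_rotatable: int
    formal_charge: int
    n_hba: int = 0
    n_aromatic_rings: int = 0
    n_acid: int = 0
    has_3d: bool = False
    fingerprint: Fingerprint | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("fingerprint")
        return d


# descriptor vector layout shared with the synthetic-library generator
DESCRIPTOR_NAMES = (
    "mw",
    "clogp",
    "n_hba",
    "n_rings",
    "n_rotatable",
    "n_aromatic_rings",
    "n_acid",
    "formal_charge",
)


def descriptor_vector(mol: Chem.Mol) -> np.ndarray:
    """The eight descriptors of :data:`DESCRIPTOR_NAMES` for one molecule."""
    acid = compiled_smarts("carboxylic_acid")
    return np.array(
        [
            Descriptors.MolWt(mol),
            Crippen.MolLogP(mol),
            rdMolDescriptors.CalcNumHBA(mol),
            rdMolDescriptors.CalcNumRings(mol),
            rdMolDescriptors.CalcNumRotatableBonds(mol),
            rdMolDescriptors.CalcNumAromaticRings(mol),
            len(mol.GetSubstructMatches(acid)),
            float(Chem.GetFormalCharge(mol)),
        ]
    )


def record_from_smiles(mol_id: str, smiles: str, *, has_3d: bool = False) -> MoleculeRecord:
    """Parse a SMILES and compute the full descriptor set.

    Raises :class:`MoleculeError` for unparseable input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeError(f"unparseable SMILES for {mol_id!r}: {smiles!r}")
    return record_from_mol(mol_id, mol, has_3d=has_3d)


def record_from_mol(mol_id: str, mol: Chem.Mol, *, has_3d: bool = False) -> MoleculeRecord:
    vec = descriptor_vector(mol)
    return MoleculeRecord(
        id=mol_id,
        smiles=Chem.MolToSmiles(mol),
        mw=float(vec[0]),
        clogp=float(vec[1]),
        n_hba=int(vec[2]),
        n_rings=int(vec[3]),
        n_rotatable=int(vec[4]),
        n_aromatic_rings=int(vec[5]),
        n_acid=int(vec[6]),
        formal_charge=int(vec[7]),
        has_3d=has_3d,
    )


def ensure_fingerprint(record: MoleculeRecord, n_bits: int = 2048, radius: int = 2) -> Fingerprint:
    """Compute (and cache on the record) the Morgan fingerprint."""
    fp = record.fingerprint
    if fp is not None and fp.n_bits == n_bits and fp.radius == radius:
        return fp
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise MoleculeError(f"unparseable SMILES for {record.id!r}")
    fp = morgan_fingerprint(mol, n_bits=n_bits, radius=radius)
    record.fingerprint = fp
    return fp


# --------------------------------------------------------------------------
# lead-like filter
# --------------------------------------------------------------------------

#: Lead-like bounds: MW < 460 g/mol, logP in [−4, 4], < 4 rings, < 10
#: rotatable bonds.  "Less than" bounds are strict; the logP interval is
#: inclusive on both ends.
LEADLIKE_BOUNDS = {"mw_max": 460.0, "clogp_min": -4.0, "clogp_max": 4.0, "rings_max": 4, "rotatable_max": 10}


@dataclass(frozen=True, slots=True)
class FilterResult:
    passed: bool
    failed_criteria: tuple[str, ...]


def leadlike_filter(record: MoleculeRecord) -> FilterResult:
    """Apply the lead-like property filter to a record's descriptors."""
    failed = []
    if not record.mw < LEADLIKE_BOUNDS["mw_max"]:
        failed.append("mw")
    if not LEADLIKE_BOUNDS["clogp_min"] <= record.clogp <= LEADLIKE_BOUNDS["clogp_max"]:
        failed.append("clogp")
    if not record.n_rings < LEADLIKE_BOUNDS["rings_max"]:
        failed.append("n_rings")
    if not record.n_rotatable < LEADLIKE_BOUNDS["rotatable_max"]:
        failed.append("n_rotatable")
    return FilterResult(passed=not failed, failed_criteria=tuple(failed))


# --------------------------------------------------------------------------
# similarity and diversity
# --------------------------------------------------------------------------


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |a∩b| / |a∪b|; two empty fingerprints give 0."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} != {b.n_bits}")
    sa, sb = set(a.on_bits), set(b.on_bits)
    union = len(sa | sb)
    if union == 0:
        return 0.0
    return len(sa & sb) / union


def diverse_subset(
    records: Sequence[MoleculeRecord],
    threshold: float,
    *,
    max_keep: int | None = None,
    exclude: Sequence[MoleculeRecord] | None = None,
) -> list[MoleculeRecord]:
    """Leader-style diversity selection over the given order.

    Walks ``records`` in order (callers pass score-sorted lists, best first)
    and keeps a record iff its maximum Tanimoto similarity to all previously
    kept records — and to the optional ``exclude`` set — is strictly below
    ``threshold``.  Every kept pair therefore satisfies similarity <
    threshold.  Stops early once ``max_keep`` records are kept.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    kept: list[MoleculeRecord] = []
    kept_bvs = []
    if exclude:
        kept_bvs.extend(ensure_fingerprint(r).to_bitvect() for r in exclude)
    for rec in records:
        bv = ensure_fingerprint(rec).to_bitvect()
        if kept_bvs:
            sims = DataStructs.BulkTanimotoSimilarity(bv, kept_bvs)
            if max(sims) >= threshold:
                continue
        kept.append(rec)
        kept_bvs.append(bv)
        if max_keep is not None and len(kept) >= max_keep:
            break
    return kept


def count_substructure(record: MoleculeRecord | str, pattern: str) -> int:
    """Number of unique matches of a SMARTS pattern (named or literal)."""
    smiles = record.smiles if isinstance(record, MoleculeRecord) else record
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeError(f"unparseable SMILES: {smiles!r}")
    return len(mol.GetSubstructMatches(compiled_smarts(pattern)))


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------


@dataclass(slots=True)
class IOReport:
    """Accounting of a read: parsed records plus per-entry failures."""

    records: list[MoleculeRecord]
    errors: list[str] = field(default_factory=list)
    extra_columns: pd.DataFrame | None = None


def read_molecules(path: str | os.PathLike) -> IOReport:
    """Read molecules from a SMILES list, a CSV with a ``smiles`` column, or SDF.

    Invalid entries are collected into the report's ``errors`` list rather
    than silently dropped.  Raises on unknown extensions and on inputs that
    yield zero valid records.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    records: list[MoleculeRecord] = []
    errors: list[str] = []
    extra: pd.DataFrame | None = None
    if ext in (".smi", ".smiles", ".txt"):
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split()
                smiles = parts[0]
                mol_id = parts[1] if len(parts) > 1 else f"line{lineno}"
                try:
                    records.append(record_from_smiles(mol_id, smiles))
                except MoleculeError as exc:
                    errors.append(str(exc))
    elif ext == ".csv":
        df = pd.read_csv(path)
        if "smiles" not in df.columns:
            raise MoleculeError(f"{path}: CSV needs a 'smiles' column")
        id_col = "id" if "id" in df.columns else None
        numeric = [c for c in df.columns if c not in ("id", "smiles") and pd.api.types.is_numeric_dtype(df[c])]
        keep_rows = []
        for idx, row in df.iterrows():
            mol_id = str(row[id_col]) if id_col else f"row{idx}"
            try:
                records.append(record_from_smiles(mol_id, str(row["smiles"])))
                keep_rows.append(idx)
            except MoleculeError as exc:
                errors.append(str(exc))
        if numeric:
            extra = df.loc[keep_rows, numeric].reset_index(drop=True)
            extra.insert(0, "id", [r.id for r in records])
    elif ext == ".sdf":
        supplier = Chem.SDMolSupplier(path, removeHs=True)
        for idx, mol in enumerate(supplier):
            if mol is None:
                errors.append(f"{path}: SDF record {idx} failed to parse")
                continue
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf{idx}"
            has_3d = mol.GetNumConformers() > 0 and mol.GetConformer().Is3D()
            records.append(record_from_mol(mol_id, mol, has_3d=has_3d))
    else:
        raise MoleculeError(f"unrecognized molecule file extension: {ext!r}")
    if not records:
        raise MoleculeError(f"{path}: no valid molecule records")
    return IOReport(records=records, errors=errors, extra_columns=extra)


def write_molecules(
    records: Iterable[MoleculeRecord],
    path: str | os.PathLike,
    extra_columns: pd.DataFrame | None = None,
) -> None:
    """Write records to CSV (id, smiles, descriptors, optional numeric columns)
    or to a one-per-line SMILES file."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    records = list(records)
    if ext in (".smi", ".smiles", ".txt"):
        with open(path, "w") as fh:
            for rec in records:
                fh.write(f"{rec.smiles} {rec.id}\n")
    elif ext == ".csv":
        df = pd.DataFrame([r.to_dict() for r in records])
        if extra_columns is not None:
            df = df.merge(extra_columns, on="id", how="left")
        df.to_csv(path, index=False)
    else:
        raise MoleculeError(f"unrecognized output extension: {ext!r}")
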