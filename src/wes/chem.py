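"""Molecule parsing and the two feature channels.

The binary channel is a 1024-bit hashed path fingerprint (RDKit topological
fingerprint); the continuous channel is the RDKit 2-D descriptor set,
standardised per feature over the training collection.  Both channels are
pluggable: precomputed feature matrices bypass chemistry entirely, which is
how the synthetic benchmarks flow through the identical downstream path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LigandRecord",
    "ReadResult",
    "StandardizationParams",
    "read_ligands",
    "compute_binary_features",
    "compute_continuous_features",
    "standardize",
    "apply_standardization",
]

DEFAULT_N_BITS = 1024


@dataclass
class LigandRecord:
    """One molecule: id, optional structure, optional precomputed features."""

    ligand_id: str
    smiles: str | None = None
    mol: object | None = field(default=None, repr=False)
    fp: np.ndarray | None = None
    desc: np.ndarray | None = None


@dataclass
class ReadResult:
    records: list
    excluded: list  # (identifier, reason) for every unparseable entry


@dataclass
class StandardizationParams:
    """Per-feature mean/sd of the training collection, plus the kept mask."""

    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray          # boolean mask over the original columns
    feature_names: list | None = None
    dropped_names: list | None = None


def _mol_from_smiles(smiles: str):
    from rdkit import Chem

    return Chem.MolFromSmiles(smiles)


def read_ligands(path, fmt: str = "smiles_tsv", id_tag: str | None = None) -> ReadResult:
    """Read molecules from a SMILES TSV (``ligand_id<TAB>smiles``) or an SDF.

    Unparseable entries are logged and collected in the exclusion list, never
    silently dropped.  A missing file or zero valid molecules is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[LigandRecord] = []
    excluded: list[tuple[str, str]] = []
    if fmt == "smiles_tsv":
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        if lines and lines[0].lower().split("\t")[:2] in (["ligand_id", "smiles"],):
            lines = lines[1:]
        for i, ln in enumerate(lines):
            parts = ln.split("\t")
            if len(parts) < 2:
                excluded.append((f"line {i + 1}", "malformed row"))
                continue
            lid, smi = parts[0].strip(), parts[1].strip()
            mol = _mol_from_smiles(smi)
            if mol is None:
                logger.warning("unparseable SMILES for %s", lid)
                excluded.append((lid, "unparseable SMILES"))
                continue
            records.append(LigandRecord(ligand_id=lid, smiles=smi, mol=mol))
    elif fmt == "sdf":
        from rdkit import Chem

        supplier = Chem.SDMolSupplier(str(path))
        for i, mol in enumerate(supplier):
            if mol is None:
                logger.warning("unparseable SDF block %d", i)
                excluded.append((f"block {i}", "unparseable SDF block"))
                continue
            if id_tag and mol.HasProp(id_tag):
                lid = mol.GetProp(id_tag)
            elif mol.HasProp("_Name") and mol.GetProp("_Name"):
                lid = mol.GetProp("_Name")
            else:
                lid = f"mol_{i}"
            records.append(LigandRecord(ligand_id=lid,
                                        smiles=Chem.MolToSmiles(mol), mol=mol))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not records:
        raise ValueError(f"no valid molecules in {path}")
    ids = [r.ligand_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ligand_id in input")
    return ReadResult(records=records, excluded=excluded)


def compute_binary_features(ligands, n_bits: int = DEFAULT_N_BITS) -> np.ndarray:
    """Hashed binary fingerprints, one row per ligand.

    Records that already carry a precomputed ``fp`` pass through unchanged
    (the synthetic path); otherwise the RDKit path-based hashed fingerprint
    of the requested width is computed from the structure.
    """
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    rows = []
    for rec in ligands:
        if rec.fp is not None:
            rows.append(np.asarray(rec.fp, dtype=np.uint8))
            continue
        mol = rec.mol if rec.mol is not None else (
            _mol_from_smiles(rec.smiles) if rec.smiles else None)
        if mol is None:
            raise ValueError(f"ligand {rec.ligand_id!r} has no structure or fingerprint")
        from rdkit import Chem

        bv = Chem.RDKFingerprint(mol, fpSize=n_bits)
        rows.append(np.frombuffer(bytes(bv.ToBitString(), "ascii"), dtype=np.uint8) - ord("0"))
    M = np.vstack(rows)
    if not np.isin(M, (0, 1)).all():
        raise ValueError("fingerprint matrix contains non-binary entries")
    return M


def _rdkit_descriptor_matrix(ligands) -> tuple[np.ndarray, list]:
    from rdkit.Chem import Descriptors

    names = [n for n, _ in Descriptors.descList]
    rows = []
    for rec in ligands:
        mol = rec.mol if rec.mol is not None else (
            _mol_from_smiles(rec.smiles) if rec.smiles else None)
        if mol is None:
            raise ValueError(f"ligand {rec.ligand_id!r} has no structure or descriptors")
        d = Descriptors.CalcMolDescriptors(mol)
        rows.append([d[n] for n in names])
    return np.asarray(rows, dtype=float), names


def standardize(matrix, feature_names=None) -> tuple[np.ndarray, StandardizationParams]:
    """Standardise each column to mean 0, sd 1 over the reference collection.

    Constant or non-finite columns are dropped and recorded in the returned
    parameters; the parameters are reused verbatim for query molecules so
    that queries are scaled by the *training* moments, never their own.
    """
    X = np.asarray(matrix, dtype=float)
    finite = np.isfinite(X).all(axis=0)
    sd = np.where(finite, np.nanstd(np.where(np.isfinite(X), X, np.nan), axis=0, ddof=0), 0.0)
    kept = finite & (sd > 0)
    if not kept.any():
        raise ValueError("every descriptor column is constant or non-finite")
    mean = X[:, kept].mean(axis=0)
    sdk = X[:, kept].std(axis=0, ddof=0)
    names = list(feature_names) if feature_names is not None else None
    params = StandardizationParams(
        mean=mean, sd=sdk, kept=kept,
        feature_names=[names[i] for i in np.where(kept)[0]] if names else None,
        dropped_names=[names[i] for i in np.where(~kept)[0]] if names else None)
    return (X[:, kept] - mean) / sdk, params


def apply_standardization(matrix, params: StandardizationParams) -> np.ndarray:
    """Scale new rows with stored training moments: (d - mu_i) / sigma_i."""
    X = np.asarray(matrix, dtype=float)
    return (X[:, params.kept] - params.mean) / params.sd


def compute_continuous_features(ligands) -> tuple[np.ndarray, StandardizationParams]:
    """Continuous descriptor matrix, standardised over the collection.

    Precomputed ``desc`` rows pass through (then only standardisation is
    applied); otherwise the RDKit 2-D descriptor set is computed.
    """
    if all(rec.desc is not None for rec in ligands):
        M = np.vstack([np.asarray(r.desc, dtype=float) for r in ligands])
        names = None
    else:
        M, names = _rdkit_descriptor_matrix(ligands)
    return standardize(M, feature_names=names)
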