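"""Interaction tables: ingestion, the five-rule positive-set filter, and
random negative-set generation.

The filter reproduces the curation applied to BindingDB-style exports:

1. drop redundant protein-ligand rows (exact duplicates on protein, ligand,
   affinity type and value);
2. drop pairs with no Ki/IC50 value or with mean affinity above 10 uM;
3. when two proteins share more than 60% of the smaller set's ligands, drop
   the protein with the smaller ligand set;
4. within each protein's set, greedily remove ligands until no remaining
   pair has unweighted Tanimoto similarity above 0.75;
5. drop proteins left with fewer than 5 ligands.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .similarity import tanimoto_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "FilterReport",
    "read_interactions",
    "write_interactions",
    "filter_positive_set",
    "generate_negative_set",
    "AFFINITY_CUTOFF_UM",
    "OVERLAP_CUTOFF",
    "TANIMOTO_CUTOFF",
    "MIN_LIGANDS",
]

AFFINITY_CUTOFF_UM = 10.0
OVERLAP_CUTOFF = 0.60
TANIMOTO_CUTOFF = 0.75
MIN_LIGANDS = 5

COLUMNS = ["protein_id", "ligand_id", "affinity_type", "affinity_uM"]


@dataclass
class FilterReport:
    """Per-step audit of the positive-set filter."""

    counts_before: dict = field(default_factory=dict)
    counts_after: dict = field(default_factory=dict)
    removed: dict = field(default_factory=dict)

    def record(self, step: str, before: int, after: int, removed: list) -> None:
        self.counts_before[step] = before
        self.counts_after[step] = after
        self.removed[step] = list(removed)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


def read_interactions(path) -> pd.DataFrame:
    """Read a tab-separated interaction table.

    Columns: ``protein_id, ligand_id, affinity_type, affinity_uM`` (header
    optional).  Missing affinities may be blank or NA.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != COLUMNS[:2]:
        df = pd.read_csv(path, sep="\t", header=None, names=COLUMNS, dtype=str)
    df["affinity_uM"] = pd.to_numeric(df["affinity_uM"], errors="coerce")
    return df


def write_interactions(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _ligand_fp_lookup(ligand_structures) -> dict:
    """Normalise the structure argument to {ligand_id: binary fp vector}."""
    from . import chem

    fps = {}
    smiles_items = []
    for lid, val in ligand_structures.items():
        if isinstance(val, str):
            smiles_items.append((lid, val))
        else:
            fps[lid] = np.asarray(val, dtype=np.uint8)
    if smiles_items:
        recs = []
        for lid, smi in smiles_items:
            mol = chem._mol_from_smiles(smi)
            if mol is None:
                raise ValueError(f"unparseable SMILES for ligand {lid!r}")
            recs.append(chem.LigandRecord(ligand_id=lid, smiles=smi, mol=mol))
        M = chem.compute_binary_features(recs)
        for rec, row in zip(recs, M):
            fps[rec.ligand_id] = row
    return fps


def filter_positive_set(records: pd.DataFrame, ligand_structures: dict
                        ) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the five curation rules in order; report every removal.

    ``ligand_structures`` maps ligand_id to a SMILES string or a precomputed
    binary fingerprint vector (needed for the intra-set similarity rule).
    Returns one row per surviving (protein, ligand) pair with its mean
    affinity, plus the :class:`FilterReport`.
    """
    df = records.copy().reset_index(drop=True)
    report = FilterReport()

    # (1) exact duplicate rows
    before = len(df)
    dup_mask = df.duplicated(subset=["protein_id", "ligand_id", "affinity_type",
                                     "affinity_uM"], keep="first")
    removed = df.loc[dup_mask, ["protein_id", "ligand_id"]].apply(tuple, axis=1).tolist()
    df = df.loc[~dup_mask]
    report.record("1_dedupe", before, len(df), removed)

    # (2) aggregate to pairs; drop no-affinity or mean > 10 uM
    pairs = (df.groupby(["protein_id", "ligand_id"], sort=True)["affinity_uM"]
             .apply(lambda s: s.dropna().mean()).reset_index())
    before = len(pairs)
    bad = pairs["affinity_uM"].isna() | (pairs["affinity_uM"] > AFFINITY_CUTOFF_UM)
    removed = pairs.loc[bad, ["protein_id", "ligand_id"]].apply(tuple, axis=1).tolist()
    pairs = pairs.loc[~bad].reset_index(drop=True)
    report.record("2_affinity", before, len(pairs), removed)

    # (3) protein-overlap rule: overlap measured against the smaller set
    sets = {p: set(g["ligand_id"]) for p, g in pairs.groupby("protein_id")}
    removed_proteins = []
    changed = True
    while changed:
        changed = False
        prots = sorted(sets)
        for i, a in enumerate(prots):
            for b in prots[i + 1:]:
                inter = len(sets[a] & sets[b])
                smaller = min(len(sets[a]), len(sets[b]))
                if smaller and inter / smaller > OVERLAP_CUTOFF:
                    if len(sets[a]) < len(sets[b]):
                        drop = a
                    elif len(sets[b]) < len(sets[a]):
                        drop = b
                    else:
                        drop = max(a, b)  # equal sizes: drop the larger id
                    removed_proteins.append(drop)
                    del sets[drop]
                    changed = True
                    break
            if changed:
                break
    before = len(pairs)
    pairs = pairs.loc[~pairs["protein_id"].isin(removed_proteins)].reset_index(drop=True)
    report.record("3_overlap", before, len(pairs), removed_proteins)

    # (4) intra-set similarity: greedy removal of the most-connected ligand
    fps = _ligand_fp_lookup(ligand_structures)
    missing = set(pairs["ligand_id"]) - set(fps)
    if missing:
        raise ValueError(f"no structure/fingerprint for ligands: {sorted(missing)}")
    removed_pairs = []
    keep_rows = np.ones(len(pairs), dtype=bool)
    for prot, grp in pairs.groupby("protein_id"):
        lids = sorted(grp["ligand_id"])
        M = np.vstack([fps[l] for l in lids])
        sim = tanimoto_matrix(M, M)
        np.fill_diagonal(sim, 0.0)
        adj = sim > TANIMOTO_CUTOFF
        active = list(range(len(lids)))
        while True:
            deg = adj[np.ix_(active, active)].sum(axis=1)
            if deg.max(initial=0) == 0:
                break
            # most neighbours first; ties by ascending ligand_id
            best = min(((-deg[k], lids[active[k]], k) for k in range(len(active))))
            victim = active[best[2]]
            removed_pairs.append((prot, lids[victim]))
            active.remove(victim)
        dropped = {lids[i] for i in range(len(lids)) if i not in active}
        if dropped:
            keep_rows &= ~((pairs["protein_id"] == prot)
                           & pairs["ligand_id"].isin(dropped)).to_numpy()
    before = len(pairs)
    pairs = pairs.loc[keep_rows].reset_index(drop=True)
    report.record("4_similarity", before, len(pairs), removed_pairs)

    # (5) minimum ligand count
    before = len(pairs)
    counts = pairs.groupby("protein_id")["ligand_id"].size()
    small = sorted(counts.index[counts < MIN_LIGANDS])
    pairs = pairs.loc[~pairs["protein_id"].isin(small)].reset_index(drop=True)
    report.record("5_min_ligands", before, len(pairs), small)

    if pairs.empty:
        raise ValueError(
            "filter removed every pair; per-step counts: "
            + json.dumps(report.counts_after))
    return pairs, report


def generate_negative_set(positives: pd.DataFrame, protein_ids, ligand_ids,
                          rng_seed: int, n: int | None = None) -> pd.DataFrame:
    """Uniform random (protein, ligand) pairs disjoint from the positives.

    Draws ``n`` (default: as many as there are positives) distinct pairs
    without replacement from the full cross product minus the positive set.
    """
    prots = sorted(set(protein_ids))
    ligs = sorted(set(ligand_ids))
    pos = set(zip(positives["protein_id"], positives["ligand_id"]))
    n = len(positives) if n is None else n
    universe = len(prots) * len(ligs) - len(pos)
    if universe < n:
        raise ValueError(f"only {universe} non-positive pairs available, need {n}")
    rng = np.random.default_rng(rng_seed)
    chosen: set[tuple[str, str]] = set()
    out = []
    while len(out) < n:
        i = int(rng.integers(len(prots)))
        j = int(rng.integers(len(ligs)))
        pair = (prots[i], ligs[j])
        if pair in pos or pair in chosen:
            continue
        chosen.add(pair)
        out.append(pair)
    return pd.DataFrame(out, columns=["protein_id", "ligand_id"]).assign(label=0)
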