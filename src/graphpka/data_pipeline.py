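"""Dataset I/O, similarity-capped splitting, graph augmentation and the
synthetic acid/base library generator.

The synthetic generator emulates the inductive-effect structure of small
organic acids and bases: an ionizable head group contributes a base pKa,
and each electron-withdrawing or -donating substituent shifts it by
``delta * rho**(d - 1)`` where ``d`` is the substituent's bond distance from
the ionization center and ``rho`` in (0, 1) is the per-bond attenuation of
the inductive effect.  Substituent positions span 1–7+ bonds so that
receptive-field experiments (layers + mask sweeps) are exercisable.

The similarity-capped split guards against rewarding memorization: whole
similarity clusters go to one side and no test molecule is more similar
than the cap (Tanimoto on circular fingerprints) to any training molecule.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit.DataStructs import BulkTanimotoSimilarity

from graphpka.chemgraph import (
    FeatureToggles,
    PairedMolecularGraph,
    build_paired_graph,
    mol_from_smiles,
    randomize_graph,
)
from graphpka.ionization import (
    add_proton,
    find_ionizable_sites,
    remove_proton,
)
from graphpka.registry import PropertyRegistry

__all__ = [
    "DatasetRecord",
    "SyntheticSpec",
    "read_records",
    "write_records",
    "record_to_paired_graph",
    "records_to_graphs",
    "morgan_fingerprints",
    "cluster_split",
    "random_split",
    "augment",
    "generate_synthetic_library",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DatasetRecord:
    """One labeled molecule: SMILES, pKa, optional ionization-center index."""

    smiles: str
    pka: float
    center: int | None = None
    split: str = "none"


# ---------------------------------------------------------------------------
# CSV I/O


def read_records(path) -> tuple[list[DatasetRecord], list[dict]]:
    """Read records from CSV (columns ``smiles``, ``pka``, optional
    ``center``, ``split``).

    Returns ``(records, rejects)``: unparseable SMILES rows are collected
    into the rejects report (and logged), never silently dropped.  Duplicate
    molecules keep the first occurrence; a conflicting label is logged with
    both values.
    """
    df = pd.read_csv(path)
    for col in ("smiles", "pka"):
        if col not in df.columns:
            raise ValueError(f"required column {col!r} missing from {path}")
    records: list[DatasetRecord] = []
    rejects: list[dict] = []
    seen: dict[tuple[str, int | None], float] = {}
    for i, row in df.iterrows():
        smiles = str(row["smiles"])
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            rejects.append({"row": int(i), "smiles": smiles,
                            "reason": "unparseable SMILES"})
            logger.warning("rejecting row %d: unparseable SMILES %r", i, smiles)
            continue
        center = None
        if "center" in df.columns and pd.notna(row["center"]):
            center = int(row["center"])
        key = (Chem.MolToSmiles(mol), center)
        pka = float(row["pka"])
        if key in seen:
            if seen[key] != pka:
                logger.warning(
                    "duplicate molecule %s with conflicting labels "
                    "%.3f vs %.3f; keeping first", key[0], seen[key], pka
                )
            continue
        seen[key] = pka
        split = str(row["split"]) if "split" in df.columns and pd.notna(
            row.get("split")) else "none"
        records.append(DatasetRecord(smiles, pka, center, split))
    return records, rejects


def write_records(records: Iterable[DatasetRecord], path) -> None:
    df = pd.DataFrame(
        [{"smiles": r.smiles, "pka": r.pka,
          "center": r.center, "split": r.split} for r in records]
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# record -> paired graph


def record_to_paired_graph(
    record: DatasetRecord,
    mode: str = "full",
    toggles: FeatureToggles | None = None,
    registry: PropertyRegistry | None = None,
    include_carbon: bool = False,
) -> PairedMolecularGraph:
    """Build the acid/base paired graph for a record's labeled center.

    The record's molecule is the neutral form; the center's role (acidic or
    basic) is looked up in the ionizable-site rule table, which also yields
    the conjugate form by removing or adding the proton.
    """
    mol = mol_from_smiles(record.smiles)
    if record.center is None:
        raise ValueError(
            f"record {record.smiles!r} has no ionization center; "
            "use the inference protocol for center-free prediction"
        )
    sites = {s.atom_index: s
             for s in find_ionizable_sites(mol, include_carbon=include_carbon)}
    try:
        site = sites[record.center]
    except KeyError:
        raise ValueError(
            f"center atom {record.center} of {record.smiles!r} is not a "
            f"detected ionizable site (sites: {sorted(sites)})"
        ) from None
    if site.role == "acidic":
        acid, base = mol, remove_proton(mol, site)
    else:
        acid, base = add_proton(mol, site), mol
    return build_paired_graph(
        acid, base, record.center, mode=mode, toggles=toggles,
        registry=registry, label=record.pka,
        group_class=site.group_class, site_role=site.role,
    )


def records_to_graphs(
    records: Sequence[DatasetRecord], **kwargs
) -> list[PairedMolecularGraph]:
    return [record_to_paired_graph(r, **kwargs) for r in records]


# ---------------------------------------------------------------------------
# splits


def morgan_fingerprints(smiles: Sequence[str], n_bits: int = 2048,
                        radius: int = 2):
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius,
                                                    fpSize=n_bits)
    fps = []
    for s in smiles:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {s!r}")
        fps.append(gen.GetFingerprint(mol))
    return fps


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_split(
    records: Sequence[DatasetRecord],
    similarity_cap: float = 0.65,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[DatasetRecord], dict]:
    """Similarity-capped train/test split on circular fingerprints.

    Molecules are clustered by sphere exclusion at the cap, clusters whose
    members are still mutually above the cap across cluster borders are
    merged, and whole clusters are assigned to one side.  The guarantee is
    hard: no test molecule has Tanimoto similarity above ``similarity_cap``
    to any training molecule.  Returns the relabeled records and a report
    (cluster sizes, max cross-set similarity, achieved fraction).
    """
    if not 0.0 < similarity_cap < 1.0:
        raise ValueError("similarity_cap must be in (0, 1)")
    n = len(records)
    if n == 0:
        return [], {"clusters": [], "achieved_fraction": 0.0,
                    "max_cross_similarity": 0.0}
    fps = morgan_fingerprints([r.smiles for r in records])

    # sphere exclusion + transitive merge of above-cap pairs
    uf = _UnionFind(n)
    for i in range(1, n):
        sims = BulkTanimotoSimilarity(fps[i], fps[:i])
        for j, s in enumerate(sims):
            if s > similarity_cap:
                uf.union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(uf.find(i), []).append(i)
    comp = list(clusters.values())

    rng = np.random.default_rng(seed)
    rng.shuffle(comp)
    comp.sort(key=len)  # stable: equal sizes stay shuffled

    target = test_fraction * n
    test_ids: set[int] = set()
    count = 0
    for members in comp:
        if count >= target:
            break
        if abs(count + len(members) - target) <= abs(count - target) or \
                count + len(members) <= target:
            test_ids.update(members)
            count += len(members)
    achieved = count / n
    if abs(achieved - test_fraction) > 0.05 and test_fraction not in (0.0, 1.0):
        biggest = max(comp, key=len)
        raise ValueError(
            f"cannot reach test fraction {test_fraction:.2f} "
            f"(achieved {achieved:.2f}); blocking cluster has "
            f"{len(biggest)} molecules, e.g. {records[biggest[0]].smiles!r}"
        )

    out = [replace(r, split="test" if i in test_ids else "train")
           for i, r in enumerate(records)]

    max_cross = 0.0
    train_fps = [fps[i] for i in range(n) if i not in test_ids]
    for i in test_ids:
        if train_fps:
            max_cross = max(max_cross, max(BulkTanimotoSimilarity(fps[i], train_fps)))
    report = {
        "n_clusters": len(comp),
        "cluster_sizes": sorted((len(c) for c in comp), reverse=True),
        "achieved_fraction": achieved,
        "max_cross_similarity": max_cross,
        "similarity_cap": similarity_cap,
    }
    return out, report


def random_split(
    records: Sequence[DatasetRecord], test_fraction: float, seed: int = 0
) -> list[DatasetRecord]:
    """Seeded uniform split (the memorization-prone baseline design)."""
    if not 0.0 <= test_fraction <= 1.0:
        raise ValueError("test_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(records)
    n_test = int(round(test_fraction * n))
    test_ids = set(rng.permutation(n)[:n_test].tolist())
    return [replace(r, split="test" if i in test_ids else "train")
            for i, r in enumerate(records)]


# ---------------------------------------------------------------------------
# augmentation


def augment(
    graphs: Sequence[PairedMolecularGraph],
    n_copies: int = 50,
    seed: int = 0,
) -> list[PairedMolecularGraph]:
    """Each graph plus ``n_copies`` randomized isomorphic copies.

    Copies carry the source graph's label and keep the center at index 0;
    the augmented set is generated once at dataset build, not per epoch.
    """
    rng = np.random.default_rng(seed)
    out: list[PairedMolecularGraph] = []
    for g in graphs:
        out.append(g)
        out.extend(randomize_graph(g, rng) for _ in range(n_copies))
    return out


# ---------------------------------------------------------------------------
# synthetic library


@dataclass(frozen=True)
class Scaffold:
    name: str
    head: str          # SMILES prefix; the ionization center is atom 0
    base_pka: float
    allow_center_sub: bool = False  # substituent directly on the head atom


@dataclass(frozen=True)
class Substituent:
    smiles: str        # appended fragment; first atom is the attachment atom
    delta: float       # pKa shift when one bond from the center


#: aliphatic/aromatic head groups with textbook base pKa values
DEFAULT_SCAFFOLDS: tuple[Scaffold, ...] = (
    Scaffold("carboxylic_acid", "OC(=O)", 4.76),
    Scaffold("amine", "N", 10.6, allow_center_sub=True),
    Scaffold("thiol", "S", 10.5),
    Scaffold("sulfonamide", "NS(=O)(=O)", 10.1),
    Scaffold("phenol_para", "Oc1ccc({chain})cc1", 10.0),
)

#: EWG/EDG substituents with first-shell pKa shifts
DEFAULT_SUBSTITUENTS: tuple[Substituent, ...] = (
    Substituent("F", -3.0),
    Substituent("Cl", -2.7),
    Substituent("Br", -2.5),
    Substituent("C#N", -3.6),
    Substituent("[N+](=O)[O-]", -4.0),
    Substituent("C", +0.4),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Grammar and attenuation parameters of the synthetic library.

    Ground truth: ``pka = base_pka + sum(delta * rho**(d-1)) + noise`` with
    ``d`` the bond distance of each substituent from the ionization center.
    """

    scaffolds: tuple[Scaffold, ...] = DEFAULT_SCAFFOLDS
    substituents: tuple[Substituent, ...] = DEFAULT_SUBSTITUENTS
    chain_lengths: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    attenuation: float = 0.4
    noise_sd: float = 0.1
    n_molecules: int = 500
    seed: int = 0
    max_substituents: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.attenuation < 1.0:
            raise ValueError("attenuation rho must be in (0, 1)")


def _chain_smiles(k: int, subs: dict[int, str]) -> str:
    """Linear carbon chain of length ``k`` with substituents at 1-based
    positions; position 0 substituents are handled by the caller."""
    parts = []
    for p in range(1, k + 1):
        parts.append("C")
        if p in subs:
            parts.append(f"({subs[p]})" if p < k else subs[p])
    return "".join(parts)


def _assemble(scaffold: Scaffold, k: int, subs: dict[int, str]) -> str:
    chain = _chain_smiles(k, {p: s for p, s in subs.items() if p > 0})
    if 0 in subs:
        chain = f"({subs[0]})" + chain if chain else subs[0]
    if "{chain}" in scaffold.head:
        if not chain:
            return scaffold.head.replace("({chain})", "").replace("{chain}", "")
        return scaffold.head.replace("{chain}", chain)
    return scaffold.head + chain


def _true_pka(
    spec: SyntheticSpec, scaffold: Scaffold, mol: Chem.Mol,
    sub_atoms: list[tuple[int, float]],
) -> float:
    from graphpka.chemgraph import bond_distances

    dist = bond_distances(mol, 0)
    pka = scaffold.base_pka
    for atom_idx, delta in sub_atoms:
        d = int(dist[atom_idx])
        pka += delta * spec.attenuation ** (d - 1)
    return pka


def generate_synthetic_library(
    spec: SyntheticSpec | None = None,
) -> list[DatasetRecord]:
    """Enumerate scaffold x chain x substituent combinations (seeded order,
    deduplicated on canonical SMILES) and label them with the ground-truth
    attenuation model plus Gaussian noise.

    Every emitted SMILES has the ionization-center atom at index 0.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)

    combos: list[tuple[Scaffold, int, tuple[tuple[int, Substituent], ...]]] = []
    for scaffold in spec.scaffolds:
        for k in spec.chain_lengths:
            positions = list(range(1, k + 1))
            if scaffold.allow_center_sub:
                positions = [0] + positions
            combos.append((scaffold, k, ()))

            def _allowed(p: int, sub: Substituent) -> bool:
                # a terminal methyl is indistinguishable from a longer chain,
                # which would give one molecule two ground truths
                return not (p == k and sub.smiles == "C")

            if spec.max_substituents >= 1:
                for p in positions:
                    for sub in spec.substituents:
                        if _allowed(p, sub):
                            combos.append((scaffold, k, ((p, sub),)))
            if spec.max_substituents >= 2:
                for p1, p2 in itertools.combinations(positions, 2):
                    for s1 in spec.substituents:
                        for s2 in spec.substituents:
                            if _allowed(p1, s1) and _allowed(p2, s2):
                                combos.append((scaffold, k, ((p1, s1), (p2, s2))))
    order = rng.permutation(len(combos))

    records: list[DatasetRecord] = []
    seen: set[str] = set()
    for idx in order:
        if len(records) >= spec.n_molecules:
            break
        scaffold, k, subs = combos[idx]
        smiles = _assemble(scaffold, k, {p: s.smiles for p, s in subs})
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        seen.add(canonical)
        sub_atoms = _locate_substituents(scaffold, k, subs)
        if sub_atoms is None:
            continue
        noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
        pka = _true_pka(spec, scaffold, mol, sub_atoms) + noise
        records.append(DatasetRecord(smiles=smiles, pka=float(pka), center=0))
    return records


def _locate_substituents(
    scaffold: Scaffold, k: int, subs: tuple
) -> list[tuple[int, float]] | None:
    """Find the atom index of each substituent's attachment atom by
    rebuilding the SMILES with atom-mapped substituent heads."""
    mapped = {}
    for m, (p, sub) in enumerate(subs, start=1):
        head, rest = _map_first_atom(sub.smiles, m)
        mapped[p] = head + rest
    smiles = _assemble(scaffold, k, mapped)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    out = []
    for m, (p, sub) in enumerate(subs, start=1):
        idx = next((a.GetIdx() for a in mol.GetAtoms()
                    if a.GetAtomMapNum() == m), None)
        if idx is None:
            return None
        out.append((idx, sub.delta))
    return out


def _map_first_atom(smiles: str, map_num: int) -> tuple[str, str]:
    """Attach an atom-map number to the first atom of a SMILES fragment.

    Bracket atoms carry no implicit hydrogens, so the H count must be made
    explicit where the organic-subset spelling implied one (methyl).
    """
    if smiles.startswith("["):
        end = smiles.index("]")
        return f"{smiles[:end]}:{map_num}]", smiles[end + 1:]
    if smiles == "C":
        return f"[CH3:{map_num}]", ""
    # one- or two-letter organic-subset element
    n = 2 if smiles[:2] in ("Cl", "Br") else 1
    return f"[{smiles[:n]}:{map_num}]", smiles[n:]
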