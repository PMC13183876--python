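"""Chemistry-principle featurization of acid/base molecular-graph pairs.

The featurization encodes, per heavy atom, the qualitative principles an
organic chemist uses to rank acidities — electronegativity, hardness and
atomic size (inductive effects), formal charge, hybridization, ring
membership and hydrogen count — and, per bond, the bond order, a revised
conjugation assignment and a *directed* bond polarization (electronegativity
difference oriented away from the ionization center, so electron-withdrawing
direction is explicit).

A molecule is always represented as a pair: the acid form and its conjugate
base, which share one heavy-atom skeleton and differ by a single proton.
Per-atom and per-bond features of both forms are concatenated, and the
ionization center is relocated to atom index 0 so the model always knows
where the proton moves.

The revised conjugation assignment departs from standard toolkit perception
on delocalized anionic groups: in a carboxylate the two C–O bonds are
resonance-equivalent and both carry the enhanced-resonance flag with a
delocalized bond order, whereas in the neutral acid the C=O and C–O(H)
bonds stay distinct.  This asymmetry between acid and base forms is exactly
the resonance stabilization that makes carboxylic acids acidic, and standard
conjugation perception erases it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from rdkit import Chem

from graphpka.registry import (
    PropertyRegistry,
    UnsupportedElementError,
    ConfigurationError,
    default_registry,
)

__all__ = [
    "FeatureToggles",
    "PairedMolecularGraph",
    "StructuralMismatchError",
    "mol_from_smiles",
    "bond_distances",
    "featurize_atoms",
    "revised_conjugation",
    "directed_polarization",
    "build_paired_graph",
    "randomize_graph",
    "compute_mask",
    "FULL_BOND_LENGTH",
    "FOCUSED_BOND_LENGTH",
]

logger = logging.getLogger(__name__)

MODES = ("full", "focused", "acid_only", "base_only")

#: paired bond-feature lengths with all bond toggles on
FULL_BOND_LENGTH = 14
FOCUSED_BOND_LENGTH = 10

_HYBRIDIZATIONS = ("sp", "sp2", "sp3", "other")
_PI_DONORS = {"N", "O", "S", "Se"}


class StructuralMismatchError(ValueError):
    """Acid and base forms do not share the same heavy-atom skeleton."""


@dataclass(frozen=True)
class FeatureToggles:
    """Feature switches, keyed in configuration files as e.g. ``atom.hardness``.

    Switched-off features contribute zero vector length (they are absent,
    not zeroed), so ablation models genuinely cannot see them.
    """

    electronegativity: bool = True
    hardness: bool = True
    atomic_diameter: bool = True
    formal_charge: bool = True
    hybridization: bool = True
    ring_size: bool = True
    n_hydrogens: bool = True
    element_onehot: bool = False
    bond_order: bool = True
    conjugation: bool = True
    polarization: bool = True

    _KEYMAP = {
        "atom.electronegativity": "electronegativity",
        "atom.hardness": "hardness",
        "atom.atomic_diameter": "atomic_diameter",
        "atom.size": "atomic_diameter",
        "atom.formal_charge": "formal_charge",
        "atom.hybridization": "hybridization",
        "atom.ring_size": "ring_size",
        "atom.n_hydrogens": "n_hydrogens",
        "atom.element_onehot": "element_onehot",
        "atom.elements": "element_onehot",
        "bond.bond_order": "bond_order",
        "bond.conjugation": "conjugation",
        "bond.polarization": "polarization",
    }

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "FeatureToggles":
        kwargs = {}
        for key, value in mapping.items():
            try:
                attr = cls._KEYMAP[key]
            except KeyError:
                raise ConfigurationError(
                    f"unknown feature toggle {key!r} "
                    f"(known: {', '.join(sorted(cls._KEYMAP))})"
                ) from None
            if isinstance(value, str):
                value = value.strip().lower() not in ("off", "false", "0", "no")
            kwargs[attr] = bool(value)
        return cls(**kwargs)


@dataclass(frozen=True)
class PairedMolecularGraph:
    """Heavy-atom graph of an acid/base pair, ionization center at index 0.

    ``atom_features`` rows and ``bond_features`` rows concatenate the acid
    and base feature blocks (single block in acid_only / base_only modes).
    ``edge_index`` lists each undirected heavy-atom bond once.
    """

    n_atoms: int
    elements: tuple[str, ...]
    edge_index: np.ndarray          # (2, n_edges), undirected
    atom_features: np.ndarray       # (n_atoms, d_atom)
    bond_features: np.ndarray       # (n_edges, d_bond)
    molecular_features: np.ndarray  # (2,): net charge, center formal charge
    bond_distance: np.ndarray       # (n_atoms,), bonds from the center
    mode: str = "full"
    label: float | None = None
    smiles: str | None = None
    group_class: str | None = None
    site_role: str | None = None
    center_input_index: int | None = None  # center's index in the input mol

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1]

    def with_label(self, label: float) -> "PairedMolecularGraph":
        return replace(self, label=float(label))


# ---------------------------------------------------------------------------
# molecule plumbing


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES; for multi-fragment input keep the largest organic
    fragment (a pKa refers to one species), logging a warning."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) > 1:
        organic = [f for f in frags if any(a.GetSymbol() == "C" for a in f.GetAtoms())]
        pool = organic or list(frags)
        mol = max(pool, key=lambda f: f.GetNumHeavyAtoms())
        logger.warning(
            "multi-fragment input %r: keeping largest organic fragment %s",
            smiles, Chem.MolToSmiles(mol),
        )
    return mol


def _skeleton(mol: Chem.Mol) -> tuple[tuple[str, ...], frozenset[tuple[int, int]]]:
    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    bonds = frozenset(
        tuple(sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx())))
        for b in mol.GetBonds()
    )
    return elements, bonds


def bond_distances(mol: Chem.Mol, center: int) -> np.ndarray:
    """Graph distance in bonds from ``center`` to every heavy atom (BFS).

    Unreachable atoms (other fragments) get -1.
    """
    n = mol.GetNumAtoms()
    dist = np.full(n, -1, dtype=np.int64)
    dist[center] = 0
    frontier = [center]
    while frontier:
        nxt = []
        for i in frontier:
            for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if dist[j] < 0:
                    dist[j] = dist[i] + 1
                    nxt.append(j)
        frontier = nxt
    return dist


# ---------------------------------------------------------------------------
# atom features


def _ring_size(mol: Chem.Mol, idx: int) -> int:
    sizes = [len(ring) for ring in mol.GetRingInfo().AtomRings() if idx in ring]
    return min(sizes) if sizes else 0


def _hybridization(atom: Chem.Atom) -> str:
    h = atom.GetHybridization()
    if h == Chem.HybridizationType.SP:
        return "sp"
    if h == Chem.HybridizationType.SP2:
        return "sp2"
    if h == Chem.HybridizationType.SP3:
        return "sp3"
    return "other"


def atom_feature_names(
    toggles: FeatureToggles, registry: PropertyRegistry
) -> list[str]:
    names: list[str] = []
    for f in ("electronegativity", "hardness", "atomic_diameter"):
        if getattr(toggles, f):
            names.append(f)
    if toggles.formal_charge:
        names.append("formal_charge")
    if toggles.hybridization:
        names += [f"hyb_{h}" for h in _HYBRIDIZATIONS]
    if toggles.ring_size:
        names.append("ring_size")
    if toggles.n_hydrogens:
        names.append("n_hydrogens")
    if toggles.element_onehot:
        names += [f"elem_{s}" for s in registry.elements if s != "H"]
    return names


def featurize_atoms(
    mol: Chem.Mol,
    toggles: FeatureToggles | None = None,
    registry: PropertyRegistry | None = None,
) -> np.ndarray:
    """Per-heavy-atom feature block for one form (acid or base).

    Raises :class:`UnsupportedElementError` for elements outside the
    registry — never a silent zero vector.
    """
    toggles = toggles or FeatureToggles()
    reg = registry if registry is not None else default_registry()
    heavy = [s for s in reg.elements if s != "H"]
    rows = []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in reg.properties:
            raise UnsupportedElementError(
                f"element {sym!r} (atom {atom.GetIdx()}) is not in the "
                f"property registry"
            )
        row: list[float] = []
        for f in ("electronegativity", "hardness", "atomic_diameter"):
            if getattr(toggles, f):
                row.append(reg.normalized(sym, f))
        if toggles.formal_charge:
            row.append(float(atom.GetFormalCharge()))
        if toggles.hybridization:
            hyb = _hybridization(atom)
            row += [1.0 if h == hyb else 0.0 for h in _HYBRIDIZATIONS]
        if toggles.ring_size:
            row.append(reg.normalize(min(_ring_size(mol, atom.GetIdx()), 8), "ring_size"))
        if toggles.n_hydrogens:
            row.append(reg.normalize(min(atom.GetTotalNumHs(), 4), "n_hydrogens"))
        if toggles.element_onehot:
            row += [1.0 if s == sym else 0.0 for s in heavy]
        rows.append(row)
    d = len(atom_feature_names(toggles, reg))
    return np.asarray(rows, dtype=np.float64).reshape(len(rows), d)


# ---------------------------------------------------------------------------
# bond features


@dataclass(frozen=True)
class ConjugationAssignment:
    """Per-bond conjugation indicators plus resonance-equivalent groups."""

    conjugated: np.ndarray          # (n_bonds,) bool
    enhanced: np.ndarray            # (n_bonds,) bool
    delocalized: np.ndarray         # (n_bonds,) bool: bond-order override
    shared_atom: dict[int, int] = field(default_factory=dict)
    # bond index -> pi-center atom of its equivalent group (polarization anchor)


def _in_pi_system(atom: Chem.Atom) -> bool:
    for b in atom.GetBonds():
        if b.GetIsAromatic() or b.GetBondType() in (
            Chem.BondType.DOUBLE, Chem.BondType.TRIPLE, Chem.BondType.AROMATIC
        ):
            return True
    return False


def revised_conjugation(mol: Chem.Mol) -> ConjugationAssignment:
    """Conjugation indicators that distinguish delocalized conjugate bases.

    The plain ``conjugated`` flag follows standard alternating-pi perception.
    On top of it, a single bond from a pi-system atom to a negatively charged
    lone-pair donor is flagged ``enhanced`` (the lone pair delocalizes into
    the pi system).  When an atom bears both a double bond and a singly
    bonded negatively charged partner of the same element (carboxylate,
    sulfonate, nitro-anion pattern — or the cationic mirror image, e.g.
    amidinium), those bonds form a resonance-equivalent group: all are
    flagged conjugated + enhanced and their bond order is marked delocalized
    so the group's bonds featurize identically.
    """
    n_bonds = mol.GetNumBonds()
    conj = np.zeros(n_bonds, dtype=bool)
    enh = np.zeros(n_bonds, dtype=bool)
    deloc = np.zeros(n_bonds, dtype=bool)
    shared: dict[int, int] = {}

    for b in mol.GetBonds():
        conj[b.GetIdx()] = b.GetIsConjugated()

    for b in mol.GetBonds():
        if b.GetBondType() not in (Chem.BondType.SINGLE, Chem.BondType.AROMATIC):
            continue
        for donor, other in ((b.GetBeginAtom(), b.GetEndAtom()),
                             (b.GetEndAtom(), b.GetBeginAtom())):
            if (donor.GetSymbol() in _PI_DONORS
                    and donor.GetFormalCharge() < 0
                    and _in_pi_system(other)):
                enh[b.GetIdx()] = True
                conj[b.GetIdx()] = True

    for atom in mol.GetAtoms():
        for sign in (-1, +1):
            groups: dict[str, list[Chem.Bond]] = {}
            anchors: dict[str, list[Chem.Bond]] = {}
            for b in atom.GetBonds():
                nb = b.GetOtherAtom(atom)
                if nb.GetSymbol() not in _PI_DONORS:
                    continue
                if (b.GetBondType() == Chem.BondType.DOUBLE
                        and nb.GetFormalCharge() == (sign if sign > 0 else 0)):
                    anchors.setdefault(nb.GetSymbol(), []).append(b)
                elif (b.GetBondType() == Chem.BondType.SINGLE
                      and nb.GetFormalCharge() == (sign if sign < 0 else 0)
                      and nb.GetTotalNumHs() + len(nb.GetNeighbors()) < 4):
                    groups.setdefault(nb.GetSymbol(), []).append(b)
            for elem, singles in groups.items():
                if sign < 0:
                    charged = [b for b in singles
                               if b.GetOtherAtom(atom).GetFormalCharge() < 0]
                else:
                    charged = anchors.get(elem, [])
                if not charged or elem not in anchors or not anchors[elem]:
                    continue
                if sign > 0 and not singles:
                    continue
                group = anchors[elem] + singles
                for b in group:
                    i = b.GetIdx()
                    conj[i] = True
                    enh[i] = True
                    deloc[i] = True
                    shared[i] = atom.GetIdx()

    return ConjugationAssignment(conj, enh, deloc, shared)


def directed_polarization(
    mol: Chem.Mol,
    center: int,
    registry: PropertyRegistry | None = None,
    conj: ConjugationAssignment | None = None,
) -> np.ndarray:
    """Signed per-bond electronegativity difference, directed away from the
    ionization center: for bond (a, b) with a closer to the center, the
    value is EN(b) − EN(a) in Pauling units.

    Equidistant atom pairs (odd cycles) get 0 — no direction is defined.
    Bonds in a resonance-equivalent group are oriented away from the group's
    shared pi-center atom instead, so equivalent bonds stay identical.
    """
    reg = registry if registry is not None else default_registry()
    dist = bond_distances(mol, center)
    out = np.zeros(mol.GetNumBonds(), dtype=np.float64)
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if dist[i] < 0 or dist[j] < 0:
            raise ValueError(
                f"bond ({i},{j}) is disconnected from the ionization center"
            )
        en_i = reg.get(mol.GetAtomWithIdx(i).GetSymbol(), "electronegativity")
        en_j = reg.get(mol.GetAtomWithIdx(j).GetSymbol(), "electronegativity")
        k = b.GetIdx()
        if conj is not None and k in conj.shared_atom:
            a = conj.shared_atom[k]
            out[k] = (en_j - en_i) if a == i else (en_i - en_j)
        elif dist[i] < dist[j]:
            out[k] = en_j - en_i
        elif dist[j] < dist[i]:
            out[k] = en_i - en_j
        else:
            out[k] = 0.0
    return out


def bond_feature_names(toggles: FeatureToggles, include_order: bool = True) -> list[str]:
    names: list[str] = []
    if include_order and toggles.bond_order:
        names += ["order_single", "order_aromatic", "order_double", "order_triple"]
    if toggles.conjugation:
        names += ["conjugated", "enhanced_resonance"]
    if toggles.polarization:
        names.append("polarization")
    return names


def _featurize_bonds(
    mol: Chem.Mol,
    center: int,
    toggles: FeatureToggles,
    registry: PropertyRegistry,
    include_order: bool = True,
) -> np.ndarray:
    conj = revised_conjugation(mol)
    pol = directed_polarization(mol, center, registry, conj)
    rows = []
    for b in mol.GetBonds():
        k = b.GetIdx()
        row: list[float] = []
        if include_order and toggles.bond_order:
            if conj.delocalized[k] or b.GetBondType() == Chem.BondType.AROMATIC:
                order = "aromatic"
            elif b.GetBondType() == Chem.BondType.DOUBLE:
                order = "double"
            elif b.GetBondType() == Chem.BondType.TRIPLE:
                order = "triple"
            else:
                order = "single"
            row += [1.0 if o == order else 0.0
                    for o in ("single", "aromatic", "double", "triple")]
        if toggles.conjugation:
            row += [float(conj.conjugated[k]), float(conj.enhanced[k])]
        if toggles.polarization:
            row.append(pol[k])
        rows.append(row)
    d = len(bond_feature_names(toggles, include_order))
    return np.asarray(rows, dtype=np.float64).reshape(len(rows), d)


# ---------------------------------------------------------------------------
# paired graph assembly


def _renumber(mol: Chem.Mol, center: int) -> tuple[Chem.Mol, list[int]]:
    """Relocate ``center`` to atom index 0, preserving the rest of the order."""
    order = [center] + [i for i in range(mol.GetNumAtoms()) if i != center]
    return Chem.RenumberAtoms(mol, order), order


def build_paired_graph(
    acid_form: Chem.Mol,
    base_form: Chem.Mol,
    center: int,
    mode: str = "full",
    toggles: FeatureToggles | None = None,
    registry: PropertyRegistry | None = None,
    label: float | None = None,
    group_class: str | None = None,
    site_role: str | None = None,
) -> PairedMolecularGraph:
    """Assemble the paired acid/base graph with the center at index 0.

    ``mode`` selects which feature blocks are emitted: ``full`` concatenates
    acid and base blocks; ``focused`` drops the base form's bond-order block
    (bond order is considered equivalent between the forms); ``acid_only``
    and ``base_only`` emit a single form's blocks.
    """
    if mode not in MODES:
        raise ConfigurationError(f"unknown mode {mode!r}; expected one of {MODES}")
    toggles = toggles or FeatureToggles()
    reg = registry if registry is not None else default_registry()

    if _skeleton(acid_form) != _skeleton(base_form):
        raise StructuralMismatchError(
            "acid and base forms must share the same heavy-atom skeleton "
            "(they differ by one proton only)"
        )
    if not 0 <= center < acid_form.GetNumAtoms():
        raise ValueError(f"center index {center} out of range")

    acid, _ = _renumber(acid_form, center)
    base, _ = _renumber(base_form, center)

    blocks_atoms: list[np.ndarray] = []
    blocks_bonds: list[np.ndarray] = []
    if mode in ("full", "focused", "acid_only"):
        blocks_atoms.append(featurize_atoms(acid, toggles, reg))
        blocks_bonds.append(_featurize_bonds(acid, 0, toggles, reg, include_order=True))
    if mode in ("full", "focused", "base_only"):
        blocks_atoms.append(featurize_atoms(base, toggles, reg))
        include_order = mode != "focused"
        blocks_bonds.append(
            _featurize_bonds(base, 0, toggles, reg, include_order=include_order)
        )

    atom_features = np.concatenate(blocks_atoms, axis=1)
    bond_features = np.concatenate(blocks_bonds, axis=1)

    edges = np.array(
        [[b.GetBeginAtomIdx() for b in acid.GetBonds()],
         [b.GetEndAtomIdx() for b in acid.GetBonds()]],
        dtype=np.int64,
    ).reshape(2, acid.GetNumBonds())

    net_charge = float(sum(a.GetFormalCharge() for a in base.GetAtoms()))
    center_charge = float(base.GetAtomWithIdx(0).GetFormalCharge())

    return PairedMolecularGraph(
        n_atoms=acid.GetNumAtoms(),
        elements=tuple(a.GetSymbol() for a in acid.GetAtoms()),
        edge_index=edges,
        atom_features=atom_features,
        bond_features=bond_features,
        molecular_features=np.array([net_charge, center_charge]),
        bond_distance=bond_distances(acid, 0),
        mode=mode,
        label=label,
        smiles=Chem.MolToSmiles(base_form),
        group_class=group_class,
        site_role=site_role,
        center_input_index=center,
    )


def randomize_graph(
    graph: PairedMolecularGraph, rng: np.random.Generator
) -> PairedMolecularGraph:
    """Isomorphic copy with a random atom order; the center stays at index 0.

    Used as data augmentation: a molecule has many equivalent matrix
    representations and the model should treat them identically.
    """
    n = graph.n_atoms
    if n < 2:
        return graph
    perm = np.concatenate(([0], 1 + rng.permutation(n - 1)))
    # perm[k] = old index placed at new position k; old->new = argsort(perm)
    new_of_old = np.argsort(perm)
    atom_features = graph.atom_features[perm]
    bond_distance = graph.bond_distance[perm]
    elements = tuple(graph.elements[k] for k in perm)
    edge_order = rng.permutation(graph.n_edges) if graph.n_edges else np.array([], dtype=np.int64)
    edge_index = new_of_old[graph.edge_index][:, edge_order].reshape(2, graph.n_edges)
    bond_features = graph.bond_features[edge_order]
    return replace(
        graph,
        elements=elements,
        edge_index=edge_index,
        atom_features=atom_features,
        bond_features=bond_features,
        bond_distance=bond_distance,
    )


def compute_mask(graph: PairedMolecularGraph, mask_size: int) -> np.ndarray:
    """Boolean per-atom readout mask: include atoms within ``mask_size``
    bonds of the ionization center (the center itself always included)."""
    if mask_size < 0:
        raise ConfigurationError("mask_size must be non-negative")
    return graph.bond_distance <= mask_size
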