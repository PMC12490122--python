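"""A registry of 37 derived molecular descriptors.

The registry spans five categories: basic molecular properties,
drug-likeness metrics, functional-group counts via SMARTS matching,
structural-complexity measures, and class-specific markers for lipids,
carbohydrates and steroids.  Descriptors explicitly anchored in the method
description (glycerol backbone, acyl-glycerol linkage, steroid ring system,
pyranose/furanose/glycosidic markers, longest aliphatic chain, fused ring
pairs, ...) are flagged ``named``; the remainder of the functional-group and
property panel is a documented reconstruction (flagged ``reconstructed``)
and can be swapped out wholesale should an authoritative list be dropped in.

Two descriptors use custom graph algorithms rather than toolkit one-liners:

* ``longest_aliphatic_chain`` — the longest *simple path* (atom count) in
  the subgraph induced by non-aromatic carbon atoms, found by exhaustive
  depth-first search.  (A plain breadth-first traversal cannot find longest
  simple paths once that subgraph contains rings, so the search enumerates
  paths; molecules of ordinary size keep this cheap.)
* ``fused_ring_pairs`` — the number of unordered pairs of SSSR rings
  sharing at least one atom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, rdMolDescriptors, Descriptors

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "DescriptorInfo",
    "DESCRIPTOR_REGISTRY",
    "DESCRIPTOR_NAMES",
    "compute_descriptors",
    "longest_aliphatic_chain",
    "fused_ring_pairs",
    "GLYCEROL_BACKBONE_SMARTS",
]

GLYCEROL_BACKBONE_SMARTS = "[OX2][CX4H2][CX4H]([OX2])[CX4H2][OX2]"

_SMARTS_COUNTS = {
    # functional groups (pattern, provenance)
    "ester_count": ("[CX3](=[OX1])[OX2][#6]", "named"),
    "amide_count": ("[CX3](=[OX1])[NX3]", "named"),
    "carboxylic_acid_count": ("[CX3](=[OX1])[OX2H1]", "named"),
    "hydroxyl_count": ("[OX2H]", "named"),
    "phenol_count": ("[OX2H][c]", "reconstructed"),
    "ether_count": ("[OD2]([#6])[#6]", "named"),
    "amine_count": ("[NX3;H2,H1,H0;!$(NC=O);!$(N=O);!$(N[O-])]", "named"),
    "nitro_count": ("[$([NX3](=O)=O),$([NX3+](=O)[O-])]", "named"),
    "nitrile_count": ("[NX1]#[CX2]", "reconstructed"),
    "aldehyde_count": ("[CX3H1](=[OX1])[#6]", "reconstructed"),
    "ketone_count": ("[CX3](=[OX1])([#6])[#6]", "reconstructed"),
    "thiol_count": ("[SX2H]", "reconstructed"),
    "halogen_count": ("[F,Cl,Br,I]", "named"),
    "phosphate_count": ("[PX4](=[OX1])", "named"),
    "sulfur_atom_count": ("[#16]", "named"),
    # class-specific markers
    "glycerol_backbone_count": (GLYCEROL_BACKBONE_SMARTS, "named"),
    "pyranose_ring_count": ("[OX2;R]1[CX4;R][CX4;R][CX4;R][CX4;R][CX4;R]1", "named"),
    "furanose_ring_count": ("[OX2;R]1[CX4;R][CX4;R][CX4;R][CX4;R]1", "named"),
    "glycosidic_bond_count": ("[CX4;R;$(C[OX2;R])][OX2;!R][CX4]", "named"),
}

_ACYL_GLYCEROL_SMARTS = "[CX3](=[OX1])[OX2][CX4H2][CX4H]([OX2])[CX4H2][OX2]"


def _smarts_counter(smarts: str) -> Callable[[Chem.Mol], int]:
    pattern = Chem.MolFromSmarts(smarts)
    if pattern is None:  # registry bug, fail loudly at import
        raise ValueError(f"bad SMARTS in descriptor registry: {smarts!r}")
    return lambda mol: len(mol.GetSubstructMatches(pattern))


def longest_aliphatic_chain(mol: Chem.Mol) -> int:
    """Atom count of the longest simple path over non-aromatic carbons."""
    eligible = {
        a.GetIdx() for a in mol.GetAtoms()
        if a.GetAtomicNum() == 6 and not a.GetIsAromatic()
    }
    if not eligible:
        return 0
    adjacency: dict[int, list[int]] = {i: [] for i in eligible}
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if a in eligible and b in eligible:
            adjacency[a].append(b)
            adjacency[b].append(a)

    best = 1

    def extend(node: int, visited: set[int], length: int) -> None:
        nonlocal best
        best = max(best, length)
        for nxt in adjacency[node]:
            if nxt not in visited:
                visited.add(nxt)
                extend(nxt, visited, length + 1)
                visited.remove(nxt)

    for start in eligible:
        extend(start, {start}, 1)
    return best


def fused_ring_pairs(mol: Chem.Mol) -> int:
    """Unordered SSSR ring pairs sharing at least one atom."""
    rings = [set(r) for r in mol.GetRingInfo().AtomRings()]
    return sum(
        1
        for i in range(len(rings))
        for j in range(i + 1, len(rings))
        if rings[i] & rings[j]
    )


_ACYL_PATTERN = Chem.MolFromSmarts(_ACYL_GLYCEROL_SMARTS)


def _acyl_glycerol_linkages(mol: Chem.Mol) -> int:
    """Glycerol backbone oxygens esterified to a carbonyl carbon."""
    return len(mol.GetSubstructMatches(_ACYL_PATTERN))


def _steroid_flag(mol: Chem.Mol) -> int:
    """1 if the molecule carries a steroid-like fused four-ring system:
    a connected component of the ring-fusion graph with >= 4 rings, at
    least three 6-membered and at least one 5-membered."""
    rings = [set(r) for r in mol.GetRingInfo().AtomRings()]
    if len(rings) < 4:
        return 0
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(rings)))
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            if rings[i] & rings[j]:
                g.add_edge(i, j)
    for component in nx.connected_components(g):
        if len(component) < 4:
            continue
        sizes = sorted(len(rings[i]) for i in component)
        if sizes.count(6) >= 3 and sizes.count(5) >= 1:
            return 1
    return 0


def _chiral_centers(mol: Chem.Mol) -> int:
    return len(
        Chem.FindMolChiralCenters(
            mol, includeUnassigned=True, useLegacyImplementation=False
        )
    )


@dataclass(frozen=True)
class DescriptorInfo:
    name: str
    category: str
    provenance: str  # "named" | "reconstructed"
    fn: Callable[[Chem.Mol], float]


def _build_registry() -> dict[str, DescriptorInfo]:
    entries: list[DescriptorInfo] = []

    def add(name, category, provenance, fn):
        entries.append(DescriptorInfo(name, category, provenance, fn))

    # (1) basic molecular properties
    add("molecular_weight", "basic", "named", Descriptors.MolWt)
    add("heavy_atom_count", "basic", "reconstructed", lambda m: m.GetNumHeavyAtoms())
    add("ring_count", "basic", "named", rdMolDescriptors.CalcNumRings)
    add("aromatic_ring_count", "basic", "named", rdMolDescriptors.CalcNumAromaticRings)
    add("rotatable_bond_count", "basic", "reconstructed",
        rdMolDescriptors.CalcNumRotatableBonds)
    # (2) drug-likeness metrics
    add("h_bond_donor_count", "drug_likeness", "named", rdMolDescriptors.CalcNumHBD)
    add("h_bond_acceptor_count", "drug_likeness", "named", rdMolDescriptors.CalcNumHBA)
    add("tpsa", "drug_likeness", "named", rdMolDescriptors.CalcTPSA)
    add("logp", "drug_likeness", "reconstructed", Crippen.MolLogP)
    # (3) functional-group counts (SMARTS)
    for name, (smarts, provenance) in _SMARTS_COUNTS.items():
        if name in ("glycerol_backbone_count", "pyranose_ring_count",
                    "furanose_ring_count", "glycosidic_bond_count"):
            continue
        add(name, "functional_groups", provenance, _smarts_counter(smarts))
    add("net_formal_charge", "functional_groups", "named", Chem.GetFormalCharge)
    # (4) structural complexity
    add("chiral_center_count", "complexity", "named", _chiral_centers)
    add("bridgehead_atom_count", "complexity", "named",
        rdMolDescriptors.CalcNumBridgeheadAtoms)
    add("spiro_atom_count", "complexity", "reconstructed",
        rdMolDescriptors.CalcNumSpiroAtoms)
    add("fused_ring_pairs", "complexity", "named", fused_ring_pairs)
    add("longest_aliphatic_chain", "complexity", "named", longest_aliphatic_chain)
    add("fraction_csp3", "complexity", "reconstructed",
        rdMolDescriptors.CalcFractionCSP3)
    # (5) class-specific markers (lipids, carbohydrates, steroids)
    for name in ("glycerol_backbone_count", "pyranose_ring_count",
                 "furanose_ring_count", "glycosidic_bond_count"):
        smarts, provenance = _SMARTS_COUNTS[name]
        add(name, "class_markers", provenance, _smarts_counter(smarts))
    add("acyl_glycerol_linkage_count", "class_markers", "named",
        _acyl_glycerol_linkages)
    add("steroid_ring_system_flag", "class_markers", "named", _steroid_flag)

    registry = {info.name: info for info in entries}
    assert len(registry) == 37, f"descriptor registry has {len(registry)} entries"
    return registry


DESCRIPTOR_REGISTRY: Mapping[str, DescriptorInfo] = _build_registry()
DESCRIPTOR_NAMES: tuple[str, ...] = tuple(DESCRIPTOR_REGISTRY)


def compute_descriptors(smiles: str) -> dict[str, float]:
    """Compute all 37 descriptors for one SMILES string.

    Raises ``ValueError`` on an unparseable SMILES; callers building class
    profiles should exclude such structures and log the failure.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return {name: float(info.fn(mol)) for name, info in DESCRIPTOR_REGISTRY.items()}
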