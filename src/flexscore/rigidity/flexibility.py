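"""Per-residue flexibility index from a rigidity decomposition.

Signed per-bond convention: positive in under-constrained (flexible)
regions — floppy modes shared over the region's rotatable bonds — negative
in over-constrained regions — redundant constraints shared over the
region's bars — and zero at isostatic rigidity.  Per-residue values average
the residue's backbone bonds (N-CA, CA-C, C-N'), and the profile is mapped
onto the RCI scale by an affine rescale of the positive part so the two
routes are directly comparable.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, List, Optional, Set, Tuple

from ..types import FlexibilityProfile
from .network import Bar, BodyKey, BondNetwork, backbone_bonds
from .pebble import PebbleGame, RigidityDecomposition, pebble_game

#: default affine map raw index -> RCI units: x -> a*max(x, 0) + b.
#: b aligns the rigid limit with the RCI of ideal helical residues
#: (1 / (sum of weighted canonical helix secondary shifts) ~ 0.19 ppm^-1);
#: a carries a fully flexible bond to the RCI cap (0.6 ppm^-1).
RESCALE_A = 0.41
RESCALE_B = 0.19


class _SubNet:
    def __init__(self, bodies, bars):
        self.bodies = bodies
        self.bars = bars


def _flexible_regions(net: BondNetwork, dec: RigidityDecomposition
                      ) -> List[Tuple[Set[BodyKey], int, int]]:
    """Contract rigid clusters; connected components of the contracted bar
    graph that span more than one cluster are the flexible regions.

    Returns (bodies, floppy_modes, n_rotatable_bonds) per region.
    """
    cluster_of = dec.body_cluster
    # union-find over cluster ids via inter-cluster bars
    parent: Dict[int, int] = {}

    def find(x: int) -> int:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent.setdefault(parent[x], parent[x])
            x = parent[x]
        return x

    inter_bars: List[Bar] = []
    for bar in net.bars:
        ca, cb = cluster_of[bar.a], cluster_of[bar.b]
        if ca != cb:
            ra, rb = find(ca), find(cb)
            if ra != rb:
                parent[ra] = rb
            inter_bars.append(bar)
    if not inter_bars:
        return []
    # group clusters by root
    groups: Dict[int, Set[int]] = {}
    for bar in inter_bars:
        root = find(cluster_of[bar.a])
        groups.setdefault(root, set()).update(
            (cluster_of[bar.a], cluster_of[bar.b]))
    regions = []
    for root, clusters in groups.items():
        bodies = {b for b, c in cluster_of.items() if c in clusters}
        sub_bars = [b for b in net.bars if b.a in bodies and b.b in bodies]
        floppy = pebble_game(_SubNet(sorted(bodies), sub_bars)).internal_floppy_modes
        rot = len({(min(b.a, b.b), max(b.a, b.b)) for b in sub_bars
                   if b.kind == "covalent_single"
                   and cluster_of[b.a] != cluster_of[b.b]})
        regions.append((bodies, floppy, rot))
    return regions


def bond_indices(net: BondNetwork, dec: RigidityDecomposition
                 ) -> Dict[Tuple[BodyKey, BodyKey], float]:
    """Signed flexibility index per covalent bond (keyed by sorted body
    pair)."""
    regions = _flexible_regions(net, dec)
    region_of: Dict[BodyKey, Tuple[float]] = {}
    for bodies, floppy, rot in regions:
        idx = floppy / rot if rot > 0 else 0.0
        for b in bodies:
            region_of[b] = (idx,)
    # over-constrained: per region, -redundant / bars-in-region
    over_val: Dict[FrozenSet[BodyKey], float] = {}
    over_of: Dict[BodyKey, FrozenSet[BodyKey]] = {}
    for bodies, n_red in dec.redundant_regions:
        n_bars = sum(b.multiplicity for b in net.bars
                     if b.a in bodies and b.b in bodies)
        over_val[bodies] = -n_red / n_bars if n_bars else 0.0
        for b in bodies:
            over_of[b] = bodies
    out: Dict[Tuple[BodyKey, BodyKey], float] = {}
    for bar in net.covalent_bonds():
        key = (min(bar.a, bar.b), max(bar.a, bar.b))
        if (bar.kind == "covalent_single"
                and not dec.same_cluster(bar.a, bar.b)):
            out[key] = region_of.get(bar.a, (0.0,))[0]
        elif (bar.a in over_of and over_of.get(bar.b) is over_of[bar.a]):
            out[key] = over_val[over_of[bar.a]]
        else:
            out[key] = 0.0
    return out


CAP_RESIDUES = {"ACE", "NME", "NH2", "FOR"}


def residue_indices(net: BondNetwork, dec: RigidityDecomposition
                    ) -> Dict[int, float]:
    """Raw signed index per residue: mean over that residue's backbone
    bonds.  Residues without backbone bonds, and capping groups, are
    undefined (absent)."""
    bonds = backbone_bonds(net)
    if not bonds:
        return {}
    cap_res = {(a.chain_id, a.res_seq) for a in net.atoms.values()
               if a.res_name in CAP_RESIDUES}
    values = bond_indices(net, dec)
    acc: Dict[int, List[float]] = {}
    for a, b, res in bonds:
        chain = a[0]
        if (chain, res) in cap_res:
            continue
        key = (min(a, b), max(a, b))
        acc.setdefault(res, []).append(values.get(key, 0.0))
    return {res: sum(v) / len(v) for res, v in sorted(acc.items())}


def flexibility_index(net: BondNetwork, dec: RigidityDecomposition,
                      rescale_a: float = RESCALE_A,
                      rescale_b: float = RESCALE_B) -> FlexibilityProfile:
    """Per-residue profile rescaled to RCI units: a*max(x, 0) + b, so a
    fully flexible bond maps to the RCI cap and rigid bonds to ~0."""
    raw = residue_indices(net, dec)
    return FlexibilityProfile(
        {r: rescale_a * max(v, 0.0) + rescale_b for r, v in raw.items()})


def structure_profile(model, energy_cutoff: float = -1.0,
                      include_ligands: bool = False,
                      include_tethers: bool = True,
                      rescale_a: float = RESCALE_A,
                      rescale_b: float = RESCALE_B) -> FlexibilityProfile:
    """Convenience route: atoms -> network -> pebble game -> rescaled
    profile."""
    from .network import build_network
    net = build_network(model, energy_cutoff=energy_cutoff,
                        include_ligands=include_ligands,
                        include_tethers=include_tethers)
    dec = pebble_game(net)
    return flexibility_index(net, dec, rescale_a, rescale_b)
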