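"""Build the molecular body-bar constraint network.

Mapping (the standard FIRST-style molecular convention):

* every non-hydrogen atom is a 6-DOF body; hydrogens are merged into the
  heavy atom they ride on,
* a single covalent bond contributes 5 bars (one dihedral freedom left),
* peptide / double / terminal bonds are locked with 6 bars,
* a hydrogen bond (donor-H...acceptor, Mayo-style energy below the cutoff)
  contributes 5 bars,
* a hydrophobic tether (C/S pair of different residues within van der Waals
  contact + 0.25 A) contributes 2 bars.

Bonds to a heavy atom with no other covalent neighbour are locked because
spinning a lone atom about its own bond axis is not a physical internal
motion (with atoms as bodies it would otherwise appear as a floppy mode).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

from ..types import Atom, Model

logger = logging.getLogger(__name__)

BodyKey = Tuple[str, int, str]  # (chain_id, res_seq, atom_name)

COVALENT_CUTOFF = 1.9       # A, heavy-heavy
H_ATTACH_CUTOFF = 1.3       # A, X-H
VDW_RADII = {"C": 1.7, "S": 1.8}
TETHER_SLACK = 0.25         # A beyond vdW contact
HBOND_V0 = 8.0              # kcal/mol
HBOND_D0 = 2.8              # A, donor-acceptor equilibrium distance
HBOND_SCREEN = 4.5          # A, distance screen before energy evaluation
DEFAULT_ENERGY_CUTOFF = -1.0  # kcal/mol; bonds weaker than ~kT cannot act
# as constraints, and -1.0 is the common choice in rigidity-dilution work


@dataclass
class HbondGeometry:
    """Geometry entering the hydrogen-bond energy.

    d      donor-acceptor heavy-atom distance (A)
    theta  donor-H-acceptor angle (deg; 180 = linear)
    phi    H-acceptor-antecedent angle (deg), or None when the acceptor has
           no heavy neighbour
    acceptor_sp2  carbonyl-like acceptor (ideal phi 120 deg) vs sp3 (109.5)
    """

    d: float
    theta: float
    phi: Optional[float] = None
    acceptor_sp2: bool = True

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("donor-acceptor distance must be positive")
        for ang in (self.theta, self.phi):
            if ang is not None and not (0.0 <= ang <= 180.0):
                raise ValueError("angles must lie in [0, 180] degrees")


def hbond_energy(geom: HbondGeometry) -> float:
    """Mayo-style 12-10 hydrogen-bond energy, kcal/mol.

    E = V0 [5 (d0/d)^12 - 6 (d0/d)^10] F(angles); F in [0, 1].  The angular
    factor is cos^2(theta) * cos^2(phi - phi0) with the theta gate at 90 deg
    (theta < 90 -> +inf, i.e. no bond) and phi0 = 120 deg (sp2) or 109.5 deg
    (sp3); deviations beyond 90 deg zero the bond.
    """
    if geom.theta < 90.0:
        return math.inf
    ratio = HBOND_D0 / geom.d
    radial = HBOND_V0 * (5.0 * ratio ** 12 - 6.0 * ratio ** 10)
    f = math.cos(math.radians(180.0 - geom.theta)) ** 2
    if geom.phi is not None:
        phi0 = 120.0 if geom.acceptor_sp2 else 109.5
        dev = abs(geom.phi - phi0)
        f *= 0.0 if dev >= 90.0 else math.cos(math.radians(dev)) ** 2
    return radial * f


@dataclass
class Bar:
    a: BodyKey
    b: BodyKey
    multiplicity: int
    kind: str  # covalent_single | covalent_locked | hbond | tether
    energy: Optional[float] = None  # kcal/mol, hbond only

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("self-bars are not allowed")
        if self.multiplicity not in (2, 5, 6):
            raise ValueError(f"invalid bar multiplicity {self.multiplicity}")


class BondNetwork:
    """Bodies (heavy atoms) plus bars; duplicate (a, b, kind) pairs are
    rejected."""

    def __init__(self, bodies: Sequence[BodyKey], bars: Sequence[Bar],
                 atoms: Optional[Dict[BodyKey, Atom]] = None):
        self.bodies: List[BodyKey] = list(bodies)
        self.bars: List[Bar] = []
        self.atoms: Dict[BodyKey, Atom] = dict(atoms or {})
        seen: Set[Tuple[BodyKey, BodyKey, str]] = set()
        body_set = set(self.bodies)
        for bar in bars:
            if bar.a not in body_set or bar.b not in body_set:
                raise ValueError(f"bar references unknown body: {bar}")
            key = (min(bar.a, bar.b), max(bar.a, bar.b), bar.kind)
            if key in seen:
                raise ValueError(f"duplicate bar {key}")
            seen.add(key)
            self.bars.append(bar)

    def bars_of_kind(self, kind: str) -> List[Bar]:
        return [b for b in self.bars if b.kind == kind]

    def without_kind(self, kind: str) -> "BondNetwork":
        return BondNetwork(self.bodies,
                           [b for b in self.bars if b.kind != kind],
                           self.atoms)

    def covalent_bonds(self) -> List[Bar]:
        return [b for b in self.bars if b.kind.startswith("covalent")]

    def dump(self, path) -> None:
        """Tab-separated bar list for debugging."""
        import pandas as pd
        rows = [{
            "body_a": "/".join(map(str, b.a)), "body_b": "/".join(map(str, b.b)),
            "kind": b.kind, "multiplicity": b.multiplicity,
            "energy": "" if b.energy is None else f"{b.energy:.3f}",
        } for b in self.bars]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _bond_graph_distances(adj: Dict[BodyKey, Set[BodyKey]], start: BodyKey,
                          max_depth: int) -> Dict[BodyKey, int]:
    dist = {start: 0}
    frontier = [start]
    for depth in range(1, max_depth + 1):
        nxt = []
        for node in frontier:
            for nb in adj.get(node, ()):
                if nb not in dist:
                    dist[nb] = depth
                    nxt.append(nb)
        frontier = nxt
    return dist


def build_network(model: Model,
                  energy_cutoff: float = DEFAULT_ENERGY_CUTOFF,
                  include_ligands: bool = False,
                  include_tethers: bool = True) -> BondNetwork:
    """Construct the body-bar network for one model.

    Covalent bonds are detected by distance (heavy-heavy <= 1.9 A) which
    reproduces the residue templates for standard residues and degrades
    gracefully for non-standard ones.  Amide hydrogens must already be
    present for hydrogen-bond detection (see
    :func:`flexscore.structio.place_backbone_amide_hydrogens`).
    """
    heavy: List[Atom] = []
    hydrogens: List[Atom] = []
    for a in model:
        if a.hetero and not include_ligands:
            continue
        (hydrogens if a.is_hydrogen else heavy).append(a)
    if not heavy:
        raise ValueError("model contains no heavy atoms to analyse")

    keys: List[BodyKey] = [(a.chain_id, a.res_seq, a.name) for a in heavy]
    atoms: Dict[BodyKey, Atom] = dict(zip(keys, heavy))
    coords = np.array([a.coords for a in heavy])
    tree = cKDTree(coords)

    # hydrogens ride on their nearest heavy atom
    h_of: Dict[BodyKey, List[Atom]] = {}
    for h in hydrogens:
        d, i = tree.query(h.coords)
        if d > H_ATTACH_CUTOFF:
            logger.warning("hydrogen %s/%d too far from any heavy atom; dropped",
                           h.name, h.res_seq)
            continue
        h_of.setdefault(keys[i], []).append(h)

    # covalent bonds by distance
    adj: Dict[BodyKey, Set[BodyKey]] = {k: set() for k in keys}
    cov_pairs: List[Tuple[BodyKey, BodyKey]] = []
    for i, j in tree.query_pairs(COVALENT_CUTOFF):
        ka, kb = keys[i], keys[j]
        adj[ka].add(kb)
        adj[kb].add(ka)
        cov_pairs.append((ka, kb))

    bars: List[Bar] = []
    for ka, kb in cov_pairs:
        aa, ab = atoms[ka], atoms[kb]
        locked = False
        # peptide bond (omega locked by conjugation)
        names = {aa.name, ab.name}
        if names == {"C", "N"} and aa.res_seq != ab.res_seq:
            locked = True
        # carbonyl / any double-ish C-O
        if names in ({"C", "O"}, {"C", "OXT"}) and aa.res_seq == ab.res_seq:
            locked = True
        # terminal-atom rule: a lone atom cannot spin about its own bond
        if len(adj[ka]) == 1 or len(adj[kb]) == 1:
            locked = True
        bars.append(Bar(ka, kb, 6 if locked else 5,
                        "covalent_locked" if locked else "covalent_single"))

    # hydrogen bonds
    donors = [k for k in keys
              if atoms[k].element.upper() in ("N", "O", "S") and k in h_of]
    acceptors = [k for k in keys if atoms[k].element.upper() in ("O", "S")]
    acc_coords = np.array([atoms[k].coords for k in acceptors]) if acceptors else None
    if acc_coords is not None and donors:
        acc_tree = cKDTree(acc_coords)
        seen_hb: Set[Tuple[BodyKey, BodyKey]] = set()
        for dk in donors:
            datom = atoms[dk]
            near = _bond_graph_distances(adj, dk, 3)
            for ai in acc_tree.query_ball_point(datom.coords, HBOND_SCREEN):
                ak = acceptors[ai]
                if ak == dk or near.get(ak, 99) <= 3:
                    continue
                pair = (min(dk, ak), max(dk, ak))
                if pair in seen_hb:
                    continue
                aatom = atoms[ak]
                d = float(np.linalg.norm(datom.coords - aatom.coords))
                best = math.inf
                for h in h_of[dk]:
                    theta = _angle(datom.coords, h.coords, aatom.coords)
                    antecedents = list(adj[ak])
                    phi = (_angle(h.coords, aatom.coords,
                                  atoms[antecedents[0]].coords)
                           if antecedents else None)
                    sp2 = aatom.element.upper() == "O"
                    try:
                        e = hbond_energy(HbondGeometry(d, theta, phi, sp2))
                    except ValueError:
                        continue
                    best = min(best, e)
                if best <= energy_cutoff:
                    seen_hb.add(pair)
                    bars.append(Bar(dk, ak, 5, "hbond", energy=best))

    # hydrophobic tethers
    if include_tethers:
        hydroph = [k for k in keys if atoms[k].element.upper() in ("C", "S")]
        if hydroph:
            hcoords = np.array([atoms[k].coords for k in hydroph])
            htree = cKDTree(hcoords)
            max_cut = 2 * VDW_RADII["S"] + TETHER_SLACK
            seen_t: Set[Tuple[BodyKey, BodyKey]] = set()
            for i, j in htree.query_pairs(max_cut):
                ka, kb = hydroph[i], hydroph[j]
                aa, ab = atoms[ka], atoms[kb]
                if (aa.chain_id, aa.res_seq) == (ab.chain_id, ab.res_seq):
                    continue
                cut = (VDW_RADII[aa.element.upper()]
                       + VDW_RADII[ab.element.upper()] + TETHER_SLACK)
                if np.linalg.norm(aa.coords - ab.coords) > cut:
                    continue
                if _bond_graph_distances(adj, ka, 3).get(kb, 99) <= 3:
                    continue
                pair = (min(ka, kb), max(ka, kb))
                if pair in seen_t:
                    continue
                seen_t.add(pair)
                bars.append(Bar(ka, kb, 2, "tether"))

    net = BondNetwork(keys, bars, atoms)
    net.hydrogens = h_of  # type: ignore[attr-defined]
    return net


def backbone_bonds(net: BondNetwork) -> List[Tuple[BodyKey, BodyKey, int]]:
    """Covalent backbone bonds (N-CA, CA-C same residue; C-N' to the next)
    with the residue each is attributed to."""
    out = []
    for bar in net.covalent_bonds():
        (ca, ra, na), (cb, rb, nb) = bar.a, bar.b
        names = (na, nb)
        if ra == rb and set(names) in ({"N", "CA"}, {"CA", "C"}):
            out.append((bar.a, bar.b, ra))
        elif {na, nb} == {"C", "N"} and ra != rb:
            res = ra if na == "C" else rb
            out.append((bar.a, bar.b, res))
    return out
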