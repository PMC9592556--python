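"""The body-bar pebble game.

Each body (here: one non-hydrogen atom) carries 6 pebbles, one per rigid-body
degree of freedom.  Bars are inserted one at a time; a bar is *independent*
(consumes one pebble) iff 7 pebbles can be gathered on its two endpoints —
the combinatorial expression of (6,6)-sparsity, which characterises generic
body-bar rigidity.  Redundant bars identify over-constrained regions; after
all bars are placed, free pebbles in excess of the 6 trivial motions per
connected component are the internal floppy modes, and mutual-rigidity
queries (can a 7th pebble still be gathered on a pair?) yield the
rigid-cluster decomposition.

The outcome (floppy-mode count, cluster partition, per-region redundancy
totals) is independent of bar insertion order; only the internal pebble
orientations differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Hashable, Iterable, List, Optional, Set, Tuple

Body = Hashable

K = 6  # pebbles per body == rigid-body DOF in 3-D


class _UnionFind:
    def __init__(self) -> None:
        self.parent: Dict[Body, Body] = {}

    def find(self, x: Body) -> Body:
        p = self.parent.setdefault(x, x)
        while p != x:
            self.parent[x] = p = self.parent.setdefault(p, p)
            x, p = p, self.parent[p]
        return x

    def union(self, a: Body, b: Body) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


class PebbleGame:
    """Incremental (6,6) pebble game over a set of bodies."""

    def __init__(self, bodies: Iterable[Body]):
        self.bodies: List[Body] = list(bodies)
        if not self.bodies:
            raise ValueError("network must contain at least one body")
        self.pebbles: Dict[Body, int] = {b: K for b in self.bodies}
        # directed multigraph of consumed (independent) bars
        self.out: Dict[Body, Dict[Body, int]] = {b: {} for b in self.bodies}
        self.components = _UnionFind()
        for b in self.bodies:
            self.components.find(b)
        self.n_independent = 0
        self.n_redundant = 0

    # -- pebble searches -----------------------------------------------------

    def _find_pebble(self, root: Body, forbidden_donors: Set[Body]
                     ) -> Tuple[Optional[List[Body]], Set[Body]]:
        """Depth-first search for a free pebble reachable from ``root`` along
        edge directions.  Bodies in ``forbidden_donors`` may be traversed but
        never donate.  Returns (path root..donor, visited) or (None, visited)
        when the search is exhausted."""
        visited = {root}
        stack: List[Tuple[Body, List[Body]]] = [(root, [root])]
        while stack:
            node, path = stack.pop()
            for nxt, cnt in self.out[node].items():
                if cnt <= 0 or nxt in visited:
                    continue
                if self.pebbles[nxt] > 0 and nxt not in forbidden_donors:
                    return path + [nxt], visited
                visited.add(nxt)
                stack.append((nxt, path + [nxt]))
        return None, visited

    def _take_pebble(self, path: List[Body]) -> None:
        """Move one pebble from the end of ``path`` to its start, reversing
        the traversed edges."""
        donor = path[-1]
        self.pebbles[donor] -= 1
        self.pebbles[path[0]] += 1
        for a, b in zip(path, path[1:]):
            self.out[a][b] -= 1
            if self.out[a][b] == 0:
                del self.out[a][b]
            self.out[b][a] = self.out[b].get(a, 0) + 1

    def _gather_pair(self, u: Body, v: Body, target: int
                     ) -> Tuple[bool, Set[Body]]:
        """Gather free pebbles onto {u, v} until their joint count reaches
        ``target``.  Neither endpoint donates to the other; searches start
        from whichever endpoint still has room (< 6 pebbles)."""
        pair = {u, v}
        while self.pebbles[u] + self.pebbles[v] < target:
            progressed = False
            visited_all: Set[Body] = set()
            for root in (u, v):
                if self.pebbles[root] >= K:
                    continue
                path, visited = self._find_pebble(root, pair)
                visited_all |= visited
                if path is not None:
                    self._take_pebble(path)
                    progressed = True
                    break
            if not progressed:
                # exhausted: report the full sweep from both endpoints (the
                # over-constrained region for a redundant bar)
                for root in (u, v):
                    _, vv = self._find_pebble(root, pair)
                    visited_all |= vv
                return False, visited_all | pair
        return True, set()

    # -- bar insertion -------------------------------------------------------

    def insert_bar(self, u: Body, v: Body) -> Tuple[bool, Optional[Set[Body]]]:
        """Insert one bar between distinct bodies.

        Returns ``(True, None)`` if the bar is independent, else
        ``(False, region)`` where ``region`` is the over-constrained body set
        detected by the failed pebble search.
        """
        if u == v:
            raise ValueError("self-bars are not allowed")
        ok, visited = self._gather_pair(u, v, K + 1)
        if ok:
            payer = u if self.pebbles[u] > 0 else v
            other = v if payer is u else u
            self.pebbles[payer] -= 1
            self.out[payer][other] = self.out[payer].get(other, 0) + 1
            self.components.union(u, v)
            self.n_independent += 1
            return True, None
        # redundant: over-constrained region = bodies swept by the exhausted
        # searches from both endpoints
        self.n_redundant += 1
        return False, visited

    # -- queries -------------------------------------------------------------

    def mutually_rigid(self, u: Body, v: Body) -> bool:
        """True iff no relative motion remains between u and v (a further
        generic bar between them would be redundant)."""
        if u == v:
            return True
        ok, _ = self._gather_pair(u, v, K + 1)
        return not ok

    def free_pebbles(self) -> int:
        return sum(self.pebbles.values())

    def component_roots(self) -> Dict[Body, Body]:
        return {b: self.components.find(b) for b in self.bodies}

    def internal_floppy_modes(self) -> int:
        free_per: Dict[Body, int] = {}
        for b in self.bodies:
            root = self.components.find(b)
            free_per[root] = free_per.get(root, 0) + self.pebbles[b]
        return sum(f - K for f in free_per.values())


@dataclass
class RigidityDecomposition:
    """Result of playing the pebble game on a bond network."""

    body_cluster: Dict[Body, int]
    internal_floppy_modes: int
    n_independent: int
    n_redundant: int
    #: over-constrained regions: body set -> number of redundant constraints
    redundant_regions: List[Tuple[FrozenSet[Body], int]]
    free_pebbles: int
    n_bodies: int

    def same_cluster(self, u: Body, v: Body) -> bool:
        return self.body_cluster[u] == self.body_cluster[v]

    @property
    def n_clusters(self) -> int:
        return len(set(self.body_cluster.values()))


def pebble_game(net) -> RigidityDecomposition:
    """Play the (6,6) pebble game on a :class:`BondNetwork` (or any object
    with ``bodies`` and ``bars`` of (a, b, multiplicity)) and decompose it.

    Disconnected networks are handled per component.  The decomposition is
    independent of the order in which bars are supplied.
    """
    game = PebbleGame(net.bodies)
    region_uf = _UnionFind()
    redundant_count: Dict[Body, int] = {}
    for bar in net.bars:
        for _ in range(bar.multiplicity):
            ok, region = game.insert_bar(bar.a, bar.b)
            if not ok:
                assert region is not None
                bodies = list(region)
                for b in bodies[1:]:
                    region_uf.union(bodies[0], b)
                # count re-rooted in the final collapse below
                redundant_count[bodies[0]] = redundant_count.get(bodies[0], 0) + 1

    # rigid clusters: union bodies that are pairwise mutually rigid; testing
    # along bars suffices because mutual rigidity within one connected rigid
    # cluster is transitive and every cluster is bar-connected
    cluster_uf = _UnionFind()
    seen_pairs: Set[Tuple[Body, Body]] = set()
    for bar in net.bars:
        pair = (bar.a, bar.b) if repr(bar.a) <= repr(bar.b) else (bar.b, bar.a)
        if pair in seen_pairs:
            continue
        seen_pairs.add(pair)
        if cluster_uf.find(bar.a) == cluster_uf.find(bar.b):
            continue
        if game.mutually_rigid(bar.a, bar.b):
            cluster_uf.union(bar.a, bar.b)
    roots: Dict[Body, int] = {}
    body_cluster: Dict[Body, int] = {}
    for b in game.bodies:
        r = cluster_uf.find(b)
        body_cluster[b] = roots.setdefault(r, len(roots))

    # collapse redundant-region bookkeeping to final roots
    regions: Dict[Body, Tuple[Set[Body], int]] = {}
    for b, cnt in redundant_count.items():
        r = region_uf.find(b)
        bodies, total = regions.get(r, (set(), 0))
        regions[r] = (bodies, total + cnt)
    for b in region_uf.parent:
        r = region_uf.find(b)
        if r in regions:
            regions[r][0].add(b)
    redundant_regions = [(frozenset(bodies), cnt) for bodies, cnt in regions.values()]

    return RigidityDecomposition(
        body_cluster=body_cluster,
        internal_floppy_modes=game.internal_floppy_modes(),
        n_independent=game.n_independent,
        n_redundant=game.n_redundant,
        redundant_regions=redundant_regions,
        free_pebbles=game.free_pebbles(),
        n_bodies=len(game.bodies),
    )
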