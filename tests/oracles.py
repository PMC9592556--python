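"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's combinatorial code paths: rigidity is
checked by the rank of a numerically generic body-bar rigidity matrix,
correlations by closed-form rank arithmetic.
"""

from __future__ import annotations

from typing import Dict, Hashable, List, Sequence, Tuple

import numpy as np

DOF = 6


def _bar_row(n_bodies: int, ia: int, ib: int, pa: np.ndarray, pb: np.ndarray
             ) -> np.ndarray:
    """Rigidity-matrix row for one generic bar between body ia (attachment
    point pa) and body ib (point pb).

    Body motion is (v, w); the velocity of a point p on the body is
    v + w x p, and the bar constrains the relative point velocity along the
    bar direction u = pb - pa:  (v_b + w_b x pb - v_a - w_a x pa) . u = 0.
    Using (w x p) . u = w . (p x u), the row holds u and p x u blocks.
    """
    u = pb - pa
    row = np.zeros(DOF * n_bodies)
    row[DOF * ib:DOF * ib + 3] = u
    row[DOF * ib + 3:DOF * ib + 6] = np.cross(pb, u)
    row[DOF * ia:DOF * ia + 3] -= u
    row[DOF * ia + 3:DOF * ia + 6] -= np.cross(pa, u)
    return row


def rigidity_matrix(n_bodies: int,
                    bars: Sequence[Tuple[int, int, int]],
                    rng: np.random.Generator) -> np.ndarray:
    """Matrix with one row per bar (multiplicity expanded, generic random
    attachment points)."""
    centers = rng.normal(size=(n_bodies, 3)) * 10.0
    rows: List[np.ndarray] = []
    for a, b, mult in bars:
        for _ in range(mult):
            pa = centers[a] + rng.normal(size=3)
            pb = centers[b] + rng.normal(size=3)
            rows.append(_bar_row(n_bodies, a, b, pa, pb))
    if not rows:
        return np.zeros((0, DOF * n_bodies))
    return np.vstack(rows)


def matrix_rank(m: np.ndarray, tol: float = 1e-8) -> int:
    if m.size == 0:
        return 0
    s = np.linalg.svd(m, compute_uv=False)
    return int(np.sum(s > tol * max(m.shape) * (s[0] if s.size else 1.0)))


def oracle_floppy_modes(n_bodies: int, bars: Sequence[Tuple[int, int, int]],
                        seed: int = 0) -> int:
    """Internal floppy modes = sum over connected components of
    6 V_c - 6 - rank_c, evaluated via one global generic rigidity matrix."""
    rng = np.random.default_rng(seed)
    rank = matrix_rank(rigidity_matrix(n_bodies, bars, rng))
    # connected components of the bar graph
    parent = list(range(n_bodies))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, _ in bars:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    n_comp = len({find(i) for i in range(n_bodies)})
    return DOF * n_bodies - DOF * n_comp - rank


def oracle_rigid_pairs(n_bodies: int, bars: Sequence[Tuple[int, int, int]],
                       seed: int = 0) -> Dict[Tuple[int, int], bool]:
    """For every body pair: is all relative motion blocked?  Checked by
    whether adding 6 generic bars between the pair leaves the rank
    unchanged."""
    rng = np.random.default_rng(seed)
    base = rigidity_matrix(n_bodies, bars, rng)
    base_rank = matrix_rank(base)
    out: Dict[Tuple[int, int], bool] = {}
    for i in range(n_bodies):
        for j in range(i + 1, n_bodies):
            extra = rigidity_matrix(n_bodies, [(i, j, 6)], rng)
            rank2 = matrix_rank(np.vstack([base, extra]) if base.size else extra)
            out[(i, j)] = rank2 == base_rank
    return out


# ---------------------------------------------------------------------------
# correlation oracles
# ---------------------------------------------------------------------------

def average_ranks(x: Sequence[float]) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def pearson_closed_form(x: Sequence[float], y: Sequence[float]) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx, dy = x - x.mean(), y - y.mean()
    return float(np.dot(dx, dy) / np.sqrt(np.dot(dx, dx) * np.dot(dy, dy)))


def spearman_closed_form(x: Sequence[float], y: Sequence[float]) -> float:
    return pearson_closed_form(average_ranks(x), average_ranks(y))


def pearson_p_two_tailed(r: float, n: int) -> float:
    """t-transform with n-2 degrees of freedom (closed form via the
    regularised incomplete beta function)."""
    from scipy.special import betainc
    df = n - 2
    if abs(r) >= 1.0:
        return 0.0
    # p = I_{df/(df+t^2)}(df/2, 1/2) with t = r sqrt(df/(1-r^2)); the
    # argument simplifies to 1 - r^2
    return float(betainc(df / 2.0, 0.5, 1.0 - r * r))


def centile_closed_form(value: float, ref: Sequence[float], greater: bool) -> float:
    ref = list(ref)
    if greater:
        better = sum(1 for r in ref if r > value)
    else:
        better = sum(1 for r in ref if r < value)
    ties = sum(1 for r in ref if r == value)
    return 100.0 * (better + 0.5 * ties) / len(ref)
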