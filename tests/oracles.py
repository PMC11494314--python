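"""Independent brute-force oracles used to freeze expected values.

Everything here is written as plainly as possible — double loops over
pairs, direct evaluation of the defining sums — and deliberately shares no
code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_pc_pairs(values) -> float | None:
    """Fraction of unordered distinct-element pairs with equal values."""
    vals = [v for v in values if v is not None]
    n = len(vals)
    if n < 2:
        return None
    hits = tot = 0
    for i in range(n):
        for j in range(i + 1, n):
            tot += 1
            hits += vals[i] == vals[j]
    return hits / tot


def brute_pc_conditional(groups: dict, p_y: dict) -> float:
    """rho2-weighted average of per-group brute-force pair estimates."""
    labels = sorted(groups, key=str)
    sq = np.array([p_y[y] ** 2 for y in labels])
    rho = sq / sq.sum()
    return float(
        sum(r * brute_pc_pairs(groups[y]) for r, y in zip(rho, labels))
    )


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def brute_distance_fractions(values, dist_fn) -> dict[int, float]:
    """Per-distance fractions of unordered distinct-element pairs."""
    vals = [v for v in values if v is not None]
    tally: dict[int, int] = {}
    tot = 0
    for i in range(len(vals)):
        for j in range(i + 1, len(vals)):
            d = dist_fn(vals[i], vals[j])
            tally[d] = tally.get(d, 0) + 1
            tot += 1
    return {d: n / tot for d, n in tally.items()}


# -- direct evaluation of the defining formulas on exact distributions -----


def exact_pc(p) -> float:
    return float(sum(x * x for x in p))


def exact_h2(p) -> float:
    return -math.log2(exact_pc(p))


def exact_pc_cond(conds, p_y) -> float:
    """sum_y rho2(y) pc[X|y] with rho2(y) = P(y)^2 / sum P(y)^2."""
    sq = [w * w for w in p_y]
    z = sum(sq)
    return sum((s / z) * exact_pc(c) for s, c in zip(sq, conds))


def exact_relevancy(p_bg, conds, p_group) -> float:
    return math.log2(exact_pc_cond(conds, p_group) / exact_pc(p_bg))


def exact_conditional_relevancy(bg_xy, spec_xy_list, p_group) -> float:
    """H2[X|Y] - H2[X|Pi,Y] by direct enumeration of the joint tables.

    ``bg_xy[x][y]`` is the background joint distribution; ``spec_xy_list``
    holds one joint table per epitope group.
    """
    bg = np.asarray(bg_xy, float)
    p_y = bg.sum(axis=0)
    conds, probs = [], []
    for y in range(bg.shape[1]):
        if p_y[y] > 0:
            conds.append(bg[:, y] / p_y[y])
            probs.append(p_y[y])
    pc_bg = exact_pc_cond(conds, probs)

    conds, probs = [], []
    for g, joint in enumerate(spec_xy_list):
        joint = np.asarray(joint, float)
        py_g = joint.sum(axis=0)
        for y in range(joint.shape[1]):
            if py_g[y] > 0:
                conds.append(joint[:, y] / py_g[y])
                probs.append(p_group[g] * py_g[y])
    pc_spec = exact_pc_cond(conds, probs)
    return math.log2(pc_spec / pc_bg)


def exact_interaction(bg_xy, spec_xy_list, p_group) -> float:
    """I2([X,Y],Pi) - I2(X,Pi) - I2(Y,Pi) by direct enumeration."""
    bg = np.asarray(bg_xy, float)
    specs = [np.asarray(s, float) for s in spec_xy_list]
    i_joint = exact_relevancy(bg.ravel(), [s.ravel() for s in specs], p_group)
    i_x = exact_relevancy(bg.sum(axis=1), [s.sum(axis=1) for s in specs], p_group)
    i_y = exact_relevancy(bg.sum(axis=0), [s.sum(axis=0) for s in specs], p_group)
    return i_joint - i_x - i_y


def random_joint(rng, nx: int, ny: int) -> np.ndarray:
    return rng.dirichlet(np.ones(nx * ny)).reshape(nx, ny)
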