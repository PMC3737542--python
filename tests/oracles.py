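"""Independent brute-force oracles used by the test suite.

These deliberately share nothing with the package's dynamic programs except
the bundled parameter table: duplex energies come from exhaustive
enumeration of monotone pairings, ensemble quantities from exhaustive
enumeration of secondary structures, and seed classes from a literal
positional truth table.
"""

from __future__ import annotations

import math

import numpy as np

from mirsite.params import CANONICAL_PAIRS, encode


def _pairable(x, y):
    return (int(x), int(y)) in CANONICAL_PAIRS


# ---------------------------------------------------------------------------
# duplex: exhaustive enumeration of monotone intermolecular pairings


def enumerate_duplex_min(mirna: str, target: str, params) -> float | None:
    """Minimum duplex energy over every feasible monotone pairing.

    A pairing is a sequence of cells (i, j) with i strictly increasing and j
    strictly decreasing, every cell complementary (WC or GU), and gaps
    between consecutive cells of at most ``max_loop`` on each side.  Energy
    is initiation + stacks (adjacent cells) + linear loop penalties.
    Returns None when no pairing with negative energy exists.
    """
    mir = encode(mirna)
    tgt = encode(target)
    m, t = len(mir), len(tgt)
    cap = params.max_loop
    cells = [
        (i, j) for i in range(m) for j in range(t) if _pairable(mir[i], tgt[j])
    ]
    best = [math.inf]

    def step_cost(pi, pj, i, j):
        ga, gb = i - pi - 1, pj - j - 1
        if ga == 0 and gb == 0:
            return params.stack[4 * mir[pi] + tgt[pj], 4 * mir[i] + tgt[j]]
        if ga == 0 or gb == 0:
            return params.bulge_per_nt * (ga + gb)
        return params.internal_per_nt * (ga + gb)

    def extend(pi, pj, energy):
        if energy < best[0]:
            best[0] = energy
        for i, j in cells:
            if i <= pi or j >= pj:
                continue
            if i - pi - 1 > cap or pj - j - 1 > cap:
                continue
            extend(i, j, energy + step_cost(pi, pj, i, j))

    for i, j in cells:
        extend(i, j, params.duplex_init)
    return None if best[0] >= 0 else best[0]


# ---------------------------------------------------------------------------
# folding: exhaustive enumeration of secondary structures


def enumerate_structures(codes, banned=frozenset(), min_hairpin=3):
    """Yield every non-crossing WC/GU pair set (as a list of (i, j))."""

    def gen(i, j):
        if i > j:
            yield []
            return
        for rest in gen(i + 1, j):
            yield rest
        if i in banned:
            return
        for k in range(i + min_hairpin + 1, j + 1):
            if k in banned or not _pairable(codes[i], codes[k]):
                continue
            for inner in gen(i + 1, k - 1):
                for outer in gen(k + 1, j):
                    yield [(i, k)] + inner + outer

    yield from gen(0, len(codes) - 1)


def structure_energy(codes, pairs, params) -> float:
    """Per-pair surcharge plus nearest-neighbor stacks of adjacent pairs."""
    e = 0.0
    pair_set = set(pairs)
    for i, j in pairs:
        e += params.pair_penalty
        if (i + 1, j - 1) in pair_set:
            e += params.stack[
                4 * codes[i] + codes[j], 4 * codes[i + 1] + codes[j - 1]
            ]
    return e


def enumerate_ensemble(seq: str, params, banned=frozenset()):
    """(Z, e_ens, p, s) by direct summation over all structures."""
    codes = encode(seq)
    n = len(codes)
    z = 0.0
    p = np.zeros((n, n))
    for pairs in enumerate_structures(codes, banned, params.min_hairpin):
        w = math.exp(-structure_energy(codes, pairs, params) / params.rt)
        z += w
        for i, j in pairs:
            p[i, j] += w
    p /= z
    s = 1.0 - (p.sum(axis=1) + p.sum(axis=0))
    return z, -params.rt * math.log(z), p, s


# ---------------------------------------------------------------------------
# seed taxonomy: positional truth table


def seed_truth_table(pair_map: dict, mirna: str, target: str) -> str:
    """Literal restatement of the seed-class definitions.

    ``pair_map``: miRNA position (0-based) -> target position; sequences as
    plain strings.  Returns the class name.
    """

    def wc(mi):
        j = pair_map.get(mi)
        if j is None:
            return False
        a, b = mirna[mi], target[j]
        return {"A": "U", "U": "A", "C": "G", "G": "C"}[a] == b

    def contiguous(lo, hi):
        if not all(wc(mi) for mi in range(lo, hi)):
            return False
        return all(
            pair_map[mi + 1] == pair_map[mi] - 1 for mi in range(lo, hi - 1)
        )

    a1 = False
    if 1 in pair_map and 0 <= pair_map[1] + 1 < len(target):
        a1 = target[pair_map[1] + 1] == "A"
    if contiguous(1, 8):
        return "8mer" if a1 else "7mer-m8"
    if contiguous(1, 7):
        if a1 and not wc(7):
            return "7mer-A1"
        return "6mer"
    if contiguous(2, 8):
        return "offset-6mer"
    return "seedless"
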