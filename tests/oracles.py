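"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results from first principles (explicit
enumeration, Bio.Seq translation, direct path-length computation on a known
tree) and share no counting code with the package.
"""

from __future__ import annotations

import math
from itertools import permutations, product

import numpy as np
from Bio.Seq import Seq

NUCS = "ACGT"


def aa(codon: str) -> str:
    return str(Seq(codon).translate())


def is_stop(codon: str) -> bool:
    return aa(codon) == "*"


def oracle_codon_sites(codon: str) -> tuple[float, float]:
    """Enumerate all nine point mutations; stop-bound changes count nowhere."""
    s = n = 0.0
    for pos, nuc in product(range(3), NUCS):
        if nuc == codon[pos]:
            continue
        mutant = codon[:pos] + nuc + codon[pos + 1 :]
        if is_stop(mutant):
            continue
        if aa(mutant) == aa(codon):
            s += 1 / 3
        else:
            n += 1 / 3
    return s, n


def oracle_codon_diffs(a: str, b: str) -> tuple[float, float]:
    """Average syn/nonsyn steps over stop-free minimal mutational pathways."""
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    tallies = []
    for order in permutations(positions):
        cur, s, n, blocked = a, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if is_stop(nxt):
                blocked = True
                break
            if aa(nxt) == aa(cur):
                s += 1
            else:
                n += 1
            cur = nxt
        if not blocked:
            tallies.append((s, n))
    if not tallies:  # every path crosses a stop: count all paths, stops nonsyn
        for order in permutations(positions):
            cur, s, n = a, 0, 0
            for pos in order:
                nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                if not is_stop(nxt) and not is_stop(cur) and aa(nxt) == aa(cur):
                    s += 1
                else:
                    n += 1
                cur = nxt
            tallies.append((s, n))
    return (
        sum(t[0] for t in tallies) / len(tallies),
        sum(t[1] for t in tallies) / len(tallies),
    )


def oracle_kaks(codons_a, codons_b):
    """Whole-pair NG86 estimate built only from the two helpers above."""
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        sa, na = oracle_codon_sites(ca)
        sb, nb = oracle_codon_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        ds, dn = oracle_codon_diffs(ca, cb)
        Sd += ds
        Nd += dn
    ps, pn = Sd / S, Nd / N

    def jc(p):
        return None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return S, N, Sd, Nd, jc(ps), jc(pn)


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random binary tree by sequential attachment; returns (splits, dist).

    Distances are exact path lengths, so the matrix is additive by
    construction and the generating splits are the ground truth.
    """
    import itertools

    labels = [f"t{i}" for i in range(n_taxa)]
    # adjacency with branch lengths; start from a 3-star
    next_node = n_taxa
    adj: dict = {}

    def connect(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    def blen():
        return float(rng.uniform(0.05, 1.0))

    center = next_node
    next_node += 1
    for leaf in labels[:3]:
        connect(leaf, center, blen())
    for leaf in labels[3:]:
        # split a random existing edge and hang the new leaf off it
        edges = [(a, b) for a in adj for b in adj[a] if str(a) < str(b)]
        a, b = edges[rng.integers(len(edges))]
        w = adj[a].pop(b)
        adj[b].pop(a)
        mid = next_node
        next_node += 1
        u = float(rng.uniform(0.2, 0.8)) * w
        connect(a, mid, u)
        connect(b, mid, w - u)
        connect(leaf, mid, blen())

    def path_len(a, b):
        stack = [(a, 0.0, None)]
        while stack:
            node, dist, prev = stack.pop()
            if node == b:
                return dist
            for nxt, w in adj[node].items():
                if nxt != prev:
                    stack.append((nxt, dist + w, node))
        raise AssertionError("disconnected tree")

    dist = {
        (a, b): path_len(a, b) for a, b in itertools.combinations(labels, 2)
    }

    # splits: remove each internal edge, collect leaf side
    taxa = frozenset(labels)
    ref = min(taxa)
    splits = set()
    for a in list(adj):
        for b in list(adj[a]):
            if isinstance(a, str) or isinstance(b, str):
                continue
            if a >= b:
                continue
            side = set()
            stack = [(a, b)]
            while stack:
                node, prev = stack.pop()
                if isinstance(node, str):
                    side.add(node)
                    continue
                for nxt in adj[node]:
                    if nxt != prev:
                        stack.append((nxt, node))
            side = frozenset(side)
            if len(side) < 2 or len(taxa - side) < 2:
                continue
            splits.add(taxa - side if ref in side else side)
    return labels, dist, splits
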