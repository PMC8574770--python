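"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (explicit loops, exact
rational arithmetic, direct linear algebra) and deliberately shares no code
with the package implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb, log, sqrt

import numpy as np

MISSING = -1


# ---------------------------------------------------------------------------
# diversity statistics by direct summation
# ---------------------------------------------------------------------------

def diversity_oracle(dosage: np.ndarray, pop_of_ind: list[int]) -> dict[str, float]:
    """H_O, H_S, H_T and F-statistics by explicit per-locus summation.

    dosage: individuals x loci in {0,1,2,-1}; pop_of_ind: population index
    per individual. Components are averaged over loci; indices are ratios of
    the averages.
    """
    n_ind, n_loci = dosage.shape
    pops = sorted(set(pop_of_ind))
    ho_list, hs_list, ht_list = [], [], []
    for j in range(n_loci):
        per_pop = []
        for p in pops:
            members = [i for i in range(n_ind) if pop_of_ind[i] == p]
            called = [dosage[i, j] for i in members if dosage[i, j] != MISSING]
            if len(called) <= 1:
                continue
            n = len(called)
            freq = sum(called) / (2 * n)
            het = sum(1 for d in called if d == 1) / n
            per_pop.append((n, freq, het))
        if not per_pop:
            continue
        s = len(per_pop)
        n_tilde = s / sum(1 / n for n, _, _ in per_pop)
        ho = sum(het for _, _, het in per_pop) / s
        mean_sum_sq = sum(f * f + (1 - f) * (1 - f) for _, f, _ in per_pop) / s
        hs = (n_tilde / (n_tilde - 1)) * (1 - mean_sum_sq - ho / (2 * n_tilde))
        p_bar = sum(f for _, f, _ in per_pop) / s
        ht = 1 - (p_bar**2 + (1 - p_bar) ** 2) + hs / (n_tilde * s)
        ho_list.append(ho)
        hs_list.append(hs)
        ht_list.append(ht)
    ho = float(np.mean(ho_list))
    hs = float(np.mean(hs_list))
    ht = float(np.mean(ht_list))
    return {
        "H_O": ho,
        "H_S": hs,
        "H_T": ht,
        "F_IS": 1 - ho / hs,
        "F_ST": 1 - hs / ht,
        "F_IT": 1 - ho / ht,
    }


# ---------------------------------------------------------------------------
# three-level AMOVA from haplotype coordinates (complete data only)
# ---------------------------------------------------------------------------

def amova_oracle(
    haplotypes: np.ndarray, pop_of_unit: list[int], group_of_pop: dict[int, int]
) -> dict[str, float]:
    """Variance components via centroid sums of squares and an explicit
    linear solve of the expected-mean-square equations.

    haplotypes: units x loci 0/1 allele matrix (no missing data), so squared
    allele-difference distances coincide with squared Euclidean distances
    and sums of squares can be computed from centroids.
    """
    x = np.asarray(haplotypes, dtype=float)
    n_units = x.shape[0]
    pops = sorted(set(pop_of_unit))
    groups = sorted({group_of_pop[p] for p in pops})
    group_of_unit = [group_of_pop[p] for p in pop_of_unit]

    def ss_about_centroid(rows: list[int]) -> float:
        sub = x[rows]
        centroid = sub.mean(axis=0)
        return float(((sub - centroid) ** 2).sum())

    all_rows = list(range(n_units))
    ss_total = ss_about_centroid(all_rows)
    ss_wp = sum(
        ss_about_centroid([i for i in all_rows if pop_of_unit[i] == p]) for p in pops
    )
    ss_wg = sum(
        ss_about_centroid([i for i in all_rows if group_of_unit[i] == g])
        for g in groups
    )
    ss_ap = ss_wg - ss_wp
    ss_ag = ss_total - ss_wg

    P, G, N = len(pops), len(groups), n_units
    n_p = {p: sum(1 for q in pop_of_unit if q == p) for p in pops}
    N_g = {g: sum(1 for u in group_of_unit if u == g) for g in groups}
    sum_np2_over_ng = sum(
        sum(n_p[p] ** 2 for p in pops if group_of_pop[p] == g) / N_g[g] for g in groups
    )
    n1 = (N - sum_np2_over_ng) / (P - G)
    n2 = (sum_np2_over_ng - sum(v**2 for v in n_p.values()) / N) / (G - 1)
    n3 = (N - sum(v**2 for v in N_g.values()) / N) / (G - 1)

    ms = np.array([ss_ag / (G - 1), ss_ap / (P - G), ss_wp / (N - P)])
    # E[MS] = A @ (sigma_a^2, sigma_b^2, sigma_c^2)
    coeff = np.array([[n3, n2, 1.0], [0.0, n1, 1.0], [0.0, 0.0, 1.0]])
    v_a, v_b, v_c = np.linalg.solve(coeff, ms)
    total = v_a + v_b + v_c
    return {
        "ss": (ss_ag, ss_ap, ss_wp, ss_total),
        "components": (v_a, v_b, v_c),
        "percent": tuple(100 * v / total for v in (v_a, v_b, v_c)),
        "phi": (v_a / total, v_b / (v_b + v_c), (v_a + v_b) / total),
    }


# ---------------------------------------------------------------------------
# HWE by exhaustive allele-slot enumeration (exact)
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_aa: int, n_ab: int, n_bb: int) -> Fraction:
    """Two-sided exact HWE p-value by enumerating all allele placements.

    All C(2n, n_a) ways of placing the A alleles into 2n slots are counted;
    slots (2i, 2i+1) form individual i. Exact Fractions throughout, so the
    comparison with the analytic conditional distribution is equality.
    """
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    slots = 2 * n
    counts: dict[int, int] = {}
    for a_positions in combinations(range(slots), n_a):
        marks = [0] * slots
        for pos in a_positions:
            marks[pos] = 1
        het = sum(1 for i in range(n) if marks[2 * i] != marks[2 * i + 1])
        counts[het] = counts.get(het, 0) + 1
    total = comb(slots, n_a)
    pmf = {h: Fraction(c, total) for h, c in counts.items()}
    p_obs = pmf[n_ab]
    return sum(q for q in pmf.values() if q <= p_obs)


# ---------------------------------------------------------------------------
# TN93 closed form, independent derivation
# ---------------------------------------------------------------------------

def tn93_oracle(seq_x: str, seq_y: str) -> float:
    """TN93 distance recomputed from scratch for two aligned sequences."""
    pairs = [(a, b) for a, b in zip(seq_x, seq_y) if a in "ACGT" and b in "ACGT"]
    L = len(pairs)
    freq = {b: 0 for b in "ACGT"}
    for a, b in pairs:
        freq[a] += 1
        freq[b] += 1
    gA, gC, gG, gT = (freq[b] / (2 * L) for b in "ACGT")
    gR, gY = gA + gG, gC + gT
    p1 = sum(1 for a, b in pairs if {a, b} == {"A", "G"}) / L
    p2 = sum(1 for a, b in pairs if {a, b} == {"C", "T"}) / L
    q = sum(1 for a, b in pairs if a != b and ((a in "AG") != (b in "AG"))) / L
    c1 = 2 * gA * gG / gR
    c2 = 2 * gC * gT / gY
    c3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    w1 = 1 - p1 / c1 - q / (2 * gR)
    w2 = 1 - p2 / c2 - q / (2 * gY)
    w3 = 1 - q / (2 * gR * gY)
    if min(w1, w2, w3) <= 0:
        return float("inf")
    return -c1 * log(w1) - c2 * log(w2) - c3 * log(w3)


# ---------------------------------------------------------------------------
# random additive trees for NJ recovery
# ---------------------------------------------------------------------------

def random_additive_tree(
    n_leaves: int, rng: np.random.Generator
) -> tuple[np.ndarray, list[str], set[frozenset[str]]]:
    """A random binary tree with positive branch lengths.

    Returns (leaf-to-leaf path-length matrix, leaf names, non-trivial
    bipartitions as frozensets of the smaller side's leaf names).
    """
    labels = [f"L{i}" for i in range(n_leaves)]
    # start from a star over 3 leaves and attach remaining leaves to random edges
    nodes: dict[int, dict[int, float]] = {}
    next_id = [0]

    def new_node() -> int:
        nid = next_id[0]
        next_id[0] += 1
        nodes[nid] = {}
        return nid

    def connect(a: int, b: int, w: float) -> None:
        nodes[a][b] = w
        nodes[b][a] = w

    def blen() -> float:
        return float(rng.uniform(0.5, 2.0))

    leaf_ids = [new_node() for _ in range(3)]
    centre = new_node()
    for lid in leaf_ids:
        connect(lid, centre, blen())
    edges = [(lid, centre) for lid in leaf_ids]
    for _ in range(3, n_leaves):
        a, b = edges[int(rng.integers(len(edges)))]
        w = nodes[a][b]
        split = float(rng.uniform(0.25, 0.75)) * w
        mid = new_node()
        del nodes[a][b], nodes[b][a]
        connect(a, mid, split)
        connect(mid, b, w - split)
        leaf = new_node()
        leaf_ids.append(leaf)
        connect(leaf, mid, blen())
        edges.remove((a, b))
        edges += [(a, mid), (mid, b), (leaf, mid)]

    name_of = {lid: labels[k] for k, lid in enumerate(leaf_ids)}

    def path_lengths(start: int) -> dict[int, float]:
        dist = {start: 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, w in nodes[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        return dist

    D = np.zeros((n_leaves, n_leaves))
    for i, lid in enumerate(leaf_ids):
        dist = path_lengths(lid)
        for k, other in enumerate(leaf_ids):
            D[i, k] = dist[other]

    # bipartitions: removing each internal edge splits the leaves
    bipartitions: set[frozenset[str]] = set()
    leaf_set = set(leaf_ids)
    for a in nodes:
        for b in nodes[a]:
            if a < b:
                side = _leaves_on_side(nodes, a, b) & leaf_set
                if 1 < len(side) < n_leaves - 1:
                    names = frozenset(name_of[x] for x in side)
                    comp = frozenset(set(labels) - names)
                    bipartitions.add(min(names, comp, key=lambda f: sorted(f)))
    return D, labels, bipartitions


def _leaves_on_side(nodes: dict[int, dict[int, float]], a: int, b: int) -> set[int]:
    """Nodes reachable from ``a`` without crossing edge (a, b)."""
    seen = {a}
    stack = [a]
    while stack:
        u = stack.pop()
        for v in nodes[u]:
            if v not in seen and not (u == a and v == b):
                seen.add(v)
                stack.append(v)
    return seen


def newick_bipartitions(newick: str, labels: list[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree given in Newick form."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.encode_bipartitions()
    out: set[frozenset[str]] = set()
    taxa = set(labels)
    for bp in tree.bipartition_encoding:
        side = {t.label for t in tree.taxon_namespace.bitmask_taxa_list(bp.split_bitmask)}
        if 1 < len(side) < len(taxa) - 1:
            comp = frozenset(taxa - side)
            out.add(min(frozenset(side), comp, key=lambda f: sorted(f)))
    return out
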