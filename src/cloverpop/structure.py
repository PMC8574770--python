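"""Genetic distances, pairwise F_ST, neighbor-joining trees and PCoA.

Accession-level analyses run on Nei genetic distances (standard or unbiased)
computed from allele frequencies; individual-level trees use Tamura–Nei (TN93)
distances on pseudo-sequences spelled from homozygous genotypes. Trees come
from classic Saitou–Nei neighbor joining with deterministic tie-breaking, and
ordination is classical metric scaling (PCoA) of any of these matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .diversity import allele_frequencies, FrequencyTable
from .io_formats import MISSING, GenotypeMatrix, PopulationMap


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with optional per-pair p-values/flags."""

    ids: list[str]
    matrix: np.ndarray
    metric: str  # nei_standard | nei_unbiased | tamura_nei | fst
    p_values: np.ndarray | None = None
    #: pairs flagged unreliable (too few comparable sites) or infinite
    unreliable: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.matrix, self.matrix.T, equal_nan=True):
            raise ValueError("distance matrix not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


# ---------------------------------------------------------------------------
# Nei genetic distances
# ---------------------------------------------------------------------------

def nei_distance(ft: FrequencyTable, variant: str = "standard") -> DistanceMatrix:
    """Nei's genetic distance between populations from biallelic frequencies.

    standard:  D = -ln( J_xy / sqrt(J_x J_y) ) with locus-averaged gene
    identities J. unbiased: J_x and J_y are replaced per locus by the
    small-sample unbiased versions (2n J - 1)/(2n - 1). Loci with an
    undefined frequency in either population are dropped pairwise; a pair
    sharing no alleles at all gets +inf and is flagged.
    """
    if variant not in ("standard", "unbiased"):
        raise ValueError(f"unknown variant {variant!r}")
    s = len(ft.populations)
    if s < 2:
        raise ValueError("need at least two populations")
    p = ft.freq  # (s, L), NaN undefined
    n = ft.n_called.astype(float)
    jx_raw = p**2 + (1 - p) ** 2
    if variant == "unbiased":
        with np.errstate(invalid="ignore", divide="ignore"):
            jx_own = np.where(n > 0.5, (2 * n * jx_raw - 1) / (2 * n - 1), np.nan)
    else:
        jx_own = jx_raw

    D = np.zeros((s, s))
    flags = np.zeros((s, s), dtype=bool)
    for x in range(s):
        for y in range(x + 1, s):
            shared = ~np.isnan(p[x]) & ~np.isnan(p[y])
            if variant == "unbiased":
                shared &= (n[x] > 1) & (n[y] > 1)
            if not shared.any():
                D[x, y] = D[y, x] = np.nan
                flags[x, y] = flags[y, x] = True
                continue
            jxy = float(np.mean(p[x, shared] * p[y, shared]
                                + (1 - p[x, shared]) * (1 - p[y, shared])))
            jx = float(np.mean(jx_own[x, shared]))
            jy = float(np.mean(jx_own[y, shared]))
            if jxy <= 0 or jx <= 0 or jy <= 0:
                D[x, y] = D[y, x] = np.inf
                flags[x, y] = flags[y, x] = True
                continue
            d = -np.log(jxy / np.sqrt(jx * jy))
            D[x, y] = D[y, x] = d
    name = "nei_standard" if variant == "standard" else "nei_unbiased"
    return DistanceMatrix(list(ft.populations), D, name, unreliable=flags)


# ---------------------------------------------------------------------------
# pairwise F_ST with permutation significance
# ---------------------------------------------------------------------------

def _two_pop_fst(d1: np.ndarray, d2: np.ndarray) -> float:
    """F_ST = 1 - H_S/H_T for two populations of dosages, vectorised over loci.

    Uses the same bias-corrected estimators as the diversity module (ratio of
    locus-averaged components); loci need >= 2 called individuals per
    population to contribute.
    """
    stats = []
    for d in (d1, d2):
        called = d != MISSING
        nc = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(nc > 0, np.where(called, d, 0).sum(axis=0) / (2 * nc), np.nan)
            het = np.where(nc > 0, (d == 1).sum(axis=0) / nc, np.nan)
        stats.append((nc, freq, het))
    (n1, p1, h1), (n2, p2, h2) = stats
    valid = (n1 > 1) & (n2 > 1) & ~np.isnan(p1) & ~np.isnan(p2)
    if not valid.any():
        return np.nan
    n1, p1, h1 = n1[valid], p1[valid], h1[valid]
    n2, p2, h2 = n2[valid], p2[valid], h2[valid]
    n_tilde = 2.0 / (1.0 / n1 + 1.0 / n2)
    ho = (h1 + h2) / 2
    msp2 = ((p1**2 + (1 - p1) ** 2) + (p2**2 + (1 - p2) ** 2)) / 2
    hs = (n_tilde / (n_tilde - 1)) * (1 - msp2 - ho / (2 * n_tilde))
    pbar = (p1 + p2) / 2
    ht = 1 - (pbar**2 + (1 - pbar) ** 2) + hs / (2 * n_tilde)
    hs_bar, ht_bar = float(np.mean(hs)), float(np.mean(ht))
    if ht_bar <= 0:
        return np.nan
    return 1 - hs_bar / ht_bar


def pairwise_fst(
    m: GenotypeMatrix,
    pm: PopulationMap,
    n_permutations: int = 1000,
    seed: int = 0,
) -> DistanceMatrix:
    """Pairwise F_ST between accessions with permutation p-values.

    For each pair the statistic is computed on that pair only; significance
    comes from permuting individuals between the two accessions (upper tail,
    (hits+1)/(n+1)). Negative estimates are floored at zero in the reported
    matrix; the raw values are retained in ``raw`` on the result.
    """
    pm.check_covers(m)
    present = {pm.accession_of(i) for i in m.individual_ids}
    pops = [a for a in pm.accessions if a in present]
    rng = np.random.default_rng(seed)
    s = len(pops)
    raw = np.zeros((s, s))
    pvals = np.ones((s, s))
    members = {
        pop: np.array([i for i, iid in enumerate(m.individual_ids)
                       if pm.accession_of(iid) == pop])
        for pop in pops
    }
    for x in range(s):
        for y in range(x + 1, s):
            ix, iy = members[pops[x]], members[pops[y]]
            obs = _two_pop_fst(m.dosage[ix], m.dosage[iy])
            raw[x, y] = raw[y, x] = obs
            if np.isnan(obs):
                pvals[x, y] = pvals[y, x] = np.nan
                continue
            pooled = np.concatenate([ix, iy])
            hits = 0
            for _ in range(n_permutations):
                perm = rng.permutation(pooled)
                stat = _two_pop_fst(m.dosage[perm[: len(ix)]], m.dosage[perm[len(ix):]])
                if not np.isnan(stat) and stat >= obs - 1e-12:
                    hits += 1
            p = (hits + 1) / (n_permutations + 1)
            pvals[x, y] = pvals[y, x] = p
    result = DistanceMatrix(list(pops), np.maximum(raw, 0.0), "fst", p_values=pvals)
    result.raw = raw  # negative estimates preserved for inspection
    return result


def mean_pairwise_fst(d: DistanceMatrix) -> pd.DataFrame:
    """Each population's mean pairwise F_ST against all others."""
    s = len(d.ids)
    mask = ~np.eye(s, dtype=bool)
    means = [float(np.nanmean(d.matrix[k][mask[k]])) for k in range(s)]
    return pd.DataFrame({"population": d.ids, "mean_pairwise_fst": means})


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.label]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if not self.children:
            return self.label or ""
        inner = ",".join(f"{c._newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


@dataclass
class Tree:
    """Unrooted NJ tree, stored with an arbitrary root for serialisation."""

    root: TreeNode
    n_clamped_branches: int = 0

    def leaf_names(self) -> list[str]:
        return self.root.leaves()

    def to_newick(self) -> str:
        return self.root.to_newick()


def neighbor_joining(d: DistanceMatrix) -> Tree:
    """Saitou–Nei agglomeration with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lowest (row, column) pair in the
    current ordering, which makes degenerate inputs (e.g. equidistant points)
    deterministic. Negative branch lengths are clamped to zero with the
    deficit transferred to the sibling branch, so leaf-to-leaf path lengths
    through the join are preserved.
    """
    mat = d.matrix.copy()
    if not np.isfinite(mat).all():
        raise ValueError(
            "distance matrix contains non-finite entries; drop undefined pairs "
            "upstream (pairwise deletion) before tree building"
        )
    n = len(d.ids)
    if n < 3:
        raise ValueError("need at least three entities")
    nodes: list[TreeNode] = [TreeNode(label=i) for i in d.ids]
    clamped = 0

    while len(nodes) > 2:
        n_act = len(nodes)
        r = mat.sum(axis=1)
        q = (n_act - 2) * mat - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (row, col) tie-break: argmin of row-major flattened q
        flat = np.argmin(q)
        i, j = divmod(int(flat), n_act)
        if i > j:
            i, j = j, i
        li = mat[i, j] / 2 + (r[i] - r[j]) / (2 * (n_act - 2))
        lj = mat[i, j] - li
        if li < 0:
            lj += li
            li, clamped = 0.0, clamped + 1
        if lj < 0:
            li += lj
            lj, clamped = 0.0, clamped + 1
        parent = TreeNode(children=[(nodes[i], float(li)), (nodes[j], float(lj))])
        new_row = (mat[i] + mat[j] - mat[i, j]) / 2
        keep = [k for k in range(n_act) if k not in (i, j)]
        mat = np.vstack([mat[keep][:, keep], new_row[keep][None, :]])
        mat = np.hstack([mat, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # final edge: attach one remaining node under the other
    a, b = nodes
    final = mat[0, 1]
    if final < 0:
        final, clamped = 0.0, clamped + 1
    root = TreeNode(children=[(a, float(final)), (b, 0.0)])
    return Tree(root=root, n_clamped_branches=clamped)


# ---------------------------------------------------------------------------
# Tamura–Nei (TN93) distances between individuals
# ---------------------------------------------------------------------------

_PURINES = ("A", "G")
_PYRIMIDINES = ("C", "T")
_NUC_IX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _tn93_from_counts(
    pi: np.ndarray, p1: float, p2: float, q: float
) -> float:
    """Closed-form TN93 distance from base composition and change fractions.

    ``pi`` is the empirical base composition (A, C, G, T) of the compared
    sites; ``p1``/``p2`` are the purine/pyrimidine transition fractions and
    ``q`` the transversion fraction. Returns +inf on saturation.
    """
    pa, pc, pg, pt = pi
    pr, py = pa + pg, pc + pt
    k1 = 2 * pa * pg / pr if pr > 0 else 0.0
    k2 = 2 * pc * pt / py if py > 0 else 0.0
    terms = 0.0
    if k1 > 0:
        w1 = 1 - p1 / k1 - q / (2 * pr)
        if w1 <= 0:
            return np.inf
        terms -= k1 * np.log(w1)
    elif p1 > 0:
        return np.inf
    if k2 > 0:
        w2 = 1 - p2 / k2 - q / (2 * py)
        if w2 <= 0:
            return np.inf
        terms -= k2 * np.log(w2)
    elif p2 > 0:
        return np.inf
    if pr > 0 and py > 0:
        k3 = 2 * (pr * py - pa * pg * py / pr - pc * pt * pr / py)
        w3 = 1 - q / (2 * pr * py)
        if w3 <= 0:
            return np.inf
        terms -= k3 * np.log(w3)
    elif q > 0:
        return np.inf
    return float(terms)


def tamura_nei_distance(
    m: GenotypeMatrix,
    individuals: Sequence[str] | None = None,
    min_sites: int = 10,
) -> DistanceMatrix:
    """TN93 distances between individuals' SNP pseudo-sequences.

    Each individual is spelled as a sequence over the loci: homozygous
    reference -> reference base, homozygous alternative -> alternative base;
    heterozygous and missing genotypes are excluded pairwise. Base
    composition is estimated from the compared site set of each pair. Pairs
    with fewer than ``min_sites`` comparable sites are flagged unreliable.
    """
    if individuals is None:
        individuals = list(m.individual_ids)
    sub = m.subset_individuals(list(individuals))
    ref = np.array([_NUC_IX[l.ref] for l in sub.loci])
    alt = np.array([_NUC_IX[l.alt] for l in sub.loci])
    # per-cell base index or -1 when het/missing
    base = np.where(sub.dosage == 0, ref[None, :],
                    np.where(sub.dosage == 2, alt[None, :], -1)).astype(np.int8)

    n = len(individuals)
    D = np.zeros((n, n))
    unreliable = np.zeros((n, n), dtype=bool)
    purine = np.array([True, False, True, False])
    for x in range(n):
        for y in range(x + 1, n):
            ok = (base[x] >= 0) & (base[y] >= 0)
            n_sites = int(ok.sum())
            if n_sites < min_sites:
                unreliable[x, y] = unreliable[y, x] = True
            if n_sites == 0:
                D[x, y] = D[y, x] = np.nan
                continue
            bx, by = base[x, ok], base[y, ok]
            counts = np.bincount(np.concatenate([bx, by]), minlength=4)
            pi = counts / counts.sum()
            diff = bx != by
            transition = diff & (purine[bx] == purine[by])
            p1 = float((transition & purine[bx]).sum()) / n_sites
            p2 = float((transition & ~purine[bx]).sum()) / n_sites
            q = float((diff & ~transition).sum()) / n_sites
            dist = _tn93_from_counts(pi, p1, p2, q)
            if np.isinf(dist):
                unreliable[x, y] = unreliable[y, x] = True
            D[x, y] = D[y, x] = dist
    return DistanceMatrix(list(individuals), D, "tamura_nei", unreliable=unreliable)


# ---------------------------------------------------------------------------
# principal coordinate analysis
# ---------------------------------------------------------------------------

@dataclass
class PcoaResult:
    ids: list[str]
    coordinates: np.ndarray  # (n, n_axes)
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    percent_variance: np.ndarray  # per retained axis, of positive variance
    negative_eigenvalues: np.ndarray  # reported separately


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> PcoaResult:
    """Classical metric scaling of a distance matrix.

    Double-centres -d^2/2, eigendecomposes, and scales eigenvectors by the
    square root of their eigenvalues. Axes with negative eigenvalues (a
    non-Euclidean matrix) are excluded from the percent-variance denominator
    and reported separately.
    """
    mat = d.matrix
    if not np.isfinite(mat).all():
        raise ValueError("distance matrix contains non-finite entries")
    n = mat.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (mat**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-12
    positive = eigval > tol
    negative = eigval[eigval < -tol]
    n_pos = int(positive.sum())
    if n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; truncating"
        )
        n_axes = n_pos
    lam = eigval[:n_pos]
    coords = eigvec[:, :n_axes] * np.sqrt(lam[:n_axes]) if n_axes else np.zeros((n, 0))
    pct = 100.0 * lam[:n_axes] / lam.sum() if n_pos else np.zeros(0)
    return PcoaResult(list(d.ids), coords, lam, np.asarray(pct), negative)
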