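"""Per-locus Hardy-Weinberg tests and fdist-style F_ST outlier detection.

The HWE test uses the exact conditional (Levene/Haldane) distribution of the
heterozygote count given the allele counts; an equivalent Markov-chain Monte
Carlo mode with configurable chain length and dememorization is provided for
validation against the exact enumeration (biallelic data make enumeration
cheap, so the exact mode is the default).

The outlier scan follows the fdist recipe: per-locus F_ST and within-deme
heterozygosity are compared with the joint neutral distribution of the same
statistics under a non-hierarchical finite island model. The island model is
simulated by coalescent sampling (one biallelic locus per independent tree,
a single mutation dropped proportionally to branch length) of the observed
deme/sample configuration embedded in a larger set of demes; migration is
first calibrated by bisection so the simulated mean F_ST matches the
observed mean. Each locus's p-value is the empirical tail quantile of its
F_ST among simulated loci of similar heterozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import factorial, log
from typing import Sequence

import numpy as np
import pandas as pd

from .diversity import allele_frequencies, _locus_components
from .island import sample_island_locus
from .io_formats import MISSING, GenotypeMatrix, PopulationMap


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _levene_pmf(n_a: int, n_b: int) -> tuple[np.ndarray, list[Fraction]]:
    """Support and exact probabilities of the heterozygote count given allele
    counts (n_a copies of A, n_b of B) in n = (n_a+n_b)/2 individuals.

    Exact rational arithmetic keeps two-sided tail comparisons free of
    floating-point ties.
    """
    n2 = n_a + n_b
    n = n2 // 2
    h_min = n_a % 2
    h_support = np.arange(h_min, min(n_a, n_b) + 1, 2)
    probs = []
    for h in h_support:
        h = int(h)
        naa = (n_a - h) // 2
        nbb = (n_b - h) // 2
        num = factorial(n) * 2**h * factorial(n_a) * factorial(n_b)
        den = factorial(naa) * factorial(h) * factorial(nbb) * factorial(n2)
        probs.append(Fraction(num, den))
    return h_support, probs


@dataclass
class HweResult:
    p_value: float
    direction: str  # excess | deficit | none
    observed_het: int
    expected_het: float


def hwe_exact_test(
    n_aa: int,
    n_ab: int,
    n_bb: int,
    mode: str = "enumeration",
    chain_steps: int = 1_000_000,
    dememorization: int = 100_000,
    seed: int = 0,
) -> HweResult:
    """Exact (or Monte Carlo) HWE test for one biallelic locus.

    Two-sided p-value: total conditional probability of heterozygote counts
    whose probability does not exceed that of the observed count. Direction
    compares the observed heterozygote count with its conditional
    expectation n_a*n_b/(2n - 1).
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("negative genotype count")
    n = n_aa + n_ab + n_bb
    if n < 2:
        raise ValueError("need at least two individuals")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        raise ValueError("monomorphic locus: HWE test undefined")

    h_support, probs = _levene_pmf(n_a, n_b)
    obs_ix = int(np.flatnonzero(h_support == n_ab)[0])
    expected = n_a * n_b / (2 * n - 1.0)

    if mode == "enumeration":
        p_obs = probs[obs_ix]
        p = float(sum(q for q in probs if q <= p_obs))
    elif mode == "monte_carlo":
        logp = np.array([log(q) for q in probs])
        p = _hwe_mcmc(h_support, logp, obs_ix, chain_steps, dememorization, seed)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if n_ab > expected and p < 1 - 1e-12:
        direction = "excess"
    elif n_ab < expected and p < 1 - 1e-12:
        direction = "deficit"
    else:
        direction = "none"
    return HweResult(p, direction, n_ab, expected)


def _hwe_mcmc(
    h_support: np.ndarray,
    logp: np.ndarray,
    obs_ix: int,
    chain_steps: int,
    dememorization: int,
    seed: int,
) -> float:
    """Metropolis chain over the heterozygote-count states (+-2 proposals)."""
    rng = np.random.default_rng(seed)
    k = len(h_support)
    state = obs_ix
    threshold = logp[obs_ix] + 1e-12
    proposals = rng.integers(0, 2, size=chain_steps + dememorization) * 2 - 1
    accept_u = np.log(rng.random(size=chain_steps + dememorization))
    hits = 0
    for t in range(chain_steps + dememorization):
        candidate = state + proposals[t]
        if 0 <= candidate < k and accept_u[t] <= logp[candidate] - logp[state]:
            state = candidate
        if t >= dememorization and logp[state] <= threshold:
            hits += 1
    return max(hits, 1) / chain_steps


def hwe_scan(
    m: GenotypeMatrix,
    individuals: Sequence[str] | None = None,
    mode: str = "enumeration",
    chain_steps: int = 1_000_000,
    dememorization: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """HWE test per locus over the pooled sample (or a subset of individuals).

    Monomorphic loci are reported with NaN p-value and direction 'undefined'.
    """
    sub = m if individuals is None else m.subset_individuals(list(individuals))
    rows = []
    for j, lid in enumerate(sub.locus_ids):
        d = sub.dosage[:, j]
        counts = [(d == v).sum() for v in (0, 1, 2)]
        try:
            res = hwe_exact_test(
                *counts, mode=mode, chain_steps=chain_steps,
                dememorization=dememorization, seed=seed + j,
            )
            rows.append((lid, res.p_value, res.direction, res.observed_het, res.expected_het))
        except ValueError:
            rows.append((lid, np.nan, "undefined", counts[1], np.nan))
    return pd.DataFrame(
        rows, columns=["locus_id", "hwe_p", "direction", "observed_het", "expected_het"]
    )


# ---------------------------------------------------------------------------
# fdist outlier scan
# ---------------------------------------------------------------------------

def observed_locus_stats(m: GenotypeMatrix, pm: PopulationMap) -> pd.DataFrame:
    """Per-locus F_ST and within-deme heterozygosity (H_S scale)."""
    ft = allele_frequencies(m, pm)
    comp = _locus_components(ft)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = 1 - comp["H_S"] / comp["H_T"]
    return pd.DataFrame(
        {"locus_id": comp.index, "H_S": comp["H_S"].values, "F_ST": fst.values}
    ).reset_index(drop=True)


def _island_replicates(
    sample_sizes: Sequence[int],
    n_demes: int,
    migration_rate: float,
    n_loci: int,
    seed: int,
) -> np.ndarray:
    """Simulate independent biallelic loci under a finite island model.

    Each replicate is one single-mutation coalescent locus of diploid samples
    taken from the first ``len(sample_sizes)`` demes of an ``n_demes`` island
    model (see :mod:`cloverpop.island`). Returns per-replicate (H_S, F_ST)
    rows computed with the same estimators used for observed data.
    """
    rng = np.random.default_rng(seed)
    sizes = np.asarray(sample_sizes)
    pop_of_ind = np.repeat(np.arange(len(sizes)), sizes)
    out = np.empty((n_loci, 2))
    for r in range(n_loci):
        genotypes = sample_island_locus(sizes, n_demes, migration_rate, rng)
        out[r] = _pooled_locus_stats(genotypes, pop_of_ind, len(sizes))
    return out


def _pooled_locus_stats(
    genotypes: np.ndarray, pop_of_ind: np.ndarray, n_pops: int
) -> tuple[float, float]:
    """(H_S, F_ST) of one complete-data locus, same estimator as observed."""
    n = np.bincount(pop_of_ind, minlength=n_pops).astype(float)
    alt = np.bincount(pop_of_ind, weights=genotypes, minlength=n_pops)
    het = np.bincount(pop_of_ind, weights=(genotypes == 1), minlength=n_pops)
    p = alt / (2 * n)
    ho = float(np.mean(het / n))
    n_tilde = n_pops / np.sum(1.0 / n)
    msp2 = float(np.mean(p**2 + (1 - p) ** 2))
    hs = (n_tilde / (n_tilde - 1)) * (1 - msp2 - ho / (2 * n_tilde))
    pbar = float(np.mean(p))
    ht = 1 - (pbar**2 + (1 - pbar) ** 2) + hs / (n_tilde * n_pops)
    fst = 1 - hs / ht if ht > 0 else np.nan
    return hs, fst


def simulate_neutral_island_dataset(
    sample_sizes: Sequence[int],
    n_loci: int,
    n_demes: int = 100,
    migration_rate: float = 20.0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, PopulationMap]:
    """A fully neutral island-model dataset (for calibration studies).

    Produces a complete-data genotype matrix whose loci are independent
    coalescent island-model replicates — the scan's own null model class.
    """
    from .io_formats import Locus

    rng = np.random.default_rng(seed)
    sizes = np.asarray(sample_sizes)
    n_ind = int(sizes.sum())
    dosage = np.empty((n_ind, n_loci), dtype=np.int8)
    for r in range(n_loci):
        dosage[:, r] = sample_island_locus(sizes, n_demes, migration_rate, rng)
    loci = [Locus(f"N{j + 1:05d}", f"null{j}", 1, "A", "C") for j in range(n_loci)]
    individuals = []
    ind_to_acc = {}
    for k, size in enumerate(sample_sizes):
        for i in range(size):
            iid = f"P{k + 1:02d}_I{i + 1:02d}"
            individuals.append(iid)
            ind_to_acc[iid] = f"P{k + 1:02d}"
    accs = sorted(set(ind_to_acc.values()))
    pm = PopulationMap(
        ind_to_acc,
        {a: "island" for a in accs},
        {a: "W" for a in accs},
        {a: "diploid" for a in accs},
    )
    return GenotypeMatrix(individuals, loci, dosage), pm


def calibrate_migration(
    target_fst: float,
    sample_sizes: Sequence[int],
    n_demes: int,
    seed: int,
    n_calibration_loci: int = 800,
    tol: float = 0.003,
    max_iter: int = 10,
) -> float:
    """Bisection on the scaled migration rate M so that the simulated mean
    F_ST (ratio of locus-averaged components) matches the observed mean."""

    def mean_fst(big_m: float, it: int) -> float:
        stats = _island_replicates(
            sample_sizes, n_demes, big_m, n_calibration_loci, seed + 1000 + it
        )
        return float(np.nanmean(stats[:, 1]))

    lo, hi = 0.2, 500.0  # M = 4*N*m per deme; F_ST decreasing in M
    f_lo, f_hi = mean_fst(lo, 0), mean_fst(hi, 1)
    if not (f_hi <= target_fst <= f_lo):
        raise RuntimeError(
            f"cannot bracket observed mean F_ST {target_fst:.4f}: island model "
            f"yields [{f_hi:.4f}, {f_lo:.4f}] for M in [{lo}, {hi}]"
        )
    for it in range(max_iter):
        mid = np.sqrt(lo * hi)
        f_mid = mean_fst(mid, 2 + it)
        if abs(f_mid - target_fst) < tol:
            return mid
        if f_mid > target_fst:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def fdist_scan(
    m: GenotypeMatrix,
    pm: PopulationMap,
    n_simulations: int = 20_000,
    n_demes: int = 100,
    seed: int = 0,
    bin_size: int = 500,
    n_calibration_loci: int = 800,
) -> pd.DataFrame:
    """F_ST outlier scan against a calibrated island-model null.

    Per locus, the upper-tail p-value is the (+1-corrected) fraction of the
    ``bin_size`` simulated loci closest in heterozygosity whose F_ST is at
    least the observed value; the lower tail is symmetric. Loci with
    ``fdist_p`` (upper tail) below the significance level are the candidates
    flagged as under (diversifying) selection.
    """
    pm.check_covers(m)
    obs = observed_locus_stats(m, pm)
    informative = obs.dropna(subset=["H_S", "F_ST"])
    if len(informative) < 20:
        raise ValueError("need >= 20 informative loci to calibrate the scan")
    # mean F_ST as ratio of locus-averaged components
    ft = allele_frequencies(m, pm)
    comp = _locus_components(ft)
    target_fst = 1 - np.nanmean(comp["H_S"]) / np.nanmean(comp["H_T"])

    sizes = [len(pm.individuals_of(a)) for a in pm.accessions]
    big_m = calibrate_migration(
        float(target_fst), sizes, n_demes, seed, n_calibration_loci
    )
    sims = _island_replicates(sizes, n_demes, big_m, n_simulations, seed)
    sims = sims[~np.isnan(sims).any(axis=1)]
    order = np.argsort(sims[:, 0])
    sim_h = sims[order, 0]
    sim_fst = sims[order, 1]
    k = min(bin_size, len(sim_h))

    p_upper = np.full(len(obs), np.nan)
    p_lower = np.full(len(obs), np.nan)
    for i, row in obs.iterrows():
        if np.isnan(row["H_S"]) or np.isnan(row["F_ST"]):
            continue
        centre = np.searchsorted(sim_h, row["H_S"])
        lo = max(0, min(centre - k // 2, len(sim_h) - k))
        window = sim_fst[lo: lo + k]
        p_upper[i] = ((window >= row["F_ST"] - 1e-12).sum() + 1) / (k + 1)
        p_lower[i] = ((window <= row["F_ST"] + 1e-12).sum() + 1) / (k + 1)

    out = obs.copy()
    out["fdist_p"] = p_upper
    out["fdist_p_lower"] = p_lower
    out.attrs["migration_M"] = big_m
    out.attrs["n_simulations_used"] = len(sim_h)
    return out


def selection_report(
    hwe: pd.DataFrame,
    fdist: pd.DataFrame,
    alpha_hwe: float = 0.01,
    alpha_fdist: float = 0.05,
    effects: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join the two scans into one per-locus table with flags and counts.

    The result carries boolean columns ``hwe_deviant`` and ``under_selection``
    and (via ``attrs['counts']``) the headline tallies: deviants by direction
    and outlier totals. ``effects`` (locus_id, effect) is joined when given.
    """
    merged = hwe.merge(fdist, on="locus_id", how="outer", suffixes=("", "_fdist"))
    merged["hwe_deviant"] = merged["hwe_p"] < alpha_hwe
    merged["under_selection"] = merged["fdist_p"] < alpha_fdist
    if effects is not None:
        merged = merged.merge(effects, on="locus_id", how="left")
    merged.attrs["counts"] = {
        "hwe_deviant": int(merged["hwe_deviant"].sum()),
        "hwe_excess": int((merged["hwe_deviant"] & (merged["direction"] == "excess")).sum()),
        "hwe_deficit": int((merged["hwe_deviant"] & (merged["direction"] == "deficit")).sum()),
        "under_selection": int(merged["under_selection"].sum()),
        "both": int((merged["hwe_deviant"] & merged["under_selection"]).sum()),
    }
    return merged
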