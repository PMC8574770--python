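"""Hierarchical analysis of molecular variance (AMOVA) with permutation tests.

Diploid individuals are expanded into two pseudo-haplotypes each (phase is
arbitrary and irrelevant: the squared distance counts per-locus allele
differences, which is invariant to phase). The squared distance between two
haplotypes is the number of loci at which their alleles differ, counted over
loci where both are called.

Variance components come from the standard method-of-moments equations on
sums of squared distances partitioned across a three-stratum hierarchy
(groups / populations within groups / units within populations), with
unequal-sample-size coefficients. Two designs are exposed:

* ungrouped — groups are accessions, populations are individuals, units are
  haplotypes; the strata are among accessions / among individuals within
  accessions / within individuals, with indices F_ST, F_IS, F_IT;
* grouped — groups are accession groups (origin, type, ploidy, ...),
  populations are accessions, units are haplotypes; indices F_CT, F_SC, F_ST.

Negative variance components are reported as estimated, never truncated.
Permutation p-values use the (hits + 1)/(n + 1) convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, PopulationMap


@dataclass
class HaplotypeDistances:
    """Squared allele-difference distances between pseudo-haplotypes."""

    unit_ids: list[str]  # "<individual>/1", "<individual>/2"
    individual_of_unit: np.ndarray  # (2N,) index into individual list
    d2: np.ndarray  # (2N, 2N) squared distances


def individual_distance_matrix(m: GenotypeMatrix) -> HaplotypeDistances:
    """Expand individuals to haplotype pairs and count allele differences.

    A heterozygote contributes one reference and one alternative copy (phase
    fixed by convention: ref copy first). Loci missing in either haplotype of
    a pair are skipped for that pair (pairwise-complete counting).
    """
    n = m.n_individuals
    hap = np.full((2 * n, m.n_loci), np.nan)
    d = m.dosage
    hap[0::2] = np.where(d == MISSING, np.nan, (d == 2).astype(float))
    hap[1::2] = np.where(d == MISSING, np.nan, (d >= 1).astype(float))
    defined = ~np.isnan(hap)
    x = np.where(defined, hap, 0.0)
    md = defined.astype(float)
    xm = x * md
    # |x_i - x_j| summed over co-called loci, for 0/1 alleles:
    # sum_l m_i m_j (x_i + x_j - 2 x_i x_j)
    d2 = xm @ md.T + md @ xm.T - 2.0 * xm @ xm.T
    np.fill_diagonal(d2, 0.0)
    unit_ids = [f"{iid}/{k}" for iid in m.individual_ids for k in (1, 2)]
    return HaplotypeDistances(unit_ids, np.repeat(np.arange(n), 2), d2)


def _ssd(d2: np.ndarray, members: np.ndarray) -> float:
    block = d2[np.ix_(members, members)]
    return float(block.sum()) / (2.0 * len(members))


def _fit_components(
    d2: np.ndarray, pop_of_unit: np.ndarray, group_of_pop: np.ndarray
) -> dict[str, object]:
    """Method-of-moments variance components for the three-stratum design."""
    n_units = d2.shape[0]
    pops = np.unique(pop_of_unit)
    groups = np.unique(group_of_pop[pops])
    P, G = len(pops), len(groups)
    group_of_unit = group_of_pop[pop_of_unit]

    all_units = np.arange(n_units)
    ssd_total = _ssd(d2, all_units)
    ssd_wp = sum(_ssd(d2, np.flatnonzero(pop_of_unit == p)) for p in pops)
    ssd_wg = sum(_ssd(d2, np.flatnonzero(group_of_unit == g)) for g in groups)
    ssd_ap = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg

    df_ag, df_ap, df_wp = G - 1, P - G, n_units - P
    n_p = np.array([(pop_of_unit == p).sum() for p in pops], dtype=float)
    g_of = group_of_pop[pops]
    N_g = np.array([n_p[g_of == g].sum() for g in groups])
    N = float(n_units)

    sum_np2_over_Ng = sum(
        (n_p[g_of == g] ** 2).sum() / N_g[k] for k, g in enumerate(groups)
    )
    n1 = (N - sum_np2_over_Ng) / df_ap if df_ap > 0 else np.nan
    n2 = (sum_np2_over_Ng - (n_p**2).sum() / N) / df_ag if df_ag > 0 else np.nan
    n3 = (N - (N_g**2).sum() / N) / df_ag if df_ag > 0 else np.nan

    ms_wp = ssd_wp / df_wp if df_wp > 0 else np.nan
    ms_ap = ssd_ap / df_ap if df_ap > 0 else np.nan
    ms_ag = ssd_ag / df_ag if df_ag > 0 else np.nan

    v_c = ms_wp
    v_b = (ms_ap - v_c) / n1 if df_ap > 0 else np.nan
    v_a = (ms_ag - v_c - n2 * v_b) / n3 if df_ag > 0 else np.nan
    total = v_a + v_b + v_c

    with np.errstate(invalid="ignore", divide="ignore"):
        phi_ct = v_a / total
        phi_sc = v_b / (v_b + v_c)
        phi_st = (v_a + v_b) / total
    return {
        "ssd": (ssd_ag, ssd_ap, ssd_wp, ssd_total),
        "df": (df_ag, df_ap, df_wp, n_units - 1),
        "components": (v_a, v_b, v_c),
        "total": total,
        "indices": (float(phi_ct), float(phi_sc), float(phi_st)),
    }


@dataclass
class AmovaResult:
    """AMOVA table: one row per stratum plus the total row."""

    design: str  # "ungrouped" or the grouping name
    table: pd.DataFrame
    indices: dict[str, float]
    p_values: dict[str, float]
    n_permutations: int
    seed: int

    def percentage(self, source: str) -> float:
        row = self.table[self.table["source"] == source]
        return float(row["percent_variation"].iloc[0])


def amova(
    m: GenotypeMatrix,
    pm: PopulationMap,
    grouping: str | Mapping[str, str] | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
    accessions: Sequence[str] | None = None,
) -> AmovaResult:
    """Run the AMOVA for the ungrouped or a grouped design.

    ``grouping`` may be None (ungrouped), one of the population-map groupings
    ("origin", "type", "ploidy"), or an explicit accession -> group mapping.
    ``accessions`` restricts the analysis to a subset of accessions (the rest
    of the panel is dropped). Permutation schemes per stratum:

    * first stratum — permute whole populations among groups (ungrouped:
      individuals among accessions), statistic F_CT (ungrouped: F_ST);
    * second stratum — permute units among populations within groups
      (ungrouped: haplotypes among individuals within accessions), statistic
      F_SC (ungrouped: F_IS);
    * third stratum — permute units among populations across groups,
      statistic F_ST (ungrouped: F_IT).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    pm.check_covers(m)
    if accessions is not None:
        keep = set(accessions)
        inds = [i for i in m.individual_ids if pm.accession_of(i) in keep]
        m = m.subset_individuals(inds)

    hd = individual_distance_matrix(m)
    acc_list = sorted({pm.accession_of(i) for i in m.individual_ids})
    acc_ix = {a: k for k, a in enumerate(acc_list)}
    acc_of_ind = np.array([acc_ix[pm.accession_of(i)] for i in m.individual_ids])

    if grouping is None:
        design = "ungrouped"
        pop_of_unit = hd.individual_of_unit
        group_of_pop = acc_of_ind  # accession of each individual
        sources = (
            "Among accessions",
            "Among individuals within accessions",
            "Within individuals",
        )
        index_names = ("F_ST", "F_IS", "F_IT")
        if len(acc_list) < 2:
            raise ValueError("need at least two accessions")
    else:
        if isinstance(grouping, str):
            group_of_acc = {a: pm.group_of(a, grouping) for a in acc_list}
            design = grouping
        else:
            group_of_acc = dict(grouping)
            design = "custom"
        group_names = sorted(set(group_of_acc.values()))
        if len(group_names) < 2:
            raise ValueError("need at least two groups")
        g_ix = {g: k for k, g in enumerate(group_names)}
        pop_of_unit = acc_of_ind[hd.individual_of_unit]
        group_of_pop = np.array([g_ix[group_of_acc[a]] for a in acc_list])
        sources = (
            "Among groups",
            "Among accessions within groups",
            "Within accessions",
        )
        index_names = ("F_CT", "F_SC", "F_ST")

    obs = _fit_components(hd.d2, pop_of_unit, group_of_pop)
    rng = np.random.default_rng(seed)
    p_values = _permutation_pvalues(
        hd, pop_of_unit, group_of_pop, obs["indices"], n_permutations, rng,
        individual_level=grouping is not None,
    )

    v = obs["components"]
    table = pd.DataFrame(
        {
            "source": list(sources) + ["Total"],
            "df": list(obs["df"][:3]) + [obs["df"][3]],
            "sum_of_squares": list(obs["ssd"][:3]) + [obs["ssd"][3]],
            "variance_component": list(v) + [obs["total"]],
            "percent_variation": [100 * x / obs["total"] for x in v] + [100.0],
        }
    )
    indices = dict(zip(index_names, obs["indices"]))
    return AmovaResult(
        design=design,
        table=table,
        indices=indices,
        p_values={name: p_values[k] for k, name in enumerate(index_names)},
        n_permutations=n_permutations,
        seed=seed,
    )


def _permutation_pvalues(
    hd: HaplotypeDistances,
    pop_of_unit: np.ndarray,
    group_of_pop: np.ndarray,
    observed: tuple[float, float, float],
    n_perm: int,
    rng: np.random.Generator,
    individual_level: bool,
) -> list[float]:
    """Upper-tail permutation p-values, one per stratum index."""
    d2 = hd.d2
    n_units = d2.shape[0]
    ind_of_unit = hd.individual_of_unit
    n_ind = ind_of_unit.max() + 1
    hits = [0, 0, 0]

    # units come in individual-order pairs, so unit 2i carries individual i's pop
    pop_of_ind = pop_of_unit[0::2]

    def shuffle_individuals(within_groups: bool) -> np.ndarray:
        """Move whole individuals (haplotype pairs) among populations."""
        if within_groups:
            new = pop_of_ind.copy()
            for g in np.unique(group_of_pop):
                sel = np.flatnonzero(group_of_pop[pop_of_ind] == g)
                new[sel] = pop_of_ind[sel[rng.permutation(len(sel))]]
            return new[ind_of_unit]
        return pop_of_ind[rng.permutation(n_ind)][ind_of_unit]

    for _ in range(n_perm):
        # stratum 1: permute whole populations among groups (ungrouped:
        # whole individuals among accessions)
        fit = _fit_components(
            d2, pop_of_unit, group_of_pop[rng.permutation(len(group_of_pop))]
        )
        if fit["indices"][0] >= observed[0] - 1e-12:
            hits[0] += 1

        # stratum 2: units among populations within groups
        if individual_level:
            fit = _fit_components(d2, shuffle_individuals(within_groups=True), group_of_pop)
        else:
            new_pop = pop_of_unit.copy()
            group_of_unit = group_of_pop[pop_of_unit]
            for g in np.unique(group_of_pop):
                sel = np.flatnonzero(group_of_unit == g)
                new_pop[sel] = pop_of_unit[sel[rng.permutation(len(sel))]]
            fit = _fit_components(d2, new_pop, group_of_pop)
        if fit["indices"][1] >= observed[1] - 1e-12:
            hits[1] += 1

        # stratum 3: units among populations across groups
        if individual_level:
            fit = _fit_components(d2, shuffle_individuals(within_groups=False), group_of_pop)
        else:
            fit = _fit_components(d2, pop_of_unit[rng.permutation(n_units)], group_of_pop)
        if fit["indices"][2] >= observed[2] - 1e-12:
            hits[2] += 1

    return [
        np.nan if np.isnan(observed[k]) else (hits[k] + 1) / (n_perm + 1)
        for k in range(3)
    ]
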