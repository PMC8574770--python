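"""Gene diversity and F-statistics (Nei–Chesser bias-corrected estimators).

Per locus, with ``s`` populations having a defined allele frequency and
``n_tilde`` the harmonic-mean per-population number of called individuals:

    H_O = mean over populations of the heterozygote fraction
    H_S = n_tilde/(n_tilde - 1) * (1 - mean_s(sum_a x_sa^2) - H_O/(2 n_tilde))
    H_T = 1 - sum_a(mean_s x_sa)^2 + H_S/(n_tilde * s)

Components are averaged over loci and the fixation indices are ratios of
locus-averaged components (not averages of per-locus ratios):

    F_IS = 1 - H_O/H_S,  F_ST = 1 - H_S/H_T,  F_IT = 1 - H_O/H_T

Missing genotypes are excluded pairwise: a population with no called
individual at a locus simply drops out of that locus's averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, PopulationMap


@dataclass
class FrequencyTable:
    """Per-population alt-allele frequencies with effective sample sizes."""

    populations: list[str]
    locus_ids: list[str]
    freq: np.ndarray  # (s, L), NaN where no called individual
    n_called: np.ndarray  # (s, L) called individuals
    het_fraction: np.ndarray  # (s, L) observed heterozygote fraction, NaN if n=0


def allele_frequencies(
    m: GenotypeMatrix,
    pm: PopulationMap,
    populations: Sequence[str] | None = None,
) -> FrequencyTable:
    """Alt-allele frequency per (population, locus): sum(dosage)/(2 * n_called).

    Missing cells contribute to neither numerator nor denominator. A
    population with zero called individuals at a locus gets NaN (flagged
    undefined) and is excluded from that locus downstream.
    """
    pm.check_covers(m)
    pops = list(populations) if populations is not None else pm.accessions
    rows = {p: [] for p in pops}
    for i, iid in enumerate(m.individual_ids):
        acc = pm.accession_of(iid)
        if acc in rows:
            rows[acc].append(i)
    freq = np.full((len(pops), m.n_loci), np.nan)
    n_called = np.zeros((len(pops), m.n_loci), dtype=int)
    het = np.full((len(pops), m.n_loci), np.nan)
    for k, pop in enumerate(pops):
        d = m.dosage[rows[pop]]
        called = d != MISSING
        n = called.sum(axis=0)
        n_called[k] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[k] = np.where(n > 0, np.where(called, d, 0).sum(axis=0) / (2 * n), np.nan)
            het[k] = np.where(n > 0, (d == 1).sum(axis=0) / n, np.nan)
    return FrequencyTable(pops, m.locus_ids, freq, n_called, het)


def _locus_components(ft: FrequencyTable) -> pd.DataFrame:
    """Per-locus H_O, H_S, H_T over the populations with defined frequency."""
    s_pops, L = ft.freq.shape
    out = np.full((L, 4), np.nan)  # ho, hs, ht, s
    for j in range(L):
        defined = ~np.isnan(ft.freq[:, j])
        s = int(defined.sum())
        if s == 0:
            continue
        n = ft.n_called[defined, j].astype(float)
        if (n <= 1).any():
            # bias correction needs n >= 2 in every contributing population
            ok = n > 1
            defined = np.flatnonzero(defined)[ok]
            n = n[ok]
            s = len(n)
            if s == 0:
                continue
            defined_mask = np.zeros(s_pops, dtype=bool)
            defined_mask[defined] = True
            defined = defined_mask
        n_tilde = s / np.sum(1.0 / n)
        p = ft.freq[defined, j]
        ho = float(np.mean(ft.het_fraction[defined, j]))
        sum_sq = p**2 + (1 - p) ** 2
        hs = (n_tilde / (n_tilde - 1)) * (1 - float(np.mean(sum_sq)) - ho / (2 * n_tilde))
        p_bar = float(np.mean(p))
        ht = 1 - (p_bar**2 + (1 - p_bar) ** 2) + hs / (n_tilde * s)
        out[j] = (ho, hs, ht, s)
    return pd.DataFrame(out, columns=["H_O", "H_S", "H_T", "s"], index=ft.locus_ids)


@dataclass
class DiversitySummary:
    """Per-accession diversity (Table-1 style) plus overall F-statistics."""

    per_accession: pd.DataFrame  # accession, pct_polymorphic, H_O, H_S, F_IS
    overall: dict[str, float]  # H_O, H_S, H_T, F_IS, F_ST, F_IT
    per_locus: pd.DataFrame  # locus-wise H_O, H_S, H_T components


def diversity_summary(m: GenotypeMatrix, pm: PopulationMap) -> DiversitySummary:
    """Accession-level and overall diversity and F-statistics."""
    ft = allele_frequencies(m, pm)
    components = _locus_components(ft)

    rows = []
    for pop in ft.populations:
        sub = allele_frequencies(m, pm, populations=[pop])
        comp = _locus_components(sub)
        ho = float(np.nanmean(comp["H_O"]))
        hs = float(np.nanmean(comp["H_S"]))
        fis = 1 - ho / hs if hs > 0 else np.nan
        observed = ~np.isnan(sub.freq[0])
        poly = (sub.freq[0] > 0) & (sub.freq[0] < 1) & observed
        pct_pl = 100.0 * poly.sum() / m.n_loci if m.n_loci else np.nan
        rows.append((pop, pct_pl, ho, hs, fis))
    per_accession = pd.DataFrame(
        rows, columns=["accession", "pct_polymorphic", "H_O", "H_S", "F_IS"]
    )

    ho = float(np.nanmean(components["H_O"]))
    hs = float(np.nanmean(components["H_S"]))
    ht = float(np.nanmean(components["H_T"]))
    overall = {
        "H_O": ho,
        "H_S": hs,
        "H_T": ht,
        "F_IS": 1 - ho / hs if hs > 0 else np.nan,
        "F_ST": 1 - hs / ht if ht > 0 else np.nan,
        "F_IT": 1 - ho / ht if ht > 0 else np.nan,
    }
    return DiversitySummary(per_accession, overall, components)


def group_summary(m: GenotypeMatrix, pm: PopulationMap, grouping: str) -> pd.DataFrame:
    """Diversity statistics recomputed within each accession group.

    Each accession inside a group is treated as a population; the returned
    table carries the group-level scalar statistics (ratio-of-averages) plus
    quartiles of the per-locus values, i.e. the tabular content of a grouped
    box-plot. Within-group F_ST of a singleton group is undefined (NaN).
    """
    pm.check_covers(m)
    groups: dict[str, list[str]] = {}
    for acc in pm.accessions:
        groups.setdefault(pm.group_of(acc, grouping), []).append(acc)

    rows = []
    for group, accs in groups.items():
        inds = [i for i in m.individual_ids if pm.accession_of(i) in set(accs)]
        sub = m.subset_individuals(inds)
        ft = allele_frequencies(sub, pm, populations=accs)
        comp = _locus_components(ft)
        ho = float(np.nanmean(comp["H_O"]))
        hs = float(np.nanmean(comp["H_S"]))
        ht = float(np.nanmean(comp["H_T"]))
        singleton = len(accs) < 2
        row = {
            "group": group,
            "n_accessions": len(accs),
            "H_O": ho,
            "H_S": hs,
            "H_T": ht,
            "F_IS": 1 - ho / hs if hs > 0 else np.nan,
            "F_ST": np.nan if singleton else (1 - hs / ht if ht > 0 else np.nan),
        }
        for stat in ("H_O", "H_S", "H_T"):
            values = comp[stat].dropna()
            row[f"{stat}_q25"], row[f"{stat}_median"], row[f"{stat}_q75"] = (
                np.percentile(values, (25, 50, 75)) if len(values) else (np.nan,) * 3
            )
        rows.append(row)
    return pd.DataFrame(rows)


_ZYGOSITY = {0: "hom_ref", 1: "het", 2: "hom_alt", MISSING: "missing"}


def zygosity_table(
    m: GenotypeMatrix, pm: PopulationMap, locus_ids: Sequence[str]
) -> pd.DataFrame:
    """Per-individual genotype-class table for selected loci.

    One row per individual ordered by (origin, type, accession), one column
    per selected locus, values in {hom_ref, het, hom_alt, missing}.
    """
    pm.check_covers(m)
    sub = m.subset_loci(list(locus_ids))  # KeyError on unknown locus id
    order = sorted(
        range(m.n_individuals),
        key=lambda i: (
            pm.accession_origin[pm.accession_of(m.individual_ids[i])],
            pm.accession_type[pm.accession_of(m.individual_ids[i])],
            pm.accession_of(m.individual_ids[i]),
            m.individual_ids[i],
        ),
    )
    data = {
        "individual": [m.individual_ids[i] for i in order],
        "accession": [pm.accession_of(m.individual_ids[i]) for i in order],
    }
    for c, lid in enumerate(locus_ids):
        data[lid] = [_ZYGOSITY[int(sub.dosage[i, c])] for i in order]
    return pd.DataFrame(data)
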