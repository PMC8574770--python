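"""Single-locus coalescent sampler for the symmetric finite island model.

The fdist-style outlier scan needs tens of thousands of independent biallelic
loci simulated under an island model for the observed deme/sample
configuration. A general-purpose genealogy simulator is unnecessary for
that: each locus needs only the set of sampled lineages subtended by one
mutation dropped uniformly on the genealogy's branch length. This module
therefore runs the structured coalescent tracking, per active lineage, the
count of descendant samples in each sampled deme, and picks the mutated
branch by reservoir sampling over inter-event intervals — O(events) per
locus with no tree construction.

Time is measured in units of 2N generations per deme. With total scaled
migration M = 4Nm (m the total immigration probability per lineage per
generation, spread uniformly over the other demes):

* per-pair coalescence rate within a deme: 1
* per-lineage migration rate: M/2

Mutations land on a uniformly random point of the total branch length, so
every simulated locus is polymorphic in the pooled sample (the stop at one
remaining lineage excludes the root branch).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _sim_descendants(sample_counts, n_demes, big_m, seed):  # pragma: no cover - jit
    """One locus: per-sampled-deme counts of samples carrying the mutation.

    ``sample_counts`` are haploid sample numbers in the first ``s`` demes.
    """
    np.random.seed(seed)
    s = sample_counts.shape[0]
    k0 = int(sample_counts.sum())

    deme = np.empty(k0, dtype=np.int64)
    desc = np.zeros((k0, s), dtype=np.int64)
    occupancy = np.zeros(n_demes, dtype=np.int64)
    idx = 0
    for d in range(s):
        occupancy[d] = sample_counts[d]
        for _ in range(sample_counts[d]):
            deme[idx] = d
            desc[idx, d] = 1
            idx += 1

    coal_pairs = 0.0
    for d in range(n_demes):
        coal_pairs += occupancy[d] * (occupancy[d] - 1) / 2.0

    active = k0
    total_len = 0.0
    mut_desc = np.zeros(s, dtype=np.int64)
    mig_rate_per_lineage = big_m / 2.0

    while active > 1:
        rate = coal_pairs + active * mig_rate_per_lineage
        dt = np.random.exponential(1.0 / rate)
        interval = active * dt
        total_len += interval
        # reservoir: the mutation lands in this interval w.p. interval/total
        if np.random.random() < interval / total_len:
            pick = np.random.randint(0, active)
            for c in range(s):
                mut_desc[c] = desc[pick, c]
        if np.random.random() * rate < coal_pairs:
            # coalescence: deme chosen proportionally to its pair count
            r = np.random.random() * coal_pairs
            target = -1
            acc = 0.0
            for d in range(n_demes):
                pairs = occupancy[d] * (occupancy[d] - 1) / 2.0
                if pairs > 0.0:
                    acc += pairs
                    if r < acc:
                        target = d
                        break
            if target < 0:
                target = n_demes - 1
            # pick two distinct lineages in that deme
            first = -1
            second = -1
            n_seen = 0
            n_in = occupancy[target]
            a = np.random.randint(0, n_in)
            b = np.random.randint(0, n_in - 1)
            if b >= a:
                b += 1
            for i in range(active):
                if deme[i] == target:
                    if n_seen == a:
                        first = i
                    if n_seen == b:
                        second = i
                    n_seen += 1
            for c in range(s):
                desc[first, c] += desc[second, c]
            # swap-delete `second`
            last = active - 1
            deme[second] = deme[last]
            for c in range(s):
                desc[second, c] = desc[last, c]
            active -= 1
            coal_pairs -= n_in - 1
            occupancy[target] = n_in - 1
        else:
            pick = np.random.randint(0, active)
            old = deme[pick]
            new = np.random.randint(0, n_demes - 1)
            if new >= old:
                new += 1
            coal_pairs += occupancy[new] - (occupancy[old] - 1)
            occupancy[old] -= 1
            occupancy[new] += 1
            deme[pick] = new
    return mut_desc


def sample_island_locus(
    diploid_sample_sizes: np.ndarray,
    n_demes: int,
    big_m: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Diploid genotypes (alt dosage per individual) for one neutral locus.

    Derived alleles within a deme are assigned to haploid slots uniformly at
    random (lineages are exchangeable) and consecutive slots form an
    individual, emulating random union of gametes.
    """
    sizes = np.asarray(diploid_sample_sizes, dtype=np.int64)
    hap = (2 * sizes).astype(np.int64)
    mut = _sim_descendants(hap, n_demes, big_m, int(rng.integers(1, 2**31 - 1)))
    genotypes = np.empty(int(sizes.sum()), dtype=np.int8)
    pos = 0
    for d in range(len(sizes)):
        slots = np.zeros(hap[d], dtype=np.int8)
        if mut[d]:
            slots[rng.choice(hap[d], size=mut[d], replace=False)] = 1
        genotypes[pos: pos + sizes[d]] = slots[0::2] + slots[1::2]
        pos += sizes[d]
    return genotypes
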