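"""Discriminant analysis of principal components (DAPC).

Dosage genotypes are centred (no scaling — dosage variance is informative),
reduced by PCA, and the retained PC scores are fed to a linear discriminant
analysis that yields discriminant coordinates and posterior cluster
memberships. The number of PCs can be chosen by stratified cross-validation
of assignment accuracy, and clusters can be found de novo by k-means on the
PC scores with a BIC model-selection curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .io_formats import MISSING, GenotypeMatrix, PopulationMap


def _dosage_features(m: GenotypeMatrix) -> np.ndarray:
    """Centred dosage matrix with missing cells imputed by the locus mean."""
    x = m.dosage.astype(float)
    x[m.dosage == MISSING] = np.nan
    mu = np.nanmean(x, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    idx = np.where(np.isnan(x))
    x[idx] = mu[idx[1]]
    return x - x.mean(axis=0)


@dataclass
class PcSelection:
    n_pcs: int
    grid: np.ndarray
    mean_accuracy: np.ndarray  # mean held-out accuracy per grid point


def choose_n_pcs(
    m: GenotypeMatrix,
    labels: np.ndarray,
    max_pcs: int = 100,
    folds: int = 5,
    seed: int = 0,
) -> PcSelection:
    """Pick the PC count maximising cross-validated assignment accuracy.

    Stratified k-fold: PCA is refit on each training split. Ties in mean
    held-out accuracy are broken towards fewer PCs. Classes with fewer
    members than folds are left out of the cross-validation (with a warning)
    since they cannot appear in every training split.
    """
    labels = np.asarray(labels)
    if len(labels) != m.n_individuals:
        raise ValueError("labels must cover all individuals")
    x = _dosage_features(m)
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < folds]
    if small.size:
        warnings.warn(f"classes with < {folds} members left out of CV: {list(small)}")
        keep = ~np.isin(labels, small)
        x, labels = x[keep], labels[keep]

    rng = np.random.default_rng(seed)
    cap = min(max_pcs, x.shape[0] - 1 - x.shape[0] // folds, x.shape[1])
    grid = np.arange(1, max(cap, 1) + 1)
    scores = np.zeros((folds, len(grid)))

    # build stratified folds
    fold_of = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        members = members[rng.permutation(len(members))]
        fold_of[members] = np.arange(len(members)) % folds

    for f in range(folds):
        train, test = fold_of != f, fold_of == f
        pca = PCA(n_components=int(grid[-1]), random_state=int(seed)).fit(x[train])
        zt = pca.transform(x[train])
        zv = pca.transform(x[test])
        for gi, k in enumerate(grid):
            lda = LinearDiscriminantAnalysis().fit(zt[:, :k], labels[train])
            scores[f, gi] = float(np.mean(lda.predict(zv[:, :k]) == labels[test]))

    mean_acc = scores.mean(axis=0)
    best = int(grid[int(np.argmax(mean_acc))])  # argmax returns first max: fewest PCs
    return PcSelection(best, grid, mean_acc)


@dataclass
class ClusterSearch:
    labels: np.ndarray
    k: int
    grid: np.ndarray
    bic: np.ndarray


def find_clusters(
    m: GenotypeMatrix,
    max_k: int = 10,
    n_pcs: int = 100,
    seed: int = 0,
    n_restarts: int = 10,
) -> ClusterSearch:
    """De-novo clusters: k-means on PC scores, k chosen by a BIC curve.

    BIC(k) = n log(WSS_k / n) + k log(n) on the retained-PC space, evaluated
    for k = 1..max_k; the labels at the BIC minimum are returned together
    with the full curve.
    """
    n = m.n_individuals
    if n <= max_k:
        raise ValueError("need more individuals than candidate clusters")
    x = _dosage_features(m)
    n_pcs = min(n_pcs, n - 1, x.shape[1])
    z = PCA(n_components=n_pcs, random_state=int(seed)).fit_transform(x)
    grid = np.arange(1, max_k + 1)
    bic = np.zeros(len(grid))
    labels_at = []
    for gi, k in enumerate(grid):
        if k == 1:
            wss = float(((z - z.mean(axis=0)) ** 2).sum())
            labels_k = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=int(k), n_init=n_restarts, random_state=int(seed)).fit(z)
            wss = float(km.inertia_)
            labels_k = km.labels_
        bic[gi] = n * np.log(wss / n) + k * np.log(n)
        labels_at.append(labels_k)
    best = int(np.argmin(bic))
    return ClusterSearch(labels_at[best], int(grid[best]), grid, bic)


@dataclass
class DapcResult:
    n_pcs: int
    cumulative_variance_pct: float  # variance of retained PCs, % of total
    labels: np.ndarray
    coordinates: np.ndarray  # discriminant coordinates per individual
    posteriors: pd.DataFrame  # individuals x clusters, rows sum to 1
    accession_memberships: pd.DataFrame | None  # mean posterior per accession


def dapc_fit(
    m: GenotypeMatrix,
    labels: np.ndarray,
    n_pcs: int,
    pm: PopulationMap | None = None,
) -> DapcResult:
    """Fit the discriminant step on retained PC scores.

    Posteriors come from the LDA model; when a population map is supplied,
    per-accession membership proportions are the mean posterior over the
    accession's individuals (reports round these to the nearest 10%; full
    precision is kept here).
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    ones = [c for c in classes if (labels == c).sum() == 1]
    if ones:
        warnings.warn(f"classes with a single member kept: {ones}")
    x = _dosage_features(m)
    n_pcs = min(n_pcs, m.n_individuals - 1, x.shape[1])
    pca = PCA(n_components=n_pcs)
    z = pca.fit_transform(x)
    total_var = float(np.var(x, axis=0, ddof=1).sum())
    cum_pct = 100.0 * float(pca.explained_variance_[:n_pcs].sum()) / total_var

    lda = LinearDiscriminantAnalysis()
    lda.fit(z, labels)
    coords = lda.transform(z)
    post = pd.DataFrame(
        lda.predict_proba(z), index=m.individual_ids, columns=lda.classes_
    )

    memberships = None
    if pm is not None:
        pm.check_covers(m)
        acc = [pm.accession_of(i) for i in m.individual_ids]
        memberships = post.groupby(pd.Series(acc, index=post.index)).mean()
        memberships.index.name = "accession"
    return DapcResult(
        n_pcs=n_pcs,
        cumulative_variance_pct=cum_pct,
        labels=labels,
        coordinates=coords,
        posteriors=post,
        accession_memberships=memberships,
    )


def membership_report(result: DapcResult) -> pd.DataFrame:
    """Accession memberships rounded to the nearest 10% (table-style view)."""
    if result.accession_memberships is None:
        raise ValueError("fit was run without a population map")
    return (result.accession_memberships * 10).round() * 10
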