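"""Glucuronidome composition and shift statistics on feature tables.

Given a features x samples peak-area matrix of pattern-filtered
(glucuronidated) features, this module computes

* per-sample richness: the number of features with area strictly above a
  matrix-specific noise threshold,
* a two-group Poisson comparison of richness counts (Wald test on the log
  rate ratio),
* per-feature differential abundance: log2-transformed areas, Welch
  two-sample t-tests, Benjamini-Hochberg adjustment, with the significance
  rule q < 0.1 and |log2FC| > 1,
* Bray-Curtis sample dissimilarities and classical PCoA ordination,
* cross-matrix feature matching (precursor m/z + retention time + MS/MS
  modified cosine) with Venn-style overlap counts.

Fold changes are computed as log2(mean_b / mean_a) on raw areas; zeros are
replaced before the log2 transform by half the smallest nonzero area in the
table (configurable).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .io import FeatureTable
from .networking import modified_cosine

logger = logging.getLogger(__name__)

__all__ = [
    "NOISE_THRESHOLDS",
    "RichnessResult",
    "richness",
    "poisson_count_test",
    "differential_abundance",
    "bray_curtis",
    "PCoAResult",
    "pcoa",
    "OverlapResult",
    "match_features_across_matrices",
]

#: Matrix-specific peak-area noise thresholds (arbitrary area units).
NOISE_THRESHOLDS: dict[str, float] = {
    "colon": 250_000,
    "urine-gf-fmt": 250_000,
    "serum": 50_000,
    "urine-abx": 300_000,
}


@dataclass
class RichnessResult:
    """Per-sample count of features above the noise threshold."""

    counts: pd.Series  # indexed by sample id
    noise_threshold: float
    groups: pd.Series

    def by_group(self) -> dict[str, list[int]]:
        return {g: self.counts[self.groups == g].tolist() for g in self.groups.unique()}


def richness(table: FeatureTable, noise_threshold: float) -> RichnessResult:
    """Features per sample with area strictly greater than the threshold."""
    if noise_threshold < 0:
        raise ValueError("noise_threshold must be >= 0")
    counts = (table.areas > noise_threshold).sum(axis=0)
    counts.name = "richness"
    return RichnessResult(
        counts=counts, noise_threshold=float(noise_threshold), groups=table.samples["group"]
    )


def poisson_count_test(counts_a, counts_b) -> tuple[float, float]:
    """Two-group Poisson log-linear comparison of richness counts.

    Returns ``(rate_ratio, p_value)`` where ``rate_ratio`` is the group-B
    mean over the group-A mean and the p-value is a Wald test on the log
    rate ratio with SE = sqrt(1/sum_a + 1/sum_b) (the standard error of the
    Poisson GLM group coefficient).  A zero group total triggers a 0.5
    continuity correction on both sums, logged.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("each group needs at least one count")
    if np.any(a < 0) or np.any(b < 0) or np.any(a != np.floor(a)) or np.any(b != np.floor(b)):
        raise ValueError("counts must be non-negative integers")
    sum_a, sum_b = a.sum(), b.sum()
    if sum_a == 0 or sum_b == 0:
        logger.info("zero group total; applying 0.5 continuity correction to both sums")
        sum_a += 0.5
        sum_b += 0.5
    rate_a = sum_a / a.size
    rate_b = sum_b / b.size
    rr = rate_b / rate_a
    se = np.sqrt(1.0 / sum_a + 1.0 / sum_b)
    z = np.log(rr) / se
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return float(rr), max(p, np.nextafter(0, 1))


def differential_abundance(
    table: FeatureTable,
    group_a: str,
    group_b: str,
    fdr_cut: float = 0.1,
    lfc_cut: float = 1.0,
    pseudo_area: float | None = None,
) -> pd.DataFrame:
    """Per-feature Welch t-tests on log2 areas with BH adjustment.

    Returns columns ``feature_id, log2fc, p_value, q_value, significant``;
    ``log2fc`` is log2 of the raw group-B/group-A mean ratio and a feature is
    significant iff ``q < fdr_cut`` and ``|log2fc| > lfc_cut``.  Zeros are
    replaced by ``pseudo_area`` (default: half the smallest nonzero area in
    the table) before the log transform; a feature with zero variance in
    both groups gets p = 1.0, logged.
    """
    ids_a = table.sample_ids(group_a)
    ids_b = table.sample_ids(group_b)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("need at least 2 samples per group")
    areas = table.areas
    if pseudo_area is None:
        nonzero = areas.to_numpy()[areas.to_numpy() > 0]
        pseudo_area = float(nonzero.min()) / 2.0 if nonzero.size else 1.0
    filled = areas.where(areas > 0, pseudo_area)
    log2a = np.log2(filled[ids_a].to_numpy())
    log2b = np.log2(filled[ids_b].to_numpy())

    mean_a = areas[ids_a].mean(axis=1).to_numpy()
    mean_b = areas[ids_b].mean(axis=1).to_numpy()
    with np.errstate(divide="ignore"):
        log2fc = np.log2(np.where(mean_b > 0, mean_b, pseudo_area)
                         / np.where(mean_a > 0, mean_a, pseudo_area))

    pvals = np.ones(len(areas))
    degenerate = (np.ptp(log2a, axis=1) == 0) & (np.ptp(log2b, axis=1) == 0)
    if degenerate.any():
        logger.info("%d feature(s) with zero variance in both groups; p set to 1", degenerate.sum())
    ok = ~degenerate
    if ok.any():
        res = sps.ttest_ind(log2b[ok], log2a[ok], axis=1, equal_var=False)
        pvals[ok] = np.nan_to_num(res.pvalue, nan=1.0)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "feature_id": areas.index,
            "log2fc": log2fc,
            "p_value": pvals,
            "q_value": qvals,
            "significant": (qvals < fdr_cut) & (np.abs(log2fc) > lfc_cut),
        }
    ).reset_index(drop=True)
    return out


def bray_curtis(table: FeatureTable) -> pd.DataFrame:
    """Sample x sample Bray-Curtis dissimilarities, d = sum|x-y| / sum(x+y).

    Symmetric with zero diagonal, bounded in [0, 1].  The distance between
    two all-zero samples is defined as 0 (logged).
    """
    x = table.areas.to_numpy().T  # samples x features
    d = pdist(x, metric="braycurtis")
    if np.isnan(d).any():
        logger.info("all-zero sample pair(s); Bray-Curtis distance defined as 0")
        d = np.nan_to_num(d, nan=0.0)
    return pd.DataFrame(squareform(d), index=table.areas.columns, columns=table.areas.columns)


@dataclass
class PCoAResult:
    """Classical (metric) multidimensional scaling of a distance matrix."""

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    variance_fraction: np.ndarray  # per retained axis, relative to sum of positive eigenvalues


def pcoa(distance_matrix: pd.DataFrame | np.ndarray, k: int = 2) -> PCoAResult:
    """Principal coordinates analysis via double centering + eigendecomposition.

    The top-``k`` axes (by eigenvalue) are returned; negative eigenvalues,
    which arise for non-Euclidean dissimilarities such as Bray-Curtis, are
    reported in ``eigenvalues`` rather than silently dropped.  Asymmetric
    input raises.
    """
    if isinstance(distance_matrix, pd.DataFrame):
        labels = list(distance_matrix.index)
        d = distance_matrix.to_numpy(dtype=float)
    else:
        d = np.asarray(distance_matrix, dtype=float)
        labels = list(range(d.shape[0]))
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    k = min(k, n)
    pos = np.clip(eigvals[:k], 0.0, None)
    coords = eigvecs[:, :k] * np.sqrt(pos)
    total_pos = eigvals[eigvals > 0].sum()
    varfrac = (np.clip(eigvals[:k], 0, None) / total_pos) if total_pos > 0 else np.zeros(k)
    return PCoAResult(
        coordinates=pd.DataFrame(
            coords, index=labels, columns=[f"PCo{i + 1}" for i in range(k)]
        ),
        eigenvalues=eigvals,
        variance_fraction=varfrac,
    )


@dataclass
class OverlapResult:
    """Cross-matrix feature matching: components and Venn-style counts."""

    components: list[dict[str, list[str]]]  # matrix -> feature ids, one dict per matched group
    counts: dict[tuple[str, ...], int] = field(default_factory=dict)  # sorted matrix tuple -> count

    def count(self, *matrices: str) -> int:
        return self.counts.get(tuple(sorted(matrices)), 0)


def match_features_across_matrices(
    tables: dict[str, FeatureTable],
    prec_tol: float = 0.01,
    rt_tol: float = 12.0,
    cosine_min: float = 0.7,
    frag_tol: float = 0.01,
) -> OverlapResult:
    """Match features across matrices by m/z, RT and MS/MS similarity.

    Two features from different matrices match when |delta m/z| <= prec_tol,
    |delta RT| <= rt_tol (seconds) and, when both carry a representative
    spectrum, their modified cosine is at least ``cosine_min``; if either
    spectrum is missing the comparison falls back to m/z + RT, logged.
    Matched features are merged into connected components; ``counts`` gives,
    for every combination of matrices, the number of components observed in
    exactly that set (Venn-style, exclusive counts).
    """
    import networkx as nx

    g = nx.Graph()
    feats = []
    for matrix, table in tables.items():
        for fid, row in table.features.iterrows():
            node = (matrix, str(fid))
            g.add_node(node)
            feats.append((matrix, str(fid), float(row["mz"]), float(row["rt"]),
                          table.spectra.get(str(fid)) if table.spectra else None))
    warned = False
    for (ma, fa, mza, rta, sa), (mb, fb, mzb, rtb, sb) in itertools.combinations(feats, 2):
        if ma == mb:
            continue
        if abs(mza - mzb) > prec_tol or abs(rta - rtb) > rt_tol:
            continue
        if sa is not None and sb is not None:
            if modified_cosine(sa, sb, frag_tol)[0] < cosine_min:
                continue
        elif not warned:
            logger.info("missing representative spectra; falling back to m/z + RT matching")
            warned = True
        g.add_edge((ma, fa), (mb, fb))

    components = []
    counts: dict[tuple[str, ...], int] = {}
    for comp in nx.connected_components(g):
        members: dict[str, list[str]] = {}
        for matrix, fid in comp:
            members.setdefault(matrix, []).append(fid)
        components.append(members)
        key = tuple(sorted(members))
        counts[key] = counts.get(key, 0) + 1
    return OverlapResult(components=components, counts=counts)
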