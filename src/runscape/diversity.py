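"""Diversity summaries, genetic distances, PCA and neighbor-joining trees.

Observed/expected heterozygosity and polymorphism proportions are computed
per population; pairwise sample distances default to 1 - IBS (identity by
state, allele-sharing) with pairwise deletion of missing calls; population
substructure comes from an eigen-decomposition of the 2p-centred dosage
matrix; trees are built with Saitou–Nei neighbor-joining (deterministic
lowest-index tie-breaking, negative branch lengths clamped to zero with the
deficit moved to the adjacent branch) and exported as Newick via scikit-bio.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.tree import TreeNode

from .datamodel import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)


class DiversityError(ValueError):
    pass


def diversity_summary(
    dataset: GenotypeDataset, unbiased: bool = False
) -> pd.DataFrame:
    """Per-population Ho, He and proportion of polymorphic markers.

    Ho is the mean across markers of the heterozygote fraction among called
    samples; He the mean of ``2p(1-p)`` (times ``n/(n-1)`` when
    ``unbiased``); PN the fraction of markers with ``0 < p < 1`` in the
    population.  Markers with no called genotype in a population are
    excluded from its means.
    """
    rows = []
    for pop in dataset.populations:
        sub = dataset.subset_samples(dataset.population_indices(pop))
        g = sub.genotypes
        called = g != MISSING
        n_called = called.sum(axis=0).astype(float)
        ok = n_called > 0
        het_frac = np.zeros(g.shape[1])
        het_frac[ok] = (g == 1).sum(axis=0)[ok] / n_called[ok]
        with np.errstate(divide="ignore", invalid="ignore"):
            p = ((g == 1).sum(axis=0) + 2.0 * (g == 2).sum(axis=0)) / (
                2.0 * n_called
            )
        he = np.zeros(g.shape[1])
        he[ok] = 2.0 * p[ok] * (1.0 - p[ok])
        if unbiased:
            corr_ok = ok & (n_called > 1)
            he[corr_ok] *= n_called[corr_ok] / (n_called[corr_ok] - 1.0)
        poly = ok & (p > 0.0) & (p < 1.0)
        denom = float(ok.sum()) or 1.0
        rows.append(
            {
                "population": pop,
                "n_samples": sub.n_samples,
                "ho": float(het_frac[ok].mean()) if ok.any() else 0.0,
                "he": float(he[ok].mean()) if ok.any() else 0.0,
                "pn": float(poly.sum() / denom),
            }
        )
    return pd.DataFrame(rows, columns=["population", "n_samples", "ho", "he", "pn"])


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative sample-by-sample distance matrix."""

    matrix: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise DiversityError("distance matrix must be square")
        if m.shape[0] != len(self.ids):
            raise DiversityError("id count does not match matrix size")
        if not np.allclose(m, m.T, atol=1e-12):
            raise DiversityError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0.0):
            raise DiversityError("distance matrix diagonal must be zero")
        if np.any(m < 0.0):
            raise DiversityError("distances must be nonnegative")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.ids), columns=list(self.ids))


def ibs_distance(dataset: GenotypeDataset, metric: str = "ibs") -> DistanceMatrix:
    """Pairwise genetic distances with pairwise deletion of missing calls.

    ``metric='ibs'`` (default): ``d = 1 - mean(shared allele count / 2)``,
    i.e. mean ``|g_i - g_j| / 2`` over mutually called markers.
    ``metric='hamming'``: fraction of mutually called markers with different
    genotype codes.
    """
    if metric not in ("ibs", "hamming"):
        raise DiversityError(f"unknown distance metric {metric!r}")
    n = dataset.n_samples
    if n < 2:
        raise DiversityError("need at least two samples")
    g = dataset.genotypes.astype(np.int16)
    called = dataset.called_mask()
    d = np.zeros((n, n))
    for i in range(n):
        both = called[i] & called[i + 1 :]
        n_both = both.sum(axis=1)
        if np.any(n_both == 0):
            j = int(np.flatnonzero(n_both == 0)[0]) + i + 1
            raise DiversityError(
                f"samples {dataset.sample_ids[i]!r} and "
                f"{dataset.sample_ids[j]!r} share no called markers"
            )
        if metric == "ibs":
            diff = np.abs(g[i] - g[i + 1 :]) * both
            d[i, i + 1 :] = diff.sum(axis=1) / (2.0 * n_both)
        else:
            diff = (g[i] != g[i + 1 :]) & both
            d[i, i + 1 :] = diff.sum(axis=1) / n_both
    d = d + d.T
    return DistanceMatrix(matrix=d, ids=tuple(dataset.sample_ids))


def population_distance_matrix(
    dm: DistanceMatrix, populations: pd.Series | dict[str, str]
) -> DistanceMatrix:
    """Collapse a sample-level matrix to mean between-population distances
    (zero diagonal)."""
    pop_of = dict(populations) if not isinstance(populations, pd.Series) else (
        populations.to_dict()
    )
    labels = list(dict.fromkeys(pop_of[s] for s in dm.ids))
    idx = {lab: [k for k, s in enumerate(dm.ids) if pop_of[s] == lab] for lab in labels}
    out = np.zeros((len(labels), len(labels)))
    for a, la in enumerate(labels):
        for b in range(a + 1, len(labels)):
            lb = labels[b]
            block = dm.matrix[np.ix_(idx[la], idx[lb])]
            out[a, b] = out[b, a] = float(block.mean())
    return DistanceMatrix(matrix=out, ids=tuple(labels))


@dataclass(frozen=True)
class PCAResult:
    coordinates: pd.DataFrame  # samples x components
    eigenvalues: np.ndarray
    variance_pct: np.ndarray

    def __post_init__(self) -> None:
        v = self.variance_pct
        if np.any(v < -1e-9) or v.sum() > 100.0 + 1e-6:
            raise DiversityError("variance percentages outside [0, 100]")
        if np.any(np.diff(v) > 1e-9):
            raise DiversityError("variance percentages must be non-increasing")


def pca(
    dataset: GenotypeDataset, k: int = 10, standardize: bool = False
) -> PCAResult:
    """Principal components of the centred dosage matrix.

    Missing genotypes are imputed to the column mean (2p) and columns are
    centred by it; ``standardize`` additionally scales columns to unit
    variance (constant columns are left unscaled).  Eigenvalues are those of
    the sample covariance matrix; variance percentages are relative to the
    total variance.
    """
    n, m = dataset.n_samples, dataset.n_markers
    if not 0 < k < min(n, m):
        raise DiversityError(f"k={k} must satisfy 0 < k < min(n, m)={min(n, m)}")
    x = dataset.genotypes.astype(float)
    miss = dataset.genotypes == MISSING
    x[miss] = np.nan
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(miss)
    x[inds] = col_mean[inds[1]]
    x -= col_mean
    if standardize:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0.0] = 1.0
        x /= sd
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eig = s**2 / (n - 1)
    total = eig.sum()
    coords = u[:, :k] * s[:k]
    return PCAResult(
        coordinates=pd.DataFrame(
            coords,
            index=pd.Index(dataset.sample_ids, name="sample_id"),
            columns=[f"PC{i + 1}" for i in range(k)],
        ),
        eigenvalues=eig[:k],
        variance_pct=(100.0 * eig[:k] / total) if total > 0 else np.zeros(k),
    )


# ---------------------------------------------------------------------------
# Neighbor joining

def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor-joining tree.

    Iteratively joins the pair minimising the Q criterion, breaking ties by
    the lowest (i, j) index pair in the current matrix ordering.  Negative
    branch lengths are clamped to zero with the deficit moved to the sibling
    branch (logged).  Returns an unrooted tree as a trifurcating-rooted
    scikit-bio ``TreeNode`` whose leaves carry the input ids.
    """
    if dm.n < 3:
        raise DiversityError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=str(i)) for i in dm.ids]
    d = dm.matrix.copy()
    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = (0, 1)
        best_q = np.inf
        for i in range(n):
            for j in range(i + 1, n):
                if q[i, j] < best_q - 1e-12:
                    best_q = q[i, j]
                    best = (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        new = TreeNode(children=[child_i, child_j])
        du = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d_new = np.empty((len(keep) + 1, len(keep) + 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = du[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[k] for k in keep] + [new]
    # closed-form three-point resolution
    (a, b, c), dd = nodes, d
    la = 0.5 * (dd[0, 1] + dd[0, 2] - dd[1, 2])
    lb = 0.5 * (dd[0, 1] + dd[1, 2] - dd[0, 2])
    lc = 0.5 * (dd[0, 2] + dd[1, 2] - dd[0, 1])
    for node, ln in zip((a, b, c), (la, lb, lc)):
        if ln < 0:
            logger.warning("clamping negative terminal branch %.3g to 0", ln)
            ln = 0.0
        node.length = float(ln)
    return TreeNode(children=[a, b, c])


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0.0:
        logger.warning("clamping negative branch %.3g to 0 (deficit moved)", li)
        lj += li
        li = 0.0
    if lj < 0.0:
        logger.warning("clamping negative branch %.3g to 0 (deficit moved)", lj)
        li += lj
        lj = 0.0
    return float(li), float(max(lj, 0.0))


def to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def from_newick(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick), format="newick")
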