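"""Voxel-overlap scores between binary masks: the connectivity proxy.

For two masks on the same registered grid, P1 is the percentage of mask 1's
voxels that fall inside mask 2 and P2 the converse; the reported score is
their mean (max and min are available as alternative combine rules and give
similar pictures).  A score above 15% — strictly — counts as a significant
potential interaction, a threshold validated against double-labelling.

Matrices of scores between mask families are clustered by hierarchical
agglomerative clustering (Euclidean distance, complete linkage) for heatmap
display; the conventional -1 sentinel on the self-vs-self diagonal is a
rendering device only and never enters the numeric matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import linregress

from .volumes import BinaryMask, assert_same_grid

COMBINE_RULES = ("mean", "max", "min")
#: percent overlap above which a potential interaction counts as significant
INTERACTION_THRESHOLD = 15.0
#: diagonal sentinel used only when rendering self-vs-self heatmaps
SELF_DISPLAY_SENTINEL = -1.0


def directional_overlap(a: BinaryMask, b: BinaryMask) -> float:
    """Percentage of ``a``'s voxels that lie inside ``b``: 100 |a & b| / |a|."""
    assert_same_grid(a, b)
    n_a = a.n_voxels
    if n_a == 0:
        raise ValueError("mask 'a' is empty: directional overlap undefined")
    return 100.0 * int(np.logical_and(a.data, b.data).sum()) / n_a


@dataclass(frozen=True)
class OverlapResult:
    """Both directional overlaps and their mean/max/min combinations."""

    p1: float
    p2: float

    @property
    def mean_score(self) -> float:
        return (self.p1 + self.p2) / 2.0

    @property
    def max_score(self) -> float:
        return max(self.p1, self.p2)

    @property
    def min_score(self) -> float:
        return min(self.p1, self.p2)

    def combined(self, rule: str = "mean") -> float:
        if rule == "mean":
            return self.mean_score
        if rule == "max":
            return self.max_score
        if rule == "min":
            return self.min_score
        raise ValueError(f"combine rule must be one of {COMBINE_RULES}, got {rule!r}")


def overlap_score(a: BinaryMask, b: BinaryMask, combine: str = "mean") -> OverlapResult:
    """Overlap score of a mask pair (the ``combine`` argument only checks
    validity here; all three combinations are carried on the result)."""
    if combine not in COMBINE_RULES:
        raise ValueError(f"combine rule must be one of {COMBINE_RULES}, got {combine!r}")
    if b.n_voxels == 0:
        raise ValueError("mask 'b' is empty: directional overlap undefined")
    p1 = directional_overlap(a, b)
    p2 = directional_overlap(b, a)
    return OverlapResult(p1=p1, p2=p2)


@dataclass
class OverlapMatrix:
    """Percentage overlap scores between two mask families.

    ``values`` is a DataFrame (rows = set 1, columns = set 2) of combined
    scores in [0, 100]; with identical row/column label sets and the mean
    rule the matrix is symmetric with a 100 diagonal.
    """

    values: pd.DataFrame
    combine_rule: str = "mean"

    @property
    def row_labels(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_labels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def is_square_same_labels(self) -> bool:
        return self.row_labels == self.col_labels

    def to_csv(self, path) -> None:
        self.values.to_csv(path)

    @classmethod
    def from_csv(cls, path, combine_rule: str = "mean") -> "OverlapMatrix":
        return cls(pd.read_csv(path, index_col=0), combine_rule=combine_rule)

    def render_values(self) -> pd.DataFrame:
        """Copy with the diagonal set to the display sentinel (-1) when rows
        and columns are the same family — for heatmap rendering only."""
        out = self.values.copy()
        if self.is_square_same_labels:
            np.fill_diagonal(out.values, SELF_DISPLAY_SENTINEL)
        return out


def pairwise_matrix(
    set1: list[BinaryMask], set2: list[BinaryMask], combine: str = "mean"
) -> OverlapMatrix:
    """Overlap-score matrix between two mask families.

    The diagonal keeps its true score (100 for a mask against itself); the
    -1 sentinel is applied only at render time.  Empty masks make the score
    undefined and are reported together.
    """
    if combine not in COMBINE_RULES:
        raise ValueError(f"combine rule must be one of {COMBINE_RULES}, got {combine!r}")
    empties = [m.label for m in list(set1) + list(set2) if m.n_voxels == 0]
    if empties:
        raise ValueError(f"empty masks have undefined overlap: {sorted(set(empties))}")
    rows = [m.label for m in set1]
    cols = [m.label for m in set2]
    values = np.empty((len(set1), len(set2)))
    for i, a in enumerate(set1):
        for j, b in enumerate(set2):
            values[i, j] = overlap_score(a, b).combined(combine)
    return OverlapMatrix(
        values=pd.DataFrame(values, index=rows, columns=cols), combine_rule=combine
    )


@dataclass
class InteractionSummary:
    """Classification of matrix cells against the interaction threshold."""

    threshold: float
    significant: pd.DataFrame  # boolean, same shape as the matrix
    frac_rows_with_any: float
    frac_rows_with_none: float


def classify_interactions(
    m: OverlapMatrix, threshold: float = INTERACTION_THRESHOLD
) -> InteractionSummary:
    """Cells strictly above ``threshold`` percent are significant potential
    interactions; row fractions summarise how many row cell types have at
    least one.  The diagonal is excluded when rows and columns are the same
    family (a mask always overlaps itself)."""
    sig = m.values > threshold
    counted = sig.copy()
    if m.is_square_same_labels:
        np.fill_diagonal(counted.values, False)
    any_hit = counted.any(axis=1)
    frac_any = float(any_hit.mean()) if len(any_hit) else 0.0
    return InteractionSummary(
        threshold=float(threshold),
        significant=sig,
        frac_rows_with_any=frac_any,
        frac_rows_with_none=1.0 - frac_any,
    )


@dataclass
class ClusterResult:
    row_order: list[int]
    col_order: list[int]
    row_linkage: np.ndarray
    col_linkage: np.ndarray

    def ordered_values(self, m: OverlapMatrix) -> pd.DataFrame:
        return m.values.iloc[self.row_order, self.col_order]


def cluster_matrix(m: OverlapMatrix) -> ClusterResult:
    """Hierarchical agglomerative clustering (Euclidean distance, complete
    linkage) of the matrix's row vectors and column vectors independently;
    the returned leaf orders are for heatmap rendering.  Scores are
    clustered as they are (no standardisation)."""
    vals = m.values.to_numpy(dtype=float)
    if vals.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    row_link = hierarchy.linkage(pdist(vals, metric="euclidean"), method="complete")
    row_order = list(hierarchy.leaves_list(row_link))
    if vals.shape[1] >= 2:
        col_link = hierarchy.linkage(pdist(vals.T, metric="euclidean"), method="complete")
        col_order = list(hierarchy.leaves_list(col_link))
    else:
        col_link = np.empty((0, 4))
        col_order = list(range(vals.shape[1]))
    return ClusterResult(
        row_order=row_order, col_order=col_order,
        row_linkage=row_link, col_linkage=col_link,
    )


@dataclass(frozen=True)
class CorrelationResult:
    slope: float
    intercept: float
    r_squared: float
    n: int
    degenerate: bool = False


def axon_dendrite_relation(
    axon_m: OverlapMatrix, dend_m: OverlapMatrix
) -> CorrelationResult:
    """Least-squares relationship between a family's axonal and dendritic
    overlap scores (does co-projection of outputs predict shared inputs?).

    Both matrices must carry the same row/column label sets; the diagonal is
    excluded.  Axonal scores are regressed on dendritic scores by ordinary
    least squares and R^2 reported.  A constant predictor explains nothing:
    R^2 = 0 with the degenerate flag set.
    """
    if (axon_m.row_labels != dend_m.row_labels) or (axon_m.col_labels != dend_m.col_labels):
        raise ValueError("axon and dendrite matrices must share row/column labels")
    av = axon_m.values.to_numpy(dtype=float)
    dv = dend_m.values.to_numpy(dtype=float)
    if axon_m.is_square_same_labels:
        keep = ~np.eye(av.shape[0], dtype=bool)
    else:
        keep = np.ones(av.shape, dtype=bool)
    y, x = av[keep], dv[keep]
    if np.ptp(x) == 0:
        import warnings

        warnings.warn("constant dendritic scores: R^2 reported as 0")
        return CorrelationResult(0.0, float(np.mean(y)), 0.0, n=len(y), degenerate=True)
    fit = linregress(x, y)
    return CorrelationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(y),
    )


def plot_heatmap(m: OverlapMatrix, cluster: "ClusterResult | None" = None, ax=None,
                 self_sentinel: bool = True):
    """Render the overlap matrix as a white-to-black heatmap (optionally in
    clustered leaf order), applying the -1 diagonal sentinel at render time
    for self-vs-self matrices."""
    import matplotlib.pyplot as plt

    vals = m.render_values() if self_sentinel else m.values.copy()
    if cluster is not None:
        vals = vals.iloc[cluster.row_order, cluster.col_order]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(vals.to_numpy(), cmap="Greys", vmin=0, vmax=100, aspect="auto")
    ax.set_xticks(range(len(vals.columns)), vals.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(vals.index)), vals.index, fontsize=6)
    ax.figure.colorbar(im, ax=ax, label="% overlap")
    return ax
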