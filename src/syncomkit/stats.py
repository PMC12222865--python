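"""Statistical layer: width↔score regressions, Gaussian width
distributions, phylogenetic-distance-binned correlations, and
hierarchical clustering of producibility panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist

__all__ = [
    "RegressionFit",
    "GaussianFit",
    "linreg",
    "gaussian_fit",
    "binned_distance_correlation",
    "hier_cluster",
    "patristic_distances",
]


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least squares y = slope·x + intercept."""

    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int
    stderr: float
    intercept_stderr: float
    x_mean: float
    s_xx: float
    resid_var: float

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def confidence_band(self, x, level: float = 0.95):
        """Half-width of the mean-response confidence band at ``x``."""
        x = np.asarray(x, dtype=float)
        t = sps.t.ppf(0.5 + level / 2, self.n - 2)
        se = np.sqrt(self.resid_var * (1.0 / self.n + (x - self.x_mean) ** 2 / self.s_xx))
        return t * se


@dataclass(frozen=True)
class GaussianFit:
    mu: float
    sigma: float
    amplitude: float
    goodness: float  # R² of the histogram fit


def linreg(x, y) -> RegressionFit:
    """OLS fit with R² and the two-sided p-value of the slope.

    For simple regression the t-test on the slope is equivalent to the
    model F-test, so one p-value serves both.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("regression needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: x has zero variance")
    res = sps.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    dof = len(x) - 2
    return RegressionFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r2=float(res.rvalue**2), p_value=float(res.pvalue), n=len(x),
        stderr=float(res.stderr), intercept_stderr=float(res.intercept_stderr),
        x_mean=float(np.mean(x)), s_xx=float(np.sum((x - np.mean(x)) ** 2)),
        resid_var=float(np.sum(resid**2) / dof) if dof > 0 else float("nan"),
    )


def _gauss(x, amplitude, mu, sigma):
    return amplitude * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def gaussian_fit(values, bins: int | str = "fd") -> GaussianFit:
    """Nonlinear least-squares Gaussian fit to a histogram of ``values``.

    ``bins`` follows numpy's histogram conventions (Freedman–Diaconis by
    default). Degenerate (near-constant) data raise rather than return
    a zero-width Gaussian; a bad fit is reported through low
    ``goodness`` (R² of the fitted curve against the bin counts).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise ValueError("gaussian fit needs n >= 10")
    s = float(np.std(values))
    if s == 0:
        raise ValueError("degenerate data: zero variance (sigma -> 0)")
    counts, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = (float(counts.max()), float(np.mean(values)), s)
    try:
        popt, _ = curve_fit(_gauss, centers, counts, p0=p0, maxfev=10_000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"gaussian fit failed to converge (initial guesses "
            f"amplitude={p0[0]:.4g}, mu={p0[1]:.4g}, sigma={p0[2]:.4g})"
        ) from exc
    amplitude, mu, sigma = popt
    fitted = _gauss(centers, *popt)
    ss_res = float(np.sum((counts - fitted) ** 2))
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    goodness = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return GaussianFit(float(mu), abs(float(sigma)), float(amplitude), goodness)


def binned_distance_correlation(
    pair_scores: pd.DataFrame,
    distances: pd.DataFrame,
    bin_edges,
    score_col: str = "score",
    width_col: str = "mean_width",
) -> pd.DataFrame:
    """Per-distance-bin regression of a community score against width.

    ``pair_scores`` needs columns ``strain_a``, ``strain_b``, the score
    and the mean width; ``distances`` is a symmetric labelled matrix.
    Pairs are partitioned by the phylogenetic distance between the two
    members; each bin with ≥3 pairs gets an OLS fit of score vs width,
    smaller bins are flagged empty rather than dropped.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be increasing with >= 2 entries")
    missing = [
        (a, b) for a, b in zip(pair_scores["strain_a"], pair_scores["strain_b"])
        if a not in distances.index or b not in distances.columns
    ]
    if missing:
        raise KeyError(f"no distance for pair(s) {missing[:5]}")
    d = np.array([
        distances.loc[a, b]
        for a, b in zip(pair_scores["strain_a"], pair_scores["strain_b"])
    ])
    which = np.digitize(d, edges[1:-1], right=False)
    rows = []
    for b in range(len(edges) - 1):
        sel = pair_scores[which == b]
        row = {"bin_low": edges[b], "bin_high": edges[b + 1], "n": len(sel)}
        if len(sel) >= 3 and np.ptp(sel[width_col].to_numpy()) > 0:
            fit = linreg(sel[width_col], sel[score_col])
            row.update(slope=fit.slope, intercept=fit.intercept,
                       r2=fit.r2, p_value=fit.p_value, empty=False)
        else:
            row.update(slope=np.nan, intercept=np.nan, r2=np.nan,
                       p_value=np.nan, empty=True)
        rows.append(row)
    return pd.DataFrame(rows)


def hier_cluster(matrix: pd.DataFrame) -> dict:
    """Average-linkage hierarchical clustering of both matrix axes.

    Euclidean distances; rows/columns are pre-sorted by label so the
    result is invariant to input permutation and ties break on labels.
    Returns row/column leaf orders and the two linkage matrices.
    """
    if not np.all(np.isfinite(matrix.to_numpy())):
        raise ValueError("matrix contains non-finite entries; impute first")
    matrix = matrix.sort_index(axis=0).sort_index(axis=1)

    def _order(frame: pd.DataFrame):
        if len(frame) < 2:
            return list(frame.index), None
        Z = hierarchy.linkage(pdist(frame.to_numpy()), method="average")
        leaves = hierarchy.leaves_list(Z)
        return [frame.index[i] for i in leaves], Z

    row_order, row_linkage = _order(matrix)
    col_order, col_linkage = _order(matrix.T)
    return {
        "row_order": row_order, "col_order": col_order,
        "row_linkage": row_linkage, "col_linkage": col_linkage,
        "matrix": matrix.loc[row_order, col_order],
    }


def patristic_distances(tree_path) -> pd.DataFrame:
    """Pairwise patristic distances (summed branch lengths) from newick."""
    import dendropy

    tree = dendropy.Tree.get(path=str(tree_path), schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    mat = np.zeros((len(taxa), len(taxa)))
    for i, ti in enumerate(taxa):
        for j, tj in enumerate(taxa):
            if i < j:
                mat[i, j] = mat[j, i] = pdm.patristic_distance(ti, tj)
    return pd.DataFrame(mat, index=labels, columns=labels)
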