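"""Covariate-adjusted association statistics for brain-behavior analyses.

Global graph measures are related to the continuous symptom score with
partial correlations (covariates: age, sex, handedness, FSIQ, mean FD),
Bonferroni-corrected across the measure family, and complemented by
Zellner–Siow (JZS) Bayes factors BF01 quantifying evidence *for* the null;
BF01 > 3 is read as substantial null evidence.

Nodal maps (participation, within-module degree) are related to the score
with mass-univariate regression per node; the resulting t-map is corrected
for multiple comparisons by cluster-extent thresholding: suprathreshold
nodes (|t| beyond the two-sided voxel threshold, split by sign) are grouped
into connected components on the node lattice, and only components larger
than a Monte-Carlo-calibrated minimum size ``k_min`` are declared
significant (strict ``k > k_min``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, ndimage, sparse, stats
from scipy.ndimage import gaussian_filter
from scipy.sparse.csgraph import connected_components

#: default two-sided per-node threshold for cluster forming
VOXEL_P = 0.005
#: default cluster-extent threshold (nodes); "k > k_min" rule
K_MIN = 26
#: JZS Cauchy prior scale on the standardized slope ("medium")
JZS_SCALE = np.sqrt(2) / 2

#: covariate set used in every individual-difference analysis
DEFAULT_COVARIATES = ("age", "sex", "handedness", "fsiq", "mean_fd")


@dataclass(frozen=True)
class AssociationResult:
    """Partial-correlation summary for one measure."""

    name: str
    r_part: float
    p_part: float
    bf01: float | None
    n_used: int


# ---------------------------------------------------------------------------
# outlier handling and design building

def exclude_outliers(values, n_sd: float = 3.0) -> np.ndarray:
    """Boolean retain-mask: drop values > ``n_sd`` SDs from the mean.

    The mean and SD are computed once over *all* values (outliers included,
    not re-iterated); a value exactly at mean + n_sd*SD is retained
    (strict ``>``).  Zero-variance input retains everyone with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 subjects for outlier screening")
    sd = v.std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance: no outliers excluded", stacklevel=2)
        return np.ones(v.size, dtype=bool)
    return np.abs(v - v.mean()) <= n_sd * sd


def covariate_design(
    phenotypes: pd.DataFrame, covariates=DEFAULT_COVARIATES
) -> np.ndarray:
    """Numeric design matrix (no intercept) from a phenotype table.

    ``sex`` is coded 0/1 (alphabetical category order); ``handedness``
    (3 levels) becomes two dummy columns against the first alphabetical
    level.  Numeric columns pass through unchanged.
    """
    cols = []
    for name in covariates:
        if name not in phenotypes.columns:
            raise ValueError(f"covariate {name!r} not in phenotype table")
        col = phenotypes[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
        else:
            levels = sorted(col.astype(str).unique())
            if len(levels) < 2:
                cols.append(np.zeros(len(col)))
            else:
                for lev in levels[1:]:
                    cols.append((col.astype(str) == lev).to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(phenotypes), 0))


def _residualize(v: np.ndarray, covariates) -> tuple[np.ndarray, int]:
    """OLS residuals of v on [intercept, covariates]; returns (resid, k_cov)."""
    v = np.asarray(v, dtype=float)
    n = v.shape[0]
    if covariates is None or np.size(covariates) == 0:
        return v - v.mean(axis=0), 0
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    design = np.column_stack([np.ones(n), c])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design")
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta, c.shape[1]


# ---------------------------------------------------------------------------
# partial correlation and Bayes factors

def partial_correlation(y, x, covariates=None, name: str = "") -> AssociationResult:
    """Partial Pearson correlation of y and x given covariates.

    Both variables are residualized on [intercept, covariates]; r is the
    Pearson correlation of the residuals and p comes from the t distribution
    with n - k - 2 degrees of freedom.  Symmetric in (y, x).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be 1-D of equal length")
    ry, k = _residualize(y, covariates)
    rx, _ = _residualize(x, covariates)
    n = y.size
    df = n - k - 2
    if df < 1:
        raise ValueError(f"not enough subjects (n={n}) for {k} covariates")
    denom = np.sqrt((ry**2).sum() * (rx**2).sum())
    if denom == 0:
        raise ValueError("zero-variance variable after residualization")
    r = float(np.clip((ry * rx).sum() / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return AssociationResult(name=name, r_part=r, p_part=p, bf01=None, n_used=n)


def bonferroni_threshold(alpha: float, n_tests: int) -> tuple[float, float]:
    """Family-wise corrected per-test threshold alpha / n_tests.

    Returns (raw, rounded-to-3-decimals), e.g. (0.05, 4) -> (0.0125, 0.013).
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    raw = alpha / n_tests
    return raw, round(raw, 3)


def _jzs_log_integrand(g, n, r2, scale):
    # Zellner–Siow one-predictor marginal, g ~ InvGamma(1/2, scale^2 * n / 2),
    # in log space to avoid overflow at large n
    g = np.asarray(g, dtype=float)
    return (
        ((n - 2) / 2.0) * np.log1p(g)
        - ((n - 1) / 2.0) * np.log1p(g * (1.0 - r2))
        + 0.5 * np.log(scale**2 * n / (2.0 * np.pi))
        - 1.5 * np.log(g)
        - scale**2 * n / (2.0 * g)
    )


def _jzs_bf10(n, r2, scale):
    """BF10 by shifted adaptive quadrature of the Zellner–Siow integral."""
    grid = np.logspace(-6, 8, 400)
    shift = float(np.max(_jzs_log_integrand(grid, n, r2, scale)))
    val, _ = integrate.quad(
        lambda g: np.exp(_jzs_log_integrand(g, n, r2, scale) - shift),
        0,
        np.inf,
        limit=300,
    )
    return float(np.exp(np.log(val) + shift))


def jzs_bf01(y, x, covariates=None, scale: float = JZS_SCALE) -> float:
    """JZS Bayes factor BF01 for adding x to a covariates-only linear model.

    The null model contains the intercept and covariates; the alternative
    adds x with a Cauchy(0, ``scale``) prior on its standardized slope
    (default "medium", sqrt(2)/2).  Covariates are handled by residualizing
    y and x and reducing the effective sample size to n - k_cov; BF10 is the
    Zellner–Siow integral over the g-prior, evaluated by adaptive
    quadrature, and BF01 = 1 / BF10.  BF01 > 3 is conventionally read as
    substantial evidence for the null (no association).
    """
    x = np.asarray(x, dtype=float)
    if x.std() == 0:
        raise ValueError("zero-variance predictor")
    res = partial_correlation(y, x, covariates)
    k = (np.asarray(covariates).reshape(len(x), -1).shape[1]
         if covariates is not None and np.size(covariates) else 0)
    n_eff = res.n_used - k
    if n_eff < 3:
        raise ValueError("not enough effective observations for a Bayes factor")
    r2 = res.r_part**2
    return float(1.0 / _jzs_bf10(n_eff, r2, scale))


def associate_global_measures(
    y, measures: pd.DataFrame, covariates, alpha: float = 0.05
) -> pd.DataFrame:
    """Partial r / p / BF01 for each column of ``measures`` against y.

    Outliers (> 3 SD on the measure) are dropped per measure before the
    partial correlation; the Bonferroni threshold uses the family size
    = number of columns.
    """
    raw_thr, rounded_thr = bonferroni_threshold(alpha, measures.shape[1])
    rows = []
    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariates, dtype=float)
    for name in measures.columns:
        x = measures[name].to_numpy(dtype=float)
        keep = exclude_outliers(x)
        if x[keep].std() == 0:
            warnings.warn(
                f"measure {name!r} is constant: association undefined",
                stacklevel=2,
            )
            rows.append(
                {"measure": name, "r_part": np.nan, "p_part": np.nan,
                 "bf01": np.nan, "n_used": int(keep.sum()),
                 "significant": False, "bonferroni_p": rounded_thr}
            )
            continue
        res = partial_correlation(y[keep], x[keep], cov[keep], name=name)
        bf = jzs_bf01(y[keep], x[keep], cov[keep])
        rows.append(
            {
                "measure": name,
                "r_part": res.r_part,
                "p_part": res.p_part,
                "bf01": bf,
                "n_used": int(keep.sum()),
                "significant": res.p_part < raw_thr,
                "bonferroni_p": rounded_thr,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mass-univariate nodal regression

def mass_univariate_regression(maps, y, covariates=None) -> tuple[np.ndarray, np.ndarray]:
    """Per-node t statistic for the symptom-score slope controlling covariates.

    ``maps`` is (subjects, nodes).  Equivalent to regressing each node's
    metric on [intercept, covariates, y] and testing the y slope; computed
    via the partial correlation between each node column and y.  Constant
    node columns yield NaN with a warning.

    Returns (t, p) arrays of length n_nodes (two-sided p).
    """
    maps = np.asarray(maps, dtype=float)
    y = np.asarray(y, dtype=float)
    if maps.ndim != 2 or maps.shape[0] != y.size:
        raise ValueError("maps must be (n_subjects, n_nodes) matching y")
    rm, k = _residualize(maps, covariates)
    ry, _ = _residualize(y, covariates)
    n = y.size
    df = n - k - 2
    if df < 1:
        raise ValueError("not enough subjects for the covariate set")
    norm_m = np.sqrt((rm**2).sum(axis=0))
    norm_y = np.sqrt((ry**2).sum())
    const = norm_m == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant node column(s): t set to NaN",
            stacklevel=2,
        )
    if norm_y <= 1e-10 * np.sqrt(((y - y.mean()) ** 2).sum()):
        # score fully explained by covariates: no testable slope
        t = np.zeros(maps.shape[1])
        t[const] = np.nan
        return t, 2.0 * stats.t.sf(np.abs(t), df)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (rm.T @ ry) / (norm_m * norm_y)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt(df / (1.0 - r**2))
    t[const] = np.nan
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


# ---------------------------------------------------------------------------
# lattice adjacency and cluster-extent correction

def lattice_adjacency(coords, mode: str = "faces") -> sparse.csr_matrix:
    """Neighborhood graph of lattice nodes from their mm coordinates.

    ``mode='faces'`` connects nodes one grid step apart along a single axis
    (6-neighborhood, the conservative AFNI NN1 analog);
    ``mode='faces_edges_corners'`` connects all nodes within one step per
    axis (26-neighborhood).  The grid spacing is inferred as the smallest
    positive inter-node distance along any axis.
    """
    coords = np.asarray(coords, dtype=float)
    diffs = np.abs(coords[:, None, :] - coords[None, :, :])
    positive = diffs[diffs > 1e-9]
    if positive.size == 0:
        raise ValueError("degenerate coordinates: all nodes coincide")
    spacing = positive.min()
    step = np.round(diffs / spacing).astype(int)
    offgrid = np.abs(diffs - step * spacing) > 1e-6 * spacing
    if offgrid.any():
        raise ValueError("coordinates do not lie on a regular lattice")
    if mode == "faces":
        adj = (step.sum(axis=2) == 1)
    elif mode == "faces_edges_corners":
        adj = (step.max(axis=2) == 1)
    else:
        raise ValueError(f"unknown adjacency mode {mode!r}")
    np.fill_diagonal(adj, False)
    return sparse.csr_matrix(adj)


def _clusters(node_idx: np.ndarray, adjacency: sparse.spmatrix) -> list[np.ndarray]:
    """Connected components of the induced subgraph on ``node_idx``."""
    if node_idx.size == 0:
        return []
    sub = adjacency[node_idx][:, node_idx]
    n_comp, lab = connected_components(sub, directed=False)
    return [node_idx[lab == c] for c in range(n_comp)]


def cluster_extent_threshold(
    t_map,
    adjacency: sparse.spmatrix,
    voxel_p: float = VOXEL_P,
    k_min: int = K_MIN,
    df: int | None = None,
    t_crit: float | None = None,
    coords=None,
) -> pd.DataFrame:
    """Suprathreshold clusters larger than ``k_min`` (strict ``k > k_min``).

    Nodes with |t| beyond the two-sided ``voxel_p`` critical value are
    grouped per sign into connected components on ``adjacency``; surviving
    clusters report their sign, size k, peak statistic t_max and peak node.
    Provide either ``df`` (to derive the critical t) or ``t_crit`` directly.
    """
    t_map = np.asarray(t_map, dtype=float)
    if adjacency.shape[0] != t_map.size:
        raise ValueError("adjacency does not cover all nodes")
    if t_crit is None:
        if df is None:
            raise ValueError("need df or t_crit")
        t_crit = float(stats.t.isf(voxel_p / 2.0, df))
    rows = []
    with np.errstate(invalid="ignore"):
        for sign, mask in (
            (1, t_map > t_crit),
            (-1, t_map < -t_crit),
        ):
            for nodes in _clusters(np.where(mask)[0], adjacency):
                if nodes.size > k_min:
                    peak = nodes[np.argmax(np.abs(t_map[nodes]))]
                    row = {
                        "sign": sign,
                        "k": int(nodes.size),
                        "t_max": float(t_map[peak]),
                        "peak_node": int(peak),
                        "nodes": nodes.tolist(),
                    }
                    if coords is not None:
                        row["peak_x"], row["peak_y"], row["peak_z"] = (
                            np.asarray(coords, dtype=float)[peak].tolist()
                        )
                    rows.append(row)
    cols = ["sign", "k", "t_max", "peak_node", "nodes"]
    if coords is not None:
        cols += ["peak_x", "peak_y", "peak_z"]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["sign", "k"], ascending=[False, False]).reset_index(
        drop=True
    )


def _max_cluster_size(t_map, adjacency, t_crit) -> int:
    best = 0
    for mask in (t_map > t_crit, t_map < -t_crit):
        for nodes in _clusters(np.where(mask)[0], adjacency):
            best = max(best, nodes.size)
    return best


def monte_carlo_cluster_null(
    adjacency: sparse.spmatrix | None = None,
    voxel_p: float = VOXEL_P,
    fwe_alpha: float = 0.05,
    n_iter: int = 1000,
    seed: int = 0,
    mode: str = "permutation",
    maps=None,
    covariates=None,
    y=None,
    shape=None,
    fwhm_nodes: float = 1.0,
) -> tuple[int, np.ndarray]:
    """Monte-Carlo calibration of the cluster-extent threshold ``k_min``.

    Simulates null statistic maps, records the largest suprathreshold
    cluster per iteration (over both signs) and returns the smallest integer
    ``k_min`` whose exceedance probability P(max cluster > k_min) does not
    exceed ``fwe_alpha`` — the size such that the rule "k > k_min" controls
    family-wise error at ``fwe_alpha``.  ``fwe_alpha=1`` is satisfied by
    ``k_min = 0`` (every nonempty cluster passes), reported as minimum 0.

    ``mode='permutation'`` (default, distribution-free): the subject score
    vector is permuted against the observed metric ``maps`` (with
    ``covariates`` partialled out) and the nodal t-map recomputed.  If ``y``
    is None a standard-normal score vector is drawn once.
    ``mode='gaussian'``: smoothed Gaussian random fields on a lattice of
    ``shape`` with smoothing ``fwhm_nodes`` (FWHM in grid steps),
    standardized and thresholded at the matching normal quantile.

    Returns (k_min, null max-cluster sizes).
    """
    if n_iter < 100:
        raise ValueError("n_iter too small for a stable quantile")
    rng = np.random.default_rng(seed)
    max_sizes = np.empty(n_iter, dtype=int)
    if mode == "permutation":
        if maps is None:
            raise ValueError("permutation mode needs the observed metric maps")
        if adjacency is None:
            raise ValueError("permutation mode needs the node adjacency")
        maps = np.asarray(maps, dtype=float)
        n = maps.shape[0]
        if y is None:
            y = rng.standard_normal(n)
        y = np.asarray(y, dtype=float)
        rm, k = _residualize(maps, covariates)
        df = n - k - 2
        t_crit = float(stats.t.isf(voxel_p / 2.0, df))
        norm_m = np.sqrt((rm**2).sum(axis=0))
        norm_m[norm_m == 0] = np.nan
        cov = (np.asarray(covariates, dtype=float)
               if covariates is not None and np.size(covariates) else None)
        for it in range(n_iter):
            perm = rng.permutation(n)
            ry, _ = _residualize(y[perm], cov)
            ny = np.sqrt((ry**2).sum())
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.clip((rm.T @ ry) / (norm_m * ny), -1.0, 1.0)
                t = r * np.sqrt(df / (1.0 - r**2))
            max_sizes[it] = _max_cluster_size(np.nan_to_num(t), adjacency, t_crit)
    elif mode == "gaussian":
        if shape is None:
            raise ValueError("gaussian mode needs the lattice shape")
        sigma = fwhm_nodes / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        z_crit = float(stats.norm.isf(voxel_p / 2.0))
        structure = ndimage.generate_binary_structure(len(shape), 1)
        for it in range(n_iter):
            field = rng.standard_normal(shape)
            if sigma > 0:
                field = gaussian_filter(field, sigma)
            field = (field - field.mean()) / field.std()
            best = 0
            for mask in (field > z_crit, field < -z_crit):
                lab, n_comp = ndimage.label(mask, structure)
                if n_comp:
                    best = max(best, int(np.bincount(lab.ravel())[1:].max()))
            max_sizes[it] = best
    else:
        raise ValueError(f"unknown null mode {mode!r}")
    # smallest k with empirical P(max > k) <= alpha
    k_min = 0
    while np.mean(max_sizes > k_min) > fwe_alpha:
        k_min += 1
    return int(k_min), max_sizes
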