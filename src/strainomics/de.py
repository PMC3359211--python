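"""Time-course differential expression in the EDGE/ODP style.

Each gene is tested for within-class temporal modulation by comparing two
nested fits of its profile against time: an intercept-only null and a
natural cubic spline alternative.  The goodness-of-fit statistic
``(RSS0 - RSS1) / RSS1`` is referred to a resampling null obtained by
permuting the sample time labels, pooled across genes, and converted to
q-values with the Storey-Tibshirani estimator.  An optional ODP-style
statistic that borrows every gene's fitted models to score each gene is also
provided.  Selected genes are grouped into fermentation phases by dChip-like
hierarchical clustering (1 - Pearson distance, centroid linkage) and scored
for COG-category over/under-representation with the doubling/halving rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .expression import ExpressionStudy

DEFAULT_Q_THRESHOLD = 0.001


def natural_spline_basis(x: np.ndarray, df: int = 3) -> np.ndarray:
    """Natural cubic spline basis (df columns, intercept excluded).

    Knots sit at quantiles of the distinct values of ``x``; a natural cubic
    spline on K knots spans K dimensions including the intercept, so df
    columns require K = df + 1 knots.  df = 1 degenerates to a linear fit.
    """
    x = np.asarray(x, dtype=float)
    xs = np.unique(x)
    K = df + 1
    if len(xs) < K:
        raise ValueError(f"need >= {K} distinct time points for df={df}")
    knots = np.quantile(xs, np.linspace(0, 1, K))

    def d(k: int) -> np.ndarray:
        num = np.maximum(x - knots[k], 0) ** 3 - np.maximum(x - knots[-1], 0) ** 3
        return num / (knots[-1] - knots[k])

    cols = [x]
    for k in range(K - 2):
        cols.append(d(k) - d(K - 2))
    return np.column_stack(cols)


def _fit_rss(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Row-wise residual sum of squares of Y (G x n) on design X (n x p)."""
    Q, _ = np.linalg.qr(X)
    fitted = (Y @ Q) @ Q.T
    return np.sum((Y - fitted) ** 2, axis=1)


def _statistic_from_times(Y: np.ndarray, times: np.ndarray, spline_df: int) -> np.ndarray:
    n = Y.shape[1]
    X1 = np.column_stack([np.ones(n), natural_spline_basis(times, spline_df)])
    rss0 = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    rss1 = _fit_rss(Y, X1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = (rss0 - rss1) / rss1
    stat = np.where(rss1 <= 1e-300, np.where(rss0 > 1e-300, np.inf, 0.0), stat)
    return np.maximum(stat, 0.0)


def timecourse_statistic(study: ExpressionStudy, spline_df: int = 3) -> pd.Series:
    """Per-gene spline goodness-of-fit statistic (RSS0 - RSS1) / RSS1.

    Requires at least spline_df + 2 distinct time points so the alternative
    model leaves residual degrees of freedom.
    """
    times = study.times
    if len(np.unique(times)) < spline_df + 2:
        raise ValueError(
            f"need >= {spline_df + 2} distinct time points for spline_df={spline_df}"
        )
    stat = _statistic_from_times(study.values.to_numpy(dtype=float), times, spline_df)
    return pd.Series(stat, index=study.values.index, name="statistic")


def odp_statistic(study: ExpressionStudy, spline_df: int = 3) -> pd.Series:
    """ODP-style statistic: likelihood of each gene under all genes' fits.

    For gene i, sum over genes j of the Gaussian likelihood of x_i under
    gene j's alternative fit divided by the same sum under the null fits, so
    information is shared across genes.  O(G^2) — intended for moderate G.
    """
    times = study.times
    Y = study.values.to_numpy(dtype=float)
    G, n = Y.shape
    X1 = np.column_stack([np.ones(n), natural_spline_basis(times, spline_df)])
    Q, _ = np.linalg.qr(X1)
    mu1 = (Y @ Q) @ Q.T  # G x n fitted alternatives
    mu0 = np.tile(Y.mean(axis=1, keepdims=True), (1, n))
    s1 = np.sqrt(np.maximum(np.mean((Y - mu1) ** 2, axis=1), 1e-12))
    s0 = np.sqrt(np.maximum(np.mean((Y - mu0) ** 2, axis=1), 1e-12))

    def loglik(mu: np.ndarray, s: np.ndarray) -> np.ndarray:
        # L[i, j] = log N(x_i; mu_j, s_j) summed over samples
        sq = (
            np.sum(Y**2, axis=1)[:, None]
            - 2 * Y @ mu.T
            + np.sum(mu**2, axis=1)[None, :]
        )
        return -0.5 * sq / (s**2)[None, :] - n * np.log(s)[None, :]

    l1 = loglik(mu1, s1)
    l0 = loglik(mu0, s0)
    # log-sum-exp over j for numerical stability
    num = np.logaddexp.reduce(l1, axis=1)
    den = np.logaddexp.reduce(l0, axis=1)
    return pd.Series(np.exp(num - den), index=study.values.index, name="odp_statistic")


def permutation_null(
    study: ExpressionStudy, B: int = 200, seed: int = 0, spline_df: int = 3
) -> pd.Series:
    """Permutation p-values for the spline statistic, pooled across genes.

    Sample time labels are permuted B times (replicate indices ride along
    with their samples); the statistic is recomputed each round and all
    permuted statistics across all genes form one pooled null, so
    p = (1 + #{null >= observed}) / (1 + B * G).
    """
    if B < 50:
        raise ValueError("B must be >= 50")
    rng = np.random.default_rng(seed)
    Y = study.values.to_numpy(dtype=float)
    times = study.times
    obs = _statistic_from_times(Y, times, spline_df)
    pool: list[np.ndarray] = []
    for _ in range(B):
        perm = rng.permutation(len(times))
        pool.append(_statistic_from_times(Y, times[perm], spline_df))
    null = np.sort(np.concatenate(pool))
    n_null = len(null)
    # count of null >= obs via searchsorted on the sorted pool
    ge = n_null - np.searchsorted(null, obs, side="left")
    p = (1.0 + ge) / (1.0 + n_null)
    return pd.Series(p, index=study.values.index, name="p")


def storey_qvalues(
    p, lam: float = 0.5, pi0: float | None = None
) -> np.ndarray:
    """Storey-Tibshirani q-values with a single-lambda pi0 estimate.

    pi0 = #{p > lambda} / (m (1 - lambda)), capped at 1; q_i is the minimum
    over p_j >= p_i of pi0 * m * p_j / rank(p_j), so q is monotone in p.
    Passing ``pi0=1`` reproduces Benjamini-Hochberg adjusted p-values.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = np.sum(p > lam) / (m * (1.0 - lam))
        pi0 = min(max(pi0, 0.0), 1.0)
        if pi0 == 0.0:
            pi0 = 1.0 / m  # degenerate: every p below lambda
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    # rank factor applied as a division so that pi0 = 1 reproduces
    # Benjamini-Hochberg adjusted p-values bit for bit
    q_sorted = pi0 * (ranked / (np.arange(1, m + 1) / m))
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass(frozen=True)
class DegSelection:
    genes: list[str]
    count: int
    total: int
    percent: float


def select_degs(q, gene_ids=None, threshold: float = DEFAULT_Q_THRESHOLD) -> DegSelection:
    """Threshold q-values; report the count and percentage of total genes."""
    q = np.asarray(q, dtype=float)
    keep = np.flatnonzero(q <= threshold)
    if gene_ids is None:
        gene_ids = [str(i) for i in range(q.size)]
    gene_ids = list(gene_ids)
    genes = [gene_ids[i] for i in keep]
    percent = round(100.0 * len(keep) / q.size, 2) if q.size else 0.0
    return DegSelection(genes=genes, count=len(keep), total=q.size, percent=percent)


def standardize_rows(mat: pd.DataFrame) -> pd.DataFrame:
    """dChip-style per-gene standardisation to mean 0 and SD 1 (ddof=0)."""
    arr = mat.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise ValueError(f"constant gene cannot be standardized: {mat.index[flat[0]]}")
    return pd.DataFrame((arr - mean) / sd, index=mat.index, columns=mat.columns)


def assign_phases(
    deg_matrix: pd.DataFrame,
    times: np.ndarray,
    phase_boundaries,
) -> tuple[pd.Series, np.ndarray]:
    """Cluster DEG profiles and label each cluster with its peak phase.

    Profiles are standardized, clustered hierarchically with 1 - Pearson
    distance and centroid linkage (on standardized rows the two are
    monotonically equivalent to squared Euclidean distance), and the tree is
    cut into as many clusters as there are phases.  Each cluster gets the
    phase containing the maximum of its mean profile.
    Returns (phase per gene, linkage matrix).
    """
    if len(deg_matrix) < 2:
        raise ValueError("need >= 2 genes to cluster")
    Z = standardize_rows(deg_matrix)
    link = linkage(Z.to_numpy(), method="centroid")
    K = len(phase_boundaries)
    labels = fcluster(link, t=K, criterion="maxclust")
    times = np.asarray(times, dtype=float)
    phases = pd.Series("", index=deg_matrix.index, name="phase")
    for c in np.unique(labels):
        mean_profile = Z.to_numpy()[labels == c].mean(axis=0)
        # average replicates within each time point, then find the peak time
        uniq = np.unique(times)
        per_time = np.array([mean_profile[times == t].mean() for t in uniq])
        t_peak = uniq[int(np.argmax(per_time))]
        name = next(
            (nm for nm, lo, hi in phase_boundaries if lo <= t_peak <= hi), ""
        )
        phases.iloc[labels == c] = name
    return phases, link


def linkage_to_newick(link: np.ndarray, labels) -> str:
    """Render a scipy linkage matrix as a Newick tree string."""
    from scipy.cluster.hierarchy import to_tree

    labels = list(labels)
    root = to_tree(link)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        return f"({walk(node.left)},{walk(node.right)}):{node.dist:.6g}"

    return walk(root) + ";"


def flag_representation(chip_percent: float, deg_percent: float) -> str:
    """Doubling/halving representation rule for one functional category.

    Over-represented when the DEG percentage is at least twice the chip-wide
    percentage; under-represented when at most half of it.  Categories with a
    zero on either side are flagged neither.
    """
    if deg_percent > 0 and deg_percent >= 2.0 * chip_percent:
        return "over"
    if chip_percent > 0 and deg_percent > 0 and deg_percent <= 0.5 * chip_percent:
        return "under"
    return "neither"


def cog_representation(
    deg_genes, gene_categories: pd.Series
) -> pd.DataFrame:
    """Per-COG-category chip vs DEG percentages with over/under flags.

    ``gene_categories`` maps every gene (chip-wide) to at most one category
    (NaN/empty for unannotated genes); percentages are taken over the full
    chip and over the DEG set respectively.
    """
    cats = gene_categories.fillna("").astype(str)
    total = len(cats)
    deg = cats.loc[cats.index.intersection(pd.Index(deg_genes))]
    n_deg = len(deg)
    rows = []
    for cat in sorted(c for c in cats.unique() if c):
        chip_pct = 100.0 * (cats == cat).sum() / total
        deg_pct = 100.0 * (deg == cat).sum() / n_deg if n_deg else 0.0
        rows.append(
            {
                "category": cat,
                "chip_percent": round(chip_pct, 2),
                "deg_percent": round(deg_pct, 2),
                "flag": flag_representation(chip_pct, deg_pct),
            }
        )
    return pd.DataFrame(rows).set_index("category")


def run_de(
    study: ExpressionStudy,
    spline_df: int = 3,
    B: int = 200,
    seed: int = 0,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    phase_boundaries=None,
) -> pd.DataFrame:
    """Full DE pass for one strain: statistic, p, q, phase per gene."""
    stat = timecourse_statistic(study, spline_df)
    p = permutation_null(study, B=B, seed=seed, spline_df=spline_df)
    q = storey_qvalues(p.to_numpy())
    out = pd.DataFrame({"statistic": stat, "p": p, "q": q})
    out["phase"] = "none"
    sel = select_degs(q, gene_ids=study.values.index, threshold=q_threshold)
    if sel.count >= 2 and phase_boundaries is not None:
        phases, _ = assign_phases(
            study.values.loc[sel.genes], study.times, phase_boundaries
        )
        out.loc[phases.index, "phase"] = phases
    return out
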