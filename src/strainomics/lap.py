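"""Locally adaptive positional analysis of expression along the chromosome.

The LAP procedure integrates transcriptional and structural information in
three steps: (i) a per-gene signed between-class statistic (moderated
difference of class means), (ii) adaptive-bandwidth kernel smoothing of the
statistic along the chromosomal coordinate of each strand independently,
with the bandwidth at each gene set by the distance to its knn-th neighbour
so sparse and dense regions are treated comparably, and (iii) a permutation
test in which the raw statistics are shuffled across positions and
re-smoothed, giving each position its own null (smoothed values are not
comparable between neighbourhoods).  Positions are thresholded on
Storey q-values plus a fold-change filter, and maximal same-sign runs of
passing genes become region calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import storey_qvalues
from .expression import ExpressionStudy


@dataclass(frozen=True)
class RegionCall:
    """A contiguous run of same-strand genes called as one modulated region."""

    strand: str
    start_position: int
    end_position: int
    direction: str  # up | down
    gene_ids: tuple[str, ...]
    min_q: float


def between_class_statistic(
    study: ExpressionStudy, class_a_samples, class_b_samples
) -> pd.Series:
    """Signed moderated difference of class means per gene.

    score = (mean_a - mean_b) / (s + s0) where s is the pooled standard
    error of the difference and s0 the median of s over genes, a shrinkage
    constant that keeps near-constant genes from dominating the ranking.
    """
    a = list(class_a_samples)
    b = list(class_b_samples)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both classes need >= 2 samples")
    Ya = study.values[a].to_numpy(dtype=float)
    Yb = study.values[b].to_numpy(dtype=float)
    na, nb = Ya.shape[1], Yb.shape[1]
    diff = Ya.mean(axis=1) - Yb.mean(axis=1)
    va = Ya.var(axis=1, ddof=1)
    vb = Yb.var(axis=1, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    s = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    s0 = float(np.median(s))
    score = diff / (s + s0)
    return pd.Series(score, index=study.values.index, name="raw_stat")


def _circular_distance(pos: np.ndarray, genome_length: int | None) -> np.ndarray:
    d = np.abs(pos[:, None] - pos[None, :])
    if genome_length is not None:
        d = np.minimum(d, genome_length - d)
    return d


def _weight_matrix(
    positions: np.ndarray, knn: int, genome_length: int | None
) -> np.ndarray:
    """Row-normalised tricube weights with per-gene knn bandwidth."""
    d = _circular_distance(positions.astype(float), genome_length)
    # bandwidth: distance to the knn-th nearest *other* gene
    h = np.sort(d, axis=1)[:, knn]
    u = d / h[:, None]
    w = np.where(u < 1.0, (1.0 - np.abs(u) ** 3) ** 3, 0.0)
    return w / w.sum(axis=1, keepdims=True)


def smooth_statistic(
    positions: np.ndarray,
    raw: np.ndarray,
    knn: int = 11,
    genome_length: int | None = None,
) -> np.ndarray:
    """Adaptive-bandwidth tricube kernel smoothing of a positional statistic.

    At gene i the bandwidth h_i is the chromosomal distance to its knn-th
    nearest gene (circular distance when ``genome_length`` is given) and the
    smoothed value is the kernel-weighted mean of the raw statistics.
    """
    positions = np.asarray(positions)
    raw = np.asarray(raw, dtype=float)
    if knn % 2 == 0 or knn < 3:
        raise ValueError("knn must be odd and >= 3")
    if len(positions) < knn + 1:
        raise ValueError(f"need more than knn={knn} genes on the strand")
    W = _weight_matrix(positions, knn, genome_length)
    return W @ raw


def permutation_pvalues(
    positions: np.ndarray,
    raw: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    knn: int = 11,
    genome_length: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided position-specific permutation p-values for smoothed stats.

    Raw statistics are permuted across positions B times and re-smoothed;
    p_i = (1 + #{b : |smoothed_i^(b)| >= |smoothed_i|}) / (1 + B).  No
    pooling across genes: each position keeps its own null because each has
    a unique neighbourhood.  Returns (smoothed observed, p-values).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    raw = np.asarray(raw, dtype=float)
    W = _weight_matrix(np.asarray(positions), knn, genome_length)
    obs = W @ raw
    G = len(raw)
    perms = np.empty((G, B))
    for b in range(B):
        perms[:, b] = raw[rng.permutation(G)]
    null = W @ perms  # G x B smoothed null statistics
    exceed = np.sum(np.abs(null) >= np.abs(obs)[:, None], axis=1)
    p = (1.0 + exceed) / (1.0 + B)
    return obs, p


def lap_strand(
    study: ExpressionStudy,
    strand: str,
    class_a_samples,
    class_b_samples,
    knn: int = 11,
    B: int = 1000,
    seed: int = 0,
    genome_length: int | None = None,
) -> pd.DataFrame:
    """Steps i-iii of the positional procedure for one strand.

    Returns a per-gene table (chromosome order) with position, raw and
    smoothed statistics, class-mean log difference (fold change), and the
    permutation p-value.
    """
    raw_all = between_class_statistic(study, class_a_samples, class_b_samples)
    fc_all = study.values[list(class_a_samples)].mean(axis=1) - study.values[
        list(class_b_samples)
    ].mean(axis=1)
    mask = study.genes["strand"] == strand
    genes = study.genes[mask].sort_values("position_bp")
    pos = genes["position_bp"].to_numpy()
    raw = raw_all.loc[genes.index].to_numpy()
    smoothed, p = permutation_pvalues(
        pos, raw, B=B, seed=seed, knn=knn, genome_length=genome_length
    )
    return pd.DataFrame(
        {
            "position_bp": pos,
            "strand": strand,
            "raw_stat": raw,
            "smoothed_stat": smoothed,
            "fc": fc_all.loc[genes.index].to_numpy(),
            "p": p,
        },
        index=genes.index,
    )


def call_regions(
    stats: pd.DataFrame,
    q_threshold: float = 0.01,
    fc_threshold: float = 0.5,
) -> list[RegionCall]:
    """Maximal runs of passing, same-sign, same-strand genes.

    ``stats`` is the concatenated per-strand table from :func:`lap_strand`.
    q-values are computed over all genes (one multiple-testing family); a
    gene passes when q <= q_threshold and |fc| >= fc_threshold.  Runs are
    maximal sequences of consecutive passing genes in strand order whose
    smoothed statistics share one sign.
    """
    stats = stats.copy()
    stats["q"] = storey_qvalues(stats["p"].to_numpy())
    calls: list[RegionCall] = []
    for strand, sub in stats.groupby("strand", sort=True):
        sub = sub.sort_values("position_bp")
        passing = (
            (sub["q"] <= q_threshold)
            & (sub["fc"].abs() >= fc_threshold)
            & (sub["smoothed_stat"] != 0)
        ).to_numpy()
        sign = np.sign(sub["smoothed_stat"].to_numpy())
        run: list[int] = []
        for i in range(len(sub) + 1):
            extend = (
                i < len(sub)
                and passing[i]
                and (not run or sign[i] == sign[run[-1]])
            )
            if extend:
                run.append(i)
                continue
            if run:
                members = sub.index[run]
                calls.append(
                    RegionCall(
                        strand=str(strand),
                        start_position=int(sub["position_bp"].iloc[run[0]]),
                        end_position=int(sub["position_bp"].iloc[run[-1]]),
                        direction="up" if sign[run[0]] > 0 else "down",
                        gene_ids=tuple(members),
                        min_q=float(sub["q"].iloc[run].min()),
                    )
                )
            run = [i] if (i < len(sub) and passing[i]) else []
    calls.sort(key=lambda c: (c.strand, c.start_position))
    return calls


def regions_to_bed(calls: list[RegionCall], chrom: str, path) -> None:
    """Region calls as BED (0-based half-open; score = -log10 min_q)."""
    with open(path, "w") as fh:
        for c in calls:
            score = min(1000, int(round(-10 * np.log10(max(c.min_q, 1e-100)))))
            fh.write(
                f"{chrom}\t{c.start_position - 1}\t{c.end_position}\t"
                f"{c.direction}\t{score}\t{c.strand}\n"
            )
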