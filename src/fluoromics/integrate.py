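"""Multi-omics correlation integration.

Builds transcription-factor → gene correlation networks (top-k targets per
TF by |Pearson r|), TF vs pathway-gene correlation tables, and
gene-block vs metabolite Mantel tests (distance-matrix correlation with
permutation significance).
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError

__all__ = [
    "CorrelationEdge",
    "MantelResult",
    "pearson_with_pvalue",
    "correlation_table",
    "tf_correlation_network",
    "mantel_test",
    "mantel_by_group",
]


@dataclass(frozen=True)
class CorrelationEdge:
    """One correlation edge between two features measured across samples."""

    source: str
    target: str
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class MantelResult:
    """Mantel distance-matrix correlation with permutation significance."""

    r: float
    p: float
    permutations: int
    seed: int
    alternative: str
    method: str = "sampled"


def pearson_with_pvalue(
    x: np.ndarray, y: np.ndarray, source: str = "x", target: str = "y"
) -> CorrelationEdge:
    """Pearson product-moment r with a two-sided t-test p-value.

    p is derived from ``t = r sqrt(n-2) / sqrt(1-r^2)`` on n-2 degrees of
    freedom (the classical exact test under bivariate normality).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValidationError("need at least 3 paired samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("correlation undefined for a zero-variance vector")
    res = stats.pearsonr(x, y)
    return CorrelationEdge(source=source, target=target,
                           r=float(res.statistic), p=float(res.pvalue), n=n)


def correlation_table(
    sources: pd.DataFrame, targets: pd.DataFrame
) -> pd.DataFrame:
    """All source × target Pearson correlations over shared sample columns.

    Returns a tidy frame (source, target, r, p, n).  Used for, e.g., the
    TF-family vs Calvin-cycle-gene correlation table.
    """
    shared = [c for c in sources.columns if c in targets.columns]
    if len(shared) < 3:
        raise ValidationError("source and target tables share fewer than 3 samples")
    rows = []
    for s_id, s in sources[shared].iterrows():
        for t_id, t in targets[shared].iterrows():
            edge = pearson_with_pvalue(s.values, t.values, str(s_id), str(t_id))
            rows.append((edge.source, edge.target, edge.r, edge.p, edge.n))
    return pd.DataFrame(rows, columns=["source", "target", "r", "p", "n"])


def tf_correlation_network(
    tf_table: pd.DataFrame,
    gene_table: pd.DataFrame,
    k: int = 50,
) -> pd.DataFrame:
    """Top-k correlated genes per transcription factor.

    For each TF row, the k candidate genes with largest |Pearson r| are
    selected (ties broken by gene id, lexicographically); edges keep the
    sign of r.  If fewer than k candidates exist, all are returned with a
    warning.  Output columns: source, target, r, p, n, rank.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    edges = correlation_table(tf_table, gene_table)
    if gene_table.shape[0] < k:
        warnings.warn(
            f"only {gene_table.shape[0]} candidate genes available for top-{k} selection",
            stacklevel=2,
        )
    out = []
    for tf, sub in edges.groupby("source", sort=True):
        sub = sub.assign(abs_r=sub["r"].abs())
        sub = sub.sort_values(["abs_r", "target"], ascending=[False, True])
        sub = sub.head(k).drop(columns="abs_r").reset_index(drop=True)
        sub["rank"] = np.arange(1, len(sub) + 1)
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def _mantel_r(dx: np.ndarray, dy_condensed: np.ndarray, idx: np.ndarray) -> float:
    iu = np.triu_indices(dx.shape[0], k=1)
    return float(np.corrcoef(dx[idx][:, idx][iu], dy_condensed)[0, 1])


def mantel_test(
    matrix_x: pd.DataFrame | np.ndarray,
    matrix_y: pd.DataFrame | np.ndarray,
    permutations: int = 999,
    seed: int = 0,
    alternative: str = "greater",
    metric: str = "euclidean",
) -> MantelResult:
    """Mantel test between two feature × sample matrices.

    Sample–sample distance matrices (default Euclidean over the feature
    profiles) are computed for each input; the Mantel statistic is the
    Pearson correlation of their vectorised upper triangles.  Significance
    comes from permuting the sample labels of the first matrix.  When the
    full permutation group is no larger than the requested number of draws
    (``n! <= permutations + 1``) it is enumerated exhaustively and the
    exact p-value ``#{perm stat as-or-more extreme} / n!`` is returned
    (the identity counts, so p >= 1/n!); otherwise ``permutations`` random
    draws give ``p = (1 + #extreme) / (1 + permutations)``.  One-sided
    ``"greater"`` by default, ``"two-sided"`` optional.
    """
    x = np.asarray(matrix_x, dtype=float)
    y = np.asarray(matrix_y, dtype=float)
    if x.shape[1] != y.shape[1]:
        raise ValidationError("matrices must share the same sample set (columns)")
    n = x.shape[1]
    if n < 4:
        raise ValidationError("Mantel test needs >= 4 samples for meaningful permutation")
    if permutations < 99:
        raise ValidationError("permutations must be >= 99")
    if alternative not in ("greater", "two-sided"):
        raise ValidationError(f"unknown alternative: {alternative!r}")

    dx = squareform(pdist(x.T, metric=metric))
    dy = pdist(y.T, metric=metric)
    identity = np.arange(n)
    r_obs = _mantel_r(dx, dy, identity)

    def extreme(r_perm: float) -> bool:
        if alternative == "greater":
            return r_perm >= r_obs
        return abs(r_perm) >= abs(r_obs)

    n_fact = math.factorial(n)
    if n_fact <= permutations + 1:
        count = sum(
            extreme(_mantel_r(dx, dy, np.asarray(perm)))
            for perm in itertools.permutations(range(n))
        )
        return MantelResult(r=r_obs, p=count / n_fact, permutations=n_fact,
                            seed=seed, alternative=alternative, method="exact")

    rng = np.random.default_rng(seed)
    exceed = sum(extreme(_mantel_r(dx, dy, rng.permutation(n))) for _ in range(permutations))
    p = (1 + exceed) / (1 + permutations)
    return MantelResult(r=r_obs, p=float(p), permutations=permutations,
                        seed=seed, alternative=alternative, method="sampled")


def mantel_by_group(
    gene_table: pd.DataFrame,
    gene_groups: pd.Series,
    metabolite_table: pd.DataFrame,
    permutations: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> pd.DataFrame:
    """One Mantel test per gene group against the metabolite matrix.

    ``gene_groups`` maps gene id → group label (typically the EC number of
    the enzyme the genes encode), so each enzyme's gene block is tested
    against the metabolite profile matrix.  Returns a tidy frame
    (group, n_genes, mantel_r, p, permutations).
    """
    shared = [c for c in gene_table.columns if c in metabolite_table.columns]
    if len(shared) < 4:
        raise ValidationError("gene and metabolite tables share fewer than 4 samples")
    rows = []
    for i, (group, members) in enumerate(sorted(gene_groups.groupby(gene_groups).groups.items())):
        sub = gene_table.loc[list(members), shared]
        res = mantel_test(
            sub, metabolite_table[shared],
            permutations=permutations, seed=seed + i, alternative=alternative,
        )
        rows.append((group, len(members), res.r, res.p, res.permutations))
    return pd.DataFrame(rows, columns=["group", "n_genes", "mantel_r", "p", "permutations"])
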