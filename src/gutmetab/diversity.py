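"""Community diversity and composition statistics.

Alpha diversity (observed richness, Shannon in nats, Simpson), Bray-Curtis
beta diversity with classical PCoA ordination, top-k taxon composition bars,
and the Kruskal-Wallis -> pairwise Wilcoxon testing scheme with the
Bonferroni-style per-comparison threshold (0.05 / n_pairs, i.e. 0.0083 for
five groups).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from .stats import TestResult, rank_sum_test

__all__ = [
    "DiversityResult",
    "OrdinationResult",
    "GroupTestResult",
    "alpha_diversity",
    "alpha_diversity_table",
    "bray_curtis",
    "pcoa",
    "top_taxa_composition",
    "group_tests",
]


@dataclass(frozen=True)
class DiversityResult:
    observed_richness: int
    shannon: float  # nats
    simpson: float  # 1 - sum p^2


@dataclass
class OrdinationResult:
    """Classical-scaling embedding: sample coordinates on positive axes."""

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # retained (positive), nonincreasing
    proportion_explained: np.ndarray
    negative_eigenvalue_magnitude: float = 0.0


@dataclass
class GroupTestResult:
    omnibus_statistic: float
    omnibus_p: float
    pairwise: dict[tuple[str, str], TestResult] = field(default_factory=dict)
    per_comparison_threshold: float = 0.05


def alpha_diversity(abundances) -> DiversityResult:
    """Observed richness, Shannon entropy (nats) and Simpson index.

    Accepts counts or proportions; the vector is closed internally.
    """
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise ValueError("sample has zero total abundance")
    p = x[x > 0] / total
    return DiversityResult(
        observed_richness=int((x > 0).sum()),
        shannon=float(sps.entropy(p)),  # -sum p ln p
        simpson=float(1.0 - np.sum(p**2)),
    )


def alpha_diversity_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-sample alpha diversity for a taxa x samples table."""
    rows = {}
    for sample in matrix.columns:
        r = alpha_diversity(matrix[sample].to_numpy())
        rows[sample] = {"observed_richness": r.observed_richness, "shannon": r.shannon, "simpson": r.simpson}
    return pd.DataFrame(rows).T.rename_axis("sample")


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis distances between sample columns: sum|x-y| / sum(x+y)."""
    x = matrix.to_numpy(dtype=float).T  # samples x taxa
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    if x.shape[0] < 2:
        raise ValueError("need at least two samples")
    zero = x.sum(axis=1) == 0
    if zero.sum() >= 2:
        raise ValueError("Bray-Curtis undefined between all-zero samples")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


def pcoa(distances: pd.DataFrame, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis (classical metric scaling).

    Double-centers the squared distance matrix and eigendecomposes it; axes
    are ordered by eigenvalue and negative-eigenvalue axes are dropped, with
    their total magnitude reported.
    """
    d = np.asarray(distances, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    neg_mag = float(-eigvals[eigvals < 0].sum())
    pos = eigvals > 1e-10 * max(1.0, abs(eigvals[0]))
    eigvals_pos, vecs_pos = eigvals[pos], eigvecs[:, pos]
    if n_axes is not None:
        eigvals_pos, vecs_pos = eigvals_pos[:n_axes], vecs_pos[:, :n_axes]
    coords = vecs_pos * np.sqrt(eigvals_pos)
    labels = list(distances.index) if isinstance(distances, pd.DataFrame) else list(range(n))
    total = eigvals[eigvals > 0].sum()
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=labels,
                                 columns=[f"PCo{i+1}" for i in range(coords.shape[1])]),
        eigenvalues=eigvals_pos,
        proportion_explained=eigvals_pos / total if total > 0 else eigvals_pos,
        negative_eigenvalue_magnitude=neg_mag,
    )


def top_taxa_composition(matrix: pd.DataFrame, groups: pd.Series, k: int = 9) -> pd.DataFrame:
    """Per-group mean relative abundance (%) of the top-k taxa plus "Other".

    Taxa are ranked by grand-mean relative abundance; everything outside the
    top k is lumped into "Other". Each group's bar sums to 100%.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rel = matrix.div(matrix.sum(axis=0), axis=1)
    top = rel.mean(axis=1).sort_values(ascending=False).index[:k]
    lumped = rel.loc[top].copy()
    other = rel.drop(index=top).sum(axis=0)
    if float(other.sum()) > 0 or len(top) < len(rel):
        lumped.loc["Other"] = other
    groups = pd.Series(groups).reindex(rel.columns)
    return 100.0 * lumped.T.groupby(groups).mean().T


def group_tests(values: pd.Series, groups: pd.Series) -> GroupTestResult:
    """Kruskal-Wallis omnibus test, then pairwise two-sided Wilcoxon rank-sum.

    Raw pairwise p-values are reported together with the Bonferroni-style
    per-comparison threshold 0.05 / n_pairs (0.0083 for five groups, matching
    the *** starring convention).
    """
    values = pd.Series(values)
    groups = pd.Series(groups).reindex(values.index)
    by_group = {g: values[groups == g].to_numpy(dtype=float) for g in groups.unique()}
    if len(by_group) < 2:
        raise ValueError("need at least two groups")
    for g, v in by_group.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than two samples")
    names = sorted(by_group)
    samples = [by_group[g] for g in names]
    if np.ptp(np.concatenate(samples)) == 0:
        stat, p = 0.0, 1.0  # no variation anywhere: no signal
    else:
        stat, p = sps.kruskal(*samples)
    pairwise = {}
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    for a, b in pairs:
        pairwise[(a, b)] = rank_sum_test(by_group[a], by_group[b])
    return GroupTestResult(
        omnibus_statistic=float(stat),
        omnibus_p=float(p),
        pairwise=pairwise,
        per_comparison_threshold=0.05 / len(pairs),
    )
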