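"""Univariate cohort analyses around the classifier.

* Volcano table: per-probe two-sided Mann-Whitney tests on log2 values with
  Benjamini-Hochberg adjustment across probes.
* Serial trend test: Jonckheere-Terpstra test for ordered alternatives
  across timepoints, exact by enumeration for small designs, normal
  approximation otherwise.
* Unsupervised hierarchical clustering: per-probe z-scores, Euclidean
  distance, Ward linkage, deterministic leaf ordering.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import mannwhitneyu, norm
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SampleMeta, ValidationError, log, metadata_frame


def _log2_values(m: ExpressionMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    if m.value_kind == "normalized_log2":
        return m.data
    return np.log2(m.data + pseudocount)


# ---------------------------------------------------------------------------
# Volcano
# ---------------------------------------------------------------------------

def univariate_volcano(
    m: ExpressionMatrix,
    labels,
    case=1,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-probe differential table: log2FC, Mann-Whitney p, BH-adjusted p.

    ``labels`` maps sample id -> group (exactly two levels, each n >= 3);
    ``case`` names the level whose mean enters the fold change positively.
    Constant probes get p = 1 and are flagged.
    """
    labels = pd.Series(labels).reindex(m.data.index)
    if labels.isna().any():
        raise ValidationError("labels do not cover every sample")
    levels = sorted(labels.unique(), key=str)
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 groups, got {levels}")
    if case not in levels:
        raise ValidationError(f"case level {case!r} not among {levels}")
    control = next(l for l in levels if l != case)
    L = _log2_values(m, pseudocount)
    a = L.loc[labels == case]
    b = L.loc[labels == control]
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("each group needs n >= 3")

    rows = []
    for probe in L.columns:
        x, y = a[probe].to_numpy(), b[probe].to_numpy()
        lfc = float(x.mean() - y.mean())
        pooled = np.concatenate([x, y])
        if np.all(pooled == pooled[0]):
            rows.append((str(probe), lfc, 1.0, "constant"))
            continue
        p = float(mannwhitneyu(x, y, alternative="two-sided").pvalue)
        rows.append((str(probe), lfc, p, ""))
    table = pd.DataFrame(rows, columns=["probe", "log2fc", "p", "flag"])
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    table["test"] = "mannwhitney-u"
    return table[["probe", "log2fc", "p", "p_adj", "test", "flag"]]


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra trend test
# ---------------------------------------------------------------------------

def _jt_statistic(groups: list[np.ndarray]) -> float:
    """Sum over ordered group pairs of tie-aware Mann-Whitney counts."""
    j = 0.0
    for a, b in itertools.combinations(groups, 2):
        diff = b[None, :] - a[:, None]
        j += np.sum(diff > 0) + 0.5 * np.sum(diff == 0)
    return float(j)


def _jt_exact_p(groups: list[np.ndarray], observed: float) -> float:
    """P(J >= observed) by complete enumeration of group assignments."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    idx = list(range(len(pooled)))
    count = total = 0

    def recurse(remaining: list[int], gi: int, chosen: list[np.ndarray]):
        nonlocal count, total
        if gi == len(sizes) - 1:
            arrangement = chosen + [pooled[np.array(remaining)]]
            total += 1
            if _jt_statistic(arrangement) >= observed - 1e-9:
                count += 1
            return
        for combo in itertools.combinations(remaining, sizes[gi]):
            rest = [i for i in remaining if i not in set(combo)]
            recurse(rest, gi + 1, chosen + [pooled[np.array(combo)]])

    recurse(idx, 0, [])
    return count / total


def jonckheere_terpstra(
    groups: list[np.ndarray],
    alternative: str = "increasing",
    method: str = "auto",
    exact_max_n: int = 12,
) -> tuple[float, float]:
    """JT test for an ordered trend across groups; returns (J, p).

    ``groups`` are the samples at each ordered level (e.g. timepoint).
    ``method``: 'exact' enumerates the permutation null (feasible for small
    total n), 'normal' uses the large-sample normal approximation, 'auto'
    picks exact when total n <= ``exact_max_n``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValidationError("need >= 2 non-empty ordered groups")
    if alternative not in ("increasing", "decreasing", "two-sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    if alternative == "decreasing":
        j, p = jonckheere_terpstra(groups[::-1], "increasing", method, exact_max_n)
        return _jt_statistic(groups), p
    if alternative == "two-sided":
        j = _jt_statistic(groups)
        _, p_inc = jonckheere_terpstra(groups, "increasing", method, exact_max_n)
        _, p_dec = jonckheere_terpstra(groups, "decreasing", method, exact_max_n)
        return j, min(1.0, 2.0 * min(p_inc, p_dec))

    j = _jt_statistic(groups)
    n_total = sum(len(g) for g in groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return j, 1.0
    use_exact = method == "exact" or (method == "auto" and n_total <= exact_max_n)
    if use_exact:
        return j, _jt_exact_p(groups, j)
    sizes = np.array([len(g) for g in groups], dtype=float)
    mean = (n_total**2 - np.sum(sizes**2)) / 4.0
    var = (
        n_total**2 * (2 * n_total + 3) - np.sum(sizes**2 * (2 * sizes + 3))
    ) / 72.0
    if var <= 0:
        return j, 1.0
    z = (j - mean) / np.sqrt(var)
    return j, float(norm.sf(z))


def trend_test(
    m: ExpressionMatrix,
    meta: list[SampleMeta],
    group: str = "tumor",
    probes: list[str] | None = None,
    alternative: str = "increasing",
    method: str = "auto",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-probe JT trend p-values across ordered timepoints within a group."""
    mdf = metadata_frame(meta)
    mdf = mdf.loc[[s for s in m.sample_ids if s in mdf.index]]
    sel = mdf[(mdf["group"] == group) & mdf["timepoint_day"].notna()]
    days = sorted(sel["timepoint_day"].unique())
    if len(days) < 2:
        raise ValidationError("need >= 2 ordered timepoints in the chosen group")
    L = _log2_values(m, pseudocount)
    probes = probes or [str(c) for c in L.columns]
    rows = []
    for probe in probes:
        groups = [
            L.loc[sel.index[sel["timepoint_day"] == d], probe].to_numpy()
            for d in days
        ]
        j, p = jonckheere_terpstra(groups, alternative=alternative, method=method)
        rows.append((probe, j, p))
    return pd.DataFrame(rows, columns=["probe", "jt_statistic", "p"])


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusteringResult:
    linkage: np.ndarray
    sample_ids: list[str]
    leaf_order: list[str]
    distance: str = "euclidean"
    method: str = "ward"
    dropped_probes: list[str] = field(default_factory=list)

    def cut(self, k: int) -> pd.Series:
        """Cluster labels (1..k) from cutting the tree into k clusters."""
        labels = fcluster(self.linkage, k, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids)


def _leaf_order(Z: np.ndarray, n: int) -> list[int]:
    """Deterministic ordering: denser subtree left; tie -> smaller min index left."""
    def walk(node: int) -> tuple[list[int], int]:
        if node < n:
            return [node], node
        left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
        lo, lmin = walk(left)
        ro, rmin = walk(right)
        if len(ro) > len(lo) or (len(ro) == len(lo) and rmin < lmin):
            lo, ro = ro, lo
        return (lo + ro), min(lmin, rmin)

    order, _ = walk(2 * n - 2)
    return order


def hierarchical_cluster(
    m: ExpressionMatrix,
    probes: list[str] | None = None,
    pseudocount: float = 1.0,
) -> ClusteringResult:
    """Ward clustering of samples on per-probe z-scored log2 values."""
    if m.shape[0] < 2:
        raise ValidationError("need >= 2 samples to cluster")
    L = _log2_values(m, pseudocount)
    if probes is not None:
        missing = [p for p in probes if p not in L.columns]
        if missing:
            raise ValidationError(f"probes absent from matrix: {missing}")
        L = L[list(probes)]
    sd = L.std(axis=0, ddof=0)
    dropped = [str(c) for c in L.columns[sd == 0]]
    if dropped:
        log.warning("dropping zero-variance probes: %s", dropped)
        L = L.loc[:, sd > 0]
    if L.shape[1] == 0:
        raise ValidationError("no variable probes left to cluster on")
    Z = ((L - L.mean(axis=0)) / L.std(axis=0, ddof=0)).to_numpy()
    link = linkage(Z, method="ward", metric="euclidean")
    ids = [str(s) for s in L.index]
    order = _leaf_order(link, len(ids))
    return ClusteringResult(
        linkage=link,
        sample_ids=ids,
        leaf_order=[ids[i] for i in order],
        dropped_probes=dropped,
    )


def to_newick(result: ClusteringResult) -> str:
    """Linkage tree as a Newick string, branch lengths from merge heights."""
    Z, ids = result.linkage, result.sample_ids
    n = len(ids)
    heights = {i: 0.0 for i in range(n)}

    def build(node: int) -> str:
        if node < n:
            return ids[node].replace(" ", "_")
        row = Z[node - n]
        left, right, h = int(row[0]), int(row[1]), float(row[2])
        heights[node] = h
        parts = []
        for child in (left, right):
            label = build(child)
            parts.append(f"{label}:{h - heights[child]:.6g}")
        return f"({','.join(parts)})"

    return build(2 * n - 2) + ";"
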