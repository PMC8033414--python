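"""Abundance tables, two-group statistics and CITRUS-style SAM analysis.

Metacluster abundances are expressed as percentages of each sample's live
CD45+ events. Group comparisons use unadjusted pooled-variance (equal
standard deviation between groups) unpaired two-tailed t-tests per
metacluster, with Benjamini-Hochberg adjustment available as an option.
The CITRUS-style confirmation clusters pooled events agglomeratively in
marker space, treats every sufficiently large tree node as a feature
(per-sample fraction of events in the node), and calibrates a SAM-style
moderated d statistic by balanced group-label permutation with the
original SAM median-false-positive-count FDR.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.cluster.hierarchy import linkage

from cytofpipe.core import EventTable

GROUPS = ("chow", "HFD")


# ---------------------------------------------------------------------------
# abundance
# ---------------------------------------------------------------------------


@dataclass
class AbundanceTable:
    """Samples x metaclusters percent-of-CD45+ matrix with group labels."""

    percent: pd.DataFrame
    group: pd.Series
    n_events: pd.Series

    def __post_init__(self) -> None:
        sums = self.percent.sum(axis=1)
        if not np.allclose(sums, 100.0, atol=1e-6):
            raise ValueError("per-sample percentages must sum to 100")
        if (self.percent.to_numpy() < 0).any():
            raise ValueError("percentages must be non-negative")

    def by_group(self, column) -> tuple[np.ndarray, np.ndarray]:
        g = self.group.reindex(self.percent.index)
        a = self.percent.loc[g == GROUPS[0], column].to_numpy()
        b = self.percent.loc[g == GROUPS[1], column].to_numpy()
        return a, b


def abundance_table(
    metacluster_ids: np.ndarray,
    sample_ids: np.ndarray,
    groups: dict[str, str],
) -> AbundanceTable:
    """percent(s, m) = 100 x count(s, m) / total(s)."""
    df = pd.DataFrame({"sample": sample_ids, "meta": metacluster_ids})
    counts = df.groupby(["sample", "meta"]).size().unstack(fill_value=0)
    missing = sorted(set(groups) - set(counts.index))
    if missing:
        raise ValueError(f"samples with zero events: {missing}")
    totals = counts.sum(axis=1)
    percent = counts.div(totals, axis=0) * 100.0
    group = pd.Series({s: groups[s] for s in percent.index}, name="group")
    return AbundanceTable(percent, group, totals.rename("n_events"))


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------


def _two_group_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pooled-variance unpaired two-tailed t; returns (t, p)."""
    res = sstats.ttest_ind(b, a, equal_var=True)  # HFD - chow direction
    return float(res.statistic), float(res.pvalue)


def group_ttest(table: AbundanceTable, adjust: bool = False) -> pd.DataFrame:
    """Per-metacluster chow vs HFD pooled-variance t-tests, unadjusted by
    default; ``adjust=True`` adds Benjamini-Hochberg q-values.

    Groups with fewer than two samples yield no statistic, with the
    reason recorded per metacluster.
    """
    rows = []
    for m in table.percent.columns:
        a, b = table.by_group(m)
        row = {
            "metacluster": m,
            "mean_chow": float(a.mean()) if a.size else np.nan,
            "mean_HFD": float(b.mean()) if b.size else np.nan,
            "n_chow": a.size,
            "n_HFD": b.size,
        }
        if a.size < 2 or b.size < 2:
            row.update(t=np.nan, p=np.nan,
                       reason="fewer than 2 samples in a group; statistics not applied")
        else:
            t, p = _two_group_t(a, b)
            row.update(t=t, p=p, reason="")
        row["direction"] = (
            "up_in_HFD" if row["mean_HFD"] > row["mean_chow"] else "down_in_HFD"
        )
        rows.append(row)
    out = pd.DataFrame(rows).set_index("metacluster")
    if adjust:
        ok = out["p"].notna()
        q = np.full(len(out), np.nan)
        if ok.any():
            p = out.loc[ok, "p"].to_numpy()
            order = np.argsort(p)
            ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
            ranked = np.minimum.accumulate(ranked[::-1])[::-1]
            qq = np.empty_like(ranked)
            qq[order] = np.minimum(ranked, 1.0)
            q[np.flatnonzero(ok.to_numpy())] = qq
        out["q"] = q
    return out


def cd4_cd8_stats(
    t_counts: pd.DataFrame,
    groups: dict[str, str],
    n_cd45: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Per-sample CD4/CD8 summaries with two-group t-tests.

    ``t_counts`` holds per-sample columns ``CD4_T``, ``CD8_T``, ``DN_T``
    (and optionally ``DP_T``) from the embedding-space T-cell gates.
    Metrics: CD4/CD8 ratio, CD8 and CD4 as % of total T cells, and (when
    ``n_cd45`` is given) T cells as % of CD45+ events. Samples with zero
    CD8 counts are excluded from the ratio with a warning.
    """
    counts = t_counts.copy()
    total_t = counts.sum(axis=1)
    metrics = pd.DataFrame(index=counts.index)
    zero_cd8 = counts["CD8_T"] == 0
    if zero_cd8.any():
        warnings.warn(
            f"samples with zero CD8 counts excluded from the ratio: "
            f"{list(counts.index[zero_cd8])}",
            UserWarning, stacklevel=2,
        )
    metrics["cd4_cd8_ratio"] = np.where(
        zero_cd8, np.nan, counts["CD4_T"] / counts["CD8_T"].replace(0, np.nan)
    )
    metrics["cd8_pct_of_T"] = 100.0 * counts["CD8_T"] / total_t
    metrics["cd4_pct_of_T"] = 100.0 * counts["CD4_T"] / total_t
    if n_cd45 is not None:
        n_cd45 = pd.Series(n_cd45)
        metrics["T_pct_of_cd45"] = 100.0 * total_t / n_cd45.reindex(counts.index)
    g = pd.Series(groups).reindex(counts.index)

    rows = []
    for col in metrics.columns:
        vals = metrics[col]
        a = vals[(g == GROUPS[0]) & vals.notna()].to_numpy()
        b = vals[(g == GROUPS[1]) & vals.notna()].to_numpy()
        row = {"metric": col,
               "mean_chow": float(a.mean()) if a.size else np.nan,
               "mean_HFD": float(b.mean()) if b.size else np.nan,
               "n_chow": a.size, "n_HFD": b.size}
        if a.size >= 2 and b.size >= 2:
            t, p = _two_group_t(a, b)
            row.update(t=t, p=p)
        else:
            row.update(t=np.nan, p=np.nan)
        rows.append(row)
    stats = pd.DataFrame(rows).set_index("metric")
    stats.attrs["per_sample"] = metrics
    return stats


# ---------------------------------------------------------------------------
# CITRUS-style SAM
# ---------------------------------------------------------------------------


@dataclass
class CitrusResult:
    """Agglomerative cluster tree with per-node SAM statistics.

    ``nodes`` has one row per candidate node (>= the minimum cluster
    fraction) with columns size, d, p, fdr, significant; ``features`` is
    nodes x samples per-sample event fractions; ``members`` maps node id
    to the indices of its pooled events; ``parent`` maps node id to its
    smallest candidate ancestor (or -1).
    """

    nodes: pd.DataFrame
    features: pd.DataFrame
    members: dict[int, np.ndarray]
    parent: dict[int, int]
    linkage_matrix: np.ndarray
    event_index: np.ndarray

    @property
    def significant(self) -> list[int]:
        return list(self.nodes.index[self.nodes["significant"]])


def _balanced_permutations(
    labels: np.ndarray, n_perm: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Distinct group-label permutations, exhaustive when the number of
    distinct assignments does not exceed ``n_perm``."""
    n = len(labels)
    n1 = int((labels == GROUPS[1]).sum())
    total = math.comb(n, n1)
    if total <= n_perm:
        perms = []
        for combo in itertools.combinations(range(n), n1):
            lab = np.array([GROUPS[0]] * n, dtype=object)
            lab[list(combo)] = GROUPS[1]
            perms.append(lab)
        return perms
    perms = []
    seen = set()
    while len(perms) < n_perm:
        lab = rng.permutation(labels)
        key = tuple(lab == GROUPS[1])
        if key in seen:
            continue
        seen.add(key)
        perms.append(lab)
    return perms


def _sam_d(
    feats: np.ndarray, labels: np.ndarray, s0: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """SAM d statistic per node: (mean_HFD - mean_chow)/(s + s0), with s
    the pooled standard error and s0 the median of s over nodes unless
    given."""
    a = feats[:, labels == GROUPS[0]]
    b = feats[:, labels == GROUPS[1]]
    n1, n2 = a.shape[1], b.shape[1]
    sp2 = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    s = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if s0 is None:
        s0 = float(np.median(s))
        if s0 == 0:
            s0 = float(s.mean()) or 1e-12
    d = (b.mean(axis=1) - a.mean(axis=1)) / (s + s0)
    return d, s


def citrus_sam(
    table: EventTable,
    sample_ids: np.ndarray,
    groups: dict[str, str],
    markers: list[str] | None = None,
    min_cluster_frac: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    events_per_sample: int = 500,
    fdr_threshold: float = 0.05,
) -> CitrusResult:
    """Hierarchical (Ward) event clustering plus SAM permutation testing.

    Events are subsampled per sample (default 500) before tree building
    to keep the O(n^2) agglomeration desk-scale. Candidate nodes contain
    at least ``min_cluster_frac`` of the pooled events; the per-node
    feature is the fraction of each sample's events inside the node. FDR
    follows the original SAM definition: the median permuted count of
    |d_perm| >= |d| divided by the observed count.
    """
    markers = markers if markers is not None else table.panel.embedding_markers()
    samples = sorted(set(np.asarray(sample_ids)))
    labels = np.array([groups[s] for s in samples], dtype=object)
    for g in GROUPS:
        if (labels == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")

    rng = np.random.default_rng(seed)
    sid = np.asarray(sample_ids)
    keep = []
    for s in samples:
        idx = np.flatnonzero(sid == s)
        if idx.size > events_per_sample:
            idx = rng.choice(idx, events_per_sample, replace=False)
        keep.append(np.sort(idx))
    keep = np.concatenate(keep)
    X = table.marker_values(markers).to_numpy(dtype=float)[keep]
    sub_sid = sid[keep]
    n = len(X)

    Z = linkage(X, method="ward")
    min_size = max(1, int(np.ceil(min_cluster_frac * n)))

    # walk the merge tree accumulating member lists for candidate nodes
    members_all: dict[int, np.ndarray] = {i: np.array([i]) for i in range(n)}
    node_ids: list[int] = []
    for i, (a, b, _, size) in enumerate(Z):
        nid = n + i
        members_all[nid] = np.concatenate([members_all[int(a)], members_all[int(b)]])
        if size >= min_size:
            node_ids.append(nid)
    members = {nid: members_all[nid] for nid in node_ids}

    # smallest candidate ancestor for nesting checks
    parent_raw = {}
    for i, (a, b, _, _) in enumerate(Z):
        parent_raw[int(a)] = n + i
        parent_raw[int(b)] = n + i
    parent = {}
    cand = set(node_ids)
    for nid in node_ids:
        p = parent_raw.get(nid, -1)
        while p != -1 and p not in cand:
            p = parent_raw.get(p, -1)
        parent[nid] = p

    sample_tot = {s: int((sub_sid == s).sum()) for s in samples}
    feats = np.zeros((len(node_ids), len(samples)))
    for r, nid in enumerate(node_ids):
        ns = sub_sid[members[nid]]
        for c_i, s in enumerate(samples):
            feats[r, c_i] = (ns == s).sum() / sample_tot[s]

    d_obs, s_obs = _sam_d(feats, labels)
    s0 = float(np.median(s_obs)) or 1e-12

    perms = _balanced_permutations(labels, n_perm, rng)
    d_perm = np.array([_sam_d(feats, lab, s0=s0)[0] for lab in perms])

    abs_obs = np.abs(d_obs)
    p_vals = np.array([
        (1 + (np.abs(d_perm[:, i]) >= abs_obs[i]).sum()) / (len(perms) + 1)
        for i in range(len(node_ids))
    ])
    fdr = np.empty(len(node_ids))
    abs_perm = np.abs(d_perm)
    for i in range(len(node_ids)):
        obs_count = int((abs_obs >= abs_obs[i]).sum())
        perm_counts = (abs_perm >= abs_obs[i]).sum(axis=1)
        fdr[i] = min(1.0, float(np.median(perm_counts)) / obs_count) if obs_count else 1.0

    nodes = pd.DataFrame({
        "size": [len(members[nid]) for nid in node_ids],
        "d": d_obs,
        "p": p_vals,
        "fdr": fdr,
        "significant": fdr <= fdr_threshold,
    }, index=pd.Index(node_ids, name="node"))
    features = pd.DataFrame(feats, index=nodes.index, columns=samples)
    return CitrusResult(nodes, features, members, parent, Z, keep)


def annotate_citrus_nodes(
    result: CitrusResult, truth_populations: np.ndarray
) -> pd.Series:
    """Dominant ground-truth population per candidate node (for synthetic
    cohorts); ``truth_populations`` aligns with the events given to
    :func:`citrus_sam` pre-subsampling."""
    pops = np.asarray(truth_populations)[result.event_index]
    out = {}
    for nid, idx in result.members.items():
        vals, counts = np.unique(pops[idx].astype(str), return_counts=True)
        out[nid] = vals[np.argmax(counts)]
    return pd.Series(out, name="dominant_population")
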