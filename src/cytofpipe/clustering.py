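"""Equal-event subsampling, t-SNE embedding, embedding-space k-means,
curated merging, MEM scoring and hierarchical metaclustering.

The multistep scheme: pool an equal number of events per sample, embed
with Barnes-Hut t-SNE on the phenotyping markers, over-cluster the 2-D
embedding with k-means (k=40) so the dimensionality reduction is
preserved in the clusters, optionally merge clusters within embedding
islands (curation), score every curated cluster against all other cells
with marker enrichment modeling (MEM), and cut the Ward dendrogram of the
MEM profiles into metaclusters (default 21). No event is excluded or
double counted at any step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from cytofpipe.core import EventTable, concat_tables
from cytofpipe.gating import find_valley


def _gate_threshold(x: np.ndarray) -> float:
    """Valley threshold for a positivity gate; on unimodal channels only
    clear outliers count as positive."""
    v = find_valley(x)
    if v is not None:
        return v
    med = float(np.median(x))
    sd = 1.4826 * float(np.median(np.abs(x - med))) or float(np.std(x)) or 1.0
    return med + 3.0 * sd

MEM_CAP = 10.0


def subsample_equal(
    tables: dict[str, EventTable], n_per_file: int = 5206, seed: int = 0
) -> EventTable:
    """Draw exactly ``n_per_file`` events without replacement from every
    sample and pool them, keeping sample/batch annotations."""
    rng = np.random.default_rng(seed)
    parts = []
    for sample in sorted(tables):
        t = tables[sample]
        if t.n_events < n_per_file:
            raise ValueError(
                f"sample {sample!r} has {t.n_events} events, fewer than "
                f"n_per_file={n_per_file}; exclude it with filter_samples first"
            )
        idx = rng.choice(t.n_events, n_per_file, replace=False)
        sub = t.take(np.sort(idx))
        sub.sample_ids = np.full(n_per_file, sample, dtype=object)
        parts.append(sub)
    return concat_tables(parts)


def embed(
    table: EventTable,
    markers: list[str] | None = None,
    perplexity: float = 30.0,
    theta: float = 0.5,
    iterations: int = 4000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Barnes-Hut t-SNE of the marker matrix; returns (tsne1, tsne2, KL).

    ``theta`` is the Barnes-Hut angle. Coordinates are reproducible for a
    fixed seed on the same platform.
    """
    markers = markers if markers is not None else table.panel.embedding_markers()
    X = table.marker_values(markers).to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in embedding input")
    if len(X) < 100:
        raise ValueError("need at least 100 events to embed")
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        angle=theta,
        max_iter=iterations,
        init="pca",
        learning_rate="auto",
        random_state=seed,
        method="barnes_hut",
    )
    Y = ts.fit_transform(X)
    return Y[:, 0], Y[:, 1], float(ts.kl_divergence_)


def kmeans_clusters(
    tsne1: np.ndarray, tsne2: np.ndarray, k: int = 40, seed: int = 0, n_init: int = 10
) -> np.ndarray:
    """k-means over the 2-D embedding only; cluster ids 1..k."""
    Y = np.column_stack([tsne1, tsne2])
    if k > len(Y):
        raise ValueError(f"k={k} exceeds the {len(Y)} embedded events")
    km = KMeans(n_clusters=k, random_state=seed, n_init=n_init)
    return km.fit_predict(Y) + 1


def suggest_merges(
    tsne1: np.ndarray,
    tsne2: np.ndarray,
    cluster_ids: np.ndarray,
    max_centroid_dist_frac: float = 0.04,
) -> dict[int, int]:
    """Suggest a merge map collapsing clusters whose embedding centroids
    are mutual nearest neighbours within a small fraction of the map span
    (a reproducible stand-in for manual island curation)."""
    ids = np.unique(cluster_ids)
    cents = np.array([
        [tsne1[cluster_ids == c].mean(), tsne2[cluster_ids == c].mean()] for c in ids
    ])
    span = max(np.ptp(tsne1), np.ptp(tsne2))
    d = np.linalg.norm(cents[:, None] - cents[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    nn = d.argmin(axis=1)
    merge = {int(c): int(c) for c in ids}
    for i, c in enumerate(ids):
        j = nn[i]
        if nn[j] == i and d[i, j] < max_centroid_dist_frac * span:
            lo, hi = sorted((int(c), int(ids[j])))
            merge[hi] = merge[lo]
    return merge


def curate_clusters(cluster_ids: np.ndarray, merge_map: dict[int, int]) -> np.ndarray:
    """Relabel clusters through ``merge_map``; curated ids are consecutive
    1..m in order of the smallest merged member. Events are conserved."""
    ids = np.unique(cluster_ids)
    missing = [int(c) for c in ids if int(c) not in merge_map]
    if missing:
        raise ValueError(f"merge_map lacks cluster ids {missing}")
    targets = sorted({merge_map[int(c)] for c in ids})
    relabel = {t: i + 1 for i, t in enumerate(targets)}
    lut = {int(c): relabel[merge_map[int(c)]] for c in ids}
    return np.array([lut[int(c)] for c in cluster_ids])


# ---------------------------------------------------------------------------
# MEM
# ---------------------------------------------------------------------------


@dataclass
class MEMMatrix:
    """Clusters x markers signed enrichment scores on a [-10, 10] scale.

    ``score`` holds the rescaled scores; ``mag_pop``/``mag_ref`` the
    population and reference medians and ``iqr_pop``/``iqr_ref`` the
    interquartile ranges they were built from.
    """

    score: pd.DataFrame
    mag_pop: pd.DataFrame
    mag_ref: pd.DataFrame
    iqr_pop: pd.DataFrame
    iqr_ref: pd.DataFrame

    @property
    def clusters(self) -> list:
        return list(self.score.index)


def mem_raw_score(
    mag_pop: float, mag_ref: float, iqr_pop: float, iqr_ref: float
) -> float:
    """Unscaled MEM score for one (cluster, marker):
    (|MAG_pop - MAG_ref| + IQR_ref/IQR_pop - 1) clamped below at 0 and
    signed by (MAG_pop - MAG_ref)."""
    mag = abs(mag_pop - mag_ref) + iqr_ref / iqr_pop - 1.0
    mag = max(mag, 0.0)
    return mag if mag_pop >= mag_ref else -mag


def mem_scores(
    table: EventTable,
    curated_ids: np.ndarray,
    markers: list[str] | None = None,
    min_cluster_size: int = 20,
    iqr_epsilon: float = 0.5,
) -> MEMMatrix:
    """MEM enrichment of every cluster against all other cells.

    The reference for cluster c is the pooled set of events outside c.
    A zero population IQR is substituted by ``iqr_epsilon`` (transformed
    scale) with a warning. The final matrix is rescaled so the largest
    absolute score is 10 (an all-zero matrix stays zero).
    """
    markers = markers if markers is not None else table.panel.embedding_markers()
    ids = np.unique(curated_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 clusters for MEM scoring")
    small = [int(c) for c in ids if (curated_ids == c).sum() < min_cluster_size]
    if small:
        warnings.warn(
            f"clusters below {min_cluster_size} events: {small}; "
            "their MEM scores are noisy",
            UserWarning, stacklevel=2,
        )
    X = table.marker_values(markers).to_numpy(dtype=float)

    raw = np.zeros((len(ids), len(markers)))
    mag_pop = np.zeros_like(raw)
    mag_ref = np.zeros_like(raw)
    iqr_pop = np.zeros_like(raw)
    iqr_ref = np.zeros_like(raw)
    warned_iqr = False
    for i, c in enumerate(ids):
        inside = curated_ids == c
        pop = X[inside]
        ref = X[~inside]
        mp = np.median(pop, axis=0)
        mr = np.median(ref, axis=0)
        q75p, q25p = np.percentile(pop, [75, 25], axis=0)
        q75r, q25r = np.percentile(ref, [75, 25], axis=0)
        ip = q75p - q25p
        ir = q75r - q25r
        if np.any(ip == 0):
            if not warned_iqr:
                warnings.warn(
                    f"zero population IQR; substituting epsilon={iqr_epsilon}",
                    UserWarning, stacklevel=2,
                )
                warned_iqr = True
            ip = np.where(ip == 0, iqr_epsilon, ip)
        ir = np.where(ir == 0, iqr_epsilon, ir)
        mag_pop[i], mag_ref[i], iqr_pop[i], iqr_ref[i] = mp, mr, ip, ir
        for j in range(len(markers)):
            raw[i, j] = mem_raw_score(mp[j], mr[j], ip[j], ir[j])

    peak = np.abs(raw).max()
    score = raw * (MEM_CAP / peak) if peak > 0 else raw

    def df(a: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(a, index=list(ids), columns=markers)

    return MEMMatrix(df(score), df(mag_pop), df(mag_ref), df(iqr_pop), df(iqr_ref))


def metacluster(
    mem: MEMMatrix,
    n_meta: int = 21,
    method: str = "ward",
    metric: str = "euclidean",
) -> tuple[dict[int, int], np.ndarray, np.ndarray]:
    """Hierarchically cluster MEM rows and cut into ``n_meta`` groups.

    Returns (cluster -> metacluster id map, row linkage over clusters,
    column linkage over markers).
    """
    M = mem.score.to_numpy()
    if n_meta > len(M):
        raise ValueError(f"n_meta={n_meta} exceeds {len(M)} curated clusters")
    row_link = linkage(M, method=method, metric=metric)
    col_link = linkage(M.T, method=method, metric=metric)
    labels = fcluster(row_link, t=n_meta, criterion="maxclust")
    return (
        {int(c): int(l) for c, l in zip(mem.clusters, labels)},
        row_link,
        col_link,
    )


def metacluster_events(curated_ids: np.ndarray, meta_map: dict[int, int]) -> np.ndarray:
    """Propagate the cluster -> metacluster map to events."""
    return np.array([meta_map[int(c)] for c in curated_ids])


# ---------------------------------------------------------------------------
# embedding-space T-cell gating
# ---------------------------------------------------------------------------


def map_gate(
    tsne1: np.ndarray,
    tsne2: np.ndarray,
    table: EventTable,
    cd3_threshold: float | None = None,
    cd4_threshold: float | None = None,
    cd8_threshold: float | None = None,
) -> dict[str, np.ndarray]:
    """Gate total CD3 cells and the CD4/CD8/DN partition.

    CD3+ events are selected by CD3 intensity (threshold at the density
    valley unless supplied); within CD3+, CD4/CD8 biaxial thresholds
    partition events into CD4 T, CD8 T, DN (CD4- CD8-) and a CD4+CD8+
    remainder (DP). Masks are mutually exclusive within CD3+.
    """
    cd3 = table.marker_values("CD3").to_numpy(dtype=float)
    cd4 = table.marker_values("CD4").to_numpy(dtype=float)
    cd8 = table.marker_values("CD8").to_numpy(dtype=float)
    t3 = _gate_threshold(cd3) if cd3_threshold is None else cd3_threshold
    cd3_mask = cd3 >= t3
    if cd3_mask.sum() == 0:
        warnings.warn("no CD3+ events at the chosen threshold", UserWarning, stacklevel=2)
        empty = np.zeros_like(cd3_mask)
        return {"CD3": cd3_mask, "CD4_T": empty, "CD8_T": empty,
                "DN_T": empty, "DP_T": empty}
    t4 = _gate_threshold(cd4[cd3_mask]) if cd4_threshold is None else cd4_threshold
    t8 = _gate_threshold(cd8[cd3_mask]) if cd8_threshold is None else cd8_threshold
    pos4 = cd4 >= t4
    pos8 = cd8 >= t8
    return {
        "CD3": cd3_mask,
        "CD4_T": cd3_mask & pos4 & ~pos8,
        "CD8_T": cd3_mask & pos8 & ~pos4,
        "DN_T": cd3_mask & ~pos4 & ~pos8,
        "DP_T": cd3_mask & pos4 & pos8,
    }
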