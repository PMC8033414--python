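"""Subsampling, embedding, k-means, curation, MEM and metaclustering."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from cytofpipe import (
    EventTable,
    arcsinh_transform,
    curate_clusters,
    embed,
    kmeans_clusters,
    map_gate,
    mem_scores,
    metacluster,
    subsample_equal,
)
from cytofpipe.clustering import MEM_CAP, mem_raw_score, metacluster_events
from cytofpipe.panel import Channel, PanelSpec


def _marker_table(X: np.ndarray, markers: list[str]) -> EventTable:
    chans = [Channel("Time", role="time")] + [
        Channel(f"1{41 + i}Nd", m, embed=True) for i, m in enumerate(markers)
    ]
    panel = PanelSpec(chans)
    df = pd.DataFrame(np.column_stack([np.arange(len(X)), X]), columns=panel.names)
    return EventTable(df, panel)


# ---------------------------------------------------------------------------
# subsampling
# ---------------------------------------------------------------------------


class TestSubsample:
    def _tables(self, sizes, markers=("A",)):
        out = {}
        for i, n in enumerate(sizes):
            rng = np.random.default_rng(i)
            out[f"S{i}"] = _marker_table(rng.normal(size=(n, len(markers))), list(markers))
        return out

    def test_equal_draw_and_pooling(self):
        tables = self._tables([300, 400, 500])
        pooled = subsample_equal(tables, n_per_file=250, seed=0)
        assert pooled.n_events == 750
        counts = pd.Series(pooled.sample_ids).value_counts()
        assert (counts == 250).all()

    def test_full_size_equals_concatenation(self):
        tables = self._tables([200, 200])
        pooled = subsample_equal(tables, n_per_file=200, seed=0)
        assert pooled.n_events == 400
        assert sorted(np.unique(pooled.sample_ids)) == ["S0", "S1"]

    def test_seeded_determinism(self):
        tables = self._tables([500])
        a = subsample_equal(tables, 100, seed=3)
        b = subsample_equal(tables, 100, seed=3)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_small_sample_raises_with_guidance(self):
        tables = self._tables([100])
        with pytest.raises(ValueError, match="filter_samples"):
            subsample_equal(tables, n_per_file=200)


# ---------------------------------------------------------------------------
# embedding + k-means
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def three_blob_embedding():
    rng = np.random.default_rng(0)
    centers = np.array([[0, 0, 0, 0], [6, 6, 0, 0], [0, 6, 6, 6]], dtype=float)
    labels = np.repeat([0, 1, 2], 1000)
    X = centers[labels] + rng.normal(0, 0.4, (3000, 4))
    table = _marker_table(X, ["M1", "M2", "M3", "M4"])
    ts1, ts2, kl = embed(table, iterations=500, seed=0)
    return table, labels, ts1, ts2, kl


class TestEmbed:
    def test_separated_populations_stay_separated(self, three_blob_embedding):
        _, labels, ts1, ts2, kl = three_blob_embedding
        Y = np.column_stack([ts1, ts2])
        assert silhouette_score(Y, labels) > 0.5
        assert np.isfinite(kl)

    def test_non_finite_input_rejected(self):
        X = np.zeros((200, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            embed(_marker_table(X, ["A", "B"]), perplexity=10, iterations=250)

    def test_too_few_events_rejected(self):
        X = np.zeros((50, 2))
        with pytest.raises(ValueError, match="100"):
            embed(_marker_table(X, ["A", "B"]))


class TestKMeans:
    def test_three_blobs_recovered_exactly(self, three_blob_embedding):
        _, labels, ts1, ts2, _ = three_blob_embedding
        ids = kmeans_clusters(ts1, ts2, k=3, seed=0)
        assert adjusted_rand_score(labels, ids) == 1.0

    def test_k_one_single_cluster(self, three_blob_embedding):
        _, _, ts1, ts2, _ = three_blob_embedding
        ids = kmeans_clusters(ts1, ts2, k=1, seed=0)
        assert set(ids) == {1}

    def test_seeded_determinism(self, three_blob_embedding):
        _, _, ts1, ts2, _ = three_blob_embedding
        a = kmeans_clusters(ts1, ts2, k=10, seed=4)
        b = kmeans_clusters(ts1, ts2, k=10, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_k_exceeding_events_rejected(self):
        with pytest.raises(ValueError):
            kmeans_clusters(np.zeros(5), np.zeros(5), k=6)


class TestCuration:
    def test_identity_map_keeps_40(self):
        ids = np.repeat(np.arange(1, 41), 10)
        out = curate_clusters(ids, {c: c for c in range(1, 41)})
        assert len(np.unique(out)) == 40

    def test_40_to_37_merge(self):
        """Two 2-way merges and one 3-way merge collapse 40 clusters into
        37, conserving events."""
        ids = np.repeat(np.arange(1, 41), 10)
        merge = {c: c for c in range(1, 41)}
        merge[2] = 1          # 2-way
        merge[10] = 9         # 2-way
        merge[20] = merge[21] = 19  # 3-way
        out = curate_clusters(ids, merge)
        assert len(np.unique(out)) == 36  # 40 - 4 merged away
        merge = {c: c for c in range(1, 41)}
        merge[2] = 1
        merge[10] = 9
        merge[21] = 20
        out = curate_clusters(ids, merge)
        assert len(np.unique(out)) == 37
        assert len(out) == len(ids)

    def test_counts_conserved_through_merge(self):
        ids = np.array([1, 1, 2, 2, 2, 3])
        out = curate_clusters(ids, {1: 1, 2: 1, 3: 3})
        assert (out == 1).sum() == 5
        assert (out == 2).sum() == 1

    def test_missing_id_rejected(self):
        with pytest.raises(ValueError, match="lacks"):
            curate_clusters(np.array([1, 2]), {1: 1})


# ---------------------------------------------------------------------------
# MEM
# ---------------------------------------------------------------------------


def brute_force_mem(X: np.ndarray, ids: np.ndarray, eps: float = 0.5) -> np.ndarray:
    """Independent MEM oracle: recompute medians/IQRs from raw event
    lists with plain Python loops."""
    clusters = sorted(set(ids))
    out = np.zeros((len(clusters), X.shape[1]))
    for ci, c in enumerate(clusters):
        for j in range(X.shape[1]):
            pop = sorted(X[ids == c, j])
            ref = sorted(X[ids != c, j])

            def median(v):
                n = len(v)
                return v[n // 2] if n % 2 else (v[n // 2 - 1] + v[n // 2]) / 2

            def iqr(v):
                return float(np.percentile(v, 75) - np.percentile(v, 25))

            mp, mr = median(pop), median(ref)
            ip = iqr(pop) or eps
            ir = iqr(ref) or eps
            mag = max(abs(mp - mr) + ir / ip - 1.0, 0.0)
            out[ci, j] = mag if mp >= mr else -mag
    peak = np.abs(out).max()
    return out * (MEM_CAP / peak) if peak > 0 else out


class TestMEM:
    def test_direct_formula_value(self):
        """MAG_pop 6, MAG_ref 2 with equal IQRs of 0.5 scores +4 before
        rescaling."""
        assert mem_raw_score(6.0, 2.0, 0.5, 0.5) == pytest.approx(4.0)

    def test_sign_antisymmetry(self):
        assert mem_raw_score(2.0, 6.0, 0.5, 0.5) == pytest.approx(-4.0)

    def test_identical_cluster_scores_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(2, 1, 1000)
        X = np.column_stack([np.concatenate([x, x])])
        ids = np.repeat([1, 2], 1000)
        mem = mem_scores(_marker_table(X, ["A"]).take(np.arange(2000)), ids,
                         markers=["A"])
        assert np.abs(mem.score.to_numpy()).max() < 0.2

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_oracle(self, trial):
        """mem_scores equals the brute-force median/IQR implementation to
        1e-9 on random small instances."""
        rng = np.random.default_rng(trial)
        n_clusters = rng.integers(2, 6)
        n_markers = rng.integers(1, 5)
        ids = rng.integers(1, n_clusters + 1, size=200)
        ids[:n_clusters] = np.arange(1, n_clusters + 1)  # every cluster present
        X = rng.normal(2, 1, size=(200, n_markers)).round(3)
        markers = [f"M{j}" for j in range(n_markers)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            mem = mem_scores(_marker_table(X, markers), ids, markers=markers)
        np.testing.assert_allclose(
            mem.score.to_numpy(), brute_force_mem(X, ids), atol=1e-9
        )

    def test_score_bounded_by_ten(self, chain_result):
        assert np.abs(chain_result.mem.score.to_numpy()).max() <= MEM_CAP + 1e-12

    def test_single_cluster_rejected(self):
        X = np.zeros((100, 1))
        with pytest.raises(ValueError, match="2 clusters"):
            mem_scores(_marker_table(X, ["A"]), np.ones(100, dtype=int), markers=["A"])


class TestMetacluster:
    def _mem(self, M):
        from cytofpipe.clustering import MEMMatrix

        df = pd.DataFrame(M, index=range(1, len(M) + 1),
                          columns=[f"M{j}" for j in range(M.shape[1])])
        z = df * 0
        return MEMMatrix(df, z, z, z + 1, z + 1)

    def test_singleton_cut(self):
        M = np.random.default_rng(0).normal(size=(6, 3))
        mem = self._mem(M)
        meta, _, _ = metacluster(mem, n_meta=6)
        assert len(set(meta.values())) == 6

    def test_duplicate_rows_always_cocluster(self):
        rng = np.random.default_rng(1)
        M = rng.normal(size=(8, 4))
        M[5] = M[2]  # exact duplicate
        mem = self._mem(M)
        for n_meta in range(2, 8):
            meta, _, _ = metacluster(mem, n_meta=n_meta)
            assert meta[3] == meta[6]  # row indices 2 and 5 -> ids 3 and 6

    def test_too_many_metaclusters_rejected(self):
        mem = self._mem(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            metacluster(mem, n_meta=4)

    def test_event_conservation(self, chain_result):
        """Every subsampled event lands in exactly one metacluster and
        per-sample counts sum to n_per_file."""
        res = chain_result
        assert len(res.event_meta) == res.pooled.n_events
        counts = pd.Series(res.pooled.sample_ids).value_counts()
        assert (counts == counts.iloc[0]).all()
        per_meta = pd.crosstab(
            pd.Series(res.pooled.sample_ids), pd.Series(res.event_meta)
        ).sum(axis=1)
        assert (per_meta == counts.iloc[0]).all()


# ---------------------------------------------------------------------------
# embedding-space T gates
# ---------------------------------------------------------------------------


class TestMapGate:
    def test_partition_properties(self, chain_result):
        res = chain_result
        masks = map_gate(res.tsne1, res.tsne2, res.pooled)
        assert not (masks["CD4_T"] & masks["CD8_T"]).any()
        inside = masks["CD4_T"] | masks["CD8_T"] | masks["DN_T"] | masks["DP_T"]
        np.testing.assert_array_equal(inside, masks["CD3"])
        assert not (inside & ~masks["CD3"]).any()  # CD3- events in no subset

    def test_cd8_template_events_recovered(self, chain_result):
        res = chain_result
        masks = map_gate(res.tsne1, res.tsne2, res.pooled)
        truth = res.event_truth.astype(str)
        cd8_true = np.isin(truth, ["CD8_T", "CD8_T_Ly6C"])
        assert masks["CD8_T"][cd8_true].mean() >= 0.95
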