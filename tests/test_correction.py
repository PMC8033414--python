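"""Arcsinh transform and the three unanchored correction algorithms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from cytofpipe import (
    EventTable,
    apply_correction,
    arcsinh_transform,
    evaluate_correction,
    fit_correction,
)
from cytofpipe.correction import inverse_arcsinh
from cytofpipe.panel import Channel, PanelSpec


def _batch(values_by_marker: dict[str, np.ndarray], batch_id: str) -> EventTable:
    chans = [Channel("Time", role="time")] + [
        Channel(f"1{40 + i}Nd", m) for i, m in enumerate(values_by_marker)
    ]
    panel = PanelSpec(chans)
    n = len(next(iter(values_by_marker.values())))
    df = pd.DataFrame({"Time": np.arange(n, dtype=float)})
    for i, (m, v) in enumerate(values_by_marker.items()):
        df[f"1{40 + i}Nd_{m}"] = v
    return EventTable(df[panel.names], panel, batch_id=batch_id)


class TestArcsinh:
    def test_closed_form_values(self, small_cohort):
        _, tables, _ = small_cohort
        t = tables[0].copy()
        col = t.panel.by_marker("CD3").name
        t.data.loc[0, col] = 0.0
        t.data.loc[1, col] = 5.0
        out = arcsinh_transform(t, cofactor=5)
        assert out.data.loc[0, col] == 0.0
        assert out.data.loc[1, col] == pytest.approx(np.arcsinh(1.0), abs=1e-9)

    def test_invertible(self, small_cohort):
        _, tables, _ = small_cohort
        t = tables[0].take(np.arange(500))
        back = inverse_arcsinh(arcsinh_transform(t))
        np.testing.assert_allclose(
            back.data.to_numpy(), t.data.to_numpy(), rtol=1e-9, atol=1e-9
        )

    def test_time_channel_untouched(self, small_cohort):
        _, tables, _ = small_cohort
        t = tables[0]
        out = arcsinh_transform(t)
        np.testing.assert_array_equal(out.data["Time"], t.data["Time"])

    def test_invalid_cofactor(self, small_cohort):
        _, tables, _ = small_cohort
        with pytest.raises(ValueError):
            arcsinh_transform(tables[0], cofactor=0)


class TestRangeCorrection:
    def test_interval_alignment_forced_example(self):
        """Batch intervals [1, 9] and [2, 18] map onto the mean interval
        [1.5, 13.5]; corrected quantiles agree to 1e-9."""
        rng = np.random.default_rng(0)
        a = _batch({"X": rng.uniform(1, 9, 50_001)}, "A")
        b = _batch({"X": rng.uniform(2, 18, 50_001)}, "B")
        # pin the exact extreme quantiles
        a.data.iloc[0, 1], a.data.iloc[1, 1] = 1.0, 9.0
        b.data.iloc[0, 1], b.data.iloc[1, 1] = 2.0, 18.0
        model = fit_correction({"A": a, "B": b}, ["X"], "range",
                               quantile_pair=(0.0, 1.0))
        out = apply_correction(model, {"A": a, "B": b})
        for t in out.values():
            lo, hi = np.quantile(t.marker_values("X"), [0.0, 1.0])
            assert lo == pytest.approx(1.5, abs=1e-9)
            assert hi == pytest.approx(13.5, abs=1e-9)

    def test_quantile_pair_equalized(self, small_cohort):
        _, tables, _ = small_cohort
        batches = {t.batch_id: arcsinh_transform(t) for t in tables}
        markers = ["CD3", "CD11b", "Ly6-G"]
        model = fit_correction(batches, markers, "range")
        out = apply_correction(model, batches)
        for m in markers:
            qs = [np.quantile(t.marker_values(m), [0.001, 0.999]) for t in out.values()]
            np.testing.assert_allclose(qs[0], qs[1], atol=1e-9)

    def test_identical_batches_near_identity(self):
        rng = np.random.default_rng(1)
        x = rng.normal(3, 1, 20_000)
        a = _batch({"X": x}, "A")
        b = _batch({"X": x.copy()}, "B")
        model = fit_correction({"A": a, "B": b}, ["X"], "range")
        out = apply_correction(model, {"A": a, "B": b})
        assert np.abs(out["A"].marker_values("X").to_numpy() - x).max() < 1e-6


class TestQuantileCorrection:
    def test_all_deciles_equalized(self, small_cohort):
        _, tables, _ = small_cohort
        batches = {t.batch_id: arcsinh_transform(t) for t in tables}
        model = fit_correction(batches, ["CD11b"], "quantile")
        out = apply_correction(model, batches)
        deciles = [
            np.quantile(t.marker_values("CD11b"), np.linspace(0.1, 0.9, 9))
            for t in out.values()
        ]
        np.testing.assert_allclose(deciles[0], deciles[1], atol=5e-3)


class TestWarpCorrection:
    def test_shifted_unimodal_modes_align(self):
        """Two shifted bimodal batches (so at least two landmarks exist)
        end with their major modes within 0.05 of each other."""
        rng = np.random.default_rng(2)
        def mk(shift):
            x = np.concatenate([
                rng.normal(0.5 + shift * 0.2, 0.3, 8_000),
                rng.normal(2 + shift, 0.5, 20_000),
            ])
            return x
        a = _batch({"X": mk(0.0)}, "A")
        b = _batch({"X": mk(1.0)}, "B")
        model = fit_correction({"A": a, "B": b}, ["X"], "warp")
        out = apply_correction(model, {"A": a, "B": b})

        def mode(x):
            kde = sstats.gaussian_kde(x)
            grid = np.linspace(x.min(), x.max(), 1024)
            d = kde(grid)
            return grid[np.argmax(d)]

        m_a = mode(out["A"].marker_values("X").to_numpy())
        m_b = mode(out["B"].marker_values("X").to_numpy())
        assert abs(m_a - m_b) < 0.05

    def test_unimodal_falls_back_to_range(self):
        rng = np.random.default_rng(3)
        a = _batch({"X": rng.normal(2, 0.5, 10_000)}, "A")
        b = _batch({"X": rng.normal(3, 0.5, 10_000)}, "B")
        with pytest.warns(UserWarning, match="falling back"):
            model = fit_correction({"A": a, "B": b}, ["X"], "warp")
        assert model.metadata["fallbacks"] == ["X"]


class TestContracts:
    def test_method_none_is_identity(self, small_cohort):
        _, tables, _ = small_cohort
        batches = {t.batch_id: arcsinh_transform(t.take(np.arange(2000))) for t in tables}
        model = fit_correction(batches, ["CD3"], "none")
        out = apply_correction(model, batches)
        for b in batches:
            pd.testing.assert_frame_equal(out[b].data, batches[b].data)

    @pytest.mark.parametrize("method", ["range", "quantile", "warp"])
    def test_within_batch_rank_preserved(self, small_cohort, method):
        """Every correction is monotone: Spearman rho pre/post = 1."""
        _, tables, _ = small_cohort
        batches = {t.batch_id: arcsinh_transform(t.take(np.arange(4000))) for t in tables}
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_correction(batches, ["CD11b"], method)
        out = apply_correction(model, batches)
        for b in batches:
            pre = batches[b].marker_values("CD11b").to_numpy()
            post = out[b].marker_values("CD11b").to_numpy()
            rho = sstats.spearmanr(pre, post).statistic
            assert rho == pytest.approx(1.0, abs=1e-12)

    def test_idempotent_up_to_tolerance(self, small_cohort):
        _, tables, _ = small_cohort
        batches = {t.batch_id: arcsinh_transform(t) for t in tables}
        model = fit_correction(batches, ["CD3"], "range")
        once = apply_correction(model, batches)
        model2 = fit_correction(once, ["CD3"], "range")
        twice = apply_correction(model2, once)
        for b in batches:
            np.testing.assert_allclose(
                twice[b].marker_values("CD3"), once[b].marker_values("CD3"), atol=1e-9
            )

    def test_commutes_with_event_permutation(self, small_cohort):
        _, tables, _ = small_cohort
        batches = {t.batch_id: arcsinh_transform(t.take(np.arange(3000))) for t in tables}
        model = fit_correction(batches, ["CD3"], "range")
        out = apply_correction(model, batches)
        perm = np.random.default_rng(0).permutation(3000)
        shuffled = {b: t.take(perm) for b, t in batches.items()}
        model_p = fit_correction(shuffled, ["CD3"], "range")
        out_p = apply_correction(model_p, shuffled)
        for b in batches:
            np.testing.assert_allclose(
                out_p[b].marker_values("CD3").to_numpy(),
                out[b].marker_values("CD3").to_numpy()[perm],
                atol=1e-12,
            )

    def test_constant_marker_skipped_with_warning(self):
        a = _batch({"X": np.full(1000, 2.0)}, "A")
        b = _batch({"X": np.random.default_rng(0).normal(2, 1, 1000)}, "B")
        with pytest.warns(UserWarning, match="constant"):
            model = fit_correction({"A": a, "B": b}, ["X"], "range")
        out = apply_correction(model, {"A": a, "B": b})
        np.testing.assert_array_equal(out["A"].marker_values("X"), a.marker_values("X"))


@pytest.fixture(scope="module")
def planted():
    """Two batches drawn from one truth, corrupted by per-batch scale
    effects; the truth tables allow EMD-to-truth comparisons."""
    rng = np.random.default_rng(7)

    def mixture(w, n):
        comp = rng.random(n) < w
        return np.where(comp, rng.normal(1.0, 0.3, n), rng.normal(4.0, 0.4, n))

    truth = {"A": mixture(0.7, 20_000), "B": mixture(0.3, 20_000)}
    scales = {"A": 1.0, "B": 1.35}
    corrupted = {b: truth[b] * scales[b] for b in truth}
    batches = {b: _batch({"X": corrupted[b]}, b) for b in corrupted}
    return truth, batches


class TestEvaluation:
    def test_range_reduces_emd_on_scale_effects(self, planted):
        truth, batches = planted
        model = fit_correction(batches, ["X"], "range")
        out = apply_correction(model, batches)
        report = evaluate_correction(batches, {"range": out}, ["X"])
        emd = report.set_index(["method", "marker"])["emd"]
        assert emd[("range", "X")] < emd[("uncorrected", "X")]

    def test_quantile_worse_than_range_against_truth(self, planted):
        """On bimodal mixtures with different component weights, full
        quantile normalization erases real biology: its corrected data
        sit further from the uncorrupted truth than range-corrected
        data."""
        truth, batches = planted
        outs = {}
        for method in ("range", "quantile"):
            model = fit_correction(batches, ["X"], method)
            outs[method] = apply_correction(model, batches)
        emd_to_truth = {
            method: np.mean([
                sstats.wasserstein_distance(
                    outs[method][b].marker_values("X").to_numpy(), truth[b]
                )
                for b in batches
            ])
            for method in outs
        }
        assert emd_to_truth["quantile"] > emd_to_truth["range"]

    def test_identity_has_zero_gap_and_same_metrics(self, planted):
        _, batches = planted
        model = fit_correction(batches, ["X"], "none")
        out = apply_correction(model, batches)
        report = evaluate_correction(batches, {"none": out}, ["X"])
        r = report.set_index(["method", "marker"])
        assert r.loc[("none", "X"), "zero_gap"] == 0.0
        assert r.loc[("none", "X"), "emd"] == pytest.approx(
            r.loc[("uncorrected", "X"), "emd"]
        )
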