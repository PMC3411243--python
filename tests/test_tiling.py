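import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st

from conect.datamodel import GeneModel
from conect.tiling import (
    ExpressionCall,
    ProbePanel,
    background_threshold,
    call_genes,
    exon_and_isoform_levels,
    gc_correct,
    make_signal_track,
    median_filter,
    median_filter_3x3,
    quantile_normalize,
)

matrices = st.integers(2, 4).flatmap(
    lambda r: st.integers(3, 30).flatmap(
        lambda n: st.lists(
            st.lists(st.floats(0.1, 1e4, allow_nan=False), min_size=n, max_size=n),
            min_size=r, max_size=r,
        )
    )
)


def _panel(values, gc=None, is_random=None, gene_ids=None, n_probes=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[1]
    probes = pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n)],
            "chrom": ["c"] * n,
            "start": np.arange(n) * 33,
            "length": 50,
            "gc_count": gc if gc is not None else [25] * n,
            "is_random": is_random if is_random is not None else [False] * n,
            "gene_id": gene_ids if gene_ids is not None else ["g"] * n,
            "exon_index": 0,
        }
    )
    probes.loc[probes["is_random"], "gene_id"] = None
    return ProbePanel(probes, values)


class TestQuantileNormalize:
    def test_identical_replicates_are_fixed_point(self):
        m = np.array([[3.0, 1.0, 2.0], [3.0, 1.0, 2.0]])
        assert np.allclose(quantile_normalize(m), m)

    def test_hand_computed_mean_order_statistics(self):
        m = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        out = quantile_normalize(m)
        assert np.allclose(out, [[2.5, 3.5, 4.5], [2.5, 3.5, 4.5]])

    @settings(deadline=None, max_examples=40)
    @given(matrices)
    def test_sorted_rows_identical_after_normalization(self, rows):
        # ties are averaged, so the exact order-statistic identity is asserted
        # on tie-free rows only
        assume(all(len(set(row)) == len(row) for row in rows))
        m = np.array(rows)
        out = quantile_normalize(m)
        ref = np.sort(out[0])
        for r in range(out.shape[0]):
            assert np.allclose(np.sort(out[r]), ref)

    @settings(deadline=None, max_examples=40)
    @given(matrices)
    def test_rank_order_preserved_within_replicate(self, rows):
        m = np.array(rows)
        out = quantile_normalize(m)
        for r in range(m.shape[0]):
            for i in range(m.shape[1]):
                for j in range(m.shape[1]):
                    if m[r, i] < m[r, j]:
                        assert out[r, i] <= out[r, j]

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(np.array([[1.0, 2.0]]))


class TestMedianFilter:
    def test_constant_matrix_unchanged(self):
        m = np.full((3, 7), 4.2)
        chroms = np.array(["c"] * 7)
        starts = np.arange(7)
        assert np.allclose(median_filter_3x3(m, chroms, starts), 4.2)

    def test_three_by_three_window_median(self):
        m = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]])
        out = median_filter_3x3(m, np.array(["c"] * 3), np.arange(3))
        assert out[1] == 5.0  # median of 1..9

    def test_chromosome_edge_truncates_window(self):
        m = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]])
        out = median_filter_3x3(m, np.array(["c", "c"]), np.arange(2))
        assert out[0] == np.median([1, 10, 2, 20, 3, 30])

    def test_chromosomes_never_bridged(self):
        m = np.array([[1.0, 1.0, 100.0, 100.0]] * 3)
        chroms = np.array(["a", "a", "b", "b"])
        out = median_filter_3x3(m, chroms, np.array([0, 1, 0, 1]))
        assert np.allclose(out, [1, 1, 100, 100])

    def test_output_bounded_by_window_extrema(self, rng):
        m = rng.lognormal(0, 1, size=(3, 25))
        out = median_filter_3x3(m, np.array(["c"] * 25), np.arange(25))
        assert (out >= m.min()).all() and (out <= m.max()).all()

    def test_per_replicate_mode_keeps_matrix_shape(self, rng):
        m = rng.lognormal(0, 1, size=(3, 10))
        out = median_filter(m, np.array(["c"] * 10), np.arange(10), cross_replicate=False)
        assert out.shape == m.shape


class TestGcCorrect:
    def test_flat_random_probes_give_constant_shift(self, rng):
        n = 200
        is_random = [i % 2 == 0 for i in range(n)]
        values = np.full((2, n), 64.0)
        panel = _panel(values, gc=[20 + (i % 10) for i in range(n)], is_random=is_random)
        out = gc_correct(panel)
        assert np.allclose(out.intensities, 64.0)

    def test_linear_gc_bias_removed_from_random_bin_medians(self, rng):
        n = 600
        gc = rng.integers(15, 36, n)
        is_random = rng.random(n) < 0.5
        log2 = 8.0 + 0.1 * gc + rng.normal(0, 0.3, (3, n))
        panel = _panel(2.0**log2, gc=gc, is_random=list(is_random))
        out = gc_correct(panel)
        corrected = np.log2(out.intensities[0, is_random])
        gcs = gc[is_random]
        medians = [np.median(corrected[gcs == b]) for b in np.unique(gcs)]
        assert np.ptp(medians) < 1e-9  # per-bin medians all equal

    def test_no_random_probes_rejected(self):
        panel = _panel(np.ones((2, 4)), is_random=[False] * 4)
        with pytest.raises(ValueError, match="random"):
            gc_correct(panel)


class TestBackgroundThreshold:
    def test_identical_distributions_yield_infinite_threshold(self, rng):
        vals = rng.lognormal(0, 1, 2000)
        t = background_threshold(vals[:1000], vals[1000:], q=0.02)
        assert np.isinf(t)

    def test_separated_distributions_threshold_in_gap(self, rng):
        random_vals = rng.lognormal(0, 1, 1000)
        genic = rng.lognormal(8, 1, 1000)
        t = background_threshold(random_vals, genic, q=0.02)
        assert random_vals.max() < t <= genic.max()
        assert (genic >= t).mean() > 0.95

    def test_threshold_monotone_in_q(self, rng):
        random_vals = rng.lognormal(0, 1, 1000)
        genic = np.concatenate([rng.lognormal(0, 1, 500), rng.lognormal(3, 1, 500)])
        t_strict = background_threshold(random_vals, genic, q=0.01)
        t_loose = background_threshold(random_vals, genic, q=0.10)
        assert t_loose <= t_strict

    def test_too_few_random_probes_rejected(self, rng):
        with pytest.raises(ValueError, match="random"):
            background_threshold(rng.lognormal(0, 1, 50), rng.lognormal(0, 1, 100))


class TestLevelsAndCalls:
    def test_exon_level_is_probe_median(self):
        panel = _panel(np.array([[2.0, 4.0, 6.0]]), gene_ids=["g"] * 3)
        gene = GeneModel("g", "c", "+", [(0, 150)], [("g.t1", [0])])
        exon_levels, iso = exon_and_isoform_levels(panel, np.array([2.0, 4.0, 6.0]), [gene])
        assert exon_levels[("g", 0)] == 4.0
        assert iso["g.t1"] == 4.0

    def test_isoform_mean_is_unweighted_by_exon_length(self):
        probes = pd.DataFrame(
            {
                "probe_id": ["a", "b"],
                "chrom": ["c", "c"],
                "start": [0, 5000],
                "length": 50,
                "gc_count": 25,
                "is_random": False,
                "gene_id": "g",
                "exon_index": [0, 1],
            }
        )
        panel = ProbePanel(probes, np.array([[4.0, 8.0]]))
        gene = GeneModel("g", "c", "+", [(0, 100), (5000, 15000)], [("g.t1", [0, 1])])
        _, iso = exon_and_isoform_levels(panel, np.array([4.0, 8.0]), [gene])
        assert iso["g.t1"] == 6.0  # not pulled toward the 10 kb exon

    def test_probeless_exon_excluded_from_isoform_mean(self):
        panel = _panel(np.array([[4.0]]), gene_ids=["g"])
        gene = GeneModel("g", "c", "+", [(0, 100), (5000, 5100)], [("g.t1", [0, 1])])
        _, iso = exon_and_isoform_levels(panel, np.array([4.0]), [gene])
        assert iso["g.t1"] == 4.0

    def test_present_requires_strictly_more_than_frac(self):
        vals = np.array([[1.0] * 8 + [0.0] * 2])  # 80% above a 0.5 threshold
        panel = _panel(vals, gene_ids=["g"] * 10)
        (call,) = call_genes(panel, vals, [0.5])
        assert call.present == [True]
        exactly = np.array([[1.0] * 7 + [0.0] * 3])  # exactly 70%
        (call,) = call_genes(_panel(exactly, gene_ids=["g"] * 10), exactly, [0.5])
        assert call.present == [False]

    def test_gene_without_probes_gets_na_call(self):
        vals = np.array([[1.0] * 4])
        panel = _panel(vals, gene_ids=["g"] * 4)
        calls = call_genes(panel, vals, [0.5], all_gene_ids=["g", "ghost"])
        ghost = next(c for c in calls if c.gene_id == "ghost")
        assert ghost.consensus_present is None

    def test_present_fraction_monotone_in_threshold(self, rng):
        vals = rng.lognormal(3, 1, size=(1, 40))[None][0]
        panel = _panel(vals, gene_ids=["g"] * 40)
        fracs = []
        for t in np.quantile(vals, [0.1, 0.5, 0.9]):
            (call,) = call_genes(panel, vals, [t])
            fracs.append(call.fraction_above[0])
        assert fracs == sorted(fracs, reverse=True)


class TestSignalTrack:
    def test_probe_below_subtraction_constant_scores_zero(self, rng):
        random_vals = rng.lognormal(0, 1, 500)
        cutoff = np.quantile(random_vals, 0.98)
        vals = np.array([cutoff - 1.0, cutoff + 1.0])
        panel = _panel(vals[None, :], gene_ids=["g", "g"])
        track = make_signal_track(panel, vals, random_vals)
        assert track["score"].iloc[0] == 0.0
        assert track["score"].iloc[1] == pytest.approx(1.0)

    def test_all_random_panel_keeps_about_two_percent(self, rng):
        vals = rng.lognormal(0, 1, 5000)
        panel = _panel(vals[None, :], is_random=[True] * 5000)
        track = make_signal_track(panel, vals, vals)
        frac = (track["score"] > 0).mean()
        assert 0.01 <= frac <= 0.03

    def test_track_coordinates_are_one_based_inclusive(self):
        vals = np.array([[5.0]])
        panel = _panel(vals, gene_ids=["g"])
        track = make_signal_track(panel, vals[0], np.zeros(500))
        assert (track["start"].iloc[0], track["end"].iloc[0]) == (1, 50)
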