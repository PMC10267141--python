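"""Pairwise FC measures against brute-force oracles, plus matrix reductions."""

import numpy as np
import pytest

import ictalgraph as ig
from ictalgraph.cohort import State
from ictalgraph.config import DEFAULT_BANDS
from ictalgraph.connectivity import (
    FCMatrix,
    aec_pair,
    distance_normalize,
    fc_matrices,
    nodal_strength,
    oaec_pair,
    patient_median_strength,
    plv_pair,
)
from ictalgraph.preprocessing import SegmentSet, band_filter
from oracles import brute_aec, brute_oaec, brute_plv

FS = 500.0


def _noise_pair(seed, band=(15, 29), n=1500):
    rng = np.random.default_rng(seed)
    x = band_filter(rng.standard_normal(n), band, FS)
    y = band_filter(rng.standard_normal(n), band, FS)
    return x, y


class TestDegenerateAndAnalyticCases:
    def test_identical_signals(self, band_noise_pair):
        x, _ = band_noise_pair
        assert plv_pair(x, x) == pytest.approx(1.0, abs=1e-12)
        assert aec_pair(x, x) == pytest.approx(1.0, abs=1e-12)
        assert oaec_pair(x, x) == 0.0

    def test_oaec_ignores_rescaling_collinearity(self, band_noise_pair):
        x, _ = band_noise_pair
        assert oaec_pair(x, 3.0 * x) == 0.0

    def test_plv_of_phase_lagged_sinusoid(self):
        t = np.arange(1500) / FS
        x = np.sin(2 * np.pi * 10 * t)
        y = np.sin(2 * np.pi * 10 * t - 0.8)
        assert plv_pair(x, y) == pytest.approx(1.0, abs=1e-6)

    def test_constant_signal_warns_and_returns_zero(self):
        x = np.zeros(1500)
        with pytest.warns(UserWarning):
            assert plv_pair(x, x) == 0.0
        with pytest.warns(UserWarning):
            assert aec_pair(x, x) == 0.0


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
@pytest.mark.parametrize(
    "pair_fn,oracle",
    [(plv_pair, brute_plv), (aec_pair, brute_aec), (oaec_pair, brute_oaec)],
    ids=["plv", "aec", "oaec"],
)
def test_oracle_equivalence_on_noise_pairs(pair_fn, oracle, seed):
    """Each measure matches an independent brute-force implementation of its
    textbook definition to 1e-10 on random band-limited 3-s pairs."""
    x, y = _noise_pair(seed)
    assert pair_fn(x, y) == pytest.approx(oracle(x, y), abs=1e-10)


class TestMeasureProperties:
    def test_symmetry_and_amplitude_invariance(self):
        x, y = _noise_pair(11)
        for fn in (plv_pair, aec_pair, oaec_pair):
            assert fn(x, y) == pytest.approx(fn(y, x), abs=1e-10)
        for fn in (plv_pair, aec_pair):
            assert fn(2.5 * x, 7.0 * y) == pytest.approx(fn(x, y), abs=1e-10)

    def test_shared_envelope_couples_aec_without_phase_locking(self):
        """Two alpha-band carriers at different frequencies sharing one slow
        amplitude modulator: high AEC, low PLV, oAEC well above the null."""
        t = np.arange(3000) / FS
        rng = np.random.default_rng(5)
        mod = 1.0 + 0.8 * np.sin(2 * np.pi * 1.3 * t + rng.uniform(0, 6))
        x = mod * np.sin(2 * np.pi * 9 * t)
        y = mod * np.sin(2 * np.pi * 11 * t + 1.0)
        assert aec_pair(x, y) >= 0.8
        assert plv_pair(x, y) < 0.3
        # orthogonalization removes only the zero-lag collinear component
        assert oaec_pair(x, y) > 0.3
        assert abs(oaec_pair(x, y) - aec_pair(x, y)) < 0.5


class TestFCMatrices:
    def _segset(self, data_list, state=State.ICTAL):
        return SegmentSet(segments=data_list, band="beta", state=state, fs=FS)

    def test_vectorized_matches_pairwise(self):
        """The all-pairs path must equal the public pairwise functions."""
        rng = np.random.default_rng(2)
        seg = band_filter(rng.standard_normal((4, 1500)), (15, 29), FS)
        mats = fc_matrices(self._segset([seg]), ("AEC", "oAEC", "PLV"))
        for i in range(4):
            for j in range(i + 1, 4):
                assert mats["AEC"].values[i, j] == pytest.approx(
                    aec_pair(seg[i], seg[j]), abs=1e-10
                )
                assert mats["PLV"].values[i, j] == pytest.approx(
                    plv_pair(seg[i], seg[j]), abs=1e-10
                )
                assert mats["oAEC"].values[i, j] == pytest.approx(
                    oaec_pair(seg[i], seg[j]), abs=1e-10
                )

    def test_segment_averaging_is_arithmetic_mean(self):
        rng = np.random.default_rng(3)
        segs = [band_filter(rng.standard_normal((3, 1500)), (15, 29), FS) for _ in range(2)]
        per = [fc_matrices(self._segset([s]), ("AEC",))["AEC"].values for s in segs]
        avg = fc_matrices(self._segset(segs), ("AEC",))["AEC"].values
        np.testing.assert_allclose(avg, (per[0] + per[1]) / 2, atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            fc_matrices(self._segset([np.zeros((1, 1500))]))

    def test_offdiagonal_range_and_symmetry(self, hub_patient):
        fcs = ig.patient_fc(
            hub_patient, measures=("AEC",), bands=[DEFAULT_BANDS["beta"]],
            states=("ictal",),
        )
        fc = fcs[("AEC", "beta", State.ICTAL)]
        off = fc.values[~np.isnan(fc.values)]
        assert off.min() >= 0.0 and off.max() <= 1.0
        np.testing.assert_array_equal(fc.values, fc.values.T)


def _matrix(vals, **kw):
    kw.setdefault("measure", "AEC")
    return FCMatrix(values=np.asarray(vals, float), **kw)


class TestDistanceNormalize:
    def _shaft_channels(self, zs):
        return [
            ig.ChannelInfo(f"d{i}", "depth", "s1", (0.0, 0.0, float(z)))
            for i, z in enumerate(zs)
        ]

    def test_reference_pair_is_most_distant_and_ratio_applied(self):
        chans = self._shaft_channels([0, 5, 10])
        v = np.array(
            [[np.nan, 0.4, 0.5], [0.4, np.nan, 0.3], [0.5, 0.3, np.nan]]
        )
        out = distance_normalize(_matrix(v), chans)
        # reference pair = contacts 0 and 2 (distance 10 mm), FC 0.5
        assert out.values[0, 1] == pytest.approx(0.8)
        assert out.values[1, 2] == pytest.approx(0.6)
        assert out.values[0, 2] == pytest.approx(1.0)

    def test_values_capped_at_one(self):
        chans = self._shaft_channels([0, 5, 10])
        v = np.array(
            [[np.nan, 0.9, 0.5], [0.9, np.nan, 0.3], [0.5, 0.3, np.nan]]
        )
        out = distance_normalize(_matrix(v), chans)
        assert out.values[0, 1] == 1.0

    def test_all_subdural_patient_unchanged(self):
        chans = [
            ig.ChannelInfo(f"g{i}", "subdural", None, (float(10 * i), 0, 0))
            for i in range(3)
        ]
        v = np.array([[np.nan, 0.4, 0.5], [0.4, np.nan, 0.3], [0.5, 0.3, np.nan]])
        out = distance_normalize(_matrix(v), chans)
        np.testing.assert_array_equal(out.values[~np.isnan(out.values)],
                                      v[~np.isnan(v)])

    def test_zero_reference_warns_and_skips(self):
        chans = self._shaft_channels([0, 5, 10])
        v = np.array([[np.nan, 0.4, 0.0], [0.4, np.nan, 0.3], [0.0, 0.3, np.nan]])
        with pytest.warns(UserWarning, match="unnormalized"):
            out = distance_normalize(_matrix(v), chans)
        assert out.values[0, 1] == pytest.approx(0.4)


class TestNodalStrength:
    def test_three_node_arithmetic(self):
        v = np.array([[np.nan, 0.2, 0.6], [0.2, np.nan, 0.4], [0.6, 0.4, np.nan]])
        raw = nodal_strength(_matrix(v), normalize=False)
        np.testing.assert_allclose(raw.values, [0.4, 0.3, 0.5])
        norm = nodal_strength(_matrix(v))
        np.testing.assert_allclose(norm.values, [0.8, 0.6, 1.0])

    def test_complete_graph_equal_edges(self):
        v = np.full((4, 4), 0.3)
        np.testing.assert_allclose(nodal_strength(_matrix(v)).values, 1.0)

    def test_two_nodes_single_edge(self):
        v = np.array([[np.nan, 0.25], [0.25, np.nan]])
        np.testing.assert_allclose(nodal_strength(_matrix(v)).values, [1.0, 1.0])


class TestPatientMedianStrength:
    def _nsv(self, vals):
        return ig.NodalStrengthVector(np.asarray(vals, float), "AEC", normalized=True)

    def test_median_and_subsets(self):
        nsv = self._nsv([0.8, 0.6, 1.0])
        assert patient_median_strength(nsv) == pytest.approx(0.8)
        assert patient_median_strength(nsv, np.array([2])) == pytest.approx(1.0)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            patient_median_strength(self._nsv([0.5]), np.array([], dtype=int))
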