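"""Chromatogram decomposition: peak handling, site selection, estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicefrac import (
    ChromatogramTrace,
    InformativeSite,
    ReferencePair,
    TraceParams,
    detect_peaks,
    estimate_fraction_amplitude,
    estimate_fraction_lsq,
    extract_peak_amplitudes,
    find_informative_sites,
    reverse_complement,
    simulate_trace,
)
from splicefrac.traces import CHANNELS, lsq_design, mixture_sse


def grid_search_fraction(trace, refs, step=1e-3):
    """Brute-force oracle: exhaustive search of the mixture objective."""
    obs, ep, em = lsq_design(trace, refs)
    grid = np.arange(0.0, 1.0 + step / 2, step)
    sse = [mixture_sse(f, obs, ep, em) for f in grid]
    return float(grid[int(np.argmin(sse))])


class TestReferencePair:
    def test_long_sequence_is_insert_spliced_in(self):
        refs = ReferencePair("AAACCC", "GGG", 3)
        assert refs.long_seq == "AAAGGGCCC"

    @pytest.mark.parametrize(
        "short,insert,offset",
        [("AAACCC", "GGG", 7), ("AAACCC", "", 3), ("AAXCCC", "GGG", 3)],
    )
    def test_invalid_pairs_rejected(self, short, insert, offset):
        with pytest.raises(ValueError):
            ReferencePair(short, insert, offset)

    @given(
        short=st.text(alphabet="ACGT", min_size=1, max_size=30),
        insert=st.text(alphabet="ACGT", min_size=1, max_size=10),
        data=st.data(),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_reverse_complement_commutes_with_insertion(self, short, insert, data):
        offset = data.draw(st.integers(0, len(short)))
        refs = ReferencePair(short, insert, offset)
        rc = refs.reverse_complemented()
        assert rc.long_seq == reverse_complement(refs.long_seq)
        assert rc.short_seq == reverse_complement(refs.short_seq)


class TestDetectPeaks:
    def test_recovers_all_peaks_of_noiseless_trace(self, noiseless):
        refs = ReferencePair("ACGTACG", "TGC", 3)  # 10-base long read
        trace = simulate_trace(1.0, refs, noiseless)
        found = detect_peaks(trace.channels, noiseless.peak_spacing)
        assert found.size == 10
        assert np.all(np.abs(found - trace.peak_positions) <= 1)

    def test_flat_signal_yields_no_peaks(self):
        assert detect_peaks(np.zeros((100, 4)), 10.0).size == 0

    def test_close_peaks_collapse_to_lower_index(self):
        x = np.arange(120, dtype=float)
        signal = np.exp(-0.5 * ((x - 40) / 2.0) ** 2) + np.exp(
            -0.5 * ((x - 45) / 2.0) ** 2
        )
        channels = np.zeros((120, 4))
        channels[:, 0] = signal
        found = detect_peaks(channels, expected_spacing=12.0)
        assert found.size == 1
        assert abs(found[0] - 40) <= 1


class TestExtractPeakAmplitudes:
    def test_pure_trace_has_one_dominant_channel_per_peak(self, refs, noiseless):
        trace = simulate_trace(1.0, refs, noiseless)
        table = extract_peak_amplitudes(trace, smooth_sigma=0.0)
        long_seq = refs.long_seq
        for i, row in enumerate(table):
            top = int(np.argmax(row))
            assert CHANNELS[top] == long_seq[i]
            others = np.delete(row, top)
            assert np.all(others <= 1e-6 * row[top])

    def test_even_mixture_splits_decayed_amplitude(self, refs):
        params = TraceParams(noise_sd=0.0, decay_rate=0.01)
        trace = simulate_trace(0.5, refs, params)
        table = extract_peak_amplitudes(trace, smooth_sigma=0.0)
        site = find_informative_sites(refs, n_sites=1)[0]
        expected = 0.5 * params.base_amplitude * math.exp(
            -params.decay_rate * site.peak_index
        )
        for base in (site.base_plus, site.base_minus):
            value = table[site.peak_index, CHANNELS.index(base)]
            assert value == pytest.approx(expected, rel=1e-6)

    def test_single_peak_trace_gives_1x4_table(self):
        channels = np.zeros((30, 4))
        channels[15, 2] = 7.0
        trace = ChromatogramTrace(channels, np.array([15]))
        assert extract_peak_amplitudes(trace, smooth_sigma=0.0).shape == (1, 4)

    def test_empty_trace_rejected(self):
        trace = ChromatogramTrace(np.zeros((10, 4)), np.array([], dtype=int))
        with pytest.raises(ValueError):
            extract_peak_amplitudes(trace)


class TestFindInformativeSites:
    def test_insert_against_shifted_read(self):
        refs = ReferencePair("AAACCC", "GGG", 3)
        sites = find_informative_sites(refs, n_sites=3)
        assert [(s.peak_index, s.base_plus, s.base_minus) for s in sites] == [
            (3, "G", "C"),
            (4, "G", "C"),
            (5, "G", "C"),
        ]

    def test_homopolymer_junction_has_no_informative_sites(self):
        refs = ReferencePair("AAAA", "AA", 2)
        with pytest.warns(UserWarning, match="truncat"):
            assert find_informative_sites(refs, n_sites=3, window=3) == []

    def test_default_uses_three_sites(self, refs):
        assert len(find_informative_sites(refs)) == 3

    def test_window_truncated_at_short_read_end_with_warning(self):
        refs = ReferencePair("AAACCC", "GGG", 3)
        with pytest.warns(UserWarning, match="truncat"):
            sites = find_informative_sites(refs, n_sites=5, window=50)
        assert all(s.peak_index < len(refs.short_seq) for s in sites)


class TestAmplitudeRatio:
    def test_constant_ratio_sites(self):
        table = np.zeros((3, 4))
        # plus base G (col 2), minus base T (col 3)
        table[:, 2] = 30.0
        table[:, 3] = 70.0
        sites = [InformativeSite(i, "G", "T") for i in range(3)]
        est = estimate_fraction_amplitude(table, sites)
        assert est.fraction == pytest.approx(0.30)
        assert est.sd == 0.0
        assert est.method == "amplitude_ratio"

    def test_pure_minus_trace_estimates_zero(self, refs, noiseless):
        trace = simulate_trace(0.0, refs, noiseless)
        sites = find_informative_sites(refs)
        est = estimate_fraction_amplitude(extract_peak_amplitudes(trace), sites)
        assert est.fraction == pytest.approx(0.0, abs=1e-6)

    def test_ratio_cancels_signal_decay(self, refs):
        params = TraceParams(noise_sd=0.0, decay_rate=0.02)
        trace = simulate_trace(0.25, refs, params)
        sites = find_informative_sites(refs)
        est = estimate_fraction_amplitude(extract_peak_amplitudes(trace), sites)
        assert est.fraction == pytest.approx(0.25, abs=1e-6)

    def test_dead_sites_dropped_then_error_when_all_dead(self):
        table = np.zeros((2, 4))
        table[0, 2], table[0, 3] = 10.0, 30.0
        sites = [InformativeSite(0, "G", "T"), InformativeSite(1, "G", "T")]
        with pytest.warns(UserWarning, match="zero signal"):
            est = estimate_fraction_amplitude(table, sites)
        assert est.fraction == pytest.approx(0.25)
        assert est.n_sites == 1
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                estimate_fraction_amplitude(np.zeros((2, 4)), sites)

    def test_mean_within_site_range(self, refs):
        trace = simulate_trace(0.4, refs, TraceParams(seed=3))
        sites = find_informative_sites(refs)
        est = estimate_fraction_amplitude(extract_peak_amplitudes(trace), sites)
        assert min(est.per_site_fractions) <= est.fraction <= max(est.per_site_fractions)


class TestLeastSquares:
    def test_pure_plus_template_gives_one(self, refs, noiseless):
        trace = simulate_trace(1.0, refs, noiseless)
        assert estimate_fraction_lsq(trace, refs).fraction == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_mixture_recovered_exactly(self, refs, noiseless):
        trace = simulate_trace(0.4, refs, noiseless)
        assert estimate_fraction_lsq(trace, refs).fraction == pytest.approx(0.4, abs=1e-9)

    def test_homopolymer_junction_unidentifiable(self, noiseless):
        refs = ReferencePair("AAAAAA", "AAA", 3)
        trace = simulate_trace(0.5, refs, noiseless)
        with pytest.raises(ValueError, match="unidentifiable"):
            estimate_fraction_lsq(trace, refs)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_grid_search_oracle_on_noisy_traces(self, refs, seed):
        rng = np.random.default_rng(seed)
        f_true = rng.uniform(0, 1)
        trace = simulate_trace(f_true, refs, TraceParams(seed=seed))
        closed = estimate_fraction_lsq(trace, refs).fraction
        assert abs(closed - grid_search_fraction(trace, refs)) <= 1e-3 + 1e-12


class TestEstimatorProperties:
    def test_noiseless_estimate_strictly_increasing_in_truth(self, refs, noiseless):
        fs = np.linspace(0.02, 0.98, 25)
        amp, lsq = [], []
        sites = find_informative_sites(refs)
        for f in fs:
            trace = simulate_trace(float(f), refs, noiseless)
            amp.append(
                estimate_fraction_amplitude(extract_peak_amplitudes(trace), sites).fraction
            )
            lsq.append(estimate_fraction_lsq(trace, refs).fraction)
        assert np.all(np.diff(amp) > 0)
        assert np.all(np.diff(lsq) > 0)

    def test_methods_agree_on_noiseless_traces(self, refs, noiseless):
        sites = find_informative_sites(refs)
        for f in np.linspace(0, 1, 11):
            trace = simulate_trace(float(f), refs, noiseless)
            a = estimate_fraction_amplitude(extract_peak_amplitudes(trace), sites).fraction
            b = estimate_fraction_lsq(trace, refs).fraction
            assert abs(a - b) <= 0.02

    def test_reverse_read_recovers_same_fraction(self, refs, noiseless):
        rc = refs.reverse_complemented()
        trace = simulate_trace(0.35, rc, noiseless)
        sites = find_informative_sites(rc)
        est = estimate_fraction_amplitude(extract_peak_amplitudes(trace), sites)
        assert est.fraction == pytest.approx(0.35, abs=1e-6)
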