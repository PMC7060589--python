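"""CID/HCD pairing, reporter extraction, aggregation, QC and ratios."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import make_psm, make_spectrum
from tmtquant import chemistry as chem
from tmtquant.quantify import (ChannelDesign, QuantConfig, aggregate_protein,
                               compute_ratios, duplicate_qc,
                               duplicate_variation, extract_reporters,
                               merge_into_cid, pair_cid_hcd)

R126 = chem.REPORTER_MZ[126]


def hcd_with_reporters(intensities, scan=2, precursor=500.25):
    peaks = [(chem.REPORTER_MZ[ch], inten)
             for ch, inten in zip(chem.CHANNELS, intensities)]
    return make_spectrum(scan, "HCD", precursor, peaks)


class TestPairing:
    def test_adjacent_pair_with_same_precursor(self):
        cid = make_spectrum(1, "CID", 500.25, [[200.0, 1.0]])
        hcd = make_spectrum(2, "HCD", 500.25, [[R126, 10.0]])
        pairs, unpaired = pair_cid_hcd([cid, hcd])
        assert pairs == [(cid, hcd)] and unpaired == []

    def test_precursor_mismatch_leaves_both_unpaired(self):
        cid = make_spectrum(1, "CID", 500.25, [[200.0, 1.0]])
        hcd = make_spectrum(2, "HCD", 501.25, [[R126, 10.0]])
        pairs, unpaired = pair_cid_hcd([cid, hcd])
        assert pairs == [] and set(id(s) for s in unpaired) == {id(cid), id(hcd)}

    def test_interleaved_pairs_do_not_cross(self):
        c1 = make_spectrum(1, "CID", 500.25, [[200.0, 1.0]])
        h1 = make_spectrum(2, "HCD", 500.25, [[R126, 10.0]])
        c2 = make_spectrum(3, "CID", 600.30, [[200.0, 1.0]])
        h2 = make_spectrum(4, "HCD", 600.30, [[R126, 10.0]])
        pairs, unpaired = pair_cid_hcd([c1, h1, c2, h2])
        assert pairs == [(c1, h1), (c2, h2)] and unpaired == []

    def test_intervening_cid_blocks_pairing(self):
        c1 = make_spectrum(1, "CID", 500.25, [[200.0, 1.0]])
        c2 = make_spectrum(2, "CID", 600.30, [[200.0, 1.0]])
        h1 = make_spectrum(3, "HCD", 500.25, [[R126, 10.0]])
        pairs, unpaired = pair_cid_hcd([c1, c2, h1])
        assert pairs == []
        assert len(unpaired) == 3

    def test_second_hcd_on_same_cid_keeps_first(self, caplog):
        c1 = make_spectrum(1, "CID", 500.25, [[200.0, 1.0]])
        h1 = make_spectrum(2, "HCD", 500.25, [[R126, 10.0]])
        h2 = make_spectrum(3, "HCD", 500.25, [[R126, 20.0]])
        with caplog.at_level("WARNING"):
            pairs, unpaired = pair_cid_hcd([c1, h1, h2])
        assert pairs == [(c1, h1)] and unpaired == [h2]
        assert "already paired" in caplog.text


class TestExtractReporters:
    def test_exact_peak_extracted(self):
        hcd = make_spectrum(2, "HCD", 500.0, [[R126, 1000.0]])
        vec = extract_reporters(hcd)
        assert vec[0] == 1000.0 and np.isnan(vec[1:]).all()

    def test_25_ppm_offset_missed_15_ppm_found(self):
        off = make_spectrum(2, "HCD", 500.0, [[R126 * (1 + 25e-6), 1000.0]])
        assert np.isnan(extract_reporters(off)[0])
        near = make_spectrum(2, "HCD", 500.0, [[R126 * (1 + 15e-6), 1000.0]])
        assert extract_reporters(near)[0] == 1000.0

    def test_most_intense_in_window_wins(self):
        hcd = make_spectrum(2, "HCD", 500.0,
                            [[R126 * (1 - 10e-6), 300.0],
                             [R126 * (1 + 10e-6), 700.0]])
        assert extract_reporters(hcd)[0] == 700.0

    def test_intensity_tie_breaks_by_smaller_ppm_error(self):
        a, b = R126 * (1 - 15e-6), R126 * (1 + 5e-6)
        hcd = make_spectrum(2, "HCD", 500.0, [[a, 500.0], [b, 500.0]])
        vec = extract_reporters(hcd)
        assert vec[0] == 500.0  # the b peak (closer) is chosen, same value
        # distinguish via asymmetric intensities reversed
        hcd2 = make_spectrum(2, "HCD", 500.0, [[a, 500.0], [b, 499.0]])
        assert extract_reporters(hcd2)[0] == 500.0

    def test_cid_scan_rejected(self):
        cid = make_spectrum(1, "CID", 500.0, [[R126, 10.0]])
        with pytest.raises(ValueError, match="not an HCD"):
            extract_reporters(cid)


class TestMerge:
    def test_all_reporters_add_six_peaks(self):
        cid = make_spectrum(1, "CID", 500.25,
                            [[200.0, 1.0], [300.0, 1.0], [400.0, 1.0]])
        hcd = hcd_with_reporters([10, 20, 30, 40, 50, 60])
        vec = extract_reporters(hcd)
        merged = merge_into_cid((cid, hcd), vec)
        assert merged.peaks.shape[0] == 3 + 6
        assert np.all(np.diff(merged.peaks[:, 0]) >= 0)
        # every CID peak preserved
        for mz in (200.0, 300.0, 400.0):
            assert mz in merged.peaks[:, 0]

    def test_no_reporters_returns_cid_unchanged(self):
        cid = make_spectrum(1, "CID", 500.25, [[200.0, 1.0]])
        hcd = make_spectrum(2, "HCD", 500.25, [[300.0, 5.0]])
        vec = extract_reporters(hcd)
        merged = merge_into_cid((cid, hcd), vec)
        assert np.array_equal(merged.peaks, cid.peaks)
        assert np.isnan(merged.reporter_intensities).all()


class TestAggregation:
    def test_single_psm_means_equal_psm(self, design):
        psm = make_psm(1, 1.0, reporters=[100, 200, 150, 100, 200, 150])
        pq = aggregate_protein("P1", [psm], design)
        assert np.array_equal(pq.channel_means, [100, 200, 150, 100, 200, 150])
        assert pq.n_spectra == 1

    def test_two_psms_average_per_channel(self, design):
        psms = [make_psm(1, 1.0, reporters=[100] * 6),
                make_psm(2, 1.0, reporters=[300] * 6)]
        pq = aggregate_protein("P1", psms, design)
        assert np.array_equal(pq.channel_means, [200.0] * 6)

    def test_group_means_follow_channel_scheme(self, design):
        # channel order 126..131; sham = (ch126+ch129)/2 etc.
        psm = make_psm(1, 1.0, reporters=[100, 200, 300, 140, 260, 340])
        pq = aggregate_protein("P1", [psm], design)
        assert pq.group_means[0] == pytest.approx((100 + 140) / 2)  # sham
        assert pq.group_means[1] == pytest.approx((200 + 260) / 2)  # IR
        assert pq.group_means[2] == pytest.approx((300 + 340) / 2)  # TALE

    def test_psm_with_missing_channel_excluded_entirely(self, design):
        good = make_psm(1, 1.0, reporters=[100] * 6)
        bad = make_psm(2, 1.0, reporters=[900, np.nan, 900, 900, 900, 900])
        pq = aggregate_protein("P1", [good, bad], design)
        assert pq.n_spectra == 1
        assert np.array_equal(pq.channel_means, [100.0] * 6)

    def test_no_quantifiable_psm_drops_protein(self, design):
        bad = make_psm(1, 1.0, reporters=[np.nan] * 6)
        assert aggregate_protein("P1", [bad], design) is None


class TestDuplicateQC:
    @pytest.mark.parametrize("a, b, expected", [
        (100.0, 100.0, 0.0),
        (100.0, 140.0, 40 / 120),   # 0.333... -> excluded
        (100.0, 130.0, 30 / 115),   # 0.261 -> retained
    ])
    def test_variation_arithmetic(self, a, b, expected):
        assert duplicate_variation(a, b) == pytest.approx(expected)

    def test_qc_threshold_application(self, design):
        keep = make_psm(1, 1.0, reporters=[100, 100, 100, 130, 130, 130])
        pq = duplicate_qc(aggregate_protein("P1", [keep], design), design)
        assert pq.qc_pass and pq.group_variation.max() == pytest.approx(30 / 115)
        drop = make_psm(1, 1.0, reporters=[100, 100, 100, 140, 140, 140])
        pq2 = duplicate_qc(aggregate_protein("P2", [drop], design), design)
        assert not pq2.qc_pass and "variation" in pq2.qc_reason

    def test_zero_intensity_pair_excluded_with_reason(self, design):
        pq = aggregate_protein(
            "P1", [make_psm(1, 1.0, reporters=[0, 100, 100, 0, 100, 100])],
            design)
        pq = duplicate_qc(pq, design)
        assert not pq.qc_pass and "zero-intensity" in pq.qc_reason

    @settings(deadline=None, derandomize=True)
    @given(vals=st.lists(st.floats(min_value=1.0, max_value=1e6),
                         min_size=6, max_size=6),
           lo=st.floats(min_value=0.05, max_value=0.5),
           delta=st.floats(min_value=0.01, max_value=0.4))
    def test_raising_threshold_never_excludes(self, design, vals, lo, delta):
        pq1 = aggregate_protein("P1", [make_psm(1, 1.0, reporters=vals)], design)
        strict = duplicate_qc(pq1, design, QuantConfig(duplicate_variation_max=lo))
        loose = duplicate_qc(pq1, design,
                             QuantConfig(duplicate_variation_max=lo + delta))
        if strict.qc_pass:
            assert loose.qc_pass


class TestRatios:
    def test_equal_groups_give_zero_contrasts(self, design):
        pq = aggregate_protein("P1", [make_psm(1, 1.0, reporters=[100] * 6)],
                               design)
        pq = compute_ratios(duplicate_qc(pq, design))
        assert pq.log2_ir_vs_sham == 0.0 and pq.log2_tale_vs_ir == 0.0

    def test_doubled_ir_gives_log2_one(self, design):
        pq = aggregate_protein(
            "P1", [make_psm(1, 1.0, reporters=[100, 200, 200, 100, 200, 200])],
            design)
        pq = compute_ratios(duplicate_qc(pq, design))
        assert pq.log2_ir_vs_sham == pytest.approx(1.0)
        assert pq.log2_tale_vs_ir == pytest.approx(0.0)

    def test_swapping_groups_negates_contrast(self, design):
        r1 = [100, 200, 100, 100, 200, 100]
        r2 = [200, 100, 200, 200, 100, 200]
        pqs = [compute_ratios(duplicate_qc(aggregate_protein(
            "P", [make_psm(1, 1.0, reporters=r)], design), design))
            for r in (r1, r2)]
        assert pqs[0].log2_ir_vs_sham == pytest.approx(-pqs[1].log2_ir_vs_sham)

    @settings(deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           vals=st.lists(st.floats(min_value=10.0, max_value=1e5),
                         min_size=6, max_size=6))
    def test_global_intensity_scale_invariance(self, design, scale, vals):
        def contrasts(r):
            pq = aggregate_protein("P", [make_psm(1, 1.0, reporters=r)], design)
            pq.qc_pass = True  # QC is scale-invariant too; bypass it here
            return compute_ratios(pq).log2_ir_vs_sham, compute_ratios(pq).log2_tale_vs_ir
        base = contrasts(vals)
        scaled = contrasts([v * scale for v in vals])
        assert scaled == pytest.approx(base, abs=1e-9)
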