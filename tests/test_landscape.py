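"""Landscape tests: trimming, circular mapping, counting, windows, peaks."""

import numpy as np
import pytest

from hdnakit import (
    call_hotspots,
    circular_substring,
    count_variants,
    map_read,
    normalize_and_window,
    read_sam,
    region_variant_sum,
    trim_read,
)
from hdnakit.motifs import reverse_complement
from hdnakit.simulate import ReadSimSpec, simulate_reads


class TestTrim:
    @pytest.mark.parametrize(
        "length,expected_len",
        [(100, 60), (41, 1), (42, 2)],
    )
    def test_boundary_arithmetic(self, length, expected_len):
        out = trim_read("A" * length)
        assert out is not None and len(out) == expected_len

    @pytest.mark.parametrize("length", [40, 39, 1])
    def test_short_reads_discarded(self, length):
        assert trim_read("A" * length) is None

    def test_qualities_trimmed_in_step(self):
        seq, qual = trim_read("ACGT" * 20, "I" * 80, n=10)
        assert len(seq) == len(qual) == 60


class TestMapRead:
    def test_exact_forward_placement(self, hdna_map):
        read = circular_substring(hdna_map, 101, 200)
        ar = map_read("r", read, hdna_map)
        assert ar is not None
        assert (ar.ref_start, ar.orientation) == (101, "forward")
        assert ar.mismatch_positions == []

    def test_origin_spanning_read_maps_with_wrap(self, hdna_map):
        length = hdna_map.length
        read = circular_substring(hdna_map, length - 49, 50)
        ar = map_read("r", read, hdna_map)
        assert ar is not None
        assert ar.ref_start == length - 49
        assert ar.ref_start + ar.aligned_length - 1 > length

    def test_reverse_complement_same_footprint(self, hdna_map):
        read = circular_substring(hdna_map, 301, 400)
        ar = map_read("r", reverse_complement(read), hdna_map)
        assert ar is not None
        assert (ar.ref_start, ar.orientation) == (301, "reverse")

    def test_ambiguous_placement_unmapped(self):
        from hdnakit import PlasmidMap

        pmap = PlasmidMap(name="rep", sequence="ACGTACGGTTCACGTCAGGA" * 30)
        read = pmap.sequence[:60]  # occurs at every 20-bp period
        assert map_read("r", read, pmap) is None

    @pytest.mark.parametrize("seed", range(3))
    def test_soundness_on_error_free_simulated_reads(self, hdna_map, seed):
        spec = ReadSimSpec(read_length=80, n_reads=60, base_error_rate=0.0,
                           seed=seed)
        reads, _ = simulate_reads(hdna_map, spec)
        doubled = hdna_map.sequence + hdna_map.sequence
        for rid, seq, _ in reads:
            oriented = seq if rid.endswith("fwd") else reverse_complement(seq)
            true_starts = {
                i % hdna_map.length
                for i in range(hdna_map.length)
                if doubled[i : i + 80] == oriented
            }
            ar = map_read(rid, seq, hdna_map)
            if len(true_starts) == 1:
                assert ar is not None
                assert ar.ref_start - 1 in true_starts
                assert ar.mismatch_positions == []


class TestCountingAndNormalization:
    def test_error_free_reads_have_zero_variants(self, hdna_map):
        spec = ReadSimSpec(read_length=80, n_reads=100, base_error_rate=0.0, seed=3)
        reads, _ = simulate_reads(hdna_map, spec)
        aligned = [map_read(r, s, hdna_map) for r, s, _ in reads]
        aligned = [a for a in aligned if a]
        coverage, variants = count_variants(aligned, hdna_map)
        assert variants.sum() == 0
        assert coverage.sum() == sum(a.aligned_length for a in aligned)

    def test_single_mismatch_counted_once(self, hdna_map):
        read = list(circular_substring(hdna_map, 501, 580))
        read[40] = "A" if read[40] != "A" else "C"
        ar = map_read("r", "".join(read), hdna_map)
        coverage, variants = count_variants([ar], hdna_map)
        assert variants.sum() == 1
        assert variants[540] == 1  # position 541, 0-based 540

    def test_error_rate_recovered_within_binomial_error(self, hdna_map):
        rate = 0.002
        spec = ReadSimSpec(read_length=100, n_reads=1500,
                           base_error_rate=rate, seed=5)
        reads, _ = simulate_reads(hdna_map, spec)
        aligned = [map_read(r, s, hdna_map) for r, s, _ in reads]
        aligned = [a for a in aligned if a]
        coverage, variants = count_variants(aligned, hdna_map)
        n_bases = coverage.sum()
        observed = variants.sum() / n_bases
        se = np.sqrt(rate * (1 - rate) / n_bases)
        assert abs(observed - rate) <= 3 * se

    def test_uniform_coverage_leaves_counts_unchanged(self):
        coverage = np.full(200, 7.0)
        variants = np.zeros(200)
        variants[[10, 50, 51]] = [2, 1, 3]
        track = normalize_and_window(coverage, variants, window_size=50)
        np.testing.assert_allclose(track.normalized, variants)

    def test_normalization_depends_only_on_variant_fraction(self):
        # normalized[i] equals the variant fraction times the plasmid-wide
        # mean coverage, so doubling coverage at a position at a fixed
        # fraction changes the value only through the mean-coverage factor
        coverage = np.full(100, 10.0)
        variants = np.zeros(100)
        variants[30] = 2
        t1 = normalize_and_window(coverage, variants, window_size=10)
        coverage2, variants2 = coverage.copy(), variants.copy()
        coverage2[30] *= 2
        variants2[30] *= 2
        t2 = normalize_and_window(coverage2, variants2, window_size=10)
        assert t1.normalized[30] / coverage.mean() == pytest.approx(
            t2.normalized[30] / coverage2.mean())
        assert t2.normalized[30] == pytest.approx(0.2 * coverage2.mean())

    def test_window_mass_conservation_circular(self, rng):
        coverage = rng.integers(5, 30, size=300).astype(float)
        variants = rng.binomial(coverage.astype(int), 0.05).astype(float)
        track = normalize_and_window(coverage, variants, window_size=50)
        assert len(track.windowed) == 300
        assert track.windowed.sum() == pytest.approx(50 * track.normalized.sum())

    def test_constant_track_windows(self):
        coverage = np.full(200, 4.0)
        variants = np.full(200, 1.0)
        track = normalize_and_window(coverage, variants, window_size=50)
        np.testing.assert_allclose(track.windowed, 50.0)

    def test_single_nonzero_position_lights_window_size_windows(self):
        coverage = np.full(200, 4.0)
        variants = np.zeros(200)
        variants[120] = 1
        track = normalize_and_window(coverage, variants, window_size=50)
        assert int((track.windowed > 0).sum()) == 50

    def test_window_larger_than_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize_and_window(np.ones(30), np.zeros(30), window_size=31)

    def test_low_coverage_warns(self):
        coverage = np.zeros(100)
        coverage[:50] = 5
        with pytest.warns(UserWarning, match="coverage"):
            normalize_and_window(coverage, np.zeros(100), window_size=10)


class TestHotspotsAndRegions:
    def _track(self, signal, window=50):
        coverage = np.full(len(signal), 10.0)
        return normalize_and_window(coverage, np.asarray(signal, float),
                                    window_size=window)

    def test_flat_track_has_no_peaks(self):
        track = self._track(np.ones(500))
        assert call_hotspots(track, fold_threshold=5) == []

    def test_all_zero_track_has_no_peaks(self):
        track = self._track(np.zeros(500))
        assert call_hotspots(track) == []

    def test_single_planted_region_yields_one_overlapping_peak(self):
        signal = np.ones(1000) * 0.2
        signal[400:480] = 5.0
        peaks = call_hotspots(self._track(signal), fold_threshold=5)
        assert len(peaks) == 1
        assert peaks[0].start <= 480 and peaks[0].end >= 401

    def test_region_variant_sum_completeness(self):
        signal = np.zeros(300)
        signal[[5, 100, 250]] = [1, 2, 3]
        track = self._track(signal, window=50)
        assert region_variant_sum(track, 1, 300) == pytest.approx(6)
        assert region_variant_sum(track, 60, 90) == 0
        # wrap-around range
        assert region_variant_sum(track, 240, 10) == pytest.approx(4)

    def test_peak_recovery_on_simulated_replicates(self, hdna_map):
        # every >=10x elevated region recovered at fold_threshold 5
        from hdnakit import trim_read

        labels = ["marker_promoter", "bacterial_origin", "viral_promoter",
                  "viral_origin", "hdna_region"]
        feats = {f.label: (f.start, f.end) for f in hdna_map.features}
        for seed in range(3):
            spec = ReadSimSpec(
                read_length=100, n_reads=2000, base_error_rate=0.002,
                region_rates=[(l, 0.02) for l in labels], seed=seed)
            reads, _ = simulate_reads(hdna_map, spec)
            aligned = []
            for rid, seq, _ in reads:
                trimmed = trim_read(seq)
                if trimmed is None:
                    continue
                ar = map_read(rid, trimmed, hdna_map)
                if ar:
                    aligned.append(ar)
            track = normalize_and_window(*count_variants(aligned, hdna_map))
            peaks = call_hotspots(track, fold_threshold=5)
            for label in labels:
                s, e = feats[label]
                assert any(p.start <= e and p.end >= s for p in peaks), \
                    (seed, label)


class TestSamIngestion:
    def test_mismatches_recomputed_from_reference(self, hdna_map, tmp_path):
        read = list(circular_substring(hdna_map, 1001, 1080))
        read[10] = "A" if read[10] != "A" else "C"
        sam = tmp_path / "reads.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            f"@SQ\tSN:{hdna_map.name}\tLN:{hdna_map.length}\n"
            f"r1\t0\t{hdna_map.name}\t1001\t60\t80M\t*\t0\t0\t"
            f"{''.join(read)}\t*\n"
        )
        aligned = read_sam(sam, hdna_map)
        assert len(aligned) == 1
        assert aligned[0].ref_start == 1001
        assert aligned[0].mismatch_positions == [1011]
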