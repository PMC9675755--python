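"""Tag directory, downsampling and local-background peak calling.

The caller is checked against an independently coded exhaustive oracle that
enumerates every fixed-width window at 1 bp steps, applies the same greedy
ordering with bisect-based overlap checks, and recomputes the Poisson tail
through the regularized incomplete gamma function.
"""

import bisect

import numpy as np
import pytest
from scipy import special, stats

from enhancersens.core_io import GenomicInterval
from enhancersens.peakcall import (
    TagTrack,
    call_peaks,
    downsample_tags,
    finalize_peaks,
    make_tag_directory,
)


def track(positions, length=50_000, chrom="chr1"):
    return TagTrack(
        positions={chrom: np.array(positions, dtype=np.int64)},
        chrom_lengths={chrom: length},
    )


class TestTagDirectory:
    def test_tbp_one(self):
        t = make_tag_directory(track([5, 5, 5, 9]), tbp=1)
        assert list(t.positions["chr1"]) == [5, 9] and t.total == 2

    def test_tbp_two(self):
        t = make_tag_directory(track([5, 5, 5, 9]), tbp=2)
        assert list(t.positions["chr1"]) == [5, 5, 9] and t.total == 3

    def test_idempotent_on_unique(self):
        t0 = track([1, 4, 9, 100])
        t1 = make_tag_directory(t0, tbp=1)
        assert list(t1.positions["chr1"]) == [1, 4, 9, 100]


class TestDownsample:
    def test_identity_at_full_target(self):
        t = track([1, 5, 9])
        out = downsample_tags(t, 3, seed=0)
        assert list(out.positions["chr1"]) == [1, 5, 9]

    def test_empty_at_zero(self):
        assert downsample_tags(track([1, 5]), 0, seed=0).total == 0

    def test_target_above_n_rejected(self):
        with pytest.raises(ValueError):
            downsample_tags(track([1]), 2, seed=0)

    def test_uniform_thinning_rate(self):
        # mean retained count per 1 kb bin scales by target/N within binomial error
        rng = np.random.default_rng(0)
        pos = np.sort(rng.integers(0, 50_000, size=5000))
        t = track(pos)
        out = downsample_tags(t, 2500, seed=1)
        kept = out.positions["chr1"]
        bins = np.arange(0, 50_001, 1000)
        h_all, _ = np.histogram(pos, bins)
        h_kept, _ = np.histogram(kept, bins)
        frac = h_kept.sum() / h_all.sum()
        assert frac == 0.5
        # per-bin retention is hypergeometric around 0.5; 4 sigma bound
        p = h_kept / np.maximum(h_all, 1)
        se = np.sqrt(0.25 / np.maximum(h_all, 1))
        assert np.all(np.abs(p - 0.5) < 4 * se + 1e-9)


def oracle_call_peaks(t, control=None, local_size=20_000, fold_min=4.0, p_max=1e-4, width=500):
    """Exhaustive enumeration oracle, coded independently of the caller."""
    peaks = []
    floor = width * t.total / t.genome_length
    for chrom in sorted(t.positions):
        tags = list(t.positions[chrom])
        L = t.chrom_lengths[chrom]
        windows = []
        for s in range(0, L - width + 1):
            n = bisect.bisect_left(tags, s + width) - bisect.bisect_left(tags, s)
            if n > 0:
                windows.append((s, n))
        windows.sort(key=lambda w: (-w[1], w[0]))
        chosen = []
        chosen_sorted = []
        for s, n in windows:
            i = bisect.bisect_left(chosen_sorted, s)
            near = []
            if i > 0:
                near.append(chosen_sorted[i - 1])
            if i < len(chosen_sorted):
                near.append(chosen_sorted[i])
            if any(abs(s - c) < width for c in near):
                continue
            bisect.insort(chosen_sorted, s)
            chosen.append((s, n))
        for s, n in chosen:
            center = s + width // 2
            local = (
                bisect.bisect_left(tags, center + local_size // 2)
                - bisect.bisect_left(tags, center - local_size // 2)
                - n
            )
            expected = max(local * width / (local_size - width), floor)
            fold = n / expected
            # upper tail P(X >= n) through the regularized incomplete gamma
            p = float(special.gammainc(n, expected))
            ok = fold >= fold_min and p < p_max
            if ok and control is not None:
                scale = t.total / control.total
                c_raw = control.count(chrom, s, s + width)
                c_floor = width * control.total / control.genome_length
                ok = n / (max(c_raw, c_floor) * scale) >= fold_min
            if ok:
                peaks.append((chrom, s, n))
    return sorted(peaks)


class TestCallPeaks:
    def test_planted_cluster_arithmetic(self):
        # uniform background 1 tag / 100 bp plus a 60-tag cluster in 500 bp
        bg = np.arange(50, 50_000, 100)
        cluster = np.linspace(20_000, 20_499, 60).astype(int)
        t = track(np.sort(np.concatenate([bg, cluster])))
        peaks = call_peaks(t, local_size=20_000, fold_min=4, p_max=1e-4, peak_width=500)
        assert len(peaks) == 1
        p = peaks[0]
        # 5 bg tags fall inside the window; 195 local bg tags outside it
        assert p.tags == 65
        local_expected = 195 * 500 / 19_500
        floor = 500 * t.total / t.genome_length
        assert p.fold_local == pytest.approx(65 / max(local_expected, floor))
        assert p.fold_local == pytest.approx(12, rel=0.05)

    def test_fold_threshold_excludes(self):
        # cluster fold just below 4 over its local background
        bg = np.arange(0, 50_000, 50)  # 10 per 500 bp window
        cluster = np.linspace(20_000, 20_499, 29).astype(int)
        t = track(np.sort(np.concatenate([bg, cluster])))
        peaks = call_peaks(t, fold_min=4, p_max=1.0)
        # window holds 29+10 tags; local expectation ~10.5 => fold ~3.7 < 4
        assert peaks == []

    def test_empty_track(self):
        assert call_peaks(track([])) == []

    def test_pairwise_nonoverlapping(self):
        rng = np.random.default_rng(3)
        t = track(np.sort(rng.integers(0, 50_000, size=2000)))
        peaks = call_peaks(t, fold_min=0.0, p_max=1.0)
        starts = sorted(p.interval.start for p in peaks)
        assert all(b - a >= 500 for a, b in zip(starts, starts[1:]))

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(4)
        pos = np.sort(
            np.concatenate(
                [rng.integers(0, 50_000, 300), rng.integers(10_000, 10_500, 80)]
            )
        )
        t = track(pos)
        loose = {(p.interval.chrom, p.interval.start) for p in call_peaks(t, fold_min=2, p_max=1e-2)}
        tight_fold = {
            (p.interval.chrom, p.interval.start) for p in call_peaks(t, fold_min=6, p_max=1e-2)
        }
        tight_p = {
            (p.interval.chrom, p.interval.start) for p in call_peaks(t, fold_min=2, p_max=1e-8)
        }
        assert tight_fold <= loose and tight_p <= loose

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_random_chromosomes(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(50_000, 100_000))
        n_bg = int(rng.integers(100, 300))
        pos = [rng.integers(0, L, n_bg)]
        for _ in range(int(rng.integers(1, 5))):
            c = int(rng.integers(5000, L - 5000))
            pos.append(rng.integers(c, c + 500, int(rng.integers(30, 90))))
        t = track(np.sort(np.concatenate(pos)), length=L)
        ctrl = track(np.sort(rng.integers(0, L, n_bg)), length=L)
        got = call_peaks(t, ctrl)
        expected = oracle_call_peaks(t, ctrl)
        assert sorted((p.interval.chrom, p.interval.start, p.tags) for p in got) == expected

    def test_poisson_tail_matches_gamma_identity(self):
        # survival P(X >= k) equals the regularized lower incomplete gamma
        for k, mu in [(3, 1.2), (35, 8.0), (10_000, 9_900.0)]:
            assert stats.poisson.sf(k - 1, mu) == pytest.approx(
                float(special.gammainc(k, mu)), abs=1e-12
            )


class TestFinalize:
    def _peak(self, center, tags, chrom="chr1"):
        from enhancersens.peakcall import Peak

        return Peak(
            interval=GenomicInterval(chrom, max(0, center - 250), center + 250),
            center=center,
            tags=tags,
            fold_local=10.0,
            p_local=1e-9,
            peak_id=f"p{center}",
        )

    def test_min_tag_boundary(self):
        lengths = {"chr1": 50_000}
        kept = finalize_peaks([self._peak(1000, 34), self._peak(3000, 35)], lengths)
        assert [p.tags for p in kept] == [35]

    def test_blacklist_removal(self):
        lengths = {"chr1": 50_000}
        bl = [GenomicInterval("chr1", 1240, 1260)]
        kept = finalize_peaks(
            [self._peak(1000, 50), self._peak(3000, 50)], lengths, blacklist=bl
        )
        assert [p.center for p in kept] == [3000]

    def test_edge_clipping(self):
        lengths = {"chr1": 50_000}
        kept = finalize_peaks([self._peak(100, 50)], lengths)
        assert (kept[0].interval.start, kept[0].interval.end) == (0, 350)
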