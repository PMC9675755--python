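"""Tag-directory construction and peak calling against a local Poisson background.

A *tag* is the 5' position of a deduplicated read; strand is ignored in all
counting. Binding sites are fixed-width windows enriched at least ``fold_min``
over the expected count from the surrounding ``local_size`` bp (Poisson
upper-tail test) and, when a control track is supplied, over the
library-size-scaled control signal as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .core_io import GenomicInterval

log = logging.getLogger("enhancersens")


@dataclass
class TagTrack:
    """Per-chromosome sorted tag positions for one sample.

    ``chrom_lengths`` carries the genome geometry so that window enumeration
    and the genome-wide background floor need no separate genome object.
    """

    positions: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]
    label: tuple[str, str, str] = ("", "", "")  # (assay, condition, replicate)

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if np.any(np.diff(arr) < 0):
                arr = np.sort(arr)
            self.positions[chrom] = arr
            if chrom not in self.chrom_lengths:
                raise ValueError(f"no length for chromosome {chrom}")

    @property
    def total(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def count(self, chrom: str, start: int, end: int) -> int:
        """Tags in [start, end) on one chromosome."""
        pos = self.positions.get(chrom)
        if pos is None:
            return 0
        return int(np.searchsorted(pos, end) - np.searchsorted(pos, start))


@dataclass
class Peak:
    """A called binding site (half-open window of fixed width around center)."""

    interval: GenomicInterval
    center: int
    tags: int
    fold_local: float
    p_local: float
    fold_control: float = float("inf")
    p_control: float = 0.0
    peak_id: str = ""


def merge_tracks(tracks: list[TagTrack], label: tuple[str, str, str] = ("", "pooled", "")) -> TagTrack:
    """Pool several tracks (e.g. replicates) into one sorted track."""
    chroms = {c for t in tracks for c in t.positions}
    positions = {
        c: np.sort(np.concatenate([t.positions[c] for t in tracks if c in t.positions]))
        for c in chroms
    }
    return TagTrack(positions=positions, chrom_lengths=dict(tracks[0].chrom_lengths), label=label)


def make_tag_directory(track: TagTrack, tbp: int = 1) -> TagTrack:
    """Retain at most ``tbp`` tags per (chromosome, position)."""
    if tbp < 1:
        raise ValueError("tbp must be >= 1")
    out: dict[str, np.ndarray] = {}
    for chrom, pos in track.positions.items():
        pos = np.sort(np.asarray(pos, dtype=np.int64))
        if len(pos) == 0:
            out[chrom] = pos
            continue
        # rank of each tag within its run of equal positions
        boundaries = np.flatnonzero(np.diff(pos)) + 1
        starts = np.concatenate([[0], boundaries])
        run_id = np.searchsorted(starts, np.arange(len(pos)), side="right") - 1
        rank_in_run = np.arange(len(pos)) - starts[run_id]
        out[chrom] = pos[rank_in_run < tbp]
    return TagTrack(positions=out, chrom_lengths=dict(track.chrom_lengths), label=track.label)


def downsample_tags(track: TagTrack, target: int, seed: int) -> TagTrack:
    """Uniform subsample without replacement to exactly ``target`` tags."""
    n = track.total
    if target > n:
        raise ValueError(f"target {target} exceeds track size {n}")
    rng = np.random.default_rng(seed)
    keep = np.zeros(n, dtype=bool)
    keep[rng.choice(n, size=target, replace=False)] = True
    out: dict[str, np.ndarray] = {}
    offset = 0
    for chrom in sorted(track.positions):
        pos = track.positions[chrom]
        out[chrom] = pos[keep[offset : offset + len(pos)]]
        offset += len(pos)
    return TagTrack(positions=out, chrom_lengths=dict(track.chrom_lengths), label=track.label)


def _window_counts(pos: np.ndarray, chrom_len: int, width: int) -> np.ndarray:
    """Tag count of every width-bp window start s in [0, chrom_len - width]."""
    n_starts = chrom_len - width + 1
    if n_starts <= 0:
        return np.zeros(0, dtype=np.int64)
    starts = np.arange(n_starts, dtype=np.int64)
    return np.searchsorted(pos, starts + width) - np.searchsorted(pos, starts)


def call_peaks(
    target: TagTrack,
    control: TagTrack | None = None,
    local_size: int = 20000,
    fold_min: float = 4.0,
    p_max: float = 1e-4,
    peak_width: int = 500,
) -> list[Peak]:
    """Greedy fixed-width peak calling with a local Poisson background.

    Every possible ``peak_width`` window (1 bp steps) is a candidate; windows
    are selected greedily in decreasing tag order (leftmost wins ties) under a
    non-overlap constraint, then filtered on local fold/p and, if a control is
    given, on library-scaled control fold.

    The expected local count excludes the candidate window itself and is
    floored at the genome-wide average (``peak_width * N / genome_length``) so
    empty neighborhoods cannot produce infinite folds.
    """
    if target.total == 0:
        log.warning("empty target track; no peaks called")
        return []
    floor = peak_width * target.total / target.genome_length
    scale = (target.total / control.total) if control is not None and control.total > 0 else None

    peaks: list[Peak] = []
    for chrom in sorted(target.positions):
        pos = target.positions[chrom]
        chrom_len = target.chrom_lengths[chrom]
        counts = _window_counts(pos, chrom_len, peak_width)
        if counts.size == 0:
            continue
        cand = np.flatnonzero(counts > 0)
        order = np.lexsort((cand, -counts[cand]))
        cand = cand[order]
        blocked = np.zeros(counts.size, dtype=bool)
        selected: list[int] = []
        for s in cand:
            if blocked[s]:
                continue
            selected.append(int(s))
            blocked[max(0, s - peak_width + 1) : s + peak_width] = True

        for s in selected:
            tags = int(counts[s])
            center = s + peak_width // 2
            lo = center - local_size // 2
            hi = center + local_size // 2
            local_tags = target.count(chrom, lo, hi) - tags
            expected = max(local_tags * peak_width / (local_size - peak_width), floor)
            fold_local = tags / expected
            p_local = float(stats.poisson.sf(tags - 1, expected))
            if control is not None:
                ctrl_raw = control.count(chrom, center - peak_width // 2, center + peak_width // 2)
                ctrl_floor = peak_width * control.total / control.genome_length
                expected_ctrl = max(ctrl_raw, ctrl_floor) * scale
                fold_control = tags / expected_ctrl if expected_ctrl > 0 else float("inf")
                p_control = float(stats.poisson.sf(tags - 1, expected_ctrl))
            else:
                fold_control, p_control = float("inf"), 0.0
            if fold_local >= fold_min and p_local < p_max and fold_control >= fold_min:
                iv = GenomicInterval(chrom, s, s + peak_width)
                peaks.append(
                    Peak(iv, center, tags, fold_local, p_local, fold_control, p_control)
                )
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    for i, p in enumerate(peaks):
        p.peak_id = f"peak_{i:05d}"
    return peaks


def finalize_peaks(
    peaks: list[Peak],
    chrom_lengths: dict[str, int],
    width: int = 500,
    blacklist: list[GenomicInterval] | None = None,
    min_tags: int = 35,
) -> list[Peak]:
    """Extend to fixed width around centers, drop blacklist overlaps and weak peaks.

    Peaks with fewer than ``min_tags`` tags are removed (a count of exactly
    ``min_tags`` is retained); intervals are clipped at chromosome ends, which
    can shrink them below ``width``.
    """
    blacklist = blacklist or []
    out: list[Peak] = []
    for p in peaks:
        chrom = p.interval.chrom
        start = p.center - width // 2
        end = p.center + width // 2
        clipped_start, clipped_end = max(0, start), min(chrom_lengths[chrom], end)
        if (clipped_start, clipped_end) != (start, end):
            log.warning(
                "peak %s clipped to [%d,%d) at %s edge", p.peak_id, clipped_start, clipped_end, chrom
            )
        iv = GenomicInterval(chrom, clipped_start, clipped_end)
        if any(iv.overlaps(b) for b in blacklist):
            continue
        if p.tags < min_tags:
            continue
        out.append(replace(p, interval=iv))
    out.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return out
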