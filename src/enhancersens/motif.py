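"""PWM log-odds scanning and response-element segment dissection.

Scores are natural-log odds (sum over positions of ln(p_base/background)),
so the motif-call threshold and the segment scores are on the same scale as
the common tag-directory tooling. Segment coordinates always refer to the
plus-strand motif model: for a DR1-type response element of length 17 the
segments are the 5' extension (bases 1-4), the receptor half-site that reads
the extension (bases 5-10) and the partner half-site (bases 12-17); base 11
is the spacer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import PWM, encode_sequence, reverse_complement

log = logging.getLogger("enhancersens")

#: 1-based inclusive segment ranges on the plus-strand motif model
SEGMENTS = {"ext5": (1, 4), "ppar_hs": (5, 10), "rxr_hs": (12, 17)}
SPACER = (11, 11)


@dataclass
class MotifHit:
    """Best-scoring motif placement inside a scanned window."""

    feature_id: str
    offset: int  # 0-based start within the scanned window
    strand: str
    score: float
    segment_scores: dict[str, float]

    @property
    def ext5(self) -> float:
        return self.segment_scores["ext5"]

    @property
    def ppar_hs(self) -> float:
        return self.segment_scores["ppar_hs"]

    @property
    def rxr_hs(self) -> float:
        return self.segment_scores["rxr_hs"]


def logodds(pwm: PWM) -> np.ndarray:
    """4xL natural-log odds matrix ln(probs/background)."""
    if np.any(pwm.probs <= 0):
        raise ValueError("zero probability in PWM; use a positive pseudocount")
    return np.log(pwm.probs / pwm.background[:, None])


def _score_positions(encoded: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Score every placement of the motif along an encoded sequence.

    Placements covering an ambiguous base (N) score -inf and are skipped.
    """
    L = lo.shape[1]
    n = len(encoded) - L + 1
    if n <= 0:
        return np.zeros(0)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for i in range(L):
        col = encoded[i : i + n]
        ok = col >= 0
        valid &= ok
        scores += np.where(ok, lo[np.clip(col, 0, 3), i], 0.0)
    scores[~valid] = -np.inf
    return scores


def scan_best(window: str, pwm: PWM, feature_id: str = "") -> MotifHit | None:
    """Best log-odds placement of the motif over both strands of a window.

    Ties break to the lower offset, then to the + strand. Returns ``None``
    when the window is shorter than the motif or every placement covers an N.
    """
    L = pwm.length
    if len(window) < L:
        return None
    window = window.upper()
    lo = logodds(pwm)
    enc_fwd = encode_sequence(window)
    enc_rev = encode_sequence(reverse_complement(window))
    s_fwd = _score_positions(enc_fwd, lo)
    s_rev = _score_positions(enc_rev, lo)
    # map reverse-strand placements back to forward-window offsets
    n = len(s_fwd)
    best = (-np.inf, 0, "+")
    for strand, s in (("+", s_fwd), ("-", s_rev)):
        if s.size == 0 or not np.any(np.isfinite(s)):
            continue
        ties = np.flatnonzero(s == s.max())
        # on the - strand the lowest forward offset is the highest reverse index
        i = int(ties[0]) if strand == "+" else int(ties[-1])
        offset = i if strand == "+" else n - 1 - i
        cand = (float(s[i]), offset, strand)
        if cand[0] > best[0] or (
            cand[0] == best[0] and (cand[1], cand[2]) < (best[1], best[2])
        ):
            best = cand
    score, offset, strand = best
    if not np.isfinite(score):
        return None
    motif_seq = window[offset : offset + L]
    if strand == "-":
        motif_seq = reverse_complement(motif_seq)
    seg = _segment_scores(motif_seq, lo)
    return MotifHit(feature_id, offset, strand, score, seg)


def _segment_scores(motif_seq: str, lo: np.ndarray) -> dict[str, float]:
    enc = encode_sequence(motif_seq)
    L = lo.shape[1]
    per_pos = np.array(
        [lo[enc[i], i] if enc[i] >= 0 else 0.0 for i in range(L)]
    )
    out: dict[str, float] = {}
    for name, (lo1, hi1) in SEGMENTS.items():
        if lo1 > L:
            log.warning("motif length %d too short for segment %s; score 0", L, name)
            out[name] = 0.0
            continue
        hi = min(hi1, L)
        out[name] = float(per_pos[lo1 - 1 : hi].sum())
    lo1, hi1 = SPACER
    out["spacer"] = float(per_pos[lo1 - 1 : min(hi1, L)].sum()) if lo1 <= L else 0.0
    return out


def segment_scores(
    hit: MotifHit, call_threshold: float = -2.0
) -> tuple[float, float, float, bool]:
    """Segment scores of a hit plus the motif call (full score >= threshold)."""
    called = hit.score >= call_threshold
    return hit.ext5, hit.ppar_hs, hit.rxr_hs, called


def scan_peaks(
    genome,
    peaks,
    pwm: PWM,
    flank: int = 100,
) -> list[MotifHit | None]:
    """Best hit in [center - flank, center + flank) for each peak."""
    hits: list[MotifHit | None] = []
    for p in peaks:
        c = p.center
        chrom_len = len(genome.sequences[p.interval.chrom])
        start, end = max(0, c - flank), min(chrom_len, c + flank)
        window = genome.sequences[p.interval.chrom][start:end]
        hits.append(scan_best(window, pwm, feature_id=p.peak_id))
    return hits
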