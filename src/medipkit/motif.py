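"""Position-weight-matrix construction and promoter scanning.

Count matrices are read and written in JASPAR PFM text (via Bio.motifs).
Log-odds scores are built with a background-distributed pseudocount:

    score(b, i) = log2( f(b, i) / background(b) ),
    f(b, i) = (count(b, i) + pc * background(b)) / sum_b'(count(b', i) + pc * background(b'))

Scanning slides the matrix over both strands; the reverse strand scores the
reverse complement.  Windows containing N score -inf and never qualify.
Thresholds are either absolute bits or a fraction t of the achievable score
range, mapped to min + t * (max - min).
"""
from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import motifs as bio_motifs

from .intervals import GenomicInterval

log = logging.getLogger(__name__)

ALPHABET = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class PositionWeightMatrix:
    """A motif: per-position nucleotide counts plus a background model."""

    motif_id: str
    counts: np.ndarray  # shape (4, L), rows in A,C,G,T order
    background: np.ndarray = None  # shape (4,), sums to 1

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        bg = self.background
        bg = np.full(4, 0.25) if bg is None else np.asarray(bg, dtype=float)
        object.__setattr__(self, "background", bg)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must have shape (4, motif_length)")
        if np.any(counts.sum(axis=0) <= 0):
            raise ValueError("every motif position needs a positive count sum")
        if np.any(bg <= 0):
            raise ValueError("background frequencies must be strictly positive")
        if not np.isclose(bg.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    interval: GenomicInterval
    strand: str
    score: float  # bits
    matched_sequence: str


def read_jaspar_pfm(text_or_path) -> list[PositionWeightMatrix]:
    """Parse JASPAR-format PFMs (bracketed 2016+ or raw 4-row matrices)."""
    if hasattr(text_or_path, "read"):
        handle = text_or_path
    elif isinstance(text_or_path, str) and "\n" in text_or_path:
        handle = io.StringIO(text_or_path)
    else:
        handle = open(text_or_path)
    try:
        parsed = bio_motifs.parse(handle, "jaspar")
        out = []
        for m in parsed:
            counts = np.array([m.counts[b] for b in ALPHABET], dtype=float)
            name = m.matrix_id or m.name
            if m.name and m.matrix_id and m.name != m.matrix_id:
                name = m.matrix_id
            out.append(PositionWeightMatrix(motif_id=name, counts=counts))
        return out
    except Exception as exc:  # noqa: BLE001 - re-raise with format context
        raise ValueError(f"malformed JASPAR PFM input: {exc}") from exc
    finally:
        if handle is not text_or_path:
            handle.close()


def write_jaspar_pfm(pwms: Sequence[PositionWeightMatrix], path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id} {pwm.motif_id}\n")
            for i, b in enumerate(ALPHABET):
                row = " ".join(f"{v:.0f}" if float(v).is_integer() else f"{v:g}"
                               for v in pwm.counts[i])
                fh.write(f"{b} [ {row} ]\n")


def pwm_log_odds(
    counts: np.ndarray,
    background: np.ndarray | None = None,
    pseudocount: float = 0.8,
) -> np.ndarray:
    """Per-position per-base log2-odds (bits) with background pseudocount."""
    counts = np.asarray(counts, dtype=float)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if np.any(bg <= 0):
        raise ValueError("background frequencies must be strictly positive")
    adj = counts + pseudocount * bg[:, None]
    freq = adj / adj.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore"):
        return np.log2(freq / bg[:, None])


def _encode_seq(sequence: str) -> np.ndarray:
    """Map A,C,G,T -> 0..3 and anything else -> 4."""
    lut = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate(ALPHABET):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(sequence.encode(), dtype=np.uint8)]


def _strand_scores(lo: np.ndarray, code: np.ndarray) -> np.ndarray:
    """Score every window start on one strand; N windows get -inf."""
    m = lo.shape[1]
    n_win = len(code) - m + 1
    if n_win <= 0:
        return np.zeros(0)
    padded = np.vstack([lo, np.full((1, m), -np.inf)])  # row 4 = N
    scores = np.zeros(n_win)
    for j in range(m):
        scores += padded[code[j : j + n_win], j]
    return scores


def scan_sequence(
    pwm: PositionWeightMatrix,
    sequence: str,
    threshold: float = 0.8,
    threshold_type: str = "fraction",
    pseudocount: float = 0.8,
    chrom: str = "chr1",
) -> list[MotifHit]:
    """Hits of ``pwm`` on both strands of ``sequence``, sorted by position.

    ``threshold_type='fraction'`` maps threshold t to min + t*(max - min) of
    the achievable log-odds scores; ``'bits'`` uses the value directly.
    """
    if len(sequence) < pwm.length:
        raise ValueError("sequence shorter than motif")
    lo = pwm_log_odds(pwm.counts, pwm.background, pseudocount)
    max_score = lo.max(axis=0).sum()
    min_score = lo.min(axis=0).sum()
    if threshold_type == "fraction":
        if not (0 <= threshold <= 1):
            raise ValueError("fraction threshold must be in [0, 1]")
        cut = min_score + threshold * (max_score - min_score)
    elif threshold_type == "bits":
        cut = threshold
        if cut > max_score:
            log.warning(
                "threshold %.2f bits exceeds the max achievable score %.2f; no hits possible",
                cut, max_score,
            )
            return []
    else:
        raise ValueError("threshold_type must be 'fraction' or 'bits'")
    code_fwd = _encode_seq(sequence)
    code_rev = _encode_seq(sequence.translate(_COMP)[::-1])
    fwd = _strand_scores(lo, code_fwd)
    rev = _strand_scores(lo, code_rev)
    n = len(sequence)
    hits: list[MotifHit] = []
    for i in np.flatnonzero(fwd >= cut - 1e-12):
        hits.append(
            MotifHit(
                pwm.motif_id,
                GenomicInterval(chrom, int(i), int(i) + pwm.length, "+"),
                "+",
                float(fwd[i]),
                sequence[i : i + pwm.length].upper(),
            )
        )
    for j in np.flatnonzero(rev >= cut - 1e-12):
        start = n - pwm.length - int(j)  # map reverse-strand window to forward coords
        hits.append(
            MotifHit(
                pwm.motif_id,
                GenomicInterval(chrom, start, start + pwm.length, "-"),
                "-",
                float(rev[j]),
                sequence[start : start + pwm.length].upper().translate(_COMP)[::-1],
            )
        )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def hits_to_bed(hits: Sequence[MotifHit]) -> str:
    """BED6 text: name = motif id, score = bits x 100, rounded."""
    lines = [
        f"{h.interval.chrom}\t{h.interval.start}\t{h.interval.end}\t"
        f"{h.motif_id}\t{round(h.score * 100)}\t{h.strand}"
        for h in hits
    ]
    return "\n".join(lines) + ("\n" if lines else "")
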