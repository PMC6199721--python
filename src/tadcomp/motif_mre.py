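"""PWM construction and motif scanning with exact DP null distributions.

A position weight matrix is built directly from user-supplied aligned
entry-site sequences (21-mers for the MSL recognition element). Scanning
scores every window with the log-odds matrix; per-window p-values come
from the exact distribution of the score under an i.i.d. background,
computed by discretizing per-position scores onto an integer lattice and
convolving position-wise (the FIMO-style dynamic program). The E-value of
a window is its p-value times the number of windows scanned (both strands
counted when enabled); hits are windows with E at or below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_domains import GenomicInterval

__all__ = [
    "PWM",
    "MotifHit",
    "ScoreDistribution",
    "build_pwm",
    "score_null_distribution",
    "scan_sequence",
    "hits_to_intervals",
    "write_hits_bed",
    "read_sites",
]

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_CODE["N"] = 4
DEFAULT_BIN_WIDTH = 0.05


@dataclass
class PWM:
    """Letter probabilities per position, with log2-odds vs background."""

    width: int
    probs: np.ndarray  # (width, 4)
    background: np.ndarray  # (4,)
    log_odds: np.ndarray  # (width, 4), bits
    pseudocount: float

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        probs = self.probs[::-1, ::-1].copy()
        log_odds = np.log2(probs / self.background[None, :])
        return PWM(
            width=self.width,
            probs=probs,
            background=self.background.copy(),
            log_odds=log_odds,
            pseudocount=self.pseudocount,
        )

    def score(self, window: str) -> float:
        """Log-odds score (bits) of one width-length window."""
        codes = _encode(window)
        if (codes == 4).any():
            raise ValueError("cannot score a window containing N")
        return float(self.log_odds[np.arange(self.width), codes].sum())


@dataclass
class MotifHit:
    chrom: str
    start: int  # 0-based
    strand: str
    score: float  # bits
    p_value: float
    e_value: float


@dataclass
class ScoreDistribution:
    """Exact null score distribution on an integer lattice.

    ``int_scores`` are the per-position log-odds rounded to multiples of
    ``bin_width``; ``pmf[k]`` is the background probability that the summed
    integer score equals ``offset + k``.
    """

    bin_width: float
    int_scores: np.ndarray  # (width, 4) int64
    offset: int
    pmf: np.ndarray
    tail: np.ndarray = field(init=False)  # survival incl. the bin itself

    def __post_init__(self):
        self.tail = self.pmf[::-1].cumsum()[::-1]

    def p_value(self, int_total: np.ndarray | int) -> np.ndarray | float:
        """P(null integer score >= int_total)."""
        scalar = np.isscalar(int_total)
        idx = np.atleast_1d(np.asarray(int_total, dtype=np.int64)) - self.offset
        out = np.empty(idx.shape, dtype=float)
        below, above = idx < 0, idx >= self.tail.size
        out[below] = 1.0
        out[above] = 0.0
        mid = ~below & ~above
        out[mid] = self.tail[idx[mid]]
        return float(out[0]) if scalar else out


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    table = np.full(256, 255, dtype=np.uint8)
    for base, code in _CODE.items():
        table[ord(base)] = code
    out = table[codes]
    if (out == 255).any():
        bad = seq[int(np.argmax(out == 255))]
        raise ValueError(f"non-DNA character {bad!r} in sequence")
    return out


def build_pwm(
    sites: Sequence[str],
    pseudocount: float = 0.1,
    background: Sequence[float] | None = None,
) -> PWM:
    """Build a PWM from aligned, equal-length DNA site sequences.

    ``N`` letters are excluded from the counts; a column consisting only
    of ``N`` is an error. Probabilities use an additive pseudocount:
    ``(count + pc) / (n_effective + 4 pc)`` per column.
    """
    if len(sites) < 2:
        raise ValueError("need at least 2 site sequences")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise ValueError("site sequences must have equal length")
    counts = np.zeros((width, 4), dtype=float)
    for site in sites:
        codes = _encode(site)
        for pos, code in enumerate(codes):
            if code < 4:
                counts[pos, code] += 1
    n_eff = counts.sum(axis=1)
    if (n_eff == 0).any():
        raise ValueError("a site column contains only N")
    if background is None:
        background = np.full(4, 0.25)
    else:
        background = np.asarray(background, dtype=float)
        background = background / background.sum()
    probs = (counts + pseudocount) / (n_eff[:, None] + 4 * pseudocount)
    with np.errstate(divide="ignore"):
        log_odds = np.log2(probs / background[None, :])
    return PWM(
        width=width,
        probs=probs,
        background=background,
        log_odds=log_odds,
        pseudocount=pseudocount,
    )


def score_null_distribution(
    pwm: PWM, bin_width: float = DEFAULT_BIN_WIDTH
) -> ScoreDistribution:
    """Exact window-score distribution under the i.i.d. background.

    Per-position log-odds are rounded to the nearest multiple of
    ``bin_width`` (bits); the distribution of their sum is the
    position-wise convolution of the four-point per-position
    distributions. Masses sum to 1 up to floating-point error.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    # Zero-probability letters (pseudocount 0) have -inf log-odds; clamp to
    # a finite floor so the lattice stays bounded. -100 bits per position
    # is far below any emittable threshold.
    log_odds = np.maximum(pwm.log_odds, -100.0)
    int_scores = np.rint(log_odds / bin_width).astype(np.int64)
    pmf = np.array([1.0])
    offset = 0
    for pos in range(pwm.width):
        ks = int_scores[pos]
        lo, hi = int(ks.min()), int(ks.max())
        step = np.zeros(hi - lo + 1)
        for code in range(4):
            step[ks[code] - lo] += pwm.background[code]
        pmf = np.convolve(pmf, step)
        offset += lo
    return ScoreDistribution(
        bin_width=bin_width, int_scores=int_scores, offset=offset, pmf=pmf
    )


def _window_scores(
    codes: np.ndarray, matrix: np.ndarray, width: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding sums of ``matrix[pos, base]`` and validity (no-N) flags."""
    n_win = codes.size - width + 1
    total = np.zeros(n_win, dtype=matrix.dtype)
    has_n = np.zeros(n_win, dtype=bool)
    is_n = codes == 4
    safe = np.where(is_n, 0, codes)
    for i in range(width):
        total += matrix[i, safe[i : i + n_win]]
        has_n |= is_n[i : i + n_win]
    return total, ~has_n


def scan_sequence(
    pwm: PWM,
    sequence: str,
    chrom: str,
    e_threshold: float = 1.0e-5,
    both_strands: bool = True,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> list[MotifHit]:
    """Scan a chromosome sequence for motif occurrences.

    Every window gets a log-odds score and an exact lattice p-value; a hit
    is emitted when ``p * n_windows <= e_threshold`` where ``n_windows``
    counts all N-free windows scanned across the enabled strands. Windows
    containing N are skipped. The reverse strand scores the reverse
    complement of each window; hit coordinates always refer to the forward
    strand.
    """
    codes = _encode(sequence)
    if codes.size < pwm.width:
        raise ValueError("sequence shorter than the motif")
    strands: list[tuple[str, PWM]] = [("+", pwm)]
    if both_strands:
        strands.append(("-", pwm.reverse_complement()))
    per_strand = []
    n_windows = 0
    for strand, matrix in strands:
        dist = score_null_distribution(matrix, bin_width=bin_width)
        int_total, valid = _window_scores(codes, dist.int_scores, matrix.width)
        real_total, _ = _window_scores(codes, matrix.log_odds, matrix.width)
        n_windows += int(valid.sum())
        per_strand.append((strand, dist, int_total, real_total, valid))
    hits: list[MotifHit] = []
    for strand, dist, int_total, real_total, valid in per_strand:
        pvals = dist.p_value(int_total)
        evals = pvals * n_windows
        for pos in np.nonzero(valid & (evals <= e_threshold))[0]:
            hits.append(
                MotifHit(
                    chrom=chrom,
                    start=int(pos),
                    strand=strand,
                    score=float(real_total[pos]),
                    p_value=float(pvals[pos]),
                    e_value=float(evals[pos]),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def hits_to_intervals(hits: Sequence[MotifHit], width: int) -> list[GenomicInterval]:
    """Each hit becomes the interval [start, start + width)."""
    return [GenomicInterval(h.chrom, h.start, h.start + width) for h in hits]


def write_hits_bed(hits: Sequence[MotifHit], width: int, path) -> None:
    """BED6: chrom, start, end, name, score (bits), strand."""
    with open(path, "w") as fh:
        for i, h in enumerate(hits):
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.start + width}\tmre_{i}\t"
                f"{h.score:.4f}\t{h.strand}\n"
            )


def read_sites(path) -> list[str]:
    """Read site sequences from FASTA or one-per-line text."""
    path = Path(path)
    text = path.read_text().strip()
    if text.startswith(">"):
        sites, current = [], []
        for line in text.splitlines():
            if line.startswith(">"):
                if current:
                    sites.append("".join(current))
                    current = []
            else:
                current.append(line.strip())
        if current:
            sites.append("".join(current))
        return sites
    return [line.strip() for line in text.splitlines() if line.strip()]
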