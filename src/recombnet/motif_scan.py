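"""PWM scanning of genomic intervals.

Scores interval sequences against position weight matrices (PWMs) on both
strands, converts scores to exact p-values under an i.i.d. background via
dynamic-programming convolution on a discretized score grid, and tabulates
per-TF hit counts in hotspots and coldspots (HM/CM contingency counts for
the odds-ratio prioritization).

Scores are log-odds in bits. The p-value of a window score s is
P(score >= s) for a random background window, so a window is reported as a
hit iff its p-value is at or below the chosen threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G

#: mapping chromosome name -> length in bases
ChromLengths = dict

_IMPOSSIBLE = np.iinfo(np.int64).min // 4  # sentinel for -inf quantized scores


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int
    label: str = "other"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GenomeIntervalSet:
    """A labelled collection of intervals (e.g. all hotspots of a genome)."""

    label: str
    intervals: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.intervals)

    @property
    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self):
        return len(self.intervals)


@dataclass
class MotifMatrix:
    """Position frequency matrix for one TF binding motif.

    Rows are A, C, G, T; columns are motif positions. ``counts`` may hold
    raw counts or frequencies; scoring normalizes per column.
    """

    motif_id: str
    counts: np.ndarray
    background: np.ndarray = None
    pseudocount: float = 0.1

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(f"malformed motif {self.motif_id!r}: need a 4-row matrix")
        if self.counts.shape[1] < 1:
            raise ValueError(f"malformed motif {self.motif_id!r}: zero width")
        if (self.counts < 0).any():
            raise ValueError(f"malformed motif {self.motif_id!r}: negative entry")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence in genome coordinates (0-based half-open)."""

    motif_id: str
    chrom: str
    start: int
    end: int
    strand: str
    score: float
    p_value: float


@dataclass
class HitTable:
    """Per-motif contingency counts against hotspot/coldspot sets.

    HM = hotspots with >= 1 fully contained hit, CM likewise for coldspots;
    HN and CN follow as N_H - HM and N_C - CM.
    """

    n_hot: int
    n_cold: int
    hm: dict = field(default_factory=dict)
    cm: dict = field(default_factory=dict)

    def counts(self, motif_id: str):
        hm = self.hm.get(motif_id, 0)
        cm = self.cm.get(motif_id, 0)
        return hm, self.n_hot - hm, cm, self.n_cold - cm


def log_odds_matrix(m: MotifMatrix) -> np.ndarray:
    """4 x w log2-odds matrix with background-distributed pseudocounts.

    entry(b, j) = log2( p_hat(b, j) / background(b) ) where
    p_hat(b, j) = (counts(b,j) + pseudocount*background(b)) / (colsum_j + pseudocount).
    Zero probabilities (pseudocount 0) give -inf.
    """
    if (m.background <= 0).any():
        raise ValueError("background entries must be positive")
    colsums = m.counts.sum(axis=0)
    if ((colsums + m.pseudocount) <= 0).any():
        raise ValueError(f"motif {m.motif_id!r}: empty column with zero pseudocount")
    p = (m.counts + m.pseudocount * m.background[:, None]) / (colsums + m.pseudocount)
    with np.errstate(divide="ignore"):
        return np.log2(p / m.background[:, None])


class ScoreDistribution:
    """Exact null distribution of window scores on a discrete grid.

    Log-odds entries are quantized to multiples of ``precision`` bits and the
    distribution of the window sum under i.i.d. background bases is built by
    position-wise convolution. p-values are exact on the grid; window scores
    computed from the same quantized matrix make the lookup exact.
    """

    def __init__(self, m: MotifMatrix, precision: float = 1e-3):
        if precision <= 0:
            raise ValueError("precision must be > 0")
        self.precision = precision
        lom = log_odds_matrix(m)
        self.qmatrix = self._quantize(lom)
        self._build(m.background)

    def _quantize(self, lom: np.ndarray) -> np.ndarray:
        q = np.full(lom.shape, _IMPOSSIBLE, dtype=np.int64)
        finite = np.isfinite(lom)
        q[finite] = np.rint(lom[finite] / self.precision).astype(np.int64)
        return q

    def _build(self, background: np.ndarray) -> None:
        dist = {0: 1.0}
        p_impossible = 0.0
        for j in range(self.qmatrix.shape[1]):
            new: dict = {}
            reachable = sum(dist.values())
            for b in range(4):
                q = self.qmatrix[b, j]
                pb = background[b]
                if q == _IMPOSSIBLE:
                    p_impossible += reachable * pb
                    continue
                for s, p in dist.items():
                    new[s + q] = new.get(s + q, 0.0) + p * pb
            dist = new
        scores = np.array(sorted(dist), dtype=np.int64)
        probs = np.array([dist[s] for s in scores])
        total = probs.sum() + p_impossible
        if abs(total - 1.0) > 1e-9:
            raise AssertionError(f"score distribution mass {total} != 1")
        # survival function: P(score >= s) over the finite grid
        self.grid_scores = scores
        self.grid_probs = probs
        self._sf = np.cumsum(probs[::-1])[::-1]

    def pvalue_quantized(self, qscore: int) -> float:
        """P(window score >= qscore) for a quantized score."""
        idx = np.searchsorted(self.grid_scores, qscore, side="left")
        if idx >= len(self.grid_scores):
            return 0.0
        return float(self._sf[idx])

    def pvalue(self, score_bits: float) -> float:
        return self.pvalue_quantized(int(np.rint(score_bits / self.precision)))

    def as_mapping(self) -> dict:
        """Finite part of the distribution: score in bits -> probability."""
        return {
            float(s) * self.precision: float(p)
            for s, p in zip(self.grid_scores, self.grid_probs)
        }


def score_distribution(m: MotifMatrix, precision: float = 1e-3) -> ScoreDistribution:
    """Exact window-score null distribution for motif ``m``."""
    return ScoreDistribution(m, precision)


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes; non-ACGT characters become -1."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement_matrix(q: np.ndarray) -> np.ndarray:
    return q[COMPLEMENT_INDEX][:, ::-1]


def _window_scores(codes: np.ndarray, qmat: np.ndarray) -> np.ndarray:
    """Quantized scores of all windows; windows with non-ACGT get _IMPOSSIBLE."""
    w = qmat.shape[1]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = codes >= 0
    ok = np.ones(n, dtype=bool)
    scores = np.zeros(n, dtype=np.int64)
    safe = np.where(valid, codes, 0)
    for j in range(w):
        col = qmat[:, j][safe[j : j + n]]
        ok &= valid[j : j + n] & (col != _IMPOSSIBLE)
        scores += np.where(col == _IMPOSSIBLE, 0, col)
    scores[~ok] = _IMPOSSIBLE
    return scores


def scan_intervals(
    m: MotifMatrix,
    genome: dict,
    targets: GenomeIntervalSet,
    p_threshold: float = 1e-4,
    precision: float = 1e-3,
) -> list:
    """Scan each target interval on both strands; return contained hits.

    A window is a hit iff its exact p-value is <= ``p_threshold``. The
    reverse strand is scored with the reverse-complemented matrix, which is
    equivalent to scoring the reverse complement of the window with the
    forward matrix. Windows containing non-ACGT characters are skipped.
    """
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must be in (0, 1]")
    fwd = ScoreDistribution(m, precision)
    rc = ScoreDistribution(
        MotifMatrix(
            m.motif_id,
            m.counts[COMPLEMENT_INDEX][:, ::-1],
            background=m.background,
            pseudocount=m.pseudocount,
        ),
        precision,
    )
    w = m.width
    usable = [iv for iv in targets if iv.length >= w]
    if not usable:
        return []
    # concatenate interval sequences with -1 spacers so one vectorized pass
    # scores every window; spacer windows are invalid by construction
    sep = np.full(w - 1, -1, dtype=np.int8) if w > 1 else np.empty(0, dtype=np.int8)
    pieces, offsets = [], []
    pos = 0
    for iv in usable:
        offsets.append(pos)
        codes = encode_sequence(genome[iv.chrom][iv.start : iv.end])
        pieces.extend((codes, sep))
        pos += len(codes) + len(sep)
    concat = np.concatenate(pieces[:-1]) if w > 1 else np.concatenate(pieces[::2])
    offsets = np.array(offsets)

    hits = []
    for dist, strand in ((fwd, "+"), (rc, "-")):
        # smallest quantized score whose tail probability passes the threshold
        admit = dist._sf <= p_threshold
        if not admit.any():
            continue
        qmin = dist.grid_scores[np.argmax(admit)]
        scores = _window_scores(concat, dist.qmatrix)
        good = scores != _IMPOSSIBLE
        good[good] = scores[good] >= qmin
        for pos in np.nonzero(good)[0]:
            idx = int(np.searchsorted(offsets, pos, side="right")) - 1
            iv = usable[idx]
            off = int(pos - offsets[idx])
            hits.append(
                MotifHit(
                    motif_id=m.motif_id,
                    chrom=iv.chrom,
                    start=iv.start + off,
                    end=iv.start + off + w,
                    strand=strand,
                    score=float(scores[pos]) * precision,
                    p_value=dist.pvalue_quantized(int(scores[pos])),
                )
            )
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def _intervals_with_hit(hits, intervals) -> set:
    """Indices of intervals fully containing at least one hit."""
    by_chrom: dict = {}
    for h in hits:
        by_chrom.setdefault(h.chrom, []).append((h.start, h.end))
    for spans in by_chrom.values():
        spans.sort()
    bound = set()
    for idx, iv in enumerate(intervals):
        spans = by_chrom.get(iv.chrom)
        if not spans:
            continue
        import bisect

        i = bisect.bisect_left(spans, (iv.start, -1))
        while i < len(spans) and spans[i][0] < iv.end:
            if spans[i][1] <= iv.end:  # full containment
                bound.add(idx)
                break
            i += 1
    return bound


def tabulate_hits(hits, hot: GenomeIntervalSet, cold: GenomeIntervalSet) -> HitTable:
    """Count, per motif, hotspots/coldspots with >= 1 fully contained hit."""
    table = HitTable(n_hot=hot.n, n_cold=cold.n)
    by_motif: dict = {}
    for h in hits:
        by_motif.setdefault(h.motif_id, []).append(h)
    for motif_id, mhits in by_motif.items():
        table.hm[motif_id] = len(_intervals_with_hit(mhits, hot.intervals))
        table.cm[motif_id] = len(_intervals_with_hit(mhits, cold.intervals))
    return table


def bound_interval_indices(hits, intervals) -> set:
    """Public wrapper: indices of intervals bound (>=1 contained hit)."""
    return _intervals_with_hit(hits, intervals)


def one_hot_matrix(motif_id: str, consensus: str, pseudocount: float = 0.0) -> MotifMatrix:
    """Strict one-hot PWM for a consensus string (useful for tests/truth checks)."""
    counts = np.zeros((4, len(consensus)))
    for j, b in enumerate(consensus.upper()):
        counts[BASE_INDEX[b], j] = 1.0
    return MotifMatrix(motif_id, counts, pseudocount=pseudocount)
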