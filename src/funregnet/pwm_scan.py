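"""Position-weight-matrix promoter scanning with exact per-site p-values.

A frequency matrix (CIS-BP text dialect) is converted to a log-odds matrix

    score(b, i) = log2( (p[i][b] + pc * bg[b]) / ((1 + pc) * bg[b]) )

against a 0-order background ``bg`` with pseudocount fraction ``pc``.  The
exact null distribution of the window score is computed by dynamic
programming on an integer score lattice: every cell score is quantized to a
multiple of ``granularity`` (in bits), and the distribution of the sum over
positions under the background is built by exact convolution of the four-
outcome per-position distributions.  The survival function P(score >= s) of
that distribution gives the per-site p-value of each scanned window; windows
with p <= threshold (default 1e-4) on either strand are reported as binding
sites.

Because the scanner scores windows with the same quantized cells used by the
DP, the reported p-value is exact for the quantized score (no further
approximation beyond the initial cell rounding, which is bounded by
width * granularity / 2 bits on the score axis).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np

from funregnet.genome_io import PromoterRecord

__all__ = [
    "FrequencyMatrix",
    "BackgroundModel",
    "LogOddsMatrix",
    "ScoreDistribution",
    "HitRecord",
    "read_cisbp_matrix",
    "read_cisbp_dir",
    "to_log_odds",
    "score_distribution",
    "scan_promoter",
    "count_hits_per_edge",
    "estimate_background",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: cap on the DP support size (number of lattice points)
MAX_SUPPORT = 50_000_000


@dataclass(frozen=True)
class FrequencyMatrix:
    """A CIS-BP position frequency matrix: per-position probabilities over ACGT."""

    matrix_id: str
    tf_id: str
    probs: np.ndarray  # shape (width, 4), rows sum to 1

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4 or p.shape[0] < 1:
            raise ValueError(f"matrix {self.matrix_id}: probs must be (width, 4)")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"matrix {self.matrix_id}: rows must sum to 1")
        object.__setattr__(self, "probs", p)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))


@dataclass(frozen=True)
class BackgroundModel:
    """0-order background base composition, strictly positive."""

    probs: np.ndarray  # shape (4,)

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (4,):
            raise ValueError("background must have 4 entries (A, C, G, T)")
        if not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise ValueError(f"background must sum to 1, got {p.sum()}")
        if (p <= 0).any():
            raise ValueError("all background entries must be > 0")
        object.__setattr__(self, "probs", p)

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(np.full(4, 0.25))


@dataclass(frozen=True)
class LogOddsMatrix:
    """Log2-odds scores per position and base, plus their integer quantization.

    ``qscores`` holds each cell rounded to an integer multiple of
    ``granularity`` bits; both the scanner and the exact null distribution
    work on this lattice so p-value lookups are exact.
    """

    matrix_id: str
    scores: np.ndarray  # (width, 4) float bits
    granularity: float
    qscores: np.ndarray  # (width, 4) int64 lattice units

    @property
    def width(self) -> int:
        return self.scores.shape[0]

    def max_score(self) -> float:
        return float(self.scores.max(axis=1).sum())

    def min_score(self) -> float:
        return float(self.scores.min(axis=1).sum())


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact null distribution of the window score on the integer lattice.

    ``offset`` is the lattice value of the first pmf entry: lattice score
    ``offset + k`` has probability ``pmf[k]`` and survival
    ``survival[k] = P(score >= offset + k)``.
    """

    granularity: float
    offset: int
    pmf: np.ndarray
    survival: np.ndarray

    def p_value(self, qscore: int) -> float:
        """P(null window score >= qscore), qscore in lattice units."""
        k = qscore - self.offset
        if k <= 0:
            return 1.0
        if k >= len(self.survival):
            return 0.0
        return float(self.survival[k])


@dataclass(frozen=True)
class HitRecord:
    """One predicted binding site in a promoter.

    ``offset`` is 0-based within the promoter (5'->3' relative to the gene);
    ``strand`` is relative to the promoter; ``word`` is the matched sequence
    as read on the scanned strand (reverse complement of the promoter slice
    for ``-`` hits).
    """

    gene_id: str
    matrix_id: str
    offset: int
    strand: str
    word: str
    score: float
    p_value: float


def read_cisbp_matrix(path, tf_id: str | None = None) -> FrequencyMatrix:
    """Parse one CIS-BP text matrix: header ``Pos A C G T``, one row per
    position.

    Rows are re-normalized when they sum to 1 within 1e-3; rows further off
    (e.g. a counts-style matrix) are rejected — this reader accepts the
    frequency dialect only.
    """
    matrix_id = os.path.splitext(os.path.basename(str(path)))[0]
    rows = []
    with open(path) as fh:
        header = fh.readline().split()
        if [h.upper() for h in header[:5]] != ["POS", "A", "C", "G", "T"]:
            raise ValueError(f"{path}: expected CIS-BP header 'Pos A C G T', got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
            try:
                vals = [float(x) for x in fields[1:]]
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric cell in {line!r}")
            s = sum(vals)
            if abs(s - 1.0) > 1e-3:
                raise ValueError(
                    f"{path}:{lineno}: row sums to {s:g}, not a frequency row "
                    "(counts-style matrices are not accepted)"
                )
            rows.append([v / s for v in vals])
    if not rows:
        raise ValueError(f"{path}: matrix has no positions")
    return FrequencyMatrix(matrix_id, tf_id or matrix_id, np.array(rows))


def read_cisbp_dir(directory, matrix_to_tf: dict[str, str] | None = None) -> list[FrequencyMatrix]:
    """Read every ``*.txt`` CIS-BP matrix in a directory (sorted by name)."""
    mats = []
    for name in sorted(os.listdir(directory)):
        if not name.endswith(".txt"):
            continue
        mid = os.path.splitext(name)[0]
        tf = matrix_to_tf.get(mid) if matrix_to_tf else None
        mats.append(read_cisbp_matrix(os.path.join(str(directory), name), tf_id=tf))
    return mats


def estimate_background(sequences: list[str]) -> BackgroundModel:
    """Estimate a 0-order background from sequences (non-ACGT ignored),
    with a +1 pseudocount per base so entries stay positive."""
    counts = np.ones(4)
    for seq in sequences:
        for b in seq.upper():
            i = _BASE_INDEX.get(b)
            if i is not None:
                counts[i] += 1
    return BackgroundModel(counts / counts.sum())


def to_log_odds(
    freq: FrequencyMatrix,
    bg: BackgroundModel,
    pseudocount: float = 0.01,
    granularity: float = 0.001,
) -> LogOddsMatrix:
    """Convert a frequency matrix to log2-odds scores against ``bg``.

    ``pseudocount`` is a fraction of the background added to each cell:
    score(b, i) = log2((p + pc*bg_b) / ((1+pc)*bg_b)).  With pseudocount 0 a
    zero probability cell yields -inf; a positive pseudocount is required
    for matrices containing zeros.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if granularity <= 0:
        raise ValueError("granularity must be > 0")
    p = freq.probs
    bgp = bg.probs[None, :]
    with np.errstate(divide="ignore"):
        scores = np.log2((p + pseudocount * bgp) / ((1 + pseudocount) * bgp))
    if not np.isfinite(scores).all():
        raise ValueError(
            f"matrix {freq.matrix_id}: zero probabilities require pseudocount > 0"
        )
    qscores = np.rint(scores / granularity).astype(np.int64)
    return LogOddsMatrix(freq.matrix_id, scores, granularity, qscores)


def score_distribution(
    lom: LogOddsMatrix, bg: BackgroundModel, granularity: float | None = None
) -> ScoreDistribution:
    """Exact null distribution of the window score under the background.

    Dynamic programming on the integer lattice: start from a point mass at
    0 and convolve, position by position, with the four-outcome distribution
    {qscore(b, i) with probability bg[b]}.  The survival function is the
    suffix sum of the resulting pmf.

    ``granularity`` must match the lattice the log-odds matrix was quantized
    on; it defaults to that value and a mismatch is an error (the scanner
    and the null distribution must share one lattice for exact lookups).
    """
    if granularity is not None and not math.isclose(granularity, lom.granularity):
        raise ValueError(
            f"granularity {granularity} does not match the matrix lattice "
            f"{lom.granularity}; requantize with to_log_odds"
        )
    q = lom.qscores
    lo = int(q.min(axis=1).sum())
    hi = int(q.max(axis=1).sum())
    support = hi - lo + 1
    if support > MAX_SUPPORT:
        raise ValueError(
            f"score lattice needs {support} points (> {MAX_SUPPORT}); "
            "use a coarser granularity"
        )
    bgp = bg.probs
    # running pmf over [cur_lo, cur_hi] lattice units
    pmf = np.array([1.0])
    cur_lo = 0
    for i in range(lom.width):
        col = q[i]
        new_lo = cur_lo + int(col.min())
        new_hi = cur_lo + len(pmf) - 1 + int(col.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            shift = cur_lo + int(col[b]) - new_lo
            new[shift : shift + len(pmf)] += bgp[b] * pmf
        pmf = new
        cur_lo = new_lo
    survival = np.cumsum(pmf[::-1])[::-1]
    return ScoreDistribution(lom.granularity, cur_lo, pmf, survival)


def _encode(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes; non-ACGT -> -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        codes[arr == ord(b)] = i
    return codes


def _window_qscores(codes: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Quantized scores of all windows; returns (scores, valid mask)."""
    w = q.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    idx = np.arange(n)[:, None] + np.arange(w)[None, :]
    win = codes[idx]  # (n, w)
    valid = (win >= 0).all(axis=1)
    safe = np.where(win >= 0, win, 0)
    scores = q[np.arange(w)[None, :], safe].sum(axis=1)
    return scores, valid


def scan_promoter(
    promoter: PromoterRecord,
    lom: LogOddsMatrix,
    dist: ScoreDistribution,
    p_threshold: float = 1e-4,
) -> list[HitRecord]:
    """Scan a promoter on both strands; report windows with exact p <= threshold.

    Windows containing non-ACGT characters are skipped.  Hits are sorted by
    offset then strand.  A promoter shorter than the matrix width yields an
    empty list.
    """
    seq = promoter.sequence.upper()
    w = lom.width
    hits: list[HitRecord] = []
    if len(seq) < w:
        return hits
    codes = _encode(seq)
    g = lom.granularity
    # + strand
    scores, valid = _window_qscores(codes, lom.qscores)
    for off in np.nonzero(valid)[0]:
        p = dist.p_value(int(scores[off]))
        if p <= p_threshold:
            word = seq[off : off + w]
            hits.append(
                HitRecord(promoter.gene_id, lom.matrix_id, int(off), "+", word,
                          float(scores[off]) * g, p)
            )
    # - strand: scan the reverse complement; offset maps back to + coords
    rc = seq.translate(_COMPLEMENT)[::-1]
    rc_codes = _encode(rc)
    scores, valid = _window_qscores(rc_codes, lom.qscores)
    L = len(seq)
    for j in np.nonzero(valid)[0]:
        p = dist.p_value(int(scores[j]))
        if p <= p_threshold:
            off = L - w - int(j)
            hits.append(
                HitRecord(promoter.gene_id, lom.matrix_id, off, "-", rc[j : j + w],
                          float(scores[j]) * g, p)
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def count_hits_per_edge(edges, hits, matrix_to_tf: dict[str, str]):
    """Fill ``tfbs_count`` on inferred edges from scan hits.

    A hit supports an edge when the hit's promoter gene equals the edge's
    target gene and the hit's matrix maps to the edge's TF.  Duplicate hit
    rows are deduplicated before counting.  Edges whose TF has no matrix in
    the map keep count 0 and are flagged ``has_matrix=False`` (binding-site
    evidence never filters edges).
    """
    from dataclasses import replace

    tfs_with_matrix = set(matrix_to_tf.values())
    uniq = {(h.gene_id, h.matrix_id, h.offset, h.strand) for h in hits}
    counts: dict[tuple[str, str], int] = {}
    for gene_id, matrix_id, _off, _strand in uniq:
        tf = matrix_to_tf.get(matrix_id)
        if tf is None:
            continue
        key = (tf, gene_id)
        counts[key] = counts.get(key, 0) + 1
    out = []
    for e in edges:
        has_matrix = e.tf_id in tfs_with_matrix
        out.append(
            replace(e, tfbs_count=counts.get((e.tf_id, e.tg_id), 0), has_matrix=has_matrix)
        )
    return out
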