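"""Position weight matrices: TRANSFAC I/O, log-odds scoring, scanning, calibration.

Scores are log2 odds in bits against an i.i.d. background model, with a
pseudocount distributed proportionally to the background:

    score[i][b] = log2( (counts[i][b] + pc * bg[b]) / (sum_b'(counts[i][b'] + pc * bg[b'])) / bg[b] )

Both strands are always scanned.  A minus-strand hit is scored on the reverse
complement of the window and reported with the offset of the window's leftmost
base on the forward sequence.  Windows containing N never produce hits.

Score thresholds are calibrated empirically: the threshold for a matrix is the
smallest observed window score whose admitted hit density on a calibration
promoter set does not exceed a site-frequency cap (default one site per
2000 bp, counting both strands over single-strand length).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import motifs as _bio_motifs

from ._seqs import encode_batch, revcomp
from ._scan import collapsed_count_pair, score_windows_pair, top_scores_pair

DEFAULT_SITE_FREQUENCY_CAP = 1.0 / 2000.0  # sites per bp
UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


class TransfacParseError(ValueError):
    """Raised when a TRANSFAC flat file cannot be parsed."""


@dataclass(frozen=True)
class PWM:
    """A position count matrix with background model and scoring rules.

    Parameters
    ----------
    matrix_id : str
        Matrix identifier, e.g. ``I$KAY_01``.
    counts : (L, 4) array
        Non-negative base counts ordered A, C, G, T.
    tf_name : str
        Transcription factor name, if known.
    pseudocount : float
        Total pseudocount distributed over bases proportionally to the
        background.
    background : 4-tuple of float
        Background base probabilities (must be strictly positive and sum to 1).
    """

    matrix_id: str
    counts: np.ndarray
    tf_name: str = ""
    pseudocount: float = 1.0
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.float64)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError(f"{self.matrix_id}: counts must be (L, 4)")
        if counts.shape[0] < 1:
            raise ValueError(f"{self.matrix_id}: empty matrix")
        if (counts < 0).any():
            raise ValueError(f"{self.matrix_id}: negative counts")
        if (counts.sum(axis=1) == 0).any():
            raise ValueError(f"{self.matrix_id}: all-zero column")
        bg = np.asarray(self.background, dtype=np.float64)
        if bg.shape != (4,) or (bg <= 0).any() or abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.matrix_id}: invalid background {self.background}")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return int(self.counts.shape[0])

    @property
    def length(self) -> int:
        return len(self)

    def probabilities(self) -> np.ndarray:
        """Per-position base probabilities after pseudocount smoothing."""
        bg = np.asarray(self.background)
        num = self.counts + self.pseudocount * bg
        return num / num.sum(axis=1, keepdims=True)

    def log_odds(self) -> np.ndarray:
        """(L, 4) log2-odds score matrix in bits."""
        return np.log2(self.probabilities() / np.asarray(self.background))

    def score_lut(self) -> np.ndarray:
        """(L, 6) lookup table: columns 4 (N) and 5 (padding) are -inf."""
        lut = np.full((len(self), 6), -np.inf)
        lut[:, :4] = self.log_odds()
        return lut

    def rc_score_lut(self) -> np.ndarray:
        """Lookup table scoring the reverse-complement orientation on the forward strand."""
        lut = self.score_lut()
        out = np.full_like(lut, -np.inf)
        out[:, :4] = lut[::-1, [3, 2, 1, 0]]
        return out

    @property
    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds().min(axis=1).sum())

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.counts.argmax(axis=1))


@dataclass(frozen=True, order=True)
class MotifHit:
    """One scored motif occurrence on a promoter.

    ``offset`` is the 0-based position of the window's leftmost base on the
    forward (promoter) sequence regardless of strand.
    """

    promoter_id: str
    matrix_id: str
    offset: int
    strand: str
    score: float

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class ThresholdCalibration:
    """Result of calibrating a matrix threshold to a site-frequency cap."""

    matrix_id: str
    threshold: float
    achieved_frequency: float
    target_cap: float
    cap_unreachable: bool = False


# ---------------------------------------------------------------------------
# TRANSFAC I/O (wraps Biopython's parser; tolerant of P0/PO headers and a
# trailing consensus column, both of which Bio.motifs already accepts).
# ---------------------------------------------------------------------------

def parse_transfac(text: str, *, pseudocount: float = 1.0,
                   background: tuple[float, float, float, float] = UNIFORM_BACKGROUND) -> list[PWM]:
    """Parse a TRANSFAC-dialect flat file into a list of :class:`PWM`.

    Matrix ids come from the ID line when present, otherwise from AC.
    """
    try:
        records = _bio_motifs.parse(io.StringIO(text), "TRANSFAC", strict=False)
    except Exception as exc:  # Bio raises plain ValueError with line context
        raise TransfacParseError(str(exc)) from exc
    pwms = []
    for rec in records:
        mat_id = rec.get("ID") or rec.get("AC")
        if not mat_id:
            raise TransfacParseError("matrix block without AC or ID line")
        counts = np.column_stack([np.asarray(rec.counts[b], dtype=float) for b in "ACGT"])
        pwms.append(PWM(matrix_id=mat_id, counts=counts, tf_name=rec.get("NA") or "",
                        pseudocount=pseudocount, background=background))
    if not pwms:
        raise TransfacParseError("no matrix blocks found")
    return pwms


def read_transfac(path, **kwargs) -> list[PWM]:
    with open(path) as fh:
        return parse_transfac(fh.read(), **kwargs)


def write_transfac(pwms: Iterable[PWM]) -> str:
    """Serialize PWMs to TRANSFAC flat format (round trips through :func:`parse_transfac`)."""
    blocks = []
    for pwm in pwms:
        lines = [f"AC  {pwm.matrix_id}", "XX", f"ID  {pwm.matrix_id}", "XX"]
        if pwm.tf_name:
            lines += [f"NA  {pwm.tf_name}", "XX"]
        lines.append("P0      A      C      G      T")
        cons = pwm.consensus()
        for i, row in enumerate(pwm.counts):
            nums = "  ".join(f"{v:>16.12g}" for v in row)
            lines.append(f"{i + 1:02d}  {nums}      {cons[i]}")
        lines += ["XX", "//"]
        blocks.append("\n".join(lines))
    return "\n".join(blocks) + "\n"


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def batch_window_scores(sequences: Sequence[str], pwm: PWM,
                        encoded: tuple[np.ndarray, np.ndarray] | None = None
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Score all windows of all sequences on both strands.

    Returns ``(plus, minus, lengths)`` where ``plus`` and ``minus`` are
    (n, max_len - L + 1) float arrays (-inf marks invalid windows: padding,
    N bases, windows past a sequence's true end).  ``encoded`` lets callers
    reuse a cached ``encode_batch`` result.
    """
    codes, lengths = encoded if encoded is not None else encode_batch(list(sequences))
    plus, minus = score_windows_pair(codes, lengths, pwm.score_lut(), pwm.rc_score_lut())
    return plus, minus, lengths


def scan(sequence: str, pwm: PWM, threshold: float, promoter_id: str = "") -> list[MotifHit]:
    """Report every window on either strand scoring at least ``threshold``.

    Hits are sorted by (offset, strand); a promoter shorter than the motif
    yields an empty list.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if len(sequence) < len(pwm):
        return []
    plus, minus, _ = batch_window_scores([sequence], pwm)
    hits = []
    for strand, scores in (("+", plus[0]), ("-", minus[0])):
        for off in np.nonzero(scores >= threshold)[0]:
            hits.append(MotifHit(promoter_id, pwm.matrix_id, int(off), strand, float(scores[off])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def collapse_hits(hits: Sequence[MotifHit], motif_length: int) -> list[MotifHit]:
    """Greedy best-score non-overlap collapse, per promoter and strand.

    Prevents one strong site from being counted once per overlapping window in
    site-frequency statistics.  Ties favour the leftmost window.
    """
    kept: list[MotifHit] = []
    taken: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for h in sorted(hits, key=lambda h: (h.promoter_id, h.strand, -h.score, h.offset)):
        key = (h.promoter_id, h.strand)
        intervals = taken.setdefault(key, [])
        lo, hi = h.offset, h.offset + motif_length
        if all(hi <= s or lo >= e for s, e in intervals):
            intervals.append((lo, hi))
            kept.append(h)
    kept.sort(key=lambda h: (h.promoter_id, h.offset, h.strand))
    return kept


def _collapsed_count(plus: np.ndarray, minus: np.ndarray, threshold: float, motif_length: int) -> int:
    """Count greedy best-score non-overlapping hits at/above threshold."""
    return int(collapsed_count_pair(plus, minus, float(threshold), int(motif_length)))


# ---------------------------------------------------------------------------
# Threshold calibration
# ---------------------------------------------------------------------------

def calibrate_threshold(pwm: PWM, calibration_sequences: Sequence[str],
                        max_frequency: float = DEFAULT_SITE_FREQUENCY_CAP,
                        *, precomputed: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
                        ) -> ThresholdCalibration:
    """Calibrate a score threshold so the calibration-set hit density stays under a cap.

    Returns the smallest observed window score admitting at most
    ``max_frequency * total_bp`` window hits (both strands, raw counts) on the
    calibration set.  If even the maximum observed score exceeds the cap the
    maximum attainable matrix score is returned with ``cap_unreachable=True``.
    """
    total_bp = sum(len(s) for s in calibration_sequences)
    if np.isfinite(max_frequency) and total_bp < 10 / max_frequency:
        raise ValueError(
            f"calibration set too small: {total_bp} bp < {10 / max_frequency:.0f} bp")
    plus, minus, _ = precomputed or batch_window_scores(calibration_sequences, pwm)
    if not np.isfinite(max_frequency):
        finite_n = int(np.isfinite(plus).sum() + np.isfinite(minus).sum())
        lo = min((plus[np.isfinite(plus)].min(initial=np.inf) if plus.size else np.inf),
                 (minus[np.isfinite(minus)].min(initial=np.inf) if minus.size else np.inf))
        thr = float(lo) if np.isfinite(lo) else pwm.min_score
        return ThresholdCalibration(pwm.matrix_id, thr, finite_n / total_bp, max_frequency)
    cap_count = int(np.floor(max_frequency * total_bp))
    top, finite_n = top_scores_pair(plus, minus, max(cap_count, 0),
                                    pwm.min_score, pwm.max_score)
    if top.size == 0 or cap_count < 1:
        return ThresholdCalibration(pwm.matrix_id, pwm.max_score,
                                    0.0, max_frequency, cap_unreachable=True)
    if finite_n <= cap_count:
        # every observed window is admissible
        thr = float(top[-1])
        return ThresholdCalibration(pwm.matrix_id, thr, finite_n / total_bp, max_frequency)
    # top is sorted descending with cap_count + 1 entries; admissible thresholds
    # are observed values strictly above the (cap_count+1)-th largest score
    bound = top[cap_count]
    admissible = top[:cap_count][top[:cap_count] > bound]
    if admissible.size == 0:
        # even the highest observed score occurs more than cap_count times
        return ThresholdCalibration(pwm.matrix_id, pwm.max_score,
                                    0.0, max_frequency, cap_unreachable=True)
    thr = float(admissible[-1])
    count = int(np.searchsorted(-top, -thr, side="right"))
    return ThresholdCalibration(pwm.matrix_id, thr, count / total_bp, max_frequency)
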