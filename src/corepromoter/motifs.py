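"""Motif models: probability matrices, log-odds scoring, and scanning.

All log-odds weights and information content are expressed in log2 (bits).
Coordinates are 0-based, half-open. Sequences may declare a TSS index so that
scan regions can be given in TSS-relative coordinates (TSS = position 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

UNIFORM_BACKGROUND = np.full(4, 0.25)


class MotifError(ValueError):
    """Raised on invalid motif model input."""


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _validate_sequence(sequence: str) -> None:
    bad = set(sequence) - set("ACGTN")
    if bad:
        raise MotifError(f"non-IUPAC characters in sequence: {sorted(bad)}")


@dataclass(frozen=True)
class PositionProbabilityMatrix:
    """Per-position base probabilities of a motif.

    ``matrix`` has shape (length, 4) with columns ordered A, C, G, T; each
    row sums to 1 within 1e-9.
    """

    name: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise MotifError(f"PPM {self.name!r}: matrix must be (L, 4) with L >= 1")
        if (m < 0).any():
            raise MotifError(f"PPM {self.name!r}: negative probabilities")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise MotifError(f"PPM {self.name!r}: rows must sum to 1")
        object.__setattr__(self, "matrix", m)

    def __len__(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Log-odds motif model with an optional calibrated score threshold.

    ``weights`` has shape (length, 4) in bits. ``enriched_region`` is a
    TSS-relative half-open interval constraining hit start positions;
    ``min_score_threshold`` defaults to -inf (uncalibrated).
    """

    name: str
    weights: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    min_score_threshold: float = -np.inf
    enriched_region: tuple[int, int] | None = None
    source: str = "sequence-derived"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        q = np.asarray(self.background, dtype=float)
        if w.ndim != 2 or w.shape[1] != 4 or w.shape[0] < 1:
            raise MotifError(f"PWM {self.name!r}: weights must be (L, 4) with L >= 1")
        if not np.isfinite(w).all():
            raise MotifError(f"PWM {self.name!r}: weights must be finite")
        if q.shape != (4,) or not np.isclose(q.sum(), 1.0, atol=1e-9):
            raise MotifError(f"PWM {self.name!r}: background must be a 4-vector summing to 1")
        t = self.min_score_threshold
        if np.isfinite(t):
            lo = float(w.min(axis=1).sum())
            hi = float(w.max(axis=1).sum())
            if not (lo <= t <= hi):
                raise MotifError(
                    f"PWM {self.name!r}: threshold {t} outside attainable range [{lo}, {hi}]"
                )
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "background", q)

    def __len__(self) -> int:
        return self.weights.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.weights.min(axis=1).sum())

    def with_threshold(self, threshold: float) -> "PositionWeightMatrix":
        return replace(self, min_score_threshold=float(threshold))


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int
    strand: str
    score: float
    motif_name: str


def score_window(pwm: PositionWeightMatrix, sequence: str, offset: int, strand: str = "+") -> float:
    """Log-odds score of one window of ``sequence``.

    The window covers ``offset .. offset + len(pwm)`` on the forward strand;
    for strand '-' the window is reverse-complemented before scoring. An N
    contributes the background-expected weight of its column.
    """
    L = len(pwm)
    if offset < 0 or offset + L > len(sequence):
        raise IndexError(f"window [{offset}, {offset + L}) outside sequence of length {len(sequence)}")
    window = sequence[offset : offset + L].upper()
    _validate_sequence(window)
    if strand == "-":
        window = reverse_complement(window)
    elif strand != "+":
        raise MotifError(f"strand must be '+' or '-', got {strand!r}")
    score = 0.0
    for j, base in enumerate(window):
        if base == "N":
            score += float(pwm.background @ pwm.weights[j])
        else:
            score += float(pwm.weights[j, BASE_INDEX[base]])
    return score


def scan(
    pwm: PositionWeightMatrix,
    sequence: str,
    *,
    sequence_id: str = "seq",
    region: tuple[int, int] | None = None,
    both_strands: bool = False,
    tss_index: int = 0,
    threshold: float | None = None,
) -> list[MotifHit]:
    """All windows scoring at or above the PWM threshold.

    ``region`` is a half-open TSS-relative interval of allowed window starts
    (the sequence's TSS sits at string index ``tss_index``). Hits are sorted
    by offset, '+' before '-'. A region entirely outside the sequence yields
    an empty list with a warning.
    """
    _validate_sequence(sequence.upper())
    L = len(pwm)
    n = len(sequence)
    cutoff = pwm.min_score_threshold if threshold is None else threshold
    lo, hi = 0, n - L + 1
    if region is not None:
        lo = max(lo, region[0] + tss_index)
        hi = min(hi, region[1] + tss_index)
        if lo >= hi:
            warnings.warn(
                f"scan region {region} lies outside sequence {sequence_id!r}", stacklevel=2
            )
            return []
    hits: list[MotifHit] = []
    strands = ("+", "-") if both_strands else ("+",)
    for offset in range(lo, hi):
        for strand in strands:
            s = score_window(pwm, sequence, offset, strand)
            if s >= cutoff:
                hits.append(MotifHit(sequence_id, offset, strand, s, pwm.name))
    return hits


def best_score(
    pwm: PositionWeightMatrix,
    sequence: str,
    *,
    region: tuple[int, int] | None = None,
    both_strands: bool = False,
    tss_index: int = 0,
) -> float:
    """Maximum window score (``-inf`` when no window fits the region)."""
    hits = scan(
        pwm,
        sequence,
        region=region,
        both_strands=both_strands,
        tss_index=tss_index,
        threshold=-np.inf,
    )
    if not hits:
        return -np.inf
    return max(h.score for h in hits)


def information_content(
    ppm: PositionProbabilityMatrix, background: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Per-column relative entropy in bits and its total.

    Uses sum_b p log2(p/q) with the 0*log(0) = 0 convention. The background
    must be strictly positive.
    """
    q = UNIFORM_BACKGROUND if background is None else np.asarray(background, dtype=float)
    if (q <= 0).any():
        raise MotifError("background entries must be strictly positive")
    p = ppm.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / q), 0.0)
    per_column = terms.sum(axis=1)
    return per_column, float(per_column.sum())


def consensus(ppm: PositionProbabilityMatrix) -> tuple[str, bool]:
    """Per-column argmax base string; ties break alphabetically and are flagged."""
    idx = ppm.matrix.argmax(axis=1)
    maxima = ppm.matrix.max(axis=1)
    tied = bool((np.isclose(ppm.matrix, maxima[:, None]).sum(axis=1) > 1).any())
    return "".join(BASES[i] for i in idx), tied


def ppm_to_pwm(
    ppm: PositionProbabilityMatrix,
    background: np.ndarray | None = None,
    pseudocount: float = 0.01,
    **kwargs,
) -> PositionWeightMatrix:
    """Standard log2-odds construction with background-proportional pseudocounts.

    weight(j, b) = log2((p + pc*q) / ((1 + pc) * q)). A zero probability with
    pseudocount 0 is rejected rather than producing -inf weights.
    """
    if pseudocount < 0:
        raise MotifError("pseudocount must be >= 0")
    q = UNIFORM_BACKGROUND if background is None else np.asarray(background, dtype=float)
    p = ppm.matrix
    if pseudocount == 0 and (p == 0).any():
        raise MotifError("zero probability requires pseudocount > 0")
    weights = np.log2((p + pseudocount * q) / ((1 + pseudocount) * q))
    return PositionWeightMatrix(name=ppm.name, weights=weights, background=q, **kwargs)


def pwm_to_ppm(pwm: PositionWeightMatrix) -> PositionProbabilityMatrix:
    """Invert the log-odds construction (recovers the smoothed PPM)."""
    p = (2.0 ** pwm.weights) * pwm.background
    p /= p.sum(axis=1, keepdims=True)
    return PositionProbabilityMatrix(name=pwm.name, matrix=p)
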