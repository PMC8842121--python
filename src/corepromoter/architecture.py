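"""Gene sets, MI-optimized PWM thresholds, motif-feature association, and
promoter architecture assignment.

Motif presence in a promoter is defined as the best PWM hit inside the
motif's enriched region reaching the calibrated minimal score threshold.
Thresholds are chosen on a fixed grid by maximizing mutual information
against gene sets with which the motif is positively correlated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .motifs import PositionWeightMatrix, best_score

#: Motif composition of the four architecture classes. Class 3 splits into
#: two sub-architectures sharing a pool of weakly associated motifs.
CLASS_MOTIFS: dict[str, set[str]] = {
    "Ar1": {"INR", "MTEDPE", "CGpal", "GAGA", "GAGArev"},
    "Ar2": {"TATA-Box", "ATGAA"},
    "Ar3.1": {"DRE", "Ohler7"},
    "Ar3.2": {"INR2", "Ohler6"},
    "Ar4": {"TCT", "RDPE"},
}
CLASS3_SHARED: set[str] = {"E-Box1", "TTGTT", "TTGTTrev", "INR2rev", "AAG3"}

UNINFORMATIVE = "uninformative"


class ArchitectureError(ValueError):
    pass


@dataclass
class GeneSet:
    name: str
    members: set[str]
    rule: str


@dataclass
class ArchitectureCall:
    promoter_id: str
    label: str
    counts: dict[str, int] = field(default_factory=dict)


def build_gene_sets(features, rules: list[dict]) -> list[GeneSet]:
    """Quantile-based overlapping gene sets from a feature table.

    ``features`` is a pandas DataFrame indexed by gene id. Each rule is a
    mapping with keys ``name``, ``column``, ``kind`` ('high' or 'low') and
    ``fraction``; genes are ranked on the column and the top/bottom fraction
    selected. A constant column yields an empty set with a warning.
    """
    sets = []
    for rule in rules:
        name, col = rule["name"], rule["column"]
        kind, frac = rule["kind"], float(rule["fraction"])
        if col not in features.columns:
            raise ArchitectureError(f"rule {name!r} references missing column {col!r}")
        values = features[col]
        if len(features) == 0:
            sets.append(GeneSet(name, set(), f"{kind} {frac:g} of {col}"))
            continue
        if values.nunique() <= 1:
            warnings.warn(f"constant column {col!r}: empty gene set {name!r}", stacklevel=2)
            sets.append(GeneSet(name, set(), f"{kind} {frac:g} of {col}"))
            continue
        k = int(round(frac * len(features)))
        ordered = values.sort_values(ascending=(kind == "low"), kind="mergesort")
        members = set(ordered.index[:k])
        sets.append(GeneSet(name, members, f"{kind} {frac:g} of {col}"))
    return sets


DEFAULT_SET_RULES: list[dict] = [
    # high/low 10% per feature, plus the wider medhigh regulation class
    {"name": "min_high", "column": "min_expr", "kind": "high", "fraction": 0.1},
    {"name": "min_low", "column": "min_expr", "kind": "low", "fraction": 0.1},
    {"name": "max_high", "column": "max_expr", "kind": "high", "fraction": 0.1},
    {"name": "max_low", "column": "max_expr", "kind": "low", "fraction": 0.1},
    {"name": "MAD_high", "column": "mad_expression", "kind": "high", "fraction": 0.1},
    {"name": "MAD_low", "column": "mad_expression", "kind": "low", "fraction": 0.1},
    {"name": "MAD_medhigh", "column": "mad_expression", "kind": "high", "fraction": 0.4},
    {"name": "NP", "column": "tss_mad", "kind": "low", "fraction": 0.1},
    {"name": "BP", "column": "tss_mad", "kind": "high", "fraction": 0.1},
]


def binary_mi(x, y) -> float:
    """Plug-in mutual information (bits) of two binary vectors."""
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape:
        raise ArchitectureError("binary_mi: length mismatch")
    n = x.size
    if n < 1:
        raise ArchitectureError("binary_mi: empty input")
    mi = 0.0
    for xv in (0, 1):
        for yv in (0, 1):
            pxy = np.count_nonzero((x == xv) & (y == yv)) / n
            if pxy == 0:
                continue
            px = np.count_nonzero(x == xv) / n
            py = np.count_nonzero(y == yv) / n
            mi += pxy * np.log2(pxy / (px * py))
    return max(mi, 0.0)


def binary_mcc(x, y) -> float:
    """Matthews correlation coefficient; 0 when any margin is empty."""
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape:
        raise ArchitectureError("binary_mcc: length mismatch")
    tp = np.count_nonzero((x == 1) & (y == 1))
    tn = np.count_nonzero((x == 0) & (y == 0))
    fp = np.count_nonzero((x == 1) & (y == 0))
    fn = np.count_nonzero((x == 0) & (y == 1))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def threshold_grid(lo: float = -15.0, hi: float = 30.0, step: float = 0.1) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def optimize_threshold(
    pwm: PositionWeightMatrix,
    promoter_sequences: dict[str, str],
    gene_sets: list[GeneSet],
    *,
    grid: tuple[float, float, float] = (-15.0, 30.0, 0.1),
    tss_index: int = 100,
    both_strands: bool = False,
):
    """Pick the PWM threshold maximizing MI with any positively correlated set.

    Each promoter contributes its best window score within the PWM's enriched
    region; presence at a grid threshold t is score >= t. MI against a set is
    only considered where the presence/membership phi coefficient is
    positive. Returns ``(threshold, set_name, mi)`` or the
    :data:`UNINFORMATIVE` sentinel when no positive association exists; MI
    ties resolve to the smallest threshold.
    """
    genes = list(promoter_sequences)
    scores = np.array(
        [
            best_score(
                pwm,
                promoter_sequences[g],
                region=pwm.enriched_region,
                both_strands=both_strands,
                tss_index=tss_index,
            )
            for g in genes
        ]
    )
    memberships = {s.name: np.array([g in s.members for g in genes], dtype=int) for s in gene_sets}
    best = (None, None, 0.0)
    for t in threshold_grid(*grid):
        presence = (scores >= t).astype(int)
        for set_name, y in memberships.items():
            if binary_mcc(presence, y) <= 0:
                continue
            mi = binary_mi(presence, y)
            if mi > best[2] + 1e-12:
                best = (float(t), set_name, mi)
    if best[0] is None:
        return UNINFORMATIVE
    return best


def zscore_profile(presence_ordered, bin_size: int = 50) -> np.ndarray:
    """Binomial enrichment Z per bin of consecutively ordered genes.

    Z = (k - n*p) / sqrt(n*p*(1-p)) with p the global presence frequency;
    the trailing partial bin uses its own n. Degenerate p in {0, 1} yields an
    all-zero profile with a warning.
    """
    presence = np.asarray(presence_ordered, dtype=int)
    p = presence.mean() if presence.size else 0.0
    nbins = int(np.ceil(presence.size / bin_size))
    if p in (0.0, 1.0):
        warnings.warn("degenerate presence frequency; zero Z profile", stacklevel=2)
        return np.zeros(nbins)
    zs = np.empty(nbins)
    for i in range(nbins):
        chunk = presence[i * bin_size : (i + 1) * bin_size]
        n = chunk.size
        zs[i] = (chunk.sum() - n * p) / np.sqrt(n * p * (1 - p))
    return zs


def assign_architecture(
    promoter_id: str,
    motif_hits: set[str],
    class_motifs: dict[str, set[str]] | None = None,
) -> ArchitectureCall:
    """Label a promoter by the class with the most distinct motif hits.

    Zero hits gives 'motif-less'; a tie across classes gives 'mixed' with
    counts reported. Unknown motif names (outside every class list and the
    shared class-3 pool) are a configuration error.
    """
    classes = CLASS_MOTIFS if class_motifs is None else class_motifs
    known = set().union(*classes.values()) | CLASS3_SHARED
    unknown = motif_hits - known
    if unknown:
        raise ArchitectureError(f"unknown motif names: {sorted(unknown)}")
    counts = {label: len(motif_hits & members) for label, members in classes.items()}
    if sum(counts.values()) == 0 and not (motif_hits & CLASS3_SHARED):
        return ArchitectureCall(promoter_id, "motif-less", counts)
    top = max(counts.values())
    winners = [label for label, c in counts.items() if c == top and c > 0]
    if len(winners) == 1:
        return ArchitectureCall(promoter_id, winners[0], counts)
    if len(winners) == 0:
        # only shared class-3 motifs present
        return ArchitectureCall(promoter_id, "Ar3.1", counts)
    return ArchitectureCall(promoter_id, "mixed", counts)


DINUCLEOTIDES = [a + b for a in "ACGT" for b in "ACGT"]


def dinucleotide_profile(sequences: list[str], *, window: int = 500,
                         tss_index: int | None = None) -> tuple[np.ndarray, int]:
    """16 x window matrix of positioned dinucleotide frequencies.

    Sequences must cover ``window`` positions (by default the leading
    ``window + 1`` nt are used; pass ``tss_index`` to center on the TSS).
    Short sequences are skipped; the skip count is returned.
    """
    start = 0 if tss_index is None else tss_index - window // 2
    counts = np.zeros((16, window))
    skipped = 0
    index = {d: i for i, d in enumerate(DINUCLEOTIDES)}
    for seq in sequences:
        if start < 0 or start + window + 1 > len(seq):
            skipped += 1
            continue
        for pos in range(window):
            d = seq[start + pos : start + pos + 2]
            if d in index:
                counts[index[d], pos] += 1
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / totals, 0.0)
    return freqs, skipped


def site_position_histogram(tss_relative_starts, *, smoothing: int = 5,
                            span: tuple[int, int] = (-100, 50)):
    """Smoothed density of hit starts; returns (positions, density, peak).

    Smoothing uses a rectangular kernel (width in nucleotides) with
    truncated edges; the reported peak is the argmax of the smoothed
    histogram (leftmost on ties) and seeds consensus insertion in the
    design engine.
    """
    starts = np.asarray(list(tss_relative_starts), dtype=int)
    positions = np.arange(span[0], span[1] + 1)
    if starts.size == 0:
        return positions, np.zeros(0), None
    raw = np.array([(starts == p).sum() for p in positions], dtype=float)
    hist = raw
    if smoothing > 1:
        kernel = np.ones(smoothing)
        hist = np.convolve(raw, kernel, "same") / np.convolve(np.ones_like(raw), kernel, "same")
    # smoothed plateaus tie-break to the rawest, then leftmost, position
    top = np.isclose(hist, hist.max())
    peak = int(positions[top][np.argmax(raw[top])])
    return positions, hist, peak
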