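"""Effect sizes, pairwise additivity, activity logos, shift profiles, and
hormone inducibility analytics on normalized log2 expression values."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .motifs import PositionProbabilityMatrix, consensus as ppm_consensus, information_content

ADDITIVE_TOLERANCE = 0.2  # |additivity| below this counts as additive (log2)


class EffectError(ValueError):
    pass


@dataclass
class EffectEstimate:
    construct_id: str
    reference_id: str
    delta_log2: float
    n: int
    se: float

    @property
    def fold(self) -> float:
        return float(2.0 ** self.delta_log2)


@dataclass
class AdditivityRecord:
    promoter: str
    motif_pair: tuple[str, str]
    effect_a: float
    effect_b: float
    effect_ab: float
    sd_noise: float
    tolerance: float = ADDITIVE_TOLERANCE

    @property
    def additivity(self) -> float:
        return self.effect_ab - (self.effect_a + self.effect_b)

    @property
    def cls(self) -> str:
        a = self.additivity
        if abs(a) <= self.tolerance:
            return "additive"
        return "subadditive" if a > 0 else "superadditive"

    @property
    def gated(self) -> bool:
        """True when every participating effect clears 3x the noise scale."""
        cut = 3.0 * self.sd_noise
        return all(abs(e) > cut for e in (self.effect_a, self.effect_b, self.effect_ab))


@dataclass
class ActivityLogo:
    motif: str
    expression_ppm: PositionProbabilityMatrix
    ic_per_column: np.ndarray
    consensus: str
    incomplete_columns: list[int] = field(default_factory=list)


@dataclass
class InducibilitySummary:
    construct_id: str
    basal_x: float
    induced_x: float

    @property
    def log2_ratio(self) -> float:
        return self.induced_x - self.basal_x

    @property
    def fold(self) -> float:
        return float(2.0 ** self.log2_ratio)


def effect(construct_reps, reference_reps, *, construct_id: str = "construct",
           reference_id: str = "reference") -> EffectEstimate:
    """Mean log2 effect vs reference with a pooled-variance standard error."""
    a = np.asarray(construct_reps, dtype=float)
    b = np.asarray(reference_reps, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EffectError("empty replicate set")
    var_a = np.var(a, ddof=1) if a.size > 1 else 0.0
    var_b = np.var(b, ddof=1) if b.size > 1 else 0.0
    se = float(np.sqrt(var_a / a.size + var_b / b.size))
    return EffectEstimate(construct_id, reference_id,
                          float(a.mean() - b.mean()), int(a.size), se)


def additivity(effect_a: float, effect_b: float, effect_ab: float,
               sd_noise: float, *, promoter: str = "promoter",
               motif_pair: tuple[str, str] = ("a", "b"),
               tolerance: float = ADDITIVE_TOLERANCE) -> AdditivityRecord:
    return AdditivityRecord(promoter, motif_pair, effect_a, effect_b, effect_ab,
                            sd_noise, tolerance)


def expression_ppm(point_mutant_table: dict[int, dict[str, float]],
                   motif: str = "motif", *, log_weights: bool = False) -> ActivityLogo:
    """Activity logo from mean expression of all single-base motif variants.

    ``point_mutant_table[j][b]`` is the mean linear-scale expression of the
    variant carrying base b at position j (the consensus base maps to the
    consensus construct's expression). Columns are normalized to
    probabilities; missing variants leave a column computed over the
    available bases and flagged incomplete. ``log_weights`` switches the
    weighting to log2 expression.
    """
    L = max(point_mutant_table) + 1
    matrix = np.zeros((L, 4))
    incomplete = []
    for j in range(L):
        column = point_mutant_table.get(j, {})
        if len(column) < 4:
            incomplete.append(j)
        values = np.zeros(4)
        for i, b in enumerate("ACGT"):
            e = column.get(b, 0.0)
            if e < 0:
                raise EffectError(f"negative expression at position {j} base {b}")
            values[i] = np.log2(max(e, 1e-12)) if log_weights else e
        if log_weights:
            values = values - values.min()  # floor at 0 for weighting
        total = values.sum()
        matrix[j] = values / total if total > 0 else np.full(4, 0.25)
    ppm = PositionProbabilityMatrix(motif, matrix)
    ic, _ = information_content(ppm)
    cons, _ = ppm_consensus(ppm)
    return ActivityLogo(motif, ppm, ic, cons, incomplete)


def shift_profile(shift_effects: dict[int, list[float]],
                  wild_type_mean: float) -> tuple[dict[int, float], dict[str, int]]:
    """Map shift offset -> mean effect vs wild type; offset 0 is 0 by construction.

    Duplicate offsets are averaged with a warning (callers pass one list per
    offset). Monotonicity violations are counted per side: moving further
    from 0 should not increase activity.
    """
    curve = {0: 0.0}
    for delta, values in shift_effects.items():
        if delta == 0:
            continue
        if len(values) > 1:
            warnings.warn(f"duplicate constructs for shift {delta}; averaged", stacklevel=2)
        curve[delta] = float(np.mean(values) - wild_type_mean)
    violations = {"left": 0, "right": 0}
    for side, sign in (("right", 1), ("left", -1)):
        offsets = sorted((d for d in curve if sign * d > 0), key=abs)
        prev = 0.0
        for d in offsets:
            if curve[d] > prev + 1e-12:
                violations[side] += 1
            prev = curve[d]
    return curve, violations


def inducibility(basal_reps, induced_reps, *, construct_id: str = "construct") -> InducibilitySummary:
    a = np.asarray(basal_reps, dtype=float)
    b = np.asarray(induced_reps, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EffectError("both conditions must be measured")
    return InducibilitySummary(construct_id, float(a.mean()), float(b.mean()))


def inducibility_table(measurements: dict[str, tuple[list[float], list[float]]]):
    """Per-construct inducibility plus (basal, log2 ratio) pairs for correlation.

    Constructs missing one condition are skipped and counted.
    """
    summaries, pairs, skipped = [], [], 0
    for cid, (basal, induced) in measurements.items():
        if not basal or not induced:
            skipped += 1
            continue
        s = inducibility(basal, induced, construct_id=cid)
        summaries.append(s)
        pairs.append((s.basal_x, s.log2_ratio))
    return summaries, pairs, skipped


def compare_groups(values_a, values_b, test: str = "wilcoxon_rank_sum"):
    """Two-sided two-sample test; wraps scipy's standard implementations."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise EffectError("each group needs at least 2 values")
    if test == "wilcoxon_rank_sum":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "two_sample_t":
        res = stats.ttest_ind(a, b)
    else:
        raise EffectError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
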