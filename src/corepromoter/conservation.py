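"""Binding-site conservation against per-species sampled null sets.

The observed statistic S is the mean log-odds score difference between
reference (mel) sites and their aligned species-X counterparts. Null means
B_i come from resampling each reference site through a position-specific
substitution model learned from alignment context columns. The conservation
score is mean over i of (B_i - S) / B_i; 1 means perfect conservation, 0
background-level conservation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .motifs import BASE_INDEX, BASES, PositionWeightMatrix, score_window

SENTINEL_DEGENERATE = float("nan")


class ConservationError(ValueError):
    pass


@dataclass
class SitePairSet:
    species: str
    pairs: list[tuple[str, str]]
    context: list[list[tuple[str, str]]] | None = None  # aligned (mel, x) column pairs


@dataclass
class SubstitutionModel:
    """Per alignment column, a 4x4 row-stochastic mel->X substitution matrix."""

    matrices: np.ndarray  # (L, 4, 4)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=float)
        if m.ndim != 3 or m.shape[1:] != (4, 4):
            raise ConservationError("substitution model must be (L, 4, 4)")
        if not np.allclose(m.sum(axis=2), 1.0, atol=1e-9):
            raise ConservationError("substitution rows must sum to 1")
        self.matrices = m


@dataclass
class ConservationResult:
    species: str
    S: float
    B: np.ndarray
    score: float
    excluded_null_sets: int = 0


def observed_divergence(
    pwm: PositionWeightMatrix,
    pairs: list[tuple[str, str]],
    *,
    gap_policy: str = "skip",
) -> float:
    """Mean over sites of score(mel) - score(x); gapped sites skip by default."""
    if not pairs:
        raise ConservationError("no site pairs")
    diffs = []
    for mel, x in pairs:
        if len(mel) != len(x) or len(mel) != len(pwm):
            raise ConservationError("site pair length mismatch with motif")
        if "-" in mel or "-" in x:
            if gap_policy == "skip":
                continue
            mel = mel.replace("-", "N")
            x = x.replace("-", "N")
        diffs.append(score_window(pwm, mel, 0) - score_window(pwm, x, 0))
    if not diffs:
        raise ConservationError("all site pairs gapped; nothing to score")
    return float(np.mean(diffs))


def learn_substitution_model(
    context_columns: list[list[tuple[str, str]]],
    pseudocount: float = 0.5,
) -> SubstitutionModel:
    """Row-normalized mel->X substitution counts with additive pseudocounts.

    ``context_columns[j]`` lists the aligned (mel_base, x_base) pairs
    observed within +/-10 bp of site position j. An all-gap column falls
    back to a uniform row with a warning.
    """
    if pseudocount <= 0:
        raise ConservationError("pseudocount must be > 0")
    L = len(context_columns)
    mats = np.zeros((L, 4, 4))
    for j, column in enumerate(context_columns):
        counts = np.full((4, 4), pseudocount)
        seen = False
        for mel_b, x_b in column:
            if mel_b in BASE_INDEX and x_b in BASE_INDEX:
                counts[BASE_INDEX[mel_b], BASE_INDEX[x_b]] += 1
                seen = True
        if not seen and not column:
            warnings.warn(f"all-gap context at position {j}; uniform substitution row",
                          stacklevel=2)
        mats[j] = counts / counts.sum(axis=1, keepdims=True)
    return SubstitutionModel(mats)


def _normalized_counts(column: list[tuple[str, str]], pseudocount: float) -> np.ndarray:
    counts = np.full((4, 4), pseudocount)
    for mel_b, x_b in column:
        if mel_b in BASE_INDEX and x_b in BASE_INDEX:
            counts[BASE_INDEX[mel_b], BASE_INDEX[x_b]] += 1
    return counts / counts.sum(axis=1, keepdims=True)


def sample_null(
    model: SubstitutionModel,
    pwm: PositionWeightMatrix,
    mel_sites: list[str],
    *,
    n_sets: int = 50,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Null means B_i from resampling each mel site through the model."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = len(pwm)
    if model.matrices.shape[0] < L:
        raise ConservationError("substitution model shorter than motif")
    B = np.empty(n_sets)
    for i in range(n_sets):
        diffs = []
        for site in mel_sites:
            sampled = []
            for j, base in enumerate(site):
                if base not in BASE_INDEX:
                    sampled.append("N")
                    continue
                row = model.matrices[j, BASE_INDEX[base]]
                sampled.append(BASES[rng.choice(4, p=row)])
            diffs.append(score_window(pwm, site, 0) - score_window(pwm, "".join(sampled), 0))
        B[i] = np.mean(diffs)
    return B


def conservation_score(S: float, B) -> tuple[float, int]:
    """(1/N) sum (B_i - S)/B_i; zero B_i terms are excluded and counted.

    Returns (score, n_excluded); a NaN sentinel when every term is excluded.
    """
    B = np.asarray(B, dtype=float)
    if B.size == 0:
        raise ConservationError("empty null set")
    keep = B != 0
    excluded = int((~keep).sum())
    if not keep.any():
        return SENTINEL_DEGENERATE, excluded
    terms = (B[keep] - S) / B[keep]
    return float(terms.sum() / keep.sum()), excluded


def score_conservation(
    pwm: PositionWeightMatrix,
    site_pairs: SitePairSet,
    *,
    n_sets: int = 50,
    pseudocount: float = 0.5,
    seed: int = 0,
) -> ConservationResult:
    """End-to-end conservation scoring for one species."""
    S = observed_divergence(pwm, site_pairs.pairs)
    if site_pairs.context is None:
        raise ConservationError("context columns required to learn the null model")
    model = learn_substitution_model(site_pairs.context, pseudocount)
    mel_sites = [mel for mel, _ in site_pairs.pairs if "-" not in mel]
    B = sample_null(model, pwm, mel_sites, n_sets=n_sets, seed=seed)
    score, excluded = conservation_score(S, B)
    return ConservationResult(site_pairs.species, S, B, score, excluded)
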