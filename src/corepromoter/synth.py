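"""Seeded generators for every input the pipeline consumes.

Motifs, promoters, TSS tag tracks, toy species alignments, and simulated
dual-luciferase plates all derive deterministically from (seed, spec), and
the plate simulator carries an explicit additive-log2 truth model so that
downstream estimators can be tested for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .conservation import SitePairSet
from .design import CORE_LEN, TSS_INDEX, DesignedConstruct, MotifAnnotation, PromoterRecord
from .motifs import (
    BASES,
    PositionProbabilityMatrix,
    PositionWeightMatrix,
    best_score,
    ppm_to_pwm,
    scan,
    score_window,
)
from .plates import FF1_STRONG_RLU, Well
from .tss import TagTrack


class SynthError(ValueError):
    pass


# ---------------------------------------------------------------------------
# motifs

@dataclass(frozen=True)
class MotifSpec:
    name: str
    length: int
    target_ic: float  # total bits
    enriched_region: tuple[int, int] | None = None


def _column_ic(p: float) -> float:
    """IC in bits of a column with probability p on one base, rest uniform."""
    rest = (1 - p) / 3
    terms = [p * np.log2(4 * p)] if p > 0 else [0.0]
    if rest > 0:
        terms.append(3 * rest * np.log2(4 * rest))
    return float(sum(terms))


def _solve_column_p(ic: float) -> float:
    if ic <= 0:
        return 0.25
    if ic >= 2:
        return 1.0
    return brentq(lambda p: _column_ic(p) - ic, 0.25, 1.0 - 1e-12)


def gen_motifs(seed: int, specs: list[MotifSpec], *, calibrate: bool = True,
               n_background: int = 50) -> dict[str, PositionWeightMatrix]:
    """Seeded PPM/PWM set hitting each spec's information-content target.

    Per column, the consensus base gets probability p solved so the total IC
    matches the target (within the +/-10% contract). Thresholds are set
    midway between the consensus score and the best score seen on random
    background, so the consensus always passes and background never does.
    """
    rng = np.random.default_rng(seed)
    pwms: dict[str, PositionWeightMatrix] = {}
    for spec in specs:
        if spec.target_ic > 2 * spec.length:
            raise SynthError(f"{spec.name}: target IC {spec.target_ic} exceeds 2L")
        p = _solve_column_p(spec.target_ic / spec.length)
        matrix = np.full((spec.length, 4), (1 - p) / 3)
        consensus_idx = rng.integers(0, 4, size=spec.length)
        matrix[np.arange(spec.length), consensus_idx] = p
        ppm = PositionProbabilityMatrix(spec.name, matrix)
        pwm = ppm_to_pwm(ppm, pseudocount=0.01,
                         enriched_region=spec.enriched_region)
        if calibrate:
            cons_score = score_window(pwm, "".join(BASES[i] for i in consensus_idx), 0)
            # a rare random core can contain the consensus itself, so anchor
            # the threshold on a high quantile of background bests, not the max
            bg_bests = [
                best_score(pwm, "".join(BASES[i] for i in rng.integers(0, 4, size=CORE_LEN)))
                for _ in range(n_background)
            ]
            bg_q = float(np.quantile(bg_bests, 0.9))
            threshold = (cons_score + bg_q) / 2
            if threshold >= cons_score:
                raise SynthError(f"{spec.name}: cannot separate consensus from background")
            pwm = pwm.with_threshold(threshold)
        pwms[spec.name] = pwm
    return pwms


# ---------------------------------------------------------------------------
# promoters

@dataclass(frozen=True)
class PromoterSpec:
    id: str
    architecture: str = "unknown"
    placements: tuple[tuple[str, int], ...] = ()  # (motif name, TSS-relative start)


def gen_promoters(seed: int, specs: list[PromoterSpec],
                  pwms: dict[str, PositionWeightMatrix],
                  max_attempts: int = 200) -> list[PromoterRecord]:
    """131-nt cores with motif consensi planted in motif-free background.

    The background is rejection-sampled until a full scan (ignoring enriched
    regions) finds exactly the planted hits, so annotations are exact by
    construction.
    """
    rng = np.random.default_rng(seed)
    out = []
    for spec in specs:
        for name, start in spec.placements:
            idx = start + TSS_INDEX
            if idx < 0 or idx + len(pwms[name]) > CORE_LEN:
                raise SynthError(f"{spec.id}: {name} at {start} leaves the core")
        windows = sorted((start + TSS_INDEX, start + TSS_INDEX + len(pwms[n]), n)
                         for n, start in spec.placements)
        for lo_hi_a, lo_hi_b in zip(windows, windows[1:]):
            if lo_hi_b[0] < lo_hi_a[1]:
                raise SynthError(f"{spec.id}: overlapping placements")
        for _ in range(max_attempts):
            core = list("".join(BASES[i] for i in rng.integers(0, 4, size=CORE_LEN)))
            for name, start in spec.placements:
                cons = "".join(BASES[i] for i in pwms[name].weights.argmax(axis=1))
                idx = start + TSS_INDEX
                core[idx : idx + len(cons)] = cons
            core_str = "".join(core)
            observed = {
                (pwm.name, h.offset - TSS_INDEX)
                for pwm in pwms.values()
                for h in scan(pwm, core_str, tss_index=TSS_INDEX)
            }
            if observed == {(n, s) for n, s in spec.placements}:
                break
        else:
            raise SynthError(f"{spec.id}: could not sample a clean background")
        annotations = [
            MotifAnnotation(name, start, "+",
                            score=score_window(pwms[name], core_str, start + TSS_INDEX))
            for name, start in sorted(spec.placements, key=lambda x: x[1])
        ]
        out.append(PromoterRecord(spec.id, core_str, spec.architecture, annotations))
    return out


# ---------------------------------------------------------------------------
# truth model and plate simulation

@dataclass
class TruthModel:
    """Planted additive-log2 ground truth with optional interactions.

    Activity of a construct = parent baseline + sum of feature effects
    + sum of pairwise interaction terms + (induced ? min(boost, ceiling -
    basal) : 0). Noise is multiplicative lognormal on FF and REN.
    """

    baselines: dict[str, float]
    effects: dict[str, float] = field(default_factory=dict)
    interactions: dict[frozenset, float] = field(default_factory=dict)
    ecdysone_boost: dict[str, float] = field(default_factory=dict)
    ceiling: float = 12.0
    sigma_ff: float = 0.0
    sigma_ren: float = 0.0
    bg_level: float = 100.0
    ff2_degradation: float = 1.0
    ren_true: float = 2000.0
    norm_true: float = 5.0

    def __post_init__(self) -> None:
        if self.baselines and self.ceiling < max(self.baselines.values()):
            raise SynthError("ceiling must dominate every baseline")
        if min(self.sigma_ff, self.sigma_ren) < 0:
            raise SynthError("noise SDs must be non-negative")

    def activity(self, parent: str, features: list[str], *, induced: bool = False,
                 architecture: str = "unknown") -> float:
        a = self.baselines[parent]
        a += sum(self.effects.get(f, 0.0) for f in features)
        for pair, delta in self.interactions.items():
            if pair <= set(features):
                a += delta
        if induced:
            boost = self.ecdysone_boost.get(architecture, 0.0)
            a += max(min(boost, self.ceiling - a), 0.0)
        return a


@dataclass(frozen=True)
class ConstructTruth:
    construct_id: str
    parent: str
    features: tuple[str, ...] = ()
    architecture: str = "unknown"


def _well_name(i: int) -> str:
    return f"{'ABCDEFGH'[i // 12]}{i % 12 + 1:02d}"


def simulate_plates(
    constructs: list[ConstructTruth],
    truth: TruthModel,
    *,
    seed: int = 0,
    replicates: int = 3,
    conditions: tuple[bool, ...] = (False,),
    samples_per_plate: int = 88,
) -> list[Well]:
    """Simulate 96-well plates with control wells and lognormal noise.

    Each plate carries 2 pUC19, 2 UTC, 2 pUG9, and 2 pZQ3 control wells;
    replicate r of every construct in every condition occupies one sample
    well. FF_true = norm * REN * 2^activity + BG; strong wells (FF1 above
    the quench cutoff) store an FF2 sentinel of 0.
    """
    rng = np.random.default_rng(seed)
    jobs = [
        (c, r, cond)
        for cond in conditions
        for r in range(replicates)
        for c in constructs
    ]
    wells: list[Well] = []
    plate_no = 0
    cursor = samples_per_plate  # force controls on first plate

    def lognoise(sigma: float) -> float:
        return float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0

    for c, r, cond in jobs:
        if cursor >= samples_per_plate:
            plate_no += 1
            cursor = 0
            plate_id = f"plate{plate_no:03d}"
            slot = 0
            for role, count in (("pUC19", 2), ("UTC", 2), ("pUG9", 2), ("pZQ3", 2)):
                for _ in range(count):
                    if role in ("pUC19", "UTC"):
                        ff_true = truth.bg_level
                        ff1 = ff_true * lognoise(truth.sigma_ff)
                        ff2 = truth.bg_level * lognoise(truth.sigma_ff)
                    else:
                        # pUG9 activity fixed at 1 so Norm_pUG9 recovers the
                        # planted plate factor; pZQ3 is a moderate promoter
                        level = 1.0 if role == "pUG9" else 10.0
                        ff_true = truth.norm_true * truth.ren_true * level + truth.bg_level
                        ff1 = ff_true * lognoise(truth.sigma_ff)
                        ff2 = 0.0 if ff1 > FF1_STRONG_RLU else ff_true * lognoise(truth.sigma_ff)
                    ren = truth.ren_true * lognoise(truth.sigma_ren)
                    wells.append(Well(plate_id, _well_name(slot), role, None, cond,
                                      ff1, ff2, ren))
                    slot += 1
        activity = truth.activity(c.parent, list(c.features), induced=cond,
                                  architecture=c.architecture)
        ren = truth.ren_true * lognoise(truth.sigma_ren)
        ff_true = truth.norm_true * ren * (2.0 ** activity) + truth.bg_level
        ff1 = ff_true * lognoise(truth.sigma_ff)
        ff2 = (0.0 if ff1 > FF1_STRONG_RLU
               else ff_true * truth.ff2_degradation * lognoise(truth.sigma_ff))
        wells.append(Well(f"plate{plate_no:03d}", _well_name(8 + cursor), "sample",
                          c.construct_id, cond, ff1, ff2, ren))
        cursor += 1
    return wells


def wells_to_frame(wells: list[Well]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "plate": [w.plate_id for w in wells],
            "well": [w.position for w in wells],
            "role": [w.role for w in wells],
            "construct": [w.construct_id or "" for w in wells],
            "ecdysone": [w.ecdysone for w in wells],
            "FF1": [w.FF1 for w in wells],
            "FF2": [w.FF2 for w in wells],
            "REN": [w.REN for w in wells],
        }
    )


# ---------------------------------------------------------------------------
# TSS tag tracks

@dataclass(frozen=True)
class TssTrackSpec:
    n_clusters: int = 10
    spread: int = 0  # 0 = single position; else tags uniform over this width
    depth: int = 50  # tags per cluster
    spacing: int = 400
    margin: int = 200


def gen_tss_tags(seed: int, spec: TssTrackSpec, contig: str = "chrS") -> tuple[TagTrack, list[int]]:
    """Seeded track of evenly spaced clusters; returns (track, cluster centers)."""
    rng = np.random.default_rng(seed)
    length = spec.margin * 2 + spec.spacing * spec.n_clusters
    counts = np.zeros(length)
    centers = []
    for k in range(spec.n_clusters):
        center = spec.margin + spec.spacing * k + spec.spacing // 2
        centers.append(center)
        if spec.spread <= 0:
            counts[center] += spec.depth
        else:
            offsets = rng.integers(-(spec.spread // 2), spec.spread - spec.spread // 2,
                                   size=spec.depth)
            for o in offsets:
                counts[center + o] += 1
    return TagTrack(contig, "+", counts), centers


# ---------------------------------------------------------------------------
# toy alignments

def gen_alignments(
    seed: int,
    pwm: PositionWeightMatrix,
    *,
    species: str = "spX",
    site_rate: float = 0.1,
    context_rate: float = 0.1,
    n_sites: int = 200,
    n_context_pairs: int = 400,
) -> SitePairSet:
    """Site pairs mutated i.i.d. at ``site_rate``; context at ``context_rate``."""
    for r in (site_rate, context_rate):
        if not 0 <= r <= 0.75:
            raise SynthError("substitution rates must lie in [0, 0.75]")
    rng = np.random.default_rng(seed)
    L = len(pwm)
    ppm = (2.0 ** pwm.weights) * pwm.background
    ppm /= ppm.sum(axis=1, keepdims=True)

    def mutate(seq: str, rate: float) -> str:
        out = []
        for b in seq:
            if rng.random() < rate:
                choices = [c for c in BASES if c != b]
                out.append(choices[rng.integers(0, 3)])
            else:
                out.append(b)
        return "".join(out)

    pairs = []
    for _ in range(n_sites):
        mel = "".join(BASES[rng.choice(4, p=ppm[j])] for j in range(L))
        pairs.append((mel, mutate(mel, site_rate)))
    context = []
    for _ in range(L):
        column = []
        for _ in range(n_context_pairs):
            b = BASES[rng.integers(0, 4)]
            column.append((b, mutate(b, context_rate)))
        context.append(column)
    return SitePairSet(species, pairs, context)
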