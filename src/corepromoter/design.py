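"""Synthetic-promoter mutation design engine.

Cores are 131 nt spanning TSS-relative positions -80..+50 (TSS = 0 at string
index 80). Every mutation family operates on annotated promoter records and
emits constructs with full provenance; random replacements are rejection-
checked against the whole PWM set so no motif is created or destroyed
unintentionally.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .motifs import BASES, PositionWeightMatrix, scan, score_window

CORE_START = -80  # TSS-relative, inclusive
CORE_END = 51  # TSS-relative, exclusive
CORE_LEN = 131
TSS_INDEX = 80  # string index of the TSS inside a core

#: 1-based position of the TSS inside TSS-anchored (INR-like) motifs.
TSS_ANCHOR = {"INR": 3, "INR2": 10, "Ohler7": 5, "TCT": 6}

MUTATION_KINDS = frozenset({
    "knockout_random", "knockout_background", "knockout_pair", "knockout_all",
    "consensus_replace", "consensus_insert", "strength_series", "point_mutation",
    "substitute", "shift_motif", "shift_all_motifs", "shift_context",
    "context_exchange",
})


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class BlockLayout:
    """Coordinates of the construct building blocks.

    Blocks 3-6 tile the core exactly (46 + 25 + 18 + 42 = 131 nt); full
    assemblies are 703 nt with block 7 and 459 nt without, including the
    4-nt junction overhangs.
    """

    block1_len: int = 239
    block2_len: int = 73
    block7_len: int = 240
    overhang_len: int = 4
    # TSS-relative half-open intervals of the core blocks
    block3: tuple[int, int] = (-80, -34)
    block4: tuple[int, int] = (-34, -9)
    block5: tuple[int, int] = (-9, 9)
    block6: tuple[int, int] = (9, 51)

    @property
    def core_blocks(self) -> dict[str, tuple[int, int]]:
        return {"block3": self.block3, "block4": self.block4,
                "block5": self.block5, "block6": self.block6}

    def split_core(self, core: str) -> dict[str, str]:
        if len(core) != CORE_LEN:
            raise DesignError(f"core must be {CORE_LEN} nt, got {len(core)}")
        return {
            name: core[lo + TSS_INDEX : hi + TSS_INDEX]
            for name, (lo, hi) in self.core_blocks.items()
        }

    def join_core(self, blocks: dict[str, str]) -> str:
        for name, (lo, hi) in self.core_blocks.items():
            if len(blocks[name]) != hi - lo:
                raise DesignError(f"{name} must be {hi - lo} nt, got {len(blocks[name])}")
        return "".join(blocks[n] for n in ("block3", "block4", "block5", "block6"))


DEFAULT_LAYOUT = BlockLayout()
DEFAULT_OVERHANGS = ("ATGA", "CCAC", "TCTG", "AGGT", "CAAG")


@dataclass(frozen=True)
class MotifAnnotation:
    name: str
    start: int  # TSS-relative start
    strand: str
    score: float = float("nan")
    overlapping: bool = False

    @property
    def index(self) -> int:
        return self.start + TSS_INDEX


@dataclass
class PromoterRecord:
    id: str
    core_sequence: str
    architecture: str = "unknown"
    annotations: list[MotifAnnotation] = field(default_factory=list)
    wild_type: bool = True

    def __post_init__(self) -> None:
        if len(self.core_sequence) != CORE_LEN:
            raise DesignError(
                f"promoter {self.id!r}: core must be {CORE_LEN} nt, got {len(self.core_sequence)}"
            )
        for a in self.annotations:
            if a.index < 0 or a.index > CORE_LEN:
                raise DesignError(f"annotation {a} outside core")

    def annotation(self, motif_name: str) -> MotifAnnotation:
        matches = [a for a in self.annotations if a.name == motif_name]
        if not matches:
            raise DesignError(f"motif {motif_name!r} not annotated in promoter {self.id!r}")
        return max(matches, key=lambda a: (a.score if np.isfinite(a.score) else 0.0))


@dataclass
class MutationSpec:
    kind: str
    targets: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in MUTATION_KINDS:
            raise DesignError(f"unknown mutation kind {self.kind!r}")

    def describe(self) -> str:
        extras = ",".join(f"{k}={v}" for k, v in sorted(self.params.items())
                          if k not in ("background_core", "donor"))
        return f"{self.kind}({'+'.join(self.targets)}{';' + extras if extras else ''})"


@dataclass
class DesignedConstruct:
    id: str
    core_sequence: str
    parent_id: str
    spec_chain: list[str]
    features: list[str] = field(default_factory=list)
    intended_motifs: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.core_sequence) != CORE_LEN:
            raise DesignError(f"construct {self.id!r}: core length {len(self.core_sequence)}")


@dataclass
class ValidationReport:
    construct_id: str
    intended_losses: list[MotifAnnotation] = field(default_factory=list)
    intended_gains: list[MotifAnnotation] = field(default_factory=list)
    unintended_losses: list[MotifAnnotation] = field(default_factory=list)
    unintended_gains: list[MotifAnnotation] = field(default_factory=list)

    @property
    def dirty(self) -> bool:
        return bool(self.unintended_losses or self.unintended_gains)


# ---------------------------------------------------------------------------
# annotation

def annotate(
    promoter_id: str,
    core_sequence: str,
    pwm_set: dict[str, PositionWeightMatrix],
    *,
    architecture: str = "unknown",
    wild_type: bool = True,
) -> PromoterRecord:
    """Scan a core with every calibrated PWM inside its enriched region.

    Overlapping hits are allowed and flagged.
    """
    annotations: list[MotifAnnotation] = []
    for name, pwm in pwm_set.items():
        hits = scan(pwm, core_sequence, sequence_id=promoter_id,
                    region=pwm.enriched_region, tss_index=TSS_INDEX)
        for h in hits:
            annotations.append(
                MotifAnnotation(name, h.offset - TSS_INDEX, h.strand, h.score)
            )
    annotations.sort(key=lambda a: (a.start, a.name))
    flagged = []
    for a in annotations:
        overlaps = any(
            b is not a
            and a.index < b.index + len(pwm_set[b.name])
            and b.index < a.index + len(pwm_set[a.name])
            for b in annotations
        )
        flagged.append(MotifAnnotation(a.name, a.start, a.strand, a.score, overlaps))
    return PromoterRecord(promoter_id, core_sequence, architecture, flagged, wild_type)


# ---------------------------------------------------------------------------
# sequence editing helpers

def _replace_window(core: str, index: int, replacement: str) -> str:
    return core[:index] + replacement + core[index + len(replacement):]


def _random_bases(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _window_clean(
    core: str,
    index: int,
    length: int,
    pwm_set: dict[str, PositionWeightMatrix],
) -> bool:
    """True if no PWM hits at/above threshold anywhere across the window
    extended by (max motif length - 1) of context on each side."""
    max_len = max(len(p) for p in pwm_set.values())
    lo = max(0, index - (max_len - 1))
    hi = min(len(core), index + length + (max_len - 1))
    segment = core[lo:hi]
    for pwm in pwm_set.values():
        if np.isfinite(pwm.min_score_threshold) and scan(pwm, segment):
            return False
    return True


def _sample_clean_replacement(
    core: str,
    index: int,
    length: int,
    pwm_set: dict[str, PositionWeightMatrix],
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> str:
    for _ in range(max_attempts):
        candidate = _replace_window(core, index, _random_bases(rng, length))
        if _window_clean(candidate, index, length, pwm_set):
            return candidate
    colliding = [
        p.name for p in pwm_set.values()
        if np.isfinite(p.min_score_threshold)
        and scan(p, candidate[max(0, index - len(p) + 1): index + length + len(p) - 1])
    ]
    raise DesignError(
        f"rejection sampling exhausted after {max_attempts} attempts; "
        f"colliding PWMs: {colliding or 'unknown'}"
    )


def pwm_consensus(pwm: PositionWeightMatrix) -> str:
    return "".join(BASES[i] for i in pwm.weights.argmax(axis=1))


def _place_motifs(context: str, placements: list[tuple[int, str]], length: int = CORE_LEN) -> str:
    """Lay motif strings at fixed indices; fill the gaps with context chars.

    ``context`` supplies exactly the non-motif characters in left-to-right
    order; placements must not overlap or leave the core.
    """
    placements = sorted(placements)
    occupied = np.zeros(length, dtype=bool)
    out = [""] * length
    for idx, seq in placements:
        if idx < 0 or idx + len(seq) > length:
            raise DesignError(f"motif placement [{idx}, {idx + len(seq)}) leaves the core")
        if occupied[idx : idx + len(seq)].any():
            raise DesignError("overlapping motif placements")
        occupied[idx : idx + len(seq)] = True
        for k, ch in enumerate(seq):
            out[idx + k] = ch
    free = int((~occupied).sum())
    if len(context) != free:
        raise DesignError(f"context length {len(context)} != free positions {free}")
    it = iter(context)
    for k in range(length):
        if not occupied[k]:
            out[k] = next(it)
    return "".join(out)


def _excise(core: str, annotations: list[MotifAnnotation],
            pwm_set: dict[str, PositionWeightMatrix]) -> str:
    """Context string: the core with all annotated motif windows removed."""
    mask = np.ones(CORE_LEN, dtype=bool)
    for a in annotations:
        mask[a.index : a.index + len(pwm_set[a.name])] = False
    return "".join(ch for ch, keep in zip(core, mask) if keep)


# ---------------------------------------------------------------------------
# mutation families

def apply_mutation(
    promoter: PromoterRecord,
    spec: MutationSpec,
    pwm_set: dict[str, PositionWeightMatrix],
    rng: np.random.Generator | int | None = None,
) -> list[DesignedConstruct]:
    """Generate the construct(s) requested by one mutation spec.

    Same-seed calls are bit-reproducible. All families preserve the 131-nt
    core length (consensus insertion overwrites in place).
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(spec.seed if rng is None else rng)
    core = promoter.core_sequence
    kind = spec.kind
    chain = [spec.describe()]
    pid = promoter.id

    def construct(seq: str, suffix: str, features: list[str], intended: set[str]) -> DesignedConstruct:
        return DesignedConstruct(f"{pid}__{suffix}", seq, pid, chain, features, intended)

    if kind == "knockout_random":
        (target,) = spec.targets
        a = promoter.annotation(target)
        L = len(pwm_set[target])
        seq = _sample_clean_replacement(core, a.index, L, pwm_set, rng)
        return [construct(seq, f"ko_{target}", [f"{target}:ko"], {target})]

    if kind == "knockout_background":
        (target,) = spec.targets
        background = spec.params["background_core"]
        if len(background) != CORE_LEN:
            raise DesignError("background core must be 131 nt")
        a = promoter.annotation(target)
        L = len(pwm_set[target])
        seq = _replace_window(core, a.index, background[a.index : a.index + L])
        return [construct(seq, f"kobg_{target}", [f"{target}:ko_bg"], {target})]

    if kind == "knockout_pair":
        t1, t2 = spec.targets
        seq = core
        for t in (t1, t2):
            a = promoter.annotation(t)
            seq = _sample_clean_replacement(seq, a.index, len(pwm_set[t]), pwm_set, rng)
        return [construct(seq, f"ko_{t1}_{t2}", [f"{t1}:ko", f"{t2}:ko"], {t1, t2})]

    if kind == "knockout_all":
        mode = spec.params.get("mode", "random")
        targets = spec.targets or sorted({a.name for a in promoter.annotations})
        seq = core
        for t in targets:
            a = promoter.annotation(t)
            L = len(pwm_set[t])
            if mode == "background":
                bg = spec.params["background_core"]
                seq = _replace_window(seq, a.index, bg[a.index : a.index + L])
            else:
                seq = _sample_clean_replacement(seq, a.index, L, pwm_set, rng)
        feats = [f"{t}:ko" for t in targets]
        return [construct(seq, f"koall_{mode}", feats, set(targets))]

    if kind == "consensus_replace":
        (target,) = spec.targets
        a = promoter.annotation(target)
        seq = _replace_window(core, a.index, pwm_consensus(pwm_set[target]))
        return [construct(seq, f"cons_{target}", [f"{target}:consensus"], {target})]

    if kind == "consensus_insert":
        (target,) = spec.targets
        position = spec.params["insert_position"]  # TSS-relative start
        idx = position + TSS_INDEX
        cons = pwm_consensus(pwm_set[target])
        if idx < 0 or idx + len(cons) > CORE_LEN:
            raise DesignError(f"consensus insertion of {target} at {position} leaves the core")
        seq = _replace_window(core, idx, cons)
        return [construct(seq, f"ins_{target}", [f"{target}:insert@{position}"], {target})]

    if kind == "strength_series":
        (target,) = spec.targets
        bins = spec.params["bins"]  # list of (lo, hi) log-odds score bins
        a = promoter.annotation(target)
        pwm = pwm_set[target]
        others = {n: p for n, p in pwm_set.items() if n != target}
        cons = pwm_consensus(pwm)
        out = []
        for b, (lo, hi) in enumerate(bins):
            for _ in range(spec.params.get("max_attempts", 1000)):
                # propose by mutating k random consensus positions, which
                # reaches every score bin from background to maximum
                k = int(rng.integers(0, len(pwm) + 1))
                positions = rng.choice(len(pwm), size=k, replace=False)
                repl = list(cons)
                for j in positions:
                    repl[j] = BASES[rng.integers(0, 4)]
                repl = "".join(repl)
                if lo <= score_window(pwm, repl, 0) < hi:
                    seq = _replace_window(core, a.index, repl)
                    if _window_clean(seq, a.index, len(pwm), others):
                        out.append(construct(
                            seq, f"str_{target}_bin{b}",
                            [f"{target}:strength_bin{b}"], {target}))
                        break
            else:
                raise DesignError(
                    f"strength_series: no {target} variant in score bin [{lo}, {hi})"
                )
        return out

    if kind == "point_mutation":
        (target,) = spec.targets
        a = promoter.annotation(target)
        cons = pwm_consensus(pwm_set[target])
        base_seq = _replace_window(core, a.index, cons)
        out = [construct(base_seq, f"pm_{target}_cons", [f"{target}:consensus"], {target})]
        for j, ref in enumerate(cons):
            for alt in BASES:
                if alt == ref:
                    continue
                variant = cons[:j] + alt + cons[j + 1:]
                seq = _replace_window(core, a.index, variant)
                out.append(construct(
                    seq, f"pm_{target}_{j}{alt}", [f"{target}:pm_{j}{ref}>{alt}"], {target}))
        return out

    if kind == "substitute":
        target, donor = spec.targets
        a = promoter.annotation(target)
        seq = _sample_clean_replacement(core, a.index, len(pwm_set[target]), pwm_set, rng)
        donor_seq = spec.params.get("donor_sequence") or pwm_consensus(pwm_set[donor])
        if target in TSS_ANCHOR and donor in TSS_ANCHOR:
            anchor = a.index + TSS_ANCHOR[target] - 1
            idx = anchor - (TSS_ANCHOR[donor] - 1)
        else:
            idx = a.index
        if idx < 0 or idx + len(donor_seq) > CORE_LEN:
            raise DesignError(f"substitution of {donor} for {target} leaves the core")
        seq = _replace_window(seq, idx, donor_seq)
        return [construct(seq, f"sub_{target}_{donor}",
                          [f"{target}:sub_{donor}"], {target, donor})]

    if kind in ("shift_motif", "shift_all_motifs"):
        delta = int(spec.params["delta"])
        if kind == "shift_motif":
            (target,) = spec.targets
            moving = [promoter.annotation(target)]
            fixed = [x for x in promoter.annotations if x.name != target]
            suffix = f"shift_{target}_{delta:+d}"
            feats = [f"{target}:shift{delta:+d}"]
            intended = {target}
        else:
            moving = list(promoter.annotations)
            fixed = []
            suffix = f"shiftall_{delta:+d}"
            feats = [f"all:shift{delta:+d}"]
            intended = {x.name for x in moving}
        context = _excise(core, promoter.annotations, pwm_set)
        placements = [
            (x.index + delta, core[x.index : x.index + len(pwm_set[x.name])]) for x in moving
        ] + [
            (x.index, core[x.index : x.index + len(pwm_set[x.name])]) for x in fixed
        ]
        seq = _place_motifs(context, placements)
        return [construct(seq, suffix, feats, intended)]

    if kind == "shift_context":
        delta = int(spec.params["delta"])
        context = _excise(core, promoter.annotations, pwm_set)
        rolled = "".join(np.roll(list(context), delta))
        placements = [
            (x.index, core[x.index : x.index + len(pwm_set[x.name])])
            for x in promoter.annotations
        ]
        seq = _place_motifs(rolled, placements)
        return [construct(seq, f"shiftctx_{delta:+d}", [f"context:shift{delta:+d}"], set())]

    if kind == "context_exchange":
        donor: PromoterRecord = spec.params["donor"]
        seq = core
        for a in sorted(promoter.annotations, key=lambda x: x.start):
            seq = _sample_clean_replacement(seq, a.index, len(pwm_set[a.name]), pwm_set, rng)
        for a in sorted(donor.annotations, key=lambda x: x.start):
            motif_seq = donor.core_sequence[a.index : a.index + len(pwm_set[a.name])]
            seq = _replace_window(seq, a.index, motif_seq)
        intended = {a.name for a in promoter.annotations} | {a.name for a in donor.annotations}
        feats = [f"context:{promoter.id}<-{donor.id}"]
        return [construct(seq, f"ctx_{donor.id}", feats, intended)]

    raise DesignError(f"unhandled mutation kind {kind!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# combinatorics

def enumerate_combinatorial(
    *,
    mode: str,
    pools: dict,
    promoter: PromoterRecord | None = None,
    pwm_set: dict[str, PositionWeightMatrix] | None = None,
    sample: int | None = None,
    seed: int = 0,
    layout: BlockLayout = DEFAULT_LAYOUT,
) -> list[DesignedConstruct]:
    """Cartesian (or seeded-subsampled) combination of mutation options.

    inter_block mode: ``pools`` maps 'block3'..'block6' to lists of
    ``(label, sequence)`` with the exact block lengths; cores are simple
    concatenations. intra mode: ``pools`` maps motif name to option dicts
    ``{label, seq?, shift?}`` composed onto the promoter by motif placement.
    """
    rng = np.random.default_rng(seed)
    if mode == "inter_block":
        names = ["block3", "block4", "block5", "block6"]
        for n in names:
            if not pools.get(n):
                raise DesignError(f"empty pool for {n}")
        sizes = [len(pools[n]) for n in names]
        combos = _combo_indices(sizes, sample, rng)
        out = []
        for idx in combos:
            blocks = {n: pools[n][i][1] for n, i in zip(names, idx)}
            labels = [pools[n][i][0] for n, i in zip(names, idx)]
            core = layout.join_core(blocks)
            cid = "inter__" + "_".join(labels)
            feats = [f"{n}={lab}" for n, lab in zip(names, labels)]
            out.append(DesignedConstruct(cid, core, "inter", ["inter_block"], feats))
        return out

    if mode == "intra":
        if promoter is None or pwm_set is None:
            raise DesignError("intra mode requires promoter and pwm_set")
        motif_names = sorted(pools)
        for m in motif_names:
            if not pools[m]:
                raise DesignError(f"empty option pool for motif {m}")
        sizes = [len(pools[m]) for m in motif_names]
        combos = _combo_indices(sizes, sample, rng)
        context = _excise(promoter.core_sequence, promoter.annotations, pwm_set)
        out = []
        for idx in combos:
            placements, feats, labels = [], [], []
            for m, i in zip(motif_names, idx):
                opt = pools[m][i]
                a = promoter.annotation(m)
                seq = opt.get("seq") or promoter.core_sequence[
                    a.index : a.index + len(pwm_set[m])
                ]
                shift = int(opt.get("shift", 0))
                placements.append((a.index + shift, seq))
                labels.append(opt["label"])
                if opt["label"] != "wt":
                    feats.append(f"{m}:{opt['label']}")
            core = _place_motifs(context, placements)
            cid = f"{promoter.id}__intra__" + "_".join(labels)
            out.append(DesignedConstruct(cid, core, promoter.id, ["intra"], feats,
                                         set(motif_names)))
        return out

    raise DesignError(f"unknown combinatorial mode {mode!r}")


def _combo_indices(sizes: list[int], sample: int | None, rng: np.random.Generator):
    total = int(np.prod(sizes))
    if sample is None or sample >= total:
        flat = np.arange(total)
    else:
        flat = rng.choice(total, size=sample, replace=False)
        flat.sort()
    return [np.unravel_index(i, sizes) for i in flat]


# ---------------------------------------------------------------------------
# assembly and sanitation

def assemble(
    block1: str,
    block2: str,
    core: str,
    block7: str | None = None,
    *,
    overhangs: tuple[str, ...] = DEFAULT_OVERHANGS,
    layout: BlockLayout = DEFAULT_LAYOUT,
) -> str:
    """Concatenate [ovh, b1, ovh, b2, ovh, core, (ovh, b7,) ovh].

    Lengths are checked block by block; the result is 703 nt with block 7
    and 459 nt without.
    """
    checks = [("block1", block1, layout.block1_len), ("block2", block2, layout.block2_len),
              ("core", core, CORE_LEN)]
    if block7 is not None:
        checks.append(("block7", block7, layout.block7_len))
    for name, seq, expected in checks:
        if len(seq) != expected:
            raise DesignError(f"{name} must be {expected} nt, got {len(seq)}")
    n_junctions = 5 if block7 is not None else 4
    ovh = list(overhangs[:n_junctions])
    if len(ovh) < n_junctions or any(len(o) != layout.overhang_len for o in ovh):
        raise DesignError(f"need {n_junctions} overhangs of {layout.overhang_len} nt")
    parts = [ovh[0], block1, ovh[1], block2, ovh[2], core]
    if block7 is not None:
        parts += [ovh[3], block7, ovh[4]]
    else:
        parts += [ovh[3]]
    return "".join(parts)


def sanitize_utr(sequence: str, tss_offset: int) -> str:
    """Mutate every ATG strictly downstream of the TSS to TAG (left-to-right)."""
    if not 0 <= tss_offset <= len(sequence):
        raise DesignError("tss_offset outside sequence")
    head, tail = sequence[:tss_offset], sequence[tss_offset:]
    return head + re.sub("ATG", "TAG", tail)


# ---------------------------------------------------------------------------
# validation and clone resolution

def validate(
    construct: DesignedConstruct,
    parent: PromoterRecord,
    pwm_set: dict[str, PositionWeightMatrix],
) -> ValidationReport:
    """Compare annotations of construct vs parent and flag unintended changes.

    A change (lost or gained hit) is intended iff its motif name appears in
    the construct's intended set recorded by the design step.
    """
    child = annotate(construct.id, construct.core_sequence, pwm_set, wild_type=False)
    key = lambda a: (a.name, a.start, a.strand)
    parent_keys = {key(a): a for a in parent.annotations}
    child_keys = {key(a): a for a in child.annotations}
    report = ValidationReport(construct.id)
    for k, a in parent_keys.items():
        if k not in child_keys:
            (report.intended_losses if a.name in construct.intended_motifs
             else report.unintended_losses).append(a)
    for k, a in child_keys.items():
        if k not in parent_keys:
            (report.intended_gains if a.name in construct.intended_motifs
             else report.unintended_gains).append(a)
    return report


def resolve_clone(
    candidate_counts: dict[str, int],
    designed_library: dict[str, str],
    *,
    enrichment: float = 3.0,
    min_identity: float = 0.95,
):
    """Pick a clone's sequence by read enrichment and map it to the library.

    The top sequence is accepted only when it is at least ``enrichment``-fold
    above the runner-up (a single candidate always passes); it is then
    globally aligned (unit match score) against every designed core and the
    best identity match returned. Returns ``(construct_id, identity)`` or
    ``(None, reason)``.
    """
    if not candidate_counts:
        raise DesignError("empty candidate counts")
    ranked = sorted(candidate_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) > 1 and ranked[0][1] < enrichment * ranked[1][1]:
        return None, "ambiguous"
    top_seq = ranked[0][0]
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    best_id, best_identity = None, -1.0
    for cid, seq in designed_library.items():
        if seq == top_seq:
            best_id, best_identity = cid, 1.0
            break
        alignment = aligner.align(top_seq, seq)[0]
        matches = sum(
            1
            for (a0, a1), (b0, b1) in zip(*alignment.aligned)
            for i in range(a1 - a0)
            if top_seq[a0 + i] == seq[b0 + i]
        )
        identity = matches / max(len(top_seq), len(seq))
        if identity > best_identity:
            best_id, best_identity = cid, identity
    if best_identity < min_identity:
        return None, "defective"
    return best_id, best_identity
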