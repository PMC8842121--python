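"""Benchmark statistics on the deposited synthetic-promoter dataset.

The published study ships its raw sequences and luminescence readouts as a
supplementary dataset. When a copy converted to this package's plate CSV
schema is available locally, the functions here recompute the headline
fold-change, additivity, and inducibility statistics from scratch through
the normalization pipeline. Two files are expected under a data directory:

``plates.csv``
    The raw readouts in the standard plate schema
    (plate, well, role, construct, ecdysone, FF1, FF2, REN).
``constructs.tsv``
    Construct metadata with columns: construct, promoter, kind, targets
    (comma-separated motif names; empty for wild type), architecture.
    ``kind`` uses the mutation-family vocabulary of :mod:`.design`
    ('wild_type' for native cores).

None of the reference numbers are hard-coded here; every statistic is a
function of the supplied tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .effects import additivity
from .plates import normalize_plates, read_plates_csv

DEVELOPMENTAL = ("Ar1", "Ar2")
CONSTITUTIVE = ("Ar3.1", "Ar3.2", "Ar3", "Ar4")


class Ev1Error(ValueError):
    pass


def available(data_dir: str | Path) -> bool:
    d = Path(data_dir)
    return (d / "plates.csv").is_file() and (d / "constructs.tsv").is_file()


def load(data_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize the deposited plates and attach construct metadata."""
    d = Path(data_dir)
    if not available(d):
        raise Ev1Error(f"deposited dataset not found under {d}")
    wells = read_plates_csv(d / "plates.csv")
    frame, _ = normalize_plates(wells)
    frame = frame[frame["qc"] == ""].copy()
    meta = pd.read_csv(d / "constructs.tsv", sep="\t", keep_default_na=False)
    required = {"construct", "promoter", "kind", "targets", "architecture"}
    missing = required - set(meta.columns)
    if missing:
        raise Ev1Error(f"constructs.tsv missing columns: {sorted(missing)}")
    return frame, meta


def _mean_x(frame: pd.DataFrame, construct: str, ecdysone: bool = False) -> float:
    sel = frame[(frame["construct"] == construct) & (frame["ecdysone"] == ecdysone)]
    if sel.empty:
        raise Ev1Error(f"no passing replicates for construct {construct!r}")
    return float(sel["x"].mean())


def _find(meta: pd.DataFrame, promoter: str, kind: str, targets: set[str] | None = None) -> str:
    sel = meta[(meta["promoter"] == promoter) & (meta["kind"] == kind)]
    if targets is not None:
        sel = sel[sel["targets"].map(lambda t: set(filter(None, t.split(","))) == targets)]
    if sel.empty:
        raise Ev1Error(f"no construct: promoter={promoter} kind={kind} targets={targets}")
    return str(sel.iloc[0]["construct"])


def knockout_fold(frame, meta, promoter: str, targets: set[str], kind: str = "knockout_pair") -> float:
    """Linear fold reduction of a knockout vs its wild type (>1 = reduced)."""
    wt = _mean_x(frame, _find(meta, promoter, "wild_type"))
    ko = _mean_x(frame, _find(meta, promoter, kind, targets))
    return float(2.0 ** (wt - ko))


def pair_additivity_magnitude(frame, meta, promoter: str, motif_a: str, motif_b: str) -> float:
    """|pairwise log2 effect - sum of single log2 effects| vs wild type."""
    wt = _mean_x(frame, _find(meta, promoter, "wild_type"))
    ea = _mean_x(frame, _find(meta, promoter, "knockout_random", {motif_a})) - wt
    eb = _mean_x(frame, _find(meta, promoter, "knockout_random", {motif_b})) - wt
    eab = _mean_x(frame, _find(meta, promoter, "knockout_pair", {motif_a, motif_b})) - wt
    return abs(additivity(ea, eb, eab, sd_noise=0.0).additivity)


def consensus_fold(frame, meta, promoter: str, motif: str) -> float:
    """Linear fold increase of a consensus replacement vs wild type."""
    wt = _mean_x(frame, _find(meta, promoter, "wild_type"))
    cons = _mean_x(frame, _find(meta, promoter, "consensus_replace", {motif}))
    return float(2.0 ** (cons - wt))


def insertion_fold(frame, meta, promoters: list[str], motif: str) -> float:
    """Mean linear fold increase of consensus insertion into motif-less cores."""
    folds = []
    for p in promoters:
        wt = _mean_x(frame, _find(meta, p, "wild_type"))
        ins = _mean_x(frame, _find(meta, p, "consensus_insert", {motif}))
        folds.append(2.0 ** (ins - wt))
    return float(np.mean(folds))


def architecture_inducibility(frame, meta, architectures: tuple[str, ...]) -> float:
    """Mean induced/uninduced linear ratio over constructs of the given classes."""
    constructs = meta.loc[meta["architecture"].isin(architectures), "construct"]
    ratios = []
    for cid in constructs:
        try:
            basal = _mean_x(frame, cid, ecdysone=False)
            induced = _mean_x(frame, cid, ecdysone=True)
        except Ev1Error:
            continue
        ratios.append(2.0 ** (induced - basal))
    if not ratios:
        raise Ev1Error("no constructs with both conditions measured")
    return float(np.mean(ratios))


def inr_knockout_inducibility_ratio(frame, meta) -> float:
    """Mean over INR promoters of wild-type inducibility / knockout inducibility."""
    inr_kos = meta[(meta["kind"] == "knockout_random") & (meta["targets"] == "INR")]
    ratios = []
    for row in inr_kos.itertuples():
        try:
            wt_cid = _find(meta, row.promoter, "wild_type")
            wt_ind = _mean_x(frame, wt_cid, True) - _mean_x(frame, wt_cid, False)
            ko_ind = _mean_x(frame, row.construct, True) - _mean_x(frame, row.construct, False)
        except Ev1Error:
            continue
        ratios.append(2.0 ** (wt_ind - ko_ind))
    if not ratios:
        raise Ev1Error("no INR knockouts with both conditions measured")
    return float(np.mean(ratios))


def block7_variation_sd(frame, meta) -> float:
    """Median over (constitutive promoter, block 1) groups of the SD of mean
    log2 expression across block 7 variants (block labels read from the
    construct kind 'block_combination' with targets 'b1=<id>,b7=<id>')."""
    combos = meta[(meta["kind"] == "block_combination")
                  & meta["architecture"].isin(CONSTITUTIVE)].copy()
    if combos.empty:
        raise Ev1Error("no constitutive block-combination constructs")
    def parse(tag, key):
        parts = dict(p.split("=") for p in tag.split(",") if "=" in p)
        return parts.get(key)
    combos["b1"] = combos["targets"].map(lambda t: parse(t, "b1"))
    combos["b7"] = combos["targets"].map(lambda t: parse(t, "b7"))
    sds = []
    for (_, _), group in combos.groupby(["promoter", "b1"]):
        xs = []
        for row in group.itertuples():
            try:
                xs.append(_mean_x(frame, row.construct))
            except Ev1Error:
                continue
        if len(xs) >= 2:
            sds.append(np.std(xs, ddof=1))
    if not sds:
        raise Ev1Error("no (promoter, block1) group with >= 2 block-7 variants")
    return float(np.median(sds))


def compute_targets(data_dir: str | Path) -> dict[str, dict]:
    """All deposited-data benchmark statistics, keyed by target id."""
    frame, meta = load(data_dir)
    n = int(frame.shape[0])
    out: dict[str, dict] = {}

    def put(key, fn):
        try:
            out[key] = {"value": float(fn()), "n": n}
        except Ev1Error:
            pass

    put("t1", lambda: pair_additivity_magnitude(frame, meta, "CG17712", "DRE", "Ohler7"))
    put("t2", lambda: float(np.mean([
        knockout_fold(frame, meta, "CG8157", set(), kind="knockout_all"),
        knockout_fold(frame, meta, "RpL5", set(), kind="knockout_all"),
    ])))
    put("t3", lambda: knockout_fold(frame, meta, "RpL5", {"TCT", "RDPE"}))
    put("t4", lambda: consensus_fold(frame, meta, "GstO2", "TATA-Box"))
    put("t5", lambda: insertion_fold(frame, meta, ["CG10915", "CG15674"], "INR2"))
    put("t6", lambda: architecture_inducibility(frame, meta, DEVELOPMENTAL))
    put("t7", lambda: architecture_inducibility(frame, meta, CONSTITUTIVE))
    put("t8", lambda: inr_knockout_inducibility_ratio(frame, meta))
    put("t9", lambda: block7_variation_sd(frame, meta))
    return out
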