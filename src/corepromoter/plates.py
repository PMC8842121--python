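"""Dual-luciferase plate normalization, QC filtering, and summaries.

Per plate: background BG is the mean FF2 of the pooled negative-control
wells (pUC19 + untransfected); the normalization factor is the mean of
(FF1 - BG) / REN over pUG9 positive-control wells. A sample's firefly
readout is FF1 when FF1 > 2e5 RLU (the well is quenched before the second
read), FF2 otherwise, and its normalized log2 expression is
log2(((FF - BG) / REN) / Norm_pUG9). Wells with REN outside [300, 10000]
are dropped; replicate outliers are flagged at |x - median| >= 3 times the
library-wide noise scale (median of per-construct replicate SDs).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FF1_STRONG_RLU = 2e5
REN_MIN = 300.0
REN_MAX = 10_000.0
OUTLIER_CUTOFF = 3.0

ROLES = ("sample", "pUC19", "UTC", "pUG9", "pZQ3")
PLATE_COLUMNS = ["plate", "well", "role", "construct", "ecdysone", "FF1", "FF2", "REN"]


class NormalizationError(ValueError):
    pass


@dataclass
class Well:
    plate_id: str
    position: str
    role: str
    construct_id: str | None
    ecdysone: bool
    FF1: float
    FF2: float
    REN: float

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise NormalizationError(f"unknown well role {self.role!r}")
        if self.role != "sample" and self.construct_id:
            raise NormalizationError("control wells carry no construct id")
        if min(self.FF1, self.FF2, self.REN) < 0:
            raise NormalizationError("RLU values must be non-negative")


@dataclass
class NormalizedMeasurement:
    construct_id: str
    ecdysone: bool
    x: float
    plate_id: str
    qc: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.qc


def background(plate: list[Well]) -> float:
    """Mean of the pooled FF2 signals of pUC19 and UTC wells."""
    values = [w.FF2 for w in plate if w.role in ("pUC19", "UTC")]
    if not values:
        raise NormalizationError("no negative-control wells on plate")
    return float(np.mean(values))


def norm_factor(plate: list[Well], bg: float) -> float:
    """Mean over pUG9 wells of (FF1 - BG) / REN; non-positive factor rejects the plate."""
    terms = []
    for w in plate:
        if w.role != "pUG9":
            continue
        if w.REN == 0:
            warnings.warn(f"pUG9 well {w.position} has REN=0; skipped", stacklevel=2)
            continue
        terms.append((w.FF1 - bg) / w.REN)
    if not terms:
        raise NormalizationError("no usable pUG9 wells on plate")
    factor = float(np.mean(terms))
    if factor <= 0:
        raise NormalizationError(f"non-positive normalization factor {factor}; plate rejected")
    return factor


def normalize(plate: list[Well]) -> list[NormalizedMeasurement]:
    """Normalized log2 expression for every sample well, with QC flags."""
    bg = background(plate)
    factor = norm_factor(plate, bg)
    out = []
    for w in plate:
        if w.role != "sample":
            continue
        qc: list[str] = []
        if not (REN_MIN <= w.REN <= REN_MAX):
            qc.append("ren_out_of_range")
        ff = w.FF1 if w.FF1 > FF1_STRONG_RLU else w.FF2
        x = np.nan
        if not qc:
            if ff <= bg:
                qc.append("nonpositive_signal")
            else:
                x = float(np.log2(((ff - bg) / w.REN) / factor))
        out.append(NormalizedMeasurement(w.construct_id, w.ecdysone, x, w.plate_id, qc))
    return out


def noise_scale(measurements: list[NormalizedMeasurement]) -> float:
    """Median over multi-replicate constructs of the per-construct SD of x."""
    groups: dict[tuple[str, bool], list[float]] = {}
    for m in measurements:
        if m.ok:
            groups.setdefault((m.construct_id, m.ecdysone), []).append(m.x)
    sds = [np.std(v, ddof=1) for v in groups.values() if len(v) >= 2]
    if not sds:
        return 0.0
    return float(np.median(sds))


def outlier_flags(measurements: list[NormalizedMeasurement],
                  scale: float | None = None) -> list[NormalizedMeasurement]:
    """Flag replicates at |x - construct median| / scale >= 3.

    The scale defaults to the library-wide noise scale; a zero scale flags
    nothing and warns.
    """
    if scale is None:
        scale = noise_scale(measurements)
    if scale == 0:
        warnings.warn("zero noise scale; no outliers flagged", stacklevel=2)
        return measurements
    medians: dict[tuple[str, bool], float] = {}
    groups: dict[tuple[str, bool], list[float]] = {}
    for m in measurements:
        if m.ok:
            groups.setdefault((m.construct_id, m.ecdysone), []).append(m.x)
    medians = {k: float(np.median(v)) for k, v in groups.items()}
    for m in measurements:
        if not m.ok:
            continue
        score = (m.x - medians[(m.construct_id, m.ecdysone)]) / scale
        if abs(score) >= OUTLIER_CUTOFF:
            m.qc.append("outlier")
    return measurements


def summarize(replicates: list[float], cv_scale: str = "linear") -> dict:
    """Mean/median/SD/CV/n over a construct's surviving log2 replicates.

    CV is reported in percent on the linear scale (SD/mean of 2**x, sample
    SD) by default; pass ``cv_scale='log'`` for the SD of the log2 values.
    """
    x = np.asarray(replicates, dtype=float)
    if x.size == 0:
        return {"n": 0, "unmeasured": True}
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    if cv_scale == "linear":
        lin = 2.0 ** x
        cv = float(np.std(lin, ddof=1) / np.mean(lin) * 100) if x.size > 1 else 0.0
    else:
        cv = sd * 100
    return {
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "sd": sd,
        "cv_percent": cv,
        "n": int(x.size),
        "unmeasured": False,
    }


# ---------------------------------------------------------------------------
# tabular I/O

def wells_from_frame(frame: pd.DataFrame) -> list[Well]:
    missing = set(PLATE_COLUMNS) - set(frame.columns)
    if missing:
        raise NormalizationError(f"plate table missing columns: {sorted(missing)}")
    wells = []
    for row in frame.itertuples(index=False):
        construct = None if pd.isna(row.construct) or row.construct == "" else str(row.construct)
        wells.append(
            Well(str(row.plate), str(row.well), str(row.role), construct,
                 bool(row.ecdysone), float(row.FF1), float(row.FF2), float(row.REN))
        )
    return wells


def read_plates_csv(path: str | Path) -> list[Well]:
    return wells_from_frame(pd.read_csv(path, keep_default_na=False, na_values=[""]))


def measurements_to_frame(measurements: list[NormalizedMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "construct": [m.construct_id for m in measurements],
            "ecdysone": [m.ecdysone for m in measurements],
            "x": [m.x for m in measurements],
            "plate": [m.plate_id for m in measurements],
            "qc": [";".join(m.qc) for m in measurements],
        }
    )


def normalize_plates(wells: list[Well]) -> tuple[pd.DataFrame, dict]:
    """Normalize every plate, flag outliers library-wide, report QC counts."""
    by_plate: dict[str, list[Well]] = {}
    for w in wells:
        by_plate.setdefault(w.plate_id, []).append(w)
    measurements: list[NormalizedMeasurement] = []
    rejected_plates = []
    for plate_id, plate in sorted(by_plate.items()):
        try:
            measurements.extend(normalize(plate))
        except NormalizationError as exc:
            rejected_plates.append({"plate": plate_id, "reason": str(exc)})
    scale = noise_scale(measurements)
    outlier_flags(measurements, scale)
    qc = {
        "n_wells": len(wells),
        "n_measurements": len(measurements),
        "n_ok": sum(m.ok for m in measurements),
        "noise_scale_log2": scale,
        "rejected_plates": rejected_plates,
        "flag_counts": {
            flag: sum(flag in m.qc for m in measurements)
            for flag in ("ren_out_of_range", "nonpositive_signal", "outlier")
        },
    }
    return measurements_to_frame(measurements), qc


def write_qc_json(qc: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(qc, indent=1))
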