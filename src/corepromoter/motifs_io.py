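"""Serialization for motif models and sequences.

PPMs travel in MEME minimal motif format (read via Bio.motifs, written by
hand); full PWM models, which additionally carry a threshold, an enriched
region, a background, and a source tag, use a small JSON dialect. Sequences
use FASTA via Biopython.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import (
    BASES,
    PositionProbabilityMatrix,
    PositionWeightMatrix,
    UNIFORM_BACKGROUND,
)


def write_meme(ppms: list[PositionProbabilityMatrix], path: str | Path,
               background: np.ndarray | None = None) -> None:
    q = UNIFORM_BACKGROUND if background is None else np.asarray(background, dtype=float)
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        " ".join(f"{b} {q[i]:.6f}" for i, b in enumerate(BASES)),
        "",
    ]
    for ppm in ppms:
        lines.append(f"MOTIF {ppm.name}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {len(ppm)} nsites= 1000000 E= 0"
        )
        for row in ppm.matrix:
            lines.append(" ".join(f"{v:.6f}" for v in row))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_meme(path: str | Path) -> list[PositionProbabilityMatrix]:
    with open(path) as handle:
        records = bio_motifs.parse(handle, "minimal")
    out = []
    for m in records:
        matrix = np.array([[m.pwm[b][j] for b in BASES] for j in range(m.length)])
        matrix /= matrix.sum(axis=1, keepdims=True)
        out.append(PositionProbabilityMatrix(name=m.name, matrix=matrix))
    return out


def write_pwm_json(pwms: list[PositionWeightMatrix], path: str | Path) -> None:
    payload = {
        "log_base": 2,
        "motifs": [
            {
                "name": p.name,
                "weights": p.weights.tolist(),
                "background": p.background.tolist(),
                "min_score_threshold": None
                if not np.isfinite(p.min_score_threshold)
                else p.min_score_threshold,
                "enriched_region": list(p.enriched_region) if p.enriched_region else None,
                "source": p.source,
            }
            for p in pwms
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_pwm_json(path: str | Path) -> list[PositionWeightMatrix]:
    payload = json.loads(Path(path).read_text())
    if payload.get("log_base") != 2:
        raise ValueError("PWM JSON must declare log_base 2")
    out = []
    for m in payload["motifs"]:
        thr = m.get("min_score_threshold")
        region = m.get("enriched_region")
        out.append(
            PositionWeightMatrix(
                name=m["name"],
                weights=np.array(m["weights"], dtype=float),
                background=np.array(m["background"], dtype=float),
                min_score_threshold=-np.inf if thr is None else float(thr),
                enriched_region=tuple(region) if region else None,
                source=m.get("source", "sequence-derived"),
            )
        )
    return out


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
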