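"""Compositional prion-like-domain (PrLD) detection.

Each residue is scored with a log-likelihood ratio (in bits) between a
Q/N-rich prion-domain composition (foreground) and a blended background
composition.  The *core score* of a protein is the best sum over any
contiguous window of exactly ``l_core`` residues (default 60); proteins
whose core score reaches the calling threshold (default 25 bits) are
reported as PrLD-containing, together with domain boundaries obtained by
extending the core window while the extension keeps adding positive
score.

The background is a blend of a species-specific and a default table:
``blended = (alpha/100) * species + (1 - alpha/100) * default`` with the
blending percentage ``alpha`` defaulting to 50.

LLR values are quantised to multiples of 2**-20 bits (~1e-6), far below
any meaningful compositional signal.  Quantised values and all window
sums over realistic protein lengths are exactly representable in double
precision, so every summation order yields bit-identical scores.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from .composition import AMBIGUITY_CODES, CANONICAL_AA

__all__ = [
    "ProteinRecord",
    "LLRTable",
    "PrLDHit",
    "build_llr_table",
    "core_score",
    "domain_boundaries",
    "call_prlds",
    "read_proteome",
    "write_fasta",
    "write_hits_tsv",
    "read_hits_tsv",
]

_LLR_QUANTUM = 2.0 ** -20

HITS_COLUMNS = [
    "protein_id", "core_start", "core_end", "core_score",
    "domain_start", "domain_end",
]


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry: id, free-text description, uppercase sequence."""

    id: str
    description: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class LLRTable:
    """Per-residue log-likelihood ratios (bits) with their provenance."""

    foreground_freqs: Mapping[str, float]
    species_bg_freqs: Mapping[str, float]
    default_bg_freqs: Mapping[str, float]
    alpha: float
    llr: Mapping[str, float]

    def lookup(self) -> np.ndarray:
        """LLR per ASCII code; ambiguity codes and unknowns map to 0."""
        table = np.zeros(128)
        for aa, value in self.llr.items():
            table[ord(aa)] = value
        return table

    def per_residue(self, sequence: str) -> np.ndarray:
        codes = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
        return self.lookup()[codes]


@dataclass(frozen=True)
class PrLDHit:
    """A called prion-like domain (1-based inclusive coordinates)."""

    protein_id: str
    core_start: int
    core_end: int
    core_score: float
    domain_start: int
    domain_end: int
    corescore_threshold: float


def _validated(name: str, freqs: Mapping[str, float]) -> Dict[str, float]:
    missing = [a for a in CANONICAL_AA if a not in freqs]
    if missing:
        raise ValueError(f"{name} table missing residues: {missing}")
    total = sum(freqs[a] for a in CANONICAL_AA)
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ValueError(f"{name} table sums to {total!r}, expected 1")
    return {a: freqs[a] / total for a in CANONICAL_AA}


def build_llr_table(
    foreground_freqs: Mapping[str, float],
    species_bg_freqs: Mapping[str, float],
    default_bg_freqs: Mapping[str, float],
    alpha: float = 50.0,
) -> LLRTable:
    """Build the per-residue scoring table.

    ``alpha`` is the percentage weight on the species background in the
    blend; 100 uses the species table alone, 0 the default table alone.
    """
    if not 0.0 <= alpha <= 100.0:
        raise ValueError(f"alpha must be in [0, 100], got {alpha}")
    fg = _validated("foreground", foreground_freqs)
    sp = _validated("species background", species_bg_freqs)
    de = _validated("default background", default_bg_freqs)
    w = alpha / 100.0
    llr: Dict[str, float] = {}
    for aa in CANONICAL_AA:
        blended = w * sp[aa] + (1.0 - w) * de[aa]
        if blended <= 0.0:
            raise ValueError(
                f"blended background frequency for residue {aa!r} is not positive"
            )
        if fg[aa] <= 0.0:
            raise ValueError(
                f"foreground frequency for residue {aa!r} is not positive"
            )
        value = math.log2(fg[aa] / blended)
        llr[aa] = round(value / _LLR_QUANTUM) * _LLR_QUANTUM
    return LLRTable(
        foreground_freqs=fg,
        species_bg_freqs=sp,
        default_bg_freqs=de,
        alpha=float(alpha),
        llr=llr,
    )


def core_score(
    sequence: str, llr_table: LLRTable, l_core: int = 60
) -> Optional[Tuple[float, int, int]]:
    """Best window of exactly ``l_core`` residues.

    Returns ``(score, start, end)`` with 1-based inclusive coordinates,
    taking the leftmost window on ties, or ``None`` when the sequence is
    shorter than ``l_core`` (unscorable, not an error).
    """
    n = len(sequence)
    if n < l_core:
        return None
    vals = llr_table.per_residue(sequence)
    cs = np.concatenate(([0.0], np.cumsum(vals)))
    windows = cs[l_core:] - cs[:-l_core]
    best = int(np.argmax(windows))  # argmax returns the first maximum
    return float(windows[best]), best + 1, best + l_core


def domain_boundaries(
    sequence: str,
    llr_table: LLRTable,
    core_window: Tuple[int, int],
) -> Tuple[int, int]:
    """Maximal-scoring contiguous segment containing the core window.

    The left and right extensions are independent: each side is extended
    to the boundary maximising the cumulative extension score, and only
    if that maximum is strictly positive (ties resolved toward the
    shorter extension).  Coordinates are 1-based inclusive.
    """
    start, end = core_window
    if not (1 <= start <= end <= len(sequence)):
        raise ValueError(f"core window {core_window} outside sequence")
    vals = llr_table.per_residue(sequence)
    s0, e0 = start - 1, end - 1

    best_left, best_gain, gain = s0, 0.0, 0.0
    for i in range(s0 - 1, -1, -1):
        gain += vals[i]
        if gain > best_gain:
            best_gain, best_left = gain, i

    best_right, best_gain, gain = e0, 0.0, 0.0
    for j in range(e0 + 1, len(vals)):
        gain += vals[j]
        if gain > best_gain:
            best_gain, best_right = gain, j

    return best_left + 1, best_right + 1


def call_prlds(
    proteome: Iterable[ProteinRecord],
    llr_table: LLRTable,
    l_core: int = 60,
    threshold: float = 25.0,
) -> List[PrLDHit]:
    """Scan a proteome and return hits with core score >= ``threshold``.

    Output is sorted by descending core score, ties by protein id.
    Proteins shorter than ``l_core`` are unscorable and silently absent.
    """
    hits: List[PrLDHit] = []
    seen = set()
    for record in proteome:
        if record.id in seen:
            raise ValueError(f"duplicate protein id {record.id!r}")
        seen.add(record.id)
        scored = core_score(record.sequence, llr_table, l_core=l_core)
        if scored is None:
            continue
        score, start, end = scored
        if score >= threshold:
            dstart, dend = domain_boundaries(record.sequence, llr_table, (start, end))
            hits.append(PrLDHit(
                protein_id=record.id,
                core_start=start,
                core_end=end,
                core_score=score,
                domain_start=dstart,
                domain_end=dend,
                corescore_threshold=float(threshold),
            ))
    hits.sort(key=lambda h: (-h.core_score, h.protein_id))
    return hits


# ---------------------------------------------------------------------------
# I/O


def read_proteome(path) -> List[ProteinRecord]:
    """Read a multi-FASTA amino-acid file (id = first header token)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(
            id=rec.id,
            description=rec.description,
            sequence=str(rec.seq).upper(),
        ))
    return records


def write_fasta(records: Sequence[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def write_hits_tsv(hits: Sequence[PrLDHit], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(HITS_COLUMNS)
        for h in hits:
            writer.writerow([
                h.protein_id, h.core_start, h.core_end,
                f"{h.core_score:.6f}", h.domain_start, h.domain_end,
            ])


def read_hits_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"protein_id": str})
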