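"""Amino-acid composition tables used by the PrLD scanner.

Three packaged tables:

``PRION_DOMAIN_FREQS``
    Foreground composition of canonical Q/N-rich yeast prion-forming
    domains (Sup35/Ure2-like): glutamine + asparagine together make up
    ~46% of residues, with serine, glycine and tyrosine also enriched
    and hydrophobic/charged residues depleted.

``ARABIDOPSIS_PROTEOME_FREQS``
    Whole-proteome composition of *Arabidopsis thaliana*, the default
    species background for plant proteome scans.

``GENERIC_PROTEOME_FREQS``
    A broad cross-kingdom proteome composition used as the default
    background that the species background is blended against.

All tables are normalised to sum to exactly 1.0 at import time, so
small rounding in the literal values never propagates.
"""

from __future__ import annotations

from typing import Dict, Mapping

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Residues that may appear in protein sequences but carry no
#: compositional information for scoring (ambiguity/rare codes and stops).
AMBIGUITY_CODES = frozenset("BZJXUO*")


def _normalize(freqs: Mapping[str, float]) -> Dict[str, float]:
    missing = [a for a in CANONICAL_AA if a not in freqs]
    if missing:
        raise ValueError(f"frequency table missing residues: {missing}")
    total = sum(freqs[a] for a in CANONICAL_AA)
    if total <= 0:
        raise ValueError("frequency table sums to zero")
    return {a: freqs[a] / total for a in CANONICAL_AA}


PRION_DOMAIN_FREQS: Dict[str, float] = _normalize({
    "A": 0.040, "C": 0.002, "D": 0.020, "E": 0.020, "F": 0.020,
    "G": 0.070, "H": 0.010, "I": 0.020, "K": 0.028, "L": 0.030,
    "M": 0.022, "N": 0.220, "P": 0.048, "Q": 0.240, "R": 0.018,
    "S": 0.095, "T": 0.038, "V": 0.022, "W": 0.002, "Y": 0.035,
})

ARABIDOPSIS_PROTEOME_FREQS: Dict[str, float] = _normalize({
    "A": 0.063, "C": 0.018, "D": 0.054, "E": 0.067, "F": 0.043,
    "G": 0.064, "H": 0.023, "I": 0.053, "K": 0.064, "L": 0.095,
    "M": 0.024, "N": 0.043, "P": 0.047, "Q": 0.034, "R": 0.054,
    "S": 0.090, "T": 0.051, "V": 0.067, "W": 0.012, "Y": 0.029,
})

GENERIC_PROTEOME_FREQS: Dict[str, float] = _normalize({
    "A": 0.0826, "C": 0.0137, "D": 0.0546, "E": 0.0674, "F": 0.0386,
    "G": 0.0708, "H": 0.0227, "I": 0.0593, "K": 0.0582, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0472, "Q": 0.0393, "R": 0.0553,
    "S": 0.0660, "T": 0.0535, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
})


def read_freqs(path) -> Dict[str, float]:
    """Read a two-column (residue, frequency) TSV into a normalised table."""
    freqs: Dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            aa, value = line.split("\t")[:2]
            freqs[aa.strip().upper()] = float(value)
    return _normalize(freqs)


def write_freqs(freqs: Mapping[str, float], path) -> None:
    with open(path, "w") as fh:
        for aa in CANONICAL_AA:
            fh.write(f"{aa}\t{freqs[aa]:.8f}\n")
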