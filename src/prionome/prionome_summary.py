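"""Prionome summary tables: density, functional categories, Ts/RTR share.

A *prionome* is the full complement of prion-like proteins (PrLPs) in a
genome.  This module turns PrLD scan hits plus a per-protein annotation
table into per-species summaries: PrLP density (PrLP count / proteome
size), counts and percentage shares over ten keyword-based functional
categories, and the transposon/retrotransposon (Ts/RTR) share.

Counting is supported at both the protein and the gene level; gene-level
summaries collapse isoforms by gene id keeping the highest-scoring one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import pandas as pd

logger = logging.getLogger(__name__)

TS_RTR_CATEGORY = "Ts/RTR"
UNCLASSIFIED = "unclassified"

#: Ordered (keywords, category) priority list; the first rule with any
#: case-insensitive keyword match wins.  Illustrative defaults covering
#: the ten categories used for plant prionomes; override via config.
DEFAULT_CATEGORY_RULES: List[Tuple[Tuple[str, ...], str]] = [
    (("transposon", "retrotransposon", "transposase", "gag-pol"), TS_RTR_CATEGORY),
    (("rna-binding", "rna binding", "rna recognition", "helicase",
      "exonuclease", "rrm"), "RNA binding/regulation"),
    (("transcription factor", "dna-binding", "dna binding", "zinc finger",
      "replication", "bzip", "myb"), "DNA binding/replication/TF"),
    (("transport", "transporter", "clathrin", "vesicle"), "Transport"),
    (("flowering", "floral", "development", "leunig", "fca"),
     "Flowering/development"),
    (("kinase", "signaling", "signalling", "receptor", "g-protein"),
     "Signaling"),
    (("chromatin", "histone", "methyltransferase", "swirm"),
     "Chromatin/epigenetics"),
    (("stress", "heat shock", "chaperone", "hsp"), "Stress response"),
    (("metabolism", "metabolic", "synthase", "biosynthesis"), "Metabolism"),
    (("ubiquitin", "proteasome", "protease", "autophagy"),
     "Protein homeostasis"),
]


@dataclass(frozen=True)
class PrionomeEntry:
    protein_id: str
    gene_id: str
    category: str
    is_ts_rtr: bool
    species: str

    def __post_init__(self):
        if self.is_ts_rtr != (self.category == TS_RTR_CATEGORY):
            raise ValueError(
                f"{self.protein_id}: is_ts_rtr inconsistent with category "
                f"{self.category!r}"
            )


@dataclass(frozen=True)
class PrionomeSummary:
    species: str
    n_prlps: int
    proteome_size: int
    density: float
    category_counts: Dict[str, int] = field(default_factory=dict)
    category_percent: Dict[str, float] = field(default_factory=dict)

    @property
    def ts_rtr_share(self) -> float:
        """Exact Ts/RTR percentage (0 when the prionome is empty)."""
        return self.category_percent.get(TS_RTR_CATEGORY, 0.0)

    def percent_display(self) -> Dict[str, int]:
        """Nearest-integer percentages for table display."""
        return {c: round(p) for c, p in self.category_percent.items()}


def compute_density(n_prlps: int, proteome_size: int) -> float:
    """PrLP density: PrLP count over total protein count."""
    if proteome_size < 1:
        raise ValueError(f"proteome_size must be >= 1, got {proteome_size}")
    if not 0 <= n_prlps <= proteome_size:
        raise ValueError(
            f"n_prlps ({n_prlps}) must lie in [0, proteome_size={proteome_size}]"
        )
    return n_prlps / proteome_size


def categorize(
    annotation_text: str,
    category_rules: Sequence[Tuple[Sequence[str], str]] = DEFAULT_CATEGORY_RULES,
) -> str:
    """Assign the first (highest-priority) category whose keywords match."""
    if not category_rules:
        logger.warning("empty category rules: everything is unclassified")
        return UNCLASSIFIED
    text = annotation_text.lower()
    for keywords, category in category_rules:
        if any(kw.lower() in text for kw in keywords):
            return category
    return UNCLASSIFIED


def summarize(
    entries: Iterable[PrionomeEntry],
    proteome_size: int,
) -> PrionomeSummary:
    """Per-category counts/percentages and density for one species."""
    entries = list(entries)
    species = {e.species for e in entries}
    if len(species) > 1:
        raise ValueError(f"entries span multiple species: {sorted(species)}")
    name = species.pop() if species else ""
    n = len(entries)
    counts: Dict[str, int] = {}
    for e in entries:
        counts[e.category] = counts.get(e.category, 0) + 1
    percent = {c: 100.0 * k / n for c, k in counts.items()} if n else {}
    return PrionomeSummary(
        species=name,
        n_prlps=n,
        proteome_size=proteome_size,
        density=compute_density(n, proteome_size),
        category_counts=counts,
        category_percent=percent,
    )


def collapse_to_genes(hits: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Collapse protein-level hits to gene level, keeping the top isoform.

    ``hits`` needs protein_id and core_score columns; ``annotation``
    maps protein_id -> gene_id (+ description).  Within each gene the
    isoform with the highest core score is retained (ties by protein id).
    """
    merged = hits.merge(annotation, on="protein_id", how="left", validate="m:1")
    missing = merged["gene_id"].isna()
    if missing.any():
        names = merged.loc[missing, "protein_id"].tolist()
        raise ValueError(f"proteins missing from annotation: {names}")
    merged = merged.sort_values(
        ["gene_id", "core_score", "protein_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return merged.groupby("gene_id", sort=True).head(1).reset_index(drop=True)


def build_entries(
    hits: pd.DataFrame,
    annotation: pd.DataFrame,
    species: str,
    category_rules: Sequence[Tuple[Sequence[str], str]] = DEFAULT_CATEGORY_RULES,
    gene_level: bool = True,
) -> List[PrionomeEntry]:
    """Annotate scan hits into categorised prionome entries."""
    table = collapse_to_genes(hits, annotation) if gene_level else hits.merge(
        annotation, on="protein_id", how="left", validate="m:1")
    entries = []
    for row in table.itertuples(index=False):
        category = categorize(str(getattr(row, "description", "")), category_rules)
        entries.append(PrionomeEntry(
            protein_id=row.protein_id,
            gene_id=str(row.gene_id),
            category=category,
            is_ts_rtr=category == TS_RTR_CATEGORY,
            species=species,
        ))
    return entries


def summary_to_frame(summary: PrionomeSummary) -> pd.DataFrame:
    """Long-form per-category table (count, exact and display percent)."""
    rows = [
        {
            "species": summary.species,
            "category": c,
            "count": summary.category_counts[c],
            "percent": summary.category_percent[c],
            "percent_display": round(summary.category_percent[c]),
        }
        for c in sorted(summary.category_counts)
    ]
    return pd.DataFrame(
        rows, columns=["species", "category", "count", "percent", "percent_display"]
    )


def read_annotation_tsv(path) -> pd.DataFrame:
    """Annotation TSV with protein_id, gene_id, description columns."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"protein_id", "gene_id", "description"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    return df
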