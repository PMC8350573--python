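"""Promoter extraction and cis-binding-evidence filtering.

Promoters are strand-aware windows around the annotated transcription
start site (TSS): 1,500 bp upstream plus 200 bp downstream (TSS base
included in the downstream segment), 1,700 bp in total for genes fully
interior to their contig.  Minus-strand promoters are returned
reverse-complemented so that all sequences read 5'->3' relative to the
gene.  Binding evidence — either imported from a regulome database
table or produced by scanning promoters with a position weight matrix —
is used to retain only TF->target regulatory edges supported by a
promoter binding site.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

import networkx as nx

__all__ = [
    "PromoterRegion",
    "BindingEvidence",
    "PWM",
    "extract_promoters",
    "scan_binding_sites",
    "filter_by_binding",
    "promoters_to_fasta",
    "read_promoters_fasta",
    "read_evidence_tsv",
    "write_evidence_tsv",
    "read_pwm_counts",
]

DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class PromoterRegion:
    """Promoter-oriented sequence with its genomic interval.

    ``start``/``end`` are a 0-based half-open genomic interval;
    ``sequence`` is reverse-complemented for minus-strand genes.
    ``truncated`` marks promoters clipped at a contig edge.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    sequence: str
    truncated: bool

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(f"{self.gene_id}: sequence/interval length mismatch")


@dataclass(frozen=True)
class BindingEvidence:
    """One TF -> target binding claim (database import or PWM scan)."""

    tf_id: str
    target_gene_id: str
    source: str = "database"
    offset: Optional[int] = None
    score: Optional[float] = None
    strand: Optional[str] = None


class PWM:
    """Log-odds position weight matrix over A/C/G/T."""

    ALPHABET = "ACGT"

    def __init__(self, log_odds: np.ndarray, name: str = "pwm"):
        log_odds = np.asarray(log_odds, dtype=float)
        if log_odds.ndim != 2 or log_odds.shape[0] != 4:
            raise ValueError("log-odds matrix must be 4 x L")
        self.log_odds = log_odds
        self.name = name

    @classmethod
    def from_counts(
        cls,
        counts,
        name: str = "pwm",
        pseudocount: float = 0.25,
        background: Optional[Sequence[float]] = None,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("count matrix must be 4 x L")
        bg = np.full(4, 0.25) if background is None else np.asarray(background)
        probs = counts + pseudocount
        probs = probs / probs.sum(axis=0, keepdims=True)
        return cls(np.log2(probs / bg[:, None]), name=name)

    def __len__(self) -> int:
        return self.log_odds.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(self.ALPHABET[i] for i in np.argmax(self.log_odds, axis=0))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    def score(self, window: str) -> Optional[float]:
        """Log-odds score of one window; None if it has a non-ACGT base."""
        if len(window) != len(self):
            raise ValueError("window length does not match PWM length")
        total = 0.0
        for j, base in enumerate(window.upper()):
            i = self.ALPHABET.find(base)
            if i < 0:
                return None
            total += self.log_odds[i, j]
        return total


# ---------------------------------------------------------------------------
# Promoter extraction


def _representative_tss(db: gffutils.FeatureDB, gene) -> Optional[int]:
    """1-based TSS of the longest mRNA; fallback to the gene feature."""
    mrnas = list(db.children(gene, featuretype="mRNA"))
    feature = gene
    if mrnas:
        mrnas.sort(key=lambda m: (-(m.end - m.start + 1), m.id or ""))
        feature = mrnas[0]
    if feature.start is None or feature.end is None:
        return None
    return feature.start if gene.strand == "+" else feature.end


def extract_promoters(
    gff3_path,
    genome_path,
    upstream: int = 1500,
    downstream: int = 200,
) -> List[PromoterRegion]:
    """Strand-aware promoter windows for every annotated gene.

    The window spans ``upstream`` bases 5' of the TSS plus ``downstream``
    bases starting at the TSS itself, clipped (and flagged truncated) at
    contig edges.  Genes on contigs absent from the FASTA are an error;
    genes without usable coordinates or strand are skipped.
    """
    genome = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(genome_path), "fasta")
    }
    db = gffutils.create_db(
        str(gff3_path), ":memory:",
        merge_strategy="create_unique", keep_order=True,
    )
    promoters: List[PromoterRegion] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        if gene.strand not in {"+", "-"}:
            continue
        tss1 = _representative_tss(db, gene)
        if tss1 is None:
            continue
        if gene.seqid not in genome:
            raise ValueError(f"chromosome {gene.seqid!r} absent from genome FASTA")
        contig = genome[gene.seqid]
        tss0 = tss1 - 1
        if gene.strand == "+":
            start, end = tss0 - upstream, tss0 + downstream
        else:
            start, end = tss0 - (downstream - 1), tss0 + upstream + 1
        clipped_start, clipped_end = max(start, 0), min(end, len(contig))
        seq = contig[clipped_start:clipped_end]
        if gene.strand == "-":
            seq = seq.translate(DNA_COMPLEMENT)[::-1]
        promoters.append(PromoterRegion(
            gene_id=gene.id,
            chrom=gene.seqid,
            strand=gene.strand,
            start=clipped_start,
            end=clipped_end,
            sequence=seq,
            truncated=(clipped_start != start or clipped_end != end),
        ))
    return promoters


def promoters_to_fasta(promoters: Sequence[PromoterRegion], path) -> None:
    with open(path, "w") as fh:
        for p in promoters:
            fh.write(
                f">{p.gene_id} {p.chrom}:{p.start}-{p.end}({p.strand}) "
                f"truncated={'1' if p.truncated else '0'}\n"
            )
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i:i + 60] + "\n")


def read_promoters_fasta(path) -> List[PromoterRegion]:
    promoters = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.description.split()
        locus, flags = fields[1], fields[2]
        chrom, rest = locus.rsplit(":", 1)
        span, strand = rest[:-3], rest[-2]
        start, end = (int(x) for x in span.split("-"))
        promoters.append(PromoterRegion(
            gene_id=rec.id,
            chrom=chrom,
            strand=strand,
            start=start,
            end=end,
            sequence=str(rec.seq).upper(),
            truncated=flags.endswith("1"),
        ))
    return promoters


# ---------------------------------------------------------------------------
# Binding-site scanning and edge filtering


def scan_binding_sites(
    promoter: PromoterRegion,
    pwm: PWM,
    score_threshold: float,
    tf_id: str = "pwm",
) -> List[BindingEvidence]:
    """All PWM hits in a promoter, both orientations.

    Offsets are positions within the promoter-oriented sequence (0-based
    window start).  Windows containing non-ACGT bases are skipped.
    """
    seq = promoter.sequence.upper()
    L = len(pwm)
    hits: List[BindingEvidence] = []
    for offset in range(0, len(seq) - L + 1):
        window = seq[offset:offset + L]
        fwd = pwm.score(window)
        if fwd is not None and fwd >= score_threshold:
            hits.append(BindingEvidence(
                tf_id=tf_id, target_gene_id=promoter.gene_id, source="scan",
                offset=offset, score=fwd, strand="+",
            ))
        rev = pwm.score(str(Seq(window).reverse_complement()))
        if rev is not None and rev >= score_threshold:
            hits.append(BindingEvidence(
                tf_id=tf_id, target_gene_id=promoter.gene_id, source="scan",
                offset=offset, score=rev, strand="-",
            ))
    return hits


def filter_by_binding(
    network: nx.Graph,
    evidence: Iterable[Tuple[str, str]],
) -> nx.Graph:
    """Drop TF-source edges lacking promoter binding evidence.

    ``evidence`` is a set of (tf_id, target_gene_id) pairs.  An edge
    whose endpoint carries the TF role is kept only when the pair (in
    either orientation if both endpoints are TFs) has evidence; kept TF
    edges are flagged ``evidence_filtered``.  Edges without a TF
    endpoint pass unchanged.  The input graph is not modified.
    """
    pairs: Set[Tuple[str, str]] = set(evidence)
    out = network.copy()
    for u, v, data in list(network.edges(data=True)):
        u_tf = "TF" in network.nodes[u].get("roles", ())
        v_tf = "TF" in network.nodes[v].get("roles", ())
        if not (u_tf or v_tf):
            continue
        supported = (u_tf and (u, v) in pairs) or (v_tf and (v, u) in pairs)
        if supported:
            out.edges[u, v]["evidence_filtered"] = True
        else:
            out.remove_edge(u, v)
    return out


# ---------------------------------------------------------------------------
# I/O


def read_evidence_tsv(path) -> List[BindingEvidence]:
    evidence = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            offset = row.get("offset")
            score = row.get("score")
            evidence.append(BindingEvidence(
                tf_id=row["tf_id"],
                target_gene_id=row["target_gene_id"],
                source=row.get("source", "database"),
                offset=int(offset) if offset not in (None, "") else None,
                score=float(score) if score not in (None, "") else None,
                strand=row.get("strand") or None,
            ))
    return evidence


def write_evidence_tsv(evidence: Sequence[BindingEvidence], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["tf_id", "target_gene_id", "source", "offset",
                         "score", "strand"])
        for e in evidence:
            writer.writerow([
                e.tf_id, e.target_gene_id, e.source,
                "" if e.offset is None else e.offset,
                "" if e.score is None else f"{e.score:.4f}",
                e.strand or "",
            ])


def evidence_pairs(evidence: Iterable[BindingEvidence]) -> Set[Tuple[str, str]]:
    return {(e.tf_id, e.target_gene_id) for e in evidence}


def read_pwm_counts(path) -> PWM:
    """Read a plain-count PWM file.

    Format: optional ``>name`` header, then four lines ``A c1 c2 ...``
    (any A/C/G/T order).  Counts are converted to log-odds against a
    uniform background with pseudocount 0.25.
    """
    name = "pwm"
    rows: Dict[str, List[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].strip() or name
                continue
            parts = line.replace(":", " ").split()
            base = parts[0].upper()
            if base not in "ACGT":
                raise ValueError(f"unexpected PWM row label {parts[0]!r}")
            rows[base] = [float(x) for x in parts[1:]]
    missing = [b for b in "ACGT" if b not in rows]
    if missing:
        raise ValueError(f"PWM file missing rows for {missing}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise ValueError("PWM rows have unequal lengths")
    counts = np.array([rows[b] for b in "ACGT"])
    return PWM.from_counts(counts, name=name)


def write_pwm_counts(counts: np.ndarray, path, name: str = "pwm") -> None:
    counts = np.asarray(counts)
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for base, row in zip("ACGT", counts):
            fh.write(base + " " + " ".join(str(int(x)) for x in row) + "\n")
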