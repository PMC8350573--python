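"""Deterministic generators emulating the pipeline's input data.

Every generator is a pure function of its configuration and a seed, and
returns a ground-truth table alongside the generated data, so that
planted features (PrLD segments, co-expressed modules, promoter motifs,
role assignments) can be checked against what the pipeline recovers.

The diurnal expression model is a phase-shifted sinusoid over the
day–night cycle plus Gaussian noise: genes within a module share a
phase, and the phase offset between modules sets the sign and magnitude
of cross-module correlation (``r_cross = cos(dphase) * r_intra`` in the
noiseless-amplitude sense).  This reproduces the correlation geometry
of real circadian series without modelling read counts, dose–response
curves, or transcript-length effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .composition import (
    ARABIDOPSIS_PROTEOME_FREQS,
    CANONICAL_AA,
    PRION_DOMAIN_FREQS,
)
from .prld_scan import ProteinRecord

__all__ = [
    "ModuleSpec",
    "two_antagonistic_modules",
    "gen_proteome",
    "gen_diurnal_matrix",
    "gen_genome_with_promoters",
    "gen_role_tables",
    "validate_proteome_truth",
    "validate_matrix_truth",
    "validate_genome_truth",
]

PLANTED_DOMAIN_LENGTH = 80


@dataclass(frozen=True)
class ModuleSpec:
    """A co-expression module: size, phase (radians) and amplitude."""

    name: str
    size: int
    phase: float
    amplitude: float = 3.0


def two_antagonistic_modules(
    size_a: int = 15,
    size_b: int = 15,
    intra_r: float = 0.95,
    cross_r: float = -0.9,
    amplitude: float = 3.0,
) -> Tuple[List[ModuleSpec], float]:
    """Module pair with target intra- and (negative) cross correlations.

    For sinusoidal profiles with independent Gaussian noise the expected
    intra-module correlation is ``s / (s + sigma^2)`` with signal
    variance ``s = amplitude^2 / 2``, and the cross-module correlation
    is that value scaled by ``cos(dphase)``.  Returns the two module
    specs plus the noise standard deviation achieving the targets.
    """
    if not 0 < intra_r < 1:
        raise ValueError("intra_r must be in (0, 1)")
    if abs(cross_r) > intra_r:
        raise ValueError(
            "unattainable correlation structure: |cross_r| cannot exceed intra_r"
        )
    signal_var = amplitude ** 2 / 2.0
    noise_sd = math.sqrt(signal_var * (1.0 - intra_r) / intra_r)
    dphase = math.acos(cross_r / intra_r)
    modules = [
        ModuleSpec("module_a", size_a, phase=0.0, amplitude=amplitude),
        ModuleSpec("module_b", size_b, phase=dphase, amplitude=amplitude),
    ]
    return modules, noise_sd


# ---------------------------------------------------------------------------
# Proteomes


def _freq_arrays(freqs: Mapping[str, float]) -> Tuple[List[str], np.ndarray]:
    letters = list(CANONICAL_AA)
    probs = np.array([freqs[a] for a in letters])
    return letters, probs / probs.sum()


def gen_proteome(
    n_proteins: int,
    length_range: Tuple[int, int] = (120, 400),
    planted_fraction: float = 0.1,
    seed: int = 0,
    foreground: Optional[Mapping[str, float]] = None,
    background: Optional[Mapping[str, float]] = None,
    planted_length: int = PLANTED_DOMAIN_LENGTH,
    id_prefix: str = "P",
) -> Tuple[List[ProteinRecord], pd.DataFrame]:
    """Proteome with Q/N-rich segments planted in a fraction of proteins.

    Background residues are drawn from ``background`` (default: the
    Arabidopsis proteome table); planted proteins carry a
    ``planted_length``-residue segment drawn from ``foreground``
    (default: the prion-domain table) at a random interior offset.  The
    truth table lists, per protein, whether a segment was planted and
    its 1-based inclusive coordinates.
    """
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValueError("planted_fraction must be in [0, 1]")
    lo, hi = length_range
    if planted_fraction > 0 and lo < planted_length:
        raise ValueError(
            f"length_range lower bound {lo} is below the planted segment "
            f"length {planted_length}"
        )
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid length_range {length_range}")
    rng = np.random.default_rng(seed)
    bg_letters, bg_probs = _freq_arrays(background or ARABIDOPSIS_PROTEOME_FREQS)
    fg_letters, fg_probs = _freq_arrays(foreground or PRION_DOMAIN_FREQS)
    n_planted = int(round(n_proteins * planted_fraction))
    planted_idx = set(
        rng.choice(n_proteins, size=n_planted, replace=False).tolist()
    ) if n_planted else set()

    width = max(4, len(str(n_proteins)))
    records: List[ProteinRecord] = []
    truth_rows = []
    for i in range(n_proteins):
        pid = f"{id_prefix}{i + 1:0{width}d}"
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(bg_letters, size=length, p=bg_probs))
        row = {"protein_id": pid, "planted": False,
               "domain_start": 0, "domain_end": 0}
        if i in planted_idx:
            offset = int(rng.integers(0, length - planted_length + 1))
            segment = "".join(
                rng.choice(fg_letters, size=planted_length, p=fg_probs)
            )
            seq = seq[:offset] + segment + seq[offset + planted_length:]
            row.update(planted=True, domain_start=offset + 1,
                       domain_end=offset + planted_length)
        records.append(ProteinRecord(id=pid, description=pid, sequence=seq))
        truth_rows.append(row)
    truth = pd.DataFrame(
        truth_rows, columns=["protein_id", "planted", "domain_start", "domain_end"]
    )
    return records, truth


def validate_proteome_truth(
    records: Sequence[ProteinRecord], truth: pd.DataFrame
) -> None:
    by_id = {r.id: r for r in records}
    if set(truth["protein_id"]) != set(by_id):
        raise ValueError("truth table and proteome list different proteins")
    for row in truth.itertuples(index=False):
        if row.planted:
            rec = by_id[row.protein_id]
            if not 1 <= row.domain_start <= row.domain_end <= len(rec.sequence):
                raise ValueError(
                    f"{row.protein_id}: planted interval outside sequence"
                )


# ---------------------------------------------------------------------------
# Diurnal expression matrices


def gen_diurnal_matrix(
    n_genes: int,
    n_samples: int = 48,
    modules: Sequence[ModuleSpec] = (),
    noise_sd: float = 0.5,
    seed: int = 0,
    baseline: float = 10.0,
    period_h: float = 24.0,
    sample_interval_h: float = 0.5,
    noise_gene_sd: float = 1.0,
    gene_ids: Optional[Sequence[str]] = None,
    membership: Optional[Mapping[str, Sequence[str]]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Diurnal genes x samples matrix with planted co-expression modules.

    Module genes follow ``baseline + A * sin(2 pi t / period + phase)``
    plus N(0, noise_sd) noise; remaining genes are independent
    N(baseline, noise_gene_sd) profiles.  By default the first genes in
    order are assigned to the modules; pass ``membership`` to pin
    specific gene ids to named modules.
    """
    total_module = sum(m.size for m in modules)
    if total_module > n_genes:
        raise ValueError("modules require more genes than n_genes")
    if gene_ids is None:
        width = max(4, len(str(n_genes)))
        gene_ids = [f"g{i + 1:0{width}d}" for i in range(n_genes)]
    gene_ids = list(gene_ids)
    if len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")

    assignment: Dict[str, ModuleSpec] = {}
    if membership is None:
        cursor = 0
        for spec in modules:
            for g in gene_ids[cursor:cursor + spec.size]:
                assignment[g] = spec
            cursor += spec.size
    else:
        by_name = {m.name: m for m in modules}
        for name, members in membership.items():
            spec = by_name[name]
            members = list(members)
            if len(members) != spec.size:
                raise ValueError(
                    f"module {name}: {len(members)} members != size {spec.size}"
                )
            for g in members:
                if g not in gene_ids:
                    raise ValueError(f"module gene {g} not in gene_ids")
                if g in assignment:
                    raise ValueError(f"gene {g} assigned to two modules")
                assignment[g] = spec

    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) * sample_interval_h
    sample_ids = [f"T{h:04.1f}h".replace(".", "_") for h in t]
    values = np.empty((n_genes, n_samples))
    truth_rows = []
    for i, g in enumerate(gene_ids):
        spec = assignment.get(g)
        if spec is not None:
            signal = spec.amplitude * np.sin(
                2.0 * np.pi * t / period_h + spec.phase
            )
            values[i] = baseline + signal + rng.normal(0.0, noise_sd, n_samples)
            truth_rows.append({"gene_id": g, "module": spec.name,
                               "phase": spec.phase})
        else:
            values[i] = baseline + rng.normal(0.0, noise_gene_sd, n_samples)
            truth_rows.append({"gene_id": g, "module": "", "phase": float("nan")})
    matrix = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    matrix.index.name = "gene_id"
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "module", "phase"])
    return matrix, truth


def validate_matrix_truth(matrix: pd.DataFrame, truth: pd.DataFrame) -> None:
    if set(truth["gene_id"]) != set(matrix.index):
        raise ValueError("expression truth table and matrix disagree on genes")


# ---------------------------------------------------------------------------
# Genomes with planted promoter motifs


def gen_genome_with_promoters(
    n_genes: int,
    motif: str,
    planted_target_ids: Iterable[str],
    seed: int = 0,
    upstream: int = 1500,
    downstream: int = 200,
    gene_length: int = 1000,
    spacing: int = 4200,
    margin: int = 2000,
    chrom: str = "chr1",
    gene_ids: Optional[Sequence[str]] = None,
) -> Tuple[Dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Random genome + gene annotation with motifs planted in promoters.

    Genes alternate strands with >= 2 kb spacing so every promoter
    window (default 1,500 bp upstream + 200 bp downstream of the TSS)
    is fully interior.  For each planted target the motif consensus is
    inserted at a random offset of its promoter-oriented window (strand
    respected, so minus-strand promoters receive the reverse
    complement genomically).  Returns the genome, a gene table (1-based
    inclusive coordinates) and a truth table of planted offsets.
    """
    motif = motif.upper()
    window = upstream + downstream
    if len(motif) > window:
        raise ValueError("motif longer than the promoter window")
    # Alternating strands make promoter windows of neighboring genes
    # extend toward each other; keep them genomically disjoint so a
    # planted motif is attributable to exactly one promoter.
    if spacing < gene_length + 2 * upstream + 2:
        raise ValueError(
            "spacing too small: neighboring promoter windows would overlap"
        )
    if margin < max(upstream, downstream) + 100:
        raise ValueError("margin too small for the promoter window")
    if gene_ids is None:
        width = max(4, len(str(n_genes)))
        gene_ids = [f"g{i + 1:0{width}d}" for i in range(n_genes)]
    gene_ids = list(gene_ids)
    planted = set(planted_target_ids)
    unknown = planted - set(gene_ids)
    if unknown:
        raise ValueError(f"planted targets not among gene ids: {sorted(unknown)}")

    genome_length = margin + n_genes * spacing + margin
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    sequence = rng.choice(bases, size=genome_length)

    gene_rows = []
    truth_rows = []
    rc = str.maketrans("ACGT", "TGCA")
    for i, gid in enumerate(gene_ids):
        start1 = margin + i * spacing + 1
        end1 = start1 + gene_length - 1
        strand = "+" if i % 2 == 0 else "-"
        tss0 = (start1 - 1) if strand == "+" else (end1 - 1)
        if strand == "+":
            win_start, win_end = tss0 - upstream, tss0 + downstream
        else:
            win_start, win_end = tss0 - (downstream - 1), tss0 + upstream + 1
        offset = -1
        if gid in planted:
            offset = int(rng.integers(0, window - len(motif) + 1))
            if strand == "+":
                g0 = win_start + offset
                sequence[g0:g0 + len(motif)] = list(motif)
            else:
                g_end = win_end - offset
                g0 = g_end - len(motif)
                sequence[g0:g0 + len(motif)] = list(
                    motif.translate(rc)[::-1]
                )
        gene_rows.append({
            "gene_id": gid, "chrom": chrom, "start": start1, "end": end1,
            "strand": strand,
        })
        truth_rows.append({
            "gene_id": gid, "strand": strand, "tss": tss0 + 1,
            "planted": gid in planted, "motif_offset": offset,
        })
    genome = {chrom: "".join(sequence)}
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    )
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "strand", "tss", "planted", "motif_offset"]
    )
    return genome, genes, truth


def validate_genome_truth(
    genome: Mapping[str, str], genes: pd.DataFrame, truth: pd.DataFrame
) -> None:
    if set(genes["gene_id"]) != set(truth["gene_id"]):
        raise ValueError("genome truth table and gene table disagree")
    for row in genes.itertuples(index=False):
        if row.chrom not in genome:
            raise ValueError(f"{row.gene_id}: chrom {row.chrom} not in genome")
        if not 1 <= row.start <= row.end <= len(genome[row.chrom]):
            raise ValueError(f"{row.gene_id}: coordinates outside contig")


def write_genome_fasta(genome: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gff3(genes: pd.DataFrame, path, source: str = "prionome-sim") -> None:
    """Minimal gene + mRNA GFF3 for the generated annotation."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fields = [row.chrom, source, "gene", str(row.start), str(row.end),
                      ".", row.strand, ".", f"ID={row.gene_id}"]
            fh.write("\t".join(fields) + "\n")
            mrna = [row.chrom, source, "mRNA", str(row.start), str(row.end),
                    ".", row.strand, ".",
                    f"ID={row.gene_id}.1;Parent={row.gene_id}"]
            fh.write("\t".join(mrna) + "\n")


# ---------------------------------------------------------------------------
# Role tables


def gen_role_tables(
    gene_ids: Sequence[str],
    fractions: Mapping[str, float | int],
    seed: int = 0,
    disjoint: bool = False,
) -> Dict[str, List[str]]:
    """Random role assignments (TF, Ts/RTR, stress, memory, ...).

    ``fractions`` maps role name to either a fraction of the pool or an
    absolute count.  With ``disjoint`` each role draws from the genes
    not yet assigned; otherwise roles are drawn independently and may
    overlap.  Output lists are sorted for determinism.
    """
    gene_ids = list(gene_ids)
    rng = np.random.default_rng(seed)
    tables: Dict[str, List[str]] = {}
    pool = list(gene_ids)
    for role in fractions:
        want = fractions[role]
        if isinstance(want, (int, np.integer)):
            count = int(want)
        else:
            count = int(round(float(want) * len(gene_ids)))
        source = pool if disjoint else gene_ids
        if count > len(source):
            raise ValueError(f"role {role}: requested {count} of {len(source)} genes")
        chosen = sorted(
            rng.choice(len(source), size=count, replace=False).tolist()
        )
        members = [source[i] for i in chosen]
        tables[role] = sorted(members)
        if disjoint:
            pool = [g for g in pool if g not in set(members)]
    return tables


def gen_module_graph(
    n_modules: int = 5,
    module_size: int = 8,
    intra_p: float = 0.9,
    inter_p: float = 0.05,
    n_noise: int = 40,
    seed: int = 0,
) -> Tuple["object", List[Set[str]]]:
    """Random graph with planted dense modules for cluster recovery tests.

    Within-module edges appear with probability ``intra_p``; every other
    pair (module–module, module–noise, noise–noise) with ``inter_p``.
    Returns the graph and the planted module member sets.
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    modules: List[Set[str]] = []
    nodes: List[str] = []
    owner: Dict[str, int] = {}
    for m in range(n_modules):
        members = {f"m{m}_{i:02d}" for i in range(module_size)}
        modules.append(members)
        for v in sorted(members):
            owner[v] = m
            nodes.append(v)
    for i in range(n_noise):
        v = f"noise_{i:03d}"
        owner[v] = -1 - i
        nodes.append(v)
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            p = intra_p if owner[u] == owner[v] and owner[u] >= 0 else inter_p
            if rng.random() < p:
                graph.add_edge(u, v)
    return graph, modules


def write_role_table(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")
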