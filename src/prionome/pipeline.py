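"""End-to-end pipeline: scan -> summarize -> correlate -> filter -> cluster.

``run_pipeline`` executes the stages in order on the inputs named in a
:class:`PipelineConfig`, writes one output file per stage plus a JSON
manifest of record counts, and is fully deterministic: identical config
and inputs reproduce byte-identical outputs.  ``simulate_bundle``
generates a complete synthetic input set (proteome, annotation, diurnal
expression matrix, genome + GFF3, PWM, role tables) with ground-truth
tables, sized as a desk-scale analogue of a single-species prionome
study.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import composition, coexpression, expression_tools, grn, mcode
from . import prionome_summary as summary_mod
from . import prld_scan, regulome, synthetic_data

BUNDLE_FILES = {
    "proteome": "proteome.faa",
    "proteome_truth": "proteome_truth.tsv",
    "annotation": "annotation.tsv",
    "expression": "expression.tsv",
    "expression_truth": "expression_truth.tsv",
    "genome": "genome.fa",
    "gff3": "genes.gff3",
    "genome_truth": "genome_truth.tsv",
    "pwm": "pwm.txt",
    "roles_TF": "roles_tf.txt",
    "roles_tsrtr": "roles_tsrtr.txt",
    "roles_stress": "roles_stress.txt",
    "roles_memory": "roles_memory.txt",
}

DEFAULT_MOTIF = "TGACGTCATG"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All inputs, outputs and thresholds of one pipeline run."""

    proteome: str = ""
    annotation: str = ""
    expression: str = ""
    genome: str = ""
    gff3: str = ""
    pwm: str = ""
    roles_tf: str = ""
    roles_tsrtr: str = ""
    roles_stress: str = ""
    roles_memory: str = ""
    outdir: str = "prionome_out"
    species: str = "synthetic"

    lcore: int = 60
    alpha: float = 50.0
    corescore: float = 25.0
    r_cut: float = 0.8
    p_cut: float = 0.01
    combine_mode: str = "and"
    upstream: int = 1500
    downstream: int = 200
    e_value: float = 1e-5
    coverage: float = 50.0
    identity: float = 35.0
    mcode_vwp: float = 0.2
    mcode_haircut: bool = True
    mcode_degree_cutoff: int = 2
    hub_fraction: float = 0.05
    pwm_threshold: Optional[float] = None
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def validate_config(config: PipelineConfig) -> List[str]:
    """Range and existence checks; returns problems instead of raising."""
    errors: List[str] = []
    if not 0 <= config.alpha <= 100:
        errors.append(f"alpha out of range [0, 100]: {config.alpha}")
    if config.lcore < 1:
        errors.append(f"lcore must be positive: {config.lcore}")
    if not 0 < config.r_cut <= 1:
        errors.append(f"r_cut out of range (0, 1]: {config.r_cut}")
    if not 0 < config.p_cut <= 1:
        errors.append(f"p_cut out of range (0, 1]: {config.p_cut}")
    if config.combine_mode not in {"and", "or"}:
        errors.append(f"combine_mode must be and/or: {config.combine_mode}")
    if config.upstream < 0 or config.downstream < 0:
        errors.append("upstream/downstream must be non-negative")
    if not 0 <= config.mcode_vwp < 1:
        errors.append(f"mcode_vwp out of range [0, 1): {config.mcode_vwp}")
    if not 0 < config.hub_fraction <= 1:
        errors.append(f"hub_fraction out of range (0, 1]: {config.hub_fraction}")
    for name in ("proteome", "annotation", "expression", "genome", "gff3",
                 "pwm", "roles_tf", "roles_tsrtr", "roles_stress",
                 "roles_memory"):
        path = getattr(config, name)
        if path and not os.path.exists(path):
            errors.append(f"{name} file does not exist: {path}")
        if not path:
            errors.append(f"{name} path is not set")
    return errors


def bundle_config(bundle_dir, outdir=None, **overrides) -> PipelineConfig:
    """Config pointing at a simulated bundle directory."""
    bundle_dir = Path(bundle_dir)
    cfg = PipelineConfig(
        proteome=str(bundle_dir / BUNDLE_FILES["proteome"]),
        annotation=str(bundle_dir / BUNDLE_FILES["annotation"]),
        expression=str(bundle_dir / BUNDLE_FILES["expression"]),
        genome=str(bundle_dir / BUNDLE_FILES["genome"]),
        gff3=str(bundle_dir / BUNDLE_FILES["gff3"]),
        pwm=str(bundle_dir / BUNDLE_FILES["pwm"]),
        roles_tf=str(bundle_dir / BUNDLE_FILES["roles_TF"]),
        roles_tsrtr=str(bundle_dir / BUNDLE_FILES["roles_tsrtr"]),
        roles_stress=str(bundle_dir / BUNDLE_FILES["roles_stress"]),
        roles_memory=str(bundle_dir / BUNDLE_FILES["roles_memory"]),
        outdir=str(outdir if outdir is not None else bundle_dir / "results"),
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


# ---------------------------------------------------------------------------
# Synthetic bundle


def simulate_bundle(
    outdir,
    seed: int = 0,
    n_genes: int = 120,
    planted_fraction: float = 0.25,
    n_tfs: int = 12,
    module_size: int = 15,
    intra_r: float = 0.95,
    cross_r: float = -0.9,
    motif: str = DEFAULT_MOTIF,
) -> Dict[str, object]:
    """Write a complete synthetic input bundle; returns a truth summary.

    The bundle mirrors the shape of a single-species study: a proteome
    with Q/N-rich domains planted in a quarter of the proteins, a
    48-sample diurnal expression matrix with two mutually antagonistic
    planted modules drawn from the planted PrLP genes, prionome TFs and
    stress/memory genes, a genome whose module-gene promoters carry a
    planted TF-binding motif, and role tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2 ** 31 - 1, size=8)

    width = max(4, len(str(n_genes)))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(n_genes)]

    # Proteome (one protein per gene) with planted PrLDs.
    records, prot_truth = synthetic_data.gen_proteome(
        n_proteins=n_genes, planted_fraction=planted_fraction, seed=int(sub[0]),
        id_prefix="g",
    )
    records = [
        prld_scan.ProteinRecord(id=f"{gid}.1", description=f"{gid}.1",
                                sequence=rec.sequence)
        for gid, rec in zip(gene_ids, records)
    ]
    prot_truth = prot_truth.assign(
        protein_id=[f"{gid}.1" for gid in gene_ids], gene_id=gene_ids
    )
    planted_genes = sorted(
        prot_truth.loc[prot_truth["planted"], "gene_id"].tolist()
    )

    # Roles: Ts/RTRs concentrated in the planted prionome (the rice
    # prionome is ~65% Ts/RTR); TFs split between prionome and others.
    n_tsrtr_prlp = int(round(0.65 * len(planted_genes)))
    tsrtr = sorted(
        rng.choice(planted_genes, size=n_tsrtr_prlp, replace=False).tolist()
    )
    prlp_tf_pool = sorted(set(planted_genes) - set(tsrtr))
    n_prlp_tfs = min(7, n_tfs, len(prlp_tf_pool))
    prlp_tfs = sorted(
        rng.choice(prlp_tf_pool, size=n_prlp_tfs, replace=False).tolist()
    )
    other_pool = sorted(set(gene_ids) - set(planted_genes))
    other_tfs = sorted(
        rng.choice(other_pool, size=n_tfs - n_prlp_tfs, replace=False).tolist()
    )
    tfs = sorted(prlp_tfs + other_tfs)
    remaining = sorted(set(other_pool) - set(other_tfs))
    stress = sorted(rng.choice(remaining, size=10, replace=False).tolist())
    remaining = sorted(set(remaining) - set(stress))
    memory = sorted(rng.choice(remaining, size=10, replace=False).tolist())

    # Annotation descriptions drive the keyword categoriser.
    descriptions = {}
    for gid in gene_ids:
        if gid in tsrtr:
            desc = "retrotransposon protein, putative"
        elif gid in tfs:
            desc = "bZIP transcription factor"
        elif gid in stress:
            desc = "heat shock protein, chaperone"
        elif gid in memory:
            desc = "chromatin remodeling factor"
        elif gid in planted_genes:
            desc = "RNA-binding protein, RNA recognition motif"
        else:
            desc = "expressed protein"
        descriptions[gid] = desc
    annotation = pd.DataFrame({
        "protein_id": [f"{gid}.1" for gid in gene_ids],
        "gene_id": gene_ids,
        "description": [descriptions[g] for g in gene_ids],
    })

    # Two antagonistic modules: planted PrLPs + TFs + stress/memory genes.
    modules, noise_sd = synthetic_data.two_antagonistic_modules(
        size_a=module_size, size_b=module_size,
        intra_r=intra_r, cross_r=cross_r,
    )
    non_tf_prlps = sorted(set(planted_genes) - set(tfs))
    a_prlps = non_tf_prlps[: module_size - 7]
    b_prlps = non_tf_prlps[module_size - 7: 2 * module_size - 14]
    a_members = sorted(a_prlps + prlp_tfs[:2] + other_tfs[:2] + stress[:3])
    b_members = sorted(b_prlps + prlp_tfs[2:4] + other_tfs[2:4] + memory[:3])
    if len(a_members) != module_size or len(b_members) != module_size:
        raise ValueError("module membership bookkeeping failed")
    matrix, expr_truth = synthetic_data.gen_diurnal_matrix(
        n_genes=n_genes, modules=modules, noise_sd=noise_sd, seed=int(sub[1]),
        gene_ids=gene_ids,
        membership={"module_a": a_members, "module_b": b_members},
    )

    # Genome: motif planted in the promoters of module genes except one
    # stress and one memory member, so the binding filter has work to do.
    unplanted_demo = {stress[2], memory[2]}
    motif_targets = sorted((set(a_members) | set(b_members)) - unplanted_demo)
    genome, genes, genome_truth = synthetic_data.gen_genome_with_promoters(
        n_genes=n_genes, motif=motif, planted_target_ids=motif_targets,
        seed=int(sub[2]), gene_ids=gene_ids,
    )

    # PWM with the planted motif as consensus.
    counts = np.ones((4, len(motif)))
    for j, base in enumerate(motif):
        counts["ACGT".index(base), j] = 12
    regulome.write_pwm_counts(counts, outdir / BUNDLE_FILES["pwm"], name="tfbs")

    prld_scan.write_fasta(records, outdir / BUNDLE_FILES["proteome"])
    prot_truth.to_csv(outdir / BUNDLE_FILES["proteome_truth"], sep="\t",
                      index=False)
    annotation.to_csv(outdir / BUNDLE_FILES["annotation"], sep="\t", index=False)
    expression_tools.write_expression_tsv(
        matrix, outdir / BUNDLE_FILES["expression"])
    expr_truth.assign(
        module=expr_truth["module"],
    ).to_csv(outdir / BUNDLE_FILES["expression_truth"], sep="\t", index=False)
    synthetic_data.write_genome_fasta(genome, outdir / BUNDLE_FILES["genome"])
    synthetic_data.write_gff3(genes, outdir / BUNDLE_FILES["gff3"])
    genome_truth.to_csv(outdir / BUNDLE_FILES["genome_truth"], sep="\t",
                        index=False)
    synthetic_data.write_role_table(tfs, outdir / BUNDLE_FILES["roles_TF"])
    synthetic_data.write_role_table(tsrtr, outdir / BUNDLE_FILES["roles_tsrtr"])
    synthetic_data.write_role_table(stress, outdir / BUNDLE_FILES["roles_stress"])
    synthetic_data.write_role_table(memory, outdir / BUNDLE_FILES["roles_memory"])

    return {
        "n_genes": n_genes,
        "planted_genes": planted_genes,
        "module_a": a_members,
        "module_b": b_members,
        "tfs": tfs,
        "ts_rtr": tsrtr,
        "stress": stress,
        "memory": memory,
        "motif_targets": motif_targets,
        "noise_sd": noise_sd,
    }


# ---------------------------------------------------------------------------
# Pipeline


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Run every stage; returns (and writes) the manifest."""
    errors = validate_config(config)
    if errors:
        raise PipelineError("config", "; ".join(errors))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {"seed": config.seed, "species": config.species}

    # Stage 1: PrLD scan.
    try:
        proteome = prld_scan.read_proteome(config.proteome)
        table = prld_scan.build_llr_table(
            composition.PRION_DOMAIN_FREQS,
            composition.ARABIDOPSIS_PROTEOME_FREQS,
            composition.GENERIC_PROTEOME_FREQS,
            alpha=config.alpha,
        )
        hits = prld_scan.call_prlds(
            proteome, table, l_core=config.lcore, threshold=config.corescore
        )
        prld_scan.write_hits_tsv(hits, outdir / "hits.tsv")
        manifest["scan"] = {"proteins_in": len(proteome), "hits_out": len(hits)}
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage name is the contract
        raise PipelineError("scan", str(exc)) from exc

    # Stage 2: prionome summary.
    try:
        annotation = summary_mod.read_annotation_tsv(config.annotation)
        hits_df = prld_scan.read_hits_tsv(outdir / "hits.tsv")
        if hits_df.empty:
            entries = []
        else:
            entries = summary_mod.build_entries(
                hits_df, annotation, species=config.species
            )
        proteome_size = len(proteome)
        summary = summary_mod.summarize(entries, max(proteome_size, 1))
        summary_mod.summary_to_frame(summary).to_csv(
            outdir / "summary.tsv", sep="\t", index=False, float_format="%.4f"
        )
        prlp_genes = sorted({e.gene_id for e in entries})
        manifest["summarize"] = {
            "prlp_genes": len(prlp_genes),
            "density": round(summary.density, 4),
            "ts_rtr_share_pct": round(summary.ts_rtr_share, 2),
        }
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("summarize", str(exc)) from exc

    # Stage 3: co-expression.
    try:
        matrix = expression_tools.read_expression_tsv(config.expression)
        scaled = expression_tools.minmax_normalize_matrix(matrix)
        edges = coexpression.pairwise_correlations(scaled)
        calls = coexpression.call_edges(
            edges, r_cut=config.r_cut, p_cut=config.p_cut,
            mode=config.combine_mode,
        )
        coexpression.write_edges_tsv(edges, outdir / "edges.tsv", calls=calls)
        binary = coexpression.threshold_edges(
            edges, r_cut=config.r_cut, p_cut=config.p_cut,
            mode=config.combine_mode, genes=sorted(matrix.index.astype(str)),
        )
        coexpression.write_binary_matrix_tsv(binary, outdir / "binary_matrix.tsv")
        manifest["coexpress"] = {
            "genes": int(matrix.shape[0]),
            "pairs_tested": int(len(edges)),
            "edges_called": binary.nonzero_count(),
        }
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("coexpress", str(exc)) from exc

    # Stage 4: promoters.
    try:
        promoters = regulome.extract_promoters(
            config.gff3, config.genome,
            upstream=config.upstream, downstream=config.downstream,
        )
        regulome.promoters_to_fasta(promoters, outdir / "promoters.fa")
        manifest["promoters"] = {
            "promoters_out": len(promoters),
            "truncated": sum(p.truncated for p in promoters),
        }
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("promoters", str(exc)) from exc

    # Stage 5: binding evidence from PWM scan.
    try:
        pwm = regulome.read_pwm_counts(config.pwm)
        threshold = (
            config.pwm_threshold if config.pwm_threshold is not None
            else pwm.max_score - 1e-9
        )
        role_tables = grn.read_role_tables({
            "TF": config.roles_tf,
            "Ts/RTR": config.roles_tsrtr,
            "stress": config.roles_stress,
            "memory": config.roles_memory,
        })
        evidence: List[regulome.BindingEvidence] = []
        bound_genes = set()
        for promoter in promoters:
            hits_here = regulome.scan_binding_sites(
                promoter, pwm, threshold, tf_id=pwm.name
            )
            if hits_here:
                bound_genes.add(promoter.gene_id)
                evidence.extend(hits_here)
        regulome.write_evidence_tsv(evidence, outdir / "evidence.tsv")
        # The PWM stands for the shared binding model of the prionome
        # TF family: every TF is credited with the motif's sites.
        pairs = {
            (tf, gene) for tf in role_tables["TF"] for gene in bound_genes
        }
        manifest["evidence"] = {
            "sites": len(evidence),
            "bound_promoters": len(bound_genes),
        }
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("evidence", str(exc)) from exc

    # Stage 6: network assembly + binding filter.
    try:
        gene_map = dict(zip(annotation["protein_id"], annotation["gene_id"]))
        prlp_gene_set = {
            gene_map[h.protein_id] for h in hits if h.protein_id in gene_map
        }
        roles = dict(role_tables)
        roles["PrLP"] = prlp_gene_set
        signed = [
            (row.gene_a, row.gene_b, int(call))
            for row, call in zip(edges.itertuples(index=False), calls)
            if call != 0
        ]
        l1, l2, l3 = grn.split_layers(signed, roles)
        network = grn.assemble_layers(l1, l2, l3, roles)
        filtered = regulome.filter_by_binding(network, pairs)
        filtered.remove_nodes_from(list(nx.isolates(filtered)))
        grn.export_sif(filtered, outdir / "network.sif")
        grn.export_node_table(filtered, outdir / "network_nodes.tsv")
        hubs = grn.find_hubs(filtered, top_fraction=config.hub_fraction) \
            if filtered.number_of_nodes() else []
        (outdir / "hubs.txt").write_text("".join(h + "\n" for h in hubs))
        manifest["assemble"] = {
            "layer1_edges": len(l1), "layer2_edges": len(l2),
            "layer3_edges": len(l3),
            "edges_prefilter": network.number_of_edges(),
            "edges_postfilter": filtered.number_of_edges(),
            "nodes": filtered.number_of_nodes(),
            "hubs": len(hubs),
        }
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("assemble", str(exc)) from exc

    # Stage 7: MCODE clustering.
    try:
        clusters = mcode.predict_complexes(
            filtered, vwp=config.mcode_vwp, haircut=config.mcode_haircut,
            degree_cutoff=config.mcode_degree_cutoff,
        )
        mcode.write_clusters_tsv(clusters, outdir / "clusters.tsv")
        manifest["mcode"] = {
            "clusters": len(clusters),
            "clustered_nodes": int(sum(c.size for c in clusters)),
        }
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("mcode", str(exc)) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
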