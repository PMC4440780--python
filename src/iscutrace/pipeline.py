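"""End-to-end orchestration: simulate/load -> screen -> classify -> profile.

Every run is driven by a :class:`RunConfig` (YAML-loadable, CLI-overridable)
and writes a manifest carrying the verbatim config, its hash, the seed and
per-stage record counts, so each filtering decision that a human would
otherwise make by eye is an auditable number.  Reruns with the same config
and seed produce identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import pandas as pd

from . import seeds as seedlib
from .classify import (
    MotifSpec,
    classifications_to_frame,
    classify_hits,
    compute_logo,
    dedupe_per_species,
    detect_cys_columns,
    residue_census,
)
from .phylo import (
    build_matrix,
    clade_summary,
    cooccurrence_report,
    events_to_frame,
    flag_hgt,
    hgt_flags_to_frame,
    nj_tree,
    profile_identity_distances,
    reconstruct,
)
from .profiles import SeedAlignment, build_profile, calibrate_evalues, residues_at_refs
from .screen import (
    apply_fullseq_policy,
    hits_to_frame,
    load_corpus,
    scan_corpus,
)
from .simulate import SimulationConfig, simulate_corpus


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    corpus_dir: str = "corpus"
    out_dir: str = "out"
    seed: int = 0
    simulate: bool = False
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # profile construction / scoring
    alpha: float = 1.0
    gap_open: float = 4.0
    gap_extend: float = 1.0
    n_shuffles: int = 500
    # retrieval thresholds
    evalue_domain: float = 0.1
    evalue_fullseq: float = 1.7e-7
    min_coverage: float = 0.9
    # classification
    motif_pattern: str = "LPPVK"
    motif_max_mismatch: int = 1
    flank_max: int = 50
    window: int = 5
    min_conservation: float = 0.95
    census_rank: str = "phylum"
    # phylo
    hgt_k: int = 3
    hgt_threshold: float = 1.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["residue_108_states"] = list(d["sim"]["residue_108_states"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            sim.setdefault("residue_108_states", ["I", "L", "V"])
            sim["residue_108_states"] = tuple(sim["residue_108_states"])
            sim = SimulationConfig(**sim)
        cfg = cls(sim=sim, **d)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (filesystem paths excluded)."""
        d = self.to_dict()
        d.pop("corpus_dir", None)
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    counts: dict
    census: dict
    cooccurrence: dict
    events: list
    hgt_flags: list
    provenance: dict

    def to_dict(self) -> dict:
        return asdict(self)

    def report_hash(self) -> str:
        d = self.to_dict()
        d["provenance"] = {
            k: v for k, v in d["provenance"].items() if k != "stage_seconds"
        }
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def validate_inputs(corpus_dir) -> list[str]:
    """Cross-check FASTA/TSV/Newick consistency; returns diagnostics (empty = ok)."""
    from Bio import SeqIO

    corpus_dir = Path(corpus_dir)
    diags: list[str] = []
    genes_path = corpus_dir / "genes.tsv"
    if not genes_path.exists():
        return [f"missing gene table {genes_path}"]
    genes = pd.read_csv(genes_path, sep="\t", dtype=str)
    seqs: set[tuple[str, str]] = set()
    prot_dir = corpus_dir / "proteomes"
    if not prot_dir.is_dir():
        diags.append(f"missing proteome directory {prot_dir}")
    else:
        for fasta in sorted(prot_dir.glob("*.fasta")):
            for rec in SeqIO.parse(str(fasta), "fasta"):
                taxon, _, locus = rec.id.partition("|")
                seqs.add((taxon, locus))
    table = set(zip(genes["taxon_id"], genes["locus_id"]))
    for taxon, locus in sorted(table - seqs):
        diags.append(f"gene table references missing protein {taxon}:{locus}")
    for taxon, locus in sorted(seqs - table):
        diags.append(f"protein {taxon}:{locus} absent from gene table")
    corpus_taxa = set(genes["taxon_id"])
    tax_path = corpus_dir / "taxonomy.tsv"
    if tax_path.exists():
        tax = set(pd.read_csv(tax_path, sep="\t", dtype=str)["taxon_id"])
        for t in sorted(corpus_taxa - tax):
            diags.append(f"taxon {t} missing from taxonomy.tsv")
    else:
        diags.append(f"missing taxonomy table {tax_path}")
    tree_path = corpus_dir / "tree.nwk"
    if tree_path.exists():
        tree = dendropy.Tree.get(path=str(tree_path), schema="newick")
        leaves = {t.label for t in tree.taxon_namespace}
        for t in sorted(leaves - corpus_taxa):
            diags.append(f"tree leaf {t} has no genome in the corpus")
        for t in sorted(corpus_taxa - leaves):
            diags.append(f"genome {t} absent from the species tree")
    else:
        diags.append(f"missing species tree {tree_path}")
    return diags


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage in order and write all artifacts to out_dir."""
    t0 = time.time()
    timings: dict[str, float] = {}
    corpus_dir = Path(config.corpus_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # -- stage: corpus ------------------------------------------------------
    if config.simulate:
        config.sim.seed = config.seed
        genomes, truth, tree = simulate_corpus(config.sim, outdir=corpus_dir)
    else:
        if not corpus_dir.exists():
            raise PipelineError(f"corpus directory {corpus_dir} not found")
        genomes = load_corpus(corpus_dir)
        tree = dendropy.Tree.get(path=str(corpus_dir / "tree.nwk"), schema="newick")
    timings["corpus"] = time.time() - t0

    # -- stage: profiles + calibration --------------------------------------
    t1 = time.time()
    seeds_dir = corpus_dir / "seeds"
    if (seeds_dir / "iscu_seed.fasta").exists():
        iscu_seed = SeedAlignment.from_fasta(seeds_dir / "iscu_seed.fasta")
        cyay_seed = SeedAlignment.from_fasta(seeds_dir / "cyay_seed.fasta")
    else:
        iscu_seed = seedlib.iscu_seed()
        cyay_seed = seedlib.cyay_seed()
    iscu_profile = build_profile(iscu_seed, alpha=config.alpha)
    cyay_profile = build_profile(cyay_seed, alpha=config.alpha)
    iscu_profile.to_json(out_dir / "iscu_profile.json")
    cyay_profile.to_json(out_dir / "cyay_profile.json")

    all_proteins = [g.protein for genome in genomes for g in genome.genes]
    cal_kwargs = dict(
        targets=all_proteins,
        n_shuffles=config.n_shuffles,
        database_size=len(all_proteins),
        gap_open=config.gap_open,
        gap_extend=config.gap_extend,
    )
    iscu_cal = calibrate_evalues(iscu_profile, seed=config.seed * 2 + 1, **cal_kwargs)
    cyay_cal = calibrate_evalues(cyay_profile, seed=config.seed * 2 + 2, **cal_kwargs)
    timings["profiles"] = time.time() - t1

    # -- stage: screen -------------------------------------------------------
    t2 = time.time()
    scan_kwargs = dict(gap_open=config.gap_open, gap_extend=config.gap_extend)
    u_hits = scan_corpus(
        genomes, iscu_profile, iscu_cal, config.evalue_domain, family="U-family", **scan_kwargs
    )
    cyay_domain_hits = scan_corpus(
        genomes, cyay_profile, cyay_cal, config.evalue_domain, family="cyaY", **scan_kwargs
    )
    cyay_hits = apply_fullseq_policy(
        cyay_domain_hits, min_coverage=config.min_coverage, evalue_max=config.evalue_fullseq
    )
    hits_to_frame(u_hits + cyay_hits).to_csv(out_dir / "hits.tsv", sep="\t", index=False)
    timings["screen"] = time.time() - t2

    # -- stage: classify + census + logo -------------------------------------
    t3 = time.time()
    cys_columns = detect_cys_columns(iscu_seed, config.min_conservation)
    motif = MotifSpec(pattern=config.motif_pattern, max_mismatch=config.motif_max_mismatch)
    classifications = classify_hits(
        u_hits,
        genomes,
        iscu_profile,
        cys_columns,
        motif=motif,
        window=config.window,
        flank_max=config.flank_max,
    )
    classifications_to_frame(classifications).to_csv(
        out_dir / "classifications.tsv", sep="\t", index=False
    )
    census = residue_census(classifications, genomes, rank=config.census_rank)
    census.to_frame().to_csv(out_dir / "census.tsv", sep="\t", index=False)
    accepted = dedupe_per_species(classifications)
    if accepted:
        logo = compute_logo(accepted)
        logo.to_frame().to_csv(out_dir / "logo.tsv", sep="\t", index=False, float_format="%.6f")
    timings["classify"] = time.time() - t3

    # -- stage: phylo profile -------------------------------------------------
    t4 = time.time()
    corpus_taxa = sorted(g.taxon_id for g in genomes)
    present = {
        "iscU": {c.taxon_id for c in accepted},
        "cyaY": {h.taxon_id for h in cyay_hits},
    }
    matrix = build_matrix(present, corpus_taxa)
    matrix.to_csv(out_dir / "matrix.tsv", sep="\t")
    cooc = cooccurrence_report(matrix)
    taxonomy = {g.taxon_id: g.lineage.get("phylum", "unknown") for g in genomes}
    clade_summary(matrix, taxonomy).to_csv(out_dir / "clade_summary.tsv", sep="\t", index=False)

    # species-tree leaf labels must cover the corpus for reconstruction
    recs = {}
    for fam in ("cyaY", "iscU"):
        leaf_states = {t: bool(matrix.loc[t, fam]) for t in corpus_taxa}
        for mode in ("dollo", "fitch"):
            recs[(fam, mode)] = reconstruct(tree, leaf_states, mode=mode)
    events_to_frame(recs).to_csv(out_dir / "events.tsv", sep="\t", index=False)

    flags = []
    cyay_taxa_hits = {h.taxon_id: h for h in cyay_hits}
    if len(cyay_taxa_hits) >= 4:
        by_taxon = {g.taxon_id: g for g in genomes}
        aligned = {}
        for t, h in cyay_taxa_hits.items():
            gene = by_taxon[t].gene(h.locus_id)
            aligned[t] = residues_at_refs(h.alignment, cyay_profile, gene.protein)
        labels, D = profile_identity_distances(aligned)
        gene_tree = nj_tree(D, labels)
        gene_tree.write(path=str(out_dir / "cyay_gene_tree.nwk"), schema="newick")
        flags = flag_hgt(
            gene_tree, taxonomy, family="cyaY", k=config.hgt_k, threshold=config.hgt_threshold
        )
        hgt_flags_to_frame(flags).to_csv(out_dir / "hgt_flags.tsv", sep="\t", index=False)
    timings["phylo"] = time.time() - t4

    # -- report ---------------------------------------------------------------
    n_proteins = len(all_proteins)
    counts = {
        "genomes": len(genomes),
        "proteins_scanned": n_proteins,
        "u_domain_hits": len(u_hits),
        "cyay_domain_hits": len(cyay_domain_hits),
        "cyay_fullseq_hits": len(cyay_hits),
        "iscu_accepted": sum(1 for c in classifications if c.accepted),
        "iscu_species": len(present["iscU"]),
        "cyay_species": len(present["cyaY"]),
    }
    report = RunReport(
        counts=counts,
        census={
            "grouping": census.grouping,
            "counts": census.counts,
            "overall": census.overall(),
        },
        cooccurrence={
            "both": cooc.counts[(True, True)],
            "iscU_only": cooc.counts[(False, True)],
            "cyaY_only": cooc.counts[(True, False)],
            "neither": cooc.counts[(False, False)],
            "violations": cooc.violations,
        },
        events=[
            {
                "family": fam,
                "mode": mode,
                "cost": rec.cost,
                "gains": [f"{a}->{b}" for a, b, _ in rec.gains],
                "losses": [f"{a}->{b}" for a, b, _ in rec.losses],
            }
            for (fam, mode), rec in sorted(recs.items())
        ],
        hgt_flags=[
            {"taxon_id": f.taxon_id, "evidence": round(f.evidence, 6), "flagged": f.flagged}
            for f in flags
        ],
        provenance={
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "thresholds": {
                "evalue_domain": config.evalue_domain,
                "evalue_fullseq": config.evalue_fullseq,
                "min_coverage": config.min_coverage,
            },
            "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
        },
    )
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "report_hash": report.report_hash(),
        "seed": config.seed,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return report
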