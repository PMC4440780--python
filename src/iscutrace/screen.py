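"""Whole-proteome profile scanning and retrieval policies.

The screen aligns every protein of every genome against a family profile,
converts scores to E-values via the empirical calibration, and keeps hits
passing the configured threshold.  Two retrieval policies mirror the two
search regimes used for the frataxin/scaffold families:

- *domain mode*: keep any protein whose profile alignment reaches the
  E-value threshold (default 0.1), regardless of how much of the protein
  the domain covers;
- *full-sequence mode* (:func:`apply_fullseq_policy`): additionally require
  that the profile covers (nearly) the entire protein, operationalized as a
  minimum match-column coverage, with a much stricter E-value threshold
  (default 1.7e-7 for CyaY).

Hits within 10x of the E-value threshold are flagged ``borderline`` so a
human can review them, replacing manual alignment inspection with an
explicit, auditable rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .profiles import (
    EvalueCalibration,
    ProfileAlignment,
    ProfileModel,
    align_to_profile,
)


class CorpusError(ValueError):
    """Raised on malformed or inconsistent corpus inputs."""


@dataclass
class Gene:
    locus_id: str
    order_index: int
    strand: str
    protein: str
    annotation_label: str = ""


@dataclass
class Genome:
    """One species' ordered gene list with taxonomy labels."""

    taxon_id: str
    name: str
    lineage: dict[str, str]  # rank -> label, e.g. {"domain": ..., "phylum": ...}
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for g in self.genes:
            if not g.protein:
                raise CorpusError(f"{self.taxon_id}:{g.locus_id} has an empty protein")
            if g.locus_id in seen:
                raise CorpusError(f"duplicate locus {g.locus_id} in {self.taxon_id}")
            seen.add(g.locus_id)

    def gene(self, locus_id: str) -> Gene:
        for g in self.genes:
            if g.locus_id == locus_id:
                return g
        raise KeyError(locus_id)


@dataclass
class CalibratedHit:
    taxon_id: str
    locus_id: str
    family: str
    score_bits: float
    evalue: float
    alignment: ProfileAlignment
    borderline: bool = False


# ---------------------------------------------------------------------------
# Corpus I/O
# ---------------------------------------------------------------------------


def load_corpus(corpus_dir) -> list[Genome]:
    """Load genomes from ``proteomes/*.fasta`` + ``genes.tsv`` + ``taxonomy.tsv``.

    FASTA headers are ``taxon_id|locus_id``; the gene table carries
    (taxon_id, locus_id, order_index, strand, annotation_label); the
    taxonomy table carries (taxon_id, name, domain, phylum).
    """
    from Bio import SeqIO

    corpus_dir = Path(corpus_dir)
    genes = pd.read_csv(corpus_dir / "genes.tsv", sep="\t", dtype=str)
    genes["order_index"] = genes["order_index"].astype(int)
    genes["annotation_label"] = genes["annotation_label"].fillna("")
    taxonomy = pd.read_csv(corpus_dir / "taxonomy.tsv", sep="\t", dtype=str).set_index("taxon_id")

    proteins: dict[tuple[str, str], str] = {}
    for fasta in sorted((corpus_dir / "proteomes").glob("*.fasta")):
        for rec in SeqIO.parse(str(fasta), "fasta"):
            taxon_id, _, locus_id = rec.id.partition("|")
            if not locus_id:
                raise CorpusError(f"FASTA header {rec.id!r} is not 'taxon|locus'")
            proteins[(taxon_id, locus_id)] = str(rec.seq).upper()

    genomes = []
    for taxon_id, sub in genes.groupby("taxon_id", sort=True):
        if taxon_id not in taxonomy.index:
            raise CorpusError(f"taxon {taxon_id} missing from taxonomy.tsv")
        row = taxonomy.loc[taxon_id]
        glist = []
        for _, r in sub.sort_values("order_index").iterrows():
            key = (taxon_id, r["locus_id"])
            if key not in proteins:
                raise CorpusError(f"no protein sequence for locus {r['locus_id']} of {taxon_id}")
            glist.append(
                Gene(
                    locus_id=r["locus_id"],
                    order_index=int(r["order_index"]),
                    strand=r["strand"],
                    protein=proteins[key],
                    annotation_label=r["annotation_label"],
                )
            )
        genomes.append(
            Genome(
                taxon_id=taxon_id,
                name=row.get("name", taxon_id),
                lineage={"domain": row.get("domain", "Bacteria"), "phylum": row["phylum"]},
                genes=glist,
            )
        )
    return genomes


def write_corpus(genomes: list[Genome], corpus_dir) -> None:
    corpus_dir = Path(corpus_dir)
    (corpus_dir / "proteomes").mkdir(parents=True, exist_ok=True)
    rows = []
    tax_rows = []
    for g in sorted(genomes, key=lambda x: x.taxon_id):
        with open(corpus_dir / "proteomes" / f"{g.taxon_id}.fasta", "w") as fh:
            for gene in g.genes:
                fh.write(f">{g.taxon_id}|{gene.locus_id}\n{gene.protein}\n")
        for gene in g.genes:
            rows.append(
                (g.taxon_id, gene.locus_id, gene.order_index, gene.strand, gene.annotation_label)
            )
        tax_rows.append(
            (g.taxon_id, g.name, g.lineage.get("domain", "Bacteria"), g.lineage.get("phylum", ""))
        )
    pd.DataFrame(
        rows, columns=["taxon_id", "locus_id", "order_index", "strand", "annotation_label"]
    ).to_csv(corpus_dir / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(tax_rows, columns=["taxon_id", "name", "domain", "phylum"]).to_csv(
        corpus_dir / "taxonomy.tsv", sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


def scan_proteome(
    genome: Genome,
    profile: ProfileModel,
    calibration: EvalueCalibration,
    evalue_max: float = 0.1,
    family: str = "cyaY",
    gap_open: float = 4.0,
    gap_extend: float = 1.0,
) -> list[CalibratedHit]:
    """Align every protein of one genome to the profile; keep E <= evalue_max."""
    hits = []
    for gene in genome.genes:
        aln = align_to_profile(
            gene.protein, profile, gap_open, gap_extend, query_id=f"{genome.taxon_id}|{gene.locus_id}"
        )
        e = calibration.evalue(aln.score_bits)
        if e <= evalue_max:
            hits.append(
                CalibratedHit(
                    taxon_id=genome.taxon_id,
                    locus_id=gene.locus_id,
                    family=family,
                    score_bits=aln.score_bits,
                    evalue=float(e),
                    alignment=aln,
                    borderline=bool(e > evalue_max / 10.0),
                )
            )
    return hits


def scan_corpus(
    genomes: list[Genome],
    profile: ProfileModel,
    calibration: EvalueCalibration,
    evalue_max: float = 0.1,
    family: str = "cyaY",
    gap_open: float = 4.0,
    gap_extend: float = 1.0,
) -> list[CalibratedHit]:
    hits = []
    for g in genomes:
        hits.extend(
            scan_proteome(g, profile, calibration, evalue_max, family, gap_open, gap_extend)
        )
    return hits


def query_span_coverage(alignment: ProfileAlignment) -> float:
    """Fraction of the query contained in the aligned span (flanks excluded)."""
    if not alignment.path:
        return 0.0
    span = alignment.path[-1][0] - alignment.path[0][0] + 1
    n = span + alignment.flank_lengths[0] + alignment.flank_lengths[1]
    return span / n


def apply_fullseq_policy(
    hits: list[CalibratedHit],
    min_coverage: float = 0.9,
    evalue_max: float = 1.7e-7,
) -> list[CalibratedHit]:
    """Keep hits homologous over the entire sequence, at the strict E-value.

    "Entire sequence" is enforced in both directions: the alignment must
    cover >= ``min_coverage`` of the profile match columns *and* of the
    query.  A domain embedded in a larger fusion protein fails the query
    side of the gate no matter how significant its score is.
    """
    kept = []
    for h in hits:
        if h.alignment is None:
            raise CorpusError(f"hit {h.taxon_id}:{h.locus_id} carries no alignment")
        if (
            h.alignment.coverage >= min_coverage
            and query_span_coverage(h.alignment) >= min_coverage
            and h.evalue <= evalue_max
        ):
            kept.append(h)
    return kept


def hits_to_frame(hits: list[CalibratedHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon_id": h.taxon_id,
                "locus_id": h.locus_id,
                "family": h.family,
                "score_bits": round(h.score_bits, 6),
                "evalue": h.evalue,
                "coverage": round(h.alignment.coverage, 6),
                "borderline": h.borderline,
            }
            for h in hits
        ],
        columns=["taxon_id", "locus_id", "family", "score_bits", "evalue", "coverage", "borderline"],
    )
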