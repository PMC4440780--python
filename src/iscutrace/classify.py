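"""Four-criterion acceptance of IscU scaffold homologs, residue census, logos.

A profile hit is accepted as a genuine IscU-family scaffold only if it
satisfies all four criteria simultaneously:

(i)   the three conserved cluster-ligand cysteines are present at the
      auto-detected reference columns (``c_cys``);
(ii)  the chaperone-recognition motif (LPPVK in the reference) is present
      at reference positions 99-103, within a configurable mismatch budget
      (``c_motif``);
(iii) no additional domain: both unaligned query flanks are bounded
      (``c_nodomain``), which rejects NifU-like multi-domain fusions;
(iv)  at least one *other* isc-related gene lies within +/- ``window`` gene
      positions on the replicon (``c_neighbor``).

Accepted homologs are deduplicated to one representative per species
(best score) before the residue-108 census, because downstream statements
count species, not loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import (
    AA_INDEX,
    AMINO_ACIDS,
    ProfileModel,
    SeedAlignment,
    residues_at_refs,
)
from .screen import CalibratedHit, Genome

#: gene labels counted as isc-related when inspecting the neighborhood
DEFAULT_ISC_GENES = frozenset({"iscR", "iscS", "iscU", "iscA", "hscB", "hscA", "fdx", "iscX"})

MAX_INFORMATION = math.log2(20.0)


class ClassifyError(ValueError):
    pass


@dataclass(frozen=True)
class MotifSpec:
    """Degenerate-match specification for the chaperone-recognition motif.

    ``fixed`` indexes (0-based within the motif) must match exactly — by
    default the two prolines of LPPVK — while up to ``max_mismatch``
    substitutions are tolerated at the remaining positions.
    """

    pattern: str = "LPPVK"
    start_ref: int = 99
    fixed: tuple[int, ...] = (1, 2)
    max_mismatch: int = 1

    @property
    def refs(self) -> tuple[int, ...]:
        return tuple(range(self.start_ref, self.start_ref + len(self.pattern)))

    def matches(self, observed: str) -> bool:
        if len(observed) != len(self.pattern):
            return False
        mismatches = 0
        for i, (o, p) in enumerate(zip(observed, self.pattern)):
            if o == p:
                continue
            if i in self.fixed:
                return False
            mismatches += 1
        return mismatches <= self.max_mismatch


@dataclass
class IscUClassification:
    taxon_id: str
    locus_id: str
    c_cys: bool
    c_motif: bool
    c_nodomain: bool
    c_neighbor: bool
    residue_108: str | None
    score_bits: float = 0.0
    ref_residues: dict[int, str] = field(default_factory=dict)

    @property
    def accepted(self) -> bool:
        return self.c_cys and self.c_motif and self.c_nodomain and self.c_neighbor


def detect_cys_columns(seed: SeedAlignment, min_conservation: float = 0.95) -> set[int]:
    """Find the three most Cys-conserved reference positions in the seed.

    Returns the reference numbers of the three columns with the highest
    cysteine frequency; raises if fewer than three reach ``min_conservation``.
    """
    numbering = seed.reference_numbering()
    freqs: list[tuple[float, int]] = []
    for col, ref in numbering.items():
        n_cys = sum(1 for _, seq in seed.rows if seq[col] == "C")
        n_res = sum(1 for _, seq in seed.rows if seq[col] not in "-X")
        if n_res:
            freqs.append((n_cys / n_res, ref))
    # highest frequency first; ties resolved by smaller reference number
    freqs.sort(key=lambda t: (-t[0], t[1]))
    top = freqs[:3]
    qualifying = [ref for f, ref in top if f >= min_conservation]
    if len(qualifying) < 3:
        raise ClassifyError(
            f"only {len(qualifying)} columns reach Cys conservation "
            f">= {min_conservation}; need 3"
        )
    return set(qualifying)


def check_criteria(
    hit: CalibratedHit,
    genome: Genome,
    profile: ProfileModel,
    cys_columns: set[int],
    motif: MotifSpec | None = None,
    isc_gene_set: frozenset[str] | set[str] = DEFAULT_ISC_GENES,
    window: int = 5,
    flank_max: int = 50,
) -> IscUClassification:
    """Evaluate the four scaffold-acceptance criteria for one hit."""
    if hit.alignment is None:
        raise ClassifyError(f"hit {hit.taxon_id}:{hit.locus_id} has no alignment")
    if motif is None:
        motif = MotifSpec()
    gene = genome.gene(hit.locus_id)
    refmap = residues_at_refs(hit.alignment, profile, gene.protein)

    c_cys = all(refmap.get(ref) == "C" for ref in cys_columns)

    observed = "".join(refmap.get(r, "-") for r in motif.refs)
    c_motif = "-" not in observed and motif.matches(observed)

    flank_n, flank_c = hit.alignment.flank_lengths
    c_nodomain = flank_n <= flank_max and flank_c <= flank_max

    c_neighbor = any(
        g.locus_id != gene.locus_id
        and g.annotation_label in isc_gene_set
        and 1 <= abs(g.order_index - gene.order_index) <= window
        for g in genome.genes
    )

    return IscUClassification(
        taxon_id=hit.taxon_id,
        locus_id=hit.locus_id,
        c_cys=c_cys,
        c_motif=c_motif,
        c_nodomain=c_nodomain,
        c_neighbor=c_neighbor,
        residue_108=refmap.get(108),
        score_bits=hit.score_bits,
        ref_residues=refmap,
    )


def classify_hits(
    hits: list[CalibratedHit],
    genomes: list[Genome],
    profile: ProfileModel,
    cys_columns: set[int],
    **kwargs,
) -> list[IscUClassification]:
    by_taxon = {g.taxon_id: g for g in genomes}
    return [
        check_criteria(h, by_taxon[h.taxon_id], profile, cys_columns, **kwargs) for h in hits
    ]


def dedupe_per_species(classifications: list[IscUClassification]) -> list[IscUClassification]:
    """One accepted representative per species: highest score, then locus id."""
    best: dict[str, IscUClassification] = {}
    for c in classifications:
        if not c.accepted:
            continue
        cur = best.get(c.taxon_id)
        if cur is None or (c.score_bits, c.locus_id) > (cur.score_bits, cur.locus_id):
            best[c.taxon_id] = c
    return [best[t] for t in sorted(best)]


# ---------------------------------------------------------------------------
# Residue census
# ---------------------------------------------------------------------------


@dataclass
class ResidueCensus:
    """Counts of the residue at reference position 108 per taxonomic group."""

    grouping: str
    counts: dict[str, dict[str, int]]

    @property
    def totals(self) -> dict[str, int]:
        return {g: sum(c.values()) for g, c in self.counts.items()}

    def ilv_fraction(self, group: str) -> float | None:
        c = self.counts.get(group)
        if not c:
            return None
        total = sum(c.values())
        return sum(c.get(a, 0) for a in "ILV") / total if total else None

    def overall(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.counts.values():
            for aa, n in c.items():
                out[aa] = out.get(aa, 0) + n
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"group": g, "amino_acid": aa, "count": n}
            for g in sorted(self.counts)
            for aa, n in sorted(self.counts[g].items())
        ]
        return pd.DataFrame(rows, columns=["group", "amino_acid", "count"])


def residue_census(
    classifications: list[IscUClassification],
    genomes: list[Genome],
    rank: str = "phylum",
    deduplicate: bool = True,
) -> ResidueCensus:
    """Tally residue-108 states of accepted homologs per taxonomic group."""
    if deduplicate:
        classifications = dedupe_per_species(classifications)
    else:
        classifications = [c for c in classifications if c.accepted]
    lineage = {g.taxon_id: g.lineage for g in genomes}
    counts: dict[str, dict[str, int]] = {}
    for c in classifications:
        if c.residue_108 is None:
            continue
        group = lineage[c.taxon_id].get(rank, "unknown")
        counts.setdefault(group, {})
        counts[group][c.residue_108] = counts[group].get(c.residue_108, 0) + 1
    return ResidueCensus(grouping=rank, counts=counts)


# ---------------------------------------------------------------------------
# Sequence logo
# ---------------------------------------------------------------------------


@dataclass
class SequenceLogo:
    """Per-column residue frequencies and information content over a region."""

    region: tuple[int, int]
    positions: list[int]
    frequencies: np.ndarray  # (n_positions, 20); rows sum to 1 where defined
    information_bits: list[float | None]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.frequencies, columns=list(AMINO_ACIDS))
        df.insert(0, "ref_position", self.positions)
        df["information_bits"] = [
            np.nan if x is None else x for x in self.information_bits
        ]
        return df


def compute_logo(
    classifications: list[IscUClassification],
    region: tuple[int, int] = (99, 108),
) -> SequenceLogo:
    """Column frequencies and information R = log2(20) - H over a ref region.

    Only accepted classifications contribute; gaps (unaligned positions) are
    excluded from the denominator.  A column with no aligned residues has
    undefined information, reported as ``None``.
    """
    members = [c for c in classifications if c.accepted]
    if not members:
        raise ClassifyError("no accepted sequences to build a logo from")
    lo, hi = region
    positions = list(range(lo, hi + 1))
    freqs = np.zeros((len(positions), 20))
    info: list[float | None] = []
    for k, ref in enumerate(positions):
        counts = np.zeros(20)
        for c in members:
            aa = c.ref_residues.get(ref)
            if aa is not None and aa in AA_INDEX:
                counts[AA_INDEX[aa]] += 1
        total = counts.sum()
        if total == 0:
            info.append(None)
            continue
        f = counts / total
        freqs[k] = f
        nz = f[f > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        info.append(MAX_INFORMATION - entropy)
    return SequenceLogo(
        region=region, positions=positions, frequencies=freqs, information_bits=info
    )


def classifications_to_frame(classifications: list[IscUClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon_id": c.taxon_id,
                "locus_id": c.locus_id,
                "c_cys": c.c_cys,
                "c_motif": c.c_motif,
                "c_nodomain": c.c_nodomain,
                "c_neighbor": c.c_neighbor,
                "accepted": c.accepted,
                "residue_108": c.residue_108 if c.residue_108 else "none",
            }
            for c in classifications
        ],
        columns=[
            "taxon_id",
            "locus_id",
            "c_cys",
            "c_motif",
            "c_nodomain",
            "c_neighbor",
            "accepted",
            "residue_108",
        ],
    )
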