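"""Synthetic miniature corpora with planted ground truth.

The simulator emulates, at desk scale, the statistical structure of a
corpus of complete prokaryotic proteomes used to trace frataxin/scaffold
evolution: a Yule species tree with phylum labels on its crown clades; a
dependency-constrained gain/loss history for the two families (cyaY may
only be gained where iscU is present, and iscU may not be lost while cyaY
is present — so no genome is ever cyaY+/iscU-); profile-conditioned
protein sequences whose cluster-ligand cysteines and chaperone motif are
invariant and whose residue at reference position 108 is set per clade
(Met in one designated clade, Ile/Leu/Val elsewhere); isc-operon-like gene
neighborhoods; NifU-like, SufU-like, structural-analog and random decoys;
and planted horizontal transfers of cyaY between phyla.

Every random draw descends from a single integer seed; the same seed
yields a byte-identical corpus.  The emitted ``SimulationTruth`` carries
enough labels to score every downstream pipeline stage exactly.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np

from . import seeds as seedlib
from .profiles import AMINO_ACIDS, ProfileModel, SeedAlignment, build_profile
from .screen import Gene, Genome, write_corpus

ISC_NEIGHBOR_LABELS = ("iscR", "iscS", "iscA", "hscB", "hscA", "fdx", "iscX")


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Knobs of the synthetic corpus; defaults define the demo study."""

    n_taxa: int = 40
    seed: int = 0
    birth_rate: float = 1.0
    n_phyla: int = 6
    # presence evolution: forced gains + optional Markov rates per branch length
    iscu_loss_rate: float = 0.0
    cyay_loss_rate: float = 0.0
    iscu_gain_rate: float = 0.0
    cyay_gain_rate: float = 0.0
    cyay_clade_size: int = 25  # target leaf count of the forced cyaY gain clade
    met_clade_size: int = 12  # target leaf count of the Met-at-108 clade
    residue_108_states: tuple[str, ...] = ("I", "L", "V")  # cycled over non-Met phyla
    subst_rate: float = 0.3  # per-column resampling probability per unit branch length
    stem_scale: float = 4.0  # lengthening of inter-phylum (stem) branches
    min_phylum_size: int = 4
    hgt_divergence: float = 0.02
    n_hgt: int = 2
    hgt_activates: bool = True
    # genome layout
    genes_min: int = 30
    genes_max: int = 45
    p_ctx: float = 1.0  # probability a planted iscU gets an isc-labeled neighbor
    window: int = 5
    protein_len_min: int = 60
    protein_len_max: int = 200
    # decoys (corpus-wide counts)
    decoy_nifu: int = 10
    decoy_sufu: int = 10
    decoy_struct: int = 5
    decoy_random: int = 5
    nifu_extra_len: int = 200

    def validate(self) -> None:
        if self.n_taxa < 3:
            raise SimulationError("need at least 3 taxa")
        for r in (
            self.iscu_loss_rate,
            self.cyay_loss_rate,
            self.iscu_gain_rate,
            self.cyay_gain_rate,
            self.subst_rate,
        ):
            if r < 0:
                raise SimulationError("rates must be nonnegative")
        if not 0 <= self.p_ctx <= 1:
            raise SimulationError("p_ctx must be a probability")
        for a in self.residue_108_states:
            if a not in AMINO_ACIDS:
                raise SimulationError(f"{a!r} is not an amino acid")


@dataclass
class SimulationTruth:
    """Planted labels, ancestral states and transfers for scoring the pipeline."""

    seed: int
    tree_newick: str
    presence: dict[str, dict[str, bool]]  # family -> taxon -> present
    node_states: dict[str, dict[str, bool]]  # family -> node id -> present
    presence_events: dict[str, list[dict]]  # family -> [{branch, type}]
    labels: dict[str, dict[str, str]]  # taxon -> locus -> class label
    residue_108: dict[str, str]  # taxon -> planted state (iscU+ taxa)
    hgt_events: list[dict]  # [{donor, recipient, family}]
    phyla: dict[str, str]  # taxon -> phylum

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(**doc)


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------


def simulate_tree(n_taxa: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) tree with ``n_taxa`` leaves, labeled T01, T02, ..."""
    if n_taxa < 3:
        raise SimulationError("need at least 3 taxa")
    from dendropy.model import birthdeath

    rng = random.Random(seed)
    tree = birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=rng,
    )
    # deterministic relabeling in preorder-leaf order
    ns = dendropy.TaxonNamespace()
    width = max(2, len(str(n_taxa)))
    i = 0
    for leaf in tree.leaf_node_iter():
        i += 1
        leaf.taxon = ns.new_taxon(f"T{i:0{width}d}")
    tree.taxon_namespace = ns
    tree.is_rooted = True
    return tree


def assign_phyla(
    tree: dendropy.Tree, n_phyla: int = 6, min_size: int = 4
) -> dict[str, str]:
    """Deterministically partition leaves into crown-clade 'phyla'.

    The largest clade is split repeatedly until ``n_phyla`` groups exist.
    Splits that would create a group below ``min_size`` leaves are avoided
    when any alternative split exists, but small phyla are tolerated (real
    corpora contain them too); groups are named phylum_A, phylum_B, ... in
    preorder.
    """
    from .phylo import node_id, _index_nodes

    _index_nodes(tree)
    n_leaves: dict[int, int] = {}
    for node in tree.postorder_node_iter():
        n_leaves[id(node)] = (
            1 if node.is_leaf() else sum(n_leaves[id(c)] for c in node.child_nodes())
        )
    groups = [tree.seed_node]
    while len(groups) < n_phyla:
        splittable = [g for g in groups if not g.is_leaf()]
        if not splittable:
            break
        balanced = [
            g
            for g in splittable
            if all(n_leaves[id(c)] >= min_size for c in g.child_nodes())
        ]
        pool = balanced if balanced else splittable
        biggest = max(pool, key=lambda g: (n_leaves[id(g)], -g._iscutrace_index))
        groups.remove(biggest)
        groups.extend(biggest.child_nodes())
    groups.sort(key=lambda g: g._iscutrace_index)
    phyla: dict[str, str] = {}
    for gi, g in enumerate(groups):
        name = f"phylum_{chr(ord('A') + gi)}"
        for leaf in g.leaf_iter():
            phyla[leaf.taxon.label] = name
    return phyla


def deepen_stems(tree: dendropy.Tree, phyla: dict[str, str], stem_scale: float) -> None:
    """Lengthen every branch at or above the phylum crowns by ``stem_scale``.

    Pure-birth trees are clock-uniform, but real phyla are separated by
    deep stems; scaling the inter-phylum backbone gives between-phylum
    sequence divergences that clearly exceed within-phylum ones, which is
    the regime the taxonomic-incongruence HGT rule assumes.
    """
    if stem_scale == 1.0:
        return
    inside: set[int] = set()
    for crown in _crown_nodes(tree, phyla).values():
        for nd in crown.preorder_iter():
            if nd is not crown:
                inside.add(id(nd))
    for node in tree.preorder_node_iter():
        if node.edge.length and id(node) not in inside:
            node.edge.length = node.edge.length * stem_scale


def _crown_nodes(tree: dendropy.Tree, phyla: dict[str, str]) -> dict[str, dendropy.Node]:
    crowns: dict[str, dendropy.Node] = {}
    for name in set(phyla.values()):
        taxa = [t for t in tree.taxon_namespace if phyla[t.label] == name]
        if len(taxa) == 1:
            crowns[name] = tree.find_node_with_taxon_label(taxa[0].label)
        else:
            crowns[name] = tree.mrca(taxa=taxa)
    return crowns


def pick_clade_node(
    tree: dendropy.Tree,
    target_size: int,
    phyla: dict[str, str] | None = None,
    whole_phyla_only: bool = False,
    min_contained_phylum: int = 0,
    exclude_root: bool = True,
) -> dendropy.Node:
    """The node whose subtree size is closest to ``target_size``.

    With ``whole_phyla_only`` the subtree must be a union of complete
    phylum crowns, which keeps planted gains aligned to phylum boundaries;
    ``min_contained_phylum`` additionally rejects subtrees containing a
    phylum with fewer members (a native near-singleton phylum would be
    indistinguishable from a transfer recipient under k-NN incongruence).
    Ties resolve to the earliest node in preorder.  Constraints are
    relaxed, in reverse order, if they leave no candidate.
    """
    from .phylo import _index_nodes

    _index_nodes(tree)
    inside_crown: set[int] = set()
    if whole_phyla_only:
        if phyla is None:
            raise SimulationError("phyla required for whole_phyla_only")
        for crown in _crown_nodes(tree, phyla).values():
            for nd in crown.preorder_iter():
                if nd is not crown:
                    inside_crown.add(id(nd))
    phylum_size: dict[str, int] = {}
    if phyla:
        for p in phyla.values():
            phylum_size[p] = phylum_size.get(p, 0) + 1

    def candidates(min_ph: int):
        out = []
        for node in tree.preorder_node_iter():
            if exclude_root and node is tree.seed_node:
                continue
            if id(node) in inside_crown:
                continue
            leaves = [nd.taxon.label for nd in node.leaf_iter()]
            if min_ph and phyla:
                contained = {phyla[lab] for lab in leaves}
                if any(phylum_size[p] < min_ph for p in contained):
                    continue
            out.append((abs(len(leaves) - target_size), node._iscutrace_index, node))
        return out

    for min_ph in (min_contained_phylum, 0):
        cand = candidates(min_ph)
        if cand:
            return min(cand)[2]
    raise SimulationError("no eligible clade node")


# ---------------------------------------------------------------------------
# Presence evolution
# ---------------------------------------------------------------------------


def evolve_presence(
    tree: dendropy.Tree,
    config: SimulationConfig,
    rng: np.random.Generator,
    iscu_gain_node: dendropy.Node | None = None,
    cyay_gain_node: dendropy.Node | None = None,
    forced_losses: dict[str, list[dendropy.Node]] | None = None,
):
    """Joint two-state Markov evolution of (iscU, cyaY) along the tree.

    The dependency rule is enforced per branch: cyaY can only switch on
    where iscU is present at the child, and iscU cannot be lost on a
    branch whose parent carries cyaY.  Forced gain nodes plant the
    families deterministically (iscU defaults to a gain at the root);
    ``forced_losses`` forces a loss on the stems of the given nodes.

    Returns ``(leaf_states, node_states, events)`` with
    ``leaf_states[family][taxon] -> bool``.
    """
    from .phylo import node_id, _index_nodes

    _index_nodes(tree)
    if iscu_gain_node is None:
        iscu_gain_node = tree.seed_node
    forced_losses = forced_losses or {}
    forced_loss_ids = {
        fam: {id(n) for n in nodes} for fam, nodes in forced_losses.items()
    }

    def p_event(rate: float, bl: float) -> float:
        return min(1.0, rate * max(bl, 0.0))

    node_states: dict[str, dict[str, bool]] = {"iscU": {}, "cyaY": {}}
    events: dict[str, list[dict]] = {"iscU": [], "cyaY": []}
    state: dict[int, tuple[bool, bool]] = {}

    for node in tree.preorder_node_iter():
        nid = node_id(node)
        if node is tree.seed_node:
            u = node is iscu_gain_node
            c = node is cyay_gain_node
            if c and not u:
                raise SimulationError("cyaY gain at a node without iscU")
            if u:
                events["iscU"].append({"branch": f"origin->{nid}", "type": "gain"})
            if c:
                events["cyaY"].append({"branch": f"origin->{nid}", "type": "gain"})
        else:
            parent = node.parent_node
            pu, pc = state[id(parent)]
            pid = node_id(parent)
            bl = node.edge.length or 0.0
            # iscU transition
            u = pu
            if node is iscu_gain_node:
                u = True
            elif pu:
                if id(node) in forced_loss_ids.get("iscU", set()):
                    u = False
                elif not pc and rng.random() < p_event(config.iscu_loss_rate, bl):
                    u = False  # loss forbidden while cyaY present
            else:
                if rng.random() < p_event(config.iscu_gain_rate, bl):
                    u = True
            # cyaY transition (gain requires iscU at the child)
            c = pc
            if node is cyay_gain_node:
                if not u:
                    raise SimulationError("cyaY gain planted on an iscU- branch")
                c = True
            elif pc:
                if id(node) in forced_loss_ids.get("cyaY", set()) or rng.random() < p_event(
                    config.cyay_loss_rate, bl
                ):
                    c = False
            else:
                if u and rng.random() < p_event(config.cyay_gain_rate, bl):
                    c = True
            if not u:
                c = False  # a forced iscU loss drags cyaY with it
            if u != pu:
                events["iscU"].append(
                    {"branch": f"{pid}->{nid}", "type": "gain" if u else "loss"}
                )
            if c != pc:
                events["cyaY"].append(
                    {"branch": f"{pid}->{nid}", "type": "gain" if c else "loss"}
                )
        state[id(node)] = (u, c)
        node_states["iscU"][nid] = u
        node_states["cyaY"][nid] = c

    leaf_states = {
        "iscU": {
            nd.taxon.label: state[id(nd)][0] for nd in tree.leaf_node_iter()
        },
        "cyaY": {
            nd.taxon.label: state[id(nd)][1] for nd in tree.leaf_node_iter()
        },
    }
    return leaf_states, node_states, events


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------


def evolve_sequences(
    tree: dendropy.Tree,
    profile: ProfileModel,
    config: SimulationConfig,
    rng: np.random.Generator,
    constrained_refs: tuple[int, ...] = (),
    residue_108_by_leaf: dict[str, str] | None = None,
) -> dict[str, str]:
    """Evolve family sequences along the tree by column-wise resampling.

    The root sequence is the profile consensus.  On each branch every
    unconstrained column is independently resampled from its empirical
    column distribution with probability ``min(1, subst_rate * length)``.
    Sampling uses the seed's observed residue counts (not the pseudocount-
    smoothed scoring frequencies), so every emitted residue carries positive
    support in the profile.  Constrained columns never change; if
    ``residue_108_by_leaf`` is given, the column mapped to reference
    position 108 is overwritten with the leaf's configured state at
    emission.
    """
    cols = profile.match_columns
    m = len(cols)
    freqs = np.stack([profile.columns[c].emission_frequencies() for c in cols])
    cum = np.cumsum(freqs, axis=1)
    ref_of = profile.ref_number_of_column
    constrained_idx = {
        k for k, c in enumerate(cols) if ref_of.get(c) in set(constrained_refs)
    }
    col108 = next(
        (k for k, c in enumerate(cols) if ref_of.get(c) == 108), None
    )
    free_idx = np.array(
        [k for k in range(m) if k not in constrained_idx and k != col108], dtype=int
    )

    root_seq = np.array([AMINO_ACIDS.index(a) for a in profile.consensus])
    out: dict[str, str] = {}
    seq_at: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            seq = seq_at[id(node)]
        else:
            parent_seq = seq_at[id(node.parent_node)]
            bl = node.edge.length or 0.0
            p = min(1.0, config.subst_rate * bl)
            seq = parent_seq.copy()
            if p > 0 and free_idx.size:
                mask = rng.random(free_idx.size) < p
                resample = free_idx[mask]
                if resample.size:
                    u = rng.random(resample.size)
                    for pos, uu in zip(resample, u):
                        seq[pos] = int(np.searchsorted(cum[pos], uu))
            seq_at[id(node)] = seq
        if node.is_leaf():
            leaf_seq = seq.copy()
            label = node.taxon.label
            if residue_108_by_leaf is not None and col108 is not None:
                aa = residue_108_by_leaf.get(label)
                if aa is not None:
                    if aa not in AMINO_ACIDS:
                        raise SimulationError(f"{aa!r} is not an amino acid")
                    leaf_seq[col108] = AMINO_ACIDS.index(aa)
            out[label] = "".join(AMINO_ACIDS[i] for i in leaf_seq)
    return out


def plan_residue_108(
    tree: dendropy.Tree,
    phyla: dict[str, str],
    config: SimulationConfig,
) -> tuple[dict[str, str], dendropy.Node]:
    """Assign the planted residue-108 state per leaf.

    One clade of ~``met_clade_size`` leaves is designated Met; every other
    leaf takes its phylum's state, cycling through ``residue_108_states``.
    """
    met_node = pick_clade_node(tree, config.met_clade_size, exclude_root=True)
    met_leaves = {nd.taxon.label for nd in met_node.leaf_iter()}
    phylum_names = sorted(set(phyla.values()))
    cycle = {
        name: config.residue_108_states[i % len(config.residue_108_states)]
        for i, name in enumerate(phylum_names)
    }
    states = {}
    for leaf in tree.leaf_node_iter():
        lab = leaf.taxon.label
        states[lab] = "M" if lab in met_leaves else cycle[phyla[lab]]
    return states, met_node


# ---------------------------------------------------------------------------
# HGT planting
# ---------------------------------------------------------------------------


def plant_hgt(
    tree: dendropy.Tree,
    presence: dict[str, dict[str, bool]],
    cyay_seqs: dict[str, str],
    phyla: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[dict]:
    """Transfer cyaY into ``n_hgt`` recipients from foreign-phylum donors.

    Recipients are iscU+/cyaY- leaves whose phylum contains no native cyaY;
    the recipient's sequence is a lightly diverged copy of the donor's.
    """
    if config.n_hgt == 0:
        return []
    donors_all = sorted(t for t, p in presence["cyaY"].items() if p)
    if not donors_all:
        raise SimulationError("no cyaY+ donors available for HGT")
    native_phyla = {phyla[t] for t in donors_all}
    eligible = sorted(
        t
        for t in presence["cyaY"]
        if not presence["cyaY"][t]
        and presence["iscU"][t]
        and phyla[t] not in native_phyla
    )
    if len(eligible) < config.n_hgt:
        raise SimulationError(
            f"only {len(eligible)} eligible HGT recipients for {config.n_hgt} transfers"
        )
    if not config.hgt_activates:
        raise SimulationError("HGT into a cyaY- recipient requires activation")
    # recipients land in distinct phyla: co-recipients in one phylum would
    # shield each other from the k-NN incongruence rule
    recipients: list[str] = []
    taken_phyla: set[str] = set()
    for i in rng.permutation(len(eligible)):
        t = eligible[int(i)]
        if phyla[t] in taken_phyla:
            continue
        recipients.append(t)
        taken_phyla.add(phyla[t])
        if len(recipients) == config.n_hgt:
            break
    if len(recipients) < config.n_hgt:
        raise SimulationError(
            f"cannot place {config.n_hgt} transfers in distinct recipient phyla"
        )
    events = []
    for rec in sorted(recipients):
        foreign_donors = [d for d in donors_all if phyla[d] != phyla[rec]]
        donor = foreign_donors[int(rng.integers(len(foreign_donors)))]
        seq = list(cyay_seqs[donor])
        for i in range(len(seq)):
            if rng.random() < config.hgt_divergence:
                seq[i] = AMINO_ACIDS[int(rng.integers(20))]
        cyay_seqs[rec] = "".join(seq)
        presence["cyaY"][rec] = True
        events.append({"donor": donor, "recipient": rec, "family": "cyaY"})
    return events


# ---------------------------------------------------------------------------
# Corpus assembly
# ---------------------------------------------------------------------------


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(20, size=length))


def _free_slot(rng: np.random.Generator, n: int, used: set[int], lo: int = 0, hi: int | None = None) -> int:
    hi = n if hi is None else hi
    for _ in range(1000):
        s = int(rng.integers(lo, hi))
        if s not in used:
            used.add(s)
            return s
    raise SimulationError("genome too small to place planted genes")


def synthesize_corpus(
    tree: dendropy.Tree,
    presence: dict[str, dict[str, bool]],
    iscu_seqs: dict[str, str],
    cyay_seqs: dict[str, str],
    residue_108: dict[str, str],
    phyla: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
    iscu_profile: ProfileModel,
) -> tuple[list[Genome], dict[str, dict[str, str]]]:
    """Embed planted family genes and decoys in random genomes.

    Returns the genome list and the truth label map
    ``taxon -> locus -> {iscU, cyaY, decoy_*}``.
    """
    taxa = sorted(t.label for t in tree.taxon_namespace)
    # distribute corpus-wide decoys over genomes
    decoy_assignment: dict[str, list[str]] = {t: [] for t in taxa}
    for kind, count in (
        ("decoy_nifu", config.decoy_nifu),
        ("decoy_sufu", config.decoy_sufu),
        ("decoy_struct", config.decoy_struct),
        ("decoy_random", config.decoy_random),
    ):
        for _ in range(count):
            decoy_assignment[taxa[int(rng.integers(len(taxa)))]].append(kind)

    motif_refs = set(
        range(seedlib.ISCU_MOTIF_START, seedlib.ISCU_MOTIF_START + len(seedlib.ISCU_MOTIF))
    )
    genomes: list[Genome] = []
    labels: dict[str, dict[str, str]] = {}

    for taxon in taxa:
        n = int(rng.integers(config.genes_min, config.genes_max + 1))
        proteins = [
            _random_protein(
                rng, int(rng.integers(config.protein_len_min, config.protein_len_max + 1))
            )
            for _ in range(n)
        ]
        annot = ["hypothetical"] * n
        tax_labels: dict[str, str] = {}
        used: set[int] = set()
        w = config.window

        def plant(seq: str, label_class: str, with_context: bool) -> None:
            slot = _free_slot(rng, n, used, lo=w, hi=n - w)
            proteins[slot] = seq
            tax_labels[f"{taxon}_g{slot:03d}"] = label_class
            if with_context:
                for _ in range(1000):
                    off = int(rng.integers(-w, w + 1))
                    if off != 0 and (slot + off) not in used:
                        ctx = slot + off
                        used.add(ctx)
                        annot[ctx] = ISC_NEIGHBOR_LABELS[
                            int(rng.integers(len(ISC_NEIGHBOR_LABELS)))
                        ]
                        break
                else:  # pragma: no cover - genomes are large enough
                    raise SimulationError("no free context slot")

        if presence["iscU"][taxon]:
            plant(iscu_seqs[taxon], "iscU", with_context=rng.random() < config.p_ctx)
        if presence["cyaY"][taxon]:
            plant(cyay_seqs[taxon], "cyaY", with_context=False)
        for kind in decoy_assignment[taxon]:
            if kind == "decoy_nifu":
                domain = _decoy_domain(iscu_profile, config, rng, scramble_motif=False)
                seq = domain + _random_protein(rng, config.nifu_extra_len)
                plant(seq, kind, with_context=True)
            elif kind == "decoy_sufu":
                seq = _decoy_domain(iscu_profile, config, rng, scramble_motif=True)
                plant(seq, kind, with_context=True)
            elif kind == "decoy_struct":
                plant(_random_protein(rng, seedlib.CYAY_LENGTH), kind, with_context=False)
            else:  # decoy_random
                plant(
                    _random_protein(
                        rng,
                        int(rng.integers(config.protein_len_min, config.protein_len_max + 1)),
                    ),
                    kind,
                    with_context=False,
                )

        genes = [
            Gene(
                locus_id=f"{taxon}_g{i:03d}",
                order_index=i,
                strand="+" if rng.random() < 0.5 else "-",
                protein=proteins[i],
                annotation_label=annot[i],
            )
            for i in range(n)
        ]
        genomes.append(
            Genome(
                taxon_id=taxon,
                name=f"synthetic species {taxon}",
                lineage={"domain": "Bacteria", "phylum": phyla[taxon]},
                genes=genes,
            )
        )
        labels[taxon] = tax_labels
    return genomes, labels


def _decoy_domain(
    profile: ProfileModel,
    config: SimulationConfig,
    rng: np.random.Generator,
    scramble_motif: bool,
) -> str:
    """A profile-faithful domain; SufU-like decoys get a scrambled motif."""
    cols = profile.match_columns
    ref_of = profile.ref_number_of_column
    seq = list(profile.consensus)
    freqs = np.stack([profile.columns[c].emission_frequencies() for c in cols])
    cum = np.cumsum(freqs, axis=1)
    constrained = set(seedlib.ISCU_CONSTRAINED_REFS)
    for k, c in enumerate(cols):
        if ref_of.get(c) in constrained:
            continue
        if rng.random() < 0.1:
            seq[k] = AMINO_ACIDS[int(np.searchsorted(cum[k], rng.random()))]
    if scramble_motif:
        for k, c in enumerate(cols):
            ref = ref_of.get(c)
            if ref is not None and seedlib.ISCU_MOTIF_START <= ref < seedlib.ISCU_MOTIF_START + len(
                seedlib.ISCU_MOTIF
            ):
                seq[k] = "G"  # GGGGG: breaks the fixed prolines and the budget
    return "".join(seq)


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------


def simulate_corpus(
    config: SimulationConfig,
    outdir=None,
) -> tuple[list[Genome], SimulationTruth, dendropy.Tree]:
    """Full generation: tree, histories, sequences, genomes, truth (+ files)."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(5)]
    r_presence, r_seq_u, r_seq_c, r_hgt, r_genome = rngs

    tree = simulate_tree(config.n_taxa, config.birth_rate, config.seed)
    phyla = assign_phyla(tree, config.n_phyla, min_size=config.min_phylum_size)
    deepen_stems(tree, phyla, config.stem_scale)
    cyay_node = pick_clade_node(
        tree,
        config.cyay_clade_size,
        phyla=phyla,
        whole_phyla_only=True,
        min_contained_phylum=3,
        exclude_root=True,
    )
    presence, node_states, presence_events = evolve_presence(
        tree, config, r_presence, cyay_gain_node=cyay_node
    )

    iscu_profile = build_profile(seedlib.iscu_seed())
    cyay_profile = build_profile(seedlib.cyay_seed())

    residue_108, _met_node = plan_residue_108(tree, phyla, config)
    iscu_seqs = evolve_sequences(
        tree,
        iscu_profile,
        config,
        r_seq_u,
        constrained_refs=seedlib.ISCU_CONSTRAINED_REFS,
        residue_108_by_leaf=residue_108,
    )
    cyay_seqs = evolve_sequences(tree, cyay_profile, config, r_seq_c)

    hgt_events = plant_hgt(tree, presence, cyay_seqs, phyla, config, r_hgt)

    genomes, labels = synthesize_corpus(
        tree,
        presence,
        iscu_seqs,
        cyay_seqs,
        residue_108,
        phyla,
        config,
        r_genome,
        iscu_profile,
    )
    truth = SimulationTruth(
        seed=config.seed,
        tree_newick=tree.as_string(schema="newick").strip(),
        presence=presence,
        node_states=node_states,
        presence_events=presence_events,
        labels=labels,
        residue_108={t: residue_108[t] for t in sorted(residue_108) if presence["iscU"][t]},
        hgt_events=hgt_events,
        phyla=phyla,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_corpus(genomes, outdir)
        tree.write(path=str(outdir / "tree.nwk"), schema="newick")
        truth.to_json(outdir / "truth.json")
        seeds_dir = outdir / "seeds"
        seeds_dir.mkdir(exist_ok=True)
        seedlib.iscu_seed().to_fasta(seeds_dir / "iscu_seed.fasta")
        seedlib.cyay_seed().to_fasta(seeds_dir / "cyay_seed.fasta")
    return genomes, truth, tree
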