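"""Phylogenetic profiling: co-occurrence, parsimony reconstruction, HGT flags.

Presence/absence of the two gene families (cyaY, iscU) across the corpus is
analyzed three ways:

- a co-occurrence report testing the containment claim (every cyaY+ species
  is also iscU+);
- ancestral gain/loss reconstruction on the rooted species tree under
  either Fitch parsimony (unrestricted changes, Hartigan's count algorithm,
  exact on polytomies) or Dollo parsimony (a single gain at the MRCA of the
  present leaves, losses minimized below it);
- a taxonomic-incongruence rule on a neighbor-joining gene tree that flags
  leaves whose nearest gene-tree neighbors all belong to a foreign phylum
  as horizontal-transfer candidates.

Both parsimony modes are reported side by side because presence patterns
like a patchy subclade cannot distinguish a loss-heavy single-origin
scenario from independent gains.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd


class PhyloError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Presence/absence matrix & co-occurrence
# ---------------------------------------------------------------------------


def build_matrix(
    present: dict[str, set[str]],
    corpus_taxa: list[str],
    families: tuple[str, ...] = ("cyaY", "iscU"),
) -> pd.DataFrame:
    """Taxa x family boolean table from per-family accepted-taxon sets."""
    taxa = list(corpus_taxa)
    known = set(taxa)
    for fam, members in present.items():
        unknown = members - known
        if unknown:
            raise PhyloError(f"{fam} hit in unknown taxa: {sorted(unknown)}")
    data = {
        fam: [t in present.get(fam, set()) for t in taxa] for fam in families
    }
    return pd.DataFrame(data, index=pd.Index(taxa, name="taxon_id"))


@dataclass
class CooccurrenceReport:
    counts: dict[tuple[bool, bool], int]  # (cyaY, iscU) -> n taxa
    violations: list[str]  # taxa with cyaY present but iscU absent

    @property
    def n_taxa(self) -> int:
        return sum(self.counts.values())


def cooccurrence_report(matrix: pd.DataFrame) -> CooccurrenceReport:
    """Count the four (cyaY, iscU) presence combinations; list violations."""
    counts = {(a, b): 0 for a in (True, False) for b in (True, False)}
    violations = []
    for taxon, row in matrix.iterrows():
        key = (bool(row["cyaY"]), bool(row["iscU"]))
        counts[key] += 1
        if key == (True, False):
            violations.append(str(taxon))
    return CooccurrenceReport(counts=counts, violations=sorted(violations))


def clade_summary(matrix: pd.DataFrame, taxonomy: dict[str, str]) -> pd.DataFrame:
    """Per-clade 'x genomes encoding ... out of n available' style summary."""
    rows = []
    groups: dict[str, list[str]] = {}
    for taxon in matrix.index:
        groups.setdefault(taxonomy.get(str(taxon), "unknown"), []).append(str(taxon))
    for clade in sorted(groups):
        sub = matrix.loc[groups[clade]]
        rows.append(
            {
                "clade": clade,
                "n_genomes": len(sub),
                "n_cyaY": int(sub["cyaY"].sum()),
                "n_iscU": int(sub["iscU"].sum()),
            }
        )
    return pd.DataFrame(rows, columns=["clade", "n_genomes", "n_cyaY", "n_iscU"])


# ---------------------------------------------------------------------------
# Parsimony reconstruction
# ---------------------------------------------------------------------------


@dataclass
class AncestralReconstruction:
    mode: str  # "fitch" | "dollo"
    node_states: dict[str, bool]
    events: list[tuple[str, str, str]]  # (parent_id, child_id, "gain"|"loss")
    cost: int

    @property
    def gains(self) -> list[tuple[str, str, str]]:
        return [e for e in self.events if e[2] == "gain"]

    @property
    def losses(self) -> list[tuple[str, str, str]]:
        return [e for e in self.events if e[2] == "loss"]


def node_id(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    if node.label:
        return node.label
    return f"N{node._iscutrace_index}"


def _index_nodes(tree: dendropy.Tree) -> None:
    for i, node in enumerate(tree.preorder_node_iter()):
        node._iscutrace_index = i


def reconstruct(
    tree: dendropy.Tree,
    leaf_states: dict[str, bool],
    mode: str = "dollo",
) -> AncestralReconstruction:
    """Ancestral presence/absence by parsimony on a rooted tree.

    Fitch mode uses Hartigan's count algorithm (minimum changes, exact on
    multifurcations) with root ties resolved to *absent*; the event list is
    exactly the set of branches whose endpoints differ in state.  Dollo mode
    places the single gain on the stem of the MRCA of all present leaves and
    adds one loss on the stem of every maximal present-free subtree below
    it; its cost is losses + 1.
    """
    _index_nodes(tree)
    leaves = [nd for nd in tree.leaf_node_iter()]
    for nd in leaves:
        if nd.taxon.label not in leaf_states:
            raise PhyloError(f"leaf {nd.taxon.label!r} has no state")

    if mode == "fitch":
        return _fitch(tree, leaf_states)
    if mode == "dollo":
        return _dollo(tree, leaf_states)
    raise PhyloError(f"unknown mode {mode!r}")


def _fitch(tree: dendropy.Tree, leaf_states: dict[str, bool]) -> AncestralReconstruction:
    pref: dict[int, set[bool]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            pref[id(node)] = {leaf_states[node.taxon.label]}
            continue
        count = {True: 0, False: 0}
        for ch in node.child_nodes():
            for s in pref[id(ch)]:
                count[s] += 1
        m = max(count.values())
        pref[id(node)] = {s for s, c in count.items() if c == m}

    states: dict[str, bool] = {}
    root = tree.seed_node
    # root tie -> absent
    root_state = False if False in pref[id(root)] else True
    states[node_id(root)] = root_state
    assignment: dict[int, bool] = {id(root): root_state}
    events: list[tuple[str, str, str]] = []
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_state = assignment[id(node.parent_node)]
        if parent_state in pref[id(node)]:
            st = parent_state
        else:
            # tie between candidate states resolves to absent
            st = False if False in pref[id(node)] else True
        assignment[id(node)] = st
        states[node_id(node)] = st
        if st != parent_state:
            events.append(
                (node_id(node.parent_node), node_id(node), "gain" if st else "loss")
            )
    return AncestralReconstruction(
        mode="fitch", node_states=states, events=events, cost=len(events)
    )


def _dollo(tree: dendropy.Tree, leaf_states: dict[str, bool]) -> AncestralReconstruction:
    present_leaves = [
        nd for nd in tree.leaf_node_iter() if leaf_states[nd.taxon.label]
    ]
    if not present_leaves:
        states = {node_id(nd): False for nd in tree.preorder_node_iter()}
        return AncestralReconstruction("dollo", states, [], 0)

    # has_present[node]: any present leaf below (or at) the node
    has_present: dict[int, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            has_present[id(node)] = leaf_states[node.taxon.label]
        else:
            has_present[id(node)] = any(has_present[id(c)] for c in node.child_nodes())

    if len(present_leaves) == 1:
        gain_node = present_leaves[0]
    else:
        gain_node = tree.mrca(taxa=[nd.taxon for nd in present_leaves])

    states: dict[str, bool] = {}
    events: list[tuple[str, str, str]] = []
    inside: dict[int, bool] = {}
    for node in tree.preorder_node_iter():
        if node is gain_node:
            inside[id(node)] = True
        elif node.parent_node is not None and inside.get(id(node.parent_node), False):
            inside[id(node)] = True
        else:
            inside[id(node)] = False
        st = inside[id(node)] and has_present[id(node)]
        # a present internal node with an absent child subtree => loss branch
        states[node_id(node)] = st
        if node is gain_node:
            parent = node.parent_node
            events.append(
                (node_id(parent) if parent is not None else "origin", node_id(node), "gain")
            )
        elif inside[id(node)] and node.parent_node is not None:
            parent_st = states[node_id(node.parent_node)]
            if parent_st and not st:
                events.append((node_id(node.parent_node), node_id(node), "loss"))
        # prune: below a lost stem everything stays absent
        if not st:
            inside[id(node)] = False
    n_losses = sum(1 for e in events if e[2] == "loss")
    return AncestralReconstruction(
        mode="dollo", node_states=states, events=events, cost=n_losses + 1
    )


def events_to_frame(
    reconstructions: dict[tuple[str, str], AncestralReconstruction]
) -> pd.DataFrame:
    """(family, mode) -> reconstruction, flattened to an events table."""
    rows = []
    for (family, mode), rec in sorted(reconstructions.items()):
        for parent, child, etype in rec.events:
            rows.append(
                {
                    "family": family,
                    "mode": mode,
                    "branch": f"{parent}->{child}",
                    "event": etype,
                }
            )
    return pd.DataFrame(rows, columns=["family", "mode", "branch", "event"])


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(distances: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Neighbor-joining agglomeration with deterministic tie-breaks.

    Ties in the Q criterion are broken by the smallest (i, j) index pair in
    the current matrix order.  Negative branch lengths are clamped to zero
    with the deficit moved onto the sister branch, preserving the pair's
    summed length.
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise PhyloError("distance matrix must be symmetric with zero diagonal")
    if len(labels) != n:
        raise PhyloError("labels do not match matrix size")
    if n < 3:
        raise PhyloError("need at least 3 taxa")

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = taxa.get_taxon(lab)
        nodes.append(nd)

    D = D.copy()
    active = list(range(n))

    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = (np.inf, None, None)
        for a in range(k):
            for b in range(a + 1, k):
                if Q[a, b] < best[0] - 1e-12:
                    best = (Q[a, b], a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = D[i, j]
        li = dij / 2.0 + (r[a] - r[b]) / (2.0 * (k - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj

        # distances from the new node u to every other active node
        newd = np.zeros(D.shape[0] + 1)
        for c in active:
            if c in (i, j):
                continue
            newd[c] = 0.5 * (D[i, c] + D[j, c] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newd[:-1]
        D[:-1, -1] = newd[:-1]
        nodes.append(parent)
        active = [c for c in active if c not in (i, j)] + [len(nodes) - 1]

    # connect the last three through the central node (three-point formulas)
    x, y, z = active
    dxy, dxz, dyz = D[x, y], D[x, z], D[y, z]
    lx = max((dxy + dxz - dyz) / 2.0, 0.0)
    ly = max((dxy + dyz - dxz) / 2.0, 0.0)
    lz = max((dxz + dyz - dxy) / 2.0, 0.0)
    center = dendropy.Node()
    for nd, ln in ((nodes[x], lx), (nodes[y], ly), (nodes[z], lz)):
        center.add_child(nd)
        nd.edge.length = ln
    tree.seed_node = center
    tree.is_rooted = False
    tree.update_taxon_namespace()
    return tree


def profile_identity_distances(
    aligned: dict[str, dict[int, str]]
) -> tuple[list[str], np.ndarray]:
    """1 - identity over shared aligned profile columns, per sequence pair.

    ``aligned`` maps a sequence id to its reference-position -> residue map
    (from the profile alignment).  Pairs with no shared columns get the
    maximal distance 1.
    """
    labels = sorted(aligned)
    n = len(labels)
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            ra, rb = aligned[labels[a]], aligned[labels[b]]
            shared = set(ra) & set(rb)
            if not shared:
                d = 1.0
            else:
                ident = sum(1 for c in shared if ra[c] == rb[c])
                d = 1.0 - ident / len(shared)
            D[a, b] = D[b, a] = d
    return labels, D


# ---------------------------------------------------------------------------
# HGT flagging
# ---------------------------------------------------------------------------


@dataclass
class HgtFlag:
    taxon_id: str
    family: str
    evidence: float  # fraction of k nearest gene-tree leaves from a foreign phylum
    flagged: bool


def flag_hgt(
    gene_tree: dendropy.Tree,
    taxonomy: dict[str, str],
    family: str = "cyaY",
    k: int = 3,
    threshold: float = 1.0,
) -> list[HgtFlag]:
    """Flag taxa whose k nearest gene-tree neighbors sit in a foreign phylum.

    A leaf is flagged when the foreign fraction among its k nearest leaves
    (patristic distance, ties broken by label) reaches ``threshold`` and
    fewer than 2 of those k share its own phylum.
    """
    if k < 1:
        raise PhyloError("k must be >= 1")
    pdm = gene_tree.phylogenetic_distance_matrix()
    leaves = sorted(gene_tree.taxon_namespace, key=lambda t: t.label)
    for t in leaves:
        if t.label not in taxonomy:
            raise PhyloError(f"leaf {t.label!r} absent from taxonomy")
    flags = []
    for t in leaves:
        others = sorted(
            ((pdm.patristic_distance(t, o), o.label) for o in leaves if o is not t),
            key=lambda x: (x[0], x[1]),
        )
        nearest = others[: min(k, len(others))]
        if not nearest:
            continue
        own = taxonomy[t.label]
        n_foreign = sum(1 for _, lab in nearest if taxonomy[lab] != own)
        n_own = len(nearest) - n_foreign
        evidence = n_foreign / len(nearest)
        flags.append(
            HgtFlag(
                taxon_id=t.label,
                family=family,
                evidence=evidence,
                flagged=bool(evidence >= threshold and n_own < 2),
            )
        )
    return flags


def hgt_flags_to_frame(flags: list[HgtFlag]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon_id": f.taxon_id,
                "family": f.family,
                "evidence": round(f.evidence, 6),
                "flagged": f.flagged,
            }
            for f in flags
        ],
        columns=["taxon_id", "family", "evidence", "flagged"],
    )
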