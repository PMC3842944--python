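"""Gene-tree / species-tree reconciliation by LCA parsimony.

Each gene-tree node g is mapped to the species-tree node M(g), the lowest
common ancestor of the species carried by the leaves under g.  A node is a
duplication when it maps to the same species node as one of its children;
otherwise it is a speciation.  Losses are counted per gene-tree edge as the
number of species-tree nodes skipped between the images of parent and
child: depth(M(child)) - depth(M(parent)) - 1, plus one extra loss when the
parent is a duplication whose child image moved (the sibling copy produced
by the duplication must have died out along the skipped branch).

This is the classical parsimony reconciliation — the unique mapping that
minimizes duplications, and among duplication-minimal mappings also the
losses.  It covers the mutual-gene-loss scenarios seen in family histories
(an ancient duplication followed by independent losses in descendant
lineages) and drives the ortholog/in-paralog calls: two same-species genes
are in-paralogs relative to a species pair when their gene-tree LCA maps
strictly below the pair's divergence node, i.e. the duplication postdates
the speciation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy


def _parse_tree(tree: "str | dendropy.Tree") -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)


class SpeciesTree:
    """A rooted binary species tree with node depths and LCA queries."""

    def __init__(self, tree: "str | dendropy.Tree"):
        self.tree = _parse_tree(tree)
        labels = [t.label for t in self.tree.taxon_namespace]
        if len(set(labels)) < len(labels):
            raise ValueError("duplicate species labels")
        self.depth: dict[dendropy.Node, int] = {}
        self.parent: dict[dendropy.Node, dendropy.Node | None] = {}
        self.leaf_node: dict[str, dendropy.Node] = {}
        for node in self.tree.preorder_node_iter():
            p = node.parent_node
            self.parent[node] = p
            self.depth[node] = 0 if p is None else self.depth[p] + 1
            kids = node.child_nodes()
            if kids and len(kids) != 2:
                raise ValueError("species tree must be binary")
            if node.is_leaf():
                self.leaf_node[node.taxon.label] = node

    @property
    def species(self) -> set[str]:
        return set(self.leaf_node)

    def lca(self, a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
        while a is not b:
            if self.depth[a] < self.depth[b]:
                b = self.parent[b]
            else:
                a = self.parent[a]
        return a

    def node_label(self, node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label
        return "+".join(sorted(l.taxon.label for l in node.leaf_iter()))

    def is_strict_descendant(self, node: dendropy.Node, anc: dendropy.Node) -> bool:
        cur = self.parent[node]
        while cur is not None:
            if cur is anc:
                return True
            cur = self.parent[cur]
        return False


@dataclass
class ReconciliationResult:
    """Per-node events, the LCA map, and aggregate duplication/loss counts."""

    n_duplications: int
    n_losses: int
    node_events: dict[frozenset, str]  # leaf-set of the clade -> event
    mapping: dict[frozenset, str]  # leaf-set -> mapped species-tree node label
    inparalog_groups: list[frozenset] = field(default_factory=list)
    # internal handles used by call_inparalogs
    _gene_tree: dendropy.Tree | None = None
    _species_tree: SpeciesTree | None = None
    _node_map: dict = field(default_factory=dict)
    _gene_species: dict[str, str] = field(default_factory=dict)

    def events_table(self) -> list[dict]:
        rows = []
        for clade, event in sorted(
            self.node_events.items(), key=lambda kv: sorted(kv[0])
        ):
            rows.append(
                {
                    "clade": ",".join(sorted(clade)),
                    "event": event,
                    "mapped_species_node": self.mapping[clade],
                }
            )
        return rows

    def summary(self) -> dict:
        return {
            "n_duplications": self.n_duplications,
            "n_losses": self.n_losses,
            "inparalog_groups": [sorted(g) for g in self.inparalog_groups],
        }


def reconcile(
    gene_tree: "str | dendropy.Tree",
    species_tree: "str | SpeciesTree | dendropy.Tree",
    gene_species: Mapping[str, str],
) -> ReconciliationResult:
    """Reconcile a rooted binary gene tree against a species tree.

    Parameters
    ----------
    gene_tree
        Rooted binary gene tree (newick or dendropy).
    species_tree
        Rooted binary species tree.
    gene_species
        Map from gene-tree leaf label to species label.

    Returns
    -------
    ReconciliationResult with duplication/speciation calls per internal
    node, loss counts, and same-species in-paralog groups (maximal
    single-species clades with at least two leaves).
    """
    gt = _parse_tree(gene_tree)
    st = species_tree if isinstance(species_tree, SpeciesTree) else SpeciesTree(species_tree)

    node_map: dict[dendropy.Node, dendropy.Node] = {}
    leafset: dict[dendropy.Node, frozenset] = {}
    events: dict[frozenset, str] = {}
    mapping: dict[frozenset, str] = {}
    n_dup = 0
    n_loss = 0

    for node in gt.postorder_node_iter():
        kids = node.child_nodes()
        if node.is_leaf():
            label = node.taxon.label
            sp = gene_species.get(label)
            if sp is None:
                raise KeyError(f"gene leaf {label!r} has no species assignment")
            if sp not in st.leaf_node:
                raise KeyError(f"species {sp!r} not in species tree")
            node_map[node] = st.leaf_node[sp]
            leafset[node] = frozenset([label])
        else:
            if len(kids) != 2:
                raise ValueError("gene tree must be binary")
            node_map[node] = st.lca(node_map[kids[0]], node_map[kids[1]])
            leafset[node] = leafset[kids[0]] | leafset[kids[1]]
            is_dup = any(node_map[c] is node_map[node] for c in kids)
            events[leafset[node]] = "duplication" if is_dup else "speciation"
            if is_dup:
                n_dup += 1
        mapping[leafset[node]] = st.node_label(node_map[node])

    # loss accounting per gene-tree edge
    for node in gt.postorder_node_iter():
        if node.is_leaf():
            continue
        is_dup = events[leafset[node]] == "duplication"
        for c in node.child_nodes():
            d = st.depth[node_map[c]] - st.depth[node_map[node]]
            if is_dup:
                n_loss += d  # (d - 1) skipped nodes + 1 lost sibling copy, 0 if d == 0
            else:
                n_loss += d - 1

    groups = _maximal_single_species_clades(gt, gene_species, leafset)
    return ReconciliationResult(
        n_duplications=n_dup,
        n_losses=n_loss,
        node_events=events,
        mapping=mapping,
        inparalog_groups=groups,
        _gene_tree=gt,
        _species_tree=st,
        _node_map=node_map,
        _gene_species=dict(gene_species),
    )


def _maximal_single_species_clades(
    gt: dendropy.Tree, gene_species: Mapping[str, str], leafset: Mapping
) -> list[frozenset]:
    """Maximal clades whose leaves all share one species, with >= 2 leaves."""
    species_of: dict[dendropy.Node, str | None] = {}
    for node in gt.postorder_node_iter():
        if node.is_leaf():
            species_of[node] = gene_species[node.taxon.label]
        else:
            sp = {species_of[c] for c in node.child_nodes()}
            species_of[node] = sp.pop() if len(sp) == 1 and None not in sp else None
    groups = []
    for node in gt.preorder_node_iter():
        if node.is_leaf():
            continue
        p = node.parent_node
        if species_of[node] is not None and (p is None or species_of[p] is None):
            groups.append(leafset[node])
    return sorted(groups, key=lambda g: sorted(g))


def call_inparalogs(
    result: ReconciliationResult, species_pair: tuple[str, str]
) -> dict[str, list[frozenset]]:
    """In-paralog sets relative to a species pair's divergence.

    Two genes of the same species are in-paralogs relative to the pair when
    their gene-tree LCA maps strictly below the species-pair LCA — the
    duplication that separated them happened after the two species diverged.
    Returns, for each species of the pair, the groups with >= 2 genes.
    """
    a, b = species_pair
    if a == b:
        raise ValueError("species_pair must name two distinct species")
    st = result._species_tree
    gt = result._gene_tree
    if st is None or gt is None:
        raise ValueError("result lacks tree handles; produce it via reconcile()")
    for sp in (a, b):
        if sp not in st.leaf_node:
            raise KeyError(f"species {sp!r} not in species tree")
    pair_lca = st.lca(st.leaf_node[a], st.leaf_node[b])

    node_map = result._node_map
    # genes per species of interest
    leaves = {
        sp: [n for n in gt.leaf_node_iter() if result._gene_species[n.taxon.label] == sp]
        for sp in (a, b)
    }

    def gene_lca(x: dendropy.Node, y: dendropy.Node) -> dendropy.Node:
        ax = set()
        cur = x
        while cur is not None:
            ax.add(id(cur))
            cur = cur.parent_node
        cur = y
        while cur is not None:
            if id(cur) in ax:
                return cur
            cur = cur.parent_node
        raise RuntimeError("disconnected gene tree")  # pragma: no cover

    out: dict[str, list[frozenset]] = {}
    for sp, nodes in leaves.items():
        # equivalence: LCA maps strictly below pair_lca
        groups: list[list[dendropy.Node]] = []
        for n in nodes:
            placed = False
            for g in groups:
                anc = gene_lca(n, g[0])
                if st.is_strict_descendant(node_map[anc], pair_lca):
                    g.append(n)
                    placed = True
                    break
            if not placed:
                groups.append([n])
        out[sp] = [
            frozenset(x.taxon.label for x in g) for g in groups if len(g) >= 2
        ]
    return out
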