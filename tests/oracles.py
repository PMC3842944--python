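"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: clustering is done
by pairwise union-find over all hit pairs, and reconciliation by exhaustive
enumeration of every valid gene-node -> species-node map, scoring each
map's duplication and loss events and taking the parsimony minimum.
"""

from __future__ import annotations

import itertools

import dendropy


# ----------------------------------------------------- clustering oracle

def brute_force_cluster_count(hits, cutoff: int) -> int:
    """Connected components of the pairwise gap graph (O(n^2) union-find)."""
    parent = list(range(len(hits)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    for i, j in itertools.combinations(range(len(hits)), 2):
        a, b = hits[i], hits[j]
        if a.target_seq_id != b.target_seq_id:
            continue
        gap = max(
            0,
            max(a.target_start, b.target_start)
            - min(a.target_end, b.target_end)
            - 1,
        )
        if gap <= cutoff:
            union(i, j)
    return len({find(i) for i in range(len(hits))})


# -------------------------------------------------- reconciliation oracle

def _species_index(newick: str):
    st = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    nodes = list(st.preorder_node_iter())
    idx = {id(n): i for i, n in enumerate(nodes)}
    parent = {idx[id(n)]: (idx[id(n.parent_node)] if n.parent_node else None)
              for n in nodes}
    depth = {}
    for i, n in enumerate(nodes):
        p = parent[i]
        depth[i] = 0 if p is None else depth[p] + 1
    leaf_of = {n.taxon.label: idx[id(n)] for n in st.leaf_node_iter()}
    ancestors = {}
    for i in range(len(nodes)):
        chain = []
        cur = i
        while cur is not None:
            chain.append(cur)
            cur = parent[cur]
        ancestors[i] = set(chain)
    return nodes, parent, depth, leaf_of, ancestors


def brute_force_min_events(gene_newick: str, species_newick: str, gene_species):
    """Minimum (duplications, losses) over every valid reconciliation map.

    A map assigns each gene-tree node a species-tree node such that leaves
    map to their own species and every parent maps at-or-above its
    children's images.  Each map is scored by the standard event rules and
    the map with minimum duplications + losses is returned (ties broken by
    fewer duplications).
    """
    nodes, parent, depth, leaf_of, ancestors = _species_index(species_newick)

    def lca(a, b):
        common = ancestors[a] & ancestors[b]
        return max(common, key=lambda x: depth[x])

    gt = dendropy.Tree.get(data=gene_newick, schema="newick",
                           preserve_underscores=True)
    gnodes = list(gt.postorder_node_iter())
    internal = [g for g in gnodes if not g.is_leaf()]
    fixed = {id(g): leaf_of[gene_species[g.taxon.label]]
             for g in gnodes if g.is_leaf()}

    best = None
    for combo in itertools.product(range(len(nodes)), repeat=len(internal)):
        assign = dict(fixed)
        for g, s in zip(internal, combo):
            assign[id(g)] = s
        ok = True
        for g in internal:
            for c in g.child_nodes():
                if assign[id(g)] not in ancestors[assign[id(c)]]:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        dups = losses = 0
        for g in internal:
            m = assign[id(g)]
            c1, c2 = g.child_nodes()
            a, b = assign[id(c1)], assign[id(c2)]
            is_spec = (
                m == lca(a, b)
                and a != m
                and b != m
            )
            if not is_spec:
                dups += 1
            for c_img in (a, b):
                d = depth[c_img] - depth[m]
                losses += (d - 1) if is_spec else d
        score = (dups + losses, dups)
        if best is None or score < best[0]:
            best = (score, dups, losses)
    return best[1], best[2]


# ---------------------------------------- gene-tree shape enumeration

def all_gene_tree_shapes(n_leaves: int, species=("A", "B", "C")):
    """All rooted binary gene-tree shapes with leaves labeled by species,
    up to isomorphism, as canonical nested tuples."""

    def merge(left_set, right_set):
        return {
            tuple(sorted((l, r), key=repr)) for l in left_set for r in right_set
        }

    shapes = {1: set(species)}
    for n in range(2, n_leaves + 1):
        acc = set()
        for i in range(1, n // 2 + 1):
            acc |= merge(shapes[i], shapes[n - i])
        shapes[n] = acc
    return [s for n in range(2, n_leaves + 1) for s in shapes[n]]


def shape_to_newick(shape) -> tuple[str, dict]:
    """Canonical shape tuple -> (newick, leaf -> species map)."""
    counter = {}
    mapping = {}

    def render(node):
        if isinstance(node, str):
            counter[node] = counter.get(node, 0) + 1
            label = f"{node}{counter[node]}"
            mapping[label] = node
            return label
        return "(" + ",".join(render(c) for c in node) + ")"

    return render(shape) + ";", mapping
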