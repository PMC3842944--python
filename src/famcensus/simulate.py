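"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates the *shape* of the real inputs — predicted
proteomes with domain-hit tables, protein-vs-genome hit tables, gene and
species trees, FPKM tables — while planting a known truth that the
corresponding pipeline stage must recover exactly:

* ``gen_proteome`` plants true family members (both core domains, high
  profile score, adequate length) among decoys that each violate exactly
  one calling rule (single-domain, or fragment-length).
* ``gen_genome_hits`` plants gene loci at controlled spacings so the
  expected single-linkage cluster count under any distance cutoff follows
  directly from the planted gaps.
* ``gen_trees`` plants duplication and loss events into a gene tree such
  that LCA reconciliation provably recovers the planted counts:
  duplications are grafted as sister copies of event-free gene-tree leaves
  (+1 duplication, 0 losses each) and losses prune species leaves whose
  sibling subtree keeps survivors (+1 loss each).
* ``gen_fpkm_table`` draws FPKM values inside planned category intervals.

Protein sequences are uniform random residues over the 20-letter alphabet
and domain matches are emitted directly as table rows; the pipeline's
decision logic, not a search engine, is what these fixtures exercise.
All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from famcensus.recall import GenomicHit
from famcensus.reconcile import SpeciesTree
from famcensus.scan import DomainHit, ProteinRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


# ------------------------------------------------------------- proteome

@dataclass(frozen=True)
class SimProteomeSpec:
    """Composition of a synthetic proteome.

    ``n_true`` proteins carry the full calling evidence; single-domain
    decoys lack one of the two core domains; short decoys have the full
    architecture but length <= 200 aa.  ``length_range`` bounds the length
    of full-length proteins and must start above 200 so that planted true
    members pass the fragment filter.
    """

    n_true: int = 5
    n_decoys_single_domain: int = 3
    n_decoys_short: int = 2
    length_range: tuple[int, int] = (400, 1200)
    species: str = "synthspecies"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_true", "n_decoys_single_domain", "n_decoys_short"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.length_range
        if lo <= 200:
            raise ValueError("length_range must start above 200 aa")
        if hi < lo:
            raise ValueError("length_range must be (lo, hi) with hi >= lo")


@dataclass
class SimProteome:
    proteins: list[ProteinRecord]
    domain_hits: list[DomainHit]
    scores: dict[str, float]
    truth: pd.DataFrame  # columns: protein_id, is_true, decoy_class

    @property
    def true_ids(self) -> set[str]:
        return set(self.truth.loc[self.truth.is_true, "protein_id"])


def _core_domain_hits(
    rng: np.random.Generator, pid: str, length: int
) -> list[DomainHit]:
    # SNF2_N then Helicase_C, both inside the protein, E far below 1e-3
    snf_len = min(180, length // 3)
    hel_len = min(120, length // 4)
    snf_start = int(rng.integers(1, max(2, length - snf_len - hel_len - 10)))
    snf_end = snf_start + snf_len - 1
    hel_start = snf_end + int(rng.integers(1, 10))
    hel_end = min(length, hel_start + hel_len - 1)
    e1, e2 = 10.0 ** (-rng.uniform(5, 30, size=2))
    return [
        DomainHit(pid, "SNF2_N", snf_start, snf_end, float(e1), float(rng.uniform(80, 300))),
        DomainHit(pid, "Helicase_C", hel_start, hel_end, float(e2), float(rng.uniform(50, 200))),
    ]


def gen_proteome(spec: SimProteomeSpec) -> SimProteome:
    """Generate a proteome with planted family members and decoys."""
    rng = _rng(spec.seed)
    proteins: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    scores: dict[str, float] = {}
    truth_rows: list[tuple[str, bool, str]] = []
    lo, hi = spec.length_range

    for i in range(spec.n_true):
        pid = f"true{i + 1:03d}.1"
        length = int(rng.integers(lo, hi + 1))
        proteins.append(
            ProteinRecord(
                id=pid,
                sequence=_random_seq(rng, length),
                species=spec.species,
                gene_id=pid.rsplit(".", 1)[0],
                description="Snf2 family ATPase",
            )
        )
        hits.extend(_core_domain_hits(rng, pid, length))
        scores[pid] = float(rng.uniform(250, 600))
        truth_rows.append((pid, True, ""))

    for i in range(spec.n_decoys_single_domain):
        pid = f"single{i + 1:03d}.1"
        length = int(rng.integers(lo, hi + 1))
        proteins.append(
            ProteinRecord(
                id=pid,
                sequence=_random_seq(rng, length),
                species=spec.species,
                gene_id=pid.rsplit(".", 1)[0],
                description="helicase-like protein",
            )
        )
        # keep exactly one of the two core domains, alternating
        pair = _core_domain_hits(rng, pid, length)
        hits.append(pair[i % 2])
        scores[pid] = float(rng.uniform(250, 600))
        truth_rows.append((pid, False, "single_domain"))

    for i in range(spec.n_decoys_short):
        pid = f"short{i + 1:03d}.1"
        length = int(rng.integers(120, 201))  # <= 200 aa fragment
        proteins.append(
            ProteinRecord(
                id=pid,
                sequence=_random_seq(rng, length),
                species=spec.species,
                gene_id=pid.rsplit(".", 1)[0],
                description="Snf2 family ATPase fragment",
            )
        )
        snf_end = length // 2
        hel_end = length
        e1, e2 = 10.0 ** (-rng.uniform(5, 30, size=2))
        hits.append(DomainHit(pid, "SNF2_N", 1, snf_end, float(e1), 100.0))
        hits.append(DomainHit(pid, "Helicase_C", snf_end + 1, hel_end, float(e2), 80.0))
        scores[pid] = float(rng.uniform(250, 600))
        truth_rows.append((pid, False, "short"))

    truth = pd.DataFrame(truth_rows, columns=["protein_id", "is_true", "decoy_class"])
    return SimProteome(proteins=proteins, domain_hits=hits, scores=scores, truth=truth)


# --------------------------------------------------------- genome hits

@dataclass(frozen=True)
class SimGenomeSpec:
    """Planted gene loci on one target sequence at controlled spacings.

    ``inter_locus_gaps`` gives the gap in bp between consecutive loci
    (length ``n_loci - 1``); hits for one locus stay within a 2 kb block,
    so the planted gaps are exactly the inter-cluster gaps seen by
    single-linkage clustering.
    """

    n_loci: int = 3
    inter_locus_gaps: tuple[int, ...] = (20_000, 20_000)
    hits_per_locus: int = 3
    target_seq_id: str = "chr1"
    locus_span_bp: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if len(self.inter_locus_gaps) != self.n_loci - 1:
            raise ValueError("need exactly n_loci - 1 inter-locus gaps")
        if any(g < 0 for g in self.inter_locus_gaps):
            raise ValueError("overlapping planted loci (negative gap) rejected")
        if self.hits_per_locus < 1:
            raise ValueError("hits_per_locus must be >= 1")
        if not (1 <= self.locus_span_bp <= 2_000):
            raise ValueError("locus hit block must span at most 2 kb")


@dataclass
class SimGenomeHits:
    hits: list[GenomicHit]
    loci: list[tuple[str, int, int]]  # planted (seqid, start, end)
    spec: SimGenomeSpec = field(repr=False, default=None)

    def expected_cluster_count(self, distance_cutoff: int) -> int:
        """Clusters expected under a cutoff: brute force over planted gaps."""
        return 1 + sum(1 for g in self.spec.inter_locus_gaps if g > distance_cutoff)


def gen_genome_hits(spec: SimGenomeSpec) -> SimGenomeHits:
    """Emit protein-vs-genome hits for loci separated by planted gaps."""
    rng = _rng(spec.seed)
    hits: list[GenomicHit] = []
    loci: list[tuple[str, int, int]] = []
    start = int(rng.integers(5_000, 50_000))
    for i in range(spec.n_loci):
        end = start + spec.locus_span_bp - 1
        loci.append((spec.target_seq_id, start, end))
        # tile the block with hit fragments; first/last anchor the edges
        for j in range(spec.hits_per_locus):
            if spec.hits_per_locus == 1:
                hs, he = start, end
            else:
                frac0 = j / spec.hits_per_locus
                frac1 = (j + 1) / spec.hits_per_locus
                hs = start + int(frac0 * (spec.locus_span_bp - 1))
                he = start + int(frac1 * (spec.locus_span_bp - 1))
            strand = "+" if rng.random() < 0.5 else "-"
            hits.append(
                GenomicHit(
                    query_protein_id=f"query{int(rng.integers(1, 6))}",
                    target_seq_id=spec.target_seq_id,
                    target_start=hs,
                    target_end=he,
                    strand=strand,
                    e_value=float(10.0 ** (-rng.uniform(2, 40))),
                    bitscore=float(rng.uniform(100, 900)),
                )
            )
        if i < spec.n_loci - 1:
            start = end + spec.inter_locus_gaps[i] + 1
    return SimGenomeHits(hits=hits, loci=loci, spec=spec)


def gen_annotation(
    sim: SimGenomeHits, annotated_indices: Sequence[int]
) -> tuple[list[dict], list[str]]:
    """Annotation gene records covering a subset of the planted loci.

    Returns (gene records, family gene ids) for
    :func:`famcensus.recall.reconcile_with_annotation`.
    """
    genes = []
    fam_ids = []
    for i in annotated_indices:
        seqid, s, e = sim.loci[i]
        gid = f"annot_gene_{i + 1}"
        genes.append({"gene_id": gid, "seqid": seqid, "start": s, "end": e})
        fam_ids.append(gid)
    return genes, fam_ids


# --------------------------------------------------------------- trees

@dataclass(frozen=True)
class SimTreeSpec:
    """Planted duplication-loss history on a given species tree.

    ``dup_species`` / ``loss_species`` optionally pin events to species;
    unpinned events are placed on randomly chosen (seeded) species subject
    to the recoverability constraints described in the module docstring.
    """

    species_tree: str = "((A,B),(C,D));"
    n_duplications: int = 0
    n_losses: int = 0
    dup_species: tuple[str, ...] = ()
    loss_species: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_duplications < 0 or self.n_losses < 0:
            raise ValueError("event counts must be >= 0")
        if self.dup_species and len(self.dup_species) != self.n_duplications:
            raise ValueError("dup_species length must equal n_duplications")
        if self.loss_species and len(self.loss_species) != self.n_losses:
            raise ValueError("loss_species length must equal n_losses")


@dataclass
class SimTrees:
    gene_tree_newick: str
    species_tree_newick: str
    gene_species: dict[str, str]
    events: list[dict]  # planted {"type": ..., "species": ...}

    @property
    def n_duplications(self) -> int:
        return sum(1 for e in self.events if e["type"] == "duplication")

    @property
    def n_losses(self) -> int:
        return sum(1 for e in self.events if e["type"] == "loss")


def _clone_congruent(st: SpeciesTree) -> tuple[dendropy.Tree, dict[str, str]]:
    taxa = dendropy.TaxonNamespace()
    gt = dendropy.Tree(taxon_namespace=taxa)

    def build(snode, gparent):
        gnode = dendropy.Node()
        gparent.add_child(gnode) if gparent is not None else None
        if snode.is_leaf():
            label = f"{snode.taxon.label}_g1"
            gnode.taxon = taxa.new_taxon(label)
        else:
            for c in snode.child_nodes():
                build(c, gnode)
        return gnode

    root = build(st.tree.seed_node, None)
    gt.seed_node = root
    mapping = {t.label: t.label.rsplit("_g", 1)[0] for t in taxa}
    return gt, mapping


def gen_trees(spec: SimTreeSpec) -> SimTrees:
    """Generate a gene tree with a recoverable planted dup-loss history.

    Starting from the gene tree congruent with the species tree, losses
    prune species leaves (never two siblings, and never emptying either
    side of the root) and duplications graft a sister copy of one existing
    gene leaf.  Under LCA parsimony each pruned leaf contributes exactly
    one loss and each graft exactly one duplication, so reconciliation
    recovers the planted counts exactly.
    """
    st = SpeciesTree(spec.species_tree)
    rng = _rng(spec.seed)
    gt, gene_species = _clone_congruent(st)
    events: list[dict] = []

    # ---- losses: prune species leaves under recoverability constraints
    pruned: set[str] = set()
    root_kids = st.tree.seed_node.child_nodes()
    root_sides = [
        {l.taxon.label for l in k.leaf_iter()} for k in root_kids
    ] if root_kids else []

    def prunable(sp: str) -> bool:
        node = st.leaf_node[sp]
        parent = st.parent[node]
        if parent is None:
            return False
        sib = [c for c in parent.child_nodes() if c is not node][0]
        sib_species = {l.taxon.label for l in sib.leaf_iter()}
        if not (sib_species - pruned - {sp}):
            return False
        for side in root_sides:
            if sp in side and not (side - pruned - {sp}):
                return False
        return True

    loss_targets = list(spec.loss_species)
    for k in range(spec.n_losses):
        if loss_targets:
            sp = loss_targets[k]
            if sp not in st.leaf_node:
                raise ValueError(f"loss species {sp!r} not in species tree")
            if not prunable(sp):
                raise ValueError(
                    f"planted loss of {sp!r} would not be recoverable "
                    "(sibling subtree or root side would be emptied)"
                )
        else:
            candidates = sorted(s for s in st.species - pruned if prunable(s))
            if not candidates:
                raise ValueError("no recoverable loss placement left")
            sp = candidates[int(rng.integers(len(candidates)))]
        leaf = gt.find_node_with_taxon_label(f"{sp}_g1")
        gt.prune_subtree(leaf, suppress_unifurcations=True)
        del gene_species[f"{sp}_g1"]
        pruned.add(sp)
        events.append({"type": "loss", "species": sp})

    # ---- duplications: graft sister copies of surviving gene leaves
    copy_counter = {sp: 1 for sp in st.species if sp not in pruned}
    dup_targets = list(spec.dup_species)
    for k in range(spec.n_duplications):
        if dup_targets:
            sp = dup_targets[k]
            if sp not in st.leaf_node:
                raise ValueError(f"duplication species {sp!r} not in species tree")
            if sp in pruned:
                raise ValueError(f"cannot duplicate pruned species {sp!r}")
        else:
            candidates = sorted(copy_counter)
            sp = candidates[int(rng.integers(len(candidates)))]
        old_label = f"{sp}_g{int(rng.integers(1, copy_counter[sp] + 1))}"
        copy_counter[sp] += 1
        new_label = f"{sp}_g{copy_counter[sp]}"
        leaf = gt.find_node_with_taxon_label(old_label)
        parent = leaf.parent_node
        joint = dendropy.Node()
        if parent is None:  # single-leaf gene tree
            gt.seed_node = joint
        else:
            parent.remove_child(leaf)
            parent.add_child(joint)
        joint.add_child(leaf)
        new_leaf = dendropy.Node()
        new_leaf.taxon = gt.taxon_namespace.new_taxon(new_label)
        joint.add_child(new_leaf)
        gene_species[new_label] = sp
        events.append({"type": "duplication", "species": sp})

    newick = gt.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()
    return SimTrees(
        gene_tree_newick=newick,
        species_tree_newick=st.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip(),
        gene_species=gene_species,
        events=events,
    )


# ---------------------------------------------------------------- FPKM

_CATEGORY_INTERVALS = {
    "low": (0.0, 5.0),
    "moderate": (5.0, 200.0),  # open at 5
    "high": (200.0, 2000.0),  # open at 200
}


def gen_fpkm_table(
    category_plan: Mapping[str, "str | Mapping[str, str]"],
    libraries: Sequence[str],
    seed: int = 0,
) -> pd.DataFrame:
    """FPKM long table whose values fall inside planned category intervals.

    ``category_plan`` maps each gene to a single category (applied to all
    libraries) or to a per-library category mapping.  Values are drawn
    uniformly inside low: [0, 5], moderate: (5, 200], high: (200, 2000].
    """
    rng = _rng(seed)
    rows = []
    for gene, plan in category_plan.items():
        for lib in libraries:
            cat = plan if isinstance(plan, str) else plan[lib]
            if cat not in _CATEGORY_INTERVALS:
                raise ValueError(f"unknown expression category {cat!r}")
            lo, hi = _CATEGORY_INTERVALS[cat]
            if cat == "low":
                val = float(rng.uniform(lo, hi))
            else:
                # open lower bound: shift off the boundary
                val = float(lo + (hi - lo) * (1.0 - rng.random() * 0.999))
            rows.append((gene, lib, val, cat))
    return pd.DataFrame(rows, columns=["gene_id", "library_id", "fpkm", "category"])
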