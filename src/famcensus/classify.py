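"""Reference-anchored subfamily classification and the census matrix.

Subfamily labels are transferred from reference leaves (genes with a known
subfamily, e.g. the annotated Arabidopsis set) to unlabeled leaves of a
gene tree: each unlabeled leaf takes the label of the smallest clade that
contains it together with at least one reference leaf, provided all
reference leaves in that clade agree.  Disagreeing clades yield
"not classified" — the conservative behavior that leaves genuinely novel
members (or database sequences outside known subfamilies) unassigned.

The census matrix counts classified members per species and subfamily and
carries the summary statistics used to compare genomes: per-subfamily mean
and population standard deviation, per-cell deviation in sd units, and
quartiles/IQR of the per-species totals.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from famcensus.config import ClassifyConfig

NOT_CLASSIFIED = "not classified"


@dataclass(frozen=True)
class LeafInfo:
    leaf_id: str
    species: str = ""
    reference_subfamily: str | None = None
    support: float | None = None

    def __post_init__(self) -> None:
        if self.support is not None and not (0 <= self.support <= 100):
            raise ValueError("support must be in [0, 100]")


@dataclass(frozen=True)
class SubfamilyAssignment:
    leaf_id: str
    subfamily: str
    anchor_clade_size: int = 0
    anchor_support: float | None = None
    species: str = ""


class LabeledTree:
    """A gene tree whose leaves carry species and optional reference labels.

    Leaf metadata may be embedded in the newick labels as
    ``leaf_id|species|subfamily`` triplets (empty fields allowed) or
    supplied via a sidecar mapping ``leaf_id -> LeafInfo``.
    """

    def __init__(self, tree: dendropy.Tree, leaves: Mapping[str, LeafInfo]):
        labels = [t.label for t in tree.taxon_namespace]
        if len(set(labels)) < len(labels):
            raise ValueError("duplicate leaf ids in tree")
        missing = {t.label for t in tree.taxon_namespace} - set(leaves)
        if missing:
            raise ValueError(f"leaves without metadata: {sorted(missing)}")
        self.tree = tree
        self.leaves = dict(leaves)

    @classmethod
    def from_newick(
        cls, newick: str, labels: Mapping[str, LeafInfo] | None = None
    ) -> "LabeledTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:
            raise ValueError(f"invalid newick tree: {exc}") from exc
        if labels is not None:
            return cls(tree, labels)
        # parse embedded id|species|subfamily triplets and relabel taxa
        info: dict[str, LeafInfo] = {}
        for taxon in tree.taxon_namespace:
            parts = (taxon.label or "").split("|")
            leaf_id = parts[0]
            species = parts[1] if len(parts) > 1 and parts[1] else ""
            subfam = parts[2] if len(parts) > 2 and parts[2] else None
            taxon.label = leaf_id
            info[leaf_id] = LeafInfo(leaf_id, species, subfam)
        return cls(tree, info)

    def rooted_copy(self, cfg: ClassifyConfig | None = None) -> dendropy.Tree:
        """Return a rooted copy of the gene tree.

        A tree whose root already bifurcates is taken as rooted and left
        alone.  A genuinely unrooted tree (trifurcating root, the usual
        output of tree estimation) is rooted by midpoint by default, or on
        the configured outgroup.
        """
        cfg = cfg or ClassifyConfig()
        t = self.tree.clone(depth=1)
        if cfg.rooting == "outgroup":
            og = t.find_node_with_taxon_label(cfg.outgroup)
            if og is None:
                raise ValueError(f"outgroup leaf {cfg.outgroup!r} not in tree")
            t.to_outgroup_position(og, update_bipartitions=False)
            return t
        if cfg.rooting == "none" or len(t.seed_node.child_nodes()) == 2:
            return t
        # midpoint rooting needs branch lengths; unit lengths if absent
        if all(e.length is None for e in t.preorder_edge_iter()):
            for e in t.preorder_edge_iter():
                e.length = 1.0
        t.reroot_at_midpoint(update_bipartitions=False)
        return t


def assign_subfamilies(
    tree: LabeledTree, cfg: ClassifyConfig | None = None
) -> list[SubfamilyAssignment]:
    """Label every leaf of a gene tree by its reference-anchored clade.

    For each unlabeled leaf, walk rootward to the smallest clade containing
    at least one reference leaf.  If all references in that clade share one
    subfamily (or, with ``cfg.majority_vote``, a strict majority exists),
    the leaf takes that label; otherwise it is "not classified".  Reference
    leaves keep their own labels.
    """
    cfg = cfg or ClassifyConfig()
    rooted = tree.rooted_copy(cfg)
    info = tree.leaves

    out: list[SubfamilyAssignment] = []
    for leaf in rooted.leaf_node_iter():
        li = info[leaf.taxon.label]
        if li.reference_subfamily is not None:
            out.append(
                SubfamilyAssignment(
                    li.leaf_id, li.reference_subfamily, 1, li.support, li.species
                )
            )
            continue
        node = leaf.parent_node
        assigned = None
        while node is not None:
            clade_leaves = [n.taxon.label for n in node.leaf_iter()]
            refs = [
                info[x].reference_subfamily
                for x in clade_leaves
                if info[x].reference_subfamily is not None
            ]
            if refs:
                counts = pd.Series(refs).value_counts()
                if len(counts) == 1:
                    label = counts.index[0]
                elif cfg.majority_vote and counts.iloc[0] > len(refs) / 2:
                    label = counts.index[0]
                else:
                    label = NOT_CLASSIFIED
                support = None
                try:
                    support = float(node.label) if node.label else None
                except (TypeError, ValueError):
                    support = None
                assigned = SubfamilyAssignment(
                    li.leaf_id, label, len(clade_leaves), support, li.species
                )
                break
            node = node.parent_node
        if assigned is None:  # no reference leaf anywhere in the tree
            assigned = SubfamilyAssignment(li.leaf_id, NOT_CLASSIFIED, 0, None, li.species)
        out.append(assigned)
    out.sort(key=lambda a: a.leaf_id)
    return out


@dataclass
class CensusMatrix:
    """Species x subfamily count matrix with census summary statistics."""

    counts: pd.DataFrame  # species rows, subfamily columns, int
    subfamily_mean: pd.Series
    subfamily_sd: pd.Series
    z: pd.DataFrame  # (count - mean) / sd, 0 where sd == 0
    species_totals: pd.Series
    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    def to_tsv(self) -> str:
        buf = io.StringIO()
        full = self.counts.copy()
        full["total"] = self.species_totals
        full.to_csv(buf, sep="\t")
        return buf.getvalue()


def build_census(
    assignments: Mapping[str, Sequence[str]] | Iterable[SubfamilyAssignment],
    included_genomes: Sequence[str],
) -> CensusMatrix:
    """Build the species x subfamily census matrix.

    Parameters
    ----------
    assignments
        Either a mapping ``species -> list of subfamily labels`` or an
        iterable of :class:`SubfamilyAssignment` (species taken from the
        records).  "not classified" members are excluded from the counts.
    included_genomes
        Species with whole-genome data; only these enter the matrix, and a
        species outside this set raises an error.

    Notes
    -----
    Per-subfamily mean is total / n_genomes and sd is the population
    standard deviation (divide by n), so a genome absent from a subfamily
    still contributes a zero count.  Quartiles of the per-species totals
    use linear interpolation on the sorted values.
    """
    if isinstance(assignments, Mapping):
        per_species = {sp: list(labels) for sp, labels in assignments.items()}
    else:
        per_species = {}
        for a in assignments:
            per_species.setdefault(a.species, []).append(a.subfamily)

    bad = set(per_species) - set(included_genomes)
    if bad:
        raise ValueError(f"species outside included genome set: {sorted(bad)}")

    rows = []
    for sp in included_genomes:
        for label in per_species.get(sp, []):
            if label != NOT_CLASSIFIED:
                rows.append((sp, label))
    if rows:
        df = pd.DataFrame(rows, columns=["species", "subfamily"])
        counts = (
            df.groupby(["species", "subfamily"], sort=True)
            .size()
            .unstack(fill_value=0)
            .reindex(index=list(included_genomes), fill_value=0)
        )
        counts.columns.name = None
        counts.index.name = "species"
    else:
        counts = pd.DataFrame(
            index=pd.Index(list(included_genomes), name="species"), dtype=int
        )

    n = len(included_genomes)
    if counts.shape[1] and n:
        mean = counts.sum(axis=0) / n
        sd = counts.std(axis=0, ddof=0)
        z = counts.sub(mean, axis=1).div(sd.replace(0, np.nan), axis=1).fillna(0.0)
    else:
        mean = pd.Series(dtype=float)
        sd = pd.Series(dtype=float)
        z = counts.astype(float)

    totals = counts.sum(axis=1) if counts.shape[1] else pd.Series(
        0, index=counts.index, dtype=int
    )
    if len(totals):
        q1, q3 = np.percentile(np.sort(totals.to_numpy()), [25, 75])
    else:
        q1 = q3 = 0.0
    return CensusMatrix(
        counts=counts,
        subfamily_mean=mean,
        subfamily_sd=sd,
        z=z,
        species_totals=totals,
        q1=float(q1),
        q3=float(q3),
    )


def totals_quartiles(totals: Sequence[float]) -> tuple[float, float, float]:
    """Q1, Q3 and IQR of per-species totals (linear interpolation)."""
    arr = np.sort(np.asarray(totals, dtype=float))
    q1, q3 = np.percentile(arr, [25, 75])
    return float(q1), float(q3), float(q3 - q1)
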