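"""End-to-end census orchestration.

``run_census`` ties the stages together on file inputs: candidate calling
on the proteome, locus recall on genome hits, subfamily classification on
the gene tree, reconciliation against the species tree, disorder/
architecture tracks, and expression categorization.  Stages run when their
inputs are present; each stage failure aborts with a stage-named error and
leaves a FAILED marker next to the partial outputs.  A JSON manifest
records the config hash and input checksums so runs are reproducible and
comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from famcensus import io as fio
from famcensus.classify import LabeledTree, assign_subfamilies, build_census
from famcensus.config import PipelineConfig
from famcensus.expression import categorize_table, expressed_flags, expression_matrix
from famcensus.features import disorder_profile, summarize_architecture
from famcensus.recall import cluster_hits, emit_regions, reconcile_with_annotation
from famcensus.reconcile import reconcile
from famcensus.scan import collapse_to_loci, extract_atpase_region, filter_candidates

logger = logging.getLogger("famcensus")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for exit codes."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_census(cfg: PipelineConfig, inputs: Mapping[str, str]) -> dict:
    """Run every stage whose inputs are present.

    Recognized input keys: ``proteome`` (FASTA), ``domain_hits`` (TSV),
    ``profile_scores`` (TSV), ``genome_hits`` (12-column TSV),
    ``annotation`` (GFF3), ``family_gene_ids`` (one id per line),
    ``gene_tree`` (newick with id|species|subfamily leaf labels),
    ``species_tree`` (newick), ``fpkm`` (TSV: gene_id, library_id, fpkm).

    Returns a summary dict (also written as ``manifest.json``).
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    summary: dict = {"stages": {}}

    def _input_path(key: str) -> Path | None:
        p = inputs.get(key)
        return Path(p) if p else None

    def _run(stage: str, fn):
        try:
            logger.info("[%s] running", stage)
            result = fn()
            summary["stages"][stage] = result
        except Exception as exc:
            failed_marker.write_text(f"{stage}: {exc}\n")
            raise StageError(stage, exc) from exc

    # ---- scan -----------------------------------------------------
    proteome_p = _input_path("proteome")
    if proteome_p is not None:
        def scan_stage():
            proteome = fio.read_proteome(proteome_p)
            hits = (
                fio.read_domain_hits_tsv(_input_path("domain_hits"))
                if inputs.get("domain_hits")
                else []
            )
            scores = (
                fio.read_profile_scores(_input_path("profile_scores"))
                if inputs.get("profile_scores")
                else {}
            )
            cands = filter_candidates(proteome, hits, scores, cfg.scan)
            loci = collapse_to_loci(cands)
            rows = [
                (
                    c.protein.id, c.protein.species, c.protein.gene_id,
                    c.protein.length, c.atpase_bitscore,
                    c.atpase_span[0], c.atpase_span[1],
                )
                for c in loci
            ]
            pd.DataFrame(
                rows,
                columns=[
                    "protein_id", "species", "gene_id", "length",
                    "atpase_bitscore", "atpase_start", "atpase_end",
                ],
            ).to_csv(out / "candidates.tsv", sep="\t", index=False)
            with open(out / "atpase_regions.fasta", "w") as fh:
                for c in loci:
                    fh.write(f">{c.protein.id}\n{extract_atpase_region(c, cfg.scan)}\n")
            return {"n_candidates": len(cands), "n_loci": len(loci)}

        _run("scan", scan_stage)

    # ---- recall ---------------------------------------------------
    if inputs.get("genome_hits"):
        def recall_stage():
            hits = [
                h
                for h in fio.read_genome_hits(_input_path("genome_hits"))
                if h.e_value < cfg.recall.hit_evalue_max
            ]
            clusters = cluster_hits(hits, cfg.recall)
            fio.write_clusters_tsv(clusters, out / "clusters.tsv")
            fio.write_gff3(
                emit_regions(clusters, cfg.recall.region_padding_bp),
                out / "regions.gff3",
            )
            result = {"n_clusters": len(clusters)}
            if inputs.get("annotation") and inputs.get("family_gene_ids"):
                genes = fio.read_gff3_genes(_input_path("annotation"))
                fam_ids = [
                    ln.strip()
                    for ln in _input_path("family_gene_ids").read_text().splitlines()
                    if ln.strip()
                ]
                part = reconcile_with_annotation(clusters, genes, fam_ids)
                pd.DataFrame(
                    [part.counts]
                ).to_csv(out / "locus_partition.tsv", sep="\t", index=False)
                result["partition"] = part.counts
            return result

        _run("recall", recall_stage)

    # ---- classify -------------------------------------------------
    if inputs.get("gene_tree"):
        def classify_stage():
            tree = LabeledTree.from_newick(_input_path("gene_tree").read_text())
            assigns = assign_subfamilies(tree, cfg.classify)
            pd.DataFrame(
                [
                    (a.leaf_id, a.species, a.subfamily, a.anchor_clade_size)
                    for a in assigns
                ],
                columns=["leaf_id", "species", "subfamily", "anchor_clade_size"],
            ).to_csv(out / "assignments.tsv", sep="\t", index=False)
            result = {"n_assigned": len(assigns)}
            genomes = cfg.included_genomes or sorted(
                {a.species for a in assigns if a.species}
            )
            if genomes:
                census = build_census(
                    [a for a in assigns if a.species in genomes], genomes
                )
                (out / "census.tsv").write_text(census.to_tsv())
                result["census"] = {
                    "q1": census.q1,
                    "q3": census.q3,
                    "iqr": census.iqr,
                }
            return result

        _run("classify", classify_stage)

    # ---- reconcile ------------------------------------------------
    if inputs.get("gene_tree") and inputs.get("species_tree"):
        def reconcile_stage():
            tree = LabeledTree.from_newick(_input_path("gene_tree").read_text())
            gene_species = {lid: li.species for lid, li in tree.leaves.items()}
            res = reconcile(
                tree.rooted_copy(cfg.classify),
                _input_path("species_tree").read_text(),
                gene_species,
            )
            (out / "reconciliation.json").write_text(
                json.dumps(res.summary(), indent=2, sort_keys=True)
            )
            pd.DataFrame(res.events_table()).to_csv(
                out / "reconciliation_events.tsv", sep="\t", index=False
            )
            return res.summary()

        _run("reconcile", reconcile_stage)

    # ---- features -------------------------------------------------
    if proteome_p is not None:
        def features_stage():
            proteome = fio.read_proteome(proteome_p)
            hits = (
                fio.read_domain_hits_tsv(_input_path("domain_hits"))
                if inputs.get("domain_hits")
                else []
            )
            rows = []
            arch_rows = []
            for p in proteome:
                prof = disorder_profile(p.id, p.sequence, cfg.disorder)
                for s, e in prof.regions:
                    rows.append((p.id, s, e))
                summ = summarize_architecture(p, hits, prof)
                for el in summ.elements:
                    arch_rows.append((p.id, el.name, el.start, el.end, el.kind))
            pd.DataFrame(rows, columns=["protein_id", "start", "end"]).to_csv(
                out / "disorder_regions.tsv", sep="\t", index=False
            )
            pd.DataFrame(
                arch_rows, columns=["protein_id", "element", "start", "end", "kind"]
            ).to_csv(out / "architecture.tsv", sep="\t", index=False)
            return {"n_proteins": len(proteome), "n_disordered_regions": len(rows)}

        _run("features", features_stage)

    # ---- expression -----------------------------------------------
    if inputs.get("fpkm"):
        def expression_stage():
            table = pd.read_csv(_input_path("fpkm"), sep="\t")
            cat = categorize_table(table, cfg.expression)
            cat.to_csv(out / "expression_categories.tsv", sep="\t", index=False)
            flags = expressed_flags(table, cfg.expression)
            flags.to_frame().to_csv(out / "expressed_flags.tsv", sep="\t")
            mat, mask = expression_matrix(table)
            mat.to_csv(out / "expression_matrix.tsv", sep="\t")
            return {
                "n_genes": int(mat.shape[0]) if not mat.empty else 0,
                "n_expressed": int(flags.sum()) if len(flags) else 0,
            }

        _run("expression", expression_stage)

    # ---- manifest -------------------------------------------------
    manifest = {
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
        "inputs": {
            k: {"path": str(v), "sha256": _sha256(Path(v))}
            for k, v in inputs.items()
            if v and Path(v).exists()
        },
        "stages": summary["stages"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def validate_inputs(inputs: Mapping[str, str], cfg: PipelineConfig | None = None) -> list[dict]:
    """Report-only validation: format verdicts and referential checks."""
    report: list[dict] = []

    def entry(key: str, ok: bool, errors: list[str]):
        report.append({"input": key, "path": str(inputs.get(key, "")), "ok": ok,
                       "errors": errors})

    proteome = None
    if inputs.get("proteome"):
        errs = []
        try:
            proteome = fio.read_proteome(Path(inputs["proteome"]))
            text = Path(inputs["proteome"]).read_text().splitlines()
            for lineno, line in enumerate(text, start=1):
                if line.startswith(">") and (
                    lineno == len(text) or text[lineno].startswith(">")
                ):
                    errs.append(f"line {lineno}: FASTA header without sequence")
        except Exception as exc:
            errs.append(str(exc))
        entry("proteome", not errs, errs)

    if inputs.get("domain_hits"):
        errs = []
        try:
            hits = fio.read_domain_hits_tsv(Path(inputs["domain_hits"]))
            if proteome is not None:
                known = {p.id for p in proteome}
                for h in hits:
                    if h.protein_id not in known:
                        errs.append(f"hit references unknown protein {h.protein_id!r}")
        except Exception as exc:
            errs.append(str(exc))
        entry("domain_hits", not errs, errs)

    if inputs.get("gene_tree") and inputs.get("species_tree"):
        errs = []
        try:
            from famcensus.reconcile import SpeciesTree

            tree = LabeledTree.from_newick(Path(inputs["gene_tree"]).read_text())
            st = SpeciesTree(Path(inputs["species_tree"]).read_text())
            for lid, li in tree.leaves.items():
                if li.species and li.species not in st.species:
                    errs.append(f"leaf {lid!r}: species {li.species!r} not in species tree")
        except Exception as exc:
            errs.append(str(exc))
        entry("gene_tree", not errs, errs)

    if inputs.get("fpkm"):
        errs = []
        try:
            df = pd.read_csv(Path(inputs["fpkm"]), sep="\t")
            missing = {"gene_id", "library_id", "fpkm"} - set(df.columns)
            if missing:
                errs.append(f"missing columns: {sorted(missing)}")
            elif (df["fpkm"] < 0).any():
                errs.append("negative FPKM values")
        except Exception as exc:
            errs.append(str(exc))
        entry("fpkm", not errs, errs)

    return report
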