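"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA goes through Biopython; tabular files through pandas.  Two domain-hit
dialects are accepted: the per-domain tabular output of profile-search
tools (whitespace-delimited, ``#`` comment lines) and a simplified 6-column
TSV.  Protein-vs-genome hits use the standard 12-column tabular dialect
where a target start greater than the target end denotes the minus strand.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from famcensus.recall import GenomicHit, LocusCluster
from famcensus.scan import DomainHit, ProteinRecord


# ---------------------------------------------------------------- FASTA

def read_proteome(path: str | Path, species: str = "") -> list[ProteinRecord]:
    """Read a protein FASTA; gene_id defaults to the id minus a trailing
    ``.N`` isoform suffix."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        gene_id = pid.rsplit(".", 1)[0] if "." in pid else pid
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            ProteinRecord(
                id=pid,
                sequence=str(rec.seq),
                species=species,
                gene_id=gene_id,
                description=desc,
            )
        )
    return records


def write_proteome(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


# ---------------------------------------------------------- domain hits

#: column order of the simplified domain-hit TSV
DOMTSV_COLUMNS = ["protein_id", "domain", "start", "end", "evalue", "bitscore"]


def read_domain_hits_tsv(path: str | Path) -> list[DomainHit]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(DOMTSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"domain TSV missing columns: {sorted(missing)}")
    return [
        DomainHit(
            protein_id=str(r.protein_id),
            domain_name=str(r.domain),
            ali_start=int(r.start),
            ali_end=int(r.end),
            e_value=float(r.evalue),
            bitscore=float(r.bitscore),
        )
        for r in df.itertuples()
    ]


def write_domain_hits_tsv(hits: Iterable[DomainHit], path: str | Path) -> None:
    rows = [
        (h.protein_id, h.domain_name, h.ali_start, h.ali_end, h.e_value, h.bitscore)
        for h in hits
    ]
    pd.DataFrame(rows, columns=DOMTSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_domain_hits_domtbl(path: str | Path) -> list[DomainHit]:
    """Parse per-domain tabular output of a profile search (19+ columns).

    Column layout (0-based): 0 target/domain name, 3 query/protein name,
    12 independent E-value, 13 domain score, 17/18 alignment coordinates.
    """
    hits = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split()
        if len(f) < 19:
            raise ValueError(f"malformed domain-table line: {line[:60]!r}")
        hits.append(
            DomainHit(
                protein_id=f[3],
                domain_name=f[0],
                ali_start=int(f[17]),
                ali_end=int(f[18]),
                e_value=float(f[12]),
                bitscore=float(f[13]),
            )
        )
    return hits


def read_profile_scores(path: str | Path) -> dict[str, float]:
    """Two-column TSV (protein_id, bitscore) -> mapping."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = list(df.columns[:2])
    return {str(r[cols[0]]): float(r[cols[1]]) for _, r in df.iterrows()}


def write_profile_scores(scores: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        sorted(scores.items()), columns=["protein_id", "bitscore"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------- genome hits

BLAST12_COLUMNS = [
    "query", "target", "identity", "length", "mismatches", "gaps",
    "qstart", "qend", "tstart", "tend", "evalue", "bitscore",
]


def read_genome_hits(path: str | Path) -> list[GenomicHit]:
    """Read 12-column protein-vs-genome hits; tstart > tend means minus."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=BLAST12_COLUMNS)
    hits = []
    for r in df.itertuples():
        s, e = int(r.tstart), int(r.tend)
        strand = "+" if s <= e else "-"
        if strand == "-":
            s, e = e, s
        hits.append(
            GenomicHit(
                query_protein_id=str(r.query),
                target_seq_id=str(r.target),
                target_start=s,
                target_end=e,
                strand=strand,
                e_value=float(r.evalue),
                bitscore=float(r.bitscore),
            )
        )
    return hits


def write_genome_hits(hits: Iterable[GenomicHit], path: str | Path) -> None:
    rows = []
    for h in hits:
        s, e = h.target_start, h.target_end
        if h.strand == "-":
            s, e = e, s
        rows.append(
            (h.query_protein_id, h.target_seq_id, 100.0, e - s + 1 if s <= e else s - e + 1,
             0, 0, 1, 1, s, e, h.e_value, h.bitscore)
        )
    pd.DataFrame(rows, columns=BLAST12_COLUMNS).to_csv(
        path, sep="\t", index=False, header=False
    )


# ----------------------------------------------------------------- GFF3

def _format_attributes(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def write_gff3(records: Iterable[dict], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for r in records:
        attrs = r.get("attributes", {})
        lines.append(
            "\t".join(
                str(r.get(k, "."))
                for k in ("seqid", "source", "type", "start", "end", "score",
                          "strand", "phase")
            )
            + "\t"
            + _format_attributes(attrs)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3_genes(path: str | Path, feature_type: str = "gene") -> list[dict]:
    """Read GFF3 records of one feature type as simple gene mappings."""
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9:
            raise ValueError(f"malformed GFF3 line: {line[:60]!r}")
        if f[2] != feature_type:
            continue
        attrs = _parse_attributes(f[8])
        genes.append(
            {
                "gene_id": attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}"),
                "seqid": f[0],
                "start": int(f[3]),
                "end": int(f[4]),
                "strand": f[6],
                "attributes": attrs,
            }
        )
    return genes


def write_clusters_tsv(clusters: Iterable[LocusCluster], path: str | Path) -> None:
    rows = [
        (c.target_seq_id, c.span[0], c.span[1], len(c.member_hits), c.n_distinct_queries)
        for c in clusters
    ]
    pd.DataFrame(
        rows, columns=["target_seq_id", "start", "end", "n_hits", "n_queries"]
    ).to_csv(path, sep="\t", index=False)
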