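"""Readers and writers for the pipeline's file formats.

FASTA goes through Biopython, GFF3 through gffutils (in-memory database),
tables through pandas. Gene identifiers are treated case-sensitively and
never normalized: public *B. rapa* annotations mix styles such as
``BraA03G024630`` and ``BraA03g024630``, and silently folding case would
merge distinct loci.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path
from typing import Iterable, Literal

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    NUCLEOTIDE_ALPHABET,
    PROTEIN_ALPHABET,
    CdsRecord,
    DomainAnnotation,
    GeneModel,
    ProteinRecord,
)

logger = logging.getLogger("ccch_survey")


def configure_logging(level: int = logging.INFO) -> None:
    """Send pipeline logs to standard error with a compact format."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


def read_fasta(
    path: str | Path, alphabet: Literal["protein", "nucleotide"]
) -> list[ProteinRecord] | list[CdsRecord]:
    """Parse a FASTA file into protein or CDS records.

    The first whitespace-delimited header token is the record ID. Sequences
    are uppercased. Gap characters ("-") are rejected for nucleotide input
    and stripped with a warning for protein input (alignment rows are
    accepted but stored unaligned). Duplicate IDs and characters outside the
    alphabet raise ``ValueError``.
    """
    if alphabet not in ("protein", "nucleotide"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    allowed = PROTEIN_ALPHABET if alphabet == "protein" else NUCLEOTIDE_ALPHABET
    records: list = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if rid in seen:
            raise ValueError(f"duplicate FASTA id {rid!r} in {path}")
        seen.add(rid)
        seq = str(entry.seq).upper()
        if "-" in seq:
            if alphabet == "nucleotide":
                raise ValueError(f"CDS {rid!r}: gap characters not allowed")
            logger.warning("protein %s: stripping %d gap characters", rid, seq.count("-"))
            seq = seq.replace("-", "")
        bad = set(seq) - allowed
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise ValueError(
                f"record {rid!r}: character {seq[pos]!r} at position {pos} "
                f"outside {alphabet} alphabet"
            )
        if alphabet == "protein":
            records.append(ProteinRecord(id=rid, sequence=seq))
        else:
            records.append(CdsRecord(id=rid, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord | CdsRecord], path: str | Path, width: int = 60) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_domain_annotations(path: str | Path) -> dict[str, list[DomainAnnotation]]:
    """Read an external domain-annotation TSV (protein_id, domain, start, end).

    Coordinates in the file are 1-based inclusive (the convention of SMART /
    CDD exports); they are converted to 0-based half-open.
    """
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[DomainAnnotation]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.protein_id), []).append(
            DomainAnnotation(name=str(row.domain), start=int(row.start) - 1, end=int(row.end))
        )
    return out


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3.

    Exon structure uses ``exon`` features when present, else ``CDS`` features,
    merged per gene. When a gene has several mRNA isoforms the longest
    transcript (by summed exon length) is kept, so each gene contributes one
    structure. GFF3's 1-based inclusive coordinates become 0-based half-open.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = gene.id
        best_exons: list[tuple[int, int]] = []
        best_len = -1
        mrnas = list(db.children(gene, featuretype="mRNA"))
        parents = mrnas if mrnas else [gene]
        for parent in parents:
            exons = list(db.children(parent, featuretype="exon", order_by="start"))
            if not exons:
                exons = list(db.children(parent, featuretype="CDS", order_by="start"))
            ivs = [(f.start - 1, f.end) for f in exons]
            total = sum(e - s for s, e in ivs)
            if total > best_len:
                best_len = total
                best_exons = ivs
        models.append(
            GeneModel(
                gene_id=gene_id,
                chromosome=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                start=gene.start - 1,
                end=gene.end,
                exons=best_exons,
            )
        )
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as minimal GFF3 (gene + mRNA + exon features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(
                f"{m.chromosome}\tccch_survey\tgene\t{m.start + 1}\t{m.end}\t.\t"
                f"{m.strand}\t.\tID={m.gene_id}\n"
            )
            fh.write(
                f"{m.chromosome}\tccch_survey\tmRNA\t{m.start + 1}\t{m.end}\t.\t"
                f"{m.strand}\t.\tID={m.gene_id}.t1;Parent={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.chromosome}\tccch_survey\texon\t{s + 1}\t{e}\t.\t"
                    f"{m.strand}\t.\tID={m.gene_id}.t1.exon{i};Parent={m.gene_id}.t1\n"
                )


# ---------------------------------------------------------------------------
# Cq tables

CQ_COLUMNS = ["gene_id", "condition", "time_h", "replicate", "cq", "is_reference"]


def read_cq_table(path: str | Path) -> pd.DataFrame:
    """Read a replicate qPCR Cq table (TSV) and validate its shape."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CQ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Cq table {path}: missing columns {missing}")
    df["is_reference"] = df["is_reference"].astype(bool)
    if (df["cq"] <= 0).any():
        raise ValueError(f"Cq table {path}: Cq values must be positive")
    return df


def write_cq_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
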