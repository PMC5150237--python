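"""Readers and writers for the package's plain-text formats.

TSV dialect: UTF-8, tab separated, one header row; allele sets are
comma-joined, candidate lists semicolon-joined. Allele catalogs are FASTA
with one record per allele (ID ``GENE-k``); simulated reads are FASTA with
``individual=... gene=...`` tags in the description.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import CODING_GENES, Allele, ChoiceEvent, GenotypeTable

__all__ = [
    "translate_cds",
    "write_allele_fasta",
    "read_allele_fasta",
    "write_genotypes",
    "read_genotypes",
    "write_events",
    "read_events",
    "write_reads_fasta",
]


def translate_cds(dna: str) -> str:
    """Translate an in-frame coding sequence; '*' marks stop codons."""
    if len(dna) % 3 != 0:
        raise ValueError(f"sequence length {len(dna)} not divisible by 3")
    return str(Seq(dna).translate())


def write_allele_fasta(alleles: Iterable[Allele], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(a.dna), id=a.allele_id, description=f"gene={a.gene}")
        for a in alleles
    ]
    SeqIO.write(records, str(path), "fasta")


def read_allele_fasta(path: str | Path, gene: str | None = None) -> list[Allele]:
    """Load a catalog; gene comes from the ``gene=`` tag or the ID prefix."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        g = gene
        for tok in rec.description.split():
            if tok.startswith("gene="):
                g = tok[5:]
        if g is None:
            g = rec.id.rsplit("-", 1)[0]
        dna = str(rec.seq).upper()
        aa = translate_cds(dna) if g in CODING_GENES else ""
        out.append(Allele(allele_id=rec.id, gene=g, dna=dna, aa=aa))
    return out


def write_genotypes(genotypes: GenotypeTable, path: str | Path) -> None:
    rows = [
        {"individual_id": ind, "gene": gene, "alleles": ",".join(sorted(alleles))}
        for (ind, gene), alleles in genotypes.items()
    ]
    pd.DataFrame(rows, columns=["individual_id", "gene", "alleles"]).to_csv(
        path, sep="\t", index=False
    )


def read_genotypes(path: str | Path) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    table = GenotypeTable()
    for row in df.itertuples(index=False):
        table.set(row.individual_id, row.gene, row.alleles.split(","))
    return table


def write_events(events: Iterable[ChoiceEvent], path: str | Path) -> None:
    rows = [
        {
            "offspring_id": e.offspring_id,
            "mother_id": e.mother_id,
            "father_id": e.father_id,
            "candidate_ids": ";".join(e.candidate_ids),
            "colony": e.colony,
            "conception_year": e.conception_year,
        }
        for e in events
    ]
    pd.DataFrame(
        rows,
        columns=[
            "offspring_id",
            "mother_id",
            "father_id",
            "candidate_ids",
            "colony",
            "conception_year",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> list[ChoiceEvent]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        ChoiceEvent(
            offspring_id=row.offspring_id,
            mother_id=row.mother_id,
            father_id=row.father_id,
            candidate_ids=tuple(row.candidate_ids.split(";")),
            colony=row.colony,
            conception_year=int(row.conception_year),
        )
        for row in df.itertuples(index=False)
    ]


def write_reads_fasta(reads, path: str | Path) -> None:
    """Write simulated reads; see :mod:`mhcmate.simulate` for the Read type."""
    records = []
    for i, r in enumerate(reads):
        records.append(
            SeqRecord(
                Seq(r.sequence),
                id=f"read{i:06d}",
                description=f"individual={r.individual_id} gene={r.gene}",
            )
        )
    SeqIO.write(records, str(path), "fasta")
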