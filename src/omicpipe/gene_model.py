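"""Gene models parsed from GTF.

Provides the gene universe used throughout the pipeline: exonic gene
lengths (the ``L`` denominator of FPKM normalization), biotype
classification (the protein-coding set whose summed counts form the
library-size denominator), and genomic spans for gene-level copy-number
summaries.

Coordinates follow the GTF convention: 1-based, inclusive on both ends.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import pandas as pd

__all__ = [
    "GeneRecord",
    "GeneModel",
    "GtfParseError",
    "parse_gtf",
    "exonic_length",
    "count_by_biotype",
    "write_gene_table",
]


class GtfParseError(ValueError):
    """Raised when a GTF line cannot be interpreted; names the line number."""


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


@dataclass
class GeneRecord:
    """One gene: identity, biotype, location, and its exon intervals.

    ``exons`` are 1-based inclusive ``(start, end)`` tuples; they may
    overlap and need not be sorted.
    """

    gene_id: str
    biotype: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        """Full genomic extent (min exon start, max exon end)."""
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)


@dataclass
class GeneModel:
    """A collection of gene records keyed by gene_id."""

    records: dict[str, GeneRecord]
    version_label: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self.records[gene_id]

    def protein_coding_ids(self) -> list[str]:
        """Gene ids whose biotype is ``protein_coding``."""
        return [g for g, r in self.records.items() if r.biotype == "protein_coding"]


def _parse_attributes(block: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(block))
    if not attrs:
        raise GtfParseError(f"line {lineno}: malformed attribute block: {block!r}")
    return attrs


def parse_gtf(stream: TextIO | Iterable[str], version_label: str = "") -> GeneModel:
    """Parse ``gene`` and ``exon`` features from GTF text into a GeneModel.

    Each ``gene`` feature becomes one record; ``exon`` features are
    attached to their gene via the ``gene_id`` attribute. Exons appearing
    before their gene feature are tolerated. A gene whose exons land on a
    different chromosome than the gene itself is rejected rather than
    silently split.

    Raises
    ------
    GtfParseError
        On malformed lines/attribute blocks (naming the line number),
        duplicate gene_ids, or cross-chromosome genes.
    """
    records: dict[str, GeneRecord] = {}
    pending_exons: dict[str, list[tuple[str, int, int]]] = {}

    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_block = fields
        if feature not in ("gene", "exon"):
            continue
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise GtfParseError(f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}") from None
        if start > end:
            raise GtfParseError(f"line {lineno}: start {start} > end {end}")
        attrs = _parse_attributes(attr_block, lineno)
        if "gene_id" not in attrs:
            raise GtfParseError(f"line {lineno}: missing gene_id attribute")
        gid = attrs["gene_id"]

        if feature == "gene":
            if gid in records:
                raise GtfParseError(f"line {lineno}: duplicate gene_id {gid!r}")
            biotype = attrs.get("gene_type", attrs.get("gene_biotype", ""))
            records[gid] = GeneRecord(gene_id=gid, biotype=biotype, chrom=chrom, strand=strand)
            for echrom, estart, eend in pending_exons.pop(gid, []):
                if echrom != chrom:
                    raise GtfParseError(
                        f"line {lineno}: gene {gid!r} has exons on {echrom} but gene on {chrom}"
                    )
                records[gid].exons.append((estart, eend))
        else:  # exon
            if gid in records:
                rec = records[gid]
                if chrom != rec.chrom:
                    raise GtfParseError(
                        f"line {lineno}: exon of {gid!r} on {chrom}, gene on {rec.chrom}"
                    )
                rec.exons.append((start, end))
            else:
                pending_exons.setdefault(gid, []).append((chrom, start, end))

    if pending_exons:
        orphan = next(iter(pending_exons))
        raise GtfParseError(f"exon(s) reference unknown gene_id {orphan!r}")
    for rec in records.values():
        if not rec.exons:
            # a gene feature without exon children: treat its own span as one exon
            raise GtfParseError(f"gene {rec.gene_id!r} has no exon features")
    return GeneModel(records=records, version_label=version_label)


def exonic_length(gene: GeneRecord) -> int:
    """Number of bases covered by the union of the gene's exons.

    Overlapping exons are merged; strand is ignored. This is the gene
    length ``L`` used by FPKM and FPKM-UQ.
    """
    if not gene.exons:
        return 0
    total = 0
    cur_s, cur_e = None, None
    for s, e in sorted(gene.exons):
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    total += cur_e - cur_s + 1
    return total


def count_by_biotype(model: GeneModel) -> dict[str, int]:
    """Number of genes per biotype; values sum to ``len(model)``."""
    counts: dict[str, int] = {}
    for rec in model.records.values():
        counts[rec.biotype] = counts.get(rec.biotype, 0) + 1
    return counts


def write_gene_table(model: GeneModel, path: str) -> pd.DataFrame:
    """Write the gene table (gene_id, biotype, chrom, exonic_length) as TSV."""
    rows = [
        {
            "gene_id": r.gene_id,
            "biotype": r.biotype,
            "chrom": r.chrom,
            "exonic_length": exonic_length(r),
        }
        for r in model.records.values()
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "biotype", "chrom", "exonic_length"])
    df.to_csv(path, sep="\t", index=False)
    return df
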