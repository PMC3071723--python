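"""Readers and writers for the pipeline's plain-text formats.

All tables are UTF-8 TSV (descriptions contain commas), counts are strict
integers (no thousands separators, no decimals), and the sentinels "inf"
and "NA" stand for infinite fold values and absent p-values respectively.
"""

from __future__ import annotations

import math
import re
import warnings
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .annotation import AnnotationRecord
from .enrichment import (
    Basis,
    ContigCountRecord,
    EnrichmentCall,
    LibrarySizes,
    PartitionSummary,
)
from .qpcr import CtMeasurement, GroupComparison, RelativeQuantity

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_fasta_lengths",
    "read_annotation_table",
    "read_ceg_hits",
    "read_ct_table",
    "write_calls",
    "write_summary",
    "write_truth_table",
    "write_qpcr_report",
]

COUNT_HEADER = ("contig_id", "count_a", "count_b")
_INT_RE = re.compile(r"^\d+$")


class TableFormatError(ValueError):
    """Malformed input table (message carries the file and line number)."""


def _parse_int(token: str, path: Path, lineno: int, what: str) -> int:
    if not _INT_RE.match(token):
        raise TableFormatError(
            f"{path}:{lineno}: {what} {token!r} is not a plain non-negative "
            "integer (thousands separators and decimals are rejected)"
        )
    return int(token)


def read_count_table(path: str | Path) -> tuple[list[ContigCountRecord], LibrarySizes]:
    """Read a contig count TSV; returns records and reads-in-contigs sizes.

    Header must be ``contig_id<TAB>count_a<TAB>count_b``.  Duplicate ids,
    negative or non-integer counts, and short rows are rejected with the
    offending line number.  A header-only file yields an empty table and
    sizes (0, 0) with a warning (zero sizes cannot feed the test directly).
    """
    path = Path(path)
    records: list[ContigCountRecord] = []
    seen: dict[str, int] = {}
    sum_a = sum_b = 0
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n")
        if tuple(header.split("\t")) != COUNT_HEADER:
            expected = "\t".join(COUNT_HEADER)
            raise TableFormatError(
                f"{path}:1: expected header {expected!r}, got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise TableFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            cid, a_tok, b_tok = fields
            if cid in seen:
                raise TableFormatError(
                    f"{path}:{lineno}: duplicate contig_id {cid!r} "
                    f"(first seen on line {seen[cid]})"
                )
            seen[cid] = lineno
            x = _parse_int(a_tok, path, lineno, "count_a")
            y = _parse_int(b_tok, path, lineno, "count_b")
            records.append(ContigCountRecord(cid, x, y))
            sum_a += x
            sum_b += y
    if not records:
        warnings.warn(f"{path}: count table has no data rows", stacklevel=2)
        return [], LibrarySizes(n_a=1, n_b=1, basis=Basis.READS_IN_CONTIGS)
    return records, LibrarySizes(n_a=sum_a, n_b=sum_b, basis=Basis.READS_IN_CONTIGS)


def write_count_table(records: Iterable[ContigCountRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(COUNT_HEADER) + "\n")
        for rec in records:
            fh.write(f"{rec.contig_id}\t{rec.x}\t{rec.y}\n")


def read_fasta_lengths(path: str | Path) -> dict[str, int]:
    """Sequence lengths (bp) per record id; ids cut at first whitespace.

    Duplicate ids raise; empty sequences are excluded with a warning.
    """
    path = Path(path)
    lengths: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in lengths:
            raise TableFormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        n = len(rec.seq)
        if n == 0:
            warnings.warn(
                f"{path}: record {rec.id!r} has an empty sequence; excluded",
                stacklevel=2,
            )
            continue
        lengths[rec.id] = n
    return lengths


def read_annotation_table(
    path: str | Path,
    fasta_lengths: dict[str, int] | None = None,
) -> list[AnnotationRecord]:
    """Read a contig annotation TSV.

    Columns: contig_id, length_bp, description, go_terms (semicolon-joined,
    optional; the column itself may be absent).  ``fasta_lengths`` fills
    length_bp for rows where it is empty.
    """
    path = Path(path)
    records: list[AnnotationRecord] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if header[:3] != ["contig_id", "length_bp", "description"]:
            raise TableFormatError(
                f"{path}:1: expected columns contig_id, length_bp, description"
                "[, go_terms]"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TableFormatError(
                    f"{path}:{lineno}: expected >= 3 fields, got {len(fields)}"
                )
            cid = fields[0]
            if cid in seen:
                raise TableFormatError(
                    f"{path}:{lineno}: duplicate contig_id {cid!r}"
                )
            seen.add(cid)
            if fields[1]:
                length = _parse_int(fields[1], path, lineno, "length_bp")
            elif fasta_lengths and cid in fasta_lengths:
                length = fasta_lengths[cid]
            else:
                raise TableFormatError(
                    f"{path}:{lineno}: length_bp missing for {cid!r} and no "
                    "FASTA lengths supplied"
                )
            go = (
                tuple(t for t in fields[3].split(";") if t)
                if len(fields) > 3 and fields[3]
                else ()
            )
            records.append(
                AnnotationRecord(
                    contig_id=cid,
                    description=fields[2],
                    length_bp=length,
                    go_terms=go,
                )
            )
    return records


def read_ceg_hits(path: str | Path) -> dict[str, int]:
    """Two-column TSV gene_id, n_hits -> mapping."""
    path = Path(path)
    hits: dict[str, int] = {}
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if header != ["gene_id", "n_hits"]:
            raise TableFormatError(f"{path}:1: expected header gene_id<TAB>n_hits")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise TableFormatError(
                    f"{path}:{lineno}: expected 2 fields, got {len(fields)}"
                )
            gene, tok = fields
            if gene in hits:
                raise TableFormatError(f"{path}:{lineno}: duplicate gene {gene!r}")
            hits[gene] = _parse_int(tok, path, lineno, "n_hits")
    return hits


CT_HEADER = ("sample_id", "group", "gene", "replicate", "ct_target", "ct_reference")


def read_ct_table(path: str | Path) -> list[CtMeasurement]:
    """Long-format qPCR CT table."""
    path = Path(path)
    out: list[CtMeasurement] = []
    with path.open(encoding="utf-8") as fh:
        header = tuple(fh.readline().rstrip("\r\n").split("\t"))
        if header != CT_HEADER:
            expected = "\t".join(CT_HEADER)
            raise TableFormatError(f"{path}:1: expected header {expected!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise TableFormatError(
                    f"{path}:{lineno}: expected 6 fields, got {len(fields)}"
                )
            try:
                out.append(
                    CtMeasurement(
                        sample_id=fields[0],
                        group=fields[1],
                        gene=fields[2],
                        replicate=int(fields[3]),
                        ct_target=float(fields[4]),
                        ct_reference=float(fields[5]),
                    )
                )
            except ValueError as exc:
                raise TableFormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def _fmt_fold(fold: float) -> str:
    return "inf" if math.isinf(fold) else f"{fold:.6g}"


def _fmt_p(p: float | None) -> str:
    return "NA" if p is None else f"{p:.6e}"


CALL_COLUMNS = (
    "contig_id",
    "partition",
    "x",
    "y",
    "rate_a",
    "rate_b",
    "fold",
    "p_value",
    "direction",
    "enriched",
    "robust",
)


def write_calls(calls: Iterable[EnrichmentCall], path: str | Path) -> None:
    """Write enrichment calls as TSV (inf/NA sentinels, p in 6-sig sci)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    [
                        c.contig_id,
                        c.partition.value,
                        str(c.x),
                        str(c.y),
                        f"{c.rate_a:.6e}",
                        f"{c.rate_b:.6e}",
                        _fmt_fold(c.fold),
                        _fmt_p(c.p_value),
                        c.direction.value,
                        str(c.enriched).lower(),
                        str(c.robust).lower(),
                    ]
                )
                + "\n"
            )


def write_summary(
    summary: PartitionSummary,
    path: str | Path,
    n_enriched_a: int | None = None,
    n_enriched_b: int | None = None,
) -> None:
    """Write a partition summary in the study's table layout."""
    path = Path(path)
    lines = [
        ("total_reads", summary.total_reads),
        ("reads_library_a", summary.reads_a),
        ("reads_library_b", summary.reads_b),
        ("n_contigs", summary.n_contigs),
        ("mixed_contigs", summary.n_mixed),
        ("a_only_contigs", summary.n_a_only),
        ("b_only_contigs", summary.n_b_only),
    ]
    if n_enriched_a is not None:
        lines.append(("enriched_toward_a", n_enriched_a))
    if n_enriched_b is not None:
        lines.append(("enriched_toward_b", n_enriched_b))
    with path.open("w", encoding="utf-8") as fh:
        fh.write("metric\tvalue\n")
        for key, value in lines:
            fh.write(f"{key}\t{value}\n")


def write_truth_table(truth, path: str | Path) -> None:
    """Write a simulation truth table (DataFrame) as TSV."""
    truth.to_csv(path, sep="\t", index=False)


def write_qpcr_report(
    rqs: Sequence[RelativeQuantity],
    comparisons: Sequence[GroupComparison],
    rq_path: str | Path,
    comparison_path: str | Path,
) -> None:
    with Path(rq_path).open("w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\tgene\treplicate\tdelta_ct\tdelta_delta_ct\trq\n")
        for r in rqs:
            fh.write(
                f"{r.sample_id}\t{r.group}\t{r.gene}\t{r.replicate}\t"
                f"{r.delta_ct:.6g}\t{r.delta_delta_ct:.6g}\t{r.rq:.6g}\n"
            )
    with Path(comparison_path).open("w", encoding="utf-8") as fh:
        fh.write(
            "gene\tgroup_a\tgroup_b\tmean_rq_a\tmean_rq_b\tt_statistic\t"
            "p_value\tsignificant\tdegenerate\n"
        )
        for c in comparisons:
            fh.write(
                f"{c.gene}\t{c.group_a}\t{c.group_b}\t{c.mean_rq_a:.6g}\t"
                f"{c.mean_rq_b:.6g}\t{c.t_statistic:.6g}\t{c.p_value:.6e}\t"
                f"{str(c.significant).lower()}\t{str(c.degenerate).lower()}\n"
            )
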