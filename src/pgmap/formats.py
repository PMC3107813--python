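"""Input/output: FASTA reading plus the ePST FASTA, TSV and GFF3 writers.

FASTA parsing is delegated to Biopython's ``SeqIO``; this module owns the
normalization rules (case, RNA->DNA, duplicate-id handling, peptide
screening) and the three output formats, which are kept mutually
consistent: every ePST appears as exactly one FASTA record, one TSV row
and one GFF3 feature with identical coordinates.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .automaton import Keyword
from .epst import EPST
from .sixframe import NucleotideRecord, VALID_AMINO_ACIDS

__all__ = [
    "FastaFormatError",
    "ReportRow",
    "TSV_COLUMNS",
    "read_nucleotide_fasta",
    "read_peptide_fasta",
    "report_rows",
    "write_epst_fasta",
    "write_tsv",
    "write_gff3",
]

logger = logging.getLogger(__name__)

_IUPAC_NT = frozenset("ACGTRYSWKMBDHVN")


class FastaFormatError(ValueError):
    """Raised for unreadable or empty FASTA input."""


#: TSV column order; one row per ePST.
TSV_COLUMNS = (
    "peptide_id",
    "peptide_seq",
    "record_header",
    "map_start",
    "map_end",
    "strand",
    "frame",
    "coding_nt",
    "stop_to_stop_nt",
    "epst_nt",
    "epst_start",
    "epst_end",
    "epst_length",
    "epst_protein",
)


@dataclass(frozen=True)
class ReportRow:
    """One detailed TSV line describing a peptide match and its ePST."""

    peptide_id: str
    peptide_seq: str
    record_header: str
    map_start: int
    map_end: int
    strand: str
    frame: str
    coding_nt: str
    stop_to_stop_nt: str
    epst_nt: str
    epst_start: int
    epst_end: int
    epst_length: int
    epst_protein: str


def _iter_fasta(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise FastaFormatError(f"FASTA file not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def _uniquify(seen: dict[str, int], rec_id: str) -> str:
    n = seen.get(rec_id, 0) + 1
    seen[rec_id] = n
    if n == 1:
        return rec_id
    new_id = f"{rec_id}.{n}"
    logger.warning("duplicate FASTA id %r renamed to %r", rec_id, new_id)
    return new_id


def read_nucleotide_fasta(path: str | Path) -> list[NucleotideRecord]:
    """Read genome/contig records: uppercase, U->T, IUPAC letters enforced."""
    out: list[NucleotideRecord] = []
    seen: dict[str, int] = {}
    for rec in _iter_fasta(path):
        seq = str(rec.seq).upper().replace("U", "T")
        seq = re.sub(r"\s", "", seq)
        bad = set(seq) - _IUPAC_NT
        if bad:
            raise FastaFormatError(
                f"record {rec.id!r}: non-IUPAC nucleotide character(s) "
                f"{sorted(bad)}"
            )
        if not seq:
            raise FastaFormatError(f"record {rec.id!r} has an empty sequence")
        out.append(
            NucleotideRecord(
                id=_uniquify(seen, rec.id), description=rec.description, seq=seq
            )
        )
    return out


def read_peptide_fasta(path: str | Path) -> tuple[list[Keyword], list[str]]:
    """Read peptide records; returns (keywords, skipped ids).

    Records containing ``*``, digits or other characters outside the
    20-letter amino-acid alphabet are skipped with a logged warning.
    """
    keywords: list[Keyword] = []
    skipped: list[str] = []
    seen: dict[str, int] = {}
    for rec in _iter_fasta(path):
        seq = re.sub(r"\s", "", str(rec.seq)).upper()
        rec_id = _uniquify(seen, rec.id)
        if not seq or not VALID_AMINO_ACIDS.issuperset(seq):
            bad = sorted(set(seq) - VALID_AMINO_ACIDS)
            logger.warning(
                "skipping peptide record %r: invalid character(s) %s",
                rec_id,
                bad or "<empty sequence>",
            )
            skipped.append(rec_id)
            continue
        keywords.append(Keyword(rec_id, seq))
    return keywords, skipped


def report_rows(
    epsts: list[EPST], headers: dict[str, str] | None = None
) -> list[ReportRow]:
    """Assemble TSV rows from ePSTs (headers map record id -> full header)."""
    headers = headers or {}
    rows = []
    for e in epsts:
        m = e.match
        rows.append(
            ReportRow(
                peptide_id=m.peptide_id,
                peptide_seq=m.peptide_seq,
                record_header=headers.get(m.record_id, m.record_id),
                map_start=m.nt_start,
                map_end=m.nt_end,
                strand=m.strand,
                frame=m.frame_label,
                coding_nt=m.coding_nt,
                stop_to_stop_nt=e.stop_to_stop_nt,
                epst_nt=e.nt_seq,
                epst_start=e.epst_start,
                epst_end=e.epst_end,
                epst_length=len(e.nt_seq),
                epst_protein=e.protein_seq,
            )
        )
    return rows


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def epst_fasta_header(e: EPST) -> str:
    m = e.match
    return (
        f"epst|{m.peptide_id}|{m.record_id}|{e.epst_start}-{e.epst_end}"
        f"|{m.strand}|{m.frame_label}"
    )


def write_epst_fasta(epsts: list[EPST], path: str | Path) -> None:
    """Write one FASTA record per ePST, sequence wrapped at 60 columns."""
    with open(path, "w") as fh:
        for e in epsts:
            fh.write(f">{epst_fasta_header(e)}\n{_wrap(e.nt_seq)}\n")


def write_tsv(rows: list[ReportRow], path: str | Path) -> None:
    """Write the detailed report: header plus one tab-separated row per ePST."""
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for row in rows:
            fh.write(
                "\t".join(str(getattr(row, col)) for col in TSV_COLUMNS) + "\n"
            )


_GFF3_ESCAPE = {";": "%3B", "=": "%3D", "&": "%26", ",": "%2C", "%": "%25"}


def _gff3_escape(value: str) -> str:
    return "".join(_GFF3_ESCAPE.get(ch, ch) for ch in value)


def write_gff3(epsts: list[EPST], path: str | Path) -> None:
    """Write one ``protein_match`` feature per ePST (GFF3, 1-based, start<=end)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, e in enumerate(epsts, 1):
            m = e.match
            phase = "0" if len(e.nt_seq) % 3 == 0 else "."
            attrs = (
                f"ID=epst{i:05d};Name={_gff3_escape(m.peptide_id)};"
                f"Target={_gff3_escape(m.peptide_id)} 1 {len(m.peptide_seq)}"
            )
            fh.write(
                "\t".join(
                    (
                        m.record_id,
                        "pgmap",
                        "protein_match",
                        str(e.epst_start),
                        str(e.epst_end),
                        ".",
                        m.strand,
                        phase,
                        attrs,
                    )
                )
                + "\n"
            )
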