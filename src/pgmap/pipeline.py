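"""End-to-end orchestration: read inputs, map, extend, write the outputs.

``run_pipeline`` is the library entry point behind the command line: it
reads the peptide and nucleotide FASTA files, selects the genetic code,
maps every peptide in all six frames, extends each match into an ePST
under the configured rule, and writes the ePST FASTA, the detailed TSV
and the GFF3 track plus a skipped-peptide list.  Zero matches is a valid
result, not an error.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from . import epst as epst_mod
from .codes import load_builtin_codes, parse_code_table, select_code
from .epst import EPST, SpliceSiteSet
from .formats import (
    read_nucleotide_fasta,
    read_peptide_fasta,
    report_rows,
    write_epst_fasta,
    write_gff3,
    write_tsv,
)
from .sixframe import map_peptides

__all__ = ["PipelineConfig", "RunSummary", "run_pipeline"]

logger = logging.getLogger(__name__)

MODES = ("prokaryote", "eukaryote_signal", "fixed")
SPLICE_SOURCES = ("canonical", "genesplicer", "none")


@dataclass
class PipelineConfig:
    """All run options for one mapping run.

    ``code_table_path`` of ``None`` selects the bundled NCBI table file.
    ``splice_source`` and ``genesplicer_path`` only apply in
    ``eukaryote_signal`` mode; ``extension_nt`` only in ``fixed`` mode.
    """

    peptide_path: str | Path
    genome_path: str | Path
    output_prefix: str | Path
    code_table_path: str | Path | None = None
    code_id: int = 1
    mode: str = "prokaryote"
    splice_source: str = "canonical"
    genesplicer_path: str | Path | None = None
    extension_nt: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.splice_source not in SPLICE_SOURCES:
            raise ValueError(
                f"splice source must be one of {SPLICE_SOURCES}, "
                f"got {self.splice_source!r}"
            )
        if self.mode == "eukaryote_signal" and self.splice_source == "genesplicer":
            if not self.genesplicer_path:
                raise ValueError(
                    "genesplicer splice source requires a prediction file"
                )


@dataclass
class RunSummary:
    """Counts describing one completed run."""

    n_peptides_in: int = 0
    n_peptides_skipped: int = 0
    n_records: int = 0
    n_matches: int = 0
    n_peptides_with_match: int = 0
    n_epsts: int = 0
    per_record_matches: dict[str, int] = field(default_factory=dict)


def _splice_sites_for(config, record, strand, gs_sites):
    """Coding-strand-space splice sites for one record/strand."""
    if config.splice_source == "none":
        return SpliceSiteSet(frozenset(), frozenset(), source="none")
    if config.splice_source == "canonical":
        return epst_mod.canonical_splice_sites(record, strand)
    sites = gs_sites
    if strand == "-":
        sites = epst_mod.mirror_sites(sites, len(record.seq))
    return sites


def run_pipeline(config: PipelineConfig) -> RunSummary:
    """Execute read -> translate -> map -> extend -> write; returns counts."""
    if config.code_table_path is None:
        codes = load_builtin_codes()
    else:
        codes = parse_code_table(Path(config.code_table_path).read_text())
    code = select_code(codes, config.code_id)
    logger.info("using genetic code %d (%s)", code.id, code.name)

    peptides, skipped = read_peptide_fasta(config.peptide_path)
    records = read_nucleotide_fasta(config.genome_path)
    matches = map_peptides(peptides, records, code)

    by_id = {r.id: r for r in records}
    gs_sites = None
    if config.mode == "eukaryote_signal" and config.splice_source == "genesplicer":
        gs_sites = epst_mod.parse_genesplicer(
            Path(config.genesplicer_path).read_text()
        )

    epsts: list[EPST] = []
    for m in matches:
        record = by_id[m.record_id]
        if config.mode == "prokaryote":
            e = epst_mod.extend_prokaryotic(m, record, code)
        elif config.mode == "eukaryote_signal":
            sites = _splice_sites_for(config, record, m.strand, gs_sites)
            e = epst_mod.extend_eukaryotic_signal(m, record, code, sites)
        else:
            e = epst_mod.extend_fixed(m, record, code, config.extension_nt)
        epsts.append(e)

    prefix = Path(config.output_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    headers = {r.id: r.description for r in records}
    write_epst_fasta(epsts, f"{prefix}.fasta")
    write_tsv(report_rows(epsts, headers), f"{prefix}.tsv")
    write_gff3(epsts, f"{prefix}.gff3")
    with open(f"{prefix}.skipped.txt", "w") as fh:
        for pid in skipped:
            fh.write(pid + "\n")

    per_record = Counter(m.record_id for m in matches)
    summary = RunSummary(
        n_peptides_in=len(peptides) + len(skipped),
        n_peptides_skipped=len(skipped),
        n_records=len(records),
        n_matches=len(matches),
        n_peptides_with_match=len({m.peptide_id for m in matches}),
        n_epsts=len(epsts),
        per_record_matches=dict(per_record),
    )
    logger.info(
        "%d/%d peptides matched; %d matches -> %d ePSTs across %d records",
        summary.n_peptides_with_match,
        summary.n_peptides_in,
        summary.n_matches,
        summary.n_epsts,
        summary.n_records,
    )
    return summary
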