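"""Extension of peptide matches into expressed Protein Sequence Tags.

An ePST is the nucleotide neighbourhood of a mapped peptide, extended to
plausible translation boundaries.  Three extension rules are provided:

* **prokaryotic** — extend 3' to the first in-frame stop codon
  (included); locate the first in-frame stop strictly upstream of the
  peptide, then take the first in-frame start codon between that stop and
  the peptide start as the 5' end, falling back to the peptide start when
  no start codon intervenes.
* **eukaryotic signal-bounded** — scan codon-by-codon both ways, stopping
  at the first in-frame stop codon, in-frame start codon (5' only) or
  splice-site signal (GT donor downstream, AG acceptor upstream),
  whichever comes first; splice sites are either canonical dinucleotides
  or GeneSplicer predictions.
* **fixed-length** — a symmetric flank of a user-chosen number of
  nucleotides, clamped at the sequence ends.

All extension happens in coding-strand space: a match on the ``-`` strand
is mirrored onto the reverse complement, extended identically, and the
resulting span mapped back to forward coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .codes import GeneticCode
from .sixframe import NucleotideRecord, PeptideMatch, reverse_complement, _translate

__all__ = [
    "SpliceSiteSet",
    "EPST",
    "GeneSplicerError",
    "canonical_splice_sites",
    "parse_genesplicer",
    "mirror_sites",
    "extend_prokaryotic",
    "extend_eukaryotic_signal",
    "extend_fixed",
]

logger = logging.getLogger(__name__)

# Canonical intron boundary dinucleotides.
_DONOR_SIGNAL = "GT"
_ACCEPTOR_SIGNAL = "AG"


class GeneSplicerError(ValueError):
    """Raised when a GeneSplicer prediction file yields no usable rows."""


@dataclass(frozen=True)
class SpliceSiteSet:
    """Splice signal positions (1-based) on one strand of a record.

    ``donors`` holds the first base of each putative donor (GT) signal,
    ``acceptors`` the last base of each acceptor (AG) signal.
    """

    donors: frozenset[int]
    acceptors: frozenset[int]
    source: str = "canonical"


@dataclass(frozen=True)
class EPST:
    """An extended tag anchored on one peptide match.

    ``epst_start``/``epst_end`` are 1-based inclusive forward-strand
    coordinates; ``nt_seq`` is read on the coding strand, so for ``-``
    strand matches it is the reverse complement of the forward slice.
    ``stop_to_stop_nt`` is the wider context running from the 5' in-frame
    stop codon upstream of the peptide to the 3' in-frame stop downstream
    (both included, truncated at sequence ends).  ``boundary_5`` /
    ``boundary_3`` record which rule terminated each end.
    """

    match: PeptideMatch
    epst_start: int
    epst_end: int
    nt_seq: str
    protein_seq: str
    stop_to_stop_nt: str
    boundary_5: str
    boundary_3: str


# --- coding-strand geometry -------------------------------------------------


def _to_coding(match: PeptideMatch, record: NucleotideRecord):
    """Return (coding_seq, cs_start, cs_end) with 1-based inclusive bounds."""
    L = len(record.seq)
    if match.strand == "+":
        return record.seq, match.nt_start, match.nt_end
    return (
        reverse_complement(record.seq),
        L - match.nt_end + 1,
        L - match.nt_start + 1,
    )


def _to_forward(strand: str, L: int, cs_start: int, cs_end: int) -> tuple[int, int]:
    if strand == "+":
        return cs_start, cs_end
    return L - cs_end + 1, L - cs_start + 1


def _scan_3prime_stop(seq: str, cs_end: int, code: GeneticCode) -> tuple[int, str]:
    """First in-frame stop at/after the peptide end; stop codon included."""
    L = len(seq)
    p = cs_end + 1
    while p + 2 <= L:
        if seq[p - 1 : p + 2] in code.stop_codons:
            return p + 2, "stop_codon"
        p += 3
    return cs_end + 3 * ((L - cs_end) // 3), "sequence_end"


def _upstream_stop(seq: str, cs_start: int, code: GeneticCode) -> int | None:
    """Codon start of the first in-frame stop strictly upstream, if any."""
    s = cs_start - 3
    while s >= 1:
        if seq[s - 1 : s + 2] in code.stop_codons:
            return s
        s -= 3
    return None


def _frame_first_codon(cs_start: int) -> int:
    """Start of the first complete codon of the peptide's frame."""
    return (cs_start - 1) % 3 + 1


def _stop_to_stop(
    seq: str, cs_start: int, cs_end: int, code: GeneticCode
) -> str:
    """Context from the 5' in-frame stop to the 3' in-frame stop, inclusive."""
    up = _upstream_stop(seq, cs_start, code)
    lo = up if up is not None else _frame_first_codon(cs_start)
    hi, _ = _scan_3prime_stop(seq, cs_end, code)
    return seq[lo - 1 : hi]


def _build(
    match: PeptideMatch,
    record: NucleotideRecord,
    code: GeneticCode,
    seq: str,
    lo: int,
    hi: int,
    b5: str,
    b3: str,
    cs_start: int,
    cs_end: int,
    codon_mode: bool = True,
) -> EPST:
    nt_seq = seq[lo - 1 : hi]
    if codon_mode:
        protein = _translate(nt_seq, code)
    else:
        # translate from the first complete codon of the peptide's frame
        t = lo + (_frame_first_codon(cs_start) - lo) % 3
        protein = _translate(seq[t - 1 : hi], code)
    fwd_start, fwd_end = _to_forward(match.strand, len(record.seq), lo, hi)
    return EPST(
        match=match,
        epst_start=fwd_start,
        epst_end=fwd_end,
        nt_seq=nt_seq,
        protein_seq=protein,
        stop_to_stop_nt=_stop_to_stop(seq, cs_start, cs_end, code),
        boundary_5=b5,
        boundary_3=b3,
    )


# --- extension rules --------------------------------------------------------


def extend_prokaryotic(
    match: PeptideMatch, record: NucleotideRecord, code: GeneticCode
) -> EPST:
    """Extend to an ORF-like unit: 5' stop -> first start codon; 3' stop.

    The 3' stop codon is included in the tag.  When no start codon lies
    between the upstream in-frame stop and the peptide, the peptide start
    itself begins the tag; when a sequence end interrupts either scan the
    tag is truncated at the last complete codon and flagged.
    """
    seq, cs_start, cs_end = _to_coding(match, record)
    hi, b3 = _scan_3prime_stop(seq, cs_end, code)

    up = _upstream_stop(seq, cs_start, code)
    scan_from = up + 3 if up is not None else _frame_first_codon(cs_start)
    lo, b5 = cs_start, "peptide_start"
    s = scan_from
    while s <= cs_start:
        if seq[s - 1 : s + 2] in code.start_codons:
            lo, b5 = s, "start_codon"
            break
        s += 3
    return _build(match, record, code, seq, lo, hi, b5, b3, cs_start, cs_end)


def canonical_splice_sites(record: NucleotideRecord, strand: str) -> SpliceSiteSet:
    """Positions of every GT donor / AG acceptor in coding-strand space."""
    seq = record.seq if strand == "+" else reverse_complement(record.seq)
    donors = frozenset(
        i + 1 for i in range(len(seq) - 1) if seq[i : i + 2] == _DONOR_SIGNAL
    )
    acceptors = frozenset(
        i + 2 for i in range(len(seq) - 1) if seq[i : i + 2] == _ACCEPTOR_SIGNAL
    )
    return SpliceSiteSet(donors, acceptors, source="canonical")


def parse_genesplicer(text: str) -> SpliceSiteSet:
    """Parse GeneSplicer predictions: ``end5 end3 score confidence type``.

    Donor rows contribute min(end5, end3) (first base of the signal),
    acceptor rows max(end5, end3) (last base).  Malformed rows are logged
    and skipped; a file with no parseable rows raises
    :class:`GeneSplicerError`.
    """
    donors, acceptors = set(), set()
    n_parsed = 0
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split()
        try:
            end5, end3 = int(fields[0]), int(fields[1])
            site_type = fields[4].lower()
            if site_type == "donor":
                donors.add(min(end5, end3))
            elif site_type == "acceptor":
                acceptors.add(max(end5, end3))
            else:
                raise ValueError(site_type)
        except (IndexError, ValueError):
            logger.warning("skipping malformed GeneSplicer row %d: %r", lineno, line)
            continue
        n_parsed += 1
    if n_parsed == 0:
        raise GeneSplicerError(
            "no parseable rows found; is this a GeneSplicer prediction file?"
        )
    return SpliceSiteSet(frozenset(donors), frozenset(acceptors), source="genesplicer")


def mirror_sites(sites: SpliceSiteSet, length: int) -> SpliceSiteSet:
    """Mirror forward-strand site positions into reverse-complement space."""
    return SpliceSiteSet(
        donors=frozenset(length - p + 1 for p in sites.donors),
        acceptors=frozenset(length - p + 1 for p in sites.acceptors),
        source=sites.source,
    )


def extend_eukaryotic_signal(
    match: PeptideMatch,
    record: NucleotideRecord,
    code: GeneticCode,
    sites: SpliceSiteSet,
) -> EPST:
    """Signal-bounded extension for spliced genomes.

    ``sites`` must already be in the coding-strand space of the match
    (:func:`canonical_splice_sites` produces that directly; forward-strand
    predictions can be converted with :func:`mirror_sites`).  Scanning is
    codon-by-codon and nearest-wins: 3' stops at the first in-frame stop
    codon (included) or just before the first donor signal; 5' stops at
    the first in-frame start codon (included), in-frame stop codon (not
    included) or just after the nearest acceptor signal.
    """
    seq, cs_start, cs_end = _to_coding(match, record)
    L = len(seq)

    donor = min((d for d in sites.donors if d > cs_end), default=None)
    hi, b3 = cs_end, None
    p = cs_end + 1
    while True:
        if p + 2 > L:
            hi, b3 = cs_end + 3 * ((L - cs_end) // 3), "sequence_end"
            break
        if donor is not None and p + 2 >= donor:
            hi, b3 = p - 1, "splice_donor"
            break
        if seq[p - 1 : p + 2] in code.stop_codons:
            hi, b3 = p + 2, "stop_codon"
            break
        p += 3

    acceptor = max((a for a in sites.acceptors if a < cs_start), default=None)
    lo, b5 = cs_start, None
    s = cs_start - 3
    while True:
        if s < 1:
            lo, b5 = _frame_first_codon(cs_start), "sequence_end"
            break
        if acceptor is not None and s <= acceptor:
            lo, b5 = s + 3, "splice_acceptor"
            break
        codon = seq[s - 1 : s + 2]
        if codon in code.stop_codons:
            lo, b5 = s + 3, "stop_codon"
            break
        if codon in code.start_codons:
            lo, b5 = s, "start_codon"
            break
        s -= 3
    return _build(match, record, code, seq, lo, hi, b5, b3, cs_start, cs_end)


def extend_fixed(
    match: PeptideMatch, record: NucleotideRecord, code: GeneticCode, n_nt: int
) -> EPST:
    """Symmetric flank of ``n_nt`` nucleotides, clamped at sequence ends.

    No codon-boundary guarantee: the protein column is translated from the
    first complete codon of the peptide's frame inside the span.
    """
    if n_nt < 0:
        raise ValueError(f"extension length must be non-negative, got {n_nt}")
    seq, cs_start, cs_end = _to_coding(match, record)
    L = len(seq)
    lo = max(1, cs_start - n_nt)
    hi = min(L, cs_end + n_nt)
    b5 = "sequence_end" if cs_start - n_nt < 1 else "fixed_length"
    b3 = "sequence_end" if cs_end + n_nt > L else "fixed_length"
    return _build(
        match, record, code, seq, lo, hi, b5, b3, cs_start, cs_end, codon_mode=False
    )
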