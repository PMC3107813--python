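"""NCBI genetic code tables: parsing, selection and codon translation.

A genetic code table file assigns an amino acid to each of the 64
unambiguous codons (``ncbieaa``, with ``*`` for stop) and flags initiation
codons (``sncbieaa``, ``M`` at start positions).  Codons are listed in the
NCBI order: bases nested T, C, A, G with the first base slowest, so TTT is
codon 0 and GGG is codon 63.

Two dialects are accepted: the NCBI toolkit ``gc.prt`` block layout
(``name``/``id``/``ncbieaa``/``sncbieaa`` fields plus ``-- Base1/2/3``
comment rows) and a simplified layout of bare ``field value`` lines.  A
copy of the common tables in the block layout ships with the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "GeneticCode",
    "CodeTableError",
    "NCBI_CODON_ORDER",
    "parse_code_table",
    "load_builtin_codes",
    "select_code",
    "translate_codon",
    "serialize_code_table",
]

_BASES = "TCAG"
#: The 64 codons in NCBI table order (TTT, TTC, ... GGA, GGG).
NCBI_CODON_ORDER: tuple[str, ...] = tuple(
    a + b + c for a in _BASES for b in _BASES for c in _BASES
)

_DNA = frozenset("ACGT")


class CodeTableError(ValueError):
    """Raised for malformed genetic code table files or bad code lookups."""


@dataclass(frozen=True)
class GeneticCode:
    """A numbered NCBI translation table.

    Attributes
    ----------
    name:
        Human-readable table name, e.g. ``"Standard"``.
    id:
        NCBI translation table number (1 = standard, 11 = bacterial, ...).
    aa_table:
        Mapping of all 64 uppercase DNA codons to one-letter amino acids,
        with ``*`` marking stop codons.
    start_codons:
        Codons flagged as initiation codons in ``sncbieaa``.
    stop_codons:
        Codons translating to ``*``; always disjoint from ``start_codons``.
    """

    name: str
    id: int
    aa_table: dict[str, str]
    start_codons: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if set(self.aa_table) != set(NCBI_CODON_ORDER):
            raise CodeTableError(
                f"code {self.id!r} ({self.name}): aa_table must cover exactly "
                f"the 64 unambiguous codons"
            )
        if self.start_codons & self.stop_codons:
            raise CodeTableError(
                f"code {self.id!r} ({self.name}): start and stop codon sets overlap"
            )

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.aa_table.items() if aa == "*")


def _normalize_codon(codon: str) -> str:
    return codon.upper().replace("U", "T")


def translate_codon(code: GeneticCode, codon: str) -> str:
    """Translate one codon; any non-ACGT character yields ``'X'``.

    Input is uppercased and RNA ``U`` is mapped to ``T`` first, so mixed-case
    and RNA-alphabet FASTA input translates identically.  ``'X'`` can never
    match a peptide residue, which preserves exact-match semantics in the
    presence of ambiguity codes.
    """
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    codon = _normalize_codon(codon)
    if not _DNA.issuperset(codon):
        return "X"
    return code.aa_table[codon]


_FIELD_RE = re.compile(r'^\s*(name|id|ncbieaa|sncbieaa)\s+"?(.*?)"?\s*,?\s*$')


def parse_code_table(text: str) -> list[GeneticCode]:
    """Parse a genetic code table file into :class:`GeneticCode` entries.

    Accepts the NCBI ``gc.prt`` block layout and the simplified line
    layout (see module docstring).  ``-- Base1/2/3`` rows and other
    comments are ignored; the codon order is fixed by convention.
    """
    entries: list[GeneticCode] = []
    current: dict[str, str] = {}
    seen_ids: set[int] = set()

    def flush() -> None:
        if not current:
            return
        for fld in ("name", "id", "ncbieaa", "sncbieaa"):
            if fld not in current:
                label = current.get("name") or current.get("id") or "<unnamed>"
                raise CodeTableError(f"entry {label!r}: missing field {fld!r}")
        name = current["name"]
        try:
            code_id = int(current["id"])
        except ValueError:
            raise CodeTableError(f"entry {name!r}: non-integer id {current['id']!r}")
        for fld in ("ncbieaa", "sncbieaa"):
            if len(current[fld]) != 64:
                raise CodeTableError(
                    f"entry {name!r}: {fld} has length {len(current[fld])}, expected 64"
                )
        if code_id in seen_ids:
            raise CodeTableError(f"duplicate code id {code_id}")
        seen_ids.add(code_id)
        aa_table = dict(zip(NCBI_CODON_ORDER, current["ncbieaa"]))
        starts = frozenset(
            codon
            for codon, flag in zip(NCBI_CODON_ORDER, current["sncbieaa"])
            if flag == "M"
        )
        entries.append(GeneticCode(name, code_id, aa_table, starts))
        current.clear()

    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("--") or not stripped:
            continue
        if stripped.replace(",", "").strip() == "}":
            flush()
            continue
        m = _FIELD_RE.match(line)
        if not m:
            continue
        fld, value = m.group(1), m.group(2)
        # gc.prt entries carry a second short name (e.g. "SGC0"); keep the first.
        if fld == "name" and "name" in current and "ncbieaa" not in current:
            continue
        if fld in current:  # new entry begins (simplified layout has no braces)
            flush()
        current[fld] = value
    flush()

    if not entries:
        raise CodeTableError("no genetic code entries found in table file")
    return entries


def serialize_code_table(codes: list[GeneticCode]) -> str:
    """Render codes back into the NCBI block layout (round-trips the parser)."""
    blocks = []
    for code in codes:
        ncbieaa = "".join(code.aa_table[c] for c in NCBI_CODON_ORDER)
        sncbieaa = "".join(
            "M" if c in code.start_codons else "-" for c in NCBI_CODON_ORDER
        )
        blocks.append(
            " {\n"
            f'  name "{code.name}" ,\n'
            f"  id {code.id} ,\n"
            f'  ncbieaa  "{ncbieaa}",\n'
            f'  sncbieaa "{sncbieaa}"\n'
            "  -- Base1  " + "".join(c[0] for c in NCBI_CODON_ORDER) + "\n"
            "  -- Base2  " + "".join(c[1] for c in NCBI_CODON_ORDER) + "\n"
            "  -- Base3  " + "".join(c[2] for c in NCBI_CODON_ORDER) + "\n"
            " }"
        )
    return "Genetic-code-table ::= {\n" + " ,\n".join(blocks) + "\n}\n"


def load_builtin_codes() -> list[GeneticCode]:
    """Load the genetic code table file distributed with the package."""
    text = (
        resources.files("pgmap.data").joinpath("genetic_code_table.txt").read_text()
    )
    return parse_code_table(text)


def select_code(codes: list[GeneticCode], code_id: int) -> GeneticCode:
    """Return the table with the given NCBI id from a parsed file."""
    for code in codes:
        if code.id == code_id:
            return code
    available = ", ".join(str(c.id) for c in codes) or "none"
    raise CodeTableError(f"code {code_id} not found; available: {available}")
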