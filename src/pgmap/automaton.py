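"""Aho-Corasick multi-pattern exact matching over amino-acid text.

The matcher is built from scratch: a keyword trie whose nodes get failure
links (the longest proper suffix of the node's path that is itself a trie
path) computed breadth-first, with output sets merged along failure links.
Construction is linear in the total length of the patterns and a scan is
linear in the text length — each text character advances the cursor once,
regardless of how many keywords match.  This is what lets a single pass
over a six-frame translated genome find every peptide at once instead of
rescanning per peptide.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

__all__ = ["Keyword", "Hit", "Automaton", "build_automaton", "find_matches"]


@dataclass(frozen=True)
class Keyword:
    """A search pattern: a peptide id and its uppercase amino-acid sequence."""

    id: str
    pattern: str


@dataclass(frozen=True)
class Hit:
    """One occurrence: ``text[start:end]`` equals the keyword's pattern."""

    keyword_id: str
    start: int
    end: int


@dataclass
class Automaton:
    """Goto/fail/output machine over an implicit alphabet.

    State 0 is the root.  ``goto`` holds one sparse transition map per
    state; ``fail`` the failure links (root fails to itself); ``out`` the
    sorted keyword ids whose patterns end at each state (including those
    inherited through failure links).  ``pattern_len`` gives each
    keyword's length so hits can report their start offset.
    """

    goto: list[dict[str, int]] = field(default_factory=lambda: [{}])
    fail: list[int] = field(default_factory=lambda: [0])
    out: list[tuple[str, ...]] = field(default_factory=lambda: [()])
    pattern_len: dict[str, int] = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.goto)


def build_automaton(keywords: list[Keyword]) -> Automaton:
    """Build the keyword trie with failure links.

    Duplicate patterns are allowed; their ids aggregate on the same output
    state.  The state count is bounded by 1 + the summed pattern lengths.
    """
    if not keywords:
        raise ValueError("keyword list must be nonempty")
    auto = Automaton()
    raw_out: list[set[str]] = [set()]
    for kw in keywords:
        if not kw.pattern:
            raise ValueError(f"keyword {kw.id!r} has an empty pattern")
        auto.pattern_len[kw.id] = len(kw.pattern)
        state = 0
        for ch in kw.pattern:
            nxt = auto.goto[state].get(ch)
            if nxt is None:
                nxt = len(auto.goto)
                auto.goto[state][ch] = nxt
                auto.goto.append({})
                auto.fail.append(0)
                raw_out.append(set())
            state = nxt
        raw_out[state].add(kw.id)

    # Breadth-first failure links; outputs inherit from the failure target,
    # so a scan never needs to chase the fail chain to report nested matches.
    queue: deque[int] = deque(auto.goto[0].values())
    while queue:
        state = queue.popleft()
        for ch, nxt in auto.goto[state].items():
            queue.append(nxt)
            f = auto.fail[state]
            while f and ch not in auto.goto[f]:
                f = auto.fail[f]
            auto.fail[nxt] = auto.goto[f].get(ch, 0)
            if auto.fail[nxt] == nxt:  # root self-transition guard
                auto.fail[nxt] = 0
            raw_out[nxt] |= raw_out[auto.fail[nxt]]
    auto.out = [tuple(sorted(s)) for s in raw_out]
    return auto


def find_matches(auto: Automaton, text: str) -> list[Hit]:
    """Report every occurrence of every keyword in ``text``.

    Includes overlapping and nested occurrences.  Hits are ordered by end
    offset, ties broken by keyword id.  Characters outside every pattern
    (e.g. ``*`` or ``X`` in a translated frame) simply reset progress via
    the failure links.
    """
    hits: list[Hit] = []
    state = 0
    for i, ch in enumerate(text):
        while state and ch not in auto.goto[state]:
            state = auto.fail[state]
        state = auto.goto[state].get(ch, 0)
        for kw_id in auto.out[state]:
            end = i + 1
            hits.append(Hit(kw_id, end - auto.pattern_len[kw_id], end))
    return hits
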