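import pytest

from pgmap.codes import load_builtin_codes, select_code


@pytest.fixture(scope="session")
def codes():
    return load_builtin_codes()


@pytest.fixture(scope="session")
def std(codes):
    """The standard genetic code (NCBI table 1)."""
    return select_code(codes, 1)


def naive_hits(patterns: dict[str, str], text: str):
    """Per-keyword overlapping substring scan; the matcher's oracle."""
    hits = set()
    for kid, pat in patterns.items():
        start = text.find(pat)
        while start != -1:
            hits.add((kid, start, start + len(pat)))
            start = text.find(pat, start + 1)
    return hits
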