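"""Drug-name normalization shared by ingestion, tagging and sensitivity filters."""

from __future__ import annotations

import re

_PUNCT = re.compile(r"[^\w\s]", re.UNICODE)


def normalize_name(name: str) -> str:
    """Casefold, replace punctuation by spaces, collapse whitespace.

    ``"VELCADE."`` and ``"velcade"`` normalize identically; tokens inside
    combination strings (``"carfilzomib + dexamethasone"``) survive as
    separate tokens.
    """
    return " ".join(_PUNCT.sub(" ", name.casefold()).split())


def tokens(name: str) -> tuple[str, ...]:
    return tuple(normalize_name(name).split())


def contains_token_phrase(haystack: str, phrase: str) -> bool:
    """True iff the normalized tokens of *phrase* occur as a contiguous
    subsequence of the normalized tokens of *haystack*.

    Exact-token matching, not substring matching: ``"bortez"`` never matches
    ``"bortezomib"``.
    """
    h = tokens(haystack)
    p = tokens(phrase)
    if not p or len(p) > len(h):
        return False
    return any(h[i : i + len(p)] == p for i in range(len(h) - len(p) + 1))
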