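"""Shared tokenization.

One tokenizer serves both the dictionary matcher and the inverted index so
that entity boundaries and index terms agree.  A token is a maximal run of
alphanumeric characters, optionally joined by internal hyphens ("BCR-ABL" is
a single token); any other character is a boundary.  Leading/trailing hyphens
are stripped.  No stemming.
"""

from __future__ import annotations

import re

_TOKEN_RE = re.compile(r"[0-9A-Za-z]+(?:-[0-9A-Za-z]+)*")


def token_spans(text: str) -> list[tuple[int, int, str]]:
    """Return (start, end, token_text) for every token, in text order.

    Spans are 0-based half-open character offsets into ``text``; the token
    text preserves the original case.
    """
    return [(m.start(), m.end(), m.group()) for m in _TOKEN_RE.finditer(text)]


def tokenize(text: str) -> list[str]:
    """Lowercased token stream used for index keys and query terms."""
    return [t.lower() for _, _, t in token_spans(text)]
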