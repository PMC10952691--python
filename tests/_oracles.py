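"""Independent reference implementations used only to cross-check the package.

These are deliberately written against the *textual* form of trait
expressions (not the package's token/AST path) so that agreement between
the two routes is meaningful.
"""

from __future__ import annotations

import re

_HYPHENS = "‐‑‒–−"


def _canon(text: str) -> str:
    for h in _HYPHENS:
        text = text.replace(h, "-")
    return re.sub(r"\s+", "", text)


def _split_top_level_commas(text: str) -> list[str]:
    parts, depth, start = [], 0, 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif ch == "," and depth == 0:
            parts.append(text[start:i])
            start = i + 1
    parts.append(text[start:])
    return parts


def eval_expression_text(raw: str, genes: set[str]) -> bool:
    """Direct recursive interpreter over the printed expression string.

    OR over top-level commas; AND over juxtaposed terms; '-'-signed terms
    ignored; unsigned and '+'-signed atoms required.
    """
    text = _canon(raw)
    return _eval(text, genes)


def _eval(text: str, genes: set[str]) -> bool:
    parts = _split_top_level_commas(text)
    if len(parts) > 1:
        return any(_eval(p, genes) for p in parts)
    # conjunction scan
    i, n = 0, len(text)
    while i < n:
        sign = "+"
        if text[i] in "+-":
            sign = text[i]
            i += 1
        if i < n and text[i] == "(":
            depth, j = 1, i + 1
            while depth:
                if text[j] == "(":
                    depth += 1
                elif text[j] == ")":
                    depth -= 1
                j += 1
            inner = text[i + 1 : j - 1]
            if sign != "-" and not _eval(inner, genes):
                return False
            i = j
        else:
            m = re.match(r"[A-Za-z0-9_]+", text[i:])
            assert m, f"bad expression fragment: {text[i:]!r}"
            symbol = m.group(0)
            if sign != "-" and symbol not in genes:
                return False
            i += len(symbol)
    return True


def n50_bruteforce(lengths: list[int]) -> int:
    """N50 by direct definition: scan descending until >= half the total."""
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc >= total / 2:
            return length
    raise ValueError("empty input")


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
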