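"""RNA sequence primitives shared across the pipeline.

All sequences inside the package live in the uppercase RNA alphabet
``{A, C, G, U}``; DNA input (``T``) is normalized on entry.  Approximate
matching uses edit distance (substitutions, insertions, deletions) in infix
mode — the pattern may match anywhere inside the text — which is the error
model of ``agrep``-style quantification; a Hamming mode (substitutions only,
equal length windows) is available as an alternative interpretation.
"""

from __future__ import annotations

import edlib

RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T to U; reject characters outside the alphabet."""
    s = seq.upper().replace("T", "U")
    if not s:
        raise ValueError("empty sequence")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement in RNA space (A<->U, G<->C)."""
    return seq.translate(_COMPLEMENT)[::-1]


def infix_edit_distance(pattern: str, text: str, max_errors: int) -> int:
    """Minimal edit distance of ``pattern`` to any substring of ``text``.

    Returns -1 when the distance exceeds ``max_errors`` (edlib's convention).
    """
    if not pattern or not text:
        return -1
    return edlib.align(pattern, text, mode="HW", k=max_errors)["editDistance"]


def infix_match(pattern: str, text: str, max_errors: int) -> bool:
    """True iff ``pattern`` occurs inside ``text`` within ``max_errors`` edits."""
    return infix_edit_distance(pattern, text, max_errors) >= 0


def infix_locations(pattern: str, text: str, max_errors: int):
    """Best-distance end locations of ``pattern`` inside ``text``.

    Returns ``(distance, [(start, end), ...])`` with 0-based half-open
    coordinates, or ``(-1, [])`` when nothing matches within ``max_errors``.
    edlib reports inclusive end positions and may leave the start as None for
    infix alignments; the start is recovered conservatively from the pattern
    length.
    """
    res = edlib.align(pattern, text, mode="HW", k=max_errors, task="locations")
    d = res["editDistance"]
    if d < 0:
        return -1, []
    locs = []
    for start, end in res["locations"]:
        if start is None:
            start = max(0, end + 1 - len(pattern) - d)
        locs.append((start, end + 1))
    return d, locs


def hamming_window_match(pattern: str, text: str, max_errors: int) -> bool:
    """Substitution-only infix match: some window of ``text`` with the exact
    pattern length differs in at most ``max_errors`` positions."""
    m, n = len(pattern), len(text)
    if m > n:
        return False
    for start in range(n - m + 1):
        errors = 0
        for a, b in zip(pattern, text[start : start + m]):
            if a != b:
                errors += 1
                if errors > max_errors:
                    break
        else:
            return True
    return False


def hamming_distance(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal-length sequences")
    return sum(x != y for x, y in zip(a, b))
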