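"""Degenerate active-site pattern notation.

Patterns use the compact notation common in PKS literature:

* an uppercase letter matches that residue;
* ``x`` matches any residue;
* a letter followed by a parenthesized alternative list, e.g. ``I(V)``,
  matches exactly one of the listed residues (``I`` or ``V``).

``GHSI(V)GE`` therefore denotes a 6-residue site whose fourth position may
be either isoleucine or valine.
"""

from __future__ import annotations

import re

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_TOKEN = re.compile(r"([A-Zx])(\(([A-Z]+)\))?")


class PatternError(ValueError):
    """Raised for malformed or unsatisfiable degenerate patterns."""


def parse_pattern(pattern: str) -> list[frozenset[str]]:
    """Expand a degenerate pattern into one residue set per position."""
    if not pattern:
        raise PatternError("empty pattern")
    positions: list[frozenset[str]] = []
    pos = 0
    while pos < len(pattern):
        m = _TOKEN.match(pattern, pos)
        if m is None:
            raise PatternError(f"bad pattern {pattern!r} at index {pos}")
        letter, _, alts = m.groups()
        if letter == "x":
            if alts:
                raise PatternError(f"wildcard cannot take alternatives: {pattern!r}")
            positions.append(frozenset(AMINO_ACIDS))
        else:
            allowed = {letter} | set(alts or "")
            bad = allowed - set(AMINO_ACIDS)
            if bad:
                raise PatternError(f"non-residue letters {sorted(bad)} in {pattern!r}")
            positions.append(frozenset(allowed))
        pos = m.end()
    return positions


def pattern_length(pattern: str) -> int:
    return len(parse_pattern(pattern))


def matches(pattern: str, window: str) -> bool:
    """True when *window* satisfies *pattern* exactly (same length)."""
    positions = parse_pattern(pattern)
    if len(window) != len(positions):
        return False
    return all(res in allowed for res, allowed in zip(window, positions))


def to_regex(pattern: str) -> re.Pattern[str]:
    """Compile a degenerate pattern into an anchored-width regex."""
    parts = []
    for allowed in parse_pattern(pattern):
        if len(allowed) == len(AMINO_ACIDS):
            parts.append(f"[{AMINO_ACIDS}]")
        elif len(allowed) == 1:
            parts.append(next(iter(allowed)))
        else:
            parts.append("[" + "".join(sorted(allowed)) + "]")
    return re.compile("".join(parts))


def find_all(pattern: str, sequence: str) -> list[int]:
    """0-based start offsets of every (possibly overlapping) match."""
    rx = to_regex(pattern)
    hits = []
    pos = 0
    while True:
        m = rx.search(sequence, pos)
        if m is None:
            return hits
        hits.append(m.start())
        pos = m.start() + 1


def instantiate(pattern: str, rng, wildcard_alphabet: str = "AEGIKNRST") -> str:
    """Draw a concrete window satisfying *pattern*.

    Wildcard positions are drawn uniformly from *wildcard_alphabet*, a
    deliberately reduced residue set that cannot complete the packaged
    classification motifs by accident.
    """
    out = []
    for allowed in parse_pattern(pattern):
        if len(allowed) == len(AMINO_ACIDS):
            out.append(wildcard_alphabet[rng.integers(len(wildcard_alphabet))])
        else:
            choices = sorted(allowed)
            out.append(choices[rng.integers(len(choices))])
    return "".join(out)
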