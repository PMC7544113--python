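"""Vectorised IUPAC pattern matching on circular sequences.

Shared by the in silico PCR and restriction modules.  A pattern position
written with an IUPAC ambiguity code matches any base of its expansion; an
ambiguity code (including N) in the *genome* never matches anything —
conservative behaviour for assembled sequences.
"""

from __future__ import annotations

import numpy as np

from .errors import PlastotypeError
from .io import IUPAC_EXPAND, CircularSequence

_TABLES: dict[str, np.ndarray] = {}


def _allowed_table(code: str) -> np.ndarray:
    """Boolean lookup over byte values: genome bytes matched by pattern code."""
    tab = _TABLES.get(code)
    if tab is None:
        tab = np.zeros(256, dtype=bool)
        for b in IUPAC_EXPAND[code]:
            tab[ord(b)] = True
        _TABLES[code] = tab
    return tab


def find_matches(seq: CircularSequence, pattern: str, max_mismatch: int = 0):
    """All start positions where ``pattern`` matches ``seq``.

    Returns a list of ``(position, mismatches)`` with 1-based start
    positions.  On a circular sequence, matches may wrap the origin and
    every rotation yields the same circular start set.
    """
    pattern = pattern.upper()
    m = len(pattern)
    n = len(seq)
    if m > n:
        raise PlastotypeError(
            f"pattern of length {m} longer than sequence of length {n}"
        )
    for c in pattern:
        if c not in IUPAC_EXPAND:
            raise PlastotypeError(f"pattern contains non-IUPAC character {c!r}")
    g = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)
    if seq.circular:
        gd = np.concatenate([g, g[: m - 1]])
        nwin = n
    else:
        gd = g
        nwin = n - m + 1
    mism = np.zeros(nwin, dtype=np.int32)
    for j, c in enumerate(pattern):
        mism += ~_allowed_table(c)[gd[j : j + nwin]]
    hits = np.nonzero(mism <= max_mismatch)[0]
    return [(int(p) + 1, int(mism[p])) for p in hits]
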