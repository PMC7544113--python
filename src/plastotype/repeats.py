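"""Repeat scanning: microsatellites, tandem repeats and dispersed repeats.

Three detectors at the thresholds conventional for plastome surveys:

* perfect SSRs (unit 1–6 bp) with minimum copy numbers 10 / 5 / 4 / 3 / 3 / 3
  for mono- through hexanucleotide units;
* near-tandem duplications with periods above the SSR range, scored against
  a per-column consensus unit;
* dispersed repeat pairs (forward, reverse, complement, palindromic) of at
  least 30 bp with Hamming distance at most 3, enumerated as canonical
  maximal intervals per diagonal via exact-seed windows — by pigeonhole any
  qualifying pair shares an exact seed of ``min_len // (max_mismatch + 1)``
  aligned bases, so the seeded scan is complete.

Every reported repeat is self-verifying: re-extracting its copies from the
sequence reproduces the stated identity / mismatch bound.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import CircularSequence, complement, revcomp

#: Minimum perfect copy numbers per unit size.
DEFAULT_SSR_THRESHOLDS = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}


def canonical_motif(motif: str) -> str:
    """Lexicographic minimum over all rotations of the motif and of its
    reverse complement — a strand- and phase-independent motif label."""
    rc = revcomp(motif)
    u = len(motif)
    return min(
        min(motif[i:] + motif[:i] for i in range(u)),
        min(rc[i:] + rc[:i] for i in range(u)),
    )


def _is_primitive(motif: str) -> bool:
    """True when the motif is not a whole-number repetition of a shorter unit."""
    u = len(motif)
    for p in range(1, u):
        if u % p == 0 and motif == motif[:p] * (u // p):
            return False
    return True


@dataclass(frozen=True)
class Ssr:
    """A perfect simple-sequence repeat (microsatellite)."""

    motif: str
    canonical: str
    unit: int
    copies: int
    start: int   # 1-based; on a circle the run may wrap the origin
    length: int  # copies * unit

    @property
    def end(self) -> int:
        return self.start + self.length - 1


def find_ssrs(seq: CircularSequence, thresholds: dict | None = None) -> list:
    """All maximal perfect tandem runs of 1–6 bp units meeting the copy-number
    thresholds.

    Runs are reported 5'→3' at the primitive unit of their motif (an ATAT…
    run is a dinucleotide repeat, never a tetranucleotide one), with the
    canonical strand-independent motif attached.  Runs crossing the circular
    origin are found once, so SSR counts are rotation-invariant.
    """
    thr = dict(DEFAULT_SSR_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    s = seq.residues
    n = len(s)
    if seq.circular:
        ext = s + s[: min(n - 1, 600)]
    else:
        ext = s
    g = np.frombuffer(ext.encode("ascii"), dtype=np.uint8)
    out = []
    for u, min_copies in sorted(thr.items()):
        if len(ext) <= u:
            continue
        eq = g[:-u] == g[u:]
        idx = np.flatnonzero(eq)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        for a, b in zip(idx[starts], idx[ends]):
            if a >= n:  # duplicate of a run already seen in the first copy
                continue
            if seq.circular and a == 0 and s[-1] == s[(u - 1) % n]:
                continue  # continuation of a run that wraps the origin
            total = min(int(b - a + 1) + u, n)
            copies = total // u
            if copies < min_copies:
                continue
            motif = ext[a : a + u]
            if not _is_primitive(motif):
                continue
            out.append(
                Ssr(motif, canonical_motif(motif), u, copies, a + 1, copies * u)
            )
    return sorted(out, key=lambda r: (r.start, r.unit))


@dataclass(frozen=True)
class TandemRepeatHit:
    """A (near-)tandem duplication with period above the SSR range.

    ``identity`` is the fraction of run positions agreeing with the
    per-column consensus unit; ``copies`` may be fractional.
    """

    period: int
    copies: float
    start: int
    length: int
    unit: str
    identity: float


def _consensus_identity(region: str, p: int):
    """Majority consensus unit of a run and the run's identity to it."""
    cols = [[] for _ in range(p)]
    for i, ch in enumerate(region):
        cols[i % p].append(ch)
    unit = "".join(max(sorted(set(c)), key=c.count) for c in cols)
    mismatches = sum(1 for i, ch in enumerate(region) if ch != unit[i % p])
    return unit, 1.0 - mismatches / len(region)


def find_tandem_repeats(
    seq: CircularSequence,
    min_period: int = 7,
    max_period: int = 100,
    min_len: int = 26,
    min_identity: float = 0.9,
) -> list:
    """Deterministic detection of near-tandem duplications.

    For each candidate period the self-match profile of the sequence at
    that lag is segmented into runs (tolerating the isolated breaks a
    substitution leaves), and each candidate run is scored against its
    consensus unit.  Overlapping hits across periods are merged keeping the
    highest-identity (then smallest-period) hit.
    """
    s = seq.residues
    n = len(s)
    ext = s + s[: min(n - 1, 2 * max_period)] if seq.circular else s
    g = np.frombuffer(ext.encode("ascii"), dtype=np.uint8)
    hits = []
    for p in range(min_period, min(max_period, len(ext) // 2) + 1):
        eq = g[:-p] == g[p:]
        idx = np.flatnonzero(eq)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        raw_runs = [
            (int(a), int(b)) for a, b in zip(idx[starts], idx[ends])
            # runs shorter than 4 are chance matches at this lag, not copies
            if b - a + 1 >= min(4, p)
        ]
        # merge runs separated by the isolated breaks a substitution leaves
        merged = []
        for a, b in raw_runs:
            if merged and a - merged[-1][1] - 1 <= 3:
                merged[-1][1] = b
            else:
                merged.append([a, b])
        for a, b in merged:
            if a >= n:
                continue
            total = int(b - a + 1) + p
            if total < max(min_len, 2 * p):
                continue
            region = ext[a : a + total]
            unit, ident = _consensus_identity(region, p)
            if ident < min_identity:
                continue
            hits.append(
                TandemRepeatHit(p, round(total / p, 2), a + 1, total, unit, ident)
            )
    # resolve overlaps: highest identity wins, then smallest period
    hits.sort(key=lambda h: (-h.identity, h.period, h.start))
    kept = []
    for h in hits:
        h_end = h.start + h.length - 1
        clash = False
        for k in kept:
            k_end = k.start + k.length - 1
            ov = min(h_end, k_end) - max(h.start, k.start) + 1
            if ov > 0.5 * min(h.length, k.length):
                clash = True
                break
        if not clash:
            kept.append(h)
    return sorted(kept, key=lambda h: (h.start, h.period))


@dataclass(frozen=True)
class DispersedRepeatHit:
    """A pair of similar copies at distinct loci.

    ``start1``/``start2`` are 1-based starts of the two copies (start1 <
    start2); for 'palindromic' the second copy is the reverse complement of
    the first, for 'reverse' its reversal, for 'complement' its base-wise
    complement.
    """

    orientation: str  # 'forward' | 'palindromic' | 'reverse' | 'complement'
    start1: int
    start2: int
    length: int
    mismatches: int

    def extract(self, seq: CircularSequence):
        """Return the two copies, the second transformed back to the first's
        orientation (self-verification helper)."""
        c1 = seq.residues[self.start1 - 1 : self.start1 - 1 + self.length]
        c2 = seq.residues[self.start2 - 1 : self.start2 - 1 + self.length]
        if self.orientation == "palindromic":
            c2 = revcomp(c2)
        elif self.orientation == "reverse":
            c2 = c2[::-1]
        elif self.orientation == "complement":
            c2 = complement(c2)
        return c1, c2


_ORIENTATIONS = ("forward", "palindromic", "reverse", "complement")


def _maximal_intervals(vfun, lo: int, hi: int, i_min: int, i_max: int,
                       budget: int, min_len: int):
    """Canonical maximal intervals of a mismatch indicator within [lo, hi].

    ``vfun(i)`` gives 0/1 mismatch at diagonal coordinate ``i`` for any
    ``i_min-1 <= i <= i_max+1`` (out-of-range treated as blocking).  Yields
    ``(a, b, mismatches)`` for every interval of length >= min_len that
    cannot be extended on either side without exceeding the budget.
    """
    a = lo
    b = lo - 1
    mism = 0
    while a <= hi:
        if b < a - 1:
            b = a - 1
            mism = 0
        while b < i_max and mism + vfun(b + 1) <= budget:
            b += 1
            mism += vfun(b)
        length = b - a + 1
        left_blocked = a == i_min or (mism + vfun(a - 1) > budget)
        right_blocked = b == i_max or (mism + vfun(b + 1) > budget)
        if length >= min_len and left_blocked and right_blocked:
            yield a, b, mism
        mism -= vfun(a)
        a += 1


def find_dispersed_repeats(
    seq: CircularSequence,
    min_len: int = 30,
    max_mismatch: int = 3,
    include_ir_pair: bool = False,
    ir_intervals: tuple | None = None,
) -> list:
    """All maximal dispersed repeat pairs in the four orientations.

    Seed length is ``max(4, min_len // (max_mismatch + 1))`` exact bases
    (complete by pigeonhole); candidate diagonals are then resolved into
    canonical maximal intervals.  Copies must not overlap.  The genome-scale
    IR pair would dominate the report, so by default palindromic hits whose
    copies both lie inside supplied ``ir_intervals`` — or, lacking those,
    palindromic hits of 1 kb and more — are excluded; pass
    ``include_ir_pair=True`` to keep them.

    The scan is linear in the given rotation (a pair straddling the origin
    is found after rotation).
    """
    s = seq.residues
    n = len(s)
    k = max(4, min_len // (max_mismatch + 1))
    s_arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    pad = (max_mismatch + 1) * (k + 1) + min_len
    results = {}
    for orientation in _ORIENTATIONS:
        if orientation == "forward":
            t = s
        elif orientation == "palindromic":
            t = revcomp(s)
        elif orientation == "reverse":
            t = s[::-1]
        else:
            t = complement(s)
        t_arr = np.frombuffer(t.encode("ascii"), dtype=np.uint8)
        reversed_map = orientation in ("palindromic", "reverse")

        index = defaultdict(list)
        for q in range(n - k + 1):
            index[t[q : q + k]].append(q)
        diagonals = defaultdict(list)
        for i in range(n - k + 1):
            for q in index.get(s[i : i + k], ()):
                d = q - i
                if orientation in ("forward", "complement") and d <= 0:
                    continue  # symmetric / trivial diagonal
                diagonals[d].append(i)

        for d, anchors in diagonals.items():
            i_min = max(0, -d)
            i_max = min(n - 1, n - 1 - d)
            anchors = sorted(set(anchors))
            segments = []
            for a in anchors:
                lo = max(i_min, a - pad)
                hi = min(i_max, a + k - 1 + pad)
                if segments and lo <= segments[-1][1] + 1:
                    segments[-1][1] = max(segments[-1][1], hi)
                else:
                    segments.append([lo, hi])
            for lo, hi in segments:
                if hi - lo + 1 < min_len:
                    continue
                v_lo = max(i_min, lo - 1)
                v_hi = min(i_max, hi + 1 + pad)
                v_seg = (
                    s_arr[v_lo : v_hi + 1] != t_arr[v_lo + d : v_hi + d + 1]
                ).astype(np.int8)
                # fast reject: no min_len window in this segment fits the budget
                if len(v_seg) < min_len:
                    continue
                csum = np.concatenate(([0], np.cumsum(v_seg)))
                if (csum[min_len:] - csum[:-min_len]).min() > max_mismatch:
                    continue

                def vfun(i, _v=v_seg, _lo=v_lo, _hi=v_hi):
                    if _lo <= i <= _hi:
                        return int(_v[i - _lo])
                    return 1

                for a, b, mism in _maximal_intervals(
                    vfun, lo, hi, i_min, i_max, max_mismatch, min_len
                ):
                    length = b - a + 1
                    if reversed_map:
                        j = n - 1 - (b + d)
                    else:
                        j = a + d
                    x1, x2 = sorted((a, j))
                    if x2 <= x1 + length - 1:
                        continue  # overlapping copies are tandem, not dispersed
                    key = (orientation, x1, x2, length)
                    results[key] = DispersedRepeatHit(
                        orientation, x1 + 1, x2 + 1, length, mism
                    )

    hits = list(results.values())
    if not include_ir_pair:
        if ir_intervals is not None:
            (s1, e1), (s2, e2) = ir_intervals

            def mostly_inside(x, length, lo, hi):
                ov = min(x + length - 1, hi) - max(x, lo) + 1
                return ov >= 0.8 * length

            hits = [
                h for h in hits
                if not (
                    h.orientation == "palindromic"
                    and mostly_inside(h.start1, h.length, s1, e1)
                    and mostly_inside(h.start2, h.length, s2, e2)
                )
            ]
        else:
            hits = [
                h for h in hits
                if not (h.orientation == "palindromic" and h.length >= 1000)
            ]
    return sorted(hits, key=lambda h: (h.start1, h.start2, h.orientation))


def write_repeats(ssrs, tandems, dispersed, path) -> None:
    """Combined repeat report TSV."""
    with Path(path).open("w") as fh:
        fh.write("class\tmotif_or_unit\tstart\tstart2\tlength\tcopies\tdetail\n")
        for r in ssrs:
            fh.write(
                f"SSR\t{r.motif}\t{r.start}\t-\t{r.length}\t{r.copies}\t"
                f"canonical={r.canonical}\n"
            )
        for t in tandems:
            fh.write(
                f"tandem\t{t.unit}\t{t.start}\t-\t{t.length}\t{t.copies}\t"
                f"identity={t.identity:.3f}\n"
            )
        for h in dispersed:
            fh.write(
                f"dispersed\t{h.orientation}\t{h.start1}\t{h.start2}\t{h.length}\t2\t"
                f"mismatches={h.mismatches}\n"
            )
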