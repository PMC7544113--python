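"""Quadripartite structure of a plastome.

Land-plant plastomes carry two identical inverted-repeat copies (IRb, IRa)
that separate a large and a small single-copy region (LSC, SSC).  This
module finds the longest exact inverted-repeat pair on the circle,
partitions the genome into the four segments, canonicalises the rotation
so the LSC starts at position 1 (the convention used for deposited potato
plastomes), and reports the genes at the four junctions:

    JLB  LSC|IRb      JSB  IRb|SSC      JSA  SSC|IRa      JLA  IRa|LSC

Junction positions are reported as the 1-based coordinate of the *last*
base of the upstream segment; the physical junction lies between that base
and the next one.  IR detection is exact-match by design: the IR copies of
assembled plastomes are perfect duplicates, and exactness keeps detection
deterministic and rotation-invariant.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

from .errors import DegenerateGenomeError, PlastotypeError, StructureNotFoundError
from .io import CircularSequence, FeatureTable, revcomp, rotate


def _interval_len(iv: tuple, n: int) -> int:
    """Length of a 1-based inclusive circular interval (start, end)."""
    s, e = iv
    return (e - s) % n + 1


@dataclass(frozen=True)
class QuadripartiteStructure:
    """LSC/IRb/SSC/IRa intervals plus the four junction positions.

    Intervals are 1-based inclusive and may wrap the origin (start > end)
    until :func:`canonicalize` has been applied.
    """

    lsc: tuple
    irb: tuple
    ssc: tuple
    ira: tuple
    genome_length: int

    def __post_init__(self):
        n = self.genome_length
        lens = [self.segment_length(k) for k in ("lsc", "irb", "ssc", "ira")]
        if sum(lens) != n:
            raise DegenerateGenomeError(
                f"segment lengths {lens} do not sum to genome length {n}"
            )
        if self.segment_length("irb") != self.segment_length("ira"):
            raise DegenerateGenomeError("IR copies of unequal length")
        if self.segment_length("lsc") <= self.segment_length("ssc"):
            raise DegenerateGenomeError("LSC not longer than SSC")

    def segment_length(self, name: str) -> int:
        return _interval_len(getattr(self, name), self.genome_length)

    @property
    def ir_length(self) -> int:
        return self.segment_length("irb")

    @property
    def junctions(self) -> dict:
        """Junction positions: last base of the upstream segment."""
        return {
            "JLB": self.lsc[1],
            "JSB": self.irb[1],
            "JSA": self.ssc[1],
            "JLA": self.ira[1],
        }

    @property
    def is_canonical(self) -> bool:
        return self.lsc[0] == 1

    def segments(self):
        for name in ("lsc", "irb", "ssc", "ira"):
            yield name.upper() if name != "lsc" else "LSC", getattr(self, name)


def find_inverted_repeat(seq: CircularSequence, min_len: int = 1000) -> tuple:
    """Longest pair of non-overlapping exact reverse-complement intervals.

    Returns two 1-based inclusive intervals ``((s1, e1), (s2, e2))`` with
    ``s1 < s2``, each at least ``min_len`` bp; ties are broken by the
    smaller start of the first interval.  Raises
    :class:`StructureNotFoundError` when no such pair exists (the genome is
    then not quadripartite at this threshold).

    The default ``min_len`` of 1000 bp skips small dispersed inverted
    repeats; plastome IRs are tens of kb.
    """
    if not seq.circular:
        raise PlastotypeError("inverted-repeat detection requires a circular sequence")
    n = len(seq)
    if n <= 2 * min_len:
        raise StructureNotFoundError(
            f"genome of {n} bp too short for two IR copies of >= {min_len} bp"
        )
    s = seq.residues
    dd = s + s
    rd = revcomp(dd)
    k = min(min_len, 21)

    index = defaultdict(list)
    for q in range(len(rd) - k + 1):
        index[rd[q : q + k]].append(q)

    diagonals = defaultdict(list)
    for p in range(len(dd) - k + 1):
        for q in index.get(dd[p : p + k], ()):
            diagonals[p - q].append(p)

    candidates = set()
    for d, ps in diagonals.items():
        ps.sort()
        run_start = prev = ps[0]
        runs = []
        for p in ps[1:]:
            if p == prev + 1:
                prev = p
            else:
                runs.append((run_start, prev))
                run_start = prev = p
        runs.append((run_start, prev))
        for p0, p1 in runs:
            length = min(p1 - p0 + k, n)
            if length < min_len:
                continue
            q0 = p0 - d
            a = p0 % n
            b = (2 * n - length - q0) % n
            if a == b:
                continue
            # circular overlap check
            if (b - a) % n < length or (a - b) % n < length:
                continue
            first, second = sorted((a, b))
            candidates.add((first, second, length))

    if not candidates:
        raise StructureNotFoundError(
            f"no inverted repeat of >= {min_len} bp found in {seq.id!r}"
        )
    first, second, length = min(candidates, key=lambda c: (-c[2], c[0], c[1]))
    iv1 = (first + 1, (first + length - 1) % n + 1)
    iv2 = (second + 1, (second + length - 1) % n + 1)
    return iv1, iv2


def partition_quadripartite(seq: CircularSequence, ir_pair: tuple) -> QuadripartiteStructure:
    """Partition the circle into LSC, IRb, SSC and IRa.

    The longer of the two arcs between the IR copies is the LSC, the
    shorter the SSC; IRb is the IR copy that follows the LSC in forward
    orientation.  Equal arcs are a degenerate genome and rejected.
    """
    n = len(seq)
    (s1, e1), (s2, e2) = ir_pair
    ir_len = _interval_len(ir_pair[0], n)
    if ir_len != _interval_len(ir_pair[1], n):
        raise DegenerateGenomeError("IR pair with unequal lengths")
    a0, b0 = s1 - 1, s2 - 1
    gap_ab = (b0 - (a0 + ir_len)) % n  # arc after interval 1
    gap_ba = (a0 - (b0 + ir_len)) % n  # arc after interval 2
    if gap_ab == gap_ba:
        raise DegenerateGenomeError("inter-IR arcs of equal length")
    if gap_ab == 0 or gap_ba == 0:
        raise DegenerateGenomeError("adjacent IR copies leave an empty arc")
    if gap_ab > gap_ba:
        lsc = ((a0 + ir_len) % n + 1, (b0 - 1) % n + 1)
        irb = (s2, e2)
        ssc = ((b0 + ir_len) % n + 1, (a0 - 1) % n + 1)
        ira = (s1, e1)
    else:
        lsc = ((b0 + ir_len) % n + 1, (a0 - 1) % n + 1)
        irb = (s1, e1)
        ssc = ((a0 + ir_len) % n + 1, (b0 - 1) % n + 1)
        ira = (s2, e2)
    return QuadripartiteStructure(lsc, irb, ssc, ira, n)


def detect_structure(seq: CircularSequence, min_len: int = 1000) -> QuadripartiteStructure:
    """Convenience: IR detection followed by partitioning."""
    return partition_quadripartite(seq, find_inverted_repeat(seq, min_len))


def canonicalize(seq: CircularSequence, structure: QuadripartiteStructure):
    """Rotate so that the LSC begins at position 1; idempotent.

    Returns ``(rotated_sequence, updated_structure)``.  Only the rotation
    is canonicalised — the input strand is preserved.
    """
    n = structure.genome_length
    origin = structure.lsc[0]
    if origin == 1:
        return seq, structure
    rotated = rotate(seq, origin)

    def shift(iv):
        s, e = iv
        return ((s - origin) % n + 1, (e - origin) % n + 1)

    new = QuadripartiteStructure(
        shift(structure.lsc), shift(structure.irb),
        shift(structure.ssc), shift(structure.ira), n,
    )
    return rotated, new


@dataclass(frozen=True)
class JunctionEntry:
    """Primary feature at one junction.

    ``relation`` is 'spans' when the feature covers both flanking bases of
    the junction, otherwise 'upstream'/'downstream' for the nearest feature
    with its distance in bp (0 when abutting).
    """

    junction: str
    position: int
    feature: str          # feature name or 'none'
    relation: str         # 'spans' | 'upstream' | 'downstream' | 'none'
    distance: int = 0
    neighbors: tuple = () # (name, relation, distance) for both sides when not spanned


@dataclass(frozen=True)
class JunctionReport:
    entries: tuple

    def __getitem__(self, junction: str) -> JunctionEntry:
        for e in self.entries:
            if e.junction == junction:
                return e
        raise KeyError(junction)


def junction_report(structure: QuadripartiteStructure, features: FeatureTable) -> JunctionReport:
    """Locate the gene containing or nearest each of the four junctions.

    Features must be on the canonicalised coordinate system.  A feature
    spans a junction at position J when it covers both J and J+1 (mod
    genome length); origin-wrapping features are handled through their
    flagged halves.
    """
    if not structure.is_canonical:
        raise PlastotypeError("junction_report requires a canonicalized structure")
    n = structure.genome_length
    entries = []
    for name, pos in structure.junctions.items():
        nxt = pos % n + 1
        spanning = [
            f for f in features
            if (f.start <= pos <= f.end and f.start <= nxt <= f.end)
            or (f.wraps_origin and ((f.end == n and pos == n) or (f.start == 1 and nxt == 1)))
        ]
        if spanning:
            f = min(spanning, key=lambda f: (len(f), f.name))
            entries.append(JunctionEntry(name, pos, f.name, "spans", 0))
            continue
        best = None
        sides = []
        for f in features:
            up_d = (pos - f.end) % n       # feature upstream of the junction
            down_d = (f.start - nxt) % n   # feature downstream of the junction
            if up_d <= down_d:
                cand = (up_d, f.name, "upstream")
            else:
                cand = (down_d, f.name, "downstream")
            sides.append(cand)
            if best is None or cand < best:
                best = cand
        if best is None:
            entries.append(JunctionEntry(name, pos, "none", "none"))
        else:
            up = min((c for c in sides if c[2] == "upstream"), default=None)
            down = min((c for c in sides if c[2] == "downstream"), default=None)
            neighbors = tuple(
                (c[1], c[2], c[0]) for c in (up, down) if c is not None
            )
            entries.append(
                JunctionEntry(name, pos, best[1], best[2], best[0], neighbors)
            )
    return JunctionReport(tuple(entries))


def drop_one_ir(seq: CircularSequence, structure: QuadripartiteStructure) -> CircularSequence:
    """Linearised sequence with the IRb copy removed (LSC + SSC + IRa).

    Used to de-duplicate the IR before phylogenetic analysis.  The result
    is linear; running structure detection on it fails, so the operation
    cannot be applied twice.
    """
    lsc = seq.fetch(*structure.lsc)
    ssc = seq.fetch(*structure.ssc)
    ira = seq.fetch(*structure.ira)
    return CircularSequence(seq.id, lsc + ssc + ira, circular=False)


def write_structure(structure: QuadripartiteStructure, genome_id: str, path) -> None:
    """Structure report TSV: segment, start, end, length."""
    with Path(path).open("w") as fh:
        fh.write("genome\tsegment\tstart\tend\tlength\n")
        for name, (s, e) in structure.segments():
            fh.write(
                f"{genome_id}\t{name}\t{s}\t{e}\t"
                f"{_interval_len((s, e), structure.genome_length)}\n"
            )


def write_junctions(report: JunctionReport, genome_id: str, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("genome\tjunction\tposition\tfeature\trelation\tdistance\n")
        for e in report.entries:
            fh.write(
                f"{genome_id}\t{e.junction}\t{e.position}\t{e.feature}\t"
                f"{e.relation}\t{e.distance}\n"
            )
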