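"""In silico PCR on circular genomes.

Potato cpDNA types are profiled with chloroplast microsatellite (NTCP)
markers whose PCR product *sizes* are diagnostic.  This module locates
primer-binding sites on the circle (IUPAC-aware, optional mismatches) and
derives amplicon sizes, including products that span the sequence origin.

The primer sequences of the published NTCP panel are not distributed with
the package (they come from the marker literature, not from this work);
``load_primer_panel`` reads a user-supplied panel TSV and the packaged
template ``data/primer_panel_template.tsv`` shows the format.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from ._match import find_matches
from .errors import PlastotypeError
from .io import IUPAC_EXPAND, CircularSequence, revcomp


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primers of one marker, both written 5'→3'."""

    marker: str
    forward: str
    reverse: str

    def __post_init__(self):
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if len(p) < 10:
                raise PlastotypeError(
                    f"marker {self.marker}: {name} primer shorter than 10 nt"
                )
            bad = set(p) - set(IUPAC_EXPAND)
            if bad:
                raise PlastotypeError(
                    f"marker {self.marker}: {name} primer has non-IUPAC {sorted(bad)}"
                )


@dataclass(frozen=True)
class PrimerSite:
    """One primer-binding site; ``position`` is the 1-based 5' end of the
    primer on the genome's forward coordinate system."""

    position: int
    strand: str  # '+' or '-'
    mismatches: int


def find_primer_sites(seq: CircularSequence, primer: str, max_mismatch: int = 0) -> list:
    """All circular binding sites of a primer on either strand.

    A '+' hit anneals to the bottom strand and extends rightwards; a '-'
    hit anneals to the top strand (the primer matches as its reverse
    complement) and extends leftwards.  IUPAC codes in the primer match
    their expansion; N or ambiguity codes in the genome never match.
    """
    m = len(primer)
    sites = [
        PrimerSite(pos, "+", mm) for pos, mm in find_matches(seq, primer, max_mismatch)
    ]
    n = len(seq)
    for pos, mm in find_matches(seq, revcomp(primer), max_mismatch):
        five_prime = (pos - 1 + m - 1) % n + 1
        sites.append(PrimerSite(five_prime, "-", mm))
    return sorted(sites, key=lambda s: (s.position, s.strand))


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product on the circle.

    ``start`` and ``end`` are the 5' ends of the two primers (1-based);
    ``length`` is the circular distance from start to end inclusive, i.e.
    the product includes both primer footprints.
    """

    marker: str
    start: int
    end: int
    length: int
    strand: str  # strand carrying the forward-primer hit
    mismatches: int = 0


def amplify(
    seq: CircularSequence,
    pair: PrimerPair,
    max_product: int = 5000,
    max_mismatch: int = 0,
) -> list:
    """All products of a primer pair, sorted by length.

    Every opposing-strand hit combination whose circular span is at most
    ``max_product`` (and long enough to hold both primers) yields one
    amplicon.  Products wrapping the origin are supported, and product
    lengths are invariant under rotation of the circle.
    """
    n = len(seq)
    fwd = find_primer_sites(seq, pair.forward, max_mismatch)
    rev = find_primer_sites(seq, pair.reverse, max_mismatch)
    min_len = len(pair.forward) + len(pair.reverse)
    out = []
    for head, tail, strand in ((fwd, rev, "+"), (rev, fwd, "-")):
        for f in (s for s in head if s.strand == "+"):
            for r in (s for s in tail if s.strand == "-"):
                length = (r.position - f.position) % n + 1
                if min_len <= length <= max_product:
                    out.append(
                        Amplicon(
                            pair.marker,
                            f.position,
                            r.position,
                            length,
                            strand,
                            f.mismatches + r.mismatches,
                        )
                    )
    return sorted(out, key=lambda a: (a.length, a.start))


@dataclass(frozen=True)
class MarkerCall:
    """Product-size call for one marker: a unique size, the smallest of
    several (flag 'multiple'), or 'absent'."""

    marker: str
    size: int | None
    flag: str  # 'unique' | 'multiple' | 'absent'


def marker_profile(
    seq: CircularSequence,
    panel: list,
    max_product: int = 5000,
    max_mismatch: int = 0,
) -> list:
    """Ordered product-size vector of a marker panel on one genome."""
    if not panel:
        raise PlastotypeError("empty primer panel")
    calls = []
    for pair in panel:
        amps = amplify(seq, pair, max_product=max_product, max_mismatch=max_mismatch)
        if not amps:
            calls.append(MarkerCall(pair.marker, None, "absent"))
        elif len({a.length for a in amps}) == 1 and len(amps) == 1:
            calls.append(MarkerCall(pair.marker, amps[0].length, "unique"))
        else:
            calls.append(MarkerCall(pair.marker, amps[0].length, "multiple"))
    return calls


def load_primer_panel(path) -> list:
    """Read a primer panel TSV: ``marker  forward_seq  reverse_seq`` with header."""
    lines = Path(path).read_text().splitlines()
    if not lines or [c.strip().lower() for c in lines[0].split("\t")[:3]] != [
        "marker", "forward_seq", "reverse_seq",
    ]:
        raise PlastotypeError(
            f"{path}: expected header 'marker\\tforward_seq\\treverse_seq'"
        )
    panel = []
    for line in lines[1:]:
        if not line.strip():
            continue
        marker, fwd, rev = (c.strip() for c in line.split("\t")[:3])
        panel.append(PrimerPair(marker, fwd, rev))
    return panel


def write_amplicons(amplicons, path) -> None:
    """Amplicon report TSV: marker, size, start, end, strand, mismatches."""
    with Path(path).open("w") as fh:
        fh.write("marker\tsize\tstart\tend\tstrand\tmismatches\n")
        for a in amplicons:
            fh.write(
                f"{a.marker}\t{a.length}\t{a.start}\t{a.end}\t{a.strand}\t{a.mismatches}\n"
            )
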