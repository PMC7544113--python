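"""In silico restriction digestion of circular DNA.

Chloroplast DNA typing in potato was historically done by restriction
fragment length polymorphism (RFLP): a plastome is digested with a
six-cutter and the fragment-length pattern compared between accessions.
This module recomputes those fragment spectra exactly on the circular
molecule — the fragment multiset is invariant under rotation and strand
flips, and its lengths always sum to the genome length.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from ._match import find_matches
from .errors import PlastotypeError
from .io import CircularSequence, revcomp


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme as a recognition site plus a cut offset.

    The offset is measured in bp from the site start on the top strand.  On
    a circle, fragment *lengths* are offset-invariant, so the packaged
    enzymes use offset 0.
    """

    name: str
    site: str
    cut_offset: int = 0

    def __post_init__(self):
        object.__setattr__(self, "site", self.site.upper())
        if len(self.site) < 4:
            raise PlastotypeError(f"enzyme {self.name}: site shorter than 4 bp")
        if not 0 <= self.cut_offset <= len(self.site):
            raise PlastotypeError(f"enzyme {self.name}: bad cut offset")

    @property
    def palindromic(self) -> bool:
        return revcomp(self.site) == self.site


#: The five enzymes used for potato cpDNA typing.
DEFAULT_ENZYMES = {
    "BamHI": RestrictionEnzyme("BamHI", "GGATCC"),
    "HindIII": RestrictionEnzyme("HindIII", "AAGCTT"),
    "KpnI": RestrictionEnzyme("KpnI", "GGTACC"),
    "PvuII": RestrictionEnzyme("PvuII", "CAGCTG"),
    "XhoI": RestrictionEnzyme("XhoI", "CTCGAG"),
}


def load_enzymes(path) -> dict:
    """Read an enzyme config TSV: ``name  site  offset`` with header."""
    lines = Path(path).read_text().splitlines()
    if not lines or [c.strip().lower() for c in lines[0].split("\t")[:3]] != [
        "name", "site", "offset",
    ]:
        raise PlastotypeError(f"{path}: expected header 'name\\tsite\\toffset'")
    out = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        name, site, offset = line.split("\t")[:3]
        out[name.strip()] = RestrictionEnzyme(name.strip(), site.strip(), int(offset))
    return out


def find_sites(seq: CircularSequence, enzyme: RestrictionEnzyme) -> list:
    """Sorted 1-based cut positions of ``enzyme`` on a circular genome.

    Both strands are scanned; the two strand readings of a palindromic site
    collapse to one cut.  Occurrences spanning the circular origin are
    found.
    """
    m = len(enzyme.site)
    n = len(seq)
    cuts = set()
    for pos, _ in find_matches(seq, enzyme.site, 0):
        cuts.add((pos - 1 + enzyme.cut_offset) % n + 1)
    if not enzyme.palindromic:
        for pos, _ in find_matches(seq, revcomp(enzyme.site), 0):
            cuts.add((pos - 1 + m - enzyme.cut_offset) % n + 1)
    return sorted(cuts)


@dataclass(frozen=True)
class FragmentSpectrum:
    """Multiset of restriction-fragment lengths for one enzyme on one genome."""

    enzyme: str
    genome_id: str
    fragments: tuple  # lengths in bp, sorted descending
    undigested: bool = False

    def __post_init__(self):
        object.__setattr__(
            self, "fragments", tuple(sorted(self.fragments, reverse=True))
        )

    @property
    def total(self) -> int:
        return sum(self.fragments)

    def __len__(self):
        return len(self.fragments)


def digest(seq: CircularSequence, enzyme: RestrictionEnzyme) -> FragmentSpectrum:
    """Fragment spectrum of a circular digest.

    Fragments are the circular gaps between consecutive cut positions; with
    no site the intact circle is returned as a single fragment flagged
    undigested.  The lengths always sum to the genome length.
    """
    n = len(seq)
    cuts = find_sites(seq, enzyme)
    if not cuts:
        return FragmentSpectrum(enzyme.name, seq.id, (n,), undigested=True)
    frags = [cuts[i + 1] - cuts[i] for i in range(len(cuts) - 1)]
    frags.append(n - cuts[-1] + cuts[0])
    return FragmentSpectrum(enzyme.name, seq.id, tuple(frags))


def default_tolerance(a: int, b: int) -> float:
    """Length-matching tolerance: max(5 bp, 0.5% of the larger fragment).

    RFLP patterns are read at gel resolution; kb-scale fragments are only
    comparable approximately, so exact matching would be wrong there.
    """
    return max(5.0, 0.005 * max(a, b))


@dataclass(frozen=True)
class SpectrumDiff:
    """Greedy best-match comparison of two fragment spectra."""

    enzyme: str
    matched: tuple = ()   # (length_in_a, length_in_b) pairs
    gains: tuple = ()     # lengths present in a, unmatched in b
    losses: tuple = ()    # lengths present in b, unmatched in a
    tolerance: str = "max(5 bp, 0.5%)"

    @property
    def empty(self) -> bool:
        return not self.gains and not self.losses and all(
            x == y for x, y in self.matched
        )

    def shifts(self, min_shift: int = 1) -> list:
        """Matched pairs whose lengths differ by at least ``min_shift`` bp."""
        return [(a, b) for a, b in self.matched if abs(a - b) >= min_shift]


def shift_tolerance(a: int, b: int) -> float:
    """Relaxed pairing tolerance for length-*shifted* fragments.

    A fragment shortened by a small deletion (tens of bp) is still the
    same fragment on a gel; shifts up to max(100 bp, 5%) are paired and
    reported through :meth:`SpectrumDiff.shifts` rather than as a
    gain/loss.
    """
    return max(100.0, 0.05 * max(a, b))


def compare_spectra(
    a: FragmentSpectrum,
    b: FragmentSpectrum,
    tolerance=None,
    shift_tol=None,
) -> SpectrumDiff:
    """Pair up fragment lengths of two digests of the same enzyme.

    Deterministic greedy pairing in two stages: walking ``a``'s lengths in
    descending order, each is matched to the closest still-unmatched length
    of ``b`` within the strict tolerance; leftovers are then paired under
    the relaxed shift tolerance, so a fragment shortened by a small
    deletion appears as a matched pair with a length shift.  Anything still
    unmatched is a gain (present in ``a``) or a loss (present in ``b``
    only).
    """
    if a.enzyme != b.enzyme:
        raise PlastotypeError(
            f"cannot compare spectra of different enzymes ({a.enzyme} vs {b.enzyme})"
        )
    remaining = list(b.fragments)
    matched, gains = [], []

    def greedy(lengths, tol):
        unpaired = []
        for la in lengths:
            best_i, best_d = None, None
            for i, lb in enumerate(remaining):
                d = abs(la - lb)
                if d <= tol(la, lb) and (best_d is None or d < best_d):
                    best_i, best_d = i, d
            if best_i is None:
                unpaired.append(la)
            else:
                matched.append((la, remaining.pop(best_i)))
        return unpaired

    leftovers = greedy(a.fragments, tolerance or default_tolerance)
    gains = greedy(leftovers, shift_tol or shift_tolerance)
    return SpectrumDiff(
        a.enzyme, tuple(matched), tuple(gains), tuple(sorted(remaining, reverse=True))
    )


def write_spectra(spectra, path) -> None:
    """Spectrum report TSV: genome, enzyme, fragment lengths comma-joined."""
    with Path(path).open("w") as fh:
        fh.write("genome\tenzyme\tfragments\n")
        for sp in spectra:
            fh.write(
                f"{sp.genome_id}\t{sp.enzyme}\t"
                + ",".join(str(x) for x in sp.fragments)
                + "\n"
            )
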