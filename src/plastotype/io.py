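"""Sequence and annotation I/O on a circular-coordinate model.

A plastome is a single circular DNA molecule; every downstream analysis in
this package (structure detection, digestion, in silico PCR, repeat
scanning) works in modular coordinates.  This module provides the
:class:`CircularSequence` container those analyses share, FASTA reading and
writing, and a small feature-table model fed either by GenBank flat files
or by a plain TSV dialect.

All coordinates in reports are 1-based inclusive; internal arithmetic is
0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO

from .errors import PlastomeIOError

# IUPAC nucleotide alphabet.  N and the ambiguity codes are legal input but
# are treated conservatively downstream: they never match a primer or an
# enzyme recognition site.
UNAMBIGUOUS = frozenset("ACGT")
AMBIGUOUS = frozenset("NRYSWKMBDHV")
ALPHABET = UNAMBIGUOUS | AMBIGUOUS

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBtgcanyrswmkvhdb",
)

#: Expansion of each IUPAC code into the unambiguous bases it stands for.
IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def complement(s: str) -> str:
    """Base-wise complement (IUPAC aware), same orientation."""
    return s.translate(_COMPLEMENT)


def revcomp(s: str) -> str:
    """Reverse complement (IUPAC aware)."""
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CircularSequence:
    """An uppercase DNA sequence with (optionally) circular topology.

    Indexing through :meth:`fetch` is modular when ``circular`` is true:
    position ``length + k`` resolves to position ``k``.
    """

    id: str
    residues: str
    circular: bool = True

    def __post_init__(self):
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - ALPHABET
        if bad:
            raise PlastomeIOError(
                f"record {self.id!r}: non-nucleotide characters {sorted(bad)}"
            )
        if not self.residues:
            raise PlastomeIOError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def fetch(self, start: int, end: int) -> str:
        """Residues of the 1-based inclusive interval ``[start, end]``.

        On a circular sequence the interval may wrap the origin
        (``start > end``) or use coordinates beyond ``length``.
        """
        n = len(self.residues)
        if not self.circular:
            if not (1 <= start <= end <= n):
                raise PlastomeIOError(
                    f"interval {start}..{end} outside linear sequence of length {n}"
                )
            return self.residues[start - 1 : end]
        i = (start - 1) % n
        j = (end - 1) % n
        if i <= j:
            return self.residues[i : j + 1]
        return self.residues[i:] + self.residues[: j + 1]

    def base_composition(self) -> dict:
        return {b: self.residues.count(b) for b in sorted(set(self.residues))}

    def reverse_complement(self) -> "CircularSequence":
        return replace(self, residues=revcomp(self.residues))


def rotate(seq: CircularSequence, new_origin: int) -> CircularSequence:
    """Rotate a circular sequence so ``new_origin`` (1-based) becomes position 1.

    Rotation preserves length and base composition, and every circular
    analysis result downstream (digestion spectra, amplicon sizes, SSR
    counts) is invariant under it.
    """
    if not seq.circular:
        raise PlastomeIOError(f"cannot rotate linear sequence {seq.id!r}")
    n = len(seq)
    if not 1 <= new_origin <= n:
        raise PlastomeIOError(f"rotation origin {new_origin} outside 1..{n}")
    k = new_origin - 1
    return replace(seq, residues=seq.residues[k:] + seq.residues[:k])


@dataclass(frozen=True)
class LoadReport:
    """Per-record positions of ambiguity codes seen while loading."""

    ambiguous: dict = field(default_factory=dict)  # id -> tuple of 1-based positions

    def __bool__(self) -> bool:
        return any(self.ambiguous.values())


def read_fasta(path, circular: bool = True, with_report: bool = False):
    """Read a (multi-)FASTA file into :class:`CircularSequence` records.

    Each record is treated as an independent circular genome (unless
    ``circular=False``).  Residues are uppercased; IUPAC ambiguity codes are
    preserved but flagged in the optional :class:`LoadReport`; characters
    outside the IUPAC alphabet raise :class:`PlastomeIOError` naming the
    record.
    """
    path = Path(path)
    records = []
    ambiguous = {}
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise PlastomeIOError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        cs = CircularSequence(rec.id, str(rec.seq), circular=circular)
        positions = tuple(
            i + 1 for i, b in enumerate(cs.residues) if b in AMBIGUOUS
        )
        if positions:
            ambiguous[cs.id] = positions
        records.append(cs)
    if not records:
        raise PlastomeIOError(f"no FASTA records found in {path}")
    if with_report:
        return records, LoadReport(ambiguous)
    return records


def write_fasta(records, path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Feature tables

FEATURE_KINDS = ("gene", "CDS", "tRNA", "rRNA", "intron", "fragment")


@dataclass(frozen=True)
class Feature:
    """One annotated feature in 1-based inclusive coordinates.

    ``wraps_origin`` flags the two halves of a feature that spanned the
    circular origin in its source record.
    """

    name: str
    kind: str
    start: int
    end: int
    strand: str = "+"
    wraps_origin: bool = False

    def __post_init__(self):
        if not self.name:
            raise PlastomeIOError("feature with empty name")
        if self.strand not in "+-":
            raise PlastomeIOError(f"feature {self.name!r}: bad strand {self.strand!r}")
        if self.start < 1 or self.end < self.start:
            raise PlastomeIOError(
                f"feature {self.name!r}: bad interval {self.start}..{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class FeatureTable:
    features: list

    def __post_init__(self):
        self.features = sorted(self.features, key=lambda f: (f.start, f.end, f.name))

    def __len__(self):
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def of_kind(self, *kinds) -> list:
        return [f for f in self.features if f.kind in kinds]


def _coerce_kind(kind: str, name: str) -> str:
    if kind in FEATURE_KINDS:
        return kind
    warnings.warn(f"feature {name!r}: unknown kind {kind!r}, keeping as 'gene'")
    return "gene"


def _split_wrapping(name, kind, start, end, strand, seq_length):
    """Split an origin-spanning feature (start > end) into two flagged parts."""
    if seq_length is None:
        raise PlastomeIOError(
            f"feature {name!r} spans the origin but sequence length is unknown"
        )
    return [
        Feature(name, kind, start, seq_length, strand, wraps_origin=True),
        Feature(name, kind, 1, end, strand, wraps_origin=True),
    ]


def read_features(path, dialect: str = "tsv", seq_length: int | None = None) -> FeatureTable:
    """Read annotations from a GenBank flat file or the feature-TSV dialect.

    The TSV dialect is tab-separated ``name  kind  start  end  strand`` with
    a mandatory header line.  Origin-spanning features (``start > end`` in
    TSV, compound locations crossing the origin in GenBank) are split into
    two parts flagged ``wraps_origin``.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_features_tsv(path, seq_length)
    if dialect == "genbank":
        return _read_features_genbank(path)
    raise PlastomeIOError(f"unknown feature dialect {dialect!r}")


def _read_features_tsv(path, seq_length):
    lines = path.read_text().splitlines()
    if not lines:
        raise PlastomeIOError(f"empty feature table {path}")
    header = lines[0].rstrip("\n").split("\t")
    if [h.strip().lower() for h in header[:5]] != ["name", "kind", "start", "end", "strand"]:
        raise PlastomeIOError(
            f"{path}: expected header 'name\\tkind\\tstart\\tend\\tstrand', got {lines[0]!r}"
        )
    feats = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            raise PlastomeIOError(f"{path}:{ln}: expected 5 tab-separated fields")
        name, kind, start, end, strand = (p.strip() for p in parts[:5])
        try:
            start, end = int(start), int(end)
        except ValueError as exc:
            raise PlastomeIOError(f"{path}:{ln}: non-integer coordinates") from exc
        kind = _coerce_kind(kind, name)
        if seq_length is not None and (start > seq_length or end > seq_length):
            raise PlastomeIOError(
                f"{path}:{ln}: feature {name!r} outside sequence of length {seq_length}"
            )
        if start > end:
            feats.extend(_split_wrapping(name, kind, start, end, strand, seq_length))
        else:
            feats.append(Feature(name, kind, start, end, strand))
    return FeatureTable(feats)


_GENBANK_KIND = {
    "gene": "gene", "CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
    "intron": "intron", "misc_feature": "fragment",
}


def _read_features_genbank(path):
    feats = []
    for rec in SeqIO.parse(str(path), "genbank"):
        n = len(rec.seq)
        for ft in rec.features:
            if ft.type == "source":
                continue
            kind = _GENBANK_KIND.get(ft.type)
            if kind is None:
                kind = _coerce_kind(ft.type, ft.type)
            quals = ft.qualifiers
            name = (quals.get("gene") or quals.get("locus_tag") or [ft.type])[0]
            strand = "-" if ft.location.strand == -1 else "+"
            start = int(ft.location.start) + 1
            end = int(ft.location.end)
            if start > end:  # compound location across the origin
                feats.extend(_split_wrapping(name, kind, start, end, strand, n))
            else:
                feats.append(Feature(name, kind, start, end, strand))
    if not feats:
        raise PlastomeIOError(f"no features parsed from {path}")
    return FeatureTable(feats)


def write_features(table: FeatureTable, path) -> None:
    """Write a feature table in the TSV dialect (round-trips with read_features)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("name\tkind\tstart\tend\tstrand\n")
        for f in table:
            fh.write(f"{f.name}\t{f.kind}\t{f.start}\t{f.end}\t{f.strand}\n")
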