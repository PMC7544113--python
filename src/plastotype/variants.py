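"""Variant calling from a plastome multiple sequence alignment.

The panel's diversity is summarised against a *majority-call* reference:
at every alignment column, any symbol with frequency above 50% of the rows
is the reference allele.  SNP sites are columns with at least two distinct
unambiguous bases (gap and N are missing data, never alleles), classified
as singleton (every minor allele occurs in exactly one row) or
parsimony-informative (at least two alleles in at least two rows each),
with the allele number recorded ("singleton-2", "parsimony-informative-3",
…).  InDel events are counted per genome: each maximal run of columns
where exactly one of {row, consensus} is gapped is one insertion or
deletion for that row.

Alignment itself is delegated — either to an external MAFFT executable or
to a precomputed aligned FASTA — because the analysis here is the calling
and annotation, not a new aligner.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .errors import AlignerUnavailableError, PlastomeIOError, PlastotypeError
from .io import FeatureTable, write_fasta
from .structure import QuadripartiteStructure

BASES = frozenset("ACGT")
GAP = "-"


@dataclass(frozen=True)
class Msa:
    """A multiple sequence alignment over {A,C,G,T,N,-}."""

    ids: tuple
    rows: tuple

    def __post_init__(self):
        if len(self.ids) != len(self.rows) or len(self.rows) < 2:
            raise PlastotypeError("an MSA needs >= 2 rows with matching ids")
        if len(set(self.ids)) != len(self.ids):
            raise PlastotypeError("duplicate row ids in MSA")
        width = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise PlastomeIOError(
                    f"MSA row {rid!r} has length {len(row)}, expected {width}"
                )
        object.__setattr__(self, "rows", tuple(r.upper() for r in self.rows))

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def row(self, rid: str) -> str:
        return self.rows[self.ids.index(rid)]

    @classmethod
    def from_fasta(cls, path) -> "Msa":
        recs = list(SeqIO.parse(str(path), "fasta"))
        if not recs:
            raise PlastomeIOError(f"no alignment rows in {path}")
        return cls(tuple(r.id for r in recs), tuple(str(r.seq) for r in recs))


def align(sequences: list, engine: str = "mafft", extra_args: tuple = ()) -> Msa:
    """Align sequences with an external engine and parse the aligned FASTA.

    Sequences should first be rotated to a shared canonical origin (see the
    structure module) so the alignment is not dominated by a spurious
    rotation offset.  If the engine is missing, the error directs users to
    the precomputed-MSA path (:meth:`Msa.from_fasta`).
    """
    exe = shutil.which(engine)
    if exe is None:
        raise AlignerUnavailableError(
            f"alignment engine {engine!r} not found on PATH; align externally and "
            "load the result with Msa.from_fasta(path)"
        )
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "input.fasta"
        write_fasta(sequences, inp)
        cmd = [exe, "--auto", "--quiet", *extra_args, str(inp)]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise AlignerUnavailableError(
                f"{engine} failed (exit {proc.returncode}): {proc.stderr[:500]}"
            )
        out = Path(tmp) / "aligned.fasta"
        out.write_text(proc.stdout)
        return Msa.from_fasta(out)


@dataclass(frozen=True)
class ConsensusSequence:
    """Per-column majority symbol with a majority/tie flag.

    The majority symbol has frequency > 50% of rows; exact-half columns are
    flagged 'tie' and carry the lexicographically smallest most-frequent
    symbol (the gap symbol sorts before the bases).
    """

    symbols: str
    flags: tuple  # 'majority' | 'tie' per column

    def __len__(self):
        return len(self.symbols)


def build_consensus(msa: Msa) -> ConsensusSequence:
    n = msa.n_rows
    symbols = []
    flags = []
    for col in zip(*msa.rows):
        counts = Counter(col)
        top = max(counts.values())
        best = min(sym for sym, c in counts.items() if c == top)
        symbols.append(best)
        flags.append("majority" if top * 2 > n else "tie")
    return ConsensusSequence("".join(symbols), tuple(flags))


@dataclass
class VariantSite:
    """One SNP column of the alignment (1-based column index)."""

    column: int
    alleles: dict            # base -> row count
    consensus_allele: str
    site_class: str          # e.g. 'singleton-2', 'parsimony-informative-2'
    region: str = "-"        # LSC | SSC | IR | unplaced
    context: str = "-"       # CDS | intron | intergenic
    gene: str = "-"


def _classify(counts: Counter) -> str:
    k = len(counts)
    n_ge2 = sum(1 for c in counts.values() if c >= 2)
    kind = "parsimony-informative" if n_ge2 >= 2 else "singleton"
    return f"{kind}-{k}"


def call_snps(msa: Msa, consensus: ConsensusSequence):
    """SNP sites plus per-genome SNP counts versus the majority consensus.

    A column is a site when at least two distinct bases occur among the
    rows; gaps and N are ignored as missing data.  A genome's count is the
    number of sites where its base differs from the consensus allele.
    """
    sites = []
    per_genome = {rid: 0 for rid in msa.ids}
    for c in range(msa.n_cols):
        col = [row[c] for row in msa.rows]
        counts = Counter(b for b in col if b in BASES)
        if len(counts) < 2:
            continue
        cons = consensus.symbols[c]
        sites.append(
            VariantSite(c + 1, dict(counts), cons, _classify(counts))
        )
        for rid, b in zip(msa.ids, col):
            if b in BASES and b != cons:
                per_genome[rid] += 1
    return sites, per_genome


@dataclass
class IndelEvent:
    """One insertion or deletion of a genome relative to the consensus.

    The event is a maximal run of alignment columns in which exactly one of
    {row, consensus} is gapped; ``kind`` is 'insertion' when the consensus
    side is gapped, 'deletion' when the row side is.
    """

    genome_id: str
    col_start: int  # 1-based inclusive
    col_end: int
    kind: str
    length: int
    region: str = "-"
    context: str = "-"
    gene: str = "-"


def call_indels(msa: Msa, consensus: ConsensusSequence):
    """InDel events plus per-genome event counts.

    Totals are per genome: a gap run shared by several rows counts once per
    row.  A union view of distinct events is available by deduplicating on
    (col_start, col_end, kind).
    """
    events = []
    per_genome = {rid: 0 for rid in msa.ids}
    cons = consensus.symbols
    for rid, row in zip(msa.ids, msa.rows):
        c = 0
        n = msa.n_cols
        while c < n:
            row_gap = row[c] == GAP
            cons_gap = cons[c] == GAP
            if row_gap == cons_gap:
                c += 1
                continue
            kind = "deletion" if row_gap else "insertion"
            start = c
            while c < n and (row[c] == GAP) == row_gap and (cons[c] == GAP) == cons_gap:
                c += 1
            events.append(IndelEvent(rid, start + 1, c, kind, c - start))
            per_genome[rid] += 1
    return events, per_genome


def distinct_events(events) -> list:
    """Union view: one representative per (interval, kind)."""
    seen = {}
    for e in events:
        seen.setdefault((e.col_start, e.col_end, e.kind), e)
    return list(seen.values())


# ---------------------------------------------------------------------------
# Annotation

def _column_map(row: str):
    """Map 1-based ungapped positions of a row to 1-based alignment columns."""
    cols = []
    for c, ch in enumerate(row, start=1):
        if ch != GAP:
            cols.append(c)
    return cols


def annotate_variants(
    sites,
    events,
    features: FeatureTable,
    structure: QuadripartiteStructure,
    msa: Msa,
    reference_row: str,
):
    """Label variants by genomic region and by gene context.

    Feature and structure coordinates refer to the *ungapped* reference
    row; they are projected through that row's gaps onto alignment columns.
    Region is LSC/SSC/IR from the quadripartite structure; context is
    CDS/intron/intergenic (gene-type features count as CDS); variants
    outside the projected genome span are labelled 'unplaced'.
    """
    ref = msa.row(reference_row)
    cols = _column_map(ref)
    ref_len = len(cols)

    col_of = {}
    for pos, c in enumerate(cols, start=1):
        col_of[pos] = c

    # reverse: alignment column -> reference position (position whose base
    # occupies the column; None inside reference gaps)
    pos_of = [None] * (msa.n_cols + 1)
    for pos, c in enumerate(cols, start=1):
        pos_of[c] = pos

    def nearest_pos(col: int):
        """Reference position at or left of an alignment column."""
        c = col
        while c >= 1 and pos_of[c] is None:
            c -= 1
        return pos_of[c] if c >= 1 else None

    n = structure.genome_length

    def region_of(pos: int) -> str:
        for name, iv in structure.segments():
            s, e = iv
            if s <= e:
                inside = s <= pos <= e
            else:
                inside = pos >= s or pos <= e
            if inside:
                return "IR" if name in ("IRB", "IRA") else name
        return "unplaced"

    def context_of(pos: int):
        covering = [
            f for f in features if f.start <= pos <= f.end
        ]
        introns = [f for f in covering if f.kind == "intron"]
        if introns:
            return "intron", introns[0].name
        genic = [f for f in covering if f.kind in ("CDS", "gene", "tRNA", "rRNA")]
        if genic:
            f = min(genic, key=lambda f: (len(f), f.name))
            return "CDS", f.name
        return "intergenic", "-"

    for site in sites:
        pos = nearest_pos(site.column)
        if pos is None or pos > ref_len or pos > n:
            site.region, site.context, site.gene = "unplaced", "-", "-"
            continue
        site.region = region_of(pos)
        site.context, site.gene = context_of(pos)
    for ev in events:
        pos = nearest_pos(ev.col_start)
        if pos is None or pos > ref_len or pos > n:
            ev.region, ev.context, ev.gene = "unplaced", "-", "-"
            continue
        ev.region = region_of(pos)
        ev.context, ev.gene = context_of(pos)

    per_gene = Counter()
    for site in sites:
        if site.gene != "-":
            per_gene[(site.gene, "SNP")] += 1
    for ev in events:
        if ev.gene != "-":
            per_gene[(ev.gene, ev.kind)] += 1
    tally = pd.DataFrame(
        [(g, k, c) for (g, k), c in sorted(per_gene.items())],
        columns=["gene", "variant_kind", "count"],
    )
    return sites, events, tally


def write_variant_report(sites, events, path) -> None:
    """VCF-like TSV of sites plus an event table."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("record\tcolumn\tdetail\tclass\tregion\tcontext\tgene\n")
        for s in sites:
            alleles = ",".join(f"{b}:{c}" for b, c in sorted(s.alleles.items()))
            fh.write(
                f"SNP\t{s.column}\t{alleles}\t{s.site_class}\t{s.region}\t"
                f"{s.context}\t{s.gene}\n"
            )
        for e in events:
            fh.write(
                f"InDel\t{e.col_start}-{e.col_end}\t{e.genome_id}:{e.length}bp\t"
                f"{e.kind}\t{e.region}\t{e.context}\t{e.gene}\n"
            )
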