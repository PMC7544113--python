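"""Synthetic plastome-like genomes with fully known ground truth.

Every pipeline stage in this package is testable without downloads: this
module generates circular quadripartite genomes that carry, by
construction, an exact inverted-repeat pair, the diagnostic loci of each
potato cpDNA type, microsatellite-marker primer cassettes with
type-specific product sizes, and implanted SSR / tandem / dispersed
repeats — all recorded in a :class:`SyntheticTruth` sufficient to predict
every module's expected output.

Two scales are available: ``toy`` (~20 kb) keeps the proportions of a
potato plastome shrunk for fast tests; ``full`` (~155 kb) reproduces the
real segment sizes (LSC ~86 kb, SSC ~18.4 kb, IR ~25.6 kb ×2).  Base
composition is biased to ~62% AT, matching the ~38% GC of potato
plastomes.

All randomness flows from the single user seed; the same
(type, seed, scale) always reproduces identical bytes.  Two genomes with
the same seed share their entire background and differ only at the
type-diagnostic blocks, mirroring how the real types differ by single
point mutations and short deletions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import PlastotypeError
from .haplotyping import (
    LOCUS_CCSA, LOCUS_CEMA_PETA, LOCUS_DEL48, LOCUS_DEL241, LOCUS_RPS11,
    DiagnosticLocus,
)
from .io import CircularSequence, Feature, FeatureTable, revcomp
from .pcr import PrimerPair

CP_TYPES = ("S", "C", "A", "W", "W2", "T")
_SCALES = ("toy", "full")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_P = np.array([0.31, 0.19, 0.19, 0.31])  # ~62% AT


def _random_dna(rng, n: int, forbidden=()) -> str:
    """Random background DNA avoiding the given exact substrings."""
    while True:
        s = np.frombuffer(
            rng.choice(_BASES, size=n, p=_P).tobytes(), dtype=np.uint8
        ).tobytes().decode("ascii")
        if not any(f in s for f in forbidden):
            return s


# ---------------------------------------------------------------------------
# Fixed sequence constants shared by every synthetic genome.  They come from
# a constant generator stream so the diagnostic anchors, marker primers and
# deletion payloads are the same in every run and every genome — the config
# emitted by synthetic_diagnostics()/synthetic_primer_panel() matches any
# genome this module produces.

_ENZYME_SITES = ("GGATCC", "AAGCTT", "GGTACC", "CAGCTG", "CTCGAG")


def _make_constants():
    rng = np.random.default_rng(20201008)

    def clean(n):
        while True:
            s = _random_dna(rng, n)
            if not any(site in s or site in revcomp(s) for site in _ENZYME_SITES):
                return s

    anchors = {k: clean(20) for k in (
        "cem5", "cem3", "del48_5", "del48_3", "ccsa5", "ccsa3",
        "rps11_5", "rps11_3", "del241_5", "del241_3",
    )}
    del48 = clean(48)
    del241 = clean(241)
    primers = {m: (clean(20), clean(20)) for m in (
        "NTCP6", "NTCP7", "NTCP8", "NTCP9", "NTCP12", "NTCP14", "NTCP18",
    )}
    inserts = {m: clean(300) for m in primers}  # master inserts; prefixes used
    return anchors, del48, del241, primers, inserts


_ANCHORS, _DEL48, _DEL241, _PRIMERS, _INSERTS = _make_constants()

#: Strings that must occur exactly once in a genome (or not at all):
#: background fillers and the IR are rejection-sampled against them.
_FORBIDDEN = tuple(
    list(_ANCHORS.values())
    + [revcomp(a) for a in _ANCHORS.values()]
    + [p for pair in _PRIMERS.values() for p in pair]
    + [revcomp(p) for pair in _PRIMERS.values() for p in pair]
)

# The diagnostic point mutations, written as ancestral/derived 6-mers that
# differ by exactly one base (G→A creates the cemA–petA BamHI site, G→C the
# ccsA BamHI site, A→G the rps11 PvuII site).
_CEM_SITE, _CEM_NO = "GGATCC", "GGATCT"
_CCSA_SITE, _CCSA_NO = "GGATCC", "GGATGC"
_RPS11_SITE, _RPS11_NO = "CAGCTG", "CAACTG"

#: Marker product sizes implanted per type, echoing the published marker
#: table (S/C/A rows; the W and W2 rows are the patterns observed for the
#: accessions typed W and W2; T is synthetic — no published T row exists).
MARKER_SIZES = {
    "S": (127, 173, 251, 289, 129, 150, 186),
    "C": (173, 174, 251, 289, 126, 150, 187),
    "A": (174, 174, 250, 289, 127, 151, 186),
    "W": (174, 174, 255, 310, 125, 150, 188),
    "W2": (174, 174, 253, 249, 128, 154, 186),
    "T": (175, 174, 252, 290, 128, 150, 186),
}

_MARKER_ORDER = ("NTCP6", "NTCP7", "NTCP8", "NTCP9", "NTCP12", "NTCP14", "NTCP18")

#: Expected diagnostic-locus states per type (the Fig.-style evolution
#: logic: W ancestral; W2 = rps11 site; C = cemA–petA site; A = C + ccsA
#: site; S = C + 48 bp deletion; T = 241 bp deletion).
LOCUS_STATES = {
    "S": {LOCUS_CEMA_PETA: "present", LOCUS_DEL48: "present", LOCUS_CCSA: "absent",
          LOCUS_RPS11: "absent", LOCUS_DEL241: "absent"},
    "C": {LOCUS_CEMA_PETA: "present", LOCUS_DEL48: "absent", LOCUS_CCSA: "absent",
          LOCUS_RPS11: "absent", LOCUS_DEL241: "absent"},
    "A": {LOCUS_CEMA_PETA: "present", LOCUS_DEL48: "absent", LOCUS_CCSA: "present",
          LOCUS_RPS11: "absent", LOCUS_DEL241: "absent"},
    "W": {LOCUS_CEMA_PETA: "absent", LOCUS_DEL48: "absent", LOCUS_CCSA: "absent",
          LOCUS_RPS11: "absent", LOCUS_DEL241: "absent"},
    "W2": {LOCUS_CEMA_PETA: "absent", LOCUS_DEL48: "absent", LOCUS_CCSA: "absent",
           LOCUS_RPS11: "present", LOCUS_DEL241: "absent"},
    "T": {LOCUS_CEMA_PETA: "absent", LOCUS_DEL48: "absent", LOCUS_CCSA: "absent",
          LOCUS_RPS11: "absent", LOCUS_DEL241: "present"},
}


def synthetic_diagnostics() -> list:
    """Diagnostic-locus config matching every genome from this module."""
    return [
        DiagnosticLocus(LOCUS_CEMA_PETA, "site_gain", _CEM_SITE,
                        _ANCHORS["cem5"], _ANCHORS["cem3"]),
        DiagnosticLocus(LOCUS_DEL48, "deletion", "",
                        _ANCHORS["del48_5"], _ANCHORS["del48_3"], 48, 48),
        DiagnosticLocus(LOCUS_CCSA, "site_gain", _CCSA_SITE,
                        _ANCHORS["ccsa5"], _ANCHORS["ccsa3"]),
        DiagnosticLocus(LOCUS_RPS11, "site_gain", _RPS11_SITE,
                        _ANCHORS["rps11_5"], _ANCHORS["rps11_3"]),
        DiagnosticLocus(LOCUS_DEL241, "deletion", "",
                        _ANCHORS["del241_5"], _ANCHORS["del241_3"], 241, 241),
    ]


def synthetic_primer_panel() -> list:
    """The seven synthetic marker primer pairs implanted in every genome."""
    return [PrimerPair(m, *_PRIMERS[m]) for m in _MARKER_ORDER]


# ---------------------------------------------------------------------------
# Block-based genome skeleton

@dataclass
class _Block:
    name: str
    segment: str            # LSC | IRB | SSC | IRA
    content: object         # str (shared) or dict type -> str (typed)
    mutable: bool = False   # eligible for panel SNP/InDel implants

    def for_type(self, cp_type: str) -> str:
        if isinstance(self.content, dict):
            return self.content[cp_type]
        return self.content


def _ssr_block(unit: str, copies: int):
    """Perfect SSR flanked by guard bases that stop run extension."""
    run = unit * copies
    left = "C" if unit[-1] != "C" else "G"
    right = "C" if unit[0] != "C" else "G"
    return left + run + right


#: Implanted repeats: (unit, copies) at or above the reporting thresholds.
_SSR_IMPLANTS = (("A", 12), ("AT", 7), ("AAT", 5), ("ACGT", 3), ("AACGT", 3))


def _skeleton(seed: int, scale: str):
    """Build the ordered block list shared by all types at this seed."""
    if scale not in _SCALES:
        raise PlastotypeError(f"unknown scale {scale!r}; use one of {_SCALES}")
    rng = np.random.default_rng([int(seed), 0 if scale == "toy" else 1, 77])
    if scale == "full":
        # calibrated so the S-type genome reproduces the reference potato
        # plastome dimensions: LSC 85,930 / IR 25,593 / SSC 18,376 (155,492 bp)
        ir_len, ssc_len, lsc_base = 25593, 18376, 86023
    else:
        ir_len, ssc_len, lsc_base = 3300, 2400, 11000

    blocks = []

    def filler(name, segment, n, mutable=True):
        blocks.append(_Block(name, segment, _random_dna(rng, n, _FORBIDDEN), mutable))

    # --- LSC functional content (groups separated by background fillers) ---
    groups = []
    for m in _MARKER_ORDER:
        fwd, rev = _PRIMERS[m]
        lens = {t: MARKER_SIZES[t][_MARKER_ORDER.index(m)] - 40 for t in CP_TYPES}
        groups.append([
            _Block(f"{m}_fwd", "LSC", fwd),
            _Block(f"{m}_insert", "LSC",
                   {t: _INSERTS[m][: lens[t]] for t in CP_TYPES}),
            _Block(f"{m}_rev", "LSC", revcomp(rev)),
        ])
    groups.append([
        _Block("del48_a5", "LSC", _ANCHORS["del48_5"]),
        _Block("del48_payload", "LSC",
               {t: ("" if t == "S" else _DEL48) for t in CP_TYPES}),
        _Block("del48_a3", "LSC", _ANCHORS["del48_3"]),
    ])
    groups.append([
        _Block("cem_a5", "LSC", _ANCHORS["cem5"]),
        _Block("cem_variant", "LSC",
               {t: (_CEM_SITE if t in ("S", "C", "A") else _CEM_NO)
                for t in CP_TYPES}),
        _Block("cem_a3", "LSC", _ANCHORS["cem3"]),
    ])
    groups.append([
        _Block("rps11_a5", "LSC", _ANCHORS["rps11_5"]),
        _Block("rps11_variant", "LSC",
               {t: (_RPS11_SITE if t == "W2" else _RPS11_NO)
                for t in CP_TYPES}),
        _Block("rps11_a3", "LSC", _ANCHORS["rps11_3"]),
    ])
    groups.append([
        _Block("del241_a5", "LSC", _ANCHORS["del241_5"]),
        _Block("del241_payload", "LSC",
               {t: ("" if t == "T" else _DEL241) for t in CP_TYPES}),
        _Block("del241_a3", "LSC", _ANCHORS["del241_3"]),
    ])
    for unit, copies in _SSR_IMPLANTS:
        groups.append([_Block(f"ssr_{unit}", "LSC", _ssr_block(unit, copies))])
    disp_f = _random_dna(rng, 35, _FORBIDDEN)
    disp_p = _random_dna(rng, 35, _FORBIDDEN)
    groups.append([_Block("disp_fwd_1", "LSC", disp_f)])
    groups.append([_Block("disp_fwd_2", "LSC", disp_f)])
    groups.append([_Block("disp_pal_1", "LSC", disp_p)])
    groups.append([_Block("disp_pal_2", "LSC", revcomp(disp_p))])
    unit30 = _random_dna(rng, 30, _FORBIDDEN)
    unit90 = _random_dna(rng, 90, _FORBIDDEN)
    groups.append([_Block("tandem30", "LSC", unit30 * 3)])
    groups.append([_Block("tandem90", "LSC", unit90 * 2)])

    # widest variant (type C) defines the filler budget
    fixed_len = sum(
        len(b.content["C"]) if isinstance(b.content, dict) else len(b.content)
        for grp in groups for b in grp
    )
    n_fillers = len(groups) + 1
    budget = lsc_base - fixed_len
    if budget < n_fillers * 30:
        raise PlastotypeError("LSC too small for the functional content")
    per = budget // n_fillers
    extra = budget - per * n_fillers
    filler("lsc_fill_0", "LSC", per + extra)
    for i, grp in enumerate(groups):
        blocks.extend(grp)
        filler(f"lsc_fill_{i + 1}", "LSC", per)

    # --- IR + SSC ----------------------------------------------------------
    ir_seq = _random_dna(rng, ir_len, _FORBIDDEN)
    blocks.append(_Block("irb", "IRB", ir_seq))
    ssc_fixed = 20 + 6 + 20
    half = (ssc_len - ssc_fixed) // 2
    filler("ssc_fill_0", "SSC", half)
    blocks.append(_Block("ccsa_a5", "SSC", _ANCHORS["ccsa5"]))
    blocks.append(_Block("ccsa_variant", "SSC",
                         {t: (_CCSA_SITE if t == "A" else _CCSA_NO)
                          for t in CP_TYPES}))
    blocks.append(_Block("ccsa_a3", "SSC", _ANCHORS["ccsa3"]))
    filler("ssc_fill_1", "SSC", ssc_len - ssc_fixed - half)
    blocks.append(_Block("ira", "IRA", revcomp(ir_seq)))

    _block_ir_extension(blocks)
    return blocks


def _block_ir_extension(blocks):
    """Adjust single bases flanking the IR pair so the exact inverted repeat
    cannot extend by chance into the single-copy regions."""
    by_name = {b.name: b for b in blocks}
    lsc_blocks = [b for b in blocks if b.segment == "LSC"]
    first_lsc, last_lsc = lsc_blocks[0], lsc_blocks[-1]
    ssc_blocks = [b for b in blocks if b.segment == "SSC"]
    first_ssc, last_ssc = ssc_blocks[0], ssc_blocks[-1]
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}

    def fix(block, index, other_char):
        s = block.content
        if s[index] == comp[other_char]:
            repl = "A" if comp[other_char] != "A" else "C"
            block.content = s[:index] + repl + s[index + 1:] if index >= 0 else (
                s[:len(s) + index] + repl + s[len(s) + index + 1:]
            )

    # JLB/JLA side: last LSC base vs first LSC base
    fix(last_lsc, -1, first_lsc.content[0])
    # JSB/JSA side: first SSC base vs last SSC base
    fix(first_ssc, 0, last_ssc.content[-1])
    assert by_name  # structure retained


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic genome (or panel member)."""

    seed: int
    cp_type: str
    scale: str
    genome_length: int
    segments: dict = field(default_factory=dict)   # LSC/IRB/SSC/IRA -> (start, end)
    junctions: dict = field(default_factory=dict)
    locus_states: dict = field(default_factory=dict)
    marker_sizes: tuple = ()
    ssrs: tuple = ()        # (motif, copies, start)
    dispersed: tuple = ()   # (orientation, start1, start2, length)
    tandems: tuple = ()     # (period, start, length)


def _assemble(blocks, cp_type: str):
    """Concatenate blocks for a type; return sequence and block offsets."""
    parts = []
    offsets = {}
    pos = 0
    for b in blocks:
        s = b.for_type(cp_type)
        offsets[b.name] = (pos, pos + len(s))  # 0-based half-open
        parts.append(s)
        pos += len(s)
    return "".join(parts), offsets


def _features_for(offsets, segments) -> FeatureTable:
    """Synthetic gene annotations anchored on the assembled coordinates."""
    feats = []

    def gene(name, start0, end0, kind="gene"):
        feats.append(Feature(name, kind, start0 + 1, end0, "+"))

    a5, _ = offsets["del48_a5"]
    _, a3 = offsets["del48_a3"]
    gene("rps16", max(0, a5 - 100), a5 - 20)
    gene("trnQ-UUG", a3 + 20, a3 + 100, kind="tRNA")
    c5, _ = offsets["cem_a5"]
    _, c3 = offsets["cem_a3"]
    gene("cemA", max(0, c5 - 100), c5 - 20)
    gene("petA", c3 + 20, c3 + 100)
    r5, _ = offsets["rps11_a5"]
    _, r3 = offsets["rps11_a3"]
    gene("rps11", r5, r3)                       # point mutation inside the gene
    s5, _ = offsets["ccsa_a5"]
    _, s3 = offsets["ccsa_a3"]
    gene("ccsA", s5, s3, kind="CDS")
    lsc_s, lsc_e = segments["LSC"]
    gene("rps19", lsc_e - 99, lsc_e + 100)      # spans JLB
    irb_s, irb_e = segments["IRB"]
    gene("ndhF", irb_e - 79, irb_e + 120)       # spans JSB
    ssc_s, ssc_e = segments["SSC"]
    gene("ycf1", ssc_e - 149, ssc_e + 150)      # spans JSA
    f0_s, f0_e = offsets["lsc_fill_0"]
    width = f0_e - f0_s
    if width >= 240:
        gene("atpB", f0_s + 10, f0_s + 10 + 90, kind="CDS")
        gene("clpP", f0_s + 120, f0_s + 120 + 80)
        feats.append(Feature("clpP", "intron", f0_s + 141, f0_s + 180, "+"))
    return FeatureTable(feats)


def generate_plastome(cp_type: str, seed: int, scale: str = "toy"):
    """One synthetic circular genome of the requested cpDNA type.

    Returns ``(sequence, features, truth)``.  The genome carries an exact
    IR pair at known coordinates, the type's diagnostic loci, one marker
    cassette per synthetic NTCP marker with the type's product size, and
    the implanted repeat set — all recorded in the truth object.
    """
    if cp_type not in CP_TYPES:
        raise PlastotypeError(f"unknown cpDNA type {cp_type!r}; use one of {CP_TYPES}")
    blocks = _skeleton(seed, scale)
    residues, offsets = _assemble(blocks, cp_type)
    seq = CircularSequence(f"synthetic_{cp_type}_{seed}_{scale}", residues)

    segments = {}
    for seg in ("LSC", "IRB", "SSC", "IRA"):
        seg_blocks = [b.name for b in blocks if b.segment == seg]
        start = offsets[seg_blocks[0]][0]
        end = offsets[seg_blocks[-1]][1]
        segments[seg] = (start + 1, end)  # 1-based inclusive

    truth = SyntheticTruth(
        seed=seed,
        cp_type=cp_type,
        scale=scale,
        genome_length=len(residues),
        segments=segments,
        junctions={
            "JLB": segments["LSC"][1],
            "JSB": segments["IRB"][1],
            "JSA": segments["SSC"][1],
            "JLA": segments["IRA"][1],
        },
        locus_states=dict(LOCUS_STATES[cp_type]),
        marker_sizes=MARKER_SIZES[cp_type],
        ssrs=tuple(
            (unit, copies, offsets[f"ssr_{unit}"][0] + 2)  # +1 guard, +1 to 1-based
            for unit, copies in _SSR_IMPLANTS
        ),
        dispersed=(
            ("forward", offsets["disp_fwd_1"][0] + 1,
             offsets["disp_fwd_2"][0] + 1, 35),
            ("palindromic", offsets["disp_pal_1"][0] + 1,
             offsets["disp_pal_2"][0] + 1, 35),
        ),
        tandems=(
            (30, offsets["tandem30"][0] + 1, 90),
            (90, offsets["tandem90"][0] + 1, 180),
        ),
    )
    features = _features_for(offsets, segments)
    return seq, features, truth


# ---------------------------------------------------------------------------
# Panels with implanted variants

@dataclass
class PanelTruth:
    """Ground truth for a multi-genome panel derived from one ancestor."""

    seed: int
    scale: str
    ids: tuple
    types: tuple
    msa: object                     # variants.Msa built by construction
    substitutions: tuple            # (genome_id, column, ref_base, alt_base)
    indel_events: tuple             # (genome_id, col_start, col_end, kind, length)
    diagnostic_columns: tuple       # (column, {type: base}) single-base sites
    structural_blocks: tuple        # (col_start, col_end, name) length-variant spans
    member_truths: tuple = ()       # per-genome SyntheticTruth


def generate_panel(
    n_genomes: int = 5,
    base_type_mix=None,
    snp_rate: float = 2e-4,
    indel_rate: float = 5e-5,
    seed: int = 0,
    scale: str = "toy",
    shared_deletion=None,
):
    """A panel of genomes derived from one ancestor with implanted variants.

    ``base_type_mix`` assigns a cpDNA type per genome (default: all W, so
    the panel differs only by the implanted events).  Substitutions and
    indels are implanted at globally non-overlapping positions inside the
    background fillers (never in the IR, anchors, primers or diagnostic
    loci), at the given per-base rates (both must be in [0, 0.01]).
    ``shared_deletion=(k, length)`` additionally implants one deletion of
    the given length shared by the first ``k`` genomes.

    Returns ``(genomes, truth)`` where the truth carries the exact MSA
    built from the known events plus the implanted variant lists.
    """
    if not 0 <= snp_rate <= 0.01 or not 0 <= indel_rate <= 0.01:
        raise PlastotypeError("snp_rate and indel_rate must lie in [0, 0.01]")
    if base_type_mix is None:
        base_type_mix = ["W"] * n_genomes
    if len(base_type_mix) != n_genomes:
        raise PlastotypeError("base_type_mix length must equal n_genomes")
    for t in base_type_mix:
        if t not in CP_TYPES:
            raise PlastotypeError(f"unknown cpDNA type {t!r} in base_type_mix")

    blocks = _skeleton(seed, scale)
    rng = np.random.default_rng([int(seed), 1234, n_genomes])
    ids = tuple(f"panel_{seed}_{g}" for g in range(n_genomes))
    present = sorted(set(base_type_mix), key=CP_TYPES.index)

    # ---- sample events in mutable blocks, globally non-overlapping -------
    mutable = [b for b in blocks if b.mutable]
    events = {b.name: [] for b in mutable}  # (kind, local_pos, payload, genome_idx)
    used = {b.name: [] for b in mutable}

    def reserve(block, lo, hi, pad=15):
        for a, b_ in used[block.name]:
            if lo - pad < b_ and a < hi + pad:
                return False
        used[block.name].append((lo, hi))
        return True

    def sample_position(block, span):
        width = len(block.content)
        if width < span + 40:
            return None
        for _ in range(30):
            p = int(rng.integers(20, width - span - 20))
            if reserve(block, p, p + span):
                return p
        return None

    if shared_deletion is not None:
        k_rows, del_len = shared_deletion
        blk = max(mutable, key=lambda b: len(b.content))
        p = sample_position(blk, del_len)
        if p is None:
            raise PlastotypeError("no room for the shared deletion")
        for g in range(min(k_rows, n_genomes)):
            events[blk.name].append(("deletion", p, del_len, g))

    total_mut = sum(len(b.content) for b in mutable)
    for g in range(n_genomes):
        n_sub = rng.binomial(total_mut, snp_rate)
        n_ind = rng.binomial(total_mut, indel_rate)
        weights = np.array([len(b.content) for b in mutable], dtype=float)
        weights /= weights.sum()
        for _ in range(int(n_sub)):
            blk = mutable[int(rng.choice(len(mutable), p=weights))]
            p = sample_position(blk, 1)
            if p is None:
                continue
            old = blk.content[p]
            alt = str(rng.choice([b for b in "ACGT" if b != old]))
            events[blk.name].append(("substitution", p, alt, g))
        for _ in range(int(n_ind)):
            blk = mutable[int(rng.choice(len(mutable), p=weights))]
            length = int(rng.integers(1, 13))
            kind = "deletion" if rng.random() < 0.5 else "insertion"
            p = sample_position(blk, length if kind == "deletion" else 1)
            if p is None:
                continue
            payload = length if kind == "deletion" else _random_dna(rng, length, _FORBIDDEN)
            events[blk.name].append((kind, p, payload, g))

    # ---- build the alignment block by block ------------------------------
    col = 0
    rows = [[] for _ in range(n_genomes)]
    substitutions = []
    indel_events = []
    diagnostic_cols = []
    structural = []
    for b in blocks:
        if isinstance(b.content, dict):
            variants = {t: b.content[t] for t in present}
            widths = {t: len(v) for t, v in variants.items()}
            width = max(widths.values())
            if width == 0:
                continue
            if len(set(variants.values())) > 1 and len(set(widths.values())) == 1:
                # same-length variants: record the single differing column
                diff_cols = [
                    i for i in range(width)
                    if len({variants[t][i] for t in present}) > 1
                ]
                for i in diff_cols:
                    diagnostic_cols.append(
                        (col + i + 1, {t: variants[t][i] for t in present})
                    )
            elif len(set(widths.values())) > 1:
                structural.append((col + 1, col + width, b.name))
            for g, t in enumerate(base_type_mix):
                v = variants[t]
                rows[g].append(v + "-" * (width - len(v)))
            col += width
            continue

        content = b.content
        evs = sorted(events.get(b.name, ()), key=lambda e: e[1])
        ins_at = {}
        for kind, p, payload, g in evs:
            if kind == "insertion":
                ins_at.setdefault(p, []).append((payload, g))
        # column layout: base positions plus insertion columns after each pos
        width = len(content)
        for g in range(n_genomes):
            chars = list(content)
            for kind, p, payload, gg in evs:
                if gg != g:
                    continue
                if kind == "substitution":
                    chars[p] = payload
                elif kind == "deletion":
                    for i in range(p, p + payload):
                        chars[i] = "-"
            pieces = []
            for i, ch in enumerate(chars):
                pieces.append(ch)
                if i in ins_at:
                    for payload, gg in ins_at[i]:
                        pieces.append(payload if gg == g else "-" * len(payload))
            rows[g].append("".join(pieces))

        # truth columns: map local position -> alignment column
        col_of = {}
        c = col
        for i in range(width):
            col_of[i] = c + 1
            c += 1
            if i in ins_at:
                for payload, gg in ins_at[i]:
                    for j in range(len(payload)):
                        col_of[(i, gg, j)] = c + 1
                        c += 1
        for kind, p, payload, g in evs:
            if kind == "substitution":
                substitutions.append((ids[g], col_of[p], content[p], payload))
            elif kind == "deletion":
                indel_events.append(
                    (ids[g], col_of[p], col_of[p + payload - 1], "deletion", payload)
                )
            else:
                indel_events.append(
                    (ids[g], col_of[(p, g, 0)],
                     col_of[(p, g, len(payload) - 1)], "insertion", len(payload))
                )
        col = c

    from .variants import Msa  # local import to avoid a cycle

    row_strs = tuple("".join(r) for r in rows)
    msa = Msa(ids, row_strs)
    genomes = []
    member_truths = []
    for g, t in enumerate(base_type_mix):
        residues = row_strs[g].replace("-", "")
        genomes.append(CircularSequence(ids[g], residues))
        _, _, truth = generate_plastome(t, seed, scale)
        member_truths.append(truth)

    truth = PanelTruth(
        seed=seed,
        scale=scale,
        ids=ids,
        types=tuple(base_type_mix),
        msa=msa,
        substitutions=tuple(substitutions),
        indel_events=tuple(indel_events),
        diagnostic_columns=tuple(diagnostic_cols),
        structural_blocks=tuple(structural),
        member_truths=tuple(member_truths),
    )
    return genomes, truth
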