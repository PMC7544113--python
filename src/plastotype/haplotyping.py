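"""Chloroplast DNA (cpDNA) type assignment for potato plastomes.

Potato plastomes fall into historically defined haplotype classes
(W, W1, W2, W3, C, S, A, T).  The W-type is ancestral; the others derive
from it by point mutations visible as restriction-fragment changes, except
the T-type which arises by a 241 bp deletion:

* a G→A change creating a BamHI site in the cemA–petA intergenic region
  separates {S, C, A} from {W family, T} (seen as a gained 3.77 kb
  fragment);
* within that clade, a conserved 48 bp deletion between rps16 and
  trnQ-UUG marks the S-type (a HindIII fragment 48 bp shorter), and a G→C
  change creating a second BamHI site inside ccsA marks the A-type (loss
  of a ~300 bp fragment); otherwise the plastome is C-type;
* outside it, the 241 bp deletion marks the T-type and an A→G change
  creating a PvuII site in rps11 marks the W2-type; otherwise W.

Two complementary inputs drive the call: the product-size profile of seven
chloroplast microsatellite (NTCP) markers compared against published
reference patterns, and the diagnostic-locus states above read directly
from the sequence (with the restriction-fragment shifts as corroborating
evidence).  Sequence-level diagnostics take precedence over spectrum-diff
heuristics because fragment matching uses gel-scale tolerances.

Diagnostic loci are defined by two flanking anchor k-mers (config data,
not coordinates) so typing tolerates length variation elsewhere in the
genome.  W1/W3 are representable states but have no packaged sequence
rules and are never emitted by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from ._match import find_matches
from .errors import PlastotypeError
from .io import CircularSequence, revcomp
from .restriction import DEFAULT_ENZYMES, digest

CP_TYPES = ("S", "C", "A", "W", "W1", "W2", "W3", "T", "C/A", "inconclusive")

# Canonical names of the packaged diagnostic loci, used by the decision tree.
LOCUS_CEMA_PETA = "cemA_petA_BamHI"
LOCUS_DEL48 = "rps16_trnQ_del48"
LOCUS_CCSA = "ccsA_BamHI"
LOCUS_RPS11 = "rps11_PvuII"
LOCUS_DEL241 = "del241"


@dataclass(frozen=True)
class DiagnosticLocus:
    """A typing-diagnostic sequence feature located by flanking anchors.

    ``mechanism`` is 'site_gain' / 'site_loss' (an enzyme recognition site
    created or destroyed between the anchors) or 'deletion' (the
    inter-anchor distance shortened by ``expected_deletion_len`` relative
    to ``reference_gap``).  Anchors must occur uniquely in a genome for the
    locus to be resolvable.
    """

    name: str
    mechanism: str
    enzyme_site: str = ""
    anchor5: str = ""
    anchor3: str = ""
    expected_deletion_len: int = 0
    reference_gap: int = 0

    def __post_init__(self):
        if self.mechanism not in ("site_gain", "site_loss", "deletion"):
            raise PlastotypeError(
                f"locus {self.name}: unknown mechanism {self.mechanism!r}"
            )
        if self.mechanism == "deletion" and self.expected_deletion_len <= 0:
            raise PlastotypeError(
                f"locus {self.name}: deletion mechanism needs an expected length"
            )
        if self.mechanism != "deletion" and not self.enzyme_site:
            raise PlastotypeError(f"locus {self.name}: enzyme site required")
        if len(self.anchor5) < 10 or len(self.anchor3) < 10:
            raise PlastotypeError(f"locus {self.name}: anchors must be >= 10 nt")


def load_diagnostics(path) -> list:
    """Read a diagnostic-locus config TSV.

    Columns: name, mechanism, enzyme_site, anchor5, anchor3,
    expected_deletion_len, reference_gap (header required).
    """
    lines = Path(path).read_text().splitlines()
    expected = ["name", "mechanism", "enzyme_site", "anchor5", "anchor3",
                "expected_deletion_len", "reference_gap"]
    if not lines or [c.strip().lower() for c in lines[0].split("\t")[:7]] != expected:
        raise PlastotypeError(f"{path}: expected header {'	'.join(expected)!r}")
    loci = []
    for line in lines[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        parts = [c.strip() for c in line.split("\t")]
        loci.append(
            DiagnosticLocus(
                parts[0], parts[1], parts[2], parts[3], parts[4],
                int(parts[5] or 0), int(parts[6] or 0),
            )
        )
    return loci


def _unique_position(seq: CircularSequence, anchor: str):
    """1-based start of the anchor if it occurs exactly once, else None/count."""
    hits = [p for p, _ in find_matches(seq, anchor, 0)]
    return (hits[0], 1) if len(hits) == 1 else (None, len(hits))


def detect_diagnostic_loci(seq: CircularSequence, loci) -> dict:
    """State of each diagnostic locus in a genome.

    'present' means the derived (mutated) state: the gained site exists /
    the lost site is gone / the deletion has happened.  Anchors found zero
    times on the forward strand are retried on the reverse complement; any
    anchor found more than once yields 'unresolvable', never a guess.
    """
    states = {}
    rc = None
    for locus in loci:
        states[locus.name] = _detect_one(seq, locus)
        if states[locus.name] == "unresolvable":
            if rc is None:
                rc = seq.reverse_complement()
            retry = _detect_one(rc, locus)
            if retry != "unresolvable":
                states[locus.name] = retry
    return states


def _detect_one(seq: CircularSequence, locus: DiagnosticLocus) -> str:
    n = len(seq)
    p5, c5 = _unique_position(seq, locus.anchor5)
    p3, c3 = _unique_position(seq, locus.anchor3)
    if p5 is None or p3 is None:
        return "unresolvable"
    gap = (p3 - (p5 + len(locus.anchor5))) % n
    if locus.mechanism == "deletion":
        if gap == locus.reference_gap - locus.expected_deletion_len:
            return "present"
        if gap == locus.reference_gap:
            return "absent"
        return "unresolvable"
    region = seq.fetch(p5, p5 + len(locus.anchor5) + gap + len(locus.anchor3) - 1)
    site = locus.enzyme_site.upper()
    found = site in region or revcomp(site) in region
    if locus.mechanism == "site_gain":
        return "present" if found else "absent"
    return "absent" if found else "present"  # site_loss: loss present when site gone


# ---------------------------------------------------------------------------
# Method 1: microsatellite marker profiles

NTCP_MARKERS = ("NTCP6", "NTCP7", "NTCP8", "NTCP9", "NTCP12", "NTCP14", "NTCP18")

#: Published product-size patterns of the seven NTCP markers.  Several exact
#: C-type rows exist (the reference studies report accession-level size
#: variation at NTCP8/NTCP12); one pattern is shared by the C and A types
#: and maps to the ambiguous 'C/A' call that RFLP analysis then refines.
MARKER_REFERENCE_TABLE = (
    ((127, 173, 251, 289, 129, 150, 186), "S"),
    ((173, 174, 251, 289, 126, 150, 187), "C"),
    ((174, 174, 249, 289, 127, 151, 186), "C"),
    ((174, 174, 250, 289, 126, 150, 186), "C"),
    ((174, 174, 250, 289, 127, 151, 186), "C/A"),
)


@dataclass(frozen=True)
class MarkerTypingCall:
    call: str
    profile: tuple
    evidence: tuple = ()


def type_by_markers(profile, reference_table=MARKER_REFERENCE_TABLE) -> MarkerTypingCall:
    """Match a marker product-size vector against the reference patterns.

    An exact match yields that pattern's type; the pattern shared by the C
    and A types yields 'C/A'; anything else (including absent or multiple
    products) is 'inconclusive'.
    """
    sizes = []
    for entry in profile:
        size = getattr(entry, "size", entry)
        sizes.append(size)
    width = len(reference_table[0][0])
    if len(sizes) != width:
        raise PlastotypeError(
            f"profile has {len(sizes)} markers, reference table has {width}"
        )
    prof = tuple(sizes)
    if any(s is None for s in prof):
        return MarkerTypingCall(
            "inconclusive", prof, ("one or more markers absent or multi-product",)
        )
    for pattern, cp_type in reference_table:
        if prof == pattern:
            return MarkerTypingCall(
                cp_type, prof, (f"profile matches reference pattern {pattern}",)
            )
    return MarkerTypingCall("inconclusive", prof, ("no reference pattern match",))


# ---------------------------------------------------------------------------
# Method 2: RFLP / diagnostic-locus decision tree

@dataclass(frozen=True)
class RflpTypingCall:
    call: str
    states: dict
    evidence: tuple = ()


_REQUIRED = {
    LOCUS_CEMA_PETA: "cemA–petA BamHI site (3.77 kb fragment gain; separates S/C/A)",
    LOCUS_DEL48: "48 bp rps16–trnQ deletion (HindIII fragment 48 bp shorter; S-type)",
    LOCUS_CCSA: "ccsA BamHI site (~300 bp fragment loss; A-type)",
    LOCUS_RPS11: "rps11 PvuII site (20.9 kb fragment gain; W2-type)",
    LOCUS_DEL241: "241 bp deletion (T-type)",
}


def type_by_rflp(
    seq: CircularSequence,
    diagnostics,
    enzymes=None,
    corroborate: bool = False,
) -> RflpTypingCall:
    """Assign a cpDNA type from sequence-level diagnostic-locus states.

    Decision tree: the cemA–petA BamHI site present sends the genome to
    {S, C, A} — the 48 bp deletion then means S, else the ccsA BamHI site
    means A, else C.  With the cemA–petA site absent, the 241 bp deletion
    means T, the rps11 PvuII site means W2, and no change at all means W.
    Contradictory or unresolvable states yield 'inconclusive' with the
    conflicting evidence, never a guess.

    With ``corroborate=True`` the relevant digests are run and the matching
    fragment sizes appended as evidence (the call itself never depends on
    them — fragment matching uses gel-scale tolerances).
    """
    states = detect_diagnostic_loci(seq, diagnostics)
    evidence = []
    unresolved = [n for n, s in states.items() if s == "unresolvable"]
    for name in unresolved:
        evidence.append(f"locus {name} unresolvable (anchors absent or ambiguous)")

    def state(name):
        return states.get(name, "missing")

    call = None
    if state(LOCUS_CEMA_PETA) == "present":
        sub = {state(LOCUS_DEL48), state(LOCUS_CCSA)}
        if "unresolvable" in sub or "missing" in sub:
            call = "inconclusive"
            evidence.append("S/C/A branch entered but a branch locus is unusable")
        elif state(LOCUS_DEL48) == "present" and state(LOCUS_CCSA) == "present":
            call = "inconclusive"
            evidence.append("contradiction: both the S and the A diagnostic present")
        elif state(LOCUS_DEL48) == "present":
            call = "S"
            evidence.append(_REQUIRED[LOCUS_DEL48] + ": present")
        elif state(LOCUS_CCSA) == "present":
            call = "A"
            evidence.append(_REQUIRED[LOCUS_CCSA] + ": present")
        else:
            call = "C"
            evidence.append("no S or A diagnostic on top of the cemA–petA site gain")
        evidence.insert(0, _REQUIRED[LOCUS_CEMA_PETA] + ": present")
    elif state(LOCUS_CEMA_PETA) == "absent":
        if state(LOCUS_DEL48) == "present" or state(LOCUS_CCSA) == "present":
            call = "inconclusive"
            evidence.append(
                "contradiction: S/A diagnostic present without the cemA–petA site"
            )
        else:
            sub = {state(LOCUS_DEL241), state(LOCUS_RPS11)}
            if "unresolvable" in sub or "missing" in sub:
                call = "inconclusive"
                evidence.append("W-family branch entered but a branch locus is unusable")
            elif state(LOCUS_DEL241) == "present" and state(LOCUS_RPS11) == "present":
                call = "inconclusive"
                evidence.append("contradiction: both the T and the W2 diagnostic present")
            elif state(LOCUS_DEL241) == "present":
                call = "T"
                evidence.append(_REQUIRED[LOCUS_DEL241] + ": present")
            elif state(LOCUS_RPS11) == "present":
                call = "W2"
                evidence.append(_REQUIRED[LOCUS_RPS11] + ": present")
            else:
                call = "W"
                evidence.append("no diagnostic change: ancestral W-type")
        evidence.insert(0, _REQUIRED[LOCUS_CEMA_PETA] + ": absent")
    else:
        call = "inconclusive"
        evidence.append("cemA–petA locus unusable; decision tree cannot start")

    if corroborate and call in ("S", "C", "A"):
        enzymes = enzymes or DEFAULT_ENZYMES
        sp = digest(seq, enzymes["BamHI"])
        near = [f for f in sp.fragments if abs(f - 3769) <= 25]
        evidence.append(
            f"BamHI digest fragment near 3769 bp: {near[0] if near else 'none'}"
        )
    return RflpTypingCall(call, states, tuple(evidence))


# ---------------------------------------------------------------------------
# Combined report

@dataclass
class TypingReport:
    """Per-genome typing evidence trail and the final cpDNA type."""

    genome_id: str
    final_type: str
    marker_call: str = "unavailable"
    rflp_call: str = "unavailable"
    marker_profile: tuple = ()
    locus_states: dict = field(default_factory=dict)
    evidence: tuple = ()

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def assign_type(
    genome_id: str,
    marker_call: MarkerTypingCall | None = None,
    rflp_call: RflpTypingCall | None = None,
) -> TypingReport:
    """Combine the marker and RFLP calls into a final type.

    Compatible calls (equal; marker 'C/A' refined by RFLP to C or A; either
    side inconclusive) resolve to the more specific call.  Incompatible
    calls yield 'inconclusive' carrying both evidence trails.
    """
    if marker_call is None and rflp_call is None:
        raise PlastotypeError("at least one of marker_call / rflp_call is required")
    evidence = []
    if marker_call is not None:
        evidence.append(f"marker analysis: {marker_call.call}")
        evidence.extend(marker_call.evidence)
    if rflp_call is not None:
        evidence.append(f"RFLP/sequence analysis: {rflp_call.call}")
        evidence.extend(rflp_call.evidence)

    m = marker_call.call if marker_call else None
    r = rflp_call.call if rflp_call else None
    if m is None:
        final = r
    elif r is None:
        final = m
    elif m == r:
        final = m
    elif m == "inconclusive":
        final = r
    elif r == "inconclusive":
        final = m
    elif m == "C/A" and r in ("C", "A"):
        final = r
        evidence.append(f"ambiguous C/A marker pattern refined to {r} by RFLP")
    else:
        final = "inconclusive"
        evidence.append(f"conflict: marker call {m} vs RFLP call {r}")

    return TypingReport(
        genome_id,
        final,
        m or "unavailable",
        r or "unavailable",
        tuple(marker_call.profile) if marker_call else (),
        dict(rflp_call.states) if rflp_call else {},
        tuple(evidence),
    )


def write_typing_reports(reports, path_json, path_tsv=None) -> None:
    payload = [r.to_dict() for r in reports]
    Path(path_json).write_text(json.dumps(payload, indent=2) + "\n")
    if path_tsv:
        with Path(path_tsv).open("w") as fh:
            fh.write("genome\tfinal_type\tmarker_call\trflp_call\n")
            for r in reports:
                fh.write(
                    f"{r.genome_id}\t{r.final_type}\t{r.marker_call}\t{r.rflp_call}\n"
                )
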