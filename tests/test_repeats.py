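"""SSR, tandem-repeat and dispersed-repeat detection."""

import pytest

from plastotype import (
    CircularSequence,
    find_dispersed_repeats,
    find_ssrs,
    find_tandem_repeats,
)
from plastotype.io import complement, revcomp, rotate
from plastotype.repeats import DEFAULT_SSR_THRESHOLDS, canonical_motif

from conftest import random_circle


def linear(seq_str, sid="toy"):
    return CircularSequence(sid, seq_str, circular=False)


# --------------------------------------------------------------------------
# Independent SSR oracle: enumerate every (start, unit) pair directly.

def oracle_ssrs(seq, thresholds=None):
    thr = dict(DEFAULT_SSR_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    s = seq.residues
    n = len(s)
    ext = s + s[: min(n - 1, 600)] if seq.circular else s
    found = set()
    for u, min_copies in thr.items():
        for i in range(min(n, len(ext) - u)):
            motif = ext[i : i + u]
            if len(motif) < u:
                continue
            # primitive motif only
            if any(u % p == 0 and motif == motif[:p] * (u // p)
                   for p in range(1, u)):
                continue
            # left-maximal: the run must not continue to the left
            if i > 0 and ext[i - 1] == ext[i - 1 + u]:
                continue
            if seq.circular and i == 0 and s[-1] == s[(u - 1) % n]:
                continue
            copies = 1
            while ext[i : i + u] == ext[i + copies * u : i + (copies + 1) * u]:
                copies += 1
                if copies * u >= n:
                    break
            # partial extra periodicity beyond full copies is irrelevant to
            # the copy count
            if copies >= min_copies:
                found.add((motif, u, copies, i + 1))
    return found


class TestSsrs:
    def test_mono_threshold_edge(self):
        body = "GC" * 30
        hit = linear(body + "G" + "A" * 10 + "C" + body)
        miss = linear(body + "G" + "A" * 9 + "C" + body)
        runs = [r for r in find_ssrs(hit) if r.motif == "A"]
        assert len(runs) == 1 and runs[0].copies == 10
        assert not [r for r in find_ssrs(miss) if r.motif == "A"]

    def test_dinucleotide_reported_once_at_primitive_unit(self):
        seq = linear("GGCGGC" + "C" + "AT" * 7 + "C" + "GGCGGC")
        runs = find_ssrs(seq)
        assert len(runs) == 1
        r = runs[0]
        assert r.unit == 2 and r.motif == "AT" and r.copies == 7
        assert r.canonical == "AT"

    def test_canonical_motif_strand_and_rotation_independent(self):
        assert canonical_motif("GA") == canonical_motif("AG")   # rotation
        assert canonical_motif("AT") == canonical_motif(revcomp("AT"))
        assert canonical_motif("AAC") == canonical_motif("GTT")  # revcomp

    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_agrees_with_enumeration_oracle_on_random_circle(self, seed):
        seq = random_circle(2000, seed=seed)
        low = {1: 5, 2: 3, 3: 3, 4: 2, 5: 2, 6: 2}  # low thresholds: more hits
        got = {(r.motif, r.unit, r.copies, r.start) for r in find_ssrs(seq, low)}
        assert got == oracle_ssrs(seq, low)

    def test_counts_rotation_invariant_including_origin_spanning_run(self):
        base = random_circle(500, seed=30).residues
        # place a mono run across the origin: 6 A at the end + 6 A at the start
        s = "A" * 6 + "C" + base[7:-7] + "G" + "A" * 6
        seq = CircularSequence("wrap", s)
        counts = len(find_ssrs(seq))
        for origin in (3, 250, 495):
            assert len(find_ssrs(rotate(seq, origin))) == counts

    def test_counts_strand_symmetric(self):
        seq, _, _ = _toy_genome()
        fwd = sorted(r.canonical for r in find_ssrs(seq))
        rev = sorted(r.canonical for r in find_ssrs(seq.reverse_complement()))
        assert fwd == rev


def _toy_genome():
    from plastotype import generate_plastome
    return generate_plastome("W", 13, "toy")


class TestTandemRepeats:
    UNIT = "ACGTTGCATCGAATGCCTGAGTTACGTAGC"  # 30 bp, non-periodic

    def test_exact_three_copies(self):
        pad = random_circle(300, seed=40).residues
        seq = linear(pad + self.UNIT * 3 + pad)
        hits = [h for h in find_tandem_repeats(seq) if h.period == 30]
        assert len(hits) == 1
        h = hits[0]
        assert h.copies == 3.0 and h.identity == 1.0 and h.length == 90
        assert h.unit == self.UNIT

    def test_one_substitution_keeps_high_identity(self):
        pad = random_circle(300, seed=41).residues
        copy2 = "T" + self.UNIT[1:] if self.UNIT[0] != "T" else "A" + self.UNIT[1:]
        seq = linear(pad + self.UNIT + copy2 + self.UNIT + pad)
        hits = [h for h in find_tandem_repeats(seq) if h.period == 30]
        assert len(hits) == 1 and hits[0].identity >= 0.97

    def test_90bp_unit_two_copies_detected(self):
        unit90 = random_circle(90, seed=42).residues
        pad = random_circle(400, seed=43).residues
        seq = linear(pad + unit90 * 2 + pad)
        assert any(h.period == 90 and h.copies >= 2.0
                   for h in find_tandem_repeats(seq))

    def test_reports_are_self_verifying(self):
        seq, _, _ = _toy_genome()
        for h in find_tandem_repeats(seq):
            region = seq.fetch(h.start, h.start + h.length - 1)
            mism = sum(
                1 for i, ch in enumerate(region) if ch != h.unit[i % h.period]
            )
            assert 1.0 - mism / len(region) >= 0.9


# --------------------------------------------------------------------------
# Independent dispersed oracle: full per-diagonal scan, no seeding.

def oracle_dispersed(seq, min_len, max_mismatch):
    s = seq.residues
    n = len(s)
    out = set()
    for orientation in ("forward", "palindromic", "reverse", "complement"):
        if orientation == "forward":
            t = s
        elif orientation == "palindromic":
            t = revcomp(s)
        elif orientation == "reverse":
            t = s[::-1]
        else:
            t = complement(s)
        reversed_map = orientation in ("palindromic", "reverse")
        d_range = range(1, n) if orientation in ("forward", "complement") else \
            range(-(n - 1), n)
        for d in d_range:
            i_min, i_max = max(0, -d), min(n - 1, n - 1 - d)
            if i_max - i_min + 1 < min_len:
                continue
            v = [1 if s[i] != t[i + d] else 0 for i in range(i_min, i_max + 1)]
            a_rel = 0
            b_rel = -1
            mism = 0
            width = len(v)
            while a_rel < width:
                if b_rel < a_rel - 1:
                    b_rel = a_rel - 1
                    mism = 0
                while b_rel + 1 < width and mism + v[b_rel + 1] <= max_mismatch:
                    b_rel += 1
                    mism += v[b_rel]
                length = b_rel - a_rel + 1
                left_blocked = a_rel == 0 or mism + v[a_rel - 1] > max_mismatch
                right_blocked = b_rel == width - 1 or mism + v[b_rel + 1] > max_mismatch
                if length >= min_len and left_blocked and right_blocked:
                    a, b = i_min + a_rel, i_min + b_rel
                    j = (n - 1 - (b + d)) if reversed_map else a + d
                    x1, x2 = sorted((a, j))
                    if x2 > x1 + length - 1:
                        out.add((orientation, x1 + 1, x2 + 1, length, mism))
                mism -= v[a_rel]
                a_rel += 1
    return out


class TestDispersedRepeats:
    def test_exact_forward_duplication(self):
        core = random_circle(35, seed=50).residues[:30]
        pad1 = random_circle(120, seed=51).residues
        pad2 = random_circle(120, seed=52).residues
        seq = linear(pad1 + core + pad2 + core + pad1[:40])
        hits = [h for h in find_dispersed_repeats(seq)
                if h.orientation == "forward"]
        assert len(hits) >= 1
        best = max(hits, key=lambda h: h.length)
        assert best.mismatches == 0 and best.length >= 30
        c1, c2 = best.extract(seq)
        assert c1 == c2

    def test_palindromic_pair(self):
        core = random_circle(40, seed=53).residues[:30]
        pad1 = random_circle(150, seed=54).residues
        pad2 = random_circle(150, seed=55).residues
        seq = linear(pad1 + core + pad2 + revcomp(core) + pad1[:40])
        hits = [h for h in find_dispersed_repeats(seq)
                if h.orientation == "palindromic"]
        assert hits and max(h.length for h in hits) >= 30

    @pytest.mark.parametrize("seed", [60, 61])
    def test_matches_exhaustive_oracle_at_reduced_scale(self, seed):
        seq = random_circle(500, seed=seed)
        got = {
            (h.orientation, h.start1, h.start2, h.length, h.mismatches)
            for h in find_dispersed_repeats(
                seq, min_len=20, max_mismatch=3, include_ir_pair=True
            )
        }
        assert got == oracle_dispersed(seq, 20, 3)

    def test_reports_are_self_verifying(self):
        seq, _, truth = _toy_genome()
        hits = find_dispersed_repeats(seq, include_ir_pair=True)
        for h in hits:
            c1, c2 = h.extract(seq)
            assert sum(1 for a, b in zip(c1, c2) if a != b) == h.mismatches <= 3
            assert h.length >= 30

    def test_ir_pair_excluded_by_default_but_flag_restores_it(self):
        seq, _, truth = _toy_genome()
        ir = (truth.segments["IRB"], truth.segments["IRA"])
        with_ir = find_dispersed_repeats(seq, include_ir_pair=True)
        without = find_dispersed_repeats(seq, ir_intervals=ir)
        big_palindromes = [h for h in with_ir
                           if h.orientation == "palindromic" and h.length >= 1000]
        assert big_palindromes and not [
            h for h in without
            if h.orientation == "palindromic" and h.length >= 1000
        ]

    def test_implanted_pairs_recovered(self):
        seq, _, truth = _toy_genome()
        hits = find_dispersed_repeats(seq)
        for orientation, s1, s2, length in truth.dispersed:
            assert any(
                h.orientation == orientation
                and h.start1 <= s1
                and h.start2 <= s2
                and h.start1 + h.length >= s1 + length
                for h in hits
            ), (orientation, s1, s2)
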