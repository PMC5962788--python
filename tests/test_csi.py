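import itertools
import random

import pytest

from sigscan.csi import (
    ColumnParams,
    FlankParams,
    INGROUP_EXCLUSIVE_GAP,
    INGROUP_EXCLUSIVE_RESIDUE,
    OTHER,
    SHARED,
    IndelBlock,
    classify_columns,
    detect_csis,
    expand_signature_rows,
    extract_signature_segment,
    find_indel_blocks,
    format_signature_report,
    match_clade_pattern,
    score_flanks,
    subject_carries_indel,
    validate_specificity,
)
from sigscan.seq_io import Alignment, GroupManifest, HitRecord, HitTable, SequenceRecord

from conftest import random_alignment_and_manifest


def two_clade_manifest(n_in, n_out, ingroup_label="In"):
    entries = {f"A{i}": {"class": "In"} for i in range(1, n_in + 1)}
    entries.update({f"O{i}": {"class": "Out"} for i in range(1, n_out + 1)})
    return GroupManifest(entries).with_ingroup("class", ingroup_label)


def flanked_alignment(n_in=3, n_out=2, insert="WWW", flank=10, exception=None):
    """Conserved flanks around a clade-restricted insertion."""
    left = "ACDEFGHIKL"[:flank] if flank <= 10 else "ACDEFGHIKL" * 4
    left = (left * 4)[:flank]
    right = ("MNPQRSTVWY" * 4)[:flank]
    rows = []
    for i in range(1, n_in + 1):
        body = insert if f"A{i}" != exception else "-" * len(insert)
        rows.append((f"A{i}", left + body + right))
    for i in range(1, n_out + 1):
        rows.append((f"O{i}", left + "-" * len(insert) + right))
    return Alignment(rows)


class TestClassifyColumns:
    def test_exclusive_residue_column(self):
        aln = Alignment(
            [("A1", "W"), ("A2", "W"), ("A3", "W"), ("O1", "-"), ("O2", "-")]
        )
        man = two_clade_manifest(3, 2)
        # single-column alignment: pad so constructor keeps the gap column
        aln = Alignment(
            [("A1", "AWA"), ("A2", "AWA"), ("A3", "AWA"), ("O1", "A-A"), ("O2", "A-A")]
        )
        assert classify_columns(aln, man) == [SHARED, INGROUP_EXCLUSIVE_RESIDUE, SHARED]

    def test_all_residue_is_shared(self):
        aln = Alignment([("A1", "W"), ("A2", "W"), ("A3", "W"), ("O1", "W"), ("O2", "W")])
        assert classify_columns(aln, two_clade_manifest(3, 2)) == [SHARED]

    def test_tau_in_fraction_threshold(self):
        aln = Alignment(
            [("A1", "AWA"), ("A2", "AWA"), ("A3", "A-A"), ("O1", "A-A"), ("O2", "A-A")]
        )
        man = two_clade_manifest(3, 2)
        # 2 of 3 in-group rows bear a residue: below tau_in=1.0, above 0.6
        assert classify_columns(aln, man)[1] == OTHER
        assert (
            classify_columns(aln, man, ColumnParams(tau_in=0.6))[1]
            == INGROUP_EXCLUSIVE_RESIDUE
        )

    def test_exclusive_gap_column(self):
        aln = Alignment(
            [("A1", "A-A"), ("A2", "A-A"), ("A3", "A-A"), ("O1", "AWA"), ("O2", "AWA")]
        )
        assert (
            classify_columns(aln, two_clade_manifest(3, 2))[1] == INGROUP_EXCLUSIVE_GAP
        )

    def test_taxon_missing_from_manifest_errors(self):
        aln = Alignment([("A1", "AA"), ("zz", "AA")])
        with pytest.raises(ValueError, match="zz"):
            classify_columns(aln, two_clade_manifest(1, 1))


def brute_force_blocks(aln, man):
    """Independent oracle: per-column set logic plus itertools.groupby runs."""
    ingroup = man.ingroup_taxa()
    in_taxa = [t for t in aln.taxa if t in ingroup]
    out_taxa = [t for t in aln.taxa if t not in ingroup]

    def state(c):
        col = {t: aln.row(t)[c] for t in aln.taxa}
        in_res = [t for t in in_taxa if col[t] != "-"]
        out_res = [t for t in out_taxa if col[t] != "-"]
        if in_taxa and out_taxa:
            if len(in_res) == len(in_taxa) and not out_res:
                return "ins"
            if not in_res and len(out_res) == len(out_taxa):
                return "del"
        return "bg"

    blocks = []
    pos = 0
    for key, group in itertools.groupby(range(aln.length), key=state):
        cols = list(group)
        if key in ("ins", "del"):
            blocks.append((key, cols[0], cols[-1] + 1))
    return blocks


class TestFindIndelBlocks:
    def test_two_column_block(self):
        aln = Alignment(
            [
                ("A1", "AAWWAA"),
                ("A2", "AAWWAA"),
                ("A3", "AAWWAA"),
                ("O1", "AA--AA"),
                ("O2", "AA--AA"),
            ]
        )
        man = two_clade_manifest(3, 2)
        blocks = find_indel_blocks(aln, classify_columns(aln, man), man)
        assert len(blocks) == 1
        b = blocks[0]
        assert (b.col_start, b.col_end, b.indel_type) == (2, 4, "insertion")
        sizes = b.carrier_sizes()
        assert min(sizes.values()) == max(sizes.values()) == 2

    def test_partial_carrier_gives_size_range(self):
        aln = Alignment(
            [
                ("A1", "AAWWAA"),
                ("A2", "AAW-AA"),
                ("O1", "AA--AA"),
                ("O2", "AA--AA"),
            ]
        )
        man = two_clade_manifest(2, 2)
        states = classify_columns(aln, man, ColumnParams(tau_in=0.5))
        blocks = find_indel_blocks(aln, states, man)
        sizes = blocks[0].carrier_sizes()
        assert (min(sizes.values()), max(sizes.values())) == (1, 2)

    def test_no_exclusive_columns_empty(self):
        aln = Alignment([("A1", "AAA"), ("A2", "AAA"), ("O1", "AAA"), ("O2", "AAA")])
        man = two_clade_manifest(2, 2)
        assert find_indel_blocks(aln, classify_columns(aln, man), man) == []

    def test_matches_brute_force_oracle_on_random_alignments(self):
        rng = random.Random(42)
        checked = 0
        for _ in range(300):
            made = random_alignment_and_manifest(rng)
            if made is None:
                continue
            aln, man = made
            states = classify_columns(aln, man)
            got = [
                (b.indel_type[:3], b.col_start, b.col_end)
                for b in find_indel_blocks(aln, states, man)
            ]
            want = [
                (k.replace("ins", "ins").replace("del", "del"), s, e)
                for k, s, e in brute_force_blocks(aln, man)
            ]
            want = [
                ("ins" if k == "ins" else "del", s, e) for k, s, e in brute_force_blocks(aln, man)
            ]
            assert got == want, f"{aln.rows}"
            checked += 1
        assert checked > 200


class TestScoreFlanks:
    def make(self, left, right, block_cols=2):
        """Alignment whose flank columns are given explicitly per side."""
        rows = {}
        for name in ("A1", "A2", "O1", "O2"):
            ingroup = name.startswith("A")
            body = "W" * block_cols if ingroup else "-" * block_cols
            rows[name] = left[name] + body + right[name]
        return Alignment(list(rows.items()))

    def test_boundary_exactly_F_passes(self):
        # 5 identical flank columns per side
        same = {"A1": "ACDEF", "A2": "ACDEF", "O1": "ACDEF", "O2": "ACDEF"}
        aln = self.make(same, same)
        man = two_clade_manifest(2, 2)
        block = find_indel_blocks(aln, classify_columns(aln, man), man)[0]
        left, right, passed = score_flanks(aln, block, FlankParams(min_conserved=5))
        assert (left, right, passed) == (5, 5, True)

    def test_boundary_F_minus_1_fails(self):
        left = {"A1": "ACDEF", "A2": "ACDEF", "O1": "ACDEF", "O2": "ACDEG"}
        right = {"A1": "ACDEF", "A2": "ACDEF", "O1": "ACDEF", "O2": "ACDEF"}
        aln = self.make(left, right)
        man = two_clade_manifest(2, 2)
        block = find_indel_blocks(aln, classify_columns(aln, man), man)[0]
        l, r, passed = score_flanks(
            aln, block, FlankParams(min_conserved=5, conservation_rule="identical_only")
        )
        assert (l, r, passed) == (4, 5, False)

    def test_strong_group_column_counts(self):
        # I/L/V fall in the MILV strong group
        left = {"A1": "IACDE", "A2": "LACDE", "O1": "VACDE", "O2": "IACDE"}
        right = {"A1": "ACDEF", "A2": "ACDEF", "O1": "ACDEF", "O2": "ACDEF"}
        aln = self.make(left, right)
        man = two_clade_manifest(2, 2)
        block = find_indel_blocks(aln, classify_columns(aln, man), man)[0]
        strict = score_flanks(
            aln, block, FlankParams(min_conserved=5, conservation_rule="identical_only")
        )
        grouped = score_flanks(
            aln,
            block,
            FlankParams(min_conserved=5, conservation_rule="identical_or_strong_group"),
        )
        assert strict[0] == 4 and grouped[0] == 5
        assert not strict[2] and grouped[2]

    def test_gap_columns_skipped_not_counted(self):
        # a column with a gap in one row is skipped, window walks past it
        rows = [
            ("A1", "ACDEF-GWWMNPQRS"),
            ("A2", "ACDEF-GWWMNPQRS"),
            ("O1", "ACDEFHG--MNPQRS"),
            ("O2", "ACDEF-G--MNPQRS"),
        ]
        aln = Alignment(rows)
        man = two_clade_manifest(2, 2)
        block = find_indel_blocks(aln, classify_columns(aln, man), man)[0]
        left, right, passed = score_flanks(aln, block, FlankParams(min_conserved=5))
        assert left == 6  # ACDEF G, the gap dialect column skipped
        assert passed


class TestMatchClade:
    def test_full_class_matches_with_no_exceptions(self, manifest_5in_4out):
        block = IndelBlock(0, 1, "insertion", {}, frozenset(f"A{i}" for i in range(1, 6)))
        rank, label, exc = match_clade_pattern(
            block, manifest_5in_4out, [f"A{i}" for i in range(1, 6)] + ["O1", "O2"]
        )
        assert (rank, label, exc) == ("class", "In", ())

    def test_exception_taxon_listed(self, manifest_5in_4out):
        carriers = frozenset({"A1", "A2", "A3", "A4"})
        taxa = [f"A{i}" for i in range(1, 6)] + ["O1"]
        assert match_clade_pattern(block_of(carriers), manifest_5in_4out, taxa) is None
        rank, label, exc = match_clade_pattern(
            block_of(carriers), manifest_5in_4out, taxa, max_exceptions=1
        )
        assert (rank, label, exc) == ("class", "In", ("A5",))

    def test_carrier_outside_every_clade_gives_none(self, manifest_5in_4out):
        carriers = frozenset({"A1", "A2", "A3", "A4", "A5", "O1"})
        taxa = list(manifest_5in_4out.known_taxa)
        assert (
            match_clade_pattern(
                block_of(carriers), manifest_5in_4out, taxa, max_exceptions=2
            )
            is None
        )

    def test_smallest_clade_wins(self, manifest_5in_4out):
        # A1+A2 are the Gsub genus nested inside the class
        carriers = frozenset({"A1", "A2"})
        taxa = [f"A{i}" for i in range(1, 6)] + ["O1"]
        rank, label, exc = match_clade_pattern(
            block_of(carriers), manifest_5in_4out, taxa, max_exceptions=3
        )
        assert (rank, label) == ("genus", "Gsub")

    def test_membership_restricted_to_alignment_taxa(self, manifest_5in_4out):
        # A5 missing from the alignment is missing data, not an exception
        carriers = frozenset({"A1", "A2", "A3", "A4"})
        taxa = ["A1", "A2", "A3", "A4", "O1", "O2"]
        rank, label, exc = match_clade_pattern(
            block_of(carriers), manifest_5in_4out, taxa, max_exceptions=0
        )
        assert (rank, label, exc) == ("class", "In", ())


def block_of(carriers):
    return IndelBlock(0, 1, "insertion", {}, frozenset(carriers))


class TestExtractSegment:
    def make_family(self, ref_len=400, block_at=150, block_len=3):
        rng = random.Random(7)
        base = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(ref_len))
        ins = "W" * block_len
        rows = [
            ("A1", base[:block_at] + ins + base[block_at:]),
            ("A2", base[:block_at] + ins + base[block_at:]),
            ("O1", base[:block_at] + "-" * block_len + base[block_at:]),
            ("O2", base[:block_at] + "-" * block_len + base[block_at:]),
        ]
        aln = Alignment(rows)
        man = two_clade_manifest(2, 2)
        block = find_indel_blocks(aln, classify_columns(aln, man), man)[0]
        return aln, block

    def test_centering_arithmetic(self):
        aln, block = self.make_family()
        seg = extract_signature_segment(aln, block, "A1", target_len=80)
        # block residues sit at ungapped 151..153 of the reference; an 80 aa
        # window centered there spans ~112..191
        assert len(seg.residues) == 80
        start, end = map(int, seg.description.split("region=")[1].split(" ")[0].split("-"))
        assert start <= 151 and end >= 153
        assert abs((start + end) / 2 - 152) <= 1

    def test_clamped_near_sequence_start(self):
        aln, block = self.make_family(block_at=3)
        seg = extract_signature_segment(aln, block, "A1", target_len=80)
        start, end = map(int, seg.description.split("region=")[1].split(" ")[0].split("-"))
        assert start == 1 and end == 80 and len(seg.residues) == 80

    def test_short_reference_whole_sequence(self, caplog):
        aln, block = self.make_family(ref_len=47, block_at=20)
        with caplog.at_level("WARNING", logger="sigscan.csi"):
            seg = extract_signature_segment(aln, block, "A1", target_len=80)
        assert len(seg.residues) == 50  # 47 + 3 inserted
        assert any("whole sequence" in r.message for r in caplog.records)


class TestDetectCsis:
    def test_planted_insertion_recovered(self, manifest_5in_4out):
        aln = flanked_alignment(n_in=5, n_out=4, insert="WWW", flank=12)
        recs = detect_csis(aln, manifest_5in_4out)
        assert len(recs) == 1
        r = recs[0]
        assert (r.indel_type, r.size_min, r.size_max) == ("insertion", 3, 3)
        assert (r.clade_rank, r.clade_label, r.exceptions) == ("class", "In", ())

    def test_no_exclusive_columns_gives_empty(self, manifest_5in_4out):
        rows = [(t, "ACDEFGHIKL") for t in manifest_5in_4out.known_taxa]
        recs = detect_csis(Alignment(rows), manifest_5in_4out)
        assert recs == []

    def test_insufficient_taxa_errors(self):
        man = two_clade_manifest(1, 2)
        aln = Alignment([("A1", "AAA"), ("O1", "AAA"), ("O2", "AAA")])
        with pytest.raises(ValueError, match="insufficient taxa"):
            detect_csis(aln, man)

    def test_row_order_permutation_invariance(self, manifest_5in_4out):
        aln = flanked_alignment(n_in=5, n_out=4, insert="QQ", flank=8)
        base = detect_csis(aln, manifest_5in_4out, reference_taxon="A1")
        rng = random.Random(3)
        rows = aln.rows
        for _ in range(5):
            rng.shuffle(rows)
            shuffled = detect_csis(
                Alignment(rows), manifest_5in_4out, reference_taxon="A1"
            )
            assert set(shuffled) == set(base)

    def test_monotone_in_F_and_exceptions(self, manifest_5in_4out):
        aln = flanked_alignment(n_in=5, n_out=4, insert="DD", flank=6, exception="A5")
        counts = []
        for F in (3, 5, 6):
            fp = FlankParams(min_conserved=F)
            counts.append(
                len(detect_csis(aln, manifest_5in_4out, flank_params=fp, max_exceptions=1))
            )
        assert counts == sorted(counts, reverse=True)
        n1 = len(detect_csis(aln, manifest_5in_4out, max_exceptions=1,
                             flank_params=FlankParams(min_conserved=5)))
        n0 = len(detect_csis(aln, manifest_5in_4out, max_exceptions=0,
                             flank_params=FlankParams(min_conserved=5)))
        assert n0 <= n1


class TestSignatureReport:
    def build(self, manifest_5in_4out):
        aln = flanked_alignment(n_in=5, n_out=4, insert="WWW", flank=10)
        rec = detect_csis(aln, manifest_5in_4out)[0]
        return aln, rec

    def test_identity_dashes_and_gap_placeholders(self, manifest_5in_4out):
        aln, rec = self.build(manifest_5in_4out)
        report = format_signature_report(rec, aln, manifest_5in_4out)
        body = [ln for ln in report.splitlines() if not ln.startswith("#")]
        # every non-reference in-group row identical to reference: all dashes
        a2 = next(ln for ln in body if ln.startswith("A2"))
        assert set(a2.split()[-1]) == {"-"}
        o1 = next(ln for ln in body if ln.startswith("O1"))
        assert o1.split()[-1].count(".") == 3  # gap placeholders at the insert

    def test_in_clade_rows_first_and_header_coordinates(self, manifest_5in_4out):
        aln, rec = self.build(manifest_5in_4out)
        report = format_signature_report(rec, aln, manifest_5in_4out)
        names = [ln.split()[0] for ln in report.splitlines() if not ln.startswith("#")]
        assert names[:5] == ["A1", "A2", "A3", "A4", "A5"]
        header = report.splitlines()[1]
        assert f"{rec.region_start}–{rec.region_end}" in header

    def test_round_trip_reproduces_residues(self, manifest_5in_4out):
        aln, rec = self.build(manifest_5in_4out)
        report = format_signature_report(rec, aln, manifest_5in_4out)
        expanded = expand_signature_rows(report)
        cols = range(rec.region_col_start, rec.region_col_end)
        for taxon, got in expanded.items():
            original = "".join(aln.row(taxon)[c] for c in cols)
            assert got == original, taxon


class TestSpecificity:
    def build(self):
        man = two_clade_manifest(3, 2)
        rng = random.Random(17)
        base = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(300))
        ins = "WKY"
        at = 150
        rows = [(f"A{i}", base[:at] + ins + base[at:]) for i in (1, 2, 3)]
        rows += [(f"O{i}", base[:at] + "---" + base[at:]) for i in (1, 2)]
        aln = Alignment(rows)
        rec = detect_csis(aln, man)[0]
        states = classify_columns(aln, man)
        block = find_indel_blocks(aln, states, man)[0]
        carrier_seq = (base[:at] + ins + base[at:])
        lacker_seq = base
        return man, aln, rec, block, carrier_seq, lacker_seq

    def hit(self, subject_id, taxon, bitscore=500.0):
        return HitRecord(
            "q", subject_id, 99.0, 100, 1, 0, 1, 100, 1, 100, 1e-50, bitscore, taxon
        )

    def test_all_in_clade_carriers_pass(self):
        man, aln, rec, block, carrier, _ = self.build()
        hits = HitTable([self.hit("A1|p", "A1"), self.hit("A2|p", "A2")])
        subjects = {
            "A1|p": SequenceRecord("A1|p", carrier),
            "A2|p": SequenceRecord("A2|p", carrier),
        }
        res = validate_specificity(rec, block, aln, hits, subjects, man)
        assert res.passed and res.n_checked == 2

    def test_out_clade_carrier_is_violation(self):
        man, aln, rec, block, carrier, _ = self.build()
        hits = HitTable([self.hit("O9|p", "O9")])
        man.entries["O9"] = {"class": "Out"}
        subjects = {"O9|p": SequenceRecord("O9|p", carrier)}
        res = validate_specificity(rec, block, aln, hits, subjects, man)
        assert not res.passed
        assert res.violations[0][0] == "O9|p"

    def test_in_clade_lacker_is_violation_unless_excepted(self):
        man, aln, rec, block, _, lacker = self.build()
        hits = HitTable([self.hit("A3|p", "A3")])
        subjects = {"A3|p": SequenceRecord("A3|p", lacker)}
        res = validate_specificity(rec, block, aln, hits, subjects, man)
        assert not res.passed
        from dataclasses import replace

        rec2 = replace(rec, exceptions=("A3",))
        res2 = validate_specificity(rec2, block, aln, hits, subjects, man)
        assert res2.passed

    def test_missing_subject_recorded_unevaluated(self):
        man, aln, rec, block, carrier, _ = self.build()
        hits = HitTable([self.hit("A1|p", "A1"), self.hit("gone|p", "A2", 400.0)])
        subjects = {"A1|p": SequenceRecord("A1|p", carrier)}
        res = validate_specificity(rec, block, aln, hits, subjects, man)
        assert res.passed
        assert "gone|p" in res.unevaluated

    def test_carrier_test_direct(self):
        man, aln, rec, block, carrier, lacker = self.build()
        seg = extract_signature_segment(aln, block, "A1")
        start = int(seg.description.split("region=")[1].split(" ")[0].split("-")[0])
        from sigscan.csi import _segment_indel_offset

        offsets = _segment_indel_offset(aln, block, "A1", start)
        assert subject_carries_indel(
            seg, offsets, "insertion", (3, 3), SequenceRecord("s", carrier)
        )
        assert not subject_carries_indel(
            seg, offsets, "insertion", (3, 3), SequenceRecord("s", lacker)
        )
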