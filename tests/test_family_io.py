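"""Membership-table I/O and the name-grammar codec."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panfam import (
    AssignedName,
    MemberRecord,
    NameStatus,
    NameStyle,
    format_name,
    parse_name,
    read_membership,
    write_membership,
)
from panfam.errors import (
    MembershipFormatError,
    NameFormatError,
    NameGrammarError,
    PanfamError,
    UnknownMemberError,
)

HEADER = "accession\tgene_id\tchromosome\tstart\tend\tstrand\tclade\n"


def _write(tmp_path, body, header=HEADER):
    p = tmp_path / "members.tsv"
    p.write_text(header + body)
    return p


class TestReadMembership:
    def test_minimal_row(self, tmp_path):
        path = _write(tmp_path, "A1\tg1\t2\t100\t900\t+\t\n")
        (rec,) = read_membership(path)
        assert rec == MemberRecord("A1", "g1", 2, 100, 900, strand="+")

    @pytest.mark.parametrize("token", ["0", "Un", "", "chrUn"])
    def test_unplaced_tokens_normalised(self, tmp_path, token):
        path = _write(tmp_path, f"A1\tg1\t{token}\t1\t9\t\t\n")
        assert read_membership(path)[0].chromosome == 0

    def test_missing_column_named(self, tmp_path):
        path = _write(
            tmp_path, "A1\tg1\t2\t1\n", header="accession\tgene_id\tchromosome\tstart\n"
        )
        with pytest.raises(MembershipFormatError, match="end"):
            read_membership(path)

    def test_bad_chromosome_reports_line(self, tmp_path):
        path = _write(
            tmp_path, "A1\tg1\t2\t1\t9\t\t\nA1\tg2\tX\t1\t9\t\t\n"
        )
        with pytest.raises(MembershipFormatError, match="line 3"):
            read_membership(path)

    def test_non_integer_coordinate_reports_line(self, tmp_path):
        path = _write(tmp_path, "A1\tg1\t2\tfoo\t9\t\t\n")
        with pytest.raises(MembershipFormatError, match="line 2"):
            read_membership(path)

    def test_underscore_accession_rejected(self, tmp_path):
        path = _write(tmp_path, "A_1\tg1\t2\t1\t9\t\t\n")
        with pytest.raises(MembershipFormatError, match="_"):
            read_membership(path)

    def test_order_and_count_preserved_roundtrip(self, tmp_path, sisrs_members):
        path = tmp_path / "fixture.tsv"
        write_membership(sisrs_members, path)
        back = read_membership(path)
        assert len(back) == len(sisrs_members) == 678
        assert [m.gene_id for m in back] == [m.gene_id for m in sisrs_members]
        assert back == [
            m for m in sisrs_members
        ]  # all fields survive the round trip


class TestNameGrammar:
    """Parse/format against the inferred SiSRS profile (x per clade: 2,2,3,4,5,6)."""

    @pytest.mark.parametrize(
        "text, N, n, x, y, status",
        [
            ("Q13_SiSRS3.1_3D3", 3, 1, 3, 3, NameStatus.DUPLICATE),
            ("Q13_SiSRS6.1_6D6", 6, 1, 6, 6, NameStatus.DUPLICATE),
            ("C26_SiSRS6_6T1", 6, 0, 6, 1, NameStatus.CORE_TRANSLOCATED),
            ("L10_SiSRS3.1_3D8", 3, 1, 3, 8, NameStatus.DUPLICATE),
            ("L34_SiSRS1_2", 1, 0, 2, 2, NameStatus.CORE_IN_PLACE),
            # suffix omitted: resolved from the profile
            ("L34_SiSRS1", 1, 0, 2, 2, NameStatus.CORE_IN_PLACE),
            ("Q13_SiSRS3.1_3", 3, 1, 3, 3, NameStatus.DUPLICATE),
            ("C16_SiSRS2.1_2D0", 2, 1, 2, 0, NameStatus.UNPLACED_DUPLICATE),
        ],
    )
    def test_parse_published_forms(self, sisrs_profile, text, N, n, x, y, status):
        nm = parse_name(text, sisrs_profile)
        assert (nm.core_index, nm.copy_ordinal) == (N, n)
        assert (nm.expected_chrom, nm.actual_chrom) == (x, y)
        assert nm.status is status

    @pytest.mark.parametrize(
        "fields, style, expected",
        [
            (("L10", 3, 1, 3, 8, NameStatus.DUPLICATE), NameStyle.FULL, "L10_SiSRS3.1_3D8"),
            (("Q13", 6, 1, 6, 6, NameStatus.DUPLICATE), NameStyle.SHORT, "Q13_SiSRS6.1_6"),
            (("Q13", 6, 1, 6, 6, NameStatus.DUPLICATE), NameStyle.MINIMAL, "Q13_SiSRS6.1"),
            (("L34", 1, 0, 2, 2, NameStatus.CORE_IN_PLACE), NameStyle.FULL, "L34_SiSRS1_2"),
            (("L34", 1, 0, 2, 2, NameStatus.CORE_IN_PLACE), NameStyle.MINIMAL, "L34_SiSRS1"),
            (("C26", 6, 0, 6, 1, NameStatus.CORE_TRANSLOCATED), NameStyle.FULL, "C26_SiSRS6_6T1"),
        ],
    )
    def test_format_published_forms(self, fields, style, expected):
        acc, N, n, x, y, status = fields
        nm = AssignedName(acc, "SiSRS", N, n, x, y, status)
        assert format_name(nm, style) == expected

    def test_out_of_range_core_index(self, sisrs_profile):
        with pytest.raises(UnknownMemberError):
            parse_name("L34_SiSRS9", sisrs_profile)

    @pytest.mark.parametrize(
        "bad",
        [
            "L34_SiSRS1_2D",  # malformed suffix: no y
            "L34_SiSRS1_2X3",  # unknown connector
            "L34_SiSRS1_2D3",  # D suffix on a core instance (no ordinal)
            "L34_SiSRS1.1_2T3",  # T suffix on an additional copy
            "L34_SiSRS1_2T2",  # transfer to the expected chromosome
            "L34_SiSRS1_5",  # bare x contradicting the profile locus
            "L34SiSRS1",  # missing delimiter
            "L34_SiSRS",  # no core index
            "L34_SiSRS1_2_3",  # too many fields
        ],
    )
    def test_grammar_errors(self, sisrs_profile, bad):
        with pytest.raises(NameGrammarError):
            parse_name(bad, sisrs_profile)

    def test_minimal_refused_for_translocated_core(self):
        nm = AssignedName("C26", "SiSRS", 6, 0, 6, 1, NameStatus.CORE_TRANSLOCATED)
        with pytest.raises(NameFormatError):
            format_name(nm, NameStyle.MINIMAL)

    def test_minimal_refused_for_dispersed_duplicate(self):
        nm = AssignedName("L10", "SiSRS", 3, 1, 3, 8, NameStatus.DUPLICATE)
        with pytest.raises(NameFormatError):
            format_name(nm, NameStyle.MINIMAL)

    def test_invariant_violating_fields_rejected(self):
        with pytest.raises(NameFormatError):
            AssignedName("A", "SiSRS", 1, 0, 2, 5, NameStatus.CORE_IN_PLACE)
        with pytest.raises(NameFormatError):
            AssignedName("A", "SiSRS", 1, 0, 2, 3, NameStatus.DUPLICATE)


def _valid_names(profile):
    """All valid field combinations: status x ordinal 0..3 x chromosome 0..9."""
    for N in profile.indices:
        x = profile.expected_chrom(N)
        for n, y in itertools.product(range(4), range(10)):
            if n == 0:
                if y == x:
                    status = NameStatus.CORE_IN_PLACE
                elif y == 0:
                    status = NameStatus.UNPLACED_CORE
                else:
                    status = NameStatus.CORE_TRANSLOCATED
            else:
                status = (
                    NameStatus.DUPLICATE if y >= 1 else NameStatus.UNPLACED_DUPLICATE
                )
            yield AssignedName("A9", "SiSRS", N, n, x, y, status)


class TestRoundTrip:
    def test_full_style_roundtrip_exhaustive(self, sisrs_profile):
        for nm in _valid_names(sisrs_profile):
            assert parse_name(format_name(nm, NameStyle.FULL), sisrs_profile) == nm

    def test_short_style_roundtrip_exhaustive(self, sisrs_profile):
        for nm in _valid_names(sisrs_profile):
            assert parse_name(format_name(nm, NameStyle.SHORT), sisrs_profile) == nm

    @settings(derandomize=True, max_examples=400)
    @given(
        st.text(alphabet="QLC0123456789._DTSiRS_", min_size=0, max_size=18)
    )
    def test_grammar_totality_fuzz(self, sisrs_profile, text):
        """Arbitrary strings either raise a grammar error or parse to a name
        that re-renders (in some style) to exactly the input: no silent
        misparses."""
        try:
            nm = parse_name(text, sisrs_profile)
        except PanfamError:
            return
        renderings = set()
        for style in NameStyle:
            try:
                renderings.add(format_name(nm, style))
            except NameFormatError:
                pass
        assert text in renderings
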