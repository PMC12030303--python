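"""Alignment identity, clade assignment, and core-profile inference."""

import itertools
import random

import numpy as np
import pytest

from panfam import (
    AlignmentScoring,
    MemberRecord,
    assign_clades,
    global_identity,
    infer_core_profile,
    read_profile,
    write_profile,
)
from panfam.errors import (
    DegenerateInputError,
    EmptyProfileError,
    UnassignableError,
    UnresolvedLocusError,
)
from panfam.family_io import UNASSIGNED
from panfam.simulate import AMINO_ACIDS

from _oracles import oracle_identity

DEFAULT = AlignmentScoring()
ALT = AlignmentScoring(match_score=2, mismatch_score=-1, gap_score=-2)


class TestGlobalIdentity:
    def test_identical_sequences(self):
        assert global_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_single_substitution(self):
        # optimum has 3 matches over 4 columns (exhaustive enumeration
        # confirms no gapped alignment scores higher)
        assert global_identity("ACGT", "ACGA") == 0.75

    def test_single_mismatch_pair(self):
        assert global_identity("A", "G") == 0.0

    def test_symmetry(self):
        rng = random.Random(0)
        for _ in range(30):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
            assert global_identity(a, b) == global_identity(b, a)

    def test_empty_sequence_rejected(self):
        with pytest.raises(DegenerateInputError):
            global_identity("", "ACGT")

    @pytest.mark.parametrize("scoring", [DEFAULT, ALT], ids=["default", "alt"])
    def test_matches_enumeration_oracle_short(self, scoring):
        """Exhaustive two-letter pairs up to length 4 agree with the
        brute-force alignment-enumeration oracle."""
        strings = [
            "".join(s)
            for n in range(1, 5)
            for s in itertools.product("AB", repeat=n)
        ]
        for a in strings:
            for b in strings:
                expected = oracle_identity(
                    a, b, scoring.match_score, scoring.mismatch_score,
                    scoring.gap_score,
                )
                assert global_identity(a, b, scoring) == pytest.approx(expected)

    def test_matches_enumeration_oracle_sampled(self):
        """Seeded longer two-letter pairs (length 5-6) agree with the oracle."""
        rng = random.Random(42)
        for _ in range(120):
            a = "".join(rng.choice("AB") for _ in range(rng.randint(5, 6)))
            b = "".join(rng.choice("AB") for _ in range(rng.randint(5, 6)))
            expected = oracle_identity(a, b, 1.0, 0.0, -1.0)
            assert global_identity(a, b) == pytest.approx(expected)


def _member(acc, gene, chrom, start, clade=None, seq=None):
    return MemberRecord(acc, gene, chrom, start, start + 99,
                        clade_label=clade, sequence=seq)


class TestAssignClades:
    REPS = {1: "MKLVNNAGITRDNLLMRM", 2: "MSTDLFGHIKAPQRWYEV", 3: "MGGACCAGGTTTACCAAC"}

    def test_exact_match_assigns_with_full_identity(self):
        m = _member("A1", "g1", 3, 10, seq=self.REPS[3])
        (out,) = assign_clades([m], self.REPS)
        assert out.clade_label == 3

    def test_below_threshold_is_unassigned(self):
        m = _member("A1", "g1", 3, 10, seq="WWWWWWWWWWWWWWWWWW")
        (out,) = assign_clades([m], self.REPS)
        assert out.clade_label == UNASSIGNED

    def test_labeled_members_pass_through(self):
        m = _member("A1", "g1", 3, 10, clade=2)
        assert assign_clades([m], self.REPS) == [m]

    def test_missing_label_and_sequence_is_an_error(self):
        with pytest.raises(UnassignableError, match="g1"):
            assign_clades([_member("A1", "g1", 3, 10)], self.REPS)

    def test_mutated_members_recover_their_source(self):
        """Point-mutated copies (rate 0.05) are assigned back to the
        representative they came from; cross-checked by brute-forcing all
        pairwise identities."""
        rng = np.random.default_rng(11)
        reps = {
            c: "".join(rng.choice(list(AMINO_ACIDS), size=40))
            for c in (1, 2, 3)
        }
        members, truth = [], []
        for i in range(6):
            src = 1 + i % 3
            seq = "".join(
                rng.choice([x for x in AMINO_ACIDS if x != ch])
                if rng.random() < 0.05
                else ch
                for ch in reps[src]
            )
            members.append(_member("A1", f"g{i}", 1, 10 + i, seq=seq))
            truth.append(src)
        out = assign_clades(members, reps)
        assert [m.clade_label for m in out] == truth
        for m, src in zip(members, truth):
            identities = {
                c: global_identity(m.sequence, reps[c]) for c in reps
            }
            assert max(identities, key=identities.get) == src


def _profile_members(presence, n_acc=10):
    """One clade per (label, chrom) with given per-accession presence."""
    members = []
    for a in range(n_acc):
        acc = f"A{a}"
        for label, frac in presence.items():
            if a < round(frac * n_acc):
                members.append(
                    _member(acc, f"{acc}.g{label}", label, label * 1000,
                            clade=label)
                )
    return members


class TestInferCoreProfile:
    def test_single_accession_all_core(self):
        members = [
            _member("A1", f"g{c}", c, c * 1000, clade=c) for c in (1, 2, 3)
        ]
        profile = infer_core_profile(members)
        assert profile.k == 3
        assert all(c.presence_fraction == 1.0 for c in profile.core_clades)

    def test_threshold_excludes_rare_clade(self):
        members = _profile_members({1: 1.0, 2: 0.4})
        profile = infer_core_profile(members, presence_threshold=0.8)
        assert [c.source_label for c in profile.core_clades] == [1]

    def test_indices_ordered_by_chrom_then_start(self):
        # two clades on chromosome 1, ordered by median start
        members = []
        for a in range(4):
            members.append(_member(f"A{a}", f"A{a}.x", 1, 9000, clade=7))
            members.append(_member(f"A{a}", f"A{a}.y", 1, 100, clade=8))
            members.append(_member(f"A{a}", f"A{a}.z", 2, 50, clade=9))
        profile = infer_core_profile(members)
        assert [c.source_label for c in profile.core_clades] == [8, 7, 9]
        assert profile.index_for_label(8) == 1

    def test_invariant_to_member_order(self, sisrs_members, sisrs_profile):
        rng = random.Random(5)
        shuffled = list(sisrs_members)
        rng.shuffle(shuffled)
        assert infer_core_profile(shuffled) == sisrs_profile

    def test_raising_threshold_never_enlarges_core(self):
        members = _profile_members({1: 1.0, 2: 0.9, 3: 0.6, 4: 0.3})
        previous = None
        for threshold in (0.2, 0.5, 0.8, 0.95):
            labels = {
                c.source_label
                for c in infer_core_profile(
                    members, presence_threshold=threshold
                ).core_clades
            }
            if previous is not None:
                assert labels <= previous
            previous = labels

    def test_modal_chromosome_tie_is_an_error(self):
        members = [
            _member("A1", "g1", 1, 100, clade=1),
            _member("A2", "g2", 2, 100, clade=1),
        ]
        with pytest.raises(UnresolvedLocusError):
            infer_core_profile(members)

    def test_no_core_clade_is_an_error(self):
        # every accession carries only a private clade -> presence 0.1 each
        members = [
            _member(f"A{a}", f"A{a}.g", 1, 100 + a, clade=a + 1)
            for a in range(10)
        ]
        with pytest.raises(EmptyProfileError):
            infer_core_profile(members, presence_threshold=0.8)

    def test_duplicated_instances_do_not_shift_the_locus(self):
        # clade 1 duplicated onto chromosome 9 in most accessions; the
        # expected chromosome still comes from single-copy instances
        members = []
        for a in range(10):
            acc = f"A{a}"
            members.append(_member(acc, f"{acc}.a", 1, 100, clade=1))
            if a < 8:
                members.append(_member(acc, f"{acc}.b", 9, 100, clade=1))
        profile = infer_core_profile(members)
        assert profile.expected_chrom(1) == 1

    def test_profile_roundtrip_through_text_file(self, tmp_path, sisrs_profile):
        path = tmp_path / "profile.tsv"
        write_profile(sisrs_profile, path)
        assert read_profile(path) == sisrs_profile
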