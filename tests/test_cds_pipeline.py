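"""Global alignment, CDS verification, labeling, splitting, balancing."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phoskan.cds_pipeline import (
    ScoringScheme,
    SiteRecord,
    balance_undersample,
    extract_cds_from_genbank,
    label_sites,
    needleman_wunsch,
    reverse_translate,
    split_by_protein,
    verify_and_strip,
)
from phoskan.errors import FrameError, PhosKANError, VerificationFailure

from conftest import (
    TOY_GENBANK_JOIN,
    TOY_GENBANK_NO_CDS,
    TOY_GENBANK_ONE_CDS,
    TOY_GENBANK_TWO_CDS,
)


def brute_force_best_score(a, b, scoring):
    """Independent oracle: exhaustive recursion over all global alignments."""
    if not a and not b:
        return 0.0
    options = []
    if a and b:
        sub = scoring.match if a[0] == b[0] else scoring.mismatch
        options.append(sub + brute_force_best_score(a[1:], b[1:], scoring))
    if a:
        options.append(scoring.gap + brute_force_best_score(a[1:], b, scoring))
    if b:
        options.append(scoring.gap + brute_force_best_score(a, b[1:], scoring))
    return max(options)


class TestNeedlemanWunsch:
    def test_worked_example(self):
        res = needleman_wunsch("MST", "MGT",
                               ScoringScheme(match=1, mismatch=-1, gap=-2))
        assert res.score == 1
        assert res.identity_percent == pytest.approx(100 * 2 / 3, abs=0.01)

    def test_identical_sequences(self):
        res = needleman_wunsch("MSTY", "MSTY")
        assert res.identity_percent == 100.0
        assert res.score == 4.0

    def test_empty_conventions(self):
        scoring = ScoringScheme()
        allgap = needleman_wunsch("MSTY", "", scoring)
        assert allgap.identity_percent == 0.0
        assert allgap.score == 4 * scoring.gap
        both = needleman_wunsch("", "", scoring)
        assert both.score == 0.0 and both.identity_percent == 100.0

    def test_matches_bruteforce_on_all_short_pairs(self):
        # DP optimum equals exhaustive alignment enumeration for every
        # pair of sequences of length <= 4 over a 3-letter alphabet
        scoring = ScoringScheme(match=1, mismatch=-1, gap=-2)
        alphabet = "ABC"
        seqs = [
            "".join(t)
            for n in range(5)
            for t in itertools.product(alphabet, repeat=n)
        ]
        for a in seqs:
            for b in seqs:
                res = needleman_wunsch(a, b, scoring)
                assert res.score == brute_force_best_score(a, b, scoring), (
                    a, b)

    @settings(max_examples=100, deadline=None)
    @given(st.text(alphabet="ACDE", max_size=8),
           st.text(alphabet="ACDE", max_size=8))
    def test_alignment_invariants(self, a, b):
        res = needleman_wunsch(a, b)
        assert len(res.aligned_a) == len(res.aligned_b)
        assert res.aligned_a.replace("-", "") == a
        assert res.aligned_b.replace("-", "") == b
        assert (res.identity_percent == 100.0) == (a == b)

    def test_score_agrees_with_biopython(self):
        from Bio.Align import PairwiseAligner

        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = aligner.extend_gap_score = -2
        rng = np.random.default_rng(0)
        for _ in range(30):
            a = "".join(rng.choice(list("MSTYA"), rng.integers(1, 10)))
            b = "".join(rng.choice(list("MSTYA"), rng.integers(1, 10)))
            ours = needleman_wunsch(a, b, ScoringScheme(1, -1, -2))
            assert ours.score == aligner.score(a, b)


class TestGenBankExtraction:
    def test_single_cds(self):
        out = extract_cds_from_genbank(TOY_GENBANK_ONE_CDS)
        assert out == [("ATGTCATAA", "MS")]

    def test_two_cds_features(self):
        out = extract_cds_from_genbank(TOY_GENBANK_TWO_CDS)
        assert len(out) == 2
        assert out[0] == ("ATGTCATAA", "MS")
        assert out[1] == ("ATGACTTGA", "MT")

    def test_join_location_is_spliced(self):
        # manual splice of the ORIGIN block: 3..8 + 15..20
        origin = "ccatgtcaggttttacgggtcccc".upper()
        expected = origin[2:8] + origin[14:20]
        out = extract_cds_from_genbank(TOY_GENBANK_JOIN)
        assert out == [(expected, "MSTG")]

    def test_no_cds_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert extract_cds_from_genbank(TOY_GENBANK_NO_CDS) == []


class TestVerifyAndStrip:
    def test_accepts_and_strips_terminal_stop(self):
        rec = verify_and_strip("ATGTCATAA", "MS", protein_id="p")
        assert rec.cds_seq == "ATGTCA"
        assert len(rec.cds_seq) == 3 * len(rec.protein_seq)
        assert rec.identity_percent == 100.0

    def test_accepts_cds_without_stop(self):
        rec = verify_and_strip("ATGTCA", "MS")
        assert rec.cds_seq == "ATGTCA"

    def test_rejects_mismatch_with_identity(self):
        with pytest.raises(VerificationFailure) as exc:
            verify_and_strip("ATGTCA", "MT")
        assert exc.value.reason == "identity_below_100"
        assert exc.value.identity_percent == 50.0

    def test_rejects_internal_stop(self):
        with pytest.raises(VerificationFailure) as exc:
            verify_and_strip("ATGTGATCA", "MS")
        assert exc.value.reason == "internal_stop"

    def test_frame_error(self):
        with pytest.raises(FrameError):
            verify_and_strip("ATGTC", "MS")

    def test_reverification_idempotent(self, small_study):
        # any record accepted once passes against its own protein again
        for pid in list(small_study.proteins)[:5]:
            rec = verify_and_strip(small_study.cds[pid],
                                   small_study.proteins[pid], protein_id=pid)
            again = verify_and_strip(rec.cds_seq, rec.protein_seq)
            assert again.cds_seq == rec.cds_seq


class TestReverseTranslate:
    def test_round_trip_loses_no_records(self, small_study, tmp_path):
        from phoskan.toydata import generate_toy_study

        generate_toy_study(small_study.spec, out_dir=tmp_path)
        records = {pid: str(tmp_path / "genbank" / f"{pid}.gb")
                   for pid in small_study.proteins}
        accepted, report = reverse_translate(small_study.proteins, records)
        assert len(accepted) == len(small_study.proteins)
        assert report.empty
        for rec in accepted:
            assert len(rec.cds_seq) == 3 * len(rec.protein_seq)

    def test_missing_record_reported(self):
        accepted, report = reverse_translate({"p1": "MS"}, {})
        assert not accepted
        assert report.iloc[0]["reason"] == "no_genbank_record"


class TestLabelSites:
    def test_exhaustive_enumeration(self):
        sites = label_sites("p", "MSTYS", {2})
        assert [(s.position, s.residue, s.label) for s in sites] == [
            (2, "S", "P"), (3, "T", "NP"), (4, "Y", "NP"), (5, "S", "NP"),
        ]

    def test_annotation_on_non_sty_rejected(self):
        with pytest.raises(PhosKANError):
            label_sites("p", "MSTYS", {1})

    def test_no_candidate_residues(self):
        assert label_sites("p", "MGAL", set()) == []

    def test_every_sty_appears_exactly_once(self, small_study):
        for pid, seq in small_study.proteins.items():
            positions = [s.position for s in small_study.sites
                         if s.protein_id == pid]
            expected = [i + 1 for i, c in enumerate(seq) if c in "STY"]
            assert sorted(positions) == expected


class TestSplitsAndBalancing:
    def test_nine_to_one(self):
        ids = [f"p{i}" for i in range(10)]
        split = split_by_protein(ids, ratio=0.9, seed=0)
        assert len(split.train_ids) == 9 and len(split.test_ids) == 1

    @pytest.mark.parametrize("seed", [0, 1, 42])
    def test_partition_properties(self, seed):
        ids = [f"p{i}" for i in range(17)]
        split = split_by_protein(ids, ratio=0.8, seed=seed)
        assert split.train_ids | split.test_ids == set(ids)
        assert not split.train_ids & split.test_ids
        again = split_by_protein(ids, ratio=0.8, seed=seed)
        assert again.train_ids == split.train_ids

    def test_too_few_ids(self):
        with pytest.raises(PhosKANError):
            split_by_protein(["only"], 0.9, 0)

    def _sites(self, n_pos, n_neg):
        return [SiteRecord("p", i + 1, "S", "P") for i in range(n_pos)] + [
            SiteRecord("q", i + 1, "S", "NP") for i in range(n_neg)
        ]

    def test_undersampling_balances(self):
        out = balance_undersample(self._sites(5, 20), seed=0)
        assert sum(s.label == "P" for s in out) == 5
        assert sum(s.label == "NP" for s in out) == 5

    def test_already_balanced_unchanged(self):
        sites = self._sites(5, 5)
        assert balance_undersample(sites, seed=0) == sites

    def test_negatives_are_a_subset(self):
        sites = self._sites(3, 12)
        out = balance_undersample(sites, seed=1)
        in_neg = {(s.protein_id, s.position) for s in sites if s.label == "NP"}
        for s in out:
            if s.label == "NP":
                assert (s.protein_id, s.position) in in_neg

    def test_single_class_rejected(self):
        with pytest.raises(PhosKANError):
            balance_undersample(self._sites(5, 0), seed=0)
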