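import itertools
import math

import numpy as np
import pytest

from suspect._tables import AA_ALPHABET, AA_INDEX
from suspect.conservation import (
    MSA,
    PSSM,
    MsaRow,
    SENTINEL_EVALUE,
    compute_pssm_from_msa,
    divergence_features,
    gap_fraction,
    js_divergence,
    percent_identity,
    pfam_emission_delta,
    pssm_features,
    read_msa,
    read_psiblast_pssm,
    write_psiblast_pssm,
)
from suspect.core import SAV
from suspect.errors import BoundsError, FormatError, ParseError, ValidationError

UNIFORM = np.full(20, 0.05)


class TestMsaIO:
    def test_read_with_evalues(self, tmp_path):
        p = tmp_path / "m.afa"
        p.write_text(">q\nACDEFGHIKL\n>s2 evalue=1e-30\nACDEFGHIKL\n>s3\nAC-EFGHIKL\n")
        msa = read_msa(p)
        assert msa.n_rows == 3 and msa.n_columns == 10
        assert msa.rows[1].evalue == 1e-30 and msa.rows[2].evalue is None

    def test_ragged_alignment_rejected(self, tmp_path):
        p = tmp_path / "m.afa"
        p.write_text(">q\nACDEFGHIKL\n>s\nACDEFGHIK\n")
        with pytest.raises(FormatError):
            read_msa(p)

    def test_insert_columns_dropped_from_mapping(self):
        msa = MSA([MsaRow("q", "AC-EF"), MsaRow("s", "ACDEF", 1e-5)])
        assert msa.query_columns() == [0, 1, 3, 4]
        assert msa.column_for_position(3) == 3  # third query residue is E


class TestPssmIO:
    def test_reorders_psiblast_column_order(self, tmp_path):
        order = "ARNDCQEGHILKMFPSTWYV"
        vals = {aa: i for i, aa in enumerate(order)}  # A->0 ... V->19
        row = " ".join(str(vals[aa]) for aa in order)
        zeros = " ".join("0" for _ in range(20))
        p = tmp_path / "p.pssm"
        p.write_text(
            "header line one\n"
            + "    " + "  ".join(order) + "  " + "  ".join(order) + "\n"
            + f"1 M {row} {zeros}\n"
        )
        pssm = read_psiblast_pssm(p)
        assert pssm.score(1, "A") == 0 and pssm.score(1, "V") == 19
        assert pssm.score(1, "R") == 1  # second column of the file

    def test_truncated_row_is_parse_error(self, tmp_path):
        p = tmp_path / "p.pssm"
        p.write_text("1 M " + " ".join("0" for _ in range(39)) + "\n")
        with pytest.raises(ParseError, match=":1"):
            read_psiblast_pssm(p)

    def test_query_length_mismatch(self, tmp_path):
        pssm = PSSM(np.zeros((2, 20)))
        p = tmp_path / "p.pssm"
        write_psiblast_pssm(pssm, "MK", p)
        with pytest.raises(FormatError, match="query length"):
            read_psiblast_pssm(p, query="MKV")

    def test_write_read_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        pssm = PSSM(np.round(rng.normal(size=(4, 20)), 2))
        p = tmp_path / "p.pssm"
        write_psiblast_pssm(pssm, "MKVA", p)
        back = read_psiblast_pssm(p, query="MKVA")
        np.testing.assert_allclose(back.scores, pssm.scores, atol=1e-9)


class TestPssmFeatures:
    def test_wt_to_mut_delta(self):
        scores = np.zeros((3, 20))
        scores[1, AA_INDEX["C"]] = 2.0
        scores[1, AA_INDEX["G"]] = -1.0
        feats = pssm_features(PSSM(scores), SAV("P43246", 2, "C", "G"))
        assert feats == {"wt_score": 2.0, "mut_score": -1.0, "delta": 3.0}

    def test_delta_antisymmetric_under_swap(self):
        rng = np.random.default_rng(0)
        pssm = PSSM(rng.normal(size=(5, 20)))
        fwd = pssm_features(pssm, SAV("X", 3, "A", "W"))
        rev = pssm_features(pssm, SAV("X", 3, "W", "A"))
        assert fwd["delta"] == -rev["delta"]

    def test_position_out_of_range(self):
        with pytest.raises(BoundsError):
            pssm_features(PSSM(np.zeros((3, 20))), SAV("X", 5, "A", "V"))


class TestComputePssm:
    def test_conserved_column_log_odds_signs(self):
        rows = [MsaRow("q", "A")] + [MsaRow(f"s{i}", "A", 1e-9) for i in range(99)]
        pssm = compute_pssm_from_msa(MSA(rows), pseudocount=0.01)
        assert pssm.score(1, "A") > 0
        assert pssm.score(1, "W") < 0

    def test_background_column_scores_vanish(self):
        # one of each amino acid against a uniform background
        rows = [MsaRow(f"s{i}", aa, 1e-9) for i, aa in enumerate(AA_ALPHABET)]
        pssm = compute_pssm_from_msa(MSA(rows), pseudocount=1e-9, background=UNIFORM)
        np.testing.assert_allclose(pssm.scores, 0.0, atol=1e-6)

    def test_single_row_finite(self):
        pssm = compute_pssm_from_msa(MSA([MsaRow("q", "MKV")]), pseudocount=1.0)
        assert np.isfinite(pssm.scores).all()


class TestJsDivergence:
    def test_identical_distributions_give_zero(self):
        rows = [MsaRow(f"s{i}", aa, 1e-9) for i, aa in enumerate(AA_ALPHABET)]
        assert js_divergence(MSA(rows), 0, background=UNIFORM) == pytest.approx(0.0)

    def test_pure_column_against_uniform(self):
        rows = [MsaRow(f"s{i}", "A", 1e-9) for i in range(10)]
        jsd = js_divergence(MSA(rows), 0, background=UNIFORM)
        assert jsd == pytest.approx(0.8550, abs=1e-4)

    def test_high_gap_column_excluded(self):
        rows = [MsaRow("q", "A")] + [MsaRow(f"s{i}", "-", 1e-9) for i in range(1999)]
        msa = MSA(rows)
        assert gap_fraction(msa, 0) == pytest.approx(0.9995)
        assert js_divergence(msa, 0) is None

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(1)
        aa = list(AA_ALPHABET)
        for _ in range(20):
            rows = [MsaRow(f"s{i}", aa[rng.integers(20)], 1e-9) for i in range(15)]
            jsd = js_divergence(MSA(rows), 0, background=UNIFORM)
            assert 0.0 <= jsd <= 1.0

    def test_symmetric_under_lambda_swap(self):
        # JSD(P, Q; lam) with P the column and Q uniform equals
        # JSD(Q, P; 1-lam); realise the swap by exchanging the roles.
        rows = [MsaRow(f"s{i}", "AC"[i % 2], 1e-9) for i in range(10)]
        msa = MSA(rows)
        lam = 0.3
        a = js_divergence(msa, 0, lam=lam, background=UNIFORM)

        # swapped oracle computed directly from the definition
        p = np.zeros(20)
        p[AA_INDEX["A"]] = p[AA_INDEX["C"]] = 0.5
        q = UNIFORM
        m = (1 - lam) * q + lam * p
        kl = lambda a_, b_: np.where(a_ > 0, a_ * np.log2(np.where(a_ > 0, a_ / b_, 1)), 0).sum()
        swapped = (1 - lam) * kl(q, m) + lam * kl(p, m)
        assert a == pytest.approx(swapped)


class TestGapFraction:
    @pytest.mark.parametrize(
        "column,expected", [("AA--------", 0.0)]
    )
    def test_no_gaps(self, column, expected):
        msa = MSA([MsaRow("q", "A"), MsaRow("s", "A", 1.0)])
        assert gap_fraction(msa, 0) == 0.0

    def test_fraction_and_complement(self):
        rows = [MsaRow("q", "A")] + [
            MsaRow(f"s{i}", "-" if i < 2 else "A", 1e-9) for i in range(9)
        ]
        msa = MSA(rows)
        frac = gap_fraction(msa, 0)
        assert frac == pytest.approx(0.2)
        nongap = sum(r.aligned[0] not in "-." for r in msa.rows) / msa.n_rows
        assert frac + nongap == 1.0

    def test_all_gap_rows(self):
        msa = MSA([MsaRow("q", "A"), MsaRow("s", "-", 1.0), MsaRow("t", "-", 2.0)])
        assert gap_fraction(msa, 0) == pytest.approx(2 / 3)


class TestDivergenceFeatures:
    def test_best_evalue_rows_found(self, toy_msa):
        # position 3 (D): hom1 has wt, hom2 (E=1e-20) has G, hom3 gap
        feats = divergence_features(toy_msa, SAV("q", 3, "D", "G"))
        assert feats["first_nonwt_evalue"] == 1e-20
        assert feats["first_mut_evalue"] == 1e-20
        assert feats["first_mut_identity"] == pytest.approx(80.0)

    def test_absent_mutant_gets_sentinel(self, toy_msa):
        feats = divergence_features(toy_msa, SAV("q", 3, "D", "K"))
        assert feats["first_mut_evalue"] == SENTINEL_EVALUE
        assert feats["first_mut_identity"] == 0.0
        assert feats["first_nonwt_evalue"] == 1e-20  # hom2's G still counts

    def test_query_only_msa(self):
        msa = MSA([MsaRow("q", "ACDEF")])
        feats = divergence_features(msa, SAV("q", 1, "A", "V"))
        assert feats["first_nonwt_evalue"] == SENTINEL_EVALUE
        assert feats["first_nonwt_identity"] == 0.0
        assert feats["first_mut_identity"] == 0.0

    def test_agrees_with_brute_force_over_row_orderings(self, toy_msa):
        """Result depends only on E-values, not file order of homologues."""
        sav = SAV("q", 3, "D", "G")
        expected = divergence_features(toy_msa, sav)
        others = toy_msa.rows[1:]
        for perm in itertools.permutations(others):
            msa = MSA([toy_msa.rows[0], *perm])
            assert divergence_features(msa, sav) == expected

    def test_rows_without_evalue_ordered_last(self):
        msa = MSA(
            [
                MsaRow("q", "AD"),
                MsaRow("noev", "AV", None),
                MsaRow("withev", "AW", 1e-3),
            ]
        )
        feats = divergence_features(msa, SAV("q", 2, "D", "V"))
        # withev sorts first; its W is non-wt, the mutant V comes from noev
        assert feats["first_nonwt_evalue"] == 1e-3
        assert feats["first_mut_evalue"] == SENTINEL_EVALUE  # noev has no E-value

    def test_identity_over_shared_columns(self, toy_msa):
        # hom3 "AC-EW" vs query "ACDEF": 4 shared columns, 3 identical
        assert percent_identity(toy_msa, 3) == pytest.approx(75.0)
        assert percent_identity(toy_msa, 3, over_query_length=True) == pytest.approx(60.0)


class TestPfamEmission:
    def test_difference(self):
        emissions = {5: {aa: 0.05 for aa in AA_ALPHABET}}
        emissions[5]["C"] = 0.50
        emissions[5]["G"] = 0.05
        delta = pfam_emission_delta(emissions, SAV("q", 5, "C", "G"))
        assert delta == pytest.approx(0.45)

    def test_outside_domain_is_missing(self):
        assert math.isnan(pfam_emission_delta({}, SAV("q", 5, "C", "G")))
        assert math.isnan(pfam_emission_delta(None, SAV("q", 5, "C", "G")))

    def test_invalid_probability(self):
        emissions = {5: {aa: 0.05 for aa in AA_ALPHABET}}
        emissions[5]["C"] = 1.3
        with pytest.raises(ValidationError):
            pfam_emission_delta(emissions, SAV("q", 5, "C", "G"))
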