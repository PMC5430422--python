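"""Parsing, OR/CI conversion and allele harmonization."""

import io
import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gripmr import (
    ConfigurationError,
    ExposureAssociation,
    HarmonizationError,
    OutcomeAssociation,
    harmonize,
    logor_from_or,
    parse_summary_table,
    se_from_or_ci,
)
from gripmr.sumstats import (
    flip_orientation,
    is_palindromic,
    or_ci_from_logbeta,
    outcome_table,
)

Z95 = 1.959963984540054


class TestConversions:
    @pytest.mark.parametrize(
        "odds_ratio, expected",
        [(1.0, 0.0), (0.95, math.log(0.95)), (0.90, math.log(0.90))],
    )
    def test_log_transform(self, odds_ratio, expected):
        assert logor_from_or(odds_ratio) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_log_transform_rejects_nonpositive(self, bad):
        with pytest.raises(ValueError):
            logor_from_or(bad)

    @pytest.mark.parametrize(
        "lo, hi, expected",
        [
            # widths of the published CAD intervals, back-transformed
            (0.85, 1.02, (math.log(1.02) - math.log(0.85)) / (2 * Z95)),
            (0.9, 0.9995, (math.log(0.9995) - math.log(0.9)) / (2 * Z95)),
        ],
    )
    def test_se_from_ci(self, lo, hi, expected):
        assert se_from_or_ci(lo, hi, 0.95) == pytest.approx(expected, rel=1e-12)

    def test_se_from_ci_frozen_values(self):
        # frozen from direct evaluation of (ln U - ln L) / (2 z)
        assert se_from_or_ci(0.85, 1.02) == pytest.approx(0.0465114559, abs=1e-9)
        assert se_from_or_ci(0.9, 0.9995) == pytest.approx(0.0267505912, abs=1e-9)

    def test_zero_width_interval_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert se_from_or_ci(1.0, 1.0, 0.95) == 0.0

    def test_invalid_intervals(self):
        with pytest.raises(ValueError):
            se_from_or_ci(1.02, 0.85)
        with pytest.raises(ValueError):
            se_from_or_ci(-0.1, 1.0)
        with pytest.raises(ValueError):
            se_from_or_ci(0.9, 1.0, level=1.5)


class TestParsing:
    def test_published_exposure_row(self, exposures):
        rec = {e.snp_id: e for e in exposures}["rs3121278"]
        assert rec == ExposureAssociation(
            snp_id="rs3121278",
            effect_allele="T",
            other_allele="G",
            beta=-0.26,
            se=0.06,
            eaf=0.18,
            p_value=6.18e-5,
            n=34910,  # parsed from the printed "34,910"
        )

    def test_published_cad_row_is_ci_derived(self, cad_outcomes):
        rec = {o.snp_id: o for o in cad_outcomes}["rs752045"]
        assert rec.beta == pytest.approx(math.log(0.95), abs=1e-12)
        assert rec.se == pytest.approx(0.0267505912, abs=1e-9)
        assert rec.derivation == "ci-derived"
        assert rec.scale == "log-odds"
        assert (rec.source_or, rec.source_ci_lower, rec.source_ci_upper) == (0.95, 0.9, 0.9995)

    def test_empty_body_returns_empty_list(self, caplog):
        src = io.StringIO("snp_id\teffect_allele\tother_allele\tbeta\tse\teaf\tp_value\tn\n")
        df = pd.read_csv(src, sep="\t")
        with caplog.at_level("WARNING"):
            assert parse_summary_table(df, role="exposure") == []
        assert "empty" in caplog.text

    def test_missing_column_names_the_column(self):
        df = pd.DataFrame({"snp_id": ["rs1"], "effect_allele": ["A"], "other_allele": ["G"]})
        with pytest.raises(ConfigurationError, match="beta"):
            parse_summary_table(df, role="exposure")

    def test_column_map_renames(self):
        df = pd.DataFrame(
            {
                "rsid": ["rs1"],
                "ea": ["A"],
                "oa": ["G"],
                "b": [0.1],
                "stderr": [0.02],
                "freq": [0.3],
                "p": [0.01],
                "size": [1000],
            }
        )
        (rec,) = parse_summary_table(
            df,
            role="exposure",
            column_map={
                "snp_id": "rsid",
                "effect_allele": "ea",
                "other_allele": "oa",
                "beta": "b",
                "se": "stderr",
                "eaf": "freq",
                "p_value": "p",
                "n": "size",
            },
        )
        assert rec.beta == 0.1 and rec.n == 1000

    def test_value_errors_carry_row_index(self):
        df = pd.DataFrame(
            {
                "snp_id": ["rs1"],
                "effect_allele": ["A"],
                "other_allele": ["G"],
                "or": [-0.5],
                "ci_lower": [0.8],
                "ci_upper": [1.1],
            }
        )
        with pytest.raises(ValueError, match="row 0"):
            parse_summary_table(df, role="outcome")

    def test_eaf_out_of_range_rejected(self):
        df = pd.DataFrame(
            {
                "snp_id": ["rs1"],
                "effect_allele": ["A"],
                "other_allele": ["G"],
                "beta": [0.1],
                "se": [0.02],
                "eaf": [1.2],
                "p_value": [0.01],
                "n": [1000],
            }
        )
        with pytest.raises(ValueError, match="eaf"):
            parse_summary_table(df, role="exposure")


class TestRecordInvariants:
    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError):
            ExposureAssociation("rs1", "A", "A", 0.1, 0.02, 0.3, 0.01, 1000)

    @pytest.mark.parametrize("field, value", [("se", 0.0), ("eaf", 0.0), ("eaf", 1.0), ("n", 1)])
    def test_domain_bounds(self, field, value):
        kwargs = dict(
            snp_id="rs1", effect_allele="A", other_allele="G",
            beta=0.1, se=0.02, eaf=0.3, p_value=0.01, n=1000,
        )
        kwargs[field] = value
        with pytest.raises(ValueError):
            ExposureAssociation(**kwargs)


def _outcome(snp="rs1", ea="T", oa="G", beta=0.05, se=0.02, **kw):
    return OutcomeAssociation(snp, ea, oa, beta, se, **kw)


def _exposure(snp="rs1", ea="T", oa="G", beta=-0.26):
    return ExposureAssociation(snp, ea, oa, beta, 0.06, 0.18, 1e-4, 34910)


class TestHarmonize:
    def test_same_orientation_copies_through(self):
        pair = harmonize(_exposure(), _outcome(beta=math.log(0.93)))
        assert pair.exposure_beta == -0.26
        assert pair.outcome_beta == pytest.approx(math.log(0.93))
        assert pair.effect_allele == "T"

    def test_swapped_alleles_flip_sign(self):
        pair = harmonize(_exposure(ea="G", oa="A", beta=0.47), _outcome(ea="A", oa="G", beta=0.05))
        assert pair.exposure_beta == 0.47
        assert pair.outcome_beta == pytest.approx(-0.05)

    def test_strand_complement_fallback(self):
        # exposure T/G, outcome reported on the opposite strand as A/C
        pair = harmonize(_exposure(), _outcome(ea="A", oa="C", beta=0.05))
        assert pair.outcome_beta == pytest.approx(0.05)
        # complemented and swapped: C/A aligns with T/G after flip
        pair = harmonize(_exposure(), _outcome(ea="C", oa="A", beta=0.05))
        assert pair.outcome_beta == pytest.approx(-0.05)

    def test_palindromic_policy(self):
        exp = _exposure(ea="A", oa="T")
        out = _outcome(ea="A", oa="T")
        with pytest.raises(HarmonizationError, match="palindromic"):
            harmonize(exp, out, palindrome_policy="error")
        assert harmonize(exp, out, palindrome_policy="drop") is None

    def test_snp_id_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            harmonize(_exposure(snp="rs1"), _outcome(snp="rs2"))

    def test_irreconcilable_alleles_name_both_pairs(self):
        with pytest.raises(HarmonizationError, match="T/G.*A/G"):
            harmonize(_exposure(), _outcome(ea="A", oa="G"))

    def test_idempotent(self):
        pair = harmonize(_exposure(), _outcome(beta=0.05))
        again = harmonize(
            _exposure(),
            _outcome(ea=pair.effect_allele, oa=pair.other_allele, beta=pair.outcome_beta,
                     se=pair.outcome_se),
        )
        assert again == pair

    @given(
        beta=st.floats(-1, 1, allow_nan=False),
        swapped=st.booleans(),
    )
    def test_double_flip_is_identity(self, beta, swapped):
        """Flipping the orientation of both records changes nothing."""
        exp = _exposure(ea="G" if swapped else "T", oa="T" if swapped else "G")
        out = _outcome(beta=beta, ea=exp.effect_allele, oa=exp.other_allele)
        direct = harmonize(exp, out)
        flipped_exp = replace(
            exp, effect_allele=exp.other_allele, other_allele=exp.effect_allele,
            beta=-exp.beta, eaf=1 - exp.eaf,
        )
        both_flipped = harmonize(flipped_exp, flip_orientation(out))
        assert both_flipped.outcome_beta / both_flipped.exposure_beta == pytest.approx(
            direct.outcome_beta / direct.exposure_beta, rel=1e-12, abs=1e-12
        )
        assert both_flipped.outcome_se == direct.outcome_se

    def test_is_palindromic(self):
        assert is_palindromic("A", "T") and is_palindromic("C", "G")
        assert not is_palindromic("T", "G")


class TestFixtureRoundTrips:
    @pytest.mark.parametrize(
        "outcome", ["cad", "mi", "t2d", "bmi", "ldl", "hdl", "tg", "glucose"]
    )
    def test_ci_rebuild_matches_printed_bounds(self, outcome):
        """Rebuilding each OR interval from (beta, ci-derived se) recovers the
        printed bounds to within one unit of the table's two-decimal
        precision (the printed intervals are rounded and not exactly
        symmetric on the log scale, so half-digit recovery is unattainable)."""
        from gripmr import load_outcome_fixture

        for rec in load_outcome_fixture(outcome):
            _, lo, hi = or_ci_from_logbeta(rec.beta, rec.se, rec.ci_level)
            assert lo == pytest.approx(rec.source_ci_lower, abs=0.011)
            assert hi == pytest.approx(rec.source_ci_upper, abs=0.011)

    def test_outcome_serialization_preserves_source_cells(self, cad_outcomes):
        table = outcome_table(cad_outcomes)
        assert list(table["or"]) == [0.93, 0.95]
        assert list(table["ci_lower"]) == [0.85, 0.9]
        assert list(table["ci_upper"]) == [1.02, 0.9995]
        reparsed = parse_summary_table(table, role="outcome")
        assert reparsed == cad_outcomes
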