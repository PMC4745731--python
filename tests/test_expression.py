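"""Expression I/O, CNR and the BTIF significance/fold-change gate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import prediction_interval_p
from pascore.errors import ParseError, ValidationError
from pascore.expression import (
    ExpressionCohort,
    compute_btif,
    compute_cnr,
    load_cohort,
    read_expression,
    split_by_phenotype,
)


def _cohort_one_gene(case_values, control_values, gene="G1"):
    case = np.asarray(case_values, dtype=float)[None, :]
    ctrl = np.asarray(control_values, dtype=float)[None, :]
    return ExpressionCohort(
        genes=[gene],
        case_matrix=case,
        control_matrix=ctrl,
        case_ids=[f"s{i}" for i in range(case.shape[1])],
        control_ids=[f"n{i}" for i in range(ctrl.shape[1])],
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def test_tsv_read_preserves_order_and_labels(tmp_path):
    f = tmp_path / "e.tsv"
    f.write_text("gene\ts1\ts2\nGa\t1\t2\nGb\t3\t4\nGc\t5\t6\n")
    df = read_expression(f)
    assert list(df.index) == ["GA", "GB", "GC"]
    assert list(df.columns) == ["s1", "s2"]
    assert df.shape == (3, 2)


def test_duplicate_gene_rows_collapse_by_mean(tmp_path, caplog):
    f = tmp_path / "e.tsv"
    f.write_text("gene\ts1\nGa\t2\nGA\t4\n")
    with caplog.at_level("WARNING"):
        df = read_expression(f)
    assert df.loc["GA", "s1"] == 3.0
    assert any("duplicate" in r.message for r in caplog.records)


def test_log2_input_unlogs(tmp_path):
    f = tmp_path / "e.tsv"
    f.write_text("gene\ts1\nGa\t3\n")
    assert read_expression(f, log2_input=True).loc["GA", "s1"] == 8.0


def test_non_numeric_cell_is_a_parse_error(tmp_path):
    f = tmp_path / "e.tsv"
    f.write_text("gene\ts1\ts2\nGa\t1\toops\n")
    with pytest.raises(ParseError, match="non-numeric"):
        read_expression(f)


def test_gct_dims_mismatch_is_an_error(tmp_path):
    f = tmp_path / "e.gct"
    f.write_text(
        "#1.2\n5\t2\nNAME\tDescription\ts1\ts2\nGa\tx\t1\t2\nGb\ty\t3\t4\n"
    )
    with pytest.raises(ParseError, match="declares"):
        read_expression(f, format="gct")


def test_gct_read_ok(tmp_path):
    f = tmp_path / "e.gct"
    f.write_text(
        "#1.2\n2\t2\nNAME\tDescription\ts1\ts2\nGa\tx\t1\t2\nGb\ty\t3\t4\n"
    )
    df = read_expression(f, format="gct")
    assert df.shape == (2, 2)
    assert df.loc["GB", "s2"] == 4.0


def test_phenotype_split_and_two_file_load(tmp_path):
    f = tmp_path / "e.tsv"
    f.write_text("gene\ta\tb\tc\td\nGa\t1\t2\t3\t4\nGb\t5\t6\t7\t8\n")
    ph = tmp_path / "ph.tsv"
    ph.write_text("sample\tlabel\na\tcase\nb\tcase\nc\tcontrol\nd\tcontrol\n")
    cohort = load_cohort(f, phenotype_path=ph)
    assert cohort.case_ids == ["a", "b"]
    assert cohort.control_ids == ["c", "d"]
    assert cohort.case_matrix[1, 1] == 6.0

    ph_missing = tmp_path / "ph2.tsv"
    ph_missing.write_text("a\tcase\nb\tcase\nc\tcontrol\n")
    with pytest.raises(ValidationError, match="lacks labels"):
        split_by_phenotype(read_expression(f), ph_missing)


def test_cohort_invariants_enforced():
    with pytest.raises(ValidationError, match="control"):
        _cohort_one_gene([1.0], [2.0])  # single control
    with pytest.raises(ValidationError, match="negative"):
        _cohort_one_gene([-1.0], [2.0, 3.0])
    with pytest.raises(ValidationError, match="shape"):
        ExpressionCohort(
            genes=["G1", "G2"],
            case_matrix=np.ones((1, 1)),
            control_matrix=np.ones((2, 2)),
            case_ids=["s"],
            control_ids=["n1", "n2"],
        )


# ---------------------------------------------------------------------------
# CNR
# ---------------------------------------------------------------------------

def test_cnr_against_control_mean():
    cohort = _cohort_one_gene([100.0, 50.0], [40.0, 60.0])
    stats = compute_cnr(cohort)
    assert stats.cnr[0, 0] == pytest.approx(2.0)
    assert stats.cnr[0, 1] == pytest.approx(1.0)
    assert stats.defined_mask.all()


def test_cnr_undefined_for_nonpositive_inputs():
    cohort = _cohort_one_gene([100.0, 0.0], [0.0, 0.0])
    stats = compute_cnr(cohort)
    assert not stats.defined_mask.any()
    assert np.isnan(stats.cnr).all()


# ---------------------------------------------------------------------------
# BTIF
# ---------------------------------------------------------------------------

def test_btif_inside_fold_interval_is_zero_despite_significance():
    # CNR 1.185 (inside 0.66-1.5) with p ~ 0.17 from the frozen oracle;
    # even with alpha = 0.5 > p the fold gate alone must veto the flag.
    cohort = _cohort_one_gene([120.0], [100.0, 110.0, 90.0, 105.0])
    stats = compute_btif(compute_cnr(cohort), cohort, alpha=0.5)
    assert stats.pvalue[0, 0] == pytest.approx(0.1704656450421617, rel=1e-9)
    assert stats.btif[0, 0] == 0


def test_btif_set_for_tight_controls_and_large_fold():
    cohort = _cohort_one_gene([300.0], [100.0, 110.0, 90.0, 105.0])
    stats = compute_btif(compute_cnr(cohort), cohort)
    assert stats.cnr[0, 0] == pytest.approx(2.962962962962963)
    assert stats.pvalue[0, 0] == pytest.approx(0.001476859454638019, rel=1e-9)
    assert stats.btif[0, 0] == 1


def test_btif_vetoed_by_wide_control_spread():
    cohort = _cohort_one_gene([300.0], [10.0, 300.0, 30.0, 60.0])
    stats = compute_btif(compute_cnr(cohort), cohort)
    assert stats.cnr[0, 0] == pytest.approx(3.0)
    assert stats.pvalue[0, 0] == pytest.approx(0.33428533366883073, rel=1e-9)
    assert stats.btif[0, 0] == 0


def test_btif_pvalues_match_oracle_on_random_genes():
    rng = np.random.default_rng(7)
    ctrl = rng.lognormal(5, 1, size=(20, 6))
    case = rng.lognormal(5, 1, size=(20, 3))
    cohort = ExpressionCohort(
        genes=[f"g{i}" for i in range(20)],
        case_matrix=case,
        control_matrix=ctrl,
        case_ids=["a", "b", "c"],
        control_ids=[f"n{i}" for i in range(6)],
    )
    stats = compute_btif(compute_cnr(cohort), cohort)
    for gi in range(20):
        for si in range(3):
            expected = prediction_interval_p(case[gi, si], ctrl[gi])
            assert stats.pvalue[gi, si] == pytest.approx(expected, rel=1e-9)


def test_zero_control_variance_convention():
    cohort = _cohort_one_gene([100.0, 300.0], [100.0, 100.0, 100.0])
    stats = compute_btif(compute_cnr(cohort), cohort)
    assert stats.pvalue[0, 0] == 1.0  # case equals control mean
    assert stats.pvalue[0, 1] == 0.0  # any deviation is "certain"
    assert stats.btif[0, 1] == 1  # CNR = 3 outside interval, p = 0


def test_case_at_control_mean_never_flags(demo_cohort):
    stats = compute_btif(compute_cnr(demo_cohort), demo_cohort)
    # sample s2 was built exactly at the control mean for every gene
    assert stats.btif[:, 1].sum() == 0
    assert np.allclose(stats.cnr[:, 1], 1.0)


@given(scale=st.floats(min_value=1e-3, max_value=1e3))
@settings(deadline=None, max_examples=25, derandomize=True)
def test_scale_invariance_of_cnr_p_and_btif(scale):
    rng = np.random.default_rng(11)
    ctrl = rng.lognormal(4, 0.4, size=(6, 4))
    case = rng.lognormal(4, 0.8, size=(6, 2))

    def run(mult):
        cohort = ExpressionCohort(
            genes=[f"g{i}" for i in range(6)],
            case_matrix=case * mult,
            control_matrix=ctrl * mult,
            case_ids=["a", "b"],
            control_ids=["n1", "n2", "n3", "n4"],
        )
        return compute_btif(compute_cnr(cohort), cohort)

    base, scaled = run(1.0), run(scale)
    assert np.allclose(base.cnr, scaled.cnr, rtol=1e-9)
    assert np.allclose(base.pvalue, scaled.pvalue, rtol=1e-7, atol=1e-12)
    assert np.array_equal(base.btif, scaled.btif)


def test_cnr_strictly_increases_with_case_value():
    ctrl = [80.0, 120.0, 100.0]
    lo = compute_cnr(_cohort_one_gene([90.0], ctrl)).cnr[0, 0]
    hi = compute_cnr(_cohort_one_gene([91.0], ctrl)).cnr[0, 0]
    assert hi > lo


def test_btif_parameter_validation(demo_cohort):
    stats = compute_cnr(demo_cohort)
    with pytest.raises(ValidationError, match="alpha"):
        compute_btif(stats, demo_cohort, alpha=1.5)
    with pytest.raises(ValidationError, match="fc_low"):
        compute_btif(stats, demo_cohort, fc_low=2.0, fc_high=1.5)
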