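"""Differential screen: I/O validation, Welch test, thresholds, invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sigreverse import compute_differential, read_expression, welch_t
from sigreverse.errors import (
    DuplicateGeneError,
    GroupSizeError,
    NonNumericValueError,
    UnknownSampleError,
)
from sigreverse.signature import ExpressionMatrix


def _write_matrix(tmp_path, rows, header="gene_id\ts1\ts2\ts3\ts4"):
    p = tmp_path / "expr.tsv"
    p.write_text(header + "\n" + "\n".join(rows) + "\n")
    return p


def _write_groups(tmp_path, pairs):
    p = tmp_path / "groups.csv"
    p.write_text("sample_id,group\n" + "\n".join(f"{s},{g}" for s, g in pairs) + "\n")
    return p


GOOD_ROWS = ["g1\t1.0\t2.0\t3.0\t4.0", "g2\t2.0\t2.0\t2.0\t2.0", "g3\t5.5\t4.5\t3.5\t2.5"]
GOOD_GROUPS = [("s1", "case"), ("s2", "case"), ("s3", "control"), ("s4", "control")]


def test_read_expression_roundtrip(tmp_path):
    """A hand-written 3x4 TSV + 2/2 groups CSV reads back intact, order preserved."""
    mp = _write_matrix(tmp_path, GOOD_ROWS)
    gp = _write_groups(tmp_path, GOOD_GROUPS)
    expr = read_expression(mp, gp)
    assert expr.gene_ids == ["g1", "g2", "g3"]
    assert expr.sample_ids == ["s1", "s2", "s3", "s4"]
    assert expr.values.loc["g3", "s4"] == 2.5
    assert expr.samples_in("case") == ["s1", "s2"]


@pytest.mark.parametrize(
    "rows, groups, exc",
    [
        (GOOD_ROWS, GOOD_GROUPS + [("s9", "case")], UnknownSampleError),
        (GOOD_ROWS + ["g1\t1\t1\t1\t1"], GOOD_GROUPS, DuplicateGeneError),
        (["g1\t1.0\tNOPE\t3.0\t4.0"], GOOD_GROUPS, NonNumericValueError),
        (GOOD_ROWS, [("s1", "case"), ("s2", "control"), ("s3", "control"), ("s4", "control")], GroupSizeError),
        (GOOD_ROWS, GOOD_GROUPS[:3], UnknownSampleError),  # unlabelled matrix sample
    ],
    ids=["unknown-sample", "duplicate-gene", "non-numeric", "small-group", "missing-label"],
)
def test_read_expression_named_errors(tmp_path, rows, groups, exc):
    mp = _write_matrix(tmp_path, rows)
    gp = _write_groups(tmp_path, groups)
    with pytest.raises(exc):
        read_expression(mp, gp)


@pytest.mark.parametrize(
    "case, control, t_exp, p_exp",
    [
        ([1, 2, 3, 4], [1, 2, 3, 4], 0.0, 1.0),
        ([1, 2, 3, 4], [2, 3, 4, 5], -1.0954451150, 0.3153335962),
        ([5, 5, 5], [5, 5, 5], 0.0, 1.0),
    ],
    ids=["identical", "unit-shift", "constant-equal"],
)
def test_welch_t_reference_values(case, control, t_exp, p_exp):
    """Frozen Welch-Satterthwaite values, including zero-variance conventions."""
    t, p = welch_t(case, control)
    assert t == pytest.approx(t_exp, abs=1e-9)
    assert p == pytest.approx(p_exp, abs=1e-9)


def test_welch_t_constant_unequal_is_infinite():
    t, p = welch_t([5.0, 5.0], [3.0, 3.0])
    assert t == np.inf and p == 0.0
    t, p = welch_t([3.0, 3.0], [5.0, 5.0])
    assert t == -np.inf and p == 0.0


def test_welch_t_rejects_tiny_groups():
    with pytest.raises(GroupSizeError):
        welch_t([1.0], [1.0, 2.0])


def test_welch_t_matches_scipy():
    """Independent cross-check against scipy's Welch implementation."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        a = rng.normal(size=rng.integers(2, 15))
        b = rng.normal(scale=2.0, size=rng.integers(2, 15))
        t, p = welch_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)


def _matrix_from_effects(effects, n=6, sigma=0.05, seed=3):
    """Small ExpressionMatrix with specified per-gene log2 case-control shifts."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(len(effects))]
    samples = [f"c{i}" for i in range(n)] + [f"h{i}" for i in range(n)]
    values = 7.0 + rng.normal(0, sigma, size=(len(effects), 2 * n))
    for i, e in enumerate(effects):
        values[i, :n] += e
    groups = pd.Series(["case"] * n + ["control"] * n, index=samples)
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), groups)


def test_directions_and_strictness():
    """Clear shifts classify up/down; thresholds are strict inequalities."""
    expr = _matrix_from_effects([1.0, -1.0, 0.0])
    records, signature = compute_differential(expr)
    by_gene = {r.gene_id: r for r in records}
    assert by_gene["g0"].direction == "up"
    assert by_gene["g1"].direction == "down"
    assert by_gene["g2"].direction == "not_significant"
    assert signature.up_genes == ["g0"] and signature.down_genes == ["g1"]

    # a gene whose fold change equals fc_min exactly must NOT pass (> is strict)
    import warnings

    fc_g0 = by_gene["g0"].fold_change
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records2, _ = compute_differential(expr, fc_min=fc_g0)
    assert {r.gene_id: r for r in records2}["g0"].direction == "not_significant"


def test_every_gene_in_exactly_one_class():
    expr = _matrix_from_effects([1.0, -1.0, 0.3, -0.3, 0.0, 2.0], sigma=0.2)
    records, _ = compute_differential(expr)
    assert all(r.direction in {"up", "down", "not_significant"} for r in records)
    assert len(records) == 6


def test_label_swap_negates_fold_changes():
    """Swapping case/control negates every log2FC and exchanges up/down sets."""
    expr = _matrix_from_effects([1.0, -1.0, 0.2, 0.0], sigma=0.1)
    rec_a, sig_a = compute_differential(expr)
    rec_b, sig_b = compute_differential(expr.swap_labels())
    for ra, rb in zip(rec_a, rec_b):
        assert ra.log2_fc == pytest.approx(-rb.log2_fc, abs=1e-12)
        assert ra.p_value == pytest.approx(rb.p_value, abs=1e-12)
    assert sig_a.up_genes == sig_b.down_genes
    assert sig_a.down_genes == sig_b.up_genes


def test_tightening_thresholds_never_adds_genes():
    import warnings

    expr = _matrix_from_effects([0.6, -0.6, 0.45, -0.45, 0.3, 0.0], sigma=0.4, seed=11)
    _, loose = compute_differential(expr, fc_min=1.2, p_max=0.2)
    for fc_min, p_max in [(1.3, 0.2), (1.2, 0.05), (1.5, 0.01)]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tightest settings may empty the signature
            _, tight = compute_differential(expr, fc_min=fc_min, p_max=p_max)
        assert set(tight.up_genes) <= set(loose.up_genes)
        assert set(tight.down_genes) <= set(loose.down_genes)


def test_empty_screen_warns_not_raises():
    expr = _matrix_from_effects([0.0, 0.0, 0.0], sigma=0.05)
    with pytest.warns(UserWarning, match="empty signature"):
        _, signature = compute_differential(expr, fc_min=5.0, p_max=0.001)
    assert signature.is_empty


def test_signature_ordering_is_deterministic():
    """Signature lists sort by ascending p, then descending FC, then gene id."""
    expr = _matrix_from_effects([2.0, 0.8, 1.4, -0.9, -1.8], sigma=0.3, seed=5)
    records, signature = compute_differential(expr)
    by_gene = {r.gene_id: r for r in records}
    ups = [(by_gene[g].p_value, -by_gene[g].fold_change, g) for g in signature.up_genes]
    assert ups == sorted(ups)
    downs = [(by_gene[g].p_value, -by_gene[g].fold_change, g) for g in signature.down_genes]
    assert downs == sorted(downs)
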