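"""t-tests, BH adjustment, DEG calling, response classes, PCA, 2^-ddCt."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import xhyb
from xhyb import ValidationError
from tests.conftest import full_mask


def textbook_welch(x, y):
    """Welch t and p straight from the formulae, via the t survival function."""
    from scipy.stats import t as tdist

    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    v1 = x.var(ddof=1) / n1
    v2 = y.var(ddof=1) / n2
    t = (x.mean() - y.mean()) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return t, 2 * tdist.sf(abs(t), df)


def stepup_bh(p):
    """Brute-force Benjamini–Hochberg step-up definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = running
    q = np.empty(m)
    q[order] = q_sorted
    return q


def test_welch_identical_groups():
    res = xhyb.welch_t([1, 2, 3], [1, 2, 3])
    assert res.t == 0.0 and res.p == 1.0


def test_welch_degenerate_zero_variance_flagged():
    res = xhyb.welch_t([0, 0, 0, 0], [1, 1, 1, 1])
    assert res.p == 0.0 and res.degenerate
    same = xhyb.welch_t([2, 2], [2, 2])
    assert same.p == 1.0 and same.t == 0.0


@settings(deadline=None, max_examples=50)
@given(seed=st.integers(0, 100_000))
def test_welch_matches_textbook_formula(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, 4)
    y = rng.normal(0.5, 2, 3)
    res = xhyb.welch_t(x, y)
    t, p = textbook_welch(x, y)
    assert res.t == pytest.approx(t, abs=1e-10)
    assert res.p == pytest.approx(p, abs=1e-10)


def test_welch_needs_two_replicates():
    with pytest.raises(ValidationError):
        xhyb.welch_t([1.0], [1.0, 2.0])


def test_bh_manual_stepup_example():
    q = xhyb.bh_adjust([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_bh_constant_and_single():
    np.testing.assert_allclose(xhyb.bh_adjust([0.3, 0.3, 0.3]), 0.3)
    np.testing.assert_allclose(xhyb.bh_adjust([0.123]), [0.123])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValidationError):
        xhyb.bh_adjust([0.5, 1.2])
    with pytest.raises(ValidationError):
        xhyb.bh_adjust([-0.1])


@settings(deadline=None, max_examples=50)
@given(seed=st.integers(0, 100_000), n=st.integers(1, 1000))
def test_bh_equals_brute_force_stepup(seed, n):
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=n)
    np.testing.assert_allclose(xhyb.bh_adjust(p), stepup_bh(p), atol=1e-12)
    # q >= p always
    assert (xhyb.bh_adjust(p) >= p - 1e-12).all()


def test_noise_free_deg_set_equals_planted(noise_free_run, expr_for):
    layout, truth, gdna, sheet, rna = noise_free_run
    for g in ("DipC", "TN"):
        expr = expr_for(g, normalize=False)
        degs = xhyb.call_degs(expr, sheet, g)
        assert set(degs["probe_set_id"]) == truth.de_sets(g)
        d = truth.de_frame(g)
        merged = degs.set_index("probe_set_id")
        assert (merged.loc[d.index, "direction"] == d["de_status"]).all()


def test_fc_gate_is_strict():
    """A set with tiny q but fold change below the gate is not a DEG."""
    rng = np.random.default_rng(7)
    ids = pd.Index([f"S{i}" for i in range(30)], name="probe_set_id")
    base = rng.normal(10, 0.01, (30, 7))
    base[0, :4] += 0.9  # log2fc 0.9 -> fold 1.87 < 2, wildly significant
    cols = [f"wl{i}" for i in range(4)] + [f"ws{i}" for i in range(3)]
    expr = xhyb.ExpressionMatrix(pd.DataFrame(base, index=ids, columns=cols))
    sheet = xhyb.SampleSheet(
        pd.DataFrame(
            {
                "sample_id": cols,
                "genotype": "G",
                "treatment": ["water_limited"] * 4 + ["water_sufficient"] * 3,
                "replicate": [1, 2, 3, 4, 1, 2, 3],
                "excluded": False,
            }
        )
    )
    c = xhyb.contrast(expr, sheet, "G")
    row = c.set_index("probe_set_id").loc["S0"]
    assert row["q"] < 0.05 and row["fold_change"] < 2
    degs = xhyb.call_degs(expr, sheet, "G")
    assert "S0" not in set(degs["probe_set_id"])


def test_insufficient_replicates_names_group(default_sheet, expr_for):
    expr = expr_for("DipC", normalize=False)
    sheet = default_sheet
    for rep in (1, 2):
        sheet = sheet.exclude(f"DipC.water_sufficient.rep{rep}")
    with pytest.raises(ValidationError, match="water_sufficient"):
        xhyb.call_degs(expr, sheet, "DipC")


def test_overlap_boundary_identity_and_direction_matching():
    a = pd.DataFrame(
        {"probe_set_id": ["S1", "S2", "S3"], "direction": ["up", "down", "up"]}
    )
    b_disjoint = pd.DataFrame({"probe_set_id": ["S9"], "direction": ["up"]})
    ov = xhyb.overlap_degs(a, b_disjoint)
    assert ov.n_common == 0 and len(ov.specific_a) == 3

    ov_same = xhyb.overlap_degs(a, a)
    assert ov_same.n_common == 3
    assert not ov_same.specific_a and not ov_same.specific_b

    flipped = a.copy()
    flipped["direction"] = ["down", "up", "down"]
    ov_flip = xhyb.overlap_degs(a, flipped)
    assert ov_flip.n_common == 0  # same ids, opposite direction


def test_classification_noise_free_matches_planted(noise_free_run, expr_for):
    layout, truth, gdna, sheet, rna = noise_free_run
    for g in ("DipC", "TN"):
        expr = expr_for(g, normalize=False)
        degs = xhyb.call_degs(expr, sheet, g)
        rec = xhyb.contrast(expr, sheet, g, ("recovery", "water_sufficient"))
        classified = xhyb.classify_response(degs, rec)
        got = classified.set_index("probe_set_id")["response_class"]
        want = truth.de_frame(g)["response_class"]
        assert (got.loc[want.index] == want).all()
        # every stress DEG is in exactly one class
        assert set(got.unique()) <= {"responsive", "perturbed"}


def test_classification_missing_set_is_unclassified():
    degs = pd.DataFrame({"probe_set_id": ["S1"], "direction": ["up"]})
    rec = pd.DataFrame(
        {"probe_set_id": ["S2"], "q": [0.5], "fold_change": [1.0]}
    )
    out = xhyb.classify_response(degs, rec)
    assert list(out["response_class"]) == ["unclassified"]


def test_pca_degenerate_and_conservation():
    ids = pd.Index(["a", "b", "c"], name="probe_set_id")
    one_dir = pd.DataFrame(
        [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [0.5, 1.0, 1.5]],
        index=ids, columns=["s1", "s2", "s3"],
    )
    fr, _ = xhyb.pca_variance(xhyb.ExpressionMatrix(one_dir))
    assert fr[0] == pytest.approx(1.0)
    np.testing.assert_allclose(fr[1:], 0.0, atol=1e-12)

    rng = np.random.default_rng(8)
    m = pd.DataFrame(rng.normal(size=(10, 6)), index=[f"S{i}" for i in range(10)])
    m.index.name = "probe_set_id"
    fr, _ = xhyb.pca_variance(xhyb.ExpressionMatrix(m))
    assert fr.sum() == pytest.approx(1.0)

    const = pd.DataFrame(np.full((4, 3), 2.0), index=list("abcd"))
    const.index.name = "probe_set_id"
    fr, _ = xhyb.pca_variance(xhyb.ExpressionMatrix(const))
    np.testing.assert_allclose(fr, 0.0)


def test_pca_matches_eigendecomposition_oracle():
    rng = np.random.default_rng(9)
    m = pd.DataFrame(
        rng.normal(size=(10, 6)),
        index=pd.Index([f"S{i}" for i in range(10)], name="probe_set_id"),
        columns=[f"c{j}" for j in range(6)],
    )
    fr, _ = xhyb.pca_variance(xhyb.ExpressionMatrix(m))
    centered = m.to_numpy() - m.to_numpy().mean(axis=1, keepdims=True)
    eigvals = np.sort(np.linalg.eigvalsh(centered.T @ centered))[::-1]
    np.testing.assert_allclose(fr, eigvals[: len(fr)] / eigvals.sum(), atol=1e-8)


def test_pca_invariant_under_sample_relabeling():
    rng = np.random.default_rng(10)
    m = pd.DataFrame(
        rng.normal(size=(12, 5)),
        index=pd.Index([f"S{i}" for i in range(12)], name="probe_set_id"),
        columns=list("abcde"),
    )
    fr1, _ = xhyb.pca_variance(xhyb.ExpressionMatrix(m))
    fr2, _ = xhyb.pca_variance(xhyb.ExpressionMatrix(m[list("ecadb")]))
    np.testing.assert_allclose(fr1, fr2, atol=1e-10)


def ddct_table(rows):
    return pd.DataFrame(rows, columns=["gene", "sample", "condition", "ct"])


def test_ddct_arithmetic_examples():
    # treated Ct 20 (ref 15) vs calibrator 18 (ref 15): ddCt = 2, fold = 0.25
    t = ddct_table(
        [
            ("g", "s1", "treated", 20.0), ("ref", "s1", "treated", 15.0),
            ("g", "s2", "calib", 18.0), ("ref", "s2", "calib", 15.0),
        ]
    )
    out = xhyb.delta_delta_ct(t, "ref", "calib").set_index("condition")
    assert out.at["treated", "fold_change"] == pytest.approx(0.25)
    assert out.at["calib", "fold_change"] == pytest.approx(1.0)  # ddCt = 0

    t2 = ddct_table(
        [
            ("g", "s1", "treated", 20.0), ("ref", "s1", "treated", 16.0),
            ("g", "s2", "calib", 22.0), ("ref", "s2", "calib", 16.0),
        ]
    )
    out2 = xhyb.delta_delta_ct(t2, "ref", "calib").set_index("condition")
    assert out2.at["treated", "delta_delta_ct"] == pytest.approx(-2.0)
    assert out2.at["treated", "fold_change"] == pytest.approx(4.0)


def test_ddct_missing_reference_rejected():
    t = ddct_table([("g", "s1", "treated", 20.0), ("ref", "s2", "calib", 15.0),
                    ("g", "s2", "calib", 18.0)])
    with pytest.raises(ValidationError, match="s1"):
        xhyb.delta_delta_ct(t, "ref", "calib")
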