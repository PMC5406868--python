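"""Differential expression, response classification, PCA QC and 2^-ddCt.

A gene (probe set) is differentially expressed in a contrast when it passes
both gates: Benjamini–Hochberg adjusted p-value <= q_max (default 0.05,
Welch t-test) and linear fold change strictly > fc_min (default 2).  Stress
DEGs are then partitioned by what happens after re-watering: a DEG whose
recovery-vs-water-sufficient contrast is non-significant has returned to
the pre-treatment level (``responsive``); one still significant retains a
dehydration-induced state change (``perturbed``).

The relative qPCR quantity 2^-ddCt is included because it is the standard
bench validation of array fold changes: dCt normalizes the target gene to a
reference (housekeeping) gene within each sample, ddCt to a calibrator
condition, and 2^-ddCt is the resulting fold change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .chipmodel import ExpressionMatrix, SampleSheet, ValidationError

STRESS_PAIR = ("water_limited", "water_sufficient")
RECOVERY_PAIR = ("recovery", "water_sufficient")

CONTRAST_COLUMNS = [
    "probe_set_id", "mean_1", "mean_2", "log2fc", "fold_change",
    "direction", "t", "p", "q", "degenerate",
]


class WelchResult(NamedTuple):
    t: float
    p: float
    degenerate: bool = False


def welch_t(group1, group2, pooled: bool = False) -> WelchResult:
    """Two-sided unequal-variance t-test (Welch–Satterthwaite df).

    When both sample variances are zero the test is degenerate: equal means
    give (t=0, p=1); unequal means give p=0 with the degenerate flag set.
    ``pooled=True`` switches to the classical equal-variance test.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs >= 2 replicate values")
    t, p, deg = _t_test_kernel(x[None, :], y[None, :], pooled=pooled)
    return WelchResult(float(t[0]), float(p[0]), bool(deg[0]))


def _t_test_kernel(x: np.ndarray, y: np.ndarray, pooled: bool = False):
    """Row-wise t-test on (n_tests, n1) vs (n_tests, n2) arrays."""
    n1, n2 = x.shape[1], y.shape[1]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1, v2 = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    diff = m1 - m2
    if pooled:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = np.full_like(se2, n1 + n2 - 2.0)
    else:
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
    degenerate = se2 == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # both variances zero: t undefined; decide on the means alone
    zero_eq = degenerate & (diff == 0.0)
    zero_ne = degenerate & (diff != 0.0)
    t[zero_eq], p[zero_eq] = 0.0, 1.0
    t[zero_ne] = np.sign(diff[zero_ne]) * np.inf
    p[zero_ne] = 0.0
    return t, p, degenerate


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def contrast(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    genotype: str,
    treatment_pair=STRESS_PAIR,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-set statistics for group1 - group2 of one genotype.

    Returns a frame with means, signed log2 fold change, linear fold change
    ``2**|log2fc|``, direction (up/down in group1), Welch t, p and BH q
    computed over all tested sets of this contrast.
    """
    t1, t2 = treatment_pair
    g1 = sheet.samples_for(genotype, t1)
    g2 = sheet.samples_for(genotype, t2)
    for name, ids in ((t1, g1), (t2, g2)):
        if len(ids) < 2:
            raise ValidationError(
                f"group ({genotype}, {name}) has {len(ids)} non-excluded "
                "replicates; need >= 2"
            )
    missing = (set(g1) | set(g2)) - set(expr.sample_ids)
    if missing:
        raise ValidationError(f"samples {sorted(missing)} absent from matrix")
    x = expr.values[g1].to_numpy()
    y = expr.values[g2].to_numpy()
    t, p, deg = _t_test_kernel(x, y, pooled=pooled)
    log2fc = x.mean(axis=1) - y.mean(axis=1)
    out = pd.DataFrame(
        {
            "probe_set_id": expr.probe_set_ids,
            "mean_1": x.mean(axis=1),
            "mean_2": y.mean(axis=1),
            "log2fc": log2fc,
            "fold_change": np.exp2(np.abs(log2fc)),
            "direction": np.where(log2fc > 0, "up", "down"),
            "t": t,
            "p": p,
            "q": bh_adjust(p),
            "degenerate": deg,
        }
    )
    out.attrs["contrast"] = f"{genotype}:{t1}_vs_{t2}"
    return out


def call_degs(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    genotype: str,
    treatment_pair=STRESS_PAIR,
    q_max: float = 0.05,
    fc_min: float = 2.0,
    pooled: bool = False,
) -> pd.DataFrame:
    """DEG table: rows of the contrast passing q <= q_max and fold > fc_min.

    The fold-change gate is strict (> fc_min); the FDR gate is inclusive
    (<= q_max).  ``response_class`` starts as ``unclassified`` and is filled
    by :func:`classify_response`.
    """
    stats_df = contrast(expr, sheet, genotype, treatment_pair, pooled=pooled)
    keep = (stats_df["q"] <= q_max) & (stats_df["fold_change"] > fc_min)
    degs = stats_df.loc[keep].copy()
    degs.insert(0, "contrast", stats_df.attrs["contrast"])
    degs["response_class"] = "unclassified"
    degs.attrs["contrast"] = stats_df.attrs["contrast"]
    return degs.reset_index(drop=True)


@dataclass(frozen=True)
class DEGOverlap:
    common_up: frozenset
    common_down: frozenset
    specific_a: frozenset
    specific_b: frozenset

    @property
    def n_common(self) -> int:
        return len(self.common_up) + len(self.common_down)


def overlap_degs(table_a: pd.DataFrame, table_b: pd.DataFrame) -> DEGOverlap:
    """Cross-genotype DEG overlap, matched on probe set id *and* direction."""
    def by_dir(t, d):
        return set(t.loc[t["direction"] == d, "probe_set_id"])

    a_up, a_down = by_dir(table_a, "up"), by_dir(table_a, "down")
    b_up, b_down = by_dir(table_b, "up"), by_dir(table_b, "down")
    common_up = a_up & b_up
    common_down = a_down & b_down
    common = common_up | common_down
    return DEGOverlap(
        common_up=frozenset(common_up),
        common_down=frozenset(common_down),
        specific_a=frozenset((a_up | a_down) - common),
        specific_b=frozenset((b_up | b_down) - common),
    )


def classify_response(
    deg_stress: pd.DataFrame,
    recovery_contrast: pd.DataFrame,
    q_max: float = 0.05,
    fc_min: float = 2.0,
    rule: str = "nonsig_recovery",
) -> pd.DataFrame:
    """Partition stress DEGs into responsive vs perturbed.

    Default rule (``nonsig_recovery``): a stress DEG is ``responsive`` when
    the recovery-vs-water-sufficient contrast is non-significant for it
    (q > q_max or fold change <= fc_min), else ``perturbed``.  Alternative
    rule (``sig_stress_vs_recovery``): pass the water-limited-vs-recovery
    contrast instead and a DEG is responsive when that contrast *is*
    significant (expression moved back).  Sets missing from the contrast
    are ``unclassified``.
    """
    if rule not in ("nonsig_recovery", "sig_stress_vs_recovery"):
        raise ValidationError(f"unknown classify rule {rule!r}")
    rc = recovery_contrast.set_index("probe_set_id")
    out = deg_stress.copy()
    classes = []
    for ps in out["probe_set_id"]:
        if ps not in rc.index:
            classes.append("unclassified")
            continue
        significant = (rc.at[ps, "q"] <= q_max) and (
            rc.at[ps, "fold_change"] > fc_min
        )
        if rule == "nonsig_recovery":
            classes.append("perturbed" if significant else "responsive")
        else:
            classes.append("responsive" if significant else "perturbed")
    out["response_class"] = classes
    return out


def pca_variance(
    expr: ExpressionMatrix, n_components: int | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """PCA of samples after centering each probe set.

    Returns ``(variance_fractions, scores)`` where scores has one row per
    sample and one column per component.  A constant matrix yields all-zero
    fractions.
    """
    x = expr.values.to_numpy(dtype=float)
    n_samples = x.shape[1]
    if n_samples < 2:
        raise ValidationError("PCA needs >= 2 samples")
    centered = x - x.mean(axis=1, keepdims=True)
    # SVD of sets x samples; right singular vectors are sample directions
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    total = (s**2).sum()
    k = n_samples if n_components is None else min(n_components, len(s))
    if total == 0.0:
        fractions = np.zeros(min(k, len(s)))
        scores = np.zeros((n_samples, len(fractions)))
    else:
        fractions = (s[:k] ** 2) / total
        scores = vt[:k].T * s[:k]
    scores_df = pd.DataFrame(
        scores,
        index=expr.sample_ids,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return fractions, scores_df


def delta_delta_ct(
    ct: pd.DataFrame, reference_gene: str, calibrator_condition: str
) -> pd.DataFrame:
    """Relative qPCR quantification by the 2^-ddCt method.

    ``ct`` needs columns ``gene, sample, condition, ct``.  Per sample,
    dCt = Ct_target - Ct_reference; per (gene, condition),
    ddCt = mean dCt(condition) - mean dCt(calibrator) and the fold change
    is 2**-ddCt.  The reference gene must be measured in every sample.
    """
    required = {"gene", "sample", "condition", "ct"}
    if not required <= set(ct.columns):
        raise ValidationError(f"Ct table needs columns {sorted(required)}")
    ref = ct[ct["gene"] == reference_gene].set_index("sample")["ct"]
    targets = ct[ct["gene"] != reference_gene]
    missing = set(targets["sample"]) - set(ref.index)
    if missing:
        raise ValidationError(
            f"reference gene {reference_gene!r} not measured in samples "
            f"{sorted(missing)}"
        )
    if calibrator_condition not in set(ct["condition"]):
        raise ValidationError(
            f"calibrator condition {calibrator_condition!r} absent from table"
        )
    d = targets.copy()
    d["dct"] = d["ct"].to_numpy() - ref.loc[d["sample"]].to_numpy()
    mean_dct = d.groupby(["gene", "condition"])["dct"].mean().reset_index()
    cal = mean_dct[mean_dct["condition"] == calibrator_condition].set_index(
        "gene"
    )["dct"]
    rows = []
    for _, r in mean_dct.iterrows():
        if r["gene"] not in cal.index:
            raise ValidationError(
                f"gene {r['gene']!r} lacks calibrator-condition measurements"
            )
        ddct = r["dct"] - cal.loc[r["gene"]]
        rows.append(
            {
                "gene": r["gene"],
                "condition": r["condition"],
                "delta_delta_ct": ddct,
                "fold_change": 2.0**-ddct,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "condition", "delta_delta_ct", "fold_change"])
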