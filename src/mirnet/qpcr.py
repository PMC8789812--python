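"""Comparative-Ct (ddCt) relative quantification for qPCR validation.

Given a long Ct table (sample, group, target, replicate, ct), the analysis
averages technical replicates, normalizes each target against the arithmetic
mean Ct of the endogenous controls (dCt), contrasts group means
(ddCt = mean dCt test - mean dCt reference) and reports RQ = 2^(-ddCt).
Group differences are tested per target with a two-sample t-test on per-sample
dCt values, Benjamini-Hochberg corrected across targets, and flagged
significant by the vendor rule: RQ > 2 or RQ < 0.5 AND corrected p < 0.05.
Amplification efficiency is assumed to be 2 (the ddCt assumption).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import adjust_bh

CT_COLUMNS = ("sample", "group", "target", "replicate", "ct")


def _check_ct(ct: pd.DataFrame) -> None:
    for col in CT_COLUMNS:
        if col not in ct.columns:
            raise ValueError(f"Ct table missing column {col!r}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")


def aggregate_replicates(ct: pd.DataFrame, max_spread: float = 0.5) -> pd.DataFrame:
    """Mean Ct per (sample, target) with a replicate-spread QC flag.

    Replicates whose range exceeds ``max_spread`` cycles usually indicate a
    pipetting or amplification problem; the mean is still reported, flagged.
    """
    _check_ct(ct)
    agg = (
        ct.groupby(["sample", "group", "target"], sort=False)["ct"]
        .agg(ct_mean="mean", spread=lambda v: v.max() - v.min(), n="size")
        .reset_index()
    )
    agg["qc_flag"] = agg["spread"] > max_spread
    return agg


def delta_ct(ct_means: pd.DataFrame, controls: list[str]) -> pd.DataFrame:
    """dCt = Ct(target) - mean Ct(endogenous controls), per sample.

    Samples missing any control are excluded (with a warning column would be
    overkill: they are simply absent from the output).  The arithmetic mean of
    control Ct corresponds to the geometric mean of control expression.
    """
    if not controls:
        raise ValueError("need at least one endogenous control")
    wide = ct_means.pivot_table(index=["sample", "group"], columns="target", values="ct_mean")
    have_controls = wide[list(controls)].notna().all(axis=1)
    wide = wide.loc[have_controls]
    ref = wide[list(controls)].mean(axis=1)
    dct = wide.sub(ref, axis=0)
    out = dct.reset_index().melt(
        id_vars=["sample", "group"], var_name="target", value_name="delta_ct"
    )
    return out.dropna(subset=["delta_ct"]).reset_index(drop=True)


def relative_quant(
    dct: pd.DataFrame, test_group: str, reference_group: str
) -> pd.DataFrame:
    """Point estimates per target: ddCt, RQ = 2^(-ddCt), log2fc = -ddCt."""
    test = dct[dct["group"] == test_group]
    ref = dct[dct["group"] == reference_group]
    if test.empty or ref.empty:
        raise ValueError("both test and reference groups must be non-empty")
    ddct = (
        test.groupby("target")["delta_ct"].mean()
        - ref.groupby("target")["delta_ct"].mean()
    ).dropna()
    out = pd.DataFrame(
        {
            "test_group": test_group,
            "reference_group": reference_group,
            "delta_delta_ct": ddct,
            "rq": np.power(2.0, -ddct),
            "log2fc": -ddct,
        }
    )
    return out.reset_index()


def rq_test(
    dct: pd.DataFrame,
    test_group: str,
    reference_group: str,
    alpha: float = 0.05,
    equal_var: bool = True,
    exclude: list[str] | None = None,
) -> pd.DataFrame:
    """Relative quantification with t-tests, BH correction and the vendor rule.

    Per target, a two-sample t-test (Student's by default, Welch with
    ``equal_var=False``) compares per-sample dCt between the groups; p-values
    are BH-adjusted across targets within the comparison.  ``significant`` is
    True only when both the magnitude gate (RQ > 2 or RQ < 0.5) and the
    adjusted p < ``alpha`` hold.  Targets in ``exclude`` (e.g. the endogenous
    controls) are dropped before testing.
    """
    sub = dct[~dct["target"].isin(exclude or [])]
    result = relative_quant(sub, test_group, reference_group).set_index("target")
    pvals = {}
    flagged = {}
    for target, row in result.iterrows():
        a = sub.loc[(sub["group"] == test_group) & (sub["target"] == target), "delta_ct"]
        b = sub.loc[(sub["group"] == reference_group) & (sub["target"] == target), "delta_ct"]
        if len(a) < 2 or len(b) < 2:
            pvals[target], flagged[target] = np.nan, "too_few_samples"
            continue
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            pvals[target], flagged[target] = np.nan, "degenerate_variance"
            continue
        pvals[target] = stats.ttest_ind(a, b, equal_var=equal_var).pvalue
        flagged[target] = ""
    result["p"] = pd.Series(pvals)
    result["padj"] = adjust_bh(result["p"])
    result["flag"] = pd.Series(flagged)
    magnitude = (result["rq"] > 2.0) | (result["rq"] < 0.5)
    result["significant"] = magnitude & (result["padj"] < alpha) & result["padj"].notna()
    return result.reset_index()


def rank_normalizers(
    ct: pd.DataFrame,
    candidates: list[str],
    ct_range: tuple[float, float] = (20.0, 30.0),
    max_missing: float = 0.2,
) -> pd.DataFrame:
    """Rank endogenous-control candidates by cross-sample stability.

    Primary key: standard deviation of mean Ct across samples (ascending —
    a good normalizer barely moves); secondary: distance of the mean Ct from
    the midpoint of the assay's preferred Ct range.  Candidates missing in
    more than ``max_missing`` of samples are excluded.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    means = aggregate_replicates(ct)
    n_samples = means["sample"].nunique()
    midpoint = 0.5 * (ct_range[0] + ct_range[1])
    rows = []
    for cand in candidates:
        block = means[means["target"] == cand]
        coverage = block["sample"].nunique() / n_samples
        if coverage < 1.0 - max_missing:
            continue
        rows.append(
            {
                "target": cand,
                "ct_sd": block["ct_mean"].std(ddof=1),
                "ct_mean": block["ct_mean"].mean(),
                "midpoint_distance": abs(block["ct_mean"].mean() - midpoint),
                "coverage": coverage,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out = out.sort_values(["ct_sd", "midpoint_distance"], kind="mergesort", ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def spike_in_qc(ct: pd.DataFrame, spike: str = "cel-miR-39-3p", n_sd: float = 2.0) -> pd.DataFrame:
    """Flag samples whose exogenous spike-in Ct deviates > n_sd from the mean.

    The spike-in monitors reverse-transcription efficiency per sample; it is a
    QC gate only and plays no role in normalization.
    """
    means = aggregate_replicates(ct)
    block = means[means["target"] == spike]
    if block.empty:
        raise ValueError(f"spike-in {spike!r} not present in the Ct table")
    mu, sd = block["ct_mean"].mean(), block["ct_mean"].std(ddof=1)
    out = block[["sample", "group", "ct_mean"]].copy()
    out["qc_fail"] = (out["ct_mean"] - mu).abs() > n_sd * sd if sd > 0 else False
    return out.reset_index(drop=True)
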