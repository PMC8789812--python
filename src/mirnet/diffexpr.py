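"""Negative-binomial Wald differential expression over a contrast scheme.

Per miRNA, a two-group NB generalized linear model with log link,

    counts_j ~ NB(mean = s_j * exp(b0 + b1 * x_j),  dispersion alpha_i)

is fitted by iteratively reweighted least squares at a fixed method-of-moments
dispersion, with the log size factor as offset.  The Wald statistic b1/se(b1)
is referred to the standard normal; p-values are Benjamini-Hochberg adjusted
and miRNAs with adjusted p strictly below the threshold are called
differentially expressed (DEMs).

This is a transparent approximation of the full DESeq2 machinery: no
dispersion shrinkage toward a trend, no independent filtering, no outlier
refitting, no fold-change shrinkage.  Its calibration (type-I error, p-value
uniformity, effect recovery, FDR control) is what the test suite asserts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import NormalizationResult, filter_expressed, size_factors

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8


@dataclass(frozen=True)
class ContrastSpec:
    """One comparison: test groups vs reference groups, optional site limits.

    ``site_restriction`` maps a group label to the only collection site whose
    samples should represent it (e.g. restrict CTR to GOE for a dnPD vs
    CTR_GOE contrast); unrestricted groups contribute all their samples.
    """

    name: str
    test_groups: frozenset
    reference_groups: frozenset
    site_restriction: dict = field(default_factory=dict, hash=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "test_groups", frozenset(self.test_groups))
        object.__setattr__(self, "reference_groups", frozenset(self.reference_groups))
        if self.test_groups & self.reference_groups:
            raise ValueError("test and reference groups must be disjoint")

    def select(self, samplesheet: pd.DataFrame) -> pd.Series:
        """Boolean mask (test=True/reference=False) over selected samples."""
        for g in self.test_groups | self.reference_groups:
            if g not in set(samplesheet["group"]):
                raise ValueError(f"group {g!r} not present in the sample sheet")
        keep = samplesheet["group"].isin(self.test_groups | self.reference_groups)
        for group, site in self.site_restriction.items():
            keep &= (samplesheet["group"] != group) | (samplesheet["site"] == site)
        sel = samplesheet.loc[keep]
        if sel.empty or not sel["group"].isin(self.test_groups).any() or not (
            sel["group"].isin(self.reference_groups).any()
        ):
            raise ValueError(f"contrast {self.name!r} is empty after site restriction")
        return sel["group"].isin(self.test_groups)


def default_contrasts(samplesheet: pd.DataFrame) -> list[ContrastSpec]:
    """The discovery contrast scheme: patients and centenarians vs controls.

    dnPD and CENT are each compared with CTR restricted per collection site
    (CTR_GOE, CTR_UNIBO) and combined (CTR_ALL); dnPD is also compared with
    CENT and with the pooled CTR + CENT reference.  Contrasts whose groups are
    absent from the sample sheet are skipped.
    """
    present = set(samplesheet["group"])
    sites = lambda g: set(samplesheet.loc[samplesheet["group"] == g, "site"])
    specs: list[ContrastSpec] = []

    def add(name, test, ref, restrict=None):
        if set(test) <= present and set(ref) <= present:
            specs.append(ContrastSpec(name, frozenset(test), frozenset(ref), restrict or {}))

    for phenotype in ("dnPD", "CENT"):
        for site in sorted(sites("CTR") if "CTR" in present else set()):
            add(f"{phenotype}_vs_CTR_{site}", {phenotype}, {"CTR"}, {"CTR": site})
        add(f"{phenotype}_vs_CTR_ALL", {phenotype}, {"CTR"})
    add("dnPD_vs_CENT", {"dnPD"}, {"CENT"})
    add("dnPD_vs_CTR_CENT", {"dnPD"}, {"CTR", "CENT"})
    return specs


def estimate_dispersions(
    normalized: pd.DataFrame, groups: pd.Series, floor: float = DISPERSION_FLOOR
) -> pd.Series:
    """Method-of-moments NB dispersion from pooled within-group moments.

    alpha_i = max((pooled within-group variance - mean) / mean^2, floor),
    computed on normalized counts; the pooling removes the group-mean signal
    so planted effects do not inflate the dispersion.
    """
    arr = normalized.to_numpy(dtype=float)
    groups = groups.loc[normalized.columns]
    num = np.zeros(len(normalized))
    den = 0.0
    for g in groups.unique():
        cols = (groups == g).to_numpy()
        if cols.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        num += arr[:, cols].var(axis=1, ddof=1) * (cols.sum() - 1)
        den += cols.sum() - 1
    pooled_var = num / den
    mean = arr.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mean) / mean**2
    alpha = np.where(np.isfinite(alpha), alpha, floor)
    return pd.Series(np.maximum(alpha, floor), index=normalized.index, name="alpha")


def _irls_two_group(
    y: np.ndarray,
    log_s: np.ndarray,
    x: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-10,
):
    """Vectorized IRLS for the two-group NB log-link GLM at fixed dispersion.

    ``y`` is miRNA x sample, ``x`` the 0/1 test indicator, ``log_s`` the
    offset.  Returns natural-log coefficients ``b0, b1``, ``se(b1)`` and a
    convergence mask.  Fisher-scoring weights are mu/(1 + alpha*mu).
    """
    m, n = y.shape
    mean_all = np.maximum((y / np.exp(log_s)).mean(axis=1), 1e-8)
    b0 = np.log(mean_all)
    b1 = np.zeros(m)
    converged = np.zeros(m, dtype=bool)
    a = alpha[:, None]
    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * x[None, :] + log_s[None, :]
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + a * mu)
        z = (eta - log_s[None, :]) + (y - mu) / mu
        sw = w.sum(axis=1)
        swx = (w * x[None, :]).sum(axis=1)  # also sum w over test samples
        swz = (w * z).sum(axis=1)
        swxz = (w * x[None, :] * z).sum(axis=1)
        det = sw * swx - swx**2  # since x is 0/1, sum w x^2 = sum w x
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        new_b0 = (swx * swz - swx * swxz) / det
        new_b1 = (sw * swxz - swx * swz) / det
        step = np.nanmax(
            np.abs(np.stack([new_b0 - b0, new_b1 - b1])), axis=0
        )
        b0, b1 = new_b0, new_b1
        converged = step < tol
        if converged.all():
            break
    eta = np.clip(b0[:, None] + b1[:, None] * x[None, :] + log_s[None, :], -30, 30)
    mu = np.exp(eta)
    w = mu / (1.0 + a * mu)
    sw = w.sum(axis=1)
    swx = (w * x[None, :]).sum(axis=1)
    det = sw * swx - swx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = sw / det
    se = np.sqrt(np.where(var_b1 > 0, var_b1, np.nan))
    # runaway coefficients (a group with all-zero counts) are not informative
    converged &= np.abs(b1) < 20.0
    return b0, b1, se, converged


def wald_test(
    counts: pd.DataFrame,
    norm: NormalizationResult,
    dispersions: pd.Series,
    contrast: ContrastSpec,
    samplesheet: pd.DataFrame,
) -> pd.DataFrame:
    """Per-miRNA NB Wald test for one contrast.

    Returns a DataFrame indexed by miRNA with columns baseMean (mean
    normalized count over the contrast's samples), log2fc, se (log2 scale),
    pvalue, padj and converged.  All-zero rows get missing statistics.
    """
    is_test = contrast.select(samplesheet)
    cols = is_test.index
    y = counts.loc[:, cols].to_numpy(dtype=float)
    log_s = np.log(norm.size_factors.loc[cols].to_numpy(dtype=float))
    x = is_test.to_numpy(dtype=float)
    alpha = dispersions.loc[counts.index].to_numpy(dtype=float)

    base_mean = norm.normalized.loc[:, cols].mean(axis=1).to_numpy()
    nonzero = base_mean > 0
    b1 = np.full(len(counts), np.nan)
    se = np.full(len(counts), np.nan)
    conv = np.zeros(len(counts), dtype=bool)
    if nonzero.any():
        _, b1_nz, se_nz, conv_nz = _irls_two_group(
            y[nonzero], log_s, x, alpha[nonzero]
        )
        b1[nonzero], se[nonzero], conv[nonzero] = b1_nz, se_nz, conv_nz

    with np.errstate(invalid="ignore", divide="ignore"):
        z = b1 / se
    pvals = np.where(conv & np.isfinite(z), 2.0 * stats.norm.sf(np.abs(z)), np.nan)
    result = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2fc": b1 / LN2,
            "se": se / LN2,
            "pvalue": pvals,
            "converged": conv,
        },
        index=counts.index,
    )
    result["padj"] = adjust_bh(result["pvalue"])
    return result


def adjust_bh(pvals) -> pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing p-values are excluded from the denominator and returned missing;
    adjusted values are the running minimum of m*p/rank from the largest p
    down, capped at 1.
    """
    p = pd.Series(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = pd.Series(np.nan, index=p.index)
    ok = p.notna()
    m = int(ok.sum())
    if m == 0:
        return out
    sub = p[ok].sort_values(kind="mergesort")
    adj = sub.to_numpy() * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out[sub.index] = np.minimum(adj, 1.0)
    return out


def call_dems(result: pd.DataFrame, alpha: float = 0.05) -> set:
    """miRNAs with adjusted p strictly below ``alpha``."""
    padj = result["padj"]
    return set(result.index[padj.notna() & (padj < alpha)])


def run_contrasts(
    counts: pd.DataFrame,
    samplesheet: pd.DataFrame,
    specs: list[ContrastSpec] | None = None,
    pooled_normalization: bool = True,
    pseudo_reference: bool = False,
) -> dict:
    """Run the full contrast scheme; returns {contrast name: result frame}.

    Normalization is shared across contrasts by default (all samples pooled);
    dispersions are re-estimated per contrast on its own samples.
    """
    if specs is None:
        specs = default_contrasts(samplesheet)
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate contrast names")
    expressed = filter_expressed(counts)
    norm_all = size_factors(expressed, pseudo_reference=pseudo_reference)
    results = {}
    for spec in specs:
        is_test = spec.select(samplesheet)
        cols = is_test.index
        if pooled_normalization:
            norm = NormalizationResult(
                size_factors=norm_all.size_factors,
                normalized=norm_all.normalized,
                log_matrix=norm_all.log_matrix,
            )
        else:
            norm = size_factors(expressed[cols], pseudo_reference=pseudo_reference)
        disp = estimate_dispersions(
            norm.normalized.loc[:, cols], samplesheet.loc[cols, "group"]
        )
        results[spec.name] = wald_test(expressed, norm, disp, spec, samplesheet)
    return results
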