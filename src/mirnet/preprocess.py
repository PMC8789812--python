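"""Count preprocessing: UMI collapse, expressed filter, normalization, PCA QC.

The central object is a miRNA x sample integer count matrix (a DataFrame)
paired with a sample sheet.  Normalization uses the median-of-ratios size
factor estimator: each sample's depth factor is the median, over reference
rows, of its counts divided by the row's geometric mean.  Rows containing any
zero are excluded from the reference by default (the standard convention);
a pseudo-reference fallback over positive entries is available for sparse
matrices.  Spike-in rows, identified by an id prefix, are carried through as
ordinary rows but excluded from size-factor estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

REQUIRED_RECORD_COLS = ("sample", "mirna", "sequence", "umi")


@dataclass
class NormalizationResult:
    """Size factors plus the normalized and log2(normalized + 1) matrices."""

    size_factors: pd.Series
    normalized: pd.DataFrame
    log_matrix: pd.DataFrame


def collapse_umis(
    records: pd.DataFrame,
    mirna_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Collapse UMI-tagged read records to a count matrix.

    Reads sharing the same sequence and the same UMI within a (sample, miRNA)
    cell are PCR duplicates of one molecule and contribute a single count:
    the count is the number of distinct ``(sequence, umi)`` pairs.  Declared
    ``mirna_ids`` / ``sample_ids`` fix the output axes (zero-filled), which
    also makes an empty record set meaningful.
    """
    for col in REQUIRED_RECORD_COLS:
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    bad = records.index[
        (records["sequence"].astype(str).str.len() == 0)
        | (records["umi"].astype(str).str.len() == 0)
    ]
    if len(bad):
        raise ValueError(f"malformed record(s) at index {list(bad[:5])}: empty sequence or umi")

    if len(records):
        dedup = records.drop_duplicates(["sample", "mirna", "sequence", "umi"])
        counts = dedup.groupby(["mirna", "sample"]).size().unstack(fill_value=0)
    else:
        counts = pd.DataFrame(dtype=np.int64)
    if mirna_ids is not None:
        counts = counts.reindex(index=mirna_ids, fill_value=0)
    if sample_ids is not None:
        counts = counts.reindex(columns=sample_ids, fill_value=0)
    return counts.astype(np.int64)


def filter_expressed(counts: pd.DataFrame) -> pd.DataFrame:
    """Keep miRNAs with UMI count > 0 in at least one sample (idempotent)."""
    return counts.loc[(counts > 0).any(axis=1)]


def size_factors(
    counts: pd.DataFrame,
    pseudo_reference: bool = False,
    spike_prefix: str | None = "spikein-",
) -> NormalizationResult:
    """Median-of-ratios depth normalization.

    For reference rows i (all entries positive), let ``g_i`` be the geometric
    mean of row i; then ``s_j = median_i counts_ij / g_i``.  With
    ``pseudo_reference=True`` the geometric mean is taken over positive entries
    only and every row with at least one positive entry is usable (for sparse
    matrices where no row is positive everywhere).
    """
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    use = np.ones(len(counts), dtype=bool)
    if spike_prefix:
        use &= ~counts.index.astype(str).str.startswith(spike_prefix)

    with np.errstate(divide="ignore"):
        logc = np.log(arr)
    if pseudo_reference:
        pos = arr > 0
        usable = use & (pos.sum(axis=1) > 0)
        if not usable.any():
            raise ValueError("no usable rows: matrix has no positive entries")
        loggeo = np.where(
            pos[usable].sum(axis=1) > 0,
            np.nansum(np.where(pos[usable], logc[usable], np.nan), axis=1)
            / pos[usable].sum(axis=1),
            np.nan,
        )
        ratios = logc[usable] - loggeo[:, None]
        ratios[~pos[usable]] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            logs = np.nanmedian(ratios, axis=0)
    else:
        usable = use & (arr > 0).all(axis=1)
        if not usable.any():
            raise ValueError(
                "no row is positive in all samples; re-run with pseudo_reference=True"
            )
        loggeo = logc[usable].mean(axis=1)
        logs = np.median(logc[usable] - loggeo[:, None], axis=0)

    s = pd.Series(np.exp(logs), index=counts.columns, name="size_factor")
    normalized = counts / s
    return NormalizationResult(
        size_factors=s,
        normalized=normalized,
        log_matrix=np.log2(normalized + 1.0),
    )


def pca_qc(
    norm: NormalizationResult, n_top_variance: int = 500, n_components: int = 2
):
    """PCA of samples on the most variable log-expression rows (QC only).

    Uses ``log2(normalized + 1)`` in place of a variance-stabilizing
    transform — adequate for diagnostic sample clustering, not for inference.
    Returns ``(coordinates, explained_variance_ratio)`` with coordinates
    centered per component.
    """
    log_m = norm.log_matrix
    if log_m.shape[1] < 3:
        raise ValueError("PCA QC needs at least 3 samples")
    variances = log_m.var(axis=1)
    top = variances.sort_values(ascending=False).index[:n_top_variance]
    x = log_m.loc[top].to_numpy().T  # samples x features
    n_components = min(n_components, x.shape[0] - 1, x.shape[1])
    if np.allclose(x, x[0]):
        coords = np.zeros((x.shape[0], max(n_components, 1)))
        evr = np.zeros(max(n_components, 1))
    else:
        pca = PCA(n_components=n_components)
        coords = pca.fit_transform(x)
        evr = pca.explained_variance_ratio_
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=log_m.columns, columns=cols), evr
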