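"""Candidate-marker selection from DEM sets across contrasts.

Exclusive (UpSet-style) intersections of the DEM sets partition their union;
each intersection's size is scored against a Monte-Carlo null in which sets of
the observed sizes are drawn uniformly from the expressed-miRNA universe.
Candidates are then chosen by two rules: (i) all DEMs in the most significant
multi-contrast intersections, and (ii) the most significant DEMs unique to a
single contrast — both gated by an average-expression floor (default 5
normalized counts, a practical qPCR detectability bound).  A manual list
accommodates literature-driven additions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def intersection_matrix(dem_sets: dict, min_display: int = 10) -> pd.DataFrame:
    """Exclusive intersections of named DEM sets.

    Every miRNA in the union is assigned to exactly one row keyed by the
    frozenset of contrasts containing it, so row sizes sum to the union size.
    Rows smaller than ``min_display`` are kept but flagged ``below_display``.
    """
    if len(dem_sets) < 2:
        raise ValueError("need at least 2 DEM sets")
    names = list(dem_sets)
    if len(set(names)) != len(names):
        raise ValueError("duplicate contrast names")
    signature: dict = {}
    for name, members in dem_sets.items():
        for m in members:
            signature.setdefault(m, set()).add(name)
    rows = {}
    for m, sig in signature.items():
        rows.setdefault(frozenset(sig), []).append(m)
    table = pd.DataFrame(
        [
            {
                "contrasts": tuple(sorted(sig)),
                "degree": len(sig),
                "size": len(members),
                "members": tuple(sorted(members)),
            }
            for sig, members in rows.items()
        ]
    )
    if table.empty:
        table = pd.DataFrame(columns=["contrasts", "degree", "size", "members"])
    table["below_display"] = table.get("size", pd.Series(dtype=int)) < min_display
    return table.sort_values(
        ["size", "degree"], ascending=[False, False], ignore_index=True
    )


def intersection_significance(
    table: pd.DataFrame,
    set_sizes: dict,
    universe_size: int,
    n_draws: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo significance of each exclusive intersection.

    Null model: independent uniform random sets of the observed sizes drawn
    from a universe of ``universe_size`` miRNAs; p is the (add-one) fraction
    of draws whose exclusive intersection is at least as large as observed.
    For two sets the plain-overlap tail is also hypergeometric, which the test
    suite uses as a cross-check.
    """
    names = list(set_sizes)
    if any(k > universe_size for k in set_sizes.values()):
        raise ValueError("universe smaller than one of the sets")
    rng = np.random.default_rng(seed)
    bit = {name: 1 << i for i, name in enumerate(names)}
    sig_codes = np.array(
        [sum(bit[c] for c in row) for row in table["contrasts"]], dtype=np.int64
    )
    observed = table["size"].to_numpy()

    exceed = np.zeros(len(table), dtype=np.int64)
    n_codes = 1 << len(names)
    for _ in range(n_draws):
        member_code = np.zeros(universe_size, dtype=np.int64)
        for name in names:
            chosen = rng.choice(universe_size, size=set_sizes[name], replace=False)
            member_code[chosen] |= bit[name]
        counts = np.bincount(member_code, minlength=n_codes)
        exceed += counts[sig_codes] >= observed
    out = table.copy()
    out["p"] = (exceed + 1.0) / (n_draws + 1.0)
    return out


def select_candidates(
    results: dict,
    dem_sets: dict,
    intersection_table: pd.DataFrame,
    expr_floor: float = 5.0,
    top_k_intersections: int = 2,
    n_unique: int = 3,
    manual: list | None = None,
) -> pd.DataFrame:
    """Apply the candidate-selection rules.

    Rule (i): all DEMs in the ``top_k_intersections`` most significant
    multi-contrast exclusive intersections.  Rule (ii): per contrast, the
    ``n_unique`` smallest-padj DEMs exclusive to it (ties broken by |log2fc|
    then id).  Manual additions are kept (flagged if absent from the results).
    Every selected miRNA must pass the expression floor: its mean baseMean
    over the contrasts where it is a DEM must be >= ``expr_floor``.
    """
    if "p" not in intersection_table.columns:
        raise ValueError("intersection table lacks significance column 'p'; run "
                         "intersection_significance first")
    base_mean = {}
    for mirna in set().union(*dem_sets.values()) if dem_sets else set():
        vals = [
            results[c].loc[mirna, "baseMean"]
            for c, members in dem_sets.items()
            if mirna in members and mirna in results[c].index
        ]
        base_mean[mirna] = float(np.mean(vals)) if vals else np.nan

    chosen: dict = {}

    def add(mirna, reason, sources):
        if mirna in chosen:
            return
        chosen[mirna] = {"mirna": mirna, "reason": reason,
                         "source_contrasts": ",".join(sorted(sources)), "flag": ""}

    multi = intersection_table[intersection_table["degree"] >= 2]
    multi = multi.sort_values(
        ["p", "size"], ascending=[True, False], kind="mergesort"
    ).head(top_k_intersections)
    for _, row in multi.iterrows():
        for mirna in row["members"]:
            if base_mean.get(mirna, 0.0) >= expr_floor:
                add(mirna, "shared_top_intersections", row["contrasts"])

    singles = intersection_table[intersection_table["degree"] == 1]
    for _, row in singles.iterrows():
        contrast = row["contrasts"][0]
        res = results[contrast]
        members = [m for m in row["members"] if base_mean.get(m, 0.0) >= expr_floor]
        ranked = sorted(
            members,
            key=lambda m: (res.loc[m, "padj"], -abs(res.loc[m, "log2fc"]), m),
        )
        for mirna in ranked[:n_unique]:
            add(mirna, "top_unique", [contrast])

    for mirna in manual or []:
        known = any(mirna in res.index for res in results.values())
        if mirna in chosen:
            continue
        entry = {"mirna": mirna, "reason": "manual", "source_contrasts": "", "flag": ""}
        if not known:
            warnings.warn(f"manual candidate {mirna!r} absent from the count matrix")
            entry["flag"] = "not_in_matrix"
        chosen[mirna] = entry

    cols = ["mirna", "reason", "source_contrasts", "flag"]
    return pd.DataFrame(list(chosen.values()), columns=cols)


def pairwise_overlap_p(size_a: int, size_b: int, overlap: int, universe: int) -> float:
    """Hypergeometric tail P(overlap >= observed) for two uniform random sets."""
    return float(stats.hypergeom.sf(overlap - 1, universe, size_a, size_b))
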