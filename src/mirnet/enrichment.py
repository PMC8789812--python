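"""miRNA-target and gene-set over-representation against user-supplied tables.

All enrichment is one-sided hypergeometric: for a gene g targeted by K of the
M miRNAs in the interaction table, the probability that a uniform random list
of n miRNAs contains at least the observed k targeting miRNAs is
P(X >= k), X ~ Hypergeom(M, K, n).  P-values are BH-corrected, and reported
hits additionally require a minimum number of supporting interactions
(default 2) and, by default, strong experimental evidence.  The enrichment
universe is always the supplied table itself — external web tools' internal
universes are not reproducible and are out of scope.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import adjust_bh

EVIDENCE_CLASSES = ("non-functional", "weak", "strong")

_EVIDENCE_ALIASES = {
    "strong": "strong",
    "strong functional": "strong",
    "strong functional mti": "strong",
    "functional mti": "strong",
    "weak": "weak",
    "weak functional": "weak",
    "functional mti (weak)": "weak",
    "non-functional": "non-functional",
    "nonfunctional": "non-functional",
    "non functional": "non-functional",
    "non-functional mti": "non-functional",
}


def normalize_mti(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize an MTI table: evidence vocabulary, duplicate rows removed."""
    for col in ("mirna", "gene", "evidence"):
        if col not in table.columns:
            raise ValueError(f"MTI table missing column {col!r}")
    out = table.copy()
    ev = out["evidence"].astype(str).str.strip().str.lower()
    unknown = set(ev) - set(_EVIDENCE_ALIASES)
    if unknown:
        raise ValueError(f"unknown evidence label(s): {sorted(unknown)[:5]}")
    out["evidence"] = ev.map(_EVIDENCE_ALIASES)
    return out.drop_duplicates(["mirna", "gene", "evidence"]).reset_index(drop=True)


def classify_mti(table: pd.DataFrame, mirna: str) -> dict:
    """Distinct target-gene counts per evidence class for one miRNA.

    A gene supported by several evidence classes counts once in each class,
    so the class counts can sum to more than the distinct-target total.
    """
    table = normalize_mti(table)
    sub = table[table["mirna"] == mirna]
    if sub.empty:
        warnings.warn(f"miRNA {mirna!r} not present in the MTI table")
    return {
        cls: int(sub.loc[sub["evidence"] == cls, "gene"].nunique())
        for cls in EVIDENCE_CLASSES
    }


def target_enrichment(
    mirna_list: list[str],
    table: pd.DataFrame,
    min_interactions: int = 2,
    fdr: float = 0.05,
    strong_only: bool = True,
) -> pd.DataFrame:
    """Per-gene over-representation of targets of a miRNA list.

    Population = distinct miRNAs in the (evidence-filtered) table; draws = the
    part of the list present in that population.  A gene is ``enriched`` when
    it is hit by at least ``min_interactions`` list miRNAs and its BH-adjusted
    p is below ``fdr``.
    """
    if not mirna_list:
        raise ValueError("miRNA list is empty")
    table = normalize_mti(table)
    if strong_only:
        table = table[table["evidence"] == "strong"]
    population = set(table["mirna"])
    draws = set(mirna_list) & population
    if not draws:
        warnings.warn("miRNA list is disjoint from the MTI table")
        return pd.DataFrame(
            columns=["gene", "hits", "targeting_mirnas", "expected", "p", "fdr",
                     "contributing_mirnas", "enriched"]
        )
    m_total = len(population)
    n_draws = len(draws)
    pairs = table[["mirna", "gene"]].drop_duplicates()
    per_gene = pairs.groupby("gene")["mirna"].agg(set)
    rows = []
    for gene, targeting in per_gene.items():
        k = len(targeting & draws)
        big_k = len(targeting)
        p = float(stats.hypergeom.sf(k - 1, m_total, big_k, n_draws)) if k else 1.0
        rows.append(
            {
                "gene": gene,
                "hits": k,
                "targeting_mirnas": big_k,
                "expected": big_k * n_draws / m_total,
                "p": p,
                "contributing_mirnas": ",".join(sorted(targeting & draws)),
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = adjust_bh(out["p"])
    out["enriched"] = (out["hits"] >= min_interactions) & (out["fdr"] < fdr)
    return out.sort_values(["p", "gene"], ignore_index=True)


def geneset_enrichment(
    genes: list[str], genesets: dict, universe: list[str]
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a gene list per set."""
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    genes_set = set(genes) & universe_set
    if set(genes) - universe_set:
        warnings.warn("gene list contains genes outside the universe; ignored")
    m_total = len(universe_set)
    rows = []
    for name, members in genesets.items():
        members_in = set(members) & universe_set
        k = len(genes_set & members_in)
        p = float(stats.hypergeom.sf(k - 1, m_total, len(members_in), len(genes_set))) if k else 1.0
        rows.append(
            {
                "geneset": name,
                "hits": k,
                "set_size": len(members_in),
                "expected": len(members_in) * len(genes_set) / m_total,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = adjust_bh(out["p"])
    return out.sort_values(["p", "geneset"], ignore_index=True)


def annotate_disease(mirna: str, association_table: pd.DataFrame) -> dict:
    """Disease associations of one miRNA with causality counts.

    Expects columns (mirna, disease, causal).  Rows are de-duplicated before
    counting; returns the filtered rows and (total, causal) summary counts.
    """
    for col in ("mirna", "disease", "causal"):
        if col not in association_table.columns:
            raise ValueError(f"association table missing column {col!r}")
    dedup = association_table.drop_duplicates(["mirna", "disease", "causal"])
    sub = dedup[dedup["mirna"] == mirna]
    return {
        "associations": sub.reset_index(drop=True),
        "total": int(len(sub)),
        "causal": int(sub["causal"].astype(bool).sum()),
    }


def mirna_pathway_table(
    pathway_sets: dict, table: pd.DataFrame, mirna_list: list[str]
) -> pd.DataFrame:
    """Tabular miRNA-augmented pathways: (pathway, gene, repressing miRNA).

    For each pathway gene targeted by a list miRNA, one row — the informational
    content of a miRNA-augmented pathway diagram, without the drawing.
    """
    table = normalize_mti(table)
    sub = table[table["mirna"].isin(mirna_list)][["mirna", "gene"]].drop_duplicates()
    rows = [
        {"pathway": name, "gene": gene, "mirna": mirna}
        for name, members in pathway_sets.items()
        for mirna, gene in sub.itertuples(index=False)
        if gene in set(members)
    ]
    return pd.DataFrame(rows, columns=["pathway", "gene", "mirna"])


def read_gmt(path) -> dict:
    """Read a GMT gene-set file (name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict, path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
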