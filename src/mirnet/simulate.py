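"""Synthetic serum small-RNA cohorts with known ground truth.

Generates UMI count matrices shaped like a multi-site serum miRNA-seq study
(phenotype groups dnPD / CTR / CENT / adPD / PDsibs across sites GOE / UNIBO /
SAS), plus the auxiliary inputs of the downstream stages: UMI-tagged read
records, qPCR Ct tables, miRNA-target interaction tables and gene-set
collections.  Every generator is deterministic given its seed.

Counts follow a negative-binomial model

    counts_ij ~ NB(mean = s_j * q_i * 2**beta[i, group(j)],  dispersion alpha_i)

with log-normal baseline expression ``q_i``, log-normal sample depth factors
``s_j`` and multiplicative planted group effects ``2**beta``.  Co-expression
blocks are induced by a Gaussian copula: a latent block-equicorrelated normal
layer is pushed through the per-entry NB quantile function, which plants rank
correlation without altering the NB marginals.
"""

from __future__ import annotations

import string
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("dnPD", "CTR", "CENT", "adPD", "PDsibs")
SITES = ("GOE", "UNIBO", "SAS")

#: Discovery-cohort composition: 61 drug-naive patients and 58 age-matched
#: controls from Goettingen, 19 controls and 27 centenarians from Bologna
#: (165 serum samples in total).
DEFAULT_GROUP_SIZES = {"dnPD": 61, "CTR": 77, "CENT": 27}
DEFAULT_SITE_OF_GROUP = {
    "dnPD": "GOE",
    "CTR": {"GOE": 58, "UNIBO": 19},
    "CENT": "UNIBO",
    "adPD": "GOE",
    "PDsibs": "SAS",
}


@dataclass
class BlockSpec:
    """A planted co-expression block: ``size`` miRNAs at Spearman ``rho``."""

    size: int
    rho: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"block rho must be in [0, 1), got {self.rho}")
        if self.size < 2:
            raise ValueError(f"block size must be >= 2, got {self.size}")


@dataclass
class DESpec:
    """Planted differential expression for one group vs the baseline."""

    fraction: float
    log2fc: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("de fraction must be in [0, 1]")
        if not np.isfinite(self.log2fc):
            raise ValueError("de log2fc must be finite")


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the discovery cohort: ~2,500 expressed miRNAs over 165
    serum samples in three phenotype groups at two collection sites, with
    moderate NB overdispersion and ~2x spread in sequencing depth.  The study
    publishes no count-distribution parameters, so the expression-scale
    defaults are realistic free choices, not calibrated values.
    """

    n_mirnas: int = 2500
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    site_of_group: dict = field(default_factory=lambda: dict(DEFAULT_SITE_OF_GROUP))
    depth_logsd: float = 0.35
    basemean_logmu: float = 3.0
    basemean_logsd: float = 1.6
    dispersion: float | tuple = 0.15  # constant alpha, or ("gamma", shape, scale)
    de_spec: dict = field(default_factory=dict)  # group -> DESpec (or (frac, lfc))
    module_spec: list = field(default_factory=list)  # list of BlockSpec / (size, rho)
    seed: int = 0

    def __post_init__(self) -> None:
        for g in self.group_sizes:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}; expected one of {GROUPS}")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs at least 2 samples")
        if self.n_mirnas <= 0:
            raise ValueError("n_mirnas must be positive")
        self.module_spec = [
            b if isinstance(b, BlockSpec) else BlockSpec(*b) for b in self.module_spec
        ]
        self.de_spec = {
            g: (s if isinstance(s, DESpec) else DESpec(*s))
            for g, s in self.de_spec.items()
        }
        if sum(b.size for b in self.module_spec) > self.n_mirnas:
            raise ValueError("module_spec blocks exceed n_mirnas")


@dataclass
class GroundTruth:
    """What was planted: per-group log2 effects, block ids, true depth factors."""

    de_log2fc: pd.DataFrame  # miRNA x group, 0 where null
    module_membership: pd.Series  # miRNA -> block id (int) or "none"
    size_factors_true: pd.Series  # sample -> positive real


def _latent_rho(spearman_rho: float) -> float:
    """Latent normal correlation hitting a Spearman target (2 sin(pi rho/6))."""
    return 2.0 * np.sin(np.pi * spearman_rho / 6.0)


def _nb_quantile(u: np.ndarray, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB quantile with mean/dispersion parameterization (alpha=0 -> Poisson)."""
    if alpha <= 0:
        return stats.poisson.ppf(u, mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return stats.nbinom.ppf(u, r, p)


def _make_samplesheet(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for group, n in config.group_sizes.items():
        site_spec = config.site_of_group.get(group, SITES[0])
        if isinstance(site_spec, dict):
            total = sum(site_spec.values())
            if total == n:
                alloc = dict(site_spec)
            else:
                # rescale the split proportionally to the requested group size
                keys = list(site_spec)
                alloc = {s: int(round(site_spec[s] * n / total)) for s in keys}
                alloc[keys[0]] += n - sum(alloc.values())
            sites = [s for s, k in alloc.items() for _ in range(k)]
        else:
            sites = [site_spec] * n
        for k, site in enumerate(sites):
            rows.append(
                {
                    "sample": f"{group}_{site}_{k:03d}",
                    "group": group,
                    "site": site,
                    "age": float(np.round(rng.normal(105 if group == "CENT" else 66, 6), 1)),
                    "sex": rng.choice(["M", "F"]),
                }
            )
    return pd.DataFrame(rows).set_index("sample")


def generate_cohort(config: SimConfig):
    """Draw a synthetic cohort.

    Returns ``(counts, samplesheet, truth)`` where ``counts`` is a
    miRNA x sample integer DataFrame, ``samplesheet`` carries group/site/age/sex
    per sample, and ``truth`` records everything that was planted.
    """
    rng = np.random.default_rng(config.seed)
    mirnas = [f"miR-sim-{i:04d}" for i in range(config.n_mirnas)]

    samplesheet = _make_samplesheet(config, rng)
    n_samples = len(samplesheet)
    s = np.exp(rng.normal(0.0, config.depth_logsd, n_samples))
    s /= np.exp(np.mean(np.log(s)))  # geometric mean 1: identifiable depths

    q = np.exp(rng.normal(config.basemean_logmu, config.basemean_logsd, config.n_mirnas))

    disp = config.dispersion
    if isinstance(disp, tuple):
        _, shape, scale = disp
        alpha = rng.gamma(shape, scale, config.n_mirnas)
    else:
        alpha = np.full(config.n_mirnas, float(disp))

    # planted group effects on log2 scale, sign split evenly
    beta = pd.DataFrame(0.0, index=mirnas, columns=list(config.group_sizes))
    for group, spec in config.de_spec.items():
        n_de = int(round(spec.fraction * config.n_mirnas))
        chosen = rng.choice(config.n_mirnas, size=n_de, replace=False)
        signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
        beta.iloc[chosen, beta.columns.get_loc(group)] = signs * abs(spec.log2fc)

    # block membership: contiguous blocks over a seeded shuffle of the rows
    membership = pd.Series("none", index=mirnas, dtype=object)
    order = rng.permutation(config.n_mirnas)
    pos = 0
    block_rows: list[np.ndarray] = []
    for b, block in enumerate(config.module_spec):
        idx = order[pos : pos + block.size]
        membership.iloc[idx] = b
        block_rows.append(idx)
        pos += block.size

    # Gaussian-copula uniforms: block rows share a per-sample latent factor
    u = rng.random((config.n_mirnas, n_samples))
    for block, idx in zip(config.module_spec, block_rows):
        rho = _latent_rho(block.rho)
        shared = rng.normal(0.0, 1.0, n_samples)
        eps = rng.normal(0.0, 1.0, (len(idx), n_samples))
        z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps
        u[idx] = stats.norm.cdf(z)

    group_of = samplesheet["group"].to_numpy()
    mean = (
        s[None, :]
        * q[:, None]
        * np.power(2.0, beta.loc[:, group_of].to_numpy(dtype=float))
    )

    counts = np.empty((config.n_mirnas, n_samples), dtype=np.int64)
    in_block = membership.to_numpy() != "none"
    # block rows go through the NB quantile (copula); the rest are drawn
    # directly, which is both equivalent in distribution and much faster
    if in_block.any():
        for i in np.where(in_block)[0]:
            counts[i] = _nb_quantile(u[i], mean[i], alpha[i]).astype(np.int64)
    free = np.where(~in_block)[0]
    for i in free:
        if alpha[i] <= 0:
            counts[i] = rng.poisson(mean[i])
        else:
            r = 1.0 / alpha[i]
            p = r / (r + mean[i])
            counts[i] = rng.negative_binomial(r, p)

    counts_df = pd.DataFrame(counts, index=mirnas, columns=samplesheet.index)
    truth = GroundTruth(
        de_log2fc=beta,
        module_membership=membership,
        size_factors_true=pd.Series(s, index=samplesheet.index, name="size_factor"),
    )
    return counts_df, samplesheet, truth


# ---------------------------------------------------------------------------
# UMI read records (the inverse of UMI collapse)
# ---------------------------------------------------------------------------

_B36 = string.digits + string.ascii_uppercase


def _seq_for(mirna: str) -> str:
    """Deterministic synthetic 22-mer for a miRNA id (stable across calls)."""
    r = np.random.default_rng(zlib.crc32(mirna.encode()))
    return "".join(r.choice(list("ACGT"), 22))


def generate_read_records(
    counts: pd.DataFrame, duplication_rate: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Expand a count matrix into UMI-tagged read records.

    Each unit of count becomes one distinct ``(sequence, umi)`` pair, replicated
    ``1 + Poisson(duplication_rate)`` times to mimic PCR duplicates.  UMIs encode
    a global counter in base-36 (length 12), so collisions are impossible by
    construction; ``collapse_umis`` inverts this exactly at any duplication rate.
    """
    if duplication_rate < 0:
        raise ValueError("duplication_rate must be >= 0")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)

    samples: list[str] = []
    mirnas: list[str] = []
    umis: list[str] = []
    counter = 0
    arr = counts.to_numpy()
    for i, mirna in enumerate(counts.index):
        for j, sample in enumerate(counts.columns):
            c = int(arr[i, j])
            for _ in range(c):
                code = counter
                umi = ""
                for _k in range(12):
                    umi = _B36[code % 36] + umi
                    code //= 36
                counter += 1
                reps = 1 + int(rng.poisson(duplication_rate))
                samples.extend([sample] * reps)
                mirnas.extend([mirna] * reps)
                umis.extend([umi] * reps)
    seqs = [_seq_for(m) for m in mirnas]
    records = pd.DataFrame(
        {"sample": samples, "mirna": mirnas, "sequence": seqs, "umi": umis}
    )
    # shuffle so downstream code cannot rely on emission order
    return records.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


def generate_ct_table(
    targets: list[str],
    group_sizes: dict,
    planted_log2fc: dict,
    controls: list[str],
    reference_group: str,
    noise_sd: float = 0.3,
    n_replicates: int = 2,
    seed: int = 0,
):
    """Simulate a long-format Ct table for comparative-Ct analysis.

    ``planted_log2fc`` maps group -> {target: log2FC vs the reference group}.
    Ct values are ``baseline_t - log2(relative expression) + N(0, noise_sd)``
    with per-sample noise, duplicated over technical replicates, so with
    ``noise_sd = 0`` the downstream RQ is exactly ``2**log2FC``.  Endogenous
    controls must be present with planted effect 0.

    Returns ``(ct_table, truth)`` where ``truth`` is a target x group DataFrame
    of planted log2 fold-changes.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    missing = [c for c in controls if c not in targets]
    if missing:
        raise ValueError(f"endogenous controls missing from targets: {missing}")
    for g, effects in planted_log2fc.items():
        for c in controls:
            if effects.get(c, 0.0) != 0.0:
                raise ValueError(f"control {c!r} must have planted log2fc 0")

    rng = np.random.default_rng(seed)
    baseline = {t: rng.uniform(22.0, 30.0) for t in targets}
    truth = pd.DataFrame(0.0, index=targets, columns=list(group_sizes))
    rows = []
    for group, n in group_sizes.items():
        effects = planted_log2fc.get(group, {}) if group != reference_group else {}
        for t, lfc in effects.items():
            truth.loc[t, group] = lfc
        for k in range(n):
            sample = f"{group}_{k:03d}"
            for t in targets:
                lfc = effects.get(t, 0.0)
                ct = baseline[t] - lfc + rng.normal(0.0, noise_sd)
                for rep in range(1, n_replicates + 1):
                    rows.append(
                        {
                            "sample": sample,
                            "group": group,
                            "target": t,
                            "replicate": rep,
                            "ct": ct,
                        }
                    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# miRNA-target interactions and gene sets
# ---------------------------------------------------------------------------


def generate_mti_table(
    n_mirnas: int,
    n_genes: int,
    density: float,
    strong_fraction: float = 0.11,
    nonfunctional_fraction: float = 0.015,
    seed: int = 0,
) -> pd.DataFrame:
    """Random bipartite miRNA-target table with graded evidence labels.

    A synthetic stand-in for curated MTI resources: each (miRNA, gene) pair is
    included with probability ``density`` and labelled strong / weak /
    non-functional.  Default label proportions mirror the roughly 11% strong,
    ~1.5% non-functional split seen in curated collections.
    """
    if n_mirnas <= 0 or n_genes <= 0:
        raise ValueError("n_mirnas and n_genes must be positive")
    if not (0.0 <= density <= 1.0 and 0.0 <= strong_fraction <= 1.0):
        raise ValueError("density and strong_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = rng.random((n_mirnas, n_genes)) < density
    mi, gi = np.nonzero(mask)
    weak = max(0.0, 1.0 - strong_fraction - nonfunctional_fraction)
    probs = np.array([strong_fraction, weak, nonfunctional_fraction])
    probs = probs / probs.sum() if probs.sum() > 0 else np.array([0.0, 1.0, 0.0])
    labels = rng.choice(["strong", "weak", "non-functional"], size=len(mi), p=probs)
    return pd.DataFrame(
        {
            "mirna": [f"miR-sim-{i:04d}" for i in mi],
            "gene": [f"GENE{j:05d}" for j in gi],
            "evidence": labels,
        }
    )


def generate_gene_sets(
    genes: list[str],
    n_sets: int = 20,
    size_range: tuple[int, int] = (10, 50),
    seed: int = 0,
) -> dict:
    """Random gene-set collection (GMT-style dict name -> member genes)."""
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    if lo < 1 or hi < lo or hi > len(genes):
        raise ValueError("invalid size_range for the given gene universe")
    return {
        f"SET_{k:03d}": sorted(rng.choice(genes, size=int(rng.integers(lo, hi + 1)), replace=False))
        for k in range(n_sets)
    }
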