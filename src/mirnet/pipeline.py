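"""End-to-end orchestration: discovery and validation runs with provenance.

``run_discovery`` executes preprocessing -> differential expression ->
candidate selection -> per-cohort network reconstruction -> community
detection -> DEM/community integration, writing every artifact as a
header-annotated TSV plus a JSON manifest (stage order, parameter hash,
output checksums, warnings).  ``run_validation`` runs the comparative-Ct
qPCR analysis for a candidate list across test groups.  Both are plain
functions over DataFrames; the example scripts are the user interface.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .communities import integrate_dems, louvain, node_degrees
from .diffexpr import call_dems, default_contrasts, run_contrasts
from .network import NetworkParams, build_network
from .preprocess import filter_expressed, pca_qc, size_factors
from .qpcr import rq_test, aggregate_replicates, delta_ct
from .selection import intersection_matrix, intersection_significance, select_candidates


@dataclass
class DiscoveryConfig:
    out_dir: str
    seed: int = 0
    contrasts: list | None = None  # default: the discovery scheme
    dem_alpha: float = 0.05
    expr_floor: float = 5.0
    top_k_intersections: int = 2
    n_unique: int = 3
    manual_candidates: list = field(default_factory=list)
    network_groups: tuple = ("dnPD", "CENT")
    network_params: NetworkParams | None = None
    louvain_resolution: float = 1.0
    pseudo_reference: bool = False
    pca_top: int = 500


@dataclass
class ValidationConfig:
    out_dir: str
    candidates: list = field(default_factory=list)
    controls: list = field(default_factory=lambda: ["miR-186-5p"])
    test_groups: tuple = ("dnPD", "adPD", "PDsibs")
    reference_group: str = "CTR"
    alpha: float = 0.05


def _param_hash(obj) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, seed, params_hash: str, index=True) -> str:
    """TSV with a provenance header; returns the content checksum."""
    header = f"# mirnet {__version__} seed={seed} params={params_hash}\n"
    body = df.to_csv(sep="\t", index=index)
    path.write_text(header + body)
    return hashlib.sha256(body.encode()).hexdigest()[:16]


def read_artifact_tsv(path, **kwargs) -> pd.DataFrame:
    """Read a pipeline TSV, skipping the provenance header."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def run_discovery(counts: pd.DataFrame, samplesheet: pd.DataFrame | None, config: DiscoveryConfig) -> dict:
    """Execute the discovery pipeline; returns the artifacts in memory.

    Stage order: expressed filter and normalization, PCA QC, NB Wald contrasts,
    DEM calling, exclusive-intersection significance, candidate selection,
    per-phenotype ARACNE network, Louvain communities, degree statistics and
    DEM-community integration.  Fails before writing anything if inputs are
    incomplete; any stage failure aborts with the stage name.
    """
    if samplesheet is None:
        raise ValueError("sample sheet is required (got None)")
    missing = set(counts.columns) - set(samplesheet.index)
    if missing:
        raise ValueError(f"samples missing from sample sheet: {sorted(missing)[:5]}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    phash = _param_hash(config)
    manifest = {
        "tool": f"mirnet {__version__}",
        "seed": config.seed,
        "params_hash": phash,
        "stages": [],
        "checksums": {},
        "warnings": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    artifacts: dict = {}

    def stage(name):
        manifest["stages"].append(name)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        stage("preprocessing")
        expressed = filter_expressed(counts)
        norm = size_factors(expressed, pseudo_reference=config.pseudo_reference)
        coords, evr = pca_qc(norm, n_top_variance=config.pca_top)
        artifacts["size_factors"] = norm.size_factors
        artifacts["pca"] = coords
        manifest["checksums"]["size_factors.tsv"] = _write_tsv(
            norm.size_factors.to_frame(), out / "size_factors.tsv", config.seed, phash
        )
        manifest["checksums"]["pca.tsv"] = _write_tsv(coords, out / "pca.tsv", config.seed, phash)

        stage("diffexpr")
        specs = config.contrasts or default_contrasts(samplesheet)
        results = run_contrasts(
            counts, samplesheet, specs, pseudo_reference=config.pseudo_reference
        )
        dem_sets = {name: call_dems(res, config.dem_alpha) for name, res in results.items()}
        artifacts["contrasts"] = results
        artifacts["dem_sets"] = dem_sets
        for name, res in results.items():
            manifest["checksums"][f"de_{name}.tsv"] = _write_tsv(
                res, out / f"de_{name}.tsv", config.seed, phash
            )

        stage("selection")
        nonempty = {k: v for k, v in dem_sets.items() if v}
        if len(nonempty) >= 2:
            table = intersection_matrix(nonempty)
            table = intersection_significance(
                table,
                {k: len(v) for k, v in nonempty.items()},
                universe_size=len(expressed),
                seed=config.seed,
            )
            candidates = select_candidates(
                results,
                nonempty,
                table,
                expr_floor=config.expr_floor,
                top_k_intersections=config.top_k_intersections,
                n_unique=config.n_unique,
                manual=config.manual_candidates,
            )
        else:
            table = pd.DataFrame()
            candidates = pd.DataFrame(columns=["mirna", "reason", "source_contrasts", "flag"])
            manifest["warnings"].append("fewer than 2 non-empty DEM sets; selection skipped")
        artifacts["intersections"] = table
        artifacts["candidates"] = candidates
        manifest["checksums"]["intersections.tsv"] = _write_tsv(
            table, out / "intersections.tsv", config.seed, phash, index=False
        )
        manifest["checksums"]["candidates.tsv"] = _write_tsv(
            candidates, out / "candidates.tsv", config.seed, phash, index=False
        )

        net_params = config.network_params or NetworkParams(seed=config.seed)
        artifacts["networks"] = {}
        artifacts["partitions"] = {}
        artifacts["degrees"] = {}
        artifacts["integration"] = {}
        for group in config.network_groups:
            if group not in set(samplesheet["group"]):
                manifest["warnings"].append(f"network group {group!r} absent; skipped")
                continue
            stage(f"network:{group}")
            net = build_network(counts, samplesheet, group, net_params)
            stage(f"communities:{group}")
            part = louvain(net, resolution=config.louvain_resolution, seed=config.seed)
            degrees = node_degrees(net, part)
            overlaps, summary = integrate_dems(part, dem_sets)
            artifacts["networks"][group] = net
            artifacts["partitions"][group] = part
            artifacts["degrees"][group] = degrees
            artifacts["integration"][group] = (overlaps, summary)
            manifest["checksums"][f"network_{group}.tsv"] = _write_tsv(
                net.edges, out / f"network_{group}.tsv", config.seed, phash, index=False
            )
            manifest["checksums"][f"communities_{group}.tsv"] = _write_tsv(
                part.membership.to_frame(), out / f"communities_{group}.tsv", config.seed, phash
            )
            manifest["checksums"][f"degrees_{group}.tsv"] = _write_tsv(
                degrees, out / f"degrees_{group}.tsv", config.seed, phash
            )
            manifest["checksums"][f"integration_{group}.tsv"] = _write_tsv(
                summary, out / f"integration_{group}.tsv", config.seed, phash, index=False
            )

        manifest["warnings"].extend(str(w.message) for w in caught)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    artifacts["manifest"] = manifest
    return artifacts


def run_validation(ct_table: pd.DataFrame, config: ValidationConfig) -> pd.DataFrame:
    """Comparative-Ct validation of candidates across test groups.

    Candidates absent from the Ct table are reported with a flag rather than
    failing the run.  Returns the combined RQ result table (one block per
    test group vs the reference).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not config.candidates:
        warnings.warn("empty candidate list: validation report is empty")
    measured = set(ct_table["target"])
    blocks = []
    for candidate in config.candidates:
        if candidate not in measured:
            blocks.append(
                pd.DataFrame(
                    [{"target": candidate, "flag": "not_measured"}]
                )
            )
    dct = delta_ct(aggregate_replicates(ct_table), config.controls)
    present = [c for c in config.candidates if c in measured]
    for group in config.test_groups if present else ():
        if group not in set(ct_table["group"]):
            continue
        res = rq_test(
            dct[dct["target"].isin(present)],
            group,
            config.reference_group,
            alpha=config.alpha,
            exclude=config.controls,
        )
        blocks.append(res)
    report = pd.concat(blocks, ignore_index=True) if blocks else pd.DataFrame()
    _write_tsv(report, out / "validation_rq.tsv", seed="-", params_hash=_param_hash(config), index=False)
    return report
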