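"""End-to-end orchestration: QC -> harmonize -> covariance -> scans ->
classification -> inflation diagnostics -> gene tests -> expression models.

A run is driven by one declarative config (YAML-friendly dict) and writes
tab-delimited stage outputs plus a JSON manifest recording versions, seeds,
input digests and per-stage row counts, so two runs with identical config
and inputs produce identical result-file checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .genebased import (
    DEFAULT_STAGES,
    DEFAULT_WINDOW,
    read_dosage_table,
    read_gene_models,
    run_gene_tests,
)
from .joint import estimate_covariance, genomic_lambda, joint_scan, qq_table
from .sumstats import harmonize, qc_filter, read_sumstats

logger = logging.getLogger("pleioscan")

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

STAGES = ("qc", "harmonize", "covariance", "scan", "classify", "diagnostics", "gene_tests")


@dataclasses.dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    traits: dict[str, dict]  # label -> {path, column_map}
    out_dir: str
    subsets: list[list[str]] | None = None  # default: all pairs + full set
    weights: str = "gls"
    gws: float = 5e-8
    nominal: float = 0.05
    magnitude_factor: float = 10.0
    covariance_mode: str = "all_snps"
    qc: dict = dataclasses.field(
        default_factory=lambda: {"maf_max_excl": 0.01, "r2_min_excl": 0.4, "dosvar_min_excl": 0.02}
    )
    gene_tests: dict | None = None  # {genes, panel, window, stages, seed}
    exclude_region: list | None = None  # [chrom, start, end] for lambda

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def validate_config(config: RunConfig) -> list[str]:
    """Return the list of violations (empty means valid); each names the
    offending field and constraint."""
    v: list[str] = []
    if not config.traits:
        v.append("traits: at least one trait table is required")
    for thr in ("gws", "nominal"):
        val = getattr(config, thr)
        if not 0 < val < 1:
            v.append(f"{thr} must be in (0,1), got {val}")
    if config.magnitude_factor < 1:
        v.append(f"magnitude_factor must be >= 1, got {config.magnitude_factor}")
    if config.weights not in ("gls", "equal"):
        v.append(f"weights must be gls or equal, got {config.weights!r}")
    if config.covariance_mode not in ("all_snps", "truncated"):
        v.append(f"covariance_mode must be all_snps or truncated, got {config.covariance_mode!r}")
    labels = set(config.traits)
    for subset in config.subsets or []:
        if len(set(subset)) != len(subset):
            v.append(f"subsets: duplicate trait in {subset}")
        for t in subset:
            if t not in labels:
                v.append(f"subsets: unknown trait {t!r}")
    if config.gene_tests is not None:
        gt = config.gene_tests
        if "seed" not in gt:
            v.append("gene_tests.seed is required when gene tests are enabled")
        for key in ("genes", "panel"):
            if key not in gt:
                v.append(f"gene_tests.{key} is required when gene tests are enabled")
    return v


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every enabled stage; returns (and writes) the run manifest.

    Any stage failure aborts with the stage name prefixed to the error.
    """
    violations = validate_config(config)
    if violations:
        raise ConfigurationError("invalid config: " + "; ".join(violations))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "pleioscan_version": __version__,
        "stages": [],
        "inputs": {},
        "outputs": {},
    }

    def stage(name: str, **counts):
        logger.info("stage %s: %s", name, counts)
        manifest["stages"].append({"name": name, **counts})

    try:
        traits = []
        for label, entry in config.traits.items():
            ss, load_rep = read_sumstats(
                entry["path"], entry.get("column_map"), trait_label=label
            )
            manifest["inputs"][label] = {"path": str(entry["path"]), "sha256": _digest(Path(entry["path"]))}
            ss, qc_rep = qc_filter(ss, **config.qc)
            stage(f"qc[{label}]", loaded=load_rep.n_kept, kept=qc_rep.n_kept,
                  excluded=qc_rep.n_excluded)
            traits.append(ss)
    except Exception as exc:
        raise type(exc)(f"stage qc: {exc}") from exc

    try:
        aligned, rep = harmonize(traits)
        aligned.write(out / "aligned.tsv")
        stage("harmonize", **rep)
    except Exception as exc:
        raise type(exc)(f"stage harmonize: {exc}") from exc

    try:
        Z = aligned.z_matrix()
        Sigma = estimate_covariance(Z, mode=config.covariance_mode)
        pd.DataFrame(Sigma.sigma, index=Z.traits, columns=Z.traits).to_csv(
            out / "covariance.tsv", sep="\t", float_format="%.17g"
        )
        stage("covariance", m_used=Sigma.m_used, mode=Sigma.mode)
    except Exception as exc:
        raise type(exc)(f"stage covariance: {exc}") from exc

    labels = list(Z.traits)
    subsets = config.subsets
    if subsets is None:
        subsets = [list(p) for p in itertools.combinations(labels, 2)]
        if len(labels) >= 3:
            subsets.append(labels)
    scans: dict[str, pd.DataFrame] = {}
    try:
        for subset in subsets:
            tag = "_".join(subset)
            res = joint_scan(
                Z, Sigma, subset, weights=config.weights, gws=config.gws,
                magnitude_factor=config.magnitude_factor, nominal=config.nominal,
            )
            res.to_csv(out / f"scan_{tag}.tsv", sep="\t", index=False, float_format="%.10g")
            scans[tag] = res
            n_pleio = int((res["pleio_class"] != "not_pleiotropic").sum())
            n_gws = int((res["pleio_class"] == "gws_pleiotropic").sum())
            stage(f"scan[{tag}]", n_snps=len(res), n_pleiotropic=n_pleio, n_gws=n_gws)
    except Exception as exc:
        raise type(exc)(f"stage scan: {exc}") from exc

    try:
        lam_rows = []
        excl = tuple(config.exclude_region) if config.exclude_region else None
        for tag, res in scans.items():
            lam = genomic_lambda(
                res["p_joint"], chrom=res["chrom"], pos=res["pos"], exclude_region=excl
            )
            lam_rows.append({"scan": tag, "lambda": lam})
            qq_table(res["p_joint"]).to_csv(
                out / f"qq_{tag}.tsv", sep="\t", index=False, float_format="%.10g"
            )
        pd.DataFrame(lam_rows).to_csv(out / "lambda.tsv", sep="\t", index=False,
                                      float_format="%.10g")
        stage("diagnostics", n_scans=len(lam_rows))
    except Exception as exc:
        raise type(exc)(f"stage diagnostics: {exc}") from exc

    if config.gene_tests is not None:
        try:
            gt = config.gene_tests
            genes = read_gene_models(gt["genes"])
            panel_snps, panel_X = read_dosage_table(gt["panel"])
            for tag, res in scans.items():
                table = run_gene_tests(
                    res[["snp_id", "chrom", "pos"]], res["log10p_joint"].to_numpy(),
                    genes, panel_X, panel_snps["snp_id"],
                    window=int(gt.get("window", DEFAULT_WINDOW)),
                    stages=gt.get("stages", DEFAULT_STAGES),
                    seed=int(gt["seed"]),
                )
                table.to_csv(out / f"genes_{tag}.tsv", sep="\t", index=False,
                             float_format="%.10g")
            stage("gene_tests", n_genes=len(genes), n_scans=len(scans))
        except Exception as exc:
            raise type(exc)(f"stage gene_tests: {exc}") from exc

    for f in sorted(out.glob("*.tsv")):
        manifest["outputs"][f.name] = _digest(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
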