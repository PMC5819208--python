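"""Differential-expression and cis-eQTL linear models for follow-up of scan hits.

Per candidate gene, expression (already normalized upstream — this module
deliberately takes normalized matrices as its contract) is regressed on AD
status (DGE) or on SNP dosage (eQTL) with the covariate sets used in brain
expression studies, including the five CNS cell-type marker genes (ENO2
neurons, GFAP astrocytes, CD68 microglia, OLIG2 oligodendrocytes, CD34
endothelial cells) that absorb disease-driven shifts in cell composition.

Sign convention: a negative status beta means lower expression in AD cases
than controls; a negative eQTL beta means lower expression per
effect-allele copy.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigurationError, InputError

__all__ = [
    "ExpressionStudy",
    "ExpressionResult",
    "COVARIATE_PRESETS",
    "CELL_MARKERS",
    "dge_lm",
    "eqtl_lm",
    "correct_multiple",
]

CELL_MARKERS = ("ENO2", "GFAP", "CD68", "OLIG2", "CD34")

#: named covariate sets; "markers" pulls in the five cell-type genes
COVARIATE_PRESETS: dict[str, dict] = {
    # RNA-Seq DGE design: age, sex, RIN, tissue source, flow cell + markers
    "mayo_rnaseq": {
        "numeric": ("age_at_death", "rin"),
        "categorical": ("sex", "tissue_source", "flow_cell"),
        "markers": True,
    },
    # microarray DGE design: RIN, PMI, batch, preservation, pH, age, sex + markers
    "geo_microarray": {
        "numeric": ("rin", "pmi", "ph", "age_at_death"),
        "categorical": ("sex", "batch", "preservation"),
        "markers": True,
    },
    # eQTL design: AD status, APOE-e4 dosage, age, sex, plate, RIN, adjusted RIN
    "mayo_egwas": {
        "numeric": ("status", "apoe4", "age_at_death", "rin", "rin_adj"),
        "categorical": ("sex", "plate"),
        "markers": False,
    },
}


@dataclasses.dataclass
class ExpressionResult:
    """Per-gene effect of the term of interest (status or dosage)."""

    gene_id: str
    beta: float
    se: float
    p: float
    n_used: int
    significant: bool | None = None


@dataclasses.dataclass
class ExpressionStudy:
    """Normalized expression with sample covariates and optional genotypes.

    ``expression`` is gene x sample; ``covariates`` is sample x field and must
    include ``status`` coded AD/control (or 1/0).  ``markers`` holds the
    per-sample expression of the five cell-type genes; ``dosages`` maps SNP id
    to a per-sample dosage Series in [0, 2].
    """

    expression: pd.DataFrame
    covariates: pd.DataFrame
    markers: pd.DataFrame | None = None
    dosages: dict[str, pd.Series] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if not self.expression.columns.equals(self.covariates.index):
            if set(self.expression.columns) != set(self.covariates.index):
                raise InputError("expression columns and covariate index disagree")
            self.covariates = self.covariates.loc[self.expression.columns]
        if "status" not in self.covariates.columns:
            raise InputError("covariates must include 'status'")

    @property
    def status01(self) -> pd.Series:
        s = self.covariates["status"]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            return (s.astype(str).str.upper() == "AD").astype(float)
        return s.astype(float)

    def write(self, expr_path, covar_path) -> None:
        self.expression.to_csv(expr_path, sep="\t", float_format="%.10g")
        side = self.covariates.copy()
        if self.markers is not None:
            for m in self.markers.columns:
                side[f"marker_{m}"] = self.markers[m]
        side.to_csv(covar_path, sep="\t", float_format="%.10g")

    @classmethod
    def read(cls, expr_path, covar_path) -> "ExpressionStudy":
        expr = pd.read_csv(expr_path, sep="\t", index_col=0)
        side = pd.read_csv(covar_path, sep="\t", index_col=0)
        marker_cols = [c for c in side.columns if c.startswith("marker_")]
        markers = None
        if marker_cols:
            markers = side[marker_cols].rename(columns=lambda c: c[len("marker_"):])
            side = side.drop(columns=marker_cols)
        expr.columns = expr.columns.astype(str)
        side.index = side.index.astype(str)
        return cls(expr, side, markers)


def _design(
    study: ExpressionStudy,
    covariate_set: str,
    rin_adjusted: str = "centered_squared",
    drop: Sequence[str] = (),
) -> pd.DataFrame:
    if covariate_set not in COVARIATE_PRESETS:
        raise ConfigurationError(
            f"unknown covariate preset {covariate_set!r} (have {sorted(COVARIATE_PRESETS)})"
        )
    preset = COVARIATE_PRESETS[covariate_set]
    cov = study.covariates.copy()
    cov["status"] = study.status01
    if "rin_adj" in preset["numeric"] and "rin_adj" not in cov.columns:
        rin = cov["rin"].astype(float)
        if rin_adjusted == "centered_squared":
            cov["rin_adj"] = (rin - rin.mean()) ** 2
        elif rin_adjusted == "verbatim":
            cov["rin_adj"] = rin - rin.mean() ** 2
        else:
            raise ConfigurationError(f"unknown rin_adjusted form {rin_adjusted!r}")
    cols = {}
    for name in preset["numeric"]:
        if name in drop:
            continue
        if name not in cov.columns:
            raise ConfigurationError(f"covariate {name!r} missing from study covariates")
        cols[name] = pd.to_numeric(cov[name], errors="coerce")
    frame = pd.DataFrame(cols, index=cov.index)
    for name in preset["categorical"]:
        if name in drop:
            continue
        if name not in cov.columns:
            raise ConfigurationError(f"covariate {name!r} missing from study covariates")
        dummies = pd.get_dummies(cov[name].astype(str), prefix=name, drop_first=True)
        frame = pd.concat([frame, dummies.astype(float)], axis=1)
    if preset["markers"]:
        if study.markers is None:
            raise ConfigurationError(
                f"preset {covariate_set!r} needs cell-marker expression but the study has none"
            )
        for m in study.markers.columns:
            frame[f"marker_{m}"] = study.markers[m].astype(float)
    return frame


def _fit_term(
    gene_id: str, yvals: pd.Series, term: pd.Series, design: pd.DataFrame
) -> ExpressionResult:
    X = pd.concat([term.rename("_term"), design], axis=1)
    data = pd.concat([yvals.rename("_y"), X], axis=1).dropna()  # listwise deletion
    y = data["_y"].to_numpy(dtype=float)
    Xm = sm.add_constant(data.drop(columns="_y").astype(float), has_constant="add")
    n_used = len(data)
    if n_used - Xm.shape[1] < 10:
        raise InputError(
            f"{gene_id}: only {n_used - Xm.shape[1]} residual degrees of freedom (need >= 10)"
        )
    rank = np.linalg.matrix_rank(Xm.to_numpy())
    if rank < Xm.shape[1]:
        # name columns involved in the collinearity via QR pivoting
        q, r = np.linalg.qr(Xm.to_numpy())
        small = np.abs(np.diag(r)) < 1e-8 * np.abs(np.diag(r)).max()
        bad = [c for c, s in zip(Xm.columns, small) if s]
        raise InputError(f"{gene_id}: design is rank deficient; collinear columns {bad}")
    fit = sm.OLS(y, Xm).fit()
    return ExpressionResult(
        gene_id=gene_id,
        beta=float(fit.params["_term"]),
        se=float(fit.bse["_term"]),
        p=float(fit.pvalues["_term"]),
        n_used=n_used,
    )


def dge_lm(
    study: ExpressionStudy,
    gene: str,
    covariate_set: str = "mayo_rnaseq",
) -> ExpressionResult:
    """Differential expression of one gene, AD vs control, by OLS.

    Returns the status term: beta < 0 means lower expression in AD cases.
    """
    if gene not in study.expression.index:
        raise InputError(f"gene {gene!r} not in expression matrix")
    y = study.expression.loc[gene]
    design = _design(study, covariate_set, drop=("status",))
    return _fit_term(gene, y, study.status01, design)


def eqtl_lm(
    study: ExpressionStudy,
    gene: str,
    snp_dosage,
    stratum: str = "all",
    covariate_set: str = "mayo_egwas",
    rin_adjusted: str = "centered_squared",
) -> ExpressionResult:
    """cis-eQTL association of one gene's expression with a SNP dosage.

    ``snp_dosage`` is a SNP id registered in the study, or a per-sample
    array/Series of dosages in [0, 2].  ``stratum`` restricts to AD cases or
    controls; within a stratum the status covariate is dropped.  Beta is per
    effect-allele copy.
    """
    if gene not in study.expression.index:
        raise InputError(f"gene {gene!r} not in expression matrix")
    if isinstance(snp_dosage, str):
        if snp_dosage not in study.dosages:
            raise InputError(f"SNP {snp_dosage!r} not registered in study")
        dos = study.dosages[snp_dosage].astype(float)
    else:
        dos = pd.Series(np.asarray(snp_dosage, dtype=float), index=study.expression.columns)
    if ((dos < 0) | (dos > 2)).any():
        raise InputError("dosages must lie in [0, 2]")

    status = study.status01
    if stratum == "all":
        mask = pd.Series(True, index=status.index)
        drop: tuple[str, ...] = ()
    elif stratum in ("AD", "control"):
        mask = status == (1.0 if stratum == "AD" else 0.0)
        drop = ("status",)
    else:
        raise ConfigurationError(f"stratum must be all/AD/control, got {stratum!r}")
    if not mask.any():
        raise InputError(f"stratum {stratum!r} is empty")
    dos_s = dos[mask]
    if dos_s.nunique() < 2:
        raise InputError(f"dosage is monomorphic within stratum {stratum!r}")
    y = study.expression.loc[gene][mask]
    design = _design(study, covariate_set, rin_adjusted=rin_adjusted, drop=drop).loc[mask]
    return _fit_term(gene, y, dos_s.rename("dosage"), design)


def correct_multiple(
    results: Sequence[ExpressionResult], alpha: float = 0.05
) -> tuple[list[ExpressionResult], float]:
    """Bonferroni-flag a batch of results; returns (flagged results, threshold)."""
    if not results:
        raise InputError("no results to correct")
    threshold = alpha / len(results)
    flagged = [dataclasses.replace(r, significant=bool(r.p < threshold)) for r in results]
    return flagged, threshold
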