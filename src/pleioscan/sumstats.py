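"""Reading, QC filtering and cross-trait harmonization of GWAS summary statistics.

A per-trait summary-statistics table carries, per SNP, the effect and
reference allele, effect-allele frequency, the regression coefficient
(log-odds for ordinal/binary traits) and its standard error, plus the
optional imputation-quality fields used by the QC filter.  Harmonization
aligns several traits onto one shared SNP set with a single effect-allele
orientation so that signed Z scores are comparable across traits, which is
what the joint (O'Brien) test requires.

p-values present in input files are ignored and recomputed from beta/SE so
joint and univariate p-values share one convention.  Internally p-values
are carried in log10 space: a two-sided normal tail underflows a double
near ``|z| = 38.5``, far short of the signals a genome-wide scan can produce.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError

__all__ = [
    "TraitSumStats",
    "AlignedSumStats",
    "LoadReport",
    "QCReport",
    "read_sumstats",
    "qc_filter",
    "harmonize",
    "z_and_p",
    "z_to_log10p",
    "log10p_to_p",
]

#: canonical column names; the column map translates file headers to these
MANDATORY_COLUMNS = ("snp_id", "chrom", "pos", "effect_allele", "ref_allele", "eaf", "beta", "se")
OPTIONAL_COLUMNS = ("p", "imput_r2", "dosage_var")
_NUMERIC = ("pos", "eaf", "beta", "se", "p", "imput_r2", "dosage_var")
_VALID_ALLELES = frozenset("ACGT")
#: unordered allele pairs that are their own reverse complement
AMBIGUOUS_PAIRS = frozenset({frozenset(("A", "T")), frozenset(("C", "G"))})

_LN10 = math.log(10.0)


# ---------------------------------------------------------------------------
# z / p conversion


def z_to_log10p(z):
    """log10 of the two-sided standard-normal tail probability of ``z``.

    Safe for arbitrarily large ``|z|`` (computed from the log survival
    function, never from the underflowing tail itself).
    """
    z = np.asarray(z, dtype=float)
    out = (stats.norm.logsf(np.abs(z)) + math.log(2.0)) / _LN10
    return out if out.ndim else float(out)


def log10p_to_p(log10p):
    """Plain p from log10 p; underflows to 0 below ~1e-308 (log10 p stays exact)."""
    return np.power(10.0, np.asarray(log10p, dtype=float))


def z_and_p(beta: float, se: float) -> tuple[float, float]:
    """Signed Z statistic and two-sided p from an effect estimate and its SE.

    The p-value is computed through the log survival function.  In the
    extreme regime where a double would underflow (``|z| > 38``) an
    extended-precision float is returned so p is never exactly 0 for
    ``|z| <= 40``.

    Raises
    ------
    InputError
        If ``se <= 0``.
    """
    if not se > 0:
        raise InputError(f"standard error must be positive, got {se!r}")
    z = beta / se
    log10p = z_to_log10p(z)
    p = 10.0 ** log10p
    if p == 0.0:
        p = np.exp(np.longdouble(log10p) * np.longdouble(_LN10))
    return z, p


# ---------------------------------------------------------------------------
# containers


@dataclasses.dataclass
class LoadReport:
    """Accounting of rows dropped while parsing one summary-statistics file."""

    n_read: int
    n_kept: int
    n_bad_numeric: int = 0
    n_bad_allele: int = 0
    n_bad_domain: int = 0  # se<=0 or eaf outside (0,1)
    n_duplicate_position: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_read - self.n_kept

    def __str__(self) -> str:  # structured text for logs
        return (
            f"read={self.n_read} kept={self.n_kept} dropped={self.n_dropped} "
            f"(bad_numeric={self.n_bad_numeric}, bad_allele={self.n_bad_allele}, "
            f"bad_domain={self.n_bad_domain}, duplicate_position={self.n_duplicate_position})"
        )


@dataclasses.dataclass
class QCReport:
    """Per-rule exclusion counts from :func:`qc_filter` (a SNP may trip several)."""

    n_in: int
    n_kept: int
    n_maf: int
    n_imput_r2: int
    n_dosage_var: int

    @property
    def n_excluded(self) -> int:
        return self.n_in - self.n_kept

    def __str__(self) -> str:
        return (
            f"in={self.n_in} kept={self.n_kept} excluded={self.n_excluded} "
            f"(maf={self.n_maf}, imput_r2={self.n_imput_r2}, dosage_var={self.n_dosage_var})"
        )


class TraitSumStats:
    """One trait's per-SNP association results.

    Parameters
    ----------
    trait_label
        Name of the trait (e.g. ``"NP"``).
    records
        DataFrame with the canonical columns (``snp_id``, ``chrom``, ``pos``,
        ``effect_allele``, ``ref_allele``, ``eaf``, ``beta``, ``se`` and the
        optional QC fields).  Validated on construction: unique snp_id,
        positive SE, frequency strictly inside (0, 1).
    """

    def __init__(self, trait_label: str, records: pd.DataFrame):
        missing = [c for c in MANDATORY_COLUMNS if c not in records.columns]
        if missing:
            raise ConfigurationError(f"records missing mandatory column(s): {missing}")
        if records["snp_id"].duplicated().any():
            dupes = records.loc[records["snp_id"].duplicated(), "snp_id"].tolist()[:5]
            raise InputError(f"duplicate snp_id values (first few: {dupes})")
        if not (records["se"] > 0).all():
            raise InputError("all standard errors must be > 0")
        if not records["eaf"].between(0, 1, inclusive="neither").all():
            raise InputError("all effect-allele frequencies must lie strictly in (0,1)")
        self.trait_label = str(trait_label)
        self.records = records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def __repr__(self) -> str:
        return f"TraitSumStats({self.trait_label!r}, {len(self)} SNPs)"

    @property
    def maf(self) -> pd.Series:
        """Minor-allele frequency, ``min(eaf, 1 - eaf)``."""
        return np.minimum(self.records["eaf"], 1.0 - self.records["eaf"])

    def write(self, path) -> None:
        """Write a tab-delimited file that :func:`read_sumstats` reads back
        (numerics at 17 significant digits, i.e. a lossless round trip)."""
        self.records.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_label: str | None = None,
) -> tuple[TraitSumStats, LoadReport]:
    """Parse one tab- or comma-delimited summary-statistics file.

    ``column_map`` maps canonical names to the file's header names; the
    identity map is assumed for any canonical name not listed.  Rows with
    unparseable numerics, invalid alleles, out-of-domain values, or
    duplicated (chrom, pos) keys are dropped and counted in the report.

    Raises
    ------
    ConfigurationError
        If a mandatory mapped column is absent from the file.
    InputError
        If the file has no data rows.
    """
    column_map = dict(column_map or {})
    # peek at the header to pick the delimiter
    header = pd.read_csv(path, sep="\t", nrows=0)
    sep = "\t" if len(header.columns) > 1 else ","
    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    if df.empty:
        raise InputError(f"no data rows in {path}")

    rename: dict[str, str] = {}
    for canon in MANDATORY_COLUMNS + OPTIONAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src in df.columns:
            rename[src] = canon
        elif canon in MANDATORY_COLUMNS:
            raise ConfigurationError(
                f"mandatory column {canon!r} (file column {src!r}) not found in {path}"
            )
    df = df.rename(columns=rename)[list(rename.values())]

    n_read = len(df)
    for col in _NUMERIC:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    need = [c for c in ("pos", "eaf", "beta", "se") if c in df.columns]
    ok_numeric = df[need].notna().all(axis=1)
    n_bad_numeric = int((~ok_numeric).sum())
    df = df[ok_numeric]

    ea = df["effect_allele"].str.upper()
    ra = df["ref_allele"].str.upper()
    ok_allele = ea.isin(_VALID_ALLELES) & ra.isin(_VALID_ALLELES) & (ea != ra)
    n_bad_allele = int((~ok_allele).sum())
    df = df[ok_allele].assign(effect_allele=ea[ok_allele], ref_allele=ra[ok_allele])

    ok_domain = (df["se"] > 0) & df["eaf"].between(0, 1, inclusive="neither")
    n_bad_domain = int((~ok_domain).sum())
    df = df[ok_domain]

    # multi-allelic / duplicated positions: drop every copy, with a count
    dup = df.duplicated(subset=["chrom", "pos"], keep=False)
    n_dup = int(dup.sum())
    df = df[~dup]

    df = df.astype({"pos": np.int64})
    report = LoadReport(
        n_read=n_read,
        n_kept=len(df),
        n_bad_numeric=n_bad_numeric,
        n_bad_allele=n_bad_allele,
        n_bad_domain=n_bad_domain,
        n_duplicate_position=n_dup,
    )
    label = trait_label if trait_label is not None else str(path)
    return TraitSumStats(label, df.reset_index(drop=True)), report


def qc_filter(
    stats: TraitSumStats,
    maf_max_excl: float = 0.01,
    r2_min_excl: float = 0.4,
    dosvar_min_excl: float = 0.02,
) -> tuple[TraitSumStats, QCReport]:
    """Exclude SNPs failing the standard imputation-era QC rules.

    A SNP is excluded when MAF <= ``maf_max_excl``, imputation R^2 <=
    ``r2_min_excl``, or dosage variance <= ``dosvar_min_excl`` (all
    boundaries inclusive exclusions).  A missing optional field passes its
    criterion — these filters are routinely applied upstream and absence
    must not erase data.  Never raises; everything is reported.
    """
    rec = stats.records
    maf = np.minimum(rec["eaf"], 1.0 - rec["eaf"])
    bad_maf = maf <= maf_max_excl
    if "imput_r2" in rec.columns:
        bad_r2 = rec["imput_r2"].le(r2_min_excl).fillna(False)
    else:
        bad_r2 = pd.Series(False, index=rec.index)
    if "dosage_var" in rec.columns:
        bad_dv = rec["dosage_var"].le(dosvar_min_excl).fillna(False)
    else:
        bad_dv = pd.Series(False, index=rec.index)
    bad = bad_maf | bad_r2 | bad_dv
    report = QCReport(
        n_in=len(rec),
        n_kept=int((~bad).sum()),
        n_maf=int(bad_maf.sum()),
        n_imput_r2=int(bad_r2.sum()),
        n_dosage_var=int(bad_dv.sum()),
    )
    return TraitSumStats(stats.trait_label, rec[~bad].reset_index(drop=True)), report


# ---------------------------------------------------------------------------
# harmonization


class AlignedSumStats:
    """K traits aligned on a shared SNP set with one effect-allele orientation.

    ``table`` holds the SNP index columns (snp_id, chrom, pos, effect_allele,
    ref_allele) followed by ``beta_<trait>``, ``se_<trait>``, ``z_<trait>``,
    ``log10p_<trait>`` and ``p_<trait>`` per trait.
    """

    INDEX_COLS = ("snp_id", "chrom", "pos", "effect_allele", "ref_allele")

    def __init__(self, table: pd.DataFrame, traits: Sequence[str]):
        self.table = table.reset_index(drop=True)
        self.traits = list(traits)
        for t in self.traits:
            z = self.table[f"beta_{t}"] / self.table[f"se_{t}"]
            if not np.allclose(z, self.table[f"z_{t}"], rtol=1e-12, atol=1e-12):
                raise InputError(f"z_{t} inconsistent with beta_{t}/se_{t}")

    def __len__(self) -> int:
        return len(self.table)

    def __repr__(self) -> str:
        return f"AlignedSumStats({self.traits}, {len(self)} SNPs)"

    def z_matrix(self) -> "ZMatrix":
        from .joint import ZMatrix  # local import to avoid a cycle

        z = self.table[[f"z_{t}" for t in self.traits]].to_numpy(dtype=float)
        snps = self.table[list(self.INDEX_COLS)].copy()
        return ZMatrix(values=z, snps=snps, traits=list(self.traits))

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def read(cls, path) -> "AlignedSumStats":
        table = pd.read_csv(path, sep="\t")
        traits = [c[len("beta_"):] for c in table.columns if c.startswith("beta_")]
        return cls(table, traits)


def _is_ambiguous(ea: pd.Series, ra: pd.Series) -> pd.Series:
    return ((ea == "A") & (ra == "T")) | ((ea == "T") & (ra == "A")) | (
        (ea == "C") & (ra == "G")
    ) | ((ea == "G") & (ra == "C"))


def harmonize(
    traits: Sequence[TraitSumStats],
    ambiguous_policy: str = "keep",
) -> tuple[AlignedSumStats, dict]:
    """Align several traits' statistics onto one orientation per SNP.

    SNPs are keyed by (chrom, pos); the first trait fixes the effect-allele
    orientation.  When another trait lists the same two alleles swapped, its
    beta sign is flipped and eaf complemented.  SNPs whose allele pair cannot
    be reconciled are dropped and counted.  Strand-ambiguous (A/T, C/G) SNPs
    are kept and matched by allele letters under the default policy;
    ``ambiguous_policy="drop"`` removes them instead.

    Returns the aligned table and a report dict with drop counts.

    Raises
    ------
    InputError
        If no traits are given or no SNP is shared by all traits.
    """
    if not traits:
        raise InputError("harmonize needs at least one trait table")
    if ambiguous_policy not in ("keep", "drop"):
        raise ConfigurationError(f"unknown ambiguous_policy {ambiguous_policy!r}")
    labels = [t.trait_label for t in traits]
    if len(set(labels)) != len(labels):
        raise ConfigurationError(f"duplicate trait labels: {labels}")

    ref = traits[0].records.set_index(["chrom", "pos"])
    n_ambiguous_dropped = 0
    if ambiguous_policy == "drop":
        amb = _is_ambiguous(ref["effect_allele"], ref["ref_allele"])
        n_ambiguous_dropped += int(amb.sum())
        ref = ref[~amb]

    out = ref[["snp_id", "effect_allele", "ref_allele"]].copy()
    out[f"beta_{labels[0]}"] = ref["beta"]
    out[f"se_{labels[0]}"] = ref["se"]
    out[f"eaf_{labels[0]}"] = ref["eaf"]
    n_irreconcilable = 0

    for t in traits[1:]:
        rec = t.records.set_index(["chrom", "pos"])
        if ambiguous_policy == "drop":
            amb = _is_ambiguous(rec["effect_allele"], rec["ref_allele"])
            n_ambiguous_dropped += int(amb.sum())
            rec = rec[~amb]
        joined = out.join(rec[["effect_allele", "ref_allele", "beta", "se", "eaf"]],
                          how="inner", rsuffix="_new")
        same = (joined["effect_allele"] == joined["effect_allele_new"]) & (
            joined["ref_allele"] == joined["ref_allele_new"]
        )
        swapped = (joined["effect_allele"] == joined["ref_allele_new"]) & (
            joined["ref_allele"] == joined["effect_allele_new"]
        )
        n_irreconcilable += int((~(same | swapped)).sum())
        joined = joined[same | swapped]
        sign = np.where(joined["effect_allele"] == joined["effect_allele_new"], 1.0, -1.0)
        joined[f"beta_{t.trait_label}"] = joined["beta"] * sign
        joined[f"se_{t.trait_label}"] = joined["se"]
        joined[f"eaf_{t.trait_label}"] = np.where(sign > 0, joined["eaf"], 1.0 - joined["eaf"])
        out = joined.drop(
            columns=["effect_allele_new", "ref_allele_new", "beta", "se", "eaf"]
        )

    if out.empty:
        raise InputError("no SNP is shared by all traits after allele reconciliation")

    out = out.reset_index().sort_values(["chrom", "pos"]).reset_index(drop=True)
    for lab in labels:
        z = out[f"beta_{lab}"] / out[f"se_{lab}"]
        out[f"z_{lab}"] = z
        out[f"log10p_{lab}"] = z_to_log10p(z.to_numpy())
        out[f"p_{lab}"] = log10p_to_p(out[f"log10p_{lab}"])
    cols = list(AlignedSumStats.INDEX_COLS) + [
        f"{f}_{lab}" for lab in labels for f in ("beta", "se", "eaf", "z", "log10p", "p")
    ]
    report = {
        "n_aligned": len(out),
        "n_irreconcilable": n_irreconcilable,
        "n_ambiguous_dropped": n_ambiguous_dropped,
    }
    return AlignedSumStats(out[cols], labels), report
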