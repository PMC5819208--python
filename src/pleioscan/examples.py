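"""Published worked-example inputs for the pleiotropy declaration rule.

Two genome-wide-significant index SNPs from a published pleiotropy scan of
three neuropathological traits (neuritic plaques NP, neurofibrillary
tangles NFT, cerebral amyloid angiopathy CAA) in AD autopsy cohorts:
rs34487851 near C2orf40/ECRG4 and rs79524815 in HDAC9.  Per SNP the
univariate p-values and the three bivariate joint p-values are recorded;
these printed values exercise the declaration rule exactly as reported
(rs34487851 is GWS-pleiotropic for NP+NFT, rs79524815 for NFT+CAA).
"""

from __future__ import annotations

import pandas as pd

from .joint import classify_pleiotropy

__all__ = ["INDEX_SNPS", "TRAIT_PAIRS", "classify_index_snps"]

TRAIT_PAIRS = (("NP", "NFT"), ("NP", "CAA"), ("NFT", "CAA"))

#: per-SNP published statistics: univariate beta (SE) / p per trait and
#: joint p per trait pair; betas are on the ordinal/binary log-odds scale
INDEX_SNPS: dict[str, dict] = {
    "rs34487851": {
        "chrom": "2",
        "gene": "C2orf40",
        "effect_allele": "G",
        "ref_allele": "A",
        "eaf": 0.27,
        "univariate": {
            "NP": {"beta": -0.30, "se": 0.06, "p": 7.7e-7},
            "NFT": {"beta": -0.25, "se": 0.06, "p": 4.5e-6},
            "CAA": {"beta": -0.14, "se": 0.08, "p": 0.06},
        },
        "joint_p": {
            ("NP", "NFT"): 2.0e-8,
            ("NP", "CAA"): 2.5e-6,
            ("NFT", "CAA"): 2.1e-5,
        },
    },
    "rs79524815": {
        "chrom": "7",
        "gene": "HDAC9",
        "effect_allele": "G",
        "ref_allele": "T",
        "eaf": 0.03,
        "univariate": {
            "NP": {"beta": 0.43, "se": 0.19, "p": 0.03},
            "NFT": {"beta": 0.79, "se": 0.19, "p": 2.3e-5},
            "CAA": {"beta": 1.16, "se": 0.26, "p": 9.1e-6},
        },
        "joint_p": {
            ("NP", "NFT"): 1.3e-4,
            ("NP", "CAA"): 3.3e-6,
            ("NFT", "CAA"): 1.1e-8,
        },
    },
}


def classify_index_snps(**rule_kwargs) -> pd.DataFrame:
    """Apply the pleiotropy declaration rule to every published
    (SNP, trait-pair) combination.

    Returns a table with snp_id, trait pair, joint and univariate p-values
    and the assigned class; with default thresholds exactly two rows are
    genome-wide-significant pleiotropic.
    """
    rows = []
    for snp_id, rec in INDEX_SNPS.items():
        for t1, t2 in TRAIT_PAIRS:
            p_joint = rec["joint_p"][(t1, t2)]
            p1 = rec["univariate"][t1]["p"]
            p2 = rec["univariate"][t2]["p"]
            rows.append(
                {
                    "snp_id": snp_id,
                    "pair": f"{t1}+{t2}",
                    "p_joint": p_joint,
                    f"p_univ_1": p1,
                    f"p_univ_2": p2,
                    "pleio_class": classify_pleiotropy(p_joint, [p1, p2], **rule_kwargs),
                }
            )
    return pd.DataFrame(rows)
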