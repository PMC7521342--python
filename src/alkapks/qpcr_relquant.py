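"""Relative qPCR quantification by the 2^-ddCt method.

For each sample, technical replicates of each gene are averaged to a mean
Ct; dCt = Ct(target) - Ct(reference) removes sample-to-sample input
differences (actin is the conventional reference); ddCt = dCt(group) -
dCt(calibrator group) expresses each group relative to a calibrator, whose
relative quantity (RQ = 2^-ddCt) is 1 by construction.  Amplification
efficiency is fixed at 2 per cycle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["relative_quantification", "validate_ct_table"]

_REQUIRED = ("sample", "group", "gene", "replicate", "ct")


def validate_ct_table(ct: pd.DataFrame, reference_gene: str) -> None:
    missing_cols = set(_REQUIRED) - set(ct.columns)
    if missing_cols:
        raise ValueError(f"Ct table lacks columns: {sorted(missing_cols)}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive cycle numbers")
    with_ref = set(ct.loc[ct["gene"] == reference_gene, "sample"])
    lacking = sorted(set(ct["sample"]) - with_ref)
    if lacking:
        raise ValueError(
            f"reference gene {reference_gene!r} not measured in samples: {lacking}"
        )


def relative_quantification(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str = "ACT",
    calibrator_group: str = "Ha-leaf",
) -> pd.DataFrame:
    """Per-group relative expression of ``target_gene``.

    Technical replicates are averaged before biological ones.  Returns a
    DataFrame indexed by group with columns delta_ct, ddct, rq and sd_rq
    (the dispersion of per-biological-replicate RQ values).
    """
    validate_ct_table(ct, reference_gene)
    if target_gene not in set(ct["gene"]):
        raise ValueError(f"target gene {target_gene!r} absent from Ct table")
    if calibrator_group not in set(ct["group"]):
        raise ValueError(f"calibrator group {calibrator_group!r} absent")

    # technical replicates -> one Ct per (sample, gene)
    per_sample = (
        ct.groupby(["sample", "group", "gene"], sort=True)["ct"]
        .mean()
        .reset_index()
        .pivot_table(index=["sample", "group"], columns="gene", values="ct")
        .reset_index()
    )
    if per_sample[target_gene].isna().any():
        bad = per_sample.loc[per_sample[target_gene].isna(), "sample"].tolist()
        raise ValueError(f"target {target_gene!r} missing in samples: {bad}")
    per_sample["delta_ct"] = per_sample[target_gene] - per_sample[reference_gene]

    # biological replicates -> one dCt per group
    group_dct = per_sample.groupby("group")["delta_ct"].mean()
    calibrator_dct = group_dct[calibrator_group]
    ddct = group_dct - calibrator_dct
    rq = np.power(2.0, -ddct)

    # replicate-level dispersion of RQ around the group value
    per_sample["rq_rep"] = np.power(
        2.0, -(per_sample["delta_ct"] - calibrator_dct)
    )
    sd_rq = per_sample.groupby("group")["rq_rep"].std(ddof=1)

    out = pd.DataFrame(
        {"delta_ct": group_dct, "ddct": ddct, "rq": rq, "sd_rq": sd_rq}
    )
    out.index.name = "group"
    out.attrs["target"] = target_gene
    out.attrs["reference"] = reference_gene
    out.attrs["calibrator"] = calibrator_group
    return out
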