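"""Relative gene expression by the 2^-ddCT method and group comparison.

Target-gene CT values are normalised to a reference (housekeeping) gene
within each sample (dCT = mean target CT - mean reference CT across
technical replicates), then to a calibrator genotype group
(ddCT = dCT - mean calibrator dCT).  The relative quantity is
RQ = 2^-ddCT, so the calibrator group averages RQ ~ 1 (geometric mean
exactly 1).  Between-genotype comparison uses a two-tailed two-sample
t-test, by default on log2(RQ) = -ddCT, which is Gaussian when CT noise
is Gaussian; testing raw RQ is available via ``scale="rq"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_CT_COLUMNS = (
    "sample_id",
    "gene",
    "genotype_group",
    "ct_target",
    "ct_reference",
)


def relative_quantity(records: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """Per-sample relative quantities for one gene's CT records.

    ``records`` needs the columns ``sample_id, gene, genotype_group,
    ct_target, ct_reference`` (one row per technical replicate).  Samples
    missing a reference CT are dropped with a warning.  Returns one row
    per sample with ``dct, ddct, rq``.
    """
    missing = set(REQUIRED_CT_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"missing CT columns: {sorted(missing)}")
    if records["gene"].nunique() > 1:
        raise ValueError("relative_quantity expects records for a single gene")
    bad = records.groupby("sample_id")["ct_reference"].apply(
        lambda s: s.isna().all()
    )
    if bad.any():
        warnings.warn(
            f"dropping samples without reference CT: {bad[bad].index.tolist()}",
            stacklevel=2,
        )
        records = records[~records["sample_id"].isin(bad[bad].index)]
    per_sample = (
        records.groupby(["sample_id", "genotype_group"], as_index=False)
        .agg(ct_target=("ct_target", "mean"), ct_reference=("ct_reference", "mean"))
    )
    per_sample["dct"] = per_sample["ct_target"] - per_sample["ct_reference"]
    cal = per_sample.loc[per_sample["genotype_group"] == calibrator, "dct"]
    if cal.empty:
        raise ValueError(f"calibrator group {calibrator!r} is empty")
    per_sample["ddct"] = per_sample["dct"] - cal.mean()
    per_sample["rq"] = 2.0 ** (-per_sample["ddct"])
    per_sample["gene"] = records["gene"].iloc[0]
    return per_sample


@dataclass
class GroupComparison:
    gene: str
    group_a: str
    group_b: str
    t: float
    p: float
    direction: str  # 'up' / 'down' / 'none': group_b relative to group_a
    mean_rq_a: float
    mean_rq_b: float


def compare_groups(
    rq: pd.DataFrame,
    group_a: str,
    group_b: str,
    scale: str = "log2",
) -> GroupComparison:
    """Two-tailed t-test of relative expression between genotype groups.

    ``scale="log2"`` (default) tests ``-ddct``; ``scale="rq"`` tests the
    raw relative quantities.  Direction reports whether ``group_b`` is up-
    or down-regulated relative to ``group_a``.
    """
    if scale not in ("log2", "rq"):
        raise ValueError("scale must be 'log2' or 'rq'")
    col = "ddct" if scale == "log2" else "rq"
    a = rq.loc[rq["genotype_group"] == group_a, col].to_numpy(float)
    b = rq.loc[rq["genotype_group"] == group_b, col].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 samples")
    if scale == "log2":
        a, b = -a, -b  # log2(RQ) = -ddCT
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0  # identical degenerate groups carry no signal
    else:
        t, p = stats.ttest_ind(a, b)
    mean_a = float(rq.loc[rq["genotype_group"] == group_a, "rq"].mean())
    mean_b = float(rq.loc[rq["genotype_group"] == group_b, "rq"].mean())
    if mean_b > mean_a:
        direction = "up"
    elif mean_b < mean_a:
        direction = "down"
    else:
        direction = "none"
    return GroupComparison(
        gene=str(rq["gene"].iloc[0]) if "gene" in rq else "",
        group_a=group_a,
        group_b=group_b,
        t=float(t),
        p=float(p),
        direction=direction,
        mean_rq_a=mean_a,
        mean_rq_b=mean_b,
    )
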