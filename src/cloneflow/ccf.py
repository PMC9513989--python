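"""Cancer cell fraction (CCF) estimation from VAF, purity and copy number.

For a mutation present at multiplicity m on a locus of total copy number
CN in a sample of purity p, the expected VAF of a mutation carried by a
fraction ccf of tumor cells is

    vaf = p * m * ccf / (p * CN + (1 - p) * 2)

so the point estimate inverts to ccf = vaf * (p CN + (1-p) 2) / (p m).
Raw estimates slightly above 1 are routine binomial noise at ~40-50x
coverage; they are clamped, and flagged only beyond a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CcfEstimate",
    "estimate_multiplicity",
    "ccf_from_vaf",
    "cellular_prevalence_profile",
    "CLAMP_TOL",
]

#: raw CCF may exceed 1 by this much before the estimate is flagged
CLAMP_TOL = 0.05


@dataclass
class CcfEstimate:
    variant_id: str
    sample_id: str
    vaf: float
    purity: float
    copy_number: int
    multiplicity: int
    ccf: float
    clipped: bool


def estimate_multiplicity(vaf: float, purity: float, copy_number: int) -> int:
    """Most likely mutant-copy count: round(vaf (p CN + (1-p) 2) / p), clamped to 1..CN.

    Raises for CN = 0 (homozygous deletion leaves nothing to estimate).
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if copy_number == 0:
        raise ValueError("copy_number 0: multiplicity unestimable on a homozygous deletion")
    if copy_number < 0:
        raise ValueError(f"copy_number must be >= 1, got {copy_number}")
    raw = vaf * (purity * copy_number + (1 - purity) * 2) / purity
    return int(min(max(round(raw), 1), copy_number))


def ccf_from_vaf(
    vaf: float,
    purity: float,
    copy_number: int = 2,
    multiplicity: int = 1,
    variant_id: str = "",
    sample_id: str = "",
) -> CcfEstimate:
    """Purity/copy-number-adjusted cancer cell fraction of one observation."""
    if purity == 0:
        raise ValueError("purity 0: no tumor content, CCF undefined")
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if not 1 <= multiplicity <= copy_number:
        raise ValueError(
            f"multiplicity must be in 1..copy_number, got m={multiplicity}, CN={copy_number}"
        )
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"vaf must be in [0, 1], got {vaf}")
    raw = vaf * (purity * copy_number + (1 - purity) * 2) / (purity * multiplicity)
    return CcfEstimate(
        variant_id=variant_id,
        sample_id=sample_id,
        vaf=vaf,
        purity=purity,
        copy_number=copy_number,
        multiplicity=multiplicity,
        ccf=min(raw, 1.0),
        clipped=raw > 1.0 + CLAMP_TOL,
    )


def cellular_prevalence_profile(
    estimates: Sequence[CcfEstimate], cluster_of_variant: Mapping[str, int]
) -> pd.DataFrame:
    """Clusters x samples matrix of mean CCF (cellular prevalence).

    Entry (c, s) is the arithmetic mean of CCFs of cluster c's variants
    observed in sample s; a cluster with no observed variant in a sample is
    NaN (missing), never 0.
    """
    unassigned = {e.variant_id for e in estimates} - set(cluster_of_variant)
    if unassigned:
        raise KeyError(f"variants without a cluster: {sorted(unassigned)[:3]}")
    rows = [
        {"cluster": cluster_of_variant[e.variant_id], "sample_id": e.sample_id, "ccf": e.ccf}
        for e in estimates
    ]
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    prof = df.pivot_table(index="cluster", columns="sample_id", values="ccf", aggfunc="mean")
    return prof.sort_index()
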