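"""Relative qPCR quantification (2^-ddCt) and RNA-Seq concordance.

Ct replicates are aggregated by arithmetic mean; amplification efficiency is
fixed at 2 (one doubling per cycle), the ddCt method's assumption.  The
normalizer gene is always a parameter, never hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConcordanceResult", "ddct_fold_change", "concordance"]


@dataclass(frozen=True)
class ConcordanceResult:
    """Direction agreement between qPCR and RNA-Seq fold changes."""

    agreement: float  # fraction of shared keys with folds on the same side of 1
    n: int
    ties: int  # pairs where one of the folds equals exactly 1


def _mean_ct(records: pd.DataFrame, gene: str, sample: str) -> float:
    sel = records[(records["gene"] == gene) & (records["sample"] == sample)]
    if sel.empty:
        raise KeyError(f"no Ct replicates for gene={gene!r}, sample={sample!r}")
    ct = sel["ct"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ct)) or np.any(ct <= 0):
        raise ValueError(f"Ct values for gene={gene!r}, sample={sample!r} must be positive")
    return float(ct.mean())


def ddct_fold_change(
    records: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    sample: str,
    calibrator_sample: str,
) -> float:
    """Fold change of ``sample`` vs ``calibrator_sample`` by 2^-ddCt.

    ``records`` needs columns ``gene, sample, ct`` (one row per technical
    replicate).  dCt_s = mean Ct(target, s) - mean Ct(reference, s);
    ddCt = dCt_sample - dCt_calibrator; returns 2**-ddCt.
    """
    dct_sample = _mean_ct(records, target_gene, sample) - _mean_ct(
        records, reference_gene, sample
    )
    dct_cal = _mean_ct(records, target_gene, calibrator_sample) - _mean_ct(
        records, reference_gene, calibrator_sample
    )
    return float(2.0 ** -(dct_sample - dct_cal))


def concordance(qpcr_folds: dict, pipeline_folds: dict) -> ConcordanceResult:
    """Fraction of shared (gene, comparison) keys with same-side fold changes.

    A fold exactly equal to 1 agrees with either side and is flagged in
    ``ties``.  Raises when the two fold tables share no keys.
    """
    shared = sorted(set(qpcr_folds) & set(pipeline_folds))
    if not shared:
        raise ValueError("no shared (gene, comparison) keys between fold tables")
    agree = ties = 0
    for key in shared:
        a, b = float(qpcr_folds[key]), float(pipeline_folds[key])
        if a <= 0 or b <= 0:
            raise ValueError(f"fold changes must be positive, got {a}, {b} for {key}")
        if a == 1.0 or b == 1.0:
            ties += 1
            agree += 1
        elif (a > 1.0) == (b > 1.0):
            agree += 1
    return ConcordanceResult(agreement=agree / len(shared), n=len(shared), ties=ties)
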