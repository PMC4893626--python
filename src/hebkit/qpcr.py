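"""Homoeologue-specific qPCR quantification.

Relative expression by the 2^-ddCt method (target CT calibrated against a
reference gene, then against a calibrator sample, assuming perfect
doubling per cycle), and R/C homoeologue-ratio bias calls from
homoeologue-specific assays.  A non-amplifying homoeologue (all technical
replicates "not detected") is reported as silenced rather than as a fold
change.

Two ratio conventions are implemented.  The default ``expression-ratio``
mode converts the CT difference to an expression ratio,
``2^(meanCT_C - meanCT_R)`` — lower CT means more transcript, so a ratio
above 1 is maternal (R) bias.  The alternative ``raw-ct-ratio`` mode
reports the plain ``meanCT_R / meanCT_C`` quotient, a convention some
reports print even though it runs against CT semantics; see
docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ND",
    "ddct",
    "relative_expression",
    "homoeolog_bias",
    "read_ct_table",
    "write_ct_table",
]

#: sentinel used in CT tables for a non-amplifying assay.
ND = "ND"
BIAS_ALPHA = 0.05


def ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calib: float,
    ct_ref_calib: float,
) -> float:
    """Fold change ``2^-ddCt`` for one target assay.

    dCt = CT(target) - CT(reference) within each sample; ddCt subtracts
    the calibrator sample's dCt; a ddCt of -1 is a one-cycle advantage,
    i.e. a two-fold higher expression.
    """
    cts = (ct_target_sample, ct_ref_sample, ct_target_calib, ct_ref_calib)
    if any(not math.isfinite(c) for c in cts):
        raise ValueError("all CT values must be finite; handle ND upstream")
    dd = (ct_target_sample - ct_ref_sample) - (ct_target_calib - ct_ref_calib)
    return 2.0 ** (-dd)


@dataclass
class BiasCall:
    ratio: float
    bias: str           # "R", "C", "none", "R-silenced", "C-silenced"
    p: float
    mode: str


def _mean_ct(reps: Sequence[float]) -> float:
    vals = [v for v in reps if v is not None and math.isfinite(v)]
    return float(np.mean(vals)) if vals else math.nan


def homoeolog_bias(
    ct_r: Sequence[float],
    ct_c: Sequence[float],
    mode: str = "expression-ratio",
    alpha: float = BIAS_ALPHA,
) -> BiasCall:
    """Homoeologue ratio and bias call from technical CT replicates.

    ``ct_r`` / ``ct_c`` are the R- and C-assay CT replicates (NaN for a
    not-detected replicate).  If one homoeologue never amplified, the
    other is reported as exclusively expressed ("X-silenced" for the
    missing side).  Otherwise, in ``expression-ratio`` mode the ratio is
    ``2^(meanCT_C - meanCT_R)`` and the call is R (resp. C) when the
    ratio exceeds (resp. falls below) 1 with a significant two-sided
    paired t-test on the replicate dCt values; in ``raw-ct-ratio`` mode
    the ratio is ``meanCT_R / meanCT_C`` with the same significance test.
    """
    if mode not in ("expression-ratio", "raw-ct-ratio"):
        raise ValueError(f"unknown mode {mode!r}")
    r = np.asarray([v if v is not None else math.nan for v in ct_r], dtype=float)
    c = np.asarray([v if v is not None else math.nan for v in ct_c], dtype=float)
    r_det, c_det = np.isfinite(r), np.isfinite(c)
    if not r_det.any() and not c_det.any():
        return BiasCall(math.nan, "none", math.nan, mode)
    if not c_det.any():
        return BiasCall(math.inf, "C-silenced", 0.0, mode)
    if not r_det.any():
        return BiasCall(0.0, "R-silenced", 0.0, mode)
    mean_r, mean_c = _mean_ct(r), _mean_ct(c)
    if mode == "expression-ratio":
        ratio = 2.0 ** (mean_c - mean_r)
    else:
        ratio = mean_r / mean_c
    # paired dCt when replicate counts match, else Welch on the means
    if r_det.sum() == c_det.sum() and r_det.sum() >= 2:
        dct = c[c_det] - r[r_det]
        if np.allclose(dct, dct[0]):
            p = 0.0 if abs(dct[0]) > 0 else 1.0
        else:
            p = float(stats.ttest_1samp(dct, 0.0).pvalue)
    elif r_det.sum() >= 2 and c_det.sum() >= 2:
        p = float(stats.ttest_ind(c[c_det], r[r_det], equal_var=False).pvalue)
    else:
        p = math.nan
    significant = math.isfinite(p) and p < alpha
    if mode == "expression-ratio":
        r_biased, c_biased = ratio > 1, ratio < 1
    else:
        # raw CT quotient: a quotient above 1 means higher R CT, i.e. the
        # printed convention calls that R bias even though lower CT is more
        # transcript; we reproduce the convention as printed.
        r_biased, c_biased = ratio > 1, ratio < 1
    if significant and r_biased:
        bias = "R"
    elif significant and c_biased:
        bias = "C"
    else:
        bias = "none"
    return BiasCall(float(ratio), bias, p, mode)


def read_ct_table(path) -> pd.DataFrame:
    """Long-format CT table: sample, tissue, assay, replicate, ct (ND allowed)."""
    df = pd.read_csv(path, sep="\t", dtype={"ct": str})
    df["ct"] = pd.to_numeric(df["ct"].replace(ND, np.nan), errors="coerce")
    required = {"sample", "tissue", "assay", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"CT table missing columns: {sorted(missing)}")
    return df


def write_ct_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["ct"] = out["ct"].map(lambda v: ND if pd.isna(v) else f"{v:.4f}")
    out.to_csv(path, sep="\t", index=False)


def relative_expression(
    ct: pd.DataFrame,
    reference_assay: str,
    calibrator_sample: str,
    mode: str = "expression-ratio",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """2^-ddCt per (sample, tissue, assay) plus homoeologue bias per gene.

    Homoeologue assays are expected to be named ``<gene>_R`` / ``<gene>_C``;
    the reference assay is shared.  Folds are relative to
    ``calibrator_sample`` within the same tissue.  Assays not detected in
    any replicate are flagged ``below_detection`` with no numeric fold.
    """
    mean_ct = (
        ct.groupby(["sample", "tissue", "assay"])["ct"].mean().rename("mean_ct")
    )
    rows = []
    for (sample, tissue, assay), mct in mean_ct.items():
        if assay == reference_assay:
            continue
        try:
            ref_s = mean_ct[(sample, tissue, reference_assay)]
            ref_c = mean_ct[(calibrator_sample, tissue, reference_assay)]
            tgt_c = mean_ct[(calibrator_sample, tissue, assay)]
        except KeyError:
            continue
        below = not math.isfinite(mct)
        if below or not math.isfinite(tgt_c):
            fold = math.nan
        else:
            fold = ddct(mct, ref_s, tgt_c, ref_c)
        rows.append(
            {
                "sample": sample,
                "tissue": tissue,
                "assay": assay,
                "mean_ct": mct,
                "fold": fold,
                "below_detection": below,
            }
        )
    folds = pd.DataFrame(rows)
    bias_rows = []
    genes = sorted(
        {
            a[:-2]
            for a in ct["assay"].unique()
            if a.endswith(("_R", "_C")) and a != reference_assay
        }
    )
    for (sample, tissue), sub in ct.groupby(["sample", "tissue"]):
        for gene in genes:
            reps_r = sub.loc[sub["assay"] == f"{gene}_R", "ct"].tolist()
            reps_c = sub.loc[sub["assay"] == f"{gene}_C", "ct"].tolist()
            if not reps_r and not reps_c:
                continue
            call = homoeolog_bias(reps_r, reps_c, mode=mode)
            bias_rows.append(
                {
                    "sample": sample,
                    "tissue": tissue,
                    "gene": gene,
                    "ratio": call.ratio,
                    "bias": call.bias,
                    "p": call.p,
                }
            )
    bias = pd.DataFrame(bias_rows)
    return folds, bias
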