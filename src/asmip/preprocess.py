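"""Raw readouts -> log2 signal tables.

Array data are background-subtracted per physical array (one tissue x
dilution), thresholded against the unused-feature noise floor, and reduced
to the single most informative dilution per gene and tissue.  Sequencing
counts are log2-transformed with low-count flagging; qPCR cycle
thresholds are already on the log2 scale and only need a sign flip (and a
reference subtraction for delta-Ct).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .synthetic_data import REFERENCE_TISSUE

logger = logging.getLogger("asmip")

#: Canonical column order for log2 signal tables.
LOG_COLUMNS = [
    "platform",
    "gene_id",
    "junction_id",
    "tag",
    "tissue_id",
    "theta",
    "missing",
    "missing_reason",
    "low_confidence",
]

_KEY = ["gene_id", "junction_id", "tag", "tissue_id"]


def subtract_background(arrays: pd.DataFrame, z: float = 1.96) -> pd.DataFrame:
    """Subtract the per-array unused-feature background.

    For every array (one tissue x dilution): background = mean of the
    unused-feature values, noise floor = ``z`` times their sample SD.
    Every probe value is reduced by the background; corrected values at or
    below the noise floor are marked missing (``below_background``).
    Unused rows are dropped from the output; the per-array threshold is
    carried in a ``bg_threshold`` column for dilution selection.
    """
    unused = arrays[arrays["is_unused_feature"].astype(bool)]
    probes = arrays[~arrays["is_unused_feature"].astype(bool)].copy()
    stats = (
        unused.groupby(["tissue_id", "dilution"], dropna=False)["value"]
        .agg(bg_mean="mean", bg_sd=lambda s: s.std(ddof=1), n_unused="count")
        .reset_index()
    )
    if len(stats) == 0 or (stats["n_unused"] < 2).any():
        raise ValueError("each array needs >= 2 unused features to estimate background")
    probes = probes.merge(stats, on=["tissue_id", "dilution"], how="left")
    if probes["bg_mean"].isna().any():
        raise ValueError("array without unused features encountered")
    probes["value"] = probes["value"] - probes["bg_mean"]
    probes["bg_threshold"] = z * probes["bg_sd"]
    probes["missing"] = probes["value"] <= probes["bg_threshold"]
    probes["missing_reason"] = np.where(probes["missing"], "below_background", "")
    return probes.drop(columns=["bg_mean", "bg_sd", "n_unused"]).reset_index(drop=True)


def select_dilution(arrays: pd.DataFrame, upper: float = 3500.0) -> pd.DataFrame:
    """Keep, per (gene, tissue), the dilution with the most in-range probes.

    A probe is in range when its background-corrected value lies strictly
    between the array's noise floor and ``upper``.  Ties go to the lowest
    input volume (least saturation risk).  In the winning dilution, values
    at or above ``upper`` are marked missing (``out_of_range``).
    """
    df = arrays.copy()
    df["_in_range"] = (~df["missing"]) & (df["value"] < upper)
    counts = (
        df.groupby(["gene_id", "tissue_id", "dilution_factor"], dropna=False)["_in_range"]
        .sum()
        .reset_index(name="n_in_range")
        .sort_values(["gene_id", "tissue_id", "dilution_factor"], kind="stable")
    )
    # idxmax keeps the first (= lowest-volume) dilution on ties
    winners = counts.loc[
        counts.groupby(["gene_id", "tissue_id"])["n_in_range"].idxmax(),
        ["gene_id", "tissue_id", "dilution_factor", "n_in_range"],
    ]
    starved = winners[winners["n_in_range"] == 0]
    for _, row in starved.iterrows():
        logger.warning(
            "gene %s tissue %s: no in-range probes at any dilution",
            row["gene_id"],
            row["tissue_id"],
        )
    out = df.merge(
        winners[["gene_id", "tissue_id", "dilution_factor"]],
        on=["gene_id", "tissue_id", "dilution_factor"],
    )
    saturated = (~out["missing"]) & (out["value"] >= upper)
    out.loc[saturated, "missing"] = True
    out.loc[saturated, "missing_reason"] = "out_of_range"
    return out.drop(columns="_in_range").reset_index(drop=True)


def log_transform(
    table: pd.DataFrame,
    min_reads: int = 4,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """theta = log2(value), platform-aware.

    * array: background-corrected values; existing missing flags are kept.
    * seq: zero counts become missing (``zero_count``) unless a pseudocount
      is supplied; counts below ``min_reads`` are flagged low-confidence
      but retained.
    * qpcr: Ct is already a log2 quantity; theta = -Ct so that larger
      theta means more template, matching the other platforms.

    Raises on negative non-missing array/seq values and on duplicate
    (gene, junction, tag, tissue) keys.
    """
    df = table.copy()
    if "missing" not in df.columns:
        df["missing"] = False
        df["missing_reason"] = ""
    if df.duplicated(subset=_KEY).any():
        raise ValueError(
            "duplicate (gene, junction, tag, tissue) keys; run select_dilution first"
        )
    platform = df["platform"].to_numpy()
    value = df["value"].to_numpy(dtype=float)
    theta = np.full(len(df), np.nan)
    missing = df["missing"].to_numpy(dtype=bool)
    reason = df["missing_reason"].astype(str).replace("nan", "").to_numpy(dtype=object)
    low_conf = np.zeros(len(df), dtype=bool)

    is_qpcr = platform == "qpcr"
    is_seq = platform == "seq"
    is_array = ~is_qpcr & ~is_seq

    if np.any(~missing & ~is_qpcr & (value < 0)):
        raise ValueError("negative input value in array/seq data")

    # qPCR: dropout rows carry NaN Ct
    qpcr_nan = is_qpcr & ~np.isfinite(value)
    missing[qpcr_nan] = True
    reason[qpcr_nan] = "dropout"
    ok = is_qpcr & ~missing
    theta[ok] = -value[ok]

    v = value + (pseudocount if pseudocount else 0.0)
    zero = is_seq & ~missing & (v <= 0)
    missing[zero] = True
    reason[zero] = "zero_count"
    ok = is_seq & ~missing
    theta[ok] = np.log2(v[ok])
    low_conf[is_seq & ~missing & (value < min_reads)] = True

    nonpos = is_array & ~missing & (value <= 0)
    missing[nonpos] = True
    reason[nonpos] = "below_background"
    ok = is_array & ~missing
    theta[ok] = np.log2(value[ok])

    out = df[["platform"] + _KEY].copy()
    out["theta"] = theta
    out["missing"] = missing
    out["missing_reason"] = reason
    out["low_confidence"] = low_conf
    return out[LOG_COLUMNS].reset_index(drop=True)


def qpcr_delta_ct(
    ct: pd.DataFrame, reference_tissue: str = REFERENCE_TISSUE
) -> pd.DataFrame:
    """Per primer set and tissue: d = Ct_reference - Ct_tissue.

    One d per (junction, primer set, tissue); when both primer sets have
    values they are kept as tags 1 and 2 for downstream averaging, and a
    failed set simply contributes no rows, so the surviving set is used
    alone.  Junctions with neither set measured are absent from the output.
    """
    df = ct[ct["value"].notna()]
    ref = df[df["tissue_id"] == reference_tissue]
    if len(ref) == 0:
        raise ValueError("reference tissue required for delta-Ct")
    ref = ref[["gene_id", "junction_id", "tag", "value"]].rename(columns={"value": "_ct_ref"})
    sam = df[df["tissue_id"] != reference_tissue].merge(
        ref, on=["gene_id", "junction_id", "tag"]
    )
    out = sam[["gene_id", "junction_id", "tag", "tissue_id"]].copy()
    out["platform"] = "qpcr"
    out["theta"] = sam["_ct_ref"] - sam["value"]
    out["missing"] = False
    out["missing_reason"] = ""
    out["low_confidence"] = False
    return out[LOG_COLUMNS].reset_index(drop=True)
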