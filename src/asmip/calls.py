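"""Cutoff derivation and ternary / binary splice calls."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd


@dataclass
class CutoffSpec:
    """A symmetric +/- score cutoff and how it was obtained."""

    score_type: str
    platform: str
    cutoff: float
    provenance: str  # "derived_mean3sd" | "fixed"
    mean_used: float | None = None
    three_sd_used: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def derive_cutoff(
    scores,
    baseline: str = "constitutive_only",
    annot: pd.DataFrame | None = None,
    score_type: str = "",
    platform: str = "",
) -> CutoffSpec:
    """cutoff = |mean| + 3 * SD of the baseline scores (symmetric +/-).

    ``scores`` is a score table or a plain array of baseline score values.
    With ``baseline="constitutive_only"`` an annotation table is required
    and only constitutive junctions contribute; ``baseline="all"`` uses
    every score.  Fewer than 10 baseline scores raise.
    """
    if isinstance(scores, pd.DataFrame):
        df = scores
        if baseline == "constitutive_only":
            if annot is None:
                raise ValueError("constitutive_only baseline requires an annotation table")
            df = df.merge(annot, on=["gene_id", "junction_id"])
            df = df[df["status"] == "constitutive"]
        elif baseline != "all":
            raise ValueError(f"unknown baseline: {baseline}")
        values = df["value"].to_numpy(dtype=float)
        if not score_type and "score_type" in df.columns and len(df):
            score_type = str(df["score_type"].iloc[0])
        if not platform and "platform" in df.columns and len(df):
            platform = str(df["platform"].iloc[0])
    else:
        values = np.asarray(scores, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 10:
        raise ValueError(f"need >= 10 baseline scores, got {len(values)}")
    mean = float(np.mean(values))
    three_sd = 3.0 * float(np.std(values, ddof=1))
    return CutoffSpec(
        score_type=score_type,
        platform=platform,
        cutoff=abs(mean) + three_sd,
        provenance="derived_mean3sd",
        mean_used=mean,
        three_sd_used=three_sd,
    )


def make_calls(scores: pd.DataFrame, cutoff) -> pd.DataFrame:
    """Ternary calls: +1 above +cutoff, -1 below -cutoff, else 0.

    Scores exactly equal to +/- cutoff are called 0 (strict inequality).
    """
    c = cutoff.cutoff if isinstance(cutoff, CutoffSpec) else float(cutoff)
    if c < 0:
        raise ValueError("cutoff must be >= 0")
    value = scores["value"].to_numpy(dtype=float)
    call = np.where(value > c, 1, np.where(value < -c, -1, 0))
    out = scores[["gene_id", "junction_id", "tissue_id"]].copy()
    out["call"] = call.astype(int)
    out["score"] = value
    out["cutoff"] = c
    return out.reset_index(drop=True)


_CALL_KEY = ["gene_id", "junction_id", "tissue_id"]


def binarize(calls: pd.DataFrame, truth_calls: pd.DataFrame) -> pd.DataFrame:
    """Pair ternary calls with a second call set and binarize (nonzero vs zero).

    A pair counts as a concordant positive only when both calls are
    nonzero AND share sign; both-nonzero pairs of opposite sign are
    recorded as discordant (they are never true positives).  Key sets must
    match exactly; a mismatch raises listing the offending keys.
    """
    merged = calls[_CALL_KEY + ["call"]].merge(
        truth_calls[_CALL_KEY + ["call"]],
        on=_CALL_KEY,
        how="outer",
        suffixes=("", "_truth"),
        indicator=True,
    )
    bad = merged[merged["_merge"] != "both"]
    if len(bad):
        keys = bad[_CALL_KEY + ["_merge"]].to_string(index=False, max_rows=20)
        raise ValueError(f"binarize: {len(bad)} unmatched (junction, tissue) keys:\n{keys}")
    merged = merged.drop(columns="_merge")
    a = merged["call"].astype(int)
    b = merged["call_truth"].astype(int)
    merged["call_bin"] = (a != 0).astype(int)
    merged["truth_bin"] = (b != 0).astype(int)
    merged["concordant_positive"] = (a != 0) & (b != 0) & (np.sign(a) == np.sign(b))
    merged["discordant"] = (a != 0) & (b != 0) & (np.sign(a) != np.sign(b))
    merged["concordant_negative"] = (a == 0) & (b == 0)
    return merged.rename(columns={"call_truth": "truth_call"}).reset_index(drop=True)
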