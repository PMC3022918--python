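"""Probe-effect-corrected splice scores.

Two scores per (junction, tissue):

* R-score — reference-based.  d = theta_tissue - theta_reference removes
  the probe effect; centering d on the gene's constitutive junctions
  removes the expression baseline; tag-averaged, scale-normalised by a
  robust per-gene scale of the constitutive values.

* M-score — model-based.  A per-gene additive (junction, tag) x tissue
  model is fit by median polish; the residuals are the splicing signal,
  tag-averaged and divided by the gene-level MAD of the residuals.  Needs
  neither a reference sample nor constitutive annotation.

Both scores are invariant to per-(junction, tag) constant shifts (probe
effects) and per-(gene, tissue) constant shifts (expression / dilution
offsets); the test suite asserts this at 1e-9.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .synthetic_data import REFERENCE_TISSUE

logger = logging.getLogger("asmip")

#: Canonical column order for score tables.
SCORE_COLUMNS = [
    "gene_id",
    "junction_id",
    "tissue_id",
    "score_type",
    "value",
    "n_tags_used",
    "platform",
]


@dataclass
class MedianPolishFit:
    """Additive fit of one two-way table: value = overall + row + col + residual."""

    overall: float
    row_effects: pd.Series
    col_effects: pd.Series
    residuals: pd.DataFrame
    n_iterations: int
    converged: bool
    gene_id: str | None = None


@dataclass
class IntermediateScores:
    """Intermediate quantities of the scoring pipeline, for diagnostics and tests."""

    d: pd.DataFrame | None = None  # per (junction, tag, tissue): theta - theta_ref
    dbar_c: pd.DataFrame | None = None  # per (gene, tag, tissue): constitutive mean of d
    f: pd.DataFrame | None = None  # d - dbar_c
    fbar: pd.DataFrame | None = None  # tag-averaged f (or f*)
    s_g: pd.Series | None = None  # per gene robust scale
    fstar: pd.DataFrame | None = None  # median-polish residuals
    sstar_g: pd.Series | None = None  # per gene MAD of f*
    fits: dict = field(default_factory=dict)


def median_polish(
    matrix: pd.DataFrame | np.ndarray,
    tol: float = 0.01,
    max_iter: int = 10,
    init: str | None = None,
) -> MedianPolishFit:
    """Fit an additive model by alternating row / column median sweeps.

    Missing cells (NaN) are ignored by the medians and stay missing in the
    residuals.  Iteration stops when the proportional reduction of the sum
    of absolute residuals over observed cells drops below ``tol``, or
    after ``max_iter`` sweep pairs.  Raises on an empty matrix or one with
    a fully missing row or column.

    ``init="colmean"`` seeds the column effects with the column means
    before the median sweeps.  Because the mean is linear, this makes the
    residuals of a complete matrix exactly invariant to adding a constant
    to any full row or column (a plain row-first polish is exactly
    row-shift invariant but only approximately column-shift invariant,
    since the sweep order makes its fixed point path-dependent).
    """
    if isinstance(matrix, pd.DataFrame):
        x = matrix.to_numpy(dtype=float)
        row_index, col_index = matrix.index, matrix.columns
    else:
        x = np.asarray(matrix, dtype=float)
        if x.ndim == 1:
            x = x.reshape(1, -1)
        row_index = pd.RangeIndex(x.shape[0])
        col_index = pd.RangeIndex(x.shape[1])
    if x.size == 0:
        raise ValueError("median_polish: empty matrix")
    obs = np.isfinite(x)
    if (~obs).all(axis=1).any() or (~obs).all(axis=0).any():
        raise ValueError("median_polish: matrix has a fully missing row or column")

    z = x.copy()
    row = np.zeros(x.shape[0])
    col = np.zeros(x.shape[1])
    overall = 0.0
    if init == "colmean":
        cm = np.nanmean(z, axis=0)
        z -= cm[None, :]
        col += cm
    elif init is not None:
        raise ValueError(f"unknown init: {init}")
    sar_prev = float(np.nansum(np.abs(z)))
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        rd = np.nanmedian(z, axis=1)
        z -= rd[:, None]
        row += rd
        shift = float(np.median(col))
        col -= shift
        overall += shift

        cd = np.nanmedian(z, axis=0)
        z -= cd[None, :]
        col += cd
        shift = float(np.median(row))
        row -= shift
        overall += shift

        sar_new = float(np.nansum(np.abs(z)))
        if sar_new == 0.0 or sar_prev == 0.0:
            converged = True
            break
        if (sar_prev - sar_new) / sar_prev < tol:
            converged = True
            break
        sar_prev = sar_new

    return MedianPolishFit(
        overall=overall,
        row_effects=pd.Series(row, index=row_index, name="row_effect"),
        col_effects=pd.Series(col, index=col_index, name="col_effect"),
        residuals=pd.DataFrame(z, index=row_index, columns=col_index),
        n_iterations=n_iter,
        converged=converged,
    )


def _robust_scale(values: np.ndarray, method: str = "mad", fallback_sd: bool = True) -> float:
    """MAD x 1.4826 (optionally an iterated Huber scale), SD fallback when zero."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return np.nan
    if method == "huber":
        from statsmodels.robust.scale import huber

        try:
            return float(huber(v)[1])
        except Exception:  # pragma: no cover - huber can fail on degenerate input
            pass
    elif method != "mad":
        raise ValueError(f"unknown scale method: {method}")
    s = float(median_abs_deviation(v, scale="normal"))
    if s == 0.0 and fallback_sd and len(v) > 1:
        s = float(np.std(v, ddof=1))
    return s


def r_score(
    theta: pd.DataFrame,
    annot: pd.DataFrame,
    scale: str = "mad",
    reference_tissue: str = REFERENCE_TISSUE,
) -> tuple[pd.DataFrame, IntermediateScores]:
    """Reference-based splice scores.

    Genes lacking two constitutive junctions with data are skipped with a
    warning.  A gene whose robust scale is zero (after SD fallback) keeps
    R = 0 rows where the centered signal is exactly zero and drops the
    rest as undefined, so no infinities are ever emitted.
    """
    obs = theta[~theta["missing"]]
    ref = obs[obs["tissue_id"] == reference_tissue]
    ref = ref[["gene_id", "junction_id", "tag", "theta"]].rename(columns={"theta": "_theta_ref"})
    sam = obs[obs["tissue_id"] != reference_tissue].merge(
        ref, on=["gene_id", "junction_id", "tag"]
    )
    if len(sam) == 0:
        raise ValueError("r_score: no data with a reference tissue present")
    sam = sam.assign(d=sam["theta"] - sam["_theta_ref"])
    sam = sam.merge(annot, on=["gene_id", "junction_id"], how="left")
    platform = obs["platform"].iloc[0]

    d_frames, dbar_frames, f_frames, fbar_frames = [], [], [], []
    score_frames = []
    s_g: dict[str, float] = {}

    for gene, sub in sam.groupby("gene_id", sort=True):
        con = sub[sub["status"] == "constitutive"]
        if con["junction_id"].nunique() < 2:
            logger.warning("r_score: gene %s skipped (<2 constitutive junctions with data)", gene)
            continue
        dbar = (
            con.groupby(["tag", "tissue_id"])["d"].mean().reset_index(name="dbar_c")
        )
        merged = sub.merge(dbar, on=["tag", "tissue_id"], how="inner")
        merged = merged.assign(f=merged["d"] - merged["dbar_c"])
        fbar = (
            merged.groupby(["junction_id", "tissue_id"])
            .agg(fbar=("f", "mean"), n_tags_used=("f", "size"), status=("status", "first"))
            .reset_index()
        )
        con_fbar = fbar.loc[fbar["status"] == "constitutive", "fbar"].to_numpy()
        s = _robust_scale(con_fbar, method=scale, fallback_sd=True)
        s_g[gene] = s

        d_frames.append(sub[["gene_id", "junction_id", "tag", "tissue_id", "d"]])
        dbar_frames.append(dbar.assign(gene_id=gene))
        f_frames.append(
            merged[["gene_id", "junction_id", "tag", "tissue_id", "f"]]
        )
        fbar_frames.append(fbar.assign(gene_id=gene))

        if not np.isfinite(s):
            logger.warning("r_score: gene %s skipped (no constitutive scale)", gene)
            continue
        if s == 0.0:
            keep = fbar[fbar["fbar"] == 0.0].copy()
            if len(keep) < len(fbar):
                logger.warning(
                    "r_score: gene %s has zero scale; %d nonzero rows undefined",
                    gene,
                    len(fbar) - len(keep),
                )
            keep = keep.assign(value=0.0)
        else:
            keep = fbar.assign(value=fbar["fbar"] / s)
        keep = keep.assign(gene_id=gene, score_type="R", platform=platform)
        score_frames.append(keep[SCORE_COLUMNS])

    inter = IntermediateScores(
        d=pd.concat(d_frames, ignore_index=True) if d_frames else None,
        dbar_c=pd.concat(dbar_frames, ignore_index=True) if dbar_frames else None,
        f=pd.concat(f_frames, ignore_index=True) if f_frames else None,
        fbar=pd.concat(fbar_frames, ignore_index=True) if fbar_frames else None,
        s_g=pd.Series(s_g, name="s_g"),
    )
    scores = (
        pd.concat(score_frames, ignore_index=True)
        if score_frames
        else pd.DataFrame(columns=SCORE_COLUMNS)
    )
    return scores, inter


def m_score(
    theta: pd.DataFrame,
    tol: float = 0.01,
    max_iter: int = 10,
) -> tuple[pd.DataFrame, IntermediateScores]:
    """Model-based splice scores via per-gene median polish.

    All tissues (including any reference sample) enter the fit as ordinary
    columns.  Genes with fewer than two junctions or two tissues are
    skipped; a gene whose residual MAD is zero has undefined M-scores and
    is reported as such rather than dividing by zero.
    """
    obs = theta[~theta["missing"]]
    if len(obs) == 0:
        raise ValueError("m_score: no observed data")
    platform = obs["platform"].iloc[0]

    fstar_frames, fbar_frames, score_frames = [], [], []
    sstar: dict[str, float] = {}
    fits: dict[str, MedianPolishFit] = {}

    for gene, sub in obs.groupby("gene_id", sort=True):
        if sub["junction_id"].nunique() < 2 or sub["tissue_id"].nunique() < 2:
            logger.warning("m_score: gene %s skipped (<2 junctions or <2 tissues)", gene)
            continue
        mat = sub.pivot(index=["junction_id", "tag"], columns="tissue_id", values="theta")
        # colmean init => residuals exactly invariant to probe-effect (row)
        # and expression/dilution (column) shifts on complete matrices
        fit = median_polish(mat, tol=tol, max_iter=max_iter, init="colmean")
        fit.gene_id = gene
        fits[gene] = fit

        fstar = (
            fit.residuals.stack()
            .dropna()
            .rename("fstar")
            .reset_index()
            .rename(columns={"level_2": "tissue_id"})
        )
        fstar["gene_id"] = gene
        fstar_frames.append(
            fstar[["gene_id", "junction_id", "tag", "tissue_id", "fstar"]]
        )
        s = float(median_abs_deviation(fstar["fstar"], scale="normal"))
        sstar[gene] = s

        fbar = (
            fstar.groupby(["junction_id", "tissue_id"])
            .agg(fbar=("fstar", "mean"), n_tags_used=("fstar", "size"))
            .reset_index()
            .assign(gene_id=gene)
        )
        fbar_frames.append(fbar)
        if s == 0.0:
            logger.warning("m_score: gene %s has zero residual MAD; M undefined", gene)
            continue
        keep = fbar.assign(value=fbar["fbar"] / s, score_type="M", platform=platform)
        score_frames.append(keep[SCORE_COLUMNS])

    inter = IntermediateScores(
        fstar=pd.concat(fstar_frames, ignore_index=True) if fstar_frames else None,
        fbar=pd.concat(fbar_frames, ignore_index=True) if fbar_frames else None,
        sstar_g=pd.Series(sstar, name="sstar_g"),
        fits=fits,
    )
    scores = (
        pd.concat(score_frames, ignore_index=True)
        if score_frames
        else pd.DataFrame(columns=SCORE_COLUMNS)
    )
    return scores, inter


def tissue_pair_scores(scores: pd.DataFrame, pairs) -> pd.DataFrame:
    """Per-junction |score_A - score_B| for one designated tissue pair per gene.

    ``pairs`` maps gene_id -> (tissue_a, tissue_b), either as a dict or a
    DataFrame with columns gene_id, tissue_a, tissue_b.  The difference of
    two same-gene scores is itself a splice score with the baseline
    shifted to the pair, which is what the control ROC consumes.  Genes
    with a missing pair tissue are skipped with a warning.
    """
    if isinstance(pairs, pd.DataFrame):
        pair_map = {
            r["gene_id"]: (r["tissue_a"], r["tissue_b"]) for _, r in pairs.iterrows()
        }
    else:
        pair_map = dict(pairs)
    frames = []
    for gene, sub in scores.groupby("gene_id", sort=True):
        if gene not in pair_map:
            continue
        a, b = pair_map[gene]
        sa = sub[sub["tissue_id"] == a]
        sb = sub[sub["tissue_id"] == b]
        if len(sa) == 0 or len(sb) == 0:
            logger.warning("tissue_pair_scores: gene %s missing tissue %s or %s", gene, a, b)
            continue
        merged = sa.merge(
            sb, on=["gene_id", "junction_id", "score_type", "platform"], suffixes=("_a", "_b")
        )
        out = merged[["gene_id", "junction_id", "score_type", "platform"]].copy()
        out["tissue_id"] = f"{a}|{b}"
        out["value"] = (merged["value_a"] - merged["value_b"]).abs()
        out["n_tags_used"] = merged[["n_tags_used_a", "n_tags_used_b"]].min(axis=1)
        frames.append(out[SCORE_COLUMNS])
    if not frames:
        return pd.DataFrame(columns=SCORE_COLUMNS)
    return pd.concat(frames, ignore_index=True)
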