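"""Concordance-index AUC, sensitivity/specificity, and score correlations."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr
from sklearn.metrics import roc_auc_score, roc_curve

from .synthetic_data import REFERENCE_TISSUE, SimulationTruth


@dataclass
class EvalReport:
    """Summary statistics of one evaluation run."""

    auc: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    pearson_r: float | None = None
    spearman_rho: float | None = None
    n_positive: int = 0
    n_negative: int = 0
    n_discordant: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def concordance_auc(scores, labels) -> float:
    """P(random positive outranks random negative), ties credited 0.5.

    Equals the trapezoidal area under the full ROC curve.  Raises on
    single-class input.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("concordance_auc: need at least one item of each label")
    return float(roc_auc_score(labels, scores))


def roc_coordinates(scores, labels) -> pd.DataFrame:
    """ROC curve as a (fpr, tpr, threshold) table for plotting elsewhere."""
    fpr, tpr, thr = roc_curve(np.asarray(labels, dtype=int), np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def sens_spec(paired: pd.DataFrame) -> tuple[float, float]:
    """Sensitivity and specificity from a binarized call/truth pairing.

    sensitivity = concordant positives / truth positives;
    specificity = concordant negatives / truth negatives.  Opposite-sign
    (discordant) pairs are never true positives, so they count against
    sensitivity.  An undefined fraction (no truth positives or negatives)
    is reported as NaN.
    """
    n_pos = int((paired["truth_call"] != 0).sum())
    n_neg = int((paired["truth_call"] == 0).sum())
    sens = float(paired["concordant_positive"].sum()) / n_pos if n_pos else float("nan")
    spec = float(paired["concordant_negative"].sum()) / n_neg if n_neg else float("nan")
    return sens, spec


_SCORE_KEY = ["gene_id", "junction_id", "tissue_id"]


def correlate(scores_a: pd.DataFrame, scores_b: pd.DataFrame) -> tuple[float, float, int]:
    """Pearson r and Spearman rho over the shared non-missing keys.

    Both coefficients are reported; requires at least 3 shared keys.
    Returns (pearson_r, spearman_rho, n).
    """
    a = scores_a[_SCORE_KEY + ["value"]].dropna(subset=["value"])
    b = scores_b[_SCORE_KEY + ["value"]].dropna(subset=["value"])
    merged = a.merge(b, on=_SCORE_KEY, suffixes=("_a", "_b"))
    n = len(merged)
    if n < 3:
        raise ValueError(f"correlate: need >= 3 shared keys, got {n}")
    pr = float(pearsonr(merged["value_a"], merged["value_b"]).statistic)
    sr = float(spearmanr(merged["value_a"], merged["value_b"]).statistic)
    return pr, sr, n


def choose_tissue_pairs(truth: SimulationTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pick, per gene, the tissue pair that exhibits the most splicing.

    Mirrors the control evaluation design, where pairs of tissues known to
    show alternative splicing for the assayed genes are compared.  Returns
    (pairs, labels): ``pairs`` has columns gene_id/tissue_a/tissue_b;
    ``labels`` has one row per evaluable junction with label 1 for an
    alternative junction whose delta differs between the pair tissues and
    0 for a constitutive junction.  Alternative junctions that do not
    differ within the chosen pair are excluded (they are not expected to
    show splicing for that pair).
    """
    deltas = truth.deltas[truth.deltas["tissue_id"] != REFERENCE_TISSUE]
    wide = deltas.pivot(index=["gene_id", "junction_id"], columns="tissue_id", values="delta")
    tissues = list(wide.columns)
    pair_rows, label_frames = [], []
    for gene, sub in wide.groupby(level="gene_id", sort=True):
        best, best_n = None, -1
        for i in range(len(tissues)):
            for j in range(i + 1, len(tissues)):
                a, b = tissues[i], tissues[j]
                n_diff = int((sub[a] != sub[b]).sum())
                if n_diff > best_n:
                    best, best_n = (a, b), n_diff
        a, b = best
        pair_rows.append((gene, a, b))
        lab = sub.reset_index()[["gene_id", "junction_id"]].copy()
        lab["label"] = (sub[a] != sub[b]).astype(int).to_numpy()
        lab["_alt"] = ((sub[a] != 0) | (sub[b] != 0) | (sub != 0).any(axis=1)).to_numpy()
        label_frames.append(lab)
    pairs = pd.DataFrame(pair_rows, columns=["gene_id", "tissue_a", "tissue_b"])
    labels = pd.concat(label_frames, ignore_index=True)
    labels = labels.merge(truth.annotation, on=["gene_id", "junction_id"])
    # drop alternative junctions invisible to the chosen pair
    keep = (labels["status"] == "constitutive") | (labels["label"] == 1)
    labels = labels[keep][["gene_id", "junction_id", "label"]].reset_index(drop=True)
    return pairs, labels
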