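"""End-to-end orchestration: simulate -> preprocess -> score -> call -> evaluate.

A run writes every intermediate table, the resolved config, and a log to
one output directory.  All randomness flows from the single config seed,
so identical config + seed reproduces byte-identical tables.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import calls as calls_mod
from . import evaluate as eval_mod
from . import io as io_mod
from . import preprocess as pre_mod
from . import scoring as score_mod
from . import synthetic_data as sim_mod
from .synthetic_data import SimConfig

logger = logging.getLogger("asmip")

STAGES = ["simulate", "preprocess", "score", "call", "evaluate"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    platform: str = "seq"  # seq | array | qpcr
    score_method: str = "M"  # M | R | both
    z: float = 1.96
    upper: float = 3500.0
    min_reads: int = 4
    pseudocount: float = 0.0
    tol: float = 0.01
    max_iter: int = 10
    cutoff: str = "fixed:1.3"  # fixed:<x> | derive:constitutive | derive:all
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "sim"}
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = SimConfig.from_dict(d.pop("sim", {}) or {})
        return cls(sim=sim, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(io_mod.load_config(path) or {})

    def to_yaml(self, path) -> Path:
        return io_mod.dump_config(self.to_dict(), path)


def _parse_cutoff(spec: str):
    kind, _, arg = spec.partition(":")
    if kind == "fixed":
        return "fixed", float(arg)
    if kind == "derive":
        if arg not in ("constitutive", "all"):
            raise ValueError(f"unknown cutoff baseline: {arg}")
        return "derive", arg
    raise ValueError(f"unknown cutoff spec: {spec}")


def _setup_logging(out_dir: Path, level: str) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, level.upper(), logging.INFO))
    return handler


def run_pipeline(config: PipelineConfig, out_dir, seed: int | None = None) -> Path:
    """Execute all stages, writing intermediates and an evaluation report.

    Returns the output directory.  A stage failure leaves partial outputs
    plus a ``FAILED`` marker and raises :class:`StageError`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = replace(config, sim=replace(config.sim, seed=int(seed)))
    handler = _setup_logging(out, config.log_level)
    stage = STAGES[0]
    try:
        logger.info(
            "run start: platform=%s seed=%d numpy=%s pandas=%s python=%s",
            config.platform, config.sim.seed, np.__version__, pd.__version__,
            sys.version.split()[0],
        )
        config.to_yaml(out / "config_resolved.yaml")

        # --- simulate -------------------------------------------------
        truth = sim_mod.simulate_truth(config.sim)
        renderer = {
            "seq": sim_mod.render_sequencing,
            "array": sim_mod.render_array,
            "qpcr": sim_mod.render_qpcr,
        }.get(config.platform)
        if renderer is None:
            raise ValueError(f"unknown platform: {config.platform}")
        signal = renderer(truth, config.sim)
        io_mod.write_table(truth.probe_effects, out / "truth_probe_effects.tsv")
        io_mod.write_table(truth.baselines, out / "truth_baselines.tsv")
        io_mod.write_table(truth.deltas, out / "truth_deltas.tsv")
        io_mod.write_table(truth.annotation, out / "annotation.tsv")
        io_mod.write_table(sim_mod.truth_calls(truth), out / "truth_calls.tsv")
        io_mod.write_table(signal, out / "signal.tsv")
        logger.info("simulate: %d signal rows", len(signal))

        # --- preprocess -----------------------------------------------
        stage = "preprocess"
        if config.platform == "array":
            corrected = pre_mod.subtract_background(signal, z=config.z)
            selected = pre_mod.select_dilution(corrected, upper=config.upper)
            theta = pre_mod.log_transform(
                selected, min_reads=config.min_reads, pseudocount=config.pseudocount
            )
        else:
            theta = pre_mod.log_transform(
                signal, min_reads=config.min_reads, pseudocount=config.pseudocount
            )
            if config.platform == "qpcr":
                io_mod.write_table(pre_mod.qpcr_delta_ct(signal), out / "delta_ct.tsv")
        io_mod.write_table(theta, out / "log_signal.tsv")
        logger.info("preprocess: %d rows (%d missing)", len(theta), int(theta["missing"].sum()))

        # --- score ----------------------------------------------------
        stage = "score"
        frames = []
        inter_m = None
        if config.score_method in ("M", "both"):
            m, inter_m = score_mod.m_score(theta, tol=config.tol, max_iter=config.max_iter)
            frames.append(m)
        if config.score_method in ("R", "both"):
            r, _ = score_mod.r_score(theta, truth.annotation)
            frames.append(r)
        if not frames:
            raise ValueError(f"unknown score_method: {config.score_method}")
        scores = pd.concat(frames, ignore_index=True)
        io_mod.write_table(scores, out / "scores.tsv")
        if inter_m is not None and inter_m.fits:
            io_mod.write_table(_fits_table(inter_m.fits), out / "polish_fits.tsv")
        logger.info("score: %d score rows", len(scores))

        # --- call -----------------------------------------------------
        stage = "call"
        primary_type = "M" if config.score_method in ("M", "both") else "R"
        primary = scores[scores["score_type"] == primary_type]
        kind, arg = _parse_cutoff(config.cutoff)
        if kind == "fixed":
            spec = calls_mod.CutoffSpec(
                score_type=primary_type, platform=config.platform,
                cutoff=arg, provenance="fixed",
            )
        else:
            baseline = "constitutive_only" if arg == "constitutive" else "all"
            spec = calls_mod.derive_cutoff(primary, baseline=baseline, annot=truth.annotation)
        call_table = calls_mod.make_calls(primary, spec)
        io_mod.write_table(call_table, out / "calls.tsv")
        (out / "cutoff.json").write_text(spec.to_json() + "\n")
        logger.info("call: cutoff=%.4f nonzero=%d", spec.cutoff, int((call_table["call"] != 0).sum()))

        # --- evaluate -------------------------------------------------
        stage = "evaluate"
        truth_call_table = sim_mod.truth_calls(truth)
        eval_calls = call_table[call_table["tissue_id"] != sim_mod.REFERENCE_TISSUE]
        keys = eval_calls[["gene_id", "junction_id", "tissue_id"]]
        aligned_truth = truth_call_table.merge(keys, on=list(keys.columns))
        paired = calls_mod.binarize(eval_calls, aligned_truth)
        sens, spec_frac = eval_mod.sens_spec(paired)

        pairs, labels = eval_mod.choose_tissue_pairs(truth)
        pair_scores = score_mod.tissue_pair_scores(primary, pairs)
        merged = pair_scores.merge(labels, on=["gene_id", "junction_id"])
        auc = None
        if merged["label"].nunique() == 2:
            auc = eval_mod.concordance_auc(merged["value"], merged["label"])
            io_mod.write_table(
                eval_mod.roc_coordinates(merged["value"], merged["label"]), out / "roc.tsv"
            )
        io_mod.write_table(pair_scores, out / "pair_scores.tsv")

        truth_scores = truth.deltas.rename(columns={"delta": "value"})
        pr, sr, n_corr = eval_mod.correlate(primary, truth_scores)
        report = eval_mod.EvalReport(
            auc=auc,
            sensitivity=sens,
            specificity=spec_frac,
            pearson_r=pr,
            spearman_rho=sr,
            n_positive=int((paired["truth_call"] != 0).sum()),
            n_negative=int((paired["truth_call"] == 0).sum()),
            n_discordant=int(paired["discordant"].sum()),
        )
        (out / "eval.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        logger.info("evaluate: auc=%s sens=%.3f spec=%.3f", auc, sens, spec_frac)
        return out
    except Exception as exc:
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        raise StageError(stage, exc) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()


def _fits_table(fits: dict) -> pd.DataFrame:
    """Flatten median-polish fits into a long diagnostics table."""
    rows = []
    for gene, fit in fits.items():
        rows.append((gene, "overall", "", fit.overall))
        for key, v in fit.row_effects.items():
            label = "|".join(str(k) for k in key) if isinstance(key, tuple) else str(key)
            rows.append((gene, "row", label, v))
        for key, v in fit.col_effects.items():
            rows.append((gene, "col", str(key), v))
    return pd.DataFrame(rows, columns=["gene_id", "term", "key", "effect"])
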