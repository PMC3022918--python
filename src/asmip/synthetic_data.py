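"""Synthetic junction-assay data with known ground truth.

Generates the three platform readouts (array fluorescence with dilution
series, sequencing tag counts, qPCR Ct) from a shared additive log2 model

    theta[j, k, i, g] = p[j, k, g] + t[i, g] + delta[j, i, g] + eps

where ``p`` is a per-(junction, tag) probe effect, ``t`` a per-(gene,
tissue) expression baseline, ``delta`` the splicing shift (zero for
constitutive junctions and in the reference sample), and ``eps`` is
Gaussian noise.  Every renderer is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

#: Identifier of the simulated reference sample (a baseline tissue mixture).
REFERENCE_TISSUE = "REF"

#: Canonical column order for raw per-platform measurement tables.
SIGNAL_COLUMNS = [
    "platform",
    "gene_id",
    "junction_id",
    "tag",
    "tissue_id",
    "dilution",
    "dilution_factor",
    "value",
    "is_unused_feature",
]

# Fixed per-stage stream offsets so each renderer draws from its own
# reproducible stream regardless of call order.
_TRUTH_STREAM, _SEQ_STREAM, _ARRAY_STREAM, _QPCR_STREAM = range(4)

_DILUTION_LABELS = ["low", "mid", "high"]


def _stream(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one synthetic dataset.

    ``junctions_per_gene`` and ``tissue_baseline_range`` are inclusive
    ``(low, high)`` ranges.  All scales are log2 units except the array
    fluorescence parameters.
    """

    n_genes: int = 10
    junctions_per_gene: tuple[int, int] = (6, 12)
    n_tissues: int = 5
    frac_alternative: float = 0.3
    delta_magnitude: float = 2.5
    probe_effect_sd: float = 1.0
    tissue_baseline_range: tuple[float, float] = (-2.0, 2.0)
    noise_sd: float = 0.4
    seq_depth_scale: float = 1000.0
    seq_dispersion: float = 0.0
    array_background_mean: float = 100.0
    array_background_sd: float = 20.0
    array_saturation: float = 3500.0
    array_gain: float | None = None  # fluorescence per unit signal; None = auto
    dilution_factors: tuple[float, float, float] = (0.01, 0.1, 1.0)
    n_unused_features: int = 20
    qpcr_dropout_prob: float = 0.0
    ct_intercept: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.junctions_per_gene
        if not (2 <= lo <= hi):
            raise ValueError("junctions_per_gene must satisfy 2 <= low <= high")
        if self.n_tissues < 2:
            raise ValueError("n_tissues must be >= 2")
        if not 0.0 <= self.frac_alternative <= 1.0:
            raise ValueError("frac_alternative must lie in [0, 1]")
        for name in ("probe_effect_sd", "noise_sd", "array_background_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tissue_baseline_range[0] > self.tissue_baseline_range[1]:
            raise ValueError("tissue_baseline_range must be (low, high)")
        if len(self.dilution_factors) != 3:
            raise ValueError("exactly three dilution_factors are required")
        d = self.dilution_factors
        if not (0 < d[0] < d[1] < d[2]):
            raise ValueError("dilution_factors must be strictly increasing and positive")
        if self.n_unused_features < 2:
            raise ValueError("n_unused_features must be >= 2")
        if not 0.0 <= self.qpcr_dropout_prob <= 1.0:
            raise ValueError("qpcr_dropout_prob must lie in [0, 1]")
        if self.seq_depth_scale < 0 or self.seq_dispersion < 0:
            raise ValueError("seq_depth_scale and seq_dispersion must be >= 0")

    def to_dict(self) -> dict:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        kwargs = dict(d)
        for k in ("junctions_per_gene", "tissue_baseline_range", "dilution_factors"):
            if k in kwargs and kwargs[k] is not None:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)


@dataclass
class SimulationTruth:
    """Ground-truth generating parameters for one simulated dataset."""

    probe_effects: pd.DataFrame  # gene_id, junction_id, tag, p
    baselines: pd.DataFrame  # gene_id, tissue_id, t (includes REF)
    deltas: pd.DataFrame  # gene_id, junction_id, tissue_id, delta (dense, incl REF)
    annotation: pd.DataFrame  # gene_id, junction_id, status
    tissues: list[str]
    noise_sd: float
    config: SimConfig


def simulate_truth(config: SimConfig) -> SimulationTruth:
    """Draw probe effects, tissue baselines, and splicing deltas.

    Per gene, ``ceil(frac_alternative * n_junctions)`` junctions are made
    alternative; each receives ``+/- delta_magnitude`` (one random sign) in
    a random minority subset of tissues (1 .. floor(n_tissues / 2)), never
    in the reference sample.  Raises if a gene would be left with no
    constitutive junction, since reference-based scoring needs a
    constitutive baseline.
    """
    config.validate()
    rng = _stream(config.seed, _TRUTH_STREAM)
    tissues = [f"T{i + 1}" for i in range(config.n_tissues)]
    samples = tissues + [REFERENCE_TISSUE]
    lo_j, hi_j = config.junctions_per_gene
    lo_t, hi_t = config.tissue_baseline_range
    max_subset = max(1, config.n_tissues // 2)

    probe_rows: list[tuple] = []
    base_rows: list[tuple] = []
    delta_rows: list[tuple] = []
    annot_rows: list[tuple] = []

    for gi in range(config.n_genes):
        gene = f"G{gi + 1:03d}"
        n_junc = int(rng.integers(lo_j, hi_j + 1))
        n_alt = math.ceil(config.frac_alternative * n_junc)
        if n_alt >= n_junc:
            raise ValueError(
                f"gene {gene}: frac_alternative={config.frac_alternative} leaves no "
                "constitutive junction to anchor the baseline"
            )
        junctions = [f"{e + 1}-{e + 2}" for e in range(n_junc)]
        alt_idx = set(
            rng.choice(n_junc, size=n_alt, replace=False).tolist() if n_alt else []
        )

        for j, junc in enumerate(junctions):
            status = "alternative" if j in alt_idx else "constitutive"
            annot_rows.append((gene, junc, status))
            for tag in (1, 2):
                p = rng.normal(0.0, config.probe_effect_sd) if config.probe_effect_sd else 0.0
                probe_rows.append((gene, junc, tag, p))

        for sample in samples:
            base_rows.append((gene, sample, rng.uniform(lo_t, hi_t)))

        delta = np.zeros((n_junc, len(samples)))
        for j in sorted(alt_idx):
            sign = float(rng.choice([-1.0, 1.0]))
            k = int(rng.integers(1, max_subset + 1))
            hit = rng.choice(config.n_tissues, size=k, replace=False)
            delta[j, hit] = sign * config.delta_magnitude
        for j, junc in enumerate(junctions):
            for si, sample in enumerate(samples):
                delta_rows.append((gene, junc, sample, delta[j, si]))

    return SimulationTruth(
        probe_effects=pd.DataFrame(
            probe_rows, columns=["gene_id", "junction_id", "tag", "p"]
        ),
        baselines=pd.DataFrame(base_rows, columns=["gene_id", "tissue_id", "t"]),
        deltas=pd.DataFrame(
            delta_rows, columns=["gene_id", "junction_id", "tissue_id", "delta"]
        ),
        annotation=pd.DataFrame(annot_rows, columns=["gene_id", "junction_id", "status"]),
        tissues=tissues,
        noise_sd=config.noise_sd,
        config=config,
    )


def latent_signal(truth: SimulationTruth) -> pd.DataFrame:
    """Noise-free latent log2 signal grid: theta0 = p + t + delta.

    One row per (gene, junction, tag, sample incl. reference), sorted by key.
    """
    grid = truth.probe_effects.merge(truth.baselines, on="gene_id")
    grid = grid.merge(truth.deltas, on=["gene_id", "junction_id", "tissue_id"], how="left")
    grid["delta"] = grid["delta"].fillna(0.0)
    grid["theta0"] = grid["p"] + grid["t"] + grid["delta"]
    grid = grid.sort_values(["gene_id", "junction_id", "tag", "tissue_id"], kind="stable")
    return grid.reset_index(drop=True)


def _as_signal(df: pd.DataFrame) -> pd.DataFrame:
    for col in SIGNAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col in ("dilution", "dilution_factor") else False
    df = df[SIGNAL_COLUMNS].reset_index(drop=True)
    df["tag"] = df["tag"].astype("Int64")
    df["value"] = df["value"].astype(float)
    df["is_unused_feature"] = df["is_unused_feature"].astype(bool)
    return df


def render_sequencing(truth: SimulationTruth, config: SimConfig | None = None) -> pd.DataFrame:
    """Sequencing tag counts: count ~ Poisson(seq_depth_scale * 2**theta).

    ``seq_dispersion > 0`` switches to a gamma-Poisson mixture with
    variance mu + dispersion * mu**2.
    """
    config = config or truth.config
    rng = _stream(config.seed, _SEQ_STREAM)
    grid = latent_signal(truth)
    n = len(grid)
    eps = rng.normal(0.0, config.noise_sd, n) if config.noise_sd else np.zeros(n)
    mu = config.seq_depth_scale * np.exp2(grid["theta0"].to_numpy() + eps)
    if config.seq_dispersion > 0:
        shape = 1.0 / config.seq_dispersion
        lam = rng.gamma(shape, mu * config.seq_dispersion)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)
    out = grid[["gene_id", "junction_id", "tag", "tissue_id"]].copy()
    out["platform"] = "seq"
    out["value"] = counts.astype(float)
    out["is_unused_feature"] = False
    return _as_signal(out)


def render_array(truth: SimulationTruth, config: SimConfig | None = None) -> pd.DataFrame:
    """Array fluorescence: three dilutions per sample plus unused features.

    intensity = min(saturation, background_draw + gain * v * 2**theta),
    clipped at zero.  The gain is fixed so the mid dilution puts the median
    latent signal halfway between background and the saturation ceiling.
    The latent noise term is shared across the three dilutions of one
    sample (they are aliquots of the same reacted material); per-array
    variation enters through the background draws.
    """
    config = config or truth.config
    rng = _stream(config.seed, _ARRAY_STREAM)
    grid = latent_signal(truth)
    n = len(grid)
    eps = rng.normal(0.0, config.noise_sd, n) if config.noise_sd else np.zeros(n)
    grid = grid.assign(theta=grid["theta0"] + eps)

    if config.array_gain is not None:
        gain = config.array_gain
    else:
        target = 0.5 * (config.array_background_mean + config.array_saturation)
        med = float(np.median(grid["theta0"]))
        v_mid = config.dilution_factors[1]
        gain = (target - config.array_background_mean) / (v_mid * 2.0**med)

    samples = truth.tissues + [REFERENCE_TISSUE]
    frames = []
    for sample in samples:
        sub = grid[grid["tissue_id"] == sample]
        signal = np.exp2(sub["theta"].to_numpy())
        for label, v in zip(_DILUTION_LABELS, config.dilution_factors):
            if config.array_background_sd:
                bg = rng.normal(config.array_background_mean, config.array_background_sd, len(sub))
                bg_unused = rng.normal(
                    config.array_background_mean, config.array_background_sd, config.n_unused_features
                )
            else:
                bg = np.full(len(sub), config.array_background_mean)
                bg_unused = np.full(config.n_unused_features, config.array_background_mean)
            inten = np.minimum(config.array_saturation, bg + gain * v * signal)
            probes = sub[["gene_id", "junction_id", "tag"]].copy()
            probes["tissue_id"] = sample
            probes["dilution"] = label
            probes["dilution_factor"] = v
            probes["value"] = np.clip(inten, 0.0, None)
            probes["is_unused_feature"] = False
            unused = pd.DataFrame(
                {
                    "gene_id": pd.NA,
                    "junction_id": pd.NA,
                    "tag": pd.NA,
                    "tissue_id": sample,
                    "dilution": label,
                    "dilution_factor": v,
                    "value": np.clip(bg_unused, 0.0, None),
                    "is_unused_feature": True,
                }
            )
            frames.append(probes)
            frames.append(unused)
    out = pd.concat(frames, ignore_index=True)
    out["platform"] = "array"
    return _as_signal(out)


def render_qpcr(truth: SimulationTruth, config: SimConfig | None = None) -> pd.DataFrame:
    """qPCR cycle thresholds: Ct = ct_intercept - theta + noise, two primer sets.

    The two primer sets play the role of the two tags and reuse the
    per-(junction, tag) probe effects.  Each (junction, primer set) fails
    outright (no Ct in any sample) with probability ``qpcr_dropout_prob``.
    """
    config = config or truth.config
    rng = _stream(config.seed, _QPCR_STREAM)
    grid = latent_signal(truth)
    n = len(grid)
    eps = rng.normal(0.0, config.noise_sd, n) if config.noise_sd else np.zeros(n)
    ct = config.ct_intercept - grid["theta0"].to_numpy() + eps

    out = grid[["gene_id", "junction_id", "tag", "tissue_id"]].copy()
    out["platform"] = "qpcr"
    out["value"] = ct
    out["is_unused_feature"] = False

    probes = (
        out[["gene_id", "junction_id", "tag"]]
        .drop_duplicates()
        .sort_values(["gene_id", "junction_id", "tag"], kind="stable")
        .reset_index(drop=True)
    )
    drop = rng.random(len(probes)) < config.qpcr_dropout_prob
    dropped = probes[drop]
    if len(dropped):
        out = out.merge(
            dropped.assign(_drop=True), on=["gene_id", "junction_id", "tag"], how="left"
        )
        out = out[out["_drop"].isna()].drop(columns="_drop")
    return _as_signal(out)


def truth_calls(truth: SimulationTruth) -> pd.DataFrame:
    """Ternary ground-truth splice calls: sign of delta per (junction, tissue)."""
    d = truth.deltas[truth.deltas["tissue_id"] != REFERENCE_TISSUE].copy()
    d["call"] = np.sign(d["delta"]).astype(int)
    return d[["gene_id", "junction_id", "tissue_id", "call"]].reset_index(drop=True)
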