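from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from asmip.synthetic_data import REFERENCE_TISSUE, SimConfig, SimulationTruth

REPO_ROOT = Path(__file__).resolve().parents[1]


@pytest.fixture
def demo_config_path() -> Path:
    return REPO_ROOT / "configs" / "demo.yaml"


def make_theta(rows, platform="seq"):
    """Build a LogSignalTable from (gene, junction, tag, tissue, theta) tuples."""
    df = pd.DataFrame(rows, columns=["gene_id", "junction_id", "tag", "tissue_id", "theta"])
    df["platform"] = platform
    df["missing"] = False
    df["missing_reason"] = ""
    df["low_confidence"] = False
    return df


def make_manual_truth(
    probe_effects,
    baselines,
    deltas=None,
    n_tissues=2,
    config=None,
):
    """Assemble a SimulationTruth from explicit parameter dicts.

    probe_effects: {(gene, junction, tag): p}
    baselines: {(gene, tissue): t}  (must include REF)
    deltas: {(gene, junction, tissue): delta} sparse, default 0
    """
    deltas = deltas or {}
    tissues = sorted({t for (_, t) in baselines if t != REFERENCE_TISSUE})
    pe = pd.DataFrame(
        [(g, j, k, v) for (g, j, k), v in probe_effects.items()],
        columns=["gene_id", "junction_id", "tag", "p"],
    )
    bl = pd.DataFrame(
        [(g, t, v) for (g, t), v in baselines.items()],
        columns=["gene_id", "tissue_id", "t"],
    )
    samples = tissues + [REFERENCE_TISSUE]
    drows = []
    juncs = sorted({(g, j) for (g, j, _) in probe_effects})
    for g, j in juncs:
        for s in samples:
            drows.append((g, j, s, float(deltas.get((g, j, s), 0.0))))
    dl = pd.DataFrame(drows, columns=["gene_id", "junction_id", "tissue_id", "delta"])
    status = {
        (g, j): ("alternative" if any(v != 0 for (gg, jj, _), v in deltas.items() if (gg, jj) == (g, j)) else "constitutive")
        for g, j in juncs
    }
    annot = pd.DataFrame(
        [(g, j, s) for (g, j), s in status.items()],
        columns=["gene_id", "junction_id", "status"],
    )
    config = config or SimConfig(n_tissues=max(2, len(tissues)))
    return SimulationTruth(
        probe_effects=pe,
        baselines=bl,
        deltas=dl,
        annotation=annot,
        tissues=tissues,
        noise_sd=config.noise_sd,
        config=config,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(7)
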