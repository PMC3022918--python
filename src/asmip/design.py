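"""Assay design constants: the probed gene panel and control-set sizes.

The panel targets 17 genes, each probed at every exon-exon junction, in
five individual tissues plus a multi-tissue reference mixture.  A subset
of junctions was additionally measured by junction-spanning qPCR, and a
literature/RefSeq-derived control set (known-alternative positives,
predicted-constitutive negatives) backs the control ROC evaluation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: The five individual tissues profiled (the reference mixture is extra).
TISSUES = ["placenta", "skeletal_muscle", "stomach", "cerebellum", "frontal_lobe"]

#: Junctions with informative junction-spanning qPCR primer sets.
QPCR_JUNCTIONS = 47

#: Known alternatively spliced control junctions (positives).
POSITIVE_CONTROL_JUNCTIONS = 58

#: Predicted constitutive control junctions (negatives).
NEGATIVE_CONTROL_JUNCTIONS = 99


def load_design() -> pd.DataFrame:
    """Return the gene panel with per-gene constitutive/alternative junction counts."""
    path = resources.files("asmip").joinpath("data/probe_design.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def total_junctions(design: pd.DataFrame | None = None) -> int:
    """Total probed junctions: sum of constitutive and alternative counts over genes."""
    if design is None:
        design = load_design()
    return int(design["n_constitutive"].sum() + design["n_alternative"].sum())


def total_events(design: pd.DataFrame | None = None) -> int:
    """Total splice events assayed: every junction in every individual tissue."""
    return total_junctions(design) * len(TISSUES)


def qpcr_events() -> int:
    """Splice events with direct qPCR measurements."""
    return QPCR_JUNCTIONS * len(TISSUES)


def control_set_size() -> int:
    """Size of the combined control set for the control ROC analysis."""
    return POSITIVE_CONTROL_JUNCTIONS + NEGATIVE_CONTROL_JUNCTIONS
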