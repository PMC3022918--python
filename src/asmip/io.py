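"""TSV and config file I/O.

All tables are plain TSV with a one-line header so intermediates are
diff-able and hand-auditable.  ``read_table(write_table(df))`` restores an
equal in-memory frame for every schema the pipeline emits.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

_BOOL_COLS = {"is_unused_feature", "missing", "low_confidence", "concordant_positive",
              "concordant_negative", "discordant"}
_STR_COLS = {"platform", "gene_id", "junction_id", "tissue_id", "dilution",
             "missing_reason", "status", "score_type"}
_INT_COLS = {"tag", "call", "truth_call", "n_tags_used", "label", "call_bin", "truth_bin"}


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in df.columns:
        if col in _BOOL_COLS:
            if df[col].dtype == object:
                df[col] = df[col].map({"True": True, "False": False})
            df[col] = df[col].astype(bool)
        elif col in _INT_COLS:
            df[col] = df[col].astype("Int64")
        elif col in _STR_COLS:
            df[col] = df[col].astype("string").astype(object)
    if "missing_reason" in df.columns:
        df["missing_reason"] = df["missing_reason"].fillna("")
    return df


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_config(data: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
    return path
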