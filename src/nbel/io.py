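"""Readers and writers for the pair-score TSV dialect, configs and manifests.

The TSV dialect: a header line ``pair_id<TAB>src_1<TAB>...<TAB>src_p`` with
one row per protein pair, an optional trailing ``label`` column (0/1), and
no missing entries.  Predictions are written as
``pair_id<TAB>posterior_prob<TAB>predicted``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model_core import Hyperparams, ScoreMatrix

__all__ = [
    "read_pairs_tsv",
    "write_pairs_tsv",
    "write_predictions_tsv",
    "load_hyperparams",
    "write_manifest",
]


def read_pairs_tsv(path) -> tuple[ScoreMatrix, np.ndarray | None]:
    """Parse a pair-score TSV; returns (ScoreMatrix, labels-or-None).

    Rejects duplicate pair identifiers and any non-numeric or missing score
    entry, naming the offending row and column.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str}, keep_default_na=False, na_values=[])
    if df.shape[1] < 2 or df.columns[0] != "pair_id":
        raise ValueError(f"{path}: first column must be 'pair_id' followed by score columns")
    ids = df["pair_id"].tolist()
    if len(set(ids)) != len(ids):
        dup = df["pair_id"][df["pair_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate pair_id {dup!r}")
    score_cols = [c for c in df.columns[1:] if c != "label"]
    if not score_cols:
        raise ValueError(f"{path}: no score columns found")
    numeric = {}
    for c in score_cols + (["label"] if "label" in df.columns else []):
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.index[col.isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"{path}: malformed number in column {c!r}, line {bad[0] + 2} "
                f"(value {df[c].iloc[bad[0]]!r})"
            )
        numeric[c] = col.to_numpy(dtype=float)
    scores = np.column_stack([numeric[c] for c in score_cols])
    labels = None
    if "label" in df.columns:
        lab = numeric["label"]
        if not np.isin(lab, (0, 1)).all():
            raise ValueError(f"{path}: label column must be 0/1")
        labels = lab.astype(np.int64)
    return ScoreMatrix(pair_ids=ids, scores=scores), labels


def write_pairs_tsv(path, sm: ScoreMatrix, labels: np.ndarray | None = None) -> None:
    cols = {"pair_id": sm.pair_ids}
    for j in range(sm.p):
        cols[f"src_{j + 1}"] = sm.scores[:, j]
    if labels is not None:
        cols["label"] = np.asarray(labels, dtype=np.int64)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_predictions_tsv(path, pair_ids, prob, predicted) -> None:
    pd.DataFrame(
        {"pair_id": pair_ids, "posterior_prob": prob, "predicted": np.asarray(predicted, dtype=np.int64)}
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def load_hyperparams(path) -> Hyperparams:
    """Read a flat key/value YAML file into :class:`Hyperparams`.

    Unknown keys are an error, so typos fail loudly.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    valid = set(Hyperparams.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"{path}: unknown hyperparameter keys {sorted(unknown)}")
    return Hyperparams(**raw)


def write_manifest(path, config: dict, seed: int) -> Path:
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump({"config": config, "seed": seed, "version": __version__}, fh, indent=2, default=str)
    return path
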