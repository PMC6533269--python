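"""CSV/JSON readers and writers for the pipeline's file formats."""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    CSV_FLOAT_FORMAT,
    ChoiceTrialTable,
    CondensedSimilarity,
    PatternMatrix,
    WeightMatrix,
    condensed_index,
)
from .errors import ValidationError
from .patterns import VoxelMask

__all__ = [
    "load_pattern_csv",
    "write_pattern_csv",
    "load_weight_csv",
    "write_weight_csv",
    "load_similarity_csv",
    "write_similarity_csv",
    "load_choice_csv",
    "write_choice_csv",
    "load_stopwords",
    "write_voxel_mask",
    "load_voxel_mask",
]


def _read_labeled_csv(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    sep = sep or ("\t" if path.suffix.lower() in (".tsv", ".tab") else ",")
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep))
    labels = header[1:]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValidationError(f"{path.name}: duplicated column label(s) {dupes}")
    df = pd.read_csv(path, index_col=0, sep=sep, float_precision="round_trip")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path.name}: non-numeric cell ({exc})") from None
    if df.isna().any().any():
        raise ValidationError(f"{path.name}: missing or ragged cells")
    return df


def load_pattern_csv(path: str | Path, participant_id: str | None = None) -> PatternMatrix:
    """Read a PatternMatrix CSV/TSV (voxel ids in the first column)."""
    df = _read_labeled_csv(path)
    pid = participant_id if participant_id is not None else Path(path).stem
    return PatternMatrix(
        df.to_numpy(), [str(c) for c in df.columns], [str(i) for i in df.index], pid
    )


def write_pattern_csv(m: PatternMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, float_format=CSV_FLOAT_FORMAT)


def load_weight_csv(path: str | Path, normalized: bool = False) -> WeightMatrix:
    df = _read_labeled_csv(path)
    return WeightMatrix(
        df.to_numpy(),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        normalized=normalized,
    )


def write_weight_csv(w: WeightMatrix, path: str | Path) -> None:
    w.to_frame().to_csv(path, float_format=CSV_FLOAT_FORMAT)


def write_similarity_csv(sim: CondensedSimilarity, path: str | Path) -> None:
    sim.to_frame().to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def load_similarity_csv(path: str | Path) -> CondensedSimilarity:
    """Read a condensed similarity CSV (target_i, target_j, value, kind).

    Rows must follow the canonical pair ordering implied by the label order
    of first appearance.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("target_i", "target_j", "value", "kind"):
        if col not in df.columns:
            raise ValidationError(f"{Path(path).name}: missing column {col!r}")
    labels: list[str] = []
    for t in pd.concat([df["target_i"], df["target_j"]]).astype(str):
        if t not in labels:
            labels.append(t)
    n = len(labels)
    if len(df) != n * (n - 1) // 2:
        raise ValidationError(
            f"{Path(path).name}: {len(df)} rows for {n} targets; expected "
            f"{n * (n - 1) // 2}"
        )
    pos = {t: k for k, t in enumerate(labels)}
    i, j = condensed_index(n)
    got_i = df["target_i"].astype(str).map(pos).to_numpy()
    got_j = df["target_j"].astype(str).map(pos).to_numpy()
    lo, hi = np.minimum(got_i, got_j), np.maximum(got_i, got_j)
    if not (np.array_equal(lo, i) and np.array_equal(hi, j)):
        raise ValidationError(f"{Path(path).name}: rows not in canonical pair order")
    kinds = set(df["kind"].astype(str))
    if len(kinds) != 1:
        raise ValidationError(f"{Path(path).name}: mixed similarity kinds {kinds}")
    return CondensedSimilarity(df["value"].to_numpy(float), labels, kinds.pop())


def load_choice_csv(path: str | Path) -> ChoiceTrialTable:
    return ChoiceTrialTable(pd.read_csv(path, float_precision="round_trip"))


def write_choice_csv(t: ChoiceTrialTable, path: str | Path) -> None:
    t.frame.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def load_stopwords(path: str | Path) -> list[str]:
    """One word per line; blank lines and '#' comments ignored."""
    words = []
    for line in Path(path).read_text().splitlines():
        word = line.strip()
        if word and not word.startswith("#"):
            words.append(word)
    return words


def write_voxel_mask(mask: VoxelMask, path: str | Path) -> None:
    """One voxel id per line, with a JSON sidecar of threshold and reliability."""
    path = Path(path)
    path.write_text("\n".join(mask.selected) + "\n")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "threshold_used": mask.threshold_used,
                "patternwise_reliability": mask.patternwise_reliability,
                "n_selected": len(mask.selected),
            },
            indent=2,
        )
    )


def load_voxel_mask(path: str | Path) -> VoxelMask:
    path = Path(path)
    selected = [x for x in path.read_text().splitlines() if x.strip()]
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return VoxelMask(selected, meta["threshold_used"], meta["patternwise_reliability"])
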