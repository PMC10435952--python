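"""Readers and writers for the package's tabular interchange formats.

All tables are TSV or CSV (delimiter chosen from the file extension), UTF-8,
"." decimal separator:

* labels table:      sample_id, label [, replicate_sd]
* features table:    sample_id + one numeric column per feature
* confounder table:  sample_id + one column per confounder
* pair set:          hi, lo, delta_used
* score table:       sample_id, score
* verdict table:     hi, lo, credit
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .auc import PairVerdict, ScoreTable
from .errors import InputError
from .rankability import LabeledSample, RankablePair, RankablePairSet

logger = logging.getLogger(__name__)

__all__ = [
    "read_dataset",
    "read_table",
    "read_pairs", "write_pairs",
    "read_scores", "write_scores",
    "read_verdicts", "write_verdicts",
    "write_report",
]


def _sep(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV/CSV with a header row."""
    return pd.read_csv(path, sep=_sep(path))


def _indexed(df: pd.DataFrame, what: str) -> pd.DataFrame:
    if "sample_id" not in df.columns:
        raise InputError(f"{what} table lacks a 'sample_id' column")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise InputError(f"duplicate sample_id in {what} table: {sorted(set(dup))}")
    return df.set_index("sample_id")


def read_dataset(
    features_path: Optional[str | Path],
    labels_path: str | Path,
    confounders_path: Optional[str | Path] = None,
) -> list[LabeledSample]:
    """Join feature / label / confounder tables on sample_id.

    Samples present in the features table but missing a label are dropped
    with a warning; feature column order is preserved.  ``features_path``
    may be None when only precomputed scores will be evaluated.
    """
    labels = _indexed(read_table(labels_path), "labels")
    if "label" not in labels.columns:
        raise InputError("labels table lacks a 'label' column")

    feats = None
    if features_path is not None:
        feats = _indexed(read_table(features_path), "features")
        bad = feats.columns[~feats.dtypes.map(
            lambda t: np.issubdtype(t, np.number))]
        if len(bad):
            for col in bad:
                row = feats[col][pd.to_numeric(feats[col], errors="coerce").isna()]
                if len(row):
                    raise InputError(
                        f"non-numeric feature cell at row {row.index[0]!r}, "
                        f"column {col!r}"
                    )
            feats = feats.astype(float)
        dropped = feats.index.difference(labels.index)
        if len(dropped):
            logger.warning(
                "dropping %d feature-table samples with no label: %s",
                len(dropped), sorted(dropped),
            )
        ids = [i for i in feats.index if i in labels.index]
    else:
        ids = list(labels.index)

    confs = None
    if confounders_path is not None:
        confs = _indexed(read_table(confounders_path), "confounders")

    out = []
    for sid in ids:
        sd = None
        if "replicate_sd" in labels.columns:
            v = labels.at[sid, "replicate_sd"]
            sd = None if pd.isna(v) else float(v)
        cmap = {}
        if confs is not None and sid in confs.index:
            cmap = {
                c: (v if isinstance(v := confs.at[sid, c], str) else float(v))
                for c in confs.columns
            }
        out.append(
            LabeledSample(
                sample_id=str(sid),
                label=float(labels.at[sid, "label"]),
                features=(
                    feats.loc[sid].to_numpy(dtype=float)
                    if feats is not None else None
                ),
                replicate_sd=sd,
                confounders=cmap,
            )
        )
    return out


def write_pairs(pairs: RankablePairSet, path: str | Path) -> None:
    pd.DataFrame(
        [(p.hi, p.lo, p.delta_used) for p in pairs],
        columns=["hi", "lo", "delta_used"],
    ).to_csv(path, sep=_sep(path), index=False)


def read_pairs(path: str | Path, n_samples: Optional[int] = None) -> RankablePairSet:
    df = read_table(path)
    pairs = tuple(
        RankablePair(hi=str(r.hi), lo=str(r.lo), delta_used=float(r.delta_used))
        for r in df.itertuples()
    )
    if n_samples is None:
        n_samples = len({s for p in pairs for s in (p.hi, p.lo)})
    return RankablePairSet(pairs=pairs, n_samples=n_samples)


def write_scores(scores: ScoreTable, path: str | Path) -> None:
    pd.DataFrame(
        sorted(scores.entries.items()), columns=["sample_id", "score"]
    ).to_csv(path, sep=_sep(path), index=False)


def read_scores(path: str | Path) -> ScoreTable:
    df = read_table(path)
    if not {"sample_id", "score"} <= set(df.columns):
        raise InputError("scores table needs 'sample_id' and 'score' columns")
    return ScoreTable(
        entries={str(r.sample_id): float(r.score) for r in df.itertuples()}
    )


def write_verdicts(verdicts: Sequence[PairVerdict], path: str | Path) -> None:
    pd.DataFrame(
        [(v.pair.hi, v.pair.lo, v.pair.delta_used, v.credit) for v in verdicts],
        columns=["hi", "lo", "delta_used", "credit"],
    ).to_csv(path, sep=_sep(path), index=False)


def read_verdicts(path: str | Path) -> list[PairVerdict]:
    df = read_table(path)
    delta = df["delta_used"] if "delta_used" in df.columns else [0.5] * len(df)
    return [
        PairVerdict(
            pair=RankablePair(hi=str(h), lo=str(l), delta_used=float(d)),
            credit=float(c),
        )
        for h, l, d, c in zip(df["hi"], df["lo"], delta, df["credit"])
    ]


def write_report(results: dict, out_path: str | Path, seed: Optional[int] = None) -> None:
    """Machine-readable JSON with stable key ordering for diffability."""
    payload = dict(results)
    if seed is not None:
        payload["seed"] = seed
    import paireval

    payload.setdefault("versions", {})["paireval"] = paireval.__version__
    Path(out_path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_jsonify) + "\n"
    )


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return vars(obj)
    return str(obj)
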