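"""Glue from recordings to feature tables and LOSO-ready datasets."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .features import (
    DEFAULT_BANDS,
    BandDefinition,
    extract_conventional_features,
    extract_knowledge_features,
)
from .io import Hypnogram, Recording, SleepStage, segment_epochs
from .preprocess import FilterSpec, bandpass_filter


def extract_recording_features(
    recording: Recording,
    hypnogram: Hypnogram | None = None,
    feature_mode: str = "knowledge",
    filter_spec: FilterSpec | None = None,
    bands: dict[str, BandDefinition] | None = None,
) -> tuple[np.ndarray, list[SleepStage], list[str]]:
    """Band-pass each 30-s epoch and extract one feature vector per epoch.

    Returns (X, stages, schema); stages are UNKNOWN when no hypnogram is
    given.
    """
    if feature_mode not in ("knowledge", "conventional"):
        raise ValueError(f"unknown feature_mode {feature_mode!r}")
    filter_spec = filter_spec or FilterSpec()
    rows, stages, schema = [], [], None
    for epoch, stage in segment_epochs(recording, hypnogram):
        filtered = bandpass_filter(epoch, filter_spec)
        if feature_mode == "knowledge":
            fv = extract_knowledge_features(filtered, bands=bands)
        else:
            fv = extract_conventional_features(filtered)
        rows.append(fv.values)
        stages.append(stage)
        schema = fv.schema
    return np.vstack(rows), stages, schema


def features_to_frame(
    X: np.ndarray, stages: list[SleepStage], schema: list[str], subject_id: str
) -> pd.DataFrame:
    """Feature matrix as a tidy table with subject/epoch/stage columns."""
    df = pd.DataFrame(X, columns=schema)
    df.insert(0, "subject_id", subject_id)
    df.insert(1, "epoch_index", np.arange(len(stages)))
    df.insert(2, "stage", [s.value for s in stages])
    return df


def write_feature_csv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, index=False)


def read_feature_csv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def frame_to_dataset(
    df: pd.DataFrame,
) -> dict[str, tuple[np.ndarray, list[SleepStage]]]:
    """Split a (possibly multi-subject) feature table into a LOSO dataset."""
    meta = ["subject_id", "epoch_index", "stage"]
    feat_cols = [c for c in df.columns if c not in meta]
    out: dict[str, tuple[np.ndarray, list[SleepStage]]] = {}
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("epoch_index")
        out[str(sid)] = (
            grp[feat_cols].to_numpy(dtype=float),
            [SleepStage(s) for s in grp["stage"]],
        )
    return out


def cohort_to_dataset(
    cohort: list[tuple[Recording, Hypnogram]],
    feature_mode: str = "knowledge",
    filter_spec: FilterSpec | None = None,
    bands: dict[str, BandDefinition] | None = None,
) -> dict[str, tuple[np.ndarray, list[SleepStage]]]:
    """Per-subject labeled feature sets for in-memory cohorts."""
    out = {}
    for rec, hyp in cohort:
        X, y, _ = extract_recording_features(
            rec, hyp, feature_mode=feature_mode, filter_spec=filter_spec, bands=bands
        )
        out[rec.subject_id] = (X, y)
    return out
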