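"""On-disk schemas for the pipeline: samples, layouts, trials, measures.

All files are plain CSV with documented headers; coordinates are screen
pixels (origin top-left, y increasing downward) and word bounding boxes are
half-open ``[x_min, x_max)``.  Word indices are 0-based internally while
region labels stay 1-based (1..5) as conventionally printed.

Schemas
-------
samples.csv        participant, trial, t, x, y          (t in ms from trial onset)
layout.csv         trial, word_index, text, x_min, x_max, y_min, y_max, region
trials.csv         participant_id, trial_id, item_id, element, grammaticality,
                   gender, is_filler, is_practice, has_question
measures.csv       participant_id, item_id, region, gaze_duration, go_past,
                   total_duration, fp_reg, reg_in, grammaticality, gender,
                   element, source
comprehension.csv  participant_id, item_id, correct
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ELEMENTS, GENDERS, GRAMMATICALITY

log = logging.getLogger("motr")

MEASURE_COLUMNS = ("gaze_duration", "go_past", "total_duration", "fp_reg", "reg_in")
SOURCES = ("motr", "eyetracking")


class SchemaError(ValueError):
    """A file does not have the expected columns."""


class ValidationError(ValueError):
    """A file has the right shape but violates a content invariant."""


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


# ---------------------------------------------------------------------------
# samples
# ---------------------------------------------------------------------------

def read_samples(path: str | Path) -> pd.DataFrame:
    """Read timestamped mouse samples, sorted by (participant, trial, t).

    Rows out of time order are sorted (with a warning); duplicated
    (participant, trial, t) keys are a validation error.  x/y must be finite.
    """
    df = pd.read_csv(path)
    _require_columns(df, ("participant", "trial", "t", "x", "y"), str(path))
    for col in ("t", "x", "y"):
        if not np.isfinite(df[col].to_numpy(dtype=float)).all():
            bad = df.index[~np.isfinite(df[col].astype(float))].tolist()[:5]
            raise ValidationError(f"{path}: non-finite {col} at rows {bad}")
    key = ["participant", "trial"]
    if not df.groupby(key, sort=False)["t"].apply(lambda s: s.is_monotonic_increasing).all():
        log.warning("%s: samples not time-ordered within trial; sorting", path)
        df = df.sort_values(key + ["t"], kind="stable").reset_index(drop=True)
    dup = df.duplicated(subset=key + ["t"])
    if dup.any():
        first = df.loc[dup, key + ["t"]].iloc[0]
        raise ValidationError(
            f"{path}: duplicated sample time t={first['t']} in trial "
            f"{first['trial']!r} of participant {first['participant']!r}"
        )
    log.info("read %d samples from %s", len(df), path)
    return df.reset_index(drop=True)


def write_samples(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, ("participant", "trial", "t", "x", "y"), "samples")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# layouts
# ---------------------------------------------------------------------------

LAYOUT_COLUMNS = ("trial", "word_index", "text", "x_min", "x_max", "y_min", "y_max", "region")


def _boxes_overlap(a, b) -> bool:
    # half-open boxes: touching edges do not overlap
    return (a.x_min < b.x_max and b.x_min < a.x_max
            and a.y_min < b.y_max and b.y_min < a.y_max)


def validate_layout(df: pd.DataFrame) -> None:
    for trial, g in df.groupby("trial", sort=False):
        g = g.sort_values("word_index")
        idx = g["word_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise ValidationError(f"layout trial {trial!r}: word_index not contiguous from 0")
        reg = g["region"].to_numpy()
        if (np.diff(reg) < 0).any():
            raise ValidationError(
                f"layout trial {trial!r}: region labels decrease along word order"
            )
        if (g["x_max"].to_numpy() <= g["x_min"].to_numpy()).any() or (
            g["y_max"].to_numpy() <= g["y_min"].to_numpy()
        ).any():
            raise ValidationError(f"layout trial {trial!r}: empty bounding box")
        recs = list(g.itertuples())
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                if _boxes_overlap(recs[i], recs[j]):
                    raise ValidationError(
                        f"layout trial {trial!r}: boxes of words "
                        f"{recs[i].word_index} and {recs[j].word_index} overlap"
                    )


def read_layout(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, LAYOUT_COLUMNS, str(path))
    validate_layout(df)
    log.info("read layout for %d trials from %s", df["trial"].nunique(), path)
    return df.reset_index(drop=True)


def write_layout(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, LAYOUT_COLUMNS, "layout")
    validate_layout(df)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# trials / comprehension
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = (
    "participant_id", "trial_id", "item_id", "element", "grammaticality",
    "gender", "is_filler", "is_practice", "has_question",
)


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, TRIAL_COLUMNS, str(path))
    return df


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    out = df.rename(columns={"participant": "participant_id"})
    _require_columns(out, TRIAL_COLUMNS, "trials")
    out.loc[:, TRIAL_COLUMNS].to_csv(path, index=False)


def read_comprehension(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ("participant_id", "item_id", "correct"), str(path))
    vals = set(df["correct"].unique())
    if not vals <= {0, 1}:
        raise ValidationError(f"{path}: correct must be binary, found {sorted(vals - {0, 1})}")
    return df


def write_comprehension(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# measures
# ---------------------------------------------------------------------------

def validate_measures(df: pd.DataFrame, what: str = "measures") -> None:
    for col, allowed in (
        ("grammaticality", GRAMMATICALITY),
        ("gender", GENDERS),
        ("element", ELEMENTS),
        ("source", SOURCES),
    ):
        bad = set(df[col].dropna().unique()) - set(allowed)
        if bad:
            raise ValidationError(
                f"{what}: unknown {col} level(s) {sorted(bad)}; allowed: {list(allowed)}"
            )
    for col in ("gaze_duration", "go_past", "total_duration"):
        v = df[col].to_numpy(dtype=float)
        if (v[~np.isnan(v)] < 0).any():
            raise ValidationError(f"{what}: negative {col}")
    for col in ("fp_reg", "reg_in"):
        v = df[col].dropna().unique()
        if not set(np.asarray(v, dtype=float)) <= {0.0, 1.0}:
            raise ValidationError(f"{what}: {col} must be binary")
    gaze = df["gaze_duration"].to_numpy(dtype=float)
    for other in ("go_past", "total_duration"):
        o = df[other].to_numpy(dtype=float)
        both = ~np.isnan(gaze) & ~np.isnan(o)
        if (gaze[both] > o[both] + 1e-9).any():
            raise ValidationError(f"{what}: gaze_duration exceeds {other}")


def read_measures(path: str | Path, source: str | None = None) -> pd.DataFrame:
    """Read a reading-measure table; identical models fit either source.

    ``source`` tags rows ('motr' or 'eyetracking') when the file does not
    carry a source column, so externally computed (eye-tracking style)
    measure tables flow through the same analysis path.
    """
    df = pd.read_csv(path)
    if "source" not in df.columns:
        if source is None:
            raise SchemaError(f"{path}: no source column and no source argument given")
        df["source"] = source
    elif source is not None and not (df["source"] == source).all():
        raise ValidationError(f"{path}: source column conflicts with source={source!r}")
    _require_columns(
        df,
        ("participant_id", "item_id", "region") + MEASURE_COLUMNS
        + ("grammaticality", "gender", "element", "source"),
        str(path),
    )
    validate_measures(df, str(path))
    return df


def write_measures(df: pd.DataFrame, path: str | Path) -> None:
    validate_measures(df)
    df.to_csv(path, index=False)
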