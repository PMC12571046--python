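"""From mouse trajectories to attentional associations to reading measures.

A mouse-tracking-for-reading trial yields 20 Hz cursor samples.  Each sample
is assigned to the nearest word (Euclidean distance to the word's bounding
box, zero inside; leftmost word wins ties); maximal runs of consecutive
samples on the same word are merged into *attentional associations*, the
fixation analogue.  Associations shorter than 160 ms or longer than 4000 ms
are excluded (bounds inclusive: exactly 160 ms or 4000 ms is kept), after
which adjacent same-word associations are re-merged by default.  Five
reading measures are then computed per word or region:

* gaze duration   - first-pass dwell before any exit,
* go-past time    - all dwell from first entry until first passing rightward,
* total duration  - all dwell,
* FPReg           - regression launched at the end of the first pass,
* RegIn           - a later fixation landing on the unit from its right.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("motr")

#: Nominal inter-sample period at 20 Hz sampling, in ms.
SAMPLE_PERIOD_MS = 50.0


@dataclass
class FilterPolicy:
    """Association-duration exclusion rule (fixation filtering analogue)."""

    min_duration: float = 160.0
    max_duration: float = 4000.0
    remerge_after_filter: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_duration < self.max_duration:
            raise ValueError("need 0 < min_duration < max_duration")


# ---------------------------------------------------------------------------
# sample -> word assignment
# ---------------------------------------------------------------------------

def assign_nearest_word(samples: pd.DataFrame, layout: pd.DataFrame) -> np.ndarray:
    """Nearest word (0-based index) for every sample of one trial.

    Distance is Euclidean from the point to the nearest point of the word's
    half-open bounding box (0 inside the box).  Exact ties go to the word
    with the smaller index (leftmost in reading order).
    """
    if len(layout) == 0:
        raise ValueError("empty layout: no words to assign samples to")
    lay = layout.sort_values("word_index")
    x = samples["x"].to_numpy(dtype=float)[:, None]
    y = samples["y"].to_numpy(dtype=float)[:, None]
    dx = np.maximum(
        np.maximum(lay["x_min"].to_numpy()[None, :] - x, x - lay["x_max"].to_numpy()[None, :]),
        0.0,
    )
    dy = np.maximum(
        np.maximum(lay["y_min"].to_numpy()[None, :] - y, y - lay["y_max"].to_numpy()[None, :]),
        0.0,
    )
    d2 = dx * dx + dy * dy
    return lay["word_index"].to_numpy()[np.argmin(d2, axis=1)]


# ---------------------------------------------------------------------------
# associations
# ---------------------------------------------------------------------------

def merge_associations(
    samples: pd.DataFrame,
    word_index: np.ndarray,
    period: float = SAMPLE_PERIOD_MS,
) -> pd.DataFrame:
    """Merge consecutive same-word samples of one time-ordered trial.

    One association per maximal run; its duration runs to the onset of the
    next association, and the final run is credited one nominal sample
    period beyond its last sample.
    """
    t = samples["t"].to_numpy(dtype=float)
    w = np.asarray(word_index)
    if len(t) == 0:
        return pd.DataFrame(columns=["word_index", "onset", "duration"])
    starts = np.flatnonzero(np.r_[True, w[1:] != w[:-1]])
    onsets = t[starts]
    ends = np.r_[onsets[1:], t[-1] + period]
    return pd.DataFrame(
        {"word_index": w[starts], "onset": onsets, "duration": ends - onsets}
    )


def _remerge(assocs: pd.DataFrame) -> pd.DataFrame:
    """Merge now-adjacent same-word associations, summing durations."""
    if len(assocs) == 0:
        return assocs
    w = assocs["word_index"].to_numpy()
    starts = np.flatnonzero(np.r_[True, w[1:] != w[:-1]])
    grp = np.cumsum(np.r_[True, w[1:] != w[:-1]]) - 1
    dur = np.bincount(grp, weights=assocs["duration"].to_numpy())
    return pd.DataFrame(
        {
            "word_index": w[starts],
            "onset": assocs["onset"].to_numpy()[starts],
            "duration": dur,
        }
    )


def filter_associations(assocs: pd.DataFrame, policy: FilterPolicy | None = None) -> pd.DataFrame:
    """Apply the duration exclusion rule to one trial's associations.

    Strictly-shorter-than-min and strictly-longer-than-max associations are
    removed.  If ``remerge_after_filter``, associations that became adjacent
    on the same word are merged (durations summed) and the merged result is
    re-checked against the maximum only.
    """
    if policy is None:
        policy = FilterPolicy()
    keep = (assocs["duration"] >= policy.min_duration) & (
        assocs["duration"] <= policy.max_duration
    )
    out = assocs.loc[keep].reset_index(drop=True)
    if policy.remerge_after_filter:
        out = _remerge(out)
        out = out.loc[out["duration"] <= policy.max_duration].reset_index(drop=True)
    log.debug("filtered associations: %d -> %d", len(assocs), len(out))
    return out


# ---------------------------------------------------------------------------
# reading measures
# ---------------------------------------------------------------------------

def _unit_measures(units: np.ndarray, durations: np.ndarray, all_units: np.ndarray) -> pd.DataFrame:
    """Five reading measures over a merged unit sequence of one trial.

    ``units`` must have no two consecutive equal entries.  Units in
    ``all_units`` that never receive an association get all-missing rows.
    Go-past is missing for units never exited rightward (right-censored);
    FPReg is missing when the trial ends during the unit's first pass.
    """
    n = len(units)
    csum = np.r_[0.0, np.cumsum(durations)]
    rows = []
    for u in all_units:
        idx = np.flatnonzero(units == u)
        if len(idx) == 0:
            rows.append((u, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        f = idx[0]
        gaze = durations[f]
        if f + 1 < n:
            fp_reg = 1.0 if units[f + 1] < u else 0.0
        else:
            fp_reg = np.nan
        right = np.flatnonzero(units[f:] > u)
        if len(right):
            go_past = csum[f + right[0]] - csum[f]
        else:
            go_past = np.nan
        total = durations[idx].sum()
        # RegIn: u revisited after having been exited rightward — running
        # max of units from the first encounter, checked before each revisit
        prior = np.r_[-np.inf, np.maximum.accumulate(units[f:])[:-1]]
        reg_in = 1.0 if (prior[idx - f] > u).any() else 0.0
        rows.append((u, gaze, go_past, total, fp_reg, reg_in))
    return pd.DataFrame(
        rows,
        columns=["unit", "gaze_duration", "go_past", "total_duration", "fp_reg", "reg_in"],
    )


def compute_measures(
    assocs: pd.DataFrame,
    layout: pd.DataFrame,
    granularity: str = "region",
) -> pd.DataFrame:
    """Reading measures for one trial at word or region granularity.

    At region granularity, associations are relabelled by their word's
    region and adjacent same-region associations merged before the measure
    walk; "to the right" is then region order.  Layout units with no
    association get all-missing rows.
    """
    if granularity not in ("word", "region"):
        raise ValueError("granularity must be 'word' or 'region'")
    word_region = dict(
        zip(layout["word_index"].to_numpy(), layout["region"].to_numpy())
    )
    unknown = set(assocs["word_index"]) - set(word_region)
    if unknown:
        raise KeyError(f"associations reference words absent from layout: {sorted(unknown)}")
    if granularity == "word":
        units = assocs["word_index"].to_numpy()
        all_units = np.sort(layout["word_index"].unique())
    else:
        units = np.array([word_region[w] for w in assocs["word_index"]])
        all_units = np.sort(layout["region"].unique())
    # collapse consecutive same-unit runs so each first pass is one row
    merged = _remerge(
        pd.DataFrame(
            {
                "word_index": units,
                "onset": assocs["onset"].to_numpy() if len(assocs) else [],
                "duration": assocs["duration"].to_numpy(dtype=float),
            }
        )
    )
    out = _unit_measures(
        merged["word_index"].to_numpy(), merged["duration"].to_numpy(dtype=float), all_units
    )
    return out.rename(columns={"unit": granularity})


def measures_from_samples(
    samples: pd.DataFrame,
    layouts: pd.DataFrame,
    policy: FilterPolicy | None = None,
    granularity: str = "region",
    period: float = SAMPLE_PERIOD_MS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-trial pipeline over a samples table.

    Returns ``(measures, associations)``; measures carry participant and
    trial keys plus one row per layout unit.
    """
    if policy is None:
        policy = FilterPolicy()
    lay_by_trial = dict(tuple(layouts.groupby("trial", sort=False)))
    all_measures, all_assocs = [], []
    n_in = n_out = 0
    for (participant, trial), g in samples.groupby(["participant", "trial"], sort=False):
        if trial not in lay_by_trial:
            raise KeyError(f"no layout for trial {trial!r}")
        lay = lay_by_trial[trial]
        w = assign_nearest_word(g, lay)
        assoc = merge_associations(g, w, period=period)
        n_in += len(assoc)
        assoc = filter_associations(assoc, policy)
        n_out += len(assoc)
        region_map = dict(zip(lay["word_index"], lay["region"]))
        a = assoc.assign(
            participant=participant,
            trial=trial,
            region=[region_map[w_] for w_ in assoc["word_index"]],
        )
        all_assocs.append(a)
        m = compute_measures(assoc, lay, granularity=granularity)
        m.insert(0, "participant", participant)
        m.insert(1, "trial", trial)
        all_measures.append(m)
    log.info("associations kept after filtering: %d of %d", n_out, n_in)
    measures = pd.concat(all_measures, ignore_index=True) if all_measures else pd.DataFrame()
    assocs = pd.concat(all_assocs, ignore_index=True) if all_assocs else pd.DataFrame()
    return measures, assocs


# ---------------------------------------------------------------------------
# participant exclusion
# ---------------------------------------------------------------------------

def filter_participants(
    measures: pd.DataFrame,
    comprehension: pd.DataFrame,
    threshold: float = 0.8,
    participant_col: str = "participant_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop participants whose comprehension accuracy falls below threshold.

    Accuracy exactly at the threshold is retained.  Returns the retained
    measures and a per-participant report (accuracy, n_questions, excluded).
    Raises if a participant in the measures has no comprehension records.
    """
    acc = (
        comprehension.groupby("participant_id")["correct"]
        .agg(accuracy="mean", n_questions="size")
        .reset_index()
    )
    participants = pd.Index(measures[participant_col].unique())
    missing = participants.difference(acc["participant_id"])
    if len(missing):
        raise ValueError(
            f"no comprehension records for participant(s) {sorted(missing)}; "
            "cannot assess accuracy"
        )
    acc = acc[acc["participant_id"].isin(participants)].reset_index(drop=True)
    acc["excluded"] = acc["accuracy"] < threshold
    dropped = set(acc.loc[acc["excluded"], "participant_id"])
    kept = measures[~measures[participant_col].isin(dropped)].reset_index(drop=True)
    log.info(
        "participant filter at %.2f: excluded %d of %d participants",
        threshold, len(dropped), len(acc),
    )
    return kept, acc
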