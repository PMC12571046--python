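"""Experimental design cells and study-plan generation.

The study crosses Grammaticality (match vs. mismatch between the agreeing
element and the head noun), Gender of the head noun (feminine vs. masculine),
and the Agreeing element (modifying adjective, predicative adjective, or
verb).  Because no verb instantiates phrase-internal agreement, the nominal
2 x 2 x 2 design collapses to six element-by-grammaticality conditions;
crossing in gender yields twelve design cells.  Agreement type (internal vs.
external) and lexical category (adjective vs. verb) are deterministic
functions of the agreeing element and are modelled through contrast coding
rather than as separate factors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

ELEMENTS = ("modAdj", "predAdj", "verb")
GRAMMATICALITY = ("match", "mismatch")
GENDERS = ("feminine", "masculine")

#: Number of stimulus regions; the head noun sits in region 3.
N_REGIONS = 5
CRITICAL_REGION = 3


@dataclass(frozen=True)
class DesignCell:
    """One of the twelve design cells (element x grammaticality x gender)."""

    element: str
    grammaticality: str
    gender: str

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise ValueError(f"element must be one of {ELEMENTS}, got {self.element!r}")
        if self.grammaticality not in GRAMMATICALITY:
            raise ValueError(
                f"grammaticality must be one of {GRAMMATICALITY}, got {self.grammaticality!r}"
            )
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}, got {self.gender!r}")

    @property
    def agr_type(self) -> str:
        """Internal agreement holds only inside the nominal phrase (modAdj)."""
        return "internal" if self.element == "modAdj" else "external"

    @property
    def lex_cat(self) -> str:
        return "verb" if self.element == "verb" else "adjective"

    @property
    def label(self) -> str:
        return f"{self.element}:{self.grammaticality}:{self.gender}"


#: Canonical ordering of the twelve cells, used everywhere a cell axis appears.
ALL_CELLS: tuple[DesignCell, ...] = tuple(
    DesignCell(e, g, d)
    for e, g, d in itertools.product(ELEMENTS, GRAMMATICALITY, GENDERS)
)
CELL_LABELS: tuple[str, ...] = tuple(c.label for c in ALL_CELLS)


def cell_label(element: str, grammaticality: str, gender: str) -> str:
    return DesignCell(element, grammaticality, gender).label


@dataclass
class StudyPlan:
    """Counts defining one instantiation of the reading study.

    Defaults reproduce the study design: 24 target items (8 per agreeing
    element), 48 fillers (half grammatical), 4 practice items, 3 lists,
    and 42 comprehension questions over the 72 non-practice items.
    """

    n_participants: int = 64
    n_items_per_element: int = 8
    n_fillers: int = 48
    n_practice: int = 4
    n_lists: int = 3
    n_questions: int = 42

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if self.n_items_per_element % 2:
            raise ValueError(
                "n_items_per_element must be even so that each list assigns half "
                "of each element's items to the mismatch condition"
            )
        if self.n_lists < 1:
            raise ValueError("n_lists must be positive")
        total = self.n_targets + self.n_fillers
        if self.n_questions > total:
            raise ValueError("n_questions exceeds the number of non-practice items")

    @property
    def n_targets(self) -> int:
        return 3 * self.n_items_per_element

    @property
    def items_per_condition(self) -> int:
        """Target items each participant reads per agreeing element."""
        return self.n_items_per_element


def _target_item_ids(plan: StudyPlan) -> list[tuple[str, str, int]]:
    ids = []
    k = 0
    for e in ELEMENTS:
        for j in range(plan.n_items_per_element):
            k += 1
            ids.append((f"t{k:02d}", e, j))
    return ids


def make_design(plan: StudyPlan | None = None, seed: int = 0) -> pd.DataFrame:
    """Build the full trial table: one row per participant x item.

    List assignment rotates participants over ``n_lists`` lists.  Within a
    list, each element's items split evenly between match and mismatch, and
    head-noun gender is counterbalanced so that every participant sees two
    items in each of the twelve design cells (at the default plan size).
    Across lists every target item occurs in both grammaticality conditions,
    so no participant ever sees an item in more than one condition.

    Returns a DataFrame with columns: participant_id, list, item_id,
    trial_index, element, grammaticality, gender, is_filler, is_practice,
    has_question, trial_id.
    """
    plan = plan or StudyPlan()
    rng = np.random.default_rng(seed)
    targets = _target_item_ids(plan)
    filler_ids = [f"f{j + 1:02d}" for j in range(plan.n_fillers)]
    practice_ids = [f"pr{j + 1}" for j in range(plan.n_practice)]

    # Comprehension questions attach to a fixed item subset, shared by all
    # participants (questions are a property of the item).
    non_practice = [t[0] for t in targets] + filler_ids
    question_items = set(
        rng.choice(non_practice, size=plan.n_questions, replace=False)
    )

    rows = []
    for p in range(plan.n_participants):
        pid = f"p{p + 1:03d}"
        lst = p % plan.n_lists
        trial_rows = []
        for item_id, element, j in targets:
            gram = GRAMMATICALITY[(j + lst) % 2]
            gender = GENDERS[(j // 2 + lst) % 2]
            trial_rows.append(
                dict(
                    participant_id=pid,
                    list=lst,
                    item_id=item_id,
                    element=element,
                    grammaticality=gram,
                    gender=gender,
                    is_filler=False,
                    is_practice=False,
                )
            )
        for j, item_id in enumerate(filler_ids):
            trial_rows.append(
                dict(
                    participant_id=pid,
                    list=lst,
                    item_id=item_id,
                    element=None,
                    grammaticality=GRAMMATICALITY[j % 2],
                    gender=None,
                    is_filler=True,
                    is_practice=False,
                )
            )
        for item_id in practice_ids:
            trial_rows.append(
                dict(
                    participant_id=pid,
                    list=lst,
                    item_id=item_id,
                    element=None,
                    grammaticality="match",
                    gender=None,
                    is_filler=True,
                    is_practice=True,
                )
            )
        # Per-participant presentation order: practice first, then a
        # participant-specific shuffle of the experimental items.
        exp = [r for r in trial_rows if not r["is_practice"]]
        prac = [r for r in trial_rows if r["is_practice"]]
        prng = participant_rng(seed, p)
        order = prng.permutation(len(exp))
        for i, r in enumerate(prac):
            r["trial_index"] = i
        for i, k in enumerate(order):
            exp[k]["trial_index"] = len(prac) + i
        rows.extend(prac + exp)

    df = pd.DataFrame(rows)
    df["has_question"] = df["item_id"].isin(question_items) & ~df["is_practice"]
    df["trial_id"] = _trial_ids(df)
    return df.sort_values(["participant_id", "trial_index"]).reset_index(drop=True)


def _trial_ids(df: pd.DataFrame) -> pd.Series:
    """Condition-specific trial identifier (layouts differ by condition)."""

    def one(row):
        if row.is_filler:
            return str(row.item_id)
        return f"{row.item_id}.{row.grammaticality[:2]}.{row.gender[0]}"

    return df.apply(one, axis=1)


def participant_rng(master_seed: int, participant_index: int) -> np.random.Generator:
    """Counter-derived per-participant substream.

    Adding participants never perturbs the streams of existing ones.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), int(participant_index)])
    )
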