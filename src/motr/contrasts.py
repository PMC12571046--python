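"""Hypothesis-matrix contrast coding via the generalized inverse.

Comparisons of interest are written down directly as *hypothesis* weights
over the twelve design cells (each non-intercept row sums to zero and is
scaled so that applying it to a vector of cell means yields a difference of
averaged condition means).  The model's coding (contrast) matrix is the
Moore-Penrose generalized inverse of the hypothesis matrix, so a regression
coefficient on a contrast-coded predictor is directly the hypothesis-weighted
condition difference.

Sign conventions, anchored to the substantive reading of the effects:

* ``Gram``        = mismatch - match (positive = mismatch penalty),
* ``Gen``         = masculine - feminine (arbitrary, documented),
* ``AgrType``     = internal - external (negative = external agreement slower),
* ``LexCat``      = verb - adjective (negative = adjectives slower),
* interactions    = the corresponding difference of mismatch penalties,
* three-way rows  = the gender difference of the matching two-way row.

The ``GramxGen`` two-way term is omitted from the default predictor set (the
three-way terms are kept); pass ``include_gram_gen=True`` to add it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ALL_CELLS, CELL_LABELS, DesignCell

#: Relative tolerance for rank and round-trip checks.
RANK_TOL = 1e-10

DEFAULT_EFFECTS = (
    "Gram",
    "Gen",
    "AgrType",
    "LexCat",
    "GramxAgrType",
    "GramxLexCat",
    "GramxGenxAgrType",
    "GramxGenxLexCat",
)


def comparison(positive: list[str], negative: list[str]) -> pd.Series:
    """Weights for ``mean(positive cells) - mean(negative cells)``.

    Cell sets must be disjoint, non-empty subsets of the twelve cell labels.
    """
    pos, neg = set(positive), set(negative)
    if pos & neg:
        raise ValueError(f"cell sets overlap: {sorted(pos & neg)}")
    unknown = (pos | neg) - set(CELL_LABELS)
    if unknown:
        raise ValueError(f"unknown cells: {sorted(unknown)}")
    if not pos or not neg:
        raise ValueError("both cell sets must be non-empty")
    w = pd.Series(0.0, index=list(CELL_LABELS))
    w[list(pos)] = 1.0 / len(pos)
    w[list(neg)] = -1.0 / len(neg)
    return w


def _cells(**conditions) -> list[str]:
    out = []
    for c in ALL_CELLS:
        ok = True
        for attr, vals in conditions.items():
            if getattr(c, attr) not in vals:
                ok = False
                break
        if ok:
            out.append(c.label)
    return out


def _mismatch_penalty(**conditions) -> pd.Series:
    """mismatch - match difference within the given cell subset."""
    return comparison(
        _cells(grammaticality=("mismatch",), **conditions),
        _cells(grammaticality=("match",), **conditions),
    )


def default_hypothesis_matrix(include_gram_gen: bool = False) -> pd.DataFrame:
    """The study's named comparisons as rows over the twelve cells."""
    rows = {
        "Gram": comparison(
            _cells(grammaticality=("mismatch",)), _cells(grammaticality=("match",))
        ),
        "Gen": comparison(
            _cells(gender=("masculine",)), _cells(gender=("feminine",))
        ),
        "AgrType": comparison(
            _cells(agr_type=("internal",)), _cells(agr_type=("external",))
        ),
        "LexCat": comparison(_cells(lex_cat=("verb",)), _cells(lex_cat=("adjective",))),
        "GramxAgrType": _mismatch_penalty(agr_type=("internal",))
        - _mismatch_penalty(agr_type=("external",)),
        "GramxLexCat": _mismatch_penalty(lex_cat=("verb",))
        - _mismatch_penalty(lex_cat=("adjective",)),
        "GramxGenxAgrType": (
            _mismatch_penalty(agr_type=("internal",), gender=("masculine",))
            - _mismatch_penalty(agr_type=("external",), gender=("masculine",))
        )
        - (
            _mismatch_penalty(agr_type=("internal",), gender=("feminine",))
            - _mismatch_penalty(agr_type=("external",), gender=("feminine",))
        ),
        "GramxGenxLexCat": (
            _mismatch_penalty(lex_cat=("verb",), gender=("masculine",))
            - _mismatch_penalty(lex_cat=("adjective",), gender=("masculine",))
        )
        - (
            _mismatch_penalty(lex_cat=("verb",), gender=("feminine",))
            - _mismatch_penalty(lex_cat=("adjective",), gender=("feminine",))
        ),
    }
    if include_gram_gen:
        rows["GramxGen"] = _mismatch_penalty(gender=("masculine",)) - _mismatch_penalty(
            gender=("feminine",)
        )
    return build_hypothesis_matrix(rows)


def build_hypothesis_matrix(rows: dict[str, pd.Series]) -> pd.DataFrame:
    """Assemble and validate a hypothesis matrix from named weight rows.

    Every row must be indexed by the twelve cell labels and sum to zero
    (centered comparison).
    """
    H = pd.DataFrame({name: w.reindex(CELL_LABELS) for name, w in rows.items()}).T
    if H.isna().any().any():
        raise ValueError("weight rows must cover all twelve design cells")
    sums = H.sum(axis=1)
    bad = sums[np.abs(sums) > 1e-12]
    if len(bad):
        raise ValueError(f"non-centered hypothesis rows (weights must sum to 0): {list(bad.index)}")
    return H


def _dependent_rows(M: np.ndarray, names: list[str]) -> list[str]:
    dep, kept = [], []
    for i, name in enumerate(names):
        cand = M[kept + [i]]
        if np.linalg.matrix_rank(cand, tol=RANK_TOL * max(1.0, np.abs(M).max())) == len(kept) + 1:
            kept.append(i)
        else:
            dep.append(name)
    return dep


def hypothesis_to_contrast(H: pd.DataFrame) -> pd.DataFrame:
    """Contrast (coding) matrix: generalized inverse of the hypothesis matrix.

    The hypothesis matrix is augmented with an equal-weight intercept row,
    then pseudo-inverted; the result has one row per design cell and one
    column per predictor (``Intercept`` first).  Raises if the hypothesis
    rows are linearly dependent, listing the offending rows.
    """
    names = list(H.index)
    M = H.to_numpy(dtype=float)
    if np.linalg.matrix_rank(M, tol=RANK_TOL * max(1.0, np.abs(M).max())) < len(names):
        raise ValueError(
            f"hypothesis matrix is rank deficient; dependent rows: {_dependent_rows(M, names)}"
        )
    n_cells = M.shape[1]
    intercept = np.full((1, n_cells), 1.0 / n_cells)
    aug = np.vstack([intercept, M])
    X = np.linalg.pinv(aug)
    return pd.DataFrame(X, index=list(H.columns), columns=["Intercept"] + names)


def default_contrast_matrix(include_gram_gen: bool = False) -> pd.DataFrame:
    return hypothesis_to_contrast(default_hypothesis_matrix(include_gram_gen))


def between_item_predictors(X: pd.DataFrame) -> list[str]:
    """Predictors constant within an item (they never vary across a given
    item's presentations, so they get no by-item random slope).

    An item's agreeing element is fixed, while its grammaticality and
    head-noun gender rotate across lists; a column is between-item iff its
    twelve values depend only on the element.
    """
    out = []
    elements = pd.Series([DesignCell(*lbl.split(":")).element for lbl in X.index])
    for col in X.columns:
        if col == "Intercept":
            continue
        vals = X[col].to_numpy()
        if all(
            np.allclose(vals[elements == e], vals[elements == e][0])
            for e in elements.unique()
        ):
            out.append(col)
    return out


def attach_contrasts(measures: pd.DataFrame, X: pd.DataFrame) -> pd.DataFrame:
    """Join contrast-coded predictor columns onto a measures table.

    Each measure row's (element, grammaticality, gender) cell is looked up in
    the contrast matrix; unknown cells raise.  The returned frame carries the
    predictor columns plus ``attrs['predictors']`` and
    ``attrs['within_item_predictors']``.
    """
    labels = (
        measures["element"].astype(str)
        + ":"
        + measures["grammaticality"].astype(str)
        + ":"
        + measures["gender"].astype(str)
    )
    unknown = set(labels) - set(X.index)
    if unknown:
        raise KeyError(f"design cells not covered by the contrast matrix: {sorted(unknown)}")
    pred_cols = [c for c in X.columns if c != "Intercept"]
    coded = X.loc[labels, pred_cols].reset_index(drop=True)
    coded.index = measures.index
    frame = pd.concat([measures, coded], axis=1)
    frame.attrs["predictors"] = pred_cols
    between = between_item_predictors(X)
    frame.attrs["within_item_predictors"] = [c for c in pred_cols if c not in between]
    return frame


def save_contrasts(path: str | Path, H: pd.DataFrame, X: pd.DataFrame) -> None:
    """Serialize hypothesis and contrast matrices with their labels."""
    payload = {
        "hypothesis": {"rows": list(H.index), "cells": list(H.columns), "weights": H.to_numpy().tolist()},
        "contrast": {"cells": list(X.index), "columns": list(X.columns), "values": X.to_numpy().tolist()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_contrasts(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    payload = json.loads(Path(path).read_text())
    H = pd.DataFrame(
        payload["hypothesis"]["weights"],
        index=payload["hypothesis"]["rows"],
        columns=payload["hypothesis"]["cells"],
    )
    X = pd.DataFrame(
        payload["contrast"]["values"],
        index=payload["contrast"]["cells"],
        columns=payload["contrast"]["columns"],
    )
    return H, X
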