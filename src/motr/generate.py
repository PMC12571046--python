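"""Synthetic study generator with known ground truth.

Three layers, each usable alone:

1. :func:`motr.design.make_design` builds the factorial trial table;
2. :func:`simulate_measures` draws region-level reading measures from the
   analysis model itself (lognormal reading times or Bernoulli regression
   indicators with crossed, correlated participant/item random effects), so
   the generative truth is exactly what the fitted model estimates;
3. :func:`simulate_trajectories` renders target region dwell times as raw
   20 Hz cursor trajectories (saccadic dwell-and-jump or smooth-scan
   profiles) over synthesized monospace word layouts, so the whole
   processing pipeline can be exercised round-trip.

Effect-size defaults mimic a typical agreement-mismatch reading study: a
~40-80 ms mismatch penalty on ~500 ms region totals, small interaction
terms, and a regression-out rate around 0.15 that rises under mismatch.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .contrasts import default_contrast_matrix
from .design import (
    CRITICAL_REGION,
    N_REGIONS,
    StudyPlan,
    make_design,
    participant_rng,
)
from .trajectory import SAMPLE_PERIOD_MS

log = logging.getLogger("motr")

_DEFAULT_RT_BETA = {
    "Gram": 0.10,
    "Gen": 0.02,
    "AgrType": -0.12,
    "LexCat": -0.10,
    "GramxAgrType": 0.05,
    "GramxLexCat": 0.0,
    "GramxGenxAgrType": 0.05,
    "GramxGenxLexCat": 0.0,
}
_DEFAULT_BIN_BETA = {
    "Gram": 0.45,
    "Gen": 0.05,
    "AgrType": -0.15,
    "LexCat": -0.05,
    "GramxAgrType": 0.15,
    "GramxLexCat": 0.0,
    "GramxGenxAgrType": 0.05,
    "GramxGenxLexCat": 0.0,
}


@dataclass
class GenerativeParams:
    """Ground-truth parameters of the crossed random-effects model.

    ``beta0`` is on log-ms (reading times) or log-odds (binary); ``beta``
    maps contrast names to coefficients; ``sd_participant`` / ``sd_item``
    map 'Intercept' and slope names to random-effect standard deviations;
    correlation matrices default to identity.
    """

    beta0: float = 6.2
    beta: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_RT_BETA))
    sd_participant: Mapping[str, float] = field(
        default_factory=lambda: {"Intercept": 0.25, "slopes": 0.05}
    )
    sd_item: Mapping[str, float] = field(
        default_factory=lambda: {"Intercept": 0.12, "slopes": 0.04}
    )
    corr_participant: np.ndarray | None = None
    corr_item: np.ndarray | None = None
    sigma: float = 0.35

    def sd_vector(self, names: list[str], group: str) -> np.ndarray:
        src = self.sd_participant if group == "participant" else self.sd_item
        out = np.array(
            [float(src.get(n, src.get("slopes", 0.0))) for n in names], dtype=float
        )
        if (out < 0).any():
            raise ValueError("random-effect standard deviations must be non-negative")
        return out

    def corr_matrix(self, dim: int, group: str) -> np.ndarray:
        R = self.corr_participant if group == "participant" else self.corr_item
        if R is None:
            return np.eye(dim)
        R = np.asarray(R, dtype=float)
        if R.shape != (dim, dim):
            raise ValueError(f"correlation matrix must be {dim}x{dim}, got {R.shape}")
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("correlation matrix must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("correlation matrix must be positive definite")
        return R


def default_rt_params() -> GenerativeParams:
    return GenerativeParams()


def default_binary_params() -> GenerativeParams:
    """Regression-indicator truth (FPReg-like): base rate ~0.15."""
    return GenerativeParams(
        beta0=-1.7,
        beta=dict(_DEFAULT_BIN_BETA),
        sd_participant={"Intercept": 0.5, "slopes": 0.1},
        sd_item={"Intercept": 0.2, "slopes": 0.1},
        sigma=np.nan,
    )


def _re_chol(params: GenerativeParams, names: list[str], group: str) -> np.ndarray:
    sd = params.sd_vector(names, group)
    R = params.corr_matrix(len(names), group)
    return sd[:, None] * np.linalg.cholesky(R)


def draw_random_effects(
    params: GenerativeParams,
    ids: list,
    names: list[str],
    group: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    L = _re_chol(params, names, group)
    z = rng.standard_normal((len(ids), len(names)))
    return pd.DataFrame(z @ L.T, index=pd.Index(ids), columns=names)


def _design_matrix(design: pd.DataFrame, X: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    labels = (
        design["element"].astype(str)
        + ":"
        + design["grammaticality"].astype(str)
        + ":"
        + design["gender"].astype(str)
    )
    return X.loc[labels].to_numpy(dtype=float), list(X.columns)


def simulate_measures(
    design: pd.DataFrame,
    params: GenerativeParams | None = None,
    contrasts: pd.DataFrame | None = None,
    response: str = "lognormal",
    rng: np.random.Generator | int | None = None,
    measure: str = "total_duration",
) -> tuple[pd.DataFrame, dict]:
    """Draw one measure per target trial from the generative model.

    ``design`` is a trial table (target rows are used); returns a measures
    table (io schema, non-simulated measure columns missing) and a truth
    record holding every parameter and latent draw.
    """
    if params is None:
        params = default_rt_params() if response == "lognormal" else default_binary_params()
    if contrasts is None:
        contrasts = default_contrast_matrix()
    if response not in ("lognormal", "bernoulli"):
        raise ValueError("response must be 'lognormal' or 'bernoulli'")
    rng = np.random.default_rng(rng)
    tgt = design[~design["is_filler"]].reset_index(drop=True)
    Xmat, names = _design_matrix(tgt, contrasts)
    from .contrasts import between_item_predictors

    item_names = ["Intercept"] + [
        n for n in names if n != "Intercept" and n not in between_item_predictors(contrasts)
    ]
    beta = np.array(
        [params.beta0] + [float(params.beta.get(n, 0.0)) for n in names if n != "Intercept"]
    )
    pids = sorted(tgt["participant_id"].unique())
    iids = sorted(tgt["item_id"].unique())
    b = draw_random_effects(params, pids, names, "participant", rng)
    c = draw_random_effects(params, iids, item_names, "item", rng)

    item_cols = [names.index(n) for n in item_names]
    eta = (
        Xmat @ beta
        + np.einsum("np,np->n", Xmat, b.loc[tgt["participant_id"]].to_numpy())
        + np.einsum(
            "np,np->n", Xmat[:, item_cols], c.loc[tgt["item_id"]].to_numpy()
        )
    )
    if response == "lognormal":
        if not np.isfinite(params.sigma) or params.sigma < 0:
            raise ValueError("lognormal response needs a non-negative finite sigma")
        y = np.exp(eta + params.sigma * rng.standard_normal(len(eta)))
    else:
        y = (rng.random(len(eta)) < expit(eta)).astype(float)

    out = tgt[["participant_id", "item_id", "element", "grammaticality", "gender"]].copy()
    out["region"] = CRITICAL_REGION
    for col in ("gaze_duration", "go_past", "total_duration", "fp_reg", "reg_in"):
        out[col] = np.nan
    out[measure] = y
    out["source"] = "motr"
    truth = {
        "response": response,
        "measure": measure,
        "beta0": params.beta0,
        "beta": {n: float(beta[i]) for i, n in enumerate(names)},
        "sigma": float(params.sigma) if response == "lognormal" else None,
        "sd_participant": params.sd_vector(names, "participant").tolist(),
        "sd_item": params.sd_vector(item_names, "item").tolist(),
        "predictors": names,
        "item_predictors": item_names,
        "b": b.to_numpy().tolist(),
        "c": c.to_numpy().tolist(),
        "eta": eta.tolist(),
    }
    return out, truth


# ---------------------------------------------------------------------------
# layouts
# ---------------------------------------------------------------------------

CHAR_W = 14.0       # monospace px per character
SPACE_W = 14.0
LINE_Y = (300.0, 336.0)
X_START = 40.0

# region-2 word lengths by agreeing element: the long-form (modifying)
# adjective is one character longer than the short-form predicative one,
# mirroring the length asymmetry such designs must watch for.
_ELEMENT_LEN = {"modAdj": 8, "predAdj": 7, "verb": 7}
_LETTERS = np.array(list("abcdefghijklmnopqrstuvwxyz"))


def make_layout(
    trial_id: str,
    rng: np.random.Generator,
    element: str | None = None,
    n_regions: int = N_REGIONS,
) -> pd.DataFrame:
    """Single-line monospace layout, one word per region."""
    rows, x = [], X_START
    for r in range(1, n_regions + 1):
        if r == 2 and element in _ELEMENT_LEN:
            n_chars = _ELEMENT_LEN[element]
        else:
            n_chars = int(rng.integers(4, 10))
        text = "".join(rng.choice(_LETTERS, size=n_chars))
        rows.append(
            dict(
                trial=trial_id,
                word_index=r - 1,
                text=text,
                x_min=x,
                x_max=x + n_chars * CHAR_W,
                y_min=LINE_Y[0],
                y_max=LINE_Y[1],
                region=r,
            )
        )
        x += n_chars * CHAR_W + SPACE_W
    return pd.DataFrame(rows)


def make_layouts(design: pd.DataFrame, seed: int) -> pd.DataFrame:
    """One layout per distinct trial_id, deterministic in (seed, trial_id)."""
    meta = design.drop_duplicates("trial_id")[["trial_id", "element"]]
    out = []
    for k, row in enumerate(meta.itertuples()):
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, 7_000_000, zlib.crc32(str(row.trial_id).encode())])
        )
        out.append(make_layout(row.trial_id, rng, element=row.element))
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def _saccadic_trial(
    lay: pd.DataFrame,
    targets: dict[int, float],
    regression: dict | None,
    rng: np.random.Generator,
    period: float,
) -> pd.DataFrame:
    """Dwell near each word's center, jumping between words in one step."""
    words = {int(r.region): r for r in lay.sort_values("word_index").itertuples()}
    plan: list[tuple[int, float]] = []
    for region in sorted(words):
        plan.append((region, targets.get(region, 0.0)))
        if regression and regression["launch_region"] == region:
            plan.append((int(regression["landing_region"]), float(regression["revisit_ms"])))
    xs, ys = [], []
    for region, target in plan:
        n = int(round(target / period))
        if n == 0:
            log.warning("region %d target %.0f ms < one sample period; skipped", region, target)
            continue
        w = words[region]
        cx, cy = (w.x_min + w.x_max) / 2.0, (w.y_min + w.y_max) / 2.0
        half_w = (w.x_max - w.x_min) / 2.0 - 1.0
        xs.append(np.clip(cx + rng.normal(0.0, 1.5, n), cx - half_w, cx + half_w))
        ys.append(np.clip(cy + rng.normal(0.0, 1.5, n), w.y_min + 1.0, w.y_max - 1.0))
    if not xs:
        return pd.DataFrame(columns=["t", "x", "y"])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    return pd.DataFrame({"t": np.arange(len(x)) * period, "x": x, "y": y})


def _smooth_trial(
    lay: pd.DataFrame,
    targets: dict[int, float],
    regression: dict | None,
    rng: np.random.Generator,
    period: float,
) -> pd.DataFrame:
    """Piecewise-constant-velocity scan; never stops moving forward."""
    words = {int(r.region): r for r in lay.sort_values("word_index").itertuples()}
    plan: list[tuple[int, float]] = []
    for region in sorted(words):
        plan.append((region, targets.get(region, 0.0)))
        if regression and regression["launch_region"] == region:
            plan.append((int(regression["landing_region"]), float(regression["revisit_ms"])))
    # segments: (x_from, x_to, duration_ms)
    segs = []
    pos = None
    for region, target in plan:
        w = words[region]
        if target <= 0:
            continue
        if pos is not None:
            segs.append((pos, w.x_min + 1.0, period))  # gap crossing, one period
            pos = w.x_min + 1.0
        else:
            pos = w.x_min + 1.0
        segs.append((pos, w.x_max - 1.0, float(target)))
        pos = w.x_max - 1.0
    if not segs:
        return pd.DataFrame(columns=["t", "x", "y"])
    cy = (lay["y_min"].iloc[0] + lay["y_max"].iloc[0]) / 2.0
    t_bounds = np.cumsum([0.0] + [s[2] for s in segs])
    grid = np.arange(0.0, t_bounds[-1], period)
    x = np.empty_like(grid)
    for i, (x0, x1, dur) in enumerate(segs):
        inside = (grid >= t_bounds[i]) & (grid < t_bounds[i + 1])
        frac = (grid[inside] - t_bounds[i]) / dur
        x[inside] = x0 + frac * (x1 - x0)
    y = cy + rng.normal(0.0, 1.0, len(grid))
    return pd.DataFrame({"t": grid, "x": x, "y": y})


def simulate_trajectories(
    trials: pd.DataFrame,
    layouts: pd.DataFrame,
    region_times: pd.DataFrame,
    regressions: pd.DataFrame | None = None,
    profile: str = "saccadic",
    seed: int = 0,
    period: float = SAMPLE_PERIOD_MS,
) -> pd.DataFrame:
    """Render target region dwell times as raw mouse samples.

    ``region_times`` has columns (participant_id, trial_id, region,
    target_ms); ``regressions`` optionally (participant_id, trial_id,
    launch_region, landing_region, revisit_ms).  Returns a samples table.
    """
    if profile not in ("saccadic", "smooth"):
        raise ValueError("profile must be 'saccadic' or 'smooth'")
    render = _saccadic_trial if profile == "saccadic" else _smooth_trial
    lay_by_trial = dict(tuple(layouts.groupby("trial", sort=False)))
    times = region_times.groupby(["participant_id", "trial_id"], sort=False)
    regs = (
        {k: v.iloc[0].to_dict() for k, v in regressions.groupby(["participant_id", "trial_id"])}
        if regressions is not None and len(regressions)
        else {}
    )
    pid_index = {p: i for i, p in enumerate(sorted(trials["participant_id"].unique()))}
    out = []
    for (pid, tid), g in times:
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [int(seed), 13_000_000, pid_index[pid], zlib.crc32(str(tid).encode())]
            )
        )
        targets = dict(zip(g["region"].astype(int), g["target_ms"].astype(float)))
        df = render(lay_by_trial[tid], targets, regs.get((pid, tid)), rng, period)
        df.insert(0, "participant", pid)
        df.insert(1, "trial", tid)
        out.append(df)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=["participant", "trial", "t", "x", "y"]
    )


# ---------------------------------------------------------------------------
# full-study simulation
# ---------------------------------------------------------------------------

#: Baseline log-ms dwell for non-critical regions 1, 2, 4, 5.
REGION_INTERCEPTS = {1: 6.0, 2: 6.1, 4: 6.05, 5: 5.95}

#: Post-critical revisit dwell (log-ms) when a regression is inserted.
REVISIT_MU, REVISIT_SD = 5.9, 0.25


def simulate_study(
    plan: StudyPlan | None = None,
    rt_params: GenerativeParams | None = None,
    fpreg_params: GenerativeParams | None = None,
    seed: int = 0,
    profile: str = "saccadic",
    accuracy: float = 0.95,
    regression_landing: int = 2,
) -> dict:
    """Simulate a complete study: design, layouts, trajectories, questions.

    The critical region's dwell follows the full lognormal model; other
    regions get baseline dwell with the same participant/item intercepts.
    A first-pass regression out of the critical region is inserted with the
    probability given by the Bernoulli model, landing on
    ``regression_landing`` (region 2 by default, under the head noun's
    agreement controller).  Comprehension answers are Bernoulli(`accuracy`).

    Returns dict with keys: design, layouts, samples, trials, comprehension,
    region_times, regressions, truth.
    """
    plan = plan or StudyPlan()
    rt_params = rt_params or default_rt_params()
    fpreg_params = fpreg_params or default_binary_params()
    X = default_contrast_matrix()
    design = make_design(plan, seed)
    layouts = make_layouts(design, seed)

    tgt = design[~design["is_filler"]].reset_index(drop=True)
    Xmat, names = _design_matrix(tgt, X)
    from .contrasts import between_item_predictors

    item_names = ["Intercept"] + [
        n for n in names if n != "Intercept" and n not in between_item_predictors(X)
    ]
    item_cols = [names.index(n) for n in item_names]

    irng = np.random.default_rng(np.random.SeedSequence([seed, 5_000_000]))
    all_items = sorted(design["item_id"].unique())
    c_rt = draw_random_effects(rt_params, all_items, item_names, "item", irng)
    c_bin = draw_random_effects(fpreg_params, all_items, item_names, "item", irng)

    pids = sorted(design["participant_id"].unique())
    beta_rt = np.array(
        [rt_params.beta0]
        + [float(rt_params.beta.get(n, 0.0)) for n in names if n != "Intercept"]
    )
    beta_bin = np.array(
        [fpreg_params.beta0]
        + [float(fpreg_params.beta.get(n, 0.0)) for n in names if n != "Intercept"]
    )

    region_rows, reg_rows, comp_rows = [], [], []
    b_rt_all, b_bin_all = {}, {}
    tgt_by_pid = dict(tuple(tgt.groupby("participant_id", sort=False)))
    xrow_by_tid = {}
    for i, tid in enumerate(tgt["trial_id"]):
        xrow_by_tid[tid] = Xmat[i]
    for p_index, pid in enumerate(pids):
        prng = participant_rng(seed, p_index)
        b_rt = draw_random_effects(rt_params, [pid], names, "participant", prng).iloc[0]
        b_bin = draw_random_effects(fpreg_params, [pid], names, "participant", prng).iloc[0]
        b_rt_all[pid], b_bin_all[pid] = b_rt.tolist(), b_bin.tolist()
        for trial in design[design["participant_id"] == pid].itertuples():
            tid = trial.trial_id
            if trial.is_filler:
                x = np.zeros(len(names))
                x[0] = 1.0
                c_rt_j = np.zeros(len(item_names))
                c_rt_j[0] = c_rt.loc[trial.item_id, "Intercept"]
                c_bin_j = np.zeros(len(item_names))
            else:
                x = xrow_by_tid[tid]
                c_rt_j = c_rt.loc[trial.item_id].to_numpy()
                c_bin_j = c_bin.loc[trial.item_id].to_numpy()
            eta_rt = x @ beta_rt + x @ b_rt.to_numpy() + x[item_cols] @ c_rt_j
            base = b_rt["Intercept"] + c_rt_j[0]
            for region in range(1, N_REGIONS + 1):
                if region == CRITICAL_REGION:
                    mu = eta_rt
                else:
                    mu = REGION_INTERCEPTS[region] + base
                target = float(
                    np.exp(mu + rt_params.sigma * prng.standard_normal())
                )
                region_rows.append((pid, tid, trial.item_id, region, target))
            eta_bin = x @ beta_bin + x @ b_bin.to_numpy() + x[item_cols] @ c_bin_j
            if not trial.is_filler and prng.random() < expit(eta_bin):
                revisit = float(np.exp(REVISIT_MU + REVISIT_SD * prng.standard_normal()))
                reg_rows.append((pid, tid, CRITICAL_REGION, regression_landing, revisit))
            if trial.has_question:
                comp_rows.append((pid, trial.item_id, int(prng.random() < accuracy)))

    region_times = pd.DataFrame(
        region_rows, columns=["participant_id", "trial_id", "item_id", "region", "target_ms"]
    )
    regressions = pd.DataFrame(
        reg_rows,
        columns=["participant_id", "trial_id", "launch_region", "landing_region", "revisit_ms"],
    )
    comprehension = pd.DataFrame(
        comp_rows, columns=["participant_id", "item_id", "correct"]
    )
    samples = simulate_trajectories(
        design, layouts, region_times, regressions, profile=profile, seed=seed
    )
    truth = {
        "seed": seed,
        "profile": profile,
        "rt": {
            "beta": dict(zip(names, beta_rt.tolist())),
            "sigma": rt_params.sigma,
            "b": b_rt_all,
            "c": c_rt.to_numpy().tolist(),
        },
        "fpreg": {
            "beta": dict(zip(names, beta_bin.tolist())),
            "b": b_bin_all,
            "c": c_bin.to_numpy().tolist(),
        },
        "region_intercepts": REGION_INTERCEPTS,
    }
    trials = design.rename(columns={"participant": "participant_id"})
    return dict(
        design=design,
        layouts=layouts,
        samples=samples,
        trials=trials,
        comprehension=comprehension,
        region_times=region_times,
        regressions=regressions,
        truth=truth,
    )
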