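"""shadowVIMP variable selection.

The procedure: in each of ``niter`` iterations a fresh row-wise permuted
shadow block is appended to the predictor matrix, a random forest is fitted
on the n x 2p' extended matrix, and the scaled permutation importance
(z-score) of every original and shadow column is recorded.  Two permutation
p-values are available for variable j:

* per-variable: the median importance of x_j across iterations is compared
  with the empirical distribution of its own shadow's importances, with an
  appended +inf element so p-values are never zero:
  ``p_j = (#{shadow_t >= median(orig_j)} + 1) / (niter + 1)``.
* pooled: every shadow column is standardized by its own across-iteration
  mean and sd, the original column is standardized by *its shadow's* mean
  and sd (so shadow-specific bias, e.g. from correlation or cardinality,
  raises the bar for its original), and the standardized median is compared
  against the pool of all p'*niter standardized shadow importances.  The
  pooled support refines the attainable p-values from 1/(niter+1) to
  1/(p'*niter+1), which is what makes multiple-testing adjustment feasible
  at realistic iteration counts.

Ties count against the variable (>=): a variable whose importance merely
equals shadow importances gains no evidence.

Pre-selection runs the procedure in stages with decreasing alpha thresholds
(default 30 iters at 0.30, 120 at 0.15, 1000 at 0.05), dropping variables
-- and their shadows -- between stages; the pooled criterion is used during
pre-selection stages.  Final-stage p-values are adjusted with
Benjamini-Hochberg (FDR), Holm (FWER) and Bonferroni over the full family
of p original hypotheses, variables dropped during pre-selection entering
as p = 1: screening shrinks the design matrix, not the multiplicity burden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from statsmodels.stats.multitest import multipletests

from .forest import PermutationImportanceForest, _order_codes

__all__ = [
    "StagePlan",
    "VimpTrace",
    "SelectionResult",
    "ShadowVimpSelector",
    "run_iterations",
    "run_shadowvimp",
    "per_variable_pvalue",
    "pooled_pvalue",
    "pooled_pvalues",
    "adjust_pvalues",
    "min_iterations",
    "DegenerateShadowError",
]

logger = logging.getLogger("shadowvimp")

DEFAULT_STAGES = ((30, 0.30), (120, 0.15), (1000, 0.05))

_ADJUST_METHODS = {
    "bh": "fdr_bh",
    "fdr": "fdr_bh",
    "fdr_bh": "fdr_bh",
    "holm": "holm",
    "fwer": "holm",
    "bonferroni": "bonferroni",
}


class DegenerateShadowError(ValueError):
    """A shadow column has zero importance spread and cannot be standardized."""


# --------------------------------------------------------------------------
# plan / result containers


@dataclass(frozen=True)
class StagePlan:
    """Ordered pre-selection stages plus the final testing stage.

    ``stages`` is a list of (niter, alpha) pairs with strictly decreasing
    alpha; the last entry is the final stage.  ``criterion`` selects the
    final-stage p-value ("pooled" or "per-variable"); pre-selection stages
    always use the pooled criterion.  ``final_alpha`` defaults to the last
    stage's alpha.
    """

    stages: tuple = DEFAULT_STAGES
    criterion: str = "pooled"
    final_alpha: float | None = None

    def __post_init__(self) -> None:
        if len(self.stages) < 1:
            raise ValueError("need at least one stage")
        alphas = [a for _, a in self.stages]
        for niter, a in self.stages:
            if niter < 1 or not 0 < a <= 1:
                raise ValueError(f"invalid stage ({niter}, {a})")
        if any(a2 >= a1 for a1, a2 in zip(alphas, alphas[1:])):
            raise ValueError("stage alpha thresholds must be strictly decreasing")
        if self.criterion not in ("pooled", "per-variable"):
            raise ValueError(f"unknown criterion {self.criterion!r}")

    @property
    def alpha(self) -> float:
        return self.final_alpha if self.final_alpha is not None else self.stages[-1][1]


@dataclass
class VimpTrace:
    """Scaled importances over iterations: (niter, p') original and shadow halves."""

    original: np.ndarray
    shadow: np.ndarray
    columns: np.ndarray
    iteration_seeds: np.ndarray

    def __post_init__(self) -> None:
        if self.original.shape != self.shadow.shape:
            raise ValueError("original and shadow halves must have the same shape")


@dataclass
class SelectionResult:
    """Final p-values, adjustments and selection flags for every input column.

    Columns dropped during pre-selection carry NaN p-values (the "not
    assessed at final stage" sentinel); ``last_stage`` records the last
    stage at which each column was assessed (1-based; surviving to the
    final stage means ``last_stage == n_stages``).
    """

    columns: np.ndarray
    p_raw: np.ndarray
    median_vimp: np.ndarray
    p_adjusted: dict
    selected: dict
    last_stage: np.ndarray
    n_stages: int
    final_alpha: float
    criterion: str
    traces: list = field(default_factory=list)

    def selection_category(self) -> np.ndarray:
        """Strictest threshold each variable passes (for annotated VIMP plots)."""
        cat = np.full(self.columns.shape, "not selected", dtype=object)
        cat[self.selected["unadjusted"]] = "unadjusted"
        cat[self.selected["FDR"]] = "FDR"
        cat[self.selected["FWER"]] = "FWER"
        dropped = self.last_stage < self.n_stages
        cat[dropped] = "dropped in pre-selection"
        return cat

    def to_frame(self) -> pd.DataFrame:
        """Per-variable results table (one row per input column)."""
        return pd.DataFrame(
            {
                "variable": self.columns,
                "median_vimp": self.median_vimp,
                "p_raw": self.p_raw,
                "p_BH": self.p_adjusted["BH"],
                "p_Holm": self.p_adjusted["Holm"],
                "p_Bonferroni": self.p_adjusted["Bonferroni"],
                "selected_unadj": self.selected["unadjusted"],
                "selected_FDR": self.selected["FDR"],
                "selected_FWER": self.selected["FWER"],
                "last_stage": self.last_stage,
            }
        )

    def vimp_long(self) -> pd.DataFrame:
        """Long-format per-iteration importances from the final-stage trace.

        One row per (variable, iteration) for originals and shadows of the
        variables assessed at the final stage -- sufficient to redraw
        annotated importance boxplots.
        """
        trace = self.traces[-1]
        niter, p = trace.original.shape
        category = dict(zip(self.columns, self.selection_category()))
        frames = []
        for is_shadow, half in ((False, trace.original), (True, trace.shadow)):
            frames.append(
                pd.DataFrame(
                    {
                        "variable": np.repeat(trace.columns, niter),
                        "iteration": np.tile(np.arange(1, niter + 1), p),
                        "vimp": half.T.ravel(),
                        "is_shadow": is_shadow,
                        "selection_category": [
                            category[c] for c in np.repeat(trace.columns, niter)
                        ],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# p-values


def per_variable_pvalue(orig, shad) -> float:
    """Permutation p-value of one variable against its own shadow (+inf element)."""
    orig = np.asarray(orig, dtype=float)
    shad = np.asarray(shad, dtype=float)
    if orig.size < 1 or shad.size != orig.size:
        raise ValueError("orig and shad must be equal-length, non-empty vectors")
    m = np.median(orig)
    return (np.count_nonzero(shad >= m) + 1) / (shad.size + 1)


def pooled_pvalues(trace: VimpTrace, degenerate: str = "error") -> np.ndarray:
    """Pooled permutation p-values for all columns of a trace.

    Each shadow column is standardized by its own across-iteration mean and
    sample sd; each original's median is standardized by its *shadow's*
    mean and sd; the reference pool is all p'*niter standardized shadow
    entries plus an +inf element.

    A shadow column with zero importance spread (a column no tree ever
    split on, possible only at small tree/iteration counts in very wide
    matrices) cannot be standardized: ``degenerate="error"`` raises, while
    ``degenerate="unit"`` leaves such columns on the raw z-score scale
    (mean 0, sd 1), which compares the already scale-free z-scores without
    the shadow-specific adjustment.
    """
    shad = trace.shadow
    mean = shad.mean(axis=0)
    sd = shad.std(axis=0, ddof=1)
    bad = sd == 0
    if bad.any():
        if degenerate != "unit":
            raise DegenerateShadowError(
                "shadow columns with zero importance spread cannot be standardized: "
                f"{list(np.asarray(trace.columns)[bad])}"
            )
        mean = np.where(bad, 0.0, mean)
        sd = np.where(bad, 1.0, sd)
    pool = ((shad - mean) / sd).ravel()
    pool.sort()
    stat = (np.median(trace.original, axis=0) - mean) / sd
    count = pool.size - np.searchsorted(pool, stat, side="left")
    return (count + 1) / (pool.size + 1)


def pooled_pvalue(trace: VimpTrace, j: int) -> float:
    """Pooled permutation p-value of column j (see :func:`pooled_pvalues`)."""
    return float(pooled_pvalues(trace)[j])


def adjust_pvalues(p, method: str) -> np.ndarray:
    """Adjusted p-values under BH (step-up), Holm (step-down) or Bonferroni."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    key = method.lower()
    if key not in _ADJUST_METHODS:
        raise ValueError(f"unknown adjustment {method!r}")
    return multipletests(p, method=_ADJUST_METHODS[key])[1]


def min_iterations(alpha: float, m: int) -> int:
    """Smallest niter whose p-value granularity beats the Bonferroni bar.

    Returns the smallest integer with ``1/(niter+1) < alpha/m`` (strict),
    i.e. the iteration count at which the per-variable criterion could in
    principle reach significance after correcting m tests at level alpha.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    frac = Fraction(str(alpha))
    if not 0 < frac <= 1:
        raise ValueError("alpha must be in (0, 1]")
    # need niter + 1 > m/alpha, so niter = floor(m * den / num)
    return (m * frac.denominator) // frac.numerator


# --------------------------------------------------------------------------
# iteration engine


def _resolve_task(y) -> str:
    y = pd.Series(y)
    if not pd.api.types.is_numeric_dtype(y):
        return "classification"
    vals = np.unique(y.to_numpy())
    if vals.size <= 2 and np.isin(vals, (0, 1)).all():
        return "classification"
    return "regression"


class _PreparedData:
    """Numeric view of (X, y): categoricals integer-coded, orderings cached."""

    def __init__(self, X, y, task: str, categorical=None):
        if isinstance(X, pd.DataFrame):
            names = np.asarray(X.columns, dtype=object)
            if len(set(names)) != len(names):
                raise ValueError("duplicate column names in X")
            cat_set = set(categorical or [])
            cat_set |= {c for c in names if not pd.api.types.is_numeric_dtype(X[c])}
            frame = X
        else:
            Xarr = np.asarray(X)
            if Xarr.ndim != 2:
                raise ValueError("X must be 2-dimensional")
            names = np.asarray([f"x{i + 1}" for i in range(Xarr.shape[1])], dtype=object)
            cat_set = {names[i] for i in (categorical or [])}
            frame = pd.DataFrame(Xarr, columns=names)

        y = np.asarray(pd.Series(y).to_numpy())
        if frame.shape[0] != y.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        self.task = task
        if task == "classification":
            classes = np.unique(y)
            if classes.size > 2:
                raise ValueError("only binary classification is supported")
            self.y = np.searchsorted(classes, y).astype(np.float64)
            self.classes = classes
            self.signal = self.y  # positive-class indicator
        else:
            self.y = np.asarray(y, dtype=np.float64)
            self.signal = self.y
        if np.isnan(self.y).any():
            raise ValueError("missing values in y")

        n, p = frame.shape
        raw = np.empty((n, p), dtype=np.float64)
        cat_mask = np.zeros(p, dtype=bool)
        n_cats = np.zeros(p, dtype=int)
        self.categories: list = [None] * p
        for i, c in enumerate(names):
            col = frame[c]
            if c in cat_set:
                cats = np.asarray(sorted(pd.unique(col.dropna())))
                codes = np.searchsorted(cats, col.to_numpy())
                raw[:, i] = codes
                cat_mask[i] = True
                n_cats[i] = cats.size
                self.categories[i] = cats
            else:
                raw[:, i] = col.to_numpy(dtype=np.float64)
        if np.isnan(raw).any():
            bad = names[np.isnan(raw).any(axis=0)]
            raise ValueError(f"missing values in columns {list(bad)}")
        self.names = names
        self.raw = raw
        self.cat_mask = cat_mask
        self.n_cats = n_cats
        self.n, self.p = n, p
        # original columns' target-ordered encoding is iteration-invariant
        self.encoded = self._encode(raw, cat_mask, n_cats)

    def _encode(self, raw, cat_mask, n_cats):
        enc = raw.copy()
        for i in np.flatnonzero(cat_mask):
            codes = raw[:, i].astype(np.intp)
            ranks = _order_codes(codes, self.signal, n_cats[i])
            enc[:, i] = ranks[codes]
        return enc

    def subset(self, idx: np.ndarray) -> "_PreparedData":
        sub = object.__new__(_PreparedData)
        sub.task = self.task
        sub.y = self.y
        sub.signal = self.signal
        if self.task == "classification":
            sub.classes = self.classes
        sub.names = self.names[idx]
        sub.raw = np.ascontiguousarray(self.raw[:, idx])
        sub.cat_mask = self.cat_mask[idx]
        sub.n_cats = self.n_cats[idx]
        sub.categories = [self.categories[i] for i in idx]
        sub.n, sub.p = sub.raw.shape
        sub.encoded = np.ascontiguousarray(self.encoded[:, idx])
        return sub


def _iteration_zscores(prep: _PreparedData, seed_pair, n_trees, mtry, min_samples_split):
    """One shadowVIMP iteration: extend, fit, return 2p'-vector of z-scores."""
    rng = np.random.default_rng(int(seed_pair[0]))
    n, p = prep.n, prep.p
    perm = rng.permutation(n)
    Xe = np.empty((n, 2 * p), dtype=np.float32)
    Xe[:, :p] = prep.encoded
    Xe[:, p:] = prep.encoded[perm]  # placeholder; correct for continuous columns
    for i in np.flatnonzero(prep.cat_mask):
        # shadow categoricals are re-ordered against the outcome independently
        codes = prep.raw[perm, i].astype(np.intp)
        ranks = _order_codes(codes, prep.signal, prep.n_cats[i])
        Xe[:, p + i] = ranks[codes]
    forest = PermutationImportanceForest(
        n_trees=n_trees,
        mtry=mtry,
        task=prep.task,
        min_samples_split=min_samples_split,
        random_state=np.random.RandomState(int(seed_pair[1])),
    )
    y_fit = prep.y if prep.task == "regression" else prep.classes[prep.y.astype(int)]
    forest.fit(Xe, y_fit)
    return forest.zscores(random_state=rng)


def _iteration_seed_pairs(seed, niter: int) -> np.ndarray:
    """Counter-based per-iteration seeds: (niter, 2) ints from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(2 * niter, dtype=np.uint32)
    return state.reshape(niter, 2).astype(np.int64)


def _run_prepared(prep, niter, n_trees, mtry, min_samples_split, seed, n_jobs=1):
    seeds = _iteration_seed_pairs(seed, niter)
    if n_jobs == 1:
        rows = [
            _iteration_zscores(prep, seeds[t], n_trees, mtry, min_samples_split)
            for t in range(niter)
        ]
    else:
        rows = Parallel(n_jobs=n_jobs)(
            delayed(_iteration_zscores)(prep, seeds[t], n_trees, mtry, min_samples_split)
            for t in range(niter)
        )
    Z = np.vstack(rows)
    return VimpTrace(
        original=Z[:, : prep.p],
        shadow=Z[:, prep.p :],
        columns=prep.names,
        iteration_seeds=seeds[:, 0].copy(),
    )


def run_iterations(
    X,
    y,
    niter: int,
    *,
    task: str = "auto",
    n_trees: int = 10_000,
    mtry: int | str = "sqrt",
    min_samples_split: int | None = None,
    categorical=None,
    seed=None,
    n_jobs: int = 1,
) -> VimpTrace:
    """Record scaled importances of originals and r-shadows over ``niter`` iterations.

    Every iteration draws a fresh row permutation, extends X by the shadow
    block, fits a forest on the 2p' columns (mtry evaluated on 2p' when
    "sqrt") and stores the z-scores.  Iterations are independent given
    their counter-derived seeds, so ``n_jobs`` changes wall time, never the
    trace.
    """
    if task == "auto":
        task = _resolve_task(y)
    prep = _PreparedData(X, y, task, categorical)
    return _run_prepared(prep, niter, n_trees, mtry, min_samples_split, seed, n_jobs)


# --------------------------------------------------------------------------
# the staged procedure


def run_shadowvimp(
    X,
    y,
    plan: StagePlan | Sequence | None = None,
    *,
    criterion: str | None = None,
    task: str = "auto",
    n_trees: int = 10_000,
    mtry: int | str = "sqrt",
    min_samples_split: int | None = None,
    categorical=None,
    seed=None,
    n_jobs: int = 1,
) -> SelectionResult:
    """Run staged shadowVIMP selection and return per-variable results.

    Pre-selection stages drop variables (and their shadows) whose pooled
    p-value exceeds the stage threshold; the final stage computes the
    configured criterion's p-values, their BH/Holm/Bonferroni adjustments
    over the surviving hypotheses, and selection flags at ``final_alpha``.
    """
    if plan is None:
        plan = StagePlan()
    elif not isinstance(plan, StagePlan):
        plan = StagePlan(stages=tuple(tuple(s) for s in plan))
    if criterion is not None and criterion != plan.criterion:
        plan = StagePlan(plan.stages, criterion, plan.final_alpha)
    if task == "auto":
        task = _resolve_task(y)

    prep = _PreparedData(X, y, task, categorical)
    p = prep.p
    n_stages = len(plan.stages)
    stage_seeds = np.random.SeedSequence(seed).generate_state(n_stages, dtype=np.uint32)

    active = np.arange(p)
    last_stage = np.zeros(p, dtype=int)
    p_raw = np.full(p, np.nan)
    median_vimp = np.full(p, np.nan)
    traces: list[VimpTrace] = []

    for s, (niter_s, alpha_s) in enumerate(plan.stages, start=1):
        final = s == n_stages
        if active.size == 0:
            logger.info("stage %d skipped: no surviving variables", s)
            break
        sub = prep.subset(active)
        trace = _run_prepared(
            sub, niter_s, n_trees, mtry, min_samples_split, int(stage_seeds[s - 1]), n_jobs
        )
        traces.append(trace)
        use_pooled = plan.criterion == "pooled" or not final
        if use_pooled:
            n_degen = int((trace.shadow.std(axis=0, ddof=1) == 0).sum())
            if n_degen:
                logger.warning(
                    "stage %d: %d shadow column(s) were never split on; "
                    "left unstandardized in the pool", s, n_degen,
                )
            pv = pooled_pvalues(trace, degenerate="unit")
        else:
            pv = np.array(
                [
                    per_variable_pvalue(trace.original[:, j], trace.shadow[:, j])
                    for j in range(sub.p)
                ]
            )
        last_stage[active] = s
        if final:
            p_raw[active] = pv
            median_vimp[active] = np.median(trace.original, axis=0)
        else:
            keep = pv <= alpha_s
            logger.info(
                "stage %d (niter=%d, alpha=%.3g): %d -> %d variables",
                s, niter_s, alpha_s, active.size, int(keep.sum()),
            )
            active = active[keep]

    final_mask = last_stage == n_stages
    p_adjusted = {
        name: np.full(p, np.nan) for name in ("BH", "Holm", "Bonferroni")
    }
    if final_mask.any():
        # the family is all p original hypotheses: variables dropped during
        # pre-selection enter the adjustment as p = 1 (tested, not rejected),
        # so screening does not silently shrink the multiplicity burden
        family = np.where(np.isnan(p_raw), 1.0, p_raw)
        for name in p_adjusted:
            p_adjusted[name][final_mask] = adjust_pvalues(family, name)[final_mask]
    fa = plan.alpha
    with np.errstate(invalid="ignore"):
        selected = {
            "unadjusted": np.where(np.isnan(p_raw), False, p_raw <= fa),
            "FDR": np.where(np.isnan(p_adjusted["BH"]), False, p_adjusted["BH"] <= fa),
            "FWER": np.where(np.isnan(p_adjusted["Holm"]), False, p_adjusted["Holm"] <= fa),
            "Bonferroni": np.where(
                np.isnan(p_adjusted["Bonferroni"]), False, p_adjusted["Bonferroni"] <= fa
            ),
        }
    selected = {k: v.astype(bool) for k, v in selected.items()}
    logger.info(
        "final stage: %d assessed, %d selected unadjusted / %d FDR / %d FWER at alpha=%.3g",
        int(final_mask.sum()),
        int(selected["unadjusted"].sum()),
        int(selected["FDR"].sum()),
        int(selected["FWER"].sum()),
        fa,
    )
    return SelectionResult(
        columns=prep.names,
        p_raw=p_raw,
        median_vimp=median_vimp,
        p_adjusted=p_adjusted,
        selected=selected,
        last_stage=last_stage,
        n_stages=n_stages,
        final_alpha=fa,
        criterion=plan.criterion,
        traces=traces,
    )


class ShadowVimpSelector(SelectorMixin, BaseEstimator):
    """scikit-learn feature selector running the shadowVIMP procedure.

    Parameters mirror :func:`run_shadowvimp`; ``adjustment`` picks which
    selection ("unadjusted", "fdr"/"bh", "fwer"/"holm", "bonferroni") the
    transformer's support mask uses at level ``alpha``.

    Attributes (after fit)
    ----------------------
    result_ : SelectionResult
    pvalues_ : raw final-stage p-values (NaN for variables dropped earlier)
    pvalues_adjusted_ : dict of BH/Holm/Bonferroni adjusted p-values
    stage_history_ : last stage at which each variable was assessed
    support_ : boolean selection mask under (adjustment, alpha)
    """

    def __init__(
        self,
        stages=DEFAULT_STAGES,
        criterion: str = "pooled",
        alpha: float = 0.05,
        adjustment: str = "fwer",
        n_trees: int = 10_000,
        mtry: int | str = "sqrt",
        task: str = "auto",
        min_samples_split: int | None = None,
        categorical=None,
        n_jobs: int = 1,
        random_state=None,
    ):
        self.stages = stages
        self.criterion = criterion
        self.alpha = alpha
        self.adjustment = adjustment
        self.n_trees = n_trees
        self.mtry = mtry
        self.task = task
        self.min_samples_split = min_samples_split
        self.categorical = categorical
        self.n_jobs = n_jobs
        self.random_state = random_state

    _ADJ_KEY = {
        "unadjusted": "unadjusted",
        "none": "unadjusted",
        "fdr": "FDR",
        "bh": "FDR",
        "fdr_bh": "FDR",
        "fwer": "FWER",
        "holm": "FWER",
        "bonferroni": "Bonferroni",
    }

    def fit(self, X, y):
        key = str(self.adjustment).lower()
        if key not in self._ADJ_KEY:
            raise ValueError(f"unknown adjustment {self.adjustment!r}")
        plan = StagePlan(
            stages=tuple(tuple(s) for s in self.stages),
            criterion=self.criterion,
            final_alpha=self.alpha,
        )
        self.result_ = run_shadowvimp(
            X,
            y,
            plan,
            task=self.task,
            n_trees=self.n_trees,
            mtry=self.mtry,
            min_samples_split=self.min_samples_split,
            categorical=self.categorical,
            seed=self.random_state,
            n_jobs=self.n_jobs,
        )
        self.pvalues_ = self.result_.p_raw
        self.pvalues_adjusted_ = self.result_.p_adjusted
        self.stage_history_ = self.result_.last_stage
        self.support_ = self.result_.selected[self._ADJ_KEY[key]]
        self.n_features_in_ = self.result_.columns.size
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def _get_support_mask(self):
        return self.support_

    def transform(self, X):
        mask = self.get_support()
        if isinstance(X, pd.DataFrame):
            return X.loc[:, mask]
        return np.asarray(X)[:, mask]
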