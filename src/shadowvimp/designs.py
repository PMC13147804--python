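"""Benchmark data generators with ground-truth informativeness labels.

Four designs from the random-forest variable-importance literature:

* ``degenhardt`` -- high-dimensional regression: six latent U(0,1)
  variables, each represented by a block of g correlated predictors (g in
  {10, 50}); the outcome depends non-linearly on the first three latents;
  independent U(0,1) noise columns pad the matrix to p = 5000.
* ``friedman`` -- the classic low-dimensional regression benchmark:
  y = 10 sin(pi x1 x2) + 20 (x3 - 0.5)^2 + 10 x4 + 5 x5 + noise with five
  additional uninformative U(0,1) columns.
* ``strobl`` -- the categorical-cardinality bias design: one N(0,1)
  predictor and four uniform multinomials with 2/4/10/20 levels; a binary
  outcome depends only on the binary x2 (P(y=1) = 0.3 or 0.7).
* ``nicodemus-null`` -- the correlated null: twelve standard normals, the
  first four pairwise correlated at 0.9; the outcome is generated from a
  linear model and then permuted, so every variable is uninformative.

Normal noise terms quoted as ``N(0, c)`` are interpreted with ``c`` as the
*variance* (sd = sqrt(c)); flip ``NOISE_PARAM_IS_VARIANCE`` to read them as
standard deviations.  The choice affects no truth labels or column counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DesignDataset",
    "gen_degenhardt",
    "gen_friedman",
    "gen_strobl",
    "gen_nicodemus_null",
    "make_design",
    "friedman_mean",
    "DESIGNS",
]

NOISE_PARAM_IS_VARIANCE = True


def _noise_sd(param: float) -> float:
    return float(np.sqrt(param)) if NOISE_PARAM_IS_VARIANCE else float(param)


@dataclass
class DesignDataset:
    """Generated predictors, outcome and per-column informativeness truth."""

    X: pd.DataFrame
    y: np.ndarray
    truth: np.ndarray
    design_name: str
    task: str
    params: dict = field(default_factory=dict)
    seed: int | None = None
    categorical: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.truth.shape[0] != self.X.shape[1]:
            raise ValueError("truth must have one entry per predictor column")


def friedman_mean(X) -> np.ndarray:
    """Noiseless Friedman regression surface evaluated on rows of X."""
    X = np.asarray(X, dtype=float)
    return (
        10 * np.sin(np.pi * X[:, 0] * X[:, 1])
        + 20 * (X[:, 2] - 0.5) ** 2
        + 10 * X[:, 3]
        + 5 * X[:, 4]
    )


def gen_friedman(n: int = 100, seed=None) -> DesignDataset:
    """Friedman benchmark: 5 informative + 5 uninformative U(0,1) predictors."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, size=(n, 10))
    y = friedman_mean(X) + rng.normal(0.0, _noise_sd(0.2), size=n)
    frame = pd.DataFrame(X, columns=[f"x{i + 1}" for i in range(10)])
    truth = np.array([True] * 5 + [False] * 5)
    return DesignDataset(frame, y, truth, "friedman", "regression", {"n": n}, seed)


def _degenhardt_outcome(v: np.ndarray, rng, n: int) -> np.ndarray:
    return (
        0.25 * np.exp(4.0 * v[:, 0])
        + 4.0 / (1.0 + np.exp(-20.0 * (v[:, 1] - 0.5)))
        + 3.0 * v[:, 2]
        + rng.normal(0.0, _noise_sd(0.2), size=n)
    )


def gen_degenhardt(n: int = 100, g: int = 10, seed=None) -> DesignDataset:
    """Block-correlated high-dimensional design (p = 5000).

    Six latent variables v_w ~ U(0,1) each spawn a block of g predictors
    x_{w,j} = v_w + (0.01 + 0.5 (j-1)/(g-1)) * nu with nu drawn per entry,
    so within-block correlation to the latent decreases with j.  The
    outcome depends on v_1..v_3 only; blocks 4-6 are correlated decoys and
    the remaining 5000 - 6g columns are independent U(0,1) noise.
    """
    if g not in (10, 50):
        raise ValueError("group size g must be 10 or 50")
    rng = np.random.default_rng(seed)
    p_total = 5000
    v = rng.uniform(0.0, 1.0, size=(n, 6))
    y = _degenhardt_outcome(v, rng, n)
    scale = 0.01 + 0.5 * np.arange(g) / (g - 1)
    blocks = v[:, :, None] + scale[None, None, :] * rng.normal(
        0.0, _noise_sd(0.3), size=(n, 6, g)
    )
    noise = rng.uniform(0.0, 1.0, size=(n, p_total - 6 * g))
    X = np.concatenate([blocks.reshape(n, 6 * g), noise], axis=1)
    names = [f"g{w + 1}_x{j + 1}" for w in range(6) for j in range(g)]
    names += [f"noise{i + 1}" for i in range(p_total - 6 * g)]
    truth = np.zeros(p_total, dtype=bool)
    truth[: 3 * g] = True
    return DesignDataset(
        pd.DataFrame(X, columns=names), y, truth, "degenhardt", "regression",
        {"n": n, "g": g}, seed,
    )


def gen_strobl(n: int = 100, seed=None) -> DesignDataset:
    """Mixed-cardinality classification design; only the binary x2 is informative."""
    rng = np.random.default_rng(seed)
    cards = (2, 4, 10, 20)
    x1 = rng.normal(0.0, 1.0, size=n)
    cats = [rng.integers(0, k, size=n) for k in cards]
    prob = np.where(cats[0] == 1, 0.7, 0.3)
    y = (rng.random(n) < prob).astype(int)
    frame = pd.DataFrame({"x1": x1})
    for i, col in enumerate(cats, start=2):
        frame[f"x{i}"] = pd.Categorical(col)
    truth = np.array([False, True, False, False, False])
    return DesignDataset(
        frame, y, truth, "strobl", "classification", {"n": n}, seed,
        categorical=["x2", "x3", "x4", "x5"],
    )


def gen_nicodemus_null(n: int = 100, seed=None) -> DesignDataset:
    """Correlated null design: 12 normals (4 equicorrelated at 0.9), permuted outcome."""
    rng = np.random.default_rng(seed)
    cov = np.eye(12)
    cov[:4, :4] = 0.9
    np.fill_diagonal(cov[:4, :4], 1.0)
    L = np.linalg.cholesky(cov)
    X = rng.standard_normal((n, 12)) @ L.T
    beta = np.array([5, 5, 2, 0, -5, -5, -2, 0, 0, 0, 0, 0], dtype=float)
    y = X @ beta + rng.normal(0.0, _noise_sd(0.5), size=n)
    y = y[rng.permutation(n)]
    frame = pd.DataFrame(X, columns=[f"x{i + 1}" for i in range(12)])
    truth = np.zeros(12, dtype=bool)
    return DesignDataset(frame, y, truth, "nicodemus-null", "regression", {"n": n}, seed)


DESIGNS = {
    "degenhardt": gen_degenhardt,
    "friedman": gen_friedman,
    "strobl": gen_strobl,
    "nicodemus-null": gen_nicodemus_null,
}


def make_design(name: str, n: int = 100, seed=None, **params) -> DesignDataset:
    """Generate a named benchmark design (see :data:`DESIGNS`)."""
    key = name.lower().replace("_", "-")
    if key not in DESIGNS:
        raise ValueError(f"unknown design {name!r}; choose from {sorted(DESIGNS)}")
    return DESIGNS[key](n=n, seed=seed, **params)
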