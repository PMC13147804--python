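"""Shadow-variable construction.

A shadow variable is an outcome-decoupled permuted copy of a predictor that
is appended to the design matrix to supply an empirical importance null.
Two schemes are provided:

* row-wise ("r-shadow"): one permutation of the sample indices is applied
  to *every* column simultaneously, i.e. whole rows of X are shuffled.
  Column marginals and the entire inter-predictor correlation matrix are
  preserved exactly, so each original variable can be compared with a
  shadow that shares its correlation-induced importance bias.
* per-column: each column is permuted independently (the Boruta-style
  scheme); marginals are preserved but cross-column association is
  destroyed.  Provided for row-vs-column ablations.

``extend`` appends the shadow block to X, giving the n x 2p matrix on which
the shadowVIMP forests are fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PermutationSpec", "ExtendedMatrix", "row_permute", "column_permute", "extend"]

ROW_SUFFIX = "__rshadow"
COLUMN_SUFFIX = "__cshadow"


@dataclass(frozen=True)
class PermutationSpec:
    """Realized permutation(s) of {0..n-1} used to build a shadow block."""

    scheme: str  # "row-wise" | "per-column"
    indices: np.ndarray  # (n,) for row-wise, (p, n) for per-column

    def __post_init__(self) -> None:
        idx = np.atleast_2d(self.indices)
        n = idx.shape[1]
        ref = np.arange(n)
        for row in idx:
            if not np.array_equal(np.sort(row), ref):
                raise ValueError("stored indices must be bijections of {0..n-1}")


@dataclass
class ExtendedMatrix:
    """Original columns followed by their shadow copies (n x 2p)."""

    X: pd.DataFrame
    origin_map: dict  # shadow column name -> original column name
    n: int
    p: int
    spec: PermutationSpec


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X))


def row_permute(X, seed=None) -> tuple[pd.DataFrame, PermutationSpec]:
    """Row-wise permuted copy of X: one permutation applied to all columns.

    Categorical values travel with their rows, and the column-wise
    correlation matrix of the result equals that of X exactly (same
    multiset of rows).
    """
    Xf = _as_frame(X)
    if Xf.shape[0] < 2:
        raise ValueError("need at least 2 rows to permute")
    rng = np.random.default_rng(seed)
    theta = rng.permutation(Xf.shape[0])
    shadow = Xf.iloc[theta].reset_index(drop=True)
    return shadow, PermutationSpec("row-wise", theta)


def column_permute(X, seed=None) -> tuple[pd.DataFrame, PermutationSpec]:
    """Independently permuted copy of each column (Boruta-style shadows)."""
    Xf = _as_frame(X)
    if Xf.shape[0] < 2:
        raise ValueError("need at least 2 rows to permute")
    rng = np.random.default_rng(seed)
    thetas = np.stack([rng.permutation(Xf.shape[0]) for _ in range(Xf.shape[1])])
    shadow = pd.DataFrame(
        {c: Xf[c].to_numpy()[thetas[i]] for i, c in enumerate(Xf.columns)}
    )
    return shadow, PermutationSpec("per-column", thetas)


def extend(X, scheme: str = "row-wise", seed=None) -> ExtendedMatrix:
    """Append a shadow block to X, returning the n x 2p extended matrix.

    Shadow columns are named deterministically from their originals
    (``<name>__rshadow`` / ``<name>__cshadow``) and ``origin_map`` records
    the shadow -> original correspondence.
    """
    Xf = _as_frame(X)
    names = list(Xf.columns)
    if len(set(names)) != len(names):
        raise ValueError("duplicate column names in X")
    if scheme == "row-wise":
        shadow, spec = row_permute(Xf, seed)
        suffix = ROW_SUFFIX
    elif scheme == "per-column":
        shadow, spec = column_permute(Xf, seed)
        suffix = COLUMN_SUFFIX
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    shadow.columns = [f"{c}{suffix}" for c in names]
    ext = pd.concat([Xf.reset_index(drop=True), shadow], axis=1)
    origin = {f"{c}{suffix}": c for c in names}
    return ExtendedMatrix(X=ext, origin_map=origin, n=Xf.shape[0], p=Xf.shape[1], spec=spec)
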