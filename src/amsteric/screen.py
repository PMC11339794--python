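"""Exhaustive best-subset multilinear screening of descriptor tables.

Given a descriptor table, a response column (a reaction or activation Gibbs
energy) and a pool of candidate descriptors, :func:`screen` fits ordinary
least squares with intercept for *every* subset of 1..max_vars candidates and
ranks the fits by R² within each subset size.  Missing cells are handled by
listwise deletion per evaluated subset (each fit keeps every row complete for
its own variables, maximising n per fit), and the number of rows actually
used is recorded on every fit so that it can be compared with published
system counts.

R² is 1 − SS_res/SS_tot, which for OLS with an intercept equals the squared
Pearson correlation between fitted and observed values; RMSE uses the
population denominator n (the unbiased n − p − 1 variant is also reported in
ledgers).  No multiple-testing correction is applied — these are raw
best-subset statistics, and the number of subsets searched is part of the
output so selection effects stay visible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .descriptors import DescriptorRecord, records_to_dataframe

__all__ = ["ScreenConfig", "ModelFit", "ScreenResult", "fit_ols", "screen",
           "apply_robustness", "apply_filter", "report"]

RobustnessMode = Literal["none", "clip_negative_to_zero", "drop_negative"]


@dataclass(frozen=True)
class ScreenConfig:
    """Configuration of one screening run.

    ``filter`` is an optional strict predicate ``(column, threshold)`` keeping
    rows with column > threshold (rows missing the filter column are dropped);
    the canonical use is ``("pyramidalization", 0.450)`` to restrict to
    clearly pyramidal amines.  ``robustness`` transforms the response before
    fitting: clip negative values to zero, or drop those rows entirely.
    """

    response: str
    candidates: tuple[str, ...]
    max_vars: int = 3
    filter: tuple[str, float] | None = None
    robustness: RobustnessMode = "none"
    top_k: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(self, "candidates", tuple(self.candidates))
        if not 1 <= self.max_vars <= 3:
            raise ValueError(f"max_vars must be 1..3, got {self.max_vars}")
        if not self.candidates:
            raise ValueError("candidate list is empty")
        if len(set(self.candidates)) != len(self.candidates):
            raise ValueError("candidate columns must be distinct")
        if self.response in self.candidates:
            raise ValueError(f"response {self.response!r} cannot be a candidate")
        if self.robustness not in ("none", "clip_negative_to_zero", "drop_negative"):
            raise ValueError(f"unknown robustness mode {self.robustness!r}")


@dataclass(frozen=True)
class ModelFit:
    """One fitted OLS model: y ≈ intercept + Σ coef_i · x_i."""

    variables: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    r2: float
    rmse: float
    n: int

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = table.loc[:, list(self.variables)].to_numpy(dtype=float)
        return self.intercept + X @ np.asarray(self.coefficients)

    @property
    def rmse_unbiased(self) -> float:
        """RMSE with the n − p − 1 denominator."""
        p = len(self.variables)
        if self.n <= p + 1:
            return float("nan")
        return self.rmse * np.sqrt(self.n / (self.n - p - 1))


@dataclass(frozen=True)
class ScreenResult:
    """Ranked fits per subset size, plus bookkeeping of the search."""

    config: ScreenConfig
    fits_by_size: dict[int, tuple[ModelFit, ...]]
    n_subsets_evaluated: int
    n_rows_after_filter: int

    def best(self, size: int) -> ModelFit:
        return self.fits_by_size[size][0]


def fit_ols(rows: pd.DataFrame | np.ndarray, response: np.ndarray,
            variables: Sequence[str] | None = None) -> ModelFit:
    """Ordinary least squares with intercept on complete data.

    ``rows`` is the design (n, p) without the intercept column; ``variables``
    names the columns (taken from the DataFrame when omitted).  A constant
    response is a defined degenerate case: slope(s) from the normal equations
    are ~0 and R² is 0 by the SS_tot = 0 guard.  Rank-deficient designs raise
    with the names of the collinear columns.
    """
    if isinstance(rows, pd.DataFrame):
        names = tuple(rows.columns) if variables is None else tuple(variables)
        X = rows.to_numpy(dtype=float)
    else:
        X = np.asarray(rows, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = tuple(variables) if variables is not None else tuple(
            f"x{i}" for i in range(X.shape[1])
        )
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need n >= p + 2 rows, got n={n}, p={p}")
    A = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(A)
    if rank < p + 1:
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {p + 1}); "
            f"collinear columns among {list(names)}"
        )
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ beta
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    r2 = min(max(r2, 0.0), 1.0)
    rmse = float(np.sqrt(ss_res / n))
    return ModelFit(
        variables=names,
        coefficients=tuple(float(b) for b in beta[1:]),
        intercept=float(beta[0]),
        r2=r2,
        rmse=rmse,
        n=n,
    )


def apply_robustness(
    table: pd.DataFrame, response: str, mode: RobustnessMode
) -> pd.DataFrame:
    """Response transformation for robustness re-fits.

    ``clip_negative_to_zero`` maps negative response values to 0 (barrierless
    processes treated as zero-barrier); ``drop_negative`` removes those rows.
    Everything else is untouched; ``none`` is the identity.
    """
    if mode == "none":
        return table
    out = table.copy()
    y = out[response]
    if mode == "clip_negative_to_zero":
        out[response] = y.where(~(y < 0), 0.0)
    elif mode == "drop_negative":
        out = out[~(y < 0)]
    else:
        raise ValueError(f"unknown robustness mode {mode!r}")
    return out


def apply_filter(table: pd.DataFrame, column: str, threshold: float) -> pd.DataFrame:
    """Keep rows with ``column > threshold`` (strict; missing cells drop)."""
    return table[table[column] > threshold]


def _as_dataframe(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table.copy()
    if table and isinstance(table[0], DescriptorRecord):
        return records_to_dataframe(table)
    return pd.DataFrame(table)


def screen(table, config: ScreenConfig) -> ScreenResult:
    """Exhaustively fit all 1..max_vars candidate subsets and rank by R².

    ``table`` is a DataFrame or a list of :class:`DescriptorRecord`.  The
    filter and robustness transforms are applied first, then each subset is
    fitted on its own complete rows (listwise deletion per subset).  Ties in
    R² break toward fewer variables, then lexicographic variable names, so
    the ranking is deterministic.
    """
    df = _as_dataframe(table)
    missing_cols = [c for c in (config.response, *config.candidates) if c not in df.columns]
    if missing_cols:
        raise KeyError(f"table lacks columns {missing_cols}")
    if config.filter is not None:
        df = apply_filter(df, *config.filter)
    df = apply_robustness(df, config.response, config.robustness)
    df = df[df[config.response].notna()]

    fits_by_size: dict[int, list[ModelFit]] = {}
    n_evaluated = 0
    any_fit = False
    for size in range(1, config.max_vars + 1):
        fits = []
        for subset in itertools.combinations(sorted(config.candidates), size):
            n_evaluated += 1
            sub = df[list(subset) + [config.response]].dropna()
            if len(sub) < size + 2:
                continue
            fits.append(
                fit_ols(sub[list(subset)], sub[config.response].to_numpy())
            )
        fits.sort(key=lambda f: (-f.r2, len(f.variables), f.variables))
        fits_by_size[size] = tuple(fits[: config.top_k])
        any_fit = any_fit or bool(fits)
    if not any_fit:
        raise ValueError(
            "no candidate subset retained enough complete rows to fit "
            f"(response {config.response!r}, {len(df)} rows after filtering)"
        )
    return ScreenResult(
        config=config,
        fits_by_size=fits_by_size,
        n_subsets_evaluated=n_evaluated,
        n_rows_after_filter=int(df[config.response].notna().sum()),
    )


def report(screens: dict[str, ScreenResult]) -> pd.DataFrame:
    """Flatten screening results into a tidy ledger table.

    Keys of ``screens`` label the runs (e.g. ``"dg_eq2"`` or
    ``"dg_eq2|pyr>0.450"``); one row per ranked fit with the equation label,
    filter, robustness mode, subset size, rank, n, variables (';'-joined),
    coefficients (';'-joined), intercept, R² and both RMSE conventions.
    The table round-trips losslessly through CSV.
    """
    rows = []
    for label, result in screens.items():
        cfg = result.config
        filt = f"{cfg.filter[0]}>{cfg.filter[1]}" if cfg.filter else ""
        for size, fits in result.fits_by_size.items():
            for rank, fit in enumerate(fits, start=1):
                rows.append(
                    {
                        "screen": label,
                        "response": cfg.response,
                        "filter": filt,
                        "robustness": cfg.robustness,
                        "n_vars": size,
                        "rank": rank,
                        "n": fit.n,
                        "variables": ";".join(fit.variables),
                        "coefficients": ";".join(f"{c:.10g}" for c in fit.coefficients),
                        "intercept": fit.intercept,
                        "r2": fit.r2,
                        "rmse": fit.rmse,
                        "rmse_unbiased": fit.rmse_unbiased,
                        "n_subsets_searched": result.n_subsets_evaluated,
                    }
                )
    return pd.DataFrame(rows)
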