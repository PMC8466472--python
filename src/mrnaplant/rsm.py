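"""Coded quadratic response-surface models (RSM) with term-wise ANOVA.

A coded RSM regresses a response on factors linearly mapped from their
physical ranges onto [-1, +1]:

    y = b0 + sum_i b_i x_i + sum_{i<j} b_ij x_i x_j + sum_i b_ii x_i^2

Models may be sparse (e.g. a purely linear screening model): absent terms
carry coefficient 0.  Fitting is ordinary least squares; the ANOVA table
reports the partial (type-III) sum of squares, F and p per term, which for
the orthogonal designs used in screening coincides with the classical
sequential decomposition.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InvalidInputError, SingularFitError


def term_names(factor_names: list[str]) -> list[str]:
    """Canonical term order: intercept, linear, pairwise, quadratic."""
    names = ["Intercept"] + list(factor_names)
    names += [f"{a}*{b}" for a, b in itertools.combinations(factor_names, 2)]
    names += [f"{a}^2" for a in factor_names]
    return names


@dataclass
class CodedRSM:
    """Quadratic response surface in coded (+/-1) factors.

    ``coefficients`` maps term names (see :func:`term_names`) to values;
    missing terms are zero.  ``coding_ranges`` maps each factor to its
    (low_physical, high_physical) pair, i.e. the values coded as -1 and +1.
    """

    factor_names: list[str]
    coding_ranges: dict[str, tuple[float, float]]
    coefficients: dict[str, float]
    response_name: str = "response"
    anova: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        valid = set(term_names(self.factor_names))
        unknown = set(self.coefficients) - valid
        if unknown:
            raise InvalidInputError(f"unknown RSM terms: {sorted(unknown)}")
        for f in self.factor_names:
            if f not in self.coding_ranges:
                raise InvalidInputError(f"missing coding range for factor {f!r}")
            lo, hi = self.coding_ranges[f]
            if not lo < hi:
                raise InvalidInputError(
                    f"coding range for {f!r} must have low < high")

    # -- coding ------------------------------------------------------------
    def code(self, physical: np.ndarray) -> np.ndarray:
        """Map physical factor values (n, k) onto coded [-1, +1] units."""
        physical = np.atleast_2d(np.asarray(physical, dtype=float))
        if physical.shape[1] != len(self.factor_names):
            raise InvalidInputError(
                f"expected {len(self.factor_names)} factors, "
                f"got {physical.shape[1]}")
        lo = np.array([self.coding_ranges[f][0] for f in self.factor_names])
        hi = np.array([self.coding_ranges[f][1] for f in self.factor_names])
        return (2.0 * physical - (hi + lo)) / (hi - lo)

    def decode(self, coded: np.ndarray) -> np.ndarray:
        coded = np.atleast_2d(np.asarray(coded, dtype=float))
        lo = np.array([self.coding_ranges[f][0] for f in self.factor_names])
        hi = np.array([self.coding_ranges[f][1] for f in self.factor_names])
        return (coded * (hi - lo) + hi + lo) / 2.0

    def coefficient_vector(self) -> np.ndarray:
        return np.array([self.coefficients.get(t, 0.0)
                         for t in term_names(self.factor_names)])

    # -- evaluation --------------------------------------------------------
    def predict_coded(self, coded: np.ndarray) -> np.ndarray:
        coded = np.atleast_2d(np.asarray(coded, dtype=float))
        X = design_matrix(coded)
        return X @ self.coefficient_vector()


def design_matrix(coded: np.ndarray) -> np.ndarray:
    """Model matrix columns in canonical term order for coded runs (n, k)."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    n, k = coded.shape
    cols = [np.ones(n)]
    cols += [coded[:, i] for i in range(k)]
    cols += [coded[:, i] * coded[:, j]
             for i, j in itertools.combinations(range(k), 2)]
    cols += [coded[:, i] ** 2 for i in range(k)]
    return np.column_stack(cols)


def rsm_predict(model: CodedRSM, physical_factors) -> float | np.ndarray:
    """Evaluate the model at physical factor settings.

    Settings outside the coding ranges are legal (the polynomial
    extrapolates) but raise a UserWarning.
    """
    physical = np.atleast_2d(np.asarray(physical_factors, dtype=float))
    coded = model.code(physical)
    if np.any(np.abs(coded) > 1 + 1e-9):
        warnings.warn("factor setting outside coding range; extrapolating",
                      UserWarning, stacklevel=2)
    out = model.predict_coded(coded)
    return float(out[0]) if out.shape == (1,) else out


def rsm_fit(design: np.ndarray, responses: np.ndarray,
            factor_names: list[str],
            coding_ranges: dict[str, tuple[float, float]],
            response_name: str = "response",
            coded: bool = True) -> CodedRSM:
    """Least-squares quadratic fit with a term-wise ANOVA table.

    ``design`` holds one run per row, in coded units unless ``coded=False``
    (then rows are physical and are coded via ``coding_ranges`` first).
    Raises :class:`SingularFitError` for rank-deficient designs.
    """
    proto = CodedRSM(factor_names, coding_ranges,
                     {}, response_name=response_name)
    runs = np.atleast_2d(np.asarray(design, dtype=float))
    if not coded:
        runs = proto.code(runs)
    y = np.asarray(responses, dtype=float)
    X = design_matrix(runs)
    names = term_names(factor_names)
    if len(y) < X.shape[1]:
        raise InvalidInputError(
            f"need at least {X.shape[1]} runs for {len(names)} coefficients, "
            f"got {len(y)}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularFitError("design is rank deficient for a full "
                               "quadratic model")
    res = sm.OLS(y, X).fit()
    coeffs = dict(zip(names, res.params))

    # term-wise ANOVA: partial SS_j = beta_j^2 / [(X'X)^-1]_jj, F_j on
    # (1, df_resid); plus whole-model row and residual/total book-ends.
    xtx_inv = np.linalg.inv(X.T @ X)
    df_resid = int(res.df_resid)
    ms_resid = res.ssr / df_resid if df_resid > 0 else np.nan
    rows = []
    ss_model = float(np.sum((res.fittedvalues - y.mean()) ** 2))
    df_model = X.shape[1] - 1
    f_model = (ss_model / df_model) / ms_resid if df_resid > 0 else np.nan
    p_model = stats.f.sf(f_model, df_model, df_resid) if df_resid > 0 else np.nan
    rows.append(("Model", ss_model, df_model, ss_model / df_model,
                 f_model, p_model))
    for j, name in enumerate(names):
        if name == "Intercept":
            continue
        ss = res.params[j] ** 2 / xtx_inv[j, j]
        fj = ss / ms_resid if df_resid > 0 else np.nan
        pj = stats.f.sf(fj, 1, df_resid) if df_resid > 0 else np.nan
        rows.append((name, ss, 1, ss, fj, pj))
    rows.append(("Residual", res.ssr, df_resid, ms_resid, np.nan, np.nan))
    ss_total = float(np.sum((y - y.mean()) ** 2))
    rows.append(("Cor Total", ss_total, len(y) - 1, np.nan, np.nan, np.nan))
    anova = pd.DataFrame(rows, columns=["term", "SS", "df", "MS", "F", "p"])

    return CodedRSM(factor_names, coding_ranges, coeffs,
                    response_name=response_name, anova=anova)
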