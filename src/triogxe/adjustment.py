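"""Construction of the adjustment covariate X for the log-GRR model.

Three forms are supported: oracle stratum dummy variables, the expected
exposure given genetic markers (EEGM) as a scalar surrogate for the strata,
and principal-component scores scaled to the unit interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

_METHODS = ("stratum", "eegm", "pcs")


@dataclass(frozen=True)
class AdjustmentSpec:
    """Which adjustment to build and its dimension (number of dummies or
    selected PCs; always 1 for EEGM)."""

    method: str
    k: int = 1

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if self.method == "eegm" and self.k != 1:
            raise ValueError("EEGM adjustment is a single scalar covariate (k=1)")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def stratum_dummies(labels: np.ndarray) -> np.ndarray:
    """Dummy-code stratum labels: with strata 0..K the k-th column indicates
    membership in stratum k > 0, the lowest stratum being the baseline.

    Returns an n-by-K matrix; raises if only one stratum is present.
    """
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if levels.size < 2:
        raise ValueError(
            "stratum dummies need at least two distinct strata "
            f"(got {levels.tolist()})"
        )
    return (labels[:, None] == levels[None, 1:]).astype(float)


def eegm(
    exposures: np.ndarray,
    scores: np.ndarray,
    exposure_type: str = "continuous",
) -> np.ndarray:
    """Expected exposure given genetic markers: fitted values of the
    regression of E on the PC scores (linear for continuous E, logistic for
    binary E, fitted probabilities returned).

    The regression includes an intercept; fitted values are used raw. The
    result is invariant to invertible affine transformations of the score
    columns, since only the regression span matters.
    """
    exposures = np.asarray(exposures, float)
    scores = np.asarray(scores, float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if scores.shape[0] != exposures.shape[0]:
        raise ValueError("exposures and scores must have the same number of rows")
    design = sm.add_constant(scores, has_constant="add")
    if exposure_type == "continuous":
        fitted = sm.OLS(exposures, design).fit().fittedvalues
    elif exposure_type == "binary":
        vals = np.unique(exposures)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("binary exposure must be coded 0/1")
        try:
            res = sm.Logit(exposures, design).fit(disp=0, maxiter=200)
        except Exception as exc:  # PerfectSeparationError and friends
            raise RuntimeError(
                f"logistic EEGM regression failed (possible separation): {exc}"
            ) from exc
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError(
                "logistic EEGM regression did not converge (possible separation)"
            )
        fitted = res.predict(design)
    else:
        raise ValueError(f"unknown exposure_type {exposure_type!r}")
    return np.asarray(fitted, float)


def scale_unit_interval(scores: np.ndarray) -> np.ndarray:
    """Shift and scale each column to span [0, 1] (subtract the minimum,
    divide by the range), preserving order within columns.

    With PC scores this puts hypothetical 'ancestral prototypes' at 0 and 1,
    so covariate contrasts at x = 0 and x = 1 are interpretable. Constant
    columns raise.
    """
    scores = np.asarray(scores, float)
    one_d = scores.ndim == 1
    if one_d:
        scores = scores[:, None]
    lo = scores.min(axis=0)
    rng = scores.max(axis=0) - lo
    if np.any(rng == 0.0):
        bad = np.flatnonzero(rng == 0.0).tolist()
        raise ValueError(f"cannot scale constant column(s) {bad} to the unit interval")
    out = (scores - lo) / rng
    return out[:, 0] if one_d else out
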