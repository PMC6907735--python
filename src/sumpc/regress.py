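"""OLS solutions from reconstructed sufficient statistics.

Coefficients solve the normal equations (X'X) beta = X'y by a symmetric
factorization rather than the explicit inverse; the residual variance is
(y'y - beta'X'y) / (n - p - 1) and coefficient variances are the diagonal
of sigma^2 (X'X)^{-1}.  Inference uses the two-sided t distribution with
n - p - 1 degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg, stats

from .errors import DegreesOfFreedomError, PanelError, SingularModelError
from .moments import ModelSpec, MomentSet, build_moments
from .sumstats_io import SummaryPanel

#: condition-number guard for the normal-equation matrix
MAX_CONDITION = 1e12
#: residual variances in (-CLIP_FRACTION * y'y, 0) are treated as rounding
CLIP_FRACTION = 1e-10


@dataclass(frozen=True)
class FitResult:
    """Coefficients and inference for one fitted model (intercept first)."""

    term_names: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    sigma2: float
    df: int
    t_stats: np.ndarray
    p_values: np.ndarray
    n: int

    def __post_init__(self) -> None:
        k = len(self.term_names)
        for arr in (self.coefficients, self.standard_errors, self.t_stats, self.p_values):
            if arr.shape != (k,):
                raise PanelError("fit result arrays disagree in length")

    def term(self, name: str) -> int:
        return self.term_names.index(name)

    @property
    def neglog10_p(self) -> np.ndarray:
        """-log10 of the two-sided p-values, computed on the log scale.

        Stays finite far beyond float underflow of the p-value itself.
        """
        with np.errstate(invalid="ignore"):
            logsf = stats.t.logsf(np.abs(self.t_stats), self.df)
        out = -(logsf + math.log(2.0)) / math.log(10.0)
        out[np.isinf(self.t_stats)] = np.inf
        return out


def _factor(xtx: np.ndarray):
    cond = np.linalg.cond(xtx)
    if not np.isfinite(cond) or cond > MAX_CONDITION:
        raise SingularModelError(
            f"normal-equation matrix is ill-conditioned (cond={cond:.3g})"
        )
    try:
        return linalg.cho_factor(xtx, lower=True)
    except linalg.LinAlgError as exc:
        raise SingularModelError(f"normal-equation matrix not positive definite: {exc}")


def solve_coefficients(m: MomentSet) -> np.ndarray:
    """Solve (X'X) beta = X'y."""
    beta = linalg.cho_solve(_factor(m.xtx), m.xty)
    return beta


def residual_variance(m: MomentSet, beta: np.ndarray) -> float:
    """sigma^2 = (y'y - beta'X'y) / (n - p - 1), with tiny-negative clipping."""
    df = m.n - (m.p + 1)
    if df <= 0:
        raise DegreesOfFreedomError(f"no residual degrees of freedom (n={m.n}, p={m.p})")
    rss = m.yty - float(beta @ m.xty)
    if rss < 0:
        if rss < -CLIP_FRACTION * max(abs(m.yty), 1.0):
            raise PanelError(
                f"negative residual sum of squares ({rss!r}); panel is self-contradictory"
            )
        rss = 0.0
    return rss / df


def standard_errors(m: MomentSet, sigma2: float) -> np.ndarray:
    """Square roots of the diagonal of sigma^2 (X'X)^{-1}."""
    k = m.p + 1
    inv = linalg.cho_solve(_factor(m.xtx), np.eye(k))
    diag = np.clip(np.diag(inv), 0.0, None)
    return np.sqrt(sigma2 * diag)


def fit_moments(m: MomentSet) -> FitResult:
    """Full OLS fit from a MomentSet."""
    beta = solve_coefficients(m)
    sigma2 = residual_variance(m, beta)
    se = standard_errors(m, sigma2)
    return finalize_fit(m.term_names, beta, se, sigma2, m.n - (m.p + 1), m.n)


def finalize_fit(
    term_names: Sequence[str],
    beta: np.ndarray,
    se: np.ndarray,
    sigma2: float,
    df: int,
    n: int,
) -> FitResult:
    """Attach t statistics and two-sided t p-values to estimates."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    t = np.empty_like(beta)
    pos = se > 0
    t[pos] = beta[pos] / se[pos]
    t[~pos] = np.sign(beta[~pos]) * np.inf
    t[~pos & (beta == 0)] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    return FitResult(
        term_names=tuple(term_names),
        coefficients=beta,
        standard_errors=se,
        sigma2=float(sigma2),
        df=int(df),
        t_stats=t,
        p_values=np.clip(p, 0.0, 1.0),
        n=int(n),
    )


def fit(panel: SummaryPanel, spec: ModelSpec) -> FitResult:
    """Fit one model on a summary panel via moment reconstruction."""
    return fit_moments(build_moments(panel, spec))


def combine_adjusted_fits(fits: Sequence[FitResult], weights: Sequence[float]) -> np.ndarray:
    """Coefficients of ``sum_h c_h y_h ~ X`` from per-phenotype fits on the
    same design: beta = sum_h c_h beta_h.

    Only the coefficients combine this way; standard errors of the
    combination require y'y and must come from a full :func:`fit`.
    """
    if len(fits) != len(weights):
        raise PanelError("one weight per fit required")
    if not fits:
        raise PanelError("no fits supplied")
    first = fits[0]
    for f in fits[1:]:
        if f.term_names != first.term_names or f.df != first.df:
            raise PanelError("fits were not produced on identical designs")
    out = np.zeros_like(first.coefficients)
    for w, f in zip(weights, fits):
        out = out + float(w) * f.coefficients
    return out
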