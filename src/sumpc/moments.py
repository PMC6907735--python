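"""Reconstruction of OLS sufficient statistics from a summary panel.

For a single-SNP multiple-regression model ``c'Y ~ 1 + g + covariates``
every entry of the normal equations can be written in terms of released
summary statistics:

- sums of a predictor:          sum(x_k) = n * mean(x_k)
- predictor cross-products:     sum(x_k x_l) = cov(x_k, x_l) (n-1) + n mean_k mean_l
- genotype-variable covariance: cov(g, v) = slope(v ~ g) * var(g)
- response cross-products (for the combined response y = sum_h c_h y_h):
  X'y and y'y expand bilinearly in the weights c over the released
  covariances and means.

Genotype moments come either from the released sample moments ("exact
mode": reconstruction is bit-exact against raw OLS) or, when the release
carries only an allele frequency p, from the Hardy-Weinberg values 2p and
2p(1-p) ("HWE mode": approximate under HWE deviation).

Sample covariances use the n-1 denominator throughout; exactness depends
on matching this convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import CompletenessError, PanelError, SchemaError
from .sumstats_io import SummaryPanel

logger = logging.getLogger(__name__)

INTERCEPT = "intercept"


@dataclass(frozen=True)
class ModelSpec:
    """One single-SNP regression model on a summary panel.

    The response is the linear combination ``sum_h c_h y_h`` given by
    ``response`` as (variable, weight) pairs.  Predictors are the genotype
    dosage of ``snp_id`` (if given) followed by ``covariates``; an
    intercept is always included.  With ``center_response`` the response
    variables are mean-centered, so all response mean terms vanish from
    the reconstruction (covariances and slopes are shift-invariant).
    """

    response: tuple[tuple[str, float], ...]
    covariates: tuple[str, ...] = ()
    snp_id: str | None = None
    center_response: bool = False
    include_intercept: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "response", tuple((str(v), float(c)) for v, c in self.response))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if not self.response:
            raise SchemaError("model needs at least one response term")
        if not all(np.isfinite(c) for _, c in self.response):
            raise SchemaError("non-finite response weight")
        names = [v for v, _ in self.response]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate response variable")
        preds = self.predictors
        if len(set(preds)) != len(preds):
            raise SchemaError("duplicate predictor")
        if not self.include_intercept:
            raise SchemaError("models without an intercept are out of scope")

    @property
    def predictors(self) -> tuple[str, ...]:
        """Non-intercept design columns, genotype first when present."""
        if self.snp_id is None:
            return self.covariates
        return (self.snp_id,) + self.covariates

    @property
    def term_names(self) -> tuple[str, ...]:
        return (INTERCEPT,) + self.predictors

    def with_snp(self, snp_id: str) -> "ModelSpec":
        return replace(self, snp_id=snp_id)

    def with_weights(self, weights: Sequence[float]) -> "ModelSpec":
        if len(weights) != len(self.response):
            raise SchemaError("weight vector length mismatch")
        return replace(
            self,
            response=tuple((v, float(c)) for (v, _), c in zip(self.response, weights)),
        )

    def describe(self) -> str:
        resp = " + ".join(f"{c:g}*{v}" for v, c in self.response)
        return f"{resp} ~ {' + '.join(self.term_names)}"


@dataclass(frozen=True)
class MomentSet:
    """Sufficient statistics of one model: X'X, X'y, y'y, n, p."""

    xtx: np.ndarray
    xty: np.ndarray
    yty: float
    n: int
    p: int
    term_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.xtx.shape != (self.p + 1, self.p + 1) or self.xty.shape != (self.p + 1,):
            raise SchemaError("moment dimensions disagree")


def genotype_moments(
    maf: float, geno_mean: float | None = None, geno_var: float | None = None
) -> tuple[float, float]:
    """Mean and variance of the additive dosage.

    Released sample moments take precedence; otherwise the Hardy-Weinberg
    values 2p and 2p(1-p) are derived from the allele frequency.
    """
    if geno_mean is not None and geno_var is not None:
        return float(geno_mean), float(geno_var)
    if not (0.0 < maf < 1.0):
        raise PanelError(f"allele frequency {maf} outside (0,1) and no explicit moments")
    if geno_mean is None and geno_var is None:
        return 2.0 * maf, 2.0 * maf * (1.0 - maf)
    # one explicit moment: fill the gap from HWE
    mean = float(geno_mean) if geno_mean is not None else 2.0 * maf
    var = float(geno_var) if geno_var is not None else 2.0 * maf * (1.0 - maf)
    return mean, var


def _model_n(panel: SummaryPanel, spec: ModelSpec) -> int:
    if spec.snp_id is None:
        return panel.n
    snp = panel.snp(spec.snp_id)
    if snp.n != panel.n:
        logger.warning(
            "SNP %s has n=%d but panel n=%d; using the minimum",
            spec.snp_id, snp.n, panel.n,
        )
    return min(panel.n, snp.n)


def _resolve(panel: SummaryPanel, spec: ModelSpec) -> None:
    if spec.snp_id is not None and spec.snp_id not in panel._snp_by_id:
        raise CompletenessError(f"unknown SNP {spec.snp_id!r}")
    for name in spec.covariates:
        if name not in panel._var_by_name:
            raise CompletenessError(f"unknown covariate {name!r}")
    for name, _ in spec.response:
        if name not in panel._var_by_name:
            raise CompletenessError(f"unknown response variable {name!r}")


def _geno_cov(panel: SummaryPanel, snp_id: str, variable: str, geno_var: float) -> float:
    """cov(g, v) from the simple-regression identity slope * var(g)."""
    if not panel.has_assoc(snp_id, variable):
        raise CompletenessError(
            f"no association record for ({snp_id!r}, {variable!r})"
        )
    return panel.assoc_record(snp_id, variable).slope * geno_var


def predictor_cross_cov(
    panel: SummaryPanel, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Mean vector and covariance matrix of the non-intercept predictors.

    Covariate blocks are read off the released covariance matrix; the
    genotype row/column is filled via ``slope * var(g)`` and the genotype
    diagonal from :func:`genotype_moments`.
    """
    _resolve(panel, spec)
    preds = spec.predictors
    k = len(preds)
    means = np.empty(k)
    cov = np.empty((k, k))

    geno_var = None
    if spec.snp_id is not None:
        snp = panel.snp(spec.snp_id)
        g_mean, geno_var = genotype_moments(snp.maf, snp.geno_mean, snp.geno_var)
        means[0] = g_mean
        cov[0, 0] = geno_var

    offset = 1 if spec.snp_id is not None else 0
    for i, name in enumerate(spec.covariates):
        means[offset + i] = panel.variable(name).mean
        for j, other in enumerate(spec.covariates[: i + 1]):
            try:
                v = panel.cov.get(name, other)
            except KeyError:
                raise CompletenessError(
                    f"covariance for ({name!r}, {other!r}) missing from panel"
                ) from None
            cov[offset + i, offset + j] = cov[offset + j, offset + i] = v
        if spec.snp_id is not None:
            v = _geno_cov(panel, spec.snp_id, name, geno_var)
            cov[0, offset + i] = cov[offset + i, 0] = v
    return means, cov


def build_xtx(n: int, means: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Assemble X'X from predictor means and covariances.

    Border row/column are the predictor sums ``n * mean``; the interior is
    ``cov * (n-1) + n * outer(mean, mean)``.
    """
    means = np.asarray(means, dtype=float)
    cov = np.asarray(cov, dtype=float)
    p = means.shape[0]
    if cov.shape != (p, p):
        raise SchemaError(f"covariance shape {cov.shape} does not match {p} means")
    xtx = np.empty((p + 1, p + 1))
    xtx[0, 0] = n
    xtx[0, 1:] = xtx[1:, 0] = n * means
    xtx[1:, 1:] = cov * (n - 1) + n * np.outer(means, means)
    return xtx


def _response_stats(panel: SummaryPanel, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Weights c and means of the response variables (zero when centered)."""
    c = np.array([w for _, w in spec.response])
    if spec.center_response:
        mu = np.zeros(len(c))
    else:
        mu = np.array([panel.variable(v).mean for v, _ in spec.response])
    return c, mu


def build_xty(panel: SummaryPanel, spec: ModelSpec) -> np.ndarray:
    """Assemble X'y for the combined response ``sum_h c_h y_h``.

    Entry 0 is ``n * sum_h c_h mean(y_h)``; the entry for predictor x_k is
    ``(sum_h c_h cov(x_k, y_h)) (n-1) + n mean(x_k) sum_h c_h mean(y_h)``
    with the genotype covariance supplied by the simple-regression slope.
    """
    _resolve(panel, spec)
    n = _model_n(panel, spec)
    c, mu = _response_stats(panel, spec)
    cy_bar = float(c @ mu)

    preds = spec.predictors
    xty = np.empty(len(preds) + 1)
    xty[0] = n * cy_bar

    geno_var = None
    if spec.snp_id is not None:
        snp = panel.snp(spec.snp_id)
        g_mean, geno_var = genotype_moments(snp.maf, snp.geno_mean, snp.geno_var)

    for i, name in enumerate(preds):
        if spec.snp_id is not None and i == 0:
            cov_xy = sum(
                w * _geno_cov(panel, spec.snp_id, v, geno_var) for v, w in spec.response
            )
            x_mean = g_mean
        else:
            cov_xy = 0.0
            for v, w in spec.response:
                try:
                    cov_xy += w * panel.cov.get(name, v)
                except KeyError:
                    raise CompletenessError(
                        f"covariance for ({name!r}, {v!r}) missing from panel"
                    ) from None
            x_mean = panel.variable(name).mean
        xty[i + 1] = cov_xy * (n - 1) + n * x_mean * cy_bar
    return xty


def build_yty(panel: SummaryPanel, spec: ModelSpec) -> float:
    """Assemble y'y = sum_hj c_h c_j (cov(y_h,y_j)(n-1) + mean_h mean_j n)."""
    _resolve(panel, spec)
    n = _model_n(panel, spec)
    c, mu = _response_stats(panel, spec)
    names = [v for v, _ in spec.response]
    try:
        sub = panel.cov.submatrix(names)
    except KeyError:
        raise CompletenessError(
            f"response covariance block missing for {names}"
        ) from None
    yty = float(c @ (sub.values * (n - 1) + n * np.outer(mu, mu)) @ c)
    return yty


def build_moments(panel: SummaryPanel, spec: ModelSpec) -> MomentSet:
    """Compose X'X, X'y and y'y into the model's full sufficient statistics."""
    _resolve(panel, spec)
    n = _model_n(panel, spec)
    if spec.snp_id is not None:
        snp = panel.snp(spec.snp_id)
        if snp.geno_mean is None or snp.geno_var is None:
            logger.info(
                "SNP %s: genotype moments derived from allele frequency under HWE; "
                "reconstruction is approximate", spec.snp_id,
            )
    means, cov = predictor_cross_cov(panel, spec)
    return MomentSet(
        xtx=build_xtx(n, means, cov),
        xty=build_xty(panel, spec),
        yty=build_yty(panel, spec),
        n=n,
        p=len(spec.predictors),
        term_names=spec.term_names,
    )
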