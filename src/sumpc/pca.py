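"""Principal-component regression on summary statistics.

The j-th principal component score of centered phenotypes Y is the linear
combination with weights given by the eigenvector of cov(Y) belonging to
the j-th largest eigenvalue.  Because the score is a linear combination,
its covariate-adjusted regression on a SNP reduces to the combined-
response moment reconstruction with weights phi_j and centered response
means — no subject-level data required.

Eigenvectors are sign-ambiguous; for byte-stable output each column is
flipped so its largest-absolute entry is positive (ties broken at the
lowest index), and equal eigenvalues are ordered by the variable index of
the dominant loading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import PanelError
from . import pheno_cov
from .moments import ModelSpec
from .regress import FitResult, finalize_fit, fit as _fit
from .sumstats_io import CovarianceMatrix, SummaryPanel

logger = logging.getLogger(__name__)

#: eigenvalues this far below zero (relative to the largest) are a domain error
PSD_RTOL = 1e-8


@dataclass(frozen=True)
class PcBasis:
    """Eigenvalues (descending) and sign-fixed eigenvector weights."""

    eigenvalues: np.ndarray
    weights: np.ndarray  # column j = weights of PC j+1
    scaled: bool
    variable_names: tuple[str, ...]

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def component_weights(self, component: int) -> np.ndarray:
        """Weights of the 1-based ``component``."""
        if not 1 <= component <= self.n_components:
            raise IndexError(
                f"component {component} out of range 1..{self.n_components}"
            )
        return self.weights[:, component - 1]

    @property
    def proportion_variance(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else self.eigenvalues * 0.0


def _fix_signs(weights: np.ndarray) -> np.ndarray:
    out = weights.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))  # argmax takes the lowest index on ties
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def _order_components(eigenvalues: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Descending eigenvalues; exact ties ordered by dominant-loading index."""
    order = list(np.argsort(-eigenvalues, kind="stable"))
    scale = max(float(np.max(np.abs(eigenvalues))), 1.0)
    i = 0
    while i < len(order):
        j = i + 1
        while j < len(order) and abs(eigenvalues[order[j]] - eigenvalues[order[i]]) <= 1e-12 * scale:
            j += 1
        if j - i > 1:
            order[i:j] = sorted(order[i:j], key=lambda k: int(np.argmax(np.abs(weights[:, k]))))
        i = j
    order = np.array(order)
    return eigenvalues[order], weights[:, order]


def pc_weights(cov: CovarianceMatrix, scaled: bool = False) -> PcBasis:
    """Eigendecomposition of a covariance (or derived correlation) matrix."""
    values = cov.values
    if scaled:
        sd = np.sqrt(np.diag(values))
        if np.any(sd <= 0):
            raise PanelError("zero variance; cannot scale to a correlation matrix")
        values = values / np.outer(sd, sd)
    eig, vec = np.linalg.eigh(values)
    if eig.min() < -PSD_RTOL * max(float(eig.max()), 1.0):
        raise PanelError(
            f"matrix is not positive semidefinite (min eigenvalue {eig.min():.3g}); "
            "repair it first (pheno_cov.repair_psd)"
        )
    eig = np.clip(eig, 0.0, None)[::-1]
    vec = vec[:, ::-1]
    vec = _fix_signs(vec)
    eig, vec = _order_components(eig, vec)
    return PcBasis(
        eigenvalues=eig, weights=vec, scaled=scaled, variable_names=cov.variables
    )


def center_coefficients(fit: FitResult, mu: float) -> FitResult:
    """Transform a fit of y into the fit of y - mu.

    Only the intercept moves (down by mu); slopes, standard errors,
    residual variance and degrees of freedom are unchanged.
    """
    beta = fit.coefficients.copy()
    beta[0] -= mu
    return finalize_fit(fit.term_names, beta, fit.standard_errors, fit.sigma2, fit.df, fit.n)


def standardize_coefficients(fit: FitResult, mu: float, sigma: float) -> FitResult:
    """Transform a fit of y into the fit of (y - mu) / sigma.

    All coefficients (after the intercept shift) and all standard errors
    divide by sigma, the residual variance by sigma^2; t statistics and
    p-values are unchanged.
    """
    if sigma <= 0:
        raise PanelError(f"sigma must be positive, got {sigma}")
    beta = fit.coefficients.copy()
    beta[0] -= mu
    beta /= sigma
    se = fit.standard_errors / sigma
    return finalize_fit(fit.term_names, beta, se, fit.sigma2 / sigma**2, fit.df, fit.n)


def pc_model_spec(
    panel: SummaryPanel,
    phenotypes: Sequence[str],
    covariates: Sequence[str],
    component: int,
    scaled: bool = False,
    cov: CovarianceMatrix | None = None,
) -> tuple[ModelSpec, PcBasis]:
    """Build the combined-response model of one PC score (no SNP bound yet).

    The PC basis comes from the phenotype block of the panel covariance
    (or a supplied matrix, e.g. an estimate), repaired to PSD if needed.
    With ``scaled`` the score is built from standardized phenotypes, so
    the raw-phenotype weights are phi_j / sd_h.
    """
    phenotypes = tuple(phenotypes)
    block = cov if cov is not None else panel.cov.submatrix(phenotypes)
    if tuple(block.variables) != phenotypes:
        block = block.submatrix(phenotypes)
    if not pheno_cov.is_psd(block, rtol=PSD_RTOL):
        block = pheno_cov.repair_psd(block)
    basis = pc_weights(block, scaled=scaled)
    phi = basis.component_weights(component)
    if scaled:
        sd = np.sqrt(np.diag(block.values))
        weights = phi / sd
    else:
        weights = phi
    spec = ModelSpec(
        response=tuple(zip(phenotypes, weights)),
        covariates=tuple(covariates),
        center_response=True,
    )
    return spec, basis


def pc_fit(
    panel: SummaryPanel,
    phenotypes: Sequence[str],
    covariates: Sequence[str],
    snp_id: str,
    component: int,
    scaled: bool = False,
    cov: CovarianceMatrix | None = None,
) -> FitResult:
    """Covariate-adjusted regression of a PC score on one SNP,
    reconstructed entirely from summary statistics."""
    spec, _ = pc_model_spec(panel, phenotypes, covariates, component, scaled, cov)
    return _fit(panel, spec.with_snp(snp_id))
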