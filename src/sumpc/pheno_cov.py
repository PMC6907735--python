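"""Phenotype covariance estimation from per-SNP slope correlations.

When a release omits the variable covariance matrix it can be
approximated from the association table alone: across a genome of mostly
unassociated SNPs the sampling noise of the simple-regression slopes for
two variables is correlated exactly as the variables themselves are, so

    cov(y_h, y_j) ~= cor(b_h, b_j) * sqrt(var(y_h) var(y_j))

where b_h is the vector of slopes of y_h against every SNP and the
variances come from the descriptive table.  Accuracy improves with the
number of SNPs correlated and degrades with the fraction of truly
associated SNPs among them; an optional |t| cutoff excludes the latter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import PanelError, SchemaError
from .sumstats_io import CovarianceMatrix, SummaryPanel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SlopeMatrix:
    """Simple-regression slopes, SNPs in rows, variables in columns."""

    snp_ids: tuple[str, ...]
    variables: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        s, m = len(self.snp_ids), len(self.variables)
        if self.values.shape != (s, m):
            raise SchemaError(f"slope matrix shape {self.values.shape} != ({s}, {m})")
        if s < 3:
            raise PanelError("slope correlation needs at least 3 SNPs")
        if not np.all(np.isfinite(self.values)):
            raise SchemaError("non-finite slope")


def slope_matrix_from_panel(
    panel: SummaryPanel, variables: Sequence[str] | None = None
) -> SlopeMatrix:
    """Extract the S x m slope matrix from a panel's association table."""
    names = tuple(variables) if variables is not None else panel.variable_names
    snp_ids = panel.snp_ids
    values = np.empty((len(snp_ids), len(names)))
    for i, sid in enumerate(snp_ids):
        for j, v in enumerate(names):
            if not panel.has_assoc(sid, v):
                raise PanelError(f"no slope for ({sid!r}, {v!r})")
            values[i, j] = panel.assoc_record(sid, v).slope
    return SlopeMatrix(snp_ids, names, values)


def estimate_cov(slopes: SlopeMatrix, variances: Sequence[float]) -> CovarianceMatrix:
    """Covariance matrix with the supplied variances on the diagonal and
    off-diagonals cor(b_h, b_j) * sqrt(var_h var_j) (Pearson, across SNPs)."""
    var = np.asarray(variances, dtype=float)
    if var.shape != (len(slopes.variables),):
        raise SchemaError("one variance per slope column required")
    if np.any(var <= 0):
        raise PanelError("variances must be positive")
    sd_b = slopes.values.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd_b == 0)
    if dead.size:
        raise PanelError(
            f"degenerate slope column(s) {[slopes.variables[i] for i in dead]}: "
            "no variation across SNPs"
        )
    cor = np.corrcoef(slopes.values, rowvar=False)
    sd = np.sqrt(var)
    cov = cor * np.outer(sd, sd)
    np.fill_diagonal(cov, var)
    cov = (cov + cov.T) / 2.0
    return CovarianceMatrix(slopes.variables, cov)


def estimate_cov_from_panel(
    panel: SummaryPanel,
    variables: Sequence[str] | None = None,
    max_abs_t: float | None = None,
) -> CovarianceMatrix:
    """Estimate the variable covariance matrix from a panel's slopes.

    With ``max_abs_t`` set, SNPs whose simple-regression |t| exceeds the
    cutoff for any variable are excluded from the correlation, limiting
    the influence of truly associated markers.  The number of SNPs used
    is logged.
    """
    slopes = slope_matrix_from_panel(panel, variables)
    variances = np.array([panel.variable(v).variance for v in slopes.variables])
    if max_abs_t is not None:
        t = _simple_regression_t(panel, slopes, variances)
        keep = np.all(np.abs(t) <= max_abs_t, axis=1)
        if keep.sum() < 3:
            raise PanelError(
                f"|t| <= {max_abs_t} leaves {int(keep.sum())} SNPs; need >= 3"
            )
        slopes = SlopeMatrix(
            tuple(np.asarray(slopes.snp_ids)[keep]),
            slopes.variables,
            slopes.values[keep],
        )
    logger.info("covariance estimated from %d SNPs", len(slopes.snp_ids))
    return estimate_cov(slopes, variances)


def _simple_regression_t(
    panel: SummaryPanel, slopes: SlopeMatrix, variances: np.ndarray
) -> np.ndarray:
    """t statistics of the underlying simple regressions, from summaries only."""
    from .moments import genotype_moments

    n = panel.n
    ssx = np.array(
        [
            genotype_moments(s.maf, s.geno_mean, s.geno_var)[1] * (n - 1)
            for s in (panel.snp(sid) for sid in slopes.snp_ids)
        ]
    )
    ssy = variances * (n - 1)
    rss = np.clip(ssy[None, :] - slopes.values**2 * ssx[:, None], 0.0, None)
    se = np.sqrt(rss / (n - 2) / ssx[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, slopes.values / np.where(se > 0, se, 1.0), np.inf)
    return t


def repair_psd(cov: CovarianceMatrix, epsilon: float = 1e-10) -> CovarianceMatrix:
    """Project a symmetric matrix to positive semidefiniteness.

    Eigenvalues below ``epsilon * max(eigenvalue)`` are clipped up to that
    floor, the matrix is reassembled, and the diagonal is rescaled back to
    the input variances.  Already-PSD inputs pass through unchanged.
    """
    vals = cov.values
    eig, vec = np.linalg.eigh(vals)
    floor = epsilon * max(float(eig.max()), 0.0)
    if eig.min() >= 0:
        return CovarianceMatrix(cov.variables, vals.copy())
    if eig.max() <= 0:
        raise PanelError("matrix has no positive eigenvalue; cannot repair")
    logger.warning(
        "covariance not positive semidefinite (min eigenvalue %.3g); clipping", eig.min()
    )
    clipped = np.clip(eig, floor, None)
    out = (vec * clipped) @ vec.T
    out = (out + out.T) / 2.0
    # congruence by a positive diagonal preserves PSD and restores variances
    scale = np.sqrt(np.diag(vals) / np.diag(out))
    out = out * np.outer(scale, scale)
    np.fill_diagonal(out, np.diag(vals))
    out = (out + out.T) / 2.0
    return CovarianceMatrix(cov.variables, out)


def is_psd(cov: CovarianceMatrix, rtol: float = 1e-12) -> bool:
    eig = np.linalg.eigvalsh(cov.values)
    return bool(eig.min() >= -rtol * max(float(eig.max()), 1.0))
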