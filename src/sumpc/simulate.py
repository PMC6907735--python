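"""Synthetic biobank generator, raw-data OLS oracle, and validation report.

The generator emulates a small GWAS cohort: binomial(2, p) genotype
dosages at Beta-distributed allele frequencies (Hardy-Weinberg by
construction), Poisson ages, Bernoulli sexes, and three quantitative
phenotypes linearly driven by the first ``n_causal`` SNPs plus age and
sex, with jointly Gaussian residuals whose covariance is chosen so the
total phenotype correlations average 0.30 (y1,y2), -0.08 (y1,y3) and
0.07 (y2,y3).

``summarize_raw`` turns a simulated cohort into exactly the statistics a
biobank would release; ``ols_oracle`` fits any model directly on the
subject-level data; ``validate`` sweeps replicates and reports the
per-SNP error of every summary-statistic fit against the oracle (mean
across SNPs, and the variance of the per-SNP error within one genome —
the intra-genomic variance — summarized across replicates).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import PanelError, SchemaError, SingularModelError
from . import pheno_cov
from .moments import ModelSpec
from .pca import pc_model_spec
from .regress import FitResult, finalize_fit, fit as summary_fit
from .sumstats_io import (
    AssocRecord,
    CovarianceMatrix,
    SnpInfo,
    SummaryPanel,
    VariableStats,
)

logger = logging.getLogger(__name__)

PHENOTYPES = ("y1", "y2", "y3")
COVARIATES = ("age", "sex")

# Defaults calibrated once so total phenotype covariance hits the target
# correlations (0.30, -0.08, 0.07) with unit variances in expectation;
# E[2p(1-p)] = 0.28796 under Beta(2,8) truncated to [0.01, 0.5].
DEFAULT_SNP_EFFECTS = (
    (0.10, 0.10, 0.10, 0.10, 0.10, 0.10, 0.10, 0.10, 0.10, 0.10),
    (0.08, 0.08, 0.08, 0.08, 0.08, -0.06, -0.06, 0.06, 0.06, 0.06),
    (-0.05, 0.05, -0.05, 0.05, -0.05, 0.05, -0.05, 0.05, -0.05, 0.05),
)
DEFAULT_AGE_EFFECTS = (0.03, 0.02, -0.015)
DEFAULT_SEX_EFFECTS = (0.4, -0.2, 0.3)
DEFAULT_RESIDUAL_COV = (
    (0.886204, 0.276754, -0.0875),
    (0.276754, 0.955602, 0.100288),
    (-0.0875, 0.100288, 0.959051),
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort.

    Desk-scale defaults: 2,000 subjects x 2,000 SNPs x 20 replicates
    (``cluster_scale()`` switches to 100,000 SNPs x 1,000 replicates).
    """

    n_subjects: int = 2000
    n_snps: int = 2000
    n_causal: int = 10
    maf_beta: tuple[float, float] = (2.0, 8.0)
    maf_bounds: tuple[float, float] = (0.01, 0.5)
    age_rate: float = 50.0
    snp_effects: tuple = DEFAULT_SNP_EFFECTS
    age_effects: tuple = DEFAULT_AGE_EFFECTS
    sex_effects: tuple = DEFAULT_SEX_EFFECTS
    residual_cov: tuple = DEFAULT_RESIDUAL_COV
    n_replicates: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        gamma = np.asarray(self.snp_effects, dtype=float)
        if gamma.shape != (len(PHENOTYPES), self.n_causal):
            raise SchemaError(
                f"snp_effects shape {gamma.shape} != (3, n_causal={self.n_causal})"
            )
        if self.n_causal > self.n_snps:
            raise SchemaError("n_causal exceeds n_snps")
        lo, hi = self.maf_bounds
        if not (0.0 < lo < hi <= 0.5):
            raise SchemaError("maf_bounds must satisfy 0 < lo < hi <= 0.5")
        R = np.asarray(self.residual_cov, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R, R.T):
            raise SchemaError("residual_cov must be symmetric 3x3")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise SchemaError("residual_cov must be positive semidefinite")
        if self.n_subjects <= 4:
            raise SchemaError("need more subjects than model parameters")
        if self.age_rate <= 0 or self.n_replicates < 1:
            raise SchemaError("invalid age_rate or n_replicates")

    def cluster_scale(self) -> "SimConfig":
        return replace(self, n_snps=100_000, n_replicates=1000)

    @property
    def expected_maf_variance_term(self) -> float:
        """E[2p(1-p)] under the truncated Beta, by quadrature."""
        from scipy import integrate, stats

        a, b = self.maf_beta
        lo, hi = self.maf_bounds
        z = stats.beta.cdf(hi, a, b) - stats.beta.cdf(lo, a, b)
        val, _ = integrate.quad(
            lambda p: 2 * p * (1 - p) * stats.beta.pdf(p, a, b) / z, lo, hi
        )
        return val

    @property
    def true_phenotype_cov(self) -> np.ndarray:
        """Phenotype covariance implied by the config, in expectation over MAFs."""
        gamma = np.asarray(self.snp_effects, dtype=float)
        systematic = (
            gamma @ gamma.T * self.expected_maf_variance_term
            + np.outer(self.age_effects, self.age_effects) * self.age_rate
            + np.outer(self.sex_effects, self.sex_effects) * 0.25
        )
        return systematic + np.asarray(self.residual_cov, dtype=float)


def snp_id(i: int) -> str:
    return f"snp{i + 1:06d}"


@dataclass
class RawDataset:
    """Subject-level data for one simulated cohort."""

    genotypes: np.ndarray  # (n, M) dosages in {0,1,2}
    snp_ids: tuple[str, ...]
    mafs: np.ndarray  # drawn allele frequencies
    age: np.ndarray
    sex: np.ndarray
    phenotypes: np.ndarray  # (n, 3)
    true_cov: np.ndarray  # phenotype covariance implied by the config
    config: SimConfig

    def column(self, name: str) -> np.ndarray:
        """Any variable or SNP column by name, as float."""
        if name == "age":
            return self.age.astype(float)
        if name == "sex":
            return self.sex.astype(float)
        if name in PHENOTYPES:
            return self.phenotypes[:, PHENOTYPES.index(name)]
        try:
            j = self.snp_ids.index(name)
        except ValueError:
            raise KeyError(f"unknown column {name!r}") from None
        return self.genotypes[:, j].astype(float)


def simulate_dataset(config: SimConfig, rng: np.random.Generator | None = None) -> RawDataset:
    """Draw one cohort; fully reproducible from ``config.seed`` when no
    generator is supplied."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, M = config.n_subjects, config.n_snps
    a, b = config.maf_beta
    lo, hi = config.maf_bounds

    # inverse-CDF truncation keeps the draw count independent of rejection
    from scipy import stats as sps

    u = rng.uniform(sps.beta.cdf(lo, a, b), sps.beta.cdf(hi, a, b), size=M)
    mafs = sps.beta.ppf(u, a, b)

    genotypes = rng.binomial(2, mafs, size=(n, M)).astype(np.int8)
    age = rng.poisson(config.age_rate, size=n)
    sex = rng.integers(0, 2, size=n)

    gamma = np.asarray(config.snp_effects, dtype=float)
    eps = rng.multivariate_normal(
        np.zeros(3), np.asarray(config.residual_cov, dtype=float), size=n,
        method="cholesky",
    )
    phenotypes = (
        genotypes[:, : config.n_causal].astype(float) @ gamma.T
        + np.outer(age, config.age_effects)
        + np.outer(sex, config.sex_effects)
        + eps
    )
    return RawDataset(
        genotypes=genotypes,
        snp_ids=tuple(snp_id(i) for i in range(M)),
        mafs=mafs,
        age=age,
        sex=sex,
        phenotypes=phenotypes,
        true_cov=config.true_phenotype_cov,
        config=config,
    )


def summarize_raw(raw: RawDataset, mode: str = "exact") -> SummaryPanel:
    """The summary-statistic release for a simulated cohort.

    Per (SNP, variable) the closed-form simple regression gives
    slope = cov(g, v)/var(g) and intercept = mean(v) - slope*mean(g);
    descriptives and the variable covariance are sample moments.  In
    ``exact`` mode the panel carries sample genotype moments; in ``hwe``
    mode only the sample allele frequency, leaving downstream fits to the
    Hardy-Weinberg approximation.
    """
    if mode not in ("exact", "hwe"):
        raise SchemaError(f"unknown mode {mode!r}")
    n = raw.config.n_subjects
    names = COVARIATES + PHENOTYPES
    V = np.column_stack([raw.column(v) for v in names])
    v_mean = V.mean(axis=0)
    v_cov = np.cov(V, rowvar=False, ddof=1)

    G = raw.genotypes.astype(float)
    g_mean = G.mean(axis=0)
    g_var = G.var(axis=0, ddof=1)
    poly = g_var > 0
    if not np.all(poly):
        logger.warning("excluding %d monomorphic SNP(s)", int((~poly).sum()))

    Gc = G[:, poly] - g_mean[poly]
    cross = Gc.T @ (V - v_mean) / (n - 1)  # (M_poly, 5) genotype-variable covariances
    slopes = cross / g_var[poly, None]
    intercepts = v_mean[None, :] - slopes * g_mean[poly, None]

    kept = np.flatnonzero(poly)
    variables = [
        VariableStats(v, float(v_mean[i]), float(v_cov[i, i]),
                      "covariate" if v in COVARIATES else "phenotype")
        for i, v in enumerate(names)
    ]
    snps = []
    assoc = []
    for row, j in enumerate(kept):
        sid = raw.snp_ids[j]
        freq = float(g_mean[j] / 2.0)
        if mode == "exact":
            snps.append(SnpInfo(sid, freq, n, float(g_mean[j]), float(g_var[j])))
        else:
            snps.append(SnpInfo(sid, freq, n))
        for i, v in enumerate(names):
            assoc.append(AssocRecord(sid, v, float(slopes[row, i]), float(intercepts[row, i])))

    return SummaryPanel(
        variables=variables,
        cov=CovarianceMatrix(names, v_cov),
        snps=snps,
        assoc=assoc,
    )


def ols_oracle(raw: RawDataset, spec: ModelSpec) -> FitResult:
    """Direct least squares on the subject-level data — the ground truth
    every summary-statistic reconstruction must match."""
    n = raw.config.n_subjects
    cols = [np.ones(n)] + [raw.column(p) for p in spec.predictors]
    X = np.column_stack(cols)
    y = np.zeros(n)
    for v, w in spec.response:
        col = raw.column(v)
        if spec.center_response:
            col = col - col.mean()
        y = y + w * col
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise SingularModelError(f"design is rank deficient ({rank} < {X.shape[1]})")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - X.shape[1]
    if df <= 0:
        raise PanelError("no residual degrees of freedom")
    sigma2 = float(resid @ resid) / df
    inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(sigma2 * np.diag(inv), 0.0, None))
    return finalize_fit(spec.term_names, beta, se, sigma2, df, n)


# ---------------------------------------------------------------------------
# Validation sweep
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Analysis:
    """One response definition swept across all SNPs during validation.

    Either fixed ``weights`` over the phenotypes (a combined response,
    e.g. (1, 0, 0) for plain y1) or a PC ``component`` whose weights are
    derived per replicate from the covariance source.
    """

    name: str
    covariates: tuple[str, ...] = COVARIATES
    weights: tuple[float, ...] | None = None
    component: int | None = None
    scaled: bool = False
    center: bool = False

    def __post_init__(self) -> None:
        if (self.weights is None) == (self.component is None):
            raise SchemaError("exactly one of weights/component must be given")


METRICS = ("slope", "se", "neglog10p")


@dataclass
class ErrorReport:
    """Per-replicate error summaries of summary-statistic fits vs. the oracle.

    ``per_replicate`` has one row per (analysis, replicate) with the mean
    across SNPs of each error metric (summary minus oracle, at the SNP
    term) and the intra-genomic variance (the variance of the per-SNP
    error within that replicate, ddof=1).  ``per_snp`` holds the raw
    per-SNP errors; ``summary`` aggregates across replicates.
    """

    per_replicate: pd.DataFrame
    per_snp: pd.DataFrame
    config: SimConfig
    cov_source: str

    @property
    def summary(self) -> pd.DataFrame:
        rows = []
        for (analysis, metric), grp in self.per_replicate.groupby(
            ["analysis", "metric"], sort=False
        ):
            rows.append(
                {
                    "analysis": analysis,
                    "metric": metric,
                    "mean_error": grp["mean_error"].mean(),
                    "max_abs_mean_error": grp["mean_error"].abs().max(),
                    "mean_intra_genomic_variance": grp["intra_genomic_variance"].mean(),
                    "max_intra_genomic_variance": grp["intra_genomic_variance"].max(),
                }
            )
        return pd.DataFrame(rows)

    def to_files(self, prefix: str | os.PathLike) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.per_replicate.to_csv(f"{prefix}_replicates.tsv", sep="\t", index=False)
        self.summary.to_csv(f"{prefix}_summary.tsv", sep="\t", index=False)
        meta = {
            "cov_source": self.cov_source,
            "n_subjects": self.config.n_subjects,
            "n_snps": self.config.n_snps,
            "n_replicates": self.config.n_replicates,
            "seed": self.config.seed,
        }
        with open(f"{prefix}_meta.json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)


def _analysis_spec(panel: SummaryPanel, analysis: Analysis) -> ModelSpec:
    if analysis.component is not None:
        spec, _ = pc_model_spec(
            panel, PHENOTYPES, analysis.covariates, analysis.component,
            scaled=analysis.scaled,
        )
        return spec
    return ModelSpec(
        response=tuple(zip(PHENOTYPES, analysis.weights)),
        covariates=analysis.covariates,
        center_response=analysis.center,
    )


def fit_errors(
    raw: RawDataset,
    panel: SummaryPanel,
    analysis: Analysis,
    snp_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-SNP error (summary fit minus oracle) of slope, SE and -log10 p
    at the SNP term for one analysis."""
    template = _analysis_spec(panel, analysis)
    ids = tuple(snp_ids) if snp_ids is not None else panel.snp_ids
    if not ids:
        raise PanelError("no SNPs to fit")
    rows = []
    for sid in ids:
        spec = template.with_snp(sid)
        ours = summary_fit(panel, spec)
        ref = ols_oracle(raw, spec)
        i = ours.term(sid)
        rows.append(
            {
                "snp_id": sid,
                "slope": ours.coefficients[i] - ref.coefficients[i],
                "se": ours.standard_errors[i] - ref.standard_errors[i],
                "neglog10p": ours.neglog10_p[i] - ref.neglog10_p[i],
                "oracle_slope": ref.coefficients[i],
                "oracle_se": ref.standard_errors[i],
                "oracle_neglog10p": ref.neglog10_p[i],
            }
        )
    df = pd.DataFrame(rows)
    df.insert(0, "analysis", analysis.name)
    return df


def validate(
    config: SimConfig,
    analyses: Sequence[Analysis],
    cov_source: str = "true",
    mode: str = "exact",
    n_fit_snps: int | None = None,
) -> ErrorReport:
    """Simulate -> summarize -> fit (summary route and oracle) -> aggregate.

    ``cov_source='true'`` uses the released sample covariance;
    ``'estimated'`` replaces it with the slope-correlation estimate over
    the whole panel.  ``n_fit_snps`` caps how many SNPs are fitted (the
    covariance estimate still uses all of them).
    """
    if cov_source not in ("true", "estimated"):
        raise SchemaError(f"unknown cov_source {cov_source!r}")
    if not analyses:
        raise PanelError("no analyses requested")
    if n_fit_snps is not None and n_fit_snps < 1:
        raise PanelError("no SNPs requested")

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    rep_rows = []
    snp_frames = []
    for r, ss in enumerate(seeds):
        raw = simulate_dataset(config, np.random.default_rng(ss))
        panel = summarize_raw(raw, mode=mode)
        if cov_source == "estimated":
            panel = panel.with_cov(pheno_cov.estimate_cov_from_panel(panel))
        ids = panel.snp_ids[:n_fit_snps] if n_fit_snps else panel.snp_ids
        for analysis in analyses:
            errors = fit_errors(raw, panel, analysis, ids)
            errors.insert(1, "replicate", r)
            snp_frames.append(errors)
            for metric in METRICS:
                e = errors[metric].to_numpy()
                rep_rows.append(
                    {
                        "analysis": analysis.name,
                        "metric": metric,
                        "replicate": r,
                        "mean_error": float(e.mean()),
                        "intra_genomic_variance": float(e.var(ddof=1)) if len(e) > 1 else 0.0,
                    }
                )
    return ErrorReport(
        per_replicate=pd.DataFrame(rep_rows),
        per_snp=pd.concat(snp_frames, ignore_index=True),
        config=config,
        cov_source=cov_source,
    )


# ---------------------------------------------------------------------------
# Raw dataset TSV round trip (CLI plumbing)
# ---------------------------------------------------------------------------


def write_raw(raw: RawDataset, directory: str | os.PathLike) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    gdf = pd.DataFrame(raw.genotypes, columns=list(raw.snp_ids))
    gdf.to_csv(d / "genotypes.tsv", sep="\t", index=False)
    pdf = pd.DataFrame(
        {
            "age": raw.age,
            "sex": raw.sex,
            **{v: raw.phenotypes[:, i] for i, v in enumerate(PHENOTYPES)},
        }
    )
    pdf.to_csv(d / "subjects.tsv", sep="\t", index=False, float_format="%.17g")
    pd.DataFrame({"snp_id": raw.snp_ids, "maf": raw.mafs}).to_csv(
        d / "mafs.tsv", sep="\t", index=False, float_format="%.17g"
    )
    cfg = {
        k: (list(map(list, v)) if k in ("snp_effects", "residual_cov") else list(v) if isinstance(v, tuple) else v)
        for k, v in raw.config.__dict__.items()
    }
    with open(d / "config.json", "w", encoding="utf-8") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)


def read_raw(directory: str | os.PathLike) -> RawDataset:
    d = Path(directory)
    with open(d / "config.json", "r", encoding="utf-8") as fh:
        cfg = json.load(fh)
    for k in ("maf_beta", "maf_bounds", "age_effects", "sex_effects"):
        cfg[k] = tuple(cfg[k])
    for k in ("snp_effects", "residual_cov"):
        cfg[k] = tuple(tuple(row) for row in cfg[k])
    config = SimConfig(**cfg)
    gdf = pd.read_csv(d / "genotypes.tsv", sep="\t")
    pdf = pd.read_csv(d / "subjects.tsv", sep="\t", float_precision="round_trip")
    mdf = pd.read_csv(d / "mafs.tsv", sep="\t", float_precision="round_trip")
    return RawDataset(
        genotypes=gdf.to_numpy(dtype=np.int8),
        snp_ids=tuple(gdf.columns),
        mafs=mdf["maf"].to_numpy(),
        age=pdf["age"].to_numpy(),
        sex=pdf["sex"].to_numpy(),
        phenotypes=pdf[list(PHENOTYPES)].to_numpy(),
        true_cov=config.true_phenotype_cov,
        config=config,
    )
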