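"""Domain types and TSV readers/writers for summary-statistic panels.

A *summary panel* is the complete statistical release a biobank would
publish in place of subject-level data: per-variable descriptives, the
variable covariance matrix, per-SNP genotype information, and per-(SNP,
variable) simple-regression coefficients.  Four tab-delimited files carry
the panel:

- ``assoc.tsv``      snp_id, variable, slope, intercept
- ``snps.tsv``       snp_id, maf, n, geno_mean (optional), geno_var (optional)
- ``variables.tsv``  variable, role, mean, variance
- ``cov.tsv``        square covariance matrix, variable names as header and
  first column

Values are written with 17 significant digits so a write/read round trip
is bit-exact for any finite panel.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, IntegrityError, SchemaError

logger = logging.getLogger(__name__)

#: relative tolerance for covariance-matrix symmetry
SYMMETRY_RTOL = 1e-12
#: relative tolerance for cov diagonal vs. released variance agreement
DIAG_RTOL = 1e-8

ROLES = ("phenotype", "covariate")


@dataclass(frozen=True)
class VariableStats:
    """Descriptive statistics for one released variable."""

    name: str
    mean: float
    variance: float
    role: str = "phenotype"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for variable {self.name!r}")
        if not math.isfinite(self.mean) or not math.isfinite(self.variance):
            raise SchemaError(f"non-finite descriptives for variable {self.name!r}")
        if self.variance < 0:
            raise SchemaError(f"negative variance for variable {self.name!r}")


@dataclass(frozen=True)
class SnpInfo:
    """Per-SNP genotype summary.

    ``geno_mean``/``geno_var`` are the sample moments of the additive dosage
    (0/1/2).  When absent they are derivable under Hardy-Weinberg
    equilibrium as 2p and 2p(1-p) from the stored allele frequency.
    """

    snp_id: str
    maf: float
    n: int
    geno_mean: float | None = None
    geno_var: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.maf < 1.0):
            raise SchemaError(f"maf for {self.snp_id!r} must lie in (0,1), got {self.maf}")
        if self.n <= 0:
            raise SchemaError(f"non-positive n for {self.snp_id!r}")
        if self.geno_var is not None and self.geno_var < 0:
            raise SchemaError(f"negative genotype variance for {self.snp_id!r}")


@dataclass(frozen=True)
class AssocRecord:
    """Slope/intercept of one simple regression ``variable ~ SNP dosage``."""

    snp_id: str
    variable: str
    slope: float
    intercept: float | None = None

    def __post_init__(self) -> None:
        bad = not math.isfinite(self.slope) or (
            self.intercept is not None and not math.isfinite(self.intercept)
        )
        if bad:
            raise SchemaError(
                f"non-finite association for ({self.snp_id!r}, {self.variable!r})"
            )


@dataclass
class CovarianceMatrix:
    """Symmetric covariance matrix over an ordered set of variables."""

    variables: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        self.values = np.asarray(self.values, dtype=float)
        m = len(self.variables)
        if self.values.shape != (m, m):
            raise SchemaError(
                f"covariance shape {self.values.shape} does not match "
                f"{m} variable names"
            )
        scale = max(float(np.max(np.abs(self.values))), 1.0)
        if not np.allclose(self.values, self.values.T, rtol=0, atol=SYMMETRY_RTOL * scale):
            raise ConsistencyError("covariance matrix is asymmetric beyond tolerance")
        self._index = {v: i for i, v in enumerate(self.variables)}
        if len(self._index) != m:
            raise IntegrityError("duplicate variable names in covariance matrix")

    def get(self, a: str, b: str) -> float:
        try:
            return float(self.values[self._index[a], self._index[b]])
        except KeyError as exc:
            raise KeyError(f"variable {exc.args[0]!r} not in covariance matrix") from None

    def submatrix(self, names: Sequence[str]) -> "CovarianceMatrix":
        idx = [self._index[v] for v in names]
        return CovarianceMatrix(tuple(names), self.values[np.ix_(idx, idx)])

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CovarianceMatrix)
            and self.variables == other.variables
            and np.array_equal(self.values, other.values)
        )


@dataclass
class SummaryPanel:
    """A validated summary-statistic release.

    Lookup dictionaries are built once so per-SNP model assembly is O(1)
    per statistic.
    """

    variables: list[VariableStats]
    cov: CovarianceMatrix
    snps: list[SnpInfo]
    assoc: list[AssocRecord]
    n: int = 0
    _var_by_name: dict = field(default_factory=dict, repr=False, compare=False, init=False)
    _snp_by_id: dict = field(default_factory=dict, repr=False, compare=False, init=False)
    _assoc_by_key: dict = field(default_factory=dict, repr=False, compare=False, init=False)

    def __post_init__(self) -> None:
        # canonical row order, so construction, write and read all agree
        self.snps = sorted(self.snps, key=lambda s: s.snp_id)
        self.assoc = sorted(self.assoc, key=lambda a: (a.snp_id, a.variable))
        if self.n == 0 and self.snps:
            self.n = min(s.n for s in self.snps)
        self.validate()

    # -- lookups -----------------------------------------------------------
    def variable(self, name: str) -> VariableStats:
        return self._var_by_name[name]

    def snp(self, snp_id: str) -> SnpInfo:
        return self._snp_by_id[snp_id]

    def assoc_record(self, snp_id: str, variable: str) -> AssocRecord:
        return self._assoc_by_key[(snp_id, variable)]

    def has_assoc(self, snp_id: str, variable: str) -> bool:
        return (snp_id, variable) in self._assoc_by_key

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(s.snp_id for s in self.snps)

    def with_cov(self, cov: CovarianceMatrix) -> "SummaryPanel":
        """A copy of the panel with the covariance matrix replaced."""
        return SummaryPanel(
            variables=list(self.variables),
            cov=cov,
            snps=list(self.snps),
            assoc=list(self.assoc),
            n=self.n,
        )

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        self._var_by_name = {}
        for v in self.variables:
            if v.name in self._var_by_name:
                raise IntegrityError(f"duplicate variable {v.name!r}")
            self._var_by_name[v.name] = v

        self._snp_by_id = {}
        n_major = 0
        for s in self.snps:
            if s.snp_id in self._snp_by_id:
                raise IntegrityError(f"duplicate SNP {s.snp_id!r}")
            self._snp_by_id[s.snp_id] = s
            n_major += s.maf > 0.5
        if n_major:
            logger.warning(
                "%d SNP(s) store an allele frequency > 0.5; genotype moments are "
                "computed from the stored allele regardless", n_major
            )

        if self.snps:
            ns = {s.n for s in self.snps}
            if len(ns) > 1:
                logger.warning(
                    "heterogeneous per-SNP sample sizes (%d..%d); model fits use "
                    "the minimum n among their inputs", min(ns), max(ns)
                )
            if self.n <= 0:
                raise IntegrityError("panel n must be positive")

        self._assoc_by_key = {}
        for a in self.assoc:
            key = (a.snp_id, a.variable)
            if key in self._assoc_by_key:
                raise IntegrityError(f"duplicate association record for {key}")
            if a.snp_id not in self._snp_by_id:
                raise IntegrityError(f"association references unknown SNP {a.snp_id!r}")
            if a.variable not in self._var_by_name:
                raise IntegrityError(
                    f"association references unknown variable {a.variable!r}"
                )
            self._assoc_by_key[key] = a

        for name in self.variable_names:
            if name not in self.cov:
                raise IntegrityError(f"variable {name!r} missing from covariance matrix")
        for name in self.cov.variables:
            if name not in self._var_by_name:
                raise IntegrityError(
                    f"covariance matrix names unknown variable {name!r}"
                )
            diag = self.cov.get(name, name)
            var = self._var_by_name[name].variance
            scale = max(abs(var), abs(diag), 1e-300)
            if abs(diag - var) > DIAG_RTOL * scale:
                raise ConsistencyError(
                    f"covariance diagonal for {name!r} ({diag!r}) disagrees with "
                    f"released variance ({var!r})"
                )


def mean_from_intercept(intercept: float, slope: float, geno_mean: float) -> float:
    """Recover a variable mean from a simple-regression line.

    A least-squares line passes through the point of means, so
    ``mean(y) = intercept + slope * mean(g)``.  Used when a release carries
    intercepts but no descriptive table.
    """
    return intercept + slope * geno_mean


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

FILE_NAMES = {
    "assoc": "assoc.tsv",
    "snps": "snps.tsv",
    "variables": "variables.tsv",
    "cov": "cov.tsv",
}


def _fmt(x: float | None) -> str:
    if x is None:
        return ""
    return format(float(x), ".17g")


def _require_columns(df: pd.DataFrame, cols: Iterable[str], fname: str) -> None:
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"{fname}: missing required column {c!r}")


def read_panel(directory: str | os.PathLike) -> SummaryPanel:
    """Read and validate a summary panel from a directory of TSV files."""
    d = Path(directory)
    paths = {k: d / v for k, v in FILE_NAMES.items()}
    for k, p in paths.items():
        if not p.is_file():
            raise SchemaError(f"missing panel file {p}")

    kw = dict(sep="\t", float_precision="round_trip")

    vdf = pd.read_csv(paths["variables"], **kw)
    _require_columns(vdf, ["variable", "role", "mean", "variance"], "variables.tsv")
    variables = [
        VariableStats(str(r.variable), float(r.mean), float(r.variance), str(r.role))
        for r in vdf.itertuples()
    ]

    sdf = pd.read_csv(paths["snps"], **kw)
    _require_columns(sdf, ["snp_id", "maf", "n"], "snps.tsv")
    has_gm = "geno_mean" in sdf.columns
    has_gv = "geno_var" in sdf.columns
    snps = []
    for r in sdf.itertuples():
        gm = float(r.geno_mean) if has_gm and pd.notna(r.geno_mean) else None
        gv = float(r.geno_var) if has_gv and pd.notna(r.geno_var) else None
        snps.append(SnpInfo(str(r.snp_id), float(r.maf), int(r.n), gm, gv))

    adf = pd.read_csv(paths["assoc"], **kw)
    _require_columns(adf, ["snp_id", "variable", "slope"], "assoc.tsv")
    has_int = "intercept" in adf.columns
    assoc = [
        AssocRecord(
            str(r.snp_id),
            str(r.variable),
            float(r.slope),
            float(r.intercept) if has_int and pd.notna(r.intercept) else None,
        )
        for r in adf.itertuples()
    ]

    cdf = pd.read_csv(paths["cov"], index_col=0, **kw)
    cov = CovarianceMatrix(tuple(str(c) for c in cdf.columns), cdf.to_numpy(dtype=float))
    if tuple(str(i) for i in cdf.index) != cov.variables:
        raise SchemaError("cov.tsv row and column names disagree")

    return SummaryPanel(variables=variables, cov=cov, snps=snps, assoc=assoc)


def write_panel(panel: SummaryPanel, directory: str | os.PathLike) -> None:
    """Write a panel as four TSV files with deterministic order and full precision."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    with open(d / FILE_NAMES["variables"], "w", encoding="utf-8") as fh:
        fh.write("variable\trole\tmean\tvariance\n")
        for v in panel.variables:
            fh.write(f"{v.name}\t{v.role}\t{_fmt(v.mean)}\t{_fmt(v.variance)}\n")

    with open(d / FILE_NAMES["snps"], "w", encoding="utf-8") as fh:
        fh.write("snp_id\tmaf\tn\tgeno_mean\tgeno_var\n")
        for s in sorted(panel.snps, key=lambda s: s.snp_id):
            fh.write(
                f"{s.snp_id}\t{_fmt(s.maf)}\t{s.n}\t{_fmt(s.geno_mean)}\t{_fmt(s.geno_var)}\n"
            )

    with open(d / FILE_NAMES["assoc"], "w", encoding="utf-8") as fh:
        fh.write("snp_id\tvariable\tslope\tintercept\n")
        for a in sorted(panel.assoc, key=lambda a: (a.snp_id, a.variable)):
            fh.write(f"{a.snp_id}\t{a.variable}\t{_fmt(a.slope)}\t{_fmt(a.intercept)}\n")

    with open(d / FILE_NAMES["cov"], "w", encoding="utf-8") as fh:
        names = panel.cov.variables
        fh.write("variable\t" + "\t".join(names) + "\n")
        for i, name in enumerate(names):
            row = "\t".join(_fmt(x) for x in panel.cov.values[i])
            fh.write(f"{name}\t{row}\n")


def write_cov(cov: CovarianceMatrix, path: str | os.PathLike) -> None:
    """Write a bare covariance matrix in the cov.tsv dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("variable\t" + "\t".join(cov.variables) + "\n")
        for i, name in enumerate(cov.variables):
            fh.write(name + "\t" + "\t".join(_fmt(x) for x in cov.values[i]) + "\n")


def read_cov(path: str | os.PathLike) -> CovarianceMatrix:
    """Read a bare covariance matrix written by :func:`write_cov`."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    cov = CovarianceMatrix(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float))
    if tuple(str(i) for i in df.index) != cov.variables:
        raise SchemaError(f"{path}: row and column names disagree")
    return cov
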