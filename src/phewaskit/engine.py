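"""Per-study exhaustive SNP × phenotype association scanning.

The protocol: for every race/ethnicity stratum, every SNP and every phenotype,
fit an additive genetic model (dosage = 0, 1 or 2 copies of the coded allele).
Continuous phenotypes get an ordinary least-squares fit on the raw scale and,
when enabled, a second fit after a log(1+y) transform (the "+1" keeps
zero-valued measurements in the analysis).  Binary phenotypes get a logistic
fit.  Categorical phenotypes with k ≥ 3 levels are binned into k "A versus
not A" binary phenotypes, each fit by logistic regression.  Every test is a
complete-case analysis; the coded-allele frequency (CAF) and sample size are
recorded per test.  All p-values are two-sided (t for linear, Wald for
logistic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (AssociationResult, PhenotypeDescriptor, SnpRecord,
                   StudyDataset, results_to_frame)

__all__ = [
    "EngineConfig",
    "FitResult",
    "SkipRecord",
    "code_additive",
    "transform_log1p",
    "bin_categorical",
    "fit_linear",
    "fit_logistic",
    "run_study_phewas",
]


@dataclass(frozen=True)
class EngineConfig:
    """Scan configuration.

    min_n
        Minimum complete cases per test (default 10).  Set to 0 to run every
        testable stratum regardless of size.
    min_minor_allele_count
        Minimum minor-allele count among complete cases (default 5); guards
        logistic fits against near-monomorphic dosage columns.
    include_log1p
        Fit continuous phenotypes on the log(1+y) scale as a second result
        row (default True).
    covariates
        Optional phenotype names used as covariates in every fit; the default
        scan is unadjusted.
    """

    min_n: int = 10
    min_minor_allele_count: int = 5
    include_log1p: bool = True
    covariates: tuple[str, ...] = ()
    max_logistic_iter: int = 100

    def __post_init__(self):
        if self.min_n < 2 and self.min_n != 0:
            raise ValueError("min_n must be 0 or >= 2")


@dataclass(frozen=True)
class FitResult:
    beta: float
    se: float
    p: float
    n: int


@dataclass(frozen=True)
class SkipRecord:
    """One skipped test with its reason (enumerated in the scan's skip log)."""

    study_id: str
    stratum: str
    snp_id: str
    phenotype_name: str
    reason: str


class FitError(ValueError):
    """Raised when a single fit cannot produce a valid result."""


def code_additive(genotype_column: Sequence[float] | pd.Series,
                  snp: SnpRecord) -> tuple[np.ndarray, float]:
    """Validate an additive dosage column and compute its CAF.

    Returns ``(dosage, caf)`` where dosage is a float array with NaN for
    missing and ``caf = mean(dosage)/2`` over non-missing entries (NaN when
    the column is all-missing, in which case the test is skipped upstream).
    """
    dose = np.asarray(genotype_column, dtype=float)
    finite = dose[~np.isnan(dose)]
    if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
        bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))][0]
        raise ValueError(
            f"{snp.snp_id}: dosage value {bad!r} outside {{0,1,2,missing}}")
    caf = float(finite.mean() / 2.0) if finite.size else float("nan")
    return dose, caf


def transform_log1p(values: Sequence[float] | pd.Series) -> np.ndarray:
    """Natural log of (1 + value), preserving missing.

    Values below -1 are undefined and raise; values in (-1, 0) are transformed
    with a warning (the +1 offset exists so that measurements recorded as zero
    stay in the analysis, not to admit negative measurements).
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[~np.isnan(arr)]
    if (finite < -1).any():
        raise ValueError("log1p transform undefined for values < -1")
    if ((finite > -1) & (finite < 0)).any():
        warnings.warn("log1p applied to negative values in (-1, 0)",
                      RuntimeWarning, stacklevel=2)
    out = np.full_like(arr, np.nan)
    ok = ~np.isnan(arr)
    out[ok] = np.log1p(arr[ok])
    return out


def bin_categorical(values: Sequence[float] | pd.Series,
                    descriptor: PhenotypeDescriptor,
                    ) -> list[tuple[str, np.ndarray]]:
    """Bin a k-level categorical phenotype into k "A versus not A" binaries.

    Returns ``[(bin_label, 0/1 vector with NaN preserved), ...]`` for each
    observed level, sorted by level; levels with zero cases are dropped and a
    single observed level yields an empty list (no contrast).  True binary
    phenotypes are analyzed once, not binned into two complements.
    """
    if descriptor.value_kind != "categorical":
        raise ValueError(
            f"{descriptor.name}: bin_categorical requires a categorical "
            f"descriptor, got {descriptor.value_kind}")
    arr = np.asarray(values, dtype=float)
    levels = np.unique(arr[~np.isnan(arr)])
    if levels.size < 2:
        return []
    out = []
    for level in levels:
        binary = np.where(np.isnan(arr), np.nan,
                          (arr == level).astype(float))
        label = f"{descriptor.name}={level:g}"
        out.append((label, binary))
    return out


def _complete_cases(dosage: np.ndarray, y: np.ndarray,
                    covariates: np.ndarray | None):
    mask = ~np.isnan(dosage) & ~np.isnan(y)
    if covariates is not None and covariates.size:
        mask &= ~np.isnan(covariates).any(axis=1)
    return mask


def fit_linear(dosage: Sequence[float], y: Sequence[float],
               covariates: np.ndarray | None = None,
               min_n: int = 10) -> FitResult:
    """OLS slope of y on dosage with intercept; two-sided t-test p-value.

    Without covariates this is the closed-form simple regression; with
    covariates a full OLS fit.  Complete-case analysis; raises FitError for
    constant dosage/outcome or n below ``min_n``.
    """
    d = np.asarray(dosage, dtype=float)
    yv = np.asarray(y, dtype=float)
    mask = _complete_cases(d, yv, covariates)
    n = int(mask.sum())
    if n < max(min_n, 3):
        raise FitError(f"n={n} below minimum")
    d, yv = d[mask], yv[mask]
    if np.ptp(d) == 0:
        raise FitError("constant dosage")
    if np.ptp(yv) == 0:
        raise FitError("constant outcome")
    if covariates is None or covariates.size == 0:
        res = stats.linregress(d, yv)
        if not np.isfinite(res.stderr) or res.stderr <= 0:
            raise FitError("degenerate fit (zero residual variance)")
        return FitResult(float(res.slope), float(res.stderr),
                         float(res.pvalue), n)
    import statsmodels.api as sm
    X = np.column_stack([np.ones(n), d, covariates[mask]])
    fit = sm.OLS(yv, X).fit()
    se = float(fit.bse[1])
    if not np.isfinite(se) or se <= 0:
        raise FitError("degenerate fit")
    return FitResult(float(fit.params[1]), se, float(fit.pvalues[1]), n)


def fit_logistic(dosage: Sequence[float], y_binary: Sequence[float],
                 covariates: np.ndarray | None = None,
                 min_n: int = 10, min_mac: int = 0,
                 maxiter: int = 100) -> FitResult:
    """Maximum-likelihood log-odds per coded-allele copy, with intercept.

    Two-sided Wald p-value on the dosage coefficient.  Results are withheld
    (FitError) on complete/quasi-complete separation, non-convergence within
    ``maxiter`` iterations, one-class outcomes, or a minor-allele count among
    complete cases below ``min_mac``.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    d = np.asarray(dosage, dtype=float)
    yv = np.asarray(y_binary, dtype=float)
    mask = _complete_cases(d, yv, covariates)
    n = int(mask.sum())
    if n < max(min_n, 3):
        raise FitError(f"n={n} below minimum")
    d, yv = d[mask], yv[mask]
    classes = np.unique(yv)
    if classes.size != 2:
        raise FitError("outcome does not take exactly two levels")
    if not np.isin(classes, (0.0, 1.0)).all():
        yv = (yv == classes[1]).astype(float)
    if np.ptp(d) == 0:
        raise FitError("constant dosage")
    mac = min(d.sum(), 2 * n - d.sum())
    if mac < min_mac:
        raise FitError(f"minor allele count {mac:g} below minimum")
    cols = [np.ones(n), d]
    if covariates is not None and covariates.size:
        cols.append(covariates[mask])
    X = np.column_stack(cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(yv, X).fit(disp=0, maxiter=maxiter,
                                      warn_convergence=False)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise FitError(f"separation or singular fit: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise FitError("logistic fit did not converge")
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(beta) or not np.isfinite(se) or se <= 0 or se > 1e3:
        raise FitError("quasi-complete separation (unbounded estimate)")
    return FitResult(beta, se, float(fit.pvalues[1]), n)


def _caf_and_n(dosage: np.ndarray, mask: np.ndarray) -> float:
    d = dosage[mask]
    return float(d.mean() / 2.0)


def run_study_phewas(dataset: StudyDataset, config: EngineConfig | None = None,
                     ) -> tuple[pd.DataFrame, list[SkipRecord]]:
    """Run the full scan for one study: every stratum × SNP × phenotype.

    Returns the standardized result frame (one row per test) and a skip log.
    Output order is deterministic: stratum, SNP (registry order), phenotype
    (panel order), transform (raw before log1p), categorical bins by level.
    Continuous phenotypes emit two rows (raw + log1p) when enabled, binary
    one, k-level categorical k (one per bin); tests failing the minimum-n,
    minor-allele-count, monomorphism or separation gates are skipped and
    logged, not errors.
    """
    config = config or EngineConfig()
    results: list[AssociationResult] = []
    skips: list[SkipRecord] = []
    study = dataset.study_id

    cov_arr_full = None
    if config.covariates:
        missing = [c for c in config.covariates
                   if c not in dataset.phenotypes.columns]
        if missing:
            raise ValueError(f"covariate(s) not in phenotype panel: {missing}")
        cov_arr_full = dataset.phenotypes[list(config.covariates)].to_numpy(
            dtype=float)

    strata = dataset.strata.to_numpy()
    pheno_mat = dataset.phenotypes.to_numpy(dtype=float) \
        if dataset.phenotypes.shape[1] else np.empty((len(dataset.subjects), 0))
    pheno_names = list(dataset.phenotypes.columns)
    dose_mat = dataset.dosages.to_numpy(dtype=float) \
        if dataset.dosages.shape[1] else np.empty((len(dataset.subjects), 0))

    for stratum in dataset.stratum_labels():
        srows = strata == stratum
        covs = cov_arr_full[srows] if cov_arr_full is not None else None
        for j, snp in enumerate(dataset.snps):
            dose, caf_all = code_additive(dose_mat[srows, j], snp)
            finite = dose[~np.isnan(dose)]
            if finite.size == 0:
                skips.append(SkipRecord(study, stratum, snp.snp_id, "*",
                                        "all genotypes missing"))
                continue
            if np.ptp(finite) == 0:
                skips.append(SkipRecord(study, stratum, snp.snp_id, "*",
                                        "monomorphic in stratum"))
                continue
            for k, name in enumerate(pheno_names):
                if name in config.covariates:
                    continue
                desc = dataset.dictionary[name]
                yv = pheno_mat[srows, k]
                _scan_one(results, skips, study, stratum, snp, dose, yv,
                          desc, covs, config)

    frame = results_to_frame(results)
    return frame, skips


def _emit(results, study, stratum, snp, name, transform, model, fit,
          dose, mask):
    caf = _caf_and_n(dose, mask)
    results.append(AssociationResult(
        study_id=study, stratum=stratum, snp_id=snp.snp_id,
        coded_allele=snp.coded_allele, caf=caf, phenotype_name=name,
        transform=transform, model=model, beta=fit.beta, se=fit.se, p=fit.p,
        n=fit.n))


def _scan_one(results, skips, study, stratum, snp, dose, yv, desc, covs,
              config: EngineConfig) -> None:
    name = desc.name

    def skip(reason, label=name):
        skips.append(SkipRecord(study, stratum, snp.snp_id, label, reason))

    if desc.value_kind == "continuous":
        mask = _complete_cases(dose, yv, covs)
        try:
            fit = fit_linear(dose, yv, covs, min_n=config.min_n)
            _emit(results, study, stratum, snp, name, "none", "linear",
                  fit, dose, mask)
        except FitError as exc:
            skip(f"linear: {exc}")
        if config.include_log1p:
            try:
                ty = transform_log1p(yv)
            except ValueError as exc:
                skip(f"log1p: {exc}")
                return
            try:
                fit = fit_linear(dose, ty, covs, min_n=config.min_n)
                _emit(results, study, stratum, snp, name, "log1p", "linear",
                      fit, dose, mask)
            except FitError as exc:
                skip(f"log1p linear: {exc}")
    elif desc.value_kind == "binary":
        mask = _complete_cases(dose, yv, covs)
        try:
            fit = fit_logistic(dose, yv, covs, min_n=config.min_n,
                               min_mac=config.min_minor_allele_count,
                               maxiter=config.max_logistic_iter)
            _emit(results, study, stratum, snp, name, "none", "logistic",
                  fit, dose, mask)
        except FitError as exc:
            skip(f"logistic: {exc}")
    elif desc.value_kind == "categorical":
        bins = bin_categorical(yv, desc)
        if not bins:
            skip("categorical: fewer than two observed levels")
            return
        for label, binary in bins:
            mask = _complete_cases(dose, binary, covs)
            try:
                fit = fit_logistic(dose, binary, covs, min_n=config.min_n,
                                   min_mac=config.min_minor_allele_count,
                                   maxiter=config.max_logistic_iter)
                _emit(results, study, stratum, snp, label, "none", "logistic",
                      fit, dose, mask)
            except FitError as exc:
                skip(f"logistic bin: {exc}", label)
    else:  # pragma: no cover - descriptors validate value_kind
        raise ValueError(f"unknown value_kind {desc.value_kind!r}")
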