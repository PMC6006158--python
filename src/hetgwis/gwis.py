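"""Two-phase genome-wide interaction scan.

Phase one (filtering) screens SNPs (minor-allele frequency, exact HWE
p-value, reported not filtered), adjusts for ancestry via principal
components of the genetic relationship matrix, and computes per SNP the
summed stratified likelihood-ratio statistic: a 2-DF LRT for SNP and
SNP-by-pack-years in ever smokers plus a 1-DF LRT for SNP in never
smokers, referred to chi-square(3).  A pooled homoscedastic 3-DF LRT is
computed alongside as the comparison arm.  Phase two (testing) refits
the top-ranked SNPs in a pooled model with group-specific covariance and
reports per-coefficient Wald tests plus the overall F test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from ._exceptions import (
    CollinearityError,
    DesignError,
    FitError,
    OptimizationQualityError,
    PCAError,
    ScreeningError,
    TestError,
)
from .io_config import GenotypeMatrix, PhenotypeTable, RunConfig
from .lmmcore import (
    DesignBundle,
    FitResult,
    ModelSpec,
    TestResult,
    build_design,
    fit_ml,
    lrt,
    status_dummy_levels,
    wald_joint,
    wald_term,
)

logger = logging.getLogger("hetgwis")

GWIS_COLUMNS = ("snp_id", "maf", "hwe_p", "stat_3df", "p_3df", "p_homo", "converged")


# ---------------------------------------------------------------------------
# screening statistics
# ---------------------------------------------------------------------------


def compute_maf(dosages: np.ndarray) -> float:
    """Folded minor-allele frequency of one dosage vector (missing excluded)."""
    d = np.asarray(dosages, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ScreeningError("all dosages missing")
    f = d.sum() / (2.0 * d.size)
    return float(min(f, 1.0 - f))


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """(hom-major, het, hom-minor) counts treating dosage as minor-allele count."""
    d = np.asarray(dosages, dtype=float)
    d = d[np.isfinite(d)]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Given the allele counts, sums the conditional probabilities of every
    heterozygote count whose probability does not exceed that of the
    observed count.  Exact over the full enumeration; suitable for
    arbitrary counts.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ScreeningError("negative genotype counts")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ScreeningError("empty genotype counts")
    rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_r = (rare - hets) // 2
    hom_c = n - hom_r - hets
    logp = (hets * math.log(2.0)
            + gammaln(n + 1) - gammaln(hom_r + 1) - gammaln(hets + 1) - gammaln(hom_c + 1))
    logp = logp - logsumexp(logp)
    obs = np.flatnonzero(hets == n_Aa)
    if obs.size == 0:  # impossible configuration given allele parity; defensive
        raise ScreeningError("observed heterozygote count inconsistent with allele counts")
    p_obs = logp[obs[0]]
    mask = logp <= p_obs + 1e-12
    return float(min(1.0, np.exp(logsumexp(logp[mask]))))


# ---------------------------------------------------------------------------
# GRM principal components
# ---------------------------------------------------------------------------


@dataclass
class PCResult:
    """Ancestry principal components of the genetic relationship matrix."""

    sample_ids: list[str]
    scores: np.ndarray            # (n_samples, n_pcs), columns orthogonal
    eigenvalues: np.ndarray       # non-increasing
    variance_explained: np.ndarray

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"pc{k + 1}" for k in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)


def grm_pca(genotypes: GenotypeMatrix, n_pcs: int) -> PCResult:
    """Eigendecompose the GRM built from standardized dosages.

    Each SNP column is centered at twice its allele frequency and scaled
    by sqrt(2 f (1 - f)); missing calls are mean-imputed before
    standardization.  Scores are eigenvectors scaled by the square root
    of their eigenvalues.
    """
    X = genotypes.dosages.astype(float).copy()
    n = X.shape[0]
    if n < n_pcs + 1:
        raise PCAError(f"need at least n_pcs+1={n_pcs + 1} samples, have {n}")
    f = np.nanmean(X, axis=0) / 2.0
    poly = (f > 0) & (f < 1)
    if not poly.any():
        raise PCAError("no polymorphic SNPs")
    X = X[:, poly]
    f = f[poly]
    mask = np.isnan(X)
    if mask.any():
        X[mask] = np.broadcast_to(2.0 * f, X.shape)[mask]
    Z = (X - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))
    M = Z.shape[1]
    grm = (Z @ Z.T) / M
    vals, vecs = np.linalg.eigh(grm)
    order = np.argsort(vals)[::-1][:n_pcs]
    vals_top = np.clip(vals[order], 0.0, None)
    scores = vecs[:, order] * np.sqrt(vals_top)[None, :]
    ve = vals_top / np.trace(grm)
    return PCResult(list(genotypes.sample_ids), scores, vals_top, ve)


# ---------------------------------------------------------------------------
# model-spec builders (the scan's fixed-effect lists)
# ---------------------------------------------------------------------------


def _pc_terms(n_pcs: int) -> tuple[str, ...]:
    return tuple(f"pc{k + 1}" for k in range(n_pcs))


def filtering_spec(stratum: str, n_pcs: int = 10, max_visits: int = 3,
                   with_snp: bool = True,
                   covariance: str = "unstructured_marginal") -> ModelSpec:
    """Stratified filtering-step model for one smoking stratum.

    Ever smokers carry pack-years, SNP and SNP-by-pack-years; never
    smokers carry the SNP main effect only.
    """
    if stratum == "ever":
        terms = ("intercept", "age", "sex", "bmi", "height", "time",
                 "pack_years", "sex:age") + _pc_terms(n_pcs)
        snp_terms = ("snp", "snp:pack_years") if with_snp else ()
    elif stratum == "never":
        terms = ("intercept", "age", "sex", "bmi", "height", "time",
                 "sex:age") + _pc_terms(n_pcs)
        snp_terms = ("snp",) if with_snp else ()
    else:
        raise DesignError(f"filtering stratum must be 'ever' or 'never', got {stratum!r}")
    return ModelSpec(fixed_terms=terms + snp_terms, smoking_coding="two_level",
                     covariance=covariance, covariance_groups="shared",
                     max_visits=max_visits)


def pooled_spec(model: str, coding: str = "two_level", n_pcs: int = 10,
                max_visits: int = 3, with_snp: bool = True,
                covariance: str = "unstructured_marginal",
                drop_time_terms: bool = False) -> ModelSpec:
    """Pooled model for the homoscedastic comparator or the testing step.

    ``model="homoscedastic"`` shares one covariance across strata and
    uses a common covariate slope set; ``model="heteroscedastic"`` adds
    the status-specific covariate slopes and a covariance per stratum.
    SNP terms, when present, always come last so designs extend an
    SNP-free base.
    """
    if model == "homoscedastic":
        terms = ["intercept", "age", "sex", "bmi", "height", "time",
                 "pack_years", "sex:age", "status", "sex:status"]
        groups = "shared"
    elif model == "heteroscedastic":
        terms = ["intercept", "age", "sex", "bmi", "height", "time",
                 "pack_years", "sex:age", "status", "age:status",
                 "sex:status", "height:status", "time:status"]
        groups = "by_status"
    else:
        raise DesignError(f"pooled model must be 'homoscedastic' or 'heteroscedastic'")
    if drop_time_terms:
        terms = [t for t in terms if t not in ("time", "time:status")]
    terms += list(_pc_terms(n_pcs))
    if n_pcs >= 1:
        terms.append("pc1:status")
    if with_snp:
        terms += ["snp", "snp:status", "snp:pack_years"]
    return ModelSpec(fixed_terms=tuple(terms), smoking_coding=coding,
                     covariance=covariance, covariance_groups=groups,
                     max_visits=max_visits)


SNP_TERMS_EVER = ("snp", "snp:pack_years")
SNP_TERMS_NEVER = ("snp",)
SNP_TERMS_POOLED = ("snp", "snp:status", "snp:pack_years")


# ---------------------------------------------------------------------------
# per-SNP tests
# ---------------------------------------------------------------------------


@dataclass
class _Context:
    """Reduced (SNP-free) design and fit, reused across a scan."""

    bundle: DesignBundle
    reduced_fit: FitResult


def _make_context(records: PhenotypeTable, spec_no_snp: ModelSpec,
                  pcs: pd.DataFrame | None) -> _Context:
    bundle = build_design(records, spec_no_snp, pcs=pcs)
    fit = fit_ml(spec_no_snp, bundle)
    if not fit.converged:
        fit = fit_ml(spec_no_snp, bundle, init=fit)
    if not fit.converged:
        raise FitError("reduced (SNP-free) model did not converge")
    return _Context(bundle, fit)


def _fit_full(ctx: _Context, snp_map, terms) -> FitResult:
    full_bundle = ctx.bundle.with_snp(snp_map, terms)
    fit = fit_ml(full_bundle.spec, full_bundle, init=ctx.reduced_fit.theta)
    if fit.converged and fit.loglik < ctx.reduced_fit.loglik - 1e-6:
        # warm start should make this impossible; refit cold as a fallback
        fit = fit_ml(full_bundle.spec, full_bundle)
    return fit


def three_df_test(snp: pd.Series, records: PhenotypeTable,
                  pcs: pd.DataFrame | None = None, *,
                  max_visits: int | None = None,
                  covariance: str = "unstructured_marginal",
                  contexts: "dict | None" = None):
    """Summed stratified LRT: 2 DF in ever smokers + 1 DF in never smokers.

    Returns ``(TestResult, fits)`` with the chi-square(3) p-value and the
    four stratum fits.  ``contexts`` lets a scan reuse the SNP-free
    reduced fits; standalone calls build them on the fly.
    """
    smoking = records.smoking_of()
    n_never = int((smoking == "never").sum())
    n_ever = int(smoking.isin(("former", "current")).sum())
    if n_never == 0 or n_ever == 0:
        raise TestError("empty smoking stratum; use the pooled test instead")
    mv = max_visits or records.max_visits
    if contexts is None:
        contexts = {
            "ever": _make_context(records.stratum("ever"),
                                  filtering_spec("ever", _infer_n_pcs(pcs), mv, with_snp=False,
                                                 covariance=covariance), pcs),
            "never": _make_context(records.stratum("never"),
                                   filtering_spec("never", _infer_n_pcs(pcs), mv, with_snp=False,
                                                  covariance=covariance), pcs),
        }
    fits = {}
    parts = {}
    for stratum, terms, df in (("ever", SNP_TERMS_EVER, 2), ("never", SNP_TERMS_NEVER, 1)):
        ctx = contexts[stratum]
        full = _fit_full(ctx, snp, terms)
        fits[f"{stratum}_full"] = full
        fits[f"{stratum}_reduced"] = ctx.reduced_fit
        parts[stratum] = lrt(full, ctx.reduced_fit, df)
    stat = parts["ever"].statistic + parts["never"].statistic
    p = float(stats.chi2.sf(stat, 3)) if stat > 0 else 1.0
    return TestResult(statistic=stat, df=3, p=p, kind="LRT"), fits


def homoscedastic_test(snp: pd.Series, records: PhenotypeTable,
                       pcs: pd.DataFrame | None = None, *,
                       max_visits: int | None = None,
                       covariance: str = "unstructured_marginal",
                       context: "_Context | None" = None) -> TestResult:
    """Pooled 3-DF LRT under a shared covariance (the comparison arm)."""
    mv = max_visits or records.max_visits
    if context is None:
        spec0 = pooled_spec("homoscedastic", n_pcs=_infer_n_pcs(pcs), max_visits=mv,
                            with_snp=False, covariance=covariance)
        context = _make_context(records, spec0, pcs)
    full = _fit_full(context, snp, SNP_TERMS_POOLED)
    return lrt(full, context.reduced_fit, 3)


@dataclass
class PooledTestOutcome:
    """Testing-step output for one SNP: fit, per-term and overall tests."""

    fit: FitResult
    per_term: dict
    overall: TestResult


def pooled_heteroscedastic_test(snp: pd.Series, records: PhenotypeTable,
                                pcs: pd.DataFrame | None = None, *,
                                coding: str = "two_level",
                                max_visits: int | None = None,
                                covariance: str = "unstructured_marginal",
                                context: "_Context | None" = None) -> PooledTestOutcome:
    """Pooled heteroscedastic fit with Wald tests of the SNP terms.

    Reports a two-sided Wald test per SNP coefficient (main effect, one
    per status dummy, pack-years interaction) and the joint F test of all
    of them ("overall effects").
    """
    smoking = records.smoking_of()
    if coding in ("two_level", "three_level") and (smoking == "never").sum() == 0:
        raise DesignError(f"coding {coding!r} needs never smokers as reference; use smokers_only")
    mv = max_visits or records.max_visits
    if context is None:
        spec0 = pooled_spec("heteroscedastic", coding=coding, n_pcs=_infer_n_pcs(pcs),
                            max_visits=mv, with_snp=False, covariance=covariance)
        context = _make_context(records, spec0, pcs)
    fit = _fit_full(context, snp, SNP_TERMS_POOLED)
    snp_cols = ["snp"] + [f"snp:status[{lv}]" for lv in status_dummy_levels(coding)] \
        + ["snp:pack_years"]
    per_term = {c: wald_term(fit, c) for c in snp_cols}
    overall = wald_joint(fit, snp_cols)
    return PooledTestOutcome(fit=fit, per_term=per_term, overall=overall)


def _infer_n_pcs(pcs: pd.DataFrame | None) -> int:
    if pcs is None:
        return 0
    if isinstance(pcs, PCResult):
        return pcs.scores.shape[1]
    return sum(1 for c in pcs.columns if c.startswith("pc"))


def significance_threshold(alpha: float, n_tests: int) -> float:
    """Bonferroni-adjusted per-test significance level."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------


@dataclass
class GwisResult:
    filter_table: pd.DataFrame
    testing_table: pd.DataFrame
    threshold: float
    pcs: PCResult | None
    n_snps_tested: int
    n_nonconverged: int


def run_gwis(genotypes: GenotypeMatrix, records: PhenotypeTable,
             config: RunConfig, pcs: PCResult | None = None) -> GwisResult:
    """Filtering scan plus testing step over the top-ranked SNPs.

    Monomorphic SNPs are excluded up front (the filter table holds one
    row per polymorphic SNP); HWE p-values are reported but never used to
    exclude.  SNPs whose fits fail appear with ``converged=False`` and do
    not enter the ranking.  Subjects missing a SNP's dosage are dropped
    for that SNP only (complete-case per SNP).
    """
    if pcs is None and config.n_pcs > 0:
        pcs = grm_pca(genotypes, config.n_pcs)
    pcs_df = pcs.scores_frame() if pcs is not None else None
    mv = config.max_visits

    common = [s for s in genotypes.sample_ids if s in set(records.subjects)]
    if not common:
        raise DesignError("no overlap between genotyped samples and phenotype subjects")
    records = records.subset_subjects(common)

    cov = config.covariance
    contexts = {
        "ever": _make_context(records.stratum("ever"),
                              filtering_spec("ever", config.n_pcs, mv, with_snp=False,
                                             covariance=cov), pcs_df),
        "never": _make_context(records.stratum("never"),
                               filtering_spec("never", config.n_pcs, mv, with_snp=False,
                                              covariance=cov), pcs_df),
        "homo": _make_context(records,
                              pooled_spec("homoscedastic", n_pcs=config.n_pcs, max_visits=mv,
                                          with_snp=False, covariance=cov), pcs_df),
    }

    rows = []
    n_nonconv = 0
    for j, snp_id in enumerate(genotypes.snp_ids):
        if (j + 1) % 100 == 0:
            logger.info("gwis: %d/%d SNPs processed", j + 1, genotypes.n_snps)
        dos = genotypes.dosage_series(snp_id).reindex(common)
        try:
            maf = compute_maf(dos.to_numpy())
        except ScreeningError:
            continue
        if maf == 0.0:
            continue
        if config.maf_min is not None and maf < config.maf_min:
            continue
        if config.max_missing is not None and float(dos.isna().mean()) > config.max_missing:
            continue
        hwe_p = hwe_exact_test(*genotype_counts(dos.to_numpy()))
        try:
            if dos.isna().any():
                kept = records.subset_subjects(dos.dropna().index)
                test3, _ = three_df_test(dos.dropna(), kept, pcs_df, max_visits=mv,
                                         covariance=cov)
                p_homo = homoscedastic_test(dos.dropna(), kept, pcs_df, max_visits=mv,
                                            covariance=cov).p
            else:
                test3, _ = three_df_test(dos, records, pcs_df, max_visits=mv,
                                         contexts=contexts)
                p_homo = homoscedastic_test(dos, records, pcs_df, max_visits=mv,
                                            context=contexts["homo"]).p
            rows.append((snp_id, maf, hwe_p, test3.statistic, test3.p, p_homo, True))
        except (FitError, CollinearityError, TestError, OptimizationQualityError):
            n_nonconv += 1
            rows.append((snp_id, maf, hwe_p, np.nan, np.nan, np.nan, False))

    filter_table = pd.DataFrame(rows, columns=list(GWIS_COLUMNS))
    ranked = filter_table[filter_table["converged"]].sort_values(
        ["p_3df", "stat_3df", "snp_id"], ascending=[True, False, True], kind="mergesort")
    top = ranked.head(config.filter_top_k)["snp_id"].tolist()

    het_ctx = _make_context(records,
                            pooled_spec("heteroscedastic", n_pcs=config.n_pcs,
                                        max_visits=mv, with_snp=False,
                                        covariance=cov), pcs_df)
    trows = []
    for snp_id in top:
        dos = genotypes.dosage_series(snp_id).reindex(common)
        try:
            if dos.isna().any():
                kept = records.subset_subjects(dos.dropna().index)
                out = pooled_heteroscedastic_test(dos.dropna(), kept, pcs_df, max_visits=mv,
                                                  covariance=cov)
            else:
                out = pooled_heteroscedastic_test(dos, records, pcs_df, max_visits=mv,
                                                  context=het_ctx)
        except (FitError, CollinearityError, TestError, OptimizationQualityError):
            trows.append({"snp_id": snp_id, "converged": False})
            continue
        row = {"snp_id": snp_id, "converged": True,
               "overall_p": out.overall.p, "overall_F": out.overall.statistic}
        for name, tr in out.per_term.items():
            row[f"beta[{name}]"] = out.fit.coef(name)
            row[f"se[{name}]"] = out.fit.coef_se(name)
            row[f"p[{name}]"] = tr.p
        trows.append(row)
    testing_table = pd.DataFrame(trows)

    threshold = significance_threshold(config.alpha, max(len(filter_table), 1))
    return GwisResult(filter_table=filter_table, testing_table=testing_table,
                      threshold=threshold, pcs=pcs,
                      n_snps_tested=len(filter_table), n_nonconverged=n_nonconv)
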