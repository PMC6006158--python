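"""Cohort-specific model selection and direction-informed replication.

Model selection fits a configurable grid of SNP-free candidate models
(smoking coding x covariance structure x shared-vs-per-group covariance)
and picks the minimum-AIC candidate; because no SNP column ever enters
this stage, it cannot bias the subsequent SNP inference.  Replication
then refits the discovery SNPs under the selected specification and
reports one-tailed Wald p-values in the discovery direction (two-tailed
where no direction transfers, e.g. smokers-only cohorts whose
never-referenced discovery coefficients have no analogue).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import (
    CollinearityError,
    ContractError,
    DesignError,
    FitError,
    SelectionError,
    TestError,
)
from .io_config import GenotypeMatrix, PhenotypeTable
from .lmmcore import (
    FitResult,
    ModelSpec,
    TestResult,
    build_design,
    fit_ml,
    status_dummy_levels,
    wald_joint,
    wald_term,
)
from .gwis import (
    SNP_TERMS_POOLED,
    _make_context,
    pooled_spec,
)


@dataclass
class CandidateModelSet:
    """Admissible SNP-free candidates with their fitted AICs."""

    candidates: list[ModelSpec]
    aics: list[float] = field(default_factory=list)
    converged: list[bool] = field(default_factory=list)
    selected: int | None = None

    def __post_init__(self) -> None:
        for spec in self.candidates:
            if spec.has_snp_terms:
                raise ContractError("model-selection candidates must not contain SNP terms")

    def table(self) -> pd.DataFrame:
        rows = []
        for i, spec in enumerate(self.candidates):
            rows.append({
                "coding": spec.smoking_coding,
                "covariance": spec.covariance,
                "groups": spec.covariance_groups,
                "aic": self.aics[i] if self.aics else np.nan,
                "converged": self.converged[i] if self.converged else None,
                "selected": (i == self.selected),
            })
        return pd.DataFrame(rows)


def admissible_codings(records: PhenotypeTable) -> tuple[str, ...]:
    """Smoking codings compatible with the cohort's observed strata."""
    present = set(records.df["smoking"])
    if "never" in present:
        codings = ["two_level"]
        if {"former", "current"} <= present:
            codings.append("three_level")
        return tuple(codings)
    if {"former", "current"} <= present:
        return ("smokers_only",)
    raise DesignError("cohort has a single smoking stratum; no coding is admissible")


def candidate_grid(records: PhenotypeTable, n_pcs: int = 0,
                   codings: tuple[str, ...] | None = None,
                   structures: tuple[str, ...] = ("independence", "random_intercept",
                                                  "unstructured_marginal"),
                   group_choices: tuple[str, ...] = ("shared", "by_status")) -> CandidateModelSet:
    """Default candidate set spanning codings, structures and grouping."""
    if codings is None:
        codings = admissible_codings(records)
    mv = records.max_visits
    cross_sectional = mv == 1 or (records.df["time"] == 0).all()
    cands = []
    for coding in codings:
        for structure in structures:
            for grp in group_choices:
                spec = pooled_spec("heteroscedastic", coding=coding, n_pcs=n_pcs,
                                   max_visits=mv, with_snp=False, covariance=structure,
                                   drop_time_terms=cross_sectional)
                if grp == "shared":
                    spec = ModelSpec(fixed_terms=spec.fixed_terms, smoking_coding=coding,
                                     covariance=structure, covariance_groups="shared",
                                     max_visits=mv)
                cands.append(spec)
    return CandidateModelSet(candidates=cands)


def select_model(records: PhenotypeTable,
                 candidates: CandidateModelSet | None = None,
                 pcs: pd.DataFrame | None = None,
                 n_pcs: int = 0) -> tuple[ModelSpec, pd.DataFrame]:
    """Fit every admissible SNP-free candidate and return the AIC winner.

    Ties are broken toward fewer parameters, then list order.  Returns
    the selected spec together with the full AIC table for reporting.
    """
    if candidates is None:
        candidates = candidate_grid(records, n_pcs=n_pcs)
    aics, conv, ks = [], [], []
    for spec in candidates.candidates:
        try:
            bundle = build_design(records, spec, pcs=pcs)
            fit = fit_ml(spec, bundle)
            aics.append(fit.aic if fit.converged else np.inf)
            conv.append(bool(fit.converged))
            ks.append(fit.k)
        except (FitError, CollinearityError, DesignError):
            aics.append(np.inf)
            conv.append(False)
            ks.append(np.inf)
    if not any(conv):
        raise SelectionError("no candidate model converged")
    order = sorted(range(len(aics)), key=lambda i: (round(aics[i], 6), ks[i], i))
    candidates.aics = aics
    candidates.converged = conv
    candidates.selected = order[0]
    return candidates.candidates[order[0]], candidates.table()


def one_tailed_p(fit: FitResult, term: str, expected_sign: str) -> TestResult:
    """Directional Wald test with the alternative fixed by the discovery sign."""
    if expected_sign not in ("+", "-"):
        raise TestError(f"expected_sign must be '+' or '-', got {expected_sign!r}")
    b = fit.coef(term)
    se = fit.coef_se(term)
    if se <= 0:
        raise TestError(f"zero standard error for term {term!r}")
    z = b / se
    p = float(stats.norm.sf(z)) if expected_sign == "+" else float(stats.norm.cdf(z))
    return TestResult(statistic=z * z, df=1, p=p, kind="one_tailed_Wald")


@dataclass
class ReplicationRow:
    snp_id: str
    cohort: str
    present: bool
    converged: bool = False
    betas: dict = field(default_factory=dict)
    ses: dict = field(default_factory=dict)
    pvalues: dict = field(default_factory=dict)
    overall_p: float = np.nan
    tail_direction: dict = field(default_factory=dict)

    def to_flat(self) -> dict:
        row = {"snp_id": self.snp_id, "cohort": self.cohort,
               "present": self.present, "converged": self.converged,
               "overall_p": self.overall_p}
        for name in self.betas:
            row[f"beta[{name}]"] = self.betas[name]
            row[f"se[{name}]"] = self.ses[name]
            row[f"p[{name}]"] = self.pvalues[name]
            row[f"tail[{name}]"] = self.tail_direction.get(name, "two")
        return row


def replicate(snps: list[str], genotypes: GenotypeMatrix, records: PhenotypeTable,
              discovery_directions: dict, selected: ModelSpec,
              pcs: pd.DataFrame | None = None,
              cohort: str = "replication") -> list[ReplicationRow]:
    """Refit discovery SNPs under the cohort's selected model.

    ``discovery_directions`` maps each SNP id to ``{term: "+"|"-"}`` for
    the terms whose discovery direction transfers; terms without an
    entry, and every term when the cohort uses the smokers-only coding,
    are tested two-tailed.  SNPs absent from the cohort's genotypes are
    reported as missing rows rather than raised.
    """
    base = selected.without_snp_terms()
    ctx = _make_context(records, base, pcs)
    two_tailed_only = selected.smoking_coding == "smokers_only"
    snp_cols_for = ["snp"] + [f"snp:status[{lv}]" for lv in
                              status_dummy_levels(selected.smoking_coding)] + ["snp:pack_years"]
    rows = []
    for snp_id in snps:
        if snp_id not in genotypes.snp_ids:
            rows.append(ReplicationRow(snp_id=snp_id, cohort=cohort, present=False))
            continue
        dos = genotypes.dosage_series(snp_id)
        dos = dos.reindex(records.subjects).dropna()
        kept = records.subset_subjects(dos.index) if len(dos) < records.n_subjects else records
        try:
            if kept is records:
                bundle = ctx.bundle.with_snp(dos, SNP_TERMS_POOLED)
                fit = fit_ml(bundle.spec, bundle, init=ctx.reduced_fit.theta)
            else:
                bundle = build_design(kept, base, pcs=pcs).with_snp(dos, SNP_TERMS_POOLED)
                fit = fit_ml(bundle.spec, bundle)
        except (FitError, CollinearityError) as exc:
            rows.append(ReplicationRow(snp_id=snp_id, cohort=cohort, present=True,
                                       converged=False))
            continue
        dirs = discovery_directions.get(snp_id, {})
        row = ReplicationRow(snp_id=snp_id, cohort=cohort, present=True,
                             converged=fit.converged)
        for name in snp_cols_for:
            row.betas[name] = fit.coef(name)
            row.ses[name] = fit.coef_se(name)
            sign = None if two_tailed_only else dirs.get(name)
            if sign in ("+", "-"):
                row.pvalues[name] = one_tailed_p(fit, name, sign).p
                row.tail_direction[name] = sign
            else:
                row.pvalues[name] = wald_term(fit, name).p
                row.tail_direction[name] = "two"
        row.overall_p = wald_joint(fit, snp_cols_for).p
        rows.append(row)
    return rows


def replication_table(rows: list[ReplicationRow]) -> pd.DataFrame:
    return pd.DataFrame([r.to_flat() for r in rows])
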