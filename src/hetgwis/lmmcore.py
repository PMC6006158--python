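"""Maximum-likelihood linear mixed models with stratum-specific covariance.

The marginal model for subject ``i`` in covariance group ``g`` is

    y_i ~ MVN(X_i beta, V_g[s_i, s_i])

where ``s_i`` is the subject's set of observed visit indices and ``V_g``
is parameterized by one of three structures:

``independence``
    V_g = sigma_g^2 * I.
``random_intercept``
    V_g = sigma_g^2 * J + diag(d_1..d_m)  (random intercept plus a
    diagonal residual with per-visit variances).
``unstructured_marginal``
    V_g is a free symmetric positive-definite matrix.  A random intercept
    added to an unstructured residual is not separately identified (their
    sum is itself unstructured), so the single marginal matrix is
    estimated directly and the intercept variance reported as absorbed.

Fixed effects are profiled out by generalized least squares at every
covariance proposal; the profiled deviance is minimized over
unconstrained parameters (log-variances; log-Cholesky factors for the
unstructured matrix), which keeps every reachable covariance PD.
Estimation is plain ML, not REML: the downstream likelihood-ratio tests
compare fixed-effect nestings and the AIC comparisons span different
fixed-effect sets, both of which require ML likelihoods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from ._exceptions import (
    CollinearityError,
    DesignError,
    FitError,
    NotPositiveDefiniteError,
    OptimizationQualityError,
    TestError,
)
from .io_config import PhenotypeTable

_LOG_2PI = math.log(2.0 * math.pi)

STRUCTURES = ("independence", "random_intercept", "unstructured_marginal")
CODINGS = ("two_level", "three_level", "smokers_only")

#: dummy levels introduced by each smoking coding (reference level first in comment)
_CODING_DUMMIES = {
    "two_level": ("ever",),          # reference: never
    "three_level": ("former", "current"),  # reference: never
    "smokers_only": ("current",),    # reference: former
}

_CODING_GROUPS = {
    "two_level": ("never", "ever"),
    "three_level": ("never", "former", "current"),
    "smokers_only": ("former", "current"),
}


def status_dummy_levels(coding: str) -> tuple[str, ...]:
    if coding not in _CODING_DUMMIES:
        raise DesignError(f"unknown smoking coding {coding!r}")
    return _CODING_DUMMIES[coding]


def coding_groups(coding: str) -> tuple[str, ...]:
    return _CODING_GROUPS[coding]


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Declarative fixed-effect list, smoking coding and covariance choice.

    ``fixed_terms`` is an ordered tuple of term names drawn from:
    ``intercept, age, sex, bmi, height, time, pack_years, sex:age,
    status, age:status, sex:status, height:status, time:status,
    pc1..pcK, pc1:status, snp, snp:status, snp:pack_years``.
    ``covariance_groups`` is ``"shared"`` (one covariance for everyone) or
    ``"by_status"`` (one per level of the smoking coding, including the
    reference level).
    """

    fixed_terms: tuple[str, ...]
    smoking_coding: str = "two_level"
    covariance: str = "unstructured_marginal"
    covariance_groups: str = "by_status"
    max_visits: int = 3
    response: str = "fev1"

    def __post_init__(self) -> None:
        if self.covariance not in STRUCTURES:
            raise DesignError(f"unknown covariance structure {self.covariance!r}")
        if self.smoking_coding not in CODINGS:
            raise DesignError(f"unknown smoking coding {self.smoking_coding!r}")
        if self.covariance_groups not in ("shared", "by_status"):
            raise DesignError(f"covariance_groups must be 'shared' or 'by_status'")
        if self.max_visits < 1:
            raise DesignError("max_visits must be >= 1")

    @property
    def has_snp_terms(self) -> bool:
        return any(t.startswith("snp") for t in self.fixed_terms)

    def without_snp_terms(self) -> "ModelSpec":
        return replace(self, fixed_terms=tuple(t for t in self.fixed_terms if not t.startswith("snp")))

    def group_labels(self) -> tuple[str, ...]:
        if self.covariance_groups == "shared":
            return ("all",)
        return coding_groups(self.smoking_coding)


# ---------------------------------------------------------------------------
# design bundle
# ---------------------------------------------------------------------------


@dataclass
class Block:
    """Subjects sharing a covariance group and an observed-visit pattern."""

    group: str
    visits: tuple[int, ...]          # 1-based observed visit indices
    X: np.ndarray                    # (n_subj, m, p)
    y: np.ndarray                    # (n_subj, m)
    sample_idx: np.ndarray           # (n_subj,) indices into bundle.subject_ids
    aux: dict = field(default_factory=dict)
    _stats: tuple | None = None

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return len(self.visits)

    def suffstats(self):
        """Cross-moment tensors (Cxx[j,k]=sum_i x_ij x_ik^T etc.)."""
        if self._stats is None:
            Cxx = np.einsum("njp,nkq->jkpq", self.X, self.X, optimize=True)
            Cxy = np.einsum("njp,nk->jkp", self.X, self.y, optimize=True)
            Cyy = np.einsum("nj,nk->jk", self.y, self.y)
            self._stats = (Cxx, Cxy, Cyy)
        return self._stats


@dataclass
class DesignBundle:
    """Blocked design produced by :func:`build_design`."""

    spec: ModelSpec
    colnames: list[str]
    blocks: list[Block]
    subject_ids: list[str]
    groups: tuple[str, ...]
    n_obs: int

    @property
    def p(self) -> int:
        return len(self.colnames)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def stacked_X(self) -> np.ndarray:
        return np.concatenate([b.X.reshape(-1, self.p) for b in self.blocks], axis=0)

    def with_snp(self, snp_by_subject: Mapping[str, float] | pd.Series,
                 terms: Sequence[str]) -> "DesignBundle":
        """Append SNP fixed-effect columns to an SNP-free design.

        ``terms`` is an ordered subset of ``("snp", "snp:status",
        "snp:pack_years")``.  Dosages are constant within subject; the
        interaction columns reuse the status dummies and the per-visit
        pack-years stored in each block's ``aux``.
        """
        if isinstance(snp_by_subject, pd.Series):
            snp_by_subject = snp_by_subject.to_dict()
        dummy_levels = status_dummy_levels(self.spec.smoking_coding)
        new_names = []
        for t in terms:
            if t == "snp":
                new_names.append("snp")
            elif t == "snp:status":
                new_names.extend(f"snp:status[{lv}]" for lv in dummy_levels)
            elif t == "snp:pack_years":
                new_names.append("snp:pack_years")
            else:
                raise DesignError(f"unknown SNP term {t!r}")
        blocks = []
        for b in self.blocks:
            g = np.array([snp_by_subject[self.subject_ids[i]] for i in b.sample_idx], dtype=float)
            if np.isnan(g).any():
                raise DesignError("missing dosage inside with_snp; subset subjects first")
            cols = []
            for t in terms:
                if t == "snp":
                    cols.append(np.broadcast_to(g[:, None], (b.n, b.m)))
                elif t == "snp:status":
                    for d in range(len(dummy_levels)):
                        cols.append(g[:, None] * b.aux["dummies"][:, d][:, None] * np.ones((1, b.m)))
                elif t == "snp:pack_years":
                    cols.append(g[:, None] * b.aux["pack_years"])
            Xs = np.stack(cols, axis=2)
            blocks.append(Block(b.group, b.visits, np.concatenate([b.X, Xs], axis=2),
                                b.y, b.sample_idx, b.aux))
        spec = replace(self.spec, fixed_terms=self.spec.fixed_terms + tuple(terms))
        return DesignBundle(spec, self.colnames + new_names, blocks,
                            self.subject_ids, self.groups, self.n_obs)


def build_design(records: PhenotypeTable, spec: ModelSpec,
                 pcs: "pd.DataFrame | None" = None,
                 snp: Mapping[str, float] | pd.Series | None = None) -> DesignBundle:
    """Turn long-format records into per-subject design blocks.

    ``pcs`` is a DataFrame of PC scores indexed by subject id with
    columns ``pc1..pcK``; required when the spec references PC terms.
    ``snp`` maps subject id to minor-allele dosage; required when the
    spec has SNP terms.  Status dummies are coded 0/1 against the spec's
    reference level (never smokers, or former smokers under
    ``smokers_only``).
    """
    df = records.df
    coding = spec.smoking_coding
    dummy_levels = status_dummy_levels(coding)
    status = df["smoking"].to_numpy()

    needs_status = any("status" in t for t in spec.fixed_terms) or spec.covariance_groups == "by_status"
    if needs_status:
        present = set(status)
        for lv in coding_groups(coding):
            if lv == "ever":
                ok = bool(present & {"former", "current"})
            else:
                ok = lv in present
            if not ok:
                raise DesignError(f"smoking coding {coding!r}: stratum {lv!r} is empty")
        if coding == "smokers_only" and "never" in present:
            raise DesignError("smokers_only coding on a cohort containing never smokers")

    dummies = np.zeros((len(df), len(dummy_levels)))
    for d, lv in enumerate(dummy_levels):
        if lv == "ever":
            dummies[:, d] = np.isin(status, ("former", "current")).astype(float)
        else:
            dummies[:, d] = (status == lv).astype(float)

    if pcs is not None and not isinstance(pcs, pd.DataFrame):
        pcs = pcs.scores_frame()  # PCResult duck-typing

    base = {
        "age": df["age0"].to_numpy(float),
        "sex": df["sex"].to_numpy(float),
        "bmi": df["bmi"].to_numpy(float),
        "height": df["height"].to_numpy(float),
        "time": df["time"].to_numpy(float),
        "pack_years": df["pack_years"].to_numpy(float),
    }
    subj = df["subject_id"].to_numpy()

    def pc_col(k: int) -> np.ndarray:
        if pcs is None:
            raise DesignError(f"spec references pc{k} but no PC scores were supplied")
        name = f"pc{k}"
        if name not in pcs.columns:
            raise DesignError(f"PC scores lack column {name}")
        return pcs[name].reindex(subj).to_numpy(float)

    snp_row = None
    if spec.has_snp_terms:
        if snp is None:
            raise DesignError("spec has SNP terms but no dosages were supplied")
        if isinstance(snp, pd.Series):
            snp = snp.to_dict()
        snp_row = np.array([snp.get(s, np.nan) for s in subj], dtype=float)
        if np.isnan(snp_row).any():
            raise DesignError("missing dosage for a subject in the records; apply complete-case subsetting first")

    cols: list[np.ndarray] = []
    names: list[str] = []

    def add(name: str, v: np.ndarray) -> None:
        names.append(name)
        cols.append(np.asarray(v, dtype=float))

    for term in spec.fixed_terms:
        if term == "intercept":
            add("intercept", np.ones(len(df)))
        elif term in base:
            add(term, base[term])
        elif term == "sex:age":
            add("sex:age", base["sex"] * base["age"])
        elif term == "status":
            for d, lv in enumerate(dummy_levels):
                add(f"status[{lv}]", dummies[:, d])
        elif term in ("age:status", "sex:status", "height:status", "time:status"):
            v = base[term.split(":")[0]]
            for d, lv in enumerate(dummy_levels):
                add(f"{term.split(':')[0]}:status[{lv}]", v * dummies[:, d])
        elif term.startswith("pc") and ":" not in term:
            k = int(term[2:])
            add(term, pc_col(k))
        elif term == "pc1:status":
            v = pc_col(1)
            for d, lv in enumerate(dummy_levels):
                add(f"pc1:status[{lv}]", v * dummies[:, d])
        elif term == "snp":
            add("snp", snp_row)
        elif term == "snp:status":
            for d, lv in enumerate(dummy_levels):
                add(f"snp:status[{lv}]", snp_row * dummies[:, d])
        elif term == "snp:pack_years":
            add("snp:pack_years", snp_row * base["pack_years"])
        else:
            raise DesignError(f"term {term!r} references no known column")

    X = np.column_stack(cols) if cols else np.zeros((len(df), 0))
    y = df[spec.response].to_numpy(float)

    # covariance group per row
    if spec.covariance_groups == "shared":
        group_row = np.full(len(df), "all", dtype=object)
    else:
        group_row = np.empty(len(df), dtype=object)
        for lv in coding_groups(coding):
            if lv == "ever":
                group_row[np.isin(status, ("former", "current"))] = "ever"
            elif lv == "never":
                group_row[status == "never"] = "never"
            else:
                group_row[status == lv] = lv

    # block by (group, visit pattern); rows are already sorted subject/visit
    subject_ids = list(dict.fromkeys(subj))
    sidx = {s: i for i, s in enumerate(subject_ids)}
    starts = np.flatnonzero(np.r_[True, subj[1:] != subj[:-1]])
    ends = np.r_[starts[1:], len(subj)]
    visits_arr = df["visit"].to_numpy()
    per_pattern: dict[tuple, list[tuple[int, int]]] = {}
    for s, e in zip(starts, ends):
        pattern = tuple(int(v) for v in visits_arr[s:e])
        if max(pattern) > spec.max_visits:
            raise DesignError(f"subject {subj[s]} has visit {max(pattern)} > max_visits={spec.max_visits}")
        key = (group_row[s], pattern)
        per_pattern.setdefault(key, []).append((s, e))

    blocks = []
    for (grp, pattern), spans in sorted(per_pattern.items(), key=lambda kv: (str(kv[0][0]), kv[0][1])):
        m = len(pattern)
        nb = len(spans)
        Xb = np.empty((nb, m, X.shape[1]))
        yb = np.empty((nb, m))
        pyb = np.empty((nb, m))
        db = np.empty((nb, len(dummy_levels)))
        idxb = np.empty(nb, dtype=int)
        for i, (s, e) in enumerate(spans):
            Xb[i] = X[s:e]
            yb[i] = y[s:e]
            pyb[i] = base["pack_years"][s:e]
            db[i] = dummies[s]
            idxb[i] = sidx[subj[s]]
        blocks.append(Block(str(grp), pattern, Xb, yb, idxb,
                            aux={"pack_years": pyb, "dummies": db}))

    groups = tuple(g for g in (spec.group_labels()) if any(b.group == g for b in blocks))
    if not groups:
        groups = tuple(sorted({b.group for b in blocks}))
    return DesignBundle(spec, names, blocks, subject_ids, groups, len(df))


# ---------------------------------------------------------------------------
# covariance parameterization
# ---------------------------------------------------------------------------


def n_cov_params(structure: str, m: int) -> int:
    if structure == "independence":
        return 1
    if structure == "random_intercept":
        return 1 if m == 1 else 1 + m
    if structure == "unstructured_marginal":
        return m * (m + 1) // 2
    raise DesignError(f"unknown covariance structure {structure!r}")


def _theta_to_V(structure: str, m: int, theta: np.ndarray) -> np.ndarray:
    """Unconstrained parameters -> full m x m PD covariance."""
    theta = np.asarray(theta, dtype=float)
    if structure == "independence":
        return np.exp(theta[0]) * np.eye(m)
    if structure == "random_intercept":
        if m == 1:
            return np.array([[np.exp(theta[0])]])
        s2 = np.exp(theta[0])
        d = np.exp(theta[1:1 + m])
        return s2 * np.ones((m, m)) + np.diag(d)
    # unstructured: log-Cholesky
    L = np.zeros((m, m))
    idx = 0
    for j in range(m):
        for k in range(j + 1):
            if j == k:
                L[j, k] = np.exp(theta[idx])
            else:
                L[j, k] = theta[idx]
            idx += 1
    return L @ L.T


def _theta_to_natural(structure: str, m: int, theta: np.ndarray) -> dict:
    V = _theta_to_V(structure, m, theta)
    if structure == "independence":
        return {"structure": structure, "sigma2": float(np.exp(theta[0])), "V": V}
    if structure == "random_intercept":
        if m == 1:
            return {"structure": structure, "sigma2": float(np.exp(theta[0])),
                    "resid_diag": np.zeros(1), "V": V}
        return {"structure": structure, "sigma2": float(np.exp(theta[0])),
                "resid_diag": np.exp(theta[1:1 + m]), "V": V}
    return {"structure": structure, "sigma2": None, "V": V}  # intercept absorbed


def _natural_to_theta(structure: str, m: int, cp: dict) -> np.ndarray:
    if structure == "independence":
        return np.array([math.log(cp["sigma2"])])
    if structure == "random_intercept":
        if m == 1:
            return np.array([math.log(cp["sigma2"])])
        return np.concatenate([[math.log(cp["sigma2"])], np.log(cp["resid_diag"])])
    L = np.linalg.cholesky(cp["V"])
    out = []
    for j in range(m):
        for k in range(j + 1):
            out.append(math.log(L[j, j]) if j == k else L[j, k])
    return np.array(out)


def _default_theta(structure: str, m: int, v0: float) -> np.ndarray:
    v0 = max(v0, 1e-8)
    if structure == "independence":
        return np.array([math.log(v0)])
    if structure == "random_intercept":
        if m == 1:
            return np.array([math.log(v0)])
        return np.concatenate([[math.log(v0 / 2)], np.full(m, math.log(v0 / 2))])
    V0 = v0 * (0.5 * np.eye(m) + 0.5)
    return _natural_to_theta("unstructured_marginal", m, {"V": V0})


def marginal_covariance(spec: ModelSpec, group: str, visits: Sequence[int],
                        cov_params: Mapping[str, Mapping]) -> np.ndarray:
    """Marginal covariance of one group restricted to observed visits.

    ``cov_params`` maps group label to a natural-scale parameter mapping:
    ``{"sigma2": ...}`` for independence, ``{"sigma2": ..., "resid_diag":
    ...}`` for random_intercept, ``{"V": matrix}`` for
    unstructured_marginal.  Raises
    :class:`NotPositiveDefiniteError` when the construction is not PD.
    """
    cp = cov_params[group]
    visits = sorted(int(v) for v in visits)
    if not visits or visits[0] < 1 or visits[-1] > spec.max_visits:
        raise DesignError(f"visits {visits} outside 1..{spec.max_visits}")
    m = spec.max_visits
    structure = spec.covariance
    if structure == "independence":
        V = float(cp["sigma2"]) * np.eye(m)
    elif structure == "random_intercept":
        d = np.asarray(cp.get("resid_diag", np.zeros(m)), dtype=float)
        if d.size == 1 and m > 1:
            d = np.repeat(d, m)
        V = float(cp["sigma2"]) * np.ones((m, m)) + np.diag(d[:m])
    else:
        V = np.asarray(cp["V"], dtype=float)
    idx = np.array(visits) - 1
    Vs = V[np.ix_(idx, idx)]
    if not np.allclose(Vs, Vs.T):
        raise NotPositiveDefiniteError("covariance is not symmetric")
    try:
        np.linalg.cholesky(Vs)
    except np.linalg.LinAlgError as exc:
        raise NotPositiveDefiniteError(f"covariance not positive definite for visits {visits}") from exc
    return Vs


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def loglik(spec: ModelSpec, bundle: DesignBundle, beta: np.ndarray,
           cov_params: Mapping[str, Mapping]) -> float:
    """Exact MVN log-likelihood at explicit parameters.

    Sums, over subjects, the multivariate-normal log-density of the
    subject's response vector with mean ``X_i beta`` and covariance
    ``marginal_covariance`` restricted to the observed visits.
    """
    beta = np.asarray(beta, dtype=float)
    total = 0.0
    for b in bundle.blocks:
        V = marginal_covariance(spec, b.group, b.visits, cov_params)
        try:
            c, low = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError as exc:
            raise FitError(f"singular covariance in group {b.group}, visits {b.visits}") from exc
        logdet = 2.0 * np.log(np.diag(c)).sum()
        R = b.y - b.X @ beta                       # (n, m)
        Z = linalg.cho_solve((c, low), R.T)        # (m, n)
        quad = np.einsum("nm,mn->", R, Z)
        total += -0.5 * (b.n * (b.m * _LOG_2PI + logdet) + quad)
    return float(total)


class _ProfiledObjective:
    """Negative profiled log-likelihood over covariance parameters.

    Uses per-block cross-moment tensors so each evaluation costs
    O(m^2 p^2) per block instead of O(n m p^2).
    """

    def __init__(self, bundle: DesignBundle):
        self.bundle = bundle
        spec = bundle.spec
        self.groups = bundle.groups
        self.m = spec.max_visits
        self.structure = spec.covariance
        self.npar_per_group = n_cov_params(self.structure, self.m)
        self.p = bundle.p
        self._split = {}
        off = 0
        for g in self.groups:
            self._split[g] = slice(off, off + self.npar_per_group)
            off += self.npar_per_group
        self.n_theta = off

    def group_theta(self, theta: np.ndarray, group: str) -> np.ndarray:
        return np.asarray(theta)[self._split[group]]

    def components(self, theta: np.ndarray):
        """(A, b, c, logdet_sum) of the GLS normal equations at theta."""
        A = np.zeros((self.p, self.p))
        bvec = np.zeros(self.p)
        c = 0.0
        ld = 0.0
        Vfull = {g: _theta_to_V(self.structure, self.m, self.group_theta(theta, g))
                 for g in self.groups}
        for blk in self.bundle.blocks:
            idx = np.array(blk.visits) - 1
            V = Vfull[blk.group][np.ix_(idx, idx)]
            try:
                cf = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return None
            W = linalg.cho_solve((cf, True), np.eye(blk.m))
            ld += blk.n * 2.0 * np.log(np.diag(cf)).sum()
            Cxx, Cxy, Cyy = blk.suffstats()
            A += np.einsum("jk,jkpq->pq", W, Cxx)
            bvec += np.einsum("jk,jkp->p", W, Cxy)
            c += float(np.einsum("jk,jk->", W, Cyy))
        return A, bvec, c, ld

    def nll_beta(self, theta: np.ndarray):
        comp = self.components(theta)
        if comp is None:
            return 1e12, None, None
        A, bvec, c, ld = comp
        try:
            cf = linalg.cho_factor(A)
            beta = linalg.cho_solve(cf, bvec)
        except linalg.LinAlgError:
            return 1e12, None, None
        quad = c - float(bvec @ beta)
        nll = 0.5 * (self.bundle.n_obs * _LOG_2PI + ld + quad)
        return nll, beta, A

    def __call__(self, theta: np.ndarray) -> float:
        return self.nll_beta(theta)[0]


# ---------------------------------------------------------------------------
# fit result and tests
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """ML estimates and diagnostics of one mixed-model fit."""

    spec: ModelSpec
    colnames: list[str]
    beta_hat: np.ndarray
    vcov_beta: np.ndarray
    cov_params: dict
    loglik: float
    k: int
    aic: float
    converged: bool
    n_subjects: int
    n_obs: int
    rank_x: int
    theta: np.ndarray
    n_iter: int = 0
    message: str = ""

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov_beta))

    def coef(self, name: str) -> float:
        return float(self.beta_hat[self.colnames.index(name)])

    def coef_se(self, name: str) -> float:
        return float(self.se()[self.colnames.index(name)])

    def to_dict(self) -> dict:
        return {
            "colnames": self.colnames,
            "beta_hat": self.beta_hat.tolist(),
            "loglik": self.loglik,
            "k": self.k,
            "aic": self.aic,
            "converged": self.converged,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
        }


@dataclass(frozen=True)
class TestResult:
    """Statistic, reference distribution and p-value of one test."""

    __test__ = False  # keep pytest collection away

    statistic: float
    df: int
    p: float
    kind: str                    # LRT | Wald | F | one_tailed_Wald
    df_denom: float | None = None
    statistic_chi2: float | None = None
    p_chi2: float | None = None


def _check_collinearity(bundle: DesignBundle) -> None:
    X = bundle.stacked_X()
    if X.shape[1] == 0:
        raise FitError("empty design")
    norms = np.linalg.norm(X, axis=0)
    zero = [bundle.colnames[j] for j in np.flatnonzero(norms < 1e-12)]
    if zero:
        raise CollinearityError(f"all-zero design columns: {zero}")
    Xs = X / norms
    s = np.linalg.svd(Xs, compute_uv=False)
    tol = max(X.shape) * np.finfo(float).eps * s[0]
    if s[-1] < max(tol, 1e-10):
        # name columns implicated in the near-null space
        _, _, vt = np.linalg.svd(Xs)
        v = np.abs(vt[-1])
        names = [bundle.colnames[j] for j in np.flatnonzero(v > 0.1)]
        raise CollinearityError(f"collinear design columns: {names}")


def fit_ml(spec: ModelSpec, bundle: DesignBundle,
           init: "FitResult | np.ndarray | None" = None,
           max_iter: int = 500) -> FitResult:
    """Maximize the marginal likelihood by profiled quasi-Newton.

    ``init`` may be a previous :class:`FitResult` with the same
    covariance layout (its theta is reused as a warm start) or a raw
    unconstrained parameter vector.  Non-convergence is reported through
    ``converged=False``, never raised, so genome-wide loops survive
    individual hard SNPs.
    """
    _check_collinearity(bundle)
    obj = _ProfiledObjective(bundle)

    if isinstance(init, FitResult):
        theta0 = np.asarray(init.theta, dtype=float)
        if theta0.size != obj.n_theta:
            raise FitError("warm-start theta has wrong dimension")
    elif init is not None:
        theta0 = np.asarray(init, dtype=float)
        if theta0.size != obj.n_theta:
            raise FitError("init theta has wrong dimension")
    else:
        v0 = float(np.var(np.concatenate([b.y.ravel() for b in bundle.blocks])))
        t = _default_theta(obj.structure, obj.m, v0)
        theta0 = np.tile(t, len(obj.groups))

    res = optimize.minimize(
        obj, theta0, method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-6},
    )
    success = bool(res.success)
    theta_hat = res.x
    best_fun = float(res.fun)
    n_iter = int(res.nit)
    if not success:
        # line searches on finite-difference gradients abort near the
        # optimum (the deviance's curvature makes the gradient's noise
        # floor large while attainable improvements are tiny), so judge
        # stationarity by what a derivative-free polish can still gain
        polish = optimize.minimize(
            obj, theta_hat, method="Nelder-Mead",
            options={"maxiter": 2000, "fatol": 1e-10, "xatol": 1e-8},
        )
        n_iter += int(polish.nit)
        gain = best_fun - float(polish.fun)
        if polish.fun <= best_fun:
            theta_hat = polish.x
            best_fun = float(polish.fun)
        tol = max(1e-6, abs(best_fun) * 1e-9)
        if polish.success or 0 <= gain < tol:
            success = True
        else:
            retry = optimize.minimize(
                obj, theta_hat, method="L-BFGS-B",
                options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-6},
            )
            n_iter += int(retry.nit)
            further = float(polish.fun) - float(retry.fun)
            if retry.fun <= best_fun:
                theta_hat = retry.x
                best_fun = float(retry.fun)
            # stationary once another quasi-Newton pass gains < tol
            success = bool(retry.success) or further < tol
    res_jac = getattr(res, "jac", None)
    nll, beta, A = obj.nll_beta(theta_hat)
    if beta is None:
        raise FitError("likelihood undefined at optimizer solution")
    vcov = np.linalg.inv(A)
    vcov = 0.5 * (vcov + vcov.T)
    cov_params = {g: _theta_to_natural(obj.structure, obj.m, obj.group_theta(theta_hat, g))
                  for g in obj.groups}
    k = bundle.p + obj.n_theta
    ll = -float(nll)
    grad_ok = success or (res_jac is not None and float(np.max(np.abs(res_jac))) < 1e-3)
    return FitResult(
        spec=bundle.spec,
        colnames=list(bundle.colnames),
        beta_hat=np.asarray(beta),
        vcov_beta=vcov,
        cov_params=cov_params,
        loglik=ll,
        k=k,
        aic=-2.0 * ll + 2.0 * k,
        converged=grad_ok,
        n_subjects=bundle.n_subjects,
        n_obs=bundle.n_obs,
        rank_x=bundle.p,
        theta=np.asarray(res.x),
        n_iter=int(res.nit),
        message=str(res.message),
    )


def lrt(full: FitResult, reduced: FitResult, df: int,
        tol: float = 1e-2) -> TestResult:
    """Likelihood-ratio test of nested ML fits against chi-square(df)."""
    if not (full.converged and reduced.converged):
        raise TestError("LRT requires both fits converged")
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -tol:
        raise OptimizationQualityError(
            f"full log-likelihood {full.loglik:.6f} below reduced {reduced.loglik:.6f}; refit needed"
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return TestResult(statistic=stat, df=df, p=p, kind="LRT")


def wald_joint(fit: FitResult, coefficient_subset: Sequence[str | int]) -> TestResult:
    """Joint Wald test of a coefficient subset being zero.

    The quadratic form ``W = beta' Vsub^{-1} beta`` is referred both to
    chi-square(q) and, as ``W/q``, to F(q, n_obs - rank(X)); the reported
    p-value comes from the F form (the finite-sample convention of the
    mixed-model software this mirrors), with the chi-square companion in
    ``statistic_chi2``/``p_chi2``.
    """
    if not coefficient_subset:
        raise TestError("empty coefficient subset")
    idx = [fit.colnames.index(c) if isinstance(c, str) else int(c)
           for c in coefficient_subset]
    b = fit.beta_hat[idx]
    V = fit.vcov_beta[np.ix_(idx, idx)]
    try:
        W = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise TestError("singular coefficient sub-covariance") from exc
    q = len(idx)
    df_denom = max(fit.n_obs - fit.rank_x, 1)
    Fstat = W / q
    p_f = float(stats.f.sf(Fstat, q, df_denom)) if W > 0 else 1.0
    p_chi2 = float(stats.chi2.sf(W, q)) if W > 0 else 1.0
    return TestResult(statistic=Fstat, df=q, p=p_f, kind="F",
                      df_denom=float(df_denom), statistic_chi2=W, p_chi2=p_chi2)


def wald_term(fit: FitResult, term: str) -> TestResult:
    """Two-sided single-coefficient Wald test (z-based)."""
    b = fit.coef(term)
    se = fit.coef_se(term)
    if se <= 0:
        raise TestError(f"zero standard error for term {term!r}")
    z = b / se
    return TestResult(statistic=z * z, df=1, p=float(2.0 * stats.norm.sf(abs(z))),
                      kind="Wald")


def aic_of(fit: FitResult) -> float:
    """AIC = -2 loglik + 2 k with k counting fixed effects and free covariance parameters."""
    if not fit.converged:
        raise TestError("AIC requires a converged fit")
    return -2.0 * fit.loglik + 2.0 * fit.k
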