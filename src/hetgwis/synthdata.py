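"""Synthetic cohort generation.

Cohorts are generated with exactly the statistical structure the
analysis assumes: Hardy-Weinberg genotypes, longitudinal covariates,
baseline-fixed smoking strata, group-specific random-intercept plus
residual covariance, and configurable SNP main / SNP-by-smoking /
SNP-by-pack-years effects, so every downstream stage is testable without
any external download.  Covariate distributions are loose calibrations
to the reference study designs and are fully configurable; tests should
depend only on declared scenario parameters, never on the defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import ScenarioError
from .io_config import GenotypeMatrix, PhenotypeTable

_ALLELES = ("A", "C", "G", "T")

#: generative fixed-effect coefficients, keyed by design term.  The
#: smoking status dummy in the generator is always never-vs-ever.
DEFAULT_COVARIATE_EFFECTS = {
    "intercept": -2.0,
    "age": -0.022,
    "sex": 0.45,
    "bmi": -0.012,
    "height": 0.032,
    "time": -0.030,
    "pack_years": -0.004,
    "sex:age": 0.002,
    "status": -0.12,
    "age:status": -0.002,
    "sex:status": 0.05,
    "height:status": 0.0008,
    "time:status": -0.012,
}


def _exchangeable(var: float, rho: float, m: int) -> np.ndarray:
    return var * ((1.0 - rho) * np.eye(m) + rho * np.ones((m, m)))


@dataclass
class SimScenario:
    """Full description of one synthetic-cohort experiment.

    Setting every ``beta_snp*`` to zero defines the null of the joint
    SNP tests.  ``Sigma_never``/``Sigma_ever`` are residual covariance
    matrices over ``max_visits`` visits; together with the
    random-intercept variances ``sigma2_*`` they define the marginal
    visit-vector covariance ``sigma2_g * J + Sigma_g`` per stratum.
    """

    n_subjects: int = 1000
    n_snps: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    smoking_proportions: tuple[float, float, float] = (0.5, 0.25, 0.25)  # never/former/current
    max_visits: int = 3
    visit_spacing_years: float = 2.0
    beta_snp: float = 0.0
    beta_snp_smoking: float = 0.0
    beta_snp_packyears: float = 0.0
    covariate_effects: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    sigma2_never: float = 0.04
    sigma2_ever: float = 0.15
    Sigma_never: np.ndarray | None = None
    Sigma_ever: np.ndarray | None = None
    dropout_prob: float = 0.0
    # carried forward by default: the visit-wise increment for current
    # smokers makes the SNP-by-pack-years contrast effectively low-n and
    # slows the joint test's convergence to its chi-square limit
    pack_years_update: str = "carry_forward"   # or "update"
    pack_years_median: float = 12.0
    # log-scale sd of the lognormal pack-years draw; heavy tails make the
    # SNP-by-pack-years contrast hinge on a handful of subjects and
    # destabilize genome-wide inflation estimates at moderate n
    pack_years_sigma: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ScenarioError("n_subjects must be >= 2")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ScenarioError("maf_range must lie within (0, 0.5]")
        props = np.asarray(self.smoking_proportions, dtype=float)
        if props.min() < 0 or abs(props.sum() - 1.0) > 1e-8:
            raise ScenarioError("smoking_proportions must be non-negative and sum to 1")
        if self.max_visits < 1:
            raise ScenarioError("max_visits must be >= 1")
        if not (0.0 <= self.dropout_prob < 1.0):
            raise ScenarioError("dropout_prob must lie in [0, 1)")
        if self.pack_years_update not in ("update", "carry_forward"):
            raise ScenarioError("pack_years_update must be 'update' or 'carry_forward'")
        m = self.max_visits
        if self.Sigma_never is None:
            self.Sigma_never = _exchangeable(0.06, 0.25, m)
        if self.Sigma_ever is None:
            self.Sigma_ever = _exchangeable(0.25, 0.25, m)
        for name in ("Sigma_never", "Sigma_ever"):
            S = np.asarray(getattr(self, name), dtype=float)
            if S.shape != (m, m):
                raise ScenarioError(f"{name} must be {m}x{m}")
            if not np.allclose(S, S.T):
                raise ScenarioError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(S).min() <= 0:
                raise ScenarioError(f"{name} must be positive definite")
            setattr(self, name, S)

    @property
    def is_null(self) -> bool:
        return self.beta_snp == self.beta_snp_smoking == self.beta_snp_packyears == 0.0

    def replace(self, **kwargs) -> "SimScenario":
        d = dataclasses.asdict(self)
        d.update(kwargs)
        return SimScenario(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["Sigma_never"] = np.asarray(self.Sigma_never).tolist()
        d["Sigma_ever"] = np.asarray(self.Sigma_ever).tolist()
        d["maf_range"] = list(self.maf_range)
        d["smoking_proportions"] = list(self.smoking_proportions)
        return d


def preset(name: str) -> SimScenario:
    """Named scenarios mirroring the reference study designs.

    ``kare_like``: three visits two years apart, never/former/current
    close to 4926/1742/1866 of 8534, strongly heteroscedastic.
    ``genie_like``: repeated visits, three strata.  ``mesa_like``:
    cross-sectional, three strata.  ``copdgene_like``: cross-sectional
    smokers-only (no never smokers).
    """
    if name == "kare_like":
        return SimScenario(
            n_subjects=8534, max_visits=3,
            smoking_proportions=(4926 / 8534, 1742 / 8534, 1866 / 8534),
        )
    if name == "genie_like":
        return SimScenario(
            n_subjects=5971, max_visits=3,
            smoking_proportions=(0.569, 0.302, 0.129),
        )
    if name == "mesa_like":
        return SimScenario(
            n_subjects=1033, max_visits=1,
            smoking_proportions=(0.444, 0.453, 0.103),
            Sigma_never=np.array([[0.06]]), Sigma_ever=np.array([[0.25]]),
        )
    if name == "copdgene_like":
        return SimScenario(
            n_subjects=6670, max_visits=1,
            smoking_proportions=(0.0, 0.61, 0.39),
            Sigma_never=np.array([[0.06]]), Sigma_ever=np.array([[0.25]]),
            pack_years_median=40.0,
        )
    raise KeyError(f"unknown preset {name!r}")


def null_calibration_scenario(seed: int, n_snps: int = 1000,
                              n_subjects: int = 1000) -> SimScenario:
    """Canonical strongly heteroscedastic null scenario for calibration studies.

    Three biennial visits, never/former/current close to the 4926/1742/1866
    reference split, a ten-fold never-vs-ever marginal variance ratio, no
    SNP effects.  Pack-years are kept moderately dispersed (log-sd 0.25):
    the SNP-by-pack-years contrast shares the pack-years vector across
    every SNP, so heavier tails would couple the scan's statistics through
    a handful of subjects and blur single-scan inflation estimates.
    """
    return SimScenario(
        n_subjects=n_subjects, n_snps=n_snps, seed=seed, dropout_prob=0.0,
        sigma2_never=0.04, sigma2_ever=0.4,
        Sigma_never=_exchangeable(0.06, 0.25, 3),
        Sigma_ever=_exchangeable(0.6, 0.25, 3),
        pack_years_sigma=0.25,
        smoking_proportions=(4926 / 8534, 1742 / 8534, 1866 / 8534),
    )


def simulate_genotypes(scenario: SimScenario, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Independent HWE genotypes: per SNP, MAF ~ U(maf_range), dosage ~ Binomial(2, MAF)."""
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    n, m = scenario.n_subjects, scenario.n_snps
    lo, hi = scenario.maf_range
    mafs = rng.uniform(lo, hi, size=m)
    dosages = rng.binomial(2, mafs[None, :], size=(n, m)).astype(float)
    sample_ids = [f"S{i + 1:06d}" for i in range(n)]
    snp_ids = [f"snp{j + 1:05d}" for j in range(m)]
    alleles = []
    for _ in range(m):
        a, b = rng.choice(4, size=2, replace=False)
        alleles.append((_ALLELES[a], _ALLELES[b]))
    return GenotypeMatrix(sample_ids, snp_ids, dosages, alleles)


def simulate_cohort(scenario: SimScenario, genotypes: GenotypeMatrix,
                    causal_snp: str | None = None,
                    rng: np.random.Generator | None = None) -> PhenotypeTable:
    """Draw covariates and responses for every genotyped subject.

    The response mean follows the generative fixed-effect dictionary
    (never-vs-ever status coding), plus the SNP main, SNP-by-ever and
    SNP-by-pack-years effects when ``causal_snp`` is given.  Residuals
    are a stratum-specific random intercept plus a visit-vector MVN draw
    from ``Sigma_g`` restricted to observed visits; visits after the
    first are dropped independently with ``dropout_prob``.
    """
    rng = np.random.default_rng(scenario.seed + 1) if rng is None else rng
    n = genotypes.n_samples
    if n != scenario.n_subjects:
        raise ScenarioError("genotypes do not cover the scenario's subjects")
    if causal_snp is not None and causal_snp not in genotypes.snp_ids:
        raise KeyError(f"causal SNP {causal_snp!r} not in genotypes")

    eff = dict(DEFAULT_COVARIATE_EFFECTS)
    eff.update(scenario.covariate_effects)
    mvis = scenario.max_visits
    spacing = scenario.visit_spacing_years

    age = rng.uniform(40.0, 69.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    height = rng.normal(160.0, 8.0, size=n) + 10.0 * sex
    bmi0 = rng.normal(24.6, 3.0, size=n)
    smoking = rng.choice(np.array(["never", "former", "current"]),
                         size=n, p=np.asarray(scenario.smoking_proportions, dtype=float))
    ever = np.isin(smoking, ("former", "current"))
    current = smoking == "current"

    py0 = np.zeros(n)
    py0[ever] = np.exp(rng.normal(np.log(scenario.pack_years_median),
                                  scenario.pack_years_sigma, size=int(ever.sum())))

    if causal_snp is not None:
        g = genotypes.column(causal_snp)
        g = np.where(np.isnan(g), 0.0, g)
    else:
        g = np.zeros(n)

    b = np.where(ever,
                 rng.normal(0.0, np.sqrt(scenario.sigma2_ever), size=n),
                 rng.normal(0.0, np.sqrt(scenario.sigma2_never), size=n))
    L_never = np.linalg.cholesky(scenario.Sigma_never)
    L_ever = np.linalg.cholesky(scenario.Sigma_ever)
    eps = rng.standard_normal((n, mvis))
    eps = np.where(ever[:, None], eps @ L_ever.T, eps @ L_never.T)

    observed = np.ones((n, mvis), dtype=bool)
    if mvis > 1 and scenario.dropout_prob > 0:
        observed[:, 1:] = rng.random((n, mvis - 1)) >= scenario.dropout_prob

    rows = []
    for j in range(mvis):
        t = j * spacing
        keep = observed[:, j]
        if scenario.pack_years_update == "update":
            # current smokers accrue roughly one pack-year per elapsed year
            py = py0 + np.where(current, t * 1.0, 0.0)
        else:
            py = py0
        bmi = bmi0 + rng.normal(0.0, 0.3, size=n) if j > 0 else bmi0
        mean = (
            eff["intercept"]
            + eff["age"] * age
            + eff["sex"] * sex
            + eff["bmi"] * bmi
            + eff["height"] * height
            + eff["time"] * t
            + eff["pack_years"] * py
            + eff["sex:age"] * sex * age
            + eff["status"] * ever
            + eff["age:status"] * age * ever
            + eff["sex:status"] * sex * ever
            + eff["height:status"] * height * ever
            + eff["time:status"] * t * ever
        )
        if causal_snp is not None:
            mean = mean + (scenario.beta_snp * g
                           + scenario.beta_snp_smoking * g * ever
                           + scenario.beta_snp_packyears * g * py)
        y = mean + b + eps[:, j]
        for i in np.flatnonzero(keep):
            rows.append((genotypes.sample_ids[i], None, t, y[i], age[i], int(sex[i]),
                         height[i], bmi[i], smoking[i], py[i]))

    df = pd.DataFrame(rows, columns=["subject_id", "visit", "time", "fev1", "age0",
                                     "sex", "height", "bmi", "smoking", "pack_years"])
    df = df.sort_values(["subject_id", "time"], kind="mergesort")
    # renumber observed visits 1..n_i without gaps (dropout removes slots)
    df["visit"] = df.groupby("subject_id", sort=False).cumcount() + 1
    # the table invariant requires time 0 at visit 1; dropout only affects j >= 2
    return PhenotypeTable(df)
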