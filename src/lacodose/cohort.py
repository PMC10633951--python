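"""Virtual-patient cohorts for CRRT dosing simulations.

Virtual critically ill adults are described by four parameters — body
weight, weight-normalised volume of distribution, non-renal clearance and
the sieving/saturation coefficient — each drawn from a truncated normal
distribution whose mean, SD and truncation limits come from published
pharmacokinetic studies of lacosamide in adults receiving CRRT.  Weight is
floored at 40 kg so every virtual patient is adult-sized; the extraction
coefficient is confined to [0, 1] because it is a fraction.

Sampling is by inverse CDF on the truncated marginal, so ``sd = 0``
degenerates cleanly to the mean and tight bounds cost nothing.  An optional
correlation structure between weight, Vd/kg and non-renal clearance is
applied as a Gaussian copula on the latent normals; the marginals remain
exactly the specified truncated normals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ParameterDistribution",
    "CohortSpec",
    "sample_truncated_normal",
    "sample_cohort",
    "default_cohort_spec",
    "WEIGHT_KG",
    "VD_PER_KG",
    "CLNR_ML_MIN",
    "SIEVING",
    "COHORT_COLUMNS",
    "write_cohort_csv",
    "read_cohort_csv",
]

COHORT_COLUMNS = ["weight_kg", "vd_per_kg", "clnr_ml_min", "sieving_coefficient"]


@dataclass(frozen=True)
class ParameterDistribution:
    """Normal distribution truncated to ``[lower, upper]``.

    Units are whatever the parameter is natively expressed in (kg, L/kg,
    mL/min, dimensionless fraction).
    """

    mean: float
    sd: float
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean):
            raise ValueError(f"mean must be finite, got {self.mean}")
        if not self.sd >= 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if not self.lower < self.upper:
            raise ValueError(
                f"degenerate truncation bounds: lower={self.lower} >= upper={self.upper}"
            )
        if self.sd == 0 and not (self.lower <= self.mean <= self.upper):
            raise ValueError(
                f"sd = 0 with mean {self.mean} outside [{self.lower}, {self.upper}]"
            )

    @property
    def _ab(self) -> tuple[float, float]:
        # standardised truncation points for scipy.stats.truncnorm
        return (self.lower - self.mean) / self.sd, (self.upper - self.mean) / self.sd

    def truncated_mean(self) -> float:
        """Closed-form mean of the truncated distribution."""
        if self.sd == 0:
            return self.mean
        a, b = self._ab
        return float(stats.truncnorm.mean(a, b, loc=self.mean, scale=self.sd))

    def cdf(self, x):
        """CDF of the truncated distribution (vectorised)."""
        if self.sd == 0:
            return np.where(np.asarray(x) >= self.mean, 1.0, 0.0)
        a, b = self._ab
        return stats.truncnorm.cdf(x, a, b, loc=self.mean, scale=self.sd)

    def ppf(self, q):
        """Inverse CDF of the truncated distribution (vectorised)."""
        q = np.asarray(q, dtype=float)
        if self.sd == 0:
            return np.full_like(q, self.mean)
        a, b = self._ab
        x = stats.truncnorm.ppf(q, a, b, loc=self.mean, scale=self.sd)
        # keep samples strictly inside the limits even if q underflows to 0/1
        lo = np.nextafter(self.lower, self.upper)
        hi = np.nextafter(self.upper, self.lower)
        return np.clip(x, lo, hi)


# Published simulation inputs: mean ± SD [limits]
WEIGHT_KG = ParameterDistribution(75.40, 18.40, lower=40.0)
VD_PER_KG = ParameterDistribution(0.61, 0.12, lower=0.40, upper=1.00)
CLNR_ML_MIN = ParameterDistribution(16.60, 6.09, lower=3.33, upper=26.67)
SIEVING = ParameterDistribution(0.78, 0.08, lower=0.0, upper=1.0)


def sample_truncated_normal(
    dist: ParameterDistribution, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` values from a truncated normal by inverse-CDF sampling."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return dist.ppf(rng.random(n))


def _identity3() -> np.ndarray:
    return np.eye(3)


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one reproducible cohort of virtual patients.

    ``correlation`` is a 3x3 matrix over the latent normals of
    (weight, vd_per_kg, clnr); the sieving coefficient is always sampled
    independently.  Identity (the default) means full independence.
    """

    n: int = 10_000
    seed: int = 0
    weight_dist: ParameterDistribution = WEIGHT_KG
    vd_per_kg_dist: ParameterDistribution = VD_PER_KG
    clnr_dist: ParameterDistribution = CLNR_ML_MIN
    sc_dist: ParameterDistribution = SIEVING
    correlation: np.ndarray = field(default_factory=_identity3)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"cohort size must be >= 1, got {self.n}")
        corr = np.asarray(self.correlation, dtype=float)
        if corr.shape != (3, 3):
            raise ValueError(f"correlation must be 3x3, got shape {corr.shape}")
        if not np.allclose(corr, corr.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("correlation matrix must be positive semi-definite")
        object.__setattr__(self, "correlation", corr)

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=seed)


def default_cohort_spec(n: int = 10_000, seed: int = 0) -> CohortSpec:
    """The study's cohort: published distributions, independence."""
    return CohortSpec(n=n, seed=seed)


def sample_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Sample a cohort of virtual patients.

    Returns a DataFrame with columns ``weight_kg, vd_per_kg, clnr_ml_min,
    sieving_coefficient``, one row per patient, in deterministic order:
    the same spec (including seed) always yields a bit-identical cohort.
    """
    rng = np.random.default_rng(spec.seed)
    # latent correlated normals for (weight, vd_per_kg, clnr)
    z = rng.standard_normal((spec.n, 3))
    corr = spec.correlation
    if not np.array_equal(corr, np.eye(3)):
        # eigendecomposition tolerates PSD-but-singular matrices
        w, v = np.linalg.eigh(corr)
        z = z @ (v * np.sqrt(np.clip(w, 0.0, None))).T
    u = stats.norm.cdf(z)
    cohort = pd.DataFrame(
        {
            "weight_kg": spec.weight_dist.ppf(u[:, 0]),
            "vd_per_kg": spec.vd_per_kg_dist.ppf(u[:, 1]),
            "clnr_ml_min": spec.clnr_dist.ppf(u[:, 2]),
            "sieving_coefficient": sample_truncated_normal(spec.sc_dist, spec.n, rng),
        }
    )
    return cohort


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, columns=COHORT_COLUMNS)


def read_cohort_csv(path) -> pd.DataFrame:
    cohort = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return cohort[COHORT_COLUMNS]
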