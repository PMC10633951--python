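"""Body-weight effect on target attainment: binning and risk ratios.

The 10,000-patient attainment analysis stratifies patients into weight
bins and, for each bin, estimates the risk ratio of *not* attaining the PD
target for patients outside the bin relative to patients inside it (the
bin is the reference group).  On a 2x2 collapse the closed form is

    RR = (f_rest / n_rest) / (f_bin / n_bin)

with the Wald confidence interval ``exp(ln RR ± z * SE)``,
``SE = sqrt(1/f_rest - 1/n_rest + 1/f_bin - 1/n_bin)`` and the exact
97.5% normal quantile for z.  A generic log-binomial GLM (binomial family,
log link) is provided for regression on arbitrary covariates; on a single
bin indicator it agrees with the closed form.

Bin boundaries follow the published labels, disambiguated so the bins
partition (40, inf): [40,60), [60,70], (70,80], (80,90], (90,100],
(100,110], (110,120], (120,130], (130,140], (140,inf).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "WeightBinTable",
    "RRResult",
    "WEIGHT_BIN_LABELS",
    "REFERENCE_WEIGHT_BIN_COUNTS",
    "assign_bins",
    "rr_vs_rest",
    "attainment_from_simulation",
    "attainment_table",
    "log_binomial_fit",
]

WEIGHT_BIN_LABELS = (
    "< 60", "60-70", "71-80", "81-90", "91-100",
    "100-110", "110-120", "120-130", "130-140", "> 140",
)
_UPPER_EDGES = np.array([60.0, 70.0, 80.0, 90.0, 100.0, 110.0, 120.0, 130.0, 140.0])

# Published weight-bin attainment counts (n not attained, n attained) from
# the reference 10,000-patient simulation of lacosamide dosing during CRRT;
# the study's risk-ratio analysis runs on these counts.
REFERENCE_WEIGHT_BIN_COUNTS = {
    "< 60": (828, 1142),
    "60-70": (384, 1924),
    "71-80": (147, 2088),
    "81-90": (33, 1545),
    "91-100": (3, 968),
    "100-110": (8, 511),
    "110-120": (8, 230),
    "120-130": (13, 92),
    "130-140": (4, 42),
    "> 140": (9, 21),
}


@dataclass(frozen=True)
class RRResult:
    """Risk ratio with Wald 95% CI and two-sided p value."""

    rr: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class WeightBinTable:
    """Attainment counts per weight bin.

    ``n_fail[i]`` patients in bin i did not attain the target,
    ``n_attain[i]`` did.
    """

    labels: tuple[str, ...]
    n_fail: np.ndarray
    n_attain: np.ndarray

    def __post_init__(self) -> None:
        self.n_fail = np.asarray(self.n_fail, dtype=int)
        self.n_attain = np.asarray(self.n_attain, dtype=int)
        if not (len(self.labels) == len(self.n_fail) == len(self.n_attain)):
            raise ValueError("labels and counts must align")
        if np.any(self.n_fail < 0) or np.any(self.n_attain < 0):
            raise ValueError("counts must be >= 0")

    @property
    def n_per_bin(self) -> np.ndarray:
        return self.n_fail + self.n_attain

    @property
    def total(self) -> int:
        return int(self.n_per_bin.sum())

    @classmethod
    def from_counts(cls, counts: dict[str, tuple[int, int]]) -> "WeightBinTable":
        labels = tuple(counts)
        fail, attain = zip(*counts.values())
        return cls(labels, np.array(fail), np.array(attain))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_label": self.labels, "n_fail": self.n_fail, "n_attain": self.n_attain}
        )


def assign_bins(weights) -> np.ndarray:
    """Weight-bin index for each weight (>= 40 kg); 0 = '< 60'."""
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 40):
        raise ValueError("weights must exceed the 40 kg adult floor")
    idx = np.digitize(w, _UPPER_EDGES, right=True)
    # [40,60) is open at 60 but [60,70] is closed at 60
    return np.where((idx == 0) & (w >= 60.0), 1, idx)


def rr_vs_rest(table: WeightBinTable, bin_index: int) -> RRResult:
    """Risk ratio of non-attainment, rest-of-cohort vs the indexed bin.

    The bin is the reference group; an RR above 1 means patients outside
    the bin fail the target more often than patients inside it.
    """
    f_b = int(table.n_fail[bin_index])
    n_b = int(table.n_per_bin[bin_index])
    f_r = int(table.n_fail.sum()) - f_b
    n_r = table.total - n_b
    if f_b < 1 or f_r < 1:
        raise ValueError(
            "risk ratio undefined: zero failures in the bin or its complement"
        )
    rr = (f_r / n_r) / (f_b / n_b)
    se = np.sqrt(1 / f_r - 1 / n_r + 1 / f_b - 1 / n_b)
    z975 = stats.norm.ppf(0.975)
    zstat = np.log(rr) / se
    return RRResult(
        rr=rr,
        ci_low=rr * np.exp(-z975 * se),
        ci_high=rr * np.exp(z975 * se),
        p=float(2 * stats.norm.sf(abs(zstat))),
    )


def attainment_from_simulation(
    cohort: pd.DataFrame, daily_codes: np.ndarray, rule: str = "day3_in_range"
) -> tuple[np.ndarray, WeightBinTable]:
    """Per-patient attainment booleans plus the binned count table.

    ``daily_codes`` is the ``(3, n)`` class-code array from
    :func:`lacodose.pta.daily_classification` (0 = in range).  The default
    rule calls a patient an attainer iff its day-3 metric is in range;
    ``"all_days_in_range"`` requires all three days.
    """
    if rule == "day3_in_range":
        attained = daily_codes[2] == 0
    elif rule == "all_days_in_range":
        attained = np.all(daily_codes == 0, axis=0)
    else:
        raise ValueError(f"unknown attainment rule {rule!r}")
    return attained, attainment_table(cohort["weight_kg"], attained)


def attainment_table(weights, attained) -> WeightBinTable:
    """Bin per-patient attainment outcomes by body weight."""
    idx = assign_bins(weights)
    attained = np.asarray(attained, dtype=bool)
    n_bins = len(WEIGHT_BIN_LABELS)
    fail = np.bincount(idx[~attained], minlength=n_bins)
    ok = np.bincount(idx[attained], minlength=n_bins)
    return WeightBinTable(WEIGHT_BIN_LABELS, fail, ok)


def log_binomial_fit(
    outcomes, design: pd.DataFrame, add_intercept: bool = True
) -> dict[str, RRResult]:
    """Log-binomial regression: RR per covariate via a log-link GLM.

    ``outcomes`` are per-subject failure indicators; exponentiated slope
    coefficients are risk ratios.  Log-link binomial fits can fail to
    converge (fitted risks are not constrained below 1); non-convergence
    raises with a diagnostic so callers can fall back to the closed-form
    2x2 ratio of :func:`rr_vs_rest`.
    """
    y = np.asarray(outcomes, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcomes must contain both failures and successes")
    X = design.astype(float)
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        # the log link intentionally models risks, not odds; statsmodels
        # warns that it does not respect the binomial domain
        warnings.simplefilter("ignore")
        model = sm.GLM(
            y, X, family=sm.families.Binomial(link=sm.families.links.Log())
        )
    try:
        fit = model.fit(maxiter=200)
    except Exception as err:  # pragma: no cover - backend-specific failures
        raise RuntimeError(f"log-binomial fit failed: {err}") from err
    if not fit.converged:
        raise RuntimeError(
            "log-binomial fit did not converge "
            f"(deviance {fit.deviance:.4g}); use the closed-form 2x2 RR instead"
        )
    out: dict[str, RRResult] = {}
    ci = fit.conf_int()
    for name in X.columns:
        if name == "const":
            continue
        out[name] = RRResult(
            rr=float(np.exp(fit.params[name])),
            ci_low=float(np.exp(ci.loc[name, 0])),
            ci_high=float(np.exp(ci.loc[name, 1])),
            p=float(fit.pvalues[name]),
        )
    return out
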