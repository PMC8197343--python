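"""Log-probit quantal dose-response fitting.

The model: an animal at dose :math:`d` is protected with probability

.. math:: p(d) = \\Phi\\big(\\beta_0 + \\beta_1 \\log_{10} d\\big),

with protected counts binomial per dose group.  In the classical probit
convention the response is reported as ``probit = 5 + \\Phi^{-1}(p)``, so
50% protection sits at 5 probits and the 16-84% band spans 4-6 probits.
The median effective dose is the dose at 5 probits,
``log10(ED50) = (5 - intercept)/slope``; its standard error comes from the
fit covariance by the delta method, and the SEM on the mg/kg scale is
``ED50 * ln(10) * SE(log10 ED50)``.

Estimation is maximum-likelihood binomial probit regression (IRLS via
statsmodels GLM).  Dose groups with 0% or 100% protection enter the
likelihood directly; a legacy working-probit mode with the 1/(4n)
correction is available for comparison with older hand calculations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .data import DoseResponseDataset

__all__ = [
    "QuantalProbitModel",
    "ProbitResults",
    "ParallelismTest",
    "NonIdentifiableError",
    "fit_log_probit",
    "count_informative",
    "test_parallelism",
    "PROBIT_OFFSET",
]

#: classical probit convention: probit = 5 + inverse-normal of the proportion
PROBIT_OFFSET = 5.0


class NonIdentifiableError(ValueError):
    """The dataset cannot pin down a finite dose-response line."""


class QuantalProbitModel:
    """Binomial probit regression of protection on log10 dose.

    Parameters
    ----------
    dataset : DoseResponseDataset
        Dose ladder with protected / tested counts per group.

    Examples
    --------
    >>> from isoquantal.data import DoseResponseDataset, QuantalDoseGroup
    >>> ds = DoseResponseDataset("LCM", (
    ...     QuantalDoseGroup(1.0, 8, 0),
    ...     QuantalDoseGroup(10.0, 8, 4),
    ...     QuantalDoseGroup(100.0, 8, 8)))
    >>> res = QuantalProbitModel(ds).fit()
    >>> round(res.ed50, 6)
    10.0
    """

    def __init__(self, dataset: DoseResponseDataset):
        if len(dataset.groups) < 2:
            raise NonIdentifiableError(
                f"{dataset.subject_label}: at least 2 dose levels are required"
            )
        self.dataset = dataset
        self.log10_dose = np.log10(np.asarray(dataset.doses, dtype=float))
        self.n_subjects = np.array([g.n_subjects for g in dataset.groups])
        self.n_responders = np.array([g.n_responders for g in dataset.groups])

    @classmethod
    def from_dataframe(cls, df, subject_label: str | None = None):
        """Build from a long-format frame with dose/n_subjects/n_responders."""
        from .data import QuantalDoseGroup

        if subject_label is not None and "subject_label" in df.columns:
            df = df[df["subject_label"] == subject_label]
        label = subject_label or (
            str(df["subject_label"].iloc[0]) if "subject_label" in df.columns
            else "subject"
        )
        groups = tuple(
            QuantalDoseGroup(float(r.dose), int(r.n_subjects), int(r.n_responders))
            for r in df.itertuples()
        )
        return cls(DoseResponseDataset(label, groups))

    def loglike(self, intercept: float, slope: float) -> float:
        """Binomial log-likelihood at probit-convention (intercept, slope).

        The constant binomial coefficients are omitted; identical to the
        quantity maximised by :meth:`fit` up to that additive constant.
        """
        z = (intercept - PROBIT_OFFSET) + slope * self.log10_dose
        logp = stats.norm.logcdf(z)
        logq = stats.norm.logcdf(-z)
        return float(np.sum(self.n_responders * logp
                            + (self.n_subjects - self.n_responders) * logq))

    def _check_identifiable(self) -> None:
        props = self.n_responders / self.n_subjects
        if np.all(props == 0.0) or np.all(props == 1.0):
            raise NonIdentifiableError(
                f"{self.dataset.subject_label}: all groups at "
                f"{'0%' if props[0] == 0 else '100%'} response; "
                "ED50 is not identifiable"
            )

    def fit(self, method: str = "ml", informative: str = "fitted") -> "ProbitResults":
        """Fit the log-probit line.

        Parameters
        ----------
        method : {"ml", "working-probit"}
            "ml" (default) is exact maximum likelihood by IRLS.
            "working-probit" is the legacy iterative weighted regression on
            working probits with the 1/(4n) correction for 0%/100% groups.
        informative : {"fitted", "observed"}
            Convention for the informative-animal count (4-6 probit band).
        """
        self._check_identifiable()
        if method == "ml":
            partial = (self.n_responders > 0) & (self.n_responders < self.n_subjects)
            if not partial.any():
                raise NonIdentifiableError(
                    f"{self.dataset.subject_label}: every group at 0% or 100%; "
                    "the ML slope diverges (use method='working-probit')"
                )
            b0, b1, cov = self._fit_ml()
        elif method == "working-probit":
            b0, b1, cov = self._fit_working_probit()
        else:
            raise ValueError(f"unknown method {method!r}")

        if b1 <= 0:
            raise NonIdentifiableError(
                f"{self.dataset.subject_label}: fitted slope {b1:.3g} <= 0; "
                "dose-response not monotone increasing"
            )
        if not (np.isfinite(cov).all() and np.isfinite([b0, b1]).all()):
            raise NonIdentifiableError(
                f"{self.dataset.subject_label}: unstable fit "
                "(quasi-separated data); covariance not finite"
            )
        return ProbitResults(self, b0, b1, cov, informative=informative)

    def _fit_ml(self):
        endog = np.column_stack([self.n_responders,
                                 self.n_subjects - self.n_responders])
        exog = sm.add_constant(self.log10_dose)
        family = sm.families.Binomial(link=sm.families.links.Probit())
        with warnings.catch_warnings():
            # boundary fitted probabilities at extreme doses are expected in
            # quantal designs; identifiability is checked separately above
            warnings.simplefilter("ignore")
            res = sm.GLM(endog, exog, family=family).fit(maxiter=200, tol=1e-12)
        b0, b1 = res.params
        cov = np.asarray(res.cov_params())
        return float(b0), float(b1), cov

    def _fit_working_probit(self, n_iter: int = 25):
        # Finney-style iteration: probits of corrected proportions, weights
        # n * phi(z)^2 / (p (1-p)) recomputed from the current line.
        n = self.n_subjects
        p_obs = np.clip(self.n_responders / n, 1.0 / (4 * n), 1 - 1.0 / (4 * n))
        x = self.log10_dose
        y = stats.norm.ppf(p_obs)
        w = np.ones_like(y)
        b0 = b1 = 0.0
        for _ in range(n_iter):
            W = np.diag(w)
            X = np.column_stack([np.ones_like(x), x])
            beta, *_ = np.linalg.lstsq(np.sqrt(W) @ X, np.sqrt(w) * y, rcond=None)
            b0, b1 = beta
            z = b0 + b1 * x
            p_hat = np.clip(stats.norm.cdf(z), 1e-10, 1 - 1e-10)
            phi = stats.norm.pdf(z)
            # working probit response and weights for the next round
            y = z + (p_obs - p_hat) / np.maximum(phi, 1e-12)
            w = n * phi**2 / (p_hat * (1 - p_hat))
        X = np.column_stack([np.ones_like(x), x])
        cov = np.linalg.inv(X.T @ np.diag(w) @ X)
        return float(b0), float(b1), cov


class ProbitResults:
    """Fitted log-probit line with ED50 +/- SEM and diagnostics.

    Attributes
    ----------
    intercept : float
        Probits of response at log10 dose = 0 (probit convention, 50% = 5).
    slope : float
        Probits per unit log10 dose (positive for protective agents).
    ed50, sem_ed50 : float
        Median effective dose and its delta-method SEM, mg/kg.
    log10_ed50, se_log10_ed50 : float
        Same on the log10 scale (the scale the line is fitted on).
    n_informative : int
        Animals in groups whose effect falls in the 4-6 probit band.
    covariance : ndarray
        2x2 covariance of (intercept, slope).
    """

    def __init__(self, model: QuantalProbitModel, b0: float, b1: float,
                 cov: np.ndarray, informative: str = "fitted"):
        self.model = model
        self.dataset = model.dataset
        self.intercept = b0 + PROBIT_OFFSET
        self.slope = b1
        self.covariance = np.asarray(cov, dtype=float)
        self.log10_ed50 = -b0 / b1
        # delta method on g(b) = -b0/b1: grad = (-1/b1, b0/b1^2)
        grad = np.array([-1.0 / b1, b0 / b1**2])
        var = float(grad @ self.covariance @ grad)
        self.se_log10_ed50 = math.sqrt(max(var, 0.0))
        self.ed50 = 10.0 ** self.log10_ed50
        self.sem_ed50 = self.ed50 * math.log(10.0) * self.se_log10_ed50
        self.se_slope = math.sqrt(max(self.covariance[1, 1], 0.0))
        self.n_total = model.dataset.n_total
        self.informative_convention = informative
        self.n_informative = count_informative(model.dataset, self,
                                               convention=informative)

    def predict_probit(self, dose) -> np.ndarray:
        """Fitted probits of response at the given dose(s), mg/kg."""
        dose = np.asarray(dose, dtype=float)
        return self.intercept + self.slope * np.log10(dose)

    def predict_proportion(self, dose) -> np.ndarray:
        return stats.norm.cdf(self.predict_probit(dose) - PROBIT_OFFSET)

    def conf_int_log10_ed50(self, alpha: float = 0.05) -> tuple[float, float]:
        """Normal-theory CI for log10 ED50."""
        z = stats.norm.ppf(1 - alpha / 2)
        return (self.log10_ed50 - z * self.se_log10_ed50,
                self.log10_ed50 + z * self.se_log10_ed50)

    def to_summary_record(self):
        from .data import SummaryEffectRecord

        return SummaryEffectRecord(self.dataset.subject_label, self.ed50,
                                   self.sem_ed50, max(self.n_informative, 2))

    def loglike(self) -> float:
        return self.model.loglike(self.intercept, self.slope)

    def summary(self) -> str:
        lines = [
            "Log-probit quantal dose-response fit",
            "=" * 52,
            f"subject:          {self.dataset.subject_label}",
            f"dose groups:      {len(self.dataset.groups)}"
            f"   animals: {self.n_total}",
            f"intercept:        {self.intercept:10.4f}  (probits at 1 mg/kg)",
            f"slope:            {self.slope:10.4f} ± {self.se_slope:.4f}"
            "  (probits / log10 dose)",
            f"log10 ED50:       {self.log10_ed50:10.4f} ± {self.se_log10_ed50:.4f}",
            f"ED50 (mg/kg):     {self.ed50:10.4f} ± {self.sem_ed50:.4f} (SEM)",
            f"n informative:    {self.n_informative:5d}  "
            f"({self.informative_convention} 4-6 probit band)",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<ProbitResults {self.dataset.subject_label}: "
                f"ED50={self.ed50:.4g}±{self.sem_ed50:.2g} mg/kg>")


def fit_log_probit(dataset: DoseResponseDataset, method: str = "ml",
                   informative: str = "fitted") -> ProbitResults:
    """Fit a log-probit line to one dataset (functional wrapper)."""
    return QuantalProbitModel(dataset).fit(method=method, informative=informative)


def count_informative(dataset: DoseResponseDataset, fit: ProbitResults,
                      convention: str = "fitted") -> int:
    """Animals in dose groups whose effect lies in the closed 4-6 probit band
    (16-84% protection).

    ``convention="fitted"`` (default) evaluates the fitted line at the tested
    doses; ``"observed"`` uses the observed proportions (0/n and n/n groups
    then never qualify, their probits being infinite).
    """
    if convention == "fitted":
        probits = fit.predict_probit(np.asarray(dataset.doses))
    elif convention == "observed":
        props = np.array([g.proportion for g in dataset.groups])
        with np.errstate(divide="ignore"):
            probits = PROBIT_OFFSET + stats.norm.ppf(props)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    in_band = (probits >= 4.0) & (probits <= 6.0)
    return int(sum(g.n_subjects for g, ok in zip(dataset.groups, in_band) if ok))


@dataclass(frozen=True)
class ParallelismTest:
    """Two-sided Welch test of slope equality between two fitted lines."""

    slope_a: float
    slope_b: float
    se_slope_a: float
    se_slope_b: float
    t: float
    df: float
    p: float
    parallel: bool
    alpha: float = 0.05


def test_parallelism(fit_a: ProbitResults, fit_b: ProbitResults,
                     alpha: float = 0.05) -> ParallelismTest:
    """Test whether two dose-response lines are parallel (equal slopes).

    Parallelism of the single-drug lines is the precondition for fixed-ratio
    isobolographic additivity, so it is checked before any mixture analysis.
    Uses t = (slope_a - slope_b) / sqrt(se_a^2 + se_b^2) with
    Welch-Satterthwaite degrees of freedom built from per-fit df = n_total - 2.
    """
    se_a, se_b = fit_a.se_slope, fit_b.se_slope
    if se_a <= 0 or se_b <= 0:
        raise ValueError("slope standard errors must be positive")
    va, vb = se_a**2, se_b**2
    t = (fit_a.slope - fit_b.slope) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (fit_a.n_total - 2)
                           + vb**2 / (fit_b.n_total - 2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return ParallelismTest(fit_a.slope, fit_b.slope, se_a, se_b,
                           t=t, df=df, p=min(p, 1.0), parallel=bool(p > alpha),
                           alpha=alpha)
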