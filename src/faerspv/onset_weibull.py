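"""Time-to-onset (TTO) analysis with the Weibull shape parameter test.

TTO is the number of days from initiation of the suspect drug to the
adverse-event date.  Pooled TTO values are summarised by median and
quartiles and fitted with a two-parameter Weibull distribution whose
density is

    f(t) = (β/α) (t/α)^{β−1} exp(−(t/α)^β),   t > 0,

with scale α (days) and dimensionless shape β.  The shape parameter and
its 95% CI classify the hazard:

* **early failure** — CI entirely below 1: the hazard decreases with
  time on drug (events cluster soon after initiation);
* **random failure** — CI contains 1: constant hazard (exponential);
* **wear-out failure** — CI entirely above 1: hazard increases.

Fitting maximises the likelihood in (log α, log β); 95% CIs are Wald
intervals on the log scale from the observed information at the optimum,
exponentiated back, so the bounds are always positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize
from statsmodels.tools.numdiff import approx_hess

from .faers_io import MISSING, PartialDate, RawTable, parse_faers_date, FaersParseError
from .curation import AEReport

__all__ = [
    "EULER_GAMMA",
    "OnsetSample",
    "TTOSummary",
    "TherapyRecord",
    "WeibullFit",
    "WeibullTTOModel",
    "WeibullTTOResults",
    "FitError",
    "therapy_from_table",
    "compute_tto",
    "median_iqr",
    "fit_weibull",
    "classify_profile",
    "round_half_up",
]

EULER_GAMMA = 0.5772156649015329

DEFAULT_MIN_N = 30  # smallest sample the Wald machinery is trusted on


class FitError(RuntimeError):
    """The likelihood optimiser failed to converge; carries diagnostics."""


@dataclass(frozen=True)
class TherapyRecord:
    """One THER row: start of therapy for one drug on one report."""

    primaryid: str
    dsg_drug_seq: str
    start_dt: PartialDate | None


@dataclass
class OnsetSample:
    """Usable positive day counts plus an exclusion audit."""

    values: np.ndarray
    n_source_reports: int
    n_excluded: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and self.values.min() <= 0:
            raise ValueError("onset values must be positive day counts")

    @property
    def n_usable(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class TTOSummary:
    """Median and quartiles in whole days."""

    median: int
    q25: int
    q75: int

    def __post_init__(self):
        if not self.q25 <= self.median <= self.q75:
            raise ValueError("quartiles out of order")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (the convention of printed clinical tables)."""
    from decimal import Decimal, ROUND_HALF_UP

    q = Decimal(1).scaleb(-ndigits)
    v = float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
    return v


def _to_date(pd_: PartialDate | None) -> date | None:
    """Day for day-precision, day 1 for month-precision, None otherwise."""
    if pd_ is None:
        return None
    if pd_.precision == "day":
        return date(pd_.year, pd_.month, min(pd_.day, _month_len(pd_.year, pd_.month)))
    if pd_.precision == "month":
        return date(pd_.year, pd_.month, 1)
    return None


def _month_len(year: int, month: int) -> int:
    import calendar

    return calendar.monthrange(year, month)[1]


def therapy_from_table(ther: RawTable) -> list[TherapyRecord]:
    records = []
    for rec in ther.iter_dicts():
        if rec.get("primaryid", MISSING) == MISSING:
            continue
        try:
            start = parse_faers_date(rec.get("start_dt", MISSING))
        except FaersParseError:
            start = None
        records.append(
            TherapyRecord(rec["primaryid"], rec.get("dsg_drug_seq", MISSING), start)
        )
    return records


def compute_tto(
    therapy_records: Iterable[TherapyRecord],
    demo_reports: Iterable[AEReport],
    case_ids: set[str],
    target_report_ids: set[str] | None = None,
    suspect_seqs: set[tuple[str, str]] | None = None,
) -> OnsetSample:
    """Days from earliest suspect-drug start to the event date, per report.

    *suspect_seqs* restricts therapy rows to (primaryid, drug_seq) pairs
    of suspect drugs; ``None`` uses every therapy row of the report.
    Reports with unusable dates (missing, or year-precision only) or
    non-positive intervals are excluded and counted.
    """
    scope = case_ids if target_report_ids is None else case_ids & target_report_ids
    event_by_id = {r.primaryid: r.event_dt for r in demo_reports}
    starts: dict[str, list[date]] = {}
    for t in therapy_records:
        if t.primaryid not in scope:
            continue
        if suspect_seqs is not None and (t.primaryid, t.dsg_drug_seq) not in suspect_seqs:
            continue
        d = _to_date(t.start_dt)
        if d is not None:
            starts.setdefault(t.primaryid, []).append(d)

    values: list[float] = []
    excl = {"missing_event_dt": 0, "missing_start_dt": 0, "nonpositive": 0}
    for pid in scope:
        event = _to_date(event_by_id.get(pid))
        if event is None:
            excl["missing_event_dt"] += 1
            continue
        if pid not in starts:
            excl["missing_start_dt"] += 1
            continue
        tto = (event - min(starts[pid])).days
        if tto <= 0:
            excl["nonpositive"] += 1
            continue
        values.append(float(tto))
    return OnsetSample(np.array(sorted(values)), len(scope), excl)


def median_iqr(sample: OnsetSample | Sequence[float]) -> TTOSummary:
    """Median and quartiles (linear interpolation), rounded half-up to days."""
    values = sample.values if isinstance(sample, OnsetSample) else np.asarray(sample, float)
    if values.size == 0:
        raise ValueError("cannot summarise an empty onset sample")
    q25, med, q75 = np.percentile(values, [25, 50, 75])
    return TTOSummary(
        int(round_half_up(med)), int(round_half_up(q25)), int(round_half_up(q75))
    )


# ---------------------------------------------------------------------------
# Weibull maximum likelihood


def _nll_and_grad(theta: np.ndarray, logx: np.ndarray) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and gradient in (log alpha, log beta)."""
    la, lb = theta
    beta = math.exp(lb)
    n = logx.size
    u = beta * (logx - la)          # = beta * ln(x/alpha)
    u = np.clip(u, -700.0, 700.0)   # guard overflow far from optimum
    z = np.exp(u)                   # (x/alpha)^beta
    sum_logx = float(logx.sum())
    ll = n * lb - beta * n * la + (beta - 1.0) * sum_logx - float(z.sum())
    d_la = beta * (float(z.sum()) - n)
    d_lb = n + beta * (sum_logx - n * la) - float((z * (logx - la)).sum()) * beta
    return -ll, -np.array([d_la, d_lb])


def _moment_start(logx: np.ndarray) -> np.ndarray:
    """Log-spacing moment start: Var(ln X) = pi^2 / (6 beta^2)."""
    s = float(np.std(logx))
    beta0 = math.pi / (math.sqrt(6.0) * s) if s > 0 else 1.0
    la0 = float(np.mean(logx)) + EULER_GAMMA / beta0
    return np.array([la0, math.log(beta0)])


class WeibullTTOModel:
    """Two-parameter Weibull model for positive onset times.

    Examples
    --------
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> t = 100 * rng.weibull(0.8, size=500)
    >>> res = WeibullTTOModel(t).fit()
    >>> 0.6 < res.beta < 1.0
    True
    """

    def __init__(self, values: Sequence[float] | OnsetSample, min_n: int = DEFAULT_MIN_N):
        if isinstance(values, OnsetSample):
            values = values.values
        self.values = np.asarray(values, dtype=float)
        if self.values.size and self.values.min() <= 0:
            raise ValueError("Weibull support is t > 0")
        if self.values.size < min_n:
            raise ValueError(
                f"need at least {min_n} usable onset values, got {self.values.size}"
            )
        self._logx = np.log(self.values)

    @property
    def nobs(self) -> int:
        return int(self.values.size)

    def loglike(self, alpha: float, beta: float) -> float:
        nll, _ = _nll_and_grad(np.array([math.log(alpha), math.log(beta)]), self._logx)
        return -nll

    def fit(self, tol: float = 1e-8) -> "WeibullTTOResults":
        theta0 = _moment_start(self._logx)
        opt = minimize(
            _nll_and_grad,
            theta0,
            args=(self._logx,),
            jac=True,
            method="L-BFGS-B",
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
        )
        if not opt.success and float(np.max(np.abs(opt.jac))) > 1e-3 * self.nobs:
            raise FitError(f"Weibull MLE did not converge: {opt.message}")
        theta = opt.x
        hess = approx_hess(theta, lambda th: _nll_and_grad(th, self._logx)[0])
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate data
            raise FitError(f"observed information singular: {exc}") from exc
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        return WeibullTTOResults(self, theta, se, -opt.fun)


@dataclass(frozen=True)
class WeibullFit:
    """Point estimates, 95% CIs and failure-profile label."""

    alpha: float
    beta: float
    alpha_ci: tuple[float, float]
    beta_ci: tuple[float, float]
    profile: str

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Weibull parameters must be positive")
        for lo, hi in (self.alpha_ci, self.beta_ci):
            if not 0 < lo <= hi:
                raise ValueError("CI bounds must be positive and ordered")


def classify_profile(fit: "WeibullFit | WeibullTTOResults") -> str:
    """Hazard classification from the shape-parameter CI (exhaustive rules)."""
    lo, hi = fit.beta_ci
    if hi < 1.0:
        return "early failure"
    if lo > 1.0:
        return "wear-out failure"
    return "random failure"


class WeibullTTOResults:
    """Fitted Weibull TTO model: estimates, Wald CIs, profile, summary."""

    Z = 1.959963984540054

    def __init__(self, model: WeibullTTOModel, theta: np.ndarray,
                 se_log: np.ndarray, llf: float):
        self.model = model
        self._theta = theta            # (log alpha, log beta)
        self._se_log = se_log
        self.llf = float(llf)

    @property
    def alpha(self) -> float:
        return float(math.exp(self._theta[0]))

    @property
    def beta(self) -> float:
        return float(math.exp(self._theta[1]))

    def _ci(self, i: int) -> tuple[float, float]:
        lo = math.exp(self._theta[i] - self.Z * self._se_log[i])
        hi = math.exp(self._theta[i] + self.Z * self._se_log[i])
        return (float(lo), float(hi))

    @property
    def alpha_ci(self) -> tuple[float, float]:
        return self._ci(0)

    @property
    def beta_ci(self) -> tuple[float, float]:
        return self._ci(1)

    @property
    def profile(self) -> str:
        return classify_profile(self)

    @property
    def nobs(self) -> int:
        return self.model.nobs

    def median(self) -> float:
        """Model-implied median alpha * (ln 2)^(1/beta)."""
        return self.alpha * math.log(2.0) ** (1.0 / self.beta)

    def as_fit(self) -> WeibullFit:
        return WeibullFit(self.alpha, self.beta, self.alpha_ci, self.beta_ci,
                          self.profile)

    def summary(self) -> str:
        a_lo, a_hi = self.alpha_ci
        b_lo, b_hi = self.beta_ci
        return "\n".join(
            [
                "Weibull time-to-onset fit",
                f"n = {self.nobs}, log-likelihood = {self.llf:.2f}",
                f"scale alpha = {self.alpha:.2f} days (95% CI {a_lo:.2f}-{a_hi:.2f})",
                f"shape beta  = {self.beta:.2f}      (95% CI {b_lo:.2f}-{b_hi:.2f})",
                f"failure profile: {self.profile}",
            ]
        )


def fit_weibull(
    sample: OnsetSample | Sequence[float], min_n: int = DEFAULT_MIN_N
) -> WeibullFit:
    """Functional wrapper: MLE fit returning the frozen :class:`WeibullFit`."""
    return WeibullTTOModel(sample, min_n=min_n).fit().as_fit()
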