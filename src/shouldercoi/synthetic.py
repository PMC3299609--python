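"""Synthetic electronic-patient-record cohorts for shoulder-pain costing.

The generator emulates a six-month primary-care cohort: 204 adults aged
20-64 presenting with shoulder pain to a GP or physiotherapist in two
municipalities.  Its statistical targets are the published utilization
margins: mean (SD) GP visits 0.89 (0.97), PT visits 3.91 (7.40), x-ray and
ultrasound probabilities 0.28 / 0.11, prescription probability 0.28, 20%
of patients with any sick leave averaging 9.04 (29.17) days, and 11% of
sick-leave days at a partial grade.

Modelling choices:

* Visit counts are zero-inflated negative binomial, moment-matched to the
  target mean/SD (the PT variance is far above its mean, so a Poisson
  cannot reproduce it).
* Every patient presented at least once, so a patient whose sampled GP and
  PT counts are both zero receives one index visit; the count-distribution
  means are pre-adjusted by a fixed-point iteration so the marginal means
  still hit their targets after this correction.
* Sick-leave occurrence and duration are coupled to the PT visit count
  through a Gaussian copula (positive dependence), so the expensive tail
  co-occurs with heavy utilization, as the published high-cost subgroup
  shows.  Durations are lognormal, capped at the window length, with
  (mu, sigma) solved numerically so the *capped* moments match the targets.
* A fraction of each sick-leave spell is prescribed at a partial grade
  drawn uniformly from {25, 50, 75}%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
import numpy as np
from scipy import optimize, stats

from .cohort import (
    CATEGORY_CODES,
    DiagnosisCategory,
    DrugClass,
    ImagingEvent,
    MedicationPrescription,
    Modality,
    PatientRecord,
    Provider,
    Sex,
    SickLeavePrescription,
    VisitEvent,
    Window,
)
from .errors import ConfigurationError

__all__ = [
    "CountDistParams",
    "DurationDistParams",
    "SyntheticCohortConfig",
    "generate_cohort",
    "GENERATED_CATEGORIES",
]

#: Diagnosis categories the generator samples from, in weight order.
GENERATED_CATEGORIES = (
    DiagnosisCategory.SUBACROMIAL_PAIN,
    DiagnosisCategory.STIFFNESS,
    DiagnosisCategory.FRACTURE,
    DiagnosisCategory.DISLOCATION,
)

_PARTIAL_GRADES = (25, 50, 75)


@dataclass(frozen=True)
class CountDistParams:
    """Zero-inflated negative binomial, parameterized by its marginal moments."""

    mean: float
    sd: float
    zero_inflation: float = 0.0


@dataclass(frozen=True)
class DurationDistParams:
    """Heavy-tailed (lognormal) sick-leave duration, marginal over the cohort.

    ``mean`` and ``sd`` are per-patient full-day targets including the
    zero-day patients; the conditional distribution given any sick leave is
    derived from them together with the any-sick-leave probability.
    """

    mean: float = 9.04
    sd: float = 29.17


@dataclass
class SyntheticCohortConfig:
    """Study-condition defaults for the synthetic cohort generator."""

    n_patients: int = 204
    age_range: tuple[int, int] = (20, 64)
    age_mean: float = 48.0
    age_sd: float = 11.0
    female_fraction: float = 103 / 204
    #: weights over (subacromial pain, stiffness, fracture, dislocation)
    category_weights: tuple[float, float, float, float] = (
        181 / 204,
        10 / 204,
        7 / 204,
        6 / 204,
    )
    gp_visits_dist: CountDistParams = field(
        default_factory=lambda: CountDistParams(mean=0.89, sd=0.97)
    )
    pt_visits_dist: CountDistParams = field(
        default_factory=lambda: CountDistParams(mean=3.91, sd=7.40)
    )
    xray_prob: float = 0.28
    ultrasound_prob: float = 0.11
    rx_prob: float = 0.28
    referral_prob: float = 29 / 204
    surgery_given_referral_prob: float = 4 / 29
    postop_rehab_prob: float = 19 / 204
    sickleave_any_prob: float = 0.20
    sickleave_days_dist: DurationDistParams = field(default_factory=DurationDistParams)
    partial_fraction: float = 0.11
    #: Gaussian-copula correlation between PT visit count and sick leave
    pt_sickleave_dependence: float = 0.4
    window: Window = field(
        default_factory=lambda: Window(date(2009, 1, 1), date(2009, 6, 30))
    )
    holiday_window: Window | None = None
    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the first invalid field."""
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        lo, hi = self.age_range
        if not (20 <= lo <= hi <= 64):
            raise ConfigurationError("age_range must lie within [20, 64]")
        for name in (
            "female_fraction",
            "xray_prob",
            "ultrasound_prob",
            "rx_prob",
            "referral_prob",
            "surgery_given_referral_prob",
            "postop_rehab_prob",
            "sickleave_any_prob",
            "partial_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a proportion in [0, 1]")
        w = np.asarray(self.category_weights, dtype=float)
        if (w < 0).any() or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
            raise ConfigurationError("category_weights must be non-negative and sum to 1")
        for name in ("gp_visits_dist", "pt_visits_dist"):
            d: CountDistParams = getattr(self, name)
            if d.mean < 0 or d.sd <= 0 or not 0 <= d.zero_inflation < 1:
                raise ConfigurationError(f"{name} has invalid distribution parameters")
        d = self.sickleave_days_dist
        if d.mean <= 0 or d.sd <= 0:
            raise ConfigurationError("sickleave_days_dist has invalid distribution parameters")
        if not -1.0 < self.pt_sickleave_dependence < 1.0:
            raise ConfigurationError("pt_sickleave_dependence must be in (-1, 1)")
        if self.age_sd <= 0:
            raise ConfigurationError("age_sd must be > 0")


# ---------------------------------------------------------------------------
# count distributions


@dataclass(frozen=True)
class _CountFit:
    """Fitted sampling form of a zero-inflated count distribution."""

    zero_inflation: float
    kind: str  # "nb" or "poisson"
    r: float = 0.0
    p: float = 0.0
    lam: float = 0.0

    def ppf(self, u: np.ndarray) -> np.ndarray:
        out = np.zeros(u.shape, dtype=np.int64)
        mask = u >= self.zero_inflation
        uu = (u[mask] - self.zero_inflation) / (1.0 - self.zero_inflation)
        if self.kind == "nb":
            out[mask] = stats.nbinom.ppf(uu, self.r, self.p).astype(np.int64)
        else:
            out[mask] = stats.poisson.ppf(uu, self.lam).astype(np.int64)
        return out

    @property
    def zero_prob(self) -> float:
        if self.kind == "nb":
            p0 = stats.nbinom.pmf(0, self.r, self.p)
        else:
            p0 = stats.poisson.pmf(0, self.lam)
        return self.zero_inflation + (1.0 - self.zero_inflation) * float(p0)


def _fit_count_dist(params: CountDistParams, mean_override: float | None = None) -> _CountFit:
    """Moment-match the non-zero-inflated part to the marginal mean/SD targets."""
    pi = params.zero_inflation
    m = params.mean if mean_override is None else mean_override
    v = params.sd**2
    mu_nb = m / (1.0 - pi)
    # marginal second moment = (1-pi) * (var_nb + mu_nb^2)
    var_nb = (v + m**2) / (1.0 - pi) - mu_nb**2
    if var_nb > mu_nb:
        r = mu_nb**2 / (var_nb - mu_nb)
        p = r / (r + mu_nb)
        return _CountFit(zero_inflation=pi, kind="nb", r=r, p=p)
    return _CountFit(zero_inflation=pi, kind="poisson", lam=mu_nb)


def _adjust_means_for_index_visit(
    cfg: SyntheticCohortConfig,
) -> tuple[_CountFit, _CountFit, float]:
    """Pre-shrink the count means so the index-visit correction is unbiased.

    Patients sampled with zero GP and zero PT visits receive one index
    visit (GP with probability proportional to the GP share of visits).
    This fixed point chooses adjusted sampling means so the final marginal
    means equal the configured targets.
    """
    m_gp, m_pt = cfg.gp_visits_dist.mean, cfg.pt_visits_dist.mean
    if m_gp + m_pt <= 0:
        raise ConfigurationError(
            "gp_visits_dist/pt_visits_dist: at least one visit mean must be positive"
        )
    w_gp = m_gp / (m_gp + m_pt)
    adj_gp, adj_pt = m_gp, m_pt
    for _ in range(100):
        fit_gp = _fit_count_dist(cfg.gp_visits_dist, adj_gp)
        fit_pt = _fit_count_dist(cfg.pt_visits_dist, adj_pt)
        p00 = fit_gp.zero_prob * fit_pt.zero_prob
        new_gp = max(m_gp - w_gp * p00, 1e-9)
        new_pt = max(m_pt - (1.0 - w_gp) * p00, 1e-9)
        if abs(new_gp - adj_gp) < 1e-12 and abs(new_pt - adj_pt) < 1e-12:
            break
        adj_gp, adj_pt = new_gp, new_pt
    return _fit_count_dist(cfg.gp_visits_dist, adj_gp), _fit_count_dist(
        cfg.pt_visits_dist, adj_pt
    ), w_gp


# ---------------------------------------------------------------------------
# sick-leave duration


def _capped_lognormal_moments(mu: float, sigma: float, cap: float) -> tuple[float, float]:
    """Mean and SD of min(LogNormal(mu, sigma), cap)."""
    lc = math.log(cap)
    z = (lc - mu) / sigma
    a1 = math.exp(mu + sigma**2 / 2) * stats.norm.cdf(z - sigma) + cap * stats.norm.sf(z)
    a2 = (
        math.exp(2 * mu + 2 * sigma**2) * stats.norm.cdf(z - 2 * sigma)
        + cap**2 * stats.norm.sf(z)
    )
    return a1, math.sqrt(max(a2 - a1**2, 0.0))


def _solve_duration_params(
    dist: DurationDistParams, any_prob: float, cap_days: int
) -> tuple[float, float]:
    """(mu, sigma) of the lognormal whose window-capped moments hit the targets.

    Targets are conditional on having any sick leave: mean = marginal mean
    / P(any), and the conditional SD follows from the marginal moments.
    """
    mc = dist.mean / any_prob
    e2 = (dist.sd**2 + dist.mean**2) / any_prob
    vc = e2 - mc**2
    if vc <= 0:
        raise ConfigurationError("sickleave_days_dist: implied conditional variance <= 0")
    sc = math.sqrt(vc)
    if mc >= cap_days:
        raise ConfigurationError(
            "sickleave_days_dist: conditional mean exceeds the measurement window"
        )

    # start from the uncapped lognormal moment match
    sigma0 = math.sqrt(math.log(1.0 + vc / mc**2))
    mu0 = math.log(mc) - sigma0**2 / 2

    def eqs(x: np.ndarray) -> np.ndarray:
        mu, log_sigma = x
        m, s = _capped_lognormal_moments(mu, math.exp(log_sigma), cap_days)
        return np.array([m - mc, s - sc])

    sol, info, ok, _ = optimize.fsolve(
        eqs, np.array([mu0, math.log(sigma0)]), full_output=True
    )
    if ok == 1 and np.abs(info["fvec"]).max() < 1e-6 * max(mc, sc):
        return float(sol[0]), float(math.exp(sol[1]))
    # capping infeasible for these targets: fall back to the uncapped match
    return mu0, sigma0


# ---------------------------------------------------------------------------
# cohort generation


def _sample_ages(cfg: SyntheticCohortConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.age_range
    a = (lo - 0.5 - cfg.age_mean) / cfg.age_sd
    b = (hi + 0.5 - cfg.age_mean) / cfg.age_sd
    raw = stats.truncnorm.ppf(
        rng.random(cfg.n_patients), a, b, loc=cfg.age_mean, scale=cfg.age_sd
    )
    return np.clip(np.round(raw), lo, hi).astype(int)


def _visit_offsets(
    n_visits: int, max_offset: int, rng: np.random.Generator
) -> np.ndarray:
    """Day offsets of a patient's visits from the window start.

    Inter-visit gaps are 3-28 days so every simulated history forms a
    single treatment episode under the one-month gap rule; long histories
    are compressed proportionally to fit the window.
    """
    if n_visits == 1:
        return np.array([rng.integers(0, max_offset + 1)])
    gaps = rng.integers(3, 29, size=n_visits - 1)
    pos = np.concatenate([[0], np.cumsum(gaps)])
    span = int(pos[-1])
    if span > max_offset:
        pos = np.round(pos * (max_offset / span)).astype(int)
        span = int(pos[-1])
    start = int(rng.integers(0, max_offset - span + 1))
    return pos + start


def _make_sick_leave(
    first_offset: int,
    n_days: int,
    cfg: SyntheticCohortConfig,
    rng: np.random.Generator,
) -> list[SickLeavePrescription]:
    """One sick-leave spell starting at the first visit, split into a full-grade
    part and (for ``partial_fraction`` of its days) a partial-grade tail."""
    window = cfg.window
    max_start = window.n_days - n_days
    start_off = min(first_offset, max_start)
    start = window.start + timedelta(days=int(max(start_off, 0)))

    n_partial = int(round(cfg.partial_fraction * n_days))
    n_full = n_days - n_partial
    spells: list[SickLeavePrescription] = []
    if n_full > 0:
        spells.append(
            SickLeavePrescription(start, start + timedelta(days=n_full - 1), grade=100)
        )
    if n_partial > 0:
        grade = int(rng.choice(_PARTIAL_GRADES))
        p_start = start + timedelta(days=n_full)
        spells.append(
            SickLeavePrescription(p_start, p_start + timedelta(days=n_partial - 1), grade=grade)
        )
    return spells


def generate_cohort(
    config: SyntheticCohortConfig | None = None, seed: int | None = None
) -> list[PatientRecord]:
    """Generate a synthetic shoulder-pain cohort.

    Deterministic for a fixed (config, seed); ``seed`` overrides
    ``config.seed`` when given.  Every record satisfies the record
    invariants and all event dates fall inside the configured window.
    """
    cfg = config or SyntheticCohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_patients
    if n == 0:
        return []

    window = cfg.window
    max_offset = window.n_days - 1

    ages = _sample_ages(cfg, rng)
    female = rng.random(n) < cfg.female_fraction
    municipality = rng.integers(0, 2, size=n)
    categories = rng.choice(len(GENERATED_CATEGORIES), size=n, p=cfg.category_weights)

    fit_gp, fit_pt, w_gp = _adjust_means_for_index_visit(cfg)
    rho = cfg.pt_sickleave_dependence
    z_pt = rng.standard_normal(n)
    z_extra = rng.standard_normal(n)
    z_sl = rho * z_pt + math.sqrt(1.0 - rho**2) * z_extra

    gp_counts = fit_gp.ppf(rng.random(n))
    pt_counts = fit_pt.ppf(stats.norm.cdf(z_pt))
    index_coin = rng.random(n) < w_gp
    both_zero = (gp_counts == 0) & (pt_counts == 0)
    gp_counts[both_zero & index_coin] += 1
    pt_counts[both_zero & ~index_coin] += 1

    u_sl = stats.norm.cdf(z_sl)
    has_sl = u_sl > 1.0 - cfg.sickleave_any_prob
    mu_d, sigma_d = _solve_duration_params(
        cfg.sickleave_days_dist, cfg.sickleave_any_prob, window.n_days
    )
    v = np.clip((u_sl - (1.0 - cfg.sickleave_any_prob)) / cfg.sickleave_any_prob, 0, 1)
    with np.errstate(divide="ignore"):
        raw_days = np.exp(mu_d + sigma_d * stats.norm.ppf(np.where(has_sl, v, 0.5)))
    sl_days = np.clip(np.round(raw_days), 1, window.n_days).astype(int)

    has_xray = rng.random(n) < cfg.xray_prob
    has_us = rng.random(n) < cfg.ultrasound_prob
    has_rx = rng.random(n) < cfg.rx_prob
    referred = rng.random(n) < cfg.referral_prob
    operated = referred & (rng.random(n) < cfg.surgery_given_referral_prob)
    postop = rng.random(n) < cfg.postop_rehab_prob

    records: list[PatientRecord] = []
    for i in range(n):
        category = GENERATED_CATEGORIES[categories[i]]
        codes = sorted(CATEGORY_CODES[category])
        n_vis = int(gp_counts[i] + pt_counts[i])
        offsets = _visit_offsets(n_vis, max_offset, rng)
        provider_pool = [Provider.GP] * int(gp_counts[i]) + [Provider.PT] * int(pt_counts[i])
        providers = [provider_pool[j] for j in rng.permutation(n_vis)]
        visit_codes = rng.choice(len(codes), size=n_vis)
        visits = [
            VisitEvent(
                date=window.start + timedelta(days=int(off)),
                provider=prov,
                codes=(codes[int(ci)],),
            )
            for off, prov, ci in zip(offsets, providers, visit_codes)
        ]
        first_off, last_off = int(offsets.min()), int(offsets.max())

        imaging = []
        for flag, modality in ((has_xray[i], Modality.XRAY), (has_us[i], Modality.ULTRASOUND)):
            if flag:
                off = int(rng.integers(first_off, last_off + 1))
                imaging.append(
                    ImagingEvent(window.start + timedelta(days=off), modality)
                )
        prescriptions = []
        if has_rx[i]:
            off = int(rng.integers(first_off, last_off + 1))
            drug = DrugClass.ANALGESIC if rng.random() < 0.5 else DrugClass.NSAID
            prescriptions.append(
                MedicationPrescription(window.start + timedelta(days=off), drug)
            )
        sick_leaves = (
            _make_sick_leave(first_off, int(sl_days[i]), cfg, rng) if has_sl[i] else []
        )

        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:04d}",
                age=int(ages[i]),
                sex=Sex.FEMALE if female[i] else Sex.MALE,
                municipality=("municipality_a", "municipality_b")[int(municipality[i])],
                visits=visits,
                sick_leaves=sick_leaves,
                prescriptions=prescriptions,
                imaging=imaging,
                referrals=int(referred[i]),
                surgeries=int(operated[i]),
                postoperative_rehab=bool(postop[i]),
            )
        )
    return records
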