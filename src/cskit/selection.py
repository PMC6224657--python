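"""Per-dose selection dynamics of a drug-resistant clone in a mixed population.

A mutant clone whose cells die less readily under a cytotoxic drug gains a
per-dose fitness advantage even when its proliferation rate is unchanged.
With apoptotic fractions ``a_mut`` and ``a_wt`` per dose, the live-cell
ratio shifts by

    r = (1 - a_mut) / (1 - a_wt)

per treatment round.  Two ways of compounding r over n rounds are exposed:

* ``compound_naive`` multiplies the starting *proportion* by r**n and clamps
  at 1.  This mirrors the back-of-envelope calculation often quoted for
  competition experiments (e.g. 20% * 1.46**4 ~ 90%) but is not a proper
  probability update.
* ``compound_normalized`` applies r**n to the *odds* f/(1-f), which is the
  mathematically consistent two-clone update and the default for simulation
  and fitting.

The stochastic counterpart (``simulate_competition``) draws binomial
survival per clone per dose, with clone-neutral regrowth between doses, and
binomial sampling noise at each measurement (a flow-cytometry count).
``fit_fitness`` inverts the model: given measured (mutant, total) counts and
the cumulative dose count at each time, it maximizes the binomial likelihood
over r, profiling out the baseline fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SelectionParams",
    "CompetitionSpec",
    "Trajectory",
    "FitnessEstimate",
    "survival_ratio",
    "compound_naive",
    "compound_normalized",
    "predict_trajectory",
    "simulate_competition",
    "fit_fitness",
    "normalize_foldchange",
    "pool_trajectories",
]

#: Profile-likelihood cutoff for a 95% CI: chi2(1) quantile.
CHI2_95_CUTOFF = 3.841458820694124
#: Search box for the per-dose ratio r.
R_BOUNDS = (0.2, 5.0)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionParams:
    """Deterministic model parameters.

    f0     starting mutant fraction, in (0, 1)
    r      per-dose live-cell ratio mutant:WT, > 0
    model  'naive' (proportion times r**n, clamped) or 'normalized'
           (odds times r**n)
    """

    f0: float
    r: float
    model: str = "normalized"

    def __post_init__(self) -> None:
        if not 0.0 < self.f0 < 1.0:
            raise ValueError(f"f0 must be in (0, 1), got {self.f0}")
        if self.r <= 0.0:
            raise ValueError(f"r must be > 0, got {self.r}")
        if self.model not in ("naive", "normalized"):
            raise ValueError(f"model must be 'naive' or 'normalized', got {self.model!r}")


@dataclass(frozen=True)
class CompetitionSpec:
    """A mixing/competition experiment: two clones, repeated dosing.

    Defaults describe a 20:80 mutant:WT mix of ~1e6 cells dosed every
    4 days for 4 doses, with per-dose apoptotic fractions 0.49 (mutant)
    and 0.65 (WT), flow measurements of 10,000 cells on days 0/4/8/12/15,
    in triplicate.
    """

    f0: float = 0.20
    n0: int = 1_000_000
    a_mut: float = 0.49
    a_wt: float = 0.65
    growth: float = 2.0
    n_doses: int = 4
    dose_interval_days: float = 4.0
    measure_days: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 15.0)
    sample_size: int = 10_000
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.f0 < 1.0:
            raise ValueError(f"f0 must be in (0, 1), got {self.f0}")
        if self.n0 < 2:
            raise ValueError(f"n0 must be >= 2, got {self.n0}")
        for name in ("a_mut", "a_wt"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.growth < 1.0:
            raise ValueError(f"growth must be >= 1, got {self.growth}")
        if self.n_doses < 0:
            raise ValueError(f"n_doses must be >= 0, got {self.n_doses}")
        if self.dose_interval_days <= 0:
            raise ValueError(f"dose_interval_days must be > 0, got {self.dose_interval_days}")
        if self.sample_size < 1:
            raise ValueError(f"sample_size must be >= 1, got {self.sample_size}")
        if self.replicates < 0:
            raise ValueError(f"replicates must be >= 0, got {self.replicates}")
        md = tuple(self.measure_days)
        if any(t2 < t1 for t1, t2 in zip(md, md[1:])):
            raise ValueError("measure_days must be non-decreasing")
        object.__setattr__(self, "measure_days", md)

    @property
    def dose_days(self) -> tuple[float, ...]:
        return tuple(i * self.dose_interval_days for i in range(self.n_doses))

    @property
    def horizon_days(self) -> float:
        """Last simulated day: one dose interval past the final dose."""
        return self.n_doses * self.dose_interval_days

    def ratio(self) -> float:
        return survival_ratio(self.a_mut, self.a_wt)


@dataclass
class Trajectory:
    """Time-ordered (day, mutant_count, total_count) measurements."""

    points: list[tuple[float, int, int]]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [p[0] for p in self.points]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("trajectory times must be non-decreasing")
        for t, k, n in self.points:
            if not 0 <= k <= n:
                raise ValueError(f"need 0 <= mutant_count <= total_count at day {t}, got {k}/{n}")

    @property
    def times(self) -> list[float]:
        return [p[0] for p in self.points]

    @property
    def fractions(self) -> list[float]:
        """Mutant fraction per point; NaN where total_count == 0."""
        return [k / n if n > 0 else math.nan for _, k, n in self.points]

    def to_records(self, replicate: int = 0) -> list[dict]:
        return [
            {"replicate": replicate, "day": t, "mutant_count": k, "total_count": n}
            for t, k, n in self.points
        ]


@dataclass
class FitnessEstimate:
    """Maximum-likelihood per-dose ratio with a profile-likelihood 95% CI."""

    r_hat: float
    ci_low: float
    ci_high: float
    loglik: float
    n_obs: int
    converged: bool
    f0_hat: float = math.nan
    model: str = "normalized"

    def __post_init__(self) -> None:
        if self.converged and not (self.ci_low <= self.r_hat <= self.ci_high):
            raise ValueError("converged estimate requires ci_low <= r_hat <= ci_high")


# ---------------------------------------------------------------------------
# deterministic model
# ---------------------------------------------------------------------------

def survival_ratio(a_mut: float, a_wt: float) -> float:
    """Per-dose live-cell ratio (1 - a_mut) / (1 - a_wt).

    With 49% apoptotic mutant cells and 65% apoptotic WT cells the surviving
    pools are 51:35, a ratio of ~1.46 per dose.
    """
    if not 0.0 <= a_mut < 1.0:
        raise ValueError(f"a_mut must be in [0, 1), got {a_mut}")
    if not 0.0 <= a_wt < 1.0:
        raise ValueError(f"a_wt must be in [0, 1), got {a_wt}")
    return (1.0 - a_mut) / (1.0 - a_wt)


def compound_naive(f0: float, r: float, n: int) -> float:
    """Proportion-times-ratio compounding: min(f0 * r**n, 1).

    Treats the ratio as acting directly on a proportion (the back-of-envelope
    convention, e.g. 0.20 * 1.457**4 -> 0.90); clamped at 1 because the
    product is not a true probability.
    """
    _check_compound_args(f0, r, n)
    return min(f0 * r ** n, 1.0)


def compound_normalized(f0: float, r: float, n: int) -> float:
    """Odds-update compounding: odds_n = [f0/(1-f0)] * r**n, returned as a fraction.

    The consistent two-clone update: mutant and WT pools each shrink by
    their own survival per dose, so their ratio (the odds) multiplies by r.
    Always in (0, 1).
    """
    _check_compound_args(f0, r, n)
    odds = f0 / (1.0 - f0) * r ** n
    return odds / (1.0 + odds)


def _check_compound_args(f0: float, r: float, n: int) -> None:
    if not 0.0 < f0 < 1.0:
        raise ValueError(f"f0 must be in (0, 1), got {f0}")
    if r <= 0.0:
        raise ValueError(f"r must be > 0, got {r}")
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")


def predict_trajectory(params: SelectionParams, n_doses: int) -> list[float]:
    """Expected mutant fraction after 0, 1, ..., n_doses doses."""
    fn = compound_naive if params.model == "naive" else compound_normalized
    return [fn(params.f0, params.r, k) for k in range(n_doses + 1)]


# ---------------------------------------------------------------------------
# stochastic simulator
# ---------------------------------------------------------------------------

def simulate_competition(
    spec: CompetitionSpec,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
    *,
    n_mut0: int | None = None,
    n_wt0: int | None = None,
) -> Trajectory:
    """Simulate one replicate of a two-clone competition under repeated dosing.

    Per dose: binomial survival of each clone with probabilities 1 - a_mut
    and 1 - a_wt, then deterministic clone-neutral regrowth by ``spec.growth``.
    At each measure day a binomial sample of ``spec.sample_size`` cells is
    recorded (measurements on a dose day precede the dose).  Zero counts are
    absorbing; if the whole population dies the trajectory is truncated and
    flagged in ``meta['extinct_day']`` rather than raising.

    ``n_mut0``/``n_wt0`` override the initial pools (used by the chimerism
    generator to model an engraftment bottleneck).
    """
    if seed is None:
        seed = spec.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    horizon = spec.horizon_days
    for t in spec.measure_days:
        if t > horizon:
            raise ValueError(
                f"measure day {t} is beyond the simulated horizon of {horizon} days"
            )

    if n_mut0 is None:
        n_mut0 = int(round(spec.f0 * spec.n0))
    if n_wt0 is None:
        n_wt0 = spec.n0 - int(round(spec.f0 * spec.n0))
    n_mut, n_wt = int(n_mut0), int(n_wt0)

    dose_days = set(spec.dose_days)
    events = sorted(dose_days | set(spec.measure_days))
    points: list[tuple[float, int, int]] = []
    meta: dict = {
        "f0": spec.f0,
        "a_mut": spec.a_mut,
        "a_wt": spec.a_wt,
        "r_true": spec.ratio(),
        "n_doses": spec.n_doses,
    }

    for t in events:
        n_measure = sum(1 for m in spec.measure_days if m == t)
        for _ in range(n_measure):
            total = n_mut + n_wt
            if total == 0:
                meta["extinct_day"] = t
                return Trajectory(points=points, meta=meta)
            k = int(rng.binomial(spec.sample_size, n_mut / total))
            points.append((t, k, spec.sample_size))
        if t in dose_days:
            if n_mut > 0:
                n_mut = int(rng.binomial(n_mut, 1.0 - spec.a_mut))
            if n_wt > 0:
                n_wt = int(rng.binomial(n_wt, 1.0 - spec.a_wt))
            # clone-neutral regrowth: rescales counts, leaves the fraction alone
            n_mut = int(round(n_mut * spec.growth))
            n_wt = int(round(n_wt * spec.growth))
        if n_mut + n_wt == 0:
            meta["extinct_day"] = t
            break

    return Trajectory(points=points, meta=meta)


def pool_trajectories(trajectories: Sequence[Trajectory]) -> Trajectory:
    """Sum mutant and total counts across replicates at matching times."""
    if not trajectories:
        raise ValueError("need at least one trajectory to pool")
    acc: dict[float, list[int]] = {}
    for traj in trajectories:
        for t, k, n in traj.points:
            kk = acc.setdefault(t, [0, 0])
            kk[0] += k
            kk[1] += n
    points = [(t, acc[t][0], acc[t][1]) for t in sorted(acc)]
    return Trajectory(points=points, meta={"pooled_from": len(trajectories)})


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _model_fraction(f0: float, r: float, doses: np.ndarray, model: str) -> np.ndarray:
    if model == "naive":
        return np.minimum(f0 * r ** doses, 1.0)
    odds = f0 / (1.0 - f0) * r ** doses
    return odds / (1.0 + odds)


def fit_fitness(
    traj: Trajectory,
    doses_before: Mapping[float, int],
    model: str = "normalized",
) -> FitnessEstimate:
    """Maximum-likelihood per-dose ratio r from a measured trajectory.

    ``doses_before`` maps each measurement time to the cumulative number of
    doses delivered before that measurement.  The binomial log-likelihood
    sum_i log Bin(k_i | n_i, p_model(f0, r; d_i)) is maximized by a bounded
    1-D search on log r in [ln 0.2, ln 5], with the baseline fraction f0
    profiled out by an inner bounded search.  The 95% CI is the profile
    likelihood interval at the chi2(1) cutoff, clipped to the search box
    where the likelihood never drops below the cutoff.

    Degenerate data (every measurement at fraction 0 or at fraction 1)
    yields a non-converged estimate with infinite bounds.
    """
    if model not in ("naive", "normalized"):
        raise ValueError(f"model must be 'naive' or 'normalized', got {model!r}")
    obs = [(t, k, n) for t, k, n in traj.points if n > 0]
    if len(obs) < 2:
        raise ValueError("need at least 2 measurements with total_count > 0")
    try:
        doses = np.array([float(doses_before[t]) for t, _, _ in obs])
    except KeyError as exc:
        raise ValueError(f"doses_before has no entry for measurement time {exc.args[0]}") from None
    k = np.array([p[1] for p in obs], dtype=float)
    n = np.array([p[2] for p in obs], dtype=float)

    if np.all(k == 0) or np.all(k == n):
        return FitnessEstimate(
            r_hat=math.nan, ci_low=-math.inf, ci_high=math.inf,
            loglik=0.0, n_obs=len(obs), converged=False, model=model,
        )

    eps = 1e-12

    def loglik(f0: float, r: float) -> float:
        p = np.clip(_model_fraction(f0, r, doses, model), eps, 1.0 - eps)
        return float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))

    f0_bounds = (1e-6, 1.0 - 1e-6)

    def profile(log_r: float) -> tuple[float, float]:
        r = math.exp(log_r)
        res = optimize.minimize_scalar(
            lambda f0: -loglik(f0, r), bounds=f0_bounds, method="bounded",
            options={"xatol": 1e-10},
        )
        return -res.fun, float(res.x)

    lo, hi = math.log(R_BOUNDS[0]), math.log(R_BOUNDS[1])
    outer = optimize.minimize_scalar(
        lambda lr: -profile(lr)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    log_r_hat = float(outer.x)
    ll_max, f0_hat = profile(log_r_hat)
    r_hat = math.exp(log_r_hat)

    target = ll_max - CHI2_95_CUTOFF / 2.0

    def deficit(lr: float) -> float:
        return profile(lr)[0] - target

    ci_low = R_BOUNDS[0]
    if deficit(lo) < 0:
        ci_low = math.exp(optimize.brentq(deficit, lo, log_r_hat, xtol=1e-8))
    ci_high = R_BOUNDS[1]
    if deficit(hi) < 0:
        ci_high = math.exp(optimize.brentq(deficit, log_r_hat, hi, xtol=1e-8))

    return FitnessEstimate(
        r_hat=r_hat, ci_low=ci_low, ci_high=ci_high, loglik=ll_max,
        n_obs=len(obs), converged=bool(outer.success), f0_hat=f0_hat, model=model,
    )


# ---------------------------------------------------------------------------
# trajectory utilities
# ---------------------------------------------------------------------------

def normalize_foldchange(
    traj: Trajectory, baseline_time: float
) -> list[tuple[float, float]]:
    """Fold change of the mutant fraction relative to its value at baseline_time.

    Mirrors the convention of tracking chimerism as fold change over the
    engraftment baseline: the returned value at baseline_time is exactly 1.
    """
    baseline = None
    for t, kk, nn in traj.points:
        if math.isclose(t, baseline_time, abs_tol=1e-9) and nn > 0:
            baseline = kk / nn
            break
    if baseline is None:
        raise ValueError(f"no measurement with total_count > 0 at baseline time {baseline_time}")
    if baseline == 0:
        raise ValueError(
            f"fraction at baseline time {baseline_time} is 0; choose another baseline"
        )
    out: list[tuple[float, float]] = []
    for t, kk, nn in traj.points:
        if nn == 0:
            continue
        frac = kk / nn
        fold = 1.0 if math.isclose(t, baseline_time, abs_tol=1e-9) else frac / baseline
        out.append((t, fold))
    return out
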