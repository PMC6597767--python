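"""Virtual-patient generator.

Emulates the structure of a dose-titration clinic dataset — an initial
untreated review followed by irregularly spaced follow-ups with stepped-down
daily doses — so that fitting, what-if solving and cohort evaluation are
testable end to end without any external data.

Ground-truth kinetics are sampled to honour every validity condition by
construction: the integration constant is pinned to the sampled initial FT4
through the initial-condition identity ``c1 = 1/y1 - c/a``, and the
untreated steady state ``a/c`` is drawn *below* the initial level so that
``c1 < 0`` always holds. Observation noise is additive Gaussian on FT4 with
a positivity floor; the schedule/dose stream and the noise stream are
seeded separately, so changing the noise seed never changes visit times or
doses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError
from .kinetics import check_validity, ft4_solution
from .params import ModelParams
from .series import PatientSeries

__all__ = ["SyntheticSpec", "TitrationPolicy", "sample_truth", "simulate_series",
           "simulate_cohort"]


@dataclass(frozen=True)
class TitrationPolicy:
    """Simple step-down dosing rule.

    The initial dose depends on FT4 severity at presentation; at each
    review the dose is halved once the model-predicted FT4 at the next
    review falls below the step-down threshold. A fixture mirroring common
    titration practice, not a clinical recommendation.
    """

    severe_ft4: float = 40.0   # pmol/l; above this start high
    dose_high: float = 30.0    # mg/day
    dose_low: float = 15.0     # mg/day
    stepdown_ft4: float = 20.0  # halve the dose below this predicted level

    def initial_dose(self, y1: float) -> float:
        return self.dose_high if y1 > self.severe_ft4 else self.dose_low


@dataclass(frozen=True)
class SyntheticSpec:
    """Cohort-generation settings.

    Ranges mirror a titration clinic population: initial FT4 20-90 pmol/l,
    2-10 reviews per patient, review intervals 28-180 days, synthesis rates
    spanning the slow-to-fast equilibration regimes seen in fitted patients.
    ``steady_frac_range`` places the untreated steady state ``a/c`` at that
    fraction of the initial FT4 (keeping ``c1`` negative by construction).
    """

    n_patients: int = 20
    a_range: tuple = (0.05, 5.0)        # log-uniform, 1/day
    ic50_range: tuple = (20.0, 120.0)   # uniform, mg
    initial_ft4_range: tuple = (20.0, 90.0)   # pmol/l
    steady_frac_range: tuple = (0.3, 0.9)     # a/c as fraction of y1
    visits_range: tuple = (2, 10)       # inclusive
    interval_range: tuple = (28.0, 180.0)     # days
    policy: TitrationPolicy = TitrationPolicy()
    noise_sd: float = 1.0               # pmol/l, additive Gaussian
    noise_floor: float = 0.5            # pmol/l, positivity clip
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise DomainError("n_patients must be >= 1")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be nonnegative")
        if self.visits_range[0] < 2:
            raise DomainError("every patient needs at least 2 visits")


def sample_truth(spec: SyntheticSpec, seed: int, max_tries: int = 1000):
    """Draw one ground-truth parameter set and its initial FT4.

    Returns ``(ModelParams, y1)``. The draw is rejection-sampled until the
    full validity report passes (by construction this succeeds immediately,
    but the guarantee is enforced, with a budget).
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        y1 = rng.uniform(*spec.initial_ft4_range)
        a = np.exp(rng.uniform(np.log(spec.a_range[0]), np.log(spec.a_range[1])))
        steady0 = y1 * rng.uniform(*spec.steady_frac_range)
        c = a / steady0
        ic50 = rng.uniform(*spec.ic50_range)
        c1 = 1.0 / y1 - c / a
        grid = [(t, d) for t in (0.0, 30.0, 400.0) for d in (0.0, 30.0, 60.0)]
        if c1 < 0 and check_validity((a, c, ic50, c1), grid).ok:
            return ModelParams(a=a, c=c, ic50=ic50, c1=c1), float(y1)
    raise DomainError("rejection-sampling budget exceeded; spec ranges invalid")


def simulate_series(
    truth: ModelParams,
    y1: float,
    spec: SyntheticSpec,
    patient_id: str,
    schedule_seed: int,
    noise_seed: int,
) -> PatientSeries:
    """Forward-simulate one patient's visit series from known kinetics.

    Visit 1 observes ``y1``; each follow-up observes the closed-form FT4 at
    the cumulative time under the latest prescribed dose (the same plug-in
    convention the estimator uses), plus observation noise. Doses follow
    ``spec.policy`` deterministically from the *noise-free* model, so two
    simulations differing only in ``noise_seed`` share identical doses and
    visit times.
    """
    rng_sched = np.random.default_rng(schedule_seed)
    rng_noise = np.random.default_rng(noise_seed)
    m = int(rng_sched.integers(spec.visits_range[0], spec.visits_range[1] + 1))
    intervals = [0.0] + [
        float(np.round(rng_sched.uniform(*spec.interval_range)))
        for _ in range(m - 1)
    ]
    times = np.cumsum(intervals)

    doses = [0.0]
    d = truth.meta.get("initial_dose") or spec.policy.initial_dose(y1)
    for i in range(1, m):
        doses.append(d)
        y_next = float(ft4_solution(truth, times[i], d))
        if y_next < spec.policy.stepdown_ft4:
            d = d / 2.0
    y_true = np.array(
        [y1] + [float(ft4_solution(truth, times[i], doses[i])) for i in range(1, m)]
    )
    noise = rng_noise.normal(0.0, spec.noise_sd, size=m) if spec.noise_sd > 0 else 0.0
    y_obs = np.maximum(y_true + noise, spec.noise_floor)
    return PatientSeries.from_arrays(patient_id, doses, intervals, y_obs)


def simulate_cohort(spec: SyntheticSpec):
    """Generate a cohort; returns ``(list of PatientSeries, dict of truths)``.

    Truths are keyed by patient id and carry the sampled initial FT4 in
    their metadata. Regeneration under the same spec (seed included) is
    byte-identical after serialization.
    """
    root = np.random.default_rng(spec.seed)
    # independent child seeds per patient, split by purpose
    seeds = root.integers(0, 2**31 - 1, size=(spec.n_patients, 3))
    cohort, truths = [], {}
    for k in range(spec.n_patients):
        pid = f"S{k + 1:03d}"
        truth, y1 = sample_truth(spec, int(seeds[k, 0]))
        truth = ModelParams(
            a=truth.a, c=truth.c, ic50=truth.ic50, c1=truth.c1,
            meta={"patient_id": pid, "initial_ft4": y1},
        )
        cohort.append(
            simulate_series(truth, y1, spec, pid, int(seeds[k, 1]), int(seeds[k, 2]))
        )
        truths[pid] = truth
    return cohort, truths
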