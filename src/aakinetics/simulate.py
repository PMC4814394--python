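"""Synthetic data generators emulating the crossover trial and rat assay.

Raw individual-level data from the study were never published, so the
package ships generators that reproduce its data-generating processes:

* :func:`simulate_trial` — a randomized four-way crossover: five subjects
  x four supplements sampled on the study grid (0, 10, 20, 30, 45, 60,
  90, 120 min). True curves follow the zeroth-order-appearance model;
  subject and subject x supplement random effects perturb the transformed
  parameters (log-normal on k1, k3, x0; truncated normal on y0), and
  additive Gaussian noise truncated at zero emulates assay error. One
  subject x supplement arm is excluded by default, mirroring the study's
  protocol deviation.
* :func:`simulate_balance` — the 5-day nitrogen balance: target TD and BV
  are inverted through the balance equations to the implied faecal and
  urinary nitrogen, which are then perturbed with measurement noise.

Both are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import presets
from .fitting import ObservationSeries
from .kinetics import KineticParams, _plasma_zeroth
from .quality import NitrogenBalance

__all__ = ["TrialDesign", "BalanceDesign", "simulate_trial", "simulate_balance"]


@dataclass(frozen=True)
class TrialDesign:
    """Design of a simulated crossover trial.

    Random-effect sds are relative: they act on the log scale for k1, k3
    and x0 (a sd of 0.2 means ~20 % parameter variation) and scale y0 for
    the baseline effect. ``noise_sd`` is relative to each noise-free
    curve's maximum when ``noise_mode="relative"``, or an absolute
    concentration when ``"absolute"``.
    """

    n_subjects: int = 5
    supplements: dict[str, KineticParams] = field(
        default_factory=lambda: dict(presets.DEFAULT_TRIAL_PARAMS)
    )
    times: tuple[float, ...] = presets.TRIAL_TIME_GRID
    re_sd_subject: float = 0.2
    re_sd_interaction: float = 0.2
    noise_sd: float = 0.05
    noise_mode: str = "relative"
    excluded_arms: tuple[tuple[int, str], ...] = (presets.EXCLUDED_ARM,)
    analyte: str = "TAA"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.supplements:
            raise ValueError("at least one supplement is required")
        t = np.asarray(self.times, dtype=float)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("time grid must start at 0 and strictly increase")
        for name in ("re_sd_subject", "re_sd_interaction", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_mode not in ("relative", "absolute"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")


def _phi(p: KineticParams) -> np.ndarray:
    return np.array([np.log(p.k1), np.log(p.k3), np.log(p.x0), p.y0])


def simulate_trial(design: TrialDesign) -> tuple[list[ObservationSeries], pd.DataFrame]:
    """Simulate the crossover trial; returns (series, truth table).

    The truth table records, per generated arm, the perturbed "true"
    parameters on the natural scale alongside the design fixed effects.
    """
    rng = np.random.default_rng(design.seed)
    t = np.asarray(design.times, dtype=float)
    labels = list(design.supplements)
    excluded = set(design.excluded_arms)
    series: list[ObservationSeries] = []
    truth_rows = []
    for subj in range(1, design.n_subjects + 1):
        b = np.zeros(4)
        b[:3] = rng.normal(0.0, design.re_sd_subject, size=3)
        b_y0 = rng.normal(0.0, design.re_sd_subject)
        for lab in labels:
            p = design.supplements[lab]
            c = np.zeros(4)
            c[:3] = rng.normal(0.0, design.re_sd_interaction, size=3)
            c_y0 = rng.normal(0.0, design.re_sd_interaction)
            pert = b[:3] + c[:3]
            y0 = max(p.y0 * (1.0 + b_y0 + c_y0), 0.0)
            if np.any(pert):
                k1, k3, x0 = np.exp(_phi(p)[:3] + pert)
            else:  # bit-exact degenerate path (no exp/log round trip)
                k1, k3, x0 = p.k1, p.k3, p.x0
            clean = _plasma_zeroth(k1, k3, x0, y0, t)
            sd = (
                design.noise_sd * float(clean.max())
                if design.noise_mode == "relative"
                else design.noise_sd
            )
            noisy = np.maximum(clean + rng.normal(0.0, sd, size=t.size), 0.0) if sd > 0 else clean
            if (subj, lab) in excluded:
                continue
            series.append(
                ObservationSeries(
                    subject=subj, supplement=lab, analyte=design.analyte,
                    times=t.copy(), concentrations=noisy,
                )
            )
            truth_rows.append(
                {
                    "subject": subj, "supplement": lab, "analyte": design.analyte,
                    "k1_true": float(k1), "k3_true": float(k3),
                    "x0_true": float(x0), "y0_true": float(y0),
                    "k1_fixed": p.k1, "k3_fixed": p.k3,
                    "x0_fixed": p.x0, "y0_fixed": p.y0,
                }
            )
    return series, pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class BalanceDesign:
    """Design of a simulated nitrogen-balance assay.

    Targets are (TD %, BV %) per diet. The daily ration and balance
    length default to the study protocol: 10 g dry matter and 150 mg N
    per day over 5 days. Noise sds are per balance period, in mg N; the
    defaults give group SEMs of the magnitude reported for five animals.
    """

    n_animals: int = 5
    diets: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            d: (presets.TRUE_DIGESTIBILITY[d], presets.BIOLOGICAL_VALUE[d])
            for d in presets.SUPPLEMENTS
        }
    )
    dm_per_day: float = presets.BALANCE_DM_PER_DAY
    n_per_day: float = presets.BALANCE_N_PER_DAY
    days: int = presets.BALANCE_DAYS
    noise_sd_faeces: float = 8.0
    noise_sd_urine: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1 or self.days < 1:
            raise ValueError("n_animals and days must be >= 1")
        if self.dm_per_day <= 0 or self.n_per_day <= 0:
            raise ValueError("rations must be positive")
        for d, (td, bv) in self.diets.items():
            if not (0 < td < 110 and 0 < bv < 110):
                raise ValueError(f"diet {d!r}: target TD/BV must lie in (0, 110)")
        if self.noise_sd_faeces < 0 or self.noise_sd_urine < 0:
            raise ValueError("noise sds must be >= 0")


def simulate_balance(
    design: BalanceDesign,
) -> tuple[dict[str, list[NitrogenBalance]], pd.DataFrame]:
    """Simulate the balance assay; returns ({diet: records}, truth table).

    The noise-free faecal and urinary nitrogen are obtained by inverting
    the TD and BV equations at the target values:

        N_faeces = N_metabolic + N_intake (1 - TD/100)
        N_urine  = N_endogenous + N_intake TD/100 (1 - BV/100)

    then perturbed with Gaussian measurement noise and floored at zero.
    """
    rng = np.random.default_rng(design.seed)
    intake = design.n_per_day * design.days
    dm = design.dm_per_day * design.days
    n_metabolic = presets.N_METABOLIC_RATE * dm
    n_endogenous = presets.N_ENDOGENOUS_RATE * design.days
    out: dict[str, list[NitrogenBalance]] = {}
    truth_rows = []
    for diet, (td, bv) in design.diets.items():
        f0 = n_metabolic + intake * (1.0 - td / 100.0)
        u0 = n_endogenous + intake * td / 100.0 * (1.0 - bv / 100.0)
        if f0 < 0 or u0 < 0:
            raise ValueError(
                f"diet {diet!r}: targets TD={td}, BV={bv} imply negative nitrogen"
            )
        records = []
        for _ in range(design.n_animals):
            f = max(f0 + rng.normal(0.0, design.noise_sd_faeces), 0.0) \
                if design.noise_sd_faeces > 0 else f0
            u = max(u0 + rng.normal(0.0, design.noise_sd_urine), 0.0) \
                if design.noise_sd_urine > 0 else u0
            records.append(
                NitrogenBalance(
                    n_intake=intake, n_faeces=f, n_urine=u,
                    dm_feed=dm, days=design.days,
                )
            )
        out[diet] = records
        truth_rows.append(
            {
                "diet": diet, "td_target": td, "bv_target": bv,
                "n_faeces_clean": f0, "n_urine_clean": u0,
                "n_intake": intake, "dm_feed": dm,
            }
        )
    return out, pd.DataFrame(truth_rows)
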