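"""Synthetic quadrat-census datasets with known ground truth.

The field study this package models censused a single barnacle cohort in
52 quadrats of 5×5 cm on each of two shores, with settlement density
manipulated across quadrats and photographs taken in June, July, October
and February.  Those raw data were never deposited, so this module
generates datasets of exactly that shape from a known truth:

* settlement densities drawn log-uniformly across quadrats (emulating the
  experimental density manipulation, which spans orders of magnitude);
* survival over each census interval governed by a chosen macroscopic
  survival form on operculum cover, with a period-varying
  resource-independent survival ``alpha`` and an optional extra mortality
  term from the cover of dead shells;
* operculum area growing by Ford–Walford steps, independent of density
  (operculum area is the non-plastic trait);
* basal area responding plastically to crowding, ``B(N) = B_max/(1+c N)``,
  so mean basal area shrinks at high density;
* dead-shell cover accumulating as a persistence fraction of the basal
  area freed by deaths;
* demographic noise as binomial survival of integer individuals, and
  lognormal measurement jitter on recorded trait areas.

Every latent quantity (true survival per interval, true trait values) is
returned in a truth log so parameter-recovery experiments can compare
estimates against the exact generating values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GrowthParams, SurvivalForm, grow_step
from .inference import BASE_DAYS, QuadratObservation

__all__ = [
    "StudyDesign",
    "TruthParams",
    "sample_settlement",
    "basal_area",
    "simulate_dataset",
    "observations_from_frame",
    "DEFAULT_DESIGN",
    "DEFAULT_TRUTH",
]


@dataclass(frozen=True)
class StudyDesign:
    """Shape of the census design: shores × quadrats × census intervals."""

    n_shores: int = 2
    n_quadrats: int = 52
    quadrat_area_mm2: float = 2500.0  # 5 cm × 5 cm
    schedule: tuple[tuple[str, float], ...] = (
        ("June-July", 30.0),
        ("July-October", 90.0),
        ("October-February", 120.0),
    )

    def __post_init__(self) -> None:
        if self.n_shores < 1 or self.n_quadrats < 1:
            raise ValueError("need at least one shore and one quadrat")
        if len(self.schedule) < 1:
            raise ValueError("need at least one census interval")
        if any(days <= 0 for _, days in self.schedule):
            raise ValueError("interval lengths must be positive")

    @property
    def shore_labels(self) -> tuple[str, ...]:
        return tuple(f"Shore-{i + 1}" for i in range(self.n_shores))

    @property
    def periods(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.schedule)


@dataclass(frozen=True)
class TruthParams:
    """Generating truth for a synthetic dataset.

    ``alpha`` maps each shore label to one resource-independent survival
    per census period (per 30-day base step).  ``beta_live`` / ``beta_dead``
    map shore to the live-cover and dead-cover mortality parameters (units
    mm⁻² of per-quadrat cover).  Operculum growth parameters are in mm² per
    individual with ``K`` per 30-day step.
    """

    form: SurvivalForm = SurvivalForm.LOGISTIC
    alpha: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "Shore-1": (0.97, 0.92, 0.92),
            "Shore-2": (0.98, 0.96, 0.96),
        }
    )
    beta_live: Mapping[str, float] = field(
        default_factory=lambda: {"Shore-1": 4.08e-2, "Shore-2": 3.21e-2}
    )
    beta_dead: Mapping[str, float] = field(
        default_factory=lambda: {"Shore-1": 3.61e-2, "Shore-2": 8.36e-2}
    )
    operc_growth: GrowthParams = GrowthParams(K=0.12, phi_inf=0.5, phi_0=0.1)
    basal_max_mm2: float = 5.0
    basal_crowding: float = 0.02  # c in B(N) = B_max / (1 + c N)
    settlement_min: float = 100.0
    settlement_max: float = 600.0
    dead_persistence: float = 0.1
    trait_noise_sd: float = 0.05  # lognormal sigma on recorded trait areas
    mode: str = "binomial"  # "binomial" (integer counts) or "continuous"

    def __post_init__(self) -> None:
        object.__setattr__(self, "form", SurvivalForm(self.form))
        if not (0.0 < self.settlement_min <= self.settlement_max):
            raise ValueError(
                f"settlement range must satisfy 0 < min <= max, got "
                f"[{self.settlement_min}, {self.settlement_max}]"
            )
        if not (0.0 <= self.dead_persistence <= 1.0):
            raise ValueError("dead_persistence must be in [0, 1]")
        if self.trait_noise_sd < 0:
            raise ValueError("trait_noise_sd must be >= 0")
        if self.mode not in ("binomial", "continuous"):
            raise ValueError(f"mode must be 'binomial' or 'continuous', got {self.mode!r}")
        for shore, alphas in self.alpha.items():
            if any(not (0.0 < a <= 1.0) for a in alphas):
                raise ValueError(f"alpha values for {shore} must be in (0, 1]")
        for m in (self.beta_live, self.beta_dead):
            if any(b < 0 for b in m.values()):
                raise ValueError("beta values must be >= 0")


DEFAULT_DESIGN = StudyDesign()
DEFAULT_TRUTH = TruthParams()


def sample_settlement(
    design: StudyDesign, truth: TruthParams, rng: np.random.Generator
) -> np.ndarray:
    """Initial settler densities for one shore's quadrats, log-uniform.

    The experimental manipulation spanned a wide density range; a
    log-uniform law puts equal effort per decade, so the median equals
    ``sqrt(min * max)``.  A degenerate range (min == max) yields constant
    densities.
    """
    lo, hi = truth.settlement_min, truth.settlement_max
    if lo == hi:
        return np.full(design.n_quadrats, float(lo))
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=design.n_quadrats))


def basal_area(N: float | np.ndarray, truth: TruthParams) -> float | np.ndarray:
    """Mean basal area per individual at density ``N`` (plastic crowding law).

    ``B(N) = B_max / (1 + c N)``: equal to ``B_max`` in an empty quadrat and
    strictly decreasing with density when ``c > 0``.
    """
    N_arr = np.asarray(N, dtype=float)
    if np.any(N_arr < 0):
        raise ValueError("density must be >= 0")
    out = truth.basal_max_mm2 / (1.0 + truth.basal_crowding * N_arr)
    if np.isscalar(N) or N_arr.ndim == 0:
        return float(out)
    return out


def _survival_base(
    form: SurvivalForm, alpha: float, u_live: float, beta_live: float,
    u_dead: float, beta_dead: float,
) -> float:
    """Per-base-step survival under the macro form with live + dead terms."""
    load = beta_live * u_live + beta_dead * u_dead
    if form is SurvivalForm.EXPONENTIAL:
        return alpha * math.exp(-load)
    if form is SurvivalForm.LOGISTIC:
        aprime = 1.0 / alpha - 1.0
        return 1.0 / (1.0 + aprime * math.exp(load))
    return alpha / (1.0 + load)


def simulate_dataset(
    design: StudyDesign = DEFAULT_DESIGN,
    truth: TruthParams = DEFAULT_TRUTH,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Generate one study-shaped dataset plus a hidden truth log.

    Returns ``(table, truth_log)``.  The table has one row per
    quadrat × census interval with the standard schema (shore, quadrat,
    period, T_days, N_start, N_end, operc_area, basal_area, dead_cover);
    trait areas carry the measurement jitter, while the truth log records
    the exact latent survival and trait values per row.

    Randomness is organised as one sub-stream per (shore, quadrat), so
    enlarging the design never perturbs the draws of existing quadrats.
    """
    rows: list[dict] = []
    latent: list[dict] = []
    for s_idx, shore in enumerate(design.shore_labels):
        alphas = truth.alpha[shore]
        if len(alphas) != len(design.schedule):
            raise ValueError(
                f"{shore}: need one alpha per census interval "
                f"({len(design.schedule)}), got {len(alphas)}"
            )
        b_live = truth.beta_live[shore]
        b_dead = truth.beta_dead[shore]
        for q_idx in range(design.n_quadrats):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(s_idx, q_idx))
            )
            lo, hi = truth.settlement_min, truth.settlement_max
            n0 = lo if lo == hi else math.exp(rng.uniform(math.log(lo), math.log(hi)))
            N = max(float(round(n0)), 1.0) if truth.mode == "binomial" else float(n0)
            operc = truth.operc_growth.phi_0
            dead = 0.0
            for p_idx, (period, days) in enumerate(design.schedule):
                u_live = operc * N
                lam30 = _survival_base(
                    truth.form, alphas[p_idx], u_live, b_live, dead, b_dead
                )
                lam_T = lam30 ** (days / BASE_DAYS)
                if truth.mode == "binomial":
                    n_end = float(rng.binomial(int(N), lam_T)) if N > 0 else 0.0
                else:
                    n_end = N * lam_T
                basal = basal_area(N, truth)
                jit_o = (
                    float(rng.lognormal(0.0, truth.trait_noise_sd))
                    if truth.trait_noise_sd > 0 else 1.0
                )
                jit_b = (
                    float(rng.lognormal(0.0, truth.trait_noise_sd))
                    if truth.trait_noise_sd > 0 else 1.0
                )
                rows.append({
                    "shore": shore,
                    "quadrat": f"Q{q_idx + 1:02d}",
                    "period": period,
                    "T_days": days,
                    "N_start": N,
                    "N_end": n_end,
                    "operc_area": operc * jit_o,
                    "basal_area": basal * jit_b,
                    "dead_cover": dead,
                })
                latent.append({
                    "shore": shore, "quadrat": f"Q{q_idx + 1:02d}",
                    "period": period, "lambda_30": lam30, "lambda_T": lam_T,
                    "operc_true": operc, "basal_true": basal,
                    "u_live": u_live, "u_dead": dead,
                })
                deaths = N - n_end
                dead += truth.dead_persistence * deaths * basal
                N = n_end
                operc = grow_step(operc, truth.operc_growth,
                                  n_steps=days / BASE_DAYS)
    table = pd.DataFrame(rows)
    truth_log = {
        "seed": seed,
        "design": {
            "n_shores": design.n_shores,
            "n_quadrats": design.n_quadrats,
            "quadrat_area_mm2": design.quadrat_area_mm2,
            "schedule": list(design.schedule),
        },
        "truth": {
            "form": truth.form.value,
            "alpha": {k: list(v) for k, v in truth.alpha.items()},
            "beta_live": dict(truth.beta_live),
            "beta_dead": dict(truth.beta_dead),
            "operc_growth": {
                "K": truth.operc_growth.K,
                "phi_inf": truth.operc_growth.phi_inf,
                "phi_0": truth.operc_growth.phi_0,
            },
            "basal_max_mm2": truth.basal_max_mm2,
            "basal_crowding": truth.basal_crowding,
            "settlement_range": [truth.settlement_min, truth.settlement_max],
            "dead_persistence": truth.dead_persistence,
            "trait_noise_sd": truth.trait_noise_sd,
            "mode": truth.mode,
        },
        "latent": latent,
    }
    return table, truth_log


def observations_from_frame(table: pd.DataFrame) -> list[QuadratObservation]:
    """Convert a schema-shaped DataFrame into typed observations."""
    return [
        QuadratObservation(
            shore=str(r.shore), quadrat=str(r.quadrat), period=str(r.period),
            T_days=float(r.T_days), N_start=float(r.N_start),
            N_end=float(r.N_end), operc_area=float(r.operc_area),
            basal_area=float(r.basal_area), dead_cover=float(r.dead_cover),
        )
        for r in table.itertuples()
    ]
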