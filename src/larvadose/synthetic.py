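"""Synthetic inputs with the statistical structure the analyses assume.

Two generators: (i) multi-position S11 sweeps whose stirred component is a
circular complex Gaussian (Rayleigh magnitudes — the well-stirred ideal) or
carries a dominant unstirred offset (Rician — a badly stirred chamber), and
(ii) larval development cohorts with temperature-linear development rates,
diet effects, Bernoulli mortality and wing lengths drawn from the
random-intercept linear mixed model.  Both are fully seeded; a given seed
reproduces its output byte for byte.

The cohort defaults mirror the study design: four conditions (LC, LE, HC,
HE) x two diets, 5 replicate runs of 168 larvae each, and per-condition
water-temperature measurement lists of the study's sizes (84, 7, 96 and 38
measurements).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .devstats import CohortTable
from .rc import S11Sweep

__all__ = [
    "S11GeneratorSpec",
    "CohortGeneratorSpec",
    "simulate_s11",
    "simulate_cohort",
    "TEMPERATURE_DEFAULTS",
    "WING_MODEL_DEFAULTS",
]

#: Per-condition water temperature mean [degC], sd, and measurement count.
TEMPERATURE_DEFAULTS = {
    "LC": (28.23, 0.63, 84),
    "LE": (28.16, 0.19, 7),
    "HC": (30.33, 0.11, 96),
    "HE": (29.95, 0.70, 38),
}

#: Wing-length mixed-model generating parameters [um]: fixed effects against
#: the LC/Tetramin baseline, run-intercept sd and residual sd.
WING_MODEL_DEFAULTS = {
    "intercept": 2992.23,
    "condition": {"HC": -82.14, "HE": -75.63, "LE": 2.18},
    "diet": {"M": -386.16},
    "interaction": {("HC", "M"): 15.41, ("HE", "M"): -13.49, ("LE", "M"): -45.02},
    "run_sd": 38.86,
    "residual_sd": 101.22,
}


@dataclass
class S11GeneratorSpec:
    """Recipe for a stirred-chamber S11 ensemble.

    ``family="rayleigh"`` adds a circular complex Gaussian stirred part of
    per-component sd ``stirred_scale`` to the unstirred profile mu(f);
    ``family="rician"`` additionally gives every stirrer position a fixed
    position-dependent offset of magnitude ``rician_offset``, breaking the
    Rayleigh behaviour of the stirred magnitudes.
    """

    frequencies: np.ndarray
    n1: int = 16
    n2: int = 16
    unstirred: complex | np.ndarray = 0.1 + 0.0j
    stirred_scale: float | np.ndarray = 0.05
    family: str = "rayleigh"
    rician_offset: float = 0.0
    seed: int | None = 0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if np.any(np.asarray(self.stirred_scale) <= 0):
            raise ValueError("stirred scale must be positive (degenerate ensemble)")
        if self.family not in ("rayleigh", "rician"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "rician" and self.rician_offset <= 0:
            raise ValueError("rician family needs a positive offset")


def simulate_s11(spec: S11GeneratorSpec) -> S11Sweep:
    """Draw a seeded multi-position S11 sweep from the generator spec."""
    rng = np.random.default_rng(spec.seed)
    n_pos = spec.n1 * spec.n2
    n_f = len(spec.frequencies)
    mu = np.broadcast_to(np.asarray(spec.unstirred, complex), (n_f,))
    s = np.broadcast_to(np.asarray(spec.stirred_scale, float), (n_f,))
    z = rng.normal(scale=1.0, size=(n_pos, n_f)) + 1j * rng.normal(scale=1.0, size=(n_pos, n_f))
    values = mu[None, :] + s[None, :] * z
    if spec.family == "rician":
        # fixed per-position offset, constant over frequency: an unstirred
        # stirrer-correlated component that survives the mean subtraction
        phases = np.exp(2j * np.pi * rng.random(n_pos))
        offsets = spec.rician_offset * phases
        offsets -= offsets.mean()
        values = values + offsets[:, None]
    positions = [(i, j) for i in range(spec.n1) for j in range(spec.n2)]
    peak = np.abs(values).max()
    if peak > 1.0:  # keep the sweep passive
        values = values * (0.99 / peak)
    return S11Sweep(spec.frequencies, positions, values)


@dataclass
class CohortGeneratorSpec:
    """Recipe for a synthetic development cohort.

    Development rate follows ``rate = a_diet + b_diet * T + eps`` with T the
    condition's water-temperature mean and eps per-larva Gaussian noise;
    pupation day is the rounded reciprocal, emergence follows after an
    integer lag.  ``exposure_slope_offset`` shifts b for the exposed
    conditions (LE, HE) to build in a non-thermal exposure effect.  Wing
    lengths are drawn from the random-intercept LMM for 10 measured larvae
    per sex per run and diet.
    """

    temperatures: dict = field(default_factory=lambda: dict(TEMPERATURE_DEFAULTS))
    rate_intercept: dict = field(default_factory=lambda: {"T": -0.172, "M": -0.206})
    rate_slope: dict = field(default_factory=lambda: {"T": 0.012, "M": 0.012})
    rate_noise_sd: float = 0.015
    exposure_slope_offset: float = 0.0
    mortality: float = 0.06
    emergence_lag_days: int = 2
    larvae_per_run: int = 168
    runs_per_condition: int = 5
    wings_measured_per_sex: int = 10
    wing_model: dict = field(default_factory=lambda: dict(WING_MODEL_DEFAULTS))
    seed: int | None = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mortality <= 1.0:
            raise ValueError("mortality must be a probability")
        if self.rate_noise_sd < 0 or self.wing_model["run_sd"] < 0 or self.wing_model["residual_sd"] < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.emergence_lag_days < 1:
            raise ValueError("emergence lag must be >= 1 day")
        if self.larvae_per_run < 2 or self.runs_per_condition < 1:
            raise ValueError("need at least 2 larvae and 1 run")


def _wing_mean(wm: dict, condition: str, diet: str) -> float:
    mu = wm["intercept"]
    mu += wm["condition"].get(condition, 0.0)
    mu += wm["diet"].get(diet, 0.0)
    mu += wm["interaction"].get((condition, diet), 0.0)
    return mu


def simulate_cohort(spec: CohortGeneratorSpec) -> CohortTable:
    """Draw a seeded cohort with the generator's development and wing laws."""
    rng = np.random.default_rng(spec.seed)
    wm = spec.wing_model
    rows = []
    temps = {}
    for cond, (mean, sd, n_meas) in spec.temperatures.items():
        temps[cond] = rng.normal(mean, sd, size=n_meas)

    run_counter = 0
    for cond, (t_mean, _sd, _n) in spec.temperatures.items():
        exposed = cond in ("LE", "HE")
        for _ in range(spec.runs_per_condition):
            run_counter += 1
            run_id = f"{cond}{run_counter}"
            run_wing_offset = rng.normal(0.0, wm["run_sd"])
            half = spec.larvae_per_run // 2
            diets = ["M"] * half + ["T"] * (spec.larvae_per_run - half)
            # pick which survivors get wings measured, per diet x sex, later
            for i, diet in enumerate(diets):
                b = spec.rate_slope[diet] + (spec.exposure_slope_offset if exposed else 0.0)
                rate = spec.rate_intercept[diet] + b * t_mean + rng.normal(0.0, spec.rate_noise_sd)
                rate = max(rate, 1.0 / 30.0)  # floor: no development slower than 30 d
                pup = max(1, int(round(1.0 / rate)))
                emerg = pup + spec.emergence_lag_days
                sex = "F" if rng.random() < 0.5 else "M"
                dies = rng.random() < spec.mortality
                rows.append({
                    "id": f"{run_id}-{i:03d}",
                    "run": run_id,
                    "generation": "G1",
                    "condition": cond,
                    "diet": diet,
                    "pupation_day": np.nan if dies else float(pup),
                    "emergence_day": np.nan if dies else float(emerg),
                    "death_day": float(rng.integers(1, max(pup, 2))) if dies else np.nan,
                    "sex": sex,
                    "wing_left": np.nan,
                    "wing_right": np.nan,
                    "_run_wing_offset": run_wing_offset,
                })

    df = pd.DataFrame(rows)
    # wing measurement: 10 per sex per run x diet among emerged adults
    for (_run, diet, sex), g in df[df["emergence_day"].notna()].groupby(["run", "diet", "sex"]):
        take = g.index[: spec.wings_measured_per_sex]
        for idx in take:
            mu = _wing_mean(wm, df.at[idx, "condition"], diet) + df.at[idx, "_run_wing_offset"]
            df.at[idx, "wing_left"] = mu + rng.normal(0.0, wm["residual_sd"])
            df.at[idx, "wing_right"] = mu + rng.normal(0.0, wm["residual_sd"])
    df = df.drop(columns=["_run_wing_offset"])
    return CohortTable(records=df, temperatures=temps)
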