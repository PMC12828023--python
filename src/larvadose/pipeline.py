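"""End-to-end orchestration: characterize -> dose -> analyze.

`run_all` executes the three pipeline stages from a single YAML-style
configuration, generating synthetic inputs where measurement files are not
supplied, and writes JSON/CSV reports with a provenance block (package
version, seeds, configuration hash) so a rerun with the same configuration
reproduces the same files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .constants import FIELD_HIGH_EXPOSURE, FIELD_LOW_EXPOSURE
from .devstats import (
    CohortTable,
    asymmetry_test,
    compare_slopes,
    development_rate,
    logrank_test,
    mortality_test,
    ph_check,
    slope_resampling,
    wing_lmm,
)
from .dosimetry import REFERENCE_PABS_VERTICAL, dose_summary, scale_pabs
from .io import read_cohort_csv, read_sweep_csv, read_temperatures_csv
from .rc import characterize
from .synthetic import CohortGeneratorSpec, S11GeneratorSpec, simulate_cohort, simulate_s11

__all__ = ["RunConfig", "run_all", "analyze_cohort"]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    out_dir: str = "results"
    seed: int = 0
    # chamber characterization
    sweep_csv: str | None = None
    target_ghz: float = 3.6
    subset: tuple[int, int] | None = (8, 8)
    cv_cutoff_ghz: float = 3.6
    # dosimetry
    incident_fields: tuple[float, float] = (FIELD_LOW_EXPOSURE, FIELD_HIGH_EXPOSURE)
    # development analysis
    records_csv: str | None = None
    temps_csv: str | None = None
    B: int = 10_000
    synthetic: bool = True
    generator: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def analyze_cohort(cohort: CohortTable, B: int = 10_000, seed: int | None = 0) -> dict:
    """Run the full development-statistics battery on one cohort.

    Returns a dict with Table-1-shaped pairwise log-rank rows, the slope
    resampling Welch comparisons per diet and event, the wing-length LMM
    terms, and the asymmetry and mortality Kruskal-Wallis tests.
    """
    rng = np.random.default_rng(seed)
    records = cohort.records

    logrank_rows = []
    for event in ("pupation", "emergence"):
        for diet in ("M", "T"):
            for a, b in (("LC", "LE"), ("HC", "HE")):
                ga = cohort.subset(a, diet)
                gb = cohort.subset(b, diet)
                if ga.empty or gb.empty:
                    continue
                res = logrank_test(ga, gb, event=event)
                try:
                    ph_p, reliable = ph_check(ga, gb, event=event)
                except ValueError:
                    ph_p, reliable = np.nan, None
                logrank_rows.append({
                    "event": event, "diet": diet, "group_a": a, "group_b": b,
                    "chi2": res.statistic, "df": res.df, "p": res.p_value,
                    "schoenfeld_p": ph_p, "reliable": reliable,
                })

    slope_rows = []
    for event, col in (("pupation", "pupation_day"), ("emergence", "emergence_day")):
        for diet in ("M", "T"):
            def _pair(c1, c2):
                r1 = development_rate(cohort.subset(c1, diet)[col].dropna().to_numpy())
                r2 = development_rate(cohort.subset(c2, diet)[col].dropna().to_numpy())
                return slope_resampling(
                    r1, cohort.temperatures[c1], r2, cohort.temperatures[c2],
                    B=B, seed=rng,
                )
            try:
                control = _pair("LC", "HC")
                exposed = _pair("LE", "HE")
            except (KeyError, ValueError):
                continue
            cmp_res = compare_slopes(control, exposed)
            slope_rows.append({
                "event": event, "diet": diet, "B": B,
                "mean_slope_control": float(control.slopes.mean()),
                "mean_slope_exposed": float(exposed.slopes.mean()),
                "t": cmp_res.statistic, "df": cmp_res.df, "p": cmp_res.p_value,
            })

    out: dict = {
        "logrank": pd.DataFrame(logrank_rows),
        "slopes": pd.DataFrame(slope_rows),
    }

    try:
        fit = wing_lmm(cohort, sex="F")
        out["wing_lmm"] = fit.terms.reset_index(names="term").assign(
            run_sd=fit.run_sd, residual_sd=fit.residual_sd
        )
        out["wing_lmm_fit"] = fit
    except ValueError:
        out["wing_lmm"] = pd.DataFrame()
    try:
        out["asymmetry"] = asymmetry_test(records).to_dict()
    except ValueError:
        out["asymmetry"] = None
    try:
        out["mortality"] = mortality_test(records).to_dict()
    except ValueError:
        out["mortality"] = None
    deaths = int(records["death_day"].notna().sum())
    emerg = int(records["emergence_day"].notna().sum())
    out["overall_mortality"] = deaths / (deaths + emerg) if deaths + emerg else np.nan
    return out


def run_all(config: RunConfig) -> dict:
    """Execute the pipeline and write the report bundle under ``config.out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    # --- stage 1: chamber characterization -----------------------------
    try:
        if config.sweep_csv:
            sweep = read_sweep_csv(config.sweep_csv)
        elif config.synthetic:
            freqs = np.linspace(1.0e9, 5.9e9, 197)
            sweep = simulate_s11(S11GeneratorSpec(frequencies=freqs, seed=seed))
        else:
            raise FileNotFoundError("no sweep CSV supplied and synthetic inputs disabled")
        report = characterize(
            sweep,
            target=config.target_ghz * 1e9,
            subset=config.subset,
            cv_cutoff=config.cv_cutoff_ghz * 1e9,
        )
    except Exception as exc:
        raise RuntimeError(f"characterize stage failed ({config.sweep_csv or 'synthetic'}): {exc}") from exc
    pd.DataFrame({
        "frequency_hz": report.frequencies,
        "a2m": report.a2m, "r1": report.r1, "cv": report.cv,
        "a2m_smooth": report.a2m_smooth, "r1_smooth": report.r1_smooth,
        "cv_smooth": report.cv_smooth,
    }).to_csv(out_dir / "uniformity.csv", index=False)

    # --- stage 2: dosimetry bookkeeping --------------------------------
    try:
        e_le, e_he = config.incident_fields
        doses = {}
        for (model, e_ref), pabs in REFERENCE_PABS_VERTICAL.items():
            if e_ref != FIELD_LOW_EXPOSURE:
                continue
            doses[model] = {
                "pabs_w_le": scale_pabs(pabs, FIELD_LOW_EXPOSURE, e_le),
                "pabs_w_he": scale_pabs(pabs, FIELD_LOW_EXPOSURE, e_he),
            }
    except Exception as exc:
        raise RuntimeError(f"dose stage failed: {exc}") from exc

    # --- stage 3: development statistics -------------------------------
    try:
        if config.records_csv:
            cohort = read_cohort_csv(config.records_csv, config.temps_csv)
        elif config.synthetic:
            cohort = simulate_cohort(CohortGeneratorSpec(seed=seed, **config.generator))
        else:
            raise FileNotFoundError(
                f"records file {config.records_csv!r} not found and synthetic inputs disabled"
            )
        analysis = analyze_cohort(cohort, B=config.B, seed=seed)
    except RuntimeError:
        raise
    except Exception as exc:
        raise RuntimeError(f"analyze stage failed ({config.records_csv or 'synthetic'}): {exc}") from exc

    analysis["logrank"].to_csv(out_dir / "logrank_table.csv", index=False)
    analysis["slopes"].to_csv(out_dir / "slope_comparisons.csv", index=False)
    if len(analysis["wing_lmm"]):
        analysis["wing_lmm"].to_csv(out_dir / "wing_lmm_table.csv", index=False)

    bundle = {
        "provenance": {
            "package": "larvadose",
            "version": __version__,
            "seed": seed,
            "config_hash": config.config_hash(),
        },
        "uniformity": report.to_dict(),
        "dose": doses,
        "asymmetry": analysis["asymmetry"],
        "mortality": analysis["mortality"],
        "overall_mortality": analysis["overall_mortality"],
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=float)
    return bundle
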