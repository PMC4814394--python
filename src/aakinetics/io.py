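"""Readers, writers, run configuration and the end-to-end pipeline.

Observation files are tidy CSV with columns
``subject,supplement,analyte,time_min,concentration``; one row per
sample. A pre-ingestion sample may carry a negative ``time_min`` and is
mapped to the t = 0 baseline. Balance records and amino-acid profiles are
also tidy CSV; reference patterns and run options live in a YAML config.

:func:`run_pipeline` ties the stages together: population fit per
analyte, Monte-Carlo AUC interval per supplement, pairwise comparisons
for all supplement pairs; it writes a parameter table (k1 with Wald 95 %
CI), an AUC table and a pairwise table, plus a JSON run log carrying the
seed, configuration hash, software versions, draw count and exclusions.
Any stage failure removes partial outputs and re-raises with the stage
name.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, presets
from .fitting import ObservationSeries, PopulationFit, fit_population
from .kinetics import TimeWindow
from .mcauc import MIN_DRAWS, mc_auc_ci, mc_pairwise_auc
from .quality import AminoAcidProfile, NitrogenBalance

__all__ = [
    "RunConfig",
    "read_observations",
    "write_observations",
    "read_balance_records",
    "read_profiles",
    "load_config",
    "run_pipeline",
]

OBS_COLUMNS = ["subject", "supplement", "analyte", "time_min", "concentration"]
BALANCE_COLUMNS = [
    "animal", "diet", "n_intake_mg", "n_faeces_mg", "n_urine_mg", "dm_feed_g", "days",
]


def read_observations(path) -> list[ObservationSeries]:
    """Read a tidy observation CSV into validated series.

    Series are grouped by subject x supplement x analyte and sorted by
    time; malformed input raises with the offending row numbers (1-based,
    header = row 1).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df.copy()
    df["_row"] = df.index + 2  # 1-based with header row
    for col in ("time_min", "concentration"):
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric {col} in rows {bad['_row'].tolist()}"
            )
        df[col] = pd.to_numeric(df[col])
    neg = df[df["concentration"] < 0]
    if len(neg):
        raise ValueError(
            f"{path}: negative concentrations in rows {neg['_row'].tolist()}"
        )
    # map pre samples to t = 0 before checking duplicates
    df.loc[df["time_min"] < 0, "time_min"] = 0.0
    dup = df[df.duplicated(["subject", "supplement", "analyte", "time_min"], keep=False)]
    if len(dup):
        raise ValueError(
            f"{path}: duplicate (subject, supplement, analyte, time) rows "
            f"{sorted(dup['_row'].tolist())}"
        )
    series = []
    for (subj, supp, analyte), grp in df.groupby(
        ["subject", "supplement", "analyte"], sort=True
    ):
        grp = grp.sort_values("time_min")
        series.append(
            ObservationSeries(
                subject=subj, supplement=str(supp), analyte=str(analyte),
                times=grp["time_min"].to_numpy(),
                concentrations=grp["concentration"].to_numpy(),
            )
        )
    return series


def write_observations(series_set, path) -> None:
    """Write series to the tidy CSV format that :func:`read_observations` reads."""
    rows = [
        {
            "subject": s.subject, "supplement": s.supplement, "analyte": s.analyte,
            "time_min": t, "concentration": c,
        }
        for s in series_set
        for t, c in zip(s.times, s.concentrations)
    ]
    pd.DataFrame(rows, columns=OBS_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_balance_records(path) -> dict[str, list[NitrogenBalance]]:
    """Read nitrogen-balance records grouped by diet."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in BALANCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out: dict[str, list[NitrogenBalance]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["diet"]), []).append(
            NitrogenBalance(
                n_intake=float(row["n_intake_mg"]),
                n_faeces=float(row["n_faeces_mg"]),
                n_urine=float(row["n_urine_mg"]),
                dm_feed=float(row["dm_feed_g"]),
                days=int(row["days"]),
            )
        )
    return out


def write_balance_records(balances: dict[str, list[NitrogenBalance]], path) -> None:
    rows = []
    for diet, records in balances.items():
        for i, b in enumerate(records, start=1):
            rows.append(
                {
                    "animal": i, "diet": diet, "n_intake_mg": b.n_intake,
                    "n_faeces_mg": b.n_faeces, "n_urine_mg": b.n_urine,
                    "dm_feed_g": b.dm_feed, "days": b.days,
                }
            )
    pd.DataFrame(rows, columns=BALANCE_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_profiles(path) -> dict[str, AminoAcidProfile]:
    """Read amino-acid profiles from tidy CSV (label, amino_acid, mg_per_g)."""
    df = pd.read_csv(path)
    needed = ["label", "amino_acid", "mg_per_g"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = {}
    for label, grp in df.groupby("label", sort=True):
        comp = dict(zip(grp["amino_acid"].str.lower(), grp["mg_per_g"].astype(float)))
        out[str(label)] = AminoAcidProfile(label=str(label), composition=comp)
    return out


@dataclass(frozen=True)
class RunConfig:
    """Options for one pipeline run."""

    observations: str
    output_dir: str
    analytes: tuple[str, ...] = ()  # empty = all analytes present
    window: tuple[float, float] = (0.0, 120.0)
    n_draws: int = 50_000
    seed: int = 0
    method: str = "laplace"
    reference_pattern: str = "fao_who_2007_child_3_10"

    def __post_init__(self) -> None:
        if self.n_draws < MIN_DRAWS:
            raise ValueError(f"n_draws must be >= {MIN_DRAWS}, got {self.n_draws}")
        TimeWindow(*self.window)  # validates
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        if self.reference_pattern not in presets.REFERENCE_PATTERNS:
            raise ValueError(
                f"unknown reference pattern {self.reference_pattern!r}; "
                f"available: {sorted(presets.REFERENCE_PATTERNS)}"
            )


def load_config(path) -> RunConfig:
    """Load a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "analytes" in raw and raw["analytes"] is not None:
        raw["analytes"] = tuple(raw["analytes"])
    if "window" in raw and raw["window"] is not None:
        raw["window"] = tuple(float(v) for v in raw["window"])
    return RunConfig(**raw)


def _config_hash(config: RunConfig) -> str:
    # identifies the analysis, not where it lands: output_dir excluded
    payload = {k: v for k, v in asdict(config).items() if k != "output_dir"}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _wald_ci(fit: PopulationFit, supplement: str, index: int = 0):
    """Wald 95 % CI on the log scale for one transformed parameter."""
    se = math.sqrt(max(fit.covariance_block(supplement)[index, index], 0.0))
    est = fit.fixed_effects_transformed[supplement][index]
    return math.exp(est - 1.96 * se), math.exp(est + 1.96 * se)


def run_pipeline(config: RunConfig) -> dict:
    """Fit, infer AUCs and write the report tables for every analyte.

    Returns a dict with the fits and the three output tables; writes
    ``parameter_table.csv``, ``auc_table.csv``, ``pairwise_table.csv`` and
    ``run_log.json`` into the output directory.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "read_observations"
    try:
        all_series = read_observations(config.observations)
        if not all_series:
            raise ValueError(f"{config.observations}: no observation rows")
        analytes = (
            list(config.analytes)
            if config.analytes
            else sorted({s.analyte for s in all_series})
        )
        window = TimeWindow(*config.window)
        ss = np.random.SeedSequence(config.seed)
        fits: dict[str, PopulationFit] = {}
        param_rows, auc_rows, pair_rows = [], [], []
        for analyte in analytes:
            series = [s for s in all_series if s.analyte == analyte]
            if not series:
                raise ValueError(f"no observations for analyte {analyte!r}")
            stage = f"fit_population[{analyte}]"
            fit_seed, mc_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
            fit = fit_population(series, method=config.method, seed=fit_seed)
            fits[analyte] = fit
            for lab in fit.supplement_labels:
                lo, hi = _wald_ci(fit, lab, index=0)
                param_rows.append(
                    {
                        "analyte": analyte, "supplement": lab,
                        "k1": fit.fixed_effects[lab].k1,
                        "k1_ci_low": lo, "k1_ci_high": hi,
                        "k3": fit.fixed_effects[lab].k3,
                        "x0": fit.fixed_effects[lab].x0,
                        "y0": fit.fixed_effects[lab].y0,
                    }
                )
            stage = f"mc_auc_ci[{analyte}]"
            for i, lab in enumerate(fit.supplement_labels):
                est = mc_auc_ci(
                    fit, lab, window=window, n_draws=config.n_draws,
                    seed=mc_seed + i,
                )
                auc_rows.append(
                    {
                        "analyte": analyte, "supplement": lab, "auc": est.point,
                        "auc_median": est.point_median,
                        "ci_low": est.ci_low, "ci_high": est.ci_high,
                        "n_draws": est.n_draws,
                    }
                )
            stage = f"mc_pairwise_auc[{analyte}]"
            for j, (a, b) in enumerate(
                itertools.combinations(fit.supplement_labels, 2)
            ):
                pw = mc_pairwise_auc(
                    fit, a, b, window=window, n_draws=config.n_draws,
                    seed=mc_seed + 100 + j,
                )
                pair_rows.append(
                    {
                        "analyte": analyte, "supplement_a": a, "supplement_b": b,
                        "auc_diff": pw.diff_point, "ci_low": pw.diff_ci_low,
                        "ci_high": pw.diff_ci_high, "p_value": pw.p_value,
                    }
                )
        stage = "write_outputs"
        tables = {
            "parameter_table": pd.DataFrame(param_rows),
            "auc_table": pd.DataFrame(auc_rows),
            "pairwise_table": pd.DataFrame(pair_rows),
        }
        meta = {
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "aakinetics_version": __version__,
            "numpy_version": np.__version__,
            "n_draws": config.n_draws,
            "method": config.method,
            "window": list(config.window),
            "analytes": analytes,
            "n_series": len(all_series),
        }
        for name, df in tables.items():
            p = outdir / f"{name}.csv"
            with open(p, "w", newline="") as fh:
                fh.write(f"# seed={meta['seed']} config_hash={meta['config_hash']}\n")
                df.to_csv(fh, index=False)
            written.append(p)
        log_path = outdir / "run_log.json"
        log_path.write_text(json.dumps(meta, indent=2))
        written.append(log_path)
    except Exception as err:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage {stage}: {err}") from err
    return {"fits": fits, **tables, "log": meta}
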