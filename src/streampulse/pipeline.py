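"""End-to-end orchestration: simulate -> classify -> screen -> factorize
-> assess, as a seeded, logged, resumable run.

Every stage derives its own seed from the single global seed and the stage
name (crc32 hash), so a stage can be deleted and recomputed in isolation
and still reproduce byte-identical numeric output.  Each run directory
gets a ``manifest.json`` with the effective configuration, its hash, the
derived seeds and the package version.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (
    ConcentrationMatrix,
    HydroSeries,
    read_concentration_table,
    read_timeseries,
    write_compound_metadata,
    write_concentration_table,
    write_timeseries,
)
from .exposure import (
    SamplingScheme,
    composite_average,
    exceedance_assessment,
    window_factors,
)
from .hydro_events import EventConfig, EventCatalog, event_summary, find_dry_periods, segment_events
from .pmf import PMFConfig, detect_elbow, fingerprints, fit_multi, scan_factor_numbers
from .screening import SpeciesScreener
from .synthetic import simulate_dataset

__all__ = ["RunConfig", "run_pipeline", "make_report", "derive_seed"]

STAGES = ["simulate", "events", "screen", "pmf", "exposure"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: (seed * 1000003 + crc32(stage)) mod 2^31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serialisable)."""

    out_dir: str = "run"
    seed: int = 0
    simulate: bool = True
    # synthetic-data stage
    duration_days: float = 41.0
    gap_fraction: float = 0.05
    kappa: float = 1.0
    event_rate: float = 0.55
    # external inputs (used when simulate=False)
    rain_path: str | None = None
    level_path: str | None = None
    concentrations_path: str | None = None
    compounds_path: str | None = None
    # event classification
    intensity_threshold: float = 1.0
    event_gap_hours: float = 2.0
    dry_level_sd_threshold: float = 0.5
    # factorization
    pmf_p: int | str = "auto"  # integer, or 'auto' for the scan elbow
    pmf_n_runs: int = 20
    pmf_scan: tuple[int, int] | None = (2, 9)
    pmf_max_iter: int = 2000
    pmf_tol: float = 1e-8
    run_scan: bool = True
    # exposure
    composite_windows_days: list[float] = field(default_factory=lambda: [3.5])
    below_loq_rule: str = "set_to_loq"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(data.get("pmf_scan"), list):
            data["pmf_scan"] = tuple(data["pmf_scan"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d.get("pmf_scan"), tuple):
            d["pmf_scan"] = list(d["pmf_scan"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _stage_done(out: Path, files: list[str]) -> bool:
    return all((out / f).exists() for f in files)


def _stage_simulate(cfg: RunConfig, out: Path) -> None:
    seed = derive_seed(cfg.seed, "simulate")
    truth, hydro = simulate_dataset(
        seed=seed,
        duration_days=cfg.duration_days,
        kappa=cfg.kappa,
        gap_fraction=cfg.gap_fraction,
        event_rate=cfg.event_rate,
    )
    write_timeseries(hydro.rain, out / "rain.csv")
    write_timeseries(hydro.water_level, out / "level.csv")
    write_concentration_table(truth.X_observed, out / "concentrations.csv")
    write_compound_metadata(truth.X_observed.compounds, out / "compounds.csv")
    truth.G_true.rename_axis("timestamp").to_csv(out / "truth_G.csv")
    pd.DataFrame(
        truth.F_true,
        index=[f"F{k+1}" for k in range(truth.F_true.shape[0])],
        columns=truth.X_clean.columns,
    ).rename_axis("factor").to_csv(out / "truth_F.csv")
    truth.event_table.to_csv(out / "truth_events.csv", index=False)


def _load_inputs(cfg: RunConfig, out: Path):
    if cfg.simulate:
        rain = read_timeseries(out / "rain.csv", "rain")
        level = read_timeseries(out / "level.csv", "water_level")
        matrix = read_concentration_table(out / "concentrations.csv", str(out / "compounds.csv"))
    else:
        for name in ("rain_path", "level_path", "concentrations_path", "compounds_path"):
            if getattr(cfg, name) is None:
                raise ValueError(f"simulate=False requires {name}")
        rain = read_timeseries(cfg.rain_path, "rain")
        level = read_timeseries(cfg.level_path, "water_level")
        matrix = read_concentration_table(cfg.concentrations_path, cfg.compounds_path)
    return HydroSeries(rain=rain, water_level=level), matrix


def _stage_events(cfg: RunConfig, out: Path, hydro: HydroSeries) -> EventCatalog:
    ecfg = EventConfig(
        intensity_threshold=cfg.intensity_threshold,
        event_gap=pd.Timedelta(hours=cfg.event_gap_hours),
        dry_level_sd_threshold=cfg.dry_level_sd_threshold,
    )
    catalog = segment_events(hydro.rain, ecfg)
    catalog.dry_periods = find_dry_periods(hydro.rain, hydro.water_level, ecfg)
    catalog.events.to_csv(out / "events.csv", index=False)
    catalog.dry_periods.to_csv(out / "dry_periods.csv", index=False)
    event_summary(catalog, hydro.rain).to_csv(out / "event_summary.csv", index=False)
    return catalog


def _stage_screen(cfg: RunConfig, out: Path, matrix: ConcentrationMatrix) -> SpeciesScreener:
    screener = SpeciesScreener().fit(matrix)
    screener.report_.to_frame().to_csv(out / "screening.csv")
    screener.transform(matrix).rename_axis("timestamp").to_csv(out / "pmf_X.csv")
    screener.transform_uncertainty(matrix).rename_axis("timestamp").to_csv(out / "pmf_U.csv")
    return screener


def _stage_pmf(cfg: RunConfig, out: Path) -> dict:
    X = pd.read_csv(out / "pmf_X.csv", index_col="timestamp", parse_dates=True)
    U = pd.read_csv(out / "pmf_U.csv", index_col="timestamp", parse_dates=True)
    seed = derive_seed(cfg.seed, "pmf")
    pconf = PMFConfig(
        p=6,
        n_runs=cfg.pmf_n_runs,
        p_scan=cfg.pmf_scan,
        max_iter=cfg.pmf_max_iter,
        tol=cfg.pmf_tol,
        seed=seed,
    )
    diagnostics: dict = {"seed": seed}
    if cfg.run_scan or cfg.pmf_p == "auto":
        scan_conf = PMFConfig(
            p=6, n_runs=min(cfg.pmf_n_runs, 4), p_scan=cfg.pmf_scan,
            max_iter=cfg.pmf_max_iter, tol=cfg.pmf_tol, seed=seed,
        )
        scan = scan_factor_numbers(X, U, scan_conf)
        scan.to_csv(out / "pmf_scan.csv", index=False)
        diagnostics["elbow"] = detect_elbow(scan)
    p = diagnostics.get("elbow", 6) if cfg.pmf_p == "auto" else int(cfg.pmf_p)
    pconf.p = p
    model, stability = fit_multi(X, U, p, pconf)
    model.F.rename_axis("factor").to_csv(out / "pmf_F.csv")
    model.G.rename_axis("timestamp").to_csv(out / "pmf_G.csv")
    model.E.rename_axis("timestamp").to_csv(out / "pmf_residuals.csv")
    fp = fingerprints(model)
    fp.percent.rename_axis("factor").to_csv(out / "pmf_fingerprints.csv")
    diagnostics.update(
        {
            "p": p,
            "q_true": model.q_true,
            "q_robust": model.q_robust,
            "q_exp": model.q_exp,
            "q_ratio": model.q_robust / model.q_exp,
            "mean_r2": float(model.per_species_r2.mean()),
            "converged": bool(model.converged),
            "run_q_robust": [float(v) for v in model.run_q_values],
            "stability_relative_spread": stability["relative_spread"],
        }
    )
    with open(out / "pmf_diagnostics.json", "w") as fh:
        json.dump(diagnostics, fh, indent=2)
    return diagnostics


def _stage_exposure(cfg: RunConfig, out: Path, matrix: ConcentrationMatrix) -> dict:
    rows = []
    counts_all = {}
    for days in cfg.composite_windows_days:
        scheme = SamplingScheme(
            window=pd.Timedelta(days=days), below_loq_rule=cfg.below_loq_rule
        )
        composites = {}
        for c in matrix.compounds:
            series = matrix.values[c.compound_id]
            comp = composite_average(series, c.loq, scheme)
            composites[c.compound_id] = comp
            wf = window_factors(series, comp, c.loq)
            ok = wf[wf["valid"] & wf["factor"].notna()]
            rows.append(
                {
                    "compound_id": c.compound_id,
                    "window_days": days,
                    "max_highfreq": float(series.max(skipna=True)),
                    "worst_underestimation": float(ok["factor"].max()) if len(ok) else np.nan,
                }
            )
        report = exceedance_assessment(matrix, composites)
        report.per_compound.to_csv(
            out / f"exposure_{str(days).replace('.', 'p')}d.csv", index=False
        )
        counts_all[f"{days}d"] = report.counts
    pd.DataFrame(rows).to_csv(out / "underestimation.csv", index=False)
    with open(out / "exposure_counts.json", "w") as fh:
        json.dump(counts_all, fh, indent=2)
    return counts_all


def run_pipeline(cfg: RunConfig, resume: bool = False) -> Path:
    """Execute all stages into ``cfg.out_dir``; with ``resume=True``,
    stages whose outputs already exist are skipped.  Any stage failure
    aborts with the stage name; completed outputs persist."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        if cfg.simulate and not (resume and _stage_done(out, ["concentrations.csv"])):
            _stage_simulate(cfg, out)
        hydro, matrix = _load_inputs(cfg, out)

        stage = "events"
        if not (resume and _stage_done(out, ["events.csv", "event_summary.csv"])):
            _stage_events(cfg, out, hydro)

        stage = "screen"
        if not (resume and _stage_done(out, ["screening.csv", "pmf_X.csv", "pmf_U.csv"])):
            _stage_screen(cfg, out, matrix)

        stage = "pmf"
        if not (resume and _stage_done(out, ["pmf_F.csv", "pmf_diagnostics.json"])):
            _stage_pmf(cfg, out)

        stage = "exposure"
        if not (resume and _stage_done(out, ["underestimation.csv", "exposure_counts.json"])):
            _stage_exposure(cfg, out, matrix)
    except Exception as exc:  # noqa: BLE001 — re-raise with stage context
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "stage_seeds": {s: derive_seed(cfg.seed, s) for s in STAGES},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


def make_report(run_dir: str | Path) -> str:
    """Human-readable run summary; missing stage outputs are listed and a
    partial report is still produced."""
    out = Path(run_dir)
    lines = [f"streampulse run report — {out}"]
    missing = []

    if (out / "event_summary.csv").exists():
        ev = pd.read_csv(out / "events.csv") if (out / "events.csv").exists() else pd.DataFrame()
        summary = pd.read_csv(out / "event_summary.csv")
        total = summary.loc[summary["event"] == "campaign", "total_rain"]
        n_large = int((ev["kind"] == "large").sum()) if len(ev) else 0
        n_small = int((ev["kind"] == "small").sum()) if len(ev) else 0
        lines.append(
            f"events: {n_large} large, {n_small} small; "
            f"total rain {float(total.iloc[0]):.1f} mm"
        )
    else:
        missing.append("events")

    if (out / "screening.csv").exists():
        sc = pd.read_csv(out / "screening.csv")
        counts = sc["species_class"].value_counts().to_dict()
        lines.append(f"screening: {counts}")
    else:
        missing.append("screen")

    if (out / "pmf_diagnostics.json").exists():
        with open(out / "pmf_diagnostics.json") as fh:
            diag = json.load(fh)
        lines.append(
            f"pmf: p={diag['p']}, Q_robust/Q_exp={diag['q_ratio']:.2f}, "
            f"mean R2={diag['mean_r2']:.2f}, converged={diag['converged']}"
        )
        if "elbow" in diag:
            lines.append(f"pmf scan elbow: p={diag['elbow']}")
        if (out / "truth_F.csv").exists() and (out / "pmf_F.csv").exists():
            from .pmf import match_factors

            F_est = pd.read_csv(out / "pmf_F.csv", index_col="factor")
            F_true = pd.read_csv(out / "truth_F.csv", index_col="factor")
            if F_est.shape[0] == F_true.shape[0]:
                _, cos = match_factors(F_est, F_true)
                lines.append(
                    f"recovery vs truth: mean matched profile cosine "
                    f"{np.nanmean(cos):.3f}"
                )
    else:
        missing.append("pmf")

    if (out / "exposure_counts.json").exists():
        with open(out / "exposure_counts.json") as fh:
            counts = json.load(fh)
        for window, c in counts.items():
            lines.append(
                f"exposure {window}: {c['ppp_aqs_highfreq']} PPPs > AQS (20-min), "
                f"{c['ppp_rac_highfreq']} PPPs > RAC (20-min), "
                f"{c['ppp_rac_composite']} PPPs > RAC (composite)"
            )
        if (out / "underestimation.csv").exists():
            ue = pd.read_csv(out / "underestimation.csv")
            worst = ue.loc[ue["worst_underestimation"].idxmax()]
            lines.append(
                f"worst underestimation: {worst['compound_id']} "
                f"x{worst['worst_underestimation']:.1f} ({worst['window_days']}-day window)"
            )
    else:
        missing.append("exposure")

    if missing:
        lines.append(f"missing stages: {', '.join(missing)}")
    return "\n".join(lines)
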