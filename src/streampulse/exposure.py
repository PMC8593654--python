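"""Acute-exposure assessment: composite-sampling emulation, peak
underestimation factors, and exceedances of acute quality standards (AQS)
and regulatory acceptable concentrations (RAC).

Regulatory monitoring programs pool water into time-composite samples
(3.5 days during the spraying season, 14 days otherwise) and compare the
composite mean against acute standards.  Short concentration peaks are
averaged away by this scheme; the *underestimation factor* — the maximum
high-frequency (20-min) concentration in a window divided by that window's
composite mean — quantifies the bias.  Composite windows are half-open
intervals aligned to the record start plus a configurable offset; the
offset sweep bounds how much the factor depends on when the sampler
happened to start.

Below-LOQ handling for composites follows the monitoring convention:
values below the LOQ enter the composite as LOQ (configurable).  Windows
missing more than ``max_gap_fraction`` of their samples are flagged
invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CompoundMeta, ConcentrationMatrix

__all__ = [
    "SamplingScheme",
    "ExposureReport",
    "composite_average",
    "underestimation_factor",
    "window_factors",
    "exceedance_assessment",
    "start_offset_sweep",
]

BELOW_LOQ_RULES = ("set_to_loq", "set_to_half_loq", "zero")


@dataclass(frozen=True)
class SamplingScheme:
    """A time-composite emulation scheme."""

    window: pd.Timedelta = pd.Timedelta("3.5D")
    start_offset: pd.Timedelta = pd.Timedelta(0)
    below_loq_rule: str = "set_to_loq"
    max_gap_fraction: float = 0.10

    def __post_init__(self) -> None:
        if pd.Timedelta(self.window) <= pd.Timedelta(0):
            raise ValueError("window must be > 0")
        if self.below_loq_rule not in BELOW_LOQ_RULES:
            raise ValueError(f"below_loq_rule must be one of {BELOW_LOQ_RULES}")
        if not 0 <= self.max_gap_fraction < 1:
            raise ValueError("max_gap_fraction must be in [0, 1)")


def _apply_rule(values: pd.Series, loq: float, rule: str) -> pd.Series:
    below = values < loq
    if rule == "set_to_loq":
        return values.mask(below, loq)
    if rule == "set_to_half_loq":
        return values.mask(below, loq / 2.0)
    return values.mask(below, 0.0)


def composite_average(
    series: pd.Series, loq: float, scheme: SamplingScheme
) -> pd.DataFrame:
    """Emulate time-composite sampling of one compound's 20-min series.

    Returns one row per window [offset + k*window, offset + (k+1)*window):
    window_start, window_end, composite (mean over non-gap samples after
    the below-LOQ rule), n_samples, gap_fraction, valid, partial.  Gaps
    are NaN samples; a window whose gap fraction exceeds the scheme's
    ``max_gap_fraction`` is flagged invalid (composite still reported).
    """
    step = series.index[1] - series.index[0] if len(series) > 1 else pd.Timedelta("20min")
    window = pd.Timedelta(scheme.window)
    if window < step:
        raise ValueError("window shorter than one sample step")
    start = series.index[0] + pd.Timedelta(scheme.start_offset)
    record_end = series.index[-1] + step
    substituted = _apply_rule(series, loq, scheme.below_loq_rule)

    rows = []
    k = 0
    while start + k * window < record_end:
        w0 = start + k * window
        w1 = w0 + window
        chunk = substituted[(substituted.index >= w0) & (substituted.index < w1)]
        n_slots = int(window / step)
        n_valid = int(chunk.notna().sum())
        gap_fraction = 1.0 - n_valid / n_slots if n_slots else 1.0
        rows.append(
            {
                "window_start": w0,
                "window_end": w1,
                "composite": float(chunk.mean()) if n_valid else np.nan,
                "n_samples": n_valid,
                "gap_fraction": gap_fraction,
                "valid": gap_fraction <= scheme.max_gap_fraction,
                "partial": w1 > record_end,
            }
        )
        k += 1
    return pd.DataFrame(rows)


def underestimation_factor(
    highfreq: pd.Series,
    composites: pd.DataFrame,
    window_index: int,
    loq: float | None = None,
) -> tuple[float, bool]:
    """Peak-to-composite ratio for one window: max 20-min value divided by
    the composite mean.

    Returns ``(factor, is_bound)``.  When the composite mean is below the
    LOQ the true denominator is unknown; the LOQ is used instead and the
    result flagged as a lower bound.  A zero composite (possible under the
    'zero' rule) makes the factor undefined (NaN, flagged)."""
    row = composites.iloc[window_index]
    w0, w1 = row["window_start"], row["window_end"]
    peak = highfreq[(highfreq.index >= w0) & (highfreq.index < w1)].max()
    denom = row["composite"]
    is_bound = False
    if loq is not None and (pd.isna(denom) or denom < loq):
        denom = loq
        is_bound = True
    if pd.isna(denom) or denom == 0:
        return float("nan"), True
    return float(peak / denom), is_bound


def window_factors(
    highfreq: pd.Series, composites: pd.DataFrame, loq: float | None = None
) -> pd.DataFrame:
    """Underestimation factor for every window of a composite table."""
    rows = []
    for i in range(len(composites)):
        f, bound = underestimation_factor(highfreq, composites, i, loq)
        rows.append(
            {
                "window_start": composites.iloc[i]["window_start"],
                "factor": f,
                "is_bound": bound,
                "valid": bool(composites.iloc[i]["valid"]),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ExposureReport:
    """Per-compound exceedance bookkeeping at both temporal resolutions.

    ``per_compound`` columns: max_highfreq, max_composite, n_aqs_samples,
    n_aqs_episodes, aqs_highfreq, aqs_composite, (same for rac),
    underestimation (worst valid window).  ``counts`` holds the distinct
    PPP tallies and episode/sample totals.  Compounds lacking both
    standards are listed in ``unassessed``.
    """

    per_compound: pd.DataFrame
    counts: dict
    composites: dict[str, pd.DataFrame] = field(default_factory=dict)
    unassessed: list[str] = field(default_factory=list)


def _episodes(exceeding: np.ndarray) -> int:
    """Number of maximal runs of consecutive True samples."""
    if exceeding.size == 0:
        return 0
    x = exceeding.astype(int)
    return int(x[0] + np.sum((np.diff(x) == 1)))


def exceedance_assessment(
    matrix: ConcentrationMatrix,
    composites: dict[str, pd.DataFrame],
    meta: list[CompoundMeta] | None = None,
) -> ExposureReport:
    """Count standard exceedances at 20-min and composite resolution.

    A 20-min exceedance is a sample above the standard; an *episode* is a
    maximal run of consecutive exceeding samples; a composite exceedance
    is a composite mean above the standard.  Compounds with neither AQS
    nor RAC are excluded from all tallies and listed."""
    meta = meta or matrix.compounds
    by_id = {c.compound_id: c for c in meta}
    rows = []
    unassessed = []
    for cid in matrix.compound_ids:
        c = by_id[cid]
        if c.aqs is None and c.rac is None:
            unassessed.append(cid)
            continue
        series = matrix.values[cid].dropna()
        comp = composites.get(cid)
        comp_vals = (
            comp.loc[comp["valid"], "composite"].dropna()
            if comp is not None and len(comp)
            else pd.Series(dtype=float)
        )
        entry = {
            "compound_id": cid,
            "max_highfreq": float(series.max()) if len(series) else np.nan,
            "max_composite": float(comp_vals.max()) if len(comp_vals) else np.nan,
        }
        for std_name in ("aqs", "rac"):
            std = getattr(c, std_name)
            if std is None:
                entry.update(
                    {
                        f"n_{std_name}_samples": 0,
                        f"n_{std_name}_episodes": 0,
                        f"{std_name}_highfreq": False,
                        f"{std_name}_composite": False,
                    }
                )
                continue
            exceed = series.to_numpy() > std
            entry[f"n_{std_name}_samples"] = int(exceed.sum())
            entry[f"n_{std_name}_episodes"] = _episodes(exceed)
            entry[f"{std_name}_highfreq"] = bool(exceed.any())
            entry[f"{std_name}_composite"] = bool((comp_vals > std).any())
        rows.append(entry)

    per_compound = pd.DataFrame(rows)
    if len(per_compound):
        counts = {
            "ppp_aqs_highfreq": int(per_compound["aqs_highfreq"].sum()),
            "ppp_aqs_composite": int(per_compound["aqs_composite"].sum()),
            "ppp_rac_highfreq": int(per_compound["rac_highfreq"].sum()),
            "ppp_rac_composite": int(per_compound["rac_composite"].sum()),
            "episodes_aqs_highfreq": int(per_compound["n_aqs_episodes"].sum()),
            "episodes_rac_highfreq": int(per_compound["n_rac_episodes"].sum()),
            "samples_aqs_highfreq": int(per_compound["n_aqs_samples"].sum()),
            "samples_rac_highfreq": int(per_compound["n_rac_samples"].sum()),
        }
    else:
        counts = {k: 0 for k in (
            "ppp_aqs_highfreq", "ppp_aqs_composite", "ppp_rac_highfreq",
            "ppp_rac_composite", "episodes_aqs_highfreq", "episodes_rac_highfreq",
            "samples_aqs_highfreq", "samples_rac_highfreq",
        )}
    return ExposureReport(
        per_compound=per_compound,
        counts=counts,
        composites=composites,
        unassessed=unassessed,
    )


def start_offset_sweep(
    highfreq: pd.Series,
    scheme: SamplingScheme,
    offsets: list[pd.Timedelta],
    loq: float | None = None,
) -> pd.DataFrame:
    """Worst-case underestimation over composite start offsets.

    Recomputes the composites and per-window factors for each offset and
    reports, per offset, the maximum factor over valid windows.  The
    overall worst case is the table's max row."""
    rows = []
    for off in offsets:
        sch = SamplingScheme(
            window=scheme.window,
            start_offset=pd.Timedelta(off),
            below_loq_rule=scheme.below_loq_rule,
            max_gap_fraction=scheme.max_gap_fraction,
        )
        comp = composite_average(highfreq, loq if loq is not None else 0.0, sch)
        wf = window_factors(highfreq, comp, loq)
        ok = wf[wf["valid"] & wf["factor"].notna()]
        rows.append(
            {
                "offset": pd.Timedelta(off),
                "max_factor": float(ok["factor"].max()) if len(ok) else np.nan,
                "argmax_window": (
                    ok.loc[ok["factor"].idxmax(), "window_start"] if len(ok) else pd.NaT
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tabular (peak vs composite) assessment
# ---------------------------------------------------------------------------


def peak_vs_composite_assessment(table: pd.DataFrame) -> pd.DataFrame:
    """Assess a ready-made comparison table of per-compound maxima and
    composite concentrations against their standards.

    Expected columns: compound, max_20min, composite, composite_below_loq
    (bool), loq (used as the denominator bound when the composite is
    censored), aqs, rac.  Missing max_20min means the compound was not
    measured at high frequency.  Adds: underestimation, is_bound,
    aqs_highfreq, rac_highfreq, aqs_composite, rac_composite.
    """
    out = table.copy()
    factors, bounds = [], []
    for _, row in out.iterrows():
        peak = row.get("max_20min")
        comp = row.get("composite")
        if pd.isna(peak):
            factors.append(np.nan)
            bounds.append(False)
            continue
        if bool(row.get("composite_below_loq", False)) or (
            pd.notna(row.get("loq")) and pd.notna(comp) and comp < row["loq"]
        ):
            factors.append(float(peak) / float(row["loq"]))
            bounds.append(True)
        elif pd.isna(comp) or comp == 0:
            factors.append(np.nan)
            bounds.append(True)
        else:
            factors.append(float(peak) / float(comp))
            bounds.append(False)
    out["underestimation"] = factors
    out["is_bound"] = bounds

    def _exceeds(value, std):
        return bool(pd.notna(value) and pd.notna(std) and value > std)

    out["aqs_highfreq"] = [
        _exceeds(r["max_20min"], r.get("aqs")) for _, r in out.iterrows()
    ]
    out["rac_highfreq"] = [
        _exceeds(r["max_20min"], r.get("rac")) for _, r in out.iterrows()
    ]
    comp_eff = out.apply(
        lambda r: np.nan if bool(r.get("composite_below_loq", False)) else r["composite"],
        axis=1,
    )
    out["aqs_composite"] = [
        _exceeds(v, r.get("aqs")) for v, (_, r) in zip(comp_eff, out.iterrows())
    ]
    out["rac_composite"] = [
        _exceeds(v, r.get("rac")) for v, (_, r) in zip(comp_eff, out.iterrows())
    ]
    return out
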