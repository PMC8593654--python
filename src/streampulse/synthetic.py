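"""Synthetic catchment: rainfall, stream level and multi-compound
concentration series with known ground-truth factor structure.

The generator emulates the statistical regime of a 41-day, 20-minute
resolution monitoring campaign in a small agricultural stream: episodic
rainfall (a mix of sub- and supra-threshold storms separated by dry
spells), a linear-reservoir water-level response, and concentration
dynamics driven by a small number of latent sources.  Each pulse-type
source responds to rain through a lagged gamma kernel with event-specific
activation (different storms mobilise different sources); one "legacy"
source anti-correlates with water level, emulating dilution of a
groundwater-borne historical contaminant during events.

Observation noise is zero-truncated Gaussian with standard deviation
``sqrt((a_j * x)**2 + kappa * LOQ_j**2)`` — the same functional form the
factor-analysis uncertainty model assumes — and values below the LOQ are
flagged as censored while the drawn value is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CompoundMeta, ConcentrationMatrix, HydroSeries

__all__ = [
    "SourceScenario",
    "SimulationTruth",
    "simulate_rainfall",
    "simulate_water_level",
    "simulate_concentrations",
    "default_scenario",
    "default_compounds",
    "simulate_dataset",
]

RAIN_STEP = pd.Timedelta("10min")
LEVEL_STEP = pd.Timedelta("15min")
CHEM_STEP = pd.Timedelta("20min")
_T0 = pd.Timestamp("2019-05-27 00:00")  # arbitrary campaign start


@dataclass
class SourceScenario:
    """Ground-truth source structure for the concentration generator.

    ``profiles_true`` has one row per factor (ng/l per unit contribution).
    Pulse factors respond to rainfall through a gamma kernel with the given
    lag (minutes), time constant (hours) and gain (contribution per mm);
    legacy factors instead scale inversely with water level.
    """

    profiles_true: np.ndarray  # (p, m), nonnegative
    lags_min: np.ndarray  # (p,) minutes, >= 0
    taus_h: np.ndarray  # (p,) kernel time constant, hours
    gains: np.ndarray  # (p,) contribution per mm rain
    baselines: np.ndarray  # (p,) constant contribution
    legacy_flags: np.ndarray  # (p,) bool
    activation_prob: float = 0.7  # chance a pulse factor responds to an event
    species_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.profiles_true = np.asarray(self.profiles_true, dtype=float)
        if self.profiles_true.ndim != 2 or self.profiles_true.shape[0] < 1:
            raise ValueError("profiles_true must be a (p, m) matrix, p >= 1")
        if (self.profiles_true < 0).any():
            raise ValueError("profiles_true must be nonnegative")
        for name in ("lags_min", "taus_h", "gains", "baselines"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.n_factors,):
                raise ValueError(f"{name} must have length p={self.n_factors}")
            setattr(self, name, arr)
        if (self.lags_min < 0).any():
            raise ValueError("lags must be >= 0")
        self.legacy_flags = np.asarray(self.legacy_flags, dtype=bool)

    @property
    def n_factors(self) -> int:
        return self.profiles_true.shape[0]

    @property
    def n_species(self) -> int:
        return self.profiles_true.shape[1]


@dataclass
class SimulationTruth:
    """Everything a recovery test needs: the latent contributions, the
    noiseless matrix, the observed (noisy, censored) matrix and the planted
    event table."""

    G_true: pd.DataFrame  # (n, p)
    X_clean: pd.DataFrame  # (n, m), == G_true @ profiles_true exactly
    X_observed: ConcentrationMatrix
    event_table: pd.DataFrame
    F_true: np.ndarray  # (p, m)


# ---------------------------------------------------------------------------
# Rainfall
# ---------------------------------------------------------------------------


def simulate_rainfall(
    duration_days: float = 41.0,
    event_rate: float = 0.55,
    seed: int | None = None,
    *,
    p_large: float = 0.35,
    large_peak_mean: float = 2.2,
    max_intensity: float = 14.5,
    return_events: bool = False,
):
    """Generate a 10-minute rainfall series (mm per step).

    Events are contiguous wet spells separated by at least 2 h of dry
    weather.  With probability ``p_large`` an event is a storm whose peak
    intensity exceeds 1 mm/10 min (drawn as ``1.3 + Exp(large_peak_mean)``,
    capped at ``max_intensity``); otherwise all its steps stay below
    1 mm/10 min.  Defaults target roughly 0.55 events/day with about a
    third large, the regime of a wet alpine-foreland growing season.

    Returns the series, and with ``return_events=True`` also a DataFrame of
    planted events (start, end, kind, max_intensity, total_mm).
    """
    if duration_days <= 0:
        raise ValueError("duration_days must be > 0")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration_days * 24 * 6))
    rain = np.zeros(n_steps)
    events: list[dict] = []

    min_gap = 13  # > 2 h of dry steps between events
    mean_event_len = 16.0
    mean_gap = max(min_gap + 1.0, 144.0 / max(event_rate, 1e-9) - mean_event_len)

    t = int(min_gap + rng.exponential(mean_gap)) if event_rate > 0 else n_steps
    while t < n_steps and event_rate > 0:
        large = rng.random() < p_large
        if large:
            dur = int(rng.integers(6, 49))  # 1 to 8 hours
            peak = min(1.3 + rng.exponential(large_peak_mean), max_intensity)
            i0 = max(dur / 6.0, 1.0)  # sharp early peak, fast decay
            i = np.arange(dur, dtype=float)
            env = (i + 1) / i0 * np.exp(1.0 - (i + 1) / i0)
            env /= env.max()
            prof = peak * env * rng.uniform(0.7, 1.0, dur)
            kpk = int(np.argmax(env))
            prof[kpk] = peak  # planted maximum survives jitter
            # rescale off-peak mass toward a realistic event total (mm)
            target = peak + rng.gamma(4.0, 1.8)
            off = prof.sum() - peak
            if off > 0:
                scale = np.clip((target - peak) / off, 0.02, 1.0)
                mask_off = np.ones(dur, dtype=bool)
                mask_off[kpk] = False
                prof[mask_off] *= scale
        else:
            dur = int(rng.integers(1, 7))
            prof = rng.uniform(0.05, 0.6, dur)
            prof[rng.integers(0, dur)] = rng.uniform(0.3, 0.95)
        dur = min(dur, n_steps - t)
        prof = prof[:dur]
        rain[t : t + dur] = prof
        events.append(
            {
                "start_step": t,
                "end_step": t + dur,
                "kind": "large" if prof.max() > 1.0 else "small",
                "max_intensity": float(prof.max()),
                "total_mm": float(prof.sum()),
            }
        )
        t = t + dur + int(min_gap + rng.exponential(mean_gap))

    index = pd.date_range(_T0, periods=n_steps, freq=RAIN_STEP)
    series = pd.Series(rain, index=index, name="rain")
    if return_events:
        ev = pd.DataFrame(
            events,
            columns=["start_step", "end_step", "kind", "max_intensity", "total_mm"],
        )
        ev["start"] = index[0] + ev["start_step"] * RAIN_STEP if len(ev) else pd.NaT
        return series, ev
    return series


# ---------------------------------------------------------------------------
# Water level
# ---------------------------------------------------------------------------


def simulate_water_level(
    rain: pd.Series,
    baseflow: float = 10.0,
    reservoir_k: pd.Timedelta | str = "20h",
    gain: float = 1.2,
    output_spacing: pd.Timedelta | str | None = None,
) -> pd.Series:
    """Water level (cm) from a single linear reservoir driven by rainfall.

    Each rain step's mass enters storage instantaneously at the step start;
    between inputs, storage decays exponentially with time constant
    ``reservoir_k`` so the level relaxes toward ``baseflow`` with half-life
    ``k*ln(2)``.  ``gain`` is cm of level per mm of stored rain.  Output is
    on the rain grid unless ``output_spacing`` is given, in which case the
    exact solution is evaluated at those instants (default pipeline use:
    15-minute level readings).
    """
    k = pd.Timedelta(reservoir_k)
    if k <= pd.Timedelta(0):
        raise ValueError("reservoir_k must be > 0")
    dt = (rain.index[1] - rain.index[0]) if len(rain) > 1 else RAIN_STEP
    decay = np.exp(-dt / k)
    r = rain.to_numpy(dtype=float)
    # storage immediately after the input at each step
    s = np.empty_like(r)
    acc = 0.0
    for i, ri in enumerate(r):
        acc = acc * decay if i else 0.0
        acc += ri
        s[i] = acc

    if output_spacing is None:
        level = baseflow + gain * s
        return pd.Series(level, index=rain.index, name="water_level")

    spacing = pd.Timedelta(output_spacing)
    t_end = rain.index[-1] + dt
    n_out = int(np.floor((t_end - rain.index[0]) / spacing))
    out_index = pd.DatetimeIndex(rain.index[0] + spacing * np.arange(n_out))
    step_of = np.searchsorted(rain.index.view("int64"), out_index.view("int64"), "right") - 1
    elapsed = (out_index.view("int64") - rain.index.view("int64")[step_of]).astype(float)
    frac = np.exp(-elapsed / float(k.value))
    level = baseflow + gain * s[step_of] * frac
    return pd.Series(level, index=out_index, name="water_level")


# ---------------------------------------------------------------------------
# Concentrations
# ---------------------------------------------------------------------------


def _gamma_kernel(lag_min: float, tau_h: float) -> np.ndarray:
    """Discrete unit-mass response kernel on the 10-min grid: a shape-2
    gamma pulse delayed by ``lag_min`` (rounded to the grid)."""
    lag_steps = int(round(lag_min / 10.0))
    tau_steps = max(tau_h * 6.0, 0.5)
    length = int(np.ceil(tau_steps * 8)) + 1
    i = np.arange(length, dtype=float)
    body = i * np.exp(-i / tau_steps)
    if body.sum() == 0:
        body[0] = 1.0
    body /= body.sum()
    return np.concatenate([np.zeros(lag_steps), body])


def simulate_concentrations(
    scenario: SourceScenario,
    rain: pd.Series,
    level: pd.Series,
    meta: list[CompoundMeta],
    seed: int | None = None,
    *,
    kappa: float = 1.0,
    censor: bool = True,
    gap_fraction: float = 0.0,
    event_table: pd.DataFrame | None = None,
) -> SimulationTruth:
    """Generate the observed concentration matrix and its ground truth.

    Pulse factors: contribution = baseline + gain * (activated rain (*)
    gamma kernel); per-event activations are Bernoulli(activation_prob) x
    Gamma(2, 0.5) draws, so different storms mobilise different sources.
    Legacy factors: contribution = baseline * min(level)/level (dilution).

    Noise: zero-truncated Gaussian, sd = sqrt((a_j x)^2 + kappa LOQ_j^2)
    around the clean value.  With ``censor=True`` cells whose observed
    value falls below the compound LOQ are flagged below-LOQ; the drawn
    value is stored unchanged.  ``gap_fraction`` of rows is blanked out in
    a few contiguous maintenance-style blocks.
    """
    if scenario.n_species != len(meta):
        raise ValueError(
            f"scenario has {scenario.n_species} species but metadata lists {len(meta)}"
        )
    rng = np.random.default_rng(seed)
    p = scenario.n_factors
    r = rain.to_numpy(dtype=float)
    n10 = len(r)
    # chemistry grid = every second rain step
    chem_index = rain.index[::2]
    n = len(chem_index)

    # event-specific source activations
    activations = np.ones((p, n10))
    if event_table is not None and len(event_table):
        for k in range(p):
            if scenario.legacy_flags[k]:
                continue
            for _, ev in event_table.iterrows():
                if rng.random() < scenario.activation_prob:
                    amp = rng.gamma(1.2, 1.0)
                else:
                    amp = 0.0
                activations[k, int(ev["start_step"]) : int(ev["end_step"])] = amp

    level_chem = np.interp(
        chem_index.view("int64").astype(float),
        level.index.view("int64").astype(float),
        level.to_numpy(dtype=float),
    )
    lref = float(level_chem.min())

    G = np.empty((n, p))
    for k in range(p):
        if scenario.legacy_flags[k]:
            G[:, k] = scenario.baselines[k] * lref / level_chem
        else:
            kern = _gamma_kernel(scenario.lags_min[k], scenario.taus_h[k])
            conv = np.convolve(r * activations[k], kern)[:n10]
            G[:, k] = scenario.baselines[k] + scenario.gains[k] * conv[::2]

    F = scenario.profiles_true
    X_clean = G @ F

    loq = np.array([c.loq for c in meta])
    a = np.array([c.error_fraction for c in meta])
    sd = np.sqrt((a[None, :] * X_clean) ** 2 + kappa * loq[None, :] ** 2)
    if np.all(sd == 0):
        X_obs = X_clean.copy()
    else:
        lower = np.where(sd > 0, -X_clean / np.where(sd > 0, sd, 1.0), 0.0)
        noise = stats.truncnorm.rvs(
            lower, np.inf, loc=0.0, scale=np.where(sd > 0, sd, 1.0),
            size=X_clean.shape, random_state=rng,
        )
        X_obs = X_clean + np.where(sd > 0, noise, 0.0)

    ids = [c.compound_id for c in meta]
    values = pd.DataFrame(X_obs, index=chem_index, columns=ids)

    if gap_fraction > 0:
        n_gap = int(round(gap_fraction * n))
        n_blocks = max(1, min(4, n_gap // 8))
        per_block = max(1, n_gap // n_blocks)
        starts = rng.choice(np.arange(1, n - per_block - 1), size=n_blocks, replace=False)
        for s0 in starts:
            values.iloc[int(s0) : int(s0) + per_block] = np.nan

    matrix = ConcentrationMatrix(values=values, compounds=list(meta))
    if not censor:
        matrix.below_loq.loc[:, :] = False

    ev = event_table if event_table is not None else pd.DataFrame(
        columns=["start_step", "end_step", "kind", "max_intensity", "total_mm"]
    )
    return SimulationTruth(
        G_true=pd.DataFrame(G, index=chem_index, columns=[f"F{k+1}" for k in range(p)]),
        X_clean=pd.DataFrame(X_clean, index=chem_index, columns=ids),
        X_observed=matrix,
        event_table=ev,
        F_true=F.copy(),
    )


# ---------------------------------------------------------------------------
# Default study-shaped scenario
# ---------------------------------------------------------------------------

_SPECIES = [
    # (id, class, legacy, loq ng/l, error fraction, aqs, rac)
    ("oxadixyl", "fungicide", True, 6.0, 0.03, None, None),
    ("simazine", "herbicide", False, 5.0, 0.04, 1000.0, None),
    ("azoxystrobin_tp", "TP_fungicide", False, 10.0, 0.05, None, None),
    ("myclobutanil", "fungicide", False, 8.0, 0.06, 1500.0, None),
    ("terbuthylazine_tp", "TP_herbicide", False, 5.0, 0.04, None, None),
    ("metolachlor", "herbicide", False, 4.0, 0.02, 1200.0, 690.0),
    ("metamitron", "herbicide", False, 15.0, 0.07, 10000.0, None),
    ("napropamide", "herbicide", False, 10.0, 0.05, 6600.0, None),
    ("pyrimethanil", "fungicide", False, 12.0, 0.08, 7000.0, None),
    ("thiacloprid", "insecticide", False, 3.0, 0.06, 80.0, 200.0),
    ("azoxystrobin", "fungicide", False, 6.0, 0.03, 550.0, 3300.0),
    ("cyprodinil", "fungicide", False, 10.0, 0.09, 3300.0, None),
    ("fluopyram", "fungicide", False, 8.0, 0.04, 25100.0, 13500.0),
    ("fenhexamid", "fungicide", False, 20.0, 0.10, 29000.0, None),
    ("fenpyrazamine", "fungicide", False, 15.0, 0.11, None, None),
    ("nicosulfuron", "herbicide", False, 2.0, 0.05, 230.0, 230.0),
    ("diuron", "herbicide", False, 5.0, 0.04, 250.0, 1830.0),
]


def default_compounds() -> list[CompoundMeta]:
    """17 compounds with LOQs, error fractions and (where defined) acute
    quality standards spanning the realistic monitoring range."""
    return [
        CompoundMeta(cid, cls, legacy, loq, err, aqs, rac)
        for cid, cls, legacy, loq, err, aqs, rac in _SPECIES
    ]


def default_scenario() -> SourceScenario:
    """Six sources over 17 species: one legacy dilution factor loading
    almost entirely on the withdrawn fungicide, and five event-driven
    factors with distinct lags, time constants and near-block species
    fingerprints (ng/l per unit contribution)."""
    m = len(_SPECIES)
    F = np.zeros((6, m))
    # factor 1: legacy / dilution — oxadixyl ~99% plus traces of old residues
    F[0, 0] = 135.0
    F[0, 1] = 25.0
    F[0, 2] = 40.0
    F[0, 3] = 12.0
    F[0, 4] = 18.0
    # factor 2: early herbicide flush
    F[1, 5] = 420.0
    F[1, 6] = 260.0
    F[1, 4] = 9.0
    # factor 3: napropamide-dominated source
    F[2, 7] = 900.0
    F[2, 5] = 30.0
    F[2, 8] = 40.0
    # factor 4: fungicide+insecticide mix (berry crops)
    F[3, 8] = 180.0
    F[3, 9] = 240.0
    F[3, 11] = 90.0
    F[3, 12] = 160.0
    # factor 5: fungicide source, large dynamic range
    F[4, 10] = 650.0
    F[4, 11] = 130.0
    F[4, 12] = 2400.0
    F[4, 7] = 40.0
    # factor 6: late-season mix
    F[5, 13] = 300.0
    F[5, 14] = 170.0
    F[5, 15] = 45.0
    F[5, 16] = 60.0
    F[5, 3] = 20.0
    return SourceScenario(
        profiles_true=F,
        lags_min=np.array([0.0, 20.0, 240.0, 60.0, 140.0, 480.0]),
        taus_h=np.array([1.0, 0.7, 2.0, 1.2, 1.8, 3.0]),
        gains=np.array([0.0, 2.2, 1.8, 2.0, 2.7, 1.8]),
        baselines=np.array([1.0, 0.09, 0.075, 0.11, 0.09, 0.13]),
        legacy_flags=np.array([True, False, False, False, False, False]),
        activation_prob=0.6,
        species_ids=[s[0] for s in _SPECIES],
    )


def simulate_dataset(
    seed: int = 0,
    duration_days: float = 41.0,
    scenario: SourceScenario | None = None,
    meta: list[CompoundMeta] | None = None,
    *,
    kappa: float = 1.0,
    gap_fraction: float = 0.05,
    event_rate: float = 0.55,
) -> tuple[SimulationTruth, HydroSeries]:
    """End-to-end default simulation: rainfall, level (15-min output) and
    concentrations.  One seed drives all three stages."""
    rng = np.random.default_rng(seed)
    s_rain, s_conc = rng.integers(0, 2**31, size=2)
    rain, events = simulate_rainfall(
        duration_days, event_rate=event_rate, seed=int(s_rain), return_events=True
    )
    level10 = simulate_water_level(rain)
    level15 = simulate_water_level(rain, output_spacing=LEVEL_STEP)
    truth = simulate_concentrations(
        scenario or default_scenario(),
        rain,
        level10,
        meta or default_compounds(),
        seed=int(s_conc),
        kappa=kappa,
        gap_fraction=gap_fraction,
        event_table=events,
    )
    return truth, HydroSeries(rain=rain, water_level=level15)
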