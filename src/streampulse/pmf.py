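"""Uncertainty-weighted, nonnegativity-constrained, robust positive matrix
factorization (PMF).

The model is X = G F + E with G (n x p) and F (p x m) nonnegative; the fit
minimises the weighted least-squares objective

    Q = sum_ij ( (x_ij - (GF)_ij) / u_ij )**2

where u_ij is the per-cell measurement uncertainty.  The solver is
alternating weighted nonnegative least squares in its hierarchical (HALS)
form: each factor row/column update is an exact coordinate minimisation
under nonnegativity, so Q is non-increasing across sweeps.

Robust mode caps the influence of outlying cells: whenever a cell's scaled
residual |e_ij / u_ij| exceeds ``robust_cutoff`` (default 4), its effective
uncertainty is inflated to |e_ij| / cutoff for the next pass, and the
reported Q_robust excludes those cells entirely.  Multi-start fitting (20
runs by default) guards against poor local minima; Q_robust/Q_exp, with
Q_exp = n*m_good - p*(n + m_good), is the factor-number diagnostic: it
tends to 1 when p and the uncertainties are both adequate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, nnls
from sklearn.base import BaseEstimator

__all__ = [
    "PMFConfig",
    "PMFModel",
    "FingerprintTable",
    "BootstrapResult",
    "RobustPMF",
    "fit_single",
    "fit_multi",
    "q_expected",
    "scan_factor_numbers",
    "detect_elbow",
    "fingerprints",
    "per_species_fit",
    "bootstrap",
    "match_factors",
]


@dataclass
class PMFConfig:
    """Fitting configuration shared by the pipeline stages."""

    p: int = 6
    n_runs: int = 20
    p_scan: tuple[int, int] | None = None  # inclusive; default 2..m_good-1
    robust_cutoff: float = 4.0
    max_iter: int = 5000
    tol: float = 1e-8
    tol_iters: int = 10
    robust_passes: int = 4
    seed: int = 0
    bootstrap_reps: int = 50
    bootstrap_block: int = 72  # samples per moving block (one day at 20 min)

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.robust_cutoff <= 0:
            raise ValueError("robust_cutoff must be > 0")


@dataclass
class PMFModel:
    """A fitted factorization with its diagnostics.

    ``F`` (p x m) are factor profiles (ng/l per unit contribution), ``G``
    (n x p) the per-sample contributions, ``C = G F`` the fitted
    concentrations and ``E = X - C`` the residuals.
    """

    F: pd.DataFrame
    G: pd.DataFrame
    E: pd.DataFrame
    q_true: float
    q_robust: float
    q_exp: int
    per_species_r2: pd.Series
    converged: bool
    run_q_values: np.ndarray
    outlier_mask: np.ndarray
    seed: int

    @property
    def C(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.G.to_numpy() @ self.F.to_numpy(),
            index=self.G.index,
            columns=self.F.columns,
        )

    @property
    def n_factors(self) -> int:
        return self.F.shape[0]


def q_expected(n: int, m_good: int, p: int) -> int:
    """Expected value of Q under correct uncertainties:
    n*m_good - p*(n + m_good), the residual degrees of freedom."""
    if n <= 0 or m_good <= 0 or p < 0:
        raise ValueError("n, m_good must be positive and p nonnegative")
    q = n * m_good - p * (n + m_good)
    if q <= 0:
        raise ValueError(
            f"over-parameterized: n={n}, m_good={m_good}, p={p} leaves no "
            "residual degrees of freedom"
        )
    return q


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------

_TINY = 1e-300


@numba.njit(cache=True)
def _hals_core(X, U, G, F, max_iter, tol, tol_iters, floor, cutoff, burn_in):  # pragma: no cover
    """Weighted HALS with interleaved robust reweighting.

    With cutoff > 0, after ``burn_in`` sweeps the per-cell weight becomes
    min(1/u^2, (cutoff/|e|)^2) — equivalent to inflating the effective
    uncertainty of an outlying cell to |e|/cutoff, which caps its
    objective contribution near cutoff^2 (a redescending M-loss whose
    reweighted updates remain monotone).
    """
    n, m = X.shape
    p = F.shape[0]
    R = np.empty((n, m))
    W = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            s = 0.0
            for k in range(p):
                s += G[i, k] * F[k, j]
            R[i, j] = X[i, j] - s
            W[i, j] = 1.0 / (U[i, j] * U[i, j])

    num = np.empty(m)
    den = np.empty(m)
    delta = np.empty(m)
    f2w = np.empty(m)
    q_prev = 1e300
    stable = 0
    for it in range(max_iter):
        # F rows: exact coordinate minimisation under nonnegativity
        for k in range(p):
            for j in range(m):
                num[j] = 0.0
                den[j] = 0.0
            for i in range(n):
                g = G[i, k]
                if g != 0.0:
                    g2 = g * g
                    for j in range(m):
                        w = W[i, j]
                        num[j] += g * w * R[i, j]
                        den[j] += g2 * w
            for j in range(m):
                if den[j] > _TINY:
                    v = num[j] / den[j] + F[k, j]
                    if v < floor:
                        v = floor
                else:
                    v = floor
                delta[j] = v - F[k, j]
                F[k, j] = v
            for i in range(n):
                g = G[i, k]
                if g != 0.0:
                    for j in range(m):
                        R[i, j] -= g * delta[j]
        # G columns
        for k in range(p):
            for j in range(m):
                f2w[j] = F[k, j] * F[k, j]
            for i in range(n):
                s_num = 0.0
                s_den = 0.0
                for j in range(m):
                    w = W[i, j]
                    s_num += F[k, j] * w * R[i, j]
                    s_den += f2w[j] * w
                if s_den > _TINY:
                    v = s_num / s_den + G[i, k]
                    if v < floor:
                        v = floor
                else:
                    v = floor
                dg = v - G[i, k]
                G[i, k] = v
                if dg != 0.0:
                    for j in range(m):
                        R[i, j] -= dg * F[k, j]
        # drift control on the maintained residual
        if (it + 1) % 100 == 0:
            for i in range(n):
                for j in range(m):
                    s = 0.0
                    for k in range(p):
                        s += G[i, k] * F[k, j]
                    R[i, j] = X[i, j] - s
        # robust reweighting: cap the influence of outlying cells
        if cutoff > 0.0 and it + 1 >= burn_in:
            for i in range(n):
                for j in range(m):
                    w0 = 1.0 / (U[i, j] * U[i, j])
                    r = R[i, j]
                    if r != 0.0:
                        wr = (cutoff / r) * (cutoff / r)
                        W[i, j] = wr if wr < w0 else w0
                    else:
                        W[i, j] = w0
        q = 0.0
        for i in range(n):
            for j in range(m):
                q += W[i, j] * R[i, j] * R[i, j]
        rel = abs(q_prev - q) / q_prev if q_prev > _TINY else 0.0
        stable = stable + 1 if rel < tol else 0
        q_prev = q
        if stable >= tol_iters:
            return True, it + 1
    return False, max_iter


def _hals(
    X: np.ndarray,
    U: np.ndarray,
    G: np.ndarray,
    F: np.ndarray,
    max_iter: int,
    tol: float,
    tol_iters: int,
    floor: float,
    cutoff: float = 0.0,
    burn_in: int = 3,
) -> tuple[bool, int]:
    """In-place HALS sweeps on (G, F); returns (converged, n_iter)."""
    conv, iters = _hals_core(
        np.ascontiguousarray(X),
        np.ascontiguousarray(U),
        G,
        F,
        max_iter,
        tol,
        tol_iters,
        floor,
        cutoff,
        burn_in,
    )
    return bool(conv), int(iters)


class RobustPMF(BaseEstimator):
    """Scikit-learn style estimator for robust uncertainty-weighted PMF.

    Parameters
    ----------
    n_components : int
        Number of factors p.
    n_runs : int
        Random restarts; the run with the lowest Q_robust is kept.
    robust_cutoff : float
        Scaled-residual threshold |e/u| beyond which a cell is treated as
        an outlier (down-weighted while fitting, excluded from Q_robust).
    robust_passes : int
        Robust mode switch: > 1 enables the interleaved reweighting
        (1 = plain weighted fit with post-hoc outlier flagging).
    max_iter, tol, tol_iters :
        Convergence: relative Q change < tol over tol_iters consecutive
        sweeps, capped at max_iter sweeps.
    random_state : int or None
        Base seed; run r uses random_state + r.

    Attributes
    ----------
    components_ : ndarray (p, m) — factor profiles F.
    contributions_ : ndarray (n, p) — training-set G.
    q_true_, q_robust_, q_expected_ : objective diagnostics.
    outlier_mask_ : boolean (n, m), cells excluded from Q_robust.
    run_q_robust_ : ndarray (n_runs,), per-run best Q_robust.
    converged_, n_iter_, best_run_, degenerate_reseeded_ : fit metadata.
    """

    def __init__(
        self,
        n_components: int = 6,
        n_runs: int = 20,
        robust_cutoff: float = 4.0,
        robust_passes: int = 4,
        max_iter: int = 5000,
        tol: float = 1e-8,
        tol_iters: int = 10,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.n_runs = n_runs
        self.robust_cutoff = robust_cutoff
        self.robust_passes = robust_passes
        self.max_iter = max_iter
        self.tol = tol
        self.tol_iters = tol_iters
        self.random_state = random_state

    # -- internals ----------------------------------------------------------

    def _single_run(self, X: np.ndarray, U: np.ndarray, seed: int):
        n, m = X.shape
        p = self.n_components
        rng = np.random.default_rng(seed)
        col_scale = X.mean(axis=0)
        floor = 1e-12 * float(col_scale.mean())
        # entries uniform on (0, 1]; F rows carry the column scale
        F = (1.0 - rng.random((p, m))) * col_scale[None, :]
        G = 1.0 - rng.random((n, p))

        cutoff = self.robust_cutoff if self.robust_passes > 1 else 0.0
        converged, iters = _hals(
            X, U, G, F, self.max_iter, self.tol, self.tol_iters, floor, cutoff
        )
        # degenerate factor: re-seed once, refit
        reseeded = False
        dead = (F <= floor).all(axis=1) | (G <= floor).all(axis=0)
        if dead.any():
            reseeded = True
            for k in np.flatnonzero(dead):
                F[k] = (1.0 - rng.random(m)) * col_scale
                G[:, k] = 1.0 - rng.random(n)
            conv2, it2 = _hals(
                X, U, G, F, self.max_iter, self.tol, self.tol_iters, floor, cutoff
            )
            converged, iters = conv2, iters + it2

        E = X - G @ F
        scaled = E / U
        outliers = np.abs(scaled) > self.robust_cutoff
        q_true = float(np.sum(scaled**2))
        q_robust = float(np.sum(scaled[~outliers] ** 2))
        # capped objective for run selection: comparable across runs even
        # when they exclude different numbers of cells
        q_capped = q_robust + self.robust_cutoff**2 * int(outliers.sum())
        return G, F, q_true, q_robust, q_capped, outliers, converged, iters, reseeded

    # -- API ----------------------------------------------------------------

    def fit(self, X, uncertainty=None, y=None) -> "RobustPMF":
        """Fit on an (n, m) matrix of strictly positive concentrations with
        matching per-cell uncertainties (default: unit weights)."""
        X_arr = np.asarray(X, dtype=float)
        if X_arr.ndim != 2:
            raise ValueError("X must be 2-D")
        n, m = X_arr.shape
        if uncertainty is None:
            U = np.ones_like(X_arr)
        else:
            U = np.asarray(uncertainty, dtype=float)
        if U.shape != X_arr.shape:
            raise ValueError("uncertainty must have the same shape as X")
        if not (U > 0).all():
            raise ValueError("uncertainties must be strictly positive")
        if np.isnan(X_arr).any():
            raise ValueError("X contains NaN; drop gap rows before fitting")
        if not self.n_components < min(n, m):
            raise ValueError(
                f"n_components={self.n_components} must be < min(n, m)={min(n, m)}"
            )

        base_seed = (
            self.random_state
            if self.random_state is not None
            else int(np.random.default_rng().integers(0, 2**31))
        )
        best = None
        run_q = np.empty(self.n_runs)
        run_conv = np.zeros(self.n_runs, dtype=bool)
        for r in range(self.n_runs):
            out = self._single_run(X_arr, U, base_seed + r)
            run_q[r] = out[3]
            run_conv[r] = out[6]
            if best is None or out[4] < best[1][4]:
                best = (r, out)

        r_best, (G, F, q_true, q_robust, _q_capped, outliers, conv, iters, reseeded) = best
        self.components_ = F
        self.contributions_ = G
        self.q_true_ = q_true
        self.q_robust_ = q_robust
        try:
            self.q_expected_ = q_expected(n, m, self.n_components)
        except ValueError:
            self.q_expected_ = None
        self.outlier_mask_ = outliers
        self.converged_ = bool(conv)
        self.n_iter_ = iters
        self.best_run_ = r_best
        self.base_seed_ = base_seed
        self.run_q_robust_ = run_q
        self.run_converged_ = run_conv
        self.degenerate_reseeded_ = reseeded
        self.n_features_in_ = m
        return self

    def transform(self, X, uncertainty=None) -> np.ndarray:
        """Contributions G for new samples under the fitted profiles
        (per-row weighted nonnegative least squares)."""
        X_arr = np.asarray(X, dtype=float)
        U = (
            np.ones_like(X_arr)
            if uncertainty is None
            else np.asarray(uncertainty, dtype=float)
        )
        F = self.components_
        G = np.empty((X_arr.shape[0], F.shape[0]))
        for i in range(X_arr.shape[0]):
            A = (F / U[i][None, :]).T
            b = X_arr[i] / U[i]
            G[i], _ = nnls(A, b)
        return G

    def inverse_transform(self, G) -> np.ndarray:
        return np.asarray(G, dtype=float) @ self.components_

    def score(self, X, uncertainty=None) -> float:
        """Negative Q of X under the fitted profiles (higher is better)."""
        G = self.transform(X, uncertainty)
        U = (
            np.ones_like(np.asarray(X, dtype=float))
            if uncertainty is None
            else np.asarray(uncertainty, dtype=float)
        )
        E = np.asarray(X, dtype=float) - G @ self.components_
        return -float(np.sum((E / U) ** 2))

    def to_model(self, X, seed: int | None = None) -> PMFModel:
        """Package the fitted state as a :class:`PMFModel`."""
        if isinstance(X, pd.DataFrame):
            index, columns = X.index, list(X.columns)
            X_arr = X.to_numpy(dtype=float)
        else:
            X_arr = np.asarray(X, dtype=float)
            index = pd.RangeIndex(X_arr.shape[0])
            columns = [f"s{j}" for j in range(X_arr.shape[1])]
        factors = [f"F{k+1}" for k in range(self.n_components)]
        C = self.contributions_ @ self.components_
        r2, _ = per_species_fit(C, X_arr)
        return PMFModel(
            F=pd.DataFrame(self.components_, index=factors, columns=columns),
            G=pd.DataFrame(self.contributions_, index=index, columns=factors),
            E=pd.DataFrame(X_arr - C, index=index, columns=columns),
            q_true=self.q_true_,
            q_robust=self.q_robust_,
            q_exp=self.q_expected_ if self.q_expected_ is not None else 0,
            per_species_r2=pd.Series(r2, index=columns),
            converged=self.converged_,
            run_q_values=self.run_q_robust_.copy(),
            outlier_mask=self.outlier_mask_.copy(),
            seed=seed if seed is not None else self.base_seed_,
        )


# ---------------------------------------------------------------------------
# Functional wrappers and diagnostics
# ---------------------------------------------------------------------------


def _as_array(X) -> np.ndarray:
    return X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)


def fit_single(X, U, p: int, seed: int, cfg: PMFConfig | None = None) -> PMFModel:
    """One seeded fit (one random start)."""
    cfg = cfg or PMFConfig(p=p)
    est = RobustPMF(
        n_components=p,
        n_runs=1,
        robust_cutoff=cfg.robust_cutoff,
        robust_passes=cfg.robust_passes,
        max_iter=cfg.max_iter,
        tol=cfg.tol,
        tol_iters=cfg.tol_iters,
        random_state=seed,
    ).fit(_as_array(X), _as_array(U))
    return est.to_model(X, seed=seed)


def fit_multi(
    X, U, p: int, cfg: PMFConfig | None = None
) -> tuple[PMFModel, dict]:
    """Best-of-n_runs fit plus a stability report: the relative spread
    (max-min)/median of the per-run Q_robust values."""
    cfg = cfg or PMFConfig(p=p)
    est = RobustPMF(
        n_components=p,
        n_runs=cfg.n_runs,
        robust_cutoff=cfg.robust_cutoff,
        robust_passes=cfg.robust_passes,
        max_iter=cfg.max_iter,
        tol=cfg.tol,
        tol_iters=cfg.tol_iters,
        random_state=cfg.seed,
    ).fit(_as_array(X), _as_array(U))
    q = est.run_q_robust_
    stability = {
        "q_robust_runs": q.copy(),
        "relative_spread": float((q.max() - q.min()) / max(np.median(q), _TINY)),
        "n_converged": int(est.run_converged_.sum()),
        "best_run": est.best_run_,
    }
    return est.to_model(X, seed=cfg.seed), stability


def scan_factor_numbers(X, U, cfg: PMFConfig | None = None) -> pd.DataFrame:
    """Fit every p in the scan range; one row per p with the best
    Q_robust, the Q_robust/Q_exp ratio and the multi-run spread.  Factor
    number selection from this table is the analyst's call; see
    :func:`detect_elbow` for the automated curvature heuristic used in the
    recovery experiments."""
    cfg = cfg or PMFConfig()
    X_arr, U_arr = _as_array(X), _as_array(U)
    n, m = X_arr.shape
    lo, hi = cfg.p_scan if cfg.p_scan is not None else (2, m - 1)
    rows = []
    for p in range(lo, hi + 1):
        sub = PMFConfig(
            p=p,
            n_runs=cfg.n_runs,
            robust_cutoff=cfg.robust_cutoff,
            max_iter=cfg.max_iter,
            tol=cfg.tol,
            tol_iters=cfg.tol_iters,
            robust_passes=cfg.robust_passes,
            seed=cfg.seed,
        )
        model, stab = fit_multi(X_arr, U_arr, p, sub)
        rows.append(
            {
                "p": p,
                "q_robust": model.q_robust,
                "q_exp": q_expected(n, m, p),
                "q_ratio": model.q_robust / q_expected(n, m, p),
                "stability": stab["relative_spread"],
                "converged_runs": stab["n_converged"],
            }
        )
    return pd.DataFrame(rows)


def detect_elbow(scan: pd.DataFrame, column: str = "q_robust") -> int:
    """Elbow of the Q(p) curve: the p with maximal discrete curvature
    (second difference) of log Q — the point where a steep decrease turns
    flat."""
    if len(scan) < 3:
        raise ValueError("need at least three scanned factor numbers")
    p_vals = scan["p"].to_numpy()
    logq = np.log10(np.maximum(scan[column].to_numpy(dtype=float), 1e-30))
    curv = logq[:-2] - 2 * logq[1:-1] + logq[2:]
    return int(p_vals[1:-1][int(np.argmax(curv))])


@dataclass
class FingerprintTable:
    """Percent of each species' profile mass in each factor, and the
    (factor, species) pairs at or above the cutoff."""

    percent: pd.DataFrame  # (p, m), columns sum to 100 where defined
    filtered_pairs: list[tuple[str, str, float]]
    undefined_species: list[str] = field(default_factory=list)


def fingerprints(model: PMFModel | pd.DataFrame, cutoff_percent: float = 25.0) -> FingerprintTable:
    """Column-normalise F to percent and keep pairs >= cutoff (inclusive).

    Species with an all-zero profile column have no defined fingerprint and
    are flagged rather than divided by zero.
    """
    F = model.F if isinstance(model, PMFModel) else model
    total = F.sum(axis=0)
    undefined = list(total.index[total == 0])
    percent = 100.0 * F.div(total.where(total > 0), axis=1)
    pairs = [
        (str(k), str(j), float(percent.loc[k, j]))
        for j in percent.columns
        for k in percent.index
        if pd.notna(percent.loc[k, j]) and percent.loc[k, j] >= cutoff_percent
    ]
    return FingerprintTable(percent=percent, filtered_pairs=pairs, undefined_species=undefined)


def per_species_fit(C, X) -> tuple[np.ndarray, float]:
    """R-squared of fitted vs observed per species and the overall mean.

    Zero-variance species are undefined (NaN) and excluded from the mean.
    """
    C_arr, X_arr = _as_array(C), _as_array(X)
    ss_res = np.sum((X_arr - C_arr) ** 2, axis=0)
    ss_tot = np.sum((X_arr - X_arr.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, np.nan)
    mean = float(np.nanmean(r2)) if np.isfinite(r2).any() else float("nan")
    return r2, mean


def match_factors(F_est, F_true) -> tuple[np.ndarray, np.ndarray]:
    """Optimal scale-invariant factor matching.

    Returns ``(perm, cos)`` where estimated factor k matches true factor
    ``perm[k]`` with cosine similarity ``cos[k]``.  The assignment
    maximises total cosine similarity (Hungarian algorithm).  With unequal
    factor counts, the best partial matching over min(p_est, p_true) pairs
    is returned; unmatched estimated factors get perm -1 and cos NaN.
    """
    A = _as_array(F_est)
    B = _as_array(F_true)
    na = np.linalg.norm(A, axis=1, keepdims=True)
    nb = np.linalg.norm(B, axis=1, keepdims=True)
    S = (A / np.where(na > 0, na, 1.0)) @ (B / np.where(nb > 0, nb, 1.0)).T
    rows, cols = linear_sum_assignment(-S)
    perm = np.full(A.shape[0], -1, dtype=int)
    cos = np.full(A.shape[0], np.nan)
    perm[rows] = cols
    cos[rows] = S[rows, cols]
    return perm, cos


@dataclass
class BootstrapResult:
    """Moving-block bootstrap summary: per-base-factor mapping rates and
    profile inter-quartile ranges over the mapped replicates."""

    n_reps: int
    mapping_rate: pd.Series
    profile_q25: pd.DataFrame
    profile_q75: pd.DataFrame
    unmapped_fraction: float


def bootstrap(
    X,
    U,
    model: PMFModel,
    cfg: PMFConfig | None = None,
    *,
    min_correlation: float = 0.6,
) -> BootstrapResult:
    """Assess factor stability by refitting on moving-block resamples.

    Each replicate draws ceil(n/block) contiguous row blocks with
    replacement, refits from the base solution (warm start), and maps each
    replicate factor to the base factor whose profile it correlates with
    most (requiring Pearson r >= ``min_correlation``).  Reported per base
    factor: the fraction of replicates in which at least one replicate
    factor mapped to it, and the 25-75% envelope of mapped profiles.
    Replicate factors that map nowhere are counted, never dropped silently.
    """
    cfg = cfg or PMFConfig(p=model.n_factors)
    X_arr, U_arr = _as_array(X), _as_array(U)
    n, m = X_arr.shape
    p = model.n_factors
    factors, columns = list(model.F.index), list(model.F.columns)
    if cfg.bootstrap_reps == 0:
        return BootstrapResult(
            n_reps=0,
            mapping_rate=pd.Series(dtype=float),
            profile_q25=pd.DataFrame(columns=columns),
            profile_q75=pd.DataFrame(columns=columns),
            unmapped_fraction=0.0,
        )
    rng = np.random.default_rng(cfg.seed)
    block = min(max(cfg.bootstrap_block, 1), n)
    n_blocks = int(np.ceil(n / block))
    F_base = model.F.to_numpy()
    G_base = model.G.to_numpy()

    mapped_profiles: dict[int, list[np.ndarray]] = {k: [] for k in range(p)}
    hit = np.zeros((cfg.bootstrap_reps, p), dtype=bool)
    unmapped = 0
    for rep in range(cfg.bootstrap_reps):
        starts = rng.integers(0, n - block + 1, size=n_blocks)
        rows = np.concatenate([np.arange(s, s + block) for s in starts])[:n]
        Xb, Ub = X_arr[rows], U_arr[rows]
        est = RobustPMF(
            n_components=p,
            n_runs=1,
            robust_cutoff=cfg.robust_cutoff,
            robust_passes=cfg.robust_passes,
            max_iter=cfg.max_iter,
            tol=cfg.tol,
            tol_iters=cfg.tol_iters,
            random_state=int(rng.integers(0, 2**31)),
        )
        # warm start at the base solution (standard bootstrap practice)
        est.n_runs = 1
        G0, F0 = G_base[rows].copy(), F_base.copy()
        floor = 1e-12 * float(Xb.mean())
        _hals(
            Xb, Ub, G0, F0, cfg.max_iter, cfg.tol, cfg.tol_iters, floor,
            cfg.robust_cutoff, 0,
        )
        # map replicate factors to base factors by profile correlation
        for k in range(p):
            prof = F0[k]
            best_r, best_base = -np.inf, -1
            for kb in range(p):
                base = F_base[kb]
                if prof.std() == 0 or base.std() == 0:
                    r = 1.0 if np.allclose(prof, base) else -np.inf
                else:
                    r = float(np.corrcoef(prof, base)[0, 1])
                if r > best_r:
                    best_r, best_base = r, kb
            if best_r >= min_correlation:
                hit[rep, best_base] = True
                mapped_profiles[best_base].append(prof.copy())
            else:
                unmapped += 1

    q25 = pd.DataFrame(
        [
            np.percentile(np.vstack(v), 25, axis=0) if v else np.full(m, np.nan)
            for v in mapped_profiles.values()
        ],
        index=factors,
        columns=columns,
    )
    q75 = pd.DataFrame(
        [
            np.percentile(np.vstack(v), 75, axis=0) if v else np.full(m, np.nan)
            for v in mapped_profiles.values()
        ],
        index=factors,
        columns=columns,
    )
    return BootstrapResult(
        n_reps=cfg.bootstrap_reps,
        mapping_rate=pd.Series(hit.mean(axis=0), index=factors),
        profile_q25=q25,
        profile_q75=q75,
        unmapped_fraction=unmapped / (cfg.bootstrap_reps * p),
    )
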