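"""Input screening for the factor analysis: below-LOQ substitution, the
per-cell uncertainty matrix, per-species signal-to-noise and the
bad/weak/good species classification.

Rules (all operating on the *raw* stored values):

* substitution (factor-analysis input only): x < LOQ  ->  LOQ/2
* uncertainty:  u = sqrt((a*x)^2 + LOQ^2)   if x > LOQ
                u = (5/6) * LOQ             if x <= LOQ
* distance:     d = 0                        if x <= LOQ
                d = (x - u) / u              if x >  LOQ
* S/N_j = mean over samples of d_ij; species are *bad* if S/N <= 0.2,
  *weak* if 0.2 < S/N <= 1, *good* otherwise.  Bad species are excluded
  from the factorization; weak species keep their data but have their
  uncertainty tripled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data_model import CompoundMeta, ConcentrationMatrix

__all__ = [
    "UncertaintyMatrix",
    "ScreeningReport",
    "SpeciesScreener",
    "substitute_below_loq",
    "compute_uncertainty",
    "signal_to_noise",
    "prepare_pmf_input",
]

SN_BAD_CUT = 0.2
SN_WEAK_CUT = 1.0
WEAK_UNCERTAINTY_FACTOR = 3.0


@dataclass
class UncertaintyMatrix:
    """Per-cell uncertainties (ng/l) and the substituted concentration
    matrix used as factorization input.  Cells in gap rows are NaN."""

    u: pd.DataFrame
    substituted_x: pd.DataFrame


@dataclass
class ScreeningReport:
    """Per-species signal-to-noise, class, and the full distance matrix."""

    sn_ratio: pd.Series
    species_class: pd.Series  # 'bad' | 'weak' | 'good'
    d: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sn_ratio": self.sn_ratio, "species_class": self.species_class}
        ).rename_axis("compound_id")


def _loq_series(matrix: ConcentrationMatrix) -> pd.Series:
    return matrix.loq


def substitute_below_loq(matrix: ConcentrationMatrix) -> pd.DataFrame:
    """Replace censored values (x < LOQ) by LOQ/2; gap cells stay NaN."""
    loq = _loq_series(matrix)
    x = matrix.values
    return x.mask(x.lt(loq, axis=1), loq / 2.0, axis=1)


def compute_uncertainty(
    matrix: ConcentrationMatrix, meta: list[CompoundMeta] | None = None
) -> UncertaintyMatrix:
    """Per-cell uncertainty from the raw values (branch by x vs LOQ) plus
    the LOQ/2-substituted input matrix."""
    meta = meta or matrix.compounds
    loq = pd.Series({c.compound_id: c.loq for c in meta}, dtype=float)[
        matrix.compound_ids
    ]
    a = pd.Series({c.compound_id: c.error_fraction for c in meta}, dtype=float)[
        matrix.compound_ids
    ]
    if (loq <= 0).any():
        raise ValueError("all LOQ values must be > 0")
    x = matrix.values
    above = x.gt(loq, axis=1)
    u_above = np.sqrt((x.mul(a, axis=1)) ** 2 + (loq**2))
    u_below = pd.DataFrame(
        np.broadcast_to((5.0 / 6.0) * loq.to_numpy(), x.shape),
        index=x.index,
        columns=x.columns,
    )
    u = u_above.where(above, u_below).where(x.notna())
    return UncertaintyMatrix(u=u, substituted_x=substitute_below_loq(matrix))


def signal_to_noise(
    matrix: ConcentrationMatrix, uncertainty: UncertaintyMatrix
) -> ScreeningReport:
    """Per-species S/N (mean distance d over non-gap samples) and class."""
    loq = _loq_series(matrix)
    x = matrix.values
    u = uncertainty.u
    d = ((x - u) / u).where(x.gt(loq, axis=1), 0.0).where(x.notna())
    sn = d.mean(axis=0, skipna=True)
    cls = pd.Series(
        np.where(sn <= SN_BAD_CUT, "bad", np.where(sn <= SN_WEAK_CUT, "weak", "good")),
        index=sn.index,
    )
    return ScreeningReport(sn_ratio=sn, species_class=cls, d=d)


class SpeciesScreener(BaseEstimator):
    """Screen species and assemble the factorization input.

    A scikit-learn style transformer over :class:`ConcentrationMatrix`
    inputs.  ``fit`` computes the uncertainty matrix, the per-species S/N
    and classes; ``transform`` returns the prepared concentration matrix
    (LOQ/2 substituted, bad species dropped, gap rows dropped) and
    ``transform_uncertainty`` the matching uncertainty matrix (weak
    species tripled).

    Parameters
    ----------
    bad_cut, weak_cut : float
        S/N cut-points between bad/weak and weak/good species.

    Attributes
    ----------
    uncertainty_ : UncertaintyMatrix
    report_ : ScreeningReport
    kept_species_ : list of species retained (weak + good)
    m_good_ : number of retained species (enters the expected objective)
    """

    def __init__(self, bad_cut: float = SN_BAD_CUT, weak_cut: float = SN_WEAK_CUT):
        self.bad_cut = bad_cut
        self.weak_cut = weak_cut

    def fit(self, X: ConcentrationMatrix, y=None) -> "SpeciesScreener":
        self.uncertainty_ = compute_uncertainty(X)
        report = signal_to_noise(X, self.uncertainty_)
        if (self.bad_cut, self.weak_cut) != (SN_BAD_CUT, SN_WEAK_CUT):
            sn = report.sn_ratio
            report.species_class = pd.Series(
                np.where(
                    sn <= self.bad_cut,
                    "bad",
                    np.where(sn <= self.weak_cut, "weak", "good"),
                ),
                index=sn.index,
            )
        self.report_ = report
        keep = report.species_class != "bad"
        self.kept_species_ = list(report.species_class.index[keep])
        self.m_good_ = len(self.kept_species_)
        if self.m_good_ < 2:
            raise ValueError(
                f"only {self.m_good_} species survive screening; need >= 2"
            )
        return self

    def transform(self, X: ConcentrationMatrix) -> pd.DataFrame:
        """Prepared concentration input: substituted, filtered, gap-free."""
        sub = substitute_below_loq(X)
        return sub.loc[~X.gap, self.kept_species_]

    def transform_uncertainty(self, X: ConcentrationMatrix) -> pd.DataFrame:
        """Matching uncertainties: weak species inflated by the factor 3."""
        u = compute_uncertainty(X).u.loc[~X.gap, self.kept_species_].copy()
        weak = [
            s
            for s in self.kept_species_
            if self.report_.species_class[s] == "weak"
        ]
        u[weak] = u[weak] * WEAK_UNCERTAINTY_FACTOR
        return u


def prepare_pmf_input(
    matrix: ConcentrationMatrix,
    uncertainty: UncertaintyMatrix | None = None,
    report: ScreeningReport | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Functional wrapper over :class:`SpeciesScreener`: returns the
    prepared (X', U', kept species) triple.  ``uncertainty`` / ``report``
    may be passed for inspection but are recomputed from the matrix (they
    are pure functions of it)."""
    screener = SpeciesScreener().fit(matrix)
    return (
        screener.transform(matrix),
        screener.transform_uncertainty(matrix),
        screener.kept_species_,
    )
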