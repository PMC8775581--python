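"""Assay statistics: plating efficiency, survival fraction, MTT viability.

Clonogenic quantities follow the standard normalization

    PE = 100 * colonies / seeded                      (untreated control)
    SF = 100 * colonies / (seeded * PE / 100)         (treated wells)

so the untreated control has SF = 100% by construction.  MTT viability is
the treated-to-control absorbance ratio in percent with a propagated
standard error.  ``dose_response_table`` joins assay records to per-cell
absorbed doses and can optionally fit a mono-exponential survival curve
SF = exp(-alpha * D) by least squares on log SF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ClonogenicRecord:
    """One clonogenic well: cells seeded and colonies formed.

    A colony is >= 50 cells by assay convention (metadata only).
    """

    condition: str
    activity_MBq: float
    seeded: int
    colonies: int
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.seeded <= 0:
            raise ValueError("seeded must be > 0")
        if self.colonies < 0:
            raise ValueError("colonies must be >= 0")


@dataclass(frozen=True)
class MTTRecord:
    """One MTT well: 570 nm absorbance."""

    condition: str
    activity_MBq: float
    absorbance: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.absorbance < 0:
            raise ValueError("absorbance must be >= 0")


def plating_efficiency(colonies: int, seeded: int) -> float:
    """PE in percent: 100 x colonies / seeded."""
    if seeded <= 0:
        raise ValueError("seeded must be > 0")
    return 100.0 * colonies / seeded


def survival_fraction(colonies: int, seeded: int, pe_percent: float) -> float:
    """SF in percent, PE-normalised: 100 x colonies / (seeded x PE/100)."""
    if pe_percent <= 0:
        raise ValueError("plating efficiency must be > 0")
    return 100.0 * colonies / (seeded * pe_percent / 100.0)


def viability_percent(treated: list[float],
                      control: list[float]) -> tuple[float, float]:
    """MTT viability: 100 x mean(treated)/mean(control), with its SEM.

    The standard error combines the SEMs of both means by first-order
    propagation of the ratio.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.size == 0 or control.size == 0:
        raise ValueError("need at least one treated and one control value")
    mc = control.mean()
    if mc <= 0:
        raise ValueError("control mean must be > 0")
    mt = treated.mean()
    v = 100.0 * mt / mc
    sem_t = treated.std(ddof=1) / math.sqrt(treated.size) if treated.size > 1 else 0.0
    sem_c = control.std(ddof=1) / math.sqrt(control.size) if control.size > 1 else 0.0
    rel = math.hypot(sem_t / mt if mt else 0.0, sem_c / mc)
    return v, v * rel


@dataclass
class ExponentialFit:
    """Mono-exponential survival fit SF = exp(-alpha D): estimate and 95% CI."""

    alpha_per_Gy: float
    ci_low: float
    ci_high: float


def fit_exponential_survival(dose_Gy: np.ndarray, sf_percent: np.ndarray,
                             weights: np.ndarray | None = None,
                             ) -> ExponentialFit:
    """Least squares of log(SF) on dose through the origin, 95% CI.

    ``weights`` should be inverse variances of log SF; for Poisson colony
    counts use the counts themselves (var(log N) ~ 1/N).  The standard
    error is inflated by the residual dispersion when it exceeds 1.
    Records with SF <= 0 (zero colonies) are dropped.
    """
    dose_Gy = np.asarray(dose_Gy, dtype=float)
    sf = np.asarray(sf_percent, dtype=float) / 100.0
    w = np.ones_like(sf) if weights is None else np.asarray(weights, float)
    ok = sf > 0
    d, y, w = dose_Gy[ok], np.log(sf[ok]), w[ok]
    if (d != 0).sum() < 1:
        raise ValueError("need at least one positive-dose record")
    swxx = float(w @ (d * d))
    alpha = -float(w @ (d * y)) / swxx
    resid = y + alpha * d
    dof = max(len(d) - 1, 1)
    dispersion = max(float(w @ (resid * resid)) / dof, 1.0)
    se = math.sqrt(dispersion / swxx)
    t = stats.t.ppf(0.975, dof)
    return ExponentialFit(alpha, alpha - t * se, alpha + t * se)


def dose_response_table(records: pd.DataFrame, doses: dict[float, tuple],
                        fit: bool = False):
    """Join assay records to per-cell doses; optional exponential fit.

    ``records`` needs columns ``activity_MBq`` and either ``sf_percent``
    (clonogenic, from :func:`survival_fraction`) or ``viability_percent``;
    ``doses`` maps each activity (MBq) to ``(dose_Gy, stderr_Gy)``.
    Returns the joined table sorted by dose, plus the
    :class:`ExponentialFit` when requested (else None).
    """
    value_col = ("sf_percent" if "sf_percent" in records.columns
                 else "viability_percent")
    missing = set(records["activity_MBq"]) - set(doses)
    if missing:
        raise KeyError(f"no dose report for activities {sorted(missing)}")
    grouped = records.groupby("activity_MBq")[value_col] \
                     .agg(["mean", "sem", "size"]).reset_index()
    grouped["dose_Gy"] = [doses[a][0] for a in grouped["activity_MBq"]]
    grouped["dose_stderr_Gy"] = [doses[a][1] for a in grouped["activity_MBq"]]
    grouped = grouped.rename(columns={"mean": value_col, "sem": "sem_percent",
                                      "size": "n_replicates"})
    grouped = grouped.sort_values("dose_Gy").reset_index(drop=True)
    result = None
    if fit:
        # fit on the replicate-level records for honest degrees of freedom;
        # colony counts give the inverse-variance weights of log SF
        d = np.array([doses[a][0] for a in records["activity_MBq"]])
        w = (np.maximum(records["colonies"].to_numpy(), 1.0)
             if "colonies" in records.columns else None)
        result = fit_exponential_survival(d, records[value_col].to_numpy(), w)
    return grouped, result
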