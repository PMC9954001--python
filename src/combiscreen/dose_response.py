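"""Vehicle normalization, Hill fitting, trapezoidal AUC and the 0–100 drug score.

The score is a min–max normalization of the area under the viability curve,

    score = 100 * (1 - (AUC - AUC_min) / (AUC_max - AUC_min)),

where 100 corresponds to killing of all cells (AUC = AUC_min) and 0 to no
effect (AUC = AUC_max). Growth-stimulating drugs — viability above vehicle —
score below 0; scores are never clipped. The AUC is the trapezoid sum
Σ ΔX·(Y1+Y2)/2 over the measured points with X = log10(dose) by default,
matching the uniform spacing of a log-serial dilution ladder.

By default AUC anchors are theoretical: AUC_min = 0 (full kill at every
dose) and AUC_max = the log10-dose range × viability 1 (no effect). These
make scores comparable across plates and screens; empirical per-screen
anchors can be supplied instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseCurve",
    "HillFit",
    "AucScore",
    "normalize_viability",
    "fit_hill",
    "compute_auc",
    "auc_anchors",
    "score_from_auc",
    "score_curve",
    "score_plate",
]

#: Fitted curves flatter than this viability range are flagged unconverged.
FLAT_RANGE = 0.05


@dataclass
class DoseResponseCurve:
    """Replicate-averaged viability of one treatment on one sample.

    ``doses`` is the plotting/integration abscissa in µM (for a fixed-ratio
    drug pair, the first component's dose); ``dose_a``/``dose_b`` retain the
    component doses of each point for combination-index work. Viability is a
    fraction of the vehicle mean (1 = vehicle); values above 1 (growth
    stimulation) are preserved, not clipped.
    """

    sample_id: str
    treatment: str
    doses: np.ndarray
    viability: np.ndarray
    replicate_sd: np.ndarray | None = None
    dose_a: np.ndarray | None = None
    dose_b: np.ndarray | None = None
    dose_tier: str = "cmax"

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.doses.size != self.viability.size:
            raise ValueError("doses and viability must have equal length")
        if self.doses.size < 2:
            raise ValueError("a dose-response curve needs at least 2 doses")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if np.any(self.viability < 0):
            raise ValueError("viability fractions cannot be negative")
        if self.replicate_sd is not None:
            self.replicate_sd = np.asarray(self.replicate_sd, dtype=float)


@dataclass(frozen=True)
class HillFit:
    """Four-parameter logistic fit of a dose-response curve."""

    top: float
    bottom: float
    ec50: float
    slope: float
    converged: bool
    rss: float
    flat: bool = False

    def predict(self, dose: np.ndarray | float) -> np.ndarray | float:
        d = np.asarray(dose, dtype=float)
        v = self.bottom + (self.top - self.bottom) / (1.0 + (d / self.ec50) ** self.slope)
        return v if v.ndim else float(v)


@dataclass(frozen=True)
class AucScore:
    """Trapezoidal AUC with its anchors and the resulting 0–100 score."""

    auc: float
    auc_min: float
    auc_max: float
    score: float


def normalize_viability(plate: pd.DataFrame) -> list[DoseResponseCurve]:
    """Normalize raw signals to the vehicle mean and average replicates.

    Each sample's wells are divided by the mean vehicle signal of that
    sample; a sample with no vehicle wells, or with a non-positive vehicle
    mean, is a hard error naming the sample. Replicates at the same dose are
    averaged; their sd is retained.
    """
    curves: list[DoseResponseCurve] = []
    for sample_id, grp in plate.groupby("sample_id", sort=True):
        veh = grp.loc[grp["is_vehicle"].astype(bool), "raw_signal"]
        if veh.empty:
            raise ValueError(f"sample {sample_id!r}: no vehicle wells")
        veh_mean = float(veh.mean())
        if veh_mean <= 0:
            raise ValueError(f"sample {sample_id!r}: vehicle mean signal is not positive")
        treated = grp.loc[~grp["is_vehicle"].astype(bool)].copy()
        if treated.empty:
            continue
        treated["viability"] = treated["raw_signal"] / veh_mean
        tier_col = treated["dose_tier"] if "dose_tier" in treated else pd.Series("cmax", index=treated.index)
        for (treatment, tier), tg in treated.groupby([treated["treatment_id"], tier_col], sort=True):
            agg = (
                tg.groupby(["dose_a_um", "dose_b_um"], sort=True)["viability"]
                .agg(["mean", "std", "size"])
                .reset_index()
            )
            # abscissa: component-A dose for single agents and fixed-ratio
            # pairs; component-B dose when A is absent
            x = np.where(agg["dose_a_um"] > 0, agg["dose_a_um"], agg["dose_b_um"])
            order = np.argsort(x)
            curves.append(
                DoseResponseCurve(
                    sample_id=str(sample_id),
                    treatment=str(treatment),
                    doses=x[order],
                    viability=agg["mean"].to_numpy()[order],
                    replicate_sd=np.nan_to_num(agg["std"].to_numpy()[order]),
                    dose_a=agg["dose_a_um"].to_numpy()[order],
                    dose_b=agg["dose_b_um"].to_numpy()[order],
                    dose_tier=str(tier),
                )
            )
    return curves


def _hill(logd: np.ndarray, top: float, bottom: float, log_ec50: float, slope: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (logd - log_ec50)))


def fit_hill(curve: DoseResponseCurve) -> HillFit:
    """Least-squares four-parameter logistic fit on the log10-dose axis.

    With fewer than 4 distinct doses the top and bottom are fixed at the
    observed extremes and only (ec50, slope) are fitted. A flat curve
    (viability range < 0.05) or optimizer failure yields ``converged=False``.
    """
    y = curve.viability
    if np.ptp(y) < FLAT_RANGE:
        return HillFit(float(y.max()), float(y.min()), float("nan"), float("nan"),
                       converged=False, rss=float(np.sum((y - y.mean()) ** 2)), flat=True)
    logd = np.log10(curve.doses)
    p0 = [float(y.max()), float(y.min()), float(np.median(logd)), 1.0]
    try:
        if np.unique(curve.doses).size >= 4:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _hill, logd, y, p0=p0, maxfev=20000,
                    bounds=([-1.0, -1.0, logd.min() - 3, 0.05], [5.0, 5.0, logd.max() + 3, 20.0]),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            top, bottom, log_ec50, slope = (float(p) for p in popt)
        else:
            top, bottom = float(y.max()), float(y.min())

            def two_param(ld, log_ec50, slope):
                return _hill(ld, top, bottom, log_ec50, slope)

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(two_param, logd, y, p0=p0[2:], maxfev=20000)
            log_ec50, slope = (float(p) for p in popt)
    except (RuntimeError, ValueError):
        return HillFit(float(y.max()), float(y.min()), float("nan"), float("nan"),
                       converged=False, rss=float("nan"))
    resid = y - _hill(logd, top, bottom, log_ec50, slope)
    return HillFit(top, bottom, 10.0 ** log_ec50, slope, converged=True,
                   rss=float(np.sum(resid**2)))


def compute_auc(curve: DoseResponseCurve, dose_axis: str = "log10") -> float:
    """Trapezoid sum Σ ΔX·(Y1+Y2)/2 over the measured points.

    X is log10(dose in µM) by default (``dose_axis="linear"`` uses raw µM).
    Viability is floored at 0 before integrating — the maximum scoreable
    effect is killing every cell — while values above 1 are kept, so growth
    stimulation inflates the AUC and drives the score negative.
    """
    if np.any(curve.doses <= 0):
        raise ValueError("compute_auc requires strictly positive doses")
    if dose_axis == "log10":
        x = np.log10(curve.doses)
    elif dose_axis == "linear":
        x = curve.doses
    else:
        raise ValueError(f"unknown dose_axis {dose_axis!r}")
    y = np.maximum(curve.viability, 0.0)
    return float(np.trapezoid(y, x))


def auc_anchors(curve: DoseResponseCurve, dose_axis: str = "log10") -> tuple[float, float]:
    """Theoretical (AUC_min, AUC_max): full kill and no effect over the ladder."""
    if dose_axis == "log10":
        width = float(np.log10(curve.doses[-1]) - np.log10(curve.doses[0]))
    else:
        width = float(curve.doses[-1] - curve.doses[0])
    return 0.0, width


def score_from_auc(auc: float, auc_min: float, auc_max: float) -> float:
    """Min–max normalized drug score: 100 = full kill, 0 = no effect, < 0 = stimulation."""
    if auc_max <= auc_min:
        raise ValueError("auc_max must exceed auc_min")
    return 100.0 * (1.0 - (auc - auc_min) / (auc_max - auc_min))


def score_curve(
    curve: DoseResponseCurve,
    dose_axis: str = "log10",
    anchors: tuple[float, float] | None = None,
) -> AucScore:
    """Compute the AUC and its 0–100 score for one curve."""
    auc = compute_auc(curve, dose_axis=dose_axis)
    auc_min, auc_max = anchors if anchors is not None else auc_anchors(curve, dose_axis)
    return AucScore(auc, auc_min, auc_max, score_from_auc(auc, auc_min, auc_max))


def score_plate(plate: pd.DataFrame, dose_axis: str = "log10", fit: bool = True) -> pd.DataFrame:
    """Normalize a plate table and score every curve.

    Returns a long table (sample_id, treatment, dose_tier, auc, score, ec50,
    converged) with one row per scored curve. The Hill fit only serves EC50
    reporting — the score is computed on the measured points — so ``fit=False``
    skips it for speed on large panels.
    """
    rows = []
    for curve in normalize_viability(plate):
        sc = score_curve(curve, dose_axis=dose_axis)
        row = {
            "sample_id": curve.sample_id,
            "treatment": curve.treatment,
            "dose_tier": curve.dose_tier,
            "auc": sc.auc,
            "score": sc.score,
        }
        if fit:
            hf = fit_hill(curve)
            row["ec50"] = hf.ec50
            row["converged"] = hf.converged
        rows.append(row)
    return pd.DataFrame(rows)
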