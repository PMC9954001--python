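"""Chou–Talalay median-effect fitting and combination-index synergy analysis.

The median-effect model relates dose D to fraction affected fa through
fa/(1-fa) = (D/Dm)^m, with Dm the dose producing half effect and m the
sigmoidicity. Taking log10 of both sides linearizes the model, so (Dm, m)
come from an ordinary least-squares fit of log10(fa/(1-fa)) on log10(D).

For a dose pair (d_a, d_b) producing fraction affected fa, the (exclusive,
two-term) combination index is

    CI = d_a / Dx_a(fa) + d_b / Dx_b(fa),

where Dx_i(fa) = Dm_i * (fa/(1-fa))^(1/m_i) is the dose of drug i alone
required for the same effect. CI < 1 indicates synergism, CI = 1 additivity
(the Loewe reference), and CI > 1 antagonism. The screen combines fixed
dose pairs (Cmax and 10% Cmax) rather than a constant-ratio dilution
series, so each measured pair is evaluated at its own observed fa
(non-constant-ratio design).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dose_response import DoseResponseCurve

__all__ = [
    "MedianEffectFit",
    "CombinationPoint",
    "CIResult",
    "FaCiTable",
    "fraction_affected",
    "fit_median_effect",
    "required_dose",
    "combination_index",
    "fa_ci_table",
]

#: Default clamp bounds for fa: the linearization diverges at 0 and 1.
CLAMP_BOUNDS = (0.01, 0.99)

#: |CI - 1| within this band is reported as "additive" rather than letting
#: noise flip the synergism/antagonism call; the raw CI is always reported.
ADDITIVE_BAND = 0.05


@dataclass(frozen=True)
class MedianEffectFit:
    """Per-drug (Dm, m) from the linearized median-effect regression."""

    drug: str
    dm: float
    m: float
    r: float
    n_points: int

    def __post_init__(self) -> None:
        if self.dm <= 0:
            raise ValueError("dm must be > 0")


@dataclass(frozen=True)
class CombinationPoint:
    """Component doses of one measured combination well and its observed fa."""

    dose_a: float
    dose_b: float
    fa: float
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.dose_a < 0 or self.dose_b < 0 or (self.dose_a == 0 and self.dose_b == 0):
            raise ValueError("doses must be non-negative and not both zero")
        if not (0.0 < self.fa < 1.0):
            raise ValueError("fa must lie in the open interval (0, 1)")


@dataclass(frozen=True)
class CIResult:
    fa: float
    ci: float
    classification: str  # synergism | additive | antagonism
    clamped: bool = False


@dataclass
class FaCiTable:
    """Per-concentration CI results sorted by fa, with an overall synergy call."""

    table: pd.DataFrame
    synergistic_overall: bool


def fraction_affected(
    curve: DoseResponseCurve,
    clamp_bounds: tuple[float, float] = CLAMP_BOUNDS,
) -> pd.DataFrame:
    """fa = 1 - viability per dose, clamped to ``clamp_bounds``.

    Clamped points are flagged; they stay available for CI evaluation but
    must be excluded from median-effect regression, where the logit
    transform would place them at spurious extremes.
    """
    lo, hi = clamp_bounds
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("clamp bounds must satisfy 0 < lo < hi < 1")
    fa_raw = 1.0 - curve.viability
    fa = np.clip(fa_raw, lo, hi)
    return pd.DataFrame(
        {
            "dose": curve.doses,
            "dose_a": curve.dose_a if curve.dose_a is not None else curve.doses,
            "dose_b": curve.dose_b if curve.dose_b is not None else np.zeros_like(curve.doses),
            "fa": fa,
            "clamped": (fa_raw < lo) | (fa_raw > hi),
        }
    )


def fit_median_effect(
    doses: np.ndarray,
    fa: np.ndarray,
    drug: str = "",
    clamped: np.ndarray | None = None,
) -> MedianEffectFit:
    """OLS of log10(fa/(1-fa)) on log10(dose); m = slope, Dm = 10^(-b/m)."""
    doses = np.asarray(doses, dtype=float)
    fa = np.asarray(fa, dtype=float)
    keep = np.ones(doses.size, dtype=bool) if clamped is None else ~np.asarray(clamped, dtype=bool)
    doses, fa = doses[keep], fa[keep]
    if np.any(doses <= 0):
        raise ValueError("median-effect fit requires strictly positive doses")
    if np.any((fa <= 0) | (fa >= 1)):
        raise ValueError("fa values must lie strictly inside (0, 1)")
    if np.unique(doses).size < 2:
        raise ValueError("median-effect fit needs >= 2 unclamped points with distinct doses")
    x = np.log10(doses)
    y = np.log10(fa / (1.0 - fa))
    if np.unique(doses).size == 2 and doses.size == 2:
        # exact 2x2 solve; linregress leaves r undefined for 2 points anyway
        m = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - m * x[0]
        r = 1.0
    else:
        res = stats.linregress(x, y)
        m, intercept, r = float(res.slope), float(res.intercept), float(res.rvalue)
    if m <= 0:
        raise ValueError(f"median-effect slope m={m:.3g} is not positive; drug {drug!r} is not inhibitory over these doses")
    dm = 10.0 ** (-intercept / m)
    return MedianEffectFit(drug=drug, dm=float(dm), m=float(m), r=float(r), n_points=int(doses.size))


def fit_median_effect_curve(curve: DoseResponseCurve, clamp_bounds: tuple[float, float] = CLAMP_BOUNDS) -> MedianEffectFit:
    """Convenience: fraction-affected transform + median-effect fit of a curve."""
    pts = fraction_affected(curve, clamp_bounds)
    return fit_median_effect(
        pts["dose"].to_numpy(), pts["fa"].to_numpy(),
        drug=curve.treatment, clamped=pts["clamped"].to_numpy(),
    )


def required_dose(fit: MedianEffectFit, fa: float) -> float:
    """Dose of the drug alone producing fraction affected fa: Dm·(fa/(1-fa))^(1/m)."""
    if not (0.0 < fa < 1.0):
        raise ValueError("fa must lie in the open interval (0, 1)")
    return fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)


def classify_ci(ci: float, additive_band: float = ADDITIVE_BAND) -> str:
    if abs(ci - 1.0) <= additive_band:
        return "additive"
    return "synergism" if ci < 1.0 else "antagonism"


def combination_index(
    point: CombinationPoint,
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    additive_band: float = ADDITIVE_BAND,
) -> CIResult:
    """Two-term combination index of one dose pair at its observed fa."""
    dx_a = required_dose(fit_a, point.fa)
    dx_b = required_dose(fit_b, point.fa)
    ci = point.dose_a / dx_a + point.dose_b / dx_b
    return CIResult(fa=point.fa, ci=float(ci),
                    classification=classify_ci(ci, additive_band),
                    clamped=point.clamped)


def fa_ci_table(
    points: list[CombinationPoint],
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    additive_band: float = ADDITIVE_BAND,
) -> FaCiTable:
    """CI per measured concentration point, sorted by fa.

    The combination is flagged synergistic overall when a strict majority of
    points have CI < 1 — the "CI below 1 for most drug concentrations" call.
    """
    if not points:
        raise ValueError("fa_ci_table needs at least one combination point")
    results = [combination_index(p, fit_a, fit_b, additive_band) for p in points]
    df = pd.DataFrame(
        {
            "dose_a": [p.dose_a for p in points],
            "dose_b": [p.dose_b for p in points],
            "fa": [r.fa for r in results],
            "ci": [r.ci for r in results],
            "classification": [r.classification for r in results],
            "clamped": [r.clamped for r in results],
        }
    ).sort_values("fa", kind="mergesort", ignore_index=True)
    overall = bool((df["ci"] < 1.0).sum() > len(df) / 2)
    return FaCiTable(table=df, synergistic_overall=overall)


def combo_points_from_curve(
    curve: DoseResponseCurve,
    clamp_bounds: tuple[float, float] = CLAMP_BOUNDS,
) -> list[CombinationPoint]:
    """Turn a normalized combination curve into CI-ready points."""
    pts = fraction_affected(curve, clamp_bounds)
    return [
        CombinationPoint(float(row.dose_a), float(row.dose_b), float(row.fa), bool(row.clamped))
        for row in pts.itertuples()
    ]
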