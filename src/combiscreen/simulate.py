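"""Synthetic viability-screen generator.

Produces plate-level viability data, drug-combination responses with known
ground-truth synergy, and expression / Ct tables with planted effects, so
that every downstream analysis stage can be validated without external data.

The single-agent model is a four-parameter Hill curve anchored at the drug's
clinically reported maximum plasma concentration (Cmax): the top screening
dose equals Cmax and lower doses follow a log-serial dilution (half-log
steps by default, six points). Combinations are constructed from the Loewe
additivity equation with a scalar interaction factor ``psi`` applied to both
component doses, so that the exact combination index of the generated data
is ``1/psi`` — a closed-form oracle for the synergy module.

Noise is multiplicative lognormal on the positive plate readout (sd given on
the log scale), reflecting the heteroscedastic, strictly positive character
of luminescence viability reads. All randomness flows from an explicit seed;
no global RNG state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "DrugSpec",
    "ComboSpec",
    "PLATE_COLUMNS",
    "dose_ladder",
    "hill_viability",
    "loewe_fraction_affected",
    "simulate_single_agent",
    "simulate_combination",
    "simulate_panel",
    "simulate_expression",
    "simulate_ct",
]

#: Required columns of a long-format plate table. Concentrations are in µM.
PLATE_COLUMNS = (
    "sample_id",
    "treatment_id",
    "dose_a_um",
    "dose_b_um",
    "replicate",
    "raw_signal",
    "is_vehicle",
)

HALF_LOG = math.sqrt(10.0)

#: Expected vehicle-well luminescence; an arbitrary positive scale that the
#: vehicle normalization divides out.
BASELINE_SIGNAL = 1000.0


@dataclass(frozen=True)
class DrugSpec:
    """A single agent: its Cmax anchor and the Hill curve it follows.

    ``ec50``/``hill_slope`` double as the exact median-effect parameters
    (Dm, m) whenever ``hill_top == 1`` and ``hill_bottom == 0``, which is the
    configuration used for synergy ground-truth constructions.
    """

    name: str
    cmax: float
    ec50: float
    hill_slope: float = 1.0
    hill_top: float = 1.0
    hill_bottom: float = 0.0

    def __post_init__(self) -> None:
        if self.cmax <= 0:
            raise ValueError(f"{self.name}: cmax must be > 0, got {self.cmax}")
        if self.ec50 <= 0:
            raise ValueError(f"{self.name}: ec50 must be > 0, got {self.ec50}")
        if self.hill_slope <= 0:
            raise ValueError(f"{self.name}: hill_slope must be > 0")
        if not (0.0 <= self.hill_bottom <= self.hill_top):
            raise ValueError(
                f"{self.name}: need 0 <= hill_bottom <= hill_top, got "
                f"bottom={self.hill_bottom}, top={self.hill_top}"
            )

    @property
    def median_effect_params(self) -> tuple[float, float]:
        """Exact (Dm, m) of the generated fraction-affected curve.

        Valid as exact median-effect parameters when the curve spans the full
        0–1 viability range (top=1, bottom=0); otherwise they describe the
        half-effect point of the *scaled* curve.
        """
        return self.ec50, self.hill_slope


@dataclass(frozen=True)
class ComboSpec:
    """Two drugs combined at fixed dose pairs under a Loewe interaction.

    ``psi`` scales both component doses inside the Loewe equation, so the
    combination index of the noise-free generated data equals ``1/psi``:
    psi > 1 is synergistic, psi = 1 exactly additive, psi < 1 antagonistic.
    """

    drug_a: DrugSpec
    drug_b: DrugSpec
    psi: float = 1.0
    dose_pairs: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.psi <= 0:
            raise ValueError(f"psi must be > 0, got {self.psi}")
        for drug in (self.drug_a, self.drug_b):
            if drug.hill_top <= drug.hill_bottom:
                raise ValueError(
                    f"{drug.name}: combination components must be strictly "
                    "monotone (hill_top > hill_bottom)"
                )
        for da, db in self.dose_pairs:
            if da < 0 or db < 0 or (da == 0 and db == 0):
                raise ValueError(
                    f"invalid dose pair ({da}, {db}): doses must be "
                    "non-negative and not both zero"
                )

    @property
    def name(self) -> str:
        return f"{self.drug_a.name}+{self.drug_b.name}"

    def default_dose_pairs(self, n: int = 6, dilution: float = HALF_LOG) -> tuple[tuple[float, float], ...]:
        """Fixed-ratio ladder topping at (Cmax_a, Cmax_b)."""
        return tuple(
            (self.drug_a.cmax / dilution**k, self.drug_b.cmax / dilution**k)
            for k in range(n)
        )


def dose_ladder(top: float, n_doses: int = 6, dilution: float = HALF_LOG) -> np.ndarray:
    """Descending log-serial dilution series starting at ``top`` (µM)."""
    if top <= 0:
        raise ValueError("top dose must be > 0")
    if n_doses < 2:
        raise ValueError("need at least 2 doses")
    if dilution <= 1:
        raise ValueError("dilution factor must exceed 1")
    return top / dilution ** np.arange(n_doses)


def hill_viability(dose: np.ndarray | float, spec: DrugSpec) -> np.ndarray | float:
    """Noise-free viability fraction at ``dose`` µM under ``spec``'s curve."""
    d = np.asarray(dose, dtype=float)
    v = spec.hill_bottom + (spec.hill_top - spec.hill_bottom) / (
        1.0 + (d / spec.ec50) ** spec.hill_slope
    )
    return v if v.ndim else float(v)


def _noise(rng: np.random.Generator, n: int, noise_sd: float) -> np.ndarray:
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return np.ones(n)
    return np.exp(rng.normal(0.0, noise_sd, size=n))


def _plate_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    extra = [c for c in df.columns if c not in PLATE_COLUMNS]
    return df[[*PLATE_COLUMNS, *extra]]


def _vehicle_rows(sample_id: str, n_reps: int, rng: np.random.Generator, noise_sd: float) -> list[dict]:
    noise = _noise(rng, n_reps, noise_sd)
    return [
        {
            "sample_id": sample_id,
            "treatment_id": "vehicle",
            "dose_a_um": 0.0,
            "dose_b_um": 0.0,
            "replicate": r,
            "raw_signal": BASELINE_SIGNAL * noise[r],
            "is_vehicle": True,
            "dose_tier": "cmax",
        }
        for r in range(n_reps)
    ]


def simulate_single_agent(
    spec: DrugSpec,
    n_doses: int = 6,
    n_reps: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
    sample_id: str = "S1",
    dilution: float = HALF_LOG,
    top_dose: float | None = None,
    dose_tier: str = "cmax",
    include_vehicle: bool = True,
    ec50_multiplier: float = 1.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one drug on one sample over a Cmax-anchored dose ladder.

    Mean viability at dose d is the Hill curve of ``spec`` (with the ec50
    optionally perturbed by ``ec50_multiplier`` for per-sample sensitivity),
    times lognormal noise with log-scale sd ``noise_sd``. Vehicle wells have
    expected viability 1. Identical seeds yield bit-identical tables.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    doses = dose_ladder(top_dose if top_dose is not None else spec.cmax, n_doses, dilution)
    eff = DrugSpec(
        spec.name, spec.cmax, spec.ec50 * ec50_multiplier,
        spec.hill_slope, spec.hill_top, spec.hill_bottom,
    )
    rows: list[dict] = []
    if include_vehicle:
        rows.extend(_vehicle_rows(sample_id, n_reps, rng, noise_sd))
    for d in doses:
        v = hill_viability(d, eff)
        noise = _noise(rng, n_reps, noise_sd)
        for r in range(n_reps):
            rows.append(
                {
                    "sample_id": sample_id,
                    "treatment_id": spec.name,
                    "dose_a_um": float(d),
                    "dose_b_um": 0.0,
                    "replicate": r,
                    "raw_signal": BASELINE_SIGNAL * v * noise[r],
                    "is_vehicle": False,
                    "dose_tier": dose_tier,
                }
            )
    return _plate_frame(rows)


def loewe_fraction_affected(
    dose_a: float,
    dose_b: float,
    dm_a: float,
    m_a: float,
    dm_b: float,
    m_b: float,
    psi: float = 1.0,
    eps: float = 1e-6,
) -> tuple[float, bool]:
    """Fraction affected solving the scaled Loewe equation.

    Solves psi*d_a/Dx_a(fa) + psi*d_b/Dx_b(fa) = 1 for fa, where
    Dx_i(fa) = Dm_i * (fa/(1-fa))^(1/m_i) is the median-effect dose required
    for effect fa. Returns (fa, clamped): when no root exists inside
    (eps, 1-eps) the fa is clamped to the nearer boundary and flagged.
    """
    if dose_a < 0 or dose_b < 0 or (dose_a == 0 and dose_b == 0):
        raise ValueError("dose pair must be non-negative and not both zero")

    def g(fa: float) -> float:
        ratio = (fa / (1.0 - fa))
        dx_a = dm_a * ratio ** (1.0 / m_a)
        dx_b = dm_b * ratio ** (1.0 / m_b)
        return psi * dose_a / dx_a + psi * dose_b / dx_b - 1.0

    lo, hi = eps, 1.0 - eps
    g_lo, g_hi = g(lo), g(hi)
    if g_lo <= 0:  # even a negligible effect overshoots: doses are tiny
        return lo, True
    if g_hi >= 0:  # effect saturates below the top of the open interval
        return hi, True
    fa = brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16)
    return float(fa), False


def simulate_combination(
    spec: ComboSpec,
    n_reps: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
    sample_id: str = "S1",
    include_vehicle: bool = True,
    dose_tier: str = "cmax",
    ec50_multiplier: float = 1.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a drug pair at fixed dose pairs under a Loewe construction.

    The noise-free viability at each pair is 1 - fa with fa from
    :func:`loewe_fraction_affected`; rows where the solver hit the open
    interval's boundary carry ``clamped=True``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    pairs = spec.dose_pairs or spec.default_dose_pairs()
    dm_a, m_a = spec.drug_a.median_effect_params
    dm_b, m_b = spec.drug_b.median_effect_params
    dm_a *= ec50_multiplier
    dm_b *= ec50_multiplier
    rows: list[dict] = []
    if include_vehicle:
        rows.extend(_vehicle_rows(sample_id, n_reps, rng, noise_sd))
    for da, db in pairs:
        fa, clamped = loewe_fraction_affected(da, db, dm_a, m_a, dm_b, m_b, spec.psi)
        v = 1.0 - fa
        noise = _noise(rng, n_reps, noise_sd)
        for r in range(n_reps):
            rows.append(
                {
                    "sample_id": sample_id,
                    "treatment_id": spec.name,
                    "dose_a_um": float(da),
                    "dose_b_um": float(db),
                    "replicate": r,
                    "raw_signal": BASELINE_SIGNAL * v * noise[r],
                    "is_vehicle": False,
                    "dose_tier": dose_tier,
                    "clamped": clamped,
                }
            )
    df = _plate_frame(rows)
    if "clamped" in df.columns:
        df["clamped"] = df["clamped"].astype("boolean").fillna(False).astype(bool)
    return df


def simulate_panel(
    n_samples: int,
    treatments: list[DrugSpec | ComboSpec],
    missing_fraction: float = 0.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    n_doses: int = 6,
    n_reps: int = 3,
    sample_sd: float = 0.2,
    tiers: tuple[str, ...] = ("cmax", "10pct_cmax"),
) -> pd.DataFrame:
    """Simulate a treatments × samples screening panel.

    Each sample gets a lognormal sensitivity multiplier (sd ``sample_sd`` on
    the log scale) applied to every drug's ec50, emulating between-patient
    heterogeneity. Every treatment is run at each dose tier: a 6-point
    ladder topping at Cmax, or at 10% Cmax for the low tier (for pairs, both
    components are diluted together at fixed ratio). A ``missing_fraction``
    of (sample, treatment) cells is left untested.
    """
    if not (0.0 <= missing_fraction < 1.0):
        raise ValueError("missing_fraction must be in [0, 1)")
    if n_samples < 1 or not treatments:
        raise ValueError("need at least one sample and one treatment")
    tier_frac = {"cmax": 1.0, "10pct_cmax": 0.1}
    for t in tiers:
        if t not in tier_frac:
            raise ValueError(f"unknown dose tier {t!r}")

    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    multipliers = np.exp(rng.normal(0.0, sample_sd, size=n_samples)) if sample_sd > 0 else np.ones(n_samples)
    missing = (
        rng.random((n_samples, len(treatments))) < missing_fraction
        if missing_fraction > 0
        else np.zeros((n_samples, len(treatments)), dtype=bool)
    )

    frames: list[pd.DataFrame] = []
    for i, sample in enumerate(samples):
        frames.append(
            _plate_frame(_vehicle_rows(sample, n_reps, rng, noise_sd))
        )
        for j, treatment in enumerate(treatments):
            if missing[i, j]:
                continue
            for tier in tiers:
                frac = tier_frac[tier]
                if isinstance(treatment, ComboSpec):
                    pairs = tuple(
                        (frac * treatment.drug_a.cmax / HALF_LOG**k,
                         frac * treatment.drug_b.cmax / HALF_LOG**k)
                        for k in range(n_doses)
                    )
                    tiered = ComboSpec(treatment.drug_a, treatment.drug_b, treatment.psi, pairs)
                    frames.append(
                        simulate_combination(
                            tiered, n_reps=n_reps, noise_sd=noise_sd,
                            sample_id=sample, include_vehicle=False,
                            dose_tier=tier, ec50_multiplier=float(multipliers[i]),
                            rng=rng,
                        )
                    )
                else:
                    frames.append(
                        simulate_single_agent(
                            treatment, n_doses=n_doses, n_reps=n_reps,
                            noise_sd=noise_sd, sample_id=sample,
                            top_dose=frac * treatment.cmax, dose_tier=tier,
                            include_vehicle=False,
                            ec50_multiplier=float(multipliers[i]), rng=rng,
                        )
                    )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Expression and Ct fixtures
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTable:
    """Gene × sample intensity matrix with sample group labels."""

    values: pd.DataFrame          # genes × samples, intensity (linear) scale
    groups: pd.Series             # sample -> group label
    de_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("gene identifiers must be unique")
        self.values.index.name = "gene"
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")


def simulate_expression(
    n_genes: int,
    groups: dict[str, int],
    de_genes: int,
    log2fc: float = 2.0,
    sigma: float = 0.1,
    seed: int = 0,
    base_log2: float = 10.0,
) -> ExpressionTable:
    """Two-group (or multi-group) expression matrix with planted effects.

    The first ``de_genes`` genes get a group-mean log2 shift of ``log2fc``
    in every non-reference group (reference = first key of ``groups``);
    all genes get gaussian noise of sd ``sigma`` on the log2 scale.
    Intensities are returned on the linear scale (2**log2).
    """
    if de_genes > n_genes:
        raise ValueError("de_genes cannot exceed n_genes")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    planted = genes[:de_genes]
    group_names = list(groups)
    sample_ids: list[str] = []
    labels: list[str] = []
    cols: list[np.ndarray] = []
    base = base_log2 + rng.normal(0.0, 1.0, size=n_genes)  # per-gene baseline
    for g_idx, gname in enumerate(group_names):
        shift = np.zeros(n_genes)
        if g_idx > 0:
            shift[:de_genes] = log2fc
        for k in range(groups[gname]):
            sid = f"{gname}{k + 1}"
            sample_ids.append(sid)
            labels.append(gname)
            cols.append(base + shift + rng.normal(0.0, sigma, size=n_genes))
    log2_mat = np.column_stack(cols)
    values = pd.DataFrame(2.0 ** log2_mat, index=genes, columns=sample_ids)
    return ExpressionTable(values, pd.Series(labels, index=sample_ids), planted)


def simulate_ct(
    targets: list[str],
    reference: str = "RAB14",
    planted_ddct: dict[str, float] | None = None,
    sd: float = 0.1,
    n_reps: int = 3,
    seed: int = 0,
    calibrator_group: str = "vehicle",
    treated_group: str = "treated",
    base_ct: float = 25.0,
    reference_ct: float = 18.0,
) -> pd.DataFrame:
    """Long-format Ct table (gene, group, replicate, ct) with planted ΔΔCt.

    The treated-group Ct of each target is shifted by its planted ΔΔCt, so
    the downstream fold change is 2**(-planted_ddct). The reference gene is
    stable across groups.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 (error propagation needs variance)")
    if reference in (planted_ddct or {}):
        raise ValueError("reference gene cannot carry a planted shift")
    planted_ddct = planted_ddct or {}
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for gene in [*targets, reference]:
        base = reference_ct if gene == reference else base_ct
        for group in (calibrator_group, treated_group):
            shift = planted_ddct.get(gene, 0.0) if (group == treated_group and gene != reference) else 0.0
            noise = rng.normal(0.0, sd, size=n_reps) if sd > 0 else np.zeros(n_reps)
            for r in range(n_reps):
                rows.append(
                    {"gene": gene, "group": group, "replicate": r, "ct": base + shift + noise[r]}
                )
    return pd.DataFrame(rows)
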