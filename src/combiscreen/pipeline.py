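"""Run configuration and the end-to-end screening pipeline.

A :class:`RunConfig` captures every tunable of a run — dose axis, AUC
anchors, fa clamp bounds, CI additive band, DEG thresholds, seed — and
round-trips losslessly through YAML. :func:`run_pipeline` executes
normalize → score → rank → synergy over a plate table (read from CSV or
simulated) and writes all result TSVs plus a machine-readable manifest
containing the resolved configuration, its hash, and the seed, so a rerun
with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import dose_response, io, ranking, synergy
from .simulate import ComboSpec, DrugSpec, simulate_panel

__all__ = ["RunConfig", "run_pipeline", "config_hash"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run."""

    plates_csv: str | None = None
    simulate: dict | None = None          # kwargs for a synthetic panel
    drugs: list[dict] = field(default_factory=list)
    combos: list[dict] = field(default_factory=list)
    synergy_pairs: list[list[str]] = field(default_factory=list)
    dose_axis: str = "log10"
    auc_anchors: str = "theoretical"      # or "empirical"
    clamp_bounds: tuple[float, float] = (0.01, 0.99)
    additive_band: float = 0.05
    fc_threshold: float = 1.0
    alpha: float = 0.05
    adjust_p: bool = False
    ranking_tier: str = "10pct_cmax"
    min_samples: int = 3
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        lo, hi = self.clamp_bounds
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"invalid clamp bounds ({lo}, {hi}): need 0 < lo < hi < 1")
        if self.additive_band < 0:
            raise ValueError("additive_band must be >= 0")
        if self.dose_axis not in ("log10", "linear"):
            raise ValueError(f"unknown dose_axis {self.dose_axis!r}")
        if self.auc_anchors not in ("theoretical", "empirical"):
            raise ValueError(f"unknown auc_anchors {self.auc_anchors!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.fc_threshold < 0:
            raise ValueError("fc_threshold must be >= 0")
        if self.plates_csv is None and self.simulate is None:
            raise ValueError("config must provide plates_csv or a simulate block")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "clamp_bounds" in data:
            data["clamp_bounds"] = tuple(data["clamp_bounds"])
        return cls(**data)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["clamp_bounds"] = list(self.clamp_bounds)
        return d


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.as_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _specs_from_config(config: RunConfig) -> list[DrugSpec | ComboSpec]:
    drugs = {d["name"]: DrugSpec(**d) for d in config.drugs}
    treatments: list[DrugSpec | ComboSpec] = list(drugs.values())
    for combo in config.combos:
        treatments.append(
            ComboSpec(
                drug_a=drugs[combo["drug_a"]],
                drug_b=drugs[combo["drug_b"]],
                psi=combo.get("psi", 1.0),
            )
        )
    return treatments


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute normalize → score → rank → synergy and write the report bundle.

    Returns the manifest dictionary. Outputs under ``config.out_dir``:
    ``plate.csv`` (when simulated), ``scores.tsv``, ``ranking.tsv``,
    ``heatmap.tsv``, ``fa_ci_<pair>.tsv`` per configured synergy pair, and
    ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.plates_csv is not None:
        plate = io.read_plate_csv(config.plates_csv)
        logger.info("loaded %d wells from %s", len(plate), config.plates_csv)
    else:
        treatments = _specs_from_config(config)
        sim_kwargs = dict(config.simulate or {})
        plate = simulate_panel(treatments=treatments, seed=config.seed, **sim_kwargs)
        io.write_plate_csv(plate, out / "plate.csv")
        logger.info("simulated %d wells", len(plate))

    scored = dose_response.score_plate(plate, dose_axis=config.dose_axis)
    _write_tsv(scored, out / "scores.tsv")

    matrix = ranking.build_score_matrix(scored, dose_tier=config.ranking_tier)
    rank_df = ranking.rank_treatments(matrix, min_samples=config.min_samples)
    _write_tsv(rank_df, out / "ranking.tsv")
    _write_tsv(ranking.to_heatmap_table(matrix, rank_df), out / "heatmap.tsv")

    curves = dose_response.normalize_viability(plate)
    synergy_files: dict[str, str] = {}
    for pair in config.synergy_pairs:
        name_a, name_b = pair
        combo_name = f"{name_a}+{name_b}"
        n_flagged = 0
        tables = []
        for sample_id in sorted({c.sample_id for c in curves}):
            fit_a = fit_b = None
            combo_curve = None
            for c in curves:
                if c.sample_id != sample_id or c.dose_tier != "cmax":
                    continue
                if c.treatment == name_a:
                    fit_a = synergy.fit_median_effect_curve(c, config.clamp_bounds)
                elif c.treatment == name_b:
                    fit_b = synergy.fit_median_effect_curve(c, config.clamp_bounds)
                elif c.treatment == combo_name:
                    combo_curve = c
            if fit_a is None or fit_b is None or combo_curve is None:
                logger.info("sample %s: pair %s incomplete, skipped", sample_id, combo_name)
                continue
            points = synergy.combo_points_from_curve(combo_curve, config.clamp_bounds)
            n_flagged += sum(p.clamped for p in points)
            result = synergy.fa_ci_table(points, fit_a, fit_b, config.additive_band)
            tbl = result.table.copy()
            tbl.insert(0, "sample_id", sample_id)
            tbl["synergistic_overall"] = result.synergistic_overall
            tables.append(tbl)
        if tables:
            fname = f"fa_ci_{name_a}_{name_b}.tsv"
            _write_tsv(pd.concat(tables, ignore_index=True), out / fname)
            synergy_files[combo_name] = fname
            logger.info("pair %s: %d clamped fa points flagged", combo_name, n_flagged)

    manifest = {
        "config": config.as_dict(),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "n_wells": int(len(plate)),
        "n_curves": int(len(scored)),
        "top_treatment": (
            str(rank_df.loc[rank_df["rank"] == 1, "treatment"].iloc[0])
            if (rank_df["rank"] == 1).any()
            else None
        ),
        "synergy_outputs": synergy_files,
        "outputs": ["scores.tsv", "ranking.tsv", "heatmap.tsv", *synergy_files.values()],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
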