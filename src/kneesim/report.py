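"""End-to-end study driver and report assembly.

Runs the full tibial-slope experiment from one configuration: generate (or
load) the knee, build the 2-technique x 5-slope variants, run the laxity
battery and the squat per variant, and summarize per-3-degree force trends
and percent changes relative to the same-technique neutral-slope case.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ReferencingTechnique, STUDY_SLOPES_DEG
from .laxity import STUDY_ANGLES_DEG, LaxityTable, run_laxity_battery
from .model import KneeModel, model_to_yaml, save_model
from .squat import SquatOutcomes, SquatTrajectory, patellar_height, simulate_squat
from .synthetic import KneeGenConfig, generate_knee

__all__ = ["StudyConfig", "StudyReport", "per3deg_trend", "run_study"]


@dataclass(frozen=True)
class StudyConfig:
    generator: KneeGenConfig = field(default_factory=KneeGenConfig)
    trajectory: SquatTrajectory = field(default_factory=SquatTrajectory)
    techniques: tuple = (ReferencingTechnique.ACR, ReferencingTechnique.CPR)
    slopes_deg: tuple = STUDY_SLOPES_DEG
    angles_deg: tuple = STUDY_ANGLES_DEG
    run_laxity: bool = True
    run_squat: bool = True


def per3deg_trend(peaks_by_slope: dict[float, float]) -> float:
    """Average change per 3-degree step across the 0/+3/+6/+9 posterior cases.

    Raises ``KeyError`` if a posterior slope case is missing.
    """
    slopes = (0.0, 3.0, 6.0, 9.0)
    vals = [peaks_by_slope[s] for s in slopes]
    diffs = np.diff(vals)
    return float(diffs.mean())


def _percent_change(value: float, baseline: float) -> float:
    if baseline == 0.0:
        return float("nan")
    return 100.0 * (value - baseline) / baseline


@dataclass(frozen=True)
class StudyReport:
    """Everything the study produces, plus provenance."""

    model: KneeModel
    laxity: LaxityTable | None
    squat: dict[tuple[str, float], SquatOutcomes]
    squat_peaks: pd.DataFrame | None
    trends: dict[str, float]
    laxity_percent_change: pd.DataFrame | None
    provenance: dict
    failures: tuple[str, ...] = ()

    def summary_dict(self) -> dict:
        out = {
            "provenance": self.provenance,
            "trends": self.trends,
            "failures": list(self.failures),
        }
        if self.laxity is not None:
            out["laxity_rows"] = len(self.laxity)
        if self.squat_peaks is not None:
            out["squat_peaks"] = self.squat_peaks.to_dict(orient="records")
        return out


def _laxity_percent_change(table: LaxityTable) -> pd.DataFrame:
    """Per (technique, slope != 0, flexion, test): percent change vs the
    same-technique neutral-slope laxity."""
    df = table.to_dataframe()
    rows = []
    for (tech, test, ang), grp in df.groupby(["technique", "test", "flexion_deg"]):
        base = grp.loc[grp["slope_deg"] == 0.0, "value"]
        if base.empty:
            continue
        b = float(base.iloc[0])
        for _, r in grp.iterrows():
            if r["slope_deg"] == 0.0:
                continue
            rows.append(
                {
                    "technique": tech,
                    "slope_deg": r["slope_deg"],
                    "flexion_deg": ang,
                    "test": test,
                    "value": r["value"],
                    "baseline": b,
                    "percent_change": _percent_change(r["value"], b),
                }
            )
    return pd.DataFrame(rows)


def run_study(
    config: StudyConfig | None = None,
    model: KneeModel | None = None,
    out_dir: str | Path | None = None,
) -> StudyReport:
    """Run the complete study design from one configuration.

    Stage failures are recorded in ``failures`` and the run continues where
    possible.  When ``out_dir`` is given, writes model.yaml, laxity.csv,
    squat.csv, squat_peaks.csv and report.json.
    """
    config = config or StudyConfig()
    if model is None:
        model = generate_knee(config.generator)
    model_yaml = model_to_yaml(model)
    failures: list[str] = []

    laxity = None
    laxity_pct = None
    if config.run_laxity:
        laxity = run_laxity_battery(
            model, config.techniques, config.slopes_deg, config.angles_deg
        )
        laxity_pct = _laxity_percent_change(laxity)
        n_bad = sum(1 for m in laxity.measurements if not m.converged)
        if n_bad:
            failures.append(f"laxity: {n_bad} non-converged cells")

    squat: dict[tuple[str, float], SquatOutcomes] = {}
    peaks_rows = []
    trends: dict[str, float] = {}
    if config.run_squat:
        for technique in config.techniques:
            technique = ReferencingTechnique(technique)
            for slope in config.slopes_deg:
                variant = model.with_slope_case(model.make_slope_case(technique, slope))
                out = simulate_squat(variant, config.trajectory)
                squat[(technique.value, float(slope))] = out
                if not out.all_converged:
                    failures.append(f"squat {technique.value} {slope:+g}: non-converged samples")
                row = {"technique": technique.value, "slope_deg": float(slope)}
                row.update(out.peaks)
                row["cop_travel_medial_m"] = out.cop_travel_medial
                row["cop_travel_lateral_m"] = out.cop_travel_lateral
                peaks_rows.append(row)
        peaks_df = pd.DataFrame(peaks_rows)

        # patellar height at 60 degrees flexion vs same-technique baseline
        for technique in config.techniques:
            technique = ReferencingTechnique(technique).value
            base = squat.get((technique, 0.0))
            if base is None:
                continue
            s = base.samples
            bseries = s.loc[s["converged"]]

            def baseline_fn(phi, _b=bseries):
                return float(
                    np.interp(phi, _b["flexion_deg"].iloc[: len(_b) // 2 + 1], _b["patellar_height_raw_m"].iloc[: len(_b) // 2 + 1])
                )

            for slope in config.slopes_deg:
                out = squat.get((technique, float(slope)))
                if out is None:
                    continue
                res60 = _result_at(out, 60.0)
                if res60 is not None:
                    trends[f"patellar_height_60deg_{technique.lower()}_{_slope_tag(slope)}_mm"] = (
                        1e3 * patellar_height(res60, model, baseline_fn)
                    )

        for technique in config.techniques:
            technique = ReferencingTechnique(technique).value
            sub = peaks_df[peaks_df["technique"] == technique]
            by_slope = {
                r["slope_deg"]: r for _, r in sub.iterrows()
            }
            try:
                for col, tag in (
                    ("quad_force_pbw", "quad"),
                    ("quad_femur_force_pbw", "quad_femur"),
                    ("pfj_force_pbw", "pfj"),
                ):
                    trends[f"{tag}_peak_trend_{technique.lower()}_pbw_per_3deg"] = per3deg_trend(
                        {s: float(r[col]) for s, r in by_slope.items()}
                    )
            except KeyError:
                failures.append(f"squat trends {technique}: missing slope case")
    else:
        peaks_df = None

    from . import __version__ as pkg_version

    provenance = {
        "package_version": pkg_version,
        "seed": model.seed,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config.generator), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "model_hash": hashlib.sha256(model_yaml.encode()).hexdigest()[:16],
    }

    report = StudyReport(
        model=model,
        laxity=laxity,
        squat=squat,
        squat_peaks=peaks_df,
        trends=trends,
        laxity_percent_change=laxity_pct,
        provenance=provenance,
        failures=tuple(failures),
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_model(model, out / "model.yaml")
        if laxity is not None:
            laxity.to_dataframe().to_csv(out / "laxity.csv", index=False)
            laxity_pct.to_csv(out / "laxity_percent_change.csv", index=False)
        if peaks_df is not None:
            peaks_df.to_csv(out / "squat_peaks.csv", index=False)
            pd.concat(
                [
                    o.samples.assign(technique=k[0], slope_deg=k[1])
                    for k, o in squat.items()
                ],
                ignore_index=True,
            ).to_csv(out / "squat.csv", index=False)
        (out / "report.json").write_text(json.dumps(report.summary_dict(), indent=2, default=float))
    return report


def _slope_tag(slope: float) -> str:
    s = int(round(slope))
    return f"plus{s}" if s >= 0 else f"minus{-s}"


def _result_at(out: SquatOutcomes, flexion_deg: float):
    """First converged descend-phase result at the given flexion angle."""
    for res in out.results:
        if res.converged and abs(res.flexion_deg - flexion_deg) < 1e-9:
            return res
    return None
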