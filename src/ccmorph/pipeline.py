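"""End-to-end study orchestration: cohort -> profiles -> omnibus -> post-hoc.

:func:`run_study` reproduces the analysis structure of a multi-group
callosal morphometry study: thickness profiles for every subject, an
omnibus diagnosis ANCOVA over all positions, and pairwise post-hoc
contrasts that are fitted only when the omnibus family contains at least
one FDR-significant position (the gate can be disabled for methodological
work). All tables are written as TSV plus a JSON manifest that records the
resolved configuration hash, seed, package version, per-stage row counts
and the gate decision, so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .contour_io import (
    ContourPair,
    SubjectRecord,
    read_contours,
    read_covariates,
    records_to_frame,
    write_contours,
    write_covariates,
)
from .geometry import (
    MidlineMode,
    ThicknessProfile,
    compute_profile,
    profiles_to_cdv,
    write_profiles,
)
from .stats import (
    AnalysisConfig,
    adjusted_group_means,
    build_design,
    fit_pointwise_omnibus,
    fit_pointwise_posthoc,
    RESULT_COLUMNS,
)
from .synthetic import EffectMap, SimulationConfig, preset_effectmaps, simulate_cohort

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class StudyRunConfig:
    """One reproducible study run.

    Exactly one of (``contours_path`` and ``covariates_path``) or
    ``simulation`` must be provided. ``contrasts=None`` expands to the
    default set: every patient group vs the control group, then every
    patient-group pair.
    """

    out_dir: str | Path
    contours_path: Optional[str | Path] = None
    covariates_path: Optional[str | Path] = None
    simulation: Optional[SimulationConfig] = None
    effect_preset: str = "null"
    analysis: AnalysisConfig = AnalysisConfig()
    midline_mode: MidlineMode = "pointwise_average"
    contrasts: Optional[Sequence[tuple[str, str]]] = None
    gate_posthoc: bool = True

    def __post_init__(self) -> None:
        file_input = self.contours_path is not None or self.covariates_path is not None
        if file_input and self.simulation is not None:
            raise ValueError("provide either input paths or a simulation config, not both")
        if not file_input and self.simulation is None:
            raise ValueError("provide input paths or a simulation config")
        if file_input and (self.contours_path is None or self.covariates_path is None):
            raise ValueError("both contours_path and covariates_path are required")


@dataclasses.dataclass
class StudyResult:
    """In-memory view of a completed run."""

    profiles: list[ThicknessProfile]
    cdv: pd.DataFrame
    omnibus: pd.DataFrame
    posthoc: dict[str, pd.DataFrame]
    adjusted_means: pd.DataFrame
    manifest: dict
    out_dir: Path

    @property
    def combined(self) -> pd.DataFrame:
        frames = [self.omnibus, *self.posthoc.values()]
        return pd.concat(frames, ignore_index=True)


def default_contrasts(
    groups: Sequence[str], control_label: str
) -> list[tuple[str, str]]:
    """Patient-vs-control contrasts first, then all patient pairs."""
    patients = sorted(g for g in set(groups) if g != control_label)
    out = [(g, control_label) for g in patients if control_label in groups]
    out += list(itertools.combinations(patients, 2))
    return out


def _config_hash(config: StudyRunConfig) -> str:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            # out_dir is where results land, not what they are
            return {
                f.name: enc(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
                if f.name != "out_dir"
            }
        if isinstance(obj, (Path,)):
            return str(obj)
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, (list, tuple)):
            return [enc(x) for x in obj]
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        return obj

    blob = json.dumps(enc(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def load_or_simulate(
    config: StudyRunConfig,
) -> tuple[list[ContourPair], list[SubjectRecord]]:
    """Resolve the run's inputs: read files or simulate the cohort."""
    if config.simulation is not None:
        presets = preset_effectmaps(config.simulation.n_points)
        if config.effect_preset not in presets:
            raise ValueError(
                f"unknown effect preset {config.effect_preset!r}; "
                f"available: {sorted(presets)}"
            )
        return simulate_cohort(config.simulation, presets[config.effect_preset])
    return (
        read_contours(config.contours_path),
        read_covariates(config.covariates_path),
    )


def run_study(config: StudyRunConfig) -> StudyResult:
    """Execute the full pipeline and write the results bundle.

    Writes per-comparison TSVs, a combined pointwise TSV, the
    covariate-adjusted group-means TSV, the per-subject profile CSV and
    ``manifest.json`` under ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    analysis = config.analysis

    pairs, records = load_or_simulate(config)
    log.info("stage=input subjects=%d", len(records))
    profiles = [
        compute_profile(p, analysis.n_points, config.midline_mode) for p in pairs
    ]
    cdv = profiles_to_cdv(profiles)
    rec_df = records_to_frame(records)
    if set(cdv.index) != set(rec_df["subject_id"]):
        raise ValueError("contours and covariates cover different subjects")
    log.info("stage=profiles profiles=%d n_points=%d", len(profiles), analysis.n_points)

    design = build_design(rec_df, analysis)
    omnibus = fit_pointwise_omnibus(cdv, design, analysis)
    gate_open = bool(omnibus["significant"].any()) or not config.gate_posthoc
    log.info(
        "stage=omnibus significant=%d gate_open=%s",
        int(omnibus["significant"].sum()), gate_open,
    )

    contrasts = config.contrasts
    if contrasts is None:
        contrasts = default_contrasts(design.groups, analysis.control_label)
    posthoc: dict[str, pd.DataFrame] = {}
    if gate_open:
        for a, b in contrasts:
            res = fit_pointwise_posthoc(cdv, rec_df, a, b, analysis)
            posthoc[f"{a}_vs_{b}"] = res
            log.info(
                "stage=posthoc contrast=%s_vs_%s significant=%d",
                a, b, int(res["significant"].sum()),
            )

    means = adjusted_group_means(cdv, design, analysis)

    write_profiles(profiles, out_dir / "profiles.csv")
    omnibus.to_csv(out_dir / "omnibus.tsv", sep="\t", index=False)
    for name, res in posthoc.items():
        res.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    combined = pd.concat([omnibus, *posthoc.values()], ignore_index=True)
    combined.to_csv(out_dir / "pointwise_results.tsv", sep="\t", index=False)
    means.to_csv(out_dir / "adjusted_means.tsv", sep="\t", index=False)
    if config.simulation is not None:
        write_contours(pairs, out_dir / "contours.csv")
        write_covariates(records, out_dir / "covariates.csv")

    manifest = {
        "version": __version__,
        "config_sha256": _config_hash(config),
        "seed": None if config.simulation is None else config.simulation.seed,
        "n_subjects": len(records),
        "n_profiles": len(profiles),
        "design_rows": design.n,
        "n_points": analysis.n_points,
        "gate_posthoc": config.gate_posthoc,
        "gate_open": gate_open,
        "omnibus_significant_positions": int(omnibus["significant"].sum()),
        "comparisons": {
            name: int(res["significant"].sum()) for name, res in posthoc.items()
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return StudyResult(
        profiles=profiles,
        cdv=cdv,
        omnibus=omnibus,
        posthoc=posthoc,
        adjusted_means=means,
        manifest=manifest,
        out_dir=out_dir,
    )


def export_pointwise_map(
    results: pd.DataFrame,
    upper: np.ndarray,
    lower: np.ndarray,
) -> pd.DataFrame:
    """Join one comparison's pointwise results onto the callosal outline.

    Each position's statistic is mirrored onto both the upper and lower
    boundary coordinates (the single CDV per position describes both), so a
    100-position result yields a 200-row plottable table with columns
    ``comparison, boundary, position, x_mm, y_mm, p_fdr, significant``.
    """
    upper = np.asarray(upper, float)
    lower = np.asarray(lower, float)
    n = len(results)
    if upper.shape != (n, 2) or lower.shape != (n, 2):
        raise ValueError(
            f"boundary coordinates must be ({n}, 2) arrays matching the results"
        )
    if results["comparison"].nunique() != 1:
        raise ValueError("results must contain exactly one comparison")
    rows = []
    for bname, coords in (("upper", upper), ("lower", lower)):
        for (_, r), (x, y) in zip(results.iterrows(), coords):
            rows.append(
                (r["comparison"], bname, int(r["position"]), float(x), float(y),
                 float(r["p_fdr"]), bool(r["significant"]))
            )
    return pd.DataFrame(
        rows,
        columns=["comparison", "boundary", "position", "x_mm", "y_mm",
                 "p_fdr", "significant"],
    )
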