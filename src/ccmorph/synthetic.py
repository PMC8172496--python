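"""Synthetic midsagittal callosal cohorts for end-to-end pipeline testing.

The anatomy is stylized, not atlas-based: the callosal centerline is a
circular arc (span and height in mm) and the upper/lower boundaries are
offsets along the local normal by a position-dependent half-thickness

    h(t) = subject_scale * effect(t) * template(t)

where ``template`` is a smooth baseline profile with bulges at the genu and
splenium, a thinner body, and tapered tips, and ``effect`` is a per-group
multiplicative thinning map (1.0 = no effect, 0.8 = 20% thinning). Vertex
coordinates are then perturbed with isotropic Gaussian noise emulating
tracing error. An arc keeps the centerline curvature low and uniform so
that independently resampling the two boundaries by their own arc lengths
recovers the injected half-thickness profile almost exactly.

Inter-subject variability has two components. A global size factor is tied
to the subject's simulated intracranial volume (bigger heads, thicker
callosa), which is what the TIV covariate adjusts out downstream. On top of
that, each subject carries a smooth low-frequency regional modulation of
log-thickness (a few random cosine modes along the midline), mimicking the
fact that individual anatomy varies regionally rather than by a single
global multiplier; this keeps distant positions only weakly correlated, so
pointwise tests behave like a genuinely mass-univariate family.

Covariates are drawn to mimic the matched case-control design: one age draw
is shared across groups subject-for-subject (exact matching), sex alternates
M/F within each group, and clinical covariates exist only for patients.
Covariates carry no structural effect on thickness, so they act as pure
noise regressors downstream.

Everything is deterministic given the config seed; the seed is expanded
into independent per-subject substreams so a cohort is reproducible even
under subsetting.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Mapping, Optional, Sequence

import numpy as np

from .contour_io import CONTROL_LABEL, ContourPair, Polyline, SubjectRecord, validate_contour_pair

DEFAULT_GROUPS = ("OCD", "SZ", "BD", "MDD", "HC")

#: 1-based position windows used by the effect presets. The rostrum and
#: isthmus windows locate the focal thinning of the schizophrenia preset;
#: the middle-body window is spared by the global OCD preset.
ROSTRUM_WINDOW = (1, 8)
ISTHMUS_WINDOW = (70, 80)
MIDDLE_BODY_WINDOW = (40, 60)

#: Default thinning factor applied inside affected windows (20% thinning).
DEFAULT_THINNING = 0.8


@dataclasses.dataclass(frozen=True)
class TemplateParams:
    """Baseline half-thickness profile of the template callosum (mm).

    The profile is ``amplitude`` times a fixed-shape curve: a constant base
    plus Gaussian bulges at the genu and splenium, minus a Gaussian dip over
    the body and exponential tapers at the two tips. ``amplitude`` scales
    the whole profile linearly.
    """

    amplitude: float = 1.0
    base_mm: float = 2.3
    genu_amp_mm: float = 1.5
    genu_center: float = 0.10
    genu_width: float = 0.12
    splenium_amp_mm: float = 1.7
    splenium_center: float = 0.90
    splenium_width: float = 0.13
    body_dip_mm: float = 0.7
    body_center: float = 0.50
    body_width: float = 0.24
    tip_drop_mm: float = 0.8
    tip_width: float = 0.09


@dataclasses.dataclass(frozen=True)
class ArchParams:
    """Circular-arc centerline: anterior-posterior span and apex height, mm."""

    span_mm: float = 70.0
    height_mm: float = 16.0


@dataclasses.dataclass(frozen=True)
class CovariateModel:
    """Group-wise covariate distributions (means/SDs loosely matching a
    typical adult psychiatric cohort)."""

    age_mean: float = 40.5
    age_sd: float = 11.0
    age_range: tuple[float, float] = (18.0, 65.0)
    education_means: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "OCD": 13.0, "SZ": 12.4, "BD": 14.7, "MDD": 13.2, "HC": 16.0,
        }
    )
    education_sd: float = 3.4
    education_min: float = 5.0
    tiv_mean: float = 1420.0
    tiv_sd: float = 110.0
    tiv_male_shift: float = 80.0
    duration_means: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"OCD": 19.2, "SZ": 24.1, "BD": 12.0, "MDD": 9.6}
    )
    duration_sds: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"OCD": 12.3, "SZ": 9.0, "BD": 10.0, "MDD": 9.7}
    )
    cpz_means: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"OCD": 61.0, "SZ": 118.5, "BD": 81.0, "MDD": 23.2}
    )
    cpz_sds: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"OCD": 60.0, "SZ": 100.0, "BD": 70.0, "MDD": 30.0}
    )


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Full description of a synthetic cohort.

    ``subject_field_sd`` is the pointwise SD of each subject's smooth
    log-thickness modulation field (about a 10% regional coefficient of
    variation at the default); ``tiv_log_coef`` couples log-thickness to
    the subject's standardized intracranial volume (the head-size effect
    the TIV covariate adjusts out); ``point_noise_sd`` is isotropic
    per-vertex tracing noise in mm.
    """

    n_per_group: int = 30
    groups: Sequence[str] = DEFAULT_GROUPS
    n_points: int = 100
    template: TemplateParams = TemplateParams()
    arch: ArchParams = ArchParams()
    n_vertices: int = 120
    subject_field_sd: float = 0.10
    subject_field_modes: int = 4
    tiv_log_coef: float = 0.08
    point_noise_sd: float = 0.10
    covariates: CovariateModel = CovariateModel()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.subject_field_sd < 0 or self.point_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclasses.dataclass(frozen=True)
class EffectMap:
    """Per-group multiplicative half-thickness factors over positions.

    Controls are always at 1.0; factors must be strictly positive.
    """

    factors: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        facs = {g: np.asarray(f, dtype=float) for g, f in self.factors.items()}
        for g, f in facs.items():
            if np.any(f <= 0):
                raise ValueError(f"group {g!r}: effect factors must be > 0")
        hc = facs.get(CONTROL_LABEL)
        if hc is not None and not np.allclose(hc, 1.0):
            raise ValueError("control group factors must all be 1.0")
        object.__setattr__(self, "factors", facs)

    def for_group(self, group: str, n_points: int) -> np.ndarray:
        f = self.factors.get(group)
        if f is None:
            return np.ones(n_points)
        if len(f) != n_points:
            raise ValueError(
                f"effect map for {group!r} has {len(f)} positions, expected {n_points}"
            )
        return f


def template_profile(
    n_points: int = 100, params: TemplateParams = TemplateParams()
) -> np.ndarray:
    """Baseline half-thickness (mm) at ``n_points`` uniform arc positions.

    Strictly positive and smooth, with local maxima in the anterior and
    posterior fifths (genu, splenium) and a minimum over the middle fifth
    under default parameters.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    t = np.linspace(0.0, 1.0, n_points)
    p = params
    shape = (
        p.base_mm
        + p.genu_amp_mm * np.exp(-(((t - p.genu_center) / p.genu_width) ** 2))
        + p.splenium_amp_mm * np.exp(-(((t - p.splenium_center) / p.splenium_width) ** 2))
        - p.body_dip_mm * np.exp(-(((t - p.body_center) / p.body_width) ** 2))
        - p.tip_drop_mm * (np.exp(-((t / p.tip_width) ** 2))
                           + np.exp(-(((1.0 - t) / p.tip_width) ** 2)))
    )
    h = p.amplitude * shape
    if np.any(h <= 0):
        raise ValueError("template parameters yield non-positive half-thickness")
    return h


def _arch_centerline(arch: ArchParams, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centerline points and outward unit normals on the circular arc.

    ``t`` in [0, 1] is exactly the arc-length fraction (constant speed on a
    circle). Anterior end at t = 0, x = 0.
    """
    S, H = arch.span_mm, arch.height_mm
    R = S**2 / (8.0 * H) + H / 2.0
    phi = np.arcsin(S / (2.0 * R))
    alpha = -phi + 2.0 * phi * t          # signed angle from apex
    cx, cy = S / 2.0, H - R               # circle center
    normals = np.column_stack([np.sin(alpha), np.cos(alpha)])
    points = np.column_stack([cx + R * np.sin(alpha), cy + R * np.cos(alpha)])
    return points, normals


def smooth_log_field(
    rng: np.random.Generator,
    n_points: int,
    pointwise_sd: float,
    n_modes: int = 4,
) -> np.ndarray:
    """A smooth zero-mean random field over positions (log-thickness units).

    Sum of ``n_modes`` random-phase cosine modes scaled so the pointwise SD
    equals ``pointwise_sd``; low mode numbers keep the field smooth along
    the midline while distant positions stay only weakly correlated.
    """
    t = np.linspace(0.0, 1.0, n_points)
    if pointwise_sd == 0 or n_modes == 0:
        # consume no randomness only when the field is disabled entirely
        return np.zeros(n_points)
    amps = rng.normal(0.0, 1.0, n_modes)
    phases = rng.uniform(0.0, 2.0 * np.pi, n_modes)
    field = np.zeros(n_points)
    for k in range(1, n_modes + 1):
        field += amps[k - 1] * np.cos(np.pi * k * t + phases[k - 1])
    return pointwise_sd * np.sqrt(2.0 / n_modes) * field


def synth_contour_pair(
    template: np.ndarray,
    effect: np.ndarray,
    subject_scale: float | np.ndarray = 1.0,
    point_noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    arch: ArchParams = ArchParams(),
    n_vertices: int = 120,
    subject_id: str = "synthetic",
    max_retries: int = 10,
) -> ContourPair:
    """Build one subject's noisy contour pair from template and effect map.

    ``subject_scale`` may be a scalar (global size factor) or a per-position
    array (regionally varying factor). The returned pair always passes
    :func:`validate_contour_pair` with no errors; if the noise draw produces
    a degenerate polyline the noise is redrawn up to ``max_retries`` times
    before raising.
    """
    template = np.asarray(template, float)
    effect = np.asarray(effect, float)
    scale = np.broadcast_to(np.asarray(subject_scale, float), template.shape)
    if template.shape != effect.shape:
        raise ValueError("template and effect must have the same length")
    if rng is None:
        rng = np.random.default_rng()
    t_dense = np.linspace(0.0, 1.0, n_vertices)
    t_template = np.linspace(0.0, 1.0, len(template))
    h = np.interp(t_dense, t_template, scale * effect * template)
    center, normals = _arch_centerline(arch, t_dense)
    upper_clean = center + h[:, None] * normals
    lower_clean = center - h[:, None] * normals

    last_report = None
    for _ in range(max_retries + 1):
        noise_u = rng.normal(0.0, point_noise_sd, upper_clean.shape)
        noise_l = rng.normal(0.0, point_noise_sd, lower_clean.shape)
        pair = ContourPair(
            subject_id,
            Polyline(upper_clean + noise_u),
            Polyline(lower_clean + noise_l),
        )
        last_report = validate_contour_pair(pair)
        if last_report.ok:
            return pair
    raise RuntimeError(
        f"could not generate a valid contour pair after {max_retries} retries: "
        + "; ".join(last_report.errors)
    )


def _window_mask(n_points: int, window: tuple[int, int]) -> np.ndarray:
    lo, hi = window
    pos = np.arange(1, n_points + 1)
    return (pos >= lo) & (pos <= hi)


def preset_effectmaps(
    n_points: int = 100,
    thinning: float = DEFAULT_THINNING,
    rostrum: tuple[int, int] = ROSTRUM_WINDOW,
    isthmus: tuple[int, int] = ISTHMUS_WINDOW,
    middle_body: tuple[int, int] = MIDDLE_BODY_WINDOW,
) -> Dict[str, EffectMap]:
    """Named effect presets.

    ``null``: no group effects. ``ocd_global``: OCD thinned everywhere
    except the middle-body window. ``sz_focal``: SZ thinned only in the
    rostrum and isthmus windows. ``paper_like``: both combined, mood
    disorder groups null — the qualitative pattern of widespread
    obsessive-compulsive thinning, focal schizophrenia thinning, and intact
    mood-disorder anatomy.
    """
    ones = np.ones(n_points)
    ocd = np.full(n_points, thinning)
    ocd[_window_mask(n_points, middle_body)] = 1.0
    sz = ones.copy()
    sz[_window_mask(n_points, rostrum) | _window_mask(n_points, isthmus)] = thinning
    return {
        "null": EffectMap({}),
        "ocd_global": EffectMap({"OCD": ocd}),
        "sz_focal": EffectMap({"SZ": sz}),
        "paper_like": EffectMap({"OCD": ocd.copy(), "SZ": sz.copy()}),
    }


def injected_positions(effects: EffectMap, group: str, n_points: int) -> np.ndarray:
    """1-based positions where a group's effect factor differs from 1."""
    f = effects.for_group(group, n_points)
    return np.flatnonzero(f != 1.0) + 1


def _truncated_normal(
    rng: np.random.Generator, mean, sd, low, high, size
) -> np.ndarray:
    """Normal draw with resampling into [low, high] (clipped as last resort)."""
    out = rng.normal(mean, sd, size)
    for _ in range(50):
        bad = (out < low) | (out > high)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.clip(out, low, high)


def simulate_cohort(
    config: SimulationConfig = SimulationConfig(),
    effects: Optional[EffectMap] = None,
) -> tuple[list[ContourPair], list[SubjectRecord]]:
    """Simulate a full matched cohort of contour pairs and subject records.

    One age vector is drawn and shared across groups subject-for-subject
    (exact age matching); sex alternates M/F within each group. Healthy
    controls have absent clinical covariates. Deterministic given
    ``config.seed``.
    """
    if effects is None:
        effects = EffectMap({})
    cov = config.covariates
    n = config.n_per_group
    groups = list(config.groups)

    root = np.random.SeedSequence(config.seed)
    cov_stream, *subject_streams = root.spawn(1 + n * len(groups))
    cov_rng = np.random.default_rng(cov_stream)

    ages = _truncated_normal(
        cov_rng, cov.age_mean, cov.age_sd, *cov.age_range, size=n
    )
    template = template_profile(config.n_points, config.template)

    pairs: list[ContourPair] = []
    records: list[SubjectRecord] = []
    stream_iter = iter(subject_streams)
    for g in groups:
        effect = effects.for_group(g, config.n_points)
        edu = _truncated_normal(
            cov_rng, cov.education_means.get(g, 13.0), cov.education_sd,
            cov.education_min, 30.0, size=n,
        )
        sexes = np.where(np.arange(n) % 2 == 0, "M", "F")
        tiv = cov_rng.normal(cov.tiv_mean, cov.tiv_sd, n) + np.where(
            sexes == "M", cov.tiv_male_shift, 0.0
        )
        if g == CONTROL_LABEL:
            durations = cpzs = [None] * n
        else:
            max_dur = np.maximum(ages - 18.0, 0.5)
            durations = np.minimum(
                _truncated_normal(
                    cov_rng, cov.duration_means.get(g, 12.0),
                    cov.duration_sds.get(g, 10.0), 0.0, 60.0, size=n,
                ),
                max_dur,
            )
            cpzs = _truncated_normal(
                cov_rng, cov.cpz_means.get(g, 50.0), cov.cpz_sds.get(g, 50.0),
                0.0, 2000.0, size=n,
            )
        z_tiv = (tiv - (cov.tiv_mean + cov.tiv_male_shift / 2.0)) / cov.tiv_sd
        for j in range(n):
            sid = f"{g}{j + 1:03d}"
            rng = np.random.default_rng(next(stream_iter))
            field = smooth_log_field(
                rng, config.n_points, config.subject_field_sd,
                config.subject_field_modes,
            )
            scale = np.exp(config.tiv_log_coef * z_tiv[j] + field)
            pairs.append(
                synth_contour_pair(
                    template, effect, scale, config.point_noise_sd, rng,
                    arch=config.arch, n_vertices=config.n_vertices,
                    subject_id=sid,
                )
            )
            records.append(
                SubjectRecord(
                    subject_id=sid,
                    diagnosis=g,
                    sex=str(sexes[j]),
                    age=float(ages[j]),
                    education=float(edu[j]),
                    tiv=float(tiv[j]),
                    illness_duration=None if durations[j] is None else float(durations[j]),
                    cpz=None if cpzs[j] is None else float(cpzs[j]),
                )
            )
    return pairs, records
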