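"""Parametric proximal-tibia generator, analytic prism oracle and cohorts.

No anatomical mesh repository ships with the package: every downstream
stage (plateau-plane recovery, oblique sectioning, tunnel measurement,
cohort statistics) is exercised on synthetic bones built here.

Two kinds of solids are produced:

* :func:`generate_tibia` lofts superellipse-like cortical outlines (with an
  anterior crest bump) from a flat articular plateau down the shaft, giving
  a watertight genus-0 surface together with exact ground-truth landmarks
  (plateau plane, PCL attachment centre, crest apex curve).
* :func:`prism_tibia` builds an extruded rectangular "tibia" whose tunnel
  geometry is known in closed form (:func:`prism_expected`), the
  hand-checkable oracle for the sectioning/entry/measurement chain.

:func:`sample_cohort` draws a study population (default 31 male / 32 female
knees, ages 18-49, heights 144-192 cm) whose latent skeletal scale is
coupled to height and sex so that the cohort reproduces the reported
morphometric correlation structure (height-TTL r around 0.6-0.75, weak
negative age effect, null BMI effect, 5-8 mm male-female TTL gap).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import trimesh
from scipy.optimize import brentq

from .geometry import AnatomicalFrame

__all__ = [
    "ShapeCoefficients",
    "TibiaParams",
    "GroundTruthLandmarks",
    "SubjectCovariates",
    "PopulationConfig",
    "GenerationError",
    "generate_tibia",
    "prism_tibia",
    "prism_expected",
    "PrismSpec",
    "sample_cohort",
    "observer_jitter",
    "jitter_points",
    "mirror_x",
]

DEFAULT_ANGLE_SET = (40.0, 45.0, 50.0, 55.0, 60.0)


class GenerationError(ValueError):
    """Raised when shape parameters produce a degenerate solid."""


@dataclass(frozen=True)
class ShapeCoefficients:
    """Dimensionless coefficients of the cortical outline loft.

    ``superellipse_exponent`` controls corner squareness of the transverse
    outline; ``shaft_fraction`` is the asymptotic shaft/plateau width ratio;
    ``taper_length_frac`` sets the metaphyseal taper e-folding length as a
    fraction of the plateau AP depth; ``crest_width_rad`` is the angular
    half-width of the anterior crest bump.
    """

    superellipse_exponent: float = 2.5
    shaft_fraction: float = 0.30
    taper_length_frac: float = 0.80
    crest_width_rad: float = 0.55
    anterior_share: float = 0.52  # anterior fraction of the AP depth
    anterior_recession: float = 0.25  # mm of anterior retreat per mm of depth
    anterior_floor_frac: float = 0.25  # minimum anterior semi-depth fraction


@dataclass(frozen=True)
class TibiaParams:
    """Geometric parameters of one synthetic proximal tibia (lengths in mm)."""

    plateau_ml_width: float = 76.0
    plateau_ap_depth: float = 52.7
    posterior_slope: float = 7.0
    shaft_length: float = 150.0
    crest_ml_offset: float = 0.0
    crest_prominence: float = 4.6
    pcl_depth_below_plateau: float = 10.0
    pcl_ml_offset: float = 5.1
    cortical_outline_shape: ShapeCoefficients = field(default_factory=ShapeCoefficients)
    global_scale: float = 1.0
    side: Literal["right", "left"] = "right"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "plateau_ml_width",
            "plateau_ap_depth",
            "shaft_length",
            "crest_prominence",
            "global_scale",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.posterior_slope <= 20.0:
            raise ValueError("posterior_slope must lie in [0, 20] degrees")
        if not 0.0 < self.pcl_depth_below_plateau < 25.0:
            raise ValueError("pcl_depth_below_plateau must lie in (0, 25) mm")
        if self.side not in ("right", "left"):
            raise ValueError("side must be 'right' or 'left'")


@dataclass
class GroundTruthLandmarks:
    """Construction ground truth attached to a synthetic tibia."""

    plateau_point: np.ndarray
    plateau_normal: np.ndarray
    pcl_attachment: np.ndarray
    crest_apex_curve: np.ndarray
    frame: AnatomicalFrame
    side: Literal["right", "left"] = "right"

    @property
    def plateau_plane_true(self):
        return self.plateau_point, self.plateau_normal


@dataclass(frozen=True)
class SubjectCovariates:
    """Anthropomorphic covariates of one simulated patient."""

    sex: Literal["male", "female"]
    age: float
    height: float  # cm
    bmi: float  # kg/m^2
    knee_side: Literal["right", "left"] = "right"

    def __post_init__(self) -> None:
        if not 18 <= self.age <= 60:
            raise ValueError("age out of the 18-60 study range")
        if not 140 <= self.height <= 200:
            raise ValueError("height out of the 140-200 cm range")
        if not 15 <= self.bmi <= 35:
            raise ValueError("bmi out of the 15-35 range")


@dataclass(frozen=True)
class PopulationConfig:
    """Cohort sampling model.

    The latent skeletal scale of subject *i* is

        s_i = base(sex) * (1 + kappa * (h_i - h0)/h0
                             + age_effect * (age_i - 34) + eta_i)

    with ``kappa`` chosen so that corr(height, s) matches
    ``height_size_corr`` and ``eta`` absorbing the remaining anatomical
    variance up to ``scale_rel_sd``.  All TTL-relevant bone dimensions scale
    with ``s``; BMI is sampled independently (``bmi_effect`` = 0 reproduces
    the reported null BMI correlation).
    """

    n_male: int = 31
    n_female: int = 32
    height_size_corr: float = 0.74
    age_effect: float = -0.003  # relative scale per year
    bmi_effect: float = 0.0
    sex_scale_ratio: float = 1.086  # male/female mean skeletal scale
    scale_rel_sd: float = 0.065  # pooled relative SD of the latent scale
    noise_sd_mm: float = 0.8  # residual anatomical noise on local features
    seed: int = 0

    # population anchors (cm / years), matching the study cohort summary
    height_mean_male: float = 177.0
    height_mean_female: float = 158.2
    height_sd_within: float = 8.0
    height_ref: float = 167.4
    age_mean: float = 34.0
    age_sd: float = 8.0
    bmi_mean: float = 23.6
    bmi_sd: float = 3.7

    def __post_init__(self) -> None:
        if self.n_male < 0 or self.n_female < 0:
            raise ValueError("cohort sizes must be >= 0")
        if not -1 <= self.height_size_corr <= 1:
            raise ValueError("height_size_corr must lie in [-1, 1]")


# ---------------------------------------------------------------------------
# outline model


def _superellipse(theta: np.ndarray, rx: float, ry: float, n: float):
    c, s = np.cos(theta), np.sin(theta)
    x = rx * np.sign(c) * np.abs(c) ** (2.0 / n)
    y = ry * np.sign(s) * np.abs(s) ** (2.0 / n)
    return x, y


class _Loft:
    """Evaluates the transverse cortical outline of a parametric tibia."""

    def __init__(self, p: TibiaParams):
        g = p.global_scale
        sh = p.cortical_outline_shape
        self.rx0 = 0.5 * p.plateau_ml_width * g
        self.ry_a0 = sh.anterior_share * p.plateau_ap_depth * g
        self.ry_p0 = (1.0 - sh.anterior_share) * p.plateau_ap_depth * g
        self.ry0 = max(self.ry_a0, self.ry_p0)  # used only for bound checks
        self.n = sh.superellipse_exponent
        self.f = sh.shaft_fraction
        self.k_a = sh.anterior_recession  # linear anterior retreat (mm/mm)
        self.floor_a = sh.anterior_floor_frac * self.ry_a0
        self.lam = sh.taper_length_frac * p.plateau_ap_depth * g
        self.crest_amp = p.crest_prominence * g
        self.crest_w = sh.crest_width_rad
        self.slope_tan = math.tan(math.radians(p.posterior_slope))
        # crest apex azimuth: anterior point whose x equals the crest offset
        off = np.clip(p.crest_ml_offset * g, -0.5 * self.rx0, 0.5 * self.rx0)
        self.theta_crest = self._solve_theta_for_x(off, anterior=True)
        if self.crest_amp >= 0.9 * min(self.rx0, self.ry0):
            raise GenerationError("crest prominence too large for the outline")

    def _solve_theta_for_x(self, x_target: float, anterior: bool) -> float:
        lo, hi = (0.05 * np.pi, 0.95 * np.pi) if anterior else (1.05 * np.pi, 1.95 * np.pi)

        def fx(t):
            x, _ = _superellipse(np.asarray([t]), self.rx0, self.ry0, self.n)
            return float(x[0]) - x_target

        # x(theta) decreases over (0, pi) and increases over (pi, 2 pi)
        return brentq(fx, lo, hi, xtol=1e-12)

    def taper(self, z):
        return self.f + (1.0 - self.f) * np.exp(np.minimum(z, 0.0) / self.lam)

    def center(self, z):
        """Transverse-section centre: the shaft drifts anteriorly going
        distal, realising the posterior slope of the plateau."""
        z = np.asarray(z, dtype=float)
        return np.stack(
            [np.zeros_like(z), -self.slope_tan * z, z], axis=-1
        )

    def ry_anterior(self, z: float) -> float:
        return max(self.ry_a0 + self.k_a * min(z, 0.0), self.floor_a)

    def outline(self, theta: np.ndarray, z: float) -> np.ndarray:
        """(n, 3) outline points of the transverse section at height z.

        The posterior half tapers exponentially with the rest of the
        metaphysis; the anterior half recedes linearly with depth, the
        shape of the subcutaneous anterior cortex the crest rides on.
        """
        t = float(self.taper(z))
        x, y_pos = _superellipse(theta, self.rx0 * t, self.ry_p0 * t, self.n)
        _, y_ant = _superellipse(theta, self.rx0 * t, self.ry_anterior(z), self.n)
        y = np.where(np.sin(theta) >= 0.0, y_ant, y_pos)
        base = np.stack([x, y], axis=-1)
        r = np.linalg.norm(base, axis=-1)
        dtheta = np.angle(np.exp(1j * (theta - self.theta_crest)))
        bump = self.crest_amp * np.exp(-0.5 * (dtheta / self.crest_w) ** 2)
        pts2 = base * (1.0 + bump / np.maximum(r, 1e-9))[:, None]
        c = self.center(z)
        out = np.empty((len(theta), 3))
        out[:, 0] = pts2[:, 0] + c[0]
        out[:, 1] = pts2[:, 1] + c[1]
        out[:, 2] = z
        return out

    def crest_apex(self, z: float) -> np.ndarray:
        """Most anterior outline point at height z (dense search + refine)."""
        grid = np.linspace(self.theta_crest - 1.2, self.theta_crest + 1.2, 801)
        pts = self.outline(grid, z)
        k = int(np.argmax(pts[:, 1]))
        lo, hi = max(k - 1, 0), min(k + 1, len(grid) - 1)
        fine = np.linspace(grid[lo], grid[hi], 201)
        pts = self.outline(fine, z)
        return pts[int(np.argmax(pts[:, 1]))]


def _build_levels(shaft_length: float, d_exit: float, level_mm: float) -> np.ndarray:
    n = max(int(round(shaft_length / level_mm)), 8)
    z = np.linspace(0.0, -shaft_length, n + 1)
    # force an exact level at the PCL attachment depth
    k = int(np.argmin(np.abs(z + d_exit)))
    k = min(max(k, 1), len(z) - 2)
    z[k] = -d_exit
    return z


def generate_tibia(
    params: TibiaParams,
    level_mm: float = 2.0,
    n_theta: int = 128,
) -> tuple[trimesh.Trimesh, GroundTruthLandmarks]:
    """Loft a watertight synthetic proximal tibia with ground-truth landmarks.

    The articular plateau is the flat top cap at z = 0 (plateau plane
    normal +Z exactly); the shaft axis leans anteriorly by the posterior
    slope angle, so the dihedral between the true plateau normal and the
    shaft axis equals ``params.posterior_slope`` by construction.  The PCL
    attachment centre is an exact mesh vertex on the posterior cortex at
    ``pcl_depth_below_plateau`` mm below the plateau.

    ``level_mm`` / ``n_theta`` set the loft resolution (transverse level
    spacing and circumferential sample count).
    """
    loft = _Loft(params)
    g = params.global_scale
    d_exit = params.pcl_depth_below_plateau * g
    levels = _build_levels(params.shaft_length * g, d_exit, level_mm)

    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    # make the PCL azimuth an exact grid column so the attachment is a vertex
    # solve on the plateau outline for the azimuth whose x at depth d_exit
    # (where the outline is shrunk by taper) equals the requested ML offset
    theta_pcl = loft._solve_theta_for_x(
        float(np.clip(params.pcl_ml_offset * g, -0.4 * loft.rx0, 0.4 * loft.rx0))
        / float(loft.taper(-d_exit)),
        anterior=False,
    )
    theta = theta.copy()
    theta[int(np.argmin(np.abs(np.angle(np.exp(1j * (theta - theta_pcl))))))] = theta_pcl

    rings = [loft.outline(theta, z) for z in levels]
    verts = np.concatenate(rings, axis=0)
    n_lev = len(levels)

    faces = []
    for i in range(n_lev - 1):
        a = i * n_theta + np.arange(n_theta)
        b = (i + 1) * n_theta + np.arange(n_theta)
        a2, b2 = np.roll(a, -1), np.roll(b, -1)
        faces.append(np.stack([a, b, b2], axis=1))
        faces.append(np.stack([a, b2, a2], axis=1))
    # caps: triangle fans about ring centroids
    top_c = len(verts)
    verts = np.vstack([verts, rings[0].mean(axis=0)])
    bot_c = len(verts)
    verts = np.vstack([verts, rings[-1].mean(axis=0)])
    top = np.arange(n_theta)
    faces.append(np.stack([np.full(n_theta, top_c), top, np.roll(top, -1)], axis=1))
    bot = (n_lev - 1) * n_theta + np.arange(n_theta)
    faces.append(np.stack([np.full(n_theta, bot_c), np.roll(bot, -1), bot], axis=1))
    faces = np.concatenate(faces, axis=0)

    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:  # defensive: the winding above is outward already
        mesh.invert()
    if not mesh.is_watertight:
        raise GenerationError("generated surface is not watertight")

    k_level = int(np.flatnonzero(np.isclose(levels, -d_exit))[0])
    k_theta = int(np.flatnonzero(theta == theta_pcl)[0])
    pcl = rings[k_level][k_theta].copy()

    crest_z = np.linspace(0.0, -params.shaft_length * g, 60)
    crest_curve = np.stack([loft.crest_apex(z) for z in crest_z])

    frame = AnatomicalFrame()
    landmarks = GroundTruthLandmarks(
        plateau_point=np.zeros(3),
        plateau_normal=np.array([0.0, 0.0, 1.0]),
        pcl_attachment=pcl,
        crest_apex_curve=crest_curve,
        frame=frame,
        side=params.side,
    )
    if params.side == "left":
        mesh, landmarks = mirror_x(mesh, landmarks, new_side="left")
    return mesh, landmarks


def mirror_x(
    mesh: trimesh.Trimesh,
    landmarks: GroundTruthLandmarks,
    new_side: Literal["right", "left"],
) -> tuple[trimesh.Trimesh, GroundTruthLandmarks]:
    """Mirror a tibia (and its landmarks) across the sagittal x = 0 plane."""
    m = mesh.copy()
    m.vertices = m.vertices * np.array([-1.0, 1.0, 1.0])
    m.invert()
    flip = np.array([-1.0, 1.0, 1.0])
    lm = GroundTruthLandmarks(
        plateau_point=landmarks.plateau_point * flip,
        plateau_normal=landmarks.plateau_normal * flip,
        pcl_attachment=landmarks.pcl_attachment * flip,
        crest_apex_curve=landmarks.crest_apex_curve * flip,
        frame=landmarks.frame,
        side=new_side,
    )
    return m, lm


# ---------------------------------------------------------------------------
# analytic prism oracle


@dataclass(frozen=True)
class PrismSpec:
    """Extruded-box 'tibia' with a flat top plateau and flat anterior face."""

    half_width: float = 30.0  # x in [-half_width, half_width]
    y_anterior: float = 30.0
    y_posterior: float = -50.0
    depth: float = 160.0  # extends z in [-depth, 0]; holds sections up to ~64 deg
    exit_point: tuple[float, float, float] = (0.0, -40.0, -10.0)

    def __post_init__(self) -> None:
        ex, ey, ez = self.exit_point
        if not (-self.depth < ez < 0):
            raise ValueError("exit point must lie below the plateau inside the prism")
        if not (self.y_posterior <= ey <= self.y_anterior):
            raise ValueError("exit point outside the prism")


def prism_tibia(
    spec: PrismSpec = PrismSpec(), max_edge: float = 4.0
) -> tuple[trimesh.Trimesh, GroundTruthLandmarks]:
    """Subdivided box mesh realising :class:`PrismSpec`, plus landmarks."""
    ext = np.array(
        [2 * spec.half_width, spec.y_anterior - spec.y_posterior, spec.depth]
    )
    center = np.array(
        [0.0, 0.5 * (spec.y_anterior + spec.y_posterior), -0.5 * spec.depth]
    )
    box = trimesh.creation.box(extents=ext)
    box.apply_translation(center)
    box = box.subdivide_to_size(max_edge=max_edge)
    lm = GroundTruthLandmarks(
        plateau_point=np.array([0.0, center[1], 0.0]),
        plateau_normal=np.array([0.0, 0.0, 1.0]),
        pcl_attachment=np.asarray(spec.exit_point, dtype=float),
        crest_apex_curve=np.stack(
            [
                np.array([0.0, spec.y_anterior, 0.0]),
                np.array([0.0, spec.y_anterior, -spec.depth]),
            ]
        ),
        frame=AnatomicalFrame(),
        side="right",
    )
    return box, lm


def prism_expected(spec: PrismSpec, tta_deg: float, offset_mm: float = 20.0) -> dict:
    """Closed-form tunnel geometry on the prism (worked by trigonometry).

    The oblique section plane through the exit point E, inclined ``tta`` to
    the plateau with its hinge parallel to the ML axis and descending
    anteriorly, meets the anterior face y = y_a along the horizontal line
    z = z_c = E_z - (y_a - E_y) tan(tta).  The crest ("TTA") point is the
    mid-anterior point (0, y_a, z_c); the AM/AL entries sit ``offset_mm``
    medial/lateral along that line.  TTH is the entry depth below the
    plateau, TTL the entry-exit chord.
    """
    if not 0.0 < tta_deg < 90.0:
        raise ValueError("tta must lie in (0, 90) degrees")
    ex, ey, ez = spec.exit_point
    z_c = ez - (spec.y_anterior - ey) * math.tan(math.radians(tta_deg))
    if z_c < -spec.depth:
        raise ValueError("section exits below the prism; enlarge depth")
    crest = np.array([0.0, spec.y_anterior, z_c])
    am = np.array([-offset_mm, spec.y_anterior, z_c])
    al = np.array([offset_mm, spec.y_anterior, z_c])
    exit_pt = np.array([ex, ey, ez])
    return {
        "crest": crest,
        "entry_am": am,
        "entry_al": al,
        "ttl_am": float(np.linalg.norm(am - exit_pt)),
        "ttl_al": float(np.linalg.norm(al - exit_pt)),
        "tth": float(-z_c),
    }


# ---------------------------------------------------------------------------
# cohort sampling


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _pooled_height_sd(cfg: PopulationConfig) -> float:
    n = cfg.n_male + cfg.n_female
    wm = cfg.n_male / n if n else 0.5
    wf = 1.0 - wm
    mu = wm * cfg.height_mean_male + wf * cfg.height_mean_female
    var = (
        cfg.height_sd_within**2
        + wm * (cfg.height_mean_male - mu) ** 2
        + wf * (cfg.height_mean_female - mu) ** 2
    )
    return math.sqrt(var)


def _calibrate_scale_model(config: PopulationConfig) -> tuple[float, dict, float]:
    """Solve the latent-scale couplings from the configured targets.

    Returns ``(kappa, base_by_sex, eta_sd)`` such that the sampled scale
    s = base(sex) * (1 + kappa*(h - h0)/h0 + age_effect*(age - age0) + eta)
    has corr(height, s) = ``height_size_corr``, SD ``scale_rel_sd`` and
    male/female mean ratio ``sex_scale_ratio``.  The residual sex factor is
    itself height-correlated (through sex), so the exact first and second
    moments of the two-point sex mixture are used, with a short fixed point
    on the residual.
    """
    sigma_h = _pooled_height_sd(config)
    n_total = config.n_male + config.n_female
    wm = config.n_male / n_total if n_total else 0.5
    wf = 1.0 - wm
    h0 = config.height_ref
    mus = {"male": config.height_mean_male, "female": config.height_mean_female}
    ws = {"male": wm, "female": wf}
    deltas = {s: (mus[s] - h0) / h0 for s in mus}
    mean_h = wm * mus["male"] + wf * mus["female"]
    sw2 = config.height_sd_within**2
    age_var = (config.age_effect * config.age_sd) ** 2
    sigma_s = config.scale_rel_sd
    rho = config.height_size_corr

    kappa = rho * sigma_s * h0 / sigma_h
    base = {"male": 1.0, "female": 1.0}
    for _ in range(12):
        r_height = (1.0 + kappa * deltas["male"]) / (1.0 + kappa * deltas["female"])
        residual = config.sex_scale_ratio / r_height
        base = {"male": math.sqrt(residual), "female": 1.0 / math.sqrt(residual)}
        # cov(h, s) = C0 + kappa * C1 over the sex mixture
        c0 = sum(ws[s] * base[s] * mus[s] for s in ws) - mean_h * sum(
            ws[s] * base[s] for s in ws
        )
        c1 = sum(ws[s] * base[s] * (mus[s] * deltas[s] + sw2 / h0) for s in ws) - (
            mean_h * sum(ws[s] * base[s] * deltas[s] for s in ws)
        )
        kappa = max((rho * sigma_h * sigma_s - c0) / c1, 0.0)
    # variance of the structural part b*(1 + kappa*Delta)
    means = {s: base[s] * (1.0 + kappa * deltas[s]) for s in ws}
    ev = sum(ws[s] * means[s] for s in ws)
    ev2 = sum(
        ws[s] * (means[s] ** 2 + (base[s] * kappa) ** 2 * sw2 / h0**2) for s in ws
    )
    var_struct = ev2 - ev**2
    eb2 = sum(ws[s] * base[s] ** 2 for s in ws)
    eta_var = (sigma_s**2 - var_struct) / eb2 - age_var
    return kappa, base, math.sqrt(max(eta_var, 0.0))


def sample_cohort(
    config: PopulationConfig,
    base_params: TibiaParams | None = None,
) -> list[tuple[TibiaParams, SubjectCovariates]]:
    """Draw a seeded cohort of (bone parameters, covariates) pairs.

    Deterministic under ``config.seed``; per-subject randomness comes from
    counter-derived child seeds, never global state.
    """
    base = base_params if base_params is not None else TibiaParams()
    n = config.n_male + config.n_female
    if n == 0:
        return []
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31 - 1))
        for s in np.random.SeedSequence(config.seed).spawn(n)
    ]

    sexes = ["male"] * config.n_male + ["female"] * config.n_female
    kappa, base_by_sex, eta_sd = _calibrate_scale_model(config)

    cohort: list[tuple[TibiaParams, SubjectCovariates]] = []
    for i, sex in enumerate(sexes):
        h_mu = config.height_mean_male if sex == "male" else config.height_mean_female
        height = float(
            _truncated_normal(rng, h_mu, config.height_sd_within, 144.0, 198.0, 1)[0]
        )
        age = float(_truncated_normal(rng, config.age_mean, config.age_sd, 18.0, 49.0, 1)[0])
        bmi = float(_truncated_normal(rng, config.bmi_mean, config.bmi_sd, 15.9, 32.9, 1)[0])
        side = "right" if rng.random() < 0.5 else "left"

        scale = base_by_sex[sex] * (
            1.0
            + kappa * (height - config.height_ref) / config.height_ref
            + config.age_effect * (age - config.age_mean)
            + config.bmi_effect * (bmi - config.bmi_mean)
            + rng.normal(0.0, eta_sd)
        )
        scale = float(np.clip(scale, 0.6, 1.5))

        d_exit = float(
            np.clip(
                base.pcl_depth_below_plateau + rng.normal(0.0, config.noise_sd_mm) / max(scale, 1e-6),
                3.0,
                24.0,
            )
        )
        crest = float(
            max(base.crest_prominence + rng.normal(0.0, 0.5 * config.noise_sd_mm), 0.5)
        )
        slope = float(np.clip(rng.normal(base.posterior_slope, 1.0), 2.0, 14.0))
        ap_jitter = float(rng.normal(1.0, 0.015))

        params = replace(
            base,
            plateau_ap_depth=base.plateau_ap_depth * ap_jitter,
            posterior_slope=slope,
            crest_prominence=crest,
            pcl_depth_below_plateau=d_exit,
            global_scale=base.global_scale * scale,
            side=side,
            seed=child_seeds[i],
        )
        cov = SubjectCovariates(sex=sex, age=age, height=height, bmi=bmi, knee_side=side)
        cohort.append((params, cov))
    return cohort


# ---------------------------------------------------------------------------
# observer jitter


def jitter_points(points: np.ndarray, sigma_mm: float, rng) -> np.ndarray:
    """Isotropic Gaussian perturbation of one or more 3D points."""
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pts = np.asarray(points, dtype=float)
    return pts + rng.normal(0.0, sigma_mm, pts.shape)


def observer_jitter(
    landmarks: GroundTruthLandmarks, sigma_mm: float, seed: int
) -> GroundTruthLandmarks:
    """Simulated manual-marking variability on the PCL attachment point.

    Models one observer session: the clinically hand-placed landmark is
    displaced isotropically with SD ``sigma_mm`` per axis (RMS displacement
    sigma * sqrt(3)).  Reproducible under ``seed``; ``sigma_mm = 0`` is the
    identity.
    """
    rng = np.random.default_rng(seed)
    return GroundTruthLandmarks(
        plateau_point=landmarks.plateau_point.copy(),
        plateau_normal=landmarks.plateau_normal.copy(),
        pcl_attachment=jitter_points(landmarks.pcl_attachment, sigma_mm, rng),
        crest_apex_curve=landmarks.crest_apex_curve.copy(),
        frame=landmarks.frame,
        side=landmarks.side,
    )
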