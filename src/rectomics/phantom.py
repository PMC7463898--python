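"""Synthetic rectal-environment phantoms.

Generates tube-like wall/lumen geometries with class-dependent wall
thickness, thickness variability, lumen eccentricity and directional
intensity heterogeneity, so the whole feature-extraction and modeling
pipeline can be exercised and validated without patient data.

The phantom is deliberately schematic: each axial section carries an
elliptical lumen surrounded by an annular wall whose centre, radius,
thickness and orientation evolve smoothly along the rectum via first-order
autoregressive profiles.  Intensities are arbitrary units (the analysis
normalizes features, not intensities): a bright wall with a class-scaled
sinusoidal ripple along the in-plane x axis, a dark lumen, and Gaussian
noise everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import Mask, StudyCase, Volume

YPT_LOW = "ypT0-2"
YPT_HIGH = "ypT3-4"
CLASSES = (YPT_LOW, YPT_HIGH)


@dataclass(frozen=True)
class PhantomParams:
    """Study conditions for the phantom cohort.

    Per-class dictionaries are keyed by ``"ypT0-2"`` / ``"ypT3-4"``.  The
    defaults encode the hypothesized disease effects: non-regressed
    (ypT3-4) tumours have thicker, more variable rectal walls, more
    eccentric lumens and stronger directional gradient expression inside
    the wall.
    """

    n_sections: tuple[int, int] = (20, 60)      # per-case uniform draw
    section_shape: tuple[int, int] = (80, 80)   # pixels
    spacing: tuple[float, float, float] = (0.781, 0.781, 4.0)  # mm
    wall_thickness_mean: dict = field(
        default_factory=lambda: {YPT_LOW: 4.0, YPT_HIGH: 6.5})  # mm
    wall_thickness_sd: dict = field(
        default_factory=lambda: {YPT_LOW: 0.8, YPT_HIGH: 1.6})  # mm
    lumen_eccentricity_mean: dict = field(
        default_factory=lambda: {YPT_LOW: 0.45, YPT_HIGH: 0.65})
    lumen_eccentricity_sd: dict = field(
        default_factory=lambda: {YPT_LOW: 0.10, YPT_HIGH: 0.10})
    gradient_heterogeneity: dict = field(
        default_factory=lambda: {YPT_LOW: 6.0, YPT_HIGH: 12.0})  # ripple amplitude
    lumen_radius_mean: float = 8.0   # mm
    lumen_radius_sd: float = 0.8     # mm, along-z AR variation
    ripple_wavelength: float = 6.0   # mm, along in-plane x
    noise_sd: float = 4.0            # intensity units
    class_prevalence: float = 22 / 52  # fraction ypT0-2 (discovery cohort)
    seed: int = 0

    def __post_init__(self):
        for c in CLASSES:
            if self.wall_thickness_mean[c] <= 0:
                raise ValueError("wall thickness must be positive")
            if not (0 <= self.lumen_eccentricity_mean[c] < 1):
                raise ValueError("eccentricity mean must be in [0, 1)")
        if not (0 < self.class_prevalence < 1):
            raise ValueError("class prevalence must be in (0, 1)")

    def null(self) -> "PhantomParams":
        """Copy with identical parameters for both classes (no class effect)."""
        def same(d):
            m = (d[YPT_LOW] + d[YPT_HIGH]) / 2
            return {YPT_LOW: m, YPT_HIGH: m}
        return replace(
            self,
            wall_thickness_mean=same(self.wall_thickness_mean),
            wall_thickness_sd=same(self.wall_thickness_sd),
            lumen_eccentricity_mean=same(self.lumen_eccentricity_mean),
            lumen_eccentricity_sd=same(self.lumen_eccentricity_sd),
            gradient_heterogeneity=same(self.gradient_heterogeneity),
        )


@dataclass(frozen=True)
class EffectSpec:
    """Table-level effect injection used for parameter-recovery testing."""

    affected_feature_names: tuple[str, ...]
    effect_size_d: float = 1.5
    noise_feature_count: int = 0

    def __post_init__(self):
        if self.effect_size_d < 0:
            raise ValueError("effect size d must be >= 0")
        if self.noise_feature_count < 0:
            raise ValueError("noise feature count must be >= 0")


def _ar1(rng, n, mean, sd, rho=0.85):
    """Stationary AR(1) profile along the section axis."""
    x = np.empty(n)
    x[0] = rng.normal(0.0, 1.0)
    innov = rng.normal(0.0, 1.0, size=n - 1) if n > 1 else []
    for i in range(1, n):
        x[i] = rho * x[i - 1] + np.sqrt(1 - rho**2) * innov[i - 1]
    return mean + sd * x


def generate_phantom_case(params: PhantomParams, label: str,
                          case_seed: int, *, case_id: str | None = None,
                          institution: str = "inst1", field_T: float = 3.0,
                          sex: str = "M", cohort: str = "discovery") -> StudyCase:
    """Generate one phantom study case.

    Deterministic for fixed ``(params, label, case_seed)``.  Raises if the
    requested wall ring cannot fit inside ``section_shape``.
    """
    if label not in CLASSES:
        raise ValueError(f"unknown class label {label!r}")
    rng = np.random.default_rng([int(case_seed) & 0x7FFFFFFF, params.seed])
    nx, ny = params.section_shape
    dx, dy, dz = params.spacing
    lo, hi = params.n_sections
    nz = int(rng.integers(lo, hi + 1)) if hi > lo else int(lo)

    # --- longitudinal geometry profiles (physical mm) ---
    t_case = max(1.0, rng.normal(params.wall_thickness_mean[label],
                                 params.wall_thickness_sd[label] / 2))
    thickness = np.clip(
        _ar1(rng, nz, t_case, params.wall_thickness_sd[label] / 2), 1.0, None)
    radius = np.clip(
        _ar1(rng, nz, params.lumen_radius_mean, params.lumen_radius_sd), 3.0, None)
    ecc_case = float(np.clip(
        rng.normal(params.lumen_eccentricity_mean[label],
                   params.lumen_eccentricity_sd[label]), 0.0, 0.92))
    ecc = np.clip(_ar1(rng, nz, ecc_case, 0.03), 0.0, 0.95)
    cx = _ar1(rng, nz, 0.0, 1.2, rho=0.9)
    cy = _ar1(rng, nz, 0.0, 1.2, rho=0.9)
    phi = _ar1(rng, nz, rng.uniform(0, np.pi), 0.1, rho=0.9)

    # --- rasterize masks ---
    xs = (np.arange(nx) - (nx - 1) / 2) * dx
    ys = (np.arange(ny) - (ny - 1) / 2) * dy
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    lumen = np.zeros((nx, ny, nz), dtype=bool)
    wall = np.zeros((nx, ny, nz), dtype=bool)
    half_extent = min(nx * dx, ny * dy) / 2
    for s in range(nz):
        shrink = (1 - ecc[s] ** 2) ** 0.25
        a, b = radius[s] / shrink, radius[s] * shrink
        ao, bo = a + thickness[s], b + thickness[s]
        if max(ao, bo) + max(abs(cx[s]), abs(cy[s])) >= half_extent - 1.0:
            raise ValueError(
                "section_shape too small to contain wall ring "
                f"(outer semi-axis {max(ao, bo):.1f} mm at section {s}, "
                f"half-extent {half_extent:.1f} mm)")
        u = (xx - cx[s]) * np.cos(phi[s]) + (yy - cy[s]) * np.sin(phi[s])
        v = -(xx - cx[s]) * np.sin(phi[s]) + (yy - cy[s]) * np.cos(phi[s])
        in_lumen = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        in_outer = (u / ao) ** 2 + (v / bo) ** 2 <= 1.0
        lumen[:, :, s] = in_lumen
        wall[:, :, s] = in_outer & ~in_lumen

    # --- primary treated tumour sub-span (contiguous, >= 3 sections) ---
    span_len = int(rng.integers(4, min(9, nz) + 1)) if nz >= 4 else nz
    start_max = nz - span_len
    mid = start_max // 2
    start = int(np.clip(mid + rng.integers(-2, 3), 0, start_max))
    primary = np.zeros_like(wall)
    primary[:, :, start:start + span_len] = wall[:, :, start:start + span_len]

    # --- intensities ---
    amp = params.gradient_heterogeneity[label]
    phase = rng.uniform(0, 2 * np.pi)
    ripple2d = amp * np.sin(2 * np.pi * xx / params.ripple_wavelength + phase)
    vol = np.full((nx, ny, nz), 50.0)
    vol[lumen] = 25.0
    wall_val = 100.0 + ripple2d[..., None] * np.ones((1, 1, nz))
    vol[wall] = wall_val[wall]
    # mild in-plane blur emulates partial-volume softening at interfaces
    vol = ndimage.gaussian_filter(vol, sigma=(0.6, 0.6, 0.0))
    if params.noise_sd > 0:
        vol = vol + rng.normal(0.0, params.noise_sd, size=vol.shape)

    cid = case_id or f"case{case_seed:08d}"
    return StudyCase(
        case_id=cid,
        volume=Volume(vol, spacing=params.spacing),
        wall=Mask(wall, "entire_wall", spacing=params.spacing),
        lumen=Mask(lumen, "lumen", spacing=params.spacing),
        primary=Mask(primary, "primary_tumor", spacing=params.spacing),
        ypT_group=label, institution=institution, field_T=field_T,
        sex=sex, cohort=cohort,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Validation-cohort prevalence of ypT0-2 (16 of 42 hold-out studies).
VALIDATION_PREVALENCE = 16 / 42


def _institution_plan(n_validation, rng):
    """Split validation cases over two external institutions with a mix of
    field strengths (inst2 predominantly 1.5 T, inst3 predominantly 3 T)."""
    n2 = int(round(n_validation * 31 / 42))
    plan = []
    for i in range(n_validation):
        if i < n2:
            inst, p3 = "inst2", 3 / 31
        else:
            inst, p3 = "inst3", 8 / 11
        field = 3.0 if rng.random() < p3 else 1.5
        plan.append((inst, field))
    return plan


def generate_cohorts(params: PhantomParams, n_discovery: int = 52,
                     n_validation: int = 42, seed: int = 0,
                     prevalence_discovery: float | None = None,
                     prevalence_validation: float | None = None,
                     ) -> tuple[list[StudyCase], list[StudyCase]]:
    """Generate discovery and hold-out validation phantom cohorts.

    Case ids are disjoint across cohorts; validation cases carry distinct
    institution labels and a mix of 1.5/3.0 T field-strength tags; class
    counts match ``round(prevalence * n)``.
    """
    if n_discovery <= 0 or n_validation <= 0:
        raise ValueError("cohort sizes must be positive")
    p_d = params.class_prevalence if prevalence_discovery is None else prevalence_discovery
    p_v = VALIDATION_PREVALENCE if prevalence_validation is None else prevalence_validation
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 7919])

    def make(n, prev, cohort, prefix, meta_fn):
        n_low = int(round(prev * n))
        labels = np.array([YPT_LOW] * n_low + [YPT_HIGH] * (n - n_low))
        rng.shuffle(labels)
        cases = []
        for i, lab in enumerate(labels):
            inst, fld = meta_fn(i)
            sex = "M" if rng.random() < (30 / 52 if cohort == "discovery"
                                         else 31 / 42) else "F"
            if inst == "inst3":
                sex = "M"  # the VA cohort is all-male
            cs = int(rng.integers(0, 2**31))
            cases.append(generate_phantom_case(
                params, str(lab), cs, case_id=f"{prefix}{i + 1:03d}",
                institution=inst, field_T=fld, sex=sex, cohort=cohort))
        return cases

    disc = make(n_discovery, p_d, "discovery", "D",
                lambda i: ("inst1", 3.0 if rng.random() < 51 / 52 else 1.5))
    plan = _institution_plan(n_validation, rng)
    val = make(n_validation, p_v, "validation", "V", lambda i: plan[i])
    return disc, val


# ---------------------------------------------------------------------------
# Feature-level effect injection (parameter-recovery plumbing)
# ---------------------------------------------------------------------------

def inject_feature_effects(table, spec: EffectSpec, seed: int = 0):
    """Shift named features by ``d`` pooled-SD units for the ypT3-4 class
    and append pure-noise columns.

    Returns a new :class:`~rectomics.features.FeatureTable`; the input is
    not modified.
    """
    from .features import FeatureTable

    df = table.data.copy()
    missing = [f for f in spec.affected_feature_names if f not in df.columns]
    if missing:
        raise KeyError(f"unknown feature name(s): {missing}")
    labels = table.labels
    hi = (labels == YPT_HIGH).to_numpy()
    n1, n2 = int(hi.sum()), int((~hi).sum())
    for name in spec.affected_feature_names:
        x = df[name].to_numpy(dtype=float)
        s1 = x[hi].var(ddof=1) if n1 > 1 else 0.0
        s2 = x[~hi].var(ddof=1) if n2 > 1 else 0.0
        pooled = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / max(n1 + n2 - 2, 1))
        if pooled == 0:
            pooled = 1.0
        x[hi] = x[hi] + spec.effect_size_d * pooled
        df[name] = x
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 104729])
    for j in range(spec.noise_feature_count):
        df[f"noise.{j:03d}"] = rng.normal(size=len(df))
    return FeatureTable(data=df, meta=table.meta.copy(),
                        normalization=table.normalization)


def perturb_annotations(case: StudyCase, seed: int = 0,
                        shift_sd: float = 0.7, morph_p: float = 0.6):
    """Emulate a second expert annotation by jittering the wall and lumen
    masks (per-section subpixel shift plus random dilation/erosion).

    Returns ``(wall2, lumen2)`` with lumen re-subtracted from the wall so
    the nesting invariant still holds.
    """
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 15485863])
    out = {}
    for m in (case.wall, case.lumen):
        v = m.voxels.copy()
        nz = v.shape[2]
        for s in range(nz):
            sec = v[:, :, s]
            if not sec.any():
                continue
            shift = rng.normal(0, shift_sd, size=2).round().astype(int)
            sec = np.roll(np.roll(sec, shift[0], axis=0), shift[1], axis=1)
            r = rng.random()
            if r < morph_p / 2:
                sec = ndimage.binary_dilation(sec)
            elif r < morph_p:
                sec = ndimage.binary_erosion(sec)
            v[:, :, s] = sec
        out[m.role] = v
    lumen2 = out["lumen"]
    wall2 = out["entire_wall"] & ~lumen2
    if not wall2.any() or not lumen2.any():  # degenerate perturbation
        return case.wall, case.lumen
    return (Mask(wall2, "entire_wall", spacing=case.wall.spacing),
            Mask(lumen2, "lumen", spacing=case.lumen.spacing))
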