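"""Synthetic OCTA phantoms: vascular networks with known ground truth.

A phantom emulates a macula-centered en-face angiogram: bright curvilinear
vessels radiating (and branching) from the fovea across a dark background,
a central avascular zone with a controllable, irregularly perturbed
boundary, multiplicative speckle noise and a smooth illumination ramp.

Vessel centerlines are sinusoid-perturbed radial curves, so each one has a
closed-form parameterization whose arc (geodesic) and chord lengths are
known to quadrature precision — giving analytic tortuosity ground truth.
Disease-stage cohorts are generated by ordinal ramps of the generator
parameters: with severity, tortuosity amplitude, caliber, FAZ size and
boundary irregularity go up while vessel count goes down.  The sickle-cell
profiles push tortuosity hardest; the diabetic profiles push vessel loss
and FAZ enlargement, mirroring the different vascular signatures of the
two diseases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import AngiogramImage

LABELS = (
    "control", "mild_npdr", "moderate_npdr", "severe_npdr",
    "mild_scr", "severe_scr",
)


@dataclass(frozen=True)
class PhantomSpec:
    """Generator parameters for one SCP/DCP phantom pair.

    ``tortuosity_amp`` is the sinusoid amplitude in pixels applied
    perpendicular to each vessel's radial course; 0 gives straight
    vessels.  ``faz_irregularity`` is the relative amplitude of the FAZ
    boundary perturbation; 0 gives a circle.
    """

    image_px: int = 304
    fov_mm: float = 6.0
    n_vessels: int = 90
    tortuosity_amp: float = 1.0
    vessel_radius_px: float = 1.6
    faz_radius_mm: float = 0.25
    faz_irregularity: float = 0.05
    noise_sigma: float = 0.10
    bias_strength: float = 0.15
    branch_prob: float = 0.8
    seed: int = 0

    def __post_init__(self):
        for name in ("tortuosity_amp", "faz_irregularity", "noise_sigma",
                     "bias_strength", "vessel_radius_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.faz_radius_mm < self.fov_mm / 2:
            raise ValueError("faz_radius_mm must lie in (0, fov_mm/2)")
        if self.n_vessels < 1:
            raise ValueError("n_vessels must be >= 1")

    @property
    def mm_per_pixel(self) -> float:
        return self.fov_mm / self.image_px


@dataclass
class Centerline:
    """One vessel centerline with analytic length ground truth."""

    points: np.ndarray  # (n, 2) float (row, col)
    geodesic_px: float
    chord_px: float

    @property
    def tortuosity(self) -> float:
        return self.geodesic_px / self.chord_px if self.chord_px > 0 else np.inf


@dataclass
class PhantomTruth:
    """Ground truth accompanying one generated phantom pair (SCP layer)."""

    vessel_mask: np.ndarray
    faz_mask: np.ndarray
    centerlines: list[Centerline]
    spec: PhantomSpec


_FAZ_HARMONICS = ((2, 0.5), (3, 0.35), (5, 0.15))


def _faz_boundary_radius(phi: np.ndarray, radius_px: float,
                         irregularity: float, phases) -> np.ndarray:
    """Perturbed FAZ boundary radius as a function of polar angle."""
    r = np.ones_like(phi)
    for (k, w), ph in zip(_FAZ_HARMONICS, phases):
        r = r + irregularity * w * np.sin(k * phi + ph)
    return radius_px * r


def _vessel_curve(rng, center, r_start, r_end, amp, n_samples=400):
    """Sinusoid-perturbed radial curve; returns points and analytic lengths."""
    theta = rng.uniform(0, 2 * np.pi)
    # narrow frequency jitter: tortuosity scales with (amp * freq)^2, so a
    # wide frequency band would drown the amplitude dial in geometry noise
    freq = rng.uniform(4.5, 5.5)
    phase = rng.uniform(0, 2 * np.pi)
    return _curve_from(center, theta, r_start, r_end, amp, freq, phase, n_samples)


def _curve_from(center, theta, r_start, r_end, amp, freq, phase, n_samples):
    t = np.linspace(0.0, 1.0, n_samples)
    r = r_start + t * (r_end - r_start)
    off = amp * np.sin(2 * np.pi * freq * t + phase)
    d_rad = np.array([np.cos(theta), np.sin(theta)])
    d_tan = np.array([-np.sin(theta), np.cos(theta)])
    pts = center + np.outer(r, d_rad) + np.outer(off, d_tan)
    seglen = np.hypot(*np.diff(pts, axis=0).T)
    geodesic = float(seglen.sum())
    chord = float(np.hypot(*(pts[-1] - pts[0])))
    return pts, geodesic, chord


def _rasterize(curves, shape, radius_px):
    canvas = np.zeros(shape, dtype=bool)
    for pts in curves:
        # dense samples: consecutive points < 1 px apart, so rounding connects
        dense = _densify(pts)
        rr = np.clip(np.round(dense[:, 0]).astype(int), 0, shape[0] - 1)
        cc = np.clip(np.round(dense[:, 1]).astype(int), 0, shape[1] - 1)
        inside = (dense[:, 0] > -0.5) & (dense[:, 0] < shape[0] - 0.5) & \
                 (dense[:, 1] > -0.5) & (dense[:, 1] < shape[1] - 0.5)
        canvas[rr[inside], cc[inside]] = True
    if not canvas.any():
        return canvas, np.full(shape, np.inf)
    dist = ndimage.distance_transform_edt(~canvas)
    return dist <= radius_px, dist


def _densify(pts: np.ndarray) -> np.ndarray:
    steps = np.hypot(*np.diff(pts, axis=0).T)
    if steps.max() <= 0.7:
        return pts
    n = int(np.ceil(steps.max() / 0.5))
    t = np.linspace(0, 1, len(pts))
    tt = np.linspace(0, 1, len(pts) * max(2, n))
    return np.column_stack([np.interp(tt, t, pts[:, 0]),
                            np.interp(tt, t, pts[:, 1])])


def _render_layer(spec: PhantomSpec, rng: np.random.Generator,
                  n_vessels: int, radius_px: float):
    """Draw one plexus: returns (image float array, vessel mask, centerlines,
    faz mask)."""
    n = spec.image_px
    center = np.array([(n - 1) / 2.0, (n - 1) / 2.0])
    faz_radius_px = spec.faz_radius_mm / spec.mm_per_pixel

    # FAZ mask from the perturbed polar boundary
    rr, cc = np.mgrid[0:n, 0:n]
    dr, dc = rr - center[0], cc - center[1]
    dist = np.hypot(dr, dc)
    phi = np.arctan2(dr, dc)
    faz_phases = rng.uniform(0, 2 * np.pi, size=len(_FAZ_HARMONICS))
    boundary = _faz_boundary_radius(phi, faz_radius_px, spec.faz_irregularity,
                                    faz_phases)
    faz_mask = dist < boundary

    max_boundary = faz_radius_px * (1 + 1.0 * spec.faz_irregularity)
    r_start = max_boundary + radius_px + 2.0
    r_end = (n / 2.0) * np.sqrt(2.0) + 4.0
    if r_start >= r_end:
        raise ValueError("FAZ too large: vessels cannot avoid it")

    curves: list[Centerline] = []
    pts_list = []
    # parafoveal capillary ring: a closed vessel bordering the FAZ, as in
    # real retinas; it also gives the avascular zone a well-defined rim
    phi_ring = np.linspace(0, 2 * np.pi, 720)
    r_ring = _faz_boundary_radius(phi_ring, faz_radius_px,
                                  spec.faz_irregularity, faz_phases) \
        + radius_px + 1.5
    ring = np.column_stack([center[0] + r_ring * np.sin(phi_ring),
                            center[1] + r_ring * np.cos(phi_ring)])
    pts_list.append(ring)
    # a limited set of primaries leaves the FAZ rim; the rest start at
    # staggered radii so the perifovea is a mesh, not a merged plate.
    # Angles and start radii are stratified (even grid plus jitter): a
    # plexus tiles its territory, and stratification keeps the per-region
    # vessel count tightly coupled to n_vessels instead of Binomial noise.
    n_primary = min(n_vessels, max(8, int(round(0.18 * n_vessels))))
    n_secondary = n_vessels - n_primary
    prim_angles = (2 * np.pi * (np.arange(n_primary)
                                + rng.uniform(-0.25, 0.25, n_primary))
                   / max(n_primary, 1))
    if n_secondary:
        sec_angles = (2 * np.pi * (np.arange(n_secondary)
                                   + rng.uniform(-0.35, 0.35, n_secondary))
                      / n_secondary)
        sec_angles = rng.permutation(sec_angles)
        sec_starts = (r_start + 8.0
                      + (0.75 * r_end - r_start - 8.0)
                      * (np.arange(n_secondary) + rng.uniform(0, 1, n_secondary))
                      / n_secondary)
    for i in range(n_vessels):
        if i < n_primary:
            r0, theta = r_start, float(prim_angles[i])
        else:
            r0 = float(sec_starts[i - n_primary])
            theta = float(sec_angles[i - n_primary])
        pts, geo, chord = _curve_from(
            center, theta, r0, r_end, spec.tortuosity_amp,
            rng.uniform(4.5, 5.5), rng.uniform(0, 2 * np.pi), 400,
        )
        curves.append(Centerline(pts, geo, chord))
        pts_list.append(pts)
        if rng.uniform() < spec.branch_prob:
            # child branch from mid-course, deviated radial direction
            t0 = rng.uniform(0.25, 0.6)
            i0 = int(t0 * (len(pts) - 1))
            origin = pts[i0]
            base_theta = np.arctan2(origin[1] - center[1], origin[0] - center[0])
            theta = base_theta + rng.uniform(0.12, 0.45) * rng.choice([-1, 1])
            r_off = float(np.hypot(*(origin - center)))
            cpts, cgeo, cchord = _curve_from(
                origin - r_off * np.array([np.cos(theta), np.sin(theta)]),
                theta, r_off, r_end, spec.tortuosity_amp,
                rng.uniform(4.5, 5.5), rng.uniform(0, 2 * np.pi),
                n_samples=300,
            )
            curves.append(Centerline(cpts, cgeo, cchord))
            pts_list.append(cpts)

    vessel_mask, dist_to_vessel = _rasterize(pts_list, (n, n), radius_px)
    vessel_mask &= ~faz_mask

    # soft-edged bright vessels on a dim background
    profile = np.exp(-np.maximum(dist_to_vessel - radius_px, 0.0) ** 2 / (2 * 0.8**2))
    profile[faz_mask] = 0.0
    img = 0.12 + 0.82 * profile
    img = img * (1.0 + spec.noise_sigma * rng.standard_normal((n, n)))
    ramp = 1.0 + spec.bias_strength * ((cc / (n - 1)) - 0.5)
    img = np.clip(img * ramp, 0.0, None)
    return img, vessel_mask, curves, faz_mask


def generate_phantom(spec: PhantomSpec):
    """Generate one SCP/DCP pair plus ground truth; seed-deterministic.

    The DCP is rendered from an independent sub-seed with denser, finer
    vessels, as in real angiograms where the deep plexus is a fine
    capillary mesh.
    """
    rng_s = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    rng_d = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))

    img_s, vmask, curves, faz = _render_layer(
        spec, rng_s, spec.n_vessels, spec.vessel_radius_px
    )
    img_d, *_ = _render_layer(
        spec, rng_d, int(spec.n_vessels * 1.35), spec.vessel_radius_px * 0.75
    )
    scp = AngiogramImage(img_s, layer="SCP", fov_mm=spec.fov_mm)
    dcp = AngiogramImage(img_d, layer="DCP", fov_mm=spec.fov_mm)
    truth = PhantomTruth(vessel_mask=vmask, faz_mask=faz,
                         centerlines=curves, spec=spec)
    return scp, dcp, truth


# ---------------------------------------------------------------------------
# stage-parameterized cohorts

#: Ordinal parameter ramps per diagnostic group.  With severity, tortuosity
#: amplitude, caliber and FAZ size/irregularity increase while the vessel
#: count decreases; the SCR branch is tortuosity-dominant, the DR branch
#: dropout/FAZ-dominant.
DEFAULT_PROFILES: dict[str, dict] = {
    "control":       dict(n_vessels=90, tortuosity_amp=1.0, vessel_radius_px=1.6,
                          faz_radius_mm=0.25, faz_irregularity=0.05),
    "mild_npdr":     dict(n_vessels=76, tortuosity_amp=1.4, vessel_radius_px=1.7,
                          faz_radius_mm=0.31, faz_irregularity=0.12),
    "moderate_npdr": dict(n_vessels=62, tortuosity_amp=1.8, vessel_radius_px=1.8,
                          faz_radius_mm=0.37, faz_irregularity=0.20),
    "severe_npdr":   dict(n_vessels=48, tortuosity_amp=2.2, vessel_radius_px=1.9,
                          faz_radius_mm=0.44, faz_irregularity=0.28),
    "mild_scr":      dict(n_vessels=80, tortuosity_amp=3.5, vessel_radius_px=1.8,
                          faz_radius_mm=0.30, faz_irregularity=0.30),
    "severe_scr":    dict(n_vessels=66, tortuosity_amp=5.5, vessel_radius_px=2.0,
                          faz_radius_mm=0.36, faz_irregularity=0.45),
}


def generate_cohort(
    stage_profiles: dict[str, dict] | None = None,
    n_per_group: int = 10,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    jitter_sigma: float = 0.06,
):
    """Generate a labeled cohort of phantom pairs.

    Returns ``(records, manifest)`` where each record is
    ``(subject_id, eye, label, scp, dcp, truth)`` and the manifest is a
    DataFrame of subject ids and labels.  Within-group variation comes
    from lognormal per-subject jitter of the continuous parameters.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    profiles = stage_profiles or DEFAULT_PROFILES
    missing = set(LABELS) - set(profiles)
    if missing:
        raise ValueError(f"profiles missing labels: {sorted(missing)}")
    base = base_spec or PhantomSpec()

    records = []
    rows = []
    ss = np.random.SeedSequence(seed)
    for gi, label in enumerate(LABELS):
        deltas = profiles[label]
        for si in range(n_per_group):
            sub_seed = int(np.random.default_rng(ss.spawn(1)[0]).integers(2**31))
            jrng = np.random.default_rng(sub_seed)
            params = dict(deltas)
            for key in ("tortuosity_amp", "vessel_radius_px",
                        "faz_radius_mm", "faz_irregularity"):
                params[key] = params[key] * float(np.exp(
                    jitter_sigma * jrng.standard_normal()))
            params["n_vessels"] = max(4, int(round(
                params["n_vessels"] * np.exp(jitter_sigma * jrng.standard_normal()))))
            spec = replace(base, seed=sub_seed, **params)
            scp, dcp, truth = generate_phantom(spec)
            subject = f"{label}_{si:03d}"
            records.append((subject, "OD", label, scp, dcp, truth))
            rows.append({"subject_id": subject, "eye": "OD", "label": label})
    manifest = pd.DataFrame(rows)
    return records, manifest
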