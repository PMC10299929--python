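"""Synthetic bifurcating-arch generator.

Produces labeled fetal-like great-vessel anatomies — three centerline
segments (AAo+arch, arterial duct, descending aorta) meeting at a single
bifurcation origin, each with a smooth maximal-inscribed-radius profile —
so the full shape-modeling pipeline can be exercised and tested without
any patient data.  The anatomical factors it parameterizes are the ones
that discriminate duct-dependent coarctation from false-positive cases:
isthmus insertion angle, arch superiority, duct aneurysm/tortuosity and
ascending-aortic caliber.

Geometry is built from C1-smooth cubic Hermite splines through a small
set of control points in a local vertical plane spanned by the duct's
horizontal direction and the body axis Z, with the duct's lateral bowing
taken out of plane.  Segment arc lengths, the apex height, the insertion
angle and all radii are exact (zero-noise) by construction, so every
stated parameter can be recovered from the generated points by direct
measurement.

Coordinate frame (fetal axes): +X left->right, +Z inferior->superior,
+Y completing a right-handed frame.  Units are millimetres throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.interpolate import CubicHermiteSpline
from scipy.optimize import brentq

from .centerline import ArchCenterline, Centerline, DEFAULT_COUNTS, resample_centerline
from .errors import ParameterError

__all__ = [
    "ArchParams", "SyntheticCohortSpec", "SyntheticCohort",
    "generate_arch", "generate_cohort", "centerline_to_tube_mesh",
    "coa_like_params", "fp_like_params", "attenuated_contrast",
    "DEFAULT_PARAM_SDS",
]


@dataclass
class ArchParams:
    """Parameters of one synthetic arch anatomy (lengths/radii in mm).

    ``isthmus_insertion_angle`` is the angle (degrees) between the
    isthmus tangent and the duct tangent at the bifurcation, measured in
    the vertical plane through the duct direction: ~90 deg means the
    isthmus drops vertically onto the duct (coarctation-like), larger
    values mean a shallow lateral insertion.  ``duct_bow`` is the lateral
    bowing amplitude of the duct as a fraction of its length;
    ``duct_aneurysm_amp`` the peak fractional radius increase at mid-duct.
    The last three fields are pose only (removed by alignment).
    """

    aao_length: float = 38.0
    ad_length: float = 22.0
    dao_length: float = 30.0
    arch_apex_height: float = 14.0
    isthmus_insertion_angle: float = 120.0
    duct_bow: float = 0.12
    duct_aneurysm_amp: float = 0.2
    r_aao: float = 3.0
    r_isthmus: float = 2.0
    r_ad: float = 2.6
    r_dao: float = 2.4
    noise_sd: float = 0.0
    # pose (not shape): duct azimuth/elevation and world-space origin
    ad_azimuth_deg: float = 35.0
    ad_elevation_deg: float = -8.0
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def validate(self) -> None:
        positive = ("aao_length", "ad_length", "dao_length", "arch_apex_height",
                    "r_aao", "r_isthmus", "r_ad", "r_dao")
        for name in positive:
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0")
        if self.duct_aneurysm_amp < 0:
            raise ParameterError("duct_aneurysm_amp must be >= 0")
        if self.duct_bow < 0:
            raise ParameterError("duct_bow must be >= 0")
        if not 0 < self.isthmus_insertion_angle < 180:
            raise ParameterError("isthmus_insertion_angle must be in (0, 180)")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        # the arch apex must clear the top of the straight isthmus section
        phi = math.radians(self.ad_elevation_deg + self.isthmus_insertion_angle)
        isth_top = 0.2 * self.aao_length * math.sin(phi)
        if self.arch_apex_height <= isth_top + 0.02 * self.aao_length:
            raise ParameterError(
                "arch_apex_height is too small for the isthmus geometry")

    def to_dict(self) -> dict:
        return asdict(self)


def coa_like_params() -> ArchParams:
    """Generator defaults for the coarctation-like class (class 1).

    Near-perpendicular superior isthmus insertion, higher arch apex,
    non-aneurysmal duct, smaller ascending aorta and isthmus calibers.
    These are generator defaults chosen to mirror the qualitative
    contrast between the outcome groups; they are not measured values.
    """
    return ArchParams(aao_length=36.0, ad_length=22.0, dao_length=30.0,
                      arch_apex_height=16.0, isthmus_insertion_angle=92.0,
                      duct_bow=0.08, duct_aneurysm_amp=0.05,
                      r_aao=2.6, r_isthmus=1.7, r_ad=2.7, r_dao=2.4,
                      noise_sd=0.15)


def fp_like_params() -> ArchParams:
    """Generator defaults for the false-positive-like class (class 0).

    Shallow lateral insertion, flatter arch, aneurysmal bowed duct,
    larger ascending aorta and isthmus calibers.
    """
    return ArchParams(aao_length=38.0, ad_length=22.0, dao_length=30.0,
                      arch_apex_height=12.0, isthmus_insertion_angle=138.0,
                      duct_bow=0.16, duct_aneurysm_amp=0.40,
                      r_aao=3.4, r_isthmus=2.4, r_ad=2.6, r_dao=2.5,
                      noise_sd=0.15)


def attenuated_contrast(scale: float) -> tuple[ArchParams, ArchParams]:
    """Class means blended toward their midpoint by 1 - ``scale``.

    ``scale=1`` keeps the default contrast; ``scale=0`` makes the
    classes identical.  Useful for studies of finite-sample behavior
    (overfitting, subset variance) where the default contrast is so
    strong that classification saturates.
    """
    if not 0 <= scale <= 1:
        raise ParameterError("scale must be in [0, 1]")
    p0, p1 = fp_like_params(), coa_like_params()
    d0, d1 = asdict(p0), asdict(p1)
    out0, out1 = dict(d0), dict(d1)
    for key, v0 in d0.items():
        if isinstance(v0, (int, float)):
            mid = 0.5 * (v0 + d1[key])
            out0[key] = mid + scale * (v0 - mid)
            out1[key] = mid + scale * (d1[key] - mid)
    return ArchParams(**out0), ArchParams(**out1)


DEFAULT_PARAM_SDS: dict[str, float] = {
    "aao_length": 2.5, "ad_length": 1.8, "dao_length": 2.5,
    "arch_apex_height": 1.5, "isthmus_insertion_angle": 9.0,
    "duct_bow": 0.04, "duct_aneurysm_amp": 0.07,
    "r_aao": 0.25, "r_isthmus": 0.2, "r_ad": 0.2, "r_dao": 0.2,
    "noise_sd": 0.0, "ad_azimuth_deg": 8.0, "ad_elevation_deg": 4.0,
}


@dataclass
class SyntheticCohortSpec:
    """Class-conditional sampling distributions for a labeled cohort.

    Per-case parameters are drawn from independent Gaussians around the
    class means, truncated by reject-and-resample to the parameter
    invariants.  Class 1 is the coarctation-like class.
    """

    n_cases: int = 100
    prevalence: float = 0.4
    class0_means: ArchParams = field(default_factory=fp_like_params)
    class1_means: ArchParams = field(default_factory=coa_like_params)
    param_sds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PARAM_SDS))
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 2:
            raise ParameterError("n_cases must be >= 2")
        if not 0 < self.prevalence < 1:
            raise ParameterError("prevalence must be in (0, 1)")
        n1 = int(round(self.prevalence * self.n_cases))
        if n1 == 0 or n1 == self.n_cases:
            raise ParameterError(
                "prevalence leaves one class empty at this n_cases")
        unknown = set(self.param_sds) - set(asdict(self.class0_means))
        if unknown:
            raise ParameterError(f"unknown param_sds keys: {sorted(unknown)}")


@dataclass
class SyntheticCohort:
    """A generated cohort: anatomies, binary labels and per-case params."""

    arches: list[ArchCenterline]
    labels: np.ndarray
    params: list[ArchParams]
    case_ids: list[str]
    spec: SyntheticCohortSpec

    @property
    def n_cases(self) -> int:
        return len(self.arches)


# ---------------------------------------------------------------------------
# single-arch construction
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _hermite_curve(knots: np.ndarray, tangents: np.ndarray, n: int) -> np.ndarray:
    """Sample a C1 cubic Hermite curve with chord-length parameterization."""
    chords = np.linalg.norm(np.diff(knots, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(chords)])
    spline = CubicHermiteSpline(u, knots, tangents)
    return spline(np.linspace(0.0, u[-1], n))


def _build_aao(p: ArchParams, e1, e2, e3, B, n_dense: int) -> np.ndarray:
    """AAo free end -> apex -> straight isthmus -> bifurcation origin.

    The isthmus (distal 20% of the segment) is exactly straight along
    the requested insertion direction; the ascending limb's free end is
    slid along its own direction until the total arc length matches
    ``aao_length`` (bracketed root find).
    """
    L = p.aao_length
    psi = math.radians(p.ad_elevation_deg)
    phi = psi + math.radians(p.isthmus_insertion_angle)
    d_isth = math.cos(phi) * e1 + math.sin(phi) * e3  # away from origin, up the isthmus
    li = 0.2 * L
    c1 = B + li * d_isth
    apex = B + (li * math.cos(phi) - 0.22 * L) * e1 + p.arch_apex_height * e3
    f0 = apex - 0.12 * L * e1 - 0.30 * L * e3
    u_desc = _unit(f0 - apex)

    def curve(ext: float) -> np.ndarray:
        f = f0 + ext * u_desc
        knots = np.array([f, apex, c1, B])
        tangents = np.array([_unit(apex - f), e1, -d_isth, -d_isth])
        return _hermite_curve(knots, tangents, n_dense)

    lo = -0.6 * np.linalg.norm(f0 - apex)
    hi = 1.5 * L

    def objective(ext):
        return _polyline_length(curve(ext)) - L

    f_lo = objective(lo)
    if f_lo > 0:
        raise ParameterError("aao_length is too short for this arch geometry")
    return curve(brentq(objective, lo, hi, xtol=1e-10))


def _ad_chord(p: ArchParams) -> float:
    """Chord length giving the requested duct arc length at the set bow."""
    bow = p.duct_bow * p.ad_length
    if bow == 0:
        return p.ad_length

    t = np.linspace(0.0, 1.0, 800)
    off = bow * np.sin(np.pi * t) ** 2

    def arclen(chord):
        xy = np.column_stack([t * chord, off])
        return _polyline_length(np.column_stack([xy, np.zeros_like(t)]))

    lo, hi = 0.2 * p.ad_length, p.ad_length
    if arclen(lo) > p.ad_length:
        raise ParameterError("duct_bow is too large for ad_length")
    return brentq(lambda c: arclen(c) - p.ad_length, lo, hi, xtol=1e-10)


def _radius_profiles(p: ArchParams, counts) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_aao, n_ad, n_dao = counts
    # AAo: caliber r_aao proximally, smooth taper to r_isthmus in the
    # distal fifth (the isthmus surrogate)
    s = np.linspace(0.0, 1.0, n_aao)
    t = np.clip((s - 0.55) / 0.25, 0.0, 1.0)
    smooth = t * t * (3 - 2 * t)
    r_aao = p.r_aao + (p.r_isthmus - p.r_aao) * smooth
    # AD: constant caliber with an optional Gaussian aneurysm bump at mid-duct
    s = np.linspace(0.0, 1.0, n_ad)
    bump = np.exp(-(((s - 0.5) / 0.16) ** 2)) if p.duct_aneurysm_amp > 0 else 0.0
    r_ad = p.r_ad * (1.0 + p.duct_aneurysm_amp * bump)
    r_dao = np.full(n_dao, p.r_dao)
    return r_aao, np.asarray(r_ad, dtype=float) * np.ones(n_ad), r_dao


def generate_arch(params: ArchParams, seed: int = 0,
                  counts: tuple[int, int, int] = DEFAULT_COUNTS,
                  n_dense: int = 400) -> ArchCenterline:
    """Generate one synthetic arch centerline (deterministic given seed).

    Returns segments in the pipeline ordering convention: AAo and AD from
    their free ends toward the bifurcation origin, DAo from the origin
    toward the diaphragm, resampled to ``counts`` points each.
    """
    params.validate()
    p = params
    rng = np.random.default_rng(seed)

    az = math.radians(p.ad_azimuth_deg)
    e1 = np.array([math.cos(az), math.sin(az), 0.0])
    e3 = np.array([0.0, 0.0, 1.0])
    e2 = np.cross(e3, e1)
    B = np.asarray(p.origin_mm, dtype=float)

    psi = math.radians(p.ad_elevation_deg)
    u_ad = math.cos(psi) * e1 + math.sin(psi) * e3

    # duct: straight chord along u_ad plus an out-of-plane sin^2 bow whose
    # slope vanishes at both ends (tangent at the origin stays u_ad)
    chord = _ad_chord(p)
    t = np.linspace(0.0, 1.0, n_dense)
    bow = p.duct_bow * p.ad_length * np.sin(np.pi * t) ** 2
    ad_dense = B[None] + np.outer(t * chord, u_ad) + np.outer(bow, e2)
    ad_dense = ad_dense[::-1]  # free end -> origin

    aao_dense = _build_aao(p, e1, e2, e3, B, n_dense)  # free end -> origin

    u_dao = _unit(-0.08 * e1 + 0.15 * e2 - 1.0 * e3)
    dao_dense = B[None] + np.outer(np.linspace(0.0, p.dao_length, n_dense), u_dao)

    n_aao, n_ad, n_dao = counts
    aao_p, _ = _resample(aao_dense, n_aao)
    ad_p, _ = _resample(ad_dense, n_ad)
    dao_p, _ = _resample(dao_dense, n_dao)
    r_aao, r_ad, r_dao = _radius_profiles(p, counts)

    if p.noise_sd > 0:
        aao_p = aao_p + rng.normal(0.0, p.noise_sd, aao_p.shape)
        ad_p = ad_p + rng.normal(0.0, p.noise_sd, ad_p.shape)
        dao_p = dao_p + rng.normal(0.0, p.noise_sd, dao_p.shape)

    return ArchCenterline(Centerline(aao_p, r_aao), Centerline(ad_p, r_ad),
                          Centerline(dao_p, r_dao), B.copy())


def _resample(points: np.ndarray, n: int):
    line = resample_centerline(Centerline(points, np.ones(len(points))), n)
    return line.points, line.radius


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------


def _sample_params(means: ArchParams, sds: dict[str, float],
                   rng: np.random.Generator, max_tries: int = 200) -> ArchParams:
    base = asdict(means)
    for _ in range(max_tries):
        draw = dict(base)
        for name, sd in sds.items():
            if sd > 0:
                draw[name] = rng.normal(base[name], sd)
        draw["origin_mm"] = tuple(draw["origin_mm"])
        candidate = ArchParams(**draw)
        try:
            candidate.validate()
        except ParameterError:
            continue
        return candidate
    raise ParameterError(
        "could not draw valid parameters after truncation; reduce param_sds")


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Draw a labeled cohort of synthetic arches (reproducible from seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases
    n1 = int(round(spec.prevalence * n))
    labels = np.zeros(n, dtype=int)
    labels[:n1] = 1
    rng.shuffle(labels)

    arches, params, case_ids = [], [], []
    for i in range(n):
        means = spec.class1_means if labels[i] == 1 else spec.class0_means
        p = _sample_params(means, spec.param_sds, rng)
        arch_seed = int(rng.integers(0, 2**31 - 1))
        arches.append(generate_arch(p, seed=arch_seed))
        params.append(p)
        case_ids.append(f"case_{i:04d}")
    return SyntheticCohort(arches, labels, params, case_ids, spec)


# ---------------------------------------------------------------------------
# planted-subspace feature cohorts (for validating the statistics)
# ---------------------------------------------------------------------------


def planted_mode_cohort(n_cases: int = 100, n_features: int = 404,
                        n_signal_modes: int = 3, n_background_modes: int = 27,
                        signal_sd: float = 6.0, shift_sd_units: float = 1.2,
                        background_sd: float = 2.5, noise_sd: float = 0.3,
                        prevalence: float = 0.4, seed: int = 0):
    """Gaussian feature cohort whose class signal lives in a few directions.

    Variation is spread over ``n_signal_modes`` high-variance latent
    directions carrying a class mean shift of ``shift_sd_units`` of
    their own SD, plus ``n_background_modes`` label-independent
    directions with geometrically decaying SDs and isotropic noise on
    all features.  Returns ``(features, labels, signal_directions)``;
    used to validate mode recovery, t-test calibration and the
    overfitting signature of the mode-count sweep.
    """
    rng = np.random.default_rng(seed)
    n1 = int(round(prevalence * n_cases))
    labels = np.zeros(n_cases, dtype=int)
    labels[:n1] = 1
    rng.shuffle(labels)
    m = n_signal_modes + n_background_modes
    basis = np.linalg.qr(rng.normal(size=(n_features, m)))[0].T  # (m, p)
    sds = np.concatenate([
        np.full(n_signal_modes, signal_sd),
        background_sd * 0.85 ** np.arange(n_background_modes)])
    z = rng.normal(size=(n_cases, m)) * sds
    z[labels == 1, :n_signal_modes] += shift_sd_units * signal_sd
    X = z @ basis + rng.normal(0.0, noise_sd, size=(n_cases, n_features))
    return X, labels, basis[:n_signal_modes]


# ---------------------------------------------------------------------------
# tube meshing
# ---------------------------------------------------------------------------


def _parallel_transport_frames(points: np.ndarray):
    tang = np.gradient(points, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    normals = np.zeros_like(points)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, tang[0])) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    n = ref - np.dot(ref, tang[0]) * tang[0]
    normals[0] = n / np.linalg.norm(n)
    for i in range(1, len(points)):
        n = normals[i - 1] - np.dot(normals[i - 1], tang[i]) * tang[i]
        nn = np.linalg.norm(n)
        normals[i] = n / nn if nn > 1e-12 else normals[i - 1]
    binormals = np.cross(tang, normals)
    return normals, binormals


def _sweep_tube(line: Centerline, res: int):
    import trimesh

    pts, rad = line.points, line.radius
    normals, binormals = _parallel_transport_frames(pts)
    phi = 2 * np.pi * np.arange(res) / res
    rings = (pts[:, None, :]
             + rad[:, None, None] * (np.cos(phi)[None, :, None] * normals[:, None, :]
                                     + np.sin(phi)[None, :, None] * binormals[:, None, :]))
    verts = rings.reshape(-1, 3)
    n_rings = len(pts)
    faces = []
    for i in range(n_rings - 1):
        a = i * res + np.arange(res)
        b = i * res + (np.arange(res) + 1) % res
        c = a + res
        d = b + res
        faces.append(np.column_stack([a, b, d]))
        faces.append(np.column_stack([a, d, c]))
    faces = np.vstack(faces)
    # end caps: fan to the centerline endpoints
    verts = np.vstack([verts, pts[0][None], pts[-1][None]])
    c0, c1 = len(verts) - 2, len(verts) - 1
    first = np.arange(res)
    last = (n_rings - 1) * res + np.arange(res)
    cap0 = np.column_stack([first, np.full(res, c0), np.roll(first, -1)])
    cap1 = np.column_stack([last, np.roll(last, -1), np.full(res, c1)])
    faces = np.vstack([faces, cap0, cap1])
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.fix_normals()
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
    return mesh


def centerline_to_tube_mesh(arch: ArchCenterline,
                            circumferential_resolution: int = 16):
    """Sweep circular tubes along each segment and emit the 4 landmarks.

    Returns ``(mesh, landmarks)`` where the mesh is the triangle-soup
    union of three capped tubes (one per segment) and the landmarks are
    the extraction protocol's four anchors: DAo at the diaphragm, AD at
    the pulmonary bifurcation, the mid-duct point and AAo at the level
    of the right pulmonary artery (here: the AAo free end).
    """
    import trimesh

    for name, seg in arch.segments().items():
        if np.any(seg.radius <= 0):
            raise ParameterError(f"{name} radii must be positive to mesh a tube")
        if _self_intersects(seg):
            warnings.warn(f"{name} tube may self-intersect; mesh emitted anyway",
                          stacklevel=2)
    tubes = [_sweep_tube(seg, circumferential_resolution)
             for seg in (arch.aao, arch.ad, arch.dao)]
    mesh = trimesh.util.concatenate(tubes)

    s = arch.ad.arc_lengths()
    mid = int(np.argmin(np.abs(s - 0.5 * s[-1])))
    landmarks = {
        "dao_diaphragm": arch.dao.points[-1].copy(),
        "ad_pa_bifurcation": arch.ad.points[0].copy(),
        "ad_medial": arch.ad.points[mid].copy(),
        "aao_rpa": arch.aao.points[0].copy(),
    }
    return mesh, landmarks


def _self_intersects(seg: Centerline) -> bool:
    """Cheap heuristic: tube sections far apart along the centerline but
    closer in space than their summed radii."""
    pts, rad = seg.points, seg.radius
    s = seg.arc_lengths()
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    rsum = rad[:, None] + rad[None, :]
    arc_gap = np.abs(s[:, None] - s[None, :])
    suspect = (arc_gap > 2.5 * rsum) & (d < 0.8 * rsum)
    return bool(suspect.any())
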