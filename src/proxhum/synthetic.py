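"""Parametric proximal-humerus generator with closed-form ground truth.

The synthetic bone emulates the segmented surface a CT workflow would
produce: a cylindrical upper shaft along +z, a spherical (optionally
anteroposteriorly scaled, i.e. ellipsoidal) articular cap cut by an
anatomic-neck plane inclined at a controllable angle to the shaft axis, a
greater-tuberosity prominence lateral to the cap, and a conical metaphyseal
fillet joining cap rim to shaft so the mesh is watertight.  The fillet is
excluded from all labelled regions so it cannot perturb argmax landmarks.

Every anatomic parameter of the generated bone has a closed form:

=============  =========================================================
NSA            ``alpha + 90`` (neck plane inclined ``alpha`` to shaft)
HHT            ``R - d`` (head radius minus cut distance)
cASD           ``2 * sqrt(R**2 - d**2)`` (rim chord in the coronal plane)
aASD           ``head_ap_scale * cASD`` (ellipsoid scaling, by construction)
TSH            ``tuberosity_height_offset`` (axial gap G -> H)
=============  =========================================================

The cohort simulator draws per-subject parameter vectors from per-sex
multivariate normals (means/SDs and the 3-D correlation structure of the
reference population) and maps them to generator parameters by inverting
the closed forms.  A rater simulator adds two-way crossed rater/residual
noise for reproducibility (ICC) studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import AxisLine, Plane
from .mesh import LandmarkSet, TriangleMesh

__all__ = [
    "HumerusParams",
    "TruthRecord",
    "CohortSpec",
    "DEFAULT_COHORT_SPEC",
    "generate_humerus",
    "generate_cohort",
    "draw_parameters",
    "simulate_raters",
    "simulate_study",
    "anatomic_range_sweep",
]


# ---------------------------------------------------------------------------
# generator parameters and ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HumerusParams:
    """Generative parameters of one synthetic proximal humerus (mm / deg).

    Defaults reproduce the reference population's mean bone:
    NSA 132.1 deg, HHT 18.8 mm, cASD 44.2 mm, aASD 40.4 mm, TSH 7.2 mm.
    """

    shaft_radius: float = 12.5
    shaft_length: float = 60.0
    head_radius: float = 22.394
    neck_cut_distance: float = 3.594
    neck_inclination_deg: float = 42.1
    head_ap_scale: float = 0.914
    tuberosity_height_offset: float = 7.2
    tuberosity_radial_offset: float = 3.0
    mesh_edge_length: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        v = []
        if not 0 < self.neck_cut_distance < self.head_radius:
            v.append(
                f"neck_cut_distance must lie in (0, head_radius): "
                f"{self.neck_cut_distance} vs R={self.head_radius}"
            )
        if not 0 < self.neck_inclination_deg < 90:
            v.append(f"neck_inclination_deg must lie in (0, 90): {self.neck_inclination_deg}")
        if not 0.5 <= self.head_ap_scale <= 1.2:
            v.append(f"head_ap_scale must lie in [0.5, 1.2]: {self.head_ap_scale}")
        if not self.mesh_edge_length > 0:
            v.append(f"mesh_edge_length must be positive: {self.mesh_edge_length}")
        if not self.shaft_radius > 0:
            v.append(f"shaft_radius must be positive: {self.shaft_radius}")
        if not self.shaft_length > 4 * self.mesh_edge_length:
            v.append("shaft_length too short for the requested mesh resolution")
        if not self.tuberosity_radial_offset >= 0:
            v.append("tuberosity_radial_offset must be non-negative")
        if v:
            raise ValidationError(v)

    # -- closed forms -------------------------------------------------------

    @property
    def rim_radius(self) -> float:
        """Radius of the anatomic-neck rim circle, sqrt(R^2 - d^2)."""
        return math.sqrt(self.head_radius**2 - self.neck_cut_distance**2)

    @property
    def apex_clearance(self) -> float:
        """Axial drop from the articular apex G down to the rim point C.

        ``R * (1 - cos(beta_rim - gamma))`` when the head apex lies inside
        the cap (gamma <= beta_rim), else 0 (the apex is the rim point C
        itself).  The tuberosity apex must sit below C on the metaphysis,
        so ``tuberosity_height_offset`` has to exceed this clearance.
        """
        beta_rim = math.acos(self.neck_cut_distance / self.head_radius)
        gamma = math.radians(90.0 - self.neck_inclination_deg)
        if gamma > beta_rim:
            return 0.0
        return self.head_radius * (1.0 - math.cos(beta_rim - gamma))

    def min_tuberosity_offset(self) -> float:
        # apex must sit at least ~1 fillet ring below the rim point C
        return self.apex_clearance + max(1.5 * self.mesh_edge_length, 1.0)

    @classmethod
    def from_measurements(
        cls,
        nsa_deg: float,
        hht_mm: float,
        casd_mm: float,
        aasd_mm: float,
        tsh_mm: float,
        **kwargs,
    ) -> "HumerusParams":
        """Invert the closed forms: anatomic parameters -> generator parameters.

        rho = cASD / 2 and HHT = R - d, rho^2 = R^2 - d^2 give exactly
        R = (rho^2 + HHT^2) / (2 HHT) and d = R - HHT; the anteroposterior
        scale is aASD / cASD.  Values are clamped into the generator's
        validity region (inclination, scale, tuberosity clearance), so the
        returned params' own ``TruthRecord`` is authoritative.
        """
        rho = casd_mm / 2.0
        if not 0 < hht_mm < rho:
            hht_mm = min(max(hht_mm, 0.05 * rho), 0.95 * rho)
        R = (rho**2 + hht_mm**2) / (2.0 * hht_mm)
        d = R - hht_mm
        alpha = min(max(nsa_deg - 90.0, 5.0), 85.0)
        scale = min(max(aasd_mm / casd_mm, 0.5), 1.2)
        p = cls(
            head_radius=R,
            neck_cut_distance=d,
            neck_inclination_deg=alpha,
            head_ap_scale=scale,
            tuberosity_height_offset=tsh_mm,
            **kwargs,
        )
        lo = p.min_tuberosity_offset()
        if tsh_mm < lo:
            p = replace(p, tuberosity_height_offset=lo)
        return p


@dataclass(frozen=True)
class TruthRecord:
    """Closed-form true parameter values and landmarks of a synthetic bone."""

    nsa_deg: float
    alpha_deg: float
    hht_mm: float
    casd_mm: float
    aasd_mm: float
    tsh_mm: float
    C: np.ndarray
    D: np.ndarray
    E: np.ndarray
    F: np.ndarray
    G: np.ndarray
    H: np.ndarray
    shaft_axis: AxisLine
    neck_plane: Plane


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------


def _ring_count(params: HumerusParams) -> int:
    """Columns around the bone; K = 2 (mod 4) keeps mesh vertices off the
    axial section plane (theta = pi/2) while pinning C (0) and D (pi)."""
    circum = 2.0 * math.pi * max(params.rim_radius, params.shaft_radius)
    K = max(32, int(math.ceil(circum / params.mesh_edge_length)))
    return K + ((2 - K) % 4)


def generate_humerus(params: HumerusParams):
    """Build a watertight labelled mesh plus landmarks and ground truth.

    Returns
    -------
    (TriangleMesh, LandmarkSet, TruthRecord)
    """
    params.validate()
    h = params.mesh_edge_length
    R, d, s = params.head_radius, params.neck_cut_distance, params.head_ap_scale
    r_s, L = params.shaft_radius, params.shaft_length
    alpha = params.neck_inclination_deg
    gamma = math.radians(90.0 - alpha)
    beta_rim = math.acos(d / R)
    rho = params.rim_radius

    # frame of the neck plane: n = cap axis, u = steepest-ascent (superior)
    # in-plane direction, w = +x (anterior); (u, w, n) right-handed
    n = np.array([0.0, math.sin(gamma), math.cos(gamma)])
    u = np.array([0.0, -math.cos(gamma), math.sin(gamma)])
    w = np.array([1.0, 0.0, 0.0])

    z_pad = 2.0
    o = np.array([0.0, 0.0, L + z_pad + rho * math.sin(gamma)])  # rim centre
    c_h = o - d * n  # head centre

    # closed-form articular apex height
    if gamma <= beta_rim:
        G_true = c_h + R * np.array([0.0, 0.0, 1.0])
    else:
        G_true = o + rho * u  # = C
    z_apex = G_true[2] - params.tuberosity_height_offset

    tsh_lo = params.min_tuberosity_offset()
    violations = []
    if params.tuberosity_height_offset < tsh_lo:
        violations.append(
            f"tuberosity_height_offset {params.tuberosity_height_offset:.2f} mm "
            f"below geometric minimum {tsh_lo:.2f} mm (apex would reach the rim)"
        )
    if z_apex < L + 2 * h:
        violations.append("tuberosity apex would fall below the shaft top")
    if violations:
        raise ValidationError(violations)

    K = _ring_count(params)
    theta = 2.0 * math.pi * np.arange(K) / K

    # rim ring (cap ring j=0), anteroposterior scaling applied about x=0
    rim = o + rho * (np.outer(np.cos(theta), u) + np.outer(np.sin(theta), w))
    rim[:, 0] *= s

    # shaft columns share the rim's azimuthal ordering so the fillet does
    # not twist
    e = rim[:, :2].copy()
    norms = np.linalg.norm(e, axis=1)
    small = norms < 1e-9
    if np.any(small):
        e[small] = np.column_stack([np.sin(theta[small]), -np.cos(theta[small])])
        norms[small] = 1.0
    e /= norms[:, None]

    n_shaft = max(2, int(math.ceil(L / h)))
    z_levels = np.linspace(0.0, L, n_shaft + 1)
    shaft = np.concatenate(
        [
            np.column_stack([r_s * e[:, 0], r_s * e[:, 1], np.full(K, z)])
            for z in z_levels
        ]
    )

    S = shaft[-K:]  # shaft-top ring
    M = max(2, int(math.ceil(np.linalg.norm(rim - S, axis=1).max() / h)))
    band = np.concatenate(
        [S + (t / M) * (rim - S) for t in range(1, M)]
    ) if M > 1 else np.empty((0, 3))

    n_cap = max(3, int(math.ceil(R * beta_rim / h)))
    betas = beta_rim * (1.0 - np.arange(n_cap) / n_cap)  # j=0 is the rim
    cap = np.concatenate(
        [
            c_h
            + R * math.cos(b) * n
            + R * math.sin(b) * (np.outer(np.cos(theta), u) + np.outer(np.sin(theta), w))
            for b in betas
        ]
    )
    cap[:, 0] = c_h[0] + s * (cap[:, 0] - c_h[0])
    pole = c_h + R * n  # x = 0, unaffected by scaling

    # ---- index layout ----
    i_bottom = 0
    base_shaft = 1
    base_band = base_shaft + (n_shaft + 1) * K
    base_cap = base_band + (M - 1) * K
    i_pole = base_cap + n_cap * K

    vertices = np.concatenate(
        [np.zeros((1, 3)), shaft, band, cap, [pole]]
    )

    # ---- tuberosity: displace fillet vertices near the lateral column ----
    col_phi = np.arctan2(e[:, 1], e[:, 0])  # azimuth per column
    phi_apex = col_phi[0]  # column 0 = lateral (below C)
    dphi = np.angle(np.exp(1j * (col_phi - phi_apex)))
    sector = math.radians(28.0)

    col0 = base_band + np.arange(M - 1) * K  # column-0 fillet vertices
    z_col0 = vertices[col0, 2]
    t_apex = int(np.clip(np.searchsorted(z_col0, z_apex), 1, M - 1)) - 1
    i_apex = int(col0[t_apex])

    ring_dz = max((z_col0[-1] - z_col0[0]) / max(M - 2, 1), h)
    bump_rows = max(3, int(math.ceil(3.0 / ring_dz)))
    band_t = np.repeat(np.arange(M - 1), K)  # ring index per band vertex
    band_k = np.tile(np.arange(K), M - 1)
    prof_az = np.cos(0.5 * math.pi * np.clip(np.abs(dphi[band_k]) / sector, 0, 1)) ** 2
    prof_t = np.cos(
        0.5 * math.pi * np.clip(np.abs(band_t - t_apex) / bump_rows, 0, 1)
    ) ** 2
    profile = prof_az * prof_t
    profile[np.abs(dphi[band_k]) >= sector] = 0.0
    profile[np.abs(band_t - t_apex) >= bump_rows] = 0.0

    band_slice = slice(base_band, base_cap)
    bv = vertices[band_slice]
    radial = bv[:, :2].copy()
    rn = np.linalg.norm(radial, axis=1)
    rn[rn < 1e-9] = 1.0
    radial /= rn[:, None]
    bv[:, :2] += params.tuberosity_radial_offset * profile[:, None] * radial
    vertices[band_slice] = bv

    # pin the apex vertex exactly: lateral of column 0, at height z_apex
    H_true = np.array([0.0, vertices[i_apex, 1], z_apex])
    vertices[i_apex] = H_true

    # ---- labels ----
    labels = np.array(["other"] * len(vertices), dtype=object)
    labels[base_shaft : base_shaft + (n_shaft + 1) * K] = "shaft"
    labels[base_cap:] = "articular_surface"
    tub = np.flatnonzero(profile >= 0.25) + base_band
    tub = tub[vertices[tub, 2] <= z_apex - 0.25 * h]
    labels[tub] = "greater_tuberosity"
    labels[i_apex] = "greater_tuberosity"

    # ---- faces ----
    faces = []

    def strip(lower, upper):
        """Outward-oriented quad strip between two K-rings (CCW from above)."""
        k = np.arange(K)
        k1 = (k + 1) % K
        faces.append(np.column_stack([lower + k, lower + k1, upper + k1]))
        faces.append(np.column_stack([lower + k, upper + k1, upper + k]))

    # bottom disc, outward -z
    k = np.arange(K)
    k1 = (k + 1) % K
    ring0 = base_shaft
    faces.append(np.column_stack([np.full(K, i_bottom), ring0 + k1, ring0 + k]))

    ring_bases = (
        [base_shaft + i * K for i in range(n_shaft + 1)]
        + [base_band + t * K for t in range(M - 1)]
        + [base_cap + j * K for j in range(n_cap)]
    )
    for lo, up in zip(ring_bases[:-1], ring_bases[1:]):
        strip(lo, up)

    top = ring_bases[-1]
    faces.append(np.column_stack([np.full(K, i_pole), top + k, top + k1]))
    faces = np.concatenate(faces)

    mesh = TriangleMesh(vertices=vertices, faces=faces, region_labels=labels)

    # ---- landmarks & truth ----
    C = rim[0].copy()
    D = rim[K // 2].copy()
    kE = K // 4  # K = 2 (mod 4): lands just off theta = pi/2, an exact vertex
    E = rim[kE].copy()
    F_true = pole.copy()

    landmarks = LandmarkSet(C=C, D=D, E=E, F=F_true, G=G_true, H=H_true)
    truth = TruthRecord(
        nsa_deg=alpha + 90.0,
        alpha_deg=alpha,
        hht_mm=R - d,
        casd_mm=2.0 * rho,
        aasd_mm=s * 2.0 * rho,
        tsh_mm=params.tuberosity_height_offset,
        C=C,
        D=D,
        E=E,
        F=F_true,
        G=G_true,
        H=H_true,
        shaft_axis=AxisLine(np.zeros(3), np.array([0.0, 0.0, 1.0])),
        neck_plane=Plane(o, n),
    )
    return mesh, landmarks, truth


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

PARAMS_3D = ("NSA", "TSH", "HHT", "cASD", "aASD")
PARAMS_2D = ("NSA", "TSH", "HHT", "cASD")

# reference population, per-sex mean/SD (3-D CT block and radiograph block)
_MALE_3D = {"NSA": (131.4, 3.9), "TSH": (7.7, 2.6), "HHT": (20.1, 1.6),
            "cASD": (47.3, 2.3), "aASD": (43.1, 2.2)}
_FEMALE_3D = {"NSA": (132.6, 4.8), "TSH": (6.8, 2.1), "HHT": (17.7, 2.0),
              "cASD": (41.7, 3.4), "aASD": (38.2, 2.9)}
_MALE_2D = {"NSA": (132.1, 5.6), "TSH": (10.1, 3.0), "HHT": (24.4, 1.9),
            "cASD": (49.8, 4.0)}
_FEMALE_2D = {"NSA": (133.7, 4.7), "TSH": (9.7, 2.4), "HHT": (22.4, 2.1),
              "cASD": (43.6, 3.6)}

# correlation structure of the 3-D parameters (order PARAMS_3D)
_CORR_3D = np.array(
    [
        [1.000, 0.586, 0.106, 0.020, 0.036],
        [0.586, 1.000, 0.391, 0.361, 0.413],
        [0.106, 0.391, 1.000, 0.705, 0.681],
        [0.020, 0.361, 0.705, 1.000, 0.907],
        [0.036, 0.413, 0.681, 0.907, 1.000],
    ]
)

# pooled SDs used to scale rater noise
_TOTAL_SD_3D = {"NSA": 4.4, "TSH": 2.3, "HHT": 2.2, "cASD": 4.1, "aASD": 3.6}
_TOTAL_SD_2D = {"NSA": 5.2, "TSH": 2.7, "HHT": 2.3, "cASD": 4.9}


@dataclass(frozen=True)
class CohortSpec:
    """Distributional spec of the simulated cohort.

    ``male_3d``/``female_3d`` map parameter name to (mean, SD); ``corr_3d``
    is the 5x5 correlation matrix over ``PARAMS_3D``.  The radiographic
    block is drawn conditionally on its 3-D counterpart with paired
    correlation ``paired_corr`` (the within-subject modality coupling,
    unreported upstream; 0.8 is a deliberate, documented choice).  Rater
    noise scales are fractions of each parameter's pooled SD, chosen so the
    simulated reproducibility matches the reference ICC ranges
    (3-D ~0.88-0.94, radiographs ~0.74-0.86).
    """

    male_3d: dict = field(default_factory=lambda: dict(_MALE_3D))
    female_3d: dict = field(default_factory=lambda: dict(_FEMALE_3D))
    male_2d: dict = field(default_factory=lambda: dict(_MALE_2D))
    female_2d: dict = field(default_factory=lambda: dict(_FEMALE_2D))
    corr_3d: np.ndarray = field(default_factory=lambda: _CORR_3D.copy())
    paired_corr: float = 0.8
    error_sd_frac_3d: float = 1.0 / 3.2
    rater_sd_frac_3d: float = 0.1
    error_sd_frac_2d: float = 0.5
    rater_sd_frac_2d: float = 0.125

    def noise_sd(self, parameter: str, modality: str):
        """(rater SD, residual SD) for one parameter/modality."""
        if modality == "3d":
            sd = _TOTAL_SD_3D[parameter]
            return sd * self.rater_sd_frac_3d, sd * self.error_sd_frac_3d
        sd = _TOTAL_SD_2D[parameter]
        return sd * self.rater_sd_frac_2d, sd * self.error_sd_frac_2d


DEFAULT_COHORT_SPEC = CohortSpec()


def _nearest_pd(corr: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped nearest positive-definite repair of a correlation
    matrix; raises if the input is not even symmetrisable."""
    a = np.asarray(corr, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError(f"correlation matrix must be square, got {a.shape}")
    a = 0.5 * (a + a.T)
    vals, vecs = np.linalg.eigh(a)
    if vals.min() > eps:
        return a
    vals = np.clip(vals, eps, None)
    b = (vecs * vals) @ vecs.T
    dd = np.sqrt(np.diag(b))
    b = b / np.outer(dd, dd)
    vals2 = np.linalg.eigvalsh(b)
    if vals2.min() <= 0:
        raise ValidationError("correlation matrix could not be repaired to PD")
    return b


def draw_parameters(
    n_male: int,
    n_female: int,
    spec: CohortSpec = DEFAULT_COHORT_SPEC,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject anatomic parameters (both modalities) for a cohort.

    Columns: subject_id, sex ('M'/'F'), then ``<param>_3d`` for the five
    3-D parameters and ``<param>_2d`` for the four radiographic ones.
    """
    if n_male < 0 or n_female < 0 or n_male + n_female == 0:
        raise ValidationError("cohort sizes must be non-negative and not both zero")
    rng = np.random.default_rng(seed)
    corr = _nearest_pd(spec.corr_3d)
    rows = []
    sid = 0
    for sex, n, m3, m2 in (
        ("M", n_male, spec.male_3d, spec.male_2d),
        ("F", n_female, spec.female_3d, spec.female_2d),
    ):
        if n == 0:
            continue
        mu = np.array([m3[p][0] for p in PARAMS_3D])
        sd = np.array([m3[p][1] for p in PARAMS_3D])
        cov = corr * np.outer(sd, sd)
        x3 = rng.multivariate_normal(mu, cov, size=n, method="cholesky")
        z3 = (x3 - mu) / sd
        rho = spec.paired_corr
        for i in range(n):
            row = {"subject_id": sid, "sex": sex}
            for j, p in enumerate(PARAMS_3D):
                row[f"{p}_3d"] = x3[i, j]
            for j, p in enumerate(PARAMS_2D):
                mu2, sd2 = m2[p]
                j3 = PARAMS_3D.index(p)
                row[f"{p}_2d"] = mu2 + sd2 * (
                    rho * z3[i, j3] + math.sqrt(1 - rho**2) * rng.standard_normal()
                )
            rows.append(row)
            sid += 1
    return pd.DataFrame(rows)


def generate_cohort(
    n_male: int,
    n_female: int,
    spec: CohortSpec = DEFAULT_COHORT_SPEC,
    seed: int = 0,
    mesh_edge_length: float = 0.5,
):
    """Draw a cohort and map each subject to generator parameters.

    Returns a list of ``(HumerusParams, sex)``; meshes are built lazily by
    :func:`generate_humerus` so statistical stages that need only the
    parameter values stay cheap.
    """
    df = draw_parameters(n_male, n_female, spec=spec, seed=seed)
    out = []
    for _, r in df.iterrows():
        p = HumerusParams.from_measurements(
            nsa_deg=r["NSA_3d"],
            hht_mm=r["HHT_3d"],
            casd_mm=r["cASD_3d"],
            aasd_mm=r["aASD_3d"],
            tsh_mm=r["TSH_3d"],
            mesh_edge_length=mesh_edge_length,
            seed=int(seed),
        )
        out.append((p, r["sex"]))
    return out


def simulate_raters(
    values=None,
    sigma_rater: float = 0.0,
    sigma_error: float = 0.0,
    n_raters: int = 3,
    n_sessions: int = 2,
    seed: int = 0,
    sigma_between: Optional[float] = None,
    n_subjects: Optional[int] = None,
) -> pd.DataFrame:
    """Two-way crossed measurement table: value = true + rater effect + error.

    ``values`` are per-subject true values; alternatively pass
    ``sigma_between`` and ``n_subjects`` to draw them from N(0, sigma^2).
    Returns a long table (subject, rater, session, value), reproducible
    for a given seed.
    """
    if sigma_rater < 0 or sigma_error < 0:
        raise ValidationError("noise SDs must be non-negative")
    rng = np.random.default_rng(seed)
    if values is None:
        if sigma_between is None or n_subjects is None:
            raise ValidationError(
                "either values or (sigma_between, n_subjects) must be given"
            )
        values = rng.normal(0.0, sigma_between, n_subjects)
    values = np.asarray(values, dtype=float)
    ns = len(values)
    rater_fx = rng.normal(0.0, sigma_rater, n_raters)
    rows = []
    for r in range(n_raters):
        for s in range(n_sessions):
            noise = rng.normal(0.0, sigma_error, ns)
            for i in range(ns):
                rows.append(
                    {
                        "subject": i,
                        "rater": r + 1,
                        "session": s + 1,
                        "value": values[i] + rater_fx[r] + noise[i],
                    }
                )
    return pd.DataFrame(rows)


def simulate_study(
    n_male: int = 54,
    n_female: int = 66,
    spec: CohortSpec = DEFAULT_COHORT_SPEC,
    seed: int = 0,
    n_reliability: int = 36,
    n_raters: int = 3,
) -> pd.DataFrame:
    """Simulate the full measurement campaign as a long cohort table.

    Every subject is measured once by the main examiner (rater 1,
    session 1) in both modalities; a random reliability subset is measured
    a second time by the main examiner (session 2) and once by each other
    examiner.  Columns: subject_id, sex, parameter, modality, rater,
    session, value.
    """
    rng = np.random.default_rng(seed)
    df = draw_parameters(n_male, n_female, spec=spec, seed=int(rng.integers(2**31)))
    n_total = len(df)
    n_rel = min(n_reliability, n_total)
    rel_ids = set(rng.choice(df["subject_id"].to_numpy(), size=n_rel, replace=False))

    # one additive effect per (rater, parameter, modality)
    combos = [(p, "3d") for p in PARAMS_3D] + [(p, "2d") for p in PARAMS_2D]
    rater_fx = {
        (r, p, mod): rng.normal(0.0, spec.noise_sd(p, mod)[0])
        for r in range(1, n_raters + 1)
        for (p, mod) in combos
    }
    # rater 1 is the reference examiner: no systematic offset
    for (p, mod) in combos:
        rater_fx[(1, p, mod)] = 0.0

    rows = []

    def measure(sid, sex, rater, session):
        r = df.loc[df["subject_id"] == sid].iloc[0]
        for p, mod in combos:
            true = r[f"{p}_{'3d' if mod == '3d' else '2d'}"]
            _, sig_e = spec.noise_sd(p, mod)
            rows.append(
                {
                    "subject_id": sid,
                    "sex": sex,
                    "parameter": p,
                    "modality": "3d" if mod == "3d" else "xray",
                    "rater": rater,
                    "session": session,
                    "value": true + rater_fx[(rater, p, mod)] + rng.normal(0.0, sig_e),
                }
            )

    for _, r in df.iterrows():
        measure(r["subject_id"], r["sex"], rater=1, session=1)
    for _, r in df.iterrows():
        if r["subject_id"] in rel_ids:
            measure(r["subject_id"], r["sex"], rater=1, session=2)
            for rr in range(2, n_raters + 1):
                measure(r["subject_id"], r["sex"], rater=rr, session=1)
    return pd.DataFrame(rows)


def anatomic_range_sweep(n: int = 20, mesh_edge_length: float = 0.5):
    """Deterministic parameter sweep spanning the reference anatomic ranges.

    NSA 120.5-142.6 deg, HHT 10.3-23.3 mm, cASD 36.3-52.3 mm swept jointly
    (respecting the physique correlation that makes extreme mixed combos
    geometrically impossible), with the AP scale and tuberosity offset
    cycling through their plausible ranges.
    """
    out = []
    for i in range(n):
        f = i / (n - 1) if n > 1 else 0.5
        nsa = 120.5 + f * (142.6 - 120.5)
        hht = 10.3 + f * (23.3 - 10.3)
        casd = 36.3 + f * (52.3 - 36.3)
        g_scale = 0.86 + 0.12 * (((i * 7) % n) / max(n - 1, 1))
        tsh = 3.8 + 11.1 * (((i * 3) % n) / max(n - 1, 1))
        out.append(
            HumerusParams.from_measurements(
                nsa_deg=nsa,
                hht_mm=hht,
                casd_mm=casd,
                aasd_mm=g_scale * casd,
                tsh_mm=tsh,
                mesh_edge_length=mesh_edge_length,
            )
        )
    return out
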