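"""Analytic voxel phantoms and morphology-linked synthetic survival cohorts.

The package's measurements (confluence demarcation, surface projection,
CCL/mDBLC, voxel volumes) are validated against phantoms whose ground truth is
known in closed form:

``slab``
    A box-shaped left atrium whose flat face is the plane z = 0, with a
    straight cylindrical confluence running parallel to the face at gap ``d``.
    Truth: CCL = L (tube length), DBLC = d uniformly, volumes are a box
    product and a cylinder.
``sphere_arc``
    A spherical atrium of radius R with the confluence bent along a concentric
    arc of radius R + g subtending angle theta. Truth: the projected curve is
    the concentric arc on the sphere, so CCL = R*theta, DBLC = g uniformly,
    confluence volume is the Pappus torus-sector form pi*r^2*(R+g)*theta.
``ellipsoid_tree``
    An ellipsoidal atrium with a straight confluence above one pole. Only the
    volumes have closed forms; gap/length truths are left NaN.

Each phantom carries four pulmonary vein stubs and a vertical vein (VV)
arranged as the supracardiac type Ia layout (right upper/inferior PVs joining
the confluence at one end, left upper PV and the VV at the other); the type Ib
layout mirrors the VV to the right side. Junction planes are realised exactly:
the confluence label occupies the region between the two planes orthogonal to
its axis at the attachment points, so the demarcation truth is by construction.

Truth quantities are always closed forms, never measured from the raster.

The synthetic cohort generator draws per-subject geometries whose analytic
iTVLC and CCL/mDBLC ratio span realistic infant ranges, then simulates
right-censored PPVS times whose hazard is log-linear in those two markers.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .io import LabelSchema, LabelVolume, PatientRecord, Role

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "PhantomConfigError",
    "make_phantom",
    "make_synthetic_cohort",
    "cohort_truth_frame",
]


class PhantomConfigError(ValueError):
    """Invalid or unresolvable phantom geometry."""


@dataclasses.dataclass
class PhantomConfig:
    """Geometry of one phantom; defaults reproduce the reference slab case."""

    kind: str = "slab"                       # slab | sphere_arc | ellipsoid_tree
    spacing: float = 0.5                     # isotropic voxel edge, mm

    # --- left atrium ---
    slab_extent: tuple[float, float, float] = (40.0, 10.0, 20.0)
    #: (x width, extra y margin beyond the confluence span, z thickness), mm
    la_radius: float = 20.0                  # sphere_arc LA radius, mm
    la_axes: tuple[float, float, float] = (20.0, 20.0, 20.0)  # ellipsoid semi-axes

    # --- confluence ---
    confluence_length: float = 30.0          # slab/ellipsoid tube length L, mm
    gap: float = 3.0                         # slab d / sphere g / ellipsoid pole gap, mm
    r_confluence: float = 2.5                # tube radius, mm
    theta: float = 1.0                       # sphere_arc subtended angle, rad

    # --- vein stubs ---
    pv_radius: float = 1.5
    pv_length: float = 10.0
    vv_radius: float = 1.75
    vv_length: float = 12.0

    vv_side: str = "left"                    # left = type Ia, right = type Ib
    strict: bool = True                      # escalate resolution warnings
    allow_degenerate: bool = False           # permit gap <= r_confluence (g -> 0 tests)
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in ("slab", "sphere_arc", "ellipsoid_tree"):
            raise PhantomConfigError(f"unknown phantom kind {self.kind!r}")
        if self.spacing <= 0:
            raise PhantomConfigError("spacing must be > 0")
        if self.vv_side not in ("left", "right"):
            raise PhantomConfigError(f"vv_side must be left|right, got {self.vv_side!r}")
        if self.gap <= 0 and not self.allow_degenerate:
            raise PhantomConfigError("gap must be > 0 (set allow_degenerate for g->0 tests)")
        if self.r_confluence >= self.gap and not self.allow_degenerate:
            raise PhantomConfigError(
                f"confluence tube (r={self.r_confluence}) would intersect the LA "
                f"label (gap={self.gap})"
            )
        min_r = min(self.r_confluence, self.pv_radius, self.vv_radius)
        if self.strict and min_r < 2.0 * self.spacing:
            raise PhantomConfigError(
                f"tube radius {min_r} mm < 2*spacing ({2 * self.spacing} mm): "
                "under-resolved; refine spacing or disable strict mode"
            )


@dataclasses.dataclass
class PhantomTruth:
    """Closed-form ground truth attached to a phantom."""

    la_volume_cm3: float
    confluence_volume_cm3: float
    centerline: np.ndarray            # true confluence centerline polyline, world mm
    ccl_mm: float                     # true corresponding confluence length
    dblc_mm: float                    # true uniform LA-confluence gap
    junction_right: np.ndarray        # world mm, RUPV/RIPV end (Ia)
    junction_left: np.ndarray         # world mm, LUPV/VV end (Ia)


# ---------------------------------------------------------------------------
# rasterization helpers
# ---------------------------------------------------------------------------

def _grid(lo: np.ndarray, hi: np.ndarray, sp: float, pad: int = 3):
    """Voxel-center grid covering [lo, hi] with centers at half-spacing offsets."""
    k0 = np.floor(lo / sp).astype(int) - pad
    k1 = np.ceil(hi / sp).astype(int) + pad
    shape = tuple((k1 - k0).astype(int))
    origin = k0 * sp + sp / 2.0
    axes = [origin[i] + np.arange(shape[i]) * sp for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    return origin, shape, X, Y, Z


def _dist_to_segment(X, Y, Z, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each grid point to segment ab."""
    ab = b - a
    L2 = float(ab @ ab)
    px, py, pz = X - a[0], Y - a[1], Z - a[2]
    t = np.clip((px * ab[0] + py * ab[1] + pz * ab[2]) / L2, 0.0, 1.0)
    return np.sqrt(
        (px - t * ab[0]) ** 2 + (py - t * ab[1]) ** 2 + (pz - t * ab[2]) ** 2
    )


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _stub(X, Y, Z, base: np.ndarray, direction, length: float, radius: float):
    """(mask, radius-normalized distance) for a tube around a segment."""
    d = _dist_to_segment(X, Y, Z, base, base + _unit(direction) * length)
    return d <= radius, d / radius


def _masked_stub(X, Y, Z, base, direction, length, radius, la_mask):
    mask, d = _stub(X, Y, Z, base, direction, length, radius)
    return mask & ~la_mask, d


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

def make_phantom(config: PhantomConfig) -> tuple[LabelVolume, PhantomTruth]:
    """Rasterize a phantom and return it with its closed-form truth.

    Label precedence: LA, then confluence, then vein stubs — so the confluence
    label spans exactly the region between the two junction planes and the
    stub labels meet it across those planes.
    """
    config.validate()
    if config.kind == "slab":
        vol, truth = _make_slab(config)
    elif config.kind == "sphere_arc":
        vol, truth = _make_sphere_arc(config)
    else:
        vol, truth = _make_ellipsoid(config)
    return vol, truth


def _paint(labels: np.ndarray, mask: np.ndarray, value: int) -> None:
    labels[mask & (labels == 0)] = value


def _assemble(
    shape, origin, sp, la_mask, conf_mask,
    stubs: dict[Role, tuple[np.ndarray, np.ndarray]],
) -> LabelVolume:
    schema = LabelSchema()
    labels = np.zeros(shape, dtype=np.uint8)
    _paint(labels, la_mask, schema[Role.LA])
    _paint(labels, conf_mask, schema[Role.PVC])
    # voxels inside several stubs go to the nearest axis (radius-normalized),
    # so stubs sharing an attachment point split the contact surface fairly
    roles = list(stubs)
    dist = np.stack([np.where(stubs[r][0], stubs[r][1], np.inf) for r in roles])
    any_stub = np.isfinite(dist).any(axis=0)
    winner = np.argmin(dist, axis=0)
    for k, role in enumerate(roles):
        _paint(labels, any_stub & (winner == k), schema[role])
    _absorb_crumbs(labels, [schema[r] for r in roles])
    return LabelVolume(
        voxels=labels, spacing=(sp, sp, sp), origin=tuple(origin), schema=schema
    )


def _absorb_crumbs(labels: np.ndarray, stub_values: list[int]) -> None:
    """Reassign small disconnected fragments of stub labels (paint-order
    interleaving artifacts) to the dominant adjacent label."""
    from scipy import ndimage

    struct = ndimage.generate_binary_structure(3, 1)
    for val in stub_values:
        mask = labels == val
        comp, n = ndimage.label(mask, structure=struct)
        if n <= 1:
            continue
        sizes = ndimage.sum_labels(mask, comp, index=range(1, n + 1))
        main = int(np.argmax(sizes)) + 1
        for ci in range(1, n + 1):
            if ci == main:
                continue
            frag = comp == ci
            ring = ndimage.binary_dilation(frag, structure=struct) & ~frag
            neigh = labels[ring]
            neigh = neigh[(neigh != 0) & (neigh != val)]
            labels[frag] = np.bincount(neigh).argmax() if neigh.size else 0


def _slab_stub_layout(config: PhantomConfig, d: float, L: float):
    """Stub bases/directions for the slab frame (confluence along +y at z=d)."""
    right_end = np.array([0.0, 0.0, d])     # y = 0 end
    left_end = np.array([0.0, L, d])        # y = L end
    mid = np.array([0.0, 0.65 * L, d])
    if config.vv_side == "left":            # type Ia
        layout = {
            Role.RUPV: (right_end, (+0.5, -1.0, +0.5)),
            Role.RIPV: (right_end, (-0.5, -1.0, +0.5)),
            Role.LUPV: (left_end, (-0.5, +1.0, +0.5)),
            Role.VV: (left_end, (+0.4, +1.0, +1.2)),
            Role.LIPV: (mid, (-0.7, +0.2, +0.7)),
        }
    else:                                   # type Ib: VV mirrored to the right end
        layout = {
            Role.RUPV: (right_end, (+0.5, -1.0, +0.5)),
            Role.VV: (right_end, (-0.4, -1.0, +1.2)),
            Role.LUPV: (left_end, (-0.5, +1.0, +0.5)),
            Role.LIPV: (left_end, (+0.5, +1.0, +0.5)),
            Role.RIPV: (mid, (+0.7, -0.2, +0.7)),
        }
    return layout, right_end, left_end


def _make_slab(config: PhantomConfig) -> tuple[LabelVolume, PhantomTruth]:
    sp = config.spacing
    L, d, rc = config.confluence_length, config.gap, config.r_confluence
    wx, my, tz = config.slab_extent
    reach = max(config.pv_length, config.vv_length) + 4.0
    lo = np.array([-max(wx / 2, reach), -my - reach, -tz])
    hi = np.array([max(wx / 2, reach), L + my + reach, d + rc + reach])
    origin, shape, X, Y, Z = _grid(lo, hi, sp)

    la = (np.abs(X) <= wx / 2) & (Y >= -my) & (Y <= L + my) & (Z <= 0) & (Z >= -tz)
    a, b = np.array([0.0, 0.0, d]), np.array([0.0, L, d])
    conf = (_dist_to_segment(X, Y, Z, a, b) <= rc) & (Y >= 0) & (Y <= L)
    conf &= ~la
    layout, j_right, j_left = _slab_stub_layout(config, d, L)
    stubs = {
        role: _masked_stub(
            X, Y, Z, base, u,
            config.vv_length if role is Role.VV else config.pv_length,
            config.vv_radius if role is Role.VV else config.pv_radius,
            la,
        )
        for role, (base, u) in layout.items()
    }
    vol = _assemble(shape, origin, sp, la, conf, stubs)
    n_pts = max(int(round(L / sp)) + 1, 2)
    center = np.stack(
        [np.zeros(n_pts), np.linspace(0.0, L, n_pts), np.full(n_pts, d)], axis=1
    )
    truth = PhantomTruth(
        la_volume_cm3=wx * (L + 2 * my) * tz / 1000.0,
        confluence_volume_cm3=math.pi * rc**2 * L / 1000.0,
        centerline=center,
        ccl_mm=L,
        dblc_mm=d,
        junction_right=j_right,
        junction_left=j_left,
    )
    return vol, truth


def _make_sphere_arc(config: PhantomConfig) -> tuple[LabelVolume, PhantomTruth]:
    sp = config.spacing
    R, g, th, rc = config.la_radius, config.gap, config.theta, config.r_confluence
    Ra = R + g
    reach = max(config.pv_length, config.vv_length) + 4.0
    lim = Ra + rc + reach
    lo = np.array([-R - 2.0, -R - 2.0, -lim])
    hi = np.array([lim, lim, lim])
    origin, shape, X, Y, Z = _grid(lo, hi, sp)

    la = X**2 + Y**2 + Z**2 <= R**2
    phi = np.arctan2(Y, X)
    rxy = np.hypot(X, Y)
    conf = (np.sqrt((rxy - Ra) ** 2 + Z**2) <= rc) & (phi >= 0.0) & (phi <= th)
    conf &= ~la

    def arc_point(p):
        return np.array([Ra * math.cos(p), Ra * math.sin(p), 0.0])

    j_right, j_left = arc_point(0.0), arc_point(th)
    e_r0, e_t0 = _unit(j_right), np.array([0.0, -1.0, 0.0])   # outward continuation
    e_r1 = _unit(j_left)
    e_t1 = np.array([-math.sin(th), math.cos(th), 0.0])
    ez = np.array([0.0, 0.0, 1.0])
    mid = arc_point(0.65 * th)
    if config.vv_side == "left":
        layout = {
            Role.RUPV: (j_right, e_t0 + 0.4 * e_r0 + 0.5 * ez),
            Role.RIPV: (j_right, e_t0 + 0.4 * e_r0 - 0.5 * ez),
            Role.LUPV: (j_left, e_t1 + 0.4 * e_r1 - 0.5 * ez),
            Role.VV: (j_left, e_t1 + 0.3 * e_r1 + 1.2 * ez),
            Role.LIPV: (mid, _unit(mid) + 0.6 * ez),
        }
    else:
        layout = {
            Role.RUPV: (j_right, e_t0 + 0.4 * e_r0 - 0.5 * ez),
            Role.VV: (j_right, e_t0 + 0.3 * e_r0 + 1.2 * ez),
            Role.LUPV: (j_left, e_t1 + 0.4 * e_r1 - 0.5 * ez),
            Role.LIPV: (j_left, e_t1 + 0.4 * e_r1 + 0.5 * ez),
            Role.RIPV: (mid, _unit(mid) + 0.6 * ez),
        }
    stubs = {
        role: _masked_stub(
            X, Y, Z, base, u,
            config.vv_length if role is Role.VV else config.pv_length,
            config.vv_radius if role is Role.VV else config.pv_radius,
            la,
        )
        for role, (base, u) in layout.items()
    }
    vol = _assemble(shape, origin, sp, la, conf, stubs)
    n_pts = max(int(round(Ra * th / sp)) + 1, 2)
    phis = np.linspace(0.0, th, n_pts)
    center = np.stack(
        [Ra * np.cos(phis), Ra * np.sin(phis), np.zeros(n_pts)], axis=1
    )
    truth = PhantomTruth(
        la_volume_cm3=4.0 / 3.0 * math.pi * R**3 / 1000.0,
        confluence_volume_cm3=math.pi * rc**2 * Ra * th / 1000.0,  # Pappus
        centerline=center,
        ccl_mm=R * th,
        dblc_mm=g,
        junction_right=j_right,
        junction_left=j_left,
    )
    return vol, truth


def _make_ellipsoid(config: PhantomConfig) -> tuple[LabelVolume, PhantomTruth]:
    sp = config.spacing
    a, b, c = config.la_axes
    L, d, rc = config.confluence_length, config.gap, config.r_confluence
    z0 = c + d
    reach = max(config.pv_length, config.vv_length) + 4.0
    lo = np.array([-a - reach, min(-b, -L / 2) - reach, -c - 2.0])
    hi = np.array([a + reach, max(b, L / 2) + reach, z0 + rc + reach])
    origin, shape, X, Y, Z = _grid(lo, hi, sp)

    la = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0
    p0, p1 = np.array([0.0, -L / 2, z0]), np.array([0.0, L / 2, z0])
    conf = (_dist_to_segment(X, Y, Z, p0, p1) <= rc) & (Y >= -L / 2) & (Y <= L / 2)
    conf &= ~la
    layout, _, _ = _slab_stub_layout(config, z0, L)
    # recenter the slab layout's y span [0, L] onto [-L/2, L/2]
    shift = np.array([0.0, -L / 2, 0.0])
    stubs = {
        role: _masked_stub(
            X, Y, Z, base + shift, u,
            config.vv_length if role is Role.VV else config.pv_length,
            config.vv_radius if role is Role.VV else config.pv_radius,
            la,
        )
        for role, (base, u) in layout.items()
    }
    vol = _assemble(shape, origin, sp, la, conf, stubs)
    n_pts = max(int(round(L / sp)) + 1, 2)
    center = np.stack(
        [np.zeros(n_pts), np.linspace(-L / 2, L / 2, n_pts), np.full(n_pts, z0)],
        axis=1,
    )
    truth = PhantomTruth(
        la_volume_cm3=4.0 / 3.0 * math.pi * a * b * c / 1000.0,
        confluence_volume_cm3=math.pi * rc**2 * L / 1000.0,
        centerline=center,
        ccl_mm=float("nan"),     # projection onto an ellipsoid has no closed form
        dblc_mm=float("nan"),
        junction_right=p0,
        junction_left=p1,
    )
    return vol, truth


# ---------------------------------------------------------------------------
# synthetic survival cohorts
# ---------------------------------------------------------------------------

#: default parameter ranges for cohort geometries (documented stand-ins: the
#: marker ranges bracket the observed medians iTVLC ~ 20 cm^3/m^2 and
#: CCL/mDBLC ~ 7.6 with quartiles ~ (4.9, 11.5))
COHORT_RANGES = {
    "itvlc": (10.0, 30.0),        # cm^3/m^2
    "ratio": (3.0, 13.0),         # dimensionless
    "gap": (1.2, 2.0),            # mm, brackets the observed mDBLC ~ 1.5
    "bsa": (0.20, 0.34),          # m^2, infant range around median 0.26
    "slab_width": 20.0,           # mm, fixed LA face width
    "slab_margin": 5.0,           # mm beyond the confluence span
    "r_confluence": 1.0,          # mm (cohort phantoms are small)
    "prepvo_prob": 0.34,          # observed prePVO prevalence
    "age_log_mean": math.log(61.0),   # median age 61 days
    "age_log_sd": 0.8,
}

#: marker centering used inside the simulated hazard (see module docstring)
HAZARD_CENTER = {"itvlc": 20.0, "ratio": 8.0}


def _cohort_config(itvlc, ratio, gap, bsa, rng) -> PhantomConfig:
    """Slab geometry whose analytic markers equal the drawn (itvlc, ratio)."""
    L = ratio * gap
    rc = COHORT_RANGES["r_confluence"]
    v_conf = math.pi * rc**2 * L                      # mm^3
    v_la = itvlc * bsa * 1000.0 - v_conf              # mm^3
    if v_la <= 0:
        raise PhantomConfigError("infeasible cohort geometry: non-positive LA volume")
    wx = COHORT_RANGES["slab_width"]
    my = COHORT_RANGES["slab_margin"]
    tz = v_la / (wx * (L + 2 * my))                   # thickness from volume
    return PhantomConfig(
        kind="slab",
        spacing=0.5,
        slab_extent=(wx, my, tz),
        confluence_length=L,
        gap=gap,
        r_confluence=rc,
        pv_radius=1.0,
        pv_length=6.0,
        vv_radius=1.0,
        vv_length=7.0,
        strict=False,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def make_synthetic_cohort(
    n: int,
    effect_itvlc: float = -0.15,
    effect_ratio: float = -0.10,
    censor_rate: float = 0.3,
    seed: int = 0,
    baseline_hazard: float = 0.03,
) -> list[tuple[PhantomConfig, PatientRecord]]:
    """Draw ``n`` phantom geometries with exponential PPVS times.

    The hazard is log-linear in the analytic markers,
    ``h_i = h0 * exp(b1*(iTVLC_i - 20) + b2*(ratio_i - 8))`` per month
    (centering only rescales the baseline; Cox estimates of b1, b2 are
    unaffected). Censoring is independent uniform on (0, tau) with tau
    calibrated on the drawn sample so the censored fraction is ~``censor_rate``;
    ``censor_rate=0`` yields a fully observed cohort. Deterministic for a
    fixed seed.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not (0.0 <= censor_rate < 1.0):
        raise ValueError(f"censor_rate must be in [0, 1), got {censor_rate}")
    if not (np.isfinite(effect_itvlc) and np.isfinite(effect_ratio)):
        raise ValueError("effects must be finite")
    rng = np.random.default_rng(seed)
    itvlc = rng.uniform(*COHORT_RANGES["itvlc"], size=n)
    ratio = rng.uniform(*COHORT_RANGES["ratio"], size=n)
    gap = rng.uniform(*COHORT_RANGES["gap"], size=n)
    bsa = rng.uniform(*COHORT_RANGES["bsa"], size=n)
    age = np.exp(
        rng.normal(COHORT_RANGES["age_log_mean"], COHORT_RANGES["age_log_sd"], size=n)
    )
    prepvo = rng.random(n) < COHORT_RANGES["prepvo_prob"]

    lp = effect_itvlc * (itvlc - HAZARD_CENTER["itvlc"]) + effect_ratio * (
        ratio - HAZARD_CENTER["ratio"]
    )
    rate = baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)

    if censor_rate == 0.0:
        time, event = t_event, np.ones(n, dtype=bool)
    else:
        u = rng.random(n)

        def censored_frac(tau: float) -> float:
            return float(np.mean(u * tau < t_event))

        lo_t, hi_t = 1e-6, float(t_event.max()) * 2
        while censored_frac(hi_t) > censor_rate and hi_t < 1e9:
            hi_t *= 2
        for _ in range(80):
            mid = 0.5 * (lo_t + hi_t)
            if censored_frac(mid) > censor_rate:
                lo_t = mid
            else:
                hi_t = mid
        c = u * 0.5 * (lo_t + hi_t)
        event = t_event <= c
        time = np.where(event, t_event, c)

    out: list[tuple[PhantomConfig, PatientRecord]] = []
    for i in range(n):
        cfg = _cohort_config(itvlc[i], ratio[i], gap[i], bsa[i], rng)
        rec = PatientRecord(
            id=f"S{i:04d}",
            age_days=float(age[i]),
            bsa_m2=float(bsa[i]),
            prepvo=bool(prepvo[i]),
            time_months=float(time[i]),
            event=bool(event[i]),
            covariates={"itvlc_true": float(itvlc[i]), "ratio_true": float(ratio[i])},
        )
        out.append((cfg, rec))
    return out


def cohort_truth_frame(cohort: Sequence[tuple[PhantomConfig, PatientRecord]]):
    """Analytic marker values and outcomes as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for cfg, rec in cohort:
        rows.append(
            {
                "id": rec.id,
                "itvlc": rec.covariates["itvlc_true"],
                "ratio": rec.covariates["ratio_true"],
                "age_days": rec.age_days,
                "bsa_m2": rec.bsa_m2,
                "prepvo": float(rec.prepvo),
                "time_months": rec.time_months,
                "event": bool(rec.event),
            }
        )
    return pd.DataFrame(rows)
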