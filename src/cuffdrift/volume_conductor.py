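"""Cuff/nerve geometry and analytic leadfield computation.

The nerve is modeled as a straight cylinder along z (mm), concentric with a
56-contact cuff (7 rings x 8 contacts on the inner cuff surface).  Three
fascicles (tibial, peroneal, sural) sit inside the epineurium, each wrapped in
a perineurium shell.  Encapsulation tissue grows as an annulus between the
epineurium and the cuff, parameterized by a fill fraction in [0, 1].

The leadfield maps a unit source current at a position inside the nerve to the
potential at each contact.  Instead of a finite-element solve, each
(source, contact) gain is approximated as a point source in an effective
homogeneous medium,

    gain(i, j) = 1 / (4 pi sigma_eff(i, j) d(i, j)),

where d is the Euclidean source-contact distance (converted to meters) and
sigma_eff is the length-weighted series (harmonic-mean) conductivity along the
straight segment from source j to contact i, split at its intersections with
the nested layer boundaries.  The anisotropic endoneurium uses

    sigma(alpha) = sigma_long * cos^2(alpha) + sigma_rad * sin^2(alpha)

for the angle alpha between the segment and the nerve axis.  This straight-ray
approximation preserves the geometry, conductivity and perturbation
dependence of the potentials; it is not a reproduction of a full FEM solution.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CuffGeometry",
    "Fascicle",
    "TissueModel",
    "Leadfield",
    "DEFAULT_FASCICLES",
    "DEFAULT_CONDUCTIVITIES",
    "ENCAPSULATION_LEVELS",
    "build_contact_positions",
    "compute_leadfield",
    "apply_encapsulation",
    "rotation_permutation",
    "channel_ring_slot",
]

#: Conductivities in S/m for each tissue layer.
DEFAULT_CONDUCTIVITIES: dict[str, float] = {
    "endoneurium_radial": 8.26e-2,
    "endoneurium_longitudinal": 5.71e-1,
    "perineurium": 2.10e-3,
    "epineurium": 8.26e-2,
    "encapsulation": 6.59e-2,
    "saline": 2.00e-1,
    "cuff": 1.00e-7,
}

#: Named encapsulation-growth time points mapped to annulus fill fractions.
ENCAPSULATION_LEVELS: dict[str, float] = {
    "Base": 0.0,
    "ET1": 1.0 / 3.0,
    "ET2": 2.0 / 3.0,
    "ET3": 1.0,
}


def _default_ring_positions(n_rings: int, cuff_length_mm: float, margin_mm: float = 1.5):
    return tuple(np.linspace(margin_mm, cuff_length_mm - margin_mm, n_rings))


@dataclass(frozen=True)
class CuffGeometry:
    """Multi-contact nerve cuff: ``n_rings`` rings of ``contacts_per_ring``
    contacts on the inner surface of a cylinder of radius ``cuff_radius_mm``.

    All lengths are in mm; z runs along the nerve axis with z=0 at the
    proximal cuff edge.  Angles are degrees counter-clockwise viewed from the
    proximal end.  Channels are numbered ring-major (ring 1 proximal, 8
    angular slots per ring), giving 56 channels with the defaults.
    """

    n_rings: int = 7
    contacts_per_ring: int = 8
    cuff_radius_mm: float = 0.8  # 800 um
    cuff_length_mm: float = 23.0
    ring_axial_positions_mm: tuple[float, ...] = field(default=None)  # type: ignore[assignment]
    rotation_offset_deg: float = 0.0

    def __post_init__(self):
        if self.ring_axial_positions_mm is None:
            object.__setattr__(
                self,
                "ring_axial_positions_mm",
                _default_ring_positions(self.n_rings, self.cuff_length_mm),
            )
        if self.n_rings < 1 or self.contacts_per_ring < 1:
            raise ValueError("need at least one ring and one contact per ring")
        if len(self.ring_axial_positions_mm) != self.n_rings:
            raise ValueError("ring_axial_positions_mm length must equal n_rings")
        z = np.asarray(self.ring_axial_positions_mm, dtype=float)
        if np.any(z < 0) or np.any(z > self.cuff_length_mm):
            raise ValueError("ring positions must lie within [0, cuff_length]")

    @property
    def n_channels(self) -> int:
        return self.n_rings * self.contacts_per_ring

    @property
    def slot_angle_deg(self) -> float:
        return 360.0 / self.contacts_per_ring

    @property
    def contact_angles_deg(self) -> np.ndarray:
        """Canonical (rotation 0) angle of each angular slot."""
        return self.rotation_offset_deg + self.slot_angle_deg * np.arange(self.contacts_per_ring)


def channel_ring_slot(geometry: CuffGeometry, channel: int) -> tuple[int, int]:
    """Map a ring-major channel index to its 0-based (ring, angular slot)."""
    if not 0 <= channel < geometry.n_channels:
        raise ValueError(f"channel {channel} out of range")
    return divmod(channel, geometry.contacts_per_ring)


@dataclass(frozen=True)
class Fascicle:
    """One fascicle: a cylinder parallel to the nerve axis.

    ``radius_mm`` is the outer (perineurium) radius; the endoneurium core has
    radius ``radius_mm - perineurium_thickness``.
    """

    name: str
    center_offset_mm: float
    center_angle_deg: float
    radius_mm: float

    @property
    def center_xy(self) -> tuple[float, float]:
        a = np.deg2rad(self.center_angle_deg)
        return (self.center_offset_mm * np.cos(a), self.center_offset_mm * np.sin(a))


DEFAULT_FASCICLES: tuple[Fascicle, ...] = (
    Fascicle("tibial", 0.30, 90.0, 0.35),
    Fascicle("peroneal", 0.35, 210.0, 0.25),
    Fascicle("sural", 0.40, 330.0, 0.15),
)


@dataclass(frozen=True)
class TissueModel:
    """Layered tissue model of the cuffed nerve segment.

    ``encapsulation_fill`` linearly fills the annulus between the epineurium
    and the cuff: the encapsulation boundary sits at
    ``epineurium_radius + fill * (cuff_radius - epineurium_radius)``, with
    saline beyond it.
    """

    fascicles: tuple[Fascicle, ...] = DEFAULT_FASCICLES
    perineurium_thickness_mm: float = 0.065
    epineurium_radius_mm: float = 0.70
    conductivities: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CONDUCTIVITIES))
    encapsulation_fill: float = 0.0

    def __post_init__(self):
        missing = set(DEFAULT_CONDUCTIVITIES) - set(self.conductivities)
        if missing:
            raise ValueError(f"missing conductivities: {sorted(missing)}")
        for k, v in self.conductivities.items():
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"conductivity {k!r} must be finite and > 0")
        if not 0.0 <= self.encapsulation_fill <= 1.0:
            raise ValueError("encapsulation_fill must lie in [0, 1]")
        for f in self.fascicles:
            if f.center_offset_mm + f.radius_mm > self.epineurium_radius_mm:
                raise ValueError(f"fascicle {f.name!r} extends outside the epineurium")
            if f.radius_mm <= self.perineurium_thickness_mm:
                raise ValueError(f"fascicle {f.name!r} thinner than its perineurium")

    def fascicle(self, name: str) -> Fascicle:
        for f in self.fascicles:
            if f.name == name:
                return f
        raise KeyError(name)

    def encapsulation_radius_mm(self, cuff_radius_mm: float) -> float:
        gap = cuff_radius_mm - self.epineurium_radius_mm
        return self.epineurium_radius_mm + self.encapsulation_fill * gap


def apply_encapsulation(tissue: TissueModel, fill: float) -> TissueModel:
    """Return a copy of ``tissue`` with the encapsulation fill replaced."""
    if not np.isfinite(fill) or not 0.0 <= fill <= 1.0:
        raise ValueError(f"encapsulation fill must lie in [0, 1], got {fill}")
    return dataclasses.replace(tissue, encapsulation_fill=float(fill))


def build_contact_positions(geometry: CuffGeometry, rotation_deg: float = 0.0) -> np.ndarray:
    """3-D positions (mm) of all contacts, ring-major, rotated by ``rotation_deg``.

    Rotation adds the same angle to every contact (the cuff rotates rigidly
    around the nerve axis); axial positions are unchanged.
    """
    if not np.isfinite(rotation_deg):
        raise ValueError("rotation_deg must be finite")
    if not 0.0 <= rotation_deg < 360.0:
        raise ValueError(f"rotation_deg must lie in [0, 360), got {rotation_deg}")
    angles = np.deg2rad(geometry.contact_angles_deg + rotation_deg)
    out = np.empty((geometry.n_channels, 3))
    R = geometry.cuff_radius_mm
    for r, z in enumerate(geometry.ring_axial_positions_mm):
        rows = slice(r * geometry.contacts_per_ring, (r + 1) * geometry.contacts_per_ring)
        out[rows, 0] = R * np.cos(angles)
        out[rows, 1] = R * np.sin(angles)
        out[rows, 2] = z
    return out


def rotation_permutation(geometry: CuffGeometry, k_slots: int) -> np.ndarray:
    """Channel permutation ``p`` with ``L_rot[c] == L_0[p[c]]`` for a rigid
    rotation by ``k_slots`` angular slots (k * 45 deg with the defaults).

    After rotating by k slots, the contact in (ring r, slot s) occupies the
    canonical position of slot s+k, so its leadfield row equals the
    rotation-0 row of channel (r, s+k mod contacts_per_ring).
    """
    if not 0 <= k_slots < geometry.contacts_per_ring:
        raise ValueError("k_slots must lie in [0, contacts_per_ring)")
    cpr = geometry.contacts_per_ring
    perm = np.empty(geometry.n_channels, dtype=int)
    for c in range(geometry.n_channels):
        r, s = divmod(c, cpr)
        perm[c] = r * cpr + (s + k_slots) % cpr
    return perm


@dataclass(frozen=True)
class Leadfield:
    """Gain matrix (M channels x N sources, ohms) for unit source currents."""

    gains: np.ndarray
    source_positions_mm: np.ndarray
    rotation_deg: float = 0.0
    encapsulation_fill: float = 0.0

    def __post_init__(self):
        if self.gains.shape[1] != self.source_positions_mm.shape[0]:
            raise ValueError("gains columns must match number of source positions")
        if not np.all(np.isfinite(self.gains)):
            raise ValueError("leadfield gains must be finite")

    @property
    def n_channels(self) -> int:
        return self.gains.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gains.shape[1]


def _cylinder_crossings(p_xy, v_xy, center, radius):
    """Segment parameters t where p + t v crosses an axis-parallel cylinder.

    Returns an (N, 2) array; non-crossing entries are 0 (zero-length segment
    boundaries at the start, harmless after sorting).
    """
    rel = p_xy - np.asarray(center)
    a = np.einsum("ij,ij->i", v_xy, v_xy)
    b = 2.0 * np.einsum("ij,ij->i", rel, v_xy)
    c = np.einsum("ij,ij->i", rel, rel) - radius * radius
    disc = b * b - 4.0 * a * c
    out = np.zeros((p_xy.shape[0], 2))
    ok = (disc > 0) & (a > 0)
    sq = np.sqrt(disc[ok])
    out[ok, 0] = (-b[ok] - sq) / (2.0 * a[ok])
    out[ok, 1] = (-b[ok] + sq) / (2.0 * a[ok])
    return np.clip(out, 0.0, 1.0)


def compute_leadfield(
    geometry: CuffGeometry,
    tissue: TissueModel,
    source_positions_mm: np.ndarray,
    rotation_deg: float = 0.0,
) -> Leadfield:
    """Compute the leadfield for point sources inside the nerve.

    Every source must lie strictly inside the epineurium.  See the module
    docstring for the straight-ray series-conductivity approximation.
    """
    src = np.atleast_2d(np.asarray(source_positions_mm, dtype=float))
    if src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("source positions must be an (N, 3) array")
    if not np.all(np.isfinite(src)):
        raise ValueError("source positions must be finite")
    r_src = np.hypot(src[:, 0], src[:, 1])
    if np.any(r_src >= tissue.epineurium_radius_mm):
        raise ValueError("all sources must lie strictly inside the epineurium")
    if tissue.epineurium_radius_mm >= geometry.cuff_radius_mm:
        raise ValueError("epineurium radius must be smaller than the cuff radius")

    contacts = build_contact_positions(geometry, rotation_deg)
    cond = tissue.conductivities
    r_enc = tissue.encapsulation_radius_mm(geometry.cuff_radius_mm)
    peri = tissue.perineurium_thickness_mm

    # Boundary cylinders: per fascicle the endoneurium core and perineurium
    # outer surface, then the epineurium and the encapsulation front.
    cylinders = []
    for f in tissue.fascicles:
        cx, cy = f.center_xy
        cylinders.append(((cx, cy), f.radius_mm - peri))
        cylinders.append(((cx, cy), f.radius_mm))
    cylinders.append(((0.0, 0.0), tissue.epineurium_radius_mm))
    cylinders.append(((0.0, 0.0), r_enc))

    n_src = src.shape[0]
    gains = np.empty((geometry.n_channels, n_src))
    p_xy = src[:, :2]

    for i, cpos in enumerate(contacts):
        d_vec = cpos[None, :] - src
        d = np.linalg.norm(d_vec, axis=1)
        if np.any(d == 0):
            raise ValueError("zero source-contact distance")
        cos2_alpha = (d_vec[:, 2] / d) ** 2
        sigma_endo = (
            cond["endoneurium_longitudinal"] * cos2_alpha
            + cond["endoneurium_radial"] * (1.0 - cos2_alpha)
        )

        v_xy = d_vec[:, :2]
        ts = [np.zeros((n_src, 1)), np.ones((n_src, 1))]
        for center, radius in cylinders:
            ts.append(_cylinder_crossings(p_xy, v_xy, center, radius))
        ts = np.sort(np.concatenate(ts, axis=1), axis=1)
        mid = 0.5 * (ts[:, 1:] + ts[:, :-1])  # (N, K) midpoints
        seg = np.diff(ts, axis=1) * d[:, None]  # segment lengths, mm

        mx = p_xy[:, 0:1] + mid * v_xy[:, 0:1]
        my = p_xy[:, 1:2] + mid * v_xy[:, 1:2]
        r_mid = np.hypot(mx, my)

        sigma = np.where(
            r_mid < tissue.epineurium_radius_mm,
            cond["epineurium"],
            np.where(r_mid < r_enc, cond["encapsulation"], cond["saline"]),
        )
        for f in tissue.fascicles:
            cx, cy = f.center_xy
            rf = np.hypot(mx - cx, my - cy)
            sigma = np.where(rf < f.radius_mm, cond["perineurium"], sigma)
            sigma = np.where(rf < f.radius_mm - peri, sigma_endo[:, None], sigma)

        resistance_mm = (seg / sigma).sum(axis=1)  # mm per (S/m)
        sigma_eff = d / resistance_mm
        gains[i] = 1.0 / (4.0 * np.pi * sigma_eff * d * 1e-3)

    return Leadfield(
        gains=gains,
        source_positions_mm=src,
        rotation_deg=float(rotation_deg),
        encapsulation_fill=tissue.encapsulation_fill,
    )
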