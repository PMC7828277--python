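"""Compound action potential (CAP) simulation on the cuff leadfield.

A CAP is modeled as a charge-balanced current waveform fired simultaneously
by every node of Ranvier along a fascicular pathway, with a constant
conduction delay s_k / v between nodes (all fibers of the pathway firing in
perfect synchrony, so the compound shape is a scaled single-fiber shape).
Channel potentials are the leadfield-weighted sum of the delayed node
currents.  Recordings are tripole-referenced by subtracting the mean of the
two outer contact rings, then assembled into long time series and corrupted
with white Gaussian noise at a prescribed whole-series SNR.

Fiber classes follow the large myelinated afferents of the rat sciatic
nerve: A-alpha (tibial, peroneal) with 1.70 mm node spacing and 94.86 m/s,
A-beta (sural) with 1.16 mm spacing and 64.72 m/s.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .volume_conductor import CuffGeometry, Leadfield, TissueModel, compute_leadfield

__all__ = [
    "SAMPLING_RATE_HZ",
    "FiberSpec",
    "FIBER_CLASSES",
    "PATHWAY_FIBER_CLASS",
    "PATHWAY_LABELS",
    "SourceTemplate",
    "NodeSet",
    "PathwaySpec",
    "MultiChannelRecording",
    "CapBank",
    "default_pathway",
    "place_nodes",
    "simulate_cap",
    "tripole_reference",
    "assemble_time_series",
    "add_noise",
    "global_peak_index",
    "build_cap_bank",
    "series_noise_sigma",
]

SAMPLING_RATE_HZ = 30_000.0

PATHWAY_LABELS = ("tibial", "peroneal", "sural")


@dataclass(frozen=True)
class FiberSpec:
    """Fiber class parameters: node-of-Ranvier spacing and conduction velocity."""

    fiber_class: str
    node_spacing_mm: float
    conduction_velocity_m_s: float

    def __post_init__(self):
        if self.node_spacing_mm <= 0 or self.conduction_velocity_m_s <= 0:
            raise ValueError("node spacing and conduction velocity must be positive")


FIBER_CLASSES: dict[str, FiberSpec] = {
    "Aalpha": FiberSpec("Aalpha", 1.70, 94.86),
    "Abeta": FiberSpec("Abeta", 1.16, 64.72),
}

PATHWAY_FIBER_CLASS: dict[str, str] = {
    "tibial": "Aalpha",
    "peroneal": "Aalpha",
    "sural": "Abeta",
}


@dataclass(frozen=True)
class SourceTemplate:
    """Charge-balanced source current waveform (Ricker wavelet).

    The second derivative of a Gaussian integrates to zero exactly, so each
    node injects zero net charge.  ``sigma_ms`` sets the width (main lobe
    roughly 2*sqrt(3)*sigma ~ 0.35 ms at the default); support is truncated
    at ``n_sigma`` standard deviations, wide enough that the discrete sample
    sum is zero to well below 1e-9 of the total absolute amplitude.
    """

    amplitude: float = 1.0
    sigma_ms: float = 0.1
    n_sigma: float = 8.0
    sampling_rate_hz: float = SAMPLING_RATE_HZ

    def __post_init__(self):
        if self.sigma_ms <= 0 or self.n_sigma <= 0:
            raise ValueError("sigma_ms and n_sigma must be positive")

    @property
    def duration_ms(self) -> float:
        return 2.0 * self.n_sigma * self.sigma_ms

    def __call__(self, t_ms: np.ndarray) -> np.ndarray:
        """Evaluate the waveform at times (ms) relative to its center."""
        t = np.asarray(t_ms, dtype=float)
        u = t / self.sigma_ms
        out = self.amplitude * (1.0 - u * u) * np.exp(-0.5 * u * u)
        return np.where(np.abs(u) <= self.n_sigma, out, 0.0)

    @property
    def samples(self) -> np.ndarray:
        """Waveform sampled on the recording clock, centered on its peak."""
        dt_ms = 1e3 / self.sampling_rate_hz
        n = int(np.floor(self.n_sigma * self.sigma_ms / dt_ms))
        return self(np.arange(-n, n + 1) * dt_ms)


@dataclass(frozen=True)
class NodeSet:
    """Node-of-Ranvier positions along one pathway trajectory.

    ``arclengths_mm`` are measured from the proximal end of the trajectory.
    """

    positions_mm: np.ndarray  # (K, 3)
    arclengths_mm: np.ndarray  # (K,)

    def __len__(self) -> int:
        return self.positions_mm.shape[0]


class _SplinePath:
    """Arc-length parameterized cubic-spline curve through control points."""

    def __init__(self, control_points_mm: np.ndarray, n_dense: int = 4000):
        cp = np.asarray(control_points_mm, dtype=float)
        if cp.ndim != 2 or cp.shape[1] != 3 or cp.shape[0] < 2:
            raise ValueError("need at least two 3-D control points")
        chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(cp, axis=0), axis=1))])
        if chord[-1] == 0:
            raise ValueError("degenerate control polygon")
        spline = CubicSpline(chord, cp, axis=0)
        u = np.linspace(0.0, chord[-1], n_dense)
        pts = spline(u)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        self._s = np.concatenate([[0.0], np.cumsum(seg)])
        self._pts = pts
        self.length_mm = float(self._s[-1])

    def at(self, s_mm: np.ndarray) -> np.ndarray:
        s = np.asarray(s_mm, dtype=float)
        return np.stack([np.interp(s, self._s, self._pts[:, k]) for k in range(3)], axis=-1)


@dataclass(frozen=True)
class PathwaySpec:
    """A labeled fascicular pathway: spline trajectory + fiber class + a bank
    of lateral source offsets emulating distinct fiber positions within the
    fascicle."""

    label: str
    control_points_mm: np.ndarray
    fiber: FiberSpec
    radial_offsets_mm: np.ndarray  # (B, 2) lateral (x, y) offsets
    path: _SplinePath = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "path", _SplinePath(self.control_points_mm))

    @property
    def n_offsets(self) -> int:
        return self.radial_offsets_mm.shape[0]


def default_pathway(
    label: str,
    tissue: TissueModel,
    n_offsets: int = 20,
    seed: int = 0,
    z_start_mm: float = -3.5,
    z_end_mm: float = 26.5,
    wiggle_mm: float = 0.02,
    n_control: int = 7,
) -> PathwaySpec:
    """Build a pathway along a fascicle center with a gentle lateral wiggle
    and a seeded bank of within-fascicle source offsets.

    The trajectory spans the cuff with margin on both sides; offsets are drawn
    uniformly in a disk small enough that every offset trajectory stays inside
    the fascicle's endoneurium.
    """
    fasc = tissue.fascicle(label)
    fiber = FIBER_CLASSES[PATHWAY_FIBER_CLASS[label]]
    rng = np.random.default_rng(seed)
    cx, cy = fasc.center_xy
    z = np.linspace(z_start_mm, z_end_mm, n_control)
    cp = np.stack(
        [
            cx + rng.uniform(-wiggle_mm, wiggle_mm, n_control),
            cy + rng.uniform(-wiggle_mm, wiggle_mm, n_control),
            z,
        ],
        axis=1,
    )
    r_endo = fasc.radius_mm - tissue.perineurium_thickness_mm
    r_max = max(r_endo - wiggle_mm - 0.01, 0.01)
    theta = rng.uniform(0, 2 * np.pi, n_offsets)
    rad = r_max * np.sqrt(rng.uniform(0, 1, n_offsets))
    offsets = np.stack([rad * np.cos(theta), rad * np.sin(theta)], axis=1)
    return PathwaySpec(label, cp, fiber, offsets)


def place_nodes(pathway: PathwaySpec, offset_index: int | None = None) -> NodeSet:
    """Place nodes of Ranvier at the fiber's node spacing along the pathway.

    Consecutive nodes are separated by ``node_spacing_mm`` of arc length,
    starting at the proximal end and covering the full curve
    (floor(L / spacing) + 1 nodes).  ``offset_index`` selects one lateral
    offset from the pathway's bank; ``None`` uses the centerline.
    """
    spacing = pathway.fiber.node_spacing_mm
    L = pathway.path.length_mm
    if L < spacing:
        raise ValueError("pathway shorter than one node spacing")
    s = np.arange(int(np.floor(L / spacing)) + 1) * spacing
    pos = pathway.path.at(s)
    if offset_index is not None:
        dx, dy = pathway.radial_offsets_mm[offset_index]
        pos = pos + np.array([dx, dy, 0.0])
    return NodeSet(positions_mm=pos, arclengths_mm=s)


@dataclass
class MultiChannelRecording:
    """Multi-channel recording: ``samples`` is channels x time in arbitrary
    potential units (leadfield ohms x unit source current)."""

    samples: np.ndarray
    sampling_rate_hz: float = SAMPLING_RATE_HZ
    referenced: bool = False
    event_peaks: np.ndarray | None = None  # sample index of each CAP peak
    event_labels: np.ndarray | None = None
    snr_db: float | None = None

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


def global_peak_index(samples: np.ndarray) -> tuple[int, int]:
    """(time, channel) of the global maximum of |samples|.

    Ties are broken toward the earliest sample, then the lowest channel.
    """
    flat = np.argmax(np.abs(samples).T)  # time-major scan
    t, c = divmod(int(flat), samples.shape[0])
    return t, c


def simulate_cap(
    leadfield: Leadfield,
    nodes: NodeSet,
    template: SourceTemplate,
    velocity_m_s: float,
    clip_ms: float | None = None,
    pad_ms: float = 1.0,
) -> MultiChannelRecording:
    """Simulate one clean, unreferenced CAP on all channels.

    Channel i receives sum_k gains[i, k] * template(t - s_k / v) where s_k is
    the arc length of node k from the proximal end of the pathway.  The
    leadfield columns must correspond one-to-one to the nodes.  If ``clip_ms``
    is given, the recording is clipped to that length centered on the global
    peak (ties: earliest sample, lowest channel).
    """
    if velocity_m_s <= 0:
        raise ValueError("velocity must be positive")
    if leadfield.n_sources != len(nodes):
        raise ValueError("leadfield columns must match the node count")
    rate = template.sampling_rate_hz
    dt_ms = 1e3 / rate
    delays_ms = nodes.arclengths_mm / velocity_m_s  # mm / (m/s) == ms
    t_end = delays_ms.max() + template.duration_ms / 2 + pad_ms
    t = np.arange(0.0, t_end + 2 * pad_ms + template.duration_ms / 2, dt_ms)
    # (K, T) template matrix; center the first node's waveform at pad time
    t0 = pad_ms + template.duration_ms / 2
    wave = template(t[None, :] - t0 - delays_ms[:, None])
    samples = leadfield.gains @ wave
    rec = MultiChannelRecording(samples=samples, sampling_rate_hz=rate, referenced=False)
    if clip_ms is not None:
        n_clip = int(round(clip_ms * 1e-3 * rate))
        pk, _ = global_peak_index(samples)
        lo = max(0, min(pk - n_clip // 2, samples.shape[1] - n_clip))
        rec.samples = samples[:, lo : lo + n_clip]
    return rec


def tripole_reference(recording: MultiChannelRecording, geometry: CuffGeometry) -> MultiChannelRecording:
    """Subtract the instantaneous mean of the two outer contact rings from
    every channel (common-mode rejection)."""
    if recording.referenced:
        raise ValueError("recording is already tripole-referenced")
    cpr = geometry.contacts_per_ring
    outer = np.r_[0:cpr, (geometry.n_rings - 1) * cpr : geometry.n_rings * cpr]
    ref = recording.samples[outer].mean(axis=0, keepdims=True)
    return dataclasses.replace(recording, samples=recording.samples - ref, referenced=True)


@dataclass(frozen=True)
class CapBank:
    """Per-pathway bank of referenced, peak-centered CAP clips.

    ``clips`` has shape (B, C, L); every clip's global peak sits at
    ``peak_offset`` so extraction windows line up across bank entries.
    """

    label: str
    clips: np.ndarray
    peak_offset: int
    sampling_rate_hz: float = SAMPLING_RATE_HZ

    @property
    def n_entries(self) -> int:
        return self.clips.shape[0]

    @property
    def clip_len(self) -> int:
        return self.clips.shape[2]


def build_cap_bank(
    geometry: CuffGeometry,
    tissue: TissueModel,
    pathway: PathwaySpec,
    template: SourceTemplate,
    rotation_deg: float = 0.0,
    clip_len: int = 100,
    peak_offset: int = 49,
) -> CapBank:
    """Simulate one referenced CAP clip per lateral source offset.

    Each clip is recentered so the global peak of the referenced signal falls
    at ``peak_offset`` (window convention: 49 samples before, 50 after).
    """
    node_sets = [place_nodes(pathway, b) for b in range(pathway.n_offsets)]
    counts = [len(ns) for ns in node_sets]
    all_pos = np.concatenate([ns.positions_mm for ns in node_sets], axis=0)
    lf = compute_leadfield(geometry, tissue, all_pos, rotation_deg)
    clips = np.empty((pathway.n_offsets, geometry.n_channels, clip_len))
    col = 0
    for b, ns in enumerate(node_sets):
        sub = Leadfield(
            gains=lf.gains[:, col : col + counts[b]],
            source_positions_mm=ns.positions_mm,
            rotation_deg=rotation_deg,
            encapsulation_fill=tissue.encapsulation_fill,
        )
        col += counts[b]
        rec = simulate_cap(sub, ns, template, pathway.fiber.conduction_velocity_m_s)
        ref = tripole_reference(rec, geometry)
        pk, _ = global_peak_index(ref.samples)
        lo = pk - peak_offset
        if lo < 0 or lo + clip_len > ref.samples.shape[1]:
            raise ValueError("simulated CAP too short for the requested clip")
        clips[b] = ref.samples[:, lo : lo + clip_len]
    return CapBank(label=pathway.label, clips=clips, peak_offset=peak_offset)


def assemble_time_series(
    bank: CapBank,
    n_events: int,
    duration_s: float,
    seed: int,
) -> MultiChannelRecording:
    """Assemble a long single-pathway series of non-overlapping CAPs.

    Onsets are drawn uniformly at random (seeded) subject to a minimum
    separation of one clip length; events cycle deterministically through the
    bank's lateral offsets.
    """
    rate = bank.sampling_rate_hz
    total = int(round(duration_s * rate))
    L = bank.clip_len
    free = total - n_events * L
    if n_events < 1:
        raise ValueError("need at least one event")
    if free < 0:
        raise ValueError(
            f"cannot pack {n_events} clips of {L} samples into {total} samples"
        )
    rng = np.random.default_rng(seed)
    onsets = np.sort(rng.integers(0, free + 1, size=n_events)) + np.arange(n_events) * L
    samples = np.zeros((bank.clips.shape[1], total))
    for k, onset in enumerate(onsets):
        samples[:, onset : onset + L] += bank.clips[k % bank.n_entries]
    peaks = onsets + bank.peak_offset
    return MultiChannelRecording(
        samples=samples,
        sampling_rate_hz=rate,
        referenced=True,
        event_peaks=peaks,
        event_labels=np.full(n_events, bank.label, dtype=object),
    )


def add_noise(recording: MultiChannelRecording, snr_db: float, seed: int) -> MultiChannelRecording:
    """Add white Gaussian noise at a whole-series SNR.

    One noise standard deviation is used for all channels:
    sigma^2 = P_signal / 10^(snr_db / 10), with P_signal the mean squared
    value over every channel and the full duration, silence included.
    """
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    p_signal = float(np.mean(recording.samples**2))
    if p_signal == 0.0:
        raise ValueError("zero-signal series: SNR undefined")
    sigma = np.sqrt(p_signal / 10.0 ** (snr_db / 10.0))
    rng = np.random.default_rng(seed)
    noisy = recording.samples + rng.normal(0.0, sigma, recording.samples.shape)
    return dataclasses.replace(recording, samples=noisy, snr_db=float(snr_db))


def series_noise_sigma(
    bank: CapBank,
    snr_db: float,
    n_events: int = 10_000,
    duration_s: float = 53.333,
) -> float:
    """Noise standard deviation implied by the nominal full-length series.

    The assembled series is exactly the bank clips placed at non-overlapping
    onsets, so its mean squared value is the event-cycled clip energy divided
    by the series size; no series needs to be materialized.
    """
    total = int(round(duration_s * bank.sampling_rate_hz))
    if n_events * bank.clip_len > total:
        raise ValueError("nominal series cannot hold the requested events")
    idx = np.arange(n_events) % bank.n_entries
    counts = np.bincount(idx, minlength=bank.n_entries)
    energy = float(np.sum(counts * np.sum(bank.clips**2, axis=(1, 2))))
    p_signal = energy / (total * bank.clips.shape[1])
    return float(np.sqrt(p_signal / 10.0 ** (snr_db / 10.0)))
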