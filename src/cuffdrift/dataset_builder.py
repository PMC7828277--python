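"""Spatiotemporal signature datasets: extraction, normalization, ordering,
fold assignment and cross-time-point interpolation.

A signature is the 56-channel x 100-sample window around one CAP peak
(3.333 ms at 30 kHz: 49 samples before the peak, the peak, 50 after).  A
dataset pools the signatures of one simulated time point, normalized into
[-1, 1] by the single maximum absolute amplitude across all of its CAPs, and
carries a stratified fold assignment for cross-validation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .cap_simulator import MultiChannelRecording
from .volume_conductor import CuffGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "CLASS_LABELS",
    "WINDOW_BEFORE",
    "WINDOW_AFTER",
    "WINDOW_LEN",
    "Signature",
    "SignatureDataset",
    "extract_signatures",
    "normalize_dataset",
    "reorder",
    "temporal_permutation",
    "build_dataset",
    "interpolate_datasets",
]

CLASS_LABELS: tuple[str, ...] = ("tibial", "peroneal", "sural")
WINDOW_BEFORE = 49
WINDOW_AFTER = 50
WINDOW_LEN = WINDOW_BEFORE + 1 + WINDOW_AFTER  # 100 samples = 3.333 ms


def label_to_index(label: str) -> int:
    return CLASS_LABELS.index(label)


@dataclass
class Signature:
    """One labeled spatiotemporal signature (channels x time)."""

    matrix: np.ndarray
    label: str
    peak_index: int | None = None
    timepoint_id: str | None = None
    ordering: str = "raw"

    def __post_init__(self):
        if self.matrix.shape[1] != WINDOW_LEN:
            raise ValueError(f"signature must have {WINDOW_LEN} time samples")
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class SignatureDataset:
    """Labeled signatures for one simulated time point.

    ``matrices``: (N, C, T) array; ``labels``: (N,) int class indices into
    ``CLASS_LABELS``; ``folds``: (N,) int fold ids in [0, n_folds) or None.
    """

    matrices: np.ndarray
    labels: np.ndarray
    folds: np.ndarray | None = None
    snr_db: float | None = None
    timepoint_id: str | None = None
    normalization_constant: float | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.matrices.ndim != 3:
            raise ValueError("matrices must be (N, channels, time)")
        if self.labels.shape[0] != self.matrices.shape[0]:
            raise ValueError("labels must match matrices")

    def __len__(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_folds(self) -> int:
        if self.folds is None:
            raise ValueError("dataset has no fold assignment")
        return int(self.folds.max()) + 1

    def fold_mask(self, folds) -> np.ndarray:
        folds = np.atleast_1d(folds)
        return np.isin(self.folds, folds)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=len(CLASS_LABELS))


def extract_signatures(
    noisy_series: MultiChannelRecording,
    clean_event_peaks: np.ndarray,
    labels: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut the [peak-49, peak+50] window around each clean-signal peak.

    Peaks too close to the series edges are skipped with a logged warning.
    Returns (matrices, kept_indices).
    """
    peaks = np.asarray(clean_event_peaks, dtype=int)
    T = noisy_series.n_samples
    keep = (peaks >= WINDOW_BEFORE) & (peaks + WINDOW_AFTER < T)
    n_skip = int((~keep).sum())
    if n_skip:
        logger.warning("skipping %d event(s) too close to the series edge", n_skip)
    kept = np.flatnonzero(keep)
    out = np.empty((kept.size, noisy_series.n_channels, WINDOW_LEN))
    for i, p in enumerate(peaks[kept]):
        out[i] = noisy_series.samples[:, p - WINDOW_BEFORE : p + WINDOW_AFTER + 1]
    return out, kept


def normalize_dataset(matrices: np.ndarray) -> tuple[np.ndarray, float]:
    """Scale a whole dataset into [-1, 1] by its single global max |value|.

    Returns (normalized matrices, normalization constant).  The maximum
    absolute value after normalization is exactly 1.
    """
    const = float(np.max(np.abs(matrices)))
    if const == 0.0:
        raise ValueError("all-zero dataset cannot be normalized")
    return matrices / const, const


def temporal_permutation(n_rings: int = 7, contacts_per_ring: int = 8) -> np.ndarray:
    """Row permutation from ring-major (spatial) to slot-major (temporal)
    channel ordering: raw row (ring r, slot s) moves to position s*n_rings + r."""
    perm = np.empty(n_rings * contacts_per_ring, dtype=int)
    for s in range(contacts_per_ring):
        for r in range(n_rings):
            perm[s * n_rings + r] = r * contacts_per_ring + s
    return perm


def reorder(matrix: np.ndarray, mode: str, geometry: CuffGeometry | None = None) -> np.ndarray:
    """Reorder signature rows for the classifier's two input emphases.

    ``spatial`` keeps the raw ring-major order (identity); ``temporal``
    groups rows longitudinally, one angular slot at a time.  Works on a
    single (C, T) signature or a batch (N, C, T).
    """
    n_rings = geometry.n_rings if geometry is not None else 7
    cpr = geometry.contacts_per_ring if geometry is not None else 8
    if mode == "spatial":
        return matrix.copy()
    if mode == "temporal":
        perm = temporal_permutation(n_rings, cpr)
        return matrix[..., perm, :].copy()
    raise ValueError(f"unknown ordering mode {mode!r}")


def build_dataset(
    matrices: np.ndarray,
    labels: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    snr_db: float | None = None,
    timepoint_id: str | None = None,
    normalize: bool = True,
) -> SignatureDataset:
    """Normalize and assign seeded stratified cross-validation folds.

    With equal class counts divisible by ``n_folds`` every fold holds the
    same number of signatures from each class (full-study scale: 5 folds of 6000,
    2000 per class, from a 30,000-CAP dataset).
    """
    labels = np.asarray(labels)
    if labels.dtype.kind in "USO":
        labels = np.array([label_to_index(l) for l in labels])
    counts = np.bincount(labels, minlength=len(CLASS_LABELS))
    if np.any(counts < n_folds):
        raise ValueError("every class needs at least n_folds samples")
    const = None
    if normalize:
        matrices, const = normalize_dataset(matrices)
    folds = np.empty(len(labels), dtype=int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        folds[test_idx] = f
    return SignatureDataset(
        matrices=matrices,
        labels=labels,
        folds=folds,
        snr_db=snr_db,
        timepoint_id=timepoint_id,
        normalization_constant=const,
        seed=seed,
    )


def interpolate_datasets(
    ds_a: SignatureDataset, ds_b: SignatureDataset, alpha: float
) -> SignatureDataset:
    """Linear interpolation between two corresponding datasets.

    The datasets must come from the same generator seed and source bank so
    signatures correspond one-to-one in order (same labels and folds); each
    output matrix is (1 - alpha) * A + alpha * B.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if ds_a.matrices.shape != ds_b.matrices.shape:
        raise ValueError("datasets have mismatched sizes")
    if not np.array_equal(ds_a.labels, ds_b.labels):
        raise ValueError("datasets have mismatched labels")
    if (ds_a.folds is None) != (ds_b.folds is None) or (
        ds_a.folds is not None and not np.array_equal(ds_a.folds, ds_b.folds)
    ):
        raise ValueError("datasets have mismatched fold assignments")
    mats = (1.0 - alpha) * ds_a.matrices + alpha * ds_b.matrices
    return dataclasses.replace(
        ds_a,
        matrices=mats,
        timepoint_id=f"{ds_a.timepoint_id}+{alpha:g}*({ds_b.timepoint_id})",
        normalization_constant=None,
    )
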