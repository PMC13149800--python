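"""Segmented 3D golden-angle spiral-phyllotaxis radial k-space trajectory.

The free-running acquisition samples k-space along radial spokes whose tip
directions follow a sunflower (spiral phyllotaxis) pattern on the unit
hemisphere.  Spokes are grouped into segments (interleaves); each segment
sweeps the polar angle top-to-bottom from the +z pole, and successive
segments are rotated about the main axis by the golden angle, so the full
set fills the hemisphere quasi-uniformly.

Conventions
-----------
* k-space coordinates are dimensionless "cycles per voxel", so the grid
  Nyquist limit is |k| = 0.5 along each axis.  Physical units (1/mm) only
  appear at I/O, via the field of view.
* Spoke ``n`` (global acquisition-ordered index, ``n = j * n_segments + s``
  for within-segment index ``j`` of segment ``s``) points at polar angle
  ``theta_n = (pi/2) * sqrt(n / (N - 1))`` and azimuth
  ``phi_n = n * GOLDEN_ANGLE``.  Each spoke spans ``[-k_max, +k_max]``, so
  the hemisphere of directions covers the full sphere of measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Golden angle in degrees: 360 * (1 - 1/golden ratio), to the precision
#: conventionally used for phyllotaxis trajectory generation.
GOLDEN_ANGLE_DEG = 137.50776405

__all__ = [
    "GOLDEN_ANGLE_DEG",
    "TrajectorySpec",
    "RadialTrajectory",
    "phyllotaxis_directions",
    "radial_samples",
]


@dataclass(frozen=True)
class TrajectorySpec:
    """Geometry of the segmented radial acquisition.

    Parameters
    ----------
    n_segments : int
        Number of interleaves (pole-to-equator sweeps).
    readouts_per_segment : int
        Spokes per interleave.
    samples_per_readout : int
        Complex samples acquired along each spoke.
    k_max : float
        Spoke half-length in cycles/voxel; at most the grid Nyquist 0.5.
    """

    n_segments: int
    readouts_per_segment: int
    samples_per_readout: int
    k_max: float = 0.5

    def __post_init__(self) -> None:
        if self.n_segments < 1 or self.readouts_per_segment < 1:
            raise ValueError("segment and readout counts must be >= 1")
        if self.samples_per_readout < 1:
            raise ValueError("samples_per_readout must be >= 1")
        if not 0.0 < self.k_max <= 0.5:
            raise ValueError("k_max must lie in (0, 0.5]")

    @property
    def n_readouts(self) -> int:
        return self.n_segments * self.readouts_per_segment


@dataclass
class RadialTrajectory:
    """Radial sampling pattern in acquisition order.

    Attributes
    ----------
    directions : (n_readouts, 3) float64
        Unit spoke directions, acquisition-ordered.
    samples : (n_readouts, samples_per_readout, 3) float64 or None
        k-space coordinates of every sample, in cycles/voxel; ``None``
        until :func:`radial_samples` has been applied.
    spec : TrajectorySpec
    """

    directions: np.ndarray
    spec: TrajectorySpec
    samples: np.ndarray | None = field(default=None)

    @property
    def n_readouts(self) -> int:
        return self.directions.shape[0]

    def coords_flat(self) -> np.ndarray:
        """All sample coordinates as a flat (n_readouts * n_samples, 3) array."""
        if self.samples is None:
            raise ValueError("trajectory has no per-sample coordinates yet")
        return self.samples.reshape(-1, 3)


def phyllotaxis_directions(spec: TrajectorySpec) -> RadialTrajectory:
    """Generate unit spoke directions for the segmented phyllotaxis pattern.

    Within each segment the polar angle grows monotonically from the +z
    pole (top-to-bottom); at a fixed within-segment index, consecutive
    segments are offset in azimuth by exactly one golden angle.

    Returns a :class:`RadialTrajectory` with ``samples=None``.
    """
    n_total = spec.n_readouts
    # global spoke index, acquisition order: segment-major
    s = np.repeat(np.arange(spec.n_segments), spec.readouts_per_segment)
    j = np.tile(np.arange(spec.readouts_per_segment), spec.n_segments)
    n = j * spec.n_segments + s

    if n_total == 1:
        theta = np.zeros(1)
    else:
        theta = 0.5 * np.pi * np.sqrt(n / (n_total - 1))
    phi = n * np.deg2rad(GOLDEN_ANGLE_DEG)

    directions = np.stack(
        [
            np.sin(theta) * np.cos(phi),
            np.sin(theta) * np.sin(phi),
            np.cos(theta),
        ],
        axis=1,
    )
    # renormalize to keep unit norm to strict tolerance
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    return RadialTrajectory(directions=directions, spec=spec)


def radial_samples(
    trajectory: RadialTrajectory,
    samples_per_readout: int | None = None,
    k_max: float | None = None,
) -> RadialTrajectory:
    """Discretize each spoke into uniformly spaced samples over [-k_max, k_max].

    The sampling is symmetric about the k-space origin; for an odd number
    of samples the central sample lies exactly at k = 0.
    """
    spec = trajectory.spec
    n_samp = spec.samples_per_readout if samples_per_readout is None else samples_per_readout
    kmx = spec.k_max if k_max is None else k_max
    if n_samp < 2:
        raise ValueError("samples_per_readout must be >= 2")
    if not 0.0 < kmx <= 0.5:
        raise ValueError("k_max must lie in (0, 0.5]")

    radii = np.linspace(-kmx, kmx, n_samp)
    samples = trajectory.directions[:, None, :] * radii[None, :, None]
    out_spec = TrajectorySpec(
        n_segments=spec.n_segments,
        readouts_per_segment=spec.readouts_per_segment,
        samples_per_readout=n_samp,
        k_max=kmx,
    )
    return RadialTrajectory(
        directions=trajectory.directions.copy(), spec=out_spec, samples=samples
    )


def make_trajectory(spec: TrajectorySpec) -> RadialTrajectory:
    """Convenience: directions plus per-sample coordinates in one call."""
    return radial_samples(phyllotaxis_directions(spec))
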