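"""Synthetic inputs with known ground truth for the whole pipeline.

Everything the analysis consumes can be generated here: a neck-like
digital phantom with two bright cylindrical carotid lumina whose diameter
pulsates between the diastolic (D_d) and systolic (D_s) values, a
continuous multi-coil radial k-space acquisition of that phantom with
pulse-oximeter triggers, parallel M-mode wall-boundary traces, and paired
brachial pressure readings.  Each generator is a pure function of its
parameters and a seed, and the true D_d / D_s / RDC / pressures travel
with the data so every downstream stage is a parameter-recovery exercise.

The phantom emulates inflow contrast (unsaturated blood entering the
excited slab appears bright) simply by making the lumen the brightest
compartment; no MR signal equations are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nufft import DirectDft, GriddingNufft
from .trajectory import RadialTrajectory

__all__ = [
    "DiameterWaveform",
    "PhantomSpec",
    "PhysioRecord",
    "RawKSpace",
    "MModeTrace",
    "PressurePair",
    "make_diameter_waveform",
    "render_phantom",
    "simulate_physio",
    "simulate_acquisition",
    "simulate_mmode",
    "simulate_pressures",
    "make_coil_maps",
]


# ---------------------------------------------------------------------------
# diameter waveform


@dataclass
class DiameterWaveform:
    """Lumen diameter over one cardiac cycle on a uniform phase grid.

    ``phase_times`` are ms offsets within the cycle (endpoint excluded);
    the continuous waveform is a raised-cosine systolic bump over the
    first ``systolic_fraction`` of the cycle followed by a flat diastole
    at ``d_d_true``.  The bump is symmetric about mid-systole (equal
    upstroke and decay), and the sampled extrema are pinned to the true
    D_s / D_d exactly.
    """

    phase_times: np.ndarray  # ms
    diameters: np.ndarray  # mm
    rr_ms: float
    d_d_true: float
    d_s_true: float
    systolic_fraction: float
    shape: str = "bump"
    _t_peak: float = field(repr=False, default=0.0)

    @property
    def n_phases(self) -> int:
        return len(self.phase_times)

    @property
    def rdc_true(self) -> float:
        """Ground-truth relative diameter change, percent."""
        return (self.d_s_true - self.d_d_true) / self.d_d_true * 100.0

    def at_fraction(self, frac) -> np.ndarray:
        """Continuous diameter at cardiac phase fraction(s) in [0, 1)."""
        frac = np.mod(np.asarray(frac, dtype=float), 1.0)
        t = frac * self.rr_ms
        dd, ds = self.d_d_true, self.d_s_true
        if ds == dd:
            return np.full_like(t, dd)
        tp = self._t_peak
        out = np.full_like(t, dd)
        if self.shape == "pulse":
            # fast systolic upstroke, slow decay over the rest of the
            # cycle; the minimum is reached only at the end-diastolic foot
            up = t <= tp
            out[up] = dd + (ds - dd) * 0.5 * (1 - np.cos(np.pi * t[up] / tp))
            down = t > tp
            out[down] = dd + (ds - dd) * 0.5 * (
                1 + np.cos(np.pi * (t[down] - tp) / (self.rr_ms - tp))
            )
            return out
        ts = self.systolic_fraction * self.rr_ms
        up = t <= tp
        out[up] = dd + (ds - dd) * 0.5 * (1 - np.cos(np.pi * t[up] / tp))
        down = (t > tp) & (t < ts)
        out[down] = dd + (ds - dd) * 0.5 * (1 + np.cos(np.pi * (t[down] - tp) / (ts - tp)))
        return out

    def nearest_phase(self, frac) -> np.ndarray:
        """Index of the waveform grid point nearest to phase fraction(s)."""
        frac = np.mod(np.asarray(frac, dtype=float), 1.0)
        return np.mod(np.rint(frac * self.n_phases).astype(int), self.n_phases)


def make_diameter_waveform(
    d_d: float,
    d_s: float,
    rr_ms: float = 960.0,
    systolic_fraction: float = 0.35,
    n_phases: int = 40,
    shape: str = "bump",
) -> DiameterWaveform:
    """Build the ground-truth pulsation waveform.

    ``shape="bump"`` is a symmetric raised-cosine systolic bump over
    ``systolic_fraction`` of the cycle with a flat diastole; ``"pulse"``
    is a distension-like profile (raised-cosine upstroke over half the
    systolic fraction, then a slow raised-cosine decay over the rest of
    the cycle, so the diastolic minimum is only reached at the
    end-diastolic foot).

    Raises
    ------
    ValueError
        If ``d_s < d_d``, diameters are non-positive, or the systolic
        fraction is not in (0, 1).
    """
    if d_s < d_d:
        raise ValueError("systolic diameter must be >= diastolic diameter")
    if d_d <= 0:
        raise ValueError("diameters must be positive")
    if not 0.0 < systolic_fraction < 1.0:
        raise ValueError("systolic_fraction must be in (0, 1)")
    if n_phases < 2:
        raise ValueError("need at least 2 phases")
    if shape not in ("bump", "pulse"):
        raise ValueError("shape must be 'bump' or 'pulse'")
    phase_times = np.arange(n_phases) * (rr_ms / n_phases)
    ts = systolic_fraction * rr_ms
    wf = DiameterWaveform(
        phase_times=phase_times,
        diameters=np.empty(n_phases),
        rr_ms=float(rr_ms),
        d_d_true=float(d_d),
        d_s_true=float(d_s),
        systolic_fraction=float(systolic_fraction),
        shape=shape,
        _t_peak=float(ts / 2.0),
    )
    wf.diameters = wf.at_fraction(phase_times / rr_ms)
    # pin the sampled extrema to the exact ground truth (the grid may
    # otherwise straddle the continuous peak)
    wf.diameters[np.argmax(wf.diameters)] = d_s
    wf.diameters[np.argmin(wf.diameters)] = d_d
    return wf


# ---------------------------------------------------------------------------
# phantom


@dataclass
class PhantomSpec:
    """Two axial bright cylinders (LC and RC lumina) in a uniform background.

    Physical coordinates follow ``mm = voxel index * voxel_mm`` with voxel
    centers at integer indices.  ``background_roi`` is a per-axis
    (start, stop) voxel box used for apparent-SNR noise estimation.
    """

    grid_size: int = 64
    voxel_mm: float = 0.6
    vessel_centers_mm: tuple = ((12.0, 19.2), (26.4, 19.2))  # (x, y) of LC, RC
    wall_thickness_mm: float = 0.9
    lumen_intensity: float = 10.0
    wall_intensity: float = 0.6
    background_intensity: float = 1.0
    background_roi: tuple = ((2, 10), (4, 60), (2, 62))
    supersample: int = 4

    def __post_init__(self) -> None:
        if not (
            self.lumen_intensity > self.wall_intensity
            and self.lumen_intensity > self.background_intensity
        ):
            raise ValueError("lumen must be the brightest compartment")

    @property
    def fov_mm(self) -> float:
        return self.grid_size * self.voxel_mm

    def background_mask(self) -> np.ndarray:
        m = np.zeros((self.grid_size,) * 3, dtype=bool)
        (x0, x1), (y0, y1), (z0, z1) = self.background_roi
        m[x0:x1, y0:y1, z0:z1] = True
        return m

    def lumen_mask(self, diameter_mm: float, vessel: int = 0) -> np.ndarray:
        """Voxels strictly inside the lumen of one vessel (conservative)."""
        n, v = self.grid_size, self.voxel_mm
        cx, cy = self.vessel_centers_mm[vessel]
        xx, yy = np.meshgrid(np.arange(n) * v, np.arange(n) * v, indexing="ij")
        inplane = (xx - cx) ** 2 + (yy - cy) ** 2 <= (diameter_mm / 2 - v) ** 2
        return np.broadcast_to(inplane[:, :, None], (n, n, n)).copy()


def render_phantom(spec: PhantomSpec, diameter_mm: float) -> np.ndarray:
    """Render the 3D phantom at one lumen diameter (same for both vessels).

    Voxel values at lumen/wall edges are sub-voxel occupancy-weighted
    mixes computed on a ``supersample``-times finer in-plane grid, so the
    rendering is smooth (and monotone) in the diameter.
    """
    n, v, ss = spec.grid_size, spec.voxel_mm, spec.supersample
    r_lumen = diameter_mm / 2.0
    r_outer = r_lumen + spec.wall_thickness_mm
    for cx, cy in spec.vessel_centers_mm:
        lo, hi = min(cx, cy) - r_outer, max(cx, cy) + r_outer
        if lo < 0 or hi > (n - 1) * v:
            raise ValueError(
                f"vessel at ({cx}, {cy}) mm with outer radius {r_outer:.2f} mm "
                "exits the image grid"
            )
    # supersampled in-plane coordinates: voxel i covers [i-0.5, i+0.5)*v
    fine = (np.arange(n * ss) + 0.5) / ss - 0.5  # voxel units
    fine_mm = fine * v
    xx, yy = np.meshgrid(fine_mm, fine_mm, indexing="ij")
    plane = np.full((n * ss, n * ss), spec.background_intensity)
    for cx, cy in spec.vessel_centers_mm:
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        plane[r2 <= r_outer**2] = spec.wall_intensity
        plane[r2 <= r_lumen**2] = spec.lumen_intensity
    # block-average back to voxel resolution
    plane = plane.reshape(n, ss, n, ss).mean(axis=(1, 3))
    return np.broadcast_to(plane[:, :, None], (n, n, n)).copy()


# ---------------------------------------------------------------------------
# physiology


@dataclass
class PhysioRecord:
    """Pulse-oximeter trigger times (ms from acquisition start)."""

    trigger_times: np.ndarray
    duration_ms: float

    def __post_init__(self) -> None:
        t = np.asarray(self.trigger_times, dtype=float)
        if len(t) >= 2:
            rr = np.diff(t)
            if np.any(rr <= 200.0):
                raise ValueError("RR intervals must exceed 200 ms")
            if np.any(rr <= 0):
                raise ValueError("trigger times must be strictly increasing")
        self.trigger_times = t


def simulate_physio(
    duration_ms: float, mean_rr_ms: float = 960.0, sd_rr_ms: float = 0.0, seed: int = 0
) -> PhysioRecord:
    """Triggers at cumulative sums of RR ~ Normal(mean, sd) truncated at 3 sd."""
    if mean_rr_ms <= 0:
        raise ValueError("mean_rr_ms must be positive")
    if sd_rr_ms < 0:
        raise ValueError("sd_rr_ms must be non-negative")
    if mean_rr_ms - 3 * sd_rr_ms <= 200.0:
        raise ValueError("RR variability too large: truncated RR could fall below 200 ms")
    rng = np.random.default_rng(seed)
    triggers = [0.0]
    while True:
        rr = mean_rr_ms + np.clip(rng.normal(0.0, sd_rr_ms) if sd_rr_ms else 0.0,
                                  -3 * sd_rr_ms, 3 * sd_rr_ms)
        nxt = triggers[-1] + rr
        if nxt >= duration_ms:
            break
        triggers.append(nxt)
    return PhysioRecord(np.asarray(triggers), float(duration_ms))


# ---------------------------------------------------------------------------
# k-space acquisition


@dataclass
class RawKSpace:
    """Continuously acquired multi-coil radial k-space with metadata."""

    data: np.ndarray  # (n_readouts, n_samples, n_coils) complex
    timestamps: np.ndarray  # ms per readout
    trajectory: RadialTrajectory
    coil_maps: np.ndarray  # (n_coils, n, n, n) complex
    tr_ms: float
    noise_sd: float
    physio: PhysioRecord
    ground_truth: dict = field(default_factory=dict)

    @property
    def n_coils(self) -> int:
        return self.coil_maps.shape[0]


def make_coil_maps(grid_size: int, n_coils: int = 4, phase_scale: float = 0.1) -> np.ndarray:
    """Smooth Gaussian-profile receive sensitivities, SOS-normalized to 1.

    Coils sit on the lateral faces of the volume; each has a broad
    Gaussian magnitude profile and a gentle linear phase, which is enough
    to exercise the coil-combination operator without modelling a real
    30-element array.
    """
    n = grid_size
    c = (n - 1) / 2.0
    centers = [(-0.2 * n, c, c), (1.2 * n, c, c), (c, -0.2 * n, c), (c, 1.2 * n, c),
               (-0.2 * n, -0.2 * n, c), (1.2 * n, 1.2 * n, c),
               (-0.2 * n, 1.2 * n, c), (1.2 * n, -0.2 * n, c)]
    if n_coils > len(centers):
        raise ValueError(f"at most {len(centers)} coils supported")
    width = 0.9 * n
    ax = np.arange(n)
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    maps = np.empty((n_coils, n, n, n), dtype=np.complex128)
    for i, (cx, cy, cz) in enumerate(centers[:n_coils]):
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2
        mag = np.exp(-r2 / (2 * width**2))
        phase = phase_scale * 2 * np.pi * ((xx - cx) + (yy - cy)) / n
        maps[i] = mag * np.exp(1j * phase)
    sos = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    return maps / sos


def simulate_acquisition(
    waveform: DiameterWaveform,
    spec: PhantomSpec,
    trajectory: RadialTrajectory,
    coil_maps: np.ndarray,
    tr_ms: float = 5.97,
    noise_sd: float = 0.0,
    physio: PhysioRecord | None = None,
    seed: int = 0,
    forward_model: str = "nufft",
    precision="fast",
) -> RawKSpace:
    """Simulate the free-running acquisition of the pulsating phantom.

    Readout ``i`` is acquired at ``t_i = i * tr_ms``; its cardiac phase is
    the fraction of the current RR interval elapsed since the preceding
    trigger, mapped to the nearest waveform grid point.  Sample values are
    the (NUFFT or exact-DFT) Fourier transform of coil-weighted phantom
    renderings at that phase, plus i.i.d. complex Gaussian noise with
    standard deviation ``noise_sd`` per real/imaginary component.

    ``forward_model="dft"`` uses exact direct summation (oracle mode, only
    for small problems); ``"nufft"`` uses the gridding operator at the
    given ``precision``.
    """
    if trajectory.samples is None:
        raise ValueError("trajectory must carry per-sample coordinates")
    n_readouts, n_samples, _ = trajectory.samples.shape
    timestamps = np.arange(n_readouts) * tr_ms
    if physio is None:
        physio = simulate_physio(timestamps[-1] + tr_ms, waveform.rr_ms, 0.0, seed)
    if timestamps[-1] >= physio.duration_ms:
        raise ValueError("acquisition extends beyond the physiological record")

    triggers = physio.trigger_times
    idx = np.searchsorted(triggers, timestamps, side="right") - 1
    if np.any(idx < 0):
        raise ValueError("readouts precede the first trigger in simulation")
    prev = triggers[idx]
    mean_rr = np.mean(np.diff(triggers)) if len(triggers) >= 2 else waveform.rr_ms
    nxt = np.where(idx + 1 < len(triggers), triggers[np.minimum(idx + 1, len(triggers) - 1)],
                   prev + mean_rr)
    frac = (timestamps - prev) / (nxt - prev)
    phase_idx = waveform.nearest_phase(frac)

    n_coils = coil_maps.shape[0]
    shape = (spec.grid_size,) * 3
    data = np.empty((n_readouts, n_samples, n_coils), dtype=np.complex128)
    for p in np.unique(phase_idx):
        rows = np.nonzero(phase_idx == p)[0]
        img = render_phantom(spec, waveform.diameters[p])
        coords = trajectory.samples[rows].reshape(-1, 3)
        op = (
            DirectDft(shape, coords)
            if forward_model == "dft"
            else GriddingNufft(shape, coords, precision=precision)
        )
        for c in range(n_coils):
            vals = op.forward(img * coil_maps[c])
            data[rows, :, c] = vals.reshape(len(rows), n_samples)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data += noise_sd * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )

    return RawKSpace(
        data=data,
        timestamps=timestamps,
        trajectory=trajectory,
        coil_maps=coil_maps,
        tr_ms=float(tr_ms),
        noise_sd=float(noise_sd),
        physio=physio,
        ground_truth={
            "d_d_mm": waveform.d_d_true,
            "d_s_mm": waveform.d_s_true,
            "rdc_percent": waveform.rdc_true,
            "waveform_diameters_mm": waveform.diameters.copy(),
        },
    )


# ---------------------------------------------------------------------------
# M-mode ultrasound


@dataclass
class MModeTrace:
    """Upper/lower wall-boundary positions versus time, M-mode style."""

    time_s: np.ndarray
    upper_mm: np.ndarray
    lower_mm: np.ndarray
    fps: float = 250.0
    resolution_mm: float = 0.1
    imt_mm: float = 0.0
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.lower_mm <= self.upper_mm):
            raise ValueError("lower boundary must lie below (greater mm than) upper")


def simulate_mmode(
    waveform: DiameterWaveform,
    n_beats: int = 5,
    drift_mm_per_s: float = 0.0,
    noise_sd_mm: float = 0.0,
    imt_mm: float = 0.6,
    physio: PhysioRecord | None = None,
    seed: int = 0,
    fps: float = 250.0,
    center_mm: float = 6.0,
) -> MModeTrace:
    """Generate wall-boundary traces for ``n_beats`` consecutive heartbeats.

    Boundaries track the *outer* wall: ``center -/+ (D(t)/2 + imt_mm)``,
    plus a shared linear drift (transducer/tissue motion, common-mode,
    cancelled by subtraction) and independent Gaussian noise per boundary.
    The nominal 0.1-mm scanner resolution is carried as metadata; the
    delineated boundaries themselves are continuous, as manual
    delineation is sub-pixel.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if physio is not None and len(physio.trigger_times) >= n_beats + 1:
        beat_bounds = physio.trigger_times[: n_beats + 1]
    else:
        beat_bounds = np.arange(n_beats + 1) * waveform.rr_ms
    duration_s = (beat_bounds[-1] - beat_bounds[0]) / 1000.0
    n_frames = int(round(duration_s * fps))
    t_s = np.arange(n_frames) / fps
    t_ms = beat_bounds[0] + t_s * 1000.0
    beat = np.searchsorted(beat_bounds, t_ms, side="right") - 1
    beat = np.clip(beat, 0, n_beats - 1)
    frac = (t_ms - beat_bounds[beat]) / (beat_bounds[beat + 1] - beat_bounds[beat])
    diam = waveform.at_fraction(frac)

    rng = np.random.default_rng(seed)
    drift = drift_mm_per_s * t_s
    half = diam / 2.0 + imt_mm
    noise_u = noise_sd_mm * rng.standard_normal(n_frames) if noise_sd_mm else 0.0
    noise_l = noise_sd_mm * rng.standard_normal(n_frames) if noise_sd_mm else 0.0
    return MModeTrace(
        time_s=t_s,
        upper_mm=center_mm - half + drift + noise_u,
        lower_mm=center_mm + half + drift + noise_l,
        fps=fps,
        imt_mm=imt_mm,
        ground_truth={
            "d_d_mm": waveform.d_d_true,
            "d_s_mm": waveform.d_s_true,
            "rdc_percent": waveform.rdc_true,
        },
    )


# ---------------------------------------------------------------------------
# pressures


@dataclass
class PressurePair:
    """Brachial systolic/diastolic pressures (mean of pre- and post-scan)."""

    p_s: float  # mmHg
    p_d: float  # mmHg

    def __post_init__(self) -> None:
        if not self.p_s > self.p_d > 0:
            raise ValueError("require p_s > p_d > 0")


def simulate_pressures(
    true_ps: float = 113.0, true_pd: float = 63.0, sd_mmHg: float = 0.0, seed: int = 0
) -> PressurePair:
    """Average of a noisy pre-scan and post-scan cuff reading."""
    if true_ps <= true_pd:
        raise ValueError("true_ps must exceed true_pd")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(4) * sd_mmHg if sd_mmHg else np.zeros(4)
    p_s = true_ps + 0.5 * (noise[0] + noise[1])
    p_d = true_pd + 0.5 * (noise[2] + noise[3])
    if p_s <= p_d:
        raise ValueError("averaged systolic pressure fell below diastolic; reduce sd")
    return PressurePair(p_s=float(p_s), p_d=float(p_d))
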