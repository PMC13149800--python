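"""Compressed-sensing reconstruction of the cardiac-binned 4D image.

The reconstruction solves::

    x_hat = argmin_x  || F C x - y ||_2^2  +  lambda_c || grad_c x ||_1

where ``F`` is the per-bin non-uniform Fourier transform, ``C`` the coil
sensitivities, ``y`` the binned raw data and ``grad_c`` the first-order
finite difference along the (periodic) cardiac dimension.  The problem is
solved with ADMM: splitting ``z = grad_c x``, an inner conjugate-gradient
solve of the normal equations for ``x``, complex soft-thresholding for
``z``, and dual ascent.  ``lambda_c`` is interpreted on a normalized
scale where the density-compensated adjoint image has unit maximum
magnitude, which makes the reference weight (0.01) meaningful for any
input scaling.

Also provides the apparent-SNR image-quality metric (mean lumen
intensity over background standard deviation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .binning import BinAssignment
from .nufft import DirectDft, GriddingNufft, apply_toeplitz, toeplitz_kernel
from .synthdata import RawKSpace

__all__ = [
    "EncodingOperator",
    "ReconConfig",
    "Image4D",
    "temporal_diff",
    "temporal_diff_adjoint",
    "soft_threshold",
    "admm_reconstruct",
    "compute_asnr",
]


@dataclass
class ReconConfig:
    """Tunable reconstruction parameters.

    ``lambda_c`` is the temporal total-variation weight under the
    normalization convention of :func:`admm_reconstruct` (unit-spectral-
    norm encoding, unit-max initial image).  ``admm_penalty`` is the
    quadratic penalty rho at the reference weight 0.01 and scales
    linearly with ``lambda_c`` (so the soft-threshold level in image
    units, lambda/rho, stays fixed while large weights genuinely stiffen
    the temporal coupling).  The inner conjugate gradient is capped at
    ``cg_max_iters`` iterations or a relative residual of ``cg_tol``.
    """

    lambda_c: float = 0.01
    n_admm_iters: int = 10
    admm_penalty: float = 0.1  # sets the soft-threshold level 0.01/admm_penalty
    #: calibration of the reference weight scale onto this package's
    #: normalization convention: the effective L1 weight is
    #: lambda_c * lambda_scale, fixed once by sweeping the reference
    #: phantom at both study scales so that the reference lambda_c = 0.01
    #: sits at the knee of the diameter-error curve
    lambda_scale: float = 0.003
    cg_max_iters: int = 10
    cg_tol: float = 1e-6
    density_compensation: bool = True
    log_objective: bool = True
    engine: str = "nufft"  # or "dft" (exact, small problems only)
    precision: str | tuple = "fast"
    use_toeplitz: bool = True
    single_precision: bool = True  # complex64 ADMM iterates (2x faster FFTs)

    def __post_init__(self) -> None:
        if self.lambda_c < 0:
            raise ValueError("lambda_c must be >= 0")
        if self.n_admm_iters < 1:
            raise ValueError("n_admm_iters must be >= 1")
        if self.admm_penalty <= 0:
            raise ValueError("admm_penalty must be positive")


@dataclass
class Image4D:
    """Cardiac-resolved 3D+phase image (complex; magnitude on export)."""

    data: np.ndarray  # (nx, ny, nz, n_phases)
    voxel_mm: float
    bin_width_ms: float

    @property
    def n_phases(self) -> int:
        return self.data.shape[-1]

    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)


class EncodingOperator:
    """Per-bin multi-coil non-uniform Fourier encoding ``A = F C``.

    ``forward`` maps a 4D image to a list of per-bin (samples, coils)
    arrays; ``adjoint`` is the exact conjugate transpose.  ``normal``
    applies the per-phase Gram ``A^H A`` (Toeplitz-accelerated for the
    gridding engine).
    """

    def __init__(
        self,
        raw: RawKSpace,
        assignment: BinAssignment,
        engine: str = "nufft",
        precision="fast",
        use_toeplitz: bool = True,
    ):
        self.shape = raw.coil_maps.shape[1:]
        self.coil_maps = raw.coil_maps
        self.n_bins = assignment.n_bins
        self.assignment = assignment
        n_samples = raw.trajectory.samples.shape[1]
        self._ops = []
        self._coords = []
        self._bin_rows = []
        for b in range(self.n_bins):
            rows = assignment.readouts_in_bin(b)
            if len(rows) == 0:
                raise ValueError(f"cardiac bin {b} contains no readouts")
            coords = raw.trajectory.samples[rows].reshape(-1, 3)
            self._bin_rows.append(rows)
            self._coords.append(coords)
            if engine == "dft":
                self._ops.append(DirectDft(self.shape, coords))
            else:
                self._ops.append(GriddingNufft(self.shape, coords, precision=precision))
        self._kernels = None
        if use_toeplitz and engine != "dft":
            self._kernels = [
                toeplitz_kernel(self.shape, c, dtype=np.complex64) for c in self._coords
            ]
        self._coil_maps_c64 = raw.coil_maps.astype(np.complex64)
        self._n_samples_per_readout = n_samples

    @property
    def n_coils(self) -> int:
        return self.coil_maps.shape[0]

    def extract_binned(self, raw: RawKSpace) -> list[np.ndarray]:
        """Pull each bin's raw samples into a (points, coils) array."""
        out = []
        for rows in self._bin_rows:
            out.append(raw.data[rows].reshape(-1, raw.n_coils))
        return out

    def forward(self, x: np.ndarray) -> list[np.ndarray]:
        if x.shape != self.shape + (self.n_bins,):
            raise ValueError("image shape mismatch")
        out = []
        for b, op in enumerate(self._ops):
            y = np.empty((op.n_samples, self.n_coils), dtype=np.complex128)
            for c in range(self.n_coils):
                y[:, c] = op.forward(self.coil_maps[c] * x[..., b])
            out.append(y)
        return out

    def adjoint(self, ys: list[np.ndarray]) -> np.ndarray:
        x = np.zeros(self.shape + (self.n_bins,), dtype=np.complex128)
        for b, op in enumerate(self._ops):
            for c in range(self.n_coils):
                x[..., b] += np.conj(self.coil_maps[c]) * op.adjoint(ys[b][:, c])
        return x

    def adjoint_dcf(self, ys: list[np.ndarray]) -> np.ndarray:
        """Density-compensated adjoint (radial |k|^2 ramp), for initialization."""
        x = np.zeros(self.shape + (self.n_bins,), dtype=np.complex128)
        for b, op in enumerate(self._ops):
            k = np.linalg.norm(self._coords[b], axis=1)
            radii = np.unique(np.round(k, 12))
            dk = np.min(np.diff(radii)) if len(radii) > 1 else 1.0 / max(self.shape)
            w = np.maximum(k, dk / 2.0) ** 2
            for c in range(self.n_coils):
                x[..., b] += np.conj(self.coil_maps[c]) * op.adjoint(w * ys[b][:, c])
        return x

    def _normal_single(self, b: int, xb: np.ndarray) -> np.ndarray:
        """Per-phase Gram ``(F_b C)^H (F_b C) xb``."""
        acc = np.zeros(self.shape, dtype=np.result_type(xb.dtype, np.complex64))
        maps = self._coil_maps_c64 if acc.dtype == np.complex64 else self.coil_maps
        if self._kernels is not None:
            for c in range(self.n_coils):
                acc += np.conj(maps[c]) * apply_toeplitz(self._kernels[b], maps[c] * xb)
        else:
            op = self._ops[b]
            for c in range(self.n_coils):
                acc += np.conj(maps[c]) * op.adjoint(op.forward(maps[c] * xb))
        return acc

    def normal(self, x: np.ndarray) -> np.ndarray:
        """Gram operator ``A^H A x``, phase by phase."""
        out = np.empty_like(x)
        for b in range(self.n_bins):
            out[..., b] = self._normal_single(b, x[..., b])
        return out

    def spectral_norm(self, n_iters: int = 8, seed: int = 0) -> float:
        """Power-iteration estimate of ``||A^H A||_2``.

        The Gram is block-diagonal over cardiac phases with near-equal
        occupancy, so iterating on the fullest bin alone is an adequate
        and cheap estimate of the global norm (used only to normalize
        the data term of the objective).
        """
        b = int(np.argmax([op.n_samples for op in self._ops]))
        rng = np.random.default_rng(seed)
        v = rng.standard_normal(self.shape) + 1j * rng.standard_normal(self.shape)
        v /= np.linalg.norm(v)
        lam = 1.0
        for _ in range(n_iters):
            w = self._normal_single(b, v)
            lam = np.linalg.norm(w)
            v = w / lam
        return float(lam)


# ---------------------------------------------------------------------------
# temporal finite difference (periodic in the cardiac dimension)


def temporal_diff(x: np.ndarray) -> np.ndarray:
    """First-order cyclic finite difference along the last (phase) axis."""
    if x.shape[-1] < 2:
        raise ValueError("temporal difference needs at least 2 cardiac phases")
    return np.roll(x, -1, axis=-1) - x


def temporal_diff_adjoint(y: np.ndarray) -> np.ndarray:
    """Exact adjoint of :func:`temporal_diff`."""
    if y.shape[-1] < 2:
        raise ValueError("temporal difference needs at least 2 cardiac phases")
    return np.roll(y, 1, axis=-1) - y


def soft_threshold(v: np.ndarray, tau: float) -> np.ndarray:
    """Complex soft-thresholding: shrink magnitudes by ``tau``, keep phase."""
    mag = np.abs(v)
    scale = np.maximum(mag - tau, 0.0) / np.where(mag > 0, mag, 1.0)
    return v * scale


# ---------------------------------------------------------------------------
# ADMM


def _cg(apply_A, b, x0, max_iters, tol):
    """Conjugate gradient for Hermitian positive (semi)definite systems."""
    x = x0.copy()
    r = b - apply_A(x)
    p = r.copy()
    rs = np.vdot(r, r).real
    b_norm = np.sqrt(np.vdot(b, b).real)
    if b_norm == 0:
        return np.zeros_like(b), 0.0
    for _ in range(max_iters):
        if np.sqrt(rs) / b_norm < tol:
            break
        Ap = apply_A(p)
        alpha = rs / np.vdot(p, Ap).real
        x += alpha * p
        r -= alpha * Ap
        rs_new = np.vdot(r, r).real
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x, np.sqrt(rs) / b_norm


def admm_reconstruct(
    binned_kspace: list[np.ndarray],
    operator: EncodingOperator,
    config: ReconConfig | None = None,
    bin_width_ms: float | None = None,
    voxel_mm: float = 0.6,
    post_denoise=None,
) -> tuple[Image4D, dict]:
    """Solve the temporally regularized least-squares problem by ADMM.

    Returns the reconstructed :class:`Image4D` (complex, in the input
    data's intensity units) and an info dict with the per-iteration
    objective (on the normalized scale, when ``log_objective``) and the
    final inner-solver residual.  ``post_denoise``, if given, is applied
    to the final 4D complex array (hook for patch-based denoising; the
    default is no post-processing).
    """
    config = config or ReconConfig()
    for b, y in enumerate(binned_kspace):
        if np.any(~np.isfinite(y)):
            raise ValueError(f"non-finite raw data in cardiac bin {b}")

    x0 = (
        operator.adjoint_dcf(binned_kspace)
        if config.density_compensation
        else operator.adjoint(binned_kspace)
    )
    if np.max(np.abs(x0)) == 0:
        raise ValueError("adjoint image is identically zero")
    # amplitude-calibrate the initialization: the (density-compensated)
    # adjoint has an arbitrary overall gain, so match it to the data in a
    # least-squares sense before normalizing
    fx0 = operator.forward(x0)
    num = sum(np.vdot(f, y).real for f, y in zip(fx0, binned_kspace))
    den = sum(np.vdot(f, f).real for f in fx0)
    x0 *= num / den
    scale = np.max(np.abs(x0))
    ys = [y / scale for y in binned_kspace]
    x = x0 / scale

    # normalization convention: data term divided by the encoding
    # spectral norm, image in units of the unit-max initialization; the
    # reference lambda_c = 0.01 is interpreted on this scale
    spec_norm = operator.spectral_norm()
    wdata = 2.0 / spec_norm
    wdtype = np.complex64 if config.single_precision else np.complex128
    x = x.astype(wdtype)
    lam = config.lambda_c * config.lambda_scale
    # penalty scales with the weight so the shrinkage level lam/rho stays
    # fixed in image units while large weights stiffen the coupling
    rho = config.admm_penalty * (lam / 0.01)

    def objective_value(xc, dxc):
        resid = operator.forward(xc)
        data = sum(np.sum(np.abs(r - y) ** 2) for r, y in zip(resid, ys))
        return float(data / spec_norm + lam * np.sum(np.abs(dxc)))

    objective = []
    cg_residual = 0.0
    if lam == 0.0 or rho == 0.0:
        # unregularized least squares: plain (warm-started) CG
        b_data = (wdata * operator.adjoint(ys)).astype(wdtype)
        for _ in range(config.n_admm_iters):
            x, cg_residual = _cg(
                lambda v: wdata * operator.normal(v),
                b_data,
                x,
                config.cg_max_iters,
                config.cg_tol,
            )
            if config.log_objective:
                objective.append(objective_value(x, temporal_diff(x)))
    else:
        b_data = (wdata * operator.adjoint(ys)).astype(wdtype)

        def gram(v):
            return wdata * operator.normal(v) + rho * temporal_diff_adjoint(
                temporal_diff(v)
            )

        z = soft_threshold(temporal_diff(x), lam / rho)
        u = temporal_diff(x) - z
        for _ in range(config.n_admm_iters):
            rhs = b_data + rho * temporal_diff_adjoint(z - u)
            x, cg_residual = _cg(gram, rhs, x, config.cg_max_iters, config.cg_tol)
            dx = temporal_diff(x)
            z = soft_threshold(dx + u, lam / rho)
            u = u + dx - z
            if config.log_objective:
                objective.append(objective_value(x, dx))
    if cg_residual > config.cg_tol and config.cg_max_iters > 0:
        warnings.warn(
            f"inner CG stopped at relative residual {cg_residual:.2e} "
            f"(> tol {config.cg_tol:.0e})",
            RuntimeWarning,
            stacklevel=2,
        )
    info = {
        "objective": np.asarray(objective),
        "cg_residual": cg_residual,
        "scale": scale,
        "spectral_norm": spec_norm,
    }
    out = x * scale
    if post_denoise is not None:
        out = post_denoise(out)
    img = Image4D(
        data=out,
        voxel_mm=voxel_mm,
        bin_width_ms=bin_width_ms if bin_width_ms is not None else float("nan"),
    )
    return img, info


# ---------------------------------------------------------------------------
# image quality


def compute_asnr(image3d: np.ndarray, lumen_mask: np.ndarray, background_mask: np.ndarray) -> float:
    """Apparent SNR: mean lumen magnitude over background magnitude sd."""
    if not lumen_mask.any() or not background_mask.any():
        raise ValueError("masks must be non-empty")
    if np.any(lumen_mask & background_mask):
        raise ValueError("lumen and background masks must be disjoint")
    mag = np.abs(image3d)
    sd = float(np.std(mag[background_mask], ddof=1))
    if sd == 0:
        raise ValueError("background standard deviation is zero")
    return float(np.mean(mag[lumen_mask]) / sd)
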