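"""Locally-low-rank + sparsity (LLRS) ADMM reconstruction.

The reconstruction solves

    min_x 1/2 ||y - DFEx||^2 + alpha * sum_{q,i} ||B_i x_q||_*
                             + beta  * sum_q     ||W x_q||_1

by variable splitting (z_iq = B_i x_q, v_q = W x_q) and the alternating
direction method of multipliers. Each iteration performs

1. a regularized SENSE normal-equation solve for x (conjugate gradients;
   because the readout axis is fully sampled the kx Fourier transforms cancel
   in the normal operator, so the systems decouple along the readout and only
   ky-kz transforms are applied inside the iteration),
2. singular value thresholding of every block Casorati matrix at alpha/mu1,
3. complex soft-thresholding of the wavelet coefficients at beta/mu2,
4. dual ascent on both constraint sets with step sizes mu1 and mu2.

The overlapping-block operator satisfies sum_i B_i^H B_i = block^2 * I and the
wavelet is orthonormal, so the Step-1 normal matrix is E^H F^H D^H D F E plus
an exact multiple of the identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as spfft

from smsmap.operators import (
    CoilMaps,
    ImageSeries,
    KSpaceData,
    adjoint,
    assemble_blocks,
    extract_blocks,
    fft_centered,
    ifft_centered,
    wavelet_adjoint,
    wavelet_forward,
)
logger = logging.getLogger(__name__)

__all__ = [
    "ReconParams",
    "AdmmState",
    "svt",
    "soft_threshold",
    "solve_step1",
    "reconstruct_llrs",
    "zero_filled",
]


@dataclass
class ReconParams:
    """Hyperparameters of the LLRS reconstruction.

    Defaults are the prospective-reconstruction settings: block size 7,
    alpha = 10^-3.75, mu1 = 10^-2.75, beta = 10^-4, mu2 = 10^-3, and 100 ADMM
    iterations; they presume k-space scaled so that the 99th-percentile
    magnitude of the zero-filled adjoint image equals one (the solver applies
    and undoes this normalization internally).
    """

    alpha: float = 10.0**-3.75
    beta: float = 1.0e-4
    mu1: float = 10.0**-2.75
    mu2: float = 1.0e-3
    block: int = 7
    max_iter: int = 100
    cg_tol: float = 1.0e-4
    cg_max_iter: int = 15
    block_mode: str = "overlap"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "mu1", "mu2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.block % 2 == 0:
            raise ValueError("block edge length must be odd")


@dataclass
class AdmmState:
    """Final splitting variables and per-iteration diagnostics."""

    x: ImageSeries
    k: int
    data_fidelity: list[float] = field(default_factory=list)
    primal_residual_llr: list[float] = field(default_factory=list)
    primal_residual_sparse: list[float] = field(default_factory=list)
    nuclear_norm: list[float] = field(default_factory=list)
    l1_norm: list[float] = field(default_factory=list)
    cg_iters: list[int] = field(default_factory=list)
    scale: float = 1.0


# ---------------------------------------------------------------------------
# proximal operators


def svt(M: np.ndarray, tau: float) -> np.ndarray:
    """Singular value thresholding: prox of ``tau * ||.||_*``.

    Computes ``U max(S - tau, 0) V^H`` from the full SVD of ``M``.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if not np.all(np.isfinite(M)):
        raise ValueError("svt input contains non-finite entries")
    if tau == 0:
        return M.copy()
    U, s, Vh = np.linalg.svd(M, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    return (U * s) @ Vh


def _svt_batch(M: np.ndarray, tau: float) -> tuple[np.ndarray, float]:
    """SVT of a stack of tall matrices (n, rows, cols), rows >= cols.

    Uses the eigendecomposition of the small Gram matrix M^H M: with
    M = U S V^H, thresholding amounts to M V diag(max(S-tau,0)/S) V^H, which
    avoids forming U for the (rows x cols) stack. Blocks whose Frobenius norm
    is at most tau are zeroed without a decomposition (sigma_max <= ||.||_F,
    so the result is exact).

    Returns the thresholded stack and the summed nuclear norm of the output.
    """
    out = np.zeros_like(M)
    fro = np.linalg.norm(M.reshape(M.shape[0], -1), axis=1)
    live = fro > tau
    if not live.any():
        return out, 0.0
    Ml = M[live]
    G = np.matmul(Ml.conj().transpose(0, 2, 1), Ml)
    w, V = np.linalg.eigh(G)
    s = np.sqrt(np.maximum(w, 0.0))
    s_thr = np.maximum(s - tau, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(s > 0, s_thr / s, 0.0).astype(w.dtype)
    proj = np.matmul(V * scale[:, None, :], V.conj().transpose(0, 2, 1))
    out[live] = np.matmul(Ml, proj)
    return out, float(s_thr.sum())


def soft_threshold(c: np.ndarray, tau: float) -> np.ndarray:
    """Complex soft-thresholding: prox of ``tau * ||.||_1`` elementwise."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    mag = np.abs(c)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(mag > 0, np.maximum(mag - tau, 0.0) / mag, 0.0)
    return c * factor


# ---------------------------------------------------------------------------
# Step 1: regularized SENSE solve


def _normal_op(
    x: np.ndarray, sens: np.ndarray, mask: np.ndarray, c: float
) -> np.ndarray:
    """Apply ``E^H F^H D F E + c I`` to (mb, T, nx, ny).

    The fully sampled readout axis is never transformed: the kx FFT commutes
    with the mask and cancels against its inverse in the normal operator, so
    the per-readout-point systems decouple and only (ky, kz) transforms run.
    """
    img = sens[:, :, None, :, :] * x[None]  # (nc, mb, T, nx, ny)
    arr = np.transpose(img, (0, 2, 3, 4, 1))  # (nc, T, nx, ny, mb)
    k = fft_centered(arr, axes=(-2, -1))
    k *= mask[None, :, None, :, :]
    arr = ifft_centered(k, axes=(-2, -1))
    img = np.transpose(arr, (0, 4, 1, 2, 3))
    out = np.sum(np.conj(sens)[:, :, None, :, :] * img, axis=0)
    return out + c * x


def _cg(matvec, rhs: np.ndarray, x0: np.ndarray, tol: float, max_iter: int):
    """Conjugate gradients on ndarrays for a Hermitian positive-definite map."""
    x = x0.copy()
    r = rhs - matvec(x)
    p = r.copy()
    rs = np.vdot(r, r).real
    rhs_norm = np.linalg.norm(rhs)
    if rhs_norm == 0:
        return np.zeros_like(rhs), 0, 0.0
    growth = 0
    n_done = 0
    prev_res = np.sqrt(rs)
    for it in range(max_iter):
        if np.sqrt(rs) / rhs_norm <= tol:
            break
        Ap = matvec(p)
        denom = np.vdot(p, Ap).real
        if denom <= 0:
            logger.warning("CG: non-positive curvature, stopping")
            break
        a = rs / denom
        x += a * p
        r -= a * Ap
        rs_new = np.vdot(r, r).real
        n_done = it + 1
        res = np.sqrt(rs_new)
        growth = growth + 1 if res > prev_res else 0
        if growth >= 5:
            logger.warning("CG: residual grew over 5 consecutive iterations")
            break
        prev_res = res
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x, n_done, float(np.sqrt(rs) / rhs_norm)


class _NormalSystem:
    """Step-1 workspace in a shift-free hybrid frame.

    The centered FFT convention wraps every transform in fftshift pairs;
    conjugating the normal operator by those (unitary) permutations lets CG
    run with plain FFTs on pre-shifted sensitivities and mask. Arrays inside
    CG live in (n_contrasts, nx, ny, mb) layout so the coil multiply
    broadcasts without transposes.
    """

    def __init__(self, sens: np.ndarray, mask: np.ndarray, c: float):
        # sens (nc, mb, nx, ny) -> (nc, 1, nx, ny, mb), ifftshifted over (y, z)
        s5 = np.ascontiguousarray(sens.transpose(0, 2, 3, 1))[:, None]
        self.sens = np.fft.ifftshift(s5, axes=(-2, -1))
        self.mask = np.fft.ifftshift(mask, axes=(-2, -1))[None, :, None, :, :]
        self.c = c

    def to_frame(self, x_im: np.ndarray) -> np.ndarray:
        """(mb, T, nx, ny) centered -> (T, nx, ny, mb) shifted."""
        return np.fft.ifftshift(x_im.transpose(1, 2, 3, 0), axes=(-2, -1)).copy()

    def from_frame(self, xs: np.ndarray) -> np.ndarray:
        return np.fft.fftshift(xs, axes=(-2, -1)).transpose(3, 0, 1, 2).copy()

    def matvec(self, xs: np.ndarray) -> np.ndarray:
        k = spfft.fftn(self.sens * xs[None], axes=(-2, -1), norm="ortho",
                       overwrite_x=True)
        k *= self.mask
        im = spfft.ifftn(k, axes=(-2, -1), norm="ortho", overwrite_x=True)
        return np.sum(np.conj(self.sens) * im, axis=0) + self.c * xs


def solve_step1(
    y: KSpaceData,
    z_minus: np.ndarray | None,
    v_minus: np.ndarray | None,
    coils: CoilMaps,
    params: ReconParams,
    warm_start: np.ndarray | None = None,
    block_shifts: list[tuple[int, int]] | None = None,
) -> tuple[np.ndarray, dict]:
    """Solve the regularized normal equation of ADMM Step 1.

    Solves ``(E^H F^H D^H D F E + (mu1*block^2 + mu2) I) x = E^H F^H D^H y +
    mu1 * sum_i B_i^H (z - lam/mu1) + mu2 * W^H (v - zeta/mu2)`` by conjugate
    gradients. ``z_minus`` is the stacked block array (mb, n_blocks, block^2,
    T) holding ``z - lam/mu1`` (``None`` to drop the term; the identity shift
    then also drops mu1, and likewise for ``v_minus``/mu2).
    """
    sens = coils.sens
    mask = y.pattern.mask
    x0 = adjoint(y, coils).data
    rhs = x0.copy()
    c = 0.0
    if z_minus is not None:
        b = params.block
        mb, T, nx, ny = x0.shape
        for q in range(mb):
            rhs[q] += params.mu1 * assemble_blocks(
                z_minus[q],
                b,
                (T, nx, ny),
                mode=params.block_mode,
                shift=(0, 0) if block_shifts is None else block_shifts[q],
            )
        c += params.mu1 * (b * b if params.block_mode == "overlap" else 1.0)
    if v_minus is not None:
        rhs += params.mu2 * wavelet_adjoint(v_minus)
        c += params.mu2
    x_init = warm_start if warm_start is not None else np.zeros_like(rhs)
    x, n_iter, rel_res = _cg(
        lambda v: _normal_op(v, sens, mask, c),
        rhs,
        x_init,
        params.cg_tol,
        params.cg_max_iter,
    )
    return x, {"cg_iters": n_iter, "cg_rel_res": rel_res}


# ---------------------------------------------------------------------------
# full ADMM


def zero_filled(y: KSpaceData, coils: CoilMaps) -> ImageSeries:
    """Zero-filled adjoint reconstruction ``E^H F^H D^H y`` (the baseline)."""
    return adjoint(y, coils)


def cg_sense(
    y: KSpaceData,
    coils: CoilMaps,
    tol: float = 1.0e-6,
    max_iter: int = 50,
) -> ImageSeries:
    """Unregularized SENSE least squares ``argmin ||y - DFEx||`` by CG.

    The normal operator is only positive semi-definite at high acceleration,
    so CG acts as an iterative regularizer: ``max_iter`` bounds the effective
    model complexity.
    """
    system = _NormalSystem(coils.sens, y.pattern.mask, 0.0)
    rhs = system.to_frame(adjoint(y, coils).data)
    x, _, _ = _cg(system.matvec, rhs, np.zeros_like(rhs), tol, max_iter)
    return ImageSeries(data=system.from_frame(x))


def reconstruct_llrs(
    y: KSpaceData,
    coils: CoilMaps,
    params: ReconParams | None = None,
    compute_dtype: np.dtype | None = np.complex64,
) -> tuple[ImageSeries, AdmmState]:
    """Run the LLRS ADMM (Steps 1-4) for ``params.max_iter`` iterations.

    k-space is scaled internally so the 99th-percentile magnitude of the
    zero-filled image is one (the regularization weights presume this scale);
    the scale is undone on output. ``compute_dtype`` selects the working
    precision (single precision by default; pass ``None`` to keep the input
    dtype).

    Returns the reconstructed series and the :class:`AdmmState` with
    per-iteration data fidelity, primal residuals, and regularizer values.
    """
    params = params or ReconParams()
    rng = np.random.default_rng(params.seed)
    mask = y.pattern.mask
    samples = y.samples
    if compute_dtype is not None:
        samples = samples.astype(compute_dtype, copy=False)
    sens = coils.sens.astype(samples.dtype, copy=False)
    coils_c = CoilMaps(sens=sens)

    x0 = adjoint(KSpaceData(samples, y.pattern), coils_c).data
    scale = float(np.percentile(np.abs(x0), 99))
    if scale <= 0:
        raise ValueError("all-zero k-space input")
    yn = KSpaceData(samples / scale, y.pattern)
    y_hybrid = ifft_centered(yn.samples, axes=(-3,))
    mb, T, nx, ny = x0.shape
    b = params.block
    mode = params.block_mode

    aty = adjoint(yn, coils_c).data
    x = x0 / scale
    n_blocks = (
        nx * ny if mode == "overlap" else (nx // b) * (ny // b)
    )
    z = np.zeros((mb, n_blocks, b * b, T), dtype=x.dtype)
    lam = np.zeros_like(z)
    v = np.zeros((mb, T, nx, ny), dtype=x.dtype)
    zeta = np.zeros_like(v)
    shifts = [(0, 0)] * mb

    c = params.mu1 * (b * b if mode == "overlap" else 1.0) + params.mu2
    tau_svt = params.alpha / params.mu1
    tau_st = params.beta / params.mu2

    system = _NormalSystem(sens, mask, c)
    x_cg = system.to_frame(x)
    state = AdmmState(x=ImageSeries(data=x), k=0, scale=scale)
    for k in range(params.max_iter):
        # Step 1: x update (CG on the shifted normal equation)
        rhs = aty.copy()
        for q in range(mb):
            rhs[q] += params.mu1 * assemble_blocks(
                z[q] - lam[q] / params.mu1, b, (T, nx, ny), mode=mode,
                shift=shifts[q],
            )
        rhs += params.mu2 * wavelet_adjoint(v - zeta / params.mu2)
        x_cg, n_cg, _ = _cg(
            system.matvec,
            system.to_frame(rhs),
            x_cg,
            params.cg_tol,
            params.cg_max_iter,
        )
        x = system.from_frame(x_cg)
        state.cg_iters.append(n_cg)

        # Steps 2 & 4a: per-slice block SVT and dual ascent
        if mode == "shifted_nonoverlap":
            shifts = [tuple(rng.integers(0, b, size=2)) for _ in range(mb)]
        res_llr = 0.0
        nuc = 0.0
        for q in range(mb):
            bx = extract_blocks(x[q], b, mode=mode, shift=shifts[q])
            z[q], nuc_q = _svt_batch(bx + lam[q] / params.mu1, tau_svt)
            diff = bx - z[q]
            lam[q] += params.mu1 * diff
            res_llr += float(np.linalg.norm(diff) ** 2)
            nuc += nuc_q
        res_llr = np.sqrt(res_llr)

        # Steps 3 & 4b: wavelet soft-thresholding and dual ascent
        wx = wavelet_forward(x)
        v = soft_threshold(wx + zeta / params.mu2, tau_st)
        dv = wx - v
        zeta += params.mu2 * dv
        res_sp = float(np.linalg.norm(dv))

        # diagnostics (hybrid readout space: the kx transform is unitary)
        k_res = _hybrid_residual(x, sens, mask, y_hybrid)
        state.data_fidelity.append(0.5 * k_res**2)
        state.primal_residual_llr.append(res_llr)
        state.primal_residual_sparse.append(res_sp)
        state.nuclear_norm.append(nuc)
        state.l1_norm.append(float(np.abs(v).sum()))
        state.k = k + 1
        if (k + 1) % 10 == 0 or k == 0:
            logger.info(
                "iter %3d | fidelity %.3e | r_llr %.3e | r_sparse %.3e",
                k + 1,
                state.data_fidelity[-1],
                res_llr,
                res_sp,
            )

    out = ImageSeries(data=x * scale)
    state.x = out
    return out, state


def _hybrid_residual(
    x: np.ndarray, sens: np.ndarray, mask: np.ndarray, y_hybrid: np.ndarray
) -> float:
    """``||D F E x - y||_F`` evaluated in the (x, ky, kz) hybrid space.

    The readout-axis transform is unitary and commutes with the mask, so the
    residual norm can be computed without it.
    """
    img = sens[:, :, None, :, :] * x[None]
    arr = np.transpose(img, (0, 2, 3, 4, 1))
    k = fft_centered(arr, axes=(-2, -1))
    k *= mask[None, :, None, :, :]
    return float(np.linalg.norm(k - y_hybrid))
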