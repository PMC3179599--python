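"""k-t PCA constrained reconstruction.

Each pixel's time course is modelled as its temporal mean plus a short
expansion in temporal principal components learned from the low-resolution
training data:

    s(x, y, t) = mu(x, y) + sum_p  w(x, y, p) * b_p(t).

Because the acquisition is fully sampled along the readout (kx) direction,
the problem separates over image columns after a 1-D inverse FFT along kx.
For each column the unknown weight maps are estimated by regularized least
squares: the data term is block-diagonal over ky lines (each acquired line
constrains the ky-spectrum of the weight maps through the temporal basis at
the frames where that line was visited), while the prior -- per-pixel weight
variances measured on the training data -- is diagonal in y.  The coupled
system is solved by preconditioned conjugate gradients, which is exact for
any lattice (including acceleration factors that do not divide the matrix
size) and for partial Fourier, where absent lines simply contribute no data
term.

The temporal mean is handled separately: the time-average of the acquired
samples of every ky line gives a full-resolution static estimate, and a
constant temporal component (orthonormal to the mean-removed PCA basis) is
appended to the model so the solver can absorb the residual static error
where the dynamics make the strided time-average inexact.

Components with small training variance are shrunk toward zero; the
Tikhonov scale ``lambda_reg`` is expressed relative to the mean training
weight variance so defaults transfer across signal scales.  All solvers are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConfigurationError, DynamicSeries, InputError, ReconstructionError
from .ktspace import KtData, SamplingPattern, cfft1, cifft1, cifft2

__all__ = ["PCBasis", "ReconConfig", "build_basis", "unfold", "recon_reference", "nrmse"]


@dataclass
class PCBasis:
    """Temporal principal-component basis learned from training data.

    ``basis`` has orthonormal columns (n_frames x n_pc), ordered by
    decreasing explained variance; ``weight_variance`` holds the squared
    projection of every training pixel time-course onto each component,
    shape (rows, cols, n_pc); ``temporal_mean`` is the per-pixel mean over
    frames removed before the PCA.
    """

    basis: np.ndarray
    weight_variance: np.ndarray
    n_pc: int
    temporal_mean: np.ndarray
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        gram = self.basis.T @ self.basis
        if not np.allclose(gram, np.eye(self.n_pc), atol=1e-8):
            raise ConfigurationError("basis columns must be orthonormal")


@dataclass
class ReconConfig:
    """Open reconstruction choices (rank, regularization, DC handling).

    ``n_refine`` extra solver passes re-measure the per-pixel weight
    variances on the previous pass's full-resolution output instead of the
    ky-blurred training images, sharpening alias discrimination; one pass
    is the default.
    """

    n_pc: int = 8
    lambda_reg: float = 3e-3
    handle_dc: bool = True
    n_refine: int = 1
    cg_tol: float = 1e-9
    cg_maxiter: int = 500

    def __post_init__(self) -> None:
        if self.n_pc < 1:
            raise ConfigurationError("n_pc must be >= 1")
        if self.lambda_reg <= 0:
            raise ConfigurationError("lambda_reg must be > 0")
        if self.n_refine < 0:
            raise ConfigurationError("n_refine must be >= 0")


def build_basis(training: DynamicSeries, n_pc: int) -> PCBasis:
    """Principal component analysis of the training pixel time-courses.

    The per-pixel temporal mean is removed, the pixels-by-frames matrix is
    decomposed by SVD, and the first ``n_pc`` right singular vectors are
    retained as the temporal basis (deterministic sign convention: the
    entry of largest magnitude of each component is positive).
    """
    nt = training.n_frames
    if n_pc > nt:
        raise ConfigurationError(f"n_pc={n_pc} exceeds the {nt} training frames")
    ny, nx = training.data.shape[1:]
    X = training.data.reshape(nt, ny * nx).T  # pixels x frames
    mean = X.mean(axis=1)
    Xc = X - mean[:, None]
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    B = Vt[:n_pc].T  # (nt, n_pc)
    flip = np.sign(B[np.argmax(np.abs(B), axis=0), np.arange(B.shape[1])])
    flip[flip == 0] = 1.0
    B = B * flip
    proj = Xc @ B  # (pixels, n_pc)
    var = (proj**2).reshape(ny, nx, n_pc)
    return PCBasis(
        basis=B,
        weight_variance=var,
        n_pc=n_pc,
        temporal_mean=mean.reshape(ny, nx),
        explained_variance=s[:n_pc] ** 2,
    )


def recon_reference(data: KtData) -> DynamicSeries:
    """Plain inverse-Fourier magnitude reconstruction of fully sampled data."""
    if not data.fully_sampled:
        raise InputError("recon_reference requires fully sampled k-t data (missing lines present)")
    img = np.abs(cifft2(data.kspace))
    return DynamicSeries(data=img, frame_times_s=data.frame_times_s.copy(), pixel_mm=data.pixel_mm)


def unfold(
    data: KtData,
    pattern: SamplingPattern,
    basis: PCBasis,
    cfg: ReconConfig | None = None,
) -> DynamicSeries:
    """Resolve undersampling by regularized least squares in x-pc space.

    See the module docstring for the model.  Output is the magnitude of the
    mean-plus-basis expansion; nonnegative by construction.
    """
    cfg = cfg or ReconConfig()
    nt, n_ky, nx = data.kspace.shape
    if basis.basis.shape[0] != nt:
        raise InputError(f"basis has {basis.basis.shape[0]} frames, data has {nt}")
    if pattern.mask.shape != (nt, n_ky):
        raise InputError("pattern mask is inconsistent with the k-t data shape")
    if basis.n_pc > cfg.n_pc:
        B = basis.basis[:, : cfg.n_pc]
        sig2_dyn = basis.weight_variance[..., : cfg.n_pc]
    else:
        B = basis.basis
        sig2_dyn = basis.weight_variance

    mask = pattern.mask  # (nt, n_ky)
    D = cifft1(data.kspace, axis=2)  # hybrid (t, ky, x)

    counts = mask.sum(axis=0)
    mhat = np.einsum("tq,tqx->qx", mask, D) / np.maximum(counts, 1)[:, None]
    if cfg.handle_dc:
        Dres = D - mhat[None, :, :]
    else:
        mhat = np.zeros_like(mhat)
        Dres = D
    Dres = Dres * mask[:, :, None]

    # augment with a constant temporal component (orthonormal to the
    # zero-mean PCA components) to carry static residuals
    const = np.full((nt, 1), 1.0 / np.sqrt(nt))
    Bt = np.concatenate([B, const], axis=1)  # (nt, P)
    P = Bt.shape[1]

    Mq = np.einsum("tq,ti,tj->qij", mask, Bt, Bt)  # (n_ky, P, P)
    rhs = np.einsum("tq,ti,tqx->xqi", mask, Bt, Dres)  # (nx, n_ky, P)
    mean_img = cifft1(mhat, axis=0)  # (y, x)

    def solve(sig2_dyn_p: np.ndarray) -> np.ndarray:
        """One regularized LS solve given per-pixel dynamic weight variances."""
        mean_var = float(sig2_dyn_p.mean())
        if mean_var <= 0:
            mean_var = 1e-30  # static data: everything shrinks to the mean
        if cfg.handle_dc:
            sig2_static = sig2_dyn_p.mean(axis=-1, keepdims=True)
        else:
            sig2_static = (basis.temporal_mean**2)[..., None] * nt
        sig2 = np.concatenate([sig2_dyn_p, sig2_static], axis=-1)  # (ny, nx, P)

        alpha = cfg.lambda_reg * mean_var
        floor = 1e-2 * mean_var
        lam_x = np.transpose(alpha / (sig2 + floor), (1, 0, 2))  # (nx, ny, P)

        lam_bar = lam_x.mean(axis=(0, 1))
        try:
            Pinv = np.linalg.inv(Mq + np.diag(lam_bar)[None, :, :])
        except np.linalg.LinAlgError as e:  # pragma: no cover - guarded by lam > 0
            raise ReconstructionError(f"singular preconditioner despite regularization: {e}") from e

        def apply_A(W: np.ndarray) -> np.ndarray:
            out = np.einsum("qij,xqj->xqi", Mq, W)
            out += cfft1(lam_x * cifft1(W, axis=1), axis=1)
            return out

        def apply_Minv(R: np.ndarray) -> np.ndarray:
            return np.einsum("qij,xqj->xqi", Pinv, R)

        # preconditioned CG on the Hermitian positive-definite normal equations
        W = np.zeros_like(rhs)
        r = rhs.copy()
        z = apply_Minv(r)
        p = z.copy()
        rz = np.vdot(r, z).real
        rhs_norm = np.linalg.norm(rhs) or 1.0
        converged = False
        for _ in range(cfg.cg_maxiter):
            Ap = apply_A(p)
            pAp = np.vdot(p, Ap).real
            if pAp <= 0:
                raise ReconstructionError(
                    f"normal equations lost positive definiteness (p'Ap={pAp:.3e}); "
                    "check lambda_reg and the training variances"
                )
            a = rz / pAp
            W += a * p
            r -= a * Ap
            if np.linalg.norm(r) / rhs_norm < cfg.cg_tol:
                converged = True
                break
            z = apply_Minv(r)
            rz_new = np.vdot(r, z).real
            p = z + (rz_new / rz) * p
            rz = rz_new
        if not converged:
            resid = np.linalg.norm(apply_A(W) - rhs) / rhs_norm
            if resid > 1e-3:
                raise ReconstructionError(
                    f"CG did not converge: relative residual {resid:.3e} after "
                    f"{cfg.cg_maxiter} iterations"
                )

        w = cifft1(W, axis=1)  # (nx, y, P)
        S = mean_img[None, :, :] + np.einsum("ti,xyi->tyx", Bt, w)
        return np.abs(S)

    out = solve(sig2_dyn)
    for _ in range(cfg.n_refine):
        # re-measure the prior on the full-resolution output of the last pass
        X = out.reshape(nt, -1).T
        Xc = X - X.mean(axis=1)[:, None]
        proj = Xc @ B
        out = solve((proj**2).reshape(out.shape[1], out.shape[2], B.shape[1]))

    return DynamicSeries(data=out, frame_times_s=data.frame_times_s.copy(), pixel_mm=data.pixel_mm)


def nrmse(recon: DynamicSeries | np.ndarray, reference: DynamicSeries | np.ndarray) -> float:
    """Whole-series normalized RMS error, ||a - b|| / ||b||."""
    a = recon.data if isinstance(recon, DynamicSeries) else np.asarray(recon)
    b = reference.data if isinstance(reference, DynamicSeries) else np.asarray(reference)
    if a.shape != b.shape:
        raise InputError("shapes differ")
    return float(np.linalg.norm(a - b) / np.linalg.norm(b))
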