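"""k-t sampling: sheared-lattice undersampling, training profiles, encoding.

The acquisition skips phase-encode (ky) lines in a lattice that shears by
one line per frame: frame ``t`` acquires the lines ``k`` with
``k % R == t % R``, so over any ``R`` consecutive frames every line is
visited exactly once.  A few central ky lines (training profiles) are
acquired in every frame; they provide the low-resolution series from which
the temporal basis of the reconstruction is learned.  Optional partial
Fourier drops the top fraction of ky space (zero-filled downstream).

k-space is centered: the DC line sits at index ``n_ky // 2``.  All
transforms are unitary (``norm="ortho"``).  Missing data is carried as an
explicit boolean mask next to the k-space values, never as an implicit
numeric zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ConfigurationError, DynamicSeries, InputError

__all__ = [
    "SamplingPattern",
    "KtData",
    "make_pattern",
    "encode",
    "extract_training",
    "cfft2",
    "cifft2",
]


def cfft2(x: np.ndarray) -> np.ndarray:
    """Centered unitary 2-D FFT over the last two axes."""
    ax = (-2, -1)
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x, axes=ax), axes=ax, norm="ortho"), axes=ax)


def cifft2(x: np.ndarray) -> np.ndarray:
    """Centered unitary 2-D inverse FFT over the last two axes."""
    ax = (-2, -1)
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(x, axes=ax), axes=ax, norm="ortho"), axes=ax)


def cfft1(x: np.ndarray, axis: int) -> np.ndarray:
    """Centered unitary 1-D FFT along ``axis``."""
    return np.fft.fftshift(
        np.fft.fft(np.fft.ifftshift(x, axes=axis), axis=axis, norm="ortho"), axes=axis
    )


def cifft1(x: np.ndarray, axis: int) -> np.ndarray:
    """Centered unitary 1-D inverse FFT along ``axis``."""
    return np.fft.fftshift(
        np.fft.ifft(np.fft.ifftshift(x, axes=axis), axis=axis, norm="ortho"), axes=axis
    )


@dataclass
class SamplingPattern:
    """Per-frame ky acquisition mask plus the training-line set."""

    mask: np.ndarray  # (n_frames, n_ky) bool, True = acquired
    training_lines: np.ndarray  # central ky indices acquired every frame
    R: int
    n_train: int
    pf_fraction: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.training_lines = np.asarray(self.training_lines, dtype=int)

    @property
    def n_frames(self) -> int:
        return self.mask.shape[0]

    @property
    def n_ky(self) -> int:
        return self.mask.shape[1]

    @property
    def lines_per_frame(self) -> np.ndarray:
        return self.mask.sum(axis=1)

    @property
    def net_acceleration(self) -> float:
        """Effective acceleration: acquirable lines over mean acquired lines."""
        return self.n_ky * self.pf_fraction / float(self.lines_per_frame.mean())


@dataclass
class KtData:
    """Masked complex k-t data (frames x ky x kx) with its pattern."""

    kspace: np.ndarray
    mask: np.ndarray  # (n_frames, n_ky)
    pattern: SamplingPattern
    frame_times_s: np.ndarray
    pixel_mm: float
    noise_sd: float = 0.0
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return self.kspace.shape[0]

    @property
    def fully_sampled(self) -> bool:
        return bool(self.mask.all())


def make_pattern(
    n_ky: int,
    n_frames: int,
    R: int,
    n_train: int,
    pf_fraction: float = 1.0,
) -> SamplingPattern:
    """Build the sheared-lattice pattern with centered training lines.

    Non-training lines obey ``k % R == t % R`` (lattice phase advances by
    one line per frame).  Training lines are the ``n_train`` lines centered
    on DC (index ``n_ky // 2``), acquired every frame.  Partial Fourier
    removes the top ``(1 - pf_fraction) * n_ky`` lines except training
    lines.
    """
    if not (1 <= R <= n_ky):
        raise ConfigurationError(f"acceleration R={R} must satisfy 1 <= R <= n_ky={n_ky}")
    if not (0 <= n_train < n_ky):
        raise ConfigurationError(f"n_train={n_train} must satisfy 0 <= n_train < n_ky={n_ky}")
    if not (0.5 < pf_fraction <= 1.0):
        raise ConfigurationError("pf_fraction must be in (0.5, 1.0]")

    dc = n_ky // 2
    start = dc - n_train // 2
    training = np.arange(start, start + n_train)

    k = np.arange(n_ky)
    t = np.arange(n_frames)
    mask = (k[None, :] % R) == (t[:, None] % R)
    mask[:, training] = True

    if pf_fraction < 1.0:
        n_cut = int(round((1.0 - pf_fraction) * n_ky))
        if n_cut > 0:
            cut = np.zeros(n_ky, dtype=bool)
            cut[n_ky - n_cut :] = True
            cut[training] = False
            mask[:, cut] = False

    return SamplingPattern(mask=mask, training_lines=training, R=R, n_train=n_train, pf_fraction=pf_fraction)


def encode(
    series: DynamicSeries,
    pattern: SamplingPattern,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> KtData:
    """Forward-encode a dynamic series into masked, noisy k-t data.

    Per-frame centered unitary 2-D FFT; seeded complex Gaussian noise of
    standard deviation ``noise_sd`` per real/imaginary component (image- and
    k-space noise levels coincide under the unitary transform); unacquired
    lines are zeroed and flagged in the mask.
    """
    if series.data.shape[1] != pattern.n_ky:
        raise InputError(
            f"series has {series.data.shape[1]} rows but pattern expects n_ky={pattern.n_ky}"
        )
    if series.n_frames != pattern.n_frames:
        raise InputError(
            f"series has {series.n_frames} frames but pattern has {pattern.n_frames}"
        )
    k = cfft2(series.data.astype(complex))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        k = k + noise_sd * (rng.standard_normal(k.shape) + 1j * rng.standard_normal(k.shape))
    k = k * pattern.mask[:, :, None]
    return KtData(
        kspace=k,
        mask=pattern.mask.copy(),
        pattern=pattern,
        frame_times_s=series.frame_times_s.copy(),
        pixel_mm=series.pixel_mm,
        noise_sd=noise_sd,
        seed=seed,
    )


def training_window(n_train: int) -> np.ndarray:
    """Raised-cosine taper across the training-band edges.

    Up to two lines at each edge are tapered (fewer for narrow bands so the
    DC line always keeps unit weight).  For the default three-line band the
    weights are [0.5, 1, 0.5], whose ky kernel ``1 + cos`` is nonnegative:
    the training image of a nonnegative object stays nonnegative.
    """
    w = np.ones(n_train)
    L = min(2, max(0, (n_train - 1) // 2))
    for d in range(L):
        taper = np.sin(np.pi * (d + 1) / (2.0 * (L + 1))) ** 2
        w[d] = min(w[d], taper)
        w[n_train - 1 - d] = min(w[n_train - 1 - d], taper)
    return w


def extract_training(data: KtData, pattern: SamplingPattern) -> DynamicSeries:
    """Low-resolution series from the training profiles only.

    Keeps the training lines (tapered across the band edges), zero-fills
    the rest and inverse-transforms each frame.  Full matrix size, low ky
    resolution; magnitude output.
    """
    if pattern.n_train < 1:
        raise ConfigurationError("extract_training requires n_train >= 1")
    w = training_window(pattern.n_train)
    k = np.zeros_like(data.kspace)
    k[:, pattern.training_lines, :] = data.kspace[:, pattern.training_lines, :] * w[None, :, None]
    img = np.abs(cifft2(k))
    return DynamicSeries(data=img, frame_times_s=data.frame_times_s.copy(), pixel_mm=data.pixel_mm)
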