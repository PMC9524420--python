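"""Target identification for SSVEP epochs.

The decoder correlates the multi-channel epoch X against a bank of
sine/cosine harmonic references, one per candidate stimulation
frequency:

    Y_m = [sin(2*pi*f_m*t); cos(2*pi*f_m*t); ...;
           sin(2*pi*H*f_m*t); cos(2*pi*H*f_m*t)],  t = 1/F ... P/F

The canonical correlation rho_m between X and Y_m measures how much of
the epoch lives in the subspace spanned by the harmonics of f_m; the
attended target is the argmax over m.  Three decoders are provided:

* plain CCA (reference signals only, training-free),
* filter-bank CCA (per-sub-band correlations, combined as a weighted
  sum of squared coefficients, exploiting harmonic structure),
* template-extended CCA (per-target averaged training templates,
  phase-aligned by circular shifting, combined with the reference
  correlation).

Canonical correlations are computed by whitening the covariance blocks
with Cholesky factors and taking the largest singular value of the
whitened cross-covariance.  Covariance blocks receive a tiny relative
ridge (1e-12 * trace/dim); if a block is numerically rank deficient the
ridge is escalated to 1e-9 * trace/dim and a warning is emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy import signal as sps

from .codec import AliasingError, CodeBook
from .synth import Epoch, EpochSet

TWO_PI = 2.0 * np.pi

__all__ = [
    "HarmonicReference",
    "CCAResult",
    "TemplateSet",
    "DecodingResult",
    "FilterBankSpec",
    "make_reference",
    "cca_coefficient",
    "classify",
    "phase_shift_template",
    "build_templates",
    "template_classify",
    "filterbank_classify",
    "default_filterbank",
]

RIDGE_DEFAULT = 1e-12
RIDGE_FALLBACK = 1e-9


@dataclass(frozen=True)
class HarmonicReference:
    """Sine/cosine harmonic reference matrix for one candidate frequency."""

    frequency: float
    matrix: np.ndarray  # 2H x P
    n_harmonics: int
    sampling_rate: float

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class CCAResult:
    """Largest canonical correlation and the two projection weight vectors."""

    rho: float
    wx: np.ndarray
    wy: np.ndarray


@dataclass(frozen=True)
class DecodingResult:
    """Per-target correlation scores and the argmax decision."""

    rho_per_target: np.ndarray
    predicted_index: int
    predicted_frequency: float


@dataclass(frozen=True)
class FilterBankSpec:
    """Sub-band edges and combination weights for filter-bank CCA."""

    band_edges: tuple[tuple[float, float], ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.band_edges) != len(self.weights):
            raise ValueError("band_edges and weights must have equal length")
        if any(w <= 0 for w in self.weights):
            raise ValueError("weights must be positive")
        lows = [b[0] for b in self.band_edges]
        if any(lo >= hi for lo, hi in self.band_edges):
            raise ValueError("each band needs low < high")
        if lows != sorted(lows):
            raise ValueError("bands must be ordered by lower edge")

    @property
    def n_subbands(self) -> int:
        return len(self.band_edges)


def default_filterbank(n_subbands: int = 5, upper: float = 88.0) -> FilterBankSpec:
    """Standard filter-bank design: sub-band b spans [8*b, upper] Hz with
    weight b**(-1.25) + 0.25 (b = 1..n)."""
    edges = tuple((8.0 * b, upper) for b in range(1, n_subbands + 1))
    weights = tuple(float(b) ** (-1.25) + 0.25 for b in range(1, n_subbands + 1))
    return FilterBankSpec(band_edges=edges, weights=weights)


@dataclass(frozen=True)
class TemplateSet:
    """Per-target averaged training templates, phase-aligned.

    ``zero_phase[m]`` is the channels x samples average of the training
    trials of target m, circularly shifted to zero phase; ``shifted[m]``
    is the same template shifted back to the target's coded phase, used
    for matching.
    """

    zero_phase: tuple[np.ndarray, ...]
    shifted: tuple[np.ndarray, ...]
    codebook: CodeBook
    sampling_rate: float


def make_reference(
    frequency: float, n_harmonics: int, sampling_rate: float, n_samples: int
) -> HarmonicReference:
    """Harmonic sine/cosine reference matrix (2H rows, P columns).

    Row 2k-2 is sin(2*pi*k*f*t) and row 2k-1 is cos(2*pi*k*f*t) for
    harmonic k, with t = 1/F, 2/F, ..., P/F.
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    if n_harmonics * frequency >= sampling_rate / 2.0:
        raise AliasingError(
            f"harmonic {n_harmonics} of {frequency} Hz exceeds Nyquist "
            f"({sampling_rate / 2} Hz)"
        )
    t = np.arange(1, n_samples + 1) / sampling_rate
    rows = []
    for k in range(1, n_harmonics + 1):
        arg = TWO_PI * k * frequency * t
        rows.append(np.sin(arg))
        rows.append(np.cos(arg))
    return HarmonicReference(
        frequency=float(frequency),
        matrix=np.vstack(rows),
        n_harmonics=int(n_harmonics),
        sampling_rate=float(sampling_rate),
    )


def _chol_with_ridge(C: np.ndarray, ridge: float):
    dim = C.shape[0]
    eps = ridge * np.trace(C) / dim
    return sla.cholesky(C + eps * np.eye(dim), lower=True)


def cca_coefficient(X: np.ndarray, Y: np.ndarray, ridge: float = RIDGE_DEFAULT) -> CCAResult:
    """Largest canonical correlation between two multi-channel signals.

    Parameters
    ----------
    X, Y : arrays with shape (channels, samples); a 1-D array is treated
        as a single channel.  Both must share the sample count.
    ridge : relative Tikhonov ridge added to the covariance blocks
        (scaled by trace/dim).

    Returns
    -------
    CCAResult with ``rho`` in [0, 1] and the canonical weight vectors.
    The result is invariant (to ~1e-8) under invertible recombination of
    either input's channels.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"sample counts differ: {X.shape[1]} vs {Y.shape[1]}")
    n = X.shape[1]
    if n <= X.shape[0] + Y.shape[0]:
        raise ValueError(
            f"need more samples ({n}) than total channels ({X.shape[0] + Y.shape[0]})"
        )
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Cxx = Xc @ Xc.T / n
    Cyy = Yc @ Yc.T / n
    Cxy = Xc @ Yc.T / n
    if np.trace(Cxx) == 0 or np.trace(Cyy) == 0:
        raise ValueError("singular input: a block has zero variance")
    try:
        Lx = _chol_with_ridge(Cxx, ridge)
        Ly = _chol_with_ridge(Cyy, ridge)
    except sla.LinAlgError:
        warnings.warn(
            "rank-deficient covariance: escalating ridge regularization",
            RuntimeWarning, stacklevel=2,
        )
        Lx = _chol_with_ridge(Cxx, RIDGE_FALLBACK)
        Ly = _chol_with_ridge(Cyy, RIDGE_FALLBACK)
    # whitened cross-covariance: K = Lx^-1 Cxy Ly^-T, rho = sigma_max(K)
    K = sla.solve_triangular(Lx, Cxy, lower=True)
    K = sla.solve_triangular(Ly, K.T, lower=True).T
    U, s, Vt = sla.svd(K, full_matrices=False)
    rho = float(min(1.0, max(0.0, s[0])))
    wx = sla.solve_triangular(Lx.T, U[:, 0], lower=False)
    wy = sla.solve_triangular(Ly.T, Vt[0], lower=False)
    return CCAResult(rho=rho, wx=wx, wy=wy)


def _reference_bank(
    codebook: CodeBook, n_harmonics: int, sampling_rate: float, n_samples: int
) -> list[HarmonicReference]:
    return [
        make_reference(c.frequency, n_harmonics, sampling_rate, n_samples)
        for c in codebook.codes
    ]


def _decision(rho: np.ndarray, codebook: CodeBook) -> DecodingResult:
    idx = int(np.argmax(rho))  # argmax takes the lowest index on ties
    return DecodingResult(
        rho_per_target=rho,
        predicted_index=idx,
        predicted_frequency=codebook[idx].frequency,
    )


def classify(epoch: Epoch, codebook: CodeBook, n_harmonics: int = 5) -> DecodingResult:
    """Plain CCA frequency recognition: rho_m against each harmonic
    reference, decision by argmax (ties broken toward the lowest index)."""
    refs = _reference_bank(codebook, n_harmonics, epoch.spec.sampling_rate, epoch.n_samples)
    rho = np.array([cca_coefficient(epoch.data, r.matrix).rho for r in refs])
    return _decision(rho, codebook)


def phase_shift_template(
    template: np.ndarray, frequency: float, phase: float, sampling_rate: float
) -> np.ndarray:
    """Circularly shift a zero-phase template to a target phase.

    The shift is ``round(((2*pi - phase) mod 2*pi) / (2*pi*frequency) *
    sampling_rate)`` samples along the last axis, so phase 0 (and any
    multiple of 2*pi) is the identity.  Sub-sample phases are rounded to
    the nearest integer sample.
    """
    template = np.asarray(template)
    if template.shape[-1] < sampling_rate / frequency:
        raise ValueError("template shorter than one stimulus cycle")
    phase = float(np.mod(phase, TWO_PI))
    if phase == 0.0:
        return template.copy()
    shift = int(round(((TWO_PI - phase) % TWO_PI) / (TWO_PI * frequency) * sampling_rate))
    return np.roll(template, shift, axis=-1)


def build_templates(
    training: EpochSet | list[Epoch], codebook: CodeBook
) -> TemplateSet:
    """Average training trials per target into phase-aligned templates.

    Each trial is first shifted to zero phase (undoing its coded phase by
    circular shifting), averaged within target, and the average is
    shifted back to the coded phase for matching.
    """
    epochs = list(training)
    if not epochs:
        raise ValueError("no training epochs")
    fs = epochs[0].spec.sampling_rate
    zero_phase = []
    shifted = []
    for code in codebook.codes:
        trials = [e for e in epochs if e.label == code.index]
        if not trials:
            raise ValueError(f"no training trials for target {code.index}")
        aligned = [
            phase_shift_template(e.data, code.frequency, -code.phase, fs) for e in trials
        ]
        zp = np.mean(aligned, axis=0)
        zero_phase.append(zp)
        shifted.append(phase_shift_template(zp, code.frequency, code.phase, fs))
    return TemplateSet(
        zero_phase=tuple(zero_phase), shifted=tuple(shifted),
        codebook=codebook, sampling_rate=fs,
    )


def template_classify(
    epoch: Epoch, codebook: CodeBook, templates: TemplateSet, n_harmonics: int = 5
) -> DecodingResult:
    """Template-extended CCA: combine the reference correlation with the
    correlation against the per-target averaged template.

    Score_m = rho_ref(m)**2 + rho_template(m)**2, equal weights; the
    combined score is mapped back through sqrt(score/2) so entries stay
    in [0, 1].
    """
    refs = _reference_bank(codebook, n_harmonics, epoch.spec.sampling_rate, epoch.n_samples)
    rho = np.empty(len(codebook))
    for m, (ref, code) in enumerate(zip(refs, codebook.codes)):
        r_ref = cca_coefficient(epoch.data, ref.matrix).rho
        tmpl = templates.shifted[m][:, : epoch.n_samples]
        r_tmp = cca_coefficient(epoch.data, tmpl).rho
        rho[m] = np.sqrt(0.5 * (r_ref**2 + r_tmp**2))
    return _decision(rho, codebook)


def _subband(data: np.ndarray, low: float, high: float, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    high = min(high, 0.99 * nyq)
    sos = sps.cheby1(6, 0.5, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, data, axis=1)


def filterbank_classify(
    epoch: Epoch,
    codebook: CodeBook,
    fb: FilterBankSpec | None = None,
    n_harmonics: int = 5,
) -> DecodingResult:
    """Filter-bank CCA: per-sub-band canonical correlations combined as
    sum_b w_b * rho_b(m)**2, decision by argmax."""
    if fb is None:
        fb = default_filterbank()
    fs = epoch.spec.sampling_rate
    nyq = fs / 2.0
    if any(lo <= 0 or lo >= nyq for lo, _ in fb.band_edges):
        raise ValueError("filter-bank band edges must lie inside (0, Nyquist)")
    refs = _reference_bank(codebook, n_harmonics, fs, epoch.n_samples)
    score = np.zeros(len(codebook))
    for (low, high), w in zip(fb.band_edges, fb.weights):
        xb = _subband(epoch.data, low, high, fs)
        for m, ref in enumerate(refs):
            score[m] += w * cca_coefficient(xb, ref.matrix).rho ** 2
    # normalize to [0, 1] scale comparable with plain rho
    rho = np.sqrt(score / sum(fb.weights))
    return _decision(rho, codebook)
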