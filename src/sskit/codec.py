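"""Frequency-phase stimulus coding for an SSVEP speller.

An M-target speller assigns each target n a unique (frequency, phase)
pair on an equally spaced grid:

    f_n   = f0 + n * delta_f
    phi_n = (phi0 + n * delta_phi) mod 2*pi

so that neighbouring targets differ both in stimulation frequency and in
initial flicker phase.  The default 40-target grid spans 8.0-15.8 Hz in
0.2 Hz steps with a 0.5*pi phase interval.

Targets are indexed from 0 internally; a display layer may add 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TWO_PI = 2.0 * np.pi

__all__ = [
    "StimulusCode",
    "CodeBook",
    "StimulusWaveform",
    "build_codebook",
    "stimulus_waveform",
    "InvalidCodebookError",
    "AliasingError",
]


class InvalidCodebookError(ValueError):
    """Raised when codebook parameters cannot produce a valid code grid."""


class AliasingError(ValueError):
    """Raised when a requested sinusoid would violate the Nyquist limit."""


@dataclass(frozen=True)
class StimulusCode:
    """One speller target: 0-based index, flicker frequency and phase."""

    index: int
    frequency: float  # Hz
    phase: float  # radians, in [0, 2*pi)

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise InvalidCodebookError(f"frequency must be > 0, got {self.frequency}")
        if not (0.0 <= self.phase < TWO_PI):
            raise InvalidCodebookError(f"phase must lie in [0, 2*pi), got {self.phase}")


@dataclass(frozen=True)
class CodeBook:
    """Ordered frequency-phase code grid for an M-target speller."""

    codes: tuple[StimulusCode, ...]
    f0: float
    delta_f: float
    phi0: float
    delta_phi: float
    grid_shape: tuple[int, int] = (5, 8)

    def __len__(self) -> int:
        return len(self.codes)

    def __getitem__(self, n: int) -> StimulusCode:
        return self.codes[n]

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([c.frequency for c in self.codes])

    @property
    def phases(self) -> np.ndarray:
        return np.array([c.phase for c in self.codes])


@dataclass(frozen=True)
class StimulusWaveform:
    """Sampled luminance waveform of one flickering target, values in [0, 1]."""

    samples: np.ndarray
    frame_rate: float
    code: StimulusCode


def _default_grid_shape(n: int) -> tuple[int, int]:
    rows = int(np.floor(np.sqrt(n)))
    while rows > 1 and n % rows:
        rows -= 1
    return (rows, n // rows)


def build_codebook(
    n_targets: int = 40,
    f0: float = 8.0,
    delta_f: float = 0.2,
    phi0: float = 0.0,
    delta_phi: float = 0.5 * np.pi,
    grid_shape: tuple[int, int] | None = None,
) -> CodeBook:
    """Build an equal-interval frequency + equally spaced phase codebook.

    Target n (0-based) flickers at ``f0 + n*delta_f`` Hz with initial
    phase ``(phi0 + n*delta_phi) mod 2*pi``.  The defaults give the
    40-target grid 8.0-15.8 Hz, 0.5*pi phase interval.

    Raises
    ------
    InvalidCodebookError
        If fewer than 2 targets, non-positive ``delta_f``, or the grid
        would contain a frequency collision.
    """
    if n_targets < 2:
        raise InvalidCodebookError(f"n_targets must be >= 2, got {n_targets}")
    if delta_f <= 0:
        raise InvalidCodebookError(f"delta_f must be > 0, got {delta_f}")
    if f0 <= 0:
        raise InvalidCodebookError(f"f0 must be > 0, got {f0}")
    n = np.arange(n_targets)
    freqs = f0 + n * delta_f
    phases = np.mod(phi0 + n * delta_phi, TWO_PI)
    # guard the half-open interval against floating roundoff at 2*pi
    phases[phases >= TWO_PI] = 0.0
    if len(np.unique(freqs)) != n_targets:
        raise InvalidCodebookError("frequency collision in codebook grid")
    codes = tuple(
        StimulusCode(index=int(i), frequency=float(freqs[i]), phase=float(phases[i]))
        for i in n
    )
    shape = grid_shape if grid_shape is not None else _default_grid_shape(n_targets)
    if shape[0] * shape[1] != n_targets:
        raise InvalidCodebookError(f"grid_shape {shape} does not hold {n_targets} targets")
    return CodeBook(
        codes=codes, f0=float(f0), delta_f=float(delta_f),
        phi0=float(phi0), delta_phi=float(delta_phi), grid_shape=shape,
    )


def stimulus_waveform(
    code: StimulusCode, frame_rate: float, duration: float
) -> StimulusWaveform:
    """Sampled-sine luminance waveform for one target.

    samples[k] = 0.5 * (1 + sin(2*pi*f*k/frame_rate + phi)), mapping the
    sine code onto a displayable non-negative luminance in [0, 1].

    Raises
    ------
    AliasingError
        If ``frame_rate < 2 * code.frequency``.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    if frame_rate < 2.0 * code.frequency:
        raise AliasingError(
            f"frame_rate {frame_rate} Hz is below Nyquist for {code.frequency} Hz"
        )
    n_frames = int(round(duration * frame_rate))
    k = np.arange(n_frames)
    samples = 0.5 * (1.0 + np.sin(TWO_PI * code.frequency * k / frame_rate + code.phase))
    return StimulusWaveform(samples=samples, frame_rate=float(frame_rate), code=code)
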