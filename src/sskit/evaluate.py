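"""Simulated-online evaluation of the speller.

Each trial is truncated causally to a data length L, decoded, and scored;
leave-one-out cross-validation builds training templates from the
remaining trials when the decoder needs them.  Performance is summarized
by classification accuracy p, bits per selection

    B = log2 N + p*log2 p + (1-p)*log2((1-p)/(N-1))

(the Wolpaw formula; 0*log2(0) is taken as 0) and the information
transfer rate ITR = B * 60 / T in bits/min, where the selection time
T = L + gaze-shift allowance.  B is non-negative, with its global
minimum of exactly 0 at chance accuracy p = 1/N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decode import FilterBankSpec, classify, filterbank_classify, template_classify
from .synth import EpochSet

__all__ = [
    "EvalConfig",
    "EvalReport",
    "DecoderConfig",
    "bits_per_selection",
    "itr",
    "loo_cv",
    "accuracy_curve",
]

DEFAULT_LENGTHS = tuple(np.arange(0.5, 4.01, 0.5).round(2))


def bits_per_selection(n_targets: int, accuracy: float) -> float:
    """Bits of information per selection (Wolpaw formula).

    B = log2(N) + p*log2(p) + (1-p)*log2((1-p)/(N-1)), with the
    convention 0*log2(0) = 0.  Equals log2(N) at p = 1 and attains its
    minimum, exactly 0, at chance p = 1/N.
    """
    if n_targets < 2:
        raise ValueError(f"n_targets must be >= 2, got {n_targets}")
    if not (0.0 <= accuracy <= 1.0):
        raise ValueError(f"accuracy must lie in [0, 1], got {accuracy}")
    n = float(n_targets)
    p = float(accuracy)
    b = np.log2(n)
    if p > 0:
        b += p * np.log2(p)
    if p < 1:
        b += (1.0 - p) * np.log2((1.0 - p) / (n - 1.0))
    return float(b)


def itr(n_targets: int, accuracy: float, selection_time: float) -> float:
    """Information transfer rate in bits/min: B * 60 / T."""
    if selection_time <= 0:
        raise ValueError(f"selection_time must be > 0, got {selection_time}")
    return bits_per_selection(n_targets, accuracy) * 60.0 / selection_time


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation protocol: data-length sweep, gaze-shift time, CV scheme."""

    data_lengths: tuple[float, ...] = DEFAULT_LENGTHS
    gaze_shift_s: float = 0.5
    accuracy_threshold: float = 0.90
    cv: str = "loo"  # "loo" | "k-fold"
    k: int = 5

    def __post_init__(self) -> None:
        ls = list(self.data_lengths)
        if not ls or any(x <= 0 for x in ls) or ls != sorted(ls):
            raise ValueError("data_lengths must be positive and ascending")
        if not (0.0 < self.accuracy_threshold < 1.0):
            raise ValueError("accuracy_threshold must lie in (0, 1)")
        if self.cv not in ("loo", "k-fold"):
            raise ValueError(f"unknown cv scheme {self.cv!r}")


@dataclass(frozen=True)
class DecoderConfig:
    """Which decoder loo_cv runs: 'cca', 'fbcca' or 'template'."""

    mode: str = "cca"
    n_harmonics: int = 5
    filterbank: FilterBankSpec | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("cca", "fbcca", "template"):
            raise ValueError(f"unknown decoder mode {self.mode!r}")

    @property
    def needs_training(self) -> bool:
        return self.mode == "template"


@dataclass(frozen=True)
class EvalReport:
    """Per-data-length performance of one session/condition."""

    condition: str
    data_lengths: tuple[float, ...]
    accuracy: tuple[float, ...]
    bits: tuple[float, ...]
    itr: tuple[float, ...]
    n_trials: int
    n_targets: int
    gaze_shift_s: float
    confusion: tuple[np.ndarray, ...]  # one n_targets x n_targets matrix per length
    accuracy_threshold: float = 0.90

    def lengths_above_threshold(self) -> tuple[float, ...]:
        """Data lengths at which accuracy reaches the configured threshold."""
        return tuple(
            L for L, p in zip(self.data_lengths, self.accuracy)
            if p >= self.accuracy_threshold
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition,
                "data_length_s": self.data_lengths,
                "accuracy": self.accuracy,
                "bits_per_selection": self.bits,
                "itr_bits_per_min": self.itr,
                "n_trials": self.n_trials,
            }
        )


def _decode_trials(
    epochs: EpochSet, length: float, decoder: DecoderConfig
) -> np.ndarray:
    """Predicted label per trial at one data length (LOO for template mode)."""
    cb = epochs.codebook
    truncated = [e.truncated(length) for e in epochs]
    preds = np.empty(len(truncated), dtype=int)

    if decoder.mode == "cca":
        for i, ep in enumerate(truncated):
            preds[i] = classify(ep, cb, decoder.n_harmonics).predicted_index
    elif decoder.mode == "fbcca":
        for i, ep in enumerate(truncated):
            preds[i] = filterbank_classify(
                ep, cb, decoder.filterbank, decoder.n_harmonics
            ).predicted_index
    else:  # template: leave-one-out template construction via sum trick
        labels = np.array([e.label for e in truncated])
        counts = {m: int(np.sum(labels == m)) for m in range(len(cb))}
        short = [m for m, c in counts.items() if c < 2]
        if short:
            raise ValueError(
                f"template decoding needs >= 2 trials per label; "
                f"label(s) {short} have fewer"
            )
        sums = {
            m: np.sum([e.data for e in truncated if e.label == m], axis=0)
            for m in range(len(cb))
        }
        from .decode import TemplateSet, phase_shift_template

        fs = epochs.spec.sampling_rate
        for i, ep in enumerate(truncated):
            zero_phase, shifted = [], []
            for code in cb.codes:
                m = code.index
                if m == ep.label:
                    avg = (sums[m] - ep.data) / (counts[m] - 1)
                else:
                    avg = sums[m] / counts[m]
                zp = phase_shift_template(avg, code.frequency, -code.phase, fs)
                zero_phase.append(zp)
                shifted.append(phase_shift_template(zp, code.frequency, code.phase, fs))
            tmpl = TemplateSet(tuple(zero_phase), tuple(shifted), cb, fs)
            preds[i] = template_classify(ep, cb, tmpl, decoder.n_harmonics).predicted_index
    return preds


def loo_cv(
    epochs: EpochSet,
    decoder: DecoderConfig | None = None,
    config: EvalConfig | None = None,
    condition: str = "",
) -> EvalReport:
    """Simulated-online evaluation over a data-length sweep.

    For each data length L, every trial is truncated to its first
    round(L*F) samples and decoded.  In 'template' mode each trial is
    scored against templates averaged from all *other* trials
    (leave-one-out); the training-free CCA/FBCCA modes need no held-out
    templates, so LOO degenerates to per-trial scoring.  Deterministic
    given the EpochSet.
    """
    decoder = decoder or DecoderConfig()
    config = config or EvalConfig()
    if len(epochs) == 0:
        raise ValueError("empty epoch set")
    labels = epochs.labels()
    n_targets = len(epochs.codebook)
    acc, bits, itrs, confs = [], [], [], []
    for L in config.data_lengths:
        preds = _decode_trials(epochs, L, decoder)
        p = float(np.mean(preds == labels))
        conf = np.zeros((n_targets, n_targets), dtype=int)
        np.add.at(conf, (labels, preds), 1)
        b = bits_per_selection(n_targets, p)
        T = L + config.gaze_shift_s
        acc.append(p)
        bits.append(b)
        itrs.append(b * 60.0 / T)
        confs.append(conf)
    return EvalReport(
        condition=condition or (epochs.epochs[0].layout or "default"),
        data_lengths=tuple(config.data_lengths),
        accuracy=tuple(acc),
        bits=tuple(bits),
        itr=tuple(itrs),
        n_trials=len(epochs),
        n_targets=n_targets,
        gaze_shift_s=config.gaze_shift_s,
        confusion=tuple(confs),
        accuracy_threshold=config.accuracy_threshold,
    )


def accuracy_curve(reports: list[EvalReport]) -> tuple[pd.DataFrame, float]:
    """Aggregate reports into a tidy accuracy/ITR table.

    Reports sharing a condition label are aggregated as mean +- sample
    standard deviation across reports (e.g. across seeds or subjects).
    Returns the table and the data length maximizing mean ITR (pooled
    over conditions).
    """
    if not reports:
        raise ValueError("no reports")
    grids = {r.data_lengths for r in reports}
    if len(grids) != 1:
        raise ValueError(f"reports use mismatched data-length grids: {grids}")
    long = pd.concat([r.to_frame() for r in reports], ignore_index=True)
    table = (
        long.groupby(["condition", "data_length_s"], sort=True)
        .agg(
            accuracy_mean=("accuracy", "mean"),
            accuracy_sd=("accuracy", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
            itr_mean=("itr_bits_per_min", "mean"),
            itr_sd=("itr_bits_per_min", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
        )
        .reset_index()
    )
    pooled = table.groupby("data_length_s")["itr_mean"].mean()
    best_length = float(pooled.idxmax())
    return table, best_length
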