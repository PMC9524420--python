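"""On-disk formats: epoch container, codebook CSV, EDF slicing, run config.

Conventions used everywhere: 0-based sample indices, half-open
[onset, onset + duration) epoch intervals, seconds as floats, CSVs with
a header row, UTF-8 and LF line endings.

The epoch container is a directory::

    data/
      spec.json       acquisition metadata + session seed
      codebook.csv    target codes (with JSON sidecar codebook.json)
      epochs.csv      index: epoch_id,label,layout,onset_s,duration_s,file
      epoch_0000.f32  one raw little-endian float32 matrix per epoch
                      (row-major, channels x samples), or .csv

The float32 dialect round-trips bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .codec import CodeBook, StimulusCode
from .synth import AcquisitionSpec, Epoch, EpochSet

__all__ = [
    "write_codebook",
    "read_codebook",
    "write_epochset",
    "read_epochset",
    "read_edf",
    "EpochSetParseError",
]


class EpochSetParseError(ValueError):
    """Malformed epoch container: names the offending file/row."""


# ---------------------------------------------------------------- codebook

def write_codebook(codebook: CodeBook, path: str | Path) -> None:
    """Write codebook CSV (index,frequency_hz,phase_rad, full precision)
    plus a JSON sidecar with the grid parameters."""
    path = Path(path)
    lines = ["index,frequency_hz,phase_rad"]
    for c in codebook.codes:
        lines.append(f"{c.index},{c.frequency!r},{c.phase!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    sidecar = {
        "f0": codebook.f0,
        "delta_f": codebook.delta_f,
        "phi0": codebook.phi0,
        "delta_phi": codebook.delta_phi,
        "grid_shape": list(codebook.grid_shape),
    }
    path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2) + "\n", encoding="utf-8", newline="\n"
    )


def read_codebook(path: str | Path) -> CodeBook:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["index", "frequency_hz", "phase_rad"]
    if list(df.columns) != expected:
        raise EpochSetParseError(f"{path}: expected header {expected}, got {list(df.columns)}")
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise EpochSetParseError(f"missing codebook sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text(encoding="utf-8"))
    codes = tuple(
        StimulusCode(index=int(r.index), frequency=float(r.frequency_hz),
                     phase=float(r.phase_rad))
        for r in df.itertuples()
    )
    return CodeBook(
        codes=codes,
        f0=float(sidecar["f0"]),
        delta_f=float(sidecar["delta_f"]),
        phi0=float(sidecar["phi0"]),
        delta_phi=float(sidecar["delta_phi"]),
        grid_shape=tuple(sidecar["grid_shape"]),
    )


# ------------------------------------------------------------- epoch sets

def write_epochset(epochs: EpochSet, path: str | Path, dialect: str = "f32") -> None:
    """Serialize an EpochSet to a directory (float32 binary or CSV matrices)."""
    if dialect not in ("f32", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    spec = epochs.spec
    meta = {
        "sampling_rate": spec.sampling_rate,
        "montage": list(spec.montage),
        "band": list(spec.band),
        "seed": epochs.seed,
        "dialect": dialect,
    }
    (path / "spec.json").write_text(
        json.dumps(meta, indent=2) + "\n", encoding="utf-8", newline="\n"
    )
    write_codebook(epochs.codebook, path / "codebook.csv")
    rows = ["epoch_id,label,layout,onset_s,duration_s,file"]
    for i, ep in enumerate(epochs):
        fname = f"epoch_{i:04d}.{dialect}"
        if dialect == "f32":
            ep.data.astype("<f4").tofile(path / fname)
        else:
            np.savetxt(path / fname, ep.data, delimiter=",")
        rows.append(
            f"{i},{ep.label},{ep.layout},{ep.onset!r},{ep.duration!r},{fname}"
        )
    (path / "epochs.csv").write_text(
        "\n".join(rows) + "\n", encoding="utf-8", newline="\n"
    )


def read_epochset(path: str | Path) -> EpochSet:
    """Load an epoch container directory; inverse of :func:`write_epochset`."""
    path = Path(path)
    spec_file = path / "spec.json"
    if not spec_file.exists():
        raise EpochSetParseError(f"missing {spec_file}")
    meta = json.loads(spec_file.read_text(encoding="utf-8"))
    spec = AcquisitionSpec(
        sampling_rate=float(meta["sampling_rate"]),
        montage=tuple(meta["montage"]),
        band=tuple(meta["band"]),
    )
    codebook = read_codebook(path / "codebook.csv")
    index_file = path / "epochs.csv"
    if not index_file.exists():
        raise EpochSetParseError(f"missing {index_file}")
    df = pd.read_csv(index_file, keep_default_na=False)
    expected = ["epoch_id", "label", "layout", "onset_s", "duration_s", "file"]
    if list(df.columns) != expected:
        raise EpochSetParseError(
            f"{index_file}: expected header {expected}, got {list(df.columns)}"
        )
    epochs = []
    for r in df.itertuples():
        mat_file = path / str(r.file)
        if not mat_file.exists():
            raise EpochSetParseError(
                f"epoch_id {r.epoch_id}: matrix file {mat_file} not found"
            )
        n_samples = int(round(float(r.duration_s) * spec.sampling_rate))
        if mat_file.suffix == ".f32":
            flat = np.fromfile(mat_file, dtype="<f4")
            expected_len = spec.n_channels * n_samples
            if flat.size != expected_len:
                raise EpochSetParseError(
                    f"epoch_id {r.epoch_id}: {mat_file} has {flat.size} values, "
                    f"expected {expected_len} (truncated or wrong shape)"
                )
            data = flat.reshape(spec.n_channels, n_samples).astype(np.float32)
        else:
            data = np.loadtxt(mat_file, delimiter=",", ndmin=2)
            if data.shape != (spec.n_channels, n_samples):
                raise EpochSetParseError(
                    f"epoch_id {r.epoch_id}: shape {data.shape} != "
                    f"({spec.n_channels}, {n_samples})"
                )
        label = int(r.label)
        if not (0 <= label < len(codebook)):
            raise EpochSetParseError(
                f"epoch_id {r.epoch_id}: label {label} outside codebook"
            )
        epochs.append(
            Epoch(data=np.asarray(data, dtype=float), onset=float(r.onset_s),
                  label=label, spec=spec, layout=str(r.layout))
        )
    return EpochSet(epochs=tuple(epochs), codebook=codebook, seed=int(meta.get("seed", 0)))


# -------------------------------------------------------------------- EDF

def read_edf(
    path: str | Path,
    events: str | Path | pd.DataFrame,
    codebook: CodeBook,
    duration_s: float | None = None,
) -> EpochSet:
    """Slice a continuous EDF recording into labelled epochs.

    Parameters
    ----------
    path : EDF file.
    events : CSV path or DataFrame with columns ``onset_s,label`` and
        optionally ``duration_s`` and ``layout``; ``duration_s`` falls
        back to the ``duration_s`` argument.
    codebook : target codes the labels index into.

    Epochs are sliced [onset, onset + duration) with 0-based sample
    indices, i.e. samples ``round(onset*F)`` to ``round((onset+dur)*F) - 1``.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # mne loads volts; the toolkit works in uV
    n_total = data.shape[1]
    if isinstance(events, (str, Path)):
        ev = pd.read_csv(events)
    else:
        ev = events.copy()
    if "onset_s" not in ev.columns or "label" not in ev.columns:
        raise EpochSetParseError("event table needs columns onset_s,label")
    high = min(float(raw.info["lowpass"] or fs / 2), 0.49 * fs)
    spec = AcquisitionSpec(
        sampling_rate=fs,
        montage=tuple(raw.ch_names),
        band=(float(raw.info["highpass"]) or 0.5, high),
    )
    has_dur = "duration_s" in ev.columns
    bad_rows = []
    epochs = []
    for r in ev.itertuples():
        dur = float(r.duration_s) if has_dur else (duration_s or 0.0)
        if dur <= 0:
            raise ValueError("no epoch duration given (column duration_s or argument)")
        start = int(round(float(r.onset_s) * fs))
        stop = start + int(round(dur * fs))
        if start < 0 or stop > n_total:
            bad_rows.append(int(r.Index))
            continue
        layout = str(getattr(r, "layout", ""))
        epochs.append(
            Epoch(data=data[:, start:stop], onset=float(r.onset_s),
                  label=int(r.label), spec=spec, layout=layout)
        )
    if bad_rows:
        raise EpochSetParseError(
            f"event rows outside the recording (0-based rows): {bad_rows}"
        )
    return EpochSet(epochs=tuple(epochs), codebook=codebook, seed=0)
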