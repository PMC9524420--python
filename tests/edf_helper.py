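"""Minimal synthetic EDF writer, used only to build test fixtures.

Writes a plain (non-plus) European Data Format file: fixed 256-byte main
header, 256 bytes of header per signal, then 1-second data records of
little-endian 16-bit integers.  Only what the reader-side tests need.
"""

from __future__ import annotations

import numpy as np

PHYS_MIN, PHYS_MAX = -1000.0, 1000.0  # uV
DIG_MIN, DIG_MAX = -32768, 32767


def quantization_step_uv() -> float:
    return (PHYS_MAX - PHYS_MIN) / (DIG_MAX - DIG_MIN)


def write_synthetic_edf(path, data_uv: np.ndarray, fs: int, ch_names: list[str]) -> None:
    """Write channels x samples microvolt data as a synthetic EDF file.

    ``fs`` must be an integer (one data record per second) and the sample
    count a multiple of ``fs``.
    """
    n_ch, n_samp = data_uv.shape
    assert n_samp % fs == 0, "sample count must be a whole number of 1 s records"
    n_rec = n_samp // fs

    def f(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        assert len(b) <= width
        return b.ljust(width)

    header = b"".join([
        f("0", 8),                        # version
        f("X X X X", 80),                 # patient id
        f("Startdate X X X X", 80),       # recording id
        f("01.01.20", 8), f("00.00.00", 8),
        f(str(256 * (1 + n_ch)), 8),      # header bytes
        f("", 44),                        # reserved
        f(str(n_rec), 8),                 # n data records
        f("1", 8),                        # record duration (s)
        f(str(n_ch), 4),
    ])
    sig_header = b"".join([
        b"".join(f(name, 16) for name in ch_names),
        b"".join(f("synthetic", 80) for _ in ch_names),
        b"".join(f("uV", 8) for _ in ch_names),
        b"".join(f(str(PHYS_MIN), 8) for _ in ch_names),
        b"".join(f(str(PHYS_MAX), 8) for _ in ch_names),
        b"".join(f(str(DIG_MIN), 8) for _ in ch_names),
        b"".join(f(str(DIG_MAX), 8) for _ in ch_names),
        b"".join(f("", 80) for _ in ch_names),     # prefiltering
        b"".join(f(str(fs), 8) for _ in ch_names),  # samples per record
        b"".join(f("", 32) for _ in ch_names),     # reserved
    ])

    gain = (DIG_MAX - DIG_MIN) / (PHYS_MAX - PHYS_MIN)
    digital = np.clip(
        np.round((data_uv - PHYS_MIN) * gain + DIG_MIN), DIG_MIN, DIG_MAX
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_rec):
            for c in range(n_ch):
                fh.write(digital[c, r * fs:(r + 1) * fs].tobytes())
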