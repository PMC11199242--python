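"""Readers and writers for recordings and analysis artifacts.

Supported inputs: EDF, BrainVision (.vhdr/.eeg/.vmrk) and a plain delimited
channels-by-samples matrix with a YAML sidecar. The plain-matrix format is the
canonical on-disk representation used by the CLI; it is TSV with a header row
of sample times (ms) and one row per channel, plus ``<name>.yaml`` carrying the
sampling rate, channel names and unit-sphere sensor positions.

EDF and BrainVision are parsed directly (pure numpy) to avoid heavyweight
optional dependencies; only the subset of each format needed for continuous
multichannel EEG is handled.
"""

from __future__ import annotations

import configparser
import json
import os
from typing import Optional

import numpy as np
import yaml

from .core import Recording

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_edf",
    "write_edf",
    "read_brainvision",
    "write_brainvision",
    "read_recording",
    "write_json",
]


# ---------------------------------------------------------------------------
# plain-matrix format


def write_matrix(rec: Recording, path: str) -> None:
    if rec.kind != "continuous":
        raise ValueError("the plain-matrix format stores continuous data")
    times = rec.times_ms()
    header = "\t".join(f"{t:.6g}" for t in times)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for row in rec.data:
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")
    sidecar = {
        "sr": float(rec.sr),
        "channel_names": list(rec.channel_names) if rec.channel_names else None,
        "channel_positions": (
            np.asarray(rec.channel_positions).tolist()
            if rec.channel_positions is not None
            else None
        ),
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)


def _sidecar_path(path: str) -> str:
    base, _ = os.path.splitext(path)
    return base + ".yaml"


def read_matrix(path: str) -> Recording:
    with open(path) as fh:
        fh.readline()  # header of sample times / indices
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    sr, names, pos = 250.0, None, None
    side = _sidecar_path(path)
    if os.path.exists(side):
        with open(side) as fh:
            meta = yaml.safe_load(fh) or {}
        sr = float(meta.get("sr", 250.0))
        names = meta.get("channel_names")
        pos = meta.get("channel_positions")
        if pos is not None:
            pos = np.asarray(pos, dtype=float)
    return Recording(data=data, sr=sr, channel_names=names, channel_positions=pos)


# ---------------------------------------------------------------------------
# EDF


def write_edf(rec: Recording, path: str, phys_range: float = 3200.0) -> None:
    """Minimal single-record EDF writer (continuous data, one data record).

    Values are quantized to 16-bit integers over ``±phys_range`` µV, the EDF
    intrinsic precision limit.
    """
    if rec.kind != "continuous":
        raise ValueError("EDF writer handles continuous data only")
    n_ch, n_samp = rec.data.shape
    duration = rec.n_samples / rec.sr
    names = rec.channel_names or [f"CH{i}" for i in range(n_ch)]

    def pad(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("X", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 + 256 * n_ch), 8),
            pad("", 44),
            pad("1", 8),
            pad(f"{duration:g}", 8),
            pad(str(n_ch), 4),
        ]
    )
    dig_min, dig_max = -32768, 32767
    sig = b"".join(pad(n, 16) for n in names)
    sig += b"".join(pad("", 80) for _ in range(n_ch))
    sig += b"".join(pad("uV", 8) for _ in range(n_ch))
    sig += b"".join(pad(f"{-phys_range:g}", 8) for _ in range(n_ch))
    sig += b"".join(pad(f"{phys_range:g}", 8) for _ in range(n_ch))
    sig += b"".join(pad(str(dig_min), 8) for _ in range(n_ch))
    sig += b"".join(pad(str(dig_max), 8) for _ in range(n_ch))
    sig += b"".join(pad("", 80) for _ in range(n_ch))
    sig += b"".join(pad(str(n_samp), 8) for _ in range(n_ch))
    sig += b"".join(pad("", 32) for _ in range(n_ch))

    scale = (dig_max - dig_min) / (2 * phys_range)
    digital = np.clip(np.round(rec.data * scale), dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header + sig)
        fh.write(digital.tobytes())  # channel-sequential within the record


def read_edf(path: str) -> Recording:
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        n_ch = int(hdr[252:256])
        n_records = int(hdr[236:244])
        record_dur = float(hdr[244:252])
        sig = fh.read(256 * n_ch)

        # field layout: label16 transducer80 unit8 pmin8 pmax8 dmin8 dmax8
        # prefilter80 nsamples8 reserved32; each field is stored contiguously
        # for all signals
        offs = {}
        cursor = 0
        for key, width in [
            ("label", 16),
            ("transducer", 80),
            ("unit", 8),
            ("pmin", 8),
            ("pmax", 8),
            ("dmin", 8),
            ("dmax", 8),
            ("prefilter", 80),
            ("nsamp", 8),
            ("reserved", 32),
        ]:
            offs[key] = (cursor, width)
            cursor += width

        def field_at(key: str) -> list[str]:
            off, width = offs[key]
            block = sig[off * n_ch : (off + width) * n_ch]
            return [
                block[i * width : (i + 1) * width].decode("ascii").strip()
                for i in range(n_ch)
            ]

        names = field_at("label")
        phys_min = np.array([float(v) for v in field_at("pmin")])
        phys_max = np.array([float(v) for v in field_at("pmax")])
        dig_min = np.array([float(v) for v in field_at("dmin")])
        dig_max = np.array([float(v) for v in field_at("dmax")])
        n_samp = np.array([int(v) for v in field_at("nsamp")])

        if not np.all(n_samp == n_samp[0]):
            raise ValueError("EDF signals with unequal sampling rates are unsupported")
        per_rec = int(n_samp[0])
        raw = np.fromfile(fh, dtype="<i2")
    expected = n_records * n_ch * per_rec
    raw = raw[:expected].reshape(n_records, n_ch, per_rec)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    data = raw.transpose(1, 0, 2).reshape(n_ch, -1).astype(float)
    data = data * gain[:, None] + (phys_min - dig_min * gain)[:, None]
    sr = per_rec / record_dur
    return Recording(data=data, sr=sr, channel_names=names)


# ---------------------------------------------------------------------------
# BrainVision

_BV_DTYPES = {"IEEE_FLOAT_32": "<f4", "INT_16": "<i2", "INT_32": "<i4"}


def write_brainvision(rec: Recording, vhdr_path: str) -> None:
    """Minimal BrainVision writer (multiplexed IEEE float binary)."""
    if rec.kind != "continuous":
        raise ValueError("BrainVision writer handles continuous data only")
    base = os.path.splitext(vhdr_path)[0]
    eeg_name = os.path.basename(base) + ".eeg"
    vmrk_name = os.path.basename(base) + ".vmrk"
    names = rec.channel_names or [f"CH{i}" for i in range(rec.n_channels)]
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        f"DataFile={eeg_name}",
        f"MarkerFile={vmrk_name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={1e6 / rec.sr:g}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    for i, name in enumerate(names, start=1):
        lines.append(f"Ch{i}={name},,1,µV")
    with open(vhdr_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
    with open(base + ".vmrk", "w", encoding="utf-8") as fh:
        fh.write("[Marker Infos]\nMk1=New Segment,,1,1,0\n")
    rec.data.T.astype("<f4").tofile(base + ".eeg")


def read_brainvision(vhdr_path: str) -> Recording:
    cfg = configparser.ConfigParser(strict=False)
    with open(vhdr_path, encoding="utf-8", errors="replace") as fh:
        content = fh.read()
    # drop the non-INI banner line
    cfg.read_string("\n".join(l for l in content.splitlines() if not l.startswith("Brain")))
    common = cfg["Common Infos"]
    if common.get("DataFormat", "BINARY").upper() != "BINARY":
        raise ValueError("only BINARY BrainVision data is supported")
    if common.get("DataOrientation", "MULTIPLEXED").upper() != "MULTIPLEXED":
        raise ValueError("only MULTIPLEXED orientation is supported")
    n_ch = int(common["NumberOfChannels"])
    sr = 1e6 / float(common["SamplingInterval"])
    fmt = cfg["Binary Infos"].get("BinaryFormat", "IEEE_FLOAT_32").upper()
    if fmt not in _BV_DTYPES:
        raise ValueError(f"unsupported BinaryFormat {fmt!r}")
    names, gains = [], []
    for i in range(1, n_ch + 1):
        entry = cfg["Channel Infos"][f"Ch{i}"]
        parts = entry.split(",")
        names.append(parts[0])
        gains.append(float(parts[2]) if len(parts) > 2 and parts[2] else 1.0)
    eeg_path = os.path.join(os.path.dirname(vhdr_path), common["DataFile"])
    raw = np.fromfile(eeg_path, dtype=_BV_DTYPES[fmt])
    data = raw.reshape(-1, n_ch).T.astype(float) * np.asarray(gains)[:, None]
    return Recording(data=data, sr=sr, channel_names=names)


# ---------------------------------------------------------------------------


def read_recording(path: str, fmt: Optional[str] = None) -> Recording:
    """Dispatch on file format (``edf``, ``brainvision`` or ``matrix``)."""
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = {".edf": "edf", ".vhdr": "brainvision"}.get(ext, "matrix")
    if fmt == "edf":
        return read_edf(path)
    if fmt == "brainvision":
        return read_brainvision(path)
    if fmt == "matrix":
        return read_matrix(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
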