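"""On-disk containers for the pipeline.

Three kinds of artifact move between stages:

* multichannel recordings as flat little-endian int16 binary files with a
  self-describing ``key=value`` sidecar meta file (a documented subset of the
  SpikeGLX dialect — ``nChans``, ``sampleRateHz``, ``dtype``, ``voltsPerBit``,
  ``channelIds``, optional ``geometry`` and ``units``);
* delimited tables (behavioral-state epochs, channel groups, event/burst/
  ripple outputs) as comma-separated UTF-8 with a mandatory header;
* plain-text TOML configuration with one block per pipeline stage.

All on-disk times are seconds and all intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

try:  # py311+
    import tomllib
except ModuleNotFoundError:  # pragma: no cover - py310 fallback
    import tomli as tomllib  # type: ignore[no-redef]

EPOCH_STATES = frozenset({"idle", "running"})
_INT16_MAX = 32767


class FormatError(ValueError):
    """Meta/table file is missing keys, self-contradictory or malformed."""


class CorruptionError(FormatError):
    """Binary payload is inconsistent with its meta (e.g. truncated file)."""


@dataclasses.dataclass
class Recording:
    """A multichannel sampled signal in physical units.

    Parameters
    ----------
    samples
        2-D array, shape ``(n_channels, n_samples)``. pA for voltage-clamp
        current, µV for extracellular voltage.
    rate_hz
        Sampling rate in Hz, > 0.
    channel_ids
        Ordered channel labels, one per row of ``samples``.
    geometry
        Optional per-channel ``(row, col)`` grid coordinates (MEA) or depth
        order (linear probe). One entry per channel, no duplicates.
    units
        Unit string for ``samples`` (``"pA"`` or ``"uV"``).
    """

    samples: np.ndarray
    rate_hz: float
    channel_ids: list[str]
    geometry: list[tuple[int, int]] | None = None
    units: str = "uV"

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.rate_hz <= 0:
            raise ValueError(f"rate_hz must be > 0, got {self.rate_hz}")
        self.channel_ids = [str(c) for c in self.channel_ids]
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_ids)} channel ids for "
                f"{self.samples.shape[0]} sample rows"
            )
        if self.geometry is not None:
            self.geometry = [(int(r), int(c)) for r, c in self.geometry]
            if len(self.geometry) != self.n_channels:
                raise ValueError("geometry must have one entry per channel")
            if len(set(self.geometry)) != len(self.geometry):
                raise ValueError("duplicate geometry coordinates")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate_hz

    def channel_index(self, channel_id: str) -> int:
        return self.channel_ids.index(str(channel_id))


# ---------------------------------------------------------------------------
# flat binary + meta


def _format_meta(rec: Recording, scale: float) -> str:
    lines = [
        f"nChans={rec.n_channels}",
        f"sampleRateHz={rec.rate_hz!r}",
        "dtype=int16",
        f"voltsPerBit={scale!r}",
        "channelIds=" + ",".join(rec.channel_ids),
        f"units={rec.units}",
    ]
    if rec.geometry is not None:
        lines.append("geometry=" + ";".join(f"{r},{c}" for r, c in rec.geometry))
    return "\n".join(lines) + "\n"


def _parse_meta(path_meta: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path_meta, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"malformed meta line {line!r} in {path_meta}")
            key, value = line.split("=", 1)
            meta[key.strip()] = value.strip()
    return meta


def read_flat_binary(path_bin: str, path_meta: str) -> Recording:
    """Read an interleaved int16 flat-binary recording and scale it to
    physical units.

    The sample count must divide exactly: ``file_size / (2 * nChans)``;
    anything else raises :class:`CorruptionError`. Missing or mutually
    contradictory meta keys raise :class:`FormatError`.
    """
    meta = _parse_meta(path_meta)
    for key in ("nChans", "sampleRateHz", "dtype", "voltsPerBit", "channelIds"):
        if key not in meta:
            raise FormatError(f"meta file {path_meta} missing key {key!r}")
    if meta["dtype"] != "int16":
        raise FormatError(f"unsupported dtype {meta['dtype']!r} (only int16)")
    n_chans = int(meta["nChans"])
    if n_chans <= 0:
        raise FormatError("nChans must be positive")
    channel_ids = meta["channelIds"].split(",") if meta["channelIds"] else []
    if len(channel_ids) != n_chans:
        raise FormatError(
            f"meta contradiction: nChans={n_chans} but "
            f"{len(channel_ids)} channelIds"
        )
    scale = float(meta["voltsPerBit"])
    rate_hz = float(meta["sampleRateHz"])

    n_bytes = os.path.getsize(path_bin)
    bytes_per_frame = 2 * n_chans
    if n_bytes % bytes_per_frame != 0:
        raise CorruptionError(
            f"{path_bin}: {n_bytes} bytes is not a whole number of "
            f"{n_chans}-channel int16 frames"
        )
    raw = np.fromfile(path_bin, dtype="<i2")
    samples = raw.reshape(-1, n_chans).T.astype(float) * scale

    geometry = None
    if "geometry" in meta and meta["geometry"]:
        geometry = [
            (int(pair.split(",")[0]), int(pair.split(",")[1]))
            for pair in meta["geometry"].split(";")
        ]
    return Recording(
        samples=samples,
        rate_hz=rate_hz,
        channel_ids=channel_ids,
        geometry=geometry,
        units=meta.get("units", "uV"),
    )


def write_flat_binary(
    rec: Recording, path_bin: str, path_meta: str, scale: float | None = None
) -> None:
    """Quantize a Recording to interleaved int16 and write binary + meta.

    ``scale`` is physical units per bit; by default it is chosen so the
    largest absolute sample maps near the int16 range. Round-trip error is
    bounded by ``scale / 2`` per sample.
    """
    if rec.n_channels == 0:
        raise FormatError("cannot write a recording with no channels")
    if not np.all(np.isfinite(rec.samples)):
        raise ValueError("recording contains non-finite samples")
    if scale is None:
        peak = float(np.max(np.abs(rec.samples))) if rec.n_samples else 0.0
        scale = peak / (_INT16_MAX - 1) if peak > 0 else 1.0
    if scale <= 0:
        raise ValueError("scale must be positive")
    quantized = np.clip(
        np.round(rec.samples / scale), -_INT16_MAX - 1, _INT16_MAX
    ).astype("<i2")
    quantized.T.reshape(-1).tofile(path_bin)
    with open(path_meta, "w", encoding="utf-8") as fh:
        fh.write(_format_meta(rec, scale))


# ---------------------------------------------------------------------------
# delimited tables


def read_epoch_table(path: str) -> pd.DataFrame:
    """Read a behavioral epoch table (``start_s,end_s,state``) and validate it."""
    tbl = pd.read_csv(path)
    return validate_epochs(tbl)


def validate_epochs(tbl: pd.DataFrame) -> pd.DataFrame:
    missing = {"start_s", "end_s", "state"} - set(tbl.columns)
    if missing:
        raise FormatError(f"epoch table missing columns {sorted(missing)}")
    tbl = tbl.copy()
    tbl["start_s"] = tbl["start_s"].astype(float)
    tbl["end_s"] = tbl["end_s"].astype(float)
    tbl["state"] = tbl["state"].astype(str)
    bad_states = set(tbl["state"]) - EPOCH_STATES
    if bad_states:
        raise ValueError(f"unknown epoch state(s) {sorted(bad_states)}")
    if (tbl["end_s"] <= tbl["start_s"]).any():
        raise ValueError("epoch with end_s <= start_s")
    tbl = tbl.sort_values("start_s", ignore_index=True)
    overlap = tbl["start_s"].to_numpy()[1:] < tbl["end_s"].to_numpy()[:-1]
    if overlap.any():
        i = int(np.flatnonzero(overlap)[0])
        raise ValueError(
            f"overlapping epochs: [{tbl.start_s[i]}, {tbl.end_s[i]}) and "
            f"[{tbl.start_s[i + 1]}, {tbl.end_s[i + 1]})"
        )
    return tbl


def read_channel_groups(path: str) -> dict[str, list[str]]:
    """Read a ``group,channel_id`` table into a group → channel-id mapping."""
    tbl = pd.read_csv(path)
    missing = {"group", "channel_id"} - set(tbl.columns)
    if missing:
        raise FormatError(f"channel-group table missing columns {sorted(missing)}")
    groups: dict[str, list[str]] = {}
    for group, sub in tbl.groupby("group", sort=False):
        groups[str(group)] = [str(c) for c in sub["channel_id"]]
    return groups


def validate_channel_groups(
    groups: Mapping[str, Sequence[str]], rec: Recording
) -> None:
    """Every referenced channel must exist in the recording (groups may overlap)."""
    known = set(rec.channel_ids)
    for group, channels in groups.items():
        unknown = set(map(str, channels)) - known
        if unknown:
            raise ValueError(
                f"group {group!r} references unknown channel(s) {sorted(unknown)}"
            )


def write_table(rows: pd.DataFrame, path: str) -> None:
    """Write a result table as comma-separated UTF-8 with header."""
    rows.to_csv(path, index=False)


def load_config(path: str) -> dict:
    """Load a TOML config with one ``[stage]`` block per pipeline stage."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)
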