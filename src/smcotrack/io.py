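"""Localization-table container and CSV round-trip.

The on-disk dialect is deliberately plain: comma-separated, dot decimal,
UTF-8, one header line with the columns ``frame,x_nm,y_nm,intensity,channel``.
Comment lines starting with ``#`` before the header carry metadata
(units, channel, seed) and are ignored on read. Coordinates are in nm
with the origin at the field's top-left corner, x rightward, y downward.
Pixel-unit input is supported via a declared pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["LocalizationTable", "read_localizations", "write_localizations",
           "ParseError", "DEFAULT_PIXEL_SIZE_NM"]

REQUIRED_COLUMNS = ("frame", "x_nm", "y_nm", "intensity", "channel")
VALID_CHANNELS = ("A", "B")

#: default EMCCD pixel pitch divided by magnification (nm per pixel)
DEFAULT_PIXEL_SIZE_NM = 107.0


class ParseError(ValueError):
    """Malformed localization file."""


@dataclass
class LocalizationTable:
    """Per-frame point detections of one spectral channel.

    Wraps a :class:`pandas.DataFrame` with columns
    ``frame, x_nm, y_nm, intensity, channel``. All rows share one channel
    tag; frames are 0-based integers; positions are finite floats in nm.
    """

    df: pd.DataFrame
    channel: str = "A"
    registered: bool = False

    def __post_init__(self) -> None:
        df = self.df
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise ParseError(f"missing column {col!r}")
        if self.channel not in VALID_CHANNELS:
            raise ParseError(f"unknown channel tag {self.channel!r}")
        if len(df):
            if not np.isfinite(df[["x_nm", "y_nm"]].to_numpy()).all():
                raise ParseError("non-finite coordinate in table")
            if (df["frame"] < 0).any():
                raise ParseError("negative frame index")
            tags = df["channel"].unique()
            if len(tags) > 1 or (len(tags) == 1 and tags[0] != self.channel):
                raise ParseError("all rows must share the table's channel tag")
        self.df = df.astype({"frame": np.int64, "x_nm": float,
                             "y_nm": float, "intensity": float})

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_frames(self) -> int:
        return 0 if not len(self.df) else int(self.df["frame"].max()) + 1

    def sorted(self) -> "LocalizationTable":
        return LocalizationTable(
            self.df.sort_values(["frame", "x_nm", "y_nm"],
                                kind="stable").reset_index(drop=True),
            channel=self.channel, registered=self.registered)

    @classmethod
    def from_arrays(cls, frame, x_nm, y_nm, intensity=None, channel="A",
                    registered=False) -> "LocalizationTable":
        frame = np.asarray(frame)
        if intensity is None:
            intensity = np.ones(len(frame))
        df = pd.DataFrame({"frame": frame, "x_nm": x_nm, "y_nm": y_nm,
                           "intensity": intensity,
                           "channel": [channel] * len(frame)})
        return cls(df, channel=channel, registered=registered)


def read_localizations(path, channel: str | None = None,
                       pixel_size_nm: float | None = None) -> LocalizationTable:
    """Read a localization CSV.

    Parameters
    ----------
    path : path-like
    channel : str, optional
        Expected channel tag; inferred from the file if omitted.
    pixel_size_nm : float, optional
        If given, the file's ``x_px``/``y_px`` columns (pixel units) are
        converted to nm with this pitch.

    Raises
    ------
    ParseError
        On a missing column, a non-numeric coordinate (the offending row
        is named), or an unknown channel tag.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if pixel_size_nm is not None:
        if "x_px" not in df.columns or "y_px" not in df.columns:
            raise ParseError("pixel-unit input requires x_px and y_px columns")
        df["x_nm"] = df["x_px"] * pixel_size_nm
        df["y_nm"] = df["y_px"] * pixel_size_nm
        df = df.drop(columns=["x_px", "y_px"])
    if "intensity" not in df.columns:
        df["intensity"] = 1.0
    for col in ("frame", "x_nm", "y_nm", "channel"):
        if col not in df.columns:
            raise ParseError(f"{path.name}: missing column {col!r}")
    for col in ("frame", "x_nm", "y_nm", "intensity"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"{path.name}: non-numeric {col!r} at row {row}")
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise ParseError(f"{path.name}: missing {col!r} at row {row}")
        df[col] = coerced
    tags = df["channel"].unique().tolist() if len(df) else []
    for tag in tags:
        if tag not in VALID_CHANNELS:
            row = int(np.flatnonzero((df["channel"] == tag).to_numpy())[0])
            raise ParseError(f"{path.name}: unknown channel tag {tag!r} at row {row}")
    if channel is None:
        channel = tags[0] if tags else "A"
    return LocalizationTable(df[list(REQUIRED_COLUMNS)], channel=channel)


def write_localizations(table: LocalizationTable, path,
                        extra_header: dict | None = None) -> None:
    """Write a localization table, sorted by frame, with a metadata header."""
    path = Path(path)
    table = table.sorted()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# smcotrack localization table; units: nm; "
                 f"channel: {table.channel}\n")
        if extra_header:
            for k, v in extra_header.items():
                fh.write(f"# {k}: {v}\n")
        table.df.to_csv(fh, index=False)
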