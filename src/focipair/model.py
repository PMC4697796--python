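"""Core domain types and delimited-text readers/writers.

Coordinate convention: continuous nanometers in image orientation, i.e.
the origin is at the top-left of the region bounding box with *y*
increasing downward.  Every distance computed anywhere in the package is
the Euclidean distance on ``(x_nm, y_nm)``.

Focus tables and localization tables are tab-separated text with a "."
decimal point and a mandatory header row; extra columns are preserved as
tags so that synthetic ground truth survives a round trip.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

__all__ = [
    "CHANNELS",
    "FormatError",
    "ValidationError",
    "DiscRegion",
    "PolygonRegion",
    "NucleusRecord",
    "FocusSet",
    "LocalizationSet",
    "FrameStack",
    "LandmarkRecord",
    "read_focus_table",
    "write_focus_table",
    "read_localization_table",
    "write_localization_table",
]

CHANNELS = ("RAD51", "DMC1", "ZIP1", "OTHER")

FOCUS_COLUMNS = ["nucleus_id", "channel", "x_nm", "y_nm", "intensity"]
LOC_COLUMNS = ["x_nm", "y_nm", "frame", "photons", "fwhm_nm"]


class FormatError(ValueError):
    """A table is structurally malformed (e.g. a mandatory column is missing)."""


class ValidationError(ValueError):
    """A record violates a domain invariant (e.g. negative intensity)."""


# ---------------------------------------------------------------------------
# Nuclear regions


@dataclass(frozen=True)
class DiscRegion:
    """Circular nuclear region; coordinates and radius in nm."""

    center_x_nm: float
    center_y_nm: float
    radius_nm: float

    def __post_init__(self) -> None:
        if not self.radius_nm > 0:
            raise ValidationError(f"radius_nm must be > 0, got {self.radius_nm}")

    @property
    def area_nm2(self) -> float:
        return math.pi * self.radius_nm**2

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        cx, cy, r = self.center_x_nm, self.center_y_nm, self.radius_nm
        return (cx - r, cy - r, cx + r, cy + r)

    def contains(self, x: float, y: float) -> bool:
        return (x - self.center_x_nm) ** 2 + (y - self.center_y_nm) ** 2 <= self.radius_nm**2

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """n i.i.d. uniform points in the disc, shape (n, 2)."""
        r = self.radius_nm * np.sqrt(rng.random(n))
        theta = rng.random(n) * 2 * math.pi
        return np.column_stack(
            (self.center_x_nm + r * np.cos(theta), self.center_y_nm + r * np.sin(theta))
        )


@dataclass(frozen=True)
class PolygonRegion:
    """Polygonal nuclear region (e.g. a traced spread mask); vertices in nm."""

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        poly = Polygon(self.vertices)
        if not poly.is_valid or poly.area <= 0:
            raise ValidationError("polygon must be simple and non-degenerate")

    @property
    def _polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area_nm2(self) -> float:
        return self._polygon.area

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self._polygon.bounds

    def contains(self, x: float, y: float) -> bool:
        poly = self._polygon
        p = Point(x, y)
        return poly.contains(p) or poly.touches(p)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Uniform points by rejection from the bounding box."""
        poly = self._polygon
        x0, y0, x1, y1 = poly.bounds
        out = np.empty((n, 2))
        filled = 0
        while filled < n:
            m = max(4 * (n - filled), 16)
            xs = rng.uniform(x0, x1, m)
            ys = rng.uniform(y0, y1, m)
            keep = np.fromiter(
                (poly.intersects(Point(x, y)) for x, y in zip(xs, ys)), bool, count=m
            )
            pts = np.column_stack((xs[keep], ys[keep]))
            take = min(len(pts), n - filled)
            out[filled : filled + take] = pts[:take]
            filled += take
        return out


Region = DiscRegion | PolygonRegion


@dataclass(frozen=True)
class NucleusRecord:
    """A spread nucleus: the bounded 2D domain for CSR null placement."""

    nucleus_id: str
    region: Region
    stage_label: str | None = None

    @property
    def area_um2(self) -> float:
        return self.region.area_nm2 / 1e6


@dataclass(frozen=True)
class LandmarkRecord:
    """A fluorescent chromosomal landmark (lacO or tetO array spot)."""

    nucleus_id: str
    kind: str
    x_nm: float
    y_nm: float

    def __post_init__(self) -> None:
        if self.kind not in ("lacO", "tetO"):
            raise ValidationError(f"landmark kind must be 'lacO' or 'tetO', got {self.kind!r}")


# ---------------------------------------------------------------------------
# Focus sets


class FocusSet:
    """Per-nucleus, per-channel focus centroids with intensities.

    Wraps a :class:`pandas.DataFrame` with mandatory columns
    ``nucleus_id, channel, x_nm, y_nm, intensity``; any extra columns are
    carried as tags (synthetic ground truth uses ``dsb_id``, ``end_id``
    and ``is_background``).  ``nuclei`` maps nucleus ids to
    :class:`NucleusRecord`; it may be empty for tables read from disk and
    can be attached later with :meth:`with_nuclei`.
    """

    def __init__(
        self,
        df: pd.DataFrame | None = None,
        nuclei: Mapping[str, NucleusRecord] | None = None,
    ) -> None:
        if df is None:
            df = pd.DataFrame(columns=FOCUS_COLUMNS)
        missing = [c for c in FOCUS_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"focus table is missing mandatory column(s): {missing}")
        df = df.reset_index(drop=True)
        if len(df):
            xy = df[["x_nm", "y_nm"]].to_numpy(float)
            if not np.all(np.isfinite(xy)):
                raise ValidationError("focus coordinates must be finite")
            bad = df.index[df["intensity"].to_numpy(float) < 0]
            if len(bad):
                raise ValidationError(f"negative intensity in row(s) {list(bad)}")
            unknown = set(df["channel"]) - set(CHANNELS)
            if unknown:
                raise ValidationError(f"unknown channel label(s): {sorted(unknown)}")
        self.df = df
        self.nuclei: dict[str, NucleusRecord] = dict(nuclei or {})
        for nid in self.df["nucleus_id"].unique():
            if self.nuclei and nid not in self.nuclei:
                raise ValidationError(f"focus nucleus_id {nid!r} has no NucleusRecord")

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_records(
        cls, records: Iterable[dict], nuclei: Mapping[str, NucleusRecord] | None = None
    ) -> "FocusSet":
        rows = list(records)
        if not rows:
            return cls(nuclei=nuclei)
        return cls(pd.DataFrame(rows), nuclei=nuclei)

    def with_nuclei(self, nuclei: Mapping[str, NucleusRecord]) -> "FocusSet":
        return FocusSet(self.df.copy(), nuclei=nuclei)

    # -- accessors -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def nucleus_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["nucleus_id"]))

    def subset(self, nucleus_id: str | None = None, channel: str | None = None) -> "FocusSet":
        df = self.df
        if nucleus_id is not None:
            df = df[df["nucleus_id"] == nucleus_id]
        if channel is not None:
            df = df[df["channel"] == channel]
        nuclei = self.nuclei
        if nucleus_id is not None and nuclei:
            nuclei = {nucleus_id: nuclei[nucleus_id]} if nucleus_id in nuclei else {}
        return FocusSet(df.copy(), nuclei=nuclei)

    def coords(self, nucleus_id: str | None = None, channel: str | None = None) -> np.ndarray:
        df = self.df
        if nucleus_id is not None:
            df = df[df["nucleus_id"] == nucleus_id]
        if channel is not None:
            df = df[df["channel"] == channel]
        return df[["x_nm", "y_nm"]].to_numpy(float)

    def region_of(self, nucleus_id: str) -> Region:
        if nucleus_id not in self.nuclei:
            raise ValidationError(f"no NucleusRecord attached for {nucleus_id!r}")
        return self.nuclei[nucleus_id].region

    def equals(self, other: "FocusSet") -> bool:
        if list(self.df.columns) != list(other.df.columns):
            return False
        try:
            pd.testing.assert_frame_equal(
                self.df.reset_index(drop=True),
                other.df.reset_index(drop=True),
                check_dtype=False,
            )
        except AssertionError:
            return False
        return True

    def concat(self, other: "FocusSet") -> "FocusSet":
        nuclei = {**self.nuclei, **other.nuclei}
        df = pd.concat([self.df, other.df], ignore_index=True)
        return FocusSet(df, nuclei=nuclei)


# ---------------------------------------------------------------------------
# Localization sets


class LocalizationSet:
    """Single-molecule localization events (dSTORM).

    Columns: ``x_nm, y_nm, frame, photons, fwhm_nm`` plus optional truth
    tags.  Records are kept sorted by ``(frame, x_nm)``.
    """

    def __init__(self, df: pd.DataFrame | None = None) -> None:
        if df is None:
            df = pd.DataFrame(columns=LOC_COLUMNS)
        missing = [c for c in LOC_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"localization table is missing mandatory column(s): {missing}")
        df = df.sort_values(["frame", "x_nm"], kind="mergesort").reset_index(drop=True)
        if len(df):
            if (df["photons"].to_numpy(float) <= 0).any():
                raise ValidationError("photons must be > 0")
            if (df["fwhm_nm"].to_numpy(float) <= 0).any():
                raise ValidationError("fwhm_nm must be > 0")
            if (df["frame"].to_numpy(int) < 0).any():
                raise ValidationError("frame index must be >= 0")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def coords(self) -> np.ndarray:
        return self.df[["x_nm", "y_nm"]].to_numpy(float)


# ---------------------------------------------------------------------------
# Frame stacks


@dataclass
class FrameStack:
    """An image stack: (n_frames, height, width), intensities >= 0."""

    frames: np.ndarray
    pixel_size_nm: float = 100.0
    background_mean: float = 0.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        if frames.ndim != 3:
            raise ValidationError("frames must be a 2D image or a 3D stack")
        if not self.pixel_size_nm > 0:
            raise ValidationError("pixel_size_nm must be > 0")
        if frames.size and frames.min() < 0:
            raise ValidationError("all intensities must be >= 0")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height_px(self) -> int:
        return self.frames.shape[1]

    @property
    def width_px(self) -> int:
        return self.frames.shape[2]

    def to_tiff(self, path: str | os.PathLike) -> None:
        import tifffile

        tifffile.imwrite(path, self.frames.astype(np.float32), photometric="minisblack")

    @classmethod
    def from_tiff(cls, path: str | os.PathLike, pixel_size_nm: float = 100.0) -> "FrameStack":
        import tifffile

        return cls(tifffile.imread(path).astype(float), pixel_size_nm=pixel_size_nm)


# ---------------------------------------------------------------------------
# Delimited-text I/O

_SEP = "\t"


def _read_table(source, mandatory: list[str], numeric: list[str]) -> pd.DataFrame:
    if isinstance(source, (str, os.PathLike)):
        df = pd.read_csv(source, sep=_SEP, dtype=str)
    else:
        df = pd.read_csv(source, sep=_SEP, dtype=str)
    for col in mandatory:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    for col in df.columns:
        if col in ("nucleus_id", "channel", "kind"):
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        raw_na = df[col].isna()
        bad = df.index[converted.isna() & ~raw_na]
        if col in numeric and len(bad):
            # +2: header line plus 1-based numbering
            raise FormatError(f"non-numeric value in column {col!r} at table row {bad[0] + 2}")
        if len(bad) == 0:
            df[col] = converted
    return df


def read_focus_table(source: str | os.PathLike | io.IOBase) -> FocusSet:
    """Read a tab-separated focus table into a :class:`FocusSet`.

    Mandatory columns ``nucleus_id, channel, x_nm, y_nm, intensity``;
    extra columns are preserved as tags.  Row order is preserved.
    """
    df = _read_table(source, FOCUS_COLUMNS, ["x_nm", "y_nm", "intensity"])
    if len(df):
        bad = df.index[df["intensity"].to_numpy(float) < 0]
        if len(bad):
            raise ValidationError(f"negative intensity at table row {bad[0] + 2}")
        df["nucleus_id"] = df["nucleus_id"].astype(str)
        df["channel"] = df["channel"].astype(str)
    else:
        df = df.astype({"x_nm": float, "y_nm": float, "intensity": float}, errors="ignore")
    return FocusSet(df)


def write_focus_table(foci: FocusSet, target: str | os.PathLike | io.IOBase) -> None:
    """Write a :class:`FocusSet` losslessly; mandatory columns first."""
    extras = [c for c in foci.df.columns if c not in FOCUS_COLUMNS]
    foci.df[FOCUS_COLUMNS + extras].to_csv(target, sep=_SEP, index=False)


def read_localization_table(source: str | os.PathLike | io.IOBase) -> LocalizationSet:
    """Read a tab-separated localization table (x_nm, y_nm, frame, photons, fwhm_nm)."""
    df = _read_table(source, LOC_COLUMNS, LOC_COLUMNS)
    if len(df):
        df["frame"] = df["frame"].astype(int)
    return LocalizationSet(df)


def write_localization_table(locs: LocalizationSet, target: str | os.PathLike | io.IOBase) -> None:
    extras = [c for c in locs.df.columns if c not in LOC_COLUMNS]
    locs.df[LOC_COLUMNS + extras].to_csv(target, sep=_SEP, index=False)
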