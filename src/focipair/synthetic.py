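"""Synthetic ground truth: nuclei, DSB-derived focus patterns, widefield
renderings and photoswitching blink stacks.

The generative model mirrors the pairing architecture of meiotic
recombinase staining: each DNA double-strand break (DSB) contributes two
resected ends that separate by up to ~400 nm; each end may carry RAD51
and/or DMC1 signal, and when both are present they sit side by side with
a sub-200 nm offset (a "co-focus").  Background foci are placed under
complete spatial randomness (CSR).  A widefield observation process can
then censor foci closer than the ~150 nm resolution floor and render
diffraction-limited images; a two-state blinking model produces dSTORM
frame stacks with per-frame ground truth.

All generators are reproducible from ``(params, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .model import DiscRegion, FocusSet, FrameStack, NucleusRecord, ValidationError

__all__ = [
    "PairModelParams",
    "EmitterModel",
    "BlinkTruth",
    "uniform_sampler",
    "constant_sampler",
    "lognormal_intensity_sampler",
    "make_nucleus",
    "simulate_dsb_pattern",
    "simulate_csr",
    "apply_resolution_censor",
    "render_widefield",
    "simulate_blink_stack",
]

Sampler = Callable[[np.random.Generator], float]


def uniform_sampler(low: float, high: float) -> Sampler:
    def sample(rng: np.random.Generator) -> float:
        return float(rng.uniform(low, high))

    return sample


def constant_sampler(value: float) -> Sampler:
    return lambda rng: float(value)


def lognormal_intensity_sampler(median: float = 100.0, sigma: float = 0.5) -> Sampler:
    """Log-normal intensities; focus brightness spans orders of magnitude."""

    def sample(rng: np.random.Generator) -> float:
        return float(rng.lognormal(mean=math.log(median), sigma=sigma))

    return sample


@dataclass
class PairModelParams:
    """Parameters of the paired-end DSB focus model.

    ``pair_sep_sampler`` draws the end-to-end separation of a DSB
    (default uniform on [150, 400] nm: enrichment is seen up to 400 nm
    with a ~150 nm detection floor).  ``cofocus_offset_sampler`` draws
    the within-end RAD51<->DMC1 offset (default uniform on [0, 150] nm).
    ``occupancy`` gives per-end probabilities of (both channels,
    RAD51 only, DMC1 only, empty); the default 0.7/0.1/0.1/0.1 puts
    ~85% of foci of either channel next to a cross-channel partner.
    """

    n_dsb: int = 10
    pair_sep_sampler: Sampler = field(default_factory=lambda: uniform_sampler(150.0, 400.0))
    cofocus_offset_sampler: Sampler = field(default_factory=lambda: uniform_sampler(0.0, 150.0))
    occupancy: tuple[float, float, float, float] = (0.7, 0.1, 0.1, 0.1)
    n_background_per_channel: int = 0
    intensity_sampler: Sampler = field(default_factory=lognormal_intensity_sampler)

    def __post_init__(self) -> None:
        if self.n_dsb < 0 or self.n_background_per_channel < 0:
            raise ValidationError("counts must be >= 0")
        occ = np.asarray(self.occupancy, float)
        if occ.shape != (4,) or (occ < 0).any() or abs(occ.sum() - 1.0) > 1e-12:
            raise ValidationError("occupancy must be 4 nonnegative probabilities summing to 1")


def make_nucleus(area_um2: float, seed: int | None = None, nucleus_id: str = "n0") -> NucleusRecord:
    """A disc-shaped nucleus of the given area, placed so all coordinates >= 0."""
    if not area_um2 > 0:
        raise ValidationError(f"area_um2 must be > 0, got {area_um2}")
    radius_nm = math.sqrt(area_um2 * 1e6 / math.pi)
    region = DiscRegion(center_x_nm=radius_nm, center_y_nm=radius_nm, radius_nm=radius_nm)
    return NucleusRecord(nucleus_id=nucleus_id, region=region)


_OCC_CHANNELS = (("RAD51", "DMC1"), ("RAD51",), ("DMC1",), ())


def simulate_dsb_pattern(
    nucleus: NucleusRecord,
    params: PairModelParams,
    seed: int | np.random.Generator | None = None,
) -> FocusSet:
    """Generate a paired-end focus pattern for one nucleus.

    For each DSB a midpoint is placed uniformly in the region and two
    ends at +/- sep/2 along a uniform random orientation (rejection
    sampling keeps both ends inside the region).  Each end independently
    draws an occupancy category; channel records are offset from the end
    by ``cofocus_offset_sampler`` at a uniform angle.  Background foci
    are CSR.  Records carry truth tags ``dsb_id``, ``end_id`` and
    ``is_background``.
    """
    rng = np.random.default_rng(seed)
    region = nucleus.region
    records: list[dict] = []
    occ = np.asarray(params.occupancy, float)
    for dsb in range(params.n_dsb):
        sep = float(params.pair_sep_sampler(rng))
        for attempt in range(10_000):
            mid = region.sample(rng, 1)[0]
            theta = rng.uniform(0, 2 * math.pi)
            d = 0.5 * sep * np.array([math.cos(theta), math.sin(theta)])
            e0, e1 = mid - d, mid + d
            if region.contains(*e0) and region.contains(*e1):
                break
        else:
            raise ValidationError("nucleus too small to place a DSB after 10000 rejections")
        for end_id, end in enumerate((e0, e1)):
            channels = _OCC_CHANNELS[int(rng.choice(4, p=occ))]
            for channel in channels:
                r = float(params.cofocus_offset_sampler(rng))
                phi = rng.uniform(0, 2 * math.pi)
                records.append(
                    {
                        "nucleus_id": nucleus.nucleus_id,
                        "channel": channel,
                        "x_nm": end[0] + r * math.cos(phi),
                        "y_nm": end[1] + r * math.sin(phi),
                        "intensity": params.intensity_sampler(rng),
                        "dsb_id": dsb,
                        "end_id": end_id,
                        "is_background": False,
                    }
                )
    for channel in ("RAD51", "DMC1"):
        pts = region.sample(rng, params.n_background_per_channel)
        for x, y in pts:
            records.append(
                {
                    "nucleus_id": nucleus.nucleus_id,
                    "channel": channel,
                    "x_nm": x,
                    "y_nm": y,
                    "intensity": params.intensity_sampler(rng),
                    "dsb_id": -1,
                    "end_id": -1,
                    "is_background": True,
                }
            )
    return FocusSet.from_records(records, nuclei={nucleus.nucleus_id: nucleus})


def simulate_csr(
    nucleus: NucleusRecord,
    n: int,
    channel: str = "RAD51",
    seed: int | np.random.Generator | None = None,
    intensity_sampler: Sampler | None = None,
) -> FocusSet:
    """n foci i.i.d. uniform over the nuclear region (the CSR null)."""
    if n < 0:
        raise ValidationError("n must be >= 0")
    rng = np.random.default_rng(seed)
    sampler = intensity_sampler or lognormal_intensity_sampler()
    pts = nucleus.region.sample(rng, n)
    records = [
        {
            "nucleus_id": nucleus.nucleus_id,
            "channel": channel,
            "x_nm": x,
            "y_nm": y,
            "intensity": sampler(rng),
        }
        for x, y in pts
    ]
    return FocusSet.from_records(records, nuclei={nucleus.nucleus_id: nucleus})


def censor_points(
    pts: np.ndarray, weights: np.ndarray | None, d_min_nm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Array form of the resolution censor (no tag bookkeeping).

    Repeatedly replaces the closest pair below ``d_min_nm`` with its
    weight-weighted centroid (weights summed) until all pairwise
    distances are >= ``d_min_nm``.  Ties broken by lexicographic order
    of the sorted coordinate tuples.  Returns (points, weights).
    """
    pts = np.asarray(pts, float).copy()
    w = np.ones(len(pts)) if weights is None else np.asarray(weights, float).copy()
    while len(pts) >= 2:
        dm = squareform(pdist(pts))
        np.fill_diagonal(dm, np.inf)
        dmin = dm.min()
        if dmin >= d_min_nm:
            break
        ii, jj = np.where(dm <= dmin)
        best = None
        for i, j in zip(ii, jj):
            if i >= j:
                continue
            key = tuple(sorted([tuple(pts[i]), tuple(pts[j])]))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        wt = w[i] + w[j]
        merged = (
            (w[i] * pts[i] + w[j] * pts[j]) / wt if wt > 0 else 0.5 * (pts[i] + pts[j])
        )
        keep = np.ones(len(pts), bool)
        keep[[i, j]] = False
        pts = np.vstack([pts[keep], merged])
        w = np.append(w[keep], wt)
    return pts, w


def _censor_one(df_block, d_min_nm: float):
    """Iteratively merge the closest sub-threshold pair; deterministic."""
    import pandas as pd

    rows = df_block.to_dict("records")
    while len(rows) >= 2:
        xy = np.array([[r["x_nm"], r["y_nm"]] for r in rows])
        dm = squareform(pdist(xy))
        np.fill_diagonal(dm, np.inf)
        dmin = dm.min()
        if dmin >= d_min_nm:
            break
        # candidate pairs at the minimum distance; ties broken by
        # lexicographic order of the sorted coordinate tuples
        ii, jj = np.where(np.isclose(dm, dmin) & (dm <= dmin))
        best = None
        for i, j in zip(ii, jj):
            if i >= j:
                continue
            key = tuple(sorted([tuple(xy[i]), tuple(xy[j])]))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        a, b = rows[i], rows[j]
        wa, wb = a["intensity"], b["intensity"]
        wt = wa + wb
        if wt > 0:
            x = (wa * a["x_nm"] + wb * b["x_nm"]) / wt
            y = (wa * a["y_nm"] + wb * b["y_nm"]) / wt
        else:  # zero-intensity degenerate pair: plain midpoint
            x = 0.5 * (a["x_nm"] + b["x_nm"])
            y = 0.5 * (a["y_nm"] + b["y_nm"])
        # carry tags of the brighter member (ties: first in row order)
        keep = a if wa >= wb else b
        merged = dict(keep)
        merged.update({"x_nm": x, "y_nm": y, "intensity": wt})
        rows = [r for k, r in enumerate(rows) if k not in (i, j)]
        rows.append(merged)
    return pd.DataFrame(rows, columns=df_block.columns) if rows else df_block.iloc[:0]


def apply_resolution_censor(foci: FocusSet, d_min_nm: float = 150.0) -> FocusSet:
    """Merge same-channel foci closer than the resolution floor.

    The closest sub-threshold pair is replaced by a single focus at the
    intensity-weighted centroid with summed intensity, repeatedly, until
    all pairwise distances are >= ``d_min_nm``.  Total intensity is
    conserved.  Applied independently per (nucleus, channel).
    """
    import pandas as pd

    if len(foci) == 0:
        return FocusSet(foci.df.copy(), nuclei=foci.nuclei)
    blocks = []
    for (nid, ch), block in foci.df.groupby(["nucleus_id", "channel"], sort=False):
        blocks.append(_censor_one(block, d_min_nm))
    df = pd.concat(blocks, ignore_index=True)
    return FocusSet(df, nuclei=foci.nuclei)


def _render_points(
    points: np.ndarray,
    weights: np.ndarray,
    shape_px: tuple[int, int],
    pixel_size_nm: float,
    psf_sigma_nm: float,
) -> np.ndarray:
    """Sum of isotropic Gaussians sampled at pixel centers.

    Each point contributes ``weight`` in total signal (pixel-center
    sampling times the pixel area approximates the unit integral).
    """
    h, w = shape_px
    img = np.zeros((h, w))
    if len(points) == 0:
        return img
    halfwidth = int(math.ceil(5 * psf_sigma_nm / pixel_size_nm))
    norm = pixel_size_nm**2 / (2 * math.pi * psf_sigma_nm**2)
    for (x, y), amp in zip(points, weights):
        cx, cy = x / pixel_size_nm - 0.5, y / pixel_size_nm - 0.5
        c0, r0 = int(round(cx)), int(round(cy))
        cols = np.arange(max(0, c0 - halfwidth), min(w, c0 + halfwidth + 1))
        rows = np.arange(max(0, r0 - halfwidth), min(h, r0 + halfwidth + 1))
        if not len(cols) or not len(rows):
            continue
        gx = np.exp(-((cols - cx) ** 2) * pixel_size_nm**2 / (2 * psf_sigma_nm**2))
        gy = np.exp(-((rows - cy) ** 2) * pixel_size_nm**2 / (2 * psf_sigma_nm**2))
        img[np.ix_(rows, cols)] += amp * norm * np.outer(gy, gx)
    return img


def _auto_shape(points: np.ndarray, pixel_size_nm: float, margin_nm: float) -> tuple[int, int]:
    if len(points) == 0:
        return (16, 16)
    x1, y1 = points.max(axis=0) + margin_nm
    return (int(math.ceil(y1 / pixel_size_nm)), int(math.ceil(x1 / pixel_size_nm)))


def render_widefield(
    foci: FocusSet,
    psf_sigma_nm: float = 110.0,
    pixel_size_nm: float = 100.0,
    background_mean: float = 0.0,
    poisson_noise: bool = False,
    seed: int | np.random.Generator | None = None,
    shape_px: tuple[int, int] | None = None,
) -> FrameStack:
    """Render foci as a single widefield frame.

    image = sum_i intensity_i * Gaussian(sigma = psf_sigma) sampled at
    pixel centers, plus a constant background, with optional Poisson
    noise.
    """
    pts = foci.coords()
    weights = foci.df["intensity"].to_numpy(float) if len(foci) else np.empty(0)
    if shape_px is None:
        shape_px = _auto_shape(pts, pixel_size_nm, margin_nm=6 * psf_sigma_nm)
    img = _render_points(pts, weights, shape_px, pixel_size_nm, psf_sigma_nm)
    img += background_mean
    if poisson_noise:
        rng = np.random.default_rng(seed)
        img = rng.poisson(img).astype(float)
    return FrameStack(img[None], pixel_size_nm=pixel_size_nm, background_mean=background_mean)


# ---------------------------------------------------------------------------
# Blinking emitters


@dataclass
class EmitterModel:
    """Ground-truth photoswitching emitters for a dSTORM simulation.

    ``positions`` holds emitter coordinates in nm; build them with
    :meth:`point_cluster` / :meth:`filament` helpers.  Each frame every
    emitter switches on independently with probability ``p_on`` and
    emits ``Poisson(photons_mean)`` photons through an isotropic
    Gaussian PSF; a Poisson background of ``background_rate`` counts per
    pixel per frame is added.
    """

    positions: np.ndarray
    p_on: float = 0.05
    photons_mean: float = 1000.0
    psf_sigma_nm: float = 130.0
    background_rate: float = 5.0
    shape_px: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        if not (0 <= self.p_on <= 1):
            raise ValidationError("p_on must be in [0, 1]")
        if self.photons_mean <= 0 or self.psf_sigma_nm <= 0 or self.background_rate < 0:
            raise ValidationError("photons_mean and psf_sigma_nm must be > 0, background >= 0")

    @staticmethod
    def point_cluster(
        center: tuple[float, float],
        sigma_nm: float,
        count: int,
        rng: np.random.Generator,
    ) -> np.ndarray:
        return np.asarray(center, float) + rng.normal(0.0, sigma_nm, size=(count, 2))

    @staticmethod
    def filament(
        p0: tuple[float, float],
        p1: tuple[float, float],
        density_per_nm: float,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """Emitters Poisson-distributed along a line segment (labeling density)."""
        if density_per_nm <= 0:
            raise ValidationError("labeling density must be > 0")
        a, b = np.asarray(p0, float), np.asarray(p1, float)
        length = float(np.linalg.norm(b - a))
        n = rng.poisson(density_per_nm * length)
        t = rng.random(n)[:, None]
        return a + t * (b - a)


@dataclass
class BlinkTruth:
    """Per-frame ground truth of a blink simulation."""

    positions: np.ndarray  # (n_emitters, 2) nm
    on: np.ndarray  # (n_frames, n_emitters) bool
    photons: np.ndarray  # (n_frames, n_emitters) float

    def on_sets(self) -> list[set[int]]:
        return [set(np.flatnonzero(row)) for row in self.on]


def simulate_blink_stack(
    model: EmitterModel,
    n_frames: int,
    pixel_size_nm: float = 100.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[FrameStack, BlinkTruth]:
    """Simulate a dSTORM acquisition.

    Per frame each emitter is on independently with ``p_on``, photon
    counts are Poisson, the PSF is rendered as in
    :func:`render_widefield` and Poisson background is added.  Returns
    the stack and the per-frame emitter states.
    """
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    m = len(model.positions)
    shape = model.shape_px or _auto_shape(
        model.positions, pixel_size_nm, margin_nm=6 * model.psf_sigma_nm
    )
    on = rng.random((n_frames, m)) < model.p_on
    photons = np.where(on, rng.poisson(model.photons_mean, size=(n_frames, m)), 0).astype(float)
    frames = np.empty((n_frames, *shape))
    for f in range(n_frames):
        idx = np.flatnonzero(on[f])
        signal = _render_points(
            model.positions[idx], photons[f, idx], shape, pixel_size_nm, model.psf_sigma_nm
        )
        frames[f] = rng.poisson(signal + model.background_rate)
    stack = FrameStack(frames, pixel_size_nm=pixel_size_nm, background_mean=model.background_rate)
    return stack, BlinkTruth(positions=model.positions.copy(), on=on, photons=photons)
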