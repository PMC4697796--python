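"""Two-channel co-focus analysis, focus-structure classification and
landmark-based selection.

A "co-focus" is a side-by-side RAD51+DMC1 spot pair offset by less than
the colocalization radius (200 nm); merging mutual cross-channel nearest
neighbors within that radius yields *composite* foci, which are then
paired by mutual nearest neighbor within the 400 nm pairing window.
Per-nucleus structures are classified into categories I-V:

I   one composite focus (RAD51-only, DMC1-only, or a co-focus);
II  two composites within 1 um of each other (a pair);
III >2 RAD51 and/or >2 DMC1 foci, all within one 1 um-linked complex;
IV  complexes separated by >1 um, but no more than 2 foci per channel;
V   complexes separated by >1 um with >2 RAD51 and/or >2 DMC1 foci.

Nuclei with no foci are NEGATIVE.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .config import DEFAULT_CONFIG, AnalysisConfig
from .model import FocusSet, LandmarkRecord, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Composite",
    "PairRecord",
    "Category",
    "VdeCategory",
    "form_composites",
    "cross_fraction_within",
    "detect_pairs",
    "pair_composition_fraction",
    "pair_intensity_shares",
    "vde_classify_nucleus",
    "classify_nuclei",
    "focus_positive_fraction",
    "landmark_filter_and_score",
]


@dataclass
class Composite:
    """A composite focus: a merged co-focus or a single-channel focus."""

    nucleus_id: str
    x_nm: float
    y_nm: float
    kind: str  # "co-focus" | "RAD51-only" | "DMC1-only"
    intensity_rad51: float
    intensity_dmc1: float

    @property
    def position(self) -> tuple[float, float]:
        return (self.x_nm, self.y_nm)


@dataclass
class PairRecord:
    """A mutual-nearest-neighbor pair of composite foci."""

    nucleus_id: str
    members: tuple[Composite, Composite]
    separation_nm: float


class Category(Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"
    NEGATIVE = "NEGATIVE"


@dataclass
class VdeCategory:
    """Per-nucleus structural class with its supporting counts."""

    nucleus_id: str
    category: Category
    n_rad51: int
    n_dmc1: int
    n_complexes: int
    n_composites: int


def _mutual_nn_pairs(a: np.ndarray, b: np.ndarray) -> list[tuple[int, int, float]]:
    """Mutual nearest-neighbor matches between two point sets."""
    if len(a) == 0 or len(b) == 0:
        return []
    tree_a, tree_b = cKDTree(a), cKDTree(b)
    d_ab, j_ab = tree_b.query(a, k=1)
    d_ba, j_ba = tree_a.query(b, k=1)
    out = []
    for i, (j, d) in enumerate(zip(np.atleast_1d(j_ab), np.atleast_1d(d_ab))):
        if np.atleast_1d(j_ba)[j] == i:
            out.append((i, int(j), float(d)))
    return out


def form_composites(foci: FocusSet, config: AnalysisConfig = DEFAULT_CONFIG) -> list[Composite]:
    """Merge mutual cross-channel nearest neighbors within the
    colocalization radius (strict ``<``) into co-foci.

    The co-focus position is the intensity-weighted centroid of its two
    members; unmerged foci become single-channel composites.  Only
    RAD51 and DMC1 channels participate.
    """
    out: list[Composite] = []
    for nid in foci.nucleus_ids:
        r_df = foci.df[(foci.df["nucleus_id"] == nid) & (foci.df["channel"] == "RAD51")]
        d_df = foci.df[(foci.df["nucleus_id"] == nid) & (foci.df["channel"] == "DMC1")]
        r_xy = r_df[["x_nm", "y_nm"]].to_numpy(float)
        d_xy = d_df[["x_nm", "y_nm"]].to_numpy(float)
        r_int = r_df["intensity"].to_numpy(float)
        d_int = d_df["intensity"].to_numpy(float)
        used_r: set[int] = set()
        used_d: set[int] = set()
        for i, j, dist in _mutual_nn_pairs(r_xy, d_xy):
            if dist < config.coloc_radius_nm:
                wr, wd = r_int[i], d_int[j]
                wt = wr + wd
                if wt > 0:
                    x = (wr * r_xy[i, 0] + wd * d_xy[j, 0]) / wt
                    y = (wr * r_xy[i, 1] + wd * d_xy[j, 1]) / wt
                else:
                    x = 0.5 * (r_xy[i, 0] + d_xy[j, 0])
                    y = 0.5 * (r_xy[i, 1] + d_xy[j, 1])
                out.append(Composite(nid, x, y, "co-focus", wr, wd))
                used_r.add(i)
                used_d.add(j)
        for i in range(len(r_xy)):
            if i not in used_r:
                out.append(Composite(nid, r_xy[i, 0], r_xy[i, 1], "RAD51-only", r_int[i], 0.0))
        for j in range(len(d_xy)):
            if j not in used_d:
                out.append(Composite(nid, d_xy[j, 0], d_xy[j, 1], "DMC1-only", 0.0, d_int[j]))
    return out


def cross_fraction_within(
    a: FocusSet, b: FocusSet, radius_nm: float = 200.0
) -> float:
    """Fraction of a-foci whose nearest b-focus (same nucleus) is closer
    than ``radius_nm`` (strict, matching "less than 200 nm").

    Nuclei where ``b`` has no foci are not counted.
    """
    n_counted = 0
    n_within = 0
    for nid in a.nucleus_ids:
        src = a.coords(nucleus_id=nid)
        tgt = b.coords(nucleus_id=nid)
        if len(src) == 0 or len(tgt) == 0:
            continue
        tree = cKDTree(tgt)
        d, _ = tree.query(src, k=1)
        d = np.atleast_1d(d)
        n_counted += len(d)
        n_within += int((d < radius_nm).sum())
    if n_counted == 0:
        return float("nan")
    return n_within / n_counted


def detect_pairs(foci: FocusSet, config: AnalysisConfig = DEFAULT_CONFIG) -> list[PairRecord]:
    """Pairs of composite foci: mutual nearest neighbors within the
    pairing window (<= 400 nm); each composite belongs to at most one
    pair.  Deterministic output order: ascending separation, then
    lexicographic position.
    """
    composites = form_composites(foci, config)
    by_nucleus: dict[str, list[Composite]] = {}
    for c in composites:
        by_nucleus.setdefault(c.nucleus_id, []).append(c)
    pairs: list[PairRecord] = []
    for nid, comps in by_nucleus.items():
        pts = np.array([c.position for c in comps])
        if len(pts) < 2:
            continue
        tree = cKDTree(pts)
        d, j = tree.query(pts, k=2)
        nn = j[:, 1]
        nd = d[:, 1]
        for i in range(len(comps)):
            k = int(nn[i])
            if k > i and nn[k] == i and nd[i] <= config.pair_window_nm:
                a, b = comps[i], comps[k]
                if b.position < a.position:
                    a, b = b, a
                pairs.append(PairRecord(nid, (a, b), float(nd[i])))
    pairs.sort(key=lambda p: (p.separation_nm, p.members[0].position, p.members[1].position))
    return pairs


_PAIR_CLASSES = ("co+co", "co+R", "co+D", "R+R", "R+D", "D+D")
_KIND_CODE = {"co-focus": "co", "RAD51-only": "R", "DMC1-only": "D"}


def pair_composition_fraction(pairs: list[PairRecord]) -> tuple[float, dict[str, int]]:
    """Fraction of pairs whose members are both co-foci, plus the full
    composition table.  Empty input yields NaN with a warning."""
    table = {k: 0 for k in _PAIR_CLASSES}
    for p in pairs:
        codes = sorted(
            (_KIND_CODE[p.members[0].kind], _KIND_CODE[p.members[1].kind]),
            key=lambda c: ("co", "R", "D").index(c),
        )
        table["+".join(codes)] += 1
    if not pairs:
        logger.warning("pair_composition_fraction: empty pair list; fraction undefined")
        return float("nan"), table
    return table["co+co"] / len(pairs), table


def pair_intensity_shares(pairs: list[PairRecord]) -> dict:
    """Within-pair intensity shares and their regression slope.

    For each pair where both members carry both channels, the brightness
    of one member is expressed as the percentage of the pair's total
    signal in that channel; the least-squares slope of DMC1 share on
    RAD51 share tests whether the two channels load coordinately
    (independent assembly predicts slope 0).
    """
    rows = []
    n_excluded = 0
    for p in pairs:
        a, b = p.members
        tot_r = a.intensity_rad51 + b.intensity_rad51
        tot_d = a.intensity_dmc1 + b.intensity_dmc1
        if not (
            a.intensity_rad51 > 0
            and b.intensity_rad51 > 0
            and a.intensity_dmc1 > 0
            and b.intensity_dmc1 > 0
        ):
            n_excluded += 1
            logger.info("pair_intensity_shares: pair in %s excluded (missing channel signal)",
                        p.nucleus_id)
            continue
        rows.append(
            {
                "nucleus_id": p.nucleus_id,
                "rad51_share_pct": 100.0 * a.intensity_rad51 / tot_r,
                "dmc1_share_pct": 100.0 * a.intensity_dmc1 / tot_d,
            }
        )
    shares = pd.DataFrame(rows, columns=["nucleus_id", "rad51_share_pct", "dmc1_share_pct"])
    slope = intercept = float("nan")
    if len(shares) >= 2 and shares["rad51_share_pct"].nunique() > 1:
        slope, intercept = np.polyfit(
            shares["rad51_share_pct"], shares["dmc1_share_pct"], deg=1
        )
    elif len(shares) >= 1:
        slope, intercept = 0.0, float(shares["dmc1_share_pct"].mean())
    return {
        "shares": shares,
        "slope": float(slope),
        "intercept": float(intercept),
        "n_excluded": n_excluded,
    }


def vde_classify_nucleus(
    foci: FocusSet, nucleus_id: str | None = None, config: AnalysisConfig = DEFAULT_CONFIG
) -> VdeCategory:
    """Classify one nucleus's focus structure into categories I-V.

    Composites are formed as in :func:`detect_pairs`; cytological
    complexes are single-linkage clusters of composites at 1 um.  The
    decision is total and mutually exclusive; channel-count rules (III,
    V) take precedence over composite-count rules where both could
    apply.
    """
    if nucleus_id is None:
        ids = foci.nucleus_ids
        if len(ids) != 1:
            raise ValidationError("vde_classify_nucleus needs a single nucleus")
        nucleus_id = ids[0]
    sub = foci.subset(nucleus_id=nucleus_id)
    n_rad51 = len(sub.subset(channel="RAD51"))
    n_dmc1 = len(sub.subset(channel="DMC1"))
    if n_rad51 + n_dmc1 == 0:
        return VdeCategory(nucleus_id, Category.NEGATIVE, 0, 0, 0, 0)
    comps = form_composites(sub, config)
    pts = np.array([c.position for c in comps])
    if len(pts) == 1:
        n_complexes = 1
    else:
        z = linkage(pdist(pts), method="single")
        labels = fcluster(z, t=config.cluster_link_nm, criterion="distance")
        n_complexes = len(set(labels))
    many = n_rad51 > 2 or n_dmc1 > 2
    if n_complexes == 1:
        if many:
            cat = Category.III
        elif len(comps) == 1:
            cat = Category.I
        elif len(comps) == 2:
            cat = Category.II
        else:
            # >=3 composites but <=2 foci per channel within one complex:
            # degenerate merging; channel counts define III
            logger.warning("nucleus %s: %d composites with <=2 foci per channel; "
                           "classifying III", nucleus_id, len(comps))
            cat = Category.III
    else:
        cat = Category.V if many else Category.IV
    return VdeCategory(nucleus_id, cat, n_rad51, n_dmc1, n_complexes, len(comps))


def classify_nuclei(foci: FocusSet, config: AnalysisConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Classify every nucleus; one row per nucleus."""
    rows = []
    for nid in foci.nucleus_ids:
        v = vde_classify_nucleus(foci, nucleus_id=nid, config=config)
        rows.append(
            {
                "nucleus_id": nid,
                "category": v.category.value,
                "n_rad51": v.n_rad51,
                "n_dmc1": v.n_dmc1,
                "n_complexes": v.n_complexes,
                "n_composites": v.n_composites,
            }
        )
    return pd.DataFrame(
        rows, columns=["nucleus_id", "category", "n_rad51", "n_dmc1", "n_complexes", "n_composites"]
    )


def focus_positive_fraction(n_positive: int, n_total: int) -> tuple[float, int]:
    """Fraction and its percentage rounded half-up to the nearest integer."""
    if n_total < 1:
        raise ValidationError("n_total must be >= 1")
    if not 0 <= n_positive <= n_total:
        raise ValidationError("n_positive must be between 0 and n_total")
    fraction = n_positive / n_total
    percent = int(math.floor(100.0 * fraction + 0.5))
    return fraction, percent


def landmark_filter_and_score(
    dmc1: FocusSet,
    landmarks: list[LandmarkRecord],
    config: AnalysisConfig = DEFAULT_CONFIG,
    anchor_radius_nm: float = 300.0,
    neighborhood_nm: float = 1000.0,
) -> pd.DataFrame:
    """Landmark-anchored selection and single/pair calls per nucleus.

    Eligibility: at least one and at most two spots of each landmark
    kind; exactly one DMC1 focus within ``anchor_radius_nm`` of the
    midpoint between the closest (tetO, lacO) spot pair; and 0-2
    additional DMC1 foci within ``neighborhood_nm`` of that anchor
    focus.  The call is "pair" when at least one additional DMC1 focus
    lies within the neighborhood, else "single".  When two tetO spots
    exist, their separation is reported as ``tetO_split_nm``.
    """
    by_nucleus: dict[str, dict[str, list[LandmarkRecord]]] = {}
    for lm in landmarks:
        by_nucleus.setdefault(lm.nucleus_id, {"lacO": [], "tetO": []})[lm.kind].append(lm)
    rows = []
    nucleus_ids = list(dict.fromkeys(list(dmc1.nucleus_ids) + list(by_nucleus)))
    for nid in nucleus_ids:
        lms = by_nucleus.get(nid, {"lacO": [], "tetO": []})
        laco, teto = lms["lacO"], lms["tetO"]
        teto_split = float("nan")
        if len(teto) == 2:
            teto_split = math.dist(
                (teto[0].x_nm, teto[0].y_nm), (teto[1].x_nm, teto[1].y_nm)
            )
        row = {
            "nucleus_id": nid,
            "eligible": False,
            "reason": "",
            "call": "",
            "tetO_split_nm": teto_split,
        }
        if not (1 <= len(laco) <= 2):
            row["reason"] = f"{len(laco)} lacO spot(s); need 1-2"
            rows.append(row)
            continue
        if not (1 <= len(teto) <= 2):
            row["reason"] = f"{len(teto)} tetO spot(s); need 1-2"
            rows.append(row)
            continue
        # anchor = midpoint of the closest (tetO, lacO) pair
        best = min(
            (
                (math.dist((t.x_nm, t.y_nm), (l.x_nm, l.y_nm)), t, l)
                for t in teto
                for l in laco
            ),
            key=lambda x: x[0],
        )
        _, t, l = best
        anchor = (0.5 * (t.x_nm + l.x_nm), 0.5 * (t.y_nm + l.y_nm))
        pts = dmc1.coords(nucleus_id=nid, channel="DMC1")
        if len(pts) == 0:
            row["reason"] = "no DMC1 foci"
            rows.append(row)
            continue
        d_anchor = np.hypot(pts[:, 0] - anchor[0], pts[:, 1] - anchor[1])
        at_anchor = np.flatnonzero(d_anchor <= anchor_radius_nm)
        if len(at_anchor) != 1:
            row["reason"] = f"{len(at_anchor)} DMC1 foci within {anchor_radius_nm:g} nm of anchor"
            rows.append(row)
            continue
        focus = pts[at_anchor[0]]
        d_focus = np.hypot(pts[:, 0] - focus[0], pts[:, 1] - focus[1])
        n_extra = int((d_focus <= neighborhood_nm).sum()) - 1
        if n_extra > 2:
            row["reason"] = f"{n_extra} additional DMC1 foci within {neighborhood_nm:g} nm"
            rows.append(row)
            continue
        row["eligible"] = True
        row["call"] = "pair" if n_extra >= 1 else "single"
        rows.append(row)
    return pd.DataFrame(rows, columns=["nucleus_id", "eligible", "reason", "call", "tetO_split_nm"])
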