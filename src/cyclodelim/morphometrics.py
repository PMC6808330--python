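"""Shell-outline geometric morphometrics and the explicit morphotype rule.

Pipeline: closed apertural-view outlines are resampled to k equally spaced
semi-landmarks (k = 200 by default), superimposed by generalized Procrustes
analysis (translation, unit centroid size, rotation — reflections are NOT
removed), ordinated by canonical variate analysis against species labels,
and sized by the area of the polygon spanned by the semi-landmarks.

The morphotype classifier encodes the published interval rule on caliper
measurements: shells with height 23–31 mm and breadth 28–35 mm are the
"widespread" morphotype; shells moderately outside those intervals (height
21–23 or 31–33 mm, breadth 26–28 or 35–37 mm) are "slightly deviating";
anything beyond (height <21 or >33 mm, breadth <26 or >37 mm) is
"deviating".  The three regions tile the positive (H, B) quadrant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .exceptions import InputError

WIDESPREAD = "widespread"
SLIGHTLY_DEVIATING = "slightly_deviating"
DEVIATING = "deviating"
MORPHOTYPES = (WIDESPREAD, SLIGHTLY_DEVIATING, DEVIATING)


# ------------------------------------------------------------------- types
@dataclass(frozen=True)
class Outline:
    """Closed 2-D outline: ordered points, implicit closure (the first point
    is not repeated at the end)."""

    specimen_id: str
    points: np.ndarray  # (m, 2)
    start_index: int | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise InputError("outline needs >= 3 two-dimensional points")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class SemiLandmarkSet:
    """k semi-landmarks equally spaced along an outline's arc length."""

    specimen_id: str
    points: np.ndarray  # (k, 2)

    @property
    def k(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class ShapeSpace:
    """Procrustes superimposition result."""

    specimen_ids: tuple[str, ...]
    aligned: np.ndarray  # (n, k, 2); centroid at origin, unit centroid size
    centroid_sizes: np.ndarray  # (n,)
    consensus: np.ndarray  # (k, 2)
    converged: bool
    n_iterations: int


@dataclass(frozen=True)
class CVAResult:
    axes: np.ndarray  # (p, n_axes) canonical vectors in the reduced space
    percents: np.ndarray  # per-axis percent of total among-group variance
    eigenvalues: np.ndarray
    scores: np.ndarray  # (n, n_axes)
    specimen_ids: tuple[str, ...]
    groups: tuple[str, ...]

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)


@dataclass(frozen=True)
class SpecimenRecord:
    """Caliper measurements of one shell (mm)."""

    specimen_id: str
    height_mm: float
    breadth_mm: float
    whorls: float | None = None
    morphotype: str | None = None


# -------------------------------------------------------------- resampling
def _signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _default_start(pts: np.ndarray) -> int:
    """Maximum x; ties broken by minimum y, then lowest index — a geometric
    stand-in for 'the widest point of the aperture on the right side'."""
    order = np.lexsort((np.arange(len(pts)), pts[:, 1], -pts[:, 0]))
    return int(order[0])


def resample_outline(o: Outline, k: int = 200) -> SemiLandmarkSet:
    """Resample a closed outline to k points at equal arc-length intervals.

    Traversal is normalized to counterclockwise before resampling and starts
    at the outline's start landmark (given, or the rightmost point).
    """
    if k < 3:
        raise InputError("k must be >= 3")
    pts = o.points
    start = o.start_index if o.start_index is not None else _default_start(pts)
    if not (0 <= start < len(pts)):
        raise InputError("start_index out of range")
    start_point = pts[start].copy()
    if _signed_area(pts) < 0:  # clockwise: reverse traversal
        pts = pts[::-1]
        start = len(pts) - 1 - start
    pts = np.roll(pts, -start, axis=0)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    perimeter = float(seg.sum())
    if perimeter <= 0:
        raise InputError("degenerate outline with zero perimeter")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(k) * perimeter / k
    x = np.interp(targets, cum, closed[:, 0])
    y = np.interp(targets, cum, closed[:, 1])
    out = np.column_stack([x, y])
    out[0] = start_point  # exact, not interpolated
    return SemiLandmarkSet(o.specimen_id, out)


# ---------------------------------------------------------------- Procrustes
def centroid_size(pts: np.ndarray) -> float:
    c = pts.mean(axis=0)
    return float(np.sqrt(((pts - c) ** 2).sum()))


def _optimal_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation (det = +1) minimizing ||x R - target||_F."""
    u, _, vt = np.linalg.svd(x.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def gpa(
    sets: Sequence[SemiLandmarkSet],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ShapeSpace:
    """Generalized Procrustes analysis (rotation-only; no reflection).

    Each configuration is translated to the origin, scaled to unit centroid
    size and iteratively rotated to the running consensus until the
    consensus moves by less than ``tol``.  Non-convergence returns the
    partial result with ``converged=False`` and a warning.
    """
    if len(sets) < 2:
        raise InputError("need at least two specimens")
    k = sets[0].k
    if any(s.k != k for s in sets):
        raise InputError("all semi-landmark sets must share the same k")
    configs = []
    sizes = []
    for s in sets:
        pts = s.points - s.points.mean(axis=0)
        cs = float(np.sqrt((pts ** 2).sum()))
        if cs == 0:
            raise InputError(f"degenerate configuration {s.specimen_id!r}")
        sizes.append(cs)
        configs.append(pts / cs)
    aligned = np.array(configs)
    consensus = aligned[0].copy()
    reference = aligned[0].copy()  # fixes the rotational gauge of the mean
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(len(aligned)):
            aligned[i] = aligned[i] @ _optimal_rotation(aligned[i], consensus)
        new = aligned.mean(axis=0)
        new -= new.mean(axis=0)
        norm = np.sqrt((new ** 2).sum())
        if norm > 0:
            new /= norm
        new = new @ _optimal_rotation(new, reference)
        if np.linalg.norm(new - consensus) < tol:
            consensus = new
            converged = True
            break
        consensus = new
    if not converged:
        warnings.warn("GPA did not converge within max_iter", RuntimeWarning)
    return ShapeSpace(
        specimen_ids=tuple(s.specimen_id for s in sets),
        aligned=aligned,
        centroid_sizes=np.array(sizes),
        consensus=consensus,
        converged=converged,
        n_iterations=it,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Rotation-only Procrustes distance between two configurations after
    centering and unit-size scaling (reflections are not removed, so a
    mirrored copy has a strictly positive distance)."""
    xa = a - a.mean(axis=0)
    xa /= np.sqrt((xa ** 2).sum())
    xb = b - b.mean(axis=0)
    xb /= np.sqrt((xb ** 2).sum())
    r = _optimal_rotation(xa, xb)
    return float(np.linalg.norm(xa @ r - xb))


# ----------------------------------------------------------------------- CVA
def cva(space: ShapeSpace, labels: Mapping[str, str]) -> CVAResult:
    """Canonical variate analysis of Procrustes-aligned coordinates.

    Procrustes coordinates are rank-deficient (2k coordinates minus the four
    similarity degrees of freedom), so the data are first reduced by PCA to
    rank min(n - g, 2k - 4); the canonical axes then solve the generalized
    eigenproblem of the among-group versus the pooled within-group
    covariance in that space.  Per-axis percentages are the eigenvalues
    normalized over the min(g - 1, rank) retained axes.
    """
    ids = space.specimen_ids
    try:
        groups = tuple(labels[i] for i in ids)
    except KeyError as e:
        raise InputError(f"missing group label for {e.args[0]!r}") from None
    uniq = sorted(set(groups))
    if len(uniq) < 2:
        raise InputError("need at least two groups")
    for gname in uniq:
        if groups.count(gname) < 2:
            raise InputError(f"group {gname!r} has fewer than two specimens")
    n, k, _ = space.aligned.shape
    g = len(uniq)
    X = space.aligned.reshape(n, 2 * k)
    X = X - X.mean(axis=0)
    r = min(n - g, 2 * k - 4)
    u, sv, vt = np.linalg.svd(X, full_matrices=False)
    nonzero = int((sv > sv[0] * 1e-10).sum()) if len(sv) else 0
    r = min(r, nonzero)
    Z = X @ vt[:r].T  # (n, r)
    grand = Z.mean(axis=0)
    W = np.zeros((r, r))
    B = np.zeros((r, r))
    for gname in uniq:
        idx = [i for i, lab in enumerate(groups) if lab == gname]
        zg = Z[idx]
        mu = zg.mean(axis=0)
        dev = zg - mu
        W += dev.T @ dev
        dmu = (mu - grand)[:, None]
        B += len(idx) * (dmu @ dmu.T)
    W /= n - g
    B /= g - 1
    evals, evecs = scipy.linalg.eigh(B, W)
    order = np.argsort(evals)[::-1]
    n_axes = min(g - 1, r)
    evals = np.clip(evals[order][:n_axes], 0.0, None)
    evecs = evecs[:, order][:, :n_axes]
    total = evals.sum()
    percents = 100.0 * evals / total if total > 0 else np.zeros_like(evals)
    scores = Z @ evecs
    return CVAResult(
        axes=evecs,
        percents=percents,
        eigenvalues=evals,
        scores=scores,
        specimen_ids=ids,
        groups=groups,
    )


# ------------------------------------------------------------------ size
def polygon_area(s: SemiLandmarkSet) -> float:
    """Absolute shoelace area of the closed semi-landmark polygon.

    Self-intersecting polygons still return the shoelace value, with a
    warning (cancellation can make it smaller than the visual footprint).
    """
    if s.k < 3:
        raise InputError("polygon needs >= 3 points")
    area = abs(_signed_area(s.points))
    from shapely.geometry import Polygon

    if not Polygon(s.points).is_valid:
        warnings.warn(
            f"self-intersecting outline {s.specimen_id!r}: shoelace area returned",
            RuntimeWarning,
        )
    return area


def size_summary(
    values: Sequence[float], groups: Sequence[str]
) -> pd.DataFrame:
    """Five-number summary (min, q1, median, q3, max) of sizes per group."""
    if len(values) != len(groups):
        raise InputError("values and groups differ in length")
    df = pd.DataFrame({"value": values, "group": groups})
    out = df.groupby("group")["value"].agg(
        n="count",
        min="min",
        q1=lambda v: v.quantile(0.25),
        median="median",
        q3=lambda v: v.quantile(0.75),
        max="max",
    )
    return out


# -------------------------------------------------------------- morphotype
def classify_morphotype(r: SpecimenRecord) -> str:
    """Interval rule on shell height H and breadth B (mm); bounds of the
    widespread class are inclusive."""
    h, b = r.height_mm, r.breadth_mm
    if h is None or b is None or not np.isfinite(h) or not np.isfinite(b):
        raise InputError(f"missing measurement for {r.specimen_id!r}")
    if h <= 0 or b <= 0:
        raise InputError(f"non-positive measurement for {r.specimen_id!r}")
    if h < 21 or h > 33 or b < 26 or b > 37:
        return DEVIATING
    if 23 <= h <= 31 and 28 <= b <= 35:
        return WIDESPREAD
    return SLIGHTLY_DEVIATING


# -------------------------------------------------------------------- TPS I/O
def read_tps(path: str | Path) -> list[Outline]:
    """Minimal TPS reader: LM= blocks of x y lines with ID= (and optional
    SCALE=, applied multiplicatively)."""
    outlines: list[Outline] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line.upper().startswith("LM="):
            i += 1
            continue
        m = int(line.split("=", 1)[1])
        pts = []
        i += 1
        while len(pts) < m:
            x, y = lines[i].split()
            pts.append((float(x), float(y)))
            i += 1
        spec_id = f"outline_{len(outlines)}"
        scale = 1.0
        while i < len(lines) and not lines[i].strip().upper().startswith("LM="):
            entry = lines[i].strip()
            if entry.upper().startswith("ID="):
                spec_id = entry.split("=", 1)[1]
            elif entry.upper().startswith("SCALE="):
                scale = float(entry.split("=", 1)[1])
            i += 1
        outlines.append(Outline(spec_id, np.asarray(pts) * scale))
    return outlines


def write_tps(outlines: Sequence[Outline | SemiLandmarkSet], path: str | Path) -> None:
    blocks = []
    for o in outlines:
        pts = o.points
        sid = o.specimen_id
        rows = "\n".join(f"{x:.6f} {y:.6f}" for x, y in pts)
        blocks.append(f"LM={len(pts)}\n{rows}\nID={sid}")
    Path(path).write_text("\n".join(blocks) + "\n")
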