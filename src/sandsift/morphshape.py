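"""Geometric and linear morphometrics for 13-point fish head configurations.

The landmark schema uses ids {1,2,3,4,5,6,7,10,11,12,13,14,15}; ids 11-14 are
semilandmarks equally spaced on the dorsal head curve between landmarks 10
(snout) and 15 (dorsal margin of the head).  Linear distances are epaxial
depth EpD(1,15), lower jaw length LJL(3,4), maxilla length ML(3,10) and eye
length EyL(5,6); the mouth angle is the signed difference between the eye-axis
and jaw-axis orientations, so an upturned mouth has a larger angle.

Shape analysis: generalized Procrustes superimposition (centre, scale to unit
centroid size, optimal rotation, iterated to a consensus), with semilandmarks
optionally slid along local curve tangents to minimise thin-plate-spline
bending energy against the consensus; allometry-free shapes as regression
residuals on log10 standard length added back to the consensus; PCA of the
aligned coordinates; and projection of external specimens into an existing
shape space by ordinary Procrustes alignment onto its consensus.

Coordinates use the mathematical convention (y increases upward).  TPS files
digitised in image coordinates (y down) can be flipped on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LANDMARK_IDS",
    "SEMILANDMARK_IDS",
    "LandmarkConfig",
    "ShapeSpace",
    "read_tps",
    "write_tps",
    "linear_distances",
    "mouth_angle",
    "standardize_jaw",
    "gpa",
    "procrustes_distance",
    "bending_energy_matrix",
    "bending_energy",
    "allometry_free",
    "shape_pca",
    "project",
]

LANDMARK_IDS: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 10, 11, 12, 13, 14, 15)
SEMILANDMARK_IDS: tuple[int, ...] = (11, 12, 13, 14)
#: dorsal head curve along which the semilandmarks slide
CURVE_IDS: tuple[int, ...] = (10, 11, 12, 13, 14, 15)

_IDX = {lm: i for i, lm in enumerate(LANDMARK_IDS)}


@dataclass(frozen=True)
class LandmarkConfig:
    """One specimen's 13 labelled 2D landmarks plus direct measurements."""

    id: str
    coords: np.ndarray                     # (13, 2), ordered as LANDMARK_IDS
    sl: float | None = None                # standard length, mm
    hw: float | None = None                # head width, mm
    cls: str | None = None                 # CAL / TAE / F2 / SANDSIFTER
    sex: str | None = None
    hypural: np.ndarray | None = None      # optional extra point used for SL

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (len(LANDMARK_IDS), 2):
            raise ValueError(f"{self.id}: expected {len(LANDMARK_IDS)} 2D points, "
                             f"got shape {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"{self.id}: non-finite landmark coordinates")
        if self.sl is not None and self.sl <= 0:
            raise ValueError(f"{self.id}: standard length must be positive")
        object.__setattr__(self, "coords", coords)

    def point(self, lm: int) -> np.ndarray:
        return self.coords[_IDX[lm]]


# ---------------------------------------------------------------------------
# TPS I/O
# ---------------------------------------------------------------------------

def read_tps(path, flip_y: bool = False) -> list[LandmarkConfig]:
    """Read landmark configurations from a TPS file.

    Supports LM=, IMAGE=, ID= and SCALE= records; coordinates are multiplied
    by the scale factor.  A 14th point, when present, is taken as the hypural
    landmark used for standard length.  ``flip_y`` negates y coordinates for
    files digitised in image convention.
    """
    configs = []
    current: dict | None = None

    def finish(cur):
        k = len(LANDMARK_IDS)
        pts = np.asarray(cur["points"], dtype=float)
        if len(pts) not in (k, k + 1):
            raise ValueError(
                f"TPS record {cur['name']!r}: expected {k} (or {k}+hypural) "
                f"landmarks, found {len(pts)} (LM={cur['lm']})")
        pts = pts * cur["scale"]
        if flip_y:
            pts = pts * np.array([1.0, -1.0])
        hyp = pts[k] if len(pts) == k + 1 else None
        sl = None
        if hyp is not None:
            sl = float(np.linalg.norm(hyp - pts[_IDX[10]]))
        configs.append(LandmarkConfig(id=cur["name"], coords=pts[:k],
                                      sl=sl, hypural=hyp))

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.upper()
            if key == "LM":
                if current is not None:
                    finish(current)
                current = {"lm": int(value), "points": [], "scale": 1.0,
                           "name": f"specimen_{len(configs) + 1}"}
            elif current is None:
                raise ValueError(f"TPS parse error: {line!r} before any LM record")
            elif key == "IMAGE":
                current["name"] = value
            elif key == "ID":
                current["name"] = value
            elif key == "SCALE":
                current["scale"] = float(value)
            else:
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(f"TPS record {current['name']!r}: "
                                     f"malformed coordinate line {line!r}")
                current["points"].append([float(parts[0]), float(parts[1])])
    if current is not None:
        finish(current)
    return configs


def write_tps(configs: list[LandmarkConfig], path, flip_y: bool = False) -> None:
    """Write configurations as TPS (unit scale; hypural point appended last)."""
    with open(path, "w") as fh:
        for cfg in configs:
            pts = cfg.coords if cfg.hypural is None else np.vstack([cfg.coords, cfg.hypural])
            if flip_y:
                pts = pts * np.array([1.0, -1.0])
            fh.write(f"LM={len(pts)}\n")
            for x, y in pts:
                fh.write(f"{x:.10g} {y:.10g}\n")
            fh.write(f"ID={cfg.id}\n")
            fh.write("SCALE=1.0\n")


# ---------------------------------------------------------------------------
# linear traits
# ---------------------------------------------------------------------------

_DISTANCE_PAIRS = {"EpD": (1, 15), "LJL": (3, 4), "ML": (3, 10), "EyL": (5, 6)}


def linear_distances(config: LandmarkConfig) -> dict[str, float]:
    """Euclidean distances EpD(1,15), LJL(3,4), ML(3,10), EyL(5,6)."""
    return {name: float(np.linalg.norm(config.point(a) - config.point(b)))
            for name, (a, b) in _DISTANCE_PAIRS.items()}


def mouth_angle(config: LandmarkConfig) -> float:
    """Mouth angle in degrees: eye-axis orientation minus jaw-axis orientation.

    MA = atan2(Y6-Y5, X6-X5)*(180/pi) - atan2(Y3-Y10, X3-X10)*(180/pi); an
    upturned mouth has a larger angle than a downturned one.
    """
    p3, p5, p6, p10 = (config.point(i) for i in (3, 5, 6, 10))
    eye = math.degrees(math.atan2(p6[1] - p5[1], p6[0] - p5[0]))
    jaw = math.degrees(math.atan2(p3[1] - p10[1], p3[0] - p10[0]))
    return eye - jaw


def _signed_angle(u: np.ndarray, v: np.ndarray) -> float:
    return math.atan2(u[0] * v[1] - u[1] * v[0], float(u @ v))


def standardize_jaw(configs: list[LandmarkConfig]) -> list[LandmarkConfig]:
    """Rotate landmark 4 about landmark 3 so the jaw-opening angle is common.

    The angle between the lower jaw (4-3) and the maxilla direction (10-3) is
    set to its mean over all specimens, removing variation from mouths left
    open to different degrees.  |LJL| is preserved for every specimen.
    """
    if not configs:
        raise ValueError("need at least one configuration")
    angles = [
        _signed_angle(c.point(10) - c.point(3), c.point(4) - c.point(3))
        for c in configs
    ]
    target = float(np.mean(angles))
    out = []
    for cfg, ang in zip(configs, angles):
        delta = target - ang
        rot = np.array([[math.cos(delta), -math.sin(delta)],
                        [math.sin(delta), math.cos(delta)]])
        coords = cfg.coords.copy()
        p3 = cfg.point(3)
        coords[_IDX[4]] = p3 + rot @ (cfg.point(4) - p3)
        out.append(replace(cfg, coords=coords))
    return out


# ---------------------------------------------------------------------------
# Procrustes machinery
# ---------------------------------------------------------------------------

def _center_scale(x: np.ndarray) -> np.ndarray:
    c = x - x.mean(axis=0)
    size = np.linalg.norm(c)
    if size == 0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return c / size


def _optimal_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation matrix (no reflection) minimising ||x R - target||."""
    u, _, vt = np.linalg.svd(x.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.diag([1.0, d])
    return u @ s @ vt


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance after centring, unit-scaling and rotation."""
    a = _center_scale(np.asarray(a, float))
    b = _center_scale(np.asarray(b, float))
    r = _optimal_rotation(b, a)
    return float(np.linalg.norm(b @ r - a))


def bending_energy_matrix(ref: np.ndarray) -> np.ndarray:
    """Thin-plate-spline bending energy matrix of a reference configuration.

    The k x k upper-left block of L^-1 with kernel U(r) = r^2 log r^2;
    symmetrised against round-off.
    """
    ref = np.asarray(ref, float)
    k = len(ref)
    d2 = np.sum((ref[:, None, :] - ref[None, :, :]) ** 2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        kern = d2 * np.log(d2)
    kern[~np.isfinite(kern)] = 0.0
    q = np.column_stack([np.ones(k), ref])
    left = np.zeros((k + 3, k + 3))
    left[:k, :k] = kern
    left[:k, k:] = q
    left[k:, :k] = q.T
    be = np.linalg.pinv(left)[:k, :k]
    return (be + be.T) / 2.0


def bending_energy(x: np.ndarray, ref: np.ndarray,
                   be: np.ndarray | None = None) -> float:
    """Bending energy of the deviation of ``x`` from ``ref`` (sum over x and y)."""
    if be is None:
        be = bending_energy_matrix(ref)
    d = np.asarray(x, float) - np.asarray(ref, float)
    return float(d[:, 0] @ be @ d[:, 0] + d[:, 1] @ be @ d[:, 1])


def _slide_pass(x: np.ndarray, consensus: np.ndarray, be: np.ndarray) -> np.ndarray:
    """One Gauss-Seidel sliding pass over the semilandmarks of one specimen.

    Each semilandmark moves along its local curve tangent (estimated from its
    neighbours on the 10-11-12-13-14-15 chain) by the step that minimises the
    bending energy of the deviation from the consensus; each single-landmark
    step can only decrease the energy.
    """
    x = x.copy()
    chain = [_IDX[i] for i in CURVE_IDS]
    for lm in SEMILANDMARK_IDS:
        j = _IDX[lm]
        pos = chain.index(j)
        tangent = x[chain[pos + 1]] - x[chain[pos - 1]]
        norm = np.linalg.norm(tangent)
        if norm == 0:
            continue
        u = tangent / norm
        d = x - consensus
        grad = float(u[0] * (be[j] @ d[:, 0]) + u[1] * (be[j] @ d[:, 1]))
        curv = float(be[j, j])
        if curv <= 0:
            continue
        x[j] -= (grad / curv) * u
    return x


@dataclass
class ShapeSpace:
    """Procrustes-aligned shapes, consensus, and (after PCA) principal axes."""

    consensus: np.ndarray                  # (13, 2)
    aligned: np.ndarray                    # (n, 13, 2)
    ids: list[str]
    meta: pd.DataFrame                     # per-specimen cls / sex / sl
    slid: bool = False
    axes: np.ndarray | None = None         # (26, n_axes), columns are PCs
    scores: np.ndarray | None = None       # (n, n_axes)
    var_frac: np.ndarray | None = None
    center: np.ndarray | None = None       # (26,) mean of flattened aligned
    allometry: np.ndarray | None = None    # (26,) slope on log10 SL

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.ids, columns=cols)


def gpa(
    configs: list[LandmarkConfig],
    slide: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
    slide_iters: int = 5,
) -> ShapeSpace:
    """Generalized Procrustes superimposition of landmark configurations.

    Shapes are centred, scaled to unit centroid size and rotated to the
    evolving consensus until the consensus changes by less than ``tol``.
    With ``slide=True`` the semilandmarks additionally slide along the dorsal
    head curve to minimise thin-plate-spline bending energy against the
    consensus (one Gauss-Seidel pass per outer iteration, ``slide_iters``
    outer iterations).
    """
    if len(configs) < 2:
        raise ValueError("need at least two configurations")
    shapes = np.stack([_center_scale(c.coords) for c in configs])
    consensus = shapes[0].copy()
    for _ in range(max_iter):
        for i in range(len(shapes)):
            shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)
        new = shapes.mean(axis=0)
        new = new - new.mean(axis=0)
        new /= np.linalg.norm(new)
        if np.linalg.norm(new - consensus) < tol:
            consensus = new
            break
        consensus = new
    if slide:
        for _ in range(slide_iters):
            be = bending_energy_matrix(consensus)
            for i in range(len(shapes)):
                shapes[i] = _slide_pass(shapes[i], consensus, be)
                shapes[i] = _center_scale(shapes[i])
                shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)
            new = shapes.mean(axis=0)
            new = new - new.mean(axis=0)
            new /= np.linalg.norm(new)
            if np.linalg.norm(new - consensus) < tol:
                break
            consensus = new
    meta = pd.DataFrame(
        {"cls": [c.cls for c in configs], "sex": [c.sex for c in configs],
         "sl": [c.sl for c in configs]},
        index=[c.id for c in configs])
    return ShapeSpace(consensus=consensus, aligned=shapes,
                      ids=[c.id for c in configs], meta=meta, slid=slide)


# ---------------------------------------------------------------------------
# allometry, PCA, projection
# ---------------------------------------------------------------------------

def allometry_free(
    space: ShapeSpace,
    log_sl: np.ndarray,
    groups: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[ShapeSpace, dict]:
    """Remove allometric shape variation by regression on log10 SL.

    Each aligned coordinate is regressed on ``log_sl`` (separately within
    ``groups`` when given, e.g. for specimen sets with different allometries);
    the residuals plus the consensus are the allometry-free shapes.  The
    report carries the Procrustes-ANOVA style F statistic for the shape~size
    regression and a residual-randomisation permutation p-value.
    """
    log_sl = np.asarray(log_sl, dtype=float)
    n = len(space.aligned)
    if log_sl.shape != (n,) or not np.all(np.isfinite(log_sl)):
        raise ValueError("log SL must be finite and one per specimen")
    y = space.aligned.reshape(n, -1)
    labels = np.zeros(n) if groups is None else np.asarray(groups)
    resid = np.empty_like(y)
    slope_pooled = None
    ss_model = ss_resid = 0.0
    df_model = 0
    for lab in np.unique(labels):
        sel = labels == lab
        x = log_sl[sel] - log_sl[sel].mean()
        yy = y[sel] - y[sel].mean(axis=0)
        sxx = float(x @ x)
        if sxx == 0:
            resid[sel] = yy
            continue
        beta = (x @ yy) / sxx           # (26,)
        fit = np.outer(x, beta)
        resid[sel] = yy - fit
        ss_model += float((fit ** 2).sum())
        ss_resid += float(((yy - fit) ** 2).sum())
        df_model += 1
        if groups is None:
            slope_pooled = beta
    df_resid = n - df_model - len(np.unique(labels))
    f_obs = (ss_model / max(df_model, 1)) / (ss_resid / df_resid) if ss_resid > 0 else np.inf
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ssm = ssr = 0.0
        for lab in np.unique(labels):
            sel = labels == lab
            x = log_sl[sel] - log_sl[sel].mean()
            yy = y[perm][sel] - y[perm][sel].mean(axis=0)
            sxx = float(x @ x)
            if sxx == 0:
                continue
            beta = (x @ yy) / sxx
            fit = np.outer(x, beta)
            ssm += float((fit ** 2).sum())
            ssr += float(((yy - fit) ** 2).sum())
        f_perm = (ssm / max(df_model, 1)) / (ssr / df_resid) if ssr > 0 else np.inf
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    adjusted = (resid + space.consensus.reshape(1, -1)).reshape(space.aligned.shape)
    out = replace(space, aligned=adjusted,
                  allometry=slope_pooled if slope_pooled is not None else None)
    report = {"F": f_obs, "df_model": df_model, "df_resid": df_resid,
              "p_perm": p, "n_perm": n_perm}
    return out, report


def shape_pca(space: ShapeSpace) -> ShapeSpace:
    """PCA of the aligned coordinates; axes ordered by variance.

    Axis signs follow a deterministic convention: the largest-magnitude
    loading of each axis is positive.
    """
    n = len(space.aligned)
    y = space.aligned.reshape(n, -1)
    center = y.mean(axis=0)
    yc = y - center
    u, s, vt = np.linalg.svd(yc, full_matrices=False)
    k = min(n - 1, yc.shape[1])
    axes = vt[:k].T                       # (26, k)
    scores = yc @ axes
    var = s[:k] ** 2
    var_frac = var / var.sum() if var.sum() > 0 else var
    for j in range(k):
        if axes[np.abs(axes[:, j]).argmax(), j] < 0:
            axes[:, j] *= -1
            scores[:, j] *= -1
    return replace(space, axes=axes, scores=scores, var_frac=var_frac, center=center)


def project(configs: list[LandmarkConfig], space: ShapeSpace) -> pd.DataFrame:
    """Project external specimens into an existing shape space.

    Each configuration is aligned onto the space's consensus by ordinary
    Procrustes (centre, unit scale, rotate; the consensus is not updated) and
    its centred flattened coordinates are multiplied by the principal axes.
    """
    if space.axes is None or space.center is None:
        raise ValueError("space has no principal axes; run shape_pca first")
    rows, ids = [], []
    for cfg in configs:
        x = _center_scale(cfg.coords)
        x = x @ _optimal_rotation(x, space.consensus)
        rows.append((x.reshape(-1) - space.center) @ space.axes)
        ids.append(cfg.id)
    cols = [f"PC{i + 1}" for i in range(space.axes.shape[1])]
    return pd.DataFrame(rows, index=ids, columns=cols)
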