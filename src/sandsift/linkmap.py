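"""Linkage-group construction and genetic-map estimation for an F2 intercross.

Markers are grouped by pairwise independence LOD (single-linkage transitive
closure at a configurable threshold, default 7.0), recombination fractions are
estimated by maximum likelihood via EM over the two-locus F2 genotype classes,
and adjacent-pair Kosambi distances accumulate into map positions.

Marker ordering within a group is either taken as given (sorted by the marker
metadata, appropriate for simulated crosses where the truth is known) or found
by a greedy nearest-neighbour seriation on the pairwise recombination-fraction
estimates.  Multipoint regression ordering, ripple steps and nearest-neighbour
fit exclusions (as implemented in proprietary mapping software) are deliberately
not reproduced; the chosen ordering strategy is recorded on the resulting map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "kosambi",
    "kosambi_inverse",
    "haldane",
    "haldane_inverse",
    "qc_markers",
    "pairwise_independence_lod",
    "group_markers",
    "estimate_rf",
    "build_map",
    "map_from_table",
    "marker_count_summary",
    "LinkageGroup",
    "LinkageMap",
]

R_CLAMP = 0.4999  # keeps Kosambi distances finite


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------

def kosambi(r: float) -> float:
    """Kosambi map distance in cM for a recombination fraction ``r``.

    d = 25 * ln((1 + 2r) / (1 - 2r)) centimorgans.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    out = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(out) if out.ndim == 0 else out


def kosambi_inverse(d_cM: float) -> float:
    """Recombination fraction for a Kosambi distance ``d_cM`` (r = tanh(2d)/2)."""
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be nonnegative")
    out = 0.5 * np.tanh(2.0 * d / 100.0)
    return float(out) if out.ndim == 0 else out


def haldane(r: float) -> float:
    """Haldane map distance in cM (no interference)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    out = -50.0 * np.log(1.0 - 2.0 * r)
    return float(out) if out.ndim == 0 else out


def haldane_inverse(d_cM: float) -> float:
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be nonnegative")
    out = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(out) if out.ndim == 0 else out


MAP_FUNCTIONS = {"kosambi": (kosambi, kosambi_inverse),
                 "haldane": (haldane, haldane_inverse)}


# ---------------------------------------------------------------------------
# marker / individual QC
# ---------------------------------------------------------------------------

def qc_markers(
    codes: pd.DataFrame,
    distortion_alpha: float = 0.01,
    max_marker_missing: float = 0.2,
    max_individual_missing: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pre-mapping quality control on an F2 genotype matrix.

    ``codes`` is individuals x markers with entries 0 (AA), 1 (AB), 2 (BB) and
    -1 for missing.  Markers under severe segregation distortion (chi-square
    goodness of fit against 1:2:1 on the non-missing counts, p < alpha) or with
    missingness above ``max_marker_missing`` are dropped first; individuals
    with missingness above ``max_individual_missing`` (over the retained
    markers) are dropped second.

    Returns the retained matrix and a tidy exclusion report with one row per
    dropped marker/individual and the reason.
    """
    if codes.empty:
        raise ValueError("genotype matrix is empty")
    rows = []
    vals = codes.to_numpy()
    n_ind = vals.shape[0]
    keep_markers = []
    for j, marker in enumerate(codes.columns):
        col = vals[:, j]
        obs = col[col >= 0]
        missing = 1.0 - obs.size / n_ind
        if obs.size == 0:
            rows.append({"item": marker, "kind": "marker", "reason": "all_missing",
                         "p": np.nan, "missing": 1.0})
            continue
        counts = np.bincount(obs, minlength=3)[:3]
        chi2, p = stats.chisquare(counts, f_exp=obs.size * np.array([0.25, 0.5, 0.25]))
        if p < distortion_alpha:
            rows.append({"item": marker, "kind": "marker",
                         "reason": "segregation_distortion", "p": p, "missing": missing})
        elif missing > max_marker_missing:
            rows.append({"item": marker, "kind": "marker", "reason": "missingness",
                         "p": p, "missing": missing})
        else:
            keep_markers.append(marker)
    out = codes[keep_markers]
    keep_ind = []
    for ind, row in out.iterrows():
        miss = float((row.to_numpy() < 0).mean()) if len(keep_markers) else 1.0
        if miss > max_individual_missing:
            rows.append({"item": ind, "kind": "individual", "reason": "missingness",
                         "p": np.nan, "missing": miss})
        else:
            keep_ind.append(ind)
    report = pd.DataFrame(rows, columns=["item", "kind", "reason", "p", "missing"])
    return out.loc[keep_ind], report


# ---------------------------------------------------------------------------
# independence LOD and grouping
# ---------------------------------------------------------------------------

def pairwise_independence_lod(codes: pd.DataFrame) -> pd.DataFrame:
    """Symmetric marker x marker independence-LOD table.

    For each marker pair the 3x3 genotype contingency table over individuals
    non-missing at both markers gives a likelihood-ratio statistic
    G = 2 * sum O * ln(O/E); the LOD is G / (2 ln 10).  Pairs with no
    overlapping individuals get LOD 0; the diagonal is set to 0.
    """
    if codes.shape[1] < 2:
        raise ValueError("need at least two markers")
    vals = codes.to_numpy()
    m = vals.shape[1]
    onehot = np.stack([(vals == g).astype(float) for g in range(3)])  # (3, n, m)
    # counts[a, b] = number of individuals with genotype a at marker i, b at j
    counts = np.einsum("anm,bnk->abmk", onehot, onehot)  # (3, 3, m, m)
    total = counts.sum(axis=(0, 1))
    row = counts.sum(axis=1)  # (3, m, m) genotype margin at first marker
    col = counts.sum(axis=0)  # (3, m, m)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = row[:, None] * col[None, :] / total
        terms = counts * np.log(counts / expected)
    terms = np.nan_to_num(terms, nan=0.0, posinf=0.0, neginf=0.0)
    g_stat = 2.0 * terms.sum(axis=(0, 1))
    lod = g_stat / (2.0 * math.log(10.0))
    lod[total == 0] = 0.0
    np.fill_diagonal(lod, 0.0)
    lod = np.maximum(lod, 0.0)
    return pd.DataFrame(lod, index=codes.columns, columns=codes.columns)


def group_markers(lod: pd.DataFrame, threshold: float = 7.0) -> list[list[str]]:
    """Partition markers into linkage groups by single-linkage closure.

    Two markers share a group iff they are connected by a chain of pairs with
    LOD >= threshold.  Groups are returned largest-first, ties broken by the
    first member's column order.
    """
    adj = csr_matrix((lod.to_numpy() >= threshold).astype(np.int8))
    n_comp, labels = connected_components(adj, directed=False)
    groups: dict[int, list[str]] = {}
    for name, lab in zip(lod.columns, labels):
        groups.setdefault(lab, []).append(name)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), lod.columns.get_loc(g[0])))
    return ordered


# ---------------------------------------------------------------------------
# recombination fraction estimation (EM)
# ---------------------------------------------------------------------------

def _joint_probs(r: float) -> np.ndarray:
    """3x3 joint genotype probabilities for two markers at recombination r.

    Genotype codes count B alleles (0=AA, 1=AB, 2=BB).  An F2 individual is
    the union of two independent gametes; each gamete carries a parental
    two-locus haplotype with probability (1-r)/2 and a recombinant one with
    probability r/2.
    """
    hap = {(0, 0): (1 - r) / 2, (1, 1): (1 - r) / 2,
           (0, 1): r / 2, (1, 0): r / 2}
    probs = np.zeros((3, 3))
    for (a1, b1), p1 in hap.items():
        for (a2, b2), p2 in hap.items():
            probs[a1 + a2, b1 + b2] += p1 * p2
    return probs


# expected number of recombinant gametes (out of 2) per joint genotype class;
# the double-heterozygote entry depends on r and is filled in per iteration
_REC_COUNT = np.array([[0.0, 1.0, 2.0],
                       [1.0, np.nan, 1.0],
                       [2.0, 1.0, 0.0]])


def estimate_rf(g1, g2, tol: float = 1e-10, max_iter: int = 1000) -> tuple[float, float]:
    """Maximum-likelihood recombination fraction between two F2 markers.

    EM over the two-locus genotype classes: the E-step assigns the expected
    number of recombinant gametes to each class (the double heterozygote is a
    mixture of coupling and repulsion phases), the M-step sets r to the mean
    recombinant fraction.  Returns (r_hat, LOD) with r clamped to [0, 0.4999];
    the LOD compares the likelihood at r_hat with free recombination (r=0.5).
    """
    a = np.asarray(g1)
    b = np.asarray(g2)
    keep = (a >= 0) & (b >= 0)
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValueError("need at least two overlapping non-missing individuals")
    counts = np.zeros((3, 3))
    np.add.at(counts, (a, b), 1.0)
    n = counts.sum()
    r = 0.25
    for _ in range(max_iter):
        rec = _REC_COUNT.copy()
        denom = (1 - r) ** 2 + r ** 2
        rec[1, 1] = 2 * r ** 2 / denom if denom > 0 else 0.0
        r_new = float((counts * rec).sum() / (2.0 * n))
        r_new = min(max(r_new, 0.0), R_CLAMP)
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new
    with np.errstate(divide="ignore"):
        ll_hat = np.where(counts > 0, counts * np.log(_joint_probs(r)), 0.0).sum()
        ll_null = np.where(counts > 0, counts * np.log(_joint_probs(0.5)), 0.0).sum()
    lod = max((ll_hat - ll_null) / math.log(10.0), 0.0)
    return r, lod


# ---------------------------------------------------------------------------
# map building
# ---------------------------------------------------------------------------

@dataclass
class LinkageGroup:
    name: str
    markers: list[str]
    positions: np.ndarray          # cumulative cM, same length as markers
    rf: np.ndarray                 # adjacent-pair r-hat, length len(markers)-1

    @property
    def length(self) -> float:
        return float(self.positions[-1]) if len(self.positions) else 0.0


@dataclass
class LinkageMap:
    groups: list[LinkageGroup]
    ordering: str = "given"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"group": g.name, "marker": m, "pos_cM": p}
            for g in self.groups
            for m, p in zip(g.markers, g.positions)
        ]
        return pd.DataFrame(rows, columns=["group", "marker", "pos_cM"])

    def summary(self) -> dict:
        counts = [len(g.markers) for g in self.groups]
        return marker_count_summary(counts) | {
            "total_length_cM": float(sum(g.length for g in self.groups)),
        }


def map_from_table(table: pd.DataFrame) -> LinkageMap:
    """Build a :class:`LinkageMap` from a (group, marker, pos_cM) table.

    Positions are taken as given (e.g. a previously estimated map, or the
    true map of a simulated cross); adjacent recombination fractions are
    back-computed through the Kosambi inverse.
    """
    groups = []
    for name, sub in table.groupby("group", sort=False):
        sub = sub.sort_values("pos_cM")
        pos = sub["pos_cM"].to_numpy(dtype=float)
        groups.append(LinkageGroup(
            name=str(name), markers=list(sub["marker"]), positions=pos,
            rf=kosambi_inverse(np.diff(pos)) if len(pos) > 1 else np.empty(0)))
    return LinkageMap(groups=groups, ordering="given")


def marker_count_summary(counts) -> dict:
    """Per-group marker-count summary (mean/SD/min/max), SD with n-1 denominator."""
    counts = np.asarray(list(counts), dtype=float)
    return {
        "n_groups": int(counts.size),
        "n_markers": int(counts.sum()),
        "mean_markers_per_group": float(counts.mean()),
        "sd_markers_per_group": float(counts.std(ddof=1)) if counts.size > 1 else 0.0,
        "min_markers_per_group": int(counts.min()),
        "max_markers_per_group": int(counts.max()),
    }


def _greedy_order(names: list[str], rf_matrix: np.ndarray) -> list[int]:
    """Nearest-neighbour seriation: start at the marker with the largest total
    recombination to the rest (a likely terminal) and extend one end greedily."""
    m = len(names)
    start = int(rf_matrix.sum(axis=1).argmax())
    order = [start]
    unused = set(range(m)) - {start}
    while unused:
        last = order[-1]
        nxt = min(unused, key=lambda j: rf_matrix[last, j])
        order.append(nxt)
        unused.discard(nxt)
    return order


def build_map(
    groups: list[list[str]],
    codes: pd.DataFrame,
    order: str = "given",
    marker_meta: pd.DataFrame | None = None,
) -> LinkageMap:
    """Assemble a :class:`LinkageMap` from grouped markers.

    ``order='given'`` keeps the supplied within-group marker order (or sorts
    by ``marker_meta`` (chrom, pos) when provided); ``order='greedy'`` runs a
    nearest-neighbour seriation minimising the sum of adjacent recombination
    fractions.  Positions accumulate adjacent-pair Kosambi distances.
    """
    if order not in {"given", "greedy"}:
        raise ValueError("order must be 'given' or 'greedy'")
    out: list[LinkageGroup] = []
    for i, members in enumerate(groups):
        members = list(members)
        if marker_meta is not None and order == "given":
            meta = marker_meta.loc[members]
            members = list(meta.sort_values(["chrom", "pos"]).index)
        if order == "greedy" and len(members) > 2:
            m = len(members)
            rf_mat = np.zeros((m, m))
            for a in range(m):
                for b in range(a + 1, m):
                    r, _ = estimate_rf(codes[members[a]].to_numpy(),
                                       codes[members[b]].to_numpy())
                    rf_mat[a, b] = rf_mat[b, a] = r
            members = [members[j] for j in _greedy_order(members, rf_mat)]
        rf = np.array([
            estimate_rf(codes[members[j]].to_numpy(), codes[members[j + 1]].to_numpy())[0]
            for j in range(len(members) - 1)
        ])
        positions = np.concatenate([[0.0], np.cumsum(kosambi(np.minimum(rf, R_CLAMP)))]) \
            if rf.size else np.zeros(1)
        out.append(LinkageGroup(name=f"LG{i + 1:02d}", markers=members,
                                positions=positions, rf=rf))
    return LinkageMap(groups=out, ordering=order)
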