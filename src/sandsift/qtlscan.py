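"""Single-QTL interval mapping for an F2 intercross.

Conditional genotype probabilities are computed on a cM grid (marker positions
plus pseudomarkers every ``step`` cM) by a hidden Markov model: the hidden
state is the true genotype {AA, AB, BB}, transitions over an interval of
recombination fraction r come from two independent gamete chains, and typed
markers emit the observed genotype with probability 1 - eps (eps/2 for each
wrong genotype); missing observations are uninformative.

The normal-model scan fits, at every grid position, a three-component normal
mixture whose component weights are the genotype probabilities, by EM
(standard interval mapping).  Covariates may shift the mean additively or
interact with the genotype (genotype-specific covariate slopes); the null
model drops the genotype terms but keeps the covariate main effects.  The
nonparametric scan is a Kruskal-Wallis statistic generalised to
probability-weighted rank sums (covariates are not supported there, matching
common practice).  Genome-wide significance comes from permuting the
phenotype (together with its covariate rows) against the genotypes; QTL
support intervals are Bayesian credible intervals on the posterior
proportional to 10^LOD, widened to the nearest flanking markers; effect sizes
are reported as percent variance explained, PVE = 100 (1 - 10^(-2 LOD / n)).

This model is autosomal only; X-chromosome bookkeeping is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .linkmap import MAP_FUNCTIONS, LinkageMap

__all__ = [
    "GenoProbGrid",
    "LodCurve",
    "PermutationResult",
    "f2_transition_matrix",
    "calc_genoprob",
    "scan_em",
    "scan_np",
    "perm_threshold",
    "bayes_interval",
    "pve",
]

F2_PRIOR = np.array([0.25, 0.5, 0.25])
LN10 = math.log(10.0)


def f2_transition_matrix(r: float) -> np.ndarray:
    """F2 genotype transition matrix over an interval with recombination r.

    Built from two independent gamete chains, each switching parental origin
    with probability r.
    """
    return np.array([
        [(1 - r) ** 2, 2 * r * (1 - r), r ** 2],
        [r * (1 - r), (1 - r) ** 2 + r ** 2, r * (1 - r)],
        [r ** 2, 2 * r * (1 - r), (1 - r) ** 2],
    ])


@dataclass
class GenoProbGrid:
    """Genotype probabilities for every individual at every grid position."""

    table: pd.DataFrame            # per position: group, pos_cM, is_marker, marker
    probs: np.ndarray              # (n_individuals, n_positions, 3)
    individuals: list[str]
    error_prob: float
    step: float
    map_function: str

    def group_slice(self, group: str) -> np.ndarray:
        return np.flatnonzero((self.table["group"] == group).to_numpy())


def _group_grid(marker_pos: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Grid positions (markers plus pseudomarkers anchored at the first marker)
    and a boolean mask of which grid slots are true markers."""
    first, last = marker_pos[0], marker_pos[-1]
    pseudo = np.arange(first, last, step) if step > 0 and last > first else np.array([first])
    merged: list[float] = []
    is_marker: list[bool] = []
    for p in np.sort(np.concatenate([marker_pos, pseudo])):
        if merged and abs(p - merged[-1]) < 1e-6:
            continue
        merged.append(float(p))
        is_marker.append(False)
    grid = np.array(merged)
    mask = np.zeros(len(grid), dtype=bool)
    for p in marker_pos:
        mask[np.abs(grid - p).argmin()] = True
    return grid, mask


def calc_genoprob(
    codes: pd.DataFrame,
    lmap: LinkageMap,
    step: float = 1.0,
    error_prob: float = 0.05,
    map_function: str = "kosambi",
) -> GenoProbGrid:
    """Forward-backward genotype probabilities on the pseudomarker grid.

    ``codes`` holds observed genotypes (0/1/2, -1 missing) for the markers on
    ``lmap``; probabilities are computed per linkage group per individual and
    rows always sum to 1.
    """
    if map_function not in MAP_FUNCTIONS:
        raise ValueError(f"unknown map function {map_function!r}")
    _, inverse = MAP_FUNCTIONS[map_function]
    eps = error_prob
    n = len(codes)
    emit_lookup = np.full((4, 3), 1.0)     # rows: missing, AA, AB, BB observed
    for g in range(3):
        emit_lookup[g + 1] = eps / 2.0
        emit_lookup[g + 1, g] = 1.0 - eps

    tables, prob_blocks = [], []
    for lg in lmap.groups:
        pos = np.asarray(lg.positions, dtype=float)
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"{lg.name}: marker positions not sorted")
        grid, is_marker = _group_grid(pos, step)
        p_count = len(grid)
        # observation index per grid slot: 0 = untyped slot, g+1 = marker obs
        obs = np.zeros((n, p_count), dtype=np.int8)
        marker_names = [""] * p_count
        for name, mpos in zip(lg.markers, pos):
            j = int(np.abs(grid - mpos).argmin())
            marker_names[j] = name
            col = codes[name].to_numpy()
            obs[:, j] = np.where(col >= 0, col + 1, 0)
        trans = [f2_transition_matrix(float(inverse(d))) for d in np.diff(grid)]

        alpha = np.empty((n, p_count, 3))
        scale = np.empty((n, p_count))
        a = F2_PRIOR * emit_lookup[obs[:, 0]]
        scale[:, 0] = a.sum(axis=1)
        alpha[:, 0] = a / scale[:, 0, None]
        for j in range(1, p_count):
            a = (alpha[:, j - 1] @ trans[j - 1]) * emit_lookup[obs[:, j]]
            scale[:, j] = a.sum(axis=1)
            alpha[:, j] = a / scale[:, j, None]
        beta = np.empty((n, p_count, 3))
        beta[:, -1] = 1.0
        for j in range(p_count - 2, -1, -1):
            b = (beta[:, j + 1] * emit_lookup[obs[:, j + 1]]) @ trans[j].T
            beta[:, j] = b / b.sum(axis=1, keepdims=True)
        post = alpha * beta
        post /= post.sum(axis=2, keepdims=True)
        prob_blocks.append(post)
        tables.append(pd.DataFrame({
            "group": lg.name, "pos_cM": grid, "is_marker": is_marker,
            "marker": marker_names,
        }))
    return GenoProbGrid(
        table=pd.concat(tables, ignore_index=True),
        probs=np.concatenate(prob_blocks, axis=1),
        individuals=list(codes.index),
        error_prob=error_prob, step=step, map_function=map_function,
    )


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

@dataclass
class LodCurve:
    """Per-position LOD values from a genome scan."""

    table: pd.DataFrame            # group, pos_cM, is_marker, marker, lod
    model: str                     # normal_em / nonparametric
    covariates: str                # none / additive / additive_interactive
    n: int                         # individuals used
    not_converged: list[int] = field(default_factory=list)

    @property
    def lod(self) -> np.ndarray:
        return self.table["lod"].to_numpy()

    def peak(self) -> pd.Series:
        return self.table.loc[self.table["lod"].idxmax()]

    @property
    def max_lod(self) -> float:
        return float(self.table["lod"].max())


def _normal_loglik(y: np.ndarray, fitted: np.ndarray) -> float:
    resid = y - fitted
    n = y.size
    s2 = float(resid @ resid) / n
    return -0.5 * n * (math.log(2 * math.pi * s2) + 1.0)


def _prepare(grid: GenoProbGrid, phenotype, covariates):
    y = np.asarray(
        phenotype.reindex(grid.individuals) if isinstance(phenotype, pd.Series)
        else phenotype, dtype=float)
    if y.shape != (len(grid.individuals),):
        raise ValueError("phenotype length must match the grid's individuals")
    x = None
    if covariates is not None:
        x = np.asarray(
            covariates.reindex(grid.individuals) if isinstance(covariates, (pd.Series, pd.DataFrame))
            else covariates, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if len(x) != len(y):
            raise ValueError("covariate rows must match the phenotype")
    keep = np.isfinite(y)
    if x is not None:
        keep &= np.all(np.isfinite(x), axis=1)
        x = x[keep]
    return y[keep], x, keep


def _scan_em_nocov(w: np.ndarray, y: np.ndarray, tol: float,
                   max_iter: int) -> tuple[np.ndarray, list[int]]:
    """Vectorised EM across all grid positions, no covariates."""
    n, p_count, _ = w.shape
    mu0, s20 = y.mean(), y.var()
    ll0 = -0.5 * n * (math.log(2 * math.pi * s20) + 1.0)
    mu = np.full((p_count, 3), mu0)
    s2 = np.full(p_count, s20)
    ll_prev = np.full(p_count, -np.inf)
    yb = y[:, None, None]
    not_conv: list[int] = []
    ll = np.full(p_count, ll0)
    for it in range(max_iter):
        dens = np.exp(-0.5 * (yb - mu) ** 2 / s2[:, None]) / np.sqrt(2 * math.pi * s2[:, None])
        num = w * dens
        mix = num.sum(axis=2)
        mix = np.maximum(mix, 1e-300)
        ll = np.log(mix).sum(axis=0)
        resp = num / mix[:, :, None]
        denom = resp.sum(axis=0)
        new_mu = np.where(denom > 1e-12, (resp * y[:, None, None]).sum(axis=0) / np.maximum(denom, 1e-12), mu)
        s2 = np.maximum((resp * (yb - new_mu) ** 2).sum(axis=(0, 2)) / n, 1e-12)
        mu = new_mu
        done = np.abs(ll - ll_prev) < tol
        ll_prev = ll
        if done.all():
            break
    else:
        not_conv = list(np.flatnonzero(~done))
    lod = (ll - ll0) / LN10
    return np.maximum(lod, 0.0), not_conv


def _design(n: int, x: np.ndarray | None, interactive: bool) -> np.ndarray:
    """Per-(individual, genotype) design rows for the mixture regression."""
    eye = np.eye(3)
    z = np.broadcast_to(eye, (n, 3, 3)).copy()     # genotype means
    if x is None:
        return z
    c = x.shape[1]
    if not interactive:
        xa = np.broadcast_to(x[:, None, :], (n, 3, c))
        return np.concatenate([z, xa], axis=2)
    inter = np.einsum("gh,nc->nghc", eye, x).reshape(n, 3, 3 * c)
    return np.concatenate([z, inter], axis=2)


def _scan_em_cov(w, y, x, interactive, tol, max_iter):
    """Per-position EM with covariates (additive or genotype-interactive)."""
    n, p_count, _ = w.shape
    x0 = np.column_stack([np.ones(n), x])
    beta0, *_ = np.linalg.lstsq(x0, y, rcond=None)
    fitted0 = x0 @ beta0
    ll0 = _normal_loglik(y, fitted0)
    s20 = float(np.mean((y - fitted0) ** 2))
    z = _design(n, x, interactive)
    p_dim = z.shape[2]
    theta_init = np.zeros(p_dim)
    theta_init[:3] = beta0[0]
    if not interactive:
        theta_init[3:] = beta0[1:]
    else:
        # genotype-specific slopes all start at the shared null slope
        theta_init[3:] = np.tile(beta0[1:], 3)
    lods = np.empty(p_count)
    not_conv = []
    for j in range(p_count):
        wj = w[:, j, :]
        theta = theta_init.copy()
        s2 = s20
        ll_prev = -np.inf
        converged = False
        for _ in range(max_iter):
            fitted = z @ theta                          # (n, 3)
            dens = np.exp(-0.5 * (y[:, None] - fitted) ** 2 / s2) / math.sqrt(2 * math.pi * s2)
            num = wj * dens
            mix = np.maximum(num.sum(axis=1), 1e-300)
            ll = float(np.log(mix).sum())
            resp = num / mix[:, None]
            a_mat = np.einsum("ng,ngp,ngq->pq", resp, z, z)
            b_vec = np.einsum("ng,ngp,n->p", resp, z, y)
            theta = np.linalg.solve(a_mat + 1e-10 * np.eye(p_dim), b_vec)
            fitted = z @ theta
            s2 = max(float((resp * (y[:, None] - fitted) ** 2).sum() / n), 1e-12)
            if abs(ll - ll_prev) < tol:
                converged = True
                break
            ll_prev = ll
        if not converged:
            not_conv.append(j)
        lods[j] = max((ll - ll0) / LN10, 0.0)
    return lods, not_conv


def scan_em(
    grid: GenoProbGrid,
    phenotype,
    covariates=None,
    interactive: bool = False,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> LodCurve:
    """EM interval-mapping scan under the normal mixture model.

    ``covariates`` (optional, e.g. sex coded 0/1) shift the phenotype mean;
    with ``interactive=True`` the covariate effect is genotype-specific.  The
    null model at every position keeps the covariate main effects and drops
    the genotype terms.  Individuals with missing phenotype or covariates are
    excluded; LOD = log10 of the alternative/null likelihood ratio.
    """
    y, x, keep = _prepare(grid, phenotype, covariates)
    if y.size < 3:
        raise ValueError("need at least three phenotyped individuals")
    w = grid.probs[keep]
    if x is None:
        lod, not_conv = _scan_em_nocov(w, y, tol, max_iter)
        covar = "none"
    else:
        lod, not_conv = _scan_em_cov(w, y, x, interactive, tol, max_iter)
        covar = "additive_interactive" if interactive else "additive"
    table = grid.table.copy()
    table["lod"] = lod
    return LodCurve(table=table, model="normal_em", covariates=covar,
                    n=int(y.size), not_converged=not_conv)


def scan_np(grid: GenoProbGrid, phenotype) -> LodCurve:
    """Nonparametric scan: probability-weighted Kruskal-Wallis statistic.

    Phenotypes are ranked (mid-ranks for ties); at each position the genotype
    probabilities act as fractional group memberships.  At a fully typed
    marker this reduces to the classical Kruskal-Wallis statistic (with tie
    correction); LOD = statistic / (2 ln 10).
    """
    y, _, keep = _prepare(grid, phenotype, None)
    if y.size < 3:
        raise ValueError("need at least three phenotyped individuals")
    w = grid.probs[keep]
    n = y.size
    ranks = rankdata(y)
    _, tie_counts = np.unique(y, return_counts=True)
    tie_term = 1.0 - (tie_counts ** 3 - tie_counts).sum() / (n ** 3 - n)
    table = grid.table.copy()
    if tie_term <= 0:          # constant phenotype: no information
        table["lod"] = 0.0
        return LodCurve(table=table, model="nonparametric", covariates="none", n=n)
    n_g = w.sum(axis=0)                          # (P, 3)
    s_g = (w * ranks[:, None, None]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rbar = s_g / n_g
    centre = (n + 1) / 2.0
    dev = np.where(n_g > 0, (rbar - centre) ** 2, 0.0)
    h = 12.0 / (n * (n + 1)) * (n_g * dev).sum(axis=1)
    h /= tie_term
    table["lod"] = np.maximum(h, 0.0) / (2.0 * LN10)
    return LodCurve(table=table, model="nonparametric", covariates="none", n=n)


# ---------------------------------------------------------------------------
# permutations, intervals, PVE
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    max_lods: np.ndarray
    thresholds: dict[float, float]
    n_perm: int

    def genomewide_p(self, peak_lod: float) -> float:
        """Add-one genome-wide p-value of an observed peak."""
        return float((1 + (self.max_lods >= peak_lod).sum()) / (self.n_perm + 1))


def perm_threshold(
    grid: GenoProbGrid,
    phenotype,
    covariates=None,
    interactive: bool = False,
    model: str = "em",
    n_perm: int = 1000,
    alphas: tuple[float, ...] = (0.05, 0.10),
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> PermutationResult:
    """Genome-wide LOD thresholds by phenotype permutation.

    The phenotype vector (with its covariate rows, so their relationship is
    preserved) is shuffled against the genotype grid ``n_perm`` times; the
    genome-wide maximum LOD of each shuffle forms the null distribution, and
    the thresholds are its empirical (1 - alpha) quantiles.
    """
    if model not in {"em", "np"}:
        raise ValueError("model must be 'em' or 'np'")
    y = np.asarray(
        phenotype.reindex(grid.individuals) if isinstance(phenotype, pd.Series)
        else phenotype, dtype=float)
    x = covariates
    if x is not None:
        x = np.asarray(
            x.reindex(grid.individuals) if isinstance(x, (pd.Series, pd.DataFrame))
            else x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
    rng = np.random.default_rng(seed)
    maxes = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.permutation(len(y))
        yp = pd.Series(y[idx], index=grid.individuals)
        xp = x[idx] if x is not None else None
        if model == "em":
            curve = scan_em(grid, yp, covariates=xp, interactive=interactive,
                            tol=tol, max_iter=max_iter)
        else:
            curve = scan_np(grid, yp)
        maxes[b] = curve.max_lod
    thresholds = {a: float(np.quantile(maxes, 1.0 - a, method="higher"))
                  for a in alphas}
    return PermutationResult(max_lods=maxes, thresholds=thresholds, n_perm=n_perm)


def bayes_interval(curve: LodCurve, group: str | None = None,
                   prob: float = 0.95) -> dict:
    """95% Bayesian credible interval for the peak's linkage group.

    The posterior over positions is proportional to 10^LOD; starting from the
    peak, the interval grows towards the neighbour with the larger posterior
    mass until it holds at least ``prob``; the endpoints are then widened to
    the nearest flanking true markers.
    """
    table = curve.table
    if group is None:
        group = str(curve.peak()["group"])
    sub = table[table["group"] == group].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no positions for group {group!r}")
    lod = sub["lod"].to_numpy()
    w = np.power(10.0, lod - lod.max())
    w /= w.sum()
    peak = int(lod.argmax())
    lo = hi = peak
    mass = w[peak]
    while mass < prob and (lo > 0 or hi < len(w) - 1):
        left = w[lo - 1] if lo > 0 else -1.0
        right = w[hi + 1] if hi < len(w) - 1 else -1.0
        if left >= right:
            lo -= 1
            mass += w[lo]
        else:
            hi += 1
            mass += w[hi]
    pos = sub["pos_cM"].to_numpy()
    markers = sub[sub["is_marker"]]
    m_pos = markers["pos_cM"].to_numpy()
    lo_candidates = m_pos[m_pos <= pos[lo] + 1e-9]
    hi_candidates = m_pos[m_pos >= pos[hi] - 1e-9]
    lo_m = float(lo_candidates.max()) if lo_candidates.size else float(m_pos.min())
    hi_m = float(hi_candidates.min()) if hi_candidates.size else float(m_pos.max())
    lo_name = markers.loc[(markers["pos_cM"] - lo_m).abs().idxmin(), "marker"]
    hi_name = markers.loc[(markers["pos_cM"] - hi_m).abs().idxmin(), "marker"]
    return {
        "group": group, "peak_cM": float(pos[peak]),
        "low_cM": float(pos[lo]), "high_cM": float(pos[hi]),
        "low_marker_cM": lo_m, "high_marker_cM": hi_m,
        "low_marker": lo_name, "high_marker": hi_name,
        "coverage": float(mass),
    }


def pve(lod: float, n: int) -> float:
    """Percent phenotypic variance explained: 100 (1 - 10^(-2 LOD / n))."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if lod < 0:
        raise ValueError("LOD must be nonnegative")
    return 100.0 * (1.0 - 10.0 ** (-2.0 * lod / n))
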