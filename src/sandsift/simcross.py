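"""Synthetic study generators: F2 crosses, phenotypes, landmarks, sand images, VCFs.

Every downstream stage of the pipeline (variant filtering, linkage mapping,
QTL scans, morphometrics, behaviour scoring) can be exercised against data
generated here, with known ground truth.  The generators emulate the structure
of an F2 intercross between two inbred-like parental lines (~113 individuals,
~1,000 biallelic markers on 22 linkage groups, parental reference panels of 6
and 5 fish), behavioural sand-sifting trials with two-layer sand images, and
13-point 2D landmark configurations with allometric shape variation.

Meiosis model: gametes are simulated as a Markov chain over marker loci whose
switch probability in each interval is the map function's recombination
fraction for that gap (no interference beyond what the map function implies
pairwise).  All generators are deterministic given their seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linkmap import MAP_FUNCTIONS
from .morphshape import LANDMARK_IDS, LandmarkConfig

__all__ = [
    "SimMap",
    "Qtl",
    "QtlArchitecture",
    "SimImageSpec",
    "simulate_map",
    "simulate_f2",
    "simulate_phenotypes",
    "simulate_landmarks",
    "simulate_sand_images",
    "simulate_vcf",
]

MISSING = -1  # genotype codes: 0=AA, 1=AB, 2=BB, -1 missing


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimMap:
    """A simulated genetic map: chromosome lengths (cM) and marker positions."""

    chromosomes: tuple[tuple[str, float], ...]
    positions: dict[str, np.ndarray]

    def __post_init__(self):
        if len(self.chromosomes) < 1:
            raise ValueError("need at least one chromosome")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has nonpositive length")
            pos = np.asarray(self.positions[name], dtype=float)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"marker positions on {name} not strictly increasing")
            if pos.min() < 0 or pos.max() > length:
                raise ValueError(f"marker positions on {name} outside [0, {length}]")

    @property
    def n_markers(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def marker_table(self) -> pd.DataFrame:
        rows = [
            {"marker": f"{chrom}_m{i + 1:03d}", "chrom": chrom, "pos_cM": p}
            for chrom, _ in self.chromosomes
            for i, p in enumerate(self.positions[chrom])
        ]
        return pd.DataFrame(rows).set_index("marker")


@dataclass(frozen=True)
class Qtl:
    chrom: str
    pos_cM: float
    additive: float      # half the difference between the two homozygotes
    dominance: float = 0.0


@dataclass(frozen=True)
class QtlArchitecture:
    """Genetic architecture of a simulated trait.

    ``label`` describes the mode expected to generate transgression:
    ``complementary`` (antagonistic additive effects dispersed between the
    parental lines), ``overdominant`` (heterozygote advantage), ``epistatic``
    or ``null``.  Epistasis terms multiply centred genotype codes
    (+1 for AA, 0 for AB, -1 for BB) of a QTL pair.
    """

    qtl: tuple[Qtl, ...] = ()
    epistasis: tuple[tuple[int, int, float], ...] = ()
    sigma_e: float = 1.0
    label: str = "null"

    def __post_init__(self):
        if self.sigma_e < 0:
            raise ValueError("environmental SD must be nonnegative")
        if self.label not in {"complementary", "overdominant", "epistatic", "null"}:
            raise ValueError(f"unknown architecture label {self.label!r}")
        if self.label == "complementary":
            signs = {np.sign(q.additive) for q in self.qtl if q.additive != 0}
            if signs != {-1.0, 1.0}:
                raise ValueError("complementary architecture requires mixed-sign "
                                 "additive effects")


@dataclass(frozen=True)
class SimImageSpec:
    """Parameters of the two-layer sand image generator.

    The before image is beige surface sand; the after image repaints disturbed
    patches with the dark bottom-layer brightness distribution so that the
    repainted pixel fraction is as close to ``turned_fraction`` as possible.
    """

    width: int = 160
    height: int = 120
    grain_px: int = 2
    beige_mean: float = 180.0
    beige_sd: float = 12.0
    black_mean: float = 40.0
    black_sd: float = 12.0
    turned_fraction: float = 0.3
    patch_radius_mean: float = 6.0
    patch_radius_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.turned_fraction <= 1.0:
            raise ValueError("turned fraction must lie in [0, 1]")
        if not self.black_mean < 80.0 < self.beige_mean:
            raise ValueError("brightness means must straddle the threshold "
                             "(black below 80, beige above)")


# ---------------------------------------------------------------------------
# map and cross
# ---------------------------------------------------------------------------

def simulate_map(
    n_chr: int = 22,
    length_cM: float = 100.0,
    markers_per_chr: int | list[int] = 43,
    seed: int = 0,
    placement: str = "even",
) -> SimMap:
    """Simulate a genetic map with ``n_chr`` chromosomes of ``length_cM``.

    ``markers_per_chr`` may be a single count or one per chromosome (>= 2
    each).  ``placement='even'`` spaces markers evenly including both
    endpoints; ``'uniform'`` draws interior positions uniformly at random
    (endpoints always included) and is deterministic given ``seed``.
    """
    if n_chr < 1:
        raise ValueError("need at least one chromosome")
    if length_cM <= 0:
        raise ValueError("chromosome length must be positive")
    if np.isscalar(markers_per_chr):
        counts = [int(markers_per_chr)] * n_chr
    else:
        counts = [int(c) for c in markers_per_chr]
        if len(counts) != n_chr:
            raise ValueError("markers_per_chr must match n_chr")
    if min(counts) < 2:
        raise ValueError("need at least two markers per chromosome")
    rng = np.random.default_rng(seed)
    chromosomes = tuple((f"chr{i + 1:02d}", float(length_cM)) for i in range(n_chr))
    positions = {}
    for (name, length), k in zip(chromosomes, counts):
        if placement == "even":
            pos = np.linspace(0.0, length, k)
        elif placement == "uniform":
            interior = np.sort(rng.uniform(0, length, size=k - 2))
            pos = np.concatenate([[0.0], interior, [length]])
            while np.any(np.diff(pos) <= 0):  # ties are measure-zero but guard anyway
                interior = np.sort(rng.uniform(0, length, size=k - 2))
                pos = np.concatenate([[0.0], interior, [length]])
        else:
            raise ValueError("placement must be 'even' or 'uniform'")
        positions[name] = pos
    return SimMap(chromosomes=chromosomes, positions=positions)


def _simulate_gametes(rng, n: int, r: np.ndarray, m: int) -> np.ndarray:
    """n gametes over m loci; allele switches between loci with probabilities r."""
    alleles = np.empty((n, m), dtype=np.int8)
    alleles[:, 0] = rng.integers(0, 2, size=n)
    if m > 1:
        switches = rng.random((n, m - 1)) < r
        alleles[:, 1:] = np.logical_xor.accumulate(
            np.concatenate([alleles[:, :1].astype(bool), switches], axis=1), axis=1
        )[:, 1:]
    return alleles


def simulate_f2(
    smap: SimMap,
    n: int,
    map_function: str = "kosambi",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate F2 genotypes (individuals x markers, codes 0/1/2 = AA/AB/BB).

    Each F2 genotype is the union of two independent gametes; a gamete is a
    Markov chain over the chromosome's marker loci with interval switch
    probability equal to the selected map function's recombination fraction
    for the marker gap.
    """
    if n < 1:
        raise ValueError("need at least one individual")
    if map_function not in MAP_FUNCTIONS:
        raise ValueError(f"unknown map function {map_function!r}")
    _, inverse = MAP_FUNCTIONS[map_function]
    rng = np.random.default_rng(seed)
    blocks = []
    for chrom, _ in smap.chromosomes:
        pos = smap.positions[chrom]
        r = inverse(np.diff(pos)) if len(pos) > 1 else np.empty(0)
        g1 = _simulate_gametes(rng, n, r, len(pos))
        g2 = _simulate_gametes(rng, n, r, len(pos))
        blocks.append(g1 + g2)  # allele 1 = parent-B allele, so 0=AA,1=AB,2=BB
    codes = np.concatenate(blocks, axis=1).astype(np.int8)
    markers = smap.marker_table().index
    index = pd.Index([f"F2_{i + 1:03d}" for i in range(n)], name="individual")
    return pd.DataFrame(codes, index=index, columns=markers)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _resolve_qtl_markers(smap: SimMap, arch: QtlArchitecture) -> list[str]:
    table = smap.marker_table()
    names = []
    for q in arch.qtl:
        lengths = dict(smap.chromosomes)
        if q.chrom not in lengths:
            raise ValueError(f"QTL chromosome {q.chrom!r} not on the map")
        if not 0 <= q.pos_cM <= lengths[q.chrom]:
            raise ValueError(f"QTL position {q.pos_cM} outside {q.chrom}")
        sub = table[table["chrom"] == q.chrom]
        names.append(sub.index[(sub["pos_cM"] - q.pos_cM).abs().argmin()])
    return names


def genetic_values(genotypes: pd.DataFrame, smap: SimMap,
                   arch: QtlArchitecture) -> np.ndarray:
    """Deterministic genetic value per individual under ``arch``.

    Each QTL is resolved to its nearest marker; genotype effects are +a for
    AA, d for AB, -a for BB.  Epistasis terms add coef * c_i * c_j with the
    centred code c = 1 - genotype.
    """
    names = _resolve_qtl_markers(smap, arch)
    value = np.zeros(len(genotypes))
    centred = {}
    for q, name in zip(arch.qtl, names):
        g = genotypes[name].to_numpy()
        effect = np.select([g == 0, g == 1, g == 2],
                           [q.additive, q.dominance, -q.additive], default=0.0)
        value += effect
        centred[name] = 1.0 - g
    for i, j, coef in arch.epistasis:
        value += coef * centred[names[i]] * centred[names[j]]
    return value


def simulate_phenotypes(
    genotypes: pd.DataFrame,
    smap: SimMap,
    arch: QtlArchitecture,
    n_parentA: int = 6,
    n_parentB: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Phenotypes for the F2 individuals and fixed-homozygote parental panels.

    Parent A is homozygous AA at every QTL, parent B homozygous BB; both get
    the architecture's epistasis contribution of their fixed backgrounds.
    Returns a frame with columns ``class`` (F2/CAL/TAE) and ``value``.
    """
    rng = np.random.default_rng(seed)
    f2_value = genetic_values(genotypes, smap, arch)
    a_sum = sum(q.additive for q in arch.qtl)
    ep_sum = sum(coef for _, _, coef in arch.epistasis)  # c=+1 (A) and c=-1 (B) both give +coef
    rows = []
    for ind, v in zip(genotypes.index, f2_value):
        rows.append({"individual": ind, "class": "F2", "value": v})
    for i in range(n_parentA):
        rows.append({"individual": f"CAL_{i + 1}", "class": "CAL", "value": a_sum + ep_sum})
    for i in range(n_parentB):
        rows.append({"individual": f"TAE_{i + 1}", "class": "TAE", "value": -a_sum + ep_sum})
    out = pd.DataFrame(rows).set_index("individual")
    out["value"] += rng.normal(0.0, arch.sigma_e, size=len(out))
    return out


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def simulate_landmarks(
    n_per_class: dict[str, int],
    class_means: dict[str, np.ndarray],
    allometry: np.ndarray | None = None,
    log_sl_mean: float = 2.0,
    log_sl_sd: float = 0.1,
    noise_sd: float = 0.0,
    nuisance: bool = True,
    seed: int = 0,
) -> list[LandmarkConfig]:
    """Simulate 13-point landmark configurations with optional allometry.

    Each specimen is its class mean plus ``(logSL - mean logSL) * allometry``
    plus isotropic landmark noise, then (when ``nuisance``) randomly rotated,
    translated and scaled — the nuisance components that Procrustes
    superimposition must remove.  Standard length in mm is ``10**logSL``.
    """
    rng = np.random.default_rng(seed)
    k = len(LANDMARK_IDS)
    allo = np.zeros((k, 2)) if allometry is None else np.asarray(allometry, float).reshape(k, 2)
    configs = []
    for cls, count in n_per_class.items():
        mean = np.asarray(class_means[cls], dtype=float).reshape(k, 2)
        for i in range(count):
            log_sl = rng.normal(log_sl_mean, log_sl_sd)
            coords = mean + (log_sl - log_sl_mean) * allo
            coords = coords + rng.normal(0.0, noise_sd, size=(k, 2))
            if nuisance:
                theta = rng.uniform(0, 2 * np.pi)
                rot = np.array([[np.cos(theta), -np.sin(theta)],
                                [np.sin(theta), np.cos(theta)]])
                scale = np.exp(rng.normal(0.0, 0.2))
                shift = rng.normal(0.0, 5.0, size=2)
                coords = scale * coords @ rot.T + shift
            configs.append(LandmarkConfig(
                id=f"{cls}_{i + 1:03d}", coords=coords,
                sl=float(10.0 ** log_sl), cls=cls,
                sex="M" if rng.random() < 0.5 else "F",
            ))
    return configs


# ---------------------------------------------------------------------------
# sand images
# ---------------------------------------------------------------------------

def simulate_sand_images(spec: SimImageSpec) -> tuple[np.ndarray, np.ndarray, float]:
    """Generate (before, after, realized_fraction) for a two-layer sand trial.

    Disturbance disks are painted until the repainted area reaches the target
    fraction; the final disk is trimmed pixel-by-pixel (nearest to its centre
    first) so the realized fraction matches the target up to integer pixel
    resolution.  The returned fraction is exactly the repainted pixel count
    divided by the total pixel count.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    before = np.clip(rng.normal(spec.beige_mean, spec.beige_sd, size=(h, w)), 0, 255)
    total = h * w
    target = int(round(spec.turned_fraction * total))
    mask = np.zeros((h, w), dtype=bool)
    if target >= total:
        mask[:] = True
    else:
        yy, xx = np.mgrid[0:h, 0:w]
        painted = 0
        for _ in range(100_000):
            if painted >= target:
                break
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            radius = max(abs(rng.normal(spec.patch_radius_mean, spec.patch_radius_sd)),
                         spec.grain_px)
            dist2 = (yy - cy) ** 2 + (xx - cx) ** 2
            disk = dist2 <= radius ** 2
            new = disk & ~mask
            n_new = int(new.sum())
            if painted + n_new <= target:
                mask |= new
                painted += n_new
            else:
                needed = target - painted
                ys, xs = np.nonzero(new)
                order = np.argsort(dist2[ys, xs], kind="stable")[:needed]
                mask[ys[order], xs[order]] = True
                painted = target
        else:  # pragma: no cover - extremely unlikely fill failure
            remaining = np.flatnonzero(~mask.ravel())
            fill = rng.choice(remaining, size=target - painted, replace=False)
            mask.ravel()[fill] = True
    after = before.copy()
    n_black = int(mask.sum())
    after[mask] = np.clip(rng.normal(spec.black_mean, spec.black_sd, size=n_black), 0, 255)
    return before, after, n_black / total


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_BP_PER_CM = 10_000


def simulate_vcf(
    smap: SimMap,
    f2_genotypes: pd.DataFrame,
    n_panelA: int = 6,
    n_panelB: int = 5,
    missing_rate: float = 0.0,
    mean_depth: float = 30.0,
    seed: int = 0,
    inject: dict[str, int] | None = None,
) -> str:
    """Render the simulated cross as VCF v4.2 text.

    Parental panels are fixed homozygotes (panel A for the reference allele,
    panel B for the alternate) at every informative site.  ``inject`` adds
    rule-violating records for filter tests; recognised keys:
    ``low_site_qual``, ``indel``, ``multiallelic``, ``monomorphic``,
    ``high_missing``, ``high_depth``, ``singleton`` and ``cluster`` (a pair of
    records within 200 bp).  Depth is 10 + Poisson(mean_depth - 10) so clean
    records never trip the genotype-depth mask.
    """
    rng = np.random.default_rng(seed)
    inject = dict(inject or {})
    samples = ([f"CAL_{i + 1}" for i in range(n_panelA)]
               + [f"TAE_{i + 1}" for i in range(n_panelB)]
               + list(f2_genotypes.index))
    n_f2 = len(f2_genotypes)

    def depth() -> int:
        return int(10 + rng.poisson(max(mean_depth - 10.0, 0.0)))

    def fmt(gt: str, gq: int = 99, dp: int | None = None) -> str:
        return f"{gt}:{gq}:{depth() if dp is None else dp}"

    def site_calls(codes: np.ndarray, gq: int = 99, dp: int | None = None) -> list[str]:
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        calls = [fmt("0/0", gq, dp) for _ in range(n_panelA)]
        calls += [fmt("1/1", gq, dp) for _ in range(n_panelB)]
        for c in codes:
            c = MISSING if missing_rate and rng.random() < missing_rate else int(c)
            calls.append(fmt(gt_map[c], gq, dp))
        return calls

    records: list[tuple[str, int, str]] = []
    table = smap.marker_table()
    for chrom, _ in smap.chromosomes:
        sub = table[table["chrom"] == chrom]
        for marker, row in sub.iterrows():
            pos_bp = int(round(row["pos_cM"] * _BP_PER_CM)) + 1
            calls = site_calls(f2_genotypes[marker].to_numpy())
            line = f"{chrom}\t{pos_bp}\t{marker}\tA\tT\t60\tPASS\t.\tGT:GQ:DP\t" + "\t".join(calls)
            records.append((chrom, pos_bp, line))

    # rule-violating records go on the last chromosome, past the real markers
    chrom = smap.chromosomes[-1][0]
    next_bp = int(round(smap.chromosomes[-1][1] * _BP_PER_CM)) + 10_000

    def extra(ref: str, alt: str, qual: float, calls: list[str]) -> None:
        nonlocal next_bp
        line = (f"{chrom}\t{next_bp}\tinjected_{next_bp}\t{ref}\t{alt}\t{qual:g}\tPASS\t."
                f"\tGT:GQ:DP\t" + "\t".join(calls))
        records.append((chrom, next_bp, line))
        next_bp += 1_000

    balanced = np.resize(np.array([0, 1, 2]), n_f2)
    for _ in range(inject.pop("low_site_qual", 0)):
        extra("A", "T", 10, site_calls(balanced))
    for _ in range(inject.pop("indel", 0)):
        extra("AT", "A", 60, site_calls(balanced))
    for _ in range(inject.pop("multiallelic", 0)):
        extra("A", "T,G", 60, site_calls(balanced))
    for _ in range(inject.pop("monomorphic", 0)):
        calls = [fmt("0/0") for _ in samples]
        extra("A", "T", 60, calls)
    for _ in range(inject.pop("high_missing", 0)):
        calls = [fmt("./.") if i % 2 == 0 else fmt("0/1") for i in range(len(samples))]
        extra("A", "T", 60, calls)
    for _ in range(inject.pop("high_depth", 0)):
        calls = site_calls(balanced, dp=200)
        extra("A", "T", 60, calls)
    for _ in range(inject.pop("singleton", 0)):
        calls = [fmt("0/1")] + [fmt("0/0") for _ in range(len(samples) - 1)]
        extra("A", "T", 60, calls)
    for _ in range(inject.pop("cluster", 0)):
        extra("A", "T", 60, site_calls(balanced))
        line = (f"{chrom}\t{next_bp - 900}\tinjected_{next_bp - 900}\tA\tT\t60\tPASS\t."
                f"\tGT:GQ:DP\t" + "\t".join(site_calls(balanced)))
        records.append((chrom, next_bp - 900, line))
    if inject:
        raise ValueError(f"unknown injection keys: {sorted(inject)}")

    records.sort(key=lambda t: (t[0], t[1]))
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##source=sandsift.simcross\n")
    for c, length in smap.chromosomes:
        buf.write(f"##contig=<ID={c},length={int(length * _BP_PER_CM) + 200_000}>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
    buf.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
              + "\t".join(samples) + "\n")
    for _, _, line in records:
        buf.write(line + "\n")
    return buf.getvalue()
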