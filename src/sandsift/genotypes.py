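"""Hard-filtering of RADseq variant calls and recoding of F2 genotypes.

Implements the marker-selection pipeline for the cross: site- and
genotype-level quality filters, removal of indels and their neighbourhoods,
multiallelic/monomorphic sites, high-missingness and paralog-like high-depth
sites, singletons/doubletons, and thinning to one SNP per 200 bp RAD locus;
then selection of markers reciprocally fixed between the two parental panels
and recoding of the F2 offspring to AA/AB/BB relative to the parent-A allele.

A site that violates several rules is attributed to the first failing rule in
the stated order, so the exclusion counts plus the retained count always sum
to the input count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "FilterThresholds",
    "F2GenotypeMatrix",
    "read_vcf",
    "filter_variants",
    "filter_individuals",
    "find_reciprocally_fixed",
    "recode_f2",
]

MISSING = -1

RULE_ORDER = (
    "site_quality",
    "indel",
    "near_indel",
    "multiallelic",
    "monomorphic",
    "missingness",
    "mean_depth",
    "mac",
    "spacing",
)


@dataclass
class VariantRecord:
    """One VCF site with per-sample genotype calls, qualities and depths."""

    chrom: str
    pos: int                       # 1-based
    ref: str
    alt: tuple[str, ...]
    qual: float
    gt: np.ndarray                 # (n_samples, 2) allele indices, -1 missing
    gq: np.ndarray                 # (n_samples,)
    dp: np.ndarray                 # (n_samples,)
    id: str = "."

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"{self.chrom}:{self.pos}: position must be >= 1")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != 1 or any(len(a) != 1 for a in self.alt)

    @property
    def missing_mask(self) -> np.ndarray:
        return (self.gt < 0).any(axis=1)

    def allele_counts(self) -> np.ndarray:
        """Counts of each allele index among non-missing genotype calls."""
        called = self.gt[~self.missing_mask].ravel()
        n_alleles = 1 + len(self.alt)
        return np.bincount(called, minlength=n_alleles)


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter thresholds (defaults are the pipeline's study values)."""

    min_site_qual: float = 30.0
    min_gq: float = 30.0
    min_dp: float = 10.0
    indel_window: int = 10         # bp, inclusive, from the indel start
    max_missing: float = 0.5
    max_mean_depth: float = 88.0
    min_minor_count: int = 3       # minor allele must occur at least this often
    spacing_bp: int = 200


def read_vcf(path) -> tuple[list[VariantRecord], list[str]]:
    """Load a VCF into :class:`VariantRecord` objects via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    records = []
    n = len(samples)
    for v in vcf:
        gt = np.array([g[:2] for g in v.genotypes], dtype=np.int16)
        gq_raw = v.format("GQ")
        dp_raw = v.format("DP")
        gq = (np.full(n, np.inf) if gq_raw is None
              else np.asarray(gq_raw, dtype=float).reshape(n))
        dp = (np.full(n, np.inf) if dp_raw is None
              else np.asarray(dp_raw, dtype=float).reshape(n))
        records.append(VariantRecord(
            chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=tuple(v.ALT),
            qual=float(v.QUAL) if v.QUAL is not None else 0.0,
            gt=gt, gq=gq, dp=dp, id=v.ID or ".",
        ))
    return records, samples


def _mask_genotypes(rec: VariantRecord, thr: FilterThresholds) -> VariantRecord:
    """Set genotypes with low quality or depth to missing (per-genotype filter)."""
    bad = (rec.gq < thr.min_gq) | (rec.dp < thr.min_dp)
    if not bad.any():
        return rec
    gt = rec.gt.copy()
    gt[bad] = MISSING
    return replace(rec, gt=gt)


def filter_variants(
    records: list[VariantRecord],
    thresholds: FilterThresholds | None = None,
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Apply the hard filters in order; return retained records and rule counts.

    Order: site quality; genotype-level GQ/DP masking (not a site drop);
    indels; sites within ``indel_window`` bp of an indel start; multiallelic;
    monomorphic (after masking); > ``max_missing`` missing genotypes; mean
    genotype depth over called samples above ``max_mean_depth``; minor allele
    count below ``min_minor_count``; thinning to one site per ``spacing_bp``
    window keeping the first by position.  Input must be position-sorted.
    """
    thr = thresholds or FilterThresholds()
    keys = list(zip([r.chrom for r in records], [r.pos for r in records]))
    if keys != sorted(keys):
        raise ValueError("records must be sorted by (chromosome, position)")
    counts = {rule: 0 for rule in RULE_ORDER}
    indel_pos: dict[str, list[int]] = {}
    for rec in records:
        if rec.is_indel:
            indel_pos.setdefault(rec.chrom, []).append(rec.pos)

    retained: list[VariantRecord] = []
    last_kept: dict[str, int] = {}
    for rec in records:
        if rec.qual < thr.min_site_qual:
            counts["site_quality"] += 1
            continue
        rec = _mask_genotypes(rec, thr)
        if rec.is_indel:
            counts["indel"] += 1
            continue
        near = any(
            p != rec.pos and abs(p - rec.pos) <= thr.indel_window
            for p in indel_pos.get(rec.chrom, ())
        )
        if near:
            counts["near_indel"] += 1
            continue
        if len(rec.alt) != 1:
            counts["multiallelic"] += 1
            continue
        ac = rec.allele_counts()
        if (ac > 0).sum() < 2:
            counts["monomorphic"] += 1
            continue
        if rec.missing_mask.mean() > thr.max_missing:
            counts["missingness"] += 1
            continue
        called = ~rec.missing_mask
        if called.any() and rec.dp[called].mean() > thr.max_mean_depth:
            counts["mean_depth"] += 1
            continue
        if ac[ac > 0].min() < thr.min_minor_count:
            counts["mac"] += 1
            continue
        prev = last_kept.get(rec.chrom)
        if prev is not None and rec.pos - prev < thr.spacing_bp:
            counts["spacing"] += 1
            continue
        last_kept[rec.chrom] = rec.pos
        retained.append(rec)
    return retained, counts


def filter_individuals(
    records: list[VariantRecord],
    samples: list[str],
    min_mean_depth: float = 20.0,
    max_missing: float = 0.5,
) -> tuple[list[str], pd.DataFrame]:
    """Drop samples with mean depth below the bound or too much missing data.

    Returns the retained sample names and a per-sample statistics table
    (mean depth over all sites, missing-genotype fraction, kept flag).
    """
    if not records:
        raise ValueError("no records to assess individuals on")
    dp = np.stack([r.dp for r in records])             # (sites, samples)
    miss = np.stack([r.missing_mask for r in records])
    mean_depth = dp.mean(axis=0)
    missing_frac = miss.mean(axis=0)
    kept = (mean_depth >= min_mean_depth) & (missing_frac <= max_missing)
    stats = pd.DataFrame({
        "mean_depth": mean_depth,
        "missing_frac": missing_frac,
        "kept": kept,
    }, index=pd.Index(samples, name="sample"))
    return [s for s, k in zip(samples, kept) if k], stats


def find_reciprocally_fixed(
    records: list[VariantRecord],
    samples: list[str],
    panel_a: list[str],
    panel_b: list[str],
    max_missing_a: int = 3,
    max_missing_b: int = 2,
) -> pd.DataFrame:
    """Select markers reciprocally fixed between the two parental panels.

    A site is kept when all non-missing panel-A genotypes are homozygous for
    one allele, all non-missing panel-B genotypes are homozygous for the
    other, and the panels have at most ``max_missing_a`` / ``max_missing_b``
    missing genotypes.  Returns a marker table indexed by record order with
    the allele index carried by parent A.
    """
    if set(panel_a) & set(panel_b):
        raise ValueError("parental panels must be disjoint")
    idx = {s: i for i, s in enumerate(samples)}
    ia = [idx[s] for s in panel_a]
    ib = [idx[s] for s in panel_b]

    rows = []
    for ri, rec in enumerate(records):
        ga, gb = rec.gt[ia], rec.gt[ib]
        miss_a = (ga < 0).any(axis=1)
        miss_b = (gb < 0).any(axis=1)
        if miss_a.sum() > max_missing_a or miss_b.sum() > max_missing_b:
            continue
        ga, gb = ga[~miss_a], gb[~miss_b]
        if len(ga) == 0 or len(gb) == 0:
            continue
        hom_a = (ga[:, 0] == ga[:, 1]).all() and len(np.unique(ga)) == 1
        hom_b = (gb[:, 0] == gb[:, 1]).all() and len(np.unique(gb)) == 1
        if not (hom_a and hom_b):
            continue
        allele_a, allele_b = int(ga[0, 0]), int(gb[0, 0])
        if allele_a == allele_b:
            continue
        rows.append({"record_index": ri, "marker": f"{rec.chrom}_{rec.pos}",
                     "chrom": rec.chrom, "pos": rec.pos, "a_allele": allele_a})
    return pd.DataFrame(rows, columns=["record_index", "marker", "chrom", "pos",
                                       "a_allele"]).set_index("marker")


@dataclass
class F2GenotypeMatrix:
    """F2 genotype codes (0=AA, 1=AB, 2=BB, -1 missing) with marker metadata."""

    codes: pd.DataFrame            # individuals x markers, int8
    markers: pd.DataFrame          # indexed by marker: chrom, pos

    def __post_init__(self):
        allowed = {-1, 0, 1, 2}
        present = set(np.unique(self.codes.to_numpy()))
        if not present <= allowed:
            raise ValueError(f"illegal genotype codes: {sorted(present - allowed)}")
        if self.markers.index.duplicated().any():
            raise ValueError("duplicate marker names in metadata")


def recode_f2(
    records: list[VariantRecord],
    marker_table: pd.DataFrame,
    samples: list[str],
    f2_samples: list[str],
) -> F2GenotypeMatrix:
    """Recode F2 genotypes at reciprocally fixed markers to AA/AB/BB.

    The code counts parent-A alleles: two A alleles -> AA (0), one -> AB (1),
    none -> BB (2); missing genotypes stay missing.
    """
    idx = {s: i for i, s in enumerate(samples)}
    f2_idx = [idx[s] for s in f2_samples]
    cols = {}
    for marker, row in marker_table.iterrows():
        rec = records[int(row["record_index"])]
        gt = rec.gt[f2_idx]
        miss = (gt < 0).any(axis=1)
        n_a = (gt == int(row["a_allele"])).sum(axis=1)
        code = (2 - n_a).astype(np.int8)
        code[miss] = MISSING
        cols[marker] = code
    codes = pd.DataFrame(cols, index=pd.Index(f2_samples, name="individual"),
                         dtype=np.int8)
    meta = marker_table[["chrom", "pos"]].copy()
    return F2GenotypeMatrix(codes=codes, markers=meta)
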