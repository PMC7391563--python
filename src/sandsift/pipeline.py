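"""End-to-end orchestration of the three analysis arms on synthetic data.

The pipeline mirrors the study's structure: (1) behavioural trials scored
into strike counts and sifting efficiency, then transgression thresholds and
permutation comparisons of class means; (2) landmark shapes through jaw
standardisation, Procrustes superimposition, allometry removal and PCA, then
per-axis transgression; (3) a simulated VCF filtered to reciprocally fixed
markers, grouped into a linkage map, and scanned for QTL with permutation
thresholds, credible intervals and PVE.  Every stage draws its seed from one
master seed, and the run manifest records parameters and derived seeds so a
run is exactly reproducible.
"""

from __future__ import annotations

import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, behavior, genotypes, linkmap, morphshape, qtlscan, simcross
from . import transgression as tg

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "behavior": {
        "n_males": {"CAL": 8, "TAE": 9, "F2": 25},
        "trials_per_male": 3,
        "threshold": 80.0,
        "scrape_mode": "complement",
        "n_perm": 2000,
        "image": {"width": 120, "height": 90},
    },
    "morph": {
        "n_per_class": {"CAL": 26, "TAE": 24, "F2": 80},
        "noise_sd": 0.01,
        "slide": True,
        "n_axes": 6,
    },
    "qtl": {
        "n_chr": 4,
        "length_cM": 60.0,
        "markers_per_chr": 7,
        "n_f2": 113,
        "step": 1.0,
        "error_prob": 0.05,
        "n_perm": 100,
        "qtl": {"chrom": "chr01", "pos_cM": 30.0, "additive": 0.8, "dominance": 0.0},
        "sigma_e": 1.0,
    },
    "stages": ["behavior", "morph", "qtl"],
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def _class_mean_shapes() -> dict[str, np.ndarray]:
    """Stylised 13-point head configurations for the three classes.

    A generic percomorph head outline; the two parental classes differ in
    epaxial depth and jaw length (the axes that differentiate the study
    species) and the F2 mean is intermediate.
    """
    base = np.array([
        [2.0, 2.2],    # 1 dorsal end of preoperculum
        [2.2, 0.4],    # 2 ventral bend of preoperculum
        [1.0, 0.6],    # 3 posterior hinge of lower jaw
        [0.1, 0.8],    # 4 anterior tip of lower jaw
        [1.3, 1.6],    # 5 anterior eye
        [1.9, 1.65],   # 6 posterior eye
        [1.6, 1.3],    # 7 ventral eye socket
        [0.2, 1.2],    # 10 snout tip
        [0.55, 1.75],  # 11 semilandmark
        [0.95, 2.2],   # 12
        [1.35, 2.55],  # 13
        [1.7, 2.8],    # 14
        [2.0, 3.0],    # 15 dorsal head margin
    ])
    cal = base.copy()
    cal[3] += [-0.08, 0.0]     # longer jaw
    cal[12] += [0.0, -0.15]    # shallower head
    tae = base.copy()
    tae[3] += [0.08, 0.0]
    tae[12] += [0.0, 0.15]
    f2 = (cal + tae) / 2.0
    return {"CAL": cal, "TAE": tae, "F2": f2}


def _run_behavior(cfg: dict, seed: int, outdir: Path, log: list[str]) -> None:
    rng = np.random.default_rng(seed)
    strike_rates = {"CAL": 8.0, "TAE": 5.0, "F2": 8.0}
    trials: list[behavior.TrialRecord] = []
    img_cfg = cfg["image"]
    for cls, count in cfg["n_males"].items():
        for i in range(count):
            ind = f"{cls}_M{i + 1:02d}"
            sl = float(rng.normal(90.0 if cls != "F2" else 100.0, 8.0))
            for t in range(1, cfg["trials_per_male"] + 1):
                strikes = int(rng.poisson(strike_rates[cls] * rng.lognormal(0, 0.6)))
                frac = min(strikes * abs(rng.normal(0.004, 0.002)), 0.6)
                spec = simcross.SimImageSpec(
                    width=img_cfg["width"], height=img_cfg["height"],
                    turned_fraction=frac, seed=int(rng.integers(2 ** 31)))
                before, after, _ = simcross.simulate_sand_images(spec)
                scrape = float(rng.choice(behavior.SCRAPE_EFFECTS, p=[0.7, 0.1, 0.1, 0.05, 0.03, 0.02]))
                trials.append(behavior.TrialRecord(
                    individual=ind, cls=cls, sex="M", trial=t, strikes=strikes,
                    scrape_effect=scrape,
                    hiding=int(rng.integers(1, 6)) if strikes == 0 else int(rng.integers(1, 4)),
                    interaction=int(rng.integers(1, 4)),
                    area_before_pct=behavior.quantify_sand_area(before, cfg["threshold"]),
                    area_after_pct=behavior.quantify_sand_area(after, cfg["threshold"]),
                    sl_mm=sl))
    valid, excluded = behavior.exclude_trials(trials)
    log.append(f"behavior: {len(excluded)} of {len(trials)} trials excluded "
               "(no strikes with hiding/interaction score 5)")
    summary = behavior.aggregate_individual(valid, statistic="max",
                                            mode=cfg["scrape_mode"])
    summary.to_csv(outdir / "behavior_individuals.csv")

    rows, perm_rows = [], []
    for trait in ("strikes", "log10_efficiency"):
        sub = summary.dropna(subset=[trait])
        parents = {c: sub.loc[sub["cls"] == c, trait].to_numpy() for c in ("CAL", "TAE")}
        thr = tg.thresholds(parents["CAL"], parents["TAE"])
        f2 = sub.loc[sub["cls"] == "F2", trait]
        table, counts = tg.classify(f2.to_numpy(), thr, ids=f2.index)
        rows.append({"trait": trait, "upper": thr.upper, "lower": thr.lower,
                     **counts, "n_f2": len(f2)})
        for a, b in (("F2", "CAL"), ("F2", "TAE"), ("TAE", "CAL")):
            xa = sub.loc[sub["cls"] == a, trait].to_numpy()
            xb = sub.loc[sub["cls"] == b, trait].to_numpy()
            p = tg.perm_test(xa, xb, n_perm=cfg["n_perm"], mode="monte_carlo",
                             seed=int(rng.integers(2 ** 31)))
            perm_rows.append({"trait": trait, "comparison": f"{a} vs {b}", "p": p})
    pd.DataFrame(rows).to_csv(outdir / "behavior_transgression.csv", index=False)
    pd.DataFrame(perm_rows).to_csv(outdir / "behavior_perm_tests.csv", index=False)


def _run_morph(cfg: dict, seed: int, outdir: Path, log: list[str]) -> None:
    rng = np.random.default_rng(seed)
    means = _class_mean_shapes()
    allometry = np.zeros((13, 2))
    allometry[12] = [0.0, 0.3]       # deeper heads in larger fish
    configs = simcross.simulate_landmarks(
        cfg["n_per_class"], means, allometry=allometry,
        noise_sd=cfg["noise_sd"], seed=int(rng.integers(2 ** 31)))
    configs = morphshape.standardize_jaw(configs)
    space = morphshape.gpa(configs, slide=cfg["slide"])
    log_sl = np.log10(space.meta["sl"].to_numpy(dtype=float))
    space, allo_report = morphshape.allometry_free(
        space, log_sl, n_perm=199, seed=int(rng.integers(2 ** 31)))
    log.append(f"morph: allometry F={allo_report['F']:.3f} "
               f"p={allo_report['p_perm']:.3f}")
    space = morphshape.shape_pca(space)
    scores = space.scores_frame().iloc[:, :cfg["n_axes"]]
    scores.to_csv(outdir / "shape_scores.csv")
    pd.DataFrame({
        "axis": [f"PC{i + 1}" for i in range(len(space.var_frac))],
        "variance_fraction": space.var_frac,
    }).to_csv(outdir / "shape_variance.csv", index=False)
    cls = space.meta["cls"]
    rows = []
    for ax in scores.columns:
        thr = tg.thresholds(scores.loc[cls == "CAL", ax], scores.loc[cls == "TAE", ax])
        _, counts = tg.classify(scores.loc[cls == "F2", ax].to_numpy(), thr)
        rows.append({"axis": ax, "upper": thr.upper, "lower": thr.lower, **counts})
    pd.DataFrame(rows).to_csv(outdir / "shape_transgression.csv", index=False)


def _run_qtl(cfg: dict, seed: int, outdir: Path, log: list[str],
             workdir: Path) -> None:
    rng = np.random.default_rng(seed)
    smap = simcross.simulate_map(cfg["n_chr"], cfg["length_cM"],
                                 cfg["markers_per_chr"],
                                 seed=int(rng.integers(2 ** 31)))
    f2 = simcross.simulate_f2(smap, cfg["n_f2"], seed=int(rng.integers(2 ** 31)))
    q = cfg["qtl"]
    arch = simcross.QtlArchitecture(
        qtl=(simcross.Qtl(q["chrom"], q["pos_cM"], q["additive"], q["dominance"]),),
        sigma_e=cfg["sigma_e"], label="overdominant" if q["additive"] == 0 else "null")
    phen = simcross.simulate_phenotypes(f2, smap, arch,
                                        seed=int(rng.integers(2 ** 31)))
    vcf_text = simcross.simulate_vcf(smap, f2, seed=int(rng.integers(2 ** 31)))
    vcf_path = workdir / "sim.vcf"
    vcf_path.write_text(vcf_text)
    records, samples = genotypes.read_vcf(vcf_path)
    records, counts = genotypes.filter_variants(records)
    log.append("genotypes: exclusions " + ", ".join(f"{k}={v}" for k, v in counts.items() if v))
    panel_a = [s for s in samples if s.startswith("CAL")]
    panel_b = [s for s in samples if s.startswith("TAE")]
    f2_samples = [s for s in samples if s.startswith("F2")]
    marker_table = genotypes.find_reciprocally_fixed(records, samples, panel_a, panel_b)
    matrix = genotypes.recode_f2(records, marker_table, samples, f2_samples)
    codes, qc_report = linkmap.qc_markers(matrix.codes)
    log.append(f"linkmap: QC dropped {len(qc_report)} markers/individuals")
    lod_table = linkmap.pairwise_independence_lod(codes)
    groups = linkmap.group_markers(lod_table, threshold=7.0)
    lmap = linkmap.build_map(groups, codes, order="given",
                             marker_meta=matrix.markers)
    lmap.to_frame().to_csv(outdir / "linkage_map.csv", index=False)
    summary = lmap.summary()
    log.append(f"linkmap: {summary['n_markers']} markers in {summary['n_groups']} groups, "
               f"mean {summary['mean_markers_per_group']:.2f} per group")

    grid = qtlscan.calc_genoprob(codes, lmap, step=cfg["step"],
                                 error_prob=cfg["error_prob"])
    y = phen.loc[phen["class"] == "F2", "value"].reindex(codes.index)
    curve = qtlscan.scan_em(grid, y)
    perms = qtlscan.perm_threshold(grid, y, n_perm=cfg["n_perm"],
                                   seed=int(rng.integers(2 ** 31)))
    peak = curve.peak()
    ci = qtlscan.bayes_interval(curve)
    curve.table.to_csv(outdir / "lod_curve.csv", index=False)
    qtl_row = pd.DataFrame([{
        "trait": "simulated", "marker_nearest": peak["marker"] or "(pseudomarker)",
        "LG": peak["group"], "cM": peak["pos_cM"],
        "CI_low_cM": ci["low_marker_cM"], "CI_high_cM": ci["high_marker_cM"],
        "CI_markers": f"{ci['low_marker']}-{ci['high_marker']}",
        "LOD": peak["lod"],
        "p_genomewide": perms.genomewide_p(curve.max_lod),
        "threshold_05": perms.thresholds[0.05],
        "threshold_10": perms.thresholds[0.10],
        "PVE": qtlscan.pve(curve.max_lod, curve.n),
        "n": curve.n,
    }])
    qtl_row.to_csv(outdir / "qtl_table.csv", index=False)


def run_pipeline(config: dict | None, outdir: str | Path, seed: int | None = None) -> dict:
    """Run the configured stages and write result tables plus a manifest.

    Returns the manifest dictionary (also written to ``manifest.yaml``).
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(cfg["seed"])
    stage_seeds = {name: int(child.generate_state(1)[0] % (2 ** 31))
                   for name, child in zip(("behavior", "morph", "qtl"),
                                          master.spawn(3))}
    log: list[str] = []
    if "behavior" in cfg["stages"]:
        _run_behavior(cfg["behavior"], stage_seeds["behavior"], outdir, log)
    if "morph" in cfg["stages"]:
        _run_morph(cfg["morph"], stage_seeds["morph"], outdir, log)
    if "qtl" in cfg["stages"]:
        _run_qtl(cfg["qtl"], stage_seeds["qtl"], outdir, log, outdir)
    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "config": cfg,
        "stage_seeds": stage_seeds,
        "log": log,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
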