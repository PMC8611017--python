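"""End-to-end orchestration: simulate/load -> call -> cluster -> tree ->
phase -> summarise -> copy-number phylogeny -> risk calls -> report.

Every stage writes its tables under the output directory and contributes to
a machine-readable ``results.json``.  All randomness derives from the
single master seed, and the results JSON contains no timestamps, so a rerun
with the same configuration is byte-identical.  A stage failure raises
:class:`StageError` naming the stage; tables written by earlier stages are
left in place for inspection.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clonetree, clustering, cnphylo, io as mio, phasing, scna, uhr, variants
from .errors import InvalidConfigError, MrevoError
from .synthetic import SimulationConfig, simulate_cohort, write_cohort

log = logging.getLogger("mrevo")


class StageError(MrevoError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All thresholds of the pipeline, with their documented defaults."""

    cohort_dir: str | None = None      # None -> simulate a cohort
    out_dir: str = "mrevo_out"
    seed: int = 0
    t_candidate: float = 0.10
    t_control: float = 0.05
    p_max: float = 0.001
    t_clonal: float = 0.10
    founding_cf: float = 0.90
    presence_cf: float = 0.05
    uhr_vaf: float = 0.05
    k_max: int = 20
    msai_p: float = 0.01
    min_snps: int = 10
    jackknife_replicates: int = 100
    jackknife_drop: float = 0.5
    min_informative_snvs: int = 5
    mycn_locus: tuple[str, int] = ("chr2", 24_000_000)
    biopsy_profile: str | None = None  # optional TSV with TMM indicators
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        for name in ("t_candidate", "t_control", "p_max", "t_clonal",
                     "founding_cf", "presence_cf", "uhr_vaf", "msai_p",
                     "jackknife_drop"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise InvalidConfigError(f"{name}={v} outside (0, 1)")
        if self.k_max < 1 or self.min_snps < 1 or self.jackknife_replicates < 1:
            raise InvalidConfigError("counts must be >= 1")
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        if isinstance(self.mycn_locus, list):
            self.mycn_locus = tuple(self.mycn_locus)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        d["mycn_locus"] = list(self.mycn_locus)
        return d

    def to_yaml(self, path) -> Path:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return Path(path)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


@dataclass
class Cohort:
    """Validated in-memory tables of one patient's multi-region data."""

    variants: pd.DataFrame
    normals: pd.DataFrame
    panel: pd.DataFrame
    snp_baf: pd.DataFrame
    segments: pd.DataFrame
    patient: str = "P01"

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.variants["sample"].unique())


def load_cohort(cohort_dir) -> Cohort:
    """Load and validate a cohort directory written by ``write_cohort``.

    On-disk 1-based coordinates are converted to internal 0-based half-open
    here and nowhere else; malformed rows raise with line numbers.
    """
    d = Path(cohort_dir)
    var = mio.read_variant_table(d / "variants.tsv")
    return Cohort(
        variants=var,
        normals=mio.read_variant_table(d / "normals.tsv"),
        panel=mio.read_variant_table(d / "panel.tsv"),
        snp_baf=mio.read_snp_baf(d / "snp_baf.tsv"),
        segments=mio.read_seg(d / "segments.seg"),
        patient=str(var["patient"].iloc[0]) if len(var) else "P01",
    )


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def _segment_lookup(segments: pd.DataFrame):
    """sample, chrom, pos -> (total_cn, is_diploid, purity) with fallback."""
    by_sample = {s: g for s, g in segments.groupby("sample")}
    purity = {s: float(g["purity"].iloc[0]) for s, g in by_sample.items()}

    def lookup(sample, chrom, pos):
        g = by_sample.get(sample)
        if g is not None:
            hit = g[(g["chrom"] == chrom) & (g["start"] <= pos)
                    & (g["end"] > pos)]
            if len(hit):
                r = hit.iloc[0]
                total = int(r["cn_major"] + r["cn_minor"])
                return total, bool(r["cn_major"] == 1 and r["cn_minor"] == 1), False
        return 2, True, True    # diploid assumed, flagged

    return lookup, purity


def call_somatic_stage(cohort: Cohort, config: PipelineConfig):
    """Fit the panel error model and call every site in every sample."""
    model = variants.fit_site_error_model(
        list(zip(cohort.panel["alt_count"], cohort.panel["depth"])))
    key_cols = ["chrom", "pos", "ref", "alt"]
    normal = cohort.normals.set_index(key_cols)
    rows = []
    for key, grp in cohort.variants.groupby(key_cols, sort=True):
        try:
            nr = normal.loc[key]
            if isinstance(nr, pd.DataFrame):
                nr = nr.iloc[0]
        except KeyError:
            continue
        for _, r in grp.iterrows():
            if r["depth"] <= 0 or nr["depth"] <= 0:
                continue
            call = variants.call_somatic_variant(
                (r["alt_count"], r["depth"]), (nr["alt_count"], nr["depth"]),
                model, t_candidate=config.t_candidate,
                t_control=config.t_control, p_max=config.p_max,
                site=f"{key[0]}:{key[1]}:{key[2]}>{key[3]}")
            rows.append((*key, r["sample"], r["alt_count"], r["depth"],
                         r.get("gene", ""), r.get("pathway", ""),
                         call.tumour_vaf, call.control_vaf, call.p_value,
                         call.status))
    calls = pd.DataFrame(rows, columns=[
        "chrom", "pos", "ref", "alt", "sample", "alt_count", "depth",
        "gene", "pathway", "vaf", "control_vaf", "p_value", "status"])
    somatic_sites = set(
        calls.loc[calls["status"] == "somatic",
                  ["chrom", "pos", "ref", "alt"]].itertuples(index=False))
    calls["site_somatic"] = [
        t in somatic_sites for t in
        calls[["chrom", "pos", "ref", "alt"]].itertuples(index=False)]
    return model, calls


def clonality_stage(calls: pd.DataFrame, segments: pd.DataFrame,
                    config: PipelineConfig, sample_ids):
    """Clonal / subclonal / subclonal-specific per somatic site."""
    lookup, seg_purity = _segment_lookup(segments)
    som = calls[calls["site_somatic"]]
    rows = []
    neutral_flags, alt_m, dep_m, ids = [], [], [], []
    for key, grp in som.groupby(["chrom", "pos", "ref", "alt"], sort=True):
        grp = grp.set_index("sample").reindex(sample_ids)
        vafs = (grp["alt_count"] / grp["depth"]).fillna(0.0).to_numpy()
        cns, neutral = [], True
        for s in sample_ids:
            total, is_dip, _ = lookup(s, key[0], key[1])
            cns.append(total)
            neutral &= is_dip
        purities = np.array([seg_purity.get(s, 0.6) for s in sample_ids])
        cl = variants.classify_clonality(
            vafs, purities, cns, t_clonal=config.t_clonal,
            variant_id=f"{key[0]}:{key[1]}:{key[2]}>{key[3]}")
        rows.append((*key, grp["gene"].dropna().iloc[0] if grp["gene"].notna().any() else "",
                     grp["pathway"].dropna().iloc[0] if grp["pathway"].notna().any() else "",
                     cl.category,
                     ";".join(s for s, p in zip(sample_ids, cl.presence) if p),
                     ";".join(f"{t:.4f}" for t in cl.thresholds)))
        neutral_flags.append(neutral)
        alt_m.append(grp["alt_count"].fillna(0).to_numpy())
        dep_m.append(grp["depth"].fillna(0).to_numpy())
        ids.append(rows[-1][0:4])
    clonality = pd.DataFrame(rows, columns=[
        "chrom", "pos", "ref", "alt", "gene", "pathway", "category",
        "present_in", "thresholds"])
    vaf_matrix = clustering.VafMatrix(
        alt=np.array(alt_m, dtype=int) if alt_m else np.zeros((0, len(sample_ids)), int),
        depth=np.array(dep_m, dtype=int) if dep_m else np.zeros((0, len(sample_ids)), int),
        neutral_mask=np.array(neutral_flags, dtype=bool),
        variant_ids=[f"{c}:{p}:{r}>{a}" for c, p, r, a in ids],
        sample_ids=list(sample_ids))
    return clonality, vaf_matrix


def clustering_stage(vaf_matrix: clustering.VafMatrix, seg_purity: dict,
                     config: PipelineConfig, seed):
    """Purity estimation and binomial-mixture model selection."""
    rng = np.random.default_rng(seed)
    neutral = vaf_matrix.neutral_mask
    alt_n = vaf_matrix.alt[neutral]
    dep_n = vaf_matrix.depth[neutral]
    purity = {}
    for j, s in enumerate(vaf_matrix.sample_ids):
        purity[s] = clustering.estimate_purity(
            alt_n[:, j], dep_n[:, j], seed=int(rng.integers(2**31)),
            fallback=seg_purity.get(s))
    model = clustering.select_model(alt_n, dep_n, k_max=config.k_max,
                                    seed=int(rng.integers(2**31)))
    rho = np.array([purity[s] for s in vaf_matrix.sample_ids])
    cf = model.cellular_fraction(rho)
    labels = np.full(len(vaf_matrix.alt), -1, dtype=int)
    labels[neutral] = model.labels
    # attach variants outside diploid segments to the nearest cluster
    attached = np.zeros(len(vaf_matrix.alt), dtype=bool)
    for i in np.flatnonzero(~neutral):
        v_vaf = np.where(vaf_matrix.depth[i] > 0,
                         vaf_matrix.alt[i] / np.maximum(vaf_matrix.depth[i], 1),
                         0.0)
        cf_var = np.clip(2.0 * v_vaf / rho, 0.0, 1.0)
        labels[i] = clustering.attach_non_neutral(model, cf, cf_var)
        attached[i] = True
    assignments = pd.DataFrame({
        "variant": vaf_matrix.variant_ids,
        "cluster": labels,
        "attached": attached,
    })
    return model, purity, cf, assignments


def clone_tree_stage(model, cf, assignments, vaf_matrix, config: PipelineConfig):
    """Build the clone tree unless the patient lacks informative SNVs."""
    with np.errstate(invalid="ignore"):
        v = np.where(vaf_matrix.depth > 0,
                     vaf_matrix.alt / np.maximum(vaf_matrix.depth, 1), 0.0)
    informative = int((np.median(v, axis=1) > 0).sum())
    if informative < config.min_informative_snvs:
        return clonetree.InsufficientSignal(
            n_informative=informative,
            threshold=config.min_informative_snvs)
    clusters = []
    for k in range(model.k):
        members = assignments.loc[assignments["cluster"] == k, "variant"]
        clusters.append(clonetree.VafCluster(
            id=k, cf=cf[k], n_snvs=len(members),
            snv_ids=tuple(members)))
    clusters = [c for c in clusters if c.n_snvs > 0]
    return clonetree.build_clone_tree(
        clusters, founding_threshold=config.founding_cf,
        presence_threshold=config.presence_cf,
        sample_ids=vaf_matrix.sample_ids)


def phasing_stage(cohort: Cohort, config: PipelineConfig):
    jseg = phasing.joint_segment(cohort.segments)
    phased = phasing.phase_haplotypes(jseg, cohort.snp_baf,
                                      min_snps=config.min_snps,
                                      p_threshold=config.msai_p)
    corrected = phasing.correct_cn_states(phased, p_threshold=config.msai_p)
    events = phasing.detect_msai(corrected, min_snps=config.min_snps,
                                 p_threshold=config.msai_p)
    return corrected, events


def cn_tree_stage(phased: phasing.PhasedSegments, config: PipelineConfig,
                  seed):
    profiles = {
        s: np.stack([phased.cn_a[:, j], phased.cn_b[:, j]], axis=1)
        for j, s in enumerate(phased.samples)}
    chrom_index = phased.segments["chrom"].to_numpy()
    tree = cnphylo.build_cn_tree(profiles, chrom_index)
    tree = cnphylo.reconstruct_ancestors(tree, profiles, chrom_index)
    if len(profiles) >= 3:
        tree.support = cnphylo.jackknife_support(
            profiles, chrom_index, n_replicates=config.jackknife_replicates,
            drop_fraction=config.jackknife_drop, seed=seed)
    return tree


def uhr_stage(cohort: Cohort, clonality_calls: pd.DataFrame,
              phased: phasing.PhasedSegments, config: PipelineConfig):
    """Assemble biopsy profiles (from a TSV or upstream stages) and classify."""
    indicators = {}
    if config.biopsy_profile:
        prof = pd.read_csv(config.biopsy_profile, sep="\t")
        for _, r in prof.iterrows():
            indicators[r["sample"]] = r.to_dict()
    chrom, pos = config.mycn_locus
    seg_hit = phased.segments[
        (phased.segments["chrom"] == chrom)
        & (phased.segments["start"] <= pos) & (phased.segments["end"] > pos)]
    somatic = cohort.variants.merge(
        clonality_calls[["chrom", "pos", "ref", "alt", "pathway"]],
        on=["chrom", "pos", "ref", "alt"], suffixes=("", "_called"))
    somatic["pathway"] = somatic["pathway_called"].where(
        somatic["pathway_called"].astype(bool), somatic["pathway"])
    calls = []
    for j, s in enumerate(phased.samples):
        ind = indicators.get(s, {})
        mycn = bool(ind.get("mycn_amplified", False))
        if not mycn and len(seg_hit):
            i = int(seg_hit.index[0])
            total = int(phased.cn_a[i, j] + phased.cn_b[i, j])
            mycn = uhr.mycn_amplified_from_cn(total, phased.ploidy[s])
        profile = uhr.BiopsyMolecularProfile(
            sample_id=s,
            tert_high=bool(ind.get("tert_high", False)),
            mycn_amplified=mycn,
            tert_rearranged=bool(ind.get("tert_rearranged", False)),
            alt_positive=bool(ind.get("alt_positive", False)),
            pathway_mutations=uhr.pathway_mutations_from_variants(somatic, s),
            timepoint=str(ind.get("timepoint", "")),
            missing_indicators=[] if ind else
            ["tert_high", "tert_rearranged", "alt_positive"])
        calls.append(uhr.classify_biopsy_uhr(profile, uhr_vaf=config.uhr_vaf))
    summary = uhr.patient_uhr_profile(calls, patient=cohort.patient)
    return calls, summary


# ---------------------------------------------------------------------------
# report + driver
# ---------------------------------------------------------------------------

def write_report(out: Path, sample_ids, clonality: pd.DataFrame,
                 scna_row, chrom_fractions, uhr_calls) -> dict:
    """Figure-ready tables: per-sample SNV clonality counts, a per-patient
    SCNA clonality row, chromosome-class fractions, and the UHR matrix."""
    counts = []
    for s in sample_ids:
        present = clonality[clonality["present_in"].str.split(";").map(
            lambda xs, s=s: s in xs)]
        row = {"sample": s, "n_snvs": len(present)}
        for cat in ("clonal", "subclonal", "subclonal_specific"):
            row[cat] = int((present["category"] == cat).sum())
        counts.append(row)
    snv_counts = pd.DataFrame(counts)
    snv_counts.to_csv(out / "snv_clonality_counts.tsv", sep="\t", index=False)
    pd.DataFrame([scna_row]).to_csv(out / "scna_clonality_summary.tsv",
                                    sep="\t", index=False,
                                    float_format="%.4f")
    pd.DataFrame([chrom_fractions]).to_csv(out / "chromosome_fractions.tsv",
                                           sep="\t", index=False,
                                           float_format="%.4f")
    uhr_df = pd.DataFrame([dataclasses.asdict(c) for c in uhr_calls])
    uhr_df.to_csv(out / "uhr_calls.tsv", sep="\t", index=False)
    return {"snv_clonality_counts": snv_counts.to_dict("records")}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the results dictionary (also on disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    stage_seed = {name: int(s.generate_state(1)[0] % (2**31))
                  for name, s in zip(
                      ["simulate", "cluster", "cntree"], ss.spawn(3))}
    results: dict = {"config": config.to_dict(), "stage_seeds": stage_seed,
                     "warnings": []}

    def run_stage(name, fn, *args, **kwargs):
        log.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as e:
            raise StageError(name, e) from e

    if config.cohort_dir:
        cohort = run_stage("load", load_cohort, config.cohort_dir)
    else:
        sim = dataclasses.replace(config.simulation,
                                  seed=stage_seed["simulate"])
        truth, tables = run_stage("simulate", simulate_cohort, sim)
        write_cohort(truth, tables, out / "cohort", sim)
        cohort = run_stage("load", load_cohort, out / "cohort")
        results["simulated"] = True

    model, calls = run_stage("call", call_somatic_stage, cohort, config)
    calls.to_csv(out / "somatic_calls.tsv", sep="\t", index=False,
                 float_format="%.6g")
    results["error_model"] = {"alpha": model.alpha, "beta": model.beta,
                              "mean": model.mean,
                              "overdispersed": model.overdispersed}
    results["n_somatic_sites"] = int(
        calls.loc[calls["site_somatic"],
                  ["chrom", "pos", "ref", "alt"]].drop_duplicates().shape[0])

    sample_ids = cohort.sample_ids
    clonality, vaf_matrix = run_stage("clonality", clonality_stage,
                                      calls, cohort.segments, config,
                                      sample_ids)
    clonality.to_csv(out / "clonality.tsv", sep="\t", index=False)
    results["snv_clonality"] = {
        cat: int((clonality["category"] == cat).sum())
        for cat in ("clonal", "subclonal", "subclonal_specific", "absent")}

    _, seg_purity = _segment_lookup(cohort.segments)
    if len(vaf_matrix.alt):
        mixture, purity, cf, assignments = run_stage(
            "cluster", clustering_stage, vaf_matrix, seg_purity, config,
            stage_seed["cluster"])
        assignments.to_csv(out / "clusters.tsv", sep="\t", index=False)
        results["purity"] = {s: round(float(p), 4) for s, p in purity.items()}
        results["mixture"] = {"k": mixture.k,
                              "bic": round(mixture.bic, 3),
                              "converged": bool(mixture.converged)}
        tree_result = run_stage("tree", clone_tree_stage, mixture, cf,
                                assignments, vaf_matrix, config)
    else:
        tree_result = clonetree.InsufficientSignal(0,
                                                   config.min_informative_snvs)
    if isinstance(tree_result, clonetree.InsufficientSignal):
        results["clone_tree"] = {"status": "insufficient_signal",
                                 "n_informative": tree_result.n_informative}
    else:
        (out / "clone_tree.nwk").write_text(
            clonetree.tree_to_newick(tree_result) + "\n")
        clonetree.edge_list(tree_result).to_csv(out / "clone_tree_edges.tsv",
                                                sep="\t", index=False)
        (out / "clone_tree.dot").write_text(clonetree.tree_to_dot(tree_result))
        pd.DataFrame([{"sample": s, "clone": c} for s, c in
                      tree_result.sample_annotation.items()]).to_csv(
            out / "sample_annotation.tsv", sep="\t", index=False)
        results["clone_tree"] = {
            "status": "ok", "n_clones": len(tree_result.clones),
            "intermixed_samples": sorted(tree_result.intermixed_samples)}
        results["warnings"].extend(tree_result.warnings)

    phased, msai_events = run_stage("phase", phasing_stage, cohort, config)
    phased_df = phased.segments.copy()
    for j, s in enumerate(phased.samples):
        phased_df[f"cnA_{s}"] = phased.cn_a[:, j]
        phased_df[f"cnB_{s}"] = phased.cn_b[:, j]
    phased_df["phased"] = phased.phased
    phased_df["n_snps"] = phased.n_snps
    phased_df.to_csv(out / "phased_segments.tsv", sep="\t", index=False)
    pd.DataFrame([dataclasses.asdict(e) for e in msai_events]).to_csv(
        out / "msai_events.tsv", sep="\t", index=False)
    results["n_msai_events"] = len(msai_events)

    events = run_stage("summarize", scna.classify_segment_events, phased)
    events.to_csv(out / "segment_events.tsv", sep="\t", index=False)
    scna_row = scna.stratify_scna_clonality(events, patient=cohort.patient)
    bands = scna.make_uniform_cytobands()
    band_events = scna.aggregate_cytobands(events, bands)
    band_events.to_csv(out / "cytoband_events.tsv", sep="\t", index=False,
                       float_format="%.4f")
    chrom_table, chrom_fractions = scna.classify_chromosomes(
        events, patient=cohort.patient)
    chrom_table.to_csv(out / "chromosome_classes.tsv", sep="\t", index=False)
    results["scna_clonality"] = {k: (round(float(v), 4)
                                     if isinstance(v, float) else v)
                                 for k, v in scna_row.items()}
    results["chromosome_fractions"] = {k: round(float(v), 4)
                                       for k, v in chrom_fractions.items()}

    cn_tree = run_stage("cntree", cn_tree_stage, phased, config,
                        stage_seed["cntree"])
    (out / "cn_tree.nwk").write_text(cn_tree.newick() + "\n")
    cn_tree.distance_matrix.to_csv(out / "cn_distances.tsv", sep="\t",
                                   float_format="%.1f")
    results["cn_tree"] = {
        "clades": sorted(",".join(sorted(c)) for c in cn_tree.clades()),
        "support": {",".join(sorted(c)): v
                    for c, v in sorted(cn_tree.support.items(),
                                       key=lambda kv: sorted(kv[0]))},
        "infeasible_pairs": [list(p) for p in cn_tree.infeasible_pairs]}

    uhr_calls, uhr_summary = run_stage("uhr", uhr_stage, cohort, clonality,
                                       phased, config)
    results["uhr"] = uhr_summary

    run_stage("report", write_report, out, sample_ids, clonality, scna_row,
              chrom_fractions, uhr_calls)
    (out / "results.json").write_text(
        json.dumps(results, indent=2, sort_keys=True, default=str) + "\n")
    return results
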