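"""Synthetic multi-region tumour cohorts with known ground truth.

Generates everything the downstream stages consume — a planted clone tree,
per-sample cancer-cell fractions (CCFs), haplotype-specific copy-number
profiles with optional mirrored subclonal allelic imbalance (MSAI), somatic
SNVs with binomially sampled read counts at a chosen mean coverage, germline
heterozygous-SNP B-allele counts, matched-normal and panel-of-normals tables,
and per-sample allele-specific segment tables.

The synthetic genome has 22 equal-length autosomes; coordinates are 0-based
half-open internally and converted to on-disk conventions only by
:mod:`mrevo.io`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidInputError

N_AUTOSOMES = 22
CHROM_LENGTH = 100_000_000


@dataclass
class SimulationConfig:
    """Parameters of one synthetic multi-region cohort.

    Coverage defaults mirror a typical multi-region study design: ~350x
    whole-exome coverage and ultra-deep ~2500x targeted re-sequencing.
    ``purity_range`` defaults to (0.6, 0.95), reflecting the common practice
    of macrodissecting regions with >60% tumour cell content.
    """

    n_samples: int = 3
    n_clones: int = 5
    n_trunk_snvs: int = 30
    n_branch_snvs_per_clone: int = 15
    purity_range: tuple[float, float] = (0.6, 0.95)
    mean_coverage_wes: float = 346.0
    mean_coverage_targeted: float = 2500.0
    n_segments: int = 44
    n_het_snps_per_segment: int = 20
    cn_event_rate: float = 1.0
    msai_probability: float = 0.05
    whole_chromosome_event_fraction: float = 0.3
    technical_error_rate: float = 0.002
    n_controls: int = 8
    pathway_snv_fraction: float = 0.05
    patient_id: str = "P01"
    seed: int = 0

    def __post_init__(self) -> None:
        self.purity_range = tuple(self.purity_range)
        for name in ("n_samples", "n_clones", "n_trunk_snvs",
                     "n_branch_snvs_per_clone", "n_segments",
                     "n_het_snps_per_segment", "n_controls"):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be >= 1")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise InvalidConfigError("purity_range must lie within (0, 1]")
        for name in ("msai_probability", "whole_chromosome_event_fraction",
                     "pathway_snv_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1]")
        if self.cn_event_rate < 0:
            raise InvalidConfigError("cn_event_rate must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["purity_range"] = list(self.purity_range)
        return d


@dataclass
class GroundTruth:
    """Planted truth of one cohort: tree, CCFs, SCNAs and SNV assignments."""

    parent: np.ndarray                 # parent[k] of clone k; root has -1
    ccf: np.ndarray                    # clones x samples, in [0, 1]
    purity: np.ndarray                 # per sample, in (0, 1]
    sample_ids: list[str]
    segments: pd.DataFrame             # chrom, start, end (0-based half-open)
    haplotype_profiles: np.ndarray     # clones x segments x 2, int copies
    msai_truth: set[int]               # joint-segment indices with planted MSAI
    chromosome_event_type: dict[str, str]   # chrom -> none|whole|segmental
    snvs: pd.DataFrame = field(default_factory=pd.DataFrame)
    cn_events: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_clones(self) -> int:
        return len(self.parent)

    @property
    def n_samples(self) -> int:
        return self.ccf.shape[1]

    def dominant_clone(self, sample_index: int) -> int:
        return dominant_clone(self.parent, self.ccf[:, sample_index])


@dataclass
class CohortTables:
    """Read-count tables emitted by :func:`simulate_reads`."""

    variants: pd.DataFrame     # patient, sample, chrom, pos, ref, alt, alt_count, depth, gene, pathway
    normals: pd.DataFrame      # matched normal counts per SNV site
    panel: pd.DataFrame        # panel-of-normals counts per SNV site
    snp_baf: pd.DataFrame      # chrom, pos, sample, b_count, depth
    segments: pd.DataFrame     # sample, chrom, start, end, cn_major, cn_minor, purity, ploidy
    snp_truth: pd.DataFrame    # chrom, pos, segment, b_on_hap_a (planted phase)


# ---------------------------------------------------------------------------
# tree / CCF / copy-number evolution
# ---------------------------------------------------------------------------

def simulate_clone_tree(n_clones: int, seed) -> np.ndarray:
    """Sample a rooted clone tree by uniform attachment.

    Each new clone attaches to a uniformly chosen existing clone, which
    produces linear and branched hierarchies alike.  Returns the parent
    vector: ``parent[0] == -1`` marks the root (founding clone).
    """
    if n_clones < 1:
        raise InvalidConfigError("n_clones must be >= 1")
    rng = np.random.default_rng(seed)
    parent = np.full(n_clones, -1, dtype=int)
    for k in range(1, n_clones):
        parent[k] = rng.integers(0, k)
    return parent


def clade(parent: np.ndarray, k: int) -> list[int]:
    """Clone ``k`` and all of its descendants, in index order."""
    members = []
    for j in range(k, len(parent)):
        if j == k:
            members.append(j)
        else:
            a = j
            while a != -1:
                if a == k:
                    members.append(j)
                    break
                a = parent[a]
    return members


def is_ancestor(parent: np.ndarray, a: int, b: int) -> bool:
    """True when clone ``a`` is an ancestor of (or equal to) clone ``b``."""
    while b != -1:
        if b == a:
            return True
        b = parent[b]
    return False


def dominant_clone(parent: np.ndarray, ccf_col: np.ndarray) -> int:
    """Deepest clone carried by >= 50% of tumour cells in a sample."""
    children = [[] for _ in parent]
    for k, p in enumerate(parent):
        if p >= 0:
            children[p].append(k)
    node = 0
    while True:
        cand = [c for c in children[node] if ccf_col[c] >= 0.5]
        if not cand:
            return node
        node = max(cand, key=lambda c: (ccf_col[c], -c))


def validate_ccf(parent: np.ndarray, ccf: np.ndarray, tol: float = 1e-9) -> None:
    """Check lineage consistency: CCF(child) <= CCF(parent) per sample and
    sibling CCFs sum to at most the parent's."""
    children = {}
    for k, p in enumerate(parent):
        if p >= 0:
            children.setdefault(p, []).append(k)
            if np.any(ccf[k] > ccf[p] + tol):
                raise InvalidInputError(
                    f"lineage violation: clone {k} exceeds parent {p}")
    for p, kids in children.items():
        if np.any(ccf[kids].sum(axis=0) > ccf[p] + tol):
            raise InvalidInputError(
                f"sibling CCFs of clone {p} exceed the parent fraction")


def simulate_ccf_matrix(parent: np.ndarray, n_samples: int, seed, *,
                        min_gap: float = 0.0,
                        identifiable: bool = False,
                        private_prob: float = 0.35,
                        fixed: np.ndarray | None = None,
                        max_attempts: int = 500) -> np.ndarray:
    """Sample a clones x samples CCF matrix by per-sample stick-breaking.

    The root clone has CCF 1 in every sample.  Each internal clone's CCF is
    split among its children plus a retained share, so lineage consistency
    holds exactly.  Individual clones may be zeroed in a sample (together
    with their descendants), producing sample-private clones.

    ``fixed`` is the deterministic escape hatch: a user-planted matrix is
    validated for lineage consistency and returned unchanged.

    ``min_gap`` enforces that every pair of clones differs by at least that
    much CCF in at least one sample; ``identifiable`` additionally requires
    the design to be recoverable by the presence-pattern tree rules (so tree
    reconstruction benchmarks measure noise, not design degeneracy).
    """
    n_clones = len(parent)
    if fixed is not None:
        fixed = np.asarray(fixed, dtype=float)
        if fixed.shape != (n_clones, n_samples):
            raise InvalidInputError("fixed CCF matrix has the wrong shape")
        validate_ccf(parent, fixed)
        return fixed.copy()

    rng = np.random.default_rng(seed)
    children = [[] for _ in range(n_clones)]
    for k, p in enumerate(parent):
        if p >= 0:
            children[p].append(k)

    for _ in range(max_attempts):
        ccf = np.zeros((n_clones, n_samples))
        ccf[0] = 1.0
        for s in range(n_samples):
            for k in range(n_clones):
                kids = children[k]
                if not kids or ccf[k, s] == 0.0:
                    continue
                # children take most of the parent stick: subclone sweeps
                # typically replace the bulk of the parental population
                w = rng.dirichlet(np.append(np.ones(len(kids)), 0.5))
                for c, wc in zip(kids, w[:-1]):
                    ccf[c, s] = ccf[k, s] * wc
            for k in range(1, n_clones):
                if ccf[k, s] > 0 and rng.random() < private_prob:
                    for d in clade(parent, k):
                        ccf[d, s] = 0.0
        if np.any(ccf[1:].max(axis=1) == 0.0):
            continue    # a clone absent everywhere
        if min_gap > 0:
            gaps = np.abs(ccf[:, None, :] - ccf[None, :, :]).max(axis=2)
            iu = np.triu_indices(n_clones, 1)
            if gaps[iu].min() < min_gap:
                continue
        if identifiable and not _design_identifiable(parent, ccf):
            continue
        return ccf
    raise InvalidInputError(
        "could not generate a CCF design satisfying the constraints; "
        "lower min_gap or the clone count")


def _design_identifiable(parent: np.ndarray, ccf: np.ndarray) -> bool:
    """True when the presence-pattern tree rules recover ``parent`` from the
    noise-free CCF matrix (and no non-root clone would merge into the trunk).
    """
    from .clonetree import VafCluster, build_clone_tree, recovered_parent_vector

    if np.any(np.all(ccf[1:] > 0.85, axis=1)):
        return False    # would risk merging into the founding clone
    if np.any((ccf > 0.02) & (ccf < 0.08)):
        return False    # too close to the 5% presence cutoff to be stable
    clusters = [VafCluster(id=k, cf=ccf[k], n_snvs=1, snv_ids=(f"c{k}",))
                for k in range(len(parent))]
    try:
        result = build_clone_tree(clusters)
        rec = recovered_parent_vector(result, len(parent))
    except Exception:
        return False
    return rec is not None and np.array_equal(rec, parent)


def make_segments(n_segments: int) -> pd.DataFrame:
    """Tile a 22-autosome synthetic genome with ``n_segments`` segments.

    Segments are distributed round-robin across chromosomes; chromosomes may
    be left empty when ``n_segments < 22``.
    """
    per_chrom = np.zeros(N_AUTOSOMES, dtype=int)
    for i in range(n_segments):
        per_chrom[i % N_AUTOSOMES] += 1
    rows = []
    for c in range(N_AUTOSOMES):
        n = per_chrom[c]
        if n == 0:
            continue
        bounds = np.linspace(0, CHROM_LENGTH, n + 1).astype(int)
        for i in range(n):
            rows.append((f"chr{c + 1}", bounds[i], bounds[i + 1]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def simulate_cn_evolution(parent: np.ndarray, config: SimulationConfig, seed):
    """Plant copy-number events on the clone tree.

    Every clone's incoming branch (including the trunk of the root clone)
    receives a Poisson number of events with mean ``cn_event_rate``.  Events
    are +-1 changes of one haplotype over a contiguous segment run; whole-
    chromosome events span every segment of a chromosome; a minority of
    segmental gains escalate to focal amplification (copy number can exceed
    4).  Losses clamp at zero and a lost haplotype is never regained: gains
    skip segments where the haplotype has zero copies.

    With probability ``msai_probability`` per segment, a mirrored gain is
    planted: haplotype A gains in one clade and haplotype B in a disjoint
    clade, which is the ground truth for MSAI detection.

    Returns ``(profiles, msai_truth, chromosome_event_type, segments, events)``.
    """
    rng = np.random.default_rng(seed)
    segments = make_segments(config.n_segments)
    n_seg = len(segments)
    chroms = segments["chrom"].unique().tolist()
    seg_of_chrom = {c: np.flatnonzero(segments["chrom"].values == c)
                    for c in chroms}

    n_clones = len(parent)
    profiles = np.zeros((n_clones, n_seg, 2), dtype=int)
    chrom_kinds: dict[str, set] = {f"chr{i + 1}": set() for i in range(N_AUTOSOMES)}
    events = []

    for k in range(n_clones):
        profiles[k] = 1 if parent[k] < 0 else profiles[parent[k]]
        prof = profiles[k].copy()
        for _ in range(rng.poisson(config.cn_event_rate)):
            chrom = chroms[rng.integers(len(chroms))]
            idx = seg_of_chrom[chrom]
            whole = rng.random() < config.whole_chromosome_event_fraction
            if whole:
                run = idx
            else:
                # focal events: geometric run length (mean ~2 segments),
                # clipped at the chromosome end
                i0 = rng.integers(len(idx))
                ln = min(int(rng.geometric(0.5)), len(idx) - i0)
                run = idx[i0:i0 + ln]
            hap = int(rng.integers(2))
            gain = rng.random() < 0.5
            if gain:
                mag = int(rng.integers(3, 15)) if (not whole and rng.random() < 0.1) else 1
                sel = run[prof[run, hap] > 0]
                if sel.size == 0:
                    continue
                prof[sel, hap] += mag
            else:
                mag = 1
                sel = run[prof[run, hap] > 0]
                if sel.size == 0:
                    continue
                prof[sel, hap] -= 1
            chrom_kinds[chrom].add("whole" if whole else "segmental")
            events.append((k, chrom, int(run[0]), int(run[-1]), hap,
                           "gain" if gain else "loss", mag, whole))
        profiles[k] = prof

    # mirrored gains on disjoint clades
    msai_truth: set[int] = set()
    pairs = [(i, j) for i in range(1, n_clones) for j in range(1, n_clones)
             if i != j and not is_ancestor(parent, i, j)
             and not is_ancestor(parent, j, i)]
    if pairs and config.msai_probability > 0:
        for s in range(n_seg):
            if rng.random() >= config.msai_probability:
                continue
            i, j = pairs[rng.integers(len(pairs))]
            planted = False
            for hap, top in ((0, i), (1, j)):
                members = [m for m in clade(parent, top)
                           if profiles[m, s, hap] > 0]
                if not members:
                    continue
                for m in members:
                    profiles[m, s, hap] += 1
                planted = True
                events.append((top, segments.loc[s, "chrom"], s, s, hap,
                               "gain", 1, False))
            if planted:
                msai_truth.add(s)
                chrom_kinds[segments.loc[s, "chrom"]].add("segmental")

    chromosome_event_type = {}
    for c in (f"chr{i + 1}" for i in range(N_AUTOSOMES)):
        kinds = chrom_kinds[c]
        if not kinds:
            chromosome_event_type[c] = "none"
        elif kinds == {"whole"}:
            chromosome_event_type[c] = "whole"
        else:
            chromosome_event_type[c] = "segmental"

    events_df = pd.DataFrame(
        events, columns=["clone", "chrom", "seg_start", "seg_end",
                         "haplotype", "kind", "magnitude", "whole_chromosome"])
    return profiles, msai_truth, chromosome_event_type, segments, events_df


# ---------------------------------------------------------------------------
# SNV catalogue and read-count sampling
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def assign_snvs(parent: np.ndarray, segments: pd.DataFrame,
                config: SimulationConfig, seed) -> pd.DataFrame:
    """Place trunk and branch SNVs at random positions of the synthetic genome.

    Each SNV belongs to one clone, sits in one segment and on one haplotype.
    A small configurable fraction is annotated with a TP53 / RAS-MAPK pathway
    label so that risk stratification can be exercised downstream.
    """
    rng = np.random.default_rng(seed)
    rows = []
    counts = [config.n_trunk_snvs] + [config.n_branch_snvs_per_clone] * (len(parent) - 1)
    i = 0
    for k, n in enumerate(counts):
        for _ in range(n):
            seg = int(rng.integers(len(segments)))
            start, end = segments.loc[seg, ["start", "end"]]
            pos = int(rng.integers(start, end))
            ref, alt = rng.choice(4, size=2, replace=False)
            pathway = ""
            if rng.random() < config.pathway_snv_fraction:
                pathway = "TP53" if rng.random() < 0.5 else "RAS_MAPK"
            rows.append((f"snv{i:04d}", segments.loc[seg, "chrom"], pos,
                         _BASES[ref], _BASES[alt], f"GENE{i:04d}", pathway,
                         k, seg, int(rng.integers(2))))
            i += 1
    return pd.DataFrame(rows, columns=[
        "snv_id", "chrom", "pos", "ref", "alt", "gene", "pathway",
        "clone", "segment", "haplotype"])


def expected_snv_vaf(truth: GroundTruth, snv_row, sample_index: int) -> float:
    """Closed-form expected VAF of one SNV in one sample.

    Uses the standard mixture model: VAF = ccf * rho * m / (rho * C_t +
    2 (1 - rho)), with total copy number C_t and mutation multiplicity m taken
    from the sample's dominant clone (the copy-number state a bulk caller
    would see).  m is 1 unless the mutated haplotype was gained (or lost) in
    the dominant clone's lineage after the mutation arose.
    """
    s = sample_index
    rho = float(truth.purity[s])
    dom = truth.dominant_clone(s)
    seg = int(snv_row["segment"])
    c = int(snv_row["clone"])
    c_t = int(truth.haplotype_profiles[dom, seg].sum())
    if is_ancestor(truth.parent, c, dom):
        m = int(truth.haplotype_profiles[dom, seg, int(snv_row["haplotype"])])
    else:
        m = 1
    denom = rho * c_t + 2.0 * (1.0 - rho)
    if denom <= 0:
        return 0.0
    return float(np.clip(truth.ccf[c, s] * rho * m / denom, 0.0, 1.0))


def simulate_reads(truth: GroundTruth, config: SimulationConfig, seed, *,
                   platform: str = "wes") -> CohortTables:
    """Sample read counts for every table the pipeline consumes.

    Depths are Poisson around the platform's mean coverage; alt counts are
    binomial at the closed-form expected VAF; germline het-SNP B-allele
    counts are binomial at the haplotype-specific expected BAF of the
    sample's dominant clone mixed with normal cells; matched-normal and
    panel-of-normals alt counts are binomial at the technical error rate.
    """
    if platform not in ("wes", "targeted"):
        raise InvalidInputError("platform must be 'wes' or 'targeted'")
    cov = (config.mean_coverage_wes if platform == "wes"
           else config.mean_coverage_targeted)
    rng = np.random.default_rng(seed)
    snvs = truth.snvs
    n_v = len(snvs)
    samples = truth.sample_ids

    var_rows = []
    for s, sid in enumerate(samples):
        depths = rng.poisson(cov, n_v)
        for i in range(n_v):
            row = snvs.iloc[i]
            vaf = expected_snv_vaf(truth, row, s)
            alt = rng.binomial(depths[i], vaf) if depths[i] > 0 else 0
            var_rows.append((config.patient_id, sid, row["chrom"],
                             int(row["pos"]), row["ref"], row["alt"],
                             int(alt), int(depths[i]), row["gene"],
                             row["pathway"]))
    variants = pd.DataFrame(var_rows, columns=[
        "patient", "sample", "chrom", "pos", "ref", "alt",
        "alt_count", "depth", "gene", "pathway"])

    def _noise_table(sample_names):
        rows = []
        for sid in sample_names:
            depths = rng.poisson(cov, n_v)
            alts = rng.binomial(depths, config.technical_error_rate)
            for i in range(n_v):
                row = snvs.iloc[i]
                rows.append((config.patient_id, sid, row["chrom"],
                             int(row["pos"]), row["ref"], row["alt"],
                             int(alts[i]), int(depths[i])))
        return pd.DataFrame(rows, columns=[
            "patient", "sample", "chrom", "pos", "ref", "alt",
            "alt_count", "depth"])

    normals = _noise_table(["NORMAL"])
    panel = _noise_table([f"PON{j:02d}" for j in range(config.n_controls)])

    # germline het SNPs with a planted phase
    segs = truth.segments
    snp_rows, truth_rows, baf_rows = [], [], []
    dom = [truth.dominant_clone(s) for s in range(len(samples))]
    for seg in range(len(segs)):
        start, end = segs.loc[seg, ["start", "end"]]
        positions = np.linspace(start, end - 1, config.n_het_snps_per_segment,
                                dtype=int)
        positions = np.unique(positions)
        flips = rng.random(len(positions)) < 0.5   # B allele on haplotype A?
        for pos, on_a in zip(positions, flips):
            truth_rows.append((segs.loc[seg, "chrom"], int(pos), seg, bool(on_a)))
            for s, sid in enumerate(samples):
                rho = truth.purity[s]
                cn_a, cn_b = truth.haplotype_profiles[dom[s], seg]
                b_cn = cn_a if on_a else cn_b
                denom = rho * (cn_a + cn_b) + 2.0 * (1.0 - rho)
                baf = (rho * b_cn + (1.0 - rho)) / denom if denom > 0 else 0.0
                depth = int(rng.poisson(config.mean_coverage_wes))
                b = int(rng.binomial(depth, baf)) if depth > 0 else 0
                baf_rows.append((segs.loc[seg, "chrom"], int(pos), sid, b, depth))
    snp_baf = pd.DataFrame(baf_rows, columns=["chrom", "pos", "sample",
                                              "b_count", "depth"])
    snp_truth = pd.DataFrame(truth_rows, columns=["chrom", "pos", "segment",
                                                  "b_on_hap_a"])

    # per-sample allele-specific segment tables (adjacent equal states merged)
    seg_rows = []
    for s, sid in enumerate(samples):
        prof = truth.haplotype_profiles[dom[s]]
        lengths = (segs["end"] - segs["start"]).to_numpy()
        ploidy = float((prof.sum(axis=1) * lengths).sum() / lengths.sum())
        for chrom, idx in segs.groupby("chrom", sort=False).groups.items():
            idx = list(idx)
            run_start = 0
            for i in range(1, len(idx) + 1):
                boundary = (i == len(idx) or
                            tuple(sorted(prof[idx[i]])) != tuple(sorted(prof[idx[run_start]])))
                if boundary:
                    a, b = prof[idx[run_start]]
                    seg_rows.append((sid, chrom,
                                     int(segs.loc[idx[run_start], "start"]),
                                     int(segs.loc[idx[i - 1], "end"]),
                                     int(max(a, b)), int(min(a, b)),
                                     round(float(truth.purity[s]), 6),
                                     round(ploidy, 6)))
                    run_start = i
    segments = pd.DataFrame(seg_rows, columns=[
        "sample", "chrom", "start", "end", "cn_major", "cn_minor",
        "purity", "ploidy"])

    return CohortTables(variants=variants, normals=normals, panel=panel,
                        snp_baf=snp_baf, segments=segments,
                        snp_truth=snp_truth)


def simulate_cohort(config: SimulationConfig, *,
                    parent_fixed: np.ndarray | None = None,
                    ccf_fixed: np.ndarray | None = None,
                    min_gap: float = 0.0,
                    identifiable: bool = False,
                    platform: str = "wes") -> tuple[GroundTruth, CohortTables]:
    """End-to-end generation: tree -> CCFs -> SCNAs -> SNVs -> read counts.

    All randomness is derived from ``config.seed`` through independent
    streams, so reruns with the same configuration are fully deterministic.
    ``parent_fixed`` / ``ccf_fixed`` plant a user-chosen tree and CCF design
    for deterministic studies.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    if parent_fixed is not None:
        parent = np.asarray(parent_fixed, dtype=int)
        if len(parent) != config.n_clones or parent[0] != -1:
            raise InvalidInputError("parent_fixed inconsistent with config")
    else:
        parent = simulate_clone_tree(config.n_clones, seeds[0])
    ccf = simulate_ccf_matrix(parent, config.n_samples, seeds[1],
                              min_gap=min_gap, identifiable=identifiable,
                              fixed=ccf_fixed)
    profiles, msai, chrom_type, segments, events = simulate_cn_evolution(
        parent, config, seeds[2])
    purity = np.random.default_rng(seeds[3]).uniform(
        config.purity_range[0], config.purity_range[1], config.n_samples)
    sample_ids = [f"S{j + 1:02d}" for j in range(config.n_samples)]
    truth = GroundTruth(parent=parent, ccf=ccf, purity=purity,
                        sample_ids=sample_ids, segments=segments,
                        haplotype_profiles=profiles, msai_truth=msai,
                        chromosome_event_type=chrom_type, cn_events=events)
    truth.snvs = assign_snvs(parent, segments, config, seeds[4])
    tables = simulate_reads(truth, config, seeds[5], platform=platform)
    return truth, tables


def write_cohort(truth: GroundTruth, tables: CohortTables, out_dir,
                 config: SimulationConfig | None = None) -> dict[str, Path]:
    """Write every cohort table plus ground truth and a JSON manifest.

    On-disk conventions: variant and SNP positions 1-based; segment intervals
    1-based inclusive (SEG convention).  Rerunning with the same config
    reproduces byte-identical files.
    """
    from . import io as mio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["variants"] = mio.write_variant_table(tables.variants, out / "variants.tsv")
    paths["normals"] = mio.write_variant_table(tables.normals, out / "normals.tsv")
    paths["panel"] = mio.write_variant_table(tables.panel, out / "panel.tsv")
    paths["snp_baf"] = mio.write_snp_baf(tables.snp_baf, out / "snp_baf.tsv")
    paths["segments"] = mio.write_seg(tables.segments, out / "segments.seg")

    gt = out / "ground_truth"
    gt.mkdir(exist_ok=True)
    pd.DataFrame({"clone": range(truth.n_clones), "parent": truth.parent}
                 ).to_csv(gt / "clone_tree.tsv", sep="\t", index=False)
    ccf = pd.DataFrame(truth.ccf, columns=truth.sample_ids)
    ccf.insert(0, "clone", range(truth.n_clones))
    ccf.to_csv(gt / "ccf.tsv", sep="\t", index=False, float_format="%.6f")
    truth.snvs.to_csv(gt / "snvs.tsv", sep="\t", index=False)
    tables.snp_truth.to_csv(gt / "snp_phase.tsv", sep="\t", index=False)
    prof = []
    for k in range(truth.n_clones):
        for s in range(len(truth.segments)):
            prof.append((k, s, truth.haplotype_profiles[k, s, 0],
                         truth.haplotype_profiles[k, s, 1]))
    pd.DataFrame(prof, columns=["clone", "segment", "cn_a", "cn_b"]
                 ).to_csv(gt / "haplotype_profiles.tsv", sep="\t", index=False)
    manifest = {
        "config": config.to_dict() if config is not None else None,
        "samples": truth.sample_ids,
        "purity": [round(float(p), 6) for p in truth.purity],
        "msai_segments": sorted(truth.msai_truth),
        "chromosome_event_type": truth.chromosome_event_type,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    paths["manifest"] = out / "manifest.json"
    return paths
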