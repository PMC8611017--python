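"""Joint segmentation, multi-region haplotype phasing and MSAI detection.

Per-sample allele-specific copy-number segments (from any caller) are first
combined into one joint consistent segmentation per patient: the breakpoint
union across samples, with each sample's copy-number states carried onto
the refined intervals and runs that are identical in every sample merged
back.

Each joint segment with enough germline heterozygous SNPs is then phased
across samples: a reference sample with significant allelic imbalance
anchors the phase — SNP B-alleles with BAF > 0.5 in the reference are
assigned to the amplified haplotype (called A) — and every sample's pooled
haplotype-A allele fraction is computed on that fixed phase.  Significant
imbalance in opposite directions in different samples on the same segment
is a mirrored subclonal allelic imbalance (MSAI) event: the hallmark of
parallel copy-number evolution from the two parental chromosomes.

Significance testing: imbalance within a single sample (needed to pick the
reference) cannot pool raw B-counts because the B-allele label of each SNP
is arbitrary; instead a folded statistic sum(max(b, n-b)) is compared with
its exact null moments under BAF 0.5 (normal approximation across SNPs).
Once the phase is anchored by the reference, every other sample gets an
exact binomial test of its pooled haplotype-A counts against 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError

MIN_SNPS = 10
P_PHASE = 0.01


@dataclass
class JointSegmentation:
    """Breakpoint-union segmentation shared by all samples of a patient."""

    segments: pd.DataFrame          # chrom, start, end (0-based half-open)
    samples: list[str]
    cn_major: np.ndarray            # n_seg x n_samples
    cn_minor: np.ndarray
    purity: dict[str, float]
    ploidy: dict[str, float]

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def lengths(self) -> np.ndarray:
        return (self.segments["end"] - self.segments["start"]).to_numpy()


@dataclass
class PhasedSegments(JointSegmentation):
    """Joint segmentation plus per-sample phased haplotype copy numbers."""

    cn_a: np.ndarray = None         # n_seg x n_samples (valid where phased)
    cn_b: np.ndarray = None
    phased: np.ndarray = None       # n_seg bool
    ref_sample: np.ndarray = None   # n_seg int, -1 when unphased
    baf_a: np.ndarray = None        # pooled haplotype-A fraction, NaN w/o SNPs
    p_value: np.ndarray = None      # per segment x sample imbalance p
    direction: np.ndarray = None    # 'A' / 'B' / ''
    n_snps: np.ndarray = None       # informative SNPs per segment
    snp_phase: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class MsaiEvent:
    """A joint segment with significant imbalance on opposite haplotypes."""

    segment_index: int
    chrom: str
    start: int
    end: int
    samples_a: tuple
    samples_b: tuple
    baf_a: dict
    p_values: dict
    n_snps: int


# ---------------------------------------------------------------------------
# joint consistent segmentation
# ---------------------------------------------------------------------------

def joint_segment(seg_table: pd.DataFrame) -> JointSegmentation:
    """Combine per-sample segmentations into the breakpoint union.

    ``seg_table`` is long-format with columns sample, chrom, start, end,
    cn_major, cn_minor, purity, ploidy (0-based half-open coordinates).
    Overlapping segments within one sample are an error; refined intervals
    not covered by every sample are dropped with a warning; adjacent
    intervals with identical states in all samples are merged back.
    """
    req = {"sample", "chrom", "start", "end", "cn_major", "cn_minor"}
    missing = req - set(seg_table.columns)
    if missing:
        raise InvalidInputError(f"segment table misses columns {sorted(missing)}")
    samples = sorted(seg_table["sample"].unique())
    for (sid, chrom), grp in seg_table.groupby(["sample", "chrom"]):
        g = grp.sort_values("start")
        if (g["end"].to_numpy()[:-1] > g["start"].to_numpy()[1:]).any():
            raise InvalidInputError(
                f"overlapping segments for sample {sid} on {chrom}")

    purity = {s: float(seg_table.loc[seg_table["sample"] == s, "purity"].iloc[0])
              if "purity" in seg_table else 1.0 for s in samples}
    ploidy = {s: float(seg_table.loc[seg_table["sample"] == s, "ploidy"].iloc[0])
              if "ploidy" in seg_table else 2.0 for s in samples}

    rows, major, minor = [], [], []
    dropped = 0
    chrom_order = list(dict.fromkeys(seg_table["chrom"]))
    for chrom in chrom_order:
        sub = seg_table[seg_table["chrom"] == chrom]
        bps = np.unique(np.concatenate([sub["start"].to_numpy(),
                                        sub["end"].to_numpy()]))
        for lo, hi in zip(bps[:-1], bps[1:]):
            states = []
            for s in samples:
                g = sub[(sub["sample"] == s) & (sub["start"] <= lo)
                        & (sub["end"] >= hi)]
                if len(g) != 1:
                    states = None
                    break
                states.append((int(g["cn_major"].iloc[0]),
                               int(g["cn_minor"].iloc[0])))
            if states is None:
                dropped += 1
                continue
            rows.append((chrom, int(lo), int(hi)))
            major.append([st[0] for st in states])
            minor.append([st[1] for st in states])
    if dropped:
        warnings.warn(f"{dropped} refined intervals not covered by every "
                      "sample were dropped", stacklevel=2)
    if not rows:
        raise InvalidInputError("joint segmentation is empty")

    segments = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    cn_major = np.array(major, dtype=int)
    cn_minor = np.array(minor, dtype=int)

    # merge back adjacent intervals identical in every sample
    keep_rows, keep_major, keep_minor = [], [], []
    for i in range(len(segments)):
        if (keep_rows
                and keep_rows[-1][0] == segments.loc[i, "chrom"]
                and keep_rows[-1][2] == segments.loc[i, "start"]
                and np.array_equal(keep_major[-1], cn_major[i])
                and np.array_equal(keep_minor[-1], cn_minor[i])):
            keep_rows[-1] = (keep_rows[-1][0], keep_rows[-1][1],
                             int(segments.loc[i, "end"]))
        else:
            keep_rows.append((segments.loc[i, "chrom"],
                              int(segments.loc[i, "start"]),
                              int(segments.loc[i, "end"])))
            keep_major.append(cn_major[i])
            keep_minor.append(cn_minor[i])
    segments = pd.DataFrame(keep_rows, columns=["chrom", "start", "end"])
    return JointSegmentation(segments=segments, samples=samples,
                             cn_major=np.array(keep_major, dtype=int),
                             cn_minor=np.array(keep_minor, dtype=int),
                             purity=purity, ploidy=ploidy)


# ---------------------------------------------------------------------------
# allelic-imbalance testing
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8192)
def _folded_null_moments(depth: int) -> tuple[float, float]:
    """Exact mean and variance of max(b, n-b) for b ~ Binomial(n, 1/2)."""
    b = np.arange(depth + 1)
    pmf = stats.binom.pmf(b, depth, 0.5)
    m = np.maximum(b, depth - b)
    mu = float((pmf * m).sum())
    var = float((pmf * m * m).sum() - mu * mu)
    return mu, var


def folded_imbalance_p(b_counts, depths) -> tuple[float, float]:
    """One-sided p-value for allelic imbalance with arbitrary allele labels.

    Returns ``(p, folded_fraction)`` where the statistic is the pooled
    majority-allele count sum(max(b, n-b)) compared with its exact null
    moments under BAF 0.5 via a normal approximation across SNPs.
    """
    b = np.asarray(b_counts, dtype=int)
    n = np.asarray(depths, dtype=int)
    ok = n > 0
    b, n = b[ok], n[ok]
    if b.size == 0:
        return 1.0, np.nan
    stat = float(np.maximum(b, n - b).sum())
    mu = var = 0.0
    for d in n:
        m, v = _folded_null_moments(int(d))
        mu += m
        var += v
    if var <= 0:
        return 1.0, stat / n.sum()
    z = (stat - mu) / np.sqrt(var)
    return float(stats.norm.sf(z)), stat / n.sum()


# ---------------------------------------------------------------------------
# reference phasing
# ---------------------------------------------------------------------------

def phase_haplotypes(jseg: JointSegmentation, snp_baf: pd.DataFrame, *,
                     min_snps: int = MIN_SNPS,
                     p_threshold: float = P_PHASE) -> PhasedSegments:
    """Anchor each segment's phase on a reference sample with imbalance.

    For every joint segment with at least ``min_snps`` heterozygous SNPs the
    reference sample is the significantly imbalanced sample with the largest
    |folded BAF - 0.5| * sqrt(total depth).  SNP B-alleles with BAF > 0.5 in
    the reference are assigned to the amplified haplotype A; all samples'
    pooled haplotype-A fractions and imbalance p-values are then computed on
    this fixed phase.  Segments where no sample is imbalanced stay unphased
    (no haplotype copy numbers; MSAI is impossible there), which is not an
    error.  Haplotype copy numbers are initialised on the A-major
    orientation; :func:`correct_cn_states` flips them where the phased BAF
    disagrees.
    """
    n_seg, n_smp = jseg.cn_major.shape
    out = PhasedSegments(
        segments=jseg.segments, samples=jseg.samples,
        cn_major=jseg.cn_major, cn_minor=jseg.cn_minor,
        purity=jseg.purity, ploidy=jseg.ploidy,
        cn_a=jseg.cn_major.copy(), cn_b=jseg.cn_minor.copy(),
        phased=np.zeros(n_seg, dtype=bool),
        ref_sample=np.full(n_seg, -1, dtype=int),
        baf_a=np.full((n_seg, n_smp), np.nan),
        p_value=np.ones((n_seg, n_smp)),
        direction=np.full((n_seg, n_smp), "", dtype=object),
        n_snps=np.zeros(n_seg, dtype=int))

    phase_rows = []
    for i in range(n_seg):
        chrom, lo, hi = jseg.segments.loc[i, ["chrom", "start", "end"]]
        snps = snp_baf[(snp_baf["chrom"] == chrom)
                       & (snp_baf["pos"] >= lo) & (snp_baf["pos"] < hi)]
        if snps.empty:
            continue
        piv_b = snps.pivot_table(index="pos", columns="sample",
                                 values="b_count", aggfunc="first")
        piv_n = snps.pivot_table(index="pos", columns="sample",
                                 values="depth", aggfunc="first")
        piv_b = piv_b.reindex(columns=jseg.samples).fillna(0)
        piv_n = piv_n.reindex(columns=jseg.samples).fillna(0)
        n_snp = len(piv_b)
        out.n_snps[i] = n_snp
        if n_snp < min_snps:
            continue

        folded = [folded_imbalance_p(piv_b[s].to_numpy(), piv_n[s].to_numpy())
                  for s in jseg.samples]
        scores = []
        for s_idx, s in enumerate(jseg.samples):
            p, frac = folded[s_idx]
            total = piv_n[s].sum()
            score = abs(frac - 0.5) * np.sqrt(total) if np.isfinite(frac) else -1
            scores.append((p, score, s_idx))
        significant = [t for t in scores if t[0] < p_threshold]
        if not significant:
            continue
        ref = max(significant, key=lambda t: (t[1], -t[2]))[2]

        rb = piv_b.iloc[:, ref].to_numpy()
        rn = piv_n.iloc[:, ref].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            on_a = np.where(rn > 0, rb / np.maximum(rn, 1) > 0.5, False)
        out.phased[i] = True
        out.ref_sample[i] = ref
        for pos, a in zip(piv_b.index, on_a):
            phase_rows.append((chrom, int(pos), i, bool(a)))

        for s_idx, s in enumerate(jseg.samples):
            b = piv_b[s].to_numpy()
            n = piv_n[s].to_numpy()
            a_count = int(np.where(on_a, b, n - b).sum())
            total = int(n.sum())
            if total == 0:
                continue
            out.baf_a[i, s_idx] = a_count / total
            if s_idx == ref:
                out.p_value[i, s_idx] = folded[s_idx][0]
                out.direction[i, s_idx] = "A"
            else:
                out.p_value[i, s_idx] = stats.binomtest(
                    a_count, total, 0.5).pvalue
                out.direction[i, s_idx] = ("A" if out.baf_a[i, s_idx] >= 0.5
                                           else "B")
    out.snp_phase = pd.DataFrame(phase_rows, columns=["chrom", "pos",
                                                      "segment", "b_on_hap_a"])
    return out


def correct_cn_states(phased: PhasedSegments, *,
                      p_threshold: float = P_PHASE) -> PhasedSegments:
    """Flip haplotype assignments that contradict the phased BAF.

    Where a sample shows significant imbalance towards haplotype B but its
    copy numbers are oriented A-major, (cnA, cnB) is swapped.  The total
    copy number is never altered.
    """
    cn_a = phased.cn_a.copy()
    cn_b = phased.cn_b.copy()
    n_seg, n_smp = cn_a.shape
    for i in range(n_seg):
        if not phased.phased[i]:
            continue
        for s in range(n_smp):
            if (phased.p_value[i, s] < p_threshold
                    and phased.direction[i, s] == "B"
                    and cn_a[i, s] > cn_b[i, s]):
                cn_a[i, s], cn_b[i, s] = cn_b[i, s], cn_a[i, s]
    out = PhasedSegments(**{**phased.__dict__})
    out.cn_a, out.cn_b = cn_a, cn_b
    return out


def detect_msai(phased: PhasedSegments, *, min_snps: int = MIN_SNPS,
                p_threshold: float = P_PHASE) -> list[MsaiEvent]:
    """Emit an MSAI event per segment with imbalance on both haplotypes.

    Requires at least one sample significantly favouring haplotype A and at
    least one favouring B on the same joint segment (each at
    p < ``p_threshold`` with >= ``min_snps`` informative SNPs).  A segment
    where only one sample is imbalanced never yields an event.
    """
    events = []
    for i in range(phased.n_segments):
        if not phased.phased[i] or phased.n_snps[i] < min_snps:
            continue
        sig = phased.p_value[i] < p_threshold
        set_a = [phased.samples[s] for s in np.flatnonzero(
            sig & (phased.direction[i] == "A"))]
        set_b = [phased.samples[s] for s in np.flatnonzero(
            sig & (phased.direction[i] == "B"))]
        if set_a and set_b:
            events.append(MsaiEvent(
                segment_index=i,
                chrom=phased.segments.loc[i, "chrom"],
                start=int(phased.segments.loc[i, "start"]),
                end=int(phased.segments.loc[i, "end"]),
                samples_a=tuple(set_a), samples_b=tuple(set_b),
                baf_a={s: float(phased.baf_a[i, j])
                       for j, s in enumerate(phased.samples)},
                p_values={s: float(phased.p_value[i, j])
                          for j, s in enumerate(phased.samples)},
                n_snps=int(phased.n_snps[i])))
    return events
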