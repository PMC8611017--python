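"""Segment-event classification and clonal/subclonal SCNA summaries.

Copy-number states are reduced to event classes relative to the sample's
baseline ploidy b = round(ploidy): deep loss (total 0), LOH (one haplotype
lost, total at most b — this includes copy-neutral LOH), amplification
(total >= 2b + 1), gain (above b but below amplification) and neutral.

Per patient, a joint segment is a clonal SCNA when every sample carries the
same non-neutral class (a 3-copy and a 4-copy gain count as one clonal
gain), subclonal when altered in some but not all samples or with
discordant classes.  Summaries report counts and the percentage of the
tiled autosomal genome affected, per-cytoband aggregation with a 50%
length-coverage rule, and the stratification of chromosomes into
unchanged / whole-chromosome / segmentally altered.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ValidationError
from .phasing import PhasedSegments
from .synthetic import CHROM_LENGTH, N_AUTOSOMES

EVENT_CLASSES = ("deep_loss", "loh", "gain", "amplification", "neutral")
BAND_COVERAGE = 0.5
WHOLE_CHROM_FRACTION = 0.95


def classify_cn(total_cn: int, min_cn: int, baseline: int) -> str:
    """Event class of one copy-number state against baseline ploidy."""
    if total_cn < 0 or min_cn < 0:
        raise InvalidInputError("copy numbers must be >= 0")
    if total_cn == 0:
        return "deep_loss"
    if min_cn == 0 and total_cn <= baseline:
        return "loh"
    if total_cn >= 2 * baseline + 1:
        return "amplification"
    if total_cn > baseline:
        return "gain"
    return "neutral"


def classify_segment_events(phased: PhasedSegments) -> pd.DataFrame:
    """Classify every joint segment in every sample.

    Returns a long table (segment, sample, chrom, start, end, length,
    event_class).  A missing ploidy defaults to 2 with a warning upstream;
    the baseline is round(ploidy) with a floor of 1.
    """
    rows = []
    for s_idx, sample in enumerate(phased.samples):
        ploidy = phased.ploidy.get(sample, 2.0)
        baseline = max(int(round(ploidy)), 1)
        for i in range(phased.n_segments):
            a = int(phased.cn_a[i, s_idx])
            b = int(phased.cn_b[i, s_idx])
            seg = phased.segments.loc[i]
            rows.append((i, sample, seg["chrom"], int(seg["start"]),
                         int(seg["end"]), int(seg["end"] - seg["start"]),
                         classify_cn(a + b, min(a, b), baseline)))
    return pd.DataFrame(rows, columns=["segment", "sample", "chrom", "start",
                                       "end", "length", "event_class"])


def segment_clonality(events: pd.DataFrame) -> pd.DataFrame:
    """Per-segment clonality: clonal, subclonal or unaffected.

    Clonal requires the identical non-neutral class in every sample; any
    other segment with at least one non-neutral sample is subclonal.  The
    result is invariant to sample order.
    """
    out = []
    for seg, grp in events.groupby("segment"):
        classes = set(grp["event_class"])
        non_neutral = classes - {"neutral"}
        if not non_neutral:
            clonality = "unaffected"
        elif len(classes) == 1:
            clonality = "clonal"
        else:
            clonality = "subclonal"
        first = grp.iloc[0]
        out.append((seg, first["chrom"], first["start"], first["end"],
                    first["length"], clonality,
                    ";".join(sorted(non_neutral))))
    return pd.DataFrame(out, columns=["segment", "chrom", "start", "end",
                                      "length", "clonality", "classes"])


def stratify_scna_clonality(events: pd.DataFrame,
                            patient: str = "P01") -> pd.Series:
    """Clonal vs subclonal segment counts and genome fractions for a patient.

    Percentages use the total tiled autosomal length as denominator; the
    union fraction (clonal% + subclonal%) is the fraction of the genome
    affected by at least one SCNA event in at least one sample.
    """
    seg = segment_clonality(events)
    total = float(seg["length"].sum())
    if total <= 0:
        raise InvalidInputError("segmentation has zero total length")
    n_clonal = int((seg["clonality"] == "clonal").sum())
    n_subclonal = int((seg["clonality"] == "subclonal").sum())
    pct_clonal = 100.0 * seg.loc[seg["clonality"] == "clonal", "length"].sum() / total
    pct_subclonal = 100.0 * seg.loc[seg["clonality"] == "subclonal", "length"].sum() / total
    return pd.Series({
        "patient": patient,
        "n_clonal_segments": n_clonal,
        "n_subclonal_segments": n_subclonal,
        "pct_genome_clonal": pct_clonal,
        "pct_genome_subclonal": pct_subclonal,
        "pct_genome_union": pct_clonal + pct_subclonal,
    })


def load_published_cohort() -> pd.DataFrame:
    """Published per-patient SCNA clonality summary of a nine-patient
    multi-region neuroblastoma cohort (clonal/subclonal segment counts and
    genome fractions as printed), bundled for cohort-level consistency
    checks of :func:`summarize_cohort`."""
    from importlib.resources import files

    path = files("mrevo") / "data" / "published_cohort_scna_clonality.tsv"
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t")


def summarize_cohort(per_patient: pd.DataFrame) -> dict:
    """Cohort medians of the per-patient clonality summaries.

    Accepts a table with columns ``n_clonal_segments``,
    ``n_subclonal_segments``, ``pct_genome_clonal`` and
    ``pct_genome_subclonal`` (one row per patient) and reports the median
    clonal / subclonal segment counts and the median and mean union genome
    fraction.
    """
    union = (per_patient["pct_genome_clonal"].astype(float)
             + per_patient["pct_genome_subclonal"].astype(float))
    return {
        "median_clonal_segments": float(per_patient["n_clonal_segments"].median()),
        "median_subclonal_segments": float(per_patient["n_subclonal_segments"].median()),
        "median_union_pct": float(union.median()),
        "mean_union_pct": float(union.mean()),
    }


# ---------------------------------------------------------------------------
# cytoband aggregation
# ---------------------------------------------------------------------------

def make_uniform_cytobands(bands_per_chrom: int = 4,
                           n_autosomes: int = N_AUTOSOMES,
                           chrom_length: int = CHROM_LENGTH) -> pd.DataFrame:
    """Uniform synthetic band table for the 22-autosome synthetic genome."""
    rows = []
    for c in range(n_autosomes):
        bounds = np.linspace(0, chrom_length, bands_per_chrom + 1).astype(int)
        for i in range(bands_per_chrom):
            arm = "p" if i < bands_per_chrom / 2 else "q"
            rows.append((f"chr{c + 1}", bounds[i], bounds[i + 1],
                         f"{c + 1}{arm}{i + 1}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "band"])


def aggregate_cytobands(events: pd.DataFrame, cytobands: pd.DataFrame, *,
                        coverage: float = BAND_COVERAGE) -> pd.DataFrame:
    """Aggregate segment events onto cytobands.

    A band carries a class in a sample iff events of that class cover at
    least ``coverage`` (default 50%) of the band's length in that sample;
    several classes may be flagged on one band.  Band and segment
    coordinates must refer to the same genome.
    """
    if not {"chrom", "start", "end", "band"} <= set(cytobands.columns):
        raise ValidationError("cytoband table needs chrom, start, end, band")
    ev = events[events["event_class"] != "neutral"]
    known = set(events["chrom"])
    if not known <= set(cytobands["chrom"]):
        raise ValidationError(
            "segments on chromosomes absent from the cytoband table: "
            f"{sorted(known - set(cytobands['chrom']))}")
    rows = []
    for _, band in cytobands.iterrows():
        blen = band["end"] - band["start"]
        if blen <= 0:
            raise ValidationError(f"band {band['band']} has non-positive length")
        sub = ev[ev["chrom"] == band["chrom"]]
        if sub.empty:
            continue
        ov = (np.minimum(sub["end"], band["end"])
              - np.maximum(sub["start"], band["start"])).clip(lower=0)
        sub = sub.assign(overlap=ov)
        sub = sub[sub["overlap"] > 0]
        for (sample, cls), grp in sub.groupby(["sample", "event_class"]):
            frac = grp["overlap"].sum() / blen
            if frac >= coverage:
                rows.append((band["band"], band["chrom"], sample, cls,
                             float(frac)))
    return pd.DataFrame(rows, columns=["band", "chrom", "sample",
                                       "event_class", "covered_fraction"])


def cytoband_clonality(band_events: pd.DataFrame, samples) -> pd.DataFrame:
    """Clonal/subclonal status per band and class across a patient's samples."""
    rows = []
    n = len(samples)
    for (band, cls), grp in band_events.groupby(["band", "event_class"]):
        carriers = set(grp["sample"])
        rows.append((band, grp["chrom"].iloc[0], cls, len(carriers),
                     "clonal" if len(carriers) == n else "subclonal"))
    return pd.DataFrame(rows, columns=["band", "chrom", "event_class",
                                       "n_samples", "clonality"])


# ---------------------------------------------------------------------------
# chromosome stratification
# ---------------------------------------------------------------------------

def classify_chromosomes(events: pd.DataFrame, *,
                         n_autosomes: int = N_AUTOSOMES,
                         whole_fraction: float = WHOLE_CHROM_FRACTION,
                         patient: str = "P01"):
    """Stratify chromosomes into unchanged / whole-chromosome / segmental.

    A chromosome is unchanged when no sample carries a non-neutral event on
    it, whole-chromosome altered when every maximal run of equal-class
    non-neutral segments spans at least ``whole_fraction`` (default 95%) of
    the chromosome's tiled length, and segmental otherwise.  Chromosomes
    absent from the segmentation count as unchanged.  Returns the per-
    chromosome table and the per-patient fractions over ``n_autosomes``.
    """
    chrom_len = events.drop_duplicates("segment").groupby("chrom")["length"].sum()
    classes = {}
    for chrom, grp in events.groupby("chrom"):
        runs_ok, any_event = True, False
        for sample, sg in grp.groupby("sample"):
            sg = sg.sort_values("start")
            run_len, run_class, prev_end = 0, None, None
            for _, r in sg.iterrows():
                cls = r["event_class"]
                contiguous = prev_end is not None and r["start"] == prev_end
                if cls == run_class and contiguous:
                    run_len += r["length"]
                else:
                    if run_class not in (None, "neutral"):
                        any_event = True
                        if run_len < whole_fraction * chrom_len[chrom]:
                            runs_ok = False
                    run_class, run_len = cls, r["length"]
                prev_end = r["end"]
            if run_class not in (None, "neutral"):
                any_event = True
                if run_len < whole_fraction * chrom_len[chrom]:
                    runs_ok = False
        if not any_event:
            classes[chrom] = "unchanged"
        elif runs_ok:
            classes[chrom] = "whole_chromosome"
        else:
            classes[chrom] = "segmental"
    for c in range(n_autosomes):
        classes.setdefault(f"chr{c + 1}", "unchanged")
    table = pd.DataFrame(sorted(classes.items(),
                                key=lambda kv: int(kv[0][3:])),
                         columns=["chrom", "class"])
    table.insert(0, "patient", patient)
    counts = table["class"].value_counts()
    fractions = {f"fraction_{k}": counts.get(k, 0) / n_autosomes
                 for k in ("unchanged", "whole_chromosome", "segmental")}
    return table, fractions
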