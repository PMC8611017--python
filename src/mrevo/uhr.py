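"""Per-biopsy ultra-high-risk (UHR) molecular classification.

A biopsy is telomere-maintenance positive (TMM+) when it carries any of:
high TERT expression, MYCN amplification, a TERT rearrangement, or
alternative lengthening of telomeres (ALT).  Mutations in the TP53 or
RAS-MAPK pathways with VAF > 5% are UHR mutations.  The classification is

* ``UHR``           — TMM+ and at least one UHR mutation,
* ``HR_TMM``        — TMM+ without a UHR mutation,
* ``TMM_negative``  — no telomere-maintenance indicator.

A patient is heterogeneous when their biopsies disagree; comparing
timepoints distinguishes UHR acquisition under therapy from UHR loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import InvalidInputError

UHR_VAF = 0.05

# Default pathway membership; fully overridable by the caller.  TERT itself
# is a telomere-maintenance indicator, not a pathway mutation.
DEFAULT_PATHWAY_GENES = {
    "TP53": ("TP53",),
    "RAS_MAPK": ("ALK", "HRAS", "NRAS", "KRAS", "BRAF", "NF1", "PTPN11",
                 "FGFR1", "RAF1"),
}


@dataclass
class BiopsyMolecularProfile:
    """Telomere-maintenance indicators and pathway mutations of one biopsy."""

    sample_id: str
    tert_high: bool = False
    mycn_amplified: bool = False
    tert_rearranged: bool = False
    alt_positive: bool = False
    pathway_mutations: list = field(default_factory=list)  # (gene, pathway, vaf)
    timepoint: str = ""
    missing_indicators: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for gene, pathway, vaf in self.pathway_mutations:
            if not 0.0 <= vaf <= 1.0:
                raise InvalidInputError(
                    f"VAF {vaf} of {gene} outside [0, 1]")
            if pathway not in DEFAULT_PATHWAY_GENES:
                raise InvalidInputError(f"unknown pathway {pathway!r}")


@dataclass
class UhrCall:
    sample_id: str
    tmm_positive: bool
    uhr_mutation_present: bool
    classification: str     # UHR | HR_TMM | TMM_negative
    timepoint: str = ""


def mycn_amplified_from_cn(total_cn: float, ploidy: float) -> bool:
    """Amplification call for the MYCN locus: total CN >= 2 * round(ploidy) + 1."""
    baseline = max(int(round(ploidy)), 1)
    return total_cn >= 2 * baseline + 1


def classify_biopsy_uhr(profile: BiopsyMolecularProfile, *,
                        uhr_vaf: float = UHR_VAF) -> UhrCall:
    """Apply the two-axis UHR rule to one biopsy.

    Missing telomere indicators are treated as negative (the profile's
    ``missing_indicators`` list records which, so downstream reports can
    flag them).
    """
    tmm = (profile.tert_high or profile.mycn_amplified
           or profile.tert_rearranged or profile.alt_positive)
    mut = any(vaf > uhr_vaf for _, _, vaf in profile.pathway_mutations)
    if tmm and mut:
        cls = "UHR"
    elif tmm:
        cls = "HR_TMM"
    else:
        cls = "TMM_negative"
    return UhrCall(sample_id=profile.sample_id, tmm_positive=tmm,
                   uhr_mutation_present=mut, classification=cls,
                   timepoint=profile.timepoint)


def patient_uhr_profile(calls: list[UhrCall], patient: str = "P01") -> dict:
    """Patient-level heterogeneity assessment across biopsies and timepoints.

    Heterogeneous iff the biopsies do not share one classification.  When
    timepoints are annotated and exactly the later timepoint is uniformly
    UHR (or uniformly non-UHR), the direction is reported as ``acquired``
    (or ``lost``).  A single biopsy is homogeneous by definition.
    """
    if not calls:
        raise InvalidInputError("at least one biopsy call is required")
    classes = [c.classification for c in calls]
    heterogeneous = len(set(classes)) > 1
    by_timepoint = {}
    for c in calls:
        by_timepoint.setdefault(c.timepoint or "all", []).append(
            c.classification)
    direction = ""
    timepoints = [t for t in by_timepoint if t != "all"] or list(by_timepoint)
    if heterogeneous and len(timepoints) >= 2:
        ordered = sorted(timepoints)
        first_uhr = all(c == "UHR" for c in by_timepoint[ordered[0]])
        last_uhr = all(c == "UHR" for c in by_timepoint[ordered[-1]])
        if last_uhr and not first_uhr:
            direction = "acquired"
        elif first_uhr and not last_uhr:
            direction = "lost"
    return {
        "patient": patient,
        "n_biopsies": len(calls),
        "n_uhr": sum(c == "UHR" for c in classes),
        "heterogeneous": heterogeneous,
        "direction": direction,
        "by_timepoint": {t: sorted(set(v)) for t, v in by_timepoint.items()},
    }


def pathway_mutations_from_variants(variants: pd.DataFrame, sample: str, *,
                                    pathway_genes=None) -> list:
    """Collect (gene, pathway, VAF) triples for one sample from a variant table.

    ``variants`` needs columns sample, gene, alt_count, depth and either a
    ``pathway`` column or membership via ``pathway_genes``.
    """
    genes = pathway_genes or DEFAULT_PATHWAY_GENES
    gene_to_pathway = {g: p for p, gs in genes.items() for g in gs}
    sub = variants[variants["sample"] == sample]
    out = []
    for _, r in sub.iterrows():
        pathway = r.get("pathway", "")
        if pd.isna(pathway) or not pathway:
            pathway = gene_to_pathway.get(r["gene"], "")
        if not pathway:
            continue
        vaf = r["alt_count"] / r["depth"] if r["depth"] > 0 else 0.0
        out.append((r["gene"], pathway, float(vaf)))
    return out
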