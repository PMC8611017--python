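"""Somatic SNV calling and clonality stratification.

Candidate calling follows the classic tumour/normal + panel-of-normals
design: a variant is somatic when (i) it is supported by a sufficient
fraction of tumour reads (>= 10% by default), (ii) the matched normal shows
fewer than 5% supporting reads, and (iii) the observed alt count is highly
unlikely (p < 0.001) under a beta-binomial model of technical mismatches
fitted to a panel of normal samples.

Clonality across a patient's samples uses the 10% VAF presence rule,
rescaled per sample for purity and local copy number: the 10% cutoff is
anchored at the expected VAF of a clonal heterozygous mutation in a diploid
region at 60% purity (0.30), and scaled proportionally elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateSiteError, InvalidInputError, NoDataError

T_CANDIDATE = 0.10      # minimum tumour VAF for a candidate call
T_CONTROL = 0.05        # maximum matched-normal VAF
P_MAX = 0.001           # beta-binomial upper-tail cutoff
T_CLONAL = 0.10         # presence threshold in VAF space (diploid anchor)
DIPLOID_ANCHOR_VAF = 0.30   # clonal het VAF at the 60%-purity diploid anchor

# Concentration used when the panel shows no overdispersion and the model
# degrades to a plain pooled binomial.
_BINOMIAL_CONCENTRATION = 1e6


@dataclass
class SiteErrorModel:
    """Beta-binomial technical-mismatch model at one site (or site class)."""

    alpha: float
    beta: float
    overdispersed: bool = True

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise InvalidInputError("alpha and beta must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    def tail_p(self, alt: int, depth: int) -> float:
        """Upper-tail probability P(X >= alt) for depth trials."""
        if depth <= 0:
            raise InvalidInputError("depth must be positive")
        if alt <= 0:
            return 1.0
        return float(stats.betabinom.sf(alt - 1, depth, self.alpha, self.beta))


@dataclass
class SomaticCall:
    site: str
    tumour_vaf: float
    control_vaf: float
    p_value: float
    status: str     # somatic | rejected_candidate | rejected_error_model

    @property
    def is_somatic(self) -> bool:
        return self.status == "somatic"


@dataclass
class ClonalityCall:
    variant_id: str
    category: str               # clonal | subclonal | subclonal_specific | absent
    presence: np.ndarray        # per-sample booleans
    thresholds: np.ndarray      # per-sample adjusted VAF thresholds
    diploid_assumed: bool = False


def fit_site_error_model(control_counts) -> SiteErrorModel:
    """Method-of-moments beta-binomial fit to panel-of-normals mismatches.

    ``control_counts`` is a sequence of ``(mismatch_count, depth)`` pairs.
    The mismatch mean is estimated from pooled counts with a 0.5/1.0
    pseudocount; overdispersion from the per-sample mismatch-fraction
    variance after subtracting the binomial sampling component.  When the
    overdispersion estimate is non-positive the model falls back to a pooled
    binomial (represented as a beta-binomial with a very large
    concentration).
    """
    pairs = [(int(x), int(n)) for x, n in control_counts if n > 0]
    if not pairs:
        raise NoDataError("no control sample has positive depth")
    if len(pairs) < 2:
        raise NoDataError("need at least two controls with positive depth")
    x = np.array([p[0] for p in pairs], dtype=float)
    n = np.array([p[1] for p in pairs], dtype=float)
    if np.any(x > n):
        raise InvalidInputError("mismatch count exceeds depth in a control")
    m = (x.sum() + 0.5) / (n.sum() + 1.0)
    m = min(max(m, 1e-12), 1.0 - 1e-12)
    p_i = x / n
    s2 = float(np.var(p_i, ddof=1))
    mean_inv_n = float(np.mean(1.0 / n))
    binom_var = m * (1.0 - m) * mean_inv_n
    denom = m * (1.0 - m) * (1.0 - mean_inv_n)
    rho = (s2 - binom_var) / denom if denom > 0 else 0.0
    if rho <= 0:
        conc = _BINOMIAL_CONCENTRATION
        return SiteErrorModel(alpha=m * conc, beta=(1.0 - m) * conc,
                              overdispersed=False)
    conc = max(1.0 / rho - 1.0, 1e-6)
    return SiteErrorModel(alpha=m * conc, beta=(1.0 - m) * conc)


def call_somatic_variant(tumour, normal, model: SiteErrorModel, *,
                         t_candidate: float = T_CANDIDATE,
                         t_control: float = T_CONTROL,
                         p_max: float = P_MAX,
                         site: str = "") -> SomaticCall:
    """Apply the three-filter somatic rule to one tumour/normal site."""
    alt_t, depth_t = int(tumour[0]), int(tumour[1])
    alt_n, depth_n = int(normal[0]), int(normal[1])
    if depth_t <= 0 or depth_n <= 0:
        raise InvalidInputError("tumour and normal depth must be positive")
    vaf_t = alt_t / depth_t
    vaf_n = alt_n / depth_n
    if vaf_t < t_candidate or vaf_n >= t_control:
        return SomaticCall(site, vaf_t, vaf_n, p_value=1.0,
                           status="rejected_candidate")
    p = model.tail_p(alt_t, depth_t)
    status = "somatic" if p < p_max else "rejected_error_model"
    return SomaticCall(site, vaf_t, vaf_n, p_value=p, status=status)


def expected_vaf(ccf: float, purity: float, tumour_total_cn: float,
                 multiplicity: float) -> float:
    """Expected VAF of a mutation: ccf * rho * m / (rho * C_t + 2 (1 - rho)).

    ``tumour_total_cn`` is the total tumour copy number at the site and
    ``multiplicity`` the number of mutated copies per carrying tumour cell.
    """
    if not 0.0 < purity <= 1.0:
        raise InvalidInputError("purity must lie in (0, 1]")
    if tumour_total_cn < 0:
        raise InvalidInputError("tumour copy number must be >= 0")
    denom = purity * tumour_total_cn + 2.0 * (1.0 - purity)
    if denom <= 0:
        raise DegenerateSiteError(
            "no DNA at this site: purity * C_t + 2 (1 - purity) == 0")
    return float(ccf * purity * multiplicity / denom)


def presence_threshold(purity: float, tumour_total_cn: float, *,
                       t_clonal: float = T_CLONAL) -> float:
    """Per-sample presence cutoff, rescaled from the diploid 60%-purity anchor.

    t_s = t_clonal * E[VAF | clonal het, rho_s, C_t] / 0.30, so a sample at
    exactly the anchor conditions keeps the plain 10% rule.
    """
    return t_clonal * expected_vaf(1.0, purity, tumour_total_cn, 1.0) \
        / DIPLOID_ANCHOR_VAF


def classify_clonality(vafs, purities, tumour_total_cn=None, *,
                       t_clonal: float = T_CLONAL,
                       variant_id: str = "") -> ClonalityCall:
    """Stratify one variant across all samples of a patient.

    ``vafs`` and ``purities`` are per-sample; ``tumour_total_cn`` gives the
    local total copy number per sample (None -> diploid assumed and the call
    is flagged).  A variant is clonal when present in every sample,
    subclonal-specific when present in exactly one, subclonal in between,
    and 'absent' when it clears the threshold nowhere.
    """
    vafs = np.asarray(vafs, dtype=float)
    purities = np.asarray(purities, dtype=float)
    if vafs.size == 0:
        raise InvalidInputError("at least one sample is required")
    if vafs.shape != purities.shape:
        raise InvalidInputError("vafs and purities must align")
    diploid_assumed = tumour_total_cn is None
    if diploid_assumed:
        cns = np.full(vafs.shape, 2.0)
    else:
        cns = np.asarray(tumour_total_cn, dtype=float)
    thresholds = np.array([
        presence_threshold(purities[s], cns[s], t_clonal=t_clonal)
        for s in range(vafs.size)])
    presence = vafs >= thresholds
    n = int(presence.sum())
    if n == vafs.size:
        category = "clonal"
    elif n == 1:
        category = "subclonal_specific"
    elif n == 0:
        category = "absent"
    else:
        category = "subclonal"
    return ClonalityCall(variant_id=variant_id, category=category,
                         presence=presence, thresholds=thresholds,
                         diploid_assumed=diploid_assumed)


def platform_concordance(calls_a: dict, calls_b: dict):
    """Fraction of shared variants with the same clonal/subclonal assignment.

    ``calls_a`` / ``calls_b`` map variant id -> category string (e.g. the
    whole-exome and the ultra-deep targeted call sets).  Returns
    ``(fraction, disagreements)`` over the shared identifiers.
    """
    shared = sorted(set(calls_a) & set(calls_b))
    if not shared:
        raise NoDataError("the two call sets share no variant identifiers")
    disagreements = [v for v in shared if calls_a[v] != calls_b[v]]
    return 1.0 - len(disagreements) / len(shared), disagreements
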