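"""Loss-of-heterozygosity analysis at pDGV loci in serial tumors.

At every germline pDGV locus, reads supporting the reference and alternative
alleles are counted in each tumor of the patient (forced allele counting; no
re-genotyping). The tumor VAF is corrected for tumor purity by dividing by
the purity and clamping to [0, 1]; a locus is called LOH when the corrected
tumor-to-normal VAF ratio is >= 1.6 (boundary inclusive). The normal VAF is
not purity-corrected.

Tumors with purity < 50% or locus coverage < 10 reads are excluded up front.
A background control stratum — protein-truncating variants in non-TSGs with
normal VAF in [0.35, 0.80] (i.e. heterozygous) — supports the density
comparison between TSG and non-TSG loci (two-sided Kolmogorov–Smirnov), and
paired primary/metastatic corrected VAFs are compared with an exact two-sided
Wilcoxon signed-rank test (sign-flip enumeration for n <= 25).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import InputError
from .io_cohort import (
    AnnotationStore,
    GeneRoleTable,
    VariantCall,
    VariantKey,
    TRUNCATING,
)

LOH_RATIO_THRESHOLD = 1.6


@dataclass(frozen=True)
class TumorObservation:
    """Read counts at one germline locus in one tumor."""

    tumor_id: str
    patient_id: str
    site: str  # primary | metastatic
    chrom: str
    pos: int
    ref: str
    alt: str
    ref_reads: int
    alt_reads: int
    purity: Optional[float]  # None -> excluded by QC

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def depth(self) -> int:
        return self.ref_reads + self.alt_reads

    @property
    def raw_vaf(self) -> float:
        return self.alt_reads / self.depth if self.depth > 0 else 0.0


@dataclass(frozen=True)
class LOHCall:
    observation: TumorObservation
    normal_vaf: float
    corrected: float
    ratio: float
    is_loh: bool
    threshold: float = LOH_RATIO_THRESHOLD


def corrected_vaf(raw_vaf: float, purity: Optional[float]) -> float:
    """Purity-corrected VAF: clamp(raw / purity, 0, 1).

    The correction rescales the tumor VAF to the tumor-cell fraction; callers
    must exclude observations with missing or non-positive purity first.
    """
    if purity is None or purity <= 0:
        raise InputError(f"invalid tumor purity {purity!r}")
    return min(max(raw_vaf / purity, 0.0), 1.0)


def call_loh(
    normal_vaf: float,
    corrected: float,
    threshold: float = LOH_RATIO_THRESHOLD,
    observation: Optional[TumorObservation] = None,
) -> LOHCall:
    """LOH iff corrected-tumor / normal VAF ratio >= threshold (inclusive)."""
    if normal_vaf <= 0:
        raise InputError("normal VAF must be > 0 (not a carried germline het)")
    ratio = corrected / normal_vaf
    return LOHCall(
        observation=observation,
        normal_vaf=normal_vaf,
        corrected=corrected,
        ratio=ratio,
        is_loh=ratio >= threshold,
        threshold=threshold,
    )


def qc_tumor_observations(
    observations: Iterable[TumorObservation],
    min_purity: float = 0.5,
    min_depth: int = 10,
) -> tuple[list[TumorObservation], dict[str, int]]:
    """Drop observations with low/missing purity or low locus coverage.

    Boundary values (purity exactly 0.5, depth exactly 10) are retained: the
    exclusion conditions are "purity < 50%" and "coverage < 10 reads".
    """
    retained = []
    removed = {"purity": 0, "depth": 0}
    for obs in observations:
        if obs.purity is None or obs.purity < min_purity:
            removed["purity"] += 1
        elif obs.depth < min_depth:
            removed["depth"] += 1
        else:
            retained.append(obs)
    return retained, removed


def build_background_controls(
    calls: Iterable[VariantCall],
    annotations: AnnotationStore,
    roles: GeneRoleTable,
    vaf_window: tuple[float, float] = (0.35, 0.80),
) -> list[VariantCall]:
    """Control stratum: truncating variants in non-TSGs, heterozygous in normal.

    Variants with normal VAF outside [0.35, 0.80] are removed since LOH is
    only defined at heterozygous loci.
    """
    lo, hi = vaf_window
    out = []
    for call in calls:
        ann = annotations.get(call.key)
        if ann.effective_effect not in TRUNCATING:
            continue
        if roles.is_tsg(ann.gene):
            continue
        if lo <= call.vaf <= hi:
            out.append(call)
    return out


def annotate_loh(
    observations: Iterable[TumorObservation],
    normal_vafs: Mapping[VariantKey, float],
    threshold: float = LOH_RATIO_THRESHOLD,
    min_purity: float = 0.5,
    min_depth: int = 10,
) -> tuple[list[LOHCall], dict[str, int]]:
    """QC + purity correction + LOH call for a batch of tumor observations.

    ``normal_vafs`` maps each locus key to the germline (normal) VAF.
    Observations whose locus has no normal VAF are dropped with a warning.
    """
    passed, removed = qc_tumor_observations(observations, min_purity, min_depth)
    calls = []
    removed["no_normal_vaf"] = 0
    for obs in passed:
        nv = normal_vafs.get(obs.key)
        if nv is None or nv <= 0:
            removed["no_normal_vaf"] += 1
            warnings.warn(f"no normal VAF for locus {obs.key}; observation dropped")
            continue
        corr = corrected_vaf(obs.raw_vaf, obs.purity)
        calls.append(call_loh(nv, corr, threshold, observation=obs))
    return calls, removed


# ---------------------------------------------------------------------------
# Distribution comparisons
# ---------------------------------------------------------------------------

def compare_vaf_densities(
    tsg_corrected_vafs: Sequence[float], control_corrected_vafs: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Kolmogorov–Smirnov test between corrected-VAF samples.

    Returns (D, p). Exact p for small samples, asymptotic otherwise
    (scipy's 'auto' policy).
    """
    if len(tsg_corrected_vafs) == 0 or len(control_corrected_vafs) == 0:
        raise InputError("both VAF samples must be non-empty")
    res = stats.ks_2samp(
        tsg_corrected_vafs, control_corrected_vafs, alternative="two-sided"
    )
    return float(res.statistic), float(res.pvalue)


def signed_rank_exact_p(diffs: Sequence[float]) -> float:
    """Exact two-sided Wilcoxon signed-rank p by sign-flip enumeration.

    Zero differences are dropped (signed-rank convention); ties among |d|
    get average ranks. The null distribution of the positive-rank sum W+ is
    built by dynamic programming over all 2^n sign assignments (ranks doubled
    to keep integer sums, so half-ranks from ties are exact); the two-sided p
    doubles the smaller tail, capped at 1.
    """
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = len(d)
    if n == 0:
        return 1.0
    ranks2 = np.asarray(stats.rankdata(np.abs(d)) * 2, dtype=int)  # integers
    w2 = int(ranks2[d > 0].sum())
    total = int(ranks2.sum())
    # DP over achievable doubled-rank sums
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    denom = counts.sum()  # 2^n
    p_le = counts[: w2 + 1].sum() / denom
    p_ge = counts[w2:].sum() / denom
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def compare_paired_primary_met(
    pairs: Sequence[tuple[float, float]], exact_max_n: int = 25
) -> tuple[float, float]:
    """Paired primary-vs-metastatic corrected VAF comparison.

    Returns (fraction of pairs with metastatic > primary, two-sided
    signed-rank p). Exact sign-flip enumeration for n <= ``exact_max_n``
    non-zero differences; normal approximation beyond. All differences zero
    is degenerate: p reported as 1 with a warning.
    """
    if len(pairs) == 0:
        raise InputError("no primary/metastatic pairs")
    diffs = [met - pri for pri, met in pairs]
    fraction_increasing = sum(1 for d in diffs if d > 0) / len(diffs)
    nonzero = [d for d in diffs if d != 0]
    if not nonzero:
        warnings.warn("all paired differences are zero; signed-rank p undefined")
        return fraction_increasing, 1.0
    if len(nonzero) <= exact_max_n:
        p = signed_rank_exact_p(nonzero)
    else:
        res = stats.wilcoxon(nonzero, alternative="two-sided", method="approx")
        p = float(res.pvalue)
    return fraction_increasing, p


def loh_fraction(calls: Sequence[LOHCall]) -> float:
    """Fraction of evaluable observations called LOH."""
    if not calls:
        raise InputError("no LOH calls")
    return sum(1 for c in calls if c.is_loh) / len(calls)
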