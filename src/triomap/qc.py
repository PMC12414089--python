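"""Genotype quality control and identity-by-descent relatedness.

The QC filter mirrors standard pre-ROH pruning of a jointly genotyped
cohort: keep biallelic autosomal SNVs called in all individuals with
minor allele frequency above 0.05 and a Hardy-Weinberg equilibrium exact
test p-value above 1e-6.  Relatedness uses the classic method-of-moments
estimator of the IBD state probabilities (Z0, Z1, Z2) from observed
identity-by-state counts, summarised as PI_HAT = Z1/2 + Z2, and is used
to verify declared parentage within trios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datamodel import (HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix,
                        Pedigree, RelatednessEstimate, TriomapError)

log = logging.getLogger(__name__)

_LOG2 = np.log(2.0)
# relative tie tolerance when comparing floating outcome probabilities
_TIE_EPS = 1e-10


@dataclass(frozen=True)
class QCParams:
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    require_complete_calls: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_min <= 0.5):
            raise TriomapError("maf_min must be in [0, 0.5]")
        if not (0.0 < self.hwe_p_min < 1.0):
            raise TriomapError("hwe_p_min must be in (0, 1)")


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg equilibrium test p-value.

    Conditions on the observed allele counts and sums the probabilities
    of every heterozygote count (same parity) whose probability does not
    exceed that of the observed configuration - the standard two-sided
    "probability mass at most observed" definition, without mid-p
    adjustment.

    Returns a p-value in (0, 1].  Symmetric in the allele labels:
    ``hwe_exact_p(a, b, c) == hwe_exact_p(c, b, a)``.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise TriomapError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise TriomapError("all genotype counts are zero")
    return _hwe_cached(n, min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa), n_Aa)


@lru_cache(maxsize=1 << 18)
def _hwe_cached(n: int, n_rare: int, het_obs: int) -> float:
    if n_rare == 0:
        return 1.0
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    # log multinomial x 2^het, conditioned on allele counts
    logp = (gammaln(n + 1) - gammaln(rare_hom + 1) - gammaln(hets + 1)
            - gammaln(common_hom + 1) + hets * _LOG2
            + gammaln(n_rare + 1) + gammaln(2 * n - n_rare + 1) - gammaln(2 * n + 1))
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.flatnonzero(hets == het_obs)[0]]
    p = probs[probs <= p_obs * (1.0 + _TIE_EPS)].sum()
    return float(min(p, 1.0))


# -- site-level QC -------------------------------------------------------


def site_genotype_counts(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-site counts of hom-ref / het / hom-alt / missing calls."""
    c = matrix.calls
    return pd.DataFrame({
        "variant_id": matrix.variant_ids,
        "n_AA": (c == HOM_REF).sum(axis=0),
        "n_Aa": (c == HET).sum(axis=0),
        "n_aa": (c == HOM_ALT).sum(axis=0),
        "n_missing": (c == MISSING).sum(axis=0),
    })


def qc_site_table(matrix: GenotypeMatrix, params: QCParams = QCParams()
                  ) -> pd.DataFrame:
    """Per-site QC verdicts; the filter keeps rows where ``keep`` is true.

    MAF is computed over non-missing calls; with complete calls required
    this equals the all-sample frequency.
    """
    tab = site_genotype_counts(matrix)
    called = (tab.n_AA + tab.n_Aa + tab.n_aa).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = (2 * tab.n_aa + tab.n_Aa).to_numpy() / (2.0 * called)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    maf = np.where(called > 0, maf, 0.0)
    hwe = np.ones(len(tab))
    for i, (a, b, c) in enumerate(zip(tab.n_AA, tab.n_Aa, tab.n_aa)):
        if a + b + c > 0:
            hwe[i] = hwe_exact_p(int(a), int(b), int(c))
    tab["maf"] = maf
    tab["hwe_p"] = hwe
    keep = (maf > params.maf_min) & (hwe > params.hwe_p_min)
    if params.require_complete_calls:
        keep &= tab.n_missing.to_numpy() == 0
    tab["keep"] = keep
    return tab


def qc_filter(matrix: GenotypeMatrix, params: QCParams = QCParams()
              ) -> GenotypeMatrix:
    """Drop sites failing MAF / HWE / completeness; never alters genotypes.

    Site order is preserved; the operation is idempotent.
    """
    tab = qc_site_table(matrix, params)
    keep = tab["keep"].to_numpy()
    if not keep.any():
        log.warning("qc_filter: no sites pass QC")
    return matrix.subset_sites(keep)


# -- identity by descent -------------------------------------------------


def alt_allele_frequencies(matrix: GenotypeMatrix) -> np.ndarray:
    """Alt allele frequency per site over all non-missing calls.

    Frequencies are pooled over the full loaded cohort, cases included.
    """
    c = matrix.calls
    called = (c != MISSING).sum(axis=0)
    alt = (2 * (c == HOM_ALT) + (c == HET)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * called)
    return np.where(called > 0, p, np.nan)


def ibd_estimate(matrix: GenotypeMatrix, sample_a: str, sample_b: str,
                 min_sites: int = 100,
                 allele_freqs: np.ndarray | None = None) -> RelatednessEstimate:
    """Method-of-moments IBD estimate for one sample pair.

    Uses observed IBS 0/1/2 counts versus their expectations given the
    cohort allele frequencies; negative intermediate estimates are
    projected back onto the probability simplex.
    """
    p = alt_allele_frequencies(matrix) if allele_freqs is None else allele_freqs
    ga = matrix.sample_calls(sample_a).astype(np.int16)
    gb = matrix.sample_calls(sample_b).astype(np.int16)
    ok = (ga != MISSING) & (gb != MISSING) & (p > 0) & (p < 1) & np.isfinite(p)
    m = int(ok.sum())
    if m < min_sites:
        raise TriomapError(
            f"only {m} informative complete pairwise calls for "
            f"({sample_a}, {sample_b}); need at least {min_sites}")
    ga, gb, p = ga[ok], gb[ok], p[ok]
    q = 1.0 - p
    diff = np.abs(ga - gb)
    o0 = float((diff == 2).sum())
    o1 = float((diff == 1).sum())
    o2 = float((diff == 0).sum())
    # expectations per IBD state, summed over sites
    e0_ibd0 = float((2 * p**2 * q**2).sum())
    e1_ibd0 = float((4 * p**3 * q + 4 * p * q**3).sum())
    e2_ibd0 = m - e0_ibd0 - e1_ibd0
    e1_ibd1 = float((2 * p * q).sum())
    e2_ibd1 = m - e1_ibd1
    z0 = o0 / e0_ibd0 if e0_ibd0 > 0 else 0.0
    z1 = (o1 - z0 * e1_ibd0) / e1_ibd1 if e1_ibd1 > 0 else 0.0
    z2 = (o2 - z0 * e2_ibd0 - z1 * e2_ibd1) / m
    z = np.clip([z0, z1, z2], 0.0, None)
    total = z.sum()
    z = z / total if total > 0 else np.array([1.0, 0.0, 0.0])
    return RelatednessEstimate(sample_a=sample_a, sample_b=sample_b,
                               z0=float(z[0]), z1=float(z[1]), z2=float(z[2]),
                               n_sites=m)


def mendelian_error_rate(matrix: GenotypeMatrix, parent: str, child: str) -> float:
    """Fraction of both-called sites with opposing homozygotes."""
    gp = matrix.sample_calls(parent)
    gc = matrix.sample_calls(child)
    ok = (gp != MISSING) & (gc != MISSING)
    if not ok.any():
        return float("nan")
    opposing = ((gp[ok] == HOM_REF) & (gc[ok] == HOM_ALT)) | \
               ((gp[ok] == HOM_ALT) & (gc[ok] == HOM_REF))
    return float(opposing.sum() / ok.sum())


@dataclass(frozen=True)
class ParentageThresholds:
    pi_hat_min: float = 0.4
    pi_hat_max: float = 0.6
    z0_max: float = 0.1


def verify_parentage(pedigree: Pedigree, matrix: GenotypeMatrix,
                     thresholds: ParentageThresholds = ParentageThresholds(),
                     min_sites: int = 100) -> pd.DataFrame:
    """Check every declared parent-offspring pair in the trios.

    Returns one report row per (case, parent) pair - two per trio - with
    the IBD estimate, the opposing-homozygote (Mendelian-error) rate and
    a PASS/FAIL verdict.  Failures are report rows, never exceptions.
    """
    freqs = alt_allele_frequencies(matrix)
    rows = []
    for trio in pedigree.trios():
        for role, parent in (("sire", trio.sire), ("dam", trio.dam)):
            est = ibd_estimate(matrix, trio.case, parent, min_sites=min_sites,
                               allele_freqs=freqs)
            mer = mendelian_error_rate(matrix, parent, trio.case)
            ok = (thresholds.pi_hat_min <= est.pi_hat <= thresholds.pi_hat_max
                  and est.z0 <= thresholds.z0_max)
            rows.append({
                "case": trio.case, "parent": parent, "parent_role": role,
                "pi_hat": est.pi_hat, "z0": est.z0, "z1": est.z1, "z2": est.z2,
                "n_sites": est.n_sites, "mendel_error_rate": mer,
                "verdict": "PASS" if ok else "FAIL",
            })
    return pd.DataFrame(rows)
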