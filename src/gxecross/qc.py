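"""Variant-level quality control, risk-allele dosage coding, and the CGS.

Genotypes are represented throughout as additive risk-allele dosages in
``{0, 1, 2}``: the count of copies of the declared risk allele.  The
cumulative genetic score (CGS) is the unweighted per-individual sum of
dosages across a SNP panel; published effect sizes are carried as metadata
only and never weight the score.

The Hardy-Weinberg test is the chi-square goodness of fit of the three
observed genotype counts against the proportions (q^2, 2pq, p^2) implied by
the sample allele frequency.  The statistically standard test spends one
degree of freedom on the estimated allele frequency (``df=1``); a
``df=2`` mode is provided because published HWE p-values for this panel are
consistent with a plain two-degree three-category test.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SnpInfo",
    "HweResult",
    "QcThresholds",
    "QcReport",
    "hwe_test",
    "variant_qc",
    "code_risk_dosage",
    "compute_cgs",
]


@dataclass(frozen=True)
class SnpInfo:
    """Metadata for one biallelic SNP.

    ``risk_allele`` is the allele counted by the additive dosage coding;
    ``source_beta`` is the published per-allele effect, kept as metadata.
    """

    snp_id: str
    risk_allele: str
    other_allele: str
    source_beta: float | None = None
    source_trait: str = ""
    gene_label: str = ""
    base_pair: int | None = None

    def __post_init__(self) -> None:
        if self.risk_allele == self.other_allele:
            raise ValueError(
                f"{self.snp_id}: risk and other allele must differ "
                f"(both {self.risk_allele!r})"
            )


@dataclass(frozen=True)
class HweResult:
    """Chi-square goodness of fit of genotype counts to Hardy-Weinberg."""

    chi2: float
    df: int
    p: float
    observed_counts: tuple[float, float, float]
    expected_counts: tuple[float, float, float]
    allele_freq: float  # frequency of the risk allele


def hwe_test(counts, df: int = 1) -> HweResult:
    """Test genotype counts (hom-other, het, hom-risk) against HWE.

    Parameters
    ----------
    counts
        Triple of nonnegative genotype counts ordered by risk-allele
        dosage: (0 copies, 1 copy, 2 copies).
    df
        Degrees of freedom for the reference chi-square distribution.
        ``1`` (default) is the standard biallelic goodness-of-fit test,
        in which the allele frequency is estimated from the same counts;
        ``2`` treats the three categories as a plain multinomial fit.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.shape != (3,):
        raise ValueError("counts must be a triple (hom-other, het, hom-risk)")
    if np.any(obs < 0):
        raise ValueError("genotype counts must be nonnegative")
    n = obs.sum()
    if n <= 0:
        raise ValueError("all-zero genotype counts: no individuals to test")
    if df not in (1, 2):
        raise ValueError("df must be 1 or 2")

    p_risk = (2 * obs[2] + obs[1]) / (2 * n)
    q = 1.0 - p_risk
    expected = n * np.array([q**2, 2 * p_risk * q, p_risk**2])

    # cells with zero expectation force zero observation (monomorphic SNP)
    mask = expected > 0
    chi2 = float(np.sum((obs[mask] - expected[mask]) ** 2 / expected[mask]))
    pval = float(stats.chi2.sf(chi2, df))
    return HweResult(
        chi2=chi2,
        df=df,
        p=pval,
        observed_counts=tuple(obs),
        expected_counts=tuple(expected),
        allele_freq=float(p_risk),
    )


@dataclass(frozen=True)
class QcThresholds:
    """Variant-level inclusion thresholds.

    A SNP fails when its call rate is below ``call_rate``, its minor allele
    frequency is below ``maf``, or its HWE p-value is below ``hwe_p``.
    """

    call_rate: float = 0.95
    maf: float = 0.02
    hwe_p: float = 1e-5


@dataclass
class QcReport:
    """Per-SNP QC metrics with pass flags, plus per-sample missingness.

    Flag-based: nothing is dropped; :meth:`passing_snps` and
    :meth:`drop_failures` derive filtered views.
    """

    per_snp: pd.DataFrame
    per_sample_missing: pd.Series
    thresholds: QcThresholds = field(default_factory=QcThresholds)

    def passing_snps(self) -> list[str]:
        return list(self.per_snp.index[self.per_snp["pass_all"]])

    def drop_failures(self, dosages: pd.DataFrame) -> pd.DataFrame:
        """Return the dosage table restricted to SNPs passing all filters."""
        return dosages[self.passing_snps()]


def variant_qc(
    dosages: pd.DataFrame,
    thresholds: QcThresholds | None = None,
    hwe_df: int = 1,
) -> QcReport:
    """Compute call rate, MAF and HWE per SNP and flag threshold failures.

    ``dosages`` is individuals x SNPs with entries in {0, 1, 2} or NaN for
    missing calls.  Filtering is non-destructive: the report carries named
    boolean flags per SNP.
    """
    if thresholds is None:
        thresholds = QcThresholds()
    if dosages.shape[0] == 0 or dosages.shape[1] == 0:
        raise ValueError("empty dosage table")

    rows = []
    for snp in dosages.columns:
        col = dosages[snp].to_numpy(dtype=float)
        called = col[~np.isnan(col)]
        call_rate = len(called) / len(col)
        if len(called) == 0:
            rows.append(
                dict(snp_id=snp, call_rate=0.0, risk_freq=np.nan, maf=np.nan,
                     hwe_chi2=np.nan, hwe_p=np.nan,
                     pass_call_rate=False, pass_maf=False, pass_hwe=False)
            )
            continue
        counts = tuple(int(np.sum(called == k)) for k in (0, 1, 2))
        if sum(counts) != len(called):
            raise ValueError(f"{snp}: dosages must be 0/1/2 or missing")
        hwe = hwe_test(counts, df=hwe_df)
        maf = min(hwe.allele_freq, 1.0 - hwe.allele_freq)
        rows.append(
            dict(
                snp_id=snp,
                call_rate=call_rate,
                risk_freq=hwe.allele_freq,
                maf=maf,
                hwe_chi2=hwe.chi2,
                hwe_p=hwe.p,
                pass_call_rate=call_rate >= thresholds.call_rate,
                pass_maf=maf >= thresholds.maf,
                pass_hwe=hwe.p >= thresholds.hwe_p,
            )
        )
    per_snp = pd.DataFrame(rows).set_index("snp_id", drop=False)
    per_snp["pass_all"] = (
        per_snp["pass_call_rate"] & per_snp["pass_maf"] & per_snp["pass_hwe"]
    )
    per_sample = dosages.isna().mean(axis=1)
    per_sample.name = "missing_fraction"
    return QcReport(per_snp=per_snp, per_sample_missing=per_sample, thresholds=thresholds)


_GT_SPLIT = re.compile(r"[/|]")


def code_risk_dosage(calls, snp: SnpInfo, sample_ids=None) -> np.ndarray:
    """Code genotype calls as risk-allele dosage 0/1/2.

    ``calls`` is a sequence of diploid genotype strings, either compact
    ("CT") or separator-delimited ("C/T", "C|T").  Example: for a SNP with
    alleles C/T and risk allele T, CC -> 0, CT -> 1, TT -> 2.

    Raises ``ValueError`` naming the SNP and the offending sample when a
    call uses an allele other than the two declared ones.
    """
    out = np.empty(len(calls), dtype=float)
    for i, call in enumerate(calls):
        if call is None or (isinstance(call, float) and np.isnan(call)):
            out[i] = np.nan
            continue
        alleles = _GT_SPLIT.split(call) if _GT_SPLIT.search(call) else list(call)
        if len(alleles) != 2:
            raise ValueError(f"{snp.snp_id}: malformed genotype call {call!r}")
        dosage = 0
        for a in alleles:
            if a in (".", ""):
                dosage = np.nan
                break
            if a == snp.risk_allele:
                dosage += 1
            elif a != snp.other_allele:
                sid = sample_ids[i] if sample_ids is not None else i
                raise ValueError(
                    f"{snp.snp_id}: undeclared allele {a!r} in sample {sid} "
                    f"(declared {snp.other_allele}/{snp.risk_allele})"
                )
        out[i] = dosage
    return out


def compute_cgs(dosages: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Unweighted cumulative genetic score: per-individual sum of dosages.

    Requires complete dosages (complete-case contract); with m SNPs the
    score lies in [0, 2m].
    """
    arr = np.asarray(dosages, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if np.isnan(arr).any():
        raise ValueError("missing dosages: CGS requires complete cases")
    return arr.sum(axis=1)
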