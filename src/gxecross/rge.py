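"""Gene-environment correlation (rGE) screen.

Before the environment can act as a moderator in a G×E model it must be
exogenous to genotype: a SNP whose dosage correlates with the environment
confounds moderation with gene-environment correlation.  The screen runs a
two-sided Pearson test of each SNP's dosage (and of the CGS) against the
environment and excludes SNPs whose correlation is significant; the CGS is
then recomputed on the retained panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gxecross.cohort import Cohort
from gxecross.qc import compute_cgs

__all__ = ["RgeResult", "ScreenReport", "pearson_rge", "screen_panel"]


@dataclass(frozen=True)
class RgeResult:
    label: str  # snp_id or "CGS"
    r: float
    p: float
    n: int
    excluded: bool
    undefined: bool = False  # constant input: correlation not estimable


def pearson_rge(x, pe, alpha: float = 0.05, label: str = "") -> RgeResult:
    """Two-sided Pearson correlation test of a genetic variable against PE.

    ``excluded`` is True when p < alpha (default 0.05).  A constant input
    vector makes the correlation undefined; the result is flagged rather
    than raised so that panel screening can proceed.
    """
    x = np.asarray(x, dtype=float)
    pe = np.asarray(pe, dtype=float)
    if x.shape != pe.shape:
        raise ValueError("vectors must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if np.std(x) == 0.0 or np.std(pe) == 0.0:
        return RgeResult(label=label, r=np.nan, p=np.nan, n=n, excluded=False, undefined=True)
    r, p = stats.pearsonr(x, pe)
    return RgeResult(label=label, r=float(r), p=float(p), n=n, excluded=bool(p < alpha))


@dataclass
class ScreenReport:
    """Panel-wide rGE screen: per-SNP and CGS results, retained set."""

    results: list[RgeResult]
    retained: list[str]
    cgs_retained: np.ndarray  # CGS recomputed on the retained panel

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(label=r.label, r=r.r, p=r.p, n=r.n,
                     excluded=r.excluded, undefined=r.undefined)
                for r in self.results
            ]
        )


def screen_panel(cohort: Cohort, alpha: float = 0.05) -> ScreenReport:
    """Screen every SNP and the CGS against the environment.

    Flags SNPs whose dosage-PE Pearson test has p < alpha, recomputes the
    CGS over the retained SNPs, and never modifies the dosage table itself.
    """
    if len(cohort.snp_ids) == 0:
        raise ValueError("empty SNP panel")
    results = [
        pearson_rge(cohort.dosage(snp), cohort.pe, alpha=alpha, label=snp)
        for snp in cohort.snp_ids
    ]
    results.append(pearson_rge(np.asarray(cohort.cgs), cohort.pe, alpha=alpha, label="CGS"))
    retained = [r.label for r in results[:-1] if not r.excluded]
    cgs_retained = (
        compute_cgs(cohort.dosages[retained]) if retained else np.zeros(cohort.n)
    )
    return ScreenReport(results=results, retained=retained, cgs_retained=cgs_retained)
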