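"""In-memory cohort container shared by all analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gxecross.qc import compute_cgs

__all__ = ["Cohort"]


@dataclass
class Cohort:
    """Complete-case analysis set: phenotype, environment, covariates, dosages.

    Attributes
    ----------
    ids : array of str
        Individual identifiers.
    phenotype : array of float
        Outcome Y (reading score; the instrument counts 0-150 characters).
    pe : array of float
        Environment X1, parental education: mean of the two parents'
        integer education levels 1-8, hence on a 0.5-step grid in [1, 8].
    pe_father, pe_mother : arrays of int or None
        The underlying parent levels when known.
    age : array of float
        Age in months.
    sex : array of int
        Binary code, 0 = male, 1 = female.
    dosages : DataFrame
        Individuals x SNPs risk-allele dosages in {0, 1, 2}.
    cgs : array of float
        Cumulative genetic score X2 = row sum of ``dosages`` (over the
        retained panel; recomputed by the rGE screen when SNPs are excluded).
    meta : dict
        Free-form provenance (e.g. simulation truth).
    """

    ids: np.ndarray
    phenotype: np.ndarray
    pe: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    dosages: pd.DataFrame
    cgs: np.ndarray | None = None
    pe_father: np.ndarray | None = None
    pe_mother: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name in ("phenotype", "pe", "age", "sex"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length {len(getattr(self, name))} != n={n}")
        if len(self.dosages) != n:
            raise ValueError("dosage table row count mismatch")
        if self.cgs is None:
            self.cgs = compute_cgs(self.dosages)
        self.validate()

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)

    def validate(self) -> None:
        pe = np.asarray(self.pe, dtype=float)
        if np.isnan(pe).any() or pe.min() < 1 or pe.max() > 8:
            raise ValueError("PE must be complete and lie in [1, 8]")
        if not np.allclose(pe * 2, np.round(pe * 2)):
            raise ValueError("PE values must lie on the 0.5-step grid")
        d = self.dosages.to_numpy(dtype=float)
        if np.isnan(d).any() or not np.isin(d, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be complete and in {0, 1, 2}")
        if not np.array_equal(np.asarray(self.cgs, dtype=float), d.sum(axis=1)):
            raise ValueError("CGS must equal the row sum of dosages")
        if np.isnan(np.asarray(self.phenotype, dtype=float)).any():
            raise ValueError("phenotype must be complete (complete-case contract)")

    def dosage(self, snp_id: str) -> np.ndarray:
        return self.dosages[snp_id].to_numpy(dtype=float)

    def pe_range(self) -> tuple[float, float]:
        """Observed environment range [min(PE), max(PE)] of the sample."""
        return float(np.min(self.pe)), float(np.max(self.pe))

    def phenotype_frame(self) -> pd.DataFrame:
        """Phenotype/covariate table in the on-disk column layout."""
        father = self.pe_father if self.pe_father is not None else np.full(self.n, np.nan)
        mother = self.pe_mother if self.pe_mother is not None else np.full(self.n, np.nan)
        return pd.DataFrame(
            {
                "id": self.ids,
                "score": self.phenotype,
                "age_months": self.age,
                "sex": self.sex,
                "pe_father": father,
                "pe_mother": mother,
            }
        )
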