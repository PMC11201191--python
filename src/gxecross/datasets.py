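"""Reference data for the dyslexia-SNP reading-ability study.

The panel below lists nine SNPs previously associated with reading-related
traits in genome-wide scans (non-word reading, phoneme awareness, rapid
automatized naming, word reading, latent naming speed), together with the
published risk allele and effect size.  They form the default panel of the
synthetic-cohort generator and of the worked examples.

The ``other_allele`` column is known from the genotyping context only for
rs281238 (C/T); for the remaining SNPs a plausible non-risk allele is
assigned so that synthetic genotype files are well formed.  Only the risk
allele enters any computation.
"""

from __future__ import annotations

import pandas as pd

#: Genotype counts for rs281238 in the study cohort of 1477 school-aged
#: children, split by low/high parental-education subgroup:
#: CC = 279/266, CT = 373/314, TT = 128/117.  T is the risk allele.
RS281238_COUNTS_BY_PE_GROUP = ((279, 266), (373, 314), (128, 117))

#: The same counts pooled across the environment subgroups (CC, CT, TT).
RS281238_GENOTYPE_COUNTS = tuple(sum(pair) for pair in RS281238_COUNTS_BY_PE_GROUP)

#: Complete-case analysis sample size of the study cohort.
STUDY_SAMPLE_SIZE = 1477

_PANEL_ROWS = [
    # snp_id, trait, risk_allele, other_allele, beta, gene, base_pair
    ("rs1541518", "non-word reading", "G", "A", 0.177, "ADCYAP1R1", 31108665),
    ("rs281238", "phoneme awareness", "T", "C", 0.156, "SEMA6D", 47432075),
    ("rs4571421", "RAN pictures", "C", "T", 0.168, "LINC02118", 188588642),
    ("rs7301219", "RAN pictures", "C", "A", 0.151, "", 43731097),
    ("rs9925265", "phoneme awareness", "G", "T", 0.148, "SLC12A3", 126496851),
    ("rs7187223", "non-word reading", "A", "G", 0.251, "", 82424128),
    ("rs764255", "word reading", "T", "C", -0.077, "ZFHX3", 72271184),
    ("rs6963842", "RAN letters", "G", "A", 0.020, "LAMB1", 107994544),
    ("rs9540938", "latent naming speed", "A", "G", float("nan"), "PCDH9", 66867593),
]


def dyslexia_snp_panel() -> pd.DataFrame:
    """Metadata table for the nine-SNP reading/dyslexia panel.

    Returns a DataFrame with columns ``snp_id``, ``source_trait``,
    ``risk_allele``, ``other_allele``, ``source_beta``, ``gene_label``,
    ``base_pair``, one row per SNP, indexed by ``snp_id``.
    """
    df = pd.DataFrame(
        _PANEL_ROWS,
        columns=[
            "snp_id",
            "source_trait",
            "risk_allele",
            "other_allele",
            "source_beta",
            "gene_label",
            "base_pair",
        ],
    )
    return df.set_index("snp_id", drop=False)
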