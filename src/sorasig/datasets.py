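"""Packaged reference data.

Ships the three annotated RCC patient cohorts (microarray, RNA-seq and
qRT-PCR profiling arms of the sorafenib-response study), the reference
differential-expression screen of the ten sorafenib target genes in the
microarray discovery cohort, and the qRT-PCR primer panel (8 target +
6 housekeeping genes).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cohort import CohortAnnotation, Platform, load_annotation

__all__ = [
    "SORAFENIB_TARGETS",
    "HOUSEKEEPING_PRIMER_PANEL",
    "HOUSEKEEPING_METHODS_SET",
    "load_cohort",
    "load_all_cohorts",
    "reference_target_de",
    "qpcr_primers",
]

#: The ten tyrosine kinases sorafenib is known to inhibit -- the
#: candidate gene set from which the response signature is selected.
SORAFENIB_TARGETS: tuple[str, ...] = (
    "RAF1", "BRAF", "RET", "FLT1", "FGFR1",
    "KIT", "PDGFRB", "FLT3", "FLT4", "KDR",
)

#: Housekeeping genes on the shipped qRT-PCR primer panel (default ΔCt
#: reference set).
HOUSEKEEPING_PRIMER_PANEL: tuple[str, ...] = (
    "ACTB", "VCP", "DIABLO", "EIF3B", "PSMB2", "POLR2C",
)

#: Alternative housekeeping set (GAPDH instead of EIF3B) named in the
#: study methods; the primer panel above is the default.
HOUSEKEEPING_METHODS_SET: tuple[str, ...] = (
    "ACTB", "GAPDH", "POLR2C", "PSMB2", "DIABLO", "VCP",
)

_COHORT_FILES = {
    Platform.MICROARRAY: "cohort_microarray.tsv",
    Platform.RNASEQ_COUNTS: "cohort_rnaseq.tsv",
    Platform.PCR_CT: "cohort_qpcr.tsv",
}


def _data_path(name: str):
    return resources.files("sorasig.data").joinpath(name)


def load_cohort(platform: Platform | str) -> CohortAnnotation:
    """Load one of the three packaged patient cohorts by profiling platform."""
    platform = Platform(platform)
    with resources.as_file(_data_path(_COHORT_FILES[platform])) as p:
        return load_annotation(p, platform=platform)


def load_all_cohorts() -> dict[Platform, CohortAnnotation]:
    return {pf: load_cohort(pf) for pf in _COHORT_FILES}


def reference_target_de() -> pd.DataFrame:
    """Reference differential-expression screen of the sorafenib target
    genes in the microarray discovery cohort (two-sided t-test p-value
    and log2 fold-change, responders vs poor responders), indexed by gene.
    """
    with resources.as_file(_data_path("target_de_microarray.tsv")) as p:
        return pd.read_csv(p, sep="\t", index_col="gene")


def qpcr_primers() -> pd.DataFrame:
    """qRT-PCR primer panel: gene, role (target/housekeeping), primer pair."""
    with resources.as_file(_data_path("qpcr_primers.tsv")) as p:
        return pd.read_csv(p, sep="\t")
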