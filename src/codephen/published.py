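"""Published validation linkage tables for RA phenotyping algorithms.

These are the reported 3x3 linkage tables from the Welsh (ABMU) primary-care
validation of three RA phenotyping algorithms — the data-driven rule
algorithm, the QOF register definition, and the Thomas et al. expert code
list — over 475,580 adults, with reference diagnoses from the linked
secondary-care rheumatology system.  They ship with the package as worked
inputs for the scenario-analysis machinery: all best/worst-case metrics and
cohort fractions are recomputed from these integers at run time, never
stored.
"""

from __future__ import annotations

from .validation import LinkageTable

ABMU_POPULATION = 475_580

#: Data-driven rule algorithm vs reference diagnosis.
DATA_DRIVEN_TABLE = LinkageTable(
    a=1323, b=396, e=2560,
    c=265, d=10084, f=459_727,
    g=138, h=1087,
    population_size=ABMU_POPULATION,
)

#: QOF RA register definition vs reference diagnosis.
QOF_TABLE = LinkageTable(
    a=1377, b=513, e=2851,
    c=211, d=9967, f=459_436,
    g=138, h=1087,
    population_size=ABMU_POPULATION,
)

#: Thomas et al. expert-knowledge algorithm vs reference diagnosis.
THOMAS_TABLE = LinkageTable(
    a=1333, b=570, e=2139,
    c=255, d=9910, f=460_148,
    g=138, h=1087,
    population_size=ABMU_POPULATION,
)

PUBLISHED_TABLES = {
    "data_driven": DATA_DRIVEN_TABLE,
    "qof": QOF_TABLE,
    "thomas": THOMAS_TABLE,
}
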