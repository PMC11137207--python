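"""Published cohort manifest: per-platform sample counts of the five GEO
series that form the merged infant-sepsis cohort.

The counts are the study-design inputs of the analysis (dataset, microarray
platform, case group and per-group sizes).  They drive the cohort-size
arithmetic checks and give the synthetic generator a realistic shape to
emulate.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import Group

__all__ = ["CohortManifestEntry", "COHORT_MANIFEST", "cohort_totals", "group_size"]


@dataclass(frozen=True)
class CohortManifestEntry:
    dataset_id: str
    platform_id: str
    case_group: Group
    n_cases: int
    n_controls: int

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls


#: One entry per contributing microarray platform (GSE25504 spans three).
COHORT_MANIFEST: tuple[CohortManifestEntry, ...] = (
    CohortManifestEntry("GSE64456", "GPL10558", Group.BACTEREMIA, 32, 14),
    CohortManifestEntry("GSE25504", "GPL6947", Group.BACTEREMIA, 25, 35),
    CohortManifestEntry("GSE25504", "GPL15158", Group.BACTEREMIA, 23, 27),
    CohortManifestEntry("GSE25504", "GPL13667", Group.BACTEREMIA, 9, 6),
    CohortManifestEntry("GSE69686", "GPL20292", Group.BACTEREMIA, 64, 58),
    CohortManifestEntry("GSE26378", "GPL570", Group.SEPTIC_SHOCK, 13, 2),
    CohortManifestEntry("GSE26440", "GPL570", Group.SEPTIC_SHOCK, 17, 10),
)


def cohort_totals() -> dict[str, int]:
    """Total merged-cohort size and per-dataset totals."""
    per_dataset: dict[str, int] = {}
    for e in COHORT_MANIFEST:
        per_dataset[e.dataset_id] = per_dataset.get(e.dataset_id, 0) + e.n_total
    return {"total": sum(per_dataset.values()), **per_dataset}


def group_size(group: Group | str) -> int:
    """Number of case samples in a clinical group, summed over datasets."""
    group = Group(group)
    if group is Group.HEALTHY_CONTROL:
        return sum(e.n_controls for e in COHORT_MANIFEST)
    return sum(e.n_cases for e in COHORT_MANIFEST if e.case_group is group)
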