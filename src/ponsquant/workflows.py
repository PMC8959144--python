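"""End-to-end cohort workflows built from the module primitives."""

from __future__ import annotations

import pandas as pd

from ponsquant import counting, stats, synthetic
from ponsquant.stats import AnovaResult
from ponsquant.synthetic import SectionSpec


def count_cohort(specs: list[SectionSpec], **pipeline_kwargs) -> pd.DataFrame:
    """Run the full counting pipeline over a cohort of section specs.

    Returns the concatenated per-section raw count table (one row per
    region per section per animal, plus the unassigned bucket).
    """
    tables = []
    for spec in specs:
        sections, plates, region_map, _ = synthetic.make_section_set(spec)
        for img, plate in zip(sections, plates):
            tables.append(
                counting.count_section(
                    img,
                    plate,
                    region_map,
                    animal_id=spec.animal_id,
                    genotype=spec.genotype,
                    **pipeline_kwargs,
                )
            )
    return pd.concat(tables, ignore_index=True)


def ms_percentage_comparison(
    raw_counts: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, AnovaResult]:
    """Motor/somatosensory percentage table and its two-way comparison.

    Normalizes each animal's M and S counts to percentages of their sum,
    then runs genotype × region ANOVA with Bonferroni-corrected genotype
    contrasts within each region.
    """
    genotype_of = raw_counts.groupby("animal_id")["genotype"].first()
    ms = counting.normalize_counts(raw_counts, "MS_percentage")
    ms["genotype"] = ms["animal_id"].map(genotype_of)
    rows = []
    for r in ms.itertuples():
        rows.append({"value": r.pct_M, "genotype": r.genotype, "region": "M"})
        rows.append({"value": r.pct_S, "genotype": r.genotype, "region": "S"})
    result = stats.two_way_anova(pd.DataFrame(rows), alpha=alpha)
    return ms, result
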