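"""Full pipeline wiring: genotype QC -> parentage -> animal QC.

The stages run in fixed order; genotypes failing genotype QC never reach
the later stages, parentage runs validation against listed parents, then
prediction for unresolved animals, then trio mating validation, and
animal QC consumes everything.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import animal_qc, genotype_qc, parentage
from .types import (
    Animal,
    DEFAULT_THRESHOLDS,
    GenotypeRecord,
    SnpMap,
    Thresholds,
    Validity,
)


@dataclass
class PipelineConfig:
    thresholds: Thresholds = DEFAULT_THRESHOLDS
    run_parentage: bool = True
    run_prediction: bool = True
    run_trios: bool = True
    run_animal_qc: bool = True


@dataclass
class PipelineResult:
    genotype_qc: list[genotype_qc.GenotypeQCResult]
    parentage_validation: list[parentage.ParentageResult] = field(default_factory=list)
    parentage_predictions: list[parentage.ParentageResult] = field(default_factory=list)
    trios: list[parentage.TrioResult] = field(default_factory=list)
    animal_reports: list[animal_qc.AnimalQCReport] = field(default_factory=list)

    @property
    def n_invalidated(self) -> int:
        return sum(
            r.final_state in (Validity.INVALID, Validity.UNRESOLVED)
            for r in self.animal_reports
        )


def run_pipeline(
    records: list[GenotypeRecord],
    animals: dict[str, Animal],
    snp_map: SnpMap,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    config = config or PipelineConfig()
    th = config.thresholds
    qc_results = genotype_qc.run_genotype_qc(records, snp_map, th)
    passed = [r for r in records if r.valid is Validity.VALID]
    result = PipelineResult(genotype_qc=qc_results)
    if not passed:
        return result

    panel = snp_map.panel_index
    all_snps = snp_map.autosomal_index  # duo tests never use chrX/chrY
    ctx_records = passed

    if config.run_parentage:
        table = parentage.build_candidate_table(ctx_records, panel, th)
        validated_both: dict[str, dict[str, parentage.ParentageResult]] = {}
        for aid in table.animal_ids:
            an = animals.get(aid)
            if an is None:
                continue
            per_role: dict[str, parentage.ParentageResult] = {}
            for role, pid in (("sire", an.listed_sire), ("dam", an.listed_dam)):
                if not pid or pid not in table.records:
                    continue
                res = parentage.validate_parent(
                    table.records[aid], table.records[pid], panel, all_snps, role, th
                )
                result.parentage_validation.append(res)
                per_role[role] = res
            validated_both[aid] = per_role

        if config.run_prediction:
            for aid, per_role in validated_both.items():
                needs = not (
                    "sire" in per_role and per_role["sire"].verdict.is_validated
                    and "dam" in per_role and per_role["dam"].verdict.is_validated
                )
                if needs:
                    result.parentage_predictions.extend(
                        parentage.predict_parents(aid, table, animals, panel, all_snps, th)
                    )

        if config.run_trios:
            for aid, per_role in validated_both.items():
                if (
                    "sire" in per_role and per_role["sire"].verdict.is_validated
                    and "dam" in per_role and per_role["dam"].verdict.is_validated
                ):
                    an = animals[aid]
                    result.trios.append(
                        parentage.count_msm(
                            table.records[aid],
                            table.records[an.listed_sire],
                            table.records[an.listed_dam],
                            panel,
                            th,
                        )
                    )

    if config.run_animal_qc:
        result.animal_reports = animal_qc.run_animal_qc(
            ctx_records, animals, snp_map, th
        )
    return result


def summary_frame(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for rep in result.animal_reports:
        rows.append(
            {
                "sample_id": rep.sample_id,
                "animal_id": rep.animal_id,
                "final_state": rep.final_state.value,
                **{f"check_{k}": v for k, v in rep.outcomes.items()},
            }
        )
    return pd.DataFrame(rows)
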