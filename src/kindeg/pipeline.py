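"""End-to-end kinetic-degradomics pipeline over an identified-peptide table.

Triage -> empirical-null fit on annotated N-termini -> ratio correction ->
efficiency classification of proteolytic neo-N-termini. This is the
composition the analysis drivers and the command-line tools run; each stage
is importable on its own from the sibling modules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .classifier import (
    ClassificationSummary,
    EfficiencyCall,
    NullModel,
    RatioPair,
    Region,
    classify_table as _classify_table,
    correct_ratios as _correct_ratios,
    fit_null as _fit_null,
)
from .io import NTermPeptide, TriageCategory, TriageSummary, summarize_triage, triage_nterm
from .sites import CleavageSite


@dataclass(frozen=True)
class PipelineResult:
    triage: TriageSummary
    null_raw: NullModel
    null_corrected: NullModel
    calls: list[EfficiencyCall]
    summary: ClassificationSummary


def _pair(p: NTermPeptide) -> RatioPair | None:
    if p.has_ratios:
        return RatioPair(p.ratio_a, p.ratio_b)
    return None


def run_pipeline(
    peptides: Sequence[NTermPeptide],
    coverage: float = 0.98,
    region: Region | str = Region.RECT,
) -> PipelineResult:
    """Run triage, null fitting, correction and classification.

    The null is fitted on annotated N-termini with complete ratio pairs;
    every ratio is then corrected by the fitted locations, the null is
    refitted on the corrected annotated pairs for reporting (its locations
    are ~0 by construction), and each proteolytic neo-N-terminus is called
    efficient or bystander against that corrected null. Neo peptides with a
    missing ratio are carried through as unclassifiable.
    """
    triage = summarize_triage(peptides)
    annotated = [
        _pair(p)
        for p in peptides
        if triage_nterm(p) is TriageCategory.ANNOTATED_START and p.has_ratios
    ]
    null_raw = _fit_null(annotated, coverage=coverage)

    neo = [p for p in peptides if triage_nterm(p) is TriageCategory.PROTEOLYTIC_NEO]
    corrected_neo = _correct_ratios([_pair(p) for p in neo], null_raw)
    corrected_ann = _correct_ratios(annotated, null_raw)
    null_corrected = _fit_null(
        [p for p in corrected_ann if p is not None], coverage=coverage
    )

    events: list[tuple[CleavageSite | None, RatioPair | None]] = [
        (CleavageSite(p.protein_acc, p.start_pos - 1) if p.start_pos >= 2 else None, r)
        for p, r in zip(neo, corrected_neo)
    ]
    calls, summary = _classify_table(events, null_corrected, region=region)
    return PipelineResult(triage, null_raw, null_corrected, calls, summary)
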