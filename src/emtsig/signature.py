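"""Consensus gene-list construction and the diagnostic x prognostic
direction-concordance intersection — the signature derivation itself.

A gene enters the final signature when it is (a) deregulated in tumor vs
normal tissue and (b) coherently prognostic across DMFS, OS and RFS, with
the two directions concordant: up-regulated genes whose high expression
worsens prognosis (``up_worse``) or down-regulated genes whose high
expression improves prognosis (``down_better``). Overlapping genes with
conflicting directions are retained as ``discordant`` for audit, never
silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import AnalysisConfig
from .diffexpr import ExpressionCohort, DifferentialResult, differential_expression
from .errors import ParameterError
from .survival import ENDPOINTS, PrognosticCall, SurvivalCohort, classify_prognosis
from .tables import DiagnosticTableRow, PrognosticTableRow, SignatureEntry

__all__ = [
    "ConsensusGeneList",
    "PipelineReport",
    "consensus_filter",
    "derive_signature",
    "run_full_pipeline",
]


@dataclass(frozen=True)
class ConsensusGeneList:
    """Genes retained by the minimum-study-recurrence filter."""

    genes: frozenset[str]
    support: dict[str, int]
    n_studies: int
    min_studies: int


def consensus_filter(
    study_lists: Sequence[Iterable[str]], min_studies: int = 2
) -> ConsensusGeneList:
    """Retain genes reported by at least ``min_studies`` distinct studies.

    ``support[g]`` counts the number of distinct study lists containing g
    (for every gene seen in any list); the retained set is
    {g : support[g] >= min_studies}.
    """
    if len(study_lists) < 1:
        raise ParameterError("need at least one study list")
    if min_studies < 1:
        raise ParameterError("min_studies must be >= 1")
    sets = [set(lst) for lst in study_lists]
    if min_studies > len(sets):
        warnings.warn(
            f"min_studies={min_studies} exceeds the {len(sets)} available "
            "studies; the consensus set is necessarily empty",
            stacklevel=2,
        )
    support: dict[str, int] = {}
    for s in sets:
        for g in s:
            support[g] = support.get(g, 0) + 1
    retained = frozenset(g for g, k in support.items() if k >= min_studies)
    return ConsensusGeneList(retained, support, len(sets), min_studies)


_CONCORDANT = {("up", "worse"): "up_worse", ("down", "better"): "down_better"}


def derive_signature(
    diagnostic: Sequence[DiagnosticTableRow],
    prognostic: Sequence[PrognosticTableRow],
) -> list[SignatureEntry]:
    """Intersect the diagnostic and prognostic tables by gene symbol.

    Every gene present in both tables yields an entry; the concordant
    classes are up_worse (up-regulated, high expression hazardous) and
    down_better (down-regulated, high expression protective). Output is
    sorted by class (up_worse, down_better, discordant) then gene, and is
    order-invariant in both inputs.
    """
    diag = {r.gene: r for r in diagnostic}
    prog = {r.gene: r for r in prognostic}
    if len(diag) != len(diagnostic) or len(prog) != len(prognostic):
        raise ParameterError("duplicate gene symbols in an input table")
    entries = []
    for gene in diag.keys() & prog.keys():
        dd, pd_ = diag[gene].direction, prog[gene].direction
        klass = _CONCORDANT.get((dd, pd_), "discordant")
        entries.append(
            SignatureEntry(gene, dd, pd_, concordant=klass != "discordant", klass=klass)
        )
    class_rank = {"up_worse": 0, "down_better": 1, "discordant": 2}
    entries.sort(key=lambda e: (class_rank[e.klass], e.gene))
    return entries


@dataclass
class PipelineReport:
    """Intermediate tables and the final signature of a full pipeline run."""

    consensus: ConsensusGeneList
    differential: list[DifferentialResult]
    prognostic_calls: list[PrognosticCall]
    diagnostic_rows: list[DiagnosticTableRow]
    prognostic_rows: list[PrognosticTableRow]
    signature: list[SignatureEntry]
    warnings: list[str] = field(default_factory=list)

    @property
    def concordant(self) -> list[SignatureEntry]:
        return [e for e in self.signature if e.concordant]

    def signature_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": e.gene,
                    "diagnostic_direction": e.diagnostic_direction,
                    "prognostic_direction": e.prognostic_direction,
                    "concordant": e.concordant,
                    "class": e.klass,
                }
                for e in self.signature
            ]
        )


def run_full_pipeline(
    study_lists: Sequence[Iterable[str]],
    expression_cohort: ExpressionCohort,
    survival_cohorts: Mapping[str, SurvivalCohort],
    config: AnalysisConfig | None = None,
) -> PipelineReport:
    """Consensus filter -> Welch screen -> three-endpoint prognostic screen
    -> direction-concordance intersection.

    Only consensus genes are screened. Genes missing from the expression
    or survival cohorts are dropped with a warning. Deterministic given
    ``config.rng_seed``.
    """
    config = config or AnalysisConfig()
    notes: list[str] = []
    consensus = consensus_filter(study_lists, config.min_studies)
    if not consensus.genes:
        notes.append("consensus gene set is empty; signature is empty")
        return PipelineReport(consensus, [], [], [], [], [], notes)

    expr_genes = [g for g in expression_cohort.genes if g in consensus.genes]
    missing_expr = sorted(consensus.genes - set(expr_genes))
    if missing_expr:
        notes.append(f"{len(missing_expr)} consensus gene(s) absent from expression cohort")
    sub = ExpressionCohort(
        values=expression_cohort.values.loc[expr_genes], group=expression_cohort.group
    )
    differential = differential_expression(sub, config)
    diagnostic_rows = [
        DiagnosticTableRow(r.gene, r.direction, r.p_value)
        for r in differential
        if r.significant
    ]

    surv_genes = set.intersection(
        *(set(c.genes) for c in survival_cohorts.values())
    ) if survival_cohorts else set()
    calls: list[PrognosticCall] = []
    prognostic_rows: list[PrognosticTableRow] = []
    for gene in expr_genes:
        if gene not in surv_genes:
            notes.append(f"{gene} absent from a survival cohort; skipped")
            continue
        call = classify_prognosis(gene, survival_cohorts, config)
        calls.append(call)
        if call.coherent:
            prognostic_rows.append(
                PrognosticTableRow(
                    gene,
                    call.direction,
                    call.per_endpoint["DMFS"][0],
                    call.per_endpoint["OS"][0],
                    call.per_endpoint["RFS"][0],
                )
            )

    signature = (
        derive_signature(diagnostic_rows, prognostic_rows)
        if diagnostic_rows and prognostic_rows
        else []
    )
    return PipelineReport(
        consensus, differential, calls, diagnostic_rows, prognostic_rows,
        signature, notes,
    )
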