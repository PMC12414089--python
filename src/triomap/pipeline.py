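"""End-to-end trio analysis: QC -> parentage -> ROH -> filtering ->
cohort/evidence classification -> report.

This is the orchestration layer used by the CLI, the examples and the
acceptance checks; every step is an ordinary call into the per-stage
modules and can be run separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from .classify import (Classification, EvidenceProfile, RuleTable, classify,
                       load_candidate_genes, report)
from .datamodel import (CandidateVariant, GenotypeMatrix, Pedigree,
                        ROHProfile)
from .mendelian import (filter_denovo, filter_recessive_private,
                        filter_recessive_shared, impact_prefilter, scenario)
from .qc import QCParams, qc_filter, verify_parentage
from .roh import ROHParams, colocalize, roh_profile

from .datamodel import BOVINE_AUTOSOME_SNV_BP


@dataclass
class TrioAnalysisResult:
    qc_matrix: GenotypeMatrix
    parentage: pd.DataFrame
    roh_profiles: dict[str, ROHProfile]
    candidates: list[CandidateVariant]
    report: pd.DataFrame


def classify_candidates(candidates: list[CandidateVariant],
                        evidence_votes: Mapping[str, int],
                        candidate_genes: frozenset[str] | None = None,
                        breed_specific: Mapping[str, bool] | None = None,
                        rules: RuleTable = RuleTable()) -> None:
    """Attach evidence and a classification label to each candidate.

    ``evidence_votes`` maps variant_id -> in-silico deleterious votes
    (input evidence, never computed); unknown variants get 0 votes.
    """
    genes = load_candidate_genes() if candidate_genes is None else candidate_genes
    for c in candidates:
        c.votes = int(evidence_votes.get(c.variant_id, 0))
        c.known_candidate_gene = c.site.gene in genes
        c.breed_specific = bool(breed_specific.get(c.variant_id, False)) \
            if breed_specific else False
        profile = EvidenceProfile(
            votes=c.votes,
            known_candidate_gene=c.known_candidate_gene,
            segregation_consistent=(c.case_call == 2 and c.sire_call == 1
                                    and c.dam_call == 1),
            control_hom_count=c.control_hom,
            control_het_count=c.control_het,
            breed_specific=c.breed_specific,
            loss_of_function=c.site.impact == "HIGH",
        )
        cls: Classification = classify(profile, rules)
        c.classification = cls.label
        c.fired_rules = list(cls.fired_rules)


def run_trio_analysis(matrix: GenotypeMatrix, pedigree: Pedigree,
                      evidence_votes: Mapping[str, int],
                      qc_params: QCParams = QCParams(),
                      roh_params: ROHParams = ROHParams(),
                      rules: RuleTable = RuleTable(),
                      scenario_name: str = "recessive_private",
                      genome_denominator_bp: int = BOVINE_AUTOSOME_SNV_BP,
                      candidate_genes: frozenset[str] | None = None,
                      ) -> TrioAnalysisResult:
    """Run the full discovery analysis on one cohort.

    ROH detection runs on the QC-filtered SNV set; the Mendelian
    scenario filters run on the protein-changing subset of the *full*
    matrix (rare causal alleles rarely survive a MAF > 0.05 screen).
    Controls for filtering are all samples except the trio's case (and,
    under the sire-mosaic scenario, except the sire).
    """
    qc_matrix = qc_filter(matrix, qc_params)
    parentage = verify_parentage(pedigree, qc_matrix)
    trios = pedigree.trios()
    profiles = {t.case: roh_profile(qc_matrix, t.case, roh_params,
                                    genome_denominator_bp) for t in trios}

    protein = impact_prefilter(matrix)
    scen = scenario(scenario_name)
    candidates: list[CandidateVariant] = []
    if scenario_name == "recessive_shared":
        controls_by_case = {t.case: [s for s in matrix.samples if s != t.case]
                            for t in trios}
        shared = filter_recessive_shared(protein, trios, controls_by_case, scen)
        for cands in shared.values():
            candidates.extend(cands)
    else:
        for t in trios:
            controls = [s for s in matrix.samples if s != t.case]
            if scenario_name == "recessive_private":
                cands = filter_recessive_private(protein, t, controls, scen)
            else:
                cands = filter_denovo(protein, t, controls, scen)
            candidates.extend(cands)

    for c in candidates:
        c.roh_segment = colocalize(c.site, profiles[c.case])
    classify_candidates(candidates, evidence_votes,
                        candidate_genes=candidate_genes, rules=rules)
    return TrioAnalysisResult(qc_matrix=qc_matrix, parentage=parentage,
                              roh_profiles=profiles, candidates=candidates,
                              report=report(candidates))
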