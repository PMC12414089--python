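"""Cohort genotype screening and evidence-based variant classification.

``screen_cohorts`` does the population-count arithmetic of a variant
occurrence table (allele frequency, homozygote and carrier counts,
breed specificity) and ``classify`` maps an :class:`EvidenceProfile`
through a transparent, configurable rule table to one of the labels
``likely_pathogenic`` / ``uncertain_significance`` / ``likely_benign``,
reporting every fired rule.

The rule table is a deliberately simple, auditable stand-in for
guideline-based (ACMG-style) interpretation: a variant is called likely
pathogenic when it segregates with the phenotype, is essentially absent
in homozygous form from unaffected animals, is predicted deleterious by
at least three in-silico tools, and has gene-level or rarity-level
support (a known phenotype candidate gene, breed-restricted occurrence,
or predicted loss of function).  It is called likely benign when the
in-silico support is absent and either unaffected homozygotes exist or
there is no gene-level evidence at all; everything else is of uncertain
significance.  In-silico verdicts are always consumed as input counts
(0-5 tools by default), never computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .datamodel import CandidateVariant, CohortCounts, TriomapError

LABELS = ("likely_pathogenic", "uncertain_significance", "likely_benign")


# -- cohort screening ----------------------------------------------------


@dataclass(frozen=True)
class CohortSummary:
    variant_id: str
    populations: tuple[str, ...]
    n_varvar: int
    n_refvar: int
    n_refref: int
    includes_case: bool
    allele_frequency: float
    breed_specific: bool

    @property
    def n_genotyped(self) -> int:
        return self.n_varvar + self.n_refvar + self.n_refref


def screen_cohorts(variant_id: str, counts: CohortCounts,
                   populations: Optional[Sequence[str]] = None,
                   breed: Optional[str] = None,
                   include_case: bool = True) -> CohortSummary:
    """Summarise a variant's genotype counts over selected populations.

    ``allele_frequency = (2*n_varvar + n_refvar) / (2*n_genotyped)``.
    With ``include_case=False`` one homozygous individual is removed
    from each population cell flagged as containing the case.  Breed
    specificity is judged over *all* populations of the variant: true
    iff variant alleles occur in exactly one breed.
    """
    sub = counts.rows(variant_id, populations)
    if breed is not None:
        sub = sub[sub["population"].map(CohortCounts.breed_of) == breed]
    if sub.empty:
        raise TriomapError(f"no cohort counts for {variant_id} "
                           f"in the selected populations")
    n_vv = int(sub["n_varvar"].sum())
    n_rv = int(sub["n_refvar"].sum())
    n_rr = int(sub["n_refref"].sum())
    has_case = bool(sub["includes_case"].any())
    if not include_case and has_case:
        n_case_cells = int(sub["includes_case"].sum())
        if n_vv < n_case_cells:
            raise TriomapError(f"{variant_id}: cannot exclude case from a cell "
                               "without a homozygote")
        n_vv -= n_case_cells
    total = n_vv + n_rv + n_rr
    if total == 0:
        raise TriomapError(f"{variant_id}: zero genotypes in selection")
    freq = (2 * n_vv + n_rv) / (2 * total)

    allrows = counts.rows(variant_id)
    carrier_breeds = {CohortCounts.breed_of(p)
                      for p, vv, rv in zip(allrows["population"],
                                           allrows["n_varvar"],
                                           allrows["n_refvar"])
                      if vv + rv > 0}
    return CohortSummary(variant_id=variant_id,
                         populations=tuple(sub["population"]),
                         n_varvar=n_vv, n_refvar=n_rv, n_refref=n_rr,
                         includes_case=has_case and include_case,
                         allele_frequency=freq,
                         breed_specific=len(carrier_breeds) == 1)


def count_homozygotes(variant_id: str, counts: CohortCounts,
                      populations: Optional[Sequence[str]] = None,
                      breed: Optional[str] = None,
                      exclude_case: bool = True) -> int:
    """Sum of var/var genotypes over selected populations, optionally
    subtracting the case from cells flagged as containing it."""
    sub = counts.rows(variant_id, populations)
    if breed is not None:
        sub = sub[sub["population"].map(CohortCounts.breed_of) == breed]
    n_vv = int(sub["n_varvar"].sum())
    if exclude_case:
        n_vv -= int(sub["includes_case"].sum())
    if n_vv < 0:
        raise TriomapError(f"{variant_id}: case-containing cell without a homozygote")
    return n_vv


# -- classification ------------------------------------------------------


@dataclass(frozen=True)
class EvidenceProfile:
    votes: int  # in-silico deleterious verdicts, consumed as input
    known_candidate_gene: bool
    segregation_consistent: bool
    control_hom_count: int
    control_het_count: int = 0
    breed_specific: bool = False
    loss_of_function: bool = False


@dataclass(frozen=True)
class RuleTable:
    """Thresholds for the default label rules; fully configurable."""

    n_tools: int = 5
    pathogenic_min_votes: int = 3
    pathogenic_max_control_hom: int = 1
    benign_max_votes: int = 1
    benign_min_unaffected_hom: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleTable":
        with Path(path).open() as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass(frozen=True)
class Classification:
    label: str
    fired_rules: tuple[str, ...]


def classify(profile: EvidenceProfile, rules: RuleTable = RuleTable()
             ) -> Classification:
    """Deterministic label from the rule table; see module docstring.

    Monotone: raising votes or lowering the unaffected homozygote count
    never moves the label toward benign.
    """
    if profile.votes > rules.n_tools:
        raise TriomapError(f"votes {profile.votes} exceed the configured "
                           f"{rules.n_tools} in-silico tools")
    if profile.votes < 0 or profile.control_hom_count < 0:
        raise TriomapError("negative evidence counts")

    fired: list[str] = []
    gene_evidence = (profile.known_candidate_gene or profile.breed_specific
                     or profile.loss_of_function)
    if profile.known_candidate_gene:
        fired.append("gene:known_candidate")
    if profile.breed_specific:
        fired.append("gene:breed_specific_rarity")
    if profile.loss_of_function:
        fired.append("gene:loss_of_function")

    if (profile.segregation_consistent
            and profile.control_hom_count <= rules.pathogenic_max_control_hom
            and profile.votes >= rules.pathogenic_min_votes
            and gene_evidence):
        fired += ["segregation:consistent",
                  f"rarity:control_hom<={rules.pathogenic_max_control_hom}",
                  f"insilico:votes>={rules.pathogenic_min_votes}"]
        return Classification("likely_pathogenic", tuple(fired))

    if (profile.votes <= rules.benign_max_votes
            and not profile.loss_of_function
            and (profile.control_hom_count >= rules.benign_min_unaffected_hom
                 or not profile.known_candidate_gene)):
        fired.append(f"insilico:votes<={rules.benign_max_votes}")
        if profile.control_hom_count >= rules.benign_min_unaffected_hom:
            fired.append(f"population:unaffected_hom>={rules.benign_min_unaffected_hom}")
        else:
            fired.append("gene:no_candidate_evidence")
        return Classification("likely_benign", tuple(fired))

    fired.append("default:insufficient_evidence")
    return Classification("uncertain_significance", tuple(fired))


# -- reporting -----------------------------------------------------------

REPORT_COLUMNS = ["variant_id", "gene", "impact", "scenario", "case",
                  "case_call", "sire_call", "dam_call",
                  "control_hom", "control_het",
                  "roh_chrom", "roh_start_bp", "roh_end_bp", "roh_length_bp",
                  "votes", "known_candidate_gene", "breed_specific",
                  "classification", "fired_rules"]


def report(candidates: list[CandidateVariant]) -> pd.DataFrame:
    """One deterministic row per classified candidate variant."""
    rows = []
    for c in candidates:
        seg = c.roh_segment
        rows.append({
            "variant_id": c.variant_id, "gene": c.site.gene,
            "impact": c.site.impact, "scenario": c.scenario, "case": c.case,
            "case_call": c.case_call, "sire_call": c.sire_call,
            "dam_call": c.dam_call, "control_hom": c.control_hom,
            "control_het": c.control_het,
            "roh_chrom": seg.chrom if seg else "",
            "roh_start_bp": seg.start_bp if seg else 0,
            "roh_end_bp": seg.end_bp if seg else 0,
            "roh_length_bp": seg.length_bp if seg else 0,
            "votes": -1 if c.votes is None else c.votes,
            "known_candidate_gene": bool(c.known_candidate_gene),
            "breed_specific": bool(c.breed_specific),
            "classification": c.classification or "",
            "fired_rules": ";".join(c.fired_rules),
        })
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return df.sort_values(["case", "variant_id"], kind="stable").reset_index(drop=True)


def write_report(df: pd.DataFrame, tsv_path: str | Path,
                 summary_path: str | Path | None = None) -> None:
    df.to_csv(tsv_path, sep="\t", index=False)
    if summary_path is not None:
        lines = [f"{len(df)} candidate variant(s)"]
        for label in LABELS:
            n = int((df["classification"] == label).sum()) if len(df) else 0
            lines.append(f"  {label}: {n}")
        for _, r in df.iterrows():
            lines.append(f"  {r['case']}  {r['gene'] or '-'}  {r['variant_id']}"
                         f"  {r['scenario']}  -> {r['classification']}")
        Path(summary_path).write_text("\n".join(lines) + "\n")


def read_report(tsv_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(tsv_path, sep="\t", keep_default_na=False,
                     dtype={"variant_id": str, "gene": str, "roh_chrom": str,
                            "fired_rules": str, "classification": str})
    return df[REPORT_COLUMNS]


# -- shipped reference data ----------------------------------------------


def _data_path(name: str):
    return resources.files("triomap").joinpath("data", name)


def load_candidate_genes() -> frozenset[str]:
    """The known depigmentation/albinism candidate genes in cattle."""
    text = _data_path("depigmentation_candidate_genes.txt").read_text()
    return frozenset(g.strip() for g in text.splitlines()
                     if g.strip() and not g.startswith("#"))


def load_case_variant_counts() -> CohortCounts:
    """The published cohort genotype-count table for the 11 private
    homozygous protein-changing variants of the three white-coat cases."""
    from .io import read_cohort_counts
    with resources.as_file(_data_path("case_variant_counts.tsv")) as p:
        return read_cohort_counts(p)


def load_case_variant_evidence() -> pd.DataFrame:
    """Reconstructed (synthetic) evidence profiles for the 11 variants.

    The in-silico vote counts and impact classes are encoded from the
    narrative variant descriptions, not from the original supplementary
    tables, which are not shipped; they are stand-ins adequate for
    exercising the classifier.
    """
    with resources.as_file(_data_path("case_variant_evidence_synthetic.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#",
                           dtype={"variant_id": str, "gene": str})


def classify_case_variant_table(rules: RuleTable = RuleTable()) -> pd.DataFrame:
    """Classify the shipped variant table end to end.

    Control homozygote counts and breed specificity are recomputed from
    the cohort counts; votes, impact and segregation come from the
    evidence table.  Returns one row per variant with the label.
    """
    counts = load_case_variant_counts()
    evidence = load_case_variant_evidence()
    genes = load_candidate_genes()
    rows = []
    for _, ev in evidence.iterrows():
        vid = ev["variant_id"]
        summary = screen_cohorts(vid, counts, include_case=True)
        hom = count_homozygotes(vid, counts, exclude_case=True)
        profile = EvidenceProfile(
            votes=int(ev["votes"]),
            known_candidate_gene=ev["gene"] in genes,
            segregation_consistent=bool(ev["segregation_consistent"]),
            control_hom_count=hom,
            control_het_count=int(summary.n_refvar),
            breed_specific=summary.breed_specific,
            loss_of_function=ev["impact"] == "HIGH",
        )
        cls = classify(profile, rules)
        rows.append({"variant_id": vid, "gene": ev["gene"], "case": ev["case"],
                     "votes": profile.votes,
                     "control_hom": hom,
                     "breed_specific": profile.breed_specific,
                     "known_candidate_gene": profile.known_candidate_gene,
                     "loss_of_function": profile.loss_of_function,
                     "classification": cls.label,
                     "fired_rules": ";".join(cls.fired_rules)})
    return pd.DataFrame(rows)
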