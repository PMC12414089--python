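"""Trio Mendelian variant-filtering scenarios.

Four scenarios over case/sire/dam trios against a control cohort:

* ``recessive_private``  - case hom-alt, both parents obligate het
  carriers, at most ``max_control_hom`` homozygous controls.
* ``recessive_shared``   - the intersection of per-trio recessive
  retention across two or more trios (one shared causal allele).
* ``denovo_postzygotic`` - case het, both parents hom-ref, allele absent
  from every control.
* ``denovo_mosaic``      - case het, sire het (germline mosaicism
  detectable in semen-derived DNA), dam hom-ref, allele absent from all
  controls excluding the case's sire.

Sites with a missing call inside the trio are skipped for that trio
(parents are obligate carriers under the recessive model, so an
uncallable parent disqualifies the site); skipped counts are logged.
Missing control genotypes count as non-carriers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datamodel import (HET, HOM_ALT, HOM_REF, MISSING, CandidateVariant,
                        GenotypeMatrix, Trio, TriomapError)

log = logging.getLogger(__name__)

SCENARIOS = ("recessive_shared", "recessive_private",
             "denovo_postzygotic", "denovo_mosaic")


@dataclass(frozen=True)
class FilterScenario:
    name: str
    max_control_hom: int = 1
    allow_control_het: bool = True
    exclude_sire_from_controls: bool = False

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise TriomapError(f"unknown scenario {self.name!r}")
        if self.name.startswith("denovo") and self.allow_control_het:
            raise TriomapError("de novo scenarios require allele absence in controls")
        if self.name == "denovo_mosaic" and not self.exclude_sire_from_controls:
            raise TriomapError("denovo_mosaic must exclude the sire from controls")
        if self.name != "denovo_mosaic" and self.exclude_sire_from_controls:
            raise TriomapError(f"{self.name} must not exclude the sire from controls")


def scenario(name: str, max_control_hom: int = 1) -> FilterScenario:
    """Build a consistent :class:`FilterScenario` by name."""
    if name in ("recessive_shared", "recessive_private"):
        return FilterScenario(name=name, max_control_hom=max_control_hom,
                              allow_control_het=True)
    if name == "denovo_postzygotic":
        return FilterScenario(name=name, max_control_hom=0,
                              allow_control_het=False)
    if name == "denovo_mosaic":
        return FilterScenario(name=name, max_control_hom=0,
                              allow_control_het=False,
                              exclude_sire_from_controls=True)
    raise TriomapError(f"unknown scenario {name!r}")


def impact_prefilter(matrix: GenotypeMatrix,
                     allowed: frozenset[str] | set[str] = frozenset({"HIGH", "MODERATE"})
                     ) -> GenotypeMatrix:
    """Keep protein-changing sites only (HIGH or MODERATE impact)."""
    mask = np.array([s.impact in allowed for s in matrix.sites])
    return matrix.subset_sites(mask)


def _control_rows(matrix: GenotypeMatrix, controls: list[str]) -> np.ndarray:
    return matrix.calls[[matrix.sample_index(s) for s in controls]] \
        if controls else np.zeros((0, matrix.n_sites), dtype=np.int8)


def _candidates(matrix, mask, trio, scen, gc, gs, gd, ctrl_hom, ctrl_het):
    out = []
    for j in np.flatnonzero(mask):
        out.append(CandidateVariant(
            site=matrix.sites[j], scenario=scen.name, case=trio.case,
            case_call=int(gc[j]), sire_call=int(gs[j]), dam_call=int(gd[j]),
            control_hom=int(ctrl_hom[j]), control_het=int(ctrl_het[j])))
    return out


def filter_recessive_private(matrix: GenotypeMatrix, trio: Trio,
                             controls: list[str],
                             scen: FilterScenario | None = None
                             ) -> list[CandidateVariant]:
    """Private recessive filter for one trio.

    Retains sites where the case is hom-alt, both parents are het
    (obligate carriers), and the variant is homozygous in at most
    ``max_control_hom`` controls; het carriers among controls are
    permitted.
    """
    scen = scen or scenario("recessive_private")
    gc = matrix.sample_calls(trio.case)
    gs = matrix.sample_calls(trio.sire)
    gd = matrix.sample_calls(trio.dam)
    callable_ = (gc != MISSING) & (gs != MISSING) & (gd != MISSING)
    n_skipped = int((~callable_).sum())
    if n_skipped:
        log.info("recessive_private(%s): %d sites skipped for missing trio calls",
                 trio.case, n_skipped)
    ctrl = _control_rows(matrix, controls)
    ctrl_hom = (ctrl == HOM_ALT).sum(axis=0)
    ctrl_het = (ctrl == HET).sum(axis=0)
    mask = (callable_ & (gc == HOM_ALT) & (gs == HET) & (gd == HET)
            & (ctrl_hom <= scen.max_control_hom))
    return _candidates(matrix, mask, trio, scen, gc, gs, gd, ctrl_hom, ctrl_het)


def filter_recessive_shared(matrix: GenotypeMatrix, trios: list[Trio],
                            controls_by_case: dict[str, list[str]],
                            scen: FilterScenario | None = None
                            ) -> dict[str, list[CandidateVariant]]:
    """Homozygous allele common to all cases.

    Runs the private recessive filter per trio and intersects the
    variant ids; returns the retained candidates keyed by case.
    """
    if len(trios) < 2:
        raise TriomapError("recessive_shared needs at least two trios")
    scen = scen or scenario("recessive_shared")
    per_trio = {t.case: filter_recessive_private(matrix, t,
                                                 controls_by_case[t.case], scen)
                for t in trios}
    shared = None
    for cands in per_trio.values():
        ids = {c.variant_id for c in cands}
        shared = ids if shared is None else shared & ids
    shared = shared or set()
    return {case: [c for c in cands if c.variant_id in shared]
            for case, cands in per_trio.items()}


def filter_denovo(matrix: GenotypeMatrix, trio: Trio, controls: list[str],
                  scen: FilterScenario) -> list[CandidateVariant]:
    """De novo filters: isolated post-zygotic or sire-mosaic germline."""
    if scen.name not in ("denovo_postzygotic", "denovo_mosaic"):
        raise TriomapError(f"not a de novo scenario: {scen.name}")
    gc = matrix.sample_calls(trio.case)
    gs = matrix.sample_calls(trio.sire)
    gd = matrix.sample_calls(trio.dam)
    callable_ = (gc != MISSING) & (gs != MISSING) & (gd != MISSING)
    ctrl_samples = [s for s in controls
                    if not (scen.exclude_sire_from_controls and s == trio.sire)]
    ctrl = _control_rows(matrix, ctrl_samples)
    ctrl_hom = (ctrl == HOM_ALT).sum(axis=0)
    ctrl_het = (ctrl == HET).sum(axis=0)
    absent = (ctrl_hom == 0) & (ctrl_het == 0)
    if scen.name == "denovo_postzygotic":
        mask = callable_ & (gc == HET) & (gs == HOM_REF) & (gd == HOM_REF) & absent
    else:  # denovo_mosaic
        mask = callable_ & (gc == HET) & (gs == HET) & (gd == HOM_REF) & absent
    return _candidates(matrix, mask, trio, scen, gc, gs, gd, ctrl_hom, ctrl_het)
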