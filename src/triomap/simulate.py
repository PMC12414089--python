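"""Gene-dropping simulator for consanguineous trio WGS studies.

Generates diploid biallelic genotypes over a scaled 29-autosome genome
by dropping founder haplotypes through a configurable pedigree with
Poisson recombination, implants a causal recessive allele on one
haplotype of the pedigree's shared ancestor, and forces the case to be
autozygous for it by rejection sampling over the meioses of the causal
chromosome (so recombination still shapes realistic segment
boundaries).  The emitted truth table records the implanted variant,
the case's surrounding identity-by-descent segment, and per-individual
carrier status, which downstream modules use as oracles.

Pedigree templates
------------------
``consanguineous_mating``
    the case's sire is also its maternal grandsire (sire x daughter),
    the tightest loop; the case's parents have kinship 1/4.
``inbreeding_loop``
    the case's parents descend through separate chains from one common
    founder couple several generations back (first cousins at minimal
    depth, kinship 1/16, halving per extra generation of depth).
``outbred``
    the parents share no ancestor.

Chromosome lengths default to 10 Mb - a desk-scale stand-in - so ROH
thresholds stated in kb remain exercisable; every downstream threshold
is configurable.  Founder allele frequencies are drawn uniformly on
[0.05, 0.5]; there is no background linkage disequilibrium beyond the
pedigree-induced IBD.  With zero error and missing rates, genotypes are
Mendelian-consistent by construction (except at the implanted site in
the two de novo modes, which is the point of those modes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .datamodel import (HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix,
                        Pedigree, PedigreeRecord, TriomapError, VariantSite)
from .io import dump_config, write_pedigree, write_vcf

TEMPLATES = ("consanguineous_mating", "inbreeding_loop", "outbred")
MODES = ("recessive", "denovo", "mosaic")

_NUC = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    n_autosomes: int = 29
    chrom_length_bp: int = 10_000_000
    n_sites_per_chrom: int = 800
    af_low: float = 0.05
    af_high: float = 0.5
    recomb_rate_morgan_per_bp: float = 1e-8  # 1 cM/Mb
    template: str = "consanguineous_mating"
    depth: int = 3
    n_controls: int = 100
    mode: str = "recessive"
    causal_chrom: str = "1"
    causal_pos: int = 5_000_000
    causal_impact: str = "MODERATE"
    causal_gene: str = "TYR"
    causal_votes: int = 4
    #: impact class mixture for background sites
    impact_probs: tuple[float, ...] = (0.01, 0.05, 0.04, 0.90)  # HIGH,MODERATE,LOW,MODIFIER
    error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    max_rejection: int = 5000

    def __post_init__(self) -> None:
        for r in (self.af_low, self.af_high, self.error_rate, self.missing_rate):
            if not (0.0 <= r <= 1.0):
                raise TriomapError("rates and frequencies must lie in [0, 1]")
        if self.n_sites_per_chrom < 2:
            raise TriomapError("need at least 2 sites per chromosome")
        if self.template not in TEMPLATES:
            raise TriomapError(f"unknown template {self.template!r}")
        if self.mode not in MODES:
            raise TriomapError(f"unknown mode {self.mode!r}")
        if self.causal_impact not in ("HIGH", "MODERATE"):
            raise TriomapError("causal variant must be protein-changing")


@dataclass(frozen=True)
class CausalTruth:
    case: str
    variant_id: str
    chrom: str
    pos: int
    #: autozygous (IBD) segment around the causal site, 1-based inclusive;
    #: zero-length (start==end==pos) is impossible under recessive mode
    ibd_start_bp: int
    ibd_end_bp: int
    carriers: dict[str, int] = field(default_factory=dict, hash=False, compare=False)


@dataclass
class TruthTable:
    entries: list[CausalTruth]

    def for_case(self, case: str) -> CausalTruth:
        for e in self.entries:
            if e.case == case:
                return e
        raise KeyError(case)


@dataclass
class SimResult:
    matrix: GenotypeMatrix
    pedigree: Pedigree
    truth: TruthTable
    #: in-silico vote counts per protein-changing variant_id (evidence input)
    evidence: dict[str, int]
    config: SimConfig

    @property
    def genome_denominator_bp(self) -> int:
        return self.config.n_autosomes * self.config.chrom_length_bp


# -- pedigree construction ----------------------------------------------


def build_pedigree(template: str, depth: int, n_controls: int = 0,
                   prefix: str = "") -> Pedigree:
    """Build one of the study pedigree templates plus founder controls.

    ``depth`` counts generations from the topmost ancestors to the case
    (consanguineous_mating needs >= 3, inbreeding_loop >= 4, outbred
    >= 2); too small a depth cannot close the loop and raises.
    """
    P = prefix
    recs: list[PedigreeRecord] = []

    def founder(iid: str, sex: int) -> str:
        recs.append(PedigreeRecord(P + iid, "0", "0", sex, "control"))
        return P + iid

    def child(iid: str, sire: str, dam: str, sex: int, role: str = "control") -> str:
        recs.append(PedigreeRecord(P + iid, sire, dam, sex, role))
        return P + iid

    if template == "consanguineous_mating":
        if depth < 3:
            raise TriomapError("consanguineous_mating needs depth >= 3 "
                               "to close the sire-daughter loop")
        # chain of founder ancestors above the sire for depth > 3
        top = founder("A1", 1)
        for g in range(2, depth - 1):
            mate = founder(f"A{g}m", 2)
            top = child(f"A{g}", top, mate, 1)
        sire = top
        gdam = founder("GDAM", 2)
        dam = child("DAM", sire, gdam, 2, "dam")
        # re-tag the sire record with its role
        recs = [replace(r, role="sire") if r.iid == sire else r for r in recs]
        child("CASE", sire, dam, 1, "case")
    elif template == "inbreeding_loop":
        if depth < 4:
            raise TriomapError("inbreeding_loop needs depth >= 4 so the "
                               "common ancestors sit >= 2 generations back")
        gs = founder("GS", 1)
        gd = founder("GD", 2)
        # two descent chains of depth-2 meioses each down to sire and dam
        a = child("L1", gs, gd, 1)
        b = child("R1", gs, gd, 2)
        for g in range(2, depth - 1):
            a = child(f"L{g}", a, founder(f"L{g}m", 2), 1)
            b = child(f"R{g}", founder(f"R{g}s", 1), b, 2)
        recs = [replace(r, role="sire") if r.iid == a else
                replace(r, role="dam") if r.iid == b else r for r in recs]
        child("CASE", a, b, 1, "case")
    else:  # outbred
        if depth < 2:
            raise TriomapError("outbred pedigree needs depth >= 2")
        s = founder("PS1", 1)
        d = founder("PD1", 2)
        for g in range(2, depth):
            s = child(f"PS{g}", s, founder(f"PS{g}m", 2), 1)
            d = child(f"PD{g}", founder(f"PD{g}s", 1), d, 2)
        recs = [replace(r, role="sire") if r.iid == s else
                replace(r, role="dam") if r.iid == d else r for r in recs]
        child("CASE", s, d, 1, "case")

    for k in range(1, n_controls + 1):
        founder(f"CTRL{k:03d}", 1 + (k % 2))
    return Pedigree(recs)


def shared_ancestor(pedigree: Pedigree, template: str, prefix: str = "") -> str:
    """The individual whose haplotype seeds the causal recessive allele."""
    if template == "consanguineous_mating":
        case = pedigree.get(prefix + "CASE")
        return case.sire
    if template == "inbreeding_loop":
        return prefix + "GS"
    raise TriomapError("outbred pedigrees have no shared ancestor to seed")


def _causal_founders(pedigree: Pedigree, template: str, prefix: str
                     ) -> list[str]:
    """Founders whose first haplotype carries the causal allele.

    Looped templates seed one haplotype of the shared ancestor (the case
    becomes homozygous only by autozygosity); the outbred template seeds
    one founder on each parental line, so homozygosity arises without
    identity by descent.
    """
    if template in ("consanguineous_mating", "inbreeding_loop"):
        return [shared_ancestor(pedigree, template, prefix)]
    return [prefix + "PS1", prefix + "PD1"]


# -- gene drop -----------------------------------------------------------


def _meiosis(hap_a: np.ndarray, hap_b: np.ndarray, positions: np.ndarray,
             length_bp: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """One recombined gamete: crossover count ~ Poisson(length * rate),
    crossover positions uniform, starting haplotype fair."""
    n_x = rng.poisson(length_bp * rate)
    start = int(rng.integers(2))
    if n_x == 0:
        return (hap_a if start == 0 else hap_b).copy()
    cuts = np.sort(rng.integers(1, length_bp + 1, size=n_x))
    phase = (start + np.searchsorted(cuts, positions, side="right")) % 2
    return np.where(phase == 0, hap_a, hap_b)


def gene_drop(pedigree: Pedigree, config: SimConfig,
              causal_by_case: Optional[dict[str, tuple[str, int]]] = None,
              prefix_by_case: Optional[dict[str, str]] = None
              ) -> SimResult:
    """Drop genotypes through the pedigree and implant the causal allele.

    ``causal_by_case`` maps each case to its causal (chrom, pos); by
    default the single case uses ``config.causal_chrom/causal_pos``.
    Rejection sampling re-draws the meioses of each causal chromosome
    until the corresponding case is homozygous (recessive mode); it
    raises after ``config.max_rejection`` attempts with advice to use a
    deeper loop.
    """
    rng = np.random.default_rng(config.seed)
    cases = pedigree.cases()
    if causal_by_case is None:
        if len(cases) != 1:
            raise TriomapError("multi-case pedigrees need explicit causal_by_case")
        causal_by_case = {cases[0]: (config.causal_chrom, config.causal_pos)}
    prefix_by_case = prefix_by_case or {c: "" for c in cases}

    chroms = [str(c) for c in range(1, config.n_autosomes + 1)]
    L = config.chrom_length_bp
    n_sites = config.n_sites_per_chrom

    # site maps and founder frequencies
    positions = {c: np.sort(rng.choice(np.arange(1, L + 1), size=n_sites,
                                       replace=False)) for c in chroms}
    freqs = {c: rng.uniform(config.af_low, config.af_high, size=n_sites)
             for c in chroms}

    founders = pedigree.founders()
    hap_of = {f: (2 * i, 2 * i + 1) for i, f in enumerate(founders)}
    n_haps = 2 * len(founders)
    founder_alleles = {c: (rng.random((n_haps, n_sites)) < freqs[c]
                           ).astype(np.uint8) for c in chroms}

    # causal sites: nearest simulated site to the requested position
    causal_site = {}
    for case, (cc, cp) in causal_by_case.items():
        j = int(np.argmin(np.abs(positions[cc] - cp)))
        causal_site[case] = (cc, j)
    carrier_haps: dict[str, list[int]] = {}
    for case, (cc, j) in causal_site.items():
        founder_alleles[cc][:, j] = 0
        if config.mode == "recessive":
            haps = [hap_of[f][0] for f in _causal_founders(
                pedigree, config.template, prefix_by_case[case])]
            founder_alleles[cc][haps, j] = 1
            carrier_haps[case] = haps

    order = pedigree.topological_order()
    nonfounders = [i for i in order if pedigree.get(i).sire != "0"]

    def drop_chrom(c: str, chrom_rng: np.random.Generator
                   ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Ancestry (founder-haplotype id per site) for every individual."""
        anc: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for f in founders:
            a, b = hap_of[f]
            anc[f] = (np.full(n_sites, a, dtype=np.int32),
                      np.full(n_sites, b, dtype=np.int32))
        for iid in nonfounders:
            rec = pedigree.get(iid)
            pa = _meiosis(*anc[rec.sire], positions[c], L,
                          config.recomb_rate_morgan_per_bp, chrom_rng)
            pb = _meiosis(*anc[rec.dam], positions[c], L,
                          config.recomb_rate_morgan_per_bp, chrom_rng)
            anc[iid] = (pa, pb)
        return anc

    causal_chroms = {cc for cc, _ in causal_site.values()}
    ancestry: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for c in chroms:
        if c not in causal_chroms or config.mode != "recessive":
            ancestry[c] = drop_chrom(c, rng)
            continue
        # rejection sampling: redraw this chromosome's meioses until every
        # case whose causal site lives here is homozygous for the allele
        targets = [(case, j) for case, (cc, j) in causal_site.items() if cc == c]
        for attempt in range(config.max_rejection):
            anc = drop_chrom(c, rng)
            ok = True
            alle = founder_alleles[c]
            for case, j in targets:
                ha, hb = anc[case]
                if not (alle[ha[j], j] == 1 and alle[hb[j], j] == 1):
                    ok = False
                    break
            if ok:
                ancestry[c] = anc
                break
        else:
            raise TriomapError(
                f"rejection sampling failed after {config.max_rejection} "
                f"attempts on chromosome {c}; the pedigree loop may be too "
                "deep for homozygosity to be reachable - use a shallower "
                "template or raise max_rejection")

    # genotypes
    samples = pedigree.individuals
    site_arange = np.arange(n_sites)
    geno = {c: np.empty((len(samples), n_sites), dtype=np.int8) for c in chroms}
    for c in chroms:
        alle = founder_alleles[c]
        for i, iid in enumerate(samples):
            ha, hb = ancestry[c][iid]
            geno[c][i] = alle[ha, site_arange] + alle[hb, site_arange]

    # de novo / mosaic: overwrite the causal site after the drop
    if config.mode in ("denovo", "mosaic"):
        for case, (cc, j) in causal_site.items():
            geno[cc][:, j] = HOM_REF
            geno[cc][samples.index(case), j] = HET
            if config.mode == "mosaic":
                sire = pedigree.get(case).sire
                geno[cc][samples.index(sire), j] = HET

    # truth: IBD segment around each causal site (pre error injection)
    truth_entries = []
    site_meta: dict[tuple[str, int], tuple[str, str]] = {}  # (chrom,j) -> (gene,impact)
    for case, (cc, j) in causal_site.items():
        ha, hb = ancestry[cc][case]
        if config.mode == "recessive" and ha[j] == hb[j]:
            # autozygous: extend the run of shared haplotype ancestry
            ibd = ha == hb
            lo = j
            while lo > 0 and ibd[lo - 1]:
                lo -= 1
            hi = j
            while hi < n_sites - 1 and ibd[hi + 1]:
                hi += 1
            seg = (int(positions[cc][lo]), int(positions[cc][hi]))
        else:
            seg = (int(positions[cc][j]), int(positions[cc][j]))
        carriers = {iid: int(geno[cc][i, j]) for i, iid in enumerate(samples)}
        truth_entries.append(CausalTruth(
            case=case, variant_id="", chrom=cc, pos=int(positions[cc][j]),
            ibd_start_bp=seg[0], ibd_end_bp=seg[1], carriers=carriers))
        site_meta[(cc, j)] = (config.causal_gene, config.causal_impact)

    # error / missingness injection
    for c in chroms:
        g = geno[c]
        if config.error_rate > 0:
            err = rng.random(g.shape) < config.error_rate
            shift = rng.integers(1, 3, size=g.shape)
            g[err] = (g[err] + shift[err]) % 3
        if config.missing_rate > 0:
            g[rng.random(g.shape) < config.missing_rate] = MISSING

    # site annotations and assembly
    impact_names = ("HIGH", "MODERATE", "LOW", "MODIFIER")
    sites: list[VariantSite] = []
    call_blocks = []
    evidence: dict[str, int] = {}
    vote_probs = (0.55, 0.25, 0.12, 0.05, 0.02, 0.01)
    for c in chroms:
        imp_idx = rng.choice(4, size=n_sites, p=config.impact_probs)
        ref_idx = rng.integers(0, 4, size=n_sites)
        alt_off = rng.integers(1, 4, size=n_sites)
        votes_bg = rng.choice(6, size=n_sites, p=vote_probs)
        for j in range(n_sites):
            gene, impact = site_meta.get(
                (c, j), (f"G{c}_{j // 25}", impact_names[imp_idx[j]]))
            ref = _NUC[ref_idx[j]]
            alt = _NUC[(ref_idx[j] + alt_off[j]) % 4]
            site = VariantSite(chrom=c, pos=int(positions[c][j]), ref=ref,
                               alt=alt, gene=gene, impact=impact)
            sites.append(site)
            if impact == "MODERATE":
                evidence[site.variant_id] = int(votes_bg[j])
            elif impact == "HIGH":
                # loss-of-function alleles are not scorable by the
                # missense predictors; no in-silico votes
                evidence[site.variant_id] = 0
        call_blocks.append(geno[c])

    matrix = GenotypeMatrix(samples, sites, np.concatenate(call_blocks, axis=1))

    # fill variant ids into truth, override causal votes
    final_entries = []
    for e in truth_entries:
        idx = matrix.chrom_indices()[e.chrom]
        pos_arr = matrix.positions[idx]
        j = int(idx[np.searchsorted(pos_arr, e.pos)])
        vid = matrix.sites[j].variant_id
        evidence[vid] = config.causal_votes
        final_entries.append(replace(e, variant_id=vid))

    return SimResult(matrix=matrix, pedigree=pedigree,
                     truth=TruthTable(final_entries), evidence=evidence,
                     config=config)


# -- top-level scenarios -------------------------------------------------


def simulate_trio_dataset(config: SimConfig = SimConfig()) -> SimResult:
    """One affected trio (plus controls) with an implanted causal allele."""
    ped = build_pedigree(config.template, config.depth, config.n_controls)
    return gene_drop(ped, config)


def simulate_multi_trio_dataset(config: SimConfig, n_trios: int = 3
                                ) -> SimResult:
    """Several independent affected families sharing one control pool
    and one site map, each with its own private causal allele on its own
    chromosome - the negative-control design for shared-allele and
    shared-ROH searches."""
    if n_trios > config.n_autosomes:
        raise TriomapError("more trios than chromosomes to host causal sites")
    recs: list[PedigreeRecord] = []
    prefixes = [f"F{k}_" for k in range(1, n_trios + 1)]
    for pfx in prefixes:
        recs.extend(build_pedigree(config.template, config.depth, 0,
                                   prefix=pfx).records)
    for k in range(1, config.n_controls + 1):
        recs.append(PedigreeRecord(f"CTRL{k:03d}", "0", "0", 1 + (k % 2),
                                   "control"))
    ped = Pedigree(recs)
    causal = {f"{pfx}CASE": (str(k + 1), config.causal_pos)
              for k, pfx in enumerate(prefixes)}
    prefix_by_case = {f"{pfx}CASE": pfx for pfx in prefixes}
    return gene_drop(ped, config, causal_by_case=causal,
                     prefix_by_case=prefix_by_case)


# -- emission ------------------------------------------------------------


def emit(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write VCF, pedigree, truth and evidence tables plus a config echo.

    Deterministic ordering throughout: a fixed seed yields byte-identical
    files on repeated runs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "data.vcf",
        "ped": outdir / "pedigree.ped",
        "truth": outdir / "truth.tsv",
        "evidence": outdir / "evidence.tsv",
        "config": outdir / "config-echo.yaml",
    }
    contigs = {str(c): result.config.chrom_length_bp
               for c in range(1, result.config.n_autosomes + 1)}
    write_vcf(result.matrix, paths["vcf"], contig_lengths=contigs)
    write_pedigree(result.pedigree, paths["ped"])
    with paths["truth"].open("w") as fh:
        fh.write("case\tvariant_id\tchrom\tpos\tibd_start_bp\tibd_end_bp\tcarriers\n")
        for e in result.truth.entries:
            carr = ",".join(f"{k}:{v}" for k, v in sorted(e.carriers.items()))
            fh.write(f"{e.case}\t{e.variant_id}\t{e.chrom}\t{e.pos}\t"
                     f"{e.ibd_start_bp}\t{e.ibd_end_bp}\t{carr}\n")
    with paths["evidence"].open("w") as fh:
        fh.write("variant_id\tvotes\n")
        for vid in sorted(result.evidence):
            fh.write(f"{vid}\t{result.evidence[vid]}\n")
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in vars(result.config).items()}
    dump_config(cfg, paths["config"])
    return paths
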