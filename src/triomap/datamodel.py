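"""Core domain types shared by every analysis stage.

The package works on diploid, biallelic SNV/indel genotypes over the 29
bovine-style autosomes.  All coordinates are 1-based inclusive (VCF/HGVS
convention); conversion to 0-based half-open happens only at the BED
boundary in :mod:`triomap.io`.

Genotype call codes
-------------------
========  =====================
code      meaning
========  =====================
``0``     homozygous reference
``1``     heterozygous
``2``     homozygous alternate
``-1``    missing / no call
========  =====================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

VALID_CALLS = frozenset({HOM_REF, HET, HOM_ALT, MISSING})
IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")

#: Total autosomal length covered by SNV positions in the real cattle
#: genotype set this pipeline models; the default denominator for F_ROH.
BOVINE_AUTOSOME_SNV_BP = 2_488_313_529


class TriomapError(ValueError):
    """Base error for invalid inputs to triomap."""


@dataclass(frozen=True)
class VariantSite:
    """A biallelic variant site with its functional annotation.

    ``impact`` is the annotation severity class consumed from upstream
    functional annotation (HIGH = loss-of-function, MODERATE =
    protein-changing, LOW, MODIFIER); triomap never computes it.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    impact: str = "MODIFIER"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise TriomapError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise TriomapError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.impact not in IMPACT_CLASSES:
            raise TriomapError(f"unknown impact class {self.impact!r}")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


class GenotypeMatrix:
    """Samples x sites matrix of genotype call codes plus site metadata.

    Sites are strictly sorted by ``(chrom, pos)`` with numeric chromosome
    ordering and carry no duplicate variant ids.  ``calls`` is an
    ``int8`` array of shape ``(n_samples, n_sites)``.
    """

    def __init__(self, samples: Sequence[str], sites: Sequence[VariantSite],
                 calls: np.ndarray) -> None:
        self.samples = list(samples)
        self.sites = list(sites)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(self.samples), len(self.sites)):
            raise TriomapError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites")
        bad = ~np.isin(calls, (HOM_REF, HET, HOM_ALT, MISSING))
        if bad.any():
            raise TriomapError(f"invalid call codes present: {np.unique(calls[bad])}")
        self.calls = calls
        keys = [(_chrom_key(s.chrom), s.pos, s.ref, s.alt) for s in self.sites]
        if any(keys[i] >= keys[i + 1] for i in range(len(keys) - 1)):
            raise TriomapError("sites must be strictly sorted by (chrom, pos, ref, alt)")
        ids = [s.variant_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise TriomapError("duplicate variant ids")
        self._sample_idx = {s: i for i, s in enumerate(self.samples)}
        if len(self._sample_idx) != len(self.samples):
            raise TriomapError("duplicate sample ids")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def variant_ids(self) -> list[str]:
        return [s.variant_id for s in self.sites]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([s.chrom for s in self.sites])

    def sample_calls(self, sample: str) -> np.ndarray:
        return self.calls[self._sample_idx[sample]]

    def sample_index(self, sample: str) -> int:
        return self._sample_idx[sample]

    def chrom_indices(self) -> dict[str, np.ndarray]:
        """Site index array per chromosome, in matrix order."""
        out: dict[str, np.ndarray] = {}
        chroms = self.chroms
        for c in dict.fromkeys(chroms.tolist()):
            out[c] = np.flatnonzero(chroms == c)
        return out

    # -- subsetting ------------------------------------------------------
    def subset_sites(self, mask_or_index: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        sites = [self.sites[i] for i in idx]
        return GenotypeMatrix(self.samples, sites, self.calls[:, idx])

    def subset_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        rows = [self._sample_idx[s] for s in samples]
        return GenotypeMatrix(list(samples), self.sites, self.calls[rows])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (self.samples == other.samples and self.sites == other.sites
                and np.array_equal(self.calls, other.calls))

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_sites} sites)"


def _chrom_key(chrom: str) -> tuple[int, str]:
    try:
        return (int(chrom), "")
    except ValueError:
        return (10**9, chrom)


# -- pedigree ------------------------------------------------------------

ROLES = ("case", "sire", "dam", "control")


@dataclass(frozen=True)
class PedigreeRecord:
    iid: str
    sire: str  # "0" if unknown / founder
    dam: str
    sex: int  # 1 male, 2 female, 0 unknown
    role: str = "control"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise TriomapError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class Trio:
    case: str
    sire: str
    dam: str


class Pedigree:
    """A set of individuals with parent links; validates acyclicity."""

    def __init__(self, records: Iterable[PedigreeRecord]) -> None:
        self.records = list(records)
        self._by_id = {r.iid: r for r in self.records}
        if len(self._by_id) != len(self.records):
            raise TriomapError("duplicate individual ids in pedigree")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(iid: str, stack: list[str]) -> None:
            if iid not in self._by_id:
                return
            st = state.get(iid)
            if st == 1:
                return
            if st == 0:
                raise TriomapError(f"pedigree cycle involving {' -> '.join(stack + [iid])}")
            state[iid] = 0
            rec = self._by_id[iid]
            for parent in (rec.sire, rec.dam):
                if parent != "0":
                    visit(parent, stack + [iid])
            state[iid] = 1

        for r in self.records:
            visit(r.iid, [])

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, iid: str) -> PedigreeRecord:
        return self._by_id[iid]

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    @property
    def individuals(self) -> list[str]:
        return [r.iid for r in self.records]

    def founders(self) -> list[str]:
        return [r.iid for r in self.records if r.sire == "0" and r.dam == "0"]

    def cases(self) -> list[str]:
        return [r.iid for r in self.records if r.role == "case"]

    def controls(self) -> list[str]:
        return [r.iid for r in self.records if r.role == "control"]

    def trios(self) -> list[Trio]:
        """Each case with both parents present forms a trio."""
        out = []
        for r in self.records:
            if r.role != "case":
                continue
            if r.sire == "0" or r.dam == "0":
                raise TriomapError(f"case {r.iid} lacks a recorded sire/dam")
            if r.sire not in self._by_id or r.dam not in self._by_id:
                raise TriomapError(f"case {r.iid}: parents not in pedigree")
            out.append(Trio(case=r.iid, sire=r.sire, dam=r.dam))
        return out

    def topological_order(self) -> list[str]:
        """Parents before offspring."""
        order: list[str] = []
        seen: set[str] = set()

        def visit(iid: str) -> None:
            if iid in seen or iid not in self._by_id:
                return
            seen.add(iid)
            rec = self._by_id[iid]
            for p in (rec.sire, rec.dam):
                if p != "0":
                    visit(p)
            order.append(iid)

        for r in self.records:
            visit(r.iid)
        return order


# -- cohort genotype counts ----------------------------------------------


class CohortCounts:
    """Per (variant, population) genotype count triples.

    Thin wrapper over a DataFrame with columns ``variant_id, population,
    n_varvar, n_refvar, n_refref, includes_case``.  Population labels use
    the convention ``<breed>_<cohort>`` (e.g. ``Simmental_wgs``,
    ``others_array``); the breed is everything before the final
    underscore.
    """

    COLUMNS = ["variant_id", "population", "n_varvar", "n_refvar", "n_refref",
               "includes_case"]

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise TriomapError(f"cohort counts missing columns {missing}")
        df = df[self.COLUMNS].copy()
        for c in ("n_varvar", "n_refvar", "n_refref"):
            df[c] = df[c].astype(int)
            if (df[c] < 0).any():
                raise TriomapError(f"negative count in column {c}")
        df["includes_case"] = df["includes_case"].astype(bool)
        self.df = df.reset_index(drop=True)

    def variant_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["variant_id"]))

    def populations(self, variant_id: str) -> list[str]:
        return list(self.df.loc[self.df["variant_id"] == variant_id, "population"])

    def rows(self, variant_id: str, populations: Optional[Sequence[str]] = None
             ) -> pd.DataFrame:
        sub = self.df[self.df["variant_id"] == variant_id]
        if populations is not None:
            sub = sub[sub["population"].isin(populations)]
        return sub

    @staticmethod
    def breed_of(population: str) -> str:
        return population.rsplit("_", 1)[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortCounts):
            return NotImplemented
        return self.df.equals(other.df)


# -- ROH -----------------------------------------------------------------


@dataclass(frozen=True)
class ROHSegment:
    """A run of homozygosity; coordinates 1-based inclusive at SNV positions."""

    sample: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snv: int

    def __post_init__(self) -> None:
        if self.end_bp < self.start_bp:
            raise TriomapError("segment end before start")
        if self.n_snv < 1:
            raise TriomapError("segment with no SNVs")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start_bp <= pos <= self.end_bp


@dataclass
class ROHProfile:
    sample: str
    segments: list[ROHSegment]
    genome_denominator_bp: int = BOVINE_AUTOSOME_SNV_BP

    @property
    def f_roh(self) -> float:
        from .roh import f_roh  # local import to avoid cycle
        return f_roh(self.segments, self.genome_denominator_bp)

    @property
    def total_length_bp(self) -> int:
        return sum(s.length_bp for s in self.segments)

    @property
    def mean_length_bp(self) -> float:
        if not self.segments:
            return 0.0
        return self.total_length_bp / len(self.segments)


# -- relatedness ---------------------------------------------------------


@dataclass(frozen=True)
class RelatednessEstimate:
    sample_a: str
    sample_b: str
    z0: float
    z1: float
    z2: float
    n_sites: int

    @property
    def pi_hat(self) -> float:
        return self.z1 / 2.0 + self.z2


# -- candidate variants --------------------------------------------------


@dataclass
class CandidateVariant:
    """A site that survived one of the Mendelian filtering scenarios."""

    site: VariantSite
    scenario: str
    case: str
    case_call: int
    sire_call: int
    dam_call: int
    control_hom: int
    control_het: int
    roh_segment: Optional[ROHSegment] = None
    votes: Optional[int] = None
    known_candidate_gene: Optional[bool] = None
    breed_specific: Optional[bool] = None
    classification: Optional[str] = None
    fired_rules: list[str] = field(default_factory=list)

    @property
    def variant_id(self) -> str:
        return self.site.variant_id
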