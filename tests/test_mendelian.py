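"""The four trio filtering scenarios and their invariants."""

import numpy as np
import pytest

import triomap as tm
from triomap.datamodel import (HET, HOM_ALT, HOM_REF, MISSING, Trio,
                               VariantSite)
from triomap.mendelian import (FilterScenario, filter_denovo,
                               filter_recessive_private,
                               filter_recessive_shared, impact_prefilter,
                               scenario)


def _matrix(columns, samples):
    """columns: list of (impact, {sample: call}); unlisted samples hom-ref."""
    sites = []
    calls = np.zeros((len(samples), len(columns)), dtype=np.int8)
    for j, (impact, geno) in enumerate(columns):
        sites.append(VariantSite("1", 100 * (j + 1), "A", "C",
                                 gene=f"g{j}", impact=impact))
        for s, call in geno.items():
            calls[samples.index(s), j] = call
    return tm.GenotypeMatrix(samples, sites, calls)


TRIO = Trio(case="CASE", sire="SIRE", dam="DAM")
SAMPLES = ["CASE", "SIRE", "DAM", "C1", "C2", "C3"]
CONTROLS = ["SIRE", "DAM", "C1", "C2", "C3"]


class TestImpactPrefilter:
    def test_keeps_protein_changing_only(self):
        m = _matrix([("MODIFIER", {}), ("HIGH", {}), ("LOW", {}),
                     ("MODERATE", {})], SAMPLES)
        kept = impact_prefilter(m)
        assert [s.impact for s in kept.sites] == ["HIGH", "MODERATE"]

    def test_equals_predicate_scan_on_simulated_sites(self, recessive_sim):
        m = recessive_sim.matrix
        kept = impact_prefilter(m)
        expected = [s.variant_id for s in m.sites
                    if s.impact in ("HIGH", "MODERATE")]
        assert kept.variant_ids == expected


class TestRecessivePrivate:
    def test_retention_and_obligate_carrier_rule(self):
        m = _matrix([
            ("MODERATE", {"CASE": HOM_ALT, "SIRE": HET, "DAM": HET}),  # keep
            ("MODERATE", {"CASE": HOM_ALT, "SIRE": HET, "DAM": HOM_REF}),  # dam 0
            ("MODERATE", {"CASE": HET, "SIRE": HET, "DAM": HET}),  # case not hom
        ], SAMPLES)
        got = filter_recessive_private(m, TRIO, CONTROLS)
        assert [c.variant_id for c in got] == ["1:100:A:C"]
        assert got[0].case_call == HOM_ALT and got[0].control_hom == 0

    def test_control_homozygote_ceiling(self):
        base = {"CASE": HOM_ALT, "SIRE": HET, "DAM": HET}
        m = _matrix([
            ("MODERATE", {**base, "C1": HOM_ALT}),                  # 1 hom: keep
            ("MODERATE", {**base, "C1": HOM_ALT, "C2": HOM_ALT}),   # 2 homs: drop
            ("MODERATE", {**base, "C1": HET, "C2": HET}),           # carriers ok
        ], SAMPLES)
        got = filter_recessive_private(m, TRIO, CONTROLS)
        assert [c.variant_id for c in got] == ["1:100:A:C", "1:300:A:C"]

    def test_missing_trio_call_skips_site(self):
        m = _matrix([("MODERATE", {"CASE": HOM_ALT, "SIRE": MISSING,
                                   "DAM": HET})], SAMPLES)
        assert filter_recessive_private(m, TRIO, CONTROLS) == []

    def test_simulated_causal_variant_retained(self, recessive_sim):
        res = recessive_sim
        protein = impact_prefilter(res.matrix)
        trio = res.pedigree.trios()[0]
        controls = [s for s in res.matrix.samples if s != trio.case]
        got = filter_recessive_private(protein, trio, controls)
        assert res.truth.for_case(trio.case).variant_id in \
            {c.variant_id for c in got}


class TestRecessiveShared:
    def test_same_allele_in_all_trios_is_retained(self):
        trios = [Trio("CASE", "SIRE", "DAM"), Trio("K2", "S2", "D2")]
        samples = ["CASE", "SIRE", "DAM", "K2", "S2", "D2", "C1"]
        shared_site = ("MODERATE", {"CASE": HOM_ALT, "SIRE": HET, "DAM": HET,
                                    "K2": HOM_ALT, "S2": HET, "D2": HET})
        private_site = ("MODERATE", {"CASE": HOM_ALT, "SIRE": HET, "DAM": HET})
        m = _matrix([shared_site, private_site], samples)
        controls = {t.case: [s for s in samples if s != t.case] for t in trios}
        got = filter_recessive_shared(m, trios, controls)
        assert {c.variant_id for v in got.values() for c in v} == {"1:100:A:C"}

    def test_distinct_private_alleles_yield_empty_set(self):
        """Reproduces the negative result: cases homozygous for different
        private alleles share no candidate."""
        trios = [Trio("CASE", "SIRE", "DAM"), Trio("K2", "S2", "D2")]
        samples = ["CASE", "SIRE", "DAM", "K2", "S2", "D2"]
        m = _matrix([
            ("MODERATE", {"CASE": HOM_ALT, "SIRE": HET, "DAM": HET}),
            ("MODERATE", {"K2": HOM_ALT, "S2": HET, "D2": HET}),
        ], samples)
        controls = {t.case: [s for s in samples if s != t.case] for t in trios}
        got = filter_recessive_shared(m, trios, controls)
        assert all(v == [] for v in got.values())

    def test_equals_bruteforce_intersection(self, recessive_sim):
        """Shared filter == per-trio private filters intersected by id."""
        res = recessive_sim
        protein = impact_prefilter(res.matrix)
        trio = res.pedigree.trios()[0]
        fake = Trio(case="CTRL001", sire="CTRL002", dam="CTRL003")
        trios = [trio, fake]
        controls = {t.case: [s for s in res.matrix.samples if s != t.case]
                    for t in trios}
        got = filter_recessive_shared(protein, trios, controls)
        per_trio = [
            {c.variant_id for c in filter_recessive_private(
                protein, t, controls[t.case], scenario("recessive_shared"))}
            for t in trios]
        expected = set.intersection(*per_trio)
        assert {c.variant_id for v in got.values() for c in v} == expected


class TestDenovo:
    def test_scenario_patterns(self):
        m = _matrix([
            ("MODERATE", {"CASE": HET}),                    # postzygotic
            ("MODERATE", {"CASE": HET, "SIRE": HET}),       # mosaic
            ("MODERATE", {"CASE": HET, "DAM": HET}),        # inherited: neither
            ("MODERATE", {"CASE": HET, "C1": HET}),         # present in control
        ], SAMPLES)
        post = filter_denovo(m, TRIO, CONTROLS, scenario("denovo_postzygotic"))
        mosa = filter_denovo(m, TRIO, CONTROLS, scenario("denovo_mosaic"))
        assert [c.variant_id for c in post] == ["1:100:A:C"]
        assert [c.variant_id for c in mosa] == ["1:200:A:C"]

    def test_mosaic_simulation_recovered(self):
        cfg = tm.SimConfig(mode="mosaic", seed=13, n_controls=30,
                           n_sites_per_chrom=80, n_autosomes=4)
        res = tm.simulate_trio_dataset(cfg)
        trio = res.pedigree.trios()[0]
        controls = [s for s in res.matrix.samples if s != trio.case]
        protein = impact_prefilter(res.matrix)
        got = filter_denovo(protein, trio, controls, scenario("denovo_mosaic"))
        assert res.truth.for_case(trio.case).variant_id in \
            {c.variant_id for c in got}

    def test_scenario_settings_validated(self):
        with pytest.raises(tm.TriomapError):
            FilterScenario("denovo_postzygotic", allow_control_het=True)
        with pytest.raises(tm.TriomapError):
            FilterScenario("denovo_mosaic", allow_control_het=False,
                           exclude_sire_from_controls=False)
        with pytest.raises(tm.TriomapError):
            FilterScenario("recessive_private", exclude_sire_from_controls=True)


class TestScenarioInvariants:
    def test_recessive_and_postzygotic_outputs_disjoint(self, recessive_sim):
        res = recessive_sim
        protein = impact_prefilter(res.matrix)
        trio = res.pedigree.trios()[0]
        controls = [s for s in res.matrix.samples if s != trio.case]
        rec = {c.variant_id
               for c in filter_recessive_private(protein, trio, controls)}
        dnv = {c.variant_id
               for c in filter_denovo(protein, trio, controls,
                                      scenario("denovo_postzygotic"))}
        assert rec.isdisjoint(dnv)

    def test_filters_idempotent_over_site_subsets(self, recessive_sim):
        """Filtering the already-retained site subset returns it unchanged."""
        res = recessive_sim
        protein = impact_prefilter(res.matrix)
        trio = res.pedigree.trios()[0]
        controls = [s for s in res.matrix.samples if s != trio.case]
        first = filter_recessive_private(protein, trio, controls)
        ids = {c.variant_id for c in first}
        sub = protein.subset_sites(
            np.array([vid in ids for vid in protein.variant_ids]))
        second = filter_recessive_private(sub, trio, controls)
        assert {c.variant_id for c in second} == ids
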