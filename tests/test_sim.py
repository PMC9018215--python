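"""Simulator: gene dropping, phenotype model, reference cohort, CAD liability."""
import dataclasses
import filecmp

import numpy as np
import pytest
from scipy.stats import chisquare

from hyperlpa import sim
from hyperlpa.core import (
    KIV2_4925,
    RS140570886,
    RS186696265,
    RS3798220,
    ConfigurationError,
    LpaAllele,
    PedigreeMember,
    StructureError,
)


def _couple_with_children(n_children):
    members = [
        PedigreeMember(member_id="F", sex="male"),
        PedigreeMember(member_id="M", sex="female"),
    ]
    members += [
        PedigreeMember(member_id=f"C{i}", father_id="F", mother_id="M")
        for i in range(n_children)
    ]
    return members


def _plain_allele(aid, kiv=30, expr=10.0, flags=()):
    return LpaAllele(allele_id=aid, kiv_count=kiv, snp_flags=frozenset(flags),
                     base_expression=expr)


class TestGeneDrop:
    def test_child_alleles_closed_over_parental_pairs(self):
        fa = {"F": (_plain_allele("A"), _plain_allele("B")),
              "M": (_plain_allele("C"), _plain_allele("D"))}
        drop = sim.gene_drop(_couple_with_children(5), fa, seed=3)
        for i in range(5):
            pat, mat = drop[f"C{i}"]
            assert pat.allele_id in {"A", "B"}
            assert mat.allele_id in {"C", "D"}

    def test_missing_founder_assignment_is_configuration_error(self):
        fa = {"F": (_plain_allele("A"), _plain_allele("B"))}
        with pytest.raises(ConfigurationError):
            sim.gene_drop(_couple_with_children(1), fa, seed=0)

    def test_cyclic_pedigree_is_structure_error(self):
        members = [
            PedigreeMember(member_id="X", father_id="Y", mother_id="Z"),
            PedigreeMember(member_id="Y", father_id="X", mother_id="Z"),
            PedigreeMember(member_id="Z"),
        ]
        with pytest.raises(StructureError):
            sim.gene_drop(members, {"Z": (_plain_allele("a"), _plain_allele("b"))},
                          seed=0)

    def test_deterministic_under_fixed_seed(self):
        fa = {"F": (_plain_allele("A"), _plain_allele("B")),
              "M": (_plain_allele("C"), _plain_allele("D"))}
        ped = _couple_with_children(10)
        d1 = sim.gene_drop(ped, fa, seed=11)
        d2 = sim.gene_drop(ped, fa, seed=11)
        assert {k: (a.allele_id, b.allele_id) for k, (a, b) in d1.items()} == \
               {k: (a.allele_id, b.allele_id) for k, (a, b) in d2.items()}

    def test_transmission_frequency_and_mendelian_consistency(self):
        # 10,000 offspring of an (A,B) x (C,D) couple: allele A transmitted
        # with binomial frequency 0.5 +- 0.015, every child's alleles being
        # copies of parental alleles
        fa = {"F": (_plain_allele("A"), _plain_allele("B")),
              "M": (_plain_allele("C"), _plain_allele("D"))}
        ped = _couple_with_children(10_000)
        drop = sim.gene_drop(ped, fa, seed=1234)
        n_a = 0
        for i in range(10_000):
            pat, mat = drop[f"C{i}"]
            assert pat in fa["F"] and mat in fa["M"]
            n_a += pat.allele_id == "A"
        assert abs(n_a / 10_000 - 0.5) <= 0.015

    def test_template_high_labels_match_21kiv_carriage(self):
        # every member labelled high carries the 21-KIV allele, except the
        # spouse II-C1 and his daughter III-C3 whose elevation comes from
        # the 15-KIV allele that entered the pedigree by marriage
        drop = sim.template_gene_drop()
        carriers = {m for m, pair in drop.items()
                    if any(a.kiv_count == 21 for a in pair)}
        high = {m.member_id for m in sim.figure_pedigree()
                if m.lpa_phenotype == "high"}
        assert high - carriers == {"II-C1", "III-C3"}
        normal = {m.member_id for m in sim.figure_pedigree()
                  if m.lpa_phenotype == "normal"}
        assert not (normal & carriers)

    def test_template_transmission_is_mendelian(self):
        drop = sim.template_gene_drop()
        by_id = {m.member_id: m for m in sim.figure_pedigree()}
        for mid, (pat, mat) in drop.items():
            m = by_id[mid]
            if m.is_founder:
                continue
            assert pat in drop[m.father_id]
            assert mat in drop[m.mother_id]


class TestLpaAllele:
    def test_kiv_count_bounds(self):
        with pytest.raises(ConfigurationError):
            _plain_allele("bad", kiv=9)
        with pytest.raises(ConfigurationError):
            _plain_allele("bad", kiv=51)

    def test_kiv2_copies(self):
        assert _plain_allele("a", kiv=21).kiv2_copies == 12

    def test_expression_curve_monotone_in_isoform_size(self):
        cfg = sim.SimConfig()
        sizes = range(10, 51)
        exprs = [cfg.expression(k) for k in sizes]
        assert all(a > b for a, b in zip(exprs, exprs[1:]))


class TestSimulateLpa:
    def test_two_null_alleles_give_zero(self):
        cfg = sim.SimConfig(noise_sigma=0.0)
        null = _plain_allele("null", kiv=40, expr=0.0)
        rec = sim.simulate_lpa((null, null), cfg, seed=0)
        assert rec.lpa_nmol_l == pytest.approx(0.0)

    def test_rare_snps_strictly_raise_lpa(self):
        cfg = sim.SimConfig(noise_sigma=0.0)
        bare = sim.make_allele("bare21", 21, (), cfg)
        loaded = sim.make_allele("a21", 21,
                                 (RS3798220, RS186696265, RS140570886), cfg)
        other = sim.make_allele("n30", 30, (), cfg)
        low = sim.simulate_lpa((bare, other), cfg, seed=0).lpa_nmol_l
        high = sim.simulate_lpa((loaded, other), cfg, seed=0).lpa_nmol_l
        assert high > low

    def test_unknown_snp_flag_is_configuration_error(self):
        cfg = sim.SimConfig()
        odd = LpaAllele("odd", 21, frozenset({"rs0000001"}), 10.0)
        with pytest.raises(ConfigurationError):
            sim.simulate_lpa((odd, odd), cfg, seed=0)

    def test_monte_carlo_mean_matches_closed_form(self):
        cfg = sim.SimConfig()
        a = sim.make_allele("a21", 21, (RS3798220, RS186696265, RS140570886), cfg)
        b = sim.make_allele("n30", 30, (), cfg)
        expected = sim.expected_lpa((a, b), cfg)
        rng = np.random.default_rng(5)
        draws = np.array([sim.simulate_lpa((a, b), cfg, seed=rng).lpa_nmol_l
                          for _ in range(5000)])
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 3 * se

    def test_dominant_fraction_bounds_and_enhancer_draw(self):
        cfg = sim.SimConfig()
        a = sim.make_allele("a21", 21, (RS186696265, RS140570886, RS3798220), cfg)
        b = sim.make_allele("n30", 30, (), cfg)
        rng = np.random.default_rng(9)
        fracs = [sim.simulate_lpa((a, b), cfg, seed=rng).dominant_isoform_fraction
                 for _ in range(500)]
        assert all(0.5 <= f <= 1.0 for f in fracs)
        assert abs(np.mean(fracs) - cfg.dominant_fraction_mean) < 0.05

    def test_oxpl_elevated_on_rs3798220(self):
        cfg = sim.SimConfig(noise_sigma=0.0, oxpl_sd_carrier=0.0,
                            oxpl_sd_noncarrier=0.0)
        carrier = sim.make_allele("a21", 21, (RS3798220,), cfg)
        plain = sim.make_allele("n30", 30, (), cfg)
        hi = sim.simulate_lpa((carrier, plain), cfg, 0).oxpl_per_lpa_nmol_l
        lo = sim.simulate_lpa((plain, plain), cfg, 0).oxpl_per_lpa_nmol_l
        assert hi == pytest.approx(cfg.oxpl_baseline + cfg.oxpl_rs3798220_increment)
        assert lo == pytest.approx(cfg.oxpl_baseline)


class TestSegregationFidelity:
    def test_threshold_partition_matches_figure_labels(self):
        # noise off: Lp(a) > 150 nmol/L exactly for the 21-KIV carriers plus
        # the two members whose elevation the spouse's alleles explain
        cfg = sim.SimConfig(noise_sigma=0.0, ldl_sd=0.0,
                            oxpl_sd_carrier=0.0, oxpl_sd_noncarrier=0.0)
        drop = sim.template_gene_drop(cfg)
        above = {m for m, g in drop.items()
                 if sim.simulate_lpa(g, cfg, seed=0).lpa_nmol_l > 150}
        carriers = {m for m, g in drop.items()
                    if any(a.kiv_count == 21 for a in g)}
        assert above == carriers | {"II-C1", "III-C3"}

    def test_threshold_partition_equals_carriers_without_spouse_alleles(self):
        cfg = sim.SimConfig(noise_sigma=0.0)
        fa = sim.default_founder_alleles(cfg)
        fa["II-C1"] = (sim.make_allele("n30.c1", 30, (), cfg),
                       sim.make_allele("n31.c1", 31, (), cfg))
        drop = sim.template_gene_drop(cfg, fa)
        above = {m for m, g in drop.items()
                 if sim.simulate_lpa(g, cfg, seed=0).lpa_nmol_l > 150}
        carriers = {m for m, g in drop.items()
                    if any(a.kiv_count == 21 for a in g)}
        assert above == carriers


class TestReferenceCohort:
    def test_degenerate_frequencies(self):
        fixed = sim.simulate_reference_cohort(50, [("s0", 0.0), ("s1", 1.0)],
                                              seed=0)
        assert (fixed["s0"] == 0).all()
        assert (fixed["s1"] == 2).all()

    def test_frequency_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            sim.simulate_reference_cohort(10, [("s", 1.2)], seed=0)

    def test_heterozygote_fraction_at_hwe(self):
        df = sim.simulate_reference_cohort(10_000, [("s", 0.3)], seed=21)
        het = (df["s"] == 1).mean()
        assert abs(het - 0.42) <= 0.015

    def test_hwe_chisquare_calibration(self):
        # goodness-of-fit against (q^2, 2pq, p^2) not rejected at alpha=0.001
        # for (almost) every seed
        # common frequencies and n chosen so every expected genotype count
        # is large enough for the chi-square approximation to hold its level
        freqs = [0.1, 0.2, 0.3, 0.4, 0.45]
        sites = [(f"s{i}", f) for i, f in enumerate(freqs)]
        n, passes = 4000, 0
        for seed in range(200):
            df = sim.simulate_reference_cohort(n, sites, seed=seed)
            ok = True
            for (key, p) in sites:
                obs = np.array([(df[key] == k).sum() for k in (0, 1, 2)])
                exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
                _, pval = chisquare(obs, exp)
                ok &= pval > 0.001
            passes += ok
        assert passes / 200 >= 0.99


class TestCadLiability:
    def test_infinite_threshold_means_nobody_affected(self):
        cfg = sim.SimConfig(cad_beta=0.0, cad_baseline_prevalence=0.0)
        rng = np.random.default_rng(0)
        assert all(
            sim.simulate_cad(30.0, rng.standard_normal(), cfg, rng) == "unaffected"
            for _ in range(200)
        )

    def test_baseline_prevalence_under_null_beta(self):
        cfg = sim.SimConfig(cad_beta=0.0, cad_baseline_prevalence=0.05)
        rng = np.random.default_rng(77)
        n = 10_000
        affected = sum(
            sim.simulate_cad(30.0, rng.standard_normal(), cfg, rng) == "affected"
            for _ in range(n)
        )
        assert abs(affected / n - 0.05) <= 0.01

    def test_high_lpa_raises_risk_when_beta_positive(self):
        cfg = sim.SimConfig(cad_beta=2.0)
        rng = np.random.default_rng(3)
        lpa = rng.lognormal(3.0, 1.0, size=2000)
        status = np.array([
            sim.simulate_cad(x, rng.standard_normal(), cfg, rng) == "affected"
            for x in lpa
        ])
        top = status[lpa >= np.quantile(lpa, 0.9)].mean()
        bottom = status[lpa <= np.quantile(lpa, 0.1)].mean()
        assert top > bottom


class TestFixtureEmission:
    def test_byte_identical_reproduction(self, tmp_path):
        cfg = sim.SimConfig(reference_n=40, seed=5)
        sim.write_fixtures(tmp_path / "a", cfg)
        sim.write_fixtures(tmp_path / "b", cfg)
        names = ["family.vcf", "reference.vcf", "family.ped", "phenotypes.tsv",
                 "founder_alleles.tsv", "exons.bed", "lpa_weights.tsv",
                 "cad_weights.tsv", "manifest.json"]
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", names, shallow=False)
        assert mismatch == [] and errors == []

    def test_manifest_names_planted_site(self, fixture_run):
        _, manifest = fixture_run
        planted = manifest["planted_causal"]
        assert planted["id"] == RS3798220
        assert planted["chrom"] == "chr6"
        assert len(manifest["exome_samples"]) == 13
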