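"""Mendelian sex-locus model: gametes, crosses, colony dynamics, estimation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.optimize import brentq

from aedes_gss.genetics import (
    ColonyState,
    Genotype,
    Haplotype,
    OffspringDistribution,
    RateEstimate,
    ScreeningRecord,
    SortingPolicy,
    StrainSpec,
    contamination_closed_form,
    cross,
    crossing_scheme,
    estimate_recombination_rate,
    gamete_distribution,
    load_strains,
    parse_genotype,
    parse_haplotype,
    phenotype_of,
    propagate_colony,
    save_strains,
    simulate_cohort,
)

# ---------------------------------------------------------------------------
# Independent enumeration oracle: explicit gamete-pair enumeration without the
# Counter-collapse used by the implementation.


def oracle_cross(mother: Genotype, father: Genotype, rm: float, rf: float) -> dict:
    def gametes(g, r):
        h1, h2 = g.haplotypes
        return [
            (h1, (1 - r) / 2),
            (h2, (1 - r) / 2),
            (Haplotype(h1.sex_allele, h2.marker), r / 2),
            (Haplotype(h2.sex_allele, h1.marker), r / 2),
        ]

    out: dict = {}
    for hm, pm in gametes(mother, rm):
        for hf, pf in gametes(father, rf):
            g = Genotype(hm, hf)
            out[g] = out.get(g, 0.0) + pm * pf
    return out


markers = st.sampled_from([None, "GFP", "YFP", "DsRed"])
rates = st.floats(min_value=0.0, max_value=0.5, allow_nan=False)


@st.composite
def female_genotypes(draw):
    return Genotype(Haplotype("m", draw(markers)), Haplotype("m", draw(markers)))


@st.composite
def any_genotypes(draw):
    male = draw(st.booleans())
    h1 = Haplotype("M" if male else "m", draw(markers))
    return Genotype(h1, Haplotype("m", draw(markers)))


class TestHaplotypeGenotype:
    def test_bracket_notation_round_trip(self):
        for text in ("m[GFP]/M", "m/m", "M[YFP]/m", "m[GFP]/m[GFP]"):
            g = parse_genotype(text)
            assert parse_genotype(str(g)) == g

    def test_mm_double_male_rejected(self):
        with pytest.raises(ValueError):
            Genotype(Haplotype("M"), Haplotype("M", "GFP"))

    def test_unknown_marker_rejected(self):
        with pytest.raises(ValueError):
            parse_haplotype("m[NotAFluor]")

    def test_unordered_pair(self):
        assert parse_genotype("M/m[GFP]") == parse_genotype("m[GFP]/M")


class TestGameteDistribution:
    def test_hemizygous_male_rates(self):
        gd = gamete_distribution(parse_genotype("m[GFP]/M"), 0.001)
        expect = {"m[GFP]": 0.4995, "M": 0.4995, "M[GFP]": 0.0005, "m": 0.0005}
        assert {str(h): p for h, p in gd.items()} == pytest.approx(expect)

    def test_homozygous_collapse(self):
        gd = gamete_distribution(parse_genotype("m/m"), 0.1)
        assert {str(h): p for h, p in gd.items()} == {"m": 1.0}

    @given(any_genotypes(), rates)
    @settings(max_examples=200, derandomize=True)
    def test_sums_to_one(self, g, r):
        assert sum(p for _, p in gamete_distribution(g, r).items()) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_rate_out_of_range(self):
        with pytest.raises(ValueError):
            gamete_distribution(parse_genotype("m/M"), 0.6)


class TestCross:
    @given(female_genotypes(), any_genotypes(), rates, rates)
    @settings(max_examples=200, derandomize=True)
    def test_agrees_with_enumeration_oracle(self, mother, father, rm, rf):
        dist = cross(mother, father, rm, rf)
        expected = oracle_cross(mother, father, rm, rf)
        assert set(dist.probs) <= set(expected)
        for g, p in expected.items():
            assert dist[g] == pytest.approx(p, abs=1e-12)
        assert sum(p for _, p in dist.items()) == pytest.approx(1.0, abs=1e-12)

    def test_scheme_without_recombination(self):
        dist = cross(parse_genotype("m/m"), parse_genotype("m[GFP]/M"))
        assert {str(g): p for g, p in dist.items()} == pytest.approx(
            {"m/m[GFP]": 0.5, "m/M": 0.5}
        )
        part = {str(k): v for k, v in dist.sex_fluorescence_partition().items()}
        assert part == pytest.approx({"female:GFPx1": 0.5, "male:nonfluorescent": 0.5})

    def test_scheme_with_recombination(self):
        dist = cross(parse_genotype("m/m"), parse_genotype("m[GFP]/M"), r_father=0.001)
        assert {str(g): p for g, p in dist.items()} == pytest.approx(
            {"m/m[GFP]": 0.4995, "m/M": 0.4995, "m/M[GFP]": 0.0005, "m/m": 0.0005}
        )

    def test_all_female_cross(self):
        dist = cross(parse_genotype("m/m"), parse_genotype("m/m"))
        assert all(not g.is_male and not g.marker_copies() for g, _ in dist.items())

    def test_male_mother_rejected(self):
        with pytest.raises(ValueError):
            cross(parse_genotype("m/M"), parse_genotype("m/m"))


class TestPhenotype:
    @pytest.mark.parametrize(
        "genotype, sex, copies",
        [
            ("m/M", "male", {}),
            ("m[GFP]/m[GFP]", "female", {"GFP": 2}),
            ("M[YFP]/m", "male", {"YFP": 1}),
            ("m[GFP]/M[YFP]", "male", {"GFP": 1, "YFP": 1}),
        ],
    )
    def test_sex_and_copy_number(self, genotype, sex, copies):
        ph = phenotype_of(parse_genotype(genotype))
        assert ph.sex == sex and ph.copies == copies


class TestCrossingScheme:
    def test_no_recombination_all_negatives_male(self, aal_strains):
        M_strain, m_strain = aal_strains
        m0 = StrainSpec("m0", m_strain.male_genotype, m_strain.female_genotype, 0.0)
        res = crossing_scheme(M_strain, m0)
        assert res.nonfluorescent_fraction == pytest.approx(0.5, abs=1e-12)
        assert res.female_contamination == 0.0

    @pytest.mark.parametrize("r", [0.0, 1e-4, 1e-3, 0.01, 0.1, 0.5])
    def test_closed_form_matches_enumeration(self, aal_strains, r):
        M_strain, m_strain = aal_strains
        m_r = StrainSpec("m_r", m_strain.male_genotype, m_strain.female_genotype, r)
        res = crossing_scheme(M_strain, m_r)
        # non-fluorescent mass is exactly 1/2 for every r; contamination = r
        assert res.nonfluorescent_fraction == pytest.approx(0.5, abs=1e-12)
        assert res.female_contamination == pytest.approx(
            contamination_closed_form(r), abs=1e-12
        )

    def test_invalid_scheme_genotypes(self, aal_strains):
        M_strain, _ = aal_strains
        bad_m = StrainSpec(
            "bad", parse_genotype("m[GFP]/M[GFP]"), parse_genotype("m[GFP]/m[GFP]"), 0.0
        )
        with pytest.raises(ValueError):
            crossing_scheme(M_strain, bad_m)  # father not hemizygous


class TestSimulateCohort:
    def test_deterministic_and_sums(self, aal_strains):
        M_strain, m_strain = aal_strains
        dist = crossing_scheme(M_strain, m_strain).offspring
        a = simulate_cohort(dist, 65_839, seed=7)
        b = simulate_cohort(dist, 65_839, seed=7)
        assert a.counts == b.counts
        assert a.total == 65_839

    def test_zero_size(self, aal_strains):
        M_strain, m_strain = aal_strains
        dist = crossing_scheme(M_strain, m_strain).offspring
        assert simulate_cohort(dist, 0, seed=1).total == 0

    def test_goodness_of_fit(self, aal_strains):
        M_strain, m_strain = aal_strains
        dist = crossing_scheme(M_strain, m_strain).offspring
        n = 100_000
        cohort = simulate_cohort(dist, n, seed=11)
        genos = sorted(dist.probs, key=str)
        obs = np.array([cohort.counts.get(g, 0) for g in genos])
        exp = np.array([dist[g] * n for g in genos])
        _, p = stats.chisquare(obs, exp)
        assert p > 0.01


class TestPropagateColony:
    def _initial(self, strain, n, seed):
        dist = cross(
            strain.female_genotype,
            strain.male_genotype,
            strain.recomb_rate,
            strain.recomb_rate,
        )
        return simulate_cohort(dist, n, seed)

    def test_zero_rate_no_recombinants(self, aal_strains):
        _, m_strain = aal_strains
        strain = StrainSpec("m0", m_strain.male_genotype, m_strain.female_genotype, 0.0)
        traj = propagate_colony(
            self._initial(strain, 5000, 3),
            strain,
            generations=5,
            policy=SortingPolicy(mode="none", offspring_per_generation=5000),
            seed=3,
        )
        assert (traj.recombinant_genotype_freq == 0).all()

    def test_unsorted_colony_accumulates_linearly(self, aal_strains):
        """Without purification the recombinant genotype frequency grows
        roughly linearly in generation number."""
        _, m_strain = aal_strains
        strain = StrainSpec("mhot", m_strain.male_genotype, m_strain.female_genotype, 0.01)
        trajs = [
            propagate_colony(
                self._initial(strain, 20_000, 100 + s),
                strain,
                generations=8,
                policy=SortingPolicy(
                    mode="none", n_mothers=500, n_fathers=500,
                    offspring_per_generation=20_000,
                ),
                seed=s,
            )
            for s in range(5)
        ]
        mean_freq = np.mean([t.recombinant_genotype_freq.to_numpy() for t in trajs], axis=0)
        gens = np.arange(1, 9)
        slope, intercept = np.polyfit(gens, mean_freq, 1)
        fitted = slope * gens + intercept
        ss_res = np.sum((mean_freq - fitted) ** 2)
        ss_tot = np.sum((mean_freq - mean_freq.mean()) ** 2)
        assert slope > 0
        assert 1 - ss_res / ss_tot > 0.9

    def test_perfect_filter_caps_recombinants_at_rate(self, aal_strains):
        """With a perfect per-generation re-check the recombinant phenotype
        frequency at sorting stays at the single-meiosis rate (here only the
        father's meiosis is visible: the mother is marker-homozygous)."""
        _, m_strain = aal_strains
        r = 0.005
        strain = StrainSpec("mflt", m_strain.male_genotype, m_strain.female_genotype, r)
        n = 20_000
        traj = propagate_colony(
            self._initial(strain, n, 5),
            strain,
            generations=10,
            policy=SortingPolicy(
                mode="perfect", n_mothers=500, n_fathers=500,
                offspring_per_generation=n,
            ),
            seed=5,
        )
        bound = r + 4 * math.sqrt(r * (1 - r) / n)
        assert (traj.recombinant_phenotype_freq <= bound).all()

    def test_extinction_error(self, aal_strains):
        _, m_strain = aal_strains
        females_only = ColonyState(
            0, {m_strain.female_genotype: 100}
        )
        with pytest.raises(RuntimeError):
            propagate_colony(
                females_only, m_strain, 1, SortingPolicy(mode="none"), seed=0
            )


def oracle_exact_ci(k: int, n: int, confidence: float) -> tuple[float, float]:
    """Root-finding oracle: invert the binomial CDF directly."""
    alpha = 1 - confidence
    lower = 0.0 if k == 0 else brentq(
        lambda p: 1 - stats.binom.cdf(k - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12
    )
    upper = 1.0 if k == n else brentq(
        lambda p: stats.binom.cdf(k, n, p) - alpha / 2, 1e-12, 1 - 1e-12
    )
    return lower, upper


class TestRateEstimation:
    @pytest.mark.parametrize(
        "k, n, expected",
        [(1, 10_000, 1e-4), (0, 5_000, 0.0), (4, 50_000, 8e-5)],
    )
    def test_point_estimates(self, k, n, expected):
        est = estimate_recombination_rate(ScreeningRecord(n, k))
        assert est.point == pytest.approx(expected)

    @pytest.mark.parametrize("k, n", [(1, 10_000), (4, 50_000), (0, 1_000), (12, 500)])
    def test_exact_interval_matches_root_finding_oracle(self, k, n):
        est = estimate_recombination_rate(ScreeningRecord(n, k), confidence=0.95)
        lo, hi = oracle_exact_ci(k, n, 0.95)
        assert est.lower == pytest.approx(lo, abs=1e-9)
        assert est.upper == pytest.approx(hi, abs=1e-9)

    def test_zero_events_lower_bound_zero(self):
        est = estimate_recombination_rate(ScreeningRecord(1_000, 0))
        assert est.point == 0.0 and est.lower == 0.0 and est.upper > 0.0

    @pytest.mark.parametrize("true_rate, n", [(1e-4, 30_000), (1e-3, 20_000)])
    def test_interval_coverage_near_nominal(self, true_rate, n):
        """Exact binomial intervals cover the true rare-event rate at least
        ~95% of the time (conservative by construction)."""
        rng = np.random.default_rng(42)
        ks = rng.binomial(n, true_rate, size=1_000)
        covered = 0
        for k in ks:
            est = estimate_recombination_rate(ScreeningRecord(n, int(k)))
            covered += est.lower <= true_rate <= est.upper
        assert covered / 1_000 >= 0.93

    def test_invalid_record(self):
        with pytest.raises(ValueError):
            ScreeningRecord(0, 0)
        with pytest.raises(ValueError):
            ScreeningRecord(10, 11)


class TestStrainIO:
    def test_round_trip(self, aal_strains, tmp_path):
        M_strain, m_strain = aal_strains
        strains = {s.name: s for s in aal_strains}
        path = tmp_path / "strains.yaml"
        save_strains(strains, path)
        loaded = load_strains(path)
        assert loaded == strains
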