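"""Junction sampling and the allelic-exclusion population model."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vdjnmd.tables_synthetic import HYBRIDOMA_CONFIG_COUNTS
from vdjnmd.vdj_sim import (
    ALIVE_PRODUCTIVE,
    DJ,
    VDJ,
    SimParams,
    read_population_alleles,
    sample_junction,
    simulate_population,
    tally_configs,
    two_vdj_fraction_expected,
    write_population_tsv,
)


class TestSampleJunction:
    def test_precise_joining_with_zero_parameters(self, fixture, rng):
        v, d, j = fixture.segments
        params = SimParams(trim_mean=0.0, n_mean=0.0)
        event = sample_junction(v, d, j, params, rng)
        assert event.junction_seq == v.seq + d.seq + j.seq
        assert event.net_shift == 0
        assert (event.v_trim, event.d5_trim, event.d3_trim, event.j_trim) == (0, 0, 0, 0)

    def test_fixed_seed_reproduces_the_event(self, fixture):
        v, d, j = fixture.segments
        params = SimParams()
        e1 = sample_junction(v, d, j, params, np.random.default_rng(42))
        e2 = sample_junction(v, d, j, params, np.random.default_rng(42))
        assert e1 == e2

    def test_junction_consistent_with_trims_and_additions(self, fixture, rng):
        v, d, j = fixture.segments
        params = SimParams()
        for _ in range(200):
            e = sample_junction(v, d, j, params, rng)
            rebuilt = (
                v.seq[: len(v.seq) - e.v_trim]
                + e.n1
                + d.seq[e.d5_trim: len(d.seq) - e.d3_trim]
                + e.n2
                + j.seq[e.j_trim:]
            )
            assert e.junction_seq == rebuilt
            assert e.net_shift == (len(rebuilt) - len(v.seq + d.seq + j.seq)) % 3

    def test_net_shift_uniform_over_frames(self, fixture, rng):
        """30,000 junctions: frame shifts uniform over {0,1,2} (chi-square)."""
        v, d, j = fixture.segments
        params = SimParams()
        shifts = np.array(
            [sample_junction(v, d, j, params, rng).net_shift for _ in range(30_000)]
        )
        counts = np.bincount(shifts, minlength=3)
        chi2 = ((counts - 10_000) ** 2 / 10_000).sum()
        assert stats.chi2.sf(chi2, df=2) > 1e-4
        se = math.sqrt((1 / 3) * (2 / 3) / 30_000)
        for c in counts:
            assert abs(c / 30_000 - 1 / 3) < 3 * se


class TestSimulatePopulation:
    @pytest.mark.parametrize("p_if", [0.1, 1 / 3, 0.9])
    def test_two_vdj_fraction_matches_closed_form(self, p_if, rng):
        n = 30_000
        cells = simulate_population(SimParams(p_if=p_if, n_cells=n), rng)
        alive = [c for c in cells if c.fate == ALIVE_PRODUCTIVE]
        alive_frac = len(alive) / n
        expected_alive = 1 - (1 - p_if) ** 2
        assert abs(alive_frac - expected_alive) < 3 * math.sqrt(
            expected_alive * (1 - expected_alive) / n
        )
        two = sum(c.n_vdj == 2 for c in alive) / len(alive)
        expected_two = two_vdj_fraction_expected(p_if)
        se = math.sqrt(expected_two * (1 - expected_two) / len(alive))
        assert abs(two - expected_two) < 3 * se

    def test_always_productive_means_no_second_rearrangement(self, rng):
        cells = simulate_population(SimParams(p_if=1.0, n_cells=500), rng)
        assert all(c.fate == ALIVE_PRODUCTIVE for c in cells)
        assert all(c.n_vdj == 1 for c in cells)
        assert all(
            c.alleles[1 - c.productive_allele].state == DJ for c in cells
        )

    def test_two_vdj_fraction_bounded_when_p_at_least_third(self, rng):
        """(1-p)/(2-p) is decreasing in p, so p >= 1/3 caps two-VDJ at 40%."""
        for p in (1 / 3, 0.5, 0.8):
            cells = simulate_population(SimParams(p_if=p, n_cells=20_000), rng)
            tally = tally_configs(cells)
            assert tally.pct_two_vdj / 100 <= 0.40 + 3 * math.sqrt(0.4 * 0.6 / tally.n_alive)

    def test_sequence_mode_productivity_close_to_one_third(self, fixture, annotators, rng):
        """In-frame junctions are ~1/3; junction-internal stops shave a little off."""
        cells = simulate_population(
            SimParams(n_cells=6000),
            rng,
            genotypes=("A", "A"),
            mode="sequence",
            models=fixture.models,
            segments=fixture.segments,
            annotators=annotators,
        )
        # every completed junction is a fresh draw, so pooling them estimates
        # the per-junction productive probability
        draws = [a for c in cells for a in c.alleles if a.junction is not None]
        in_frame = [a for a in draws if a.junction.net_shift == 0]
        frac_if = len(in_frame) / len(draws)
        se = (frac_if * (1 - frac_if) / len(draws)) ** 0.5
        assert abs(frac_if - 1 / 3) < 3 * se
        # productive = in-frame AND no junction-internal stop; the internal-stop
        # events depress productivity a few percent below 1/3
        frac_prod = sum(a.productive for a in draws) / len(draws)
        assert frac_prod <= frac_if
        assert abs(frac_prod - 1 / 3) < 0.05
        # self-consistency: every productive draw is in-frame and PTC-negative
        assert all(a.annotation.productive == a.productive for a in draws)
        assert all(a.junction.net_shift == 0 for a in draws if a.productive)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimParams(p_if=1.5)
        with pytest.raises(ValueError):
            SimParams(n_cells=0)


class TestTallyConfigs:
    def test_hand_counts(self):
        table = pd.DataFrame(
            {
                "genotype": ["A/A", "A/A"],
                "allele1_state": [VDJ, VDJ],
                "allele2_state": [DJ, VDJ],
                "count": [68, 32],
            }
        )
        tally = tally_configs(table)
        assert tally.n_two_vdj == 32
        assert tally.pct_two_vdj == pytest.approx(32.0)

    def test_all_single_vdj(self):
        table = pd.DataFrame(
            {
                "genotype": ["A/A"],
                "allele1_state": [VDJ],
                "allele2_state": [DJ],
                "count": [50],
            }
        )
        assert tally_configs(table).pct_two_vdj == 0.0

    def test_synthetic_hybridoma_table_reproduces_reported_percentages(self):
        for genotype, expected in (("A/A", 32.0), ("F/F", 35.0)):
            sub = HYBRIDOMA_CONFIG_COUNTS[HYBRIDOMA_CONFIG_COUNTS["genotype"] == genotype]
            assert tally_configs(sub).pct_two_vdj == pytest.approx(expected)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            tally_configs([])
        with pytest.raises(ValueError):
            tally_configs(pd.DataFrame(columns=["genotype", "allele1_state", "allele2_state", "count"]))

    def test_heterozygote_single_vdj_split_is_symmetric(self, rng):
        """Identical rearrangement parameters give a ~50/50 genotype split."""
        cells = simulate_population(
            SimParams(n_cells=50_000), rng, genotypes=("A", "F")
        )
        tally = tally_configs(cells)
        n_a = tally.single_vdj_by_genotype.get("A", 0)
        n = tally.n_one_vdj
        se = math.sqrt(0.25 / n)
        assert abs(n_a / n - 0.5) < 3 * se


class TestPopulationIO:
    def test_tsv_roundtrip_preserves_alleles(self, fixture, annotators, rng, tmp_path):
        cells = simulate_population(
            SimParams(n_cells=300),
            rng,
            genotypes=("A", "F"),
            mode="sequence",
            models=fixture.models,
            segments=fixture.segments,
            annotators=annotators,
        )
        path = tmp_path / "population.tsv"
        write_population_tsv(cells, path)
        alleles = read_population_alleles(path)
        expected = sum(
            a.state == VDJ
            for c in cells
            if c.fate == ALIVE_PRODUCTIVE
            for a in c.alleles
        )
        assert len(alleles) == expected
        assert set(alleles["nmd_class"]) <= {"PTC_NEG", "PTC_EJC", "PTC_FAILSAFE"}
        assert (alleles["junction_seq"].str.len() > 0).all()
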