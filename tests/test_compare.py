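"""Cross-dataset comparisons: crosstabs, pairings, correlations."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from odoratlas.compare import (
    concentration_pair_deltas,
    correlate_pi_oviposition,
    cross_species_correlation,
    crosstab_techniques,
    or_activation_vs_pi,
    pair_by_assay_category,
)
from odoratlas.errors import EmptySelectionError, SkippedComparison
from odoratlas.simulate import SyntheticConfig, generate_database
from odoratlas.stats import sign_rank_test

from conftest import make_records


def _or_records(values, technique="empty_neuron", unit="spikes/s"):
    return make_records(
        [
            {"odorant_canonical": f"odorant-{j:03d}", "response_value": v,
             "receptor_or_sensillum": "OR01", "technique": technique,
             "response_unit": unit}
            for j, v in enumerate(values)
        ]
    )


def _behavior(rows):
    return make_records(
        [
            {"data_type": "BEHAVIOR", "technique": "behavior",
             "response_unit": "PI", "behavioral_context": "host_seeking_foraging",
             **r}
            for r in rows
        ]
    )


class TestTechniqueCrosstab:
    def test_hand_counted_cells(self):
        en = _or_records([5.0, 0.0, -3.0, 0.0])
        oo = _or_records([0.0, 0.0, 0.0, 2.0], technique="oocyte", unit="nA")
        ct = crosstab_techniques(en, oo)
        assert ct.n_pairs == 4
        assert ct.en_nonzero_oo_zero == 2
        assert ct.en_zero_oo_nonzero == 1
        assert ct.oo_zero_breakdown == (1, 1, 1)

    def test_identical_datasets_are_symmetric(self):
        en = _or_records([5.0, 0.0, -3.0, 7.0])
        ct = crosstab_techniques(en, en)
        assert ct.en_nonzero_oo_zero == 0
        assert ct.en_zero_oo_nonzero == 0

    def test_breakdown_partitions_the_oocyte_zeros(self, default_db):
        rec = default_db.records
        en = rec[(rec.data_type == "OR") & (rec.technique == "empty_neuron")
                 & (rec.species == "Aedes_aegypti")]
        oo = rec[(rec.data_type == "OR") & (rec.technique == "oocyte")]
        ct = crosstab_techniques(en, oo)
        oo_zero_total = sum(ct.oo_zero_breakdown)
        assert ct.en_nonzero_oo_zero == (
            ct.oo_zero_breakdown[0] + ct.oo_zero_breakdown[2]
        )
        assert oo_zero_total <= ct.n_pairs

    def test_no_shared_keys_signals(self):
        en = _or_records([1.0])
        oo = _or_records([1.0], technique="oocyte")
        oo.loc[:, "odorant_canonical"] = "odorant-999"
        with pytest.raises(EmptySelectionError):
            crosstab_techniques(en, oo)

    def test_threshold_monotonicity(self):
        # a less sensitive second technique loses more pairs as its
        # detection threshold rises
        counts = []
        for theta in (0.0, 10.0, 20.0, 40.0):
            cfg = SyntheticConfig(seed=303, n_odorants=80, n_ors=10,
                                  oocyte_threshold=theta)
            db = generate_database(cfg)
            rec = db.records
            en = rec[(rec.data_type == "OR") & (rec.technique == "empty_neuron")
                     & (rec.species == "Aedes_aegypti")]
            oo = rec[(rec.data_type == "OR") & (rec.technique == "oocyte")]
            counts.append(crosstab_techniques(en, oo).en_nonzero_oo_zero)
        assert counts == sorted(counts)


class TestAssayPairing:
    SPLIT = ({"landing"}, {"dual_port", "y_tube"})

    def test_averaging_rule(self):
        df = _behavior(
            [
                {"odorant_canonical": "odorant-X", "concentration_value": 1e-1,
                 "assay_category": "landing", "response_value": -0.4},
                {"odorant_canonical": "odorant-X", "concentration_value": 1e-1,
                 "assay_category": "landing", "response_value": -0.2,
                 "study_id": "study-02"},
                {"odorant_canonical": "odorant-X", "concentration_value": 1e-1,
                 "assay_category": "dual_port", "response_value": 0.1},
            ]
        )
        pc = pair_by_assay_category(df, self.SPLIT)
        assert pc.n == 1
        assert pc.pairs.loc[0, "value_a"] == pytest.approx(-0.3)
        assert pc.pairs.loc[0, "value_b"] == pytest.approx(0.1)

    def test_unmatched_odor_excluded(self):
        df = _behavior(
            [
                {"odorant_canonical": "odorant-X", "assay_category": "landing",
                 "response_value": -0.4},
            ]
        )
        with pytest.raises(EmptySelectionError):
            pair_by_assay_category(df, self.SPLIT)

    def test_antisymmetric_under_group_swap(self, default_db):
        beh = default_db.records.query(
            "data_type == 'BEHAVIOR' and species == 'Aedes_aegypti' "
            "and behavioral_context == 'host_seeking_foraging'"
        )
        fwd = pair_by_assay_category(beh, self.SPLIT)
        rev = pair_by_assay_category(beh, self.SPLIT[::-1])
        assert fwd.mean_delta == pytest.approx(-rev.mean_delta)
        np.testing.assert_allclose(
            (fwd.pairs["value_a"] - fwd.pairs["value_b"]).to_numpy(),
            -(rev.pairs["value_a"] - rev.pairs["value_b"]).to_numpy(),
        )

    def test_recovers_planted_landing_offset(self, default_db):
        beh = default_db.records.query(
            "data_type == 'BEHAVIOR' and species == 'Aedes_aegypti' "
            "and behavioral_context == 'host_seeking_foraging'"
        )
        pc = pair_by_assay_category(beh, self.SPLIT)
        assert pc.n >= 30
        assert pc.mean_delta == pytest.approx(-0.3, abs=0.1)

    def test_row_order_invariance(self, default_db):
        beh = default_db.records.query(
            "data_type == 'BEHAVIOR' and species == 'Aedes_aegypti'"
        )
        shuffled = beh.sample(frac=1.0, random_state=0)
        a = pair_by_assay_category(beh, self.SPLIT)
        b = pair_by_assay_category(shuffled, self.SPLIT)
        assert a.mean_delta == pytest.approx(b.mean_delta)
        assert a.n == b.n


class TestOviposition:
    def _df(self, pi, ovi):
        rows = []
        for j, (p, o) in enumerate(zip(pi, ovi)):
            common = {"odorant_canonical": f"odorant-{j:03d}",
                      "concentration_value": 1e-2}
            rows.append({**common, "assay_category": "dual_port",
                         "response_value": p})
            rows.append({**common, "assay_category": "dual_port",
                         "behavioral_context": "oviposition", "response_value": o})
        return _behavior(rows)

    def test_equal_vectors_give_r_one(self):
        vals = [0.1, -0.2, 0.4, 0.0, -0.5]
        res = correlate_pi_oviposition(self._df(vals, vals), "Aedes_aegypti")
        assert res.pearson_r == pytest.approx(1.0)

    def test_four_items_is_skipped(self):
        vals = [0.1, -0.2, 0.4, 0.0]
        with pytest.raises(SkippedComparison):
            correlate_pi_oviposition(self._df(vals, vals), "Aedes_aegypti")

    def test_independent_indices_correlate_near_zero(self):
        # null behavior of the matched correlation at n = 20: centered on
        # zero with the sampling spread expected of n = 20 (the 95th
        # percentile of |R| under independence is ~0.44)
        rng = np.random.default_rng(11)
        rs = []
        for _ in range(200):
            pi = rng.uniform(-0.5, 0.5, 20).round(4)
            ovi = rng.uniform(-0.5, 0.5, 20).round(4)
            rs.append(
                correlate_pi_oviposition(
                    self._df(pi, ovi), "Aedes_aegypti"
                ).pearson_r
            )
        rs = np.abs(rs)
        assert np.median(rs) < 0.2
        assert np.quantile(rs, 0.95) < 0.5


class TestCrossSpecies:
    def _df(self, species, table):
        rows = []
        for (odor, dec), pi in table.items():
            rows.append(
                {"species": species, "odorant_canonical": odor,
                 "concentration_value": 10.0**dec, "assay_category": "dual_port",
                 "response_value": pi}
            )
        return _behavior(rows)

    def test_identical_tables_give_r_one(self):
        table = {(f"odorant-{j:03d}", -2): round(0.05 * j - 0.3, 3)
                 for j in range(12)}
        df = pd.concat([self._df("Aedes_aegypti", table),
                        self._df("Anopheles_gambiae", table)])
        res = cross_species_correlation(df, "Aedes_aegypti", "Anopheles_gambiae")
        assert res.pearson_r == pytest.approx(1.0)
        assert res.n == 12

    def test_nine_common_odors_is_skipped(self):
        table = {(f"odorant-{j:03d}", -2): 0.1 for j in range(9)}
        df = pd.concat([self._df("Aedes_aegypti", table),
                        self._df("Anopheles_gambiae", table)])
        with pytest.raises(SkippedComparison):
            cross_species_correlation(df, "Aedes_aegypti", "Anopheles_gambiae")

    def test_two_decades_apart_excluded(self):
        base = {(f"odorant-{j:03d}", -2): round(0.05 * j, 3) for j in range(10)}
        df_a = self._df("Aedes_aegypti", base)
        table_b = {(f"odorant-{j:03d}", -2): round(0.05 * j, 3)
                   for j in range(1, 10)}
        table_b[("odorant-000", -4)] = 0.3  # two decades from -2: no match
        df_b = self._df("Anopheles_gambiae", table_b)
        res = cross_species_correlation(
            pd.concat([df_a, df_b]), "Aedes_aegypti", "Anopheles_gambiae",
            min_common_odors=9,
        )
        assert "odorant-000" not in set(res.matched_items["odorant_canonical"])

    def test_one_decade_apart_matches(self):
        table_a = {(f"odorant-{j:03d}", -2): 0.1 * j for j in range(10)}
        table_b = {(f"odorant-{j:03d}", -3): 0.1 * j for j in range(10)}
        df = pd.concat([self._df("Aedes_aegypti", table_a),
                        self._df("Anopheles_gambiae", table_b)])
        res = cross_species_correlation(df, "Aedes_aegypti", "Anopheles_gambiae")
        assert res.n == 10


class TestConcentrationDeltas:
    def test_hand_example(self):
        rows = []
        for dec, vals in ((-3, [0.3, 0.3]), (-2, [0.1, 0.1])):
            for i, v in enumerate(vals):
                rows.append(
                    {"odorant_canonical": "odorant-X",
                     "assay_category": "dual_port",
                     "concentration_value": 10.0**dec, "response_value": v,
                     "study_id": f"study-{i}"}
                )
        pc = concentration_pair_deltas(_behavior(rows))
        assert pc.n == 1
        assert pc.pairs.loc[0, "delta"] == pytest.approx(-0.2)

    def test_hundredfold_gap_is_no_pair(self):
        rows = []
        for dec in (-4, -2):
            for i in range(2):
                rows.append(
                    {"odorant_canonical": "odorant-X",
                     "assay_category": "dual_port",
                     "concentration_value": 10.0**dec, "response_value": 0.1,
                     "study_id": f"study-{i}"}
                )
        with pytest.raises(EmptySelectionError):
            concentration_pair_deltas(_behavior(rows))

    def test_single_measurement_cells_excluded(self):
        rows = [
            {"odorant_canonical": "odorant-X", "assay_category": "dual_port",
             "concentration_value": 10.0**dec, "response_value": 0.1}
            for dec in (-3, -2)
        ]
        with pytest.raises(EmptySelectionError):
            concentration_pair_deltas(_behavior(rows))

    def test_sign_filter(self, default_db):
        beh = default_db.records.query(
            "data_type == 'BEHAVIOR' and behavioral_context == "
            "'host_seeking_foraging'"
        )
        neg = concentration_pair_deltas(beh, lower_pi_sign="negative")
        assert (neg.pairs["pi_low"] < 0).all()


class TestOrActivationCount:
    def _frames(self, responses_by_odor, pis):
        or_rows, beh_rows = [], []
        for odor, resps in responses_by_odor.items():
            for k, v in enumerate(resps):
                or_rows.append(
                    {"odorant_canonical": odor,
                     "receptor_or_sensillum": f"OR{k:02d}", "response_value": v}
                )
        for odor, pi in pis.items():
            beh_rows.append(
                {"odorant_canonical": odor, "assay_category": "dual_port",
                 "response_value": pi}
            )
        return make_records(or_rows), _behavior(beh_rows)

    def test_at_least_ten_spikes_counts(self):
        orr, beh = self._frames(
            {
                "odorant-000": [12.0, 9.0, -5.0, 30.0],
                "odorant-001": [10.0, 0.0, 0.0, 0.0],  # exactly 10 counts
                "odorant-002": [0.0, 0.0, 0.0, 0.0],
            },
            {"odorant-000": 0.1, "odorant-001": 0.2, "odorant-002": 0.3},
        )
        res = or_activation_vs_pi(orr, beh, threshold=10.0)
        counts = dict(
            zip(res.matched_items["odorant_canonical"],
                res.matched_items["n_activated"])
        )
        assert counts == {"odorant-000": 2, "odorant-001": 1, "odorant-002": 0}

    def test_too_few_odors_signals(self):
        orr, beh = self._frames(
            {"odorant-000": [12.0]}, {"odorant-000": 0.1}
        )
        with pytest.raises(SkippedComparison):
            or_activation_vs_pi(orr, beh)

    def test_negative_loading_recovered(self):
        # PI built with a negative loading on the activation count: the
        # recovered correlation should be negative in nearly every replicate
        neg = 0
        for i in range(100):
            cfg = SyntheticConfig(
                seed=9000 + i, n_odorants=60, n_ors=12, n_species=1,
                or_count_loading=0.05, pi_noise_sd=0.05,
                assay_offsets={}, missing_property_rate=0.0,
            )
            db = generate_database(cfg)
            rec = db.records
            en = rec[(rec.data_type == "OR") & (rec.technique == "empty_neuron")]
            beh = rec[(rec.data_type == "BEHAVIOR")
                      & (rec.behavioral_context == "host_seeking_foraging")]
            neg += or_activation_vs_pi(en, beh).pearson_r < 0
        assert neg >= 95


class TestSignRank:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            n = int(rng.integers(3, 11))
            d = rng.normal(0.3, 1.0, n)
            res = sign_rank_test(d)
            nz = d[d != 0]
            ranks = stats.rankdata(np.abs(nz))
            w_obs = ranks[nz > 0].sum()
            dist = np.array(
                [
                    sum(r for s, r in zip(signs, ranks) if s)
                    for signs in product([0, 1], repeat=len(nz))
                ]
            )
            expected = min(
                1.0, 2 * min(np.mean(dist <= w_obs), np.mean(dist >= w_obs))
            )
            assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_zeros_dropped_and_degenerate(self):
        res = sign_rank_test([0.0, 0.0, 1.0, -2.0])
        assert res.n == 2
        assert sign_rank_test([0.0, 0.0]).p_value is None
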