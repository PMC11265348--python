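"""Theil-L index, decomposition additivity and contribution rates."""

import math

import numpy as np
import pytest

from equihealth import (
    MissingDataError,
    PovertyStatus,
    ResourceKind,
    decompose,
    group_aggregate,
    theil_between,
    theil_tables,
    theil_within,
    validate_panel,
)

from conftest import direct_mld, make_record, make_slice


def random_slice(rng, n=None):
    n = n or int(rng.integers(2, 13))
    populations = rng.uniform(1_000, 500_000, n)
    densities = rng.lognormal(mean=1.0, sigma=0.7, size=n)
    personnel = densities * populations / 1000.0
    return make_slice(list(populations), list(personnel))


class TestTheilWithin:
    def test_single_county_is_zero(self):
        assert theil_within([make_record()], ResourceKind.BEDS) == 0.0

    def test_two_counties_equal_population_densities_one_and_three(
        self, toy_two_county_slice
    ):
        value = theil_within(toy_two_county_slice, ResourceKind.PERSONNEL)
        expected = 0.5 * math.log(2.0) + 0.5 * math.log(2.0 / 3.0)
        assert value == pytest.approx(expected)
        assert value == pytest.approx(0.1438, abs=5e-5)

    def test_equal_densities_any_populations_give_zero(self):
        populations = [5_000.0, 80_000.0, 210_000.0]
        records = make_slice(populations, [p * 0.004 for p in populations])
        assert theil_within(records, ResourceKind.PERSONNEL) == pytest.approx(
            0.0, abs=1e-15
        )

    def test_zero_resource_not_computable(self):
        records = [make_record(county_id="a"), make_record(county_id="b", beds=0.0)]
        with pytest.raises(MissingDataError, match="zero resource"):
            theil_within(records, ResourceKind.BEDS)

    def test_log_base_rescales(self, toy_two_county_slice):
        nat = theil_within(toy_two_county_slice, ResourceKind.PERSONNEL)
        b10 = theil_within(toy_two_county_slice, ResourceKind.PERSONNEL, log_base=10)
        assert b10 == pytest.approx(nat / math.log(10.0))


class TestTheilBetween:
    @staticmethod
    def _aggregates(populations_by_group, beds_by_group):
        records = []
        for g, (pops, beds) in enumerate(zip(populations_by_group, beds_by_group)):
            for i, (p, b) in enumerate(zip(pops, beds)):
                records.append(
                    make_record(county_id=f"g{g}c{i}", population=p, beds=b,
                                prefecture=f"pref_{g}")
                )
        return [
            group_aggregate(
                records,
                selector=lambda r, g=g: r.prefecture == f"pref_{g}",
                parent=lambda r: True,
                resource=ResourceKind.BEDS,
                group_label=f"g{g}",
            )
            for g in range(len(populations_by_group))
        ]

    def test_aligned_shares_give_zero(self):
        aggs = self._aggregates([[10_000.0], [10_000.0]], [[100.0], [100.0]])
        assert theil_between(aggs) == pytest.approx(0.0, abs=1e-15)

    def test_hand_evaluated_share_split(self):
        # G = (0.5, 0.5), T = (0.25, 0.75)
        aggs = self._aggregates([[10_000.0], [10_000.0]], [[100.0], [300.0]])
        expected = 0.5 * math.log(2.0) + 0.5 * math.log(2.0 / 3.0)
        assert theil_between(aggs) == pytest.approx(expected)

    def test_single_group_covering_parent_is_zero(self):
        aggs = self._aggregates([[10_000.0, 20_000.0]], [[100.0, 250.0]])
        assert theil_between(aggs) == pytest.approx(0.0, abs=1e-15)

    def test_non_partition_rejected(self):
        aggs = self._aggregates([[10_000.0], [10_000.0]], [[100.0], [300.0]])
        with pytest.raises(ValueError, match="partition"):
            theil_between(aggs[:1])


class TestDecompose:
    def test_two_singleton_groups_put_everything_between(self, toy_two_county_slice):
        dec = decompose(toy_two_county_slice, ResourceKind.PERSONNEL)
        expected = 0.5 * math.log(2.0) + 0.5 * math.log(2.0 / 3.0)
        assert dec.within_by_group == {
            "impoverished": 0.0,
            "non_impoverished": 0.0,
        }
        assert dec.between == pytest.approx(expected)
        assert dec.overall == pytest.approx(expected)
        assert dec.contribution_between == pytest.approx(1.0)

    def test_fully_equal_panel_is_degenerate(self):
        records = make_slice([10_000.0] * 4, [100.0] * 4)
        dec = decompose(records, ResourceKind.PERSONNEL)
        assert dec.overall == pytest.approx(0.0, abs=1e-15)
        assert dec.contribution_between is None
        assert all(v is None for v in dec.contribution_within.values())

    def test_missing_cell_not_computable_with_reason(self):
        records = make_slice([10_000.0, 20_000.0], [50.0, 80.0])
        records.append(make_record(county_id="c999", personnel=None,
                                   poverty_status=PovertyStatus.NON_IMPOVERISHED))
        dec = decompose(records, ResourceKind.PERSONNEL)
        assert not dec.computable
        assert "c999" in dec.reason

    def test_overall_matches_one_level_oracle(self):
        """decompose().overall equals the direct pooled mean log deviation."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            records = random_slice(rng, n=8)
            dec = decompose(records, ResourceKind.PERSONNEL)
            oracle = direct_mld(
                [r.population for r in records],
                [r.personnel for r in records],
            )
            assert dec.overall == pytest.approx(oracle, abs=1e-10)

    def test_additivity_and_contribution_closure(self):
        rng = np.random.default_rng(43)
        for _ in range(200):
            records = random_slice(rng)
            dec = decompose(records, ResourceKind.PERSONNEL)
            recombined = dec.between + sum(
                dec.group_population_shares[g] * dec.within_by_group[g]
                for g in dec.within_by_group
            )
            assert abs(dec.overall - recombined) < 1e-10
            if dec.contribution_between is not None:
                total = dec.contribution_between + sum(
                    v for v in dec.contribution_within.values()
                )
                assert total == pytest.approx(1.0, abs=1e-10)

    def test_nonnegative_on_positive_data(self):
        rng = np.random.default_rng(44)
        for _ in range(100):
            dec = decompose(random_slice(rng), ResourceKind.PERSONNEL)
            assert dec.overall >= 0.0
            assert dec.between >= -1e-15
            assert all(v >= 0.0 for v in dec.within_by_group.values())

    def test_scale_and_replication_invariance(self):
        rng = np.random.default_rng(45)
        records = random_slice(rng, n=6)
        dec = decompose(records, ResourceKind.PERSONNEL)

        scaled = [
            make_record(county_id=r.county_id, population=r.population,
                        poverty_status=r.poverty_status,
                        personnel=r.personnel * 7.5, beds=r.beds)
            for r in records
        ]
        dec_scaled = decompose(scaled, ResourceKind.PERSONNEL)
        assert dec_scaled.overall == pytest.approx(dec.overall, abs=1e-12)
        assert dec_scaled.between == pytest.approx(dec.between, abs=1e-12)

        duplicated = records + [
            make_record(county_id=r.county_id + "_copy", population=r.population,
                        poverty_status=r.poverty_status,
                        personnel=r.personnel, beds=r.beds)
            for r in records
        ]
        dec_dup = decompose(duplicated, ResourceKind.PERSONNEL)
        assert dec_dup.overall == pytest.approx(dec.overall, abs=1e-12)
        for g, v in dec.within_by_group.items():
            assert dec_dup.within_by_group[g] == pytest.approx(v, abs=1e-12)


def test_theil_tables_isolate_missing_blocks():
    records = []
    for province, blank_2019 in (("prov_a", False), ("prov_x", True)):
        for i in range(4):
            status = (
                PovertyStatus.IMPOVERISHED if i < 2 else PovertyStatus.NON_IMPOVERISHED
            )
            for year in (2018, 2019):
                records.append(
                    make_record(
                        county_id=f"{province}_{i}", province=province, year=year,
                        poverty_status=status,
                        population=40_000.0 + 5_000.0 * i,
                        personnel=None if (blank_2019 and year == 2019) else 300.0 + 20.0 * i,
                    )
                )
    indices, contributions = theil_tables(
        validate_panel(records), ResourceKind.PERSONNEL
    )
    bad = indices[indices.reason != ""]
    assert len(bad) == 1
    assert (bad.iloc[0].province, bad.iloc[0].year) == ("prov_x", 2019)
    good = indices[indices.reason == ""]
    assert good.overall.notna().all()
    good_contrib = contributions[contributions.reason == ""]
    closure = good_contrib.between + good_contrib.within_impoverished + \
        good_contrib.within_non_impoverished
    assert np.allclose(closure, 1.0, atol=1e-10)
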