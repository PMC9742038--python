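import numpy as np
import pandas as pd
import pytest

from ageplace import prescribing


def _reg(rows):
    return pd.DataFrame(
        rows, columns=["practice_id", "year", "month", "area_id", "patients"]
    )


def _ledger(rows):
    return pd.DataFrame(
        rows, columns=["practice_id", "year", "month", "chemical_class", "items"]
    )


class TestRegistrationProportions:
    def test_single_area_gets_full_share(self):
        shares = prescribing.registration_proportions(
            _reg([("G1", 2015, 1, "A", 25)])
        )
        assert shares["share"].tolist() == [1.0]

    def test_split_shares(self):
        shares = prescribing.registration_proportions(
            _reg([("G1", 2015, 1, "A", 30), ("G1", 2015, 1, "B", 10)])
        )
        out = shares.set_index("area_id")["share"]
        assert out["A"] == pytest.approx(0.75)
        assert out["B"] == pytest.approx(0.25)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            prescribing.registration_proportions(
                _reg([("G1", 2015, 1, "A", -1)])
            )

    def test_zero_total_practice_months_emit_no_shares(self):
        shares = prescribing.registration_proportions(
            _reg([("G1", 2015, 1, "A", 0), ("G2", 2015, 1, "A", 5)])
        )
        assert set(shares["practice_id"]) == {"G2"}

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"G{p}", 2015, m, f"A{a}", int(rng.integers(0, 50)))
            for p in range(5) for m in (1, 2) for a in range(4)
        ]
        reg = _reg(rows)
        shares = prescribing.registration_proportions(reg)
        for _, r in shares.iterrows():
            sub = reg[
                (reg["practice_id"] == r["practice_id"])
                & (reg["year"] == r["year"]) & (reg["month"] == r["month"])
            ]
            expected = (
                sub.loc[sub["area_id"] == r["area_id"], "patients"].sum()
                / sub["patients"].sum()
            )
            assert r["share"] == pytest.approx(expected, abs=1e-12)
        sums = shares.groupby(["practice_id", "year", "month"])["share"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)


class TestAllocateItems:
    def test_arithmetic_split(self):
        shares = prescribing.registration_proportions(
            _reg([("G1", 2015, 1, "A", 30), ("G1", 2015, 1, "B", 10)])
        )
        alloc, un = prescribing.allocate_items(
            _ledger([("G1", 2015, 1, "AChEI", 100)]), shares, "AChEI"
        )
        got = alloc.set_index("area_id")["items"]
        assert got["A"] == pytest.approx(75.0)
        assert got["B"] == pytest.approx(25.0)
        assert un.empty

    def test_empty_ledger_empty_allocation(self):
        shares = prescribing.registration_proportions(
            _reg([("G1", 2015, 1, "A", 5)])
        )
        alloc, un = prescribing.allocate_items(
            _ledger([]), shares, "Memantine"
        )
        assert alloc.empty and un.empty

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="chemical_class"):
            prescribing.allocate_items(_ledger([]), _reg([("G1", 2015, 1, "A", 5)]), "Aspirin")

    def test_unmatched_practice_months_reported_not_dropped(self):
        shares = prescribing.registration_proportions(
            _reg([("G1", 2015, 1, "A", 5)])
        )
        alloc, un = prescribing.allocate_items(
            _ledger([("G2", 2015, 1, "AChEI", 10)]), shares, "AChEI"
        )
        assert alloc.empty
        assert un["practice_id"].tolist() == ["G2"]

    def test_missing_month_falls_back_to_nearest_earlier(self):
        shares = prescribing.registration_proportions(
            _reg([("G1", 2015, 1, "A", 30), ("G1", 2015, 1, "B", 10),
                  ("G1", 2015, 3, "A", 10), ("G1", 2015, 3, "B", 30)])
        )
        alloc, un = prescribing.allocate_items(
            _ledger([("G1", 2015, 4, "AChEI", 40)]), shares, "AChEI"
        )
        got = alloc.set_index("area_id")["items"]
        assert got["A"] == pytest.approx(10.0)  # March shares, not January
        assert got["B"] == pytest.approx(30.0)
        assert un.empty

    def test_conservation_and_brute_force_equivalence(self):
        rng = np.random.default_rng(1)
        reg = _reg(
            [(f"G{p}", 2015, m, f"A{a}", int(rng.integers(1, 40)))
             for p in range(3) for m in (1, 2) for a in range(4)]
        )
        led = _ledger(
            [(f"G{p}", 2015, m, "AChEI", int(rng.integers(0, 200)))
             for p in range(3) for m in (1, 2)]
        )
        shares = prescribing.registration_proportions(reg)
        alloc, _ = prescribing.allocate_items(led, shares, "AChEI")
        assert alloc["items"].sum() == pytest.approx(
            led["items"].sum(), rel=1e-9
        )
        # brute-force double loop
        expected = {}
        for _, lrow in led.iterrows():
            sub = reg[
                (reg["practice_id"] == lrow["practice_id"])
                & (reg["month"] == lrow["month"])
            ]
            tot = sub["patients"].sum()
            for _, rrow in sub.iterrows():
                key = (rrow["area_id"], lrow["month"])
                expected[key] = expected.get(key, 0.0) + lrow["items"] * rrow["patients"] / tot
        for _, arow in alloc.iterrows():
            assert arow["items"] == pytest.approx(
                expected[(arow["area_id"], arow["month"])], rel=1e-9
            )

    def test_linearity_merging_ledgers(self):
        rng = np.random.default_rng(2)
        reg = _reg(
            [(f"G{p}", 2015, 1, f"A{a}", int(rng.integers(1, 40)))
             for p in range(3) for a in range(3)]
        )
        shares = prescribing.registration_proportions(reg)
        l1 = _ledger([(f"G{p}", 2015, 1, "AChEI", int(rng.integers(0, 99))) for p in range(3)])
        l2 = _ledger([(f"G{p}", 2015, 1, "AChEI", int(rng.integers(0, 99))) for p in range(3)])
        merged, _ = prescribing.allocate_items(pd.concat([l1, l2]), shares, "AChEI")
        a1, _ = prescribing.allocate_items(l1, shares, "AChEI")
        a2, _ = prescribing.allocate_items(l2, shares, "AChEI")
        summed = (
            pd.concat([a1, a2]).groupby(["area_id", "year", "month"])["items"].sum()
        )
        got = merged.set_index(["area_id", "year", "month"])["items"]
        pd.testing.assert_series_equal(got.sort_index(), summed.sort_index())


class TestAnnualRate:
    def _pop(self, rows):
        return pd.DataFrame(rows, columns=["area_id", "pop_50_plus"])

    def test_arithmetic(self):
        alloc = pd.DataFrame({"area_id": ["A"], "year": [2015], "month": [1], "items": [500.0]})
        out = prescribing.annual_rate(alloc, self._pop([("A", 100)]), n_years=5)
        assert out["rate"].iloc[0] == pytest.approx(1.0)

    def test_doubling_population_halves_rate(self):
        alloc = pd.DataFrame({"area_id": ["A"], "year": [2015], "month": [1], "items": [500.0]})
        r1 = prescribing.annual_rate(alloc, self._pop([("A", 100)]), 5)["rate"].iloc[0]
        r2 = prescribing.annual_rate(alloc, self._pop([("A", 200)]), 5)["rate"].iloc[0]
        assert r2 == pytest.approx(r1 / 2)

    def test_zero_population_flagged_not_infinite(self):
        alloc = pd.DataFrame({"area_id": ["A"], "year": [2015], "month": [1], "items": [10.0]})
        out = prescribing.annual_rate(alloc, self._pop([("A", 0)]), 5)
        assert out["missing"].iloc[0]
        assert np.isnan(out["rate"].iloc[0])

    def test_unmatched_area_errors(self):
        alloc = pd.DataFrame({"area_id": ["Z"], "year": [2015], "month": [1], "items": [10.0]})
        with pytest.raises(ValueError, match="Z"):
            prescribing.annual_rate(alloc, self._pop([("A", 10)]), 5)


def test_latent_rate_recovery_on_synthetic_defaults(
    small_config, population, prescribing_sources
):
    """Apportioning the generated ledger recovers the planted area rates."""
    ledger, registration, latent = prescribing_sources
    rates = prescribing.area_rates(ledger, registration, population)
    merged = rates.merge(latent, on=["area_id", "chemical_class"])
    for cls, sub in merged.groupby("chemical_class"):
        r = np.corrcoef(sub["rate"], sub["annual_rate"])[0, 1]
        assert r >= 0.8, f"{cls}: r={r:.3f}"
    assert (rates["rate"].dropna() >= 0).all()
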