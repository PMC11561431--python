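"""Cohen's d, mean CIs, the PCI and the determinant-selection table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from behavdet import reference
from behavdet.potential import (
    change_potential_table,
    cohens_d,
    compute_pci,
    mean_ci,
    plot_ciber,
)


class TestCohensD:
    def test_worked_example_equals_one(self):
        scores = np.array([1, 2, 3, 2, 3, 4], dtype=float)
        positive = np.array([True, True, True, False, False, False])
        d, (lo, hi) = cohens_d(scores, positive)
        assert d == 1.0
        assert lo < d < hi

    def test_identical_distributions_give_zero(self):
        scores = np.array([1, 2, 3, 1, 2, 3], dtype=float)
        positive = np.array([True, True, True, False, False, False])
        d, _ = cohens_d(scores, positive)
        assert d == 0.0

    def test_small_group_and_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1, 2, 3], [True, False, False])
        with pytest.raises(ValueError):
            cohens_d([2, 2, 2, 2], [True, True, False, False])


class TestMeanCI:
    def test_hand_computed_interval(self):
        m, (lo, hi) = mean_ci([1, 2, 3, 4, 5])
        assert m == 3
        assert lo == pytest.approx(1.04, abs=0.01)
        assert hi == pytest.approx(4.96, abs=0.01)

    def test_constant_vector_zero_width(self):
        m, (lo, hi) = mean_ci([2, 2, 2])
        assert lo == m == hi

    def test_width_shrinks_with_n(self):
        rng = np.random.default_rng(0)
        widths = []
        for n in (50, 500, 5000):
            x = rng.normal(3, 1, n)
            _, (lo, hi) = mean_ci(x)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            mean_ci([3.0])


class TestPCI:
    def test_reproduces_published_table_within_rounding(self):
        # published (mean, d) pairs carry 2 decimals; the printed PCI must be
        # recovered to within that rounding slack on every row
        for row in reference.DETERMINANT_TABLE:
            pci = round(compute_pci(row.mean, row.d), 2)
            # integer hundredths: the published table carries 2 decimals
            assert abs(round(pci * 100) - round(row.pci_printed * 100)) <= 3, row

    def test_boundary_cases_are_zero(self):
        assert compute_pci(1.0, 0.9) == 0.0
        assert compute_pci(3.0, 0.0) == 0.0

    def test_mean_off_scale_rejected(self):
        with pytest.raises(ValueError):
            compute_pci(0.5, 1.0)
        with pytest.raises(ValueError):
            compute_pci(5.4, 1.0)

    @given(
        m1=st.floats(1.001, 5.0), m2=st.floats(1.001, 5.0),
        d1=st.floats(0.01, 2.0), d2=st.floats(0.01, 2.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_mean_and_effect(self, m1, m2, d1, d2):
        if m1 != m2:
            lo_m, hi_m = sorted((m1, m2))
            assert compute_pci(lo_m, d1) < compute_pci(hi_m, d1)
        if d1 != d2:
            lo_d, hi_d = sorted((d1, d2))
            assert compute_pci(m1, lo_d) < compute_pci(m1, hi_d)


@pytest.fixture(scope="module")
def table_fixture(strong_dataset):
    ds = strong_dataset
    assignment = {
        item: int(ds.true_assignment[item][1:]) for item in ds.signal_items
    }
    table = change_potential_table(
        ds.responses, ds.responses.positive, assignment
    )
    return ds, assignment, table


class TestChangePotentialTable:
    def test_record_cardinality(self, table_fixture):
        ds, assignment, table = table_fixture
        n_items = len(assignment)
        n_clusters = len(set(assignment.values()))
        assert len(table) == n_items + n_clusters

    def test_internal_consistency_of_pci(self, table_fixture):
        _, _, table = table_fixture
        recomputed = (np.abs(1 - table["mean"]) * table["d"] ** 2).to_numpy()
        np.testing.assert_allclose(table["pci"].to_numpy(), recomputed,
                                   atol=1e-12)

    def test_items_sorted_by_pci_within_cluster(self, table_fixture):
        _, _, table = table_fixture
        for _, block in table[table["level"] == "item"].groupby("cluster"):
            pcis = block["pci"].to_numpy()
            assert (pcis[:-1] >= pcis[1:] - 1e-15).all()

    def test_cluster_rows_close_last_in_each_block(self, table_fixture):
        _, _, table = table_fixture
        for _, block in table.groupby("cluster", sort=False):
            assert block["level"].iloc[-1] == "cluster"

    def test_ci_brackets_point_estimates(self, table_fixture):
        _, _, table = table_fixture
        assert (table["d_lo"] <= table["d"]).all()
        assert (table["d"] <= table["d_hi"]).all()
        assert (table["mean_pos_lo"] <= table["mean_pos"]).all()
        assert (table["mean_neg"] <= table["mean_neg_hi"]).all()


class TestCiberPlot:
    def test_file_written_and_seed_deterministic(self, table_fixture, tmp_path):
        ds, assignment, _ = table_fixture
        items = list(assignment)[:2]
        entities = {i: [i] for i in items}
        p1 = plot_ciber(ds.responses, ds.responses.positive, entities,
                        tmp_path / "c1.svg", order=items, seed=5)
        p2 = plot_ciber(ds.responses, ds.responses.positive, entities,
                        tmp_path / "c2.svg", order=items, seed=5)
        assert p1.stat().st_size > 0
        assert p1.read_bytes() == p2.read_bytes()

    def test_group_diamonds_separate_for_large_effect(self, table_fixture):
        ds, _, table = table_fixture
        # strongest planted effect: group mean CIs should not overlap at n=2000
        row = table.loc[table["d"].idxmax()]
        assert row["mean_pos_hi"] < row["mean_neg_lo"]
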