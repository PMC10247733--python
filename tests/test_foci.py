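"""DAPI binning, foci-count ratios and co-localization metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from haplocycle.errors import DegenerateDataError
from haplocycle.foci import (
    ColocParams,
    FociTable,
    colocalize,
    dapi_bin,
    foci_ratio,
    stage_stratified_report,
)


def _table(intensities, group="haploid", replicate=1, foci_rows=()):
    cells = pd.DataFrame({
        "group": group, "replicate": replicate,
        "dapi_intensity": intensities,
    }, index=pd.Index([f"c{i}" for i in range(len(intensities))], name="cell_id"))
    foci = pd.DataFrame(list(foci_rows), columns=["cell_id", "channel", "x", "y"])
    return FociTable(cells=cells, foci=foci)


def _counts_table(counts, group, replicate):
    """FociTable with the given per-cell gH2AX counts at dummy positions."""
    rows = []
    ids = [f"{group}_{replicate}_c{i}" for i in range(len(counts))]
    for cid, k in zip(ids, counts):
        rows += [(cid, "gH2AX", 0.0, 0.0)] * int(k)
    cells = pd.DataFrame({
        "group": group, "replicate": replicate, "dapi_intensity": 1.0,
    }, index=pd.Index(ids, name="cell_id"))
    return FociTable(cells=cells, foci=pd.DataFrame(
        rows, columns=["cell_id", "channel", "x", "y"]
    ))


def _concat(tables):
    return FociTable(
        cells=pd.concat([t.cells for t in tables]),
        foci=pd.concat([t.foci for t in tables], ignore_index=True),
    )


class TestDapiBin:
    def test_quantile_arithmetic(self):
        t = _table(np.arange(1.0, 11.0))
        bins = dapi_bin(t, ColocParams(dapi_bin_quantiles=(0.3, 0.7)))
        assert list(bins) == ["low"] * 3 + ["medium"] * 4 + ["high"] * 3

    def test_all_equal_intensities_rejected(self):
        with pytest.raises(DegenerateDataError, match="degenerate"):
            dapi_bin(_table(np.full(10, 2.0)))

    def test_high_bin_tracks_g2_fraction(self):
        from haplocycle.config import SimConfig
        from haplocycle.synthetic import simulate_foci

        cfg = SimConfig(seed=41)
        cfg.foci.n_cells_per_group = 400
        cfg.foci.g2_fraction = 0.3
        table = simulate_foci(cfg)
        bins = dapi_bin(table, ColocParams(dapi_bin_quantiles=(0.3, 0.7)))
        # with a clean bimodal mixture the top 30% quantile bin is all G2-like
        hap = table.cells["group"] == "haploid"
        high_mean = table.cells.loc[hap & (bins == "high"), "dapi_intensity"].mean()
        low_mean = table.cells.loc[hap & (bins == "low"), "dapi_intensity"].mean()
        assert high_mean / low_mean == pytest.approx(2.0, rel=0.1)


class TestFociRatio:
    def test_identical_tables_give_unit_ratio(self):
        rng = np.random.default_rng(0)
        parts = [_counts_table(rng.poisson(5, 30), g, r)
                 for g in ("diploid", "haploid") for r in (1, 2, 3)]
        t = _concat(parts)
        a = t.subset(t.cells["group"] == "diploid")
        b = FociTable(cells=a.cells.copy(), foci=a.foci.copy())
        ratios, _ = foci_ratio(a, b)
        np.testing.assert_allclose(ratios, 1.0)

    def test_one_sample_t_against_expectation(self):
        """Replicate ratios (1.0, 1.1, 0.9) against an expected 2.0:
        t = (1 - 2) / (0.1 / sqrt(3)) = -17.32, two-sided p = 0.00332."""
        a = _concat([_counts_table([r * 10] * 10, "diploid", i + 1)
                     for i, r in enumerate((1.0, 1.1, 0.9))])
        b = _concat([_counts_table([10] * 10, "haploid", i + 1) for i in range(3)])
        ratios, p = foci_ratio(a, b, expected_ratio=2.0)
        np.testing.assert_allclose(np.sort(ratios), [0.9, 1.0, 1.1])
        assert p == pytest.approx(0.003317, abs=2e-5)

    def test_zero_variance_reports_undefined(self):
        a = _concat([_counts_table([10] * 5, "diploid", r) for r in (1, 2)])
        b = _concat([_counts_table([5] * 5, "haploid", r) for r in (1, 2)])
        ratios, p = foci_ratio(a, b)
        np.testing.assert_allclose(ratios, 2.0)
        assert np.isnan(p)

    def test_poisson_two_to_one_not_significant(self):
        rng = np.random.default_rng(3)
        a = _concat([_counts_table(rng.poisson(20, 200), "diploid", r)
                     for r in (1, 2, 3)])
        b = _concat([_counts_table(rng.poisson(10, 200), "haploid", r)
                     for r in (1, 2, 3)])
        ratios, p = foci_ratio(a, b, expected_ratio=2.0)
        assert ratios.mean() == pytest.approx(2.0, rel=0.1)
        assert p > 0.05


class TestColocalize:
    def test_identical_coordinates_full_occupancy(self, rng):
        a = rng.uniform(0, 10, size=(7, 2))
        assert colocalize(a, a.copy(), 0.5) == (1.0, 1.0)

    def test_all_beyond_radius_zero_occupancy(self):
        a = np.array([[0.0, 0.0], [1.0, 0.0]])
        b = a + 100.0
        assert colocalize(a, b, 0.5) == (0.0, 0.0)

    def test_matches_all_pairs_oracle(self, rng):
        a = rng.uniform(0, 5, size=(20, 2))
        b = rng.uniform(0, 5, size=(15, 2))
        r = 0.7
        fa, fb = colocalize(a, b, r)
        d = cdist(a, b)
        assert fa == pytest.approx((d.min(axis=1) <= r).mean())
        assert fb == pytest.approx((d.min(axis=0) <= r).mean())

    def test_monotone_in_radius(self, rng):
        a = rng.uniform(0, 5, size=(25, 2))
        b = rng.uniform(0, 5, size=(25, 2))
        fracs = [colocalize(a, b, r)[0] for r in (0.1, 0.5, 1.0, 3.0)]
        assert all(x <= y for x, y in zip(fracs, fracs[1:]))

    def test_empty_sides_are_nan(self):
        fa, fb = colocalize(np.empty((0, 2)), np.array([[0.0, 0.0]]), 0.5)
        assert np.isnan(fa) and fb == 0.0


class TestStageStratifiedReport:
    def _two_group_table(self, deficit_in_high=False):
        """Three DAPI levels per group; RAD51 co-localizes everywhere except
        (optionally) in the haploid high bin."""
        rng = np.random.default_rng(5)
        parts = []
        for grp in ("diploid", "haploid"):
            for rep in (1, 2):
                for level, dapi in (("low", 1.0), ("medium", 2.0), ("high", 4.0)):
                    ids = [f"{grp}{rep}{level}{i}" for i in range(12)]
                    cells = pd.DataFrame({
                        "group": grp, "replicate": rep,
                        "dapi_intensity": dapi * rng.lognormal(0, 0.02, 12),
                    }, index=pd.Index(ids, name="cell_id"))
                    rows = []
                    drop = deficit_in_high and grp == "haploid" and level == "high"
                    for cid in ids:
                        for k in range(3):
                            x, y = rng.uniform(0, 30, 2)
                            rows.append((cid, "gH2AX", x, y))
                            if not drop:
                                rows.append((cid, "RAD51", x + 0.1, y))
                    parts.append(FociTable(cells=cells, foci=pd.DataFrame(
                        rows, columns=["cell_id", "channel", "x", "y"])))
        return _concat(parts)

    def test_stage_specific_deficit_detected_only_in_high_bin(self):
        rep = stage_stratified_report(self._two_group_table(deficit_in_high=True))
        assert rep.loc["high", "frac_gH2AX_occupied_haploid"] < 0.2
        assert rep.loc["low", "frac_gH2AX_occupied_haploid"] > 0.9
        assert rep.loc["high", "frac_gH2AX_occupied_diploid"] > 0.9
        assert rep.loc["high", "occupancy_p_between_groups"] < 0.01
        assert rep.loc["low", "occupancy_p_between_groups"] > 0.5 or np.isnan(
            rep.loc["low", "occupancy_p_between_groups"]
        )

    def test_missing_group_in_bin_does_not_crash(self):
        t = self._two_group_table()
        only_hap = t.subset(t.cells["group"] == "haploid")
        rep = stage_stratified_report(only_hap)
        assert len(rep) == 3
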