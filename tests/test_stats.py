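"""Statistical primitives against hand computations and scipy references."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

from sinusid.protocols import ProtocolQuartet
from sinusid.stats import (
    build_tables,
    paired_t_test,
    pearson_r,
    quartets_to_frame,
    separability,
)


class TestPairedT:
    def test_identical_vectors_degenerate(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == 1.0
        assert res.degenerate

    def test_constant_nonzero_difference_flagged(self):
        with pytest.raises(ZeroDivisionError):
            paired_t_test([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])

    def test_hand_computed_example(self):
        """t = mean(d) / (sd(d)/sqrt(n)) on d = x - y, df = n - 1."""
        x = np.array([1.1, 2.0, 3.2, 4.1])
        y = np.array([1.0, 2.2, 2.9, 4.4])
        d = x - y  # [0.1, -0.2, 0.3, -0.3]
        n = 4
        dbar = d.sum() / n
        sd = np.sqrt(((d - dbar) ** 2).sum() / (n - 1))
        t_hand = dbar / (sd / np.sqrt(n))
        res = paired_t_test(x, y)
        assert res.t == pytest.approx(t_hand, abs=1e-12)
        assert res.df == 3
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t_hand), 3), abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [2.0])
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_agrees_with_scipy_on_random_fixtures(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            x = rng.normal(size=n)
            y = x + rng.normal(scale=0.7, size=n)
            mine = paired_t_test(x, y)
            ref = sps.ttest_rel(x, y)
            assert mine.t == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-10)


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson_r(x, -x).r == pytest.approx(-1.0)
        assert pearson_r(x, -x).p == 0.0

    def test_hand_computed_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 5.0])
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        r_hand = sxy / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        res = pearson_r(x, y)
        assert res.r == pytest.approx(r_hand, abs=1e-12)
        t = r_hand * np.sqrt(2 / (1 - r_hand**2))
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t), 2), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 2.0], [1.0, 2.0])

    def test_agrees_with_scipy_on_random_fixtures(self):
        rng = np.random.default_rng(321)
        for _ in range(100):
            n = int(rng.integers(4, 50))
            x = rng.normal(size=n)
            y = 0.4 * x + rng.normal(size=n)
            mine = pearson_r(x, y)
            ref = sps.pearsonr(x, y)
            assert mine.r == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-10)


class TestSeparability:
    def test_clean_separation(self):
        sep = separability([0.1, 0.2], [2.0, 3.0])
        assert not sep.overlap
        assert sep.accuracy == 1.0
        assert sep.max_match_rms == 0.2
        assert sep.min_mismatch_rms == 2.0
        assert sep.threshold_mm == 0.96

    def test_overlap_detected(self):
        sep = separability([1.0], [0.5])
        assert sep.overlap
        assert sep.accuracy == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            separability([], [1.0])


def _quartet(pair_id, is_match, rms, sizes=(0.0, 0.0, 0.0)):
    return ProtocolQuartet(
        pair_id=pair_id,
        is_match=is_match,
        rms=dict(zip("ABCD", rms)),
        size_deltas={"breadth": sizes[0], "height": sizes[1], "volume": sizes[2]},
    )


class TestBuildTables:
    def make_quartets(self):
        out = []
        rng = np.random.default_rng(5)
        for i in range(4):
            base = 0.15 + 0.02 * i
            out.append(_quartet(f"m{i}", True,
                                base + rng.normal(scale=0.005, size=4),
                                sizes=tuple(rng.uniform(0.2, 1.5, size=3))))
        for i in range(4):
            base = 2.0 + 0.3 * i
            out.append(_quartet(f"x{i}", False,
                                base + rng.normal(scale=0.4, size=4),
                                sizes=tuple(rng.uniform(3.0, 15.0, size=3))))
        return out

    def test_table1_means_match_hand_aggregation(self):
        quartets = self.make_quartets()
        tables = build_tables(quartets)
        df = quartets_to_frame(quartets)
        matches = df[df["is_match"]]
        assert tables.table1.loc[("matches", "mean"), "rms_A"] == pytest.approx(
            matches["rms_A"].mean()
        )
        assert tables.table1.loc[("matches", "sd"), "rms_A"] == pytest.approx(
            matches["rms_A"].std(ddof=1)
        )

    def test_hand_built_two_value_means(self):
        q1 = _quartet("a", True, [0.1, 0.2, 0.3, 0.4], sizes=(1.0, 2.0, 3.0))
        q2 = _quartet("b", True, [0.3, 0.35, 0.1, 0.25], sizes=(3.0, 4.0, 5.0))
        mm = [
            _quartet("c", False, [2.0, 2.0, 3.0, 3.0], sizes=(8, 4, 2)),
            _quartet("d", False, [3.0, 2.5, 2.0, 4.5], sizes=(12, 6, 3)),
        ]
        tables = build_tables([q1, q2] + mm)
        t1 = tables.table1
        assert t1.loc[("matches", "mean"), "rms_A"] == pytest.approx(0.2)
        assert t1.loc[("matches", "mean"), "delta_breadth"] == pytest.approx(2.0)
        # |B-C| column: |0.2-0.3|=0.1 and |0.35-0.1|=0.25 -> mean 0.175
        assert t1.loc[("matches", "mean"), "delta_B-C"] == pytest.approx(0.175)

    def test_all_identical_quartets_zero_sd(self):
        quartets = [_quartet(f"m{i}", True, [0.2, 0.2, 0.2, 0.2]) for i in range(3)]
        quartets += [_quartet(f"x{i}", False, [2.0, 2.0, 2.0, 2.0]) for i in range(3)]
        tables = build_tables(quartets)
        assert (tables.table1.xs("sd", level="stat").abs() < 1e-12).all().all()

    def test_insufficient_groups_rejected(self):
        with pytest.raises(ValueError):
            build_tables([_quartet("a", True, [0.1] * 4)] * 3)

    def test_table_shapes_and_separation(self, tmp_path):
        tables = build_tables(self.make_quartets())
        assert tables.table2.shape == (4, 2)
        assert tables.table3.shape == (24, 2)
        assert ((tables.table2 >= 0) & (tables.table2 <= 1)).all().all()
        assert not tables.separation.overlap
        assert set(tables.per_group_separation) == set("ABCD")
        tables.to_csv(tmp_path)
        assert (tmp_path / "table2_paired_t.csv").exists()
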