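"""Domain summaries, phenotype × domain matrices, severity %, regression."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import foldscan as fs
from foldscan.cohort_stats import DomainSummaryRow
from foldscan.variants import AnnotatedVariant


def _variant(pos, domain, rho, ddg, phenotype="USH1B", category="moderate", high=False):
    return AnnotatedVariant(
        raw_change=f"p.A{pos}V", wt_aa="A", pos=pos, mut_aa="V",
        consequence="missense", phenotype_raw=phenotype, phenotype=phenotype,
        source="test", domain=domain, ddg=ddg, propensity=rho,
        category=category, high_destabilizing=high,
    )


class TestSummarizeByDomain:
    def test_single_variant_row(self, myo7a_map):
        rows = fs.summarize_by_domain([_variant(1400, "FERM-1", 0.8, 1.5)], myo7a_map)
        assert rows == [
            DomainSummaryRow("FERM-1", (1258, 1602), 1, 0.8, 1.5, "")
        ]

    def test_means_match_brute_force(self, myo7a_map):
        rng = np.random.default_rng(3)
        rhos = rng.uniform(0, 1, 10)
        ddgs = rng.normal(1, 2, 10)
        variants = [_variant(1300 + i, "FERM-1", r, d) for i, (r, d) in enumerate(zip(rhos, ddgs))]
        [row] = fs.summarize_by_domain(variants, myo7a_map)
        assert row.n == 10
        assert row.mean_propensity == pytest.approx(rhos.mean())
        assert row.mean_ddg == pytest.approx(ddgs.mean())
        assert min(rhos) <= row.mean_propensity <= max(rhos)

    def test_unassigned_only_cohort(self, myo7a_map):
        rows = fs.summarize_by_domain([_variant(30, "unassigned", 0.5, 0.0)], myo7a_map)
        assert [r.domain for r in rows] == ["unassigned"]

    def test_rows_follow_map_order(self, myo7a_map):
        variants = [
            _variant(2000, "FERM-2", 0.5, 1.0),
            _variant(100, "Motor domain", 0.5, 1.0),
            _variant(900, "single α-helix", 0.5, 1.0),
        ]
        rows = fs.summarize_by_domain(variants, myo7a_map)
        assert [r.domain for r in rows] == ["Motor domain", "single α-helix", "FERM-2"]


class TestPhenotypeDomainCounts:
    def test_constructed_counts(self, myo7a_map):
        variants = [_variant(100, "Motor domain", 0.5, 1.0, phenotype="USH1B")] * 3
        variants += [_variant(1650, "SH3", 0.5, 1.0, phenotype="deafness")]
        matrix = fs.phenotype_domain_counts(variants, myo7a_map)
        assert matrix.counts.loc["USH1B", "Motor domain"] == 3
        assert matrix.counts.loc["deafness", "SH3"] == 1
        assert matrix.total == 4

    def test_empty_cohort_is_all_zero(self, myo7a_map):
        matrix = fs.phenotype_domain_counts([], myo7a_map)
        assert matrix.total == 0

    def test_grand_total_conserved(self, myo7a_map):
        rng = np.random.default_rng(9)
        domains = myo7a_map.names
        variants = [
            _variant(1, str(rng.choice(domains)), 0.5, 1.0,
                     phenotype=str(rng.choice(["USH1", "USH1B", "deafness"])))
            for _ in range(57)
        ]
        assert fs.phenotype_domain_counts(variants, myo7a_map).total == 57

    def test_published_hgmd_domain_totals(self, myo7a_map):
        """A cohort drawn to the published HGMD per-domain totals keeps them
        through annotation-free counting: motor region (incl. nested motifs) 79,
        IQ repeats 6, MyTH4 domains 21 and 13, FERM 17 and 24, SH3 4."""
        from foldscan.synthetic_data import positions_for_domain_counts

        counts = {
            "Motor domain": 79,
            "IQ1": 2, "IQ2": 1, "IQ3": 1, "IQ4": 1, "IQ5": 1,
            "MyTH-1": 21, "MyTH-2": 13,
            "FERM-1": 17, "FERM-2": 24,
            "SH3": 4,
        }
        positions = positions_for_domain_counts(myo7a_map, counts, seed=2)
        variants = [
            _variant(p, fs.assign_domain(p, myo7a_map), 0.5, 1.0) for p in positions
        ]
        matrix = fs.phenotype_domain_counts(variants, myo7a_map)
        col = matrix.counts.sum(axis=0)
        motor = col["Motor domain"] + col["ATP-binding motif"] + col["Actin-binding"]
        iq = sum(col[f"IQ{i}"] for i in range(1, 6))
        assert motor == 79
        assert iq == 6
        assert (col["MyTH-1"], col["MyTH-2"]) == (21, 13)
        assert (col["FERM-1"], col["FERM-2"]) == (17, 24)
        assert col["SH3"] == 4
        assert matrix.total == 79 + 6 + 21 + 13 + 17 + 24 + 4


class TestSeverityPercentages:
    def test_published_hgmd_fractions(self):
        summary = fs.severity_percentages(
            counts={"severe": 93, "moderate": 51, "stabilizing": 30, "weak": 4},
            n_high_destabilizing=77,
        )
        assert summary.n_total == 178
        assert summary.percent_high_destabilizing == 43.26
        assert summary.percent["severe"] == 52.25

    def test_published_clinvar_fractions(self):
        summary = fs.severity_percentages(
            counts={"severe": 266, "moderate": 201, "stabilizing": 16, "weak": 45},
            n_high_destabilizing=221,
        )
        assert summary.percent_high_destabilizing == 41.86
        assert round(summary.percent_high_destabilizing, 1) == 41.9
        assert summary.percent["severe"] == 50.38

    def test_zero_count_category_and_empty_cohort(self):
        summary = fs.severity_percentages(
            counts={"severe": 10}, n_high_destabilizing=0
        )
        assert summary.percent["weak"] == 0.0
        with pytest.raises(ValueError):
            fs.severity_percentages(counts={})

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 500), min_size=4, max_size=4))
    def test_percentages_sum_to_hundred(self, ks):
        if sum(ks) == 0:
            ks[0] = 1
        counts = dict(zip(("stabilizing", "weak", "moderate", "severe"), ks))
        summary = fs.severity_percentages(counts=counts)
        assert sum(summary.percent.values()) == pytest.approx(100.0, abs=0.02)


from tests_oracles import brute_force_adj_r2


class TestDomainRegression:
    def _rows(self, xs, ys):
        return [
            DomainSummaryRow(f"d{i}", None, 1, y, x)
            for i, (x, y) in enumerate(zip(xs, ys))
        ]

    def test_published_hgmd_rows_reproduce_adj_r2(self):
        rows = fs.load_published_domain_summary("hgmd")
        assert len(rows) == 13
        summary = fs.domain_regression(rows, cohort="hgmd")
        assert summary.adj_r2 == pytest.approx(0.69, abs=0.005)

    def test_published_clinvar_rows_reproduce_adj_r2(self):
        rows = fs.load_published_domain_summary("clinvar")
        assert len(rows) == 15
        summary = fs.domain_regression(rows, cohort="clinvar")
        assert summary.adj_r2 == pytest.approx(0.35, abs=0.005)

    def test_perfect_line(self):
        summary = fs.domain_regression(self._rows([0, 1, 2], [0.1, 0.3, 0.5]))
        assert summary.r2 == pytest.approx(1.0)
        assert summary.adj_r2 == pytest.approx(1.0)
        assert summary.slope == pytest.approx(0.2)

    def test_requires_three_rows_and_varying_predictor(self):
        with pytest.raises(ValueError, match="≥ 3"):
            fs.domain_regression(self._rows([0, 1], [0, 1]))
        with pytest.raises(ValueError, match="zero variance"):
            fs.domain_regression(self._rows([1, 1, 1], [0, 0.5, 1]))

    def test_r2_symmetric_under_axis_swap(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=8), rng.uniform(0, 1, 8)
        a = fs.domain_regression(self._rows(x, y))
        b = fs.domain_regression(self._rows(y, x))
        assert a.r2 == pytest.approx(b.r2, rel=1e-12)

    def test_matches_normal_equations_oracle_on_random_inputs(self):
        rng = np.random.default_rng(12345)
        for _ in range(100):
            n = int(rng.integers(3, 12))
            x = rng.normal(scale=2.0, size=n)
            while np.ptp(x) == 0:
                x = rng.normal(scale=2.0, size=n)
            y = 0.3 * x + rng.normal(scale=0.5, size=n)
            summary = fs.domain_regression(self._rows(x, y))
            beta, r2, adj = brute_force_adj_r2(x, y)
            assert summary.intercept == pytest.approx(beta[0], abs=1e-9)
            assert summary.slope == pytest.approx(beta[1], abs=1e-9)
            assert summary.r2 == pytest.approx(r2, abs=1e-9)
            assert summary.adj_r2 == pytest.approx(adj, abs=1e-9)
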