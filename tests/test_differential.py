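"""Comparison construction, normalization, censoring, p-values and CGSig."""

import math

import numpy as np
import pytest
from scipy import stats

from toothprot.differential import (
    ComparisonSpec,
    RatioResult,
    build_comparisons,
    censored_log2,
    comparison_pvalues,
    compute_ratio_results,
    normalize_abundances,
    select_cgsig,
)
from toothprot.io_formats import SpecimenDesign, ValidationError

from conftest import make_dataset, make_design, make_record

SIDS = ("T1", "T2", "C1", "C2")


class TestBuildComparisons:
    def test_two_by_two_batch_yields_full_cross(self):
        specs = build_comparisons(make_design("group1"))
        assert len(specs) == 4
        assert {(s.treatment, s.control) for s in specs} == {
            ("T1", "C1"), ("T1", "C2"), ("T2", "C1"), ("T2", "C2")
        }

    def test_two_batches_of_one_pair_yield_two(self):
        design = (make_design("group1", 1, 1)
                  + make_design("group2", 1, 1, offset=1))
        assert len(build_comparisons(design)) == 2

    def test_cartesian_product_count(self):
        specs = build_comparisons(make_design("group1", 3, 2))
        assert len(specs) == 6
        assert len({s.comparison_id for s in specs}) == 6

    def test_batch_missing_an_arm_rejected(self):
        design = [SpecimenDesign("T1", "group1", "treatment", "L1")]
        with pytest.raises(ValidationError):
            build_comparisons(design)


class TestNormalize:
    def test_equal_totals_are_left_alone(self):
        ds = make_dataset([
            make_record("P1", {"T1": 1.0, "T2": 2.0, "C1": 3.0, "C2": 4.0}),
            make_record("P2", {"T1": 9.0, "T2": 8.0, "C1": 7.0, "C2": 6.0}),
        ])
        out = normalize_abundances(ds)
        for orig, normed in zip(ds.records, out.records):
            for s in SIDS:
                assert normed.abundances[s] == pytest.approx(orig.abundances[s])

    def test_doubled_specimen_scaled_back(self):
        ds = make_dataset([
            make_record("P1", {"T1": 2.0, "T2": 1.0, "C1": 1.0, "C2": 1.0}),
            make_record("P2", {"T1": 6.0, "T2": 3.0, "C1": 3.0, "C2": 3.0}),
        ])
        out = normalize_abundances(ds)
        assert out.records[0].abundances["T1"] == pytest.approx(1.0)
        assert out.records[1].abundances["T1"] == pytest.approx(3.0)

    def test_totals_equal_after_normalization(self):
        rng = np.random.default_rng(11)
        records = [
            make_record(
                f"P{i}",
                {s: float(rng.lognormal(3, 1)) for s in SIDS},
            )
            for i in range(40)
        ]
        out = normalize_abundances(make_dataset(records))
        totals = {
            s: sum(r.abundances[s] for r in out.records) for s in SIDS
        }
        target = next(iter(totals.values()))
        for total in totals.values():
            assert total == pytest.approx(target, abs=1e-9 * target)

    def test_all_missing_specimen_rejected(self):
        ds = make_dataset([
            make_record("P1", {"T1": None, "T2": 1.0, "C1": 1.0, "C2": 1.0},
                        n_peptides=1),
        ])
        with pytest.raises(ValidationError, match="T1"):
            normalize_abundances(ds)


class TestCensoredLog2:
    @pytest.mark.parametrize(
        "raw,expected,censored",
        [
            (1.0, 0.0, False),
            (0.5, -1.0, False),
            (12.0, 3.32, True),     # +sentinel: raw ratios cap at 10-fold
            (1 / 12.0, -3.32, True),
            (9.0, math.log2(9.0), False),
        ],
    )
    def test_values(self, raw, expected, censored):
        value, flag = censored_log2(raw)
        assert value == pytest.approx(expected)
        assert flag is censored

    def test_missing_propagates(self):
        assert censored_log2(None) == (None, False)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValidationError):
            censored_log2(0.0)


def _peptide_dataset(log2_ratios, treatment="T1", control="C1"):
    """One protein whose peptide T/C log2 ratios equal `log2_ratios`."""
    peptides = {}
    for i, r in enumerate(log2_ratios):
        base = 100.0 * (i + 1)
        per_spec = {s: base for s in SIDS}
        per_spec[treatment] = base * 2.0 ** r
        peptides[f"pep{i + 1}"] = per_spec
    return make_dataset([
        make_record("P1", {s: 100.0 for s in SIDS}, peptides=peptides)
    ])


class TestComparisonPvalues:
    SPEC = ComparisonSpec("group1:T1/C1", "group1", "T1", "C1")

    def test_closed_form_t_statistic(self):
        ratios = [1.0, 1.1, 0.9, 1.2, 0.8]
        ds = _peptide_dataset(ratios)
        p, adj = comparison_pvalues(ds, self.SPEC)["P1"]
        # t = mean / (sd / sqrt(n)) = 14.14 on 4 df
        ref = stats.ttest_1samp(ratios, 0.0)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)
        assert p < 1e-3
        assert adj >= p

    def test_zero_variance_at_null_gives_p_one(self):
        p, adj = comparison_pvalues(_peptide_dataset([0.0] * 4), self.SPEC)["P1"]
        assert p == 1.0 and adj == 1.0

    def test_zero_variance_off_null_gives_missing(self):
        p, adj = comparison_pvalues(_peptide_dataset([1.0] * 4), self.SPEC)["P1"]
        assert p is None and adj is None

    def test_fewer_than_two_usable_peptides_gives_missing(self):
        p, _ = comparison_pvalues(_peptide_dataset([0.7]), self.SPEC)["P1"]
        assert p is None

    def test_unknown_specimen_rejected(self):
        with pytest.raises(ValidationError):
            comparison_pvalues(
                _peptide_dataset([0.1, 0.2]),
                ComparisonSpec("x", "group1", "T9", "C1"),
            )

    def test_benjamini_hochberg_matches_hand_stepup(self):
        # four proteins engineered to give distinct raw p-values
        records = []
        for i, ratios in enumerate(
            [[1.0, 1.1, 0.9], [0.8, 1.3, 1.0], [0.6, 1.5, 0.9], [0.4, 1.2, 1.6]]
        ):
            peptides = {}
            for j, r in enumerate(ratios):
                base = 50.0 * (j + 1)
                per_spec = {s: base for s in SIDS}
                per_spec["T1"] = base * 2.0 ** r
                peptides[f"pep{j + 1}"] = per_spec
            records.append(
                make_record(f"P{i}", {s: 100.0 for s in SIDS}, peptides=peptides)
            )
        out = comparison_pvalues(make_dataset(records), self.SPEC)
        accs = sorted(out)
        raw = np.array([out[a][0] for a in accs])
        adj = np.array([out[a][1] for a in accs])

        # independent step-up oracle
        m = raw.size
        order = np.argsort(raw)
        expected = np.empty(m)
        running = 1.0
        for rank_from_top in range(m, 0, -1):
            i = order[rank_from_top - 1]
            running = min(running, raw[i] * m / rank_from_top)
            expected[i] = running
        assert adj == pytest.approx(expected, rel=1e-12)

    def test_bh_of_uniform_grid_collapses_to_max(self):
        # {0.01, 0.02, 0.03, 0.04} -> all adjusted to 0.04
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert adj == pytest.approx([0.04] * 4)


class TestRatioResults:
    def test_antisymmetry_under_arm_swap(self):
        ds = _peptide_dataset([0.9, 1.1, 1.0, 0.8])
        forward = ComparisonSpec("f", "group1", "T1", "C1")
        backward = ComparisonSpec("b", "group1", "C1", "T1")
        rf = compute_ratio_results(ds, [forward])[0]
        # swapped-arm run computed on a design where C1 is "treatment"
        rb_p = comparison_pvalues(ds, backward)["P1"]
        assert rf.log2_ratio is not None
        rb_raw = (
            ds.records[0].abundances["C1"] / ds.records[0].abundances["T1"]
        )
        assert math.log2(rb_raw) == pytest.approx(-rf.log2_ratio)
        assert rb_p[0] == pytest.approx(rf.p_value)

    def test_missing_side_blanks_everything(self):
        ds = make_dataset([
            make_record("P1", {"T1": None, "T2": 2.0, "C1": 1.0, "C2": 1.0})
        ])
        spec = ComparisonSpec("group1:T1/C1", "group1", "T1", "C1")
        r = compute_ratio_results(ds, [spec])[0]
        assert r.missing
        assert r.raw_ratio is None and r.log2_ratio is None
        assert r.p_value is None and r.adj_p_value is None


def _rr(acc, comp, adj_p, missing=False, log2=1.0):
    if missing:
        return RatioResult(acc, comp, None, None, False, None, None)
    return RatioResult(acc, comp, 2.0 ** log2, log2, False,
                       adj_p, adj_p)


class TestSelectCgsig:
    def test_significant_in_one_batch_only_is_excluded(self):
        g1 = [_rr("A", "g1:c0", 0.01)] + [_rr("A", f"g1:c{i}", 0.5) for i in (1, 2, 3)]
        g2 = [_rr("A", f"g2:c{i}", 0.5) for i in range(4)]
        assert select_cgsig(g1, g2) == []

    def test_significant_once_per_batch_is_included(self):
        g1 = [_rr("A", "g1:c0", 0.04)] + [_rr("A", f"g1:c{i}", 0.9) for i in (1, 2, 3)]
        g2 = [_rr("A", "g2:c0", 0.05)] + [_rr("A", f"g2:c{i}", 0.9) for i in (1, 2, 3)]
        assert select_cgsig(g1, g2) == ["A"]

    def test_two_missing_comparisons_discard_a_significant_protein(self):
        g1 = [_rr("A", "g1:c0", 0.01), _rr("A", "g1:c1", None, missing=True)] + [
            _rr("A", f"g1:c{i}", 0.9) for i in (2, 3)
        ]
        g2 = [_rr("A", "g2:c0", 0.01), _rr("A", "g2:c1", None, missing=True)] + [
            _rr("A", f"g2:c{i}", 0.9) for i in (2, 3)
        ]
        assert select_cgsig(g1, g2) == []
        # a single missing comparison is tolerated
        g2_ok = [_rr("A", "g2:c0", 0.01)] + [_rr("A", f"g2:c{i}", 0.9) for i in (1, 2, 3)]
        assert select_cgsig(g1, g2_ok) == ["A"]

    def test_monotone_in_alpha_and_max_missing(self):
        rng = np.random.default_rng(3)
        g1, g2 = [], []
        for i in range(60):
            acc = f"P{i}"
            for batch, coll in (("g1", g1), ("g2", g2)):
                for c in range(4):
                    if rng.random() < 0.1:
                        coll.append(_rr(acc, f"{batch}:c{c}", None, missing=True))
                    else:
                        coll.append(_rr(acc, f"{batch}:c{c}", float(rng.random())))
        prev_alpha: set = set()
        for alpha in (0.01, 0.05, 0.2, 0.8, 1.0):
            now = set(select_cgsig(g1, g2, alpha=alpha))
            assert prev_alpha <= now
            prev_alpha = now
        prev_missing: set = set()
        for max_missing in (0, 1, 2, 8):
            now = set(select_cgsig(g1, g2, alpha=0.2, max_missing=max_missing))
            assert prev_missing <= now
            prev_missing = now

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValidationError):
            select_cgsig([], [], alpha=0.0)
        with pytest.raises(ValidationError):
            select_cgsig([], [], alpha=1.2)
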