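"""Unit tests for truth matching, recovery, stratification and rounding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asmbench import evalkit, simgenome
from asmbench.callers import Call
from asmbench.errors import InputError
from asmbench.simgenome import TruthVariant


def _truth(positions, genotype="HET", chrom="chr1"):
    return [
        TruthVariant(chrom, p, "A", "C", "SNV", genotype) for p in positions
    ]


def _calls(positions, chrom="chr1", alt="C"):
    return [Call(chrom, p, "A", alt, "HET", "alignment") for p in positions]


class TestMatchCalls:
    def test_identity(self):
        truth = _truth([10, 20, 30])
        ev = evalkit.match_calls(truth, _calls([10, 20, 30]))
        assert (ev.tp, ev.fp, ev.fn) == (3, 0, 0)
        assert ev.recall == 1.0 and ev.precision == 1.0

    def test_empty_calls_flagged(self):
        ev = evalkit.match_calls(_truth([10]), [])
        assert ev.recall == 0.0 and ev.precision == 0.0
        assert ev.no_calls

    def test_hand_set_algebra(self):
        ev = evalkit.match_calls(_truth([1, 2, 3]), _calls([2, 3, 4]))
        assert (ev.tp, ev.fn, ev.fp) == (2, 1, 1)
        assert ev.recall == pytest.approx(2 / 3)
        assert ev.precision == pytest.approx(2 / 3)

    def test_allele_must_match(self):
        ev = evalkit.match_calls(_truth([10]), _calls([10], alt="G"))
        assert (ev.tp, ev.fp, ev.fn) == (0, 1, 1)

    def test_duplicates_rejected(self):
        with pytest.raises(InputError):
            evalkit.match_calls(_truth([10, 10]), [])
        with pytest.raises(InputError):
            evalkit.match_calls(_truth([10]), _calls([5, 5]))

    @settings(max_examples=50, deadline=None)
    @given(
        st.sets(st.integers(1, 500), max_size=60),
        st.sets(st.integers(1, 500), max_size=60),
    )
    def test_conservation_tp_plus_fn(self, truth_pos, call_pos):
        """tp + fn always equals |truth| and the sets partition cleanly."""
        truth = _truth(sorted(truth_pos))
        ev = evalkit.match_calls(truth, _calls(sorted(call_pos)))
        assert ev.tp + ev.fn == len(truth)
        assert ev.tp_set | ev.fn_set == {v.key for v in truth}
        assert not (ev.tp_set & ev.fp_set)


class TestPaperArithmetic:
    """Recall/precision/recovery recomputed from printed count triples."""

    @pytest.mark.parametrize(
        "tp,fn,expected",
        [
            (1_803_891, 1_706_451, 0.51),
            (1_810_100, 1_700_242, 0.52),
            (2_613_576, 896_766, 0.74),
            (3_434_979, 75_363, 0.98),
        ],
    )
    def test_recall_two_dp(self, tp, fn, expected):
        assert evalkit.round_half_up(tp / (tp + fn), 2) == expected

    @pytest.mark.parametrize(
        "tp,fp,expected",
        [
            (3_503_529, 528_789, 0.87),
            (1_803_891, 115_787, 0.94),
            (1_810_100, 189_185, 0.91),
            (2_613_576, 927_616, 0.74),
        ],
    )
    def test_precision_two_dp(self, tp, fp, expected):
        assert evalkit.round_half_up(tp / (tp + fp), 2) == expected

    @pytest.mark.parametrize(
        "recovered,missed,expected",
        [
            (10_843, 341_558, 3),
            (9_060, 120_804, 7),
            (5_756, 54_591, 11),
            (2_892, 25_788, 11),
            (1_797, 17_850, 10),
        ],
    )
    def test_recovery_rate_percent(self, recovered, missed, expected):
        truth = _truth(range(1, missed + 1))
        ev = evalkit.match_calls(truth, [])
        calls_b = _calls(range(1, recovered + 1))
        rec = evalkit.recovery(truth, ev, calls_b)
        assert rec.rate == expected
        assert rec.recovered <= rec.missed


class TestRecovery:
    def test_empty_calls_b(self):
        truth = _truth([1, 2, 3])
        ev = evalkit.match_calls(truth, [])
        assert evalkit.recovery(truth, ev, []).rate == 0

    def test_nothing_missed_flagged(self):
        truth = _truth([1, 2])
        ev = evalkit.match_calls(truth, _calls([1, 2]))
        rec = evalkit.recovery(truth, ev, _calls([1]))
        assert rec.rate == 0 and rec.no_missed


class TestZygosityRatio:
    def test_ratios(self):
        vs = _truth([1] * 0)  # empty base
        vs = _truth(range(1, 11), "HOM") + _truth(range(11, 16), "HET")
        z = evalkit.zygosity_ratio(vs)
        assert (z.n_hom, z.n_het) == (10, 5)
        assert z.ratio == 2.0
        z0 = evalkit.zygosity_ratio(_truth(range(1, 6), "HET"))
        assert z0.ratio == 0.0

    def test_undefined_without_hets(self):
        z = evalkit.zygosity_ratio(_truth([1, 2], "HOM"))
        with pytest.raises(InputError):
            _ = z.ratio


class TestRoundHalfUp:
    @pytest.mark.parametrize(
        "value,digits,expected",
        [
            (0.93968, 2, 0.94),
            (10.544, 0, 11),
            (0.5, 0, 1),
            (0.125, 2, 0.13),  # would round to 0.12 under banker's rounding
            (3.1746, 0, 3),
            (7.4997, 0, 7),
        ],
    )
    def test_values(self, value, digits, expected):
        assert evalkit.round_half_up(value, digits) == expected


class TestStratifyByRegion:
    def test_empty_model_intergenic_equals_global(self):
        truth = _truth([100, 200, 300])
        ev = evalkit.match_calls(truth, _calls([200, 300, 400]))
        strata = evalkit.stratify_by_region(
            ev, simgenome.GeneModel(genes=[]), 1000
        )
        inter = strata["intergenic"]
        assert (inter["tp"], inter["fp"], inter["fn"]) == (ev.tp, ev.fp, ev.fn)
        for name in ("CDS", "UTR", "intron"):
            assert strata[name]["tp"] == 0

    def test_partition_sums_to_global(self):
        g = simgenome.generate_reference(10_000, seed=137)
        model = simgenome.generate_gene_model(g, 3, seed=139)
        rng = np.random.default_rng(149)
        truth_pos = sorted(rng.choice(range(1, 10_001), 50, replace=False).tolist())
        call_pos = sorted(rng.choice(range(1, 10_001), 50, replace=False).tolist())
        ev = evalkit.match_calls(_truth(truth_pos), _calls(call_pos))
        strata = evalkit.stratify_by_region(ev, model, 10_000)
        for attr, total in (("tp", ev.tp), ("fp", ev.fp), ("fn", ev.fn)):
            assert sum(s[attr] for s in strata.values()) == total

    def test_hand_placed_variants(self):
        g = simgenome.generate_reference(10_000, seed=151)
        model = simgenome.generate_gene_model(g, 2, seed=151)
        region = model.region_array(10_000)
        # pick one known position per region present in this model
        picks = {}
        for code, name in simgenome.REGION_NAMES.items():
            idx = np.nonzero(region == code)[0]
            if idx.size:
                picks[name] = int(idx[0]) + 1
        truth = _truth(sorted(picks.values()))
        ev = evalkit.match_calls(truth, _calls(sorted(picks.values())))
        strata = evalkit.stratify_by_region(ev, model, 10_000)
        for name, pos in picks.items():
            assert strata[name]["tp"] == 1


class TestStratifyByConfidence:
    def _ev(self, tp_pos, fp_pos):
        truth = _truth(sorted(tp_pos))
        calls = _calls(sorted(set(tp_pos) | set(fp_pos)))
        return evalkit.match_calls(truth, calls)

    def test_hand_table(self):
        regions = simgenome.ConfidenceRegions(high=[(0, 1000)], genome_length=2000)
        tp = list(range(1, 91)) + list(range(1001, 1011))  # 90 high, 10 low
        fp = list(range(101, 151)) + list(range(1101, 1151))  # 50 high, 50 low
        out = evalkit.stratify_by_confidence(self._ev(tp, fp), regions)
        assert out["table"] == [[90, 10], [50, 50]]
        # Pearson on expected [[70,30],[70,30]]: 2*400/70 + 2*400/30
        assert out["chi2"] == pytest.approx(800 / 70 + 800 / 30, abs=1e-6)
        assert out["p"] < 0.001

    def test_null_case(self):
        regions = simgenome.ConfidenceRegions(high=[(0, 1000)], genome_length=2000)
        tp = list(range(1, 51)) + list(range(1001, 1051))
        fp = list(range(101, 151)) + list(range(1101, 1151))
        out = evalkit.stratify_by_confidence(self._ev(tp, fp), regions)
        assert out["chi2"] == pytest.approx(0.0, abs=1e-9)
        assert out["p"] == pytest.approx(1.0)

    def test_extreme_separation(self):
        regions = simgenome.ConfidenceRegions(high=[(0, 1000)], genome_length=2000)
        tp = list(range(1, 101))  # all high
        fp = list(range(1001, 1101))  # all low
        out = evalkit.stratify_by_confidence(self._ev(tp, fp), regions)
        assert out["p"] < 0.001

    def test_zero_margin_skipped(self):
        regions = simgenome.ConfidenceRegions(high=[(0, 2000)], genome_length=2000)
        out = evalkit.stratify_by_confidence(self._ev([1, 2], [10]), regions)
        assert not out["tested"] and out["p"] is None


@settings(max_examples=50, deadline=None)
@given(
    st.sets(st.integers(1, 200), max_size=40),
    st.sets(st.integers(1, 200), max_size=40),
    st.sets(st.integers(1, 200), max_size=40),
)
def test_venn_decomposition_additive(t, a, b):
    """The seven disjoint regions sum to |union| and are non-negative."""
    keys = lambda s: {("chr1", p, "C") for p in s}
    counts = evalkit.venn_counts(keys(t), keys(a), keys(b))
    assert all(v >= 0 for v in counts.values())
    assert sum(counts.values()) == len(keys(t) | keys(a) | keys(b))
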