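"""Rates, normalization, quartile selection, register means, ROC."""

import numpy as np
import pytest

from bashmap.io_formats import SequenceRecord
from bashmap.reactivity import (
    ReactivityProfile,
    bottom_quartile_gs,
    misincorporation_rates,
    normalize_reactivity,
    register_mean_rates,
    roc_auc,
)
from bashmap.simulate import ConformerSpec, EnsembleSpec, simulate_reads
from conftest import make_readset


def profile_from(rates, seq=None):
    seq = seq or "G" * len(rates)
    return ReactivityProfile.from_rates(SequenceRecord("x", seq), np.asarray(rates, float))


class TestRates:
    def test_unanimous_column(self, tiny_readset):
        prof = misincorporation_rates(tiny_readset, min_cov=1)
        assert np.allclose(prof.rates(), [0, 1, 0, 0])

    def test_half_column(self):
        rs = make_readset("ACGU", ["0100", "0000"])
        prof = misincorporation_rates(rs, min_cov=1)
        assert prof.rate_at(2) == pytest.approx(0.5)

    def test_low_coverage_flagged(self):
        rs = make_readset("ACGU", [(1, "01"), (1, "0100")])
        prof = misincorporation_rates(rs, min_cov=2)
        assert np.isnan(prof.rate_at(3))
        assert prof.data.loc[2, "flag"] == "low_coverage"
        assert prof.rate_at(1) == 0.0

    def test_matches_brute_force_counts(self):
        rng = np.random.default_rng(0)
        L, n = 12, 40
        rows = []
        for _ in range(n):
            s = int(rng.integers(1, L + 1))
            e = int(rng.integers(s, L + 1))
            rows.append((s, "".join(rng.choice(["0", "1"], size=e - s + 1))))
        rs = make_readset("A" * L, rows)
        prof = misincorporation_rates(rs, min_cov=1)
        for pos in range(1, L + 1):
            hits = sum(r.bit_at(pos) for r in rs.reads if r.covers(pos))
            cov = sum(1 for r in rs.reads if r.covers(pos))
            expected = hits / cov if cov else np.nan
            got = prof.rate_at(pos)
            assert (np.isnan(got) and cov == 0) or got == pytest.approx(expected)


class TestNormalization:
    def test_uniform_rates_map_to_one(self):
        prof = normalize_reactivity(profile_from([0.02] * 10), per_base=False)
        assert np.allclose(prof.reactivities(), 1.0)

    def test_boxplot_outlier_dropped(self):
        rates = [0.01] * 9 + [0.50]
        prof = normalize_reactivity(profile_from(rates), per_base=False)
        assert np.allclose(prof.reactivities()[:9], 1.0)
        assert prof.norm_params["factors"]["all"] == pytest.approx(0.01)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        rates = rng.uniform(0.001, 0.2, size=30)
        r1 = normalize_reactivity(profile_from(rates), per_base=False).reactivities()
        r2 = normalize_reactivity(profile_from(rates * 7.3), per_base=False).reactivities()
        assert np.allclose(r1, r2)

    def test_idempotent_on_normalized(self):
        rng = np.random.default_rng(2)
        rates = rng.uniform(0.001, 0.2, size=40)
        once = normalize_reactivity(profile_from(rates), per_base=False)
        renorm = ReactivityProfile.from_rates(
            SequenceRecord("x", "G" * 40), once.reactivities()
        )
        twice = normalize_reactivity(renorm, per_base=False)
        assert twice.norm_params["factors"]["all"] == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_class_flagged(self):
        prof = normalize_reactivity(profile_from([0.0] * 5), per_base=False)
        assert np.isnan(prof.reactivities()).all()
        assert (prof.data["flag"] == "unnormalized").all()

    def test_per_base_uses_separate_factors(self):
        seq = "AAAAGGGG"
        rates = [0.1, 0.1, 0.1, 0.1, 0.01, 0.01, 0.01, 0.01]
        prof = normalize_reactivity(profile_from(rates, seq), per_base=True)
        assert np.allclose(prof.reactivities(), 1.0)


class TestBottomQuartileGs:
    def test_two_lowest_of_eight(self):
        rates = [0.01, 0.02, 0.05, 0.08, 0.10, 0.15, 0.20, 0.30]
        # percentile (linear) of 8 values: between 2nd and 3rd; ties included
        got = bottom_quartile_gs(profile_from(rates))
        assert got == {1, 2}

    def test_all_ties_included(self):
        got = bottom_quartile_gs(profile_from([0.05] * 6))
        assert got == {1, 2, 3, 4, 5, 6}

    def test_no_gs_empty(self):
        got = bottom_quartile_gs(profile_from([0.1, 0.2], seq="AC"))
        assert got == set()

    def test_matches_percentile_oracle(self):
        rng = np.random.default_rng(3)
        rates = rng.uniform(0, 1, size=23)
        cutoff = np.percentile(rates, 25)
        expected = {i + 1 for i, r in enumerate(rates) if r <= cutoff}
        assert bottom_quartile_gs(profile_from(rates)) == expected


class TestRegisterMeans:
    def test_single_member(self):
        prof = profile_from([0.1, 0.2, 0.3])
        out = register_mean_rates(prof, [[2]])
        assert out["mean_rate"].iloc[0] == pytest.approx(0.2)

    def test_uniform_rates_equal_means(self):
        prof = profile_from([0.1] * 8)
        out = register_mean_rates(prof, [[1, 2], [3, 4], [5, 6, 7]])
        assert np.allclose(out["mean_rate"], 0.1)
        assert out["is_min"].all()

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        rates = rng.uniform(0, 1, size=20)
        prof = profile_from(rates)
        regs = [[1, 5, 9], [2, 3], [10, 11, 12, 13]]
        out = register_mean_rates(prof, regs)
        for row, members in zip(out.itertuples(), regs):
            assert row.mean_rate == pytest.approx(np.mean([rates[m - 1] for m in members]))
        assert out.loc[out["is_min"], "mean_rate"].iloc[0] == out["mean_rate"].min()


class TestRocAuc:
    def test_perfect_separation(self):
        seq = "AAAAAA"
        labels = {1: "unpaired", 2: "unpaired", 3: "unpaired", 4: "paired", 5: "paired", 6: "paired"}
        prof = profile_from([0.5, 0.4, 0.3, 0.1, 0.05, 0.01], seq)
        assert roc_auc(prof, labels, bases=("A",))["A"] == pytest.approx(1.0)

    def test_no_information(self):
        seq = "AAAA"
        labels = {1: "unpaired", 2: "unpaired", 3: "paired", 4: "paired"}
        prof = profile_from([0.2, 0.2, 0.2, 0.2], seq)
        assert roc_auc(prof, labels, bases=("A",))["A"] == pytest.approx(0.5)

    def test_matches_all_pairs_count(self):
        rng = np.random.default_rng(5)
        L = 20
        seq = "A" * L
        rates = np.round(rng.uniform(0, 0.3, size=L), 2)  # rounding creates ties
        lab = rng.choice(["paired", "unpaired"], size=L)
        labels = {i + 1: lab[i] for i in range(L)}
        prof = profile_from(rates, seq)
        got = roc_auc(prof, labels, bases=("A",))["A"]
        unp = rates[lab == "unpaired"]
        par = rates[lab == "paired"]
        wins = sum((u > p) + 0.5 * (u == p) for u in unp for p in par)
        assert got == pytest.approx(wins / (len(unp) * len(par)))


def test_structural_class_rate_ordering_on_simulation():
    """Mean rate ordering single-stranded G > paired G > quartet G (strict)."""
    seq = list("A" * 40)
    for i in range(8):
        seq[i] = "G"       # helix 5' side: paired G's
        seq[39 - i] = "C"  # helix 3' side
    quartet = [12, 17, 22, 27]
    for p in quartet:
        seq[p - 1] = "G"
    ss_g = [30, 31]
    for p in ss_g:
        seq[p - 1] = "G"
    seq = "".join(seq)
    structure = "(" * 8 + "." * 24 + ")" * 8
    ref = SequenceRecord("ordering", seq)
    conf = ConformerSpec(name="c", structure=structure, quartet_sets=[quartet])
    spec = EnsembleSpec(
        reference=ref, conformers=[conf], proportions=[1.0], n_reads=20000, seed=8
    )
    rs, _ = simulate_reads(spec)
    prof = misincorporation_rates(rs, min_cov=100)
    ss = np.mean([prof.rate_at(p) for p in ss_g])
    paired = np.mean([prof.rate_at(p) for p in range(1, 9)])
    quart = np.mean([prof.rate_at(p) for p in quartet])
    assert ss > paired > quart
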