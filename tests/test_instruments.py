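import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrscreen.exceptions import ComputationError, InputError
from mrscreen.instruments import (
    ClumpConfig,
    LDPanel,
    PRIMARY,
    STRINGENT,
    compute_f,
    compute_r2,
    ld_clump,
    select_instruments,
    steiger_filter,
)
from mrscreen.simulate import SimConfig, scenario_presets, simulate_pair
from mrscreen.sumstats import harmonize

from conftest import make_iv, make_variant


class TestComputeR2:
    def test_zero_beta_gives_zero(self):
        assert compute_r2(0.0, 0.3, 0.01, 10000) == 0.0

    def test_direct_arithmetic(self):
        # beta^2 = 0.01, N*SE^2 = 1.0 -> 0.01/1.01
        assert compute_r2(0.1, 0.3, 0.01, 10000) == pytest.approx(0.01 / 1.01)

    @pytest.mark.parametrize("eaf", [0.1, 0.3, 0.49])
    def test_eaf_cancels(self, eaf):
        assert compute_r2(0.1, eaf, 0.01, 10000) == pytest.approx(compute_r2(0.1, 0.25, 0.01, 10000))

    def test_range(self):
        assert 0.0 <= compute_r2(5.0, 0.2, 0.001, 100) < 1.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ComputationError):
            compute_r2(float("nan"), 0.3, 0.01, 10000)
        with pytest.raises(ComputationError):
            compute_r2(0.1, 0.3, 0.0, 10000)


class TestComputeF:
    def test_zero_r2(self):
        assert compute_f(0.0, 100) == 0.0

    def test_direct_arithmetic(self):
        assert compute_f(0.5, 4) == pytest.approx(2.0)

    def test_monotone_in_r2(self):
        grid = np.linspace(0.0, 0.9, 50)
        vals = [compute_f(r, 1000) for r in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_r2_out_of_range_rejected(self):
        with pytest.raises(ComputationError):
            compute_f(1.0, 100)


def _candidates(pvals, positions, chrom="1"):
    return [make_variant(f"v{i}", 0.1, 0.01, p, chrom=chrom, pos=pos)
            for i, (p, pos) in enumerate(zip(pvals, positions))]


def clump_fixpoint_oracle(cands, panel, cfg):
    """Independent characterization: the unique subset S such that each
    p-eligible candidate is in S iff compatible with its smaller-p members."""
    elig = sorted((c for c in cands if c.pvalue < cfg.p_threshold),
                  key=lambda c: (c.pvalue, str(c.chrom), c.pos, c.variant_id))

    def incompatible(a, b):
        if a.chrom != b.chrom:
            return False
        if abs(a.pos - b.pos) > cfg.window_kb * 1000:
            return False
        if a.variant_id not in panel or b.variant_id not in panel:
            return False
        return panel.r2_between(a.variant_id, b.variant_id) >= cfg.r2_threshold

    solutions = []
    for mask in itertools.product([0, 1], repeat=len(elig)):
        S = [c for c, m in zip(elig, mask) if m]
        ok = True
        for i, c in enumerate(elig):
            earlier = [s for s in S if (s.pvalue, str(s.chrom), s.pos, s.variant_id)
                       < (c.pvalue, str(c.chrom), c.pos, c.variant_id)]
            should_be_in = not any(incompatible(c, e) for e in earlier)
            if bool(mask[i]) != should_be_in:
                ok = False
                break
        if ok:
            solutions.append([c.variant_id for c in S])
    assert len(solutions) == 1
    return solutions[0]


class TestLdClump:
    def test_single_candidate_below_threshold(self):
        cands = _candidates([1e-8], [100])
        panel = LDPanel.identity(["v0"])
        assert ld_clump(cands, panel, PRIMARY) == ["v0"]

    def test_correlated_pair_keeps_smaller_p(self):
        cands = _candidates([1e-7, 1e-9], [100_000, 200_000])
        panel = LDPanel(["v0", "v1"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert ld_clump(cands, panel, PRIMARY) == ["v1"]

    def test_pair_outside_window_both_kept(self):
        cands = _candidates([1e-9, 1e-7], [100_000, 900_000])
        panel = LDPanel(["v0", "v1"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        assert set(ld_clump(cands, panel, PRIMARY)) == {"v0", "v1"}

    def test_cross_chromosome_independent(self):
        a = make_variant("v0", 0.1, 0.01, 1e-9, chrom="1", pos=100)
        b = make_variant("v1", 0.1, 0.01, 1e-8, chrom="2", pos=100)
        panel = LDPanel(["v0", "v1"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        assert set(ld_clump([a, b], panel, PRIMARY)) == {"v0", "v1"}

    def test_absent_from_panel_treated_independent(self):
        cands = _candidates([1e-9, 1e-8], [100_000, 150_000])
        panel = LDPanel.identity(["v0"])
        assert set(ld_clump(cands, panel, PRIMARY)) == {"v0", "v1"}

    def test_p_filter_empty_result(self):
        cands = _candidates([1e-3], [100])
        assert ld_clump(cands, LDPanel.identity(["v0"]), PRIMARY) == []

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_fixpoint_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        pvals = 10.0 ** rng.uniform(-12, -3, n)
        pos = rng.integers(1, 2_000_000, n)
        corr = rng.uniform(0, 1, (n, n))
        r2 = (corr + corr.T) / 2
        np.fill_diagonal(r2, 1.0)
        cands = _candidates(pvals, pos)
        panel = LDPanel([c.variant_id for c in cands], r2)
        assert ld_clump(cands, panel, PRIMARY) == clump_fixpoint_oracle(cands, panel, PRIMARY)

    def test_clumped_set_pairwise_below_threshold(self):
        rng = np.random.default_rng(7)
        n = 40
        pvals = 10.0 ** rng.uniform(-12, -6.5, n)
        pos = rng.integers(1, 5_000_000, n)
        corr = rng.uniform(0, 1, (n, n))
        r2 = (corr + corr.T) / 2
        np.fill_diagonal(r2, 1.0)
        cands = _candidates(pvals, pos)
        panel = LDPanel([c.variant_id for c in cands], r2)
        kept = ld_clump(cands, panel, PRIMARY)
        by_id = {c.variant_id: c for c in cands}
        for a, b in itertools.combinations(kept, 2):
            ca, cb = by_id[a], by_id[b]
            if abs(ca.pos - cb.pos) <= PRIMARY.window_kb * 1000:
                assert panel.r2_between(a, b) < PRIMARY.r2_threshold

    def test_ld_free_panel_returns_p_filtered_set(self):
        cands = _candidates([1e-9, 1e-8, 1e-3], [1, 100, 200])
        panel = LDPanel.identity([c.variant_id for c in cands])
        assert set(ld_clump(cands, panel, PRIMARY)) == {"v0", "v1"}


class TestLDPanel:
    def test_symmetry_enforced(self):
        with pytest.raises(InputError):
            LDPanel(["a", "b"], np.array([[1.0, 0.5], [0.2, 1.0]]))

    def test_diagonal_enforced(self):
        with pytest.raises(InputError):
            LDPanel(["a", "b"], np.array([[0.9, 0.5], [0.5, 1.0]]))

    def test_round_trip_square_tsv(self, tmp_path):
        panel = LDPanel(["a", "b"], np.array([[1.0, 0.25], [0.25, 1.0]]))
        panel.write(tmp_path / "ld.tsv")
        back = LDPanel.read(tmp_path / "ld.tsv")
        assert back.variant_ids == ["a", "b"]
        assert back.r2_between("a", "b") == pytest.approx(0.25)

    def test_long_format(self, tmp_path):
        (tmp_path / "ld.tsv").write_text("id1\tid2\tr2\nrsA\trsB\t0.4\n")
        panel = LDPanel.read(tmp_path / "ld.tsv")
        assert panel.r2_between("rsA", "rsB") == pytest.approx(0.4)

    def test_from_dosages_matches_corrcoef(self):
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, size=(200, 4)).astype(float)
        panel = LDPanel.from_dosages(list("abcd"), dos)
        expected = np.corrcoef(dos, rowvar=False) ** 2
        assert np.allclose(panel.r2, expected)


class TestSteigerFilter:
    def test_clear_direction_kept(self):
        iv = make_iv("v0", 0.2, 0.009, 0.01, 0.01, n_exp=10000, n_out=50000)
        assert iv.r2_exp > 0.01 and iv.r2_out < 1e-4
        kept, removed = steiger_filter([iv])
        assert [k.variant_id for k in kept] == ["v0"] and removed == []

    def test_wrong_direction_removed(self):
        iv = make_iv("v0", 0.02, 0.009, 0.5, 0.01, n_exp=10000, n_out=50000)
        assert iv.r2_out > iv.r2_exp
        kept, removed = steiger_filter([iv])
        assert kept == [] and removed == ["v0"]

    def test_reverse_scenario_majority_removed(self):
        removed_frac = []
        for seed in range(20):
            cfg = scenario_presets(seed)["reverse_causal"]
            exp, out, _panel, _truth = simulate_pair(cfg)
            ivs = harmonize(exp, out)
            kept, removed = steiger_filter(ivs)
            removed_frac.append(len(removed) / len(ivs))
        assert np.mean(removed_frac) > 0.5


class TestSelectInstruments:
    def test_no_significant_variants(self):
        exp = [make_variant("v0", 0.01, 0.01, 0.5)]
        out = [make_variant("v0", 0.0, 0.02, 0.9, n=50000)]
        from mrscreen.instruments import SelectionLog
        log = SelectionLog()
        assert select_instruments(exp, out, LDPanel.identity(["v0"]), log=log) == []
        assert log.reason == "no significant variants"

    def test_high_eaf_excluded_by_maf_filter(self):
        exp = [make_variant("v0", 0.5, 0.01, 1e-20, eaf=0.97)]
        out = [make_variant("v0", 0.1, 0.02, 1e-4, eaf=0.97, n=50000)]
        from mrscreen.instruments import SelectionLog
        log = SelectionLog()
        select_instruments(exp, out, LDPanel.identity(["v0"]), log=log)
        assert log.n_after_maf == 0

    def test_strong_independent_variants_all_retained(self):
        cfg = SimConfig(n_snps=10, gamma_mean=0.15, gamma_sd=0.01, gamma_min_abs=0.12,
                        eaf_range=(0.3, 0.5), theta=0.2, seed=11)
        exp, out, panel, _ = simulate_pair(cfg)
        ivs = select_instruments(exp, out, panel)
        assert len(ivs) == 10

    def test_f_and_threshold_invariants_on_output(self):
        cfg = SimConfig(theta=0.2, seed=5)
        exp, out, panel, _ = simulate_pair(cfg)
        ivs = select_instruments(exp, out, panel)
        assert ivs
        for iv in ivs:
            assert iv.f_stat >= 10.0
            assert iv.pvalue_exp < PRIMARY.p_threshold
            assert compute_f(compute_r2(iv.beta_exp, iv.eaf, iv.se_exp, iv.n_exp), iv.n_exp) == iv.f_stat

    def test_stringent_nested_in_primary(self):
        cfg = SimConfig(theta=0.2, seed=9)
        exp, out, panel, _ = simulate_pair(cfg)
        primary = select_instruments(exp, out, panel, PRIMARY)
        stringent = select_instruments(exp, out, panel, STRINGENT)
        assert len(stringent) <= len(primary)


class TestClumpConfig:
    def test_invalid_thresholds_rejected(self):
        with pytest.raises(InputError):
            ClumpConfig(p_threshold=0.0)
        with pytest.raises(InputError):
            ClumpConfig(r2_threshold=1.5)
        with pytest.raises(InputError):
            ClumpConfig(window_kb=0)
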