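import numpy as np
import pytest
from scipy import stats

from axenet.master_table import read_master_table, write_master_table
from axenet.synthetic import (
    DEFAULT_SUCCESS_PROB,
    SyntheticConfig,
    generate_master_table,
    recovery_report,
    transition_matrix,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_publications": 0},
            {"p_in": 0.1, "p_out": 0.5},
            {"workflow_length": (0, 4)},
            {"continue_prob": 1.5},
            {"success_prob": {"Mkpk": 0.5}},
        ],
    )
    def test_invalid_config_rejected_before_generation(self, kwargs):
        with pytest.raises(ValueError):
            generate_master_table(SyntheticConfig(**kwargs))

    def test_rubric_distribution_must_sum_to_one(self):
        bad = {q: dict(d) for q, d in SyntheticConfig().rubric_distribution.items()}
        bad["q1"]["yes"] = 0.9
        with pytest.raises(ValueError, match="sum to 1"):
            generate_master_table(SyntheticConfig(rubric_distribution=bad))


class TestTransitionMatrix:
    def test_rows_are_stochastic(self):
        m = transition_matrix(SyntheticConfig())
        assert np.allclose(m.sum(axis=1), 1.0)

    def test_equal_probabilities_give_uniform_matrix(self):
        m = transition_matrix(SyntheticConfig(p_in=0.3, p_out=0.3))
        assert np.allclose(m, 1.0 / m.shape[0])

    def test_within_cluster_entries_dominate(self):
        config = SyntheticConfig(p_in=0.8, p_out=0.05)
        m = transition_matrix(config)
        codes = list(config.planted_partition)
        part = config.planted_partition
        i, j = 0, next(k for k, c in enumerate(codes) if part[c] == part[codes[0]] and k != 0)
        k = next(k for k, c in enumerate(codes) if part[c] != part[codes[0]])
        assert m[i, j] > m[i, k]


class TestGeneration:
    def test_same_seed_is_deterministic(self):
        a, la = generate_master_table(SyntheticConfig(seed=5))
        b, lb = generate_master_table(SyntheticConfig(seed=5))
        assert a.records == b.records
        assert la == lb

    def test_different_seeds_differ(self):
        a, _ = generate_master_table(SyntheticConfig(seed=5))
        b, _ = generate_master_table(SyntheticConfig(seed=6))
        assert a.records != b.records

    def test_generated_table_passes_validation_round_trip(self, tmp_path, synthetic_default):
        tbl, _ = synthetic_default
        path = tmp_path / "synthetic.csv"
        write_master_table(tbl, path)
        reread = read_master_table(path)
        assert len(reread) == len(tbl)

    def test_transition_cluster_bias_not_rejected_by_chi_square(self):
        """Pooled same-cluster vs cross-cluster next-step frequencies follow
        the configured transition matrix (goodness of fit at alpha=0.01)."""
        config = SyntheticConfig(seed=11, n_publications=400)
        tbl, _ = generate_master_table(config)
        part = config.planted_partition
        m = transition_matrix(config)
        codes = list(part)
        p_same = m[0, [i for i, c in enumerate(codes) if part[c] == part[codes[0]]]].sum()
        n_same = n_diff = 0
        for rec in tbl.records:
            for a, b in zip(rec.methods, rec.methods[1:]):
                if part[a] == part[b]:
                    n_same += 1
                else:
                    n_diff += 1
        total = n_same + n_diff
        result = stats.chisquare([n_same, n_diff], [total * p_same, total * (1 - p_same)])
        assert result.pvalue > 0.01

    def test_empirical_rate_tracks_configured_probability(self):
        """With every other method certain to succeed, a method's empirical
        success rate is binomial around its configured probability."""
        probs = {code: 1.0 for code in DEFAULT_SUCCESS_PROB}
        probs["Mkpk"] = 0.9
        config = SyntheticConfig(seed=13, n_publications=200, success_prob=probs)
        tbl, ledger = generate_master_table(config)
        uses = [r for r in tbl.records if "Mkpk" in r.methods]
        rate = sum(r.outcome == "success" for r in uses) / len(uses)
        se = np.sqrt(0.9 * 0.1 / len(uses))
        assert abs(rate - 0.9) <= 3 * se

    def test_ledger_expected_rates_match_per_record_bookkeeping(self, synthetic_default):
        tbl, ledger = synthetic_default
        probs = ledger["per_record_success_prob"]
        expected = ledger["expected_method_rates"]["overall"]
        for code, info in expected.items():
            ps = [
                probs[f"{r.publication_id}/{r.species}"]
                for r in tbl.records
                if code in r.methods
            ]
            assert info["n_uses"] == len(ps)
            assert info["expected_rate"] == pytest.approx(np.mean(ps))


class TestRecoveryReport:
    def test_mismatched_ledger_rejected(self, synthetic_default):
        tbl, _ = synthetic_default
        _, other = generate_master_table(SyntheticConfig(seed=99, n_publications=5))
        with pytest.raises(ValueError, match="ledger"):
            recovery_report(tbl, other)

    def test_no_structure_gives_near_zero_ari(self):
        """With p_in == p_out the walk has no community signal, so the
        recovered-vs-planted ARI distribution is centred near zero."""
        aris = []
        for seed in range(8):
            config = SyntheticConfig(seed=seed, p_in=0.3, p_out=0.3, n_publications=80)
            tbl, ledger = generate_master_table(config)
            aris.append(recovery_report(tbl, ledger).ari)
        assert abs(np.mean(aris)) < 0.15

    def test_large_sample_rate_errors_small(self):
        """Law-of-large-numbers check: in the near-infinite-data limit every
        filtered method's empirical rate is within 0.05 of the generator
        truth.  The corpus is sized so that 0.05 corresponds to >3.5 binomial
        standard errors for every method (~500 uses each)."""
        config = SyntheticConfig(seed=3, n_publications=5000)
        tbl, ledger = generate_master_table(config)
        assert len(tbl) >= 10000
        rep = recovery_report(tbl, ledger)
        assert rep.max_rate_error < 0.05
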