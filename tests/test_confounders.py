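import numpy as np
import pytest

import paireval as pe
from paireval.errors import ConfigurationError, InputError

from conftest import random_instance


def smp(i, label, conf):
    return pe.LabeledSample(
        sample_id=f"s{i}", label=float(label), confounders={"c": conf}
    )


class TestDiscreteSplit:
    def test_two_by_two_subtype_combinatorics(self):
        # 2 luminal (labels 0, 1) + 2 basal (labels 2, 3): all 6 pairs rankable
        samples = [smp(0, 0, "lum"), smp(1, 1, "lum"),
                   smp(2, 2, "bas"), smp(3, 3, "bas")]
        spec = pe.DeltaSpec(mode="absolute_difference", constant_delta=0.5)
        pairs = pe.build_rankable_pairs(samples, spec)
        cs = pe.ConfounderSpec(name="c", kind="discrete")
        matched, mismatched = pe.split_pairs_discrete(pairs, samples, cs)
        assert (len(matched), len(mismatched)) == (2, 4)

    def test_single_group_puts_everything_in_matched(self):
        samples = [smp(i, i, "lum") for i in range(4)]
        pairs = pe.build_rankable_pairs(samples, pe.DeltaSpec())
        cs = pe.ConfounderSpec(name="c", kind="discrete")
        matched, mismatched = pe.split_pairs_discrete(pairs, samples, cs)
        assert len(matched) == len(pairs) and len(mismatched) == 0

    def test_partition_is_disjoint_and_complete(self, rng):
        samples = [
            smp(i, rng.normal(), rng.choice(["a", "b", "c"]))
            for i in range(15)
        ]
        pairs = pe.build_rankable_pairs(
            samples, pe.DeltaSpec(mode="absolute_difference", constant_delta=0.2)
        )
        cs = pe.ConfounderSpec(name="c", kind="discrete")
        matched, mismatched = pe.split_pairs_discrete(pairs, samples, cs)
        km = {(p.hi, p.lo) for p in matched}
        kmm = {(p.hi, p.lo) for p in mismatched}
        assert km | kmm == {(p.hi, p.lo) for p in pairs}
        assert km & kmm == set()

    def test_missing_confounder_value_names_samples(self):
        samples = [smp(0, 0, "lum"), smp(1, 1, "lum"),
                   pe.LabeledSample(sample_id="s2", label=2.0)]
        pairs = pe.build_rankable_pairs(samples, pe.DeltaSpec())
        cs = pe.ConfounderSpec(name="c", kind="discrete")
        with pytest.raises(InputError, match="s2"):
            pe.split_pairs_discrete(pairs, samples, cs)


class TestContinuousSelection:
    def continuous_spec(self, mismatched="max_difference", seed=0):
        return pe.ConfounderSpec(
            name="c", kind="continuous", censor_at=90.0,
            matched_strategy="min_difference",
            mismatched_strategy=mismatched, seed=seed,
        )

    def test_closest_in_age_is_matched(self):
        samples = [smp(0, 0, 75.0), smp(1, 1, 74.0), smp(2, 1, 89.0)]
        pairs = pe.build_rankable_pairs(samples, pe.DeltaSpec())
        matched, mismatched = pe.select_pairs_continuous(
            pairs, samples, self.continuous_spec()
        )
        m_keys = {frozenset((p.hi, p.lo)) for p in matched}
        assert frozenset(("s0", "s1")) in m_keys  # age gap 1 < 14
        mm_keys = {frozenset((p.hi, p.lo)) for p in mismatched}
        assert frozenset(("s0", "s2")) in mm_keys

    def test_two_censored_values_count_as_gap_zero(self):
        samples = [smp(0, 0, 92.0), smp(1, 1, 95.0), smp(2, 1, 89.0)]
        pairs = pe.build_rankable_pairs(samples, pe.DeltaSpec())
        matched, _ = pe.select_pairs_continuous(
            pairs, samples, self.continuous_spec()
        )
        m_keys = {frozenset((p.hi, p.lo)) for p in matched}
        assert frozenset(("s0", "s1")) in m_keys  # both 90+: gap 0 beats 3

    def test_max_difference_picks_farthest_partner(self):
        # index 90+ sample: partners aged 74 and 89 -> mismatched partner 74
        samples = [smp(0, 0, 93.0), smp(1, 1, 74.0), smp(2, 1, 89.0)]
        pairs = pe.build_rankable_pairs(samples, pe.DeltaSpec())
        _, mismatched = pe.select_pairs_continuous(
            pairs, samples, self.continuous_spec()
        )
        mm_keys = {frozenset((p.hi, p.lo)) for p in mismatched}
        assert frozenset(("s0", "s1")) in mm_keys

    def test_matched_gap_never_exceeds_mismatched_gap(self, rng):
        samples = [
            smp(i, rng.integers(0, 3), float(rng.uniform(65, 95)))
            for i in range(20)
        ]
        pairs = pe.build_rankable_pairs(samples, pe.DeltaSpec())
        spec = self.continuous_spec()
        matched, mismatched = pe.select_pairs_continuous(pairs, samples, spec)
        conf = {s.sample_id: float(s.confounders["c"]) for s in samples}

        def gap(p):
            v1, v2 = conf[p.hi], conf[p.lo]
            if v1 >= 90 and v2 >= 90:
                return 0.0
            return abs(min(v1, 90) - min(v2, 90))

        # per index sample: the matched partner is at least as close along
        # the confounder as the mismatched (max-separation) partner
        matched_gap = {}
        for p in matched:
            for idx in (p.hi, p.lo):
                g = gap(p)
                matched_gap[idx] = min(matched_gap.get(idx, np.inf), g)
        for p in mismatched:
            for idx in (p.hi, p.lo):
                if idx in matched_gap:
                    assert matched_gap[idx] <= gap(p) + 1e-9

    def test_deterministic_given_seed(self, rng):
        samples = [
            smp(i, rng.integers(0, 2), float(rng.uniform(65, 95)))
            for i in range(15)
        ]
        pairs = pe.build_rankable_pairs(samples, pe.DeltaSpec())
        spec = self.continuous_spec(mismatched="random_from_censored", seed=42)
        r1 = pe.select_pairs_continuous(pairs, samples, spec)
        r2 = pe.select_pairs_continuous(pairs, samples, spec)
        assert [(p.hi, p.lo) for p in r1[0]] == [(p.hi, p.lo) for p in r2[0]]
        assert [(p.hi, p.lo) for p in r1[1]] == [(p.hi, p.lo) for p in r2[1]]

    def test_random_from_censored_requires_seed(self):
        with pytest.raises(ConfigurationError):
            pe.ConfounderSpec(
                name="c", kind="continuous", censor_at=90.0,
                matched_strategy="min_difference",
                mismatched_strategy="random_from_censored",
            )


class TestConfounderEffect:
    def test_confounded_scenario_collapses_matched_auc(self):
        res = pe.run_confounder_study(n_seeds=5, base_seed=200, confounded=True)
        assert res.median_delta_auc > 0.15
        assert res.significant_fraction(0.01) > 0.5

    def test_clean_scenario_shows_no_gap(self):
        res = pe.run_confounder_study(n_seeds=5, base_seed=200, confounded=False)
        assert res.median_abs_delta_auc < 0.05

    def test_fisher_p_uniform_when_matching_is_irrelevant(self, rng):
        """Permuting the matched flag on exchangeable verdicts gives ~U(0,1) p."""
        samples, table = random_instance(rng, n=24, n_classes=2)
        pairs = pe.build_rankable_pairs(samples, pe.DeltaSpec())
        verdicts = pe.score_pairs(pairs, table)
        keys = [p for p in pairs]
        n_m = len(keys) // 2
        ps = []
        for _ in range(1000):
            perm = rng.permutation(len(keys))
            matched = pe.RankablePairSet(
                pairs=tuple(keys[i] for i in perm[:n_m]),
                n_samples=pairs.n_samples,
            )
            mismatched = pe.RankablePairSet(
                pairs=tuple(keys[i] for i in perm[n_m:]),
                n_samples=pairs.n_samples,
            )
            eff = pe.confounder_effect(verdicts, matched, mismatched)
            ps.append(eff.p_value)
        # Kolmogorov distance to uniform; exact-test discreteness keeps the
        # empirical CDF below the diagonal, never far above it
        ps = np.sort(ps)
        grid = (np.arange(len(ps)) + 1) / len(ps)
        ks = np.max(grid - ps)  # one-sided: anti-conservatism would show here
        assert ks < 0.1


class TestAnova:
    def test_identical_group_means_give_zero_f(self):
        f, p = pe.anova_f([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # SSB = 13.5, SSW = 4, df (1, 4): F = 13.5 / 1 = 13.5
        f, p = pe.anova_f([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert f == pytest.approx(13.5)

    def test_null_permutation_distribution_covers_observed(self, rng):
        labels = rng.normal(size=24)
        groups = np.array(["a", "b", "c"]).repeat(8)
        f_obs, _ = pe.anova_f(labels, groups)
        f_perm = []
        for _ in range(300):
            f_p, _ = pe.anova_f(labels, rng.permutation(groups))
            f_perm.append(f_p)
        frac_above = np.mean(np.array(f_perm) >= f_obs)
        assert 0.01 < frac_above < 1.0  # observed F is unexceptional for null data

    def test_small_group_rejected(self):
        with pytest.raises(InputError):
            pe.anova_f([1, 2, 3], ["a", "a", "b"])
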