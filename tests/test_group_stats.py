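"""Pillai trace, sphericity, split-plot ANCOVA, post hoc contrasts.

pingouin serves as an independent oracle for the no-covariate mixed ANOVA
and for the sphericity indices; the implementation itself is classical
split-plot algebra.
"""

import numpy as np
import pandas as pd
import pytest

from connsweep.group_stats import (DegenerateDataError, PolicyError,
                                   decomposition_anova, mixed_ancova,
                                   omnibus_mancova, orthonormal_contrasts,
                                   pillai_f, pillai_trace, posthoc_contrasts,
                                   sphericity)
from connsweep.synthetic_data import simulate_summary_cohort


class TestPillai:
    def test_zero_hypothesis_gives_zero(self):
        E = np.eye(3) * 2.0
        assert pillai_trace(np.zeros((3, 3)), E) == 0.0

    def test_single_dv_closed_form(self):
        """One DV: V = SSH/(SSH+SSE); SSH=3, SSE=1 gives 0.75 and the F
        approximation reduces to the univariate F."""
        V = pillai_trace(np.array([[3.0]]), np.array([[1.0]]))
        assert V == pytest.approx(0.75)
        res = pillai_f(V, p=1, q=1, n_e=10)
        assert res.F == pytest.approx(10 * 3.0 / 1.0)
        assert (res.df1, res.df2) == (1, 10)

    def test_matches_eigenvalue_oracle(self):
        """V equals the sum of lambda/(1+lambda) over eigenvalues of
        E^-1 H on random SPD inputs."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            A = rng.standard_normal((3, 8))
            B = rng.standard_normal((3, 12))
            H, E = A @ A.T, B @ B.T
            lam = np.linalg.eigvals(np.linalg.solve(E, H)).real
            assert pillai_trace(H, E) == pytest.approx(
                np.sum(lam / (1 + lam)), abs=1e-10)

    def test_invariant_under_dv_transformation(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((4, 9))
        B = rng.standard_normal((4, 20))
        H, E = A @ A.T, B @ B.T
        T = rng.standard_normal((4, 4))  # invertible a.s.
        V1 = pillai_trace(H, E)
        V2 = pillai_trace(T @ H @ T.T, T @ E @ T.T)
        assert V1 == pytest.approx(V2, abs=1e-8)


class TestSphericity:
    def test_compound_symmetry_is_spherical(self):
        k = 5
        Sig = 0.4 * np.ones((k, k)) + 0.6 * np.eye(k)
        s = sphericity(Sig, n_e=30)
        assert s.W == pytest.approx(1.0, abs=1e-10)
        assert s.epsilon == pytest.approx(1.0, abs=1e-10)

    def test_two_levels_always_spherical(self):
        Sig = np.array([[2.0, 0.3], [0.3, 1.0]])
        s = sphericity(Sig, n_e=20)
        assert s.epsilon == 1.0 and s.W == 1.0 and s.p == 1.0

    @pytest.mark.parametrize("k", [3, 4, 5, 6])
    def test_ar1_matches_eigenvalue_oracle(self, k):
        rho = 0.8
        Sig = rho ** np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        s = sphericity(Sig, n_e=40)
        C = orthonormal_contrasts(k)
        lam = np.linalg.eigvalsh(C @ Sig @ C.T)
        eps = lam.sum() ** 2 / ((k - 1) * np.sum(lam**2))
        W = np.prod(lam) / (lam.mean()) ** (k - 1)
        assert s.epsilon == pytest.approx(eps, abs=1e-12)
        assert s.W == pytest.approx(W, abs=1e-12)
        assert 1.0 / (k - 1) <= s.epsilon <= 1.0

    def test_epsilon_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((25, 4)) @ rng.standard_normal((4, 4))
        data = pd.DataFrame(Y, columns=list("abcd"))
        data["subject"] = range(25)
        long = data.melt("subject", var_name="cond")
        eps_pg = pg.epsilon(data[list("abcd")], correction="gg")
        s = sphericity(np.cov(Y.T), n_e=24)
        assert s.epsilon == pytest.approx(float(eps_pg), abs=1e-8)


class TestMixedAncova:
    def test_identical_values_degenerate(self):
        t = simulate_summary_cohort(seed=0)
        t["value"] = 1.0
        with pytest.raises(DegenerateDataError):
            mixed_ancova(t, "dc")

    def test_between_f_equals_squared_pooled_t_on_subject_means(self):
        """For the 2-level between factor (no covariate) the split-plot F
        equals the squared pooled two-sample t on subject means."""
        from scipy.stats import ttest_ind

        t = simulate_summary_cohort(seed=5)
        t = t.drop(columns=["age"])
        res = mixed_ancova(t, "dc")
        means = t.groupby(["participant", "group"])["value"].mean().reset_index()
        a = means[means.group == "HC"].value
        b = means[means.group == "PPV"].value
        tt = ttest_ind(a, b)
        assert res.effects["group"].F == pytest.approx(tt.statistic**2, rel=1e-10)
        assert res.effects["group"].p == pytest.approx(tt.pvalue, rel=1e-10)

    def test_matches_pingouin_mixed_anova(self):
        """Without the covariate, F statistics for group, network and the
        interaction match pingouin's mixed_anova."""
        pg = pytest.importorskip("pingouin")
        # balanced groups: Type III and pingouin's convention coincide
        t = simulate_summary_cohort(seed=7, n_ppv=18).drop(columns=["age"])
        res = mixed_ancova(t, "dc")
        aov = pg.mixed_anova(data=t, dv="value", within="network",
                             subject="participant", between="group")
        by = {r.Source: r for r in aov.itertuples()}
        assert res.effects["group"].F == pytest.approx(by["group"].F, rel=1e-8)
        assert res.effects["network"].F == pytest.approx(by["network"].F, rel=1e-8)
        assert res.effects["group:network"].F == pytest.approx(
            by["Interaction"].F, rel=1e-8)

    def test_gg_correction_reported_when_mauchly_violated(self):
        """Strongly non-spherical data trigger the GG-adjusted report with
        deflated dfs."""
        rng = np.random.default_rng(11)
        rows = []
        # AR(1)-correlated within-subject noise -> sphericity violated
        k = 6
        Sig = 0.95 ** np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        Sig *= np.outer(np.linspace(0.2, 3.0, k), np.linspace(0.2, 3.0, k))
        L = np.linalg.cholesky(Sig)
        nets = [f"n{i}" for i in range(k)]
        ages = rng.uniform(20, 60, 40)
        for i in range(40):
            vals = L @ rng.standard_normal(k)
            for j, net in enumerate(nets):
                rows.append({"participant": f"s{i}", "group": "HC" if i < 20 else "PPV",
                             "age": ages[i], "network": net, "measure": "dc",
                             "value": vals[j]})
        t = pd.DataFrame(rows)
        res = mixed_ancova(t, "dc", levels=tuple(nets))
        assert res.sphericity.p < 0.05
        assert res.gg_applied
        rep = res.reported("network")
        assert rep.df1 < 5 and rep.df2 < res.effects["network"].df2

    def test_null_calibration_of_interaction(self):
        """Under the null the group x network interaction rejects at ~5%
        (500 seeded replicates, binomial band)."""
        rej = 0
        N = 500
        for s in range(N):
            t = simulate_summary_cohort(seed=s)
            uni = mixed_ancova(t, "dc")
            rej += uni.reported("group:network").p < 0.05
        assert 0.032 <= rej / N <= 0.071

    def test_power_to_detect_injected_interaction(self):
        """A sensorimotor shift of one within-cell sd for PPV is detected
        by the interaction in >= 80% of replicates."""
        hits = 0
        N = 100
        eff = np.sqrt(2.0)  # 1 within-cell sd at subject_sd = noise_sd = 1
        for s in range(N):
            t = simulate_summary_cohort(
                seed=20_000 + s, cell_effects={("PPV", "sensorimotor"): eff})
            uni = mixed_ancova(t, "dc")
            hits += uni.reported("group:network").p < 0.05
        assert hits / N >= 0.8


class TestOmnibus:
    def test_duplicated_measures_reduce_to_univariate(self):
        t = simulate_summary_cohort(seed=9, measures=("dc",))
        uni = mixed_ancova(t, "dc")
        omni = omnibus_mancova(t, measures=("dc", "dc", "dc"))
        assert omni.effects["group"].F == pytest.approx(
            uni.effects["group"].F, rel=1e-8)
        assert omni.effects["group"].p == pytest.approx(
            uni.effects["group"].p, rel=1e-6)

    def test_null_interaction_calibrated(self):
        rej = 0
        N = 300
        for s in range(N):
            t = simulate_summary_cohort(seed=40_000 + s,
                                        measures=("dc", "cc", "ecc"))
            omni = omnibus_mancova(t)
            rej += omni.effects["group:network"].p < 0.05
        assert 0.02 <= rej / N <= 0.085

    def test_omnibus_detects_effect_in_one_measure_only(self):
        """An effect present only in ecc is caught by the omnibus while the
        dc-only univariate stays quiet (power comparison)."""
        omni_hits = uni_hits = 0
        N = 60
        eff = 1.5 * np.sqrt(2.0)
        for s in range(N):
            t = simulate_summary_cohort(seed=60_000 + s,
                                        measures=("dc", "cc", "ecc"))
            mask = (t.measure == "ecc") & (t.group == "PPV") & \
                   (t.network == "sensorimotor")
            t.loc[mask, "value"] += eff
            omni_hits += omnibus_mancova(t).effects["group:network"].p < 0.05
            uni_hits += mixed_ancova(t, "dc").reported("group:network").p < 0.05
        assert omni_hits / N >= 0.8
        assert uni_hits / N <= 0.2


class TestPosthoc:
    def test_refused_without_upstream_significance(self):
        t = simulate_summary_cohort(seed=13)
        with pytest.raises(PolicyError):
            posthoc_contrasts(t, "dc", upstream_significant=False)

    def test_family_of_one_unadjusted(self):
        t = simulate_summary_cohort(seed=14, levels=("sensorimotor",))
        # single within level: fit group difference directly
        cs = posthoc_contrasts(t, "dc", levels=("sensorimotor",))
        assert cs[0].p_adjusted == pytest.approx(cs[0].p_unadjusted)

    def test_adjustment_monotone(self):
        t = simulate_summary_cohort(seed=15)
        for c in posthoc_contrasts(t, "dc"):
            assert c.p_adjusted >= c.p_unadjusted

    def test_difference_orientation_hc_minus_ppv(self):
        t = simulate_summary_cohort(
            seed=16, cell_effects={("PPV", net): -2.0 for net in
                                   ("cingulo-opercular", "fronto-parietal",
                                    "default-mode", "sensorimotor",
                                    "occipital", "cerebellum")})
        cs = posthoc_contrasts(t, "dc")
        assert all(c.difference > 0 for c in cs)

    def test_familywise_error_controlled_under_null(self):
        """The probability that ANY of the six Tukey-adjusted contrasts
        rejects stays near (at most slightly above) 5% under the null —
        the max-|t| calibration of the studentized-range family."""
        N = 400
        any_rej = 0
        for s in range(N):
            t = simulate_summary_cohort(seed=80_000 + s)
            cs = posthoc_contrasts(t, "dc")
            any_rej += any(c.p_adjusted < 0.05 for c in cs)
        assert any_rej / N <= 0.09


class TestDecompositionAnova:
    @staticmethod
    def _decomp_table(seed, gap_within=0.0, gap_other=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(36):
            group = "HC" if i < 18 else "PPV"
            base = rng.normal(0, 1)
            for part in ("within", "pair", "rest"):
                val = base + rng.normal(0, 1)
                if group == "PPV":
                    val += gap_within if part == "within" else gap_other
                rows.append({"participant": f"s{i}", "group": group,
                             "focal": "sensorimotor", "partition": part,
                             "value": val})
        return pd.DataFrame(rows)

    def test_identical_values_degenerate(self):
        t = self._decomp_table(0)
        t["value"] = 2.0
        with pytest.raises(DegenerateDataError):
            decomposition_anova(t, "sensorimotor")

    def test_null_calibrated(self):
        rej = 0
        N = 300
        for s in range(N):
            uni, _ = decomposition_anova(self._decomp_table(s), "sensorimotor")
            rej += uni.effects["group"].p < 0.05
        assert 0.025 <= rej / N <= 0.085

    def test_injected_within_gap_detected(self):
        """A group connectivity gap concentrated in the within-network
        type drives both the group main effect and the within-type
        contrast in >= 80% of replicates."""
        hits_group = hits_contrast = 0
        N = 100
        for s in range(N):
            t = self._decomp_table(1000 + s, gap_within=2.0, gap_other=1.0)
            uni, cs = decomposition_anova(t, "sensorimotor")
            hits_group += uni.effects["group"].p < 0.05
            within = [c for c in cs if c.level == "within"][0]
            hits_contrast += within.p_adjusted < 0.05
        assert hits_group / N >= 0.8
        assert hits_contrast / N >= 0.8

    def test_missing_focal_rejected(self):
        with pytest.raises(ValueError, match="cerebellum"):
            decomposition_anova(self._decomp_table(0), "cerebellum")
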