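"""Bivariate association scan, corrections, partitions, higher-order tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_geno
from wheatmt.containers import STAGE1, STAGE2, KinshipMatrix, TraitDataset
from wheatmt.mtgwas import (
    bh_qvalues,
    correct_multiplicity,
    effective_association_count,
    higher_order_test,
    scan_bivariate,
    stability_ratio,
    variance_partition,
)


class TestMultiplicity:
    def test_bh_step_up_formula(self):
        q = bh_qvalues([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_passthrough(self):
        assert bh_qvalues([0.37])[0] == pytest.approx(0.37)

    def test_against_statsmodels_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.random(200) ** 2
        ours = bh_qvalues(p)
        _, theirs, *_ = multipletests(p, method="fdr_bh")
        assert np.allclose(ours, theirs)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=50))
    @settings(max_examples=30, deadline=None)
    def test_bh_monotone_in_p(self, ps):
        q = bh_qvalues(ps)
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_bonferroni_printed_threshold(self):
        thr = correct_multiplicity(np.ones(18856), "bonferroni", alpha=0.05)
        assert thr == pytest.approx(2.652e-6, rel=1e-3)

    def test_meff_threshold_and_nesting(self):
        p = np.ones(100)
        bon = correct_multiplicity(p, "bonferroni", alpha=0.05)
        meff = correct_multiplicity(p, "meff", alpha=0.05, m_eff_count=40)
        assert bon < meff  # fewer effective tests -> milder threshold
        assert meff == pytest.approx(0.05 / 40)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            correct_multiplicity([], "fdr")


class TestEffectiveAssociations:
    def test_perfect_ld_collapses_to_one(self):
        rng = np.random.default_rng(1)
        base = 2.0 * (rng.random(80) < 0.4)
        geno = make_geno(np.column_stack([base, base, base]))
        assert effective_association_count(["m0", "m1", "m2"], geno) == 1

    def test_independent_markers_identity_spectrum(self):
        rng = np.random.default_rng(2)
        D = 2.0 * (rng.random((500, 6)) < 0.4)
        geno = make_geno(D)
        ids = [f"m{j}" for j in range(6)]
        assert effective_association_count(ids, geno) == 6  # ceil(0.95 * 6)

    def test_eight_blocks_from_eighteen_markers(self):
        # 18 markers arranged in 8 perfect-LD blocks collapse to 8
        # effective associations
        rng = np.random.default_rng(3)
        block_sizes = [3, 3, 3, 2, 2, 2, 2, 1]
        cols = []
        for b in block_sizes:
            base = 2.0 * (rng.random(400) < rng.uniform(0.2, 0.5))
            cols.extend([base] * b)
        geno = make_geno(np.column_stack(cols))
        ids = [f"m{j}" for j in range(18)]
        assert effective_association_count(ids, geno) == 8


@pytest.fixture(scope="module")
def scan_setup():
    """60-genotype panel, two environments, two traits with one shared QTL."""
    rng = np.random.default_rng(123)
    n = 60
    D = 2.0 * (rng.random((n, 40)) < rng.uniform(0.2, 0.5, size=40))
    geno = make_geno(D)
    ids = [f"g{i}" for i in range(n)]
    A = 2.0 * np.eye(n)
    kin = KinshipMatrix(A=A, RD=1 - np.eye(n), genotype_ids=ids)
    causal = D[:, 0]
    rows = []
    g = {t: np.sqrt(0.3) * rng.standard_normal(n) for t in ("T1", "T2")}
    for env in ("E1", "E2"):
        for t, a in (("T1", 0.8), ("T2", -0.6)):
            rows.append(
                pd.DataFrame(
                    {
                        "genotype": ids,
                        "environment": env,
                        "trait": t,
                        "value": a * causal
                        + g[t]
                        + 0.3 * rng.standard_normal(n),
                    }
                )
            )
    blues1 = TraitDataset(pd.concat(rows, ignore_index=True), stage=STAGE1)
    return geno, blues1, kin


class TestScan:
    def test_causal_marker_found_and_gating_invariant(self, scan_setup):
        geno, blues1, kin = scan_setup
        summary = scan_bivariate(
            geno, blues1, kin, ("T1", "T2"), markers=[f"m{j}" for j in range(20)]
        )
        recs = {r.marker_id: r for r in summary.records}
        assert recs["m0"].p_raw < 1e-4
        assert recs["m0"].significant["fdr"]
        # declared-pleiotropic implies global AND both individual tests pass
        for r in summary.records:
            if r.significant.get("fdr"):
                assert r.q_fdr < 0.05
                assert all(
                    r.wald_per_trait[t].p_value < 0.05 for t in r.trait_pair
                )

    def test_covariation_sign_matches_design(self, scan_setup):
        geno, blues1, kin = scan_setup
        summary = scan_bivariate(geno, blues1, kin, ("T1", "T2"), markers=["m0"])
        r = summary.records[0]
        # effects were built with opposite signs (+0.8, -0.6)
        assert r.covariation_sign == -1
        assert r.covariation_sign == int(np.sign(r.alpha["T1"] * r.alpha["T2"]))

    def test_null_pvalues_uniform(self, structured_A):
        # markers orthogonal to the phenotype: global Wald p-values are
        # uniform (KS test at alpha = 0.01)
        rng = np.random.default_rng(9)
        n = structured_A.n
        lam, U = structured_A.eig()
        L_A = U * np.sqrt(lam)[None, :]
        D = 2.0 * (rng.random((n, 150)) < rng.uniform(0.2, 0.5, size=150))
        geno = make_geno(D)
        geno.genotype_ids = list(structured_A.genotype_ids)
        rows = []
        for t in ("T1", "T2"):
            y = L_A @ rng.standard_normal(n) * np.sqrt(0.4) + np.sqrt(
                0.2
            ) * rng.standard_normal(n)
            rows.append(
                pd.DataFrame(
                    {
                        "genotype": structured_A.genotype_ids,
                        "environment": "E1",
                        "trait": t,
                        "value": y,
                    }
                )
            )
        blues1 = TraitDataset(pd.concat(rows, ignore_index=True), stage=STAGE1)
        summary = scan_bivariate(
            geno, blues1, kinship=structured_A, trait_pair=("T1", "T2")
        )
        pvals = [r.p_raw for r in summary.records]
        assert len(pvals) > 100
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_monomorphic_markers_skipped(self, scan_setup):
        geno, blues1, kin = scan_setup
        D = geno.dosages.copy()
        D[:, 5] = 2.0
        geno2 = make_geno(D)
        summary = scan_bivariate(
            geno2, blues1, kin, ("T1", "T2"), markers=["m5", "m6"]
        )
        assert [r.marker_id for r in summary.records] == ["m6"]


class TestVariancePartition:
    def _blues2(self, y_by_trait, ids):
        rows = [
            pd.DataFrame({"genotype": ids, "trait": t, "value": v})
            for t, v in y_by_trait.items()
        ]
        return TraitDataset(pd.concat(rows, ignore_index=True), stage=STAGE2)

    def test_full_explanation_and_duplicate(self):
        rng = np.random.default_rng(4)
        base = 2.0 * (rng.random(50) < 0.4)
        geno = make_geno(np.column_stack([base, base]))
        ids = [f"g{i}" for i in range(50)]
        blues2 = self._blues2({"T1": 1.7 * base}, ids)
        out = variance_partition(blues2, ["m0", "m1"], geno, {"T1": 1.0})
        first = out[(out["marker"] == "m0")].iloc[0]
        second = out[(out["marker"] == "m1")].iloc[0]
        assert first["R2_marker"] == pytest.approx(1.0)
        assert second["R2_marker"] == pytest.approx(0.0, abs=1e-10)

    def test_genetic_share_is_r2_over_h2(self):
        rng = np.random.default_rng(5)
        m = 2.0 * (rng.random(200) < 0.5)
        y = 0.3 * m + rng.standard_normal(200)
        geno = make_geno(m[:, None])
        ids = [f"g{i}" for i in range(200)]
        out = variance_partition(
            self._blues2({"T1": y}, ids), ["m0"], geno, {"T1": 0.5}
        )
        row = out.iloc[0]
        assert row["genetic_share_marker"] == pytest.approx(
            row["R2_marker"] / 0.5
        )
        assert (out["R2_cumulative"].diff().dropna() >= -1e-12).all()


class TestHigherOrder:
    def _three_trait_setup(self, seed, effects):
        rng = np.random.default_rng(seed)
        n = 80
        D = 2.0 * (rng.random((n, 10)) < 0.4)
        geno = make_geno(D)
        ids = [f"g{i}" for i in range(n)]
        kin = KinshipMatrix(A=2 * np.eye(n), RD=1 - np.eye(n), genotype_ids=ids)
        causal = D[:, 0]
        rows = []
        for t, a in effects.items():
            y = a * causal + np.sqrt(0.25) * rng.standard_normal(n) + np.sqrt(
                0.15
            ) * rng.standard_normal(n)
            rows.append(
                pd.DataFrame(
                    {"genotype": ids, "environment": "E1", "trait": t, "value": y}
                )
            )
        blues1 = TraitDataset(pd.concat(rows, ignore_index=True), stage=STAGE1)
        return geno, blues1, kin

    def test_three_trait_pleiotropic_marker_declared(self):
        geno, blues1, kin = self._three_trait_setup(
            11, {"T1": 0.7, "T2": 0.7, "T3": -0.7}
        )
        out = higher_order_test(
            geno, blues1, kin, "m0", ("T1", "T2", "T3"),
            alpha=0.1, m_eff_count=10,
        )
        assert out["declared"]
        assert set(out["per_trait"]) == {"T1", "T2", "T3"}

    def test_single_trait_marker_not_declared(self):
        geno, blues1, kin = self._three_trait_setup(
            12, {"T1": 0.8, "T2": 0.0, "T3": 0.0}
        )
        out = higher_order_test(
            geno, blues1, kin, "m0", ("T1", "T2", "T3"),
            alpha=0.1, m_eff_count=10,
        )
        assert not out["declared"]

    def test_two_trait_reduction_matches_scan(self):
        geno, blues1, kin = self._three_trait_setup(13, {"T1": 0.7, "T2": 0.6})
        out = higher_order_test(
            geno, blues1, kin, "m0", ("T1", "T2"), alpha=0.1, m_eff_count=10,
        )
        summary = scan_bivariate(geno, blues1, kin, ("T1", "T2"), markers=["m0"])
        rec = summary.records[0]
        for t in ("T1", "T2"):
            assert out["per_trait"][t].p_value == pytest.approx(
                rec.wald_per_trait[t].p_value, rel=1e-3, abs=1e-12
            )


class TestStabilityRatio:
    def _blues1(self, y_env, ids):
        rows = []
        for env, y in y_env.items():
            rows.append(
                pd.DataFrame(
                    {"genotype": ids, "environment": env, "trait": "T1",
                     "value": y}
                )
            )
        return TraitDataset(pd.concat(rows, ignore_index=True), stage=STAGE1)

    def test_stable_effects_give_large_ratio(self):
        rng = np.random.default_rng(21)
        n = 150
        m = 2.0 * (rng.random(n) < 0.4)
        geno = make_geno(m[:, None])
        ids = [f"g{i}" for i in range(n)]
        y_env = {
            env: 0.9 * m + 0.1 * rng.standard_normal(n)
            for env in ("E1", "E2", "E3")
        }
        assert stability_ratio(self._blues1(y_env, ids), ["m0"], geno, "T1") > 10

    def test_env_specific_effects_give_small_ratio(self):
        rng = np.random.default_rng(22)
        n = 150
        m = 2.0 * (rng.random(n) < 0.4)
        geno = make_geno(m[:, None])
        ids = [f"g{i}" for i in range(n)]
        y_env = {
            env: rng.normal() * m + 0.1 * rng.standard_normal(n)
            for env in ("E1", "E2", "E3", "E4")
        }
        assert stability_ratio(self._blues1(y_env, ids), ["m0"], geno, "T1") < 1.5

    def test_no_effect_flagged_undefined(self):
        # phenotype carries only environment effects: marker and interaction
        # sums of squares are both exactly zero
        n = 100
        m = np.repeat([0.0, 2.0], n // 2)
        geno = make_geno(m[:, None])
        ids = [f"g{i}" for i in range(n)]
        y_env = {"E1": np.full(n, 1.0), "E2": np.full(n, 3.0)}
        with pytest.raises(ValueError, match="undefined"):
            stability_ratio(self._blues1(y_env, ids), ["m0"], geno, "T1")

    def test_zero_interaction_variance_is_inf(self):
        n = 100
        m = np.repeat([0.0, 2.0], n // 2)
        geno = make_geno(m[:, None])
        ids = [f"g{i}" for i in range(n)]
        y_env = {"E1": 0.5 * m, "E2": 0.5 * m + 1.0}
        with pytest.warns(UserWarning, match="inf"):
            ratio = stability_ratio(self._blues1(y_env, ids), ["m0"], geno, "T1")
        assert ratio == float("inf")
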