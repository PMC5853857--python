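"""Two-stage BLUE pipeline: heritability formulas, invariances, recovery."""

import numpy as np
import pandas as pd
import pytest

from wheatmt.containers import STAGE2, TraitDataset
from wheatmt.genostats import kinship_from_genotypes
from wheatmt.phenostage import (
    VarianceComponents,
    heritabilities,
    phenotypic_correlations,
    run_stage1,
    stage1_blues,
    stage2_blues,
)
from wheatmt.synthetic_data import (
    SimPopulationSpec,
    SimTraitSpec,
    simulate_genotypes,
    simulate_phenotypes,
)


def vc(g, gxe, err, n_env=2, n_rep=2):
    return VarianceComponents(
        sigma2_G=g,
        sigma2_GxE=gxe,
        sigma2_Error=err,
        sigma2_e_stage2=gxe + err,
        n_env=n_env,
        n_rep=n_rep,
    )


class TestHeritability:
    def test_printed_component_example(self):
        h2p, h2e = heritabilities(vc(1.0, 1.0, 1.0, n_env=2, n_rep=2))
        assert h2p == pytest.approx(1 / 3)
        assert h2e == pytest.approx(1 / (1 + 0.5 + 0.25))
        assert h2e == pytest.approx(0.5714, abs=1e-4)

    def test_noise_free_components(self):
        h2p, h2e = heritabilities(vc(2.0, 0.0, 0.0))
        assert h2p == 1.0 and h2e == 1.0

    def test_entry_mean_monotone_in_replication(self):
        prev = 0.0
        for n_env in (1, 2, 4, 8, 64):
            _, h2e = heritabilities(vc(1.0, 1.0, 1.0, n_env=n_env, n_rep=n_env))
            assert h2e > prev
            prev = h2e
        assert prev > 0.97  # h2_entry -> 1 in the limit

    def test_entry_at_least_plot(self):
        for g, ge, e in [(1, 0.5, 1), (0.3, 0.2, 2), (2, 0, 0.1)]:
            h2p, h2e = heritabilities(vc(g, ge, e))
            assert h2e >= h2p

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            heritabilities(vc(0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            heritabilities(vc(-1.0, 0.0, 1.0))


def _plots(seed=0, n=60, n_env=2, var=None, iid_kinship=False, **spec_kw):
    geno = simulate_genotypes(
        SimPopulationSpec(n_genotypes=n, n_markers_per_chrom=40,
                          n_chromosomes=2, seed=seed)
    )
    if iid_kinship:
        # unrelated genotypes: polygenic values i.i.d. with variance var_G
        from wheatmt.containers import KinshipMatrix

        kin = KinshipMatrix(
            A=2.0 * np.eye(n),
            RD=1.0 - np.eye(n),
            genotype_ids=list(geno.genotype_ids),
        )
    else:
        kin = kinship_from_genotypes(geno)
    var = var or {"G": 1.0, "GxE": 0.3, "Err": 0.5}
    spec = SimTraitSpec(
        trait_names=["GY"],
        var_G={"GY": var["G"]},
        var_GxE={"GY": var["GxE"]},
        var_Error={"GY": var["Err"]},
        n_environments=n_env,
        n_replicates=2,
        **spec_kw,
    )
    return simulate_phenotypes(geno, kin, spec, seed=seed + 1)


class TestStage1:
    def test_variance_free_design_reproduces_genotype_means(self):
        ds = _plots(
            var={"G": 1.0, "GxE": 0.0, "Err": 0.0}, var_Rep=0.0, var_Block=0.0
        )
        blues, s2e, flags = stage1_blues(ds, "GY", "E1")
        means = (
            ds.data[(ds.data["trait"] == "GY") & (ds.data["environment"] == "E1")]
            .groupby("genotype")["value"]
            .mean()
        )
        assert np.allclose(blues.sort_index(), means.sort_index(), atol=1e-4)
        assert s2e == pytest.approx(0.0, abs=1e-6)

    def test_replicate_shift_absorbed(self):
        ds = _plots(seed=3)
        shifted = ds.data.copy()
        mask = (
            (shifted["trait"] == "GY")
            & (shifted["environment"] == "E1")
            & (shifted["replicate"] == "R1")
        )
        shifted.loc[mask, "value"] += 5.0
        ds2 = TraitDataset(shifted, stage=ds.stage)
        b1, _, _ = stage1_blues(ds, "GY", "E1")
        b2, _, _ = stage1_blues(ds2, "GY", "E1")
        # a constant added to one replicate moves into the replicate effect;
        # BLUE contrasts are untouched (overall level may shift)
        d1 = b1 - b1.mean()
        d2 = b2 - b2.mean()
        assert np.allclose(d1.sort_index(), d2.sort_index(), atol=0.05)

    def test_single_replicate_passthrough(self):
        ds = _plots(seed=4)
        one_rep = TraitDataset(
            ds.data[ds.data["replicate"] == "R1"].copy(), stage=ds.stage
        )
        blues, s2e, flags = stage1_blues(one_rep, "GY", "E1")
        assert flags.get("single_replicate")
        assert np.isnan(s2e)

    def test_recovers_true_genotype_values_within_2se(self):
        # GLS oracle: with known variance components, the mixed-model BLUEs
        # must sit within ~2 standard errors of the simulated truth
        geno = simulate_genotypes(
            SimPopulationSpec(n_genotypes=50, n_markers_per_chrom=30,
                              n_chromosomes=2, seed=8)
        )
        kin = kinship_from_genotypes(geno)
        spec = SimTraitSpec(
            trait_names=["GY"],
            var_G={"GY": 1.0},
            var_GxE={"GY": 0.0},
            var_Error={"GY": 0.25},
            n_environments=1,
            n_replicates=3,
            var_Rep=0.2,
            var_Block=0.2,
        )
        ds = simulate_phenotypes(geno, kin, spec, seed=9)
        blues, _, _ = stage1_blues(ds, "GY", "E1")
        truth = (
            ds.data.groupby("genotype")["value"].mean()
        )  # noise averages out over 3 reps
        se = np.sqrt(0.25 / 3)
        err = (blues.sort_index() - truth.sort_index()).abs()
        assert (err < 2 * 2 * se).mean() > 0.95


class TestStage2:
    def test_balanced_stage2_equals_mean_of_stage1(self):
        ds = _plots(seed=5)
        stage1, errs = run_stage1(ds)
        blues, vc_out, flags = stage2_blues(stage1, "GY", errs["GY"])
        means = stage1.data.groupby("genotype")["value"].mean()
        assert np.allclose(blues.sort_index(), means.sort_index(), atol=1e-3)

    def test_error_free_simulation_gxe_equals_stage2_residual(self):
        ds = _plots(seed=6, var={"G": 1.0, "GxE": 0.4, "Err": 0.0})
        stage1, errs = run_stage1(ds)
        _, vc_out, _ = stage2_blues(stage1, "GY", errs["GY"])
        assert vc_out.sigma2_Error == pytest.approx(0.0, abs=1e-4)
        assert vc_out.sigma2_GxE == pytest.approx(
            vc_out.sigma2_e_stage2, abs=1e-4
        )

    def test_single_environment_flagged(self):
        ds = _plots(seed=7, n_env=1)
        stage1, errs = run_stage1(ds)
        blues, vc_out, flags = stage2_blues(stage1, "GY", errs["GY"])
        assert flags.get("single_environment")
        assert vc_out is None

    def test_component_recovery(self):
        # reduced-scale recovery check on unrelated genotypes: 100 genotypes,
        # 4 environments, 2 replicates, averaged over seeds.  The GxE
        # estimand of the two-stage subtraction is GxE + Err/nRep - Err
        # (stage-2 BLUEs average the replicates, the full plot error is
        # subtracted), so recovery is asserted against that quantity.
        true = {"G": 1.0, "GxE": 0.5, "Err": 0.2}
        gxe_estimand = true["GxE"] + true["Err"] / 2 - true["Err"]
        est = {"G": [], "GxE": [], "Err": []}
        import warnings as _w

        for seed in range(6):
            ds = _plots(seed=20 + seed, n=100, n_env=4, var=true,
                        iid_kinship=True)
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                stage1, errs = run_stage1(ds)
                _, vc_out, _ = stage2_blues(stage1, "GY", errs["GY"])
            est["G"].append(vc_out.sigma2_G)
            est["GxE"].append(vc_out.sigma2_GxE)
            est["Err"].append(vc_out.sigma2_Error)
        assert np.mean(est["G"]) == pytest.approx(true["G"], abs=0.15)
        assert np.mean(est["GxE"]) == pytest.approx(gxe_estimand, abs=0.15)
        assert np.mean(est["Err"]) == pytest.approx(true["Err"], abs=0.15)


class TestPhenotypicCorrelations:
    def _blues(self, arr, traits=("A", "B")):
        n = arr.shape[0]
        rows = []
        for k, t in enumerate(traits):
            rows.append(
                pd.DataFrame(
                    {"genotype": [f"g{i}" for i in range(n)], "trait": t,
                     "value": arr[:, k]}
                )
            )
        return TraitDataset(pd.concat(rows, ignore_index=True), stage=STAGE2)

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        ds = self._blues(np.column_stack([x, x]))
        R, P = phenotypic_correlations(ds)
        assert R.loc["A", "B"] == pytest.approx(1.0)

    def test_closed_form_t_test(self):
        # engineered r = 0.5 at n = 27: t = 2.886, two-sided p ~ 0.0078
        n = 27
        rng = np.random.default_rng(1)
        for _ in range(200):
            x = rng.normal(size=n)
            y = 0.5 * x + np.sqrt(0.75) * rng.normal(size=n)
            x = (x - x.mean()) / x.std()
            y = (y - y.mean()) / y.std()
            r = np.corrcoef(x, y)[0, 1]
            if abs(r - 0.5) < 1e-3:
                break
        else:
            # construct exactly: project to achieve r = 0.5
            y = y - np.dot(x, y) / n * x
            y = y / y.std()
            y = 0.5 * x + np.sqrt(0.75) * y
            r = np.corrcoef(x, y)[0, 1]
        ds = self._blues(np.column_stack([x, y]))
        R, P = phenotypic_correlations(ds)
        t_expected = R.loc["A", "B"] * np.sqrt((n - 2) / (1 - R.loc["A", "B"] ** 2))
        from scipy import stats as ss

        assert P.loc["A", "B"] == pytest.approx(
            2 * ss.t.sf(abs(t_expected), n - 2)
        )
        assert abs(R.loc["A", "B"] - 0.5) < 2e-3
        assert P.loc["A", "B"] == pytest.approx(0.0078, abs=1e-3)

    def test_independent_traits_rarely_exceed_02(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            ds = self._blues(rng.normal(size=(372, 2)))
            R, _ = phenotypic_correlations(ds)
            if abs(R.loc["A", "B"]) < 0.2:
                hits += 1
        assert hits >= 38  # >= 95% of seeds

    def test_constant_trait_flagged(self):
        arr = np.column_stack([np.zeros(10), np.arange(10.0)])
        ds = self._blues(arr)
        with pytest.warns(UserWarning, match="constant"):
            R, P = phenotypic_correlations(ds)
        assert np.isnan(R.loc["A", "B"])
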