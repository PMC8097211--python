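"""Dyad design, logistic fitting, and the blocked QAP-DSP permutation test."""

import numpy as np
import pandas as pd
import pytest

import driftnet as dn
from driftnet.dyadic import _logit_irls, permute_dyadic


def frame_of(n_per_block, blocks=("g1",), seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for b, label in enumerate(blocks):
        for k in range(n_per_block):
            rows.append(
                {
                    "nest_id": f"{label}N{k}", "building_id": label, "aggregation_id": label,
                    "x": b * 500.0 + rng.uniform(0, 10), "y": rng.uniform(0, 10),
                    "adults": int(rng.integers(5, 30)),
                    "brood_egg": 5, "brood_small": 5,
                    "brood_medium": int(rng.integers(3, 12)),
                    "brood_large": int(rng.integers(3, 12)),
                    "brood_pupae": 3,
                }
            )
    return dn.ColonyFrame(nests=pd.DataFrame(rows))


def network_for(frame, seed=0, density=0.4):
    rng = np.random.default_rng(seed)
    n = len(frame.nests)
    O = (rng.random((n, n)) < density).astype(int)
    np.fill_diagonal(O, 0)
    return dn.DriftNetwork("pooled", frame.nest_ids, O, O * rng.integers(1, 5, (n, n)))


class TestBuildDesign:
    def test_block_of_three_gives_six_ordered_dyads(self):
        frame = frame_of(3)
        design = dn.build_design(network_for(frame), frame)
        assert len(design) == 6

    def test_no_cross_block_rows(self):
        frame = frame_of(3, blocks=("g1", "g2"))
        # second block has 4 nests
        frame2 = frame_of(4, blocks=("g2",), seed=1)
        nests = pd.concat(
            [frame.nests[frame.nests["building_id"] == "g1"], frame2.nests], ignore_index=True
        )
        frame = dn.ColonyFrame(nests=nests)
        design = dn.build_design(network_for(frame), frame)
        assert len(design) == 3 * 2 + 4 * 3
        merged = design.merge(frame.nests[["nest_id", "building_id"]],
                              left_on="recipient", right_on="nest_id")
        assert (merged["block"] == merged["building_id"]).all()

    def test_undefined_wb_nest_excluded(self):
        frame = frame_of(4)
        frame.nests.loc[0, ["brood_medium", "brood_large"]] = [0, 0]
        design = dn.build_design(network_for(frame), frame)
        assert frame.nest_ids[0] not in set(design["donor"]) | set(design["recipient"])
        assert len(design) == 3 * 2


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        design = pd.DataFrame(
            {"y": [1] * 25 + [0] * 75, "block": "g1",
             "donor": "a", "recipient": "b"}
        )
        fit = dn.fit_logistic(design, covariates=[])
        assert fit["coef"]["intercept"] == pytest.approx(np.log(25 / 75), abs=1e-6)

    def test_matches_brute_force_likelihood_maximization(self):
        """12-row two-covariate fixture against an independent optimizer."""
        design = pd.DataFrame(
            {
                "y":  [0, 1, 1, 0, 1, 0, 0, 1, 0, 1, 1, 0],
                "x1": [0.2, 1.5, 2.2, 0.7, 2.9, 3.1, 1.1, 2.5, 0.4, 3.4, 2.0, 1.3],
                "x2": [1.0, 0.0, 1.0, 1.0, 0.0, 1.0, 0.0, 0.0, 1.0, 1.0, 0.0, 0.0],
            }
        )
        fit = dn.fit_logistic(design, covariates=["x1", "x2"])

        def nll(beta):
            eta = beta[0] + design["x1"] * beta[1] + design["x2"] * beta[2]
            return float(np.sum(np.log1p(np.exp(eta)) - design["y"] * eta))

        # brute force: iterated grid refinement, no gradients
        centre = np.zeros(3)
        width = 8.0
        for _ in range(12):
            grids = [np.linspace(c - width, c + width, 11) for c in centre]
            best = min(
                ((a, b, c) for a in grids[0] for b in grids[1] for c in grids[2]),
                key=lambda p: nll(np.array(p)),
            )
            centre = np.array(best)
            width /= 4.0
        assert np.allclose(fit["coef"].to_numpy(), centre, atol=1e-3)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        frame = frame_of(8, seed=3)
        design = dn.build_design(network_for(frame, seed=3), frame)
        fit = dn.fit_logistic(design)
        X = sm.add_constant(design[dn.dyadic.COVARIATES])
        ref = sm.GLM(design["y"], X, family=sm.families.Binomial()).fit()
        assert np.allclose(fit["coef"].to_numpy(), ref.params.to_numpy(), atol=1e-5)

    def test_separation_flagged(self):
        design = pd.DataFrame({"y": [1, 1, 1, 1], "block": "g1", "donor": "a", "recipient": "b"})
        fit = dn.fit_logistic(design, covariates=[])
        assert fit["separated"]

    def test_separable_covariate_flagged_not_divergent(self):
        design = pd.DataFrame({"y": [0, 0, 0, 1, 1, 1], "x": [0, 1, 2, 10, 11, 12.0]})
        beta, conv, sep = _logit_irls(
            np.column_stack([np.ones(6), design["x"]]), design["y"].to_numpy(float)
        )
        assert sep
        assert np.abs(beta).max() <= 30.0 + 1e-9


class TestPermuteDyadic:
    def test_matrix_form_equivalence(self):
        """Row-level permutation equals P M P^T on the dyadic matrix."""
        rng = np.random.default_rng(0)
        n = 5
        donor, recip = map(np.array, zip(*[(i, j) for i in range(n) for j in range(n) if i != j]))
        vec = rng.normal(size=len(donor))
        relabel = rng.permutation(n)
        out = permute_dyadic(vec, relabel, donor, recip, n)
        M = np.zeros((n, n))
        M[donor, recip] = vec
        P = np.eye(n)[relabel]  # P[new, old]... build explicitly and compare
        M_perm = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                M_perm[relabel[i], relabel[j]] = M[i, j]
        assert np.allclose(out, M_perm[donor, recip])

    def test_blockwise_relabelling_never_mixes_blocks(self):
        n = 6
        donor, recip = map(np.array, zip(*[(i, j) for i in range(n) for j in range(n)
                                           if i != j and (i < 3) == (j < 3)]))
        vec = np.arange(len(donor), dtype=float)
        relabel = np.array([1, 2, 0, 3, 5, 4])  # permutes within {0,1,2} and {3,4,5}
        out = permute_dyadic(vec, relabel, donor, recip, n)
        # values from block one stay on block-one dyads
        block1_rows = donor < 3
        assert set(out[block1_rows]) == set(vec[block1_rows])
        assert set(out[~block1_rows]) == set(vec[~block1_rows])


class TestQapDsp:
    def test_identity_relabelling_gives_tail_probability_one(self, monkeypatch):
        frame = frame_of(5, seed=4)
        design = dn.build_design(network_for(frame, seed=4), frame)

        class IdentityRng:
            def permutation(self, n):
                return np.arange(n)

        monkeypatch.setattr("driftnet.dyadic.check_rng", lambda seed: IdentityRng())
        est = dn.LogisticMrqap(n_permutations=10, seed=0).fit(design)
        for c in dn.dyadic.COVARIATES:
            assert est.result_.loc[c, "p_lower"] == 1.0
            assert est.result_.loc[c, "p_upper"] == 1.0

    def test_seed_reproducibility(self):
        frame = frame_of(6, seed=5)
        design = dn.build_design(network_for(frame, seed=5), frame)
        a = dn.LogisticMrqap(n_permutations=50, seed=9).fit(design)
        b = dn.LogisticMrqap(n_permutations=50, seed=9).fit(design)
        pd.testing.assert_frame_equal(a.result_, b.result_)

    def test_tail_probabilities_overlap_on_ties(self):
        frame = frame_of(6, seed=6)
        design = dn.build_design(network_for(frame, seed=6), frame)
        est = dn.LogisticMrqap(n_permutations=99, seed=2).fit(design)
        for c in dn.dyadic.COVARIATES:
            row = est.result_.loc[c]
            assert row["p_lower"] + row["p_upper"] >= 1.0
            assert 0 < row["p_lower"] <= 1.0 and 0 < row["p_upper"] <= 1.0

    def test_small_blocks_excluded_with_remaining_usable(self):
        frame = frame_of(2, blocks=("tiny",), seed=7)
        big = frame_of(6, blocks=("big",), seed=8)
        combined = dn.ColonyFrame(nests=pd.concat([frame.nests, big.nests], ignore_index=True))
        design = dn.build_design(network_for(combined, seed=8), combined)
        est = dn.LogisticMrqap(n_permutations=20, seed=0).fit(design)
        assert est.result_ is not None

    def test_strong_negative_distance_effect_detected(self):
        cfg = dn.GeneratorConfig(
            seed=77, n_buildings=2, nests_per_building=10, mean_group_size=12,
            sigma_gen=4.0, beta_distance=-0.5, beta_size_donor=0, beta_size_recipient=0,
            beta_wb_donor=0, beta_wb_recipient=0, preference_sd=0.5, n_periods=1,
            days_per_period=5, events_per_wasp_day=3, natal_return_prob=0.9,
        )
        frame = dn.generate_layout(cfg)
        O, W = dn.simulate_drift_counts(frame, cfg)
        net = dn.DriftNetwork("pooled", frame.nest_ids, O[0], W[0])
        est = dn.LogisticMrqap(n_permutations=199, seed=1).fit(dn.build_design(net, frame))
        row = est.result_.loc["distance"]
        assert row["estimate"] < 0
        assert row["p_lower"] < 0.05
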