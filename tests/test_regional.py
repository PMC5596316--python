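"""Empirical-Bayes DE posterior and four-pole enrichment calling."""

import numpy as np
import pytest

from tfcatalog import (
    GroundTruth,
    SimConfig,
    call_poles,
    de_posterior,
    gen_counts,
    multi_axis_count,
    pairwise_de,
    pole_decision,
    size_factors,
)

from conftest import make_expression_set


def simulate_counts(rng, means, n_reps=2, size=10.0, lib=None):
    means = np.asarray(means, dtype=float)[:, None]
    lib = np.ones(n_reps) if lib is None else np.asarray(lib)
    mu = np.maximum(means * lib[None, :], 1e-12)
    return rng.negative_binomial(size, size / (size + mu))


class TestSizeFactors:
    def test_recovers_depth_ratio(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(3, 1, 500)
        counts = np.column_stack([
            rng.poisson(base), rng.poisson(2 * base), rng.poisson(base)])
        sf = size_factors(counts)
        assert sf[1] / sf[0] == pytest.approx(2.0, rel=0.1)


class TestDePosterior:
    def test_identical_replicates_give_low_ppde(self):
        ya = np.array([[100, 100], [20, 20], [500, 500]])
        pp = de_posterior(ya, ya.copy())
        assert (pp < 0.5).all()

    def test_all_zero_gene_gets_zero(self):
        ya = np.array([[0, 0], [100, 120]])
        yb = np.array([[0, 0], [90, 110]])
        assert de_posterior(ya, yb)[0] == 0.0

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            de_posterior(np.array([[1]]), np.array([[1, 2]]))

    def test_null_calibration_small(self):
        """Null 2 vs 2: few genes cross the 0.95 posterior cutoff."""
        rng = np.random.default_rng(10)
        base = np.maximum(rng.lognormal(np.log(30), 1.2, 800), 0.5)
        ya = simulate_counts(rng, base, lib=np.array([0.8, 1.2]))
        yb = simulate_counts(rng, base, lib=np.array([1.1, 0.9]))
        pp = de_posterior(ya, yb)
        assert (pp >= 0.95).mean() <= 0.05

    def test_strong_fold_changes_are_detected(self):
        rng = np.random.default_rng(11)
        base = np.full(400, 50.0)
        de = np.zeros(400, bool)
        de[:40] = True
        mb = np.where(de, base * 8, base)
        pp = de_posterior(simulate_counts(rng, base), simulate_counts(rng, mb))
        assert (pp[de] >= 0.95).mean() >= 0.8
        assert (pp[~de] >= 0.95).mean() <= 0.05

    def test_ppde_increases_with_effect_size(self):
        """Mean posterior on planted genes grows with the fold at fixed depth.

        A minority of genes is planted DE so normalization stays anchored
        by the null majority.
        """
        rng = np.random.default_rng(12)
        n = 400
        base = np.full(n, 80.0)
        de = np.zeros(n, bool)
        de[:60] = True
        mean_pp = []
        for fold in (1.5, 3.0, 8.0):
            mb = np.where(de, base * fold, base)
            ya = simulate_counts(rng, base)
            yb = simulate_counts(rng, mb)
            mean_pp.append(de_posterior(ya, yb)[de].mean())
        assert mean_pp[0] < mean_pp[1] < mean_pp[2]


class TestPairwiseDe:
    def test_missing_region_is_reported(self):
        expr = make_expression_set({"AC": [5.0, 1.0], "DMZ": [5.0, 1.0]})
        with pytest.raises(ValueError, match="VEG"):
            pairwise_de(expr)

    def test_gene_de_in_a_single_comparison_is_included(self):
        rng = np.random.default_rng(13)
        n = 300
        base = np.full(n, 60.0)
        regions = {}
        for r in ("AC", "DMZ", "LMZ", "VMZ", "VEG"):
            m = base.copy()
            if r == "AC":
                m[0] *= 10  # gene g0 enriched only in AC (vs everything else)
            regions[r] = simulate_counts(rng, m)
        expr = _expr_from_counts(regions)
        _, union = pairwise_de(expr)
        assert "g0" in union

    def test_null_simulation_yields_near_empty_set(self):
        cfg = SimConfig(n_genes=300, frac_tf=0.3, pole_fold=1.0, seed=3,
                        decoy_frac=0.0)
        truth = _counts_truth(cfg)
        regional, _ = gen_counts(truth, cfg)
        _, union = pairwise_de(regional)
        assert len(union) <= 0.05 * cfg.n_genes

    def test_planted_regional_genes_recovered_with_few_false_calls(self):
        """Strongly planted pole genes are recovered; false additions <= 5%."""
        cfg = SimConfig(n_genes=400, frac_tf=0.5, pole_fold=8.0,
                        frac_pole_genes=0.1, seed=4, decoy_frac=0.0)
        truth = _counts_truth(cfg, pole_base_mean=150.0)
        regional, _ = gen_counts(truth, cfg)
        _, union = pairwise_de(regional)
        planted = set(truth.pole_truth)
        assert len(planted & union) / len(planted) >= 0.9
        false = union - planted
        assert len(false) <= 0.05 * cfg.n_genes


class TestPoleCalls:
    @pytest.mark.parametrize("fold_ok", [True, False])
    @pytest.mark.parametrize("tpm_ok", [True, False])
    @pytest.mark.parametrize("ppde_ok", [True, False])
    def test_rule_truth_table(self, fold_ok, tpm_ok, ppde_ok):
        """A pole is called only when all three cutoffs hold."""
        fold = 2.5 if fold_ok else 1.5
        tpm = 5.0 if tpm_ok else 0.5
        ppde = 0.99 if ppde_ok else 0.5
        assert pole_decision(fold, tpm, ppde) == (fold_ok and tpm_ok and ppde_ok)

    def test_boundary_values_are_inclusive(self):
        assert pole_decision(2.0, 1.0, 0.95)

    def test_dorsal_call_from_tpm_and_posterior(self):
        expr = make_expression_set({
            "AC": [3.0], "DMZ": [10.0], "LMZ": [3.0], "VMZ": [4.0], "VEG": [3.0]})
        ppde = {("DMZ", "VMZ"): np.array([0.99, 0.0]),
                ("AC", "VEG"): np.array([0.1, 0.0])}  # filler gene appended
        calls, summary = call_poles(expr, ppde_table=ppde)
        assert len(calls) == 1
        call = calls[0]
        assert call.pole == "dorsal" and call.axis == "DV"
        assert call.fold == pytest.approx(2.5, rel=1e-2)
        assert summary["per_pole"]["dorsal"] == 1

    def test_tpm_floor_blocks_low_expression(self):
        expr = make_expression_set({
            "AC": [0.1], "DMZ": [0.8], "LMZ": [0.1], "VMZ": [0.1], "VEG": [0.1]})
        ppde = {("DMZ", "VMZ"): np.array([0.999, 0.0]),
                ("AC", "VEG"): np.array([0.999, 0.0])}
        calls, _ = call_poles(expr, ppde_table=ppde)
        assert [c for c in calls if c.axis == "DV"] == []

    def test_at_most_one_pole_per_axis(self):
        expr = make_expression_set({
            "AC": [50.0], "DMZ": [40.0], "LMZ": [5.0], "VMZ": [5.0], "VEG": [5.0]})
        ppde = {("DMZ", "VMZ"): np.array([0.99, 0.0]),
                ("AC", "VEG"): np.array([0.99, 0.0])}
        calls, summary = call_poles(expr, ppde_table=ppde)
        by_axis = {}
        for c in calls:
            by_axis.setdefault(c.axis, []).append(c.pole)
        assert all(len(set(p)) == len(p) == 1 for p in by_axis.values())
        assert summary["multi_axis"] == 1  # dorsal + animal

    def test_closed_loop_pole_recovery(self):
        cfg = SimConfig(n_genes=300, frac_tf=0.5, pole_fold=8.0,
                        frac_pole_genes=0.08, seed=6, decoy_frac=0.0)
        truth = _counts_truth(cfg, pole_base_mean=150.0)
        regional, _ = gen_counts(truth, cfg)
        calls, summary = call_poles(regional)
        called = {(c.gene_id, c.pole) for c in calls}
        planted = {(g, p) for g, poles in truth.pole_truth.items() for p in poles}
        recovered = len(planted & called) / len(planted)
        assert recovered >= 0.9
        false = {g for g, _ in called} - set(truth.pole_truth)
        assert len(false) <= 0.05 * cfg.n_genes


class TestAxisBookkeeping:
    def test_published_style_arithmetic(self):
        assert multi_axis_count([30, 26, 70, 130], 218) == 38

    def test_unique_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            multi_axis_count([5, 5], 11)

    def test_more_than_two_axes_implied_rejected(self):
        # sum 20 with only 6 unique genes would need >2 axes for someone
        with pytest.raises(ValueError):
            multi_axis_count([10, 10], 6)

    def test_identity_against_direct_count(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(40)]
        axes = {g: set(rng.choice(["DV", "AV"], size=rng.integers(1, 3),
                                  replace=False)) for g in genes}
        per_pole_total = sum(len(a) for a in axes.values())
        unique = len(axes)
        direct_multi = sum(1 for a in axes.values() if len(a) > 1)
        assert multi_axis_count([per_pole_total], unique) == direct_multi


def _counts_truth(cfg: SimConfig, pole_base_mean: float | None = None) -> GroundTruth:
    """Ground truth for count generation without sequences: plants poles on
    a TF subset directly (optionally pinning their base means)."""
    rng = cfg.rng(99)
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    truth = GroundTruth(transcript_of={g: f"{g}.t1" for g in genes})
    n_tf = int(round(cfg.frac_tf * cfg.n_genes))
    tfs = sorted(rng.choice(genes, size=n_tf, replace=False).tolist())
    truth.tf_gene_ids = set(tfs)
    n_pole = int(round(cfg.frac_pole_genes * n_tf))
    if n_pole:
        dv = rng.choice(tfs, size=2 * n_pole, replace=False)
        av = rng.choice(tfs, size=2 * n_pole, replace=False)
        for g in dv[:n_pole]:
            truth.pole_truth.setdefault(g, set()).add("dorsal")
        for g in dv[n_pole:]:
            truth.pole_truth.setdefault(g, set()).add("ventral")
        for g in av[:n_pole]:
            truth.pole_truth.setdefault(g, set()).add("animal")
        for g in av[n_pole:]:
            truth.pole_truth.setdefault(g, set()).add("vegetal")
    if pole_base_mean is not None:
        for g in truth.pole_truth:
            truth.base_mean[g] = pole_base_mean
    return truth


def _expr_from_counts(regions: dict[str, np.ndarray]):
    import pandas as pd
    from tfcatalog import ExpressionSet

    n = next(iter(regions.values())).shape[0]
    genes = [f"g{i}" for i in range(n)]
    cols, meta, data = [], [], []
    for r, mat in regions.items():
        for rep in range(mat.shape[1]):
            cols.append(f"{r}_{rep + 1}")
            meta.append((f"{r}_{rep + 1}", r, rep + 1))
            data.append(mat[:, rep])
    counts = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    metadata = pd.DataFrame(meta, columns=["sample", "region", "replicate"]
                            ).set_index("sample")
    return ExpressionSet(counts=counts,
                         eff_length=pd.Series(1000.0, index=genes),
                         metadata=metadata)
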