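"""Normalization chain RDr -> RDrp -> X against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from panelcnv import (
    CnvEvent,
    SimulationConfig,
    apply_pca,
    compute_rdr,
    fit_pca,
    group_depth,
    median_normalize,
    normalize_to_x,
    simulate_depth,
    spike_cnvs,
)
from panelcnv.normalize import NormalizedMatrix, PcaBasis, choose_n_components

from conftest import build_panel, depth_from_array


@pytest.fixture(scope="module")
def flat_panel():
    """7 single-bin exons in one gene: groups are easy to enumerate."""
    return build_panel({"G": [100] * 7}, window_sizes=())


def _single_bin_depth(panel, arr, specimens):
    tids = [b.target_id for b in panel.bins()]
    return depth_from_array(arr, tids, specimens)


class TestGroupDepth:
    def test_length_weighted_mean(self):
        panel = build_panel({"G": [300]}, bin_size=100)
        # one 300bp exon -> 3 bins of 100; override lengths via two-bin gene
        panel2 = build_panel({"H": [200, 100]}, window_sizes=())
        tids = [b.target_id for b in panel2.bins()]
        m = depth_from_array([[100.0], [400.0]], tids, ["s1"])
        gd = group_depth(m, panel2)
        assert gd.values.loc["H|whole_gene", "s1"] == pytest.approx(
            (200 * 100 + 100 * 400) / 300
        )

    def test_single_bin_identity(self, flat_panel):
        arr = np.arange(7, dtype=float).reshape(7, 1) + 1
        gd = group_depth(_single_bin_depth(flat_panel, arr, ["s1"]), flat_panel)
        for b, v in zip(flat_panel.bins(), arr[:, 0]):
            assert gd.values.loc[f"{b.target_id}|G", "s1"] == v

    def test_uniform_depth_constant(self, flat_panel):
        gd = group_depth(
            _single_bin_depth(flat_panel, np.full((7, 1), 42.0), ["s1"]), flat_panel
        )
        assert np.allclose(gd.values.to_numpy(), 42.0)


class TestRdr:
    def test_forced_arithmetic(self):
        panel = build_panel({"G": [100, 100, 100]}, window_sizes=())
        m = _single_bin_depth(panel, [[100.0], [300.0], [200.0]], ["s1"])
        rdr = compute_rdr(group_depth(m, panel), panel)
        sb = [f"{b.target_id}|G" for b in panel.bins()]
        assert list(rdr.values.loc[sb, "s1"]) == [0.5, 1.5, 1.0]

    def test_constant_specimen_all_one(self, flat_panel):
        m = _single_bin_depth(flat_panel, np.full((7, 1), 77.0), ["s1"])
        rdr = compute_rdr(group_depth(m, flat_panel), flat_panel)
        assert np.allclose(rdr.values.to_numpy(), 1.0)

    @given(scale=st.floats(0.1, 10.0))
    def test_scale_invariance(self, flat_panel, scale):
        arr = np.array([[10.0], [20.0], [30.0], [40.0], [50.0], [60.0], [70.0]])
        a = compute_rdr(group_depth(_single_bin_depth(flat_panel, arr, ["s"]), flat_panel), flat_panel)
        b = compute_rdr(group_depth(_single_bin_depth(flat_panel, arr * scale, ["s"]), flat_panel), flat_panel)
        assert np.allclose(a.values.to_numpy(), b.values.to_numpy())

    def test_mean_one_invariant(self, demo):
        depth, _ = simulate_depth(SimulationConfig(n_specimens=5, seed=41), demo)
        rdr = compute_rdr(group_depth(depth, demo), demo)
        sb = rdr.single_bin_mask()
        means = rdr.values.to_numpy()[sb].mean(axis=0)
        assert np.allclose(means, 1.0, atol=1e-9)

    def test_zero_specimen_unscorable(self, flat_panel):
        m = _single_bin_depth(flat_panel, np.zeros((7, 1)), ["s1"])
        rdr = compute_rdr(group_depth(m, flat_panel), flat_panel)
        assert rdr.unscorable_specimens == ("s1",)


class TestPca:
    def test_rank_one_structure_captured(self, flat_panel):
        """Rank-1 synthetic data + tiny noise: one component explains
        nearly all variance (cross-checked against an SVD oracle)."""
        rng = np.random.default_rng(0)
        u = rng.normal(size=30)
        v = rng.normal(size=7)
        data = 1.0 + np.outer(u, v) * 0.05 + rng.normal(size=(30, 7)) * 1e-4
        tids = [f"{b.target_id}|G" for b in flat_panel.bins()]
        nm = NormalizedMatrix(
            "RDr", pd.DataFrame(data.T, index=tids, columns=[f"s{i}" for i in range(30)]),
            pd.Series("single_bin", index=tids),
        )
        basis = fit_pca(nm, n_components=1, var_target=None)
        assert basis.explained_variance_ratio[0] > 0.99
        # SVD oracle: leading right singular vector of the centered data
        c = data - data.mean(axis=0)
        _, _, vt = np.linalg.svd(c, full_matrices=False)
        assert abs(np.dot(vt[0], basis.components[0])) == pytest.approx(1.0, abs=1e-6)

    def test_orthonormal_loadings(self, demo):
        depth, _ = simulate_depth(SimulationConfig(n_specimens=40, seed=42), demo)
        rdr = compute_rdr(group_depth(depth, demo), demo)
        basis = fit_pca(rdr, n_components=3, var_target=None)
        gram = basis.components @ basis.components.T
        assert np.allclose(gram, np.eye(3), atol=1e-8)

    def test_k0_identity(self, demo):
        depth, _ = simulate_depth(SimulationConfig(n_specimens=10, seed=43), demo)
        rdr = compute_rdr(group_depth(depth, demo), demo)
        basis = fit_pca(rdr, n_components=0)
        rdrp = apply_pca(rdr, basis)
        assert rdrp.values.equals(rdr.values)

    def test_specimen_on_mean_plus_component_restored(self, flat_panel):
        """A specimen equal to the training mean plus a small multiple of
        component 1 is projected back onto the mean row."""
        rng = np.random.default_rng(1)
        data = 1.0 + rng.normal(size=(40, 7)) * 0.02
        v1 = rng.normal(size=7)
        v1 /= np.linalg.norm(v1)
        data += np.outer(rng.normal(size=40) * 0.2, v1)  # dominant direction
        tids = [f"{b.target_id}|G" for b in flat_panel.bins()]
        strata = pd.Series("single_bin", index=tids)
        nm = NormalizedMatrix(
            "RDr", pd.DataFrame(data.T, index=tids, columns=[f"s{i}" for i in range(40)]), strata
        )
        basis = fit_pca(nm, n_components=1, var_target=None)
        probe = basis.mean + 0.05 * basis.components[0]
        pm = NormalizedMatrix("RDr", pd.DataFrame(probe[:, None], index=tids, columns=["p"]), strata)
        out = apply_pca(pm, basis)
        assert np.allclose(out.values["p"].to_numpy(), basis.mean, atol=1e-10)

    def test_too_few_specimens_rejected(self, flat_panel):
        tids = [f"{b.target_id}|G" for b in flat_panel.bins()]
        nm = NormalizedMatrix(
            "RDr", pd.DataFrame(np.ones((7, 4)), index=tids,
                                columns=list("abcd")), pd.Series("single_bin", index=tids)
        )
        with pytest.raises(ValueError):
            fit_pca(nm, n_components=5)

    @pytest.mark.parametrize(
        "ratios,k,expected",
        [([0.95, 0.03, 0.01], 5, 1), ([0.5, 0.3, 0.2], 2, 2), ([0.2] * 5, 5, 5)],
    )
    def test_component_cap(self, ratios, k, expected):
        assert choose_n_components(np.array(ratios), k, 0.90) == expected

    def test_sparse_signal_survives_dense_factor_removal(self, demo):
        """A 4-exon het deletion keeps its ~0.5 depth ratio through removal
        of a dense technical component."""
        cfg = SimulationConfig(
            n_specimens=100, n_technical_factors=1, technical_sd=0.08,
            dispersion=0.001, seed=44,
        )
        depth, truth = simulate_depth(cfg, demo)
        rdr_train = compute_rdr(group_depth(depth, demo), demo)
        basis = fit_pca(rdr_train, n_components=1, var_target=None)
        ev = CnvEvent("spec0005", "CDH1", (4, 9), "het_del")
        spiked, table = spike_cnvs(depth, [ev], demo, truth)
        x = normalize_to_x(spiked, demo, basis)
        mu = normalize_to_x(depth, demo, basis)  # pre-spike reference
        bins = table.iloc[0]["bins"].split(",")
        sb = [f"{b}|G" for b in bins]
        ratio = (
            x.values.loc[sb, "spec0005"] / mu.values.loc[sb, "spec0005"]
        ).mean()
        assert ratio == pytest.approx(0.5, abs=0.05)


class TestMedianNormalize:
    def test_constant_row_to_one(self, flat_panel):
        tids = [f"{b.target_id}|G" for b in flat_panel.bins()]
        nm = NormalizedMatrix(
            "RDrp", pd.DataFrame(np.full((7, 1), 3.3), index=tids, columns=["s"]),
            pd.Series("single_bin", index=tids),
        )
        assert np.allclose(median_normalize(nm).values.to_numpy(), 1.0)

    @pytest.mark.parametrize("n_groups", [5, 6])
    def test_median_one_odd_and_even(self, n_groups):
        panel = build_panel({"G": [100] * n_groups}, window_sizes=())
        rng = np.random.default_rng(2)
        arr = rng.uniform(10, 100, size=(n_groups, 3))
        m = depth_from_array(arr, [b.target_id for b in panel.bins()], ["a", "b", "c"])
        x = normalize_to_x(m, panel)
        sb = x.single_bin_mask()
        med = np.median(x.values.to_numpy()[sb], axis=0)
        assert np.allclose(med, 1.0, atol=1e-12)

    def test_brute_force_oracle_k0(self):
        """With no PCA, X must equal RDr / per-specimen median RDr —
        checked against a direct transcription on random 5x7 matrices."""
        panel = build_panel({"G": [100] * 5}, window_sizes=())
        rng = np.random.default_rng(3)
        for _ in range(10):
            arr = rng.uniform(5, 500, size=(5, 7))
            m = depth_from_array(arr, [b.target_id for b in panel.bins()],
                                 [f"s{i}" for i in range(7)])
            x = normalize_to_x(m, panel)
            sb_ids = [f"{b.target_id}|G" for b in panel.bins()]
            got = x.values.loc[sb_ids].to_numpy()
            # oracle
            rdr = arr / arr.mean(axis=0, keepdims=True)
            expected = rdr / np.median(rdr, axis=0, keepdims=True)
            assert np.allclose(got, expected, atol=1e-12)


def test_null_x_concentrates_near_one(demo):
    """On a null simulation without technical factors, |X - 1| rarely
    exceeds 0.3 at single-bin level relative to the per-bin reference."""
    depth, _ = simulate_depth(
        SimulationConfig(n_specimens=60, n_technical_factors=0, seed=45), demo
    )
    x = normalize_to_x(depth, demo)
    sb = x.single_bin_mask()
    vals = x.values.to_numpy()[sb]
    ref = np.median(vals, axis=1, keepdims=True)  # per-bin profile
    frac = (np.abs(vals / ref - 1.0) > 0.3).mean()
    assert frac < 0.01


def test_full_chain_scale_invariance(demo):
    depth, _ = simulate_depth(SimulationConfig(n_specimens=12, seed=46), demo)
    rdr = compute_rdr(group_depth(depth, demo), demo)
    basis = fit_pca(rdr, n_components=2)
    x1 = normalize_to_x(depth, demo, basis)
    scaled = depth.values.copy()
    scaled["spec0003"] *= 7.5
    from panelcnv import DepthMatrix

    x2 = normalize_to_x(
        DepthMatrix(values=scaled, batch_labels=depth.batch_labels.copy()), demo, basis
    )
    assert np.allclose(x1.values.to_numpy(), x2.values.to_numpy(), atol=1e-12)
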