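"""Z / Z.adj scoring, flagging and call merging."""

import numpy as np
import pandas as pd
import pytest

from panelcnv import (
    Cutoffs,
    batch_mu,
    flag_groups,
    merge_calls,
    score_matrix,
    set_confirmation,
    write_calls_tsv,
    read_calls_tsv,
    write_calls_vcf,
    z_adj,
    z_score,
)
from panelcnv.normalize import NormalizedMatrix

from conftest import build_panel


def _nm(values, strata="single_bin"):
    values = pd.DataFrame(values)
    values.index = [f"g{i}" for i in range(values.shape[0])]
    values.columns = [f"s{i}" for i in range(values.shape[1])]
    if isinstance(strata, str):
        strata = pd.Series(strata, index=values.index)
    return NormalizedMatrix("X", values, strata)


class TestBatchMu:
    def test_median_of_three(self):
        nm = _nm(np.array([[0.9, 1.0, 1.1]]))
        labels = pd.Series("b", index=nm.values.columns)
        assert batch_mu(nm, labels).loc["g0", "b"] == 1.0

    def test_identical_specimens(self):
        nm = _nm(np.full((2, 4), 2.5))
        labels = pd.Series("b", index=nm.values.columns)
        assert (batch_mu(nm, labels) == 2.5).all().all()

    def test_small_batch_rejected(self):
        nm = _nm(np.ones((1, 2)))
        labels = pd.Series("b", index=nm.values.columns)
        with pytest.raises(ValueError, match="pool"):
            batch_mu(nm, labels)

    def test_qc_fail_excluded(self):
        nm = _nm(np.array([[1.0, 1.0, 1.0, 99.0]]))
        labels = pd.Series("b", index=nm.values.columns)
        qc = pd.Series([True, True, True, False], index=nm.values.columns)
        assert batch_mu(nm, labels, qc).loc["g0", "b"] == 1.0

    def test_one_carrier_in_92_barely_moves_mu(self):
        """Order-statistics check: replacing one of 92 null values with a
        het-del value moves the median by < 0.6%."""
        rng = np.random.default_rng(8)
        null = 1.0 + 0.05 * rng.standard_normal(92)
        shifted = null.copy()
        shifted[0] = 0.5
        shift = abs(np.median(shifted) - np.median(null)) / np.median(null)
        assert shift < 0.006


class TestZScores:
    def test_forced_arithmetic(self):
        nm = _nm(np.array([[1.0], [1.05], [0.5]]))
        mu = pd.DataFrame({"b": [1.0, 1.0, 1.0]}, index=nm.values.index)
        sigma = pd.Series(0.05, index=nm.values.index)
        labels = pd.Series("b", index=nm.values.columns)
        z = z_score(nm, mu, labels, sigma)
        assert list(z["s0"].round(10)) == [0.0, 1.0, -10.0]

    def test_sigma_zero_unscorable(self):
        nm = _nm(np.ones((2, 1)))
        mu = pd.DataFrame({"b": [1.0, 1.0]}, index=nm.values.index)
        sigma = pd.Series([0.0, 0.1], index=nm.values.index)
        labels = pd.Series("b", index=nm.values.columns)
        z = z_score(nm, mu, labels, sigma)
        assert np.isnan(z.iloc[0, 0]) and z.iloc[1, 0] == 0.0

    def test_batch_median_zero_invariant(self):
        rng = np.random.default_rng(9)
        nm = _nm(rng.uniform(0.8, 1.2, size=(6, 9)))
        labels = pd.Series("b", index=nm.values.columns)
        mu = batch_mu(nm, labels)
        sigma = pd.Series(rng.uniform(0.01, 0.1, size=6), index=nm.values.index)
        z = z_score(nm, mu, labels, sigma)
        assert np.allclose(np.median(z.to_numpy(), axis=1), 0.0, atol=1e-12)

    def test_zadj_forced(self):
        # one group at Z=6, five others whose sd is 2
        others = np.array([2.0, -2.0, 2.0, -2.0, 0.0])
        assert np.std(others, ddof=1) == pytest.approx(2.0, rel=1e-12)
        z = pd.DataFrame(np.r_[6.0, others][:, None],
                         index=[f"g{i}" for i in range(6)], columns=["s"])
        strata = pd.Series("single_bin", index=z.index)
        za = z_adj(z, strata)
        assert za.loc["g0", "s"] == pytest.approx(3.0, rel=1e-12)

    def test_zadj_scale_cancellation(self):
        """Inflating all of a specimen's Z threefold leaves Z.adj intact —
        the statistic isolates pattern from specimen noisiness."""
        rng = np.random.default_rng(10)
        z = pd.DataFrame(rng.standard_normal((8, 1)),
                         index=[f"g{i}" for i in range(8)], columns=["s"])
        strata = pd.Series("single_bin", index=z.index)
        assert np.allclose(z_adj(3 * z, strata), z_adj(z, strata), equal_nan=True)

    def test_zadj_constant_row_nan(self):
        z = pd.DataFrame(np.full((5, 1), 2.0), index=[f"g{i}" for i in range(5)],
                         columns=["s"])
        za = z_adj(z, pd.Series("single_bin", index=z.index))
        assert za.isna().all().all()

    def test_brute_force_oracle(self):
        """Z and Z.adj on random 6x9 matrices match a direct transcription
        of the formulas to 1e-12."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            x = rng.uniform(0.5, 1.5, size=(6, 9))
            sigma_v = rng.uniform(0.02, 0.2, size=6)
            nm = _nm(x)
            labels = pd.Series("b", index=nm.values.columns)
            sigma = pd.Series(sigma_v, index=nm.values.index)
            mu = batch_mu(nm, labels)
            z = z_score(nm, mu, labels, sigma).to_numpy()
            za = z_adj(pd.DataFrame(z, index=nm.values.index, columns=nm.values.columns),
                       nm.strata).to_numpy()
            # oracle
            mu_o = np.median(x, axis=1)
            z_o = (x - mu_o[:, None]) / sigma_v[:, None]
            za_o = np.empty_like(z_o)
            for g in range(6):
                for s in range(9):
                    others = np.delete(z_o[:, s], g)
                    za_o[g, s] = z_o[g, s] / np.std(others, ddof=1)
            assert np.allclose(z, z_o, atol=1e-12)
            assert np.allclose(za, za_o, atol=1e-12)


class TestFlagging:
    def _zz(self, z, zadj):
        idx = [f"g{i}" for i in range(len(z))]
        strata = pd.Series("single_bin", index=idx)
        Z = pd.DataFrame(np.asarray(z, dtype=float)[:, None], index=idx, columns=["s"])
        A = pd.DataFrame(np.asarray(zadj, dtype=float)[:, None], index=idx, columns=["s"])
        return Z, A, strata

    def test_flag_sources(self):
        Z, A, strata = self._zz([-10.0, 2.0, 0.0], [1.0, 5.0, 0.0])
        cut = Cutoffs(z={"single_bin": 3.5}, zadj={"single_bin": 3.5})
        flag, src = flag_groups(Z, A, cut, strata)
        assert list(flag["s"]) == [True, True, False]
        assert list(src["s"]) == [1, 2, 0]  # Z, Zadj, none

    def test_both_rule(self):
        Z, A, strata = self._zz([-10.0, 2.0], [1.0, 5.0])
        cut = Cutoffs(z={"single_bin": 3.5}, zadj={"single_bin": 3.5})
        flag, _ = flag_groups(Z, A, cut, strata, rule="both")
        assert not flag["s"].any()

    def test_nan_never_flags(self):
        Z, A, strata = self._zz([np.nan], [np.nan])
        cut = Cutoffs(z={"single_bin": 1.0}, zadj={"single_bin": 1.0})
        flag, _ = flag_groups(Z, A, cut, strata)
        assert not flag["s"].any()

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(12)
        Z, A, strata = self._zz(rng.standard_normal(50) * 3, rng.standard_normal(50) * 3)
        flags = []
        for c in (6.0, 4.0, 2.0, 1.0):
            cut = Cutoffs(z={"single_bin": c}, zadj={"single_bin": c})
            f, _ = flag_groups(Z, A, cut, strata)
            flags.append(f.to_numpy())
        for tight, loose in zip(flags, flags[1:]):
            assert (loose | ~tight).all()  # lowering a cutoff never removes a flag

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            Cutoffs(z={"single_bin": 0.0}, zadj={"single_bin": 1.0})


@pytest.fixture(scope="module")
def merge_panel():
    return build_panel({"G": [100] * 6}, window_sizes=(4,))


class TestMergeCalls:
    @pytest.fixture()
    def panel(self, merge_panel):
        return merge_panel

    def _scores(self, panel, flagged_groups, x=None, mu_val=1.0):
        gids = [g.group_id for g in panel.groups]
        specimens = ["s"]
        strata = pd.Series({g.group_id: g.stratum for g in panel.groups})
        X = pd.DataFrame(
            np.ones((len(gids), 1)) if x is None else x, index=gids, columns=specimens
        )
        Z = pd.DataFrame(np.zeros((len(gids), 1)), index=gids, columns=specimens)
        flag = pd.DataFrame(False, index=gids, columns=specimens)
        for g, zval in flagged_groups.items():
            flag.loc[g, "s"] = True
            Z.loc[g, "s"] = zval
        src = pd.DataFrame(np.where(flag, 1, 0), index=gids, columns=specimens)
        mu = pd.DataFrame({"default": np.full(len(gids), mu_val)}, index=gids)
        from panelcnv.score import ScoreMatrix

        return ScoreMatrix(
            specimen_ids=specimens, group_ids=gids, Z=Z, Zadj=Z * np.nan, mu=mu,
            X=X, flag=flag, flag_source=src, strata=strata,
        )

    def test_window_flag_merges_to_one_call(self, panel):
        """A flagged 4-exon window projects to one 4-exon deletion call."""
        x = np.ones((len(panel.groups), 1))
        gidx = {g.group_id: i for i, g in enumerate(panel.groups)}
        for e in (2, 3, 4, 5):
            x[gidx[f"G|ex{e}|b1|G"]] = 0.5
        scores = self._scores(panel, {"G|ex2-5|w4": -8.0}, x=x)
        calls = merge_calls(scores, panel)
        assert len(calls) == 1
        c = calls[0]
        assert (c.first_exon, c.last_exon, c.cnv_type) == (2, 5, "DEL")
        assert c.best_group_id == "G|ex2-5|w4"
        assert c.mean_X_ratio == pytest.approx(0.5)

    def test_disjoint_flags_two_calls(self, panel):
        x = np.ones((len(panel.groups), 1))
        gidx = {g.group_id: i for i, g in enumerate(panel.groups)}
        x[gidx["G|ex1|b1|G"]] = 0.5
        x[gidx["G|ex5|b1|G"]] = 1.6
        scores = self._scores(panel, {"G|ex1|b1|G": -6.0, "G|ex5|b1|G": 7.0}, x=x)
        calls = merge_calls(scores, panel)
        assert len(calls) == 2
        types = {(c.first_exon, c.cnv_type) for c in calls}
        assert types == {(1, "DEL"), (5, "DUP")}

    def test_no_flags_no_calls(self, panel):
        assert merge_calls(self._scores(panel, {}), panel) == []

    def test_status_and_confirmation(self, panel):
        x = np.ones((len(panel.groups), 1))
        scores = self._scores(panel, {"G|ex1|b1|G": -6.0}, x=x)
        calls = merge_calls(scores, panel)
        assert calls[0].status == "flagged_pending_confirmation"
        done = set_confirmation(calls, {("s", "G"): "refuted"})
        assert done[0].status == "refuted"
        with pytest.raises(ValueError):
            set_confirmation(calls, {("s", "G"): "maybe"})


class TestCallIO:
    def _call(self):
        from panelcnv.score import CnvCall

        return CnvCall(
            specimen_id="s1", gene="G", chrom="chr1", start=100, end=400,
            first_exon=1, last_exon=2, bins=("G|ex1|b1", "G|ex2|b1"),
            cnv_type="DEL", best_group_id="G|ex1-2|w2", max_abs_Z=7.5,
            mean_X_ratio=0.51, flag_source="both",
        )

    def test_tsv_roundtrip(self, tmp_path):
        path = tmp_path / "calls.tsv"
        write_calls_tsv([self._call()], path)
        (back,) = read_calls_tsv(path)
        assert back == self._call()

    def test_empty_calls_header_only(self, tmp_path):
        path = tmp_path / "calls.tsv"
        write_calls_tsv([], path)
        assert read_calls_tsv(path) == []
        assert path.read_text().startswith("specimen_id\t")

    def test_vcf_records(self, tmp_path):
        path = tmp_path / "calls.vcf"
        write_calls_vcf([self._call()], path)
        text = path.read_text()
        assert "##fileformat=VCFv4.2" in text
        body = [l for l in text.splitlines() if not l.startswith("#")]
        assert len(body) == 1
        fields = body[0].split("\t")
        assert fields[0] == "chr1" and fields[1] == "101" and fields[4] == "<DEL>"
        assert "SVTYPE=DEL" in fields[7] and "END=400" in fields[7]
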