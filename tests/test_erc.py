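"""Winsorization, Fisher transform, and pairwise ERC behavior."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ratecov.erc import (
    ERCMatrix,
    all_pairs_erc,
    fisher_transform,
    pairwise_erc,
    winsorize,
)
from ratecov.rer import RERMatrix


def make_rer(rows: dict, n_species=None) -> RERMatrix:
    df = pd.DataFrame(rows).T
    df.columns = [f"s{i:03d}" for i in range(df.shape[1])]
    species = {
        g: frozenset(f"sp{i}" for i in range(n_species or df.shape[1] + 1))
        for g in df.index
    }
    return RERMatrix(values=df, method="log-ratio", species=species)


class TestWinsorize:
    def test_canonical_example(self):
        out = winsorize(np.arange(1, 11, dtype=float), k=3)
        assert list(out) == [4, 4, 4, 4, 5, 6, 7, 7, 7, 7]

    def test_constant_vector_unchanged(self):
        v = np.full(10, 2.5)
        assert list(winsorize(v, 3)) == list(v)

    def test_boundary_ties_resolved_by_value(self):
        v = np.array([-5, 0, 0, 0, 0, 0, 0, 0, 0, 9, 9, 9, 9], dtype=float)
        # sort-and-replace oracle
        srt = np.sort(v)
        expected = np.clip(v, srt[3], srt[-4])
        assert list(winsorize(v, 3)) == list(expected)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            winsorize(np.arange(6, dtype=float), 3)

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=8, max_size=40),
        st.integers(1, 3),
    )
    @settings(deadline=None, max_examples=50)
    def test_idempotent_and_order_preserving(self, vals, k):
        v = np.asarray(vals)
        if len(v) <= 2 * k:
            return
        once = winsorize(v, k)
        assert list(winsorize(once, k)) == list(once)
        # element order is preserved: ranks never cross after capping
        srt = np.sort(v)
        for i, j in zip(range(len(v)), range(1, len(v))):
            if v[i] <= v[j]:
                assert once[i] <= once[j]


class TestFisherTransform:
    def test_closed_form(self):
        assert fisher_transform(0.5, 103) == pytest.approx(
            0.5 * np.log(3) * 10, abs=1e-12
        )

    def test_zero_and_odd_symmetry(self):
        assert fisher_transform(0.0, 50) == 0.0
        assert fisher_transform(-0.5, 103) == pytest.approx(
            -fisher_transform(0.5, 103), abs=1e-12
        )

    def test_monotone_in_r_and_n(self):
        rs = np.linspace(-0.95, 0.95, 21)
        vals = [fisher_transform(r, 40) for r in rs]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        ns = [4, 10, 50, 300]
        vals = [fisher_transform(0.6, n) for n in ns]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_r_of_one_clamped_finite(self):
        assert np.isfinite(fisher_transform(1.0, 28))
        assert fisher_transform(1.0, 28) > 10

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n=3"):
            fisher_transform(0.5, 3)


class TestPairwiseERC:
    def test_identical_vectors_give_r_one(self, rng):
        v = rng.standard_normal(28)
        rer = make_rer({"a": v, "b": v})
        val = pairwise_erc(rer, "a", "b")
        assert not val.filtered
        assert val.r == pytest.approx(1.0)
        assert val.n_branches == 28
        assert np.isfinite(val.fterc) and val.fterc > 10

    def test_shared_species_threshold_boundary(self, rng):
        v = rng.standard_normal(26)
        rer14 = make_rer({"a": v, "b": v}, n_species=14)
        assert pairwise_erc(rer14, "a", "b").filter_reason == "too few shared species"
        rer15 = make_rer({"a": v, "b": v}, n_species=15)
        assert not pairwise_erc(rer15, "a", "b").filtered

    def test_zero_variance_filtered(self):
        rer = make_rer({"a": np.zeros(20), "b": np.arange(20.0)})
        assert pairwise_erc(rer, "a", "b").filter_reason == "zero variance"

    def test_brute_force_sigma_formula_oracle(self, rng):
        a = rng.standard_normal(20)
        b = 0.6 * a + 0.8 * rng.standard_normal(20)
        rer = make_rer({"a": a, "b": b})
        val = pairwise_erc(rer, "a", "b", winsor_k=3)
        wa, wb = winsorize(a, 3), winsorize(b, 3)
        n = 20
        num = n * (wa * wb).sum() - wa.sum() * wb.sum()
        den = np.sqrt(n * (wa**2).sum() - wa.sum() ** 2) * np.sqrt(
            n * (wb**2).sum() - wb.sum() ** 2
        )
        r = num / den
        assert val.r == pytest.approx(r, abs=1e-12)
        assert val.fterc == pytest.approx(
            np.arctanh(r) * np.sqrt(17), abs=1e-10
        )

    def test_restriction_to_shared_branches(self, rng):
        a = rng.standard_normal(30)
        b = rng.standard_normal(30)
        a[5:10] = np.nan
        b[20:24] = np.nan
        rer = make_rer({"a": a, "b": b})
        val = pairwise_erc(rer, "a", "b")
        assert val.n_branches == 30 - 5 - 4

    def test_branch_order_permutation_invariance(self, rng):
        a, b = rng.standard_normal(25), rng.standard_normal(25)
        perm = rng.permutation(25)
        r1 = pairwise_erc(make_rer({"a": a, "b": b}), "a", "b").r
        r2 = pairwise_erc(make_rer({"a": a[perm], "b": b[perm]}), "a", "b").r
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestAllPairs:
    def test_matches_looped_pairwise_calls(self, rng):
        rows = {f"g{i}": rng.standard_normal(24) for i in range(5)}
        rows["g2"][4:8] = np.nan  # force the general (incomplete) path
        rer = make_rer(rows)
        mat = all_pairs_erc(rer)
        from itertools import combinations

        for a, b in combinations(sorted(rows), 2):
            want = pairwise_erc(rer, a, b)
            got = mat.get(a, b)
            if want.filtered:
                assert got.filter_reason == want.filter_reason
            else:
                assert got.fterc == pytest.approx(want.fterc, abs=1e-12)

    def test_complete_fast_path_matches_loop(self, rng):
        rows = {f"g{i}": rng.standard_normal(30) for i in range(6)}
        rer = make_rer(rows)
        mat = all_pairs_erc(rer)
        for a, b in [("g0", "g3"), ("g1", "g5")]:
            assert mat.get(a, b).fterc == pytest.approx(
                pairwise_erc(rer, a, b).fterc, abs=1e-10
            )

    def test_all_pairs_below_species_threshold_fully_filtered(self, rng):
        rows = {f"g{i}": rng.standard_normal(20) for i in range(3)}
        rer = make_rer(rows, n_species=10)
        mat = all_pairs_erc(rer)
        assert mat.edges["filter_reason"].notna().all()

    def test_perfect_latent_factor_gives_r_one(self):
        shared = np.sin(np.arange(30))
        rer = make_rer({f"g{i}": shared for i in range(3)})
        mat = all_pairs_erc(rer)
        assert np.allclose(mat.edges["r"].dropna(), 1.0)

    def test_tsv_round_trip(self, rng, tmp_path):
        rows = {f"g{i}": rng.standard_normal(30) for i in range(4)}
        mat = all_pairs_erc(make_rer(rows))
        path = tmp_path / "erc.tsv"
        mat.to_tsv(path)
        back = ERCMatrix.from_tsv(path)
        assert back.get("g0", "g1").fterc == pytest.approx(
            mat.get("g0", "g1").fterc
        )


def test_fterc_null_normalization(rng):
    """Fisher z property: independent RERs give ftERC with mean ~0, var ~1."""
    for n in (20, 50, 200):
        fts = []
        for _ in range(600):
            a = winsorize(rng.standard_normal(n), 3)
            b = winsorize(rng.standard_normal(n), 3)
            fts.append(fisher_transform(float(np.corrcoef(a, b)[0, 1]), n))
        fts = np.asarray(fts)
        se = fts.std() / np.sqrt(len(fts))
        assert abs(fts.mean()) < 3 * se
        assert 0.8 < fts.var() < 1.2


def test_winsorization_bounds_outlier_effect(rng):
    """A single outlier branch moves ftERC less with Winsorization than without."""
    n = 40
    a = rng.standard_normal(n)
    b = 0.5 * a + np.sqrt(0.75) * rng.standard_normal(n)
    a_out, b_out = a.copy(), b.copy()
    a_out[0], b_out[0] = 12.0, 12.0  # one spuriously shared extreme branch

    def ft(x, y, k):
        xw, yw = winsorize(x, k), winsorize(y, k)
        return fisher_transform(float(np.corrcoef(xw, yw)[0, 1]), n)

    change_winsor = abs(ft(a_out, b_out, 3) - ft(a, b, 3))
    change_raw = abs(ft(a_out, b_out, 0) - ft(a, b, 0))
    assert change_winsor < change_raw
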