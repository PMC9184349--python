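import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import beta_mntd_oracle, brute_force_cophenetic, random_tree
from ecoassembly.io import OtuTable, read_tree
from ecoassembly.phylo import (beta_mntd, beta_nti_matrix,
                               cophenetic_distances, mntd_weighted, nti)


class TestCophenetic:
    def test_toy_path_sums(self, toy_tree):
        d = cophenetic_distances(toy_tree, ids=["A", "B", "C"])
        m = np.asarray(d.data)
        assert m[0, 1] == 2 and m[0, 2] == 4 and m[1, 2] == 4
        assert np.all(np.diag(m) == 0)

    def test_star_tree(self):
        t = read_tree("(A:3,B:3,C:3,D:3);")
        m = np.asarray(cophenetic_distances(t, ids=list("ABCD")).data)
        off = m[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 6.0)

    def test_matches_path_walk_oracle(self):
        t = random_tree(20, seed=9)
        ids = sorted(t.leaf_labels)
        d = np.asarray(cophenetic_distances(t, ids=ids).data)
        oracle = brute_force_cophenetic(t)
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                assert d[i, j] == pytest.approx(
                    oracle[frozenset((a, ids[j]))], abs=1e-10)


class TestMntd:
    def test_two_taxa(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        assert mntd_weighted([0.5, 0.5], d) == pytest.approx(2.0)

    def test_single_taxon_flagged(self):
        assert math.isnan(mntd_weighted([1.0], np.zeros((1, 1))))

    def test_matches_scan_oracle(self):
        rng = np.random.default_rng(3)
        t = random_tree(10, seed=3)
        ids = sorted(t.leaf_labels)
        d = np.asarray(t.cophenetic(ids).data)
        for _ in range(20):
            f = rng.dirichlet(np.ones(10)) * (rng.random(10) > 0.3)
            if (f > 0).sum() < 2:
                continue
            w = f[f > 0] / f[f > 0].sum()
            sup = np.flatnonzero(f > 0)
            expected = sum(
                wi * min(d[i, j] for j in sup if j != i)
                for wi, i in zip(w, sup))
            assert mntd_weighted(f, d) == pytest.approx(expected, abs=1e-12)


class TestBetaMntd:
    def test_identity_is_zero(self):
        d = np.array([[0, 2, 3], [2, 0, 1], [3, 1, 0.0]])
        f = np.array([0.5, 0.3, 0.2])
        assert beta_mntd(f, f, d) == 0.0

    def test_singleton_pair(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        assert beta_mntd([1.0, 0.0], [0.0, 1.0], d) == pytest.approx(2.0)

    def test_empty_community_rejected(self):
        d = np.zeros((2, 2))
        with pytest.raises(ValueError, match="empty"):
            beta_mntd([0.0, 0.0], [1.0, 0.0], d)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(12)
        for rep in range(50):
            n = int(rng.integers(3, 9))
            t = random_tree(n, seed=100 + rep)
            ids = sorted(t.leaf_labels)
            d = np.asarray(t.cophenetic(ids).data)
            f_k = rng.dirichlet(np.ones(n)) * (rng.random(n) > 0.3)
            f_l = rng.dirichlet(np.ones(n)) * (rng.random(n) > 0.3)
            if f_k.sum() == 0 or f_l.sum() == 0:
                continue
            got = beta_mntd(f_k, f_l, d)
            assert got == pytest.approx(beta_mntd_oracle(f_k, f_l, d),
                                        abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_symmetric_and_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        d = rng.random((n, n)) * 5
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        f_k = rng.dirichlet(np.ones(n))
        f_l = rng.dirichlet(np.ones(n))
        a = beta_mntd(f_k, f_l, d)
        assert a == pytest.approx(beta_mntd(f_l, f_k, d), abs=1e-12)
        assert a >= 0


def _counts(rows, ids=None, otus=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    otus = otus or [f"O{i}" for i in range(len(rows[0]))]
    return OtuTable(pd.DataFrame(rows, index=ids, columns=otus))


class TestNti:
    def test_full_pool_community_flagged(self):
        """A community holding every pool taxon is invariant under label
        shuffles, so its null collapses and the NTI is flagged."""
        t = random_tree(6, seed=1)
        ids = sorted(t.leaf_labels)
        d = t.cophenetic(ids)
        table = _counts([[1] * 6, [1, 2, 3, 4, 5, 6]], otus=ids)
        res = nti(table, d, n_null=99, seed=0)
        assert not res.table.loc["s0", "valid"]
        assert math.isnan(res.table.loc["s0", "nti"])

    def test_sister_pair_clustered(self):
        """Two sister taxa on a tree with distant outgroups are clustered:
        observed MNTD beats nearly every relabelling, so NTI > 0."""
        t = read_tree("(((A:1,B:1):9,(C:1,D:1):9):10,(E:5,F:5):15);")
        ids = sorted(t.leaf_labels)
        d = t.cophenetic(ids)
        table = _counts([[1, 1, 0, 0, 0, 0], [1, 1, 1, 1, 1, 1]], otus=ids)
        res = nti(table, d, n_null=999, seed=0)
        assert res.table.loc["s0", "valid"]
        assert res.table.loc["s0", "nti"] > 0

    def test_rejects_bad_n_null(self, toy_dataset):
        with pytest.raises(ValueError):
            nti(toy_dataset.otu, toy_dataset.cophenetic(), n_null=0)


class TestBetaNtiMatrix:
    def test_identical_pair_flagged_invalid(self):
        """Shared taxa stay at distance 0 under every joint relabelling, so
        an identical pair's null is degenerate and the pair is flagged."""
        t = random_tree(8, seed=2)
        ids = sorted(t.leaf_labels)
        d = t.cophenetic(ids)
        table = _counts([[2, 1, 0, 0, 1, 0, 3, 1]] * 2 + [[1] * 8], otus=ids)
        tm = beta_nti_matrix(table, d, n_null=199, seed=0)
        i, j = tm.ids.index("s0"), tm.ids.index("s1")
        assert not tm.valid[i, j]
        assert math.isnan(tm.values[i, j])

    def test_near_identical_pair_strongly_negative(self):
        t = random_tree(12, seed=5)
        ids = sorted(t.leaf_labels)
        d = t.cophenetic(ids)
        a = [5, 4, 3, 2, 1, 1, 1, 1, 1, 1, 0, 0]
        b = [5, 4, 3, 2, 1, 1, 1, 1, 1, 0, 1, 0]
        c = [0, 0, 1, 0, 2, 0, 4, 0, 1, 3, 0, 5]
        tm = beta_nti_matrix(_counts([a, b, c], otus=ids), d,
                             n_null=999, seed=0)
        assert tm.pair_value("s0", "s1") < -1.0

    def test_deterministic_rerun(self, neutral_ds):
        ds, _ = neutral_ds
        d = ds.cophenetic()
        pool = ds.sample_ids[:8]
        a = beta_nti_matrix(ds.otu, d, pool=pool, n_null=99, seed=7)
        b = beta_nti_matrix(ds.otu, d, pool=pool, n_null=99, seed=7)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.to_frame().equals(b.to_frame())

    def test_pool_restriction_shrinks_taxa(self, neutral_ds):
        ds, _ = neutral_ds
        d = ds.cophenetic()
        pool = ds.sample_ids[:4]
        tm = beta_nti_matrix(ds.otu, d, pool=pool, n_null=9, seed=0)
        assert set(tm.ids) == set(pool)

    def test_small_pool_rejected(self, neutral_ds):
        ds, _ = neutral_ds
        with pytest.raises(ValueError, match="at least 2"):
            beta_nti_matrix(ds.otu, ds.cophenetic(),
                            pool=ds.sample_ids[:1], n_null=9)
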