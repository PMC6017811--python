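import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famspace import Alignment, rank_encode, run_pca, family_separation
from famspace.rank_pca import DegenerateInputError


def _aln_from_columns(*columns: str) -> Alignment:
    """Build an alignment whose j-th column is the j-th argument string."""
    n = len(columns[0])
    seqs = tuple("".join(col[i] for col in columns) for i in range(n))
    return Alignment(ids=tuple(f"s{i}" for i in range(n)), seqs=seqs)


class TestRankEncode:
    def test_frequency_ordering(self):
        rm = rank_encode(_aln_from_columns("AAC"))
        assert rm.values[:, 0].tolist() == [1, 1, 2]

    def test_tie_broken_alphabetically(self):
        # C and A occur once each: A outranks C by one-letter code
        rm = rank_encode(_aln_from_columns("CA"))
        assert rm.values[:, 0].tolist() == [2, 1]

    def test_conserved_column_is_constant(self):
        rm = rank_encode(_aln_from_columns("GGG"))
        assert rm.values[:, 0].tolist() == [1, 1, 1]

    def test_gap_worst_rank(self):
        rm = rank_encode(_aln_from_columns("A-A-"), gap_policy="gap_worst_rank")
        # only A observed (rank 1); gaps get max rank + 1 = 2
        assert rm.values[:, 0].tolist() == [1, 2, 1, 2]

    def test_gap_as_symbol_participates(self):
        rm = rank_encode(_aln_from_columns("--A"))
        assert rm.values[:, 0].tolist() == [1, 1, 2]

    def test_gap_loses_alphabetical_tie(self):
        rm = rank_encode(_aln_from_columns("-A"))
        assert rm.values[:, 0].tolist() == [2, 1]

    def test_single_sequence_rejected(self):
        aln = Alignment(ids=("s0",), seqs=("ACD",))
        with pytest.raises(ValueError):
            rank_encode(aln)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_permutation_equivariance(self, seed):
        """Permuting sequence order permutes rank-matrix rows identically."""
        rng = np.random.default_rng(seed)
        n, p = 6, 12
        seqs = tuple(
            "".join(rng.choice(list("ACDEG-"), size=p)) for _ in range(n)
        )
        aln = Alignment(ids=tuple(f"s{i}" for i in range(n)), seqs=seqs)
        perm = rng.permutation(n)
        shuffled = Alignment(
            ids=tuple(aln.ids[i] for i in perm),
            seqs=tuple(aln.seqs[i] for i in perm),
        )
        rm = rank_encode(aln)
        rm_shuffled = rank_encode(shuffled)
        np.testing.assert_array_equal(rm.values[perm], rm_shuffled.values)


class TestRunPCA:
    def test_single_variable_column_concentrates_pc1(self):
        aln = _aln_from_columns("AACC", "GGGG", "KKKK")
        res = run_pca(rank_encode(aln), k=1)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)
        assert abs(res.loadings[0, 0]) == pytest.approx(1.0)
        assert res.loadings[1, 0] == pytest.approx(0.0)

    def test_matches_covariance_eigendecomposition(self, rng):
        """Scores/loadings agree (up to sign) with a brute-force
        eigendecomposition of the sample covariance matrix."""
        X = rng.integers(1, 6, size=(4, 3)).astype(float)
        from famspace.rank_pca import RankMatrix

        rm = RankMatrix(values=X.astype(int), row_ids=("a", "b", "c", "d"),
                        gap_policy="gap_as_symbol")
        res = run_pca(rm, k=2)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / (X.shape[0] - 1))
        order = np.argsort(evals)[::-1]
        for j in range(2):
            v = evecs[:, order[j]]
            cos = abs(float(v @ res.loadings[:, j]))
            assert cos == pytest.approx(1.0, abs=1e-10)
            np.testing.assert_allclose(
                np.abs(Xc @ v), np.abs(res.scores[:, j]), atol=1e-10
            )

    def test_duplicate_rows_same_scores(self):
        aln = _aln_from_columns("AACCA", "GGKKG", "WWYYW")
        res = run_pca(rank_encode(aln), k=2)
        np.testing.assert_allclose(res.scores[0], res.scores[4], atol=1e-12)

    def test_loadings_unit_norm_and_evf_monotone(self, rng):
        from famspace.rank_pca import RankMatrix

        X = rng.integers(1, 8, size=(10, 6))
        rm = RankMatrix(values=X, row_ids=tuple(map(str, range(10))),
                        gap_policy="gap_as_symbol")
        res = run_pca(rm, k=4)
        np.testing.assert_allclose(
            np.linalg.norm(res.loadings, axis=0), 1.0, atol=1e-12
        )
        evf = res.explained_variance_fraction
        assert np.all(np.diff(evf) <= 1e-12)
        assert evf.sum() <= 1.0 + 1e-12

    def test_total_variance_identity_at_full_rank(self, rng):
        """Sum of all component variances equals the total variance of the
        centred matrix."""
        from famspace.rank_pca import RankMatrix

        X = rng.integers(1, 8, size=(9, 5))
        rm = RankMatrix(values=X, row_ids=tuple(map(str, range(9))),
                        gap_policy="gap_as_symbol")
        res = run_pca(rm, k=5)
        Xc = X - X.mean(axis=0)
        total = np.sum(Xc**2)
        var_scores = np.sum(res.scores**2)
        assert var_scores == pytest.approx(total)
        assert res.explained_variance_fraction.sum() == pytest.approx(1.0)

    def test_reconstruction_at_full_rank(self, rng):
        from famspace.rank_pca import RankMatrix

        X = rng.integers(1, 8, size=(7, 4)).astype(float)
        rm = RankMatrix(values=X.astype(int), row_ids=tuple(map(str, range(7))),
                        gap_policy="gap_as_symbol")
        res = run_pca(rm, k=4)
        recon = res.scores @ res.loadings.T + res.column_means
        np.testing.assert_allclose(recon, X, atol=1e-10)

    def test_k_out_of_range(self):
        rm = rank_encode(_aln_from_columns("AAC", "CCA"))
        with pytest.raises(ValueError):
            run_pca(rm, k=3)

    def test_constant_matrix_degenerate(self):
        rm = rank_encode(_aln_from_columns("GGG", "AAA"))
        with pytest.raises(DegenerateInputError):
            run_pca(rm, k=1)


class TestFamilySeparation:
    @staticmethod
    def _result_from_points(points):
        from famspace.rank_pca import PCAResult

        pts = np.asarray(points, dtype=float)
        return PCAResult(
            scores=pts,
            loadings=np.eye(pts.shape[1]),
            explained_variance_fraction=np.full(pts.shape[1], 0.5),
            column_means=np.zeros(pts.shape[1]),
            k=pts.shape[1],
            row_ids=tuple(f"p{i}" for i in range(len(pts))),
        )

    def test_well_separated_families(self):
        res = self._result_from_points([(0, 0), (0, 1), (10, 10), (10, 11)])
        labels = {"p0": "A", "p1": "A", "p2": "B", "p3": "B"}
        assert family_separation(res, labels, (1, 2)) > 0.9

    def test_identical_points_degenerate(self):
        res = self._result_from_points([(1, 1)] * 4)
        labels = {"p0": "A", "p1": "A", "p2": "B", "p3": "B"}
        with pytest.raises(DegenerateInputError):
            family_separation(res, labels, (1, 2))

    def test_singleton_family_excluded_with_warning(self):
        res = self._result_from_points(
            [(0, 0), (0, 1), (10, 10), (10, 11), (5, 5)]
        )
        labels = {"p0": "A", "p1": "A", "p2": "B", "p3": "B", "p4": "C"}
        with pytest.warns(UserWarning, match="single-member"):
            s = family_separation(res, labels, (1, 2))
        assert s > 0.9

    def test_fewer_than_two_usable_families(self):
        res = self._result_from_points([(0, 0), (0, 1), (5, 5)])
        with pytest.raises(ValueError):
            family_separation(res, {"p0": "A", "p1": "A", "p2": "B"}, (1, 2))

    def test_permuted_labels_destroy_separation(self, rng):
        """Random label permutations on well-separated data give silhouettes
        near zero: |mean s| < 0.2 over 100 permutations."""
        pts = np.concatenate(
            [rng.normal(0, 0.5, (10, 2)), rng.normal(20, 0.5, (10, 2))]
        )
        res = self._result_from_points(pts)
        base = ["A"] * 10 + ["B"] * 10
        sils = []
        for _ in range(100):
            perm = rng.permutation(20)
            labels = {f"p{i}": base[perm[i]] for i in range(20)}
            sils.append(family_separation(res, labels, (1, 2)))
        assert abs(np.mean(sils)) < 0.2
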