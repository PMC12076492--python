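import numpy as np
import pytest

from metacv import (
    AtomRecord, ComDistanceCV, ContactSet, HLDAError, LinearComboCV, Selection,
    Structure, TwoStateSpec, evaluate_cv, export_cv_text, gen_two_state_descriptors,
    harmonic_scatter, hlda_direction, parse_cv_text, rank_and_select,
    state_statistics, write_model,
)
from metacv.contacts import ContactDescriptor
from oracles import rayleigh_direction


def make_pool(n):
    """n salt-bridge descriptors over protomer pairs (A,B), (B,C), ..."""
    chains = "ABCDEFGH"
    contacts = [
        ContactDescriptor("salt_bridge", (chains[i], 2, "OE1"), (chains[i + 1], 3, "NZ"),
                          chains[i], chains[i + 1])
        for i in range(n)
    ]
    return ContactSet(contacts)


class TestStateStatistics:
    def test_two_point_sample(self):
        st = state_statistics(np.array([[1.0], [3.0]]), ["d1"])
        assert st.mu[0] == pytest.approx(2.0)
        assert st.sigma[0, 0] == pytest.approx(2.0 + 1e-6)

    def test_constant_column_gets_ridge_variance(self):
        st = state_statistics(np.full((50, 2), 4.0), ["d1", "d2"])
        np.testing.assert_allclose(np.diag(st.sigma), 1e-6)

    def test_monte_carlo_mean_within_four_se(self):
        rng = np.random.default_rng(42)
        mu = np.array([3.0, 5.0, 7.0])
        cov = np.diag([0.5, 1.0, 2.0])
        x = rng.multivariate_normal(mu, cov, size=10_000)
        st = state_statistics(x, ["a", "b", "c"])
        se = np.sqrt(np.diag(cov) / 10_000)
        assert np.all(np.abs(st.mu - mu) < 4 * se)

    def test_single_frame_is_error(self):
        with pytest.raises(HLDAError):
            state_statistics(np.array([[1.0]]), ["d1"])


class TestHarmonicScatter:
    def test_1d_harmonic_mean(self):
        s = harmonic_scatter(np.array([[1.0]]), np.array([[3.0]]))
        assert s[0, 0] == pytest.approx(0.75)

    def test_equal_covariance_limit(self):
        sigma = np.array([[2.0, 0.3], [0.3, 1.0]])
        np.testing.assert_allclose(harmonic_scatter(sigma, sigma), sigma / 2)

    def test_diagonal_componentwise(self):
        s = harmonic_scatter(np.diag([1.0, 2.0]), np.diag([2.0, 2.0]))
        np.testing.assert_allclose(np.diag(s), [2 / 3, 1.0])
        assert abs(s[0, 1]) < 1e-12


def stats_from(mu, sigma, labels):
    from metacv.hlda import StateStatistics

    return StateStatistics(np.asarray(mu, float), np.asarray(sigma, float), 100, labels)


class TestDirection:
    def test_identity_scatter_normalized_mean_difference(self):
        a = stats_from([3.0, 4.0], np.eye(2), ["x", "y"])
        b = stats_from([0.0, 0.0], np.eye(2), ["x", "y"])
        m = hlda_direction(a, b, s_w=np.eye(2))
        np.testing.assert_allclose(m.w, [0.6, 0.8])

    def test_diagonal_solve(self):
        a = stats_from([2.0, 4.0], np.eye(2), ["x", "y"])
        b = stats_from([0.0, 0.0], np.eye(2), ["x", "y"])
        m = hlda_direction(a, b, s_w=np.diag([1.0, 4.0]))
        np.testing.assert_allclose(m.w, [2 / np.sqrt(5), 1 / np.sqrt(5)], atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_generalized_eigenproblem_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = 5
        qa, qb = rng.normal(size=(2, d, d))
        sigma_a = qa @ qa.T + 0.1 * np.eye(d)
        sigma_b = qb @ qb.T + 0.1 * np.eye(d)
        mu_a, mu_b = rng.normal(size=(2, d))
        labels = [f"d{i}" for i in range(d)]
        m = hlda_direction(stats_from(mu_a, sigma_a, labels),
                           stats_from(mu_b, sigma_b, labels))
        w_ref = rayleigh_direction(sigma_a, sigma_b, mu_a, mu_b)
        assert abs(m.w @ w_ref) >= 1 - 1e-8

    def test_identical_means_is_error(self):
        a = stats_from([1.0], [[1.0]], ["x"])
        with pytest.raises(HLDAError):
            hlda_direction(a, a)

    def test_state_swap_flips_sign_only(self):
        rng = np.random.default_rng(3)
        sigma = np.diag(rng.uniform(0.5, 2.0, 4))
        a = stats_from(rng.normal(size=4), sigma, list("wxyz"))
        b = stats_from(rng.normal(size=4), 2 * sigma, list("wxyz"))
        m_ab = hlda_direction(a, b)
        m_ba = hlda_direction(b, a)
        np.testing.assert_allclose(m_ab.w, -m_ba.w, atol=1e-12)

    def test_equal_covariance_reduces_to_classical_lda(self):
        rng = np.random.default_rng(4)
        q = rng.normal(size=(4, 4))
        sigma = q @ q.T + 0.5 * np.eye(4)
        mu_a, mu_b = rng.normal(size=(2, 4))
        m = hlda_direction(stats_from(mu_a, sigma, list("wxyz")),
                           stats_from(mu_b, sigma, list("wxyz")))
        lda = np.linalg.solve(sigma, mu_a - mu_b)
        lda /= np.linalg.norm(lda)
        assert abs(m.w @ lda) >= 1 - 1e-10

    def test_sign_convention_state_a_scores_higher(self):
        rng = np.random.default_rng(5)
        mu_a, mu_b = rng.normal(size=(2, 3))
        sigma = np.eye(3)
        m = hlda_direction(stats_from(mu_a, sigma, "abc"), stats_from(mu_b, sigma, "abc"))
        cv = LinearComboCV(make_pool(3), m.w)
        assert evaluate_cv(cv, descriptors=mu_a) > evaluate_cv(cv, descriptors=mu_b)


class TestEvaluate:
    def test_dot_product(self):
        cv = LinearComboCV(make_pool(2), np.array([0.6, 0.8]))
        assert evaluate_cv(cv, descriptors=[1.0, 1.0]) == pytest.approx(1.4)

    def test_com_distance_two_atoms(self):
        atoms = [
            AtomRecord(1, "CA", "C", "GLY", 1, "A", (0.0, 0.0, 0.0)),
            AtomRecord(2, "CA", "C", "GLY", 1, "B", (5.0, 0.0, 0.0)),
        ]
        s = Structure(atoms)
        cv = ComDistanceCV(Selection(chain_id="A"), Selection(chain_id="B"))
        assert evaluate_cv(cv, frame=s.coords(), topology=s) == pytest.approx(5.0)

    def test_dimension_mismatch_is_error(self):
        cv = LinearComboCV(make_pool(2), np.array([0.6, 0.8]))
        with pytest.raises(HLDAError):
            evaluate_cv(cv, descriptors=[1.0])


class TestRankAndSelect:
    def _model(self, weights, pool):
        from metacv.hlda import HLDAModel

        w = np.asarray(weights, float)
        return HLDAModel(np.eye(len(w)), w / np.linalg.norm(w), pool.labels)

    def test_top_k_renormalized(self):
        pool = make_pool(3)
        model = self._model([0.9, 0.3, 0.1], pool)
        cv = rank_and_select(model, pool, k=2)
        assert len(cv.contacts) == 2
        np.testing.assert_allclose(np.linalg.norm(cv.weights), 1.0)
        np.testing.assert_allclose(sorted(np.abs(cv.weights)), [0.316227766, 0.9486832981])

    def test_filter_precedes_ranking(self):
        pool = make_pool(3)
        model = self._model([0.9, 0.3, 0.1], pool)
        # keep only residues of contacts 2 and 3 (chains B..D)
        keep = {("B", 2), ("C", 2), ("D", 3)}
        cv = rank_and_select(model, pool, residue_filter=keep, k=2)
        assert pool.labels[0] not in cv.contacts.labels

    def test_tied_contributions_break_by_label(self):
        pool = make_pool(3)
        model = self._model([0.5, 0.5, 0.5], pool)
        cv = rank_and_select(model, pool, k=2)
        assert cv.contacts.labels == sorted(pool.labels)[:2]

    def test_too_few_survivors_warns_and_keeps_all(self):
        pool = make_pool(2)
        model = self._model([0.6, 0.8], pool)
        with pytest.warns(UserWarning, match="survive"):
            cv = rank_and_select(model, pool, k=5)
        assert len(cv.contacts) == 2

    def test_scale_equivariance_preserves_state_ordering(self):
        rng = np.random.default_rng(6)
        spec = TwoStateSpec(np.array([6.0, 9.0]), np.array([4.0, 7.0]),
                            np.eye(2) * 0.3, np.eye(2) * 0.5, n=2000, seed=8)
        xa, xb, _ = gen_two_state_descriptors(spec)
        scale = np.array([3.0, 1.0])
        labels = ["d1", "d2"]
        m1 = hlda_direction(state_statistics(xa, labels), state_statistics(xb, labels))
        m2 = hlda_direction(state_statistics(xa * scale, labels),
                            state_statistics(xb * scale, labels))
        assert (xa @ m1.w).mean() > (xb @ m1.w).mean()
        assert ((xa * scale) @ m2.w).mean() > ((xb * scale) @ m2.w).mean()


class TestSeparation:
    def test_six_sigma_separation_has_zero_overlap(self):
        dim, sep = 3, 6.0
        spec = TwoStateSpec(np.full(dim, 5.0 + sep), np.full(dim, 5.0),
                            np.eye(dim), np.eye(dim), n=10_000, seed=11)
        xa, xb, _ = gen_two_state_descriptors(spec)
        labels = [f"d{i}" for i in range(dim)]
        m = hlda_direction(state_statistics(xa, labels), state_statistics(xb, labels))
        assert (xa @ m.w).min() > (xb @ m.w).max()


class TestExport:
    def _topology(self, pool):
        atoms = []
        serial = 1
        for c in pool:
            for chain, res, name in (c.atom_a, c.atom_b):
                atoms.append(AtomRecord(serial, name, name[0], "GLU" if name[0] == "O" else "LYS",
                                        res, chain, (float(serial), 0.0, 0.0)))
                serial += 1
        return Structure(atoms)

    def test_linear_combo_roundtrip(self):
        pool = make_pool(3)
        topo = self._topology(pool)
        cv = LinearComboCV(pool, np.array([0.6, -0.64, 0.48]))
        text = export_cv_text(cv, topo)
        assert text.count("DISTANCE") == 3 and "COMBINE" in text
        cv2 = parse_cv_text(text, topo)
        assert cv2.contacts.labels == cv.contacts.labels
        np.testing.assert_allclose(cv2.weights, cv.weights, atol=1e-6)

    def test_export_is_deterministic(self):
        pool = make_pool(2)
        topo = self._topology(pool)
        cv = LinearComboCV(pool, np.array([0.6, 0.8]))
        assert export_cv_text(cv, topo) == export_cv_text(cv, topo)

    def test_com_distance_layout(self):
        atoms = [
            AtomRecord(1, "CA", "C", "GLY", 1, "A", (0.0, 0.0, 0.0)),
            AtomRecord(2, "CA", "C", "GLY", 1, "B", (5.0, 0.0, 0.0)),
        ]
        topo = Structure(atoms)
        cv = ComDistanceCV(Selection(chain_id="A"), Selection(chain_id="B"))
        text = export_cv_text(cv, topo)
        assert text.count("COM ") == 2 and "DISTANCE ATOMS=ga,gb" in text


def test_model_table_sorted_by_contribution(tmp_path):
    from metacv.hlda import HLDAModel

    w = np.array([0.1, 0.7, -0.7029])
    w = w / np.linalg.norm(w)
    model = HLDAModel(np.eye(3), w, ["a", "b", "c"])
    path = tmp_path / "model.tsv"
    write_model(path, model)
    rows = path.read_text().splitlines()[1:]
    contribs = [float(r.split("\t")[2]) for r in rows]
    assert contribs == sorted(contribs, reverse=True)
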