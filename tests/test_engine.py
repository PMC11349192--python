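import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import sparse, special

from ivea.engine import (
    GammaQ,
    Hyperparameters,
    InferenceInput,
    compute_elbo,
    gamma_expectations,
    initialize_state,
    load_inference_input,
    run_inference,
    save_inference_input,
    save_state,
    update_q_k,
    update_q_oE,
    update_q_oP,
    update_q_v,
    update_q_w,
    update_rho,
)
from ivea.gig import gig_entropy, gig_expectations, gig_log_norm

import oracles


def _toy_input(t, c, xE=(40,), lE=(0.5,), xP=(200,), lP=(1.0,), s=(1.0,), lT=(2.0,)):
    n_g, n_r = len(t), len(xE)
    return InferenceInput(
        gene_ids=np.array([f"g{i}" for i in range(n_g)], dtype=object),
        element_ids=np.array([f"e{i}" for i in range(n_r)], dtype=object),
        t=np.array(t, dtype=int),
        lT=np.array(lT * n_g if len(lT) == 1 else lT, dtype=float),
        s=np.array(s * n_g if len(s) == 1 else s, dtype=float),
        xP=np.array(xP * n_g if len(xP) == 1 else xP, dtype=int),
        lP=np.array(lP * n_g if len(lP) == 1 else lP, dtype=float),
        xE=np.array(xE, dtype=int),
        lE=np.array(lE, dtype=float),
        C=sparse.csr_matrix(np.asarray(c, dtype=float)),
    )


class TestGammaExpectations:
    def test_mean(self):
        assert gamma_expectations(GammaQ(2.0, 4.0))["mean"] == pytest.approx(0.5)

    def test_mean_log_euler_mascheroni(self):
        got = gamma_expectations(GammaQ(1.0, 1.0))["mean_log"]
        assert got == pytest.approx(-0.5772156649015329, abs=1e-12)
        want = oracles.gamma_quadrature_expectations(1.0, 1.0, math.log)
        assert got == pytest.approx(want, rel=1e-8)

    def test_jensen_strict(self):
        for a in (0.3, 1.0, 7.0, 150.0):
            e = gamma_expectations(GammaQ(a, 2.0))
            assert e["mean_log"] < np.log(e["mean"])

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            gamma_expectations(GammaQ(0.0, 1.0))


class TestRho:
    def test_symmetric_case(self):
        inp = _toy_input([10], [[1.0, 1.0]], xE=(5, 5), lE=(0.5, 0.5))
        st = initialize_state(inp, Hyperparameters())
        st.expect["ln_w"] = np.zeros(2)
        update_rho(st, inp)
        assert st.rho == pytest.approx([0.5, 0.5])

    def test_proportional_to_contact(self):
        inp = _toy_input([10], [[2.0, 1.0]], xE=(5, 5), lE=(0.5, 0.5))
        st = initialize_state(inp, Hyperparameters())
        st.expect["ln_w"] = np.zeros(2)
        update_rho(st, inp)
        assert st.rho == pytest.approx([2 / 3, 1 / 3])

    def test_rows_sum_to_one(self, medium_input, medium_state):
        indptr = medium_input.C.indptr
        sums = np.add.reduceat(medium_state.rho, indptr[:-1])
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_empty_row_rejected_at_input(self):
        with pytest.raises(ValueError, match="empty contact row"):
            _toy_input([10, 5], [[1.0, 1.0], [0.0, 0.0]], xE=(5, 5), lE=(0.5, 0.5))

    def test_logsumexp_stability(self):
        inp = _toy_input([10], [[1.0, 1.0]], xE=(5, 5), lE=(0.5, 0.5))
        st = initialize_state(inp, Hyperparameters())
        st.expect["ln_w"] = np.array([690.0, 690.0 - np.log(3.0)])
        update_rho(st, inp)
        assert np.isfinite(st.rho).all()
        assert st.rho == pytest.approx([0.75, 0.25])


class TestUpdateArithmetic:
    hyper = Hyperparameters()

    def _state(self, inp, hyper=None):
        st = initialize_state(inp, hyper or self.hyper)
        update_rho(st, inp)
        return st

    def test_qv_shape(self):
        inp = _toy_input([100], [[1.0]])
        st = self._state(inp)
        update_q_v(st, inp, self.hyper)
        assert float(st.qv.a[0]) == pytest.approx(180.0)  # alpha_v + t

    def test_qv_shape_zero_count(self):
        inp = _toy_input([0], [[1.0]])
        st = self._state(inp)
        update_q_v(st, inp, self.hyper)
        assert float(st.qv.a[0]) == pytest.approx(80.0)

    def test_qv_rate_linear_in_contacts(self):
        inp1 = _toy_input([10], [[1.0]])
        inp2 = _toy_input([10], [[2.0]])
        st1, st2 = self._state(inp1), self._state(inp2)
        st2.expect = {k: (np.copy(v) if isinstance(v, np.ndarray) else v) for k, v in st1.expect.items()}
        update_q_v(st1, inp1, self.hyper)
        update_q_v(st2, inp2, self.hyper)
        prior_term = (self.hyper.alpha_v / inp1.s) * st1.expect["inv_oP"]
        data1 = float(st1.qv.b[0]) - float(prior_term[0])
        data2 = float(st2.qv.b[0]) - float(prior_term[0])
        assert data2 == pytest.approx(2 * data1)

    def test_qw_shape_single_gene(self):
        inp = _toy_input([50], [[1.0]])
        st = self._state(inp)
        update_q_w(st, inp, self.hyper)
        assert float(st.qw.a[0]) == pytest.approx(60.0)  # alpha_w + t * rho(=1)

    def test_qw_uncontacted_element_pure_prior(self):
        inp = _toy_input([50], [[1.0, 0.0]], xE=(5, 7), lE=(0.5, 2.0))
        st = self._state(inp)
        update_q_w(st, inp, self.hyper)
        assert st.qw.a[1] == pytest.approx(self.hyper.alpha_w)
        want = (self.hyper.alpha_w / inp.lE[1]) * st.expect["inv_oE"][1]
        assert st.qw.b[1] == pytest.approx(want)

    def test_qw_no_lE_prior_term(self):
        hyper = Hyperparameters(variant="no_lE")
        inp = _toy_input([50], [[1.0]], lE=(2.0,))
        st = self._state(inp, hyper)
        inv_oE = np.copy(st.expect["inv_oE"])
        k = st.expect["k"]
        cross = inp.C.T @ (inp.lT * st.expect["v"])
        update_q_w(st, inp, hyper)
        assert st.qw.b[0] == pytest.approx(
            float(hyper.alpha_w * inv_oE[0] + k * cross[0])
        )  # no division by lE

    def test_qoP_parameters(self):
        hyper = Hyperparameters(alpha_o=1.0, beta_o=1e-3)
        inp = _toy_input([10], [[1.0]], xP=(200,), lP=(1.0,))
        st = self._state(inp, hyper)
        e_v = np.copy(st.expect["v"])
        update_q_oP(st, inp, hyper)
        assert st.qoP.lam[0] == pytest.approx(1.0 - 80.0 + 200)  # = 121
        assert st.qoP.chi[0] == pytest.approx(2 * 80.0 * e_v[0] / inp.s[0])
        assert st.qoP.chi[0] > 0
        assert st.qoP.psi[0] == pytest.approx(2.002)

    def test_qoE_parameters_and_negative_lam(self):
        hyper = Hyperparameters(alpha_o=1.0, alpha_w=10.0)
        inp = _toy_input([10], [[1.0]], xE=(0,), lE=(0.5,))
        st = self._state(inp, hyper)
        e_w = np.copy(st.expect["w"])
        update_q_oE(st, inp, hyper)
        assert st.qoE.lam[0] == pytest.approx(-9.0)
        assert st.qoE.chi[0] == pytest.approx(2 * 10.0 * e_w[0] / 0.5)

    def test_qoE_no_lE_chi(self):
        std = Hyperparameters()
        nolE = Hyperparameters(variant="no_lE")
        inp = _toy_input([10], [[1.0]], xE=(5,), lE=(0.5,))
        st1, st2 = self._state(inp, std), self._state(inp, nolE)
        st2.expect["w"] = np.copy(st1.expect["w"])
        update_q_oE(st1, inp, std)
        update_q_oE(st2, inp, nolE)
        # with lE=0.5 the standard chi (divided by lE) is twice the no_lE chi
        assert st1.qoE.chi[0] == pytest.approx(2 * st2.qoE.chi[0])
        # psi keeps the observation-model lE in both variants
        assert st1.qoE.psi[0] == pytest.approx(st2.qoE.psi[0])

    def test_qoE_psi_monotone_in_lE(self):
        hyper = Hyperparameters()
        psis = []
        for le in (0.3, 0.8, 2.0):
            inp = _toy_input([10], [[1.0]], lE=(le,))
            st = self._state(inp, hyper)
            update_q_oE(st, inp, hyper)
            psis.append(float(st.qoE.psi[0]))
        assert psis == sorted(psis)

    def test_qk_shape_and_invariance(self):
        hyper = Hyperparameters(alpha_k=1.0)
        inp = _toy_input([10, 0, 5], [[1.0], [1.0], [1.0]], xE=(5,), lE=(0.5,))
        st = run_inference(inp, hyper, max_iter=7, track_elbo=False)
        assert float(st.qk.a) == pytest.approx(16.0)  # alpha_k + sum t, every sweep

    def test_k_inversely_scales_with_contacts(self):
        hyper = Hyperparameters(beta_k=1e-9)
        inp = _toy_input([500, 300], [[1.0, 0.5], [0.2, 2.0]], xE=(40, 60), lE=(0.5, 1.0))
        st1 = run_inference(inp, hyper, track_elbo=False)
        st2 = run_inference(replace(inp, C=inp.C * 10.0), hyper, track_elbo=False)
        assert st2.expect["k"] == pytest.approx(st1.expect["k"] / 10.0, rel=1e-3)


class TestPosteriorIdentities:
    def test_identities_every_iteration(self, medium_input):
        hyper = Hyperparameters()
        st = initialize_state(medium_input, hyper)
        t = medium_input.t
        for _ in range(25):
            update_rho(st, medium_input)
            update_q_w(st, medium_input, hyper)
            update_q_v(st, medium_input, hyper)
            update_q_oE(st, medium_input, hyper)
            update_q_oP(st, medium_input, hyper)
            update_q_k(st, medium_input, hyper)
            assert np.array_equal(st.qv.a, hyper.alpha_v + t)
            assert float(st.qk.a) == hyper.alpha_k + t.sum()
            assert np.sum(st.qw.a - hyper.alpha_w) == pytest.approx(t.sum(), rel=1e-12)
            sums = np.add.reduceat(st.rho, medium_input.C.indptr[:-1])
            assert np.allclose(sums, 1.0, atol=1e-10)


class TestElbo:
    def test_monotone_on_fixtures(self, tiny_input, degenerate_input, medium_input):
        for inp in (tiny_input, degenerate_input, medium_input):
            st = run_inference(inp, max_iter=60)
            elbo = np.array(st.elbo_trace)
            assert np.all(np.diff(elbo) >= -1e-8 * np.abs(elbo[:-1]))

    def test_rho_perturbation_lowers_bound(self, tiny_input):
        hyper = Hyperparameters()
        st = run_inference(tiny_input, hyper, max_iter=20)
        base = compute_elbo(st, tiny_input, hyper)
        rng = np.random.default_rng(0)
        rho = st.rho.copy()
        noise = rng.uniform(0.5, 2.0, rho.size)
        perturbed = rho * noise
        sums = np.add.reduceat(perturbed, tiny_input.C.indptr[:-1])
        row = tiny_input.row_index()
        st.rho = perturbed / sums[row]
        assert compute_elbo(st, tiny_input, hyper) < base
        st.rho = rho

    def test_matches_quadrature_on_single_pair_toy(self):
        # 1 gene x 1 enhancer: recompute every q(v)/q(w)-dependent expectation
        # and entropy by numerical quadrature and reassemble the bound.
        hyper = Hyperparameters()
        inp = _toy_input([120], [[0.8]], xE=(30,), lE=(0.6,), xP=(90,), lP=(0.9,), s=(1.3,))
        st = run_inference(inp, hyper)
        got = compute_elbo(st, inp, hyper)

        q = oracles.gamma_quadrature_expectations
        av, bv = float(st.qv.a[0]), float(st.qv.b[0])
        aw, bw = float(st.qw.a[0]), float(st.qw.b[0])
        Ev, Elnv = q(av, bv, lambda x: x), q(av, bv, math.log)
        Ew, Elnw = q(aw, bw, lambda x: x), q(aw, bw, math.log)
        Hv = q(av, bv, lambda x: -(av * math.log(bv) - special.gammaln(av)
                                   + (av - 1) * math.log(x) - bv * x))
        Hw = q(aw, bw, lambda x: -(aw * math.log(bw) - special.gammaln(aw)
                                   + (aw - 1) * math.log(x) - bw * x))
        ex = st.expect
        t, lT, s, xP, lP = (float(inp.t[0]), float(inp.lT[0]), float(inp.s[0]),
                            float(inp.xP[0]), float(inp.lP[0]))
        xE, lE, c = float(inp.xE[0]), float(inp.lE[0]), float(inp.C.data[0])
        ao, bo, ak, bk = hyper.alpha_o, hyper.beta_o, hyper.alpha_k, hyper.beta_k
        alv, alw = hyper.alpha_v, hyper.alpha_w
        e_k, e_lnk = ex["k"], ex["ln_k"]
        oP, ioP, lnoP = float(ex["oP"][0]), float(ex["inv_oP"][0]), float(ex["ln_oP"][0])
        oE, ioE, lnoE = float(ex["oE"][0]), float(ex["inv_oE"][0]), float(ex["ln_oE"][0])
        want = (
            t * (math.log(lT) + e_lnk + Elnv + math.log(c) + Elnw)
            - lT * e_k * Ev * c * Ew
            + xP * (math.log(lP) + lnoP) - lP * oP
            + xE * (math.log(lE) + lnoE) - lE * oE
            + alv * math.log(alv / s) - special.gammaln(alv) - alv * lnoP
            + (alv - 1) * Elnv - (alv / s) * ioP * Ev
            + alw * math.log(alw / lE) - special.gammaln(alw) - alw * lnoE
            + (alw - 1) * Elnw - (alw / lE) * ioE * Ew
            + ao * math.log(bo) - special.gammaln(ao) + (ao - 1) * lnoP - bo * oP
            + ao * math.log(bo) - special.gammaln(ao) + (ao - 1) * lnoE - bo * oE
            + ak * math.log(bk) - special.gammaln(ak) + (ak - 1) * e_lnk - bk * e_k
            + Hv + Hw
            + float(st.qk.a) - math.log(float(st.qk.b)) + special.gammaln(float(st.qk.a))
            + (1 - float(st.qk.a)) * special.digamma(float(st.qk.a))
            + float(gig_entropy(st.qoP.lam, st.qoP.chi, st.qoP.psi)[0])
            + float(gig_entropy(st.qoE.lam, st.qoE.chi, st.qoE.psi)[0])
        )
        assert got == pytest.approx(want, rel=1e-4)

    def test_nonfinite_term_reports_name(self, tiny_input):
        hyper = Hyperparameters()
        st = run_inference(tiny_input, hyper, max_iter=5)
        st.expect["v"] = st.expect["v"] * np.inf
        with pytest.raises(FloatingPointError, match="lik_t|prior_v"):
            compute_elbo(st, tiny_input, hyper)


class TestRunInference:
    def test_deterministic(self, tiny_input):
        st1 = run_inference(tiny_input)
        st2 = run_inference(tiny_input)
        assert np.array_equal(st1.expect["w"], st2.expect["w"])
        assert np.array_equal(st1.rho, st2.rho)
        assert st1.elbo_trace == st2.elbo_trace

    def test_fixed_point_consistency(self, medium_input, medium_state):
        assert medium_state.converged
        hyper = Hyperparameters()
        st = medium_state
        w_before = np.copy(st.expect["w"])
        update_rho(st, medium_input)
        update_q_w(st, medium_input, hyper)
        rel = np.abs(st.expect["w"] - w_before) / np.maximum(w_before, 1e-12)
        assert float(rel.max()) < 5e-3

    def test_converges_before_max_iter(self, medium_state):
        assert medium_state.converged
        assert medium_state.iteration < 500
        assert medium_state.delta_trace[-1] < 5e-3

    def test_exchangeability_under_element_permutation(self, tiny_input):
        st1 = run_inference(tiny_input, track_elbo=False)
        perm = np.array([3, 1, 4, 0, 2])
        C = sparse.csr_matrix(tiny_input.C.toarray()[:, perm])
        permuted = replace(
            tiny_input,
            element_ids=tiny_input.element_ids[perm],
            xE=tiny_input.xE[perm],
            lE=tiny_input.lE[perm],
            C=C,
        )
        st2 = run_inference(permuted, track_elbo=False)
        assert st2.expect["w"] == pytest.approx(st1.expect["w"][perm], rel=1e-9)
        assert st2.expect["v"] == pytest.approx(st1.expect["v"], rel=1e-9)

    def test_zero_count_gene_supported(self):
        inp = _toy_input([0, 40], [[1.0, 0.5], [0.3, 1.0]], xE=(5, 5), lE=(0.5, 0.5))
        st = run_inference(inp)
        assert np.isfinite(st.expect["v"]).all()
        assert float(st.qv.a[0]) == pytest.approx(80.0)


class TestSerialization:
    def test_input_roundtrip(self, tmp_path, tiny_input):
        save_inference_input(tiny_input, tmp_path)
        back = load_inference_input(tmp_path)
        assert list(back.gene_ids) == list(tiny_input.gene_ids)
        assert np.array_equal(back.t, tiny_input.t)
        assert np.allclose(back.C.toarray(), tiny_input.C.toarray())

    def test_state_dump_bitwise_deterministic(self, tmp_path, tiny_input):
        hyper = Hyperparameters()
        for d in ("a", "b"):
            st = run_inference(tiny_input, hyper)
            save_state(st, tiny_input, tmp_path / d, hyper=hyper)
        for name in ("q_v.tsv", "q_w.tsv", "q_oP.tsv", "q_oE.tsv", "q_k.tsv", "run.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
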