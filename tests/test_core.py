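import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pvrnn_mw import core
from conftest import zero_params


# ---------------------------------------------------------------------------
# single-step dynamics
# ---------------------------------------------------------------------------

def test_forward_step_leaky_decay():
    # zero drive, tau=2: internal state halves each step
    specs = [core.LayerSpec(3, 0, 2.0, 0.0)]
    p = zero_params(specs)
    fr = core.initial_frame(specs)
    fr.h[0][:] = [1.0, -2.0, 0.5]
    fr.d[0][:] = np.tanh(fr.h[0])
    nxt = core.forward_step(fr, "prior", p, rng=np.random.default_rng(0))
    assert np.allclose(nxt.h[0], [0.5, -1.0, 0.25])
    assert np.allclose(nxt.d[0], np.tanh(nxt.h[0]))


def test_forward_step_tau_one_bias_only():
    specs = [core.LayerSpec(2, 0, 1.0, 0.0)]
    p = zero_params(specs)
    p.bh[0, :2] = 0.7
    fr = core.initial_frame(specs)
    fr.h[0][:] = [3.0, -3.0]
    fr.d[0][:] = np.tanh(fr.h[0])
    for _ in range(3):
        fr = core.forward_step(fr, "prior", p, rng=np.random.default_rng(0))
        assert np.allclose(fr.h[0], 0.7)


def test_forward_step_matches_scalar_arithmetic():
    # independent hand evaluation for a 1-layer, n_d=2, n_z=1 network
    specs = [core.LayerSpec(2, 1, 2.0, 0.1)]
    p = core.init_params(specs, seed=3)
    rng = np.random.default_rng(4)
    p.bh += 0.2 * rng.standard_normal(p.bh.shape)
    p.bmup += 0.1; p.bsigp -= 0.2
    fr = core.initial_frame(specs)
    fr.h[0][:] = [0.3, -0.4]
    fr.d[0][:] = np.tanh(fr.h[0])
    eps = [np.array([0.37])]
    nxt = core.forward_step(fr, "prior", p, eps=eps)

    d0, d1 = math.tanh(0.3), math.tanh(-0.4)
    mu = math.tanh(p.Wmu[0, 0, 0] * d0 + p.Wmu[0, 0, 1] * d1 + p.bmup[0, 0])
    sg = math.exp(p.Wsig[0, 0, 0] * d0 + p.Wsig[0, 0, 1] * d1 + p.bsigp[0, 0])
    z = mu + sg * 0.37
    for i in range(2):
        u = (p.Wdd[0, i, 0] * d0 + p.Wdd[0, i, 1] * d1
             + p.Wzd[0, i, 0] * z + p.bh[0, i])
        h = 0.5 * fr.h[0][i] + 0.5 * u
        assert abs(nxt.h[0][i] - h) < 1e-12
    xb = core.readout(nxt.d[0], p)
    for o in range(2):
        v = math.tanh(p.Wout[o, 0] * nxt.d[0][0] + p.Wout[o, 1] * nxt.d[0][1] + p.bout[o])
        assert abs(xb[o] - v) < 1e-12


def test_prior_and_posterior_heads():
    specs = [core.LayerSpec(3, 2, 1.0, 0.0)]
    p = zero_params(specs)
    mu, sg = core.compute_prior(np.zeros(3), p, 0)
    assert np.allclose(mu, 0.0) and np.allclose(sg, 1.0)
    p.bsigp[0, :2] = math.log(2.0)
    _, sg = core.compute_prior(np.zeros(3), p, 0)
    assert np.allclose(sg, 2.0)
    # posterior with zero A and equal biases reduces to the prior
    p2 = core.init_params(specs, seed=8)
    d_prev = np.random.default_rng(1).uniform(-1, 1, 3)
    A0 = (np.zeros(2), np.zeros(2))
    mp, sp = core.compute_prior(d_prev, p2, 0)
    mq, sq = core.compute_posterior(d_prev, A0, p2, 0)
    assert np.allclose(mp, mq) and np.allclose(sp, sq)
    with pytest.raises(core.ContractError):
        core.compute_posterior(d_prev, None, p2, 0)
    # mu bounded by tanh even for large drive (saturates toward +-1)
    mu, _ = core.compute_prior(5 * d_prev, p2, 0)
    assert np.all(np.abs(mu) < 1.0)


def test_sample_z_clt_and_determinism():
    mu = np.array([0.3, -1.0])
    sg = np.array([0.5, 2.0])
    rng = np.random.default_rng(0)
    draws = np.stack([core.sample_z(mu, sg, rng=rng) for _ in range(10_000)])
    se = sg / np.sqrt(10_000)
    assert np.all(np.abs(draws.mean(axis=0) - mu) < 4 * se)
    a = core.sample_z(mu, sg, rng=np.random.default_rng(3))
    b = core.sample_z(mu, sg, rng=np.random.default_rng(3))
    assert np.array_equal(a, b)
    assert np.allclose(core.sample_z(mu, np.full(2, 1e-12), rng=rng), mu, atol=1e-10)
    with pytest.raises(core.ContractError):
        core.sample_z(mu, np.array([1.0, 0.0]), rng=rng)


# ---------------------------------------------------------------------------
# KL and free energy
# ---------------------------------------------------------------------------

def test_kl_unit_analytic_values():
    assert core.kl_unit(0.3, 0.7, 0.3, 0.7) == pytest.approx(0.0, abs=1e-15)
    assert core.kl_unit(1.0, 1.0, 0.0, 1.0) == pytest.approx(0.5)
    with pytest.raises(core.ContractError):
        core.kl_unit(0.0, -1.0, 0.0, 1.0)


def test_kl_unit_against_monte_carlo():
    rng = np.random.default_rng(12)
    for _ in range(10):
        mq, mp = rng.uniform(-1, 1, 2)
        sq, sp = rng.uniform(0.3, 2.0, 2)
        x = rng.normal(mq, sq, 200_000)
        logq = -0.5 * ((x - mq) / sq) ** 2 - np.log(sq)
        logp = -0.5 * ((x - mp) / sp) ** 2 - np.log(sp)
        samples = logq - logp
        mc = samples.mean()
        se = samples.std(ddof=1) / np.sqrt(samples.size)
        assert abs(core.kl_unit(mq, sq, mp, sp) - mc) < 4 * se


@given(st.floats(-3, 3), st.floats(-3, 3),
       st.floats(0.05, 5), st.floats(0.05, 5))
def test_kl_unit_nonnegative(mq, mp, sq, sp):
    assert core.kl_unit(mq, sq, mp, sp) >= -1e-12


def test_free_energy_vanishes_when_matched():
    specs = [core.LayerSpec(3, 2, 2.0, 1.0)]
    p = zero_params(specs)  # Xbar == 0 everywhere
    frames = []
    fr = core.initial_frame(specs)
    for t in range(4):
        A0 = [(np.zeros(2), np.zeros(2))]
        fr = core.forward_step(fr, "posterior", p, A_t=A0,
                               eps=[np.zeros(2)], first_step=(t == 0))
        frames.append(fr)
    fe = core.free_energy(frames, np.zeros((4, 2)), p)
    assert fe.total == pytest.approx(0.0, abs=1e-14)
    assert fe.accuracy == pytest.approx(0.0, abs=1e-14)


def test_free_energy_weight_scaling(tiny_params, random_posterior_problem):
    Amu, Asig, eps, targets = random_posterior_problem
    cache = core.unroll(tiny_params, 7, 3, Amu=Amu, Asig=Asig, eps=eps)
    fe1 = core.free_energy_from_cache(cache, targets, tiny_params, w=[0.5, 0.2])
    fe2 = core.free_energy_from_cache(cache, targets, tiny_params, w=[1.0, 0.4])
    fe0 = core.free_energy_from_cache(cache, targets, tiny_params, w=[0.0, 0.0])
    assert fe0.total == pytest.approx(fe0.accuracy / 2)
    # doubling both w doubles exactly the complexity share
    assert fe2.total - fe0.total == pytest.approx(2 * (fe1.total - fe0.total))


def test_free_energy_matches_independent_scalar_recomputation(tiny_params, tiny_specs,
                                                              random_posterior_problem):
    """From-scratch pure-python evaluation of the full objective on a
    fixed tiny net, compared at 1e-10."""
    Amu, Asig, eps, targets = random_posterior_problem
    T, B = 7, 3
    p = tiny_params
    total_ref = 0.0
    for b in range(B):
        h = {l: [0.0] * s.n_d for l, s in enumerate(tiny_specs)}
        d = {l: [0.0] * s.n_d for l, s in enumerate(tiny_specs)}
        acc = 0.0
        comp = [0.0, 0.0]
        for t in range(T):
            zs = {}
            kls = {}
            for l, s in enumerate(tiny_specs):
                z_l = []
                for r in range(s.n_z):
                    ap = p.bmup[l, r]; sp = p.bsigp[l, r]
                    aq = p.bmuq[l, r] + Amu[t, l, r, b]
                    sq = p.bsigq[l, r] + Asig[t, l, r, b]
                    for j in range(s.n_d):
                        ap += p.Wmu[l, r, j] * d[l][j]
                        sp += p.Wsig[l, r, j] * d[l][j]
                        aq += p.Wmuq[l, r, j] * d[l][j]
                        sq += p.Wsigq[l, r, j] * d[l][j]
                    mup, sigp = math.tanh(ap), math.exp(min(max(sp, -10), 10))
                    if t == 0:
                        mup, sigp = 0.0, 1.0
                    muq, sigq = math.tanh(aq), math.exp(min(max(sq, -10), 10))
                    z_l.append(muq + sigq * eps[t, l, r, b])
                    kls[(l, r)] = (math.log(sigp / sigq)
                                   + ((muq - mup) ** 2 + sigq ** 2) / (2 * sigp ** 2) - 0.5)
                zs[l] = z_l
            newh = {}
            for l, s in enumerate(tiny_specs):
                al = 1.0 / s.tau
                newh[l] = []
                for i in range(s.n_d):
                    u = p.bh[l, i]
                    for j in range(s.n_d):
                        u += p.Wdd[l, i, j] * d[l][j]
                    for r in range(s.n_z):
                        u += p.Wzd[l, i, r] * zs[l][r]
                    if l + 1 < len(tiny_specs):
                        for j in range(tiny_specs[l + 1].n_d):
                            u += p.Wtd[l, i, j] * d[l + 1][j]
                    if l > 0:
                        for j in range(tiny_specs[l - 1].n_d):
                            u += p.Wbu[l, i, j] * d[l - 1][j]
                    newh[l].append((1 - al) * h[l][i] + al * u)
            h = newh
            d = {l: [math.tanh(v) for v in h[l]] for l in h}
            for (l, r), v in kls.items():
                comp[l] += v
            for o in range(2):
                xb = p.bout[o]
                for j in range(tiny_specs[0].n_d):
                    xb += p.Wout[o, j] * d[0][j]
                acc += (targets[t, o, b] - math.tanh(xb)) ** 2
        total_ref += (acc / 2
                      + sum(s.w / s.n_z * comp[l] for l, s in enumerate(tiny_specs)))
    total_ref /= B
    cache = core.unroll(p, T, B, Amu=Amu, Asig=Asig, eps=eps)
    fe = core.free_energy_from_cache(cache, targets, p)
    assert fe.total == pytest.approx(total_ref, abs=1e-10)


# ---------------------------------------------------------------------------
# kernel/reference equivalence, bounds, gradients
# ---------------------------------------------------------------------------

def test_kernel_matches_stepwise_reference(tiny_params, tiny_specs,
                                           random_posterior_problem):
    Amu, Asig, eps, targets = random_posterior_problem
    T, B = 7, 3
    cache = core.unroll(tiny_params, T, B, Amu=Amu, Asig=Asig, eps=eps)
    for b in range(B):
        fr = core.initial_frame(tiny_specs)
        for t in range(T):
            A_t = [(Amu[t, l, :s.n_z, b], Asig[t, l, :s.n_z, b])
                   for l, s in enumerate(tiny_specs)]
            e_t = [eps[t, l, :s.n_z, b] for l, s in enumerate(tiny_specs)]
            fr = core.forward_step(fr, "posterior", tiny_params, A_t=A_t,
                                   eps=e_t, first_step=(t == 0))
            for l, s in enumerate(tiny_specs):
                assert np.allclose(fr.h[l], cache.h[t + 1, l, :s.n_d, b], atol=1e-12)
                assert np.allclose(fr.muq[l], cache.muq[t, l, :s.n_z, b], atol=1e-12)
                assert np.allclose(fr.sigp[l], cache.sigp[t, l, :s.n_z, b], atol=1e-12)
            assert np.allclose(core.readout(fr.d[0], tiny_params),
                               cache.xbar[t, :, b], atol=1e-12)
            assert np.all(np.abs(fr.d[0]) < 1.0)
            assert np.all(np.abs(cache.xbar[t, :, b]) < 1.0)


def test_gradients_match_finite_differences(tiny_params, random_posterior_problem):
    Amu, Asig, eps, targets = random_posterior_problem
    T, B = 7, 3
    cache = core.unroll(tiny_params, T, B, Amu=Amu, Asig=Asig, eps=eps)
    g = core.backward(tiny_params, cache, targets)

    def objective():
        c = core.unroll(tiny_params, T, B, Amu=Amu, Asig=Asig, eps=eps)
        return core.free_energy_from_cache(c, targets, tiny_params).total

    rng = np.random.default_rng(0)
    h = 1e-6
    worst = 0.0
    for name in ("Wdd", "Wzd", "Wtd", "Wbu", "bh", "Wmu", "Wsig",
                 "bmup", "bsigp", "bmuq", "bsigq", "Wout", "bout"):
        arr = getattr(tiny_params, name)
        for _ in range(4):
            idx = tuple(rng.integers(s) for s in arr.shape)
            orig = arr[idx]
            arr[idx] = orig + h
            fp = objective()
            arr[idx] = orig - h
            fm = objective()
            arr[idx] = orig
            fd = (fp - fm) / (2 * h)
            an = g[name][idx]
            if abs(fd) > 1e-9 or abs(an) > 1e-9:
                worst = max(worst, abs(fd - an) / max(abs(fd), abs(an)))
    assert worst < 1e-4


def test_checkpoint_roundtrip(tmp_path, tiny_params):
    path = tmp_path / "model.npz"
    core.save_checkpoint(path, tiny_params, extra={"epoch": 3})
    back, extra = core.load_checkpoint(path)
    assert int(extra["epoch"]) == 3
    for name, arr in tiny_params.trainable().items():
        assert np.array_equal(arr, getattr(back, name))
    assert back.tied_heads and back.Wmuq is back.Wmu


def test_larger_w_tightens_posterior_to_prior(tiny_params, tiny_specs):
    """Minimizing free energy over A at high w must end with KL no
    larger, and reconstruction error no smaller, than at low w."""
    from pvrnn_mw.training import Adam
    T = 12
    nzm = tiny_params.Wzd.shape[2]
    rng = np.random.default_rng(3)
    targets = rng.uniform(-0.7, 0.7, size=(T, 2, 1))
    eps = np.zeros((T, 2, nzm, 1))  # deterministic objective

    results = {}
    for wval in (0.01, 100.0):
        Amu = np.zeros((T, 2, nzm, 1))
        Asig = np.zeros((T, 2, nzm, 1))
        opt = Adam({"Amu": Amu, "Asig": Asig}, lr=0.05)
        w = [wval, wval]
        for _ in range(400):
            cache = core.unroll(tiny_params, T, 1, Amu=Amu, Asig=Asig, eps=eps)
            g = core.backward(tiny_params, cache, targets, w=w)
            opt.step({"Amu": Amu, "Asig": Asig}, {"Amu": g["Amu"], "Asig": g["Asig"]})
        cache = core.unroll(tiny_params, T, 1, Amu=Amu, Asig=Asig, eps=eps)
        fe = core.free_energy_from_cache(cache, targets, tiny_params, w=w)
        results[wval] = (fe.complexity_per_layer.sum(), fe.accuracy)
    kl_low, err_low = results[0.01]
    kl_high, err_high = results[100.0]
    assert kl_high <= kl_low
    assert err_high >= err_low
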