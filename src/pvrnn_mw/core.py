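"""Hierarchical variational RNN: dynamics, Gaussian latents, free energy.

The network stacks ``L`` recurrent layers.  Each layer ``l`` carries
deterministic units ``d = tanh(h)`` updated with leaky-integrator dynamics
under a time constant ``tau``, plus Gaussian stochastic units ``z``.  A
prior head maps the previous ``d`` to (mu_p, sigma_p); the approximate
posterior adds per-step adaptive variables (A_mu, A_sigma) before the same
nonlinearities.  The bottom layer's ``d`` is read out through a tanh-affine
map into sensory space.

The training/inference objective is a normalized free energy:

    F = sum_t sum_l (w_l / R_z^l) * KL[q || p]_(t,l)  +  (1/R_X) sum_t ||X_t - Xbar_t||^2

where ``w_l`` is the per-layer meta-prior weighting the complexity
(KL) term against the accuracy (squared reconstruction error) term.

Two equivalent computational routes are provided: a readable per-step
reference API (``forward_step`` and friends, used for validation) and
numba-compiled sequence kernels with a hand-derived backward pass
(used by training and online inference).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

__all__ = [
    "LayerSpec",
    "NetworkParams",
    "LatentFrame",
    "FreeEnergyBreakdown",
    "init_params",
    "initial_frame",
    "forward_step",
    "compute_prior",
    "compute_posterior",
    "sample_z",
    "readout",
    "kl_unit",
    "free_energy",
    "unroll",
    "free_energy_from_cache",
    "backward",
    "save_checkpoint",
    "load_checkpoint",
]

#: clamp for the pre-exp log-sigma activations; keeps sigma in
#: [e^-10, e^10] and avoids overflow in early training
SIG_CLIP = 10.0


class ContractError(ValueError):
    """An operation was called outside its domain contract."""


class StructuralError(ValueError):
    """Shapes or layer wiring are inconsistent."""


@dataclass(frozen=True)
class LayerSpec:
    """Per-layer sizes and constants: deterministic units ``n_d``,
    stochastic units ``n_z``, integration time constant ``tau`` (>= 1)
    and meta-prior weight ``w`` (>= 0)."""

    n_d: int
    n_z: int
    tau: float
    w: float

    def __post_init__(self):
        if self.n_d < 1:
            raise StructuralError("n_d must be >= 1")
        if self.n_z < 0:
            raise StructuralError("n_z must be >= 0")
        if self.tau < 1:
            raise StructuralError("tau must be >= 1")
        if self.w < 0:
            raise StructuralError("w must be >= 0")


@dataclass
class NetworkParams:
    """All weights of the generative and inference models, padded to the
    maximal layer width so the compiled kernels can treat layers
    uniformly.  ``Wtd`` maps the upper neighbor's ``d`` down into a layer,
    ``Wbu`` the lower neighbor's ``d`` up; both are absent (zero, and
    never read) at the boundaries.  With ``tied_heads`` the posterior
    reuses the prior's input weights (``Wmuq is Wmu``) and differs only
    in its biases and adaptive variables."""

    nd: np.ndarray
    nz: np.ndarray
    tau: np.ndarray
    w: np.ndarray
    rx: int
    tied_heads: bool
    Wdd: np.ndarray
    Wzd: np.ndarray
    Wtd: np.ndarray
    Wbu: np.ndarray
    bh: np.ndarray
    Wmu: np.ndarray
    Wsig: np.ndarray
    Wmuq: np.ndarray
    Wsigq: np.ndarray
    bmup: np.ndarray
    bsigp: np.ndarray
    bmuq: np.ndarray
    bsigq: np.ndarray
    Wout: np.ndarray
    bout: np.ndarray

    @property
    def n_layers(self) -> int:
        return len(self.nd)

    @property
    def layer_specs(self) -> list[LayerSpec]:
        return [LayerSpec(int(self.nd[l]), int(self.nz[l]), float(self.tau[l]), float(self.w[l]))
                for l in range(self.n_layers)]

    def trainable(self) -> dict[str, np.ndarray]:
        """Named parameter tensors subject to gradient updates.  With tied
        heads the posterior input weights are aliases and are excluded."""
        names = ["Wdd", "Wzd", "Wtd", "Wbu", "bh", "Wmu", "Wsig",
                 "bmup", "bsigp", "bmuq", "bsigq", "Wout", "bout"]
        if not self.tied_heads:
            names += ["Wmuq", "Wsigq"]
        return {n: getattr(self, n) for n in names}

    def copy(self) -> "NetworkParams":
        kw = {}
        for f in self.__dataclass_fields__:
            v = getattr(self, f)
            kw[f] = v.copy() if isinstance(v, np.ndarray) else v
        p = NetworkParams(**kw)
        if p.tied_heads:
            p.Wmuq = p.Wmu
            p.Wsigq = p.Wsig
        return p


def _glorot(rng, n_out, n_in, m_out, m_in):
    """Glorot-uniform block of logical size (n_out, n_in) inside a zero
    pad of size (m_out, m_in)."""
    w = np.zeros((m_out, m_in))
    if n_out > 0 and n_in > 0:
        lim = np.sqrt(6.0 / (n_out + n_in))
        w[:n_out, :n_in] = rng.uniform(-lim, lim, size=(n_out, n_in))
    return w


def init_params(specs: Sequence[LayerSpec], rx: int = 2, seed: int = 0,
                tied_heads: bool = True) -> NetworkParams:
    """Seeded Glorot-uniform weights, zero biases; layer 0 is the bottom
    (sensory-adjacent) layer."""
    L = len(specs)
    if L < 1:
        raise StructuralError("need at least one layer")
    rng = np.random.default_rng(seed)
    nd = np.array([s.n_d for s in specs], dtype=np.int64)
    nz = np.array([s.n_z for s in specs], dtype=np.int64)
    tau = np.array([s.tau for s in specs], dtype=np.float64)
    w = np.array([s.w for s in specs], dtype=np.float64)
    ndm, nzm = int(nd.max()), int(max(nz.max(), 1))

    Wdd = np.stack([_glorot(rng, nd[l], nd[l], ndm, ndm) for l in range(L)])
    Wzd = np.stack([_glorot(rng, nd[l], nz[l], ndm, nzm) for l in range(L)])
    Wtd = np.stack([_glorot(rng, nd[l], nd[l + 1], ndm, ndm) if l + 1 < L
                    else np.zeros((ndm, ndm)) for l in range(L)])
    Wbu = np.stack([_glorot(rng, nd[l], nd[l - 1], ndm, ndm) if l > 0
                    else np.zeros((ndm, ndm)) for l in range(L)])
    bh = np.zeros((L, ndm))
    Wmu = np.stack([_glorot(rng, nz[l], nd[l], nzm, ndm) for l in range(L)])
    Wsig = np.stack([_glorot(rng, nz[l], nd[l], nzm, ndm) for l in range(L)])
    Wout = _glorot(rng, rx, nd[0], rx, ndm)
    p = NetworkParams(
        nd=nd, nz=nz, tau=tau, w=w, rx=rx, tied_heads=tied_heads,
        Wdd=Wdd, Wzd=Wzd, Wtd=Wtd, Wbu=Wbu, bh=bh,
        Wmu=Wmu, Wsig=Wsig,
        Wmuq=Wmu if tied_heads else np.stack([_glorot(rng, nz[l], nd[l], nzm, ndm) for l in range(L)]),
        Wsigq=Wsig if tied_heads else np.stack([_glorot(rng, nz[l], nd[l], nzm, ndm) for l in range(L)]),
        bmup=np.zeros((L, nzm)), bsigp=np.zeros((L, nzm)),
        bmuq=np.zeros((L, nzm)), bsigq=np.zeros((L, nzm)),
        Wout=Wout, bout=np.zeros(rx),
    )
    return p


# ---------------------------------------------------------------------------
# reference per-step API (readable route, used to validate the kernels)
# ---------------------------------------------------------------------------

@dataclass
class LatentFrame:
    """Per-layer state at one time step: lists (bottom layer first) of
    unpadded vectors.  ``d = tanh(h)`` always; sigma entries are strictly
    positive."""

    h: list[np.ndarray]
    d: list[np.ndarray]
    mup: list[np.ndarray]
    sigp: list[np.ndarray]
    muq: list[np.ndarray]
    sigq: list[np.ndarray]
    z: list[np.ndarray]


def initial_frame(specs: Sequence[LayerSpec]) -> LatentFrame:
    """The t=0 anchor: h = 0 (hence d = 0), no latents drawn yet."""
    zs = [np.zeros(s.n_d) for s in specs]
    zz = [np.zeros(s.n_z) for s in specs]
    ones = [np.ones(s.n_z) for s in specs]
    return LatentFrame(h=[v.copy() for v in zs], d=[v.copy() for v in zs],
                       mup=[v.copy() for v in zz], sigp=[v.copy() for v in ones],
                       muq=[v.copy() for v in zz], sigq=[v.copy() for v in ones],
                       z=[v.copy() for v in zz])


def compute_prior(d_prev: np.ndarray, params: NetworkParams, layer: int):
    """Prior Gaussian (mu_p, sigma_p) of one layer from its previous d."""
    l, n, m = layer, params.nz[layer], params.nd[layer]
    a = params.Wmu[l, :n, :m] @ d_prev + params.bmup[l, :n]
    s = np.clip(params.Wsig[l, :n, :m] @ d_prev + params.bsigp[l, :n], -SIG_CLIP, SIG_CLIP)
    return np.tanh(a), np.exp(s)


def compute_posterior(d_prev: np.ndarray, A_t, params: NetworkParams, layer: int):
    """Posterior Gaussian (mu_q, sigma_q): the prior mapping shifted by
    the adaptive variables (A_mu, A_sigma) and the posterior biases."""
    if A_t is None:
        raise ContractError("posterior undefined without adaptive variables A")
    A_mu, A_sig = A_t
    l, n, m = layer, params.nz[layer], params.nd[layer]
    a = params.Wmuq[l, :n, :m] @ d_prev + A_mu + params.bmuq[l, :n]
    s = np.clip(params.Wsigq[l, :n, :m] @ d_prev + A_sig + params.bsigq[l, :n],
                -SIG_CLIP, SIG_CLIP)
    return np.tanh(a), np.exp(s)


def sample_z(mu: np.ndarray, sigma: np.ndarray, rng=None, eps: np.ndarray | None = None):
    """Reparameterized draw z = mu + sigma * eps, eps ~ N(0, I)."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ContractError("sigma must be strictly positive")
    if eps is None:
        gen = np.random.default_rng() if rng is None else rng
        eps = gen.standard_normal(np.shape(mu))
    return np.asarray(mu) + sigma * eps


def readout(d_bottom: np.ndarray, params: NetworkParams) -> np.ndarray:
    """Sensory prediction Xbar from the bottom layer's d."""
    m = params.nd[0]
    return np.tanh(params.Wout[:, :m] @ d_bottom + params.bout)


def forward_step(prev: LatentFrame, z_source: str, params: NetworkParams,
                 *, A_t=None, eps=None, rng=None, first_step: bool = False) -> LatentFrame:
    """One step of the recurrence from a fully populated frame at t-1.

    ``z_source`` selects whether z is drawn from the prior (generation)
    or the posterior (learning / error regression).  ``eps`` is a list of
    per-layer standard-normal vectors; if omitted, drawn from ``rng``.
    ``first_step`` replaces the prior at the very first step of a stream
    with the unit Gaussian N(0, I).
    """
    if z_source not in ("prior", "posterior"):
        raise ContractError("z_source must be 'prior' or 'posterior'")
    L = params.n_layers
    if len(prev.d) != L or any(prev.d[l].shape[0] != params.nd[l] for l in range(L)):
        raise StructuralError("frame does not match network layer sizes")
    if rng is None:
        rng = np.random.default_rng()
    new = LatentFrame(h=[], d=[], mup=[], sigp=[], muq=[], sigq=[], z=[])
    for l in range(L):
        nzl = params.nz[l]
        mup, sigp = compute_prior(prev.d[l], params, l)
        if first_step:
            mup, sigp = np.zeros(nzl), np.ones(nzl)
        if A_t is not None:
            muq, sigq = compute_posterior(prev.d[l], A_t[l], params, l)
        else:
            if z_source == "posterior":
                raise ContractError("posterior step requires A_t")
            muq, sigq = mup.copy(), sigp.copy()
        e = eps[l] if eps is not None else rng.standard_normal(nzl)
        if z_source == "prior":
            z = mup + sigp * e
        else:
            z = muq + sigq * e
        new.mup.append(mup); new.sigp.append(sigp)
        new.muq.append(muq); new.sigq.append(sigq)
        new.z.append(z)
    for l in range(L):
        n, tau = params.nd[l], params.tau[l]
        u = (params.Wdd[l, :n, :n] @ prev.d[l]
             + params.Wzd[l, :n, :params.nz[l]] @ new.z[l]
             + params.bh[l, :n])
        if l + 1 < L:
            u = u + params.Wtd[l, :n, :params.nd[l + 1]] @ prev.d[l + 1]
        if l > 0:
            u = u + params.Wbu[l, :n, :params.nd[l - 1]] @ prev.d[l - 1]
        h = (1.0 - 1.0 / tau) * prev.h[l] + (1.0 / tau) * u
        new.h.append(h)
        new.d.append(np.tanh(h))
    return new


def kl_unit(mu_q, sigma_q, mu_p, sigma_p):
    """Closed-form KL divergence between two univariate Gaussians,
    elementwise over arrays:

        ln(sigma_p/sigma_q) + ((mu_q-mu_p)^2 + sigma_q^2) / (2 sigma_p^2) - 1/2
    """
    sigma_q = np.asarray(sigma_q, dtype=float)
    sigma_p = np.asarray(sigma_p, dtype=float)
    if np.any(sigma_q <= 0) or np.any(sigma_p <= 0):
        raise ContractError("sigmas must be strictly positive")
    mu_q = np.asarray(mu_q, dtype=float)
    mu_p = np.asarray(mu_p, dtype=float)
    return (np.log(sigma_p / sigma_q)
            + ((mu_q - mu_p) ** 2 + sigma_q ** 2) / (2.0 * sigma_p ** 2) - 0.5)


@dataclass
class FreeEnergyBreakdown:
    """Raw complexity (summed KL per layer) and accuracy (summed squared
    error); ``total`` applies the meta-prior and dimension normalizations."""

    complexity_per_layer: np.ndarray
    accuracy: float
    total: float


def _weighted_total(complexity_per_layer, accuracy, params, w=None) -> float:
    w = params.w if w is None else np.asarray(w, dtype=float)
    tot = accuracy / params.rx
    for l in range(params.n_layers):
        if params.nz[l] > 0:
            tot += w[l] / params.nz[l] * complexity_per_layer[l]
    return tot


def free_energy(frames: Sequence[LatentFrame], targets: np.ndarray,
                params: NetworkParams, w=None) -> FreeEnergyBreakdown:
    """Reference evaluation of the objective over a posterior-driven
    frame sequence against targets of shape (T, R_X)."""
    targets = np.asarray(targets, dtype=float)
    if len(frames) != targets.shape[0]:
        raise StructuralError("frames and targets length mismatch")
    L = params.n_layers
    comp = np.zeros(L)
    acc = 0.0
    for t, fr in enumerate(frames):
        for l in range(L):
            if params.nz[l] > 0:
                comp[l] += kl_unit(fr.muq[l], fr.sigq[l], fr.mup[l], fr.sigp[l]).sum()
        e = targets[t] - readout(fr.d[0], params)
        acc += float(e @ e)
    return FreeEnergyBreakdown(complexity_per_layer=comp, accuracy=acc,
                               total=_weighted_total(comp, acc, params, w))


# ---------------------------------------------------------------------------
# compiled sequence kernels (batched unroll + hand-derived BPTT)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _unroll_kernel(Wdd, Wzd, Wtd, Wbu, bh, Wmu, Wsig, Wmuq, Wsigq,
                   bmup, bsigp, bmuq, bsigq, Wout, bout,
                   nd, nz, tau, Amu, Asig, eps, h0, d0,
                   use_posterior, unit_prior_t1,
                   h, d, z, mup, sigp, muq, sigq, spr, sqr, xbar):
    T, L, _, B = eps.shape
    RX = Wout.shape[0]
    h[0] = h0
    d[0] = d0
    for t in range(1, T + 1):
        for l in range(L):
            nzl = nz[l]
            ndl = nd[l]
            for r in range(nzl):
                for b in range(B):
                    ap = bmup[l, r]
                    sp = bsigp[l, r]
                    aq = bmuq[l, r] + Amu[t - 1, l, r, b]
                    sq = bsigq[l, r] + Asig[t - 1, l, r, b]
                    for j in range(ndl):
                        dj = d[t - 1, l, j, b]
                        ap += Wmu[l, r, j] * dj
                        sp += Wsig[l, r, j] * dj
                        aq += Wmuq[l, r, j] * dj
                        sq += Wsigq[l, r, j] * dj
                    if sp > SIG_CLIP:
                        sp = SIG_CLIP
                    elif sp < -SIG_CLIP:
                        sp = -SIG_CLIP
                    if sq > SIG_CLIP:
                        sq = SIG_CLIP
                    elif sq < -SIG_CLIP:
                        sq = -SIG_CLIP
                    mp = np.tanh(ap)
                    sgp = np.exp(sp)
                    if t == 1 and unit_prior_t1:
                        mp = 0.0
                        sgp = 1.0
                        sp = 0.0
                    mq = np.tanh(aq)
                    sgq = np.exp(sq)
                    mup[t - 1, l, r, b] = mp
                    sigp[t - 1, l, r, b] = sgp
                    spr[t - 1, l, r, b] = sp
                    muq[t - 1, l, r, b] = mq
                    sigq[t - 1, l, r, b] = sgq
                    sqr[t - 1, l, r, b] = sq
                    if use_posterior:
                        z[t - 1, l, r, b] = mq + sgq * eps[t - 1, l, r, b]
                    else:
                        z[t - 1, l, r, b] = mp + sgp * eps[t - 1, l, r, b]
        for l in range(L):
            ndl = nd[l]
            nzl = nz[l]
            al = 1.0 / tau[l]
            for i in range(ndl):
                for b in range(B):
                    u = bh[l, i]
                    for j in range(ndl):
                        u += Wdd[l, i, j] * d[t - 1, l, j, b]
                    for r in range(nzl):
                        u += Wzd[l, i, r] * z[t - 1, l, r, b]
                    if l + 1 < L:
                        for j in range(nd[l + 1]):
                            u += Wtd[l, i, j] * d[t - 1, l + 1, j, b]
                    if l > 0:
                        for j in range(nd[l - 1]):
                            u += Wbu[l, i, j] * d[t - 1, l - 1, j, b]
                    hv = (1.0 - al) * h[t - 1, l, i, b] + al * u
                    h[t, l, i, b] = hv
                    d[t, l, i, b] = np.tanh(hv)
        for o in range(RX):
            for b in range(B):
                v = bout[o]
                for j in range(nd[0]):
                    v += Wout[o, j] * d[t, 0, j, b]
                xbar[t - 1, o, b] = np.tanh(v)


@njit(cache=True)
def _backward_kernel(Wdd, Wzd, Wtd, Wbu, Wmu, Wsig, Wmuq, Wsigq, Wout,
                     nd, nz, tau, wvec, targets, Amu_used, eps,
                     h, d, z, mup, sigp, muq, sigq, spr, sqr, xbar,
                     unit_prior_t1,
                     gWdd, gWzd, gWtd, gWbu, gbh, gWmu, gWsig, gWmuq, gWsigq,
                     gbmup, gbsigp, gbmuq, gbsigq, gWout, gbout, gAmu, gAsig):
    T, L, nzm, B = eps.shape
    RX = Wout.shape[0]
    ndm = d.shape[2]
    kB = 1.0 / B

    Gnext = np.zeros((L, ndm, B))
    G = np.zeros((L, ndm, B))
    gap_n = np.zeros((L, nzm, B))
    gsp_n = np.zeros((L, nzm, B))
    gaq_n = np.zeros((L, nzm, B))
    gsq_n = np.zeros((L, nzm, B))
    go = np.zeros((RX, B))
    D = np.zeros((ndm, B))
    gz = np.zeros((nzm, B))

    for t in range(T, 0, -1):
        for o in range(RX):
            for b in range(B):
                xb = xbar[t - 1, o, b]
                go[o, b] = kB * (2.0 / RX) * (xb - targets[t - 1, o, b]) * (1.0 - xb * xb)
        # grads w.r.t. h_t via d_t for every layer
        for l in range(L):
            ndl = nd[l]
            for i in range(ndl):
                for b in range(B):
                    D[i, b] = 0.0
            if l == 0:
                for j in range(ndl):
                    for o in range(RX):
                        for b in range(B):
                            D[j, b] += Wout[o, j] * go[o, b]
            # recurrent paths from t+1 (Gnext holds dF/dh_{t+1})
            al = 1.0 / tau[l]
            for j in range(ndl):
                for i in range(ndl):
                    for b in range(B):
                        D[j, b] += Wdd[l, i, j] * al * Gnext[l, i, b]
            if l + 1 < L:
                au = 1.0 / tau[l + 1]
                for j in range(ndl):
                    for i in range(nd[l + 1]):
                        for b in range(B):
                            D[j, b] += Wbu[l + 1, i, j] * au * Gnext[l + 1, i, b]
            if l > 0:
                ad = 1.0 / tau[l - 1]
                for j in range(ndl):
                    for i in range(nd[l - 1]):
                        for b in range(B):
                            D[j, b] += Wtd[l - 1, i, j] * ad * Gnext[l - 1, i, b]
            # latent-head paths from t+1 (heads condition on d_t)
            for j in range(ndl):
                for r in range(nz[l]):
                    for b in range(B):
                        D[j, b] += (Wmu[l, r, j] * gap_n[l, r, b]
                                    + Wsig[l, r, j] * gsp_n[l, r, b]
                                    + Wmuq[l, r, j] * gaq_n[l, r, b]
                                    + Wsigq[l, r, j] * gsq_n[l, r, b])
            for i in range(ndl):
                for b in range(B):
                    dv = d[t, l, i, b]
                    G[l, i, b] = D[i, b] * (1.0 - dv * dv) + (1.0 - al) * Gnext[l, i, b]
        # per-layer latent grads at t and parameter accumulation
        for l in range(L):
            ndl = nd[l]
            nzl = nz[l]
            al = 1.0 / tau[l]
            cl = wvec[l] / nzl if nzl > 0 else 0.0
            for r in range(nzl):
                for b in range(B):
                    s = 0.0
                    for i in range(ndl):
                        s += Wzd[l, i, r] * al * G[l, i, b]
                    gz[r, b] = s
            for r in range(nzl):
                for b in range(B):
                    mp = mup[t - 1, l, r, b]
                    sgp = sigp[t - 1, l, r, b]
                    mq = muq[t - 1, l, r, b]
                    sgq = sigq[t - 1, l, r, b]
                    dm = mq - mp
                    sp2 = sgp * sgp
                    gzv = gz[r, b]
                    gmuq = kB * cl * dm / sp2 + gzv
                    gaq = gmuq * (1.0 - mq * mq)
                    if abs(sqr[t - 1, l, r, b]) >= SIG_CLIP:
                        gsq = 0.0
                    else:
                        gsq = kB * cl * (-1.0 + sgq * sgq / sp2) + gzv * sgq * eps[t - 1, l, r, b]
                    if t == 1 and unit_prior_t1:
                        gap = 0.0
                        gsp = 0.0
                    else:
                        gmup = -kB * cl * dm / sp2
                        gap = gmup * (1.0 - mp * mp)
                        if abs(spr[t - 1, l, r, b]) >= SIG_CLIP:
                            gsp = 0.0
                        else:
                            gsp = kB * cl * (1.0 - (dm * dm + sgq * sgq) / sp2)
                    gaq_n[l, r, b] = gaq
                    gsq_n[l, r, b] = gsq
                    gap_n[l, r, b] = gap
                    gsp_n[l, r, b] = gsp
                    gAmu[t - 1, l, r, b] = gaq
                    gAsig[t - 1, l, r, b] = gsq
                    gbmuq[l, r] += gaq
                    gbsigq[l, r] += gsq
                    gbmup[l, r] += gap
                    gbsigp[l, r] += gsp
                    for j in range(ndl):
                        dj = d[t - 1, l, j, b]
                        gWmuq[l, r, j] += gaq * dj
                        gWsigq[l, r, j] += gsq * dj
                        gWmu[l, r, j] += gap * dj
                        gWsig[l, r, j] += gsp * dj
            for i in range(ndl):
                for b in range(B):
                    g = al * G[l, i, b]
                    gbh[l, i] += g
                    for j in range(ndl):
                        gWdd[l, i, j] += g * d[t - 1, l, j, b]
                    for r in range(nzl):
                        gWzd[l, i, r] += g * z[t - 1, l, r, b]
                    if l + 1 < L:
                        for j in range(nd[l + 1]):
                            gWtd[l, i, j] += g * d[t - 1, l + 1, j, b]
                    if l > 0:
                        for j in range(nd[l - 1]):
                            gWbu[l, i, j] += g * d[t - 1, l - 1, j, b]
        for o in range(RX):
            for b in range(B):
                gbout[o] += go[o, b]
                for j in range(nd[0]):
                    gWout[o, j] += go[o, b] * d[t, 0, j, b]
        for l in range(L):
            for i in range(nd[l]):
                for b in range(B):
                    Gnext[l, i, b] = G[l, i, b]


@dataclass
class UnrollCache:
    """Arrays produced by one batched unroll; time-major with batch last:
    ``h``/``d`` are (T+1, L, ndm, B) including the anchor at index 0,
    latent arrays are (T, L, nzm, B) and ``xbar`` is (T, RX, B)."""

    h: np.ndarray
    d: np.ndarray
    z: np.ndarray
    mup: np.ndarray
    sigp: np.ndarray
    muq: np.ndarray
    sigq: np.ndarray
    spr: np.ndarray
    sqr: np.ndarray
    xbar: np.ndarray
    Amu: np.ndarray
    Asig: np.ndarray
    eps: np.ndarray
    unit_prior_t1: bool


def unroll(params: NetworkParams, T: int, B: int = 1, *, Amu=None, Asig=None,
           eps=None, h0=None, d0=None, posterior: bool = True,
           unit_prior_t1: bool = True, rng=None) -> UnrollCache:
    """Run the recurrence for T steps over a batch.

    ``posterior=True`` draws z from the adapted posterior (requires Amu/
    Asig); ``posterior=False`` is the generative (prior) rollout.  Pass
    ``eps=0`` arrays for a mean (noise-free) pass.
    """
    L, ndm = params.n_layers, params.Wdd.shape[1]
    nzm = params.Wzd.shape[2]
    if Amu is None:
        Amu = np.zeros((T, L, nzm, B))
    if Asig is None:
        Asig = np.zeros((T, L, nzm, B))
    if eps is None:
        rng = np.random.default_rng() if rng is None else rng
        eps = rng.standard_normal((T, L, nzm, B))
    if h0 is None:
        h0 = np.zeros((L, ndm, B))
    if d0 is None:
        d0 = np.tanh(h0)
    if posterior and (Amu.shape != (T, L, nzm, B)):
        raise StructuralError("Amu has wrong shape")
    h = np.zeros((T + 1, L, ndm, B))
    d = np.zeros((T + 1, L, ndm, B))
    z = np.zeros((T, L, nzm, B))
    mup = np.zeros((T, L, nzm, B)); sigp = np.ones((T, L, nzm, B))
    muq = np.zeros((T, L, nzm, B)); sigq = np.ones((T, L, nzm, B))
    spr = np.zeros((T, L, nzm, B)); sqr = np.zeros((T, L, nzm, B))
    xbar = np.zeros((T, params.rx, B))
    _unroll_kernel(params.Wdd, params.Wzd, params.Wtd, params.Wbu, params.bh,
                   params.Wmu, params.Wsig, params.Wmuq, params.Wsigq,
                   params.bmup, params.bsigp, params.bmuq, params.bsigq,
                   params.Wout, params.bout,
                   params.nd, params.nz, params.tau, Amu, Asig, eps,
                   np.ascontiguousarray(h0), np.ascontiguousarray(d0),
                   posterior, unit_prior_t1,
                   h, d, z, mup, sigp, muq, sigq, spr, sqr, xbar)
    return UnrollCache(h=h, d=d, z=z, mup=mup, sigp=sigp, muq=muq, sigq=sigq,
                       spr=spr, sqr=sqr, xbar=xbar, Amu=Amu, Asig=Asig, eps=eps,
                       unit_prior_t1=unit_prior_t1)


def free_energy_from_cache(cache: UnrollCache, targets: np.ndarray,
                           params: NetworkParams, w=None) -> FreeEnergyBreakdown:
    """Objective over a batched cache, averaged over the batch.
    ``targets`` has shape (T, R_X, B) (or (T, R_X) for B = 1)."""
    targets = np.asarray(targets, dtype=float)
    if targets.ndim == 2:
        targets = targets[:, :, None]
    T, L, nzm, B = cache.eps.shape
    if targets.shape[0] != T:
        raise StructuralError("targets and cache length mismatch")
    comp = np.zeros(L)
    for l in range(L):
        n = params.nz[l]
        if n > 0:
            comp[l] = kl_unit(cache.muq[:, l, :n], cache.sigq[:, l, :n],
                              cache.mup[:, l, :n], cache.sigp[:, l, :n]).sum() / B
    acc = float(((targets - cache.xbar) ** 2).sum()) / B
    return FreeEnergyBreakdown(complexity_per_layer=comp, accuracy=acc,
                               total=_weighted_total(comp, acc, params, w))


def backward(params: NetworkParams, cache: UnrollCache, targets: np.ndarray,
             w=None) -> dict[str, np.ndarray]:
    """Gradients of the batch-mean objective with respect to every
    parameter tensor and the adaptive variables (keys ``Amu``/``Asig``).
    With tied heads the prior/posterior input-weight gradients are summed
    into ``Wmu``/``Wsig``."""
    targets = np.asarray(targets, dtype=float)
    if targets.ndim == 2:
        targets = targets[:, :, None]
    wvec = params.w if w is None else np.asarray(w, dtype=float)
    g = {n: np.zeros_like(v) for n, v in [
        ("Wdd", params.Wdd), ("Wzd", params.Wzd), ("Wtd", params.Wtd),
        ("Wbu", params.Wbu), ("bh", params.bh),
        ("Wmu", params.Wmu), ("Wsig", params.Wsig),
        ("Wmuq", params.Wmuq), ("Wsigq", params.Wsigq),
        ("bmup", params.bmup), ("bsigp", params.bsigp),
        ("bmuq", params.bmuq), ("bsigq", params.bsigq),
        ("Wout", params.Wout), ("bout", params.bout)]}
    gAmu = np.zeros_like(cache.Amu)
    gAsig = np.zeros_like(cache.Asig)
    _backward_kernel(params.Wdd, params.Wzd, params.Wtd, params.Wbu,
                     params.Wmu, params.Wsig, params.Wmuq, params.Wsigq, params.Wout,
                     params.nd, params.nz, params.tau, wvec,
                     np.ascontiguousarray(targets), cache.Amu, cache.eps,
                     cache.h, cache.d, cache.z, cache.mup, cache.sigp,
                     cache.muq, cache.sigq, cache.spr, cache.sqr, cache.xbar,
                     cache.unit_prior_t1,
                     g["Wdd"], g["Wzd"], g["Wtd"], g["Wbu"], g["bh"],
                     g["Wmu"], g["Wsig"], g["Wmuq"], g["Wsigq"],
                     g["bmup"], g["bsigp"], g["bmuq"], g["bsigq"],
                     g["Wout"], g["bout"], gAmu, gAsig)
    if params.tied_heads:
        g["Wmu"] += g.pop("Wmuq")
        g["Wsig"] += g.pop("Wsigq")
    g["Amu"] = gAmu
    g["Asig"] = gAsig
    return g


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

_CKPT_VERSION = 1


def save_checkpoint(path: str | Path, params: NetworkParams, extra: dict | None = None):
    """Single-archive binary checkpoint (numpy .npz) of all tensors,
    layer constants and a version stamp."""
    arrays = {f: getattr(params, f) for f in params.__dataclass_fields__
              if isinstance(getattr(params, f), np.ndarray)}
    arrays["_version"] = np.array(_CKPT_VERSION)
    arrays["_rx"] = np.array(params.rx)
    arrays["_tied"] = np.array(int(params.tied_heads))
    if extra:
        for k, v in extra.items():
            arrays["x_" + k] = np.asarray(v)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[NetworkParams, dict]:
    with np.load(path) as f:
        if int(f["_version"]) != _CKPT_VERSION:
            raise StructuralError("unsupported checkpoint version")
        tied = bool(int(f["_tied"]))
        kw = dict(rx=int(f["_rx"]), tied_heads=tied)
        for name in NetworkParams.__dataclass_fields__:
            if name in ("rx", "tied_heads"):
                continue
            kw[name] = f[name]
        extra = {k[2:]: f[k] for k in f.files if k.startswith("x_")}
    p = NetworkParams(**kw)
    if tied:
        p.Wmuq = p.Wmu
        p.Wsigq = p.Wsig
    return p, extra
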