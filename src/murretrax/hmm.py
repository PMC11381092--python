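"""Multivariate hidden Markov model for behaviour classification.

Each GPS fix carries four observation channels — wing-beat frequency (Hz),
pitch (degrees), per-interval maximum depth (m) and distance from the
colony (km) — and the bird is in one of four latent behaviours: COLONY
(resting at the colony), FLY, SWIM, DIVE.  Channels are conditionally
independent given the state.  Non-negative channels that are exactly zero
outside their active behaviour (depth, wing-beat, colony distance) use a
zero-inflated gamma emission: a point mass pi0 at 0 plus a gamma density on
the positive part.  Pitch is Gaussian.

Fitting is Baum-Welch EM over multiple deployments treated as independent
sequences sharing one parameter set; decoding is Viterbi with ties broken
toward the lower state index (fixed order COLONY < FLY < SWIM < DIVE);
missing channel values simply drop out of the emission product.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, digamma, polygamma

from .config import STATES

CHANNELS = ("wingbeat_hz", "pitch", "depth", "dist_colony_km")

_MIN_SIGMA = 1e-3
_MIN_RESP = 1e-8


class DegenerateStateError(RuntimeError):
    """EM drove a state's total responsibility to (numerical) zero."""


# ---------------------------------------------------------------------------
# emission families

@dataclass
class Gaussian:
    mu: float
    sigma: float

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        s = max(self.sigma, _MIN_SIGMA)
        return -0.5 * ((x - self.mu) / s) ** 2 - np.log(s) - 0.5 * np.log(2 * np.pi)

    def fit_weighted(self, x: np.ndarray, w: np.ndarray) -> "Gaussian":
        sw = w.sum()
        if sw < _MIN_RESP:
            return self
        mu = float((w * x).sum() / sw)
        var = float((w * (x - mu) ** 2).sum() / sw)
        return Gaussian(mu, max(np.sqrt(var), _MIN_SIGMA))

    def to_dict(self):
        return {"family": "gaussian", "mu": self.mu, "sigma": self.sigma}


@dataclass
class ZeroInflatedGamma:
    """Point mass pi0 at zero plus Gamma(shape, rate) on x > 0."""

    pi0: float
    shape: float
    rate: float

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.full(x.shape, -np.inf)
        zero = x == 0.0
        pi0 = np.clip(self.pi0, 1e-12, 1.0 - 1e-12)
        out[zero] = np.log(pi0)
        pos = x > 0
        if pos.any():
            a, r = self.shape, self.rate
            xp = x[pos]
            out[pos] = (np.log1p(-pi0) + a * np.log(r) - gammaln(a)
                        + (a - 1.0) * np.log(xp) - r * xp)
        return out

    def fit_weighted(self, x: np.ndarray, w: np.ndarray) -> "ZeroInflatedGamma":
        sw = w.sum()
        if sw < _MIN_RESP:
            return self
        zero = x == 0.0
        pi0 = float(w[zero].sum() / sw)
        pos = x > 0
        wp, xp = w[pos], x[pos]
        if wp.sum() < 10 * _MIN_RESP or pos.sum() < 2:
            return ZeroInflatedGamma(pi0, self.shape, self.rate)
        m = float((wp * xp).sum() / wp.sum())
        mlog = float((wp * np.log(xp)).sum() / wp.sum())
        s = np.log(m) - mlog
        if s <= 1e-8:          # near-degenerate positive part
            a = 1e4
        else:
            a = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
            for _ in range(25):   # Newton on log a - psi(a) = s
                f = np.log(a) - digamma(a) - s
                fp = 1.0 / a - polygamma(1, a)
                step = f / fp
                a_new = a - step
                if a_new <= 0:
                    a_new = a / 2.0
                if abs(a_new - a) < 1e-10 * a:
                    a = a_new
                    break
                a = a_new
        a = float(np.clip(a, 1e-3, 1e6))
        cand = ZeroInflatedGamma(pi0, a, a / m)
        # generalized-EM guard: never move to a worse weighted likelihood
        # (the Newton solve can be capped when the positive part degenerates)
        keep = ZeroInflatedGamma(pi0, self.shape, self.rate)
        if (w * keep.logpdf(x)).sum() > (w * cand.logpdf(x)).sum():
            return keep
        return cand

    @property
    def mean_positive(self) -> float:
        return self.shape / self.rate

    def to_dict(self):
        return {"family": "zigamma", "pi0": self.pi0,
                "shape": self.shape, "rate": self.rate}


def _dist_from_dict(d: dict):
    if d["family"] == "gaussian":
        return Gaussian(d["mu"], d["sigma"])
    if d["family"] == "zigamma":
        return ZeroInflatedGamma(d["pi0"], d["shape"], d["rate"])
    raise ValueError(f"unknown emission family {d['family']!r}")


# ---------------------------------------------------------------------------
# model specification

@dataclass
class HMMSpec:
    """Initial distribution, transition matrix and per-state channel emissions."""

    states: tuple = STATES
    init: np.ndarray = None
    trans: np.ndarray = None
    emissions: dict = None     # state -> {channel -> distribution}

    def __post_init__(self):
        self.states = tuple(self.states)
        n = len(self.states)
        if self.init is None:
            self.init = np.full(n, 1.0 / n)
        if self.trans is None:
            self.trans = np.full((n, n), 1.0 / n)
        self.init = np.asarray(self.init, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        self.validate()

    def validate(self):
        n = len(self.states)
        if self.init.shape != (n,) or self.trans.shape != (n, n):
            raise ValueError("init/trans shape does not match state count")
        if abs(self.init.sum() - 1.0) > 1e-8:
            raise ValueError("init must sum to 1")
        if np.any(np.abs(self.trans.sum(axis=1) - 1.0) > 1e-8):
            raise ValueError("transition rows must sum to 1")
        if np.any(self.init < -1e-12) or np.any(self.trans < -1e-12):
            raise ValueError("probabilities must be non-negative")
        if self.emissions is not None:
            for s in self.states:
                for ch, dist in self.emissions[s].items():
                    for v in dist.to_dict().values():
                        if isinstance(v, float) and not np.isfinite(v):
                            raise ValueError(f"non-finite emission parameter in {s}/{ch}")

    @property
    def channels(self) -> tuple:
        first = self.emissions[self.states[0]]
        return tuple(first.keys())

    def to_dict(self) -> dict:
        return {
            "states": list(self.states),
            "init": self.init.tolist(),
            "trans": self.trans.tolist(),
            "emissions": {s: {ch: d.to_dict() for ch, d in self.emissions[s].items()}
                          for s in self.states},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMSpec":
        em = {s: {ch: _dist_from_dict(dd) for ch, dd in chs.items()}
              for s, chs in d["emissions"].items()}
        return cls(states=tuple(d["states"]), init=np.array(d["init"]),
                   trans=np.array(d["trans"]), emissions=em)

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "HMMSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class BehaviorSequence:
    """Decoded per-fix behaviour for one deployment."""

    deployment_id: str
    states: np.ndarray          # array of state labels (str)
    log_likelihood: float       # forward (marginal) log-likelihood, nats
    spec: HMMSpec = field(repr=False, default=None)

    def __len__(self):
        return len(self.states)


# ---------------------------------------------------------------------------
# inference primitives

def _obs_frame(x) -> pd.DataFrame:
    fixes = getattr(x, "fixes", x)
    return fixes


def log_emission_matrix(obs: pd.DataFrame, spec: HMMSpec) -> np.ndarray:
    """(T, S) per-fix log emission likelihoods; missing channels are skipped."""
    T = len(obs)
    S = len(spec.states)
    logB = np.zeros((T, S))
    for ch in spec.channels:
        if ch not in obs.columns:
            continue
        x = obs[ch].to_numpy(dtype=float)
        ok = np.isfinite(x)
        if not ok.any():
            continue
        for j, s in enumerate(spec.states):
            lp = spec.emissions[s][ch].logpdf(x[ok])
            logB[ok, j] += lp
    return logB


def _forward_scaled(logB: np.ndarray, init: np.ndarray, trans: np.ndarray):
    """Scaled forward pass; returns (alpha_hat, log c_t) with sum_t log c = LL."""
    T, S = logB.shape
    shift = logB.max(axis=1, keepdims=True)
    shift[~np.isfinite(shift)] = 0.0
    B = np.exp(logB - shift)
    alpha = np.empty((T, S))
    logc = np.empty(T)
    a = init * B[0]
    c = a.sum()
    if c <= 0:
        raise ValueError("observation has zero likelihood under all states")
    alpha[0] = a / c
    logc[0] = np.log(c) + shift[0, 0]
    for t in range(1, T):
        a = (alpha[t - 1] @ trans) * B[t]
        c = a.sum()
        if c <= 0:
            raise ValueError("observation has zero likelihood under all states")
        alpha[t] = a / c
        logc[t] = np.log(c) + shift[t, 0]
    return alpha, logc


def forward_loglik(deployment, spec: HMMSpec) -> float:
    """Marginal log-likelihood log sum_paths P(path, data) via the forward pass."""
    obs = _obs_frame(deployment)
    logB = log_emission_matrix(obs, spec)
    _, logc = _forward_scaled(logB, spec.init, spec.trans)
    ll = float(logc.sum())
    if not np.isfinite(ll):
        raise ValueError("non-finite log-likelihood")
    return ll


def viterbi_path(obs: pd.DataFrame, spec: HMMSpec) -> tuple[np.ndarray, float]:
    """Most probable state path (indices) and its joint log probability."""
    logB = log_emission_matrix(obs, spec)
    T, S = logB.shape
    with np.errstate(divide="ignore"):
        log_init = np.log(spec.init)
        log_trans = np.log(spec.trans)
    delta = log_init + logB[0]
    psi = np.zeros((T, S), dtype=np.intp)
    for t in range(1, T):
        cand = delta[:, None] + log_trans          # (from, to)
        psi[t] = np.argmax(cand, axis=0)           # ties -> lowest index
        delta = cand[psi[t], np.arange(S)] + logB[t]
    path = np.empty(T, dtype=np.intp)
    path[-1] = int(np.argmax(delta))
    best = float(delta[path[-1]])
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path, best


def decode(deployment, spec: HMMSpec) -> BehaviorSequence:
    """Viterbi-decode one deployment into a labelled BehaviorSequence."""
    obs = _obs_frame(deployment)
    path, _ = viterbi_path(obs, spec)
    labels = np.asarray(spec.states, dtype=object)[path]
    ll = forward_loglik(obs, spec)
    dep_id = getattr(deployment, "bird_id", "seq")
    return BehaviorSequence(deployment_id=dep_id, states=labels,
                            log_likelihood=ll, spec=spec)


# ---------------------------------------------------------------------------
# Baum-Welch EM

def _e_step(obs: pd.DataFrame, spec: HMMSpec):
    logB = log_emission_matrix(obs, spec)
    T, S = logB.shape
    alpha, logc = _forward_scaled(logB, spec.init, spec.trans)
    shift = logB.max(axis=1, keepdims=True)
    shift[~np.isfinite(shift)] = 0.0
    B = np.exp(logB - shift)
    beta = np.empty((T, S))
    beta[-1] = 1.0
    csc = np.exp(logc - shift[:, 0])   # scale factors in shifted space
    trans = spec.trans
    for t in range(T - 2, -1, -1):
        beta[t] = (trans @ (B[t + 1] * beta[t + 1])) / max(csc[t + 1], 1e-300)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    # expected transition counts
    xi_sum = np.zeros((S, S))
    for t in range(T - 1):
        m = trans * np.outer(alpha[t], B[t + 1] * beta[t + 1]) / max(csc[t + 1], 1e-300)
        tot = m.sum()
        if tot > 0:
            xi_sum += m / tot
    return gamma, xi_sum, float(logc.sum())


class BehaviorHMM:
    """Baum-Welch/Viterbi HMM with a scikit-learn-style surface.

    Parameters
    ----------
    init_spec : HMMSpec, optional
        Starting parameters.  When omitted, a k-means initialization over
        the pooled channels is used (see :func:`init_spec_from_data`) with
        ``n_restarts`` perturbed restarts, best log-likelihood kept.
    max_iter, tol : EM stopping rule (tol in nats of total log-likelihood).
    n_restarts : number of random perturbations of the initial spec.
    random_state : seed for restarts.

    Fitted attributes: ``spec_``, ``loglik_history_`` (one entry per EM
    iteration, non-decreasing), ``converged_``.
    """

    def __init__(self, init_spec: HMMSpec | None = None, max_iter: int = 100,
                 tol: float = 1e-4, n_restarts: int = 0, random_state: int | None = None):
        self.init_spec = init_spec
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.random_state = random_state

    def get_params(self, deep=True):
        return {"init_spec": self.init_spec, "max_iter": self.max_iter,
                "tol": self.tol, "n_restarts": self.n_restarts,
                "random_state": self.random_state}

    def set_params(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    # -- fitting -----------------------------------------------------------
    def fit(self, deployments) -> "BehaviorHMM":
        obs_list = [_obs_frame(d) for d in deployments]
        if len(obs_list) == 0:
            raise ValueError("need at least one deployment")
        rng = np.random.default_rng(self.random_state)
        spec0 = self.init_spec
        if spec0 is None:
            spec0 = init_spec_from_data(obs_list, rng)
        candidates = [spec0] + [_perturb_spec(spec0, rng) for _ in range(self.n_restarts)]
        best = None
        for cand in candidates:
            spec, hist = self._em(obs_list, cand)
            if best is None or hist[-1] > best[1][-1]:
                best = (spec, hist)
        self.spec_, self.loglik_history_ = best
        self.converged_ = (len(self.loglik_history_) < self.max_iter + 1)
        return self

    def _em(self, obs_list, spec: HMMSpec):
        S = len(spec.states)
        history = []
        prev_ll = -np.inf
        for it in range(self.max_iter):
            gamma0 = np.zeros(S)
            trans_num = np.zeros((S, S))
            gammas = []
            total_ll = 0.0
            for obs in obs_list:
                gamma, xi_sum, ll = _e_step(obs, spec)
                gamma0 += gamma[0]
                trans_num += xi_sum
                gammas.append(gamma)
                total_ll += ll
            history.append(total_ll)
            if total_ll + 1e-9 < prev_ll:
                raise RuntimeError(
                    f"EM log-likelihood decreased at iteration {it}: "
                    f"{prev_ll:.6f} -> {total_ll:.6f}")
            occ = sum(g.sum(axis=0) for g in gammas)
            for j, s in enumerate(spec.states):
                if occ[j] < _MIN_RESP:
                    raise DegenerateStateError(f"state {s} starved during EM")
            if total_ll - prev_ll < self.tol and it > 0:
                break
            prev_ll = total_ll
            # M-step
            init = gamma0 / gamma0.sum()
            denom = trans_num.sum(axis=1, keepdims=True)
            trans = np.where(denom > 0, trans_num / np.maximum(denom, 1e-300),
                             spec.trans)
            trans /= trans.sum(axis=1, keepdims=True)
            emissions = {}
            for j, s in enumerate(spec.states):
                emissions[s] = {}
                for ch in spec.channels:
                    xs, ws = [], []
                    for obs, g in zip(obs_list, gammas):
                        if ch not in obs.columns:
                            continue
                        x = obs[ch].to_numpy(dtype=float)
                        ok = np.isfinite(x)
                        xs.append(x[ok])
                        ws.append(g[ok, j])
                    x = np.concatenate(xs) if xs else np.empty(0)
                    w = np.concatenate(ws) if ws else np.empty(0)
                    emissions[s][ch] = spec.emissions[s][ch].fit_weighted(x, w)
            spec = HMMSpec(states=spec.states, init=init, trans=trans,
                           emissions=emissions)
        return spec, history

    # -- prediction --------------------------------------------------------
    def decode(self, deployment) -> BehaviorSequence:
        return decode(deployment, self.spec_)

    def predict(self, deployment) -> np.ndarray:
        return self.decode(deployment).states

    def score(self, deployment) -> float:
        return forward_loglik(deployment, self.spec_)


def fit_hmm(deployments, init_spec: HMMSpec, max_iter: int = 100,
            tol: float = 1e-4) -> HMMSpec:
    """Functional wrapper: Baum-Welch from an explicit starting spec."""
    model = BehaviorHMM(init_spec=init_spec, max_iter=max_iter, tol=tol).fit(deployments)
    return model.spec_


# ---------------------------------------------------------------------------
# initialization helpers

def _fit_channel(dist, x, w):
    return dist.fit_weighted(x, w)


def default_emissions() -> dict:
    """A physically sensible starting emission set for the four behaviours."""
    zg = ZeroInflatedGamma
    return {
        "COLONY": {"wingbeat_hz": zg(0.95, 2.0, 1.0), "pitch": Gaussian(0.0, 15.0),
                   "depth": zg(0.999, 2.0, 0.5), "dist_colony_km": zg(0.9, 1.5, 3.0)},
        "FLY": {"wingbeat_hz": zg(0.02, 40.0, 5.0), "pitch": Gaussian(0.0, 10.0),
                "depth": zg(0.999, 2.0, 0.5), "dist_colony_km": zg(0.01, 2.0, 0.1)},
        "SWIM": {"wingbeat_hz": zg(0.9, 2.0, 1.0), "pitch": Gaussian(0.0, 20.0),
                 "depth": zg(0.99, 2.0, 0.5), "dist_colony_km": zg(0.01, 2.0, 0.1)},
        "DIVE": {"wingbeat_hz": zg(0.9, 2.0, 1.0), "pitch": Gaussian(-30.0, 20.0),
                 "depth": zg(0.02, 3.0, 0.15), "dist_colony_km": zg(0.01, 2.0, 0.1)},
    }


def init_spec_from_data(obs_list, rng) -> HMMSpec:
    """k-means over standardized channels, clusters mapped to behaviours.

    DIVE is the cluster with the deepest mean depth, FLY the fastest mean
    wing-beat of the rest, COLONY the closest to the colony, SWIM the
    remainder.
    """
    from sklearn.cluster import KMeans

    pooled = pd.concat(obs_list, ignore_index=True)
    X = pooled[list(CHANNELS)].to_numpy(dtype=float)
    med = np.nanmedian(X, axis=0)
    X = np.where(np.isfinite(X), X, med)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    km = KMeans(n_clusters=4, n_init=5,
                random_state=int(rng.integers(0, 2**31 - 1))).fit((X - mu) / sd)
    lab = km.labels_
    means = {c: X[lab == c].mean(axis=0) for c in range(4)}
    remaining = set(range(4))
    mapping = {}
    dive = max(remaining, key=lambda c: means[c][2])
    mapping[dive] = "DIVE"; remaining.remove(dive)
    fly = max(remaining, key=lambda c: means[c][0])
    mapping[fly] = "FLY"; remaining.remove(fly)
    colony = min(remaining, key=lambda c: means[c][3])
    mapping[colony] = "COLONY"; remaining.remove(colony)
    mapping[remaining.pop()] = "SWIM"

    emissions = default_emissions()
    order = {s: i for i, s in enumerate(STATES)}
    state_of = np.array([order[mapping[c]] for c in lab])
    for c, s in mapping.items():
        w = (lab == c).astype(float)
        for k, ch in enumerate(CHANNELS):
            x = pooled[ch].to_numpy(dtype=float)
            ok = np.isfinite(x)
            emissions[s][ch] = emissions[s][ch].fit_weighted(x[ok], w[ok])
    trans = np.full((4, 4), 0.0)
    for a, b in zip(state_of[:-1], state_of[1:]):
        trans[a, b] += 1.0
    trans += 1.0        # Laplace smoothing
    trans /= trans.sum(axis=1, keepdims=True)
    init = np.bincount(state_of, minlength=4).astype(float)
    init /= init.sum()
    return HMMSpec(states=STATES, init=init, trans=trans, emissions=emissions)


def _perturb_spec(spec: HMMSpec, rng) -> HMMSpec:
    n = len(spec.states)
    init = spec.init + rng.uniform(0, 0.1, n)
    init /= init.sum()
    trans = spec.trans + rng.uniform(0, 0.05, (n, n))
    trans /= trans.sum(axis=1, keepdims=True)
    emissions = {}
    for s in spec.states:
        emissions[s] = {}
        for ch, d in spec.emissions[s].items():
            f = float(np.exp(rng.normal(0, 0.1)))
            if isinstance(d, Gaussian):
                emissions[s][ch] = Gaussian(d.mu + rng.normal(0, 0.1 * max(d.sigma, 1e-3)),
                                            d.sigma * f)
            else:
                emissions[s][ch] = ZeroInflatedGamma(
                    float(np.clip(d.pi0 * f, 1e-6, 1 - 1e-6)), d.shape * f, d.rate)
    return HMMSpec(states=spec.states, init=init, trans=trans, emissions=emissions)
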