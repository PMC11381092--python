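"""Independent oracles shared across test modules."""

import itertools

import numpy as np

from murretrax.hmm import Gaussian, HMMSpec, ZeroInflatedGamma, log_emission_matrix


def brute_force(obs, spec):
    """Exhaustive sum/argmax over all state paths (oracle for short sequences)."""
    logB = log_emission_matrix(obs, spec)
    T, S = logB.shape
    with np.errstate(divide="ignore"):
        li, lt = np.log(spec.init), np.log(spec.trans)
    best, best_path = -np.inf, None
    logps = []
    for path in itertools.product(range(S), repeat=T):
        lp = li[path[0]] + logB[0, path[0]]
        for a, b, t in zip(path[:-1], path[1:], range(1, T)):
            lp += lt[a, b] + logB[t, b]
        logps.append(lp)
        if lp > best:
            best, best_path = lp, path
    total = np.logaddexp.reduce(logps)
    return total, best, best_path


def random_spec(rng, n_states, channels=("pitch",)):
    """Random valid HMM spec with Gaussian/zero-inflated-gamma channels."""
    init = rng.dirichlet(np.ones(n_states))
    trans = rng.dirichlet(np.ones(n_states), size=n_states)
    names = [f"s{i}" for i in range(n_states)]
    emissions = {}
    for s in names:
        emissions[s] = {}
        for ch in channels:
            if ch == "pitch":
                emissions[s][ch] = Gaussian(rng.normal(0, 3), rng.uniform(0.5, 2.0))
            else:
                emissions[s][ch] = ZeroInflatedGamma(rng.uniform(0.1, 0.9),
                                                     rng.uniform(0.5, 5.0),
                                                     rng.uniform(0.2, 2.0))
    return HMMSpec(states=tuple(names), init=init, trans=trans, emissions=emissions)
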