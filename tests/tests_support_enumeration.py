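"""Shared test oracle: exact posterior edge probabilities by enumeration.

Only usable at toy scale (2^V parent sets per vertex); the fixed-lambda
posterior factorizes over vertices, so each column is enumerated separately.
"""

import itertools

import numpy as np

from ssps.model import log_marginal_likelihood_vertex, log_prior_vertex


def enumerate_exact_edge_posterior(data, prior, lambdas):
    v = data.n_variables
    probs = np.zeros((v, v))
    subsets = list(
        itertools.chain.from_iterable(
            itertools.combinations(range(v), k) for k in range(v + 1)
        )
    )
    for j in range(v):
        weights = []
        for pa in subsets:
            z = np.zeros(v)
            z[list(pa)] = 1
            weights.append(
                log_marginal_likelihood_vertex(data, j, set(pa))
                + log_prior_vertex(z, prior.conf[:, j], lambdas[j])
            )
        w = np.exp(np.array(weights) - max(weights))
        w /= w.sum()
        for pa, wk in zip(subsets, w):
            for i in pa:
                probs[i, j] += wk
    return probs
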