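"""Shared independent oracles for the test suite."""

import numpy as np


def pairwise_t_stats(y, groups, names):
    """|t| for every pair of groups using the pooled within-group variance."""
    stats = {}
    samples = {g: y[groups == g] for g in names}
    df = sum(len(s) - 1 for s in samples.values())
    pooled = sum((len(s) - 1) * s.var(ddof=1) for s in samples.values()) / df
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            se = np.sqrt(pooled * (1 / len(samples[a]) + 1 / len(samples[b])))
            stats[(a, b)] = abs(samples[a].mean() - samples[b].mean()) / se
    return stats


def permutation_max_t(y, groups, n_perm, rng):
    """Independent max-|t| permutation reference for all-pairs adjusted p.

    For each permutation of the outcome vector the maximum pairwise |t| is
    recorded; a pair's adjusted p is the fraction of permutations whose
    max-|t| reaches the pair's observed |t| — the resampling analogue of the
    studentized-range family-wise adjustment.
    """
    names = sorted(np.unique(groups).tolist())
    observed = pairwise_t_stats(y, groups, names)
    max_null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(y)
        max_null[i] = max(pairwise_t_stats(perm, groups, names).values())
    return {
        pair: float((max_null >= t_obs - 1e-12).mean())
        for pair, t_obs in observed.items()
    }
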