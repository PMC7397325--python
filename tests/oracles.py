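"""Independent oracle implementations used by the test suite.

These deliberately avoid the package's own code paths (and lifelines):
straightforward formula evaluation / enumeration, vectorised only over
permutations.
"""

import itertools

import numpy as np


def two_group_logrank_statistic(times, events, group):
    """Textbook O-E chi-square for two groups, Efron-free, from scratch."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group, dtype=int)
    order = np.argsort(times, kind="stable")
    times, events, group = times[order], events[order], group[order]
    U = V = 0.0
    n = len(times)
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n_r = at_risk.sum()
        n1_r = (at_risk & (group == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == 1)).sum()
        U += d1 - d * n1_r / n_r
        if n_r > 1:
            V += d * (n1_r / n_r) * (1 - n1_r / n_r) * (n_r - d) / (n_r - 1)
    return U * U / V if V > 0 else 0.0


def logrank_permutation_p(times, events, group, n_perm, seed):
    """Monte-Carlo permutation p-value of the two-group log-rank statistic.

    Vectorised for the fully-observed, distinct-times case: with subjects
    sorted by time, U = sum(z_i - n1r_i / Nr_i) and
    V = sum(n1r_i (Nr_i - n1r_i) / Nr_i^2) where n1r is the group-1 at-risk
    count just before each event.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group, dtype=int)
    assert events.all() and len(np.unique(times)) == len(times), \
        "fast oracle assumes no censoring and distinct times"
    order = np.argsort(times)
    z_obs = group[order]
    n = len(times)
    n1 = int(group.sum())
    nr = n - np.arange(n)  # at risk before each event

    def chi2(Z):
        # Z: (B, n) permuted group indicators sorted by time
        n1r = n1 - np.concatenate(
            [np.zeros((Z.shape[0], 1)), np.cumsum(Z, axis=1)[:, :-1]], axis=1)
        U = (Z - n1r / nr).sum(axis=1)
        V = (n1r * (nr - n1r) / nr**2).sum(axis=1)
        return np.where(V > 0, U * U / V, 0.0)

    obs = chi2(z_obs[None, :])[0]
    rng = np.random.default_rng(seed)
    count = 0
    chunk = 10_000
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        idx = rng.permuted(np.tile(np.arange(n), (b, 1)), axis=1)
        Z = np.take_along_axis(np.tile(z_obs, (b, 1)), idx, axis=1)
        count += int((chi2(Z) >= obs - 1e-12).sum())
        done += b
    return obs, (count + 1) / (n_perm + 1)


def hypergeom_tail_enumeration(N, m, n, k):
    """P(overlap >= k) over all C(N, n) draws, by exhaustive enumeration."""
    universe = list(range(N))
    a = set(universe[:m])
    total = hits = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        hits += len(a & set(draw)) >= k
    return hits / total


def pathway_zscore_loop(matrix, gene_set, sample):
    """Loop-based activation z-score, independent of the vectorised path."""
    values = [matrix.at[g, sample] for g in matrix.index]
    in_set = [matrix.at[g, sample] for g in matrix.index if g in gene_set.genes]
    mean_all = sum(values) / len(values)
    var = sum((v - mean_all) ** 2 for v in values) / (len(values) - 1)
    mean_set = sum(in_set) / len(in_set)
    return (mean_set - mean_all) / (var ** 0.5 / len(in_set) ** 0.5)
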