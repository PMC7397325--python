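"""Overlap, differential-expression and enrichment statistics for signatures.

* Hypergeometric upper-tail tests of the overlap between two gene sets
  restricted to an explicit universe (the observed overlap k against sets of
  sizes m and n drawn from N genes), computed on the log scale so that
  p-values far below 1e-300 survive.
* Moderated-t differential expression, one-vs-rest per subgroup, with the
  per-gene variance shrunk toward an empirical-Bayes prior whose scale and
  degrees of freedom are estimated by the method of moments on the
  log-variances; genes are called significant when the Benjamini–Hochberg
  adjusted p-value and a linear fold-change filter both pass.
* A sample-level GSEA: the weighted Kolmogorov–Smirnov running-sum
  enrichment score of a sample set along a continuous ranking (e.g. cancers
  ranked by DESNT gamma), with a permutation p-value over random member
  sets of equal size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DegenerateInputError
from .expression_io import GeneSet
from .nnmf_subgrouping import SubgroupAssignment

__all__ = [
    "OverlapResult",
    "DEResult",
    "hypergeom_overlap",
    "pairwise_overlap_matrix",
    "moderated_t_de",
    "bh_adjust",
    "gsea_enrichment",
]


@dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric overlap of two gene sets within a universe."""

    set_a_name: str
    set_b_name: str
    k: int
    m: int
    n: int
    N: int
    p: float
    #: log10 of the upper-tail probability; exact even where p underflows
    log10_p: float = 0.0


def _universe_genes(universe) -> frozenset[str]:
    if isinstance(universe, GeneSet):
        return universe.genes
    return frozenset(universe)


def hypergeom_overlap(a: GeneSet, b: GeneSet, universe) -> OverlapResult:
    """Upper-tail probability of the observed overlap between ``a`` and ``b``.

    Both sets are intersected with the universe first; p = P(X >= k) for
    X ~ Hypergeometric(N, m, n), evaluated in log space.
    """
    U = _universe_genes(universe)
    if not U:
        raise DegenerateInputError("universe is empty")
    ga, gb = a.genes & U, b.genes & U
    if not ga or not gb:
        empty = a.name if not ga else b.name
        raise DegenerateInputError(
            f"set {empty!r} has no genes inside the universe"
        )
    k, m, n, N = len(ga & gb), len(ga), len(gb), len(U)
    if k == 0:
        p, log10_p = 1.0, 0.0
    else:
        log_p = float(stats.hypergeom.logsf(k - 1, N, m, n))
        log10_p = log_p / np.log(10.0)
        # p itself may underflow; keep it strictly positive (log10_p is exact)
        p = min(float(np.exp(log_p)), 1.0) or 5e-324
    return OverlapResult(a.name, b.name, k=k, m=m, n=n, N=N, p=p, log10_p=log10_p)


def pairwise_overlap_matrix(sets: Sequence[GeneSet], universe) -> pd.DataFrame:
    """All pairwise overlap tests as a long-form symmetric table.

    Self-pairs are reported with k = m.  Columns: set_a, set_b, k, m, n, N, p.
    """
    if len(sets) < 2:
        raise ConfigError("pairwise overlap requires at least two sets")
    rows = []
    for i, a in enumerate(sets):
        for j, b in enumerate(sets):
            if j < i:
                continue
            r = hypergeom_overlap(a, b, universe)
            rows.append(r)
            if j > i:
                rows.append(OverlapResult(r.set_b_name, r.set_a_name,
                                          k=r.k, m=r.n, n=r.m, N=r.N,
                                          p=r.p, log10_p=r.log10_p))
    out = pd.DataFrame([vars(r) for r in rows])
    return out.rename(columns={"set_a_name": "set_a", "set_b_name": "set_b"})


def bh_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ConfigError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior_variance(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Empirical-Bayes prior (d0, s0^2) for gene variances.

    Moment-matches the log-variances against a scaled F distribution: with
    e = log(s^2) - digamma(df/2) + log(df/2), the excess variance of e over
    trigamma(df/2) determines the prior degrees of freedom d0, and its mean
    determines the prior scale s0^2.  d0 is floored at 1 and capped at 1e6
    (effectively infinite shrinkage when gene variances are homogeneous).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return 1e6, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        d0 = 1e6
    else:
        d0 = float(np.clip(2.0 * _trigamma_inverse(evar), 1.0, 1e6))
    s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


@dataclass
class DEResult:
    """Per-gene moderated-t statistics and per-subgroup significant lists."""

    table: pd.DataFrame
    significant: dict
    prior: dict
    fdr_threshold: float
    fc_threshold: float


def moderated_t_de(matrix: pd.DataFrame, labels: SubgroupAssignment | pd.Series,
                   fdr_threshold: float = 0.001, fc_threshold: float = 1.4,
                   prior_df: float | None = None) -> DEResult:
    """One-vs-rest moderated-t differential expression per subgroup.

    ``matrix`` holds log2-scale expression (genes x samples); the log2 fold
    change is the difference of group means.  BH adjustment is applied
    within each one-vs-rest contrast.  ``prior_df`` overrides the estimated
    prior degrees of freedom (0 recovers the ordinary two-sample pooled t).
    Genes are significant when adjusted p < ``fdr_threshold`` and the linear
    fold change exceeds ``fc_threshold`` (|log2FC| > log2(fc_threshold)).
    """
    y = labels.labels if isinstance(labels, SubgroupAssignment) else labels
    y = y.loc[[s for s in matrix.columns if s in y.index]]
    if len(y) != matrix.shape[1]:
        missing = set(matrix.columns) - set(y.index)
        raise ConfigError(f"samples without labels: {sorted(missing)[:5]}")
    groups = sorted(pd.unique(y))
    counts = y.value_counts()
    small = [g for g in groups if counts[g] < 3]
    if small:
        raise ConfigError(f"subgroup(s) with fewer than 3 samples: {small}")
    X = matrix.to_numpy(dtype=float)
    tables = []
    significant: dict = {}
    prior: dict = {}
    log_fc_cut = np.log2(fc_threshold)
    for g in groups:
        in_g = (y == g).to_numpy()
        n1, n2 = int(in_g.sum()), int((~in_g).sum())
        m1, m2 = X[:, in_g].mean(axis=1), X[:, ~in_g].mean(axis=1)
        v1 = X[:, in_g].var(axis=1, ddof=1)
        v2 = X[:, ~in_g].var(axis=1, ddof=1)
        df = n1 + n2 - 2
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        if prior_df is None:
            d0, s02 = estimate_prior_variance(s2, df)
        else:
            d0 = float(prior_df)
            _, s02 = estimate_prior_variance(s2, df)
        if d0 > 0:
            s2_mod = (d0 * s02 + df * s2) / (d0 + df)
        else:
            s2_mod = s2
        se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, (m1 - m2) / se, 0.0)
        total_df = min(d0 + df, 1e6)
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
        adj = bh_adjust(p)
        log2fc = m1 - m2
        sig = (adj < fdr_threshold) & (np.abs(log2fc) > log_fc_cut)
        tab = pd.DataFrame({
            "subgroup": g,
            "gene": matrix.index,
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "adj_p": adj,
            "significant": sig,
        })
        tables.append(tab)
        significant[g] = list(matrix.index[sig])
        prior[g] = {"d0": d0, "s0_sq": s02, "residual_df": df}
    return DEResult(table=pd.concat(tables, ignore_index=True),
                    significant=significant, prior=prior,
                    fdr_threshold=fdr_threshold, fc_threshold=fc_threshold)


def gsea_enrichment(scores: pd.Series, member_set: Iterable[str], n_perm: int = 10000,
                    seed: int = 0, weight: float = 1.0) -> tuple[float, float]:
    """Enrichment of a sample set at one end of a continuous ranking.

    Items are ranked by decreasing score; the running sum gains
    |score|^weight (normalised) at members and loses 1/(N - Nh) at
    non-members.  The enrichment score ES is the signed extreme deviation of
    the running sum.  The p-value is the fraction of ``n_perm`` random
    member sets of equal size whose |ES| reaches |ES|, with a +1
    pseudo-count on both numerator and denominator.
    """
    members = frozenset(member_set)
    items = scores.index
    if not members:
        raise DegenerateInputError("member set is empty")
    if not members <= set(items):
        raise ConfigError("member set contains items absent from the ranking")
    if members >= set(items):
        raise DegenerateInputError("member set covers the whole ranking")
    order = np.argsort(-scores.to_numpy(), kind="stable")
    ranked_items = items.to_numpy()[order]
    ranked_scores = scores.to_numpy()[order]
    hit = np.isin(ranked_items, list(members))
    es = _ks_running_score(ranked_scores, hit, weight)
    rng = np.random.default_rng(seed)
    n, nh = len(ranked_items), int(hit.sum())
    exceed = 0
    for _ in range(n_perm):
        perm_hit = np.zeros(n, dtype=bool)
        perm_hit[rng.choice(n, size=nh, replace=False)] = True
        if abs(_ks_running_score(ranked_scores, perm_hit, weight)) >= abs(es):
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return float(es), float(p)


def _ks_running_score(ranked_scores: np.ndarray, hit: np.ndarray, weight: float) -> float:
    w = np.abs(ranked_scores) ** weight if weight != 0 else np.ones_like(ranked_scores)
    hit_w = np.where(hit, w, 0.0)
    total_hit = hit_w.sum()
    if total_hit == 0:
        return 0.0
    n_miss = (~hit).sum()
    running = np.cumsum(hit_w / total_hit - np.where(hit, 0.0, 1.0 / n_miss))
    return float(running[np.argmax(np.abs(running))])
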