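"""Synthetic prostate-cancer cohort generator.

Produces expression matrices, clinical tables and admixture (gamma) tables
with the statistical structure the downstream analysis assumes:

* a small number of latent subgroups, each over-activating a distinct block
  of control pathways (a constant shift, in within-sample SD units, on that
  subgroup's pathway genes);
* per-subgroup differentially expressed (DE) genes;
* per-sample admixture proportions gamma over latent expression signatures
  (Dirichlet rows summing to 1), one signature designated "DESNT"-like, with
  gamma-weighted effects on a dedicated block of genes;
* exponential time-to-recurrence whose log-hazard is additive in the
  subgroup effect and in the DESNT-like gamma, with independent exponential
  censoring tuned to an approximate target censoring rate.

Every draw flows from a single :class:`numpy.random.Generator` seeded from
``SimConfig.seed``, so identical configurations give bit-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateInputError
from .expression_io import GeneSet, write_expression, write_gmt

__all__ = ["SimConfig", "TruthLabels", "generate_cohort", "generate_signature_collection", "write_cohort"]

#: column name of the poor-prognosis latent signature in gamma tables
DESNT_COLUMN = "DESNT"

#: genes carrying each latent signature's gamma-weighted effect
GENES_PER_LATENT_SIGNATURE = 50

#: effect size (in noise-SD units) of a latent signature at gamma = 1
LATENT_EFFECT = 1.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults describe the reference study conditions: 300 samples, 2000
    genes, 14 disjoint 40-gene pathways, three subgroups separated by a
    one-SD activation shift, four latent admixture signatures (the first
    DESNT-like), exponential recurrence with a poor-prognosis subgroup-1
    hazard and a gamma-linked DESNT hazard, and ~50% censoring.
    """

    n_genes: int = 2000
    n_samples: int = 300
    n_pathways: int = 14
    genes_per_pathway: int = 40
    n_subgroups: int = 3
    activation_shift: float = 1.0
    n_latent_signatures: int = 4
    gamma_concentration: float = 0.5
    n_de_genes_per_subgroup: int = 100
    de_log2fc: float = 1.0
    baseline_hazard: float = 0.01
    subgroup_log_hazard: tuple[float, ...] = (1.2, 0.0, 0.3)
    desnt_gamma_log_hazard: float = 1.5
    censoring_rate: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_samples", "n_pathways", "genes_per_pathway",
                     "n_subgroups", "n_latent_signatures", "n_de_genes_per_subgroup"):
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be a positive integer")
        if self.genes_per_pathway * self.n_pathways > self.n_genes:
            raise ConfigError(
                "genes_per_pathway x n_pathways exceeds n_genes "
                f"({self.genes_per_pathway} x {self.n_pathways} > {self.n_genes})"
            )
        if len(self.subgroup_log_hazard) != self.n_subgroups:
            raise ConfigError(
                "subgroup_log_hazard must have one entry per subgroup "
                f"(got {len(self.subgroup_log_hazard)}, expected {self.n_subgroups})"
            )
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be positive")
        if not 0.0 < self.censoring_rate < 1.0:
            raise ConfigError("censoring_rate must lie strictly between 0 and 1")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.gamma_concentration <= 0:
            raise ConfigError("gamma_concentration must be positive")
        object.__setattr__(self, "subgroup_log_hazard", tuple(float(x) for x in self.subgroup_log_hazard))


@dataclass
class TruthLabels:
    """Ground truth of a simulated cohort.

    ``subgroup`` maps each sample to its generative subgroup (1-based);
    ``gamma_true`` is the samples x latent-signatures admixture table;
    ``de_genes`` the per-subgroup differentially expressed genes;
    ``pathway_sets`` the disjoint pathway definitions;
    ``active_pathways`` the pathway names over-activated in each subgroup;
    ``latent_genes`` the genes carrying each latent signature's effect.
    """

    subgroup: pd.Series
    gamma_true: pd.DataFrame
    de_genes: dict[int, list[str]]
    pathway_sets: list[GeneSet]
    active_pathways: dict[int, list[str]] = field(default_factory=dict)
    latent_genes: dict[str, list[str]] = field(default_factory=dict)

    def background_genes(self, all_genes: list[str]) -> list[str]:
        """Genes untouched by any simulated effect (pure noise rows)."""
        touched: set[str] = set()
        for gs in self.pathway_sets:
            touched |= gs.genes
        for genes in self.de_genes.values():
            touched |= set(genes)
        for genes in self.latent_genes.values():
            touched |= set(genes)
        return [g for g in all_genes if g not in touched]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:05d}" for i in range(1, n + 1)]


def _pathway_names(n: int) -> list[str]:
    return [f"PW{i:02d}" for i in range(1, n + 1)]


def _split_pathways(names: list[str], n_subgroups: int) -> dict[int, list[str]]:
    """Deal the pathway names into contiguous near-equal blocks, one per subgroup."""
    blocks = np.array_split(np.asarray(names, dtype=object), n_subgroups)
    return {g + 1: list(block) for g, block in enumerate(blocks)}


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, TruthLabels]:
    """Simulate one cohort.

    Returns the genes x samples expression matrix, the clinical table
    (index: sample ID; columns time [months], event, gleason, cohort) and
    the :class:`TruthLabels`.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    samples = _sample_ids(config.n_samples)
    pathways = _pathway_names(config.n_pathways)

    # disjoint pathway blocks at the start of the gene list
    pathway_sets = []
    for i, pw in enumerate(pathways):
        members = genes[i * config.genes_per_pathway:(i + 1) * config.genes_per_pathway]
        pathway_sets.append(GeneSet(name=pw, genes=frozenset(members)))
    n_pathway_genes = config.n_pathways * config.genes_per_pathway

    # near-balanced subgroup labels, shuffled
    base = np.tile(np.arange(1, config.n_subgroups + 1),
                   config.n_samples // config.n_subgroups + 1)[: config.n_samples]
    subgroup = pd.Series(rng.permutation(base), index=samples, name="subgroup")
    active = _split_pathways(pathways, config.n_subgroups)

    # DE genes: disjoint blocks immediately after the pathway genes
    free = genes[n_pathway_genes:]
    needed_de = config.n_subgroups * config.n_de_genes_per_subgroup
    n_latent_genes = config.n_latent_signatures * GENES_PER_LATENT_SIGNATURE
    if len(free) < needed_de + n_latent_genes:
        raise ConfigError(
            "n_genes too small for the requested pathway, DE and latent gene blocks"
        )
    de_genes = {
        g + 1: free[g * config.n_de_genes_per_subgroup:(g + 1) * config.n_de_genes_per_subgroup]
        for g in range(config.n_subgroups)
    }
    latent_names = [DESNT_COLUMN] + [f"LS{i}" for i in range(2, config.n_latent_signatures + 1)]
    latent_start = needed_de
    latent_genes = {
        name: free[latent_start + i * GENES_PER_LATENT_SIGNATURE:
                   latent_start + (i + 1) * GENES_PER_LATENT_SIGNATURE]
        for i, name in enumerate(latent_names)
    }

    # gamma admixture rows
    gamma = rng.dirichlet([config.gamma_concentration] * config.n_latent_signatures,
                          size=config.n_samples)
    gamma_true = pd.DataFrame(gamma, index=samples, columns=latent_names)

    # expression: Gaussian noise + activation shifts + DE shifts + gamma effects
    X = rng.normal(0.0, config.noise_sd, size=(config.n_genes, config.n_samples))
    gene_pos = {g: i for i, g in enumerate(genes)}
    shift = config.activation_shift * config.noise_sd
    pw_members = {gs.name: sorted(gs.genes) for gs in pathway_sets}
    for g in range(1, config.n_subgroups + 1):
        cols = np.flatnonzero((subgroup == g).to_numpy())
        rows = [gene_pos[gid] for pw in active[g] for gid in pw_members[pw]]
        X[np.ix_(rows, cols)] += shift
        de_rows = [gene_pos[gid] for gid in de_genes[g]]
        X[np.ix_(de_rows, cols)] += config.de_log2fc
    for name, lg in latent_genes.items():
        rows = [gene_pos[gid] for gid in lg]
        X[rows, :] += LATENT_EFFECT * config.noise_sd * gamma_true[name].to_numpy()[None, :]
    expr = pd.DataFrame(X.copy(), index=genes, columns=samples)

    # survival: exponential event times, independent exponential censoring
    log_hazard = (np.log(config.baseline_hazard)
                  + np.asarray(config.subgroup_log_hazard)[subgroup.to_numpy() - 1]
                  + config.desnt_gamma_log_hazard * gamma_true[DESNT_COLUMN].to_numpy())
    hazard = np.exp(log_hazard)
    event_time = rng.exponential(1.0 / hazard)
    # P(censored) = lc / (lc + hazard) per sample; tune lc against mean hazard
    lc = config.censoring_rate / (1.0 - config.censoring_rate) * hazard.mean()
    censor_time = rng.exponential(1.0 / lc, size=config.n_samples)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    gleason = _simulate_gleason(rng, subgroup.to_numpy(), config.n_subgroups)
    clinical = pd.DataFrame(
        {"time": time, "event": event, "gleason": gleason, "cohort": "SIM"},
        index=pd.Index(samples, name="sample_id"),
    )

    truth = TruthLabels(
        subgroup=subgroup,
        gamma_true=gamma_true,
        de_genes=de_genes,
        pathway_sets=pathway_sets,
        active_pathways=active,
        latent_genes=latent_genes,
    )
    return expr, clinical, truth


# Gleason 6..10 probabilities: poor-prognosis subgroup 1 skews high grade
_GLEASON_POOR = np.array([0.05, 0.15, 0.30, 0.30, 0.20])
_GLEASON_GOOD = np.array([0.25, 0.35, 0.25, 0.10, 0.05])
_GLEASON_MID = np.array([0.15, 0.30, 0.30, 0.15, 0.10])


def _simulate_gleason(rng: np.random.Generator, subgroup: np.ndarray, n_subgroups: int) -> np.ndarray:
    probs = {1: _GLEASON_POOR}
    for g in range(2, n_subgroups + 1):
        probs[g] = _GLEASON_MID if g % 2 else _GLEASON_GOOD
    out = np.empty(len(subgroup), dtype=int)
    for g in range(1, n_subgroups + 1):
        idx = np.flatnonzero(subgroup == g)
        out[idx] = rng.choice(np.arange(6, 11), size=len(idx), p=probs[g])
    return out


def generate_signature_collection(
    truth: TruthLabels,
    config: SimConfig,
    overlap_fraction: float,
    seed: int,
    set_sizes: tuple[int, ...] = (40, 40),
) -> list[GeneSet]:
    """Build a catalogue of prognostic-signature stand-ins.

    For each subgroup and each requested set size, a signature is sampled
    without replacement: ``round(overlap_fraction * size)`` genes from that
    subgroup's DE pool and the remainder from background (non-DE,
    non-pathway) genes.  Signatures sharing a subgroup pool therefore
    "converge" by construction, while signatures of different subgroups (or
    with ``overlap_fraction = 0``) overlap only at the hypergeometric null
    rate.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ConfigError("overlap_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    all_genes = _gene_ids(config.n_genes)
    background = truth.background_genes(all_genes)
    sets: list[GeneSet] = []
    for g in sorted(truth.de_genes):
        pool = list(truth.de_genes[g])
        if not pool:
            raise DegenerateInputError(f"subgroup {g} has an empty DE-gene pool")
        for j, size in enumerate(set_sizes):
            k = int(round(overlap_fraction * size))
            if k > len(pool):
                raise ConfigError(
                    f"requested {k} DE genes from a pool of {len(pool)} (subgroup {g})"
                )
            if size - k > len(background):
                raise ConfigError("background gene pool too small for requested set size")
            de_part = rng.choice(pool, size=k, replace=False) if k else np.array([], dtype=object)
            bg_part = (rng.choice(background, size=size - k, replace=False)
                       if size > k else np.array([], dtype=object))
            name = f"SIG_SG{g}_{chr(ord('A') + j)}"
            sets.append(GeneSet(name=name, genes=frozenset(map(str, [*de_part, *bg_part]))))
    return sets


def write_cohort(out_dir, config: SimConfig, overlap_fraction: float = 0.6) -> None:
    """Simulate a cohort and write all its artefacts under ``out_dir``.

    Writes expression.tsv, clinical.tsv, gamma.tsv, pathways.gmt,
    signatures.gmt and truth.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, clinical, truth = generate_cohort(config)
    write_expression(expr, out / "expression.tsv")
    clinical.to_csv(out / "clinical.tsv", sep="\t")
    truth.gamma_true.rename_axis("sample_id").to_csv(out / "gamma.tsv", sep="\t", float_format="%.10g")
    write_gmt(truth.pathway_sets, out / "pathways.gmt")
    signatures = generate_signature_collection(truth, config, overlap_fraction, seed=config.seed + 1)
    write_gmt(signatures, out / "signatures.gmt")
    payload = {
        "config": asdict(config),
        "subgroup": truth.subgroup.to_dict(),
        "de_genes": {str(k): v for k, v in truth.de_genes.items()},
        "active_pathways": {str(k): v for k, v in truth.active_pathways.items()},
        "latent_genes": truth.latent_genes,
    }
    with open(out / "truth.json", "w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=1)
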