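"""Synthetic two-group microarray experiments with known ground truth.

Emulates the statistical shape of a small two-color-free rodent microarray
study: a few thousand genes, two small treatment arms, log-normal-scale
intensities, gene-wise variances drawn from a scaled inverse-chi-square
prior (the exchangeability model the moderated t-test assumes), a minority
of genes differentially expressed with a fixed log2 effect, signal
concentrated in designated gene sets, decoy sets that overlap the signal
sets, and a preferential-attachment interactome with STRING-style integer
confidence scores.

Everything is driven by one :class:`SimulationConfig`; identical config
(including seed) yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import CONTROL, TREATED, ExpressionMatrix, InputError, ProbeAnnotation

logger = logging.getLogger("pathrank.synthetic_data")


class ConfigError(InputError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults describe the study conditions downstream stages are exercised
    under: 2000 genes, 5 animals per arm, variance prior
    inverse-chi-square(d0=4, s0sq=0.05) on the log2 scale, 10% of genes
    differentially expressed at |log2 FC| = 2, one signal gene set with 80%
    DE members plus a fully overlapping decoy among 20 sets, and a
    preferential-attachment interactome averaging ~6 partners per gene.
    """

    n_genes: int = 2000
    n_probes_per_gene: int = 1
    n_per_group: int = 5
    prior_df_d0: float = 4.0
    prior_var_s0sq: float = 0.05
    de_fraction: float = 0.1
    effect_size: float = 2.0
    n_sets: int = 20
    set_size_range: tuple[int, int] = (10, 50)
    n_signal_sets: int = 1
    n_decoy_overlap_sets: int = 1
    overlap_fraction: float = 1.0
    signal_de_fraction: float = 0.8
    interactome_edges_per_node: float = 3.0
    probe_noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_probes_per_gene": self.n_probes_per_gene,
            "n_per_group": self.n_per_group,
        }
        for name, v in counts.items():
            if v < 1:
                raise ConfigError(f"{name} must be >= 1, got {v}")
        for name, v in {"n_sets": self.n_sets, "n_signal_sets": self.n_signal_sets,
                        "n_decoy_overlap_sets": self.n_decoy_overlap_sets}.items():
            if v < 0:
                raise ConfigError(f"{name} must be >= 0, got {v}")
        for name, v in {"prior_df_d0": self.prior_df_d0,
                        "prior_var_s0sq": self.prior_var_s0sq,
                        "interactome_edges_per_node": self.interactome_edges_per_node,
                        }.items():
            if not v > 0:
                raise ConfigError(f"{name} must be > 0, got {v}")
        for name, v in {"de_fraction": self.de_fraction,
                        "overlap_fraction": self.overlap_fraction,
                        "signal_de_fraction": self.signal_de_fraction}.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.set_size_range
        if lo < 2 or hi < lo:
            raise ConfigError(f"invalid set_size_range {self.set_size_range}")
        if self.n_signal_sets + self.n_decoy_overlap_sets > self.n_sets:
            raise ConfigError("signal + decoy sets exceed n_sets")
        if self.n_signal_sets > 0 and self.de_fraction * self.n_genes < 1:
            raise ConfigError(
                "signal sets requested but de_fraction * n_genes < 1: "
                "no DE genes available to carry the signal"
            )

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one of the named substreams."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class SyntheticTruth:
    """Ground truth recorded during generation.

    ``de_genes`` maps each differentially expressed gene to its signed log2
    effect (treated minus control); ``decoy_sets`` maps each decoy set id to
    the signal set it overlaps; ``gene_variances`` records the true
    gene-wise variances drawn from the prior.
    """

    genes: list[str]
    de_genes: dict[str, float] = field(default_factory=dict)
    gene_variances: dict[str, float] = field(default_factory=dict)
    signal_sets: list[str] = field(default_factory=list)
    decoy_sets: dict[str, str] = field(default_factory=dict)

    def non_de_genes(self) -> list[str]:
        return [g for g in self.genes if g not in self.de_genes]

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)


def gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:06d}" for i in range(n)]


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def generate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ProbeAnnotation, SyntheticTruth]:
    """Simulate a raw-intensity table plus its probe annotation and truth.

    Gene-wise true variances are drawn as ``s0sq * d0 / chi2(d0)``; sample
    intensities on the log2 scale are normal around the gene baseline, with
    treated means shifted by the signed effect for DE genes.  With
    ``n_probes_per_gene > 1`` every probe repeats the gene value with
    independent N(0, probe_noise_sd^2) noise.  Values are returned on the
    raw intensity scale (2^x) so the pipeline's log2 step applies.
    """
    rng = config.rng(1)
    genes = gene_ids(config.n_genes)
    n = config.n_genes
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    variances = (
        config.prior_var_s0sq * config.prior_df_d0 / rng.chisquare(config.prior_df_d0, size=n)
    )

    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    effect = np.zeros(n)
    effect[de_idx] = signs * config.effect_size

    k = config.n_per_group
    sd = np.sqrt(variances)[:, None]
    treated = baseline[:, None] + effect[:, None] + rng.normal(0.0, 1.0, (n, k)) * sd
    control = baseline[:, None] + rng.normal(0.0, 1.0, (n, k)) * sd
    log2_vals = np.hstack([treated, control])
    sample_ids = [f"T{i + 1:02d}" for i in range(k)] + [f"C{i + 1:02d}" for i in range(k)]
    group_of = {s: (TREATED if s.startswith("T") else CONTROL) for s in sample_ids}

    npp = config.n_probes_per_gene
    if npp > 1:
        rep = np.repeat(log2_vals, npp, axis=0)
        rep = rep + rng.normal(0.0, config.probe_noise_sd, rep.shape)
        row_ids = [f"P_{g}_{j + 1:02d}" for g in genes for j in range(npp)]
        probe_to_gene = {f"P_{g}_{j + 1:02d}": g for g in genes for j in range(npp)}
        log2_vals = rep
    else:
        row_ids = genes
        probe_to_gene = {g: g for g in genes}

    values = pd.DataFrame(np.power(2.0, log2_vals), index=row_ids, columns=sample_ids)
    matrix = ExpressionMatrix(values=values, group_of=group_of)
    truth = SyntheticTruth(
        genes=genes,
        de_genes={genes[i]: float(effect[i]) for i in de_idx},
        gene_variances={g: float(v) for g, v in zip(genes, variances)},
    )
    return matrix, ProbeAnnotation(probe_to_gene=probe_to_gene), truth


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def generate_genesets(config: SimulationConfig, truth: SyntheticTruth):
    """Build a gene-set collection with signal, decoy and background sets.

    Signal sets take ``signal_de_fraction`` of their members from the DE
    genes; each decoy takes ``overlap_fraction`` of its parent signal set's
    members and pads with non-DE filler; the rest are uniform draws from the
    non-DE pool.  The set ids of signal and decoy sets are recorded on the
    truth object.
    """
    from .gsea import GeneSet, GeneSetCollection

    rng = config.rng(2)
    lo, hi = config.set_size_range
    if hi > config.n_genes:
        raise ConfigError(
            f"set_size_range {config.set_size_range} exceeds universe of "
            f"{config.n_genes} genes"
        )
    de_pool = sorted(truth.de_genes)
    non_de = truth.non_de_genes()
    sets: dict[str, GeneSet] = {}

    def sample(pool: list[str], size: int, exclude: set[str] = frozenset()) -> list[str]:
        avail = [g for g in pool if g not in exclude]
        size = min(size, len(avail))
        idx = rng.choice(len(avail), size=size, replace=False)
        return [avail[i] for i in sorted(idx)]

    signal_members: dict[str, list[str]] = {}
    truth.signal_sets = []
    truth.decoy_sets = {}
    for i in range(config.n_signal_sets):
        size = int(rng.integers(lo, hi + 1))
        n_sig = max(1, int(round(config.signal_de_fraction * size)))
        members = sample(de_pool, n_sig)
        members += sample(non_de, size - len(members), exclude=set(members))
        sid = f"signal_{i + 1:02d}"
        sets[sid] = GeneSet(sid, f"signal set {i + 1}", "synthetic", frozenset(members))
        signal_members[sid] = members
        truth.signal_sets.append(sid)

    for i in range(config.n_decoy_overlap_sets):
        parent = truth.signal_sets[i % config.n_signal_sets]
        pmembers = signal_members[parent]
        n_overlap = int(round(config.overlap_fraction * len(pmembers)))
        members = sample(pmembers, n_overlap)
        # filler scales with the overlap portion: enough dilution that the
        # decoy is never an exact duplicate of its parent (and loses to it
        # in a head-to-head ranking), little enough that the decoy still
        # reaches significance through the shared genes
        n_filler = max(2, -(-n_overlap // 2))
        members += sample(non_de, n_filler, exclude=set(members))
        did = f"decoy_{i + 1:02d}"
        sets[did] = GeneSet(did, f"decoy of {parent}", "synthetic", frozenset(members))
        truth.decoy_sets[did] = parent

    n_background = config.n_sets - config.n_signal_sets - config.n_decoy_overlap_sets
    for i in range(n_background):
        size = int(rng.integers(lo, hi + 1))
        members = sample(non_de, size)
        rid = f"random_{i + 1:03d}"
        sets[rid] = GeneSet(rid, f"background set {i + 1}", "synthetic", frozenset(members))

    return GeneSetCollection(sets=sets)


# ---------------------------------------------------------------------------
# Interactome
# ---------------------------------------------------------------------------

def generate_interactome(config: SimulationConfig, truth: SyntheticTruth) -> nx.Graph:
    """Preferential-attachment interactome over the gene universe.

    Hubs arise naturally so betweenness rankings are non-degenerate; each
    edge carries a uniform integer ``combined_score`` in [150, 999],
    spanning STRING's low-to-highest-confidence range.
    """
    if config.n_genes < 2:
        raise ConfigError("interactome needs at least 2 genes")
    rng = config.rng(3)
    m = max(1, int(round(config.interactome_edges_per_node)))
    m = min(m, config.n_genes - 1)
    nx_seed = int(np.random.SeedSequence([config.seed, 3]).generate_state(1)[0] % (2**31))
    graph = nx.barabasi_albert_graph(config.n_genes, m, seed=nx_seed)
    perm = rng.permutation(config.n_genes)
    mapping = {i: truth.genes[perm[i]] for i in graph.nodes}
    graph = nx.relabel_nodes(graph, mapping)
    edges = sorted(tuple(sorted(e)) for e in graph.edges)
    scores = rng.integers(150, 1000, size=len(edges))
    out = nx.Graph()
    out.add_nodes_from(sorted(graph.nodes))
    for (u, v), s in zip(edges, scores):
        out.add_edge(u, v, combined_score=int(s))
    return out


def write_interactome(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node1\tnode2\tcombined_score\n")
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{u}\t{v}\t{graph.edges[u, v]['combined_score']}\n")
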