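"""Synthetic study generator.

Emulates, with planted group-level effects, the inputs of a gene-set
conservation comparison: a target and a non-target gene set, a
Pfam-style family map, a BioMart-style ortholog table with dN/dS over
a species panel, paired human/ortholog protein sequences, and an
HPRD-style undirected PPI network.

Planted effects (all configurable):

* per-row omega = dN/dS drawn log-normal with a group-specific log
  mean (log 0.10 targets vs log 0.13 non-targets by default), and
  dN = omega * dS so the extracted ratio recovers omega exactly;
* per-species one-to-one ortholog presence probability (0.9 vs 0.75);
* ortholog sequences derived from the human sequence by independent
  per-site substitution with probability min(0.95, divergence_scale *
  omega), so conservation scores degrade with omega;
* Chung-Lu expected-degree network with group degree propensities
  (3:1) plus triad closures around target nodes to raise their
  clustering.

Each sub-generator consumes its own pseudo-random stream spawned from
the master seed, so enabling or resizing one component does not
perturb the others.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import AMINO_ACIDS
from .genesets import FamilyMap, GeneSet
from .netmetrics import InteractionNetwork
from .orthology import ONE2ONE, SPECIES_PANEL, OrthologTable

__all__ = [
    "SimConfig",
    "SyntheticStudy",
    "simulate_orthology",
    "simulate_sequences",
    "simulate_network",
    "simulate_families",
    "simulate_study",
]

#: Species whose sequence pairs are generated by default (the alignment
#: stage is the expensive one, so it runs on a 5-species subset).
DEFAULT_SEQUENCE_SPECIES: tuple[str, ...] = ("amel", "btau", "cfam", "cjac", "cpor")


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    n_targets: int = 300
    n_nontargets: int = 900
    species: tuple[str, ...] = SPECIES_PANEL
    seed: int = 0
    # evolutionary-rate effect: log-normal omega, group log-means
    omega_logmean_target: float = math.log(0.10)
    omega_logmean_nontarget: float = math.log(0.13)
    omega_logsd: float = 0.8
    # synonymous rate distribution (shared between groups)
    ds_logmean: float = math.log(0.5)
    ds_logsd: float = 0.4
    # ortholog-presence effect
    ortholog_prob_target: float = 0.9
    ortholog_prob_nontarget: float = 0.75
    one2many_prob: float = 0.05
    missing_rate: float = 0.02
    # sequence divergence
    seq_len_range: tuple[int, int] = (80, 200)
    divergence_scale: float = 2.0
    sequence_species: tuple[str, ...] = DEFAULT_SEQUENCE_SPECIES
    # network effect
    degree_weight_target: float = 3.0
    degree_weight_nontarget: float = 1.0
    mean_degree: float = 8.0
    triad_closure_prob: float = 0.2
    # family structure
    n_families: int = 150
    family_overlap: float = 0.1

    def __post_init__(self) -> None:
        if self.n_targets <= 0 or self.n_nontargets <= 0 or self.n_families <= 0:
            raise ValueError("counts must be positive")
        for name in (
            "ortholog_prob_target", "ortholog_prob_nontarget",
            "one2many_prob", "missing_rate", "triad_closure_prob", "family_overlap",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if len(set(self.species)) != len(self.species) or not all(self.species):
            raise ValueError("species codes must be unique and non-empty")
        lo, hi = self.seq_len_range
        if lo < 20 or hi < lo:
            raise ValueError("seq_len_range must satisfy 20 <= min <= max")
        if self.divergence_scale < 0:
            raise ValueError("divergence_scale must be non-negative")
        if self.degree_weight_target <= 0 or self.degree_weight_nontarget <= 0:
            raise ValueError("degree weights must be positive")
        if self.mean_degree <= 0:
            raise ValueError("mean_degree must be positive")
        unknown = set(self.sequence_species) - set(self.species)
        if unknown:
            raise ValueError(f"sequence_species not in the species panel: {sorted(unknown)}")
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "sequence_species", tuple(self.sequence_species))
        object.__setattr__(self, "seq_len_range", tuple(self.seq_len_range))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["species"] = list(self.species)
        d["sequence_species"] = list(self.sequence_species)
        d["seq_len_range"] = list(self.seq_len_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("species", "sequence_species", "seq_len_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def target_ids(self) -> list[str]:
        return [f"T{i:05d}" for i in range(1, self.n_targets + 1)]

    def nontarget_ids(self) -> list[str]:
        return [f"N{i:05d}" for i in range(1, self.n_nontargets + 1)]


@dataclass(frozen=True)
class SyntheticStudy:
    """One complete simulated data set."""

    config: SimConfig
    target_genes: GeneSet
    nontarget_genes: GeneSet
    family_map: FamilyMap
    ortholog_table: OrthologTable
    #: species -> gene -> (human residues, ortholog residues)
    sequence_pairs: dict[str, dict[str, tuple[str, str]]]
    network: InteractionNetwork


def _streams(config: SimConfig) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(4)
    names = ("orthology", "sequences", "network", "families")
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def simulate_orthology(config: SimConfig, rng: np.random.Generator) -> OrthologTable:
    """Ortholog rows per (gene, species) with group-planted omega and presence."""
    frames = []
    groups = [
        (config.target_ids(), config.ortholog_prob_target, config.omega_logmean_target),
        (config.nontarget_ids(), config.ortholog_prob_nontarget, config.omega_logmean_nontarget),
    ]
    for species in config.species:
        for gene_ids, p_present, logmean in groups:
            n = len(gene_ids)
            u = rng.random(n)
            u2 = rng.random(n)
            omega = rng.lognormal(mean=logmean, sigma=config.omega_logsd, size=n)
            ds = rng.lognormal(mean=config.ds_logmean, sigma=config.ds_logsd, size=n)
            miss = rng.random(n) < config.missing_rate
            miss_which = rng.random(n) < 0.5  # True: drop dn, False: drop ds
            is_one2one = u < p_present
            is_one2many = ~is_one2one & (u2 < config.one2many_prob)
            emit = is_one2one | is_one2many
            if not emit.any():
                continue
            dn = omega * ds
            dn = np.where(miss & miss_which, np.nan, dn)
            ds_out = np.where(miss & ~miss_which, np.nan, ds)
            idx = np.flatnonzero(emit)
            frames.append(
                pd.DataFrame(
                    {
                        "human_gene": [gene_ids[i] for i in idx],
                        "species": species,
                        "ortholog_gene": [f"{species}_{gene_ids[i]}" for i in idx],
                        "homology_type": np.where(
                            is_one2one[idx], ONE2ONE, "ortholog_one2many"
                        ),
                        "dn": dn[idx],
                        "ds": ds_out[idx],
                    }
                )
            )
    if not frames:
        df = pd.DataFrame(
            columns=["human_gene", "species", "ortholog_gene", "homology_type", "dn", "ds"]
        )
        df["dn"] = df["dn"].astype(float)
        df["ds"] = df["ds"].astype(float)
        return OrthologTable(df)
    return OrthologTable(pd.concat(frames, ignore_index=True))


def simulate_sequences(
    config: SimConfig, table: OrthologTable, rng: np.random.Generator
) -> dict[str, dict[str, tuple[str, str]]]:
    """Human proteins plus per-site-substituted orthologs.

    Each human gene gets one random protein; for every one-to-one row
    (in the configured sequence species) whose dN and dS are present,
    the ortholog is the human sequence with each site substituted,
    uniformly among the other 19 residues, with probability
    min(0.95, divergence_scale * omega).
    """
    all_genes = config.target_ids() + config.nontarget_ids()
    known = set(all_genes)
    unknown = set(table.df["human_gene"]) - known
    if unknown:
        raise ValueError(f"ortholog table references unknown genes: {sorted(unknown)[:5]}")
    aa = np.array(list(AMINO_ACIDS))
    lo, hi = config.seq_len_range
    human: dict[str, str] = {}
    for gene in all_genes:
        length = int(rng.integers(lo, hi + 1))
        human[gene] = "".join(aa[rng.integers(0, 20, size=length)])
    pairs: dict[str, dict[str, tuple[str, str]]] = {}
    for species in config.sequence_species:
        rows = table.one2one(species)
        rows = rows[rows["dn"].notna() & rows["ds"].notna() & (rows["ds"] > 0)]
        by_gene: dict[str, tuple[str, str]] = {}
        for gene, dn, ds in sorted(zip(rows["human_gene"], rows["dn"], rows["ds"])):
            seq = human[gene]
            p_sub = min(0.95, config.divergence_scale * (dn / ds))
            hit = rng.random(len(seq)) < p_sub
            if hit.any():
                chars = np.array(list(seq))
                # uniform among the 19 non-identical residues: draw an
                # index in 0..18 and skip past the current residue
                cur_idx = np.searchsorted(aa, chars[hit])
                r = rng.integers(0, 19, size=int(hit.sum()))
                chars[hit] = aa[r + (r >= cur_idx)]
                orth = "".join(chars)
            else:
                orth = seq
            by_gene[gene] = (seq, orth)
        pairs[species] = by_gene
    return pairs


def simulate_network(config: SimConfig, rng: np.random.Generator) -> InteractionNetwork:
    """Chung-Lu expected-degree graph with triad closures at target nodes."""
    targets = config.target_ids()
    nontargets = config.nontarget_ids()
    nodes = targets + nontargets
    prop = np.array(
        [config.degree_weight_target] * len(targets)
        + [config.degree_weight_nontarget] * len(nontargets)
    )
    w = config.mean_degree * prop / prop.mean()
    total_w = w.sum()
    n = len(nodes)
    adj: dict[str, set[str]] = {v: set() for v in nodes}
    for i in range(n - 1):
        p = np.minimum(1.0, w[i] * w[i + 1 :] / total_w)
        hits = np.flatnonzero(rng.random(n - 1 - i) < p)
        for j in hits:
            u, v = nodes[i], nodes[i + 1 + j]
            adj[u].add(v)
            adj[v].add(u)
    # triad closure around targets raises their clustering coefficient
    for node in targets:
        if rng.random() >= config.triad_closure_prob:
            continue
        nbrs = sorted(adj[node])
        if len(nbrs) < 2:
            continue
        a, b = (nbrs[k] for k in rng.choice(len(nbrs), size=2, replace=False))
        adj[a].add(b)
        adj[b].add(a)
    edges = [(u, v) for u, nbrs in adj.items() for v in nbrs if u < v]
    return InteractionNetwork(edges, nodes=nodes)


def simulate_families(config: SimConfig, rng: np.random.Generator) -> FamilyMap:
    """Disjoint family pools for the two groups, with an overlap fraction.

    Targets draw from a target-family pool; non-targets from a disjoint
    pool, except a ``family_overlap`` fraction placed into target
    families (the genes a family-exclusion control construction must
    drop).
    """
    n_target_fams = max(1, config.n_families // 3)
    n_nontarget_fams = max(1, config.n_families - n_target_fams)
    target_fams = [f"FT{i:04d}" for i in range(1, n_target_fams + 1)]
    nontarget_fams = [f"FN{i:04d}" for i in range(1, n_nontarget_fams + 1)]
    assignments: dict[str, frozenset[str]] = {}
    for gene in config.target_ids():
        assignments[gene] = frozenset({target_fams[rng.integers(0, n_target_fams)]})
    for gene in config.nontarget_ids():
        if rng.random() < config.family_overlap:
            fam = target_fams[rng.integers(0, n_target_fams)]
        else:
            fam = nontarget_fams[rng.integers(0, n_nontarget_fams)]
        assignments[gene] = frozenset({fam})
    return FamilyMap(assignments)


def _write_fasta(path: Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def simulate_study(config: SimConfig, out_dir: str | Path | None = None) -> SyntheticStudy:
    """Compose all four generators from one seed; optionally write files.

    Written files: ``targets.txt``, ``nontargets.txt``,
    ``orthologs.tsv``, ``seqs_<species>_human.fasta`` /
    ``seqs_<species>_ortholog.fasta`` per sequence species, ``ppi.tsv``,
    ``families.tsv``, and ``manifest.json`` echoing the config.
    """
    streams = _streams(config)
    table = simulate_orthology(config, streams["orthology"])
    pairs = simulate_sequences(config, table, streams["sequences"])
    network = simulate_network(config, streams["network"])
    families = simulate_families(config, streams["families"])
    study = SyntheticStudy(
        config=config,
        target_genes=GeneSet("targets", frozenset(config.target_ids())),
        nontarget_genes=GeneSet("nontargets", frozenset(config.nontarget_ids())),
        family_map=families,
        ortholog_table=table,
        sequence_pairs=pairs,
        network=network,
    )
    if out_dir is not None:
        write_study(study, out_dir)
    return study


def write_study(study: SyntheticStudy, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "targets.txt").write_text(
        "\n".join(sorted(study.target_genes.genes)) + "\n"
    )
    (out / "nontargets.txt").write_text(
        "\n".join(sorted(study.nontarget_genes.genes)) + "\n"
    )
    study.ortholog_table.write(out / "orthologs.tsv")
    for species, by_gene in study.sequence_pairs.items():
        genes = sorted(by_gene)
        _write_fasta(out / f"seqs_{species}_human.fasta", [(g, by_gene[g][0]) for g in genes])
        _write_fasta(
            out / f"seqs_{species}_ortholog.fasta", [(g, by_gene[g][1]) for g in genes]
        )
    study.network.write(out / "ppi.tsv")
    with open(out / "families.tsv", "w") as fh:
        fh.write("gene\tfamily\n")
        for gene in sorted(study.family_map.assignments):
            for fam in sorted(study.family_map.assignments[gene]):
                fh.write(f"{gene}\t{fam}\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(study.config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
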