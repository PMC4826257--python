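"""Orchestration of the two-level comparison.

Level one compares the two gene sets within each species (or within
the network) by Wilcoxon rank-sum tests on per-gene feature values;
level two compares the per-species group medians across the species
panel by a Wilcoxon signed-rank test ("cross-species" test).  The
cross-species test defaults to the normal approximation with
continuity correction and without tie correction; exact mode is
available via a flag and is the default for ortholog percentages
(21 tie-free pairs).

:func:`run_all` reads a study directory (synthetic or real), runs the
four comparisons -- dN/dS, conservation score, ortholog percentage,
network topology -- and writes one TSV per comparison plus a
``summary.json`` with every cross-species test result and the
directional findings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import ScoringScheme, conservation_scores
from .genesets import GeneSet, read_gene_list
from .netmetrics import read_edge_list, topology_table
from .orthology import (
    OrthologTable,
    evolutionary_rates,
    ortholog_percentage,
    read_ortholog_table,
)
from .stats import SummaryStats, TestResult, rank_sum_test, signed_rank_test, summarize

logger = logging.getLogger(__name__)

NETWORK_FEATURES = ("degree", "clustering", "betweenness", "aspl")

__all__ = [
    "ComparisonRow",
    "ComparisonTable",
    "compare_feature",
    "compare_ortholog_percentages",
    "compare_topology",
    "run_all",
]


@dataclass(frozen=True)
class ComparisonRow:
    feature: str
    species: str  # species code, or "(network)" for topology rows
    group1: SummaryStats | None
    group2: SummaryStats | None
    rank_sum_p: float | None


@dataclass(frozen=True)
class ComparisonTable:
    feature: str
    rows: tuple[ComparisonRow, ...]
    cross_species: TestResult | None

    def to_frame(self) -> pd.DataFrame:
        def cols(s: SummaryStats | None, prefix: str) -> dict:
            if s is None:
                return {
                    f"{prefix}_n": 0,
                    f"{prefix}_median": math.nan,
                    f"{prefix}_lower_quartile": math.nan,
                    f"{prefix}_upper_quartile": math.nan,
                }
            return {
                f"{prefix}_n": s.n,
                f"{prefix}_median": s.median,
                f"{prefix}_lower_quartile": s.lower_quartile,
                f"{prefix}_upper_quartile": s.upper_quartile,
            }

        records = []
        for row in self.rows:
            rec = {"feature": row.feature, "species": row.species}
            rec.update(cols(row.group1, "group1"))
            rec.update(cols(row.group2, "group2"))
            rec["rank_sum_p"] = row.rank_sum_p if row.rank_sum_p is not None else math.nan
            records.append(rec)
        return pd.DataFrame(records)

    def write(self, path: str | Path) -> None:
        df = self.to_frame().copy()
        for col in df.columns:
            if col.endswith(("median", "quartile")):
                df[col] = df[col].map(lambda v: f"{v:.4f}")
        df["rank_sum_p"] = df["rank_sum_p"].map(
            lambda v: "" if math.isnan(v) else f"{v:.3e}"
        )
        df.to_csv(path, sep="\t", index=False)

    def median_pairs(self) -> list[tuple[float, float]]:
        return [
            (row.group1.median, row.group2.median)
            for row in self.rows
            if row.group1 is not None and row.group2 is not None
        ]


def compare_feature(
    values_by_species: dict[str, tuple[list[float], list[float]]],
    feature: str = "feature",
    exact_cross_species: bool = False,
    cross_species_tie_correction: bool = False,
) -> ComparisonTable:
    """Per-species rank-sum tests plus the cross-species signed-rank test.

    ``values_by_species`` maps each species code to the two groups'
    per-gene value lists.  Species where either group is empty get a
    row with missing summaries/p and are excluded from the
    cross-species pairing.
    """
    if not values_by_species:
        raise ValueError("no species to compare")
    rows = []
    for species in values_by_species:
        v1, v2 = values_by_species[species]
        s1 = summarize(v1) if len(v1) else None
        s2 = summarize(v2) if len(v2) else None
        if s1 is None or s2 is None:
            logger.warning("%s/%s: empty group, no rank-sum test", feature, species)
            p = None
        else:
            p = rank_sum_test(
                v1, v2, method="normal_approx",
                continuity_correction=True, tie_correction=True,
            ).p_two_sided
        rows.append(ComparisonRow(feature, species, s1, s2, p))
    pairs = [
        (r.group1.median, r.group2.median)
        for r in rows
        if r.group1 is not None and r.group2 is not None
    ]
    cross = signed_rank_test(
        pairs,
        method="exact" if exact_cross_species else "normal_approx",
        continuity_correction=True,
        tie_correction=cross_species_tie_correction,
    )
    return ComparisonTable(feature=feature, rows=tuple(rows), cross_species=cross)


def compare_ortholog_percentages(
    table: OrthologTable,
    targets: GeneSet,
    nontargets: GeneSet,
    species_panel: tuple[str, ...],
) -> ComparisonTable:
    """One percentage per group per species; exact cross-species test."""
    if not species_panel:
        raise ValueError("empty species panel")
    rows = []
    for species in species_panel:
        p1 = ortholog_percentage(table, targets, species)
        p2 = ortholog_percentage(table, nontargets, species)
        rows.append(
            ComparisonRow(
                feature="ortholog_percentage",
                species=species,
                group1=SummaryStats(1, p1, p1, p1),
                group2=SummaryStats(1, p2, p2, p2),
                rank_sum_p=None,
            )
        )
    cross = signed_rank_test(
        [(r.group1.median, r.group2.median) for r in rows], method="exact"
    )
    return ComparisonTable(
        feature="ortholog_percentage", rows=tuple(rows), cross_species=cross
    )


def compare_topology(net, targets: GeneSet, nontargets: GeneSet) -> ComparisonTable:
    """Rank-sum comparison of the four node metrics between the gene sets."""
    rows1 = topology_table(net, targets)
    rows2 = topology_table(net, nontargets)
    if not rows1 or not rows2:
        raise ValueError("a gene set is disjoint from the network")
    getters = {
        "degree": lambda t: float(t.degree),
        "clustering": lambda t: t.clustering_coefficient,
        "betweenness": lambda t: t.betweenness,
        "aspl": lambda t: t.avg_shortest_path,
    }
    rows = []
    for feature in NETWORK_FEATURES:
        v1 = [getters[feature](t) for t in rows1]
        v2 = [getters[feature](t) for t in rows2]
        if feature == "aspl":  # isolated nodes have no defined path length
            v1 = [v for v in v1 if not math.isnan(v)]
            v2 = [v for v in v2 if not math.isnan(v)]
        p = rank_sum_test(
            v1, v2, method="normal_approx",
            continuity_correction=True, tie_correction=True,
        ).p_two_sided
        rows.append(
            ComparisonRow(feature, "(network)", summarize(v1), summarize(v2), p)
        )
    return ComparisonTable(feature="topology", rows=tuple(rows), cross_species=None)


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required input file not found: {path}")
    return path


def run_all(
    study_dir: str | Path,
    out_dir: str | Path,
    targets_path: str | Path | None = None,
    nontargets_path: str | Path | None = None,
    species_panel: tuple[str, ...] | None = None,
    scheme: ScoringScheme | None = None,
    exact_cross_species: bool = False,
    cross_species_tie_correction: bool = False,
) -> Path:
    """Run all four comparisons on a study directory and write a report.

    Outputs ``table_dnds.tsv``, ``table_conservation.tsv``,
    ``table_orthopct.tsv``, ``table_topology.tsv``, ``summary.json``.
    """
    study = Path(study_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    targets = read_gene_list(
        _require(Path(targets_path) if targets_path else study / "targets.txt"),
        label="targets",
    )
    nontargets = read_gene_list(
        _require(Path(nontargets_path) if nontargets_path else study / "nontargets.txt"),
        label="nontargets",
    )
    table = read_ortholog_table(_require(study / "orthologs.tsv"), species_panel=None)
    panel = species_panel or table.species_panel

    dnds = compare_feature(
        {
            sp: (
                [r.omega for r in evolutionary_rates(table, targets, sp)],
                [r.omega for r in evolutionary_rates(table, nontargets, sp)],
            )
            for sp in panel
        },
        feature="dnds",
        exact_cross_species=exact_cross_species,
        cross_species_tie_correction=cross_species_tie_correction,
    )

    seq_species = sorted(
        p.name.split("_")[1] for p in study.glob("seqs_*_human.fasta")
    )
    conservation = None
    if seq_species:
        values = {}
        for sp in seq_species:
            human = study / f"seqs_{sp}_human.fasta"
            orth = _require(study / f"seqs_{sp}_ortholog.fasta")
            values[sp] = (
                [r.score for r in conservation_scores(human, orth, targets, sp, scheme)],
                [r.score for r in conservation_scores(human, orth, nontargets, sp, scheme)],
            )
        conservation = compare_feature(
            values,
            feature="conservation_score",
            exact_cross_species=exact_cross_species,
            cross_species_tie_correction=cross_species_tie_correction,
        )

    orthopct = compare_ortholog_percentages(table, targets, nontargets, tuple(panel))
    net = read_edge_list(_require(study / "ppi.tsv"))
    topology = compare_topology(net, targets, nontargets)

    dnds.write(out / "table_dnds.tsv")
    if conservation is not None:
        conservation.write(out / "table_conservation.tsv")
    orthopct.write(out / "table_orthopct.tsv")
    topology.write(out / "table_topology.tsv")

    manifest = study / "manifest.json"
    digest = (
        hashlib.sha256(manifest.read_bytes()).hexdigest() if manifest.exists() else None
    )

    def direction(tbl: ComparisonTable | None, lower: bool) -> dict | None:
        if tbl is None:
            return None
        pairs = tbl.median_pairs()
        n_dir = sum(1 for a, b in pairs if (a < b if lower else a > b))
        return {
            "n_species": len(pairs),
            "n_species_in_direction": n_dir,
            "direction": "group1_lower" if lower else "group1_higher",
            "holds": n_dir > len(pairs) / 2,
            "cross_species": tbl.cross_species.to_dict() if tbl.cross_species else None,
        }

    topo_findings = {}
    for row in topology.rows:
        lower = row.feature == "aspl"  # tighter structure: shorter paths
        holds = (
            row.group1.median < row.group2.median
            if lower
            else row.group1.median > row.group2.median
        )
        if row.group1.median == row.group2.median:
            holds = None  # medians can tie on discrete metrics: inconclusive
        topo_findings[row.feature] = {
            "direction": "group1_lower" if lower else "group1_higher",
            "holds": holds,
            "rank_sum_p": row.rank_sum_p,
        }

    summary = {
        "version": __version__,
        "study_dir": str(study),
        "manifest_sha256": digest,
        "n_targets": len(targets),
        "n_nontargets": len(nontargets),
        "species_panel": list(panel),
        "findings": {
            "dnds_lower_in_group1": direction(dnds, lower=True),
            "conservation_higher_in_group1": direction(conservation, lower=False),
            "ortholog_percentage_higher_in_group1": direction(orthopct, lower=False),
            "topology": topo_findings,
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
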