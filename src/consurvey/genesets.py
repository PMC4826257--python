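"""Gene sets and the family-exclusion control set.

A control ("non-target") set is derived from a protein-family map
(Pfam-style gene -> family assignments) by excluding every gene that
shares any family with a gene of the query set.  This is a whole-family
exclusion: the control set contains only genes whose entire family
annotation is disjoint from the families of the query set, so that no
control gene has a domain in common with a query gene.  Genes without
any family annotation are ineligible as controls, because domain
dissimilarity cannot be certified for them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["GeneSet", "FamilyMap", "read_gene_list", "read_family_map", "derive_nontargets"]


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of gene identifiers."""

    label: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("gene set label must be non-empty")
        if any((not g) or g != g.strip() for g in self.genes):
            raise ValueError("gene identifiers must be non-empty and stripped")
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass(frozen=True)
class FamilyMap:
    """Mapping gene identifier -> set of family accessions."""

    assignments: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        frozen = {}
        for gene, fams in self.assignments.items():
            fams = frozenset(fams)
            if not fams:
                raise ValueError(f"gene {gene!r} has an empty family set")
            frozen[gene] = fams
        object.__setattr__(self, "assignments", frozen)

    def families_of(self, genes) -> frozenset[str]:
        """Union of family accessions over the given genes (missing genes ignored)."""
        out: set[str] = set()
        for g in genes:
            out |= self.assignments.get(g, frozenset())
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.assignments)

    def __contains__(self, gene: str) -> bool:
        return gene in self.assignments


def read_gene_list(path: str | Path, label: str | None = None) -> GeneSet:
    """Read a one-identifier-per-line gene list.

    Blank lines and ``#`` comment lines are ignored; duplicates are
    dropped with a warning; an empty result is an error.
    """
    path = Path(path)
    seen: set[str] = set()
    n_dups = 0
    for line in path.read_text().splitlines():
        token = line.strip()
        if not token or token.startswith("#"):
            continue
        if token in seen:
            n_dups += 1
        else:
            seen.add(token)
    if n_dups:
        logger.warning("%s: %d duplicate gene identifiers ignored", path, n_dups)
    if not seen:
        raise ValueError(f"{path}: no gene identifiers found")
    return GeneSet(label=label or path.stem, genes=frozenset(seen))


def read_family_map(path: str | Path) -> FamilyMap:
    """Read a two-column TSV ``gene<TAB>family_accession`` (header required)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["gene", "family"]
    if list(df.columns) != expected:
        raise ValueError(
            f"{path}: expected header columns {expected}, found {list(df.columns)}"
        )
    if df.isna().any().any():
        raise ValueError(f"{path}: empty gene or family fields")
    assignments: dict[str, set[str]] = {}
    for gene, fam in zip(df["gene"].str.strip(), df["family"].str.strip()):
        assignments.setdefault(gene, set()).add(fam)
    if not assignments:
        raise ValueError(f"{path}: no family assignments found")
    return FamilyMap({g: frozenset(f) for g, f in assignments.items()})


def derive_nontargets(
    targets: GeneSet, families: FamilyMap, label: str = "nontargets"
) -> GeneSet:
    """Family-exclusion control set.

    Returns every gene in ``families`` whose family set is disjoint from
    the union of families of the target genes.  Targets themselves are
    always excluded; genes absent from the family map are never
    returned.  An empty result is allowed (with a warning) -- it occurs
    when targets blanket every family.
    """
    if len(targets) == 0:
        raise ValueError("target gene set is empty")
    if len(families) == 0:
        raise ValueError("family map is empty")
    annotated_targets = [g for g in targets.genes if g in families]
    if not annotated_targets:
        logger.warning(
            "no target gene appears in the family map; exclusion is vacuous"
        )
    excluded_families = families.families_of(annotated_targets)
    kept = frozenset(
        g
        for g, fams in families.assignments.items()
        if g not in targets and fams.isdisjoint(excluded_families)
    )
    if not kept:
        logger.warning("family exclusion removed every candidate gene")
    return GeneSet(label=label, genes=kept)
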