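"""Conservation scores from optimal local protein alignment.

The conservation score of a (human gene, species) pair is the raw
score of the optimal Smith-Waterman local alignment between the human
protein and its species ortholog, under BLOSUM62 with affine gap
penalties (default open 11, extend 1, so a gap of length L costs
11 + L).  Higher scores mean higher conservation.  Exact local
alignment replaces the heuristic BLASTP search: it is deterministic
and oracle-verifiable, and its score bounds the BLASTP score from
above for the same scoring scheme.

The alignment engine is Biopython's :class:`Bio.Align.PairwiseAligner`
in local mode.  The empty alignment is always admissible, so scores
are non-negative.  In the BLOSUM62 shipped with Biopython, the unknown
residue X scores 0 against every standard residue and -1 against X.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .genesets import GeneSet

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

__all__ = [
    "AMINO_ACIDS",
    "ProteinSequence",
    "ScoringScheme",
    "ConservationRecord",
    "read_fasta",
    "read_matrix",
    "local_alignment_score",
    "conservation_scores",
]


@dataclass(frozen=True)
class ProteinSequence:
    """An identifier plus residues over the 20 standard letters and X."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (positive costs)."""

    matrix: substitution_matrices.Array = field(
        default_factory=lambda: substitution_matrices.load("BLOSUM62")
    )
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        mat = self.matrix
        for a in mat.alphabet:
            for b in mat.alphabet:
                if mat[a, b] != mat[b, a]:
                    raise ValueError(f"substitution matrix not symmetric at ({a},{b})")

    def aligner(self) -> PairwiseAligner:
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = self.matrix
        # a gap of length L costs gap_open + L * gap_extend
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@dataclass(frozen=True)
class ConservationRecord:
    human_gene: str
    species: str
    score: int

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("conservation score must be non-negative")


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read protein FASTA; id = header token up to the first whitespace."""
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinSequence(id=rec.id, residues=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def read_matrix(path: str | Path) -> substitution_matrices.Array:
    """Read a substitution matrix in NCBI text format."""
    return substitution_matrices.read(str(path))


def local_alignment_score(
    a: ProteinSequence | str,
    b: ProteinSequence | str,
    scheme: ScoringScheme | None = None,
) -> int:
    """Optimal Smith-Waterman local-alignment score (raw, integer).

    Symmetric in its arguments; >= 0 because the empty alignment is
    allowed.
    """
    if isinstance(a, str):
        a = ProteinSequence(id="a", residues=a)
    if isinstance(b, str):
        b = ProteinSequence(id="b", residues=b)
    scheme = scheme or ScoringScheme()
    score = scheme.aligner().score(a.residues, b.residues)
    return max(0, int(round(score)))


def conservation_scores(
    human_fasta: str | Path,
    ortholog_fasta: str | Path,
    genes: GeneSet,
    species: str,
    scheme: ScoringScheme | None = None,
) -> list[ConservationRecord]:
    """Score each gene's human/ortholog pair; genes without a pair are skipped.

    The two FASTA files must carry identical id sets (records are keyed
    by the human gene id in both).
    """
    scheme = scheme or ScoringScheme()
    human = {s.id: s for s in read_fasta(human_fasta)}
    orth = {s.id: s for s in read_fasta(ortholog_fasta)}
    if set(human) != set(orth):
        only_h = sorted(set(human) - set(orth))[:5]
        only_o = sorted(set(orth) - set(human))[:5]
        raise ValueError(
            f"id mismatch between {human_fasta} and {ortholog_fasta}: "
            f"human-only {only_h}, ortholog-only {only_o}"
        )
    aligner = scheme.aligner()
    records = []
    n_absent = 0
    for gene in sorted(genes.genes):
        if gene not in human:
            n_absent += 1
            continue
        score = aligner.score(human[gene].residues, orth[gene].residues)
        records.append(
            ConservationRecord(
                human_gene=gene, species=species, score=max(0, int(round(score)))
            )
        )
    if n_absent:
        logger.info(
            "conservation_scores(%s, %s): %d genes without a sequence pair skipped",
            genes.label, species, n_absent,
        )
    return records
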