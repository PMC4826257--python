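"""Ortholog tables, evolutionary rates, and ortholog percentages.

The input is a BioMart-style TSV of orthology rows between human genes
and one of a panel of species, carrying the homology type and the
nonsynonymous (dN) and synonymous (dS) substitution rates.  Two
features are derived per gene set:

* the evolutionary rate omega = dN/dS, restricted to one-to-one
  orthologs with both rates present and dS > 0;
* the ortholog percentage, the fraction of the gene set with a
  one-to-one ortholog in a species (regardless of dN/dS availability),
  times 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genesets import GeneSet

logger = logging.getLogger(__name__)

#: The 21-species panel (Ensembl abbreviations) used by default:
#: giant panda, cow, dog, marmoset, guinea pig, horse, ground squirrel,
#: elephant, opossum, ferret, little brown bat, rhesus macaque, mouse,
#: gibbon, rabbit, bushbaby, orangutan, chimpanzee, rat, Tasmanian
#: devil, pig.
SPECIES_PANEL: tuple[str, ...] = (
    "amel", "btau", "cfam", "cjac", "cpor", "ecab", "itri",
    "lafr", "mdom", "mfur", "mluc", "mmul", "mmus", "nleu",
    "ocun", "ogar", "pabe", "ptro", "rnor", "shar", "sscr",
)

HOMOLOGY_TYPES = ("ortholog_one2one", "ortholog_one2many", "ortholog_many2many", "other")
ONE2ONE = "ortholog_one2one"

_COLUMNS = ["human_gene", "species", "ortholog_gene", "homology_type", "dn", "ds"]

__all__ = [
    "SPECIES_PANEL",
    "ONE2ONE",
    "OrthologTable",
    "RateRecord",
    "read_ortholog_table",
    "evolutionary_rates",
    "ortholog_percentage",
]


@dataclass(frozen=True)
class RateRecord:
    human_gene: str
    species: str
    omega: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.omega) and self.omega >= 0):
            raise ValueError(f"omega must be finite and >= 0, got {self.omega}")


class OrthologTable:
    """Typed orthology table backed by a DataFrame.

    Columns: ``human_gene, species, ortholog_gene, homology_type, dn,
    ds`` with dn/ds as floats (NaN = missing).  At most one one-to-one
    record per (human_gene, species) pair.
    """

    def __init__(self, df: pd.DataFrame):
        if list(df.columns) != _COLUMNS:
            raise ValueError(f"expected columns {_COLUMNS}, got {list(df.columns)}")
        df = df.reset_index(drop=True)
        bad_type = ~df["homology_type"].isin(HOMOLOGY_TYPES)
        if bad_type.any():
            raise ValueError(
                f"unknown homology types: {sorted(df.loc[bad_type, 'homology_type'].unique())}"
            )
        for col in ("dn", "ds"):
            vals = df[col].to_numpy(dtype=float)
            if np.any(vals[~np.isnan(vals)] < 0):
                raise ValueError(f"negative {col} values present")
        one2one = df[df["homology_type"] == ONE2ONE]
        dup = one2one.duplicated(subset=["human_gene", "species"])
        if dup.any():
            pairs = one2one.loc[dup, ["human_gene", "species"]].head(5).to_records(index=False)
            raise ValueError(f"duplicate one-to-one records, e.g. {list(pairs)}")
        self.df = df

    @property
    def species_panel(self) -> tuple[str, ...]:
        return tuple(sorted(self.df["species"].unique()))

    def __len__(self) -> int:
        return len(self.df)

    def one2one(self, species: str) -> pd.DataFrame:
        if species not in set(self.df["species"]):
            raise ValueError(f"species {species!r} not present in the table")
        mask = (self.df["species"] == species) & (self.df["homology_type"] == ONE2ONE)
        return self.df[mask]

    def write(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.6g")


def read_ortholog_table(
    path: str | Path, species_panel: Sequence[str] | None = SPECIES_PANEL
) -> OrthologTable:
    """Read an ortholog TSV; malformed numeric rows are rejected with a log.

    Missing dn/ds may be encoded as an empty field or ``NA``.  Species
    codes are validated against ``species_panel`` (pass None to skip).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != _COLUMNS:
        raise ValueError(f"{path}: expected header {_COLUMNS}, found {list(df.columns)}")

    def parse_rate(raw: str) -> float:
        s = raw.strip()
        if s in ("", "NA"):
            return np.nan
        v = float(s)  # ValueError on garbage
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"rate {v} not finite and non-negative")
        return v

    dn, ds, bad_rows = [], [], []
    for i, (raw_dn, raw_ds) in enumerate(zip(df["dn"], df["ds"])):
        try:
            parsed = (parse_rate(raw_dn), parse_rate(raw_ds))
        except ValueError:
            bad_rows.append(i)
            # +2: one for the header line, one for 1-based numbering
            logger.warning("%s: rejected malformed row at line %d", path, i + 2)
            continue
        dn.append(parsed[0])
        ds.append(parsed[1])
    if bad_rows:
        logger.warning("%s: rejected %d malformed rows", path, len(bad_rows))
        df = df.drop(index=bad_rows).reset_index(drop=True)
    out = df[["human_gene", "species", "ortholog_gene", "homology_type"]].copy()
    out["dn"] = np.array(dn, dtype=float)
    out["ds"] = np.array(ds, dtype=float)
    if species_panel is not None:
        unknown = set(out["species"]) - set(species_panel)
        if unknown:
            raise ValueError(f"{path}: species codes outside the panel: {sorted(unknown)}")
    return OrthologTable(out)


def evolutionary_rates(
    table: OrthologTable, genes: GeneSet, species: str
) -> list[RateRecord]:
    """omega = dN/dS per gene with a usable one-to-one record.

    A record is usable when dn and ds are both present and ds > 0
    (dn = 0 with ds > 0 yields omega = 0 and is kept).  Exclusions are
    counted by reason and logged.
    """
    sub = table.one2one(species)
    sub = sub[sub["human_gene"].isin(genes.genes)]
    covered = set(sub["human_gene"])
    n_no_record = len(genes) - len(covered)
    missing = sub["dn"].isna() | sub["ds"].isna()
    ds_zero = ~missing & (sub["ds"] == 0)
    usable = sub[~missing & ~ds_zero]
    logger.info(
        "evolutionary_rates(%s, %s): %d rates; excluded %d without one2one, "
        "%d with missing dN/dS, %d with dS=0",
        genes.label, species, len(usable), n_no_record,
        int(missing.sum()), int(ds_zero.sum()),
    )
    return [
        RateRecord(human_gene=g, species=species, omega=float(dn / ds))
        for g, dn, ds in zip(usable["human_gene"], usable["dn"], usable["ds"])
    ]


def ortholog_percentage(table: OrthologTable, genes: GeneSet, species: str) -> float:
    """Percent of ``genes`` with a one-to-one ortholog in ``species``.

    The denominator is the full gene set; dN/dS availability is
    irrelevant here.
    """
    if len(genes) == 0:
        raise ValueError("empty gene set")
    sub = table.one2one(species)
    n_with = len(set(sub["human_gene"]) & genes.genes)
    return 100.0 * n_with / len(genes)
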