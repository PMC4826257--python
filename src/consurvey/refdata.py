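"""Published reference medians for the drug-target conservation comparison.

Per-species median feature values reported for the FDA-approved
drug-target gene set (1347 genes, DrugBank) versus the Pfam-disjoint
non-target gene set (4181 genes), computed from Ensembl release-69
orthology data over the 21-species panel.  Each entry maps a species
code to ``(target median, non-target median)``.

These are inputs for the cross-species signed-rank recomputation: the
per-gene data behind them came from external database releases and is
not redistributed here.
"""

from __future__ import annotations

__all__ = ["DNDS_MEDIANS", "CONSERVATION_MEDIANS"]

#: Median dN/dS of drug-target vs non-target genes per species.
DNDS_MEDIANS: dict[str, tuple[float, float]] = {
    "amel": (0.1104, 0.1280),
    "btau": (0.1028, 0.1246),
    "cfam": (0.1057, 0.1270),
    "cjac": (0.1584, 0.1893),
    "cpor": (0.1026, 0.1211),
    "ecab": (0.1177, 0.1352),
    "itri": (0.1027, 0.1181),
    "lafr": (0.1173, 0.1400),
    "mdom": (0.0757, 0.0943),
    "mfur": (0.0975, 0.1233),
    "mluc": (0.1281, 0.1407),
    "mmul": (0.1578, 0.1970),
    "mmus": (0.0910, 0.1125),
    "nleu": (0.1735, 0.2235),
    "ocun": (0.1014, 0.1178),
    "ogar": (0.1163, 0.1395),
    "pabe": (0.1561, 0.2022),
    "ptro": (0.1718, 0.2184),
    "rnor": (0.0931, 0.1159),
    "shar": (0.0756, 0.0938),
    "sscr": (0.1130, 0.1321),
}

#: Median protein-alignment conservation score (BLASTP/BLOSUM62 raw
#: score) of drug-target vs non-target genes per species.
CONSERVATION_MEDIANS: dict[str, tuple[float, float]] = {
    "amel": (838.00, 613.00),
    "btau": (840.00, 615.00),
    "cfam": (859.00, 622.00),
    "cjac": (905.00, 655.00),
    "cpor": (828.00, 587.00),
    "ecab": (845.00, 608.00),
    "itri": (817.50, 594.00),
    "lafr": (831.50, 591.50),
    "mdom": (773.00, 514.50),
    "mfur": (856.50, 636.00),
    "mluc": (823.50, 582.00),
    "mmul": (895.00, 644.00),
    "mmus": (852.00, 602.00),
    "nleu": (900.00, 669.00),
    "ocun": (845.00, 608.00),
    "ogar": (863.00, 628.00),
    "pabe": (877.00, 655.00),
    "ptro": (925.50, 682.00),
    "rnor": (804.00, 569.00),
    "shar": (701.00, 499.00),
    "sscr": (768.50, 565.00),
}
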