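"""Program annotation by gene-set overlap.

Discovered programs are annotated by testing their top-weighted gene
lists against reference signatures (e.g. published endothelial subtype
signatures supplied as GMT) with the two-sided hypergeometric test,
conditioning on a gene universe that defaults to the genes of the
analyzed matrix. The same machinery provides over-representation
analysis against arbitrary GMT pathway collections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .cnmf import ProgramSet
from .stats import adjust_pvalues, hypergeometric_overlap_test

__all__ = [
    "GeneSignature",
    "read_gmt",
    "write_gmt",
    "annotate_programs",
    "over_representation",
]


@dataclass
class GeneSignature:
    """Named ordered gene list (uppercase symbols)."""

    name: str
    genes: tuple
    source: str = ""

    def __post_init__(self) -> None:
        genes = tuple(dict.fromkeys(str(g).upper() for g in self.genes))
        if not genes:
            raise ValueError(f"signature {self.name!r} is empty")
        self.genes = genes


def read_gmt(path: str) -> list:
    """Read a GMT file (name, description, genes...) into signatures."""
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out.append(GeneSignature(parts[0], tuple(parts[2:]), source=parts[1]))
    return out


def write_gmt(path: str, sets: dict, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *[str(g).upper() for g in genes]]) + "\n")


def _overlap_table(gene_sets: dict, references: list, universe) -> pd.DataFrame:
    universe = {str(g).upper() for g in universe}
    rows = []
    for ref in references:
        ref_in = [g for g in ref.genes if g in universe]
        if not ref_in:
            warnings.warn(
                f"reference {ref.name!r} has no genes in the universe; skipped"
            )
            continue
        for prog_name, genes in gene_sets.items():
            prog_in = [g for g in genes if g in universe]
            if not prog_in:
                warnings.warn(f"program {prog_name!r} has no genes in the universe; skipped")
                continue
            res = hypergeometric_overlap_test(prog_in, ref_in, universe)
            rows.append(
                {
                    "program": prog_name,
                    "reference_signature": ref.name,
                    "overlap_count": int(res.statistic),
                    "p_two_sided": res.p_value,
                }
            )
    table = pd.DataFrame(rows, columns=["program", "reference_signature", "overlap_count", "p_two_sided"])
    if len(table):
        table["p_adj"] = adjust_pvalues(table["p_two_sided"].values).adjusted
    else:
        table["p_adj"] = []
    return table


def annotate_programs(program_set: ProgramSet, references: list, universe=None) -> pd.DataFrame:
    """Hypergeometric overlap of each program's top genes with each
    reference signature; BH-adjusted across the whole table.

    ``universe`` defaults to the genes of the analyzed matrix (the
    program set's gene space): overlap probabilities condition on genes
    that could have been tested, not the genome.
    """
    if not references:
        raise ValueError("references must be nonempty")
    if universe is None:
        universe = program_set.gene_ids
    return _overlap_table(program_set.gene_sets(), references, universe)


def over_representation(program_set: ProgramSet, pathways, universe=None) -> pd.DataFrame:
    """Over-representation of program top genes in pathway collections.

    ``pathways`` is a GMT-style mapping (name -> gene list) or a list of
    :class:`GeneSignature`. Ranked (KS-style) enrichment is deliberately
    out of scope; over-representation covers the same annotation need on
    user-supplied collections.
    """
    if not pathways:
        raise ValueError("pathway collection must be nonempty")
    if isinstance(pathways, dict):
        pathways = [GeneSignature(k, tuple(v)) for k, v in pathways.items()]
    if universe is None:
        universe = program_set.gene_ids
    return _overlap_table(program_set.gene_sets(), pathways, universe)
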