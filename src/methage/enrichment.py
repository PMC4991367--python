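"""Fisher's-exact gene-set enrichment of a CpG list.

CpGs are mapped to genes and deduplicated before testing, so a gene measured
by several probes counts once — the contingency tables are gene-level. For
each term a one-sided (greater) Fisher exact test asks whether the hit list
is over-represented among the term's genes relative to the gene universe.
Both the raw p-value and a Benjamini-Hochberg q-value are reported.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["map_probes_to_genes", "fisher_term_enrichment", "read_term_map"]


def map_probes_to_genes(probes: list[str], annotation: pd.DataFrame) -> set[str]:
    """Unique gene ids for a probe list (``gene_ids`` may be ';'-separated)."""
    present = [p for p in probes if p in annotation.index]
    genes: set[str] = set()
    for entry in annotation.loc[present, "gene_ids"]:
        genes.update(g for g in str(entry).split(";") if g)
    return genes


def fisher_term_enrichment(
    cpg_set: list[str],
    universe: list[str],
    annotation: pd.DataFrame,
    terms: dict[str, set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of ``cpg_set`` genes against each term.

    ``cpg_set`` must be a subset of ``universe`` (both probe lists). Returns a
    table with the 2x2 counts, odds ratio, raw p, BH q, and a ``called``
    column at raw p < ``alpha``.
    """
    if not set(cpg_set) <= set(universe):
        raise ValueError("cpg_set must be a subset of the universe")
    hit_genes = map_probes_to_genes(list(cpg_set), annotation)
    universe_genes = map_probes_to_genes(list(universe), annotation)
    if not universe_genes:
        raise ValueError("no probes could be mapped to genes")
    rows = []
    for term, term_genes in terms.items():
        in_universe = term_genes & universe_genes
        if not in_universe:
            logger.warning("term %s covers no universe genes; skipped", term)
            continue
        a = len(hit_genes & in_universe)
        b = len(hit_genes - in_universe)
        c = len(in_universe - hit_genes)
        d = len(universe_genes) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {"term": term, "set_in_term": a, "set_not_term": b,
             "bg_in_term": c, "bg_not_term": d, "odds_ratio": odds, "p": p}
        )
    table = pd.DataFrame(rows).set_index("term")
    if table.empty:
        return table
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    table["called"] = table["p"] < alpha
    return table.sort_values("p")


def read_term_map(path) -> dict[str, set[str]]:
    """Gene→term map from a two-column TSV (gene, term) or GMT file."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        is_gmt = len(first.rstrip("\n").split("\t")) > 2
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not fields or not fields[0]:
                continue
            if is_gmt:
                terms.setdefault(fields[0], set()).update(g for g in fields[2:] if g)
            else:
                gene, term = fields[0], fields[1]
                terms.setdefault(term, set()).add(gene)
    return terms
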