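"""Local gene-set enrichment by Fisher's exact test.

A minimal replacement for web-based enrichment services: given a query gene
list, a background universe and a collection of gene sets (e.g. read from a
GMT file), each set is tested with a one-sided Fisher exact test on the
2x2 membership table and p-values are Benjamini-Hochberg corrected.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from scipy import stats

__all__ = ["read_gmt", "fisher_enrichment"]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def fisher_enrichment(
    query: list[str],
    gene_sets: dict[str, list[str]],
    universe: list[str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of ``query`` in each gene set.

    Genes outside ``universe`` are ignored. Returns a frame with overlap
    counts, odds ratio, p, BH-corrected q and ``significant`` (q < fdr),
    sorted by p.
    """
    from statsmodels.stats.multitest import multipletests

    uni = set(universe)
    q = set(query) & uni
    if not q:
        raise ValueError("query has no genes in the universe")
    rows = []
    for name, genes in gene_sets.items():
        s = set(genes) & uni
        a = len(q & s)
        b = len(q - s)
        c = len(s - q)
        d = len(uni) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {
                "gene_set": name,
                "overlap": a,
                "query_size": len(q),
                "set_size": len(s),
                "odds_ratio": odds,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < fdr
    return out.sort_values("p").reset_index(drop=True)
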