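"""5' exon-coverage bias of knockout transcriptomes.

Premature transcription termination or defective elongation leaves reads
piled on 5' exons. To quantify this, exons are categorized from a gene
model (First / AlternativeFirst / Internal / Last / AlternativeLast,
strand-aware), per-exon read counts are normalized to log2 reads-per-
million, fold enrichment is computed against non-targeting control (NTC)
samples, and the 5' bias of a gene in a knockout is

    bias5 = lfc(First exon) - lfc(Last exon)

(the log2 of the linear ratio of fold enrichments). Genes are clustered by
their bias pattern across knockouts with complete-linkage hierarchical
clustering, and cluster gene lists can be tested for enrichment against
user-supplied gene sets with a local Fisher exact test.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "ExonRecord",
    "CATEGORY_PRIORITY",
    "classify_exons",
    "exon_coverage",
    "five_prime_bias",
    "first_exon_shift_test",
    "cluster_bias",
    "count_exon_overlaps",
]

#: Category priority on conflicts (an exon initial in one transcript and
#: terminal in another keeps the higher-priority label).
CATEGORY_PRIORITY = ["First", "Last", "AlternativeFirst", "AlternativeLast", "Internal"]


@dataclass(frozen=True)
class ExonRecord:
    """One exon (0-based half-open coordinates) with its category."""

    gene_id: str
    exon_id: str
    chrom: str
    strand: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    category: str


def classify_exons(gtf: str, from_string: bool = False) -> list[ExonRecord]:
    """Categorize every exon of a GTF gene model.

    Per gene (strand-aware): ``First`` is the 5'-most transcript-initial
    exon, ``AlternativeFirst`` the other transcript-initial exons, ``Last``
    the 3'-most transcript-terminal exon, ``AlternativeLast`` the other
    terminal exons, ``Internal`` everything else. Exons shared verbatim
    between transcripts are single records; conflicting labels resolve by
    :data:`CATEGORY_PRIORITY`. GTF coordinates (1-based inclusive) become
    0-based half-open.

    ``gtf`` is a path, or the document text with ``from_string=True``.
    """
    import gffutils

    data = gtf if from_string else open(gtf).read()
    db = gffutils.create_db(
        data,
        ":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
        verbose=False,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    records: list[ExonRecord] = []
    rank = {c: i for i, c in enumerate(CATEGORY_PRIORITY)}
    for gene in db.features_of_type("gene"):
        gid = gene.id
        strand = gene.strand
        exons: dict[tuple[int, int], dict] = {}
        initial: set[tuple[int, int]] = set()
        terminal: set[tuple[int, int]] = set()
        for tr in db.children(gene, featuretype="transcript"):
            tr_exons = sorted(
                db.children(tr, featuretype="exon"), key=lambda e: e.start
            )
            if not tr_exons:
                continue
            keys = []
            for e in tr_exons:
                key = (e.start - 1, e.end)  # to 0-based half-open
                keys.append(key)
                if key not in exons:
                    eid = e.attributes.get("exon_id", [f"{gid}:{e.start}-{e.end}"])[0]
                    exons[key] = {"exon_id": eid, "chrom": e.seqid}
            five = keys[0] if strand == "+" else keys[-1]
            three = keys[-1] if strand == "+" else keys[0]
            initial.add(five)
            terminal.add(three)
        if not exons:
            raise ValueError(f"gene {gid} has no exons")

        def five_prime_pos(key: tuple[int, int]) -> int:
            return key[0] if strand == "+" else -key[1]

        first = min(initial, key=five_prime_pos) if initial else None
        last = max(terminal, key=five_prime_pos) if terminal else None
        for key, meta in exons.items():
            cats = []
            if key == first:
                cats.append("First")
            elif key in initial:
                cats.append("AlternativeFirst")
            if key == last:
                cats.append("Last")
            elif key in terminal:
                cats.append("AlternativeLast")
            if not cats:
                cats.append("Internal")
            category = min(cats, key=lambda c: rank[c])
            records.append(
                ExonRecord(
                    gene_id=gid,
                    exon_id=meta["exon_id"],
                    chrom=meta["chrom"],
                    strand=strand,
                    start=key[0],
                    end=key[1],
                    category=category,
                )
            )
    return records


def exons_to_bed(records: list[ExonRecord], path) -> None:
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda r: (r.chrom, r.start)):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}|{r.exon_id}|{r.category}"
                f"\t0\t{r.strand}\n"
            )


def count_exon_overlaps(
    reads: pd.DataFrame, records: list[ExonRecord]
) -> pd.DataFrame:
    """Count reads overlapping each exon by >= 1 bp (strand-aware).

    ``reads`` has columns sample, chrom, start, end, strand (0-based
    half-open). A read overlapping two exons counts once for each. Returns
    columns sample, gene_id, exon_id, count.
    """
    from intervaltree import IntervalTree

    trees: dict[tuple[str, str], IntervalTree] = {}
    for i, r in enumerate(records):
        trees.setdefault((r.chrom, r.strand), IntervalTree()).addi(r.start, r.end, i)

    counts = np.zeros(len(records), dtype=np.int64)
    tallies: dict[str, np.ndarray] = {}
    for sample, chrom, start, end, strand in zip(
        reads["sample"], reads["chrom"], reads["start"], reads["end"], reads["strand"]
    ):
        tally = tallies.setdefault(sample, counts.copy())
        tree = trees.get((chrom, strand))
        if tree is None:
            continue
        for iv in tree.overlap(start, end):
            tally[iv.data] += 1
    rows = []
    for sample, tally in tallies.items():
        for r, c in zip(records, tally):
            rows.append(
                {"sample": sample, "gene_id": r.gene_id, "exon_id": r.exon_id, "count": int(c)}
            )
    return pd.DataFrame(rows)


def exon_coverage(
    counts: pd.DataFrame,
    records: list[ExonRecord],
    min_gene_reads: int = 10,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Normalized per-exon coverage: log2(RPM + pseudocount).

    ``counts`` has columns sample, gene_id, exon_id, count (as produced by
    :func:`count_exon_overlaps` or a simulator). Genes with fewer than
    ``min_gene_reads`` assigned reads in a sample are dropped from that
    sample. RPM normalizes by the sample's total assigned reads. Returns the
    table with added columns category and rpm_log2.
    """
    cat = {(r.gene_id, r.exon_id): r.category for r in records}
    df = counts.copy()
    df["category"] = [
        cat.get((g, e)) for g, e in zip(df["gene_id"], df["exon_id"])
    ]
    if df["category"].isna().any():
        missing = df[df["category"].isna()][["gene_id", "exon_id"]].iloc[0]
        raise ValueError(f"exon not in gene model: {tuple(missing)}")

    totals = df.groupby("sample")["count"].transform("sum")
    if (totals <= 0).any():
        raise ValueError("sample with zero assigned reads")
    gene_totals = df.groupby(["sample", "gene_id"])["count"].transform("sum")
    df = df[gene_totals >= min_gene_reads].copy()
    sample_total = counts.groupby("sample")["count"].sum()  # pre-filter totals
    rpm = df["count"] / df["sample"].map(sample_total).to_numpy() * 1e6
    df["rpm_log2"] = np.log2(rpm + pseudocount)
    return df.reset_index(drop=True)


def five_prime_bias(
    coverage: pd.DataFrame, ntc_samples: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fold enrichment versus NTC and the per-gene 5' bias.

    lfc = rpm_log2(sample) - mean over NTC samples of rpm_log2, per exon;
    bias5 = lfc(First) - lfc(Last). Genes lacking a First or Last exon in
    both the sample and the NTC reference are excluded. Returns
    ``(lfc_table, bias_table)``; the bias table has columns sample, gene_id,
    bias5, lfc_first, lfc_last.
    """
    missing = set(ntc_samples) - set(coverage["sample"])
    if missing:
        raise ValueError(f"NTC samples absent from coverage: {sorted(missing)}")
    ntc = (
        coverage[coverage["sample"].isin(ntc_samples)]
        .groupby(["gene_id", "exon_id"])["rpm_log2"]
        .mean()
    )
    df = coverage[~coverage["sample"].isin(ntc_samples)].copy()
    key = pd.MultiIndex.from_frame(df[["gene_id", "exon_id"]])
    df["lfc"] = df["rpm_log2"].to_numpy() - ntc.reindex(key).to_numpy()
    df = df.dropna(subset=["lfc"])

    fl = df[df["category"].isin(["First", "Last"])]
    wide = fl.pivot_table(
        index=["sample", "gene_id"], columns="category", values="lfc", aggfunc="mean"
    )
    wide = wide.dropna(subset=["First", "Last"]) if {"First", "Last"} <= set(
        wide.columns
    ) else wide.iloc[0:0].reindex(columns=["First", "Last"])
    bias = wide.reset_index().rename(
        columns={"First": "lfc_first", "Last": "lfc_last"}
    )
    bias["bias5"] = bias["lfc_first"] - bias["lfc_last"]
    return df, bias[["sample", "gene_id", "lfc_first", "lfc_last", "bias5"]]


def first_exon_shift_test(
    lfc_table: pd.DataFrame,
    sample: str,
    reference_sample: str | None = None,
) -> tuple[float, float]:
    """t-test of a knockout's per-gene First-exon fold enrichments.

    Two-sample Welch t-test against ``reference_sample``'s First-exon lfc
    distribution when given (the control-comparison default), else a
    one-sample t-test against zero. Returns (t, p).
    """
    firsts = lfc_table[lfc_table["category"] == "First"]
    a = firsts.loc[firsts["sample"] == sample, "lfc"].to_numpy()
    if len(a) < 3:
        raise ValueError(f"fewer than 3 First-exon genes for sample {sample}")
    if reference_sample is None:
        t, p = stats.ttest_1samp(a, 0.0)
    else:
        b = firsts.loc[firsts["sample"] == reference_sample, "lfc"].to_numpy()
        if len(b) < 3:
            raise ValueError("fewer than 3 First-exon genes in reference")
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def cluster_bias(
    bias: pd.DataFrame, n_clusters: int = 12
) -> tuple[pd.Series, dict[int, list[str]]]:
    """Hierarchically cluster genes by their 5' bias across knockouts.

    The genes x knockouts bias matrix (genes with any missing value dropped)
    is clustered by complete linkage on Euclidean distances and the tree is
    cut into ``n_clusters``. Returns (per-gene cluster labels, per-cluster
    gene lists).
    """
    mat = bias.pivot_table(index="gene_id", columns="sample", values="bias5")
    mat = mat.dropna()
    if len(mat) < n_clusters:
        raise ValueError(f"{len(mat)} genes < {n_clusters} clusters")
    Z = hierarchy.linkage(mat.to_numpy(), method="complete", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    out = pd.Series(labels, index=mat.index, name="cluster")
    lists = {int(c): sorted(out.index[out == c]) for c in np.unique(labels)}
    return out, lists
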