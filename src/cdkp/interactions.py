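"""Genetic-interaction scoring for combinatorial knockout screens.

A dual-guide construct's fitness is modeled as additive in log scale,

    f_{g1g2} = f_{g1} + f_{g2} + pi_{g1g2},

where pi is the genetic-interaction term. Single-guide fitnesses are imputed
by summing the model over all pairs containing each guide and dropping the
interaction sums (interactions are assumed rare and centered on zero), which
yields the linear system A x = b with

    A = (N-2) I + J   (diagonal N-1, off-diagonal 1),
    b_i = sum over observed pairs containing g_i of f_{pair}.

Guide-level pi values are averaged over all guide combinations of a gene
pair in both cassette orders (4 guides/gene -> 4*4*2 = 32 values), z-scored
within each (timepoint, replicate), and summarized as the median z across
samples. Negative final scores indicate synthetic-sick/lethal pairs,
positive scores synergistic growth advantage.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "solve_single_fitness",
    "impute_single_fitness",
    "score_pi",
    "aggregate_genes",
    "summarize_and_call",
    "score_screen",
]


def solve_single_fitness(
    pair_fitness: Mapping[tuple[str, str], float],
    guides: Sequence[str],
    average_orders: bool = False,
) -> pd.Series:
    """Impute per-guide fitness from observed pair fitnesses.

    Each observed ordered pair (i, j) contributes one additive-model equation
    to the rows of both of its guides; with a complete pair matrix the system
    reduces to A = (N-2) I + J, solved in closed form using
    A^{-1} b = (b - 1 * sum(b) / (2N-2)) / (N-2). Incomplete matrices are
    solved with the same per-row construction over observed pairs only
    (diagonal = observed degree), via least squares.

    ``average_orders`` pre-averages f over (i, j) and (j, i) before building
    the system; by default both orders enter as independent observations.
    """
    guides = list(guides)
    n = len(guides)
    if n < 3:
        raise ValueError("need at least 3 guides to separate interactions")
    idx = {g: k for k, g in enumerate(guides)}

    obs: dict[tuple[int, int], float] = {}
    for (a, b), f in pair_fitness.items():
        if a == b:
            raise ValueError(f"self-pair ({a},{a}) is not a valid construct")
        if a not in idx or b not in idx:
            raise ValueError(f"pair ({a},{b}) uses guides absent from the list")
        obs[(idx[a], idx[b])] = float(f)
    if average_orders:
        merged: dict[tuple[int, int], list[float]] = {}
        for (i, j), f in obs.items():
            merged.setdefault((min(i, j), max(i, j)), []).append(f)
        obs = {k: float(np.mean(v)) for k, v in merged.items()}

    complete = len(obs) == n * (n - 1) or (average_orders and len(obs) == n * (n - 1) // 2)
    if complete:
        b = np.zeros(n)
        for (i, j), f in obs.items():
            b[i] += f
            b[j] += f
        # Both orders present doubles every row; the closed form is invariant
        # to that overall scale only if we rescale b accordingly.
        scale = 2.0 if not average_orders else 1.0
        b = b / scale
        x = (b - b.sum() / (2 * n - 2)) / (n - 2)
        return pd.Series(x, index=guides, name="f_g")

    A = np.zeros((n, n))
    b = np.zeros(n)
    for (i, j), f in obs.items():
        for row, other in ((i, j), (j, i)):
            A[row, row] += 1.0
            A[row, other] += 1.0
            b[row] += f
    degree = np.diag(A)
    if (degree == 0).any():
        missing = [guides[k] for k in np.where(degree == 0)[0]]
        raise ValueError(f"guides with no observed pair: {missing}")
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    return pd.Series(x, index=guides, name="f_g")


def impute_single_fitness(
    fitness: pd.DataFrame, average_orders: bool = False
) -> pd.DataFrame:
    """Per-(timepoint, replicate) single-guide fitness table.

    ``fitness`` is the construct-level table from
    :func:`cdkp.counting.compute_fitness` (columns g1, g2, timepoint,
    replicate, f). Returns columns guide_id, timepoint, replicate, f_g.
    """
    _require(fitness, ["g1", "g2", "timepoint", "replicate", "f"])
    out = []
    for (t, r), sub in fitness.groupby(["timepoint", "replicate"]):
        guides = sorted(set(sub["g1"]) | set(sub["g2"]))
        pf = {
            (a, b): f
            for a, b, f in zip(sub["g1"], sub["g2"], sub["f"])
        }
        singles = solve_single_fitness(pf, guides, average_orders=average_orders)
        out.append(
            pd.DataFrame(
                {
                    "guide_id": singles.index,
                    "timepoint": t,
                    "replicate": r,
                    "f_g": singles.to_numpy(),
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def score_pi(fitness: pd.DataFrame, singles: pd.DataFrame) -> pd.DataFrame:
    """Guide-level interaction: pi = f_pair - f_g1 - f_g2, per sample."""
    _require(fitness, ["g1", "g2", "timepoint", "replicate", "f"])
    _require(singles, ["guide_id", "timepoint", "replicate", "f_g"])
    s = singles.set_index(["guide_id", "timepoint", "replicate"])["f_g"]
    df = fitness.copy()
    k1 = pd.MultiIndex.from_frame(df[["g1", "timepoint", "replicate"]])
    k2 = pd.MultiIndex.from_frame(df[["g2", "timepoint", "replicate"]])
    f1 = s.reindex(k1).to_numpy()
    f2 = s.reindex(k2).to_numpy()
    if np.isnan(f1).any() or np.isnan(f2).any():
        raise ValueError("single-guide fitness missing for some constructs")
    df["pi"] = df["f"].to_numpy() - f1 - f2
    return df


def aggregate_genes(
    pi_guide: pd.DataFrame,
    guide_to_gene: Mapping[str, str],
    include_same_gene: bool = False,
) -> pd.DataFrame:
    """Mean guide-level pi per unordered gene pair, per sample.

    All guide combinations and both cassette orders are pooled (4 guides per
    gene and full data -> 32 values per gene pair). Gene pairs with zero
    observed combinations are simply absent. Same-gene pairs (two different
    guides of one gene) are excluded by default.

    Returns columns gene_a, gene_b (sorted), timepoint, replicate, score,
    n_combinations.
    """
    _require(pi_guide, ["g1", "g2", "timepoint", "replicate", "pi"])
    df = pi_guide.copy()
    unmapped = (set(df["g1"]) | set(df["g2"])) - set(guide_to_gene)
    if unmapped:
        raise ValueError(f"guides without a gene label: {sorted(unmapped)[:5]}")
    ga = df["g1"].map(guide_to_gene)
    gb = df["g2"].map(guide_to_gene)
    swap = ga > gb
    df["gene_a"] = ga.where(~swap, gb)
    df["gene_b"] = gb.where(~swap, ga)
    if not include_same_gene:
        df = df[df["gene_a"] != df["gene_b"]]
    agg = (
        df.groupby(["gene_a", "gene_b", "timepoint", "replicate"])["pi"]
        .agg(score="mean", n_combinations="size")
        .reset_index()
    )
    return agg


def summarize_and_call(
    gene_scores: pd.DataFrame, z_cut: float = 2.0
) -> pd.DataFrame:
    """Z-normalize gene scores per sample, median across samples, and call.

    The raw gene-pair scores are z-scored over all gene pairs within each
    (timepoint, replicate); the final interaction score is the median z
    across all samples. Taking a median across samples shrinks the score's
    spread (the per-sample z's are only weakly correlated), so the median is
    not itself unit-normal; ``final_z`` re-standardizes it across gene pairs
    and calls apply ``z_cut`` there, keeping the threshold's nominal
    normal-tail meaning: final_z <= -z_cut is ``synthetic_lethal``,
    >= +z_cut ``synergistic``, otherwise ``none``. Pooling screens of
    several cell lines is done upstream by assigning each line distinct
    replicate labels ("pan" mode).
    """
    if z_cut <= 0:
        raise ValueError("z_cut must be positive")
    _require(gene_scores, ["gene_a", "gene_b", "timepoint", "replicate", "score"])
    df = gene_scores.copy()
    grouped = df.groupby(["timepoint", "replicate"])["score"]
    mu = grouped.transform("mean")
    sd = grouped.transform(lambda s: s.to_numpy().std(ddof=0))
    if (sd == 0).any():
        raise ValueError("degenerate sample: zero variance of gene scores")
    df["z"] = (df["score"] - mu) / sd
    final = (
        df.groupby(["gene_a", "gene_b"])
        .agg(
            gene_final=("z", "median"),
            n_samples=("z", "size"),
            mean_combinations=("n_combinations", "mean")
            if "n_combinations" in df.columns
            else ("z", "size"),
        )
        .reset_index()
    )
    spread = final["gene_final"].to_numpy().std(ddof=0)
    if spread == 0:
        raise ValueError("degenerate screen: all gene pairs share one score")
    final["final_z"] = (final["gene_final"] - final["gene_final"].mean()) / spread
    final["call"] = "none"
    final.loc[final["final_z"] <= -z_cut, "call"] = "synthetic_lethal"
    final.loc[final["final_z"] >= z_cut, "call"] = "synergistic"
    return final, df


def score_screen(
    counts: pd.DataFrame,
    guide_to_gene: Mapping[str, str],
    pseudocount: float = 1.0,
    t0: int | float | None = None,
    z_cut: float = 2.0,
    average_orders: bool = False,
) -> dict:
    """End-to-end scoring: counts -> abundance -> fitness -> pi -> gene calls.

    Returns a dict with keys ``fitness`` (construct level), ``singles``,
    ``pi`` (guide level), ``gene_scores`` (per sample), ``gene_z`` and
    ``gene_final`` (with calls).
    """
    from .counting import compute_abundance, compute_fitness

    ab = compute_abundance(counts, pseudocount=pseudocount)
    fit = compute_fitness(ab, t0=t0)
    singles = impute_single_fitness(fit, average_orders=average_orders)
    pi = score_pi(fit, singles)
    gene_scores = aggregate_genes(pi, guide_to_gene)
    final, gene_z = summarize_and_call(gene_scores, z_cut=z_cut)
    return {
        "fitness": fit,
        "singles": singles,
        "pi": pi,
        "gene_scores": gene_scores,
        "gene_z": gene_z,
        "gene_final": final,
    }


def _require(df: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns {missing}")
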