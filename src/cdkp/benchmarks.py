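"""Planted-truth benchmarks of every pipeline stage on synthetic data.

Each function simulates data under the package's default study conditions,
runs the corresponding analysis end to end, and reports how well the planted
ground truth is recovered. They power both the test suite and the
reproduction script, and are useful for sanity-checking parameter changes.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from . import cellcycle as cc
from .counting import count_pairs, match_read
from .effects import (
    QCConfig,
    contour_covers,
    differential_expression,
    knockout_profiles,
    magnitude_vs_fitness,
    qc_and_normalize,
)
from .interactions import score_screen, solve_single_fitness
from .library import build_reference, enumerate_pairs
from .simulate import (
    default_cell_truth,
    default_coverage_truth,
    default_marker_sets,
    default_screen_truth,
    simulate_cells,
    simulate_exon_coverage,
    simulate_knockout_expression,
    simulate_reads,
    simulate_screen,
    synthetic_library,
)

__all__ = [
    "library_combinatorics",
    "imputation_oracle",
    "screen_recovery",
    "screen_null_calibration",
    "counting_exactness",
    "cellcycle_recovery",
    "ko_shift_detection",
    "kuiper_type1_rate",
    "signal_removal",
    "de_benchmark",
    "contour_coverage",
    "magnitude_fitness_benchmark",
    "coverage_bias_benchmark",
]


# ---------------------------------------------------------------------------
# library & imputation
# ---------------------------------------------------------------------------

def library_combinatorics(seed: int = 0) -> dict:
    """Design counts of the full 112-guide dual-guide library."""
    lib = synthetic_library(n_genes=26, guides_per_gene=4, seed=seed)
    pairs = enumerate_pairs(lib)
    ref = build_reference(lib)
    # guide-level pi values pooled per gene pair: 4 x 4 combinations x 2 orders
    g2g = lib.guide_to_gene()
    a, b = lib.genes[0], lib.genes[1]
    combos = sum(
        1
        for g1, g2 in pairs
        if {g2g[g1], g2g[g2]} == {a, b}
    )
    return {
        "n_guides": len(lib),
        "n_pairs": len(pairs),
        "n_contigs": len(ref),
        "combos_per_gene_pair": combos,
    }


def imputation_oracle(seed: int = 0, n_range: tuple[int, int] = (3, 20)) -> dict:
    """Closed-form single-fitness solve vs a generic dense solver."""
    max_err = 0.0
    max_pi_additive = 0.0
    for n in range(n_range[0], n_range[1] + 1):
        rng = np.random.default_rng(seed + n)
        F = rng.normal(size=(n, n))
        guides = [f"g{i}" for i in range(n)]
        pairs = {
            (guides[i], guides[j]): float(F[i, j])
            for i in range(n)
            for j in range(n)
            if i != j
        }
        got = solve_single_fitness(pairs, guides).to_numpy()
        # independent generic solve of the same per-row system
        A = np.zeros((n, n))
        b = np.zeros(n)
        idx = {g: k for k, g in enumerate(guides)}
        for (x, y), f in pairs.items():
            for row, other in ((idx[x], idx[y]), (idx[y], idx[x])):
                A[row, row] += 1
                A[row, other] += 1
                b[row] += f
        exp = np.linalg.lstsq(A, b, rcond=None)[0]
        max_err = max(max_err, float(np.max(np.abs(got - exp))))

        a_vec = rng.normal(size=n)
        additive = {
            (guides[i], guides[j]): float(a_vec[i] + a_vec[j])
            for i in range(n)
            for j in range(n)
            if i != j
        }
        singles = solve_single_fitness(additive, guides).to_numpy()
        max_err = max(max_err, float(np.max(np.abs(singles - a_vec))))
        pi_residual = max(
            abs(f - singles[idx[x]] - singles[idx[y]])
            for (x, y), f in additive.items()
        )
        max_pi_additive = max(max_pi_additive, float(pi_residual))
    return {"solver_max_abs_error": max_err, "additive_max_abs_pi": max_pi_additive}


# ---------------------------------------------------------------------------
# screen
# ---------------------------------------------------------------------------

PLANTED_PAIR = ("GENE03", "GENE07")


def screen_recovery(
    seed: int = 0,
    n_genes: int = 20,
    depth: int = 1_000_000,
    planted_pi: float = -1.5,
) -> dict:
    """Recovery of a planted interaction and of single-guide fitnesses.

    Simulates the default screen (3 post-baseline timepoints x 2 replicates)
    with one planted synthetic-lethal gene pair, scores it, and reports the
    planted pair's rank among gene-level final scores, the Spearman
    correlation of planted vs imputed guide fitness, and the planted
    interaction recovered in planted units (per-sample affine alignment of
    construct fitness on the planted growth rates undoes the timepoint
    scaling and z-standardization).
    """
    lib = synthetic_library(n_genes=n_genes, seed=seed)
    truth = default_screen_truth(
        lib, seed=seed, depth=depth, pi_true={PLANTED_PAIR: planted_pi}
    )
    counts = simulate_screen(lib, truth)
    res = score_screen(counts, lib.guide_to_gene())

    final = res["gene_final"].sort_values("gene_final").reset_index(drop=True)
    mask = (final["gene_a"] == PLANTED_PAIR[0]) & (final["gene_b"] == PLANTED_PAIR[1])
    rank = int(final.index[mask][0]) + 1

    singles = res["singles"]
    last_t = singles["timepoint"].max()
    f_g = singles[singles["timepoint"] == last_t].groupby("guide_id")["f_g"].mean()
    rho = float(
        stats.spearmanr([truth.f_true[g] for g in f_g.index], f_g.to_numpy()).statistic
    )

    g2g = lib.guide_to_gene()
    recovered = []
    for (t, r), sub in res["pi"].groupby(["timepoint", "replicate"]):
        rate = np.array(
            [
                truth.f_true[x] + truth.f_true[y] + truth.pi_of(g2g[x], g2g[y])
                for x, y in zip(sub["g1"], sub["g2"])
            ]
        )
        slope = np.polyfit(rate, sub["f"], 1)[0]
        genes_a = sub["g1"].map(g2g)
        genes_b = sub["g2"].map(g2g)
        hit = ((genes_a == PLANTED_PAIR[0]) & (genes_b == PLANTED_PAIR[1])) | (
            (genes_a == PLANTED_PAIR[1]) & (genes_b == PLANTED_PAIR[0])
        )
        recovered.append(float(sub.loc[hit, "pi"].mean() / slope))
    return {
        "planted_pair_rank": rank,
        "planted_pi": planted_pi,
        "pi_recovered": float(np.mean(recovered)),
        "fitness_spearman": rho,
        "n_gene_pairs": len(final),
    }


def screen_null_calibration(
    seed: int = 0, n_seeds: int = 20, n_genes: int = 20, depth: int = 1_000_000
) -> dict:
    """Per-tail call rate at |z| >= 2 under a no-interaction null."""
    neg, pos, n_pairs = [], [], 0
    for k in range(n_seeds):
        s = (seed + 7919 * k) % (2**31)
        lib = synthetic_library(n_genes=n_genes, n_ntc=0, n_aavs=0, seed=s)
        truth = default_screen_truth(lib, seed=s, depth=depth)
        res = score_screen(simulate_screen(lib, truth), lib.guide_to_gene())
        fz = res["gene_final"]["final_z"]
        neg.append(float((fz <= -2).mean()))
        pos.append(float((fz >= 2).mean()))
        n_pairs += len(fz)
    return {
        "neg_tail_pct": 100 * float(np.mean(neg)),
        "pos_tail_pct": 100 * float(np.mean(pos)),
        "n_gene_pairs_total": n_pairs,
    }


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def _dp_levenshtein_prefix(query: str, target: str) -> int:
    # independent dynamic-programming oracle (min edit distance to a prefix)
    m, n = len(query), len(target)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        qi = query[i - 1]
        for j in range(1, n + 1):
            cost = 0 if qi == target[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return min(prev)


def counting_exactness(seed: int = 0, n_genes: int = 8, mean_count: int = 20) -> dict:
    """Error-free read counting closure, edit-distance filter, oracle audit."""
    lib = synthetic_library(n_genes=n_genes, guides_per_gene=4, seed=seed)
    ref = build_reference(lib)
    pairs = enumerate_pairs(lib)
    rng = np.random.default_rng(seed)
    truth_counts = pd.DataFrame(
        {
            "g1": [a for a, _ in pairs],
            "g2": [b for _, b in pairs],
            "timepoint": 0.0,
            "replicate": 1,
            "count": rng.poisson(mean_count, size=len(pairs)),
        }
    )
    reads = simulate_reads(truth_counts, lib, error_rate=0.0, seed=seed)
    table, report = count_pairs(
        ((rid, r1) for rid, r1, _ in reads),
        ((rid, r2) for rid, _, r2 in reads),
        lib,
        ref,
    )
    merged = table.merge(truth_counts, on=["g1", "g2"], suffixes=("_got", "_true"))
    exact = bool((merged["count_got"] == merged["count_true"]).all())

    # edit-distance filter: k substitutions for k in 1..3
    from .library import READ1_PREFIX, READ1_SUFFIX

    accept = {}
    g = lib.guides[0]
    for k in (1, 2, 3):
        spacer = list(g.spacer)
        for i in range(k):
            spacer[5 * i] = "A" if spacer[5 * i] != "A" else "C"
        gid, d, _ = match_read(READ1_PREFIX + "".join(spacer) + READ1_SUFFIX, 1, ref)
        accept[k] = gid is not None
    # oracle agreement on randomized reads
    small = synthetic_library(n_genes=2, guides_per_gene=4, seed=seed + 1)
    small_ref = build_reference(small)
    contigs = list(small_ref.contigs.items())
    bases = "ACGT"
    agree = 0
    n_oracle = 1000
    for _ in range(n_oracle):
        (pos, _gid), contig = contigs[rng.integers(len(contigs))]
        read = list(contig)
        for _ in range(rng.integers(0, 5)):
            op = rng.integers(3)
            i = int(rng.integers(len(read)))
            if op == 0:
                read[i] = bases[rng.integers(4)]
            elif op == 1 and len(read) > 40:
                del read[i]
            else:
                read.insert(i, bases[rng.integers(4)])
        seq = "".join(read)
        got_gid, got_d, _ = match_read(seq, pos, small_ref)
        off = small_ref.spacer_offset(pos)
        window = seq[off : off + 22]
        dists = sorted(
            (
                _dp_levenshtein_prefix(c[off : off + 20], window),
                gid2,
            )
            for (p2, gid2), c in small_ref.contigs.items()
            if p2 == pos
        )
        d0, oracle_gid = dists[0]
        if d0 > 2 or (len(dists) > 1 and dists[1][0] == d0):
            oracle_gid = None
        agree += got_gid == oracle_gid
    return {
        "count_table_exact": exact,
        "n_reads": int(report.n_pairs),
        "edit1_accepted": accept[1],
        "edit2_accepted": accept[2],
        "edit3_rejected": not accept[3],
        "oracle_agreement_pct": 100.0 * agree / n_oracle,
    }


# ---------------------------------------------------------------------------
# cell cycle
# ---------------------------------------------------------------------------

def cellcycle_recovery(
    seed: int = 0, n_cells: int = 2000, mds_n_init: int = 4
) -> dict:
    """Circular embedding of the default (unperturbed) simulation.

    Reports the Fisher-Lee circular correlation between inferred and planted
    angles, the worst planted-boundary recovery error over the five phase
    cutpoints, and arc contiguity (each phase should occupy one arc).
    """
    markers = default_marker_sets()
    adata = simulate_cells(default_cell_truth(seed=seed), markers, n_cells=n_cells)
    norm = cc.normalize_counts(adata.to_df())
    E_ik, E_i = cc.phase_scores(norm, markers)
    coarse = cc.coarse_classify(E_ik)
    emb = cc.embed_cells(E_i, coarse, seed=seed, n_init=mds_n_init)
    corr = cc.circular_correlation(
        emb["theta"].to_numpy(), adata.obs["theta_true"].to_numpy()
    )

    rmap, _ = cc.assign_phase_ranges(emb["theta"], coarse, n_bins=60)
    recovered_edges = sorted(
        {arc[0] % (2 * np.pi) for arcs in rmap.merged_ranges.values() for arc in arcs}
    )
    errs = []
    for edge in cc.DEFAULT_PHASE_BOUNDARIES[:-1]:
        d = min(
            min(abs(r - edge), 2 * np.pi - abs(r - edge)) for r in recovered_edges
        )
        errs.append(d)
    arcs_per_phase = [len(v) for v in rmap.merged_ranges.values() if v]
    return {
        "circular_correlation": float(corr),
        "boundary_max_error_deg": float(np.degrees(max(errs))),
        "max_arcs_per_phase": int(max(arcs_per_phase)),
        "n_cells": n_cells,
    }


def ko_shift_detection(
    seed: int = 0, n_cells: int = 1500, ko_fraction: float = 1 / 3
) -> dict:
    """Kuiper detection of a knockout concentrating cells near G1/S.

    A third of the cells carry a knockout whose phase density piles up at
    the G1/S arc center (~500 knockout cells); the rest are uniform
    controls. Angles are inferred by the full embedding pipeline before
    testing.
    """
    g1s_center = float(
        (cc.DEFAULT_PHASE_BOUNDARIES[2] + cc.DEFAULT_PHASE_BOUNDARIES[3]) / 2
    )
    truth = default_cell_truth(
        seed=seed,
        ko_fractions={"CDK_KO": ko_fraction},
        density_shift={"CDK_KO": (g1s_center, 4.0, 0.6)},
    )
    markers = default_marker_sets()
    adata = simulate_cells(truth, markers, n_cells=n_cells)
    norm = cc.normalize_counts(adata.to_df())
    E_ik, E_i = cc.phase_scores(norm, markers)
    coarse = cc.coarse_classify(E_ik)
    emb = cc.embed_cells(E_i, coarse, seed=seed, n_init=2)
    ctrl = (adata.obs["knockout"] == "control").to_numpy()
    v, p = cc.kuiper_test(
        emb["theta"].to_numpy()[~ctrl], emb["theta"].to_numpy()[ctrl]
    )
    return {
        "kuiper_V": float(v),
        "kuiper_p": float(p),
        "n_ko_cells": int((~ctrl).sum()),
    }


def kuiper_type1_rate(seed: int = 0, trials: int = 1000, n: int = 200) -> dict:
    """Rejection rate at p < 0.05 for two same-distribution angular samples."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(trials):
        a = rng.uniform(0, 2 * np.pi, n)
        b = rng.uniform(0, 2 * np.pi, n)
        _, p = cc.kuiper_test(a, b)
        hits += p < 0.05
    return {"type1_rate_pct": 100.0 * hits / trials, "trials": trials}


def signal_removal(seed: int = 0, n_cells: int = 800) -> dict:
    """Cell-cycle signal removal: markers flattened, background preserved."""
    markers = default_marker_sets()
    adata = simulate_cells(default_cell_truth(seed=seed), markers, n_cells=n_cells)
    norm = cc.normalize_counts(adata.to_df())
    E_ik, E_i = cc.phase_scores(norm, markers)
    coarse = cc.coarse_classify(E_ik)
    emb = cc.embed_cells(E_i, coarse, seed=seed)
    resid = cc.remove_cellcycle_signal(norm, E_ik, emb["theta"])
    th = emb["theta"].to_numpy()

    def theta_r2(values: np.ndarray) -> float:
        fit = cc._periodic_loess(th, values, span=0.3)
        return 1.0 - np.var(values - fit) / np.var(values)

    marker_r2 = [theta_r2(resid[g].to_numpy()) for g in markers.all_genes[::5]]
    bg = [g for g in norm.columns if g.startswith("BG")]
    bg_corr = [float(np.corrcoef(norm[g], resid[g])[0, 1]) for g in bg]
    return {
        "marker_theta_r2_max_pct": 100.0 * float(np.max(marker_r2)),
        "background_r_median": float(np.median(bg_corr)),
        "n_cells": n_cells,
    }


# ---------------------------------------------------------------------------
# expression effects
# ---------------------------------------------------------------------------

def _balanced_signature(n_de: int, offset: int = 0) -> dict[str, float]:
    # mass-balanced: one third doubled (+1), two thirds halved (-1)
    n_up = n_de // 3
    return {
        f"G{j + 1 + offset:04d}": (1.0 if j < n_up else -1.0) for j in range(n_de)
    }


def de_benchmark(
    seed: int = 0,
    n_genes: int = 2000,
    n_de: int = 200,
    cells_per_group: int = 200,
    n_knockouts: int = 3,
) -> dict:
    """Mann-Whitney/BH differential expression on planted signatures.

    Each knockout carries a mass-balanced 200-gene signature; recall and
    empirical FDR are pooled over knockouts.
    """
    effects = {
        f"KO{k}": _balanced_signature(n_de, offset=k * n_de)
        for k in range(n_knockouts)
    }
    adata = simulate_knockout_expression(
        effects,
        n_genes=n_genes,
        cells_per_knockout=cells_per_group,
        baseline_cells=cells_per_group,
        seed=seed,
    )
    norm = qc_and_normalize(adata, QCConfig(min_genes_per_cell=5))
    tp = fp = fn = 0
    for ko, shifts in effects.items():
        res = differential_expression(norm, ko)
        called = set(res.index[res["de"]])
        truth = set(shifts)
        tp += len(called & truth)
        fp += len(called - truth)
        fn += len(truth - called)
    return {
        "recall_pct": 100.0 * tp / (tp + fn),
        "fdr_pct": 100.0 * fp / max(tp + fp, 1),
        "n_planted_per_knockout": n_de,
        "n_knockouts": n_knockouts,
    }


def contour_coverage(
    seed: int = 0,
    runs: int = 500,
    n_cells: int = 250,
    n_boot: int = 300,
    n_genes: int = 30,
) -> dict:
    """Coverage of the true median by the bootstrap 95% contour.

    Each run simulates a null knockout, bootstraps its median fold-change
    profile, and checks whether the knockout's 95% contour (over two
    representative genes) covers the true value — the population median
    expression minus the run's fixed baseline. Per-gene base means depend on
    the run's seed, so the population median is estimated per run from a
    large companion simulation sharing that seed (hence the same means).
    """
    pick_idx = [n_genes // 3, 2 * n_genes // 3]
    covered = 0
    log2 = math.log(2.0)
    for run in range(runs):
        s = (seed + 104729 * (run + 1)) % (2**31)
        adata = simulate_knockout_expression(
            {"KO": {}},
            n_genes=n_genes,
            cells_per_knockout=n_cells,
            baseline_cells=2 * n_cells,
            seed=s,
        )
        norm = qc_and_normalize(adata, QCConfig(min_genes_per_cell=1))
        base_mask = np.asarray(adata.obs["knockout"]) == "AAVS1"
        base_med = np.median(np.asarray(norm.X)[base_mask], axis=0)
        profs = knockout_profiles(norm, n_boot=n_boot, seed=s)
        cloud = profs["KO"].boot_medians[:, pick_idx]

        big = simulate_knockout_expression(
            {}, n_genes=n_genes, baseline_cells=20_000, seed=s
        )
        big_norm = qc_and_normalize(big, QCConfig(min_genes_per_cell=1))
        pop_median = np.median(np.asarray(big_norm.X), axis=0)
        true_lfc = (pop_median[pick_idx] - base_med[pick_idx]) / log2
        covered += contour_covers(true_lfc, cloud)
    return {"coverage_pct": 100.0 * covered / runs, "runs": runs}


def magnitude_fitness_benchmark(seed: int = 0) -> dict:
    """Transcriptional magnitude vs fitness when effect size tracks -fitness."""
    fitness = {}
    effects = {}
    for i, f in enumerate([-3.0, -2.5, -2.0, -1.5, -1.0, -0.5, 0.0]):
        ko = f"KO{i}"
        effects[ko] = _balanced_signature(int(-f * 30))
        fitness[ko] = f
    adata = simulate_knockout_expression(
        effects, n_genes=400, cells_per_knockout=80, baseline_cells=120, seed=seed
    )
    norm = qc_and_normalize(adata, QCConfig(min_genes_per_cell=5))
    profs = knockout_profiles(norm, n_boot=20, seed=seed)
    r, p, _ = magnitude_vs_fitness(profs, pd.Series(fitness))
    return {"pearson_r": float(r), "p": float(p), "n_knockouts": len(fitness)}


# ---------------------------------------------------------------------------
# coverage bias
# ---------------------------------------------------------------------------

def coverage_bias_benchmark(seed: int = 0, planted_bias: float = 2.0) -> dict:
    """Planted 5' bias recovery, NTC self-contrast, cluster separation."""
    from .coverage import classify_exons, cluster_bias, exon_coverage, five_prime_bias

    n_biased = 10
    biased_genes = [f"SIMG{i + 1:03d}" for i in range(n_biased)]
    truth = default_coverage_truth(
        seed=seed,
        n_genes=40,
        bias_true={("KO_A", g): planted_bias for g in biased_genes},
    )
    counts, gtf = simulate_exon_coverage(truth)
    records = classify_exons(gtf, from_string=True)
    cov = exon_coverage(counts, records)
    _, bias = five_prime_bias(cov, list(truth.ntc_samples))
    hit = bias[(bias["sample"] == "KO_A") & bias["gene_id"].isin(biased_genes)]

    # NTC against itself: identically zero
    ntc_dup = counts[counts["sample"] == "NTC_1"].assign(sample="KO_SELF")
    cov_self = exon_coverage(
        pd.concat([counts[counts["sample"] == "NTC_1"], ntc_dup]), records
    )
    _, bias_self = five_prime_bias(cov_self, ["NTC_1"])

    # cluster separation on KO_A bias: biased vs unbiased genes
    labels, _ = cluster_bias(bias[bias["sample"] == "KO_A"], n_clusters=2)
    biased_labels = set(labels.reindex(biased_genes).dropna())
    other_labels = set(labels.drop(index=biased_genes, errors="ignore"))
    clean_split = len(biased_labels) == 1 and biased_labels.isdisjoint(other_labels)
    return {
        "planted_bias": planted_bias,
        "bias_recovered_mean": float(hit["bias5"].mean()),
        "bias_recovered_max_err": float((hit["bias5"] - planted_bias).abs().max()),
        "ntc_self_bias_max_abs": float(bias_self["bias5"].abs().max()),
        "cluster_recovery_clean": bool(clean_split),
        "reads_per_gene": truth.reads_per_gene,
    }
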