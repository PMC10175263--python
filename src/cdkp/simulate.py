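"""Synthetic data generators with planted ground truth.

Every downstream analysis in this package has a matching simulator here:

* :func:`simulate_screen` — exponential clonal growth of dual-guide
  constructs with multiplicative (log-additive) fitness plus planted
  interaction terms, read out under multinomial sequencing noise;
* :func:`simulate_reads` — paired cassette reads for a count table, with
  iid per-base substitution errors;
* :func:`simulate_cells` — single cells on a circular cell-cycle coordinate
  whose marker programs are smooth unimodal bumps of the phase angle,
  sampled with gamma-Poisson (negative binomial) counting noise, including
  knockout-specific distortions of the angular density;
* :func:`simulate_exon_coverage` — per-exon read counts with planted 5'
  (first-exon) enrichment for chosen knockouts, plus the matching GTF.

All generators are pure functions of their inputs and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cellcycle import DEFAULT_PHASE_BOUNDARIES, PHASES, PhaseGeneSets
from .counting import COUNT_COLUMNS
from .library import (
    DNA_ALPHABET,
    Guide,
    GuideLibrary,
    READ1_PREFIX,
    READ1_SUFFIX,
    READ2_PREFIX,
    READ2_SUFFIX,
    SPACER_LEN,
    enumerate_pairs,
)

__all__ = [
    "synthetic_library",
    "ScreenTruth",
    "default_screen_truth",
    "simulate_screen",
    "simulate_reads",
    "write_fastq_pair",
    "CellSimTruth",
    "default_marker_sets",
    "default_cell_truth",
    "simulate_cells",
    "simulate_knockout_expression",
    "CoverageSimTruth",
    "default_coverage_truth",
    "simulate_exon_coverage",
]


# ---------------------------------------------------------------------------
# guide library
# ---------------------------------------------------------------------------

def synthetic_library(
    n_genes: int = 26,
    guides_per_gene: int = 4,
    n_ntc: int = 4,
    n_aavs: int = 4,
    seed: int = 0,
) -> GuideLibrary:
    """Random guide library shaped like a combinatorial knockout design.

    Defaults mirror a 26-gene, 4-guides-per-gene design with 4 non-targeting
    and 4 safe-harbor control guides (112 guides total). Spacers are random
    distinct 20-mers.
    """
    rng = np.random.default_rng(seed)
    spacers: set[str] = set()

    def draw_spacer() -> str:
        while True:
            s = "".join(rng.choice(list(DNA_ALPHABET), SPACER_LEN))
            if s not in spacers:
                spacers.add(s)
                return s

    guides = []
    for gi in range(n_genes):
        gene = f"GENE{gi + 1:02d}"
        for k in range(guides_per_gene):
            guides.append(Guide(f"{gene}_g{k + 1}", gene, draw_spacer()))
    for k in range(n_ntc):
        guides.append(Guide(f"NTC_g{k + 1}", "NTC", draw_spacer()))
    for k in range(n_aavs):
        guides.append(Guide(f"AAVS1_g{k + 1}", "AAVS1", draw_spacer()))
    return GuideLibrary(guides, n_guides_per_gene=guides_per_gene)


# ---------------------------------------------------------------------------
# screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenTruth:
    """Planted parameters of a fitness screen.

    ``f_true`` maps guide_id to its per-screen log2 fitness effect (0 for
    controls), ``pi_true`` maps an unordered gene pair to a planted
    interaction. ``tau`` is the growth timescale; by default the full screen
    duration, so fitness units are log2 change per screen.
    """

    f_true: dict[str, float]
    pi_true: dict[tuple[str, str], float] = field(default_factory=dict)
    depth: int = 1_000_000
    timepoints: tuple[float, ...] = (0.0, 7.0, 14.0, 21.0)
    replicates: int = 2
    seed: int = 0
    tau: float | None = None
    p0_log_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        self.pi_true = {
            tuple(sorted(k)): v for k, v in self.pi_true.items()
        }

    def pi_of(self, gene_a: str, gene_b: str) -> float:
        return self.pi_true.get(tuple(sorted((gene_a, gene_b))), 0.0)


def default_screen_truth(
    library: GuideLibrary,
    seed: int = 0,
    fitness_sd: float = 1.0,
    pi_true: dict[tuple[str, str], float] | None = None,
    depth: int = 1_000_000,
) -> ScreenTruth:
    """Gaussian fitness effects for targeting guides, zero for controls.

    Guides of the same gene share the gene's fitness effect plus small
    guide-level variation (sd 0.2 * fitness_sd), mimicking variable cutting
    efficiency.
    """
    rng = np.random.default_rng(seed)
    gene_f = {g: float(rng.normal(0, fitness_sd)) for g in library.genes}
    gene_f["NTC"] = 0.0
    gene_f["AAVS1"] = 0.0
    f_true = {}
    for g in library:
        jitter = 0.0 if g.is_control else float(rng.normal(0, 0.2 * fitness_sd))
        f_true[g.guide_id] = gene_f[g.gene] + jitter
    return ScreenTruth(
        f_true=f_true, pi_true=dict(pi_true or {}), depth=depth, seed=seed
    )


def simulate_screen(library: GuideLibrary, truth: ScreenTruth) -> pd.DataFrame:
    """Multinomial counts of an exponentially growing construct pool.

    Construct abundance follows p(t) ∝ p(t0) * 2^((f_g1 + f_g2 + pi) * t/tau)
    and each (timepoint, replicate) sample draws exactly ``depth`` reads
    multinomially. Initial abundances are mildly lognormal around uniform
    (library synthesis unevenness). Deterministic given ``truth.seed``.
    """
    missing = [g for g in truth.f_true if g not in library]
    if missing:
        raise ValueError(f"truth refers to guides absent from library: {missing[:5]}")
    pairs = enumerate_pairs(library)
    g2gene = library.guide_to_gene()
    rng = np.random.default_rng(truth.seed)

    tau = truth.tau if truth.tau is not None else max(truth.timepoints) or 1.0
    rate = np.array(
        [
            truth.f_true.get(a, 0.0)
            + truth.f_true.get(b, 0.0)
            + truth.pi_of(g2gene[a], g2gene[b])
            for a, b in pairs
        ]
    )
    p0 = np.exp(rng.normal(0.0, truth.p0_log_sd, size=len(pairs)))
    p0 /= p0.sum()

    rows = []
    for rep in range(1, truth.replicates + 1):
        for t in truth.timepoints:
            p = p0 * np.exp2(rate * t / tau)
            p /= p.sum()
            counts = rng.multinomial(truth.depth, p)
            rows.append(
                pd.DataFrame(
                    {
                        "g1": [a for a, _ in pairs],
                        "g2": [b for _, b in pairs],
                        "timepoint": t,
                        "replicate": rep,
                        "count": counts,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)[COUNT_COLUMNS]


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_reads(
    pair_counts: pd.DataFrame,
    library: GuideLibrary,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Paired cassette reads for one count-table sample.

    Emits ``(read_id, read1, read2)`` with read 1 = constant 5' context +
    position-1 spacer + 3' context and read 2 likewise for position 2,
    exactly ``count`` pairs per construct, with iid per-base substitutions at
    ``error_rate``. The input table must contain a single
    (timepoint, replicate) sample.
    """
    if not 0.0 <= error_rate <= 0.25:
        raise ValueError("error_rate must be in [0, 0.25]")
    samples = pair_counts[["timepoint", "replicate"]].drop_duplicates()
    if len(samples) != 1:
        raise ValueError(
            "pair_counts must hold one (timepoint, replicate) sample; "
            "filter before simulating reads"
        )
    rng = np.random.default_rng(seed)
    reads = []
    rid = 0
    for g1, g2, n in zip(pair_counts["g1"], pair_counts["g2"], pair_counts["count"]):
        if n == 0:
            continue
        r1 = READ1_PREFIX + library[g1].spacer + READ1_SUFFIX
        r2 = READ2_PREFIX + library[g2].spacer + READ2_SUFFIX
        for _ in range(int(n)):
            reads.append(
                (
                    f"read{rid}:{g1}:{g2}",
                    _mutate(r1, error_rate, rng),
                    _mutate(r2, error_rate, rng),
                )
            )
            rid += 1
    return reads


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0:
        return seq
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if len(hits) == 0:
        return seq
    out = list(seq)
    for i in hits:
        alternatives = [b for b in DNA_ALPHABET if b != out[i]]
        out[i] = alternatives[rng.integers(3)]
    return "".join(out)


def write_fastq_pair(
    reads: list[tuple[str, str, str]], r1_path: str | Path, r2_path: str | Path
) -> None:
    """Write simulated read pairs as two phred-33 FASTQ files."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for rid, r1, r2 in reads:
            f1.write(f"@{rid}\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{rid}\n{r2}\n+\n{'I' * len(r2)}\n")


# ---------------------------------------------------------------------------
# single cells
# ---------------------------------------------------------------------------

@dataclass
class CellSimTruth:
    """Planted parameters of a cycling single-cell population.

    Cells live at angles theta on the cell-cycle circle partitioned by
    ``phase_boundaries`` (canonical layout by default). Marker genes have
    mean expression baseline + amplitude * exp(kappa*(cos(theta - peak) - 1)),
    a smooth unimodal circular bump peaking inside their phase's arc.
    ``density_shift`` maps a knockout gene to (mu, kappa, weight): a fraction
    ``weight`` of its cells is drawn from a von Mises at mu instead of the
    uniform base density. ``noise`` is the gamma-Poisson overdispersion
    (variance = mean + noise * mean^2).
    """

    phase_boundaries: np.ndarray = field(
        default_factory=lambda: DEFAULT_PHASE_BOUNDARIES.copy()
    )
    ko_fractions: dict[str, float] = field(default_factory=dict)
    density_shift: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    amplitude: float = 4.0
    baseline: float = 0.3
    kappa: float = 4.0
    noise: float = 0.3
    background_mean: float = 1.5
    seed: int = 0


def default_marker_sets(n_per_phase: int = 20) -> PhaseGeneSets:
    """Synthetic marker genes, ``n_per_phase`` per phase, named by phase."""
    sets = {}
    for k in PHASES:
        tag = k.replace("/", "")
        sets[k] = [f"{tag}_MK{j + 1:02d}" for j in range(n_per_phase)]
    return PhaseGeneSets(sets)


def default_cell_truth(seed: int = 0, **overrides) -> CellSimTruth:
    return CellSimTruth(seed=seed, **overrides)


def simulate_cells(
    truth: CellSimTruth,
    marker_sets: PhaseGeneSets | None = None,
    n_cells: int = 2000,
    n_background_genes: int = 200,
):
    """Single-cell counts over marker plus background genes.

    Returns an :class:`anndata.AnnData` with raw counts in ``X``; ``obs``
    holds ``knockout`` ("control" or gene), planted ``theta_true`` and
    ``phase_true``; ``var`` holds each gene's phase (or "background"), peak
    angle and amplitude. Deterministic given ``truth.seed``.
    """
    import anndata as ad

    if marker_sets is None:
        marker_sets = default_marker_sets()
    if n_cells < 2 * len(PHASES):
        raise ValueError("need at least 2 cells per phase")
    frac_sum = sum(truth.ko_fractions.values())
    if frac_sum > 1.0 + 1e-9:
        raise ValueError("knockout fractions exceed 1")
    rng = np.random.default_rng(truth.seed)

    # cell assignment to knockouts
    kos = list(truth.ko_fractions)
    probs = [truth.ko_fractions[k] for k in kos] + [1.0 - frac_sum]
    assignment = rng.choice(len(kos) + 1, size=n_cells, p=probs)
    knockout = np.array([kos[i] if i < len(kos) else "control" for i in assignment])

    theta = rng.uniform(0, 2 * np.pi, size=n_cells)
    for ko, (mu, kappa, weight) in truth.density_shift.items():
        sel = np.flatnonzero(knockout == ko)
        shifted = sel[rng.random(len(sel)) < weight]
        theta[shifted] = rng.vonmises(mu, kappa, size=len(shifted)) % (2 * np.pi)

    bounds = np.asarray(truth.phase_boundaries)
    phase_idx = np.clip(
        np.searchsorted(bounds, theta, side="right") - 1, 0, len(PHASES) - 1
    )
    phase_true = np.array([PHASES[i] for i in phase_idx])

    # marker programs tile each phase arc evenly (cycling transcriptional
    # programs peak continuously around the cycle, not at one shared time)
    genes, peaks, amps, phases_of_gene = [], [], [], []
    for ki, k in enumerate(PHASES):
        lo, hi = bounds[ki], bounds[ki + 1]
        m = len(marker_sets[k])
        for j, g in enumerate(marker_sets[k]):
            genes.append(g)
            peaks.append(float(lo + (j + 0.5) * (hi - lo) / m))
            amps.append(truth.amplitude)
            phases_of_gene.append(k)
    for j in range(n_background_genes):
        genes.append(f"BG{j + 1:04d}")
        peaks.append(np.nan)
        amps.append(0.0)
        phases_of_gene.append("background")
    bg_means = np.exp(rng.normal(math.log(truth.background_mean), 0.5, n_background_genes))

    n_genes = len(genes)
    mean = np.empty((n_cells, n_genes))
    n_markers = n_genes - n_background_genes
    peak_arr = np.array(peaks[:n_markers])
    amp_arr = np.array(amps[:n_markers])
    mean[:, :n_markers] = truth.baseline + amp_arr[None, :] * np.exp(
        truth.kappa * (np.cos(theta[:, None] - peak_arr[None, :]) - 1.0)
    )
    mean[:, n_markers:] = bg_means[None, :]

    if truth.noise > 0:
        shape = 1.0 / truth.noise
        lam = mean * rng.gamma(shape, 1.0 / shape, size=mean.shape)
    else:
        lam = mean
    counts = rng.poisson(lam).astype(np.int32)

    obs = pd.DataFrame(
        {
            "knockout": knockout,
            "theta_true": theta,
            "phase_true": phase_true,
        },
        index=[f"cell{i:05d}" for i in range(n_cells)],
    )
    var = pd.DataFrame(
        {"phase": phases_of_gene, "peak_angle": peaks, "amplitude": amps},
        index=genes,
    )
    return ad.AnnData(X=counts, obs=obs, var=var)


# ---------------------------------------------------------------------------
# knockout transcriptomes
# ---------------------------------------------------------------------------

def simulate_knockout_expression(
    knockout_effects: dict[str, dict[str, float]],
    n_genes: int = 1000,
    cells_per_knockout: int = 200,
    baseline_cells: int = 200,
    baseline_label: str = "AAVS1",
    mean_log_mu: float = 2.5,
    mean_log_sd: float = 0.8,
    noise: float = 0.3,
    preserve_total: bool = True,
    seed: int = 0,
):
    """Single-cell counts for knockouts with planted expression shifts.

    Genes are named ``G0001``..; per-gene base means are lognormal.
    ``knockout_effects`` maps a knockout label to {gene: log2 shift}; cells
    of that knockout have the gene's mean multiplied by 2**shift. With
    ``preserve_total`` (default) each knockout's mean vector is rescaled to
    the baseline total, mimicking a compositional readout with unchanged
    library size — the regime in which total-count normalization is exact.
    Counts are gamma-Poisson with overdispersion ``noise``. Control cells
    carry ``baseline_label``. Deterministic given ``seed``.
    """
    import anndata as ad

    rng = np.random.default_rng(seed)
    genes = [f"G{j + 1:04d}" for j in range(n_genes)]
    gene_idx = {g: j for j, g in enumerate(genes)}
    base_mean = np.exp(rng.normal(mean_log_mu, mean_log_sd, n_genes))

    labels, blocks = [], []
    groups = [(baseline_label, {})] + [
        (ko, eff) for ko, eff in knockout_effects.items()
    ]
    for ko, eff in groups:
        n = baseline_cells if ko == baseline_label else cells_per_knockout
        mean = np.tile(base_mean, (n, 1))
        for g, shift in eff.items():
            mean[:, gene_idx[g]] *= 2.0**shift
        if preserve_total and eff:
            mean *= base_mean.sum() / mean[0].sum()
        if noise > 0:
            shape = 1.0 / noise
            lam = mean * rng.gamma(shape, 1.0 / shape, size=mean.shape)
        else:
            lam = mean
        blocks.append(rng.poisson(lam).astype(np.int32))
        labels.extend([ko] * n)

    X = np.vstack(blocks)
    obs = pd.DataFrame(
        {"knockout": labels}, index=[f"cell{i:06d}" for i in range(len(labels))]
    )
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))


# ---------------------------------------------------------------------------
# exon coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageSimTruth:
    """Planted 5' coverage bias per (knockout sample, gene).

    Genes are single-transcript models with ``n_exons`` exons of
    ``exon_len`` bp. Non-targeting control samples have uniform expected
    per-exon coverage; a planted bias multiplies the expected coverage of
    the 5'-most (First) exon by 2**bias. ``reads_per_gene`` sets the
    expected total reads per gene per sample (Poisson).
    """

    n_genes: int = 50
    n_exons: int = 5
    exon_len: int = 200
    intron_len: int = 500
    samples: tuple[str, ...] = ("NTC_1", "NTC_2", "KO_A", "KO_B")
    ntc_samples: tuple[str, ...] = ("NTC_1", "NTC_2")
    bias_true: dict[tuple[str, str], float] = field(default_factory=dict)
    reads_per_gene: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exons < 2 and self.bias_true:
            raise ValueError("cannot plant a 5' bias on single-exon genes")
        for s in self.ntc_samples:
            if s not in self.samples:
                raise ValueError(f"NTC sample {s} not among samples")


def default_coverage_truth(seed: int = 0, **overrides) -> CoverageSimTruth:
    return CoverageSimTruth(seed=seed, **overrides)


def simulate_exon_coverage(
    truth: CoverageSimTruth,
) -> tuple[pd.DataFrame, str]:
    """Per-exon read counts plus the matching GTF text.

    Returns ``(counts, gtf)`` where ``counts`` has columns sample, gene_id,
    exon_id, count, and ``gtf`` is a GTF document with one transcript per
    gene (alternating strand). Deterministic given ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    genes = [f"SIMG{i + 1:03d}" for i in range(truth.n_genes)]
    strands = ["+" if i % 2 == 0 else "-" for i in range(truth.n_genes)]

    gtf_lines = []
    exon_ids: dict[str, list[str]] = {}
    pos = 1000
    for gid, strand in zip(genes, strands):
        starts = [
            pos + e * (truth.exon_len + truth.intron_len)
            for e in range(truth.n_exons)
        ]
        gene_start, gene_end = starts[0], starts[-1] + truth.exon_len - 1
        attrs = f'gene_id "{gid}"; transcript_id "{gid}.T1";'
        gtf_lines.append(
            f'chrS\tsim\tgene\t{gene_start}\t{gene_end}\t.\t{strand}\t.\tgene_id "{gid}";'
        )
        gtf_lines.append(
            f"chrS\tsim\ttranscript\t{gene_start}\t{gene_end}\t.\t{strand}\t.\t{attrs}"
        )
        ids = []
        for e, s in enumerate(starts):
            eid = f"{gid}.E{e + 1}"
            gtf_lines.append(
                f"chrS\tsim\texon\t{s}\t{s + truth.exon_len - 1}\t.\t{strand}\t.\t"
                f'{attrs} exon_id "{eid}";'
            )
            ids.append(eid)
        # exon order in genomic coordinates; 5'-most depends on strand
        exon_ids[gid] = ids
        pos = gene_end + 10_000

    rows = []
    per_exon = truth.reads_per_gene / truth.n_exons
    for sample in truth.samples:
        for gid, strand in zip(genes, strands):
            lam = np.full(truth.n_exons, per_exon, dtype=float)
            bias = truth.bias_true.get((sample, gid), 0.0)
            if bias:
                first_idx = 0 if strand == "+" else truth.n_exons - 1
                lam[first_idx] *= 2.0**bias
            counts = rng.poisson(lam)
            for eid, c in zip(exon_ids[gid], counts):
                rows.append(
                    {"sample": sample, "gene_id": gid, "exon_id": eid, "count": int(c)}
                )
    counts_df = pd.DataFrame(rows)
    return counts_df, "\n".join(gtf_lines) + "\n"
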