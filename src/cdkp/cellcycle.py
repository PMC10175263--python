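"""Circular cell-cycle embedding and phase statistics for single cells.

Cycling cells traverse a closed loop in expression space, so their
cell-cycle state is naturally a point on a circle. Given five marker-gene
sets J_k for the coarse phases K = {M, M/G1, G1/S, S, G2/M}, each cell i
gets

* per-phase scores  E_ik = mean expression over J_k,
* a pan-phase profile E_i (expression over the union of all marker genes),
* a coarse label     C_i = argmax_k E_ik.

Pairwise cosine distances of the pan-phase profiles, D = 1 - cos, are
embedded in 2D by metric MDS and converted to polar coordinates (r, theta).
Angular bins are labeled by the modal coarse label of their cells, which
assigns each arc of the circle a phase. Knockout-induced redistribution of
cells around the circle is tested with the two-sample Kuiper statistic (a
rotation-invariant Kolmogorov-Smirnov analogue), and the cell-cycle signal
can be regressed out of the full matrix using theta-smoothed phase scores.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PHASES",
    "DEFAULT_PHASE_BOUNDARIES",
    "PhaseGeneSets",
    "phase_scores",
    "coarse_classify",
    "embed_cells",
    "assign_phase_ranges",
    "kuiper_statistic",
    "kuiper_test",
    "remove_cellcycle_signal",
    "expand_markers",
    "circular_correlation",
    "normalize_counts",
]

#: Canonical phase order around the circle (counter-clockwise).
PHASES = ["M", "M/G1", "G1/S", "S", "G2/M"]

#: Canonical angular arcs (radians) for each phase, in PHASES order: five
#: equal arcs. The layout is a convention that fixes the orientation of the
#: embedding; equal widths keep phase-score crossings symmetric about the
#: arc boundaries.
DEFAULT_PHASE_BOUNDARIES = np.linspace(0.0, 2 * np.pi, len(PHASES) + 1)

#: Reference angle at which the circular mean of M/G1-labeled cells is placed
#: when canonicalizing an embedding (center of the canonical M/G1 arc).
MG1_REFERENCE_ANGLE = float(
    (DEFAULT_PHASE_BOUNDARIES[1] + DEFAULT_PHASE_BOUNDARIES[2]) / 2
)


class PhaseGeneSets:
    """Marker gene sets J_k per cell-cycle phase; a gene belongs to one set."""

    def __init__(self, sets: dict[str, list[str]]):
        missing = [k for k in PHASES if not sets.get(k)]
        if missing:
            raise ValueError(f"empty marker set for phases {missing}")
        seen: dict[str, str] = {}
        for k, genes in sets.items():
            for g in genes:
                if g in seen:
                    raise ValueError(f"gene {g} in both {seen[g]} and {k}")
                seen[g] = k
        self.sets = {k: list(sets[k]) for k in PHASES}

    def __getitem__(self, phase: str) -> list[str]:
        return self.sets[phase]

    @property
    def all_genes(self) -> list[str]:
        return [g for k in PHASES for g in self.sets[k]]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tphase\n")
            for k in PHASES:
                for g in self.sets[k]:
                    fh.write(f"{g}\t{k}\n")

    @classmethod
    def from_tsv(cls, path) -> "PhaseGeneSets":
        df = pd.read_csv(path, sep="\t")
        return cls({k: list(sub["gene"]) for k, sub in df.groupby("phase")})


def normalize_counts(counts: pd.DataFrame, target_sum: float = 1e4) -> pd.DataFrame:
    """Total-count normalize each cell to ``target_sum`` then log1p."""
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("cell with zero total counts")
    return np.log1p(counts.div(totals, axis=0) * target_sum)


def phase_scores(
    expr: pd.DataFrame, sets: PhaseGeneSets
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell phase means E_ik and the pan-phase profile E_i.

    ``expr`` is a normalized cells x genes matrix. Marker genes absent from
    the matrix are dropped with a warning; a phase losing all its genes is an
    error.
    """
    e_ik = {}
    present_union: list[str] = []
    for k in PHASES:
        genes = [g for g in sets[k] if g in expr.columns]
        dropped = len(sets[k]) - len(genes)
        if dropped:
            warnings.warn(f"{dropped} marker gene(s) of phase {k} not in matrix")
        if not genes:
            raise ValueError(f"no marker genes of phase {k} present in matrix")
        e_ik[k] = expr[genes].mean(axis=1)
        present_union.extend(genes)
    E_ik = pd.DataFrame(e_ik, index=expr.index)[PHASES]
    E_i = expr[present_union]
    return E_ik, E_i


def coarse_classify(E_ik: pd.DataFrame) -> pd.Series:
    """Coarse phase label C_i = argmax_k E_ik; ties go to the first phase in
    canonical order."""
    arr = E_ik[PHASES].to_numpy()
    idx = np.argmax(arr, axis=1)  # first maximum on ties
    return pd.Series([PHASES[i] for i in idx], index=E_ik.index, name="C_i")


def cosine_distance_matrix(profiles: pd.DataFrame) -> np.ndarray:
    """D_mn = 1 - cosine similarity of rows (pan-phase profiles)."""
    X = profiles.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        raise ValueError("all-zero pan-phase profile; drop those cells first")
    Xn = X / norms[:, None]
    D = 1.0 - Xn @ Xn.T
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


def _circmean(theta: np.ndarray) -> float:
    return math.atan2(np.sin(theta).sum(), np.cos(theta).sum()) % (2 * np.pi)


def embed_cells(
    E_i: pd.DataFrame,
    coarse: pd.Series | None = None,
    seed: int = 0,
    n_init: int = 4,
    max_iter: int = 150,
    canonicalize: bool = True,
) -> pd.DataFrame:
    """Metric-MDS embedding of pan-phase profiles and polar conversion.

    Cosine distances D = 1 - cos are embedded in 2D by metric MDS (SMACOF
    stress majorization, seeded), then converted to polar coordinates
    r = sqrt(D1^2 + D2^2), theta = atan2(D2, D1) in [0, 2pi). Because an MDS
    solution is arbitrary up to rotation/reflection, the embedding is
    canonicalized when coarse labels are given: rotated so the circular mean
    of M/G1 cells sits at the canonical M/G1 arc center, and reflected so the
    phase order runs counter-clockwise.

    Returns a frame with columns D1, D2, r, theta (and C_i if given).
    """
    from sklearn.manifold import MDS

    if len(E_i) < 10:
        raise ValueError("need at least 10 cells to embed")
    D = cosine_distance_matrix(E_i)
    if not D.any():
        raise ValueError("degenerate distance matrix (all zeros)")
    mds = MDS(
        n_components=2,
        metric="precomputed",
        init="random",
        random_state=seed,
        n_init=n_init,
        max_iter=max_iter,
        normalized_stress=False,
    )
    XY = mds.fit_transform(D)
    XY = XY - XY.mean(axis=0)
    out = pd.DataFrame(XY, columns=["D1", "D2"], index=E_i.index)
    theta = np.arctan2(out["D2"], out["D1"]).to_numpy() % (2 * np.pi)
    r = np.hypot(out["D1"], out["D2"]).to_numpy()
    if coarse is not None:
        out["C_i"] = coarse.reindex(out.index)
        theta = _canonicalize_theta(theta, out["C_i"].to_numpy())
        out["D1"] = r * np.cos(theta)
        out["D2"] = r * np.sin(theta)
    out["r"] = r
    out["theta"] = theta
    return out


def _canonicalize_theta(theta: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Rotate/reflect angles into the canonical phase layout.

    The circular mean of M/G1-labeled cells is moved to the canonical M/G1
    arc center; the result is reflected about that axis if the mean angular
    step along the phase sequence runs clockwise.
    """
    theta = np.asarray(theta, dtype=float) % (2 * np.pi)
    anchor = "M/G1" if (labels == "M/G1").any() else PHASES[0]
    ref = (
        MG1_REFERENCE_ANGLE
        if anchor == "M/G1"
        else _arc_center(PHASES.index(anchor))
    )
    mean_anchor = _circmean(theta[labels == anchor])
    theta = (theta + (ref - mean_anchor)) % (2 * np.pi)

    # Orientation: signed steps between consecutive phase means should be
    # positive (counter-clockwise) on average.
    means = []
    for k in PHASES:
        sel = labels == k
        if sel.sum() >= 3:
            means.append(_circmean(theta[sel]))
    step_sum = 0.0
    for a, b in zip(means, means[1:] + means[:1]):
        d = (b - a) % (2 * np.pi)
        step_sum += d if d <= np.pi else d - 2 * np.pi
    if step_sum < 0:
        theta = (2 * ref - theta) % (2 * np.pi)
    return theta


def _arc_center(i: int) -> float:
    return float((DEFAULT_PHASE_BOUNDARIES[i] + DEFAULT_PHASE_BOUNDARIES[i + 1]) / 2)


@dataclass
class PhaseRangeMap:
    """Angular bins, their modal phase labels, and merged per-phase arcs."""

    bin_edges: np.ndarray
    bin_labels: list[str]
    merged_ranges: dict[str, list[tuple[float, float]]]

    def label_of(self, theta: float) -> str:
        i = int(np.searchsorted(self.bin_edges, theta % (2 * np.pi), side="right")) - 1
        return self.bin_labels[min(max(i, 0), len(self.bin_labels) - 1)]


def assign_phase_ranges(
    theta: pd.Series, coarse: pd.Series, n_bins: int = 60
) -> tuple[PhaseRangeMap, pd.Series]:
    """Label angular bins by the modal coarse phase of their cells.

    Each of ``n_bins`` equal arcs gets the most frequent C_i among its cells
    (ties broken by canonical phase order); empty bins inherit the label of
    the nearest non-empty bin (circularly). Each cell's assigned phase is its
    bin's label. Also returns per-phase merged contiguous arcs.
    """
    if n_bins < len(PHASES):
        raise ValueError(f"n_bins must be >= {len(PHASES)}")
    edges = np.linspace(0, 2 * np.pi, n_bins + 1)
    th = theta.to_numpy() % (2 * np.pi)
    bins = np.clip(np.searchsorted(edges, th, side="right") - 1, 0, n_bins - 1)

    labels: list[str | None] = []
    order = {k: i for i, k in enumerate(PHASES)}
    cvals = coarse.to_numpy()
    for b in range(n_bins):
        members = cvals[bins == b]
        if len(members) == 0:
            labels.append(None)
            continue
        counts: dict[str, int] = {}
        for c in members:
            counts[c] = counts.get(c, 0) + 1
        best = max(counts.items(), key=lambda kv: (kv[1], -order[kv[0]]))
        labels.append(best[0])

    # Fill empty bins from the circularly nearest labeled bin.
    filled = list(labels)
    if all(l is None for l in filled):
        raise ValueError("no cells to label bins with")
    for b in range(n_bins):
        if filled[b] is None:
            for d in range(1, n_bins):
                for cand in ((b - d) % n_bins, (b + d) % n_bins):
                    if labels[cand] is not None:
                        filled[b] = labels[cand]
                        break
                if filled[b] is not None:
                    break
    final_labels: list[str] = [l for l in filled]  # type: ignore[misc]

    merged: dict[str, list[tuple[float, float]]] = {k: [] for k in PHASES}
    start = 0
    for b in range(1, n_bins + 1):
        if b == n_bins or final_labels[b] != final_labels[start]:
            merged[final_labels[start]].append((edges[start], edges[b]))
            start = b
    # join the wrap-around run
    if (
        len(final_labels) > 1
        and final_labels[0] == final_labels[-1]
        and len(merged[final_labels[0]]) > 1
    ):
        first = merged[final_labels[0]][0]
        last = merged[final_labels[0]][-1]
        if first[0] == 0.0 and last[1] == edges[-1]:
            merged[final_labels[0]] = merged[final_labels[0]][1:-1] + [
                (last[0], first[1] + 2 * np.pi)
            ]

    assigned = pd.Series(
        [final_labels[b] for b in bins], index=theta.index, name="phase_assigned"
    )
    return PhaseRangeMap(edges, final_labels, merged), assigned


def kuiper_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Kuiper statistic V = max(F_a - F_b) + max(F_b - F_a).

    Evaluated over the pooled sample points; invariant to a common rotation
    of both samples (the defining property that makes it suitable for
    circular data, unlike the Kolmogorov-Smirnov statistic).
    """
    a = np.sort(np.asarray(a, dtype=float) % (2 * np.pi))
    b = np.sort(np.asarray(b, dtype=float) % (2 * np.pi))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    pooled.sort()
    fa = np.searchsorted(a, pooled, side="right") / len(a)
    fb = np.searchsorted(b, pooled, side="right") / len(b)
    diff = fa - fb
    return float(diff.max() - diff.min())


def _kuiper_fpp(v_star: float, terms: int = 100) -> float:
    """Asymptotic upper-tail probability of the Kuiper statistic."""
    if v_star < 0.4:
        return 1.0
    p = 0.0
    for j in range(1, terms + 1):
        x = j * j * v_star * v_star
        p += (4.0 * x - 1.0) * math.exp(-2.0 * x)
    return float(min(max(2.0 * p, 0.0), 1.0))


def kuiper_test(
    theta_ko: np.ndarray,
    theta_ctrl: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    min_asymptotic_n: int = 20,
) -> tuple[float, float]:
    """Two-sample Kuiper test of angular distributions.

    Returns (V, p). The p-value uses the asymptotic series with Stephens'
    small-sample correction of the effective sample size; below
    ``min_asymptotic_n`` per group it falls back to a seeded permutation
    null.
    """
    a = np.asarray(theta_ko, dtype=float)
    b = np.asarray(theta_ctrl, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("need at least 5 cells per group")
    v = kuiper_statistic(a, b)
    if min(len(a), len(b)) >= min_asymptotic_n:
        ne = len(a) * len(b) / (len(a) + len(b))
        v_star = v * (math.sqrt(ne) + 0.155 + 0.24 / math.sqrt(ne))
        return v, _kuiper_fpp(v_star)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if kuiper_statistic(perm[: len(a)], perm[len(a) :]) >= v:
            hits += 1
    return v, (hits + 1) / (n_perm + 1)


def _periodic_loess(
    theta: np.ndarray, y: np.ndarray, span: float = 0.3
) -> np.ndarray:
    """Periodic local linear regression of y on theta.

    Each point is fit from the fraction ``span`` of nearest neighbors in
    circular distance with tricube weights; the circle is handled by taking
    angular differences modulo 2 pi mapped to [-pi, pi].
    """
    th = np.asarray(theta, dtype=float) % (2 * np.pi)
    n = len(th)
    k = max(int(math.ceil(span * n)), 5)
    if n < k:
        raise ValueError("fewer cells than smoother bandwidth")
    order = np.argsort(th)
    th_s, y_s = th[order], np.asarray(y, dtype=float)[order]
    fitted = np.empty(n)
    # circular signed distance matrix built lazily per point via windowing on
    # the sorted angles (window of k nearest circular neighbors)
    ext_th = np.concatenate([th_s - 2 * np.pi, th_s, th_s + 2 * np.pi])
    ext_y = np.concatenate([y_s, y_s, y_s])
    for i in range(n):
        c = n + i
        lo, hi = c - k, c + k + 1
        d = ext_th[lo:hi] - th_s[i]
        idx = np.argsort(np.abs(d))[:k]
        dd = d[idx]
        yy = ext_y[lo:hi][idx]
        h = np.abs(dd).max()
        if h == 0:
            fitted[i] = yy.mean()
            continue
        w = (1 - (np.abs(dd) / h) ** 3) ** 3
        W = np.sum(w)
        xw = np.sum(w * dd)
        xxw = np.sum(w * dd * dd)
        yw = np.sum(w * yy)
        xyw = np.sum(w * dd * yy)
        denom = W * xxw - xw * xw
        if abs(denom) < 1e-12:
            fitted[i] = yw / W
        else:
            b1 = (W * xyw - xw * yw) / denom
            b0 = (yw - b1 * xw) / W
            fitted[i] = b0  # local fit evaluated at dd = 0
    out = np.empty(n)
    out[order] = fitted
    return out


def remove_cellcycle_signal(
    expr: pd.DataFrame,
    E_ik: pd.DataFrame,
    theta: pd.Series,
    span: float = 0.3,
) -> pd.DataFrame:
    """Regress the cell-cycle signal out of an expression matrix.

    The five phase scores are smoothed over theta with a periodic local
    linear smoother; every gene is then residualized on the smoothed scores
    (plus intercept) by ordinary least squares. Returns the residual matrix
    (zero-centered per gene).
    """
    th = theta.reindex(expr.index).to_numpy()
    if np.isnan(th).any():
        raise ValueError("theta missing for some cells")
    smooth = np.column_stack(
        [_periodic_loess(th, E_ik[k].reindex(expr.index).to_numpy(), span) for k in PHASES]
    )
    X = np.column_stack([np.ones(len(expr)), smooth])
    Y = expr.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return pd.DataFrame(resid, index=expr.index, columns=expr.columns)


def expand_markers(
    expr: pd.DataFrame,
    sets: PhaseGeneSets,
    var_sd_cut: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Propose new phase markers from co-expression with known markers.

    For each gene outside the marker sets, its score for phase k is the mean
    Pearson correlation with the known markers of k. A gene is assigned to
    its top-scoring phase when (a) that top score is positive (co-expressed,
    not merely least anti-correlated), (b) a t-test of its per-marker
    correlations for that phase against those of every other phase is
    significant at ``alpha``, and (c) the variance of its five phase scores
    exceeds the across-gene mean by ``var_sd_cut`` standard deviations. Constant genes
    are excluded (correlation undefined).

    Returns a frame indexed by candidate gene with the five phase scores,
    ``phase`` (assigned phase or None), and ``score_variance``.
    """
    if len(expr) < 50:
        raise ValueError("need at least 50 cells for co-expression scoring")
    known = [g for g in sets.all_genes if g in expr.columns]
    unknown = [g for g in expr.columns if g not in set(sets.all_genes)]
    X = expr[unknown].to_numpy(dtype=float)
    M = expr[known].to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    unknown = [g for g, k in zip(unknown, keep) if k]
    X = X[:, keep]
    Xz = (X - X.mean(0)) / X.std(0)
    Mz = (M - M.mean(0)) / np.where(M.std(0) == 0, 1, M.std(0))
    C = (Xz.T @ Mz) / len(expr)  # genes x markers correlation

    marker_phase = np.array(
        [next(k for k in PHASES if g in set(sets[k])) for g in known]
    )
    rows = []
    for gi, gene in enumerate(unknown):
        per_phase = {k: C[gi, marker_phase == k] for k in PHASES}
        scores = {k: float(v.mean()) for k, v in per_phase.items()}
        top = max(PHASES, key=lambda k: scores[k])
        significant = scores[top] > 0
        for k in PHASES:
            if not significant:
                break
            if k == top:
                continue
            t, p = stats.ttest_ind(
                per_phase[top], per_phase[k], equal_var=False
            )
            if not (t > 0 and p / 2 < alpha):  # one-sided: top exceeds k
                significant = False
        rows.append(
            {
                "gene": gene,
                **scores,
                "top_phase": top,
                "significant": significant,
                "score_variance": float(np.var(list(scores.values()))),
            }
        )
    out = pd.DataFrame(rows).set_index("gene")
    if out.empty:
        out["phase"] = []
        return out
    var_thresh = out["score_variance"].mean() + var_sd_cut * out["score_variance"].std()
    out["phase"] = np.where(
        out["significant"] & (out["score_variance"] > var_thresh),
        out["top_phase"],
        None,
    )
    return out


def circular_correlation(alpha: np.ndarray, beta: np.ndarray) -> float:
    """Fisher-Lee circular correlation between two paired angle sets.

    r = sum_{i<j} sin(a_i - a_j) sin(b_i - b_j) / sqrt(sum sin^2 * sum sin^2).
    Invariant to separate rotations of either variable and well defined even
    for uniform marginals (unlike mean-direction-based estimators); +1 for
    identical orderings around the circle, -1 for reflected ones.
    """
    a = np.asarray(alpha, dtype=float)
    b = np.asarray(beta, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    sa = np.sin(a[:, None] - a[None, :])
    sb = np.sin(b[:, None] - b[None, :])
    denom = math.sqrt(float((sa**2).sum()) * float((sb**2).sum()))
    if denom == 0:
        return 0.0
    return float((sa * sb).sum() / denom)
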