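"""Guide-pair counting and construct fitness from paired cassette reads.

Reads are assigned to guides by windowed Levenshtein matching against the
expected-position contig (read 1 can only hit position-1 contigs, read 2 only
position-2 contigs). A mate pair is counted iff both reads match within edit
distance 2, unambiguously, and the resulting ordered guide pair exists in the
library design. Counts are then turned into log2 relative abundances x,
fold changes m versus the baseline timepoint, and z-standardized construct
fitnesses f:

    x_{g1g2}   = log2( (M_{g1g2}+c) / sum(M+c) )
    m_{g1g2,t} = x_{g1g2,t} - x_{g1g2,t0}
    f_{g1g2,t} = (m_{g1g2,t} - mu_t) / sigma_t

with mu_t, sigma_t taken over all constructs in one (timepoint, replicate)
sample (population standard deviation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import edlib
import numpy as np
import pandas as pd

from .library import (
    GuideLibrary,
    PositionReference,
    READ1_PREFIX,
    READ2_PREFIX,
    SPACER_LEN,
    enumerate_pairs,
)

__all__ = [
    "ReadPairAssignment",
    "AssignmentReport",
    "match_read",
    "count_pairs",
    "compute_abundance",
    "compute_fitness",
    "read_count_table",
    "write_count_table",
]

MAX_EDIT_DIST = 2

COUNT_COLUMNS = ["g1", "g2", "timepoint", "replicate", "count"]


@dataclass
class ReadPairAssignment:
    read_id: str
    g1: str | None
    g2: str | None
    dist1: int | None
    dist2: int | None
    valid: bool
    reason: str = "ok"


@dataclass
class AssignmentReport:
    """Tally of read-pair fates; assigned + rejected == input pairs."""

    n_pairs: int = 0
    n_assigned: int = 0
    rejected: dict[str, int] = field(default_factory=dict)

    def reject(self, reason: str) -> None:
        self.rejected[reason] = self.rejected.get(reason, 0) + 1

    @property
    def n_rejected(self) -> int:
        return sum(self.rejected.values())

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_assigned": self.n_assigned,
            "rejected": dict(self.rejected),
        }


def match_read(
    read_seq: str,
    position: int,
    reference: PositionReference,
    max_dist: int = MAX_EDIT_DIST,
) -> tuple[str | None, int | None, str]:
    """Assign one read to the guide expected at its cassette position.

    The spacer window — the bases following the constant 5' anchor, with
    ``max_dist`` slack for indels — is compared by Levenshtein distance to the
    spacer of every contig at this position; distance counts the best
    alignment of the full spacer against a prefix of the window, so indels
    shift subsequent bases without cascading mismatches.

    Returns ``(guide_id, distance, reason)``; ``guide_id`` is ``None`` when
    the minimum distance exceeds ``max_dist`` (reason ``"distance"``), when
    two guides tie at the minimum (``"ambiguous"``), or when the read does
    not cover the spacer window (``"too_short"``).
    """
    if position not in (1, 2):
        raise ValueError("position must be 1 or 2")
    offset = reference.spacer_offset(position)
    spacers = _position_spacers(reference, position)
    return _match_window(read_seq, offset, spacers, max_dist)


def _position_spacers(
    reference: PositionReference, position: int
) -> list[tuple[str, str]]:
    offset = reference.spacer_offset(position)
    return [
        (gid, contig[offset : offset + SPACER_LEN])
        for (pos, gid), contig in reference.contigs.items()
        if pos == position
    ]


def _match_window(
    read_seq: str,
    offset: int,
    spacers: list[tuple[str, str]],
    max_dist: int,
    exact: dict[str, str] | None = None,
) -> tuple[str | None, int | None, str]:
    if len(read_seq) < offset + SPACER_LEN:
        return None, None, "too_short"
    window = read_seq[offset : offset + SPACER_LEN + max_dist]
    if exact is not None:
        gid = exact.get(window[:SPACER_LEN])
        if gid is not None:
            # Spacers are unique, so an exact hit cannot be tied at distance 0.
            return gid, 0, "ok"

    best_gid: str | None = None
    best_dist = SPACER_LEN + 1
    tie = False
    for gid, spacer in spacers:
        # SHW: spacer aligned end-free against the window, i.e. distance to
        # the best-matching window prefix, so indels do not cascade.
        d = edlib.align(spacer, window, mode="SHW", task="distance")["editDistance"]
        if d < best_dist:
            best_dist, best_gid, tie = d, gid, False
        elif d == best_dist:
            tie = True
    if best_dist > max_dist:
        return None, best_dist, "distance"
    if tie:
        return None, best_dist, "ambiguous"
    return best_gid, best_dist, "ok"


def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()
            fh.readline()
            yield header[1:].split()[0].rstrip("\n"), seq


def count_pairs(
    r1: str | Path | Iterable[tuple[str, str]],
    r2: str | Path | Iterable[tuple[str, str]],
    library: GuideLibrary,
    reference: PositionReference,
    timepoint: int | float = 0,
    replicate: int = 1,
    max_dist: int = MAX_EDIT_DIST,
) -> tuple[pd.DataFrame, AssignmentReport]:
    """Count valid guide pairs from mated read streams.

    ``r1``/``r2`` are FASTQ paths (optionally gzipped) or iterables of
    ``(read_id, sequence)``. Returns a count table over all designed pairs
    (zeros included) for one (timepoint, replicate) sample, plus a report of
    rejection reasons. Orphan mates are rejected, never fatal.
    """
    if isinstance(r1, (str, Path)):
        r1 = _iter_fastq(r1)
    if isinstance(r2, (str, Path)):
        r2 = _iter_fastq(r2)

    pair_set = set(enumerate_pairs(library))
    counts: dict[tuple[str, str], int] = {p: 0 for p in pair_set}
    report = AssignmentReport()

    spacers = {p: _position_spacers(reference, p) for p in (1, 2)}
    offsets = {p: reference.spacer_offset(p) for p in (1, 2)}
    exact = {p: {sp: gid for gid, sp in spacers[p]} for p in (1, 2)}
    cache: dict[tuple[int, str], tuple[str | None, int | None, str]] = {}

    def matched(position: int, seq: str):
        key = (position, seq)
        hit = cache.get(key)
        if hit is None:
            hit = _match_window(
                seq, offsets[position], spacers[position], max_dist, exact[position]
            )
            if len(cache) < 2_000_000:
                cache[key] = hit
        return hit

    it1, it2 = iter(r1), iter(r2)
    while True:
        rec1 = next(it1, None)
        rec2 = next(it2, None)
        if rec1 is None and rec2 is None:
            break
        report.n_pairs += 1
        if rec1 is None or rec2 is None:
            report.reject("orphan_mate")
            continue
        g1, d1, why1 = matched(1, rec1[1])
        g2, d2, why2 = matched(2, rec2[1])
        if g1 is None or g2 is None:
            report.reject(why1 if g1 is None else why2)
            continue
        if (g1, g2) not in pair_set:
            report.reject("unexpected_pair")
            continue
        counts[(g1, g2)] += 1
        report.n_assigned += 1

    rows = [
        {"g1": a, "g2": b, "timepoint": timepoint, "replicate": replicate, "count": n}
        for (a, b), n in counts.items()
    ]
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS).sort_values(["g1", "g2"])
    return df.reset_index(drop=True), report


def _check_count_table(counts: pd.DataFrame) -> None:
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"count table missing columns {missing}")
    if (counts["count"] < 0).any():
        raise ValueError("negative counts")


def compute_abundance(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Log2 relative abundance x per construct within each sample.

    x = log2((M + c) / sum(M + c)) over all constructs of one
    (timepoint, replicate) sample, so sum(2^x) == 1 per sample.
    """
    _check_count_table(counts)
    df = counts.copy()
    adj = df["count"].astype(float) + pseudocount
    if (adj <= 0).any():
        raise ValueError("counts plus pseudocount must be positive")
    totals = adj.groupby([df["timepoint"], df["replicate"]]).transform("sum")
    if (totals <= 0).any():
        raise ValueError("sample with zero total count")
    df["x"] = np.log2(adj / totals)
    return df


def compute_fitness(
    abundance: pd.DataFrame,
    t0: int | float | None = None,
    pool_replicates: bool = False,
) -> pd.DataFrame:
    """Fold change m versus the baseline and z-standardized fitness f.

    ``t0`` defaults to the smallest timepoint. Standardization uses the
    population of all constructs within one (timepoint, replicate) sample;
    with ``pool_replicates`` the replicates of a timepoint are standardized
    together. Baseline rows are dropped from the output.
    """
    if "x" not in abundance.columns:
        raise ValueError("run compute_abundance first (missing column 'x')")
    df = abundance.copy()
    if t0 is None:
        t0 = df["timepoint"].min()
    base = df[df["timepoint"] == t0]
    if base.empty:
        raise ValueError(f"baseline timepoint {t0} not present")
    base_x = base.set_index(["g1", "g2", "replicate"])["x"]
    rest = df[df["timepoint"] != t0].copy()
    key = pd.MultiIndex.from_frame(rest[["g1", "g2", "replicate"]])
    rest["m"] = rest["x"].to_numpy() - base_x.reindex(key).to_numpy()
    if rest["m"].isna().any():
        raise ValueError("constructs missing from the baseline sample")

    group_cols = ["timepoint"] if pool_replicates else ["timepoint", "replicate"]
    grouped = rest.groupby(group_cols)["m"]
    mu = grouped.transform("mean")
    sigma = grouped.transform(lambda s: s.to_numpy().std(ddof=0))
    if (sigma == 0).any():
        raise ValueError("degenerate sample: zero variance of fold changes")
    rest["f"] = (rest["m"] - mu) / sigma
    return rest.reset_index(drop=True)


def write_count_table(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_count_table(df)
    return df
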