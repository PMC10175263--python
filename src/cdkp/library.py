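"""Dual-guide library combinatorics.

A combinatorial knockout library pairs every guide with every other guide in
both cassette positions. This module enumerates the ordered pairs, assembles
the synthesis oligos from the fixed cassette scaffold, generates the random
barcode segment that couples the two spacers through PCR, and builds the
two-position alignment reference used for read counting.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "Guide",
    "GuideLibrary",
    "OligoDesign",
    "PositionReference",
    "BarcodeSet",
    "enumerate_pairs",
    "generate_barcodes",
    "hamming_audit",
    "assemble_oligo",
    "parse_oligo",
    "build_oligo_pool",
    "build_reference",
]

DNA_ALPHABET = "ACGT"
SPACER_LEN = 20

# Oligo scaffold: 5' constant, spacer 1, linker, 15-nt barcode, linker, spacer 2,
# 3' constant.  Total assembled length 24+20+11+15+11+20+29 = 130 nt.
OLIGO_5PRIME = "TCTTGTGGAAAGGACGAAACACCG"
OLIGO_LINKER1 = "GTTTTGAGACG"
OLIGO_LINKER2 = "CGTCTCGTTTG"
OLIGO_3PRIME = "GTTTTAGAGCTAGAAATAGCAAGTTAAAA"
BARCODE_LEN = 15

# Sequencing cassette layouts.  Read 1 covers the position-1 spacer, read 2 the
# position-2 spacer, each flanked by constant context.
READ1_PREFIX = "TATATATCTTGTGGAAAGGACGAAACACCG"
READ1_SUFFIX = "GTTTCAGAGCTATGCTGGAAACTGCATAGCAAGTTGAAATAAGGCTAGTCC"
READ2_PREFIX = "CCTTATTTTAACTTGCTATTTCTAGCTCTAAAAC"
READ2_SUFFIX = "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGG"

#: Gene labels reserved for control guides.
CONTROL_GENES = frozenset({"AAVS1", "NTC"})


def _validate_spacer(spacer: str) -> None:
    if len(spacer) != SPACER_LEN or any(b not in DNA_ALPHABET for b in spacer):
        raise ValueError(
            f"spacer must be {SPACER_LEN} nt over ACGT, got {spacer!r}"
        )


@dataclass(frozen=True)
class Guide:
    """A single sgRNA: identifier, target gene symbol and 20-nt spacer.

    Control guides use the reserved gene labels ``AAVS1`` (cutting but
    neutral safe-harbor controls) and ``NTC`` (non-targeting controls).
    """

    guide_id: str
    gene: str
    spacer: str

    def __post_init__(self) -> None:
        _validate_spacer(self.spacer)

    @property
    def is_control(self) -> bool:
        return self.gene in CONTROL_GENES


class GuideLibrary:
    """Ordered collection of guides with unique ids and spacers."""

    def __init__(self, guides: Iterable[Guide], n_guides_per_gene: int = 4):
        self.guides: list[Guide] = list(guides)
        self.n_guides_per_gene = n_guides_per_gene
        ids = [g.guide_id for g in self.guides]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate guide_id in library")
        spacers = [g.spacer for g in self.guides]
        if len(set(spacers)) != len(spacers):
            raise ValueError("duplicate spacer in library")
        self._by_id = {g.guide_id: g for g in self.guides}

    def __len__(self) -> int:
        return len(self.guides)

    def __iter__(self) -> Iterator[Guide]:
        return iter(self.guides)

    def __getitem__(self, guide_id: str) -> Guide:
        return self._by_id[guide_id]

    def __contains__(self, guide_id: str) -> bool:
        return guide_id in self._by_id

    @property
    def guide_ids(self) -> list[str]:
        return [g.guide_id for g in self.guides]

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.guides:
            seen.setdefault(g.gene, None)
        return list(seen)

    def guide_to_gene(self) -> dict[str, str]:
        return {g.guide_id: g.gene for g in self.guides}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("guide_id\tgene\tspacer\n")
            for g in self.guides:
                fh.write(f"{g.guide_id}\t{g.gene}\t{g.spacer}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, n_guides_per_gene: int = 4) -> "GuideLibrary":
        guides = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {c: i for i, c in enumerate(header)}
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                guides.append(
                    Guide(parts[idx["guide_id"]], parts[idx["gene"]], parts[idx["spacer"]])
                )
        return cls(guides, n_guides_per_gene=n_guides_per_gene)


@dataclass(frozen=True)
class OligoDesign:
    """One synthesis oligo: an ordered guide pair plus its 15-nt barcode."""

    g1: str
    g2: str
    barcode15: str
    oligo: str


@dataclass
class PositionReference:
    """Expected read sequences per (cassette position, guide).

    Contig names follow ``pos{1|2}|{guide_id}``. Position-1 contigs embed the
    read-1 constant context, position-2 contigs the read-2 context, so each
    read can only match contigs expected at its own position.
    """

    contigs: dict[tuple[int, str], str]

    def __len__(self) -> int:
        return len(self.contigs)

    def spacer_offset(self, position: int) -> int:
        return len(READ1_PREFIX) if position == 1 else len(READ2_PREFIX)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for (pos, gid), seq in self.contigs.items():
                fh.write(f">pos{pos}|{gid}\n{seq}\n")


def enumerate_pairs(library: GuideLibrary) -> list[tuple[str, str]]:
    """All ordered guide pairs (g1, g2), g1 != g2, in lexicographic index order.

    Both orders are distinct constructs, so a library of n guides yields
    n*(n-1) pairs (e.g. 112 guides -> 12,432 constructs).
    """
    if len(library) == 0:
        raise ValueError("cannot enumerate pairs of an empty library")
    ids = library.guide_ids
    return [(a, b) for a in ids for b in ids if a != b]


@dataclass
class BarcodeSet:
    """Result of barcode generation: the code words plus a shortfall flag."""

    barcodes: list[str]
    requested: int
    shortfall: bool
    reason: str = ""

    def __iter__(self) -> Iterator[str]:
        return iter(self.barcodes)

    def __len__(self) -> int:
        return len(self.barcodes)


def hamming_audit(barcodes: Iterable[str]) -> int:
    """Exhaustive pairwise minimum Hamming distance of a barcode set.

    Returns the minimum over all pairs; for fewer than two barcodes returns
    the barcode length + 1 (vacuously any constraint holds).
    """
    bcs = list(barcodes)
    if len(bcs) < 2:
        return (len(bcs[0]) if bcs else 0) + 1
    best = len(bcs[0]) + 1
    for i in range(len(bcs)):
        for j in range(i + 1, len(bcs)):
            d = sum(a != b for a, b in zip(bcs[i], bcs[j]))
            if d < best:
                best = d
    return best


def generate_barcodes(
    length_nt: int, min_hamming: int, count: int, seed: int
) -> BarcodeSet:
    """DNA barcodes with a guaranteed pairwise Hamming distance.

    Greedy rejection: candidates are scanned and accepted iff they sit at
    Hamming distance >= ``min_hamming`` from every barcode accepted so far.
    For small spaces the scan is lexicographic over all words (a "lexicode",
    which attains the optimal code size for the small parameters used here,
    e.g. 64 words at length 5 / distance 3); the seed is then applied as a
    per-position alphabet permutation — a Hamming isometry — so different
    seeds give different but equally large codes. Large spaces fall back to
    seeded random sampling. Deterministic given ``seed``. If ``count`` code
    words cannot be found — the Singleton bound caps any such code at
    4**(length - min_hamming + 1) — the maximal set found is returned with
    ``shortfall=True``.
    """
    if not (1 <= min_hamming <= length_nt):
        raise ValueError("require 1 <= min_hamming <= length_nt")
    if count < 1:
        raise ValueError("count must be >= 1")

    singleton_bound = 4 ** (length_nt - min_hamming + 1)
    rng = random.Random(seed)
    accepted: list[str] = []

    def compatible(cand: str) -> bool:
        for b in accepted:
            if sum(a != c for a, c in zip(b, cand)) < min_hamming:
                return False
        return True

    space = 4**length_nt
    if space <= 65536:
        maps = [
            dict(zip(DNA_ALPHABET, rng.sample(DNA_ALPHABET, 4)))
            for _ in range(length_nt)
        ]
        for w in _all_kmers(length_nt):
            if compatible("".join(w)):
                accepted.append("".join(w))
                if len(accepted) >= count:
                    break
        accepted = [
            "".join(m[b] for m, b in zip(maps, w)) for w in accepted
        ]
    else:
        misses = 0
        while len(accepted) < count and misses < 20000:
            cand = "".join(rng.choice(DNA_ALPHABET) for _ in range(length_nt))
            if compatible(cand):
                accepted.append(cand)
                misses = 0
            else:
                misses += 1

    shortfall = len(accepted) < count
    reason = ""
    if shortfall:
        if count > singleton_bound:
            reason = (
                f"count {count} exceeds the Singleton bound "
                f"4^({length_nt}-{min_hamming}+1) = {singleton_bound}"
            )
        else:
            reason = f"search exhausted after finding {len(accepted)} barcodes"
    return BarcodeSet(accepted, requested=count, shortfall=shortfall, reason=reason)


def _all_kmers(k: int):
    if k == 0:
        yield ()
        return
    for rest in _all_kmers(k - 1):
        for b in DNA_ALPHABET:
            yield (b, *rest)


def assemble_oligo(g1: Guide, g2: Guide, barcode15: str) -> OligoDesign:
    """Assemble one 130-nt synthesis oligo from the fixed cassette scaffold."""
    if g1.guide_id == g2.guide_id or g1.spacer == g2.spacer:
        raise ValueError("a construct must pair two distinct guides")
    if len(barcode15) != BARCODE_LEN or any(b not in DNA_ALPHABET for b in barcode15):
        raise ValueError(f"barcode must be {BARCODE_LEN} nt over ACGT")
    oligo = (
        OLIGO_5PRIME
        + g1.spacer
        + OLIGO_LINKER1
        + barcode15
        + OLIGO_LINKER2
        + g2.spacer
        + OLIGO_3PRIME
    )
    return OligoDesign(g1=g1.guide_id, g2=g2.guide_id, barcode15=barcode15, oligo=oligo)


def parse_oligo(oligo: str) -> tuple[str, str, str]:
    """Invert :func:`assemble_oligo`: recover (spacer1, barcode15, spacer2).

    Raises ``ValueError`` if any constant scaffold segment is not where the
    grammar places it.
    """
    i = 0
    segments = []
    for const, var_len in [
        (OLIGO_5PRIME, SPACER_LEN),
        (OLIGO_LINKER1, BARCODE_LEN),
        (OLIGO_LINKER2, SPACER_LEN),
        (OLIGO_3PRIME, 0),
    ]:
        if oligo[i : i + len(const)] != const:
            raise ValueError(f"scaffold segment mismatch at offset {i}")
        i += len(const)
        segments.append(oligo[i : i + var_len])
        i += var_len
    if i != len(oligo):
        raise ValueError("trailing sequence after scaffold")
    spacer1, barcode, spacer2, _ = segments
    return spacer1, barcode, spacer2


def build_oligo_pool(
    library: GuideLibrary, seed: int, word_length: int = 5, word_min_hamming: int = 3
) -> list[OligoDesign]:
    """One oligo per ordered guide pair, each with a unique 15-nt barcode.

    Barcodes are unique permutations of three distinct 5-nt code words drawn
    from a minimum-Hamming-distance-3 pool, which keeps any two 15-mers
    distinguishable even under a few synthesis or sequencing errors.
    """
    pairs = enumerate_pairs(library)
    words = generate_barcodes(word_length, word_min_hamming, 4**word_length, seed)
    pool = words.barcodes
    n = len(pool)
    if n * (n - 1) * (n - 2) < len(pairs):
        raise ValueError(
            f"{n} code words give only {n*(n-1)*(n-2)} three-word permutations "
            f"for {len(pairs)} constructs"
        )
    rng = random.Random(seed + 1)
    used: set[tuple[int, int, int]] = set()
    oligos = []
    for g1_id, g2_id in pairs:
        while True:
            perm = tuple(rng.sample(range(n), 3))
            if perm not in used:
                used.add(perm)
                break
        barcode = "".join(pool[i] for i in perm)
        oligos.append(assemble_oligo(library[g1_id], library[g2_id], barcode))
    return oligos


def build_reference(library: GuideLibrary) -> PositionReference:
    """Expected-sequence contigs for both cassette positions.

    Each guide yields two contigs — its spacer embedded in the read-1 context
    (position 1) and in the read-2 context (position 2) — for 2*n contigs
    total (e.g. 112 guides -> 224 contigs).
    """
    if len(library) == 0:
        raise ValueError("empty library")
    contigs: dict[tuple[int, str], str] = {}
    for g in library:
        contigs[(1, g.guide_id)] = READ1_PREFIX + g.spacer + READ1_SUFFIX
        contigs[(2, g.guide_id)] = READ2_PREFIX + g.spacer + READ2_SUFFIX
    return PositionReference(contigs=contigs)


def oligos_to_tsv(oligos: Iterable[OligoDesign], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("g1\tg2\tbarcode\toligo\n")
        for o in oligos:
            fh.write(f"{o.g1}\t{o.g2}\t{o.barcode15}\t{o.oligo}\n")
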