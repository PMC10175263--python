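"""Read matching, pair counting and the abundance/fitness transforms."""

import numpy as np
import pandas as pd
import pytest

from cdkp.counting import (
    compute_abundance,
    compute_fitness,
    count_pairs,
    match_read,
)
from cdkp.library import READ1_PREFIX, READ1_SUFFIX, build_reference
from cdkp.simulate import simulate_reads, synthetic_library, write_fastq_pair


def levenshtein_to_prefix(query: str, target: str) -> int:
    """Oracle: min edit distance of query to any prefix of target.

    Full O(mn) dynamic program; the answer is the minimum of the last row
    (the unaligned target tail is free), matching the windowed-prefix
    semantics of the matcher it audits.
    """
    m, n = len(query), len(target)
    d = np.zeros((m + 1, n + 1), dtype=int)
    d[:, 0] = np.arange(m + 1)
    d[0, :] = np.arange(n + 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            cost = 0 if query[i - 1] == target[j - 1] else 1
            d[i, j] = min(d[i - 1, j] + 1, d[i, j - 1] + 1, d[i - 1, j - 1] + cost)
    return int(d[m].min())


def brute_force_match(read, position, reference, max_dist=2):
    offset = reference.spacer_offset(position)
    window = read[offset : offset + 20 + max_dist]
    best = []
    for (pos, gid), contig in reference.contigs.items():
        if pos != position:
            continue
        spacer = contig[offset : offset + 20]
        best.append((levenshtein_to_prefix(spacer, window), gid))
    best.sort()
    d, gid = best[0]
    if d > max_dist:
        return None, d
    if len(best) > 1 and best[1][0] == d:
        return None, d
    return gid, d


class TestMatchRead:
    def test_exact(self, tiny_library, tiny_reference):
        g = tiny_library.guides[0]
        read = READ1_PREFIX + g.spacer + READ1_SUFFIX
        gid, d, why = match_read(read, 1, tiny_reference)
        assert (gid, d, why) == (g.guide_id, 0, "ok")

    @pytest.mark.parametrize("n_subs,expect_hit", [(1, True), (2, True), (3, False)])
    def test_substitution_tolerance(self, tiny_library, tiny_reference, n_subs, expect_hit):
        g = tiny_library.guides[0]
        spacer = list(g.spacer)
        for i in range(n_subs):
            spacer[3 * i] = "A" if spacer[3 * i] != "A" else "C"
        read = READ1_PREFIX + "".join(spacer) + READ1_SUFFIX
        gid, d, why = match_read(read, 1, tiny_reference)
        if expect_hit:
            assert gid == g.guide_id and d == n_subs
        else:
            assert gid is None and why == "distance"

    def test_short_read(self, tiny_reference):
        gid, d, why = match_read("ACGT", 1, tiny_reference)
        assert gid is None and why == "too_short"

    def test_agrees_with_bruteforce_oracle(self, tiny_reference):
        rng = np.random.default_rng(11)
        contigs = list(tiny_reference.contigs.items())
        bases = np.array(list("ACGT"))
        for _ in range(300):
            (pos, gid), contig = contigs[rng.integers(len(contigs))]
            read = list(contig)
            for _ in range(rng.integers(0, 5)):  # up to 4 random edits
                op = rng.integers(3)
                i = rng.integers(len(read))
                if op == 0:
                    read[i] = str(rng.choice(bases))
                elif op == 1 and len(read) > 30:
                    del read[i]
                else:
                    read.insert(i, str(rng.choice(bases)))
            seq = "".join(read)
            got_gid, got_d, _ = match_read(seq, pos, tiny_reference)
            exp_gid, exp_d = brute_force_match(seq, pos, tiny_reference)
            assert got_gid == exp_gid
            if got_gid is not None:
                assert got_d == exp_d


class TestCountPairs:
    def test_closure_with_simulator(self, tiny_library, tiny_reference):
        rng = np.random.default_rng(0)
        from cdkp.library import enumerate_pairs

        pairs = enumerate_pairs(tiny_library)
        truth_counts = pd.DataFrame(
            {
                "g1": [a for a, _ in pairs],
                "g2": [b for _, b in pairs],
                "timepoint": 0.0,
                "replicate": 1,
                "count": rng.integers(0, 20, size=len(pairs)),
            }
        )
        reads = simulate_reads(truth_counts, tiny_library, error_rate=0.0, seed=1)
        table, report = count_pairs(
            ((rid, r1) for rid, r1, _ in reads),
            ((rid, r2) for rid, _, r2 in reads),
            tiny_library,
            tiny_reference,
        )
        merged = table.merge(truth_counts, on=["g1", "g2"], suffixes=("_got", "_true"))
        assert (merged["count_got"] == merged["count_true"]).all()
        assert report.n_assigned == truth_counts["count"].sum()
        assert report.n_assigned + report.n_rejected == report.n_pairs

    def test_unexpected_pair_rejected(self, tiny_library, tiny_reference):
        g = tiny_library.guides[0]
        read1 = READ1_PREFIX + g.spacer + READ1_SUFFIX
        from cdkp.library import READ2_PREFIX, READ2_SUFFIX

        read2 = READ2_PREFIX + g.spacer + READ2_SUFFIX  # same guide both sides
        table, report = count_pairs(
            [("r1", read1)], [("r1", read2)], tiny_library, tiny_reference
        )
        assert report.rejected == {"unexpected_pair": 1}
        assert table["count"].sum() == 0

    def test_orphan_mate(self, tiny_library, tiny_reference):
        g = tiny_library.guides[0]
        read1 = READ1_PREFIX + g.spacer + READ1_SUFFIX
        table, report = count_pairs(
            [("r1", read1)], [], tiny_library, tiny_reference
        )
        assert report.rejected == {"orphan_mate": 1}

    def test_empty_input(self, tiny_library, tiny_reference):
        table, report = count_pairs([], [], tiny_library, tiny_reference)
        assert report.n_pairs == 0
        assert table["count"].sum() == 0

    def test_fastq_files(self, tiny_library, tiny_reference, tmp_path):
        counts = pd.DataFrame(
            {
                "g1": [tiny_library.guides[0].guide_id],
                "g2": [tiny_library.guides[1].guide_id],
                "timepoint": 0.0,
                "replicate": 1,
                "count": [5],
            }
        )
        reads = simulate_reads(counts, tiny_library, seed=0)
        r1, r2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
        write_fastq_pair(reads, r1, r2)
        table, report = count_pairs(r1, r2, tiny_library, tiny_reference)
        assert report.n_assigned == 5
        assert table["count"].sum() == 5


class TestAbundance:
    def test_closed_form_no_pseudocount(self):
        df = pd.DataFrame(
            {"g1": ["a", "b"], "g2": ["b", "a"], "timepoint": 0, "replicate": 1,
             "count": [3, 1]}
        )
        out = compute_abundance(df, pseudocount=0.0)
        x = out.set_index("g1")["x"]
        assert x["a"] == pytest.approx(np.log2(3 / 4))
        assert x["b"] == pytest.approx(-2.0)

    def test_single_construct(self):
        df = pd.DataFrame(
            {"g1": ["a"], "g2": ["b"], "timepoint": 0, "replicate": 1, "count": [7]}
        )
        assert compute_abundance(df, pseudocount=0.0)["x"].iloc[0] == 0.0

    def test_pseudocount(self):
        df = pd.DataFrame(
            {"g1": ["a", "b"], "g2": ["b", "a"], "timepoint": 0, "replicate": 1,
             "count": [0, 1]}
        )
        out = compute_abundance(df, pseudocount=1.0)
        assert out.set_index("g1")["x"]["a"] == pytest.approx(np.log2(1 / 3))

    def test_sums_to_one(self, screen_library):
        from cdkp.simulate import default_screen_truth, simulate_screen

        counts = simulate_screen(
            screen_library, default_screen_truth(screen_library, seed=0, depth=10000)
        )
        ab = compute_abundance(counts)
        sums = ab.groupby(["timepoint", "replicate"])["x"].agg(
            lambda s: np.exp2(s).sum()
        )
        assert np.allclose(sums, 1.0)

    def test_all_zero_sample_rejected(self):
        df = pd.DataFrame(
            {"g1": ["a"], "g2": ["b"], "timepoint": 0, "replicate": 1, "count": [0]}
        )
        with pytest.raises(ValueError):
            compute_abundance(df, pseudocount=0.0)


def _fitness_frame(x_t0, x_t1):
    n = len(x_t0)
    rows = []
    for t, xs in ((0, x_t0), (1, x_t1)):
        for i, x in enumerate(xs):
            rows.append(
                {"g1": f"a{i}", "g2": f"b{i}", "timepoint": t, "replicate": 1, "x": x}
            )
    return pd.DataFrame(rows)


class TestFitness:
    def test_hand_zscore(self):
        df = _fitness_frame([0.0, 0.0, 0.0], [-2.0, 0.0, 2.0])
        out = compute_fitness(df)
        expected = np.array([-2, 0, 2]) / np.std([-2, 0, 2])
        assert np.allclose(np.sort(out["f"]), np.sort(expected))
        assert out["f"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        df = _fitness_frame([0.1, 0.2], [0.1, 0.2])  # all m = 0
        with pytest.raises(ValueError, match="degenerate"):
            compute_fitness(df)

    def test_location_invariance(self):
        base = _fitness_frame([0.0, 0.3, -0.1], [0.5, -0.2, 0.4])
        shifted = base.copy()
        shifted.loc[shifted["timepoint"] == 1, "x"] += 3.7
        f0 = compute_fitness(base)["f"].to_numpy()
        f1 = compute_fitness(shifted)["f"].to_numpy()
        assert np.allclose(f0, f1)

    def test_order_invariance(self):
        df = _fitness_frame([0.0, 0.3, -0.1], [0.5, -0.2, 0.4])
        perm = df.sample(frac=1.0, random_state=4)
        a = compute_fitness(df).set_index(["g1", "g2"])["f"]
        b = compute_fitness(perm).set_index(["g1", "g2"])["f"]
        assert np.allclose(a.sort_index(), b.sort_index())
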