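"""Exon categories, coverage normalization, 5' bias and clustering."""

import numpy as np
import pandas as pd
import pytest

from cdkp.coverage import (
    classify_exons,
    cluster_bias,
    count_exon_overlaps,
    exon_coverage,
    first_exon_shift_test,
    five_prime_bias,
)
from cdkp.simulate import default_coverage_truth, simulate_exon_coverage


def _gtf(lines):
    return "\n".join(lines) + "\n"


def _feature(ftype, start, end, strand, gid, tid=None, eid=None):
    attrs = f'gene_id "{gid}";'
    if tid:
        attrs += f' transcript_id "{tid}";'
    if eid:
        attrs += f' exon_id "{eid}";'
    return f"chr1\ttest\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}"


def _single_transcript_gtf(strand="+"):
    return _gtf(
        [
            _feature("gene", 100, 1000, strand, "gA"),
            _feature("transcript", 100, 1000, strand, "gA", "tA1"),
            _feature("exon", 100, 200, strand, "gA", "tA1", "e1"),
            _feature("exon", 400, 500, strand, "gA", "tA1", "e2"),
            _feature("exon", 900, 1000, strand, "gA", "tA1", "e3"),
        ]
    )


class TestClassifyExons:
    def test_single_transcript_plus(self):
        recs = classify_exons(_single_transcript_gtf("+"), from_string=True)
        cats = {r.exon_id: r.category for r in recs}
        assert cats == {"e1": "First", "e2": "Internal", "e3": "Last"}

    def test_single_transcript_minus(self):
        recs = classify_exons(_single_transcript_gtf("-"), from_string=True)
        cats = {r.exon_id: r.category for r in recs}
        assert cats == {"e3": "First", "e2": "Internal", "e1": "Last"}

    def test_two_transcript_worked_example(self):
        gtf = _gtf(
            [
                _feature("gene", 100, 1000, "+", "gA"),
                _feature("transcript", 100, 1000, "+", "gA", "t1"),
                _feature("exon", 100, 200, "+", "gA", "t1", "e1"),
                _feature("exon", 400, 500, "+", "gA", "t1", "e2"),
                _feature("exon", 900, 1000, "+", "gA", "t1", "e3"),
                _feature("transcript", 400, 1000, "+", "gA", "t2"),
                _feature("exon", 400, 500, "+", "gA", "t2", "e2"),
                _feature("exon", 900, 1000, "+", "gA", "t2", "e3"),
            ]
        )
        recs = classify_exons(gtf, from_string=True)
        cats = {r.exon_id: r.category for r in recs}
        assert cats == {"e1": "First", "e2": "AlternativeFirst", "e3": "Last"}
        assert len(recs) == 3  # shared exons are single records

    def test_strand_flip_swaps_first_last(self):
        plus = {r.exon_id: r.category for r in
                classify_exons(_single_transcript_gtf("+"), from_string=True)}
        minus = {r.exon_id: r.category for r in
                 classify_exons(_single_transcript_gtf("-"), from_string=True)}
        assert plus["e1"] == minus["e3"] == "First"
        assert plus["e3"] == minus["e1"] == "Last"

    def test_coordinates_half_open(self):
        recs = classify_exons(_single_transcript_gtf("+"), from_string=True)
        e1 = next(r for r in recs if r.exon_id == "e1")
        assert (e1.start, e1.end) == (99, 200)


class TestOverlapCounting:
    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        recs = classify_exons(_single_transcript_gtf("+"), from_string=True)
        starts = rng.integers(0, 1100, size=300)
        reads = pd.DataFrame(
            {
                "sample": "s1",
                "chrom": "chr1",
                "start": starts,
                "end": starts + rng.integers(20, 120, size=300),
                "strand": rng.choice(["+", "-"], size=300),
            }
        )
        got = count_exon_overlaps(reads, recs).set_index("exon_id")["count"]
        for r in recs:
            expected = int(
                (
                    (reads["strand"] == r.strand)
                    & (reads["start"] < r.end)
                    & (reads["end"] > r.start)
                ).sum()
            )
            assert got[r.exon_id] == expected

    def test_read_spanning_two_exons_counts_twice(self):
        recs = classify_exons(_single_transcript_gtf("+"), from_string=True)
        reads = pd.DataFrame(
            {"sample": ["s1"], "chrom": ["chr1"], "start": [150], "end": [450],
             "strand": ["+"]}
        )
        got = count_exon_overlaps(reads, recs).set_index("exon_id")["count"]
        assert got["e1"] == 1 and got["e2"] == 1 and got["e3"] == 0


class TestCoverageNormalization:
    def _counts(self, e1, e2, e3, sample="s1"):
        return pd.DataFrame(
            {"sample": sample, "gene_id": "gA", "exon_id": ["e1", "e2", "e3"],
             "count": [e1, e2, e3]}
        )

    def test_low_count_gene_dropped(self):
        recs = classify_exons(_single_transcript_gtf("+"), from_string=True)
        cov = exon_coverage(self._counts(3, 3, 3), recs)  # 9 reads < 10
        assert cov.empty

    def test_rpm_log2_closed_form(self):
        recs = classify_exons(_single_transcript_gtf("+"), from_string=True)
        counts = self._counts(100, 999_800, 100)  # total 1e6
        cov = exon_coverage(counts, recs).set_index("exon_id")
        assert cov.loc["e1", "rpm_log2"] == pytest.approx(np.log2(101))


class TestFivePrimeBias:
    def test_self_contrast_identically_zero(self):
        truth = default_coverage_truth(seed=1, n_genes=10)
        counts, gtf = simulate_exon_coverage(truth)
        recs = classify_exons(gtf, from_string=True)
        dup = counts[counts["sample"] == "NTC_1"].assign(sample="KO_SELF")
        cov = exon_coverage(pd.concat([counts[counts["sample"] == "NTC_1"], dup]), recs)
        _, bias = five_prime_bias(cov, ["NTC_1"])
        assert (bias["bias5"] == 0).all()

    def test_lfc_convention(self):
        # lfc(First)=+1, lfc(Last)=-1 => bias5 = 2
        truth = default_coverage_truth(seed=2, n_genes=4, reads_per_gene=200_000)
        counts, gtf = simulate_exon_coverage(truth)
        recs = classify_exons(gtf, from_string=True)
        cat = {(r.gene_id, r.exon_id): r.category for r in recs}
        ko = counts[counts["sample"] == "NTC_1"].assign(sample="KO_MADE")
        scale = {"First": 2.0, "Last": 0.5}
        ko["count"] = [
            int(c * scale.get(cat[(g, e)], 1.0))
            for c, g, e in zip(ko["count"], ko["gene_id"], ko["exon_id"])
        ]
        cov = exon_coverage(pd.concat([counts, ko]), recs)
        _, bias = five_prime_bias(cov, ["NTC_1", "NTC_2"])
        made = bias[bias["sample"] == "KO_MADE"]
        # RPM renormalization shifts both exons equally, so the difference
        # stays log2(2) - log2(0.5) = 2
        assert made["bias5"].mean() == pytest.approx(2.0, abs=0.1)

    def test_planted_bias_recovery(self):
        truth = default_coverage_truth(
            seed=3,
            n_genes=30,
            bias_true={("KO_A", f"SIMG{i + 1:03d}"): 2.0 for i in range(5)},
        )
        counts, gtf = simulate_exon_coverage(truth)
        recs = classify_exons(gtf, from_string=True)
        cov = exon_coverage(counts, recs)
        _, bias = five_prime_bias(cov, list(truth.ntc_samples))
        hit = bias[(bias["sample"] == "KO_A") & bias["gene_id"].isin(
            [f"SIMG{i + 1:03d}" for i in range(5)]
        )]
        assert np.allclose(hit["bias5"], 2.0, atol=0.3)

    def test_shift_test_detects(self):
        truth = default_coverage_truth(
            seed=4,
            n_genes=40,
            bias_true={("KO_A", f"SIMG{i + 1:03d}"): 1.5 for i in range(40)},
        )
        counts, gtf = simulate_exon_coverage(truth)
        recs = classify_exons(gtf, from_string=True)
        cov = exon_coverage(counts, recs)
        lfc, _ = five_prime_bias(cov, list(truth.ntc_samples))
        t, p = first_exon_shift_test(lfc, "KO_A", "KO_B")
        assert t > 0 and p < 1e-6
        t0, p0 = first_exon_shift_test(lfc, "KO_B")
        assert p0 > 0.01


class TestClusterBias:
    def _bias_frame(self, groups):
        rows = []
        for gene, pattern in groups.items():
            for sample, v in pattern.items():
                rows.append({"sample": sample, "gene_id": gene, "bias5": v})
        return pd.DataFrame(rows)

    def test_two_planted_groups(self):
        groups = {}
        for i in range(6):
            groups[f"up{i}"] = {f"KO{j}": 2.0 + 0.01 * i for j in range(4)}
            groups[f"flat{i}"] = {f"KO{j}": 0.0 + 0.01 * i for j in range(4)}
        labels, lists = cluster_bias(self._bias_frame(groups), n_clusters=2)
        up = {labels[f"up{i}"] for i in range(6)}
        flat = {labels[f"flat{i}"] for i in range(6)}
        assert len(up) == 1 and len(flat) == 1 and up != flat

    def test_column_permutation_invariant(self):
        rng = np.random.default_rng(5)
        frame = self._bias_frame(
            {f"g{i}": {f"KO{j}": float(rng.normal()) for j in range(4)}
             for i in range(20)}
        )
        labels1, _ = cluster_bias(frame, n_clusters=4)
        permuted = frame.copy()
        mapping = {"KO0": "KO2", "KO2": "KO0", "KO1": "KO3", "KO3": "KO1"}
        permuted["sample"] = permuted["sample"].map(mapping)
        labels2, _ = cluster_bias(permuted, n_clusters=4)
        # same partition (labels may be renamed)
        df = pd.DataFrame({"a": labels1, "b": labels2})
        assert df.groupby("a")["b"].nunique().max() == 1

    def test_too_many_clusters(self):
        frame = self._bias_frame({"g1": {"KO0": 1.0}, "g2": {"KO0": 2.0}})
        with pytest.raises(ValueError):
            cluster_bias(frame, n_clusters=5)
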