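import numpy as np
import pytest

from linkread.strainflow import (
    MIN_TOTAL_DEPTH,
    SnvRecord,
    analyze_sample_pair,
    build_maf_matrix,
    cluster_maf,
    detect_strain_shift,
    filter_snvs,
    parse_vcf_snvs,
)


def snv(
    position=100,
    total_depth=20,
    alt_support=10,
    quality=50.0,
    sample_id="S1",
    genome_id="sp1",
    ref="A",
    alt="G",
):
    return SnvRecord(
        genome_id=genome_id,
        position=position,
        ref_allele=ref,
        alt_allele=alt,
        total_depth=total_depth,
        alt_support=alt_support,
        quality=quality,
        sample_id=sample_id,
    )


class TestFilter:
    def test_boundary_values_pass(self):
        rec = snv(total_depth=6, alt_support=2, quality=15.0)
        assert filter_snvs([rec], "freebayes") == [rec]

    def test_depth_five_removed(self):
        rec = snv(total_depth=5, alt_support=5, quality=99.0)
        assert filter_snvs([rec], "samtools") == []

    def test_alt_support_one_removed(self):
        rec = snv(total_depth=50, alt_support=1, quality=99.0)
        assert filter_snvs([rec], "freebayes") == []

    def test_quality_below_15_removed(self):
        rec = snv(total_depth=50, alt_support=10, quality=14.9)
        assert filter_snvs([rec], "freebayes") == []

    def test_instrain_not_filtered(self):
        rec = snv(total_depth=3, alt_support=1, quality=0.0)
        assert filter_snvs([rec], "instrain") == [rec]

    def test_unknown_caller_rejected(self):
        with pytest.raises(ValueError):
            filter_snvs([], "gatk")

    def test_default_depth_threshold_is_six(self):
        assert MIN_TOTAL_DEPTH == 6

    def test_filtering_monotone_in_thresholds(self, rng):
        records = [
            snv(
                position=i,
                total_depth=int(rng.integers(1, 40)),
                alt_support=0,
                quality=float(rng.integers(0, 60)),
            )
            for i in range(200)
        ]
        for r in records:
            r.alt_support = int(rng.integers(0, r.total_depth + 1))
        prev = len(records) + 1
        for min_depth in (0, 4, 6, 10, 20):
            n = len(filter_snvs(records, "freebayes", min_depth=min_depth))
            assert n <= prev
            prev = n


class TestMafMatrix:
    def test_minor_allele_from_reference_sample(self):
        # reference ref:alt = 8:2 -> minor is alt, reference cell 0.2
        samples = {
            "S1": [snv(total_depth=10, alt_support=2, sample_id="S1")],
            "S2": [snv(total_depth=10, alt_support=5, sample_id="S2")],
        }
        m = build_maf_matrix(samples, "S1", min_minor_support=2)
        row = m.values.iloc[0]
        assert row["S1"] == pytest.approx(0.2)
        assert bool(m.minor_is_alt.iloc[0]) is True

    def test_tie_resolves_to_alt(self):
        samples = {"S1": [snv(total_depth=10, alt_support=5)]}
        m = build_maf_matrix(samples, "S1")
        assert bool(m.minor_is_alt.iloc[0]) is True
        assert m.values.iloc[0]["S1"] == pytest.approx(0.5)

    def test_cell_may_exceed_half_in_other_samples(self):
        samples = {
            "S1": [snv(total_depth=10, alt_support=2, sample_id="S1")],
            "S2": [snv(total_depth=12, alt_support=10, sample_id="S2")],
        }
        m = build_maf_matrix(samples, "S1")
        assert m.values.iloc[0]["S2"] == pytest.approx(10 / 12)

    def test_reference_column_at_most_half(self, rng):
        records = {"S1": [], "S2": []}
        for i in range(50):
            depth = int(rng.integers(6, 40))
            alt = int(rng.integers(0, depth + 1))
            records["S1"].append(
                snv(position=i, total_depth=depth, alt_support=alt, sample_id="S1")
            )
            records["S2"].append(
                snv(position=i, total_depth=30,
                    alt_support=int(rng.integers(0, 31)), sample_id="S2")
            )
        m = build_maf_matrix(records, "S1", min_minor_support=0)
        assert (m.values["S1"] <= 0.5 + 1e-12).all()

    def test_min_minor_support_gate(self):
        # minor support 2 in every sample -> row excluded at the >=3 default
        samples = {"S1": [snv(total_depth=20, alt_support=2)]}
        m = build_maf_matrix(samples, "S1")
        assert len(m.values) == 0

    def test_row_missing_from_reference_dropped(self):
        samples = {
            "S1": [snv(position=1)],
            "S2": [snv(position=2, sample_id="S2")],
        }
        m = build_maf_matrix(samples, "S1")
        assert m.n_rows_dropped_no_reference == 1
        assert all(k[1] == 1 for k in m.values.index)

    def test_site_absent_from_sample_is_missing(self):
        samples = {
            "S1": [snv(position=1, total_depth=20, alt_support=8)],
            "S2": [],
        }
        m = build_maf_matrix(samples, "S1")
        assert np.isnan(m.values.iloc[0]["S2"])


class TestClustering:
    def blobs(self, rng, n=50, sigma=0.02):
        a = rng.normal((0.1, 0.1), sigma, size=(n, 2))
        b = rng.normal((0.45, 0.9), sigma, size=(n, 2))
        X = np.clip(np.vstack([a, b]), 0, 1)
        labels_true = np.array([0] * n + [1] * n)
        return X, labels_true

    def test_two_separated_blobs(self, rng):
        X, truth = self.blobs(rng)
        labels, k = cluster_maf(X, seed=0)
        assert k == 2
        # labels match blob membership up to permutation
        first, second = labels[: len(labels) // 2], labels[len(labels) // 2 :]
        assert len(set(first.tolist())) == 1 and len(set(second.tolist())) == 1
        assert first[0] != second[0]

    def test_identical_rows_single_cluster(self):
        X = np.tile([0.3, 0.3], (10, 1))
        labels, k = cluster_maf(X)
        assert k == 1 and set(labels.tolist()) == {0}

    def test_row_shuffle_invariance(self, rng):
        X, _ = self.blobs(rng)
        labels_a, k_a = cluster_maf(X, seed=7)
        perm = rng.permutation(len(X))
        labels_b, k_b = cluster_maf(X[perm], seed=7)
        assert k_a == k_b
        # partition identity: same pairs together
        same_a = labels_a[perm][:, None] == labels_a[perm][None, :]
        same_b = labels_b[:, None] == labels_b[None, :]
        assert (same_a == same_b).all()

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            cluster_maf(np.array([[0.1, 0.2], [0.3, 0.4]]))

    def test_nan_rejected(self):
        X = np.array([[0.1, np.nan], [0.2, 0.3], [0.4, 0.5]])
        with pytest.raises(ValueError):
            cluster_maf(X)


class TestShiftDetection:
    def test_crossed_event(self):
        X = np.array([[0.10, 0.80]] * 5)
        events = detect_strain_shift(np.zeros(5, dtype=int), X, ("S1", "S2"))
        assert events[0].crossed is True

    def test_small_shift_not_crossed(self):
        X = np.array([[0.10, 0.30]] * 4)
        (e,) = detect_strain_shift(np.zeros(4, dtype=int), X, ("S1", "S2"))
        assert e.crossed is False and e.delta == pytest.approx(0.2)

    def test_exactly_half_not_crossed(self):
        X = np.array([[0.50, 0.50]] * 3)
        (e,) = detect_strain_shift(np.zeros(3, dtype=int), X, ("S1", "S2"))
        assert e.crossed is False

    def test_events_sorted_by_abs_delta(self):
        X = np.array([[0.1, 0.2]] * 3 + [[0.1, 0.9]] * 3)
        labels = np.array([0] * 3 + [1] * 3)
        events = detect_strain_shift(labels, X, ("S1", "S2"))
        assert abs(events[0].delta) >= abs(events[1].delta)

    def test_planted_shift_recovery_rate(self):
        # planted crossing cluster (0.1 -> 0.9, sigma 0.05, 20+ SNVs) must be
        # flagged crossed in >= 95% of seeded replicates
        n_rep, hits = 40, 0
        for rep in range(n_rep):
            r = np.random.default_rng(1000 + rep)
            stable = np.clip(r.normal((0.1, 0.1), 0.05, size=(25, 2)), 0, 1)
            shifted = np.clip(r.normal((0.1, 0.9), 0.05, size=(25, 2)), 0, 1)
            X = np.vstack([stable, shifted])
            labels, _ = cluster_maf(X, seed=rep)
            events = detect_strain_shift(labels, X, ("S1", "S2"))
            if any(e.crossed for e in events):
                hits += 1
        assert hits / n_rep >= 0.95


class TestPairAnalysis:
    def test_end_to_end_deterministic(self, rng):
        samples = {"S1": [], "S5": []}
        for i in range(40):
            shifted = i >= 20
            ref_alt = int(rng.integers(1, 4))
            tgt_alt = int(rng.integers(16, 20)) if shifted else ref_alt
            samples["S1"].append(
                snv(position=i, total_depth=20, alt_support=ref_alt,
                    sample_id="S1")
            )
            samples["S5"].append(
                snv(position=i, total_depth=20, alt_support=tgt_alt,
                    sample_id="S5")
            )
        m = build_maf_matrix(samples, "S1")
        r1 = analyze_sample_pair(m, "S5", "sp1", seed=3)
        r2 = analyze_sample_pair(m, "S5", "sp1", seed=3)
        assert r1 is not None
        events1, labels1, k1 = r1
        events2, labels2, k2 = r2
        assert k1 == k2 and (labels1 == labels2).all()
        assert [e.cluster_id for e in events1] == [e.cluster_id for e in events2]
        assert any(e.crossed for e in events1)

    def test_species_with_too_few_rows_skipped(self):
        samples = {
            "S1": [snv(position=1, total_depth=20, alt_support=8)],
            "S2": [snv(position=1, total_depth=20, alt_support=8,
                       sample_id="S2")],
        }
        m = build_maf_matrix(samples, "S1")
        assert analyze_sample_pair(m, "S2", "sp1") is None


VCF_TEMPLATE = """\
##fileformat=VCFv4.2
##contig=<ID=sp1,length=100000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="allele depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
{rows}
"""


class TestVcfParsing:
    def test_parse_and_filter(self, tmp_path):
        rows = "\n".join(
            [
                "sp1\t100\t.\tA\tG\t50\tPASS\tDP=20\tGT:DP:AD\t0/1:20:12,8",
                "sp1\t200\t.\tC\tT\t10\tPASS\tDP=30\tGT:DP:AD\t0/1:30:25,5",
                "sp1\t300\t.\tG\tA\t99\tPASS\tDP=5\tGT:DP:AD\t0/1:5:3,2",
                "sp1\t400\t.\tT\tTA\t99\tPASS\tDP=30\tGT:DP:AD\t0/1:30:20,10",
            ]
        )
        path = tmp_path / "s1.vcf"
        path.write_text(VCF_TEMPLATE.format(rows=rows))
        records = parse_vcf_snvs(path, "S1")
        assert len(records) == 3  # the indel row is dropped
        assert records[0].total_depth == 20 and records[0].alt_support == 8
        kept = filter_snvs(records, "freebayes")
        # row 2 fails quality (<15), row 3 fails depth (<6)
        assert [r.position for r in kept] == [100]

    def test_multiallelic_split(self, tmp_path):
        rows = "sp1\t100\t.\tA\tG,C\t50\tPASS\tDP=30\tGT:DP:AD\t1/2:30:10,12,8"
        path = tmp_path / "s1.vcf"
        path.write_text(VCF_TEMPLATE.format(rows=rows))
        records = parse_vcf_snvs(path, "S1")
        assert [(r.alt_allele, r.alt_support) for r in records] == [
            ("G", 12),
            ("C", 8),
        ]
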