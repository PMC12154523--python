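"""Trimming, two-stage classification, homograft subtraction, accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graftflow.align import TranscriptAligner
from graftflow.classify import (
    ClassificationParams,
    ReadAccounting,
    TrimParams,
    classify_experiment,
    classify_sample,
    mapped_rate,
    subtract_homograft,
    trim_read,
)
from graftflow.datasets import grafting_read_accounting
from graftflow.simulate import ReadSet, SimulationConfig, simulate_experiment


def _oracle_trim(seq, quals, window, min_q, min_len):
    """Brute-force sliding-window oracle: scan every full window 5'->3',
    cut before the first one whose mean quality is below threshold."""
    cut = len(seq)
    for start in range(0, len(seq) - window + 1):
        if sum(quals[start : start + window]) / window < min_q:
            cut = start
            break
    if cut < min_len:
        return None
    return seq[:cut]


class TestTrim:
    def test_high_quality_read_unchanged(self):
        seq = "A" * 100
        qual = chr(30 + 33) * 100
        out = trim_read(seq, qual, TrimParams(4, 15, 75))
        assert out == (seq, qual)

    def test_low_quality_read_discarded(self):
        assert trim_read("A" * 100, chr(2 + 33) * 100) is None

    def test_partial_quality_drop_matches_oracle(self):
        quals = [30] * 80 + [2] * 20
        seq = "G" * 100
        out = trim_read(seq, quals, TrimParams(4, 15, 75))
        expected = _oracle_trim(seq, quals, 4, 15, 75)
        assert out is not None and out[0] == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            trim_read("ACGT", [30, 30, 30])

    @given(st.lists(st.integers(min_value=0, max_value=41), min_size=1,
                    max_size=60))
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_trim_equals_exhaustive_window_scan(self, quals):
        seq = "A" * len(quals)
        params = TrimParams(window=4, min_mean_quality=15, min_length=5)
        out = trim_read(seq, quals, params)
        expected = _oracle_trim(seq, quals, 4, 15, 5)
        if expected is None:
            assert out is None
        else:
            assert out is not None and out[0] == expected


class TestMappedRate:
    @pytest.mark.parametrize("mapped,clean,expected", [
        (32_064, 8_828_672, 0.36),
        (495_277, 16_256_512, 3.05),
        (0, 1000, 0.0),
        (1, 800, 0.13),  # 0.125 rounds half away from zero
    ])
    def test_rates(self, mapped, clean, expected):
        assert mapped_rate(mapped, clean) == expected

    def test_reproduces_published_accounting(self):
        """The printed per-sample mapped rates for both genomes follow from
        the printed read counts under half-away-from-zero rounding."""
        table = grafting_read_accounting()
        for _, row in table.iterrows():
            assert mapped_rate(row.rootstock_mapped_reads,
                               row.rootstock_clean_reads) == pytest.approx(
                row.rootstock_rate_pct)
            assert mapped_rate(row.scion_mapped_reads,
                               row.scion_clean_reads) == pytest.approx(
                row.scion_rate_pct)

    def test_zero_clean_rejected(self):
        with pytest.raises(ValueError):
            mapped_rate(0, 0)

    def test_accounting_invariants(self):
        with pytest.raises(ValueError):
            ReadAccounting("s", clean_reads=10, scion_mapped=5, unmapped=4,
                           rootstock_mapped=0)
        with pytest.raises(ValueError):
            ReadAccounting("s", clean_reads=10, scion_mapped=8, unmapped=2,
                           rootstock_mapped=3)


@pytest.fixture(scope="module")
def classified(small_experiment):
    return classify_experiment(small_experiment)


def _origin_of(name: str) -> str:
    return name.split("|origin=")[1].split("|")[0]


class TestClassifySample:
    def test_all_reads_from_one_scion_gene(self):
        gene = "".join(np.random.default_rng(1).choice(list("ACGT"), size=400))
        scion = TranscriptAligner({"sc": gene}, "scion")
        root = TranscriptAligner({"rs": gene[::-1]}, "rootstock")
        reads = ReadSet([f"r{i}" for i in range(20)],
                        [gene[i : i + 100] for i in range(20)],
                        ["I" * 100] * 20)
        counts, acc = classify_sample(reads, scion, root)
        assert acc.scion_mapped == acc.clean_reads == 20
        assert acc.unmapped == 0
        assert counts.empty

    def test_classification_agrees_with_provenance(self, small_experiment,
                                                   classified):
        """Error-laden heterograft reads: rootstock-origin reads are rescued
        against the rootstock set, scion-origin reads are not (their
        identity to the wrong genome is ~the ortholog identity, 0.85)."""
        exp = small_experiment
        scion_aln = TranscriptAligner(exp.scion_genes, "scion")
        root_aln = TranscriptAligner(exp.rootstock_genes, "rootstock")
        reads = exp.reads["hetero_stem_1"]
        counts, acc = classify_sample(reads, scion_aln, root_aln,
                                      sample_id="hetero_stem_1")
        assert acc.rootstock_mapped == counts.sum()
        params = ClassificationParams()
        rescued_origins = []
        missed_root = 0
        for name, seq in zip(reads.names, reads.sequences):
            hit = scion_aln.align(seq)
            scion_mapped = (hit is not None
                            and hit.identity >= params.scion_identity_min
                            and hit.aligned_read_fraction
                            >= params.scion_coverage_min)
            if scion_mapped:
                if _origin_of(name) == "rootstock":
                    missed_root += 1  # ortholog window reached 90% identity
                continue
            rhit = root_aln.align(seq)
            if (rhit is not None
                    and rhit.identity >= params.rootstock_identity_min):
                rescued_origins.append(_origin_of(name))
        true_root = sum(_origin_of(n) == "rootstock" for n in reads.names)
        # no scion-origin read is ever rescued (identity to the wrong
        # genome ~0.85 < 0.95) and nearly all rootstock reads are
        assert all(o == "rootstock" for o in rescued_origins)
        assert len(rescued_origins) >= 0.9 * true_root
        assert missed_root <= 0.1 * true_root

    def test_homograft_candidates_essentially_zero(self, classified):
        homo_cols = [a.sample_id for a in classified.accounting
                     if a.sample_id.startswith("homo")]
        assert classified.counts[homo_cols].to_numpy().sum() == 0

    def test_accounting_conservation(self, classified):
        for acc in classified.accounting:
            assert acc.scion_mapped + acc.unmapped == acc.clean_reads
            assert acc.rootstock_mapped <= acc.unmapped

    def test_empty_read_set(self, small_experiment):
        exp = small_experiment
        scion_aln = TranscriptAligner(exp.scion_genes, "scion")
        root_aln = TranscriptAligner(exp.rootstock_genes, "rootstock")
        counts, acc = classify_sample(ReadSet([], [], []), scion_aln, root_aln)
        assert acc.clean_reads == 0 and counts.empty

    def test_provenance_tags_carry_no_signal(self, small_experiment):
        """Permuting the provenance suffixes of read names leaves the
        classification byte-identical (the classifier never reads them)."""
        exp = small_experiment
        scion_aln = TranscriptAligner(exp.scion_genes, "scion")
        root_aln = TranscriptAligner(exp.rootstock_genes, "rootstock")
        reads = exp.reads["hetero_pulp_1"]
        rng = np.random.default_rng(0)
        suffixes = [n.split("|", 1)[1] for n in reads.names]
        rng.shuffle(suffixes)
        shuffled = ReadSet(
            [n.split("|", 1)[0] + "|" + s
             for n, s in zip(reads.names, suffixes)],
            reads.sequences, reads.qualities)
        c1, a1 = classify_sample(reads, scion_aln, root_aln)
        c2, a2 = classify_sample(shuffled, scion_aln, root_aln)
        assert c1.equals(c2)
        assert a1.scion_mapped == a2.scion_mapped
        assert a1.rootstock_mapped == a2.rootstock_mapped

    def test_identity_threshold_monotonicity(self, small_experiment):
        """Raising the rescue identity threshold never enlarges the
        candidate set (set inclusion along 0.90 -> 0.95 -> 0.99)."""
        exp = small_experiment
        scion_aln = TranscriptAligner(exp.scion_genes, "scion")
        root_aln = TranscriptAligner(exp.rootstock_genes, "rootstock")
        reads = exp.reads["hetero_stem_2"]
        previous = None
        for thr in (0.90, 0.95, 0.99):
            params = ClassificationParams(rootstock_identity_min=thr)
            counts, _ = classify_sample(reads, scion_aln, root_aln, params)
            current = set(counts.index[counts > 0])
            if previous is not None:
                assert current <= previous
            previous = current

    def test_paired_fragments_counted_once(self):
        cfg = SimulationConfig(
            n_genes=10, gene_length_range=(300, 400), n_mobile=3,
            mobility_factor_near=0.05, mobility_factor_far=0.01,
            reads_per_sample=300, paired=True, error_rate=0.0, seed=13)
        exp = simulate_experiment(cfg)
        scion_aln = TranscriptAligner(exp.scion_genes, "scion")
        root_aln = TranscriptAligner(exp.rootstock_genes, "rootstock")
        reads = exp.reads["hetero_stem_1"]
        counts, acc = classify_sample(reads, scion_aln, root_aln)
        assert acc.clean_reads == 300  # fragments, not mates
        assert acc.scion_mapped + acc.unmapped == 300
        true_root = sum(_origin_of(n) == "rootstock" for n in reads.names)
        assert counts.sum() == true_root


class TestSubtractHomograft:
    def test_gene_detected_in_control_is_excluded(self):
        hetero = pd.DataFrame({"h1": [50, 40]}, index=["g1", "g2"])
        homo = pd.DataFrame({"c1": [3, 0]}, index=["g1", "g2"])
        mobile, filtered = subtract_homograft(hetero, homo)
        assert mobile == ["g2"]
        assert "g1" not in filtered.index

    def test_gene_clean_in_all_controls_is_retained(self):
        hetero = pd.DataFrame({"h1": [50]}, index=["g1"])
        homo = pd.DataFrame({"c1": [0], "c2": [0]}, index=["g1"])
        mobile, _ = subtract_homograft(hetero, homo)
        assert mobile == ["g1"]

    def test_threshold_configurable(self):
        hetero = pd.DataFrame({"h1": [50]}, index=["g1"])
        homo = pd.DataFrame({"c1": [1]}, index=["g1"])
        params = ClassificationParams(homograft_detection_threshold=2)
        mobile, _ = subtract_homograft(hetero, homo, params)
        assert mobile == ["g1"]

    def test_empty_homograft_warns_and_passes_through(self):
        hetero = pd.DataFrame({"h1": [5]}, index=["g1"])
        homo = pd.DataFrame(index=["g1"])
        with pytest.warns(UserWarning, match="homograft"):
            mobile, _ = subtract_homograft(hetero, homo)
        assert mobile == ["g1"]

    def test_full_pipeline_recovers_planted_mobile_set(
            self, small_experiment, classified):
        truth = small_experiment.truth.mobile_gene_ids
        called = set(classified.mobile_genes)
        tp = len(called & truth)
        assert tp / len(truth) >= 0.9       # sensitivity
        assert tp / max(1, len(called)) >= 0.9  # precision

    def test_distance_effect(self, classified):
        frame = classified.accounting_frame()
        near = frame.loc[[i for i in frame.index if "stem" in i and
                          i.startswith("hetero")], "rootstock_rate_of_clean"]
        far = frame.loc[[i for i in frame.index if "pulp" in i and
                         i.startswith("hetero")], "rootstock_rate_of_clean"]
        assert near.min() > far.max()
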