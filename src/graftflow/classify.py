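"""Mobile-transcript read classification.

Implements the heterograft identification procedure: quality trimming
(sliding-window, Trimmomatic semantics), mapping of clean reads to the
scion transcript set, rescue of the unmapped remainder against the
rootstock set under a >=95% identity rule, and subtraction of genes that
are also detected in homograft controls (false positives driven by
ortholog homology and sequencing error). Also produces per-sample read
accounting (clean reads, mapped reads, mapped rate per genome).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .align import TranscriptAligner
from .simulate import GraftSample, ReadSet, SimulatedExperiment

logger = logging.getLogger(__name__)

__all__ = [
    "TrimParams", "ClassificationParams", "ReadAccounting",
    "trim_read", "trim_read_set", "classify_sample", "classify_experiment",
    "subtract_homograft", "mapped_rate",
]


@dataclass(frozen=True)
class TrimParams:
    """Sliding-window quality trimming parameters.

    Defaults correspond to the common Trimmomatic setting
    SLIDINGWINDOW:4:15 MINLEN:75.
    """

    window: int = 4
    min_mean_quality: float = 15.0
    min_length: int = 75

    def __post_init__(self) -> None:
        if self.window < 1 or self.min_length < 1:
            raise ValueError("window and min_length must be >= 1")


@dataclass(frozen=True)
class ClassificationParams:
    """Thresholds of the two-stage read classifier.

    A read is scion-mapped when its best scion hit reaches
    ``scion_identity_min`` identity over ``scion_coverage_min`` of its
    length; only non-scion-mapped reads are examined against the rootstock
    set, where ``rootstock_identity_min`` (default 0.95 — the >=95%
    sequence-identity rule) and ``rootstock_coverage_min`` apply. A
    rootstock gene seen at least ``homograft_detection_threshold`` times in
    any homograft control is discarded as a cross-mapping artifact.
    """

    scion_identity_min: float = 0.90
    scion_coverage_min: float = 0.90
    rootstock_identity_min: float = 0.95
    rootstock_coverage_min: float = 0.80
    homograft_detection_threshold: int = 1
    seed_k: int = 15
    seed_stride: int = 1

    def __post_init__(self) -> None:
        for name in ("scion_identity_min", "scion_coverage_min",
                     "rootstock_identity_min", "rootstock_coverage_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.homograft_detection_threshold < 0:
            raise ValueError("homograft_detection_threshold must be >= 0")


@dataclass
class ReadAccounting:
    """Table-1-style per-sample read accounting.

    ``rootstock_mapped_rate`` uses the reads submitted to the rescue stage
    (the scion-unmapped reads) as its denominator, matching the published
    accounting convention for the second genome.
    """

    sample_id: str
    clean_reads: int
    scion_mapped: int
    unmapped: int
    rootstock_mapped: int

    def __post_init__(self) -> None:
        if self.scion_mapped + self.unmapped != self.clean_reads:
            raise ValueError("scion_mapped + unmapped must equal clean_reads")
        if self.rootstock_mapped > self.unmapped:
            raise ValueError("rootstock_mapped cannot exceed unmapped")

    @property
    def scion_mapped_rate(self) -> float:
        return mapped_rate(self.scion_mapped, self.clean_reads)

    @property
    def rootstock_mapped_rate(self) -> float:
        if self.unmapped == 0:
            return 0.0
        return mapped_rate(self.rootstock_mapped, self.unmapped)

    @property
    def rootstock_rate_of_clean(self) -> float:
        """Rootstock-mapped reads as a share of the whole clean library.

        The published accounting divides by the rescue-stage input
        (scion-unmapped reads), which in deep real libraries is dominated
        by unalignable junk and therefore tracks mobile abundance. The
        synthetic libraries contain no junk, so the distance effect is
        read off this whole-library rate instead.
        """
        return mapped_rate(self.rootstock_mapped, self.clean_reads)


def mapped_rate(mapped: int, clean: int) -> float:
    """Percentage of clean reads mapped, rounded half-away-from-zero to 2 dp."""
    if clean <= 0:
        raise ValueError("clean read count must be positive")
    if not (0 <= mapped <= clean):
        raise ValueError("mapped must satisfy 0 <= mapped <= clean")
    pct = Decimal(100 * mapped) / Decimal(clean)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# trimming

def trim_read(sequence: str, qualities, params: TrimParams = TrimParams()):
    """Sliding-window trim of a single read.

    Scans 5'->3' over every full window of ``params.window`` bases; at the
    first window whose mean quality falls below ``min_mean_quality`` the
    read is cut immediately before the window's first base. Reads shorter
    than ``min_length`` after cutting are discarded (returns None).

    ``qualities`` may be a Phred+33 string or a sequence of integer scores.
    """
    if isinstance(qualities, str):
        q = np.frombuffer(qualities.encode("ascii"), dtype=np.uint8) - 33
    else:
        q = np.asarray(qualities, dtype=float)
    if len(q) != len(sequence):
        raise ValueError("sequence and qualities must have equal length")
    n, w = len(sequence), params.window
    cut = n
    if n >= w:
        means = np.convolve(q, np.ones(w) / w, mode="valid")
        failing = np.nonzero(means < params.min_mean_quality)[0]
        if failing.size:
            cut = int(failing[0])
    elif n > 0 and q.mean() < params.min_mean_quality:
        cut = 0
    if cut < params.min_length:
        return None
    return sequence[:cut], qualities[:cut]


def trim_read_set(reads: ReadSet, params: TrimParams = TrimParams()) -> ReadSet:
    """Trim every read, dropping discarded ones.

    For paired sets both mates are trimmed and a fragment is dropped when
    either mate falls below the minimum length.
    """
    if reads.paired:
        names, seqs, quals, m_seqs, m_quals = [], [], [], [], []
        for name, s1, q1, s2, q2 in zip(reads.names, reads.sequences,
                                        reads.qualities, reads.mate_sequences,
                                        reads.mate_qualities):
            out1 = trim_read(s1, q1, params)
            out2 = trim_read(s2, q2, params)
            if out1 is not None and out2 is not None:
                names.append(name)
                seqs.append(out1[0])
                quals.append(out1[1])
                m_seqs.append(out2[0])
                m_quals.append(out2[1])
        return ReadSet(names, seqs, quals, m_seqs, m_quals)
    names, seqs, quals = [], [], []
    for name, seq, qual in zip(reads.names, reads.sequences, reads.qualities):
        out = trim_read(seq, qual, params)
        if out is not None:
            names.append(name)
            seqs.append(out[0])
            quals.append(out[1])
    return ReadSet(names, seqs, quals)


# ---------------------------------------------------------------------------
# classification

def classify_sample(
    reads: ReadSet,
    scion_aligner: TranscriptAligner,
    rootstock_aligner: TranscriptAligner,
    params: ClassificationParams = ClassificationParams(),
    sample_id: str = "sample",
    trim: TrimParams | None = TrimParams(),
) -> tuple[pd.Series, ReadAccounting]:
    """Two-stage classification of one library.

    Returns ``(candidate_counts, accounting)`` where ``candidate_counts``
    maps rootstock gene ids to the number of reads rescued against them
    under the identity/coverage thresholds. Paired fragments are counted
    once: mates are aligned independently and the stronger hit (ties to
    mate 1) decides.
    """
    if trim is not None:
        reads = trim_read_set(reads, trim)
    clean = len(reads)
    counts: dict[str, int] = {}
    scion_mapped = 0
    rootstock_mapped = 0

    def best_of(aligner, s1, s2):
        h1 = aligner.align(s1)
        if s2 is None:
            return h1
        h2 = aligner.align(s2)
        if h1 is None:
            return h2
        if h2 is None or h2.score <= h1.score:  # ties -> mate 1
            return h1
        return h2

    mate_seqs = reads.mate_sequences if reads.paired else [None] * clean
    for seq, mate in zip(reads.sequences, mate_seqs):
        hit = best_of(scion_aligner, seq, mate)
        if (hit is not None and hit.identity >= params.scion_identity_min
                and hit.aligned_read_fraction >= params.scion_coverage_min):
            scion_mapped += 1
            continue
        rhit = best_of(rootstock_aligner, seq, mate)
        if (rhit is not None and rhit.identity >= params.rootstock_identity_min
                and rhit.aligned_read_fraction >= params.rootstock_coverage_min):
            rootstock_mapped += 1
            counts[rhit.target_gene] = counts.get(rhit.target_gene, 0) + 1
    accounting = ReadAccounting(
        sample_id=sample_id, clean_reads=clean, scion_mapped=scion_mapped,
        unmapped=clean - scion_mapped, rootstock_mapped=rootstock_mapped)
    series = pd.Series(counts, dtype=int).sort_index()
    series.name = sample_id
    return series, accounting


@dataclass
class ClassificationResult:
    """Candidate counts and accounting for a whole experiment."""

    counts: pd.DataFrame              # rootstock genes x samples
    accounting: list[ReadAccounting]
    samples: list[GraftSample]
    mobile_genes: list[str] = field(default_factory=list)
    filtered_counts: pd.DataFrame | None = None

    def accounting_frame(self) -> pd.DataFrame:
        rows = [{
            "sample_id": a.sample_id, "clean_reads": a.clean_reads,
            "scion_mapped": a.scion_mapped,
            "scion_mapped_rate": a.scion_mapped_rate,
            "unmapped": a.unmapped, "rootstock_mapped": a.rootstock_mapped,
            "rootstock_mapped_rate": a.rootstock_mapped_rate,
            "rootstock_rate_of_clean": a.rootstock_rate_of_clean,
        } for a in self.accounting]
        return pd.DataFrame(rows).set_index("sample_id")


def classify_experiment(
    experiment: SimulatedExperiment,
    params: ClassificationParams = ClassificationParams(),
    trim: TrimParams | None = TrimParams(),
) -> ClassificationResult:
    """Run the full pipeline on a simulated experiment.

    Classifies every sample, then subtracts rootstock genes detected in
    the homograft controls from the heterograft candidate tables.
    """
    scion_aln = TranscriptAligner(experiment.scion_genes, "scion",
                                  seed_k=params.seed_k,
                                  seed_stride=params.seed_stride)
    root_aln = TranscriptAligner(experiment.rootstock_genes, "rootstock",
                                 seed_k=params.seed_k,
                                 seed_stride=params.seed_stride)
    cols, accounting = {}, []
    for sample in experiment.samples:
        counts, acc = classify_sample(
            experiment.reads[sample.sample_id], scion_aln, root_aln,
            params, sample.sample_id, trim)
        cols[sample.sample_id] = counts
        accounting.append(acc)
    all_genes = sorted(set().union(*[set(c.index) for c in cols.values()]))
    counts = pd.DataFrame(
        {s: c.reindex(all_genes, fill_value=0) for s, c in cols.items()},
        index=all_genes, dtype=int)
    hetero = [s.sample_id for s in experiment.samples if s.graft_type == "hetero"]
    homo = [s.sample_id for s in experiment.samples if s.graft_type == "homo"]
    mobile, filtered = subtract_homograft(counts[hetero], counts[homo], params)
    return ClassificationResult(counts=counts, accounting=accounting,
                                samples=experiment.samples,
                                mobile_genes=mobile, filtered_counts=filtered)


def subtract_homograft(
    hetero_counts: pd.DataFrame,
    homo_counts: pd.DataFrame,
    params: ClassificationParams = ClassificationParams(),
) -> tuple[list[str], pd.DataFrame]:
    """Remove rootstock genes detected in homograft controls.

    Any gene whose candidate count reaches
    ``params.homograft_detection_threshold`` in ANY homograft sample is
    removed from every heterograft table; the survivors are the mobile
    mRNA candidate set. With no homograft samples all genes pass (warned).
    """
    hetero_counts = hetero_counts.copy()
    if homo_counts.shape[1] == 0:
        warnings.warn("no homograft controls supplied; all candidate genes "
                      "pass the false-positive filter", stacklevel=2)
        return sorted(hetero_counts.index), hetero_counts
    common = homo_counts.reindex(hetero_counts.index, fill_value=0)
    detected = (common >= params.homograft_detection_threshold).any(axis=1)
    keep = hetero_counts.index[~detected]
    filtered = hetero_counts.loc[keep]
    filtered = filtered.loc[filtered.sum(axis=1) > 0]
    return sorted(filtered.index), filtered
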