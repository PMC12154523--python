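"""Desk-scale read-to-transcript alignment.

Reads are aligned to a transcript set by exact k-mer seeding on both
strands followed by banded global extension of the read against the
seeded reference (edlib's bit-vector alignment in infix mode, i.e. the
whole read against the best-matching reference window). Identity is
BLAST-like: matching columns divided by alignment columns. This stands in,
at transcript scale and deterministically, for the genome aligners used in
full-size mobile-RNA studies.

Coordinates are 0-based half-open; ties between equally scoring targets
break to the lexicographically smallest gene id, then the + strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

__all__ = ["AlignmentHit", "TranscriptAligner", "hits_from_sam"]

_CIGAR_RE = re.compile(r"(\d+)([=XID])")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentHit:
    """Best alignment of one read against one reference gene."""

    read_id: str
    target_gene: str
    target_genome: str  # "scion" | "rootstock" (or caller-supplied label)
    identity: float     # matching columns / alignment columns, in [0, 1]
    aligned_read_fraction: float
    score: int          # matches - mismatches - gaps
    strand: str         # "+" | "-"

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must be in [0, 1]")
        if not (0.0 < self.aligned_read_fraction <= 1.0):
            raise ValueError("aligned_read_fraction must be in (0, 1]")


def _cigar_stats(cigar: str) -> tuple[int, int, int, int]:
    """(matches, mismatches, gaps, read bases consumed) from an extended cigar."""
    eq = x = gaps = consumed = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op == "=":
            eq += n
            consumed += n
        elif op == "X":
            x += n
            consumed += n
        elif op == "I":  # gap in target, consumes read
            gaps += n
            consumed += n
        else:            # "D": gap in read, consumes target
            gaps += n
    return eq, x, gaps, consumed


class TranscriptAligner:
    """k-mer-seeded aligner over a fixed reference gene set.

    Parameters
    ----------
    references:
        Mapping of gene id to DNA sequence (A/C/G/T).
    genome_label:
        Label stamped on every hit ("scion" or "rootstock" in the grafting
        pipeline).
    seed_k:
        Seed k-mer length. A read shares a seed with a target whenever an
        exact k-mer (on either strand) occurs in both.
    seed_stride:
        Spacing of the k-mer positions sampled from each read. 1 examines
        every read k-mer (exhaustive seeding); larger strides trade a
        slightly increased chance of missing a borderline target for
        speed. The final k-mer of the read is always sampled.
    """

    def __init__(self, references: dict[str, str], genome_label: str = "scion",
                 seed_k: int = 15, seed_stride: int = 1):
        if not references:
            raise ValueError("reference gene set is empty")
        if seed_k < 4:
            raise ValueError("seed_k must be >= 4")
        self.references = {g: s.upper() for g, s in references.items()}
        self.genome_label = genome_label
        self.seed_k = seed_k
        self.seed_stride = max(1, seed_stride)
        self._index: dict[str, tuple[str, ...]] = {}
        index: dict[str, set[str]] = {}
        for gid, seq in self.references.items():
            for i in range(len(seq) - seed_k + 1):
                index.setdefault(seq[i : i + seed_k], set()).add(gid)
        self._index = {k: tuple(sorted(v)) for k, v in index.items()}

    def _seed_candidates(self, read: str) -> set[str]:
        k = self.seed_k
        idx = self._index
        hits: set[str] = set()
        positions = list(range(0, len(read) - k + 1, self.seed_stride))
        last = len(read) - k
        if positions and positions[-1] != last:
            positions.append(last)
        for i in positions:
            found = idx.get(read[i : i + k])
            if found:
                hits.update(found)
        return hits

    def align(self, read: str, read_id: str = "") -> AlignmentHit | None:
        """Best hit of ``read`` against the reference set, or None.

        Both strands are searched (the reverse complement of the read is
        seeded and extended against the forward reference). Returns None
        when the read is shorter than the seed length or shares no seed
        k-mer with any target.
        """
        read = read.upper()
        if len(read) < self.seed_k:
            return None
        rc = _revcomp(read)
        best: AlignmentHit | None = None
        # '+' before '-' and lexicographic gene order make ties deterministic
        for strand, query in (("+", read), ("-", rc)):
            for gid in sorted(self._seed_candidates(query)):
                res = edlib.align(query, self.references[gid], mode="HW",
                                  task="path")
                if res["editDistance"] < 0 or res["cigar"] is None:
                    continue
                eq, x, gaps, consumed = _cigar_stats(res["cigar"])
                columns = eq + x + gaps
                hit = AlignmentHit(
                    read_id=read_id, target_gene=gid,
                    target_genome=self.genome_label,
                    identity=eq / columns if columns else 0.0,
                    aligned_read_fraction=consumed / len(read),
                    score=eq - x - gaps, strand=strand)
                if best is None or hit.score > best.score:
                    best = hit
        return best


def hits_from_sam(path, genome_label: str = "scion"):
    """Ingest pre-computed alignments from a SAM file as AlignmentHits.

    Alternative entry point for running the classification stage on the
    output of an external aligner. Identity is derived from the NM tag
    (edit distance) and the CIGAR; unmapped records are skipped. Yields one
    hit per primary alignment.
    """
    import pysam

    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            stats = rec.get_cigar_stats()[0]
            aligned = stats[0] + stats[7] + stats[8]  # M + = + X
            gaps = stats[1] + stats[2]                # I + D
            columns = aligned + gaps
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            matches = aligned - max(0, nm - gaps)
            read_len = rec.infer_read_length() or rec.query_length or aligned
            yield AlignmentHit(
                read_id=rec.query_name, target_gene=rec.reference_name,
                target_genome=genome_label,
                identity=matches / columns if columns else 0.0,
                aligned_read_fraction=min(1.0, (aligned + stats[1]) / read_len)
                if read_len else 1.0,
                score=matches - (columns - matches),
                strand="-" if rec.is_reverse else "+")
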