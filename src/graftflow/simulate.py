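"""Synthetic heterograft/homograft experiment generator.

Emulates the data shape of a rootstock/scion grafting RNA-seq study on a
cucurbit pair (e.g. watermelon scion on pumpkin rootstock): two gene sets
diverged to a controlled per-site identity (ortholog homology), a planted
subset of rootstock genes whose transcripts cross the graft union into
scion tissue, with a relative abundance that decreases with distance from
the union (stem > pulp), homograft control samples that contain no
rootstock transcripts at all, sequencing reads with substitution errors
and Phred qualities, and metabolite abundance tables with a controlled
Spearman coupling to chosen transcripts.

Every downstream stage of the package (classification, quantification,
clustering, networks) can therefore be exercised against known ground
truth without any external download.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GraftSample",
    "GroundTruth",
    "ReadSet",
    "SimulatedExperiment",
    "generate_gene_sets",
    "simulate_reads",
    "simulate_experiment",
    "simulate_metabolites",
    "calibrated_noise_sd",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: tissue vocabulary: the stem sits near the graft union, the pulp far from it
NEAR_TISSUE = "stem"
FAR_TISSUE = "pulp"
TISSUES = (NEAR_TISSUE, FAR_TISSUE)
GRAFT_TYPES = ("hetero", "homo")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated grafting experiment.

    The defaults mirror a 12-sample two-graft-type x two-tissue x three-
    replicate design at desk scale: 200 ancestor genes of 300-1500 nt,
    scion/rootstock orthologs at 85% identity, 20 mobile rootstock genes,
    a rootstock-origin read fraction of 2% in stem (near the union) and
    0.4% in pulp (far), 50,000 single-end 100 nt reads per sample and a
    0.5% per-base substitution error rate.
    """

    n_genes: int = 200
    gene_length_range: tuple[int, int] = (300, 1500)
    ortholog_identity: float = 0.85
    n_mobile: int = 20
    mobility_factor_near: float = 0.02
    mobility_factor_far: float = 0.004
    reads_per_sample: int = 50_000
    read_length: int = 100
    error_rate: float = 0.005
    paired: bool = False
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.ortholog_identity <= 1.0):
            raise ValueError("ortholog_identity must be in (0, 1]")
        if not (0.0 <= self.mobility_factor_far <= self.mobility_factor_near < 1.0):
            raise ValueError(
                "mobility factors must satisfy 0 <= far <= near < 1 "
                "(abundance of mobile transcripts decreases with distance)"
            )
        lo, hi = self.gene_length_range
        if lo > hi:
            raise ValueError("gene_length_range must be (min, max) with min <= max")
        if lo < 20:
            raise ValueError(
                "gene lengths below 20 nt cannot realize the identity target"
            )
        for name in ("n_genes", "n_mobile", "reads_per_sample", "read_length",
                     "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_mobile > self.n_genes:
            raise ValueError("n_mobile cannot exceed n_genes")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        if self.read_length > lo:
            raise ValueError("read_length must not exceed the minimum gene length")


@dataclass(frozen=True)
class GraftSample:
    """Metadata for one sequencing library."""

    sample_id: str
    graft_type: str  # "hetero" | "homo"
    tissue: str      # "stem" (near union) | "pulp" (far)
    replicate: int
    fastq_paths: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.graft_type not in GRAFT_TYPES:
            raise ValueError(f"graft_type must be one of {GRAFT_TYPES}")
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")

    @property
    def mobility_key(self) -> str:
        return "near" if self.tissue == NEAR_TISSUE else "far"


@dataclass
class ReadSet:
    """In-memory read collection (names, sequences, qualities).

    For paired-end data ``mate_sequences``/``mate_qualities`` hold the
    second mate of each fragment, index-aligned with the first; names are
    shared between mates.
    """

    names: list[str]
    sequences: list[str]
    qualities: list[str]
    mate_sequences: list[str] | None = None
    mate_qualities: list[str] | None = None

    @property
    def paired(self) -> bool:
        return self.mate_sequences is not None

    def __len__(self) -> int:
        return len(self.sequences)

    def to_fastq(self, path, mate_path=None) -> None:
        with open(path, "w") as fh:
            for name, seq, qual in zip(self.names, self.sequences, self.qualities):
                suffix = "/1" if self.paired else ""
                fh.write(f"@{name}{suffix}\n{seq}\n+\n{qual}\n")
        if self.paired and mate_path is not None:
            with open(mate_path, "w") as fh:
                for name, seq, qual in zip(self.names, self.mate_sequences,
                                           self.mate_qualities):
                    fh.write(f"@{name}/2\n{seq}\n+\n{qual}\n")


@dataclass
class GroundTruth:
    """Oracle bookkeeping for a simulated experiment.

    ``origin_counts`` rows are gene ids (scion and rootstock), columns are
    sample ids; entry = number of reads truly drawn from that transcript.
    ``abundance_table`` holds the sampling probabilities used.
    """

    mobile_gene_ids: frozenset[str]
    origin_counts: pd.DataFrame
    abundance_table: pd.DataFrame


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    scion_genes: dict[str, str]
    rootstock_genes: dict[str, str]
    ortholog_map: dict[str, str]
    samples: list[GraftSample]
    reads: dict[str, ReadSet]
    truth: GroundTruth
    gene_weights: pd.Series = field(default=None)


def generate_gene_sets(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], dict[str, str], dict[str, str]]:
    """Draw ancestor genes and diverge them into scion/rootstock orthologs.

    Each ancestor is i.i.d. uniform over {A,C,G,T}; the scion copy is the
    ancestor itself and the rootstock copy carries exactly
    ``round((1 - ortholog_identity) * length)`` point substitutions at
    distinct sites, so the realized per-site identity of every ortholog
    pair equals the target up to rounding (well within +/-2 points).

    Returns ``(scion_genes, rootstock_genes, ortholog_map)`` where the map
    sends scion gene ids to their rootstock ortholog ids.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    scion: dict[str, str] = {}
    rootstock: dict[str, str] = {}
    ortho: dict[str, str] = {}
    lo, hi = config.gene_length_range
    width = max(4, len(str(config.n_genes)))
    for g in range(config.n_genes):
        length = int(rng.integers(lo, hi + 1))
        anc = rng.choice(bases, size=length)
        n_sub = round((1.0 - config.ortholog_identity) * length)
        derived = anc.copy()
        if n_sub > 0:
            sites = rng.choice(length, size=n_sub, replace=False)
            # shift each substituted base by 1..3 positions in ACGT order:
            # guarantees a *different* base, keeping identity arithmetic exact
            shifts = rng.integers(1, 4, size=n_sub)
            idx = np.searchsorted(bases, derived[sites])
            derived[sites] = bases[(idx + shifts) % 4]
        s_id = f"SC_g{g:0{width}d}"
        r_id = f"RS_g{g:0{width}d}"
        scion[s_id] = anc.tobytes().decode("ascii")
        rootstock[r_id] = derived.tobytes().decode("ascii")
        ortho[s_id] = r_id
    return scion, rootstock, ortho


def _quality_char(error_rate: float) -> str:
    q = 40 if error_rate <= 0 else min(40, max(2, round(-10 * math.log10(error_rate))))
    return chr(q + 33)


def _draw_reads_from(
    gene_ids: list[str],
    sequences: dict[str, str],
    counts: np.ndarray,
    genome_label: str,
    sample_id: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    start_index: int,
) -> tuple[list[str], list[str], list[str], list[str] | None]:
    """Draw ``counts[g]`` reads (or fragments) from each listed gene:
    uniform start, both strands, per-base substitution errors."""
    L = config.read_length
    names: list[str] = []
    seqs: list[str] = []
    mates: list[str] | None = [] if config.paired else None
    bases = "ACGT"
    idx = start_index

    def add_errors(read: str, ne: int) -> str:
        if ne == 0:
            return read
        pos = rng.choice(L, size=ne, replace=False)
        chars = list(read)
        for p in pos:
            cur = chars[p]
            chars[p] = bases[(bases.index(cur) + rng.integers(1, 4)) % 4]
        return "".join(chars)

    for gid, c in zip(gene_ids, counts):
        if c == 0:
            continue
        gene_seq = sequences[gid]
        frag_len = min(len(gene_seq), 2 * L) if config.paired else L
        max_start = len(gene_seq) - frag_len
        starts = rng.integers(0, max_start + 1, size=c)
        strands = rng.random(c) < 0.5
        n_err = rng.binomial(L, config.error_rate, size=(c, 2))
        for s, rev, (ne1, ne2) in zip(starts, strands, n_err):
            frag = gene_seq[s : s + frag_len]
            if config.paired:
                # mate 1 reads the fragment's 5' end on the sequenced
                # strand, mate 2 the opposite end on the opposite strand
                if rev:
                    m1, m2 = _revcomp(frag)[:L], frag[:L]
                else:
                    m1, m2 = frag[:L], _revcomp(frag[-L:])
                seqs.append(add_errors(m1, ne1))
                mates.append(add_errors(m2, ne2))
            else:
                read = _revcomp(frag) if rev else frag
                seqs.append(add_errors(read, ne1))
            names.append(f"{sample_id}:r{idx:07d}|origin={genome_label}|gene={gid}")
            idx += 1
    qual = _quality_char(config.error_rate) * L
    quals = [qual] * len(seqs)
    return names, seqs, quals, mates


def simulate_reads(
    sample: GraftSample,
    config: SimulationConfig,
    scion_genes: dict[str, str],
    rootstock_genes: dict[str, str],
    mobile_gene_ids: list[str],
    gene_weights: pd.Series,
    rng: np.random.Generator,
) -> tuple[ReadSet, pd.Series]:
    """Simulate one library.

    Homograft samples draw only from scion transcripts. Heterograft samples
    draw each read from the mobile rootstock pool with probability equal to
    the tissue's mobility factor (near/stem > far/pulp), otherwise from the
    scion pool. Within each pool genes are sampled proportionally to their
    expression weight. Read names carry a reserved ``|origin=...|gene=...``
    provenance suffix for oracle use only; the classifier never reads it.

    Returns the reads plus the per-gene true origin counts for the sample.
    """
    if not scion_genes:
        raise ValueError("empty transcript set")
    n = config.reads_per_sample
    if sample.graft_type == "homo":
        n_root = 0
    else:
        m = getattr(config, f"mobility_factor_{sample.mobility_key}")
        n_root = int(rng.binomial(n, m))
    n_scion = n - n_root

    scion_ids = sorted(scion_genes)
    w_s = gene_weights.loc[scion_ids].to_numpy(dtype=float)
    scion_counts = rng.multinomial(n_scion, w_s / w_s.sum())

    mobile_ids = sorted(mobile_gene_ids)
    if n_root > 0:
        w_m = gene_weights.loc[mobile_ids].to_numpy(dtype=float)
        mobile_counts = rng.multinomial(n_root, w_m / w_m.sum())
    else:
        mobile_counts = np.zeros(len(mobile_ids), dtype=int)

    names_s, seqs_s, quals_s, mates_s = _draw_reads_from(
        scion_ids, scion_genes, scion_counts, "scion", sample.sample_id,
        config, rng, 0)
    names_r, seqs_r, quals_r, mates_r = _draw_reads_from(
        mobile_ids, rootstock_genes, mobile_counts, "rootstock",
        sample.sample_id, config, rng, len(seqs_s))

    names = names_s + names_r
    seqs = seqs_s + seqs_r
    quals = quals_s + quals_r
    # interleave origins so order carries no signal
    order = rng.permutation(len(seqs))
    if config.paired:
        mates = mates_s + mates_r
        reads = ReadSet([names[i] for i in order], [seqs[i] for i in order],
                        [quals[i] for i in order],
                        [mates[i] for i in order], [quals[i] for i in order])
    else:
        reads = ReadSet([names[i] for i in order], [seqs[i] for i in order],
                        [quals[i] for i in order])

    origin = pd.Series(0, index=scion_ids + mobile_ids, dtype=int)
    origin.loc[scion_ids] = scion_counts
    origin.loc[mobile_ids] += mobile_counts
    return reads, origin


def default_samples(config: SimulationConfig) -> list[GraftSample]:
    """The full two-graft-type x two-tissue x n-replicate design."""
    samples = []
    for graft in GRAFT_TYPES:
        for tissue in TISSUES:
            for rep in range(1, config.n_replicates + 1):
                samples.append(GraftSample(
                    sample_id=f"{graft}_{tissue}_{rep}",
                    graft_type=graft, tissue=tissue, replicate=rep))
    return samples


def simulate_experiment(
    config: SimulationConfig | None = None,
    samples: list[GraftSample] | None = None,
) -> SimulatedExperiment:
    """Generate gene sets, reads for every sample, and the ground truth.

    Deterministic under ``config.seed``: regenerating with the same config
    yields byte-identical sequences and reads.
    """
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.seed)
    scion, rootstock, ortho = generate_gene_sets(config, rng)
    rootstock_ids = sorted(rootstock)
    mobile_ids = [str(g) for g in rng.choice(rootstock_ids, size=config.n_mobile,
                                             replace=False)]
    # lognormal expression weights, one per gene id (rootstock ortholog
    # shares its scion gene's weight so mobile abundance tracks expression)
    scion_ids = sorted(scion)
    w = np.exp(rng.normal(0.0, 1.0, size=len(scion_ids)))
    weights = pd.Series(
        np.concatenate([w, w]),
        index=scion_ids + [ortho[s] for s in scion_ids], dtype=float)

    if samples is None:
        samples = default_samples(config)

    reads: dict[str, ReadSet] = {}
    origin_cols: dict[str, pd.Series] = {}
    abund_cols: dict[str, pd.Series] = {}
    all_ids = scion_ids + rootstock_ids
    for sample in samples:
        sample_rng = np.random.default_rng(
            [config.seed, zlib.crc32(sample.sample_id.encode()) % (2**31)])
        rs, origin = simulate_reads(
            sample, config, scion, rootstock, mobile_ids, weights, sample_rng)
        reads[sample.sample_id] = rs
        origin_cols[sample.sample_id] = origin.reindex(all_ids, fill_value=0)
        if sample.graft_type == "homo":
            m = 0.0
        else:
            m = getattr(config, f"mobility_factor_{sample.mobility_key}")
        p = pd.Series(0.0, index=all_ids)
        ws = weights.loc[scion_ids]
        p.loc[scion_ids] = (1 - m) * ws / ws.sum()
        if m > 0:
            wm = weights.loc[sorted(mobile_ids)]
            p.loc[sorted(mobile_ids)] = m * wm / wm.sum()
        abund_cols[sample.sample_id] = p

    truth = GroundTruth(
        mobile_gene_ids=frozenset(mobile_ids),
        origin_counts=pd.DataFrame(origin_cols),
        abundance_table=pd.DataFrame(abund_cols),
    )
    return SimulatedExperiment(
        config=config, scion_genes=scion, rootstock_genes=rootstock,
        ortholog_map=ortho, samples=samples, reads=reads, truth=truth,
        gene_weights=weights)


# ---------------------------------------------------------------------------
# metabolites

def calibrated_noise_sd(target_rho: float) -> float:
    """Noise s.d. under which the generator attains ``target_rho`` on average.

    The metabolite is built on the normal scores of the transcript ranks
    (a Gaussian copula), so a target Spearman rho_s corresponds to a
    Pearson correlation rho_p = 2 sin(pi * rho_s / 6) between the latent
    normals; mixing the signal with weight rho_p and independent noise of
    s.d. sqrt(1 - rho_p^2) realizes it.
    """
    rho_p = 2.0 * math.sin(math.pi * target_rho / 6.0)
    return math.sqrt(max(0.0, 1.0 - rho_p * rho_p))


def simulate_metabolites(
    expression: pd.DataFrame,
    couplings: list[tuple[str, str, float]],
    noise_sd: float | None = None,
    seed: int = 0,
    n_uncoupled: int = 0,
) -> pd.DataFrame:
    """Generate a metabolite x sample abundance table.

    Each coupling ``(gene_id, metabolite_id, target_rho)`` produces a
    metabolite whose profile is ``sign-matched`` to the gene's expression
    ranks: with ``noise_sd=0`` the realized Spearman correlation is exactly
    +/-1 (monotone transform), and with ``noise_sd=None`` the noise is
    calibrated per coupling so the realized rho matches the target on
    average. ``n_uncoupled`` extra metabolites are pure noise.
    """
    n_samples = expression.shape[1]
    if n_samples < 3:
        raise ValueError("at least 3 samples are required for rank correlation")
    rng = np.random.default_rng(seed)
    rows: dict[str, np.ndarray] = {}
    from scipy.stats import norm, rankdata

    for gene_id, met_id, rho in couplings:
        if abs(rho) > 1:
            raise ValueError(f"|target rho| must be <= 1 (got {rho})")
        if gene_id not in expression.index:
            raise KeyError(f"coupled gene {gene_id!r} absent from expression table")
        x = expression.loc[gene_id].to_numpy(dtype=float)
        # normal scores of the expression ranks (ties -> mean rank)
        z = norm.ppf(rankdata(x) / (n_samples + 1.0))
        rho_p = 2.0 * math.sin(math.pi * rho / 6.0)
        sd = calibrated_noise_sd(rho) if noise_sd is None else noise_sd
        y = rho_p * z + sd * rng.normal(size=n_samples)
        if noise_sd == 0:
            y = math.copysign(1.0, rho) * z  # exact monotone coupling
        rows[met_id] = y
    for j in range(n_uncoupled):
        rows[f"met_noise_{j:03d}"] = rng.normal(size=n_samples)
    return pd.DataFrame(rows, index=expression.columns).T


def simulate_count_matrix(
    n_genes: int = 200,
    n_per_group: int = 3,
    n_de: int = 0,
    fold: float = 4.0,
    mean_count: float = 50.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Poisson count matrix with optional planted fold changes.

    The first ``n_de`` genes carry a true ``fold``-times higher mean in
    group A than in group B; the rest are null. Per-gene base means are
    lognormal around ``mean_count``. Returns (counts, gene_lengths,
    de_gene_ids); columns are A_1..A_n then B_1..B_n.

    This drives operating-characteristic checks of the differential
    caller (false-positive rate under the null, sensitivity and empirical
    FDR with planted effects) without running the read-level simulator.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    base = mean_count * np.exp(rng.normal(0.0, 0.7, size=n_genes))
    mean_a = base.copy()
    mean_a[:n_de] *= fold
    cols = {}
    for r in range(1, n_per_group + 1):
        cols[f"A_{r}"] = rng.poisson(mean_a)
    for r in range(1, n_per_group + 1):
        cols[f"B_{r}"] = rng.poisson(base)
    counts = pd.DataFrame(cols, index=genes)
    lengths = pd.Series(rng.integers(300, 1501, size=n_genes), index=genes,
                        dtype=float)
    return counts, lengths, genes[:n_de]


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Convenience: a copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
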