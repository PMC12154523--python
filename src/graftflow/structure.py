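"""RNA secondary structure at desk scale.

Candidate mobile transcripts are folded under a deliberately simple
energy model — every allowed pair (AU/UA, GC/CG, GU/UG) contributes a
constant energy of ``pair_energy`` (default -1) and hairpin loops must
enclose at least ``min_hairpin`` unpaired bases — rather than a full
nearest-neighbor thermodynamic parameter set. Within that model the
module provides the complete structure toolkit: maximum-pairing folding
(Nussinov dynamic programming with deterministic traceback), the
partition function and base-pair probabilities (McCaskill-style
inside/outside recursions), per-position pairing entropy, the standard
loop decomposition (hairpin / stack / bulge / internal / multibranch /
external), and mountain-plot profiles (MFE, ensemble, centroid).

Structural *counts* from full thermodynamic folders are therefore not
comparable number-for-number; the loop taxonomy, probability and entropy
machinery are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DotBracketStructure", "LoopCensus", "PairProbabilityProfile",
    "nussinov_fold", "pair_probabilities", "decompose_loops",
    "mountain_heights", "ensemble_mountain_heights", "centroid_structure",
    "mountain_profile",
]

_PAIRABLE = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
             ("G", "U"), ("U", "G")}
DEFAULT_MIN_HAIRPIN = 3
#: sequences longer than this overflow the unscaled partition function
MAX_FOLD_LENGTH = 2000


def _normalize(sequence: str) -> str:
    """Upcase and apply the T->U convention; reject invalid characters."""
    seq = sequence.upper().replace("T", "U")
    for i, ch in enumerate(seq):
        if ch not in "ACGU":
            raise ValueError(
                f"invalid character {sequence[i]!r} at position {i}")
    if not seq:
        raise ValueError("sequence must be non-empty")
    return seq


def _pair_matrix(seq: str, min_hairpin: int) -> np.ndarray:
    n = len(seq)
    ok = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + min_hairpin + 1, n):
            if (seq[i], seq[j]) in _PAIRABLE:
                ok[i, j] = True
    return ok


def _pairs_from_dotbracket(structure: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            pairs.append((stack.pop(), i))
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r} at {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return sorted(pairs)


@dataclass(frozen=True)
class DotBracketStructure:
    """A sequence with a pseudoknot-free dot-bracket structure."""

    sequence: str
    structure: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.structure):
            raise ValueError("sequence and structure lengths differ")
        _pairs_from_dotbracket(self.structure)  # validates balance

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return _pairs_from_dotbracket(self.structure)

    def __len__(self) -> int:
        return len(self.sequence)

    def to_vienna(self, name: str = "seq") -> str:
        return f">{name}\n{self.sequence}\n{self.structure}\n"


@dataclass(frozen=True)
class LoopCensus:
    """Counts from the loop decomposition of one structure."""

    n_external: int = 0
    n_hairpin: int = 0
    n_internal: int = 0
    n_bulge: int = 0
    n_multibranch: int = 0
    n_stacks: int = 0


@dataclass
class PairProbabilityProfile:
    """Ensemble pairing probabilities of one sequence.

    ``P[i, j]`` is the probability that bases i and j are paired
    (symmetric); ``unpaired[i] = 1 - sum_j P[i, j]``; ``entropy`` is the
    per-position Shannon entropy (nats) over the pairing states
    {unpaired, paired-with-j}.
    """

    sequence: str
    P: np.ndarray
    unpaired: np.ndarray
    entropy: np.ndarray


# ---------------------------------------------------------------------------
# maximum-pairing fold

def nussinov_fold(sequence: str,
                  min_hairpin: int = DEFAULT_MIN_HAIRPIN) -> DotBracketStructure:
    """Maximum base-pairing structure by Nussinov dynamic programming.

    Maximizes the number of allowed pairs subject to the minimum hairpin
    size, in O(n^3). The traceback is deterministic: position i is left
    unpaired whenever that is optimal, otherwise paired with its smallest
    optimal partner j.
    """
    seq = _normalize(sequence)
    n = len(seq)
    ok = _pair_matrix(seq, min_hairpin)
    # M[i, j] over half-open [i, j): padded so empty intervals read 0
    M = np.zeros((n + 2, n + 2), dtype=np.int32)

    def cell(i: int, j: int) -> int:  # inclusive interval [i, j]
        return M[i + 1, j + 1] if j >= i else 0

    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            best = cell(i + 1, j)
            js = np.nonzero(ok[i, i + 1 : j + 1])[0]
            if js.size:
                js = js + i + 1
                inner = M[i + 2, js]            # cell(i+1, jp-1)
                right = M[js + 2, j + 1]        # cell(jp+1, j)
                best = max(best, int((1 + inner + right).max()))
            M[i + 1, j + 1] = best

    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        if cell(i, j) == cell(i + 1, j):  # prefer i unpaired
            stack.append((i + 1, j))
            continue
        target = cell(i, j)
        for jp in range(i + min_hairpin + 1, j + 1):
            if ok[i, jp] and 1 + cell(i + 1, jp - 1) + cell(jp + 1, j) == target:
                structure[i] = "("
                structure[jp] = ")"
                stack.append((i + 1, jp - 1))
                stack.append((jp + 1, j))
                break
    return DotBracketStructure(sequence=seq, structure="".join(structure))


# ---------------------------------------------------------------------------
# partition function and pair probabilities

def pair_probabilities(
    sequence: str,
    pair_energy: float = -1.0,
    kT: float = 1.0,
    min_hairpin: int = DEFAULT_MIN_HAIRPIN,
    max_length: int = MAX_FOLD_LENGTH,
) -> PairProbabilityProfile:
    """McCaskill-style base-pair probabilities under the constant-energy model.

    Every allowed pair carries Boltzmann weight ``w = exp(-pair_energy/kT)``;
    inside recursions accumulate the partition function over all
    pseudoknot-free structures, outside recursions convert it into
    ``P[i, j]``. Probability mass is conserved per position:
    ``unpaired[i] + sum_j P[i, j] = 1``.
    """
    seq = _normalize(sequence)
    n = len(seq)
    if n > max_length:
        raise ValueError(
            f"sequence length {n} exceeds the partition-function cap "
            f"({max_length}); fold a subsequence or rescale the energy model")
    if kT <= 0:
        raise ValueError("kT must be positive")
    w = float(np.exp(-pair_energy / kT))
    ok = _pair_matrix(seq, min_hairpin)

    # inside: Q[i, j] over inclusive [i, j] with empty == 1 (padded)
    Q = np.ones((n + 2, n + 2))
    Qb = np.zeros((n, n))

    def q(i: int, j: int) -> float:
        return Q[i + 1, j + 1] if j >= i else 1.0

    for span in range(0, n):
        for i in range(0, n - span):
            j = i + span
            if span >= 1 and ok[i, j]:
                Qb[i, j] = w * q(i + 1, j - 1)
            total = q(i, j - 1)  # j unpaired
            ks = np.nonzero(ok[i : j + 1, j])[0]
            if ks.size:
                ks = ks + i
                total += float((Q[i + 1, ks] * Qb[ks, j]).sum())  # q(i, k-1)
            Q[i + 1, j + 1] = total

    Z = q(0, n - 1)
    P = np.zeros((n, n))
    if not np.isfinite(Z):
        raise OverflowError(
            "partition function overflowed; reduce sequence length or kT")

    # outside, pairs processed by decreasing span; T accumulates the
    # enclosed-by-(p,q) contributions
    T = np.zeros((n, n))
    pair_list = [(i, j) for i in range(n) for j in range(i + 1, n) if ok[i, j]]
    pair_list.sort(key=lambda ij: ij[1] - ij[0], reverse=True)
    for p, qq in pair_list:
        if Qb[p, qq] == 0.0:
            continue
        ext = q(0, p - 1) * q(qq + 1, n - 1) / Z
        P[p, qq] = Qb[p, qq] * (ext + T[p, qq])
        if P[p, qq] <= 0.0 or qq - p < 2:
            continue
        C = P[p, qq] * w / Qb[p, qq]
        # distribute to all (i, j) strictly inside (p, qq):
        # contribution C * q(p+1, i-1) * q(j+1, qq-1)
        inner = np.arange(p + 1, qq)
        left = Q[p + 2, inner]          # q(p+1, i-1)
        right = Q[inner + 2, qq]        # q(j+1, qq-1)
        T[p + 1 : qq, p + 1 : qq] += C * np.outer(left, right)

    P = P + P.T
    paired = P.sum(axis=1)
    unpaired = np.clip(1.0 - paired, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(P > 0, np.log(P), 0.0)
        ent = -(P * logs).sum(axis=1)
        ent -= np.where(unpaired > 0, unpaired * np.log(unpaired), 0.0)
    return PairProbabilityProfile(sequence=seq, P=np.triu(P) + np.triu(P, 1).T,
                                  unpaired=unpaired,
                                  entropy=np.maximum(ent, 0.0))


# ---------------------------------------------------------------------------
# loop decomposition

def decompose_loops(structure) -> LoopCensus:
    """Standard loop decomposition of a dot-bracket structure.

    A pair enclosing no pair closes a hairpin; a pair directly enclosing
    exactly one pair closes a stack (no unpaired bases), a bulge (unpaired
    bases on one side only) or an internal loop (both sides); a pair
    directly enclosing two or more pairs closes a multibranch loop.
    Unpaired bases outside every pair form one external loop (counted once
    if any exist). Depends only on the bracket string.
    """
    if isinstance(structure, DotBracketStructure):
        s = structure.structure
    else:
        s = str(structure)
    pairs = _pairs_from_dotbracket(s)
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i

    n_hairpin = n_internal = n_bulge = n_multi = n_stack = 0
    top_level_unpaired = 0

    def children_of(i: int, j: int) -> tuple[list[tuple[int, int]], int]:
        """Direct child pairs and unpaired-base count inside (i, j)."""
        kids, unpaired, k = [], 0, i + 1
        while k < j:
            if s[k] == "(":
                kids.append((k, partner[k]))
                k = partner[k] + 1
            else:
                unpaired += 1
                k += 1
        return kids, unpaired

    # external region
    k = 0
    while k < len(s):
        if s[k] == "(":
            k = partner[k] + 1
        else:
            top_level_unpaired += 1
            k += 1

    for i, j in pairs:
        kids, unpaired = children_of(i, j)
        if not kids:
            n_hairpin += 1
        elif len(kids) == 1:
            (ci, cj) = kids[0]
            left = ci - i - 1
            right = j - cj - 1
            if left == 0 and right == 0:
                n_stack += 1
            elif left == 0 or right == 0:
                n_bulge += 1
            else:
                n_internal += 1
        else:
            n_multi += 1
    return LoopCensus(
        n_external=1 if top_level_unpaired > 0 else 0,
        n_hairpin=n_hairpin, n_internal=n_internal, n_bulge=n_bulge,
        n_multibranch=n_multi, n_stacks=n_stack)


# ---------------------------------------------------------------------------
# mountain plots

def mountain_heights(structure) -> np.ndarray:
    """m(k) = number of pairs (i, j) with i <= k < j."""
    if isinstance(structure, DotBracketStructure):
        s = structure.structure
    else:
        s = str(structure)
    pairs = _pairs_from_dotbracket(s)
    h = np.zeros(len(s))
    for i, j in pairs:
        h[i:j] += 1
    return h


def ensemble_mountain_heights(profile: PairProbabilityProfile) -> np.ndarray:
    """Expected mountain height: sum of P[i, j] over pairs spanning k."""
    n = len(profile.sequence)
    h = np.zeros(n)
    iu, ju = np.triu_indices(n, k=1)
    for i, j, p in zip(iu, ju, profile.P[iu, ju]):
        if p > 0:
            h[i:j] += p
    return h


def centroid_structure(profile: PairProbabilityProfile) -> DotBracketStructure:
    """Structure containing exactly the pairs with P[i, j] > 0.5.

    Pairs above probability one half are mutually compatible (at most one
    partner per base, no crossings), so this is always a valid structure.
    """
    n = len(profile.sequence)
    s = ["."] * n
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu, ju):
        if profile.P[i, j] > 0.5:
            s[i] = "("
            s[j] = ")"
    return DotBracketStructure(sequence=profile.sequence, structure="".join(s))


def mountain_profile(obj) -> dict[str, np.ndarray]:
    """Mountain-plot data for a structure or a probability profile.

    For a :class:`DotBracketStructure` (or bracket string) returns the MFE
    heights only; for a :class:`PairProbabilityProfile` returns the
    ensemble heights and the centroid-structure heights as well.
    """
    if isinstance(obj, PairProbabilityProfile):
        return {
            "ensemble": ensemble_mountain_heights(obj),
            "centroid": mountain_heights(centroid_structure(obj)),
        }
    return {"mfe": mountain_heights(obj)}
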