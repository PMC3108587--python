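"""Constant-size Kingman coalescent with infinite-sites mutation on L sites.

Time is measured in coalescent units (units of N generations for a haploid
locus); with k active lineages the waiting time to the next coalescence is
exponential with rate C(k,2).  Mutations fall on branches as a Poisson
process with rate theta/2 per unit branch length and are assigned to sites
uniformly without repetition while unsaturated, emulating the infinite-sites
model on a finite locus of L sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from parvapop.errors import ParameterError

#: transition target under K2P for each base; transversions pick one of the
#: two cross-class bases at random.
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
BASES = "ACGT"


@dataclass(frozen=True)
class CoalescentParams:
    """Parameters of one equilibrium coalescent sample.

    ``theta`` is the per-locus scaled mutation rate (locus length times the
    per-site theta).
    """

    n: int
    theta: float
    L: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ParameterError("sample size n must be >= 2")
        if self.theta < 0:
            raise ParameterError("theta must be >= 0")
        if self.L < 1:
            raise ParameterError("L must be >= 1")
        if self.theta > self.L:
            raise ParameterError(
                f"theta={self.theta} exceeds L={self.L}: cannot emulate infinite "
                "sites; increase L"
            )


@dataclass
class CoalescentSample:
    """Result of one simulated sample."""

    haplotype_counts: np.ndarray
    pairwise_differences: np.ndarray  # length C(n,2), |symmetric difference|
    S: int
    tmrca: float
    total_branch_length: float
    leaf_mutations: list[frozenset[int]] = field(repr=False, default_factory=list)

    @property
    def mean_pairwise_differences(self) -> float:
        return float(self.pairwise_differences.mean()) if self.pairwise_differences.size else 0.0


def simulate_genealogy(n: int, rng: np.random.Generator):
    """Draw one Kingman genealogy.

    Returns ``(segments, tmrca)`` where each segment is a
    ``(descendant leaves tuple, branch length)`` pair for one lineage from
    its birth to its coalescence (the root lineage carries no segment).
    """
    t = 0.0
    active: list[tuple[tuple[int, ...], float]] = [((i,), 0.0) for i in range(n)]
    segments: list[tuple[tuple[int, ...], float]] = []
    k = n
    while k > 1:
        t += rng.exponential(2.0 / (k * (k - 1)))
        j = int(rng.integers(k))
        i = int(rng.integers(k - 1))
        if i >= j:
            i += 1
        if i > j:
            i, j = j, i
        leaves_j, birth_j = active.pop(j)
        leaves_i, birth_i = active.pop(i)
        segments.append((leaves_i, t - birth_i))
        segments.append((leaves_j, t - birth_j))
        active.append((tuple(sorted(leaves_i + leaves_j)), t))
        k -= 1
    return segments, t


def drop_mutations(
    segments, n: int, theta: float, rng: np.random.Generator
) -> tuple[list[set[int]], int]:
    """Overlay Poisson(theta/2 per unit length) mutations on a genealogy.

    Returns per-leaf mutation-id sets and the total mutation count; each
    mutation id is a distinct (infinite-sites) site.
    """
    leaf_muts: list[set[int]] = [set() for _ in range(n)]
    if theta == 0 or not segments:
        return leaf_muts, 0
    lens = np.array([l for _, l in segments])
    total = float(lens.sum())
    M = int(rng.poisson(theta / 2.0 * total))
    if M == 0:
        return leaf_muts, 0
    seg_of = rng.choice(len(segments), size=M, p=lens / total)
    for m, s in enumerate(seg_of):
        for leaf in segments[s][0]:
            leaf_muts[leaf].add(m)
    return leaf_muts, M


def _collapse_and_diffs(leaf_muts: list[set[int]]):
    n = len(leaf_muts)
    keys = [frozenset(s) for s in leaf_muts]
    counts: dict[frozenset, int] = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    diffs = np.empty(n * (n - 1) // 2, dtype=float)
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            diffs[idx] = len(keys[i] ^ keys[j])
            idx += 1
    return np.array(list(counts.values())), diffs, keys


def simulate_coalescent_sample(
    params: CoalescentParams, rng: np.random.Generator | None = None
) -> CoalescentSample:
    """Simulate one equilibrium sample and its summary statistics."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    segments, tmrca = simulate_genealogy(params.n, rng)
    leaf_muts, M = drop_mutations(segments, params.n, params.theta, rng)
    counts, diffs, keys = _collapse_and_diffs(leaf_muts)
    return CoalescentSample(
        haplotype_counts=counts,
        pairwise_differences=diffs,
        S=M,
        tmrca=tmrca,
        total_branch_length=float(sum(l for _, l in segments)),
        leaf_mutations=[frozenset(s) for s in leaf_muts],
    )


def assign_sites(M: int, L: int, rng: np.random.Generator) -> np.ndarray:
    """Distinct 0-based site positions for M mutations on an L-site locus."""
    if M > L:
        raise ParameterError(
            f"{M} mutations exceed L={L} sites: infinite-sites saturated; increase L"
        )
    return rng.choice(L, size=M, replace=False)


def mutate_base(base: str, rng: np.random.Generator, kappa: float = 2.0) -> str:
    """Mutate one base under K2P with transition/transversion rate ratio kappa.

    ``kappa`` is the ratio of the transition rate to each of the two
    transversion rates, so a mutation is a transition with probability
    ``kappa / (kappa + 2)``.
    """
    if rng.random() < kappa / (kappa + 2.0):
        return TRANSITION[base]
    return TRANSVERSIONS[base][int(rng.integers(2))]


def sequences_from_mutations(
    leaf_muts: list[frozenset[int]] | list[set[int]],
    M: int,
    L: int,
    rng: np.random.Generator,
    kappa: float = 2.0,
    ancestral: str | None = None,
) -> tuple[list[str], str]:
    """Materialise nucleotide sequences from per-leaf mutation sets.

    Each mutation gets a distinct site and a derived base drawn under K2P.
    Returns ``(sequences, ancestral sequence)``.
    """
    if ancestral is None:
        ancestral = "".join(BASES[i] for i in rng.integers(4, size=L))
    sites = assign_sites(M, L, rng)
    derived = [mutate_base(ancestral[s], rng, kappa) for s in sites]
    seqs = []
    for muts in leaf_muts:
        chars = list(ancestral)
        for m in muts:
            chars[sites[m]] = derived[m]
        seqs.append("".join(chars))
    return seqs, ancestral
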