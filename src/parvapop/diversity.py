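"""Within-population diversity, K2P differentiation matrices and group tests.

Haplotype diversity uses Nei's bias-corrected estimator
``H = n/(n-1) * (1 - sum p_i^2)``.  Because observed sample sizes differ
across sites, diversities are additionally standardised to a common sample
size ``k`` (the smallest sample, 6) by bootstrap: draw ``k`` individuals
with replacement from the observed haplotype frequencies and average the
*uncorrected* diversity ``1 - sum p^2`` over replicates.  That expectation
has a closed form,

    E[H_k] = (1 - 1/k) * (1 - sum p_i^2) = (1 - 1/k) * H * (n-1)/n,

which the Monte-Carlo path must and does match; both are exposed.

Differentiation follows Hudson: ``FST = 1 - Hw/Hb`` with ``Hw`` the mean of
the two within-population mean pairwise K2P distances and ``Hb`` the mean
between-population K2P distance (``DXY``).  Nucleotide diversity ``pi`` uses
uncorrected p-differences (standard Nei pi); the K2P correction applies to
the distance matrices.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from parvapop.errors import (
    DegenerateAlignmentError,
    ParameterError,
    SaturationError,
    UndefinedStatisticError,
)
from parvapop.popio import HaplotypeTable, PopulationMap

DEFAULT_SEED = 20110603

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def haplotype_diversity(counts) -> float:
    """Bias-corrected haplotype diversity ``H = n/(n-1) (1 - sum p^2)``."""
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    n = c.sum()
    if n < 2:
        raise UndefinedStatisticError("haplotype diversity needs n >= 2")
    p = c / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def expected_standardized_H(H: float, n: int, k: int = 6) -> float:
    """Closed-form expectation of the size-``k`` bootstrap-standardised diversity.

    For a with-replacement subsample of size ``k`` from frequencies ``p``,
    ``E[sum phat^2] = sum p^2 + (1 - sum p^2)/k``, hence
    ``E[1 - sum phat^2] = (1 - 1/k)(1 - sum p^2)``; substituting the
    corrected ``H`` observed at size ``n`` gives
    ``(1 - 1/k) * H * (n-1)/n``.
    """
    if k < 2:
        raise ParameterError("k must be >= 2")
    if not 0.0 <= H <= 1.0:
        raise ParameterError("H must lie in [0, 1]")
    return (1.0 - 1.0 / k) * H * (n - 1) / n


def bootstrap_standardized_H(
    counts,
    k: int = 6,
    B: int = 1000,
    seed: int = DEFAULT_SEED,
) -> tuple[float, float, float]:
    """Bootstrap-standardised haplotype diversity at sample size ``k``.

    Each replicate draws ``k`` individuals with replacement from the observed
    haplotype frequencies and records the uncorrected diversity
    ``1 - sum phat^2``.  Returns ``(mean over B replicates, Monte-Carlo SE,
    closed-form expectation)``.
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    n = int(c.sum())
    if k > n:
        raise ParameterError(f"k={k} exceeds sample size n={n}: cannot standardise upward")
    if k < 2:
        raise ParameterError("k must be >= 2")
    if B < 1:
        raise ParameterError("B must be >= 1")
    p = c / n
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(k, p, size=B)  # B x nhap
    het = 1.0 - np.sum((draws / k) ** 2, axis=1)
    mean = float(het.mean())
    se = float(het.std(ddof=1) / math.sqrt(B)) if B > 1 else float("nan")
    closed = (1.0 - 1.0 / k) * (1.0 - float(np.sum(p**2)))
    return mean, se, closed


def _seq_array(seqs) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1")
    return arr.reshape(len(seqs), -1)


def nucleotide_diversity(seqs) -> float:
    """Per-site nucleotide diversity: mean pairwise p-difference / L.

    Computed per column from allele counts, which is algebraically identical
    to averaging hand-counted pairwise differences over all C(n,2) pairs.
    """
    seqs = list(seqs)
    if len(seqs) < 2:
        raise UndefinedStatisticError("nucleotide diversity needs >= 2 sequences")
    L = len(seqs[0])
    if L == 0:
        raise DegenerateAlignmentError("zero-length sequences")
    arr = _seq_array(seqs)
    n = arr.shape[0]
    npairs = n * (n - 1) / 2
    same = np.zeros(L)
    for b in (b"A", b"C", b"G", b"T", b"-", b"N"):
        c = (arr == b).sum(axis=0)
        same += c * (c - 1) / 2
    # any residual (rare ambiguity codes) handled per column
    residual = n - np.isin(arr, [b"A", b"C", b"G", b"T", b"-", b"N"]).sum(axis=0)
    cols = np.flatnonzero(residual > 0)
    for col in cols:
        _, cnt = np.unique(arr[:, col], return_counts=True)
        same[col] = np.sum(cnt * (cnt - 1) / 2)
    total = float(np.sum(npairs - same))
    return total / npairs / L


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura two-parameter distance between two equal-length sequences.

    ``d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)`` with ``P``/``Q`` the
    transition/transversion proportions over comparable (both-unambiguous)
    sites.  Raises :class:`SaturationError` when a log argument is
    non-positive.
    """
    if len(seq_a) != len(seq_b):
        raise DegenerateAlignmentError("sequences of unequal length")
    comparable = 0
    ts = 0
    tv = 0
    for a, b in zip(seq_a, seq_b):
        if a not in "ACGT" or b not in "ACGT":
            continue
        comparable += 1
        if a == b:
            continue
        if (a in PURINES) == (b in PURINES):
            ts += 1
        else:
            tv += 1
    if comparable == 0:
        raise DegenerateAlignmentError("no comparable sites")
    P = ts / comparable
    Q = tv / comparable
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"K2P undefined for P={P:.4f}, Q={Q:.4f}")
    return float(-0.5 * math.log(w1) - 0.25 * math.log(w2))


def k2p_from_proportions(P: float, Q: float) -> float:
    """K2P distance from transition/transversion proportions directly."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"K2P undefined for P={P:.4f}, Q={Q:.4f}")
    return float(-0.5 * math.log(w1) - 0.25 * math.log(w2))


@dataclass
class PairwiseMatrices:
    """Pairwise FST (floored) and K2P DXY matrices plus raw FST estimates."""

    populations: list[str]
    fst: pd.DataFrame
    dxy: pd.DataFrame
    fst_raw: pd.DataFrame

    def group_medians(self, popmap: PopulationMap, stat: str = "fst") -> dict[str, float]:
        """Median of pairwise values within and between groups.

        Keys: ``native-native``, ``invasive-invasive``, ``native-invasive``.
        """
        m = self.fst if stat == "fst" else self.dxy
        buckets: dict[str, list[float]] = {
            "native-native": [],
            "invasive-invasive": [],
            "native-invasive": [],
        }
        for a, b in itertools.combinations(self.populations, 2):
            ga, gb = popmap.group_of(a), popmap.group_of(b)
            key = f"{ga}-{gb}" if ga <= gb else f"{gb}-{ga}"
            if key == "invasive-native":
                key = "native-invasive"
            v = m.loc[a, b]
            if np.isfinite(v):
                buckets[key].append(float(v))
        return {k: (float(np.median(v)) if v else float("nan")) for k, v in buckets.items()}


def k2p_matrix(representatives, site_span: int | None = None, warn: bool = True) -> np.ndarray:
    """Pairwise K2P distances among haplotype representatives (vectorised).

    ``site_span`` is the number of comparable sites the transition and
    transversion proportions are taken over; representatives that span only
    the variable columns of a longer locus (``site_span > len(seq)``) are
    handled correctly because the omitted columns are invariant.  Saturated
    pairs become NaN.
    """
    reps = list(representatives)
    nh = len(reps)
    Lr = len(reps[0])
    if site_span is None:
        site_span = Lr
    arr = _seq_array(reps)
    purine = np.isin(arr, [b"A", b"G"])
    good = np.isin(arr, [b"A", b"C", b"G", b"T"])
    diff = (arr[:, None, :] != arr[None, :, :]) & good[:, None, :] & good[None, :, :]
    ts = (diff & (purine[:, None, :] == purine[None, :, :])).sum(axis=2)
    tv = diff.sum(axis=2) - ts
    # comparable denominator: invariant off-matrix columns are all comparable
    both_good = (good[:, None, :] & good[None, :, :]).sum(axis=2)
    comp = both_good + (site_span - Lr)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = ts / comp
        Q = tv / comp
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        dist = np.where(
            (w1 > 0) & (w2 > 0), -0.5 * np.log(np.maximum(w1, 1e-300)) - 0.25 * np.log(np.maximum(w2, 1e-300)), np.nan
        )
    np.fill_diagonal(dist, 0.0)
    if warn and np.isnan(dist).any():
        warnings.warn("saturated haplotype pairs masked in K2P matrix")
    return dist


def pairwise_matrices(
    hap: HaplotypeTable,
    popmap: PopulationMap | None = None,
    warn_saturation: bool = True,
) -> PairwiseMatrices:
    """Hudson-style FST and K2P DXY matrices over all population pairs.

    ``DXY(A,B)`` is the mean K2P distance over all between-population
    sequence pairs; ``FST = 1 - Hw/Hb`` with ``Hw`` the average of the two
    within-population mean distances and ``Hb = DXY``.  Negative raw FST
    estimates are floored at 0 in ``fst`` and preserved in ``fst_raw``.
    Saturated haplotype pairs are masked (NaN in affected cells).
    """
    pops = hap.populations
    if len(pops) < 2:
        raise ParameterError("need >= 2 populations")
    dist = k2p_matrix(hap.representatives, site_span=hap.site_span, warn=warn_saturation)
    C = hap.counts.to_numpy(dtype=float)  # nh x P
    ns = C.sum(axis=0)
    if (ns < 2).any():
        small = [p for p, n in zip(pops, ns) if n < 2]
        raise ParameterError(f"populations with n < 2: {small}")
    # mean within-population pairwise distance per population (vectorised):
    # sum_{h<g} c_h c_g d_hg = (c' D c)/2 since diag(D)=0
    P = len(pops)
    cross = C.T @ dist @ C  # P x P; entry (a,b) = sum_hg cA_h cB_g d_hg
    within = np.diag(cross) / 2.0 / (ns * (ns - 1) / 2.0)
    dxy_m = cross / np.outer(ns, ns)
    np.fill_diagonal(dxy_m, 0.0)
    hw = 0.5 * (within[:, None] + within[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = 1.0 - hw / dxy_m
    both_zero = (dxy_m == 0) & (hw == 0)
    raw = np.where(both_zero, 0.0, raw)
    floored = np.where(np.isfinite(raw), np.maximum(raw, 0.0), raw)
    np.fill_diagonal(raw, 0.0)
    np.fill_diagonal(floored, 0.0)
    return PairwiseMatrices(
        populations=pops,
        fst=pd.DataFrame(floored, index=pops, columns=pops),
        dxy=pd.DataFrame(dxy_m, index=pops, columns=pops),
        fst_raw=pd.DataFrame(raw, index=pops, columns=pops),
    )


@dataclass(frozen=True)
class ThetaEstimate:
    """Moment estimators of theta with effective-size conversion."""

    theta_pi: float
    theta_w: float
    mu: float
    c: float
    ne_pi: float
    ne_w: float


def harmonic_number(m: int) -> float:
    """``a_m = sum_{i=1}^{m} 1/i`` (Watterson's denominator uses a_{n-1})."""
    return float(sum(1.0 / i for i in range(1, m + 1)))


def segregating_sites(seqs) -> int:
    arr = _seq_array(list(seqs))
    return int(((arr != arr[0]).any(axis=0)).sum())


def theta_and_ne(seqs, mu: float, c: float = 2.0) -> ThetaEstimate:
    """Per-site Watterson and pi theta estimates plus ``Ne = theta/(c mu)``.

    The default conversion constant ``c = 2`` treats the locus as maternally
    inherited and haploid (``theta = 2 N_f mu``).  ``mu`` is the per-site
    per-generation mutation rate; the conventional mtDNA clock of 1% per
    million years (divergence) at one generation per year corresponds to
    ``mu = 0.5e-8`` per lineage.
    """
    seqs = list(seqs)
    if len(seqs) < 2:
        raise UndefinedStatisticError("theta needs n >= 2")
    if mu <= 0:
        raise ParameterError("mu must be positive")
    n = len(seqs)
    L = len(seqs[0])
    S = segregating_sites(seqs)
    theta_w = S / (harmonic_number(n - 1) * L)
    theta_pi = nucleotide_diversity(seqs)
    return ThetaEstimate(
        theta_pi=theta_pi,
        theta_w=theta_w,
        mu=mu,
        c=c,
        ne_pi=theta_pi / (c * mu),
        ne_w=theta_w / (c * mu),
    )


def group_compare(values_native, values_invasive, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test between native and invasive values.

    Exact null distribution for combined n <= 20 without ties, normal
    approximation with tie correction otherwise (scipy's ``method='auto'``
    implements exactly this switch).
    """
    x = np.asarray(list(values_native), dtype=float)
    y = np.asarray(list(values_invasive), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ParameterError("each group needs >= 2 values")
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return float(len(x) * len(y) / 2), 1.0
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="auto")
    return float(res.statistic), float(res.pvalue)


def diversity_table(
    hap: HaplotypeTable,
    popmap: PopulationMap,
    k: int = 6,
    B: int = 1000,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Per-population diversity summary (Nh, H, bootstrap H_k, pi).

    Populations carrying a flagged (putatively introgressed) haplotype get
    ``excluded_from_pi = True``; their pi is still reported but group
    comparisons downstream honour the flag.
    """
    rows = []
    flagged_idx = {hap.hap_ids.index(h) for h in hap.flagged}
    for j, pop in enumerate(hap.populations):
        col = hap.counts[pop].to_numpy()
        counts = col[col > 0]
        n = int(counts.sum())
        nh = int((col > 0).sum())
        H = haplotype_diversity(counts) if n >= 2 else 0.0
        if n >= k:
            hk, _, _ = bootstrap_standardized_H(counts, k=k, B=B, seed=seed + j)
        else:
            hk = float("nan")
        seqs = []
        for i, c in enumerate(col):
            seqs.extend([hap.representatives[i]] * int(c))
        pi = nucleotide_diversity(seqs) * len(hap.retained_columns) / hap.site_span if n >= 2 else 0.0
        carries_flagged = any(col[i] > 0 for i in flagged_idx)
        rows.append(
            {
                "population": pop,
                "group": popmap.group_of(pop),
                "n": n,
                "Nh": nh,
                "H": H,
                f"H{k}": hk,
                "pi": pi,
                "excluded_from_pi": carries_flagged,
            }
        )
    return pd.DataFrame(rows).set_index("population")
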