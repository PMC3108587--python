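"""Mutation-drift-equilibrium envelope of nucleotide vs haplotype diversity.

A population at equilibrium under constant size traces a characteristic
relationship between haplotype diversity (H) and per-site nucleotide
diversity (pi): both rise with theta = 2*N*mu.  A population assembled by
recent admixture of diverged lineages carries *excess* pi for its H, because
between-lineage differences inflate pairwise distances without adding many
haplotypes.  The envelope is built by simulating equilibrium samples over a
theta grid and recording mean H, mean pi and the empirical 5-95% pi band;
observed populations are then classified above/within/below the band at
their observed H by linear interpolation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from parvapop.coalescent import CoalescentParams, simulate_coalescent_sample
from parvapop.diversity import haplotype_diversity
from parvapop.errors import ParameterError

# 21 log-spaced theta values from 0.01 to 30 per locus, with an exact
# theta = 0 anchor so monomorphic populations interpolate rather than fall
# off the H axis.
DEFAULT_THETA_GRID = np.concatenate([[0.0], np.logspace(np.log10(0.01), np.log10(30.0), 21)])


def build_envelope(
    theta_grid=None,
    n: int = 15,
    reps: int = 1000,
    L: int = 700,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the equilibrium H-pi envelope over a grid of theta values.

    Returns a DataFrame with columns ``theta, mean_H, mean_pi, q05, q95``
    (pi per site), sorted by theta.  Per-replicate H uses the bias-corrected
    estimator so the envelope lives on the same H axis as observed tables.
    """
    if theta_grid is None:
        theta_grid = DEFAULT_THETA_GRID
    theta_grid = np.asarray(theta_grid, dtype=float)
    if np.any(np.diff(theta_grid) < 0):
        raise ParameterError("theta_grid must be sorted ascending")
    if reps < 100:
        warnings.warn("reps < 100: envelope quantiles will be unstable")
    rng = np.random.default_rng(seed)
    rows = []
    all_H = []
    all_pi = []
    for theta in theta_grid:
        params = CoalescentParams(n=n, theta=float(theta), L=L)
        H = np.empty(reps)
        pi = np.empty(reps)
        for r in range(reps):
            s = simulate_coalescent_sample(params, rng)
            H[r] = haplotype_diversity(s.haplotype_counts)
            pi[r] = s.mean_pairwise_differences / L
        all_H.append(H)
        all_pi.append(pi)
        rows.append(
            {
                "theta": float(theta),
                "mean_H": float(H.mean()),
                "mean_pi": float(pi.mean()),
                "q05": float(np.quantile(pi, 0.05)),
                "q95": float(np.quantile(pi, 0.95)),
            }
        )
    env = pd.DataFrame(rows)
    # per-replicate draws retained for conditional-band classification
    env.attrs["draws"] = np.column_stack([np.concatenate(all_H), np.concatenate(all_pi)])
    return env


def _monotone_on_H(env: pd.DataFrame) -> pd.DataFrame:
    """Reparameterise the envelope on mean H for interpolation.

    Ties/inversions in mean H across theta (Monte-Carlo noise at the flat
    ends of the curve) are resolved by averaging band values at identical H
    after sorting, giving a strictly increasing H axis.
    """
    env = env.sort_values("mean_H").reset_index(drop=True)
    env = env.groupby("mean_H", as_index=False)[["mean_pi", "q05", "q95"]].mean()
    return env


def _conditional_band(draws: np.ndarray, h_obs: float, k: int = 300):
    """5-95% band of pi conditional on realised H near ``h_obs``.

    Uses the ``k`` replicate draws closest in H, pooled across the theta
    grid: the band an *observation* should be compared with, because a
    single sample's H fluctuates around the mean-H axis the envelope curve
    is drawn on.
    """
    k = min(k, len(draws))
    idx = np.argsort(np.abs(draws[:, 0] - h_obs), kind="stable")[:k]
    pi = draws[idx, 1]
    return float(np.quantile(pi, 0.05)), float(np.quantile(pi, 0.95))


def classify_excess_pi(records: pd.DataFrame, envelope: pd.DataFrame) -> pd.DataFrame:
    """Classify observed (H, pi) points against the equilibrium band.

    ``records`` needs columns ``H`` and ``pi`` indexed by population (the
    output of :func:`parvapop.diversity.diversity_table`); populations whose
    ``excluded_from_pi`` flag is set are dropped before classification.
    Returns per-population band bounds at the observed H and a verdict in
    ``{above, within, below, NA}``; ``NA`` marks points outside the H range
    spanned by the envelope (extrapolation refused).

    When the envelope carries its per-replicate draws (as produced by
    :func:`build_envelope`), the band is the conditional 5-95% interval of
    pi given realised H (nearest-neighbour pooling over the draws), which is
    calibrated for classifying single observed populations; otherwise the
    per-theta marginal quantile curves are linearly interpolated on mean H.
    """
    df = records.copy()
    if "excluded_from_pi" in df.columns:
        df = df[~df["excluded_from_pi"].astype(bool)]
    draws = envelope.attrs.get("draws") if hasattr(envelope, "attrs") else None
    mono = _monotone_on_H(envelope)
    h_axis = mono["mean_H"].to_numpy()
    h_max = float(draws[:, 0].max()) if draws is not None else float(h_axis.max())
    h_min = float(draws[:, 0].min()) if draws is not None else float(h_axis.min())
    out = []
    for pop, row in df.iterrows():
        h_obs = float(row["H"])
        pi_obs = float(row["pi"])
        if h_obs < h_min - 1e-9 or h_obs > h_max + 1e-9:
            out.append(
                {
                    "population": pop,
                    "H_obs": h_obs,
                    "pi_obs": pi_obs,
                    "q05": float("nan"),
                    "q95": float("nan"),
                    "verdict": "NA",
                }
            )
            continue
        if draws is not None:
            q05, q95 = _conditional_band(draws, h_obs)
        else:
            q05 = float(np.interp(h_obs, h_axis, mono["q05"].to_numpy()))
            q95 = float(np.interp(h_obs, h_axis, mono["q95"].to_numpy()))
        if pi_obs > q95:
            verdict = "above"
        elif pi_obs < q05:
            verdict = "below"
        else:
            verdict = "within"
        out.append(
            {
                "population": pop,
                "H_obs": h_obs,
                "pi_obs": pi_obs,
                "q05": q05,
                "q95": q95,
                "verdict": verdict,
            }
        )
    return pd.DataFrame(out).set_index("population")
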