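"""End-to-end orchestration: config validation, staged execution, reports.

Stages run in a fixed order (io -> diversity -> matrices -> network/tree ->
envelope -> spatial -> optional ABC); each stage draws its seed from the
global seed by a fixed offset, so any stage can be rerun in isolation and
reproduce its output byte-for-byte.  Outputs are plain TSV/JSON files under
the configured output directory.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from parvapop import __version__
from parvapop.diversity import diversity_table, group_compare, pairwise_matrices
from parvapop.envelope import build_envelope, classify_excess_pi, DEFAULT_THETA_GRID
from parvapop.errors import InputError, ParameterError
from parvapop.network import SiteWeightScheme, bootstrap_support, build_mj_network
from parvapop.popio import (
    collapse_haplotypes,
    read_alignment,
    read_popmap,
    screen_divergent_haplotypes,
    write_haplotype_table,
)
from parvapop.scenarios import (
    abc_model_choice,
    abc_parameter_estimate,
    build_reference_table,
    default_scenarios,
    prior_bounds,
    summary_stats_extended,
)
from parvapop.popio import table_from_records
from parvapop.spatial import classical_mds, geo_distance_matrix, ibd_regressions, mantel_test

# fixed per-stage seed offsets fanned out from the global seed
STAGE_SEEDS = {
    "diversity": 101,
    "network": 202,
    "envelope": 303,
    "spatial": 404,
    "abc": 505,
}

_KNOWN_KEYS = {
    "fasta", "popmap", "outdir", "seed", "k", "bootstrap_reps",
    "envelope_reps", "envelope_L", "theta_grid", "mantel_permutations",
    "source_pop", "exclude", "homoplastic_sites", "network_exclude",
    "screen_fold_threshold", "nj_bootstrap", "abc",
}
_KNOWN_ABC_KEYS = {"enabled", "nsims", "tolerance", "pools", "L", "sample_override"}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    fasta: str
    popmap: str
    outdir: str = "results/run"
    seed: int = 20110603
    k: int = 6
    bootstrap_reps: int = 1000
    envelope_reps: int = 300
    envelope_L: int = 700
    theta_grid: list | None = None
    mantel_permutations: int = 1000
    source_pop: str | None = None
    exclude: list = field(default_factory=list)
    homoplastic_sites: list = field(default_factory=list)
    network_exclude: list = field(default_factory=list)
    screen_fold_threshold: float = 5.0
    nj_bootstrap: int = 200
    abc: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        abc = raw.get("abc") or {}
        bad = set(abc) - _KNOWN_ABC_KEYS
        if bad:
            raise InputError(f"unknown abc config keys: {sorted(bad)}")
        for req in ("fasta", "popmap"):
            if req not in raw:
                raise InputError(f"config missing required key {req!r}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    def stage(name):
        t0 = time.perf_counter()

        def done(**info):
            report["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3), **info}

        return done

    # ------------------------------------------------------------------ io
    done = stage("io")
    aln = read_alignment(config.fasta)
    popmap = read_popmap(config.popmap)
    hap = collapse_haplotypes(aln, popmap)
    sizes = {p: hap.sample_size(p) for p in hap.populations}
    offenders = [p for p, n in sizes.items() if n < config.k]
    if offenders:
        raise ParameterError(
            f"standard sample size k={config.k} exceeds sample size of "
            f"populations {offenders}"
        )
    flagged = screen_divergent_haplotypes(hap, config.screen_fold_threshold)
    write_haplotype_table(hap, out / "haplotype_counts.tsv", out / "haplotypes.fasta")
    done(n_sequences=len(aln), n_haplotypes=len(hap.hap_ids), flagged=sorted(flagged))

    # ----------------------------------------------------------- diversity
    done = stage("diversity")
    records = diversity_table(
        hap, popmap, k=config.k, B=config.bootstrap_reps,
        seed=config.seed + STAGE_SEEDS["diversity"],
    )
    records.to_csv(out / "diversity.tsv", sep="\t")
    ok = ~records["excluded_from_pi"].astype(bool)
    nat = records[(records["group"] == "native") & ok]
    inv = records[(records["group"] == "invasive") & ok]
    tests = {}
    if len(nat) >= 2 and len(inv) >= 2:
        for col in ("H", "pi"):
            U, p = group_compare(nat[col], inv[col])
            tests[col] = {"U": U, "p": p}
    done(**{"group_tests": tests})

    # ------------------------------------------------------------ matrices
    done = stage("matrices")
    mats = pairwise_matrices(hap, popmap)
    mats.fst.to_csv(out / "fst.tsv", sep="\t")
    mats.dxy.to_csv(out / "dxy.tsv", sep="\t")
    medians_fst = mats.group_medians(popmap, "fst")
    medians_dxy = mats.group_medians(popmap, "dxy")
    json.dump(
        {"fst": medians_fst, "dxy": medians_dxy},
        open(out / "group_medians.json", "w"), indent=2,
    )
    done(fst_medians=medians_fst)

    # -------------------------------------------------------- network/tree
    done = stage("network")
    scheme = SiteWeightScheme(homoplastic_sites=frozenset(int(s) for s in config.homoplastic_sites))
    exclusions = set(config.network_exclude) | flagged
    net = build_mj_network(hap, scheme, exclusions=exclusions)
    import networkx as nx

    g_out = net.graph.copy()
    for _u, _v, data in g_out.edges(data=True):
        data["sites"] = ",".join(map(str, data["sites"]))  # GraphML-safe
    nx.write_graphml(g_out, out / "mj_network.graphml")
    tree_info = {}
    if len(hap.hap_ids) >= 3:
        rep_aln = _haplotype_alignment(hap)
        tree = bootstrap_support(
            rep_aln, B=config.nj_bootstrap, seed=config.seed + STAGE_SEEDS["network"]
        )
        (out / "nj_tree.nwk").write_text(tree.newick() + "\n")
        tree_info = {"n_bipartitions": len(tree.supports)}
    done(n_network_nodes=net.graph.number_of_nodes(), **tree_info)

    # ------------------------------------------------------------ envelope
    done = stage("envelope")
    env = build_envelope(
        theta_grid=config.theta_grid if config.theta_grid is not None else DEFAULT_THETA_GRID,
        n=int(np.median(list(sizes.values()))),
        reps=config.envelope_reps,
        L=config.envelope_L,
        seed=config.seed + STAGE_SEEDS["envelope"],
    )
    env.to_csv(out / "envelope.tsv", sep="\t", index=False)
    calls = classify_excess_pi(records, env)
    calls.to_csv(out / "excess_pi_calls.tsv", sep="\t")
    above = calls[calls["verdict"] == "above"]
    grp = records.loc[calls.index, "group"]
    done(
        n_above=int(len(above)),
        invasive_above=int((grp.loc[above.index] == "invasive").sum()),
    )

    # ------------------------------------------------------------- spatial
    done = stage("spatial")
    spatial_info: dict = {}
    inv_pops = [p for p in hap.populations if popmap.group_of(p) == "invasive"]
    mds = classical_mds(mats.fst.fillna(0.0))
    mds["pi"] = records.loc[mds.index, "pi"]
    mds.to_csv(out / "mds.tsv", sep="\t")
    if len(inv_pops) >= 4:
        geo = geo_distance_matrix(popmap, inv_pops)
        fst_inv = mats.fst.loc[inv_pops, inv_pops]
        mantel_all = mantel_test(
            fst_inv, geo, nperm=config.mantel_permutations,
            seed=config.seed + STAGE_SEEDS["spatial"],
        )
        spatial_info["mantel_all"] = asdict(mantel_all)
        keep = [p for p in inv_pops if p not in set(config.exclude)]
        if len(keep) >= 4 and keep != inv_pops:
            mantel_core = mantel_test(
                mats.fst.loc[keep, keep], geo.loc[keep, keep],
                nperm=config.mantel_permutations,
                seed=config.seed + STAGE_SEEDS["spatial"] + 1,
            )
            spatial_info["mantel_excluding"] = asdict(mantel_core)
        source = config.source_pop or inv_pops[0]
        regs = ibd_regressions(source, mats.fst, records, geo_distance_matrix(popmap), exclude=config.exclude)
        spatial_info["regressions"] = [asdict(r) for r in regs]
    json.dump(spatial_info, open(out / "spatial.json", "w"), indent=2, default=float)
    done(**{k: v for k, v in spatial_info.items() if k.startswith("mantel")})

    # ----------------------------------------------------------------- abc
    if config.abc.get("enabled"):
        done = stage("abc")
        pools = config.abc.get("pools")
        if not pools:
            raise InputError("abc.enabled requires abc.pools (deme -> population list)")
        obs_table = _pooled_table(hap, pools)
        observed = summary_stats_extended(obs_table)
        sample_sizes = {d: obs_table.sample_size(d) for d in obs_table.populations}
        nsims = int(config.abc.get("nsims", 2000))
        L = int(config.abc.get("L", 700))
        refs = [
            build_reference_table(
                spec, sample_sizes, nsims, L=L,
                seed=config.seed + STAGE_SEEDS["abc"] + i,
            )
            for i, spec in enumerate(default_scenarios())
        ]
        result = abc_model_choice(
            observed, refs, tolerance=float(config.abc.get("tolerance", 0.01)),
            seed=config.seed + STAGE_SEEDS["abc"],
        )
        result.direct.to_csv(out / "abc_direct.tsv", sep="\t")
        result.logistic.to_csv(out / "abc_logistic.tsv", sep="\t")
        best = result.best_logistic
        best_spec = default_scenarios()[result.scenario_names.index(best)]
        post = abc_parameter_estimate(
            refs[result.scenario_names.index(best)], observed,
            tolerance=float(config.abc.get("tolerance", 0.01)),
            min_accepted=min(200, max(nsims // 10, 20)),
            bounds=prior_bounds(best_spec),
        )
        post.to_csv(out / "abc_posterior.tsv", sep="\t")
        done(best_scenario=best, t1_median=float(post.loc["t1", "median"]) if "t1" in post.index else None)

    # -------------------------------------------------------------- report
    medians = report["stages"]["matrices"]["fst_medians"]
    report["findings"] = {
        "invasive_fst_median": medians.get("invasive-invasive"),
        "native_fst_median": medians.get("native-native"),
        "invasive_differentiation_lower": (
            medians.get("invasive-invasive", np.nan) < medians.get("native-native", np.nan)
        ),
        "invasive_populations_above_envelope": report["stages"]["envelope"]["invasive_above"],
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _haplotype_alignment(hap):
    from parvapop.popio import AlignedSequenceSet

    return AlignedSequenceSet(ids=tuple(hap.hap_ids), seqs=tuple(hap.representatives))


def _pooled_table(hap, pools: dict):
    """Re-pool a haplotype table's populations into ABC demes."""
    ids, seqs, pops = [], [], []
    i = 0
    for deme, members in pools.items():
        for pop in members:
            if pop not in hap.populations:
                raise InputError(f"abc pool member {pop!r} not a population")
            for rep, c in hap.population_profile(pop):
                for _ in range(c):
                    ids.append(f"s{i}")
                    seqs.append(rep)
                    pops.append(deme)
                    i += 1
    return table_from_records(ids, seqs, pops, site_span=hap.site_span)
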