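"""Ground-truth synthetic datasets mimicking the invasion study's structure.

The generator emulates the features the analysis keys on: two or three
deeply diverged mtDNA lineages (peripheral cores 6-7 mutations from the
central core), low within-lineage equilibrium diversity, one native
contact-zone population pooling two lineages, invasive populations founded
under three contrasting spread models (multiple source-sink, stepping-stone,
long-distance from an admixed pool), optional bottlenecked satellite
populations, and an optional introgressed outlier haplotype from a diverged
donor species.  Every dataset ships with a truth manifest recording the
generating process and the qualitative verdicts the pipeline is expected to
recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from parvapop.coalescent import (
    drop_mutations,
    mutate_base,
    simulate_genealogy,
)
from parvapop.diversity import k2p_distance
from parvapop.errors import InputError, ParameterError
from parvapop.popio import (
    AlignedSequenceSet,
    PopulationMap,
    write_alignment,
    write_popmap,
)

BASES = "ACGT"

#: invasive scenario names
SCENARIOS = ("multiple_source_sink", "stepping_stone", "long_distance")


@dataclass
class SyntheticDataset:
    """Alignment + population map + truth manifest."""

    alignment: AlignedSequenceSet
    popmap: PopulationMap
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_alignment(self.alignment, outdir / "alignment.fasta")
        write_popmap(self.popmap, outdir / "popmap.tsv")
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def _random_sequence(L: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(4, size=L))


def _equilibrium_sample(
    core: str,
    theta: float,
    n: int,
    rng: np.random.Generator,
    reserved: set[int],
    kappa: float = 2.0,
) -> list[str]:
    """Sample n sequences from a single-lineage equilibrium coalescent.

    Coalescent mutations land on sites outside ``reserved`` (the lineage
    diagnostic positions), so lineage cores stay recognisable.
    """
    L = len(core)
    segments, _ = simulate_genealogy(n, rng) if n >= 2 else ([], 0.0)
    leaf_muts, M = drop_mutations(segments, n, theta, rng) if n >= 2 else ([set()], 0)
    available = np.array(sorted(set(range(L)) - reserved))
    if M > len(available):
        raise ParameterError("site budget insufficient for requested diversity")
    sites = rng.choice(available, size=M, replace=False) if M else np.array([], dtype=int)
    derived = [mutate_base(core[s], rng, kappa) for s in sites]
    out = []
    for muts in leaf_muts[:n]:
        chars = list(core)
        for m in muts:
            chars[sites[m]] = derived[m]
        out.append("".join(chars))
    return out


def generate_native_range(
    n_lineages: int = 3,
    divergence_mutations=(6, 7),
    theta_within: float = 1.0,
    contact_theta: float | None = None,
    L: int = 700,
    n_per_pop: int = 15,
    n_pops: int = 4,
    contact_zone: bool = True,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate the native range: diverged lineages + one contact zone.

    Lineage cores: the central lineage (index 2 in field terms) is the
    ancestral sequence; peripheral lineages sit ``divergence_mutations[i]``
    substitutions away at disjoint diagnostic sites.  Native populations
    cycle over lineages; the last one (when ``contact_zone``) pools the
    first two lineages 50:50, mirroring a secondary-contact population.
    """
    if n_lineages < 1:
        raise ParameterError("need >= 1 lineage")
    if len(divergence_mutations) < n_lineages - 1:
        raise ParameterError("need a divergence count per peripheral lineage")
    if any(d < 1 for d in divergence_mutations[: n_lineages - 1]):
        raise ParameterError("divergence_mutations must be >= 1")
    rng = np.random.default_rng(seed)
    ancestral = _random_sequence(L, rng)
    total_div = sum(divergence_mutations[: n_lineages - 1])
    if total_div > L // 4:
        raise ParameterError("site budget insufficient for lineage divergence")
    div_sites = rng.choice(L, size=total_div, replace=False)
    reserved = set(int(s) for s in div_sites)
    cores = [ancestral]  # lineage index 0 = central
    pos = 0
    core_sites: list[list[int]] = [[]]
    for li in range(n_lineages - 1):
        m = divergence_mutations[li]
        sites = div_sites[pos : pos + m]
        pos += m
        chars = list(ancestral)
        for s in sites:
            chars[s] = mutate_base(ancestral[s], rng)
        cores.append("".join(chars))
        core_sites.append([int(s) + 1 for s in sites])

    ids: list[str] = []
    seqs: list[str] = []
    rows = []
    lineage_of: dict[str, object] = {}
    n_plain = n_pops - 1 if (contact_zone and n_lineages >= 2) else n_pops
    for p in range(n_plain):
        name = f"NA{p + 1}"
        lin = p % n_lineages
        sample = _equilibrium_sample(cores[lin], theta_within, n_per_pop, rng, reserved)
        lat = float(rng.uniform(20, 45))
        lon = float(rng.uniform(100, 130))
        for i, s in enumerate(sample):
            ids.append(f"{name}_{i:02d}")
            seqs.append(s)
            rows.append({"id": ids[-1], "population": name, "group": "native", "lat": lat, "lon": lon})
        lineage_of[name] = lin
    if contact_zone and n_lineages >= 2:
        name = f"NA{n_pops}"
        half = n_per_pop // 2
        ct = theta_within if contact_theta is None else contact_theta
        sample = _equilibrium_sample(cores[0], ct, half, rng, reserved)
        sample += _equilibrium_sample(cores[1], ct, n_per_pop - half, rng, reserved)
        lat, lon = float(rng.uniform(35, 42)), float(rng.uniform(112, 120))
        for i, s in enumerate(sample):
            ids.append(f"{name}_{i:02d}")
            seqs.append(s)
            rows.append({"id": ids[-1], "population": name, "group": "native", "lat": lat, "lon": lon})
        lineage_of[name] = "contact(0,1)"
    aln = AlignedSequenceSet(ids=tuple(ids), seqs=tuple(seqs))
    popmap = PopulationMap(table=pd.DataFrame(rows).set_index("id"))
    manifest = {
        "kind": "native_range",
        "seed": seed,
        "L": L,
        "n_lineages": n_lineages,
        "divergence_mutations": list(divergence_mutations[: n_lineages - 1]),
        "theta_within": theta_within,
        "lineage_of": lineage_of,
        "core_divergence_sites_1based": core_sites,
        "cores": cores,
        "expected": {"contact_zone_pi_max": bool(contact_zone and n_lineages >= 2)},
    }
    return SyntheticDataset(alignment=aln, popmap=popmap, manifest=manifest)


def sample_admixed_population(
    native: SyntheticDataset,
    lineage_pair: tuple[int, int] = (1, 2),
    theta_within: float | None = None,
    n: int = 15,
    seed: int = 0,
) -> list[str]:
    """Draw one 50:50 admixed population pooling two lineages' demes.

    The half-samples come from independent equilibrium coalescents seeded on
    the two lineage cores, so between-lineage core differences dominate the
    sample's pairwise distances whenever the lineages' divergence exceeds
    the within-deme diversity — the construction behind the excess-pi
    admixture signature.
    """
    man = native.manifest
    rng = np.random.default_rng(seed)
    cores = man["cores"]
    reserved = {int(s) - 1 for sites in man["core_divergence_sites_1based"] for s in sites}
    tw = float(man["theta_within"]) if theta_within is None else theta_within
    half = n // 2
    out = _equilibrium_sample(cores[lineage_pair[0]], tw, half, rng, reserved)
    out += _equilibrium_sample(cores[lineage_pair[1]], tw, n - half, rng, reserved)
    return out


def _founder_resample(
    pool: list[str], n_out: int, founder_n: int, rng: np.random.Generator
) -> list[str]:
    """Serial-founder draw: pick founders without replacement, then expand
    the sample by drawing from the founders with replacement."""
    founder_n = min(founder_n, len(pool))
    founders = [pool[i] for i in rng.choice(len(pool), size=founder_n, replace=False)]
    return [founders[i] for i in rng.integers(founder_n, size=n_out)]


def generate_invasion(
    native: SyntheticDataset,
    scenario: str,
    n_invasive: int = 6,
    n_per_pop: int = 15,
    bottleneck: bool = True,
    n_satellites: int = 2,
    founder_n: int = 10,
    stepping_founder_n: int = 4,
    seed: int = 1,
) -> SyntheticDataset:
    """Extend a native dataset with invasive populations under one spread model.

    ``multiple_source_sink``: each invasive population is an independent
    equilibrium sample from a different native lineage (no admixture, high
    invasive-invasive differentiation, no IBD).  ``stepping_stone``: a chain
    of serial founder events starting from a 50:50 admixed pool, with
    coordinates along a line so differentiation grows with distance (IBD).
    ``long_distance``: every population independently founded from the one
    admixed pool at random coordinates (low differentiation, no IBD, excess
    pi).  With ``bottleneck``, the last ``n_satellites`` populations are
    refounded from 1-2 individuals (the recently-introduced satellite
    signature: 1-2 haplotypes, very low H).
    """
    if scenario not in SCENARIOS:
        raise InputError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    man = native.manifest
    rng = np.random.default_rng(seed)
    cores: list[str] = man["cores"]
    L = man["L"]
    theta = float(man["theta_within"])
    reserved = {int(s) - 1 for sites in man["core_divergence_sites_1based"] for s in sites}

    # Admixed source pool: fresh equilibrium samples from the two lineages
    # that contributed to the invasion, pooled 50:50.
    pool = _equilibrium_sample(cores[0], theta, 30, rng, reserved)
    if len(cores) >= 2:
        pool += _equilibrium_sample(cores[1], theta, 30, rng, reserved)

    ids = list(native.alignment.ids)
    seqs = list(native.alignment.seqs)
    rows = native.popmap.table.reset_index(names="id").to_dict("records")
    sources: dict[str, object] = {}
    satellites: list[str] = []
    prev_sample: list[str] | None = None
    for p in range(n_invasive):
        name = f"INV{p + 1}"
        if scenario == "multiple_source_sink":
            lin = p % len(cores)
            sample = _equilibrium_sample(cores[lin], theta, n_per_pop, rng, reserved)
            lat = float(rng.uniform(40, 55))
            lon = float(rng.uniform(-5, 25))
            sources[name] = f"lineage{lin}"
        elif scenario == "stepping_stone":
            if prev_sample is None:
                sample = [pool[i] for i in rng.choice(len(pool), size=n_per_pop, replace=False)]
                sources[name] = "admixed_pool"
            else:
                sample = _founder_resample(prev_sample, n_per_pop, stepping_founder_n, rng)
                sources[name] = f"INV{p}"
            lat = 48.0
            lon = 5.0 + 4.0 * p
            prev_sample = sample
        else:  # long_distance
            sample = _founder_resample(pool, n_per_pop, founder_n, rng)
            sources[name] = "admixed_pool"
            lat = float(rng.uniform(40, 55))
            lon = float(rng.uniform(-5, 25))
        for i, s in enumerate(sample):
            ids.append(f"{name}_{i:02d}")
            seqs.append(s)
            rows.append({"id": ids[-1], "population": name, "group": "invasive", "lat": lat, "lon": lon})

    if bottleneck and n_satellites > 0:
        # satellites refound the *last* continental populations from 1-2 fish
        donor = [s for s, r in zip(seqs, rows) if r["population"] == f"INV{n_invasive}"]
        for q in range(n_satellites):
            name = f"SAT{q + 1}"
            satellites.append(name)
            nf = 1 + (q % 2)
            sample = _founder_resample(donor, n_per_pop, nf, rng)
            lat = float(rng.uniform(51, 55))
            lon = float(rng.uniform(-5, 0))
            for i, s in enumerate(sample):
                ids.append(f"{name}_{i:02d}")
                seqs.append(s)
                rows.append({"id": ids[-1], "population": name, "group": "invasive", "lat": lat, "lon": lon})
            sources[name] = f"INV{n_invasive}"

    aln = AlignedSequenceSet(ids=tuple(ids), seqs=tuple(seqs))
    popmap = PopulationMap(table=pd.DataFrame(rows).set_index("id"))
    manifest = dict(man)
    manifest.update(
        {
            "kind": "invasion",
            "invasion_seed": seed,
            "scenario": scenario,
            "sources": sources,
            "satellites": satellites,
            "expected": {
                "ibd": scenario == "stepping_stone",
                "ibd_after_satellite_exclusion": scenario == "stepping_stone",
                "excess_pi_invasive": scenario == "long_distance",
                "invasive_fst_comparable_to_native": scenario == "multiple_source_sink",
                "satellite_low_diversity": bool(satellites),
            },
        }
    )
    return SyntheticDataset(alignment=aln, popmap=popmap, manifest=manifest)


def inject_introgressed_haplotype(
    dataset: SyntheticDataset,
    donor_divergence: float = 0.05,
    target_pop: str | None = None,
    seed: int = 2,
) -> SyntheticDataset:
    """Replace one individual by a haplotype from a diverged donor lineage.

    The donor sequence is built by mutating the dataset consensus until its
    K2P distance reaches approximately ``donor_divergence`` — emulating a
    mitochondrion introgressed from a related species riding in a
    misidentified individual.
    """
    if donor_divergence < 0:
        raise ParameterError("donor_divergence must be >= 0")
    rng = np.random.default_rng(seed)
    aln = dataset.alignment
    pops = dataset.popmap.populations
    if target_pop is None:
        target_pop = pops[-1]
    if target_pop not in pops:
        raise InputError(f"unknown target population {target_pop!r}")
    L = aln.L
    arr = np.array([list(s) for s in aln.seqs])
    consensus = "".join(
        max("ACGT", key=lambda b: int((arr[:, c] == b).sum())) for c in range(L)
    )
    donor = consensus
    if donor_divergence > 0.6:
        raise ParameterError("donor_divergence saturates the K2P correction")
    if donor_divergence > 0:
        chars = list(consensus)
        order = rng.permutation(L)
        k = 0
        while k2p_distance(consensus, "".join(chars)) < donor_divergence:
            if k >= L // 2:
                raise ParameterError("donor_divergence saturates the K2P correction")
            s = int(order[k])
            chars[s] = mutate_base(chars[s], rng)
            k += 1
        donor = "".join(chars)
    target_ids = dataset.popmap.ids_of(target_pop)
    victim = target_ids[-1]
    seqs = [donor if i == victim else s for i, s in zip(aln.ids, aln.seqs)]
    new_aln = AlignedSequenceSet(ids=aln.ids, seqs=tuple(seqs))
    manifest = dict(dataset.manifest)
    manifest["introgression"] = {
        "target_population": target_pop,
        "individual": victim,
        "donor_divergence": donor_divergence,
        "realised_k2p": k2p_distance(consensus, donor) if donor_divergence > 0 else 0.0,
        "seed": seed,
    }
    return SyntheticDataset(alignment=new_aln, popmap=dataset.popmap, manifest=manifest)
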