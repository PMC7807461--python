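"""Ground-truth synthetic communities for the four rumen kingdoms.

The generator emulates a cross-sectional lifetime sampling design: animals
in fourteen age groups from 7 days to 12 years, profiled for bacteria,
archaea, anaerobic fungi and ciliate protozoa, with kingdom-specific
detection onsets (bacteria from 7 d, archaea from 14 d, fungi and protozoa
from 1 month).

Counts arise from a latent-Gaussian copula: each taxon's log-abundance is

    baseline_i + effect_i * (s(age) - 1/2) + sigma * z_i,

where ``s(age) = (min(ln age, ln M) - ln a_min) / (ln M - ln a_min)`` is a
saturating log-age trajectory with true maturation age ``M`` (so planted
age-discriminatory taxa stop changing at M), and ``z`` carries correlation
blocks (shared Gaussian factors) with optional bridging hub taxa and
cross-kingdom links.  Latent log-abundances pass through a softmax and a
Dirichlet-multinomial draw at a lognormal per-sample depth, so the count
tables show realistic compositionality and overdispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import random as _pyrandom

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from rumenage.tables import (
    AGE_GROUP_DAYS,
    AGE_GROUPS,
    DEFAULT_RAREFACTION_DEPTHS,
    FeatureTable,
    SampleMetadata,
    TaxonomyMap,
)

__all__ = [
    "DiscriminatoryTaxon",
    "CorrelationBlock",
    "HubSpec",
    "CrossKingdomLink",
    "KingdomSpec",
    "CommunitySpec",
    "GroundTruth",
    "SimulationResult",
    "default_community_spec",
    "network_benchmark_spec",
    "simulate_community",
    "simulate_tree",
    "expected_recovery_report",
]

#: Table-style per-kingdom sample counts by age group (uneven by design).
DEFAULT_GROUP_SIZES: dict[str, dict[str, int]] = {
    "bacteria": dict(zip(AGE_GROUPS, (5, 5, 6, 5, 6, 7, 6, 5, 6, 5, 6, 6, 6, 6))),
    "archaea": dict(zip(AGE_GROUPS[1:], (5, 5, 5, 6, 7, 6, 5, 6, 6, 6, 6, 6, 6))),
    "fungi": dict(zip(AGE_GROUPS[2:], (5, 5, 5, 6, 5, 5, 6, 6, 5, 6, 5, 6))),
    "protozoa": dict(zip(AGE_GROUPS[2:], (6, 5, 6, 7, 6, 5, 6, 6, 6, 6, 6, 6))),
}

DEFAULT_ONSETS: dict[str, int] = {
    "bacteria": 7, "archaea": 14, "fungi": 30, "protozoa": 30,
}


@dataclass(frozen=True)
class DiscriminatoryTaxon:
    """A planted age-discriminatory taxon with a saturating trajectory.

    The taxon's latent log-abundance follows the community trajectory
    s(age) clipped to its own window [start_days, end_days]: it changes
    only while age is inside the window and is constant outside, emulating
    early, intermediate and late colonisers.  Windows must close at or
    before the community maturation age so every planted taxon is constant
    beyond it.  ``None`` bounds default to the kingdom onset and the
    maturation age.
    """

    taxon_id: str
    effect: float  # log-abundance change across the window
    start_days: float | None = None
    end_days: float | None = None


@dataclass(frozen=True)
class CorrelationBlock:
    """Taxa sharing a latent Gaussian factor (exchangeable correlation)."""

    members: tuple[str, ...]
    latent_rho: float = 0.8


@dataclass(frozen=True)
class HubSpec:
    """A taxon loading on several block factors, bridging their cliques."""

    taxon_id: str
    block_indices: tuple[int, ...]
    loading: float = 0.7


@dataclass(frozen=True)
class CrossKingdomLink:
    """A planted latent correlation between taxa of two kingdoms."""

    kingdom_a: str
    taxon_a: str
    kingdom_b: str
    taxon_b: str
    latent_rho: float = 0.8


@dataclass
class KingdomSpec:
    n_taxa: int
    onset_days: int
    depth_median: float
    depth_sigma: float = 0.4
    baseline_sigma: float = 1.2
    noise_sigma: float = 0.7
    discriminatory: tuple[DiscriminatoryTaxon, ...] = ()
    blocks: tuple[CorrelationBlock, ...] = ()
    hubs: tuple[HubSpec, ...] = ()

    def taxon_ids(self, kingdom: str) -> list[str]:
        return [f"{kingdom[:3]}_t{i:03d}" for i in range(self.n_taxa)]


@dataclass
class CommunitySpec:
    """Full study design: kingdoms, group sizes, planted signal, seed."""

    kingdoms: dict[str, KingdomSpec]
    group_sizes: dict[str, dict[str, int]]
    maturation_age_days: float = 1825.0
    overdispersion_conc: float = 300.0  # Dirichlet concentration x proportions
    cross_kingdom_links: tuple[CrossKingdomLink, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        for kd, ks in self.kingdoms.items():
            if kd not in self.group_sizes:
                raise ValueError(f"no group sizes for kingdom {kd!r}")
            if ks.onset_days not in AGE_GROUP_DAYS.values():
                raise ValueError(f"onset {ks.onset_days} not on the sampled age grid")
            ids = set(ks.taxon_ids(kd))
            for d in ks.discriminatory:
                if d.taxon_id not in ids:
                    raise ValueError(f"unknown discriminatory taxon {d.taxon_id!r}")
                if not np.isfinite(d.effect):
                    raise ValueError("effect sizes must be finite")
                if d.end_days is not None and d.end_days > self.maturation_age_days:
                    raise ValueError(
                        f"trajectory window of {d.taxon_id!r} extends past the "
                        "maturation age")
            seen: set[str] = set()
            for b in ks.blocks:
                if not (0 <= b.latent_rho < 1):
                    raise ValueError("block latent_rho must be in [0, 1)")
                for m in b.members:
                    if m not in ids:
                        raise ValueError(f"unknown block member {m!r}")
                    if m in seen:
                        raise ValueError(f"blocks overlap at taxon {m!r}")
                    seen.add(m)
            for h in ks.hubs:
                if h.taxon_id not in ids or h.taxon_id in seen:
                    raise ValueError(f"bad hub taxon {h.taxon_id!r}")
                if any(bi >= len(ks.blocks) for bi in h.block_indices):
                    raise ValueError("hub references a missing block")
                if len(h.block_indices) * h.loading**2 >= 1.0:
                    raise ValueError("hub loadings exceed unit variance")
        for link in self.cross_kingdom_links:
            for kd, t in ((link.kingdom_a, link.taxon_a), (link.kingdom_b, link.taxon_b)):
                if kd not in self.kingdoms:
                    raise ValueError(f"cross-kingdom link names unknown kingdom {kd!r}")
                if t not in self.kingdoms[kd].taxon_ids(kd):
                    raise ValueError(f"cross-kingdom link names unknown taxon {t!r}")


@dataclass
class GroundTruth:
    """What was planted: discriminatory taxa, edges, hubs, maturation age."""

    run_id: str
    discriminatory: dict[str, set[str]]
    maturation_age_days: float
    planted_edges: dict[str, set[frozenset]]
    hubs: dict[str, set[str]]
    cross_kingdom_edges: set[frozenset]
    trajectories: dict[str, pd.DataFrame]  # kingdom -> taxa x ages expected relabund


@dataclass
class SimulationResult:
    tables: dict[str, FeatureTable]
    metadata: SampleMetadata
    taxonomy: TaxonomyMap
    truth: GroundTruth


def default_community_spec(seed: int = 0) -> CommunitySpec:
    """The default lifetime-study conditions.

    Four kingdoms with table-style uneven group sizes, three planted
    age-discriminatory taxa per kingdom, two correlation blocks with a
    bridging hub in bacteria, one block per minor kingdom, one planted
    bacteria-archaea cross-kingdom pair, and a true maturation age of
    1825 days (5 years).  Depths are lognormal around ~1.4x each
    kingdom's rarefaction depth so the rarefaction stage drops some
    samples.
    """

    def disc(kd: str, onset: int, effects):
        # early, intermediate and late colonisation windows: dropping any
        # planted taxon leaves part of the age range unresolved
        windows = ((onset, 180), (90, 730), (365, 1825))
        return tuple(
            DiscriminatoryTaxon(f"{kd[:3]}_t{i:03d}", e, start_days=float(max(w[0], onset)),
                                end_days=float(w[1]))
            for i, (e, w) in enumerate(zip(effects, windows))
        )

    kingdoms = {
        "bacteria": KingdomSpec(
            n_taxa=30, onset_days=7,
            depth_median=1.4 * DEFAULT_RAREFACTION_DEPTHS["bacteria"],
            discriminatory=disc("bacteria", 7, (3.0, -3.0, 3.0)),
            blocks=(
                CorrelationBlock(tuple(f"bac_t{i:03d}" for i in range(5, 11))),
                CorrelationBlock(tuple(f"bac_t{i:03d}" for i in range(11, 17))),
            ),
            hubs=(HubSpec("bac_t020", (0, 1)),),
        ),
        "archaea": KingdomSpec(
            n_taxa=16, onset_days=14,
            depth_median=1.4 * DEFAULT_RAREFACTION_DEPTHS["archaea"],
            discriminatory=disc("archaea", 14, (2.5, -2.5, 2.5)),
            blocks=(CorrelationBlock(tuple(f"arc_t{i:03d}" for i in range(5, 9))),),
        ),
        "fungi": KingdomSpec(
            n_taxa=20, onset_days=30,
            depth_median=1.4 * DEFAULT_RAREFACTION_DEPTHS["fungi"],
            discriminatory=disc("fungi", 30, (2.5, -2.5, 2.5)),
            blocks=(CorrelationBlock(tuple(f"fun_t{i:03d}" for i in range(5, 9))),),
        ),
        "protozoa": KingdomSpec(
            n_taxa=16, onset_days=30,
            depth_median=1.4 * DEFAULT_RAREFACTION_DEPTHS["protozoa"],
            discriminatory=disc("protozoa", 30, (2.5, -2.5, 2.5)),
            blocks=(CorrelationBlock(tuple(f"pro_t{i:03d}" for i in range(5, 9))),),
        ),
    }
    return CommunitySpec(
        kingdoms=kingdoms,
        group_sizes={k: dict(v) for k, v in DEFAULT_GROUP_SIZES.items()},
        maturation_age_days=1825.0,
        cross_kingdom_links=(
            CrossKingdomLink("bacteria", "bac_t021", "archaea", "arc_t010"),
        ),
        seed=seed,
    )


def network_benchmark_spec(seed: int = 0, n_samples: int = 80) -> CommunitySpec:
    """Single-kingdom planted-block design for network benchmarking.

    One kingdom, no age effects, two six-taxon blocks with latent rho 0.8,
    one hub bridging both blocks, and independent noise taxa; ``n_samples``
    samples spread evenly over the age groups.  The blocks are kept to a
    minority of the community (closure correlations from a dominant guild
    would otherwise contaminate every pair) and overdispersion is moderate
    so the planted rank correlations remain measurable at the default
    sequencing depth.
    """
    ks = KingdomSpec(
        n_taxa=80, onset_days=7,
        depth_median=1.4 * DEFAULT_RAREFACTION_DEPTHS["bacteria"],
        blocks=(
            CorrelationBlock(tuple(f"bac_t{i:03d}" for i in range(0, 6))),
            CorrelationBlock(tuple(f"bac_t{i:03d}" for i in range(6, 12))),
        ),
        hubs=(HubSpec("bac_t012", (0, 1)),),
    )
    base, extra = divmod(n_samples, len(AGE_GROUPS))
    sizes = {g: base + (1 if i < extra else 0) for i, g in enumerate(AGE_GROUPS)}
    return CommunitySpec(
        kingdoms={"bacteria": ks},
        group_sizes={"bacteria": sizes},
        maturation_age_days=1825.0,
        overdispersion_conc=1200.0,
        seed=seed,
    )


def _s_of_age(age_days: np.ndarray, end: float, start: float) -> np.ndarray:
    """Saturating log-age ramp: 0 before ``start``, 1 from ``end`` onward."""
    num = np.minimum(np.log(age_days), np.log(end)) - np.log(start)
    den = np.log(end) - np.log(start)
    if den <= 0:
        return np.zeros_like(np.asarray(age_days, dtype=float))
    return np.clip(num / den, 0.0, 1.0)


def _latent_noise(ks: KingdomSpec, taxa: list[str], n: int,
                  rng: np.random.Generator,
                  shared: dict[str, np.ndarray]) -> np.ndarray:
    """Block/hub/cross-link structured standard-normal noise, one row per sample."""
    idx = {t: j for j, t in enumerate(taxa)}
    z = rng.standard_normal((n, len(taxa)))
    factors = [rng.standard_normal(n) for _ in ks.blocks]
    for b, f in zip(ks.blocks, factors):
        r = np.sqrt(b.latent_rho)
        for m in b.members:
            z[:, idx[m]] = r * f + np.sqrt(1 - b.latent_rho) * z[:, idx[m]]
    for h in ks.hubs:
        resid = 1.0 - len(h.block_indices) * h.loading**2
        col = sum(h.loading * factors[bi] for bi in h.block_indices)
        z[:, idx[h.taxon_id]] = col + np.sqrt(resid) * z[:, idx[h.taxon_id]]
    for t, f in shared.items():
        if t in idx:
            # cross-kingdom shared factor, rho via matched loadings
            rho = f["rho"]
            z[:, idx[t]] = np.sqrt(rho) * f["factor"] + np.sqrt(1 - rho) * z[:, idx[t]]
    return z


def simulate_community(spec: CommunitySpec) -> SimulationResult:
    """Draw count tables, metadata, taxonomy and ground truth from a spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    # global design: one physical sample per animal x age group
    max_n = {g: max(spec.group_sizes[kd].get(g, 0) for kd in spec.kingdoms)
             for g in AGE_GROUPS}
    sample_ids, rows = {}, []
    for g in AGE_GROUPS:
        for i in range(max_n[g]):
            sid, aid = f"S_{g}_{i+1}", f"Y_{g}_{i+1}"
            sample_ids[(g, i)] = sid
            rows.append({"sample_id": sid, "animal_id": aid, "age_group": g,
                         "age_days": AGE_GROUP_DAYS[g]})
    metadata = SampleMetadata(pd.DataFrame(rows))

    # cross-kingdom shared factors are drawn on the full design and sliced
    shared_factors: dict[str, dict[str, dict]] = {kd: {} for kd in spec.kingdoms}
    full_index = [sample_ids[(g, i)] for g in AGE_GROUPS for i in range(max_n[g])]
    for link in spec.cross_kingdom_links:
        f = pd.Series(rng.standard_normal(len(full_index)), index=full_index)
        shared_factors[link.kingdom_a][link.taxon_a] = {"factor": f, "rho": link.latent_rho}
        shared_factors[link.kingdom_b][link.taxon_b] = {"factor": f, "rho": link.latent_rho}

    tables: dict[str, FeatureTable] = {}
    lineages: dict[str, list[str]] = {}
    trajectories: dict[str, pd.DataFrame] = {}
    for kd, ks in spec.kingdoms.items():
        taxa = ks.taxon_ids(kd)
        for t in taxa:
            lineages[t] = [kd.capitalize(), f"p_{kd[:3]}", f"c_{kd[:3]}",
                           f"o_{kd[:3]}", f"f_{kd[:3]}", f"g_{t}", f"s_{t}"]
        ids = [sample_ids[(g, i)]
               for g in AGE_GROUPS
               for i in range(spec.group_sizes[kd].get(g, 0))
               if AGE_GROUP_DAYS[g] >= ks.onset_days]
        ages = metadata.ages_for(ids).to_numpy()
        n = len(ids)
        baseline = rng.normal(0.0, ks.baseline_sigma, len(taxa))
        # correlated-structure taxa (block members, hubs, cross-kingdom
        # links) get moderately abundant baselines: a planted correlation
        # among rare taxa would drown in count noise and test nothing
        structural = {m for b in ks.blocks for m in b.members}
        structural |= {h.taxon_id for h in ks.hubs}
        structural |= set(shared_factors[kd])
        for j, t in enumerate(taxa):
            if t in structural:
                baseline[j] = rng.normal(0.6, 0.3)
        effects = np.zeros(len(taxa))
        for d in ks.discriminatory:
            effects[taxa.index(d.taxon_id)] = d.effect
        a_min = min(AGE_GROUP_DAYS[g] for g in AGE_GROUPS
                    if AGE_GROUP_DAYS[g] >= ks.onset_days)
        s_cols = np.zeros((n, len(taxa)))
        for d in ks.discriminatory:
            j = taxa.index(d.taxon_id)
            start = d.start_days if d.start_days is not None else a_min
            end = d.end_days if d.end_days is not None else spec.maturation_age_days
            s_cols[:, j] = _s_of_age(ages, end, start) - 0.5
        shared = {t: {"factor": d["factor"].loc[ids].to_numpy(), "rho": d["rho"]}
                  for t, d in shared_factors[kd].items()}
        z = _latent_noise(ks, taxa, n, rng, shared)
        mu = baseline[None, :] + s_cols * effects[None, :] + ks.noise_sigma * z
        props = np.exp(mu - mu.max(axis=1, keepdims=True))
        props /= props.sum(axis=1, keepdims=True)
        depths = np.maximum(
            1, np.round(np.exp(rng.normal(np.log(ks.depth_median), ks.depth_sigma, n)))
        ).astype(int)
        counts = np.zeros((n, len(taxa)), dtype=np.int64)
        for i in range(n):
            q = rng.dirichlet(np.maximum(props[i] * spec.overdispersion_conc, 1e-8))
            counts[i] = rng.multinomial(depths[i], q)
        # guard: Dirichlet-multinomial can zero a sample only at tiny depth
        empty = counts.sum(axis=1) == 0
        for i in np.flatnonzero(empty):
            counts[i, int(np.argmax(props[i]))] = 1
        tables[kd] = FeatureTable(pd.DataFrame(counts, index=ids, columns=taxa), kd)

        grid = np.array(sorted({AGE_GROUP_DAYS[g] for g in AGE_GROUPS
                                if AGE_GROUP_DAYS[g] >= ks.onset_days}), dtype=float)
        sg_cols = np.zeros((len(grid), len(taxa)))
        for d in ks.discriminatory:
            j = taxa.index(d.taxon_id)
            start = d.start_days if d.start_days is not None else a_min
            end = d.end_days if d.end_days is not None else spec.maturation_age_days
            sg_cols[:, j] = _s_of_age(grid, end, start) - 0.5
        mu_grid = baseline[None, :] + sg_cols * effects[None, :]
        pg = np.exp(mu_grid - mu_grid.max(axis=1, keepdims=True))
        pg /= pg.sum(axis=1, keepdims=True)
        trajectories[kd] = pd.DataFrame(pg.T, index=taxa, columns=grid.astype(int))

    planted_edges: dict[str, set[frozenset]] = {}
    hubs: dict[str, set[str]] = {}
    for kd, ks in spec.kingdoms.items():
        edges: set[frozenset] = set()
        for b in ks.blocks:
            edges |= {frozenset((a, c)) for i, a in enumerate(b.members)
                      for c in b.members[i + 1:]}
        for h in ks.hubs:
            for bi in h.block_indices:
                edges |= {frozenset((h.taxon_id, m)) for m in ks.blocks[bi].members}
        planted_edges[kd] = edges
        hubs[kd] = {h.taxon_id for h in ks.hubs}
    cross = {frozenset((f"{l.kingdom_a}:{l.taxon_a}", f"{l.kingdom_b}:{l.taxon_b}"))
             for l in spec.cross_kingdom_links}

    truth = GroundTruth(
        run_id=f"sim-{spec.seed}",
        discriminatory={kd: {d.taxon_id for d in ks.discriminatory}
                        for kd, ks in spec.kingdoms.items()},
        maturation_age_days=spec.maturation_age_days,
        planted_edges=planted_edges,
        hubs=hubs,
        cross_kingdom_edges=cross,
        trajectories=trajectories,
    )
    return SimulationResult(tables, metadata, TaxonomyMap(lineages), truth)


def simulate_tree(tip_ids, seed: int = 0) -> str:
    """Random rooted coalescent tree over the tips, returned as newick."""
    tip_ids = list(tip_ids)
    if len(tip_ids) < 2:
        raise ValueError("need at least 2 tips")
    if len(set(tip_ids)) != len(tip_ids):
        raise ValueError("duplicate tip ids")
    tns = dendropy.TaxonNamespace(tip_ids)
    tree = treesim.pure_kingman_tree(taxon_namespace=tns, pop_size=1.0,
                                     rng=_pyrandom.Random(seed))
    for leaf in tree.leaf_node_iter():
        leaf.taxon.label = str(leaf.taxon.label)
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def _set_metrics(found: set, truth: set) -> dict[str, float]:
    tp = len(found & truth)
    precision = tp / len(found) if found else 0.0
    recall = tp / len(truth) if truth else 1.0
    return {"precision": precision, "recall": recall,
            "n_found": len(found), "n_true": len(truth)}


def expected_recovery_report(
    truth: GroundTruth,
    selected_taxa: dict[str, set[str]] | None = None,
    network_edges: dict[str, set[frozenset]] | None = None,
    hub_rankings: dict[str, list[str]] | None = None,
    estimated_maturation_days: float | None = None,
    run_id: str | None = None,
) -> dict:
    """Precision/recall of pipeline outputs against the planted truth."""
    if run_id is not None and run_id != truth.run_id:
        raise ValueError(f"run id mismatch: outputs {run_id!r} vs truth {truth.run_id!r}")
    report: dict = {}
    if selected_taxa is not None:
        report["discriminatory"] = {
            kd: _set_metrics(found, truth.discriminatory.get(kd, set()))
            for kd, found in selected_taxa.items()
        }
    if network_edges is not None:
        report["edges"] = {
            kd: _set_metrics(found, truth.planted_edges.get(kd, set()))
            for kd, found in network_edges.items()
        }
    if hub_rankings is not None:
        report["hubs"] = {
            kd: {"hub_in_top_k": bool(truth.hubs.get(kd, set()) & set(ranking))}
            for kd, ranking in hub_rankings.items()
        }
    if estimated_maturation_days is not None:
        grid = sorted(AGE_GROUP_DAYS.values())
        true_i = int(np.argmin([abs(a - truth.maturation_age_days) for a in grid]))
        est_i = int(np.argmin([abs(a - estimated_maturation_days) for a in grid]))
        report["maturation"] = {
            "estimated_days": float(estimated_maturation_days),
            "true_days": float(truth.maturation_age_days),
            "grid_point_error": abs(est_i - true_i),
        }
    return report
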