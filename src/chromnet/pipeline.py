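"""One-config orchestration of the full analysis workflow.

Stages run in dependency order: network construction at each FDR
threshold, maximal-clique profiling, Louvain community detection with
the small-community filter, subcommunity repartitioning, G(n, m) null
calibration, cross-threshold recapitulation, and feature enrichment.
Every output file is recorded in a run manifest with its SHA-256
checksum, so a rerun with identical config and seeds can be verified to
reproduce identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cliques import enumerate_maximal_cliques, max_clique_size_per_node, signal_by_clique_size
from .community import filter_small, louvain, repartition_communities
from .features import enrichment_table, label_by_overlap, mean_signal
from .io import (
    FragmentSet,
    read_features,
    read_fragments,
    read_interactions,
    read_signal,
    write_clique_table,
    write_edgelist,
    write_partition,
)
from .network import build_network, network_stats
from .nullmodels import modularity_zscore, recapitulation

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Flat configuration for one pipeline run.

    ``fdr_thresholds`` must be sorted descending (lenient first); the
    first threshold defines the primary network, and when a second,
    stricter one is present the recapitulation stage runs on the pair.
    """

    fragments: str
    interactions: str
    outdir: str
    cls: str = "inter"
    fdr_thresholds: tuple[float, ...] = (0.01, 0.0001)
    seed: int = 1
    min_community_size: int = 10
    null_replicates: int = 1000
    features: dict = field(default_factory=dict)   # name -> BED path
    signals: dict = field(default_factory=dict)    # name -> bedGraph path
    factor_features: tuple[str, ...] = ()          # BH-corrected family

    def __post_init__(self):
        if list(self.fdr_thresholds) != sorted(self.fdr_thresholds, reverse=True):
            raise ValueError("fdr_thresholds must be sorted descending (lenient first)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        if "fdr_thresholds" in raw:
            raw["fdr_thresholds"] = tuple(float(t) for t in raw["fdr_thresholds"])
        if "factor_features" in raw:
            raw["factor_features"] = tuple(raw["factor_features"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return (and write) the run manifest.

    Any stage failure raises :class:`PipelineError` naming the stage;
    outputs of completed stages are left in place.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "params": {
            "cls": config.cls,
            "fdr_thresholds": list(config.fdr_thresholds),
            "seed": config.seed,
            "min_community_size": config.min_community_size,
            "null_replicates": config.null_replicates,
        },
        "stages": {},
    }

    def record(stage: str, outputs: list[Path], **info) -> None:
        manifest["stages"][stage] = {
            "outputs": {str(p): _sha256(p) for p in outputs},
            **info,
        }

    state: dict = {}

    def stage(name):
        def wrap(fn):
            try:
                logger.info("stage %s", name)
                fn()
            except Exception as exc:  # noqa: BLE001 - abort names the stage
                raise PipelineError(name, exc) from exc
        return wrap

    @stage("build")
    def _build():
        fragments = read_fragments(config.fragments)
        records = read_interactions(config.interactions, fragments)
        networks = {}
        outputs, counts = [], {}
        for thr in config.fdr_thresholds:
            net = build_network(records, fragments, cls=config.cls, fdr_threshold=thr)
            networks[thr] = net
            out = outdir / f"network_fdr{thr:g}.tsv"
            write_edgelist(sorted(net.edges), out)
            outputs.append(out)
            stats = network_stats(net)
            counts[f"{thr:g}"] = {"nodes": stats["n_nodes"], "edges": stats["n_edges"]}
            logger.info("%s network at FDR<=%g: %d nodes, %d edges",
                        config.cls, thr, stats["n_nodes"], stats["n_edges"])
        state.update(fragments=fragments, networks=networks)
        record("build", outputs, counts=counts)

    @stage("cliques")
    def _cliques():
        net = state["networks"][config.fdr_thresholds[0]]
        profile = max_clique_size_per_node(enumerate_maximal_cliques(net))
        state["profile"] = profile
        out = outdir / "cliques.tsv"
        write_clique_table(profile.sizes, out)
        sccs = {}
        for name, path in config.signals.items():
            values = mean_signal(state["fragments"], read_signal(path, name=name))
            trend = signal_by_clique_size(profile, values)
            sccs[name] = trend.scc
        record("cliques", [out], max_clique_size=profile.max_size, signal_scc=sccs)

    @stage("communities")
    def _communities():
        net = state["networks"][config.fdr_thresholds[0]]
        part = louvain(net, seed=config.seed)
        filtered = filter_small(part.final, config.min_community_size)
        state.update(partition=part, filtered=filtered)
        out = outdir / "partition.tsv"
        write_partition(part.levels, out)
        record(
            "communities", [out],
            n_levels=part.n_levels,
            modularity=part.modularities[-1],
            retained_communities=len(filtered.communities),
            unassigned_nodes=len(filtered.unassigned),
        )

    @stage("subcommunities")
    def _subcommunities():
        net = state["networks"][config.fdr_thresholds[0]]
        subparts = repartition_communities(net, state["filtered"], seed=config.seed)
        out = outdir / "subcommunities.tsv"
        with open(out, "w") as handle:
            handle.write("fragment\tparent_community\tsubcommunity\n")
            for parent, part in subparts.items():
                for node in sorted(part.final):
                    handle.write(f"{node}\t{parent}\t{part.final[node]}\n")
        record(
            "subcommunities", [out],
            subcommunity_counts={
                str(parent): len(set(part.final.values()))
                for parent, part in subparts.items()
            },
        )

    @stage("nullmodel")
    def _nullmodel():
        net = state["networks"][config.fdr_thresholds[0]]
        result = modularity_zscore(
            net, n_replicates=config.null_replicates, seed=config.seed
        )
        out = outdir / "null_modularity.json"
        with open(out, "w") as handle:
            json.dump(
                {
                    "observed_q": result.observed_q,
                    "null_mean": result.null_mean,
                    "null_sd": result.null_sd,
                    "z": result.z,
                    "empirical_p": result.empirical_p,
                    "n_replicates": len(result.null_qs),
                },
                handle, indent=2,
            )
        record("nullmodel", [out], z=result.z, empirical_p=result.empirical_p)

    @stage("recapitulation")
    def _recap():
        if len(config.fdr_thresholds) < 2:
            record("recapitulation", [], skipped="single threshold configured")
            return
        strict_net = state["networks"][config.fdr_thresholds[1]]
        strict_part = louvain(strict_net, seed=config.seed)
        strict_f = filter_small(strict_part.final, config.min_community_size)
        lenient_f = state["filtered"]
        strict_assign = {u: c for c, nodes in strict_f.communities.items() for u in nodes}
        lenient_assign = {u: c for c, nodes in lenient_f.communities.items() for u in nodes}
        result = recapitulation(strict_assign, lenient_assign)
        out = outdir / "recapitulation.json"
        with open(out, "w") as handle:
            json.dump(
                {
                    "mean_recap": result.mean_recap,
                    "per_community": {str(k): v for k, v in result.per_community.items()},
                    "n_dropped": result.n_dropped,
                },
                handle, indent=2,
            )
        record("recapitulation", [out], mean_recap=result.mean_recap)

    @stage("enrichment")
    def _enrich():
        out = outdir / "enrichment.tsv"
        fragments = state["fragments"]
        net = state["networks"][config.fdr_thresholds[0]]
        universe_set = FragmentSet(f for f in fragments if f.id in net.nodes)
        feature_labels = {
            name: label_by_overlap(universe_set, read_features(path, name=name))
            for name, path in config.features.items()
        }
        membership_by_community = {
            c: {f.id: f.id in nodes for f in universe_set}
            for c, nodes in state["filtered"].communities.items()
        }
        results = enrichment_table(
            membership_by_community, feature_labels, fdr_families=config.factor_features
        )
        with open(out, "w") as handle:
            handle.write("community\tfeature\ta\tb\tc\td\todds_ratio\tp\tq\n")
            for r in results:
                q = "NA" if r.fdr is None else f"{r.fdr:.6g}"
                handle.write(
                    f"{r.community}\t{r.feature}\t{r.counts[0]}\t{r.counts[1]}\t"
                    f"{r.counts[2]}\t{r.counts[3]}\t{r.odds_ratio:.6g}\t{r.p:.6g}\t{q}\n"
                )
        n_sig = sum(1 for r in results if r.p < 0.05)
        record("enrichment", [out], n_tests=len(results), n_nominal_p_lt_0_05=n_sig)

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    logger.info("wrote manifest %s", manifest_path)
    return manifest
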