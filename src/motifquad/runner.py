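"""End-to-end motif-detection driver.

One run is: load and preprocess the network, census the original
network with an unfrozen class registry, freeze the registry, census
``r`` degree-preserving randomizations through the same (still
growing) quaternary tree, and score every original-network class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .graph import Graph, load_edge_list
from .canonical import ClassRegistry
from .esu import Census, census
from .quattree import QuatTree
from .randomize import SwapConfig, generate_ensemble
from .significance import MotifReport, z_scores

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one motif-detection run needs."""

    input_path: Optional[Union[str, Path]] = None
    graph: Optional[Graph] = None  # alternative to input_path
    directed: bool = True
    k: int = 3
    n_random: int = 100
    swap: SwapConfig = field(default_factory=SwapConfig)
    output_path: Optional[Union[str, Path]] = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("motif size k must be at least 2")
        if self.n_random < 0:
            raise ValueError("random-network count must be nonnegative")
        if (self.input_path is None) == (self.graph is None):
            raise ValueError("provide exactly one of input_path or graph")


@dataclass
class RunSummary:
    """Aggregate bookkeeping of one run."""

    n_vertices: int
    n_edges: int
    k: int
    total_subgraphs: int
    n_classes: int
    canonical_calls: int
    quaternary_leaves: int
    random_excluded: list[int]
    random_new_leaves: list[int]

    def format(self) -> str:
        lines = [
            f"vertices:            {self.n_vertices}",
            f"edges:               {self.n_edges}",
            f"motif size k:        {self.k}",
            f"subgraphs (original): {self.total_subgraphs}",
            f"isomorphism classes: {self.n_classes}",
            f"canonical-label calls: {self.canonical_calls}",
            f"quaternary leaves:   {self.quaternary_leaves}",
        ]
        if self.random_excluded:
            lines.append(f"random networks:     {len(self.random_excluded)}")
            lines.append(f"excluded subgraphs per random network: "
                         f"{self.random_excluded}")
        return "\n".join(lines)


@dataclass
class RunResult:
    original: Census
    randoms: list[Census]
    report: Optional[MotifReport]
    registry: ClassRegistry
    tree: QuatTree
    summary: RunSummary


def run(config: RunConfig) -> RunResult:
    """Execute a full enumeration / classification / significance run."""
    if config.graph is not None:
        g = config.graph
    else:
        g = load_edge_list(config.input_path, directed=config.directed)
    if config.k > g.n_vertices:
        raise ValueError(f"k={config.k} exceeds vertex count {g.n_vertices}")

    tree = QuatTree()
    registry = ClassRegistry()
    logger.info("census on original network (n=%d, edges=%d, k=%d)",
                g.n_vertices, g.n_edges, config.k)
    original = census(g, config.k, tree=tree, registry=registry,
                      network="original")
    if original.total == 0:
        logger.warning("no connected %d-subgraph found; the largest connected "
                       "component is smaller than k", config.k)

    registry.freeze()
    randoms: list[Census] = []
    for i, rg in enumerate(generate_ensemble(g, config.n_random, config.swap)):
        rc = census(rg, config.k, tree=tree, registry=registry,
                    network=f"random_{i}")
        randoms.append(rc)
        logger.info("random network %d: %d subgraphs, %d excluded, %d new leaves",
                    i, rc.total, rc.excluded, rc.new_leaves)

    report = z_scores(original, randoms, registry) if randoms else None
    if report is not None and config.output_path is not None:
        report.write_tsv(config.output_path)

    summary = RunSummary(
        n_vertices=g.n_vertices,
        n_edges=g.n_edges,
        k=config.k,
        total_subgraphs=original.total,
        n_classes=len(original.counts),
        canonical_calls=registry.canonical_calls,
        quaternary_leaves=tree.n_resolved_leaves(),
        random_excluded=[rc.excluded for rc in randoms],
        random_new_leaves=[rc.new_leaves for rc in randoms],
    )
    return RunResult(original=original, randoms=randoms, report=report,
                     registry=registry, tree=tree, summary=summary)
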