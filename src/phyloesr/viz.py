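"""Tree export with reconstruction-uncertainty annotations.

The expected log-probability (eLnP) of every node's reconstruction is
min-max normalized to [0, 100] across the pooled set of internal and
terminal nodes and attached as numeric node labels in the emitted Newick,
which FigTree and other viewers display as a node colouring."""

from __future__ import annotations

import logging
from typing import Mapping

from .seqio import PhyloTree

logger = logging.getLogger(__name__)


def normalize_elnp(elnp_by_node: Mapping[int, float]) -> dict[int, float]:
    """Min-max normalize eLnP values to [0, 100] (constant input -> all 50)."""
    values = list(elnp_by_node.values())
    lo, hi = min(values), max(values)
    if hi - lo <= 0:
        logger.warning("constant eLnP across nodes; all labels set to 50")
        return {n: 50.0 for n in elnp_by_node}
    return {n: 100.0 * (v - lo) / (hi - lo) for n, v in elnp_by_node.items()}


def annotate_tree_elnp(tree: PhyloTree, elnp_by_node: Mapping[int, float]) -> str:
    """Newick string with normalized eLnP labels on every annotated node."""
    norm = normalize_elnp(elnp_by_node)
    return tree.to_newick(annotations={n: round(v, 2) for n, v in norm.items()})
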