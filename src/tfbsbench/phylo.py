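"""Phylogenetic tree wrapper for branch-length conservation scoring.

Trees are parsed with dendropy but flattened into the structure branch
length scoring actually needs: for every edge, its length and the set of
leaves on the child side.  Conservation scoring treats the tree as
unrooted; the root is kept only as a traversal anchor, and a degree-two
root simply contributes its two child edges, which carry the same leaf
bipartition (equivalent to one unrooted edge with the summed length).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np


@dataclass
class PhyloTree:
    """A rooted tree with branch lengths, flattened for scoring.

    ``edge_masks[e, i]`` is True when leaf ``i`` lies on the child side
    of edge ``e``; ``edge_lengths[e]`` is that edge's branch length.
    """

    leaves: list[str]
    edge_masks: np.ndarray      # (n_edges, n_leaves) bool
    edge_lengths: np.ndarray    # (n_edges,)
    newick: str

    def __post_init__(self) -> None:
        if len(set(self.leaves)) != len(self.leaves):
            raise ValueError("duplicate leaf labels in tree")
        self.edge_lengths = np.asarray(self.edge_lengths, dtype=float)
        if np.any(~np.isfinite(self.edge_lengths)) or np.any(self.edge_lengths < 0):
            raise ValueError("branch lengths must be finite and non-negative")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def total_length(self) -> float:
        return float(self.edge_lengths.sum())

    def leaf_index(self, label: str) -> int:
        try:
            return self.leaves.index(label)
        except ValueError:
            raise KeyError(f"leaf {label!r} not in tree") from None

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:
            raise ValueError(f"invalid newick string: {exc}") from exc
        return cls.from_dendropy(dtree, newick=newick)

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree, newick: str | None = None
                      ) -> "PhyloTree":
        leaves = [lf.taxon.label for lf in dtree.leaf_node_iter()]
        index = {lab: i for i, lab in enumerate(leaves)}
        masks: list[np.ndarray] = []
        lengths: list[float] = []
        for node in dtree.preorder_node_iter():
            if node.parent_node is None:
                continue
            length = node.edge.length
            if length is None:
                warnings.warn("edge without branch length; treated as 0")
                length = 0.0
            mask = np.zeros(len(leaves), dtype=bool)
            for lf in node.leaf_iter():
                mask[index[lf.taxon.label]] = True
            masks.append(mask)
            lengths.append(float(length))
        if newick is None:
            newick = dtree.as_string(schema="newick", suppress_rooting=True).strip()
        return cls(
            leaves=leaves,
            edge_masks=(np.array(masks) if masks
                        else np.zeros((0, len(leaves)), dtype=bool)),
            edge_lengths=np.array(lengths),
            newick=newick,
        )

    def to_newick(self) -> str:
        return self.newick if self.newick.endswith(";") else self.newick + ";"
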