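"""Phylogenetic tree handling: Newick/NEXUS I/O, distances, and MAD rooting.

Trees are thin wrappers around :class:`dendropy.Tree` that enforce the
invariants the downstream likelihood machinery needs (unique non-empty tip
labels, branch lengths present and nonnegative) and add minimal-ancestor-
deviation (MAD) rooting, the method used to root extein phylogenies when no
outgroup is trustworthy.

MAD places the root at the point on a branch that minimizes the root-mean-
square relative deviation of inferred ancestor positions from tip-pair
midpoints: for a candidate root and tip pair (i, j) with ancestor ``a`` (the
node of the i--j path nearest the root), the deviation is
``r_ij = |2 d(a,i)/d(i,j) - 1|``, zero exactly when the ancestor sits at the
midpoint, as it would under a strict molecular clock.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Tree",
    "MadResult",
    "TreeError",
    "NewickParseError",
    "parse_newick",
    "read_tree",
    "write_newick",
    "tip_distance",
    "mad_root",
]


class TreeError(ValueError):
    """Invalid tree structure or failed validation."""


class NewickParseError(TreeError):
    """Malformed Newick/NEXUS input; message carries the offending position."""


class Tree:
    """A phylogeny with branch lengths.

    Parameters
    ----------
    dtree:
        The underlying :class:`dendropy.Tree`. Taken by reference.
    require_lengths:
        If True (default), every non-root edge must carry a branch length;
        a missing length raises :class:`TreeError` rather than being treated
        as zero, because the likelihood and rooting machinery need lengths.
    """

    def __init__(self, dtree: dendropy.Tree, require_lengths: bool = True):
        self._t = dtree
        self._t.seed_node.edge.length = None  # a root edge has no meaning here
        self._validate(require_lengths)
        self._pdm_cache: dict[tuple[str, str], float] | None = None

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except dendropy.utility.error.DataParseError as exc:
            raise NewickParseError(str(exc)) from exc
        return cls(dtree)

    @classmethod
    def from_nexus(cls, text: str) -> "Tree":
        """Extract the (first) tree from a NEXUS trees block."""
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="nexus",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except dendropy.utility.error.DataParseError as exc:
            raise NewickParseError(str(exc)) from exc
        return cls(dtree)

    def _validate(self, require_lengths: bool) -> None:
        labels = [lf.taxon.label if lf.taxon else None for lf in self._t.leaf_node_iter()]
        if any(lab in (None, "") for lab in labels):
            raise TreeError("every tip must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        if len(labels) < 2:
            raise TreeError("a tree needs at least 2 tips")
        for nd in self._t.preorder_node_iter():
            if nd is self._t.seed_node:
                continue
            if nd.edge.length is None:
                if require_lengths:
                    raise TreeError(
                        f"branch leading to {nd.taxon.label if nd.taxon else 'an internal node'} "
                        "has no length; branch lengths are required"
                    )
            elif nd.edge.length < 0:
                raise TreeError("negative branch length")

    # -- basic queries ----------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._t

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._t.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._t.leaf_node_iter())

    @property
    def is_rooted(self) -> bool:
        """Rooted iff the seed node is a bifurcation (a true root)."""
        return len(self._t.seed_node.child_nodes()) == 2

    @property
    def total_length(self) -> float:
        return sum(
            nd.edge.length or 0.0
            for nd in self._t.preorder_node_iter()
            if nd is not self._t.seed_node
        )

    def copy(self) -> "Tree":
        return Tree(self._t.clone(depth=1), require_lengths=False)

    # -- I/O ---------------------------------------------------------------

    def to_newick(self) -> str:
        s = self._t.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            suppress_leaf_node_labels=False,
        )
        return s.strip() + ("\n" if not s.endswith("\n") else "")

    # -- distances ---------------------------------------------------------

    def _node_tip_distances(self):
        """Distances from every node to every tip, plus per-node tip masks.

        Returns (nodes, dist, below) where ``dist[k, i]`` is the path length
        from node k to tip i and ``below[k, i]`` marks tips in node k's
        subtree (under the current display rooting).
        """
        nodes = list(self._t.postorder_node_iter())
        idx = {id(nd): k for k, nd in enumerate(nodes)}
        tips = [nd for nd in nodes if nd.is_leaf()]
        tip_idx = {id(nd): i for i, nd in enumerate(tips)}
        n, m = len(tips), len(nodes)
        dist = np.zeros((m, n))
        below = np.zeros((m, n), dtype=bool)
        for nd in nodes:  # postorder: children first
            k = idx[id(nd)]
            if nd.is_leaf():
                below[k, tip_idx[id(nd)]] = True
                continue
            for ch in nd.child_nodes():
                ck = idx[id(ch)]
                below[k] |= below[ck]
                dist[k, below[ck]] = dist[ck, below[ck]] + ch.edge.length
        # downward pass done; now fill distances to tips outside each subtree
        for nd in self._t.preorder_node_iter():
            k = idx[id(nd)]
            for ch in nd.child_nodes():
                ck = idx[id(ch)]
                outside = ~below[ck]
                dist[ck, outside] = dist[k, outside] + ch.edge.length
        tip_labels = [t.taxon.label for t in tips]
        return nodes, idx, tips, tip_labels, dist, below

    def tip_distance(self, i: str, j: str) -> float:
        """Patristic distance between tips ``i`` and ``j``."""
        if self._pdm_cache is None:
            nodes, idx, tips, labels, dist, _ = self._node_tip_distances()
            self._pdm_cache = {}
            for t_node in tips:
                row = dist[idx[id(t_node)]]
                for b, lab_b in enumerate(labels):
                    self._pdm_cache[(t_node.taxon.label, lab_b)] = float(row[b])
        try:
            return self._pdm_cache[(i, j)]
        except KeyError:
            known = set(self.tip_labels)
            missing = [x for x in (i, j) if x not in known]
            raise KeyError(f"unknown tip label(s): {missing}") from None

    def distance_matrix(self) -> pd.DataFrame:
        """All pairwise tip distances as a labeled DataFrame."""
        nodes, idx, tips, labels, dist, _ = self._node_tip_distances()
        mat = np.array([dist[idx[id(t)]] for t in tips])
        return pd.DataFrame(mat, index=labels, columns=labels)


@dataclass
class MadResult:
    """Outcome of MAD rooting.

    Attributes
    ----------
    branch:
        (parent_side, child_side) descriptors of the chosen branch; each side
        is named by its smallest tip label.
    rho:
        Relative root position along the branch, measured from the parent
        side, in [0, 1].
    score:
        Root-mean-square relative deviation at the optimum (dimensionless).
    table:
        Per-branch score table (branch id, representative labels, score, rho).
    tied:
        True when more than one branch attains the minimal score.
    """

    branch: tuple[str, str]
    rho: float
    score: float
    table: pd.DataFrame = field(repr=False)
    tied: bool = False


# -- module-level functional API -----------------------------------------


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into a validated :class:`Tree`."""
    return Tree.from_newick(text)


def read_tree(path: str) -> Tree:
    """Read a tree from a Newick or NEXUS file (sniffed from content)."""
    with open(path) as fh:
        text = fh.read()
    if text.lstrip()[:6].upper() == "#NEXUS":
        return Tree.from_nexus(text)
    return Tree.from_newick(text)


def write_newick(tree: Tree, path: str | None = None) -> str:
    s = tree.to_newick()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def tip_distance(tree: Tree, i: str, j: str) -> float:
    return tree.tip_distance(i, j)


def _deroot(dtree: dendropy.Tree) -> dendropy.Tree:
    """Collapse a basal bifurcation so every branch is counted once."""
    if len(dtree.seed_node.child_nodes()) == 2:
        dtree.collapse_basal_bifurcation()
    return dtree


def mad_root(tree: Tree) -> tuple[Tree, MadResult]:
    """Root a tree by minimal ancestor deviation.

    The tree is treated as unrooted (a basal bifurcation is collapsed
    first). Every branch is evaluated as a candidate root location; on each
    branch the optimal position has the closed form

        x* = [sum_pairs (d(i,j) - 2 d(u,i)) / d(i,j)^2]
             / [2 sum_pairs 1/d(i,j)^2],

    where the sum runs over tip pairs split by the branch, ``u`` is the
    parent-side endpoint and ``i`` the tip on the u side; x* is clamped to
    [0, branch length]. Pairs not split by the branch contribute deviations
    that do not depend on the position. The branch with the smallest RMS
    deviation wins; exact ties go to the first branch in postorder and are
    logged.

    Returns the rooted tree and a :class:`MadResult`.

    Raises
    ------
    TreeError
        For trees with fewer than 3 tips or all-zero branch lengths.
    """
    if tree.n_tips < 3:
        raise TreeError("MAD rooting needs at least 3 tips")
    work = Tree(_deroot(tree.dendropy_tree.clone(depth=1)), require_lengths=False)
    if work.total_length <= 0:
        raise TreeError("all branch lengths are zero; MAD rooting is degenerate")

    nodes, idx, tips, labels, dist, below = work._node_tip_distances()
    n = len(tips)
    tipdist = np.array([dist[idx[id(t)]] for t in tips])  # n x n
    zero_pairs = int(np.triu(tipdist == 0, k=1).sum())
    if zero_pairs:
        logger.warning("MAD: %d tip pair(s) at zero distance excluded", zero_pairs)

    seed = work.dendropy_tree.seed_node
    rows = []
    best = None  # (score, row_index, node, x, t)
    branch_nodes = []
    for nd in work.dendropy_tree.postorder_node_iter():
        if nd is seed:
            continue
        k = idx[id(nd)]
        pk = idx[id(nd.parent_node)]
        t = nd.edge.length or 0.0
        m = below[k]  # child (v) side tips
        dv = dist[k]
        du = dist[pk]

        sq_sum = 0.0
        npairs = 0
        # same-side pairs, child side: r = |d(v,i)-d(v,j)| / d(i,j)
        for side_mask, dref in ((m, dv), (~m, du)):
            ii = np.where(side_mask)[0]
            if len(ii) >= 2:
                sub = tipdist[np.ix_(ii, ii)]
                ok = np.triu(sub > 0, k=1)
                diff = np.abs(dref[ii][:, None] - dref[ii][None, :])
                with np.errstate(divide="ignore", invalid="ignore"):
                    r = np.where(ok, diff / np.where(sub > 0, sub, 1.0), 0.0)
                sq_sum += float(np.sum(r[ok] ** 2))
                npairs += int(ok.sum())
        # split pairs: i on parent (u) side, j on child side
        ui = np.where(~m)[0]
        vj = np.where(m)[0]
        x = 0.0
        if len(ui) and len(vj):
            Dc = tipdist[np.ix_(ui, vj)]
            ok = Dc > 0
            A = du[ui][:, None]
            with np.errstate(divide="ignore", invalid="ignore"):
                invd2 = np.where(ok, 1.0 / Dc**2, 0.0)
                num = np.where(ok, (Dc - 2.0 * A) * invd2, 0.0)
            denom = 2.0 * invd2.sum()
            if denom > 0 and t > 0:
                x = float(np.clip(num.sum() / denom, 0.0, t))
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.where(ok, 2.0 * (A + x) / np.where(ok, Dc, 1.0) - 1.0, 0.0)
            sq_sum += float(np.sum(r[ok] ** 2))
            npairs += int(ok.sum())
        score = math.sqrt(sq_sum / npairs) if npairs else math.inf
        rho = x / t if t > 0 else 0.0
        child_rep = min(np.array(labels)[m]) if m.any() else ""
        parent_rep = min(np.array(labels)[~m]) if (~m).any() else ""
        rows.append(
            {
                "branch": len(rows),
                "parent_side": parent_rep,
                "child_side": child_rep,
                "length": t,
                "score": score,
                "rho": rho,
            }
        )
        branch_nodes.append((nd, x, t))
        if best is None or score < best[0] - 1e-15:
            best = (score, len(rows) - 1, nd, x, t)

    table = pd.DataFrame(rows)
    score, row_i, node, x, t = best
    tied = bool((np.isclose(table["score"], score, rtol=0, atol=1e-12)).sum() > 1)
    if tied:
        logger.warning("MAD: tie among branches at score %.6g; keeping first in postorder", score)

    rooted = _reroot_on_edge(work.dendropy_tree, node, x, t)
    result = MadResult(
        branch=(table.loc[row_i, "parent_side"], table.loc[row_i, "child_side"]),
        rho=table.loc[row_i, "rho"],
        score=score,
        table=table,
        tied=tied,
    )
    return Tree(rooted, require_lengths=False), result


def _reroot_on_edge(dtree: dendropy.Tree, child_node, x: float, t: float) -> dendropy.Tree:
    """Root ``dtree`` at distance ``x`` from the parent end of child_node's edge."""
    work = dtree
    edge = child_node.edge
    # length1 -> new edge to the original parent, length2 -> to the child
    work.reroot_at_edge(edge, length1=x, length2=t - x, suppress_unifurcations=True)
    work.seed_node.edge.length = None
    return work
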