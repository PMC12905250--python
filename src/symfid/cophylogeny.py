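"""Cophylogenetic congruence analysis.

Rooted binary trees, newick I/O, minimum-cost duplication-transfer-loss
(DTL) reconciliation by dynamic programming, and the tip-randomization
permutation test of co-cladogenesis.

The reconciliation model is undated parsimony: a symbiont tree is embedded
into a host tree using four event types -- cospeciation (free), duplication,
horizontal transfer (donor and recipient host nodes must be incomparable,
i.e. neither ancestral to the other), and loss (charged per skipped host
edge).  The minimum total event cost measures topological incongruence; a
perfectly co-diverging pair reconciles at cost zero.

Significance is assessed by permuting the symbiont-tip -> host-tip
association uniformly at random and recomputing the cost.  The p-value uses
the add-one convention, so with 100 permutations the smallest attainable
p is 1/101 ~ 0.0099.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


class NewickError(ValueError):
    """Malformed newick input (unbalanced parentheses, stray tokens...)."""


class PolytomyError(NewickError):
    """Tree contains a node with more than two children."""


class DuplicateLabelError(NewickError):
    """Two tips carry the same label."""


class AssociationError(ValueError):
    """Tip association is not a bijection between the two tip sets."""


class TreeNode:
    """Node of a rooted tree; leaves carry a name, edges an optional length."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name=None, length=None, children=None, parent=None):
        self.name = name
        self.length = length
        self.children = children if children is not None else []
        self.parent = parent
        for c in self.children:
            c.parent = self

    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def copy(self) -> "TreeNode":
        node = TreeNode(name=self.name, length=self.length)
        for c in self.children:
            node.add_child(c.copy())
        return node


class PhyloTree:
    """Rooted binary tree with uniquely labelled tips.

    Validates on construction: every internal node has exactly two children
    (``PolytomyError`` otherwise) and tip labels are unique
    (``DuplicateLabelError``).  A single labelled node is a valid tree.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        labels = []
        for node in root.postorder():
            if node.is_leaf():
                if node.name is None or node.name == "":
                    raise NewickError("unlabelled tip")
                labels.append(node.name)
            elif len(node.children) != 2:
                raise PolytomyError(
                    f"internal node with {len(node.children)} children; "
                    "only strictly binary trees are supported"
                )
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise DuplicateLabelError(f"duplicate tip labels: {dup}")
        self._tip_labels = labels

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in left-to-right (input) order."""
        return list(self._tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    def tips(self) -> list[TreeNode]:
        return [n for n in self.root.postorder() if n.is_leaf()]

    def postorder(self):
        return self.root.postorder()

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy())

    def __repr__(self):
        return f"PhyloTree({self.n_tips} tips)"


_DELIMS = set("(),:;")


def parse_newick(text: str) -> PhyloTree:
    """Parse a rooted, strictly binary newick string (must end with ';').

    Polytomies and duplicate tip labels are rejected with distinct errors.
    Branch lengths are optional; internal node labels are ignored.
    """
    s = text.strip()
    if not s.endswith(";"):
        raise NewickError("newick string must terminate with ';'")
    body = s[:-1].strip()
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(body) and body[pos] == "(":
            pos += 1
            while True:
                node.add_child(parse_node())
                if pos >= len(body):
                    raise NewickError("unbalanced parentheses: unexpected end of input")
                ch = body[pos]
                if ch == ",":
                    pos += 1
                    continue
                if ch == ")":
                    pos += 1
                    break
                raise NewickError(f"unexpected character {ch!r} at position {pos}")
        # optional label
        start = pos
        while pos < len(body) and body[pos] not in _DELIMS:
            pos += 1
        label = body[start:pos].strip()
        if label:
            node.name = label
        # optional branch length
        if pos < len(body) and body[pos] == ":":
            pos += 1
            start = pos
            while pos < len(body) and body[pos] not in _DELIMS:
                pos += 1
            try:
                node.length = float(body[start:pos])
            except ValueError as exc:
                raise NewickError(f"bad branch length {body[start:pos]!r}") from exc
        return node

    root = parse_node()
    if pos != len(body):
        raise NewickError(
            f"unbalanced parentheses or trailing characters at position {pos}"
        )
    return PhyloTree(root)


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree; branch lengths written to 6 decimals when present."""

    def render(node: TreeNode) -> str:
        if node.is_leaf():
            out = node.name
        else:
            out = "(" + ",".join(render(c) for c in node.children) + ")"
        if node.length is not None:
            out += f":{node.length:.6f}"
        return out

    return render(tree.root) + ";"


def check_association(
    host: PhyloTree, symbiont: PhyloTree, assoc: dict[str, str]
) -> None:
    """Validate that ``assoc`` is a bijection symbiont tips -> host tips."""
    sym_tips = set(symbiont.tip_labels)
    host_tips = set(host.tip_labels)
    if set(assoc) != sym_tips:
        raise AssociationError("association keys do not match symbiont tip labels")
    images = list(assoc.values())
    if len(set(images)) != len(images) or set(images) != host_tips:
        raise AssociationError("association is not a bijection onto host tips")


@dataclass(frozen=True)
class DtlCosts:
    """Event costs for DTL reconciliation (cospeciation is free)."""

    dup: float = 1.0
    transfer: float = 1.0
    loss: float = 1.0

    def __post_init__(self):
        if min(self.dup, self.transfer, self.loss) < 0:
            raise ValueError("event costs must be non-negative")


@dataclass(frozen=True)
class ReconciliationResult:
    min_cost: float


def _index_host(host: PhyloTree):
    """Postorder node list plus child/parent index arrays."""
    nodes = list(host.postorder())
    idx = {id(n): i for i, n in enumerate(nodes)}
    children = [
        (idx[id(n.children[0])], idx[id(n.children[1])]) if not n.is_leaf() else None
        for n in nodes
    ]
    parent = [-1] * len(nodes)
    for i, n in enumerate(nodes):
        if not n.is_leaf():
            a, b = children[i]
            parent[a] = i
            parent[b] = i
    return nodes, children, parent


def dtl_min_cost(
    host: PhyloTree,
    symbiont: PhyloTree,
    assoc: dict[str, str],
    costs: DtlCosts = DtlCosts(),
) -> ReconciliationResult:
    """Minimum total event cost embedding ``symbiont`` into ``host``.

    Undated DTL parsimony via the standard dynamic programme.  For symbiont
    node s and host node h, c(s, h) is the optimal cost of the subtree of s
    with s mapped exactly to h; ``in_(s, h)`` relaxes the mapping to any
    descendant of h (charging one loss per skipped host edge) and
    ``out(s, h)`` to any host node incomparable to h.  Internal nodes choose
    the cheapest of cospeciation, duplication, or transfer; the root may map
    anywhere with no stem charge.
    """
    check_association(host, symbiont, assoc)
    h_nodes, h_children, h_parent = _index_host(host)
    H = len(h_nodes)
    host_tip_idx = {n.name: i for i, n in enumerate(h_nodes) if n.is_leaf()}
    internal_idx = [i for i in range(H) if h_children[i] is not None]
    INF = math.inf

    def sweep_in(c: np.ndarray) -> np.ndarray:
        in_ = c.copy()
        for i in range(H):  # postorder: children precede parents
            ch = h_children[i]
            if ch is not None:
                a, b = ch
                in_[i] = min(in_[i], in_[a] + costs.loss, in_[b] + costs.loss)
        return in_

    def sweep_out(c: np.ndarray) -> np.ndarray:
        # minc[h]: cheapest c in the subtree of h (transfer recipients land
        # exactly on their node, so no loss charge applies here)
        minc = c.copy()
        for i in range(H):
            ch = h_children[i]
            if ch is not None:
                a, b = ch
                minc[i] = min(minc[i], minc[a], minc[b])
        out = np.full(H, INF)
        for i in reversed(range(H)):  # reverse postorder: parents first
            ch = h_children[i]
            if ch is not None:
                a, b = ch
                out[a] = min(out[i], minc[b])
                out[b] = min(out[i], minc[a])
        return out

    table: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    root_c = None
    for s in symbiont.postorder():
        if s.is_leaf():
            c = np.full(H, INF)
            c[host_tip_idx[assoc[s.name]]] = 0.0
        else:
            c1, in1, out1 = table.pop(id(s.children[0]))
            c2, in2, out2 = table.pop(id(s.children[1]))
            dup = costs.dup + in1 + in2
            transfer = costs.transfer + np.minimum(in1 + out2, in2 + out1)
            c = np.minimum(dup, transfer)
            for i in internal_idx:
                a, b = h_children[i]
                cospec = min(in1[a] + in2[b], in1[b] + in2[a])
                if cospec < c[i]:
                    c[i] = cospec
        table[id(s)] = (c, sweep_in(c), sweep_out(c))
        root_c = c
    return ReconciliationResult(min_cost=float(root_c.min()))


def randomize_tip_association(
    assoc: dict[str, str], rng: np.random.Generator | int
) -> dict[str, str]:
    """Uniformly permute the host-tip images of the association.

    The identity permutation is permitted, making the null uniform over all
    bijections.  Keys are processed in sorted order so the result depends
    only on the random state, not dict insertion order.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    keys = sorted(assoc)
    values = [assoc[k] for k in keys]
    perm = rng.permutation(len(keys))
    return {k: values[p] for k, p in zip(keys, perm)}


@dataclass
class CongruenceTestResult:
    """Tip-randomization test of co-cladogenesis."""

    observed_cost: float
    permuted_costs: list[float] = field(repr=False)
    n_perm: int = 0
    p_value: float = 1.0


def cocladogenesis_test(
    host: PhyloTree,
    symbiont: PhyloTree,
    assoc: dict[str, str],
    costs: DtlCosts = DtlCosts(),
    n_perm: int = 100,
    seed: int | np.random.Generator | None = None,
) -> CongruenceTestResult:
    """Permutation test: is the observed reconciliation cost lower than
    expected for a random tip association?

    p = (1 + #{permuted cost <= observed}) / (1 + n_perm), ties counted as
    extreme, so p is bounded below by 1/(1 + n_perm).
    """
    if n_perm < 0:
        raise ValueError("n_perm must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = dtl_min_cost(host, symbiont, assoc, costs).min_cost
    permuted = []
    for _ in range(n_perm):
        shuffled = randomize_tip_association(assoc, rng)
        permuted.append(dtl_min_cost(host, symbiont, shuffled, costs).min_cost)
    tol = 1e-9
    n_extreme = sum(1 for c in permuted if c <= observed + tol)
    p = (1 + n_extreme) / (1 + n_perm)
    return CongruenceTestResult(
        observed_cost=observed, permuted_costs=permuted, n_perm=n_perm, p_value=p
    )
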