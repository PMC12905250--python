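"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package internals: the DTL oracle
enumerates every symbiont-node -> host-node mapping and costs each mapping's
events directly from first principles.
"""

from __future__ import annotations

import itertools
import math

from symfid.cophylogeny import DtlCosts, PhyloTree


def dtl_min_cost_exhaustive(
    host: PhyloTree, symbiont: PhyloTree, assoc: dict[str, str], costs: DtlCosts
) -> float:
    """Exhaustive minimum DTL cost over all node mappings (tiny trees only).

    For every assignment of symbiont internal nodes to host nodes (tips are
    pinned by the association), each internal symbiont node s mapped to h
    with children mapped to h1, h2 is costed as the cheapest consistent
    event:

    * cospeciation (h internal, h1 and h2 in distinct child subtrees of h):
      one loss per host edge skipped below each child of h;
    * duplication (h1 and h2 both descendants-or-equal of h): cost_dup plus
      losses along both paths from h;
    * transfer (one child under h, the other mapped to a node incomparable
      to h): cost_transfer plus losses along the retained child's path.

    Mappings admitting no consistent event cost infinity.
    """
    h_nodes = list(host.postorder())
    s_nodes = list(symbiont.postorder())
    h_index = {id(n): i for i, n in enumerate(h_nodes)}

    # ancestry: desc[i][j] True iff j is i itself or a descendant of i
    n_h = len(h_nodes)
    desc = [[False] * n_h for _ in range(n_h)]
    depth = [0] * n_h
    for i, n in enumerate(h_nodes):
        desc[i][i] = True
        for c in n.children:
            ci = h_index[id(c)]
            for j in range(n_h):
                desc[i][j] = desc[i][j] or desc[ci][j]
    # depths for loss counting
    def set_depth(node, d):
        depth[h_index[id(node)]] = d
        for c in node.children:
            set_depth(c, d + 1)

    set_depth(host.root, 0)

    host_tip = {n.name: h_index[id(n)] for n in h_nodes if n.is_leaf()}
    fixed = {}
    free = []
    for n in s_nodes:
        if n.is_leaf():
            fixed[id(n)] = host_tip[assoc[n.name]]
        else:
            free.append(n)

    def event_cost(h, h1, h2):
        best = math.inf
        node_h = h_nodes[h]
        if node_h.children:
            a = h_index[id(node_h.children[0])]
            b = h_index[id(node_h.children[1])]
            for x, y in ((h1, h2), (h2, h1)):
                if desc[a][x] and desc[b][y]:
                    losses = (depth[x] - depth[a]) + (depth[y] - depth[b])
                    best = min(best, costs.loss * losses)
        if desc[h][h1] and desc[h][h2]:
            losses = (depth[h1] - depth[h]) + (depth[h2] - depth[h])
            best = min(best, costs.dup + costs.loss * losses)
        for kept, moved in ((h1, h2), (h2, h1)):
            if desc[h][kept] and not desc[h][moved] and not desc[moved][h]:
                best = min(
                    best, costs.transfer + costs.loss * (depth[kept] - depth[h])
                )
        return best

    best_total = math.inf
    for assignment in itertools.product(range(n_h), repeat=len(free)):
        mapping = dict(fixed)
        for node, h in zip(free, assignment):
            mapping[id(node)] = h
        total = 0.0
        for node in free:
            h = mapping[id(node)]
            h1 = mapping[id(node.children[0])]
            h2 = mapping[id(node.children[1])]
            total += event_cost(h, h1, h2)
            if total == math.inf:
                break
        best_total = min(best_total, total)
    return best_total
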