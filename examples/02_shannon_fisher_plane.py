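"""Place toy graphs on the Shannon-Fisher plane.

H is the mean normalized random-walk entropy over nodes, F the mean
normalized Fisher information. A complete graph is maximally disordered
(H=1, F=0); an empty graph maximally ordered (H=0, F=1); sparse structured
graphs sit in between.
"""

import itertools

import numpy as np

from sfplane import AdjacencyMatrix, network_entropy, network_fisher


def coords(n, edges):
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    adj = AdjacencyMatrix(a=a, threshold_used=0.5)
    return network_entropy(adj), network_fisher(adj)


graphs = {
    "complete K5": (5, list(itertools.combinations(range(5), 2))),
    "star N=4": (4, [(0, 1), (0, 2), (0, 3)]),
    "path N=3": (3, [(0, 1), (1, 2)]),
    "empty N=4": (4, []),
}
for name, (n, edges) in graphs.items():
    h, f = coords(n, edges)
    print(f"{name:<12} (H, F) = ({h:.4f}, {f:.4f})")
print("\ndisordered graphs approach (1, 0); ordered graphs approach (0, 1)")
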