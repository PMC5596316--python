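"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: the ORF oracle
enumerates every ATG-to-stop span directly on codons; the Ward oracle
agglomerates by explicit within-cluster sum-of-squares; the Fisher oracle
sums exact hypergeometric probabilities with integer arithmetic; the
flat-cluster oracle re-evaluates the gap condition pairwise over leaves.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def brute_force_orfs(sequence: str, frames=(0, 1, 2)):
    """Every ATG-initiated span ending at a stop or the sequence end.

    Yields (frame, protein_start, protein_end, nt_start, nt_end) with
    protein coordinates on the frame's translation, 0-based half-open,
    stop codon excluded.
    """
    seq = sequence.upper()
    for frame in frames:
        codons = [seq[i:i + 3] for i in range(frame, len(seq) - 2, 3)]
        aas = ["X" if c not in _CODON_TABLE else _CODON_TABLE[c] for c in codons]
        for start in range(len(aas)):
            if aas[start] != "M":
                continue
            end = start
            while end < len(aas) and aas[end] != "*":
                end += 1
            yield (frame, start, end, frame + 3 * start, frame + 3 * end)


def best_orf(sequence: str, frames=(0, 1, 2)):
    """Longest ATG span; ties broken by lowest frame then lowest start."""
    best = None
    for orf in brute_force_orfs(sequence, frames):
        frame, start, end, *_ = orf
        key = (-(end - start), frame, start)
        if best is None or key < best[0]:
            best = (key, orf)
    return None if best is None else best[1]


def naive_ward_heights(X: np.ndarray) -> list[float]:
    """O(n^3) Ward agglomeration from the sum-of-squares definition.

    Merge cost between clusters A and B is sqrt(2 * (SSE(A+B) - SSE(A)
    - SSE(B))), which for singletons reduces to the Euclidean distance.
    Returns the sorted merge heights.
    """
    def sse(idx):
        pts = X[list(idx)]
        return float(((pts - pts.mean(axis=0)) ** 2).sum())

    clusters = [frozenset([i]) for i in range(X.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for (i, a), (j, b) in combinations(enumerate(clusters), 2):
            d = math.sqrt(2 * (sse(a | b) - sse(a) - sse(b)))
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return sorted(heights)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Sums P(table) over all tables with the observed margins whose
    probability does not exceed the observed table's (with the standard
    tiny relative tolerance for ties).
    """
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = math.comb(n, c1)

    def prob(k: int) -> Fraction:
        return Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k), denom)

    p_obs = prob(a)
    gate = p_obs + p_obs / 10**7
    total = Fraction(0)
    for k in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        p = prob(k)
        if p <= gate:
            total += p
    return float(total)


def flat_clusters_oracle(Z: np.ndarray, threshold: float) -> list[set[int]]:
    """Partition of leaves by direct evaluation of the gap condition.

    Two leaves share a cluster iff no edge on the dendrogram path between
    them has a parent-child height gap exceeding ``threshold``.
    """
    n = Z.shape[0] + 1
    heights = np.concatenate([np.zeros(n), Z[:, 2]])
    parent = {}
    for k in range(n - 1):
        parent[int(Z[k, 0])] = n + k
        parent[int(Z[k, 1])] = n + k

    def path_to_root(leaf):
        path = [leaf]
        while path[-1] in parent:
            path.append(parent[path[-1]])
        return path

    def connected(u, v):
        pu, pv = path_to_root(u), path_to_root(v)
        lca = next(x for x in pu if x in set(pv))
        edges = []
        for path in (pu, pv):
            for node in path[: path.index(lca)]:
                edges.append((parent[node], node))
        return all(heights[p] - heights[c] <= threshold for p, c in edges)

    clusters: list[set[int]] = []
    for leaf in range(n):
        for cl in clusters:
            if connected(leaf, next(iter(cl))):
                cl.add(leaf)
                break
        else:
            clusters.append({leaf})
    return clusters
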