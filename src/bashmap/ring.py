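"""Pairwise co-occurring misincorporation statistics (RING-style G-test).

For every eligible pair of positions (i, j) the reads covering both are
tallied into a 2x2 table of (modified at i) x (modified at j) and tested for
independence with the likelihood-ratio G-test,

    G = 2 * sum_cells O * ln(O / E),

with expectations E from the table margins.  A pair is positively associated
when co-modification is enriched over independence (n11 * N > row1 * col1);
negative associations are discarded downstream, since structural coupling
(breathing of a hydrogen-bonded group) produces co-modification, not
anti-correlation.  G values are compared across pairs via Z-score
normalization over a chosen pair population (by default positive G-G pairs),
and a thresholded graph of G nodes exposes clusters of structurally linked
guanosines such as the tetrads of a G-quadruplex.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import ReadSet

__all__ = [
    "PairMatrix",
    "pair_table",
    "g_test",
    "pair_matrix",
    "zscore_pairs",
    "gg_network",
    "components",
]


@dataclass
class PairMatrix:
    """Symmetric per-pair statistics over a length-L reference.

    All matrices are (L, L); entries are NaN/0 where a pair is ineligible
    (|i-j| < min_sep, < min_pair_count reads, or a zero margin).  ``valid``
    marks pairs with a defined G statistic.
    """

    G: np.ndarray
    sign: np.ndarray  # +1 / -1 / 0 (undefined)
    n11: np.ndarray
    N: np.ndarray
    valid: np.ndarray  # bool
    min_sep: int
    reference: object = None  # SequenceRecord, for base-aware subsetting
    Z: np.ndarray | None = None
    z_population: str = ""

    @property
    def L(self) -> int:
        return self.G.shape[0]

    def scaled(self) -> np.ndarray:
        """Positive-association G scaled to [0, 1] by the matrix maximum."""
        g = np.where(self.valid & (self.sign > 0), self.G, 0.0)
        m = g.max()
        return g / m if m > 0 else g

    def edge_list(self, z_threshold: float | None = None) -> pd.DataFrame:
        """Long-format table of valid positive pairs (i < j)."""
        rows = []
        L = self.L
        for i in range(L):
            for j in range(i + 1, L):
                if not self.valid[i, j] or self.sign[i, j] <= 0:
                    continue
                z = self.Z[i, j] if self.Z is not None else np.nan
                if z_threshold is not None and not (z >= z_threshold):
                    continue
                rows.append(
                    {
                        "i": i + 1,
                        "j": j + 1,
                        "G": self.G[i, j],
                        "Z": z,
                        "sign": int(self.sign[i, j]),
                        "n11": int(self.n11[i, j]),
                        "N": int(self.N[i, j]),
                    }
                )
        return pd.DataFrame(rows, columns=["i", "j", "G", "Z", "sign", "n11", "N"])


def pair_table(rs: ReadSet, i: int, j: int) -> tuple[int, int, int, int]:
    """2x2 counts (n11, n10, n01, n00) for 1-based positions i and j.

    Only reads covering both positions contribute.
    """
    n11 = n10 = n01 = n00 = 0
    for r in rs.reads:
        if not (r.covers(i) and r.covers(j)):
            continue
        bi, bj = r.bit_at(i), r.bit_at(j)
        if bi and bj:
            n11 += 1
        elif bi:
            n10 += 1
        elif bj:
            n01 += 1
        else:
            n00 += 1
    return n11, n10, n01, n00


def g_test(table: tuple[int, int, int, int]) -> tuple[float, int]:
    """Likelihood-ratio G statistic and association sign for a 2x2 table.

    Returns (G, sign); sign is +1 when co-modification is enriched
    (n11 * N > row1 * col1), -1 otherwise.  Raises ValueError when the test
    is undefined (empty table or a zero margin).
    """
    n11, n10, n01, n00 = table
    N = n11 + n10 + n01 + n00
    if N == 0:
        raise ValueError("empty pair table")
    r1, c1 = n11 + n10, n11 + n01
    if r1 == 0 or c1 == 0 or r1 == N or c1 == N:
        raise ValueError("zero margin: G-test undefined")
    obs = np.array([n11, n10, n01, n00], dtype=float)
    exp = (
        np.array([r1 * c1, r1 * (N - c1), (N - r1) * c1, (N - r1) * (N - c1)], dtype=float)
        / N
    )
    nz = obs > 0
    G = 2.0 * float(np.sum(obs[nz] * np.log(obs[nz] / exp[nz])))
    sign = 1 if n11 * N > r1 * c1 else -1
    return G, sign


def pair_matrix(
    rs: ReadSet, min_sep: int = 6, min_pair_count: int = 1
) -> PairMatrix:
    """G-test over all eligible position pairs, vectorized over the ReadSet.

    Pairs closer than ``min_sep`` are excluded: the read-level separation
    collapse deterministically suppresses nearby co-occurrences, so
    short-range pairs carry filter artifacts rather than structure.
    """
    L = rs.L
    bits = rs.bits_matrix_padded().astype(np.int64)
    cov = rs.coverage_matrix().astype(np.int64)
    n11 = bits.T @ bits
    b_cov = bits.T @ cov  # reads modified at i and covering j
    N = cov.T @ cov
    n10 = b_cov - n11
    n01 = b_cov.T - n11
    n00 = N - n11 - n10 - n01

    r1, c1 = n11 + n10, n11 + n01
    valid = (N >= max(min_pair_count, 1)) & (r1 > 0) & (c1 > 0) & (r1 < N) & (c1 < N)
    sep = np.abs(np.subtract.outer(np.arange(L), np.arange(L)))
    valid &= sep >= max(min_sep, 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        Nf = N.astype(float)
        G = np.zeros((L, L))
        for obs, er, ec in (
            (n11, r1, c1),
            (n10, r1, N - c1),
            (n01, N - r1, c1),
            (n00, N - r1, N - c1),
        ):
            E = er * ec / np.where(Nf > 0, Nf, 1.0)
            term = np.where(
                (obs > 0) & (E > 0), obs * np.log(np.where(obs > 0, obs, 1) / np.where(E > 0, E, 1)), 0.0
            )
            G += term
        G *= 2.0
    G = np.where(valid, np.maximum(G, 0.0), np.nan)
    sign = np.where(valid, np.where(n11 * N > r1 * c1, 1, -1), 0)
    np.fill_diagonal(G, np.nan)
    np.fill_diagonal(sign, 0)
    np.fill_diagonal(valid, False)
    return PairMatrix(
        G=G,
        sign=sign,
        n11=n11,
        N=N,
        valid=valid,
        min_sep=min_sep,
        reference=rs.reference,
    )


def zscore_pairs(pm: PairMatrix, subset: str = "GG") -> PairMatrix:
    """Z-score the G statistics over a pair population.

    ``subset="GG"`` (default): positive pairs where both positions are G;
    ``subset="all"``: all positive valid pairs.  The Z matrix is NaN outside
    the population.  A degenerate population (zero spread) yields all-zero Z.
    """
    L = pm.L
    pop = pm.valid & (pm.sign > 0)
    if subset == "GG":
        if pm.reference is None:
            raise ValueError("GG subset requires a reference sequence")
        is_g = np.array([b == "G" for b in pm.reference.seq])
        pop &= is_g[:, None] & is_g[None, :]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    iu = np.triu_indices(L, k=1)
    vals = pm.G[iu][pop[iu]]
    Z = np.full((L, L), np.nan)
    if len(vals):
        mu, sd = float(vals.mean()), float(vals.std())
        degenerate = sd <= 1e-12 * max(1.0, abs(mu))  # zero-spread population
        z = np.zeros_like(pm.G) if degenerate else (pm.G - mu) / sd
        Z = np.where(pop, z, np.nan)
    return PairMatrix(
        G=pm.G,
        sign=pm.sign,
        n11=pm.n11,
        N=pm.N,
        valid=pm.valid,
        min_sep=pm.min_sep,
        reference=pm.reference,
        Z=Z,
        z_population=subset,
    )


def gg_network(pm: PairMatrix, z_threshold: float = 2.0) -> nx.Graph:
    """Graph of G positions linked by co-occurring misincorporations.

    Nodes are all G positions of the reference; an edge joins i and j when
    their positive association has Z >= z_threshold.  Requires Z scores
    (see :func:`zscore_pairs`); computes them over the G-G population if
    absent.
    """
    if pm.Z is None:
        pm = zscore_pairs(pm, subset="GG")
    if pm.reference is None:
        raise ValueError("gg_network requires a reference sequence")
    g_positions = [p + 1 for p, b in enumerate(pm.reference.seq) if b == "G"]
    graph = nx.Graph()
    graph.add_nodes_from(g_positions)
    L = pm.L
    for i in range(L):
        for j in range(i + 1, L):
            z = pm.Z[i, j]
            if np.isfinite(z) and z >= z_threshold and pm.sign[i, j] > 0:
                graph.add_edge(i + 1, j + 1, Z=float(z), G=float(pm.G[i, j]))
    return graph


def components(graph: nx.Graph, nonsingleton: bool = True) -> list[set[int]]:
    """Connected components, largest first; singletons dropped by default."""
    comps = [set(c) for c in nx.connected_components(graph)]
    if nonsingleton:
        comps = [c for c in comps if len(c) > 1]
    return sorted(comps, key=len, reverse=True)
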