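"""G-quadruplex conformer enumeration and polyUG register combinatorics.

A three-tiered G-quadruplex needs four tracts of (at least) three consecutive
G's; within a G-rich sequence many distinct placements of the four tracts are
possible ("conformers"), differing in which G's of a long run participate and
in the three loop lengths.  The enumerator lists every placement under
QGRS-style constraints: tract length = tetrad size, loop lengths within
[loop_min, loop_max] with at most one zero-length loop, and total span
bounded by max_span.  Overlapping placements are all counted.

A polyUG repeat tract supports an analogous combinatorial family: a
quadruplex built from ``span_repeats`` consecutive GU repeats can start at
any of several offsets within the tract ("registers"); each register is
defined by the repeat G's it leaves out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GQuadConformer",
    "Register",
    "enumerate_conformers",
    "rank_conformers",
    "enumerate_registers",
    "register_membership",
]


@dataclass(frozen=True)
class GQuadConformer:
    """One placement of four G-tracts (1-based start positions)."""

    starts: tuple[int, int, int, int]
    tetrad: int

    @property
    def loops(self) -> tuple[int, int, int]:
        s, t = self.starts, self.tetrad
        return (s[1] - s[0] - t, s[2] - s[1] - t, s[3] - s[2] - t)

    @property
    def span(self) -> int:
        return self.starts[3] + self.tetrad - self.starts[0]

    def g_positions(self) -> list[int]:
        return [s + k for s in self.starts for k in range(self.tetrad)]

    def annotate(self, seq: str) -> str:
        """Sequence with quadruplex G's lowercased (the conformer's footprint)."""
        gset = set(self.g_positions())
        return "".join(
            c.lower() if (i + 1) in gset else c for i, c in enumerate(seq)
        )


def _normalize_seq(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"illegal characters in sequence: {sorted(bad)}")
    return seq


def enumerate_conformers(
    seq: str,
    max_span: int = 45,
    min_run: int = 3,
    loop_min: int = 0,
    loop_max: int = 36,
    tetrad: int = 3,
    max_zero_loops: int = 1,
) -> list[GQuadConformer]:
    """All placements of four length-``tetrad`` all-G tracts in ``seq``.

    Tracts must come from runs of at least ``min_run`` G's, be ordered and
    non-overlapping, with the three loop lengths in [loop_min, loop_max]
    (at most ``max_zero_loops`` of them zero) and span <= max_span.  Every
    distinct placement is returned, including overlapping alternatives
    within long G-runs.  Results are sorted by start positions.
    """
    seq = _normalize_seq(seq)
    L = len(seq)
    t = tetrad
    # candidate tract starts: all-G windows of width t inside runs >= min_run
    starts = []
    i = 0
    while i < L:
        if seq[i] == "G":
            j = i
            while j < L and seq[j] == "G":
                j += 1
            if j - i >= min_run:
                starts.extend(range(i + 1, j - t + 2))  # 1-based window starts
            i = j
        else:
            i += 1

    out: list[GQuadConformer] = []
    ns = len(starts)
    for a_idx in range(ns):
        a = starts[a_idx]
        for b_idx in range(a_idx + 1, ns):
            b = starts[b_idx]
            l1 = b - a - t
            if l1 < 0:
                continue
            if l1 > loop_max:
                break
            if l1 < loop_min:
                continue
            for c_idx in range(b_idx + 1, ns):
                c = starts[c_idx]
                l2 = c - b - t
                if l2 < 0:
                    continue
                if l2 > loop_max:
                    break
                if l2 < loop_min:
                    continue
                for d_idx in range(c_idx + 1, ns):
                    d = starts[d_idx]
                    l3 = d - c - t
                    if l3 < 0:
                        continue
                    if l3 > loop_max or d + t - a > max_span:
                        break
                    if l3 < loop_min:
                        continue
                    if sum(x == 0 for x in (l1, l2, l3)) > max_zero_loops:
                        continue
                    out.append(GQuadConformer((a, b, c, d), t))
    out.sort(key=lambda cf: cf.starts)
    return out


def rank_conformers(conformers, profile) -> pd.DataFrame:
    """Order conformers by mean misincorporation rate of their G's, ascending.

    The most protected (lowest-rate) conformer heads the table: its G's are
    the best candidates for the quadruplex actually folded in the ensemble.
    Ties are broken by 5' start, then span.
    """
    rows = []
    for cf in conformers:
        rates = np.array([profile.rate_at(p) for p in cf.g_positions()], dtype=float)
        rows.append(
            {
                "starts": cf.starts,
                "loops": cf.loops,
                "span": cf.span,
                "tetrad": cf.tetrad,
                "mean_rate": float(np.nanmean(rates)) if len(rates) else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(
            by=["mean_rate", "starts", "span"],
            key=lambda col: col.map(tuple) if col.name == "starts" else col,
            kind="stable",
        ).reset_index(drop=True)
    return out


@dataclass(frozen=True)
class Register:
    """One quadruplex register within a (UG)_n repeat tract.

    ``start_repeat`` is the 1-based index of the first spanned repeat;
    ``members`` are the 1-based sequence positions of the G of every spanned
    repeat (computed from ``g_of_repeat``).
    """

    start_repeat: int
    span_repeats: int
    members: tuple[int, ...]

    @property
    def name(self) -> str:
        return f"register_{self.start_repeat}"

    @property
    def repeats(self) -> range:
        return range(self.start_repeat, self.start_repeat + self.span_repeats)


def enumerate_registers(
    n_repeats: int,
    span_repeats: int = 12,
    g_of_repeat=None,
) -> list[Register]:
    """All placements of ``span_repeats`` consecutive repeats in a tract.

    A tract of n repeats supports n - span + 1 registers (none when the
    tract is too short).  ``g_of_repeat`` maps a 1-based repeat index to the
    sequence position of its G; the default assumes a bare (UG)_n tract,
    G of repeat k at position 2k.
    """
    if g_of_repeat is None:
        g_of_repeat = lambda k: 2 * k  # noqa: E731
    out = []
    for start in range(1, n_repeats - span_repeats + 2):
        members = tuple(g_of_repeat(k) for k in range(start, start + span_repeats))
        out.append(Register(start, span_repeats, members))
    return out


def register_membership(
    registers: list[Register], n_repeats: int
) -> tuple[list[int], int]:
    """(per-register excluded-G count, size of the all-register intersection).

    Each register leaves out the repeat G's it does not span; the
    intersection counts G's engaged in the quadruplex in every register
    (the constitutively protected core).  Both are computed from the actual
    member sets.
    """
    all_repeats = set(range(1, n_repeats + 1))
    excluded = [len(all_repeats - set(r.repeats)) for r in registers]
    if registers:
        core = set(registers[0].repeats)
        for r in registers[1:]:
            core &= set(r.repeats)
        intersection = len(core)
    else:
        intersection = 0
    return excluded, intersection
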