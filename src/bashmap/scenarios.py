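"""Canonical planted benchmark scenarios.

Each builder returns a fully specified synthetic ensemble with known ground
truth, used to validate the analysis stages end to end.  The scenarios are
fixed study conditions, not tuning knobs: their geometry and noise levels
were chosen up front from the qualitative behaviour of N7G probing data
(see the package methods notes) and are shared by the test suite and the
reproduction script.

``two_conformer_quadruplex`` is the central scenario: a mixture of a folded
G-quadruplex state and a minor state in which the quadruplex is open and a
C-rich block pairs elsewhere, mimicking an aptamer whose tertiary core
unfolds into an alternative helix.  The reference is built over {A, C, G}
only, with all pair-capable bases confined to a single variable block, so
that every fold is constant outside that block and conformational
differences are attributable to the planted switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import BitVector, ReadSet, SequenceRecord
from .simulate import ConformerSpec, EnsembleSpec

__all__ = [
    "QuadSwitchScenario",
    "two_conformer_quadruplex",
    "m2_quartet_scenario",
    "m2_hairpin_scenario",
    "two_state_bernoulli",
    "independent_readset",
]


def _structure_from_pairs(L: int, pairs: list[tuple[int, int]]) -> str:
    db = ["."] * L
    for i, j in pairs:
        db[i - 1], db[j - 1] = "(", ")"
    return "".join(db)


@dataclass
class QuadSwitchScenario:
    """The two-conformer quadruplex-switch benchmark and its ground truth."""

    spec: EnsembleSpec
    quartet_gs: list[int]  # the planted tertiary G's
    variable_region: tuple[int, int]  # 1-based inclusive block that may differ
    b_helix_pairs: list[tuple[int, int]]  # the alternative helix of the minor state


def two_conformer_quadruplex(
    n_reads: int = 10000, seed: int = 11, proportions=(0.8, 0.2)
) -> QuadSwitchScenario:
    """Folded three-tier quadruplex (major) vs open-core alternative helix.

    Reference layout (L = 85, alphabet {A, C, G}; exterior and loops are
    poly-A so they can never pair):

    * 1-4     AAAA            5' leader (constant)
    * 5-19    GGGAGGGAGGGAGGG   four G-tracts; their 12 G's form the
                                quadruplex of the major state
    * 20-21   AA
    * 22-69   (GGGA) x 12     G-rich single-stranded filler; its 36 G's stay
                              accessible in both states and anchor the upper
                              quartiles of the G-rate distribution
    * 70-71   AA
    * 72-81   CCCCCCCCCC      C block: single-stranded in the major state,
                              paired in the minor state's alternative helix
    * 82-85   AAAA            3' tail (constant)

    Major state "quad_folded": quadruplex closed (quartet G's protected),
    everything else single-stranded.  Minor state "quad_open": quadruplex
    open (its G's fully accessible on the Watson-Crick lattice), the C block
    paired into an alternative helix with 3'-filler G's.  Probing dose is
    mid-range (half of fully accessible sites modified per molecule) so that
    a minor-state molecule almost always reveals itself by at least one hit
    in the open quadruplex while closed-quadruplex false hits stay rare.
    """
    seq = (
        "AAAA"
        + "GGGAGGGAGGGAGGG"
        + "AA"
        + "GGGA" * 12
        + "AA"
        + "C" * 10
        + "AAAA"
    )
    assert len(seq) == 85
    ref = SequenceRecord("quad_switch", seq)
    quartet = [5, 6, 7, 9, 10, 11, 13, 14, 15, 17, 18, 19]

    folded = ConformerSpec(
        name="quad_folded",
        structure="." * 85,
        quartet_sets=[quartet],
    )
    # minor state: C block pairs the ten 3'-most filler G's
    b_gs = [56, 58, 59, 60, 62, 63, 64, 66, 67, 68]
    b_pairs = list(zip(b_gs, range(81, 71, -1)))
    open_state = ConformerSpec(
        name="quad_open",
        structure=_structure_from_pairs(85, b_pairs),
        quartet_sets=[],
    )
    spec = EnsembleSpec(
        reference=ref,
        conformers=[folded, open_state],
        proportions=list(proportions),
        n_reads=n_reads,
        dose=0.5,
        breathing=0.01,
        detection=0.95,
        background=0.001,
        min_sep=2,
        seed=seed,
    )
    return QuadSwitchScenario(
        spec=spec,
        quartet_gs=quartet,
        variable_region=(5, 81),
        b_helix_pairs=b_pairs,
    )


def m2_quartet_scenario(n_reads: int = 12000, seed: int = 5) -> tuple[EnsembleSpec, list[int]]:
    """Single-tetrad quadruplex for mutate-and-map: 4 spaced quartet G's.

    The quartet G's are mutually non-adjacent so that the read-level
    separation filter cannot mask their co-detection; a mutation installed
    at any of them opens the whole group.
    """
    L = 60
    quartet = [10, 20, 25, 35]
    seq = "".join("G" if (i + 1) in quartet else "A" for i in range(L))
    conf = ConformerSpec(name="tetrad", structure="." * L, quartet_sets=[quartet])
    spec = EnsembleSpec(
        reference=SequenceRecord("m2_quartet", seq),
        conformers=[conf],
        proportions=[1.0],
        n_reads=n_reads,
        dose=0.8,
        breathing=0.02,
        detection=0.95,
        background=0.002,
        min_sep=2,
        seed=seed,
    )
    return spec, quartet


def m2_hairpin_scenario(
    n_reads: int = 6400, seed: int = 5
) -> tuple[EnsembleSpec, dict[int, int]]:
    """A 10-bp G-C hairpin for mutate-and-map partner detection.

    Returns the ensemble and the stem's pair map (both directions).
    """
    L = 32
    seq = "G" * 10 + "A" * 12 + "C" * 10
    pairs = [(i, L + 1 - i) for i in range(1, 11)]
    structure = _structure_from_pairs(L, pairs)
    conf = ConformerSpec(name="hairpin", structure=structure)
    spec = EnsembleSpec(
        reference=SequenceRecord("m2_hairpin", seq),
        conformers=[conf],
        proportions=[1.0],
        n_reads=n_reads,
        dose=0.8,
        breathing=0.0,
        detection=0.95,
        background=0.002,
        min_sep=2,
        seed=seed,
    )
    pair_map = {i: j for i, j in pairs} | {j: i for i, j in pairs}
    return spec, pair_map


def two_state_bernoulli(
    n_reads: int = 20000,
    n_informative: int = 60,
    proportions=(0.7, 0.3),
    seed: int = 1,
) -> EnsembleSpec:
    """Two conformers with complementary accessibility over every position.

    State 1 is single-stranded over the 5' half and paired over the 3' half;
    state 2 is the mirror image, so all positions are informative for
    deconvolution.  No separation filter is applied (min_sep=0): the reads
    are exact product-Bernoulli draws, the model the mixture fit assumes.
    """
    L = n_informative
    half = L // 2
    ref = SequenceRecord("two_state", "A" * L)
    s1 = "." * half + "(" * (half // 2) + ")" * (half - half // 2)
    s2 = "(" * (half // 2) + ")" * (half - half // 2) + "." * half
    spec = EnsembleSpec(
        reference=ref,
        conformers=[
            ConformerSpec(name="state1", structure=s1),
            ConformerSpec(name="state2", structure=s2),
        ],
        proportions=list(proportions),
        n_reads=n_reads,
        dose=0.8,
        breathing=0.0,
        detection=0.95,
        background=0.001,
        min_sep=0,
        seed=seed,
    )
    return spec


def independent_readset(
    L: int = 101, p: float = 0.1, n_reads: int = 2000, seed: int = 0
) -> ReadSet:
    """Reads whose positions are independent Bernoulli(p) — the G-test null.

    No separation filter is applied, so every pair of positions is exactly
    independent and the G statistic should follow its chi-squared(1)
    reference distribution.
    """
    rng = np.random.default_rng(seed)
    bits = (rng.random((n_reads, L)) < p).astype(np.uint8)
    ref = SequenceRecord("independent", "A" * L)
    reads = [BitVector(f"null{i}", 1, L, bits[i]) for i in range(n_reads)]
    return ReadSet(ref, reads, metadata={"source": "independent_readset", "seed": seed})
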