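"""Synthetic single-molecule probing data with known ground truth.

The generator draws each read from a mixture of conformers.  A conformer is a
secondary structure plus an optional set of G groups whose N7 positions are
hydrogen bonded together (a G-quadruplex's tetrads).  Per-position
accessibility follows the qualitative ordering seen in N7G probing data:
single-stranded positions are readily methylated, helical positions are
protected by the duplex major groove, quadruplex G's are almost fully
protected, and helix-terminal G's are hyper-accessible.

Two stochastic mechanisms couple positions within one molecule:

* breathing - with a small per-molecule probability an entire quartet group
  transiently unfolds, exposing all of its G's at once.  This is the minimal
  mechanism producing correlated G-G misincorporations on single reads.
* mixture membership - reads from different conformers carry systematically
  different modification profiles.

Detection is imperfect: an adduct is observed as a misincorporation only with
probability ``detection``, and a small position-independent ``background``
rate adds spurious events.  Finally the read-level separation filter used on
real data (collapse of events closer than ``min_sep``) is applied, so the
simulated files have the same statistical quirks as parsed real reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    BitVector,
    ReadSet,
    SequenceRecord,
    collapse_close_misincorporations,
)

__all__ = [
    "AccessibilityModel",
    "ConformerSpec",
    "EnsembleSpec",
    "MutEffect",
    "simulate_reads",
    "simulate_m2_reads",
]


@dataclass(frozen=True)
class AccessibilityModel:
    """Accessibility assigned to each structural class, on a 0-1 scale.

    Values encode the observed ordering single-stranded > helix-terminal >
    paired > quadruplex; the literature gives the ordering, not absolute
    numbers, so these are calibration constants of the generator.
    """

    unpaired: float = 0.30
    paired: float = 0.03
    quartet: float = 0.005
    helix_terminal: float = 0.25


@dataclass
class ConformerSpec:
    """One conformational state: structure, quartet groups, accessibility."""

    name: str
    structure: str  # dot-bracket, length L
    quartet_sets: list[list[int]] = field(default_factory=list)  # 1-based G positions
    helix_terminal: list[int] = field(default_factory=list)  # 1-based positions
    accessibility: np.ndarray | None = None  # explicit per-position override
    access_model: AccessibilityModel = field(default_factory=AccessibilityModel)

    def validate(self, reference: SequenceRecord) -> None:
        L = len(reference)
        if len(self.structure) != L:
            raise ValueError(
                f"conformer {self.name!r}: structure length {len(self.structure)} != {L}"
            )
        depth = 0
        for c in self.structure:
            if c == "(":
                depth += 1
            elif c == ")":
                depth -= 1
                if depth < 0:
                    raise ValueError(f"conformer {self.name!r}: unbalanced structure")
            elif c != ".":
                raise ValueError(f"conformer {self.name!r}: illegal structure char {c!r}")
        if depth != 0:
            raise ValueError(f"conformer {self.name!r}: unbalanced structure")
        for qs in self.quartet_sets:
            for p in qs:
                if reference.base(p) != "G":
                    raise ValueError(
                        f"conformer {self.name!r}: quartet position {p} is not a G"
                    )

    def accessibility_vector(self, reference: SequenceRecord) -> np.ndarray:
        """Per-position accessibility in [0, 1], derived from the structure."""
        self.validate(reference)
        if self.accessibility is not None:
            a = np.asarray(self.accessibility, dtype=float)
            if a.shape != (len(reference),):
                raise ValueError("accessibility override has wrong length")
            if (a < 0).any() or (a > 1).any():
                raise ValueError("accessibility must lie in [0, 1]")
            return a.copy()
        m = self.access_model
        paired = np.array([c != "." for c in self.structure])
        a = np.where(paired, m.paired, m.unpaired).astype(float)
        for p in self.helix_terminal:
            a[p - 1] = m.helix_terminal
        for qs in self.quartet_sets:
            for p in qs:
                a[p - 1] = m.quartet
        return a

    def quartet_positions(self) -> set[int]:
        return {p for qs in self.quartet_sets for p in qs}


@dataclass
class EnsembleSpec:
    """A mixture of conformers plus the probing / detection noise model."""

    reference: SequenceRecord
    conformers: list[ConformerSpec]
    proportions: list[float]
    n_reads: int = 10000
    dose: float = 0.8  # fraction of a fully accessible site modified
    breathing: float = 0.02  # per-molecule, per-quartet-group opening probability
    detection: float = 0.95  # P(adduct observed as a misincorporation)
    background: float = 0.002  # position-independent spurious event rate
    min_sep: int = 2  # read-level misincorporation separation filter
    seed: int = 0

    def validate(self) -> None:
        pi = np.asarray(self.proportions, dtype=float)
        if len(pi) != len(self.conformers):
            raise ValueError("one proportion per conformer required")
        if abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {pi.sum()}, not 1")
        if not (0 <= self.dose <= 1):
            raise ValueError("dose must be in [0, 1]")
        if not (0 <= self.breathing < 1):
            raise ValueError("breathing must be in [0, 1)")
        if not (0 < self.detection <= 1):
            raise ValueError("detection must be in (0, 1]")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        for c in self.conformers:
            c.validate(self.reference)

    def to_json(self, path) -> None:
        payload = {
            "reference_id": self.reference.id,
            "conformers": [
                {
                    "name": c.name,
                    "structure": c.structure,
                    "quartet_sets": c.quartet_sets,
                    "helix_terminal": c.helix_terminal,
                }
                for c in self.conformers
            ],
            "proportions": list(map(float, self.proportions)),
            "n_reads": self.n_reads,
            "dose": self.dose,
            "breathing": self.breathing,
            "detection": self.detection,
            "background": self.background,
            "min_sep": self.min_sep,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _draw_bits(
    spec: EnsembleSpec,
    rng: np.random.Generator,
    states: np.ndarray,
    open_access: np.ndarray | None = None,
) -> np.ndarray:
    """Sample the raw (pre-collapse) bit matrix for reads in given states.

    ``open_access`` optionally overrides per-read accessibility rows
    (used for installed-mutation effects); otherwise rows follow each
    read's conformer, with whole quartet groups opened by breathing.
    """
    L = len(spec.reference)
    n = len(states)
    access = np.empty((n, L), dtype=float)
    base_access = [c.accessibility_vector(spec.reference) for c in spec.conformers]
    for k, conf in enumerate(spec.conformers):
        mask = states == k
        if not mask.any():
            continue
        access[mask] = base_access[k]
        # breathing: each quartet group opens all-or-none per molecule
        idx = np.flatnonzero(mask)
        for qs in conf.quartet_sets:
            opened = idx[rng.random(len(idx)) < spec.breathing]
            cols = np.array(qs, dtype=int) - 1
            for i in opened:
                access[i, cols] = 1.0
    if open_access is not None:
        override = ~np.isnan(open_access)
        access[override] = open_access[override]
    p_adduct = np.clip(spec.dose * access + spec.background, 0.0, 1.0)
    adduct = rng.random((n, L)) < p_adduct
    detected = rng.random((n, L)) < spec.detection
    return (adduct & detected).astype(np.uint8)


def _to_readset(spec: EnsembleSpec, bits: np.ndarray, prefix: str) -> ReadSet:
    L = len(spec.reference)
    reads = [
        BitVector(f"{prefix}{i}", 1, L, bits[i]) for i in range(bits.shape[0])
    ]
    rs = ReadSet(spec.reference, reads, metadata={"source": "simulate", "seed": spec.seed})
    return collapse_close_misincorporations(rs, spec.min_sep)


def simulate_reads(spec: EnsembleSpec) -> tuple[ReadSet, pd.DataFrame]:
    """Draw a ReadSet from the ensemble; returns (reads, per-read truth).

    The truth table records each read's conformer label.  Deterministic for
    a fixed spec (including seed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pi = np.asarray(spec.proportions, dtype=float)
    states = rng.choice(len(pi), size=spec.n_reads, p=pi)
    bits = _draw_bits(spec, rng, states)
    rs = _to_readset(spec, bits, "read")
    truth = pd.DataFrame(
        {
            "read_id": [r.read_id for r in rs.reads],
            "state": [spec.conformers[k].name for k in states],
            "state_index": states,
            "installed_mutation": pd.array([pd.NA] * spec.n_reads, dtype="Int64"),
        }
    )
    return rs, truth


@dataclass(frozen=True)
class MutEffect:
    """Structural consequence of an installed (PCR-derived) point mutation.

    ``quartet_open``: a mutation inside a quartet group unfolds the whole
    group for that molecule (all its G's become fully accessible), modelling
    the global destabilisation of a quadruplex by any single-G substitution.
    ``unmask_partner``: a mutation at a paired position exposes its
    base-pairing partner (partner accessibility raised to the single-strand
    level), the classic mutate-and-map signal.
    """

    quartet_open: bool = True
    unmask_partner: bool = True


def _pair_table(structure: str) -> dict[int, int]:
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, c in enumerate(structure, start=1):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            pairs[i], pairs[j] = j, i
    return pairs


def simulate_m2_reads(
    spec: EnsembleSpec, mut_effect: MutEffect | None = None
) -> tuple[ReadSet, pd.DataFrame]:
    """Mutate-and-map pool: every read carries one installed point mutation.

    The installed position is uniform over the reference; its bit is forced
    to 1 (it is a true sequence change, not a chemical event, so it is not
    subject to the separation collapse).  Structural effects of the mutation
    are applied per ``mut_effect`` before sampling chemical events.
    """
    spec.validate()
    if mut_effect is None:
        mut_effect = MutEffect()
    rng = np.random.default_rng(spec.seed)
    L = len(spec.reference)
    n = spec.n_reads
    pi = np.asarray(spec.proportions, dtype=float)
    states = rng.choice(len(pi), size=n, p=pi)
    installed = rng.integers(1, L + 1, size=n)

    open_access = np.full((n, L), np.nan)
    if mut_effect.quartet_open or mut_effect.unmask_partner:
        pair_tables = [_pair_table(c.structure) for c in spec.conformers]
        m_model = [c.access_model for c in spec.conformers]
        for i in range(n):
            k = states[i]
            m = int(installed[i])
            if mut_effect.quartet_open:
                for qs in spec.conformers[k].quartet_sets:
                    if m in qs:
                        open_access[i, np.array(qs) - 1] = 1.0
            if mut_effect.unmask_partner:
                partner = pair_tables[k].get(m)
                if partner is not None:
                    open_access[i, partner - 1] = m_model[k].unpaired

    bits = _draw_bits(spec, rng, states, open_access=open_access)
    rs = _to_readset(spec, bits, "m2read")
    # installed mutations are genuine mismatches: force after collapse
    for i, r in enumerate(rs.reads):
        r.bits[installed[i] - 1] = 1
    truth = pd.DataFrame(
        {
            "read_id": [r.read_id for r in rs.reads],
            "state": [spec.conformers[k].name for k in states],
            "state_index": states,
            "installed_mutation": pd.array(installed, dtype="Int64"),
        }
    )
    return rs, truth


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)
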