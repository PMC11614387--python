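"""Per-read constrained folding and structure-ensemble deconvolution.

The pipeline models every sequencing read as one RNA molecule:

1.  G's engaged in tertiary interactions are identified from population data:
    bottom-quartile N7G reactivity plus a positive co-occurring
    misincorporation link to another lowly reactive G.
2.  Each read's bitvector is edited: if the read carries no misincorporation
    at any tertiary G, those G's are forced single-stranded (bit set to 1) -
    the molecule presumably holds the tertiary fold, whose G's must not be
    base paired.  A read modified at a tertiary G comes from an alternative
    conformation, so its tertiary G's are instead freed for pairing (bits
    cleared).  All other G bits are cleared: N7G misincorporation status
    does not report on Watson-Crick pairing, and would wrongly force
    base-paired G's open.
3.  Every edited read is folded under the constraint that 1-bit positions
    stay unpaired.  The built-in engine maximises canonical pairs
    (AU, GC, GU; Nussinov dynamic programme with a minimum hairpin of 3 and
    a deterministic traceback); an external folding command can be plugged
    in instead.
4.  Structures are encoded as element-class vectors (stem / interior /
    multiloop / hairpin / 5' / 3'), reduced by PCA to two components, and
    clustered with k-means; each cluster is summarised by the member read
    nearest its centroid.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .io_formats import BitVector, ReadSet, SequenceRecord
from .reactivity import ReactivityProfile, bottom_quartile_gs
from .ring import PairMatrix, zscore_pairs

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


__all__ = [
    "ConstraintMask",
    "StructureEnsemble",
    "tertiary_g_set",
    "edit_bitvector",
    "fold_constrained",
    "element_vector",
    "ensemble_fold",
    "reduce_and_cluster",
]

FREE, FORCE_UNPAIRED = 0, 1

# element-class codes for encoded structures
STEM, INTERIOR, MULTILOOP, HAIRPIN, FIVEPRIME, THREEPRIME = 1, 2, 3, 4, 5, 6

_MIN_HAIRPIN = 3  # unpaired positions enclosed by any pair

_CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class ConstraintMask:
    """Per-position folding constraint: free or forced single-stranded."""

    flags: np.ndarray  # uint8, length L; 1 = force unpaired

    def __post_init__(self):
        object.__setattr__(
            self, "flags", np.asarray(self.flags, dtype=np.uint8)
        )

    def __len__(self) -> int:
        return len(self.flags)

    @classmethod
    def from_positions(cls, L: int, unpaired: set[int]) -> "ConstraintMask":
        flags = np.zeros(L, dtype=np.uint8)
        for p in unpaired:
            flags[p - 1] = FORCE_UNPAIRED
        return cls(flags)


def tertiary_g_set(
    profile: ReactivityProfile,
    pm: PairMatrix,
    z_threshold: float = 2.0,
) -> set[int]:
    """G's engaged in tertiary interactions: protected and correlated.

    A G qualifies when (a) its misincorporation rate is in the bottom
    quartile of G rates and (b) it shows a positive co-occurring
    misincorporation (Z >= z_threshold over the G-G pair population) with
    another bottom-quartile G.
    """
    bottom = bottom_quartile_gs(profile)
    if not bottom:
        return set()
    if pm.Z is None or pm.z_population != "GG":
        pm = zscore_pairs(pm, subset="GG")
    out = set()
    blist = sorted(bottom)
    for i in blist:
        for j in blist:
            if j <= i:
                continue
            z = pm.Z[i - 1, j - 1]
            if np.isfinite(z) and z >= z_threshold and pm.sign[i - 1, j - 1] > 0:
                out.add(i)
                out.add(j)
    return out


def edit_bitvector(
    read: BitVector, tertiary: set[int], g_positions: set[int]
) -> BitVector:
    """Apply tertiary-G editing to one read (returns a new BitVector).

    Reads with no misincorporation at any tertiary G have every tertiary G
    set to 1 (forced unpaired downstream); reads modified at a tertiary G
    have all tertiary G's cleared (freed for pairing).  Bits at all other
    G's are cleared either way; non-G positions are untouched.
    """
    bits = read.bits.copy()
    covered_tert = [p for p in tertiary if read.covers(p)]
    has_tert_hit = any(read.bit_at(p) for p in covered_tert)
    for p in covered_tert:
        bits[p - read.start] = 0 if has_tert_hit else 1
    for p in g_positions:
        if p not in tertiary and read.covers(p):
            bits[p - read.start] = 0
    return BitVector(read.read_id, read.start, read.end, bits)


# ---------------------------------------------------------------------------
# built-in maximum-pairing fold


@njit(cache=True)
def _nussinov_fill(pair_ok: np.ndarray) -> np.ndarray:  # pragma: no cover - numba
    L = pair_ok.shape[0]
    N = np.zeros((L, L), dtype=np.int32)
    for span in range(_MIN_HAIRPIN + 1, L):
        for i in range(L - span):
            j = i + span
            best = N[i, j - 1]
            for k in range(i, j - _MIN_HAIRPIN):
                if pair_ok[k, j]:
                    left = N[i, k - 1] if k > i else 0
                    cand = left + 1 + N[k + 1, j - 1]
                    if cand > best:
                        best = cand
            N[i, j] = best
    return N


def _nussinov_traceback(N: np.ndarray, pair_ok: np.ndarray) -> list[tuple[int, int]]:
    """Deterministic traceback: pair j with its 5'-most optimal partner."""
    pairs = []
    stack = [(0, N.shape[0] - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= _MIN_HAIRPIN:
            continue
        target = N[i, j]
        found = False
        for k in range(i, j - _MIN_HAIRPIN):
            if not pair_ok[k, j]:
                continue
            left = N[i, k - 1] if k > i else 0
            if left + 1 + N[k + 1, j - 1] == target:
                pairs.append((k, j))
                if k > i:
                    stack.append((i, k - 1))
                stack.append((k + 1, j - 1))
                found = True
                break
        if not found:
            stack.append((i, j - 1))
    return pairs


def _pairable_matrix(seq: str, mask: np.ndarray) -> np.ndarray:
    L = len(seq)
    ok = np.zeros((L, L), dtype=np.bool_)
    free = mask != FORCE_UNPAIRED
    for i in range(L):
        if not free[i]:
            continue
        for j in range(i + _MIN_HAIRPIN + 1, L):
            if free[j] and (seq[i], seq[j]) in _CANONICAL:
                ok[i, j] = True
    return ok


def fold_builtin(seq: str, mask: ConstraintMask) -> str:
    """Deterministic maximum canonical base pairing under the mask."""
    L = len(seq)
    if len(mask) != L:
        raise ValueError("mask length does not match sequence")
    if L <= _MIN_HAIRPIN:
        return "." * L
    pair_ok = _pairable_matrix(seq, mask.flags)
    N = _nussinov_fill(pair_ok)
    pairs = _nussinov_traceback(N, pair_ok)
    db = ["."] * L
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return "".join(db)


def _run_external(cmd: str, seq: str, mask: ConstraintMask) -> str:
    """Shell out to a user-supplied folding command.

    The command receives two lines on stdin - the sequence and a constraint
    string ('x' = force unpaired, '.' = free) - and must print a dot-bracket
    structure of the same length on stdout.
    """
    constraint = "".join("x" if f else "." for f in mask.flags)
    proc = subprocess.run(
        cmd,
        shell=True,
        input=f"{seq}\n{constraint}\n",
        capture_output=True,
        text=True,
    )
    if proc.returncode != 0:
        raise RuntimeError(f"external folding command failed: {proc.stderr.strip()}")
    db = proc.stdout.strip().splitlines()[-1].strip() if proc.stdout.strip() else ""
    if len(db) != len(seq) or set(db) - set("()."):
        raise RuntimeError("external folder returned a malformed structure")
    return db


def fold_constrained(
    seq: str, mask: ConstraintMask, backend: str = "builtin", command: str | None = None
) -> str:
    """Fold ``seq`` so that no force_unpaired position is paired.

    ``backend="builtin"`` uses the deterministic maximum-pairing dynamic
    programme; ``backend="external"`` runs ``command`` (see
    :func:`_run_external`).  A constraint violation or unbalanced output is
    a hard error regardless of backend.
    """
    seq = seq.upper().replace("T", "U")
    if backend == "builtin":
        db = fold_builtin(seq, mask)
    elif backend == "external":
        if not command:
            raise ValueError("external backend requires a folding command")
        db = _run_external(command, seq, mask)
    else:
        raise ValueError(f"unknown folding backend {backend!r}")
    _check_structure(db, mask)
    return db


def _check_structure(db: str, mask: ConstraintMask) -> None:
    depth = 0
    for i, c in enumerate(db):
        if c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
        if depth < 0:
            raise RuntimeError("unbalanced structure")
        if c != "." and mask.flags[i] == FORCE_UNPAIRED:
            raise RuntimeError(f"constraint violated: position {i + 1} is paired")
    if depth != 0:
        raise RuntimeError("unbalanced structure")


# ---------------------------------------------------------------------------
# element-class encoding


def _pairs_of(db: str) -> dict[int, int]:
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            j = stack.pop()
            pairs[i], pairs[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return pairs


def element_vector(db: str) -> np.ndarray:
    """Per-position structural element class of a dot-bracket string.

    Classes: 1 stem, 2 interior/bulge loop, 3 multiloop, 4 hairpin loop,
    5 unpaired 5' of the first helix, 6 unpaired 3' of the last helix.
    Unpaired stretches of the exterior loop between helices are multiloop
    segments.  Derived purely from the pairing pattern.
    """
    L = len(db)
    pairs = _pairs_of(db)
    out = np.zeros(L, dtype=np.int8)
    for i in pairs:
        out[i] = STEM

    def classify_loop(i: int, j: int) -> None:
        """Classify unpaired positions directly inside pair (i, j)."""
        children = 0
        unpaired: list[int] = []
        p = i + 1
        while p < j:
            if p in pairs:
                children += 1
                q = pairs[p]
                classify_loop(p, q)
                p = q + 1
            else:
                unpaired.append(p)
                p += 1
        cls = HAIRPIN if children == 0 else (INTERIOR if children == 1 else MULTILOOP)
        for p in unpaired:
            out[p] = cls

    paired_idx = sorted(p for p in pairs if p < pairs[p])
    # exterior level
    p = 0
    exterior_unpaired: list[int] = []
    ext_helices = []
    while p < L:
        if p in pairs and pairs[p] > p:
            ext_helices.append(p)
            classify_loop(p, pairs[p])
            p = pairs[p] + 1
        else:
            exterior_unpaired.append(p)
            p += 1
    if not paired_idx:
        out[:] = FIVEPRIME
        return out
    first = min(pairs)
    last = max(pairs)
    for p in exterior_unpaired:
        if p < first:
            out[p] = FIVEPRIME
        elif p > last:
            out[p] = THREEPRIME
        else:
            out[p] = MULTILOOP
    return out


# ---------------------------------------------------------------------------
# ensemble folding, reduction, clustering


@dataclass
class StructureEnsemble:
    """Per-read structures and their downstream representations."""

    reference: SequenceRecord
    read_ids: list[str]
    structures: list[str]
    elements: np.ndarray  # (n, L) int8 element classes
    tertiary: set[int] = field(default_factory=set)
    pca: np.ndarray | None = None  # (n, 2)
    clusters: np.ndarray | None = None  # (n,)
    representatives: dict[int, int] = field(default_factory=dict)  # cluster -> row
    consensus: dict[int, np.ndarray] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.read_ids)

    def cluster_proportions(self) -> np.ndarray:
        if self.clusters is None:
            raise ValueError("ensemble not clustered yet")
        counts = np.bincount(self.clusters)
        return counts / counts.sum()

    def representative_structure(self, cluster: int) -> str:
        return self.structures[self.representatives[cluster]]

    def to_frame(self) -> pd.DataFrame:
        d = {"read_id": self.read_ids, "structure": self.structures}
        if self.pca is not None:
            d["pc1"], d["pc2"] = self.pca[:, 0], self.pca[:, 1]
        if self.clusters is not None:
            d["cluster"] = self.clusters
        return pd.DataFrame(d)


def ensemble_fold(
    rs: ReadSet,
    tertiary: set[int],
    backend: str = "builtin",
    command: str | None = None,
    max_reads: int = 10000,
) -> StructureEnsemble:
    """Edit, constrain and fold the most modified reads of a ReadSet.

    Reads are ranked by misincorporation count (descending, ties in input
    order) and the top ``max_reads`` taken; each is edited for tertiary G's,
    its 1-bits become force-unpaired constraints, and the read is folded.
    Identical constraint masks are folded once and cached.
    """
    if not rs.all_full_length():
        raise ValueError("ensemble_fold requires full-length reads")
    seq = rs.reference.seq
    g_positions = set(rs.reference.positions_of("G").tolist())
    order = sorted(
        range(len(rs.reads)),
        key=lambda k: -int(rs.reads[k].bits.sum()),
    )[:max_reads]
    order.sort()  # keep input order among the selected reads

    read_ids, structures, elems = [], [], []
    cache: dict[bytes, tuple[str, np.ndarray]] = {}
    for k in order:
        edited = edit_bitvector(rs.reads[k], tertiary, g_positions)
        key = edited.bits.tobytes()
        hit = cache.get(key)
        if hit is None:
            mask = ConstraintMask(edited.bits)
            db = fold_constrained(seq, mask, backend=backend, command=command)
            hit = (db, element_vector(db))
            cache[key] = hit
        read_ids.append(rs.reads[k].read_id)
        structures.append(hit[0])
        elems.append(hit[1])
    elements = (
        np.stack(elems) if elems else np.zeros((0, rs.L), dtype=np.int8)
    )
    return StructureEnsemble(
        reference=rs.reference,
        read_ids=read_ids,
        structures=structures,
        elements=elements,
        tertiary=set(tertiary),
    )


def reduce_and_cluster(
    se: StructureEnsemble, K: int, seed: int = 0, one_hot: bool = False
) -> StructureEnsemble:
    """PCA (2 components, deterministic sign) + k-means on element vectors.

    The representative of each cluster is the read whose 2-D coordinates lie
    nearest the cluster centroid; a per-position majority element class is
    also recorded as the cluster consensus.  With ``one_hot`` the element
    classes are indicator-encoded before reduction instead of being used as
    raw integers.
    """
    X = se.elements.astype(float)
    if one_hot:
        classes = np.arange(1, 7)
        X = (se.elements[:, :, None] == classes[None, None, :]).reshape(len(se), -1).astype(float)
    n_comp = min(2, X.shape[0], X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(X)
    if coords.shape[1] < 2:
        coords = np.hstack([coords, np.zeros((coords.shape[0], 2 - coords.shape[1]))])
    # deterministic sign: the loading with largest magnitude is positive
    for c in range(min(n_comp, pca.components_.shape[0])):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            pca.components_[c] *= -1
            coords[:, c] *= -1
    km = KMeans(n_clusters=K, n_init=10, random_state=seed)
    labels = km.fit_predict(coords)
    reps: dict[int, int] = {}
    consensus: dict[int, np.ndarray] = {}
    for c in range(K):
        members = np.flatnonzero(labels == c)
        if len(members) == 0:
            continue
        d = np.linalg.norm(coords[members] - km.cluster_centers_[c], axis=1)
        reps[c] = int(members[np.argmin(d)])
        cons = np.zeros(se.elements.shape[1], dtype=np.int8)
        for pos in range(se.elements.shape[1]):
            vals, counts = np.unique(se.elements[members, pos], return_counts=True)
            cons[pos] = vals[np.argmax(counts)]
        consensus[c] = cons
    return StructureEnsemble(
        reference=se.reference,
        read_ids=se.read_ids,
        structures=se.structures,
        elements=se.elements,
        tertiary=se.tertiary,
        pca=coords,
        clusters=labels,
        representatives=reps,
        consensus=consensus,
    )
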