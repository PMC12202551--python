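"""LOV-domain mining from protein sequences.

Putative LOV domains are recognised through the superconserved nine-residue
motif G-x-N-C-R-F-L-Q-G.  Two tolerated variants occur in natural sequences:
a proline replacing the photoactive cysteine (position 4) and a tyrosine
replacing the conserved phenylalanine (position 6).  Candidates are then
scored against a user-supplied table of additional conserved alignment
columns, compared by p-distance, and grouped with a neighbor-joining tree.

Coordinates are 1-based throughout; motif start positions refer to the
unaligned sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import DegenerateDataError, InputError

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Alphabet accepted in unaligned sequences ('X' = unknown residue).
SEQ_ALPHABET = AMINO_ACIDS | {"X"}
#: Aligned sequences may additionally carry the gap character.
ALIGNED_ALPHABET = SEQ_ALPHABET | {"-"}

MOTIF_LENGTH = 9

VARIANT_CANONICAL = "canonical"
VARIANT_CYS_TO_PRO = "cys_to_pro"
VARIANT_PHE_TO_TYR = "phe_to_tyr"
VARIANT_OTHER = "other_tolerated"


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with identifier and free-text description."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("sequence record requires a non-empty id")
        if not self.seq:
            raise InputError(f"record {self.id!r}: empty sequence")

    @property
    def is_aligned(self) -> bool:
        return "-" in self.seq


@dataclass(frozen=True)
class MotifHit:
    """One match of the LOV motif in an unaligned sequence (1-based start)."""

    record_id: str
    start: int
    matched: str
    variant_class: str

    def __post_init__(self) -> None:
        if len(self.matched) != MOTIF_LENGTH:
            raise InputError("motif match must be 9 residues long")
        if self.start < 1:
            raise InputError("motif start is 1-based and must be >= 1")


@dataclass(frozen=True)
class ConservationScore:
    """Fraction of screened conserved alignment columns matched by a record."""

    record_id: str
    n_checked: int
    n_matched: int

    @property
    def fraction(self) -> float:
        return self.n_matched / self.n_checked


def _validate_unaligned(record: SequenceRecord) -> None:
    for i, ch in enumerate(record.seq, start=1):
        if ch not in SEQ_ALPHABET:
            raise InputError(
                f"record {record.id!r}: non-amino-acid character {ch!r} "
                f"at position {i}"
            )


def _classify_motif(matched: str) -> str:
    cys = matched[3] == "C"
    phe = matched[5] == "F"
    if cys and phe:
        return VARIANT_CANONICAL
    if not cys and phe:
        return VARIANT_CYS_TO_PRO
    if cys and not phe:
        return VARIANT_PHE_TO_TYR
    return VARIANT_OTHER


def _motif_matches(window: str, tolerate_variants: bool) -> bool:
    pos4 = ("C", "P") if tolerate_variants else ("C",)
    pos6 = ("F", "Y") if tolerate_variants else ("F",)
    return (
        window[0] == "G"
        and window[2] == "N"
        and window[3] in pos4
        and window[4] == "R"
        and window[5] in pos6
        and window[6] == "L"
        and window[7] == "Q"
        and window[8] == "G"
    )


def scan_lov_motif(
    record: SequenceRecord, tolerate_variants: bool = True
) -> list[MotifHit]:
    """Scan an unaligned sequence for the superconserved LOV motif.

    The pattern is G-x-N-[C/P]-R-[F/Y]-L-Q-G when ``tolerate_variants`` is
    on and the strict G-x-N-C-R-F-L-Q-G otherwise.  All (possibly
    overlapping) hits are returned in ascending start order.
    """
    if record.is_aligned:
        raise InputError(
            f"record {record.id!r}: motif scanning requires an unaligned "
            "sequence (gaps present)"
        )
    _validate_unaligned(record)
    seq = record.seq
    hits = []
    for start0 in range(len(seq) - MOTIF_LENGTH + 1):
        window = seq[start0 : start0 + MOTIF_LENGTH]
        if _motif_matches(window, tolerate_variants):
            hits.append(
                MotifHit(
                    record_id=record.id,
                    start=start0 + 1,
                    matched=window,
                    variant_class=_classify_motif(window),
                )
            )
    return hits


def screen_conserved_residues(
    record: SequenceRecord,
    positions: Mapping[int, Iterable[str]],
) -> ConservationScore:
    """Score an aligned record against a conserved-column table.

    ``positions`` maps 1-based alignment columns to the residue set allowed
    at that column.  Gaps never match.
    """
    if not positions:
        raise InputError("positions mapping is empty")
    for ch in record.seq:
        if ch not in ALIGNED_ALPHABET:
            raise InputError(
                f"record {record.id!r}: invalid character {ch!r}"
            )
    n = len(record.seq)
    n_matched = 0
    for col, allowed in positions.items():
        if not 1 <= col <= n:
            raise InputError(
                f"column {col} outside alignment of length {n}"
            )
        ch = record.seq[col - 1]
        if ch != "-" and ch in set(allowed):
            n_matched += 1
    return ConservationScore(
        record_id=record.id, n_checked=len(positions), n_matched=n_matched
    )


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with ordered labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise InputError("distance matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise InputError("duplicate labels in distance matrix")
        if not np.allclose(self.d, self.d.T):
            raise InputError("distance matrix must be symmetric")
        if np.any(self.d < 0):
            raise InputError("distance matrix must be nonnegative")
        if np.any(np.diag(self.d) != 0):
            raise InputError("distance matrix diagonal must be zero")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])


def p_distance_matrix(alignment: Sequence[SequenceRecord]) -> DistanceMatrix:
    """Pairwise p-distances over an alignment.

    For each pair, columns where either record has a gap are excluded; the
    distance is mismatches / compared columns.  A pair with zero comparable
    columns is degenerate and raises.
    """
    if len(alignment) < 2:
        raise InputError("p-distance needs at least two records")
    length = len(alignment[0].seq)
    for rec in alignment:
        if len(rec.seq) != length:
            raise InputError(
                f"record {rec.id!r}: length {len(rec.seq)} != {length}"
            )
    labels = [rec.id for rec in alignment]
    if len(set(labels)) != len(labels):
        raise InputError("duplicate record ids in alignment")
    seqs = np.array([list(rec.seq) for rec in alignment])
    gaps = seqs == "-"
    n = len(alignment)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ok = ~(gaps[i] | gaps[j])
        n_ok = int(ok.sum())
        if n_ok == 0:
            raise DegenerateDataError(
                f"records {labels[i]!r} and {labels[j]!r} share no "
                "comparable (gap-free) columns"
            )
        mism = int((seqs[i, ok] != seqs[j, ok]).sum())
        d[i, j] = d[j, i] = mism / n_ok
    return DistanceMatrix(labels=labels, d=d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; ``children`` pairs (child, branch length)."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Unrooted tree produced by neighbor joining."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        names: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                names.append(node.name)
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return names

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name
            inner = ",".join(
                f"{fmt(child)}:{bl:.10g}" for child, bl in node.children
            )
            return f"({inner})"

        return fmt(self.root) + ";"

    def leaf_distances(self) -> DistanceMatrix:
        """Patristic (path-length) distances between all leaf pairs."""
        leaves = self.leaf_names()
        n = len(leaves)
        index = {name: i for i, name in enumerate(leaves)}
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            sub = []
            for child, bl in node.children:
                part = walk(child)
                sub.append({leaf: d0 + bl for leaf, d0 in part.items()})
            for a, b in itertools.combinations(range(len(sub)), 2):
                for la, da in sub[a].items():
                    for lb, db in sub[b].items():
                        i, j = index[la], index[lb]
                        d[i, j] = d[j, i] = da + db
            merged: dict[str, float] = {}
            for part in sub:
                merged.update(part)
            return merged

        walk(self.root)
        return DistanceMatrix(labels=leaves, d=d)


def _clamp_pair(li: float, lj: float, dij: float) -> tuple[float, float]:
    # Negative NJ branch estimates are clamped to zero and the deficit moved
    # to the sibling edge so the pair's path length d(i,j) is conserved.
    if li < 0:
        return 0.0, dij
    if lj < 0:
        return dij, 0.0
    return li, lj


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining on a distance matrix.

    Ties in the Q criterion are broken deterministically by choosing the
    pair whose (lexicographically smallest leaf label, partner label) sorts
    first.  Negative branch-length estimates are clamped to zero with the
    deficit transferred to the sibling edge.  The returned tree is unrooted
    (trifurcating root for >= 3 taxa).
    """
    n = len(dm.labels)
    if n < 2:
        raise InputError("neighbor joining needs at least 2 labels")
    if n == 2:
        a, b = dm.labels
        root = TreeNode(
            children=[
                (TreeNode(name=a), dm.d[0, 1] / 2.0),
                (TreeNode(name=b), dm.d[0, 1] / 2.0),
            ]
        )
        return Tree(root=root)

    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=lab) for i, lab in enumerate(dm.labels)
    }
    # sort key of a cluster = smallest leaf label it contains
    keys: dict[int, str] = {i: lab for i, lab in enumerate(dm.labels)}
    d = {
        (i, j): float(dm.d[i, j])
        for i, j in itertools.combinations(range(n), 2)
    }

    def get(i: int, j: int) -> float:
        return d[(i, j)] if i < j else d[(j, i)]

    active = list(range(n))
    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for i, j in itertools.combinations(active, 2):
            q = (m - 2) * get(i, j) - r[i] - r[j]
            tie = tuple(sorted((keys[i], keys[j])))
            cand = (q, tie, (i, j))
            if best is None or cand[:2] < best[:2]:
                best = cand
        _, _, (i, j) = best
        dij = get(i, j)
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj, dij)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        nodes[next_id] = new
        keys[next_id] = min(keys[i], keys[j])
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (get(i, k) + get(j, k) - dij)
            key = (min(next_id, k), max(next_id, k))
            d[key] = max(dk, 0.0)
        active = [k for k in active if k not in (i, j)] + [next_id]
        nodes.pop(i), nodes.pop(j)
        next_id += 1

    # resolve the final three clusters with the three-point formulas
    a, b, c = sorted(active, key=lambda k: keys[k])
    dab, dac, dbc = get(a, b), get(a, c), get(b, c)
    la = (dab + dac - dbc) / 2.0
    lb = (dab + dbc - dac) / 2.0
    lc = (dac + dbc - dab) / 2.0
    root = TreeNode(
        children=[
            (nodes[a], max(la, 0.0)),
            (nodes[b], max(lb, 0.0)),
            (nodes[c], max(lc, 0.0)),
        ]
    )
    return Tree(root=root)
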