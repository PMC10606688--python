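"""Inter-population structure: AMOVA-based Rst, permutation tests, classical
multidimensional scaling, and neighbor-joining trees with Newick output.

Rst is estimated from a two-level analysis of molecular variance over squared
repeat-count differences: with d(i,j) = sum_l (x_il - x_jl)^2,

    SSD_total  = (1/2N) sum_i sum_j d(i,j)
    SSD_within = sum_p (1/2 n_p) sum_{i,j in p} d(i,j)
    SSD_among  = SSD_total - SSD_within
    MSD_among  = SSD_among / (P-1),  MSD_within = SSD_within / (N-P)
    n_c        = (N - sum_p n_p^2 / N) / (P-1)
    sigma2_a   = (MSD_among - MSD_within) / n_c
    Rst        = sigma2_a / (sigma2_a + MSD_within)

which, for squared Euclidean d, reduces to sums of squares about group and
grand means.  Significance comes from permuting individuals across
populations with group sizes held fixed.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.linalg

from .data import Haplotype, PopulationDataset, expected_copies
from .errors import ConfigError, YstrError

logger = logging.getLogger(__name__)

__all__ = [
    "RstResult",
    "DistanceMatrix",
    "encode_repeat_matrix",
    "amova_rst",
    "pairwise_rst",
    "rst_permutation_test",
    "bonferroni_threshold",
    "rst_matrix",
    "MdsResult",
    "classical_mds",
    "NjTree",
    "neighbor_joining",
    "write_newick",
    "read_newick",
]


# ---------------------------------------------------------------------------
# encoding haplotypes as repeat-count matrices
# ---------------------------------------------------------------------------

def encode_repeat_matrix(
    haplotypes: Sequence[Haplotype],
    loci: Sequence[str],
    *,
    cnv_policy: str = "drop",
    microvariant_policy: str = "value",
) -> tuple[np.ndarray, int]:
    """Encode haplotypes as an (n_kept, n_loci) float matrix of repeat counts.

    ``cnv_policy="drop"`` requires single-copy loci and drops individuals with
    missing or multi-allele calls at any chosen locus; ``"mean"`` instead uses
    the mean of the allele multiset (and admits multi-copy loci).
    ``microvariant_policy`` is ``"value"`` (13.1 enters as 13.1) or
    ``"round"`` (truncate to integer repeats).

    Returns the matrix and the number of dropped individuals.
    """
    if cnv_policy not in ("drop", "mean"):
        raise ConfigError(f"unknown cnv_policy {cnv_policy!r}")
    if microvariant_policy not in ("value", "round"):
        raise ConfigError(f"unknown microvariant_policy {microvariant_policy!r}")
    if not loci:
        raise ConfigError("empty locus list")
    if cnv_policy == "drop":
        multi = [l for l in loci if expected_copies(l) > 1]
        if multi:
            raise ConfigError(
                "multi-copy loci need cnv_policy='mean' or exclusion from the "
                f"locus list: {', '.join(multi)}"
            )

    def allele_value(a) -> float:
        return float(a.repeats) if microvariant_policy == "round" else a.value

    rows: list[list[float]] = []
    dropped = 0
    for h in haplotypes:
        row: list[float] = []
        for locus in loci:
            call = h.calls.get(locus)
            if call is None:
                row = []
                break
            if cnv_policy == "drop" and call.size != 1:
                row = []
                break
            row.append(
                float(np.mean([allele_value(a) for a in call.alleles]))
            )
        if row:
            rows.append(row)
        else:
            dropped += 1
    return np.asarray(rows, dtype=float), dropped


# ---------------------------------------------------------------------------
# AMOVA / Rst
# ---------------------------------------------------------------------------

def _rst_from_stacked(x: np.ndarray, sizes: np.ndarray) -> float:
    """Rst for groups stacked in ``x`` with ``sizes[p]`` rows per group."""
    n = x.shape[0]
    p = len(sizes)
    grand = x.mean(axis=0)
    ssd_total = float(((x - grand) ** 2).sum())
    starts = np.concatenate(([0], np.cumsum(sizes)[:-1]))
    group_means = np.add.reduceat(x, starts, axis=0) / sizes[:, None]
    ssd_among = float((sizes[:, None] * (group_means - grand) ** 2).sum())
    ssd_within = ssd_total - ssd_among
    msd_among = ssd_among / (p - 1)
    msd_within = ssd_within / (n - p)
    n_c = (n - float((sizes**2).sum()) / n) / (p - 1)
    sigma2_a = (msd_among - msd_within) / n_c
    denom = sigma2_a + msd_within
    if denom == 0.0:
        return 0.0
    return sigma2_a / denom


def amova_rst(groups: Sequence[np.ndarray]) -> float:
    """Rst from per-population repeat matrices (rows = individuals)."""
    if len(groups) < 2:
        raise YstrError("Rst needs at least two populations")
    sizes = np.array([g.shape[0] for g in groups])
    if (sizes < 2).any():
        raise YstrError(
            "each population needs >= 2 usable individuals, got sizes "
            f"{sizes.tolist()}"
        )
    x = np.vstack([np.atleast_2d(g) for g in groups])
    return _rst_from_stacked(x, sizes)


@dataclass(frozen=True)
class RstResult:
    """Pairwise Rst with optional permutation p-value."""

    pop_a: str
    pop_b: str
    rst: float
    p_value: float | None
    permutations: int
    loci_used: tuple[str, ...]
    n_a: int
    n_b: int
    dropped_a: int = 0
    dropped_b: int = 0


def _encode_pair(a, b, loci, cnv_policy, microvariant_policy):
    xa, dropped_a = encode_repeat_matrix(
        a.haplotypes, loci, cnv_policy=cnv_policy,
        microvariant_policy=microvariant_policy,
    )
    xb, dropped_b = encode_repeat_matrix(
        b.haplotypes, loci, cnv_policy=cnv_policy,
        microvariant_policy=microvariant_policy,
    )
    for ds, x, dr in ((a, xa, dropped_a), (b, xb, dropped_b)):
        if dr:
            logger.info(
                "population %s: dropped %d individual(s) with missing/CNV "
                "calls at the Rst loci", ds.name, dr,
            )
        if x.shape[0] < 2:
            raise YstrError(
                f"population {ds.name!r} has fewer than 2 usable individuals "
                "after filtering"
            )
    return xa, xb, dropped_a, dropped_b


def pairwise_rst(
    a: PopulationDataset,
    b: PopulationDataset,
    loci: Sequence[str],
    *,
    permutations: int = 0,
    seed: int | None = None,
    cnv_policy: str = "drop",
    microvariant_policy: str = "value",
) -> RstResult:
    """Rst between two populations, optionally with a permutation p-value."""
    xa, xb, dropped_a, dropped_b = _encode_pair(
        a, b, loci, cnv_policy, microvariant_policy
    )
    sizes = np.array([xa.shape[0], xb.shape[0]])
    pooled = np.vstack([xa, xb])
    observed = _rst_from_stacked(pooled, sizes)
    p_value = None
    if permutations:
        if seed is None:
            raise ConfigError("a seed is required for the permutation test")
        p_value = _permutation_p_value(pooled, sizes, observed, permutations, seed)
    return RstResult(
        pop_a=a.name, pop_b=b.name, rst=observed, p_value=p_value,
        permutations=permutations, loci_used=tuple(loci),
        n_a=int(sizes[0]), n_b=int(sizes[1]),
        dropped_a=dropped_a, dropped_b=dropped_b,
    )


def _permutation_p_value(pooled, sizes, observed, b, seed) -> float:
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(b):
        perm = rng.permutation(pooled.shape[0])
        if _rst_from_stacked(pooled[perm], sizes) >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (b + 1)


def rst_permutation_test(
    a: PopulationDataset,
    b: PopulationDataset,
    loci: Sequence[str],
    permutations: int,
    seed: int,
    **kwargs,
) -> float:
    """p-value for Rst(a, b) under random reassignment of individuals.

    Labels are permuted across the pooled individuals with group sizes held
    fixed; p = (#{Rst* >= Rst_obs} + 1) / (B + 1).
    """
    if permutations < 100:
        raise ConfigError("use at least 100 permutations")
    result = pairwise_rst(
        a, b, loci, permutations=permutations, seed=seed, **kwargs
    )
    assert result.p_value is not None
    return result.p_value


def bonferroni_threshold(alpha: float, k: int) -> float:
    """Per-test significance level alpha/k, rounded to 2 significant figures."""
    if not 0 < alpha < 1:
        raise ConfigError(f"alpha must be in (0,1), got {alpha}")
    if k < 1:
        raise ConfigError(f"number of comparisons must be >= 1, got {k}")
    return float(f"{alpha / k:.1e}")


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal matrix over labelled populations."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise YstrError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise YstrError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise YstrError("distance matrix diagonal is not zero")

    def __len__(self) -> int:
        return len(self.labels)

    def clamped(self) -> "DistanceMatrix":
        """Copy with negative entries (possible for raw Rst) clamped to 0."""
        return DistanceMatrix(list(self.labels), np.maximum(self.values, 0.0))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["", *self.labels])
            for label, row in zip(self.labels, self.values):
                writer.writerow([label, *(f"{v:.6g}" for v in row)])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        with open(path, encoding="utf-8", newline="") as fh:
            rows = list(csv.reader(fh, delimiter="\t"))
        if not rows or len(rows) < 2:
            raise YstrError(f"{path}: not a distance matrix")
        labels = rows[0][1:]
        values = []
        for row in rows[1:]:
            if len(row) != len(labels) + 1:
                raise YstrError(f"{path}: ragged matrix row {row[:1]}")
            try:
                values.append([float(v) for v in row[1:]])
            except ValueError as exc:
                raise YstrError(f"{path}: non-numeric entry ({exc})") from None
        row_labels = [r[0] for r in rows[1:]]
        if row_labels != labels:
            raise YstrError(f"{path}: row/column labels disagree")
        return cls(labels, np.asarray(values))


def rst_matrix(
    datasets: Sequence[PopulationDataset],
    loci: Sequence[str],
    *,
    permutations: int = 0,
    seed: int | None = None,
    cnv_policy: str = "drop",
    microvariant_policy: str = "value",
) -> tuple[DistanceMatrix, np.ndarray | None]:
    """All pairwise Rst values (raw, may be negative) and permutation p-values.

    Each pair draws an independent permutation stream spawned from ``seed``,
    so the matrix is reproducible and permutation-equivariant under input
    relabelling up to the seed assignment.
    """
    if len(datasets) < 2:
        raise YstrError("need at least two populations")
    labels = [d.name for d in datasets]
    if len(set(labels)) != len(labels):
        raise YstrError("population names must be unique")
    n = len(datasets)
    values = np.zeros((n, n))
    pvals = np.full((n, n), np.nan) if permutations else None
    if permutations and seed is None:
        raise ConfigError("a seed is required for the permutation test")
    pair_seeds = None
    if permutations:
        n_pairs = n * (n - 1) // 2
        pair_seeds = iter(np.random.SeedSequence(seed).spawn(n_pairs))
    for i in range(n):
        for j in range(i + 1, n):
            pair_seed = next(pair_seeds) if pair_seeds else None
            res = pairwise_rst(
                datasets[i], datasets[j], loci,
                permutations=permutations, seed=pair_seed,
                cnv_policy=cnv_policy, microvariant_policy=microvariant_policy,
            )
            values[i, j] = values[j, i] = res.rst
            if pvals is not None:
                pvals[i, j] = pvals[j, i] = res.p_value
    if pvals is not None:
        np.fill_diagonal(pvals, 1.0)
    return DistanceMatrix(labels, values), pvals


# ---------------------------------------------------------------------------
# classical MDS (principal coordinates)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MdsResult:
    labels: tuple[str, ...]
    coordinates: np.ndarray  # (n_labels, dims)
    eigenvalues: np.ndarray

    def to_tsv(self, path: str | Path) -> None:
        dims = self.coordinates.shape[1]
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["label", *(f"dim{i + 1}" for i in range(dims))])
            for label, row in zip(self.labels, self.coordinates):
                writer.writerow([label, *(f"{v:.10g}" for v in row)])


def classical_mds(matrix: DistanceMatrix, dims: int = 2) -> MdsResult:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centers the squared distances, eigendecomposes, and keeps the top
    ``dims`` axes scaled by the square root of their (positive) eigenvalues;
    non-positive eigenvalues contribute zero coordinates.  Each axis is
    oriented so its largest-magnitude coordinate is positive.
    """
    d = matrix.clamped().values
    n = d.shape[0]
    if dims < 1:
        raise ConfigError("dims must be >= 1")
    if dims > n:
        logger.warning("dims=%d exceeds matrix size %d; padding zeros", dims, n)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    b = (b + b.T) / 2.0  # guard symmetry against round-off
    eigvals, eigvecs = scipy.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    coords = np.zeros((n, dims))
    cutoff = max(eigvals[0], 0.0) * n * np.finfo(float).eps
    for axis in range(min(dims, n)):
        lam = eigvals[axis]
        if lam > cutoff:
            coords[:, axis] = eigvecs[:, axis] * np.sqrt(lam)
    # deterministic axis orientation
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    return MdsResult(tuple(matrix.labels), coords, eigvals)


def plot_mds(result: MdsResult, path: str | Path) -> None:  # pragma: no cover
    """Cosmetic 2-D scatter of an MDS embedding (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    xs, ys = result.coordinates[:, 0], result.coordinates[:, 1]
    ax.scatter(xs, ys)
    for label, x, y in zip(result.labels, xs, ys):
        ax.annotate(label, (x, y), fontsize=8)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

_NEWICK_UNSAFE = re.compile(r"[\s()\[\]{}:;,'\"]")


def _format_label(label: str) -> str:
    if label == "":
        raise YstrError("empty leaf labels are not allowed in Newick output")
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


class NjTree:
    """An unrooted tree with labelled leaves and branch lengths.

    Stored as an adjacency map over integer node ids; leaves carry labels.
    """

    def __init__(
        self,
        adjacency: dict[int, dict[int, float]],
        leaf_labels: dict[int, str],
    ):
        self.adjacency = adjacency
        self.leaf_labels = dict(leaf_labels)
        labels = list(self.leaf_labels.values())
        if len(set(labels)) != len(labels):
            raise YstrError("duplicate leaf labels")

    @property
    def leaves(self) -> list[str]:
        return sorted(self.leaf_labels.values())

    @property
    def n_internal(self) -> int:
        return len(self.adjacency) - len(self.leaf_labels)

    def path_length(self, label_a: str, label_b: str) -> float:
        """Sum of branch lengths along the unique path between two leaves."""
        ids = {v: k for k, v in self.leaf_labels.items()}
        start, goal = ids[label_a], ids[label_b]
        stack = [(start, -1, 0.0)]
        while stack:
            node, parent, dist = stack.pop()
            if node == goal:
                return dist
            for nbr, length in self.adjacency[node].items():
                if nbr != parent:
                    stack.append((nbr, node, dist + length))
        raise YstrError("disconnected tree")  # pragma: no cover

    def distance_matrix(self) -> DistanceMatrix:
        labels = self.leaves
        n = len(labels)
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = self.path_length(
                    labels[i], labels[j]
                )
        return DistanceMatrix(labels, values)

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions (one side each) induced by internal edges."""
        all_leaves = frozenset(self.leaf_labels.values())
        out: set[frozenset[str]] = set()
        for a in self.adjacency:
            for b in self.adjacency[a]:
                if a < b:
                    side = frozenset(self._leaves_beyond(b, a))
                    if 1 < len(side) < len(all_leaves) - 1:
                        out.add(min(side, all_leaves - side, key=sorted))
        return out

    def _leaves_beyond(self, node: int, parent: int) -> Iterable[str]:
        if node in self.leaf_labels:
            yield self.leaf_labels[node]
            return
        for nbr in self.adjacency[node]:
            if nbr != parent:
                yield from self._leaves_beyond(nbr, node)

    def same_as(self, other: "NjTree", tol: float = 1e-9) -> bool:
        """Equal leaf sets, topology, and all leaf-to-leaf path lengths."""
        if self.leaves != other.leaves:
            return False
        if self.splits() != other.splits():
            return False
        mine = self.distance_matrix().values
        theirs = other.distance_matrix().values
        return bool(np.allclose(mine, theirs, atol=tol))

    def to_newick(self, precision: int = 6) -> str:
        """Newick string rooted at an internal node (or a leaf for tiny trees)."""
        root = next(
            (n for n in sorted(self.adjacency) if n not in self.leaf_labels),
            min(self.adjacency, default=0),
        )

        def render(node: int, parent: int) -> str:
            children = [n for n in self.adjacency[node] if n != parent]
            if not children:
                return _format_label(self.leaf_labels[node])
            inner = ",".join(
                f"{render(c, node)}:{self.adjacency[node][c]:.{precision}f}"
                for c in children
            )
            label = _format_label(self.leaf_labels[node]) \
                if node in self.leaf_labels else ""
            return f"({inner}){label}"

        return render(root, -1) + ";"


def neighbor_joining(matrix: DistanceMatrix) -> NjTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The pair minimising Q(i,j) = (L-2) d(i,j) - r_i - r_j is joined; among
    ties the lexicographically smallest label pair wins (internal clusters
    are keyed by their smallest descendant leaf).  Negative limb lengths are
    clamped to zero.  The result is unrooted.
    """
    n = len(matrix)
    if n < 3:
        raise YstrError("neighbor joining needs at least 3 labels")
    d = matrix.clamped().values.copy()
    labels = list(matrix.labels)

    adjacency: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    leaf_labels = {i: labels[i] for i in range(n)}
    active = list(range(n))  # indices into d / sort_keys
    sort_keys = {i: labels[i] for i in range(n)}
    next_id = n

    def connect(a: int, b: int, length: float) -> None:
        length = max(0.0, float(length))
        adjacency.setdefault(a, {})[b] = length
        adjacency.setdefault(b, {})[a] = length

    node_of = {i: i for i in range(n)}  # matrix row -> tree node id

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((active[i], active[j]), key=lambda k: sort_keys[k]))
             for i, j in ties if i < j),
            key=lambda pair: (sort_keys[pair[0]], sort_keys[pair[1]]),
        )
        fi, fj = best
        i_pos, j_pos = active.index(fi), active.index(fj)
        dij = sub[i_pos, j_pos]
        limb_i = 0.5 * dij + (r[i_pos] - r[j_pos]) / (2 * (m - 2))
        limb_j = dij - limb_i
        new_row = 0.5 * (d[fi, active] + d[fj, active] - dij)

        u = next_id
        next_id += 1
        adjacency[u] = {}
        connect(u, node_of[fi], limb_i)
        connect(u, node_of[fj], limb_j)

        d = np.pad(d, ((0, 1), (0, 1)))
        new_idx = d.shape[0] - 1
        for pos, k in enumerate(active):
            d[new_idx, k] = d[k, new_idx] = new_row[pos]
        d[new_idx, new_idx] = 0.0
        active = [k for k in active if k not in (fi, fj)] + [new_idx]
        node_of[new_idx] = u
        sort_keys[new_idx] = min(sort_keys[fi], sort_keys[fj])

    # final 3-way join: closed-form limb lengths
    a, b, c = active
    u = next_id
    adjacency[u] = {}
    connect(u, node_of[a], 0.5 * (d[a, b] + d[a, c] - d[b, c]))
    connect(u, node_of[b], 0.5 * (d[a, b] + d[b, c] - d[a, c]))
    connect(u, node_of[c], 0.5 * (d[a, c] + d[b, c] - d[a, b]))
    return NjTree(adjacency, leaf_labels)


def write_newick(tree: NjTree, path: str | Path, precision: int = 6) -> None:
    """Write a tree as a Newick file with branch lengths."""
    Path(path).write_text(tree.to_newick(precision=precision) + "\n",
                          encoding="utf-8")


# -- minimal Newick reader (round-trip support) -----------------------------

def read_newick(text: str) -> NjTree:
    """Parse a Newick string (with branch lengths) into an :class:`NjTree`."""
    text = text.strip()
    if not text.endswith(";"):
        raise YstrError("Newick string must end with ';'")
    pos = 0
    s = text[:-1]
    adjacency: dict[int, dict[int, float]] = {}
    leaf_labels: dict[int, str] = {}
    counter = [0]

    def new_node() -> int:
        nid = counter[0]
        counter[0] += 1
        adjacency[nid] = {}
        return nid

    def parse_label() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while pos < len(s):
                if s[pos] == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    return "".join(out)
                out.append(s[pos])
                pos += 1
            raise YstrError("unterminated quoted label")
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos].strip()

    def parse_length() -> float:
        nonlocal pos
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in "(),;":
                pos += 1
            return float(s[start:pos])
        return 0.0

    def parse_subtree() -> tuple[int, float]:
        nonlocal pos
        if pos < len(s) and s[pos] == "(":
            node = new_node()
            pos += 1  # consume '('
            while True:
                child, length = parse_subtree()
                adjacency[node][child] = length
                adjacency[child][node] = length
                if pos >= len(s) or s[pos] != ",":
                    break
                pos += 1
            if pos >= len(s) or s[pos] != ")":
                raise YstrError("unbalanced parentheses in Newick string")
            pos += 1  # consume ')'
            label = parse_label()
            if label:
                leaf_labels[node] = label
            return node, parse_length()
        node = new_node()
        label = parse_label()
        if not label:
            raise YstrError("leaf without label in Newick string")
        leaf_labels[node] = label
        return node, parse_length()

    root, _ = parse_subtree()
    if pos != len(s):
        raise YstrError(f"trailing characters in Newick string: {s[pos:]!r}")
    return NjTree(adjacency, leaf_labels)
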