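"""Multilocus sequence analysis: per-family alignment, concatenation,
conserved-block trimming, genetic distances, and NJ trees with bootstrap.

Distances use pairwise deletion of gapped/ambiguous sites and support

* ``p``    — raw proportion of differing sites,
* ``JC69`` — d = -(3/4) ln(1 - 4p/3),
* ``K80``  — d = -(1/2) ln(1-2P-Q) - (1/4) ln(1-2Q), with P/Q the
  transition/transversion proportions.

The default model is K80.  Non-estimable distances (logarithm of a
non-positive argument, or zero comparable sites) are flagged as missing,
never silently zeroed.

Tree inference is distance-based neighbor joining (Saitou-Nei); bootstrap
resamples supermatrix columns with replacement and reports the percentage
of replicates containing each internal bipartition.  A trimmed
supermatrix can also be exported (FASTA/PHYLIP + RAxML-style partition
file) for an external maximum-likelihood tool.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix as SkbioDM
from skbio import TreeNode
from skbio.tree import nj

from .coregenome import GeneFamily

__all__ = [
    "Alignment",
    "SuperMatrix",
    "DistanceMatrix",
    "GblocksParams",
    "PhyloTree",
    "align_family",
    "concatenate_alignments",
    "trim_conserved_blocks",
    "genetic_distance",
    "nj_tree_with_bootstrap",
]

GAP = ord("-")
_PURINES = frozenset(b"AG")
_PYRIMIDINES = frozenset(b"CT")


@dataclass
class Alignment:
    ids: list[str]
    rows: list[str]
    family_id: str = ""

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows must have equal length")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def to_array(self) -> np.ndarray:
        return np.frombuffer("".join(self.rows).encode(), dtype=np.uint8).reshape(
            len(self.rows), -1
        )


@dataclass
class SuperMatrix:
    ids: list[str]
    rows: list[str]
    partitions: dict[str, tuple[int, int]]  # family -> half-open [start, end)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def as_alignment(self) -> Alignment:
        return Alignment(ids=self.ids, rows=self.rows, family_id="concatenated")

    def write_partitions(self, path) -> None:
        """RAxML-style partition file (1-based inclusive) for ML hand-off."""
        with Path(path).open("w") as fh:
            for name, (s, e) in self.partitions.items():
                fh.write(f"DNA, {name} = {s + 1}-{e}\n")


@dataclass
class DistanceMatrix:
    ids: list[str]
    data: np.ndarray
    model: str = "p"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.data).any())

    def value(self, a: str, b: str) -> float:
        return float(self.data[self.ids.index(a), self.ids.index(b)])


# ---------------------------------------------------------------------------
# alignment


def _mafft_available() -> bool:
    return shutil.which("mafft") is not None


def _align_mafft(ids: list[str], seqs: list[str]) -> list[str]:
    # keep original ids out of mafft (it mangles long headers); use indices
    with tempfile.TemporaryDirectory() as td:
        inp = Path(td) / "in.fa"
        with inp.open("w") as fh:
            for i, s in enumerate(seqs):
                fh.write(f">{i}\n{s}\n")
        res = subprocess.run(
            ["mafft", "--quiet", "--retree", "2", str(inp)],
            capture_output=True,
            text=True,
            check=True,
        )
    out: dict[int, str] = {}
    cur = None
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            cur = int(line[1:].strip())
            out[cur] = ""
        elif cur is not None:
            out[cur] += line.strip()
    return [out[i].upper() for i in range(len(seqs))]


def _pairwise_nw(a: str, b: str) -> tuple[str, str]:
    """Global affine-gap alignment of two sequences (for the guide stage)."""
    from Bio.Align import PairwiseAligner

    al = PairwiseAligner()
    al.mode = "global"
    al.match_score = 2.0
    al.mismatch_score = -1.0
    al.open_gap_score = -4.0
    al.extend_gap_score = -0.5
    aln = al.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    return sa, sb


def _merge_profiles(p1: list[str], p2: list[str]) -> tuple[list[str], list[str]]:
    """Profile-profile merge via consensus-sequence alignment.

    Each profile is represented by its first row with gaps kept; the gap
    pattern of the representative alignment is propagated to all rows.
    Exact sum-of-pairs profile DP is not attempted; for the desk-scale,
    low-divergence families this package targets, the representative
    heuristic reproduces the optimal alignment.
    """
    r1, r2 = p1[0], p2[0]
    a1, a2 = _pairwise_nw(r1.replace("-", "\x01"), r2.replace("-", "\x01"))
    # \x01 keeps existing gaps as ordinary (mismatching) symbols in the DP

    def expand(rows: list[str], template_in: str, aligned: str) -> list[str]:
        out = []
        for row in rows:
            buf = []
            k = 0
            for ch in aligned:
                if ch == "-":
                    buf.append("-")
                else:
                    buf.append(row[k])
                    k += 1
            out.append("".join(buf))
        return out

    return expand(p1, r1, a1), expand(p2, r2, a2)


def _align_builtin(ids: list[str], seqs: list[str]) -> list[str]:
    """Progressive alignment: similarity-ordered sequential profile merge."""
    if len(seqs) == 1:
        return list(seqs)
    # guide order: greedy nearest-neighbour chaining on shared 8-mer counts
    def kmers(s: str) -> set[str]:
        return {s[i : i + 8] for i in range(max(1, len(s) - 7))}

    sets = [kmers(s) for s in seqs]
    remaining = set(range(len(seqs)))
    order = [min(remaining)]
    remaining.discard(order[0])
    while remaining:
        last = order[-1]
        nxt = max(remaining, key=lambda j: (len(sets[last] & sets[j]), -j))
        order.append(nxt)
        remaining.discard(nxt)

    profile = [seqs[order[0]]]
    members = [order[0]]
    for j in order[1:]:
        p1, p2 = _merge_profiles(profile, [seqs[j]])
        profile = p1 + p2
        members.append(j)
    # restore input order
    out = [""] * len(seqs)
    for pos, j in enumerate(members):
        out[j] = profile[pos].replace("\x01", "-")
    return out


def align_family(family: GeneFamily | Alignment, backend: str = "auto") -> Alignment:
    """Align one gene family (mafft adapter by default, built-in fallback)."""
    if isinstance(family, Alignment):
        return family
    ids = sorted(family.members)
    seqs = [family.members[i][1].upper() for i in ids]
    if any(not s for s in seqs):
        raise ValueError(f"family {family.id!r} contains an empty sequence")
    if len(seqs) < 2:
        raise ValueError("need >= 2 sequences to align")
    if backend == "auto":
        backend = "mafft" if _mafft_available() else "builtin"
    if backend == "mafft":
        rows = _align_mafft(ids, seqs)
    elif backend == "builtin":
        rows = _align_builtin(ids, seqs)
    else:
        raise ValueError(f"unknown alignment backend {backend!r}")
    return Alignment(ids=ids, rows=rows, family_id=family.id)


def concatenate_alignments(alignments: list[Alignment]) -> SuperMatrix:
    if not alignments:
        raise ValueError("nothing to concatenate")
    taxa = sorted(alignments[0].ids)
    parts: dict[str, tuple[int, int]] = {}
    buf = {t: [] for t in taxa}
    pos = 0
    for aln in alignments:
        if sorted(aln.ids) != taxa:
            missing = sorted(set(taxa) ^ set(aln.ids))
            raise ValueError(
                f"taxa mismatch in family {aln.family_id!r}: {missing}"
            )
        idx = {t: i for i, t in enumerate(aln.ids)}
        for t in taxa:
            buf[t].append(aln.rows[idx[t]])
        parts[aln.family_id or f"part{len(parts)}"] = (pos, pos + aln.n_columns)
        pos += aln.n_columns
    return SuperMatrix(ids=taxa, rows=["".join(buf[t]) for t in taxa], partitions=parts)


# ---------------------------------------------------------------------------
# Gblocks-style trimming


@dataclass
class GblocksParams:
    """Conserved-block selection thresholds (published 0.91b defaults).

    ``min_identical`` (IS) defaults to ceil(n/2)+1; ``flank_fraction``
    (FS) to 0.85; runs of more than ``max_nonconserved`` (CP) contiguous
    nonconserved columns are removed; blocks shorter than ``min_block``
    (BL) are removed; columns containing any gap are removed.
    """

    min_identical: int | None = None
    flank_fraction: float = 0.85
    max_nonconserved: int = 8
    min_block: int = 10
    allow_gaps: bool = False


def trim_conserved_blocks(
    sm: SuperMatrix, params: GblocksParams | None = None
) -> tuple[SuperMatrix, list[int]]:
    """Select conserved blocks; returns the trimmed supermatrix and the
    kept original column indices (in order)."""
    params = params or GblocksParams()
    n = len(sm.ids)
    if n == 0 or sm.n_columns == 0:
        raise ValueError("empty supermatrix")
    IS = params.min_identical or (math.ceil(n / 2) + 1)
    FS = params.flank_fraction * n
    arr = np.frombuffer("".join(sm.rows).encode(), dtype=np.uint8).reshape(n, -1)
    L = arr.shape[1]

    status = np.zeros(L, dtype=np.int8)  # 0 nonconserved, 1 conserved, 2 highly
    gap_col = (arr == GAP).any(axis=0)
    for j in range(L):
        if gap_col[j] and not params.allow_gaps:
            status[j] = -1  # rejected outright
            continue
        col = arr[:, j]
        col = col[col != GAP]
        if col.size == 0:
            status[j] = -1
            continue
        _, counts = np.unique(col, return_counts=True)
        top = counts.max()
        if top >= FS:
            status[j] = 2
        elif top >= IS:
            status[j] = 1

    keep = status >= 1
    # remove runs of > CP contiguous nonconserved (incl. rejected) columns
    j = 0
    while j < L:
        if status[j] <= 0:
            k = j
            while k < L and status[k] <= 0:
                k += 1
            if k - j > params.max_nonconserved:
                keep[j:k] = False
            else:
                keep[j:k] = status[j:k] == 0  # short runs keep plain nonconserved
            j = k
        else:
            j += 1
    keep &= status >= 0  # gap columns never survive

    # blocks between removed stretches; trim flanks to highly conserved
    kept_idx: list[int] = []
    j = 0
    while j < L:
        if not keep[j]:
            j += 1
            continue
        k = j
        while k < L and keep[k]:
            k += 1
        block = list(range(j, k))
        while block and status[block[0]] != 2:
            block.pop(0)
        while block and status[block[-1]] != 2:
            block.pop()
        if len(block) >= params.min_block:
            kept_idx.extend(block)
        j = k

    new_parts: dict[str, tuple[int, int]] = {}
    pos = 0
    for name, (s, e) in sm.partitions.items():
        cnt = sum(1 for c in kept_idx if s <= c < e)
        new_parts[name] = (pos, pos + cnt)
        pos += cnt
    sel = np.array(kept_idx, dtype=int)
    if sel.size == 0:
        import warnings

        warnings.warn("trimming removed every column", stacklevel=2)
        rows = ["" for _ in sm.ids]
    else:
        sub = arr[:, sel]
        rows = [bytes(sub[i]).decode() for i in range(n)]
    return SuperMatrix(ids=sm.ids, rows=rows, partitions=new_parts), kept_idx


# ---------------------------------------------------------------------------
# genetic distances


def _encode(rows: list[str]) -> np.ndarray:
    return np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), -1)


def _pair_counts(a: np.ndarray, b: np.ndarray):
    """(valid sites, mismatches, transitions, transversions) with
    pairwise deletion of gaps/ambiguity."""
    acgt = np.zeros(256, dtype=bool)
    for c in b"ACGT":
        acgt[c] = True
    valid = acgt[a] & acgt[b]
    nv = int(valid.sum())
    if nv == 0:
        return 0, 0, 0, 0
    av, bv = a[valid], b[valid]
    diff = av != bv
    nd = int(diff.sum())
    purine = np.zeros(256, dtype=bool)
    for c in b"AG":
        purine[c] = True
    ts = int((diff & (purine[av] == purine[bv])).sum())
    return nv, nd, ts, nd - ts


def _model_distance(nv: int, nd: int, ts: int, tv: int, model: str) -> float:
    if nv == 0:
        return np.nan
    p = nd / nv
    if model == "p":
        return p
    if model == "jc69":
        arg = 1.0 - 4.0 * p / 3.0
        return np.nan if arg <= 0 else -0.75 * math.log(arg)
    if model == "k80":
        P, Q = ts / nv, tv / nv
        a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
        if a1 <= 0 or a2 <= 0:
            return np.nan
        return -0.5 * math.log(a1) - 0.25 * math.log(a2)
    raise ValueError(f"unknown model {model!r} (use p, jc69 or k80)")


def genetic_distance(
    aln: Alignment | SuperMatrix, model: str = "k80"
) -> DistanceMatrix:
    """Pairwise model distances with pairwise deletion; NaN where the
    model transform is undefined or no sites are comparable."""
    model = model.lower()
    if isinstance(aln, SuperMatrix):
        aln = aln.as_alignment()
    if len(aln.ids) < 2:
        raise ValueError("need >= 2 taxa")
    arr = _encode(aln.rows)
    n = len(aln.ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            nv, nd, ts, tv = _pair_counts(arr[i], arr[j])
            d[i, j] = d[j, i] = _model_distance(nv, nd, ts, tv, model)
    return DistanceMatrix(ids=aln.ids, data=d, model=model)


# ---------------------------------------------------------------------------
# NJ + bootstrap


@dataclass
class PhyloTree:
    tree: TreeNode
    supports: dict[frozenset, float] = field(default_factory=dict)
    n_boot: int = 0

    @property
    def taxa(self) -> list[str]:
        return sorted(t.name for t in self.tree.tips())

    def newick(self) -> str:
        return str(self.tree).strip()

    def bipartitions(self) -> set[frozenset]:
        return _bipartitions(self.tree)

    def tip_distances(self):
        """Cophenetic (patristic) tip-to-tip distances as a DistanceMatrix."""
        dm = self.tree.tip_tip_distances()
        ids = list(dm.ids)
        return DistanceMatrix(ids=ids, data=dm.data.copy(), model="patristic")


def _bipartitions(tree: TreeNode) -> set[frozenset]:
    all_tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            out.add(min(side, all_tips - side, key=sorted))
    return out


def _nj_from_dm(dm: DistanceMatrix) -> TreeNode:
    if dm.has_missing:
        raise ValueError(
            f"distance matrix under model {dm.model!r} has missing values; "
            "fall back to model='p'"
        )
    tree = nj(SkbioDM(dm.data, ids=dm.ids), neg_as_zero=True)
    return tree


def nj_tree_with_bootstrap(
    sm: SuperMatrix | Alignment,
    model: str = "k80",
    n_boot: int = 1000,
    seed: int = 0,
) -> PhyloTree:
    """Neighbor joining on the model distance matrix, with column-resampling
    bootstrap supports (percentages) on internal bipartitions."""
    aln = sm.as_alignment() if isinstance(sm, SuperMatrix) else sm
    if len(aln.ids) < 4:
        raise ValueError("need >= 4 taxa for an informative unrooted tree")
    arr = _encode(aln.rows)
    order = np.argsort(aln.ids)  # canonical taxon order: order-invariant boots
    ids = [aln.ids[i] for i in order]
    arr = arr[order]

    def dm_from(arr_cols: np.ndarray) -> DistanceMatrix:
        n = len(ids)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                nv, nd, ts, tv = _pair_counts(arr_cols[i], arr_cols[j])
                d[i, j] = d[j, i] = _model_distance(nv, nd, ts, tv, model)
        return DistanceMatrix(ids=ids, data=d, model=model)

    main = _nj_from_dm(dm_from(arr))
    counts: dict[frozenset, int] = {bp: 0 for bp in _bipartitions(main)}
    rng = np.random.default_rng(seed)
    L = arr.shape[1]
    done = 0
    for _ in range(n_boot):
        cols = rng.integers(0, L, size=L)
        try:
            rep = _nj_from_dm(dm_from(arr[:, cols]))
        except ValueError:
            continue  # replicate with inestimable distances is skipped
        done += 1
        rep_bps = _bipartitions(rep)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    supports = {
        bp: (100.0 * c / done if done else float("nan")) for bp, c in counts.items()
    }
    # stamp supports onto internal node names
    all_tips = frozenset(ids)
    for node in main.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = min(side, all_tips - side, key=sorted)
        if key in supports:
            node.name = f"{supports[key]:.0f}"
    return PhyloTree(tree=main, supports=supports, n_boot=done)
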