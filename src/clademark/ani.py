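"""Fragment-based average nucleotide identity (ANIb flavour), the
ANI-profile correlation clustering, and GBDP-style genome distances.

The query genome is chopped into consecutive fragments (1020 nt by
convention); each fragment is searched against the subject with exact
k-mer seeding followed by exact local affine-gap dynamic programming
(blastn-like +2/-3 scoring).  Fragments are retained iff their best hit
reaches ``min_identity_pct`` identity over at least
``min_fragment_coverage`` of the fragment; ANI is the mean identity of
retained fragments.  A pair with no retained fragment has *undefined*
ANI — flagged, never silently zero, because a zero would corrupt the
downstream Pearson correlations.

GBDP whole-sequence-length distance formulas over the retained HSPs:

    d0 = 1 - 2*sum(L) / (len_q + len_s)
    d4 = 1 - sum(identities) / sum(L)
    d6 = 1 - 2*sum(identities) / (len_q + len_s)

where L is HSP alignment length.  An in-silico DDH percentage can be
derived from a *user-supplied* monotone logistic mapping; no fitted
coefficients are shipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .seqmodel import Genome, StrainSet

__all__ = [
    "AniParams",
    "Hsp",
    "AniResult",
    "AniMatrix",
    "GbdpDistances",
    "compute_ani_pair",
    "ani_matrix",
    "correlation_clusters",
    "gbdp_distances",
    "ddh_estimate",
]


@dataclass
class AniParams:
    fragment_length: int = 1020
    min_identity_pct: float = 30.0
    min_fragment_coverage: float = 0.70
    seed_kmer: int = 15
    max_candidate_windows: int = 3
    search_reverse: bool = True

    def __post_init__(self) -> None:
        if self.fragment_length < 100:
            raise ValueError("fragment_length must be >= 100")
        if not 0 <= self.min_identity_pct <= 100:
            raise ValueError("min_identity_pct outside [0, 100]")
        if not 0 < self.min_fragment_coverage <= 1:
            raise ValueError("min_fragment_coverage outside (0, 1]")


@dataclass
class Hsp:
    fragment_index: int
    q_start: int  # fragment offset within query genome
    q_end: int
    s_start: int
    s_end: int
    columns: int
    identities: int
    strand: str = "+"

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.identities / self.columns


@dataclass
class AniResult:
    ani: float | None
    aligned_fraction: float
    hsps: list[Hsp]
    n_fragments: int
    n_retained: int

    @property
    def undefined(self) -> bool:
        return self.ani is None


@dataclass
class AniMatrix:
    ids: list[str]
    values: pd.DataFrame  # directional percentages; NaN where undefined
    aligned_fraction: pd.DataFrame

    @property
    def undefined_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def to_tsv(self, path) -> None:
        self.values.round(2).to_csv(path, sep="\t", na_rep="NA")


@dataclass
class GbdpDistances:
    d0: float
    d4: float | None
    d6: float
    hsp_total_length: int
    identity_total: int
    genome_lengths: tuple[int, int]


def _nt_aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "local"
    a.match_score = 2.0
    a.mismatch_score = -3.0
    a.open_gap_score = -7.0
    a.extend_gap_score = -2.0
    return a


def _fragments(seq: str, flen: int) -> list[tuple[int, str]]:
    """Consecutive fragments; trailing piece kept iff >= half length."""
    out = []
    for start in range(0, len(seq), flen):
        frag = seq[start : start + flen]
        if len(frag) >= flen or len(frag) * 2 >= flen:
            out.append((start, frag))
    return out


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i : i + k], []).append(i)
    return idx


def _candidate_windows(frag: str, index: dict[str, list[int]], k: int, max_windows: int):
    """Diagonal-clustered seed hits -> candidate subject windows."""
    diag_counts: dict[int, int] = {}
    for qpos in range(0, len(frag) - k + 1):
        for spos in index.get(frag[qpos : qpos + k], ()):
            d = spos - qpos
            bucket = d // 32
            diag_counts[bucket] = diag_counts.get(bucket, 0) + 1
    merged: dict[int, int] = {}
    for b, c in diag_counts.items():
        key = max(
            (b - 1, b, b + 1),
            key=lambda x: diag_counts.get(x, 0),
        )
        merged[key] = merged.get(key, 0) + c
    best = sorted(merged.items(), key=lambda kv: (-kv[1], kv[0]))[:max_windows]
    return [b * 32 for b, _ in best]


def _best_local_hit(frag: str, subject: str, diag: int, aligner: PairwiseAligner):
    margin = max(64, len(frag) // 8)
    w_start = max(0, diag - margin)
    w_end = min(len(subject), diag + len(frag) + margin)
    window = subject[w_start:w_end]
    if not window:
        return None
    alns = aligner.align(frag, window)
    if len(alns) == 0:
        return None
    aln = alns[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return None
    (qs, qe) = (aln.aligned[0][0][0], aln.aligned[0][-1][1])
    (ss, se) = (aln.aligned[1][0][0], aln.aligned[1][-1][1])
    return {
        "score": aln.score,
        "identities": int(counts.identities),
        "columns": int(columns),
        "q_span": (int(qs), int(qe)),
        "s_span": (int(ss) + w_start, int(se) + w_start),
    }


def compute_ani_pair(query: Genome, subject: Genome, p: AniParams | None = None) -> AniResult:
    """Directional fragment ANI of ``query`` against ``subject``."""
    p = p or AniParams()
    qseq, sseq = query.sequence, subject.sequence
    if not qseq or not sseq:
        raise ValueError("both genomes must be non-empty")
    aligner = _nt_aligner()
    fwd_index = _kmer_index(sseq, p.seed_kmer)
    rev = str(Seq(sseq).reverse_complement()) if p.search_reverse else ""
    rev_index = _kmer_index(rev, p.seed_kmer) if p.search_reverse else {}

    hsps: list[Hsp] = []
    identities_of_retained: list[float] = []
    retained_len = 0
    frags = _fragments(qseq, p.fragment_length)
    for fi, (qoff, frag) in enumerate(frags):
        best = None
        strand = "+"
        for st, (idx, subj) in (("+", (fwd_index, sseq)), ("-", (rev_index, rev))):
            if not idx:
                continue
            for diag in _candidate_windows(frag, idx, p.seed_kmer, p.max_candidate_windows):
                hit = _best_local_hit(frag, subj, diag, aligner)
                if hit and (best is None or hit["score"] > best["score"]):
                    best, strand = hit, st
        if best is None:
            continue
        identity = 100.0 * best["identities"] / best["columns"]
        coverage = (best["q_span"][1] - best["q_span"][0]) / len(frag)
        if identity >= p.min_identity_pct and coverage >= p.min_fragment_coverage:
            identities_of_retained.append(identity)
            retained_len += len(frag)
            hsps.append(
                Hsp(
                    fragment_index=fi,
                    q_start=qoff + best["q_span"][0],
                    q_end=qoff + best["q_span"][1],
                    s_start=best["s_span"][0],
                    s_end=best["s_span"][1],
                    columns=best["columns"],
                    identities=best["identities"],
                    strand=strand,
                )
            )
    ani = float(np.mean(identities_of_retained)) if identities_of_retained else None
    return AniResult(
        ani=ani,
        aligned_fraction=retained_len / len(qseq),
        hsps=hsps,
        n_fragments=len(frags),
        n_retained=len(identities_of_retained),
    )


def ani_matrix(ss: StrainSet, p: AniParams | None = None) -> AniMatrix:
    """All ordered pairs (directional); diagonal fixed at 100."""
    if len(ss.strains) < 2:
        raise ValueError("need >= 2 strains")
    ids = ss.ids
    vals = pd.DataFrame(np.nan, index=ids, columns=ids)
    af = pd.DataFrame(0.0, index=ids, columns=ids)
    for q in ids:
        for s in ids:
            if q == s:
                vals.loc[q, s] = 100.0
                af.loc[q, s] = 1.0
                continue
            res = compute_ani_pair(ss.genomes[q], ss.genomes[s], p)
            vals.loc[q, s] = np.nan if res.undefined else res.ani
            af.loc[q, s] = res.aligned_fraction
    return AniMatrix(ids=ids, values=vals, aligned_fraction=af)


@dataclass
class CorrClustering:
    corr: pd.DataFrame
    order: list[str]
    labels: dict[str, int] | None
    linkage_matrix: np.ndarray = field(repr=False, default=None)
    degenerate: list[str] = field(default_factory=list)


def correlation_clusters(
    m: AniMatrix,
    linkage: str = "complete",
    k: int | None = None,
    threshold: float | None = None,
    pairwise_complete: bool = False,
) -> CorrClustering:
    """Pearson correlation of ANI row profiles + hierarchical ordering.

    Profiles are the directional ANI rows (diagonal included).  Strains
    whose profile has zero variance have undefined correlations and are
    reported in ``degenerate``.
    """
    vals = m.values
    if vals.isna().any().any() and not pairwise_complete:
        raise ValueError(
            "ANI matrix has undefined cells; use pairwise_complete=True "
            "or resolve the flagged pairs"
        )
    degenerate = [i for i in m.ids if np.nanstd(vals.loc[i].values) == 0]
    corr = vals.T.corr(method="pearson")  # pandas: pairwise-complete
    np.fill_diagonal(corr.values, 1.0)
    dist = 1.0 - corr.values
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    order = [m.ids[i] for i in hierarchy.leaves_list(Z)]
    labels = None
    if k is not None:
        fl = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        labels = dict(zip(m.ids, (int(x) for x in fl)))
    elif threshold is not None:
        fl = hierarchy.fcluster(Z, t=threshold, criterion="distance")
        labels = dict(zip(m.ids, (int(x) for x in fl)))
    return CorrClustering(
        corr=corr, order=order, labels=labels, linkage_matrix=Z, degenerate=degenerate
    )


def gbdp_distances(hsps: list[Hsp], len_q: int, len_s: int) -> GbdpDistances:
    total_len = sum(h.columns for h in hsps)
    total_id = sum(h.identities for h in hsps)
    d0 = 1.0 - 2.0 * total_len / (len_q + len_s)
    d6 = 1.0 - 2.0 * total_id / (len_q + len_s)
    d4 = None if total_len == 0 else 1.0 - total_id / total_len
    return GbdpDistances(
        d0=d0,
        d4=d4,
        d6=d6,
        hsp_total_length=total_len,
        identity_total=total_id,
        genome_lengths=(len_q, len_s),
    )


def ddh_estimate(d: float, mapping: dict | None) -> float:
    """Map a GBDP distance to a DDH percentage with user-supplied logistic
    coefficients ``{"intercept": a, "slope": b}``: 100/(1+exp(-(a+b*d))).

    Refuses to guess when no mapping is supplied (the published regression
    coefficients belong to the external GGDC service, not to this package).
    """
    if mapping is None or "intercept" not in mapping or "slope" not in mapping:
        raise ValueError(
            "ddh_estimate requires logistic mapping coefficients "
            "{'intercept': a, 'slope': b}; none are shipped"
        )
    z = mapping["intercept"] + mapping["slope"] * d
    return float(100.0 / (1.0 + np.exp(-z)))
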