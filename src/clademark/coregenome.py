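"""Reciprocal-best-hit (RBH) ortholog detection and the BLAST-defined core.

Orthology is decided at the protein level: every query protein is searched
against a subject proteome with exact local Smith-Waterman alignment
(BLOSUM62, affine gaps -11/-1) and Karlin-Altschul-style e-values, the
deterministic desk-scale equivalent of a BLASTP search.  A pair (a, b) is
orthologous iff b is the best hit of a in proteome B *and* a is the best
hit of b in proteome A, both under the e-value cutoff (1e-30 by
convention for core-genome detection).  Gene families present, via RBH to
the reference, in every strain of the set constitute the core; nucleotide
sequences are then pulled for the alignment/distance stages.

Best hits are ordered by (max bitscore, min e-value, lexicographic subject
id); the paralog guard keeps at most one ortholog per (reference gene,
strain).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner, substitution_matrices

from .seqmodel import Genome, SimilarityHit, StrainSet, translate_cds

__all__ = [
    "GeneFamily",
    "OrthologTable",
    "search_all",
    "reciprocal_best_hits",
    "blast_core_genes",
]

# Gapped Karlin-Altschul parameters for BLOSUM62 with 11/1 gap costs
# (the standard values used by protein BLAST for this scoring system).
_LAMBDA = 0.267
_K = 0.041
_LN2 = math.log(2.0)


@dataclass
class GeneFamily:
    """One ortholog family: per-strain (gene id, nucleotide, protein)."""

    id: str
    members: dict[str, tuple[str, str, str]]

    def nucleotides(self) -> dict[str, str]:
        return {sid: m[1] for sid, m in self.members.items()}

    def proteins(self) -> dict[str, str]:
        return {sid: m[2] for sid, m in self.members.items()}


@dataclass
class OrthologTable:
    """reference gene id -> strain id -> SimilarityHit of the ortholog."""

    reference_id: str
    table: dict[str, dict[str, tuple[str, SimilarityHit]]] = field(default_factory=dict)


def _prot_aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    return a


def _bitscore(raw: float) -> float:
    return (_LAMBDA * raw - math.log(_K)) / _LN2


def _evalue(bits: float, m: int, n: int) -> float:
    return m * n * 2.0 ** (-bits)


def _align_stats(aligner: PairwiseAligner, q: str, s: str):
    alns = aligner.align(q, s)
    if len(alns) == 0:
        return None
    aln = alns[0]
    c = aln.counts()
    cols = c.identities + c.mismatches + c.gaps
    if cols == 0:
        return None
    return aln.score, int(c.identities), int(cols)


def search_all(
    queries: list[tuple[str, str]],
    db: list[tuple[str, str]],
    e_cutoff: float = 1e-30,
) -> list[SimilarityHit]:
    """All significant hits of every query against the database.

    Hits with e-value above the cutoff are dropped; within a query, hits
    are sorted best-first by (bitscore desc, e-value asc, subject id asc).
    """
    if not queries or not db:
        return []
    aligner = _prot_aligner()
    n_db = sum(len(s) for _, s in db)
    hits: list[SimilarityHit] = []
    for qid, qseq in queries:
        if not qseq:
            raise ValueError(f"empty query sequence {qid!r}")
        per_q: list[SimilarityHit] = []
        for sid, sseq in db:
            if not sseq:
                continue
            stats = _align_stats(aligner, qseq, sseq)
            if stats is None:
                continue
            score, ident, cols = stats
            bits = _bitscore(score)
            ev = _evalue(bits, len(qseq), n_db)
            if ev > e_cutoff:
                continue
            per_q.append(
                SimilarityHit(
                    query_id=qid,
                    subject_id=sid,
                    percent_identity=100.0 * ident / cols,
                    alignment_length=cols,
                    bitscore=bits,
                    e_value=ev,
                )
            )
        per_q.sort(key=lambda h: (-h.bitscore, h.e_value, h.subject_id))
        hits.extend(per_q)
    return hits


def best_hits(
    queries: list[tuple[str, str]],
    db: list[tuple[str, str]],
    e_cutoff: float = 1e-30,
) -> dict[str, SimilarityHit]:
    """Best hit per query (ties broken by lexicographic subject id)."""
    best: dict[str, SimilarityHit] = {}
    for h in search_all(queries, db, e_cutoff):
        if h.query_id not in best:
            best[h.query_id] = h
    return best


def reciprocal_best_hits(
    proteome_a: list[tuple[str, str]],
    proteome_b: list[tuple[str, str]],
    e_cutoff: float = 1e-30,
) -> list[tuple[str, str]]:
    """Pairs (a, b) that are mutual best hits under the cutoff."""
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    ab = best_hits(proteome_a, proteome_b, e_cutoff)
    ba = best_hits(proteome_b, proteome_a, e_cutoff)
    pairs = []
    for a, hit in ab.items():
        b = hit.subject_id
        back = ba.get(b)
        if back is not None and back.subject_id == a:
            pairs.append((a, b))
    return pairs


def blast_core_genes(
    reference: Genome,
    ss: StrainSet,
    e_cutoff: float = 1e-30,
    core_scope: str = "all",
) -> list[GeneFamily]:
    """Families with an RBH ortholog of a reference gene in every strain.

    ``core_scope='all'`` requires presence in outgroups too (filters
    post-speciation transfers); ``'group'`` requires only the non-outgroup
    strains.
    """
    if core_scope not in ("all", "group"):
        raise ValueError("core_scope must be 'all' or 'group'")
    if not reference.cds:
        raise ValueError("reference genome has no CDS")
    required = ss.ids if core_scope == "all" else ss.group_ids
    ref_prot = reference.proteome()
    gene_index = {
        g.id: g for g in reference.cds
    }

    # reference gene id -> strain -> (gene id, hit)
    table: dict[str, dict[str, tuple[str, SimilarityHit]]] = {
        gid: {} for gid, _ in ref_prot
    }
    for sid in required:
        genome = ss.genomes[sid]
        if not genome.cds:
            raise ValueError(f"strain {sid!r} lacks a proteome (no CDS)")
        sp = genome.proteome()
        ab = best_hits(ref_prot, sp, e_cutoff)
        ba = best_hits(sp, ref_prot, e_cutoff)
        for rgid, hit in ab.items():
            tgt = hit.subject_id
            back = ba.get(tgt)
            if back is not None and back.subject_id == rgid:
                table[rgid][sid] = (tgt, hit)

    ref_id = reference.strain_id
    families: list[GeneFamily] = []
    for rgid in sorted(table):
        present = table[rgid]
        if any(sid not in present for sid in required):
            continue
        members: dict[str, tuple[str, str, str]] = {}
        for sid in required:
            tgid, _ = present[sid]
            gene = next(g for g in ss.genomes[sid].cds if g.id == tgid)
            prot = gene.protein if gene.protein is not None else translate_cds(gene.nucleotide)
            members[sid] = (tgid, gene.nucleotide, prot)
        if ref_id not in members:
            rg = gene_index[rgid]
            prot = rg.protein if rg.protein is not None else translate_cds(rg.nucleotide)
            members[ref_id] = (rgid, rg.nucleotide, prot)
        families.append(GeneFamily(id=rgid, members=members))
    return families
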