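"""Domain types and I/O shared by every pipeline stage.

A *strain* is one sequenced bacterial isolate; its :class:`Genome` carries the
assembly contigs plus the predicted CDS set (nucleotide and protein).  A
:class:`StrainSet` bundles the strains under study, optionally marking
outgroup genomes (used e.g. to filter post-speciation gene transfers when
defining the core genome).

Sequences are plain uppercase strings.  IUPAC ambiguity codes are tolerated
in genomes and are treated as mismatches by every downstream aligner and
distance, which is conservative and deterministic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneRecord",
    "Strain",
    "Genome",
    "StrainSet",
    "SimilarityHit",
    "read_fasta",
    "write_fasta",
    "load_strain_table",
    "validate_strainset",
    "translate_cds",
    "cds_from_gff3",
]

ROLES = ("train", "test", "query")


@dataclass
class GeneRecord:
    """One predicted CDS: nucleotide sequence and (optionally) its protein."""

    id: str
    nucleotide: str
    protein: str | None = None
    locus_tag: str | None = None


@dataclass
class Strain:
    id: str
    claimed_species: str = "unknown"
    role: str = "query"
    source: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(
                f"strain {self.id!r}: role {self.role!r} not in {ROLES}"
            )
        if not self.claimed_species:
            self.claimed_species = "unknown"


@dataclass
class Genome:
    strain_id: str
    contigs: list[str] = field(default_factory=list)
    cds: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.contigs = [c.upper() for c in self.contigs]
        if self.total_length == 0:
            raise ValueError(f"genome {self.strain_id!r} has zero total length")

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    @property
    def sequence(self) -> str:
        """All contigs concatenated (convenience for fragment-based ANI)."""
        return "".join(self.contigs)

    def proteome(self) -> list[tuple[str, str]]:
        """(gene id, protein) pairs, translating on the fly when needed."""
        out = []
        for g in self.cds:
            prot = g.protein if g.protein is not None else translate_cds(g.nucleotide)
            out.append((g.id, prot))
        return out


@dataclass
class StrainSet:
    strains: list[Strain]
    genomes: dict[str, Genome]
    outgroups: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.strains]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate strain ids: {dup}")
        missing = [i for i in ids if i not in self.genomes]
        if missing:
            raise ValueError(f"strains without genomes: {missing}")
        stray = set(self.outgroups) - set(ids)
        if stray:
            raise ValueError(f"outgroups not in strain set: {sorted(stray)}")

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.strains]

    @property
    def group_ids(self) -> list[str]:
        """Strain ids excluding outgroups."""
        return [s.id for s in self.strains if s.id not in self.outgroups]

    def strain(self, strain_id: str) -> Strain:
        for s in self.strains:
            if s.id == strain_id:
                return s
        raise KeyError(strain_id)


@dataclass
class SimilarityHit:
    """One local-alignment hit, BLAST tabular flavoured."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    bitscore: float
    e_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity outside [0, 100]")
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` in file order.

    The record id is the first whitespace token of the header; sequences are
    uppercased.  Empty files and duplicate ids are errors.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_strain_table(path: str | Path) -> list[Strain]:
    """Load a strain metadata table (TSV or CSV with columns id/species/role).

    ``role`` must be train, test or query; an empty role or ``-`` (the
    convention for comparison outgroups) maps to query, and an empty species
    field is recorded as ``unknown``.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.DictReader(fh, delimiter=delim)
        cols = [c.strip().lower() for c in reader.fieldnames or []]
        if "id" not in cols:
            raise ValueError(f"strain table {path} lacks an 'id' column")
        strains: list[Strain] = []
        for row in reader:
            row = {k.strip().lower(): (v or "").strip() for k, v in row.items() if k}
            role = row.get("role", "").lower()
            if role in ("", "-"):
                role = "query"
            if role not in ROLES:
                raise ValueError(
                    f"strain {row.get('id')!r}: role {row.get('role')!r} "
                    f"not one of {ROLES}"
                )
            strains.append(
                Strain(
                    id=row["id"],
                    claimed_species=row.get("species", "") or "unknown",
                    role=role,
                    source=str(path),
                )
            )
    if not strains:
        raise ValueError(f"no strains in table {path}")
    return strains


def validate_strainset(ss: StrainSet) -> list[dict]:
    """Report-only QC: missing CDS, non-ACGT fraction, duplicate gene ids."""
    issues: list[dict] = []
    for sid in ss.ids:
        g = ss.genomes[sid]
        if not g.cds:
            issues.append({"strain": sid, "issue": "no_cds"})
        seq = g.sequence
        non_acgt = sum(1 for c in seq if c not in "ACGT")
        if non_acgt:
            issues.append(
                {
                    "strain": sid,
                    "issue": "non_acgt",
                    "fraction": non_acgt / len(seq),
                }
            )
        gene_ids = [c.id for c in g.cds]
        dups = sorted({i for i in gene_ids if gene_ids.count(i) > 1})
        if dups:
            issues.append({"strain": sid, "issue": "duplicate_gene_ids", "ids": dups})
    return issues


def translate_cds(nt: str) -> str:
    """Translate a CDS; internal/terminal stops become 'X' so protein
    aligners (BLOSUM62 alphabet) accept the sequence."""
    prot = str(Seq(nt[: len(nt) - len(nt) % 3]).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot.replace("*", "X")


def cds_from_gff3(genome: Genome, gff3_path: str | Path) -> list[GeneRecord]:
    """Extract CDS records from a GFF3 file (1-based inclusive coordinates).

    Only single-exon CDS features on named contigs are supported; genomes
    here are bacterial.  The contig name must match ``contig_<i>`` order of
    the genome or be resolvable by index.
    """
    contig_map: dict[str, str] = {}
    for i, c in enumerate(genome.contigs):
        contig_map[f"contig_{i}"] = c
    records: list[GeneRecord] = []
    with Path(gff3_path).open() as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "CDS":
                continue
            seqid, _, _, start, end, _, strand, _, attrs = parts[:9]
            contig = contig_map.get(seqid)
            if contig is None and len(genome.contigs) == 1:
                contig = genome.contigs[0]
            if contig is None:
                raise ValueError(f"unknown contig {seqid!r} in {gff3_path}")
            sub = contig[int(start) - 1 : int(end)]
            if strand == "-":
                sub = str(Seq(sub).reverse_complement())
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gid = attr.get("ID", f"{seqid}:{start}-{end}")
            records.append(GeneRecord(id=gid, nucleotide=sub, protein=translate_cds(sub)))
    return records
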