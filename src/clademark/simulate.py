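"""Synthetic clade generator.

Emulates the statistical structure of a group of highly related bacterial
species: K species clusters whose strains share high nucleotide identity
(~0.5-4% within-species divergence) while clusters are separated by ~7-10%
divergence, per-gene rate heterogeneity (some genes species-diagnostic,
others ribosomal-protein-like and nearly invariant), species-private
accessory function blocks, and optionally an "ecotype" strain with excess
function loss/gain relative to its conspecifics.

The genealogy is star-within-star: every species ancestor diverges
independently from the clade ancestor and every strain independently from
its species ancestor.  Configured divergences are *expected pairwise*
proportions, so edge substitution probabilities are half the configured
value; substitutions are i.i.d. per site, uniform over the three other
bases, with no indels.  This keeps truth labels unambiguous and all
per-site distance oracles exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqmodel import GeneRecord, Genome, Strain, StrainSet, translate_cds

__all__ = [
    "CladeSimConfig",
    "SimulatedClade",
    "simulate_clade",
    "simulate_function_matrix",
    "mutate_single_gene_copy",
    "marker_ranking_scenario",
]


def marker_ranking_scenario(seed: int = 0) -> CladeSimConfig:
    """Canonical marker-ranking study conditions: 4 species x 4 strains,
    1% within- / 8% between-species divergence, 10 core genes of which
    gene g000 carries a clean species-level signal (diagnostic), genes
    g001-g008 evolve fast but mostly strain-privately — weak species
    signal buried in noise, so they are imperfect discriminators — and
    g009 is invariant (ribosomal-protein-like)."""
    return CladeSimConfig(
        n_species=4,
        strains_per_species=4,
        n_core_genes=10,
        gene_length_range=(300, 600),
        within_species_divergence=0.01,
        between_species_divergence=0.08,
        gene_rate_multipliers=[2.0] + [3.0] * 8 + [0.0],
        gene_between_multipliers=[2.0] + [0.2] * 8 + [0.0],
        filler_length=0,
        seed=seed,
    )

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass
class CladeSimConfig:
    """Study conditions for one simulated clade.

    Divergences are expected pairwise proportions of differing sites;
    ``gene_rate_multipliers`` scale both within- and between-species rates
    per gene (a large multiplier makes a gene species-diagnostic, a zero
    multiplier makes it invariant, ribosomal-protein-like).
    """

    n_species: int = 4
    strains_per_species: int | list[int] = 3
    n_core_genes: int = 10
    gene_length_range: tuple[int, int] = (300, 900)
    within_species_divergence: float = 0.01
    between_species_divergence: float = 0.08
    gene_rate_multipliers: list[float] | None = None
    gene_between_multipliers: list[float] | None = None
    filler_length: int = 600
    n_accessory_genes_per_species: int = 2
    n_accessory_functions_per_species: int = 60
    repertoire_noise: float = 0.0
    ecotype_spec: tuple[str, int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if not 0 <= self.within_species_divergence < self.between_species_divergence <= 0.5:
            raise ValueError(
                "need 0 <= within_species_divergence < between_species_divergence <= 0.5"
            )
        for mults in (self.gene_rate_multipliers, self.gene_between_multipliers):
            if mults is not None:
                if len(mults) != self.n_core_genes:
                    raise ValueError("one rate multiplier per core gene required")
                if any(m < 0 for m in mults):
                    raise ValueError("rate multipliers must be >= 0")

    @property
    def strain_counts(self) -> list[int]:
        if isinstance(self.strains_per_species, int):
            return [self.strains_per_species] * self.n_species
        return list(self.strains_per_species)


@dataclass
class SimulatedClade:
    strain_set: StrainSet
    species_labels: dict[str, str]
    gene_families: dict[str, dict[str, str]]  # family id -> strain -> nt seq
    multipliers: dict[str, float]
    diagnosticity_rank: list[str]  # family ids, most diagnostic first

    def true_core_geneset(self):
        """Ground-truth core gene families as coregenome.GeneFamily objects."""
        from .coregenome import GeneFamily

        fams = []
        for fam_id, members in self.gene_families.items():
            fams.append(
                GeneFamily(
                    id=fam_id,
                    members={
                        sid: (f"{sid}|{fam_id}", nt, translate_cds(nt))
                        for sid, nt in members.items()
                    },
                )
            )
        return fams


def _random_cds(rng: np.random.Generator, length: int) -> str:
    n_codons = max(2, length // 3)
    idx = rng.integers(0, len(_CODONS), size=n_codons)
    return "".join(_CODONS[i] for i in idx)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with probability ``rate``."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    n = int(hit.sum())
    if n:
        # replace with one of the three other bases, uniformly
        cur = arr[hit]
        offs = rng.integers(1, 4, size=n)
        lut = np.full(256, 255, dtype=np.uint8)
        for i, b in enumerate(_BASES):
            lut[b] = i
        arr[hit] = _BASES[(lut[cur] + offs) % 4]
    return arr.tobytes().decode()


def mutate_single_gene_copy(gene: str, divergence: float, seed: int) -> str:
    """Mutate one gene copy; expected changed-site fraction ~= divergence."""
    if not 0 <= divergence <= 0.75:
        raise ValueError("divergence must be in [0, 0.75]")
    return _mutate(gene.upper(), divergence, np.random.default_rng(seed))


def simulate_clade(cfg: CladeSimConfig) -> SimulatedClade:
    """Simulate a clade of K species; returns genomes + truth labels/ranks.

    Genomes are the concatenated core genes plus a species-shared random
    filler block, so whole-genome ANI and core-gene distances are related
    but not identical.  Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_core_genes
    mults = cfg.gene_rate_multipliers
    if mults is None:
        mults = list(rng.uniform(0.5, 2.0, size=G))
    # between-species (species-ancestor edge) multipliers default to the
    # shared per-gene multipliers; setting one to zero while the shared
    # multiplier stays positive yields a gene whose variation is entirely
    # strain-private, i.e. carries no species signal
    bmults = cfg.gene_between_multipliers or mults
    fam_ids = [f"g{i:03d}" for i in range(G)]
    lo, hi = cfg.gene_length_range
    roots = {f: _random_cds(rng, int(rng.integers(lo, hi + 1))) for f in fam_ids}

    species_names = [f"sp{k + 1}" for k in range(cfg.n_species)]
    within_edge = cfg.within_species_divergence / 2.0
    between_edge = cfg.between_species_divergence / 2.0

    gene_families: dict[str, dict[str, str]] = {f: {} for f in fam_ids}
    species_labels: dict[str, str] = {}
    strains: list[Strain] = []
    genomes: dict[str, Genome] = {}

    for k, sp in enumerate(species_names):
        ancestors = {
            f: _mutate(roots[f], between_edge * bmults[i], rng)
            for i, f in enumerate(fam_ids)
        }
        filler = (
            "".join("ACGT"[i] for i in rng.integers(0, 4, size=cfg.filler_length))
            if cfg.filler_length
            else ""
        )
        # species-private accessory genes: the gene gain/loss component of
        # real repertoires (identical within a species, absent elsewhere)
        accessory = [
            (f"acc_{sp}_{i}", _random_cds(rng, int(rng.integers(lo, hi + 1))))
            for i in range(cfg.n_accessory_genes_per_species)
        ]
        for j in range(cfg.strain_counts[k]):
            sid = f"{sp}_s{j + 1}"
            species_labels[sid] = sp
            cds = []
            parts = []
            for i, f in enumerate(fam_ids):
                gene = _mutate(ancestors[f], within_edge * mults[i], rng)
                gene_families[f][sid] = gene
                cds.append(
                    GeneRecord(
                        id=f"{sid}|{f}",
                        nucleotide=gene,
                        protein=translate_cds(gene),
                    )
                )
                parts.append(gene)
            for acc_id, acc_nt in accessory:
                cds.append(
                    GeneRecord(
                        id=f"{sid}|{acc_id}",
                        nucleotide=acc_nt,
                        protein=translate_cds(acc_nt),
                    )
                )
                parts.append(acc_nt)
            parts.append(filler)
            strains.append(Strain(id=sid, claimed_species=sp, role="query", source="synthetic"))
            genomes[sid] = Genome(strain_id=sid, contigs=["".join(parts)], cds=cds)

    # diagnosticity is governed by the species-level (between) signal
    order = sorted(range(G), key=lambda i: (-bmults[i], fam_ids[i]))
    return SimulatedClade(
        strain_set=StrainSet(strains=strains, genomes=genomes),
        species_labels=species_labels,
        gene_families=gene_families,
        multipliers=dict(zip(fam_ids, mults)),
        diagnosticity_rank=[fam_ids[i] for i in order],
    )


def simulate_function_matrix(
    labels: dict[str, str],
    n_core_functions: int,
    cfg: CladeSimConfig,
):
    """Binary strains x functions matrix with species-private accessory blocks.

    Core functions are 1 everywhere; each species carries a private
    accessory block; the optional ecotype strain loses ``n_lost`` core
    functions and gains ``n_gained`` private ones; finally each cell is
    flipped with probability ``cfg.repertoire_noise``.
    """
    import pandas as pd

    strains = list(labels)
    species = sorted(set(labels.values()))
    cols = [f"core_{i:04d}" for i in range(n_core_functions)]
    for sp in species:
        cols += [
            f"acc_{sp}_{i:03d}" for i in range(cfg.n_accessory_functions_per_species)
        ]
    eco = cfg.ecotype_spec
    if eco is not None:
        eco_id, n_lost, n_gained = eco
        if eco_id not in labels:
            raise ValueError(f"ecotype strain {eco_id!r} not in labels")
        if n_lost > n_core_functions:
            raise ValueError("cannot lose more core functions than exist")
        cols += [f"eco_gain_{i:03d}" for i in range(n_gained)]

    m = pd.DataFrame(0, index=strains, columns=cols, dtype=np.int8)
    m.loc[:, [c for c in cols if c.startswith("core_")]] = 1
    for sp in species:
        block = [c for c in cols if c.startswith(f"acc_{sp}_")]
        m.loc[[s for s in strains if labels[s] == sp], block] = 1
    if eco is not None:
        m.loc[eco_id, cols[:n_lost]] = 0
        m.loc[eco_id, [c for c in cols if c.startswith("eco_gain_")]] = 1

    if cfg.repertoire_noise > 0:
        rng = np.random.default_rng(cfg.seed + 1)
        flips = rng.random(m.shape) < cfg.repertoire_noise
        m = (m.values ^ flips).astype(np.int8)
        m = pd.DataFrame(m, index=strains, columns=cols)
    return m
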