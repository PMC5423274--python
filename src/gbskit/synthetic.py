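"""Synthetic genomes, genotype panels, traits and full simulated GBS datasets.

Everything downstream of this module can be exercised without any real
sequencing data.  The generators emulate:

* genomes with controllable GC content and restriction-site density
  (i.i.d. base composition with P(G) = P(C) = gc/2, plus optional exact
  planting of recognition sites);
* panels of inbred or outbred (diploid/tetraploid) genotypes segregating
  SNPs at tag loci, with allele frequencies drawn from a configurable
  minor-allele-frequency distribution (uniform on [0.025, 0.5] by default,
  so a 2.5% MAF filter is actually exercised);
* additive phenotypes with a specified heritability, with true breeding
  values retained so calling/prediction error is always computable;
* end-to-end GBS datasets: digestion -> tag extraction -> biased
  multinomial read allocation -> depth-threshold genotype calling, where
  missingness arises from the depth rules and nothing else.

All operations are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .calling import Call, CallFilterRule, call_genotype
from .digest import Fragment, Tag, digest, extract_tags, select_amplifiable
from .enzymes import IUPAC, RestrictionEnzyme
from .sampling import BiasModel, DepthTable, amplification_weights


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Recipe for an i.i.d.-composition genome with optional planted sites."""

    total_length: int
    n_chromosomes: int = 1
    gc_content: float = 0.4
    planted_sites: tuple[tuple[RestrictionEnzyme, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_length < 1:
            raise ValueError("total_length must be >= 1")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")
        needed = sum(e.site_length * k for e, k in self.planted_sites)
        if needed > self.total_length:
            raise ValueError(
                f"planted sites need {needed} bases but the genome has only "
                f"{self.total_length}"
            )


def _concrete_site(enzyme: RestrictionEnzyme, rng: np.random.Generator) -> str:
    """A concrete realisation of a degenerate recognition site."""
    return "".join(
        sorted(IUPAC[c])[rng.integers(len(IUPAC[c]))] for c in enzyme.recognition
    )


def _count_matches(seq: str, enzyme: RestrictionEnzyme) -> int:
    return sum(
        enzyme.matches_at(seq, i) for i in range(len(seq) - enzyme.site_length + 1)
    )


def simulate_genome(spec: SyntheticGenomeSpec) -> dict[str, str]:
    """Generate per-chromosome sequences over {A,C,G,T}.

    Bases are i.i.d. with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2.  Each
    planted enzyme's recognition pattern ends up matching the genome
    exactly the requested number of times: sites are written at random
    non-overlapping positions and chance background matches are then
    repaired by point mutation (a bounded fix-up loop).
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    lengths = [spec.total_length // spec.n_chromosomes] * spec.n_chromosomes
    lengths[-1] += spec.total_length - sum(lengths)
    genome: dict[str, str] = {}
    for i, L in enumerate(lengths):
        seq = "".join(rng.choice(bases, size=L, p=probs))
        genome[f"chr{i + 1}"] = seq
    for enzyme, count in spec.planted_sites:
        genome = _plant_sites(genome, enzyme, count, rng)
    return genome


def _plant_sites(
    genome: dict[str, str],
    enzyme: RestrictionEnzyme,
    count: int,
    rng: np.random.Generator,
    max_rounds: int = 200,
) -> dict[str, str]:
    m = enzyme.site_length
    chroms = list(genome)
    seqs = {c: list(genome[c]) for c in chroms}
    # choose non-overlapping slots across chromosomes
    slots: list[tuple[str, int]] = []
    occupied: dict[str, set[int]] = {c: set() for c in chroms}
    weights = np.array([max(len(genome[c]) - m + 1, 0) for c in chroms], dtype=float)
    if count > 0 and weights.sum() <= 0:
        raise ValueError(
            f"cannot plant {count} sites of {enzyme.name}: chromosomes shorter "
            "than the recognition site"
        )
    attempts = 0
    while len(slots) < count:
        attempts += 1
        if attempts > 10000 * max(count, 1):
            raise ValueError(
                f"cannot place {count} non-overlapping {enzyme.name} sites"
            )
        c = chroms[rng.choice(len(chroms), p=weights / weights.sum())]
        start = int(rng.integers(0, len(genome[c]) - m + 1))
        if any(p in occupied[c] for p in range(start - m + 1, start + m)):
            continue
        slots.append((c, start))
        occupied[c].update(range(start, start + m))
    for c, start in slots:
        site = _concrete_site(enzyme, rng)
        seqs[c][start : start + m] = list(site)

    # repair chance background matches so the pattern count is exact
    planted = {c: {s for cc, s in slots if cc == c} for c in chroms}
    for _ in range(max_rounds):
        extra = []
        for c in chroms:
            s = "".join(seqs[c])
            for pos in range(len(s) - m + 1):
                if pos in planted[c]:
                    continue
                if any(abs(pos - p) < m for p in planted[c]):
                    # overlapping a planted site: mutating would damage it;
                    # only flag if it is a distinct extra match
                    if enzyme.matches_at(s, pos):
                        extra.append((c, pos, True))
                    continue
                if enzyme.matches_at(s, pos):
                    extra.append((c, pos, False))
        if not extra:
            break
        for c, pos, overlaps in extra:
            s = seqs[c]
            if overlaps:
                # pick a column of the spurious match outside every planted site
                cols = [
                    j
                    for j in range(pos, pos + m)
                    if not any(p <= j < p + m for p in planted[c])
                ]
                if not cols:
                    raise ValueError(
                        f"cannot disambiguate overlapping {enzyme.name} matches"
                    )
                j = cols[0]
            else:
                j = pos + int(rng.integers(m))
            forbidden = IUPAC[enzyme.recognition[(j - pos) % m]]
            choices = [b for b in "ACGT" if b not in forbidden]
            s[j] = choices[int(rng.integers(len(choices)))]
    else:
        raise ValueError(f"site planting for {enzyme.name} did not converge")
    out = {c: "".join(seqs[c]) for c in chroms}
    total = sum(_count_matches(out[c], enzyme) for c in chroms)
    if total != count:
        raise ValueError(
            f"planting failed: {total} matches of {enzyme.name}, wanted {count}"
        )
    return out


@dataclass(frozen=True)
class PanelSpec:
    """Recipe for a genotype panel segregating SNPs at tag loci."""

    n_genotypes: int
    ploidy: int = 2
    breeding_system: str = "inbred"  # "inbred" | "outbred"
    snp_rate: float = 0.5
    maf_low: float = 0.025
    maf_high: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 4):
            raise ValueError("ploidy must be 2 or 4")
        if self.breeding_system not in ("inbred", "outbred"):
            raise ValueError("breeding_system must be 'inbred' or 'outbred'")
        if not 0.0 <= self.snp_rate <= 1.0:
            raise ValueError("snp_rate must lie in [0, 1]")
        if not 0.0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("MAF bounds must satisfy 0 < low <= high <= 0.5")


def simulate_genotype_panel(
    tag_loci: Sequence[str], spec: PanelSpec
) -> pd.DataFrame:
    """True allele-dose table (genotypes x loci, doses 0..ploidy).

    Each locus segregates with probability ``snp_rate``; segregating loci
    draw an allele frequency uniformly from [maf_low, maf_high].  Inbred
    panels contain only homozygous genotypes (dose 0 or ploidy); outbred
    genotypes draw doses from Binomial(ploidy, p) (Hardy-Weinberg-like).
    """
    if not len(tag_loci):
        raise ValueError("empty tag-locus list")
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n_genotypes, len(tag_loci)
    doses = np.zeros((n, L), dtype=np.int64)
    segregates = rng.random(L) < spec.snp_rate
    freqs = rng.uniform(spec.maf_low, spec.maf_high, size=L)
    for j in range(L):
        if not segregates[j]:
            continue
        p = freqs[j]
        if spec.breeding_system == "inbred":
            doses[:, j] = rng.binomial(1, p, size=n) * spec.ploidy
        else:
            doses[:, j] = rng.binomial(spec.ploidy, p, size=n)
    return pd.DataFrame(
        doses,
        index=[f"G{i + 1}" for i in range(n)],
        columns=list(tag_loci),
    )


@dataclass(frozen=True)
class TraitSpec:
    """Recipe for an additive trait on a genotype panel."""

    n_qtl: int
    h2: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_qtl < 1:
            raise ValueError("n_qtl must be >= 1")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("heritability must lie in [0, 1]")


def simulate_trait(
    genotypes: pd.DataFrame, spec: TraitSpec
) -> tuple[pd.Series, pd.Series]:
    """Phenotypes and true breeding values for an additive trait.

    QTL are sampled among segregating loci (effects ~ N(0,1)); Gaussian
    noise is scaled so the realised heritability var(g)/var(y) matches
    ``h2`` in expectation.  Returns ``(phenotype, breeding_value)``.
    """
    rng = np.random.default_rng(spec.seed)
    segregating = [c for c in genotypes.columns if genotypes[c].nunique() > 1]
    if spec.n_qtl > len(segregating):
        raise ValueError(
            f"n_qtl={spec.n_qtl} exceeds the {len(segregating)} segregating loci"
        )
    qtl = list(rng.choice(segregating, size=spec.n_qtl, replace=False))
    effects = rng.normal(size=spec.n_qtl)
    g = genotypes[qtl].to_numpy(dtype=float) @ effects
    var_g = float(np.var(g))
    if spec.h2 == 0.0:
        noise_sd = 1.0 if var_g == 0 else np.sqrt(var_g)
        y = rng.normal(scale=noise_sd, size=len(g))  # genotype-independent
    elif spec.h2 == 1.0:
        y = g.copy()
    else:
        noise_var = var_g * (1.0 - spec.h2) / spec.h2
        y = g + rng.normal(scale=np.sqrt(noise_var), size=len(g))
    idx = genotypes.index
    return pd.Series(y, index=idx, name="phenotype"), pd.Series(
        g, index=idx, name="breeding_value"
    )


@dataclass
class GBSDataset:
    """A fully simulated GBS experiment with its ground truth retained."""

    markers: pd.DataFrame          # genotype x locus codes 0/1/2, NaN missing
    depth_table: DepthTable
    true_doses: pd.DataFrame       # genotype x locus allele doses (0..ploidy)
    tags: list[Tag] = field(default_factory=list)
    fragments: list[Fragment] = field(default_factory=list)


def _code_from_dose(dose: int, ploidy: int) -> int:
    if dose == 0:
        return 0
    if dose == ploidy:
        return 2
    return 1


def simulate_gbs_dataset(
    genome: dict[str, str],
    panel_spec: PanelSpec,
    enzymes: Sequence[RestrictionEnzyme],
    protocol: str,
    bias: BiasModel,
    reads_per_genotype: int,
    rule: CallFilterRule,
    seed: int = 0,
    tag_length: int = 64,
) -> GBSDataset:
    """End-to-end GBS simulation on one genome.

    Digest -> amplifiable fragments -> tags -> biased multinomial read
    allocation per genotype -> per-tag allele read draws from the true
    allele dose -> depth-threshold genotype calling.  Reads carrying each
    allele at a heterozygous tag follow Binomial(depth, dose/ploidy);
    missingness arises only from the depth rules.
    """
    rng = np.random.default_rng(seed)
    fragments = select_amplifiable(digest(genome, enzymes), protocol)
    if not fragments:
        raise ValueError(
            f"protocol {protocol!r} with enzymes "
            f"{[e.name for e in enzymes]} yields zero amplifiable fragments"
        )
    tags = [t for f in fragments for t in extract_tags(f, tag_length)]
    frag_of_tag = []
    for f in fragments:
        frag_of_tag.extend([f] * len(extract_tags(f, tag_length)))
    tags_per_fragment = [len(extract_tags(f, tag_length)) for f in fragments]
    weights = amplification_weights(fragments, bias, tags_per_fragment)
    loci = [f"{t.fragment_id}:{t.side}" for t in tags]

    panel = simulate_genotype_panel(loci, replace_seed(panel_spec, seed + 1))
    n, L = panel.shape
    depth_mat = np.stack(
        [rng.multinomial(reads_per_genotype, weights) for _ in range(n)], axis=1
    )
    depth = pd.DataFrame(depth_mat, index=loci, columns=panel.index)

    ploidy = panel_spec.ploidy
    codes = np.full((n, L), np.nan)
    doses = panel.to_numpy()
    for i in range(n):
        for j in range(L):
            d = int(depth_mat[j, i])
            if d == 0:
                continue
            dose = int(doses[i, j])
            alt = int(rng.binomial(d, dose / ploidy))
            ref = d - alt
            call = call_genotype(ref, alt, rule)
            if call is Call.MISSING:
                continue
            codes[i, j] = {"HOM_REF": 0, "HET": 1, "HOM_ALT": 2}[call.value]
    markers = pd.DataFrame(codes, index=panel.index, columns=loci)
    return GBSDataset(
        markers=markers,
        depth_table=DepthTable(depth, tags=tags, fragments=frag_of_tag),
        true_doses=panel,
        tags=tags,
        fragments=fragments,
    )


def replace_seed(spec: PanelSpec, seed: int) -> PanelSpec:
    return PanelSpec(
        n_genotypes=spec.n_genotypes,
        ploidy=spec.ploidy,
        breeding_system=spec.breeding_system,
        snp_rate=spec.snp_rate,
        maf_low=spec.maf_low,
        maf_high=spec.maf_high,
        seed=seed,
    )


def write_fasta(genome: dict[str, str], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
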