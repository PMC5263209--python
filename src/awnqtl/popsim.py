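"""Simulation of the five-founder recombinant-inbred breeding design.

The design mirrors a multiparent barley population: four wild donors are
each crossed to the recurrent parent (cv. Morex-like recipient), the F1 is
backcrossed to the recipient once, the resulting BC1F1 individuals are
intercrossed pairwise, and each intercross line is taken through single
seed descent (five selfing generations by default, giving F6).  Pedigree
expectation per line: 75% recipient genome and 12.5% from each of its two
donors.

Meiosis uses the Haldane model: crossover count per chromosome is
Poisson(length cM / 100) with independent uniform positions (no
interference, no obligate chiasma).  Genomes are stored as founder-origin
mosaics — per homolog an ordered list of (segment end in cM, founder index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    MISSING,
    FounderPanel,
    GeneticMap,
    MarkerGenotypeTable,
    PhenotypeTable,
    logger,
)

__all__ = [
    "Homolog",
    "FounderMosaic",
    "CrossDesign",
    "QTL",
    "QTLSpec",
    "simulate_gamete",
    "cross",
    "self_once",
    "founder_mosaic",
    "simulate_population",
    "simulate_phenotypes",
    "simulate_self_progeny",
    "default_panel",
    "default_map",
    "genotypes_from_mosaics",
    "truth_table",
]


# ---------------------------------------------------------------------------
# Mosaic containers


@dataclass(frozen=True)
class Homolog:
    """Piecewise-constant founder origin along one chromosome copy.

    ``ends`` are strictly increasing segment right-endpoints in cM; the last
    end equals the chromosome length.  Segment i covers (ends[i-1], ends[i]].
    """

    ends: np.ndarray
    founders: np.ndarray

    def founder_at(self, pos) -> np.ndarray:
        """Founder index at one or many cM positions (vectorised)."""
        idx = np.searchsorted(self.ends, np.atleast_1d(pos), side="left")
        idx = np.minimum(idx, len(self.ends) - 1)
        return self.founders[idx]

    @property
    def length(self) -> float:
        return float(self.ends[-1])


@dataclass(frozen=True)
class FounderMosaic:
    """Diploid founder-origin mosaic: two homologs per chromosome."""

    homologs: dict[str, tuple[Homolog, Homolog]]

    def chromosomes(self) -> list[str]:
        return list(self.homologs)

    def founder_proportions(self, n_founders: int) -> np.ndarray:
        """Genome-wide founder-origin proportions; sums to 1 exactly."""
        acc = np.zeros(n_founders)
        total = 0.0
        for pair in self.homologs.values():
            for hom in pair:
                if hom.length == 0:  # degenerate chromosome: count a point
                    acc[hom.founders[0]] += 1e-9
                    total += 1e-9
                    continue
                starts = np.concatenate(([0.0], hom.ends[:-1]))
                np.add.at(acc, hom.founders, hom.ends - starts)
                total += hom.length
        return acc / total

    def dose_at(self, chrom: str, pos: float, n_founders: int) -> np.ndarray:
        """Founder-genome dose vector at one locus: entries in {0, .5, 1}."""
        h1, h2 = self.homologs[chrom]
        d = np.zeros(n_founders)
        d[int(h1.founder_at(pos)[0])] += 0.5
        d[int(h2.founder_at(pos)[0])] += 0.5
        return d


def founder_mosaic(founder_index: int, chrom_lengths: dict[str, float]) -> FounderMosaic:
    """A fully inbred founder: both homologs one segment of that founder."""
    homs = {}
    for chrom, length in chrom_lengths.items():
        h = Homolog(np.array([max(length, 0.0)]), np.array([founder_index]))
        homs[chrom] = (h, h)
    return FounderMosaic(homs)


# ---------------------------------------------------------------------------
# Meiosis


def _recombine(h1: Homolog, h2: Homolog, rng: np.random.Generator) -> Homolog:
    length = h1.length
    n_xo = rng.poisson(length / 100.0) if length > 0 else 0
    current = int(rng.integers(2))
    if n_xo == 0:
        src = (h1, h2)[current]
        return Homolog(src.ends.copy(), src.founders.copy())
    breaks = np.sort(rng.uniform(0.0, length, size=n_xo))
    ends, founders = [], []
    prev = 0.0
    sources = (h1, h2)
    for b in np.concatenate((breaks, [length])):
        if b > prev:
            src = sources[current]
            lo = np.searchsorted(src.ends, prev, side="right")
            hi = np.searchsorted(src.ends, b, side="left")
            for i in range(lo, hi + 1):
                seg_end = min(float(src.ends[i]), b)
                if seg_end > prev:
                    if founders and founders[-1] == src.founders[i]:
                        ends[-1] = seg_end
                    else:
                        ends.append(seg_end)
                        founders.append(int(src.founders[i]))
                    prev = seg_end
        current ^= 1
    ends[-1] = length  # guard against float round-off at the telomere
    return Homolog(np.asarray(ends), np.asarray(founders))


def simulate_gamete(parent: FounderMosaic, rng: np.random.Generator) -> dict[str, Homolog]:
    """One meiotic product: per chromosome a recombinant single homolog."""
    return {c: _recombine(h1, h2, rng) for c, (h1, h2) in parent.homologs.items()}


def cross(mother: FounderMosaic, father: FounderMosaic, rng: np.random.Generator) -> FounderMosaic:
    gm, gf = simulate_gamete(mother, rng), simulate_gamete(father, rng)
    return FounderMosaic({c: (gm[c], gf[c]) for c in gm})


def self_once(plant: FounderMosaic, rng: np.random.Generator) -> FounderMosaic:
    return cross(plant, plant, rng)


# ---------------------------------------------------------------------------
# Design


@dataclass(frozen=True)
class CrossDesign:
    """Subpopulation structure: which donor pairs, how many lines each."""

    donor_pairs: list[tuple[str, str]]
    lines_per_subpop: list[int]
    ssd_generations: int = 5
    backcrosses_to_recipient: int = 1

    def __post_init__(self) -> None:
        if len(self.donor_pairs) != len(self.lines_per_subpop):
            raise ValueError("one line count per donor pair required")
        for p, q in self.donor_pairs:
            if p == q:
                raise ValueError(f"donor pair ({p}, {q}) has identical donors")

    @property
    def total_lines(self) -> int:
        return int(sum(self.lines_per_subpop))

    @staticmethod
    def all_pairs(donors: list[str], lines_per_subpop: int | list[int] = 153, **kw) -> "CrossDesign":
        """Every unordered donor pair, as in the six-subpopulation design."""
        pairs = [(donors[i], donors[j]) for i in range(len(donors)) for j in range(i + 1, len(donors))]
        if isinstance(lines_per_subpop, int):
            counts = [lines_per_subpop] * len(pairs)
        else:
            counts = list(lines_per_subpop)
        return CrossDesign(pairs, counts, **kw)


def cross_label(p: str, q: str) -> str:
    return f"{p}x{q}"


def donors_of_cross(label: str, founder_names: list[str]) -> tuple[str, str]:
    """Recover the donor pair from a cross label of the form '<p>x<q>'."""
    for p in founder_names:
        for q in founder_names:
            if p != q and cross_label(p, q) == label:
                return p, q
    raise ValueError(f"cross label {label!r} does not name two known founders")


# ---------------------------------------------------------------------------
# Population simulation


def simulate_population(
    design: CrossDesign,
    panel: FounderPanel,
    gmap: GeneticMap,
    rng: np.random.Generator,
    genotyping_error: float = 0.0,
    missing_rate: float = 0.0,
):
    """Simulate RIL mosaics, genotypes and the founder-origin truth table.

    Per line: F1 = donor x recipient, backcross(es) to the recipient, the
    two designated BC1F1s intercrossed, then ``ssd_generations`` selfings.
    Returns (mosaics, MarkerGenotypeTable, truth DataFrame).
    """
    unknown = {d for pair in design.donor_pairs for d in pair} - set(panel.donors)
    if unknown:
        raise ValueError(f"design donors not in panel: {sorted(unknown)}")
    lengths = gmap.chrom_lengths
    recipient = founder_mosaic(panel.recipient_index, lengths)
    mosaics, line_ids, cross_ids = [], [], []
    for (p, q), n_lines in zip(design.donor_pairs, design.lines_per_subpop):
        label = cross_label(p, q)
        ip, iq = panel.founder_index(p), panel.founder_index(q)
        donor_p, donor_q = founder_mosaic(ip, lengths), founder_mosaic(iq, lengths)
        for i in range(n_lines):
            bc_parents = []
            for donor in (donor_p, donor_q):
                plant = cross(donor, recipient, rng)  # F1
                for _ in range(design.backcrosses_to_recipient):
                    plant = cross(plant, recipient, rng)  # BC1F1
                bc_parents.append(plant)
            line = cross(bc_parents[0], bc_parents[1], rng)  # intercross F1
            for _ in range(design.ssd_generations):
                line = self_once(line, rng)
            mosaics.append(line)
            line_ids.append(f"{label}_{i + 1:03d}")
            cross_ids.append(label)
    geno = genotypes_from_mosaics(mosaics, panel, gmap, rng, genotyping_error, missing_rate)
    table = MarkerGenotypeTable(line_ids, cross_ids, geno)
    truth = truth_table(mosaics, line_ids, panel, gmap)
    logger.info("simulated %d lines in %d subpopulations", len(line_ids), len(design.donor_pairs))
    return mosaics, table, truth


def genotypes_from_mosaics(
    mosaics: list[FounderMosaic],
    panel: FounderPanel,
    gmap: GeneticMap,
    rng: np.random.Generator | None = None,
    genotyping_error: float = 0.0,
    missing_rate: float = 0.0,
) -> np.ndarray:
    """Read SNP dosages off mosaics via founder alleles (deterministic at
    error rate 0)."""
    n, m = len(mosaics), gmap.n_markers
    geno = np.full((n, m), MISSING, dtype=np.int8)
    col_of = {mk: j for j, mk in enumerate(gmap.markers)}
    for i, mos in enumerate(mosaics):
        for chrom in gmap.chromosomes:
            pos = gmap.positions(chrom)
            cols = [col_of[mk] for mk in gmap.markers_on(chrom)]
            h1, h2 = mos.homologs[chrom]
            f1, f2 = h1.founder_at(pos), h2.founder_at(pos)
            a1 = panel.alleles[f1, cols]
            a2 = panel.alleles[f2, cols]
            g = a1 + a2
            g[(a1 == MISSING) | (a2 == MISSING)] = MISSING
            geno[i, cols] = g
    if genotyping_error > 0 or missing_rate > 0:
        if rng is None:
            raise ValueError("rng required when error or missingness is nonzero")
        called = geno != MISSING
        if genotyping_error > 0:
            flip = called & (rng.random(geno.shape) < genotyping_error)
            # symmetric error: replace by one of the two other dosage codes
            shift = rng.integers(1, 3, size=geno.shape)
            geno[flip] = ((geno[flip] + shift[flip]) % 3).astype(np.int8)
        if missing_rate > 0:
            geno[called & (rng.random(geno.shape) < missing_rate)] = MISSING
    return geno


def truth_table(
    mosaics: list[FounderMosaic],
    line_ids: list[str],
    panel: FounderPanel,
    gmap: GeneticMap,
) -> pd.DataFrame:
    """Long table of true founder-origin dose per line and marker."""
    rows = []
    for lid, mos in zip(line_ids, mosaics):
        for chrom in gmap.chromosomes:
            pos = gmap.positions(chrom)
            names = gmap.markers_on(chrom)
            h1, h2 = mos.homologs[chrom]
            f1, f2 = h1.founder_at(pos), h2.founder_at(pos)
            for mk, a, b in zip(names, f1, f2):
                dose = np.zeros(panel.n_founders)
                dose[a] += 0.5
                dose[b] += 0.5
                rows.append((lid, mk, *dose))
    cols = ["line_id", "marker"] + [f"dose_{f}" for f in panel.founder_names]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Phenotypes


@dataclass(frozen=True)
class QTL:
    chromosome: str
    position: float
    effects: dict[str, float]  # per wild founder, trait units per genome dose


@dataclass(frozen=True)
class QTLSpec:
    """Generative phenotype model: cross means, QTL effects, residual noise.

    Effects are additive per founder-genome dose relative to the recipient
    (dose 0/0.5/1).  When ``heritability_target`` is set the residual sd is
    solved from the realised genetic variance on the plot (single-replicate)
    basis; otherwise ``residual_sd`` applies per cross (or globally).
    """

    qtls: list[QTL]
    cross_means: dict[str, float] = field(default_factory=dict)
    residual_sd: dict[str, float] | float = 10.0
    replicates: int = 4
    heritability_target: float | None = None

    def __post_init__(self) -> None:
        if self.heritability_target is not None and not 0 < self.heritability_target <= 1:
            raise ValueError("heritability_target must be in (0, 1]")


def simulate_phenotypes(
    line_ids: list[str],
    cross_ids: list[str],
    mosaics: list[FounderMosaic],
    panel: FounderPanel,
    spec: QTLSpec,
    rng: np.random.Generator,
    units: str = "mm",
) -> PhenotypeTable:
    """Draw replicate phenotypes: genetic value + Normal residual noise."""
    n = len(line_ids)
    genetic = np.zeros(n)
    for i, (cid, mos) in enumerate(zip(cross_ids, mosaics)):
        g = spec.cross_means.get(cid, 0.0)
        for qtl in spec.qtls:
            dose = mos.dose_at(qtl.chromosome, qtl.position, panel.n_founders)
            for fname, eff in qtl.effects.items():
                g += dose[panel.founder_index(fname)] * eff
        genetic[i] = g
    if spec.heritability_target is not None:
        var_g = float(np.var(genetic))
        if var_g <= 0:
            raise ValueError("heritability target unreachable: zero genetic variance")
        h2 = spec.heritability_target
        sd = 0.0 if h2 == 1 else float(np.sqrt(var_g * (1 - h2) / h2))
        sd_of = {cid: sd for cid in set(cross_ids)}
    elif isinstance(spec.residual_sd, dict):
        sd_of = spec.residual_sd
    else:
        sd_of = {cid: float(spec.residual_sd) for cid in set(cross_ids)}
    rows = []
    for i, (lid, cid) in enumerate(zip(line_ids, cross_ids)):
        sd = sd_of[cid]
        for r in range(spec.replicates):
            value = genetic[i] + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            rows.append((lid, cid, f"rep{r + 1}", value))
    return PhenotypeTable(
        pd.DataFrame(rows, columns=["line_id", "cross_id", "replicate_id", "value"]), units=units
    )


# ---------------------------------------------------------------------------
# Selfed progeny (HIF families)


def simulate_self_progeny(
    parent: FounderMosaic,
    n: int,
    panel: FounderPanel,
    gmap: GeneticMap,
    rng: np.random.Generator,
    id_prefix: str = "prog",
) -> tuple[list[FounderMosaic], MarkerGenotypeTable]:
    """n selfed offspring of one plant, each from two independent gametes."""
    if n < 1:
        raise ValueError("n must be >= 1")
    progeny = [self_once(parent, rng) for _ in range(n)]
    geno = genotypes_from_mosaics(progeny, panel, gmap)
    ids = [f"{id_prefix}_{i + 1:04d}" for i in range(n)]
    table = MarkerGenotypeTable(ids, ["self"] * n, geno)
    return progeny, table


# ---------------------------------------------------------------------------
# Default study conditions


BARLEY_CHROMOSOMES = [f"{i}H" for i in range(1, 8)]
DEFAULT_FOUNDERS = ["Morex", "HID4", "HID64", "HID369", "HID382"]


def default_map(
    markers_per_chromosome: int = 52,
    chrom_length: float = 150.0,
    chromosomes: list[str] | None = None,
) -> GeneticMap:
    """Evenly spaced synthetic map: 7 chromosomes x 52 markers ≈ the 365
    informative SNPs of a genotyping array, 150 cM per chromosome."""
    chromosomes = chromosomes or BARLEY_CHROMOSOMES
    rows = []
    for chrom in chromosomes:
        pos = np.linspace(0.0, chrom_length, markers_per_chromosome)
        for j, p in enumerate(pos):
            rows.append((f"m{chrom}_{j + 1:03d}", chrom, float(p)))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chromosome", "position"]))


def default_panel(
    gmap: GeneticMap,
    rng: np.random.Generator,
    founders: list[str] | None = None,
    informative_fraction: float = 0.5,
) -> FounderPanel:
    """Biallelic founder panel: recipient carries the reference allele
    everywhere; each donor carries the alternate allele at a random
    ``informative_fraction`` of markers (independently per donor)."""
    founders = founders or DEFAULT_FOUNDERS
    alleles = np.zeros((len(founders), gmap.n_markers), dtype=np.int8)
    for i in range(1, len(founders)):
        alleles[i] = (rng.random(gmap.n_markers) < informative_fraction).astype(np.int8)
    return FounderPanel(founders, alleles, recipient_index=0)
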