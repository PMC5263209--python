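"""Heterogeneous-inbred-family (HIF) fine mapping.

A RIL still heterozygous at a target QTL marker segregates only locally;
its selfed progeny form a near-isogenic family.  Fine mapping proceeds by
(i) selecting heterozygous parents, (ii) screening progeny for
recombination between two flanking markers, (iii) estimating local
two-point linkage from codominant genotype counts, and (iv) delimiting the
QTL interval from genotype-phenotype co-segregation across the recombinant
near-isogenic lines.

A progeny plant is called recombinant when its genotype class (0/1/2)
differs between the two flanks, which captures hom-het as well as hom-hom
transitions; under Haldane linkage the expected recombinant fraction among
selfed progeny is 1 - (1 - r)^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GeneticMap, MarkerGenotypeTable, logger

__all__ = [
    "RecombinantSet",
    "IntervalCall",
    "select_hif_lines",
    "find_recombinants",
    "estimate_two_point_rf",
    "haldane_r_to_cm",
    "haldane_cm_to_r",
    "delimit_interval",
    "assign_phenotype_class",
]


def haldane_cm_to_r(d_cm: float) -> float:
    """Haldane map function: recombination fraction for a cM distance."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def haldane_r_to_cm(r: float) -> float:
    """Inverse Haldane map function (r < 0.5)."""
    if r >= 0.5:
        return float("inf")
    return -50.0 * np.log(1.0 - 2.0 * r)


# ---------------------------------------------------------------------------
# HIF selection and recombinant screening


def select_hif_lines(genotypes: MarkerGenotypeTable, gmap: GeneticMap, marker: str) -> list[str]:
    """Lines heterozygous (dosage 1) at ``marker`` — the HIF parents."""
    col = gmap.index_of(marker)
    calls = genotypes.genotypes[:, col]
    if (calls == MISSING).all():
        raise ValueError(f"marker {marker!r} has no genotype calls")
    return [lid for lid, g in zip(genotypes.line_ids, calls) if g == 1]


@dataclass(frozen=True)
class RecombinantSet:
    """Progeny whose genotype class differs between the two flanks."""

    recombinant_ids: list[str]
    breakpoint_interval: tuple[str, str]  # the flanking marker pair screened
    non_recombinant_classes: dict[int, list[str]]  # flank genotype -> ids
    unscreenable_ids: list[str]

    @property
    def n_recombinant(self) -> int:
        return len(self.recombinant_ids)


def find_recombinants(
    progeny: MarkerGenotypeTable, gmap: GeneticMap, left: str, right: str
) -> RecombinantSet:
    """Screen selfed progeny with two flanking markers.

    Lines with a missing call at either flank are excluded and reported as
    unscreenable; non-recombinants are partitioned by their shared flank
    genotype class."""
    cl, cr = gmap.index_of(left), gmap.index_of(right)
    gl = progeny.genotypes[:, cl]
    gr = progeny.genotypes[:, cr]
    rec, unscreen = [], []
    classes: dict[int, list[str]] = {0: [], 1: [], 2: []}
    for lid, a, b in zip(progeny.line_ids, gl, gr):
        if a == MISSING or b == MISSING:
            unscreen.append(lid)
        elif a != b:
            rec.append(lid)
        else:
            classes[int(a)].append(lid)
    if unscreen:
        logger.warning("%d progeny unscreenable (missing flank call)", len(unscreen))
    return RecombinantSet(rec, (left, right), classes, unscreen)


# ---------------------------------------------------------------------------
# Two-point linkage


def estimate_two_point_rf(
    counts: np.ndarray, tol: float = 1e-10, max_iter: int = 500
) -> tuple[float, float]:
    """ML recombination fraction from a 3x3 codominant F2 count table.

    ``counts[g, h]`` is the number of selfed progeny with dosage g at the
    first marker and h at the second (coupling phase: parental gametes are
    0-0 and 2-2 haplotypes).  The double-heterozygote class mixes zero- and
    two-recombinant gamete pairs, so the ML estimate is found by EM over
    that ambiguity.  Returns (rf, cM via the inverse Haldane function);
    estimates beyond 0.5 are clamped with a warning."""
    c = np.asarray(counts, float)
    if c.shape != (3, 3) or c.sum() <= 0:
        raise ValueError("counts must be a 3x3 table with positive total")
    n_gametes = 2.0 * c.sum()
    # recombinant gametes carried by each unambiguous class
    rec_gametes = np.array([[0, 1, 2], [1, np.nan, 1], [2, 1, 0]], float)
    r = 0.25
    for _ in range(max_iter):
        # E-step: expected recombinant gametes in the double-het class
        w = r**2 / (r**2 + (1 - r) ** 2)
        expected = np.where(np.isnan(rec_gametes), 2.0 * w, rec_gametes)
        r_new = float((c * expected).sum() / n_gametes)
        r_new = min(max(r_new, 0.0), 0.5)
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new
    if r >= 0.5 - 1e-12:
        warnings.warn("estimated recombination fraction at the 0.5 boundary")
        r = 0.5
    return r, haldane_r_to_cm(r)


# ---------------------------------------------------------------------------
# Interval delimitation


@dataclass(frozen=True)
class IntervalCall:
    left: str
    right: str
    width_cm: float
    cosegregating: list[str]


def delimit_interval(
    genotypes: pd.DataFrame,
    phenotype_class: dict[str, int],
    gmap: GeneticMap,
) -> IntervalCall:
    """Delimit the QTL from recombinant NIL genotype-phenotype patterns.

    ``genotypes``: recombinant NILs x ordered interval markers, entries
    coded 0 (recipient class) / 2 (donor class) per homozygous NIL;
    ``phenotype_class`` maps NIL id -> 0 (recipient-like) or 2
    (donor-like).  Each NIL constrains the QTL to the marker region where
    its genotype equals its phenotype class; the call is the intersection
    of those regions.  Markers matching the phenotype class in every
    classified NIL are reported as co-segregating.

    With zero classified recombinants the full flank-to-flank interval is
    returned.  If no marker interval explains every NIL, a ValueError
    lists the contradictory lines."""
    markers = list(genotypes.columns)
    pos = {m: gmap.locate(m)[1] for m in markers}
    order = sorted(markers, key=lambda m: pos[m])
    lo_bound, hi_bound = -1, len(order)  # open bounds, marker indices
    blockers: dict[str, tuple[int | None, int | None]] = {}
    conflicts = []
    for lid, cls in phenotype_class.items():
        if lid not in genotypes.index:
            continue
        match = [genotypes.loc[lid, m] == cls for m in order]
        if not any(match):
            conflicts.append(lid)
            continue
        idx = [i for i, ok in enumerate(match) if ok]
        lo, hi = min(idx), max(idx)
        # genotype equals phenotype class on [lo, hi]; QTL must sit there,
        # bounded by the nearest mismatching markers on either side
        left_block = lo - 1 if lo > 0 else None
        right_block = hi + 1 if hi < len(order) - 1 else None
        blockers[lid] = (left_block, right_block)
    if conflicts:
        raise ValueError(f"no interval explains recombinant line(s): {sorted(conflicts)}")
    for left_block, right_block in blockers.values():
        if left_block is not None:
            lo_bound = max(lo_bound, left_block)
        if right_block is not None:
            hi_bound = min(hi_bound, right_block)
    if lo_bound >= hi_bound:
        raise ValueError(
            "contradictory recombinants: genotype-phenotype constraints leave no interval"
        )
    interior = order[lo_bound + 1 : hi_bound]
    coseg = [
        m
        for m in interior
        if all(
            genotypes.loc[lid, m] == cls
            for lid, cls in phenotype_class.items()
            if lid in genotypes.index
        )
    ]
    left = order[lo_bound] if lo_bound >= 0 else order[0]
    right = order[hi_bound] if hi_bound < len(order) else order[-1]
    return IntervalCall(left, right, float(pos[right] - pos[left]), coseg)


# ---------------------------------------------------------------------------
# Phenotype classification


def assign_phenotype_class(
    nil_values: dict[str, np.ndarray],
    reference_groups: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> dict[str, str | None]:
    """Assign each NIL to the reference class its mean does not differ from.

    Two-sided Welch t-test of the NIL's replicate values against each
    reference group; a NIL differing from all groups, or from none of
    several, is left unclassified (None).  NILs with fewer than two
    replicates are unclassified with a warning."""
    if len(reference_groups) < 2:
        raise ValueError("at least two reference groups required")
    out: dict[str, str | None] = {}
    for nil, values in nil_values.items():
        values = np.asarray(values, float)
        if len(values) < 2:
            warnings.warn(f"NIL {nil} has < 2 replicates; unclassified")
            out[nil] = None
            continue
        compatible = []
        for label, ref in reference_groups.items():
            _, p = stats.ttest_ind(values, np.asarray(ref, float), equal_var=False)
            if p > alpha:
                compatible.append(label)
        out[nil] = compatible[0] if len(compatible) == 1 else None
    return out
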