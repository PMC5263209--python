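"""Founder-origin posterior probabilities by hidden Markov model.

For each line the hidden state at a locus is the founder whose genome the
(nearly homozygous) line carries there.  Because every line descends from
the recipient and exactly two donors, the chain has three states:
recipient, donor_p, donor_q, with stationary prior (0.75, 0.125, 0.125)
from the backcross-intercross pedigree.  Transitions over d cM use a
jump-to-stationary kernel: stay with probability exp(-lambda * d *
map_expansion), otherwise redraw from the prior — this preserves the
stationary distribution by construction.  Emissions compare the observed
0/1/2 dosage call with the homozygous genotype expected under each state,
allowing a genotyping-error rate and a residual-heterozygosity mass for
'1' calls.  Forward-backward smoothing yields marginal posteriors, which
are embedded into a five-founder probability vector with exact zeros for
founders outside the line's cross.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, FounderPanel, GeneticMap, MarkerGenotypeTable, logger
from .popsim import donors_of_cross

__all__ = [
    "HMMParams",
    "FounderProbabilityTensor",
    "compute_founder_probs",
    "interpolate_to_grid",
    "read_tensor",
    "write_tensor",
]

_LAMBDA_PER_CM = 0.01  # baseline transition intensity per cM


@dataclass(frozen=True)
class HMMParams:
    """Transition/emission parameters of the founder-origin chain."""

    genotyping_error: float = 0.01
    recipient_prior: float = 0.75
    # The jump-to-stationary kernel redraws the state from the prior, so its
    # observable transition rate over d cM is lambda*expansion*(1 - sum pi^2)
    # ~= 0.41*lambda*expansion*d.  A once-backcrossed, intercrossed, selfed
    # RIL genome carries about 2 founder junctions per Morgan per homolog;
    # expansion 5 makes the kernel reproduce that junction intensity, and the
    # binned-reliability calibration confirms the choice on simulated data.
    map_expansion: float = 5.0
    residual_het_rate: float = 0.5 ** 5  # leftover F6 heterozygosity

    def __post_init__(self) -> None:
        if not 0 <= self.genotyping_error <= 1:
            raise ValueError("genotyping_error must be in [0, 1]")
        if not 0 < self.recipient_prior < 1:
            raise ValueError("recipient_prior must be in (0, 1)")
        if self.map_expansion < 1:
            raise ValueError("map_expansion must be >= 1")

    @property
    def prior(self) -> np.ndarray:
        d = (1.0 - self.recipient_prior) / 2.0
        return np.array([self.recipient_prior, d, d])


@dataclass(frozen=True)
class FounderProbabilityTensor:
    """lines x loci x founders posterior array plus locus coordinates.

    ``loci`` has columns marker (may be empty for grid points), chromosome,
    position.  Every (line, locus) probability vector sums to 1.
    """

    probs: np.ndarray
    line_ids: list[str]
    cross_ids: list[str]
    founder_names: list[str]
    loci: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (len(self.line_ids), len(self.loci), len(self.founder_names)):
            raise ValueError("tensor shape does not match labels")
        object.__setattr__(self, "probs", p)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, chrom: str, pos: float) -> int:
        sel = (self.loci["chromosome"] == chrom) & np.isclose(self.loci["position"], pos)
        idx = np.flatnonzero(sel.to_numpy())
        if len(idx) == 0:
            raise KeyError(f"no locus at {chrom}:{pos}")
        return int(idx[0])

    def at_marker(self, marker: str) -> np.ndarray:
        sel = np.flatnonzero((self.loci["marker"] == marker).to_numpy())
        if len(sel) == 0:
            raise KeyError(f"marker {marker!r} not in tensor")
        return self.probs[:, int(sel[0]), :]


# ---------------------------------------------------------------------------
# Chain pieces


def _emissions(
    obs: np.ndarray, state_alleles: np.ndarray, params: HMMParams
) -> np.ndarray:
    """Likelihood of each observed call under each state.

    obs: (n_loci,) dosage calls in {0,1,2,MISSING}; state_alleles:
    (n_loci, 3) founder allele per state in {0,1,MISSING}.  The expected
    homozygous call is twice the founder allele; 'error' mass is split onto
    the other homozygous call, and residual_het_rate carries the '1' calls.
    """
    n, s = state_alleles.shape
    e, h = params.genotyping_error, params.residual_het_rate
    lik = np.ones((n, s))
    known = state_alleles != MISSING
    expected = 2 * state_alleles
    for call in (0, 1, 2):
        rows = obs == call
        if not rows.any():
            continue
        block = np.ones((int(rows.sum()), s))
        k = known[rows]
        exp_b = expected[rows]
        if call == 1:
            block[k] = h
        else:
            match = exp_b == call
            block[k & match] = (1 - h) * (1 - e)
            block[k & ~match] = (1 - h) * e
        lik[rows] = block
    return lik


def _stay_probs(positions: np.ndarray, params: HMMParams) -> np.ndarray:
    d = np.diff(positions)
    return np.exp(-_LAMBDA_PER_CM * params.map_expansion * d)


def _forward_backward(lik: np.ndarray, stay: np.ndarray, prior: np.ndarray) -> np.ndarray:
    """Smoothed posteriors for the jump-to-stationary chain (scaled FB)."""
    n, s = lik.shape
    alpha = np.empty((n, s))
    scale = np.empty(n)
    a = prior * lik[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, n):
        e = stay[t - 1]
        pred = e * alpha[t - 1] + (1 - e) * prior  # rows of T applied
        a = pred * lik[t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]
    beta = np.ones((n, s))
    for t in range(n - 2, -1, -1):
        e = stay[t]
        nxt = lik[t + 1] * beta[t + 1]
        # (T @ nxt)_i = e * nxt_i + (1-e) * sum_j prior_j nxt_j
        beta[t] = (e * nxt + (1 - e) * float(prior @ nxt)) / scale[t + 1]
    post = alpha * beta
    return post / post.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Public operations


def compute_founder_probs(
    genotypes: MarkerGenotypeTable,
    panel: FounderPanel,
    gmap: GeneticMap,
    params: HMMParams | None = None,
    grid_positions: dict[str, np.ndarray] | None = None,
) -> FounderProbabilityTensor:
    """Smoothed founder-origin posteriors for every line and locus.

    Each line's cross label identifies its two possible donors; founders
    outside the cross receive probability exactly 0.  With
    ``grid_positions`` the chain is evaluated at extra silent loci (uniform
    emissions) and only those grid loci are returned.
    """
    params = params or HMMParams()
    prior = params.prior
    col_of = {mk: j for j, mk in enumerate(gmap.markers)}
    if grid_positions is None:
        loci = gmap.table.rename(columns={})[["marker", "chromosome", "position"]].copy()
    else:
        rows = [
            ("", chrom, float(p))
            for chrom in gmap.chromosomes
            for p in grid_positions.get(chrom, [])
        ]
        loci = pd.DataFrame(rows, columns=["marker", "chromosome", "position"])
    n_lines, n_founders = genotypes.n_lines, panel.n_founders
    out = np.zeros((n_lines, len(loci), n_founders))

    donor_cache: dict[str, tuple[int, int]] = {}
    for cid in set(genotypes.cross_ids):
        p, q = donors_of_cross(cid, panel.founder_names)
        donor_cache[cid] = (panel.founder_index(p), panel.founder_index(q))

    for chrom in gmap.chromosomes:
        mk_names = gmap.markers_on(chrom)
        mk_pos = gmap.positions(chrom)
        cols = np.array([col_of[m] for m in mk_names])
        if grid_positions is None:
            out_pos = mk_pos
            out_idx = np.flatnonzero((loci["chromosome"] == chrom).to_numpy())
            all_pos = mk_pos
            is_out = np.ones(len(mk_pos), bool)
            marker_slot = np.arange(len(mk_pos))
        else:
            gpos = np.asarray(grid_positions.get(chrom, []), dtype=float)
            out_idx = np.flatnonzero((loci["chromosome"] == chrom).to_numpy())
            all_pos = np.unique(np.concatenate((mk_pos, gpos)))
            is_out = np.isin(all_pos, gpos)
            marker_slot = np.searchsorted(all_pos, mk_pos)
        stay = _stay_probs(all_pos, params)
        for i in range(n_lines):
            ip, iq = donor_cache[genotypes.cross_ids[i]]
            state_founders = np.array([panel.recipient_index, ip, iq])
            obs = genotypes.genotypes[i, cols]
            state_alleles = panel.alleles[state_founders][:, cols].T  # loci x 3
            lik = np.ones((len(all_pos), 3))
            lik[marker_slot] = _emissions(obs, state_alleles, params)
            post = _forward_backward(lik, stay, prior)
            out[i][np.ix_(out_idx, state_founders)] = post[is_out]

    all_missing = (genotypes.genotypes == MISSING).all(axis=1)
    for i in np.flatnonzero(all_missing):
        logger.warning("line %s has no genotype calls; prior returned", genotypes.line_ids[i])
    return FounderProbabilityTensor(
        out, list(genotypes.line_ids), list(genotypes.cross_ids), list(panel.founder_names), loci
    )


def interpolate_to_grid(
    genotypes: MarkerGenotypeTable,
    panel: FounderPanel,
    gmap: GeneticMap,
    step: float,
    params: HMMParams | None = None,
) -> FounderProbabilityTensor:
    """Posteriors on a regular cM grid (multiples of ``step``), obtained by
    smoothing with silent loci inserted at the grid positions."""
    if step <= 0:
        raise ValueError("step must be > 0")
    grid = {}
    for chrom in gmap.chromosomes:
        length = gmap.chrom_lengths[chrom]
        pts = np.arange(0.0, length + step / 2, step)
        grid[chrom] = pts if len(pts) else np.array([0.0])
    return compute_founder_probs(genotypes, panel, gmap, params, grid_positions=grid)


# ---------------------------------------------------------------------------
# Serialisation (long TSV: line, locus, founder, probability)


def write_tensor(tensor: FounderProbabilityTensor, path) -> None:
    n, m, f = tensor.probs.shape
    loci = tensor.loci
    df = pd.DataFrame(
        {
            "line_id": np.repeat(tensor.line_ids, m * f),
            "cross_id": np.repeat(tensor.cross_ids, m * f),
            "marker": np.tile(np.repeat(loci["marker"].to_numpy(), f), n),
            "chromosome": np.tile(np.repeat(loci["chromosome"].to_numpy(), f), n),
            "position": np.tile(np.repeat(loci["position"].to_numpy(), f), n),
            "founder": np.tile(tensor.founder_names, n * m),
            "probability": tensor.probs.reshape(-1),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_tensor(path) -> FounderProbabilityTensor:
    df = pd.read_csv(path, sep="\t", dtype={"marker": str}, keep_default_na=False)
    founders = list(dict.fromkeys(df["founder"]))
    line_ids = list(dict.fromkeys(df["line_id"]))
    cross_of = dict(zip(df["line_id"], df["cross_id"]))
    first = df[df["line_id"] == line_ids[0]]
    loci = (
        first[["marker", "chromosome", "position"]]
        .drop_duplicates()
        .reset_index(drop=True)
        .astype({"position": float})
    )
    n, m, f = len(line_ids), len(loci), len(founders)
    probs = df["probability"].to_numpy(float).reshape(n, m, f)
    return FounderProbabilityTensor(
        probs, line_ids, [cross_of[l] for l in line_ids], founders, loci
    )
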