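"""Three-stage mixed-model QTL analysis with random founder effects.

Stage 1 (simple interval mapping) fits, at every locus l,

    y_ik = mu_k + x_ikl' beta_l + e_ik,

where y_ik is the replicate-mean trait of line i in cross k, mu_k are fixed
cross means, x_ikl is the 4-vector of wild-founder probabilities at the
locus, beta_l ~ N(0, sigma2_l I4) are random founder effects (deviations
from the recipient) and e_ik has cross-specific variance sigma2_e,k.

Stage 2 (multi-QTL scan) repeats the genome scan with the strongest QTLs
so far as additional random cofactor terms, excluding cofactors within a
window (default 10 cM) of the tested locus, until no locus exceeds the
significance threshold (default -log10 p = 3.2).

Stage 3 refits the joint model with all detected QTLs and reports shrunken
founder-effect predictions with prediction standard errors, plus a p value
per QTL from dropping its variance component.  Locus significance is the
likelihood-ratio test of sigma2_l = 0 against the boundary-corrected
(1/2) chi2_0 + (1/2) chi2_1 mixture null.

REML maximisation uses average-information updates with expectation-
maximisation fallback steps; fixed effects are profiled analytically.  The
response is standardised internally, so estimates are exactly scale
equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .io import GeneticMap, PhenotypeTable, logger
from .founderprob import FounderProbabilityTensor

__all__ = [
    "REMLFit",
    "ScanProfile",
    "QTLResult",
    "reml",
    "fit_locus_model",
    "scan_sim",
    "scan_mqm",
    "fit_final",
    "test_epistasis",
    "mixture_lrt_pvalue",
]

_VAR_FLOOR = 1e-10
_TOL = 1e-8
_MAX_ITER = 200


# ---------------------------------------------------------------------------
# REML core


@dataclass
class REMLFit:
    """Restricted-likelihood fit of y = F b + sum_t Z_t u_t + e."""

    loglik: float
    fixed_effects: np.ndarray  # GLS estimates for the columns of F
    resid_var: np.ndarray  # per residual group
    term_var: np.ndarray  # per random term
    blups: list[np.ndarray]
    blup_se: list[np.ndarray]
    converged: bool
    n_iter: int


class _Likelihood:
    """Woodbury-based REML pieces for diagonal-plus-low-rank covariance."""

    def __init__(self, y, F, Z_list, group_idx, n_groups):
        self.y, self.F = y, F
        self.Z_list = Z_list
        self.Z = np.hstack(Z_list) if Z_list else np.zeros((len(y), 0))
        self.block = np.concatenate(
            [np.full(Z.shape[1], t) for t, Z in enumerate(Z_list)]
        ) if Z_list else np.zeros(0, int)
        self.group_idx = group_idx
        self.n_groups = n_groups
        self.n, self.m = self.Z.shape

    def evaluate(self, resid_var, term_var):
        y, F, Z = self.y, self.F, self.Z
        D = resid_var[self.group_idx]
        Dinv = 1.0 / D
        if self.m:
            g = term_var[self.block]
            ZD = Z * Dinv[:, None]
            W = Z.T @ ZD + np.diag(1.0 / g)
            cW = linalg.cho_factor(W, lower=True)
            logdetV = np.log(D).sum() + np.log(g).sum() + 2 * np.log(
                np.diag(cW[0])
            ).sum()

            def vinv(X):
                return X * Dinv[:, None] - ZD @ linalg.cho_solve(cW, ZD.T @ X)

            diag_vinv = Dinv - np.einsum(
                "ij,ij->i", ZD, linalg.cho_solve(cW, ZD.T).T
            )
        else:

            def vinv(X):
                return X * Dinv[:, None]

            logdetV = np.log(D).sum()
            diag_vinv = Dinv
        VF = vinv(F)
        Vy = vinv(y[:, None])[:, 0]
        FVF = F.T @ VF
        cF = linalg.cho_factor(FVF, lower=True)
        logdetF = 2 * np.log(np.diag(cF[0])).sum()
        b = linalg.cho_solve(cF, F.T @ Vy)
        Py = Vy - VF @ b
        yPy = float(y @ Py)
        ll = -0.5 * (logdetV + logdetF + yPy)
        H = linalg.cho_solve(cF, VF.T)  # (FVF)^-1 F' Vinv
        diag_P = diag_vinv - np.einsum("ij,ji->i", VF, H)
        if self.m:
            VinvZ = vinv(Z)
            M1 = Z.T @ VinvZ
            M2 = VF.T @ Z
            ZPZ = M1 - M2.T @ linalg.cho_solve(cF, M2)
            ZPy = Z.T @ Py
        else:
            ZPZ = np.zeros((0, 0))
            ZPy = np.zeros(0)

        def pmul(X):
            VX = vinv(X)
            return VX - VF @ linalg.cho_solve(cF, VF.T @ X)

        return {
            "ll": ll,
            "b": b,
            "Py": Py,
            "diag_P": diag_P,
            "ZPZ": ZPZ,
            "ZPy": ZPy,
            "pmul": pmul,
        }


def _score_ai(lik: _Likelihood, state, resid_var, term_var):
    """REML score vector and average-information matrix."""
    Py, diag_P, ZPZ, ZPy = state["Py"], state["diag_P"], state["ZPZ"], state["ZPy"]
    n_g, n_t = lik.n_groups, len(lik.Z_list)
    score = np.zeros(n_g + n_t)
    dV_Py = np.zeros((lik.n, n_g + n_t))
    for k in range(n_g):
        sel = lik.group_idx == k
        score[k] = -0.5 * (diag_P[sel].sum() - (Py[sel] ** 2).sum())
        dV_Py[sel, k] = Py[sel]
    for t in range(n_t):
        cols = lik.block == t
        score[n_g + t] = -0.5 * (np.trace(ZPZ[np.ix_(cols, cols)]) - (ZPy[cols] ** 2).sum())
        dV_Py[:, n_g + t] = lik.Z[:, cols] @ ZPy[cols]
    P_dV_Py = state["pmul"](dV_Py)
    ai = 0.5 * dV_Py.T @ P_dV_Py
    return score, ai


def _em_update(lik: _Likelihood, state, resid_var, term_var):
    Py, diag_P, ZPZ, ZPy = state["Py"], state["diag_P"], state["ZPZ"], state["ZPy"]
    new_resid = resid_var.copy()
    for k in range(lik.n_groups):
        sel = lik.group_idx == k
        nk = int(sel.sum())
        s2 = resid_var[k]
        e_hat = s2 * Py[sel]
        new_resid[k] = ((e_hat**2).sum() + s2 * nk - s2**2 * diag_P[sel].sum()) / nk
    new_term = term_var.copy()
    for t in range(len(lik.Z_list)):
        cols = lik.block == t
        mt = int(cols.sum())
        g = term_var[t]
        u_hat = g * ZPy[cols]
        tr = np.trace(ZPZ[np.ix_(cols, cols)])
        new_term[t] = ((u_hat**2).sum() + g * mt - g**2 * tr) / mt
    return new_resid, new_term


def reml(
    y: np.ndarray,
    F: np.ndarray,
    Z_list: list[np.ndarray],
    group_idx: np.ndarray,
    tol: float = _TOL,
    max_iter: int = _MAX_ITER,
) -> REMLFit:
    """REML fit by average-information iterations with EM fallback.

    y is standardised internally; all reported variances, effects and the
    restricted log-likelihood are transformed back to the original scale.
    """
    y = np.asarray(y, float)
    n = len(y)
    n_groups = int(group_idx.max()) + 1
    sd = float(y.std())
    if sd == 0:
        sd = 1.0
    shift = float(y.mean())
    ys = (y - shift) / sd

    lik = _Likelihood(ys, F, Z_list, group_idx, n_groups)
    n_t = len(Z_list)
    resid_var = np.full(n_groups, 0.5)
    term_var = np.full(n_t, 0.5 / max(n_t, 1))
    state = lik.evaluate(resid_var, term_var)
    ll = state["ll"]
    converged = False
    small_streak = 0
    it = 0
    for it in range(1, max_iter + 1):
        if it <= 2:
            new_resid, new_term = _em_update(lik, state, resid_var, term_var)
        else:
            score, ai = _score_ai(lik, state, resid_var, term_var)
            theta = np.concatenate([resid_var, term_var])
            try:
                step = np.linalg.solve(ai + 1e-12 * np.eye(len(ai)), score)
            except np.linalg.LinAlgError:
                step = None
            if step is None:
                new_resid, new_term = _em_update(lik, state, resid_var, term_var)
            else:
                new = theta + step
                for _ in range(12):
                    trial = np.maximum(new, _VAR_FLOOR)
                    try:
                        trial_state = lik.evaluate(trial[:n_groups], trial[n_groups:])
                    except (np.linalg.LinAlgError, linalg.LinAlgError, ValueError):
                        trial_state = None
                    if trial_state is not None and trial_state["ll"] >= ll - 1e-12:
                        break
                    step *= 0.5
                    new = theta + step
                else:
                    trial_state = None
                if trial_state is None:
                    new_resid, new_term = _em_update(lik, state, resid_var, term_var)
                else:
                    new_resid, new_term = trial[:n_groups], trial[n_groups:]
        new_resid = np.maximum(new_resid, _VAR_FLOOR)
        new_term = np.maximum(new_term, _VAR_FLOOR) if n_t else new_term
        new_state = lik.evaluate(new_resid, new_term)
        delta = new_state["ll"] - ll
        resid_var, term_var, state, ll = new_resid, new_term, new_state, new_state["ll"]
        # the LRT consumes the restricted likelihood, so likelihood change is
        # the convergence currency; boundary crawls flatten it quickly
        if it > 2 and abs(delta) < tol:
            small_streak += 1
            if small_streak >= 2:
                converged = True
                break
        else:
            small_streak = 0

    blups, blup_se = [], []
    for t in range(n_t):
        cols = lik.block == t
        g = term_var[t]
        u = g * state["ZPy"][cols]
        pev = g * np.eye(int(cols.sum())) - g**2 * state["ZPZ"][np.ix_(cols, cols)]
        blups.append(u * sd)
        blup_se.append(np.sqrt(np.maximum(np.diag(pev), 0.0)) * sd)
    fixed = state["b"] * sd
    # undo the centering: the intercept-like columns absorb the shift
    fixed = fixed + shift * _shift_coefficients(F)
    return REMLFit(
        loglik=float(ll),
        fixed_effects=fixed,
        resid_var=resid_var * sd**2,
        term_var=term_var * sd**2,
        blups=blups,
        blup_se=blup_se,
        converged=converged,
        n_iter=it,
    )


def _shift_coefficients(F: np.ndarray) -> np.ndarray:
    """Coefficients c with F @ c = 1 (exists when F spans the constant)."""
    c, *_ = np.linalg.lstsq(F, np.ones(F.shape[0]), rcond=None)
    return c


def mixture_lrt_pvalue(lrt: float) -> float:
    """p value of the (1/2) chi2_0 + (1/2) chi2_1 boundary mixture."""
    if lrt <= 0:
        return 1.0
    return float(0.5 * stats.chi2.sf(lrt, df=1))


# ---------------------------------------------------------------------------
# Data alignment


@dataclass(frozen=True)
class _Aligned:
    y: np.ndarray
    F: np.ndarray
    group_idx: np.ndarray
    line_ids: list[str]
    tensor_rows: np.ndarray
    wild_cols: np.ndarray
    cross_labels: list[str]


def _align(tensor: FounderProbabilityTensor, phenos: PhenotypeTable, recipient_index: int = 0) -> _Aligned:
    means = phenos.line_means()
    row_of = {lid: i for i, lid in enumerate(tensor.line_ids)}
    keep = [lid for lid in means.index if lid in row_of]
    if not keep:
        raise ValueError("no phenotype line ids match the probability tensor")
    rows = np.array([row_of[lid] for lid in keep])
    y = means.loc[keep].to_numpy(float)
    crosses = [tensor.cross_ids[r] for r in rows]
    labels = sorted(set(crosses))
    g_idx = np.array([labels.index(c) for c in crosses])
    F = np.zeros((len(y), len(labels)))
    F[np.arange(len(y)), g_idx] = 1.0
    wild_cols = np.array([j for j in range(len(tensor.founder_names)) if j != recipient_index])
    return _Aligned(y, F, g_idx, keep, rows, wild_cols, labels)


def _locus_Z(tensor: FounderProbabilityTensor, aligned: _Aligned, locus: int) -> np.ndarray:
    return tensor.probs[aligned.tensor_rows, locus][:, aligned.wild_cols]


# ---------------------------------------------------------------------------
# Locus model and scans


@dataclass(frozen=True)
class ScanProfile:
    """Genome-wide -log10 p profile with the cofactors it was built under."""

    table: pd.DataFrame  # columns chromosome, position, marker, minus_log10_p
    cofactors: tuple[int, ...] = ()


@dataclass(frozen=True)
class QTLResult:
    name: str
    chromosome: str
    position: float
    peak_marker: str
    flank_left: str
    flank_right: str
    minus_log10_p: float
    effects: dict[str, tuple[float, float]]  # founder -> (effect, se)
    locus_index: int = -1


def fit_locus_model(
    tensor: FounderProbabilityTensor,
    phenos: PhenotypeTable,
    locus: int,
    cofactors: tuple[int, ...] = (),
) -> tuple[REMLFit | None, float]:
    """REML locus test: returns the full-model fit and -log10 p for the
    founder-effect variance at ``locus`` (mixture LRT against the model
    without it).  A locus with constant probabilities gives p = 1 exactly."""
    aligned = _align(tensor, phenos)
    return _fit_locus(tensor, aligned, locus, cofactors)


def _fit_locus(tensor, aligned, locus, cofactors, null_cache=None):
    Zl = _locus_Z(tensor, aligned, locus)
    if np.ptp(Zl, axis=0).max(initial=0.0) < 1e-10:
        return None, 0.0
    try:
        full = reml(aligned.y, aligned.F, [
            _locus_Z(tensor, aligned, c) for c in cofactors
        ] + [Zl], aligned.group_idx)
        null_ll = None if null_cache is None else null_cache.get(cofactors)
        if null_ll is None:
            null = reml(
                aligned.y, aligned.F,
                [_locus_Z(tensor, aligned, c) for c in cofactors],
                aligned.group_idx,
            )
            null_ll = null.loglik
            if null_cache is not None:
                null_cache[cofactors] = null_ll
    except (np.linalg.LinAlgError, linalg.LinAlgError):
        logger.warning("REML failed at locus %d; p flagged missing", locus)
        return None, float("nan")
    if not full.converged:
        logger.warning("REML not converged at locus %d within %d iterations", locus, _MAX_ITER)
        return full, float("nan")
    lrt = 2.0 * (full.loglik - null_ll)
    p = mixture_lrt_pvalue(lrt)
    return full, float(-np.log10(max(p, 1e-300)))


def scan_sim(
    tensor: FounderProbabilityTensor,
    phenos: PhenotypeTable,
    cofactors: tuple[int, ...] = (),
    exclusion_window: float = 10.0,
) -> ScanProfile:
    """Genome scan: the locus model at every tensor locus.  With cofactors
    supplied this is one iteration of the multi-QTL scan (cofactors within
    ``exclusion_window`` cM of the tested locus are dropped)."""
    aligned = _align(tensor, phenos)
    loci = tensor.loci
    vals = np.zeros(len(loci))
    null_cache: dict[tuple[int, ...], float] = {}
    for l in range(len(loci)):
        used = _usable_cofactors(loci, cofactors, l, exclusion_window)
        _, mlp = _fit_locus(tensor, aligned, l, used, null_cache)
        vals[l] = mlp
    table = loci.copy()
    table["minus_log10_p"] = vals
    return ScanProfile(table, tuple(cofactors))


def _usable_cofactors(loci, cofactors, locus, window):
    chrom = loci["chromosome"].iloc[locus]
    pos = loci["position"].iloc[locus]
    used = []
    for c in cofactors:
        if loci["chromosome"].iloc[c] != chrom:
            used.append(c)
        elif abs(loci["position"].iloc[c] - pos) > window:
            used.append(c)
    return tuple(used)


def scan_mqm(
    tensor: FounderProbabilityTensor,
    phenos: PhenotypeTable,
    threshold: float = 3.2,
    exclusion_window: float = 10.0,
    max_iterations: int = 20,
) -> tuple[list[int], ScanProfile]:
    """Iterative multi-QTL scan.

    Repeatedly scans, adds the strongest locus above ``threshold`` as a
    cofactor (each locus at most once) and rescans until no new locus
    exceeds the threshold.  Loci inside the exclusion window of an
    existing cofactor are tested with that cofactor dropped, so they would
    re-detect the same QTL; new cofactors are therefore required to lie
    outside the window of every previous one.  Returns the cofactor loci
    in detection order and the final profile."""
    cofactors: list[int] = []
    profile = scan_sim(tensor, phenos)
    loci = tensor.loci
    for _ in range(max_iterations):
        vals = profile.table["minus_log10_p"].to_numpy()
        order = _peak_order(profile.table)
        best = None
        for idx in order:
            if not (vals[idx] > threshold) or idx in cofactors:
                continue
            near = _usable_cofactors(loci, cofactors, idx, exclusion_window)
            if len(near) < len(cofactors):  # inside a cofactor's window
                continue
            best = idx
            break
        if best is None:
            break
        cofactors.append(int(best))
        logger.info(
            "cofactor added at %s %.2f cM (-log10 p = %.2f)",
            profile.table["chromosome"].iloc[best],
            profile.table["position"].iloc[best],
            vals[best],
        )
        profile = scan_sim(tensor, phenos, tuple(cofactors), exclusion_window)
    return cofactors, profile


def _peak_order(table: pd.DataFrame) -> np.ndarray:
    """Descending -log10 p; ties broken by chromosome label then cM."""
    df = table.reset_index()
    df = df.sort_values(
        ["minus_log10_p", "chromosome", "position"],
        ascending=[False, True, True],
        kind="stable",
    )
    return df["index"].to_numpy()


# ---------------------------------------------------------------------------
# Final joint model


def fit_final(
    tensor: FounderProbabilityTensor,
    phenos: PhenotypeTable,
    qtl_loci: list[int],
    gmap: GeneticMap | None = None,
    min_separation: float = 10.0,
    name_prefix: str = "Q",
) -> list[QTLResult]:
    """Joint model over all detected QTLs: founder-effect predictions with
    prediction SEs, and a per-QTL p value from dropping its term."""
    if not qtl_loci:
        raise ValueError("at least one QTL required")
    loci = tensor.loci
    for a in qtl_loci:
        for b in qtl_loci:
            if a < b and loci["chromosome"].iloc[a] == loci["chromosome"].iloc[b]:
                if abs(loci["position"].iloc[a] - loci["position"].iloc[b]) < min_separation:
                    raise ValueError(
                        f"QTL loci {a} and {b} are within {min_separation} cM; merge them"
                    )
    aligned = _align(tensor, phenos)
    Z_list = [_locus_Z(tensor, aligned, l) for l in qtl_loci]
    full = reml(aligned.y, aligned.F, Z_list, aligned.group_idx)
    results = []
    order = sorted(
        range(len(qtl_loci)),
        key=lambda t: (
            str(loci["chromosome"].iloc[qtl_loci[t]]),
            float(loci["position"].iloc[qtl_loci[t]]),
        ),
    )
    counter: dict[str, int] = {}
    names = {}
    for t in order:
        l = qtl_loci[t]
        chrom = str(loci["chromosome"].iloc[l])
        counter[chrom] = counter.get(chrom, 0) + 1
        names[l] = f"{name_prefix}{chrom.rstrip('H')}.{counter[chrom]}"
    wild_names = [tensor.founder_names[j] for j in aligned.wild_cols]
    for t, l in enumerate(qtl_loci):
        others = [Z for j, Z in enumerate(Z_list) if j != t]
        null = reml(aligned.y, aligned.F, others, aligned.group_idx)
        lrt = 2.0 * (full.loglik - null.loglik)
        mlp = float(-np.log10(max(mixture_lrt_pvalue(lrt), 1e-300)))
        chrom = str(loci["chromosome"].iloc[l])
        pos = float(loci["position"].iloc[l])
        peak = str(loci["marker"].iloc[l]) or f"{chrom}:{pos:g}"
        left, right = _flanking_markers(gmap, chrom, pos) if gmap else ("", "")
        effects = {
            fname: (float(full.blups[t][j]), float(full.blup_se[t][j]))
            for j, fname in enumerate(wild_names)
        }
        results.append(
            QTLResult(names[l], chrom, pos, peak, left, right, mlp, effects, locus_index=l)
        )
    return results


def _flanking_markers(gmap: GeneticMap, chrom: str, pos: float) -> tuple[str, str]:
    names = gmap.markers_on(chrom)
    positions = gmap.positions(chrom)
    left = [n for n, p in zip(names, positions) if p < pos - 1e-9]
    right = [n for n, p in zip(names, positions) if p > pos + 1e-9]
    return (left[-1] if left else "Start", right[0] if right else "End")


# ---------------------------------------------------------------------------
# Epistasis


def test_epistasis(
    tensor: FounderProbabilityTensor,
    phenos: PhenotypeTable,
    qtl_loci: list[int],
) -> pd.DataFrame:
    """Pairwise interaction tests between detected QTLs.

    For each pair, a random term built from the products of the two loci's
    founder-probability columns is added to the joint additive model; the
    mixture LRT p is Bonferroni-corrected over all pairs."""
    if len(qtl_loci) < 2:
        raise ValueError("at least two QTLs required")
    aligned = _align(tensor, phenos)
    Z_list = [_locus_Z(tensor, aligned, l) for l in qtl_loci]
    base = reml(aligned.y, aligned.F, Z_list, aligned.group_idx)
    rows = []
    pairs = [(a, b) for a in range(len(qtl_loci)) for b in range(a + 1, len(qtl_loci))]
    for a, b in pairs:
        inter = _interaction_columns(Z_list[a], Z_list[b])
        if inter.shape[1] == 0:
            raw = 1.0
        else:
            fit = reml(aligned.y, aligned.F, Z_list + [inter], aligned.group_idx)
            raw = mixture_lrt_pvalue(2.0 * (fit.loglik - base.loglik))
        rows.append((qtl_loci[a], qtl_loci[b], raw))
    df = pd.DataFrame(rows, columns=["locus_a", "locus_b", "p_raw"])
    df["p_bonferroni"] = np.minimum(df["p_raw"] * len(pairs), 1.0)
    return df


def _interaction_columns(Za: np.ndarray, Zb: np.ndarray) -> np.ndarray:
    cols = [Za[:, i] * Zb[:, j] for i in range(Za.shape[1]) for j in range(Zb.shape[1])]
    mat = np.column_stack(cols) if cols else np.zeros((len(Za), 0))
    keep = np.ptp(mat, axis=0) > 1e-12
    return mat[:, keep]


# ---------------------------------------------------------------------------
# Output tables


def profile_to_frame(profile: ScanProfile) -> pd.DataFrame:
    return profile.table[["chromosome", "position", "marker", "minus_log10_p"]].copy()


_QTL_FRAME_COLUMNS = [
    "qtl", "chromosome", "position_cM", "peak_marker", "flank_left",
    "flank_right", "minus_log10_p",
]


def qtls_to_frame(qtls: list[QTLResult], founder_order: list[str] | None = None) -> pd.DataFrame:
    if not qtls:
        return pd.DataFrame(columns=_QTL_FRAME_COLUMNS)
    rows = []
    for q in qtls:
        row = {
            "qtl": q.name,
            "chromosome": q.chromosome,
            "position_cM": q.position,
            "peak_marker": q.peak_marker,
            "flank_left": q.flank_left,
            "flank_right": q.flank_right,
            "minus_log10_p": q.minus_log10_p,
        }
        founders = founder_order or list(q.effects)
        for f in founders:
            eff, se = q.effects[f]
            row[f"effect_{f}"] = eff
            row[f"se_{f}"] = se
        rows.append(row)
    return pd.DataFrame(rows)
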