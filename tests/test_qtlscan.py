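"""Mixed-model scan: REML correctness, significance, detection, epistasis."""

import numpy as np
import pandas as pd
import pytest

from awnqtl.io import PhenotypeTable
from awnqtl.popsim import (
    QTL,
    CrossDesign,
    QTLSpec,
    default_map,
    default_panel,
    simulate_phenotypes,
    simulate_population,
)
from awnqtl.qtlscan import (
    fit_final,
    fit_locus_model,
    mixture_lrt_pvalue,
    reml,
    scan_mqm,
    scan_sim,
)
from awnqtl.qtlscan import test_epistasis as epistasis_scan

from conftest import AL71_EFFECTS, truth_tensor


def _phenos_from_values(table, values, replicates=1, rng=None, sd=0.0):
    rows = []
    for i, (lid, cid) in enumerate(zip(table.line_ids, table.cross_ids)):
        for k in range(replicates):
            noise = rng.normal(0, sd) if (rng is not None and sd > 0) else 0.0
            rows.append((lid, cid, f"rep{k}", values[i] + noise))
    return PhenotypeTable(
        pd.DataFrame(rows, columns=["line_id", "cross_id", "replicate_id", "value"])
    )


class TestREML:
    def test_balanced_one_way_matches_anova_closed_form(self):
        """REML on a balanced random-groups toy equals the expected-mean-
        squares ANOVA estimates to 1e-6."""
        rng = np.random.default_rng(3)
        g, r = 12, 5
        u = rng.normal(0, 2.0, g)
        y = np.repeat(u, r) + rng.normal(0, 1.5, g * r) + 10
        Z = np.zeros((g * r, g))
        Z[np.arange(g * r), np.repeat(np.arange(g), r)] = 1.0
        fit = reml(y, np.ones((g * r, 1)), [Z], np.zeros(g * r, dtype=int))
        ybar = y.reshape(g, r).mean(axis=1)
        ms_between = r * ((ybar - y.mean()) ** 2).sum() / (g - 1)
        ms_within = ((y.reshape(g, r) - ybar[:, None]) ** 2).sum() / (g * (r - 1))
        assert fit.converged
        assert fit.term_var[0] == pytest.approx((ms_between - ms_within) / r, abs=1e-6)
        assert fit.resid_var[0] == pytest.approx(ms_within, abs=1e-6)

    def test_mixture_pvalue_boundary(self):
        assert mixture_lrt_pvalue(0.0) == 1.0
        assert mixture_lrt_pvalue(-1.0) == 1.0
        assert 0 < mixture_lrt_pvalue(10.0) < 0.001

    def test_type_i_rate_of_locus_lrt(self):
        """Under pure-noise phenotypes the mixture LRT is not anti-
        conservative: empirical P(p <= 0.05) stays near or below 0.05."""
        rng = np.random.default_rng(6)
        n = 150
        Z = np.clip(rng.dirichlet([6, 1, 1], n)[:, 1:], 0, 1)
        F = np.ones((n, 1))
        gi = np.zeros(n, dtype=int)
        hits = 0
        n_sim = 400
        for _ in range(n_sim):
            y = rng.normal(0, 1, n)
            full = reml(y, F, [Z], gi)
            null = reml(y, F, [], gi)
            p = mixture_lrt_pvalue(2 * (full.loglik - null.loglik))
            hits += p <= 0.05
        assert hits / n_sim <= 0.075  # 0.05 plus Monte-Carlo slack at n=400


class TestLocusModel:
    def test_all_recipient_locus_gives_p_one(self, demo_population):
        d = demo_population
        tensor = d["tensor"]
        # fabricate a locus with every line certainly recipient
        probs = tensor.probs.copy()
        probs[:, 0, :] = 0.0
        probs[:, 0, 0] = 1.0
        from awnqtl.founderprob import FounderProbabilityTensor

        t2 = FounderProbabilityTensor(
            probs, tensor.line_ids, tensor.cross_ids, tensor.founder_names, tensor.loci
        )
        _, mlp = fit_locus_model(t2, d["phenos"], 0)
        assert mlp == 0.0

    def test_shift_by_cross_constant_leaves_profile(self, demo_population):
        """Adding a per-cross constant is absorbed by the fixed cross means."""
        d = demo_population
        locus = d["tensor"].locus_index("1H", 30.0)
        _, base = fit_locus_model(d["tensor"], d["phenos"], locus)
        shifted = d["phenos"].records.copy()
        offsets = {c: 40.0 * i for i, c in enumerate(sorted(set(shifted["cross_id"])))}
        shifted["value"] = shifted["value"] + shifted["cross_id"].map(offsets)
        _, moved = fit_locus_model(d["tensor"], PhenotypeTable(shifted), locus)
        assert moved == pytest.approx(base, abs=1e-6)

    def test_scale_equivariance(self, demo_population):
        """Multiplying phenotypes by c scales effects and SEs by c and
        leaves -log10 p unchanged."""
        d = demo_population
        locus = d["tensor"].locus_index("1H", 30.0)
        qtls = fit_final(d["tensor"], d["phenos"], [locus])
        scaled_records = d["phenos"].records.copy()
        scaled_records["value"] = scaled_records["value"] * 3.0
        qtls_scaled = fit_final(d["tensor"], PhenotypeTable(scaled_records), [locus])
        for f in qtls[0].effects:
            e1, s1 = qtls[0].effects[f]
            e2, s2 = qtls_scaled[0].effects[f]
            assert e2 == pytest.approx(3.0 * e1, abs=1e-6 * max(1, abs(e1)))
            assert s2 == pytest.approx(3.0 * s1, abs=1e-6 * max(1, s1))
        assert qtls_scaled[0].minus_log10_p == pytest.approx(
            qtls[0].minus_log10_p, abs=1e-6
        )

    def test_major_qtl_exceeds_mapping_threshold(self, demo_population):
        """A planted major QTL at the tested locus clears -log10 p = 3.2."""
        d = demo_population
        locus = d["tensor"].locus_index("1H", 30.0)
        _, mlp = fit_locus_model(d["tensor"], d["phenos"], locus)
        assert mlp > 3.2


@pytest.fixture(scope="module")
def scan_population():
    """One-chromosome population reused across detection simulations."""
    gmap = default_map(markers_per_chromosome=21, chrom_length=100.0, chromosomes=["1H"])
    rng = np.random.default_rng(17)
    panel = default_panel(gmap, rng)
    design = CrossDesign.all_pairs(panel.donors, 35)  # 210 lines
    mosaics, table, _ = simulate_population(design, panel, gmap, rng)
    tensor = truth_tensor(mosaics, table, panel, gmap)
    return gmap, panel, mosaics, table, tensor


class TestScans:
    def test_single_qtl_peak_recovered_within_5cm(self, scan_population):
        """Genome-wide peak lands within 5 cM of the planted QTL in at
        least 90% of phenotype redraws."""
        gmap, panel, mosaics, table, tensor = scan_population
        effects = dict(zip(panel.donors, AL71_EFFECTS))
        base = np.array(
            [
                sum(m.dose_at("1H", 50.0, 5)[panel.founder_index(f)] * e for f, e in effects.items())
                for m in mosaics
            ]
        )
        hits = 0
        n_sim = 20
        for s in range(n_sim):
            rng = np.random.default_rng(300 + s)
            ph = _phenos_from_values(table, 150 + base, replicates=1, rng=rng, sd=8.0)
            prof = scan_sim(tensor, ph)
            peak = prof.table.loc[prof.table["minus_log10_p"].idxmax()]
            hits += abs(peak["position"] - 50.0) <= 5.0
        assert hits >= 18

    def test_null_scan_rarely_crosses_threshold(self, scan_population):
        """Pure-noise phenotypes keep the genome-wide maximum below 3.2 in
        at least 90% of simulations."""
        gmap, panel, mosaics, table, tensor = scan_population
        clean = 0
        n_sim = 20
        for s in range(n_sim):
            rng = np.random.default_rng(500 + s)
            ph = _phenos_from_values(table, np.full(len(mosaics), 150.0), 1, rng, 8.0)
            prof = scan_sim(tensor, ph)
            clean += prof.table["minus_log10_p"].max() < 3.2
        assert clean >= 18

    def test_mqm_single_qtl_detected_once(self, scan_population):
        gmap, panel, mosaics, table, tensor = scan_population
        effects = dict(zip(panel.donors, AL71_EFFECTS))
        base = np.array(
            [
                sum(m.dose_at("1H", 50.0, 5)[panel.founder_index(f)] * e for f, e in effects.items())
                for m in mosaics
            ]
        )
        ph = _phenos_from_values(table, 150 + base, 1, np.random.default_rng(42), 8.0)
        loci, prof = scan_mqm(tensor, ph)
        assert len(loci) == 1
        assert abs(prof.table["position"].iloc[loci[0]] - 50.0) <= 5.0

    def test_mqm_two_linked_qtls_30cm_apart(self, scan_population):
        gmap, panel, mosaics, table, tensor = scan_population
        effA = dict(zip(panel.donors, AL71_EFFECTS))
        effB = dict(zip(panel.donors, [10.0, 18.0, 14.0, 20.0]))
        base = np.array(
            [
                sum(m.dose_at("1H", 30.0, 5)[panel.founder_index(f)] * e for f, e in effA.items())
                + sum(m.dose_at("1H", 60.0, 5)[panel.founder_index(f)] * e for f, e in effB.items())
                for m in mosaics
            ]
        )
        ph = _phenos_from_values(table, 150 + base, 1, np.random.default_rng(43), 6.0)
        loci, prof = scan_mqm(tensor, ph)
        found = sorted(prof.table["position"].iloc[l] for l in loci)
        assert any(abs(p - 30.0) <= 5.0 for p in found)
        assert any(abs(p - 60.0) <= 5.0 for p in found)

    def test_mqm_null_returns_empty(self, scan_population):
        gmap, panel, mosaics, table, tensor = scan_population
        ph = _phenos_from_values(table, np.full(len(mosaics), 150.0), 1,
                                 np.random.default_rng(44), 8.0)
        loci, _ = scan_mqm(tensor, ph)
        assert loci == []

    def test_threshold_monotonicity(self, demo_population):
        """Raising the significance threshold never yields more QTLs."""
        d = demo_population
        counts = []
        for thr in (3.2, 10.0, 40.0):
            loci, _ = scan_mqm(d["tensor"], d["phenos"], threshold=thr)
            counts.append(len(loci))
        assert counts[0] >= counts[1] >= counts[2]


class TestFinalModel:
    def test_effects_recovered_within_two_se(self, demo_population):
        d = demo_population
        t = d["tensor"]
        loci = [t.locus_index("1H", 30.0), t.locus_index("2H", 70.0)]
        qtls = fit_final(t, d["phenos"], loci, d["gmap"])
        truth = {
            "1H": dict(zip(d["panel"].donors, AL71_EFFECTS)),
            "2H": dict(zip(d["panel"].donors, [8.0, 2.0, 15.0, 5.0])),
        }
        for q in qtls:
            for f, (eff, se) in q.effects.items():
                assert abs(eff - truth[q.chromosome][f]) < 2.5 * se

    def test_null_dummy_qtl_effects_near_zero(self, scan_population):
        gmap, panel, mosaics, table, tensor = scan_population
        ph = _phenos_from_values(table, np.full(len(mosaics), 150.0), 1,
                                 np.random.default_rng(45), 8.0)
        qtls = fit_final(tensor, ph, [10])
        for f, (eff, se) in qtls[0].effects.items():
            assert abs(eff) < 2 * max(se, 1e-6) + 1e-6

    def test_se_shrinks_with_line_count(self, scan_population):
        """Doubling the lines shrinks the median prediction SE roughly
        like 1/sqrt(n)."""
        gmap, panel, mosaics, table, tensor = scan_population
        effects = dict(zip(panel.donors, AL71_EFFECTS))
        base = np.array(
            [
                sum(m.dose_at("1H", 50.0, 5)[panel.founder_index(f)] * e for f, e in effects.items())
                for m in mosaics
            ]
        )
        locus = tensor.locus_index("1H", 50.0)
        ratios = []
        for s in range(10):
            rng = np.random.default_rng(700 + s)
            ph_full = _phenos_from_values(table, 150 + base, 1, rng, 8.0)
            qtls_full = fit_final(tensor, ph_full, [locus])
            half = np.arange(0, len(mosaics), 2)
            from awnqtl.founderprob import FounderProbabilityTensor
            from awnqtl.io import MarkerGenotypeTable

            t_half = FounderProbabilityTensor(
                tensor.probs[half],
                [tensor.line_ids[i] for i in half],
                [tensor.cross_ids[i] for i in half],
                tensor.founder_names,
                tensor.loci,
            )
            keep = set(t_half.line_ids)
            ph_half = PhenotypeTable(
                ph_full.records[ph_full.records["line_id"].isin(keep)].reset_index(drop=True)
            )
            qtls_half = fit_final(t_half, ph_half, [locus])
            se_full = np.median([s for _, s in qtls_full[0].effects.values()])
            se_half = np.median([s for _, s in qtls_half[0].effects.values()])
            ratios.append(se_full / se_half)
        med = float(np.median(ratios))
        assert 0.55 <= med <= 0.85  # ~1/sqrt(2) = 0.71

    def test_collinear_qtls_refused(self, demo_population):
        d = demo_population
        t = d["tensor"]
        a = t.locus_index("1H", 30.0)
        b = t.locus_index("1H", 35.0)
        with pytest.raises(ValueError, match="merge"):
            fit_final(t, d["phenos"], [a, b])


class TestEpistasis:
    def test_additive_architecture_shows_no_interaction(self, demo_population):
        d = demo_population
        t = d["tensor"]
        loci = [t.locus_index("1H", 30.0), t.locus_index("2H", 70.0)]
        table = epistasis_scan(t, d["phenos"], loci)
        assert (table["p_bonferroni"] > 0.05).all()

    def test_planted_interaction_detected(self):
        """A product interaction twice the residual sd is flagged in most
        simulations."""
        gmap = default_map(markers_per_chromosome=11, chrom_length=100.0,
                           chromosomes=["1H", "2H"])
        rng = np.random.default_rng(13)
        panel = default_panel(gmap, rng)
        design = CrossDesign.all_pairs(panel.donors, 50)
        mosaics, table, _ = simulate_population(design, panel, gmap, rng)
        tensor = truth_tensor(mosaics, table, panel, gmap)
        lA = tensor.locus_index("1H", 50.0)
        lB = tensor.locus_index("2H", 50.0)
        effA = dict(zip(panel.donors, [-5.0, -15.0, -2.0, -20.0]))
        effB = dict(zip(panel.donors, [8.0, 2.0, 12.0, 5.0]))
        hits = 0
        n_sim = 10
        for s in range(n_sim):
            r2 = np.random.default_rng(100 + s)
            g = np.array(
                [
                    150.0
                    + sum(m.dose_at("1H", 50.0, 5)[panel.founder_index(f)] * e for f, e in effA.items())
                    + sum(m.dose_at("2H", 50.0, 5)[panel.founder_index(f)] * e for f, e in effB.items())
                    + 16.0 * m.dose_at("1H", 50.0, 5)[1:].sum() * m.dose_at("2H", 50.0, 5)[1:].sum()
                    for m in mosaics
                ]
            )
            ph = _phenos_from_values(table, g, 4, r2, 8.0)
            ep = epistasis_scan(tensor, ph, [lA, lB])
            hits += bool((ep["p_bonferroni"] < 0.05).iloc[0])
        assert hits >= 8

    def test_null_pair_rarely_significant(self, scan_population):
        gmap, panel, mosaics, table, tensor = scan_population
        clean = 0
        n_sim = 15
        for s in range(n_sim):
            rng = np.random.default_rng(900 + s)
            ph = _phenos_from_values(table, np.full(len(mosaics), 150.0), 1, rng, 8.0)
            ep = epistasis_scan(tensor, ph, [2, 14])
            clean += bool((ep["p_raw"] > 0.05).iloc[0])
        assert clean >= 13
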