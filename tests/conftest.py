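"""Shared fixtures: small synthetic maps, panels and populations.

Heavy simulated populations are session-scoped so several test modules can
reuse them; every fixture is seeded, so the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from awnqtl.founderprob import HMMParams, compute_founder_probs
from awnqtl.io import FounderPanel, GeneticMap, MarkerGenotypeTable
from awnqtl.popsim import (
    QTL,
    CrossDesign,
    QTLSpec,
    default_map,
    default_panel,
    simulate_phenotypes,
    simulate_population,
)

AL71_EFFECTS = [-3.5, -19.0, -1.0, -24.7]  # wild-founder effects, mm


@pytest.fixture(scope="session")
def tiny_map() -> GeneticMap:
    return GeneticMap(
        pd.DataFrame(
            {
                "marker": ["m1", "m2", "m3"],
                "chromosome": ["1H", "1H", "1H"],
                "position": [0.0, 7.0, 20.0],
            }
        )
    )


@pytest.fixture(scope="session")
def tiny_panel(tiny_map) -> FounderPanel:
    return FounderPanel(
        ["M", "A", "B"], np.array([[0, 0, 0], [1, 1, 0], [1, 0, 1]], dtype=np.int8)
    )


@pytest.fixture(scope="session")
def demo_population():
    """210 lines, 2 chromosomes, two planted QTLs; HMM tensor included."""
    gmap = default_map(markers_per_chromosome=21, chrom_length=100.0, chromosomes=["1H", "2H"])
    rng = np.random.default_rng(11)
    panel = default_panel(gmap, rng)
    design = CrossDesign.all_pairs(panel.donors, 35)
    mosaics, table, truth = simulate_population(design, panel, gmap, rng, genotyping_error=0.01)
    qtls = [
        QTL("1H", 30.0, dict(zip(panel.donors, AL71_EFFECTS))),
        QTL("2H", 70.0, dict(zip(panel.donors, [8.0, 2.0, 15.0, 5.0]))),
    ]
    spec = QTLSpec(
        qtls,
        cross_means={c: 150.0 for c in set(table.cross_ids)},
        replicates=4,
        heritability_target=0.75,
    )
    phenos = simulate_phenotypes(table.line_ids, table.cross_ids, mosaics, panel, spec, rng)
    tensor = compute_founder_probs(table, panel, gmap, HMMParams(genotyping_error=0.01))
    return {
        "gmap": gmap,
        "panel": panel,
        "design": design,
        "mosaics": mosaics,
        "table": table,
        "truth": truth,
        "qtls": qtls,
        "spec": spec,
        "phenos": phenos,
        "tensor": tensor,
    }


@pytest.fixture(scope="session")
def paper_scale_population():
    """916 lines, 7 chromosomes, the major 7HL QTL; study-condition scale."""
    gmap = default_map()  # 7 x 52 markers, 150 cM each
    rng = np.random.default_rng(20)
    panel = default_panel(gmap, rng)
    design = CrossDesign.all_pairs(panel.donors, [153, 153, 153, 153, 152, 152])
    mosaics, table, truth = simulate_population(design, panel, gmap, rng, genotyping_error=0.01)
    spec = QTLSpec(
        [QTL("7H", 133.9, dict(zip(panel.donors, AL71_EFFECTS)))],
        cross_means={c: 150.0 for c in set(table.cross_ids)},
        replicates=4,
        heritability_target=0.75,
    )
    phenos = simulate_phenotypes(table.line_ids, table.cross_ids, mosaics, panel, spec, rng)
    return {
        "gmap": gmap,
        "panel": panel,
        "mosaics": mosaics,
        "table": table,
        "truth": truth,
        "spec": spec,
        "phenos": phenos,
    }


def truth_tensor(mosaics, table: MarkerGenotypeTable, panel: FounderPanel, gmap: GeneticMap):
    """Probability tensor built from true founder doses (oracle predictors)."""
    from awnqtl.founderprob import FounderProbabilityTensor

    n, m, f = len(mosaics), gmap.n_markers, panel.n_founders
    probs = np.zeros((n, m, f))
    col = 0
    loci = gmap.table[["marker", "chromosome", "position"]].copy()
    for chrom in gmap.chromosomes:
        pos = gmap.positions(chrom)
        for i, mos in enumerate(mosaics):
            h1, h2 = mos.homologs[chrom]
            f1, f2 = h1.founder_at(pos), h2.founder_at(pos)
            for k in range(len(pos)):
                probs[i, col + k, f1[k]] += 0.5
                probs[i, col + k, f2[k]] += 0.5
        col += len(pos)
    return FounderProbabilityTensor(
        probs, list(table.line_ids), list(table.cross_ids), list(panel.founder_names), loci
    )
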