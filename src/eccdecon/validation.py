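"""In-silico validation experiments for the full pipeline.

These drivers reproduce, at synthetic-atlas scale, the study's validation
logic: known-composition pseudobulks are deconvoluted and scored against
their ground truth; composition-linked drug responses are predicted under
LOOCV with a permutation null; and the survival / association stages are
calibrated by power and type-I simulations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .atlas import build_reference
from .deconvolve import DeconvolutionOptions, assign_phenotype, deconvolute
from .drugs import ecc_drug_association, loocv_predict, minmax_normalize
from .assoc import km_logrank
from .simulate import (
    AtlasSimConfig,
    generate_drug_response,
    generate_survival,
    generate_synthetic_atlas,
    simulate_overabundant_pseudobulk,
)


def proportion_recovery(
    seed: int = 0,
    config: AtlasSimConfig | None = None,
    n_reps: int = 50,
    fracs: tuple[float, ...] = (0.2, 0.5, 0.8),
    n_cells: int = 1000,
) -> dict:
    """Overabundant-pseudobulk recovery benchmark.

    Generates a synthetic atlas, builds the reference, simulates ``n_reps``
    pseudobulks per (cell type, overabundance fraction), deconvolutes them
    and reports the per-type mean absolute error of estimated vs true
    proportions plus the dominant-type assignment accuracy at the largest
    fraction.
    """
    if config is None:
        config = AtlasSimConfig(seed=seed)
    cells, _ = generate_synthetic_atlas(config)
    atlas = build_reference(cells)
    opts = DeconvolutionOptions(min_common_genes=min(100, cells.n_genes // 2))
    rng = np.random.default_rng(seed + 1)

    abs_err: dict[str, list[float]] = {t: [] for t in atlas.cell_types}
    correct_at_max = 0
    total_at_max = 0
    max_frac = max(fracs)
    for frac in fracs:
        cols = {}
        truths = {}
        for t in atlas.cell_types:
            for rep in range(n_reps):
                pb = simulate_overabundant_pseudobulk(
                    cells, t, n_cells=n_cells, frac=frac, seed=rng)
                name = f"{t}|{frac}|{rep}"
                cols[name] = pb.bulk_counts
                truths[name] = pb.true_proportions
        bulk = pd.DataFrame(cols)
        res = deconvolute(bulk, atlas, opts)
        pheno = assign_phenotype(res.proportions)
        for name, truth in truths.items():
            est = res.proportions.loc[name]
            target = name.split("|")[0]
            for t in atlas.cell_types:
                abs_err[t].append(abs(est[t] - truth[t]))
            if frac == max_frac:
                total_at_max += 1
                if pheno.loc[name, "phenotype"] == target:
                    correct_at_max += 1

    mae_per_type = {t: float(np.mean(v)) for t, v in abs_err.items()}
    return {
        "mae_per_type": mae_per_type,
        "max_type_mae": float(max(mae_per_type.values())),
        "mean_mae": float(np.mean([e for v in abs_err.values() for e in v])),
        "dominant_accuracy": correct_at_max / total_at_max,
        "n_pseudobulks": len(fracs) * len(atlas.cell_types) * n_reps,
    }


def drug_recovery(
    seed: int = 0,
    n_samples: int = 100,
    n_types: int = 8,
    n_trees: int = 500,
    n_permutations: int = 20,
    permutation_trees: int = 100,
    noise_frac: float = 0.1,
) -> dict:
    """LOOCV signal recovery and permutation null for the drug stage.

    A one-hot beta on one cell type links composition to AUC with noise at
    ``noise_frac`` of the signal SD; the permutation null re-runs LOOCV on
    shuffled responses (smaller forests — the null does not depend on
    forest size) and reports the 95th percentile of |rho|.
    """
    rng = np.random.default_rng(seed)
    ecc = pd.DataFrame(
        rng.dirichlet(np.ones(n_types), size=n_samples),
        index=[f"sample{i}" for i in range(n_samples)],
        columns=[f"type{k}" for k in range(n_types)],
    )
    beta = np.zeros(n_types)
    beta[0] = 1.0
    signal_sd = float(ecc.iloc[:, 0].std())
    drugs = generate_drug_response(ecc, beta, noise_sd=noise_frac * signal_sd,
                                   seed=seed + 1)
    response = minmax_normalize(drugs.set_index("sample_id")["auc"])
    res = loocv_predict(ecc, response, n_trees=n_trees, seed=seed)

    perm_rhos = []
    perm_rng = np.random.default_rng(seed + 2)
    for i in range(n_permutations):
        shuffled = pd.Series(perm_rng.permutation(response.to_numpy()),
                             index=response.index)
        pr = loocv_predict(ecc, shuffled, n_trees=permutation_trees,
                           seed=seed + 100 + i)
        perm_rhos.append(abs(pr.spearman_rho))
    return {
        "spearman_rho": res.spearman_rho,
        "permuted_abs_rho_p95": float(np.percentile(perm_rhos, 95)),
        "n_samples": n_samples,
    }


def logrank_power(
    seed: int = 0,
    hazard_ratio: float = 4.0,
    n_per_arm: int = 200,
    n_replicates: int = 100,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the log-rank test under a group hazard ratio."""
    groups = pd.Series(
        ["low"] * n_per_arm + ["high"] * n_per_arm,
        index=[f"p{i}" for i in range(2 * n_per_arm)],
    )
    rejections = 0
    for rep in range(n_replicates):
        surv = generate_survival(groups,
                                 {"low": 1.0, "high": hazard_ratio},
                                 seed=seed + rep)
        if km_logrank(surv)["p_value"] < alpha:
            rejections += 1
    return {"power": rejections / n_replicates, "n_replicates": n_replicates}


def association_type1(
    seed: int = 0,
    n_drugs: int = 200,
    n_samples: int = 100,
    n_types: int = 5,
    alpha: float = 0.05,
) -> dict:
    """Type-I error calibration of the per-(type, drug) association test
    under independent-noise responses."""
    rng = np.random.default_rng(seed)
    ecc = pd.DataFrame(
        rng.dirichlet(np.ones(n_types), size=n_samples),
        index=[f"sample{i}" for i in range(n_samples)],
        columns=[f"type{k}" for k in range(n_types)],
    )
    frames = [
        pd.DataFrame({"sample_id": ecc.index, "drug": f"drug{d}",
                      "auc": rng.normal(size=n_samples)})
        for d in range(n_drugs)
    ]
    table = ecc_drug_association(ecc, pd.concat(frames, ignore_index=True))
    return {
        "type1_rate": float((table["p_value"] < alpha).mean()),
        "n_tests": len(table),
    }
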