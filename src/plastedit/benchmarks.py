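"""Cohort-scale evaluation of the pipeline on its own synthetic data.

These routines regenerate synthetic datasets under the default study
conditions, run the pipeline end to end and measure detection and
estimation quality against the planted truth. They back both the
acceptance checks and the reproduction script.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np

from .annotate import annotate_sites, position_frequency_matrix
from .caller import CallerParams, call_sites
from .gainloss import fit_rates
from .simulate import SimConfig, simulate_dataset, simulate_site_matrix


def caller_benchmark(
    seeds: Sequence[int],
    config: Optional[SimConfig] = None,
) -> Dict[str, float]:
    """Recall/precision/efficiency metrics of the caller on planted
    sites, aggregated over seeds.

    Recall is measured on non-decoy, non-indel-adjacent planted sites;
    precision over all calls with rescue enabled; indel-adjacent sites
    are tallied separately with rescue on and off; decoy polymorphisms
    are counted if ever called. Efficiency RMSE compares estimated to
    planted efficiencies on matched clean (non-indel) sites.
    """
    tp = fp = fn = 0
    indel_total = indel_with = indel_without = 0
    decoy_calls = 0
    sq_err = []
    pyr = [0, 0]  # [-1-pyrimidine count, total] over called C-to-U sites
    for seed in seeds:
        cfg = config or SimConfig()
        cfg = SimConfig(**{**cfg.__dict__, "seed": int(seed)})
        genome, genes, truth, pileup = simulate_dataset(cfg)
        sites = call_sites(pileup, CallerParams(rescue_enabled=True))
        sites_norescue = call_sites(pileup, CallerParams(rescue_enabled=False))
        called = {(s.pos, s.strand): s for s in sites}
        called_nr = {(s.pos, s.strand) for s in sites_norescue}
        truth_keys = {(s.pos, s.strand): s for s in truth.sites}
        clean_keys = {k for k, s in truth_keys.items() if not s.is_indel_adjacent}
        indel_keys = {k for k, s in truth_keys.items() if s.is_indel_adjacent}
        tp += len(set(called) & set(truth_keys))
        fp += len(set(called) - set(truth_keys))
        fn += len(clean_keys - set(called))
        indel_total += len(indel_keys)
        indel_with += len(indel_keys & set(called))
        indel_without += len(indel_keys & called_nr)
        decoy_calls += len(set(truth.decoy_positions) & {p for p, _ in called})
        for k in clean_keys & set(called):
            sq_err.append((called[k].efficiency - truth_keys[k].efficiency) ** 2)
        ann = annotate_sites([s for s in sites], genes, genome)
        ctu = [s for s in ann if s.type == "C-to-U"]
        pfm = position_frequency_matrix(ctu, genome, k=1)
        pyr[0] += (pfm.loc["C", -1] + pfm.loc["T", -1]) * len(ctu)
        pyr[1] += len(ctu)
    n_clean = tp + fn - indel_with  # planted clean sites
    return {
        "recall": (tp - indel_with) / n_clean if n_clean else float("nan"),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "efficiency_rmse": float(np.sqrt(np.mean(sq_err))) if sq_err else float("nan"),
        "decoy_calls": decoy_calls,
        "indel_recall_with_rescue": indel_with / indel_total if indel_total else float("nan"),
        "indel_recall_without_rescue": indel_without / indel_total if indel_total else float("nan"),
        "minus1_pyrimidine_fraction": pyr[0] / pyr[1] if pyr[1] else float("nan"),
        "n_ctu_called": pyr[1],
    }


def rate_recovery_benchmark(
    tree,
    gain: float = 0.5,
    loss: float = 1.0,
    n_sites: int = 2000,
    seeds: Sequence[int] = range(10),
) -> Dict[str, float]:
    """Median relative error of ML gain/loss rates over seeded
    simulations on the fixed tree."""
    err_g, err_l = [], []
    for seed in seeds:
        m = simulate_site_matrix(tree, gain, loss, n_sites, seed=int(seed))
        fit = fit_rates(m, tree)
        err_g.append(abs(fit.gain - gain) / gain)
        err_l.append(abs(fit.loss - loss) / loss)
    return {
        "gain_median_rel_err": float(np.median(err_g)),
        "loss_median_rel_err": float(np.median(err_l)),
        "n_seeds": len(err_g),
    }
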