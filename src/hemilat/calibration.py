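"""Pipeline calibration on replicated synthetic cohorts.

Two experiments characterize the full pipeline (simulation -> metrics ->
asymmetry -> adjusted GLM -> Benjamini-Hochberg):

* **Null calibration** — with no planted effects, the fraction of replicate
  cohorts in which a correction family reports any FDR-significant
  asymmetry should stay near the nominal level (BH controls the
  probability of any rejection at alpha under a complete null).
* **Effect recovery** — a leftward small-worldness effect planted through
  hemispheric rewiring at a size of ``target_sd_units`` within-group
  standard deviations of AS(sigma) should be flagged FDR-significant in
  most replicates.

The planted effect size is realised by a pilot calibration
(:func:`calibrate_sigma_delta`): estimate the null within-group SD of
AS(sigma) and the linear response of its mean to the rewiring spread delta,
then solve for the delta giving the requested shift in SD units.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .lateralization import asymmetry_score
from .metrics import small_worldness
from .pipeline import analyze_cohort
from .simulate import SimulationConfig, simulate_cohort, simulate_hemisphere_graph
from .errors import ConfigurationError

log = logging.getLogger(__name__)

# problem sizes for the replicate experiments: enough references for a
# stable per-subject sigma while keeping 100 replicates of 97 subjects
# tractable on one CPU; the MC noise they contribute is part of the
# within-group SD in whose units planted effects are expressed
CAL_N_RANDOM = 6
CAL_SWAP_FACTOR = 4


def _replicate_seed(seed: int, replicate: int) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=(1000 + replicate,))
    return int(ss.generate_state(1)[0] % (2**31))


def replicate_comparisons(
    config: SimulationConfig,
    replicate_seed: int,
    n_random: int = CAL_N_RANDOM,
    swap_factor: int = CAL_SWAP_FACTOR,
) -> pd.DataFrame:
    """One replicate: simulate a cohort and return its family-corrected
    preterm-vs-term asymmetry comparisons."""
    cohort = simulate_cohort(config, seed=replicate_seed)
    result = analyze_cohort(
        cohort,
        n_random=n_random,
        seed=replicate_seed,
        swap_factor=swap_factor,
        with_subgroup=False,
    )
    return result.comparisons


def null_fdr_rate(
    config: SimulationConfig,
    n_replicates: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    n_random: int = CAL_N_RANDOM,
    swap_factor: int = CAL_SWAP_FACTOR,
) -> dict:
    """Per-family rate of replicates with any FDR-significant outcome under
    the null (no planted effects)."""
    null_config = replace(config, asymmetry_effects={},
                          subgroup_asymmetry_effects={})
    counts: dict[str, int] = {}
    for r in range(n_replicates):
        comp = replicate_comparisons(
            null_config, _replicate_seed(seed, r),
            n_random=n_random, swap_factor=swap_factor,
        )
        for family, grp in comp.groupby("family"):
            if (grp["p_fdr"] <= alpha).any():
                counts[family] = counts.get(family, 0) + 1
            else:
                counts.setdefault(family, counts.get(family, 0))
    mc_se = float(np.sqrt(alpha * (1 - alpha) / n_replicates))
    return {
        "n_replicates": n_replicates,
        "alpha": alpha,
        "mc_se": mc_se,
        "bound": alpha + 2 * mc_se,
        "families": {
            fam: {"n_significant": c, "rate": c / n_replicates}
            for fam, c in counts.items()
        },
    }


def _pilot_as_sigma(
    config: SimulationConfig,
    delta: float,
    n_subjects: int,
    seed: int,
    n_random: int,
    swap_factor: int,
) -> np.ndarray:
    """AS(sigma) for ``n_subjects`` preterm-like subjects at rewiring
    spread ``delta``, bypassing the cohort machinery for speed."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    p_left = float(np.clip(config.lattice_rewire_prob_left - delta / 2, 0, 1))
    p_right = float(np.clip(config.lattice_rewire_prob_right + delta / 2, 0, 1))
    out = np.empty(n_subjects)
    for i in range(n_subjects):
        sigmas = {}
        for side, p in (("left", p_left), ("right", p_right)):
            net = simulate_hemisphere_graph(
                config.nodes_per_hemisphere,
                config.intra_edge_density,
                p,
                seed=int(rng.integers(2**31)),
                side=side,
            )
            sigmas[side], _ = small_worldness(
                net, n_random=n_random, seed=int(rng.integers(2**31)),
                swap_factor=swap_factor,
            )
        out[i] = asymmetry_score(sigmas["left"], sigmas["right"])
    return out


def calibrate_sigma_delta(
    config: SimulationConfig,
    target_sd_units: float = 1.5,
    seed: int = 0,
    n_pilot: int = 60,
    delta_probe: float = 0.12,
    n_random: int = CAL_N_RANDOM,
    swap_factor: int = CAL_SWAP_FACTOR,
) -> dict:
    """Rewiring spread delta giving a planted AS(sigma) shift of
    ``target_sd_units`` within-group SDs.

    Pilot simulation: null subjects give the within-group SD; probe
    subjects at ``delta_probe`` give the (approximately linear) mean
    response, and the target delta is solved from the slope.
    """
    null_as = _pilot_as_sigma(config, 0.0, n_pilot, seed,
                              n_random, swap_factor)
    probe_as = _pilot_as_sigma(config, delta_probe, n_pilot, seed + 1,
                               n_random, swap_factor)
    sd0 = float(np.std(null_as, ddof=1))
    slope = float((probe_as.mean() - null_as.mean()) / delta_probe)
    if slope <= 0:
        raise ConfigurationError(
            f"AS(sigma) response to rewiring spread is non-positive "
            f"(slope={slope:.3f}); cannot calibrate a leftward effect"
        )
    delta = target_sd_units * sd0 / slope
    p = config.lattice_rewire_prob_left
    delta_max = 2 * min(p, 1 - p)
    delta = float(min(delta, delta_max))
    return {
        "delta": delta,
        "sd_null": sd0,
        "slope_per_delta": slope,
        "target_sd_units": target_sd_units,
        "n_pilot": n_pilot,
    }


def power_detection_rate(
    config: SimulationConfig,
    delta: float,
    n_replicates: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    outcome: str = "sigma",
    n_random: int = CAL_N_RANDOM,
    swap_factor: int = CAL_SWAP_FACTOR,
) -> dict:
    """Fraction of replicates in which the planted leftward sigma effect is
    FDR-significant in the global family."""
    eff_config = replace(config, asymmetry_effects={"sigma": delta})
    n_detected = 0
    for r in range(n_replicates):
        comp = replicate_comparisons(
            eff_config, _replicate_seed(seed, r),
            n_random=n_random, swap_factor=swap_factor,
        )
        row = comp[(comp["family"] == "global") & (comp["outcome"] == outcome)]
        if not row.empty and float(row["p_fdr"].iloc[0]) <= alpha:
            n_detected += 1
    return {
        "n_replicates": n_replicates,
        "n_detected": n_detected,
        "rate": n_detected / n_replicates,
        "delta": delta,
        "alpha": alpha,
    }
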