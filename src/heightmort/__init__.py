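"""heightmort: height-stratified drought mortality in mixed forests.

Tools for asking whether an increase in pooled tree mortality with height
reflects intrinsic tall-tree vulnerability or a Simpson's-paradox artifact
of height-related changes in taxonomic composition: allometric height-
class assignment, gamma-based snag death dating, Bayesian per-cell
mortality estimation with death-date uncertainty, and counterfactual
direct standardization.
"""

from .config import ConfigError, ConvergenceError, MCMCConfig
from .allometry import (AllometryParams, HeightClassThresholds, assign_height_class,
                        compute_thresholds, default_allometry, predict_height)
from .death_dating import (GammaDeathModel, default_calibration_map,
                           fit_gamma_death_model, map_calibration_group,
                           prob_death_in_window)
from .decomposition import (detect_simpson_reversal, pooled_mortality, proportions,
                            standardize_composition, standardize_group_mortality)
from .mortality import PosteriorSamples, back_calculate, fit_mortality, summarize
from .synthetic import (SimConfig, TruthTable, generate_calibration,
                        generate_inventory, scenario_table,
                        SCENARIO_COMPOSITION_SHIFT, SCENARIO_OPPOSING_TRENDS)

__version__ = "0.1.0"

__all__ = [
    "AllometryParams", "ConfigError", "ConvergenceError", "GammaDeathModel",
    "HeightClassThresholds", "MCMCConfig", "PosteriorSamples",
    "SCENARIO_COMPOSITION_SHIFT", "SCENARIO_OPPOSING_TRENDS", "SimConfig",
    "TruthTable", "assign_height_class", "back_calculate", "compute_thresholds",
    "default_allometry", "default_calibration_map", "detect_simpson_reversal",
    "fit_gamma_death_model", "fit_mortality", "generate_calibration",
    "generate_inventory", "map_calibration_group", "pooled_mortality",
    "predict_height", "prob_death_in_window", "proportions", "scenario_table",
    "standardize_composition", "standardize_group_mortality", "summarize",
]
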