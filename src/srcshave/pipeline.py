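"""Convenience wiring of the full selection pipeline.

These helpers chain feature extraction, scaling, orientation, cross
combination, characteristic-matrix design and sliding-window shaving for the
three analysis modes (expression-only, SNP-only, combined), so callers — the
command-line interface, tests, and scripts — do not repeat the plumbing.
"""

from __future__ import annotations

from dataclasses import replace

from .features import FeatureMatrix, combine_features, extract_features, orient_significance, scale_rows
from .io import GeneMap, LabeledDataset
from .shaving import SelectionResult, ShavingConfig, shave
from .src_core import CharacteristicMatrix, design_characteristic_matrix

__all__ = ["build_features", "build_combined_features", "run_selection"]

MODES = ("expression", "snp", "combined")


def build_features(dataset: LabeledDataset, gmap: GeneMap | None = None) -> FeatureMatrix:
    """Extract, scale and orient the 5-feature matrix of one data type."""
    return orient_significance(scale_rows(extract_features(dataset, gmap)))


def build_combined_features(expr: LabeledDataset, snp: LabeledDataset,
                            gmap: GeneMap) -> FeatureMatrix:
    """Cross-combined 10-feature matrix over joint genes."""
    gmap.validate_against(expr=expr, snp=snp)
    return combine_features(build_features(expr, gmap), build_features(snp, gmap), gmap)


def _fit_window(cfg: ShavingConfig, p: int) -> ShavingConfig:
    """Shrink the window to the matrix when the default would not fit."""
    if cfg.window_length <= p or p == 0:
        return cfg
    return replace(cfg, window_length=p, step=min(cfg.step, p))


def run_selection(mode: str, cfg: ShavingConfig,
                  expr: LabeledDataset | None = None,
                  snp: LabeledDataset | None = None,
                  gmap: GeneMap | None = None,
                  cm: CharacteristicMatrix | None = None) -> SelectionResult:
    """Run sliding-window SRC selection in one of the three analysis modes."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if mode == "expression":
        if expr is None:
            raise ValueError("expression mode needs an expression dataset")
        fm = build_features(expr, gmap)
    elif mode == "snp":
        if snp is None:
            raise ValueError("snp mode needs a SNP dataset")
        fm = build_features(snp, gmap)
    else:
        if expr is None or snp is None or gmap is None:
            raise ValueError("combined mode needs both datasets and a gene map")
        fm = build_combined_features(expr, snp, gmap)
    if cm is None:
        cm = design_characteristic_matrix(fm.r)
    return shave(fm, cm, _fit_window(cfg, fm.p))
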