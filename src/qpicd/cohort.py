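"""In-memory cohort analysis: simulate -> analyse -> fit -> parameters.

Convenience layer used by the acceptance machinery and notebooks; the
file-writing pipeline in :mod:`qpicd.pipeline` wraps the same steps with
artifact output.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classify import build_parameter_table
from .dynamics import fit_cohort
from .pipeline import analyze_stack
from .synthetic import CohortConfig, simulate_cell, simulate_cohort

__all__ = ["CohortAnalysis", "analyze_cohort"]


@dataclass
class CohortAnalysis:
    """Everything the downstream statistics need, in memory."""

    truth: pd.DataFrame
    features: pd.DataFrame
    fits: pd.DataFrame
    records: list
    parameters: pd.DataFrame

    def n_sigmoidal_by_class(self) -> pd.Series:
        ns = self.fits.groupby("track_id")["n_sigmoidal"].first()
        labels = self.truth.set_index("cell_id")["class_label"]
        return ns.groupby(labels.reindex(ns.index)).mean()


def analyze_cohort(
    config: CohortConfig | None = None,
    seed: int = 0,
    n_normal: int | None = None,
    n_apoptotic: int | None = None,
    n_necrotic: int | None = None,
) -> CohortAnalysis:
    """Simulate a cohort and run segmentation, tracking, feature
    extraction and sigmoid fitting on every cell, streaming one movie at
    a time."""
    import dataclasses

    cfg = dataclasses.replace(config) if config is not None else CohortConfig()
    if n_normal is not None:
        cfg.n_normal = n_normal
    if n_apoptotic is not None:
        cfg.n_apoptotic = n_apoptotic
    if n_necrotic is not None:
        cfg.n_necrotic = n_necrotic
    cfg.seed = seed
    # draw the recipes only; movies are rendered one cell at a time
    cells, truth = simulate_cohort(config=cfg, render=False)
    tables = []
    for cell in cells:
        sim = simulate_cell(cell.cell_id, cell.spec, cfg, render=True)
        table = analyze_stack(sim.stack, cell.cell_id)
        if not table.empty:
            tables.append(table)
    features = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    fits, records = fit_cohort(features)
    parameters = build_parameter_table(fits, truth)
    return CohortAnalysis(truth, features, fits, records, parameters)
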