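"""Stage 1: median-dichotomization survival screening.

Each candidate gene splits the cohort at its median expression; the
high-vs-low survival difference is tested with the log-rank test, the
direction of effect is read off the univariate Cox hazard ratio of the
above-median indicator (HR < 1 means above-median expression is
favorable), and genes with log-rank P strictly below the threshold
(default 0.15) form the panel, ordered by ascending P.

No multiple-testing correction is applied at this stage — the screen is
deliberately permissive and the resulting panel is meant to be validated
on independent cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from roscore.cohort_io import (
    HIGH_GOOD,
    LOW_GOOD,
    ClinicalTable,
    ExpressionMatrix,
    GenePanel,
    PanelEntry,
)
from roscore.survival import cox_fit, logrank_test

logger = logging.getLogger("roscore")

__all__ = [
    "SCREEN_THRESHOLD",
    "DegenerateGeneError",
    "EmptyPanelError",
    "ScreenRecord",
    "dichotomize_by_median",
    "screen_gene",
    "build_panel",
]

SCREEN_THRESHOLD = 0.15


class DegenerateGeneError(ValueError):
    """Gene cannot be dichotomized (constant or too few values)."""


class EmptyPanelError(ValueError):
    """Screening selected zero genes."""


@dataclass
class ScreenRecord:
    """Per-gene screening outcome.

    ``direction`` is ``high_good`` iff ``hr_high_vs_low`` < 1;
    ``selected`` iff the gene survived screening at the strict threshold.
    Skipped genes (absent, missing values, constant, HR exactly 1,
    non-converged fit) carry a ``reason`` and are never selected.
    """

    gene: str
    logrank_p: float | None = None
    direction: str | None = None
    hr_high_vs_low: float | None = None
    selected: bool = False
    skipped: bool = False
    reason: str | None = None

    def to_row(self) -> dict:
        return {
            "gene": self.gene,
            "p": self.logrank_p,
            "direction": {HIGH_GOOD: "high", LOW_GOOD: "low", None: None}[self.direction],
            "hr": self.hr_high_vs_low,
            "selected": int(self.selected),
            "skipped": int(self.skipped),
            "reason": self.reason or "",
        }


def dichotomize_by_median(values) -> np.ndarray:
    """Split samples at the median: 1 = strictly above, 0 = at or below.

    Ties at the median go to the low (0) group, which keeps the split
    deterministic under any monotone transform of the values.
    """
    v = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(v)):
        raise DegenerateGeneError("missing or non-finite expression values")
    if v.size < 4:
        raise DegenerateGeneError(f"too few values to dichotomize ({v.size} < 4)")
    if np.ptp(v) == 0.0:
        raise DegenerateGeneError("constant expression; median split is degenerate")
    med = float(np.median(v))
    high = (v > med).astype(int)
    if high.sum() == 0:
        # > half the samples tie at the maximum; no one is above the median
        raise DegenerateGeneError("no sample above the median (heavy ties)")
    n_tied = int(np.sum(v == med))
    if n_tied > 0.1 * v.size:
        logger.warning("median split: %d/%d samples tie at the median", n_tied, v.size)
    return high


def screen_gene(
    gene: str,
    values,
    clinical: ClinicalTable,
    threshold: float = SCREEN_THRESHOLD,
) -> ScreenRecord:
    """Screen one gene: log-rank P of the median split + Cox direction."""
    try:
        high = dichotomize_by_median(values)
    except DegenerateGeneError as err:
        return ScreenRecord(gene=gene, skipped=True, reason=str(err))
    t = clinical.os_years
    e = clinical.os_event
    if t.size != high.size:
        raise ValueError("expression values and clinical table are not aligned")
    lr = logrank_test(t, e, high)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = cox_fit(t, e, high.astype(float), names=["high"])
    hr = float(fit.hr[0])
    if not fit.converged:
        return ScreenRecord(
            gene=gene,
            logrank_p=lr.p,
            hr_high_vs_low=hr,
            skipped=True,
            reason="Cox fit did not converge",
        )
    if hr == 1.0:
        return ScreenRecord(
            gene=gene,
            logrank_p=lr.p,
            hr_high_vs_low=hr,
            skipped=True,
            reason="hazard ratio exactly 1; direction undefined",
        )
    direction = HIGH_GOOD if hr < 1.0 else LOW_GOOD
    return ScreenRecord(
        gene=gene,
        logrank_p=lr.p,
        direction=direction,
        hr_high_vs_low=hr,
        selected=bool(lr.p < threshold),
    )


def build_panel(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    candidate_genes=None,
    screen_threshold: float = SCREEN_THRESHOLD,
) -> tuple[GenePanel, list[ScreenRecord]]:
    """Screen every candidate gene and assemble the selected panel.

    The panel lists selected genes by ascending log-rank P (ties broken by
    gene symbol); the full record list is returned for audit. Candidate
    genes absent from the matrix, or carrying missing values in this
    cohort, are skipped with a logged warning.
    """
    if expr.sample_ids != clinical.sample_ids:
        raise ValueError("expression and clinical samples are not aligned (run align_cohort)")
    if not (0.0 <= screen_threshold <= 1.0):
        raise ValueError(f"screen_threshold out of [0, 1]: {screen_threshold}")
    if candidate_genes is None:
        candidate_genes = expr.gene_ids
    candidates = [g.upper() for g in candidate_genes]
    if len(set(candidates)) != len(candidates):
        raise ValueError("duplicate candidate gene ids")

    records: list[ScreenRecord] = []
    n_absent = 0
    for gene in candidates:
        if not expr.has_gene(gene):
            records.append(ScreenRecord(gene=gene, skipped=True, reason="absent from matrix"))
            n_absent += 1
            continue
        values = expr.values_for(gene)
        if np.isnan(values).any():
            records.append(
                ScreenRecord(gene=gene, skipped=True, reason="missing expression values")
            )
            continue
        records.append(screen_gene(gene, values, clinical, threshold=screen_threshold))
    if n_absent:
        logger.warning("screening: %d/%d candidate gene(s) absent from matrix", n_absent, len(candidates))
    if n_absent == len(candidates):
        raise ValueError("no candidate gene is present in the expression matrix")

    chosen = sorted(
        (r for r in records if r.selected),
        key=lambda r: (r.logrank_p, r.gene),
    )
    if not chosen:
        raise EmptyPanelError(
            f"no gene passed screening at P < {screen_threshold}; review the threshold"
        )
    panel = GenePanel(
        [PanelEntry(gene=r.gene, direction=r.direction, p=r.logrank_p) for r in chosen]
    )
    logger.info(
        "screening: %d/%d gene(s) selected at P < %s",
        panel.K,
        len(candidates),
        screen_threshold,
    )
    return panel, records
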