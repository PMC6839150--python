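"""Stage 2: per-patient integer scores and the low/high equal-range split.

A patient earns one point per panel gene whose expression falls on the
gene's favorable side of the median: strictly above the median for
``high_good`` genes, at or below it for ``low_good`` genes. Scores range
0..K for a K-gene panel. The equal-range split labels scores > K/2 as
"high" and the rest "low"; for the published 25-gene panel this is the
0-12 / 13-25 split.

Medians default to per-cohort values (platform-independent; median
dichotomization only sees ranks), with a frozen-reference mode for
prospective single-platform use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from roscore.cohort_io import HIGH_GOOD, ExpressionMatrix, GenePanel

logger = logging.getLogger("roscore")

__all__ = ["ScoreTable", "compute_scores", "assign_groups"]

GROUP_LOW = "low"
GROUP_HIGH = "high"


@dataclass
class ScoreTable:
    """Per-sample scores with the medians used to compute them.

    ``frame`` is indexed by sample id with columns ``score``,
    ``n_genes_used`` and (after :func:`assign_groups`) ``group``.
    ``K`` is the full panel size: the group boundary sits at K/2 even when
    some panel genes were unavailable in the cohort.
    ``points`` is the sample x gene 0/1 audit matrix.
    """

    frame: pd.DataFrame
    K: int
    reference_medians: dict[str, float]
    points: pd.DataFrame | None = None
    missing_genes: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def scores(self) -> np.ndarray:
        return self.frame["score"].to_numpy(dtype=int)

    @property
    def groups(self) -> np.ndarray:
        if "group" not in self.frame.columns:
            raise ValueError("groups not assigned yet; call assign_groups first")
        return self.frame["group"].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return self.frame.reset_index()


def compute_scores(
    expr: ExpressionMatrix,
    panel: GenePanel,
    medians="per_cohort",
) -> ScoreTable:
    """Sum direction-aware points over the panel genes for every sample.

    ``medians`` is either ``"per_cohort"`` (thresholds computed from this
    matrix) or a frozen ``{gene: median}`` mapping that must cover every
    panel gene present in the matrix. Panel genes absent from the matrix,
    or with missing values in this cohort, are dropped with a prominent
    warning — they lower the attainable maximum score.
    """
    present, absent = [], []
    for entry in panel.entries:
        if not expr.has_gene(entry.gene):
            absent.append(entry.gene)
            continue
        if np.isnan(expr.values_for(entry.gene)).any():
            absent.append(entry.gene)
            logger.warning("scoring: panel gene %s has missing values; dropped", entry.gene)
            continue
        present.append(entry)
    if not present:
        raise ValueError("no panel gene is present (and complete) in the expression matrix")
    if absent:
        logger.warning(
            "scoring: %d/%d panel gene(s) unavailable in this cohort: %s "
            "(attainable maximum reduced to %d)",
            len(absent),
            panel.K,
            ", ".join(absent),
            len(present),
        )

    if isinstance(medians, str):
        if medians != "per_cohort":
            raise ValueError(f"medians must be 'per_cohort' or a mapping, got {medians!r}")
        med = {e.gene: float(np.median(expr.values_for(e.gene))) for e in present}
    else:
        med = {g.upper(): float(v) for g, v in dict(medians).items()}
        lacking = [e.gene for e in present if e.gene not in med]
        if lacking:
            raise ValueError(f"frozen medians missing panel gene(s): {', '.join(lacking)}")

    samples = expr.sample_ids
    points = pd.DataFrame(0, index=samples, columns=[e.gene for e in present], dtype=int)
    for entry in present:
        above = expr.values_for(entry.gene) > med[entry.gene]
        favorable = above if entry.direction == HIGH_GOOD else ~above
        points[entry.gene] = favorable.astype(int)
    frame = pd.DataFrame(
        {"score": points.sum(axis=1).astype(int), "n_genes_used": len(present)},
        index=pd.Index(samples, name="sample_id"),
    )
    return ScoreTable(
        frame=frame,
        K=panel.K,
        reference_medians={e.gene: med[e.gene] for e in present},
        points=points,
        missing_genes=absent,
    )


def assign_groups(
    table: ScoreTable,
    max_missing_fraction: float = 0.2,
    force: bool = False,
) -> ScoreTable:
    """Label each sample low/high by the equal-range score split.

    Boundary at K/2: score <= floor(K/2) -> low, otherwise high (for K=25:
    low = 0-12, high = 13-25). Refuses to run when more than
    ``max_missing_fraction`` of the panel was unavailable — the boundary
    presumes scores on the full 0..K range — unless ``force`` is set.
    """
    n_used = int(table.frame["n_genes_used"].min())
    missing_frac = 1.0 - n_used / table.K
    if missing_frac > max_missing_fraction and not force:
        raise ValueError(
            f"{missing_frac:.0%} of panel genes unavailable (> {max_missing_fraction:.0%}); "
            "the equal-range boundary presumes the full panel — pass force=True to override"
        )
    table.frame["group"] = np.where(table.scores > table.K / 2.0, GROUP_HIGH, GROUP_LOW)
    counts = table.frame["group"].value_counts()
    for label in (GROUP_LOW, GROUP_HIGH):
        if counts.get(label, 0) == 0:
            logger.warning("assign_groups: the %r category is empty", label)
    return table
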