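"""Synthetic expression + survival cohorts with known ground truth.

Expression is drawn i.i.d. standard normal per gene. A configurable subset
of "signal" genes carries a survival effect that acts through the
median-group indicator: a patient on a signal gene's unfavorable median
side (at-or-below median for a high_good gene, above median for a
low_good gene) multiplies their hazard by exp(beta). Effects are centered
(beta * (indicator - 1/2)) so the baseline describes the median patient;
hazard ratios are unaffected. Because the effect is a function of the
median split, the points-based score is the correctly-specified risk
model, which makes clean parameter-recovery tests possible.

Baseline survival is exponential or Weibull; censoring is independent
exponential or an administrative cutoff. All randomness flows from the
mandatory seed; there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from roscore.cohort_io import (
    HIGH_GOOD,
    LOW_GOOD,
    ClinicalTable,
    ExpressionMatrix,
    GenePanel,
    PanelEntry,
)

__all__ = [
    "SignalGene",
    "SimulationConfig",
    "SimulatedTruth",
    "simulate_cohort",
    "make_preset",
    "PRESETS",
]


@dataclass(frozen=True)
class SignalGene:
    gene: str
    direction: str  # high_good / low_good
    beta: float  # log-hazard added on the unfavorable median side

    def __post_init__(self):
        if self.direction not in (HIGH_GOOD, LOW_GOOD):
            raise ValueError(f"invalid direction {self.direction!r}")
        if not math.isfinite(self.beta):
            raise ValueError("signal effect must be finite")


@dataclass
class SimulationConfig:
    n_patients: int
    n_genes: int
    signal: tuple[SignalGene, ...] = ()
    baseline: tuple = ("exponential", 0.18)  # or ("weibull", shape, scale)
    censoring: tuple | None = ("exponential", 0.08)  # or ("admin", cutoff) or None
    covariate_effects: dict = field(default_factory=dict)
    seed: int | None = None

    def validate(self) -> None:
        if self.n_patients < 4:
            raise ValueError("need at least 4 patients")
        if self.n_genes < 1:
            raise ValueError("need at least one gene")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        kind = self.baseline[0]
        if kind == "exponential":
            if len(self.baseline) != 2 or self.baseline[1] <= 0:
                raise ValueError("exponential baseline needs a positive rate")
        elif kind == "weibull":
            if len(self.baseline) != 3 or self.baseline[1] <= 0 or self.baseline[2] <= 0:
                raise ValueError("weibull baseline needs positive shape and scale")
        else:
            raise ValueError(f"unknown baseline {kind!r}")
        if self.censoring is not None:
            ckind = self.censoring[0]
            if ckind not in ("exponential", "admin") or len(self.censoring) != 2:
                raise ValueError("censoring must be ('exponential', rate) or ('admin', cutoff)")
            if self.censoring[1] <= 0:
                raise ValueError("censoring parameter must be positive")
        genes = {s.gene for s in self.signal}
        if len(genes) != len(self.signal):
            raise ValueError("duplicate signal genes")
        allowed = {
            "age_per_year",
            "stage_iii",
            "stage_iv",
            "grade_3",
            "residual_suboptimal",
        }
        unknown = set(self.covariate_effects) - allowed
        if unknown:
            raise ValueError(f"unknown covariate effect(s): {sorted(unknown)}")


@dataclass
class SimulatedTruth:
    """Ground truth sufficient to recompute every patient's hazard."""

    directions: dict[str, str]
    betas: dict[str, float]
    hazard_multiplier: np.ndarray
    censoring_fraction: float
    baseline: tuple
    seed: int

    def true_panel(self) -> GenePanel:
        """The planted signal genes as a scoring panel (screen p = 0)."""
        return GenePanel(
            [PanelEntry(g, self.directions[g], 0.0) for g in sorted(self.directions)]
        )

    def to_dict(self) -> dict:
        return {
            "directions": self.directions,
            "betas": self.betas,
            "hazard_multiplier": self.hazard_multiplier.tolist(),
            "censoring_fraction": self.censoring_fraction,
            "baseline": list(self.baseline),
            "seed": self.seed,
        }


def _gene_names(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, SimulatedTruth]:
    """Draw one cohort (expression, clinical, truth) from the config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, g = config.n_patients, config.n_genes
    genes = _gene_names(g)
    samples = [f"S{i + 1:04d}" for i in range(n)]
    sig_names = {s.gene for s in config.signal}
    missing = sig_names - set(genes)
    if missing:
        raise ValueError(f"signal gene(s) not in the matrix: {sorted(missing)}")

    values = rng.standard_normal((g, n))
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))

    log_mult = np.zeros(n)
    for s in config.signal:
        v = expr.values_for(s.gene)
        above = v > np.median(v)
        unfavorable = ~above if s.direction == HIGH_GOOD else above
        log_mult += s.beta * (unfavorable.astype(float) - 0.5)

    # clinical covariates
    age = np.clip(np.round(rng.normal(60.0, 10.0, n)), 30, 89)
    stage = rng.choice(["I", "II", "III", "IV"], size=n, p=[0.07, 0.07, 0.66, 0.20])
    grade = rng.choice(["1", "2", "3", "other"], size=n, p=[0.05, 0.15, 0.72, 0.08])
    residual_mm = np.where(
        rng.random(n) < 0.45, 0.0, np.round(rng.exponential(15.0, n) + 1.0, 1)
    )
    eff = config.covariate_effects
    if eff:
        log_mult = log_mult + eff.get("age_per_year", 0.0) * (age - 60.0)
        log_mult = log_mult + eff.get("stage_iii", 0.0) * (stage == "III")
        log_mult = log_mult + eff.get("stage_iv", 0.0) * (stage == "IV")
        log_mult = log_mult + eff.get("grade_3", 0.0) * (grade == "3")
        log_mult = log_mult + eff.get("residual_suboptimal", 0.0) * (residual_mm > 10.0)
    mult = np.exp(log_mult)

    E = rng.exponential(1.0, n)
    if config.baseline[0] == "exponential":
        rate = config.baseline[1]
        T = E / (rate * mult)
    else:
        _, shape, scale = config.baseline
        T = scale * (E / mult) ** (1.0 / shape)

    if config.censoring is None:
        os_time, event = T, np.ones(n, dtype=int)
    else:
        ckind, cpar = config.censoring
        C = rng.exponential(1.0 / cpar, n) if ckind == "exponential" else np.full(n, float(cpar))
        os_time = np.minimum(T, C)
        event = (T <= C).astype(int)
    os_time = np.maximum(os_time, 1e-6)

    clin = ClinicalTable(
        pd.DataFrame(
            {
                "os_years": os_time,
                "os_event": event,
                "age": age,
                "stage": stage,
                "grade": grade,
                "residual_mm": residual_mm,
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )
    truth = SimulatedTruth(
        directions={s.gene: s.direction for s in config.signal},
        betas={s.gene: s.beta for s in config.signal},
        hazard_multiplier=mult,
        censoring_fraction=float(1.0 - event.mean()),
        baseline=config.baseline,
        seed=config.seed,
    )
    return expr, clin, truth


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def _alternating_signal(genes: list[str], n_signal: int, beta: float) -> tuple[SignalGene, ...]:
    out = []
    for i in range(n_signal):
        direction = HIGH_GOOD if i % 2 == 0 else LOW_GOOD
        out.append(SignalGene(genes[i], direction, beta))
    return tuple(out)


def _preset(n_patients: int, n_genes: int, n_signal: int, beta: float) -> SimulationConfig:
    genes = _gene_names(n_genes)
    return SimulationConfig(
        n_patients=n_patients,
        n_genes=n_genes,
        signal=_alternating_signal(genes, n_signal, beta),
        baseline=("exponential", 0.18),
        censoring=("exponential", 0.08),
        seed=None,
    )


PRESETS = {
    "tcga_like": dict(n_patients=511, n_genes=179, n_signal=25),
    "tothill_like": dict(n_patients=240, n_genes=179, n_signal=25),
    "tj_like": dict(n_patients=105, n_genes=25, n_signal=25),
}


def make_preset(
    name: str,
    seed: int | None = None,
    signal_beta: float = 0.4,
    **overrides,
) -> SimulationConfig:
    """Fully-specified config for a named cohort shape.

    Presets fix only the dimensions (patients, candidate genes, planted
    signal genes); ``signal_beta`` sets the per-gene log-hazard between
    median groups and further fields can be overridden via keyword
    arguments understood by :class:`SimulationConfig`.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    spec = PRESETS[name]
    cfg = _preset(spec["n_patients"], spec["n_genes"], spec["n_signal"], signal_beta)
    cfg = replace(cfg, seed=seed, **overrides)
    return cfg
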