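"""Synthetic study generator: RBS libraries, strain cohorts, build logs.

Stands in for the wet-lab measurements so the whole pipeline is testable
offline.  A planted :class:`ResponseSurfaceTruth` encodes the study system's
qualitative mechanisms:

* RBS strength of *hpaBC* rises with SD GC content, that of *ddc* falls —
  gene-context-dependent log-linear expression maps;
* dopamine titre is unimodal along the HpaBC:Ddc expression-ratio axis with
  its peak at the planted optimal ratio (default 2.6);
* titre also scales with absolute HpaBC expression through a normalized
  power term, so strains that translate the whole operon weakly produce
  little dopamine even at a balanced ratio — without this capacity term a
  pure ratio surface cannot show both of the observed GC trends (titre
  falling in gc_ddc at strong hpaBC, and falling when gc_hpaBC is reduced
  at GC-rich ddc);
* l-DOPA leaks out when the expression ratio overshoots the optimum
  (insufficient Ddc), mirroring the accumulating strains of the study.

All generators are pure functions of (arguments, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .analysis import estimate_optimal_expression_ratio
from .design import DesignTarget, assemble_design_sheet, strategy_a_match, strategy_b_sample
from .errors import ValidationError
from .kinetics import DEFAULT_RATIOS
from .rbs import RBSEntry, StrengthModel, enumerate_sd_space, gc_content, predict_tir

_OPTIMAL_RATIO_DEFAULT = 2.6
# log-ratio of the weakest-GC corner design relative to the optimum; places
# the balanced ratio inside the reachable GC grid (see docs/methods.md).
_CORNER_LOG_RATIO = -1.1


def _default_model_hpaBC() -> StrengthModel:
    return StrengthModel(intercept=0.0, gc_slope=1.5, noise_sd=0.15)


def _default_model_ddc() -> StrengthModel:
    # intercept fixed so that exp ratio at GC (0, 0) sits _CORNER_LOG_RATIO
    # below the planted optimum
    return StrengthModel(
        intercept=-(math.log(_OPTIMAL_RATIO_DEFAULT) + _CORNER_LOG_RATIO),
        gc_slope=-1.5,
        noise_sd=0.15,
    )


@dataclass
class ResponseSurfaceTruth:
    """Planted ground truth for synthetic cohorts.

    ``measurement_cv`` defaults to the relative error of the headline titre
    (1.2/69.03 ~ 1.7%); ``biomass_mean_g_per_L`` is back-computed from the
    headline titre and specific yield (69.03/34.34 ~ 2.01 g/L).
    """

    model_hpaBC: StrengthModel = field(default_factory=_default_model_hpaBC)
    model_ddc: StrengthModel = field(default_factory=_default_model_ddc)
    optimal_expr_ratio: float = _OPTIMAL_RATIO_DEFAULT
    max_titre_mg_per_L: float = 69.03
    ratio_sigma: float = 0.9  # width of the log-Gaussian ratio response
    capacity_exponent: float = 2.5  # power on normalized HpaBC expression
    dopa_leak_scale: float = 40.0  # mg/L of l-DOPA per log unit of ratio overshoot
    measurement_cv: float = 1.2 / 69.03
    biomass_mean_g_per_L: float = 69.03 / 34.34
    biomass_cv: float = 0.02

    def __post_init__(self):
        if self.model_hpaBC.gc_slope <= 0 or self.model_ddc.gc_slope >= 0:
            raise ValidationError(
                "expression maps must be increasing in GC for hpaBC and decreasing for ddc"
            )
        for name in ("optimal_expr_ratio", "max_titre_mg_per_L", "ratio_sigma"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("measurement_cv", "biomass_cv", "dopa_leak_scale", "capacity_exponent"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not self.biomass_mean_g_per_L > 0:
            raise ValidationError("biomass_mean_g_per_L must be > 0")
        self._amp_norm = self._grid_max_unnormalized()

    # -- surfaces -----------------------------------------------------------

    def expr_hpaBC(self, gc: float) -> float:
        """Noise-free hpaBC expression at a GC fraction (monotone increasing)."""
        return self.model_hpaBC.expression(gc)

    def expr_ddc(self, gc: float) -> float:
        """Noise-free ddc expression at a GC fraction (monotone decreasing)."""
        return self.model_ddc.expression(gc)

    def expr_ratio(self, gc_hpaBC: float, gc_ddc: float) -> float:
        """HpaBC:Ddc expression ratio for a design's two GC fractions."""
        return self.expr_hpaBC(gc_hpaBC) / self.expr_ddc(gc_ddc)

    def _unnormalized_titre(self, gc_hpaBC, gc_ddc):
        gh = np.asarray(gc_hpaBC, dtype=float)
        gd = np.asarray(gc_ddc, dtype=float)
        expr_h = np.exp(self.model_hpaBC.intercept + self.model_hpaBC.gc_slope * gh)
        expr_d = np.exp(self.model_ddc.intercept + self.model_ddc.gc_slope * gd)
        log_excess = np.log(expr_h / expr_d / self.optimal_expr_ratio)
        amp = (expr_h / self.expr_hpaBC(1.0)) ** self.capacity_exponent
        return amp * np.exp(-(log_excess ** 2) / (2.0 * self.ratio_sigma ** 2))

    def _grid_max_unnormalized(self) -> float:
        levels = np.arange(7) / 6.0
        gh, gd = np.meshgrid(levels, levels, indexing="ij")
        return float(np.max(self._unnormalized_titre(gh, gd)))

    def titre_surface(self, gc_hpaBC: float, gc_ddc: float) -> float:
        """Noise-free dopamine titre (mg/L); max over the GC grid equals
        ``max_titre_mg_per_L``."""
        val = self._unnormalized_titre(gc_hpaBC, gc_ddc) * (
            self.max_titre_mg_per_L / self._amp_norm
        )
        return float(val) if np.ndim(val) == 0 else val

    def dopa_leak(self, expr_ratio: float) -> float:
        """Residual l-DOPA (mg/L): zero below the optimal ratio, rising with
        the log overshoot above it (insufficient Ddc)."""
        return self.dopa_leak_scale * max(0.0, math.log(expr_ratio / self.optimal_expr_ratio))


@dataclass
class CohortSpec:
    """A synthetic cultivation campaign: design table, seed, replicate count
    (triplicates by default, as in microbioreactor runs)."""

    designs: pd.DataFrame
    seed: int
    replicates: int = 3

    def __post_init__(self):
        if self.replicates < 1:
            raise ValidationError(f"replicates must be >= 1, got {self.replicates}")
        if self.designs is None or len(self.designs) == 0:
            raise ValidationError("design table must be nonempty")


# ---------------------------------------------------------------------------
# Generators


@lru_cache(maxsize=1)
def _hexamers_by_gc() -> dict[int, tuple[str, ...]]:
    groups: dict[int, list[str]] = {g: [] for g in range(7)}
    for seq in enumerate_sd_space(6):
        groups[int(gc_content(seq) * 6)].append(seq)
    return {g: tuple(v) for g, v in groups.items()}


# fixed visiting order over GC levels so small libraries still span the range
_LEVEL_ORDER = (0, 6, 3, 2, 4, 1, 5)


def gen_rbs_library(
    n_per_context: int,
    model_hpaBC: StrengthModel,
    model_ddc: StrengthModel,
    seed: int,
) -> list[RBSEntry]:
    """Draw a characterized RBS library with ``n_per_context`` entries per gene.

    Hexamers are sampled without replacement, cycling over the seven GC levels
    (0/6..6/6) so every level is represented where capacity allows; TIRs come
    from each context's strength model with seeded lognormal noise.
    """
    if not 1 <= n_per_context <= 4096:
        raise ValidationError(f"n_per_context must be in [1, 4096], got {n_per_context}")
    rng = np.random.default_rng(seed)
    entries: list[RBSEntry] = []
    for context, model, prefix in (
        ("hpaBC", model_hpaBC, "h"),
        ("ddc", model_ddc, "d"),
    ):
        pools = {
            g: list(rng.permutation(np.array(seqs)))
            for g, seqs in _hexamers_by_gc().items()
        }
        chosen: list[str] = []
        while len(chosen) < n_per_context:
            progressed = False
            for g in _LEVEL_ORDER:
                if len(chosen) >= n_per_context:
                    break
                if pools[g]:
                    chosen.append(str(pools[g].pop()))
                    progressed = True
            if not progressed:  # pragma: no cover - n_per_context <= 4096
                break
        for i, seq in enumerate(chosen):
            tir = predict_tir(model, seq, rng)
            entries.append(RBSEntry.create(f"{prefix}{i:04d}", seq, context, tir))
    return entries


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-preserving multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    s = math.sqrt(math.log1p(cv ** 2))
    return np.exp(rng.normal(-0.5 * s * s, s, size))


def gen_strain_results(spec: CohortSpec, truth: ResponseSurfaceTruth) -> pd.DataFrame:
    """Simulated per-replicate strain performance for every design.

    Expression ratios come from the truth maps applied to the design's two GC
    fractions; titre and l-DOPA surfaces are evaluated and multiplied by
    lognormal measurement noise; biomass is drawn around its mean with its
    own CV.  Deterministic given ``spec.seed``.
    """
    designs = spec.designs
    for col in ("design_id", "gc_hpaBC", "gc_ddc"):
        if col not in designs.columns:
            raise ValidationError(f"design table missing column {col!r}")
    rng = np.random.default_rng(spec.seed)
    n = len(designs) * spec.replicates
    gc_h = np.repeat(designs["gc_hpaBC"].to_numpy(float), spec.replicates)
    gc_d = np.repeat(designs["gc_ddc"].to_numpy(float), spec.replicates)
    ids = np.repeat(designs["design_id"].to_numpy(str), spec.replicates)
    replicate = np.tile(np.arange(1, spec.replicates + 1), len(designs))

    titre0 = np.atleast_1d(truth.titre_surface(gc_h, gc_d))
    dopa0 = np.array(
        [truth.dopa_leak(truth.expr_ratio(h, d)) for h, d in zip(gc_h, gc_d)]
    )
    titre = titre0 * _lognormal_factor(rng, truth.measurement_cv, n)
    dopa = dopa0 * _lognormal_factor(rng, truth.measurement_cv, n)
    biomass = truth.biomass_mean_g_per_L * _lognormal_factor(rng, truth.biomass_cv, n)

    return pd.DataFrame(
        {
            "design_id": ids,
            "replicate": replicate,
            "dopamine_mg_per_L": titre,
            "dopa_mg_per_L": dopa,
            "biomass_g_per_L": biomass,
            "gc_hpaBC": gc_h,
            "gc_ddc": gc_d,
        }
    )


def gen_build_log(
    design_ids: Sequence[str],
    stage_success_probs: tuple[float, float, float],
    seed: int,
) -> pd.DataFrame:
    """Seeded Bernoulli build funnel with the monotone stage ladder enforced.

    ``stage_success_probs`` are the conditional per-stage success
    probabilities (PCR | designed, assembly | PCR, sequence | assembly).
    """
    probs = tuple(stage_success_probs)
    if len(probs) != 3 or any(not 0.0 <= p <= 1.0 for p in probs):
        raise ValidationError(f"stage_success_probs must be three values in [0,1], got {probs}")
    rng = np.random.default_rng(seed)
    draws = rng.random((len(design_ids), 3))
    pcr = draws[:, 0] < probs[0]
    assembled = pcr & (draws[:, 1] < probs[1])
    sequenced = assembled & (draws[:, 2] < probs[2])
    return pd.DataFrame(
        {
            "design_id": list(design_ids),
            "pcr_ok": pcr,
            "assembled_ok": assembled,
            "sequence_verified": sequenced,
        }
    )


# ---------------------------------------------------------------------------
# End-to-end experiments (design -> cohort -> learn)


def campaign_layout_sheet(
    library: Sequence[RBSEntry],
    invitro_ratios: Sequence[float] = DEFAULT_RATIOS,
    seed: int = 0,
    n_strategy_b: int = 41,
) -> pd.DataFrame:
    """The 15 + 41 = 56 design layout over a characterized library.

    Strategy A takes two TIR-ratio matches per in vitro titration point, with
    a third pick at the first point to fill the 15-design slate (how the 15
    spread over 7 points is a free choice; see docs/methods.md).
    """
    targets = [DesignTarget(float(r)) for r in invitro_ratios]
    a = strategy_a_match(library, targets[:1], n_per_target=3)
    a += strategy_a_match(library, targets[1:], n_per_target=2)
    b = strategy_b_sample(library, n_strategy_b, seed)
    return assemble_design_sheet(a, b)


def ratio_recovery_experiment(
    truth: ResponseSurfaceTruth,
    n_seeds: int = 100,
    seed0: int = 0,
    n_per_context: int = 48,
    replicates: int = 3,
) -> np.ndarray:
    """Monte-Carlo recovery of the planted optimal expression ratio.

    Per seed: generate a library, lay out a 56-design sheet, simulate the
    cohort, and estimate the titre-maximizing expression ratio from cohort
    observables alone.  The learn step first refits the per-context strength
    models to the library (log TIR on GC) and scores each design with the
    smoothed model prediction rather than its single noisy TIR measurement,
    which removes most errors-in-variables attenuation.  Returns the
    recovered ratios.
    """
    recovered = np.empty(n_seeds)
    for i in range(n_seeds):
        s = int(seed0) + 10 * i
        lib = gen_rbs_library(n_per_context, truth.model_hpaBC, truth.model_ddc, s)
        sheet = campaign_layout_sheet(lib, seed=s + 1)
        cohort = gen_strain_results(CohortSpec(sheet, seed=s + 2, replicates=replicates), truth)
        fit_h = StrengthModel.fit([e for e in lib if e.context == "hpaBC"])
        fit_d = StrengthModel.fit([e for e in lib if e.context == "ddc"])
        merged = cohort.merge(
            sheet[["design_id", "gc_hpaBC", "gc_ddc"]],
            on="design_id",
            suffixes=("", "_sheet"),
            validate="m:1",
        )
        tir_h = np.exp(fit_h.intercept + fit_h.gc_slope * merged["gc_hpaBC"].to_numpy())
        tir_d = np.exp(fit_d.intercept + fit_d.gc_slope * merged["gc_ddc"].to_numpy())
        recovered[i] = estimate_optimal_expression_ratio(
            tir_h, tir_d, merged["dopamine_mg_per_L"]
        )
    return recovered


def gc_trend_recovery_experiment(
    truth: ResponseSurfaceTruth,
    n_cohorts: int = 200,
    seed0: int = 0,
    n_per_context: int = 48,
    replicates: int = 3,
) -> dict[str, float]:
    """Fraction of synthetic cohorts recovering both planted GC trend signs.

    One seeded library/design sheet, many measurement replica cohorts; runs
    the stratified analysis fixing each context at high GC in turn.
    """
    from .analysis import gc_stratified_analysis

    lib = gen_rbs_library(n_per_context, truth.model_hpaBC, truth.model_ddc, int(seed0))
    sheet = campaign_layout_sheet(lib, seed=int(seed0) + 1)
    n_pos = n_neg = 0
    for i in range(n_cohorts):
        cohort = gen_strain_results(
            CohortSpec(sheet, seed=int(seed0) + 100 + i, replicates=replicates), truth
        )
        if gc_stratified_analysis(cohort, fixed_context="ddc").direction == "positive":
            n_pos += 1
        if gc_stratified_analysis(cohort, fixed_context="hpaBC").direction == "negative":
            n_neg += 1
    return {
        "hpaBC_positive_fraction": n_pos / n_cohorts,
        "ddc_negative_fraction": n_neg / n_cohorts,
        "n_cohorts": n_cohorts,
    }
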