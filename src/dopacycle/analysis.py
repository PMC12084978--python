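"""Test-and-learn stage: build accounting, unit conversions, benchmarking,
and the GC-stratified trend analysis.

Percentages and fold changes follow the reporting conventions of the study
system: one decimal, half-away-from-zero, for success rates and folds;
nearest integer for percent increases.  Raw (unrounded) values are available
via ``rounded=False`` so downstream arithmetic never compounds rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .rbs import round_half_up

# IUPAC 2021 conventional atomic masses (g/mol); embedded so conversions are
# bit-stable across environments.
ATOMIC_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}

#: Molecular formulas of the cascade metabolites.
FORMULAS = {
    "tyrosine": {"C": 9, "H": 11, "N": 1, "O": 3},
    "dopa": {"C": 9, "H": 11, "N": 1, "O": 4},
    "dopamine": {"C": 8, "H": 11, "N": 1, "O": 2},
}

#: Literature benchmark for in vivo dopamine production (Das et al.):
#: 27 mg/L titre, 5.17 mg/g specific yield.
BENCHMARK_TITRE_MG_PER_L = 27.0
BENCHMARK_YIELD_MG_PER_G = 5.17

_EPS_MG_PER_L = 1e-9  # guard in accumulation ratio


def molar_mass(compound: str) -> float:
    """Molar mass (g/mol) from the tabulated atomic-mass sum."""
    if compound not in FORMULAS:
        raise ValidationError(
            f"unknown compound {compound!r}; expected one of {sorted(FORMULAS)}"
        )
    return sum(ATOMIC_MASS[el] * n for el, n in FORMULAS[compound].items())


def convert_mM_to_mg_per_L(conc_mM: float, compound: str) -> float:
    """Concentration conversion: mM x molar mass = mg/L."""
    if conc_mM < 0:
        raise ValidationError(f"concentration must be >= 0, got {conc_mM}")
    return conc_mM * molar_mass(compound)


def success_rate(numerator_count: int, designed_count: int, *, rounded: bool = True) -> float:
    """Percentage of designs passing a build stage, one-decimal by default."""
    if designed_count <= 0:
        raise ValidationError(f"designed_count must be > 0, got {designed_count}")
    if numerator_count < 0 or numerator_count > designed_count:
        raise ValidationError(
            f"numerator {numerator_count} must be in [0, {designed_count}]"
        )
    value = 100.0 * numerator_count / designed_count
    return round_half_up(value, 1) if rounded else value


def fold_change(new_value: float, benchmark_value: float, *, rounded: bool = True) -> float:
    """new/benchmark, one-decimal by default."""
    if not benchmark_value > 0:
        raise ValidationError(f"benchmark must be > 0, got {benchmark_value}")
    if not new_value > 0:
        raise ValidationError(f"new value must be > 0, got {new_value}")
    value = new_value / benchmark_value
    return round_half_up(value, 1) if rounded else value


def percent_increase(new_value: float, old_value: float, *, rounded: bool = True) -> float:
    """100 * (new - old)/old; integer-rounded by default for reporting parity."""
    if not old_value > 0:
        raise ValidationError(f"old value must be > 0, got {old_value}")
    if new_value < 0:
        raise ValidationError(f"new value must be >= 0, got {new_value}")
    value = 100.0 * (new_value - old_value) / old_value
    return round_half_up(value, 0) if rounded else value


def specific_yield(titre_mg_per_L: float, biomass_g_per_L: float) -> float:
    """Product per biomass (mg/g)."""
    if not biomass_g_per_L > 0:
        raise ValidationError(f"biomass must be > 0, got {biomass_g_per_L}")
    if titre_mg_per_L < 0:
        raise ValidationError(f"titre must be >= 0, got {titre_mg_per_L}")
    return titre_mg_per_L / biomass_g_per_L


# ---------------------------------------------------------------------------
# Build accounting


@dataclass(frozen=True)
class BuildRecord:
    """Per-stage build outcome: stages form a monotone ladder, so a stage can
    only succeed if the previous one did."""

    design_id: str
    pcr_ok: bool
    assembled_ok: bool
    sequence_verified: bool

    def __post_init__(self):
        if self.assembled_ok and not self.pcr_ok:
            raise ValidationError(f"{self.design_id}: assembled without PCR success")
        if self.sequence_verified and not self.assembled_ok:
            raise ValidationError(f"{self.design_id}: sequenced without assembly success")


def funnel_counts(records: Iterable[BuildRecord]) -> dict[str, int]:
    """Stage counts of the build funnel (designed -> PCR -> assembled -> sequenced)."""
    records = list(records)
    return {
        "designed": len(records),
        "pcr_ok": sum(r.pcr_ok for r in records),
        "assembled_ok": sum(r.assembled_ok for r in records),
        "sequence_verified": sum(r.sequence_verified for r in records),
    }


def build_records_from_frame(frame: pd.DataFrame) -> list[BuildRecord]:
    required = {"design_id", "pcr_ok", "assembled_ok", "sequence_verified"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"build log missing columns: {sorted(missing)}")
    return [
        BuildRecord(
            design_id=str(r.design_id),
            pcr_ok=bool(r.pcr_ok),
            assembled_ok=bool(r.assembled_ok),
            sequence_verified=bool(r.sequence_verified),
        )
        for r in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Strain results


@dataclass(frozen=True)
class StrainResult:
    """Measured (or synthetic) performance of one constructed strain."""

    design_id: str
    dopamine_mg_per_L: float
    dopa_mg_per_L: float
    biomass_g_per_L: float
    gc_hpaBC: float
    gc_ddc: float

    def __post_init__(self):
        if self.dopamine_mg_per_L < 0 or self.dopa_mg_per_L < 0:
            raise ValidationError(f"{self.design_id}: concentrations must be >= 0")
        if not self.biomass_g_per_L > 0:
            raise ValidationError(f"{self.design_id}: biomass must be > 0")
        for gc in (self.gc_hpaBC, self.gc_ddc):
            if not 0.0 <= gc <= 1.0:
                raise ValidationError(f"{self.design_id}: GC fraction {gc} outside [0, 1]")


RESULT_COLUMNS = [
    "design_id",
    "dopamine_mg_per_L",
    "dopa_mg_per_L",
    "biomass_g_per_L",
    "gc_hpaBC",
    "gc_ddc",
]


def _as_results_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        frame = results
    else:
        frame = pd.DataFrame([vars(r) for r in results])
    missing = set(RESULT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"results table missing columns: {sorted(missing)}")
    return frame


@dataclass(frozen=True)
class TrendSummary:
    """Sign, magnitude and sample size of a GC-vs-titre rank correlation."""

    direction: str  # "positive", "negative" or "none"
    rank_correlation: float
    n: int


def gc_stratified_analysis(
    results,
    fixed_context: str = "hpaBC",
    gc_band: tuple[float, float] = (0.8, 1.0),
) -> TrendSummary:
    """Rank-correlate the free context's GC with dopamine titre.

    Strains whose ``fixed_context`` GC lies inside ``gc_band`` are retained;
    Spearman's rho between the *other* context's GC and dopamine titre is
    computed on them.  Rank correlation is used because only the direction of
    the GC effect is established, not a linear form.
    """
    if fixed_context not in ("hpaBC", "ddc"):
        raise ValidationError(f"fixed_context must be 'hpaBC' or 'ddc', got {fixed_context!r}")
    lo, hi = gc_band
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValidationError(f"gc_band {gc_band} must satisfy 0 <= lo <= hi <= 1")
    frame = _as_results_frame(results)
    fixed_col = f"gc_{fixed_context}"
    free_col = "gc_ddc" if fixed_context == "hpaBC" else "gc_hpaBC"
    in_band = frame[(frame[fixed_col] >= lo) & (frame[fixed_col] <= hi)]
    if len(in_band) < 3:
        raise InsufficientDataError(
            f"only {len(in_band)} results with {fixed_col} in [{lo}, {hi}]; need >= 3"
        )
    x = in_band[free_col].to_numpy(float)
    y = in_band["dopamine_mg_per_L"].to_numpy(float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TrendSummary(direction="none", rank_correlation=0.0, n=len(in_band))
    rho = stats.spearmanr(x, y).statistic
    if not np.isfinite(rho) or rho == 0.0:
        return TrendSummary(direction="none", rank_correlation=0.0, n=len(in_band))
    direction = "positive" if rho > 0 else "negative"
    return TrendSummary(direction=direction, rank_correlation=float(rho), n=len(in_band))


def dopa_accumulation_flags(results, threshold_ratio: float = 1.0) -> list[str]:
    """Design ids whose l-DOPA : dopamine ratio exceeds ``threshold_ratio``.

    Replicates are averaged per design before thresholding; a tiny epsilon
    guards the denominator so dopamine-free strains are always flagged when
    they accumulate any l-DOPA.  Ids are returned sorted.
    """
    if not threshold_ratio > 0:
        raise ValidationError(f"threshold_ratio must be > 0, got {threshold_ratio}")
    frame = _as_results_frame(results)
    means = frame.groupby("design_id")[["dopamine_mg_per_L", "dopa_mg_per_L"]].mean()
    ratio = means["dopa_mg_per_L"] / np.maximum(means["dopamine_mg_per_L"], _EPS_MG_PER_L)
    return sorted(means.index[ratio > threshold_ratio])


def estimate_optimal_expression_ratio(
    tir_hpaBC: Sequence[float],
    tir_ddc: Sequence[float],
    titre_mg_per_L: Sequence[float],
) -> float:
    """Recover the expression ratio maximizing titre from cohort observables.

    Fits ``ln titre ~ b0 + b1 ln TIR_h + b2 ln rho + b3 (ln rho)^2`` with
    ``rho = TIR_h / TIR_d`` (HpaBC:Ddc expression proxy) by least squares and
    returns the vertex ``exp(-b2 / (2 b3))``.  The linear ``ln TIR_h`` term
    absorbs absolute-expression (capacity) effects so the quadratic captures
    the ratio response alone.  Requires concavity (b3 < 0).
    """
    th = np.asarray(tir_hpaBC, dtype=float)
    td = np.asarray(tir_ddc, dtype=float)
    y = np.asarray(titre_mg_per_L, dtype=float)
    if th.shape != td.shape or th.shape != y.shape:
        raise ValidationError("tir_hpaBC, tir_ddc and titre must have equal length")
    if th.size < 4:
        raise InsufficientDataError("need at least 4 strains to fit the ratio response")
    if np.any(th <= 0) or np.any(td <= 0) or np.any(y <= 0):
        raise ValidationError("TIRs and titres must be strictly positive")
    lrho = np.log(th) - np.log(td)
    X = np.column_stack([np.ones_like(lrho), np.log(th), lrho, lrho ** 2])
    beta, *_ = np.linalg.lstsq(X, np.log(y), rcond=None)
    if not beta[3] < 0:
        raise InsufficientDataError("ratio response is not concave; no interior optimum")
    return float(np.exp(-beta[2] / (2.0 * beta[3])))


# ---------------------------------------------------------------------------
# Report


def analysis_report(
    results,
    build_records: Iterable[BuildRecord],
    benchmark_titre: float = BENCHMARK_TITRE_MG_PER_L,
    benchmark_yield: float = BENCHMARK_YIELD_MG_PER_G,
    threshold_ratio: float = 1.0,
) -> dict:
    """Summary of one test-and-learn round as a plain dict (JSON/markdown-able)."""
    frame = _as_results_frame(results)
    counts = funnel_counts(build_records)
    means = frame.groupby("design_id").mean(numeric_only=True)
    best_id = means["dopamine_mg_per_L"].idxmax()
    best_titre = float(means.loc[best_id, "dopamine_mg_per_L"])
    best_yield = specific_yield(best_titre, float(means.loc[best_id, "biomass_g_per_L"]))
    report = {
        "designed": counts["designed"],
        "constructed": counts["assembled_ok"],
        "sequence_verified": counts["sequence_verified"],
        "construction_success_rate_pct": success_rate(counts["assembled_ok"], counts["designed"]),
        "sequencing_success_rate_pct": success_rate(
            counts["sequence_verified"], counts["designed"]
        ),
        "best_design": str(best_id),
        "best_titre_mg_per_L": best_titre,
        "best_specific_yield_mg_per_g": best_yield,
        "titre_fold_vs_benchmark": fold_change(best_titre, benchmark_titre),
        "yield_fold_vs_benchmark": fold_change(best_yield, benchmark_yield),
        "dopa_accumulating_designs": dopa_accumulation_flags(frame, threshold_ratio),
    }
    try:
        trend_h = gc_stratified_analysis(frame, fixed_context="hpaBC")
        report["gc_ddc_trend"] = {
            "direction": trend_h.direction,
            "rank_correlation": trend_h.rank_correlation,
            "n": trend_h.n,
        }
    except InsufficientDataError:
        report["gc_ddc_trend"] = None
    try:
        trend_d = gc_stratified_analysis(frame, fixed_context="ddc")
        report["gc_hpaBC_trend"] = {
            "direction": trend_d.direction,
            "rank_correlation": trend_d.rank_correlation,
            "n": trend_d.n,
        }
    except InsufficientDataError:
        report["gc_hpaBC_trend"] = None
    return report


def report_to_markdown(report: dict) -> str:
    """Render an :func:`analysis_report` dict as a small markdown summary."""
    lines = ["# DBTL test-and-learn summary", ""]
    lines.append(
        f"Build funnel: {report['designed']} designed, "
        f"{report['constructed']} constructed "
        f"({report['construction_success_rate_pct']}%), "
        f"{report['sequence_verified']} sequence-verified "
        f"({report['sequencing_success_rate_pct']}%)."
    )
    lines.append("")
    lines.append(
        f"Best design {report['best_design']}: "
        f"{report['best_titre_mg_per_L']:.2f} mg/L dopamine, "
        f"{report['best_specific_yield_mg_per_g']:.2f} mg/g "
        f"({report['titre_fold_vs_benchmark']}x titre and "
        f"{report['yield_fold_vs_benchmark']}x yield vs benchmark)."
    )
    lines.append("")
    for key, label in (("gc_ddc_trend", "gc_ddc"), ("gc_hpaBC_trend", "gc_hpaBC")):
        trend = report.get(key)
        if trend:
            lines.append(
                f"GC trend for {label}: {trend['direction']} "
                f"(Spearman rho = {trend['rank_correlation']:.2f}, n = {trend['n']})."
            )
    flagged = report.get("dopa_accumulating_designs") or []
    lines.append("")
    lines.append(
        "l-DOPA accumulating designs: " + (", ".join(flagged) if flagged else "none") + "."
    )
    return "\n".join(lines) + "\n"
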