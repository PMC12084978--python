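"""In vitro crude-lysate cascade: l-tyrosine -> l-DOPA -> dopamine.

Two enzyme-bearing lysates (HpaBC, the tyrosine 3-monooxygenase complex, and
Ddc, the l-DOPA decarboxylase) are mixed at volume ratio r into a fixed total
reaction volume, so raising one enzyme necessarily dilutes the other: the
HpaBC lysate fraction is r/(r+1) and the Ddc fraction 1/(r+1).

States (mM): TYR (l-tyrosine), DOPA (l-DOPA), DA (dopamine), MEL (oxidized
l-DOPA lost to melanin).  Dynamics are a two-step Michaelis-Menten cascade
with an optional first-order l-DOPA oxidation sink:

    v1 = f_h * Vmax_h * TYR / (Km_h + TYR)        f_h = r/(r+1)
    v2 = f_d * Vmax_d * DOPA / (Km_d + DOPA)      f_d = 1/(r+1)

    dTYR/dt  = -v1
    dDOPA/dt =  v1 - v2 - k_ox * DOPA
    dDA/dt   =  v2
    dMEL/dt  =  k_ox * DOPA

Total mass TYR+DOPA+DA+MEL is conserved exactly by construction; the solver
is required to preserve it within tolerance.  Enzyme activities are treated
as constant over the 20 h horizon (no lysate decay) — a stated simplification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

from .errors import IntegrationError, ValidationError


@dataclass(frozen=True)
class KineticParams:
    """Cascade rate constants at lysate fraction 1.

    Km of Ddc for l-DOPA is well characterized (0.092 mM); HpaBC is not fully
    characterized on l-tyrosine, so its Km defaults to 0.1 mM — interior to
    the 0.0094-0.514 mM range reported for structurally related substrates —
    and is configurable.
    """

    vmax_hpaBC_total: float = 0.05  # mM/h at lysate fraction 1
    km_hpaBC_tyr: float = 0.1  # mM
    vmax_ddc_total: float = 30.0  # mM/h at lysate fraction 1
    km_ddc_dopa: float = 0.092  # mM
    k_oxidation: float = 0.0  # 1/h, first-order l-DOPA loss to melanin

    def __post_init__(self):
        for name in ("vmax_hpaBC_total", "vmax_ddc_total", "k_oxidation"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("km_hpaBC_tyr", "km_ddc_dopa"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class MixSpec:
    """One lysate mixing experiment.

    ``ratio_hpaBC_to_ddc`` is the volume ratio r (100 means 100:1).  Defaults
    follow the reaction-buffer protocol: 1 mM l-tyrosine substrate, 20 h at
    37 degC.
    """

    ratio_hpaBC_to_ddc: float
    substrate_tyr0: float = 1.0  # mM
    t_end: float = 20.0  # h
    reporting_step: float = 0.5  # h

    def __post_init__(self):
        if not self.ratio_hpaBC_to_ddc > 0:
            raise ValidationError(f"ratio must be > 0, got {self.ratio_hpaBC_to_ddc}")
        if self.substrate_tyr0 < 0:
            raise ValidationError(f"substrate_tyr0 must be >= 0, got {self.substrate_tyr0}")
        if not self.t_end > 0:
            raise ValidationError(f"t_end must be > 0, got {self.t_end}")
        if not 0 < self.reporting_step <= self.t_end:
            raise ValidationError(
                f"reporting_step must be in (0, t_end], got {self.reporting_step}"
            )

    @property
    def hpaBC_fraction(self) -> float:
        r = self.ratio_hpaBC_to_ddc
        return r / (r + 1.0)

    @property
    def ddc_fraction(self) -> float:
        return 1.0 / (self.ratio_hpaBC_to_ddc + 1.0)


@dataclass
class TimeCourse:
    """Simulated concentration trajectories (mM) aligned to ``times`` (h)."""

    times: np.ndarray
    tyr: np.ndarray
    dopa: np.ndarray
    dopamine: np.ndarray
    melanin: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.tyr + self.dopa + self.dopamine + self.melanin

    @property
    def final_dopamine(self) -> float:
        return float(self.dopamine[-1])

    @property
    def final_dopa(self) -> float:
        return float(self.dopa[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "tyr_mM": self.tyr,
                "dopa_mM": self.dopa,
                "dopamine_mM": self.dopamine,
                "melanin_mM": self.melanin,
            }
        )


#: Default preset used throughout: trend-calibrated to the in vitro titration
#: (monotone, converging dopamine gain from 1:1 to 100:1), not to absolute
#: figures, which are not available numerically.
DEFAULT_PARAMS = KineticParams()
DEFAULT_MIX = MixSpec(ratio_hpaBC_to_ddc=1.0)
#: Lysate volume ratios of the titration protocol (1:1 up to 100:1).
DEFAULT_RATIOS = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0)

_ABS_TOL = 1e-12  # mM, absolute solver floor


def _rhs(params: KineticParams, mix: MixSpec):
    f_h = mix.hpaBC_fraction
    f_d = mix.ddc_fraction
    v1max = f_h * params.vmax_hpaBC_total
    v2max = f_d * params.vmax_ddc_total
    km1 = params.km_hpaBC_tyr
    km2 = params.km_ddc_dopa
    kox = params.k_oxidation

    def rhs(_t, y):
        tyr, dopa = y[0], y[1]
        v1 = v1max * tyr / (km1 + tyr)
        v2 = v2max * dopa / (km2 + dopa)
        return (-v1, v1 - v2 - kox * dopa, v2, kox * dopa)

    return rhs


def simulate_mix(
    params: KineticParams,
    mix: MixSpec,
    tolerance: float = 1e-8,
) -> TimeCourse:
    """Integrate one lysate mixing experiment.

    ``tolerance`` is the relative solver tolerance (absolute floor 1e-12 mM).
    Raises :class:`IntegrationError` (carrying the last accepted state) if the
    solver fails, and validates non-negativity and mass conservation of the
    reported trajectories.
    """
    times = np.arange(0.0, mix.t_end + 0.5 * mix.reporting_step, mix.reporting_step)
    if times[-1] > mix.t_end:
        times[-1] = mix.t_end
    y0 = (mix.substrate_tyr0, 0.0, 0.0, 0.0)
    if mix.substrate_tyr0 == 0.0:
        z = np.zeros_like(times)
        return TimeCourse(times=times, tyr=z, dopa=z.copy(), dopamine=z.copy(), melanin=z.copy())

    sol = solve_ivp(
        _rhs(params, mix),
        (0.0, mix.t_end),
        y0,
        method="LSODA",
        t_eval=times,
        rtol=tolerance,
        atol=_ABS_TOL,
    )
    if not sol.success:
        last = sol.y[:, -1] if sol.y.size else None
        raise IntegrationError(f"ODE solver failed: {sol.message}", last_state=last)

    y = sol.y
    # Clip solver round-off only; a genuinely negative state is an error.
    neg_floor = -max(1e6 * _ABS_TOL, 10 * tolerance * mix.substrate_tyr0)
    if np.any(y < neg_floor):
        raise IntegrationError(
            f"negative state beyond tolerance (min {y.min():.3e} mM)", last_state=y[:, -1]
        )
    y = np.clip(y, 0.0, None)

    tc = TimeCourse(times=sol.t, tyr=y[0], dopa=y[1], dopamine=y[2], melanin=y[3])
    drift = np.max(np.abs(tc.total - mix.substrate_tyr0))
    if drift > 10 * tolerance * mix.substrate_tyr0 + 1e6 * _ABS_TOL:
        raise IntegrationError(
            f"mass conservation drift {drift:.3e} mM exceeds tolerance", last_state=y[:, -1]
        )
    return tc


def titrate(
    params: KineticParams,
    ratios: Sequence[float],
    base_mix: MixSpec = DEFAULT_MIX,
    tolerance: float = 1e-8,
) -> pd.DataFrame:
    """Run the HpaBC:Ddc ratio titration; one simulation per ratio.

    Rows follow the input ratio order.  Substrate and duration are shared
    via ``base_mix``.
    """
    from .analysis import convert_mM_to_mg_per_L

    ratios = list(ratios)
    if not ratios:
        raise ValidationError("ratios must be nonempty")
    rows = []
    for r in ratios:
        mix = replace(base_mix, ratio_hpaBC_to_ddc=float(r))
        tc = simulate_mix(params, mix, tolerance=tolerance)
        rows.append(
            {
                "ratio": float(r),
                "dopamine_mM": tc.final_dopamine,
                "dopamine_mg_per_L": convert_mM_to_mg_per_L(tc.final_dopamine, "dopamine"),
                "dopa_mM": tc.final_dopa,
            }
        )
    return pd.DataFrame(rows)


def optimal_ratio(titration: pd.DataFrame, criterion: str = "max_dopamine") -> float:
    """Ratio optimizing the chosen criterion; ties break toward the smaller ratio.

    Criteria: ``max_dopamine`` (highest final dopamine) or
    ``min_dopa_residual`` (lowest final l-DOPA).
    """
    if titration is None or len(titration) < 2:
        raise ValidationError("titration table needs at least 2 rows")
    if criterion == "max_dopamine":
        col, best = titration["dopamine_mM"].to_numpy(), np.max
    elif criterion == "min_dopa_residual":
        col, best = titration["dopa_mM"].to_numpy(), np.min
    else:
        raise ValidationError(f"unknown criterion {criterion!r}")
    target = best(col)
    ratios = titration["ratio"].to_numpy()
    return float(np.min(ratios[col == target]))


def load_experiment_config(path) -> tuple[KineticParams, MixSpec]:
    """Read a kinetics preset from a YAML key-value file.

    Recognized top-level keys: ``params`` (KineticParams fields) and ``mix``
    (MixSpec fields); missing fields fall back to defaults.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    params = KineticParams(**(cfg.get("params") or {}))
    mix_cfg = dict(cfg.get("mix") or {})
    mix_cfg.setdefault("ratio_hpaBC_to_ddc", 1.0)
    return params, MixSpec(**mix_cfg)
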