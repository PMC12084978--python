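"""Independent oracles used by the tests.

These deliberately avoid the library code paths they check: a fixed-step
explicit Euler integrator for the cascade, a closed-form implicit solution
for the single-enzyme Michaelis-Menten depletion, and hand-summed formula
masses.
"""

from __future__ import annotations

import math

from scipy.optimize import brentq


def euler_cascade(
    vmax_h: float,
    km_h: float,
    vmax_d: float,
    km_d: float,
    k_ox: float,
    ratio: float,
    tyr0: float,
    t_end: float,
    step: float = 1e-4,
) -> tuple[float, float, float, float]:
    """Fixed-step explicit Euler integration of the lysate cascade.

    Returns (tyr, dopa, dopamine, melanin) at t_end.  Effective Vmax values
    are scaled by the fixed-total-volume mixing fractions r/(r+1), 1/(r+1).
    """
    f_h = ratio / (ratio + 1.0)
    f_d = 1.0 / (ratio + 1.0)
    v1max = f_h * vmax_h
    v2max = f_d * vmax_d
    n = int(round(t_end / step))
    tyr, dopa, da, mel = tyr0, 0.0, 0.0, 0.0
    for _ in range(n):
        v1 = v1max * tyr / (km_h + tyr)
        v2 = v2max * dopa / (km_d + dopa)
        tyr -= step * v1
        dopa += step * (v1 - v2 - k_ox * dopa)
        da += step * v2
        mel += step * k_ox * dopa
        if tyr < 0.0:
            tyr = 0.0
        if dopa < 0.0:
            dopa = 0.0
    return tyr, dopa, da, mel


def closed_form_tyr(vmax_eff: float, km: float, tyr0: float, t: float) -> float:
    """Substrate remaining under single-enzyme Michaelis-Menten depletion.

    Root of the implicit integrated rate law
    km*ln(tyr0/T) + (tyr0 - T) = vmax_eff * t, solved by bisection.
    """

    def f(T: float) -> float:
        return km * math.log(tyr0 / T) + (tyr0 - T) - vmax_eff * t

    lo = tyr0 * 1e-12
    if f(lo) < 0:  # depletion practically complete
        return 0.0
    return brentq(f, lo, tyr0, xtol=1e-15, rtol=1e-14)


# Hand-summed molar masses, IUPAC conventional atomic weights
# (H 1.008, C 12.011, N 14.007, O 15.999):
DOPAMINE_MASS = 8 * 12.011 + 11 * 1.008 + 14.007 + 2 * 15.999  # C8H11NO2
LDOPA_MASS = 9 * 12.011 + 11 * 1.008 + 14.007 + 4 * 15.999  # C9H11NO4
TYROSINE_MASS = 9 * 12.011 + 11 * 1.008 + 14.007 + 3 * 15.999  # C9H11NO3


def brute_force_pair_matches(h_entries, d_entries, numeric_target: float, n: int):
    """Exhaustive cross-product TIR-ratio matching with the documented
    tie-break (distance, hpaBC sequence, ddc sequence)."""
    scored = []
    for h in h_entries:
        for d in d_entries:
            dist = abs(math.log(d.tir / h.tir) - math.log(numeric_target))
            scored.append((dist, h.sd, d.sd))
    scored.sort()
    return scored[:n]
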