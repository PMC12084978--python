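"""Translate a target enzyme ratio into bi-cistronic RBS pair designs.

Two complementary strategies populate the design sheet:

* **Strategy A** — TIR-ratio matching: for each in vitro enzyme-ratio target
  (e.g. 2:1 HpaBC:Ddc, numeric ratio 0.5 = Ddc/HpaBC), pick the RBS pairs
  whose TIR ratio TIR(ddc)/TIR(hpaBC) is closest to the target in log space.
  Log distance penalizes 2:1 and 1:2 mismatches symmetrically.
* **Strategy B** — boundary exploration: a seeded, GC-stratified sample of
  pairs across the library, always including the strongest candidate of each
  context and the AGGAGA/AGGAGA reference pair when present.

The canonical campaign layout is 15 Strategy A + 41 Strategy B = 56 designs,
labeled A.01..A.15 and B.01..B.41.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .rbs import REFERENCE_SD, RBSEntry

SHEET_COLUMNS = [
    "design_id",
    "strategy",
    "rbs_hpaBC_seq",
    "rbs_ddc_seq",
    "gc_hpaBC",
    "gc_ddc",
    "tir_hpaBC",
    "tir_ddc",
    "numeric_tir_ratio",
    "target_ratio",
    "log_distance",
]


@dataclass(frozen=True)
class DesignTarget:
    """An enzyme-ratio target, e.g. 2 for "2:1" HpaBC:Ddc.

    ``numeric_ratio`` is the Ddc/HpaBC convention forced by the worked
    example "2:1 corresponds to a numerical ratio of 0.5".
    """

    hpaBC_to_ddc_ratio: float

    def __post_init__(self):
        if not self.hpaBC_to_ddc_ratio > 0:
            raise ValidationError(
                f"target ratio must be > 0, got {self.hpaBC_to_ddc_ratio}"
            )

    @property
    def numeric_ratio(self) -> float:
        return 1.0 / self.hpaBC_to_ddc_ratio


@dataclass(frozen=True)
class RBSPairDesign:
    """A candidate (RBS_hpaBC, RBS_ddc) pair with its numeric TIR ratio."""

    rbs_hpaBC: RBSEntry
    rbs_ddc: RBSEntry
    strategy: str  # "A", "B" or "reference"
    target: DesignTarget | None = None

    def __post_init__(self):
        if self.strategy not in ("A", "B", "reference"):
            raise ValidationError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "A" and self.target is None:
            raise ValidationError("Strategy A designs require a target")

    @property
    def numeric_tir_ratio(self) -> float:
        return self.rbs_ddc.tir / self.rbs_hpaBC.tir

    @property
    def log_distance(self) -> float:
        if self.target is None:
            return 0.0
        return abs(math.log(self.numeric_tir_ratio) - math.log(self.target.numeric_ratio))

    @property
    def pair_key(self) -> tuple[str, str]:
        return (self.rbs_hpaBC.sd, self.rbs_ddc.sd)


def _split_contexts(library: Iterable[RBSEntry]) -> tuple[list[RBSEntry], list[RBSEntry]]:
    entries = list(library)
    h = [e for e in entries if e.context == "hpaBC"]
    d = [e for e in entries if e.context == "ddc"]
    if not h or not d:
        raise ValidationError("library must contain entries for both hpaBC and ddc contexts")
    return h, d


def strategy_a_match(
    library: Iterable[RBSEntry],
    targets: Sequence[DesignTarget],
    n_per_target: int = 2,
) -> list[RBSPairDesign]:
    """Best TIR-ratio matches per target over the full hpaBC x ddc cross product.

    For each target the ``n_per_target`` pairs minimizing
    ``|ln(TIR_ddc/TIR_hpaBC) - ln(target numeric ratio)|`` are returned, ties
    broken lexicographically on (hpaBC sequence, ddc sequence) so outputs are
    byte-for-byte reproducible.  Pairs are sorted by (target order, distance,
    sequences); a pair may serve several targets but is unique within one.
    """
    if not targets:
        raise ValidationError("targets must be nonempty")
    if n_per_target < 1:
        raise ValidationError(f"n_per_target must be >= 1, got {n_per_target}")
    h_entries, d_entries = _split_contexts(library)
    if n_per_target > len(h_entries) * len(d_entries):
        raise ValidationError("n_per_target exceeds the number of distinct pairs")

    log_ratio = np.log([d.tir for d in d_entries])[None, :] - np.log(
        [h.tir for h in h_entries]
    )[:, None]

    selected: list[RBSPairDesign] = []
    for target in targets:
        dist = np.abs(log_ratio - math.log(target.numeric_ratio))
        ranked = sorted(
            ((dist[i, j], h.sd, d.sd, i, j) for i, h in enumerate(h_entries) for j, d in enumerate(d_entries)),
        )
        for distance, _hs, _ds, i, j in ranked[:n_per_target]:
            selected.append(
                RBSPairDesign(
                    rbs_hpaBC=h_entries[i], rbs_ddc=d_entries[j], strategy="A", target=target
                )
            )
    return selected


def _gc_bin(entry: RBSEntry) -> int:
    # bins of width 1/6: the 7 exact GC levels of a hexamer
    return int(entry.gc_fraction * 6)


def strategy_b_sample(
    library: Iterable[RBSEntry],
    n: int,
    seed: int,
) -> list[RBSPairDesign]:
    """Seeded boundary-exploration sample of ``n`` distinct RBS pairs.

    Always includes (a) the strongest-TIR hpaBC paired with the strongest-TIR
    ddc entry, and (b) the AGGAGA/AGGAGA reference pair when both contexts
    contain the consensus sequence.  Remaining slots are filled by sampling
    stratified across the GC-fraction bins of both contexts (7 x 7 bin pairs
    interleaved in seeded order), deterministic given the seed.
    """
    h_entries, d_entries = _split_contexts(library)
    total = len(h_entries) * len(d_entries)
    if not 1 <= n <= total:
        raise ValidationError(f"n must be in [1, {total}], got {n}")

    rng = np.random.default_rng(seed)

    def strongest(entries: list[RBSEntry]) -> RBSEntry:
        return max(entries, key=lambda e: (e.tir, e.sd))

    mandatory: list[tuple[RBSEntry, RBSEntry, str]] = [
        (strongest(h_entries), strongest(d_entries), "B")
    ]
    ref_h = next((e for e in h_entries if e.sd == REFERENCE_SD), None)
    ref_d = next((e for e in d_entries if e.sd == REFERENCE_SD), None)
    if ref_h is not None and ref_d is not None:
        mandatory.append((ref_h, ref_d, "reference"))

    seen: set[tuple[str, str]] = set()
    picks: list[RBSPairDesign] = []
    for h, d, strat in mandatory:
        key = (h.sd, d.sd)
        if key not in seen and len(picks) < n:
            seen.add(key)
            picks.append(RBSPairDesign(rbs_hpaBC=h, rbs_ddc=d, strategy=strat))

    # Stratified fill: group the pair space by (hpaBC GC bin, ddc GC bin),
    # shuffle within and across groups, then take pairs round-robin.
    groups: dict[tuple[int, int], list[tuple[RBSEntry, RBSEntry]]] = {}
    for h in h_entries:
        for d in d_entries:
            groups.setdefault((_gc_bin(h), _gc_bin(d)), []).append((h, d))
    group_keys = sorted(groups)
    order = rng.permutation(len(group_keys))
    shuffled_groups = []
    for idx in order:
        pairs = sorted(groups[group_keys[idx]], key=lambda p: (p[0].sd, p[1].sd))
        perm = rng.permutation(len(pairs))
        shuffled_groups.append([pairs[i] for i in perm])

    depth = 0
    while len(picks) < n:
        advanced = False
        for grp in shuffled_groups:
            if len(picks) >= n:
                break
            if depth < len(grp):
                h, d = grp[depth]
                advanced = True
                key = (h.sd, d.sd)
                if key not in seen:
                    seen.add(key)
                    picks.append(RBSPairDesign(rbs_hpaBC=h, rbs_ddc=d, strategy="B"))
        if not advanced and len(picks) < n:  # pragma: no cover - guarded by n <= total
            raise ValidationError("exhausted pair space before reaching n")
        depth += 1
    return picks


def assemble_design_sheet(
    strategy_a: Sequence[RBSPairDesign],
    strategy_b: Sequence[RBSPairDesign],
) -> pd.DataFrame:
    """Concatenate both strategies into a stable design table.

    Ids run A.01.. then B.01.. in input order.  A sequence pair appearing in
    both strategies is kept once (under its A id) with provenance "A+B".
    """
    rows = []
    a_keys: dict[tuple[str, str], int] = {}
    for i, des in enumerate(strategy_a, start=1):
        a_keys.setdefault(des.pair_key, len(rows))
        rows.append(_sheet_row(f"A.{i:02d}", des))
    b_idx = 0
    for des in strategy_b:
        if des.pair_key in a_keys:
            rows[a_keys[des.pair_key]]["strategy"] = "A+B"
            continue
        b_idx += 1
        rows.append(_sheet_row(f"B.{b_idx:02d}", des))
    return pd.DataFrame(rows, columns=SHEET_COLUMNS)


def _sheet_row(design_id: str, des: RBSPairDesign) -> dict:
    return {
        "design_id": design_id,
        "strategy": des.strategy,
        "rbs_hpaBC_seq": des.rbs_hpaBC.sd,
        "rbs_ddc_seq": des.rbs_ddc.sd,
        "gc_hpaBC": float(des.rbs_hpaBC.gc_fraction),
        "gc_ddc": float(des.rbs_ddc.gc_fraction),
        "tir_hpaBC": des.rbs_hpaBC.tir,
        "tir_ddc": des.rbs_ddc.tir,
        "numeric_tir_ratio": des.numeric_tir_ratio,
        "target_ratio": des.target.numeric_ratio if des.target else np.nan,
        "log_distance": des.log_distance if des.target else np.nan,
    }
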