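"""Shine-Dalgarno design space and RBS strength records.

The ribosome binding sites engineered in this toolkit differ only in the
six-nucleotide Shine-Dalgarno (SD) core (consensus ``AGGAGA``).  A single SD
hexamer has 4^6 = 4,096 variants; a bi-cistronic operon with two independent
SD cores spans 4^6 x 4^6 ~ 16.8 million pairs.  Each characterized variant
carries a translation initiation rate (TIR) in arbitrary relative units —
only TIR *ratios* are consumed downstream, so no absolute calibration is
attempted.

RBS strength is summarized by a context-dependent log-linear model in GC
fraction: empirically, higher GC strengthens the RBS of *hpaBC* while the
opposite holds for *ddc*, so the slope sign is free per gene context.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidSequenceError, ValidationError

ALPHABET = "ACGT"
SD_LENGTH = 6
#: Consensus Shine-Dalgarno hexamer used as the reference design.
REFERENCE_SD = "AGGAGA"
#: Gene contexts an RBS entry may be characterized in.
CONTEXTS = ("hpaBC", "ddc", "reporter")

_MAX_K = 10  # guard against combinatorial blow-up


def canonical_sd(seq: str, k: int = SD_LENGTH) -> str:
    """Validate and canonicalize an SD sequence to uppercase ACGT.

    Lowercase input is accepted; ambiguity codes and wrong lengths are
    rejected with the offending position named.
    """
    if not isinstance(seq, str):
        raise InvalidSequenceError(f"sequence must be a string, got {type(seq).__name__}")
    s = seq.upper()
    if len(s) != k:
        raise InvalidSequenceError(
            f"sequence {seq!r} has length {len(s)}, expected {k}", position=min(len(s), k)
        )
    for i, ch in enumerate(s):
        if ch not in ALPHABET:
            raise InvalidSequenceError(
                f"invalid character {seq[i]!r} at position {i} in {seq!r}", position=i
            )
    return s


def gc_content(seq: str, k: int = SD_LENGTH) -> Fraction:
    """GC fraction of an SD sequence as an exact rational (multiple of 1/k)."""
    s = canonical_sd(seq, k)
    return Fraction(s.count("G") + s.count("C"), k)


def gc_percent(seq: str, k: int = SD_LENGTH) -> float:
    """GC content as a percentage, one decimal, half-away-from-zero."""
    frac = gc_content(seq, k)
    return round_half_up(float(100 * frac), 1)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (2.5 -> 3, -2.5 -> -3)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def enumerate_sd_space(k: int) -> list[str]:
    """All k-mers over {A,C,G,T} in lexicographic order (A < C < G < T).

    For the SD hexamer (k=6) this is the full 4,096-variant design space.
    """
    if not isinstance(k, int) or not 1 <= k <= _MAX_K:
        raise ValidationError(f"k must be an integer in [1, {_MAX_K}], got {k!r}")
    return ["".join(p) for p in itertools.product(ALPHABET, repeat=k)]


def pair_space_size(k: int) -> int:
    """Number of ordered SD pairs for a bi-cistronic operon: 4^k * 4^k.

    k=0 is admitted with the empty-product convention (size 1).
    """
    if not isinstance(k, int) or not 0 <= k <= _MAX_K:
        raise ValidationError(f"k must be an integer in [0, {_MAX_K}], got {k!r}")
    return 4 ** k * 4 ** k


@dataclass(frozen=True)
class RBSEntry:
    """One characterized SD variant: sequence, gene context, GC fraction, TIR."""

    id: str
    sd: str
    context: str
    gc_fraction: Fraction
    tir: float

    def __post_init__(self):
        object.__setattr__(self, "sd", canonical_sd(self.sd))
        if self.context not in CONTEXTS:
            raise ValidationError(
                f"unknown context {self.context!r}; expected one of {CONTEXTS}"
            )
        if not self.tir > 0:
            raise ValidationError(f"tir must be > 0, got {self.tir}")
        expected = gc_content(self.sd)
        if abs(float(self.gc_fraction) - float(expected)) > 1e-6:
            raise ValidationError(
                f"gc_fraction {self.gc_fraction} inconsistent with sequence "
                f"{self.sd} (expected {expected})"
            )
        object.__setattr__(self, "gc_fraction", expected)

    @classmethod
    def create(cls, id: str, sd: str, context: str, tir: float) -> "RBSEntry":
        """Build an entry with the GC fraction computed from the sequence."""
        sd = canonical_sd(sd)
        return cls(id=id, sd=sd, context=context, gc_fraction=gc_content(sd), tir=tir)


@dataclass
class StrengthModel:
    """Log-linear RBS strength model: log TIR = intercept + gc_slope * GC + noise.

    The functional form is a configurable stand-in — only the monotone
    direction per context is empirically established, the slope magnitude
    is free.

    Parameters
    ----------
    intercept : float
        log-TIR at GC = 0 (arbitrary relative units).
    gc_slope : float
        Change in log-TIR per unit GC fraction; sign may differ by context
        (positive for *hpaBC*, negative for *ddc*).
    noise_sd : float
        Standard deviation of lognormal measurement noise, log scale; >= 0.
    """

    intercept: float
    gc_slope: float
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")

    def mean_log_tir(self, gc: float) -> float:
        return self.intercept + self.gc_slope * float(gc)

    def expression(self, gc: float) -> float:
        """Noise-free strength at a given GC fraction: exp(intercept + slope*gc)."""
        return math.exp(self.mean_log_tir(gc))

    @classmethod
    def fit(cls, entries: Iterable[RBSEntry]) -> "StrengthModel":
        """Least-squares fit of log TIR on GC fraction over a library subset."""
        entries = list(entries)
        if len(entries) < 2:
            raise ValidationError("need at least 2 entries to fit a strength model")
        gc = np.array([float(e.gc_fraction) for e in entries])
        y = np.log([e.tir for e in entries])
        slope, intercept = np.polyfit(gc, y, 1)
        resid = y - (intercept + slope * gc)
        ddof = 2 if len(entries) > 2 else 0
        noise_sd = float(np.sqrt(np.sum(resid ** 2) / max(len(entries) - ddof, 1)))
        return cls(intercept=float(intercept), gc_slope=float(slope), noise_sd=noise_sd)


def predict_tir(
    model: StrengthModel,
    seq: str,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Predicted TIR for an SD sequence; strictly positive.

    Without ``rng`` the prediction is the deterministic model mean,
    exp(intercept + gc_slope * GC).  With a seed or generator, multiplicative
    lognormal noise of log-sd ``model.noise_sd`` is applied.
    """
    gc = gc_content(seq)
    eps = 0.0
    if rng is not None and model.noise_sd > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        eps = rng.normal(0.0, model.noise_sd)
    return math.exp(model.mean_log_tir(float(gc)) + eps)


# ---------------------------------------------------------------------------
# Library I/O

LIBRARY_COLUMNS = ["id", "sd_sequence", "context", "gc_fraction", "tir"]


def library_to_frame(entries: Sequence[RBSEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [e.id for e in entries],
            "sd_sequence": [e.sd for e in entries],
            "context": [e.context for e in entries],
            "gc_fraction": [float(e.gc_fraction) for e in entries],
            "tir": [e.tir for e in entries],
        }
    )


def frame_to_library(frame: pd.DataFrame) -> list[RBSEntry]:
    missing = set(LIBRARY_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"library table missing columns: {sorted(missing)}")
    return [
        RBSEntry.create(
            id=str(row.id), sd=str(row.sd_sequence), context=str(row.context), tir=float(row.tir)
        )
        for row in frame.itertuples(index=False)
    ]


def write_library(entries: Sequence[RBSEntry], path) -> None:
    library_to_frame(entries).to_csv(path, index=False)


def read_library(path) -> list[RBSEntry]:
    return frame_to_library(pd.read_csv(path))


def write_fasta(entries: Sequence[RBSEntry], path) -> None:
    """Export library sequences as FASTA (record id = library id)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(e.sd), id=e.id, description=f"context={e.context} tir={e.tir:g}")
        for e in entries
    ]
    seqio_write(records, path, "fasta")
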