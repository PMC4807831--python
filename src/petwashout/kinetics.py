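"""Kinetic building blocks for point-source washout PET studies.

A microlitre deposit of a positron emitter injected into tissue loses
signal through two multiplicative channels: physical radioactive decay
and biological clearance.  The measured activity factorises as

    A_meas(t) = A0 * C_bio(t) * A_phys(t)

where ``A_phys(t) = exp(-lambda_phys * t)`` is the radioactive-decay
factor of the isotope and ``C_bio`` collects everything biology does.
Two parameterisations of ``C_bio`` are provided:

* a two-component product ``C_tiss(t) * C_wash(t)`` separating passive
  tissular diffusion (the only channel left in dead tissue) from
  perfusion-driven vascular washout (alive tissue only), each modelled
  as a single exponential; and
* the classical three-exponential fast/medium/slow mixture used in
  radioactive-beam washout experiments (the Mizuno model).

Everything in this module is pure computation on scalars and arrays;
no I/O, no randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "LN2",
    "C11_HALF_LIFE_S",
    "IsotopeSpec",
    "Condition",
    "TwoComponentParams",
    "MizunoParams",
    "halflife_to_lambda",
    "lambda_to_halflife",
    "eval_two_component",
    "eval_mizuno",
    "physical_decay_factor",
    "frame_averaged_exp",
]

LN2 = math.log(2.0)

#: Carbon-11 physical half-life in seconds (20.39 min, standard nuclear data).
C11_HALF_LIFE_S = 1223.4


def halflife_to_lambda(t_half):
    """Convert a half-life in seconds to a decay constant in 1/s.

    Accepts scalars or arrays; every element must be strictly positive.
    """
    t = np.asarray(t_half, dtype=float)
    if np.any(t <= 0) or not np.all(np.isfinite(t)):
        raise ValueError(f"half-life must be finite and > 0, got {t_half!r}")
    out = LN2 / t
    return float(out) if np.isscalar(t_half) else out


def lambda_to_halflife(lmbda):
    """Convert a decay constant in 1/s to a half-life in seconds.

    ``lambda = 0`` maps to an infinite half-life (no decay) rather than
    raising, so a condition with no washout is representable.
    """
    lam = np.asarray(lmbda, dtype=float)
    if np.any(lam < 0) or np.any(np.isnan(lam)):
        raise ValueError(f"decay constant must be >= 0, got {lmbda!r}")
    with np.errstate(divide="ignore"):
        out = np.where(lam > 0, LN2 / np.where(lam > 0, lam, 1.0), np.inf)
    return float(out) if np.isscalar(lmbda) else out


@dataclass(frozen=True)
class IsotopeSpec:
    """A positron emitter characterised by its physical half-life."""

    name: str
    physical_half_life: float  # seconds

    def __post_init__(self) -> None:
        if not (math.isfinite(self.physical_half_life) and self.physical_half_life > 0):
            raise ValueError(
                f"physical_half_life must be finite and > 0, got {self.physical_half_life}"
            )

    @property
    def lambda_phys(self) -> float:
        """Physical decay constant ln2 / T_1/2, in 1/s."""
        return LN2 / self.physical_half_life

    @classmethod
    def c11(cls) -> "IsotopeSpec":
        """Carbon-11, the dominant beta+ emitter produced by carbon beams."""
        return cls("C-11", C11_HALF_LIFE_S)


class Condition(str, Enum):
    """Physiological state during the acquisition.

    In the dead condition there is no perfusion, so the washout factor is
    identically 1 and only tissular diffusion drives the biological decay.
    """

    ALIVE = "alive"
    DEAD = "dead"


@dataclass(frozen=True)
class TwoComponentParams:
    """Amplitude and decay constants of the two-component biological model.

    Parameters
    ----------
    A0 : float
        Activity at injection time, Bq (> 0).
    lambda_tiss : float
        Tissular (passive diffusion) decay constant, 1/s (>= 0).
    lambda_wash : float
        Vascular (perfusion washout) decay constant, 1/s (>= 0).
    """

    A0: float
    lambda_tiss: float
    lambda_wash: float

    def __post_init__(self) -> None:
        for name in ("A0", "lambda_tiss", "lambda_wash"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.A0 <= 0:
            raise ValueError(f"A0 must be > 0, got {self.A0}")
        if self.lambda_tiss < 0 or self.lambda_wash < 0:
            raise ValueError("decay constants must be >= 0")

    @property
    def halflife_tiss(self) -> float:
        return lambda_to_halflife(self.lambda_tiss)

    @property
    def halflife_wash(self) -> float:
        return lambda_to_halflife(self.lambda_wash)

    def lambda_bio(self, condition: Condition) -> float:
        """Total biological decay constant in the given condition."""
        if Condition(condition) is Condition.ALIVE:
            return self.lambda_tiss + self.lambda_wash
        return self.lambda_tiss

    @classmethod
    def from_halflives(
        cls, A0: float, halflife_tiss: float, halflife_wash: float | None
    ) -> "TwoComponentParams":
        """Build from half-lives in seconds; ``halflife_wash=None`` or inf means no washout."""
        lw = 0.0
        if halflife_wash is not None and math.isfinite(halflife_wash):
            lw = halflife_to_lambda(halflife_wash)
        return cls(A0, halflife_to_lambda(halflife_tiss), lw)


@dataclass(frozen=True)
class MizunoParams:
    """Fractions and decay constants of the three-exponential washout model.

    The fast component tracks blood flow (seconds), the medium one
    micro-circulation (minutes) and the slow one metabolic trapping
    (hours).  Fractions live on the simplex and the decay constants are
    ordered fast >= medium >= slow.
    """

    fractions: tuple[float, float, float]  # (M_biof, M_biom, M_bios)
    lambdas: tuple[float, float, float]  # (lambda_biof, lambda_biom, lambda_bios), 1/s

    def __post_init__(self) -> None:
        f = self.fractions
        lam = self.lambdas
        if len(f) != 3 or len(lam) != 3:
            raise ValueError("fractions and lambdas must each have 3 entries")
        if any(not (0.0 <= x <= 1.0) for x in f):
            raise ValueError(f"fractions must lie in [0, 1], got {f}")
        if abs(sum(f) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1 within 1e-9, got sum {sum(f)!r}")
        if any(x < 0 for x in lam):
            raise ValueError("decay constants must be >= 0")
        if not (lam[0] >= lam[1] >= lam[2]):
            raise ValueError(f"lambdas must be ordered fast >= medium >= slow, got {lam}")


def eval_two_component(params: TwoComponentParams, t, condition: Condition):
    """Relative activity of the two-component biological model at time(s) ``t``.

    Alive tissue decays with the sum of the tissular and washout
    constants; dead tissue with the tissular constant alone.  Returns a
    unitless value in (0, 1]; multiply by ``params.A0`` for absolute
    activity.
    """
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("t must be >= 0")
    out = np.exp(-params.lambda_bio(condition) * tt)
    return float(out) if np.isscalar(t) or tt.ndim == 0 else out


def eval_mizuno(params: MizunoParams, t):
    """Relative activity of the three-exponential mixture at time(s) ``t``."""
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("t must be >= 0")
    out = sum(
        m * np.exp(-lam * tt) for m, lam in zip(params.fractions, params.lambdas)
    )
    return float(out) if np.isscalar(t) or tt.ndim == 0 else out


def physical_decay_factor(t, isotope: IsotopeSpec):
    """Radioactive-decay factor exp(-ln2 * t / T_1/2) at time(s) ``t``."""
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("t must be >= 0")
    out = np.exp(-isotope.lambda_phys * tt)
    return float(out) if np.isscalar(t) or tt.ndim == 0 else out


def frame_averaged_exp(lmbda: float, t_start, duration):
    """Time-average of exp(-lambda t) over frames [t_start, t_start + duration].

    This is the exact closed form

        exp(-lambda t0) * (1 - exp(-lambda dt)) / (lambda dt)

    evaluated stably (via expm1) and continuously extended to 1 at
    ``lambda = 0``.  It is the quantity a scanner histogramming counts
    into a frame actually records, up to the amplitude.
    """
    if lmbda < 0:
        raise ValueError("lambda must be >= 0")
    t0 = np.asarray(t_start, dtype=float)
    dt = np.asarray(duration, dtype=float)
    if np.any(dt <= 0):
        raise ValueError("frame durations must be > 0")
    if lmbda == 0.0:
        out = np.ones_like(t0)
    else:
        x = lmbda * dt
        out = np.exp(-lmbda * t0) * (-np.expm1(-x)) / x
    if np.isscalar(t_start) and np.isscalar(duration):
        return float(out)
    return out
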