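"""Exponential washout estimation and the alive/dead decomposition.

The estimation layer follows the model/results idiom: a model object is
built from a :class:`~petwashout.tac.TimeActivityCurve`, its ``fit()``
returns a results object carrying point estimates, standard errors,
diagnostics and a ``summary()`` table.

Three estimators are provided:

* :class:`ExponentialDecayModel` — single-exponential decay
  ``A * exp(-lambda t)``, the default model for both the tissular and
  the combined alive-condition decay;
* :class:`MultiExponentialModel` — the constrained fast/medium/slow
  mixture (up to three components, fractions on the simplex, ordered
  decay constants), fitted by variable projection;
* :class:`AliveDeadDecomposition` — combines the alive- and
  dead-condition fits into tissular and washout decay constants.  In
  subtraction mode (default) the alive decay constant is the SUM of the
  tissular and washout constants, so lambda_wash = lambda_alive -
  lambda_dead; direct mode reads the alive constant as the washout
  constant itself.

All models predict FRAME-AVERAGED values (the time-average of the decay
curve over each frame) whenever the TAC carries frame durations, which
removes the O((lambda*dt)^2) midpoint bias on long frames; and when the
TAC was decay-corrected with frame-averaged physical factors the model
reproduces that correction exactly, so noiseless recovery is limited
only by optimizer precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, nnls

from .kinetics import (
    LN2,
    MizunoParams,
    frame_averaged_exp,
    lambda_to_halflife,
)
from .tac import TimeActivityCurve

__all__ = [
    "ExponentialDecayModel",
    "ExponentialFitResult",
    "MultiExponentialModel",
    "MizunoFitResult",
    "AliveDeadDecomposition",
    "DecompositionResult",
    "GroupSummary",
    "fit_single_exponential",
    "fit_mizuno",
    "decompose",
    "summarize_group",
]


def _model_context(tac: TimeActivityCurve) -> dict:
    """Resolve how the model must mirror the TAC's correction chain."""
    prov = tac.provenance or {}
    return {
        "frame_averaged": tac.frame_durations is not None,
        "physical_lambda": prov.get("physical_lambda"),
        "physical_in_data": prov.get(
            "physical_decay_in_data", not tac.decay_corrected
        ),
        "correction": prov.get("correction", "none"),
        "decay_corrected": tac.decay_corrected,
    }


def _decay_basis(lam: float, tac: TimeActivityCurve, idx: np.ndarray, ctx: dict):
    """Unit-amplitude predicted frame values for decay constant ``lam``.

    Frame-averaged when durations are known, point-evaluated otherwise;
    includes the known physical-decay factor when it is still present in
    the data, and reproduces the frame-averaged correction ratio when
    the data were corrected that way.
    """
    p = ctx["physical_lambda"]
    if ctx["frame_averaged"]:
        t0 = tac.frame_starts[idx]
        dt = tac.frame_durations[idx]
        if ctx["physical_in_data"] and p:
            return frame_averaged_exp(lam + p, t0, dt)
        if ctx["decay_corrected"] and ctx["correction"] == "frame_average" and p:
            return frame_averaged_exp(lam + p, t0, dt) / frame_averaged_exp(p, t0, dt)
        return frame_averaged_exp(lam, t0, dt)
    t = tac.times[idx]
    if ctx["physical_in_data"] and p:
        return np.exp(-(lam + p) * t)
    return np.exp(-lam * t)


def _select_window(tac: TimeActivityCurve, window) -> np.ndarray:
    t_min, t_max = (None, None) if window is None else window
    lo = -np.inf if t_min is None else t_min
    hi = np.inf if t_max is None else t_max
    return np.flatnonzero((tac.times >= lo) & (tac.times <= hi))


def _loglinear_init(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Amplitude/decay-constant starting values from log-linear regression."""
    pos = y > 0
    if pos.sum() < 2:
        return float(max(y.max(), 1.0)), 0.0
    slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
    return float(np.exp(intercept)), float(max(-slope, 0.0))


@dataclass
class ExponentialFitResult:
    """Estimates and diagnostics of a single-exponential decay fit."""

    amplitude_hat: float  # Bq
    lambda_hat: float  # 1/s
    stderr_amplitude: float
    stderr_lambda: float
    fit_window: tuple[float, float]
    n_points: int
    residual_rms: float
    converged: bool
    cov: np.ndarray | None = None

    @property
    def halflife_hat(self) -> float:
        """ln2 / lambda_hat; infinite when no decay was detected."""
        return lambda_to_halflife(max(self.lambda_hat, 0.0))

    @property
    def stderr_halflife(self) -> float:
        """Delta-method standard error of the half-life."""
        if self.lambda_hat <= 0 or not math.isfinite(self.stderr_lambda):
            return math.inf
        return LN2 * self.stderr_lambda / self.lambda_hat**2

    def summary(self) -> str:
        lines = [
            "Single-exponential decay fit",
            "=" * 44,
            f"{'n frames':<24}{self.n_points:>20d}",
            f"{'fit window [s]':<24}{self.fit_window[0]:>9.1f} .. {self.fit_window[1]:>8.1f}",
            f"{'converged':<24}{str(self.converged):>20}",
            f"{'residual RMS':<24}{self.residual_rms:>20.6g}",
            "-" * 44,
            f"{'amplitude [Bq]':<24}{self.amplitude_hat:>12.5g} ± {self.stderr_amplitude:.3g}",
            f"{'lambda [1/s]':<24}{self.lambda_hat:>12.6g} ± {self.stderr_lambda:.3g}",
            f"{'half-life [s]':<24}{self.halflife_hat:>12.6g} ± {self.stderr_halflife:.3g}",
        ]
        return "\n".join(lines)


class ExponentialDecayModel:
    """Least-squares single-exponential model ``A * exp(-lambda t)`` for a TAC.

    Parameters
    ----------
    tac : TimeActivityCurve
        The curve to fit; its provenance determines whether predictions
        are frame-averaged and how physical decay enters the model.
    window : (t_min, t_max) or None
        Restrict the fit to frames whose mid-times lie in the window.
        Useful for excluding early transients (e.g. the pressure
        re-equilibration seen in dead tumor tissue around 500 s).
    weighting : {"none", "poisson"}
        Unweighted least squares (default) or inverse-variance weights
        with variance proportional to the signal.
    """

    def __init__(
        self,
        tac: TimeActivityCurve,
        window: tuple[float | None, float | None] | None = None,
        weighting: str = "none",
    ) -> None:
        if weighting not in ("none", "poisson"):
            raise ValueError("weighting must be 'none' or 'poisson'")
        self.tac = tac
        self.window = window
        self.weighting = weighting
        self._ctx = _model_context(tac)
        self._idx = _select_window(tac, window)
        y = tac.values[self._idx]
        if (y > 0).sum() < 3:
            raise ValueError(
                f"need at least 3 frames with positive values in the window, "
                f"got {(y > 0).sum()}"
            )

    def predict(self, amplitude: float, lam: float) -> np.ndarray:
        return amplitude * _decay_basis(lam, self.tac, self._idx, self._ctx)

    def fit(self) -> ExponentialFitResult:
        idx = self._idx
        t = self.tac.times[idx]
        y = self.tac.values[idx]
        if self.weighting == "poisson":
            sig = np.sqrt(np.maximum(y, np.max(y) * 1e-12))
        else:
            sig = np.ones_like(y)

        a0, l0 = _loglinear_init(t, y)

        def residuals(p):
            return (self.predict(p[0], p[1]) - y) / sig

        res = least_squares(
            residuals,
            x0=[a0, l0],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            x_scale=[max(a0, 1e-30), max(l0, 1e-6)],
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )
        a_hat, l_hat = res.x
        # decay below numerical resolution over the whole window is no decay
        if l_hat * (t.max() - t.min()) < 1e-12:
            l_hat = 0.0
        r = self.predict(a_hat, l_hat) - y
        n = len(y)
        dof = n - 2
        se = (math.inf, math.inf)
        cov = None
        if dof > 0:
            jtj = res.jac.T @ res.jac
            try:
                cov = np.linalg.inv(jtj) * (res.fun @ res.fun) / dof
                se = tuple(np.sqrt(np.maximum(np.diag(cov), 0.0)))
            except np.linalg.LinAlgError:
                pass
        return ExponentialFitResult(
            amplitude_hat=float(a_hat),
            lambda_hat=float(l_hat),
            stderr_amplitude=float(se[0]),
            stderr_lambda=float(se[1]),
            fit_window=(float(t.min()), float(t.max())),
            n_points=n,
            residual_rms=float(np.sqrt(np.mean(r**2))),
            converged=bool(res.success and np.all(np.isfinite(res.x))),
        )


def fit_single_exponential(
    tac: TimeActivityCurve,
    window: tuple[float | None, float | None] | None = None,
    weighting: str = "none",
) -> ExponentialFitResult:
    """Fit ``A * exp(-lambda t)`` to a TAC (thin wrapper over the model class)."""
    return ExponentialDecayModel(tac, window=window, weighting=weighting).fit()


@dataclass
class MizunoFitResult:
    """Fit of the constrained multi-exponential washout mixture."""

    params: MizunoParams
    amplitude_hat: float
    n_components: int
    n_points: int
    residual_rms: float
    converged: bool
    collapsed: bool  # components merged or vanished during the fit
    lambda_gap: float  # smallest ratio between consecutive active lambdas

    @property
    def halflives(self) -> tuple[float, float, float]:
        return tuple(lambda_to_halflife(l) for l in self.params.lambdas)

    def summary(self) -> str:
        lines = [
            f"Multi-exponential washout fit ({self.n_components} component(s))",
            "=" * 52,
            f"{'n frames':<22}{self.n_points:>10d}",
            f"{'amplitude [Bq]':<22}{self.amplitude_hat:>14.6g}",
            f"{'residual RMS':<22}{self.residual_rms:>14.6g}",
            f"{'converged':<22}{str(self.converged):>10}"
            + ("   [components collapsed]" if self.collapsed else ""),
            "-" * 52,
            f"{'component':<10}{'fraction':>12}{'lambda [1/s]':>16}{'T1/2 [s]':>13}",
        ]
        for name, m, lam in zip(
            ("fast", "medium", "slow"), self.params.fractions, self.params.lambdas
        ):
            lines.append(
                f"{name:<10}{m:>12.5f}{lam:>16.6g}{lambda_to_halflife(lam):>13.6g}"
            )
        return "\n".join(lines)


class MultiExponentialModel:
    """Constrained mixture of up to three exponentials for a TAC.

    Fractions are non-negative and sum to one by construction (variable
    projection: the amplitudes are solved by non-negative least squares
    at every step and renormalised into an overall amplitude times
    simplex fractions); decay constants are returned in fast >= medium
    >= slow order.  With one component the problem is identical to
    :class:`ExponentialDecayModel` and is delegated to it.
    """

    def __init__(
        self,
        tac: TimeActivityCurve,
        n_components: int = 3,
        window: tuple[float | None, float | None] | None = None,
    ) -> None:
        if not (1 <= n_components <= 3):
            raise ValueError("n_components must be 1, 2 or 3")
        self.tac = tac
        self.n_components = n_components
        self.window = window
        self._ctx = _model_context(tac)
        self._idx = _select_window(tac, window)
        if len(self._idx) < 2 * n_components + 1:
            raise ValueError(
                f"need at least {2 * n_components + 1} frames for "
                f"{n_components} component(s), got {len(self._idx)}"
            )

    def _design(self, lambdas: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [_decay_basis(l, self.tac, self._idx, self._ctx) for l in lambdas]
        )

    def fit(self) -> MizunoFitResult:
        if self.n_components == 1:
            r = ExponentialDecayModel(self.tac, window=self.window).fit()
            return MizunoFitResult(
                params=MizunoParams((1.0, 0.0, 0.0), (r.lambda_hat, 0.0, 0.0)),
                amplitude_hat=r.amplitude_hat,
                n_components=1,
                n_points=r.n_points,
                residual_rms=r.residual_rms,
                converged=r.converged,
                collapsed=False,
                lambda_gap=math.inf,
            )

        t = self.tac.times[self._idx]
        y = self.tac.values[self._idx]
        _, l_ll = _loglinear_init(t, y)
        l_ll = max(l_ll, 1e-3 / max(t.max(), 1.0))
        n = self.n_components

        def residuals(v):
            U = self._design(np.exp(v))
            c, _ = nnls(U, y)
            return U @ c - y

        # deterministic multi-start: decade spreads around the log-linear slope
        spreads = [math.sqrt(10.0), 10.0, 10.0 ** (1.0 / 3.0)]
        centres = [1.0, 0.3, 3.0]
        best = None
        for spread in spreads:
            for centre in centres:
                lam0 = centre * l_ll * spread ** (np.arange(n) - (n - 1) / 2.0)[::-1]
                res = least_squares(
                    residuals, x0=np.log(lam0), xtol=1e-14, ftol=1e-14, gtol=1e-14
                )
                if best is None or res.cost < best.cost - 1e-30:
                    best = res

        lambdas = np.exp(best.x)
        U = self._design(lambdas)
        c, _ = nnls(U, y)
        r = U @ c - y

        order = np.argsort(lambdas)[::-1]
        lambdas, c = lambdas[order], c[order]
        # merge near-identical components: ordering alone cannot separate them
        collapsed = bool(np.any(c == 0.0))
        merged_l, merged_c = [lambdas[0]], [c[0]]
        for lam, ci in zip(lambdas[1:], c[1:]):
            if merged_l[-1] > 0 and lam / merged_l[-1] > 0.999:
                merged_c[-1] += ci
                collapsed = True
            else:
                merged_l.append(lam)
                merged_c.append(ci)
        while len(merged_l) < 3:
            merged_l.append(0.0)
            merged_c.append(0.0)

        total = sum(merged_c)
        if total <= 0:
            raise RuntimeError("multi-exponential fit found zero total amplitude")
        fractions = tuple(ci / total for ci in merged_c)
        active = [l for l, m in zip(merged_l, fractions) if m > 0 and l > 0]
        gaps = [hi / lo for hi, lo in zip(active[:-1], active[1:]) if lo > 0]
        return MizunoFitResult(
            params=MizunoParams(fractions, tuple(merged_l)),
            amplitude_hat=float(total),
            n_components=n,
            n_points=len(y),
            residual_rms=float(np.sqrt(np.mean(r**2))),
            converged=bool(best.success),
            collapsed=collapsed,
            lambda_gap=float(min(gaps)) if gaps else math.inf,
        )


def fit_mizuno(
    tac: TimeActivityCurve,
    n_components: int = 3,
    window: tuple[float | None, float | None] | None = None,
) -> MizunoFitResult:
    """Fit the constrained multi-exponential mixture (wrapper over the model)."""
    return MultiExponentialModel(tac, n_components=n_components, window=window).fit()


@dataclass
class DecompositionResult:
    """Tissular/washout decomposition from paired alive and dead fits."""

    lambda_tiss_hat: float
    lambda_alive_hat: float
    lambda_wash_hat: float
    stderr_wash: float
    mode: str
    no_detectable_washout: bool
    fit_alive: ExponentialFitResult
    fit_dead: ExponentialFitResult

    @property
    def halflife_tiss(self) -> float:
        return lambda_to_halflife(self.lambda_tiss_hat)

    @property
    def halflife_wash(self) -> float:
        if self.no_detectable_washout:
            return math.inf
        return lambda_to_halflife(self.lambda_wash_hat)

    @property
    def halflife_alive(self) -> float:
        return lambda_to_halflife(self.lambda_alive_hat)

    def summary(self) -> str:
        flag = "  [no detectable washout]" if self.no_detectable_washout else ""
        return "\n".join(
            [
                f"Alive/dead washout decomposition (mode: {self.mode}){flag}",
                "=" * 56,
                f"{'component':<12}{'lambda [1/s]':>16}{'half-life [s]':>16}",
                f"{'tissular':<12}{self.lambda_tiss_hat:>16.6g}{self.halflife_tiss:>16.6g}",
                f"{'alive total':<12}{self.lambda_alive_hat:>16.6g}{self.halflife_alive:>16.6g}",
                f"{'washout':<12}{self.lambda_wash_hat:>16.6g}{self.halflife_wash:>16.6g}",
            ]
        )


class AliveDeadDecomposition:
    """Combine alive- and dead-condition fits into the two components.

    The dead acquisition has no perfusion, so its decay constant is the
    tissular one.  In ``subtraction`` mode (default) the alive decay
    constant is the sum of the two components and the washout constant
    is the difference; in ``direct`` mode the alive constant is reported
    as the washout constant unchanged.
    """

    def __init__(
        self,
        fit_alive: ExponentialFitResult,
        fit_dead: ExponentialFitResult,
        mode: str = "subtraction",
    ) -> None:
        if mode not in ("subtraction", "direct"):
            raise ValueError("mode must be 'subtraction' or 'direct'")
        if not (fit_alive.converged and fit_dead.converged):
            raise ValueError("both condition fits must have converged")
        self.fit_alive = fit_alive
        self.fit_dead = fit_dead
        self.mode = mode

    def fit(self) -> DecompositionResult:
        la = self.fit_alive.lambda_hat
        ld = self.fit_dead.lambda_hat
        if self.mode == "direct":
            lw = la
            se = self.fit_alive.stderr_lambda
            flag = lw <= 0
        else:
            lw = la - ld
            se = math.hypot(self.fit_alive.stderr_lambda, self.fit_dead.stderr_lambda)
            flag = lw <= 0
        return DecompositionResult(
            lambda_tiss_hat=ld,
            lambda_alive_hat=la,
            lambda_wash_hat=max(lw, 0.0) if flag else lw,
            stderr_wash=se,
            mode=self.mode,
            no_detectable_washout=bool(flag),
            fit_alive=self.fit_alive,
            fit_dead=self.fit_dead,
        )


def decompose(
    fit_alive: ExponentialFitResult,
    fit_dead: ExponentialFitResult,
    mode: str = "subtraction",
) -> DecompositionResult:
    """Tissular/washout decomposition (wrapper over AliveDeadDecomposition)."""
    return AliveDeadDecomposition(fit_alive, fit_dead, mode=mode).fit()


@dataclass
class GroupSummary:
    """Across-animal mean ± SD of a half-life for one tissue and component."""

    tissue: str
    component: str  # "tissular" or "washout"
    n: int
    mean_halflife: float  # s
    sd_halflife: float  # s; 0 by convention when n = 1

    def __str__(self) -> str:
        note = "  (single animal)" if self.n == 1 else ""
        return (
            f"{self.tissue} {self.component}: "
            f"{self.mean_halflife:.0f} ± {self.sd_halflife:.0f} s (n={self.n}){note}"
        )


def summarize_group(
    halflives, tissue: str, component: str
) -> GroupSummary:
    """Arithmetic mean and sample SD (n-1 denominator) of per-animal half-lives."""
    h = np.asarray(list(halflives), dtype=float)
    if h.size == 0:
        raise ValueError("cannot summarize an empty group")
    sd = float(np.std(h, ddof=1)) if h.size > 1 else 0.0
    return GroupSummary(
        tissue=tissue,
        component=component,
        n=int(h.size),
        mean_halflife=float(np.mean(h)),
        sd_halflife=sd,
    )
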