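"""Hill-equation fitting of dose-response (thermophoresis-style) data.

The model is the four-parameter Hill isotherm

    signal(c) = baseline + amplitude * c^n / (kd^n + c^n)

fit by nonlinear least squares with multi-start initialization of kd over
the measured concentration range.  kd is optimized on a log scale for
conditioning, which also makes the fit exactly scale-equivariant: scaling
every concentration by s scales the fitted kd by s.  Uncertainty comes
from a case-resampling bootstrap (percentile interval); the Hill
coefficient is free but bounded to [0.5, 3] unless fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DoseResponse",
    "HillFit",
    "fit_hill",
    "bootstrap_ci",
    "compare_conditions",
]


@dataclass
class DoseResponse:
    """Concentration-signal table; concentrations in uM, strictly
    monotone (a titration series)."""

    conc_uM: np.ndarray
    signal: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.conc_uM = np.asarray(self.conc_uM, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.conc_uM.shape != self.signal.shape or self.conc_uM.ndim != 1:
            raise ValueError("conc_uM and signal must be 1-D arrays of equal length")
        if len(self.conc_uM) < 6:
            raise ValueError("need at least 6 titration points")
        if np.any(self.conc_uM <= 0):
            raise ValueError("concentrations must be strictly positive")
        d = np.diff(self.conc_uM)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("concentrations must be strictly monotone")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"conc_uM": self.conc_uM, "signal": self.signal, "condition": self.condition}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, condition: str | None = None) -> "DoseResponse":
        if condition is not None:
            df = df[df["condition"] == condition]
        df = df.sort_values("conc_uM", ascending=False)
        return cls(
            conc_uM=df["conc_uM"].to_numpy(),
            signal=df["signal"].to_numpy(),
            condition=condition or (df["condition"].iloc[0] if "condition" in df else ""),
        )


@dataclass
class HillFit:
    kd: float                       # uM
    hill_n: float
    amplitude: float
    baseline: float
    rss: float
    condition: str = ""
    kd_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("fitted kd must be positive")
        if self.rss < 0:
            raise ValueError("rss must be non-negative")
        if self.kd_ci is not None and not (
            self.kd_ci[0] <= self.kd <= self.kd_ci[1]
        ):
            raise ValueError("kd_ci must contain kd")


def _hill(c: np.ndarray, log_kd: float, n: float, amp: float, base: float) -> np.ndarray:
    kd = np.exp(log_kd)
    cn = c**n
    return base + amp * cn / (kd**n + cn)


_N_BOUNDS = (0.5, 3.0)


class _Packer:
    """Maps between the full (log_kd, n, amp, base) parameter vector and
    the reduced vector of free parameters."""

    def __init__(self, fix_n, fix_amp, fix_base, span, base0, c):
        self.fix = (None, fix_n, fix_amp, fix_base)
        lo_kd, hi_kd = np.log(c.min()) - 8.0, np.log(c.max()) + 8.0
        self._bounds = [
            (lo_kd, hi_kd),
            _N_BOUNDS,
            (-10 * span, 10 * span),
            (base0 - 5 * span, base0 + 5 * span),
        ]

    def pack(self, log_kd, n, amp, base):
        full = (log_kd, n, amp, base)
        return np.array([v for v, f in zip(full, self.fix) if f is None])

    def unpack(self, p):
        out, i = [], 0
        for f in self.fix:
            if f is None:
                out.append(p[i])
                i += 1
            else:
                out.append(f)
        return tuple(out)

    def bounds(self):
        lo = [b[0] for b, f in zip(self._bounds, self.fix) if f is None]
        hi = [b[1] for b, f in zip(self._bounds, self.fix) if f is None]
        return (lo, hi)


def fit_hill(
    data: DoseResponse,
    fix_n: float | None = None,
    fix_amplitude: float | None = None,
    fix_baseline: float | None = None,
    n_starts: int = 12,
    start_params: Sequence[float] | None = None,
) -> HillFit:
    """Least-squares Hill fit with a log-spaced kd start grid spanning the
    concentration range.  Deterministic for fixed data and starts.

    ``fix_n`` pins the Hill coefficient (e.g. 1 for single-site binding);
    otherwise n is free within [0.5, 3].  ``fix_amplitude``/``fix_baseline``
    pin the span of the isotherm — the natural protocol for data that are
    already normalized to fraction bound, where the Hill equation proper
    s = c^n/(kd^n + c^n) has no amplitude or offset freedom.  Raises on
    degenerate flat data or if no start converges; warns when the data do
    not bracket the fitted kd (poor dynamic range).
    """
    c, y = data.conc_uM, data.signal
    span = float(np.ptp(y))
    if span < 1e-12:
        raise ValueError("degenerate flat dose-response data")

    amp0 = span
    base0 = float(np.min(y))
    starts = np.log(np.geomspace(c.min(), c.max(), n_starts))
    packer = _Packer(fix_n, fix_amplitude, fix_baseline, span, base0, c)

    def residuals(p: np.ndarray) -> np.ndarray:
        log_kd, n, amp, base = packer.unpack(p)
        return _hill(c, log_kd, n, amp, base) - y

    bounds = packer.bounds()
    candidates: list[np.ndarray] = []
    if start_params is not None:
        candidates.append(np.asarray(start_params, dtype=float))
    for log_kd0 in starts:
        candidates.append(packer.pack(log_kd0, 1.0, amp0, base0))

    best = None
    for p0 in candidates:
        p0 = np.clip(p0, bounds[0], bounds[1])
        try:
            res = least_squares(residuals, p0, bounds=bounds, method="trf")
        except Exception:
            continue
        if not res.success:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0] - 1e-15:
            best = (rss, res.x)
    if best is None:
        raise RuntimeError("Hill fit did not converge from any start")

    rss, p = best
    log_kd, n, amp, base = packer.unpack(p)
    kd = float(np.exp(log_kd))
    if not (c.min() <= kd <= c.max()):
        warnings.warn(
            f"fitted kd {kd:.3g} uM lies outside the measured concentration "
            "range; the titration lacks dynamic range around kd",
            stacklevel=2,
        )
    return HillFit(
        kd=kd,
        hill_n=float(n),
        amplitude=float(amp),
        baseline=float(base),
        rss=rss,
        condition=data.condition,
    )


def bootstrap_ci(
    data: DoseResponse,
    fix_n: float | None = None,
    fix_amplitude: float | None = None,
    fix_baseline: float | None = None,
    n_boot: int = 500,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Case-resampling bootstrap percentile interval for kd (uM).

    Fails if more than 20% of resamples fail to fit (a sign the data
    cannot support the model).
    """
    rng = np.random.default_rng(seed)
    fit0 = fit_hill(
        data, fix_n=fix_n, fix_amplitude=fix_amplitude, fix_baseline=fix_baseline
    )
    packer = _Packer(
        fix_n, fix_amplitude, fix_baseline,
        float(np.ptp(data.signal)), float(np.min(data.signal)), data.conc_uM,
    )
    p0 = packer.pack(np.log(fit0.kd), fit0.hill_n, fit0.amplitude, fit0.baseline)
    kds: list[float] = []
    failures = 0
    n = len(data.conc_uM)
    for _ in range(n_boot):
        idx = np.sort(rng.integers(0, n, size=n))[::-1]
        # resampled points, kept in decreasing-concentration order; drop
        # duplicates' monotonicity requirement by fitting raw arrays
        c = data.conc_uM[idx]
        y = data.signal[idx]
        try:
            fit = _fit_raw(
                c, y, fix_n=fix_n, start_params=p0,
                fix_amplitude=fix_amplitude, fix_baseline=fix_baseline,
            )
            kds.append(fit[0])
        except Exception:
            failures += 1
    if failures > 0.2 * n_boot:
        raise RuntimeError(
            f"bootstrap failed: {failures}/{n_boot} resamples did not fit"
        )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(kds, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _fit_raw(
    c: np.ndarray,
    y: np.ndarray,
    fix_n: float | None,
    start_params: Sequence[float],
    fix_amplitude: float | None = None,
    fix_baseline: float | None = None,
) -> tuple[float, float, float, float]:
    """Single-start Hill fit on raw arrays (bootstrap inner loop)."""
    span = float(np.ptp(y))
    if span < 1e-12:
        raise ValueError("flat resample")
    packer = _Packer(fix_n, fix_amplitude, fix_baseline, span, float(np.min(y)), c)

    def residuals(p: np.ndarray) -> np.ndarray:
        log_kd, n, amp, base = packer.unpack(p)
        return _hill(c, log_kd, n, amp, base) - y

    bounds = packer.bounds()
    p0 = np.clip(np.asarray(start_params, dtype=float), bounds[0], bounds[1])
    res = least_squares(residuals, p0, bounds=bounds, method="trf")
    if not res.success:
        raise RuntimeError("no convergence")
    log_kd, n, amp, base = packer.unpack(res.x)
    return float(np.exp(log_kd)), float(n), float(amp), float(base)


def compare_conditions(fits: Sequence[HillFit]) -> pd.DataFrame:
    """Pairwise kd fold changes between fitted conditions.

    The ratio interval, when both fits carry bootstrap intervals, is the
    conservative quotient propagation (lo_a/hi_b, hi_a/lo_b).
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    rows = []
    for fa in fits:
        for fb in fits:
            if fa is fb:
                continue
            ratio = fa.kd / fb.kd
            if fa.kd_ci is not None and fb.kd_ci is not None:
                ci = (fa.kd_ci[0] / fb.kd_ci[1], fa.kd_ci[1] / fb.kd_ci[0])
            else:
                ci = (np.nan, np.nan)
            rows.append(
                {
                    "condition_a": fa.condition,
                    "condition_b": fb.condition,
                    "kd_a_uM": fa.kd,
                    "kd_b_uM": fb.kd,
                    "fold_change": ratio,
                    "fold_lo": ci[0],
                    "fold_hi": ci[1],
                }
            )
    return pd.DataFrame(rows)
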