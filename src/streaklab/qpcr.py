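"""Kinetic qPCR quantification with the MAK2 amplification model.

MAK2 describes amplification mechanistically by the recurrence

    D_n = D_{n-1} + k · ln(1 + D_{n-1}/k),      F_n = Fb + s · D_n

where ``D0`` is the initial target amount, ``k`` the kinetic constant
governing the exponential-to-plateau transition, ``Fb`` the baseline
fluorescence and ``s`` the fluorescence yield per unit product. In the
low-template limit D ≪ k each cycle doubles the product (ln(1+x) ≈ x);
as D approaches k the per-cycle gain saturates.

The per-reaction fit estimates ``D0`` (and ``k``, ``Fb``) by nonlinear
least squares over the pre-plateau cycles. Because F is invariant under
(D0, k, s) → (c·D0, c·k, s/c), the fit fixes ``s = 1`` and reports D0 in
fluorescence units — the convention under which MAK2 quantification is
relative, exactly what downstream reference-gene normalisation needs.
Technical replicates are averaged and target genes normalised to a
reference gene (GAPDH in the study) with standard errors propagated in
quadrature.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "MAK2Params",
    "QPCRCurve",
    "ReplicateSummary",
    "NoAmplificationError",
    "FitError",
    "mak2_forward",
    "fit_mak2",
    "average_replicates",
    "normalize_to_reference",
]


class NoAmplificationError(RuntimeError):
    """The curve shows no rise above baseline noise; nothing to fit."""


class FitError(RuntimeError):
    """The nonlinear fit failed to converge or lacked usable cycles."""


@dataclass(frozen=True)
class MAK2Params:
    """MAK2 model parameters; D0 and k share units (AFU-equivalent)."""

    d0: float
    k: float
    fb: float = 0.0
    s: float = 1.0

    def __post_init__(self):
        if self.d0 < 0:
            raise ValueError(f"d0 must be >= 0, got {self.d0!r}")
        if self.k <= 0:
            raise ValueError(f"k must be > 0, got {self.k!r}")
        if self.s <= 0:
            raise ValueError(f"s must be > 0, got {self.s!r}")


@dataclass
class QPCRCurve:
    """Per-cycle fluorescence of one reaction."""

    cycles: np.ndarray
    fluorescence: np.ndarray
    gene: str = ""
    sample: str = ""
    replicate: int = 0

    def __post_init__(self):
        self.cycles = np.asarray(self.cycles, dtype=int)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if len(self.cycles) != len(self.fluorescence):
            raise ValueError("cycles and fluorescence must have equal length")
        if len(self.cycles) < 5:
            raise ValueError("a curve needs at least 5 cycles")
        if not np.isfinite(self.fluorescence).all():
            raise ValueError("fluorescence must be finite")

    def replace(self, **changes) -> "QPCRCurve":
        return dataclasses.replace(self, **changes)


def _mak2_d(d0: float, k: float, n_cycles: int) -> np.ndarray:
    d = np.empty(n_cycles)
    cur = d0
    for i in range(n_cycles):
        cur = cur + k * np.log1p(cur / k)
        d[i] = cur
    return d


def mak2_forward(params: MAK2Params, n_cycles: int) -> QPCRCurve:
    """Evaluate the MAK2 recurrence for cycles 1..n_cycles."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    d = _mak2_d(params.d0, params.k, n_cycles)
    f = params.fb + params.s * d
    return QPCRCurve(np.arange(1, n_cycles + 1), f)


def fit_mak2(curve: QPCRCurve, cutoff_frac: float = 0.85,
             n_starts: int = 8) -> tuple[MAK2Params, dict]:
    """Fit (D0, k, Fb) to one amplification curve by least squares.

    The fit window runs from cycle 1 to the last cycle before the
    fluorescence exceeds baseline + ``cutoff_frac`` of the total rise
    (default 85%), excluding the plateau where MAK2's assumptions break
    down. D0 is multi-started over a log-spaced grid of D0/k ratios; the
    best residual wins, ties broken towards the smaller D0.

    Returns the fitted parameters (with ``s`` fixed at 1, i.e. D0 in
    fluorescence units) and a diagnostics dict.
    """
    f = curve.fluorescence
    fb0 = float(np.median(f[:5]))
    rise = float(f.max() - fb0)
    noise = float(np.std(np.diff(f[:5]))) / np.sqrt(2.0)
    floor = max(5.0 * noise, 1e-6 * max(abs(fb0), 1.0))
    if rise <= floor:
        raise NoAmplificationError(
            f"total rise {rise:.3g} below noise floor {floor:.3g}")
    above = f > fb0 + cutoff_frac * rise
    cutoff = int(np.argmax(above)) if above.any() else len(f)
    if cutoff < 8:
        raise FitError(
            f"only {cutoff} pre-plateau cycles; need >= 8 for a stable fit")
    ff = f[:cutoff]
    n = cutoff
    k0 = max(rise / 3.0, 1e-12)

    def resid(p):
        ld0, lk, fb = p
        return fb + _mak2_d(np.exp(ld0), np.exp(lk), n) - ff

    best = None
    for ratio in np.logspace(-8, -1, n_starts):
        p0 = np.array([np.log(k0 * ratio), np.log(k0), fb0])
        try:
            sol = least_squares(resid, p0, method="lm",
                                xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                max_nfev=2000)
        except Exception:
            continue
        if not np.isfinite(sol.cost):
            continue
        cand = (sol.cost, np.exp(sol.x[0]), sol)
        if best is None or cand[0] < best[0] * (1 - 1e-12) or (
                abs(cand[0] - best[0]) <= 1e-12 * max(best[0], 1e-300)
                and cand[1] < best[1]):
            best = cand
    if best is None:
        raise FitError("no multi-start converged")
    cost, d0, sol = best
    params = MAK2Params(d0=float(d0), k=float(np.exp(sol.x[1])),
                        fb=float(sol.x[2]), s=1.0)
    diag = {"cost": float(cost), "cutoff_cycle": cutoff,
            "residual_norm": float(np.sqrt(2.0 * cost)),
            "n_starts": n_starts, "success": bool(sol.success)}
    return params, diag


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean ± standard error over technical replicates."""

    mean: float
    se: float
    n: int

    @property
    def se_defined(self) -> bool:
        return self.n >= 2


def average_replicates(d0_values) -> ReplicateSummary:
    """Arithmetic mean and SE = sd/√n of replicate D0 estimates.

    A singleton yields its value with an undefined (NaN) standard error.
    """
    vals = np.asarray(list(d0_values), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one replicate")
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size >= 2 else float("nan")
    return ReplicateSummary(mean=mean, se=se, n=int(vals.size))


def normalize_to_reference(target: ReplicateSummary,
                           reference: ReplicateSummary) -> ReplicateSummary:
    """Ratio target/reference with the SE propagated in quadrature.

    SE_ratio = ratio · sqrt((SE_t/μ_t)² + (SE_r/μ_r)²).
    """
    if reference.mean <= 0:
        raise ValueError(f"reference mean must be > 0, got {reference.mean!r}")
    ratio = target.mean / reference.mean
    se = abs(ratio) * np.sqrt((target.se / target.mean) ** 2
                              + (reference.se / reference.mean) ** 2)
    return ReplicateSummary(mean=float(ratio), se=float(se),
                            n=min(target.n, reference.n))
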