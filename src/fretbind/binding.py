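"""Equilibrium binding: Kd fitting from dot-blot isotherms and
cross-condition comparisons.

The default isotherm model accounts for ligand depletion: the labeled target
is held at 0.1 nM, comparable to the sub-nanomolar Kd values of interest, so
free protein is not total protein and the hyperbolic (Langmuir) form would
overestimate Kd.  The quadratic mass-balance solution is exact for a
single site:

    bound/R = bmax * ((P + R + Kd) - sqrt((P + R + Kd)^2 - 4 P R)) / (2 R)

with P total protein, R total receptor (labeled target).  The hyperbolic
model bmax * P / (P + Kd) is offered for comparison and as the R -> 0 limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .simulate import (
    IsothermDataset,
    fraction_bound_depletion,
    fraction_bound_hyperbolic,
)

__all__ = [
    "BindingIsothermFit",
    "FoldChange",
    "TTestResult",
    "fit_isotherm",
    "fold_change",
    "compare_kd",
]


@dataclass
class BindingIsothermFit:
    """Fitted dissociation constant for one condition."""

    condition: str
    kd: float                       # nM
    kd_se: float                    # nM
    bmax: float
    model: str                      # "quadratic" or "hyperbolic"
    r_squared: float
    n_points: int
    replicate_kds: tuple[float, ...] = ()
    success: bool = True
    message: str = ""


@dataclass(frozen=True)
class FoldChange:
    """Affinity fold of condition a over b: Kd_b / Kd_a with first-order SE."""

    fold: float
    fold_se: float
    condition_a: str
    condition_b: str


@dataclass(frozen=True)
class TTestResult:
    """Two-sided unpaired Student's t-test (pooled variance)."""

    t: float
    p: float
    df: int
    mean_a: float
    mean_b: float


def _fit_one(
    conc: np.ndarray,
    fb: np.ndarray,
    model: str,
    receptor_total: float,
    bmax_cap: float,
) -> tuple[float, float, float, float, float]:
    """Fit (kd, bmax) to one pooled or single-replicate curve.

    Returns (kd, kd_se, bmax, bmax_se, r_squared).
    """
    if model == "quadratic":
        def f(p, kd, bmax):
            return fraction_bound_depletion(p, kd, receptor_total, bmax)
    else:
        def f(p, kd, bmax):
            return fraction_bound_hyperbolic(p, kd, bmax)

    # Kd init: concentration at half the apparent plateau
    plateau = max(float(np.max(fb)), 1e-3)
    half = 0.5 * plateau
    above = conc[fb >= half]
    kd0 = float(above.min()) if above.size and above.min() > 0 else max(
        float(np.median(conc[conc > 0])), 1e-3
    )
    popt, pcov = optimize.curve_fit(
        f, conc, fb, p0=[kd0, min(plateau, bmax_cap)],
        bounds=([1e-6, 1e-6], [np.inf, bmax_cap]), maxfev=20000,
    )
    perr = np.sqrt(np.diag(pcov))
    resid = fb - f(conc, *popt)
    ss_tot = float(np.sum((fb - fb.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return float(popt[0]), float(perr[0]), float(popt[1]), float(perr[1]), r2


def fit_isotherm(
    data: IsothermDataset,
    model: str = "quadratic",
    bmax_cap: float = 1.05,
) -> BindingIsothermFit:
    """Fit a single-site binding isotherm and return Kd with uncertainty.

    All replicate points are fit jointly for the headline Kd; when several
    replicates are present each is also fit alone, giving per-replicate Kds
    for downstream t-tests.  ``bmax`` is free but capped (blot transfer
    efficiency may not reach 1).
    """
    if model not in ("quadratic", "hyperbolic"):
        raise ValueError("model must be 'quadratic' or 'hyperbolic'")
    conc = data.concentrations
    if conc.size < 5:
        raise ValueError("need at least 5 concentration points")
    fb_all = data.fraction_bound
    if not np.any(fb_all > 0):
        return BindingIsothermFit(
            condition=data.condition, kd=np.nan, kd_se=np.nan, bmax=np.nan,
            model=model, r_squared=np.nan, n_points=int(fb_all.size),
            success=False, message="degenerate isotherm: fraction bound is zero everywhere",
        )

    conc_pooled = np.tile(conc, data.n_replicates)
    fb_pooled = fb_all.ravel()
    try:
        kd, kd_se, bmax, _, r2 = _fit_one(
            conc_pooled, fb_pooled, model, data.receptor_total, bmax_cap
        )
    except RuntimeError as exc:
        return BindingIsothermFit(
            condition=data.condition, kd=np.nan, kd_se=np.nan, bmax=np.nan,
            model=model, r_squared=np.nan, n_points=int(fb_all.size),
            success=False, message=f"fit did not converge: {exc}",
        )

    rep_kds: list[float] = []
    if data.n_replicates > 1:
        for r in range(data.n_replicates):
            try:
                kd_r, *_ = _fit_one(
                    conc, fb_all[r], model, data.receptor_total, bmax_cap
                )
                rep_kds.append(kd_r)
            except RuntimeError:
                rep_kds.append(np.nan)

    return BindingIsothermFit(
        condition=data.condition,
        kd=kd,
        kd_se=kd_se,
        bmax=bmax,
        model=model,
        r_squared=r2,
        n_points=int(fb_all.size),
        replicate_kds=tuple(rep_kds),
    )


def fold_change(
    fit_a: BindingIsothermFit | float,
    fit_b: BindingIsothermFit | float,
    se_a: float = 0.0,
    se_b: float = 0.0,
) -> FoldChange:
    """Affinity fold of a over b: Kd_b / Kd_a (>1 means a binds tighter).

    Accepts fitted isotherms or bare Kd values; the SE is first-order
    propagated assuming independent errors.
    """
    if isinstance(fit_a, BindingIsothermFit):
        kd_a, se_a, name_a = fit_a.kd, fit_a.kd_se, fit_a.condition
    else:
        kd_a, name_a = float(fit_a), "a"
    if isinstance(fit_b, BindingIsothermFit):
        kd_b, se_b, name_b = fit_b.kd, fit_b.kd_se, fit_b.condition
    else:
        kd_b, name_b = float(fit_b), "b"
    if not (kd_a > 0 and kd_b > 0):
        raise ValueError("both Kd values must be positive")
    fold = kd_b / kd_a
    rel = math.sqrt((se_a / kd_a) ** 2 + (se_b / kd_b) ** 2)
    return FoldChange(
        fold=fold, fold_se=fold * rel, condition_a=name_a, condition_b=name_b
    )


def compare_kd(
    replicate_kds_a: Sequence[float], replicate_kds_b: Sequence[float]
) -> TTestResult:
    """Two-tailed, unpaired Student's t-test on replicate Kd values.

    Classical pooled-variance form: t = (mean_a - mean_b) / (s_p *
    sqrt(1/n_a + 1/n_b)) with s_p^2 the pooled variance on n_a + n_b - 2
    degrees of freedom; p from the t distribution.  Zero variance in both
    groups with equal means gives t = 0, p = 1.
    """
    a = np.asarray(replicate_kds_a, dtype=float)
    b = np.asarray(replicate_kds_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicates per group")
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        t = diff / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), p=p, df=int(df),
                       mean_a=float(a.mean()), mean_b=float(b.mean()))
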