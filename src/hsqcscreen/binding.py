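"""Dissociation-constant fitting and binding classification.

Fits the single-site ligand-depletion isotherm to titration-derived
combined CSPs (globally across residues by default: one shared Kd,
per-residue maximal shifts) and classifies each candidate as a specific
binder, a non-specific binder, or a pH artifact (perturbations restricted
to histidine residues).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .spectra import AssignmentTable
from .synth import SITE1_RESIDUES, SITE2_RESIDUES, TitrationSeries, fraction_bound
from .csp import (
    CSPProfile,
    combined_csp,
    csp_profile,
    significant_residues,
    track_series,
)

__all__ = [
    "KdFit",
    "BindingClass",
    "ValidationSummary",
    "isotherm",
    "fit_kd",
    "classify_binding",
    "validate_candidates",
    "DEFAULT_KD_BOUNDS",
]

#: Kd search bounds, mM (1 μM – 1000 mM: brackets the reported ~1 mM–>10 mM
#: range with wide margin).
DEFAULT_KD_BOUNDS = (1e-3, 1e3)

#: Number of log-spaced starting points for the Kd optimisation.
DEFAULT_N_STARTS = 7

#: Saturation fraction at the top titration point below which binding is
#: considered unsaturable (non-specific).  Configurable.
DEFAULT_SATURATION_CUTOFF = 0.2


def isotherm(L_T, P_T: float, kd: float, dmax: float):
    """Predicted CSP (ppm): ``dmax × fraction_bound(P_T, L_T, kd)``."""
    return dmax * fraction_bound(P_T, L_T, kd)


@dataclass
class KdFit:
    """Result of fitting the depletion isotherm to a titration.

    ``mode='global'`` shares one Kd across residues with per-residue
    maximal shifts; ``mode='per_residue'`` fits each residue separately
    and reports the median Kd.  ``at_bound`` flags a poorly determined
    estimate pinned at a search bound.
    """

    kd_estimate: float
    kd_stderr: float
    per_residue_dmax: dict[str, float]
    rss: float
    n_points: int
    mode: str
    converged: bool
    at_bound: bool = False
    per_residue_kd: dict[str, float] = field(default_factory=dict)


def _series_csp_matrix(
    series: TitrationSeries,
    residue_subset: Sequence[str] | None = None,
    max_jump: float = 0.25,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Residue labels, ligand totals, and the (R, n_points) CSP matrix
    relative to the apo point, restricted to residues tracked at all points."""
    chains = track_series(series, max_jump=max_jump)
    totals = np.asarray(series.ligand_totals, dtype=float)
    labels = [
        lab for lab, chain in chains.items() if all(c is not None for c in chain)
    ]
    if residue_subset is not None:
        wanted = set(residue_subset)
        labels = [lab for lab in labels if lab in wanted]
    labels.sort()
    Y = np.empty((len(labels), totals.size))
    for r, lab in enumerate(labels):
        chain = chains[lab]
        x0, y0 = chain[0]
        Y[r] = [combined_csp(x - x0, y - y0) for x, y in chain]
    return labels, totals, Y


def _concentrated_rss(log_kd: float, P_T: float, totals: np.ndarray, Y: np.ndarray):
    """RSS over residues with the per-residue dmax profiled out analytically."""
    f = fraction_bound(P_T, totals, 10.0 ** log_kd)
    ff = float(f @ f)
    if ff == 0:
        return float((Y**2).sum()), np.zeros(Y.shape[0])
    dmax = (Y @ f) / ff
    resid = Y - dmax[:, None] * f[None, :]
    return float((resid**2).sum()), dmax


def _optimise_kd(
    P_T: float,
    totals: np.ndarray,
    Y: np.ndarray,
    bounds: tuple[float, float],
    n_starts: int,
) -> tuple[float, float, np.ndarray, bool]:
    """Multi-start 1D minimisation of the concentrated RSS over log10(Kd)."""
    lo, hi = np.log10(bounds[0]), np.log10(bounds[1])
    # dense log-spaced scan anchored at the requested starts, then a
    # bounded Brent refinement around the best bracket
    grid = np.linspace(lo, hi, max(n_starts * 29, 203))
    rss_grid = np.array([_concentrated_rss(g, P_T, totals, Y)[0] for g in grid])
    k = int(np.argmin(rss_grid))
    a, b = grid[max(k - 1, 0)], grid[min(k + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda g: _concentrated_rss(g, P_T, totals, Y)[0],
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-12},
    )
    best_log = float(res.x) if res.fun <= rss_grid[k] else float(grid[k])
    rss, dmax = _concentrated_rss(best_log, P_T, totals, Y)
    converged = bool(res.success) or rss <= rss_grid[k]
    return 10.0 ** best_log, rss, dmax, converged


def _kd_stderr(
    kd: float, rss: float, P_T: float, totals: np.ndarray, Y: np.ndarray, n_params: int
) -> float:
    """Standard error from the curvature of the objective at the optimum."""
    n_obs = Y.size
    dof = max(n_obs - n_params, 1)
    sigma2 = rss / dof
    h = max(1e-6 * kd, 1e-12)

    def rss_at(k: float) -> float:
        f = fraction_bound(P_T, totals, k)
        ff = float(f @ f)
        dmax = (Y @ f) / ff if ff else np.zeros(Y.shape[0])
        return float(((Y - dmax[:, None] * f[None, :]) ** 2).sum())

    curv = (rss_at(kd + h) - 2.0 * rss + rss_at(kd - h)) / h**2
    if curv <= 0 or not np.isfinite(curv):
        return float("inf")
    return float(np.sqrt(2.0 * sigma2 / curv))


def fit_kd(
    series: TitrationSeries,
    mode: str = "global",
    residue_subset: Sequence[str] | None = None,
    bounds: tuple[float, float] = DEFAULT_KD_BOUNDS,
    n_starts: int = DEFAULT_N_STARTS,
    max_jump: float = 0.25,
) -> KdFit:
    """Least-squares fit of the depletion isotherm to per-residue CSPs.

    Requires >= 3 non-zero ligand points and residues tracked across all
    points.  The global mode shares one Kd; per-residue maximal shifts
    are profiled out analytically at each candidate Kd, so the search is
    a one-dimensional multi-start optimisation over log-spaced Kd values
    within ``bounds``.  An estimate pinned at a bound is flagged
    ``at_bound`` (poorly determined; expected for linear responses).
    """
    if mode not in ("global", "per_residue"):
        raise ValueError(f"unknown fit mode {mode!r}")
    totals_all = np.asarray(series.ligand_totals, dtype=float)
    if (totals_all > 0).sum() < 3:
        raise ValueError("Kd fitting requires >= 3 non-zero ligand points")
    labels, totals, Y = _series_csp_matrix(series, residue_subset, max_jump=max_jump)
    if not labels:
        raise ValueError("no residues tracked across all titration points")
    P_T = series.protein_conc

    if mode == "global":
        kd, rss, dmax, converged = _optimise_kd(P_T, totals, Y, bounds, n_starts)
        at_bound = kd <= bounds[0] * 1.01 or kd >= bounds[1] * 0.99
        stderr = _kd_stderr(kd, rss, P_T, totals, Y, n_params=1 + len(labels))
        return KdFit(
            kd_estimate=kd,
            kd_stderr=stderr,
            per_residue_dmax=dict(zip(labels, dmax.tolist())),
            rss=rss,
            n_points=int(totals.size),
            mode=mode,
            converged=converged,
            at_bound=at_bound,
        )

    per_kd: dict[str, float] = {}
    per_dmax: dict[str, float] = {}
    rss_total = 0.0
    converged = True
    for r, lab in enumerate(labels):
        if not np.any(Y[r] > 0):
            per_dmax[lab] = 0.0  # flat residue: Kd unidentifiable, skip
            continue
        kd_r, rss_r, dmax_r, conv_r = _optimise_kd(P_T, totals, Y[r : r + 1], bounds, n_starts)
        per_kd[lab] = kd_r
        per_dmax[lab] = float(dmax_r[0])
        rss_total += rss_r
        converged = converged and conv_r
    if not per_kd:
        raise ValueError("no responding residues for a per-residue fit")
    kd_med = float(np.median(list(per_kd.values())))
    at_bound = kd_med <= bounds[0] * 1.01 or kd_med >= bounds[1] * 0.99
    return KdFit(
        kd_estimate=kd_med,
        kd_stderr=float("nan"),
        per_residue_dmax=per_dmax,
        rss=rss_total,
        n_points=int(totals.size),
        mode=mode,
        converged=converged,
        at_bound=at_bound,
        per_residue_kd=per_kd,
    )


@dataclass
class BindingClass:
    """Binding classification with the rule that fired."""

    label: str  # specific | nonspecific | pH_artifact | inconclusive
    rationale: str


def classify_binding(
    series: TitrationSeries,
    fit: KdFit,
    profile: CSPProfile,
    assign: AssignmentTable,
    site_definitions: dict[str, frozenset[str] | set[str]] | None = None,
    n_sd: float = 2.0,
    saturation_cutoff: float = DEFAULT_SATURATION_CUTOFF,
) -> BindingClass:
    """Classify a validated candidate.

    Rules, in order: perturbations restricted to histidines -> pH
    artifact; Kd pinned at a bound, saturation fraction at the top point
    below ``saturation_cutoff``, or a significant-residue set with no
    overlap with the known sub-sites -> non-specific; otherwise specific.
    An empty significant set is inconclusive.
    """
    if site_definitions is None:
        site_definitions = {"site1": SITE1_RESIDUES, "site2": SITE2_RESIDUES}
    sig = significant_residues(profile, n_sd)
    if not sig:
        return BindingClass("inconclusive", "no residues significantly perturbed")
    codes = {assign.code_of(lab) for lab in sig if lab in assign}
    if codes == {"H"}:
        return BindingClass(
            "pH_artifact",
            f"significant residues {sorted(sig)} are exclusively histidines",
        )
    if fit.at_bound:
        return BindingClass(
            "nonspecific",
            f"Kd estimate {fit.kd_estimate:.3g} mM pinned at a search bound",
        )
    sat = fraction_bound(series.protein_conc, max(series.ligand_totals), fit.kd_estimate)
    if sat < saturation_cutoff:
        return BindingClass(
            "nonspecific",
            f"saturation fraction {sat:.2f} at the top point is below {saturation_cutoff}",
        )
    site_union = set().union(*site_definitions.values())
    if not sig & site_union:
        return BindingClass(
            "nonspecific",
            "significant residues show no overlap with either binding sub-site",
        )
    return BindingClass(
        "specific",
        f"saturable (Kd {fit.kd_estimate:.3g} mM, saturation {sat:.2f}) with "
        f"site-localised perturbations {sorted(sig & site_union)}",
    )


@dataclass
class ValidationSummary:
    """Per-class counts and fit results of a candidate validation round."""

    counts: dict[str, int]
    hits: list[str]
    results: dict[str, tuple[KdFit, BindingClass]]


def validate_candidates(
    candidates: Sequence[TitrationSeries],
    assign: AssignmentTable,
    site_definitions: dict[str, frozenset[str] | set[str]] | None = None,
    n_sd: float = 2.0,
    max_jump: float = 0.25,
) -> ValidationSummary:
    """Fit + classify each candidate titration; a hit is a specific binder."""
    counts = {"specific": 0, "nonspecific": 0, "pH_artifact": 0, "inconclusive": 0}
    hits: list[str] = []
    results: dict[str, tuple[KdFit, BindingClass]] = {}
    for series in candidates:
        fit = fit_kd(series, max_jump=max_jump)
        profile = csp_profile(series, max_jump=max_jump)
        cls = classify_binding(
            series, fit, profile, assign, site_definitions, n_sd=n_sd
        )
        counts[cls.label] += 1
        if cls.label == "specific":
            hits.append(series.ligand_id)
        results[series.ligand_id] = (fit, cls)
    return ValidationSummary(counts=counts, hits=hits, results=results)
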