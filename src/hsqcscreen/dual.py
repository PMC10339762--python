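"""Dual-fragment titration analysis: shift-vector additivity.

Tests whether two fragments occupy adjoining sub-sites simultaneously:
if they do, the peak displacement with both ligands present equals the
componentwise (vector) sum of the single-ligand displacements, and the
net shift is independent of the order of addition.  Competition for a
shared site suppresses both occupancies instead, so the observed dual
shift falls short of the additive prediction.

The verdict is evaluated at the endpoint concentrations only (both
ligands at their top point, mirroring the serial-addition experiment);
full-trajectory residuals are reported for inspection but do not enter
the verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .spectra import Peak, PeakList
from .synth import TitrationSeries
from .csp import (
    DEFAULT_MAX_JUMP,
    N_WEIGHT,
    csp_profile,
    significant_residues,
    track_peaks,
    track_series,
)

__all__ = ["DualResult", "vector_sum_prediction", "analyze_dual"]

#: Default additivity tolerance, scaled ppm (≈ 5× the default ¹H noise).
DEFAULT_TOLERANCE = 0.02

Vector = tuple[float, float]


@dataclass
class DualResult:
    """Endpoint additivity comparison for one fragment pair."""

    pair: tuple[str, str]
    per_residue: dict[str, tuple[Vector, Vector, float]]
    aggregate_residual: float
    order_discrepancy: float
    verdict: str  # simultaneous | competitive | inconclusive
    trajectory_residuals: list[float] = field(default_factory=list)


def vector_sum_prediction(
    shifts_A: Mapping[str, Vector],
    shifts_B: Mapping[str, Vector],
) -> dict[str, Vector]:
    """Componentwise (Δδ_H, Δδ_N) sum per residue.

    Residues present in only one input carry the other's contribution as
    zero; the prediction is symmetric in A and B.
    """
    out: dict[str, Vector] = {}
    for lab in set(shifts_A) | set(shifts_B):
        aH, aN = shifts_A.get(lab, (0.0, 0.0))
        bH, bN = shifts_B.get(lab, (0.0, 0.0))
        out[lab] = (aH + bH, aN + bN)
    return out


def _scaled_norm(vec: np.ndarray, weight: float = N_WEIGHT) -> float:
    return float(np.hypot(vec[0], weight * vec[1]))


def _endpoints(series: TitrationSeries, max_jump: float) -> tuple[dict, dict]:
    """(apo positions, endpoint positions) per label from tracked chains."""
    chains = track_series(series, max_jump=max_jump)
    apo = {lab: np.array(c[0]) for lab, c in chains.items() if c[0] is not None}
    end = {lab: np.array(c[-1]) for lab, c in chains.items() if c[-1] is not None}
    return apo, end


def _chain_through(
    start: PeakList, points: Sequence[PeakList], max_jump: float
) -> dict[str, list[np.ndarray | None]]:
    """Track a labelled starting list through an ordered sequence of
    (possibly unlabelled) peak lists."""
    chains: dict[str, list[np.ndarray | None]] = {
        p.label: [np.array([p.delta_H, p.delta_N])] for p in start.peaks
    }
    current = start
    for point in points:
        anon = PeakList(
            [Peak(p.delta_H, p.delta_N, p.height) for p in point.peaks],
            sample_id=point.sample_id,
            conditions=point.conditions,
            protein_conc=point.protein_conc,
        )
        result = track_peaks(current, anon, max_jump=max_jump)
        next_peaks = []
        for lab, chain in chains.items():
            if chain[-1] is None:
                chain.append(None)
                continue
            match = result.matches.get(lab)
            if match is None:
                chain.append(None)
            else:
                chain.append(np.array([match.delta_H, match.delta_N]))
                next_peaks.append(Peak(match.delta_H, match.delta_N, match.height, lab))
        current = PeakList(next_peaks, sample_id=point.sample_id,
                           conditions=point.conditions, protein_conc=point.protein_conc)
    return chains


def _dual_chain(
    dual: TitrationSeries, single_fixed: TitrationSeries, max_jump: float
) -> dict[str, list[np.ndarray | None]]:
    """Label the dual series via the fixed ligand's single titration.

    The dual series starts with the fixed ligand already present, so its
    first point is assignable from the *endpoint* of the fixed ligand's
    single titration (same conditions), whose labels chain back to apo.
    """
    chains_fixed = track_series(single_fixed, max_jump=max_jump)
    start_peaks = [
        Peak(pos[-1][0], pos[-1][1], 1.0, lab)
        for lab, pos in chains_fixed.items()
        if pos[-1] is not None
    ]
    start = PeakList(start_peaks, sample_id=f"{single_fixed.ligand_id}_endpoint",
                     protein_conc=single_fixed.protein_conc)
    chains = _chain_through(start, dual.points, max_jump=max_jump)
    # drop the synthetic starting element: entries 1.. map onto dual points
    return {lab: chain[1:] for lab, chain in chains.items()}


def analyze_dual(
    series_AB: TitrationSeries,
    series_BA: TitrationSeries,
    single_A: TitrationSeries,
    single_B: TitrationSeries,
    tolerance: float = DEFAULT_TOLERANCE,
    max_jump: float = DEFAULT_MAX_JUMP,
    n_sd: float = 2.0,
) -> DualResult:
    """Endpoint shift-vector additivity and order-independence test.

    ``series_AB`` titrates fragment A into a sample pre-loaded with B at
    its top concentration (and ``series_BA`` vice versa); ``single_A`` /
    ``single_B`` are the single-ligand titrations measured to the same
    endpoint concentrations.  Per residue, the observed dual shift (mean
    of the two serial-addition endpoints, relative to apo) is compared
    with the vector sum of the single-ligand endpoint shifts; the
    aggregate residual is the RMS over residues significantly perturbed
    by either single ligand.  The order discrepancy is the RMS scaled
    distance between the two dual endpoints.

    Verdict: ``simultaneous`` when both the aggregate residual and the
    order discrepancy are within ``tolerance``; ``competitive`` when
    additivity fails with suppressed (smaller-than-predicted) observed
    shifts; ``inconclusive`` otherwise.
    """
    id_A, id_B = single_A.ligand_id, single_B.ligand_id
    singles = {id_A: single_A, id_B: single_B}
    if series_AB.ligand_id not in singles or series_BA.ligand_id not in singles:
        raise ValueError("dual series ligands do not match the single titrations")
    if series_AB.ligand_id == id_B and series_BA.ligand_id == id_A:
        series_AB, series_BA = series_BA, series_AB
    for s in (series_BA, single_A, single_B):
        if s.protein_conc != series_AB.protein_conc:
            raise ValueError("all series must share the protein concentration")
    # each dual series' fixed ligand is the one it does not vary; its own
    # single titration must reach both dual endpoint concentrations
    fixed_of = {}
    for dual in (series_AB, series_BA):
        varied = dual.ligand_id
        fixed_id = id_B if varied == id_A else id_A
        fixed_of[id(dual)] = singles[fixed_id]
        if singles[varied].ligand_totals[-1] != dual.ligand_totals[-1]:
            raise ValueError(
                f"single {varied} endpoint {singles[varied].ligand_totals[-1]} mM != "
                f"dual varied endpoint {dual.ligand_totals[-1]} mM"
            )
        fixed_conc = dual.points[-1].conditions.get(fixed_id)
        if fixed_conc is not None and fixed_conc != singles[fixed_id].ligand_totals[-1]:
            raise ValueError(
                f"fixed ligand {fixed_id} at {fixed_conc} mM in the dual series but "
                f"titrated to {singles[fixed_id].ligand_totals[-1]} mM alone"
            )

    apo_A, end_A = _endpoints(single_A, max_jump)
    apo_B, end_B = _endpoints(single_B, max_jump)
    chains_AB = _dual_chain(series_AB, fixed_of[id(series_AB)], max_jump)
    chains_BA = _dual_chain(series_BA, fixed_of[id(series_BA)], max_jump)

    labels = [
        lab
        for lab in apo_A
        if lab in apo_B and lab in end_A and lab in end_B
        and chains_AB.get(lab, [None])[-1] is not None
        and chains_BA.get(lab, [None])[-1] is not None
    ]
    per_residue: dict[str, tuple[Vector, Vector, float]] = {}
    order_sq: dict[str, float] = {}
    for lab in labels:
        apo = 0.5 * (apo_A[lab] + apo_B[lab])
        shift_A = end_A[lab] - apo
        shift_B = end_B[lab] - apo
        pred = shift_A + shift_B
        end_AB = chains_AB[lab][-1]
        end_BA = chains_BA[lab][-1]
        obs = 0.5 * (end_AB + end_BA) - apo
        residual = _scaled_norm(obs - pred)
        per_residue[lab] = (tuple(obs), tuple(pred), residual)
        order_sq[lab] = _scaled_norm(end_AB - end_BA) ** 2

    sig = (
        significant_residues(csp_profile(single_A, max_jump=max_jump), n_sd)
        | significant_residues(csp_profile(single_B, max_jump=max_jump), n_sd)
    ) & set(labels)
    if not sig:
        return DualResult((id_A, id_B), per_residue, float("nan"), float("nan"),
                          "inconclusive")
    agg = float(np.sqrt(np.mean([per_residue[lab][2] ** 2 for lab in sig])))
    order = float(np.sqrt(np.mean([order_sq[lab] for lab in sig])))

    if agg <= tolerance and order <= tolerance:
        verdict = "simultaneous"
    else:
        obs_rms = np.sqrt(np.mean([_scaled_norm(np.array(per_residue[lab][0])) ** 2
                                   for lab in sig]))
        pred_rms = np.sqrt(np.mean([_scaled_norm(np.array(per_residue[lab][1])) ** 2
                                    for lab in sig]))
        verdict = "competitive" if (agg > tolerance and obs_rms < pred_rms) else "inconclusive"

    trajectory: list[float] = []
    if (
        list(single_A.ligand_totals) == list(series_AB.ligand_totals)
        and list(single_B.ligand_totals) == list(series_BA.ligand_totals)
    ):
        chains_sA = track_series(single_A, max_jump=max_jump)
        chains_sB = track_series(single_B, max_jump=max_jump)
        n_pts = len(series_AB.points)
        for i in range(n_pts):
            vals = []
            for lab in sig:
                cA, cB = chains_sA.get(lab), chains_sB.get(lab)
                if (
                    cA is None or cB is None or cA[i] is None or cB[-1] is None
                    or chains_AB[lab][i] is None
                ):
                    continue
                apo = 0.5 * (apo_A[lab] + apo_B[lab])
                pred_i = (np.array(cA[i]) - apo) + (np.array(cB[-1]) - apo)
                obs_i = chains_AB[lab][i] - apo
                vals.append(_scaled_norm(obs_i - pred_i) ** 2)
            if vals:
                trajectory.append(float(np.sqrt(np.mean(vals))))
    return DualResult((id_A, id_B), per_residue, agg, order, verdict, trajectory)
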