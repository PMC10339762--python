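"""Synthetic screening data with the statistical structure the analysis assumes.

Generates protein-observed HSQC screening fixtures: fast-exchange peak
movement under single-site binding with ligand depletion, pooled n-plex
mixtures, titration series, dual-ligand schedules (independent sites or
competitive), Gaussian positional noise, and a packaged 2,678-fragment
library fixture against a ~75-residue CCL28-like pseudo-protein.

All generators are pure functions of (inputs, seed).

Units: protein concentrations in μM, ligand concentrations and
dissociation constants in mM, chemical shifts in ppm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .spectra import Assignment, AssignmentTable, Peak, PeakList

__all__ = [
    "FragmentRecord",
    "PlexDesign",
    "TitrationSeries",
    "DualSchedule",
    "fraction_bound",
    "simulate_sample",
    "simulate_titration",
    "simulate_dual",
    "dual_species",
    "make_ccl28_fixture",
    "make_sulfotyrosine_probe",
    "write_manifest",
    "read_manifest",
    "write_plex_design",
    "read_plex_design",
    "SITE1_RESIDUES",
    "SITE2_RESIDUES",
    "STYR_HOTSPOTS",
    "DEFAULT_NOISE_SD",
    "DEFAULT_PROTEIN_CONC",
]

#: Default protein concentration (μM) and per-axis positional noise sd (ppm).
DEFAULT_PROTEIN_CONC = 50.0
DEFAULT_NOISE_SD = (0.004, 0.02)

#: Sub-site definitions on the pseudo-CCL28 surface (disjoint label sets).
#: Site 1 is the cleft between the N-loop and the short α-helix; site 2 is
#: the sulfotyrosine recognition cleft between the N-loop and β3 strand.
#: S20/R21/L24 sit in the middle of the cleft, shared by both sub-sites,
#: and deliberately belong to neither definition.
SITE1_RESIDUES = frozenset({"E25", "Q69", "Q69sc", "M66", "T27", "A30"})
SITE2_RESIDUES = frozenset({"C11", "K49", "R50", "R52", "I53", "K83", "C54", "F12"})

#: Residues with large (> 0.6 ppm) sulfotyrosine-induced perturbations.
STYR_HOTSPOTS = frozenset({"C11", "K49", "R50", "R52", "I53", "K83"})

_HIS_RESIDUES = ("H19", "H57", "H96")
_NONSPEC_RESIDUES = ("G35", "T40", "D60", "K75", "A90", "L95", "E100", "S105")
_SHARED_CLEFT = ("S20", "R21", "L24")

_SITE_LABELS = ("site1_Nloop_helix", "site2_sY_cleft", "both", "none")

#: ¹⁵N scaling used to convert a combined-CSP magnitude into axis components.
_N_WEIGHT = 0.2


@dataclass
class FragmentRecord:
    """One library fragment with its ground-truth binding behaviour.

    ``dmax`` maps assignment label -> (Δδ_H^max, Δδ_N^max) in ppm, the
    fully-bound shift of each perturbed residue.  ``truth`` is the
    ground-truth class used to score the synthetic screen:
    ``inert``, ``specific``, ``nonspecific`` or ``ph`` (pH artifact).
    Non-specific and pH-artifact actives perturb peaks without occupying
    either sub-site, so they carry ``site_label='none'`` with a non-empty
    ``dmax``.
    """

    fragment_id: str
    library_name: str
    site_label: str
    kd: float | None = None
    dmax: dict[str, tuple[float, float]] = field(default_factory=dict)
    truth: str = "inert"

    def __post_init__(self) -> None:
        if self.site_label not in _SITE_LABELS:
            raise ValueError(f"unknown site_label {self.site_label!r}")
        if self.site_label != "none":
            if self.kd is None or self.kd <= 0:
                raise ValueError("site-binding fragments require kd > 0")
            if not self.dmax:
                raise ValueError("site-binding fragments require non-empty dmax")
        if self.dmax and (self.kd is None or self.kd <= 0):
            raise ValueError("perturbing fragments require kd > 0")

    @property
    def is_active(self) -> bool:
        return bool(self.dmax)


@dataclass
class PlexDesign:
    """Assignment of fragments to pooled samples for one screening round."""

    assignments: dict[str, list[str]]
    plex_size: int

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for plex_id, frags in self.assignments.items():
            if len(frags) > self.plex_size:
                raise ValueError(f"plex {plex_id} exceeds plex_size {self.plex_size}")
            dup = seen.intersection(frags)
            if dup:
                raise ValueError(f"fragments assigned to more than one plex: {sorted(dup)}")
            seen.update(frags)

    @property
    def fragment_ids(self) -> list[str]:
        return [f for frags in self.assignments.values() for f in frags]

    def plex_of(self, fragment_id: str) -> str:
        for plex_id, frags in self.assignments.items():
            if fragment_id in frags:
                return plex_id
        raise KeyError(fragment_id)


@dataclass
class TitrationSeries:
    """Ordered ligand totals with one peak list per point, fixed protein.

    ``ligand_totals`` refers to the varied ligand; the first point is its
    zero-concentration reference (true apo for single-ligand series; the
    fixed-ligand-only sample for dual series).
    """

    protein_conc: float
    ligand_id: str
    ligand_totals: list[float]
    points: list[PeakList]
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.ligand_totals, dtype=float)
        if t.size == 0:
            raise ValueError("ligand_totals must be non-empty")
        if t[0] != 0:
            raise ValueError("first titration point must be the 0 mM reference")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("ligand_totals must be non-negative and strictly increasing")
        if len(self.points) != t.size:
            raise ValueError("one peak list required per ligand total")
        for p in self.points:
            if p.protein_conc != self.protein_conc:
                raise ValueError("all points must share the series protein concentration")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class DualSchedule:
    """A dual titration: one ligand fixed, the other varied.

    ``mode`` selects the co-binding model used by :func:`simulate_dual`:
    ``independent_sites`` (species P, PA, PB, PAB; site-independent
    affinities) or ``competitive`` (single shared site; P, PA, PB only).
    """

    fixed_ligand: tuple[str, float]
    varied_ligand: str
    varied_totals: list[float]
    mode: str = "independent_sites"

    def __post_init__(self) -> None:
        if self.mode not in ("independent_sites", "competitive"):
            raise ValueError(f"unknown dual mode {self.mode!r}")
        if self.fixed_ligand[1] < 0:
            raise ValueError("fixed ligand concentration must be >= 0")


# ---------------------------------------------------------------------------
# Binding equilibria
# ---------------------------------------------------------------------------

def fraction_bound(P_T: float, L_T, kd: float):
    """Fraction of protein bound under the single-site ligand-depletion model.

    Solves ``P + L <-> PL`` exactly:
    ``f = (b - sqrt(b² - 4·P·L)) / (2·P)`` with ``b = P + L + kd``
    (evaluated in the cancellation-free form ``f = 2L / (b + sqrt(b²-4PL))``).

    Parameters
    ----------
    P_T : total protein, μM.
    L_T : total ligand, mM (scalar or array).
    kd : dissociation constant, mM.
    """
    L = np.asarray(L_T, dtype=float)
    if not np.isfinite(P_T) or not np.isfinite(kd) or not np.isfinite(L).all():
        raise ValueError("fraction_bound requires finite inputs")
    if P_T <= 0:
        raise ValueError("protein concentration must be > 0")
    if kd <= 0:
        raise ValueError("kd must be > 0")
    if np.any(L < 0):
        raise ValueError("ligand totals must be >= 0")
    P = P_T / 1000.0  # unify to mM
    b = P + L + kd
    disc = b * b - 4.0 * P * L
    f = 2.0 * L / (b + np.sqrt(disc))
    return float(f) if np.isscalar(L_T) else f


def dual_species(
    P_T: float,
    A_T: float,
    B_T: float,
    kd_A: float,
    kd_B: float,
    mode: str = "independent_sites",
) -> dict[str, float]:
    """Solve the coupled two-ligand mass balance.

    Returns species concentrations in mM plus the site occupancies
    ``fA``/``fB`` (fraction of protein with ligand A / B bound).

    ``independent_sites``: distinct non-interacting sites; species P, PA,
    PB and the ternary complex PAB with no cooperativity.  ``competitive``:
    a single shared site; species P, PA, PB only.  Free-ligand balances
    are root-solved with Brent's method to machine precision; a bracketing
    failure raises ``RuntimeError`` with the offending concentrations.
    """
    if A_T < 0 or B_T < 0:
        raise ValueError("ligand totals must be >= 0")
    P = P_T / 1000.0

    def _solve(func, lo, hi, what):
        try:
            return brentq(func, lo, hi, xtol=1e-18, rtol=8.9e-16, maxiter=200)
        except (ValueError, RuntimeError) as exc:
            raise RuntimeError(
                f"dual-equilibrium solver failed for {what} "
                f"(P_T={P_T} uM, A_T={A_T} mM, B_T={B_T} mM, "
                f"kd_A={kd_A}, kd_B={kd_B}, mode={mode}): {exc}"
            ) from exc

    if mode == "independent_sites":
        def _free(L_T: float, kd: float) -> float:
            if L_T == 0:
                return 0.0
            return _solve(lambda x: x + P * x / (kd + x) - L_T, 0.0, L_T, "free ligand")

        A_free = _free(A_T, kd_A)
        B_free = _free(B_T, kd_B)
        fA = A_free / (kd_A + A_free)
        fB = B_free / (kd_B + B_free)
        return {
            "P": P * (1 - fA) * (1 - fB),
            "PA": P * fA * (1 - fB),
            "PB": P * fB * (1 - fA),
            "PAB": P * fA * fB,
            "A_free": A_free,
            "B_free": B_free,
            "fA": fA,
            "fB": fB,
        }
    if mode == "competitive":
        if A_T == 0 and B_T == 0:
            pf = P
        else:
            def g(pf: float) -> float:
                A_free = A_T / (1 + pf / kd_A)
                B_free = B_T / (1 + pf / kd_B)
                return pf * (1 + A_free / kd_A + B_free / kd_B) - P

            pf = _solve(g, 0.0, P, "free protein")
        A_free = A_T / (1 + pf / kd_A)
        B_free = B_T / (1 + pf / kd_B)
        denom = 1 + A_free / kd_A + B_free / kd_B
        fA = (A_free / kd_A) / denom
        fB = (B_free / kd_B) / denom
        return {
            "P": pf,
            "PA": P * fA,
            "PB": P * fB,
            "A_free": A_free,
            "B_free": B_free,
            "fA": fA,
            "fB": fB,
        }
    raise ValueError(f"unknown dual mode {mode!r}")


# ---------------------------------------------------------------------------
# Sample / titration simulation (fast exchange)
# ---------------------------------------------------------------------------

def _point_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n)]


def simulate_sample(
    assign: AssignmentTable,
    fragments: Sequence[tuple[FragmentRecord, float]],
    protein_conc: float = DEFAULT_PROTEIN_CONC,
    noise_sd: tuple[float, float] = DEFAULT_NOISE_SD,
    seed: int = 0,
    sample_id: str = "sample",
) -> PeakList:
    """Simulate one HSQC peak list under fast exchange.

    Each residue's peak moves from its apo position by the sum over
    fragments of ``fraction_bound · (Δδ_H^max, Δδ_N^max)``; distinct-site
    fragments contribute independently (each sees the full protein pool,
    appropriate for the weak-binding, ligand-excess screening regime).
    Gaussian positional noise with per-axis sd ``noise_sd`` is added.
    Deterministic given ``seed``.
    """
    if any(conc < 0 for _, conc in fragments):
        raise ValueError("fragment concentrations must be >= 0")
    shifts: dict[str, np.ndarray] = {}
    for frag, conc in fragments:
        if conc == 0 or not frag.dmax:
            continue
        f = fraction_bound(protein_conc, conc, frag.kd)
        for label, (dH, dN) in frag.dmax.items():
            if label in assign:
                shifts[label] = shifts.get(label, np.zeros(2)) + f * np.array([dH, dN])
    rng = np.random.default_rng(seed)
    n = len(assign)
    noise_H = rng.normal(0.0, noise_sd[0], size=n)
    noise_N = rng.normal(0.0, noise_sd[1], size=n)
    peaks = []
    for i, entry in enumerate(assign):
        dH, dN = shifts.get(entry.label, (0.0, 0.0))
        peaks.append(
            Peak(
                delta_H=entry.delta_H + dH + noise_H[i],
                delta_N=entry.delta_N + dN + noise_N[i],
                height=entry.height,
                label=entry.label,
            )
        )
    conditions = {frag.fragment_id: float(conc) for frag, conc in fragments}
    return PeakList(peaks, sample_id=sample_id, conditions=conditions, protein_conc=protein_conc)


def simulate_titration(
    assign: AssignmentTable,
    fragment: FragmentRecord,
    ligand_totals: Sequence[float],
    protein_conc: float = DEFAULT_PROTEIN_CONC,
    noise_sd: tuple[float, float] = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> TitrationSeries:
    """Simulate a single-ligand titration series (point 0 is apo)."""
    totals = list(map(float, ligand_totals))
    if len(totals) == 0:
        raise ValueError("ligand_totals must be non-empty")
    seeds = _point_seeds(seed, len(totals))
    points = [
        simulate_sample(
            assign,
            [(fragment, L)],
            protein_conc=protein_conc,
            noise_sd=noise_sd,
            seed=s,
            sample_id=f"{fragment.fragment_id}_{L:g}mM",
        )
        for L, s in zip(totals, seeds)
    ]
    return TitrationSeries(
        protein_conc=protein_conc,
        ligand_id=fragment.fragment_id,
        ligand_totals=totals,
        points=points,
        seed=seed,
    )


def simulate_dual(
    assign: AssignmentTable,
    fragA: FragmentRecord,
    fragB: FragmentRecord,
    schedule: DualSchedule,
    protein_conc: float = DEFAULT_PROTEIN_CONC,
    noise_sd: tuple[float, float] = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> TitrationSeries:
    """Simulate a dual titration: one fragment fixed, the other varied.

    Occupancies come from the coupled mass balance of
    :func:`dual_species` in the schedule's mode; residue shifts are
    ``fA·ΔδA + fB·ΔδB``.  With the fixed ligand at 0 mM this reduces
    exactly to :func:`simulate_titration` of the varied ligand.
    """
    if fragA.fragment_id == fragB.fragment_id:
        raise ValueError("dual titration requires two distinct fragments")
    ids = {fragA.fragment_id: fragA, fragB.fragment_id: fragB}
    if schedule.varied_ligand not in ids or schedule.fixed_ligand[0] not in ids:
        raise ValueError("schedule ligand ids do not match the given fragments")
    if schedule.varied_ligand == schedule.fixed_ligand[0]:
        raise ValueError("fixed and varied ligand must differ")
    varied = ids[schedule.varied_ligand]
    fixed = ids[schedule.fixed_ligand[0]]
    fixed_conc = float(schedule.fixed_ligand[1])
    totals = list(map(float, schedule.varied_totals))
    seeds = _point_seeds(seed, len(totals))
    positions = assign.positions()
    points = []
    for v, s in zip(totals, seeds):
        species = dual_species(
            protein_conc,
            A_T=v,
            B_T=fixed_conc,
            kd_A=varied.kd,
            kd_B=fixed.kd,
            mode=schedule.mode,
        )
        fV, fF = species["fA"], species["fB"]
        shifts: dict[str, np.ndarray] = {}
        for frag, f in ((varied, fV), (fixed, fF)):
            for label, (dH, dN) in frag.dmax.items():
                if label in assign:
                    shifts[label] = shifts.get(label, np.zeros(2)) + f * np.array([dH, dN])
        rng = np.random.default_rng(s)
        n = len(assign)
        noise_H = rng.normal(0.0, noise_sd[0], size=n)
        noise_N = rng.normal(0.0, noise_sd[1], size=n)
        peaks = []
        for i, entry in enumerate(assign):
            dH, dN = shifts.get(entry.label, (0.0, 0.0))
            peaks.append(
                Peak(
                    entry.delta_H + dH + noise_H[i],
                    entry.delta_N + dN + noise_N[i],
                    entry.height,
                    entry.label,
                )
            )
        points.append(
            PeakList(
                peaks,
                sample_id=f"{varied.fragment_id}_{v:g}mM+{fixed.fragment_id}_{fixed_conc:g}mM",
                conditions={varied.fragment_id: v, fixed.fragment_id: fixed_conc},
                protein_conc=protein_conc,
            )
        )
    return TitrationSeries(
        protein_conc=protein_conc,
        ligand_id=varied.fragment_id,
        ligand_totals=totals,
        points=points,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Packaged CCL28-like fixture
# ---------------------------------------------------------------------------

N_FRAGMENTS = 2678
PLEX_SIZE = 12
N_SPECIFIC = 13
N_NONSPECIFIC = 8
N_PH = 4

#: Named residue positions of the pseudo-protein (one-letter code by index).
_NAMED_CODES = {
    11: "C", 12: "F", 19: "H", 20: "S", 21: "R", 24: "L", 25: "E", 27: "T",
    30: "A", 35: "G", 40: "T", 49: "K", 50: "R", 52: "R", 53: "I", 54: "C",
    57: "H", 60: "D", 66: "M", 69: "Q", 75: "K", 83: "K", 90: "A", 95: "L",
    96: "H", 100: "E", 105: "S",
}

_LIBRARIES = ("Core 1000", "Zenobia 1", "L5700", "3D Shape Diverse")

#: Fig 3 dissociation constants for the two dual-titration fragments (mM).
KD_SPB07625 = 0.85
KD_CC10501 = 6.6

_SITE2_KDS = (0.6, 1.0, 1.5, 2.0, 3.0, 5.0, 8.0)   # plus SPB07625 at 0.85
_SITE1_KDS = (1.2, 2.5, 4.0)                        # plus CC10501 at 6.6
_KD_ZT0784 = 2.0


def _sample_positions(rng: np.random.Generator, n: int, min_sep: float = 0.25) -> np.ndarray:
    """Rejection-sample n peak positions with a minimum pairwise separation
    of ``min_sep`` in the (¹H, 0.2·¹⁵N) scaled metric."""
    out: list[np.ndarray] = []
    while len(out) < n:
        cand = np.array([rng.uniform(7.2, 9.8), rng.uniform(106.0, 130.0)])
        scaled = np.array([cand[0], _N_WEIGHT * cand[1]])
        ok = True
        for p in out:
            ps = np.array([p[0], _N_WEIGHT * p[1]])
            if np.hypot(*(scaled - ps)) < min_sep:
                ok = False
                break
        if ok:
            out.append(cand)
    return np.array(out)


def _make_assignment_table(rng: np.random.Generator) -> AssignmentTable:
    named = sorted(_NAMED_CODES)
    pool = [i for i in range(4, 109) if i not in _NAMED_CODES]
    extra = sorted(rng.choice(pool, size=75 - len(named), replace=False).tolist())
    codes = "ADEFGIKLMNQRSTVWY"  # no H (histidine count is controlled), no P/C
    indices = sorted(named + extra)
    pos = _sample_positions(rng, len(indices) + 1)  # +1 for the Q69 side chain
    heights = rng.uniform(0.8, 1.3, size=len(indices) + 1)
    entries = []
    for k, idx in enumerate(indices):
        code = _NAMED_CODES.get(idx, codes[int(rng.integers(len(codes)))])
        entries.append(
            Assignment(idx, code, float(pos[k, 0]), float(pos[k, 1]), float(heights[k]))
        )
    # Gln69 side-chain NH: extra labelled entry, identical analysis path.
    entries.append(
        Assignment(69, "Q", float(pos[-1, 0]), float(pos[-1, 1]), float(heights[-1]), suffix="sc")
    )
    return AssignmentTable(entries, name="pseudo-CCL28")


def _direction_map(rng: np.random.Generator, labels: Sequence[str]) -> dict[str, float]:
    """Shift-direction angle per residue; alternate residues are forced
    H-dominant so every perturbation pattern is visible on both axes."""
    out = {}
    for i, lab in enumerate(sorted(labels)):
        if i % 2 == 0:
            out[lab] = float(rng.choice([0.0, np.pi]) + rng.uniform(-0.6, 0.6))
        else:
            out[lab] = float(rng.uniform(0.0, 2 * np.pi))
    return out


def _dmax_from(
    labels: Sequence[str],
    directions: Mapping[str, float],
    combined: Mapping[str, float],
    jitter: float = 0.0,
) -> dict[str, tuple[float, float]]:
    """Convert per-residue combined magnitudes + direction angles into
    (Δδ_H, Δδ_N) vectors; ``jitter`` rotates the whole pattern (radians)."""
    out = {}
    for lab in labels:
        c = combined[lab]
        th = directions[lab] + jitter
        out[lab] = (c * np.cos(th), c * np.sin(th) / _N_WEIGHT)
    return out


def _fixture_rng(seed: int, stream: int) -> np.random.Generator:
    """Independent, reproducible sub-streams of the fixture seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, 0xCC28, stream]))


def _make_direction_maps(seed: int) -> dict[str, dict[str, float]]:
    rng = _fixture_rng(seed, 1)
    dir_site1 = _direction_map(rng, sorted(SITE1_RESIDUES) + list(_SHARED_CLEFT))
    dir_site2 = _direction_map(rng, sorted(SITE2_RESIDUES) + list(_SHARED_CLEFT))
    # S20 and E25 move in different directions for site-1 vs site-2 binders
    # (distinct binding modes): make the shared-cleft directions opposite.
    for lab in _SHARED_CLEFT:
        dir_site1[lab] = float((dir_site2[lab] + np.pi) % (2 * np.pi))
    dir_nonspec = _direction_map(rng, _NONSPEC_RESIDUES)
    dir_his = _direction_map(rng, _HIS_RESIDUES)
    return {"site1": dir_site1, "site2": dir_site2,
            "nonspec": dir_nonspec, "his": dir_his}


def make_ccl28_fixture(
    seed: int = 0,
) -> tuple[AssignmentTable, list[FragmentRecord], PlexDesign]:
    """Deterministic packaged screening fixture.

    Returns the pseudo-CCL28 assignment table (~75 NH peaks including the
    hotspot and site residues named in the study), a 2,678-fragment
    manifest with ground truth (13 specific binders: 4 site 1, 8 site 2,
    1 both; 8 non-specific actives; 4 pH-artifact actives; the rest
    inert), and the 12-plex design of the first screening round.
    """
    assign = _make_assignment_table(_fixture_rng(seed, 0))
    dirs = _make_direction_maps(seed)
    dir_site1, dir_site2 = dirs["site1"], dirs["site2"]
    dir_nonspec, dir_his = dirs["nonspec"], dirs["his"]
    rng = _fixture_rng(seed, 2)

    def combined(labels: Sequence[str], v0: float, spread: float = 0.08) -> dict[str, float]:
        return {lab: v0 * float(rng.uniform(1 - spread, 1 + spread)) for lab in labels}

    def specific(fid, lib, site, kd, labels, directions) -> FragmentRecord:
        # per-residue Δδmax scaled so the endpoint CSP at 6 mM is ~v0
        v0 = float(rng.uniform(0.18, 0.30))
        f6 = fraction_bound(DEFAULT_PROTEIN_CONC, 6.0, kd)
        c = {lab: v / f6 for lab, v in combined(labels, v0).items()}
        return FragmentRecord(
            fid, lib, site, kd,
            _dmax_from(labels, directions, c, jitter=float(rng.uniform(-0.2, 0.2))),
            truth="specific",
        )

    actives: list[FragmentRecord] = []
    # --- site 2 (sY cleft): SPB07625 + seven analogues -------------------
    spb_labels = ["I53", "S20", "R21", "L24", "C54", "C11", "R52"]
    actives.append(specific("SPB07625", "Core 1000", "site2_sY_cleft", KD_SPB07625,
                            spb_labels, dir_site2))
    site2_extra = ["K49", "R50", "K83", "C54", "F12"]
    for i, kd in enumerate(_SITE2_KDS):
        labels = ["I53", "R52", "C11"] + [
            site2_extra[j] for j in rng.choice(5, size=int(rng.integers(2, 4)), replace=False)
        ]
        if rng.uniform() < 0.5:
            labels.append(str(rng.choice(["S20", "R21"])))
        actives.append(specific(f"SY2-{i + 1:02d}", _LIBRARIES[i % 4], "site2_sY_cleft",
                                kd, list(dict.fromkeys(labels)), dir_site2))
    # --- site 1 (N-loop / helix): CC10501 + three analogues --------------
    cc_labels = ["S20", "R21", "I53", "E25", "Q69", "Q69sc", "M66"]
    cc_dirs = dict(dir_site1)
    cc_dirs["I53"] = dir_site2["I53"]  # the one shared sY-cleft reporter
    actives.append(specific("CC10501", "Core 1000", "site1_Nloop_helix", KD_CC10501,
                            cc_labels, cc_dirs))
    site1_extra = ["T27", "A30"]
    for i, kd in enumerate(_SITE1_KDS):
        labels = ["E25", "Q69", "Q69sc", "M66"] + [
            site1_extra[j] for j in rng.choice(2, size=int(rng.integers(1, 3)), replace=False)
        ]
        if rng.uniform() < 0.5:
            labels.append("S20")
        actives.append(specific(f"SY1-{i + 1:02d}", _LIBRARIES[i % 4], "site1_Nloop_helix",
                                kd, list(dict.fromkeys(labels)), dir_site1))
    # --- ZT0784: bridges both sub-sites ----------------------------------
    zt_dirs = {**dir_site2, **{k: dir_site1[k] for k in ("E25", "Q69", "M66")}}
    actives.append(specific("ZT0784", "Zenobia 1", "both", _KD_ZT0784,
                            ["E25", "Q69", "M66", "I53", "R52", "C11", "S20"], zt_dirs))
    # --- non-specific actives: weak, unsaturable, spatially unstructured --
    for i in range(N_NONSPECIFIC):
        kd = float(rng.uniform(25.0, 35.0))
        c = combined(_NONSPEC_RESIDUES, 1.5, spread=0.1)
        actives.append(FragmentRecord(
            f"NS-{i + 1:02d}", _LIBRARIES[i % 4], "none", kd,
            _dmax_from(_NONSPEC_RESIDUES, dir_nonspec, c,
                       jitter=float(rng.uniform(-0.2, 0.2))),
            truth="nonspecific",
        ))
    # --- pH artifacts: saturable shifts restricted to histidines ----------
    for i, kd in enumerate((1.5, 2.0, 2.5, 3.0)):
        f6 = fraction_bound(DEFAULT_PROTEIN_CONC, 6.0, kd)
        c = {lab: 0.3 * float(rng.uniform(0.92, 1.08)) / f6 for lab in _HIS_RESIDUES}
        actives.append(FragmentRecord(
            f"PH-{i + 1:02d}", _LIBRARIES[i % 4], "none", kd,
            _dmax_from(_HIS_RESIDUES, dir_his, c, jitter=float(rng.uniform(-0.2, 0.2))),
            truth="ph",
        ))

    assert len(actives) == N_SPECIFIC + N_NONSPECIFIC + N_PH

    # --- scatter the actives through the 2,678-fragment manifest ----------
    slots = sorted(int(s) for s in rng.choice(N_FRAGMENTS, size=len(actives), replace=False))
    order = rng.permutation(len(actives))
    fragments: list[FragmentRecord] = []
    slot_map = {slot: actives[order[k]] for k, slot in enumerate(slots)}
    for i in range(N_FRAGMENTS):
        if i in slot_map:
            fragments.append(slot_map[i])
        else:
            fragments.append(FragmentRecord(f"F{i + 1:04d}", _LIBRARIES[i % 4], "none"))

    n_plex = int(np.ceil(N_FRAGMENTS / PLEX_SIZE))
    assignments = {
        f"P{k + 1:03d}": [f.fragment_id for f in fragments[k * PLEX_SIZE:(k + 1) * PLEX_SIZE]]
        for k in range(n_plex)
    }
    design = PlexDesign(assignments=assignments, plex_size=PLEX_SIZE)
    return assign, fragments, design


def make_sulfotyrosine_probe(seed: int = 0) -> FragmentRecord:
    """Free sulfotyrosine as a hotspot probe on the pseudo-CCL28 surface.

    The six hotspot residues carry combined Δδmax of ~0.75–1.05 ppm so
    that their perturbations exceed 0.6 ppm at the 100 mM endpoint of the
    titration ladder; three weaker cleft residues stay well below.
    Directions reuse the sY-cleft (site 2) map of the fixture so the
    probe shares reporters with the sY-cleft fragments.
    """
    dir_site2 = _make_direction_maps(seed)["site2"]
    rng = _fixture_rng(seed, 3)
    strong = {lab: float(rng.uniform(0.75, 1.05)) for lab in sorted(STYR_HOTSPOTS)}
    weak = {lab: float(rng.uniform(0.30, 0.45)) for lab in ("C54", "F12", "S20")}
    dmax = _dmax_from(list(strong) + list(weak), dir_site2, {**strong, **weak})
    return FragmentRecord("sTyr", "probe", "site2_sY_cleft", kd=5.0, dmax=dmax,
                          truth="specific")


# ---------------------------------------------------------------------------
# Manifest / plex-design CSV I/O
# ---------------------------------------------------------------------------

def write_manifest(fragments: Sequence[FragmentRecord], path: str | Path) -> None:
    """Manifest CSV: fragment_id, library_name, site_label, kd_mM, truth."""
    pd.DataFrame(
        {
            "fragment_id": [f.fragment_id for f in fragments],
            "library_name": [f.library_name for f in fragments],
            "site_label": [f.site_label for f in fragments],
            "kd_mM": [f.kd if f.kd is not None else "" for f in fragments],
            "truth": [f.truth for f in fragments],
        }
    ).to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_plex_design(design: PlexDesign, path: str | Path) -> None:
    """Plex-design CSV: plex_id, fragment_id (one row per assignment)."""
    rows = [
        {"plex_id": plex_id, "fragment_id": fid}
        for plex_id, frags in design.assignments.items()
        for fid in frags
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plex_design(path: str | Path, plex_size: int | None = None) -> PlexDesign:
    df = pd.read_csv(path)
    assignments: dict[str, list[str]] = {}
    for plex_id, group in df.groupby("plex_id", sort=False):
        assignments[str(plex_id)] = [str(f) for f in group["fragment_id"]]
    size = plex_size if plex_size is not None else max(len(v) for v in assignments.values())
    return PlexDesign(assignments=assignments, plex_size=size)
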