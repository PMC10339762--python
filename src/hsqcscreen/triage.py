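"""Primary-screen hit detection.

Difference intensity analysis (DIA), PCA embedding of whole spectra,
k-means clustering, hit flagging against a reference (solvent-only)
sample, and iterative pooled-library deconvolution planning
(12-plex -> 3-plex -> single compound).

The DIA statistic is the summed absolute intensity of a difference
spectrum over grid nodes above a noise floor: a scalar ranking of how
much a sample's fingerprint departs from the reference.  The hit flag
combines it with cluster membership (samples clustering away from the
reference) and is advisory — thresholds are configuration knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .spectra import AxisMismatchError, Spectrum2D
from .synth import PlexDesign

__all__ = [
    "TriageResult",
    "dia_statistic",
    "estimate_noise_floor",
    "pca_embed",
    "kmeans_cluster",
    "flag_hits",
    "deconvolution_plan",
]

#: Default multiplier on the region standard deviation for the noise floor.
DEFAULT_NOISE_FLOOR_SD = 5.0

#: Default multiplier on the reference-cluster median DIA for the hit flag.
DEFAULT_DIA_MULT = 3.0


@dataclass
class TriageResult:
    """Per-sample triage quantities for one screening round."""

    sample_id: str
    dia: float
    pca_coords: list[float]
    cluster: int = 0
    is_hit: bool = False
    round: str = ""
    lineage: list[str] = field(default_factory=list)


def dia_statistic(diff: Spectrum2D, noise_floor: float = 0.0) -> float:
    """Sum of |intensity| over grid nodes exceeding the noise floor.

    Monotone non-increasing in ``noise_floor``; zero for an all-zero
    difference spectrum.
    """
    if noise_floor < 0:
        raise ValueError("noise_floor must be >= 0")
    a = np.abs(diff.grid)
    return float(a[a > noise_floor].sum())


def estimate_noise_floor(
    spec: Spectrum2D,
    region: tuple[tuple[float, float], tuple[float, float]],
    c: float = DEFAULT_NOISE_FLOOR_SD,
) -> float:
    """``c ×`` standard deviation of intensities in a signal-free sub-window.

    ``region`` is ((H_min, H_max), (N_min, N_max)) in ppm and must lie
    inside the axes and contain >= 100 grid nodes.  A region overlapping
    real peaks inflates the estimate — pick an empty corner.
    """
    (h_lo, h_hi), (n_lo, n_hi) = region
    if h_lo < spec.axis_H[0] or h_hi > spec.axis_H[1] or n_lo < spec.axis_N[0] or n_hi > spec.axis_N[1]:
        raise ValueError("noise region outside spectrum axes")
    ppm_H, ppm_N = spec.ppm_H(), spec.ppm_N()
    sel_H = (ppm_H >= h_lo) & (ppm_H <= h_hi)
    sel_N = (ppm_N >= n_lo) & (ppm_N <= n_hi)
    sub = spec.grid[np.ix_(sel_H, sel_N)]
    if sub.size < 100:
        raise ValueError(f"noise region contains only {sub.size} nodes; need >= 100")
    return float(c * sub.std())


def pca_embed(
    spectra: Sequence[Spectrum2D],
    n_components: int = 2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of flattened spectra across samples.

    Grids are flattened, mean-centred across samples and projected onto
    the top right singular vectors.  The sign of each component is fixed
    by making its largest-magnitude loading positive, so coordinates are
    reproducible.  Returns (coords (n_samples, n_components), explained
    variance fractions).
    """
    if len(spectra) < 2:
        raise ValueError("PCA requires >= 2 spectra")
    first = spectra[0]
    for s in spectra[1:]:
        if not s.same_axes(first):
            raise AxisMismatchError("all spectra must share axis specs for PCA")
    X = np.stack([s.grid.ravel() for s in spectra]).astype(np.float32)
    n_components = min(n_components, len(spectra) - 1, X.shape[1])
    if np.allclose(X, X[0]):
        return np.zeros((len(spectra), n_components)), np.zeros(n_components)
    pca = PCA(n_components=n_components, svd_solver="randomized", random_state=seed)
    coords = pca.fit_transform(X)
    # sign convention: largest-magnitude loading of each component positive
    for k in range(n_components):
        j = int(np.argmax(np.abs(pca.components_[k])))
        if pca.components_[k, j] < 0:
            coords[:, k] *= -1.0
    return coords.astype(float), pca.explained_variance_ratio_.astype(float)


def kmeans_cluster(
    coords: np.ndarray,
    k: int,
    seed: int = 0,
    reference_index: int = 0,
    n_init: int = 10,
) -> np.ndarray:
    """Seeded k-means with k-means++ initialisation and >= 10 restarts.

    Labels are 1-based and renumbered so that cluster 1 contains the
    reference sample; the remaining clusters keep their relative order.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    n = coords.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    if k == 1:
        return np.ones(n, dtype=int)
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    raw = km.fit_predict(coords)
    ref_label = raw[reference_index]
    order = [ref_label] + [c for c in range(k) if c != ref_label]
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.array([remap[c] for c in raw], dtype=int)


def flag_hits(
    results: Sequence[TriageResult],
    reference_id: str,
    dia_mult: float = DEFAULT_DIA_MULT,
    dia_threshold: float | None = None,
) -> list[TriageResult]:
    """Flag samples clustering away from the reference with elevated DIA.

    ``is_hit = (cluster != reference cluster) and (dia > threshold)``
    where the threshold defaults to ``dia_mult × median DIA of the
    reference cluster``.  An absolute ``dia_threshold`` can be supplied
    instead — useful in later deconvolution rounds, where few samples
    remain but the noise-DIA scale is the same as in the first round.
    Returns the updated results.
    """
    by_id = {r.sample_id: r for r in results}
    if reference_id not in by_id:
        raise ValueError(f"reference sample {reference_id!r} not among results")
    ref_cluster = by_id[reference_id].cluster
    if dia_threshold is None:
        ref_dias = [r.dia for r in results if r.cluster == ref_cluster]
        dia_threshold = dia_mult * float(np.median(ref_dias)) if ref_dias else 0.0
    for r in results:
        r.is_hit = (r.cluster != ref_cluster) and (r.dia > dia_threshold)
    return list(results)


def deconvolution_plan(
    hit_plexes: Sequence[str],
    design: PlexDesign,
    next_size: int,
) -> PlexDesign:
    """Split each hit plex into next-round groups of at most ``next_size``.

    Groups are filled in manifest order; fragments from non-hit plexes are
    dropped.  An empty hit set yields an empty plan.
    """
    if next_size >= design.plex_size:
        raise ValueError("next_size must be smaller than the current plex size")
    if next_size < 1:
        raise ValueError("next_size must be >= 1")
    assignments: dict[str, list[str]] = {}
    for plex_id in hit_plexes:
        frags = design.assignments[plex_id]
        for g, start in enumerate(range(0, len(frags), next_size), start=1):
            assignments[f"{plex_id}.{g}"] = frags[start : start + next_size]
    return PlexDesign(assignments=assignments, plex_size=next_size)
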