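"""Data model and I/O for 2D amide-fingerprint NMR data.

The objects here cover the processed side of a protein-observed
¹H-¹⁵N HSQC experiment: an assignment table (the apo fingerprint),
discrete peak lists (Sparky-style ``.list`` files), and gridded 2D
spectra rendered from peak lists with separable Gaussian lineshapes.
Everything downstream (difference spectra, DIA, PCA, peak tracking)
consumes these containers.

Conventions
-----------
* All positions are in ppm; axes are stored ascending in ppm.  Display
  conventions (reversed ppm axes) are presentation-layer only.
* ``Spectrum2D.grid`` has shape ``(n_H, n_N)``: row index runs over the
  ¹H axis, column index over the ¹⁵N axis, both ascending in ppm.
* The Sparky ``.list`` dialect is ``label w1(¹⁵N) w2(¹H) [height]``,
  one peak per line, with an optional header line that is ignored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "Assignment",
    "AssignmentTable",
    "Peak",
    "PeakList",
    "Spectrum2D",
    "read_peak_list",
    "write_peak_list",
    "read_spectrum",
    "write_spectrum",
    "render_spectrum",
    "difference_spectrum",
    "DEFAULT_AXIS_H",
    "DEFAULT_AXIS_N",
    "DEFAULT_LINEWIDTH_H",
    "DEFAULT_LINEWIDTH_N",
]

#: Default amide-region axes: (min ppm, max ppm, points).
DEFAULT_AXIS_H = (6.0, 11.0, 512)
DEFAULT_AXIS_N = (100.0, 135.0, 256)

#: Default Gaussian linewidths (FWHM, ppm).
DEFAULT_LINEWIDTH_H = 0.02
DEFAULT_LINEWIDTH_N = 0.15

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Sparky placeholder for an unassigned peak.
_PLACEHOLDER = "?"


class PeakListParseError(ValueError):
    """Raised when a peak-list file cannot be parsed."""


class AxisMismatchError(ValueError):
    """Raised when two spectra with different axis specs are combined."""


@dataclass(frozen=True)
class Assignment:
    """One assigned amide NH resonance of the apo protein.

    ``suffix`` distinguishes side-chain NH entries (e.g. ``Q69sc``)
    from the backbone amide at the same residue index.
    """

    residue_index: int
    residue_code: str
    delta_H: float
    delta_N: float
    height: float = 1.0
    suffix: str = ""

    def __post_init__(self) -> None:
        if self.residue_index <= 0:
            raise ValueError(f"residue_index must be positive, got {self.residue_index}")
        if len(self.residue_code) != 1 or not self.residue_code.isalpha():
            raise ValueError(f"residue_code must be a one-letter code, got {self.residue_code!r}")
        if not np.isfinite([self.delta_H, self.delta_N, self.height]).all():
            raise ValueError("assignment shifts and height must be finite")

    @property
    def label(self) -> str:
        return f"{self.residue_code}{self.residue_index}{self.suffix}"


class AssignmentTable:
    """Residue-indexed reference ¹H/¹⁵N chemical shifts (the apo fingerprint).

    Backbone entries must be unique and strictly increasing in residue
    index; prolines and unassigned residues are simply absent.  Side-chain
    entries (suffix ``sc``) may share a residue index with a backbone entry
    but labels are globally unique.
    """

    def __init__(self, entries: Iterable[Assignment], name: str = "") -> None:
        entries = list(entries)
        backbone = [e.residue_index for e in entries if not e.suffix]
        if any(b - a <= 0 for a, b in zip(backbone, backbone[1:])):
            raise ValueError("backbone residue indices must be unique and strictly increasing")
        labels = [e.label for e in entries]
        if len(set(labels)) != len(labels):
            raise ValueError("assignment labels must be unique")
        self.entries: list[Assignment] = entries
        self.name = name
        self._by_label = {e.label: e for e in entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Assignment]:
        return iter(self.entries)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.entries]

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def __getitem__(self, label: str) -> Assignment:
        return self._by_label[label]

    def code_of(self, label: str) -> str:
        """One-letter residue code for an assignment label."""
        return self._by_label[label].residue_code

    def positions(self) -> dict[str, tuple[float, float]]:
        """Mapping label -> (delta_H, delta_N) in ppm."""
        return {e.label: (e.delta_H, e.delta_N) for e in self.entries}

    def to_peak_list(self, sample_id: str = "apo") -> "PeakList":
        peaks = [Peak(e.delta_H, e.delta_N, e.height, e.label) for e in self.entries]
        return PeakList(peaks, sample_id=sample_id)


@dataclass
class Peak:
    delta_H: float
    delta_N: float
    height: float = 1.0
    label: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite([self.delta_H, self.delta_N, self.height]).all():
            raise ValueError("peak position and height must be finite")


@dataclass
class PeakList:
    """Discrete peaks of one sample plus its solution conditions.

    ``conditions`` maps additive name -> total concentration in mM;
    ``protein_conc`` is the (labelled) protein concentration in μM.
    """

    peaks: list[Peak]
    sample_id: str
    conditions: dict[str, float] = field(default_factory=dict)
    protein_conc: float = 50.0

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if any(c < 0 for c in self.conditions.values()):
            raise ValueError("concentrations must be >= 0")
        labels = [p.label for p in self.peaks if p.label is not None]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate peak labels in peak list")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def by_label(self) -> dict[str, Peak]:
        return {p.label: p for p in self.peaks if p.label is not None}

    def positions(self) -> np.ndarray:
        """(n, 2) array of (delta_H, delta_N)."""
        return np.array([[p.delta_H, p.delta_N] for p in self.peaks], dtype=float).reshape(-1, 2)


@dataclass
class Spectrum2D:
    """Gridded 2D intensities with ascending ppm axes.

    ``axis_H``/``axis_N`` are (min ppm, max ppm, point count); the grid has
    shape (n_H, n_N) with rows over ¹H.
    """

    grid: np.ndarray
    axis_H: tuple[float, float, int]
    axis_N: tuple[float, float, int]
    sample_id: str
    conditions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (lo, hi, n) in (("axis_H", self.axis_H), ("axis_N", self.axis_N)):
            if n < 2:
                raise ValueError(f"{name} must have >= 2 points")
            if not lo < hi:
                raise ValueError(f"{name} min must be < max (got {lo} >= {hi})")
        self.axis_H = (float(self.axis_H[0]), float(self.axis_H[1]), int(self.axis_H[2]))
        self.axis_N = (float(self.axis_N[0]), float(self.axis_N[1]), int(self.axis_N[2]))
        expected = (self.axis_H[2], self.axis_N[2])
        if self.grid.shape != expected:
            raise ValueError(f"grid shape {self.grid.shape} does not match axes {expected}")

    def ppm_H(self) -> np.ndarray:
        lo, hi, n = self.axis_H
        return np.linspace(lo, hi, n)

    def ppm_N(self) -> np.ndarray:
        lo, hi, n = self.axis_N
        return np.linspace(lo, hi, n)

    def same_axes(self, other: "Spectrum2D") -> bool:
        return self.axis_H == other.axis_H and self.axis_N == other.axis_N


# ---------------------------------------------------------------------------
# Sparky-style .list I/O
# ---------------------------------------------------------------------------

def _format_label(label: str | None) -> str:
    if label is None:
        return _PLACEHOLDER
    return f"{label}N-H"


def _parse_label(token: str) -> str | None:
    if token in (_PLACEHOLDER, "?-?", "?N-H"):
        return None
    if token.endswith("N-H"):
        return token[:-3]
    if token.endswith("N-HN"):
        return token[:-4]
    return token


def read_peak_list(path: str | Path) -> PeakList:
    """Read a Sparky-style ``.list`` file.

    Columns are ``label w1(¹⁵N) w2(¹H) [height]``; a non-numeric header
    line is skipped.  The sample id is the file stem.  Malformed lines
    raise :class:`PeakListParseError` naming the line number; duplicate
    (non-placeholder) labels raise ``ValueError``.
    """
    path = Path(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            tokens = line.split()
            if lineno == 1 and len(tokens) >= 3:
                # optional header ("Assignment w1 w2 ...")
                try:
                    float(tokens[1])
                except ValueError:
                    continue
            if len(tokens) < 3:
                raise PeakListParseError(f"{path}:{lineno}: expected >= 3 columns, got {len(tokens)}")
            try:
                w1 = float(tokens[1])  # ¹⁵N
                w2 = float(tokens[2])  # ¹H
                height = float(tokens[3]) if len(tokens) > 3 else 1.0
            except ValueError as exc:
                raise PeakListParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            peaks.append(Peak(delta_H=w2, delta_N=w1, height=height, label=_parse_label(tokens[0])))
    return PeakList(peaks, sample_id=path.stem)


def write_peak_list(pl: PeakList, path: str | Path) -> None:
    """Write a peak list in the Sparky dialect read by :func:`read_peak_list`.

    Positions are written with 4-decimal ppm precision (the round-trip
    contract); unlabeled peaks get the ``?`` placeholder.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{'Assignment':>17s} {'w1':>9s} {'w2':>9s} {'Data Height':>14s}\n")
        for p in pl.peaks:
            fh.write(
                f"{_format_label(p.label):>17s} {p.delta_N:9.4f} {p.delta_H:9.4f} {p.height:14.6e}\n"
            )


# ---------------------------------------------------------------------------
# Spectrum2D I/O: JSON sidecar header + dense CSV matrix
# ---------------------------------------------------------------------------

def write_spectrum(spec: Spectrum2D, basepath: str | Path) -> None:
    """Write ``<base>.json`` (axes, sample id, conditions) + ``<base>.csv``.

    The CSV matrix has one row per ¹H grid point (ascending ppm) and one
    column per ¹⁵N grid point (ascending ppm).
    """
    base = Path(basepath)
    header = {
        "sample_id": spec.sample_id,
        "axis_H": list(spec.axis_H),
        "axis_N": list(spec.axis_N),
        "conditions": spec.conditions,
    }
    base.with_suffix(".json").write_text(json.dumps(header, indent=1))
    np.savetxt(base.with_suffix(".csv"), spec.grid, delimiter=",")


def read_spectrum(basepath: str | Path) -> Spectrum2D:
    base = Path(basepath)
    header = json.loads(base.with_suffix(".json").read_text())
    grid = np.loadtxt(base.with_suffix(".csv"), delimiter=",", ndmin=2)
    return Spectrum2D(
        grid=grid,
        axis_H=tuple(header["axis_H"]),
        axis_N=tuple(header["axis_N"]),
        sample_id=header["sample_id"],
        conditions=dict(header.get("conditions", {})),
    )


# ---------------------------------------------------------------------------
# Rendering and difference spectra
# ---------------------------------------------------------------------------

def render_spectrum(
    pl: PeakList,
    axis_H: tuple[float, float, int] = DEFAULT_AXIS_H,
    axis_N: tuple[float, float, int] = DEFAULT_AXIS_N,
    linewidth_H: float = DEFAULT_LINEWIDTH_H,
    linewidth_N: float = DEFAULT_LINEWIDTH_N,
) -> Spectrum2D:
    """Render a peak list onto a grid with separable Gaussian lineshapes.

    Each peak contributes ``height * exp(-ΔH²/2σ_H²) * exp(-ΔN²/2σ_N²)``
    (σ = FWHM/2.355), so the grid maximum of an isolated peak centred on a
    grid node equals its height.  Contributions are summed (rendering is
    linear in heights and in list concatenation); peaks outside the window
    contribute their tails.
    """
    if linewidth_H <= 0 or linewidth_N <= 0:
        raise ValueError("linewidths must be > 0")
    for name, (lo, hi, n) in (("axis_H", axis_H), ("axis_N", axis_N)):
        if not lo < hi:
            raise ValueError(f"{name}: min must be < max")
        if int(n) < 2:
            raise ValueError(f"{name}: need >= 2 points")
    hH = np.linspace(axis_H[0], axis_H[1], int(axis_H[2]))
    hN = np.linspace(axis_N[0], axis_N[1], int(axis_N[2]))
    grid = np.zeros((hH.size, hN.size))
    if pl.peaks:
        pos = pl.positions()
        heights = np.array([p.height for p in pl.peaks])
        sig_H = linewidth_H * _FWHM_TO_SIGMA
        sig_N = linewidth_N * _FWHM_TO_SIGMA
        gH = np.exp(-0.5 * ((hH[None, :] - pos[:, 0:1]) / sig_H) ** 2)  # (npeaks, nH)
        gN = np.exp(-0.5 * ((hN[None, :] - pos[:, 1:2]) / sig_N) ** 2)  # (npeaks, nN)
        grid = (gH * heights[:, None]).T @ gN
    return Spectrum2D(
        grid=grid,
        axis_H=(axis_H[0], axis_H[1], int(axis_H[2])),
        axis_N=(axis_N[0], axis_N[1], int(axis_N[2])),
        sample_id=pl.sample_id,
        conditions=dict(pl.conditions),
    )


def difference_spectrum(a: Spectrum2D, b: Spectrum2D) -> Spectrum2D:
    """Elementwise ``a - b``; both spectra must share axis specs exactly.

    No silent resampling: an axis mismatch raises :class:`AxisMismatchError`.
    The result records both parent sample ids.
    """
    if not a.same_axes(b):
        raise AxisMismatchError(
            f"axis mismatch: {a.axis_H}/{a.axis_N} vs {b.axis_H}/{b.axis_N}"
        )
    conditions: dict[str, float] = {**b.conditions, **a.conditions}
    return Spectrum2D(
        grid=a.grid - b.grid,
        axis_H=a.axis_H,
        axis_N=a.axis_N,
        sample_id=f"diff({a.sample_id},{b.sample_id})",
        conditions=conditions,
    )
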