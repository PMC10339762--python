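"""End-to-end pipeline orchestration and structured configuration.

Runs the complete synthetic screening campaign: pooled 12-plex -> 3-plex
-> single-compound triage, titration validation with Kd fitting and
binding classification, sub-site assignment of the validated hits,
sulfotyrosine hotspot mapping, and dual-fragment additivity analysis.
Every stage draws its randomness from seeds derived deterministically
from the single configured seed, so a rerun with the same configuration
reproduces the summary byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import synth
from .spectra import (
    AssignmentTable,
    Peak,
    PeakList,
    Spectrum2D,
    difference_spectrum,
    render_spectrum,
)
from .synth import (
    DualSchedule,
    FragmentRecord,
    PlexDesign,
    SITE1_RESIDUES,
    SITE2_RESIDUES,
    TitrationSeries,
    simulate_dual,
    simulate_sample,
    simulate_titration,
)
from .triage import TriageResult, dia_statistic, deconvolution_plan, flag_hits, kmeans_cluster, pca_embed
from .binding import ValidationSummary, validate_candidates
from .csp import assign_site, csp_profile, hotspot_by_absolute_threshold

__all__ = ["PipelineConfig", "run_screen", "run_pipeline", "REFERENCE_ID"]

logger = logging.getLogger("hsqcscreen")

REFERENCE_ID = "REF-DMSO"

_ROUND_NAMES = {12: "12plex", 3: "3plex", 1: "single"}


@dataclass
class PipelineConfig:
    """All knobs of the screening pipeline, serialisable to YAML.

    Concentrations follow the study conditions: 50 μM protein, 500 μM
    per fragment in pooled screening, validation titrations to 6 mM,
    dual titrations to 3 mM, and the 1–100 mM sulfotyrosine ladder.

    Triage renders spectra with deliberately broadened linewidths
    (``triage_linewidths``) on a 512×512 grid: broadening acts like the
    apodisation applied to real screening spectra and keeps the DIA
    statistic insensitive to sub-pixel peak placement, while positional
    noise lobes stay far below the DIA floor
    (``dia_floor_frac`` × median apo peak height).
    """

    seed: int = 2028
    protein_conc: float = 50.0               # μM
    screen_conc: float = 0.5                 # mM per fragment in pooled rounds
    titration_totals: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0)  # mM
    styr_totals: tuple[float, ...] = (0.0, 1.0, 5.0, 10.0, 20.0, 50.0, 75.0, 100.0)  # mM
    dual_conc: float = 3.0                   # mM endpoint for each dual fragment
    dual_totals: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 3.0)  # mM, varied ligand
    noise_sd: tuple[float, float] = (0.004, 0.02)  # ppm (¹H, ¹⁵N)
    n_sd: float = 2.0                        # CSP significance, mean + n_sd·SD
    hotspot_cutoff: float = 0.6              # ppm, absolute sTyr hotspot rule
    dia_mult: float = 4.0                    # flag_hits fallback: dia > mult × ref-cluster median
    dia_floor_frac: float = 0.35             # DIA floor as fraction of median apo height
    dia_peak_frac: float = 0.8               # hit threshold in units of one displaced peak's DIA
    dual_tolerance: float = 0.02             # scaled ppm
    pca_components: int = 5
    kmeans_k: int = 12
    triage_axis_H: tuple[float, float, int] = (6.0, 11.0, 512)
    triage_axis_N: tuple[float, float, int] = (100.0, 135.0, 512)
    triage_linewidths: tuple[float, float] = (0.05, 0.5)  # ppm FWHM (¹H, ¹⁵N)
    track_max_jump: float = 0.25             # scaled ppm
    styr_max_jump: float = 0.45              # scaled ppm (coarse sTyr ladder)
    plex_rounds: tuple[int, ...] = (12, 3, 1)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in data.items():
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(value, list):
                value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
            kwargs[key] = value
        return cls(**kwargs)


def _stage_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def _sample_seeds(seed: int, stage: int, n: int) -> list[int]:
    return [int(s % (2**31)) for s in np.random.SeedSequence([seed, stage]).generate_state(n)]


def _peak_displacement_dia(assign: AssignmentTable, cfg: PipelineConfig) -> float:
    """DIA contributed by one median-height peak moving far from its
    apo position: twice the supra-floor volume of a single rendered peak.

    This is the natural absolute scale of the DIA statistic under the
    triage rendering settings — noise lobes stay well below one full
    peak displacement, while any real binder displaces at least one
    peak.  Used to set the hit threshold identically in every round.
    """
    med_h = float(np.median([e.height for e in assign]))
    center = Peak(
        delta_H=0.5 * (cfg.triage_axis_H[0] + cfg.triage_axis_H[1]),
        delta_N=0.5 * (cfg.triage_axis_N[0] + cfg.triage_axis_N[1]),
        height=med_h,
    )
    one = _render_triage(
        PeakList([center], sample_id="unit-peak", protein_conc=cfg.protein_conc), cfg
    )
    floor = cfg.dia_floor_frac * med_h
    grid = np.abs(one.grid)
    return 2.0 * float(grid[grid > floor].sum())


def _render_triage(pl, cfg: PipelineConfig) -> Spectrum2D:
    spec = render_spectrum(
        pl,
        axis_H=cfg.triage_axis_H,
        axis_N=cfg.triage_axis_N,
        linewidth_H=cfg.triage_linewidths[0],
        linewidth_N=cfg.triage_linewidths[1],
    )
    spec.grid = spec.grid.astype(np.float32)
    return spec


def _screen_round(
    assign: AssignmentTable,
    frag_map: Mapping[str, FragmentRecord],
    design: PlexDesign,
    cfg: PipelineConfig,
    round_name: str,
    stage: int,
    dia_threshold: float | None = None,
) -> tuple[list[TriageResult], list[str], float]:
    """Simulate, render and triage one pooled screening round.

    Returns the triage results, the flagged plex ids, and the DIA
    threshold applied (computed from the reference-cluster median when
    not supplied)."""
    plex_ids = list(design.assignments)
    seeds = _sample_seeds(cfg.seed, stage, len(plex_ids) + 1)
    ref_pl = simulate_sample(
        assign, [], protein_conc=cfg.protein_conc, noise_sd=cfg.noise_sd,
        seed=seeds[0], sample_id=REFERENCE_ID,
    )
    ref_spec = _render_triage(ref_pl, cfg)
    dia_floor = cfg.dia_floor_frac * float(np.median([e.height for e in assign]))

    spectra = [ref_spec]
    results = [TriageResult(REFERENCE_ID, 0.0, [], round=round_name)]
    for plex_id, seed in zip(plex_ids, seeds[1:]):
        frags = [(frag_map[fid], cfg.screen_conc) for fid in design.assignments[plex_id]]
        pl = simulate_sample(
            assign, frags, protein_conc=cfg.protein_conc, noise_sd=cfg.noise_sd,
            seed=seed, sample_id=plex_id,
        )
        spec = _render_triage(pl, cfg)
        dia = dia_statistic(difference_spectrum(spec, ref_spec), noise_floor=dia_floor)
        lineage = plex_id.split(".")[:-1] if "." in plex_id else []
        results.append(TriageResult(plex_id, dia, [], round=round_name,
                                    lineage=[".".join(lineage[: i + 1]) for i in range(len(lineage))]))
        spectra.append(spec)

    coords, _ = pca_embed(spectra, n_components=cfg.pca_components,
                          seed=_stage_seed(cfg.seed, stage + 100))
    k = min(cfg.kmeans_k, len(spectra))
    labels = kmeans_cluster(coords, k=k, seed=_stage_seed(cfg.seed, stage + 200),
                            reference_index=0)
    for r, c, lab in zip(results, coords, labels):
        r.pca_coords = [float(x) for x in c]
        r.cluster = int(lab)
    if dia_threshold is None:
        ref_cluster = results[0].cluster
        ref_dias = [r.dia for r in results if r.cluster == ref_cluster]
        dia_threshold = cfg.dia_mult * float(np.median(ref_dias))
    flag_hits(results, REFERENCE_ID, dia_threshold=dia_threshold)
    hit_plexes = [r.sample_id for r in results if r.is_hit and r.sample_id != REFERENCE_ID]
    logger.info("round %s: %d samples, %d flagged (DIA threshold %.1f)",
                round_name, len(results) - 1, len(hit_plexes), dia_threshold)
    return results, hit_plexes, dia_threshold


def run_screen(
    assign: AssignmentTable,
    fragments: Sequence[FragmentRecord],
    design: PlexDesign,
    cfg: PipelineConfig,
) -> tuple[dict[str, list[TriageResult]], list[str]]:
    """Iterative multiplexed triage (12-plex -> 3-plex -> single).

    Returns per-round triage results and the single-compound candidate
    fragment ids.
    """
    frag_map = {f.fragment_id: f for f in fragments}
    rounds: dict[str, list[TriageResult]] = {}
    current = design
    hit_plexes: list[str] = []
    # absolute hit threshold: a fraction of one displaced peak's DIA,
    # identical in every round (the noise-DIA scale does not change)
    dia_threshold = cfg.dia_peak_frac * _peak_displacement_dia(assign, cfg)
    for stage, size in enumerate(cfg.plex_rounds):
        name = _ROUND_NAMES.get(size, f"{size}plex")
        if stage > 0:
            current = deconvolution_plan(hit_plexes, current, next_size=size)
        if not current.assignments:
            rounds[name] = []
            hit_plexes = []
            continue
        results, hit_plexes, dia_threshold = _screen_round(
            assign, frag_map, current, cfg, name, stage, dia_threshold=dia_threshold
        )
        rounds[name] = results
    candidates = [
        fid for plex_id in hit_plexes for fid in current.assignments[plex_id]
    ]
    return rounds, candidates


def run_pipeline(
    cfg: PipelineConfig,
    outdir: str | Path | None = None,
    fixture: tuple[AssignmentTable, list[FragmentRecord], PlexDesign] | None = None,
) -> dict:
    """Full campaign on the packaged fixture (or a supplied one).

    Stages: screen (3 rounds) -> validation titrations (Kd fit +
    classification) -> sub-site assignment of the specific hits ->
    sulfotyrosine hotspot mapping -> dual-fragment additivity.  Returns a
    machine-readable summary and, if ``outdir`` is given, writes TSV/JSON
    artifacts plus a config snapshot.
    """
    if fixture is None:
        fixture = synth.make_ccl28_fixture(cfg.seed)
    assign, fragments, design = fixture
    frag_map = {f.fragment_id: f for f in fragments}

    summary: dict = {"seed": cfg.seed, "n_screened": len(fragments)}
    if not fragments:
        summary.update(n_candidates=0, candidate_rate_percent=0.0, n_hits=0,
                       n_nonhits=0, counts={}, rounds={})
        if outdir is not None:
            _write_artifacts(Path(outdir), cfg, {}, None, summary)
        return summary

    rounds, candidates = run_screen(assign, fragments, design, cfg)
    summary["rounds"] = {
        name: {
            "n_samples": max(len(res) - 1, 0),
            "n_flagged": sum(r.is_hit for r in res),
        }
        for name, res in rounds.items()
    }
    summary["n_candidates"] = len(candidates)
    summary["candidate_rate_percent"] = round(100.0 * len(candidates) / len(fragments), 1)
    summary["candidates"] = sorted(candidates)

    # --- validation titrations -------------------------------------------
    val_seeds = _sample_seeds(cfg.seed, 1000, max(len(candidates), 1))
    series_by_id: dict[str, TitrationSeries] = {}
    for fid, s in zip(sorted(candidates), val_seeds):
        series_by_id[fid] = simulate_titration(
            assign, frag_map[fid], cfg.titration_totals,
            protein_conc=cfg.protein_conc, noise_sd=cfg.noise_sd, seed=s,
        )
    validation = validate_candidates(
        list(series_by_id.values()), assign,
        site_definitions={"site1_Nloop_helix": SITE1_RESIDUES,
                          "site2_sY_cleft": SITE2_RESIDUES},
        n_sd=cfg.n_sd, max_jump=cfg.track_max_jump,
    )
    summary["counts"] = validation.counts
    summary["n_hits"] = validation.counts["specific"]
    summary["n_nonhits"] = (
        validation.counts["nonspecific"] + validation.counts["pH_artifact"]
    )
    summary["kd_table"] = {
        fid: {
            "kd_mM": round(fit.kd_estimate, 4),
            "kd_stderr_mM": round(fit.kd_stderr, 4) if np.isfinite(fit.kd_stderr) else None,
            "class": cls.label,
            "rationale": cls.rationale,
        }
        for fid, (fit, cls) in sorted(validation.results.items())
    }

    # --- sub-site assignment of the specific hits ------------------------
    site_defs = {"site1_Nloop_helix": set(SITE1_RESIDUES), "site2_sY_cleft": set(SITE2_RESIDUES)}
    split = {"site1_Nloop_helix": 0, "site2_sY_cleft": 0, "both": 0, "unassigned": 0}
    site_of: dict[str, str] = {}
    for fid in validation.hits:
        profile = csp_profile(series_by_id[fid], max_jump=cfg.track_max_jump)
        sa = assign_site(profile, site_defs, n_sd=cfg.n_sd)
        split[sa.site] += 1
        site_of[fid] = sa.site
    summary["site_split"] = split
    summary["site_assignments"] = site_of

    # --- sulfotyrosine hotspot mapping ------------------------------------
    styr = synth.make_sulfotyrosine_probe(cfg.seed)
    styr_series = simulate_titration(
        assign, styr, cfg.styr_totals, protein_conc=cfg.protein_conc,
        noise_sd=cfg.noise_sd, seed=_stage_seed(cfg.seed, 2000),
    )
    styr_profile = csp_profile(styr_series, max_jump=cfg.styr_max_jump)
    summary["styr_hotspots"] = sorted(
        hotspot_by_absolute_threshold(styr_profile, cfg.hotspot_cutoff)
    )

    # --- dual titrations ---------------------------------------------------
    summary["dual"] = {}
    if "SPB07625" in frag_map and "CC10501" in frag_map:
        from .dual import analyze_dual  # local import to avoid cycle at module load

        pairs = {
            "independent_sites": (frag_map["SPB07625"], frag_map["CC10501"]),
        }
        if "SY2-03" in frag_map:  # a second sY-cleft binder: shared-site control
            pairs["competitive"] = (frag_map["SPB07625"], frag_map["SY2-03"])
        for mode, (fa, fb) in pairs.items():
            seeds = _sample_seeds(cfg.seed, 3000 + len(mode), 4)
            single_a = simulate_titration(assign, fa, cfg.dual_totals, cfg.protein_conc,
                                          cfg.noise_sd, seed=seeds[0])
            single_b = simulate_titration(assign, fb, cfg.dual_totals, cfg.protein_conc,
                                          cfg.noise_sd, seed=seeds[1])
            sched_ab = DualSchedule((fb.fragment_id, cfg.dual_conc), fa.fragment_id,
                                    list(cfg.dual_totals), mode=mode)
            sched_ba = DualSchedule((fa.fragment_id, cfg.dual_conc), fb.fragment_id,
                                    list(cfg.dual_totals), mode=mode)
            dual_ab = simulate_dual(assign, fa, fb, sched_ab, cfg.protein_conc,
                                    cfg.noise_sd, seed=seeds[2])
            dual_ba = simulate_dual(assign, fb, fa, sched_ba, cfg.protein_conc,
                                    cfg.noise_sd, seed=seeds[3])
            res = analyze_dual(dual_ab, dual_ba, single_a, single_b,
                               tolerance=cfg.dual_tolerance, max_jump=cfg.track_max_jump,
                               n_sd=cfg.n_sd)
            summary["dual"][mode] = {
                "pair": list(res.pair),
                "aggregate_residual_ppm": round(res.aggregate_residual, 5),
                "order_discrepancy_ppm": round(res.order_discrepancy, 5),
                "verdict": res.verdict,
            }

    if outdir is not None:
        _write_artifacts(Path(outdir), cfg, rounds, validation, summary)
    return summary


def _write_artifacts(
    outdir: Path,
    cfg: PipelineConfig,
    rounds: Mapping[str, list[TriageResult]],
    validation: ValidationSummary | None,
    summary: dict,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    for name, results in rounds.items():
        if not results:
            continue
        pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in results],
                "dia": [r.dia for r in results],
                "cluster": [r.cluster for r in results],
                "is_hit": [r.is_hit for r in results],
                "pc1": [r.pca_coords[0] if r.pca_coords else np.nan for r in results],
                "pc2": [r.pca_coords[1] if len(r.pca_coords) > 1 else np.nan for r in results],
                "lineage": ["|".join(r.lineage) for r in results],
            }
        ).to_csv(outdir / f"triage_{name}.tsv", sep="\t", index=False)
    if validation is not None:
        rows = []
        for fid, (fit, cls) in sorted(validation.results.items()):
            rows.append(
                {
                    "fragment_id": fid,
                    "kd_mM": fit.kd_estimate,
                    "kd_stderr_mM": fit.kd_stderr,
                    "converged": fit.converged,
                    "at_bound": fit.at_bound,
                    "class": cls.label,
                    "rationale": cls.rationale,
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "validation.tsv", sep="\t", index=False)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    logger.info("artifacts written to %s", outdir)
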