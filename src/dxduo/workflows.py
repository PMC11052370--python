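"""Dual-probe workflows tying the pipeline stages together.

``run_dual_dxb`` reproduces the blinking workflow (per-ring pixel ACF decay
statistics, mobility-group decomposition, cross-condition rank-sum tests,
optional radiation-damage check); ``run_dual_dxt`` the tracking workflow
(spot detection/linking or pre-tracked input, ring routing, angular
decomposition, lifetime filtering, MSD fits, theta-chi motion maps with
subtraction and hotspot comparisons). Both operate on in-memory arrays and
are wrapped by the CLI for file-driven runs.
"""

from __future__ import annotations

import itertools
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dxb import (
    ACFCurve,
    DecaySample,
    MixtureFitError,
    acf_matrix,
    compare_distributions,
    decay_stats,
    fit_acf_exponential,
    fit_two_gaussians,
    radiation_damage_check,
)
from .dxt import (
    SpotTrajectory,
    build_motion_hist,
    compute_msd,
    detect_spots,
    filter_by_lifetime,
    fit_msd,
    link_spots,
    normalize_i0,
    peak_and_fwhm,
    route_trajectories,
    subtract_hists,
    superpose_hotspots,
    to_angular,
)
from .geometry import ConfigError, RingROI
from .io import GeometryConfig, RunReport

__all__ = ["run_dual_dxb", "run_dual_dxt"]


def _ring_groups(
    rois: Sequence[RingROI], pool_by_phase: bool
) -> dict[str, list[RingROI]]:
    phases = {r.phase for r in rois}
    if len(phases) < 2:
        raise ConfigError(
            "dual workflow requires rings from at least two distinct phases"
        )
    if not pool_by_phase:
        return {r.label: [r] for r in rois}
    groups: dict[str, list[RingROI]] = {}
    for roi in rois:
        same_phase = [r for r in rois if r.phase == roi.phase]
        key = roi.label if len(same_phase) == 1 else f"{roi.phase}(pooled)"
        groups.setdefault(key, []).append(roi)
    return groups


def _ring_decay_sample(
    stack: np.ndarray,
    rois: Sequence[RingROI],
    frame_interval_s: float,
    label: str,
    condition: str,
    max_lag_frames: int | None,
    seed: int,
    report: RunReport,
) -> tuple[DecaySample, pd.DataFrame]:
    rows = []
    ts = []
    attempted = 0
    degenerate_count = 0
    for roi in rois:
        intens = stack[:, roi.pixels[:, 0], roi.pixels[:, 1]].T.astype(float)
        n = intens.shape[1]
        mlag = max_lag_frames if max_lag_frames is not None else max(1, n // 4)
        lags, values, degenerate = acf_matrix(intens, mlag, frame_interval_s)
        for i in range(values.shape[0]):
            if degenerate[i]:
                degenerate_count += 1
                continue
            attempted += 1
            curve = ACFCurve(
                lags=lags, values=values[i],
                n_pairs=np.arange(n, n - mlag - 1, -1),
            )
            fit = fit_acf_exponential(curve, seed=seed)
            rows.append(
                {
                    "pixel_row": int(roi.pixels[i, 0]),
                    "pixel_col": int(roi.pixels[i, 1]),
                    "ring_label": roi.label,
                    "k": fit.k, "A": fit.A, "T": fit.T,
                    "accepted": fit.accepted,
                    "residual_norm": fit.residual_norm,
                }
            )
            if fit.accepted:
                ts.append(fit.T)
    report.add_stage(
        f"dxb_fits[{condition}/{label}]",
        attempted=attempted, accepted=len(ts),
        degenerate_pixels_excluded=degenerate_count,
    )
    if degenerate_count:
        report.warn(
            f"{condition}/{label}: {degenerate_count} all-zero pixels excluded"
        )
    sample = DecaySample(
        values=np.array(ts), condition=condition, domain_label=label
    )
    return sample, pd.DataFrame(rows)


def run_dual_dxb(
    stacks: Mapping[str, np.ndarray],
    config: GeometryConfig,
    *,
    max_lag_frames: int | None = None,
    seed: int = 0,
    pool_by_phase: bool = True,
    damage_check: bool = False,
    out_dir: str | Path | None = None,
) -> dict:
    """Dual-probe DXB analysis of one or more conditions.

    For each ring group (by default Au rings per index, ZnO rings pooled)
    and condition: extract pixel traces, compute ACFs, fit exponentials,
    apply the acceptance filter, then summarise (box statistics, two-Gaussian
    mobility decomposition where the sample is large enough) and compare all
    condition pairs with the rank-sum test. Returns a results dict including
    the reconciled RunReport.
    """
    rois = config.build_rois()
    groups = _ring_groups(rois, pool_by_phase)
    report = RunReport(
        tool_version=__version__,
        config_echo={
            "workflow": "dual-dxb",
            "rings": [r.label for r in rois],
            "groups": sorted(groups),
            "conditions": sorted(stacks),
            "max_lag_frames": max_lag_frames,
            "pool_by_phase": pool_by_phase,
        },
        seeds={"fit": seed},
    )
    dt = config.detector.frame_interval_s
    results: dict = {"samples": {}, "stats": {}, "mixtures": {}, "fits": {},
                     "comparisons": {}, "damage": {}}
    for cond, stack in stacks.items():
        report.add_input(f"stack[{cond}]", [stack.shape, str(stack.dtype)])
        for label, group_rois in groups.items():
            sample, fits = _ring_decay_sample(
                stack, group_rois, dt, label, cond, max_lag_frames, seed, report
            )
            results["samples"][(cond, label)] = sample
            results["fits"][(cond, label)] = fits
            if sample.values.size:
                results["stats"][(cond, label)] = decay_stats(sample)
            if sample.values.size >= 50:
                try:
                    results["mixtures"][(cond, label)] = fit_two_gaussians(
                        sample, seed=seed
                    )
                except MixtureFitError as e:
                    report.warn(f"{cond}/{label}: mixture fit failed: {e}")
        if damage_check:
            for label, group_rois in groups.items():
                results["damage"][(cond, label)] = radiation_damage_check(
                    stack, group_rois[0], dt, seed=seed
                )
    for label in groups:
        for ca, cb in itertools.combinations(sorted(stacks), 2):
            sa = results["samples"].get((ca, label))
            sb = results["samples"].get((cb, label))
            if sa is not None and sb is not None and sa.values.size and sb.values.size:
                results["comparisons"][(ca, cb, label)] = compare_distributions(sa, sb)
    results["report"] = report
    if out_dir is not None:
        _write_dxb_outputs(results, Path(out_dir))
    return results


def _write_dxb_outputs(results: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for (cond, label), fits in results["fits"].items():
        fits.to_csv(out_dir / f"fits_{cond}_{label}.csv".replace("/", "-"),
                    index=False)
    summary = {}
    for (cond, label), stats in results["stats"].items():
        summary.setdefault(cond, {})[label] = stats._asdict()
    for (cond, label), mix in results["mixtures"].items():
        entry = summary.setdefault(cond, {}).setdefault(label, {})
        entry["mixture"] = {
            k: getattr(mix, k)
            for k in ("mu1", "sigma1", "mu2", "sigma2", "pct1", "pct2")
        }
    comps = {
        f"{ca} vs {cb} [{label}]": dict(res._asdict())
        for (ca, cb, label), res in results["comparisons"].items()
    }
    import json

    (out_dir / "summary.json").write_text(
        json.dumps({"distributions": summary, "comparisons": comps}, indent=2)
    )
    results["report"].to_json(out_dir / "run_report.json")


def _trajectories_from_stack(
    stack: np.ndarray,
    config: GeometryConfig,
    i0: np.ndarray | None,
    min_intensity: float,
    max_disp_px: float,
    memory_frames: int,
) -> list[SpotTrajectory]:
    geom = config.detector
    movie = stack.astype(float)
    if i0 is not None:
        movie = normalize_i0(movie, i0)
    per_frame = [
        detect_spots(movie[f], geom, min_intensity=min_intensity, frame_index=f)
        for f in range(movie.shape[0])
    ]
    return link_spots(per_frame, max_disp_px=max_disp_px,
                      memory_frames=memory_frames)


def run_dual_dxt(
    conditions: Mapping[str, np.ndarray | Sequence[SpotTrajectory]],
    config: GeometryConfig,
    *,
    i0: Mapping[str, np.ndarray] | None = None,
    min_lifetime_frames: int = 5,
    max_lifetime_frames: float = float("inf"),
    lag_frames: int = 1,
    bins: int = 50,
    min_intensity: float = 5.0,
    max_disp_px: float = 5.0,
    memory_frames: int = 2,
    routing_tolerance_px: float = 2.0,
    hotspot_quantile: float = 0.90,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Dual-probe DXT analysis across experimental conditions.

    Each condition supplies either a movie stack (tracked here) or
    pre-tracked trajectories. Trajectories are routed to rings by mean
    radius, decomposed into (chi, theta), lifetime-filtered and MSD-fitted;
    per ring, theta-chi motion histograms share bin edges across conditions
    so subtraction maps and hotspot superpositions are well defined for
    every condition pair.
    """
    rois = config.build_rois()
    if len({r.phase for r in rois}) < 2:
        raise ConfigError(
            "dual workflow requires rings from at least two distinct phases"
        )
    report = RunReport(
        tool_version=__version__,
        config_echo={
            "workflow": "dual-dxt",
            "rings": [r.label for r in rois],
            "conditions": sorted(conditions),
            "min_lifetime_frames": min_lifetime_frames,
            "lag_frames": lag_frames,
            "bins": bins,
            "angular_convention": (
                "chi = unwrapped azimuth about beam axis; "
                "theta = 0.5 * delta(2theta_scatter)"
            ),
            "axis_statistic": f"log10 temporal MSD at lag {lag_frames} frames",
        },
        seeds={"run": seed},
    )
    geom = config.detector
    results: dict = {"angular": {}, "msd_fits": {}, "hists": {},
                     "marginals": {}, "peaks": {}, "subtractions": {},
                     "hotspots": {}, "trajectories": {}}

    for cond, data in conditions.items():
        if isinstance(data, np.ndarray):
            if i0 is not None and cond not in i0:
                raise ConfigError(f"I0 series missing for condition {cond!r}")
            trajs = _trajectories_from_stack(
                data, config, i0[cond] if i0 is not None else None,
                min_intensity, max_disp_px, memory_frames,
            )
            report.add_input(f"stack[{cond}]", [data.shape, str(data.dtype)])
        else:
            trajs = list(data)
            report.add_input(f"trajectories[{cond}]", len(trajs))
        routed, routing = route_trajectories(trajs, rois, routing_tolerance_px)
        report.add_stage(
            f"routing[{cond}]", attempted=len(trajs),
            accepted=routing["assigned"],
            unassigned=routing["unassigned"], ambiguous=routing["ambiguous"],
        )
        kept = filter_by_lifetime(routed, min_lifetime_frames, max_lifetime_frames)
        report.add_stage(
            f"lifetime_filter[{cond}]", attempted=len(routed), accepted=len(kept),
        )
        results["trajectories"][cond] = kept
        for roi in rois:
            ring_trajs = [t for t in kept if t.ring_label == roi.label]
            angulars = [to_angular(t, geom) for t in ring_trajs
                        if len(t.spots) >= 4]
            results["angular"][(cond, roi.label)] = angulars
            fits = []
            for a in angulars:
                if len(a) < 16:  # fewer than 4 temporal-MSD lags
                    continue
                row = {"trajectory_id": a.trajectory_id}
                for axis in ("chi", "theta"):
                    f = fit_msd(compute_msd(a, axis=axis))
                    row.update(
                        {
                            f"D_alpha_{axis}": f.D_alpha,
                            f"alpha_{axis}": f.alpha,
                            f"beta_{axis}": f.beta,
                            f"regime_{axis}": f.regime,
                            f"converged_{axis}": f.converged,
                        }
                    )
                fits.append(row)
            results["msd_fits"][(cond, roi.label)] = pd.DataFrame(fits)

    # shared-edge histograms per ring
    for roi in rois:
        pooled = [a for cond in conditions
                  for a in results["angular"][(cond, roi.label)]]
        if not pooled:
            report.warn(f"{roi.label}: no trajectories survive filtering")
            continue
        ref_hist, _, _ = build_motion_hist(
            pooled, lag_frames=lag_frames, bins=bins
        )
        for cond in conditions:
            angulars = results["angular"][(cond, roi.label)]
            if not angulars:
                report.warn(f"{cond}/{roi.label}: no trajectories to bin")
                continue
            hist, mchi, mtheta = build_motion_hist(
                angulars, lag_frames=lag_frames,
                chi_edges=ref_hist.chi_edges, theta_edges=ref_hist.theta_edges,
            )
            results["hists"][(cond, roi.label)] = hist
            results["marginals"][(cond, roi.label)] = (mchi, mtheta)
            results["peaks"][(cond, roi.label)] = {
                "chi": peak_and_fwhm(mchi, hist.chi_edges),
                "theta": peak_and_fwhm(mtheta, hist.theta_edges),
            }
        conds_with_hist = [c for c in conditions
                           if (c, roi.label) in results["hists"]]
        for ca, cb in itertools.combinations(conds_with_hist, 2):
            results["subtractions"][(ca, cb, roi.label)] = subtract_hists(
                results["hists"][(ca, roi.label)],
                results["hists"][(cb, roi.label)],
            )
        if len(conds_with_hist) >= 2:
            results["hotspots"][roi.label] = superpose_hotspots(
                [results["hists"][(c, roi.label)] for c in conds_with_hist],
                quantile=hotspot_quantile,
            )
            results["hotspots"][roi.label]["conditions"] = conds_with_hist
    results["report"] = report
    if out_dir is not None:
        _write_dxt_outputs(results, Path(out_dir))
    return results


def _write_dxt_outputs(results: dict, out_dir: Path) -> None:
    import json

    out_dir.mkdir(parents=True, exist_ok=True)
    from .io import write_trajectories_csv

    for cond, trajs in results["trajectories"].items():
        write_trajectories_csv(out_dir / f"trajectories_{cond}.csv", trajs)
    for (cond, label), fits in results["msd_fits"].items():
        if len(fits):
            fits.to_csv(
                out_dir / f"msd_{cond}_{label}.csv".replace("/", "-"), index=False
            )
    maps = {}
    for (cond, label), hist in results["hists"].items():
        maps[f"{cond}|{label}"] = {
            "chi_edges": hist.chi_edges.tolist(),
            "theta_edges": hist.theta_edges.tolist(),
            "density": hist.density.tolist(),
            "axis_statistic": hist.axis_statistic,
            "units": "log10(deg^2)",
        }
    for (ca, cb, label), diff in results["subtractions"].items():
        maps[f"{ca}-minus-{cb}|{label}"] = {"difference": diff.tolist()}
    (out_dir / "motion_maps.json").write_text(json.dumps(maps))
    results["report"].to_json(out_dir / "run_report.json")
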