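"""Ground-truthed synthetic two-channel longitudinal movies.

The generator emulates the statistical structure the downstream analysis
assumes: transfected neurons sparsely scattered on a noisy background, a
constitutive cell-fill tracking channel, a reporter channel that is diffuse
in some neurons and punctate (aggregated) in others with total reporter flux
conserved between the two phenotypes, group-specific discrete-time death
hazards modified by aggregate status, and censoring at the final timepoint.

Death is generated on the 24 h imaging grid as a geometric process: a neuron
in group g with aggregate flag a dies in interval k (1-based) with
per-interval hazard h = baseline_g * (multiplier_g if a else 1). A neuron
dying in interval k emits no signal from frame k on; a neuron dying in
interval 1 is never imaged alive and is invisible to the tracker (ground
truth still records it). Aggregation is planted as a static property present
from the first timepoint.
"""

from __future__ import annotations

import json
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import GeneratorConfig, substream
from .imaging import Movie

__all__ = [
    "sample_cohort",
    "render_movie",
    "generate_labeled_roiset",
    "truth_to_records",
    "alive_at",
]

TRUTH_COLUMNS = [
    "neuron_id", "group", "well", "soma_radius", "aggregate_flag", "n_puncta",
    "puncta", "reporter_scale", "tracking_scale", "death_interval",
]


def _edge_margin(config: GeneratorConfig) -> float:
    """Distance from the frame edge reserved for soma radius plus drift.

    Six drift standard deviations of the full random walk keep the
    probability of a soma ever leaving the frame negligible.
    """
    r_max = config.soma_radius_mean + 3 * config.soma_radius_sd
    walk_sd = config.drift_sd * math.sqrt(max(config.n_timepoints - 1, 1))
    return r_max + 6.0 * walk_sd + 2.0


def _draw_puncta(rng: np.random.Generator, radius: float,
                 config: GeneratorConfig) -> list[dict]:
    """Punctum geometry for one aggregated neuron.

    Centers are drawn uniformly within 0.55 soma radii of the soma center so
    the puncta always lie inside the soma (no re-draws needed); flux is split
    equally; the Gaussian sigma scales with the soma radius.
    """
    lo, hi = config.n_puncta_range
    n = int(rng.integers(lo, hi + 1))
    sigma = config.punctum_radius_fraction * radius
    puncta = []
    for _ in range(n):
        rho = 0.55 * radius * math.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * math.pi)
        puncta.append(
            {"dy": rho * math.sin(theta), "dx": rho * math.cos(theta),
             "sigma": sigma}
        )
    return puncta


def _place_somata(
    rng: np.random.Generator,
    radii: np.ndarray,
    config: GeneratorConfig,
) -> np.ndarray:
    """Dart-throw initial (row, col) centers with a minimum pairwise
    separation of ``min_separation_radii`` mean soma radii, so somata never
    merge by construction (drift may still bring them closer)."""
    h, w = config.frame_shape
    margin = _edge_margin(config)
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise ValueError("frame_shape too small for drift margin")
    centers = np.empty((len(radii), 2))
    for i, r in enumerate(radii):
        for _ in range(5000):
            cand = rng.uniform([margin, margin], [h - margin, w - margin])
            if i == 0:
                centers[i] = cand
                break
            sep = 0.5 * config.min_separation_radii * (radii[:i] + r)
            if np.all(np.linalg.norm(centers[:i] - cand, axis=1) >= sep):
                centers[i] = cand
                break
        else:
            raise ValueError(
                "could not place somata with the required separation; "
                "reduce neurons_per_well or soma size"
            )
    return centers


def sample_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Sample the ground-truth table for a full cohort.

    Returns one row per neuron with columns ``TRUTH_COLUMNS`` plus per-
    timepoint centroid columns ``y_tp{k}``/``x_tp{k}`` (k = 1..n_timepoints,
    pixels). ``death_interval`` is the 1-based interval of death or NaN for
    neurons censored at the final timepoint. ``puncta`` is a JSON-encoded
    list of punctum geometries (empty for diffuse neurons).
    """
    t_cols = [f"y_tp{k}" for k in range(1, config.n_timepoints + 1)] + [
        f"x_tp{k}" for k in range(1, config.n_timepoints + 1)
    ]
    rows = []
    paths = []
    nid = 0
    for g in config.groups:
        rng = substream(config.seed, f"cohort:{g.name}")
        n = config.n_neurons_per_group
        radii = np.clip(
            rng.normal(config.soma_radius_mean, config.soma_radius_sd, n),
            4.0,
            config.soma_radius_mean + 3 * config.soma_radius_sd,
        )
        agg = rng.uniform(size=n) < g.aggregate_probability
        rep_scale = np.exp(rng.normal(0.0, config.reporter_brightness_log_sd, n))
        trk_scale = np.exp(rng.normal(0.0, config.tracking_brightness_log_sd, n))
        hazard = g.baseline_hazard_per_interval * np.where(
            agg, g.aggregate_hazard_multiplier, 1.0
        )
        death = np.full(n, np.nan)
        pos = hazard > 0
        if pos.any():
            draws = rng.geometric(hazard[pos])
            draws = np.where(draws <= config.n_timepoints, draws, np.nan)
            death[pos] = draws
        puncta = [
            json.dumps(_draw_puncta(rng, radii[i], config)) if agg[i] else "[]"
            for i in range(n)
        ]
        n_puncta = [len(json.loads(p)) for p in puncta]
        n_wells = math.ceil(n / config.neurons_per_well)
        for widx in range(n_wells):
            sl = slice(widx * config.neurons_per_well,
                       min((widx + 1) * config.neurons_per_well, n))
            idx = np.arange(sl.start, sl.stop)
            well = f"{g.name}_w{widx}"
            rng_w = substream(config.seed, f"well:{well}")
            centers = _place_somata(rng_w, radii[idx], config)
            steps = rng_w.normal(
                0.0, config.drift_sd,
                (len(idx), max(config.n_timepoints - 1, 0), 2),
            )
            path = np.concatenate(
                [centers[:, None, :], centers[:, None, :] + np.cumsum(steps, axis=1)],
                axis=1,
            )  # (n, T, 2) in (row, col)
            for j, i in enumerate(idx):
                rows.append(
                    {
                        "neuron_id": nid,
                        "group": g.name,
                        "well": well,
                        "soma_radius": float(radii[i]),
                        "aggregate_flag": bool(agg[i]),
                        "n_puncta": n_puncta[i],
                        "puncta": puncta[i],
                        "reporter_scale": float(rep_scale[i]),
                        "tracking_scale": float(trk_scale[i]),
                        "death_interval": float(death[i]),
                    }
                )
                paths.append(
                    np.concatenate([path[j, :, 0], path[j, :, 1]])
                )
                nid += 1
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    truth[t_cols] = np.asarray(paths)
    return truth


def alive_at(row: Mapping, timepoint: int) -> bool:
    """Is this ground-truth neuron alive (visible) at 1-based ``timepoint``?

    A neuron with death interval k is imaged alive at timepoints < k only, so
    alive flags are always a prefix of the timepoint sequence.
    """
    d = row["death_interval"]
    return bool(pd.isna(d) or timepoint < d)


def _render_soma(
    trk_sig: np.ndarray,
    rep_sig: np.ndarray,
    row: Mapping,
    cy: float,
    cx: float,
    rng: np.random.Generator,
    config: GeneratorConfig,
) -> None:
    """Add one live soma to the tracking and reporter signal frames in place.

    The tracking channel is a filled disc of roughly uniform intensity. The
    reporter channel is uniform for diffuse neurons; for aggregated neurons
    ``aggregate_flux_fraction`` of the same total flux is concentrated into
    Gaussian puncta (flux conserved exactly: puncta are renormalized over the
    in-soma pixel grid). Multiplicative mean-1 texture emulates intracellular
    heterogeneity.
    """
    h, w = trk_sig.shape
    r = float(row["soma_radius"])
    if cy - r < 0 or cx - r < 0 or cy + r > h - 1 or cx + r > w - 1:
        raise ValueError(
            f"soma at ({cy:.1f}, {cx:.1f}) with radius {r:.1f} does not fit "
            f"in a {h}x{w} frame"
        )
    y0, y1 = int(math.floor(cy - r)), int(math.ceil(cy + r)) + 1
    x0, x1 = int(math.floor(cx - r)), int(math.ceil(cx + r)) + 1
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    n_pix = int(mask.sum())
    if n_pix == 0:
        raise ValueError("degenerate soma with no pixels")

    def texture(cv: float) -> np.ndarray:
        if cv <= 0:
            return np.ones(n_pix)
        return np.clip(1.0 + cv * rng.standard_normal(n_pix), 0.05, None)

    trk_level = config.tracking_intensity * float(row["tracking_scale"])
    trk_vals = trk_level * texture(config.tracking_texture_cv)

    rep_level = config.soma_intensity * float(row["reporter_scale"])
    puncta = json.loads(row["puncta"]) if row["aggregate_flag"] else []
    if puncta:
        f = config.aggregate_flux_fraction
        rep_vals = np.full(n_pix, (1.0 - f) * rep_level)
        total_punctum_flux = f * rep_level * n_pix
        my, mx = yy[mask], xx[mask]
        for p in puncta:
            py, px, sig = cy + p["dy"], cx + p["dx"], p["sigma"]
            g = np.exp(-((my - py) ** 2 + (mx - px) ** 2) / (2.0 * sig * sig))
            rep_vals += g * (total_punctum_flux / len(puncta) / g.sum())
    else:
        rep_vals = np.full(n_pix, rep_level)
    rep_vals = rep_vals * texture(config.reporter_texture_cv)

    trk_sig[y0:y1, x0:x1][mask] += trk_vals
    rep_sig[y0:y1, x0:x1][mask] += rep_vals


def _apply_noise(
    signal: np.ndarray, config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """Poisson shot noise + Gaussian read noise + constant background,
    quantized to 16-bit camera digital numbers."""
    expected = signal + config.background_level
    if config.photon_scale is not None:
        ps = config.photon_scale
        frame = rng.poisson(expected * ps).astype(float) / ps
    else:
        frame = expected.astype(float)
    if config.read_noise_sd > 0:
        frame = frame + rng.normal(0.0, config.read_noise_sd, frame.shape)
    return np.clip(np.rint(frame), 0, 65535).astype(np.uint16)


def render_movie(
    truth: pd.DataFrame,
    config: GeneratorConfig,
    well: str | None = None,
) -> Movie:
    """Render the two-channel movie for one well of a ground-truth table.

    Dead neurons emit no signal from their death interval onward. Channel 0
    is the tracking channel, channel 1 the reporter channel.
    """
    wells = truth["well"].unique()
    if well is None:
        if len(wells) != 1:
            raise ValueError(
                f"truth table contains {len(wells)} wells; pass well=..."
            )
        well = wells[0]
    sub = truth[truth["well"] == well]
    if sub.empty:
        raise ValueError(f"no neurons in well {well!r}")
    h, w = config.frame_shape
    t_total = config.n_timepoints
    rng = substream(config.seed, f"render:{well}")
    frames = np.empty((t_total, 2, h, w), dtype=np.uint16)
    for t in range(t_total):
        trk_sig = np.zeros((h, w))
        rep_sig = np.zeros((h, w))
        tp = t + 1
        for _, row in sub.iterrows():
            if not alive_at(row, tp):
                continue
            cy = float(row[f"y_tp{tp}"])
            cx = float(row[f"x_tp{tp}"])
            _render_soma(trk_sig, rep_sig, row, cy, cx, rng, config)
        frames[t, 0] = _apply_noise(trk_sig, config, rng)
        frames[t, 1] = _apply_noise(rep_sig, config, rng)
    return Movie(pixels=frames, times=config.times_hours)


def generate_labeled_roiset(
    config: GeneratorConfig, n_per_class: int
) -> pd.DataFrame:
    """Render a labeled validation set of aggregated and diffuse ROIs.

    Each ROI is a single neuron rendered and measured by the same engine as
    full movies (render, background-subtract, segment, measure CV), with its
    true phenotype attached. Used to calibrate the CV classifier the way a
    manually annotated n-per-class validation set would be.

    Returns a DataFrame with columns roi_index, true_label
    ('aggregated'/'diffuse'), cv, mean, sd, area, soma_radius, n_puncta.
    """
    from .imaging import SegmentationParams, segment_frame, subtract_background

    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = substream(config.seed, "labeled_roiset")
    side = int(2 * math.ceil(config.soma_radius_mean + 3 * config.soma_radius_sd) + 24)
    rows = []
    idx = 0
    for label_name, is_agg in (("aggregated", True), ("diffuse", False)):
        for _ in range(n_per_class):
            radius = float(
                np.clip(
                    rng.normal(config.soma_radius_mean, config.soma_radius_sd),
                    4.0,
                    config.soma_radius_mean + 3 * config.soma_radius_sd,
                )
            )
            row = {
                "soma_radius": radius,
                "aggregate_flag": is_agg,
                "puncta": json.dumps(_draw_puncta(rng, radius, config))
                if is_agg
                else "[]",
                "reporter_scale": float(
                    np.exp(rng.normal(0.0, config.reporter_brightness_log_sd))
                ),
                "tracking_scale": float(
                    np.exp(rng.normal(0.0, config.tracking_brightness_log_sd))
                ),
            }
            cy = side / 2 + rng.uniform(-2, 2)
            cx = side / 2 + rng.uniform(-2, 2)
            trk_sig = np.zeros((side, side))
            rep_sig = np.zeros((side, side))
            _render_soma(trk_sig, rep_sig, row, cy, cx, rng, config)
            trk = subtract_background(_apply_noise(trk_sig, config, rng))
            rep = subtract_background(_apply_noise(rep_sig, config, rng))
            rois = segment_frame(trk, rep, SegmentationParams())
            if not rois:
                raise RuntimeError(
                    "labeled-ROI rendering produced no segmentable soma; "
                    "check noise/intensity calibration"
                )
            roi = min(
                rois,
                key=lambda r: (r.centroid[0] - cy) ** 2 + (r.centroid[1] - cx) ** 2,
            )
            rows.append(
                {
                    "roi_index": idx,
                    "true_label": label_name,
                    "cv": roi.cv,
                    "mean": roi.mean,
                    "sd": roi.sd,
                    "area": roi.area,
                    "soma_radius": radius,
                    "n_puncta": len(json.loads(row["puncta"])),
                }
            )
            idx += 1
    return pd.DataFrame(rows)


def truth_to_records(
    truth: pd.DataFrame, config: GeneratorConfig
) -> pd.DataFrame:
    """Survival records straight from ground truth (no imaging).

    One record per neuron: ``time`` in hours (death interval x interval
    length, or censoring at the last timepoint), ``event`` flag, ``group``
    and planted ``aggregate`` status. Used for generative-model oracles.
    """
    death = truth["death_interval"].to_numpy(dtype=float)
    event = ~np.isnan(death)
    time = np.where(
        event, death * config.interval_hours,
        config.n_timepoints * config.interval_hours,
    )
    return pd.DataFrame(
        {
            "neuron_id": truth["neuron_id"].to_numpy(),
            "time": time,
            "event": event,
            "group": truth["group"].to_numpy(),
            "aggregate": truth["aggregate_flag"].to_numpy(),
        }
    )
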