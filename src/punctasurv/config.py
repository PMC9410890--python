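"""Configuration objects and deterministic random-number substreams.

All randomness in the package flows from a single integer seed through named
substreams, so each stage (cohort sampling, rendering, calibration) can be
re-run independently and reproducibly.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["GroupSpec", "GeneratorConfig", "substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a named, reproducible random substream derived from ``seed``.

    The substream key is a CRC32 hash of ``name``, so the draw order of one
    stage never perturbs another stage's stream.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group (construct) in a synthetic cohort.

    Parameters
    ----------
    name
        Group label, e.g. ``"nGFP"``, ``"CGG"``, ``"GGN"``.
    aggregate_probability
        Probability, in [0, 1], that a neuron carries reporter puncta
        (an inclusion) from the first timepoint on.
    baseline_hazard_per_interval
        Per-24h-interval death probability for diffuse neurons, in [0, 1).
    aggregate_hazard_multiplier
        Multiplicative effect of aggregate status on the per-interval hazard.
        The effective hazard ``baseline * multiplier`` must stay below 1.
    """

    name: str
    aggregate_probability: float = 0.0
    baseline_hazard_per_interval: float = 0.03
    aggregate_hazard_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.aggregate_probability <= 1.0:
            raise ValueError(
                f"group {self.name!r}: aggregate_probability must be in [0, 1], "
                f"got {self.aggregate_probability}"
            )
        if not 0.0 <= self.baseline_hazard_per_interval < 1.0:
            raise ValueError(
                f"group {self.name!r}: baseline_hazard_per_interval must be in "
                f"[0, 1), got {self.baseline_hazard_per_interval}"
            )
        if self.aggregate_hazard_multiplier <= 0:
            raise ValueError(
                f"group {self.name!r}: aggregate_hazard_multiplier must be > 0"
            )
        if (
            self.baseline_hazard_per_interval * self.aggregate_hazard_multiplier
            >= 1.0
        ):
            raise ValueError(
                f"group {self.name!r}: baseline hazard x multiplier must stay "
                "below 1 (per-interval death probability)"
            )


# Default three-group study design: a non-aggregating control, a strongly
# aggregating construct whose aggregates accelerate death, and a weakly
# aggregating construct whose aggregates are hazard-neutral.
_DEFAULT_GROUPS = (
    GroupSpec("nGFP", aggregate_probability=0.0,
              baseline_hazard_per_interval=0.02,
              aggregate_hazard_multiplier=1.0),
    GroupSpec("CGG", aggregate_probability=0.485,
              baseline_hazard_per_interval=0.03,
              aggregate_hazard_multiplier=2.0),
    GroupSpec("GGN", aggregate_probability=0.25,
              baseline_hazard_per_interval=0.035,
              aggregate_hazard_multiplier=1.0),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of the synthetic-cohort generator.

    Geometry is in pixels, intensities in camera digital numbers (DN), time in
    hours. Identical config + seed yields bit-identical movies and tables.

    Notes on the imaging model
    --------------------------
    * ``photon_scale`` is the expected photon count per intensity unit; shot
      noise is Poisson on ``photon_scale * (signal + background)``. Set it to
      ``None`` to disable shot noise (the infinite-photon limit).
    * ``aggregate_flux_fraction`` of an aggregated soma's total reporter flux
      is concentrated into 1-3 Gaussian puncta; total flux is conserved
      between the diffuse and aggregated phenotypes.
    * ``reporter_texture_cv`` / ``tracking_texture_cv`` add multiplicative
      intracellular intensity heterogeneity (mean 1) on top of the rendered
      signal, emulating uneven reporter distribution in real somata.
    """

    n_neurons_per_group: int = 200
    groups: Sequence[GroupSpec] = field(default_factory=lambda: _DEFAULT_GROUPS)
    n_timepoints: int = 10
    interval_hours: float = 24.0
    frame_shape: tuple[int, int] = (512, 512)
    soma_radius_mean: float = 6.0
    soma_radius_sd: float = 0.8
    n_puncta_range: tuple[int, int] = (1, 3)
    punctum_radius_fraction: float = 0.16
    aggregate_flux_fraction: float = 0.6
    soma_intensity: float = 60.0
    tracking_intensity: float = 80.0
    reporter_brightness_log_sd: float = 0.3
    tracking_brightness_log_sd: float = 0.2
    reporter_texture_cv: float = 0.25
    tracking_texture_cv: float = 0.08
    background_level: float = 20.0
    read_noise_sd: float = 2.0
    photon_scale: float | None = 1.0
    drift_sd: float = 2.0
    neurons_per_well: int = 40
    min_separation_radii: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons_per_group < 1:
            raise ValueError("n_neurons_per_group must be >= 1")
        if not self.groups:
            raise ValueError("at least one group is required")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")
        if self.interval_hours <= 0:
            raise ValueError("interval_hours must be > 0")
        if self.soma_radius_mean <= 0 or self.soma_radius_sd <= 0:
            raise ValueError("soma radius mean and sd must be > 0")
        lo, hi = self.n_puncta_range
        if lo < 1 or hi < lo:
            raise ValueError("n_puncta_range must satisfy 1 <= lo <= hi")
        if not 0.0 < self.punctum_radius_fraction <= 0.5:
            raise ValueError("punctum_radius_fraction must be in (0, 0.5]")
        if not 0.0 < self.aggregate_flux_fraction < 1.0:
            raise ValueError("aggregate_flux_fraction must be in (0, 1)")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.photon_scale is not None and self.photon_scale <= 0:
            raise ValueError("photon_scale must be > 0 or None")
        if self.drift_sd < 0:
            raise ValueError("drift_sd must be >= 0")
        if self.neurons_per_well < 1:
            raise ValueError("neurons_per_well must be >= 1")
        if min(self.frame_shape) < 8 * self.soma_radius_mean:
            raise ValueError("frame_shape too small for the configured somata")

    @property
    def times_hours(self) -> np.ndarray:
        """Acquisition times: frame k (0-based) is imaged at 24*(k+1) h."""
        return self.interval_hours * (1 + np.arange(self.n_timepoints, dtype=float))

    def group(self, name: str) -> GroupSpec:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(f"unknown group {name!r}")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = [dataclasses.asdict(g) for g in self.groups]
        d["frame_shape"] = list(self.frame_shape)
        d["n_puncta_range"] = list(self.n_puncta_range)
        d["schema_version"] = 1
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d.pop("schema_version", None)
        d["groups"] = tuple(GroupSpec(**g) for g in d.get("groups", []))
        d["frame_shape"] = tuple(d.get("frame_shape", (512, 512)))
        d["n_puncta_range"] = tuple(d.get("n_puncta_range", (1, 3)))
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
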