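"""Ground-truth scene description for synthetic TIRFM videos.

A scene is a physical description of what sits on (and above) the supported
lipid bilayer: circular close contacts that locally exclude the fluorescent
glycocalyx, cell footprints that appear and change size, per-cell calcium
traces, and point emitters for single-molecule channels.  Everything is in
physical units (micrometres, seconds); rendering to camera pixels happens in
:mod:`closecontact.render`.

Conventions: arrays are ordered ``(time, y, x)``, coordinates are 0-based and
pixel centres sit at half-integer multiples of the pixel size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml


@dataclass
class PSFModel:
    """Gaussian approximation of the microscope point spread function.

    ``sigma_nm`` defaults to 131 nm, the width of a Gaussian fitted to the
    bead-measured PSF of a NA 1.49 TIRF objective.
    """

    sigma_nm: float = 131.0

    def __post_init__(self) -> None:
        if self.sigma_nm <= 0:
            raise ValueError(f"PSF sigma must be positive, got {self.sigma_nm}")


@dataclass
class CameraModel:
    """EMCCD camera parameters.

    ``em_gain`` is the electron-multiplication gain in ADU/photon (250 for the
    Evolve 512 Delta settings emulated here) and ``pixel_size_nm`` the
    effective sample-plane pixel size (107 nm).
    """

    em_gain: float = 250.0
    read_noise_sd: float = 10.0
    offset: float = 100.0
    quantum_efficiency: float = 0.9
    pixel_size_nm: float = 107.0

    def __post_init__(self) -> None:
        if self.em_gain <= 0:
            raise ValueError("em_gain must be positive")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size must be positive")
        if not 0 < self.quantum_efficiency <= 1:
            raise ValueError("quantum_efficiency must be in (0, 1]")


@dataclass
class ContactTruth:
    """A circular glycocalyx-exclusion region (one close contact).

    ``exclusion_depth`` is the fraction of glycocalyx signal removed inside
    the disc: in-disc intensity = background * (1 - exclusion_depth).
    """

    center_um: tuple[float, float]  # (y, x)
    diameter_um: float
    exclusion_depth: float
    birth_s: float = 0.0
    death_s: float = np.inf

    def __post_init__(self) -> None:
        if not 0 <= self.exclusion_depth <= 1:
            raise ValueError("exclusion_depth must be in [0, 1]")
        if self.diameter_um <= 0:
            raise ValueError("diameter must be positive")
        if not self.birth_s < self.death_s:
            raise ValueError("birth_time must precede death_time")

    def alive(self, t: float) -> bool:
        return self.birth_s <= t < self.death_s


@dataclass
class CellTruth:
    """A cell footprint with a scripted trajectory and calcium trace."""

    center_um: np.ndarray  # (n_frames, 2) (y, x)
    radius_um: np.ndarray  # (n_frames,)
    calcium_trace: np.ndarray  # (n_frames,)
    trigger_s: float | None = None

    def __post_init__(self) -> None:
        self.center_um = np.atleast_2d(np.asarray(self.center_um, float))
        self.radius_um = np.asarray(self.radius_um, float)
        self.calcium_trace = np.asarray(self.calcium_trace, float)
        if np.any(self.radius_um < 0):
            raise ValueError("footprint radii must be >= 0")


@dataclass
class EmitterTruth:
    """A point emitter, either immobile or diffusing with coefficient D."""

    start_um: tuple[float, float]
    brightness: float = 500.0  # photons / frame
    mobility: Literal["immobile", "diffusing"] = "immobile"
    diffusion_um2_s: float = 0.0

    def __post_init__(self) -> None:
        if self.brightness <= 0:
            raise ValueError("brightness must be positive")


@dataclass
class GroundTruthScene:
    """Full ground truth for a simulated field of view.

    ``background_intensity`` is the uniform glycocalyx signal (expected
    photons per camera pixel); 100 matches the brightness used to emulate
    experimental SLB images.
    """

    field_size_um: tuple[float, float] = (5.0, 5.0)  # (y, x)
    background_intensity: float = 100.0
    contacts: list[ContactTruth] = field(default_factory=list)
    cells: list[CellTruth] = field(default_factory=list)
    emitters: list[EmitterTruth] = field(default_factory=list)
    frame_interval_s: float = 2.0
    n_frames: int = 1

    def __post_init__(self) -> None:
        if self.field_size_um[0] <= 0 or self.field_size_um[1] <= 0:
            raise ValueError("field_size must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.background_intensity <= 0:
            raise ValueError("background_intensity must be positive")
        for i, c in enumerate(self.contacts):
            cy, cx = c.center_um
            if not (0 <= cy <= self.field_size_um[0] and 0 <= cx <= self.field_size_um[1]):
                raise ValueError(
                    f"contact {i} center {c.center_um} lies outside the "
                    f"{self.field_size_um} um field"
                )

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    # -- serialization -----------------------------------------------------

    def contact_table(self) -> pd.DataFrame:
        """Truth table of contacts, one row per contact."""
        rows = [
            {
                "contact_id": i,
                "center_y_um": c.center_um[0],
                "center_x_um": c.center_um[1],
                "diameter_um": c.diameter_um,
                "exclusion_depth": c.exclusion_depth,
                "birth_s": c.birth_s,
                "death_s": c.death_s,
            }
            for i, c in enumerate(self.contacts)
        ]
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))

        Path(path).write_text(json.dumps(asdict(self), default=_default, indent=1))


def scene_from_yaml(path: str | Path) -> GroundTruthScene:
    """Build a scene from a YAML description (the CLI input format)."""
    cfg = yaml.safe_load(Path(path).read_text())
    contacts = [ContactTruth(
        center_um=tuple(c["center_um"]),
        diameter_um=c["diameter_um"],
        exclusion_depth=c["exclusion_depth"],
        birth_s=c.get("birth_s", 0.0),
        death_s=c.get("death_s", np.inf),
    ) for c in cfg.get("contacts", [])]
    n_frames = int(cfg.get("n_frames", 1))
    cells = []
    for c in cfg.get("cells", []):
        center = np.asarray(c["center_um"], float)
        if center.ndim == 1:
            center = np.tile(center, (n_frames, 1))
        radius = np.broadcast_to(np.asarray(c["radius_um"], float), (n_frames,)).copy()
        trace = np.broadcast_to(
            np.asarray(c.get("calcium_trace", 100.0), float), (n_frames,)
        ).copy()
        cells.append(CellTruth(center, radius, trace, c.get("trigger_s")))
    emitters = [EmitterTruth(
        start_um=tuple(e["start_um"]),
        brightness=e.get("brightness", 500.0),
        mobility=e.get("mobility", "immobile"),
        diffusion_um2_s=e.get("diffusion_um2_s", 0.0),
    ) for e in cfg.get("emitters", [])]
    return GroundTruthScene(
        field_size_um=tuple(cfg.get("field_size_um", (5.0, 5.0))),
        background_intensity=cfg.get("background_intensity", 100.0),
        contacts=contacts,
        cells=cells,
        emitters=emitters,
        frame_interval_s=cfg.get("frame_interval_s", 2.0),
        n_frames=n_frames,
    )


def constant_cell(
    center_um: Sequence[float],
    radius_um: float,
    n_frames: int,
    calcium_baseline: float = 100.0,
    trigger_s: float | None = None,
    trigger_fold: float = 4.0,
    frame_interval_s: float = 2.0,
) -> CellTruth:
    """Convenience constructor: a stationary cell with an optional step-like
    calcium rise at ``trigger_s``."""
    center = np.tile(np.asarray(center_um, float), (n_frames, 1))
    radius = np.full(n_frames, radius_um)
    trace = np.full(n_frames, calcium_baseline)
    if trigger_s is not None:
        t = np.arange(n_frames) * frame_interval_s
        trace[t >= trigger_s] = calcium_baseline * trigger_fold
    return CellTruth(center, radius, trace, trigger_s)
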