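"""Ground-truthed simulation of circular exclusion-zone (cMINC) migration wells.

The simulator emulates the statistical structure of a stopper-based migration
assay: cells are seeded uniformly outside a circular cell-free zone, perform an
isotropic Gaussian random walk for the migration window, optionally divide
(Bernoulli division events, suppressed by AraC or a cytostatic drug effect),
and may be flagged non-viable (cytotoxicity).  Drug action is modelled as three
independent Hill terms — migration inhibition, cytostasis, and death — so that
migration-specific ("migrastatic") effects can be separated from cytostatic
ones, exactly the separation the AraC co-treatment achieves experimentally.

Also provided: a renderer producing two-channel (nuclei / calcein) 16-bit
images from a ground-truth well, a per-frame track simulator, a
time-of-addition exposure-schedule model for JAK-inhibitor rescue, and a
paired expression-matrix simulator with planted differential signal.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "DrugEffectModel",
    "ExposureSchedule",
    "GroundTruthWell",
    "RenderParams",
    "SimulatedExpression",
    "simulate_well",
    "render_well",
    "simulate_tracks",
    "effect_of_schedule",
    "simulate_expression",
    "simulate_dose_response_plate",
    "write_well",
    "write_tracks_csv",
    "write_expression",
]


# ---------------------------------------------------------------------------
# configuration / domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Geometry and kinetics of one simulated migration well.

    Defaults emulate a 96-well stopper assay imaged at low magnification on a
    high-content reader: a 2000x2000 px field at 1.3 um/px (2.6 mm square),
    a 770 px (~1 mm radius, i.e. 2 mm diameter) stopper footprint, and a
    seeding density of ~95,000 cells/cm^2 outside the stopper (~3400 cells in
    the visible part of the field).  ``base_step_px`` is the per-frame per-axis step SD of an
    unimpaired cell; 4.5 px / 15 min at 1.3 um/px is ~0.4 um/min mean speed,
    realistic for migrating neural crest cells, and leaves the zone only
    partially re-populated after 48 h, as in the assay.
    """

    image_shape: tuple[int, int] = (2000, 2000)  # (height, width) px
    pixel_size: float = 1.3  # um / px
    zone_center: tuple[float, float] | None = None  # (y, x) px; None = centre
    zone_radius: float = 770.0  # px
    n_cells_seeded: int = 3400
    migration_hours: float = 48.0
    frame_interval: float = 15.0  # minutes
    proliferation_rate: float = 0.5  # divisions / cell / 48 h (0 under AraC)
    arac_mode: bool = False
    base_step_px: float = 4.5  # per-axis step SD per frame at full capacity
    rng_seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_shape
        cy, cx = self.centre
        r = self.zone_radius
        if not (r > 0):
            raise ValueError("zone_radius must be positive")
        if not (r <= cy <= h - 1 - r and r <= cx <= w - 1 - r):
            raise ValueError("exclusion zone does not fit inside the image")
        if self.n_cells_seeded <= 0:
            raise ValueError("n_cells_seeded must be positive")
        if self.migration_hours <= 0:
            raise ValueError("migration_hours must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def centre(self) -> tuple[float, float]:
        if self.zone_center is not None:
            return self.zone_center
        h, w = self.image_shape
        return ((h - 1) / 2.0, (w - 1) / 2.0)

    @property
    def n_frames(self) -> int:
        """Number of random-walk steps over the migration window."""
        return int(round(self.migration_hours * 60.0 / self.frame_interval))


@dataclass(frozen=True)
class DrugEffectModel:
    """Independent Hill terms for migration inhibition, cytostasis and death.

    ``migration_capacity(c)`` returns m(c) = 1 - emax * c^h / (c^h + ec^h),
    the fraction of the unimpaired step size retained at concentration ``c``
    (pM).  Cytostasis scales the division probability the same way.
    ``death_fraction`` is the fraction of cells rendered non-viable at any
    non-zero concentration (a simple cytotoxicity term; 0 by default because
    type-I interferons are cytostatic, not cytotoxic, in this assay).
    """

    ec_mig: float = 105.0  # pM at half-maximal migration inhibition
    hill_mig: float = 1.0
    emax_mig: float = 1.0
    ec_prolif: float = 1050.0
    hill_prolif: float = 1.0
    emax_prolif: float = 1.0
    death_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.ec_mig <= 0 or self.ec_prolif <= 0:
            raise ValueError("EC values must be positive")
        for name in ("emax_mig", "emax_prolif", "death_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    @staticmethod
    def _hill(c: float, ec: float, h: float, emax: float) -> float:
        if c < 0:
            raise ValueError("concentration must be non-negative")
        if c == 0:
            return 0.0
        ch = c**h
        return emax * ch / (ch + ec**h)

    def migration_inhibition(self, concentration: float) -> float:
        return self._hill(concentration, self.ec_mig, self.hill_mig, self.emax_mig)

    def migration_capacity(self, concentration: float) -> float:
        return 1.0 - self.migration_inhibition(concentration)

    def cytostasis(self, concentration: float) -> float:
        return self._hill(
            concentration, self.ec_prolif, self.hill_prolif, self.emax_prolif
        )

    def death(self, concentration: float) -> float:
        if concentration < 0:
            raise ValueError("concentration must be non-negative")
        return self.death_fraction if concentration > 0 else 0.0


@dataclass(frozen=True)
class ExposureSchedule:
    """Time-of-addition schedule for cytokine exposure and a pathway inhibitor.

    ``inhibitor_add`` is the hour at which a JAK inhibitor terminates
    signalling (None = never).  The realized migration inhibition scales with
    a ramp of the active-signalling duration D: zero for D <= rescue_floor
    (full rescue), full for D >= rescue_ceiling, linear in between.  The 6-10 h
    window reflects the experimental bracketing of the commitment point.
    """

    ifn_start: float = 0.0
    ifn_stop: float = 48.0
    inhibitor_add: float | None = None
    rescue_floor: float = 6.0
    rescue_ceiling: float = 10.0

    def __post_init__(self) -> None:
        if not (0 <= self.ifn_start <= self.ifn_stop):
            raise ValueError("require 0 <= ifn_start <= ifn_stop")
        if not (self.rescue_floor < self.rescue_ceiling):
            raise ValueError("rescue_floor must be below rescue_ceiling")
        if self.inhibitor_add is not None and self.inhibitor_add < 0:
            raise ValueError("inhibitor_add must be non-negative")


@dataclass
class GroundTruthWell:
    """Final-state ground truth for one simulated well."""

    cell_positions: np.ndarray  # (n, 2) float (y, x) px
    viable_flags: np.ndarray  # (n,) bool
    edu_flags: np.ndarray  # (n,) bool
    n_in_zone_true: int
    zone_center: tuple[float, float]
    zone_radius: float
    condition: str = ""
    concentration: float = 0.0

    @property
    def n_cells(self) -> int:
        return int(len(self.cell_positions))

    @property
    def n_viable(self) -> int:
        return int(self.viable_flags.sum())


def effect_of_schedule(
    schedule: ExposureSchedule,
    drug: DrugEffectModel,
    concentration: float,
) -> float:
    """Migration capacity in [0, 1] under a time-of-addition schedule.

    The active-signalling duration is D = min(ifn_stop, inhibitor_add) -
    ifn_start; realized inhibition is the full-exposure inhibition scaled by
    the rescue ramp of D.
    """
    stop = schedule.ifn_stop
    if schedule.inhibitor_add is not None:
        stop = min(stop, schedule.inhibitor_add)
    duration = max(0.0, stop - schedule.ifn_start)
    lo, hi = schedule.rescue_floor, schedule.rescue_ceiling
    if duration <= lo:
        ramp = 0.0
    elif duration >= hi:
        ramp = 1.0
    else:
        ramp = (duration - lo) / (hi - lo)
    inhibition = drug.migration_inhibition(concentration) * ramp
    return 1.0 - inhibition


# ---------------------------------------------------------------------------
# well simulation
# ---------------------------------------------------------------------------


def _seed_positions(
    rng: np.random.Generator, config: SimulationConfig, n: int
) -> np.ndarray:
    """Uniform positions in the image, excluding the circular zone."""
    h, w = config.image_shape
    cy, cx = config.centre
    r2 = config.zone_radius**2
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(2 * (n - len(out)), 64)
        pts = rng.uniform([0, 0], [h - 1, w - 1], size=(m, 2))
        keep = (pts[:, 0] - cy) ** 2 + (pts[:, 1] - cx) ** 2 >= r2
        out = np.vstack([out, pts[keep]])
    return out[:n]


def simulate_well(
    config: SimulationConfig,
    drug: DrugEffectModel,
    concentration: float,
    seed: int,
    schedule: ExposureSchedule | None = None,
    condition: str = "",
) -> GroundTruthWell:
    """Simulate one well to its 48-h (by default) endpoint.

    Cells start uniformly outside the zone, divide with probability
    proliferation_rate * (1 - cytostasis) (zero in AraC mode), and random-walk
    for ``config.n_frames`` steps with per-axis step SD
    ``base_step_px * m(c)``.  Since only the endpoint matters here, the walk's
    net displacement is drawn directly from its exact Gaussian law
    N(0, n_steps * step_sd^2) per axis.  Daughters inherit the division site
    and walk independently.  A ``death_fraction`` of cells (at c > 0) is
    flagged non-viable; the ground-truth migrated count is the number of
    viable cells strictly inside the zone.
    """
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    rng = np.random.default_rng(seed)

    if schedule is not None:
        capacity = effect_of_schedule(schedule, drug, concentration)
    else:
        capacity = drug.migration_capacity(concentration)

    pos0 = _seed_positions(rng, config, config.n_cells_seeded)

    # division events (before the walk; daughters walk the full window)
    if config.arac_mode:
        p_div = 0.0
    else:
        p_div = config.proliferation_rate * (1.0 - drug.cytostasis(concentration))
        p_div *= config.migration_hours / 48.0
    divided = rng.random(config.n_cells_seeded) < p_div
    daughters = pos0[divided]
    positions = np.vstack([pos0, daughters])
    edu = np.concatenate([divided, np.ones(len(daughters), dtype=bool)])

    n_total = len(positions)
    sigma = config.base_step_px * capacity * math.sqrt(config.n_frames)
    if sigma > 0:
        positions = positions + rng.normal(0.0, sigma, size=(n_total, 2))
    h, w = config.image_shape
    positions[:, 0] = np.clip(positions[:, 0], 0, h - 1)
    positions[:, 1] = np.clip(positions[:, 1], 0, w - 1)

    viable = rng.random(n_total) >= drug.death(concentration)

    cy, cx = config.centre
    inside = (positions[:, 0] - cy) ** 2 + (positions[:, 1] - cx) ** 2 < (
        config.zone_radius**2
    )
    n_in_zone = int((inside & viable).sum())

    return GroundTruthWell(
        cell_positions=positions,
        viable_flags=viable,
        edu_flags=edu,
        n_in_zone_true=n_in_zone,
        zone_center=(cy, cx),
        zone_radius=config.zone_radius,
        condition=condition,
        concentration=concentration,
    )


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RenderParams:
    """How a ground-truth well is turned into a two-channel 16-bit image.

    Nuclei are Gaussian spots (sigma ~ nuclear radius) on the Hoechst channel;
    viable cells additionally get a wider uniform disk on the calcein channel
    (the dye stains the whole cell outline, hence the larger footprint).
    """

    nuclear_sigma: float = 2.0  # px
    nuc_amplitude: float = 3000.0
    calcein_radius: float = 9.0  # px
    cal_amplitude: float = 1500.0
    background: float = 100.0
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nuclear_sigma <= 0 or self.calcein_radius <= 0:
            raise ValueError("spot sizes must be positive")


def _add_spots(
    img: np.ndarray, positions: np.ndarray, patch: np.ndarray, half: int
) -> None:
    """Accumulate a fixed kernel patch at (rounded) positions, clipped at edges."""
    h, w = img.shape
    for y, x in positions:
        iy, ix = int(round(y)), int(round(x))
        y0, y1 = max(0, iy - half), min(h, iy + half + 1)
        x0, x1 = max(0, ix - half), min(w, ix + half + 1)
        py0, px0 = y0 - (iy - half), x0 - (ix - half)
        img[y0:y1, x0:x1] += patch[py0 : py0 + (y1 - y0), px0 : px0 + (x1 - x0)]


def render_well(
    gtw: GroundTruthWell,
    image_shape: tuple[int, int],
    render: RenderParams = RenderParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Render (nuclei_channel, calcein_channel) as uint16 arrays."""
    h, w = image_shape
    pos = np.asarray(gtw.cell_positions, dtype=float)
    if len(pos) and (
        pos[:, 0].min() < 0
        or pos[:, 1].min() < 0
        or pos[:, 0].max() > h - 1
        or pos[:, 1].max() > w - 1
    ):
        raise ValueError("cell positions outside image bounds")

    rng = np.random.default_rng(render.seed)
    nuc = np.zeros((h, w), dtype=float)
    cal = np.zeros((h, w), dtype=float)

    s = render.nuclear_sigma
    half_n = int(math.ceil(3 * s))
    yy, xx = np.mgrid[-half_n : half_n + 1, -half_n : half_n + 1]
    gauss = render.nuc_amplitude * np.exp(-(yy**2 + xx**2) / (2 * s**2))

    r = render.calcein_radius
    half_c = int(math.ceil(r))
    yy, xx = np.mgrid[-half_c : half_c + 1, -half_c : half_c + 1]
    disk = render.cal_amplitude * (yy**2 + xx**2 <= r**2).astype(float)

    if len(pos):
        _add_spots(nuc, pos, gauss, half_n)
        _add_spots(cal, pos[gtw.viable_flags], disk, half_c)

    for img in (nuc, cal):
        img += render.background
        img += rng.normal(0.0, render.noise_sd, size=img.shape)
    nuc16 = np.clip(nuc, 0, 65535).astype(np.uint16)
    cal16 = np.clip(cal, 0, 65535).astype(np.uint16)
    return nuc16, cal16


# ---------------------------------------------------------------------------
# track simulation
# ---------------------------------------------------------------------------


def simulate_tracks(
    config: SimulationConfig,
    drug: DrugEffectModel,
    concentration: float,
    n_cells: int,
    seed: int,
) -> pd.DataFrame:
    """Per-frame cell tracks from the same Gaussian-walk model.

    Returns a long-format table with columns ``track_id, frame, x_px, y_px``
    (one row per cell per frame, frames 0..n_frames).  Starting points are
    uniform outside the exclusion zone; steps are isotropic Gaussian with
    per-axis SD ``base_step_px * m(c)``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    rng = np.random.default_rng(seed)
    capacity = drug.migration_capacity(concentration)
    sigma = config.base_step_px * capacity

    n_frames = config.n_frames
    start = _seed_positions(rng, config, n_cells)
    steps = rng.normal(0.0, 1.0, size=(n_cells, n_frames, 2)) * sigma
    path = np.concatenate(
        [start[:, None, :], start[:, None, :] + np.cumsum(steps, axis=1)], axis=1
    )

    track_id = np.repeat(np.arange(n_cells), n_frames + 1)
    frame = np.tile(np.arange(n_frames + 1), n_cells)
    flat = path.reshape(-1, 2)
    return pd.DataFrame(
        {
            "track_id": track_id,
            "frame": frame,
            "x_px": flat[:, 1],
            "y_px": flat[:, 0],
        }
    )


# ---------------------------------------------------------------------------
# count-level dose-response plates
# ---------------------------------------------------------------------------


def simulate_dose_response_plate(
    drug: DrugEffectModel,
    concentrations: Sequence[float],
    n_replicates: int = 3,
    cv: float = 0.05,
    seed: int = 0,
    baseline_migrated: float = 200.0,
    baseline_viable: float = 2000.0,
    proliferation_rate: float = 0.5,
    arac_mode: bool = False,
    plate_id: str = "P1",
) -> pd.DataFrame:
    """Well-level migrated / viable counts for a concentration series.

    This is the fast, count-level counterpart of rendering and re-quantifying
    full wells: the expected migrated count is proportional to the migration
    capacity m(c) (the walk model's in-zone count is linear in the step size
    while the diffusion length stays small against the zone radius), and the
    expected viable count reflects proliferation (suppressed by cytostasis,
    absent under AraC) and death.  Replicate noise is multiplicative Gaussian
    with the given CV.  Control wells (c = 0) are included automatically.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    concs = [0.0] + [float(c) for c in concentrations if c > 0]
    rows = []
    for c in concs:
        m = drug.migration_capacity(c)
        surv = 1.0 - drug.death(c)
        if arac_mode:
            growth = 1.0
        else:
            growth = (1.0 + proliferation_rate * (1.0 - drug.cytostasis(c))) / (
                1.0 + proliferation_rate
            )
        exp_mig = baseline_migrated * m * surv * growth
        exp_via = baseline_viable * surv * growth
        for rep in range(n_replicates):
            noise_m = max(0.0, 1.0 + rng.normal(0.0, cv))
            noise_v = max(0.0, 1.0 + rng.normal(0.0, cv))
            rows.append(
                {
                    "well_id": f"{plate_id}_c{c:g}_r{rep}",
                    "plate_id": plate_id,
                    "condition": "control" if c == 0 else "treated",
                    "concentration_pM": c,
                    "n_migrated": exp_mig * noise_m,
                    "n_viable_total": exp_via * noise_v,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# paired expression matrices
# ---------------------------------------------------------------------------


@dataclass
class SimulatedExpression:
    """A paired treated/control log2 expression matrix with planted truth.

    ``truth`` is +1 for planted up-regulated probes, -1 for down, 0 for null.
    """

    values: pd.DataFrame  # probes x samples, log2 scale
    design: pd.DataFrame  # columns: sample, lot, arm
    truth: pd.Series  # indexed by probe id


def simulate_expression(
    n_probes: int,
    n_pairs: int,
    n_up: int,
    n_down: int,
    effect_log2: float,
    sd_log2: float,
    seed: int,
    d0: float = 4.0,
    baseline_mean: float = 7.0,
    baseline_sd: float = 2.0,
    lot_sd: float = 0.3,
) -> SimulatedExpression:
    """Simulate a paired (lot-matched) two-colour-style expression experiment.

    Each of ``n_pairs`` lots contributes one treated and one control sample.
    Per-probe paired-difference variances are drawn from a scaled
    inverse-chi-square law, d0 * s0^2 / chi2(d0) with s0 = ``sd_log2``, so the
    empirical-Bayes variance moments downstream estimators assume are actually
    present.  The first ``n_up`` probes are shifted +effect_log2 in the
    treated arm, the next ``n_down`` by -effect_log2.
    """
    if n_up + n_down > n_probes:
        raise ValueError("n_up + n_down must not exceed n_probes")
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    if n_probes < 1 or sd_log2 <= 0:
        raise ValueError("degenerate simulation sizes")
    rng = np.random.default_rng(seed)

    probes = np.array([f"probe_{i:05d}" for i in range(n_probes)])
    truth = np.zeros(n_probes, dtype=int)
    truth[:n_up] = 1
    truth[n_up : n_up + n_down] = -1

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_probes)
    # paired-difference variance per probe: scaled inverse chi-square
    var_diff = d0 * sd_log2**2 / rng.chisquare(d0, size=n_probes)
    # split the difference variance evenly between the two arms
    arm_sd = np.sqrt(var_diff / 2.0)

    cols: dict[str, np.ndarray] = {}
    design_rows = []
    for lot in range(n_pairs):
        lot_shift = rng.normal(0.0, lot_sd)
        for arm in ("control", "treated"):
            eps = rng.normal(0.0, 1.0, size=n_probes) * arm_sd
            x = baseline + lot_shift + eps
            if arm == "treated":
                x = x + truth * effect_log2
            name = f"lot{lot + 1}_{arm}"
            cols[name] = x
            design_rows.append({"sample": name, "lot": f"lot{lot + 1}", "arm": arm})

    values = pd.DataFrame(cols, index=probes)
    design = pd.DataFrame(design_rows)
    return SimulatedExpression(
        values=values, design=design, truth=pd.Series(truth, index=probes)
    )


# ---------------------------------------------------------------------------
# writers (TIFF pair + JSON sidecar, track CSV, expression TSV + design CSV)
# ---------------------------------------------------------------------------


def write_well(
    gtw: GroundTruthWell,
    image_shape: tuple[int, int],
    out_dir: str | Path,
    well_id: str,
    render: RenderParams = RenderParams(),
) -> dict[str, Path]:
    """Render a well and write ``<well>_nuc.tif`` / ``<well>_cal.tif`` plus a
    JSON ground-truth sidecar."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nuc, cal = render_well(gtw, image_shape, render)
    paths = {
        "nuc": out_dir / f"{well_id}_nuc.tif",
        "cal": out_dir / f"{well_id}_cal.tif",
        "truth": out_dir / f"{well_id}_truth.json",
    }
    tifffile.imwrite(paths["nuc"], nuc)
    tifffile.imwrite(paths["cal"], cal)
    truth = {
        "well_id": well_id,
        "condition": gtw.condition,
        "concentration_pM": gtw.concentration,
        "zone_center": list(gtw.zone_center),
        "zone_radius": gtw.zone_radius,
        "n_cells": gtw.n_cells,
        "n_viable": gtw.n_viable,
        "n_in_zone_true": gtw.n_in_zone_true,
        "render": dataclasses.asdict(render),
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths


def write_tracks_csv(tracks: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    tracks.to_csv(path, index=False)
    return path


def write_expression(
    sim: SimulatedExpression, out_dir: str | Path, stem: str = "expression"
) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "values": out_dir / f"{stem}.tsv",
        "design": out_dir / f"{stem}_design.csv",
        "truth": out_dir / f"{stem}_truth.csv",
    }
    sim.values.to_csv(paths["values"], sep="\t", index_label="probe_id")
    sim.design.to_csv(paths["design"], index=False)
    sim.truth.rename("truth").to_csv(paths["truth"], index_label="probe_id")
    return paths
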