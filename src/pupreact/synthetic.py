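"""Ground-truth synthetic data for every assay in the pipeline.

No animal data ship with this package, so each analysis stage has a
generator that emulates the statistical structure its assay assumes and
returns the ground truth alongside: air-puff trial tables (intensity ramp
plus ten repeated 1.0-psi stimuli, with per-animal habituation status),
rendered pup videos whose blob follows a known displacement trace, startle
trial tables with a planted prepulse-inhibition effect, two-channel
confocal stacks with a controlled colocalization fraction, and arena
trajectories with planted zone occupancies.

Randomness: every generator derives a child stream from the spec's root
seed plus a small counter key, so outputs are bit-identical for a given
spec and independent of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .arena import ArenaGeometry, Trajectory, zone_dwell_times
from .ppi import StartleSession, StartleTrial
from .puncta import ConfocalStack
from .reactivity import PuffSession, PuffTrial
from .tracking import FrameStack, TimeSeriesTrace

_STREAM = {"puff": 0, "video": 1, "startle": 2, "stack": 3, "arena": 4}
_GENOTYPES = ("control", "mutant")


def _rng(seed: int, stream: str, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAM[stream], *map(int, key)])


def _per_genotype(value, genotype: str) -> float:
    if isinstance(value, dict):
        return float(value[genotype])
    return float(value)


# --------------------------------------------------------------------------
# air-puff sessions and videos
# --------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Generative parameters for a neonatal air-puff cohort.

    Evoked peak amplitude is ``evoked_gain_control`` px/psi times the
    stimulus intensity, scaled by ``genotype_multiplier`` in mutants and,
    for animals sampled as habituating (per-genotype Bernoulli
    ``habituation_prob``), by a geometric per-trial decay of
    ``habituation_decay`` over the repeated trials.  Multiplicative
    lognormal noise (``amplitude_noise_sd``) keeps responses positive;
    baseline segments carry additive Gaussian noise.  A fraction
    ``contamination_prob`` of trials is planted with gross baseline
    movement (above ``movement_threshold``) to exercise trial exclusion.
    """

    n_control: int = 16
    n_mutant: int = 10
    evoked_gain_control: float = 20.0            # px per psi
    genotype_multiplier: float = 1.5             # mutant amplitude scale
    intensity_levels: tuple[float, ...] = (0.10, 0.25, 0.50, 0.75, 1.0)
    n_repeated: int = 10
    habituation_prob: dict | float = field(
        default_factory=lambda: {"control": 0.8, "mutant": 0.3})
    habituation_decay: float = 0.1               # per-trial fractional decrement
    amplitude_noise_sd: float = 0.2              # lognormal sigma
    baseline_noise_sd: float = 0.3               # px
    contamination_prob: float = 0.0
    movement_threshold: float = 2.0              # px
    fps: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        vals = [self.evoked_gain_control, self.genotype_multiplier,
                self.habituation_decay, self.amplitude_noise_sd,
                self.baseline_noise_sd, self.fps]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("spec values must be finite")
        if self.genotype_multiplier < 0:
            raise ValueError("genotype_multiplier must be >= 0")
        for g in _GENOTYPES:
            p = _per_genotype(self.habituation_prob, g)
            if not 0 <= p <= 1:
                raise ValueError("habituation_prob must lie in [0, 1]")
        if not 0 <= self.habituation_decay < 1:
            raise ValueError("habituation_decay must lie in [0, 1)")
        if not 0 <= self.contamination_prob <= 1:
            raise ValueError("contamination_prob must lie in [0, 1]")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if any(b >= a for a, b in zip(self.intensity_levels[1:],
                                      self.intensity_levels)):
            raise ValueError("intensity_levels must be strictly increasing")


def generate_puff_session(spec: CohortSpec, genotype: str,
                          animal_index: int) -> tuple[PuffSession, dict]:
    """One animal's air-puff session plus its ground-truth record.

    Returns the session (5 ramp trials + ``n_repeated`` 1.0-psi trials
    with peaks, baseline movement, and planted contamination) and a dict
    with the sampled habituation status, noiseless amplitudes and planted
    contaminated-trial indices.
    """
    if genotype not in _GENOTYPES:
        raise ValueError(f"genotype must be one of {_GENOTYPES}")
    gcode = _GENOTYPES.index(genotype)
    rng = _rng(spec.seed, "puff", gcode, animal_index)
    habituating = bool(rng.random() < _per_genotype(spec.habituation_prob,
                                                    genotype))
    gain = spec.evoked_gain_control * (
        spec.genotype_multiplier if genotype == "mutant" else 1.0)
    top = max(spec.intensity_levels)

    ramp_true = [gain * i for i in spec.intensity_levels]
    decay = 1.0 - spec.habituation_decay
    rep_true = [gain * top * (decay ** j if habituating else 1.0)
                for j in range(spec.n_repeated)]

    n_trials = len(ramp_true) + len(rep_true)
    noise = rng.lognormal(0.0, spec.amplitude_noise_sd, n_trials)
    contaminated = rng.random(n_trials) < spec.contamination_prob
    base_noise = np.abs(rng.normal(0.0, spec.baseline_noise_sd, (n_trials, 10)))
    baselines = base_noise.max(axis=1)
    # planted gross movement sits well above the exclusion threshold
    gross = spec.movement_threshold * (2.0 + np.abs(rng.normal(0, 1, n_trials)))
    baselines = np.where(contaminated, gross, baselines)

    def trial(k: int, intensity: float, amp: float) -> PuffTrial:
        return PuffTrial(intensity=intensity, peak=amp * noise[k],
                         baseline_movement=float(baselines[k]))

    ramp = [trial(k, i, a)
            for k, (i, a) in enumerate(zip(spec.intensity_levels, ramp_true))]
    rep = [trial(len(ramp) + j, top, a) for j, a in enumerate(rep_true)]
    session = PuffSession(animal_id=f"{genotype}_{animal_index:03d}",
                          genotype=genotype, ramp_trials=ramp,
                          repeated_trials=rep,
                          movement_threshold=spec.movement_threshold)
    truth = {"genotype": genotype, "habituating": habituating, "gain": gain,
             "ramp_amplitudes": ramp_true, "repeated_amplitudes": rep_true,
             "contaminated_trials": np.nonzero(contaminated)[0].tolist()}
    return session, truth


def generate_cohort(spec: CohortSpec) -> tuple[list[PuffSession], list[dict]]:
    """All sessions of a cohort (controls first), with ground truths."""
    sessions, truths = [], []
    for genotype, n in (("control", spec.n_control), ("mutant", spec.n_mutant)):
        for i in range(n):
            s, t = generate_puff_session(spec, genotype, i)
            sessions.append(s)
            truths.append(t)
    return sessions, truths


def evoked_trace(amplitude: float, fps: float, onset_index: int,
                 n_post: int, bump_duration_s: float = 0.1) -> TimeSeriesTrace:
    """Noiseless displacement trace: a half-sine bump after stimulus onset.

    The bump lasts ``bump_duration_s`` (100 ms by default), starts the
    sample after onset and peaks exactly at ``amplitude`` px.
    """
    n = onset_index + n_post
    values = np.zeros(n)
    width = max(2, int(round(bump_duration_s * fps)))
    k = np.arange(1, width + 1)
    bump = amplitude * np.sin(np.pi * k / width)
    # guarantee the peak equals the amplitude even for even sample counts
    bump[np.argmax(bump)] = amplitude
    stop = min(n, onset_index + width)
    values[onset_index + 1:stop + 1] = bump[:stop - onset_index]
    return TimeSeriesTrace(values=values, sampling_rate=fps,
                           onset_index=onset_index, units="px")


def generate_puff_video(spec: CohortSpec, genotype: str, animal_index: int, *,
                        amplitude: float | None = None,
                        shape: tuple[int, int] = (64, 128),
                        onset_index: int = 15, n_post: int = 72,
                        blob_radius: int = 12,
                        pixel_noise_sd: float = 2.0,
                        ) -> tuple[FrameStack, TimeSeriesTrace, dict]:
    """Render a textured body blob following a known displacement trace.

    The blob (a disk of smooth random texture) translates along +x by the
    ground-truth trace value at each frame; Gaussian pixel noise is added.
    ``amplitude`` defaults to the animal's first repeated-trial noiseless
    amplitude.  Returns (video, ground-truth trace, info) where info
    carries the blob ROI for point seeding.
    """
    if genotype not in _GENOTYPES:
        raise ValueError(f"genotype must be one of {_GENOTYPES}")
    if amplitude is None:
        _, truth = generate_puff_session(spec, genotype, animal_index)
        amplitude = truth["repeated_amplitudes"][0]
    H, W = shape
    pad = 4
    x0 = pad + blob_radius
    y0 = H // 2
    if y0 - blob_radius < pad or y0 + blob_radius > H - pad:
        raise ValueError("frame too small for the blob")
    if x0 + blob_radius + amplitude > W - pad:
        raise ValueError("frame too small for blob plus maximum displacement")

    gcode = _GENOTYPES.index(genotype)
    rng = _rng(spec.seed, "video", gcode, animal_index)
    trace = evoked_trace(amplitude, spec.fps, onset_index, n_post)

    yy, xx = np.mgrid[0:H, 0:W]
    disk = (yy - y0) ** 2 + (xx - x0) ** 2 <= blob_radius ** 2
    texture = ndimage.gaussian_filter(rng.standard_normal((H, W)), 1.2)
    texture /= texture.std() + 1e-12
    canvas = np.where(disk, np.clip(120.0 + 55.0 * texture, 10.0, 250.0), 0.0)

    T = trace.values.size
    frames = np.empty((T, H, W))
    ys = yy.astype(float)
    for t in range(T):
        frames[t] = ndimage.map_coordinates(
            canvas, [ys, xx - trace.values[t]], order=1, mode="constant")
    if pixel_noise_sd > 0:
        frames += rng.normal(0.0, pixel_noise_sd, frames.shape)
        frames = np.clip(frames, 0.0, None)
    roi = (x0 - blob_radius, y0 - blob_radius,
           2 * blob_radius + 1, 2 * blob_radius + 1)
    info = {"roi": roi, "blob_center": (x0, y0), "blob_radius": blob_radius,
            "amplitude": amplitude}
    return FrameStack(frames=frames, fps=spec.fps), trace, info


# --------------------------------------------------------------------------
# startle trial tables
# --------------------------------------------------------------------------

@dataclass
class StartleSpec:
    """Generative parameters for a tactile-PPI startle session.

    Pulse-alone responses are ``startle_scale`` x lognormal noise;
    prepulse+pulse responses are attenuated by the planted PPI effect
    ``ppi_effect`` (pi; expected %PPI = 100 pi); prepulse-alone responses
    are ``startle_scale x prepulse_reactivity + baseline_mv`` (expected
    air-puff-alone response = prepulse_reactivity); no-stim responses are
    baseline movement.  All responses are nonnegative by construction.
    """

    n_per_block: int = 10
    startle_scale: float = 100.0                  # mV
    ppi_effect: dict | float = 0.4                # pi per genotype, in [0, 1]
    prepulse_reactivity: dict | float = 0.1       # a per genotype, >= 0
    baseline_mv: float = 2.0
    lognormal_sd: float = 0.2
    isi_levels: tuple[float, ...] = (50, 100, 250, 500, 1000)
    seed: int = 0

    def __post_init__(self) -> None:
        for g in _GENOTYPES:
            pi = _per_genotype(self.ppi_effect, g)
            if not 0 <= pi <= 1:
                raise ValueError("ppi_effect must lie in [0, 1]")
            if _per_genotype(self.prepulse_reactivity, g) < 0:
                raise ValueError("prepulse_reactivity must be >= 0")
        if self.baseline_mv < 0 or self.startle_scale <= 0:
            raise ValueError("invalid scale parameters")
        if 250 not in self.isi_levels:
            raise ValueError("the reported 250-ms ISI must be present")


def generate_startle_table(spec: StartleSpec, genotype: str,
                           animal_index: int = 0,
                           ) -> tuple[StartleSession, dict]:
    """One animal's startle session in the three-block design."""
    if genotype not in _GENOTYPES:
        raise ValueError(f"genotype must be one of {_GENOTYPES}")
    gcode = _GENOTYPES.index(genotype)
    rng = _rng(spec.seed, "startle", gcode, animal_index)
    pi = _per_genotype(spec.ppi_effect, genotype)
    a = _per_genotype(spec.prepulse_reactivity, genotype)
    n = spec.n_per_block
    ln = lambda size: rng.lognormal(0.0, spec.lognormal_sd, size)

    trials: list[StartleTrial] = []
    for r in ln(n):   # block 1: acclimation pulse-alone
        trials.append(StartleTrial("pulse_alone", spec.startle_scale * r,
                                   block="pulse_alone"))
    for r in ln(n):   # block 2: prepulse alone
        trials.append(StartleTrial(
            "prepulse_alone", spec.startle_scale * a * r + spec.baseline_mv,
            block="prepulse_alone"))
    # block 3: pseudorandomized mixed block
    mixed: list[StartleTrial] = []
    for r in ln(n):
        mixed.append(StartleTrial("pulse_alone", spec.startle_scale * r,
                                  block="mixed"))
    for r in ln(n):
        mixed.append(StartleTrial("no_stim", spec.baseline_mv * r,
                                  block="mixed"))
    for isi in spec.isi_levels:
        for r in ln(n):
            mixed.append(StartleTrial(
                "prepulse_pulse", spec.startle_scale * (1.0 - pi) * r,
                isi_ms=isi, block="mixed"))
    order = rng.permutation(len(mixed))
    trials.extend(mixed[k] for k in order)

    session = StartleSession(animal_id=f"{genotype}_{animal_index:03d}",
                             genotype=genotype, trials=trials)
    truth = {"pi": pi, "prepulse_reactivity": a,
             "expected_percent_ppi": 100.0 * pi,
             "expected_airpuff_alone": a}
    return session, truth


# --------------------------------------------------------------------------
# confocal stacks
# --------------------------------------------------------------------------

@dataclass
class StackSpec:
    """Generative parameters for a two-channel confocal stack.

    ``coloc_fraction`` of the terminals receive exactly one receptor
    punctum centered within the terminal's eroded in-plane footprint
    (round(f x n) terminals, chosen at random); background receptor
    puncta are placed outside all terminal footprints at
    ``background_puncta_density`` per um^3.  Both channels are blurred by
    a Gaussian PSF and degraded by Poisson (photon) plus Gaussian (read)
    noise; set both noise parameters to 0 for a noiseless stack.
    """

    shape: tuple[int, int, int] = (8, 256, 256)
    voxel_size: tuple[float, float, float] = (0.5, 0.1, 0.1)   # um
    n_terminals: int = 50
    terminal_diameter_range: tuple[float, float] = (0.6, 1.2)  # um
    coloc_fraction: float = 0.5
    background_puncta_density: float = 0.05      # puncta per um^3
    punctum_diameter_range: tuple[float, float] = (0.1, 0.3)   # um
    psf_sigma: float = 0.08                      # um
    poisson_scale: float = 100.0                 # photons per intensity unit
    gaussian_sd: float = 0.02
    background_avoids_terminals: bool = True
    seed: int = 0
    max_retries: int = 200

    def __post_init__(self) -> None:
        if not 0 <= self.coloc_fraction <= 1:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        if self.shape[0] < 3:
            raise ValueError("need at least 3 z-planes")
        if not 0.45 <= self.voxel_size[0] <= 0.9:
            raise ValueError("z voxel size must lie in [0.45, 0.9] um")
        if self.background_puncta_density < 0:
            raise ValueError("background density must be >= 0")


def _draw_ellipsoid(volume: np.ndarray, center: tuple[float, float, float],
                    radii_um: tuple[float, float, float],
                    voxel: tuple[float, float, float], value: float,
                    labels: np.ndarray | None = None,
                    label: int = 0) -> None:
    cz, cy, cx = center
    rz, ry, rx = (max(r / v, 1e-6) for r, v in zip(radii_um, voxel))
    z0, z1 = int(max(0, np.floor(cz - rz))), int(min(volume.shape[0] - 1,
                                                     np.ceil(cz + rz)))
    y0, y1 = int(max(0, np.floor(cy - ry))), int(min(volume.shape[1] - 1,
                                                     np.ceil(cy + ry)))
    x0, x1 = int(max(0, np.floor(cx - rx))), int(min(volume.shape[2] - 1,
                                                     np.ceil(cx + rx)))
    zz, yy, xx = np.mgrid[z0:z1 + 1, y0:y1 + 1, x0:x1 + 1]
    inside = (((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2
              + ((xx - cx) / rx) ** 2) <= 1.0
    if not inside.any():
        # sub-voxel object: rasterize to its nearest voxel
        iz = int(np.clip(round(cz), 0, volume.shape[0] - 1))
        iy = int(np.clip(round(cy), 0, volume.shape[1] - 1))
        ix = int(np.clip(round(cx), 0, volume.shape[2] - 1))
        volume[iz, iy, ix] = max(volume[iz, iy, ix], value)
        if labels is not None:
            labels[iz, iy, ix] = label
        return
    sub = volume[z0:z1 + 1, y0:y1 + 1, x0:x1 + 1]
    sub[inside] = np.maximum(sub[inside], value)
    if labels is not None:
        lsub = labels[z0:z1 + 1, y0:y1 + 1, x0:x1 + 1]
        lsub[inside] = label


def generate_confocal_stack(spec: StackSpec) -> tuple[ConfocalStack, dict]:
    """Synthetic two-channel stack plus its object-level ground truth.

    Returns the stack (channels ``"terminal"`` and ``"receptor"``) and a
    labels dict: ``terminal_labels`` (noiseless label volume),
    ``terminals`` (list of dicts with center, radii, colocalized flag) and
    ``puncta`` (center, diameter, host terminal id or 0).
    """
    rng = _rng(spec.seed, "stack", 0)
    Z, Y, X = spec.shape
    vz, vy, vx = spec.voxel_size
    term = np.zeros(spec.shape)
    rec = np.zeros(spec.shape)
    tlabels = np.zeros(spec.shape, dtype=np.int32)

    d_lo, d_hi = spec.terminal_diameter_range
    max_r_um = d_hi / 2 * 1.25
    margin_y = max_r_um / vy + 2
    margin_x = max_r_um / vx + 2
    # Terminals are single-optical-section profiles (the analysis is
    # strictly 2-D per plane): each sits centered on one z-plane with a
    # sub-voxel z extent.  Same-plane neighbours keep a 0.6-um in-plane
    # gap so PSF blur cannot merge their thresholded profiles.
    terminals = []
    placed_iplane: list[tuple[int, float, float, float]] = []  # plane, y_um, x_um, r_um
    for tid in range(1, spec.n_terminals + 1):
        placed = False
        for _ in range(spec.max_retries):
            d = rng.uniform(d_lo, d_hi)
            r = d / 2
            ratio = rng.uniform(1.0, 1.2)
            ry, rx = r * ratio, r / ratio           # axis ratio <= 1.5
            rz = 0.2 * vz
            cz = int(rng.integers(1, Z - 1))
            cy = rng.uniform(margin_y, Y - 1 - margin_y)
            cx = rng.uniform(margin_x, X - 1 - margin_x)
            if all(p != cz or np.hypot(cy * vy - py, cx * vx - px) >
                   max(ry, rx) + pr + 0.6
                   for p, py, px, pr in placed_iplane):
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place terminal {tid} without overlap after "
                f"{spec.max_retries} retries")
        placed_iplane.append((cz, cy * vy, cx * vx, max(ry, rx)))
        amp = rng.uniform(0.8, 1.2)
        _draw_ellipsoid(term, (cz, cy, cx), (rz, ry, rx), spec.voxel_size,
                        amp, labels=tlabels, label=tid)
        terminals.append({"id": tid, "center_vox": (cz, cy, cx),
                          "radii_um": (rz, ry, rx), "diameter_um": d,
                          "colocalized": False})

    n_coloc = int(round(spec.coloc_fraction * spec.n_terminals))
    coloc_ids = rng.choice(spec.n_terminals, size=n_coloc, replace=False)
    puncta = []
    p_lo, p_hi = spec.punctum_diameter_range
    for idx in coloc_ids:
        t = terminals[idx]
        t["colocalized"] = True
        cz, cy, cx = t["center_vox"]
        rz, ry, rx = t["radii_um"]
        dp = rng.uniform(p_lo, min(p_hi, max(p_lo, min(ry, rx) * 0.9)))
        rp = dp / 2
        # punctum center inside the eroded in-plane footprint, central plane
        ery = max((ry - rp) / vy, 0.5)
        erx = max((rx - rp) / vx, 0.5)
        theta = rng.uniform(0, 2 * np.pi)
        u = np.sqrt(rng.uniform(0, 1))
        py = cy + u * ery * np.sin(theta)
        px = cx + u * erx * np.cos(theta)
        pz = cz                      # punctum lives on its host's section
        amp = rng.uniform(0.8, 1.2)
        _draw_ellipsoid(rec, (pz, py, px), (0.2 * vz, rp, rp),
                        spec.voxel_size, amp)
        puncta.append({"center_vox": (pz, py, px), "diameter_um": dp,
                       "host": t["id"]})

    volume_um3 = Z * Y * X * vz * vy * vx
    n_bg = int(round(spec.background_puncta_density * volume_um3))
    for _ in range(n_bg):
        for _ in range(spec.max_retries):
            dp = rng.uniform(p_lo, p_hi)
            rp = dp / 2
            pz = int(rng.integers(1, Z - 1))
            py = rng.uniform(rp / vy + 4, Y - 5 - rp / vy)
            px = rng.uniform(rp / vx + 4, X - 5 - rp / vx)
            # keep a blur-sized clearance from terminal footprints so a
            # background punctum's centroid stays outside the mask
            pad = int(np.ceil(rp / vy)) + 3
            ih = slice(int(py) - pad, int(py) + pad + 1)
            iw = slice(int(px) - pad, int(px) + pad + 1)
            if (not spec.background_avoids_terminals
                    or not tlabels[pz, ih, iw].any()):
                amp = rng.uniform(0.8, 1.2)
                _draw_ellipsoid(rec, (pz, py, px), (0.2 * vz, rp, rp),
                                spec.voxel_size, amp)
                puncta.append({"center_vox": (pz, py, px),
                               "diameter_um": dp, "host": 0})
                break
        else:
            raise RuntimeError("could not place background punctum outside "
                               "terminal footprints")

    sig = tuple(spec.psf_sigma / v for v in spec.voxel_size)
    term_img = ndimage.gaussian_filter(term, sig)
    rec_img = ndimage.gaussian_filter(rec, sig)
    if spec.poisson_scale > 0:
        term_img = rng.poisson(term_img * spec.poisson_scale) / spec.poisson_scale
        rec_img = rng.poisson(rec_img * spec.poisson_scale) / spec.poisson_scale
    if spec.gaussian_sd > 0:
        term_img = term_img + rng.normal(0, spec.gaussian_sd, term_img.shape)
        rec_img = rec_img + rng.normal(0, spec.gaussian_sd, rec_img.shape)
    term_img = np.clip(term_img, 0, None)
    rec_img = np.clip(rec_img, 0, None)

    stack = ConfocalStack(channels={"terminal": term_img, "receptor": rec_img},
                          voxel_size=spec.voxel_size)
    labels = {"terminal_labels": tlabels, "terminals": terminals,
              "puncta": puncta, "n_colocalized": n_coloc,
              "coloc_fraction_planted": n_coloc / spec.n_terminals}
    return stack, labels


# --------------------------------------------------------------------------
# arena trajectories
# --------------------------------------------------------------------------

@dataclass
class ArenaSpec:
    """Generative parameters for an arena trajectory.

    ``occupancy_bias`` maps zone names to target time fractions (summing
    to <= 1; the remainder goes to the arena's default zone).  With no
    bias an unconstrained reflected random walk is produced.  The
    trajectory is a reflected Gaussian walk confined to the active zone of
    a round-robin bout schedule, with straight dashes between zones.
    """

    arena_kind: str = "open_field"
    geometry: ArenaGeometry | None = None
    occupancy_bias: dict | None = None
    step_sd: float = 1.0                          # cm per frame
    duration: float = 600.0                       # s
    frame_rate: float = 30.0
    seed: int = 0
    bouts_per_zone: int = 5

    def __post_init__(self) -> None:
        if self.geometry is None:
            self.geometry = ArenaGeometry(kind=self.arena_kind)
        if self.geometry.kind != self.arena_kind:
            raise ValueError("geometry kind must match arena_kind")
        if self.occupancy_bias:
            total = sum(self.occupancy_bias.values())
            if total > 1 + 1e-9:
                raise ValueError("occupancy biases must sum to <= 1")
            if any(v < 0 for v in self.occupancy_bias.values()):
                raise ValueError("occupancy biases must be nonnegative")


def _zone_rects(g: ArenaGeometry) -> tuple[dict, str]:
    """Confinement rectangle per zone and the default (remainder) zone."""
    m = 0.5
    if g.kind == "open_field":
        c = g.center_margin
        return ({"center": (c + m, g.width - c - m, c + m, g.height - c - m),
                 "border": (m, g.width - m, m, c - m)}, "border")
    if g.kind == "epm":
        hw = g.arm_width / 2
        e = hw + g.arm_length
        return ({"open": (hw + m, e - m, -hw + 0.2, hw - 0.2),
                 "closed": (-hw + 0.2, hw - 0.2, hw + m, e - m),
                 "center": (-hw + 0.2, hw - 0.2, -hw + 0.2, hw - 0.2)},
                "center")
    if g.kind == "three_chamber":
        w, L = g.chamber_width, g.chamber_length
        return ({"left": (m, w - m, m, L - m),
                 "center": (w + m, 2 * w - m, m, L - m),
                 "right": (2 * w + m, 3 * w - m, m, L - m)}, "center")
    # nort
    rects = {}
    half = max(g.investigation_radius / np.sqrt(2) - 0.2, 0.5)
    for label, (cx, cy) in g.objects.items():
        rects[label] = (cx - half, cx + half, cy - half, cy + half)
    rects["elsewhere"] = (m, g.width - m, g.height - 4.0, g.height - m)
    return rects, "elsewhere"


def _reflect(v: float, lo: float, hi: float) -> float:
    if hi <= lo:
        return lo
    span = hi - lo
    v = (v - lo) % (2 * span)
    return lo + (v if v <= span else 2 * span - v)


def generate_arena_trajectory(spec: ArenaSpec) -> tuple[Trajectory, dict]:
    """Trajectory with planted zone occupancies, plus true dwell times.

    Ground truth is the actual per-zone dwell time of the generated
    samples (computed with the same zone geometry the metrics use), so
    downstream occupancy recovery is exact; agreement with the *target*
    bias holds to within the dash-time overhead (a few percent for
    multi-minute sessions).
    """
    g = spec.geometry
    rng = _rng(spec.seed, "arena", 0)
    n = int(round(spec.duration * spec.frame_rate))
    rects, default_zone = _zone_rects(g)

    if not spec.occupancy_bias:
        xmin, xmax, ymin, ymax = g.bounds()
        xs = np.empty(n)
        ys = np.empty(n)
        x, y = (xmin + xmax) / 2, (ymin + ymax) / 2
        steps = rng.normal(0, spec.step_sd, (n, 2))
        hw = g.arm_width / 2 if g.kind == "epm" else None
        for k in range(n):
            nx = _reflect(x + steps[k, 0], xmin + 0.2, xmax - 0.2)
            ny = _reflect(y + steps[k, 1], ymin + 0.2, ymax - 0.2)
            if hw is not None and abs(nx) > hw and abs(ny) > hw:
                # keep EPM walks on the cross: clamp the smaller excursion
                if abs(nx) - hw < abs(ny) - hw:
                    nx = np.clip(nx, -hw + 0.2, hw - 0.2)
                else:
                    ny = np.clip(ny, -hw + 0.2, hw - 0.2)
            x, y = nx, ny
            xs[k], ys[k] = x, y
    else:
        bias = dict(spec.occupancy_bias)
        for z in bias:
            if z not in rects:
                raise ValueError(f"zone {z!r} not defined for {g.kind!r}")
        rem = 1.0 - sum(bias.values())
        if rem > 1e-9:
            bias[default_zone] = bias.get(default_zone, 0.0) + rem
        zones = [z for z, f in bias.items() if f > 0]
        counts = {z: int(round(bias[z] * n)) for z in zones}
        bouts: list[tuple[str, int]] = []
        K = spec.bouts_per_zone
        for k in range(K):
            for z in zones:
                share = counts[z] // K + (1 if k < counts[z] % K else 0)
                if share > 0:
                    bouts.append((z, share))
        xs, ys = np.empty(n), np.empty(n)
        first_rect = rects[bouts[0][0]]
        x = (first_rect[0] + first_rect[1]) / 2
        y = (first_rect[2] + first_rect[3]) / 2
        k = 0
        dash = max(3.0 * spec.step_sd, 2.0)
        for zone, length in bouts:
            x0, x1, y0, y1 = rects[zone]
            remaining = length
            tx = rng.uniform(x0, x1)
            ty = rng.uniform(y0, y1)
            # plus-maze arms only connect through the center square
            waypoints = ([(0.0, 0.0), (tx, ty)] if g.kind == "epm"
                         else [(tx, ty)])
            for wx, wy in waypoints:
                while remaining > 0 and np.hypot(wx - x, wy - y) > 1e-9 \
                        and not (x0 <= x <= x1 and y0 <= y <= y1):
                    d = np.hypot(wx - x, wy - y)
                    step = min(dash, d)
                    x += step * (wx - x) / (d + 1e-12)
                    y += step * (wy - y) / (d + 1e-12)
                    xs[k], ys[k] = x, y
                    k += 1
                    remaining -= 1
            while remaining > 0:
                x = _reflect(x + rng.normal(0, spec.step_sd), x0, x1)
                y = _reflect(y + rng.normal(0, spec.step_sd), y0, y1)
                xs[k], ys[k] = x, y
                k += 1
                remaining -= 1
        # rounding slack: pad/truncate to exactly n samples
        if k < n:
            xs[k:] = xs[k - 1]
            ys[k:] = ys[k - 1]
        xs, ys = xs[:n], ys[:n]

    t = np.arange(n) / spec.frame_rate
    traj = Trajectory(t=t, x=xs, y=ys, frame_rate=spec.frame_rate, arena=g)
    dwell = zone_dwell_times(traj)
    total = n / spec.frame_rate
    truth = {"dwell_s": dwell,
             "fractions": {z: s / total for z, s in dwell.items()}}
    return traj, truth
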