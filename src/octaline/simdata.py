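"""Physics-based synthetic IV-OCT pullback simulator.

Generates polar B-scans with per-A-line ground truth so the whole
classification pipeline can be exercised end to end.  The signal model
is first-order single scattering: below the lumen surface the expected
linear intensity decays as ``b * exp(-2 * mu * z * dz)`` with tissue
attenuation ``mu`` (mm^-1) and axial step ``dz`` (mm), modulated by
unit-mean multiplicative speckle (fully developed speckle is
exponential on intensity) plus an additive detection-noise floor.

Tissue classes differ in attenuation and superficial structure: lipid
pools attenuate fast with a diffuse border, fibrous/intimal tissue
attenuates slowly beneath a bright superficial (intimal) layer,
calcium sits in between with a sharp border, and the metal guidewire
produces a bright surface reflection followed by a near-total shadow.
Plaques occupy contiguous angular arcs, mirroring arc-based lumen
annotation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

CLASS_NAMES = ("intimal-thickening", "fibrous", "calcific", "lipid", "guidewire")
LIPID = CLASS_NAMES.index("lipid")
GUIDEWIRE = CLASS_NAMES.index("guidewire")

#: brightness multiplier of the superficial intimal layer
INTIMA_GAIN = 3.0
#: guidewire surface reflection: gain and axial extent (pixels)
GUIDEWIRE_GAIN = 30.0
GUIDEWIRE_REFLECT_PX = 4

SPECKLE_MODELS = ("exponential-intensity", "rayleigh-amplitude", "none")


class GeometryError(ValueError):
    """Raised when a lumen offset or array shape is inconsistent."""


class ConfigError(ValueError):
    """Raised when a simulation configuration is self-contradictory."""


@dataclass(frozen=True)
class TissueOpticsConfig:
    """Optical properties of one tissue class.

    attenuation_mu is the total attenuation coefficient in mm^-1;
    backscatter_b the mean linear backscatter amplitude at the lumen
    surface; intima_thickness_px the axial extent of the bright
    superficial layer (0 disables it); shadow marks classes whose
    signal is a surface reflection followed by shadow (guidewire).
    """

    class_name: str
    attenuation_mu: float
    backscatter_b: float
    intima_thickness_px: int = 0
    shadow: bool = False

    def __post_init__(self):
        if self.class_name not in CLASS_NAMES:
            raise ConfigError(f"unknown tissue class {self.class_name!r}")
        if self.attenuation_mu < 0:
            raise ConfigError("attenuation_mu must be >= 0")
        if self.backscatter_b <= 0:
            raise ConfigError("backscatter_b must be > 0")


def default_optics() -> dict[str, TissueOpticsConfig]:
    """Default per-class optics.

    Attenuation values sit inside ranges commonly reported for coronary
    tissue; the load-bearing property is the lipid > fibrous contrast.
    """
    table = {
        "intimal-thickening": TissueOpticsConfig("intimal-thickening", 2.0, 1.0, intima_thickness_px=20),
        "fibrous": TissueOpticsConfig("fibrous", 2.0, 1.0, intima_thickness_px=20),
        "calcific": TissueOpticsConfig("calcific", 3.0, 0.7),
        "lipid": TissueOpticsConfig("lipid", 6.0, 1.2),
        "guidewire": TissueOpticsConfig("guidewire", 0.0, 1.0, shadow=True),
    }
    _check_optics_table(table, require_contrast=True)
    return table


def _check_optics_table(table: dict[str, TissueOpticsConfig],
                        require_contrast: bool = False) -> None:
    missing = set(CLASS_NAMES) - set(table)
    if missing:
        raise ConfigError(f"optics table missing classes: {sorted(missing)}")
    # default tables must show the lipid > fibrous attenuation contrast the
    # classifier learns; custom tables may disable it (null-contrast controls)
    if require_contrast and table["lipid"].attenuation_mu <= table["fibrous"].attenuation_mu:
        raise ConfigError("lipid attenuation must exceed fibrous attenuation")


def contrast_optics(mu_lipid: float = 6.0, mu_other: float = 2.0,
                    intima_thickness_px: int = 20) -> dict[str, TissueOpticsConfig]:
    """Two-level optics: lipid at mu_lipid, every other tissue at mu_other
    beneath a bright superficial layer.  mu_lipid == mu_other gives the
    zero-contrast control table."""
    table = {c: TissueOpticsConfig(c, mu_other, 1.0, intima_thickness_px)
             for c in ("intimal-thickening", "fibrous", "calcific")}
    table["lipid"] = TissueOpticsConfig("lipid", mu_lipid, 1.0)
    table["guidewire"] = TissueOpticsConfig("guidewire", 0.0, 1.0, shadow=True)
    _check_optics_table(table)
    return table


@dataclass(frozen=True)
class SimConfig:
    n_bscans: int = 1
    alines_per_bscan: int = 1024
    depth_px: int = 1024
    axial_step_um: float = 4.8
    angular_step_deg: float = 0.35
    lumen_radius_px_range: tuple[int, int] = (80, 180)
    plaque_arc_deg_range: tuple[float, float] = (40.0, 103.4)
    class_mix: float = 0.2
    noise_floor: float = 1e-4
    speckle_model: str = "exponential-intensity"
    guidewire_arc_deg: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_bscans < 1:
            raise ConfigError("n_bscans must be >= 1")
        if not 0 <= self.class_mix < 1:
            raise ConfigError("class_mix must lie in [0, 1)")
        for lo, hi in (self.lumen_radius_px_range, self.plaque_arc_deg_range):
            if lo > hi:
                raise ConfigError("range min must be <= max")
        if self.speckle_model not in SPECKLE_MODELS:
            raise ConfigError(f"speckle_model must be one of {SPECKLE_MODELS}")
        if self.lumen_radius_px_range[1] >= self.depth_px:
            raise ConfigError("lumen radius range must stay below depth_px")
        if self.class_mix > 0:
            target = self.class_mix * self.total_angle_deg
            lo, hi = self.plaque_arc_deg_range
            if not lo <= target <= hi:
                raise ConfigError(
                    f"class_mix {self.class_mix} implies a lipid arc of {target:.1f} deg, "
                    f"outside plaque_arc_deg_range {self.plaque_arc_deg_range}"
                )

    @property
    def total_angle_deg(self) -> float:
        return self.alines_per_bscan * self.angular_step_deg


@dataclass
class PolarBScan:
    """One catheter rotation: A-lines x depth, linear intensity."""

    intensity: np.ndarray
    axial_step_um: float = 4.8
    angular_step_deg: float = 0.35

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 2:
            raise GeometryError("intensity must be 2-D (A-lines x depth)")
        if (self.intensity < 0).any():
            raise GeometryError("linear intensity must be non-negative")

    @property
    def n_alines(self) -> int:
        return self.intensity.shape[0]

    @property
    def depth_px(self) -> int:
        return self.intensity.shape[1]


@dataclass
class ALineLabels:
    """Per-A-line 5-class annotation and its binary reduction."""

    class_idx: np.ndarray  # integer codes into CLASS_NAMES

    def __post_init__(self):
        self.class_idx = np.asarray(self.class_idx, dtype=np.int64)
        if self.class_idx.ndim != 1:
            raise ValueError("labels must be 1-D")
        if ((self.class_idx < 0) | (self.class_idx >= len(CLASS_NAMES))).any():
            raise ValueError("label codes must index the five tissue classes")

    @property
    def class5(self) -> np.ndarray:
        return np.array(CLASS_NAMES, dtype=object)[self.class_idx]

    @property
    def binary(self) -> np.ndarray:
        """1 for lipid, 0 for every other class (incl. guidewire)."""
        return (self.class_idx == LIPID).astype(np.int64)

    def __len__(self) -> int:
        return len(self.class_idx)


@dataclass
class SimulatedPullback:
    bscans: list[PolarBScan]
    labels: list[ALineLabels]
    truth_mu: list[np.ndarray]  # generating attenuation per A-line, mm^-1
    config: SimConfig
    optics: dict[str, TissueOpticsConfig] = field(default_factory=default_optics)

    def __len__(self) -> int:
        return len(self.bscans)


def _speckle(shape, model: str, rng: np.random.Generator) -> np.ndarray:
    if model == "none":
        return np.ones(shape)
    if model == "exponential-intensity":
        return rng.exponential(1.0, size=shape)
    # Rayleigh amplitude with unit mean-square: intensity = amplitude^2
    amp = rng.rayleigh(scale=np.sqrt(0.5), size=shape)
    return amp * amp


def simulate_aline(
    optics: TissueOpticsConfig,
    lumen_offset: int,
    sim: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One depth profile of linear intensity for a single tissue class."""
    if lumen_offset >= sim.depth_px:
        raise GeometryError(f"lumen_offset {lumen_offset} >= depth_px {sim.depth_px}")
    z = np.arange(sim.depth_px)
    depth_below = z - lumen_offset
    signal = np.zeros(sim.depth_px)
    below = depth_below >= 0
    if optics.shadow:
        reflect = below & (depth_below < GUIDEWIRE_REFLECT_PX)
        signal[reflect] = optics.backscatter_b * GUIDEWIRE_GAIN
    else:
        dz_mm = sim.axial_step_um * 1e-3
        b = np.full(sim.depth_px, optics.backscatter_b)
        if optics.intima_thickness_px > 0:
            layer = below & (depth_below < optics.intima_thickness_px)
            b[layer] *= INTIMA_GAIN
        signal[below] = b[below] * np.exp(-2.0 * optics.attenuation_mu * depth_below[below] * dz_mm)
    signal *= _speckle(signal.shape, sim.speckle_model, rng)
    if sim.noise_floor > 0:
        signal += rng.exponential(sim.noise_floor, size=signal.shape)
    return signal


def _assign_arcs(sim: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Contiguous per-class angular arcs; exactly one guidewire arc."""
    n = sim.alines_per_bscan
    if sim.class_mix > 0:
        arc_deg = rng.uniform(*sim.plaque_arc_deg_range)
        n_lipid = int(round(arc_deg / sim.angular_step_deg))
        n_lipid = min(n_lipid, n - 3)  # leave room for the other arcs
    else:
        n_lipid = 0
    n_gw = max(1, int(round(sim.guidewire_arc_deg / sim.angular_step_deg)))
    n_rest = n - n_lipid - n_gw
    if n_rest < 3:
        raise ConfigError("class_mix/guidewire arcs leave no room for background tissue")
    # split the background into intimal-thickening / fibrous / calcific arcs
    fracs = rng.dirichlet(np.ones(3) * 4.0)
    sizes = np.floor(fracs * n_rest).astype(int)
    sizes[0] += n_rest - sizes.sum()
    segments = [(CLASS_NAMES.index(c), s) for c, s in
                zip(("intimal-thickening", "fibrous", "calcific"), sizes) if s > 0]
    segments.append((GUIDEWIRE, n_gw))
    rng.shuffle(segments)
    if n_lipid > 0:
        segments.insert(rng.integers(0, len(segments) + 1), (LIPID, n_lipid))
    labels = np.concatenate([np.full(s, c, dtype=np.int64) for c, s in segments])
    return np.roll(labels, rng.integers(0, n))


def simulate_bscan(
    sim: SimConfig,
    optics_table: dict[str, TissueOpticsConfig] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PolarBScan, ALineLabels]:
    if optics_table is None:
        optics_table = default_optics()
    _check_optics_table(optics_table)
    if rng is None:
        rng = np.random.default_rng(sim.seed)
    labels = _assign_arcs(sim, rng)
    lumen_offset = int(rng.integers(sim.lumen_radius_px_range[0],
                                    sim.lumen_radius_px_range[1] + 1))
    intensity = np.empty((sim.alines_per_bscan, sim.depth_px), dtype=np.float32)
    for i, code in enumerate(labels):
        optics = optics_table[CLASS_NAMES[code]]
        intensity[i] = simulate_aline(optics, lumen_offset, sim, rng)
    bscan = PolarBScan(intensity, axial_step_um=sim.axial_step_um,
                       angular_step_deg=sim.angular_step_deg)
    return bscan, ALineLabels(labels)


def simulate_dataset(
    sim: SimConfig,
    optics_table: dict[str, TissueOpticsConfig] | None = None,
) -> SimulatedPullback:
    """n_bscans independent B-scans from per-B-scan rng substreams."""
    if optics_table is None:
        optics_table = default_optics()
    streams = [np.random.default_rng(s) for s in
               np.random.SeedSequence(sim.seed).spawn(sim.n_bscans)]
    bscans, labels, truth = [], [], []
    for rng in streams:
        b, lab = simulate_bscan(sim, optics_table, rng)
        bscans.append(b)
        labels.append(lab)
        truth.append(np.array([optics_table[c].attenuation_mu for c in lab.class5]))
    return SimulatedPullback(bscans, labels, truth, config=sim,
                             optics=dict(optics_table))


def sim_config_to_dict(sim: SimConfig) -> dict:
    d = dataclasses.asdict(sim)
    d["lumen_radius_px_range"] = list(sim.lumen_radius_px_range)
    d["plaque_arc_deg_range"] = list(sim.plaque_arc_deg_range)
    return d
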