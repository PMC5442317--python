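"""Model parameters: definition, validation, I/O and random sampling.

Units convention (used everywhere in the package):

* length  : micrometres (um)
* time    : seconds (s)
* force   : piconewtons (pN)
* energy  : pN*um  (1 kT at ~25 degC = 4.11e-3 pN*um = 4.11 pN*nm)

Every physical constant of the model lives in one of the dataclasses below,
grouped the same way the YAML configuration file is grouped.  The *reference
parameter set* returned by :func:`build_reference_params` is the documented
default used for single runs, single-parameter sweeps and as the centre of
the random-sampling study.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import yaml

# Boltzmann constant times temperature, pN*um (4.11 pN*nm, ~25 degC).
KT = 4.11e-3

#: Euler-Mascheroni constant, used in the linear regime of the wall force.
EULER_GAMMA = 0.5772156649


class ConfigurationError(ValueError):
    """A required configuration field is missing or unparsable."""


class ValidationError(ValueError):
    """A parameter value violates a model invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


# ---------------------------------------------------------------------------
# parameter groups
# ---------------------------------------------------------------------------

@dataclass
class DynamicInstabilityParams:
    """Four-parameter plus-end dynamic instability.

    growth_speed / shrinking_speed in um/s, catastrophe_frequency /
    rescue_frequency in 1/s.  Both the bounded (f_c*v_s > f_r*v_g) and
    unbounded growth regimes are legal.
    """

    growth_speed: float = 0.04
    shrinking_speed: float = 0.15
    catastrophe_frequency: float = 0.0758333333333333
    rescue_frequency: float = 0.05

    def validate(self) -> None:
        for name in ("growth_speed", "shrinking_speed",
                     "catastrophe_frequency", "rescue_frequency"):
            _require(getattr(self, name) > 0.0,
                     f"dynamic_instability.{name} must be > 0, "
                     f"got {getattr(self, name)!r}")

    def mean_length(self) -> float:
        """Steady-state mean length in the bounded-growth regime (um).

        The classic two-state result  v_g*v_s / (f_c*v_s - f_r*v_g),
        measured from the nucleation length; ``inf`` in the unbounded
        regime where the denominator is non-positive.
        """
        den = (self.catastrophe_frequency * self.shrinking_speed
               - self.rescue_frequency * self.growth_speed)
        if den <= 0.0:
            return math.inf
        return self.growth_speed * self.shrinking_speed / den


@dataclass
class StabilizationFactors:
    """Crosslink-induced stabilization of dynamic instability.

    When a doubly bound crosslinker lies within ``stabilization_length`` (um)
    of an MT plus end, that MT's parameters are rescaled toward stability:
    f_c -> f_c / catastrophe_factor, f_r -> f_r * rescue_factor,
    v_g -> v_g * growth_factor, v_s -> v_s / shrink_factor.
    All factors are >= 1; factors of exactly 1 make stabilization a no-op.
    """

    growth_factor: float = 1.5
    shrink_factor: float = 8.0
    catastrophe_factor: float = 4.0
    rescue_factor: float = 20.0
    stabilization_length: float = 0.1

    def validate(self) -> None:
        for name in ("growth_factor", "shrink_factor",
                     "catastrophe_factor", "rescue_factor"):
            _require(getattr(self, name) >= 1.0,
                     f"stabilization.{name} must be >= 1, "
                     f"got {getattr(self, name)!r}")
        _require(self.stabilization_length > 0.0,
                 "stabilization.stabilization_length must be > 0")


@dataclass
class CrosslinkerParams:
    """Passive antiparallel crosslinkers (Ase1/PRC1-like).

    Rates follow the two-head binding scheme: a free crosslinker binds one
    head to MT lattice within ``capture_radius`` at ``one_head_on_rate`` per
    um of nearby lattice; the second head binds a (strictly antiparallel)
    partner MT with a rate density proportional to the Boltzmann factor of
    the spring stretch energy, so that static filaments recover the exact
    Gibbs occupancy.  ``bell_length`` > 0 enables slip-bond (Bell) force
    dependence of the doubly bound off-rate.
    """

    number: int = 600
    spring_constant: float = 207.0        # pN/um
    rest_length: float = 0.053            # um
    one_head_on_rate: float = 500.0       # 1/(um s)
    one_head_off_rate: float = 0.15       # 1/s
    two_head_on_rate_scale: float = 10000.0  # 1/(um s)
    two_head_off_rate: float = 0.02       # 1/s
    bound_diffusion_coefficient: float = 0.1   # um^2/s
    free_diffusion_coefficient: float = 1.0    # um^2/s
    antiparallel_only: bool = True
    antiparallel_dot_threshold: float = -0.3
    characteristic_binding_energy: float = 0.0  # kT; scales second-head affinity
    capture_radius: float = 0.053         # um (defaults to rest length)
    bell_length: float = 0.0              # um; 0 = force-independent unbinding
    minus_end_exclusion: float = 0.1      # um of lattice at the minus end
                                          # occluded by SPB material (no binding)
    partition_bin_width: float = 0.01     # um quadrature bin for pair weights

    def validate(self) -> None:
        _require(self.number >= 0, "crosslinkers.number must be >= 0")
        for name in ("one_head_on_rate", "one_head_off_rate",
                     "two_head_on_rate_scale", "two_head_off_rate",
                     "bound_diffusion_coefficient",
                     "free_diffusion_coefficient"):
            _require(getattr(self, name) >= 0.0,
                     f"crosslinkers.{name} must be >= 0")
        _require(self.rest_length > 0.0, "crosslinkers.rest_length must be > 0")
        _require(self.spring_constant >= 0.0,
                 "crosslinkers.spring_constant must be >= 0")
        _require(self.capture_radius > 0.0,
                 "crosslinkers.capture_radius must be > 0")
        _require(self.partition_bin_width > 0.0,
                 "crosslinkers.partition_bin_width must be > 0")


@dataclass
class GeometryParams:
    """Nuclear envelope, spindle pole bodies and microtubule geometry."""

    envelope_diameter: float = 2.75       # um
    spb_diameter: float = 0.18            # um
    spb_diffusion_coefficient: float = 4.5e-4  # um^2/s (in-membrane)
    spb_rotational_diffusion: float = 0.05     # rad^2/s (about membrane normal)
    mt_diameter: float = 0.025            # um
    sites_per_spb: int = 14
    tether_spring_constant: float = 100.0  # pN/um (tether-spring mode only)
    tether_rest_length: float = 0.0       # um
    initial_mt_length: float = 0.1        # um
    min_mt_length: float = 0.1            # um; renucleation floor in the engine
    max_mt_length: float = 50.0           # um; safety cap
    viscosity: float = 1.0                # pN s/um^2 (~1 Pa s, nucleoplasm)
    nucleation_tilt_sigma: float = 0.3    # spread of nucleation direction
    steric_cap_force: float = 10.0        # pN; cap on pair repulsion
    spb_repulsion_constant: float = 300.0  # pN/um; SPB exclusion (MTs and SPBs)

    def validate(self) -> None:
        _require(self.envelope_diameter > 2.0 * self.initial_mt_length,
                 "geometry.envelope_diameter must exceed twice the initial "
                 f"MT length, got {self.envelope_diameter!r}")
        _require(self.sites_per_spb >= 1, "geometry.sites_per_spb must be >= 1")
        _require(self.spb_diameter < self.envelope_diameter,
                 "geometry.spb_diameter must fit inside the envelope")
        for name in ("spb_diffusion_coefficient", "mt_diameter",
                     "initial_mt_length", "viscosity"):
            _require(getattr(self, name) > 0.0,
                     f"geometry.{name} must be > 0")


@dataclass
class WallForceParams:
    """Membrane wall force on protruding MT plus tips.

    ``asymptotic_force`` F_w is the membrane-tube force the law saturates to;
    ``tube_radius`` R_tube sets the length scales.  ``const_b`` is derived as
    sqrt(2) * R_tube (the membrane tension length) and is recomputed from
    R_tube on construction/validation.  ``blend_scale`` is the decay length
    of the 1 - exp(-L) blending factor that enforces F(0) = 0.
    """

    asymptotic_force: float = 0.0        # pN (reference: zero wall force)
    tube_radius: float = 0.05            # um
    euler_gamma: float = EULER_GAMMA
    const_a: float = 0.5416
    const_c: float = 4.038
    blend_scale: float = None            # um; default 10 * tube_radius
    const_b: float = field(default=0.0)  # derived: sqrt(2)*tube_radius

    def __post_init__(self) -> None:
        self.const_b = math.sqrt(2.0) * self.tube_radius
        if self.blend_scale is None:
            self.blend_scale = 10.0 * self.tube_radius

    def validate(self) -> None:
        _require(self.asymptotic_force >= 0.0,
                 "wall_force.asymptotic_force must be >= 0")
        _require(self.tube_radius > 0.0, "wall_force.tube_radius must be > 0")
        _require(self.blend_scale > 0.0, "wall_force.blend_scale must be > 0")
        self.const_b = math.sqrt(2.0) * self.tube_radius


@dataclass
class RatchetParams:
    """Multi-filament Brownian-ratchet polymerization against load.

    A 13-protofilament MT advances by sigma = 8/13 nm per subunit addition;
    ``stall_scale`` F_s is the stall force of the ratchet law.
    """

    protofilament_count: int = 13
    subunit_increment: float = 8.0 / 13.0 * 1e-3  # um
    stall_scale: float = 8.0                      # pN
    thermal_energy: float = KT                    # pN um

    def validate(self) -> None:
        _require(self.protofilament_count == 13,
                 "ratchet.protofilament_count is fixed at 13")
        _require(abs(self.subunit_increment - 8.0 / 13.0 * 1e-3) < 1e-15,
                 "ratchet.subunit_increment is fixed at 8/13 nm")
        _require(self.stall_scale > 0.0, "ratchet.stall_scale must be > 0")
        _require(self.thermal_energy > 0.0, "ratchet.thermal_energy must be > 0")


@dataclass
class SimulationControl:
    """Numerical control: timestep, duration, output cadence, seeding."""

    timestep: float = 5e-5         # s
    total_time: float = 600.0      # s (10-min mitotic window)
    frame_interval: float = 1.0    # s
    rng_seed: int = 0
    stabilization_enabled: bool = True
    kmc_interval: int = 1          # crosslinker kMC every N timesteps
    ratchet_load_source: str = "boundary"  # "boundary" | "none"
    tether_mode: str = "pivot"     # "pivot" (minus end pinned at its site)

    def validate(self) -> None:
        _require(self.timestep > 0.0, "control.timestep must be > 0")
        _require(self.frame_interval >= self.timestep,
                 "control.frame_interval must be >= timestep")
        _require(self.total_time >= self.frame_interval,
                 "control.total_time must be >= frame_interval")
        _require(self.kmc_interval >= 1, "control.kmc_interval must be >= 1")
        _require(self.ratchet_load_source in ("boundary", "none"),
                 "control.ratchet_load_source must be 'boundary' or 'none'")
        _require(self.tether_mode == "pivot",
                 "control.tether_mode: only 'pivot' is supported by the engine")


def reduced_accuracy_control(**overrides) -> SimulationControl:
    """Coarse-timestep control settings for large batch studies.

    dt = 2 ms with crosslinker kinetics sub-sampled every 10 steps.  This is
    the documented reduced-accuracy tier used for parameter scans and sweeps;
    single-run convergence against dt = 0.5 ms is part of the test suite.
    """
    kw = dict(timestep=2e-3, kmc_interval=10)
    kw.update(overrides)
    return SimulationControl(**kw)


# ---------------------------------------------------------------------------
# aggregate
# ---------------------------------------------------------------------------

_SECTION_TYPES = {
    "geometry": GeometryParams,
    "dynamic_instability": DynamicInstabilityParams,
    "stabilization": StabilizationFactors,
    "crosslinkers": CrosslinkerParams,
    "wall_force": WallForceParams,
    "ratchet": RatchetParams,
    "control": SimulationControl,
}


@dataclass
class SimulationParameters:
    """The complete, validated parameter set of one simulation."""

    geometry: GeometryParams = field(default_factory=GeometryParams)
    dynamic_instability: DynamicInstabilityParams = field(
        default_factory=DynamicInstabilityParams)
    stabilization: StabilizationFactors = field(
        default_factory=StabilizationFactors)
    crosslinkers: CrosslinkerParams = field(default_factory=CrosslinkerParams)
    wall_force: WallForceParams = field(default_factory=WallForceParams)
    ratchet: RatchetParams = field(default_factory=RatchetParams)
    control: SimulationControl = field(default_factory=SimulationControl)
    kT: float = KT

    def validate(self) -> "SimulationParameters":
        for name in _SECTION_TYPES:
            getattr(self, name).validate()
        _require(self.kT > 0.0, "kT must be > 0")
        return self

    def copy(self) -> "SimulationParameters":
        return dataclasses.replace(
            self, **{name: dataclasses.replace(getattr(self, name))
                     for name in _SECTION_TYPES})

    def to_dict(self) -> dict:
        d = {name: dataclasses.asdict(getattr(self, name))
             for name in _SECTION_TYPES}
        d["kT"] = self.kT
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationParameters":
        kwargs = {}
        for name, typ in _SECTION_TYPES.items():
            section = dict(data.get(name, {}))
            section.pop("const_b", None)  # derived, recomputed
            known = {f.name for f in dataclasses.fields(typ)}
            unknown = set(section) - known
            if unknown:
                raise ConfigurationError(
                    f"unknown field(s) in [{name}]: {sorted(unknown)}")
            try:
                kwargs[name] = typ(**section)
            except TypeError as exc:  # pragma: no cover - defensive
                raise ConfigurationError(f"bad section [{name}]: {exc}") from exc
        kwargs["kT"] = float(data.get("kT", KT))
        return cls(**kwargs).validate()


def build_reference_params() -> SimulationParameters:
    """Return the documented reference parameter set.

    The dynamic-instability values are fixed so that the unstabilized
    bounded-growth mean length v_g*v_s/(f_c*v_s - f_r*v_g) equals 0.64 um
    exactly: the catastrophe frequency is derived from the other three
    speeds/rates and the target mean.  Stabilization factors satisfy the
    thresholds required for assembly (rescue x20 >= 10, shrink /8 >= 5).
    The reference wall force is zero, the regime in which simulated spindle
    lengths match experimentally observed short spindles.
    """
    v_g, v_s, f_r = 0.04, 0.15, 0.05
    target = 0.64
    f_c = (v_g * v_s / target + f_r * v_g) / v_s
    p = SimulationParameters(
        dynamic_instability=DynamicInstabilityParams(
            growth_speed=v_g, shrinking_speed=v_s,
            catastrophe_frequency=f_c, rescue_frequency=f_r),
    )
    return p.validate()


# ---------------------------------------------------------------------------
# config file I/O (YAML)
# ---------------------------------------------------------------------------

def load_config(path) -> SimulationParameters:
    """Load a YAML configuration file into validated parameters.

    Absent optional fields take the documented defaults; a missing or
    malformed file raises :class:`ConfigurationError`, invariant violations
    raise :class:`ValidationError` naming the offending field.
    """
    try:
        with open(path, "r") as fh:
            data = yaml.safe_load(fh)
    except OSError as exc:
        raise ConfigurationError(f"cannot read config {path!r}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse config {path!r}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config {path!r} is not a mapping")
    return SimulationParameters.from_dict(data)


def write_config(params: SimulationParameters, path) -> None:
    """Write a canonicalized copy of a resolved parameter set to YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# random sampling of the 9-parameter space
# ---------------------------------------------------------------------------

#: canonical order of the sampled quantities
SAMPLED_PARAMETERS = (
    "n_crosslinkers",
    "growth_speed",
    "shrinking_speed",
    "rescue_frequency",
    "catastrophe_frequency",
    "growth_factor",
    "shrink_factor",
    "catastrophe_factor",
    "rescue_factor",
)

_STABILIZATION_FACTOR_NAMES = (
    "growth_factor", "shrink_factor", "catastrophe_factor", "rescue_factor")


@dataclass
class SamplingRanges:
    """(min, max) bounds for each of the 9 sampled parameters."""

    bounds: dict

    def validate(self) -> "SamplingRanges":
        if set(self.bounds) != set(SAMPLED_PARAMETERS):
            missing = set(SAMPLED_PARAMETERS) - set(self.bounds)
            extra = set(self.bounds) - set(SAMPLED_PARAMETERS)
            raise ValidationError(
                f"sampling ranges must cover exactly the 9 sampled "
                f"parameters; missing={sorted(missing)} extra={sorted(extra)}")
        for name, (lo, hi) in self.bounds.items():
            _require(lo <= hi, f"sampling range for {name}: min {lo} > max {hi}")
        return self

    @classmethod
    def default(cls) -> "SamplingRanges":
        """Documented default scan ranges around the reference set.

        Dynamic-instability rates/speeds span one order of magnitude
        either side of their reference values (a range over which isolated
        mean MT lengths vary from far below to far above the pole-to-pole
        scale), the crosslinker count spans 0 to 2x its reference value, and
        stabilization factors span 1-50.
        """
        ref = build_reference_params()
        di = ref.dynamic_instability
        return cls(bounds={
            "n_crosslinkers": (0.0, 2.0 * ref.crosslinkers.number),
            "growth_speed": (0.1 * di.growth_speed, 10.0 * di.growth_speed),
            "shrinking_speed": (0.1 * di.shrinking_speed,
                                10.0 * di.shrinking_speed),
            "rescue_frequency": (0.1 * di.rescue_frequency,
                                 10.0 * di.rescue_frequency),
            "catastrophe_frequency": (0.1 * di.catastrophe_frequency,
                                      10.0 * di.catastrophe_frequency),
            "growth_factor": (1.0, 50.0),
            "shrink_factor": (1.0, 50.0),
            "catastrophe_factor": (1.0, 50.0),
            "rescue_factor": (1.0, 50.0),
        }).validate()

    @classmethod
    def from_json(cls, path) -> "SamplingRanges":
        with open(path) as fh:
            data = json.load(fh)
        return cls(bounds={k: (float(v[0]), float(v[1]))
                           for k, v in data.items()}).validate()

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({k: list(v) for k, v in self.bounds.items()}, fh,
                      indent=1, sort_keys=True)


@dataclass
class ParameterSample:
    """One point of the 9-dimensional random-sampling study."""

    index: int
    sampled: dict
    params: SimulationParameters
    outcomes: list = field(default_factory=list)  # filled by the scan driver


def apply_sampled(base: SimulationParameters, sampled: dict) -> SimulationParameters:
    """Return a copy of ``base`` with the 9 sampled quantities overridden."""
    p = base.copy()
    p.crosslinkers.number = int(round(sampled["n_crosslinkers"]))
    di = p.dynamic_instability
    di.growth_speed = sampled["growth_speed"]
    di.shrinking_speed = sampled["shrinking_speed"]
    di.rescue_frequency = sampled["rescue_frequency"]
    di.catastrophe_frequency = sampled["catastrophe_frequency"]
    st = p.stabilization
    st.growth_factor = sampled["growth_factor"]
    st.shrink_factor = sampled["shrink_factor"]
    st.catastrophe_factor = sampled["catastrophe_factor"]
    st.rescue_factor = sampled["rescue_factor"]
    return p.validate()


def sample_parameter_sets(ranges: SamplingRanges, n_sets: int, seed: int,
                          stabilization_enabled: bool = True,
                          base: SimulationParameters | None = None,
                          ) -> list[ParameterSample]:
    """Draw ``n_sets`` parameter sets uniformly over the given ranges.

    Each of the 9 parameters is drawn independently and uniformly from its
    [min, max] interval.  With ``stabilization_enabled=False`` the four
    stabilization factors are held at exactly 1 and only the remaining five
    parameters vary (the no-stabilization knockout study).  Deterministic
    given (ranges, n_sets, seed).
    """
    if n_sets < 1:
        raise ValidationError(f"n_sets must be >= 1, got {n_sets}")
    ranges.validate()
    if base is None:
        base = build_reference_params()
    rng = np.random.Generator(np.random.PCG64(seed))
    out: list[ParameterSample] = []
    for i in range(n_sets):
        sampled = {}
        for name in SAMPLED_PARAMETERS:
            lo, hi = ranges.bounds[name]
            if (not stabilization_enabled
                    and name in _STABILIZATION_FACTOR_NAMES):
                sampled[name] = 1.0
                continue
            sampled[name] = float(rng.uniform(lo, hi))
        p = apply_sampled(base, sampled)
        p.control.stabilization_enabled = stabilization_enabled
        out.append(ParameterSample(index=i, sampled=sampled, params=p))
    return out


def iter_reference_table() -> Iterator[tuple[str, object]]:
    """Yield (dotted name, value) pairs of the full reference set."""
    ref = build_reference_params()
    for section in _SECTION_TYPES:
        obj = getattr(ref, section)
        for f in dataclasses.fields(obj):
            yield f"{section}.{f.name}", getattr(obj, f.name)
    yield "kT", ref.kT
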