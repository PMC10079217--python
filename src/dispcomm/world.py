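"""Geometry and physics of the one-dimensional circular foraging world.

The environment is the perimeter of a circle, parameterized by an angle in
``[-pi, pi)``.  A nest (the communication area) is centered on 0 and five
foraging sites tile the half of the circle opposite the nest.  Two agents, a
*sender* and a *receiver*, move along the perimeter in discrete time steps;
the sender can detect food under its feet and emit a signal whose amplitude
the receiver perceives only while both agents are inside the nest.

All angle arithmetic is modulo 2*pi.  Arcs are half-open intervals
``[center - length/2, center + length/2)`` so that adjacent sites (whose
centers are pi/4 apart) tile a contiguous region without overlapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TWO_PI = 2.0 * np.pi

#: Maximum angular speed of either agent, in radians per time step.
MAX_SPEED = np.pi / 9.0

#: Number of time steps in one trial.
TRIAL_STEPS = 100

#: Centers of the five foraging sites (radians).
SITE_CENTERS = (np.pi / 2, 3 * np.pi / 4, np.pi, -3 * np.pi / 4, -np.pi / 2)

#: Arc length of each foraging site (radians).
SITE_LENGTH = np.pi / 4

#: Center and arc length of the nest / communication area (radians).
NEST_CENTER = 0.0
NEST_LENGTH = np.pi / 2


def normalize_angle(angle):
    """Normalize an angle (scalar or array) to the half-open ``[-pi, pi)``.

    Idempotent: normalizing twice gives the same value.  ``+pi`` maps to
    ``-pi`` (the two labels denote the same point on the circle).
    """
    return np.mod(np.asarray(angle) + np.pi, TWO_PI) - np.pi


@dataclass(frozen=True)
class Arc:
    """A half-open arc ``[center - length/2, center + length/2)`` on the circle."""

    center: float
    length: float

    def __post_init__(self):
        if not self.length > 0:
            raise ValueError("arc length must be positive")
        object.__setattr__(self, "center", float(normalize_angle(self.center)))

    def contains(self, position):
        """Wrap-aware membership test; accepts scalars or arrays.

        Closed at the lower edge, open at the upper edge.
        """
        offset = normalize_angle(np.asarray(position) - self.center)
        return (offset >= -self.length / 2) & (offset < self.length / 2)


@dataclass(frozen=True)
class WorldSpec:
    """Static geometry and timing constants for one experiment.

    Defaults reproduce the standard setup: five pi/4-wide foraging sites at
    pi/2, 3pi/4, pi, -3pi/4, -pi/2, a pi/2-wide nest centered on 0, maximum
    speed pi/9 per step and 100-step trials.
    """

    sites: tuple[Arc, ...] = field(
        default_factory=lambda: tuple(Arc(c, SITE_LENGTH) for c in SITE_CENTERS)
    )
    nest: Arc = field(default_factory=lambda: Arc(NEST_CENTER, NEST_LENGTH))
    max_speed: float = MAX_SPEED
    trial_steps: int = TRIAL_STEPS

    def __post_init__(self):
        if len(self.sites) != 5:
            raise ValueError("a world has exactly five foraging sites")

    @property
    def site_centers(self) -> np.ndarray:
        return np.array([a.center for a in self.sites])

    @property
    def site_length(self) -> float:
        return self.sites[0].length


def in_arc(position, arc: Arc):
    """True iff ``position`` lies inside the half-open arc (wrap-aware)."""
    return arc.contains(position)


def food_sensor(sender_pos, food_site_index: int, world: WorldSpec):
    """Floor sensor of the sender: 1 iff it stands on the food-bearing site.

    Non-food sites do not trigger the sensor.
    """
    if not 0 <= food_site_index < len(world.sites):
        raise IndexError(f"invalid foraging-site index {food_site_index}")
    return np.where(world.sites[food_site_index].contains(sender_pos), 1.0, 0.0)


def step_position(position, speed, direction, world: WorldSpec | None = None):
    """Advance an agent by ``direction * speed`` radians, wrap-normalized.

    ``speed`` must be within ``[0, max_speed]``.  Agents are points and never
    collide, so no interaction term exists.
    """
    max_speed = (world or _DEFAULT_WORLD).max_speed
    speed = np.asarray(speed)
    if np.any(speed < 0) or np.any(speed > max_speed + 1e-12):
        raise ValueError("speed out of [0, max_speed] bounds")
    return normalize_angle(np.asarray(position) + np.asarray(direction) * speed)


def perceived_signal(sender_pos, receiver_pos, emitted, world: WorldSpec):
    """Nest-gated signal transmission.

    The receiver perceives the emitted amplitude only while both agents are
    simultaneously inside the nest; elsewhere the perceived signal is 0.
    """
    gate = world.nest.contains(sender_pos) & world.nest.contains(receiver_pos)
    return np.where(gate, emitted, 0.0)


_DEFAULT_WORLD = WorldSpec()


def default_world() -> WorldSpec:
    """The standard world geometry (shared, immutable)."""
    return _DEFAULT_WORLD
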