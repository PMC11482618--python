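"""Ethogram configuration: behaviors, zone rules and their validation.

An ethogram is a catalogue of mutually exclusive behaviors used for
systematic coding.  Here each non-default behavior may carry a *zone rule*:
an axis-aligned pixel box per body part that a tracked keypoint must fall
inside for the frame to be coded as that behavior.  One behavior is the
default — it is coded whenever the animal is in view but no zone rule
matches (for elephants typically 'Standing').  Frames where no anchor
keypoint is valid are coded with the ``OUT_OF_VIEW`` sentinel, covering
both genuine absence and frames the pose model failed to label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

#: Sentinel label for time where no behavior could be observed or classified.
#: It is not a Behavior: it never has a zone rule and always loses ties.
OUT_OF_VIEW = "Out of view"


class ConfigError(ValueError):
    """Base class for ethogram-configuration validation errors."""


class MissingDefaultError(ConfigError):
    """Raised when not exactly one behavior is flagged as the default."""


class DuplicateNameError(ConfigError):
    """Raised when two behaviors share a name."""


class DuplicatePriorityError(ConfigError):
    """Raised when two zone rules share a priority rank."""


class UnknownBehaviorError(ConfigError):
    """Raised when a zone rule references an undeclared behavior."""


class UnknownBodypartError(ConfigError):
    """Raised when a rule or anchor references an undeclared body part."""


class InvalidBoxError(ConfigError):
    """Raised when a zone box has inverted or missing bounds."""


@dataclass(frozen=True)
class Behavior:
    """One ethogram entry.

    Parameters
    ----------
    name:
        Unique behavior label, e.g. ``"Lying down"``.
    is_default:
        Exactly one behavior per config is the default fallback.
    min_duration_s:
        Minimum bout length in seconds; runs shorter than this are
        relabeled to the default behavior (0 disables the rule).  Used for
        stereotypic sway, which only counts when sustained at least 5 s.
    """

    name: str
    is_default: bool = False
    min_duration_s: float = 0.0

    def __post_init__(self) -> None:
        if self.min_duration_s < 0:
            raise ConfigError(f"behavior {self.name!r}: min_duration_s must be >= 0")


@dataclass(frozen=True)
class BoxConstraint:
    """Axis-aligned pixel box one body part must lie inside (inclusive).

    Pixel coordinates follow the pose-CSV convention: origin at the image
    top-left, y increasing downward.
    """

    bodypart: str
    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min <= self.x_max and self.y_min <= self.y_max):
            raise InvalidBoxError(
                f"constraint on {self.bodypart!r}: box bounds inverted "
                f"({self.x_min}..{self.x_max}, {self.y_min}..{self.y_max})"
            )

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max


@dataclass(frozen=True)
class ZoneRule:
    """Coordinate-limit rule mapping keypoint positions to one behavior.

    A rule matches a frame iff *all* its constrained body parts are valid
    (labeled, likelihood at or above the p-cutoff) and inside their boxes.
    When several rules match, the lowest ``priority`` integer wins.
    """

    behavior: str
    priority: int
    constraints: tuple[BoxConstraint, ...]

    def __post_init__(self) -> None:
        if not self.constraints:
            raise ConfigError(f"zone rule for {self.behavior!r} has no constraints")


@dataclass
class EthogramConfig:
    """Validated ethogram plus the frame/threshold context it applies in.

    ``geometry`` is optional simulator support: a representative keypoint
    placement (pre-noise) for each behavior, used by the synthetic-night
    generator and ignored by the classifier.
    """

    behaviors: list[Behavior]
    zone_rules: list[ZoneRule]
    bodyparts: list[str]
    anchor_bodyparts: list[str]
    fps: float = 25.0
    p_cutoff: float = 0.5
    frame_width: int = 1920
    frame_height: int = 1080
    geometry: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- derived views ---------------------------------------------------
    @property
    def behavior_names(self) -> list[str]:
        return [b.name for b in self.behaviors]

    @property
    def default_behavior(self) -> str:
        return next(b.name for b in self.behaviors if b.is_default)

    @property
    def label_order(self) -> list[str]:
        """Canonical label order for reports: behaviors then OUT_OF_VIEW."""
        return self.behavior_names + [OUT_OF_VIEW]

    def rules_by_priority(self) -> list[ZoneRule]:
        return sorted(self.zone_rules, key=lambda r: r.priority)

    def tie_rank(self) -> dict[str, int]:
        """Tie-break order for second aggregation.

        Zone-ruled behaviors rank by rule priority, behaviors without a
        rule (including the default) follow in declaration order, and
        OUT_OF_VIEW ranks last so it loses every tie.
        """
        ranked = [r.behavior for r in self.rules_by_priority()]
        ranked += [b.name for b in self.behaviors if b.name not in ranked]
        ranked.append(OUT_OF_VIEW)
        return {name: i for i, name in enumerate(ranked)}

    def behavior(self, name: str) -> Behavior:
        for b in self.behaviors:
            if b.name == name:
                return b
        raise UnknownBehaviorError(f"behavior {name!r} not declared")

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        names = [b.name for b in self.behaviors]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise DuplicateNameError(f"duplicate behavior names: {dup}")
        defaults = [b.name for b in self.behaviors if b.is_default]
        if len(defaults) != 1:
            raise MissingDefaultError(
                f"exactly one default behavior required, got {defaults or 'none'}"
            )
        if OUT_OF_VIEW in names:
            raise ConfigError(
                f"{OUT_OF_VIEW!r} is a reserved sentinel, not a behavior"
            )
        priorities = [r.priority for r in self.zone_rules]
        if len(set(priorities)) != len(priorities):
            dup = sorted({p for p in priorities if priorities.count(p) > 1})
            raise DuplicatePriorityError(f"duplicate zone-rule priorities: {dup}")
        for rule in self.zone_rules:
            if rule.behavior not in names:
                raise UnknownBehaviorError(
                    f"zone rule references undeclared behavior {rule.behavior!r}"
                )
            if rule.behavior == defaults[0]:
                raise ConfigError(
                    f"default behavior {defaults[0]!r} must not have a zone rule"
                )
            for c in rule.constraints:
                if c.bodypart not in self.bodyparts:
                    raise UnknownBodypartError(
                        f"zone rule for {rule.behavior!r} references "
                        f"undeclared bodypart {c.bodypart!r}"
                    )
        for part in self.anchor_bodyparts:
            if part not in self.bodyparts:
                raise UnknownBodypartError(f"anchor bodypart {part!r} not declared")
        if not self.anchor_bodyparts:
            raise ConfigError("at least one anchor bodypart is required")
        if not self.fps > 0:
            raise ConfigError(f"fps must be > 0, got {self.fps}")
        if not 0.0 <= self.p_cutoff <= 1.0:
            raise ConfigError(f"p_cutoff must be in [0, 1], got {self.p_cutoff}")
        for behavior, placement in self.geometry.items():
            if behavior not in names:
                raise UnknownBehaviorError(
                    f"geometry given for undeclared behavior {behavior!r}"
                )
            for part in placement:
                if part not in self.bodyparts:
                    raise UnknownBodypartError(
                        f"geometry for {behavior!r} references undeclared "
                        f"bodypart {part!r}"
                    )


# -- serialization -------------------------------------------------------

def _config_to_dict(cfg: EthogramConfig) -> dict:
    return {
        "fps": cfg.fps,
        "p_cutoff": cfg.p_cutoff,
        "frame_width": cfg.frame_width,
        "frame_height": cfg.frame_height,
        "bodyparts": list(cfg.bodyparts),
        "anchor_bodyparts": list(cfg.anchor_bodyparts),
        "behaviors": [
            {
                "name": b.name,
                **({"default": True} if b.is_default else {}),
                **(
                    {"min_duration_s": b.min_duration_s}
                    if b.min_duration_s
                    else {}
                ),
            }
            for b in cfg.behaviors
        ],
        "zone_rules": [
            {
                "behavior": r.behavior,
                "priority": r.priority,
                "constraints": [
                    {
                        "bodypart": c.bodypart,
                        "x": [c.x_min, c.x_max],
                        "y": [c.y_min, c.y_max],
                    }
                    for c in r.constraints
                ],
            }
            for r in cfg.zone_rules
        ],
        "geometry": {
            behavior: {part: list(xy) for part, xy in placement.items()}
            for behavior, placement in cfg.geometry.items()
        },
    }


def _config_from_dict(raw: Mapping) -> EthogramConfig:
    try:
        behaviors = [
            Behavior(
                name=str(b["name"]),
                is_default=bool(b.get("default", False)),
                min_duration_s=float(b.get("min_duration_s", 0.0)),
            )
            for b in raw.get("behaviors", [])
        ]
        zone_rules = [
            ZoneRule(
                behavior=str(r["behavior"]),
                priority=int(r["priority"]),
                constraints=tuple(
                    BoxConstraint(
                        bodypart=str(c["bodypart"]),
                        x_min=float(c["x"][0]),
                        x_max=float(c["x"][1]),
                        y_min=float(c["y"][0]),
                        y_max=float(c["y"][1]),
                    )
                    for c in r.get("constraints", [])
                ),
            )
            for r in raw.get("zone_rules", [])
        ]
        geometry = {
            str(behavior): {
                str(part): (float(xy[0]), float(xy[1]))
                for part, xy in placement.items()
            }
            for behavior, placement in (raw.get("geometry") or {}).items()
        }
        return EthogramConfig(
            behaviors=behaviors,
            zone_rules=zone_rules,
            bodyparts=[str(p) for p in raw.get("bodyparts", [])],
            anchor_bodyparts=[str(p) for p in raw.get("anchor_bodyparts", [])],
            fps=float(raw.get("fps", 25.0)),
            p_cutoff=float(raw.get("p_cutoff", 0.5)),
            frame_width=int(raw.get("frame_width", 1920)),
            frame_height=int(raw.get("frame_height", 1080)),
            geometry=geometry,
        )
    except (KeyError, TypeError, IndexError) as exc:
        raise ConfigError(f"malformed config structure: {exc!r}") from exc


def load_config(path: str | Path) -> EthogramConfig:
    """Load and validate an ethogram config from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: config root must be a mapping")
    return _config_from_dict(raw)


def write_config(cfg: EthogramConfig, path: str | Path) -> None:
    """Write a config back to YAML; ``load_config`` round-trips it."""
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(cfg), fh, sort_keys=False)


def default_config() -> EthogramConfig:
    """The bundled elephant night-ethogram config.

    Behaviors follow the standard captive-elephant night ethogram
    (Standing as default, Lying down, Drinking, Foraging, Hay-net, and
    Swaying with a 5-s minimum).  The zone boxes and simulator geometry
    are illustrative for a 1920x1080 frame: real deployments calibrate
    them against a manually scored control period.  Swaying carries no
    zone rule — it is not localizable to a fixed image zone and is
    instead detected from trunk-root displacement.
    """
    ref = resources.files("ethotrace").joinpath("data/default_config.yaml")
    with resources.as_file(ref) as path:
        return load_config(path)
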