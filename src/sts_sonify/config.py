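"""Pipeline configuration: shipped defaults, YAML round-trip, provenance.

The shipped ``defaults.yaml`` annotates every default with a provenance
tag so the boundary between values stated by the capture/sonification
model description (``reported``) and values this package had to choose
(``implementation-default``) stays machine-readable.  User config files
may use either the annotated ``{value: ..., provenance: ...}`` leaf form
or plain values.
"""

from __future__ import annotations

import hashlib
import importlib.resources
from dataclasses import dataclass, field

import yaml

from .features import FreezeConfig, JerkConfig
from .fusion import FusionConfig
from .kinematics import Anthropometry, SegmentParams
from .mapping import ScaleSpec, default_mapping_specs
from .simulate import PostureConfig
from .synthesis import ClipParams


def _strip_provenance(node):
    """Collapse ``{value, provenance}`` leaves to plain values."""
    if isinstance(node, dict):
        if set(node) <= {"value", "provenance"} and "value" in node:
            return _strip_provenance(node["value"])
        return {k: _strip_provenance(v) for k, v in node.items()}
    return node


def load_default_tree() -> dict:
    """The shipped defaults as a plain nested dict (provenance stripped)."""
    text = (
        importlib.resources.files("sts_sonify").joinpath("defaults.yaml")
        .read_text()
    )
    return _strip_provenance(yaml.safe_load(text))


def load_provenance_tree() -> dict:
    """The shipped defaults with provenance annotations intact."""
    text = (
        importlib.resources.files("sts_sonify").joinpath("defaults.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


def _deep_update(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class PipelineConfig:
    """All tunables of the capture -> features -> sound pipeline."""

    fs: float = 100.0
    fusion: FusionConfig = field(default_factory=FusionConfig)
    anthropometry: Anthropometry = field(default_factory=Anthropometry)
    posture: PostureConfig = field(default_factory=PostureConfig)
    freeze: FreezeConfig = field(default_factory=FreezeConfig)
    jerk: JerkConfig = field(default_factory=JerkConfig)
    speed_hi: float = 0.5
    speed_lo: float = 0.03
    speed_smoothing_fc: float = 2.0
    jerk_ceiling_factor: float = 4.0
    scale: ScaleSpec = field(default_factory=ScaleSpec)
    clip: ClipParams = field(default_factory=ClipParams)
    combo: str = "SJPF"

    def mapping_specs(self) -> dict:
        return default_mapping_specs(
            speed_hi=self.speed_hi,
            speed_lo=self.speed_lo,
            jerk_threshold=self.jerk.jerk_threshold,
            jerk_ceiling=self.jerk_ceiling_factor * self.jerk.jerk_threshold,
        )

    @classmethod
    def from_tree(cls, tree: dict) -> "PipelineConfig":
        anth = tree["anthropometry"]
        return cls(
            fs=float(tree["sampling"]["fs"]),
            fusion=FusionConfig(**tree["fusion"]),
            anthropometry=Anthropometry(
                shank=SegmentParams(**anth["shank"]),
                thigh=SegmentParams(**anth["thigh"]),
                hat=SegmentParams(**anth["hat"]),
            ),
            posture=PostureConfig(
                **{k: v for k, v in tree["posture"].items()}
            ),
            freeze=FreezeConfig(**tree["features"]["freeze"]),
            jerk=JerkConfig(
                jerk_threshold=tree["features"]["jerk"]["jerk_threshold"],
                smoothing_fc=tree["features"]["jerk"]["smoothing_fc"],
            ),
            speed_hi=float(tree["mapping"]["speed_hi"]),
            speed_lo=float(tree["mapping"]["speed_lo"]),
            speed_smoothing_fc=float(tree["features"]["speed_smoothing_fc"]),
            jerk_ceiling_factor=float(tree["mapping"]["jerk_ceiling_factor"]),
            scale=ScaleSpec(tonic=float(tree["mapping"]["scale_tonic"])),
            clip=ClipParams(
                sample_rate=int(tree["synthesis"]["sample_rate"]),
                channels=int(tree["synthesis"]["channels"]),
                bit_depth=int(tree["synthesis"]["bit_depth"]),
                duration=float(tree["synthesis"]["duration"]),
            ),
            combo=str(tree["combo"]["default"]),
        )

    def to_tree(self) -> dict:
        a = self.anthropometry
        return {
            "sampling": {"fs": self.fs},
            "fusion": {
                "beta": self.fusion.beta,
                "stationary_window": self.fusion.stationary_window,
                "median_points": self.fusion.median_points,
            },
            "anthropometry": {
                seg: {"L": sp.L, "D": sp.D, "w": sp.w}
                for seg, sp in
                (("shank", a.shank), ("thigh", a.thigh), ("hat", a.hat))
            },
            "posture": {
                k: getattr(self.posture, k)
                for k in ("sit_shank", "sit_thigh", "sit_hat",
                          "stand_shank", "stand_thigh", "stand_hat")
            },
            "features": {
                "freeze": {
                    "lowpass_order": self.freeze.lowpass_order,
                    "lowpass_fc": self.freeze.lowpass_fc,
                    "velocity_threshold": self.freeze.velocity_threshold,
                    "min_dwell": self.freeze.min_dwell,
                    "rearm_fraction": self.freeze.rearm_fraction,
                },
                "jerk": {
                    "jerk_threshold": self.jerk.jerk_threshold,
                    "smoothing_fc": self.jerk.smoothing_fc,
                },
                "speed_smoothing_fc": self.speed_smoothing_fc,
            },
            "mapping": {
                "speed_hi": self.speed_hi,
                "speed_lo": self.speed_lo,
                "jerk_ceiling_factor": self.jerk_ceiling_factor,
                "scale_tonic": self.scale.tonic,
            },
            "synthesis": {
                "sample_rate": self.clip.sample_rate,
                "bit_depth": self.clip.bit_depth,
                "channels": self.clip.channels,
                "duration": self.clip.duration,
            },
            "combo": {"default": self.combo},
        }

    @classmethod
    def default(cls) -> "PipelineConfig":
        return cls.from_tree(load_default_tree())

    @classmethod
    def load(cls, path=None) -> "PipelineConfig":
        """Shipped defaults, deep-overridden by an optional user YAML."""
        tree = load_default_tree()
        if path is not None:
            with open(path) as fh:
                user = _strip_provenance(yaml.safe_load(fh) or {})
            tree = _deep_update(tree, user)
        return cls.from_tree(tree)

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_tree(), fh, sort_keys=False)

    def digest(self) -> str:
        """Stable hash of the active configuration."""
        canon = yaml.safe_dump(self.to_tree(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
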