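"""Architectural and training configuration objects.

``MACNeXtConfig`` holds the full hyperparameter set of the network: the stem
widths, the per-stage widths F and repeats R, the grouped-convolution
convention, and the class count. The default values are the reference
configuration: F = [96, 192, 384, 768], R = [1, 1, 3, 1], 224x224x3 inputs.

Grouped-convolution convention
------------------------------
Every grouped layer uses one uniform ``channels_per_group`` constant: a layer
with C_in input channels runs C_in / channels_per_group groups. The network's
description leaves the group count open; the only published constraint is the
total parameter budget of 4.4 million. Scanning the divisor-valued candidates
against the closed-form parameter count fixes the reference convention at
``channels_per_group = 2`` with a plain (ungrouped) 1x1 expansion and a
grouped 1x1 squeeze — the transition-table reading of the block — whose total
of 4,436,808 learnable scalars rounds to 4.4 million. The
``expansion_grouped`` / ``squeeze_grouped`` flags expose the alternative
pseudocode reading (grouped expansion, plain squeeze).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["MACNeXtConfig", "TrainConfig", "ConfigError", "load_config", "TINY_PRESET"]


class ConfigError(ValueError):
    """Raised when a configuration violates one of its invariants."""


@dataclass
class MACNeXtConfig:
    input_height: int = 224
    input_width: int = 224
    input_channels: int = 3
    stem_widths: tuple[int, int] = (48, 96)
    stage_widths: tuple[int, ...] = (96, 192, 384, 768)
    stage_repeats: tuple[int, ...] = (1, 1, 3, 1)
    channels_per_group: int = 2
    expansion_grouped: bool = False
    squeeze_grouped: bool = True
    num_classes: int = 24
    bn_epsilon: float = 1e-5
    bn_momentum: float = 0.1
    init_seed: int = 0

    def __post_init__(self):
        self.stem_widths = tuple(self.stem_widths)
        self.stage_widths = tuple(self.stage_widths)
        self.stage_repeats = tuple(self.stage_repeats)
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        F, R = self.stage_widths, self.stage_repeats
        if len(F) != len(R):
            raise ConfigError(f"stage_widths (len {len(F)}) and stage_repeats (len {len(R)}) must match")
        if len(F) == 0:
            raise ConfigError("at least one stage is required")
        if any(r < 1 for r in R):
            raise ConfigError(f"stage_repeats must all be >= 1, got {R}")
        if len(self.stem_widths) != 2:
            raise ConfigError("stem_widths must hold exactly two channel counts")
        if self.stem_widths[1] != F[0]:
            raise ConfigError(
                f"second stem width ({self.stem_widths[1]}) must equal the first stage width ({F[0]})"
            )
        for a, b in zip(F, F[1:]):
            if b != 2 * a:
                raise ConfigError(f"stage widths must double stage to stage; got {a} -> {b}")
        if self.num_classes < 2:
            raise ConfigError(f"num_classes must be >= 2, got {self.num_classes}")
        if self.channels_per_group < 1:
            raise ConfigError("channels_per_group must be a positive channel count")
        if not (self.bn_epsilon > 0):
            raise ConfigError("bn_epsilon must be positive")
        for cin, cout in self.grouped_layer_shapes():
            g, err = self._group_count(cin, cout)
            if err:
                raise ConfigError(err)
        # The spatial trace must not collapse to <1 pixel before the last stage.
        side = min(self.input_height, self.input_width)
        if side < 4:
            raise ConfigError(f"input sides must be >= 4, got {side}")
        side = -(-side // 4)  # stem: two stride-2 halvings
        for _ in range(len(F) - 1):
            if side < 2:
                raise ConfigError(
                    "input too small: the spatial side collapses to 1 pixel before the final stage"
                )
            side = -(-side // 2)

    def _group_count(self, cin: int, cout: int) -> tuple[int, str | None]:
        cpg = self.channels_per_group
        if cin % cpg:
            return 0, f"channels_per_group={cpg} does not divide layer width {cin}"
        g = cin // cpg
        if cout % g:
            return g, (
                f"grouped layer {cin}->{cout}: {g} groups (channels_per_group={cpg}) "
                f"do not divide the output width {cout}"
            )
        return g, None

    def groups_for(self, cin: int, cout: int) -> int:
        """Group count for a grouped layer with the given channel widths."""
        g, err = self._group_count(cin, cout)
        if err:
            raise ConfigError(err)
        return g

    def grouped_layer_shapes(self) -> list[tuple[int, int]]:
        """(C_in, C_out) of every grouped convolution in the network."""
        shapes = [(self.stem_widths[0], self.stem_widths[1])]
        n_stages = len(self.stage_widths)
        for s, f in enumerate(self.stage_widths):
            per_block = [(f, f), (f, f)]  # parallel 3x3 and 1x1
            if self.expansion_grouped:
                per_block.append((2 * f, 2 * f))
            if self.squeeze_grouped:
                per_block.append((2 * f, f))
            per_block += [(f, f), (f, f)]  # GELU / ReLU branches
            shapes += per_block * self.stage_repeats[s]
            if s < n_stages - 1:
                shapes.append((f, 2 * f))  # downsampling
        return shapes

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stem_widths"] = list(self.stem_widths)
        d["stage_widths"] = list(self.stage_widths)
        d["stage_repeats"] = list(self.stage_repeats)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MACNeXtConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown architecture config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class TrainConfig:
    """Split protocol and optimizer settings (momentum SGD, constant rate)."""

    train_fraction: float = 0.64
    val_fraction: float = 0.16
    test_fraction: float = 0.20
    momentum: float = 0.9
    epochs: int = 30
    batch_size: int = 128
    learning_rate: float = 0.01
    weight_decay: float = 1e-4
    balanced_batches: bool = False
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        total = self.train_fraction + self.val_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"split fractions must sum to 1, got {total}")
        if not (0 <= self.momentum < 1):
            raise ConfigError(f"momentum must lie in [0, 1), got {self.momentum}")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.weight_decay < 0:
            raise ConfigError("weight_decay must be nonnegative")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown training config keys: {sorted(unknown)}")
        return cls(**d)


#: Small configuration used for CPU-scale experiments and tests.
TINY_PRESET = dict(
    input_height=64,
    input_width=64,
    stem_widths=(8, 16),
    stage_widths=(16, 32),
    stage_repeats=(1, 1),
    num_classes=4,
)


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON run configuration into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
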