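"""Run configuration and reproducible seeding.

A :class:`RunConfig` gathers every knob of the pipeline in one serialisable
object (YAML/JSON); a saved config re-runs to identical results for the
deterministic stages.  A single top-level ``seed`` fans out to per-module
random generators through ``numpy.random.SeedSequence.spawn`` with a fixed,
documented stream order, so one knob controls all randomness.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np

__all__ = ["RunConfig", "derive_rngs", "SEED_STREAMS"]

#: fixed fan-out order of the per-module child seeds
SEED_STREAMS = ("synthetic", "network", "training", "video", "sampling")


def derive_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Split one seed into independent per-module generators.

    Children are spawned from ``SeedSequence(seed)`` in the order of
    :data:`SEED_STREAMS`; the mapping is stable across runs and platforms.
    """
    children = np.random.SeedSequence(seed).spawn(len(SEED_STREAMS))
    return {name: np.random.default_rng(child)
            for name, child in zip(SEED_STREAMS, children)}


def _check_keys(section: str, given: dict, allowed) -> None:
    unknown = sorted(set(given) - set(allowed))
    if unknown:
        raise ValueError(
            f"unknown config keys in '{section}': {', '.join(unknown)}")


@dataclass
class RunConfig:
    """All pipeline settings; nested sections are plain dicts validated
    against the dataclasses they configure."""

    seed: int = 0
    outdir: str = "runs"
    network: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    localisation: dict = field(default_factory=dict)
    retrieval: dict = field(default_factory=dict)
    synthetic: dict = field(default_factory=dict)

    _TRAINING_KEYS = (
        "n_iterations", "val_every", "val_fraction", "do_augment", "momentum",
        "per_foreground_class", "background_count",
        "warmup_lr", "warmup_iters", "initial_lr", "decay_factor",
        "plateau_patience",
        "min_crop", "max_crop", "out_size", "flip_lr", "rotation_range_deg",
    )
    _LOCALISATION_KEYS = ("sigma", "connectivity", "sign_modes")
    _RETRIEVAL_KEYS = ("motion_threshold", "n_train_background",
                       "n_test_background", "exclusion_halfwidth")
    _SYNTHETIC_KEYS = ("num_foreground_classes", "height", "width",
                       "speckle_strength", "shadow_probability",
                       "distractor_range", "fov_mask", "n_per_class",
                       "n_background")

    def __post_init__(self) -> None:
        from .network import NetworkConfig

        _check_keys("network", self.network,
                    [f.name for f in fields(NetworkConfig)])
        _check_keys("training", self.training, self._TRAINING_KEYS)
        _check_keys("localisation", self.localisation,
                    self._LOCALISATION_KEYS)
        _check_keys("retrieval", self.retrieval, self._RETRIEVAL_KEYS)
        _check_keys("synthetic", self.synthetic, self._SYNTHETIC_KEYS)

    # -- section builders ------------------------------------------------

    def network_config(self):
        from .network import NetworkConfig

        return NetworkConfig(**self.network)

    def synthetic_spec(self):
        from .synthetic import SyntheticSpec

        kwargs = {k: v for k, v in self.synthetic.items()
                  if k not in ("n_per_class", "n_background")}
        if "distractor_range" in kwargs:
            kwargs["distractor_range"] = tuple(kwargs["distractor_range"])
        return SyntheticSpec(**kwargs)

    def training_parts(self):
        from .training import (AugmentationSpec, BatchComposition,
                               LRSchedule)

        t = self.training
        comp = BatchComposition(**{k: t[k] for k in
                                   ("per_foreground_class",
                                    "background_count") if k in t})
        sched_keys = ("warmup_lr", "warmup_iters", "initial_lr",
                      "decay_factor", "plateau_patience")
        schedule = LRSchedule(**{k: t[k] for k in sched_keys if k in t})
        aug_keys = ("min_crop", "max_crop", "out_size", "flip_lr",
                    "rotation_range_deg")
        aug = None
        if any(k in t for k in aug_keys):
            kwargs = {k: t[k] for k in aug_keys if k in t}
            if "rotation_range_deg" in kwargs:
                kwargs["rotation_range_deg"] = tuple(
                    kwargs["rotation_range_deg"])
            aug = AugmentationSpec(**kwargs)
        run = {k: t[k] for k in ("n_iterations", "val_every", "val_fraction",
                                 "do_augment", "momentum") if k in t}
        return comp, schedule, aug, run

    # -- serialisation ---------------------------------------------------

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        _check_keys("run config", raw, [f.name for f in fields(cls)])
        return cls(**raw)
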