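"""Label taxonomy: class names, background flag, per-class saliency sign.

Bright structures (bone such as the femur or spine) produce predominantly
positive saliencies, dark fluid-filled structures (cardiac chambers and
vessels) negative ones.  The localiser exploits this as injected domain
knowledge: each class carries a sign mode — ``positive_only``,
``negative_only`` or ``both`` — used when turning its saliency map into a
confidence map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["LabelTaxonomy", "default_taxonomy"]

SIGN_MODES = ("positive_only", "negative_only", "both")


@dataclass
class LabelTaxonomy:
    """Ordered class list; the background class is one of the indices."""

    names: list[str]
    background_index: int
    sign_modes: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.background_index < len(self.names):
            raise ValueError("background_index out of range")
        for k in range(len(self.names)):
            self.sign_modes.setdefault(k, "both")
        for k, mode in self.sign_modes.items():
            if mode not in SIGN_MODES:
                raise ValueError(f"unknown sign mode {mode!r} for class {k}")

    @property
    def num_classes(self) -> int:
        return len(self.names)

    @property
    def foreground(self) -> list[int]:
        return [k for k in range(len(self.names)) if k != self.background_index]

    def mode(self, k: int) -> str:
        return self.sign_modes[k]


#: the 13 modelled standard views plus background
_CLINICAL_NAMES = [
    "Brain (Cb.)", "Brain (Tv.)", "Profile", "Lips", "Abdominal", "Kidneys",
    "Femur", "Spine (cor.)", "Spine (sag.)", "4CH", "3VV", "RVOT", "LVOT",
    "Background",
]

_POSITIVE = {"Femur", "Spine (cor.)", "Spine (sag.)", "Lips"}
_NEGATIVE = {"4CH", "3VV", "RVOT", "LVOT"}  # the cardiac views


def default_taxonomy() -> LabelTaxonomy:
    """The shipping clinical taxonomy with its per-class sign policy."""
    modes = {}
    for k, name in enumerate(_CLINICAL_NAMES):
        if name in _POSITIVE:
            modes[k] = "positive_only"
        elif name in _NEGATIVE:
            modes[k] = "negative_only"
        else:
            modes[k] = "both"
    return LabelTaxonomy(names=list(_CLINICAL_NAMES),
                         background_index=len(_CLINICAL_NAMES) - 1,
                         sign_modes=modes)
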