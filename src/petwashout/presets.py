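"""Generative tissue presets for synthetic washout studies.

Each preset stores the mean tissular and washout half-lives (seconds)
reported for carbon-11 carbonate point sources in rat tissue, together
with the across-animal standard deviations where available.  They are
used as ground-truth means when simulating studies and as the reference
values parameter-recovery experiments are judged against.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TissuePreset", "TISSUE_PRESETS", "get_preset"]


@dataclass(frozen=True)
class TissuePreset:
    name: str
    halflife_tiss_s: float
    halflife_wash_s: float
    sd_tiss_s: float | None = None
    sd_wash_s: float | None = None


#: Mean half-lives (s): tissular from dead-condition measurements, washout
#: from the alive/dead comparison.  Tumor metabolic sub-states share the
#: tumor tissular component and differ only in washout.
TISSUE_PRESETS: dict[str, TissuePreset] = {
    "brain": TissuePreset("brain", 2878.0, 330.0, sd_tiss_s=155.0, sd_wash_s=51.0),
    "muscle": TissuePreset("muscle", 2132.0, 361.0, sd_tiss_s=230.0, sd_wash_s=186.0),
    "tumor": TissuePreset("tumor", 2019.0, 621.0, sd_tiss_s=188.0, sd_wash_s=151.0),
    "tumor_necrotic": TissuePreset("tumor_necrotic", 2019.0, 613.0),
    "tumor_active": TissuePreset("tumor_active", 2019.0, 418.0),
}


def get_preset(name: str) -> TissuePreset:
    try:
        return TISSUE_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown tissue preset {name!r}; available: {sorted(TISSUE_PRESETS)}"
        ) from None
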