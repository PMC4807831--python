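"""Pipeline configuration: a strict, round-trippable YAML schema.

Unknown keys anywhere in the document are rejected, and the resolved
configuration is written next to the outputs of every run so a run can
be reproduced from its own artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .kinetics import C11_HALF_LIFE_S, IsotopeSpec
from .synthetic import AcquisitionProtocol, InjectionSpec, ScannerModel

__all__ = ["FitOptions", "PipelineConfig"]


@dataclass(frozen=True)
class FitOptions:
    mode: str = "subtraction"  # or "direct"
    t_min_s: float = 0.0
    t_max_s: float | None = None
    weighting: str = "none"  # or "poisson"

    def __post_init__(self) -> None:
        if self.mode not in ("subtraction", "direct"):
            raise ValueError("fit mode must be 'subtraction' or 'direct'")
        if self.weighting not in ("none", "poisson"):
            raise ValueError("weighting must be 'none' or 'poisson'")

    @property
    def window(self) -> tuple[float, float | None]:
        return (self.t_min_s, self.t_max_s)


_SCHEMA: dict[str, set[str] | None] = {
    "seed": None,
    "output_dir": None,
    "noise": None,
    "tissues": None,
    "design": {"n_animals", "inter_animal_cv"},
    "scanner": {"psf_fwhm_mm", "sensitivity", "voxel_size_mm", "grid_shape"},
    "injection": {"source_sigma_mm", "activity_range_bq", "position_mm"},
    "protocol": None,
    "isotope": {"name", "half_life_s"},
    "fit": {"mode", "t_min_s", "t_max_s", "weighting"},
}


def _check_keys(d: dict, allowed, context: str) -> None:
    unknown = set(d) - set(allowed)
    if unknown:
        raise ValueError(f"unknown config key(s) in {context}: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    """Everything an end-to-end run needs, resolvable to/from YAML."""

    seed: int = 1
    output_dir: str = "petwashout_results"
    noise: bool = True
    tissues: tuple[str, ...] = ("brain", "muscle", "tumor")
    n_animals: int = 4
    inter_animal_cv: float = 0.1
    scanner: ScannerModel = field(default_factory=ScannerModel)
    injection: InjectionSpec = field(default_factory=InjectionSpec)
    protocol: AcquisitionProtocol = field(
        default_factory=AcquisitionProtocol.default
    )
    isotope: IsotopeSpec = field(default_factory=IsotopeSpec.c11)
    fit: FitOptions = field(default_factory=FitOptions)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        _check_keys(d, _SCHEMA, "top level")
        kw: dict = {}
        for key in ("seed", "output_dir", "noise"):
            if key in d:
                kw[key] = d[key]
        if "tissues" in d:
            kw["tissues"] = tuple(d["tissues"])
        if "design" in d:
            sub = d["design"]
            _check_keys(sub, _SCHEMA["design"], "design")
            kw["n_animals"] = int(sub.get("n_animals", 4))
            kw["inter_animal_cv"] = float(sub.get("inter_animal_cv", 0.1))
        if "scanner" in d:
            sub = d["scanner"]
            _check_keys(sub, _SCHEMA["scanner"], "scanner")
            defaults = ScannerModel()
            vox = sub.get("voxel_size_mm", defaults.voxel_size)
            if not isinstance(vox, (list, tuple)):
                vox = (vox, vox, vox)
            kw["scanner"] = ScannerModel(
                psf_fwhm=float(sub.get("psf_fwhm_mm", defaults.psf_fwhm)),
                sensitivity=float(sub.get("sensitivity", defaults.sensitivity)),
                voxel_size=tuple(float(v) for v in vox),
                grid_shape=tuple(int(n) for n in sub.get("grid_shape", defaults.grid_shape)),
            )
        if "injection" in d:
            sub = d["injection"]
            _check_keys(sub, _SCHEMA["injection"], "injection")
            defaults = InjectionSpec()
            pos = sub.get("position_mm")
            kw["injection"] = InjectionSpec(
                position=tuple(float(v) for v in pos) if pos is not None else None,
                activity_range=tuple(
                    float(v)
                    for v in sub.get("activity_range_bq", defaults.activity_range)
                ),
                source_sigma=float(sub.get("source_sigma_mm", defaults.source_sigma)),
            )
        if "protocol" in d:
            p = d["protocol"]
            if p == "default":
                kw["protocol"] = AcquisitionProtocol.default()
            else:
                kw["protocol"] = AcquisitionProtocol(tuple(float(x) for x in p))
        if "isotope" in d:
            sub = d["isotope"]
            _check_keys(sub, _SCHEMA["isotope"], "isotope")
            kw["isotope"] = IsotopeSpec(
                name=str(sub.get("name", "C-11")),
                physical_half_life=float(sub.get("half_life_s", C11_HALF_LIFE_S)),
            )
        if "fit" in d:
            sub = d["fit"]
            _check_keys(sub, _SCHEMA["fit"], "fit")
            kw["fit"] = FitOptions(
                mode=sub.get("mode", "subtraction"),
                t_min_s=float(sub.get("t_min_s", 0.0)),
                t_max_s=None
                if sub.get("t_max_s") is None
                else float(sub["t_max_s"]),
                weighting=sub.get("weighting", "none"),
            )
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "noise": self.noise,
            "tissues": list(self.tissues),
            "design": {
                "n_animals": self.n_animals,
                "inter_animal_cv": self.inter_animal_cv,
            },
            "scanner": {
                "psf_fwhm_mm": self.scanner.psf_fwhm,
                "sensitivity": self.scanner.sensitivity,
                "voxel_size_mm": list(self.scanner.voxel_size),
                "grid_shape": list(self.scanner.grid_shape),
            },
            "injection": {
                "source_sigma_mm": self.injection.source_sigma,
                "activity_range_bq": list(self.injection.activity_range),
                "position_mm": None
                if self.injection.position is None
                else list(self.injection.position),
            },
            "protocol": list(self.protocol.frame_durations),
            "isotope": {
                "name": self.isotope.name,
                "half_life_s": self.isotope.physical_half_life,
            },
            "fit": {
                "mode": self.fit.mode,
                "t_min_s": self.fit.t_min_s,
                "t_max_s": self.fit.t_max_s,
                "weighting": self.fit.weighting,
            },
        }

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path
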