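"""Configuration of the synthetic embryo generator and pipeline runs.

The generator emulates the anterior ~third of a syncytial blastoderm embryo
(egg length 500 µm by convention) imaged as a nuclear monolayer: nuclei on a
jittered hexagonal lattice clipped to an elliptical embryo outline, an mRNA
expression domain that declines towards the posterior, and a position-dependent
probability that a cytoplasmic mRNA is engaged by ribosomes.  Axis-profile
shapes are small serializable objects rather than bare callables so a run
configuration round-trips losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import yaml


# ---------------------------------------------------------------------------
# AP-axis profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstantProfile:
    """A profile that is flat along the AP axis."""

    value: float

    def __call__(self, ap_um):
        ap_um = np.asarray(ap_um, dtype=float)
        return np.full_like(ap_um, self.value)


@dataclass(frozen=True)
class PlateauProfile:
    """Anterior plateau with a logistic decline at a posterior boundary.

    Emulates an expression domain driven from an anterior enhancer: roughly
    uniform levels that fall to zero around ``boundary_um`` over a length
    scale ``width_um``.
    """

    amplitude: float
    boundary_um: float = 250.0
    width_um: float = 25.0

    def __call__(self, ap_um):
        ap_um = np.asarray(ap_um, dtype=float)
        return self.amplitude / (1.0 + np.exp((ap_um - self.boundary_um) / self.width_um))


@dataclass(frozen=True)
class LogisticProfile:
    """Sigmoidal rise from ``low`` to ``high`` across ``midpoint_um``.

    Used for translated-fraction profiles that are repressed anteriorly and
    active in a posterior band of the expression domain.
    """

    low: float
    high: float
    midpoint_um: float
    width_um: float

    def __call__(self, ap_um):
        ap_um = np.asarray(ap_um, dtype=float)
        return self.low + (self.high - self.low) / (
            1.0 + np.exp(-(ap_um - self.midpoint_um) / self.width_um)
        )


Profile = Union[ConstantProfile, PlateauProfile, LogisticProfile]

_PROFILE_KINDS = {
    "constant": ConstantProfile,
    "plateau": PlateauProfile,
    "logistic": LogisticProfile,
}


def profile_to_dict(profile: Profile) -> dict:
    kind = next(k for k, cls in _PROFILE_KINDS.items() if isinstance(profile, cls))
    d = dataclasses.asdict(profile)
    d["kind"] = kind
    return d


def profile_from_dict(d: dict) -> Profile:
    d = dict(d)
    cls = _PROFILE_KINDS[d.pop("kind")]
    return cls(**d)


# ---------------------------------------------------------------------------
# Embryo configuration
# ---------------------------------------------------------------------------

#: per-nuclear-cycle defaults: (n_nuclei in frame, nucleus radius µm)
_CYCLE_DEFAULTS = {
    "nc12": (140, 3.5),
    "nc13": (280, 3.0),
    "nc14": (550, 2.5),
}


@dataclass
class EmbryoConfig:
    """Everything the synthetic-embryo generator needs, with study-like defaults.

    Lengths are in µm and nucleotide counts in nt.  ``rng_seed`` fixes all
    randomness: identical config + seed gives identical tables.
    """

    rng_seed: int = 0
    frame_size: tuple[float, float, float] = (220.0, 220.0, 12.0)
    embryo_length_el: float = 500.0
    embryo_width: float = 160.0
    nuclear_cycle: str = "nc12"
    n_nuclei: int | None = None
    nucleus_radius: float | None = None
    internuclear_jitter: float = 0.8
    z_jitter: float = 0.3
    orientation_deg: float = 0.0
    midline_offset_um: float = 0.0
    anterior_tip_margin: float = 25.0

    # mRNA field
    expression_profile: Profile | None = None
    translated_profile: Profile | None = None
    nuclear_fraction: float = 0.12
    mrna_intensity: float = 150.0
    mrna_cv: float = 0.20

    # nascent-protein field
    ribosome_load_mean: float = 20.0
    single_protein_intensity: float = 100.0
    single_protein_cv: float = 0.25
    intensity_cv: float = 0.10
    coloc_sigma: float = 0.10
    free_protein_density: float = 5.0e-4
    aggregate_density: float = 5.0e-5
    aggregate_brightness_factor: float = 20.0

    # 5'/3' probe pairs (probe-set centres 3092 nt apart on the transcript)
    translating_compaction_median: float = 0.25
    nontranslating_compaction_median: float = 0.20
    compaction_sigma: float = 0.30
    extra_3p_density: float = 1.0e-4

    # coding-segment lengths for the partial-epitope correction factor
    length_suntag_nt: float = 1350.0
    length_hb_nt: float = 2250.0

    # time-lapse
    n_frames: int = 40
    frame_interval_s: float = 2.0
    n_tethered_sites: int = 60
    site_jitter: float = 0.15
    diffusion_coeff: float = 5.0
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.nuclear_cycle not in _CYCLE_DEFAULTS:
            raise ValueError(f"unknown nuclear cycle {self.nuclear_cycle!r}")
        n_default, r_default = _CYCLE_DEFAULTS[self.nuclear_cycle]
        if self.n_nuclei is None:
            self.n_nuclei = n_default
        if self.nucleus_radius is None:
            self.nucleus_radius = r_default
        if self.expression_profile is None:
            amp = {"nc12": 15.0, "nc13": 25.0, "nc14": 40.0}[self.nuclear_cycle]
            self.expression_profile = PlateauProfile(amplitude=amp)
        if self.translated_profile is None:
            if self.nuclear_cycle == "nc12":
                self.translated_profile = ConstantProfile(0.55)
            elif self.nuclear_cycle == "nc13":
                self.translated_profile = ConstantProfile(0.50)
            else:  # nc14: anterior repression, posterior band
                self.translated_profile = LogisticProfile(
                    low=0.05, high=0.60, midpoint_um=150.0, width_um=20.0
                )
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        positive = {
            "embryo_length_el": self.embryo_length_el,
            "embryo_width": self.embryo_width,
            "nucleus_radius": self.nucleus_radius,
            "mrna_intensity": self.mrna_intensity,
            "single_protein_intensity": self.single_protein_intensity,
            "length_suntag_nt": self.length_suntag_nt,
            "length_hb_nt": self.length_hb_nt,
            "frame_interval_s": self.frame_interval_s,
            "ribosome_load_mean": self.ribosome_load_mean,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        nonneg = {
            "internuclear_jitter": self.internuclear_jitter,
            "z_jitter": self.z_jitter,
            "intensity_cv": self.intensity_cv,
            "mrna_cv": self.mrna_cv,
            "single_protein_cv": self.single_protein_cv,
            "coloc_sigma": self.coloc_sigma,
            "free_protein_density": self.free_protein_density,
            "aggregate_density": self.aggregate_density,
            "extra_3p_density": self.extra_3p_density,
            "translating_compaction_median": self.translating_compaction_median,
            "nontranslating_compaction_median": self.nontranslating_compaction_median,
            "site_jitter": self.site_jitter,
            "diffusion_coeff": self.diffusion_coeff,
            "compaction_sigma": self.compaction_sigma,
        }
        for name, value in nonneg.items():
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        for name, value in {
            "nuclear_fraction": self.nuclear_fraction,
            "dropout_rate": self.dropout_rate,
        }.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if any(s <= 0 for s in self.frame_size):
            raise ValueError("frame_size extents must be strictly positive")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be non-negative")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["frame_size"] = list(self.frame_size)
        d["expression_profile"] = profile_to_dict(self.expression_profile)
        d["translated_profile"] = profile_to_dict(self.translated_profile)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EmbryoConfig":
        d = dict(d)
        d["frame_size"] = tuple(d["frame_size"])
        d["expression_profile"] = profile_from_dict(d["expression_profile"])
        d["translated_profile"] = profile_from_dict(d["translated_profile"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EmbryoConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)

    @property
    def transcript_length_nt(self) -> float:
        return self.length_suntag_nt + self.length_hb_nt
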