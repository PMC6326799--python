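"""Pipeline configuration: every tunable threshold in one structured object.

The defaults are the constants the analysis is defined by: the nuclear-
periphery band 10-66.6 %DAPI, the 33.3% single-signal cytoplasm likelihood
cut, the 0.5 um molecule pairing radius, S0 = 0.5 with 250 randomizations at
FDR 0.05, imputation width 0.3 / downshift 1.8, Q-rich windows of 60 with at
least 7 scored residues, and the reciprocal-best-hit e-value cutoff 1e-5.
Configurations round-trip losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class OpticsConfig:
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1)
    psf_sigma: tuple[float, float, float] = (0.30, 0.13, 0.13)
    background_level: float = 10.0
    photon_scale: float = 5000.0
    noise_model: str = "poisson"
    dapi_falloff: float = 0.15


@dataclass
class GeometryConfig:
    cell_radii: tuple[float, float, float] = (1.8, 2.6, 2.6)
    nucleus_radii: tuple[float, float, float] = (1.0, 1.1, 1.1)
    nucleolus_radius: float = 0.35
    nucleolus_offset: tuple[float, float, float] = (0.0, 0.3, 0.0)


@dataclass
class PipelineConfig:
    periphery_band: tuple[float, float] = (10.0, 66.6)
    cytoplasm_likelihood_cut: float = 33.3
    pairing_radius_um: float = 0.5
    detection_k_mad: float = 7.0
    sampling_step_um: float | None = None  # None = half the smallest voxel
    s0: float = 0.5
    n_randomizations: int = 250
    fdr: float = 0.05
    imputation_width: float = 0.3
    imputation_downshift: float = 1.8
    qrich_window: int = 60
    qrich_min_count: int = 7
    qrich_residue: str = "Q"
    rbh_evalue_cutoff: float = 1e-5
    probe_map: dict = field(
        default_factory=lambda: {
            "red": ["geneA", "five_prime"],
            "ir": ["geneA", "internal"],
            "green": ["geneA", "three_prime"],
        }
    )
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    master_seed: int = 0

    def validate(self) -> None:
        lo, hi = self.periphery_band
        if not (0 <= lo < hi <= 100):
            raise ValueError("periphery_band must satisfy 0 <= low < high <= 100")
        if not 0 <= self.cytoplasm_likelihood_cut <= 100:
            raise ValueError("cytoplasm_likelihood_cut must lie in [0, 100]")
        if self.pairing_radius_um <= 0:
            raise ValueError("pairing_radius_um must be positive")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")
        if self.s0 < 0:
            raise ValueError("s0 must be >= 0")
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")
        if self.imputation_width < 0 or self.imputation_downshift < 0:
            raise ValueError("imputation parameters must be >= 0")
        if self.qrich_window <= 0 or self.qrich_min_count <= 0:
            raise ValueError("qrich window and min_count must be positive")
        if self.qrich_min_count > self.qrich_window:
            raise ValueError("qrich_min_count cannot exceed the window length")
        if self.rbh_evalue_cutoff <= 0:
            raise ValueError("rbh_evalue_cutoff must be positive")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "optics" in d and isinstance(d["optics"], dict):
            d["optics"] = OpticsConfig(**_tupled(d["optics"]))
        if "geometry" in d and isinstance(d["geometry"], dict):
            d["geometry"] = GeometryConfig(**_tupled(d["geometry"]))
        for key in ("periphery_band",):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _tupled(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
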