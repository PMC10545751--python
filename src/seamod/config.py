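"""Run configuration: one validated, serializable object for all stages."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .synthdata import NichedModuleSpec, VelocityFieldSpec, default_module_specs


@dataclass
class RunConfig:
    """Parameters for a full pipeline run on synthetic inputs.

    Defaults define the toy configuration: 2 oceans x 10 stations x
    3 depths x 3 size fractions, 6 planted modules of 10 ASVs, and 200
    drifters for one simulated year, sized to finish on one CPU in a few
    minutes.
    """

    seed: int = 0

    # synthetic design
    n_stations: int = 10
    depths: tuple = (20, 60, 200)
    oceans: tuple = ("atlantic", "pacific")
    fractions: tuple = ("0.2-3", "3-8", ">8")
    lat_range: tuple = (-60.0, 60.0)
    modules: list = field(default_factory=default_module_specs)
    mean_seq_depth: float = 21_791.0
    asv_noise_sd: float = 0.5

    # preprocess
    rarefaction_depth: int = 8000

    # sparcc / network
    n_boot: int = 99
    r_min: float = 0.5
    alpha: float = 0.05
    n_rewire: int = 49
    p_rewire: float = 0.5

    # assembly
    n_null_assembly: int = 199
    max_pairs_per_group: int | None = 50

    # transport
    n_drifters: int = 400
    trajectory_days: int = 540
    grid_dx: float = 3.0
    grid_dy: float = 2.0
    grid_lat_bounds: tuple = (-66.0, 66.0)
    grid_lon_bounds: tuple = (-42.0, -6.0)
    transport_dt_days: float = 30.0
    n_years: int = 5
    convergence_latitudes: tuple = (-30.0, 30.0)
    meridional_amplitude: float = 10.0
    zonal_amplitude: float = 3.0
    diffusion_sigma: float = 25.0

    def validate(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not (0.0 < self.r_min <= 1.0):
            raise ValueError(f"r_min must be in (0, 1], got {self.r_min}")
        if not (0.0 <= self.p_rewire <= 1.0):
            raise ValueError("p_rewire must be in [0, 1]")
        if self.n_stations < 2:
            raise ValueError("n_stations must be >= 2")
        if self.rarefaction_depth <= 0:
            raise ValueError("rarefaction_depth must be positive")
        if min(self.n_boot, self.n_rewire, self.n_null_assembly) < 1:
            raise ValueError("all resampling counts must be >= 1")
        if self.n_drifters < 1 or self.trajectory_days < 1 or self.n_years < 1:
            raise ValueError("transport sizes must be >= 1")
        for spec in self.module_specs():
            _ = spec  # construction itself validates

    def module_specs(self) -> list[NichedModuleSpec]:
        out = []
        for m in self.modules:
            out.append(m if isinstance(m, NichedModuleSpec) else NichedModuleSpec(
                module_id=int(m["module_id"]),
                n_asvs=int(m["n_asvs"]),
                niche_center=tuple(m["niche_center"]),
                niche_breadth=tuple(m["niche_breadth"]),
                mean_log_abundance=float(m.get("mean_log_abundance", 0.0)),
                phylo_cluster=bool(m.get("phylo_cluster", True)),
            ))
        return out

    def velocity_field(self) -> VelocityFieldSpec:
        return VelocityFieldSpec(
            convergence_latitudes=tuple(self.convergence_latitudes),
            meridional_amplitude=self.meridional_amplitude,
            zonal_amplitude=self.zonal_amplitude,
            diffusion_sigma=self.diffusion_sigma,
        )

    def to_dict(self) -> dict:
        """Canonical plain-types dict (tuples as lists) for serialization
        and equality checks."""
        d = asdict(self)
        d["modules"] = [
            m if isinstance(m, dict) else asdict(m) for m in d["modules"]
        ]
        return _plain(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("depths", "oceans", "fractions", "lat_range", "grid_lat_bounds",
                    "grid_lon_bounds", "convergence_latitudes"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        cfg = cls(**d)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _plain(obj):
    """Recursively convert tuples to lists so YAML round-trips cleanly."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
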