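"""Run configuration: YAML schema, validation, defaults.

A run config collects everything one analysis needs: input paths, frame
selectors, thermodynamic constants, the classification thresholds (bound 5 Å,
effective-RMSD 15 Å, well −4.1, deep well −8.2 kcal/mol, high-B.P.
360 num./grid), the pocket-mask specification, spline smoothing, bootstrap
size and the master seed.  Defaults equal the published analysis values.

Validation is schema-style: every offending key is collected and reported in
one :class:`ConfigError` rather than failing on the first problem.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .errors import ConfigError

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "bindscape_out"
    reference_pdb: str | None = None
    snapshots_csv: str | None = None
    atoms_csv: str | None = None
    native_pose_csv: str | None = None
    origin_selector: str = "element=ZN"
    x_anchor_selector: str = "res=1,name=CA"
    y_anchor_selector: str = "res=2,name=CA"
    temperature_K: float = 298.15
    bound_cutoff_A: float = 5.0
    effective_rmsd_A: float = 15.0
    well_cut: float = -4.1
    dw_cut: float = -8.2
    high_bp_cut: int = 360
    mask_type: str = "auto_min"  # auto_min | cap | cells
    mask_center_lat: float | None = None
    mask_center_lon: float | None = None
    mask_radius_deg: float = 15.0
    mask_cells: list = field(default_factory=list)
    spline_lambda: float = 0.0
    bootstrap_B: int = 200
    dwell_min: int = 10
    tail_fraction: float = 0.2
    # synthetic-run block
    sim_steps: int = 20000
    sim_copies: int = 4
    sim_rt: float = 0.5925
    sim_sigma_e: float = 0.3
    sim_p_unbind: float = 0.0
    sim_emit_atoms: bool = False
    sim_wells: list = field(
        default_factory=lambda: [
            {"lat": 0.0, "lon": -40.0, "depth": -8.5, "width_deg": 8.0},
            {"lat": 0.0, "lon": 40.0, "depth": -5.0, "width_deg": 8.0},
        ]
    )

    def validate(self) -> "RunConfig":
        bad: list[str] = []
        positive = {
            "temperature_K", "bound_cutoff_A", "effective_rmsd_A",
            "mask_radius_deg", "bootstrap_B", "dwell_min", "sim_steps",
            "sim_copies", "sim_rt", "sim_sigma_e",
        }
        for key in positive:
            v = getattr(self, key)
            if not isinstance(v, (int, float)) or v <= 0:
                bad.append(key)
        for key in ("well_cut", "dw_cut"):
            v = getattr(self, key)
            if not isinstance(v, (int, float)) or v >= 0:
                bad.append(key)
        if not isinstance(self.seed, int):
            bad.append("seed")
        if self.spline_lambda < 0:
            bad.append("spline_lambda")
        if not 0 < self.tail_fraction <= 1:
            bad.append("tail_fraction")
        if self.mask_type not in ("auto_min", "cap", "cells"):
            bad.append("mask_type")
        elif self.mask_type == "cap" and (
            self.mask_center_lat is None or self.mask_center_lon is None
        ):
            bad.extend(["mask_center_lat", "mask_center_lon"])
        elif self.mask_type == "cells" and not self.mask_cells:
            bad.append("mask_cells")
        for w in self.sim_wells:
            if not isinstance(w, dict) or w.get("depth", 0) >= 0 or \
                    w.get("width_deg", 0) <= 0:
                bad.append("sim_wells")
                break
        if bad:
            raise ConfigError(sorted(set(bad)))
        return self

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(unknown, f"unknown config keys: {', '.join(unknown)}")
        return cls(**data).validate()


def load_config(path, overrides: dict | None = None) -> RunConfig:
    """Read + validate a YAML config; ``overrides`` (e.g. CLI flags) win."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError([], "config root must be a mapping")
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig.from_dict(data)
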