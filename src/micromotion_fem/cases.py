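"""Simulation case configurations.

The eight shipped cases sweep micromotion displacement (1, 10, 20 um) on the
stiff silicon Michigan probe and compare probe materials (silicon,
polyimide, PVAc-NC at two thicknesses, and a modulus-matched hypothetical
probe) at fixed 1 um tangential displacement. A ninth config,
``case8_thick63``, runs the 63 um-thick compliant probe at 20 um — the
variant used for the strain-decay profile comparison, where the shipped
case table and the profile text disagree on the compliant thickness.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import DomainSpec, MeshParams, build_domain_spec
from .materials import BRAIN_E_DEFAULT

__all__ = ["CaseConfig", "case_catalog", "load_case_yaml", "dump_case_yaml"]


@dataclass(frozen=True)
class CaseConfig:
    """One simulation case: probe material/geometry, load, mesh and solver.

    ``displacement`` is the tangential (x) displacement in um applied on the
    probe top face; ``brain_E`` overrides the tissue modulus (MPa);
    ``nu_eff`` chooses the effective Poisson ratio of the equivalent-strain
    formula (``"material"`` uses each element's own ratio).
    """

    case_id: str
    probe_material: str
    probe_length: float = 1125.0
    probe_width: float = 125.0
    probe_thickness: float = 25.0
    displacement: float = 1.0
    mesh: MeshParams = field(default_factory=MeshParams)
    solver: str = "auto"
    solver_tol: float = 1e-8
    brain_E: float = BRAIN_E_DEFAULT
    nu_eff: str | float = "material"
    clamp_top: bool = True

    def __post_init__(self) -> None:
        if self.displacement <= 0:
            raise ValueError("displacement must be positive")

    def domain_spec(self) -> DomainSpec:
        return build_domain_spec(self.probe_length, self.probe_width,
                                 self.probe_thickness)

    def replace(self, **kw) -> "CaseConfig":
        return dataclasses.replace(self, **kw)


def case_catalog(mesh: MeshParams | None = None) -> dict[str, CaseConfig]:
    """The shipped case table plus the 63 um profile variant."""
    mesh = mesh or MeshParams()

    def c(cid, mat, thick, disp):
        return CaseConfig(case_id=cid, probe_material=mat,
                          probe_thickness=thick, displacement=disp, mesh=mesh)

    return {
        "case1": c("case1", "silicon", 25.0, 1.0),
        "case2": c("case2", "silicon", 25.0, 10.0),
        "case3": c("case3", "silicon", 25.0, 20.0),
        "case4": c("case4", "polyimide", 25.0, 1.0),
        "case5": c("case5", "hypothetical", 25.0, 1.0),
        "case6": c("case6", "pvac_nc", 63.0, 1.0),
        "case7": c("case7", "pvac_nc", 25.0, 1.0),
        "case8": c("case8", "pvac_nc", 25.0, 20.0),
        "case8_thick63": c("case8_thick63", "pvac_nc", 63.0, 20.0),
    }


def _to_dict(config: CaseConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def dump_case_yaml(config: CaseConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(config), sort_keys=True))


def load_case_yaml(path: str | Path) -> CaseConfig:
    d = yaml.safe_load(Path(path).read_text())
    mesh = d.pop("mesh", None)
    cfg = CaseConfig(**d)
    if mesh is not None:
        cfg = cfg.replace(mesh=MeshParams(**mesh))
    return cfg
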