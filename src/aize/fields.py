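"""Synthetic true-sensitivity visual fields on the 24-2 grid.

Real input fields for strategy evaluation come from clinical perimetry and
cannot be redistributed; this module generates stand-ins.  A normative
"hill of vision" (peak at fixation, linear decline with eccentricity)
defines normal sensitivity; normal fields are the hill plus small
measurement-scale noise shifted to a target mean deviation (MD), and
glaucomatous fields subtract one or more spatially contiguous depression
clusters (scotomas), optionally confined to a hemifield to mimic
nerve-fiber-bundle defects, scaled until the realized MD matches a target.

MD here is the unweighted mean of (sensitivity - normative) over
non-blind-spot-adjacent locations, computed against this module's own
normative model (clinical instruments use age-corrected weighted MD; no
such database is bundled, and field metadata records this definition).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import TestGrid, build_24_2
from .pmf import SUPPORT_MIN, SUPPORT_MAX

#: Floor for generated true sensitivities, dB.  Clinical perimeters report
#: thresholds no lower than 0 dB, so emulated input fields never go below
#: it (the PMF support still extends to -2 dB to keep posterior means from
#: crowding the floor).
SENSITIVITY_FLOOR = 0.0

__all__ = [
    "NormativeModel",
    "ScotomaSpec",
    "SensitivityField",
    "normative_sensitivity",
    "normative_field",
    "field_md",
    "generate_normal_field",
    "generate_glaucoma_field",
    "make_study_cohort",
    "NORMAL_MD_TARGETS",
    "GLAUCOMA_MD_TARGETS",
]

#: Cohort MD targets (dB).  Endpoints and medians match the study cohorts
#: the simulation emulates: normals median -0.77, range [-1.78, 1.50];
#: glaucoma median -10.55, range [-20.82, -0.40].
NORMAL_MD_TARGETS = (-1.78, -1.50, -1.20, -1.00, -0.85, -0.69, -0.40, 0.20, 0.90, 1.50)
GLAUCOMA_MD_TARGETS = (-20.82, -18.00, -15.00, -12.50, -11.00, -10.10, -8.00, -5.00, -2.50, -0.40)


@dataclass(frozen=True)
class NormativeModel:
    """Linear hill-of-vision model: peak at fixation, declining with r."""

    foveal_peak: float = 34.0          # dB at fixation
    eccentricity_slope: float = -0.25  # dB per degree of eccentricity

    def __post_init__(self):
        if not 25.0 < self.foveal_peak < 40.0:
            raise ValueError("foveal_peak outside the plausible (25, 40) dB band")
        if self.eccentricity_slope >= 0:
            raise ValueError("eccentricity_slope must be negative")


@dataclass(frozen=True)
class ScotomaSpec:
    """Shape parameters of the glaucomatous depression clusters."""

    min_clusters: int = 1
    max_clusters: int = 3
    sigma_min: float = 4.0             # deg, spatial extent of a cluster
    sigma_max: float = 8.0
    hemifield_prob: float = 0.8        # chance all clusters share a hemifield
    hemifield_md_limit: float = -12.0  # deeper fields need both hemifields
    noise_sd: float = 1.0              # dB, local irregularity noise
    md_tolerance: float = 0.3          # dB, MD targeting tolerance


@dataclass
class SensitivityField:
    """True sensitivities (dB per grid location) with provenance metadata."""

    grid: TestGrid
    sensitivity: np.ndarray
    label: str                       # "normal" or "glaucoma"
    md: float                        # realized mean deviation, dB
    field_id: str = ""
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        if self.sensitivity.shape != (len(self.grid),):
            raise ValueError("sensitivity must have one value per grid location")
        if np.any(self.sensitivity < SUPPORT_MIN) or np.any(self.sensitivity > SUPPORT_MAX):
            raise ValueError("sensitivities must lie within the threshold support")

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write x_deg, y_deg, sensitivity_db; metadata to a JSON sidecar."""
        path = Path(path)
        pd.DataFrame(
            {
                "x_deg": [loc.x for loc in self.grid],
                "y_deg": [loc.y for loc in self.grid],
                "sensitivity_db": self.sensitivity,
            }
        ).to_csv(path, index=False)
        if sidecar:
            meta = {"label": self.label, "md": self.md, "field_id": self.field_id}
            meta.update(self.metadata)
            path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path, grid: TestGrid | None = None) -> "SensitivityField":
        path = Path(path)
        grid = grid or build_24_2()
        df = pd.read_csv(path)
        sens = np.empty(len(grid))
        by_xy = {(row.x_deg, row.y_deg): row.sensitivity_db for row in df.itertuples()}
        for i, loc in enumerate(grid):
            key = (loc.x, loc.y)
            if key not in by_xy:
                raise ValueError(f"field file {path} missing grid location {key}")
            sens[i] = by_xy[key]
        meta = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        label = meta.pop("label", "unknown")
        field_id = meta.pop("field_id", path.stem)
        md = meta.pop("md", None)
        fld = cls(grid, sens, label, 0.0, field_id=field_id, metadata=meta)
        fld.md = md if md is not None else field_md(fld, NormativeModel())
        return fld


def normative_sensitivity(location, model: NormativeModel = NormativeModel()) -> float:
    """Normal sensitivity at a location: peak + slope * eccentricity, dB."""
    value = model.foveal_peak + model.eccentricity_slope * location.r
    return float(np.clip(value, SUPPORT_MIN, SUPPORT_MAX))


def normative_field(grid: TestGrid, model: NormativeModel = NormativeModel()) -> np.ndarray:
    return np.array([normative_sensitivity(loc, model) for loc in grid])


def _included(grid: TestGrid) -> np.ndarray:
    return np.array([not loc.blind_spot_adjacent for loc in grid])


def field_md(field: SensitivityField, model: NormativeModel = NormativeModel()) -> float:
    """Mean deviation vs the normative model over non-blind-spot points."""
    ref = normative_field(field.grid, model)
    inc = _included(field.grid)
    return float(np.mean(field.sensitivity[inc] - ref[inc]))


def generate_normal_field(
    model: NormativeModel,
    noise_sd: float,
    target_md: float,
    rng: np.random.Generator,
    grid: TestGrid | None = None,
    field_id: str = "",
) -> SensitivityField:
    """Normal field: normative hill + demeaned Gaussian noise + MD offset.

    The noise is demeaned over the MD-included locations so the uniform
    offset equals the target MD exactly; clamping to the support can in
    principle perturb the realized MD, and more than 0.1 dB of such
    perturbation is rejected.
    """
    grid = grid or build_24_2()
    ref = normative_field(grid, model)
    inc = _included(grid)
    noise = rng.normal(0.0, noise_sd, size=len(grid))
    noise -= noise[inc].mean()
    sens = np.clip(ref + noise + target_md, SENSITIVITY_FLOOR, SUPPORT_MAX)
    realized = float(np.mean(sens[inc] - ref[inc]))
    if abs(realized - target_md) > 0.1:
        raise ValueError(
            f"normal-field MD target {target_md} dB unreachable after clamping "
            f"(realized {realized:.2f} dB)"
        )
    fld = SensitivityField(
        grid, sens, "normal", realized, field_id=field_id,
        metadata={"target_md": target_md, "noise_sd": noise_sd,
                  "md_definition": "unweighted mean vs package normative model"},
    )
    return fld


def _cluster_depression(grid: TestGrid, spec: ScotomaSpec, target_md: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-scale depression profile: sum of Gaussian bumps at seed points."""
    severity = abs(target_md)
    n_clusters = int(np.clip(1 + severity // 7, spec.min_clusters, spec.max_clusters))
    xy = np.array([[loc.x, loc.y] for loc in grid])
    # deep fields spread damage over both hemifields; milder ones usually
    # respect the horizontal midline, as nerve-fiber-bundle defects do
    confine = (target_md > spec.hemifield_md_limit) and (rng.random() < spec.hemifield_prob)
    hemisign = 1.0 if rng.random() < 0.5 else -1.0
    candidates = np.arange(len(grid))
    if confine:
        candidates = candidates[np.sign(xy[:, 1]) == hemisign]
    seeds = rng.choice(candidates, size=n_clusters, replace=False)
    sigma_hi = spec.sigma_max + 0.4 * severity  # deeper damage is more extensive
    profile = np.zeros(len(grid))
    for s in seeds:
        sigma = rng.uniform(spec.sigma_min, sigma_hi)
        amp = rng.uniform(0.5, 1.0)
        d2 = np.sum((xy - xy[s]) ** 2, axis=1)
        profile += amp * np.exp(-d2 / (2 * sigma**2))
    return profile


def generate_glaucoma_field(
    model: NormativeModel,
    spec: ScotomaSpec,
    target_md: float,
    rng: np.random.Generator,
    grid: TestGrid | None = None,
    field_id: str = "",
) -> SensitivityField:
    """Glaucomatous field: scotoma clusters scaled to a target MD.

    A fixed depression profile (1-3 Gaussian clusters, depth decaying with
    distance from each cluster seed) is scaled by bisection until the
    realized MD — after clamping at the sensitivity floor — matches
    `target_md` within `spec.md_tolerance`.
    """
    grid = grid or build_24_2()
    ref = normative_field(grid, model)
    inc = _included(grid)
    noise = rng.normal(0.0, spec.noise_sd, size=len(grid))
    noise -= noise[inc].mean()
    profile = _cluster_depression(grid, spec, target_md, rng)

    def realized_md(scale: float) -> float:
        sens = np.clip(ref + noise - scale * profile, SENSITIVITY_FLOOR, SUPPORT_MAX)
        return float(np.mean(sens[inc] - ref[inc]))

    lo, hi = 0.0, 2000.0
    if realized_md(hi) > target_md + spec.md_tolerance:
        raise ValueError(f"glaucoma MD target {target_md} dB unreachable for this profile")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if realized_md(mid) > target_md:
            lo = mid
        else:
            hi = mid
    scale = 0.5 * (lo + hi)
    sens = np.clip(ref + noise - scale * profile, SENSITIVITY_FLOOR, SUPPORT_MAX)
    realized = float(np.mean(sens[inc] - ref[inc]))
    if abs(realized - target_md) > spec.md_tolerance:
        raise ValueError(
            f"glaucoma MD target {target_md} dB missed (realized {realized:.2f} dB)"
        )
    return SensitivityField(
        grid, sens, "glaucoma", realized, field_id=field_id,
        metadata={"target_md": target_md, "depression_scale": scale,
                  "scotoma_spec": asdict(spec),
                  "md_definition": "unweighted mean vs package normative model"},
    )


def mean_neighbor_difference(field: SensitivityField, max_separation: float = 6.01) -> float:
    """Mean |sensitivity difference| over orthogonally adjacent point pairs.

    A roughness measure: smooth normal hills score low, scotomatous fields
    high (steep scotoma edges).
    """
    total, count = 0.0, 0
    locs = field.grid.locations
    for i, a in enumerate(locs):
        for b in locs[i + 1:]:
            if (a.x - b.x) ** 2 + (a.y - b.y) ** 2 <= max_separation**2:
                total += abs(field.sensitivity[a.index] - field.sensitivity[b.index])
                count += 1
    return total / count


def make_study_cohort(
    rng: np.random.Generator,
    model: NormativeModel = NormativeModel(),
    scotoma_spec: ScotomaSpec = ScotomaSpec(),
    normal_noise_sd: float = 1.0,
    grid: TestGrid | None = None,
) -> list[SensitivityField]:
    """The 20-field study cohort: 10 normal + 10 glaucomatous fields.

    MD targets reproduce the emulated cohorts' printed medians and ranges
    (normals median -0.77 dB in [-1.78, 1.50]; glaucoma median -10.55 dB
    in [-20.82, -0.40]).
    """
    grid = grid or build_24_2()
    cohort: list[SensitivityField] = []
    for i, md in enumerate(NORMAL_MD_TARGETS):
        cohort.append(
            generate_normal_field(model, normal_noise_sd, md, rng, grid, field_id=f"N{i:02d}")
        )
    for i, md in enumerate(GLAUCOMA_MD_TARGETS):
        cohort.append(
            generate_glaucoma_field(model, scotoma_spec, md, rng, grid, field_id=f"G{i:02d}")
        )
    return cohort
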